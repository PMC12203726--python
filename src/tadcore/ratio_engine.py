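"""Intra-TAD / intra-scDomain ratio computation from five data modalities.

The coreness statistic of a genomic bin is the fraction of its observed
spatial contacts (multiplex-cluster co-members, pairwise contacts, nearest
structural neighbours, or imaged loci within a sphere) that lie in the same
domain as the bin.  Low values mark bins that tend to sit on the surface of
their chromatin domain's 3D structure; high values mark core bins.

Per-cluster normalisation: for bin *i* in cluster *j* with C_j unique member
bins, r_ij = N_ij / (C_j - 1) where N_ij counts same-TAD co-members; the
per-bin ratio r_i is the unweighted mean of r_ij over the clusters containing
bin *i* (each cluster one vote).  Bins without a TAD assignment contribute to
C_j (they are real cluster members) but receive no record themselves.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.stats import pearsonr, spearmanr

from .genome_model import BinIndex, RatioTrack, TADSet, bin_tad_map

logger = logging.getLogger(__name__)

__all__ = [
    "ClusterRatio",
    "StructureRatioParams",
    "ImagingParams",
    "SubsampleParams",
    "cluster_ratios",
    "sprite_ratio",
    "contact_ratio",
    "pairs_ratio",
    "structure_ratio",
    "split_track",
    "imaging_ratio",
    "average_tracks",
    "subsample_correlation",
]


@dataclass(frozen=True)
class ClusterRatio:
    """Per-(cluster, bin) ratio record: r_ij = n_intra / (cluster_size - 1)."""

    cluster_id: int
    bin_id: int
    n_intra: int
    cluster_size: int

    @property
    def ratio(self) -> float:
        return self.n_intra / (self.cluster_size - 1)


@dataclass
class StructureRatioParams:
    """Nearest-neighbour pathway settings for 3D structural models.

    k : number of Euclidean nearest neighbours examined per positioned bin.
    haplotype_aware : when True (diploid models), a neighbour counts as
        intra only if it shares both the TAD and the chromosome haplotype.
    split_to_resolution : optional finer bin size (bp); each parent bin's
        ratio is duplicated onto its children at that resolution.
    """

    k: int = 10
    haplotype_aware: bool = False
    split_to_resolution: int | None = None


@dataclass
class ImagingParams:
    """Imaging pathway settings; ``radius`` is the neighbourhood sphere in nm."""

    radius: float = 500.0


@dataclass
class SubsampleParams:
    """Cell-subsampling settings: draw ``x`` cells, ``repeats`` times."""

    x: int
    repeats: int = 100
    seed: int = 0


# ----------------------------------------------------------------- clusters


def cluster_ratios(cluster: np.ndarray, tad_of_bin: np.ndarray,
                   cluster_id: int = 0) -> list[ClusterRatio]:
    """Per-bin intra-TAD ratios within one multiplex cluster.

    ``cluster`` is the set of unique member bin ids (C_j = len(cluster) >= 2);
    ``tad_of_bin`` maps bin id -> TAD row (-1 = outside all TADs).  One record
    is emitted per TAD-assigned member; unassigned members only inflate C_j.
    """
    cluster = np.asarray(cluster, dtype=np.int64)
    c = len(cluster)
    if c < 2:
        raise ValueError(f"cluster of size {c} < 2 (pre-filter clusters first)")
    if len(np.unique(cluster)) != c:
        raise ValueError("cluster contains duplicate bins")
    tads = tad_of_bin[cluster]
    out = []
    for b, t in zip(cluster, tads):
        if t < 0:
            continue
        n_intra = int(np.sum(tads == t)) - 1
        out.append(ClusterRatio(cluster_id, int(b), n_intra, c))
    return out


def _tad_adjacency(tads: TADSet) -> tuple[np.ndarray, np.ndarray]:
    """Row numbers of the 1D-previous / next TAD on the same chromosome."""
    rec = tads.records
    n = len(rec)
    prev = np.full(n, -1, dtype=np.int64)
    nxt = np.full(n, -1, dtype=np.int64)
    for _, grp in rec.groupby("chrom", sort=False):
        rows = grp.index.to_numpy()
        prev[rows[1:]] = rows[:-1]
        nxt[rows[:-1]] = rows[1:]
    return prev, nxt


def _chrom_code_of_bins(index: BinIndex) -> np.ndarray:
    code = np.empty(index.n_bins, dtype=np.int64)
    for i, chrom in enumerate(index.chroms):
        off = index.chrom_offset(chrom)
        code[off : off + index.chrom_n_bins(chrom)] = i
    return code


def sprite_ratio(
    clusters: list[np.ndarray],
    tads: TADSet,
    index: BinIndex,
    min_bin_support: int = 100,
    mode: str = "genomewide",
    exclude_adjacent: bool = False,
) -> RatioTrack:
    """Average intra-TAD ratio per bin from SPRITE multiplex clusters.

    r_i is the unweighted mean of r_ij over the clusters containing bin i;
    bins supported by fewer than ``min_bin_support`` clusters are set missing.

    mode="intrachrom" first partitions each cluster into per-chromosome
    sub-clusters (re-deriving C_j per sub-cluster; sub-clusters of size 1 are
    dropped).  ``exclude_adjacent`` removes cluster members lying in the two
    TADs 1D-adjacent to bin i's TAD from the denominator (they are never
    intra, so N_ij is unaffected).
    """
    if mode not in ("genomewide", "intrachrom"):
        raise ValueError(f"unknown mode {mode!r}")
    if not clusters:
        raise ValueError("empty cluster list")
    tad_of_bin = bin_tad_map(tads, index)

    bins = np.concatenate(clusters)
    cid = np.repeat(np.arange(len(clusters), dtype=np.int64),
                    [len(c) for c in clusters])
    if mode == "intrachrom":
        chrom_code = _chrom_code_of_bins(index)
        n_code = len(index.chroms)
        cid = cid * n_code + chrom_code[bins]
    # compact sub-cluster ids
    _, cid = np.unique(cid, return_inverse=True)
    c_j = np.bincount(cid)
    tad = tad_of_bin[bins]

    keep = c_j[cid] >= 2  # size-1 (sub-)clusters carry no pair information
    bins, cid, tad = bins[keep], cid[keep], tad[keep]

    assigned = tad >= 0
    # count members per (cluster, tad) among assigned members
    df = pd.DataFrame({"cid": cid[assigned], "tad": tad[assigned]})
    n_ct = df.groupby(["cid", "tad"], sort=False)["cid"].transform("size").to_numpy()

    n_intra = n_ct - 1
    denom = (c_j[cid] - 1).astype(float)[assigned]
    if exclude_adjacent:
        prev, nxt = _tad_adjacency(tads)
        lookup = df.groupby(["cid", "tad"], sort=False).size().to_dict()
        a_cid = cid[assigned]
        a_tad = tad[assigned]
        excl = np.zeros(len(a_cid))
        for side in (prev, nxt):
            adj = side[a_tad]
            has = adj >= 0
            excl[has] += np.array(
                [lookup.get((c, t), 0) for c, t in zip(a_cid[has], adj[has])]
            )
        denom = denom - excl
    ok = denom > 0
    r = np.zeros(len(denom))
    r[ok] = n_intra[ok] / denom[ok]

    values = np.full(index.n_bins, np.nan)
    support = np.zeros(index.n_bins, dtype=np.int64)
    abins = bins[assigned][ok]
    np.add.at(support, abins, 1)
    acc = np.zeros(index.n_bins)
    np.add.at(acc, abins, r[ok])
    has = support > 0
    values[has] = acc[has] / support[has]
    low = has & (support < min_bin_support)
    if low.any():
        logger.info("sprite_ratio: %d bins below min support %d set missing",
                    int(low.sum()), min_bin_support)
    values[low] = np.nan
    support[low] = 0
    return RatioTrack(values, support)


# ----------------------------------------------------------------- contacts


def contact_ratio(
    contacts: pd.DataFrame,
    tads: TADSet,
    index: BinIndex,
    include_trans: bool = False,
) -> RatioTrack:
    """Intra-TAD contacts over total contacts per bin from pairwise data.

    ``contacts`` holds accumulated unordered bin-pair weights (bin1 <= bin2).
    Self-pairs are excluded; inter-chromosomal pairs count in the denominator
    only when ``include_trans``.  Contacts to TAD-unassigned partners count in
    the denominator only.  Bins with zero denominator are missing.
    """
    tad_of_bin = bin_tad_map(tads, index)
    b1 = contacts["bin1"].to_numpy(np.int64)
    b2 = contacts["bin2"].to_numpy(np.int64)
    w = contacts["weight"].to_numpy(float)
    keep = b1 != b2
    if not include_trans:
        chrom_code = _chrom_code_of_bins(index)
        keep &= chrom_code[b1] == chrom_code[b2]
    b1, b2, w = b1[keep], b2[keep], w[keep]

    t1, t2 = tad_of_bin[b1], tad_of_bin[b2]
    intra = (t1 == t2) & (t1 >= 0)
    total = np.zeros(index.n_bins)
    intra_sum = np.zeros(index.n_bins)
    support = np.zeros(index.n_bins, dtype=np.int64)
    for a, b in ((b1, b2), (b2, b1)):
        np.add.at(total, a, w)
        np.add.at(intra_sum, a, np.where(intra, w, 0.0))
        np.add.at(support, a, 1)
    values = np.full(index.n_bins, np.nan)
    # only TAD-assigned bins receive a ratio
    ok = (total > 0) & (tad_of_bin >= 0)
    values[ok] = intra_sum[ok] / total[ok]
    support[~ok] = 0
    return RatioTrack(values, support)


def average_tracks(tracks: list[RatioTrack]) -> RatioTrack:
    """Per-bin mean over tracks, ignoring missing; support = #contributors."""
    if not tracks:
        raise ValueError("no tracks to average")
    mat = np.vstack([t.values for t in tracks])
    count = np.sum(~np.isnan(mat), axis=0)
    with np.errstate(invalid="ignore"):
        mean = np.where(count > 0, np.nansum(mat, axis=0) / np.maximum(count, 1), np.nan)
    return RatioTrack(mean, count)


def pairs_ratio(
    per_cell_contacts: list[pd.DataFrame],
    tads: TADSet,
    index: BinIndex,
    include_trans: bool = False,
) -> tuple[list[RatioTrack], RatioTrack]:
    """Per-cell intra-TAD ratios from single-cell contacts plus their average.

    Each cell's ratio is :func:`contact_ratio` on that cell's pairs; the
    cell-averaged track ignores cells where a bin is unobserved, and its
    support counts contributing cells.
    """
    cell_tracks = [
        contact_ratio(c, tads, index, include_trans=include_trans)
        for c in per_cell_contacts
    ]
    return cell_tracks, average_tracks(cell_tracks)


# --------------------------------------------------------------- structures


def _knn_ratio_one_model(
    model: pd.DataFrame,
    tad_of_bin: np.ndarray,
    k: int,
    haplotype_aware: bool,
    n_bins: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-bin ratio sums and counts from one structural model."""
    xyz = model[["x", "y", "z"]].to_numpy(float)
    bins = model["bin"].to_numpy(np.int64)
    haps = model["hap"].astype(str).to_numpy()
    n = len(model)
    acc = np.zeros(n_bins)
    cnt = np.zeros(n_bins, dtype=np.int64)
    if n < k + 1:
        logger.info("structure model with %d < k+1 points skipped", n)
        return acc, cnt
    tads = tad_of_bin[bins]
    # k nearest neighbours, ties at the k-th distance broken by ascending
    # bin id (then haplotype) for determinism
    tree = cKDTree(xyz)
    kq = min(n, k + 1)
    dist, idx = tree.query(xyz, k=kq)
    order = np.lexsort((bins[idx], np.round(dist, 9)), axis=-1)
    idx = np.take_along_axis(idx, order, axis=-1)
    # drop self from each row (stable sort pushes self occurrences to the end)
    self_mask = idx == np.arange(n)[:, None]
    push = np.argsort(np.where(self_mask, 1, 0), axis=1, kind="stable")
    neigh = np.take_along_axis(idx, push, axis=1)[:, :k]
    same = tads[neigh] == tads[:, None]
    if haplotype_aware:
        same &= haps[neigh] == haps[:, None]
    ratio = same.sum(axis=1) / k
    ok = tads >= 0
    np.add.at(acc, bins[ok], ratio[ok])
    np.add.at(cnt, bins[ok], 1)
    return acc, cnt


def structure_ratio(
    structures: list[pd.DataFrame],
    tads: TADSet,
    index: BinIndex,
    params: StructureRatioParams | None = None,
) -> RatioTrack:
    """Intra-TAD ratio from 3D structural models via k nearest neighbours.

    For each positioned bin of each model, the ratio is the fraction of its
    ``k`` Euclidean nearest neighbours (over all positioned bins of that
    model) lying in the same TAD — and, when ``haplotype_aware``, on the same
    chromosome haplotype.  Ratios are averaged over all rows of all models
    that cover a bin.  ``index`` is the native resolution of the structures;
    with ``split_to_resolution`` set, the returned track aligns to
    ``BinIndex(index.chrom_sizes, split_to_resolution)`` with each parent
    bin's value duplicated onto its children.
    """
    params = params or StructureRatioParams()
    if params.k < 1:
        raise ValueError("k must be >= 1")
    tad_of_bin = bin_tad_map(tads, index)
    acc = np.zeros(index.n_bins)
    cnt = np.zeros(index.n_bins, dtype=np.int64)
    for model in structures:
        a, c = _knn_ratio_one_model(
            model, tad_of_bin, params.k, params.haplotype_aware, index.n_bins
        )
        acc += a
        cnt += c
    values = np.full(index.n_bins, np.nan)
    has = cnt > 0
    values[has] = acc[has] / cnt[has]
    track = RatioTrack(values, cnt)
    if params.split_to_resolution is not None:
        track, _ = split_track(track, index, params.split_to_resolution)
    return track


def split_track(
    track: RatioTrack, index: BinIndex, fine_bin_size: int
) -> tuple[RatioTrack, BinIndex]:
    """Duplicate each parent bin's value onto its children at a finer size.

    ``fine_bin_size`` must divide the parent bin size; e.g. a 20 kb bin's
    ratio is assigned unchanged to its two virtual 10 kb bins.
    """
    if index.bin_size % fine_bin_size != 0:
        raise ValueError(
            f"fine bin size {fine_bin_size} does not divide {index.bin_size}"
        )
    fine = BinIndex(index.chrom_sizes, fine_bin_size)
    values = np.full(fine.n_bins, np.nan)
    support = np.zeros(fine.n_bins, dtype=np.int64)
    for chrom in index.chroms:
        off_c = index.chrom_offset(chrom)
        off_f = fine.chrom_offset(chrom)
        n_f = fine.chrom_n_bins(chrom)
        parent = np.arange(n_f) * fine_bin_size // index.bin_size
        values[off_f : off_f + n_f] = track.values[off_c + parent]
        support[off_f : off_f + n_f] = track.support[off_c + parent]
    return RatioTrack(values, support), fine


# ------------------------------------------------------------------ imaging


def imaging_ratio(
    imaging: pd.DataFrame,
    segmentation: pd.DataFrame,
    index: BinIndex,
    params: ImagingParams | None = None,
) -> dict:
    """Per-cell intra-scDomain ratios from chromatin-tracing coordinates.

    For each imaged bin of each cell, the neighbourhood is the set of other
    imaged bins within ``radius`` nm of its coordinates; the ratio is the
    fraction of the neighbourhood belonging to the bin's scDomain in that
    cell.  Bins with missing coordinates, no neighbours in the sphere, or no
    domain label are missing.
    """
    params = params or ImagingParams()
    seg_by_cell = dict(tuple(segmentation.groupby("cell_id", sort=False)))
    out = {}
    for cell_id, cell in imaging.groupby("cell_id", sort=False):
        values = np.full(index.n_bins, np.nan)
        support = np.zeros(index.n_bins, dtype=np.int64)
        seg = seg_by_cell.get(cell_id)
        if seg is None:
            out[cell_id] = RatioTrack(values, support)
            continue
        obs = cell.dropna(subset=["x", "y", "z"])
        bins = index.assign_bins(obs["chrom"].to_numpy(), obs["start"].to_numpy())
        xyz = obs[["x", "y", "z"]].to_numpy(float)
        # domain label of each imaged bin from the cell's segmentation
        dom_starts = seg["start"].to_numpy()
        dom_ends = seg["end"].to_numpy()
        dom_ids = seg["domain_id"].to_numpy()
        mids = obs["start"].to_numpy() + index.bin_size / 2.0
        pos = np.searchsorted(dom_starts, mids, side="right") - 1
        label = np.full(len(obs), -1, dtype=np.int64)
        okpos = pos >= 0
        inside = np.zeros(len(obs), dtype=bool)
        inside[okpos] = mids[okpos] < dom_ends[pos[okpos]]
        label[inside] = dom_ids[pos[inside]]
        if len(obs) >= 2:
            tree = cKDTree(xyz)
            neighbors = tree.query_ball_point(xyz, params.radius)
            for row, neigh in enumerate(neighbors):
                if label[row] < 0:
                    continue
                neigh = [m for m in neigh if m != row]
                if not neigh:
                    continue
                same = np.sum(label[neigh] == label[row])
                values[bins[row]] = same / len(neigh)
                support[bins[row]] = len(neigh)
        out[cell_id] = RatioTrack(values, support)
    return out


# -------------------------------------------------------------- subsampling


def subsample_correlation(
    per_cell_tracks: list[RatioTrack],
    reference: RatioTrack,
    params: SubsampleParams,
) -> pd.DataFrame:
    """Correlation of cell-subsampled average ratios with a reference track.

    Each repeat draws ``x`` cells without replacement (seeded), averages their
    per-bin ratios (pairwise-complete), and correlates the average with the
    reference over jointly non-missing bins.  Returns one row per repeat with
    Pearson and Spearman correlations.
    """
    n_cells = len(per_cell_tracks)
    if params.x > n_cells:
        raise ValueError(f"x={params.x} exceeds available cells ({n_cells})")
    rng = np.random.default_rng(params.seed)
    rows = []
    for _ in range(params.repeats):
        draw = np.sort(rng.choice(n_cells, size=params.x, replace=False))
        avg = average_tracks([per_cell_tracks[i] for i in draw])
        joint = avg.mask & reference.mask
        a = avg.values[joint]
        b = reference.values[joint]
        if len(a) < 3 or np.std(a) == 0 or np.std(b) == 0:
            rows.append((np.nan, np.nan))
            continue
        rows.append((pearsonr(a, b)[0], spearmanr(a, b)[0]))
    return pd.DataFrame(rows, columns=["pearson", "spearman"])
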