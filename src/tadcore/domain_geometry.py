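"""Single-cell domain geometry: segmentation, hulls, co-membership, coreness.

Operates on one chromosome region imaged per cell: an array of 3D
coordinates aligned to consecutive genomic bins (NaN rows = locus not
detected).  scDomains are called from spatial insulation of the distance
matrix; convex-hull vertices mark loci on the exterior of a domain's point
cloud; geometric coreness is the normalised depth of a locus inside its
domain, used as ground truth for synthetic data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError
from scipy.spatial.distance import cdist, pdist

from .genome_model import BinIndex

logger = logging.getLogger(__name__)

__all__ = [
    "ScDomainSegmentation",
    "call_scdomains",
    "hull_vertices",
    "comembership_counts",
    "geometric_coreness",
    "segmentation_frame",
    "labels_from_segmentation",
]


@dataclass
class ScDomainSegmentation:
    """One cell's partition of the imaged region into scDomains.

    ``boundaries`` are the strictly increasing start positions (bin offsets
    within the region) of the second and later domains; ``labels[i]`` is the
    domain id (0-based, left to right) of bin offset ``i``.
    """

    boundaries: np.ndarray
    labels: np.ndarray
    insulation: np.ndarray | None = None

    def __post_init__(self):
        self.boundaries = np.asarray(self.boundaries, dtype=np.int64)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if np.any(np.diff(self.boundaries) <= 0):
            raise ValueError("boundaries must be strictly increasing")

    @property
    def n_domains(self) -> int:
        return len(self.boundaries) + 1


def _insulation_scores(coords: np.ndarray, w: int, min_usable: int = 3) -> np.ndarray:
    """Spatial insulation score at every inter-bin position.

    Score at position i contrasts the w bins upstream ([i-w, i)) with the w
    bins downstream ([i, i+w)): median cross-window pairwise distance over
    the median of within-window pairwise distances.  Missing-coordinate bins
    are skipped; a window with fewer than ``min_usable`` positioned bins
    yields no score (NaN).
    """
    n = len(coords)
    ok = ~np.isnan(coords).any(axis=1)
    scores = np.full(n, np.nan)
    for i in range(w, n - w + 1):
        up = coords[max(0, i - w) : i][ok[max(0, i - w) : i]]
        down = coords[i : i + w][ok[i : i + w]]
        if len(up) < min_usable or len(down) < min_usable:
            continue
        cross = np.median(cdist(up, down))
        within = np.median(np.concatenate([pdist(up), pdist(down)]))
        if within > 0:
            scores[i] = cross / within
    return scores


def call_scdomains(
    cell_coords: np.ndarray,
    window_w: int = 5,
    boundary_prominence: float = 1.2,
    merge_threshold: float = 0.9,
) -> ScDomainSegmentation:
    """Segment one cell's imaged region into scDomains.

    Local maxima of the spatial insulation score whose topographic
    prominence exceeds ``boundary_prominence`` become candidate boundaries;
    adjacent domains whose cross-domain median distance falls below
    ``merge_threshold`` times their pooled within-domain median distance are
    then merged (similar-pattern removal).
    """
    coords = np.asarray(cell_coords, dtype=float)
    n = len(coords)
    ok = ~np.isnan(coords).any(axis=1)
    if not ok.any():
        raise ValueError("all coordinates missing")
    if n < 2 * window_w:
        return ScDomainSegmentation(np.array([], dtype=np.int64),
                                    np.zeros(n, dtype=np.int64))
    scores = _insulation_scores(coords, window_w)
    finite = np.flatnonzero(~np.isnan(scores))
    from scipy.signal import find_peaks

    # topographic prominence separates real inter-domain peaks from the
    # ~1.0-level fluctuation of the score inside a domain
    peaks, _ = find_peaks(scores[finite], prominence=boundary_prominence)
    boundaries = list(finite[peaks])
    # enforce minimum domain width of 2 bins between consecutive boundaries
    filtered = []
    for b in boundaries:
        if filtered and b - filtered[-1] < 2:
            if scores[b] > scores[filtered[-1]]:
                filtered[-1] = b
        else:
            filtered.append(b)
    boundaries = filtered

    def labels_from(bnds):
        lab = np.zeros(n, dtype=np.int64)
        for d, b in enumerate(bnds, start=1):
            lab[b:] = d
        return lab

    # merge adjacent domains with similar spatial patterns
    merged = True
    while merged and boundaries:
        merged = False
        labels = labels_from(boundaries)
        for j, b in enumerate(boundaries):
            left = coords[(labels == j) & ok]
            right = coords[(labels == j + 1) & ok]
            if len(left) < 2 or len(right) < 2:
                continue
            cross = np.median(cdist(left, right))
            within = np.median(np.concatenate([pdist(left), pdist(right)]))
            if within > 0 and cross < merge_threshold * within:
                boundaries.pop(j)
                merged = True
                break
    return ScDomainSegmentation(
        np.array(boundaries, dtype=np.int64), labels_from(boundaries), scores
    )


def hull_vertices(cell_coords: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Flag bins on the convex hull of their scDomain's 3D point cloud.

    Returns a float vector per bin: 1.0 vertex, 0.0 interior, NaN for bins
    without coordinates.  Domains with fewer than four positioned bins, or
    degenerate (coplanar) geometry, have all their positioned bins labeled
    vertex by convention.
    """
    coords = np.asarray(cell_coords, dtype=float)
    labels = np.asarray(labels)
    ok = ~np.isnan(coords).any(axis=1)
    out = np.full(len(coords), np.nan)
    for dom in np.unique(labels):
        sel = np.flatnonzero((labels == dom) & ok)
        if len(sel) == 0:
            continue
        if len(sel) < 4:
            out[sel] = 1.0
            continue
        try:
            hull = ConvexHull(coords[sel])
        except QhullError:
            out[sel] = 1.0
            continue
        out[sel] = 0.0
        out[sel[hull.vertices]] = 1.0
    return out


def geometric_coreness(cell_coords: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Normalised depth of each bin inside its domain: 1 = at the centroid.

    coreness = 1 - (distance to domain centroid) / (max such distance in the
    domain).  NaN for bins without coordinates; if all of a domain's bins
    coincide, they all get coreness 1.
    """
    coords = np.asarray(cell_coords, dtype=float)
    labels = np.asarray(labels)
    ok = ~np.isnan(coords).any(axis=1)
    out = np.full(len(coords), np.nan)
    for dom in np.unique(labels):
        sel = np.flatnonzero((labels == dom) & ok)
        if len(sel) == 0:
            continue
        pts = coords[sel]
        d = np.linalg.norm(pts - pts.mean(axis=0), axis=1)
        dmax = d.max()
        out[sel] = 1.0 - d / dmax if dmax > 0 else 1.0
    return out


def comembership_counts(
    tads_same: np.ndarray,
    segmentations: list[np.ndarray],
    separations: list[int],
) -> pd.DataFrame:
    """Count, per bin pair at fixed 1D separations, cells sharing an scDomain.

    ``tads_same`` is a per-bin TAD assignment over the imaged region (-1 =
    none); ``segmentations`` holds one per-bin domain-label vector per cell
    (-1 = bin not imaged/labeled in that cell).  For each ordered pair
    (i, i+sep) the result records whether the two bins share a TAD and in how
    many cells they are co-imaged and co-labeled.
    """
    rows = []
    n = len(tads_same)
    seg = np.vstack(segmentations)  # cells x bins
    for sep in separations:
        if sep <= 0 or sep >= n:
            continue
        i = np.arange(n - sep)
        j = i + sep
        both = (seg[:, i] >= 0) & (seg[:, j] >= 0)
        co = both & (seg[:, i] == seg[:, j])
        same_tad = (tads_same[i] == tads_same[j]) & (tads_same[i] >= 0)
        for a, b, st, nb, nc in zip(i, j, same_tad, both.sum(axis=0), co.sum(axis=0)):
            rows.append((sep, int(a), int(b), bool(st), int(nb), int(nc)))
    return pd.DataFrame(
        rows,
        columns=["separation", "bin1", "bin2", "same_tad", "n_both_imaged", "n_comember"],
    )


# ----------------------------------------------------------------- plumbing


def segmentation_frame(
    labels: np.ndarray, index: BinIndex, chrom: str, cell_id,
    region_offset_bins: int = 0,
) -> pd.DataFrame:
    """Run-length encode per-bin domain labels into the segmentation TSV form."""
    labels = np.asarray(labels)
    rows = []
    start = 0
    for i in range(1, len(labels) + 1):
        if i == len(labels) or labels[i] != labels[start]:
            s_bp = (region_offset_bins + start) * index.bin_size
            e_bp = min((region_offset_bins + i) * index.bin_size,
                       index.chrom_sizes[chrom])
            rows.append((cell_id, chrom, s_bp, e_bp, int(labels[start])))
            start = i
    return pd.DataFrame(rows, columns=["cell_id", "chrom", "start", "end", "domain_id"])


def labels_from_segmentation(seg: pd.DataFrame, index: BinIndex) -> np.ndarray:
    """Per-bin domain id (-1 outside all domains) from one cell's segmentation."""
    out = np.full(index.n_bins, -1, dtype=np.int64)
    for chrom, grp in seg.groupby("chrom", sort=False):
        grp = grp.sort_values("start")
        off = index.chrom_offset(chrom)
        nb = index.chrom_n_bins(chrom)
        starts = np.arange(nb) * index.bin_size
        ends = np.minimum(starts + index.bin_size, index.chrom_sizes[chrom])
        mids = (starts + ends) / 2.0
        pos = np.searchsorted(grp["start"].to_numpy(), mids, side="right") - 1
        okpos = pos >= 0
        inside = np.zeros(nb, dtype=bool)
        inside[okpos] = mids[okpos] < grp["end"].to_numpy()[pos[okpos]]
        out[off : off + nb][inside] = grp["domain_id"].to_numpy()[pos[inside]]
    return out
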