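"""Self-contained generator of single-cell chromatin-domain data.

The generative model emulates the data modalities the ratio pipeline
consumes, with a known per-bin ground truth:

* one synthetic chromosome tiled by domains whose consensus intervals are
  the TADs; each cell's domain boundaries are the consensus plus a small
  1D jitter (scDomain boundary variability);
* each cell's domains are balls whose radius grows as n_k^(1/3) (constant
  density), with centres following a 3D random walk stepping by the sum of
  adjacent radii, so consecutive domains touch;
* every bin has a persistent *coreness tendency* t in [0, 1]; in each cell
  its normalised radial position inside its domain ball is a
  persistence-weighted mixture of (1 - t) and uniform noise, so high-t bins
  tend to sit near the domain centre in every cell;
* SPRITE-like clusters are spatially proximal bin sets around a random
  anchor; pairwise contacts are distance-thresholded bin pairs; expression
  has a stated negative dependence on tendency; features are implanted on
  truth-surface bins at a stated enrichment fold.

All randomness flows from ``SimConfig.seed`` through named
``numpy.random.SeedSequence`` children, so any single artifact can be
regenerated in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .genome_model import BinIndex, IntervalSet, RatioTrack, SignalTrack, TADSet
from .surface_core import classify

__all__ = [
    "SimConfig",
    "SimData",
    "gen_genome",
    "gen_tendency",
    "gen_structures",
    "gen_sprite",
    "gen_contacts",
    "gen_pairs",
    "gen_imaging",
    "gen_signals",
    "simulate",
]

_STREAMS = ("genome", "tendency", "structures", "sprite", "contacts", "signals",
            "features", "imaging")


@dataclass(frozen=True)
class SimConfig:
    """Generator settings.  Defaults are the package's standard conditions.

    Geometry is in nanometers.  ``domain_radius_scale`` sets the ball radius
    of a domain with n bins to ``domain_radius_scale * n^(1/3)`` (about
    370 nm for a 50-bin domain, i.e. sub-micron scDomains).
    ``coreness_persistence`` in [0, 1] is the weight of a bin's persistent
    tendency in its per-cell radial placement (0 = fully random each cell).
    ``expression_effect`` is the slope of log-expression on tendency
    (negative: core bins are less expressed).  ``feature_fold`` is the
    target surface enrichment fold at which features are implanted.
    """

    n_domains: int = 20
    bins_per_domain_mean: int = 50
    bins_per_domain_dispersion: float = 10.0
    gap_bins_mean: float = 0.0
    n_cells: int = 500
    bin_size: int = 10_000
    domain_radius_scale: float = 100.0
    boundary_jitter: float = 2.0
    coreness_persistence: float = 0.8
    cluster_radius: float = 200.0
    clusters_per_cell: int = 200
    contact_threshold: float = 300.0
    expression_intercept: float = 3.0
    expression_effect: float = -2.0
    noise_sd: float = 0.5
    feature_fold: float = 3.0
    feature_density: float = 0.08
    imaging_missing_rate: float = 0.10
    chrom_name: str = "chrS"
    seed: int = 0

    def rng(self, stream: str) -> np.random.Generator:
        """Named child generator, independent per data product."""
        if stream not in _STREAMS:
            raise KeyError(f"unknown stream {stream!r}")
        ss = np.random.SeedSequence(self.seed).spawn(len(_STREAMS))
        return np.random.default_rng(ss[_STREAMS.index(stream)])


@dataclass
class SimData:
    """Everything one simulation produced, in memory."""

    cfg: SimConfig
    index: BinIndex
    tads: TADSet
    tendency: np.ndarray
    cells: list  # per-cell (n_bins, 3) nm coordinates
    cell_labels: list  # per-cell per-bin domain labels
    clusters: list = field(default_factory=list)
    contacts: pd.DataFrame | None = None
    per_cell_contacts: list = field(default_factory=list)
    imaging: pd.DataFrame | None = None
    segmentation: pd.DataFrame | None = None
    expression: SignalTrack | None = None
    features: IntervalSet | None = None


def gen_genome(cfg: SimConfig) -> tuple[BinIndex, TADSet]:
    """One synthetic chromosome tiled by domains; consensus TADs.

    Domain sizes are Normal(mean, dispersion) rounded, at least 5 bins;
    optional inter-domain gaps are Poisson(gap_bins_mean) bins.
    """
    rng = cfg.rng("genome")
    sizes = np.maximum(
        5,
        np.rint(
            rng.normal(cfg.bins_per_domain_mean, cfg.bins_per_domain_dispersion,
                       cfg.n_domains)
        ).astype(int),
    )
    gaps = (
        rng.poisson(cfg.gap_bins_mean, cfg.n_domains)
        if cfg.gap_bins_mean > 0
        else np.zeros(cfg.n_domains, dtype=int)
    )
    rows = []
    cursor = 0
    for k, (n, g) in enumerate(zip(sizes, gaps)):
        start = cursor * cfg.bin_size
        end = (cursor + n) * cfg.bin_size
        rows.append((cfg.chrom_name, start, end, f"TAD_{k:03d}"))
        cursor += n + g
    length = cursor * cfg.bin_size
    index = BinIndex({cfg.chrom_name: length}, cfg.bin_size)
    tads = TADSet(pd.DataFrame(rows, columns=["chrom", "start", "end", "tad_id"]))
    return index, tads


def _consensus_boundaries(tads: TADSet, index: BinIndex) -> np.ndarray:
    """Internal domain-start bin offsets (excluding 0) for the jitter model."""
    starts = tads.records["start"].to_numpy() // index.bin_size
    return starts[1:].astype(np.int64)


def _random_units(rng: np.random.Generator, n: int) -> np.ndarray:
    v = rng.normal(size=(n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def gen_tendency(cfg: SimConfig, index: BinIndex) -> np.ndarray:
    """Per-bin persistent coreness tendency in [0, 1] (1 = deepest core)."""
    return cfg.rng("tendency").uniform(0.0, 1.0, index.n_bins)


def gen_structures(
    cfg: SimConfig, index: BinIndex, tads: TADSet
) -> tuple[list[np.ndarray], list[np.ndarray], np.ndarray]:
    """Per-cell 3D coordinates, per-cell domain labels, per-bin tendency.

    Returns ``(cells, cell_labels, tendency)`` where ``cells[c]`` is an
    (n_bins, 3) nm coordinate array and ``cell_labels[c]`` the per-bin
    scDomain label of cell c (consensus boundaries jittered per cell).
    """
    n_bins = index.n_bins
    tendency = gen_tendency(cfg, index)
    rng = cfg.rng("structures")
    consensus = _consensus_boundaries(tads, index)
    p = cfg.coreness_persistence
    cells, cell_labels = [], []
    for _ in range(cfg.n_cells):
        if cfg.boundary_jitter > 0 and len(consensus):
            shift = np.rint(rng.normal(0, cfg.boundary_jitter, len(consensus)))
            bnds = consensus + shift.astype(np.int64)
        else:
            bnds = consensus.copy()
        # keep boundaries ordered with at least 2 bins per domain
        prev = 0
        for i in range(len(bnds)):
            lo = prev + 2
            hi = n_bins - 2 * (len(bnds) - i)
            bnds[i] = min(max(bnds[i], lo), hi)
            prev = bnds[i]
        labels = np.zeros(n_bins, dtype=np.int64)
        for d, b in enumerate(bnds, start=1):
            labels[b:] = d
        dom_sizes = np.bincount(labels)
        radii = cfg.domain_radius_scale * dom_sizes ** (1.0 / 3.0)
        centers = np.zeros((len(dom_sizes), 3))
        for d in range(1, len(dom_sizes)):
            step = radii[d - 1] + radii[d]
            centers[d] = centers[d - 1] + _random_units(rng, 1)[0] * step
        u = np.clip(
            p * (1.0 - tendency) + (1.0 - p) * rng.uniform(0.0, 1.0, n_bins),
            0.0, 1.0,
        )
        coords = centers[labels] + _random_units(rng, n_bins) * (
            u * radii[labels]
        )[:, None]
        cells.append(coords)
        cell_labels.append(labels)
    return cells, cell_labels, tendency


def gen_sprite(cfg: SimConfig, cells: list[np.ndarray]) -> list[np.ndarray]:
    """Spatially proximal bin sets, one anchor per cluster, per cell.

    Each cluster takes the bins within ``cluster_radius`` of a uniformly
    chosen anchor bin in one cell and subsamples them to a log-uniform
    target size in [2, 1000]; clusters that cannot reach 2 members are
    skipped.
    """
    rng = cfg.rng("sprite")
    clusters = []
    log_lo, log_hi = np.log(2.0), np.log(1000.0)
    for coords in cells:
        tree = cKDTree(coords)
        anchors = rng.integers(0, len(coords), cfg.clusters_per_cell)
        targets = np.rint(np.exp(rng.uniform(log_lo, log_hi,
                                             cfg.clusters_per_cell))).astype(int)
        for anchor, target in zip(anchors, targets):
            members = np.array(tree.query_ball_point(coords[anchor],
                                                     cfg.cluster_radius))
            if len(members) < 2:
                continue
            size = min(max(target, 2), len(members))
            pick = rng.choice(members, size=size, replace=False)
            clusters.append(np.sort(pick).astype(np.int64))
    return clusters


def _cell_contact_pairs(coords: np.ndarray, threshold: float) -> np.ndarray:
    if threshold <= 0:
        return np.empty((0, 2), dtype=np.int64)
    tree = cKDTree(coords)
    pairs = tree.query_pairs(threshold, output_type="ndarray")
    return pairs.astype(np.int64)


def gen_contacts(cfg: SimConfig, cells: list[np.ndarray]) -> pd.DataFrame:
    """Bulk contacts: distance-thresholded bin pairs accumulated over cells."""
    counts: dict = {}
    frames = []
    for coords in cells:
        pairs = _cell_contact_pairs(coords, cfg.contact_threshold)
        frames.append(pairs)
    if not frames or sum(len(f) for f in frames) == 0:
        return pd.DataFrame({"bin1": [], "bin2": [], "weight": []})
    allp = np.vstack(frames)
    df = pd.DataFrame({"bin1": allp[:, 0], "bin2": allp[:, 1]})
    out = df.groupby(["bin1", "bin2"], as_index=False, sort=True).size()
    out = out.rename(columns={"size": "weight"})
    out["weight"] = out["weight"].astype(float)
    return out


def gen_pairs(cfg: SimConfig, cells: list[np.ndarray]) -> list[pd.DataFrame]:
    """Per-cell contacts (the .pairs modality), weight 1 per observed pair."""
    out = []
    for coords in cells:
        pairs = _cell_contact_pairs(coords, cfg.contact_threshold)
        out.append(
            pd.DataFrame(
                {"bin1": pairs[:, 0], "bin2": pairs[:, 1],
                 "weight": np.ones(len(pairs))}
            )
        )
    return out


def gen_imaging(
    cfg: SimConfig,
    index: BinIndex,
    cells: list[np.ndarray],
    cell_labels: list[np.ndarray],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Chromatin-tracing read-out: per-cell coordinates plus segmentation.

    A fraction ``imaging_missing_rate`` of loci per cell fail detection
    (missing coordinates), emulating imaging dropout.
    """
    rng = cfg.rng("imaging")
    bins = index.bins_frame()
    img_rows, seg_rows = [], []
    for c, (coords, labels) in enumerate(zip(cells, cell_labels)):
        xyz = coords.copy()
        drop = rng.random(len(xyz)) < cfg.imaging_missing_rate
        xyz[drop] = np.nan
        df = bins.copy()
        df.insert(0, "cell_id", c)
        df["x"], df["y"], df["z"] = xyz[:, 0], xyz[:, 1], xyz[:, 2]
        img_rows.append(df)
        # run-length encode labels into segmentation intervals
        start = 0
        for i in range(1, len(labels) + 1):
            if i == len(labels) or labels[i] != labels[start]:
                seg_rows.append(
                    (c, cfg.chrom_name, start * cfg.bin_size,
                     min(i * cfg.bin_size, index.chrom_sizes[cfg.chrom_name]),
                     int(labels[start]))
                )
                start = i
    imaging = pd.concat(img_rows, ignore_index=True)
    segmentation = pd.DataFrame(
        seg_rows, columns=["cell_id", "chrom", "start", "end", "domain_id"]
    )
    return imaging, segmentation


def truth_surface_labels(cfg: SimConfig, index: BinIndex, tads: TADSet,
                         tendency: np.ndarray):
    """Ground-truth surface/core labels: the q_k rule applied to 'tendency'.

    Uses the same classifier as the analysis, so implantation and recovery
    share one definition of 'surface'.
    """
    return classify(RatioTrack(tendency), tads, index)


def gen_signals(
    cfg: SimConfig, index: BinIndex, tads: TADSet, tendency: np.ndarray
) -> tuple[SignalTrack, IntervalSet]:
    """Expression with negative coreness dependence; implanted surface features.

    log-expression = intercept + expression_effect * tendency + N(0, noise_sd).
    Features are drawn without replacement from TAD bins with per-bin odds
    chosen so the expected surface enrichment fold (d/c)/(b/a) equals
    ``feature_fold``.
    """
    rng_sig = cfg.rng("signals")
    noise = rng_sig.normal(0.0, cfg.noise_sd, index.n_bins) if cfg.noise_sd > 0 \
        else np.zeros(index.n_bins)
    expr = cfg.expression_intercept + cfg.expression_effect * tendency + noise
    expression = SignalTrack(expr)

    labels = truth_surface_labels(cfg, index, tads, tendency)
    universe = np.flatnonzero(labels.labels != -1)
    surface = labels.surface_mask[universe]
    a, b = len(universe), int(surface.sum())
    m = max(1, int(round(cfg.feature_density * a)))
    f = cfg.feature_fold
    # odds w on surface bins such that expected d/m equals f * b / a
    if f * b >= a:
        w = np.inf
    else:
        w = f * (a - b) / (a - f * b)
    weights = np.where(surface, w, 1.0)
    if np.isinf(w):
        weights = np.where(surface, 1.0, 0.0)
    weights = weights / weights.sum()
    rng_feat = cfg.rng("features")
    chosen = rng_feat.choice(universe, size=m, replace=False, p=weights)
    rows = []
    for bin_id in np.sort(chosen):
        chrom, start, end = index.bin_location(int(bin_id))
        rows.append((chrom, start, end, "feature"))
    features = IntervalSet(pd.DataFrame(rows, columns=["chrom", "start", "end", "label"]))
    return expression, features


def structures_as_tables(index: BinIndex, cells: list[np.ndarray],
                         hap: str = "") -> list[pd.DataFrame]:
    """Per-cell coordinate arrays as structural-model tables (one per cell)."""
    bins = index.bins_frame()
    out = []
    for coords in cells:
        df = pd.DataFrame(
            {
                "chrom": bins["chrom"],
                "hap": hap,
                "start": bins["start"],
                "bin": np.arange(index.n_bins, dtype=np.int64),
                "x": coords[:, 0],
                "y": coords[:, 1],
                "z": coords[:, 2],
            }
        )
        out.append(df)
    return out


def simulate(cfg: SimConfig, modalities: tuple[str, ...] = ("all",)) -> SimData:
    """Run the full generator (or selected modalities) from one seed."""
    want = set(modalities)
    everything = "all" in want
    index, tads = gen_genome(cfg)
    cells, cell_labels, tendency = gen_structures(cfg, index, tads)
    sim = SimData(cfg, index, tads, tendency, cells, cell_labels)
    if everything or "sprite" in want:
        sim.clusters = gen_sprite(cfg, cells)
    if everything or "contacts" in want:
        sim.contacts = gen_contacts(cfg, cells)
    if everything or "pairs" in want:
        sim.per_cell_contacts = gen_pairs(cfg, cells)
    if everything or "imaging" in want:
        sim.imaging, sim.segmentation = gen_imaging(cfg, index, cells, cell_labels)
    if everything or "signals" in want:
        sim.expression, sim.features = gen_signals(cfg, index, tads, tendency)
    return sim
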