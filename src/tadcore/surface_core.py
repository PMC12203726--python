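"""Surface/core classification of bins within TADs and the shuffled-TAD null.

A TAD of n_k bins gets the quantile threshold q_k = n_k^(-1/3), motivated by
the surface-to-volume ratio of a sphere (S/V ∝ V^(-1/3)): bins whose
intra-TAD ratio is smaller than or equal to the q_k-th empirical quantile of
the TAD's non-missing ratios are *surface*, the rest *core*.  The shuffled-TAD
null permutes the interleaved list of TAD lengths and gap lengths per
chromosome, preserving both multisets exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome_model import BinIndex, RatioTrack, TADSet, bin_tad_map

logger = logging.getLogger(__name__)

__all__ = [
    "SurfaceCoreLabels",
    "SURFACE",
    "CORE",
    "EXCLUDED",
    "classify",
    "exclude_boundaries",
    "shuffle_tads",
]

SURFACE = 0
CORE = 1
EXCLUDED = -1

_LABEL_NAMES = {SURFACE: "surface", CORE: "core", EXCLUDED: "excluded"}


@dataclass
class SurfaceCoreLabels:
    """Per-bin surface/core labels plus the per-TAD thresholds that made them.

    ``labels[i]`` is SURFACE, CORE or EXCLUDED (bins outside TADs, with
    missing ratio, or removed by boundary exclusion).  ``per_tad`` has one
    row per TAD: tad_id, n_k, q_k = n_k^(-1/3) and the ratio value at that
    quantile.
    """

    labels: np.ndarray
    per_tad: pd.DataFrame

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=np.int64)

    @property
    def surface_mask(self) -> np.ndarray:
        return self.labels == SURFACE

    @property
    def core_mask(self) -> np.ndarray:
        return self.labels == CORE

    def to_frame(self, index: BinIndex, tads: TADSet) -> pd.DataFrame:
        df = index.bins_frame()
        tad_of_bin = bin_tad_map(tads, index)
        ids = np.array(tads.tad_ids + ["."], dtype=object)
        df["tad_id"] = ids[tad_of_bin]
        df["label"] = [_LABEL_NAMES[v] for v in self.labels]
        return df


def classify(track: RatioTrack, tads: TADSet, index: BinIndex) -> SurfaceCoreLabels:
    """Label bins surface/core within each TAD at the q_k = n_k^(-1/3) quantile.

    The threshold is the empirical quantile (linear interpolation between
    order statistics) of the TAD's non-missing ratios; the comparison is
    inclusive (ratio <= threshold -> surface), so ties never leave a TAD
    without surface bins.  n_k counts all bins of the TAD under ``index``,
    whether or not their ratio is observed.
    """
    if len(track) != index.n_bins:
        raise ValueError("track does not match bin index")
    tad_of_bin = bin_tad_map(tads, index)
    labels = np.full(index.n_bins, EXCLUDED, dtype=np.int64)
    rows = []
    for t, tad_id in enumerate(tads.tad_ids):
        sel = np.flatnonzero(tad_of_bin == t)
        n_k = len(sel)
        if n_k == 0:
            rows.append((tad_id, 0, np.nan, np.nan))
            continue
        q_k = n_k ** (-1.0 / 3.0)
        vals = track.values[sel]
        obs = ~np.isnan(vals)
        if not obs.any():
            logger.info("TAD %s has no observed ratios; all bins excluded", tad_id)
            rows.append((tad_id, n_k, q_k, np.nan))
            continue
        thr = float(np.quantile(vals[obs], q_k))
        lab = np.where(vals <= thr, SURFACE, CORE)
        lab[~obs] = EXCLUDED
        labels[sel] = lab
        rows.append((tad_id, n_k, q_k, thr))
    per_tad = pd.DataFrame(rows, columns=["tad_id", "n_k", "q_k", "threshold"])
    return SurfaceCoreLabels(labels, per_tad)


def exclude_boundaries(
    labels: SurfaceCoreLabels,
    tads: TADSet,
    index: BinIndex,
    fraction: float = 0.10,
) -> SurfaceCoreLabels:
    """Drop TAD-boundary bins and the neighbouring ``fraction`` of each TAD.

    On each flank of every TAD, the terminal bin plus the adjacent
    ceil(fraction * n_k) bins are relabeled EXCLUDED.  ``fraction`` is taken
    per flank (a 20-bin TAD at 0.10 loses bins 1-3 and 18-20, 1-based).
    """
    if not 0 <= fraction < 1:
        raise ValueError("fraction must be in [0, 1)")
    tad_of_bin = bin_tad_map(tads, index)
    out = labels.labels.copy()
    for t in range(len(tads)):
        sel = np.flatnonzero(tad_of_bin == t)
        n_k = len(sel)
        if n_k == 0:
            continue
        flank = 1 + int(np.ceil(fraction * n_k))
        out[sel[:flank]] = EXCLUDED
        out[sel[n_k - flank :]] = EXCLUDED
    return SurfaceCoreLabels(out, labels.per_tad.copy())


def shuffle_tads(tads: TADSet, chrom_sizes: dict[str, int], seed: int) -> TADSet:
    """Permute the interleaved TAD-length / gap-length list per chromosome.

    TAD lengths and gap lengths (the offset before the first TAD counts as
    a gap) are collected left to right, independently permuted, and laid
    down from the chromosome start, with each gap placed in a distinct slot
    before one of the TADs so that no two gaps coalesce.  The multiset of
    TAD sizes, the multiset of gap sizes, and the total span are therefore
    preserved exactly in the output.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for chrom, grp in tads.records.groupby("chrom", sort=False):
        if chrom not in chrom_sizes:
            raise ValueError(f"no size for chromosome {chrom!r}")
        tad_sizes = (grp["end"] - grp["start"]).to_numpy()
        tad_ids = grp["tad_id"].to_numpy()
        gap_sizes = []
        cursor = 0
        for start, end in grp[["start", "end"]].itertuples(index=False):
            if start > cursor:
                gap_sizes.append(start - cursor)
            cursor = end
        order = rng.permutation(len(tad_sizes))
        # each gap lands immediately before a distinct (shuffled) TAD
        slots = rng.choice(len(tad_sizes), size=len(gap_sizes), replace=False)
        gap_before = dict(zip(slots, rng.permutation(np.array(gap_sizes, dtype=np.int64))))
        pos = 0
        for j, i in enumerate(order):
            pos += int(gap_before.get(j, 0))
            rows.append((chrom, pos, pos + int(tad_sizes[i]), tad_ids[i]))
            pos += int(tad_sizes[i])
    return TADSet(pd.DataFrame(rows, columns=["chrom", "start", "end", "tad_id"]))
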