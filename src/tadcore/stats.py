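"""Enrichment and association statistics linking coreness to genome features.

The enrichment machinery counts genomic bins: with a universe of ``a`` TAD
bins, ``b`` of them surface (or core), ``c`` feature bins in the universe and
``d`` feature bins among the surface bins, the enrichment fold is
(d/c)/(b/a) and the p-value is the upper-tail hypergeometric probability
P(X >= d) of drawing c balls from a population of a containing b successes.
Raw p-values are the primary readout; Benjamini-Hochberg q-values can be
attached side by side via :func:`bh_adjust`.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .genome_model import BinIndex, IntervalSet, RatioTrack, SignalTrack, TADSet, bin_tad_map

logger = logging.getLogger(__name__)

__all__ = [
    "EnrichmentResult",
    "RegressionResult",
    "enrichment",
    "label_feature_bins",
    "quantile_groups",
    "per_tad_correlation",
    "group_compare",
    "interaction_regression",
    "track_correlation",
    "bh_adjust",
]


@dataclass(frozen=True)
class EnrichmentResult:
    """Bin counts and derived fold/p for one feature-vs-target comparison."""

    a: int  # universe bins
    b: int  # target (surface or core) bins
    c: int  # feature bins in universe
    d: int  # feature bins in target
    fold: float
    p_value: float


def enrichment(feature_bins, universe_bins, target_bins) -> EnrichmentResult:
    """Fold (d/c)/(b/a) and hypergeometric upper-tail p of a feature on a target.

    ``target_bins`` must be a subset of ``universe_bins``; the feature set is
    intersected with the universe first.  With ``c`` or ``b`` zero the fold is
    undefined (NaN) and p is 1.
    """
    universe = set(int(x) for x in universe_bins)
    target = set(int(x) for x in target_bins)
    if not target <= universe:
        raise ValueError("target bins must be a subset of the universe")
    feature = set(int(x) for x in feature_bins) & universe
    a, b = len(universe), len(target)
    c, d = len(feature), len(feature & target)
    if c == 0 or b == 0:
        return EnrichmentResult(a, b, c, d, float("nan"), 1.0)
    fold = (d / c) / (b / a)
    p = float(sps.hypergeom.sf(d - 1, a, b, c))
    return EnrichmentResult(a, b, c, d, fold, p)


def label_feature_bins(
    intervals: IntervalSet,
    index: BinIndex,
    exclude_labels: frozenset = frozenset({"Low-DNase"}),
) -> dict[str, np.ndarray]:
    """Per-category sets of bins overlapping at least one interval.

    A bin carries a category iff it overlaps any interval of that category,
    regardless of overlaps with other categories; intervals whose label is in
    ``exclude_labels`` (unlikely regulatory elements) are dropped first.
    """
    out: dict[str, set[int]] = {}
    for chrom, start, end, label in intervals.records.itertuples(index=False):
        label = str(label)
        if label in exclude_labels:
            continue
        if chrom not in index.chrom_sizes:
            continue
        end = min(end, index.chrom_sizes[chrom])
        if end <= start:
            continue
        off = index.chrom_offset(chrom)
        b0 = start // index.bin_size
        b1 = (end - 1) // index.bin_size
        out.setdefault(label, set()).update(range(off + b0, off + b1 + 1))
    return {k: np.array(sorted(v), dtype=np.int64) for k, v in out.items()}


def quantile_groups(values: np.ndarray, n_groups: int) -> np.ndarray:
    """Assign values to ``n_groups`` intervals with near-equal occupancy.

    Ties share one group (sizes then only approximate).  Missing values get
    group -1.  If ties collapse the partition to fewer groups a warning is
    emitted.
    """
    values = np.asarray(values, dtype=float)
    out = np.full(len(values), -1, dtype=np.int64)
    obs = ~np.isnan(values)
    if obs.sum() == 0:
        return out
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        groups = pd.qcut(values[obs], n_groups, labels=False, duplicates="drop")
    groups = np.asarray(groups, dtype=float)
    groups = np.nan_to_num(groups, nan=0.0).astype(np.int64)  # all-tied input
    n_eff = len(np.unique(groups))
    if n_eff < n_groups:
        warnings.warn(
            f"ties reduced {n_groups} requested groups to {n_eff}", stacklevel=2
        )
    out[obs] = groups
    return out


def per_tad_correlation(
    track: RatioTrack,
    expression: SignalTrack,
    tads: TADSet,
    index: BinIndex,
    min_genes: int = 5,
) -> tuple[pd.DataFrame, float, float]:
    """Per-TAD rank correlation of expression with intra-TAD ratio, plus t-test.

    For every TAD with at least ``min_genes`` bins carrying both an observed
    ratio and an observed expression value, the Spearman correlation across
    those bins is computed; the list of correlations is then tested against
    zero with a two-sided one-sample t-test.  Returns (per-TAD frame,
    t statistic, p value).
    """
    tad_of_bin = bin_tad_map(tads, index)
    joint = track.mask & expression.mask
    rows = []
    for t, tad_id in enumerate(tads.tad_ids):
        sel = np.flatnonzero((tad_of_bin == t) & joint)
        if len(sel) < min_genes:
            continue
        x = track.values[sel]
        y = expression.values[sel]
        if np.std(x) == 0 or np.std(y) == 0:
            continue
        rho = sps.spearmanr(x, y)[0]
        rows.append((tad_id, len(sel), rho))
    df = pd.DataFrame(rows, columns=["tad_id", "n_genes", "spearman"])
    if len(df) < 2:
        return df, float("nan"), float("nan")
    tstat, p = sps.ttest_1samp(df["spearman"], 0.0)
    return df, float(tstat), float(p)


def _exact_mwu_p(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sided Mann-Whitney p by exhaustive enumeration of group splits.

    Handles ties via midranks; the two-sided p is the probability, over all
    C(n1+n2, n1) assignments of the pooled ranks, of a U at least as far from
    its null mean as observed.
    """
    n1, n2 = len(a), len(b)
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    mean = n1 * n2 / 2
    dev = abs(u_obs - mean)
    hits = total = 0
    for idx in combinations(range(n1 + n2), n1):
        u = ranks[list(idx)].sum() - n1 * (n1 + 1) / 2
        total += 1
        if abs(u - mean) >= dev - 1e-12:
            hits += 1
    return float(u_obs), hits / total


def group_compare(values_a, values_b) -> tuple[float, float]:
    """Two-sided Mann-Whitney U comparison of two samples.

    Exact enumeration (tie-safe) when both groups have at most 8 values;
    otherwise the tie-corrected normal approximation.  Returns (U, p).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if len(a) == 0 or len(b) == 0:
        raise ValueError("group_compare requires two non-empty groups")
    if len(a) <= 8 and len(b) <= 8:
        return _exact_mwu_p(a, b)
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return float(res.statistic), float(res.pvalue)


@dataclass
class RegressionResult:
    """OLS fit of ratio on two signals and their interaction."""

    params: pd.Series  # intercept, x1, x2, x1:x2
    bse: pd.Series
    nobs: int
    rank_deficient: bool
    rsquared: float


def interaction_regression(
    y: RatioTrack,
    x1: SignalTrack,
    x2: SignalTrack,
    mask: np.ndarray | None = None,
) -> RegressionResult:
    """OLS of the ratio on x1, x2 and x1*x2 over jointly observed bins.

    A rank-deficient design (e.g. a constant signal) is flagged rather than
    silently pseudo-inverted into arbitrary coefficients.
    """
    import statsmodels.api as sm

    joint = y.mask & x1.mask & x2.mask
    if mask is not None:
        joint &= np.asarray(mask, dtype=bool)
    if joint.sum() < 5:
        raise ValueError("too few jointly observed bins for regression")
    yy = y.values[joint]
    a = x1.values[joint]
    b = x2.values[joint]
    X = pd.DataFrame({"x1": a, "x2": b, "x1:x2": a * b})
    X = sm.add_constant(X)
    rank = np.linalg.matrix_rank(X.to_numpy())
    fit = sm.OLS(yy, X).fit()
    return RegressionResult(
        params=fit.params,
        bse=fit.bse,
        nobs=int(fit.nobs),
        rank_deficient=rank < X.shape[1],
        rsquared=float(fit.rsquared),
    )


def track_correlation(
    track_a,
    track_b,
    index: BinIndex | None = None,
    mask_by: IntervalSet | None = None,
) -> pd.DataFrame:
    """Pearson and Spearman correlation over jointly non-missing bins.

    With ``mask_by`` given (e.g. subcompartment labels), the correlation is
    reported separately for the bins overlapping each label, in addition to
    the pooled 'all' row.
    """
    va = track_a.values if hasattr(track_a, "values") else np.asarray(track_a, float)
    vb = track_b.values if hasattr(track_b, "values") else np.asarray(track_b, float)
    joint = ~np.isnan(va) & ~np.isnan(vb)
    masks = {"all": joint}
    if mask_by is not None:
        if index is None:
            raise ValueError("mask_by requires a BinIndex")
        for label, bins in label_feature_bins(mask_by, index, frozenset()).items():
            m = np.zeros(len(va), dtype=bool)
            m[bins] = True
            masks[label] = joint & m
    rows = []
    for label, m in masks.items():
        n = int(m.sum())
        if n < 3 or np.std(va[m]) == 0 or np.std(vb[m]) == 0:
            rows.append((label, n, np.nan, np.nan))
            continue
        rows.append(
            (label, n, float(sps.pearsonr(va[m], vb[m])[0]),
             float(sps.spearmanr(va[m], vb[m])[0]))
        )
    return pd.DataFrame(rows, columns=["mask", "n", "pearson", "spearman"])


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg q-values, reported alongside (never replacing) raw p."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(p_values, dtype=float)
    out = np.full(len(p), np.nan)
    ok = ~np.isnan(p)
    if ok.any():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out
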