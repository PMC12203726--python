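"""Readers and writers for the text formats the pipeline consumes and emits.

All coordinates are converted to the internal 0-based half-open convention at
this boundary.  Readers validate strictly: malformed lines are counted and, if
they exceed the caller's tolerance (default 0), raise :class:`FormatError`
rather than being silently dropped.  Every reader that filters records returns
or logs the counts of what was removed.

On-disk dialects
----------------
BED (TADs, features)      chrom  start  end  [name]        (tab-separated)
SPRITE clusters           barcode  chrom:pos  chrom:pos …  (tab-separated)
COO contacts              chrom1  start1  chrom2  start2  weight
4DN .pairs                ``#`` header lines; columns readID chrom1 pos1
                          chrom2 pos2 [strand1 strand2] (strands ignored)
structure table           chrom[(hap)]  start  x  y  z
imaging CSV               cell_id,chrom,start,end,x,y,z  (empty field = NaN)
ratio TSV                 chrom  start  end  ratio  support   (missing = NA)
segmentation TSV          cell_id  chrom  start  end  domain_id
"""

from __future__ import annotations

import gzip
import io
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genome_model import (
    BinIndex,
    CoordinateError,
    IntervalSet,
    RatioTrack,
    SignalTrack,
    TADSet,
    UnknownChromosomeError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "FormatError",
    "FilterLog",
    "read_tads",
    "write_tads",
    "read_intervals",
    "write_intervals",
    "read_signal",
    "write_signal",
    "read_ratio",
    "write_ratio",
    "read_sprite",
    "write_sprite",
    "read_contacts_coo",
    "write_contacts_coo",
    "read_pairs",
    "write_pairs",
    "read_structure",
    "write_structure",
    "read_imaging",
    "write_imaging",
    "read_segmentation",
    "write_segmentation",
]


class FormatError(ValueError):
    """A file violates its declared dialect beyond the allowed tolerance."""


@dataclass
class FilterLog:
    """Counts of records removed or rejected while reading one file."""

    malformed_lines: int = 0
    unknown_chrom: int = 0
    dropped_small: int = 0
    dropped_large: int = 0
    total: int = 0
    details: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        d = {
            "malformed_lines": self.malformed_lines,
            "unknown_chrom": self.unknown_chrom,
            "dropped_small": self.dropped_small,
            "dropped_large": self.dropped_large,
            "total": self.total,
        }
        d.update(self.details)
        return d


def _open_text(path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def _check_tolerance(n_bad: int, n_total: int, tolerance: float, what: str) -> None:
    if n_total == 0:
        return
    if n_bad / n_total > tolerance:
        raise FormatError(
            f"{n_bad}/{n_total} {what} exceed malformed-line tolerance {tolerance}"
        )


# ---------------------------------------------------------------- BED / TADs


def read_tads(path, index: BinIndex) -> TADSet:
    """Read TAD intervals from BED.  Unnamed records get sequential ids."""
    rows = []
    with _open_text(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 3:
                raise FormatError(f"{path}:{ln}: BED line with <3 fields")
            try:
                start, end = int(f[1]), int(f[2])
            except ValueError as e:
                raise FormatError(f"{path}:{ln}: non-integer coordinate") from e
            if start < 0:
                raise CoordinateError(f"{path}:{ln}: negative coordinate")
            name = f[3] if len(f) > 3 and f[3] else f"TAD_{len(rows):05d}"
            rows.append((f[0], start, end, name))
    if not rows:
        raise FormatError(f"{path}: no TAD records")
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "tad_id"])
    for chrom in df["chrom"].unique():
        if chrom not in index.chrom_sizes:
            raise UnknownChromosomeError(f"{path}: unknown chromosome {chrom!r}")
    return TADSet(df)


def write_tads(tads: TADSet, path) -> None:
    tads.records.to_csv(path, sep="\t", header=False, index=False)


def read_intervals(path) -> IntervalSet:
    """Read labeled feature intervals from BED (4th column = label)."""
    rows = []
    with _open_text(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 3:
                raise FormatError(f"{path}:{ln}: BED line with <3 fields")
            try:
                start, end = int(f[1]), int(f[2])
            except ValueError as e:
                raise FormatError(f"{path}:{ln}: non-integer coordinate") from e
            label = f[3] if len(f) > 3 and f[3] else "feature"
            rows.append((f[0], start, end, label))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "label"])
    return IntervalSet(df)


def write_intervals(ivals: IntervalSet, path) -> None:
    ivals.records.to_csv(path, sep="\t", header=False, index=False)


# ------------------------------------------------------------------- signal


def read_signal(path, index: BinIndex) -> SignalTrack:
    """Read a bedGraph-like track into a per-bin signal.

    When a line spans several bins, its value contributes to each bin
    weighted by overlap length; a bin covered by no line is missing (NaN).
    """
    num = np.zeros(index.n_bins)
    cov = np.zeros(index.n_bins)
    with _open_text(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            f = line.split("\t")
            if len(f) < 4:
                raise FormatError(f"{path}:{ln}: bedGraph line with <4 fields")
            chrom = f[0]
            try:
                start, end, value = int(f[1]), int(f[2]), float(f[3])
            except ValueError as e:
                raise FormatError(f"{path}:{ln}: unparseable bedGraph fields") from e
            if chrom not in index.chrom_sizes:
                raise UnknownChromosomeError(f"{path}:{ln}: unknown chromosome {chrom!r}")
            if start < 0 or end <= start:
                raise CoordinateError(f"{path}:{ln}: bad interval [{start}, {end})")
            end = min(end, index.chrom_sizes[chrom])
            off = index.chrom_offset(chrom)
            b0 = start // index.bin_size
            b1 = (end - 1) // index.bin_size
            for b in range(b0, b1 + 1):
                bs = b * index.bin_size
                be = min(bs + index.bin_size, index.chrom_sizes[chrom])
                ov = min(end, be) - max(start, bs)
                num[off + b] += value * ov
                cov[off + b] += ov
    values = np.where(cov > 0, num / np.where(cov > 0, cov, 1), np.nan)
    return SignalTrack(values).check(index)


def write_signal(track: SignalTrack, index: BinIndex, path) -> None:
    """Write observed bins as bedGraph (missing bins are simply absent)."""
    df = index.bins_frame()
    df["value"] = track.values
    df = df[~df["value"].isna()]
    df.to_csv(path, sep="\t", header=False, index=False, float_format="%.10g")


# ------------------------------------------------------------------- ratios


def write_ratio(track: RatioTrack, index: BinIndex, path) -> None:
    """Ratio TSV: chrom, start, end, ratio (NA when missing), support."""
    df = index.bins_frame()
    df["ratio"] = np.round(track.values, 10)
    df["support"] = track.support
    df.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.10g")


def read_ratio(path, index: BinIndex) -> RatioTrack:
    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    if len(df) != index.n_bins:
        raise FormatError(f"{path}: {len(df)} rows != {index.n_bins} bins")
    return RatioTrack(df["ratio"].to_numpy(float), df["support"].to_numpy(np.int64))


# ------------------------------------------------------------------- SPRITE


def _parse_read(token: str, permissive: bool):
    if ":" in token:
        chrom, _, pos = token.rpartition(":")
    elif permissive and "_" in token:
        chrom, _, pos = token.rpartition("_")
    else:
        return None
    try:
        return chrom, int(pos)
    except ValueError:
        return None


def read_sprite(
    path,
    index: BinIndex,
    min_size: int = 2,
    max_size: int = 1000,
    permissive: bool = False,
    tolerance: float = 0.0,
) -> tuple[list[np.ndarray], FilterLog]:
    """Read SPRITE multi-contact clusters as per-cluster unique-bin sets.

    Reads within a cluster are deduplicated to unique genomic bins; clusters
    whose unique-bin count falls outside ``[min_size, max_size]`` are dropped
    and counted.  In permissive mode unparseable reads are counted and
    skipped instead of raising.
    """
    clusters: list[np.ndarray] = []
    log = FilterLog()
    seen = set()
    n_lines = 0
    with _open_text(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            n_lines += 1
            fields = line.split("\t")
            barcode, reads = fields[0], fields[1:]
            if barcode in seen:
                raise FormatError(f"{path}:{ln}: duplicate barcode {barcode!r}")
            seen.add(barcode)
            bins = set()
            bad = False
            for tok in reads:
                parsed = _parse_read(tok, permissive)
                if parsed is None:
                    if permissive:
                        log.malformed_lines += 1
                        continue
                    bad = True
                    break
                chrom, pos = parsed
                if chrom not in index.chrom_sizes:
                    if permissive:
                        log.unknown_chrom += 1
                        continue
                    raise UnknownChromosomeError(
                        f"{path}:{ln}: unknown chromosome {chrom!r}"
                    )
                bins.add(index.assign_bin(chrom, pos))
            if bad:
                log.malformed_lines += 1
                continue
            log.total += 1
            if len(bins) < min_size:
                log.dropped_small += 1
            elif len(bins) > max_size:
                log.dropped_large += 1
            else:
                clusters.append(np.array(sorted(bins), dtype=np.int64))
    if n_lines == 0:
        raise FormatError(f"{path}: empty SPRITE file")
    if not permissive:
        _check_tolerance(log.malformed_lines, n_lines, tolerance,
                         "malformed cluster lines")
    logger.info(
        "read_sprite: kept %d/%d clusters (%d too small, %d too large)",
        len(clusters), log.total, log.dropped_small, log.dropped_large,
    )
    return clusters, log


def write_sprite(clusters: list[np.ndarray], index: BinIndex, path) -> None:
    """Write clusters, one read per member bin at the bin midpoint."""
    with open(path, "wt") as fh:
        for i, bins in enumerate(clusters):
            reads = []
            for b in bins:
                chrom, start, end = index.bin_location(int(b))
                reads.append(f"{chrom}:{(start + end) // 2}")
            fh.write(f"cluster_{i:07d}\t" + "\t".join(reads) + "\n")


# ----------------------------------------------------------------- contacts


def _aggregate_pairs(b1: np.ndarray, b2: np.ndarray, w: np.ndarray) -> pd.DataFrame:
    lo = np.minimum(b1, b2)
    hi = np.maximum(b1, b2)
    df = pd.DataFrame({"bin1": lo, "bin2": hi, "weight": w})
    out = df.groupby(["bin1", "bin2"], as_index=False, sort=True)["weight"].sum()
    return out


def read_contacts_coo(path, index: BinIndex) -> pd.DataFrame:
    """Read COO contact text into accumulated unordered bin-pair weights.

    Returns a frame (bin1 <= bin2, weight) with duplicate and transposed
    entries summed.  Self-pairs are retained; ratio computation excludes them.
    """
    df = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        header=None,
        names=["chrom1", "start1", "chrom2", "start2", "weight"],
        dtype={"chrom1": str, "chrom2": str},
    )
    if df.empty:
        raise FormatError(f"{path}: empty contact file")
    if (df["weight"] < 0).any():
        raise FormatError(f"{path}: negative contact weight")
    b1 = index.assign_bins(df["chrom1"].to_numpy(), df["start1"].to_numpy())
    b2 = index.assign_bins(df["chrom2"].to_numpy(), df["start2"].to_numpy())
    return _aggregate_pairs(b1, b2, df["weight"].to_numpy(float))


def write_contacts_coo(contacts: pd.DataFrame, index: BinIndex, path) -> None:
    rows = []
    for b1, b2, w in contacts.itertuples(index=False):
        c1, s1, _ = index.bin_location(int(b1))
        c2, s2, _ = index.bin_location(int(b2))
        rows.append((c1, s1, c2, s2, w))
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False,
                              float_format="%.10g")


def read_pairs(paths, index: BinIndex) -> list[pd.DataFrame]:
    """Read per-cell .pairs files into per-cell accumulated bin-pair weights."""
    cells = []
    for path in paths:
        rows1, rows2 = [], []
        with _open_text(path) as fh:
            for ln, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                f = line.split("\t")
                if len(f) < 5:
                    raise FormatError(f"{path}:{ln}: .pairs line with <5 fields")
                try:
                    p1, p2 = int(f[2]), int(f[4])
                except ValueError as e:
                    raise FormatError(f"{path}:{ln}: non-integer position") from e
                rows1.append(index.assign_bin(f[1], p1))
                rows2.append(index.assign_bin(f[3], p2))
        b1 = np.array(rows1, dtype=np.int64)
        b2 = np.array(rows2, dtype=np.int64)
        cells.append(_aggregate_pairs(b1, b2, np.ones(len(b1))))
    return cells


def write_pairs(contacts: pd.DataFrame, index: BinIndex, path) -> None:
    """Write one cell's contacts in 4DN .pairs format (weights expanded)."""
    with open(path, "wt") as fh:
        fh.write("## pairs format v1.0\n#columns: readID chrom1 pos1 chrom2 pos2 strand1 strand2\n")
        rid = 0
        for b1, b2, w in contacts.itertuples(index=False):
            c1, s1, e1 = index.bin_location(int(b1))
            c2, s2, e2 = index.bin_location(int(b2))
            for _ in range(int(round(w))):
                fh.write(f"r{rid:08d}\t{c1}\t{(s1 + e1) // 2}\t{c2}\t{(s2 + e2) // 2}\t+\t+\n")
                rid += 1


# --------------------------------------------------------------- structures


def _split_hap(tag: str) -> tuple[str, str]:
    if tag.endswith(")") and "(" in tag:
        chrom, _, hap = tag[:-1].partition("(")
        return chrom, hap
    return tag, ""


def read_structure(path, index: BinIndex) -> pd.DataFrame:
    """Read a 3D structural model table.

    Columns: chrom (optionally haplotype-tagged as ``chr1(pat)``), start,
    x, y, z.  Returns a frame with columns chrom, hap, start, bin, x, y, z;
    at most one row per (haplotype-tagged chrom, start).
    """
    rows = []
    with _open_text(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 5:
                raise FormatError(f"{path}:{ln}: structure line with <5 fields")
            chrom, hap = _split_hap(f[0])
            try:
                start = int(f[1])
                x, y, z = float(f[2]), float(f[3]), float(f[4])
            except ValueError as e:
                raise FormatError(f"{path}:{ln}: unparseable structure fields") from e
            if not (np.isfinite(x) and np.isfinite(y) and np.isfinite(z)):
                raise FormatError(f"{path}:{ln}: non-finite coordinate")
            rows.append((chrom, hap, start, x, y, z))
    df = pd.DataFrame(rows, columns=["chrom", "hap", "start", "x", "y", "z"])
    if df.duplicated(["chrom", "hap", "start"]).any():
        raise FormatError(f"{path}: duplicate (chrom, haplotype, start) row")
    df["bin"] = index.assign_bins(df["chrom"].to_numpy(), df["start"].to_numpy())
    return df[["chrom", "hap", "start", "bin", "x", "y", "z"]]


def write_structure(df: pd.DataFrame, path) -> None:
    out = df.copy()
    tag = out["chrom"].astype(str)
    has_hap = out["hap"].astype(str) != ""
    tag = tag.where(~has_hap, tag + "(" + out["hap"].astype(str) + ")")
    out = pd.DataFrame(
        {"chrom": tag, "start": out["start"], "x": out["x"], "y": out["y"], "z": out["z"]}
    )
    out.to_csv(path, sep="\t", header=False, index=False, float_format="%.6f")


# ------------------------------------------------------------------ imaging


def read_imaging(path) -> pd.DataFrame:
    """Read chromatin-tracing coordinates (CSV, nm).

    Header comment ``# units=nm`` is accepted; any other declared unit is an
    error.  Empty coordinate fields become NaN (locus not detected).
    """
    with _open_text(path) as fh:
        first = fh.readline()
        skip = 0
        while first.startswith("#"):
            if "units=" in first and "units=nm" not in first.replace(" ", ""):
                raise FormatError(f"{path}: imaging units must be nm")
            skip += 1
            first = fh.readline()
    df = pd.read_csv(path, comment="#")
    req = ["cell_id", "chrom", "start", "end", "x", "y", "z"]
    if list(df.columns[:7]) != req:
        raise FormatError(f"{path}: imaging CSV must have columns {req}")
    if df.duplicated(["cell_id", "chrom", "start"]).any():
        raise FormatError(f"{path}: duplicate (cell_id, chrom, start)")
    return df


def write_imaging(df: pd.DataFrame, path) -> None:
    with open(path, "wt") as fh:
        fh.write("# units=nm\n")
        df.to_csv(fh, index=False, float_format="%.3f")


# ------------------------------------------------------------- segmentation


def read_segmentation(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    req = ["cell_id", "chrom", "start", "end", "domain_id"]
    if list(df.columns[:5]) != req:
        raise FormatError(f"{path}: segmentation TSV must have columns {req}")
    return df


def write_segmentation(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)
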