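"""Core coordinate frame and domain containers.

Everything downstream works in a single coordinate convention: 0-based,
half-open bins of a fixed size tiling each named chromosome (the last bin of
a chromosome may be short).  Bin ids are dense integers ordered by
(chromosome, start), so a per-bin quantity is just a numpy vector aligned to
a :class:`BinIndex`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "BinIndex",
    "TADSet",
    "IntervalSet",
    "SignalTrack",
    "RatioTrack",
    "GenomeModelError",
    "UnknownChromosomeError",
    "CoordinateError",
    "OverlapError",
    "assign_bin",
    "bin_tad_map",
]


class GenomeModelError(ValueError):
    """Base class for coordinate-frame violations."""


class UnknownChromosomeError(GenomeModelError):
    """A record names a chromosome absent from the bin index."""


class CoordinateError(GenomeModelError):
    """A position or interval falls outside its chromosome."""


class OverlapError(GenomeModelError):
    """Intervals that must be disjoint overlap."""


class BinIndex:
    """Fixed-size half-open bins tiling a set of named chromosomes.

    Parameters
    ----------
    chrom_sizes
        Mapping chromosome name -> length in base pairs.  Iteration order of
        the mapping fixes the global bin order.
    bin_size
        Bin width in base pairs.
    """

    def __init__(self, chrom_sizes: dict[str, int], bin_size: int):
        if bin_size <= 0:
            raise GenomeModelError(f"bin_size must be positive, got {bin_size}")
        if not chrom_sizes:
            raise GenomeModelError("chrom_sizes is empty")
        for chrom, size in chrom_sizes.items():
            if size <= 0:
                raise CoordinateError(f"chromosome {chrom!r} has non-positive length {size}")
        self.chrom_sizes = dict(chrom_sizes)
        self.bin_size = int(bin_size)
        self._chroms = list(self.chrom_sizes)
        self._nbins_per_chrom = {
            c: -(-self.chrom_sizes[c] // self.bin_size) for c in self._chroms
        }
        offsets = np.cumsum([0] + [self._nbins_per_chrom[c] for c in self._chroms])
        self._offsets = {c: int(offsets[i]) for i, c in enumerate(self._chroms)}
        self.n_bins = int(offsets[-1])

    @property
    def chroms(self) -> list[str]:
        return list(self._chroms)

    def chrom_n_bins(self, chrom: str) -> int:
        self._check_chrom(chrom)
        return self._nbins_per_chrom[chrom]

    def chrom_offset(self, chrom: str) -> int:
        self._check_chrom(chrom)
        return self._offsets[chrom]

    def _check_chrom(self, chrom: str) -> None:
        if chrom not in self.chrom_sizes:
            raise UnknownChromosomeError(f"unknown chromosome {chrom!r}")

    def assign_bin(self, chrom: str, pos: int) -> int:
        """Return the id of the unique half-open bin containing ``pos``."""
        self._check_chrom(chrom)
        if not (0 <= pos < self.chrom_sizes[chrom]):
            raise CoordinateError(
                f"position {pos} out of range for {chrom} "
                f"(length {self.chrom_sizes[chrom]})"
            )
        return self._offsets[chrom] + int(pos) // self.bin_size

    def assign_bins(self, chroms: np.ndarray, positions: np.ndarray) -> np.ndarray:
        """Vectorised :meth:`assign_bin` for parallel chrom/pos arrays."""
        chroms = np.asarray(chroms)
        positions = np.asarray(positions, dtype=np.int64)
        out = np.empty(len(positions), dtype=np.int64)
        for chrom in np.unique(chroms):
            c = str(chrom)
            self._check_chrom(c)
            sel = chroms == chrom
            pos = positions[sel]
            if pos.size and (pos.min() < 0 or pos.max() >= self.chrom_sizes[c]):
                bad = pos[(pos < 0) | (pos >= self.chrom_sizes[c])][0]
                raise CoordinateError(f"position {bad} out of range for {c}")
            out[sel] = self._offsets[c] + pos // self.bin_size
        return out

    def bin_location(self, bin_id: int) -> tuple[str, int, int]:
        """Inverse of :meth:`assign_bin`: (chrom, start, end) of a bin."""
        if not 0 <= bin_id < self.n_bins:
            raise CoordinateError(f"bin id {bin_id} out of range")
        for chrom in self._chroms:
            off = self._offsets[chrom]
            if bin_id < off + self._nbins_per_chrom[chrom]:
                start = (bin_id - off) * self.bin_size
                end = min(start + self.bin_size, self.chrom_sizes[chrom])
                return chrom, start, end
        raise AssertionError("unreachable")

    def bins_frame(self) -> pd.DataFrame:
        """All bins as a (chrom, start, end) frame in bin-id order."""
        rows = []
        for chrom in self._chroms:
            n = self._nbins_per_chrom[chrom]
            starts = np.arange(n, dtype=np.int64) * self.bin_size
            ends = np.minimum(starts + self.bin_size, self.chrom_sizes[chrom])
            rows.append(pd.DataFrame({"chrom": chrom, "start": starts, "end": ends}))
        return pd.concat(rows, ignore_index=True)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, BinIndex)
            and self.bin_size == other.bin_size
            and self.chrom_sizes == other.chrom_sizes
        )

    def __repr__(self) -> str:
        return f"BinIndex({len(self._chroms)} chroms, {self.n_bins} bins @ {self.bin_size} bp)"


class TADSet:
    """Labeled, non-overlapping genomic intervals (TADs).

    Intervals are 0-based half-open.  Within each chromosome they must be
    sorted and disjoint; gaps between consecutive TADs are allowed.
    """

    def __init__(self, records: pd.DataFrame):
        req = {"chrom", "start", "end", "tad_id"}
        if not req.issubset(records.columns):
            raise GenomeModelError(f"TADSet needs columns {sorted(req)}")
        df = records[["chrom", "start", "end", "tad_id"]].copy()
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
        if (df["start"] < 0).any():
            raise CoordinateError("negative TAD start")
        if (df["end"] <= df["start"]).any():
            bad = df[df["end"] <= df["start"]].iloc[0]
            raise CoordinateError(f"empty/inverted TAD {bad['tad_id']}")
        df = df.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)
        for chrom, grp in df.groupby("chrom", sort=False):
            starts = grp["start"].to_numpy()
            ends = grp["end"].to_numpy()
            bad = np.nonzero(starts[1:] < ends[:-1])[0]
            if bad.size:
                i = bad[0]
                raise OverlapError(
                    f"overlapping TADs on {chrom}: "
                    f"{grp['tad_id'].iloc[i]} and {grp['tad_id'].iloc[i + 1]}"
                )
        if df["tad_id"].duplicated().any():
            raise GenomeModelError("duplicate tad_id")
        self.records = df

    @property
    def tad_ids(self) -> list:
        return list(self.records["tad_id"])

    def __len__(self) -> int:
        return len(self.records)

    def n_k(self, index: BinIndex) -> np.ndarray:
        """Per-TAD bin counts under ``index`` (midpoint rule), order = records."""
        tad_of_bin = bin_tad_map(self, index)
        counts = np.bincount(tad_of_bin[tad_of_bin >= 0], minlength=len(self))
        return counts


class IntervalSet:
    """Labeled genomic intervals (cCREs, peaks, variants, state calls).

    Unlike :class:`TADSet`, intervals may overlap each other.
    """

    def __init__(self, records: pd.DataFrame):
        req = {"chrom", "start", "end", "label"}
        if not req.issubset(records.columns):
            raise GenomeModelError(f"IntervalSet needs columns {sorted(req)}")
        df = records[["chrom", "start", "end", "label"]].copy()
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
        if (df["start"] < 0).any():
            raise CoordinateError("negative interval start")
        if (df["end"] <= df["start"]).any():
            raise CoordinateError("interval with end <= start")
        if (df["label"].astype(str) == "").any():
            raise GenomeModelError("empty interval label")
        self.records = df.reset_index(drop=True)

    @property
    def labels(self) -> list[str]:
        return sorted(self.records["label"].astype(str).unique())

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class SignalTrack:
    """Per-bin real-valued signal; missing bins are NaN."""

    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)

    @property
    def mask(self) -> np.ndarray:
        """Boolean mask of observed (non-missing) bins."""
        return ~np.isnan(self.values)

    def check(self, index: BinIndex) -> "SignalTrack":
        if len(self.values) != index.n_bins:
            raise GenomeModelError(
                f"signal length {len(self.values)} != {index.n_bins} bins"
            )
        return self


@dataclass
class RatioTrack:
    """Per-bin intra-TAD (or intra-scDomain) ratio r_i with evidence counts.

    ``values[i]`` is the averaged ratio for bin i, in [0, 1], NaN when the bin
    has no supporting evidence after filtering.  ``support[i]`` counts the
    clusters / contacts / cells / models that contributed.
    """

    values: np.ndarray
    support: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.support is None:
            self.support = (~np.isnan(self.values)).astype(np.int64)
        self.support = np.asarray(self.support, dtype=np.int64)
        if len(self.support) != len(self.values):
            raise GenomeModelError("support/values length mismatch")
        ok = ~np.isnan(self.values)
        vals = self.values[ok]
        if vals.size and (vals.min() < -1e-12 or vals.max() > 1 + 1e-12):
            raise GenomeModelError("ratio values outside [0, 1]")
        if (self.support < 0).any():
            raise GenomeModelError("negative support")
        if (ok & (self.support == 0)).any() or ((~ok) & (self.support > 0)).any():
            raise GenomeModelError("support = 0 must coincide with missing value")

    @property
    def mask(self) -> np.ndarray:
        return ~np.isnan(self.values)

    def __len__(self) -> int:
        return len(self.values)


def assign_bin(chrom: str, pos: int, index: BinIndex) -> int:
    """Id of the half-open bin containing (chrom, pos). See :meth:`BinIndex.assign_bin`."""
    return index.assign_bin(chrom, pos)


def bin_tad_map(tads: TADSet, index: BinIndex) -> np.ndarray:
    """Per-bin TAD assignment under the midpoint rule.

    A bin belongs to a TAD iff the bin's midpoint lies inside the TAD's
    half-open interval.  Returns an int vector over all bins of ``index``:
    the row number of the containing TAD in ``tads.records``, or -1 when the
    bin lies outside every TAD.
    """
    out = np.full(index.n_bins, -1, dtype=np.int64)
    rec = tads.records
    for chrom, grp in rec.groupby("chrom", sort=False):
        if chrom not in index.chrom_sizes:
            raise UnknownChromosomeError(f"TAD on unknown chromosome {chrom!r}")
        if (grp["end"] > index.chrom_sizes[chrom]).any():
            raise CoordinateError(f"TAD extends past end of {chrom}")
        off = index.chrom_offset(chrom)
        n = index.chrom_n_bins(chrom)
        starts = np.arange(n, dtype=np.int64) * index.bin_size
        ends = np.minimum(starts + index.bin_size, index.chrom_sizes[chrom])
        mids = (starts + ends) / 2.0
        tstart = grp["start"].to_numpy()
        tend = grp["end"].to_numpy()
        # grp is sorted by start and disjoint: searchsorted finds the candidate TAD
        idx = np.searchsorted(tstart, mids, side="right") - 1
        valid = idx >= 0
        inside = np.zeros(n, dtype=bool)
        inside[valid] = mids[valid] < tend[idx[valid]]
        rows = grp.index.to_numpy()  # row numbers in tads.records
        out[off : off + n][inside] = rows[idx[inside]]
    return out
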