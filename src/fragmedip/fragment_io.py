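"""Reading, filtering, deduplicating and window-assigning cfDNA fragments.

A fragment is one sequenced cfDNA molecule, stored as a 0-based half-open
interval ``[start, end)`` on a named chromosome plus an optional molecular
barcode.  All downstream statistics (size distributions, short/long ratios,
window counts) operate on :class:`FragmentSet` objects produced here, either
from plain BED-like fragment tables, from paired-end alignments (SAM/BAM via
pysam), or from the cohort simulator.

Coordinate convention: 0-based, half-open throughout; fragment length is
``end - start``.  Fragments are strandless intervals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import pysam

FRAGMENT_COLUMNS = ("chrom", "start", "end", "barcode")

INPUT = "INPUT"
IP = "IP"


class FragmentTableError(ValueError):
    """Raised for malformed fragment tables (names the offending line)."""


# ---------------------------------------------------------------------------
# genome layout and window grids
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GenomeLayout:
    """Ordered chromosome names with lengths in bp."""

    chroms: tuple[str, ...]
    lengths: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.chroms) != len(self.lengths):
            raise ValueError("chroms and lengths must have equal length")
        if len(set(self.chroms)) != len(self.chroms):
            raise ValueError("chromosome names must be unique")
        if any(l <= 0 for l in self.lengths):
            raise ValueError("chromosome lengths must be positive")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "GenomeLayout":
        """Read a two-column chromosome-sizes TSV (name, length)."""
        df = pd.read_csv(path, sep="\t", header=None, usecols=[0, 1],
                         names=["chrom", "length"], dtype={"chrom": str})
        return cls(tuple(df["chrom"]), tuple(int(x) for x in df["length"]))

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for c, l in zip(self.chroms, self.lengths):
                fh.write(f"{c}\t{l}\n")

    @property
    def total_length(self) -> int:
        return int(sum(self.lengths))

    def length_of(self, chrom: str) -> int:
        try:
            return self.lengths[self.chroms.index(chrom)]
        except ValueError:
            raise KeyError(f"chromosome {chrom!r} not in genome layout") from None


@dataclass(frozen=True)
class WindowGrid:
    """Nonoverlapping tiling of a genome into fixed-size windows.

    Windows within one chromosome are disjoint and cover ``[0, length)``; the
    last window of a chromosome may be shorter.  A window is identified either
    by ``(chrom, index)`` or by a flat integer id that enumerates windows in
    layout order; the flat id is what array code uses.
    """

    layout: GenomeLayout
    window_size: int

    def __post_init__(self) -> None:
        if self.window_size <= 0:
            raise ValueError("window_size must be positive")

    @property
    def windows_per_chrom(self) -> tuple[int, ...]:
        return tuple(-(-l // self.window_size) for l in self.layout.lengths)

    @property
    def offsets(self) -> np.ndarray:
        """Flat id of the first window of each chromosome."""
        return np.concatenate([[0], np.cumsum(self.windows_per_chrom)])

    @property
    def n_windows(self) -> int:
        return int(self.offsets[-1])

    def flat_id(self, chrom: str, index: int) -> int:
        ci = self.layout.chroms.index(chrom)
        if not 0 <= index < self.windows_per_chrom[ci]:
            raise IndexError(f"window index {index} out of range for {chrom}")
        return int(self.offsets[ci] + index)

    def window_bounds(self, flat: int | np.ndarray):
        """Return (chrom, start, end) for flat window id(s)."""
        flat_arr = np.atleast_1d(np.asarray(flat, dtype=np.int64))
        offsets = self.offsets
        ci = np.searchsorted(offsets, flat_arr, side="right") - 1
        if np.any(flat_arr < 0) or np.any(flat_arr >= self.n_windows):
            raise IndexError("flat window id out of range")
        idx = flat_arr - offsets[ci]
        starts = idx * self.window_size
        lengths = np.asarray(self.layout.lengths)[ci]
        ends = np.minimum(starts + self.window_size, lengths)
        chroms = np.asarray(self.layout.chroms, dtype=object)[ci]
        if np.isscalar(flat) or np.ndim(flat) == 0:
            return str(chroms[0]), int(starts[0]), int(ends[0])
        return chroms, starts, ends

    def windows_table(self) -> pd.DataFrame:
        """All windows as a DataFrame (window, chrom, start, end)."""
        ids = np.arange(self.n_windows)
        chroms, starts, ends = self.window_bounds(ids)
        return pd.DataFrame(
            {"window": ids, "chrom": chroms, "start": starts, "end": ends}
        )


# ---------------------------------------------------------------------------
# fragment sets
# ---------------------------------------------------------------------------


@dataclass
class FragmentSet:
    """A collection of fragment records for one sample/library.

    ``frame`` has columns chrom (str), start (int64), end (int64),
    barcode (str, possibly empty).  Record order is meaningful (dedup keeps
    the first record per key).
    """

    sample_id: str
    library: str
    frame: pd.DataFrame
    dedup_applied: bool = False
    report: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.library not in (INPUT, IP):
            raise ValueError(f"library must be {INPUT!r} or {IP!r}")
        missing = [c for c in FRAGMENT_COLUMNS if c not in self.frame.columns]
        if missing:
            raise ValueError(f"fragment frame missing columns {missing}")

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def lengths(self) -> np.ndarray:
        """Fragment lengths in bp (end - start)."""
        return (self.frame["end"] - self.frame["start"]).to_numpy()

    def with_frame(self, frame: pd.DataFrame, **kw) -> "FragmentSet":
        return replace(self, frame=frame.reset_index(drop=True), **kw)


def _empty_frame() -> pd.DataFrame:
    return pd.DataFrame({
        "chrom": pd.Series(dtype=object),
        "start": pd.Series(dtype=np.int64),
        "end": pd.Series(dtype=np.int64),
        "barcode": pd.Series(dtype=object),
    })


def make_fragment_set(sample_id: str, library: str,
                      chrom: Sequence[str], start: Sequence[int],
                      end: Sequence[int], barcode: Sequence[str] | None = None,
                      dedup_applied: bool = False) -> FragmentSet:
    """Convenience constructor from parallel arrays."""
    n = len(start)
    frame = pd.DataFrame({
        "chrom": np.asarray(chrom, dtype=object),
        "start": np.asarray(start, dtype=np.int64),
        "end": np.asarray(end, dtype=np.int64),
        "barcode": (np.asarray(barcode, dtype=object)
                    if barcode is not None else np.full(n, "", dtype=object)),
    })
    return FragmentSet(sample_id, library, frame, dedup_applied=dedup_applied)


def read_fragment_table(path: str | Path, sample_id: str,
                        library: str) -> FragmentSet:
    """Read a BED-like fragment TSV: chrom, start, end[, barcode].

    Coordinates are 0-based half-open.  Records are returned in file order,
    unfiltered; a missing barcode column yields empty barcodes.  Malformed
    lines (non-integer coordinates, ``end <= start``) raise
    :class:`FragmentTableError` naming the 1-based line number.
    """
    try:
        df = pd.read_csv(path, sep="\t", header=None, dtype=str,
                         comment=None, skip_blank_lines=False)
    except pd.errors.EmptyDataError:
        return FragmentSet(sample_id, library, _empty_frame())
    if df.shape[1] < 3:
        raise FragmentTableError(
            f"{path}: fragment table needs >=3 tab-separated columns")
    chrom = df.iloc[:, 0].astype(object)
    start = pd.to_numeric(df.iloc[:, 1], errors="coerce")
    end = pd.to_numeric(df.iloc[:, 2], errors="coerce")
    bad = start.isna() | end.isna() | (start % 1 != 0) | (end % 1 != 0)
    if bad.any():
        line = int(np.flatnonzero(bad.to_numpy())[0]) + 1
        raise FragmentTableError(
            f"{path}: non-integer coordinates at line {line}")
    start = start.astype(np.int64)
    end = end.astype(np.int64)
    bad = end <= start
    if bad.any():
        line = int(np.flatnonzero(bad.to_numpy())[0]) + 1
        raise FragmentTableError(
            f"{path}: end <= start at line {line}")
    if df.shape[1] >= 4:
        barcode = df.iloc[:, 3].fillna("").astype(object)
    else:
        barcode = np.full(len(df), "", dtype=object)
    frame = pd.DataFrame({"chrom": chrom, "start": start, "end": end,
                          "barcode": barcode}).reset_index(drop=True)
    return FragmentSet(sample_id, library, frame)


def write_fragment_table(fs: FragmentSet, path: str | Path) -> None:
    """Write a fragment set as a 4-column TSV (chrom, start, end, barcode)."""
    fs.frame.to_csv(path, sep="\t", header=False, index=False,
                    columns=list(FRAGMENT_COLUMNS))


# ---------------------------------------------------------------------------
# paired-end alignments
# ---------------------------------------------------------------------------


def fragments_from_paired_alignments(
    path: str | Path,
    sample_id: str,
    library: str,
    min_insert: int = 20,
    min_mapq: int = 30,
    barcode_source: str = "tag",
    barcode_tag: str = "RX",
    name_delimiter: str = ":",
) -> FragmentSet:
    """Extract fragments from a paired-end SAM/BAM file.

    One fragment per retained read pair, spanning the leftmost reference
    start to the rightmost reference end of the two mates.  Pairs are dropped
    when either mate fails the proper-pair flag, is secondary/supplementary/
    unmapped, has mapping quality below ``min_mapq`` ("uniquely mapped"
    proxy), or when the resulting insert is shorter than ``min_insert``.
    Unpaired orphans are counted, skipped, and reported with a warning.

    ``barcode_source`` is ``"tag"`` (read the ``barcode_tag`` SAM tag) or
    ``"name"`` (leading token of the read name before ``name_delimiter``).
    Per-reason drop counts end up in the returned set's ``report``.
    """
    if barcode_source not in ("tag", "name"):
        raise ValueError("barcode_source must be 'tag' or 'name'")
    drops = {"not_proper_pair": 0, "secondary_or_supplementary": 0,
             "unmapped": 0, "low_mapq": 0, "short_insert": 0, "orphan": 0}
    pending: dict[str, pysam.AlignedSegment] = {}
    chroms: list[str] = []
    starts: list[int] = []
    ends: list[int] = []
    barcodes: list[str] = []
    with pysam.AlignmentFile(str(path), require_index=False) as af:
        for read in af:
            if read.is_secondary or read.is_supplementary:
                drops["secondary_or_supplementary"] += 1
                continue
            if read.is_unmapped or read.mate_is_unmapped:
                drops["unmapped"] += 1
                continue
            if not read.is_proper_pair:
                drops["not_proper_pair"] += 1
                continue
            if read.mapping_quality < min_mapq:
                drops["low_mapq"] += 1
                continue
            mate = pending.pop(read.query_name, None)
            if mate is None:
                pending[read.query_name] = read
                continue
            start = min(read.reference_start, mate.reference_start)
            end = max(read.reference_end, mate.reference_end)
            if end - start < min_insert:
                drops["short_insert"] += 1
                continue
            if barcode_source == "tag":
                bc = read.get_tag(barcode_tag) if read.has_tag(barcode_tag) else ""
            else:
                bc = read.query_name.split(name_delimiter, 1)[0]
            chroms.append(read.reference_name)
            starts.append(start)
            ends.append(end)
            barcodes.append(str(bc))
    if pending:
        drops["orphan"] = len(pending)
        warnings.warn(
            f"{path}: {len(pending)} orphan read(s) without a passing mate "
            "were skipped", stacklevel=2)
    fs = make_fragment_set(sample_id, library, chroms, starts, ends, barcodes)
    fs.report = {"dropped": drops, "kept": len(fs)}
    return fs


# ---------------------------------------------------------------------------
# filters
# ---------------------------------------------------------------------------


def deduplicate(fs: FragmentSet) -> FragmentSet:
    """Remove PCR duplicates: same (chrom, start, end, barcode).

    Keeps the first-encountered record per key.  The number of removed
    duplicates is recorded in the result's ``report``.
    """
    kept = fs.frame.drop_duplicates(
        subset=["chrom", "start", "end", "barcode"], keep="first")
    out = fs.with_frame(kept, dedup_applied=True)
    out.report = dict(fs.report)
    out.report["duplicates_removed"] = len(fs) - len(kept)
    return out


def filter_size_range(fs: FragmentSet, lo: int = 100,
                      hi: int = 220) -> FragmentSet:
    """Retain fragments with ``lo <= length <= hi`` (both inclusive)."""
    if lo > hi:
        raise ValueError(f"lo ({lo}) must be <= hi ({hi})")
    lengths = fs.lengths
    mask = (lengths >= lo) & (lengths <= hi)
    out = fs.with_frame(fs.frame[mask])
    out.report = dict(fs.report)
    out.report["size_filtered_out"] = int((~mask).sum())
    return out


# ---------------------------------------------------------------------------
# window assignment
# ---------------------------------------------------------------------------


def fragment_window_ids(fs: FragmentSet, grid: WindowGrid) -> np.ndarray:
    """Flat window id of each fragment under the midpoint rule.

    A fragment belongs to the window containing ``floor((start+end)/2)``;
    every fragment is assigned to exactly one window.  Raises ``KeyError``
    listing any chromosome absent from the grid's layout.
    """
    chrom_index = {c: i for i, c in enumerate(grid.layout.chroms)}
    codes = fs.frame["chrom"].map(chrom_index)
    if codes.isna().any():
        missing = sorted(set(fs.frame.loc[codes.isna(), "chrom"]))
        raise KeyError(f"chromosome(s) not in genome layout: {missing}")
    codes = codes.to_numpy(dtype=np.int64)
    starts = fs.frame["start"].to_numpy()
    ends = fs.frame["end"].to_numpy()
    lengths = np.asarray(grid.layout.lengths)[codes]
    if np.any(starts < 0) or np.any(ends > lengths):
        bad = np.flatnonzero((starts < 0) | (ends > lengths))[0]
        raise ValueError(
            f"fragment {fs.frame['chrom'].iloc[bad]}:{starts[bad]}-{ends[bad]}"
            " lies outside its chromosome")
    mid = (starts + ends) // 2
    return grid.offsets[codes] + mid // grid.window_size


def assign_to_windows(fs: FragmentSet, grid: WindowGrid) -> dict[int, np.ndarray]:
    """Map flat window id -> integer indices of the fragments it contains."""
    wid = fragment_window_ids(fs, grid)
    order = np.argsort(wid, kind="stable")
    sorted_wid = wid[order]
    uniq, starts = np.unique(sorted_wid, return_index=True)
    bounds = np.append(starts, len(sorted_wid))
    return {int(w): order[a:b]
            for w, a, b in zip(uniq, bounds[:-1], bounds[1:])}


def window_counts(fs: FragmentSet, grid: WindowGrid) -> np.ndarray:
    """Per-window fragment counts (length ``grid.n_windows``)."""
    wid = fragment_window_ids(fs, grid)
    return np.bincount(wid, minlength=grid.n_windows).astype(np.int64)
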