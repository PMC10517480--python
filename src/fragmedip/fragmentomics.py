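"""Fragment-size statistics: histograms, short/long ratios, genome profiles.

Short fragments are 100-150 bp and long fragments 151-220 bp (inclusive
bounds; 150 is short, 151 is long).  The short-fragments ratio of a library
or region is ``n_short / n_long``; it is undefined (NaN, ``defined=False``)
when there are no long fragments, never zero by convention — an empty
denominator propagating as missing avoids biasing window selection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fragment_io import FragmentSet, GenomeLayout, WindowGrid, fragment_window_ids

SIZE_LO = 100
SHORT_HI = 150
LONG_LO = 151
SIZE_HI = 220


@dataclass(frozen=True)
class SizeDistribution:
    """Integer histogram of fragment lengths over ``lo..hi`` bp inclusive."""

    counts: np.ndarray
    lo: int = SIZE_LO
    hi: int = SIZE_HI

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def sizes(self) -> np.ndarray:
        return np.arange(self.lo, self.hi + 1)

    def density(self) -> np.ndarray:
        """Counts normalized by the total within the analysis range."""
        t = self.total
        return self.counts / t if t else self.counts.astype(float)


@dataclass(frozen=True)
class RatioResult:
    """Short/long fragment counts and their ratio for one region or library."""

    n_short: int
    n_long: int

    @property
    def defined(self) -> bool:
        return self.n_long > 0

    @property
    def ratio(self) -> float:
        return self.n_short / self.n_long if self.defined else float("nan")


def size_distribution(fs: FragmentSet, lo: int = SIZE_LO,
                      hi: int = SIZE_HI) -> SizeDistribution:
    """Exact length histogram; the set must already be size-filtered."""
    lengths = fs.lengths
    if len(lengths) and (lengths.min() < lo or lengths.max() > hi):
        raise ValueError(
            f"fragment lengths outside [{lo}, {hi}]; apply filter_size_range first")
    counts = np.bincount(lengths - lo if len(lengths) else np.zeros(0, dtype=int),
                         minlength=hi - lo + 1)[: hi - lo + 1]
    return SizeDistribution(counts=counts.astype(np.int64), lo=lo, hi=hi)


def mean_size(fs: FragmentSet) -> float:
    """Arithmetic mean fragment length in bp; errors on an empty set."""
    if len(fs) == 0:
        raise ValueError("mean size undefined for an empty fragment set")
    return float(fs.lengths.mean())


def short_long_counts(lengths: np.ndarray) -> RatioResult:
    """Classify lengths at the 150/151 bp boundary within 100-220 bp."""
    n_short = int(((lengths >= SIZE_LO) & (lengths <= SHORT_HI)).sum())
    n_long = int(((lengths >= LONG_LO) & (lengths <= SIZE_HI)).sum())
    return RatioResult(n_short=n_short, n_long=n_long)


def short_fragments_ratio(fs: FragmentSet, grid: WindowGrid | None = None,
                          windows=None) -> RatioResult:
    """Short-fragments ratio of a library, optionally restricted to windows.

    ``windows`` is an iterable of flat window ids on ``grid``; restriction
    uses the same midpoint assignment as window counting, keeping ratio
    computations consistent with DMR counts.
    """
    lengths = fs.lengths
    if windows is not None:
        if grid is None:
            raise ValueError("grid is required when restricting to windows")
        wid = fragment_window_ids(fs, grid)
        mask = np.isin(wid, np.asarray(list(windows), dtype=np.int64))
        lengths = lengths[mask]
    return short_long_counts(lengths)


def per_window_short_long(fs: FragmentSet, grid: WindowGrid) -> pd.DataFrame:
    """n_short / n_long per flat window id (all windows, zeros included)."""
    wid = fragment_window_ids(fs, grid)
    lengths = fs.lengths
    short = (lengths >= SIZE_LO) & (lengths <= SHORT_HI)
    long_ = (lengths >= LONG_LO) & (lengths <= SIZE_HI)
    n = grid.n_windows
    return pd.DataFrame({
        "n_short": np.bincount(wid[short], minlength=n).astype(np.int64),
        "n_long": np.bincount(wid[long_], minlength=n).astype(np.int64),
    }, index=pd.RangeIndex(n, name="window"))


def genome_bin_profile(fs: FragmentSet, layout: GenomeLayout,
                       bin_bp: int = 5_000_000) -> pd.DataFrame:
    """Per-bin short-fragments ratio across the genome (default 5-Mb bins).

    Returns a DataFrame (chrom, start, end, n_short, n_long, ratio); bins
    without long fragments carry ``ratio = NaN``.  Computed without GC
    adjustment.
    """
    grid = WindowGrid(layout, bin_bp)
    tab = per_window_short_long(fs, grid)
    out = grid.windows_table().set_index("window")
    out["n_short"] = tab["n_short"]
    out["n_long"] = tab["n_long"]
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = out["n_short"] / out["n_long"]
    out["ratio"] = ratio.where(out["n_long"] > 0, np.nan)
    return out


def profile_delta(ip: pd.DataFrame, input_: pd.DataFrame) -> pd.Series:
    """Per-bin IP minus Input short-fragments ratio on an identical grid.

    Missing on either side propagates as missing.
    """
    same = (len(ip) == len(input_)
            and (ip["chrom"].to_numpy() == input_["chrom"].to_numpy()).all()
            and (ip["start"].to_numpy() == input_["start"].to_numpy()).all()
            and (ip["end"].to_numpy() == input_["end"].to_numpy()).all())
    if not same:
        raise ValueError("profiles are on different bin grids")
    return ip["ratio"] - input_["ratio"]


def percent_change(hypo_ratio: float, hyper_ratio: float) -> float:
    """Percent change of the hypo-window ratio relative to the hyper-window
    ratio: ``100 * (hypo - hyper) / hyper``.  Requires ``hyper_ratio > 0``."""
    if not hyper_ratio > 0:
        raise ValueError("percent change undefined for hyper_ratio <= 0")
    return 100.0 * (hypo_ratio - hyper_ratio) / hyper_ratio


def ratio_change_ip_vs_input(ip_fs: FragmentSet,
                             input_fs: FragmentSet) -> float:
    """Percent change of the short-fragments ratio from Input to IP library."""
    r_ip = short_fragments_ratio(ip_fs)
    r_in = short_fragments_ratio(input_fs)
    if not r_in.defined or not r_in.ratio > 0:
        raise ValueError("Input short-fragments ratio undefined or zero")
    if not r_ip.defined:
        raise ValueError("IP short-fragments ratio undefined")
    return percent_change(r_ip.ratio, r_in.ratio)
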