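"""Input-adjusted short-fragments ratios over DMR windows.

The raw IP short-fragments ratio of a window confounds methylation-driven
enrichment with whatever short-fragment excess the sample already had before
immunoprecipitation.  The input-adjusted ratio divides a window's IP
short-fragments ratio by the genome-wide short-fragments ratio of the
matched Input library, so a value near 1 means "no more short-skewed than
this sample's plasma at large".  (An alternative per-window-Input
denominator is available via ``mode="window_input"`` for sensitivity
analysis; the genome-wide Input denominator is the default.)

Windows entering a fragmentation profile must be informative for every
sample: at least ``min_fragments`` deduplicated IP fragments and an adjusted
ratio below ``max_adjusted_ratio`` in all samples of both cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fragment_io import FragmentSet, WindowGrid
from .fragmentomics import per_window_short_long, short_fragments_ratio


@dataclass
class SamplePair:
    """Matched Input and IP fragment sets for one participant."""

    sample_id: str
    group: str
    input_set: FragmentSet
    ip_set: FragmentSet


@dataclass(frozen=True)
class WindowSelectionCriteria:
    min_fragments: int = 20
    max_adjusted_ratio: float = 10.0
    classes: tuple[str, ...] = ("HYPO",)

    def __post_init__(self) -> None:
        if self.min_fragments < 0:
            raise ValueError("min_fragments must be >= 0")
        if not self.max_adjusted_ratio > 0:
            raise ValueError("max_adjusted_ratio must be > 0")


@dataclass
class AdjustedRatioMatrix:
    """Samples x selected windows matrix of input-adjusted ratios.

    ``values`` rows are sample ids, columns flat window ids; ``classes``
    maps each selected window to its DMR class.  Selection guarantees every
    entry is finite.
    """

    values: pd.DataFrame
    classes: dict[int, str]
    groups: dict[str, str]


def genome_wide_input_ratio(pair: SamplePair) -> float:
    """Short-fragments ratio over the sample's entire Input library."""
    r = short_fragments_ratio(pair.input_set)
    if not r.defined:
        raise ValueError(
            f"{pair.sample_id}: genome-wide Input short-fragments ratio undefined")
    return r.ratio


def adjusted_ratio_table(pairs: list[SamplePair], grid: WindowGrid,
                         windows: np.ndarray,
                         mode: str = "genome_input") -> pd.DataFrame:
    """Input-adjusted ratio for every sample x window; NaN where undefined.

    ``mode="genome_input"`` divides each window's IP ratio by the sample's
    genome-wide Input ratio; ``mode="window_input"`` divides by the same
    window's Input ratio.
    """
    if mode not in ("genome_input", "window_input"):
        raise ValueError(f"unknown adjustment mode {mode!r}")
    windows = np.asarray(windows, dtype=np.int64)
    rows = {}
    for pair in pairs:
        ip = per_window_short_long(pair.ip_set, grid).loc[windows]
        with np.errstate(divide="ignore", invalid="ignore"):
            ip_ratio = ip["n_short"] / ip["n_long"]
        ip_ratio = ip_ratio.where(ip["n_long"] > 0, np.nan)
        if mode == "genome_input":
            denom = genome_wide_input_ratio(pair)
            adj = ip_ratio / denom if denom > 0 else ip_ratio * np.nan
        else:
            inp = per_window_short_long(pair.input_set, grid).loc[windows]
            with np.errstate(divide="ignore", invalid="ignore"):
                in_ratio = inp["n_short"] / inp["n_long"]
            in_ratio = in_ratio.where((inp["n_long"] > 0) & (inp["n_short"] > 0),
                                      np.nan)
            adj = ip_ratio / in_ratio
        rows[pair.sample_id] = adj
    return pd.DataFrame(rows).T.rename_axis("sample_id")


def input_adjusted_ratio(pair: SamplePair, grid: WindowGrid, window: int,
                         mode: str = "genome_input") -> float:
    """Adjusted ratio of a single window for one sample (NaN if undefined)."""
    tab = adjusted_ratio_table([pair], grid, np.array([window]), mode=mode)
    return float(tab.iloc[0, 0])


def select_informative_windows(pairs: list[SamplePair], grid: WindowGrid,
                               dmrs: pd.DataFrame,
                               criteria: WindowSelectionCriteria = WindowSelectionCriteria(),
                               mode: str = "genome_input") -> np.ndarray:
    """Windows of the requested DMR class that are informative in EVERY sample.

    A window survives when, for all samples of both cohorts, the deduplicated
    IP fragment count in the window is >= ``min_fragments`` and the
    input-adjusted ratio is defined and < ``max_adjusted_ratio``.  Output is
    ordered by genomic position (chrom, start).
    """
    cand = dmrs.index[dmrs["class"].isin(criteria.classes)].to_numpy(np.int64)
    if len(cand) == 0:
        return cand
    keep = np.ones(len(cand), dtype=bool)
    for pair in pairs:
        tab = per_window_short_long(pair.ip_set, grid).loc[cand]
        total = (tab["n_short"] + tab["n_long"]).to_numpy()
        keep &= total >= criteria.min_fragments
    adj = adjusted_ratio_table(pairs, grid, cand, mode=mode)
    vals = adj.to_numpy()
    keep &= np.isfinite(vals).all(axis=0)
    with np.errstate(invalid="ignore"):
        keep &= np.nan_to_num(vals, nan=np.inf).max(axis=0) < criteria.max_adjusted_ratio
    selected = cand[keep]
    return np.sort(selected)  # flat ids already follow (chrom, start) order


def build_profile_matrix(pairs: list[SamplePair], grid: WindowGrid,
                         windows: np.ndarray, dmrs: pd.DataFrame | None = None,
                         mode: str = "genome_input") -> AdjustedRatioMatrix:
    """Complete adjusted-ratio matrix over pre-selected windows.

    Raises if any entry is missing — selection is supposed to guarantee
    completeness, so a NaN here is an internal consistency error.
    """
    windows = np.asarray(windows, dtype=np.int64)
    values = adjusted_ratio_table(pairs, grid, windows, mode=mode)
    if not np.isfinite(values.to_numpy()).all():
        raise ValueError("profile matrix has missing entries; "
                         "windows were not properly selected")
    classes = {}
    if dmrs is not None:
        cls = dmrs["class"]
        classes = {int(w): str(cls.loc[w]) for w in windows if w in cls.index}
    groups = {p.sample_id: p.group for p in pairs}
    return AdjustedRatioMatrix(values=values, classes=classes, groups=groups)
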