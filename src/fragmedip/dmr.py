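"""Windowed differential methylation from IP fragment counts.

cfMeDIP IP coverage of a window tracks its methylation level, so a
differential count analysis of deduplicated IP fragments per 10-kb window
between cancer and healthy cohorts identifies differentially methylated
regions (DMRs): HYPER windows gain IP counts in cancer, HYPO windows lose
them.  The model is a negative-binomial GLM with log link per window:

* library-size normalization by median-of-ratios size factors,
* per-window method-of-moments dispersion, shrunk 50/50 toward a fitted
  1/mean dispersion trend and floored at 1e-8,
* Wald test of the group effect against a standard normal reference
  (the trend-shrunk dispersion absorbs the small-sample variance
  inflation; the combination is what the null-calibration tests check),
* Benjamini-Hochberg adjustment and classification at
  ``padj < alpha`` and ``|log2FC| > L`` (defaults 0.05 and 1).

This is a deliberately compact NB pipeline: no independent filtering,
outlier handling, or posterior fold-change shrinkage.  Correctness rests on
null calibration and planted-effect recovery rather than numeric parity with
any particular reference tool.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .fragment_io import FragmentSet, WindowGrid, window_counts

HYPER = "HYPER"
HYPO = "HYPO"
NONE = "NONE"

LOG2FC_PSEUDOCOUNT = 0.5
DISPERSION_FLOOR = 1e-8


@dataclass
class CountMatrix:
    """Deduplicated IP fragment counts, windows x samples, with group labels.

    ``counts`` is indexed by flat window id with one column per sample id;
    ``groups`` maps sample id -> "healthy" | "cancer".
    """

    counts: pd.DataFrame
    groups: dict[str, str]
    grid: WindowGrid | None = None

    def __post_init__(self) -> None:
        missing = [s for s in self.counts.columns if s not in self.groups]
        if missing:
            raise ValueError(f"samples without group labels: {missing}")
        bad = {g for g in self.groups.values() if g not in ("healthy", "cancer")}
        if bad:
            raise ValueError(f"unknown group labels: {sorted(bad)}")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be nonnegative")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def group_mask(self, group: str) -> np.ndarray:
        return np.array([self.groups[s] == group for s in self.counts.columns])


def build_count_matrix(samples: list[FragmentSet], groups: dict[str, str],
                       grid: WindowGrid) -> CountMatrix:
    """Count fragments per window (midpoint rule) for each IP sample.

    Sets should be deduplicated and size-filtered to 100-220 bp first.
    All-zero windows are retained until :func:`filter_low_count_windows`.
    """
    ids = [fs.sample_id for fs in samples]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sample ids in count matrix input")
    data = {fs.sample_id: window_counts(fs, grid) for fs in samples}
    counts = pd.DataFrame(data, index=pd.RangeIndex(grid.n_windows, name="window"))
    return CountMatrix(counts=counts, groups=dict(groups), grid=grid)


def filter_low_count_windows(cm: CountMatrix,
                             min_mean: float = 10.0) -> CountMatrix:
    """Keep windows whose mean count across ALL samples is >= ``min_mean``."""
    keep = cm.counts.mean(axis=1) >= min_mean
    return CountMatrix(counts=cm.counts.loc[keep], groups=cm.groups, grid=cm.grid)


def estimate_size_factors(cm: CountMatrix,
                          method: str = "ratio") -> pd.Series:
    """Median-of-ratios library-size factors.

    For each window with all-positive counts, the reference is the geometric
    mean across samples; a sample's factor is the median over such windows of
    count / reference.  ``method="poscounts"`` falls back to a reference
    computed from positive counts only (for sparse matrices with no
    all-positive window).
    """
    y = cm.counts.to_numpy(dtype=float)
    if method == "ratio":
        allpos = (y > 0).all(axis=1)
        if not allpos.any():
            raise ValueError(
                "no window with all-positive counts; use method='poscounts'")
        yp = y[allpos]
        ref = np.exp(np.log(yp).mean(axis=1, keepdims=True))
        s = np.median(yp / ref, axis=0)
    elif method == "poscounts":
        logy = np.full(y.shape, np.nan)
        np.log(y, out=logy, where=y > 0)
        ref = np.exp(np.nanmean(logy, axis=1, keepdims=True))
        with np.errstate(invalid="ignore"):
            ratios = np.where(y > 0, y / ref, np.nan)
        s = np.nanmedian(ratios, axis=0)
    else:
        raise ValueError(f"unknown size-factor method {method!r}")
    if not np.all(np.isfinite(s)) or np.any(s <= 0):
        raise ValueError("size factors must be positive and finite")
    return pd.Series(s, index=cm.counts.columns, name="size_factor")


# ---------------------------------------------------------------------------
# dispersion and NB Wald test
# ---------------------------------------------------------------------------


def _moment_dispersions(y: np.ndarray, s: np.ndarray,
                        cancer: np.ndarray) -> np.ndarray:
    """Per-window method-of-moments NB dispersion on normalized counts.

    Uses the within-group variance of normalized counts; the Poisson part of
    that variance is approximately ``mu * mean(1/s)``, the rest is
    ``alpha * mu^2``.
    """
    norm = y / s
    n_c, n_h = int(cancer.sum()), int((~cancer).sum())
    mu = norm.mean(axis=1)
    dof = max(n_c + n_h - 2, 1)
    ss = np.zeros(len(y))
    for mask in (cancer, ~cancer):
        if mask.sum() >= 1:
            gm = norm[:, mask].mean(axis=1, keepdims=True)
            ss += ((norm[:, mask] - gm) ** 2).sum(axis=1)
    var = ss / dof
    pois = mu * np.mean(1.0 / s)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = (var - pois) / mu**2
    alpha = np.where(np.isfinite(alpha), alpha, 0.0)
    return np.clip(alpha, 0.0, 10.0)


def _trend_dispersions(alpha_raw: np.ndarray, mu: np.ndarray) -> np.ndarray:
    """Fit alpha ~ a0 + a1/mu by least squares (coefficients clipped >= 0)."""
    ok = mu > 0
    if ok.sum() < 2:
        return np.full_like(alpha_raw, DISPERSION_FLOOR)
    X = np.column_stack([np.ones(ok.sum()), 1.0 / mu[ok]])
    coef, *_ = np.linalg.lstsq(X, alpha_raw[ok], rcond=None)
    coef = np.clip(coef, 0.0, None)
    with np.errstate(divide="ignore"):
        trend = coef[0] + coef[1] / np.where(mu > 0, mu, np.inf)
    return trend


def _nb_irls(y: np.ndarray, s: np.ndarray, cancer: np.ndarray,
             alpha: np.ndarray, n_iter: int = 30,
             tol: float = 1e-10) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized IRLS for per-window NB GLM  log mu = log s + b0 + b1*group.

    Returns (b1, se_b1) per window.  ``alpha`` is the (fixed) per-window NB
    dispersion; alpha -> 0 recovers Poisson regression.
    """
    W_, S = y.shape
    offset = np.log(s)[None, :]
    x = cancer.astype(float)[None, :]
    # moment-based start values
    norm = y / s
    mu_c = norm[:, cancer].mean(axis=1) if cancer.any() else np.zeros(W_)
    mu_h = norm[:, ~cancer].mean(axis=1) if (~cancer).any() else np.zeros(W_)
    b0 = np.log(np.maximum(mu_h, 1e-8))
    b1 = np.log(np.maximum(mu_c, 1e-8)) - b0
    a = alpha[:, None]
    for _ in range(n_iter):
        eta = offset + b0[:, None] + b1[:, None] * x
        mu = np.exp(np.clip(eta, -30.0, 30.0))
        w = mu / (1.0 + a * mu)          # working weights for log link
        z = (eta - offset) + (y - mu) / mu
        sw = w.sum(axis=1)
        swx = (w * x).sum(axis=1)
        swxx = (w * x * x).sum(axis=1)
        swz = (w * z).sum(axis=1)
        swxz = (w * x * z).sum(axis=1)
        det = sw * swxx - swx**2
        det = np.where(det > 0, det, np.nan)
        nb0 = (swxx * swz - swx * swxz) / det
        nb1 = (sw * swxz - swx * swz) / det
        nb0 = np.where(np.isfinite(nb0), nb0, b0)
        nb1 = np.where(np.isfinite(nb1), nb1, b1)
        delta = np.max(np.abs(nb0 - b0) + np.abs(nb1 - b1))
        b0, b1 = nb0, nb1
        if delta < tol:
            break
    eta = offset + b0[:, None] + b1[:, None] * x
    mu = np.exp(np.clip(eta, -30.0, 30.0))
    w = mu / (1.0 + a * mu)
    sw = w.sum(axis=1)
    swx = (w * x).sum(axis=1)
    swxx = (w * x * x).sum(axis=1)
    det = sw * swxx - swx**2
    with np.errstate(divide="ignore", invalid="ignore"):
        var_b1 = sw / det
    se = np.sqrt(np.where(var_b1 > 0, var_b1, np.nan))
    return b1, se


def nb_window_test(cm: CountMatrix, size_factors: pd.Series) -> pd.DataFrame:
    """Per-window NB Wald test of cancer vs healthy.

    Returns a DataFrame indexed by window with columns ``baseMean``
    (mean normalized count), ``log2fc`` (cancer vs healthy, pseudocount
    0.5), ``dispersion`` and two-sided ``p``.  With a single-sample group
    the fold change is reported and ``p`` is missing; an empty group raises.
    """
    cancer = cm.group_mask("cancer")
    healthy = cm.group_mask("healthy")
    if cancer.sum() == 0 or healthy.sum() == 0:
        empty = "cancer" if cancer.sum() == 0 else "healthy"
        raise ValueError(f"group {empty!r} has no samples")
    y = cm.counts.to_numpy(dtype=float)
    s = size_factors.loc[cm.counts.columns].to_numpy(dtype=float)
    norm = y / s
    mu_c = norm[:, cancer].mean(axis=1)
    mu_h = norm[:, healthy].mean(axis=1)
    base_mean = norm.mean(axis=1)
    c0 = LOG2FC_PSEUDOCOUNT
    log2fc = np.log2((mu_c + c0) / (mu_h + c0))
    res = pd.DataFrame({"baseMean": base_mean, "log2fc": log2fc},
                       index=cm.counts.index)
    if cancer.sum() < 2 or healthy.sum() < 2:
        res["dispersion"] = np.nan
        res["p"] = np.nan
        return res
    alpha_raw = _moment_dispersions(y, s, cancer)
    alpha_trend = _trend_dispersions(alpha_raw, base_mean)
    alpha = np.maximum(DISPERSION_FLOOR, 0.5 * alpha_raw + 0.5 * alpha_trend)
    b1, se = _nb_irls(y, s, cancer, alpha)
    with np.errstate(divide="ignore", invalid="ignore"):
        wald = b1 / se
    p = 2.0 * stats.norm.sf(np.abs(wald))
    p = np.where(np.isfinite(wald), p, np.nan)
    res["dispersion"] = alpha
    res["p"] = p
    return res


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1).

    NaN entries are excluded from the adjustment and propagate as NaN.
    """
    p = np.asarray(p, dtype=float)
    ok = ~np.isnan(p)
    if ((p[ok] < 0) | (p[ok] > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    out = np.full(p.shape, np.nan)
    if ok.any():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


def classify_dmrs(results: pd.DataFrame, alpha: float = 0.05,
                  lfc: float = 1.0, use_padj: bool = True) -> pd.DataFrame:
    """Attach ``padj`` and a HYPER/HYPO/NONE class to NB test results.

    HYPER: significant with ``log2fc > lfc`` (more methylated in cancer);
    HYPO: significant with ``log2fc < -lfc``.  ``use_padj=False`` gates on
    the raw p-value instead (the mode used when calling within a cohort
    without the adjusted threshold).
    """
    out = results.copy()
    out["padj"] = bh_adjust(out["p"].to_numpy())
    crit = out["padj"] if use_padj else out["p"]
    sig = crit.to_numpy() < alpha
    cls = np.where(sig & (out["log2fc"].to_numpy() > lfc), HYPER,
                   np.where(sig & (out["log2fc"].to_numpy() < -lfc), HYPO, NONE))
    out["class"] = cls
    return out
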