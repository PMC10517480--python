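"""Correlation-to-healthy-baseline scoring and ROC evaluation.

A sample's DMR fragmentation profile (input-adjusted short-fragments ratios
over the selected hypomethylated windows) is compared by Pearson correlation
to the per-window median profile of the healthy samples.  Healthy profiles
resemble the baseline (high r); cancer samples deviate in patient-specific
windows (low r), so LOW correlation is cancer-like and a sample is called
cancer when ``r < cutoff`` (strict inequality).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .profiles import AdjustedRatioMatrix

POSITIVE = "cancer"
NEGATIVE = "healthy"


@dataclass(frozen=True)
class ScoreResult:
    sample_id: str
    r: float

    @property
    def defined(self) -> bool:
        return np.isfinite(self.r)


@dataclass(frozen=True)
class RocCurve:
    """ROC points ordered from (0,0) to (1,1); lower r is more cancer-like."""

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float


def healthy_median_baseline(profiles: pd.DataFrame,
                            healthy_ids: list[str]) -> pd.Series:
    """Per-window median of healthy samples' adjusted ratios.

    An even number of healthy samples averages the two middle values.
    """
    if len(healthy_ids) == 0:
        raise ValueError("baseline requires at least one healthy sample")
    missing = [h for h in healthy_ids if h not in profiles.index]
    if missing:
        raise KeyError(f"healthy samples absent from profile matrix: {missing}")
    return profiles.loc[healthy_ids].median(axis=0)


def pearson_score(profile: pd.Series, baseline: pd.Series,
                  sample_id: str = "") -> ScoreResult:
    """Pearson correlation of one sample's profile to the baseline.

    Requires >= 3 windows; zero variance on either side yields an undefined
    (NaN) score rather than an exception.
    """
    x = np.asarray(profile, dtype=float)
    y = np.asarray(baseline, dtype=float)
    if len(x) != len(y):
        raise ValueError("profile and baseline cover different windows")
    if len(x) < 3:
        raise ValueError("Pearson score needs at least 3 windows")
    if np.std(x) == 0 or np.std(y) == 0:
        return ScoreResult(sample_id=sample_id, r=float("nan"))
    r = stats.pearsonr(x, y).statistic
    return ScoreResult(sample_id=sample_id, r=float(r))


def score_samples(matrix: AdjustedRatioMatrix,
                  healthy_ids: list[str] | None = None,
                  leave_one_out: bool = False) -> pd.DataFrame:
    """Score every sample against the healthy median baseline.

    ``healthy_ids`` defaults to the matrix's healthy group.  With
    ``leave_one_out`` a healthy sample is scored against the median of the
    OTHER healthy samples.  Returns a DataFrame (sample_id, group, r).
    """
    profiles = matrix.values
    if healthy_ids is None:
        healthy_ids = [s for s in profiles.index
                       if matrix.groups.get(s) == NEGATIVE]
    baseline = healthy_median_baseline(profiles, healthy_ids)
    rows = []
    for sid in profiles.index:
        base = baseline
        if leave_one_out and sid in healthy_ids and len(healthy_ids) > 1:
            others = [h for h in healthy_ids if h != sid]
            base = healthy_median_baseline(profiles, others)
        score = pearson_score(profiles.loc[sid], base, sample_id=sid)
        rows.append({"sample_id": sid, "group": matrix.groups.get(sid, ""),
                     "r": score.r})
    return pd.DataFrame(rows).set_index("sample_id")


def classify(score: float, cutoff: float) -> str:
    """Cancer if ``r < cutoff`` else healthy (strict inequality)."""
    return POSITIVE if score < cutoff else NEGATIVE


def _validate_scores_labels(scores, labels):
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if len(scores) != len(labels):
        raise ValueError("scores and labels differ in length")
    pos = labels == POSITIVE
    neg = labels == NEGATIVE
    if not (pos | neg).all():
        raise ValueError("labels must be 'cancer' or 'healthy'")
    if pos.sum() == 0 or neg.sum() == 0:
        raise ValueError("both classes must be present")
    return scores, pos, neg


def cutoff_table(scores, labels, cutoffs) -> pd.DataFrame:
    """Sensitivity/specificity (percent, one decimal) at each cutoff.

    Sensitivity: % of cancer samples with ``r < cutoff``; specificity: % of
    healthy samples with ``r >= cutoff``.
    """
    scores, pos, neg = _validate_scores_labels(scores, labels)
    rows = []
    for c in cutoffs:
        sens = 100.0 * (scores[pos] < c).mean()
        spec = 100.0 * (scores[neg] >= c).mean()
        rows.append({"cutoff": float(c), "sensitivity": round(sens, 1),
                     "specificity": round(spec, 1)})
    return pd.DataFrame(rows)


def choose_cutoff(scores, labels) -> float:
    """Cutoff maximizing sensitivity + specificity (Youden's J).

    Candidates are midpoints between adjacent distinct scores plus one
    extreme on either side; ties break toward higher specificity, then the
    lower cutoff.
    """
    scores, pos, neg = _validate_scores_labels(scores, labels)
    uniq = np.unique(scores)
    mids = (uniq[:-1] + uniq[1:]) / 2.0
    candidates = np.concatenate([[uniq[0] - 1.0], mids, [uniq[-1] + 1.0]])
    best = None
    for c in candidates:
        sens = (scores[pos] < c).mean()
        spec = (scores[neg] >= c).mean()
        key = (sens + spec, spec, -c)
        if best is None or key > best[0]:
            best = (key, float(c))
    return best[1]


def roc_auc(scores, labels) -> RocCurve:
    """ROC curve and AUC for the "low r is cancer-like" orientation.

    The curve sweeps the cutoff over all distinct scores; AUC equals both
    the trapezoidal integral of the curve and the Mann-Whitney statistic
    ``P(r_cancer < r_healthy) + 0.5 * P(tie)``.
    """
    scores, pos, neg = _validate_scores_labels(scores, labels)
    uniq = np.unique(scores)
    tpr = [0.0]
    fpr = [0.0]
    thresholds = [-np.inf]
    for v in uniq:  # cutoff just above v: counts all scores <= v as positive
        tpr.append((scores[pos] <= v).mean())
        fpr.append((scores[neg] <= v).mean())
        thresholds.append(v)
    fpr_a = np.asarray(fpr)
    tpr_a = np.asarray(tpr)
    auc = float(np.trapezoid(tpr_a, fpr_a))
    return RocCurve(fpr=fpr_a, tpr=tpr_a,
                    thresholds=np.asarray(thresholds), auc=auc)


def bootstrap_auc_ci(scores, labels, n_boot: int = 2000,
                     level: float = 0.95,
                     seed: int | np.random.Generator = 0) -> tuple[float, float]:
    """Percentile bootstrap CI for the AUC, stratified by class."""
    scores, pos, neg = _validate_scores_labels(scores, labels)
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    sp, sn = scores[pos], scores[neg]
    aucs = np.empty(n_boot)
    labs = np.array([POSITIVE] * len(sp) + [NEGATIVE] * len(sn))
    for i in range(n_boot):
        bs = np.concatenate([rng.choice(sp, len(sp), replace=True),
                             rng.choice(sn, len(sn), replace=True)])
        aucs[i] = roc_auc(bs, labs).auc
    lo = (1.0 - level) / 2.0
    return (float(np.quantile(aucs, lo)), float(np.quantile(aucs, 1.0 - lo)))
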