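"""End-to-end orchestration: simulate / discovery / validation runs.

``run_discovery`` takes matched Input/IP fragment sets for two cohorts and
executes deduplication, size filtering, fragmentomics summaries, windowed
NB DMR calling and informative-window selection, emitting TSV artifacts and
a machine-readable report.  ``run_validation`` builds adjusted-ratio
profiles over a window set (supplied from discovery, or called within the
cohort), scores every sample against the healthy median baseline and
evaluates the classifier (cutoff table, ROC/AUC).

All counts in a report are recomputable from the stage outputs, and a fixed
config + seed reproduces artifacts byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .classifier import (
    bootstrap_auc_ci,
    choose_cutoff,
    classify,
    cutoff_table,
    roc_auc,
    score_samples,
)
from .dmr import (
    build_count_matrix,
    classify_dmrs,
    estimate_size_factors,
    filter_low_count_windows,
    nb_window_test,
)
from .fragment_io import WindowGrid, deduplicate, filter_size_range
from .fragmentomics import short_fragments_ratio
from .profiles import (
    SamplePair,
    WindowSelectionCriteria,
    build_profile_matrix,
    select_informative_windows,
)
from .simulate import SimulationConfig, SimulatedCohort, simulate_cohort


@dataclass(frozen=True)
class PipelineConfig:
    """Serializable analysis parameters for a pipeline run."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    size_lo: int = 100
    size_hi: int = 220
    min_mean_count: float = 10.0
    dmr_alpha: float = 0.05
    dmr_lfc: float = 1.0
    dmr_use_padj: bool = True
    min_fragments: int = 20
    max_adjusted_ratio: float = 10.0
    adjust_mode: str = "genome_input"
    leave_one_out: bool = False
    bin_bp: int = 5_000_000

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["simulation"] = self.simulation.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "simulation" in d:
            d["simulation"] = SimulationConfig.from_dict(d["simulation"])
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


class PipelineError(RuntimeError):
    """A stage failure, tagged with the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def _prepare_pairs(cohort: SimulatedCohort, cfg: PipelineConfig,
                   stage: str) -> tuple[list[SamplePair], dict]:
    """Dedup + size-filter every sample's Input and IP sets."""
    pairs = []
    stats = {}
    for s in cohort.samples:
        if s.ip_set is None:
            raise PipelineError(stage, f"sample {s.sample_id} has no IP library")
        prepared = {}
        for lib_name, fs in (("input", s.input_set), ("ip", s.ip_set)):
            dd = deduplicate(fs)
            sf = filter_size_range(dd, cfg.size_lo, cfg.size_hi)
            prepared[lib_name] = sf
            stats[f"{s.sample_id}.{lib_name}"] = {
                "read": len(fs),
                "duplicates_removed": dd.report["duplicates_removed"],
                "size_filtered_out": sf.report["size_filtered_out"],
                "kept": len(sf),
            }
        pairs.append(SamplePair(sample_id=s.sample_id, group=s.group,
                                input_set=prepared["input"],
                                ip_set=prepared["ip"]))
    return pairs, stats


def _check_groups(pairs: list[SamplePair], stage: str) -> None:
    for g in ("healthy", "cancer"):
        if not any(p.group == g for p in pairs):
            raise PipelineError(stage, f"group {g!r} has no samples")


def run_discovery(cohort: SimulatedCohort, cfg: PipelineConfig,
                  out_dir: str | Path | None = None) -> dict:
    """Fragment QC -> count matrix -> DMR calling -> window selection.

    Returns a report dict; when ``out_dir`` is given also writes the count
    matrix, DMR table, selected windows, per-sample ratio summaries and the
    report itself as TSV/JSON artifacts.
    """
    grid = WindowGrid(cohort.config.layout, cohort.config.window_size)
    pairs, frag_stats = _prepare_pairs(cohort, cfg, "discovery")
    _check_groups(pairs, "discovery")

    ratio_rows = []
    for p in pairs:
        r_in = short_fragments_ratio(p.input_set)
        r_ip = short_fragments_ratio(p.ip_set)
        ratio_rows.append({
            "sample_id": p.sample_id, "group": p.group,
            "input_ratio": r_in.ratio, "ip_ratio": r_ip.ratio,
            "delta": r_ip.ratio - r_in.ratio,
        })
    ratios = pd.DataFrame(ratio_rows).set_index("sample_id")

    groups = {p.sample_id: p.group for p in pairs}
    cm = build_count_matrix([p.ip_set for p in pairs], groups, grid)
    cm_f = filter_low_count_windows(cm, cfg.min_mean_count)
    if len(cm_f.counts) == 0:
        raise PipelineError("dmr_calling", "no windows pass the mean-count filter")
    sf = estimate_size_factors(cm_f)
    res = nb_window_test(cm_f, sf)
    dmrs = classify_dmrs(res, alpha=cfg.dmr_alpha, lfc=cfg.dmr_lfc,
                         use_padj=cfg.dmr_use_padj)
    criteria = WindowSelectionCriteria(min_fragments=cfg.min_fragments,
                                       max_adjusted_ratio=cfg.max_adjusted_ratio)
    selected = select_informative_windows(pairs, grid, dmrs, criteria,
                                          mode=cfg.adjust_mode)
    n_hyper = int((dmrs["class"] == "HYPER").sum())
    n_hypo = int((dmrs["class"] == "HYPO").sum())
    report = {
        "stage": "discovery",
        "version": __version__,
        "config": cfg.to_dict(),
        "fragments": frag_stats,
        "ratios": {s: {k: float(v) for k, v in row.items() if k != "group"}
                   for s, row in ratios.iterrows()},
        "windows_total": int(grid.n_windows),
        "windows_tested": int(len(cm_f.counts)),
        "dmr_counts": {"HYPER": n_hyper, "HYPO": n_hypo,
                       "total": n_hyper + n_hypo},
        "selected_windows": [int(w) for w in selected],
        "n_selected_windows": int(len(selected)),
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        wt = grid.windows_table().set_index("window")
        cm_out = wt.loc[cm_f.counts.index].join(cm_f.counts)
        cm_out.to_csv(out / "count_matrix.tsv", sep="\t")
        dmr_out = wt.loc[dmrs.index].join(dmrs)
        dmr_out.to_csv(out / "dmr_results.tsv", sep="\t")
        ratios.to_csv(out / "sample_ratios.tsv", sep="\t")
        wt.loc[selected].to_csv(out / "selected_windows.tsv", sep="\t")
        with open(out / "discovery_report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
    report["_dmrs"] = dmrs
    report["_pairs"] = pairs
    report["_grid"] = grid
    return report


def run_validation(cohort: SimulatedCohort, cfg: PipelineConfig,
                   windows: np.ndarray | None = None,
                   dmrs: pd.DataFrame | None = None,
                   out_dir: str | Path | None = None) -> dict:
    """Profile -> baseline -> scores -> cutoff table -> ROC.

    ``windows=None`` calls DMRs within the cohort (the published mode) and
    selects informative hypomethylated windows from them; otherwise the
    supplied (discovery-trained) window set is used after re-checking the
    per-sample informativeness criteria on this cohort.
    """
    grid = WindowGrid(cohort.config.layout, cohort.config.window_size)
    pairs, frag_stats = _prepare_pairs(cohort, cfg, "validation")
    _check_groups(pairs, "validation")
    healthy_ids = [p.sample_id for p in pairs if p.group == "healthy"]
    criteria = WindowSelectionCriteria(min_fragments=cfg.min_fragments,
                                       max_adjusted_ratio=cfg.max_adjusted_ratio)
    if windows is None:
        disc = run_discovery(cohort, cfg)
        dmrs = disc["_dmrs"]
        selected = np.asarray(disc["selected_windows"], dtype=np.int64)
    else:
        windows = np.asarray(windows, dtype=np.int64)
        if len(windows) == 0:
            raise PipelineError("validation", "empty window set supplied")
        if dmrs is not None:
            pseudo = dmrs.loc[dmrs.index.intersection(windows)]
        else:  # class bookkeeping only; selection still enforced per sample
            pseudo = pd.DataFrame({"class": "HYPO"},
                                  index=pd.Index(windows, name="window"))
        selected = select_informative_windows(pairs, grid, pseudo, criteria,
                                              mode=cfg.adjust_mode)
    if len(selected) == 0:
        raise PipelineError("validation",
                            "no informative windows available for profiling")
    matrix = build_profile_matrix(pairs, grid, selected, dmrs=dmrs,
                                  mode=cfg.adjust_mode)
    scores = score_samples(matrix, healthy_ids=healthy_ids,
                           leave_one_out=cfg.leave_one_out)
    labels = scores["group"].to_numpy()
    svals = scores["r"].to_numpy()
    cutoff = choose_cutoff(svals, labels)
    scores = scores.assign(
        predicted=[classify(v, cutoff) for v in svals])
    roc = roc_auc(svals, labels)
    table = cutoff_table(svals, labels, sorted({cutoff, *np.round(
        np.quantile(svals, [0.25, 0.5, 0.75]), 2)}, reverse=True))
    ci_lo, ci_hi = bootstrap_auc_ci(svals, labels,
                                    seed=cohort.config.seed)
    report = {
        "stage": "validation",
        "version": __version__,
        "config": cfg.to_dict(),
        "fragments": frag_stats,
        "n_selected_windows": int(len(selected)),
        "selected_windows": [int(w) for w in selected],
        "scores": {s: float(r) for s, r in scores["r"].items()},
        "chosen_cutoff": float(cutoff),
        "cutoff_table": table.to_dict(orient="records"),
        "auc": float(roc.auc),
        "auc_ci95": [ci_lo, ci_hi],
        "mean_r_healthy": float(scores.loc[scores["group"] == "healthy", "r"].mean()),
        "mean_r_cancer": float(scores.loc[scores["group"] == "cancer", "r"].mean()),
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        wt = grid.windows_table().set_index("window")
        header = [f"{c}:{s}-{e}" for c, s, e in
                  zip(*grid.window_bounds(selected))]
        prof = matrix.values.copy()
        prof.columns = header
        prof.to_csv(out / "profile_matrix.tsv", sep="\t")
        scores.to_csv(out / "scores.tsv", sep="\t")
        pd.DataFrame({"fpr": roc.fpr, "tpr": roc.tpr,
                      "threshold": roc.thresholds}).to_csv(
            out / "roc_points.tsv", sep="\t", index=False)
        table.to_csv(out / "cutoff_table.tsv", sep="\t", index=False)
        with open(out / "validation_report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
    report["_matrix"] = matrix
    report["_scores"] = scores
    return report


def simulate(cfg: SimulationConfig, out_dir: str | Path) -> SimulatedCohort:
    """CLI-facing wrapper around :func:`fragmedip.simulate.simulate_cohort`."""
    return simulate_cohort(cfg, out_dir=out_dir)
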