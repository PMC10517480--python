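"""Synthetic paired Input/IP cfDNA cohorts with known methylation ground truth.

The generator encodes the mechanistic picture behind DMR-dependent
fragmentation analysis: cfDNA is released by nuclease digestion of chromatin;
hypomethylated chromatin is more accessible, so fragments originating from
less-methylated windows are more often sub-mononucleosomal ("short",
100-150 bp) rather than mononucleosomal ("long", 151-220 bp).  A 5mC
immunoprecipitation then thins the Input pool molecule-by-molecule, retaining
methylated molecules with probability ``p_capture`` and unmethylated ones
with probability ``p_background``; the IP library is therefore a subset of
the Input molecules, which is what makes input adjustment meaningful.

Cancer samples are a tumor-fraction mixture: each fragment is tumor-derived
with probability ``tumor_fraction`` and then sees the tumor methylation
landscape, which differs from the healthy one exactly on planted
hypo-/hypermethylated windows.  Tumor-derived fragments also carry a small
global short-fraction boost ``gamma`` (elevated digestion in malignancy).

Two couplings deserve a note because they carry the observable signatures:

* healthy-origin short fragments are methylated with probability
  ``m * (1 - short_unmeth_coupling)`` rather than ``m`` — shorts arise
  preferentially from accessible, locally hypomethylated chromatin, so the
  IP depletes them.  Tumor-origin shorts instead come from globally
  elevated, methylation-independent digestion, so their methylation content
  samples the tumor genome at large (the mean tumor methylation) rather
  than tracking the source window.  This is why the IP-vs-Input short-ratio
  change is smaller in cancer samples, and why tumor shorts from
  hypomethylated windows survive the IP instead of vanishing with their
  window's methylation.
* with ``dmr_penetrance < 1`` each planted window is altered in a given
  cancer patient's tumor only with that probability, producing the
  patient-specific aberrant windows that a correlation-to-baseline
  classifier keys on.  The default is 1 (every patient carries every
  planted alteration, i.e. a single shared tumor landscape).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .fragment_io import (
    INPUT,
    IP,
    FragmentSet,
    GenomeLayout,
    WindowGrid,
    make_fragment_set,
    write_fragment_table,
)

HEALTHY = "healthy"
CANCER = "cancer"


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the cohort generator, with mechanistically chosen defaults.

    Sizes follow a two-component truncated-normal mixture over 100-220 bp
    (sub-mononucleosomal vs mononucleosomal).  The short-fragment probability
    of a fragment from window w is
    ``clip(pi_base + kappa * (1 - m_w) + gamma * [tumor origin], 0, 1)``.
    """

    chrom_lengths: tuple[tuple[str, int], ...] = (
        ("chr1", 10_000_000), ("chr2", 10_000_000))
    window_size: int = 10_000
    n_healthy: int = 3
    n_cancer: int = 3
    n_input_fragments: int = 200_000
    # size mixture (bp)
    mu_short: float = 135.0
    sigma_short: float = 10.0
    mu_long: float = 167.0
    sigma_long: float = 12.0
    short_lo: int = 100
    short_hi: int = 150
    long_lo: int = 151
    long_hi: int = 220
    # methylation -> fragmentation couplings
    pi_base: float = 0.145
    kappa: float = 0.15
    gamma: float = 0.02
    short_unmeth_coupling: float = 0.5
    # cancer mixture and planted effects
    tumor_fraction: float = 0.2
    delta_hypo: float = 0.5
    delta_hyper: float = 0.4
    n_hypo: int = 200
    n_hyper: int = 200
    dmr_penetrance: float = 1.0
    # IP capture model
    p_capture: float = 0.8
    p_background: float = 0.05
    # healthy methylation landscape
    beta_a: float = 8.0
    beta_b: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("pi_base", "kappa", "gamma", "tumor_fraction",
                     "delta_hypo", "delta_hyper", "p_capture",
                     "p_background", "short_unmeth_coupling",
                     "dmr_penetrance"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} must be in [0, 1]")
        if self.pi_base + self.kappa + self.gamma > 1.0:
            raise ValueError("pi_base + kappa + gamma must be <= 1")
        if self.n_hypo < 0 or self.n_hyper < 0:
            raise ValueError("planted window counts must be >= 0")
        if self.n_healthy < 0 or self.n_cancer < 0:
            raise ValueError("cohort sizes must be >= 0")

    @property
    def layout(self) -> GenomeLayout:
        names, lengths = zip(*self.chrom_lengths)
        return GenomeLayout(tuple(names), tuple(int(l) for l in lengths))

    @property
    def grid(self) -> WindowGrid:
        return WindowGrid(self.layout, self.window_size)

    @classmethod
    def strong_effect(cls, **overrides) -> "SimulationConfig":
        """High-burden preset: stronger methylation-fragmentation coupling,
        high tumor fraction, deeper planted hypomethylation expressed with
        50% per-patient penetrance, and sequencing depth matching a ~5x IP
        library (~180 IP fragments per 10-kb window)."""
        base = dict(kappa=0.45, gamma=0.04, tumor_fraction=0.9,
                    delta_hypo=0.75, dmr_penetrance=0.5,
                    n_input_fragments=600_000)
        base.update(overrides)
        return cls(**base)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["chrom_lengths"] = [list(x) for x in self.chrom_lengths]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "chrom_lengths" in d:
            d["chrom_lengths"] = tuple(
                (str(c), int(l)) for c, l in d["chrom_lengths"])
        return cls(**d)


@dataclass
class MethylationLandscape:
    """Per-window methylation in [0,1] for healthy and tumor states.

    ``m_tumor`` differs from ``m`` exactly on the planted sets: lower on
    ``hypo`` windows, higher on ``hyper`` windows.
    """

    m: np.ndarray
    m_tumor: np.ndarray
    hypo: np.ndarray
    hyper: np.ndarray

    def __post_init__(self) -> None:
        self.hypo = np.asarray(self.hypo, dtype=np.int64)
        self.hyper = np.asarray(self.hyper, dtype=np.int64)
        if np.intersect1d(self.hypo, self.hyper).size:
            raise ValueError("planted hypo and hyper sets must be disjoint")

    @property
    def n_windows(self) -> int:
        return len(self.m)


@dataclass
class SimulatedSample:
    """One participant: paired Input/IP fragment sets plus latent truth.

    ``latent`` has one row per Input fragment: source window (flat id),
    tumor origin, methylated flag, short flag; ``ip_mask`` marks the
    molecules retained by the immunoprecipitation, so IP records are by
    construction a subset of the Input molecules.
    """

    sample_id: str
    group: str
    input_set: FragmentSet
    latent: pd.DataFrame
    ip_set: FragmentSet | None = None
    ip_mask: np.ndarray | None = None


@dataclass
class SimulatedCohort:
    config: SimulationConfig
    landscape: MethylationLandscape
    samples: list[SimulatedSample]

    def by_group(self, group: str) -> list[SimulatedSample]:
        return [s for s in self.samples if s.group == group]


# ---------------------------------------------------------------------------
# landscape
# ---------------------------------------------------------------------------


def build_landscape(cfg: SimulationConfig,
                    rng: np.random.Generator | None = None) -> MethylationLandscape:
    """Draw the healthy methylation landscape and plant tumor DMR windows.

    Healthy per-window methylation is Beta(beta_a, beta_b).  Planted sets are
    disjoint; hypo windows are drawn with probability proportional to
    ``1 - m_w`` and hyper windows proportional to ``m_w`` among the
    remainder, so that windows prone to losing methylation are the less
    solidly methylated ones (and vice versa) — this gives healthy samples the
    higher short-fragment ratio in hypo vs hyper windows that is seen in
    real cohorts.  Tumor values: ``m*(1-delta_hypo)`` on hypo,
    ``m + delta_hyper*(1-m)`` on hyper, unchanged elsewhere.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    n = cfg.grid.n_windows
    if cfg.n_hypo + cfg.n_hyper > n:
        raise ValueError("more planted windows requested than windows exist")
    m = rng.beta(cfg.beta_a, cfg.beta_b, size=n)
    w_hypo = 1.0 - m
    hypo = rng.choice(n, size=cfg.n_hypo, replace=False,
                      p=w_hypo / w_hypo.sum()) if cfg.n_hypo else np.array([], dtype=np.int64)
    w_hyper = m.copy()
    w_hyper[hypo] = 0.0
    hyper = rng.choice(n, size=cfg.n_hyper, replace=False,
                       p=w_hyper / w_hyper.sum()) if cfg.n_hyper else np.array([], dtype=np.int64)
    hypo = np.sort(hypo)
    hyper = np.sort(hyper)
    m_tumor = m.copy()
    m_tumor[hypo] = m[hypo] * (1.0 - cfg.delta_hypo)
    m_tumor[hyper] = np.minimum(1.0, m[hyper] + cfg.delta_hyper * (1.0 - m[hyper]))
    return MethylationLandscape(m=m, m_tumor=m_tumor, hypo=hypo, hyper=hyper)


def _patient_tumor_landscape(cfg: SimulationConfig,
                             landscape: MethylationLandscape,
                             rng: np.random.Generator) -> np.ndarray:
    """Patient-specific tumor methylation under partial DMR penetrance.

    Each planted window carries its alteration in this patient's tumor with
    probability ``dmr_penetrance`` (at full effect size), mirroring how real
    DMRs are recurrently but not universally altered across patients.  With
    penetrance 1 the shared landscape is returned unchanged.
    """
    if cfg.dmr_penetrance >= 1.0:
        return landscape.m_tumor
    m_t = landscape.m.copy()
    on_hypo = rng.random(len(landscape.hypo)) < cfg.dmr_penetrance
    on_hyper = rng.random(len(landscape.hyper)) < cfg.dmr_penetrance
    h = landscape.hypo[on_hypo]
    m_t[h] = landscape.m[h] * (1.0 - cfg.delta_hypo)
    hh = landscape.hyper[on_hyper]
    m_t[hh] = np.minimum(1.0, landscape.m[hh]
                         + cfg.delta_hyper * (1.0 - landscape.m[hh]))
    return m_t


# ---------------------------------------------------------------------------
# fragment sampling
# ---------------------------------------------------------------------------


def _truncated_normal_lengths(rng: np.random.Generator, n: int, mu: float,
                              sigma: float, lo: int, hi: int) -> np.ndarray:
    """Integer lengths from a normal truncated to [lo, hi] inclusive."""
    if n == 0:
        return np.zeros(0, dtype=np.int64)
    a = (lo - 0.5 - mu) / sigma
    b = (hi + 0.5 - mu) / sigma
    x = stats.truncnorm.rvs(a, b, loc=mu, scale=sigma, size=n, random_state=rng)
    return np.clip(np.rint(x).astype(np.int64), lo, hi)


def sample_input_fragments(cfg: SimulationConfig,
                           landscape: MethylationLandscape,
                           group: str,
                           rng: np.random.Generator,
                           sample_id: str) -> SimulatedSample:
    """Generate one participant's Input library plus latent labels.

    Source windows are uniform over the grid; fragments are placed uniformly
    within their window (fully inside it, so the midpoint rule recovers the
    latent window exactly).  Barcodes are unique serial strings, so the
    simulated molecules are duplicate-free by construction.
    """
    if group not in (HEALTHY, CANCER):
        raise ValueError(f"group must be {HEALTHY!r} or {CANCER!r}")
    grid = cfg.grid
    n = cfg.n_input_fragments
    window = rng.integers(0, grid.n_windows, size=n)
    if group == CANCER:
        tumor = rng.random(n) < cfg.tumor_fraction
        m_tumor = _patient_tumor_landscape(cfg, landscape, rng)
    else:
        tumor = np.zeros(n, dtype=bool)
        m_tumor = landscape.m_tumor
    m_src = np.where(tumor, m_tumor[window], landscape.m[window])
    pi = np.clip(cfg.pi_base + cfg.kappa * (1.0 - m_src) + cfg.gamma * tumor,
                 0.0, 1.0)
    short = rng.random(n) < pi
    lengths = np.empty(n, dtype=np.int64)
    lengths[short] = _truncated_normal_lengths(
        rng, int(short.sum()), cfg.mu_short, cfg.sigma_short,
        cfg.short_lo, cfg.short_hi)
    lengths[~short] = _truncated_normal_lengths(
        rng, int((~short).sum()), cfg.mu_long, cfg.sigma_long,
        cfg.long_lo, cfg.long_hi)
    # methylation flag: healthy-origin shorts come from accessible (locally
    # hypomethylated) chromatin; tumor-origin shorts from global digestion,
    # so their methylation reflects the tumor genome mean, not the window
    p_meth = m_src * (1.0 - cfg.short_unmeth_coupling * (short & ~tumor))
    p_meth = np.where(short & tumor, m_tumor.mean(), p_meth)
    methylated = rng.random(n) < p_meth
    chroms, wstarts, wends = grid.window_bounds(window)
    span = wends - wstarts - lengths
    if np.any(span < 0):  # windows shorter than a fragment cannot occur at 10 kb
        raise ValueError("window size too small for sampled fragment lengths")
    start = wstarts + rng.integers(0, span + 1)
    end = start + lengths
    barcodes = np.char.add("M", np.arange(n).astype(str)).astype(object)
    input_set = make_fragment_set(sample_id, INPUT, chroms, start, end,
                                  barcodes, dedup_applied=False)
    latent = pd.DataFrame({"window": window, "tumor": tumor,
                           "methylated": methylated, "short": short})
    return SimulatedSample(sample_id=sample_id, group=group,
                           input_set=input_set, latent=latent)


def apply_ip_capture(sample: SimulatedSample, cfg: SimulationConfig,
                     rng: np.random.Generator) -> SimulatedSample:
    """Thin the Input pool into the IP library.

    Each molecule is retained with probability ``p_capture`` if methylated
    else ``p_background``; retained molecules keep their coordinates and
    barcodes.  Fills ``sample.ip_set``/``ip_mask`` in place and returns the
    sample.
    """
    meth = sample.latent["methylated"].to_numpy()
    p = np.where(meth, cfg.p_capture, cfg.p_background)
    keep = rng.random(len(p)) < p
    ip_frame = sample.input_set.frame[keep]
    sample.ip_set = sample.input_set.with_frame(ip_frame)
    sample.ip_set.library = IP
    sample.ip_mask = keep
    return sample


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------


def simulate_cohort(cfg: SimulationConfig,
                    out_dir: str | Path | None = None,
                    landscape: MethylationLandscape | None = None
                    ) -> SimulatedCohort:
    """Simulate ``n_healthy + n_cancer`` paired Input/IP samples.

    Healthy samples are named H1.. and cancer samples P1.. (grouped healthy
    first).  All randomness derives from ``cfg.seed`` through spawned child
    streams (one for the landscape, one per sample), so a fixed seed gives
    byte-identical output regardless of how samples are iterated.  When
    ``out_dir`` is given, per-sample fragment TSVs, a ground-truth manifest
    (JSON) and the config (YAML) are written there.

    Pass ``landscape`` to draw a new cohort of participants on an existing
    methylation landscape: the planted DMR windows are disease biology and
    must be shared between discovery and validation cohorts for
    discovery-trained windows to mean anything in validation.
    """
    n_samples = cfg.n_healthy + cfg.n_cancer
    seeds = np.random.SeedSequence(cfg.seed).spawn(n_samples + 1)
    if landscape is None:
        landscape = build_landscape(cfg, np.random.default_rng(seeds[0]))
    elif landscape.n_windows != cfg.grid.n_windows:
        raise ValueError("supplied landscape does not match the window grid")
    samples: list[SimulatedSample] = []
    groups = [HEALTHY] * cfg.n_healthy + [CANCER] * cfg.n_cancer
    names = ([f"H{i+1}" for i in range(cfg.n_healthy)]
             + [f"P{i+1}" for i in range(cfg.n_cancer)])
    for name, group, seed in zip(names, groups, seeds[1:]):
        rng = np.random.default_rng(seed)
        s = sample_input_fragments(cfg, landscape, group, rng, name)
        apply_ip_capture(s, cfg, rng)
        samples.append(s)
    cohort = SimulatedCohort(config=cfg, landscape=landscape, samples=samples)
    if out_dir is not None:
        write_cohort(cohort, out_dir)
    return cohort


def cohort_manifest(cohort: SimulatedCohort) -> dict:
    """Ground-truth manifest: planted windows plus per-sample latent summaries."""
    ls = cohort.landscape
    per_sample = []
    for s in cohort.samples:
        lat = s.latent
        per_sample.append({
            "sample_id": s.sample_id,
            "group": s.group,
            "n_input_fragments": int(len(s.input_set)),
            "n_ip_fragments": int(len(s.ip_set)) if s.ip_set is not None else None,
            "input_short_fraction": float(lat["short"].mean()),
            "methylated_fraction": float(lat["methylated"].mean()),
            "tumor_fraction_realized": float(lat["tumor"].mean()),
        })
    return {
        "config": cohort.config.to_dict(),
        "n_windows": int(ls.n_windows),
        "hypo_windows": [int(w) for w in ls.hypo],
        "hyper_windows": [int(w) for w in ls.hyper],
        "mean_methylation_healthy": float(ls.m.mean()),
        "samples": per_sample,
    }


def write_cohort(cohort: SimulatedCohort, out_dir: str | Path) -> None:
    import yaml

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for s in cohort.samples:
        write_fragment_table(s.input_set, out / f"{s.sample_id}.input.tsv")
        if s.ip_set is not None:
            write_fragment_table(s.ip_set, out / f"{s.sample_id}.ip.tsv")
    with open(out / "manifest.json", "w") as fh:
        json.dump(cohort_manifest(cohort), fh, indent=2, sort_keys=True)
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(cohort.config.to_dict(), fh, sort_keys=True)
    cohort.config.layout.to_tsv(out / "chrom_sizes.tsv")
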