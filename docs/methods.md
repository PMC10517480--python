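# Methods

## Overview

`fragmedip` analyzes paired Input/IP libraries from cfMeDIP-seq (cell-free
methylated-DNA immunoprecipitation sequencing) to ask whether the
fragmentation profile of plasma cfDNA in differentially methylated regions
separates cancer patients from healthy individuals.  The pipeline has five
computational stages — fragment I/O, fragment-size statistics, windowed
differential methylation, input-adjusted fragmentation profiles, and a
correlation-baseline classifier — plus a generative cohort simulator that
provides ground truth for every stage.

## Fragment handling

A fragment is a strandless 0-based half-open interval with an optional
molecular barcode; its length is `end − start`.  From paired-end
alignments, one fragment is emitted per retained read pair (leftmost start
to rightmost end).  Pairs are dropped when not properly paired, secondary/
supplementary/unmapped, below a mapping-quality floor (default 30, the
operational proxy for "uniquely mapped"), or with insert below 20 bp.  PCR
duplicates are records sharing (chromosome, start, end, barcode); the first
record per key is kept.  Analysis is restricted to 100–220 bp, the
mononucleosomal range.  Fragments are assigned to nonoverlapping genomic
windows by the midpoint rule `floor((start+end)/2)`, which gives every
fragment exactly one window and makes window counts conserve totals;
boundary-spanning behaviour therefore never double-counts.

Short fragments are 100–150 bp, long fragments 151–220 bp (inclusive).  The
short-fragments ratio of a library or region is `n_short / n_long`; an
empty denominator propagates as missing rather than zero so that sparse
windows cannot masquerade as informative.  Genome-wide profiles use 5-Mb
bins by default and are computed without GC adjustment.

## Windowed differential methylation

IP coverage of a 10-kb window tracks its methylation level, so differential
methylation is tested on deduplicated, size-filtered IP fragment counts per
window.  Windows with mean count below 10 (across all samples pooled) are
removed.  Normalization uses median-of-ratios size factors.  Per window the
model is a negative-binomial GLM with log link and the size factor as
offset; dispersion is estimated by method of moments on normalized counts
(within-group variance, Poisson part subtracted), clipped to `[0, 10]`,
shrunk 50/50 toward a `a0 + a1/μ` trend fitted across windows, and floored
at `1e−8`.  The group effect is assessed by a Wald test against a standard
normal reference; the trend shrinkage is what keeps the small-sample (3v3)
null near nominal — measured fraction of raw p < 0.05 on a pure null cohort
is ≈ 0.03.  Benjamini–Hochberg adjustment is applied across windows, and
windows are classified HYPER (`padj < α`, `log2FC > L`) or HYPO
(`log2FC < −L`), defaults α = 0.05, L = 1, with a raw-p mode for cohorts
analyzed without adjustment.  The reported `log2FC` is the ratio of group
means of normalized counts with pseudocount 0.5, which keeps zero-count
windows bounded without shrinkage machinery.

This NB pipeline is deliberately compact — no independent filtering,
outlier handling, or posterior fold-change shrinkage — and its correctness
is established by null calibration and planted-effect recovery, not by
numeric parity with any external differential-count tool.  An independent
per-window GLM fit (statsmodels, same design/offset/dispersion) is used as
a cross-check in the test suite only.

## Input-adjusted fragmentation profiles

A window's IP short-fragments ratio confounds methylation-driven capture
with pre-existing short-fragment excess.  The input-adjusted ratio divides
it by the genome-wide short-fragments ratio of the matched Input library
(default), or by the same window's Input ratio (`mode="window_input"`, for
sensitivity analysis; the genome-wide form is the only operationally
complete published definition, while figure legends suggest the per-window
form — both are provided, neither asserted as canonical).  Profile windows
must be informative in every sample of both cohorts: at least 20
deduplicated IP fragments and an adjusted ratio defined and below 10.
"Frequently altered" window sets are operationalized as exactly this
selection applied to hypomethylated DMRs, with no additional recurrence
filter.

## Classifier

The baseline profile is the per-window median of healthy samples' adjusted
ratios (even counts average the two middle values; an optional
leave-one-out mode excludes the scored healthy sample from its own
baseline).  Each sample is scored by Pearson correlation `r` to the
baseline; low correlation is cancer-like, and a sample is called cancer
when `r < cutoff` (strict).  The operating cutoff maximizes
sensitivity + specificity over midpoints of adjacent distinct scores plus
extremes, breaking ties toward higher specificity and then the lower
cutoff.  The ROC curve sweeps all distinct scores; its trapezoidal AUC
equals the Mann–Whitney statistic `P(r_cancer < r_healthy) + ½P(tie)`
exactly, including ties.  A stratified percentile bootstrap (2000
replicates) gives the AUC confidence interval; the CI method for the
published interval is unstated, so percentile bootstrap was chosen.

## The cohort simulator

The generator encodes the mechanistic model linking methylation to
fragmentation: nucleosomes in hypomethylated chromatin are more accessible
to apoptotic nucleases, so such regions release more sub-mononucleosomal
fragments; 5mC immunoprecipitation then enriches methylated molecules.

Per sample, `n_input_fragments` molecules (default 200,000) are drawn:
source window uniform over a 2 × 10-Mb genome tiled at 10 kb (2000
windows); healthy per-window methylation `m_w ~ Beta(8, 2)` (mean 0.8).  A
fragment is short with probability
`π = clip(π_base + κ(1 − m_src) + γ·[tumor], 0, 1)`, defaults
π_base = 0.145, κ = 0.15, γ = 0.02; lengths are integer truncated normals,
N(135, 10²) on [100, 150] for shorts and N(167, 12²) on [151, 220] for
longs.  Fragments lie fully inside their source window so the midpoint rule
recovers the latent window.  Barcodes are unique serials (the simulated
pool is duplicate-free; deduplication is a no-op on it by design).

Methylation of a molecule is Bernoulli in its window's level, with one
deliberate asymmetry between the two digestion pathways.  Healthy-origin
short fragments are methylated with probability `m(1 − ρ)`, ρ = 0.5 by
default (`short_unmeth_coupling`): shorts arise preferentially from locally
accessible, less-methylated chromatin, so the IP depletes them (healthy
Input ratio ≈ 0.21, IP ≈ 0.12 at defaults).  Tumor-origin short fragments
instead come from globally elevated, methylation-independent digestion, so
their methylation content samples the tumor genome at large — they are
methylated at the tumor's mean methylation level regardless of source
window (tumor-origin long fragments follow their window's tumor level
`m'`).  This asymmetry carries the cohort-level signatures: the IP-vs-Input
short-ratio change is smaller in magnitude for cancer samples (tumor
shorts resist depletion), and tumor shorts released from planted
hypomethylated windows survive the IP instead of vanishing with their
window's methylation, which is what elevates the cancer hypo-vs-hyper
percent change and the adjusted ratios over hypo windows.  Coupling tumor
shorts to their local window level instead predicts the wrong ordering on
both counts: hypo-window tumor shorts would be discarded by the capture
step while hyper-window ones were amplified.

The IP library is per-molecule Bernoulli thinning of the Input pool:
retention 0.8 if methylated, 0.05 otherwise.  This mirrors the paired
design and makes input adjustment meaningful, but it also bounds the
attainable differential signal: with tumor fraction `f_t`, the
cancer/healthy expected IP count ratio of any window lies within
`[1 − f_t, …]`, i.e. |log2FC| ≤ −log2(1 − f_t) ≈ 0.32 at the default
f_t = 0.2.  Planted-window recovery at the published |log2FC| > 1
threshold is therefore impossible at the default tumor fraction — a
structural property of the thinning model, not an estimation failure — and
the recovery tests document this.

Cancer samples are a tumor-fraction mixture (default f_t = 0.2): each
fragment is tumor-derived with probability f_t and then sees the tumor
landscape, which differs from the healthy one on 200 planted hypo windows
(`m' = m(1 − δ_hypo)`, δ = 0.5) and 200 planted hyper windows
(`m' = m + δ_hyper(1 − m)`, δ = 0.4).  Planted hypo windows are drawn with
probability ∝ (1 − m_w) and hyper windows ∝ m_w (disjoint): regions prone
to losing methylation are the less solidly methylated ones.  This biased
planting is what gives healthy samples, too, a higher short-fragments ratio
in hypo than in hyper windows, as real cohorts show; uniform planting
cannot, because healthy samples are blind to the planted sets.

With `dmr_penetrance < 1`, each planted window is altered in a given
patient's tumor only with that probability (at full effect), emulating
recurrently-but-not-universally altered DMRs.  This per-patient
heterogeneity is what a correlation-to-baseline classifier detects: a
tumor effect shared identically by all patients is close to an affine
transform of the healthy profile and barely moves Pearson r.  Default
penetrance is 1 (single shared tumor landscape).

All randomness flows from one seed through spawned child streams (one for
the landscape, one per sample), so a fixed configuration is bitwise
reproducible regardless of sample iteration order.

### The strong-effect preset

`SimulationConfig.strong_effect()` is the high-burden regime used to
demonstrate classifier separation end-to-end: κ = 0.45, f_t = 0.9,
δ_hypo = 0.75, γ = 0.04, penetrance 0.5, and 600,000 Input fragments per
sample — the depth that gives ≈ 180 IP fragments per 10-kb window,
matching a ~5× IP library rather than the shallow default.  Windows are
trained on a 12 vs 12 discovery cohort (the size of the larger published
discovery design; a 3 vs 3 cohort has no power under the thinning bound)
at α = 0.05, L = 0.2, then an 8 vs 11 validation cohort is profiled over
those windows and scored against its own healthy median baseline.  On this
fixture the healthy mean r is ≈ 0.81–0.86 and the cancer mean ≈ 0.62–0.73
across seeds, with AUC ≥ 0.95.

### What the simulator does and does not emulate

It reproduces the paired Input/IP design, mononucleosomal size mixture,
methylation-coupled short-fragment release, capture thinning, planted DMRs
with patient heterogeneity, and exact duplicate-free barcoding.  It does
not model GC bias, copy-number change, CpG-level methylation, sequencing
error, optical duplicates, or read-level data; fragment placement is
uniform within windows (no nucleosome phasing).  Passing tests therefore
validate the statistical machinery and the directional logic of the
method, not its operating characteristics on real plasma libraries —
genome scale, depth, and biological between-sample variance are all
smaller here than in real cohorts.

## Numerical and design choices

* Ratios with empty denominators are missing, never zero.
* Region restriction uses the same midpoint assignment as window counting,
  keeping DMR counts and ratio computations consistent.
* IRLS for the NB GLM runs vectorized across windows (30 iterations max,
  1e−10 coefficient tolerance, η clipped to ±30); degenerate windows fall
  back to moment estimates, and single-sample groups report fold changes
  with missing p.
* The mean-count filter pools both groups, matching the published wording
  "the mean counts" without grouping.
* Size-factor estimation errors out when no window has all-positive counts
  and offers an explicit `poscounts` fallback rather than silently
  switching.
* Dedup keeps the first-encountered record — deterministic under any
  stable input order.
* Barcode whitelists and barcode error correction are out of scope;
  barcodes are taken verbatim.

## Problem sizes used in the shipped analyses

The default study conditions are 2000 × 10-kb windows, 3 vs 3 samples,
200,000 Input fragments each; null calibration uses 10 replicate null
cohorts at those conditions; the strong-effect classifier fixture uses
12 vs 12 discovery and 8 vs 11 validation at 600,000 fragments.  These
sizes keep a full run (test suite plus acceptance script) within a few
minutes on one CPU while leaving every per-window count in the regime the
method assumes (tens to hundreds of fragments per window).

## Known limitations

* The NB Wald test is calibrated for the simulated count regime (μ ≈
  30–300, near-Poisson to mild overdispersion); heavy-tailed real data
  would warrant the exact reference tool instead.
* The thinning capture model caps between-group fold changes at
  `−log2(1 − f_t)`; simulating strongly hypermethylation-driven designs
  would need an enrichment model with competitive amplification.
* `choose_cutoff` is an in-sample operating point, as in the published
  design; prospective use should freeze both the window set and the
  baseline (the `leave_one_out` and frozen-window modes exist for that).
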