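# Methods

## Photometry signal model and correction

A simulated session carries two channels on a uniform grid (default 100 Hz,
modelling the demodulated stream of a lock-in photometry rig):

    F465(t) = B465(t) · (1 + s(t) + m(t)) + ε(t)
    F405(t) = B405(t) · (1 + κ·m(t)) + ε′(t)

* `s(t)` — sum of calcium transients, each a double-exponential kernel
  `A·(e^(−t/τ_decay) − e^(−t/τ_rise))` normalised to unit peak before
  scaling. The peak time has the closed form
  `t* = τ_rise·τ_decay/(τ_decay − τ_rise) · ln(τ_decay/τ_rise)`, which the
  tests exploit. Defaults `τ_rise = 0.5 s`, `τ_decay = 5 s` describe slow
  population GCaMP6s transients as seen in bulk fibre photometry; amplitude
  is fractional ΔF/F (default 0.05 = 5 %ΔF/F). Transients are placed
  explicitly or by a Poisson process.
* `B(t)` — per-channel bi-exponential bleach envelope
  `1 − Σ f_i(1 − e^(−t/τ_i))`; defaults lose ~20% of baseline over a
  10-minute recording (τ = 100 s and 600 s). Bleaching is generated so the
  correction has something to remove; the correction itself never models it
  explicitly.
* `m(t)` — motion artifact: white Gaussian noise low-passed at 2 Hz
  (2nd-order Butterworth, zero-phase) and rescaled to `motion_sd`
  (default 2% of baseline), shared between channels with coupling κ
  (default 1). The isosbestic correction assumes a shared artifact; κ < 1
  degrades it deliberately.
* `ε` — white Gaussian noise, default 0.5% of each channel's baseline.

The correction fits a polynomial in `F405` to `F465` by least squares over
the whole recording (default order 1; the regression direction treats the
isosbestic trace as the signal being adjusted). With κ = 1 and identical
bleach shapes the two channels are exactly affinely related, so the
order-1 fit is exact and the corrected trace is numerically zero — the
no-signal control the acceptance checks enforce at < 0.01 %ΔF/F. %ΔF/F is
`100·(F465 − F405_fitted)/F405_fitted`; a non-positive fitted reference is
an error, never clipped. The trace is then smoothed with a centred moving
average (default 1 s; edges shrink to the valid span) and decimated by a
factor of 20, the moving average acting as the anti-aliasing stage.

An alternative reading of the correction — detrending over time rather
than regressing in the 405-value domain — is deliberately not implemented
as the default; the value-domain regression is the stated behaviour, and
the fit window is the entire recording.

Amplitude recovery under the default conditions (50 sessions, three 5 %ΔF/F
transients each) carries a small negative bias, dominated by the 1-s moving
average's attenuation of the kernel peak; the acceptance run reports the
measured bias and RMSE rather than asserting zero.

## Event alignment and window statistics

Events are aligned to the nearest sample (no interpolation); the relative
timebase is anchored on the recording's own time grid so left-closed,
right-open windows have exact boundaries at representable times. Trials
without full `[−pre, +post]` coverage are excluded and counted. The default
baseline is the mean over −60–0 s, subtracted per trial (a z-score mode is
available but not asserted as the original convention). Window statistics
aggregate per animal first, then across animals — in unbalanced designs
this differs from the pooled-trial mean, and a guard test pins the order.
Epoch comparisons return the mean %ΔF/F of the cue epoch
`[presentation, eating_onset)` and the consumption epoch
`[eating_onset, +epoch_len)`, trimmed with a counted warning at the
recording edge.

## Droplet counts generator

Counts are negative binomial with per-population mean vectors: each planted
population (Agrp/Npy, Pomc, Bnc2/Lepr, Nr5a1, and a generic remainder) sets
its marker genes to program means (3–8 counts/cell) over an ambient
background of 0.02; 1,500 filler genes at mean 2 give ~1,100 detected
features and ~3,000 total counts per cell, inside the 800–5,000-feature /
12,000-count QC window of a real nuclear library. Dispersion defaults to
r = 2 (variance μ + μ²/r). Mitochondrial content is drawn per cell as a
Beta(2, 398) target fraction (mean 0.5%, so a realistic minority of cells
violates the 1% QC gate) and realised by multinomial counts over three
`mt-` genes. Hashtag counts are NB around a signal mean (200) for the
cell's own hashtag and background (10) otherwise; negatives are drawn by
zeroing hashtag rows; doublets are formed by summing the full count
profiles of two sampled singlets, reducing the barcode count by exactly the
doublet count. Truth records each barcode's population, the dominant
("primary") component for doublets — the label a clustering stage would
assign the merged profile — hashtag identity, doublet flag and target
mitochondrial fraction.

What the generator does not emulate: ambient RNA soup, UMI saturation,
batch effects, empty droplets, or continuous transcriptional gradients.
Passing screens on this data therefore demonstrate the correctness of the
filtering/screening logic, not robustness to those real-data phenomena.

## QC, demultiplexing and the candidate screen

QC keeps cells with `min_features < detected genes < max_features`
(strict, defaults 800/5,000, a feature being a gene with ≥ 1 count), total
counts ≤ 12,000 and mitochondrial fraction ≤ 1% (strict removal above),
then drops genes detected in fewer than 3 retained cells; the report
attributes removals per rule (non-exclusively) and the filter is idempotent.
Mitochondrial genes are identified by a case-insensitive `mt-` prefix,
overridable by an explicit list.

Demultiplexing CLR-transforms each hashtag across cells
(`ln(1+x) − mean`), estimates each hashtag's background from cells whose
strongest hashtag is a different one, and sets the positivity threshold at
the 0.8 quantile of those background values; one positive hashtag is a
singlet, several a doublet, none a negative. This is a transparent
background-quantile analogue of the demultiplexers used with cell hashing;
it honours the 0.8 parameter but makes no per-cell concordance claim with
any particular external implementation. Note the CLR is shift-invariant
per hashtag, so calls are insensitive to which cells were QC-removed
beforehand except through background-set membership — the pipeline's fixed
QC → demux order is therefore asserted through sharper order guards
(cell-before-gene filtering inside QC; demultiplexing before profiling,
since retained doublets measurably contaminate cluster marker profiles).

Cluster labels are pluggable: the screen consumes any per-cell labelling
(ground truth from the generator by default; a Leiden helper delegating to
scanpy is provided for externally clustered data but is not on the default
path, since community detection is a called service, not part of this
package's logic). Profiles are per-cluster means of log-normalised
expression. Classification: excitatory iff *Slc17a6* mean ≥ τ and all of
*Slc32a1*/*Gad1*/*Gad2* below; inhibitory in the converse case; ambiguous
otherwise (τ = 0.5 log-normalised units). Candidate verdict:
`Lepr mean ≥ 0.5` ∧ `Agrp, Npy, Pomc each < 0.1` ∧ `Nr5a1 < 0.5`, sorted by
Lepr mean. The thresholds are configurable; the defaults were chosen once
for the synthetic conditions since no numeric cutoffs are canonical. The
dominant failure mode of the screen on synthetic data is residual
same-hashtag doublets (undetectable by any hashtag method) carrying
*Agrp*/*Npy*/*Pomc* into the small planted cluster, which occasionally
pushes a marker mean over the 0.1 gate — roughly one matrix in twenty at
the default doublet rate.

## Co-expression

A cell expresses a gene when ≥ 2 UMIs are detected (configurable).
Two-tailed Fisher p-values are computed over the hypergeometric support
with both margins fixed, by the point-probability rule (tables no more
likely than the observed one), in exact rational arithmetic for totals
≤ 500 and in log-space with a 1e-9 relative tie guard above; tail-doubling
is available as an option since conventions differ between implementations.
Degenerate margins yield p = 1 with a flag; sample odds ratios use the
Haldane 0.5 correction (flagged) when a cell is zero. Co-localization is
the percentage of reference-positive cells positive for each query,
reported to one decimal; the triple-negative fraction is the share of
double-reference-positive cells (e.g. *Lepr*⁺/*Bnc2*⁺) carrying none of a
marker set. No multiple-testing correction is applied by default
(single-pair use); Benjamini–Hochberg is available for panel-wide screens.

## Gated test selection

For paired designs the Shapiro–Wilk gate is applied to the paired
differences (the quantity whose normality the t-test assumes); for
unpaired designs to each group, with the rank branch taken if either group
fails (α = 0.05 for the gate). Parametric branch: paired/unpaired
Student's *t* or repeated-measures ANOVA; rank branch: Wilcoxon signed-rank
(exact null for n ≤ 25, normal approximation with continuity correction
above), Mann–Whitney, or Friedman. The Friedman statistic is computed from
within-subject midranks in the tie-robust form
`(k−1)·Σ(R_j − n(k+1)/2)² / (Σr_ij² − nk(k+1)²/4)` with the all-tied case
defined as statistic 0, p = 1, and an asymptotic χ² p-value. Two-way ANOVA
is provided for factorial designs without a gate (no standard rank-based
equivalent). Every decision is recorded in a trace. Under a paired
Gaussian null (n = 8) the gated procedure's type-I error sits near the
nominal 5% — slightly conservative because ~5% of datasets are routed to
the discrete exact Wilcoxon.

## Orchestration and reproducibility

The pipeline configuration is a single validated document (pydantic
models; YAML on disk) with stage toggles and per-stage parameters; stages
run in fixed order, never mutate upstream artifacts, and the run report
records a configuration hash, seeds and artifact paths. All randomness
flows through explicit integer seeds via numpy Generators, so identical
configuration reproduces byte-identical outputs. Problem sizes used by the
default test and acceptance runs — 2,000-cell matrices, 20 screening
seeds, 50 photometry sessions of 600 s at 100 Hz, 2,000 null simulations —
were chosen as the smallest scales at which the Monte-Carlo tolerances in
the tests are meaningful.

## Known limitations

* The demultiplexer is intentionally simple; it does not fit mixture
  models and cannot flag same-hashtag doublets.
* The neuron/non-neuron gate (Tubb3/Snap25/Syt1/Elavl4 scoring) has no
  anchored cutoff; synthetic cells are all neurons, so the gate is not on
  the default path.
* Fisher's exact test is conservative at small n; rejection rates under
  independence are below nominal α by construction.
* The photometry chain reports amplitudes attenuated by the smoothing
  window; window means over long (≥ 100 s) intervals are insensitive to
  this, but single-transient peak readouts inherit a few percent of
  negative bias at the default 1-s window.
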