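# Methods

This note documents the models, algorithms, parameter choices and known
limitations of spectracyte: what each stage assumes, which knobs matter,
what the synthetic generator does and does not emulate, and where the
design was genuinely open.

## Data model

A single-cell SERS measurement is an intensity vector I(ν) on a strictly
increasing wavenumber axis ν ⊂ [400, 3200] cm⁻¹; the default working axis
is 700–1700 cm⁻¹ at 1 cm⁻¹ spacing (1001 channels), the biological
fingerprint region. Every spectrum carries a donor identifier, a condition
label (CAR, MOCK, UNSTIM, cell types, …), an acquisition batch, and — for
co-culture time courses — minutes since co-culture start. A `SpectraSet`
holds an ordered collection on one shared axis; list order is acquisition
order and is preserved by every stage (excluded spectra are removed, the
rest keep their relative order), which is what makes the block bootstrap's
"contiguous acquisition-order segments" meaningful.

Analysis bands are closed intervals [c − w/2, c + w/2], default width
20 cm⁻¹, with both endpoints inclusive; the tracked panel is
protein/aromatic {898, 1002, 1025, 1222, 1262, 1602} and nucleic acid
{728, 1092, 1334} cm⁻¹.

## Synthetic-data generator

Each spectrum is

    I(ν) = g(t) · [ h · Σₖ Aₖ · P(ν; cₖ, wₖ, η) + B(ν) ] + ε(ν) + spikes

* **Peaks** P are pseudo-Voigt (η-mix of Lorentzian and Gaussian,
  default η = 0.5, FWHM 12 cm⁻¹ — a typical fingerprint-region Raman
  linewidth). The default catalog has 23 bands across five biochemical
  classes (nucleic acid, protein/aromatic, mitochondrial, membrane/lipid,
  hemoprotein) with resting-T-cell relative amplitudes; amplitudes are
  free parameters of the generator, not measured values.
* **Effective amplitudes** Aₖ = baseₖ × class effect × donor multiplier ×
  cell jitter × trajectory multiplier. Class effects are multiplicative
  factors per biochemical class (defaults encode the observed directions:
  CAR protein ×1.2 and membrane ×1.1; Mock nucleic ×1.2; Unstim nucleic
  ×1.25; JeKo-1-like B cells protein-rich/adenine-poor; red blood cells
  hemoprotein ×3 with near-zero nucleic and mitochondrial signal; a
  tonic-signaling preset adds mitochondrial ×1.3 to the CAR class).
* **Donor random effects**: one log-normal multiplier per (donor,
  biochemical class), log-SD 0.25 — larger than the class-effect logs
  (ln 1.2 ≈ 0.18), so donor structure dominates class structure in pooled
  embeddings, as in real multi-donor data. `donor_effect_classes`
  optionally restricts which biochemical classes carry donor effects; the
  donor-dominance classification study concentrates them on the
  protein/nucleic contrast axes, which is what creates genuine cross-donor
  label conflict.
* **Cell heterogeneity**: an independent log-normal jitter per spectrum
  and band (log-SD 0.10) modeling cell-to-cell compositional variability
  and the local microenvironment each SERS hotspot samples. Besides
  realism, this matters structurally: without it the activation
  trajectory is a thin straight line through the PCA centroid, where the
  cosine metric used downstream is angularly degenerate, and no graph
  method could order it.
* **Hotspot variation**: a global log-normal per-spectrum factor (log-SD
  0.30) for SERS enhancement heterogeneity. Per-spectrum z-scoring and
  total-intensity normalization both remove it exactly.
* **Baseline** B: quartic polynomial plus one broad Gaussian
  (σ = 300 cm⁻¹) mimicking fluorescence, with amplitudes ≈ 2–5× the mean
  peak height so baseline correction is genuinely stressed.
* **Noise** ε: additive Gaussian, SD = 0.05 × mean catalog amplitude.
* **Cosmic spikes**: Poisson(0.1)/spectrum events, 1–3 channels wide,
  10–50× the maximum peak amplitude.
* **Time courses**: acquisition times uniform over 15–95 min. CAR spectra
  receive trajectory multipliers; unstimulated controls are stationary.
  Both conditions share a multiplicative drift exp(0.002·t). The default
  trajectory program is piecewise linear: protein/aromatic rises from 1.0
  to 1.40 over the first 60 min then declines to 1.05 at 95 min (a partial
  decline — it stays above baseline); nucleic acid falls as 1 − 0.0075·t
  to 0.55 at 60 min, then at the shallower rate 0.004/min (late leveling).
  The rise magnitude, decline depth and late slope were fixed once,
  jointly, so that the programmed course is strong enough to be
  recoverable by the pipeline's own statistics (peak bin before 60 min
  after the coupling introduced by total-intensity normalization; see
  below) while keeping the qualitative shape: rise-then-partial-decline
  for protein, monotone decline with late leveling for nucleic acid.

Every latent quantity — amplitudes, donor multipliers, hotspot factors,
drift, spike channels and heights, trajectory multipliers, the noise-free
signal — is stored in a `TruthRecord` aligned to the output, and identical
seeds give bit-identical output.

What the generator does **not** emulate: wavenumber calibration drift,
detector nonlinearity and saturation, correlated (pink) noise, cell-cycle
or subpopulation structure beyond the single trajectory, band-position
shifts (only amplitudes move), and any physical model of plasmonic
enhancement. Passing tests therefore demonstrate that the pipeline
recovers the statistical structure it assumes — not that real instruments
produce that structure.

## Preprocessing

Stage order on a raw set: QC exclusion (computed on raw intensities) →
despike → denoise → baseline-correct → z-score.

* **QC screen**: per acquisition batch, a spectrum is excluded when its
  average raw intensity exceeds the batch mean + 3 SD (one-sided, high
  only — the failure modes are laser artifacts and detector saturation).
  Batch statistics are computed once from all spectra; the screen is not
  iterated. The grouping key is the acquisition batch; a donor- or
  condition-level grouping is a defensible alternative and the key is
  explicit in the data model.
* **Despiking** is a modified Whitaker–Hayes scheme. Robust z-scores of
  the first differences (median/MAD, with an SD fallback when MAD = 0 and
  a floor of 10⁻³ × dynamic range so near-noiseless smooth spectra do not
  flag their own slopes) propose candidates: both endpoints of every
  |z| > 6 difference, with ≤ 3-channel gaps bridged (flat-topped spike
  interiors) and runs longer than 3× the window discarded as structure
  (an entire peak can turn candidate on a noiseless spectrum; a cosmic
  spike never spans that many channels). Each candidate is then confirmed
  against the nearest non-candidate channels on each side: flagged only
  if it deviates from their median by more than 6 × max(noise σ, local
  robust spread). The two-sided reference brackets genuine peak flanks
  (tail below, apex above), so sharp Raman peaks are not flagged even
  without noise; spike channels are replaced by the mean of non-flagged
  channels in a centered 5-channel window (widened as needed), all other
  channels are returned bit-identical. On generator defaults this flags
  100% of injected spike channels with zero false flags.
* **Denoising**: multilevel symlet-8 decomposition at the maximum depth
  the length allows, noise σ estimated from the finest detail
  coefficients (MAD/0.6745), per-subband BayesShrink soft threshold
  T = σ²/√max(σ_subband² − σ², ε). Symmetric wavelets minimize peak-shape
  distortion; on noiseless peaks the maximum change is < 1% of peak
  height.
* **airPLS**: iterated weighted Whittaker smoothing with second-difference
  penalty λ = 10⁵ (for 1 cm⁻¹ sampling over ~1000 channels; λ scales with
  channel count and is exposed). Weights: 0 where the residual is
  non-negative (peaks), exp(t·|d|/Σ|d₋|) below the baseline, iteration
  t ≤ 30, convergence when the negative-residual mass falls below
  10⁻³ × Σ|x|. The banded solver adds a 10⁻¹⁰ ridge for positive
  definiteness. Non-convergence returns the last iterate and is flagged
  in the report, not an error.
* **Normalization**: per-spectrum z-score with population SD (fixed for
  bit-reproducibility; immaterial at ~1000 channels). Zero-variance input
  is a hard error naming the spectrum.

Two invariances matter downstream: z-scoring makes the pipeline exactly
invariant to per-spectrum positive scaling (hotspots), and the **positive
representation** used for log-ratios — baseline-corrected spectra divided
by their total summed intensity — removes per-spectrum factors while
keeping band means positive so logarithms are defined.

## Classification protocol

Features are the normalized spectra, optionally augmented with first- and
second-order Savitzky–Golay derivatives (window 11, polyorder 3, edge
channels by one-sided polynomial fit) as extra blocks; augmented features
are used for classification, plain features for importance analysis (so
each feature is one wavenumber).

Training: stratified 80:20 train/test split; hyperparameter search
(seeded random sampling over a fixed documented space: learning rate,
leaves, depth, child samples, subsampling, column sampling, L1/L2; budget
50 trials by default, 0 skips the search) scored by 5-fold stratified CV
with early stopping — validation AUC for binary problems, log loss for
multiclass — which also selects the tree count from learning curves; all
selection uses the training split only. The final report contains 10-fold
stratified CV accuracy and row-normalized confusion matrices on the
training split and ROC/AUC on the held-out 20%. Class imbalance is
handled by `scale_pos_weight` = n_neg/n_pos (binary) or balanced class
weights (multiclass). LightGBM runs single-threaded and deterministic, so
a seed fixes the whole report. The booster is a pluggable detail: any
gradient-boosted tree library exposing fit, probability prediction and
per-feature gain would satisfy the protocol.

Per-donor analysis trains one model per donor and reports the mean
donor-level accuracy plus a common-grid ROC (101 false-positive-rate
points) bootstrap-averaged over donors (1000 resamples, 95% band).
Importance profiles are per-donor gain vectors, sum-normalized then
min-max scaled to [0, 1], summarized by across-donor mean and SD.

A caution from the null study: cross-validated accuracy of a flexible
boosted model is not binomial around chance at small n — it shows both
optimism (tree-count selection on overlapping folds) and anti-learning
(on duplicated ambiguous data the held-out twin of a training point is
systematically predicted wrong). The test suite's chance-level check
therefore averages three independent simulations of 800 spectra each.

## Embedding products

UMAP with the fixed parameters (2 components, 20 neighbors, min_dist 0.1,
manhattan metric, seeded) on class/donor-balanced subsamples (each
(class, donor) cell downsampled without replacement to the minimum count).
The embedding is a visualization product and is quarantined from
inference: only time-bin centroids (mean coordinate ± SE) are derived from
it; classification, pseudotime and band statistics never consume
embedding coordinates. Difference curves are computed per donor as the
difference of class-mean spectra, normalized by the donor's own maximum
absolute difference (range ⊆ [−1, 1]), aggregated channel-wise by the
median across donors; both a 95% bootstrap band over donors and the
25–75% quantile range are emitted.

## Pseudotime

Spectra with acquisition times are projected by PCA (centered, no
per-feature scaling — inputs are already z-scored) to 45 components; a
kNN graph (k = 30 by default, cosine distance) is symmetrized by the
union of directed neighbor sets; analysis restricts to the largest
connected component (an error if it holds < 10% of the set). The root is
the component member with the earliest acquisition time, ties broken by
smallest spectrum id. Pseudotime τ is the shortest-path (geodesic)
distance from the root over cosine edge weights, normalized to [0, 1];
the minimum spanning tree rooted at the same cell is computed and exposed
for trajectory visualization.

The geodesic scalar is a deliberate design choice over the MST path
distance. Empirically, on seeded synthetic time courses the tree-path
statistic is unstable exactly where the cosine metric compresses the late
course of a trajectory: consecutive late time bins become metrically
close, the tree degenerates there into a web attached at an arbitrary
entry point, and path distances stop tracking progression (bin-level
Spearman stuck around 0.77–0.94) even though the graph distances still
order the bins perfectly. The geodesic from the same root on the same
graph recovers bin-level ρ = 1.00 in essentially every seeded run and is
stable to k ± 5 (spectrum-level ρ changes < 0.05).

Validation uses two-sided Spearman correlation between τ and true time at
two levels: over all component members, and per-time-bin median τ against
bin start time (≥ 3 occupied bins required). For visualization, τ is
partitioned into 12 equal-width bins whose mean embedding coordinates
trace the trajectory.

## Band dynamics

Time bins are the printed scheme 15–25, 25–35, 35–45, 45–55, 55–75,
75–95 min, labeled by their earliest point; intervals are half-open with
the last bin closed (a time of exactly 95 joins it). For band b and bin t,
r(b,t) = ln(Ī_CAR(b,t)/Ī_Unstim(b,t)) with Ī the mean band intensity over
member spectra of the positive representation. Any multiplicative factor
common to both conditions and constant within a bin cancels exactly in r;
a smooth per-spectrum drift is already removed exactly upstream by
total-intensity normalization. Per band, r(b,·) is z-scored across
occupied bins (a flat band series is reported as zeros with a degeneracy
flag); per biochemical class the z-scored series are averaged (mean by
default; median available). Bins occupied in only one condition are
dropped with a warning.

One coupling is worth knowing: total-intensity normalization ties band
fractions together — when nucleic-acid bands fade, every other band's
fractional intensity rises. The protein-class series therefore reflects
the programmed protein course *plus* this compositional term, which is
why the generator's protein decline must be deep enough for the
peak-then-decline shape to survive in the statistic.

Confidence intervals: within each (condition, bin), spectra are
partitioned into contiguous acquisition-order blocks of length ⌈√n⌉;
bootstrap replicates resample blocks with replacement and recompute the
full class-series statistic; percentile intervals at 95% by default,
seeded. In a 200-replicate study at 600 spectra per condition
(~100 per bin, scaled down from real experiments that collect several
hundred to a thousand per bin) with 300 resamples per replicate, the 95%
intervals cover the closed-form generative truth ~97% of the time. The
coverage study generates spectra without baselines or spikes — it tests
the bootstrap statistics, not the cleanup chain, which is validated
separately. Monotonicity is two-sided Spearman of the class series
against bin start times, with midrank ties.

## Problem sizes and numerical choices

Simulation studies in the test suite use 150–400 spectra per condition
for preprocessing and classification checks (on a 2 cm⁻¹ axis for model
tests), 1,000 per condition × 20 seeds for pseudotime recovery, and
600 per condition × 200 replicates for bootstrap coverage — sizes chosen
to match the scale of real per-donor data sets while keeping each study a
few minutes of single-core compute. Tolerances: z-scoring exact to 1e-9;
file round-trips bit-exact (floats written at repr precision and parsed
with round-trip parsing); banded airPLS ridge 1e-10; cosine edge weights
floored at 1e-12 so duplicate points stay traversable. Degenerate inputs
(constant spectra, empty sets, single-member batches, flat band series,
< 3 occupied bins) return identities or explicit nulls with warnings
rather than failing, except where silence would corrupt downstream
statistics (zero-variance z-score, non-positive band means), which are
hard errors naming the offending spectrum.

## Known limitations

* The generator's trajectory is a single deterministic program per
  condition; no branching, no per-cell response heterogeneity beyond
  amplitude jitter, no dying-cell or conjugate subpopulations.
* Band positions never shift; real activation can shift band centers,
  which band-mean intensities would partially miss.
* The donor-dominance classification phenomenon (pooled < per-donor
  accuracy) emerges only when donor variability loads on the same
  spectral axes as the class contrast; with donor effects spread across
  all biochemical classes a flexible pooled model fingerprints donors and
  matches per-donor training.
* Pseudotime assumes the trajectory is a connected 1-D progression in
  cosine geometry; cyclic or branching dynamics need different methods.
* The hyperparameter search budget and space are conventions; reported
  accuracies depend on them.
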