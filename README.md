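# spectracyte

Label-free spectral cytometry of engineered T cells: a Python library for
analyzing single-cell surface-enhanced Raman spectroscopy (SERS) data from
CAR T cell experiments — identifying engineered (CAR) versus non-engineered
(Mock) cells from their vibrational fingerprints, and tracking
antigen-specific activation dynamics over time in co-culture.

It is written for spectroscopists and computational immunologists who have
per-cell intensity vectors I(ν) on a wavenumber axis ν (the 700–1700 cm⁻¹
biological fingerprint region) with metadata (donor, condition, acquisition
time, batch), and want the full analysis chain:

1. **Preprocessing** — cosmic-ray despiking (modified Whitaker–Hayes
   z-score on first differences with a local-consistency confirmation),
   wavelet denoising (BayesShrink soft thresholding, symlet-8), baseline
   correction by adaptive iteratively reweighted penalized least squares
   (airPLS: iterated Whittaker smoothing `min_z Σ wᵢ(xᵢ−zᵢ)² + λΣ(Δ²z)²`
   with peak-suppressing weights), per-spectrum z-score standardization,
   and a per-batch QC screen that drops spectra whose average raw
   intensity exceeds the batch mean + 3 SD.
2. **Classification** — LightGBM on spectra augmented with first/second
   Savitzky–Golay derivatives (window 11, polyorder 3); stratified 80:20
   split, tuning and tree-count selection by 5-fold CV with early stopping
   (150 rounds patience, ≤ 2000 rounds) on the training split only, final
   10-fold stratified CV accuracy/confusion, held-out ROC/AUC, per-donor
   models with bootstrap-averaged common-grid ROC, and sum-normalized
   min-max-scaled gain importance profiles per wavenumber.
3. **Embedding products** — class/donor-balanced UMAP (2-D, n_neighbors
   20, min_dist 0.1, manhattan metric), time-binned centroids with
   standard errors, and donor-aggregated class difference curves.
4. **Pseudotime** — PCA to 45 components, cosine-distance kNN graph
   (k = 30), largest connected component, pseudotime as normalized graph
   distance from the earliest-acquired cell, with the rooted minimum
   spanning tree for trajectory visualization; validated by two-sided
   Spearman rank correlation against acquisition time.
5. **Band dynamics** — per-time-bin log-ratios
   `r(b,t) = ln(Ī_CAR(b,t) / Ī_Unstim(b,t))` of mean band intensities
   relative to the unstimulated control (removing shared acquisition
   drift), z-scored within each 20 cm⁻¹ band across the printed time bins
   (15–25, 25–35, 35–45, 45–55, 55–75, 75–95 min), averaged within
   biochemical classes (protein/aromatic: 898, 1002, 1025, 1222, 1262,
   1602 cm⁻¹; nucleic acid: 728, 1092, 1334 cm⁻¹), with block-bootstrap
   confidence intervals and Spearman monotonicity statistics.

Because raw single-cell SERS data sets are rarely public, the package
includes a first-class synthetic-spectrum generator
(`spectracyte.simulate`) that emulates the statistical structure of such
experiments — class-dependent band amplitudes, donor random effects that
dominate class effects, cell-to-cell compositional jitter, hotspot
intensity variation, fluorescence baselines, cosmic-ray spikes and a
programmed activation trajectory — with every latent variable recorded, so
each stage of the pipeline is validated against known ground truth.

## Worked example

`examples/04_pseudotime.py` simulates a CAR + target-cell co-culture time
course (1,000 single-cell spectra acquired 15–95 min after co-culture
start), preprocesses it, and recovers the activation trajectory without
using the time labels:

```
root cell: CAR-D1-00000 (earliest acquisition time)
spectrum-level Spearman(pseudotime, true time): 0.897
bin-level Spearman (per-bin median pseudotime): 1.000
bin medians: {15: 0.185, 25: 0.255, 35: 0.399, 45: 0.593, 55: 0.732, 75: 0.818}
```

The bin-level ρ of 1.00 means the per-time-bin median pseudotime increases
strictly with true acquisition time — the unlabeled spectra alone contain
the temporal structure of antigen-specific activation.
`examples/05_band_dynamics.py` prints the band trajectories behind it:

```
protein/aromatic  series [-1.6, -0.86, -0.15, 0.49, 1.2, 0.93]  rho +0.943 (p=0.0048)
nucleic acid      series [1.35, 0.88, 0.41, -0.19, -0.94, -1.52]  rho -1.000 (p=0)
```

Protein and aromatic bands rise through the first hour of engagement and
then partially decline (immune synapse formation, increased translation),
while nucleic-acid bands decline monotonically (chromatin decondensation);
the multiplicative acquisition drift shared with the unstimulated control
cancels in the log-ratio. The other examples cover preprocessing fidelity
(`01`), per-donor versus pooled classification and importance profiles
(`02`), and embedding products with difference curves (`03`).

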