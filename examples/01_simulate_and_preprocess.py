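"""Generate a synthetic single-cell SERS data set and run the cleanup chain.

Builds 2 x 60 CAR/Mock spectra with realistic baselines, hotspot variation
and cosmic-ray spikes, then applies the four-step preprocessing (despike ->
wavelet denoise -> airPLS baseline -> per-spectrum z-score) plus the
per-batch bright-spectrum QC screen.
"""

import warnings

import numpy as np

import spectracyte as sct

warnings.filterwarnings("ignore")

cfg = sct.GeneratorConfig(n_spectra_per_condition=60, spike_rate=0.5, seed=1)
raw, truth = sct.generate_static(cfg, ["CAR", "MOCK"], ["D1"])
print(f"generated {len(raw)} spectra on {raw.axis.n_channels} channels "
      f"({raw.axis.values[0]:.0f}-{raw.axis.values[-1]:.0f} cm^-1)")
print(f"injected cosmic-ray spike channels: {truth.n_spikes()}")

pre, report = sct.run_preprocess(raw)
n_flagged = sum(f.size for f in report.spike_channels.values())
print(f"retained {len(pre)} spectra ({len(report.excluded)} excluded by QC), "
      f"{n_flagged} spike channels removed")

# preprocessed spectra are z-scored per spectrum
X = pre.intensity_matrix()
print(f"per-spectrum mean/SD after normalization: "
      f"{np.abs(X.mean(axis=1)).max():.2e} / {X.std(axis=1).mean():.6f}")

# recovery of the latent signal: correlation with the noise-free truth
rows = {sid: i for i, sid in enumerate(truth.spectrum_ids)}
r = np.mean([
    np.corrcoef(X[i], truth.normalized_truth(rows[sid]))[0, 1]
    for i, sid in enumerate(pre.ids())
])
print(f"mean correlation with noise-free truth signal: {r:.3f}")
print("numbers near 1.0 mean baseline, noise and spikes were removed "
      "without distorting the vibrational peaks")
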