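"""Time-resolved band-intensity trajectories of antigen-specific activation.

Simulates paired CAR and unstimulated co-cultures sharing a multiplicative
acquisition drift, computes the log-ratio band trajectories (CAR relative
to Unstim, z-scored within bands, averaged within each biochemical class)
over the six printed time bins, and reports block-bootstrap confidence
intervals and Spearman monotonicity statistics.
"""

import warnings

import numpy as np

import spectracyte as sct

warnings.filterwarnings("ignore")

P = sct.BiochemicalClass.PROTEIN_AROMATIC
N = sct.BiochemicalClass.NUCLEIC_ACID

cfg = sct.GeneratorConfig(
    n_spectra_per_condition=1000, seed=7, trajectory=sct.TrajectoryProgram()
)
sset, _ = sct.generate_timecourse(cfg, ["D1"])
pre, report = sct.run_preprocess(sset)
pos = sct.positive_representation(pre, report)
car = pos.select(pos.labels() == "CAR")
unstim = pos.select(pos.labels() == "UNSTIM")

traj = sct.block_bootstrap_ci(car, unstim, n_boot=500, seed=0)
mono = sct.monotonicity(traj)

print("bin starts (min):", traj.bin_starts.astype(int).tolist())
for bc, name in ((P, "protein/aromatic"), (N, "nucleic acid")):
    series = np.round(traj.class_series[bc], 2).tolist()
    rho, p = mono[bc]
    print(f"{name:17s} series {series}  rho {rho:+.3f} (p={p:.3g})")
print("protein bands rise through the first hour then partially decline; "
      "nucleic-acid bands fall monotonically (chromatin decondensation "
      "during activation); the shared acquisition drift cancels in the "
      "log-ratio")
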