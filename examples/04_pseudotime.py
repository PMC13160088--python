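"""Recover the activation trajectory without using time labels.

Simulates a CAR + JeKo-1 co-culture time course (15-95 min), preprocesses
it, and runs the unsupervised pseudotime analysis: PCA to 45 components,
cosine-distance kNN graph (k=30), largest connected component, pseudotime
as normalized geodesic distance from the earliest-acquired cell (with the
rooted minimum spanning tree available for visualization).
"""

import warnings

import numpy as np

import spectracyte as sct

warnings.filterwarnings("ignore")

cfg = sct.GeneratorConfig(
    n_spectra_per_condition=1000, seed=1, trajectory=sct.TrajectoryProgram()
)
sset, _ = sct.generate_timecourse(cfg, ["D1"], conditions=["CAR"])
pre, _ = sct.run_preprocess(sset)

res = sct.compute_pseudotime(pre, sct.PseudotimeConfig(n_pcs=45, k_neighbors=30))
tc = sct.time_correlation(res)
print(f"root cell: {res.root_id} (earliest acquisition time)")
print(f"spectrum-level Spearman(pseudotime, true time): {tc.spectrum_rho:.3f}")
print(f"bin-level Spearman (per-bin median pseudotime): {tc.bin_rho:.3f}")
print("bin medians:", {int(k): round(v, 3) for k, v in tc.bin_medians.items()})
print("a bin-level rho of 1.0 means the unlabeled spectra alone carry the "
      "temporal structure of antigen-specific activation")
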