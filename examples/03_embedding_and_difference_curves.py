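"""UMAP embedding products and donor-aggregated difference curves.

Balances a multi-donor CAR/Mock set by (class, donor), embeds it in 2-D
(manhattan metric, n_neighbors=20, min_dist=0.1), and computes the
median Mock-minus-CAR difference curve across donors with bootstrap and
quartile uncertainty bands.
"""

import warnings

import numpy as np
from sklearn.metrics import silhouette_score

import spectracyte as sct

warnings.filterwarnings("ignore")

cfg = sct.GeneratorConfig(n_spectra_per_condition=80, seed=31)
raw, _ = sct.generate_static(cfg, ["CAR", "MOCK"], ["D1", "D2", "D3"])
pre, _ = sct.run_preprocess(raw)

balanced = sct.balanced_subsample(pre, seed=0)
counts = balanced.metadata_frame().groupby(["class_label", "donor_id"]).size()
print("balanced (class, donor) counts:", sorted(set(counts)))

coords = sct.embed(balanced, sct.EmbeddingConfig(seed=0))
sil_class = silhouette_score(coords, balanced.labels())
sil_donor = silhouette_score(coords, balanced.donors())
print(f"embedding silhouette by class label: {sil_class:.3f}")
print(f"embedding silhouette by donor:       {sil_donor:.3f}")
print("donor structure dominates the pooled embedding — the donor prior "
      "that motivates per-donor classification")

dc = sct.difference_curves(pre, "CAR", "MOCK")  # curve = MOCK minus CAR
ch = {v: i for i, v in enumerate(pre.axis.values)}
print(f"median difference at 1002 cm^-1 (phenylalanine): {dc.median[ch[1002.0]]:+.3f}")
print(f"median difference at  728 cm^-1 (adenine):       {dc.median[ch[728.0]]:+.3f}")
print("negative at 1002 and positive at 728: CAR cells are protein/aromatic-"
      "enriched while Mock cells keep stronger nucleic-acid signal")
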