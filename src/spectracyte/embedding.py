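"""Manifold embedding data products: class/donor-balanced subsampling, UMAP
coordinates, time-binned centroids and donor-aggregated difference curves.

The embedding is a visualization product and is quarantined from
inference: no downstream statistic other than the time-bin centroids may
consume the 2-D coordinates (UMAP does not preserve global distances).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .spectra import SpectraSet

__all__ = [
    "EmbeddingConfig",
    "TimeBinning",
    "balanced_subsample",
    "embed",
    "time_bin_centroids",
    "difference_curves",
    "DifferenceCurves",
]


@dataclass(frozen=True)
class EmbeddingConfig:
    n_components: int = 2
    n_neighbors: int = 20
    min_dist: float = 0.1
    metric: str = "manhattan"
    seed: int = 0


@dataclass(frozen=True)
class TimeBinning:
    """Acquisition-time bins labeled by their earliest time point.

    Default bins: 15-25, 25-35, 35-45, 45-55, 55-75 and 75-95 min.
    Intervals are half-open [a, b); the last bin is closed so a time of
    exactly 95 joins it.
    """

    edges_min: tuple[float, ...] = (15.0, 25.0, 35.0, 45.0, 55.0, 75.0, 95.0)

    def __post_init__(self) -> None:
        if np.any(np.diff(self.edges_min) <= 0):
            raise ValueError("bin edges must be strictly increasing")

    @property
    def labels(self) -> tuple[float, ...]:
        return self.edges_min[:-1]

    @property
    def n_bins(self) -> int:
        return len(self.edges_min) - 1

    def assign(self, times: np.ndarray) -> np.ndarray:
        """Bin index per time; -1 for times outside the binning range."""
        t = np.asarray(times, dtype=float)
        edges = np.asarray(self.edges_min)
        idx = np.searchsorted(edges, t, side="right") - 1
        idx[t == edges[-1]] = self.n_bins - 1  # last bin is closed
        out = np.where((t >= edges[0]) & (t <= edges[-1]), idx, -1)
        return out.astype(int)


def balanced_subsample(sset: SpectraSet, seed: int = 0) -> SpectraSet:
    """Downsample every (class, donor) combination, without replacement, to
    the minimum combination count (avoids over-weighting in pooled
    embeddings).  Deterministic under ``seed``; original order preserved."""
    labels, donors = sset.labels(), sset.donors()
    keys = pd.Series(list(zip(labels, donors)))
    counts = keys.value_counts()
    if counts.empty:
        raise ValueError("empty SpectraSet")
    n_min = int(counts.min())
    rng = np.random.default_rng(seed)
    keep = np.zeros(len(sset), dtype=bool)
    for key in counts.index:
        idx = np.flatnonzero((labels == key[0]) & (donors == key[1]))
        if idx.size == 0:
            raise ValueError(f"empty (class, donor) combination {key}")
        keep[rng.choice(idx, size=n_min, replace=False)] = True
    return sset.select(keep, note=f"balanced to {n_min} per (class, donor)")


def embed(sset: SpectraSet, config: EmbeddingConfig = EmbeddingConfig()) -> np.ndarray:
    """2-D UMAP coordinates per spectrum (seeded, hence deterministic)."""
    import umap  # deferred: heavy import

    if len(sset) < config.n_neighbors + 1:
        raise ValueError(
            f"need at least n_neighbors+1={config.n_neighbors + 1} spectra, got {len(sset)}"
        )
    reducer = umap.UMAP(
        n_components=config.n_components,
        n_neighbors=config.n_neighbors,
        min_dist=config.min_dist,
        metric=config.metric,
        random_state=config.seed,
    )
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", category=UserWarning)
        return np.asarray(reducer.fit_transform(sset.intensity_matrix()))


def time_bin_centroids(
    coords: np.ndarray, sset: SpectraSet, binning: TimeBinning = TimeBinning()
) -> pd.DataFrame:
    """Mean embedding coordinate (and per-axis standard error) per
    (class, time bin); empty bins are omitted."""
    coords = np.asarray(coords, dtype=float)
    if coords.shape[0] != len(sset):
        raise ValueError("coords/spectra length mismatch")
    times = sset.times()  # raises if any time missing
    bins = binning.assign(times)
    labels = sset.labels()
    rows = []
    for cls in sorted(set(labels)):
        for b, start in enumerate(binning.labels):
            mask = (labels == cls) & (bins == b)
            n = int(mask.sum())
            if n == 0:
                continue
            pts = coords[mask]
            mean = pts.mean(axis=0)
            se = pts.std(axis=0, ddof=1) / np.sqrt(n) if n > 1 else np.zeros(coords.shape[1])
            rows.append(
                {
                    "class_label": cls,
                    "bin_start_min": start,
                    "n": n,
                    **{f"centroid_{i}": mean[i] for i in range(coords.shape[1])},
                    **{f"se_{i}": se[i] for i in range(coords.shape[1])},
                }
            )
    return pd.DataFrame(rows)


@dataclass
class DifferenceCurves:
    """Per-donor and donor-aggregated class difference curves (b minus a)."""

    wavenumbers: np.ndarray
    per_donor: dict[str, np.ndarray]  # donor -> normalized difference curve
    median: np.ndarray
    boot_low: np.ndarray  # 2.5% bootstrap percentile over donors
    boot_high: np.ndarray  # 97.5%
    quartile_low: np.ndarray  # 25% quantile across donors
    quartile_high: np.ndarray  # 75%
    skipped_donors: list[str] = field(default_factory=list)


def difference_curves(
    sset: SpectraSet,
    class_a: str,
    class_b: str,
    n_boot: int = 1000,
    seed: int = 0,
) -> DifferenceCurves:
    """Donor-wise difference of class-averaged spectra, b minus a.

    Each donor's curve is normalized by its own max |difference| (range
    within [-1, 1]), then aggregated channel-wise by the median across
    donors.  Both a 95% bootstrap band over donors and the 25-75% quantile
    range are reported.
    """
    labels, donors = sset.labels(), sset.donors()
    X = sset.intensity_matrix()
    per_donor: dict[str, np.ndarray] = {}
    skipped: list[str] = []
    for d in sorted(set(donors)):
        ma = (donors == d) & (labels == class_a)
        mb = (donors == d) & (labels == class_b)
        if not ma.any() or not mb.any():
            warnings.warn(f"donor {d!r} lacks class {class_a if not ma.any() else class_b!r}; skipped")
            skipped.append(d)
            continue
        delta = X[mb].mean(axis=0) - X[ma].mean(axis=0)
        peak = np.abs(delta).max()
        per_donor[d] = delta / peak if peak > 0 else delta
    if not per_donor:
        raise ValueError("no donor has both classes")
    arr = np.vstack(list(per_donor.values()))
    rng = np.random.default_rng(seed)
    boots = np.empty((n_boot, arr.shape[1]))
    for b in range(n_boot):
        pick = rng.integers(0, arr.shape[0], size=arr.shape[0])
        boots[b] = np.median(arr[pick], axis=0)
    return DifferenceCurves(
        wavenumbers=sset.axis.values.copy(),
        per_donor=per_donor,
        median=np.median(arr, axis=0),
        boot_low=np.percentile(boots, 2.5, axis=0),
        boot_high=np.percentile(boots, 97.5, axis=0),
        quartile_low=np.percentile(arr, 25.0, axis=0),
        quartile_high=np.percentile(arr, 75.0, axis=0),
        skipped_donors=skipped,
    )
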