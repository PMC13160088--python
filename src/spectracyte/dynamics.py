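"""Time-resolved band-intensity statistics for antigen-specific activation.

The central statistic compares target-engaged CAR co-cultures to
unstimulated (Unstim) controls: per analysis band b and time bin t,

    r(b, t) = ln( I_CAR(b, t) / I_Unstim(b, t) )

where I is the mean band intensity over member spectra of the *positive*
pre-z-score representation (baseline-corrected, total-intensity-normalized
spectra; see :func:`spectracyte.preprocess.positive_representation`).  Any
multiplicative acquisition drift g(t) applied equally to both conditions
cancels exactly in r.  Per band, r(b, .) is z-score standardized across
bins; per biochemical class, the z-scored series are averaged across the
class's bands.  Uncertainty comes from block-bootstrap resampling of
contiguous acquisition-order segments within each (condition, bin), and
monotonicity is assessed with two-sided Spearman rank correlation against
bin start time.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import spearmanr

from .bands import BandPanel, default_panel
from .embedding import TimeBinning
from .spectra import BandDefinition, BiochemicalClass, SpectraSet, WavenumberAxis, band_channels

__all__ = [
    "BandTrajectory",
    "bin_mean_spectra",
    "band_intensity",
    "logratio_trajectory",
    "block_bootstrap_ci",
    "monotonicity",
]


def bin_mean_spectra(
    sset: SpectraSet, binning: TimeBinning = TimeBinning()
) -> dict[tuple[str, float], np.ndarray]:
    """Channel-wise mean spectrum per (class_label, bin start time);
    empty bins are omitted."""
    times = sset.times()
    bins = binning.assign(times)
    labels = sset.labels()
    X = sset.intensity_matrix()
    out: dict[tuple[str, float], np.ndarray] = {}
    for cls in sorted(set(labels)):
        for b, start in enumerate(binning.labels):
            mask = (labels == cls) & (bins == b)
            if mask.any():
                out[(cls, float(start))] = X[mask].mean(axis=0)
    return out


def band_intensity(vector: np.ndarray, band: BandDefinition, axis: WavenumberAxis) -> float:
    """Arithmetic mean of a spectrum-like vector over the band's channels."""
    idx = band_channels(band, axis)
    return float(np.asarray(vector, dtype=float)[idx].mean())


@dataclass
class BandTrajectory:
    """Class-level z-scored log-ratio band trajectories across time bins."""

    bin_starts: np.ndarray  # occupied bin start times, ascending
    class_series: dict[BiochemicalClass, np.ndarray]
    band_series: dict[float, np.ndarray]  # band center -> z-scored r(b, .)
    n_car: np.ndarray  # spectra per occupied bin
    n_unstim: np.ndarray
    degenerate: bool = False  # all-zero log-ratios (conditions identical)
    ci_low: dict[BiochemicalClass, np.ndarray] = field(default_factory=dict)
    ci_high: dict[BiochemicalClass, np.ndarray] = field(default_factory=dict)


def _band_intensity_matrix(
    sset: SpectraSet, bands: tuple[BandDefinition, ...]
) -> np.ndarray:
    """(n_spectra, n_bands) per-spectrum mean band intensities."""
    X = sset.intensity_matrix()
    cols = [X[:, band_channels(b, sset.axis)].mean(axis=1) for b in bands]
    return np.column_stack(cols)


def _series_from_band_means(
    car_means: np.ndarray,  # (n_bins, n_bands) mean band intensity per bin
    un_means: np.ndarray,
    bands: tuple[BandDefinition, ...],
    aggregate: str,
) -> tuple[dict[BiochemicalClass, np.ndarray], dict[float, np.ndarray], bool]:
    if np.any(car_means <= 0) or np.any(un_means <= 0):
        raise ValueError(
            "non-positive mean band intensity; feed the positive pre-z-score "
            "representation (see preprocess.positive_representation)"
        )
    r = np.log(car_means / un_means)  # (n_bins, n_bands)
    sd = r.std(axis=0)
    degenerate = bool(np.allclose(r, 0.0))
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (r - r.mean(axis=0)) / sd
    z[:, sd == 0] = 0.0  # flat band series carry no information
    band_series = {b.center_cm1: z[:, k] for k, b in enumerate(bands)}
    agg = np.median if aggregate == "median" else np.mean
    class_series: dict[BiochemicalClass, np.ndarray] = {}
    for bc in {b.biochemical_class for b in bands}:
        cols = [k for k, b in enumerate(bands) if b.biochemical_class is bc]
        class_series[bc] = agg(z[:, cols], axis=1)
    return class_series, band_series, degenerate


def _prepare(
    car_set: SpectraSet,
    unstim_set: SpectraSet,
    panel: BandPanel,
    binning: TimeBinning,
):
    bands = panel.all_bands()
    I_car = _band_intensity_matrix(car_set, bands)
    I_un = _band_intensity_matrix(unstim_set, bands)
    bins_car = binning.assign(car_set.times())
    bins_un = binning.assign(unstim_set.times())
    occupied = []
    for b in range(binning.n_bins):
        in_car, in_un = (bins_car == b).any(), (bins_un == b).any()
        if in_car and in_un:
            occupied.append(b)
        elif in_car or in_un:
            warnings.warn(f"time bin starting {binning.labels[b]} present in one condition only; dropped")
    if not occupied:
        raise ValueError("no time bin occupied in both conditions")
    return bands, I_car, I_un, bins_car, bins_un, occupied


def logratio_trajectory(
    car_set: SpectraSet,
    unstim_set: SpectraSet,
    panel: BandPanel = default_panel(),
    binning: TimeBinning = TimeBinning(),
    aggregate: str = "mean",
) -> BandTrajectory:
    """Class-level activation trajectories relative to the Unstim control.

    Both sets must hold the positive pre-z-score representation.  See the
    module docstring for the statistic; ``aggregate`` selects the across-
    band combiner within a biochemical class ('mean' default, 'median'
    available).
    """
    bands, I_car, I_un, bins_car, bins_un, occupied = _prepare(
        car_set, unstim_set, panel, binning
    )
    car_means = np.vstack([I_car[bins_car == b].mean(axis=0) for b in occupied])
    un_means = np.vstack([I_un[bins_un == b].mean(axis=0) for b in occupied])
    class_series, band_series, degenerate = _series_from_band_means(
        car_means, un_means, bands, aggregate
    )
    return BandTrajectory(
        bin_starts=np.array([binning.labels[b] for b in occupied]),
        class_series=class_series,
        band_series=band_series,
        n_car=np.array([(bins_car == b).sum() for b in occupied]),
        n_unstim=np.array([(bins_un == b).sum() for b in occupied]),
        degenerate=degenerate,
    )


def _blocks(n: int) -> list[np.ndarray]:
    """Contiguous acquisition-order segments of length ceil(sqrt(n))."""
    L = max(1, math.isqrt(n - 1) + 1) if n > 1 else 1
    return [np.arange(s, min(s + L, n)) for s in range(0, n, L)]


def block_bootstrap_ci(
    car_set: SpectraSet,
    unstim_set: SpectraSet,
    panel: BandPanel = default_panel(),
    binning: TimeBinning = TimeBinning(),
    n_boot: int = 1000,
    level: float = 95.0,
    aggregate: str = "mean",
    seed: int = 0,
) -> BandTrajectory:
    """Trajectory plus percentile block-bootstrap confidence bands.

    Within each (condition, bin), spectra are partitioned into contiguous
    acquisition-order blocks of length ceil(sqrt(n)); each bootstrap
    replicate resamples blocks with replacement and recomputes the full
    class-series statistic.  Seeded, hence deterministic.
    """
    traj = logratio_trajectory(car_set, unstim_set, panel, binning, aggregate)
    bands, I_car, I_un, bins_car, bins_un, occupied = _prepare(
        car_set, unstim_set, panel, binning
    )
    groups: list[list[list[np.ndarray]]] = []  # [cond][bin] -> blocks of row indices
    for I, bins in ((I_car, bins_car), (I_un, bins_un)):
        per_bin = []
        for b in occupied:
            idx = np.flatnonzero(bins == b)
            blocks = [idx[blk] for blk in _blocks(idx.size)]
            if len(blocks) < 2:
                warnings.warn(
                    f"single bootstrap block in bin starting {binning.labels[b]}; "
                    "CI collapses toward a point"
                )
            per_bin.append(blocks)
        groups.append(per_bin)

    rng = np.random.default_rng(seed)
    classes = sorted({b.biochemical_class for b in bands}, key=lambda c: c.value)
    sims = {bc: np.empty((n_boot, len(occupied))) for bc in classes}
    for it in range(n_boot):
        means = []
        for ci, I in ((0, I_car), (1, I_un)):
            bin_means = np.empty((len(occupied), len(bands)))
            for k in range(len(occupied)):
                blocks = groups[ci][k]
                pick = rng.integers(0, len(blocks), size=len(blocks))
                rows = np.concatenate([blocks[j] for j in pick])
                bin_means[k] = I[rows].mean(axis=0)
            means.append(bin_means)
        cs, _, _ = _series_from_band_means(means[0], means[1], bands, aggregate)
        for bc in classes:
            sims[bc][it] = cs[bc]
    alpha = (100.0 - level) / 2.0
    for bc in classes:
        traj.ci_low[bc] = np.percentile(sims[bc], alpha, axis=0)
        traj.ci_high[bc] = np.percentile(sims[bc], 100.0 - alpha, axis=0)
    return traj


def monotonicity(
    trajectory: BandTrajectory, binning: TimeBinning | None = None
) -> dict[BiochemicalClass, tuple[float, float]]:
    """Two-sided Spearman rho (and p) of each class series vs bin start time.

    Requires >= 3 occupied bins; otherwise returns an empty dict with a
    warning.  Ties are handled by midranks.
    """
    starts = trajectory.bin_starts
    if starts.size < 3:
        warnings.warn("fewer than 3 occupied bins; monotonicity not assessed")
        return {}
    out: dict[BiochemicalClass, tuple[float, float]] = {}
    for bc, series in trajectory.class_series.items():
        rho, p = spearmanr(series, starts)
        out[bc] = (float(rho), float(p))
    return out
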