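"""Synthetic single-cell SERS spectrum generator with recorded ground truth.

Emulates the statistical structure the analysis pipeline assumes:

* class-dependent vibrational band amplitudes (protein/aromatic vs nucleic
  acid vs mitochondrial vs membrane vs hemoprotein bands),
* per-donor, per-biochemical-class log-normal random effects large enough
  to dominate class effects in pooled embeddings,
* smooth fluorescence baselines (quartic polynomial + broad Gaussian),
* per-spectrum, per-band compositional jitter (cell-to-cell biochemical
  heterogeneity and SERS microenvironment sampling),
* multiplicative per-spectrum hotspot intensity variation,
* additive Gaussian noise and Poisson-count cosmic-ray spikes,
* a time-dependent activation trajectory for co-cultured CAR cells
  (protein bands rise over the first hour then partially decline; nucleic
  acid bands decline monotonically with late leveling) on top of a global
  multiplicative acquisition drift shared by both co-culture conditions.

Each generated spectrum is

    I(nu) = g(t) * [ h_i * sum_k A_k(class, donor, t) * P(nu; c_k, w_k, eta)
                     + baseline(nu) ] + eps(nu) + spikes

with pseudo-Voigt peaks P, hotspot multiplier h_i, drift g(t) (1 for static
experiments) and A_k = base_amplitude_k * class_effect * donor_multiplier
* trajectory multiplier.  Every latent quantity is stored in a
:class:`TruthRecord`, so downstream stages can be validated against a
closed-form generative mean.  Identical seeds give bit-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

from .bands import BandCatalog, default_catalog
from .spectra import (
    BiochemicalClass,
    ClassLabel,
    SpectraSet,
    Spectrum,
    WavenumberAxis,
    default_axis,
)

__all__ = [
    "BaselineConfig",
    "TrajectoryProgram",
    "GeneratorConfig",
    "TruthRecord",
    "pseudo_voigt",
    "default_class_effects",
    "gd2_class_effects",
    "generate_static",
    "generate_timecourse",
]

_VALID_LABELS = frozenset(m.value for m in ClassLabel)


def pseudo_voigt(nu: np.ndarray, center: float, fwhm: float, eta: float) -> np.ndarray:
    """Unit-height pseudo-Voigt profile: eta*Lorentzian + (1-eta)*Gaussian."""
    x = (np.asarray(nu, dtype=float) - center) / (fwhm / 2.0)
    lorentz = 1.0 / (1.0 + x * x)
    gauss = np.exp(-math.log(2.0) * x * x)
    return eta * lorentz + (1.0 - eta) * gauss


@dataclass(frozen=True)
class BaselineConfig:
    """Smooth fluorescence baseline: quartic polynomial + one broad Gaussian.

    The polynomial is evaluated in the scaled coordinate
    u = (nu - u_center) / u_halfspan so coefficients are axis-independent.
    Default amplitudes put the baseline at roughly 2-5x the mean peak
    height, which is what makes baseline correction consequential.
    """

    poly_coeffs: tuple[float, ...] = (4.0, -1.0, 1.5, 0.0, 0.5)
    gauss_amplitude: float = 2.0
    gauss_center_cm1: float = 1150.0
    gauss_sigma_cm1: float = 300.0
    u_center: float = 1200.0
    u_halfspan: float = 500.0

    def evaluate(self, nu: np.ndarray) -> np.ndarray:
        u = (np.asarray(nu, dtype=float) - self.u_center) / self.u_halfspan
        out = np.zeros_like(u)
        for k, c in enumerate(self.poly_coeffs):
            out += c * u**k
        out += self.gauss_amplitude * np.exp(
            -0.5 * ((nu - self.gauss_center_cm1) / self.gauss_sigma_cm1) ** 2
        )
        return out


def default_protein_curve(t: float) -> float:
    """Rise over the first ~60 min, then partial decline (unimodal)."""
    if t <= 60.0:
        return 1.0 + 0.40 * t / 60.0
    return 1.40 - 0.35 * (t - 60.0) / 35.0


def default_nucleic_curve(t: float) -> float:
    """Strictly decreasing, with a slower late slope (leveling after ~1 h)."""
    if t <= 60.0:
        return 1.0 - 0.0075 * t
    return 0.55 - 0.006 * (t - 60.0)


@dataclass(frozen=True)
class TrajectoryProgram:
    """Time program of band-class multipliers for co-culture activation.

    ``protein_curve`` must be unimodal with an interior maximum over
    [min(time), max(time)]; ``nucleic_curve`` must be non-increasing.
    ``time_grid_min`` = None draws acquisition times uniformly over
    [t_start, t_stop] (default 15-95 min after co-culture start).
    """

    protein_curve: Callable[[float], float] = default_protein_curve
    nucleic_curve: Callable[[float], float] = default_nucleic_curve
    time_grid_min: tuple[float, ...] | None = None
    t_start: float = 15.0
    t_stop: float = 95.0

    def __post_init__(self) -> None:
        if self.time_grid_min is not None and len(self.time_grid_min) == 0:
            raise ValueError("time grid must be non-empty")
        lo, hi = self.time_span()
        grid = np.linspace(lo, hi, 201)
        nuc = np.array([self.nucleic_curve(t) for t in grid])
        if np.any(np.diff(nuc) > 1e-12):
            raise ValueError("nucleic_curve must be non-increasing")
        pro = np.array([self.protein_curve(t) for t in grid])
        k = int(np.argmax(pro))
        if not (np.all(np.diff(pro[: k + 1]) >= -1e-12) and np.all(np.diff(pro[k:]) <= 1e-12)):
            raise ValueError("protein_curve must be unimodal")

    def time_span(self) -> tuple[float, float]:
        if self.time_grid_min is not None:
            return (min(self.time_grid_min), max(self.time_grid_min))
        return (self.t_start, self.t_stop)

    def sample_times(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.time_grid_min is not None:
            return rng.choice(np.asarray(self.time_grid_min, dtype=float), size=n)
        return rng.uniform(self.t_start, self.t_stop, size=n)


ClassEffects = Mapping[str, Mapping[BiochemicalClass, float]]


def default_class_effects() -> dict[str, dict[BiochemicalClass, float]]:
    """Effect directions mirroring the observed class contrasts.

    CAR cells are enriched in protein/aromatic and membrane bands, Mock and
    (more so) Unstim cells in nucleic-acid bands; JeKo-1 B cells are
    protein-rich with weaker adenine signal; red blood cells are dominated
    by hemoprotein bands with almost no nucleic-acid or mitochondrial
    signal.  Magnitudes are free generator parameters, not measured values.
    """
    P, N, M, L, H = BiochemicalClass
    return {
        ClassLabel.CAR.value: {P: 1.2, L: 1.1},
        ClassLabel.MOCK.value: {N: 1.2},
        ClassLabel.UNSTIM.value: {N: 1.25},
        ClassLabel.TCELL.value: {},
        ClassLabel.BCELL_PRIMARY.value: {N: 0.8, P: 1.1},
        ClassLabel.BCELL_JEKO.value: {N: 0.7, P: 1.3},
        ClassLabel.RBC.value: {H: 3.0, N: 0.05, M: 0.1},
        ClassLabel.OTHER.value: {},
    }


def gd2_class_effects() -> dict[str, dict[BiochemicalClass, float]]:
    """CAR-vs-Mock effects for a tonic-signaling (GD2-like) construct:
    the CAR class additionally gains mitochondrial band intensity."""
    eff = default_class_effects()
    eff[ClassLabel.CAR.value] = dict(eff[ClassLabel.CAR.value])
    eff[ClassLabel.CAR.value][BiochemicalClass.MITOCHONDRIAL] = 1.3
    return eff


@dataclass(frozen=True)
class GeneratorConfig:
    """All knobs of the synthetic generator (see module docstring).

    SDs are log-scale standard deviations of log-normal multipliers:
    ``donor_sd`` acts per (donor, biochemical class) and is shared by all
    spectra of a donor (restrict it to selected classes with
    ``donor_effect_classes``); ``cell_sd`` acts per spectrum and band
    (cell-to-cell compositional heterogeneity and SERS microenvironment
    sampling); ``hotspot_sd`` scales whole spectra.  ``noise_sd`` is the
    additive Gaussian SD relative to the mean catalog peak amplitude;
    ``spike_rate`` is the expected number of cosmic-ray spikes per spectrum.
    """

    n_spectra_per_condition: int = 200
    axis: WavenumberAxis = field(default_factory=default_axis)
    catalog: BandCatalog = field(default_factory=default_catalog)
    class_effects: ClassEffects = field(default_factory=default_class_effects)
    donor_sd: float = 0.25
    donor_effect_classes: tuple[BiochemicalClass, ...] | None = None
    hotspot_sd: float = 0.30
    cell_sd: float = 0.10
    noise_sd: float = 0.05
    baseline: BaselineConfig | None = field(default_factory=BaselineConfig)
    spike_rate: float = 0.1
    peak_eta: float = 0.5
    trajectory: TrajectoryProgram | None = None
    drift_per_min: float = 0.002
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.donor_sd, self.hotspot_sd, self.cell_sd, self.noise_sd, self.spike_rate) < 0:
            raise ValueError("SDs and spike_rate must be >= 0")
        if not 0.0 <= self.peak_eta <= 1.0:
            raise ValueError("peak_eta must lie in [0, 1]")
        if self.n_spectra_per_condition < 1:
            raise ValueError("n_spectra_per_condition must be >= 1")


@dataclass
class TruthRecord:
    """Latent ground truth for a generated SpectraSet, index-aligned to it."""

    spectrum_ids: list[str]
    clean: np.ndarray  # (n, p) hotspot * peak sum, no baseline/noise/spikes/drift
    baseline: np.ndarray  # (p,) shared baseline, zeros if disabled
    hotspot: np.ndarray  # (n,)
    drift: np.ndarray  # (n,) multiplicative drift factors (1 for static)
    amplitudes: np.ndarray  # (n, K) per-spectrum effective band amplitudes
    donor_multipliers: dict[tuple[str, BiochemicalClass], float]
    spike_channels: list[np.ndarray]
    spike_heights: list[np.ndarray]
    protein_multiplier: np.ndarray  # (n,) trajectory multiplier, 1 if static
    nucleic_multiplier: np.ndarray
    times: np.ndarray  # (n,) time_min, nan for static

    def n_spikes(self) -> int:
        return int(sum(len(c) for c in self.spike_channels))

    def expected_spectrum(self, i: int) -> np.ndarray:
        """Noise- and spike-free expectation of spectrum i (incl. drift)."""
        return self.drift[i] * (self.clean[i] + self.baseline)

    def normalized_truth(self, i: int) -> np.ndarray:
        """Baseline-free, noise-free, per-spectrum z-scored truth signal."""
        x = self.clean[i]
        return (x - x.mean()) / x.std()


def _profile_matrix(config: GeneratorConfig) -> np.ndarray:
    """(K, p) matrix of unit-height peak profiles on the axis."""
    nu = config.axis.values
    return np.vstack(
        [pseudo_voigt(nu, b.center_cm1, b.width_cm1, config.peak_eta) for b in config.catalog.bands]
    )


def _donor_multipliers(
    donors: Sequence[str], config: GeneratorConfig, rng: np.random.Generator
) -> dict[tuple[str, BiochemicalClass], float]:
    affected = (
        set(config.donor_effect_classes)
        if config.donor_effect_classes is not None
        else set(BiochemicalClass)
    )
    out: dict[tuple[str, BiochemicalClass], float] = {}
    for d in donors:
        for bc in BiochemicalClass:
            draw = config.donor_sd > 0 and bc in affected
            out[(d, bc)] = float(np.exp(rng.normal(0.0, config.donor_sd))) if draw else 1.0
    return out


def _check_classes(classes: Sequence[str], config: GeneratorConfig) -> list[str]:
    labels = [c.value if isinstance(c, ClassLabel) else str(c) for c in classes]
    for c in labels:
        if c not in _VALID_LABELS:
            raise ValueError(f"unknown class label {c!r}")
        if c not in config.class_effects:
            raise ValueError(f"class label {c!r} missing from class_effects")
    return labels


def _spikes(
    n_channels: int, max_amp: float, config: GeneratorConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Cosmic-ray spikes: Poisson count, 1-3 channels wide, 10-50x max peak."""
    count = rng.poisson(config.spike_rate)
    channels: list[int] = []
    heights: list[float] = []
    for _ in range(count):
        width = int(rng.integers(1, 4))
        start = int(rng.integers(0, n_channels - width + 1))
        height = float(rng.uniform(10.0, 50.0)) * max_amp
        for w in range(width):
            channels.append(start + w)
            # edges of a multi-channel spike are slightly lower
            heights.append(height * (1.0 if w == 0 else float(rng.uniform(0.5, 1.0))))
    return np.array(channels, dtype=int), np.array(heights)


def _generate(
    config: GeneratorConfig,
    records: list[tuple[str, str, float | None]],  # (class_label, donor, time)
    donors: Sequence[str],
    rng: np.random.Generator,
    trajectory: TrajectoryProgram | None,
) -> tuple[SpectraSet, TruthRecord]:
    profiles = _profile_matrix(config)
    bands = config.catalog.bands
    base_amp = np.array([b.base_amplitude for b in bands])
    band_class = [b.biochemical_class for b in bands]
    mean_amp = float(base_amp.mean())
    noise_scale = config.noise_sd * mean_amp
    max_amp = float(base_amp.max())
    baseline = (
        config.baseline.evaluate(config.axis.values)
        if config.baseline is not None
        else np.zeros(config.axis.n_channels)
    )
    donor_mult = _donor_multipliers(donors, config, rng)

    n = len(records)
    p = config.axis.n_channels
    K = len(bands)
    amplitudes = np.empty((n, K))
    hotspot = np.empty(n)
    drift = np.ones(n)
    pro_mult = np.ones(n)
    nuc_mult = np.ones(n)
    times = np.full(n, np.nan)
    spike_ch: list[np.ndarray] = []
    spike_h: list[np.ndarray] = []
    spectra: list[Spectrum] = []
    clean = np.empty((n, p))

    counters: dict[tuple[str, str], int] = {}
    for i, (label, donor, t) in enumerate(records):
        eff = config.class_effects[label]
        amps = base_amp.copy()
        for k, bc in enumerate(band_class):
            amps[k] *= eff.get(bc, 1.0) * donor_mult[(donor, bc)]
        if trajectory is not None and t is not None and label == ClassLabel.CAR.value:
            pm = float(trajectory.protein_curve(t))
            nm = float(trajectory.nucleic_curve(t))
            pro_mult[i], nuc_mult[i] = pm, nm
            for k, bc in enumerate(band_class):
                if bc is BiochemicalClass.PROTEIN_AROMATIC:
                    amps[k] *= pm
                elif bc is BiochemicalClass.NUCLEIC_ACID:
                    amps[k] *= nm
        if t is not None:
            times[i] = t
            drift[i] = math.exp(config.drift_per_min * t)
        if config.cell_sd > 0:
            # cell-to-cell compositional heterogeneity: each cell's band
            # amplitudes jitter independently around the condition mean
            amps = amps * np.exp(rng.normal(0.0, config.cell_sd, size=amps.size))
        amplitudes[i] = amps
        h = float(np.exp(rng.normal(0.0, config.hotspot_sd))) if config.hotspot_sd > 0 else 1.0
        hotspot[i] = h
        clean[i] = h * (amps @ profiles)

        intensity = drift[i] * (clean[i] + baseline)
        if noise_scale > 0:
            intensity = intensity + rng.normal(0.0, noise_scale, size=p)
        ch, heights = _spikes(p, max_amp, config, rng)
        spike_ch.append(ch)
        spike_h.append(heights)
        if ch.size:
            intensity = intensity.copy()
            intensity[ch] += heights

        j = counters.get((label, donor), 0)
        counters[(label, donor)] = j + 1
        spectra.append(
            Spectrum(
                intensities=intensity,
                spectrum_id=f"{label}-{donor}-{j:05d}",
                donor_id=donor,
                class_label=label,
                batch_id=f"{donor}:{label}",
                time_min=t,
            )
        )

    sset = SpectraSet(config.axis, spectra, [f"simulated n={n} seed={config.seed}"])
    truth = TruthRecord(
        spectrum_ids=sset.ids(),
        clean=clean,
        baseline=baseline,
        hotspot=hotspot,
        drift=drift,
        amplitudes=amplitudes,
        donor_multipliers=donor_mult,
        spike_channels=spike_ch,
        spike_heights=spike_h,
        protein_multiplier=pro_mult,
        nucleic_multiplier=nuc_mult,
        times=times,
    )
    return sset, truth


def generate_static(
    config: GeneratorConfig,
    classes: Sequence[str | ClassLabel],
    donors: Sequence[str],
) -> tuple[SpectraSet, TruthRecord]:
    """Generate a static (no time course) SpectraSet plus its ground truth.

    ``n_spectra_per_condition`` spectra are drawn for every (class, donor)
    combination, in class-major, donor-minor, acquisition order.
    """
    if not classes:
        raise ValueError("classes must be non-empty")
    labels = _check_classes(classes, config)
    rng = np.random.default_rng(config.seed)
    records = [
        (label, donor, None)
        for label in labels
        for donor in donors
        for _ in range(config.n_spectra_per_condition)
    ]
    return _generate(config, records, donors, rng, trajectory=None)


def generate_timecourse(
    config: GeneratorConfig,
    donors: Sequence[str],
    conditions: Sequence[str | ClassLabel] = (ClassLabel.CAR, ClassLabel.UNSTIM),
) -> tuple[SpectraSet, TruthRecord]:
    """Generate a co-culture activation time course plus its ground truth.

    CAR spectra receive time-dependent protein/nucleic band multipliers
    from the trajectory program; UNSTIM spectra are time-stationary apart
    from a multiplicative acquisition drift exp(drift_per_min * t) shared
    by both conditions (so the log-ratio statistic must remove it).
    """
    if config.trajectory is None:
        raise ValueError("generate_timecourse requires config.trajectory")
    labels = _check_classes(conditions, config)
    rng = np.random.default_rng(config.seed)
    records: list[tuple[str, str, float | None]] = []
    for label in labels:
        for donor in donors:
            ts = config.trajectory.sample_times(config.n_spectra_per_condition, rng)
            records.extend((label, donor, float(t)) for t in np.sort(ts))
    return _generate(config, records, donors, rng, trajectory=config.trajectory)
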