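"""Band dynamics: band intensities, log-ratio trajectories, drift
cancellation, block bootstrap and monotonicity statistics."""

import numpy as np
import pytest
from scipy.stats import spearmanr

import spectracyte as sct
from spectracyte.dynamics import (
    _blocks,
    band_intensity,
    bin_mean_spectra,
    block_bootstrap_ci,
    logratio_trajectory,
    monotonicity,
)
from spectracyte.embedding import TimeBinning
from spectracyte.simulate import pseudo_voigt
from spectracyte.spectra import BandDefinition, BiochemicalClass

P, N = BiochemicalClass.PROTEIN_AROMATIC, BiochemicalClass.NUCLEIC_ACID


def _timed_set(axis, values_by_time, label="CAR"):
    """values_by_time: list of (time, intensity_vector)."""
    spectra = [
        sct.Spectrum(v, f"{label}{i}", "D1", label, "b0", time_min=t)
        for i, (t, v) in enumerate(values_by_time)
    ]
    return sct.SpectraSet(axis, spectra)


class TestBandIntensity:
    def test_constant_vector(self, axis):
        band = BandDefinition(1002.0, P, 20.0)
        assert band_intensity(np.full(axis.n_channels, 3.3), band, axis) == pytest.approx(3.3, abs=1e-12)

    def test_unit_peak_filling_band(self, axis):
        band = BandDefinition(1002.0, P, 20.0)
        v = np.zeros(axis.n_channels)
        from spectracyte.spectra import band_channels

        v[band_channels(band, axis)] = 1.0
        assert band_intensity(v, band, axis) == 1.0

    def test_pseudo_voigt_matches_direct_summation(self, axis):
        band = BandDefinition(1092.0, N, 20.0)
        v = pseudo_voigt(axis.values, 1092.0, 12.0, 0.5)
        from spectracyte.spectra import band_channels

        idx = band_channels(band, axis)
        expected = v[idx].sum() / idx.size
        assert band_intensity(v, band, axis) == pytest.approx(expected, abs=1e-9)


class TestBinMeanSpectra:
    def test_single_spectrum_per_bin(self, axis):
        rng = np.random.default_rng(0)
        rows = [(t, rng.normal(5, 1, axis.n_channels)) for t in (20.0, 30.0)]
        sset = _timed_set(axis, rows)
        out = bin_mean_spectra(sset)
        np.testing.assert_array_equal(out[("CAR", 15.0)], rows[0][1])
        np.testing.assert_array_equal(out[("CAR", 25.0)], rows[1][1])

    def test_symmetric_pair_zero_mean(self, axis):
        v = np.random.default_rng(1).normal(size=axis.n_channels)
        sset = _timed_set(axis, [(20.0, v), (21.0, -v)])
        out = bin_mean_spectra(sset)
        np.testing.assert_allclose(out[("CAR", 15.0)], 0.0, atol=1e-12)

    def test_noise_free_bin_means_equal_generative_means(self):
        cfg = sct.GeneratorConfig(
            n_spectra_per_condition=120,
            seed=2,
            noise_sd=0.0,
            spike_rate=0.0,
            baseline=None,
            trajectory=sct.TrajectoryProgram(),
        )
        sset, truth = sct.generate_timecourse(cfg, ["D1"], conditions=["CAR"])
        out = bin_mean_spectra(sset)
        binning = TimeBinning()
        which = binning.assign(sset.times())
        X_truth = truth.clean * truth.drift[:, None]  # baseline disabled
        for b, start in enumerate(binning.labels):
            mask = which == b
            if mask.any():
                np.testing.assert_allclose(
                    out[("CAR", start)], X_truth[mask].mean(axis=0), rtol=1e-12
                )


def _panel_positive_sets(axis, car_fn, un_fn, n_per_bin=30, seed=0):
    """Construct positive-representation sets whose band contents follow the
    given per-time multiplier functions (analytic, pipeline-free)."""
    rng = np.random.default_rng(seed)
    nu = axis.values
    base = (
        1.0 * pseudo_voigt(nu, 1002.0, 12.0, 0.5)
        + 0.5 * pseudo_voigt(nu, 898.0, 12.0, 0.5)
        + 0.5 * pseudo_voigt(nu, 1025.0, 12.0, 0.5)
        + 0.4 * pseudo_voigt(nu, 1222.0, 12.0, 0.5)
        + 0.5 * pseudo_voigt(nu, 1262.0, 12.0, 0.5)
        + 0.7 * pseudo_voigt(nu, 1602.0, 12.0, 0.5)
    )
    nuc = (
        1.0 * pseudo_voigt(nu, 728.0, 12.0, 0.5)
        + 0.7 * pseudo_voigt(nu, 1092.0, 12.0, 0.5)
        + 0.6 * pseudo_voigt(nu, 1334.0, 12.0, 0.5)
    )
    rows_car, rows_un = [], []
    for lo, hi in zip(TimeBinning().edges_min[:-1], TimeBinning().edges_min[1:]):
        for _ in range(n_per_bin):
            t = rng.uniform(lo, hi)
            rows_car.append((t, car_fn(t) @ np.vstack([base, nuc]) + 0.1))
            rows_un.append((t, un_fn(t) @ np.vstack([base, nuc]) + 0.1))
    return _timed_set(axis, rows_car, "CAR"), _timed_set(axis, rows_un, "UNSTIM")


class TestLogratioTrajectory:
    def test_identical_conditions_degenerate_zero(self, axis):
        car, un = _panel_positive_sets(
            axis, lambda t: np.array([1.0, 1.0]), lambda t: np.array([1.0, 1.0])
        )
        un2 = _timed_set(axis, [(s.time_min, s.intensities) for s in car], "UNSTIM")
        traj = logratio_trajectory(car, un2)
        assert traj.degenerate
        for series in traj.class_series.values():
            np.testing.assert_allclose(series, 0.0)

    @pytest.mark.parametrize("smooth", [False, True])
    def test_drift_cancels(self, axis, smooth):
        """A multiplicative drift applied to both conditions cancels in the
        log-ratio: exactly when the drift is constant within each time bin,
        and to within-bin-variation accuracy for a smooth drift.  (In the
        full pipeline a smooth per-spectrum drift is already removed exactly
        by total-intensity normalization.)"""

        def car_fn(t):
            return np.array([1.0 + 0.002 * t, 1.0 - 0.004 * t])

        def un_fn(t):
            return np.array([1.0, 1.0])

        car, un = _panel_positive_sets(axis, car_fn, un_fn, seed=3)
        base_traj = logratio_trajectory(car, un)
        binning = TimeBinning()
        if smooth:
            drift = lambda t: np.exp(0.2 * t / 95.0)
            atol = 0.05
        else:
            drift = lambda t: 1.0 + 0.3 * binning.assign(np.array([t]))[0]
            atol = 1e-9
        car_d = car.with_intensities(
            np.vstack([drift(s.time_min) * s.intensities for s in car])
        )
        un_d = un.with_intensities(
            np.vstack([drift(s.time_min) * s.intensities for s in un])
        )
        traj_d = logratio_trajectory(car_d, un_d)
        for bc in base_traj.class_series:
            np.testing.assert_allclose(
                base_traj.class_series[bc], traj_d.class_series[bc], atol=atol
            )

    def test_programmed_decline_gives_decreasing_series(self, axis):
        """Strictly decreasing nucleic multiplier under shared drift:
        nucleic-class series strictly decreasing over the 6 bins."""
        car_fn = lambda t: np.array([1.0, 1.0 - 0.004 * t]) * np.exp(0.002 * t)
        un_fn = lambda t: np.array([1.0, 1.0]) * np.exp(0.002 * t)
        car, un = _panel_positive_sets(axis, car_fn, un_fn, seed=4, n_per_bin=60)
        traj = logratio_trajectory(car, un)
        series = traj.class_series[N]
        assert np.all(np.diff(series) < 0)
        mono = monotonicity(traj)
        assert mono[N][0] == pytest.approx(-1.0)

    def test_non_positive_band_mean_rejected(self, axis):
        rows = [(20.0 + i, np.full(axis.n_channels, -1.0)) for i in range(12)]
        car = _timed_set(axis, rows, "CAR")
        un = _timed_set(axis, [(t, -v) for t, v in rows], "UNSTIM")
        with pytest.raises(ValueError, match="positive"):
            logratio_trajectory(car, un)

    def test_one_sided_bin_dropped_with_warning(self, axis):
        car, un = _panel_positive_sets(
            axis, lambda t: np.array([1.0, 1.0]), lambda t: np.array([1.0, 1.0])
        )
        keep = np.array([s.time_min < 75.0 for s in un])
        un_short = un.select(keep)
        with pytest.warns(UserWarning, match="dropped"):
            traj = logratio_trajectory(car, un_short)
        assert traj.bin_starts.tolist() == [15.0, 25.0, 35.0, 45.0, 55.0]


class TestBlocks:
    def test_block_lengths(self):
        blocks = _blocks(100)
        assert all(len(b) == 10 for b in blocks)
        blocks = _blocks(10)
        assert sum(len(b) for b in blocks) == 10
        assert max(len(b) for b in blocks) == 4  # ceil(sqrt(10))
        assert _blocks(1)[0].tolist() == [0]

    def test_blocks_are_contiguous_partition(self):
        for n in (7, 30, 111):
            blocks = _blocks(n)
            flat = np.concatenate(blocks)
            np.testing.assert_array_equal(flat, np.arange(n))


class TestBlockBootstrap:
    def test_zero_variance_zero_width_ci(self, axis):
        car, un = _panel_positive_sets(
            axis,
            lambda t: np.array([1.0 + 0.002 * t, 1.0 - 0.004 * t]),
            lambda t: np.array([1.0, 1.0]),
            seed=5,
        )
        # make every spectrum within a bin identical: zero sampling variance
        binning = TimeBinning()

        def freeze(sset):
            X = sset.intensity_matrix()
            which = binning.assign(sset.times())
            for b in range(binning.n_bins):
                m = which == b
                if m.any():
                    X[m] = X[m][0]
            return sset.with_intensities(X)

        traj = block_bootstrap_ci(freeze(car), freeze(un), n_boot=100, seed=0)
        for bc in traj.class_series:
            np.testing.assert_allclose(traj.ci_low[bc], traj.ci_high[bc], atol=1e-12)

    def test_ci_brackets_estimate_and_is_deterministic(self, axis):
        car, un = _panel_positive_sets(
            axis,
            lambda t: np.array([1.0 + 0.002 * t, 1.0 - 0.004 * t]),
            lambda t: np.array([1.0, 1.0]),
            seed=6,
        )
        noisy_car = car.with_intensities(
            car.intensity_matrix()
            * np.exp(np.random.default_rng(1).normal(0, 0.05, (len(car), 1)))
        )
        t1 = block_bootstrap_ci(noisy_car, un, n_boot=200, seed=9)
        t2 = block_bootstrap_ci(noisy_car, un, n_boot=200, seed=9)
        for bc in t1.class_series:
            np.testing.assert_array_equal(t1.ci_low[bc], t2.ci_low[bc])
            assert np.all(t1.ci_low[bc] <= t1.ci_high[bc])


class TestMonotonicity:
    def _traj(self, series):
        return sct.BandTrajectory(
            bin_starts=np.array([15.0, 25.0, 35.0, 45.0, 55.0, 75.0]),
            class_series={N: np.asarray(series, dtype=float)},
            band_series={},
            n_car=np.full(6, 10),
            n_unstim=np.full(6, 10),
        )

    def test_strict_monotone_series(self):
        assert monotonicity(self._traj([6, 5, 4, 3, 2, 1]))[N][0] == pytest.approx(-1.0)
        assert monotonicity(self._traj([1, 2, 3, 4, 5, 6]))[N][0] == pytest.approx(1.0)

    def test_matches_brute_force_rank_formula(self):
        series = [1.0, 3.0, 2.0, 4.0, 5.0, 6.0]
        rho, p = monotonicity(self._traj(series))[N]
        # oracle: direct Spearman on ranks
        expected_rho, expected_p = spearmanr(series, [15, 25, 35, 45, 55, 75])
        assert rho == pytest.approx(expected_rho)
        assert p == pytest.approx(expected_p)

    def test_too_few_bins_empty(self):
        traj = sct.BandTrajectory(
            bin_starts=np.array([15.0, 25.0]),
            class_series={N: np.array([1.0, 0.5])},
            band_series={},
            n_car=np.full(2, 10),
            n_unstim=np.full(2, 10),
        )
        with pytest.warns(UserWarning, match="fewer than 3"):
            assert monotonicity(traj) == {}
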