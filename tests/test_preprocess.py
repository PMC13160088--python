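"""Preprocessing chain: despiking, denoising, airPLS, z-scoring, QC screen."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import spectracyte as sct
from spectracyte.preprocess import (
    airpls_baseline,
    denoise,
    despike,
    exclude_outliers,
    normalize,
    positive_representation,
    run_preprocess,
)
from spectracyte.simulate import pseudo_voigt


def _peaky(nu, noise_sd=0.0, rng=None):
    """Smooth synthetic peak spectrum on the given axis values."""
    x = (
        1.0 * pseudo_voigt(nu, 1002.0, 12.0, 0.5)
        + 0.7 * pseudo_voigt(nu, 728.0, 12.0, 0.5)
        + 0.5 * pseudo_voigt(nu, 1450.0, 12.0, 0.5)
        + 2.0
    )
    if noise_sd > 0:
        x = x + rng.normal(0, noise_sd, nu.size)
    return x


class TestDespike:
    def test_constant_spectrum_unchanged(self):
        x = np.full(100, 3.0)
        out, spikes = despike(x)
        np.testing.assert_array_equal(out, x)
        assert spikes.size == 0

    def test_single_spike_exactly_flagged(self, axis):
        rng = np.random.default_rng(0)
        noise_sd = 0.02
        clean = _peaky(axis.values, noise_sd, rng)
        x = clean.copy()
        x[400] += 30.0  # ~30x the tallest peak
        out, spikes = despike(x)
        assert spikes.tolist() == [400]
        assert abs(out[400] - clean[400]) < 2 * noise_sd + 0.05  # window-mean repl.
        # untouched channels are bit-identical
        mask = np.ones(x.size, dtype=bool)
        mask[400] = False
        np.testing.assert_array_equal(out[mask], x[mask])

    def test_wide_spike_fully_removed(self, axis):
        rng = np.random.default_rng(1)
        x = _peaky(axis.values, 0.02, rng)
        x[600:603] += np.array([25.0, 22.0, 24.0])
        out, spikes = despike(x)
        assert set(spikes.tolist()) == {600, 601, 602}
        assert np.all(out[600:603] < 5.0)

    def test_false_flag_rate_below_one_percent(self, axis):
        """Spike-free noisy spectra: < 1% of channels flagged over 100 seeds."""
        flagged = total = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            x = _peaky(axis.values, 0.03, rng)
            _, spikes = despike(x)
            flagged += spikes.size
            total += x.size
        assert flagged / total < 0.01

    def test_sharp_peaks_never_flagged_without_noise(self, axis):
        # noiseless smooth peaks must survive despiking untouched
        x = _peaky(axis.values)
        out, spikes = despike(x)
        assert spikes.size == 0
        np.testing.assert_array_equal(out, x)

    def test_despike_idempotent(self, axis):
        rng = np.random.default_rng(7)
        new_flags = 0
        for seed in range(50):
            rng = np.random.default_rng(seed)
            x = _peaky(axis.values, 0.03, rng)
            x[200] += 20.0
            once, _ = despike(x)
            _, again = despike(once)
            new_flags += again.size
        assert new_flags <= 1  # nothing new in >= 99% of runs


class TestDenoise:
    def test_zero_spectrum_fixed_point(self):
        x = np.zeros(512)
        np.testing.assert_array_equal(denoise(x), x)

    def test_noise_variance_reduced(self):
        worse = 0
        for seed in range(50):
            rng = np.random.default_rng(seed)
            x = 5.0 + rng.normal(0, 0.1, 1001)
            if denoise(x).var() >= x.var():
                worse += 1
        assert worse == 0

    def test_peaks_preserved(self, axis):
        x = _peaky(axis.values)
        out = denoise(x)
        assert np.max(np.abs(out - x)) < 0.01 * x.max()

    def test_matches_reference_bayes_shrink(self, axis):
        """Cross-check against the independent BayesShrink implementation."""
        skimage = pytest.importorskip("skimage.restoration")
        rng = np.random.default_rng(3)
        x = _peaky(axis.values, 0.05, rng)
        ours = denoise(x)
        ref = skimage.denoise_wavelet(
            x, wavelet="sym8", method="BayesShrink", mode="soft", rescale_sigma=False
        )
        # same shrinkage family and noise estimator: outputs nearly coincide
        assert np.corrcoef(ours, ref)[0, 1] > 0.999
        assert np.max(np.abs(ours - ref)) < 0.05

    def test_short_spectrum_returned_with_warning(self):
        x = np.arange(8.0)
        with pytest.warns(UserWarning, match="short"):
            out = denoise(x)
        np.testing.assert_array_equal(out, x)


class TestAirPLS:
    def test_pure_smooth_baseline_fully_removed(self, axis):
        u = (axis.values - 1200.0) / 500.0
        x = 5.0 + 2.0 * u + 1.5 * u**2 + 0.5 * u**4
        baseline, corrected, ok = airpls_baseline(x)
        assert ok
        assert np.max(np.abs(corrected)) < 0.01 * (x.max() - x.min())

    def test_zero_spectrum_fixed_point(self):
        x = np.zeros(200)
        baseline, corrected, ok = airpls_baseline(x)
        np.testing.assert_allclose(baseline, 0, atol=1e-12)
        np.testing.assert_allclose(corrected, 0, atol=1e-12)

    def test_known_baseline_recovered(self, axis):
        """RMSE of fitted baseline < 5% of baseline range, off peak supports."""
        cfg = sct.BaselineConfig()
        true_base = cfg.evaluate(axis.values)
        x = _peaky(axis.values) - 2.0 + true_base
        baseline, _, _ = airpls_baseline(x)
        on_peak = np.zeros(axis.n_channels, dtype=bool)
        for c in (1002.0, 728.0, 1450.0):
            on_peak |= np.abs(axis.values - c) < 30
        resid = baseline[~on_peak] - true_base[~on_peak]
        rmse = np.sqrt(np.mean(resid**2))
        assert rmse < 0.05 * (true_base.max() - true_base.min())

    def test_baseline_smoother_than_input(self, axis):
        rng = np.random.default_rng(5)
        x = _peaky(axis.values, 0.05, rng) + sct.BaselineConfig().evaluate(axis.values)
        baseline, _, _ = airpls_baseline(x)
        energy = lambda v: np.sum(np.diff(v, n=2) ** 2)
        assert energy(baseline) <= energy(x)


class TestNormalize:
    def test_mean_zero_sd_one(self, axis):
        rng = np.random.default_rng(0)
        z = normalize(_peaky(axis.values, 0.1, rng))
        assert abs(z.mean()) < 1e-9
        assert abs(z.std() - 1.0) < 1e-9

    @settings(deadline=None, max_examples=25)
    @given(
        a=st.floats(min_value=0.1, max_value=50.0),
        b=st.floats(min_value=-10.0, max_value=10.0),
    )
    def test_affine_invariance(self, a, b):
        rng = np.random.default_rng(1)
        x = rng.normal(5, 1, 300)
        np.testing.assert_allclose(normalize(a * x + b), normalize(x), atol=1e-9)

    def test_negative_scale_negates(self):
        rng = np.random.default_rng(2)
        x = rng.normal(5, 1, 300)
        np.testing.assert_allclose(normalize(-2.0 * x), -normalize(x), atol=1e-9)

    def test_zero_variance_names_spectrum(self):
        with pytest.raises(ValueError, match="S99"):
            normalize(np.full(50, 3.0), "S99")


def _uniform_set(axis, scales, batch_ids):
    spectra = [
        sct.Spectrum(np.full(axis.n_channels, s), f"S{i}", "D1", "CAR", b)
        for i, (s, b) in enumerate(zip(scales, batch_ids))
    ]
    return sct.SpectraSet(axis, spectra)


class TestExcludeOutliers:
    def test_identical_spectra_none_excluded(self, axis):
        sset = _uniform_set(axis, [1.0] * 100, ["b0"] * 100)
        kept, excluded, _ = exclude_outliers(sset)
        assert len(kept) == 100 and not excluded

    def test_single_bright_spectrum_excluded(self, axis):
        rng = np.random.default_rng(0)
        scales = list(1.0 + 0.01 * rng.normal(size=99)) + [10.0]
        sset = _uniform_set(axis, scales, ["b0"] * 100)
        kept, excluded, _ = exclude_outliers(sset)
        assert list(excluded) == ["S99"]
        assert len(kept) == 99

    def test_exclusion_is_per_batch(self, axis):
        """A spectrum extreme only within its own batch is excluded, while an
        identical spectrum in a brighter batch survives."""
        rng = np.random.default_rng(1)
        lo = list(1.0 + 0.01 * rng.normal(size=50)) + [5.0]
        hi = list(5.0 + 0.01 * rng.normal(size=50)) + [5.0]
        sset = _uniform_set(axis, lo + hi, ["lo"] * 51 + ["hi"] * 51)
        kept, excluded, _ = exclude_outliers(sset)
        assert "S50" in excluded  # the 5.0 spectrum inside the dim batch
        assert "S101" not in excluded  # identical value, bright batch

    def test_threshold_is_one_sided_high(self, axis):
        scales = [1.0] * 50 + [0.01]  # very dim spectrum
        sset = _uniform_set(axis, scales, ["b0"] * 51)
        _, excluded, _ = exclude_outliers(sset)
        assert not excluded

    def test_singleton_batch_kept_with_warning(self, axis):
        sset = _uniform_set(axis, [1.0], ["solo"])
        with pytest.warns(UserWarning, match="single"):
            kept, excluded, _ = exclude_outliers(sset)
        assert len(kept) == 1


class TestFullChain:
    def test_empty_set(self, axis):
        out, report = run_preprocess(sct.SpectraSet(axis, []))
        assert len(out) == 0 and not report.excluded

    def test_clean_set_all_retained_and_normalized(self):
        cfg = sct.GeneratorConfig(n_spectra_per_condition=10, seed=13)
        sset, _ = sct.generate_static(cfg, ["CAR"], ["D1"])
        out, report = run_preprocess(sset)
        assert len(out) == len(sset)
        X = out.intensity_matrix()
        np.testing.assert_allclose(X.mean(axis=1), 0, atol=1e-9)
        np.testing.assert_allclose(X.std(axis=1), 1, atol=1e-9)

    def test_scale_invariance(self):
        """Two spectra differing only by a positive scalar preprocess to the
        same final output (hotspot invariance)."""
        cfg = sct.GeneratorConfig(
            n_spectra_per_condition=3, seed=17, hotspot_sd=0.0, spike_rate=0.0
        )
        sset, _ = sct.generate_static(cfg, ["CAR"], ["D1"])
        out1, _ = run_preprocess(sset)
        scaled = sset.with_intensities(3.7 * sset.intensity_matrix())
        out2, _ = run_preprocess(scaled)
        np.testing.assert_allclose(
            out1.intensity_matrix(), out2.intensity_matrix(), atol=1e-6
        )

    def test_recovery_of_truth_signal(self):
        """Preprocessed spectra correlate > 0.95 with the generator's
        baseline-free, noise-free, z-scored truth at default settings."""
        cfg = sct.GeneratorConfig(n_spectra_per_condition=20, seed=19)
        sset, truth = sct.generate_static(cfg, ["CAR", "MOCK"], ["D1"])
        out, report = run_preprocess(sset)
        assert len(out) == len(sset)  # ids align with truth rows
        X = out.intensity_matrix()
        for i in range(len(out)):
            r = np.corrcoef(X[i], truth.normalized_truth(i))[0, 1]
            assert r > 0.95

    def test_class_contrast_signs_survive_pipeline(self):
        effects = {"CAR": {sct.BiochemicalClass.PROTEIN_AROMATIC: 1.3},
                   "MOCK": {sct.BiochemicalClass.NUCLEIC_ACID: 1.3}}
        cfg = sct.GeneratorConfig(
            n_spectra_per_condition=60, class_effects=effects, seed=23
        )
        sset, _ = sct.generate_static(cfg, ["CAR", "MOCK"], ["D1"])
        out, _ = run_preprocess(sset)
        X, y = out.intensity_matrix(), out.labels()
        diff = X[y == "CAR"].mean(axis=0) - X[y == "MOCK"].mean(axis=0)
        ch = {v: i for i, v in enumerate(out.axis.values)}
        assert diff[ch[1002.0]] > 0 and diff[ch[728.0]] < 0

    def test_positive_representation_is_total_normalized(self):
        cfg = sct.GeneratorConfig(n_spectra_per_condition=8, seed=29)
        sset, _ = sct.generate_static(cfg, ["CAR"], ["D1"])
        out, report = run_preprocess(sset)
        pos = positive_representation(out, report)
        np.testing.assert_allclose(pos.intensity_matrix().sum(axis=1), 1.0, atol=1e-12)
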