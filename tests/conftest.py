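import pytest

import spectracyte as sct


@pytest.fixture(scope="session")
def axis():
    return sct.default_axis()  # 700..1700 step 1


@pytest.fixture(scope="session")
def coarse_axis():
    return sct.default_axis(step=2.0)  # 501 channels, for faster model tests


@pytest.fixture(scope="session")
def small_static():
    """60 spectra, 2 classes x 2 donors, default structure (seeded)."""
    cfg = sct.GeneratorConfig(n_spectra_per_condition=15, seed=11)
    return sct.generate_static(cfg, ["CAR", "MOCK"], ["D1", "D2"])


@pytest.fixture(scope="session")
def clean_config():
    """No noise, spikes, baseline or per-spectrum variation: spectra equal
    their generative means exactly."""
    return sct.GeneratorConfig(
        n_spectra_per_condition=5,
        donor_sd=0.0,
        hotspot_sd=0.0,
        cell_sd=0.0,
        noise_sd=0.0,
        spike_rate=0.0,
        baseline=None,
        seed=5,
    )
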