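import pytest

from plugdyn.bursts import (
    compute_burst_es,
    estimate_background,
    filter_bursts,
    search_bursts_dcbs,
)
from plugdyn.synthetic import (
    ConfocalSimConfig,
    TirfSimConfig,
    TwoStateModel,
    simulate_confocal_photons,
    simulate_tirf_traces,
)


@pytest.fixture(scope="session")
def two_state_model():
    return TwoStateModel(k_open=100.0, k_close=100.0)


@pytest.fixture(scope="session")
def confocal_stream(two_state_model):
    """60 s dilute diffusing two-state stream (shared, read-only)."""
    cfg = ConfocalSimConfig(duration=60.0, seed=11, concentration=2.0,
                            box_factor=10.0)
    return simulate_confocal_photons(two_state_model, cfg)


@pytest.fixture(scope="session")
def background(confocal_stream):
    return estimate_background(confocal_stream, window_s=10.0)


@pytest.fixture(scope="session")
def burst_set(confocal_stream, background):
    bs = search_bursts_dcbs(confocal_stream, background, m=10, F=6.0)
    return filter_bursts(compute_burst_es(bs))


@pytest.fixture(scope="session")
def tirf_frames():
    """Small TIRF data set with ground truth (shared, read-only)."""
    cfg = TirfSimConfig(seed=3, n_traces=25, lengths=(100, 354))
    return simulate_tirf_traces(cfg)
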