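import pytest

from clumpclock import OscillatorParams


@pytest.fixture
def params():
    """Default oscillator parameters (24-hr period, 10-hr adhesive window)."""
    return OscillatorParams()


@pytest.fixture
def noiseless_params():
    """Instrument noise off: event measurements become exact functions of size."""
    return OscillatorParams(intensity_cv=0.0, pw_noise_cv=0.0)


@pytest.fixture
def frozen_params():
    """No division, no fragmentation, no jitter: population dynamics are null."""
    return OscillatorParams(
        doubling_time=float("inf"),
        fragmentation_rate=0.0,
        phase_jitter_sd=0.0,
    )


@pytest.fixture
def clonal_params():
    """Deterministic divisions every 2 hr, no jitter, no fragmentation: exact
    cell counts for hand-computable scenarios."""
    return OscillatorParams(
        division_mode="deterministic",
        doubling_time=2.0,
        phase_jitter_sd=0.0,
        fragmentation_rate=0.0,
    )
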