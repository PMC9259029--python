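import numpy as np
import pytest

from gazestab import (
    ResponseModel,
    StimulusSpec,
    Trial,
    TrialMeta,
    generate_response,
    generate_stimulus,
)


@pytest.fixture(scope="session")
def spec2() -> StimulusSpec:
    """The low-frequency protocol stimulus: +/-30 deg, 2 Hz, 8 cycles, 1200 Hz."""
    return StimulusSpec(frequency=2.0, amplitude=30.0, n_cycles=8,
                        sample_rate=1200.0, ramp_endpoints=True)


@pytest.fixture(scope="session")
def spec6() -> StimulusSpec:
    return StimulusSpec(frequency=6.0, amplitude=30.0, n_cycles=8,
                        sample_rate=1200.0, ramp_endpoints=True)


@pytest.fixture(scope="session")
def stim2(spec2) -> np.ndarray:
    return generate_stimulus(spec2)


@pytest.fixture(scope="session")
def stim6(spec6) -> np.ndarray:
    return generate_stimulus(spec6)


@pytest.fixture(scope="session")
def ideal_trial(spec2, stim2) -> Trial:
    """Noise-free perfectly compensating trial: response = -stimulus everywhere."""
    t = np.arange(spec2.n_samples) / spec2.sample_rate
    return Trial(t, stim2, -stim2, TrialMeta(2.0, 30.0, trial_id="ideal"))


def make_noisy_trial(spec, stim, gain=0.6, phase=177.6, seed=0, **overrides) -> Trial:
    model = ResponseModel(gain=gain, phase=phase, seed=seed, **overrides)
    return generate_response(stim, model, spec)


@pytest.fixture(scope="session")
def noisy_trial(spec2, stim2) -> Trial:
    return make_noisy_trial(spec2, stim2, seed=7)
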