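import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from whiskerglm import studies, synth

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def whitenoise_session():
    """20 trials (60 s) of emulated passive white-noise deflection."""
    return synth.generate_session("passive_whitenoise", 20, seed=101)


@pytest.fixture(scope="session")
def active_session():
    """15 trials (45 s) of emulated active pole exploration."""
    return synth.generate_session("active_pole", 15, seed=202)


@pytest.fixture(scope="session")
def curvature_unit(whitenoise_session):
    """A strongly curvature-tuned constrained model neuron (~50 spikes/s)."""
    s = whitenoise_session
    return studies.make_constrained_unit(
        s.curvature_change_invmm, s.trial_bounds, target_rate_hz=50.0
    )


@pytest.fixture(scope="session")
def curvature_spikes(whitenoise_session, curvature_unit):
    return synth.generate_spikes_from_glm(
        curvature_unit, whitenoise_session, "curvature_change", seed=303
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
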