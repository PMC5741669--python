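import numpy as np
import pytest

from varivent.simulator import LungModel, simulate
from varivent.vtgen import VentilationPlan, generate_vt_sequence


@pytest.fixture
def plan_cv0():
    return VentilationPlan(mean_vt=6.0, cv_pct=0.0, n_breaths=5, body_mass=0.437, seed=0)


@pytest.fixture
def plan_cv30():
    return VentilationPlan(mean_vt=6.0, cv_pct=30.0, n_breaths=1200, body_mass=0.437, seed=1)


@pytest.fixture
def clean_signal(plan_cv0):
    """Noise-free single-compartment signal, 5 identical breaths."""
    seq = generate_vt_sequence(plan_cv0)
    model = LungModel(E=3.0, R=0.2, p0=3.0, noise_sd=0.0)
    return simulate(seq, model, plan_cv0, sampling_hz=1000.0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
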