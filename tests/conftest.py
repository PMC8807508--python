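import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from gestpbpk.compound import default_olanzapine, load_tissue_compositions
from gestpbpk.engine import DosingRegimen, build_model, simulate
from gestpbpk.physiology import reference_physiology
from gestpbpk.pk_metrics import nca
from gestpbpk.scenarios import trimester_comparison

settings.register_profile(
    "ci", deadline=None, derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def olz():
    return default_olanzapine()


@pytest.fixture(scope="session")
def ref_female():
    return reference_physiology("female", 30.0)


@pytest.fixture(scope="session")
def compositions():
    return load_tissue_compositions()


@pytest.fixture(scope="session")
def baseline_model(ref_female, olz):
    return build_model(ref_female, olz)


@pytest.fixture(scope="session")
def baseline_sim(baseline_model):
    """Single 10 mg oral dose in the reference adult, 240 h."""
    return simulate(baseline_model, DosingRegimen(dose=10.0), t_end=240.0)


@pytest.fixture(scope="session")
def baseline_metrics(baseline_sim):
    return nca(baseline_sim.time, baseline_sim.plasma_concentration, 10.0)


@pytest.fixture(scope="session")
def trimester_frame():
    """Steady-state trimester-vs-baseline comparison (canonical table)."""
    return trimester_comparison()



@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260929)
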