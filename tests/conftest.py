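import pytest

from amdprio.pipeline import analyze_study
from amdprio.simulate import simulate_study


@pytest.fixture(scope="session")
def study():
    """One shared synthetic study (default conditions, fixed seed)."""
    return simulate_study(seed=11)


@pytest.fixture(scope="session")
def study_results(study):
    """Full analysis of the shared study."""
    return analyze_study(study)
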