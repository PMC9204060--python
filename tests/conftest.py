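import warnings

import pytest

import cernaforge as cf
from cernaforge.pipeline import run_all

warnings.filterwarnings("ignore", category=RuntimeWarning)


@pytest.fixture(scope="session")
def small_study() -> cf.SimulatedStudy:
    """One scaled-down simulated study shared across the suite."""
    return cf.simulate(cf.GeneratorParams.small(), seed=42)


@pytest.fixture(scope="session")
def small_result():
    """The full pipeline run on the scaled-down study."""
    return run_all(cf.GeneratorParams.small(), seed=42)
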