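import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from funcfix import fixtures

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

# published kinetic parameters of the redesigned TEV variants and parent:
# variant -> (kcat min^-1, Km uM, printed kcat/Km, printed fold improvement)
TABLE1 = {
    "hyperTEV56": (0.0106, 1.4, 0.0077, 20.0),
    "hyperTEV60": (0.014, 1.4, 0.01, 26.0),
    "hyperTEV89": (0.0050, 2.0, 0.0024, 6.2),
    "TEVd": (0.0023, 6.0, 0.00039, None),
}


@pytest.fixture
def toy_structure():
    """10-residue helix with ligand atoms at 5 and 9 Å from residues 1, 2."""
    return fixtures.make_toy_structure(10, [5.0, 9.0], seed=11)


@pytest.fixture
def toy_30res():
    return fixtures.make_toy_structure(30, [4.0, 5.5, 8.0, 12.0], seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
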