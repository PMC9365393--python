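import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from cotasm.synth import ComplexSpec, InterfacePlan, generate_complex


@pytest.fixture(scope="session")
def bead_dimer():
    """Two 40-residue chains with one planned 20-residue contact window."""
    spec = ComplexSpec(
        "dimer", {"A": 40, "B": 40},
        plan=[InterfacePlan("A", "B", (5, 24), (11, 30))],
    )
    return generate_complex(spec)


@pytest.fixture(scope="session")
def bead_trimer():
    """Three chains; A:B planned twice the size of B:C, no A:C contact."""
    spec = ComplexSpec(
        "trimer", {"A": 80, "B": 80, "C": 60},
        plan=[
            InterfacePlan("A", "B", (5, 44), (5, 44), size_rank=1),
            InterfacePlan("B", "C", (50, 69), (5, 24), size_rank=2),
        ],
    )
    return generate_complex(spec)


@pytest.fixture(scope="session")
def homodimer():
    """Symmetric homodimer: both chains the same protein, mirrored window."""
    spec = ComplexSpec(
        "homo", {"A": 30, "B": 30},
        plan=[InterfacePlan("A", "B", (8, 23), (8, 23))],
        protein_ids={"A": "P_X", "B": "P_X"},
    )
    return generate_complex(spec)


@pytest.fixture()
def rng():
    """Fresh, fixed-seed generator per test: results never depend on
    which other tests ran first."""
    return np.random.default_rng(1)
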