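import numpy as np
import pytest

from slowbind import AssayDesign, KineticScheme, NoiseModel
from slowbind.reference import compound_scheme

#: 8-point 1:3 inhibitor dilution series from 1,333 nM plus the
#: uninhibited control, as in the canonical slow-binding experiment.
I_SERIES = tuple([0.0] + [1333.0 / 3**k for k in range(7, -1, -1)])


@pytest.fixture(scope="session")
def scheme10() -> KineticScheme:
    """One-step noncompetitive scheme with the compound-10 constants
    (apparent/true Ki 123 nM, koff 4.2e-3 min⁻¹)."""
    return compound_scheme("10", use_kiapp=True)


@pytest.fixture(scope="session")
def scheme11() -> KineticScheme:
    """Compound-11 constants: Ki 45 nM, koff 3.9e-3 min⁻¹."""
    return compound_scheme("11")


@pytest.fixture(scope="session")
def slow_binding_design() -> AssayDesign:
    """0.5 nM enzyme, 25 μM substrate, 2 h sampled each minute."""
    return AssayDesign(E0=0.5, S0=25.0, I_grid=I_SERIES,
                       t_grid=np.arange(0.0, 121.0, 1.0))


@pytest.fixture()
def noise2pct() -> NoiseModel:
    return NoiseModel(sigma_rel=0.02, seed=11)
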