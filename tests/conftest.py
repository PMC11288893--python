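import numpy as np
import pytest

from maturation import shifts, synth


@pytest.fixture(scope="session")
def shift_stats():
    return shifts.load_shift_statistics()


@pytest.fixture(scope="session")
def default_cars():
    """Default matured core-shell cube (shell adds the narrow 1665 line)."""
    return synth.make_cars_cube(synth.CarsConfig(seed=7))


@pytest.fixture(scope="session")
def regimeA():
    from maturation.thermo import InteractionParams, KineticParams

    return (
        InteractionParams(chi12=0.0, chi1s=3.0, chi2s=2.1),
        KineticParams(k1=0.2, k2=0.1, phi_tot=0.55),
    )


@pytest.fixture(scope="session")
def regimeB():
    from maturation.thermo import InteractionParams, KineticParams

    return (
        InteractionParams(chi12=0.0, chi1s=2.1, chi2s=3.0),
        KineticParams(k1=0.1, k2=0.05, phi_tot=0.55),
    )


@pytest.fixture(scope="session")
def sim_times():
    return np.linspace(0.0, 20.0, 41)
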