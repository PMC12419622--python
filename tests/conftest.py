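import numpy as np
import pytest

from arcmlc import (
    GridSpec,
    MachineModel,
    PhantomSpec,
    PrescriptionSpec,
    SynthDoseSpec,
    generate_phantom,
    generate_synthetic_dose,
    make_sphere_structure,
)


@pytest.fixture(scope="session")
def default_machine():
    return MachineModel()


@pytest.fixture(scope="session")
def small_machine():
    """10 leaf pairs x 5 mm covering [-25, 25] mm."""
    return MachineModel(leaf_pair_boundaries=tuple(np.linspace(-25.0, 25.0, 11)))


@pytest.fixture(scope="session")
def phantom():
    """Default synthetic phantom (GTV/ITV/PTV on a 1 mm grid)."""
    return generate_phantom()


@pytest.fixture(scope="session")
def small_target():
    """A 0.9 cc sphere on a compact 1 mm grid — cheap target for projection tests."""
    grid = GridSpec(origin=(-15.0, -15.0, -15.0), spacing=(1.0, 1.0, 1.0), shape=(31, 31, 31))
    return make_sphere_structure((0.0, 0.0, 0.0), 0.9, grid, name="ball")


@pytest.fixture(scope="session")
def prescription():
    return PrescriptionSpec(dose_per_fraction=15.0, n_fractions=3, idl_percent=50.0)


@pytest.fixture(scope="session")
def synthetic_dose(phantom):
    return generate_synthetic_dose(phantom["PTV"], SynthDoseSpec())


@pytest.fixture(scope="session")
def coarse_phantom():
    """2 mm phantom with just enough padding for D2cm — used by CLI tests."""
    return generate_phantom(PhantomSpec(spacing_mm=(2.0, 2.0, 2.0), pad_mm=24.0))
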