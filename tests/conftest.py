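import numpy as np
import pytest

from inkdose import load_reference_tables


@pytest.fixture(scope="session")
def tables():
    return load_reference_tables()


@pytest.fixture(scope="session")
def water_mat():
    from inkdose import water

    return water()


@pytest.fixture(scope="session")
def dermis(tables):
    from inkdose import skin_material

    return skin_material("reticular_dermis", tables)


@pytest.fixture(scope="session")
def brown100(tables):
    from inkdose import tattoo_mixture

    return tattoo_mixture("brown", 100, tables)


@pytest.fixture(scope="session")
def control_phantom(tables):
    from inkdose import build_phantom

    return build_phantom(tables=tables)


@pytest.fixture(scope="session")
def brown_phantom(tables, brown100):
    from inkdose import build_phantom

    return build_phantom(tattoo_material=brown100, tables=tables)


def hand_grid(values, dxy=2.0, dz=0.1):
    """DoseGrid with hand-set values and zero uncertainty (oracle tests)."""
    from inkdose import DoseGrid

    dose = np.asarray(values, dtype=float)
    nx, ny, nz = dose.shape
    xe = dxy * (np.arange(nx + 1) - nx / 2)
    ye = dxy * (np.arange(ny + 1) - ny / 2)
    ze = dz * np.arange(nz + 1)
    return DoseGrid(
        dose=dose,
        rel_uncertainty=np.zeros_like(dose),
        x_edges=xe,
        y_edges=ye,
        z_edges=ze,
        n_histories=0,
        seed=0,
        dose_medium=dose.copy(),
    )
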