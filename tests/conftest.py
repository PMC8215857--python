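import numpy as np
import pytest

import cochleanet as cn


@pytest.fixture(scope="session")
def model():
    return cn.default_model()


@pytest.fixture(scope="session")
def layout():
    return cn.default_layout()


@pytest.fixture(scope="session")
def network(model):
    return cn.assemble(model)


@pytest.fixture(scope="session")
def mode_profiles(model, layout, network):
    """SIV profiles of the classic modes at the bench stimulus (800 uA, e8)."""
    specs = {
        "MP": cn.StimulusSpec(mode="MP"),
        "BP": cn.StimulusSpec(mode="BP"),
        "TP0": cn.StimulusSpec(mode="TP", n=0),
        "TP1": cn.StimulusSpec(mode="TP", n=1),
        "TP2": cn.StimulusSpec(mode="TP", n=2),
        "pTP50": cn.StimulusSpec(mode="pTP", sigma=0.5),
    }
    return {
        name: cn.siv_profile(model, layout, spec, network=network)
        for name, spec in specs.items()
    }


# --- uniform ladder oracle -------------------------------------------------

LADDER_R_SERIES = 10.0  # ohm per 1 mm section
LADDER_R_SHUNT = 1000.0  # ohm per node
LADDER_NODES = 200


@pytest.fixture(scope="session")
def uniform_ladder():
    """200-node uniform ladder: 10 ohm series / 1 kohm shunt per 1 mm section.

    Realized as a constant-area lumen whose saline column gives exactly the
    series resistance.  Both ends are terminated with the ladder's
    characteristic impedance Z = r/2 + sqrt(r^2/4 + r R), so the finite
    ladder carries the infinite ladder's pure geometric decay with no end
    reflections — the closed-form root is then exact at every interior node.
    """
    conductivity = 1.6
    area = 1000.0 / (conductivity * LADDER_R_SERIES)  # R_seg = 1000 dx/(sigma A)
    geometry = cn.build_lumen(
        total_length=float(LADDER_NODES - 1),
        base_diameter=1.0,
        apex_diameter=1.0,
        step=1.0,
        taper_shape="table",
        area_table=np.array([[0.0, area], [float(LADDER_NODES - 1), area]]),
    )
    r, shunt = LADDER_R_SERIES, LADDER_R_SHUNT
    z_match = r / 2.0 + np.sqrt(r**2 / 4.0 + r * shunt)
    model = cn.CochleaModel(
        geometry=geometry,
        saline_conductivity=conductivity,
        transverse_resistances=np.full(LADDER_NODES, LADDER_R_SHUNT),
        basal_boundary_resistance=z_match,
        apical_boundary_resistance=z_match,
    )
    return model


def ladder_decay_root(r: float = LADDER_R_SERIES, shunt: float = LADDER_R_SHUNT) -> float:
    """Closed-form per-section decay of the infinite uniform ladder: the
    root rho < 1 of rho^2 - (2 + r/R) rho + 1 = 0."""
    b = 2.0 + r / shunt
    return (b - np.sqrt(b * b - 4.0)) / 2.0
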