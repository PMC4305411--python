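import numpy as np
import pytest

from cellcolony.core_state import (
    CellState,
    ContactSite,
    CycleParams,
    KineticParams,
    MechParams,
    Phase,
    WorldState,
)


@pytest.fixture
def kinetic():
    """Published kinetic rates of the adhesion pathway."""
    return KineticParams()


@pytest.fixture
def mech():
    """Published biomechanical cell parameters."""
    return MechParams()


@pytest.fixture
def cycle():
    return CycleParams()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def fresh_cell(cid=0, x=0.0, y=0.0, expression=100.0, radius=5.0, **kw):
    """A cell at its pathway initial condition (E = E_t, B = 100, EB = 0)."""
    return CellState(
        id=cid,
        position=(x, y),
        radius=radius,
        expression=expression,
        E=expression,
        B=100.0,
        EB=0.0,
        phase=kw.pop("phase", Phase.REST),
        **kw,
    )


@pytest.fixture
def isolated_cell():
    return fresh_cell()


@pytest.fixture
def touching_pair():
    """Two cells with the 1 µm² initial contact of the pipette assay."""
    import math

    d0 = 2.0 * math.sqrt(25.0 - 1.0 / math.pi)
    a = fresh_cell(0, 0.0, 0.0)
    b = fresh_cell(1, d0, 0.0)
    a.contacts[1] = ContactSite(partner_id=1, area=1.0, prev_area=1.0)
    b.contacts[0] = ContactSite(partner_id=0, area=1.0, prev_area=1.0)
    return WorldState(cells=[a, b])
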