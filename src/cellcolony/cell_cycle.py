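"""Stochastic cell cycle with pressure-gated division.

The cycle is G1 → REST → M.  During G1 (7 h) the radius grows linearly
from the newborn value R/2^{1/3} to the mature radius R.  REST lumps
together G0, S and G2 with a duration drawn uniformly from 8–18 h once per
cycle, giving total cycle lengths of 17–27 h.  At the REST→M boundary a
cell under compressive force above the 13 000 pN threshold is arrested
(contact inhibition of proliferation) and re-checked every step until the
pressure relaxes.  M entry replaces the mother by two daughters of radius
R/2^{1/3} placed symmetrically along the axis of highest pressure; during
the 2 h M phase the siblings form the dumb-bell and do not interact with
each other.
"""

from __future__ import annotations

import math
from typing import Optional, Tuple

import numpy as np

from .core_state import CellState, CycleParams, MechParams, ModelVariant, Phase, WorldState
from .mechanics import _pair_force

__all__ = [
    "advance_cycle",
    "divide",
    "division_axis",
    "draw_rest_duration",
    "randomize_cycle_position",
]


def draw_rest_duration(cycle: CycleParams, rng: np.random.Generator) -> float:
    return float(rng.uniform(cycle.rest_min, cycle.rest_max))


def g1_radius(mech: MechParams, cycle: CycleParams, clock: float) -> float:
    """Radius during G1: linear growth from R/2^{1/3} to R over t_g1."""
    frac = min(max(clock / cycle.t_g1, 0.0), 1.0)
    return mech.min_radius + frac * (mech.R - mech.min_radius)


def advance_cycle(
    cell: CellState,
    dt: float,
    pressure: float,
    cycle: CycleParams,
    mech: MechParams,
    rng: np.random.Generator,
    contact_inhibition: bool = False,
) -> bool:
    """Advance one cell's cycle state by ``dt`` minutes, in place.

    Returns True when the cell is ready to divide (REST completed and, if
    contact inhibition is enabled, pressure at or below the threshold).
    An over-pressured cell is flagged ``arrested`` and holds in REST; the
    check is repeated every step, so removing the pressure lets it resume.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    cell.phase_clock += dt
    if cell.phase is Phase.G1:
        if cell.phase_clock >= cycle.t_g1:
            cell.phase = Phase.REST
            cell.phase_clock -= cycle.t_g1
            cell.radius = mech.R
            cell.rest_duration = draw_rest_duration(cycle, rng)
        else:
            cell.radius = g1_radius(mech, cycle, cell.phase_clock)
        return False
    if cell.phase is Phase.REST:
        if cell.phase_clock >= cell.rest_duration:
            if contact_inhibition and pressure > mech.pressure_threshold:
                cell.arrested = True
                return False
            cell.arrested = False
            return True
        return False
    # M phase: daughters wait out t_m, then become independent G1 cells
    if cell.phase_clock >= cycle.t_m:
        cell.phase = Phase.G1
        cell.phase_clock = 0.0
        cell.sibling_id = None
    return False


def division_axis(
    cell: CellState,
    world: WorldState,
    mech: MechParams,
    rng: np.random.Generator,
    variant: ModelVariant | str = ModelVariant.MODEL2,
) -> np.ndarray:
    """Unit vector of the axis of highest pressure.

    Computed as the dominant eigenvector of the 2×2 compression tensor
    Σ_j |F_rep,j|·(û_j ⊗ û_j) over the repelling neighbours j, with û_j the
    centre-line direction.  Degenerate (isotropic or neighbour-free)
    configurations fall back to a uniformly random axis.
    """
    variant = ModelVariant.parse(variant)
    T = np.zeros((2, 2))
    total = 0.0
    for other in world.cells:
        if other.id == cell.id:
            continue
        pf = _pair_force(cell, other, variant, mech)
        if pf is None or pf.repulsion <= 0.0:
            continue
        u = np.asarray(pf.direction)
        T += pf.repulsion * np.outer(u, u)
        total += pf.repulsion
    if total <= 0.0:
        theta = rng.uniform(0.0, 2.0 * math.pi)
        return np.array([math.cos(theta), math.sin(theta)])
    w, v = np.linalg.eigh(T)
    if abs(w[1] - w[0]) <= 1e-12 * max(abs(w[1]), 1.0):
        theta = rng.uniform(0.0, 2.0 * math.pi)
        return np.array([math.cos(theta), math.sin(theta)])
    return v[:, int(np.argmax(w))]


def divide(
    cell: CellState,
    world: WorldState,
    rng: np.random.Generator,
    mech: MechParams,
    new_ids: Optional[Tuple[int, int]] = None,
    axis: Optional[np.ndarray] = None,
    variant: ModelVariant | str = ModelVariant.MODEL2,
) -> Tuple[CellState, CellState]:
    """Split a ready-to-divide mother into the two M-phase daughters.

    Daughters have radius R/2^{1/3} (their combined volume equals the
    mother's), centres at ±R/2 along the division axis, and start M with
    mutual interactions suppressed.  Pathway concentrations are intensive
    and are carried over to both daughters; junctional complexes are
    internalised at mitosis, so each daughter starts with EB + Σ EBc in its
    cytosolic complex pool and no contact compartments — conservation holds
    exactly per daughter.
    """
    if new_ids is None:
        top = max((c.id for c in world.cells), default=cell.id)
        new_ids = (top + 1, top + 2)
    if axis is None:
        axis = division_axis(cell, world, mech, rng, variant)
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.hypot(*axis)
    offset = 0.5 * mech.R
    eb_pool = cell.EB + cell.bound_total()
    daughters = []
    for ident, sign in zip(new_ids, (+1.0, -1.0)):
        daughters.append(
            CellState(
                id=ident,
                position=(
                    cell.position[0] + sign * offset * axis[0],
                    cell.position[1] + sign * offset * axis[1],
                ),
                radius=mech.min_radius,
                expression=cell.expression,
                E=cell.E,
                B=cell.B,
                EB=eb_pool,
                contacts={},
                phase=Phase.M,
                phase_clock=0.0,
                rest_duration=cell.rest_duration,
                arrested=False,
                sibling_id=None,
            )
        )
    daughters[0].sibling_id = new_ids[1]
    daughters[1].sibling_id = new_ids[0]
    return daughters[0], daughters[1]


def randomize_cycle_position(
    cell: CellState,
    cycle: CycleParams,
    mech: MechParams,
    rng: np.random.Generator,
) -> CellState:
    """Place a cell at a uniformly random point of its division cycle.

    Used for the founder cell of a colony run: the cycle position at seeding
    time is unknown, so age is drawn uniformly over one full cycle (with the
    rest duration drawn first).  M-phase ages are folded into late REST —
    a founder has no sibling to pair with.
    """
    cell.rest_duration = draw_rest_duration(cycle, rng)
    total = cycle.t_g1 + cell.rest_duration
    age = rng.uniform(0.0, total)
    if age < cycle.t_g1:
        cell.phase = Phase.G1
        cell.phase_clock = age
        cell.radius = g1_radius(mech, cycle, age)
    else:
        cell.phase = Phase.REST
        cell.phase_clock = age - cycle.t_g1
        cell.radius = mech.R
    return cell
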