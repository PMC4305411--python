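"""Hertz contact mechanics, bond-to-force maps and overdamped motion.

Repulsion between two compressed elastic spheres follows the Hertz model;
adhesion is obtained by translating the bound E-cadherin–β-catenin complex
level of a contact into a force through the dual-pipette calibration anchor
(210 nN).  The limiting side of a bond is the cell presenting fewer
complexes at the shared site.  Cells move overdamped: velocity equals net
force divided by the Stokes drag 6πηR, optionally with zero-mean positional
noise.  The "pressure" a cell experiences is the scalar sum of the
magnitudes of all repulsive forces acting on it — six hexagonal neighbours
at 8.5 µm spacing yield ≈13 000 pN with the default parameters, the
contact-inhibition threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

from .core_state import (
    CellState,
    MechParams,
    ModelVariant,
    Phase,
    SEPARATION_FORCE_PN,
    WorldState,
    natural_state_distance,
)

__all__ = [
    "PairForce",
    "hertz_force",
    "hertz_potential",
    "adhesion_force",
    "net_force_and_pressure",
    "motion_step",
    "DEFAULT_DISPLACEMENT_CAP",
]

#: Maximum displacement per mechanics sub-step, µm (explicit-Euler stability).
DEFAULT_DISPLACEMENT_CAP = 0.05

#: Width (µm) of the linear engagement ramp of the separation-force rule.
#: The rule "no adhesion at or inside the natural state" is discontinuous in
#: distance; ramping the force on over this thin band regularises it so that
#: a bound pair has a stable rest distance just outside the natural state
#: instead of chattering across the jump.  The band is far below the contact
#: geometry scale and well inside the positional noise amplitude.
NATURAL_STATE_RAMP_UM = 0.1

_COINCIDENT_EPS = 1e-9


@dataclass
class PairForce:
    """Force components of one interacting pair, resolved for cell i.

    ``direction`` points from j to i; the force on j is the exact negative
    (Newton's third law).  Both magnitudes are non-negative: ``repulsion``
    pushes the pair apart, ``adhesion`` pulls it together.
    """

    repulsion: float
    adhesion: float
    direction: Tuple[float, float]

    @property
    def net_on_i(self) -> Tuple[float, float]:
        f = self.repulsion - self.adhesion
        return (f * self.direction[0], f * self.direction[1])


def _hertz_prefactor(R_i, R_j, sigma_i, sigma_j, E_i, E_j) -> float:
    compliance = 0.75 * ((1.0 - sigma_i**2) / E_i + (1.0 - sigma_j**2) / E_j)
    return math.sqrt(R_i * R_j / (R_i + R_j)) / compliance


def hertz_force(
    d: float,
    R_i: float,
    R_j: float,
    sigma_i: float = 1.0 / 3.0,
    sigma_j: float = 1.0 / 3.0,
    E_i: float = 1000.0,
    E_j: float = 1000.0,
) -> float:
    """Hertz repulsive force between two spheres, pN.

    F = h^{3/2}·sqrt(R_iR_j/(R_i+R_j)) / [¾((1−σ_i²)/E_i + (1−σ_j²)/E_j)]
    with overlap h = max(0, R_i + R_j − d); zero without overlap and
    strictly increasing with the overlap.
    """
    if d < 0:
        raise ValueError("centre distance must be non-negative")
    h = R_i + R_j - d
    if h <= 0.0:
        return 0.0
    return h**1.5 * _hertz_prefactor(R_i, R_j, sigma_i, sigma_j, E_i, E_j)


def hertz_potential(
    d: float,
    R_i: float,
    R_j: float,
    sigma_i: float = 1.0 / 3.0,
    sigma_j: float = 1.0 / 3.0,
    E_i: float = 1000.0,
    E_j: float = 1000.0,
) -> float:
    """Hertz elastic potential V(d) in pN·µm, with F = −dV/dd."""
    h = R_i + R_j - d
    if h <= 0.0:
        return 0.0
    return 0.4 * h**2.5 * _hertz_prefactor(R_i, R_j, sigma_i, sigma_j, E_i, E_j)


def adhesion_force(
    variant: ModelVariant | str,
    pct_self: float,
    pct_partner: float,
    d: float = 0.0,
    R_i: float = 5.0,
    R_j: float = 5.0,
) -> float:
    """Adhesive/separation force of a bond, pN.

    The effective bond level is m = min(pct_self, pct_partner): the cell
    presenting fewer complexes limits how many trans-bonds can form.  The
    linear maps are anchored at the measured 210 nN separation force —
    m = 15% for Model 1, m = 80% for Models 2/3 — and extrapolate linearly
    beyond the anchor.  Model 3 additionally returns 0 for pairs at or
    inside their natural state (bonds resist separation but do not pull
    cells closer than a monolayer packs them).
    """
    variant = ModelVariant.parse(variant)
    if pct_self < 0 or pct_partner < 0:
        raise ValueError("bond percentages must be non-negative")
    m = min(pct_self, pct_partner)
    force = m / variant.anchor_pct * SEPARATION_FORCE_PN
    if variant is ModelVariant.MODEL3:
        gap = d - natural_state_distance(R_i, R_j)
        force *= min(max(gap / NATURAL_STATE_RAMP_UM, 0.0), 1.0)
    return force


def _pair_force(
    cell: CellState, other: CellState, variant: ModelVariant, mech: MechParams
) -> Optional[PairForce]:
    dx = cell.position[0] - other.position[0]
    dy = cell.position[1] - other.position[1]
    d = math.hypot(dx, dy)
    if d < _COINCIDENT_EPS:
        return None  # coincident centres: direction undefined, no force
    rep = 0.0
    if d < cell.radius + other.radius:
        rep = hertz_force(
            d,
            cell.radius,
            other.radius,
            mech.sigma,
            mech.sigma,
            mech.E_mod,
            mech.E_mod,
        )
    adh = 0.0
    site = cell.contacts.get(other.id)
    back = other.contacts.get(cell.id)
    if site is not None and back is not None:
        adh = adhesion_force(
            variant, site.EBc, back.EBc, d, cell.radius, other.radius
        )
    if rep == 0.0 and adh == 0.0:
        return None
    return PairForce(rep, adh, (dx / d, dy / d))


def net_force_and_pressure(
    cell: CellState,
    world: WorldState,
    variant: ModelVariant | str,
    mech: MechParams,
) -> Tuple[np.ndarray, float]:
    """Net force 2-vector (pN) and pressure (pN) on one cell.

    The pressure is the scalar sum of repulsive-force magnitudes — the
    quantity compared against the 13 000 pN contact-inhibition threshold.
    The sibling pair is skipped while both daughters are in M phase
    (dumb-bell: the two halves do not interact).
    """
    variant = ModelVariant.parse(variant)
    force = np.zeros(2)
    pressure = 0.0
    for other in world.cells:
        if other.id == cell.id:
            continue
        if (
            cell.phase is Phase.M
            and other.phase is Phase.M
            and cell.sibling_id == other.id
        ):
            continue
        pf = _pair_force(cell, other, variant, mech)
        if pf is None:
            continue
        force += np.asarray(pf.net_on_i)
        pressure += pf.repulsion
    return force, pressure


def motion_step(
    world: WorldState,
    dt: float,
    variant: ModelVariant | str = ModelVariant.MODEL2,
    mech: MechParams | None = None,
    rng: Optional[np.random.Generator] = None,
    displacement_cap: float = DEFAULT_DISPLACEMENT_CAP,
) -> WorldState:
    """Advance all positions by ``dt`` minutes of overdamped motion.

    x_j ← x_j + Δt·(ΣF_ij + noise)/(6πηR_j), sub-stepped so no cell moves
    further than ``displacement_cap`` per sub-step.  Noise enters as an
    uncorrelated zero-mean displacement of variance 2·D·Δt per axis
    (D = ``mech.noise_diffusion``).  This is the straightforward reference
    implementation used for small worlds and as an oracle for the engine's
    vectorised integrator.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    mech = mech or MechParams()
    variant = ModelVariant.parse(variant)
    if mech.noise_diffusion > 0 and rng is None:
        rng = np.random.default_rng(world.rng_seed)

    remaining = dt
    while remaining > 1e-12:
        forces = []
        vmax = 0.0
        for cell in world.cells:
            f, _ = net_force_and_pressure(cell, world, variant, mech)
            drag = 6.0 * math.pi * (mech.eta / 60.0) * cell.radius
            v = f / drag
            forces.append(v)
            vmax = max(vmax, float(np.hypot(*v)))
        sub = remaining if vmax == 0.0 else min(remaining, displacement_cap / vmax)
        for cell, v in zip(world.cells, forces):
            dxy = v * sub
            if mech.noise_diffusion > 0:
                dxy = dxy + rng.normal(
                    0.0, math.sqrt(2.0 * mech.noise_diffusion * sub), size=2
                )
            cell.position = (cell.position[0] + dxy[0], cell.position[1] + dxy[1])
        remaining -= sub
    return world
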