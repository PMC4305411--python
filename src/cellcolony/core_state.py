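"""Domain types, unit conventions and sphere-contact geometry.

Canonical internal units throughout the package:

* length        micrometre (µm)
* time          minute (min)
* force         piconewton (pN)
* elastic moduli / pressures  Pa (1 Pa = 1 pN/µm², so values carry over)
* concentrations  percent of the maximal number of E-cadherin–β-catenin
  complexes a cell can form (100 = every β-catenin molecule bound)

Cells live in a two-dimensional monolayer plane but are treated as 3-D
elastic spheres for contact areas, surface areas and volumes.  The contact
area between two overlapping spheres is the disc bounded by their circle of
intersection (the "lens" circle).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional

__all__ = [
    "MechParams",
    "KineticParams",
    "CycleParams",
    "ContactSite",
    "CellState",
    "ModelVariant",
    "WorldState",
    "Phase",
    "contact_geometry",
    "natural_state_distance",
    "sphere_surface_area",
    "SEPARATION_FORCE_PN",
    "MODEL1_ANCHOR_PCT",
    "MODEL2_ANCHOR_PCT",
]

#: Dual-pipette separation force of a mature two-cell bond, in pN (210 nN).
SEPARATION_FORCE_PN = 210_000.0
#: Bound-complex percentage that produces :data:`SEPARATION_FORCE_PN` in the
#: static-adhesion model (Model 1).
MODEL1_ANCHOR_PCT = 15.0
#: Bound-complex percentage that produces :data:`SEPARATION_FORCE_PN` in the
#: dynamic-adhesion models (Models 2 and 3).
MODEL2_ANCHOR_PCT = 80.0


class ModelVariant(enum.Enum):
    """The three adhesion-model variants.

    MODEL1   static adhesion: per-site exocytosis capped at E_t/6.
    MODEL2   dynamic adhesion: global cap 0.8·E_t plus inter-site
             redistribution of bound complexes.
    MODEL3   MODEL2 kinetics combined with the separation-force rule: the
             adhesive force vanishes for cells at or inside their natural
             state; only the Hertz repulsion acts there.
    """

    MODEL1 = "model1"
    MODEL2 = "model2"
    MODEL3 = "model3"

    @classmethod
    def parse(cls, value: "ModelVariant | str") -> "ModelVariant":
        if isinstance(value, cls):
            return value
        try:
            return cls(str(value).lower())
        except ValueError as exc:
            raise ValueError(f"unknown model variant: {value!r}") from exc

    @property
    def anchor_pct(self) -> float:
        """Bound-complex percentage mapped onto 210 nN by this variant."""
        return MODEL1_ANCHOR_PCT if self is ModelVariant.MODEL1 else MODEL2_ANCHOR_PCT

    @property
    def uses_redistribution(self) -> bool:
        return self is not ModelVariant.MODEL1


class Phase(enum.Enum):
    """Cell-cycle phase.  REST lumps together G0, S and G2."""

    G1 = "G1"
    REST = "REST"
    M = "M"


@dataclass
class MechParams:
    """Biomechanical cell parameters.

    Parameters
    ----------
    R : float
        Maximum cell radius in µm.
    sigma : float
        Poisson ratio of the cell (dimensionless, < 0.5).
    E_mod : float
        Elastic modulus in Pa (numerically equal to pN/µm²).
    eta : float
        Viscosity of the suspension medium in Pa·s (10² Poise = 10 Pa·s).
    noise_diffusion : float
        Effective diffusion coefficient of the zero-mean positional noise,
        µm²/min.  0 disables noise.  (The underlying stochastic force is
        uncorrelated with zero mean; parameterising its strength as a
        diffusivity keeps trajectories independent of the integration step.)
    pressure_threshold : float
        Compressive-force threshold for cell-cycle arrest, pN.
    """

    R: float = 5.0
    sigma: float = 1.0 / 3.0
    E_mod: float = 1000.0
    eta: float = 10.0
    noise_diffusion: float = 0.0
    pressure_threshold: float = 13_000.0

    def __post_init__(self) -> None:
        if not self.R > 0:
            raise ValueError("R must be positive")
        if not 0.0 <= self.sigma < 0.5:
            raise ValueError("Poisson ratio must lie in [0, 0.5)")
        if not self.E_mod > 0:
            raise ValueError("elastic modulus must be positive")
        if not self.eta > 0:
            raise ValueError("viscosity must be positive")
        if self.noise_diffusion < 0:
            raise ValueError("noise diffusivity must be non-negative")

    @property
    def drag_pN_min_per_um(self) -> float:
        """Stokes drag coefficient 6πηR in pN·min/µm."""
        # eta [Pa·s] == [pN·s/µm²]; divide by 60 to convert seconds to minutes
        return 6.0 * math.pi * (self.eta / 60.0) * self.R

    @property
    def min_radius(self) -> float:
        """Newborn radius R/2^{1/3} (two daughters conserve the volume)."""
        return self.R / 2.0 ** (1.0 / 3.0)


@dataclass
class KineticParams:
    """Rates of the compartmentalised E-cadherin–β-catenin model (min⁻¹).

    ``nu_p`` is per-percent per minute (mass-action binding of free
    E-cadherin and β-catenin); all others are plain first-order rates.
    """

    rho_u: float = 8.2  #: undirected complex translocation rate
    nu_n: float = 0.6  #: complex dissociation rate
    nu_p: float = 0.02  #: complex binding rate, %⁻¹·min⁻¹
    rho_c: float = 0.6  #: directed complex translocation rate
    gamma: float = 0.16  #: inter-site redistribution rate
    rho_d: float = 0.6  #: endocytosis rate after junction disassembly

    def __post_init__(self) -> None:
        for name in ("rho_u", "nu_n", "nu_p", "rho_c", "gamma", "rho_d"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass
class CycleParams:
    """Cell-cycle timing constants (minutes).

    G1 lasts ``t_g1`` with uniform radial growth, the lumped G0/S/G2 rest
    phase is drawn uniformly from ``[rest_min, rest_max]`` once per cycle,
    and M lasts ``t_m`` with the two daughters mutually non-interacting
    (the dumb-bell).  Total cycle length is therefore 17–27 h.
    """

    t_g1: float = 7.0 * 60.0
    t_m: float = 2.0 * 60.0
    rest_min: float = 8.0 * 60.0
    rest_max: float = 18.0 * 60.0

    def __post_init__(self) -> None:
        if not (0 < self.t_g1 and 0 < self.t_m):
            raise ValueError("phase durations must be positive")
        if not 0 <= self.rest_min <= self.rest_max:
            raise ValueError("rest duration range is invalid")

    @property
    def mean_cycle_length(self) -> float:
        return self.t_g1 + self.t_m + 0.5 * (self.rest_min + self.rest_max)


@dataclass
class ContactSite:
    """Per-neighbour intracellular compartment of one cell.

    ``EBc`` is the concentration of bound E-cadherin–β-catenin complexes the
    owning cell presents at this contact, in % of its maximal complex count.
    ``prev_area`` is the contact area recorded at the previous bookkeeping
    step; the relative change between the two drives directed exocytosis and
    disassembly endocytosis.  A site survives full detachment (area 0) while
    its compartment drains back into the cytosolic pool.
    """

    partner_id: int
    area: float = 0.0
    prev_area: float = 0.0
    EBc: float = 0.0

    def __post_init__(self) -> None:
        if self.area < 0 or self.prev_area < 0 or self.EBc < 0:
            raise ValueError("contact-site quantities must be non-negative")


@dataclass
class CellState:
    """Full state of one cell.

    Pathway pools satisfy two conservation laws at all times::

        E + EB + Σ_i EBc_i == expression      (E-cadherin)
        B + EB + Σ_i EBc_i == 100             (β-catenin)

    ``expression`` is the cell's E-cadherin expression level E_t in %.
    """

    id: int
    position: tuple[float, float] = (0.0, 0.0)
    radius: float = 5.0
    expression: float = 100.0
    E: float = 100.0
    B: float = 100.0
    EB: float = 0.0
    contacts: Dict[int, ContactSite] = field(default_factory=dict)
    phase: Phase = Phase.G1
    phase_clock: float = 0.0
    rest_duration: float = 13.0 * 60.0
    arrested: bool = False
    sibling_id: Optional[int] = None

    def bound_total(self) -> float:
        """Total complexes bound at contact sites, Σ_i EBc_i."""
        return sum(s.EBc for s in self.contacts.values())

    def conservation_residuals(self) -> tuple[float, float]:
        """(E-cadherin, β-catenin) conservation residuals; 0 when exact."""
        bound = self.bound_total()
        return (
            self.E + self.EB + bound - self.expression,
            self.B + self.EB + bound - 100.0,
        )

    def check_conservation(self, tol: float = 1e-6) -> None:
        re_, rb = self.conservation_residuals()
        if abs(re_) > tol or abs(rb) > tol:
            raise ValueError(
                f"cell {self.id}: conservation violated (E residual {re_:.3g}, "
                f"β residual {rb:.3g})"
            )

    def copy(self) -> "CellState":
        new = replace(self)
        new.contacts = {k: replace(v) for k, v in self.contacts.items()}
        return new


@dataclass
class WorldState:
    """Collection of cells at one instant (artifact plumbing)."""

    cells: List[CellState] = field(default_factory=list)
    time: float = 0.0
    rng_seed: int = 0
    status: str = "running"

    def __post_init__(self) -> None:
        ids = [c.id for c in self.cells]
        if len(ids) != len(set(ids)):
            raise ValueError("cell ids must be unique")

    def cell_by_id(self, cell_id: int) -> CellState:
        for c in self.cells:
            if c.id == cell_id:
                return c
        raise KeyError(cell_id)


def sphere_surface_area(radius: float) -> float:
    """Surface area 4πR² of the spherical cell, µm²."""
    return 4.0 * math.pi * radius * radius


def contact_geometry(d: float, R_i: float, R_j: float) -> tuple[float, float, float]:
    """Sphere–sphere contact geometry.

    Parameters
    ----------
    d : float
        Centre-to-centre distance, µm (>= 0).
    R_i, R_j : float
        Sphere radii, µm (> 0).

    Returns
    -------
    (overlap, contact_radius, contact_area)
        ``overlap`` is h = max(0, R_i + R_j − d); ``contact_radius`` is the
        radius of the circle in which the two sphere surfaces intersect and
        ``contact_area`` the area of the disc it bounds.  All three are zero
        for non-overlapping spheres.  When one sphere is engulfed by the
        other (d <= |R_i − R_j|) the contact disc saturates at the smaller
        sphere's great circle.
    """
    if d < 0:
        raise ValueError("centre distance must be non-negative")
    if R_i <= 0 or R_j <= 0:
        raise ValueError("radii must be positive")
    overlap = R_i + R_j - d
    if overlap <= 0:
        return 0.0, 0.0, 0.0
    overlap = min(overlap, R_i + R_j)
    r_small = min(R_i, R_j)
    if d <= abs(R_i - R_j):
        a = r_small
    else:
        # circle of intersection of two spheres at centre distance d
        a_sq = (4.0 * d * d * R_i * R_i - (d * d - R_j * R_j + R_i * R_i) ** 2) / (
            4.0 * d * d
        )
        a = math.sqrt(max(a_sq, 0.0))
        a = min(a, r_small)
    return overlap, a, math.pi * a * a


def natural_state_distance(R_i: float, R_j: Optional[float] = None) -> float:
    """Centre distance of the "natural state" of two adjacent cells, µm.

    At the natural state the diameter of the contact circle equals one sixth
    of the cell circumference, 2a* = 2πR/6.  For equal spheres this gives
    d* = 2·sqrt(R² − (πR/6)²) ≈ 1.70·R (8.52 µm at R = 5 µm, matching the
    ≈8.5 µm centre spacing of a hexagonally packed monolayer).  For unequal
    radii the target contact radius uses the mean radius and the distance is
    the sum of the two centre-to-chord distances.
    """
    if R_j is None:
        R_j = R_i
    if R_i <= 0 or R_j <= 0:
        raise ValueError("radii must be positive")
    a_star = math.pi * (R_i + R_j) / 12.0
    a_star = min(a_star, min(R_i, R_j))
    return math.sqrt(R_i * R_i - a_star * a_star) + math.sqrt(
        R_j * R_j - a_star * a_star
    )
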