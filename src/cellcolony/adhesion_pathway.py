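"""Compartmentalised E-cadherin–β-catenin kinetics of a single cell.

Each cell carries a cytosolic pool of free E-cadherin ``E``, free β-catenin
``B`` and non-junctional complexes ``EB``, plus one compartment ``EBc_i``
per cell–cell contact site.  Complexes form and dissociate by mass action
(ν_p, ν_n), are exocytosed to contact sites (directed ρ_c, undirected ρ_u),
are endocytosed when a junction disassembles (ρ_d) and — in the dynamic
adhesion models — are redistributed between contact sites (γ).

Transport driven by contact-area change uses the dimensionless relative
area-change factors a_c (gain) and a_d (loss), both clamped to [0, 1].  In
the continuous-time model they are the relative area-change rates
min(±d(ln A)/dt, 1): transport engages in proportion to how fast a
junction grows or shrinks, saturating at unit relative rate — so the rate
constants keep units of min⁻¹, trajectories converge under step halving,
and a fully detached site (a_d = 1) drains as dEBc/dt = −ρ_d·EBc until its
compartment is exhausted.  Discretely, the factor consumed over one
bookkeeping step is min(relative area change, dt·1 min⁻¹).

Two exocytosis hypotheses are implemented:

* Model 1 (static adhesion): each site individually saturates at
  τ_E = E_t/6, so a cell can always serve six neighbours.
* Model 2 (dynamic adhesion): sites share a global budget of 0.8·E_t;
  a single contact may therefore bind almost all available complexes and
  the redistribution terms equalise sites when new neighbours arrive.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

from .core_state import (
    CellState,
    ContactSite,
    KineticParams,
    ModelVariant,
    sphere_surface_area,
)

__all__ = [
    "PathwayFluxes",
    "MODEL2_SATURATION_FRACTION",
    "tau_E",
    "area_change_factors",
    "exocytosis_model1",
    "exocytosis_model2",
    "redistribution",
    "pathway_rhs",
    "step_pathway",
    "DRAINED_SITE_EPS",
]

#: Fraction of the expression level that can be junction-bound in Model 2/3.
MODEL2_SATURATION_FRACTION = 0.8

#: Sites whose compartment has drained below this level (in %) are deleted.
DRAINED_SITE_EPS = 1e-6

_AREA_EPS = 1e-12


@dataclass
class PathwayFluxes:
    """Per-site flux bookkeeping (all in %·min⁻¹ except the area factors)."""

    c: float = 0.0  #: exocytosis into the site
    d: float = 0.0  #: endocytosis out of the site
    r_in: float = 0.0  #: redistribution inflow
    r_out: float = 0.0  #: redistribution outflow
    a_c: float = 0.0  #: relative contact-area gain (dimensionless)
    a_d: float = 0.0  #: relative contact-area loss (dimensionless)


def tau_E(expression: float) -> float:
    """Model 1 per-site cap τ_E = E_t/6 (max complexes per effective bond)."""
    return expression / 6.0


def area_change_factors(site: ContactSite) -> Tuple[float, float]:
    """Relative contact-area gain/loss factors (a_c, a_d), both in [0, 1].

    a_c normalises growth by the current area, a_d shrinkage by the previous
    area, so complete disassembly (area 0 from any positive previous area)
    yields a_d = 1.
    """
    area, prev = site.area, site.prev_area
    a_c = max(0.0, (area - prev) / max(area, _AREA_EPS))
    a_d = max(0.0, (prev - area) / max(prev, _AREA_EPS))
    return min(a_c, 1.0), min(a_d, 1.0)


def _saturation_model1(cell: CellState, site_EBc: float) -> float:
    cap = tau_E(cell.expression)
    if cap <= 0.0:
        return 0.0
    return max(0.0, 1.0 - site_EBc / cap)


def _saturation_model2(cell: CellState, bound_total: Optional[float] = None) -> float:
    cap = MODEL2_SATURATION_FRACTION * cell.expression
    if cap <= 0.0:
        return 0.0
    total = cell.bound_total() if bound_total is None else bound_total
    return max(0.0, 1.0 - total / cap)


def exocytosis_model1(
    cell: CellState, site: ContactSite, a_c: float, params: KineticParams
) -> float:
    """Model 1 exocytosis flux into one site, %·min⁻¹.

    Directed transport ρ_c·EB·a_c plus undirected transport proportional to
    the site's share of the cell surface, both saturating as the site
    approaches its cap τ_E = E_t/6.
    """
    sat = _saturation_model1(cell, site.EBc)
    undirected = params.rho_u * cell.EB * site.area / sphere_surface_area(cell.radius)
    return (params.rho_c * cell.EB * a_c + undirected) * sat


def exocytosis_model2(
    cell: CellState, site: ContactSite, a_c: float, params: KineticParams
) -> float:
    """Model 2 exocytosis flux into one site, %·min⁻¹.

    Same transport structure as Model 1 but the saturation bound is global:
    the junction-bound total Σ_j EBc_j may approach 0.8·E_t.
    """
    sat = _saturation_model2(cell)
    undirected = params.rho_u * cell.EB * site.area / sphere_surface_area(cell.radius)
    return (params.rho_c * cell.EB * a_c + undirected) * sat


def redistribution(
    site_EBc: Sequence[float], gamma: float
) -> Tuple[Tuple[float, ...], Tuple[float, ...]]:
    """Inter-site redistribution fluxes (r_in_i, r_out_i), %·min⁻¹.

    r_in_i = γ·Σ_{j≠i} max(0, EBc_j − EBc_i) and symmetrically for r_out_i;
    only positive bracket terms contribute, and Σ r_in = Σ r_out exactly.
    """
    if gamma < 0:
        raise ValueError("gamma must be non-negative")
    n = len(site_EBc)
    r_in = [0.0] * n
    r_out = [0.0] * n
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            diff = site_EBc[j] - site_EBc[i]
            if diff > 0.0:
                r_in[i] += gamma * diff
            else:
                r_out[i] += gamma * (-diff)
    return tuple(r_in), tuple(r_out)


def _site_area_rates(
    cell: CellState, area_rates: Optional[Dict[int, Tuple[float, float]]]
) -> Dict[int, Tuple[float, float]]:
    """Resolve per-site (a_c, a_d) rates for a derivative evaluation.

    Without explicit rates, attached sites are taken as static (area change
    contributes nothing to the instantaneous derivative) while detached
    sites drain at a_d = 1, i.e. dEBc/dt = −ρ_d·EBc.
    """
    rates: Dict[int, Tuple[float, float]] = {}
    for pid, site in cell.contacts.items():
        if area_rates is not None and pid in area_rates:
            rates[pid] = area_rates[pid]
        elif site.area <= 0.0:
            rates[pid] = (0.0, 1.0)
        else:
            rates[pid] = (0.0, 0.0)
    return rates


def pathway_rhs(
    cell: CellState,
    variant: ModelVariant | str,
    params: KineticParams,
    area_rates: Optional[Dict[int, Tuple[float, float]]] = None,
) -> Tuple[float, float, float, Dict[int, float]]:
    """Time derivatives (dE/dt, dB/dt, dEB/dt, {partner: dEBc/dt}).

    ``area_rates`` optionally supplies instantaneous per-minute relative
    area-change rates (a_c, a_d) per partner; see :func:`_site_area_rates`
    for the defaults.  The sum of all E-carrying derivatives is zero by
    construction, and likewise for β-catenin.
    """
    variant = ModelVariant.parse(variant)
    if min(cell.E, cell.B, cell.EB) < 0 or any(
        s.EBc < 0 for s in cell.contacts.values()
    ):
        raise ValueError("negative concentration in pathway state")
    rates = _site_area_rates(cell, area_rates)

    bind = params.nu_p * cell.E * cell.B
    dissoc = params.nu_n * cell.EB

    exo = exocytosis_model1 if variant is ModelVariant.MODEL1 else exocytosis_model2
    c_flux: Dict[int, float] = {}
    d_flux: Dict[int, float] = {}
    for pid, site in cell.contacts.items():
        a_c, a_d = rates[pid]
        c_flux[pid] = exo(cell, site, a_c, params)
        d_flux[pid] = params.rho_d * a_d * site.EBc

    pids = list(cell.contacts)
    if variant.uses_redistribution and len(pids) > 1:
        r_in, r_out = redistribution(
            [cell.contacts[p].EBc for p in pids], params.gamma
        )
    else:
        r_in = r_out = tuple(0.0 for _ in pids)

    dEBc = {
        pid: c_flux[pid] - d_flux[pid] + r_in[k] - r_out[k]
        for k, pid in enumerate(pids)
    }
    dEB = bind - dissoc - sum(c_flux.values()) + sum(d_flux.values())
    dE = -bind + dissoc
    dB = -bind + dissoc
    return dE, dB, dEB, dEBc


def step_pathway(
    cell: CellState,
    dt: float,
    variant: ModelVariant | str,
    params: KineticParams,
) -> CellState:
    """Advance one cell's pathway state by ``dt`` minutes (forward Euler).

    The relative area changes stored on the contact sites (area vs
    prev_area) are consumed exactly once: after the step every site's
    prev_area is reset to its current area.  The update sub-steps adaptively
    so that no pool is overdrawn by more than half per sub-step, and any
    residual overdraw is clipped with the clipped mass returned to the donor
    pool — conservation is exact to round-off.  Drained detached sites
    (EBc < 1e-6, area 0) are removed, their remainder returned to ``EB``.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    variant = ModelVariant.parse(variant)
    new = cell.copy()

    pids = list(new.contacts)
    factors = {pid: area_change_factors(new.contacts[pid]) for pid in pids}
    detached = {pid for pid in pids if new.contacts[pid].area <= 0.0}

    # choose sub-step count so first-order outflow fractions stay below 1/2
    max_out = params.nu_p * max(new.E, new.B) * dt
    max_out = max(max_out, params.nu_n * dt)
    for pid in pids:
        a_c, a_d = factors[pid]
        max_out = max(max_out, params.rho_d * (dt if pid in detached else min(a_d, dt)))
        max_out = max(max_out, params.rho_c * min(a_c, dt) + params.rho_u * dt)
        if variant.uses_redistribution:
            max_out = max(max_out, params.gamma * dt * max(1, len(pids) - 1) * 100.0)
    n_sub = 1
    while max_out / n_sub > 0.5 and n_sub < 1 << 16:
        n_sub *= 2
    h = dt / n_sub

    surface = sphere_surface_area(new.radius)
    exo_m1 = variant is ModelVariant.MODEL1
    cap_m1 = tau_E(new.expression)
    cap_m2 = MODEL2_SATURATION_FRACTION * new.expression

    for _ in range(n_sub):
        sites = {pid: new.contacts[pid].EBc for pid in pids}
        bound = sum(sites.values())

        # per-substep transferred masses (in %)
        m_bind = params.nu_p * new.E * new.B * h
        m_bind = min(m_bind, new.E, new.B)
        m_dissoc = params.nu_n * new.EB * h

        m_c: Dict[int, float] = {}
        m_d: Dict[int, float] = {}
        for pid in pids:
            site = new.contacts[pid]
            a_c, a_d = factors[pid]
            if exo_m1:
                sat = max(0.0, 1.0 - sites[pid] / cap_m1) if cap_m1 > 0 else 0.0
            else:
                sat = max(0.0, 1.0 - bound / cap_m2) if cap_m2 > 0 else 0.0
            directed = params.rho_c * new.EB * (min(a_c, dt) / n_sub)
            undirected = params.rho_u * new.EB * (site.area / surface) * h
            m_c[pid] = (directed + undirected) * sat
            if pid in detached:
                m_d[pid] = params.rho_d * sites[pid] * h
            else:
                m_d[pid] = params.rho_d * sites[pid] * (min(a_d, dt) / n_sub)

        if variant.uses_redistribution and len(pids) > 1:
            r_in, r_out = redistribution([sites[p] for p in pids], params.gamma)
            m_rin = {pid: r_in[k] * h for k, pid in enumerate(pids)}
            m_rout = {pid: r_out[k] * h for k, pid in enumerate(pids)}
        else:
            m_rin = {pid: 0.0 for pid in pids}
            m_rout = {pid: 0.0 for pid in pids}

        # clip outflows to the donor pools (scale proportionally)
        eb_out = m_dissoc + sum(m_c.values())
        if eb_out > new.EB > 0.0:
            scale = new.EB / eb_out
            m_dissoc *= scale
            for pid in pids:
                m_c[pid] *= scale
        elif new.EB <= 0.0:
            m_dissoc = 0.0
            m_c = {pid: 0.0 for pid in pids}
        for pid in pids:
            out = m_d[pid] + m_rout[pid]
            avail = sites[pid]
            if out > avail:
                scale = avail / out if out > 0 else 0.0
                m_d[pid] *= scale
                # redistribution outflow feeds other sites' inflow: rescale
                # the matching inflows to keep Σ r_in == Σ r_out exact
                deficit = m_rout[pid] * (1.0 - scale)
                m_rout[pid] *= scale
                total_in = sum(m_rin.values())
                if total_in > 0 and deficit > 0:
                    corr = max(0.0, 1.0 - deficit / total_in)
                    for q in pids:
                        m_rin[q] *= corr

        new.E += -m_bind + m_dissoc
        new.B += -m_bind + m_dissoc
        new.EB += m_bind - m_dissoc - sum(m_c.values()) + sum(m_d.values())
        for pid in pids:
            new.contacts[pid].EBc += m_c[pid] - m_d[pid] + m_rin[pid] - m_rout[pid]
            if new.contacts[pid].EBc < 0.0:
                new.EB += new.contacts[pid].EBc
                new.contacts[pid].EBc = 0.0

    # bookkeeping: area deltas are consumed; drained detached sites removed
    for pid in pids:
        site = new.contacts[pid]
        site.prev_area = site.area
        if site.area <= 0.0 and site.EBc < DRAINED_SITE_EPS:
            new.EB += site.EBc
            del new.contacts[pid]
    return new
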