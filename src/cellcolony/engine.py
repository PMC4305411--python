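"""Simulation engine: contact bookkeeping, operator-split stepping, runs.

One engine step of length ``dt_pathway`` executes, in order:

1. arrival injection (scheduled cells entering the assay),
2. contact bookkeeping (symmetric creation/update/draining of contact
   sites from the sphere-overlap geometry),
3. one forward-Euler pathway update for every cell,
4. overdamped mechanics sub-stepped over the pathway step with a
   displacement cap,
5. cell-cycle advancement including divisions and contact inhibition,
6. collapse detection (centres closer than a fraction of the summed radii
   mean cells can no longer be identified individually; the run halts).

The engine keeps a structure-of-arrays mirror of the world (positions,
pathway pools, and N×N contact matrices) and calls a jit-compiled kernel
for the mechanics inner loop; :class:`~cellcolony.core_state.WorldState`
snapshots are materialised on demand.  Runs are exactly reproducible for a
given (config, seed).
"""

from __future__ import annotations

import math
import time as _time
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from . import adhesion_pathway as _ap
from ._speedups import colony_step_kernel, seed_kernel_rng
from .core_state import (
    CellState,
    ContactSite,
    CycleParams,
    KineticParams,
    MechParams,
    ModelVariant,
    Phase,
    SEPARATION_FORCE_PN,
    WorldState,
    natural_state_distance,
)

__all__ = [
    "Arrival",
    "RunConfig",
    "Snapshot",
    "Trajectory",
    "Simulation",
    "contact_bookkeeping",
    "step",
    "detect_collapse",
    "run",
]

_PHASES = (Phase.G1, Phase.REST, Phase.M)
_PHASE_INDEX = {p: k for k, p in enumerate(_PHASES)}

DAY_MIN = 24.0 * 60.0


@dataclass
class Arrival:
    """A cell scheduled to enter the world at a given time.

    When ``relative_to`` names an existing cell, the arriving cell's
    position is interpreted as an offset from that cell's current position
    (used to bring a fresh neighbour into contact in the staggered
    three-cell assay).
    """

    time: float
    cell: CellState
    relative_to: Optional[int] = None


@dataclass
class RunConfig:
    """Complete, reproducible description of one simulation run."""

    variant: ModelVariant = ModelVariant.MODEL2
    kinetic: KineticParams = field(default_factory=KineticParams)
    mech: MechParams = field(default_factory=MechParams)
    cycle: CycleParams = field(default_factory=CycleParams)
    contact_inhibition: bool = False
    cycle_enabled: bool = True
    dt_pathway: float = 0.01
    displacement_cap: float = 0.05
    duration: float = 100.0
    seed: int = 0
    snapshot_interval: float = 60.0
    initial_cells: List[CellState] = field(default_factory=list)
    arrivals: List[Arrival] = field(default_factory=list)
    collapse_threshold: float = 0.2
    forced_snapshot_times: Tuple[float, ...] = ()
    randomize_initial_cycle: bool = False
    scenario: Optional[str] = None

    def __post_init__(self) -> None:
        self.variant = ModelVariant.parse(self.variant)
        if self.duration < 0:
            raise ValueError("duration must be non-negative")
        if self.dt_pathway <= 0:
            raise ValueError("dt_pathway must be positive")


@dataclass
class Snapshot:
    time: float
    world: WorldState
    metrics: Dict[str, object] = field(default_factory=dict)


@dataclass
class Trajectory:
    """Ordered snapshots of a run plus summary information."""

    config: RunConfig
    snapshots: List[Snapshot] = field(default_factory=list)
    status: str = "running"
    wall_clock_s: float = 0.0

    @property
    def times(self) -> np.ndarray:
        return np.array([s.time for s in self.snapshots])

    @property
    def counts(self) -> np.ndarray:
        return np.array([len(s.world.cells) for s in self.snapshots])

    def snapshot_at(self, t: float, tol: float = 1e-6) -> Snapshot:
        for s in self.snapshots:
            if abs(s.time - t) <= tol:
                return s
        raise KeyError(f"no snapshot at t={t}")


class Simulation:
    """Structure-of-arrays world with the full stepping logic."""

    def __init__(self, config: RunConfig):
        self.config = config
        self.rng = np.random.default_rng(config.seed)
        seed_kernel_rng(int(self.rng.integers(1 << 31)))
        self.k_step = 0
        self.status = "running"
        self._arrivals = sorted(
            [replace(a) for a in config.arrivals], key=lambda a: a.time
        )
        cells = [c.copy() for c in config.initial_cells]
        if config.randomize_initial_cycle:
            from .cell_cycle import randomize_cycle_position

            for c in cells:
                randomize_cycle_position(c, config.cycle, config.mech, self.rng)
        self._from_cells(cells)

    # ------------------------------------------------------------------ setup

    def _from_cells(self, cells: Sequence[CellState]) -> None:
        n = len(cells)
        self.ids = np.array([c.id for c in cells], dtype=np.int64)
        if len(set(self.ids.tolist())) != n:
            raise ValueError("cell ids must be unique")
        self._next_id = int(self.ids.max()) + 1 if n else 0
        self.pos = np.array([c.position for c in cells], dtype=float).reshape(n, 2)
        self.radius = np.array([c.radius for c in cells], dtype=float)
        self.expression = np.array([c.expression for c in cells], dtype=float)
        self.E = np.array([c.E for c in cells], dtype=float)
        self.B = np.array([c.B for c in cells], dtype=float)
        self.EB = np.array([c.EB for c in cells], dtype=float)
        self.phase = np.array([_PHASE_INDEX[c.phase] for c in cells], dtype=np.int8)
        self.clock = np.array([c.phase_clock for c in cells], dtype=float)
        self.rest = np.array([c.rest_duration for c in cells], dtype=float)
        self.arrested = np.array([c.arrested for c in cells], dtype=bool)
        self.sibling = np.array(
            [-1 if c.sibling_id is None else c.sibling_id for c in cells],
            dtype=np.int64,
        )
        self.area = np.zeros((n, n))
        self.prev_area = np.zeros((n, n))
        self.C = np.zeros((n, n))
        self.site = np.zeros((n, n), dtype=bool)
        id_to_idx = {int(i): k for k, i in enumerate(self.ids)}
        for k, c in enumerate(cells):
            for pid, s in c.contacts.items():
                if pid in id_to_idx:
                    j = id_to_idx[pid]
                    self.area[k, j] = s.area
                    self.prev_area[k, j] = s.prev_area
                    self.C[k, j] = s.EBc
                    self.site[k, j] = True
        self.pressure = np.zeros(n)
        self._dmat = np.zeros((n, n))

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def time(self) -> float:
        return self.k_step * self.config.dt_pathway

    def _append_cells(self, cells: Sequence[CellState]) -> None:
        old = self.n
        add = len(cells)
        self.ids = np.concatenate([self.ids, [c.id for c in cells]])
        self.pos = np.vstack([self.pos, [c.position for c in cells]])
        self.radius = np.concatenate([self.radius, [c.radius for c in cells]])
        self.expression = np.concatenate(
            [self.expression, [c.expression for c in cells]]
        )
        self.E = np.concatenate([self.E, [c.E for c in cells]])
        self.B = np.concatenate([self.B, [c.B for c in cells]])
        self.EB = np.concatenate([self.EB, [c.EB for c in cells]])
        self.phase = np.concatenate(
            [self.phase, [_PHASE_INDEX[c.phase] for c in cells]]
        ).astype(np.int8)
        self.clock = np.concatenate([self.clock, [c.phase_clock for c in cells]])
        self.rest = np.concatenate([self.rest, [c.rest_duration for c in cells]])
        self.arrested = np.concatenate([self.arrested, [c.arrested for c in cells]])
        self.sibling = np.concatenate(
            [
                self.sibling,
                [-1 if c.sibling_id is None else c.sibling_id for c in cells],
            ]
        ).astype(np.int64)
        n = old + add
        for name in ("area", "prev_area", "C"):
            mat = getattr(self, name)
            new = np.zeros((n, n))
            new[:old, :old] = mat
            setattr(self, name, new)
        new_site = np.zeros((n, n), dtype=bool)
        new_site[:old, :old] = self.site
        self.site = new_site
        self.pressure = np.concatenate([self.pressure, np.zeros(add)])
        self._next_id = max(self._next_id, int(self.ids.max()) + 1)

    def _remove_cell(self, idx: int) -> None:
        keep = np.arange(self.n) != idx
        for name in (
            "ids",
            "radius",
            "expression",
            "E",
            "B",
            "EB",
            "phase",
            "clock",
            "rest",
            "arrested",
            "sibling",
            "pressure",
        ):
            setattr(self, name, getattr(self, name)[keep])
        self.pos = self.pos[keep]
        for name in ("area", "prev_area", "C", "site"):
            mat = getattr(self, name)
            setattr(self, name, mat[np.ix_(keep, keep)])

    # ------------------------------------------------------------ bookkeeping

    def _distance_matrix(self) -> np.ndarray:
        diff = self.pos[:, None, :] - self.pos[None, :, :]
        d = np.sqrt((diff**2).sum(axis=2))
        np.fill_diagonal(d, np.inf)
        return d

    def _sibling_mask(self) -> np.ndarray:
        """Boolean (N,N): True where a pair is a mutually-M sibling pair."""
        n = self.n
        mask = np.zeros((n, n), dtype=bool)
        in_m = self.phase == _PHASE_INDEX[Phase.M]
        if not in_m.any():
            return mask
        id_to_idx = {int(i): k for k, i in enumerate(self.ids)}
        for k in np.flatnonzero(in_m):
            sib = int(self.sibling[k])
            j = id_to_idx.get(sib)
            if j is not None and in_m[j]:
                mask[k, j] = True
        return mask

    def contact_bookkeeping(self) -> None:
        """Create/refresh contact sites from the current geometry.

        Overlapping non-sibling pairs carry a site on both cells; sites of
        separated pairs persist with area 0 while their compartments drain.
        New sites start with prev_area equal to the current area, so contact
        formation itself does not register as area growth.
        """
        n = self.n
        if n == 0:
            return
        d = self._distance_matrix()
        self._dmat = d
        rsum = self.radius[:, None] + self.radius[None, :]
        overlap = d < rsum
        overlap &= ~self._sibling_mask()

        # lens-circle contact areas for overlapping pairs
        area = np.zeros((n, n))
        ii, jj = np.nonzero(overlap)
        if ii.size:
            dij = d[ii, jj]
            Ri = self.radius[ii]
            Rj = self.radius[jj]
            small = np.minimum(Ri, Rj)
            with np.errstate(divide="ignore", invalid="ignore"):
                a_sq = (4 * dij**2 * Ri**2 - (dij**2 - Rj**2 + Ri**2) ** 2) / (
                    4 * dij**2
                )
            a = np.sqrt(np.clip(a_sq, 0.0, None))
            a = np.where(dij <= np.abs(Ri - Rj), small, np.minimum(a, small))
            area[ii, jj] = math.pi * a * a

        newly = overlap & ~self.site
        self.prev_area[newly] = area[newly]
        self.site |= overlap
        self.area = np.where(self.site, area, 0.0)
        # fully drained detached sites disappear (residue returned to EB)
        dead = self.site & ~overlap & (self.C < _ap.DRAINED_SITE_EPS)
        if dead.any():
            self.EB += self.C.sum(axis=1, where=dead)
            self.C[dead] = 0.0
            self.prev_area[dead] = 0.0
            self.site[dead] = False

    # ------------------------------------------------------------------ cycle

    def _cycle(self) -> None:
        if self.n == 0:
            return
        cfg = self.config
        cyc = cfg.cycle
        mech = cfg.mech
        dt = cfg.dt_pathway
        self.clock += dt

        g1 = self.phase == _PHASE_INDEX[Phase.G1]
        if g1.any():
            frac = np.clip(self.clock[g1] / cyc.t_g1, 0.0, 1.0)
            self.radius[g1] = mech.min_radius + frac * (mech.R - mech.min_radius)
            done = g1 & (self.clock >= cyc.t_g1)
            if done.any():
                self.phase[done] = _PHASE_INDEX[Phase.REST]
                self.clock[done] -= cyc.t_g1
                self.radius[done] = mech.R
                for k in np.flatnonzero(done):
                    self.rest[k] = self.rng.uniform(cyc.rest_min, cyc.rest_max)

        m_phase = self.phase == _PHASE_INDEX[Phase.M]
        m_done = m_phase & (self.clock >= cyc.t_m)
        if m_done.any():
            self.phase[m_done] = _PHASE_INDEX[Phase.G1]
            self.clock[m_done] = 0.0
            self.sibling[m_done] = -1

        rest = self.phase == _PHASE_INDEX[Phase.REST]
        ready = rest & (self.clock >= self.rest)
        if ready.any():
            if cfg.contact_inhibition:
                blocked = ready & (self.pressure > mech.pressure_threshold)
                self.arrested[blocked] = True
                ready &= ~blocked
                self.arrested[ready] = False
            for k in sorted(np.flatnonzero(ready), reverse=True):
                self._divide(int(k))

    def _division_axis(self, idx: int) -> np.ndarray:
        mech = self.config.mech
        d = self._distance_matrix()
        T = np.zeros((2, 2))
        total = 0.0
        for j in range(self.n):
            if j == idx or not np.isfinite(d[idx, j]):
                continue
            h = self.radius[idx] + self.radius[j] - d[idx, j]
            if h <= 0.0 or d[idx, j] < 1e-9:
                continue
            compliance = 0.75 * 2.0 * (1.0 - mech.sigma**2) / mech.E_mod
            w = (
                h**1.5
                * math.sqrt(
                    self.radius[idx]
                    * self.radius[j]
                    / (self.radius[idx] + self.radius[j])
                )
                / compliance
            )
            u = (self.pos[idx] - self.pos[j]) / d[idx, j]
            T += w * np.outer(u, u)
            total += w
        if total <= 0.0:
            theta = self.rng.uniform(0.0, 2.0 * math.pi)
            return np.array([math.cos(theta), math.sin(theta)])
        w_eig, v = np.linalg.eigh(T)
        if abs(w_eig[1] - w_eig[0]) <= 1e-12 * max(abs(w_eig[1]), 1.0):
            theta = self.rng.uniform(0.0, 2.0 * math.pi)
            return np.array([math.cos(theta), math.sin(theta)])
        return v[:, int(np.argmax(w_eig))]

    def _divide(self, idx: int) -> None:
        """Replace a mother by two M-phase daughters (the dumb-bell).

        Division disassembles the mother's junctions: her bound complexes
        return to the cytosolic pool, and her partners internalise their
        complexes facing her in the same way, keeping conservation exact on
        every cell.  Concentrations are intensive and carry over unchanged.
        """
        mech = self.config.mech
        axis = self._division_axis(idx)
        eb_pool = self.EB[idx] + self.C[idx].sum()
        ids = (self._next_id, self._next_id + 1)
        self._next_id += 2
        daughters = []
        for ident, sign in zip(ids, (+1.0, -1.0)):
            daughters.append(
                CellState(
                    id=ident,
                    position=(
                        self.pos[idx, 0] + sign * 0.5 * mech.R * axis[0],
                        self.pos[idx, 1] + sign * 0.5 * mech.R * axis[1],
                    ),
                    radius=mech.min_radius,
                    expression=self.expression[idx],
                    E=self.E[idx],
                    B=self.B[idx],
                    EB=eb_pool,
                    phase=Phase.M,
                    phase_clock=0.0,
                    rest_duration=self.rest[idx],
                    sibling_id=None,
                )
            )
        daughters[0].sibling_id = ids[1]
        daughters[1].sibling_id = ids[0]
        # partners internalise the complexes bound toward the mother
        partners = np.flatnonzero(self.site[:, idx])
        self.EB[partners] += self.C[partners, idx]
        self.C[partners, idx] = 0.0
        self._remove_cell(idx)
        self._append_cells(daughters)

    # --------------------------------------------------------------- stepping

    def _inject_arrivals(self) -> None:
        while self._arrivals and self._arrivals[0].time <= self.time + 1e-9:
            arr = self._arrivals.pop(0)
            cell = arr.cell.copy()
            if arr.relative_to is not None:
                ref = np.flatnonzero(self.ids == arr.relative_to)
                if ref.size == 0:
                    raise ValueError(
                        f"arrival references unknown cell {arr.relative_to}"
                    )
                cell.position = (
                    self.pos[ref[0], 0] + cell.position[0],
                    self.pos[ref[0], 1] + cell.position[1],
                )
            self._append_cells([cell])

    def detect_collapse(self) -> bool:
        """True when any non-sibling pair sits closer than the threshold."""
        thr = self.config.collapse_threshold
        if thr <= 0 or self.n < 2:
            return False
        d = self._distance_matrix()
        rsum = self.radius[:, None] + self.radius[None, :]
        close = d < thr * rsum
        close &= ~self._sibling_mask()
        return bool(close.any())

    def step(self) -> None:
        """One operator-split step: bookkeeping → pathway → mechanics →
        cycle, then collapse detection (M-phase dumb-bells excluded)."""
        if self.status != "running":
            return
        self._inject_arrivals()
        if self.n:
            kin = self.config.kinetic
            mech = self.config.mech
            in_m = self.phase == _PHASE_INDEX[Phase.M]
            sib_idx = np.full(self.n, -1, dtype=np.int64)
            if in_m.any():
                id_to_idx = {int(i): k for k, i in enumerate(self.ids)}
                for k in np.flatnonzero(in_m):
                    sib_idx[k] = id_to_idx.get(int(self.sibling[k]), -1)
            collapsed = colony_step_kernel(
                self.pos,
                self.radius,
                self.expression,
                self.E,
                self.B,
                self.EB,
                self.C,
                self.area,
                self.prev_area,
                self.site,
                in_m,
                sib_idx,
                self.pressure,
                kin.rho_u,
                kin.nu_n,
                kin.nu_p,
                kin.rho_c,
                kin.gamma,
                kin.rho_d,
                {ModelVariant.MODEL1: 1, ModelVariant.MODEL2: 2, ModelVariant.MODEL3: 3}[
                    self.config.variant
                ],
                self.config.dt_pathway,
                self.config.displacement_cap,
                mech.sigma,
                mech.E_mod,
                mech.eta,
                2.0 * mech.noise_diffusion,
                self.config.collapse_threshold,
            )
            if self.config.cycle_enabled:
                self._cycle()
            if collapsed:
                self.status = "collapsed"
        self.k_step += 1

    # -------------------------------------------------------------- snapshots

    def to_world(self) -> WorldState:
        cells = []
        id_list = self.ids.tolist()
        for k in range(self.n):
            contacts = {}
            for j in np.flatnonzero(self.site[k]):
                contacts[int(id_list[j])] = ContactSite(
                    partner_id=int(id_list[j]),
                    area=float(self.area[k, j]),
                    prev_area=float(self.prev_area[k, j]),
                    EBc=float(self.C[k, j]),
                )
            cells.append(
                CellState(
                    id=int(id_list[k]),
                    position=(float(self.pos[k, 0]), float(self.pos[k, 1])),
                    radius=float(self.radius[k]),
                    expression=float(self.expression[k]),
                    E=float(self.E[k]),
                    B=float(self.B[k]),
                    EB=float(self.EB[k]),
                    contacts=contacts,
                    phase=_PHASES[int(self.phase[k])],
                    phase_clock=float(self.clock[k]),
                    rest_duration=float(self.rest[k]),
                    arrested=bool(self.arrested[k]),
                    sibling_id=(
                        None if self.sibling[k] < 0 else int(self.sibling[k])
                    ),
                )
            )
        return WorldState(
            cells=cells, time=self.time, rng_seed=self.config.seed, status=self.status
        )


# ------------------------------------------------------------------ API layer


def contact_bookkeeping(world: WorldState, config: Optional[RunConfig] = None) -> WorldState:
    """Refresh contact sites of a world (functional wrapper)."""
    cfg = config or RunConfig(initial_cells=world.cells, duration=1.0)
    cfg = replace(cfg, initial_cells=world.cells)
    sim = Simulation(cfg)
    sim.contact_bookkeeping()
    out = sim.to_world()
    out.time = world.time
    return out


def step(world: WorldState, config: RunConfig) -> WorldState:
    """Advance a world by one pathway step (functional wrapper).

    ``run`` is the efficient entry point; this wrapper exists for
    inspection and testing of single transitions.
    """
    cfg = replace(config, initial_cells=world.cells, randomize_initial_cycle=False)
    sim = Simulation(cfg)
    sim.k_step = round(world.time / config.dt_pathway)
    sim.step()
    out = sim.to_world()
    return out


def detect_collapse(world: WorldState, threshold: float = 0.2) -> bool:
    """True iff some pair's centre distance is below threshold·(R_i+R_j).

    M-phase sibling pairs (the dumb-bell halves) are exempt: their overlap
    is the intended mitotic geometry, not a failure of the contact model.
    """
    cells = world.cells
    for a in range(len(cells)):
        for b in range(a + 1, len(cells)):
            ca, cb = cells[a], cells[b]
            if (
                ca.phase is Phase.M
                and cb.phase is Phase.M
                and ca.sibling_id == cb.id
            ):
                continue
            dx = ca.position[0] - cb.position[0]
            dy = ca.position[1] - cb.position[1]
            if math.hypot(dx, dy) < threshold * (ca.radius + cb.radius):
                return True
    return False


def run(config: RunConfig, progress: bool = False) -> Trajectory:
    """Execute a full run, snapshotting at the configured interval.

    Snapshots are taken at t = 0, at every ``snapshot_interval``, at each
    forced snapshot time (e.g. day 3 and day 7) that falls within the
    duration, and at the final time.  A collapsed run returns its partial
    trajectory with status ``"collapsed"``.
    """
    from .metrics_io import snapshot_metrics  # deferred: avoids import cycle

    t0 = _time.perf_counter()
    sim = Simulation(config)
    dt = config.dt_pathway
    n_steps = int(round(config.duration / dt))
    snap_steps = set()
    if config.snapshot_interval > 0:
        every = max(1, int(round(config.snapshot_interval / dt)))
        snap_steps.update(range(0, n_steps + 1, every))
    for t in config.forced_snapshot_times:
        if 0 <= t <= config.duration:
            snap_steps.add(int(round(t / dt)))
    snap_steps.add(0)
    snap_steps.add(n_steps)

    traj = Trajectory(config=config)

    def take(k: int) -> None:
        world = sim.to_world()
        traj.snapshots.append(
            Snapshot(
                time=k * dt,
                world=world,
                metrics=snapshot_metrics(world, config.variant),
            )
        )

    take(0)
    for k in range(1, n_steps + 1):
        sim.step()
        if sim.status != "running":
            take(k)
            break
        if k in snap_steps:
            take(k)
    traj.status = "done" if sim.status == "running" else sim.status
    traj.wall_clock_s = _time.perf_counter() - t0
    return traj
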