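"""Colony metrics, named scenarios, and file I/O.

The colony-level observables mirror the quantities used to select between
the model variants: cell count, the histogram of neighbour numbers (whose
mode is 6 in proliferating epithelial layers), the average
adhesion/separation force at cell–cell contacts, and the amount of free
cytosolic E-cadherin.  Exponential growth fitting turns a count-vs-time
series into a growth rate and doubling time.
"""

from __future__ import annotations

import dataclasses
import json
import math
import platform
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from .core_state import (
    CellState,
    ContactSite,
    CycleParams,
    KineticParams,
    MechParams,
    ModelVariant,
    Phase,
    WorldState,
)
from .engine import Arrival, RunConfig, Trajectory
from .mechanics import adhesion_force

__all__ = [
    "ColonyMetrics",
    "neighbour_histogram",
    "mean_contact_force",
    "mean_free_E",
    "snapshot_metrics",
    "fit_exponential_growth",
    "make_scenario",
    "SCENARIO_NAMES",
    "pair_distance_for_contact_area",
    "write_outputs",
    "read_config",
    "write_config",
    "config_to_dict",
    "config_from_dict",
]


@dataclass
class ColonyMetrics:
    """Per-snapshot summary of a colony."""

    n_cells: int
    neighbour_histogram: Dict[int, int]
    mean_contact_force: float
    mean_free_E: float
    status: str = "running"

    def histogram_mode(self) -> Optional[int]:
        if not self.neighbour_histogram:
            return None
        return max(self.neighbour_histogram.items(), key=lambda kv: (kv[1], -kv[0]))[0]


def _overlap_pairs(world: WorldState) -> List[Tuple[int, int, float]]:
    cells = world.cells
    out = []
    for a in range(len(cells)):
        for b in range(a + 1, len(cells)):
            dx = cells[a].position[0] - cells[b].position[0]
            dy = cells[a].position[1] - cells[b].position[1]
            d = math.hypot(dx, dy)
            if d < cells[a].radius + cells[b].radius:
                out.append((a, b, d))
    return out


def neighbour_histogram(world: WorldState) -> Dict[int, int]:
    """Histogram of neighbour numbers (neighbour = overlapping cell).

    Dumb-bell sibling suppression is ignored for counting: two touching
    daughters are each other's neighbours.  The histogram totals the cell
    count.
    """
    counts = {c.id: 0 for c in world.cells}
    for a, b, _ in _overlap_pairs(world):
        counts[world.cells[a].id] += 1
        counts[world.cells[b].id] += 1
    hist: Dict[int, int] = {}
    for v in counts.values():
        hist[v] = hist.get(v, 0) + 1
    return hist


def mean_contact_force(world: WorldState, variant: ModelVariant | str) -> float:
    """Mean adhesion/separation force over distinct contact pairs, pN.

    Each overlapping pair contributes the force of its bond under the
    variant's map — for Model 3 a pair at or inside its natural state
    contributes zero.  Returns 0 for a world without contacts.
    """
    variant = ModelVariant.parse(variant)
    forces = []
    for a, b, d in _overlap_pairs(world):
        ca, cb = world.cells[a], world.cells[b]
        site_ab = ca.contacts.get(cb.id)
        site_ba = cb.contacts.get(ca.id)
        pct_a = site_ab.EBc if site_ab else 0.0
        pct_b = site_ba.EBc if site_ba else 0.0
        forces.append(
            adhesion_force(variant, pct_a, pct_b, d, ca.radius, cb.radius)
        )
    return float(np.mean(forces)) if forces else 0.0


def mean_free_E(world: WorldState) -> float:
    """Mean free cytosolic E-cadherin concentration, %."""
    if not world.cells:
        return 0.0
    return float(np.mean([c.E for c in world.cells]))


def snapshot_metrics(world: WorldState, variant: ModelVariant | str) -> ColonyMetrics:
    return ColonyMetrics(
        n_cells=len(world.cells),
        neighbour_histogram=neighbour_histogram(world),
        mean_contact_force=mean_contact_force(world, variant),
        mean_free_E=mean_free_E(world),
        status=world.status,
    )


def fit_exponential_growth(
    times_days: Sequence[float], counts: Sequence[float]
) -> Tuple[float, float]:
    """Least-squares exponential growth fit.

    Fits log(count) = log(c0) + rate·t by linear least squares and returns
    ``(rate_per_day, doubling_time_hours)`` with doubling time ln2/rate
    (infinite for a non-growing series).
    """
    t = np.asarray(times_days, dtype=float)
    c = np.asarray(counts, dtype=float)
    if t.size < 3:
        raise ValueError("need at least three time points")
    if np.any(c < 1):
        raise ValueError("counts must be >= 1")
    slope, _ = np.polyfit(t, np.log(c), 1)
    rate = float(slope)
    doubling_h = math.inf if rate <= 0 else math.log(2.0) / rate * 24.0
    return rate, doubling_h


# ------------------------------------------------------------------ scenarios

SCENARIO_NAMES = (
    "two_cell",
    "three_cell_simultaneous",
    "three_cell_staggered",
    "single_cell_colony",
    "hexagon_test",
)

#: Second neighbour arrival time in the staggered three-cell assay, min.
STAGGERED_ARRIVAL_MIN = 20.0


def pair_distance_for_contact_area(R: float, area: float) -> float:
    """Centre distance of two equal spheres with a given contact area."""
    a_sq = area / math.pi
    if a_sq >= R * R:
        raise ValueError("contact area exceeds the great circle")
    return 2.0 * math.sqrt(R * R - a_sq)


def _fresh_cell(cid: int, x: float, y: float, expression: float, R: float) -> CellState:
    return CellState(
        id=cid,
        position=(x, y),
        radius=R,
        expression=expression,
        E=expression,
        B=100.0,
        EB=0.0,
        phase=Phase.REST,
        phase_clock=0.0,
    )


def make_scenario(name: str, **overrides) -> RunConfig:
    """Build a fully populated RunConfig for a named scenario.

    Recognised scenarios:

    * ``two_cell`` — the dual-pipette assay: two cells of radius 5 µm with
      an initial contact area of 1 µm², followed for 100 min.  No noise, no
      cycling; the assay holds the cells, so collapse detection is off.
    * ``three_cell_simultaneous`` — both neighbours in contact from t = 0.
    * ``three_cell_staggered`` — the second neighbour arrives at 20 min.
    * ``single_cell_colony`` — one founder cell at a random cycle position
      growing into a colony for 7 days (Model 3, ρ_d = 0.6, contact
      inhibition and positional noise on; daily snapshots plus day 3/7).
    * ``hexagon_test`` — a centre cell with six neighbours at 8.5 µm,
      mechanics only (pathway rates zeroed); used for the pressure anchor.

    Keyword overrides may target RunConfig fields directly, the shortcut
    keys ``rho_d``/``gamma``/``expression``/``duration_days``, or whole
    parameter objects (``kinetic``, ``mech``, ``cycle``).
    """
    if name not in SCENARIO_NAMES:
        raise ValueError(f"unknown scenario {name!r}; choose from {SCENARIO_NAMES}")

    expression = float(overrides.pop("expression", 100.0))
    kinetic: KineticParams = overrides.pop("kinetic", None) or KineticParams()
    if "rho_d" in overrides:
        kinetic = dataclasses.replace(kinetic, rho_d=float(overrides.pop("rho_d")))
    if "gamma" in overrides:
        kinetic = dataclasses.replace(kinetic, gamma=float(overrides.pop("gamma")))
    mech: MechParams = overrides.pop("mech", None) or MechParams()
    cycle: CycleParams = overrides.pop("cycle", None) or CycleParams()
    if "duration_days" in overrides:
        overrides["duration"] = float(overrides.pop("duration_days")) * 1440.0
    R = mech.R

    if name in ("two_cell", "three_cell_simultaneous", "three_cell_staggered"):
        d0 = pair_distance_for_contact_area(R, 1.0)
        cells = [_fresh_cell(0, 0.0, 0.0, expression, R)]
        arrivals: List[Arrival] = []
        cells.append(_fresh_cell(1, d0, 0.0, expression, R))
        if name == "three_cell_simultaneous":
            cells.append(_fresh_cell(2, -d0, 0.0, expression, R))
        elif name == "three_cell_staggered":
            arrivals.append(
                Arrival(
                    time=STAGGERED_ARRIVAL_MIN,
                    cell=_fresh_cell(2, -d0, 0.0, expression, R),
                    relative_to=0,
                )
            )
        cfg = RunConfig(
            variant=ModelVariant.MODEL2,
            kinetic=kinetic,
            mech=mech,
            cycle=cycle,
            cycle_enabled=False,
            contact_inhibition=False,
            duration=100.0,
            snapshot_interval=1.0,
            initial_cells=cells,
            arrivals=arrivals,
            collapse_threshold=0.0,
            scenario=name,
        )
    elif name == "single_cell_colony":
        mech = dataclasses.replace(mech, noise_diffusion=overrides.pop("noise_diffusion", 0.05))
        cfg = RunConfig(
            variant=ModelVariant.MODEL3,
            kinetic=dataclasses.replace(kinetic, rho_d=kinetic.rho_d),
            mech=mech,
            cycle=cycle,
            cycle_enabled=True,
            contact_inhibition=True,
            # colony-scale integration step: kinetic rates are ≤ 8.2 min⁻¹,
            # so 0.05 min keeps the pathway Euler update well resolved while
            # the mechanics sub-steps remain displacement-capped
            dt_pathway=0.05,
            duration=7.0 * 1440.0,
            snapshot_interval=1440.0,
            initial_cells=[_fresh_cell(0, 0.0, 0.0, expression, R)],
            collapse_threshold=0.2,
            forced_snapshot_times=(3.0 * 1440.0, 7.0 * 1440.0),
            randomize_initial_cycle=True,
            scenario=name,
        )
    else:  # hexagon_test
        spacing = overrides.pop("spacing", 8.5)
        cells = [_fresh_cell(0, 0.0, 0.0, expression, R)]
        for k in range(6):
            ang = k * math.pi / 3.0
            cells.append(
                _fresh_cell(
                    k + 1, spacing * math.cos(ang), spacing * math.sin(ang), expression, R
                )
            )
        cfg = RunConfig(
            variant=ModelVariant.MODEL2,
            kinetic=KineticParams(0.0, 0.0, 0.0, 0.0, 0.0, 0.0),
            mech=mech,
            cycle=cycle,
            cycle_enabled=False,
            duration=overrides.pop("duration", 1.0),
            snapshot_interval=1.0,
            initial_cells=cells,
            collapse_threshold=0.0,
            scenario=name,
        )

    for key, value in overrides.items():
        if not hasattr(cfg, key):
            raise ValueError(f"unknown scenario override {key!r}")
        setattr(cfg, key, value)
    cfg.variant = ModelVariant.parse(cfg.variant)
    return cfg


# ------------------------------------------------------------------------ I/O


def _cell_to_dict(c: CellState) -> dict:
    return {
        "id": c.id,
        "position": list(c.position),
        "radius": c.radius,
        "expression": c.expression,
        "E": c.E,
        "B": c.B,
        "EB": c.EB,
        "phase": c.phase.value,
        "phase_clock": c.phase_clock,
        "rest_duration": c.rest_duration,
        "arrested": c.arrested,
        "sibling_id": c.sibling_id,
        "contacts": [
            {
                "partner_id": s.partner_id,
                "area": s.area,
                "prev_area": s.prev_area,
                "EBc": s.EBc,
            }
            for s in c.contacts.values()
        ],
    }


def _cell_from_dict(d: dict) -> CellState:
    contacts = {
        int(s["partner_id"]): ContactSite(
            partner_id=int(s["partner_id"]),
            area=float(s["area"]),
            prev_area=float(s["prev_area"]),
            EBc=float(s["EBc"]),
        )
        for s in d.get("contacts", [])
    }
    return CellState(
        id=int(d["id"]),
        position=tuple(d.get("position", (0.0, 0.0))),
        radius=float(d.get("radius", 5.0)),
        expression=float(d.get("expression", 100.0)),
        E=float(d.get("E", 100.0)),
        B=float(d.get("B", 100.0)),
        EB=float(d.get("EB", 0.0)),
        contacts=contacts,
        phase=Phase(d.get("phase", "G1")),
        phase_clock=float(d.get("phase_clock", 0.0)),
        rest_duration=float(d.get("rest_duration", 780.0)),
        arrested=bool(d.get("arrested", False)),
        sibling_id=d.get("sibling_id"),
    )


def config_to_dict(cfg: RunConfig) -> dict:
    return {
        "variant": cfg.variant.value,
        "kinetic": dataclasses.asdict(cfg.kinetic),
        "mech": dataclasses.asdict(cfg.mech),
        "cycle": dataclasses.asdict(cfg.cycle),
        "contact_inhibition": cfg.contact_inhibition,
        "cycle_enabled": cfg.cycle_enabled,
        "dt_pathway": cfg.dt_pathway,
        "displacement_cap": cfg.displacement_cap,
        "duration": cfg.duration,
        "seed": cfg.seed,
        "snapshot_interval": cfg.snapshot_interval,
        "initial_cells": [_cell_to_dict(c) for c in cfg.initial_cells],
        "arrivals": [
            {
                "time": a.time,
                "cell": _cell_to_dict(a.cell),
                "relative_to": a.relative_to,
            }
            for a in cfg.arrivals
        ],
        "collapse_threshold": cfg.collapse_threshold,
        "forced_snapshot_times": list(cfg.forced_snapshot_times),
        "randomize_initial_cycle": cfg.randomize_initial_cycle,
        "scenario": cfg.scenario,
    }


def config_from_dict(data: dict) -> RunConfig:
    known = {
        "variant",
        "kinetic",
        "mech",
        "cycle",
        "contact_inhibition",
        "cycle_enabled",
        "dt_pathway",
        "displacement_cap",
        "duration",
        "seed",
        "snapshot_interval",
        "initial_cells",
        "arrivals",
        "collapse_threshold",
        "forced_snapshot_times",
        "randomize_initial_cycle",
        "scenario",
    }
    bad = set(data) - known
    if bad:
        raise ValueError(f"unknown config keys: {sorted(bad)}")
    kwargs = dict(data)
    if "variant" in kwargs:
        kwargs["variant"] = ModelVariant.parse(kwargs["variant"])
    for key, cls in (("kinetic", KineticParams), ("mech", MechParams), ("cycle", CycleParams)):
        if key in kwargs and isinstance(kwargs[key], dict):
            kwargs[key] = cls(**kwargs[key])
    if "initial_cells" in kwargs:
        kwargs["initial_cells"] = [
            c if isinstance(c, CellState) else _cell_from_dict(c)
            for c in kwargs["initial_cells"]
        ]
    if "arrivals" in kwargs:
        kwargs["arrivals"] = [
            a
            if isinstance(a, Arrival)
            else Arrival(
                time=float(a["time"]),
                cell=_cell_from_dict(a["cell"]),
                relative_to=a.get("relative_to"),
            )
            for a in kwargs["arrivals"]
        ]
    if "forced_snapshot_times" in kwargs:
        kwargs["forced_snapshot_times"] = tuple(kwargs["forced_snapshot_times"])
    return RunConfig(**kwargs)


def read_config(path: str | Path) -> RunConfig:
    """Read a run configuration from YAML or JSON."""
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError(f"config file {path} does not contain a mapping")
    return config_from_dict(data)


def write_config(cfg: RunConfig, path: str | Path) -> None:
    path = Path(path)
    data = config_to_dict(cfg)
    if path.suffix == ".json":
        path.write_text(json.dumps(data, indent=2))
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=False))


def write_outputs(trajectory: Trajectory, out_dir: str | Path) -> Dict[str, Path]:
    """Write snapshot, contact and metrics CSVs plus a JSON run manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    snap_rows = []
    contact_rows = []
    metric_rows = []
    variant = trajectory.config.variant
    for snap in trajectory.snapshots:
        world = snap.world
        hist = neighbour_histogram(world)
        nn = {c.id: 0 for c in world.cells}
        for a, b, _ in _overlap_pairs(world):
            nn[world.cells[a].id] += 1
            nn[world.cells[b].id] += 1
        pressures = {c.id: 0.0 for c in world.cells}
        for a, b, d in _overlap_pairs(world):
            from .mechanics import hertz_force

            ca, cb = world.cells[a], world.cells[b]
            rep = hertz_force(
                d,
                ca.radius,
                cb.radius,
                trajectory.config.mech.sigma,
                trajectory.config.mech.sigma,
                trajectory.config.mech.E_mod,
                trajectory.config.mech.E_mod,
            )
            pressures[ca.id] += rep
            pressures[cb.id] += rep
        for c in world.cells:
            snap_rows.append(
                {
                    "time_min": snap.time,
                    "cell_id": c.id,
                    "x_um": c.position[0],
                    "y_um": c.position[1],
                    "radius_um": c.radius,
                    "phase": c.phase.value,
                    "free_E_pct": c.E,
                    "free_B_pct": c.B,
                    "cyto_EB_pct": c.EB,
                    "n_neighbours": nn[c.id],
                    "pressure_pN": pressures[c.id],
                }
            )
        seen = set()
        for c in world.cells:
            for pid, site in c.contacts.items():
                key = (min(c.id, pid), max(c.id, pid))
                if key in seen:
                    continue
                seen.add(key)
                try:
                    partner = world.cell_by_id(pid)
                except KeyError:
                    continue
                back = partner.contacts.get(c.id)
                dx = c.position[0] - partner.position[0]
                dy = c.position[1] - partner.position[1]
                d = math.hypot(dx, dy)
                contact_rows.append(
                    {
                        "time_min": snap.time,
                        "cell_i": key[0],
                        "cell_j": key[1],
                        "area_um2": site.area,
                        "EBc_i_pct": site.EBc if c.id == key[0] else (back.EBc if back else 0.0),
                        "EBc_j_pct": (back.EBc if back else 0.0) if c.id == key[0] else site.EBc,
                        "force_pN": adhesion_force(
                            variant,
                            site.EBc,
                            back.EBc if back else 0.0,
                            d,
                            c.radius,
                            partner.radius,
                        ),
                    }
                )
        m = snap.metrics if isinstance(snap.metrics, ColonyMetrics) else snapshot_metrics(world, variant)
        metric_rows.append(
            {
                "time_min": snap.time,
                "n_cells": m.n_cells,
                "mean_contact_force_pN": m.mean_contact_force,
                "mean_free_E_pct": m.mean_free_E,
                "histogram_mode": m.histogram_mode(),
                "status": world.status,
            }
        )
    paths = {
        "snapshots": out / "snapshots.csv",
        "contacts": out / "contacts.csv",
        "metrics": out / "metrics.csv",
        "manifest": out / "manifest.json",
    }
    snap_cols = [
        "time_min", "cell_id", "x_um", "y_um", "radius_um", "phase",
        "free_E_pct", "free_B_pct", "cyto_EB_pct", "n_neighbours", "pressure_pN",
    ]
    contact_cols = [
        "time_min", "cell_i", "cell_j", "area_um2", "EBc_i_pct", "EBc_j_pct", "force_pN",
    ]
    metric_cols = [
        "time_min", "n_cells", "mean_contact_force_pN", "mean_free_E_pct",
        "histogram_mode", "status",
    ]
    pd.DataFrame(snap_rows, columns=snap_cols).to_csv(paths["snapshots"], index=False)
    pd.DataFrame(contact_rows, columns=contact_cols).to_csv(paths["contacts"], index=False)
    pd.DataFrame(metric_rows, columns=metric_cols).to_csv(paths["metrics"], index=False)
    manifest = {
        "config": config_to_dict(trajectory.config),
        "seed": trajectory.config.seed,
        "status": trajectory.status,
        "wall_clock_s": trajectory.wall_clock_s,
        "n_snapshots": len(trajectory.snapshots),
        "versions": {
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    paths["manifest"].write_text(json.dumps(manifest, indent=2))
    return paths
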