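"""Colony metrics, growth-law fitting, scenarios, file I/O and CLI."""

import json
import math

import numpy as np
import pandas as pd
import pytest

from cellcolony.core_state import ContactSite, KineticParams, ModelVariant, WorldState
from cellcolony.engine import RunConfig, Trajectory, run
from cellcolony.metrics_io import (
    SCENARIO_NAMES,
    fit_exponential_growth,
    make_scenario,
    mean_contact_force,
    neighbour_histogram,
    pair_distance_for_contact_area,
    read_config,
    snapshot_metrics,
    write_config,
    write_outputs,
    config_to_dict,
    config_from_dict,
)

from conftest import fresh_cell


def hexagon_world(spacing=8.5):
    cells = [fresh_cell(0)]
    for k in range(6):
        ang = k * math.pi / 3
        cells.append(fresh_cell(k + 1, spacing * math.cos(ang), spacing * math.sin(ang)))
    return WorldState(cells=cells)


class TestNeighbourHistogram:
    def test_two_touching_cells(self):
        w = WorldState(cells=[fresh_cell(0), fresh_cell(1, 9.0, 0.0)])
        assert neighbour_histogram(w) == {1: 2}

    def test_hexagon_centre_has_six_neighbours(self):
        hist = neighbour_histogram(hexagon_world())
        assert hist == {6: 1, 3: 6}  # rim cells touch centre and two rim mates

    def test_histogram_totals_cell_count(self):
        w = hexagon_world()
        assert sum(neighbour_histogram(w).values()) == len(w.cells)

    def test_empty_world(self):
        assert neighbour_histogram(WorldState(cells=[])) == {}


class TestMeanContactForce:
    def test_no_contacts_gives_zero(self):
        w = WorldState(cells=[fresh_cell(0), fresh_cell(1, 30.0, 0.0)])
        assert mean_contact_force(w, ModelVariant.MODEL2) == 0.0

    def test_single_pair_at_model2_anchor(self):
        a = fresh_cell(0)
        b = fresh_cell(1, 8.0, 0.0)  # inside the ~8.52 µm natural state
        a.E -= 80.0
        b.E -= 80.0
        a.contacts[1] = ContactSite(partner_id=1, area=5.0, prev_area=5.0, EBc=80.0)
        b.contacts[0] = ContactSite(partner_id=0, area=5.0, prev_area=5.0, EBc=80.0)
        w = WorldState(cells=[a, b])
        assert mean_contact_force(w, ModelVariant.MODEL2) == pytest.approx(210_000.0)
        # Model 3: the same pair inside its natural state resists nothing
        assert mean_contact_force(w, ModelVariant.MODEL3) == pytest.approx(0.0)

    def test_invariant_under_relabelling(self):
        w1 = WorldState(cells=[fresh_cell(0), fresh_cell(1, 9.0, 0.0)])
        w2 = WorldState(cells=[fresh_cell(7, 9.0, 0.0), fresh_cell(3)])
        for w in (w1, w2):
            for a in w.cells:
                for b in w.cells:
                    if a.id != b.id:
                        a.contacts[b.id] = ContactSite(partner_id=b.id, EBc=40.0, area=3.0)
        assert mean_contact_force(w1, ModelVariant.MODEL2) == pytest.approx(
            mean_contact_force(w2, ModelVariant.MODEL2)
        )


class TestGrowthFit:
    def test_recovers_generating_rate_exactly(self):
        t = np.arange(8.0)
        counts = 2.0 * np.exp(0.83 * t)
        rate, doubling = fit_exponential_growth(t, counts)
        assert rate == pytest.approx(0.83, abs=1e-10)
        assert doubling == pytest.approx(math.log(2) / 0.83 * 24.0, abs=1e-8)

    def test_constant_counts_give_zero_rate(self):
        rate, doubling = fit_exponential_growth([0, 1, 2, 3], [5, 5, 5, 5])
        assert rate == pytest.approx(0.0, abs=1e-12)
        assert doubling == math.inf

    def test_input_validation(self):
        with pytest.raises(ValueError):
            fit_exponential_growth([0, 1], [1, 2])
        with pytest.raises(ValueError):
            fit_exponential_growth([0, 1, 2], [1, 0, 2])


class TestScenarios:
    def test_two_cell_initial_contact_area_is_one_micron(self):
        cfg = make_scenario("two_cell")
        d = cfg.initial_cells[1].position[0]
        assert d == pytest.approx(pair_distance_for_contact_area(5.0, 1.0))
        assert cfg.duration == 100.0
        assert cfg.cycle_enabled is False

    def test_staggered_scenario_schedules_second_neighbour_at_20min(self):
        cfg = make_scenario("three_cell_staggered")
        assert len(cfg.initial_cells) == 2
        assert len(cfg.arrivals) == 1
        assert cfg.arrivals[0].time == 20.0

    def test_single_cell_colony_defaults(self):
        cfg = make_scenario("single_cell_colony")
        assert cfg.variant is ModelVariant.MODEL3
        assert cfg.contact_inhibition
        assert cfg.duration == 7 * 1440.0
        assert set(cfg.forced_snapshot_times) == {3 * 1440.0, 7 * 1440.0}

    def test_hexagon_test_layout(self):
        cfg = make_scenario("hexagon_test")
        assert len(cfg.initial_cells) == 7

    def test_overrides(self):
        cfg = make_scenario("single_cell_colony", rho_d=5.0, duration_days=2.0, seed=9)
        assert cfg.kinetic.rho_d == 5.0
        assert cfg.duration == 2880.0
        assert cfg.seed == 9

    def test_unknown_scenario_rejected(self):
        with pytest.raises(ValueError):
            make_scenario("mystery")
        with pytest.raises(ValueError):
            make_scenario("two_cell", nonsense=1)


class TestIO:
    def test_config_round_trip_yaml_and_json(self, tmp_path):
        cfg = make_scenario("three_cell_staggered", seed=3)
        for name in ("c.yaml", "c.json"):
            path = tmp_path / name
            write_config(cfg, path)
            back = read_config(path)
            assert config_to_dict(back) == config_to_dict(cfg)

    def test_unknown_config_keys_rejected(self):
        with pytest.raises(ValueError, match="unknown config keys"):
            config_from_dict({"variant": "model2", "bogus": 1})

    def test_outputs_written_with_expected_schema(self, tmp_path):
        cfg = make_scenario("two_cell", duration=2.0)
        traj = run(cfg)
        paths = write_outputs(traj, tmp_path / "out")
        snaps = pd.read_csv(paths["snapshots"])
        assert list(snaps.columns) == [
            "time_min", "cell_id", "x_um", "y_um", "radius_um", "phase",
            "free_E_pct", "free_B_pct", "cyto_EB_pct", "n_neighbours",
            "pressure_pN",
        ]
        counts = snaps.groupby("time_min").size()
        assert (counts == 2).all()
        manifest = json.loads(paths["manifest"].read_text())
        assert manifest["status"] == "done"
        assert manifest["config"]["seed"] == cfg.seed

    def test_empty_trajectory_gives_header_only_csvs(self, tmp_path):
        cfg = RunConfig(initial_cells=[], duration=0.0, cycle_enabled=False)
        traj = run(cfg)
        paths = write_outputs(traj, tmp_path / "out")
        snaps = pd.read_csv(paths["snapshots"])
        assert len(snaps) == 0 and "cell_id" in snaps.columns


class TestCLI:
    def test_run_and_metrics_commands(self, tmp_path):
        from click.testing import CliRunner

        from cellcolony.cli import main

        runner = CliRunner()
        out_dir = tmp_path / "out"
        res = runner.invoke(
            main,
            ["run", "--scenario", "two_cell", "--seed", "1", "--out-dir", str(out_dir)],
        )
        assert res.exit_code == 0, res.output
        assert (out_dir / "snapshots.csv").exists()
        res2 = runner.invoke(
            main,
            ["metrics", "--snapshots", str(out_dir / "snapshots.csv"),
             "--out", str(tmp_path / "g.csv")],
        )
        assert res2.exit_code == 0, res2.output

    def test_fit_command_smoke(self, tmp_path):
        from click.testing import CliRunner

        from cellcolony.calibration import make_synthetic_pipette_dataset
        from cellcolony.cli import main

        data = make_synthetic_pipette_dataset()
        ts, es = tmp_path / "ts.csv", tmp_path / "es.csv"
        data.to_csv(ts, es)
        runner = CliRunner()
        res = runner.invoke(
            main,
            ["fit", "--time-series", str(ts), "--expression-series", str(es),
             "--restarts", "1", "--no-fit-gamma", "--seed", "0",
             "--out", str(tmp_path / "fit.json")],
        )
        assert res.exit_code == 0, res.output
        report = json.loads((tmp_path / "fit.json").read_text())
        assert report["parameters"]["rho_u"] == pytest.approx(8.2, rel=0.2)
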