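"""Hertz repulsion, bond-to-force maps, pressure and overdamped motion."""

import math

import numpy as np
import pytest

from cellcolony.core_state import (
    CellState,
    ContactSite,
    MechParams,
    ModelVariant,
    Phase,
    WorldState,
    natural_state_distance,
)
from cellcolony.mechanics import (
    adhesion_force,
    hertz_force,
    hertz_potential,
    motion_step,
    net_force_and_pressure,
)

from conftest import fresh_cell


class TestHertz:
    def test_zero_without_overlap(self):
        assert hertz_force(10.0, 5.0, 5.0) == 0.0
        assert hertz_force(12.3, 5.0, 5.0) == 0.0

    def test_monolayer_spacing_force(self):
        # at 8.5 µm the repulsion is ≈ 13000/6 pN (Table-1 parameters)
        f = hertz_force(8.5, 5.0, 5.0)
        assert f == pytest.approx(13_000.0 / 6.0, rel=0.01)

    def test_strictly_increasing_with_overlap(self):
        forces = [hertz_force(d, 5.0, 5.0) for d in np.linspace(9.9, 4.0, 40)]
        assert all(b > a for a, b in zip(forces, forces[1:]))

    def test_force_is_negative_potential_gradient(self, rng):
        """F = −dV/dd on random parameter tuples (numerical derivative)."""
        for _ in range(100):
            Ri, Rj = rng.uniform(3, 7, 2)
            sig = rng.uniform(0.0, 0.45)
            E = rng.uniform(200, 5000)
            d = rng.uniform(0.5 * (Ri + Rj), 0.99 * (Ri + Rj))
            eps = 1e-6
            dv = (
                hertz_potential(d + eps, Ri, Rj, sig, sig, E, E)
                - hertz_potential(d - eps, Ri, Rj, sig, sig, E, E)
            ) / (2 * eps)
            f = hertz_force(d, Ri, Rj, sig, sig, E, E)
            assert f == pytest.approx(-dv, rel=1e-6)


class TestAdhesionMap:
    @pytest.mark.parametrize(
        "variant, m, expect_nN",
        [
            (ModelVariant.MODEL2, 80.0, 210.0),  # dynamic-adhesion anchor
            (ModelVariant.MODEL1, 15.0, 210.0),  # static-adhesion anchor
            (ModelVariant.MODEL2, 0.0, 0.0),
            (ModelVariant.MODEL2, 40.0, 105.0),
            (ModelVariant.MODEL1, 16.667, 210.0 * 16.667 / 15.0),  # linear beyond
        ],
    )
    def test_anchors_and_linearity(self, variant, m, expect_nN):
        f = adhesion_force(variant, m, m, d=20.0, R_i=5.0, R_j=5.0)
        assert f == pytest.approx(expect_nN * 1000.0, rel=1e-9)

    def test_limiting_side_sets_the_force(self):
        f = adhesion_force(ModelVariant.MODEL2, 80.0, 20.0, d=20.0)
        assert f == pytest.approx(20.0 / 80.0 * 210_000.0)

    def test_model3_gated_inside_natural_state(self):
        dnat = natural_state_distance(5.0)
        assert adhesion_force(ModelVariant.MODEL3, 80.0, 80.0, d=8.0) == 0.0
        assert adhesion_force(ModelVariant.MODEL3, 80.0, 80.0, d=dnat) == 0.0
        assert adhesion_force(ModelVariant.MODEL3, 80.0, 80.0, d=dnat + 1e-6) > 0.0

    def test_negative_bond_level_rejected(self):
        with pytest.raises(ValueError):
            adhesion_force(ModelVariant.MODEL2, -1.0, 10.0)


def hexagon_world(spacing=8.5):
    cells = [fresh_cell(0, 0.0, 0.0)]
    for k in range(6):
        ang = k * math.pi / 3
        cells.append(fresh_cell(k + 1, spacing * math.cos(ang), spacing * math.sin(ang)))
    return WorldState(cells=cells)


class TestNetForceAndPressure:
    def test_isolated_cell(self, mech):
        w = WorldState(cells=[fresh_cell(0)])
        f, p = net_force_and_pressure(w.cells[0], w, ModelVariant.MODEL2, mech)
        assert np.allclose(f, 0.0) and p == 0.0

    def test_hexagon_centre_feels_threshold_pressure(self, mech):
        """Six neighbours at 8.5 µm: zero net force, ≈13000 pN pressure."""
        w = hexagon_world()
        f, p = net_force_and_pressure(w.cells[0], w, ModelVariant.MODEL2, mech)
        assert np.linalg.norm(f) < 1e-6
        assert p == pytest.approx(13_000.0, rel=0.01)

    def test_newtons_third_law(self, mech, touching_pair):
        w = touching_pair
        w.cells[0].contacts[1].EBc = 30.0
        w.cells[1].contacts[0].EBc = 50.0
        f0, _ = net_force_and_pressure(w.cells[0], w, ModelVariant.MODEL2, mech)
        f1, _ = net_force_and_pressure(w.cells[1], w, ModelVariant.MODEL2, mech)
        assert np.allclose(f0, -f1)

    def test_m_phase_siblings_do_not_interact(self, mech):
        a = fresh_cell(0, 0.0, 0.0, phase=Phase.M)
        b = fresh_cell(1, 4.0, 0.0, phase=Phase.M)
        a.sibling_id, b.sibling_id = 1, 0
        w = WorldState(cells=[a, b])
        f, p = net_force_and_pressure(a, w, ModelVariant.MODEL2, mech)
        assert np.allclose(f, 0.0) and p == 0.0


class TestMotion:
    def test_no_force_no_motion(self, mech):
        w = WorldState(cells=[fresh_cell(0, 1.0, 2.0)])
        motion_step(w, 1.0, ModelVariant.MODEL2, mech)
        assert w.cells[0].position == (1.0, 2.0)

    def test_stokes_drag_unit_conversion(self, mech):
        # 942.5 pN on an R = 5 µm cell in 10 Pa·s medium → 1 µm/s
        drag = mech.drag_pN_min_per_um
        v_um_per_s = 942.5 / drag / 60.0
        assert v_um_per_s == pytest.approx(1.0, rel=1e-3)

    def test_overlapping_pair_separates_monotonically(self, mech):
        a = fresh_cell(0, 0.0, 0.0)
        b = fresh_cell(1, 8.0, 0.0)
        w = WorldState(cells=[a, b])
        gaps = []
        for _ in range(50):
            motion_step(w, 0.01, ModelVariant.MODEL2, mech)
            gaps.append(w.cells[1].position[0] - w.cells[0].position[0])
        assert all(b2 >= b1 for b1, b2 in zip(gaps, gaps[1:]))
        assert gaps[-1] <= 10.0 + 1e-6  # stops at tangency, no overshoot beyond

    def test_noise_has_zero_mean_displacement(self, mech):
        """Noisy displacements average to the deterministic drift."""
        mech = MechParams(noise_diffusion=0.05)
        rng = np.random.default_rng(7)
        disp = []
        for _ in range(2000):
            w = WorldState(cells=[fresh_cell(0)])
            motion_step(w, 0.5, ModelVariant.MODEL2, mech, rng=rng)
            disp.append(w.cells[0].position)
        mean = np.mean(disp, axis=0)
        sem = math.sqrt(2 * 0.05 * 0.5 / len(disp))
        assert abs(mean[0]) < 4 * sem and abs(mean[1]) < 4 * sem


class TestModel3Equilibrium:
    def test_adherent_pair_relaxes_between_natural_state_and_tangency(self, mech):
        a = fresh_cell(0, 0.0, 0.0)
        b = fresh_cell(1, 9.0, 0.0)
        a.contacts[1] = ContactSite(partner_id=1, area=5.0, prev_area=5.0, EBc=30.0)
        b.contacts[0] = ContactSite(partner_id=0, area=5.0, prev_area=5.0, EBc=30.0)
        w = WorldState(cells=[a, b])
        for _ in range(200):
            motion_step(w, 0.01, ModelVariant.MODEL3, mech)
        d3 = abs(w.cells[1].position[0] - w.cells[0].position[0])
        dnat = natural_state_distance(5.0)
        assert dnat - 0.1 <= d3 <= 10.0

    def test_model2_equilibrium_is_strictly_tighter(self, mech):
        def relax(variant):
            a = fresh_cell(0, 0.0, 0.0)
            b = fresh_cell(1, 9.0, 0.0)
            a.contacts[1] = ContactSite(partner_id=1, area=5.0, prev_area=5.0, EBc=1.0)
            b.contacts[0] = ContactSite(partner_id=0, area=5.0, prev_area=5.0, EBc=1.0)
            w = WorldState(cells=[a, b])
            for _ in range(300):
                motion_step(w, 0.01, variant, mech)
            return abs(w.cells[1].position[0] - w.cells[0].position[0])

        # small, fixed bond level: Model 2 pulls to a force balance, Model 3
        # stops at the natural state
        assert relax(ModelVariant.MODEL2) < relax(ModelVariant.MODEL3)
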