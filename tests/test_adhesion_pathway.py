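"""Compartment kinetics: fluxes, caps, conservation, steady states."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cellcolony.adhesion_pathway import (
    area_change_factors,
    exocytosis_model1,
    exocytosis_model2,
    pathway_rhs,
    redistribution,
    step_pathway,
    tau_E,
)
from cellcolony.core_state import CellState, ContactSite, KineticParams, ModelVariant

from conftest import fresh_cell


def equilibrated_cell(expression=100.0, **kw):
    """Cell with the cytosolic binding equilibrium already reached."""
    # 0 = nu_p(Et−c)(100−c) − nu_n·c  with Table rates and Et=100
    c = (230.0 - math.sqrt(230.0**2 - 4 * 10_000.0)) / 2.0
    cell = fresh_cell(expression=expression, **kw)
    if expression == 100.0:
        cell.E = 100.0 - c
        cell.B = 100.0 - c
        cell.EB = c
    return cell


class TestAreaChangeFactors:
    @pytest.mark.parametrize(
        "prev, area, a_c, a_d",
        [
            (10.0, 10.0, 0.0, 0.0),
            (10.0, 0.0, 0.0, 1.0),  # complete disassembly
            (8.0, 10.0, 0.2, 0.0),  # 20% gain relative to current area
            (10.0, 8.0, 0.0, 0.2),
            (0.0, 10.0, 1.0, 0.0),  # de-novo contact
        ],
    )
    def test_examples(self, prev, area, a_c, a_d):
        site = ContactSite(partner_id=1, area=area, prev_area=prev)
        assert area_change_factors(site) == (
            pytest.approx(a_c),
            pytest.approx(a_d),
        )

    @given(st.floats(0, 100), st.floats(0, 100))
    @settings(max_examples=100, deadline=None)
    def test_factors_bounded(self, prev, area):
        a_c, a_d = area_change_factors(
            ContactSite(partner_id=1, area=area, prev_area=prev)
        )
        assert 0.0 <= a_c <= 1.0
        assert 0.0 <= a_d <= 1.0
        assert a_c == 0.0 or a_d == 0.0


class TestExocytosis:
    def test_undirected_part_scales_with_area_fraction(self, kinetic):
        cell = fresh_cell()
        cell.EB = 50.0
        site = ContactSite(partner_id=1, area=21.53, prev_area=21.53)
        cell.contacts[1] = site
        flux = exocytosis_model1(cell, site, a_c=0.0, params=kinetic)
        # rho_u·EB·A/(4πR²) = 8.2·50·21.53/314.16
        assert flux == pytest.approx(8.2 * 50.0 * 21.53 / (4 * math.pi * 25.0), rel=1e-3)

    def test_model1_saturates_at_per_site_cap(self, kinetic):
        cell = fresh_cell()
        cell.EB = 50.0
        site = ContactSite(partner_id=1, area=10.0, prev_area=10.0, EBc=tau_E(100.0))
        cell.contacts[1] = site
        assert exocytosis_model1(cell, site, a_c=1.0, params=kinetic) == 0.0

    def test_model2_saturates_at_global_cap(self, kinetic):
        cell = fresh_cell()
        cell.EB = 50.0
        cell.contacts[1] = ContactSite(partner_id=1, area=10.0, prev_area=10.0, EBc=50.0)
        cell.contacts[2] = ContactSite(partner_id=2, area=10.0, prev_area=10.0, EBc=30.0)
        assert exocytosis_model2(cell, cell.contacts[1], a_c=1.0, params=kinetic) == 0.0

    def test_no_cytosolic_complexes_no_flux(self, kinetic):
        cell = fresh_cell()
        site = ContactSite(partner_id=1, area=10.0, prev_area=10.0)
        cell.contacts[1] = site
        assert exocytosis_model1(cell, site, 1.0, kinetic) == 0.0
        assert exocytosis_model2(cell, site, 1.0, kinetic) == 0.0


class TestRedistribution:
    def test_positive_bracket_rule(self):
        r_in, r_out = redistribution([30.0, 10.0, 20.0], gamma=0.16)
        assert r_in[1] == pytest.approx(0.16 * ((30 - 10) + (20 - 10)))
        assert r_out[1] == 0.0
        assert r_in[0] == 0.0
        assert r_out[0] == pytest.approx(0.16 * ((30 - 10) + (30 - 20)))

    @pytest.mark.parametrize("values", [[5.0], [7.0, 7.0, 7.0]])
    def test_degenerate_cases_are_quiescent(self, values):
        r_in, r_out = redistribution(values, gamma=0.16)
        assert all(v == 0.0 for v in r_in + r_out)

    @given(st.lists(st.floats(0, 80), min_size=1, max_size=6))
    @settings(max_examples=100, deadline=None)
    def test_redistribution_conserves_complexes(self, values):
        r_in, r_out = redistribution(values, gamma=0.16)
        assert sum(r_in) == pytest.approx(sum(r_out), abs=1e-9)


class TestPathwayRhs:
    def test_isolated_cell_steady_state_quadratic(self, kinetic):
        # 0.02(100−c)² = 0.6c  →  c = (230 − sqrt(12900))/2 ≈ 58.2
        cell = equilibrated_cell()
        assert cell.EB == pytest.approx(58.21, abs=0.01)
        dE, dB, dEB, dC = pathway_rhs(cell, ModelVariant.MODEL2, kinetic)
        assert dE == pytest.approx(0.0, abs=1e-9)
        assert dEB == pytest.approx(0.0, abs=1e-9)

    def test_total_derivatives_vanish(self, kinetic, rng):
        cell = fresh_cell()
        cell.E, cell.B, cell.EB = 30.0, 25.0, 25.0
        cell.contacts[1] = ContactSite(partner_id=1, area=5.0, prev_area=4.0, EBc=30.0)
        cell.contacts[2] = ContactSite(partner_id=2, area=3.0, prev_area=6.0, EBc=15.0)
        dE, dB, dEB, dC = pathway_rhs(cell, ModelVariant.MODEL2, kinetic,
                                      area_rates={1: (0.25, 0.0), 2: (0.0, 0.5)})
        assert dE + dEB + sum(dC.values()) == pytest.approx(0.0, abs=1e-9)
        assert dB + dEB + sum(dC.values()) == pytest.approx(0.0, abs=1e-9)

    def test_detached_site_drains_at_rho_d(self):
        params = KineticParams(rho_d=0.5)
        cell = fresh_cell()
        cell.E, cell.EB = 60.0, 0.0
        cell.B = 60.0
        cell.contacts[1] = ContactSite(partner_id=1, area=0.0, prev_area=3.0, EBc=40.0)
        _, _, dEB, dC = pathway_rhs(cell, ModelVariant.MODEL2, params)
        assert dC[1] == pytest.approx(-20.0)  # ρ_d·a_d·EBc with a_d = 1
        assert dEB == pytest.approx(20.0 + 0.02 * 60 * 60)

    def test_negative_concentration_rejected(self, kinetic):
        cell = fresh_cell()
        cell.E = -1.0
        with pytest.raises(ValueError):
            pathway_rhs(cell, ModelVariant.MODEL2, kinetic)


class TestStepPathway:
    def test_euler_step_matches_rhs_in_small_dt_limit(self, kinetic):
        cell = fresh_cell()
        cell.contacts[1] = ContactSite(partner_id=1, area=5.0, prev_area=5.0, EBc=10.0)
        dt = 1e-6
        dE, dB, dEB, dC = pathway_rhs(cell, ModelVariant.MODEL2, kinetic)
        out = step_pathway(cell, dt, ModelVariant.MODEL2, kinetic)
        assert out.E - cell.E == pytest.approx(dE * dt, rel=1e-4)
        assert out.EB - cell.EB == pytest.approx(dEB * dt, rel=1e-4)

    def test_conservation_over_many_random_steps(self, kinetic, rng):
        cell = fresh_cell()
        cell.contacts[1] = ContactSite(partner_id=1, area=1.0, prev_area=1.0)
        cell.contacts[2] = ContactSite(partner_id=2, area=2.0, prev_area=2.0)
        for _ in range(2000):
            for site in cell.contacts.values():
                site.prev_area = site.area
                site.area = max(0.0, site.area + rng.normal(0.0, 0.5))
            cell = step_pathway(cell, 0.01, ModelVariant.MODEL2, kinetic)
            re_, rb = cell.conservation_residuals()
            assert abs(re_) < 1e-6 and abs(rb) < 1e-6
            assert min(cell.E, cell.B, cell.EB) >= 0.0

    def test_model1_per_site_cap_never_exceeded(self, kinetic, rng):
        cell = fresh_cell()
        cell.contacts[1] = ContactSite(partner_id=1, area=20.0, prev_area=20.0)
        for _ in range(3000):
            site = cell.contacts[1]
            site.prev_area = site.area
            site.area = max(0.1, site.area + rng.normal(0.0, 1.0))
            cell = step_pathway(cell, 0.02, ModelVariant.MODEL1, kinetic)
            assert cell.contacts[1].EBc <= tau_E(cell.expression) + 1e-9

    def test_model2_global_cap_never_exceeded(self, kinetic, rng):
        cell = fresh_cell()
        cell.contacts[1] = ContactSite(partner_id=1, area=25.0, prev_area=25.0)
        cell.contacts[2] = ContactSite(partner_id=2, area=25.0, prev_area=25.0)
        for _ in range(3000):
            for site in cell.contacts.values():
                site.prev_area = site.area
                site.area = max(0.1, site.area + rng.normal(0.0, 1.0))
            cell = step_pathway(cell, 0.02, ModelVariant.MODEL2, kinetic)
            assert cell.bound_total() <= 0.8 * cell.expression + 1e-9

    def test_two_site_redistribution_equalises(self, kinetic):
        """Fixed equal areas, asymmetric start: sites converge, total kept."""
        cell = fresh_cell()
        cell.E, cell.B, cell.EB = 10.0, 10.0, 10.0
        cell.contacts[1] = ContactSite(partner_id=1, area=5.0, prev_area=5.0, EBc=80.0)
        cell.contacts[2] = ContactSite(partner_id=2, area=5.0, prev_area=5.0, EBc=0.0)
        params = KineticParams(rho_u=0.0, nu_n=0.0, nu_p=0.0, rho_c=0.0, gamma=0.16)
        for _ in range(4000):
            cell = step_pathway(cell, 0.01, ModelVariant.MODEL2, params)
        a, b = cell.contacts[1].EBc, cell.contacts[2].EBc
        assert a == pytest.approx(b, abs=1e-3)
        assert a + b == pytest.approx(80.0, abs=1e-9)

    def test_drained_detached_site_is_removed(self, kinetic):
        cell = fresh_cell()
        cell.E, cell.B = 98.0, 98.0
        cell.contacts[1] = ContactSite(partner_id=1, area=0.0, prev_area=5.0, EBc=2.0)
        params = KineticParams(rho_d=500.0)
        cell = step_pathway(cell, 0.05, ModelVariant.MODEL2, params)
        assert 1 not in cell.contacts
        re_, rb = cell.conservation_residuals()
        assert abs(re_) < 1e-9

    def test_dt_must_be_positive(self, kinetic):
        with pytest.raises(ValueError):
            step_pathway(fresh_cell(), 0.0, ModelVariant.MODEL2, kinetic)

    def test_step_halving_convergence_isolated(self, kinetic):
        """Richardson-style check: halving dt barely changes the outcome."""
        def final_EB(dt):
            cell = fresh_cell()
            cell.contacts[1] = ContactSite(partner_id=1, area=1.0, prev_area=1.0)
            for _ in range(int(round(20.0 / dt))):
                cell = step_pathway(cell, dt, ModelVariant.MODEL2, kinetic)
            return cell.contacts[1].EBc

        coarse, fine = final_EB(0.01), final_EB(0.005)
        assert coarse == pytest.approx(fine, rel=0.01)
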