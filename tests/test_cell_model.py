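"""Unit and property tests of the Wigner–Seitz cell free-energy model."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate

from brushpack import cell_model as cm
from brushpack.cell_model import (
    BrushGeometry,
    UnphysicalStateError,
    bjerrum_length,
    charge_density,
    counterion_entropy,
    elastic_energy,
    flory_energy,
    hartree_energy,
    hartree_from_profile,
    ideal_gas_free_energy,
    insertion_free_energy,
    make_state,
    manning_condensed,
    minimize_free_energy,
    size_vs_packing,
    total_free_energy,
)


class TestBjerrumLength:
    def test_water_at_room_temperature(self):
        # e²/(4π ε0 εr kB T) with CODATA constants
        assert bjerrum_length(298.0, 78.5) == pytest.approx(0.7143, abs=1e-3)

    def test_inverse_proportionality_in_permittivity(self):
        assert bjerrum_length(298.0, 157.0) / bjerrum_length(298.0, 78.5) == (
            pytest.approx(0.5)
        )

    def test_vanishes_at_infinite_permittivity(self):
        assert bjerrum_length(298.0, 1e12) == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("T,eps", [(0.0, 80.0), (-1.0, 80.0), (300.0, 0.0)])
    def test_nonpositive_inputs_rejected(self, T, eps):
        with pytest.raises(ValueError):
            bjerrum_length(T, eps)


class TestManningCondensation:
    def test_no_condensation_at_threshold(self):
        lam = bjerrum_length(298.0, 78.5)
        geom = BrushGeometry(f=30, N=40, R_PS=10.0, b=lam)
        assert geom.xi == pytest.approx(1.0)
        assert manning_condensed(geom) == 0.0

    def test_half_condensed_at_xi_two(self):
        lam = bjerrum_length(298.0, 78.5)
        geom = BrushGeometry(f=30, N=40, R_PS=10.0, b=lam / 2)
        assert manning_condensed(geom) == pytest.approx(600.0)

    def test_dsdna_condensed_fraction_matches_arithmetic(self):
        geom = BrushGeometry(f=100, N=100, R_PS=20.0, b=0.17)
        xi = bjerrum_length(298.0, 78.5) / 0.17
        assert manning_condensed(geom) / geom.total_charge == pytest.approx(
            1.0 - 1.0 / xi
        )


class TestChargeDensity:
    def test_neutrality_by_quadrature(self, mini_geom):
        state = make_state(mini_geom, R_W=50.0, L=4.0, N3=25.0)
        total, _ = integrate.quad(
            lambda r: charge_density(r, state, mini_geom) * 4 * np.pi * r**2,
            0.0, state.R_W, points=[mini_geom.R_PS, state.R(mini_geom)],
            limit=200,
        )
        assert abs(total) < 1e-8 * state.N3

    def test_zero_everywhere_without_escaped_ions(self, mini_geom):
        state = make_state(mini_geom, R_W=50.0, L=4.0, N3=0.0)
        r = np.linspace(0.0, 50.0, 64)
        assert np.all(charge_density(r, state, mini_geom) == 0.0)

    def test_inverse_square_profile_inside_brush(self, mini_geom):
        state = make_state(mini_geom, R_W=80.0, L=6.0, N3=10.0)
        r1, r2 = 11.0, 13.0
        rho1 = charge_density(r1, state, mini_geom)
        rho2 = charge_density(r2, state, mini_geom)
        assert rho1 / rho2 == pytest.approx((r2 / r1) ** 2)
        assert rho1 < 0  # brush interior carries the net negative charge

    def test_out_of_cell_rejected(self, mini_geom):
        state = make_state(mini_geom, R_W=50.0, L=4.0, N3=5.0)
        with pytest.raises(ValueError):
            charge_density(51.0, state, mini_geom)


class TestHartreeEnergy:
    def test_uniform_sphere_matches_closed_form(self):
        # self-energy of a uniform ball: U = (3/5) λ_B Q² / R
        Q, R, lam = 50.0, 8.0, 0.714
        rho0 = Q / (4 * np.pi / 3 * R**3)
        val = hartree_from_profile(
            lambda r: rho0 if r < R else 0.0, 3 * R, lam, points=[R]
        )
        exact = 0.6 * lam * Q**2 / R
        assert val == pytest.approx(exact, rel=1e-3)

    def test_analytic_matches_quadrature_on_cell_profile(self, mini_geom):
        state = make_state(mini_geom, R_W=40.0, L=5.0, N3=30.0)
        ana = hartree_energy(state, mini_geom, method="analytic")
        quad = hartree_energy(state, mini_geom, method="quadrature")
        assert ana == pytest.approx(quad, rel=1e-6)
        assert ana > 0

    def test_zero_without_charge_separation(self, mini_geom):
        state = make_state(mini_geom, R_W=40.0, L=5.0, N3=0.0)
        assert hartree_energy(state, mini_geom) == 0.0

    def test_scales_inversely_with_permittivity(self, mini_geom):
        half_eps = BrushGeometry(
            f=mini_geom.f, N=mini_geom.N, R_PS=mini_geom.R_PS,
            eps_r=mini_geom.eps_r / 2,
        )
        s1 = make_state(mini_geom, R_W=40.0, L=5.0, N3=20.0)
        s2 = make_state(half_eps, R_W=40.0, L=5.0, N3=20.0)
        assert hartree_energy(s2, half_eps) == pytest.approx(
            2.0 * hartree_energy(s1, mini_geom), rel=1e-9
        )

    def test_stable_when_brush_nearly_fills_cell(self, mini_geom):
        # the outer-shell integral must not suffer cancellation as R → R_W
        L = mini_geom.contour_length
        R_W = (mini_geom.R_PS + L) * (1 + 1e-9)
        state = make_state(mini_geom, R_W=R_W, L=L, N3=10.0)
        val = hartree_energy(state, mini_geom)
        assert np.isfinite(val) and val > 0


class TestElasticEnergy:
    def test_monotone_in_stretching(self, mini_geom):
        vals = [
            elastic_energy(make_state(mini_geom, 50.0, L, 0.0), mini_geom)
            for L in np.linspace(0.5, mini_geom.contour_length, 10)
        ]
        assert np.all(np.diff(vals) > 0)

    def test_proportional_to_chain_count(self, mini_geom):
        doubled = BrushGeometry(f=2 * mini_geom.f, N=mini_geom.N,
                                R_PS=mini_geom.R_PS)
        s1 = make_state(mini_geom, 50.0, 4.0, 0.0)
        s2 = make_state(doubled, 50.0, 4.0, 0.0)
        assert elastic_energy(s2, doubled) == pytest.approx(
            2 * elastic_energy(s1, mini_geom)
        )

    def test_value_matches_independent_transcription(self, mini_geom):
        L = 4.0
        state = make_state(mini_geom, 50.0, L, 0.0)
        expected = 1.5 * mini_geom.f * L**2 / (mini_geom.N * mini_geom.b**2)
        assert elastic_energy(state, mini_geom) == pytest.approx(expected)

    def test_overstretching_rejected(self, mini_geom):
        state = make_state(mini_geom, 50.0, mini_geom.contour_length, 0.0)
        object.__setattr__(state, "L", mini_geom.contour_length * 1.5)
        with pytest.raises(ValueError):
            elastic_energy(state, mini_geom)


class TestFloryEnergy:
    def test_quadratic_in_total_monomer_count(self, mini_geom):
        doubled = BrushGeometry(f=2 * mini_geom.f, N=mini_geom.N,
                                R_PS=mini_geom.R_PS)
        s1 = make_state(mini_geom, 50.0, 4.0, 0.0)
        s2 = make_state(doubled, 50.0, 4.0, 0.0)
        assert flory_energy(s2, doubled) == pytest.approx(
            4 * flory_energy(s1, mini_geom)
        )

    def test_vanishes_in_dilution_limit(self):
        geom = BrushGeometry(f=10, N=4000, R_PS=10.0)  # long chains, huge brush
        small = flory_energy(make_state(geom, 1e5, 600.0, 0.0), geom)
        tiny = flory_energy(make_state(geom, 1e5, 650.0, 0.0), geom)
        assert tiny < small < 4 * flory_energy(
            make_state(geom, 1e5, 300.0, 0.0), geom
        )

    def test_value_matches_independent_transcription(self, mini_geom):
        L = 4.0
        state = make_state(mini_geom, 50.0, L, 0.0)
        v_m = 4 * np.pi / 3 * mini_geom.R_m**3
        vol = 4 * np.pi / 3 * ((mini_geom.R_PS + L) ** 3 - mini_geom.R_PS**3)
        expected = 0.5 * v_m * (mini_geom.N * mini_geom.f) ** 2 / vol
        assert flory_energy(state, mini_geom) == pytest.approx(expected)


class TestCounterionEntropy:
    def test_empty_outside_population_contributes_nothing(self, mini_geom):
        state = make_state(mini_geom, 50.0, 4.0, 0.0)
        assert counterion_entropy(state, mini_geom, "outside") == 0.0

    def test_outside_term_gains_entropy_with_cell_size(self, mini_geom):
        vals = [
            counterion_entropy(make_state(mini_geom, R_W, 4.0, 30.0),
                               mini_geom, "outside")
            for R_W in [30.0, 60.0, 120.0]
        ]
        assert np.all(np.diff(vals) < 0)

    def test_uniform_density_closed_form(self):
        # ideal gas at uniform density: -TS = N (ln(n d³) - 1)
        n0, r_lo, r_hi, d = 1e-3, 5.0, 12.0, 0.7
        vol = 4 * np.pi / 3 * (r_hi**3 - r_lo**3)
        val = ideal_gas_free_energy(lambda r: n0, r_lo, r_hi, d)
        expected = n0 * vol * (np.log(n0 * d**3) - 1.0)
        assert val == pytest.approx(expected, rel=1e-9)

    def test_inside_closed_form_matches_quadrature(self, mini_geom):
        state = make_state(mini_geom, 50.0, 5.0, 10.0)
        R = state.R(mini_geom)
        delta = R - mini_geom.R_PS
        alpha = cm._free_volume_fraction(state, mini_geom)
        C = state.N2 / (4 * np.pi * delta)
        oracle = ideal_gas_free_energy(
            lambda r: C / r**2, mini_geom.R_PS, R, mini_geom.d, alpha
        )
        assert counterion_entropy(state, mini_geom, "inside") == pytest.approx(
            oracle, rel=1e-8
        )

    def test_overfilled_brush_rejected(self):
        geom = BrushGeometry(f=200, N=40, R_PS=10.0)  # monomers > shell volume
        state = make_state(geom, 100.0, 1.0, 0.0)
        with pytest.raises(UnphysicalStateError):
            counterion_entropy(state, geom, "inside")


class TestInsertionFreeEnergy:
    def test_zero_without_osmotic_counterions(self, mini_geom):
        cap = mini_geom.total_charge - manning_condensed(mini_geom)
        state = make_state(mini_geom, 50.0, 4.0, cap)  # all free ions escaped
        assert insertion_free_energy(state, mini_geom) == 0.0

    def test_warns_outside_osmotic_limit(self, mini_geom):
        cap = mini_geom.total_charge - manning_condensed(mini_geom)
        state = make_state(mini_geom, 50.0, 4.0, 0.5 * cap)  # N2 ≈ N3
        with pytest.warns(cm.OsmoticLimitWarning):
            insertion_free_energy(state, mini_geom)

    def test_cell_filling_limit_is_full_osmotic_cost(self, mini_geom):
        R_W = mini_geom.R_PS + 4.0
        state = make_state(mini_geom, R_W, 4.0, 0.0)
        assert insertion_free_energy(state, mini_geom) == pytest.approx(state.N2)

    def test_cubic_scaling_with_brush_radius(self, mini_geom):
        R_W = 200.0
        s1 = make_state(mini_geom, R_W, 4.0, 0.0)   # R = 14
        geom_long = BrushGeometry(f=mini_geom.f, N=200, R_PS=10.0)
        s2 = make_state(geom_long, R_W, 18.0, 0.0)  # R = 28 = 2 × 14
        f1 = insertion_free_energy(s1, mini_geom) / s1.N2
        f2 = insertion_free_energy(s2, geom_long) / s2.N2
        assert f2 / f1 == pytest.approx(8.0)


class TestTotalFreeEnergy:
    def test_total_is_sum_of_terms(self, mini_geom):
        b = total_free_energy(4.0, 20.0, mini_geom, 50.0)
        assert b.total == pytest.approx(
            b.U_H + b.F_el + b.F_Fl + b.TS2 + b.TS3 + b.F_p
        )

    def test_finite_on_full_grid_sweep(self, mini_geom):
        # every physically admissible point of a 50×50 (L, N3) sweep must
        # evaluate finite (below L_phys the monomers overfill the shell)
        cap = mini_geom.total_charge - manning_condensed(mini_geom)
        v_mon = 4 * np.pi / 3 * mini_geom.R_m**3 * mini_geom.total_charge
        L_phys = (mini_geom.R_PS**3 + v_mon / (4 * np.pi / 3)) ** (1 / 3) - (
            mini_geom.R_PS
        )
        Ls = np.linspace(1.01 * L_phys, mini_geom.contour_length, 50)
        N3s = np.concatenate([[0], np.geomspace(1e-6, cap * 0.999, 49)])
        vals = [
            total_free_energy(L, n3, mini_geom, 60.0).total
            for L in Ls for n3 in N3s
        ]
        assert np.all(np.isfinite(vals))

    def test_single_term_perturbation_is_additive(self, mini_geom):
        b1 = total_free_energy(4.0, 20.0, mini_geom, 50.0)
        b2 = total_free_energy(4.5, 20.0, mini_geom, 50.0)
        assert b2.total - b1.total == pytest.approx(
            (b2.U_H - b1.U_H) + (b2.F_el - b1.F_el) + (b2.F_Fl - b1.F_Fl)
            + (b2.TS2 - b1.TS2) + (b2.TS3 - b1.TS3) + (b2.F_p - b1.F_p)
        )


@settings(max_examples=30, deadline=None, derandomize=True)
@given(
    L=st.floats(0.5, 6.5),
    n3_frac=st.floats(0.0, 0.9),
    R_W=st.floats(25.0, 500.0),
)
def test_partition_closure_property(L, n3_frac, R_W):
    """N1 + N2 + N3 = N·f exactly at every evaluated point."""
    geom = BrushGeometry(f=41.6, N=40, R_PS=10.0)
    cap = geom.total_charge - manning_condensed(geom)
    state = make_state(geom, R_W, L, n3_frac * cap)
    assert state.N1 + state.N2 + state.N3 == pytest.approx(
        geom.total_charge, rel=1e-12
    )
    assert min(state.N1, state.N2, state.N3) >= 0


class TestMinimization:
    def test_minimum_beats_its_grid_neighbors(self, mini_geom):
        eq = minimize_free_energy(mini_geom, 60.0)
        assert eq.converged
        f0 = eq.breakdown.total
        dL = 0.01 * mini_geom.contour_length
        dN = max(0.02 * eq.N3_star, 1e-3)
        for sL in (-1, 0, 1):
            for sN in (-1, 0, 1):
                if sL == sN == 0:
                    continue
                L = np.clip(eq.L_star + sL * dL, 0.05 * mini_geom.contour_length,
                            mini_geom.contour_length)
                n3 = max(eq.N3_star + sN * dN, 0.0)
                assert total_free_energy(L, n3, mini_geom, 60.0).total >= (
                    f0 - 1e-9 * abs(f0)
                )

    def test_release_fraction_bounds(self, mini_geom):
        eq = minimize_free_energy(mini_geom, 100.0)
        assert 0.0 <= eq.release_fraction <= 1.0

    def test_experimental_brush_traps_nearly_all_counterions(self, exp_geom):
        """Order-10⁻⁵ release fraction for the f = 10⁵, N = 2×10⁴ brush."""
        R_0 = exp_geom.R_PS + exp_geom.contour_length
        eq = minimize_free_energy(exp_geom, R_0 * 0.01 ** (-1 / 3))
        assert eq.converged
        assert 1e-6 < eq.release_fraction < 1e-4

    def test_release_fraction_decreases_with_functionality(self, mini_geom):
        fracs = []
        for f in [10, 20, 42, 60, 83]:
            geom = BrushGeometry(f=f, N=40, R_PS=10.0)
            R_W = (geom.R_PS + geom.contour_length) * 0.1 ** (-1 / 3)
            fracs.append(minimize_free_energy(geom, R_W).release_fraction)
        assert np.all(np.diff(fracs) < 0)

    def test_release_fraction_increases_with_cell_size(self, mini_geom):
        # dilute branch: escaped-ion entropy dominates the separation cost
        fracs = [
            minimize_free_energy(mini_geom, R_W).release_fraction
            for R_W in [150.0, 300.0, 600.0, 1200.0, 2400.0]
        ]
        assert np.all(np.diff(fracs) > 0)

    def test_cell_smaller_than_core_rejected(self, mini_geom):
        with pytest.raises(ValueError):
            minimize_free_energy(mini_geom, mini_geom.R_PS * 0.5)


class TestSizeVsPacking:
    def test_curve_is_non_increasing(self, mini_geom):
        df = size_vs_packing(mini_geom, np.linspace(0.1, 1.2, 8))
        assert np.all(np.diff(df["sigma_ratio"]) <= 1e-9)

    def test_dilute_limit_is_largest(self, mini_geom):
        df = size_vs_packing(mini_geom, [0.01, 0.5, 0.9])
        assert df["sigma_ratio"].iloc[0] == df["sigma_ratio"].max()

    def test_eta_domain_checked(self, mini_geom):
        with pytest.raises(ValueError):
            size_vs_packing(mini_geom, [0.0, 0.5])
        with pytest.raises(ValueError):
            size_vs_packing(mini_geom, [1.4])
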