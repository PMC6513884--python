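"""Cradle membrane pathways: EAAT, NCX, NKA, Kir, backgrounds, ECS leak."""

import math

import numpy as np
import pytest

import pscradle as pc
from pscradle import (AstrocyteState, DomainError, astro_background_current,
                      astro_nka_currents, eaat_currents, eaat_update,
                      ecs_leak_current, kir_current, ncx_currents)

RTF = pc.CONSTANTS.RTF


def baseline_state(params) -> AstrocyteState:
    return AstrocyteState(params.k_psc_0, params.na_psc_0, params.ca_psc_0,
                          params.k_psecs_0, params.na_psecs_0, 0.0, params.v_a)


class TestEaat:
    def test_decay_reaches_j0_over_e_after_tau(self, params):
        j = params.j0_eaat
        dt = 1e-5
        for _ in range(int(params.tau_eaat / dt)):
            j = eaat_update(j, dt, False, params)
        assert j == pytest.approx(params.j0_eaat / math.e, rel=2e-3)

    def test_impulse_from_rest(self, params):
        assert eaat_update(0.0, 1e-5, True, params) == pytest.approx(0.06, rel=1e-9)

    def test_impulses_stack(self, params):
        j = eaat_update(0.0, 1e-5, True, params)
        j = eaat_update(j, 1e-5, True, params)
        assert j > params.j0_eaat

    def test_full_decay_integral_is_3mM(self, params):
        """Analytic: one impulse moves J0 * tau = 3 mM of Na+ out of the
        PsECS; the discrete integral converges to it."""
        assert params.j0_eaat * params.tau_eaat == pytest.approx(3e-3)
        j, total, dt = params.j0_eaat, 0.0, 1e-5
        for _ in range(int(1.0 / dt)):   # 20 time constants
            total += j * dt
            j = eaat_update(j, dt, False, params)
        assert total == pytest.approx(3e-3, rel=1e-3)

    def test_currents_zero_without_flux(self, params, geometry):
        assert eaat_currents(0.0, geometry, params) == (0.0, -0.0)

    def test_counter_transport_ratio_exact(self, params, geometry):
        i_na, i_k = eaat_currents(0.0123, geometry, params)
        assert i_k == -i_na / 3.0

    def test_peak_current_magnitude(self, params, geometry):
        i_na, _ = eaat_currents(params.j0_eaat, geometry, params)
        expected = params.j0_eaat * pc.CONSTANTS.F * geometry.vol_psecs
        assert i_na == pytest.approx(-expected, rel=1e-12)


class TestNcx:
    def test_equilibrium_state_carries_no_current(self, params, geometry):
        # choose Ca so the two exponent-weighted ratio terms cancel exactly
        s = baseline_state(params)
        ratio = (s.na_psc / s.na_psecs) ** 3 * math.exp(params.v_a / RTF)
        s.ca_psc = ratio * params.ca_psecs
        i_na, i_ca = ncx_currents(s, geometry, params)
        assert abs(i_na) < 1e-25 and abs(i_ca) < 1e-25

    def test_table_baseline_near_equilibrium(self, params, geometry):
        """At the printed baseline the exchanger idles: per-area current
        ~5e-7 A/m2, far below the stimulated values."""
        i_na, _ = ncx_currents(baseline_state(params), geometry, params)
        density = i_na / geometry.sa_ps
        assert density == pytest.approx(4.844e-7, rel=1e-3)
        assert abs(density) < 1e-5

    def test_stoichiometric_coupling_exact(self, params, geometry):
        rng = np.random.default_rng(7)
        s = baseline_state(params)
        for _ in range(100):
            s.na_psc = rng.uniform(5e-3, 60e-3)
            s.ca_psc = rng.uniform(20e-9, 5e-6)
            i_na, i_ca = ncx_currents(s, geometry, params)
            assert i_ca == -2.0 * i_na / 3.0

    def test_matches_brute_force_formula_on_random_states(self, params, geometry):
        """Direct re-evaluation of the exchanger expression on 1000 random
        states agrees to better than 1e-12 relative."""
        rng = np.random.default_rng(42)
        for _ in range(1000):
            s = AstrocyteState(
                k_psc=rng.uniform(0.05, 0.2),
                na_psc=rng.uniform(1e-3, 0.1),
                ca_psc=rng.uniform(1e-8, 1e-5),
                k_psecs=rng.uniform(1e-3, 0.02),
                na_psecs=rng.uniform(0.05, 0.2),
                v_a=rng.uniform(-0.1, -0.06),
            )
            i_na, _ = ncx_currents(s, geometry, params)
            expected = params.i_bar_ncx * (
                (s.na_psc / s.na_psecs) ** 3
                * math.exp(params.gamma_ncx * pc.CONSTANTS.F * s.v_a
                           / (pc.CONSTANTS.R * pc.CONSTANTS.T))
                - (s.ca_psc / params.ca_psecs)
                * math.exp((params.gamma_ncx - 1.0) * pc.CONSTANTS.F * s.v_a
                           / (pc.CONSTANTS.R * pc.CONSTANTS.T))
            ) * geometry.sa_ps
            assert i_na == pytest.approx(expected, rel=1e-12)

    def test_sodium_load_drives_reverse_mode(self, params, geometry):
        """Raising cradle Na+ pushes the exchanger further into reverse
        (Na+ efflux, Ca2+ influx)."""
        s = baseline_state(params)
        i_lo, _ = ncx_currents(s, geometry, params)
        s.na_psc = 18e-3
        i_hi, ca_hi = ncx_currents(s, geometry, params)
        assert i_hi > i_lo and i_hi > 0 and ca_hi < 0

    def test_zero_crossing_coincides_with_equilibrium_potential(self, params,
                                                                geometry):
        """The Na+ concentration at which the current vanishes is the one
        that puts E_NCX exactly at V_A (to < 0.5 mV)."""
        from scipy.optimize import brentq
        s = baseline_state(params)

        def current_at(na):
            s.na_psc = na
            return ncx_currents(s, geometry, params)[0]

        na_zero = brentq(current_at, 1e-3, 0.1, xtol=1e-12)
        e_na = pc.nernst_potential(s.na_psecs, na_zero)
        e_ca = pc.nernst_potential(params.ca_psecs, s.ca_psc, valence=2)
        e_ncx = pc.ncx_equilibrium_potential(e_na, e_ca, n=3)
        assert abs(e_ncx - params.v_a) < 5e-4

    def test_nonpositive_extracellular_rejected(self, params, geometry):
        s = baseline_state(params)
        s.na_psecs = 0.0
        with pytest.raises(DomainError):
            ncx_currents(s, geometry, params)


class TestAstroNka:
    def test_no_external_potassium_no_flux(self, params, geometry):
        s = baseline_state(params)
        s.k_psecs = 0.0
        assert astro_nka_currents(s, geometry, params) == (0.0, -0.0)

    def test_baseline_occupancy_product(self, params, geometry):
        i_na, _ = astro_nka_currents(baseline_state(params), geometry, params)
        occ = (15 / 25) ** 3 * (4 / 5.5) ** 2
        expected = 3 * pc.CONSTANTS.F * params.p_nka_max * occ * geometry.sa_ps
        assert i_na == pytest.approx(expected, rel=1e-12)

    def test_stoichiometry(self, params, geometry):
        i_na, i_k = astro_nka_currents(baseline_state(params), geometry, params)
        assert i_na / i_k == pytest.approx(-1.5, rel=1e-12)


class TestKir:
    def test_zero_at_reversal(self, params, geometry):
        s = baseline_state(params)
        s.v_a = pc.nernst_potential(s.k_psecs, s.k_psc)
        assert kir_current(s, geometry, params) == pytest.approx(0.0, abs=1e-25)

    def test_efflux_at_table_baseline(self, params, geometry):
        # E_K ~ -85.9 mV, printed V_A = -80.7 mV -> outward K+ at rest
        assert kir_current(baseline_state(params), geometry, params) > 0

    def test_elevated_ecs_potassium_flips_to_uptake(self, params, geometry):
        s = baseline_state(params)
        s.k_psecs = 8e-3
        assert kir_current(s, geometry, params) < 0

    def test_sqrt_variant_scales_conductance(self, geometry):
        p = pc.ModelParameters(variants=pc.ModelVariants(kir_sqrt_k_out=True))
        s = baseline_state(p)
        s.k_psecs = 16e-3  # 4x baseline -> sqrt factor 2
        p_lin = pc.ModelParameters()
        assert kir_current(s, geometry, p) == pytest.approx(
            2.0 * kir_current(s, geometry, p_lin), rel=1e-12)


class TestBackgroundAndLeak:
    def test_background_zero_at_reversal(self, params, geometry):
        s = baseline_state(params)
        s.v_a = pc.nernst_potential(s.na_psecs, s.na_psc)
        assert astro_background_current("na", s, geometry, params) == pytest.approx(
            0.0, abs=1e-25)

    def test_background_sodium_influx_at_baseline(self, params, geometry):
        assert astro_background_current("na", baseline_state(params),
                                        geometry, params) < 0

    def test_background_linear_in_conductance(self, params, geometry):
        s = baseline_state(params)
        doubled = params.evolve(g_na_bg=2 * params.g_na_bg)
        assert astro_background_current("na", s, geometry, doubled) == pytest.approx(
            2 * astro_background_current("na", s, geometry, params), rel=1e-12)

    def test_leak_zero_at_equal_concentrations(self, params, geometry):
        s = baseline_state(params)   # baseline PsECS == GECS
        assert ecs_leak_current("k", s, geometry, params) == pytest.approx(
            0.0, abs=1e-30)

    def test_leak_direction_follows_gradient(self, params, geometry):
        s = baseline_state(params)
        s.k_psecs = 8e-3
        assert ecs_leak_current("k", s, geometry, params) > 0

    def test_leak_scales_with_interface_area(self, params):
        g1 = pc.derive_geometry()
        g2 = pc.derive_geometry(sa_psecs_gecs=2 * g1.sa_psecs_gecs)
        s = baseline_state(params)
        s.na_psecs = 0.15
        assert ecs_leak_current("na", s, g2, params) == pytest.approx(
            2 * ecs_leak_current("na", s, g1, params), rel=1e-12)

    def test_domain_errors(self, params, geometry):
        s = baseline_state(params)
        s.k_psecs = 0.0
        with pytest.raises(DomainError):
            ecs_leak_current("k", s, geometry, params)
        with pytest.raises(DomainError):
            kir_current(s, geometry, params)
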