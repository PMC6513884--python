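"""Simulation engine: RHS wiring, Euler stepping, protocols, audits."""

import numpy as np
import pytest

import pscradle as pc
from pscradle import (AstrocyteState, CalibrationError, SimConfig,
                      StimulusSpec, concentration_rhs, euler_step,
                      evaluate_currents, initial_state, run_simulation)

F = pc.CONSTANTS.F


class TestConcentrationRhs:
    def test_all_zero_currents_give_zero_derivatives(self, params, geometry):
        rhs = concentration_rhs({}, geometry, params)
        assert all(v == 0.0 for v in rhs.values())

    def test_pure_ncx_calcium_term(self, params, geometry):
        """Only I_CaNCX nonzero: d[Ca]PsC/dt = -I_CaNCX / (2 F Vol_PsC)."""
        i = 3.7e-15
        rhs = concentration_rhs({"i_ca_ncx": i}, geometry, params)
        assert rhs["ca_psc"] == pytest.approx(-i / (2 * F * geometry.vol_ps),
                                              rel=1e-12)
        assert rhs["k_psc"] == 0.0 and rhs["na_psc"] == 0.0

    def test_membrane_flux_conserves_moles_between_compartments(self, params,
                                                                geometry):
        """A pure astrocyte K+ influx removes K+ from the PsECS and adds the
        same mole count to the cradle: Vol_PsECS d[K]PsECS = -Vol_PsC d[K]PsC."""
        rhs = concentration_rhs({"i_kir": -2e-14}, geometry, params)
        assert geometry.vol_psecs * rhs["k_psecs"] == pytest.approx(
            -geometry.vol_ps * rhs["k_psc"], rel=1e-12)

    def test_unknown_current_name_rejected(self, params, geometry):
        with pytest.raises(pc.ValidationError):
            concentration_rhs({"i_bogus": 1.0}, geometry, params)


class TestEulerStep:
    def test_zero_derivative_fixed_point(self, calibrated, geometry):
        """The calibrated resting state is an exact fixed point of the full
        step (concentration changes at machine precision only)."""
        cal, _ = calibrated
        y0 = initial_state(cal)
        y1 = euler_step(y0, 1e-5, cal, geometry)
        assert np.allclose(y1, y0, rtol=1e-12, atol=1e-15)

    def test_zero_dt_identity(self, calibrated, geometry):
        cal, _ = calibrated
        y0 = initial_state(cal)
        assert np.array_equal(euler_step(y0, 0.0, cal, geometry), y0)

    def test_spike_flag_applies_eaat_impulse(self, calibrated, geometry):
        cal, _ = calibrated
        y0 = initial_state(cal)
        y1 = euler_step(y0, 1e-5, cal, geometry, spike_now=True)
        assert y1[4] == pytest.approx(cal.j0_eaat, rel=1e-9)

    def test_wrapper_currents_match_module_functions(self, calibrated, geometry):
        """The packed kernel evaluates exactly the same pathway currents as
        the per-module Python functions (single source of truth)."""
        cal, _ = calibrated
        y = initial_state(cal)
        y[5:10] = [0.11, 0.02, 2e-7, 0.006, 0.12]   # perturbed concentrations
        y[4] = 0.03
        cur = evaluate_currents(y, cal, geometry)
        s = AstrocyteState(k_psc=y[5], na_psc=y[6], ca_psc=y[7],
                           k_psecs=y[8], na_psecs=y[9], j_eaat=y[4],
                           v_a=cal.v_a)
        i_na_ncx, i_ca_ncx = pc.ncx_currents(s, geometry, cal)
        i_na_eaat, i_k_eaat = pc.eaat_currents(y[4], geometry, cal)
        assert cur["i_na_ncx"] == pytest.approx(i_na_ncx, rel=1e-12)
        assert cur["i_ca_ncx"] == pytest.approx(i_ca_ncx, rel=1e-12)
        assert cur["i_na_eaat"] == pytest.approx(i_na_eaat, rel=1e-12)
        assert cur["i_k_eaat"] == pytest.approx(i_k_eaat, rel=1e-12)
        assert cur["i_kir"] == pytest.approx(
            pc.kir_current(s, geometry, cal), rel=1e-12)
        assert cur["i_k_ecsl"] == pytest.approx(
            pc.ecs_leak_current("k", s, geometry, cal), rel=1e-12)


class TestProtocols:
    def test_uncalibrated_parameters_rejected(self, params, geometry):
        with pytest.raises(CalibrationError):
            run_simulation(params, geometry, SimConfig())

    def test_missing_amplitude_rejected(self, calibrated, geometry):
        cal, _ = calibrated
        cfg = SimConfig(stimulus=StimulusSpec(mode="pulse", amplitude=None))
        with pytest.raises(CalibrationError):
            run_simulation(cal, geometry, cfg)

    def test_determinism_bit_identical(self, calibrated, geometry):
        cal, rep = calibrated
        cfg = SimConfig(t_settle=0.2, t_stim=1.0, t_post=0.2,
                        stimulus=StimulusSpec(mode="spike_train", rate=10.0,
                                              events=(0.05, 0.15, 0.25)))
        a = run_simulation(cal, geometry, cfg, calibration=rep)
        b = run_simulation(cal, geometry, cfg, calibration=rep)
        assert a.data.equals(b.data)
        assert np.array_equal(a.spike_times, b.spike_times)

    def test_single_spike_sodium_transient(self, calibrated, geometry):
        """One glutamate event: cradle Na+ rises after the spike, peaks, and
        relaxes back toward baseline."""
        cal, rep = calibrated
        cfg = SimConfig(t_settle=0.5, t_stim=0.1, t_post=10.0,
                        stimulus=StimulusSpec(mode="spike_train", rate=1.0,
                                              events=(0.0,)),
                        record_stride=20)
        r = run_simulation(cal, geometry, cfg, calibration=rep)
        d = r.data
        na = d["na_psc_M"].to_numpy()
        t = d["time_s"].to_numpy()
        baseline = na[t < 0.5].mean()
        peak_idx = na.argmax()
        assert t[peak_idx] > 0.5                       # peak after the event
        assert na[peak_idx] > baseline * 1.001          # visible transient
        assert na[-1] < baseline + 0.5 * (na[peak_idx] - baseline)  # relaxes

    def test_spike_train_events_trigger_eaat(self, calibrated, geometry):
        cal, rep = calibrated
        events = tuple(pc.generate_spike_train(10.0, 1.0).times)
        cfg = SimConfig(t_settle=0.2, t_stim=1.0, t_post=0.2,
                        stimulus=StimulusSpec(mode="spike_train", rate=10.0,
                                              events=events))
        r = run_simulation(cal, geometry, cfg, calibration=rep)
        assert len(r.spike_times) == 10
        assert r.data["j_eaat_M_per_s"].max() > 0.9 * cal.j0_eaat

    def test_mole_conservation_audit_on_stimulated_run(self, protocol_runs,
                                                       calibrated, geometry):
        cal, _ = calibrated
        err = pc.audit_mole_conservation(protocol_runs(10.0), geometry, cal)
        assert err < 1e-9

    def test_result_table_has_full_column_registry(self, rest_run):
        from pscradle.engine import ALL_COLUMNS
        assert list(rest_run.data.columns) == ALL_COLUMNS
        assert not rest_run.data.isna().any().any()

    def test_stimulus_calibration_meets_targets(self, stimulus_amplitudes,
                                                calibrated, geometry):
        """10, 20 and 30 Hz are each achieved within +/-0.5 Hz."""
        cal, _ = calibrated
        for rate in (10.0, 20.0, 30.0):
            stim = StimulusSpec(mode="pulse", rate=rate,
                                amplitude=stimulus_amplitudes(rate))
            assert pc.measure_firing_rate(cal, geometry, stim, 2.0) == \
                pytest.approx(rate, abs=0.5)

    def test_run_protocol_front_door(self, calibrated, geometry):
        """run_protocol accepts precalibrated parameters and a spike-train
        config and returns a complete result without further calibration."""
        cal, _ = calibrated
        cfg = SimConfig(t_settle=0.2, t_stim=0.5, t_post=0.2,
                        stimulus=StimulusSpec(mode="spike_train", rate=10.0,
                                              events=(0.05, 0.25, 0.45)))
        r = pc.run_protocol(params=cal, geometry=geometry, config=cfg)
        assert len(r.spike_times) == 3
        assert r.metadata["floor_events"] == 0

    def test_zero_rate_needs_no_stimulus(self, calibrated, geometry):
        cal, _ = calibrated
        assert pc.calibrate_stimulus(0.0, cal, geometry) == 0.0


class TestRecovery:
    def test_post_stimulus_states_move_back_toward_baseline(self, calibrated,
                                                            geometry,
                                                            stimulus_amplitudes):
        """After stimulus offset every cradle concentration turns around and
        closes part of its excursion; the pump-driven Na+ closes most of it.
        K+ keeps rising for several seconds after offset (the PsECS K+ load
        drains only slowly through the ECS leak) before declining, so the
        closure check uses the whole-run excursion maximum."""
        cal, rep = calibrated
        cfg = SimConfig(t_settle=2.0, t_stim=10.0, t_post=40.0,
                        stimulus=StimulusSpec(mode="pulse", rate=10.0,
                                              amplitude=stimulus_amplitudes(10.0)))
        r = run_simulation(cal, geometry, cfg, calibration=rep)
        d = r.data
        base = {"na_psc_M": cal.na_psc_0, "k_psc_M": cal.k_psc_0,
                "ca_psc_M": cal.ca_psc_rest}
        for col, b in base.items():
            exc = np.abs(d[col].to_numpy() - b)
            assert exc[-1] < exc.max(), col
        na_exc = np.abs(d["na_psc_M"].to_numpy() - cal.na_psc_0)
        assert na_exc[-1] < 0.15 * na_exc.max()
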