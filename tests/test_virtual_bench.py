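"""Unit and property tests for the virtual bench (lung, effort, leaks)."""

import math

import numpy as np
import pytest

import nivbench.ps_controller as psc
import nivbench.virtual_bench as vb


class TestEffortWaveform:
    def test_null_effort_is_zero_everywhere(self):
        prof = vb.EffortProfile(amplitude=0.0)
        assert vb.generate_pmus(prof, 0.37) == 0.0
        assert np.all(vb.generate_pmus(prof, np.linspace(0, 10, 57)) == 0.0)

    def test_ramp_reaches_minus_amplitude_at_rise_time(self):
        prof = vb.EffortProfile(amplitude=10.0, rise_time=0.2)
        assert vb.generate_pmus(prof, 0.2) == pytest.approx(-10.0)

    def test_exponential_release_three_time_constants(self):
        prof = vb.EffortProfile(amplitude=10.0, hold_time=0.9, relax_tau=0.1)
        t = 0.9 + 3 * 0.1
        assert vb.generate_pmus(prof, t) == pytest.approx(-10.0 * math.exp(-3.0))

    def test_periodicity(self):
        prof = vb.EffortProfile(amplitude=10.0, period=3.3)
        t = np.linspace(0, 3.2, 40)
        np.testing.assert_allclose(
            vb.generate_pmus(prof, t), vb.generate_pmus(prof, t + 2 * 3.3), atol=1e-9
        )

    @pytest.mark.parametrize("label,rate", [("normal", 18.2), ("obstructive", 14.0), ("restrictive", 18.8)])
    def test_driver_timing_matches_set_rates_within_one_per_min(self, label, rate):
        hold, period = vb.EFFORT_TIMING[label]
        set_rate = {"normal": 18, "obstructive": 14, "restrictive": 18}[label]
        assert 60.0 / period == pytest.approx(rate, abs=0.1)
        assert abs(60.0 / period - set_rate) < 1.0


class TestOcclusion:
    def test_null_effort_gives_zero_indices(self):
        prof = vb.EffortProfile(amplitude=0.0)
        assert vb.occlusion_test(prof) == (0.0, 0.0)

    def test_linear_ramp_p01_is_half_amplitude(self):
        prof = vb.EffortProfile(amplitude=12.0, rise_time=0.2)
        p01, poccl = vb.occlusion_test(prof)
        assert p01 == pytest.approx(-6.0, rel=1e-6)
        assert poccl == pytest.approx(-12.0, rel=1e-6)

    def test_calibration_round_trips_targets_within_2pct(self, effort):
        p01, poccl = vb.occlusion_test(effort)
        assert p01 == pytest.approx(-5.58, rel=0.02)
        assert poccl == pytest.approx(-13.48, rel=0.02)

    def test_equal_targets_rejected(self):
        with pytest.raises(ValueError):
            vb.calibrate_effort(-1.0, -1.0)

    def test_p01_larger_than_poccl_rejected(self):
        with pytest.raises(ValueError):
            vb.calibrate_effort(-10.0, -5.0)

    def test_positive_targets_rejected(self):
        with pytest.raises(ValueError):
            vb.calibrate_effort(5.58, -13.48)

    def test_calibrated_amplitude_equals_occlusion_plateau(self, effort):
        # under occlusion the full muscle pressure appears at the airway
        assert effort.amplitude == pytest.approx(13.48)


class TestLeakOrifice:
    def test_zero_coefficient_gives_zero_flow(self):
        spec = vb.LeakSpec.no_leak()
        assert vb.leak_flow(10.0, spec, True) == 0.0

    def test_sqrt_law(self):
        spec = vb.LeakSpec("inspiro-expiratory", "L9", 9.0, 3.0)
        assert vb.leak_flow(4.0, spec, False) == pytest.approx(6.0)
        assert vb.leak_flow(-4.0, spec, False) == pytest.approx(-6.0)

    def test_inspiratory_only_closed_during_exhalation(self):
        spec = vb.LeakSpec("inspiratory-only", "L20", 20.0, 5.0)
        assert vb.leak_flow(9.0, spec, False) == 0.0
        assert vb.leak_flow(9.0, spec, True) == pytest.approx(15.0)

    def test_l0_requires_zero_coefficient(self):
        with pytest.raises(ValueError):
            vb.LeakSpec("inspiro-expiratory", "L0", 0.0, 1.0)


class TestLungStep:
    def test_equilibrium_has_zero_flow(self):
        mech = vb.MECHANICS_PRESETS["normal"]
        v = mech.compliance * 5.0
        _, q = vb.step_lung((v, 0.0), 5.0, 0.0, mech, 2e-3)
        assert q == pytest.approx(0.0, abs=1e-12)

    def test_passive_expiration_time_constant_obstructive(self):
        """Passive decay e-folds at R*C ~= 2.00 s for the obstructive lung."""
        mech = vb.MECHANICS_PRESETS["obstructive"]
        dt = 2e-3
        v = 0.5
        t, target = 0.0, 0.5 / math.e
        while v > target:
            v, _ = vb.step_lung((v, 0.0), 0.0, 0.0, mech, dt)
            t += dt
        assert t == pytest.approx(mech.tau, rel=0.01)
        assert mech.tau == pytest.approx(2.00, abs=0.01)

    def test_pressure_step_volume_asymptote(self):
        mech = vb.MECHANICS_PRESETS["normal"]
        ps, dt = 8.0, 2e-3
        v = 0.0
        for _ in range(int(6 * mech.tau / dt)):
            v, _ = vb.step_lung((v, 0.0), ps, 0.0, mech, dt)
        assert v == pytest.approx(mech.compliance * ps, rel=0.01)

    def test_large_dt_rejected(self):
        mech = vb.MECHANICS_PRESETS["normal"]
        with pytest.raises(ValueError):
            vb.step_lung((0.0, 0.0), 5.0, 0.0, mech, 5e-3)

    def test_non_finite_state_aborts(self):
        mech = vb.MECHANICS_PRESETS["normal"]
        with pytest.raises(FloatingPointError):
            vb.step_lung((math.nan, 0.0), 5.0, 0.0, mech, 2e-3)


class TestClosedLoop:
    def test_flow_conservation_exact(self, quiet_l0_record):
        ch = quiet_l0_record.channels
        err = np.abs(ch["q_circuit"] - ch["q_lung"] - ch["q_leak"])
        assert err.max() < 1e-6

    def test_effort_rate_18_per_min(self, quiet_l0_record):
        onsets = [e.t for e in quiet_l0_record.events_of("effort_onset")]
        # rate over the record, scaled to a 2 min window
        rate = 60.0 * (len(onsets) - 1) / (onsets[-1] - onsets[0])
        assert abs(rate - 18.0) <= 1.0

    def test_end_expiratory_volume_stable_at_l0(self, quiet_l0_record):
        """No breath-to-breath volume trapping at steady state without leak."""
        fs = quiet_l0_record.sample_rate
        vol = quiet_l0_record.channels["volume"]
        onsets = [e.t for e in quiet_l0_record.events_of("effort_onset")][2:]
        eev = np.array([vol[int(round(t * fs)) - 1] for t in onsets])
        tidal = vol.max() - vol.min()
        assert np.max(np.abs(np.diff(eev))) < 0.02 * tidal

    def test_no_trigger_without_effort_at_l0(self, normal_settings):
        mech = vb.MECHANICS_PRESETS["normal"]
        prof = vb.EffortProfile(amplitude=0.0, rise_time=0.2, hold_time=0.9, period=3.3)
        rec = vb.simulate_condition(
            mech, prof, normal_settings, vb.LeakSpec.no_leak(), "IS0", duration=30.0
        )
        assert not rec.events_of("trigger")

    def test_determinism_same_seed(self, effort, normal_settings):
        mech = vb.MECHANICS_PRESETS["normal"]
        kw = dict(duration=12.0, noise=vb.NoiseSpec(), seed=7)
        a = vb.simulate_condition(mech, effort, normal_settings, vb.LeakSpec.no_leak(), "IS0", **kw)
        b = vb.simulate_condition(mech, effort, normal_settings, vb.LeakSpec.no_leak(), "IS0", **kw)
        for name in a.channels:
            np.testing.assert_array_equal(a.channels[name], b.channels[name])
        assert a.events == b.events

    def test_internal_rate_must_be_multiple_of_50(self, effort, normal_settings):
        mech = vb.MECHANICS_PRESETS["normal"]
        with pytest.raises(ValueError):
            vb.simulate_condition(
                mech, effort, normal_settings, vb.LeakSpec.no_leak(),
                duration=1.0, internal_rate=430,
            )


class TestLeakCalibration:
    def test_calibrated_levels_recover_targets_within_5pct(
        self, effort, normal_settings, leak_specs
    ):
        mech = vb.MECHANICS_PRESETS["normal"]
        for level, target in (("L9", 9.0), ("L20", 20.0)):
            spec = leak_specs["inspiro-expiratory"][level]
            rec = vb.simulate_condition(
                mech, effort, normal_settings, spec, "IS0", duration=80.0
            )
            avg = vb.breath_averaged_leak(rec, effort.period, discard=15.0)
            assert avg == pytest.approx(target, rel=0.05)

    def test_leak_increases_with_peep(self, effort, leak_specs):
        """Orifice law is monotone in pressure: higher PEEP leaks more."""
        mech = vb.MECHANICS_PRESETS["normal"]
        spec = leak_specs["inspiro-expiratory"]["L9"]
        avgs = []
        for peep in (5.0, 10.0):
            st = psc.settings_for("normal", 8.0, peep=peep)
            rec = vb.simulate_condition(mech, effort, st, spec, "IS0", duration=50.0)
            avgs.append(vb.breath_averaged_leak(rec, effort.period, discard=10.0))
        assert avgs[1] > avgs[0]

    def test_l0_needs_no_calibration(self):
        with pytest.raises(ValueError):
            vb.calibrate_leak("L0")


class TestProtocol:
    def test_default_sequence_has_six_changes(self):
        proto = vb.ProtocolSpec()
        assert proto.leak_sequence == ("L0", "L9", "L20", "L9", "L0", "L20", "L0")
        changes = sum(
            1
            for a, b in zip(proto.leak_sequence, proto.leak_sequence[1:])
            if a != b
        )
        assert changes == 6

    def test_all_l0_protocol_has_zero_leak_channel(self, effort, normal_settings):
        mech = vb.MECHANICS_PRESETS["normal"]
        proto = vb.ProtocolSpec(
            baseline_cycles=2,
            leak_sequence=("L0", "L0"),
            step_duration=5.0,
            stabilization_before_recording=0.0,
        )
        rec = vb.run_protocol(
            mech, effort, normal_settings, "IS0", "inspiro-expiratory", {},
            protocol=proto,
        )
        assert np.all(rec.channels["q_leak"] == 0.0)
        assert not rec.events_of("leak_change")

    def test_leak_change_events_at_step_spacing(self, effort, normal_settings, leak_specs):
        mech = vb.MECHANICS_PRESETS["normal"]
        proto = vb.ProtocolSpec(
            baseline_cycles=2, step_duration=10.0, stabilization_before_recording=0.0
        )
        rec = vb.run_protocol(
            mech, effort, normal_settings, "IS0", "inspiro-expiratory",
            leak_specs["inspiro-expiratory"], protocol=proto,
        )
        changes = rec.events_of("leak_change")
        assert len(changes) == 6
        gaps = np.diff([e.t for e in changes])
        np.testing.assert_allclose(gaps, 10.0, atol=1e-6)

    def test_mismatched_leak_kind_rejected(self, effort, normal_settings, leak_specs):
        mech = vb.MECHANICS_PRESETS["normal"]
        with pytest.raises(ValueError):
            vb.run_protocol(
                mech, effort, normal_settings, "IS0", "inspiratory-only",
                leak_specs["inspiro-expiratory"],
            )
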