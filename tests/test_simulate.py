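"""Tests of the synthetic telemetry / imaging / behavior generators."""

import numpy as np
import pytest

from bpvkit.simulate import (
    AnimalConfig,
    CircadianProfile,
    InvalidScheduleError,
    PressorKinetics,
    PumpSchedule,
    StimulusProtocol,
    VascularModel,
    build_pump_schedule,
    pressor_effect_trace,
    pulse_map_trace,
    simulate_arteriole_run,
    simulate_behavior_cohort,
    simulate_telemetry,
)
from bpvkit.pressure_response import PulseWindow, baroreflex_slope, ols_fit
from bpvkit.timeseries import pump_epoch_deltas


class TestPumpSchedule:
    @pytest.mark.parametrize(
        "cycle,days,expected",
        [(4.0, 1, 6), (3.0, 1, 8), (4.0, 0, 0), (3.0, 2, 16)],
    )
    def test_pulses_per_day(self, cycle, days, expected):
        assert build_pump_schedule(cycle, 1.0, days).n_pulses == expected

    def test_intervals_sorted_uniform_length(self):
        s = build_pump_schedule(3.0, 1.0, 3.0)
        starts = [a for a, _ in s.on_intervals]
        assert starts == sorted(starts)
        assert all(b - a == pytest.approx(1.0) for a, b in s.on_intervals)

    def test_on_hours_too_long_rejected(self):
        with pytest.raises(InvalidScheduleError):
            build_pump_schedule(3.0, 3.0, 1.0)

    def test_nonstandard_cycle_warns(self):
        with pytest.warns(UserWarning, match="non-standard"):
            build_pump_schedule(5.0, 1.0, 1.0)

    def test_overlapping_intervals_rejected(self):
        with pytest.raises(InvalidScheduleError):
            PumpSchedule(on_intervals=((0.0, 1.0), (0.5, 1.5)))


class TestPressorEffect:
    def test_zero_before_first_pulse_and_empty_grid(self, angii_kinetics):
        s = build_pump_schedule(4.0, 1.0, 1.0, start_hour=6.0)
        t = np.arange(0.0, 6 * 3600.0, 30.0)
        assert np.all(pressor_effect_trace(s, angii_kinetics, t) == 0.0)
        assert pressor_effect_trace(s, angii_kinetics, np.array([])).size == 0

    def test_long_on_period_reaches_plateau(self):
        kin = PressorKinetics(tau_rise_min=2.0)
        s = PumpSchedule(on_intervals=((0.0, 5.0),), cycle_hours=6.0, on_hours=5.0)
        t = np.arange(0.0, 5 * 3600.0, 30.0)
        e = pressor_effect_trace(s, kin, t)
        assert e[-1] == pytest.approx(1.0, abs=1e-3)

    def test_half_life_definition(self, angii_kinetics):
        s = build_pump_schedule(4.0, 1.0, 1.0)
        off_s = 3600.0
        half_s = angii_kinetics.t_half_decay_min * 60.0
        t = np.array([off_s, off_s + half_s])
        e = pressor_effect_trace(s, angii_kinetics, t)
        assert e[1] == pytest.approx(0.5 * e[0], rel=1e-9)


class TestTelemetry:
    def test_determinism_bit_identical(self, circadian, two_day_schedule, angii_kinetics):
        an = AnimalConfig(seed=7)
        r1 = simulate_telemetry(an, circadian, two_day_schedule, angii_kinetics, 2)
        r2 = simulate_telemetry(an, circadian, two_day_schedule, angii_kinetics, 2)
        assert r1.data.equals(r2.data)

    def test_noiseless_saline_square_circadian_two_levels(
        self, noiseless_saline_recording
    ):
        sbp = np.unique(noiseless_saline_recording.channel("sbp"))
        assert sbp.size == 2

    def test_pressure_ordering_and_pp_identity(self, noiseless_angii_recording):
        d = noiseless_angii_recording.data
        assert (d["dbp"] <= d["map"] + 1e-9).all()
        assert (d["map"] <= d["sbp"] + 1e-9).all()
        np.testing.assert_allclose(d["pp"], d["sbp"] - d["dbp"], atol=1e-12)

    def test_pump_epoch_delta_recovers_amplitude(
        self, noiseless_angii_recording, two_day_schedule, angii_kinetics
    ):
        deltas = pump_epoch_deltas(noiseless_angii_recording, two_day_schedule)
        sbp = deltas[deltas.channel == "sbp"]["delta"]
        assert sbp.mean() == pytest.approx(angii_kinetics.delta_sbp, abs=0.5)
        mapd = deltas[deltas.channel == "map"]["delta"]
        assert mapd.mean() == pytest.approx(angii_kinetics.delta_map, abs=0.5)

    def test_pulse_trough_hr_delta_matches_gain_product(
        self, noiseless_angii_recording, two_day_schedule
    ):
        deltas = pump_epoch_deltas(noiseless_angii_recording, two_day_schedule)
        hr = deltas[deltas.channel == "hr"]["delta"]
        assert hr.mean() == pytest.approx(-4.2 * 70.0, abs=3.0)

    def test_blunting_monotonically_flattens_late_slope(
        self, quiet_animal, circadian
    ):
        """Increasing gain_decline_per_day strictly flattens the late-phase
        SBP-HR slope recovered by regression."""
        schedule = build_pump_schedule(3.0, 1.0, 6.0)
        onset = schedule.on_intervals[-2][0] * 3600.0
        slopes = []
        for decline in (0.0, 0.05, 0.10):
            kin = PressorKinetics(gain_decline_per_day=decline)
            rec = simulate_telemetry(quiet_animal, circadian, schedule, kin, 6)
            fit = baroreflex_slope(rec, PulseWindow(onset_s=onset))
            slopes.append(abs(fit.slope))
        assert slopes[0] > slopes[1] > slopes[2]

    def test_days_below_one_rejected(self, quiet_animal, circadian, angii_kinetics):
        s = build_pump_schedule(4.0, 1.0, 1.0)
        with pytest.raises(ValueError):
            simulate_telemetry(quiet_animal, circadian, s, angii_kinetics, 0.5)


class TestArterioleRun:
    def test_constant_map_no_stimuli_gives_baseline(self):
        vasc = VascularModel(diameter_noise_sd=0.0, nvc_amp_lowbp=0.0, nvc_amp_highbp=0.0)
        protocol = StimulusProtocol(n_events=1)
        n = int(round(protocol.duration_s * protocol.fps))
        run = simulate_arteriole_run(
            vasc, np.full(n, vasc.ref_pressure), protocol, "control", seed=0
        )
        np.testing.assert_allclose(run.diameter_um, vasc.baseline_diameter, atol=1e-9)

    def test_mid_range_slope_recovered_from_noiseless_ramp(self):
        vasc = VascularModel(
            slope_mid=-0.05, diameter_noise_sd=0.0, nvc_amp_lowbp=0.0, nvc_amp_highbp=0.0
        )
        protocol = StimulusProtocol(n_events=1)
        n = int(round(protocol.duration_s * protocol.fps))
        m = np.linspace(51.0, 100.0, n)
        run = simulate_arteriole_run(vasc, m, protocol, "control", seed=0)
        fit = ols_fit(run.map_mmHg, run.diameter_um)
        assert fit.slope == pytest.approx(-0.05, abs=1e-6)

    def test_single_nvc_event_decays_in_closed_form(self):
        vasc = VascularModel(
            diameter_noise_sd=0.0,
            nvc_amp_lowbp=10.0,
            nvc_amp_highbp=10.0,
            recovery_k=-0.45,
        )
        protocol = StimulusProtocol(n_events=1, inter_event_gap_s=60.0)
        n = int(round(protocol.duration_s * protocol.fps))
        run = simulate_arteriole_run(
            vasc, np.full(n, 70.0), protocol, "control", seed=0
        )
        off_s = protocol.onsets_s()[0] + protocol.stim_duration_s
        t_post = run.time_s[run.time_s >= off_s] - off_s
        level = vasc.baseline_diameter * 0.10  # 10% dilation, rise saturated
        expected = vasc.baseline_diameter + level * np.exp(-0.45 * t_post)
        np.testing.assert_allclose(
            run.diameter_um[run.time_s >= off_s], expected, rtol=1e-4
        )

    def test_short_map_trace_rejected(self):
        protocol = StimulusProtocol(n_events=2)
        with pytest.raises(ValueError, match="cover"):
            simulate_arteriole_run(VascularModel(), np.full(10, 70.0), protocol)

    def test_pulse_map_trace_spans_low_and_high(self):
        m = pulse_map_trace(1000, 3.75, 70.0, 100.0, on_start_s=30.0, tau_rise_s=20.0)
        assert m[0] == pytest.approx(70.0)
        assert m[-1] == pytest.approx(100.0, abs=1.0)


class TestBehaviorCohort:
    def test_zero_noise_recognition_index_exact(self):
        nor, _ = simulate_behavior_cohort(5, ri_baseline=0.5, ri_treated=0.75, noise=0.0)
        ri = nor["t_novel_s"] / (nor["t_novel_s"] + nor["t_familiar_s"])
        base = nor["timepoint"] == "baseline"
        np.testing.assert_allclose(ri[base], 0.5, atol=1e-12)
        np.testing.assert_allclose(ri[~base], 0.75, atol=1e-12)

    def test_full_alternation_all_triplets_distinct(self):
        _, ym = simulate_behavior_cohort(
            4, alt_baseline=100.0, alt_treated=100.0, noise=0.0, seed=3
        )
        for seq in ym["entry_sequence"]:
            for i in range(len(seq) - 2):
                assert len(set(seq[i : i + 3])) == 3

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            simulate_behavior_cohort(0)
        with pytest.raises(ValueError):
            simulate_behavior_cohort(2, ri_baseline=1.5)
        with pytest.raises(ValueError):
            simulate_behavior_cohort(2, alt_baseline=120.0)


class TestConfigValidation:
    def test_animal_invariants(self):
        with pytest.raises(ValueError):
            AnimalConfig(baseline_sbp=80.0, baseline_dbp=90.0)
        with pytest.raises(ValueError):
            AnimalConfig(baseline_hr=200.0)

    def test_kinetics_invariants(self):
        with pytest.raises(ValueError):
            PressorKinetics(tau_rise_min=0.0)
        with pytest.raises(ValueError):
            PressorKinetics(gain_decline_per_day=1.0)

    def test_vascular_invariants(self):
        with pytest.raises(ValueError):
            VascularModel(break_lo=100.0, break_hi=50.0)

    def test_circadian_sinusoid_modulation_bounded(self):
        c = CircadianProfile(waveform="sinusoid")
        t = np.arange(0.0, 86400.0, 60.0)
        m = c.modulation(t)
        assert m.min() >= 0.0 and m.max() <= 1.0
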