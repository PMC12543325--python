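"""Tests of hourly extraction, phase splitting, blocks and epoch deltas."""

import numpy as np
import pandas as pd
import pytest

from bpvkit.simulate import (
    AnimalConfig,
    CircadianProfile,
    SALINE_KINETICS,
    TelemetryRecording,
    build_pump_schedule,
    simulate_telemetry,
)
from bpvkit.timeseries import (
    EpochOffsetPolicy,
    assign_phase,
    block_summaries,
    hourly_from_extracts,
    hourly_table,
    phase_split,
    pump_epoch_deltas,
)


def make_recording(values: dict, time_s: np.ndarray, cadence=30.0, **meta):
    n = time_s.size
    sbp = np.asarray(values.get("sbp", np.full(n, 120.0)), dtype=float)
    dbp = np.asarray(values.get("dbp", np.full(n, 80.0)), dtype=float)
    data = pd.DataFrame(
        {
            "time_s": time_s,
            "sbp": sbp,
            "dbp": dbp,
            "map": dbp + (sbp - dbp) / 3.0,
            "pp": sbp - dbp,
            "hr": np.asarray(values.get("hr", np.full(n, 600.0)), dtype=float),
            "activity": np.zeros(n),
            "pump_on": np.asarray(values.get("pump_on", np.zeros(n, bool))),
        }
    )
    return TelemetryRecording(data=data, cadence_s=cadence, **meta)


class TestHourlyFromExtracts:
    def test_constant_channel(self):
        t = np.arange(0.0, 2 * 3600.0, 30.0)
        rec = make_recording({"sbp": np.full(t.size, 111.0)}, t)
        h = hourly_from_extracts(rec, "sbp")
        assert (h["value"] == 111.0).all()
        assert (h["n_contributing"] == 4).all()

    def test_quarter_mark_hand_mean(self):
        t = np.arange(0.0, 3600.0, 30.0)
        sbp = np.zeros(t.size)
        marks = {0.0: 100.0, 900.0: 110.0, 1800.0: 95.0, 2700.0: 105.0}
        for i, ti in enumerate(t):
            sbp[i] = marks.get(ti, 500.0)  # off-mark records must not matter
        rec = make_recording({"sbp": sbp}, t)
        h = hourly_from_extracts(rec, "sbp")
        assert h.loc[0, "value"] == pytest.approx(102.5)

    def test_gap_covering_two_quarter_marks(self):
        t = np.arange(0.0, 3600.0, 30.0)
        keep = ~((t >= 840.0) & (t <= 1860.0))  # 17-min hole over :15 and :30
        rec = make_recording({"sbp": np.full(keep.sum(), 100.0)}, t[keep])
        h = hourly_from_extracts(rec, "sbp")
        assert h.loc[0, "n_contributing"] == 2
        assert h.loc[0, "value"] == pytest.approx(100.0)

    def test_empty_hour_is_missing_not_zero(self):
        t = np.concatenate([np.arange(0.0, 3510.0, 30.0), np.arange(7290.0, 10800.0, 30.0)])
        rec = make_recording({"sbp": np.full(t.size, 90.0)}, t)
        h = hourly_from_extracts(rec, "sbp")
        assert h.loc[1, "n_contributing"] == 0
        assert np.isnan(h.loc[1, "value"])

    def test_unknown_channel_names_valid_ones(self):
        t = np.arange(0.0, 3600.0, 30.0)
        rec = make_recording({}, t)
        with pytest.raises(KeyError, match="sbp"):
            hourly_from_extracts(rec, "not_a_channel")

    def test_invariant_to_offmark_records(self):
        """Adding records away from quarter marks leaves hourly values alone."""
        t_marks = np.array([0.0, 900.0, 1800.0, 2700.0])
        rec1 = make_recording({"sbp": np.array([100.0, 110.0, 95.0, 105.0])}, t_marks, cadence=900.0)
        h1 = hourly_from_extracts(rec1, "sbp")
        t_all = np.arange(0.0, 3600.0, 30.0)
        sbp = np.full(t_all.size, 999.0)
        for m, v in zip(t_marks, [100.0, 110.0, 95.0, 105.0]):
            sbp[t_all == m] = v
        h2 = hourly_from_extracts(make_recording({"sbp": sbp}, t_all), "sbp")
        assert h1.loc[0, "value"] == h2.loc[0, "value"]


class TestPhaseSplit:
    def test_square_wave_phase_means(self):
        hours = np.arange(24)
        values = np.where(assign_phase(hours, 6) == "active", 130.0, 110.0)
        hourly = pd.DataFrame({"hour": hours, "value": values, "n_contributing": 4})
        out = phase_split(hourly, 6)
        active = out[out.phase == "active"]["mean"].iloc[0]
        inactive = out[out.phase == "inactive"]["mean"].iloc[0]
        assert active == pytest.approx(130.0)
        assert inactive == pytest.approx(110.0)
        assert (out["n_hours"] == 12).all()

    def test_lights_on_six_hour_assignment(self):
        phases = assign_phase(np.arange(24), 6)
        assert set(np.flatnonzero(phases == "inactive")) == set(range(6, 18))
        assert set(np.flatnonzero(phases == "active")) == set(range(18, 24)) | set(range(6))

    def test_partial_second_day_has_six_hours_per_phase(self):
        hourly = pd.DataFrame(
            {"hour": np.arange(36), "value": 100.0, "n_contributing": 4}
        )
        out = phase_split(hourly, 6, treatment_start_day=0)
        day2 = out[out.day == 2]
        assert sorted(day2["n_hours"]) == [6, 6]

    def test_phase_means_average_to_daily_mean(self):
        """Equal-weight mean of the two 12-hr phase means equals the 24-hr
        mean for complete days."""
        rng = np.random.default_rng(0)
        values = rng.normal(100.0, 10.0, 48)
        hourly = pd.DataFrame(
            {"hour": np.arange(48), "value": values, "n_contributing": 4}
        )
        out = phase_split(hourly, 6)
        for day in (1, 2):
            sel = out[out.day == day]
            daily = values[(day - 1) * 24 : day * 24].mean()
            assert sel["mean"].mean() == pytest.approx(daily, abs=1e-9)


class TestBlockSummaries:
    @staticmethod
    def _phases(animal_values):
        rows = []
        for aid, const in animal_values.items():
            for day in range(-4, 5):
                for phase in ("active", "inactive"):
                    rows.append(
                        {
                            "animal_id": aid,
                            "group": "BPV",
                            "channel": "sbp",
                            "day": day,
                            "phase": phase,
                            "mean": const if np.isscalar(const) else const(day),
                            "n_hours": 12,
                        }
                    )
        return pd.DataFrame(rows)

    def test_constant_input_blocks_and_deltas(self):
        per_animal, cohort = block_summaries(self._phases({"a": 97.0}))
        assert (per_animal["mean"] == 97.0).all()
        assert np.allclose(per_animal["delta_vs_baseline"], 0.0)
        assert (cohort["sem"] == 0.0).all()

    def test_two_animal_mean_and_sem(self):
        per_animal, cohort = block_summaries(self._phases({"a": 10.0, "b": 20.0}))
        row = cohort[(cohort.block == "1-2") & (cohort.phase == "active")].iloc[0]
        assert row["mean"] == pytest.approx(15.0)
        assert row["sem"] == pytest.approx(5.0)
        assert row["n_animals"] == 2

    def test_delta_vs_baseline(self):
        per_animal, _ = block_summaries(
            self._phases({"a": (lambda day: 97.0 if day > 0 else 91.0)})
        )
        treated = per_animal[per_animal.block != "Baseline"]
        assert np.allclose(treated["delta_vs_baseline"], 6.0)

    def test_no_pretreatment_days_warns(self, caplog):
        df = self._phases({"a": 100.0})
        with caplog.at_level("WARNING"):
            block_summaries(df[df.day > 0])
        assert "Baseline" in caplog.text

    def test_animal_order_invariance(self):
        df = self._phases({"a": 10.0, "b": 20.0, "c": 15.0})
        _, cohort1 = block_summaries(df)
        _, cohort2 = block_summaries(df.sample(frac=1.0, random_state=5))
        pd.testing.assert_frame_equal(
            cohort1.reset_index(drop=True), cohort2.reset_index(drop=True)
        )


class TestPumpEpochDeltas:
    def test_noiseless_step_recovers_plus_seventy(self):
        t = np.arange(0.0, 6 * 3600.0, 30.0)
        schedule = build_pump_schedule(3.0, 1.0, 0.25)
        on = schedule.pump_on(t)
        sbp = np.where(on, 183.0, 113.0)
        rec = make_recording({"sbp": sbp, "pump_on": on}, t)
        d = pump_epoch_deltas(rec, schedule)
        assert d[d.channel == "sbp"]["delta"].iloc[0] == pytest.approx(70.0)

    def test_saline_recording_deltas_near_zero(self):
        an = AnimalConfig(noise_sd_bp=4.0, noise_sd_hr=10.0, activity_burst_rate=0.0, seed=11)
        schedule = build_pump_schedule(3.0, 1.0, 2.0)
        rec = simulate_telemetry(an, CircadianProfile(), schedule, SALINE_KINETICS, 2)
        d = pump_epoch_deltas(rec, schedule)
        sbp = d[d.channel == "sbp"]["delta"]
        # null deltas: |mean| below 3 x SEM of a 5-min window difference
        sem = 4.0 * np.sqrt(2.0 / 10.0) / np.sqrt(len(sbp))
        assert abs(sbp.mean()) < 3.0 * sem

    def test_truncated_epochs_skipped(self):
        t = np.arange(0.0, 4.5 * 3600.0, 30.0)  # recording shorter than schedule
        schedule = build_pump_schedule(3.0, 1.0, 0.5, start_hour=1.0)
        rec = make_recording({"pump_on": schedule.pump_on(t)}, t)
        d = pump_epoch_deltas(rec, schedule)
        assert set(d["pulse_idx"]) == {0}

    def test_offset_policy_moves_windows(self):
        t = np.arange(0.0, 6 * 3600.0, 30.0)
        schedule = build_pump_schedule(4.0, 1.0, 0.5)
        on = schedule.pump_on(t)
        # ramp during the on hour: early on-window sees a lower mean
        sbp = np.where(on, 113.0 + 70.0 * (t % (4 * 3600.0)) / 3600.0, 113.0)
        rec = make_recording({"sbp": sbp, "pump_on": on}, t)
        late = pump_epoch_deltas(rec, schedule)
        early = pump_epoch_deltas(
            rec, schedule, offset_policy=EpochOffsetPolicy(on_end_offset_min=30.0)
        )
        assert (
            early[early.channel == "sbp"]["delta"].iloc[0]
            < late[late.channel == "sbp"]["delta"].iloc[0]
        )


def test_hourly_table_long_format(noiseless_saline_recording):
    df = hourly_table([noiseless_saline_recording], channels=("sbp", "hr"))
    assert set(df["channel"]) == {"sbp", "hr"}
    assert df["value"].notna().all()
    assert (df["n_contributing"] == 4).all()
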