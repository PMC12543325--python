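"""Windowing and summarization of telemetry recordings.

Implements the telemetry reduction chain used for blood-pressure analysis:
quarter-hour extraction -> hourly means -> 12:12 active/inactive phase
splits -> daily and two-day block aggregation, plus pump-epoch on/off
deltas around individual infusion pulses.

Hour indices are 0-based from recording start; t = 0 is clock midnight.
Study days are 1-based from treatment onset (day 1 = first full treatment
day); baseline days are indexed <= 0.  Missing hours propagate as NaN with
``n_contributing = 0``, never as zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulate import CHANNELS, PumpSchedule, TelemetryRecording, SECONDS_PER_HOUR

logger = logging.getLogger(__name__)

QUARTER_MARKS_S = (0.0, 900.0, 1800.0, 2700.0)


def hourly_from_extracts(
    recording: TelemetryRecording, channel: str
) -> pd.DataFrame:
    """Hourly series from quarter-hour extracts.

    For each clock hour the single record nearest each of the four
    quarter-hour marks (:00, :15, :30, :45) is extracted and the <= 4
    extracted values are averaged.  A mark with no record within one
    cadence interval counts as missing; hours with no extracts at all are
    emitted with NaN and ``n_contributing = 0``.

    Returns a DataFrame with columns ``hour, value, n_contributing``.
    """
    values = recording.channel(channel)  # raises on unknown channel
    t = recording.time_s
    if t.size == 0:
        return pd.DataFrame(columns=["hour", "value", "n_contributing"])
    if SECONDS_PER_HOUR / 4.0 % recording.cadence_s != 0:
        raise ValueError("recording cadence must divide 15 min")
    n_hours = int(np.floor((t[-1] + recording.cadence_s) / SECONDS_PER_HOUR - 1e-9)) + 1
    rows = []
    for hour in range(n_hours):
        extracts = []
        for mark in QUARTER_MARKS_S:
            target = hour * SECONDS_PER_HOUR + mark
            i = int(np.searchsorted(t, target))
            best, dist = None, np.inf
            for j in (i - 1, i):
                if 0 <= j < t.size and abs(t[j] - target) < dist:
                    best, dist = j, abs(t[j] - target)
            if best is not None and dist <= recording.cadence_s:
                extracts.append(values[best])
        rows.append(
            {
                "hour": hour,
                "value": float(np.mean(extracts)) if extracts else np.nan,
                "n_contributing": len(extracts),
            }
        )
    return pd.DataFrame(rows)


def hourly_table(
    recordings: list[TelemetryRecording], channels: tuple[str, ...] = CHANNELS
) -> pd.DataFrame:
    """Long-format hourly table for a cohort.

    Columns: ``animal_id, group, hour, channel, value, n_contributing``.
    """
    frames = []
    for rec in recordings:
        for ch in channels:
            h = hourly_from_extracts(rec, ch)
            h["animal_id"] = rec.animal_id
            h["group"] = rec.group
            h["channel"] = ch
            frames.append(h)
    return pd.concat(frames, ignore_index=True)[
        ["animal_id", "group", "hour", "channel", "value", "n_contributing"]
    ]


def assign_phase(hours: np.ndarray, lights_on_clock_hour: int) -> np.ndarray:
    """'inactive' for the lights-on half of the 12:12 cycle, else 'active'."""
    hod = np.asarray(hours) % 24
    inactive = ((hod - lights_on_clock_hour) % 24) < 12
    return np.where(inactive, "inactive", "active")


def study_day(hours: np.ndarray, treatment_start_day: int) -> np.ndarray:
    """Map hour indices to study days: treatment day 1, 2, ... and
    baseline days 0, -1, ... (day 1 = first full day of treatment)."""
    abs_day = np.asarray(hours) // 24
    rel = abs_day - treatment_start_day
    return np.where(rel >= 0, rel + 1, rel)


def phase_split(
    hourly: pd.DataFrame,
    lights_on_clock_hour: int = 6,
    treatment_start_day: int = 0,
) -> pd.DataFrame:
    """Per-day active/inactive phase means of an hourly series.

    Accepts a single-channel frame from :func:`hourly_from_extracts` or the
    long cohort table from :func:`hourly_table`; rows with missing hourly
    values are excluded from means but partial days are still summarized
    (``n_hours < 12``).
    """
    df = hourly.copy()
    df["phase"] = assign_phase(df["hour"].to_numpy(), lights_on_clock_hour)
    df["day"] = study_day(df["hour"].to_numpy(), treatment_start_day)
    keys = [c for c in ("animal_id", "group", "channel") if c in df.columns]
    grouped = df.groupby(keys + ["day", "phase"], sort=True)["value"]
    out = grouped.agg(mean="mean", n_hours="count").reset_index()
    return out


def block_label(day: int, block_days: int = 2) -> str:
    start = ((int(day) - 1) // block_days) * block_days + 1
    return f"{start}-{start + block_days - 1}"


def block_summaries(
    phase_summaries: pd.DataFrame,
    block_days: int = 2,
    baseline_days: int = 5,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Baseline and two-day treatment-block aggregation.

    ``phase_summaries`` is the output of :func:`phase_split` (cohort form,
    with ``animal_id``).  The Baseline block averages the last
    ``baseline_days`` pre-treatment days (day <= 0); treatment blocks are
    consecutive non-overlapping ``block_days`` windows labelled "1-2",
    "3-4", ...

    Returns ``(per_animal, cohort)``: per-animal block means with deltas vs
    Baseline, and the cohort mean/SEM per group/phase/channel/block.
    """
    df = phase_summaries.copy()
    is_base = df["day"] <= 0
    if not is_base.any():
        logger.warning("no pre-treatment days: Baseline block omitted")
    base_keep = is_base & (df["day"] > -baseline_days)
    df = df[base_keep | ~is_base].copy()
    df["block"] = np.where(
        df["day"] <= 0,
        "Baseline",
        [block_label(d, block_days) for d in df["day"]],
    )
    keys = [c for c in ("animal_id", "group", "channel") if c in df.columns]
    per_animal = (
        df.groupby(keys + ["phase", "block"], sort=False)["mean"]
        .mean()
        .reset_index()
    )
    # order blocks: Baseline first, then by starting day
    per_animal = per_animal.sort_values(
        keys + ["phase", "block"],
        key=lambda s: s.map(_block_sort_key) if s.name == "block" else s,
        kind="stable",
    ).reset_index(drop=True)

    base = per_animal[per_animal["block"] == "Baseline"][
        keys + ["phase", "mean"]
    ].rename(columns={"mean": "baseline_mean"})
    per_animal = per_animal.merge(base, on=keys + ["phase"], how="left")
    per_animal["delta_vs_baseline"] = (
        per_animal["mean"] - per_animal["baseline_mean"]
    )

    cohort_keys = [c for c in ("group", "channel") if c in per_animal.columns]
    cohort = (
        per_animal.groupby(cohort_keys + ["phase", "block"], sort=False)["mean"]
        .agg(
            mean="mean",
            sem=lambda s: s.std(ddof=1) / np.sqrt(s.count()) if s.count() > 1 else 0.0,
            n_animals="count",
        )
        .reset_index()
    )
    cohort = cohort.sort_values(
        cohort_keys + ["phase", "block"],
        key=lambda s: s.map(_block_sort_key) if s.name == "block" else s,
        kind="stable",
    ).reset_index(drop=True)
    return per_animal, cohort


def _block_sort_key(label: str):
    return -1 if label == "Baseline" else int(str(label).split("-")[0])


@dataclass(frozen=True)
class EpochOffsetPolicy:
    """Placement of the 5-min on/off windows around a pulse.

    ``on_end_offset_min`` minutes before the end of the on-period mark the
    end of the on-window (0 = window covers the last minutes of the pulse,
    i.e. the plateau); ``off_end_offset_min`` minutes before pulse onset
    mark the end of the off-window (0 = window immediately precedes onset).
    """

    on_end_offset_min: float = 0.0
    off_end_offset_min: float = 0.0


def pump_epoch_deltas(
    recording: TelemetryRecording,
    schedule: PumpSchedule,
    window_min: float = 5.0,
    offset_policy: EpochOffsetPolicy | None = None,
    channels: tuple[str, ...] = CHANNELS,
) -> pd.DataFrame:
    """Per-pulse 5-min pump-off vs pump-on window means and deltas.

    The on-window sits at the end of the 1-hr on-period (pressor plateau)
    and the off-window in the minutes immediately preceding onset, both
    adjustable through ``offset_policy``.  Pulses whose windows fall
    outside the recording are skipped with a log entry.

    Returns a tidy frame: ``pulse_idx, phase, channel, off_mean, on_mean,
    delta``.
    """
    policy = offset_policy or EpochOffsetPolicy()
    t = recording.time_s
    w = window_min * 60.0
    rows = []
    for idx, (a_h, b_h) in enumerate(schedule.on_intervals):
        a, b = a_h * SECONDS_PER_HOUR, b_h * SECONDS_PER_HOUR
        on_end = b - policy.on_end_offset_min * 60.0
        off_end = a - policy.off_end_offset_min * 60.0
        on_lo, off_lo = on_end - w, off_end - w
        if off_lo < t[0] or on_end > t[-1] + recording.cadence_s:
            logger.info("pulse %d: window truncated by recording edge, skipped", idx)
            continue
        on_sel = (t >= on_lo) & (t < on_end)
        off_sel = (t >= off_lo) & (t < off_end)
        if not on_sel.any() or not off_sel.any():
            logger.info("pulse %d: empty epoch window, skipped", idx)
            continue
        phase = assign_phase(
            np.array([a / SECONDS_PER_HOUR]), recording.lights_on_clock_hour
        )[0]
        for ch in channels:
            v = recording.channel(ch)
            off_mean = float(v[off_sel].mean())
            on_mean = float(v[on_sel].mean())
            rows.append(
                {
                    "pulse_idx": idx,
                    "phase": phase,
                    "channel": ch,
                    "off_mean": off_mean,
                    "on_mean": on_mean,
                    "delta": on_mean - off_mean,
                }
            )
    return pd.DataFrame(
        rows, columns=["pulse_idx", "phase", "channel", "off_mean", "on_mean", "delta"]
    )
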