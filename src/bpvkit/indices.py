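"""Blood-pressure-variability indices: ARV and CV, and their time courses.

ARV (average real variability) is the mean absolute difference between
consecutive BP readings, ARV = 1/(N-1) * sum |BP_{k+1} - BP_k|; unlike the
standard deviation it is sensitive to the ordering of measurements.  CV
(coefficient of variation) is the standard deviation of hourly BP averages
divided by a reference mean (the 24-hr average for 24-hr CV).

Both indices are computed on hourly values (the product of quarter-hour
extraction, see :mod:`bpvkit.timeseries`).  For 12-hr (phase) ARV,
successive differences are taken only within a contiguous run of same-phase
hours -- never across the active/inactive boundary or across a day gap.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

from .timeseries import assign_phase, block_label, study_day

logger = logging.getLogger(__name__)


def arv(values) -> float:
    """Average real variability: mean absolute successive difference.

    ``values`` must be time-ordered with no missing entries (the caller
    drops gaps while preserving order).  Returns NaN with a warning for
    fewer than two values.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        warnings.warn("ARV requires at least 2 values; returning NaN", stacklevel=2)
        return float("nan")
    return float(np.mean(np.abs(np.diff(x))))


def _arv_segments(segments: list[np.ndarray]) -> tuple[float, int]:
    """ARV pooled over contiguous segments: total |diff| / total pairs."""
    total, pairs, n_values = 0.0, 0, 0
    for seg in segments:
        seg = np.asarray(seg, dtype=float)
        n_values += seg.size
        if seg.size >= 2:
            total += float(np.sum(np.abs(np.diff(seg))))
            pairs += seg.size - 1
    if pairs == 0:
        return float("nan"), n_values
    return total / pairs, n_values


def cv(hourly_values, reference_mean: float | None = None) -> float:
    """Coefficient of variation of hourly BP averages.

    Sample (n-1) standard deviation of the hourly values divided by
    ``reference_mean`` (default: the mean of the supplied values, i.e. the
    24-hr BP average when a full day of hourly values is passed).
    """
    x = np.asarray(hourly_values, dtype=float)
    x = x[~np.isnan(x)]
    if x.size < 2:
        warnings.warn("CV requires at least 2 values; returning NaN", stacklevel=2)
        return float("nan")
    if reference_mean is None:
        reference_mean = float(x.mean())
    if reference_mean <= 0:
        raise ValueError("reference_mean must be positive")
    return float(x.std(ddof=1) / reference_mean)


def _contiguous_runs(hours: np.ndarray, values: np.ndarray) -> list[np.ndarray]:
    """Split hour-ordered values into runs of consecutive hours."""
    order = np.argsort(hours)
    hours, values = hours[order], values[order]
    ok = ~np.isnan(values)
    hours, values = hours[ok], values[ok]
    if hours.size == 0:
        return []
    breaks = np.where(np.diff(hours) != 1)[0] + 1
    return np.split(values, breaks)


def bpv_timecourse(
    hourly: pd.DataFrame,
    lights_on_clock_hour: int = 6,
    treatment_start_day: int = 0,
    block_days: int = 2,
    baseline_days: int = 5,
    cv_use_24h_denominator: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """ARV/CV per animal/day/phase/channel with two-day block aggregation.

    ``hourly`` is the long cohort table from
    :func:`bpvkit.timeseries.hourly_table`.  For each animal, channel and
    day, ARV and CV are computed over the day's hourly values for the
    active phase, the inactive phase and the full day ("24h").  Per the
    printed CV formula the 24-hr average is the denominator of 24-hr CV;
    12-hr CV divides by the phase mean by default, or by the day's 24-hr
    mean when ``cv_use_24h_denominator`` is set.

    Returns ``(daily, per_animal_blocks, cohort_blocks)``.
    """
    df = hourly.copy()
    df["phase"] = assign_phase(df["hour"].to_numpy(), lights_on_clock_hour)
    df["day"] = study_day(df["hour"].to_numpy(), treatment_start_day)

    rows = []
    for (aid, group, ch, day), sub in df.groupby(
        ["animal_id", "group", "channel", "day"], sort=True
    ):
        hours = sub["hour"].to_numpy()
        values = sub["value"].to_numpy(dtype=float)
        phases = sub["phase"].to_numpy()
        day_mean = float(np.nanmean(values)) if np.any(~np.isnan(values)) else np.nan
        for phase in ("active", "inactive", "24h"):
            sel = np.ones(len(sub), bool) if phase == "24h" else phases == phase
            runs = _contiguous_runs(hours[sel], values[sel])
            arv_val, n_vals = _arv_segments(runs)
            flat = values[sel][~np.isnan(values[sel])]
            if flat.size >= 2:
                ref = day_mean if (phase == "24h" or cv_use_24h_denominator) else float(
                    flat.mean()
                )
                cv_val = cv(flat, ref) if ref > 0 else np.nan
            else:
                cv_val = np.nan
            rows.append(
                {
                    "animal_id": aid,
                    "group": group,
                    "channel": ch,
                    "day": day,
                    "phase": phase,
                    "arv": arv_val,
                    "cv": cv_val,
                    "n": n_vals,
                }
            )
    daily = pd.DataFrame(rows)

    blocks = daily[(daily["day"] > 0) | (daily["day"] > -baseline_days)].copy()
    blocks["block"] = np.where(
        blocks["day"] <= 0,
        "Baseline",
        [block_label(d, block_days) for d in blocks["day"]],
    )
    per_animal = (
        blocks.groupby(
            ["animal_id", "group", "channel", "phase", "block"], sort=False
        )[["arv", "cv"]]
        .mean()
        .reset_index()
    )
    all_missing = per_animal[["arv", "cv"]].isna().all(axis=1)
    if all_missing.any():
        logger.warning("%d all-missing block rows dropped", int(all_missing.sum()))
        per_animal = per_animal[~all_missing].reset_index(drop=True)

    def _sem(s: pd.Series) -> float:
        return float(s.std(ddof=1) / np.sqrt(s.count())) if s.count() > 1 else 0.0

    cohort = (
        per_animal.groupby(["group", "channel", "phase", "block"], sort=False)
        .agg(
            arv_mean=("arv", "mean"),
            arv_sem=("arv", _sem),
            cv_mean=("cv", "mean"),
            cv_sem=("cv", _sem),
            n_animals=("arv", "count"),
        )
        .reset_index()
    )
    return daily, per_animal, cohort
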