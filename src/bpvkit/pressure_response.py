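"""Regression analyses of pressure-coupled responses.

Covers the baroreflex (SBP-HR slope over a 100-min window surrounding a
single pressor pulse), the in-vivo myogenic response (MAP-diameter slope
over an imaging session), segmented cerebral-autoregulation slopes across
the lower-limit / plateau / upper-limit pressure ranges, and directional
transition slopes for low-to-high vs high-to-low BP transitions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .simulate import PumpSchedule, TelemetryRecording, SECONDS_PER_HOUR
from .timeseries import assign_phase

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SlopeFit:
    """Ordinary-least-squares fit of y on x."""

    slope: float
    intercept: float
    r_squared: float
    p_value_slope: float
    n_points: int
    x_range: tuple[float, float]


@dataclass(frozen=True)
class PulseWindow:
    """Analysis window around one infusion pulse: ``pre_min`` before onset,
    the ``pulse_min`` on-period, and ``post_min`` after offset (100 min
    total by default)."""

    onset_s: float
    pre_min: float = 20.0
    pulse_min: float = 60.0
    post_min: float = 20.0
    phase: str | None = None
    epoch: str | None = None  # Early | Late

    @property
    def total_min(self) -> float:
        return self.pre_min + self.pulse_min + self.post_min

    @property
    def start_s(self) -> float:
        return self.onset_s - self.pre_min * 60.0

    @property
    def end_s(self) -> float:
        return self.onset_s + (self.pulse_min + self.post_min) * 60.0


def ols_fit(x, y) -> SlopeFit:
    """OLS fit with a two-sided t-test p-value for the slope."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError(f"need >= 3 points for a fit, got {x.size}")
    if np.ptp(x) == 0:
        raise ValueError(f"degenerate x (all equal to {x[0]}) in fit window")
    res = stats.linregress(x, y)
    return SlopeFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        p_value_slope=float(res.pvalue),
        n_points=int(x.size),
        x_range=(float(x.min()), float(x.max())),
    )


def baroreflex_slope(
    recording: TelemetryRecording, window: PulseWindow
) -> SlopeFit:
    """SBP-HR regression over the 100-min window surrounding one pulse.

    x = SBP (mmHg), y = HR (bpm); the slope is the baroreflex gain in
    bpm/mmHg (negative for a bradycardic response).  The pulse onset is
    verified against the recording's pump annotation.
    """
    t = recording.time_s
    if window.start_s < t[0] or window.end_s > t[-1] + recording.cadence_s:
        raise ValueError("pulse window clipped by recording bounds")
    pump_on = recording.data["pump_on"].to_numpy()
    at_onset = (t >= window.onset_s) & (t < window.onset_s + 2 * recording.cadence_s)
    if not pump_on[at_onset].any():
        raise ValueError(
            f"no pump-on annotation at onset t={window.onset_s} s; "
            "window does not match a pulse"
        )
    sel = (t >= window.start_s) & (t < window.end_s)
    return ols_fit(recording.channel("sbp")[sel], recording.channel("hr")[sel])


def pulse_windows(
    recording: TelemetryRecording,
    schedule: PumpSchedule,
    early_days: tuple[int, int] = (3, 5),
    late_days: tuple[int, int] = (23, 25),
) -> list[PulseWindow]:
    """Enumerate fully-covered pulse windows, labelled by phase and epoch.

    Epoch day ranges are counted in study days (day 1 = first full
    treatment day) and are configurable; pulses outside both ranges carry
    ``epoch=None``.
    """
    t = recording.time_s
    windows = []
    for a_h, _ in schedule.on_intervals:
        w = PulseWindow(onset_s=a_h * SECONDS_PER_HOUR)
        if w.start_s < t[0] or w.end_s > t[-1] + recording.cadence_s:
            continue
        day = int(a_h // 24) - recording.treatment_start_day + 1
        if early_days[0] <= day <= early_days[1]:
            epoch = "Early"
        elif late_days[0] <= day <= late_days[1]:
            epoch = "Late"
        else:
            epoch = None
        phase = assign_phase(np.array([a_h]), recording.lights_on_clock_hour)[0]
        windows.append(
            PulseWindow(onset_s=w.onset_s, phase=str(phase), epoch=epoch)
        )
    return windows


def segmented_slopes(
    map_values,
    diameter_change_values,
    breaks: tuple[float, float] = (50.0, 100.0),
) -> dict[str, SlopeFit | None]:
    """Independent OLS fits on the three autoregulation pressure bins.

    Bins are half-open: ``[min, breaks[0]]``, ``(breaks[0], breaks[1]]``,
    ``(breaks[1], max]`` -- the lower autoregulatory limit, the plateau
    range and the upper range.  ``diameter_change_values`` are diameter
    changes relative to the reference-pressure (~70 mmHg) baseline.  Bins
    with fewer than 3 points are reported as None.
    """
    p = np.asarray(map_values, dtype=float)
    d = np.asarray(diameter_change_values, dtype=float)
    lo, hi = breaks
    masks = {"low": p <= lo, "mid": (p > lo) & (p <= hi), "high": p > hi}
    out: dict[str, SlopeFit | None] = {}
    for name, mask in masks.items():
        if mask.sum() < 3 or np.ptp(p[mask]) == 0:
            logger.info("segmented bin %r has <3 usable points; missing", name)
            out[name] = None
        else:
            out[name] = ols_fit(p[mask], d[mask])
    return out


def _first_crossing(values: np.ndarray, threshold: float, rising: bool) -> int:
    hit = values >= threshold if rising else values <= threshold
    idx = np.flatnonzero(hit)
    return int(idx[0]) if idx.size else values.size - 1


def transition_slopes(
    time_s,
    map_mmHg,
    diameter_um,
    schedule: PumpSchedule,
    settle_fraction: float = 0.9,
    ref_window_s: float = 60.0,
) -> dict[str, SlopeFit | None]:
    """Directional MAP-diameter slopes across pump on/off transitions.

    Rising (low-to-high) segments run from each pump-on onset until MAP
    first reaches ``settle_fraction`` of its plateau elevation; falling
    (high-to-low) segments symmetrically from pump-off until MAP has shed
    that fraction of the elevation.  Plateau and pre/post baselines are
    ``ref_window_s`` means adjacent to the transition.  Samples are pooled
    per direction and fitted by OLS (diameter on MAP).
    """
    t = np.asarray(time_s, dtype=float)
    p = np.asarray(map_mmHg, dtype=float)
    d = np.asarray(diameter_um, dtype=float)
    rising_idx: list[np.ndarray] = []
    falling_idx: list[np.ndarray] = []
    n_transitions = 0
    for a_h, b_h in schedule.on_intervals:
        a, b = a_h * SECONDS_PER_HOUR, b_h * SECONDS_PER_HOUR
        if not (t[0] <= a <= t[-1] or t[0] <= b <= t[-1]):
            continue
        n_transitions += 1
        pre = (t >= a - ref_window_s) & (t < a)
        plateau = (t >= b - ref_window_s) & (t < b)
        if t[0] <= a <= t[-1] and pre.any() and plateau.any():
            base, top = p[pre].mean(), p[plateau].mean()
            seg = np.flatnonzero((t >= a) & (t < b))
            if seg.size:
                stop = _first_crossing(
                    p[seg], base + settle_fraction * (top - base), rising=True
                )
                rising_idx.append(seg[: stop + 1])
        if t[0] <= b <= t[-1] and plateau.any():
            top = p[plateau].mean()
            after = np.flatnonzero(t >= b)
            if after.size:
                base = float(np.min(p[after]))
                stop = _first_crossing(
                    p[after], top - settle_fraction * (top - base), rising=False
                )
                falling_idx.append(after[: stop + 1])
    if n_transitions == 0:
        logger.warning("no pump transitions inside the run; fits missing")
        return {"low_to_high": None, "high_to_low": None}
    out: dict[str, SlopeFit | None] = {}
    for name, chunks in (("low_to_high", rising_idx), ("high_to_low", falling_idx)):
        if not chunks:
            out[name] = None
            continue
        idx = np.concatenate(chunks)
        if idx.size < 3 or np.ptp(p[idx]) == 0:
            out[name] = None
        else:
            out[name] = ols_fit(p[idx], d[idx])
    return out
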