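"""Synthetic murine telemetry, arteriole-imaging, and behavior generators.

The simulator emulates a chronic blood-pressure-variability (BPV) study
design: a subcutaneous pump delivers 1-hr pressor pulses every 3-4 hr on
top of a 12:12 circadian rhythm, while an implanted telemeter samples
SBP/DBP/HR/activity every 30 s.  Companion generators produce arteriole
diameter runs (autoregulation + neurovascular coupling) and behavior logs
(novel-object recognition, Y-maze) with configurable effect sizes, so the
analysis modules can be exercised and calibrated without animal data.

Conventions
-----------
* Time 0 of a recording is clock midnight; hour-of-day = hour index mod 24.
* The active (dark) phase is the lights-off half of the 12:12 cycle.
* MAP is composed as DBP + PP/3 (the standard one-third rule); SBP and DBP
  are the simulated channels, MAP and PP derive from them exactly.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SECONDS_PER_HOUR = 3600.0
SECONDS_PER_DAY = 86400.0

#: telemetry channels carried by every recording
CHANNELS = ("sbp", "dbp", "map", "pp", "hr", "activity")


class InvalidScheduleError(ValueError):
    """Raised when a pump schedule cannot be constructed."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PumpSchedule:
    """Infusion on/off programme of the subcutaneous pump.

    ``on_intervals`` are half-open ``(start, end)`` pairs in hours from
    recording start, sorted and non-overlapping, each of length
    ``on_hours``.
    """

    on_intervals: tuple[tuple[float, float], ...]
    infusate: str = "angII"
    bolus_volume_ul: float = 2.0
    cycle_hours: float = 4.0
    on_hours: float = 1.0

    def __post_init__(self) -> None:
        prev_end = -math.inf
        for a, b in self.on_intervals:
            if not a < b:
                raise InvalidScheduleError(f"empty interval ({a}, {b})")
            if a < prev_end:
                raise InvalidScheduleError("intervals overlap or are unsorted")
            prev_end = b

    @property
    def n_pulses(self) -> int:
        return len(self.on_intervals)

    def pump_on(self, time_s: np.ndarray) -> np.ndarray:
        """Boolean pump-state annotation on a time grid (seconds)."""
        t_h = np.asarray(time_s, dtype=float) / SECONDS_PER_HOUR
        on = np.zeros(t_h.shape, dtype=bool)
        for a, b in self.on_intervals:
            on |= (t_h >= a) & (t_h < b)
        return on


@dataclass(frozen=True)
class PressorKinetics:
    """Two-time-constant pharmacodynamic envelope of one pressor pulse.

    The unitless effect rises first-order with ``tau_rise_min`` while the
    pump is on and decays exponentially with half-life
    ``t_half_decay_min`` after it switches off; plateau BP amplitudes and
    the reflex heart-rate gain scale that envelope.  ``hr_gain`` is signed:
    negative values give the baroreflex bradycardia of angiotensin II,
    positive values the tachycardia of norepinephrine.
    ``gain_decline_per_day`` linearly blunts |hr_gain| over treatment days
    (floored at zero), emulating chronic suppression of the reflex.
    """

    tau_rise_min: float = 5.0
    t_half_decay_min: float = 10.0
    delta_sbp: float = 70.0
    delta_dbp: float = 29.0
    hr_gain: float = -4.2
    gain_decline_per_day: float = 0.0

    def __post_init__(self) -> None:
        if self.tau_rise_min <= 0 or self.t_half_decay_min <= 0:
            raise ValueError("time constants must be positive")
        if not 0 <= self.gain_decline_per_day < 1:
            raise ValueError("gain_decline_per_day must be in [0, 1)")

    @property
    def delta_map(self) -> float:
        """Plateau MAP amplitude under the MAP = DBP + PP/3 convention."""
        return self.delta_dbp + (self.delta_sbp - self.delta_dbp) / 3.0


#: saline vehicle: no pressor action at all
SALINE_KINETICS = PressorKinetics(delta_sbp=0.0, delta_dbp=0.0, hr_gain=0.0)


@dataclass(frozen=True)
class CircadianProfile:
    """12:12 light/dark modulation added during the active (dark) phase."""

    lights_on_clock_hour: int = 6
    phase_increment_sbp: float = 15.0
    phase_increment_dbp: float = 10.0
    phase_increment_hr: float = 40.0
    phase_increment_activity: float = 2.0
    waveform: str = "square"  # square | sinusoid

    def active_mask(self, time_s: np.ndarray) -> np.ndarray:
        hod = (np.asarray(time_s, float) / SECONDS_PER_HOUR) % 24.0
        # inactive = lights-on half
        return ((hod - self.lights_on_clock_hour) % 24.0) >= 12.0

    def modulation(self, time_s: np.ndarray) -> np.ndarray:
        """Unitless 0..1 waveform; multiply by a phase increment."""
        t = np.asarray(time_s, dtype=float)
        if self.waveform == "square":
            return self.active_mask(t).astype(float)
        if self.waveform == "sinusoid":
            hod = (t / SECONDS_PER_HOUR) % 24.0
            mid_active = (self.lights_on_clock_hour + 18.0) % 24.0
            return 0.5 * (1.0 + np.cos(2.0 * np.pi * (hod - mid_active) / 24.0))
        raise ValueError(f"unknown waveform {self.waveform!r}")


@dataclass(frozen=True)
class AnimalConfig:
    """Per-animal baseline physiology and noise levels."""

    animal_id: str = "m1"
    group: str = "control"  # control | BPV
    baseline_sbp: float = 113.0
    baseline_dbp: float = 80.0
    baseline_hr: float = 612.0
    noise_sd_bp: float = 6.0
    noise_sd_hr: float = 20.0
    activity_burst_rate: float = 2.0  # events/hour
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.baseline_sbp > self.baseline_dbp > 0):
            raise ValueError("require baseline_sbp > baseline_dbp > 0")
        if not (300 < self.baseline_hr < 800):
            raise ValueError("baseline_hr outside murine range (300, 800)")


@dataclass(frozen=True)
class TelemetryRecording:
    """Uniform-cadence multichannel cardiovascular time series.

    ``data`` columns: time_s, sbp, dbp, map, pp, hr, activity, pump_on.
    Invariants: DBP <= MAP <= SBP per record, PP = SBP - DBP exactly,
    uniform cadence.
    """

    data: pd.DataFrame
    cadence_s: float = 30.0
    animal_id: str = "m1"
    group: str = "control"
    lights_on_clock_hour: int = 6
    treatment_start_day: int = 0

    @property
    def time_s(self) -> np.ndarray:
        return self.data["time_s"].to_numpy()

    def channel(self, name: str) -> np.ndarray:
        if name not in CHANNELS:
            raise KeyError(f"unknown channel {name!r}; valid: {CHANNELS}")
        return self.data[name].to_numpy()

    @property
    def duration_s(self) -> float:
        t = self.time_s
        return float(t[-1] - t[0] + self.cadence_s) if len(t) else 0.0


# ---------------------------------------------------------------------------
# pump schedule and pressor envelope
# ---------------------------------------------------------------------------


def build_pump_schedule(
    cycle_hours: float,
    on_hours: float = 1.0,
    days: float = 1.0,
    infusate: str = "angII",
    start_hour: float = 0.0,
) -> PumpSchedule:
    """Programme the pump: one ``on_hours`` pulse at each multiple of
    ``cycle_hours`` within ``[start_hour, start_hour + 24*days)``.

    The study design uses cycles of 3 hr (8 pulses/day) or 4 hr
    (6 pulses/day); other cycles are accepted with a warning.
    """
    if on_hours >= cycle_hours:
        raise InvalidScheduleError(
            f"on_hours ({on_hours}) must be < cycle_hours ({cycle_hours})"
        )
    if days < 0:
        raise InvalidScheduleError("days must be >= 0")
    if cycle_hours not in (3.0, 4.0):
        warnings.warn(
            f"non-standard cycle_hours={cycle_hours}; study design uses 3 or 4",
            stacklevel=2,
        )
    horizon = 24.0 * days
    n = math.ceil(horizon / cycle_hours - 1e-12)
    starts = [start_hour + k * cycle_hours for k in range(max(n, 0))]
    intervals = tuple((s, s + on_hours) for s in starts if s - start_hour < horizon)
    return PumpSchedule(
        on_intervals=intervals,
        infusate=infusate,
        cycle_hours=cycle_hours,
        on_hours=on_hours,
    )


def pressor_effect_trace(
    schedule: PumpSchedule,
    kinetics: PressorKinetics,
    time_grid_s: np.ndarray,
    active_from_hour: float = 0.0,
) -> np.ndarray:
    """Unitless pressor envelope in [0, 1] on a sorted uniform time grid.

    While the pump is on the effect relaxes toward 1 with time constant
    ``tau_rise_min``; when it switches off the effect decays with half-life
    ``t_half_decay_min``.  Intervals starting before ``active_from_hour``
    (e.g. the saline baseline phase) contribute nothing.
    """
    t = np.asarray(time_grid_s, dtype=float)
    if t.size == 0:
        return np.zeros(0)
    effect = np.zeros_like(t)
    tau_r = kinetics.tau_rise_min * 60.0
    lam = math.log(2.0) / (kinetics.t_half_decay_min * 60.0)
    level = 0.0
    prev_end: float | None = None
    for a_h, b_h in schedule.on_intervals:
        if a_h < active_from_hour - 1e-12:
            continue
        a, b = a_h * SECONDS_PER_HOUR, b_h * SECONDS_PER_HOUR
        if prev_end is not None:
            seg = (t >= prev_end) & (t < a)
            effect[seg] = level * np.exp(-lam * (t[seg] - prev_end))
            level *= math.exp(-lam * (a - prev_end))
        seg = (t >= a) & (t < b)
        effect[seg] = 1.0 - (1.0 - level) * np.exp(-(t[seg] - a) / tau_r)
        level = 1.0 - (1.0 - level) * math.exp(-(b - a) / tau_r)
        prev_end = b
    if prev_end is not None:
        seg = t >= prev_end
        effect[seg] = level * np.exp(-lam * (t[seg] - prev_end))
    return effect


# ---------------------------------------------------------------------------
# telemetry simulation
# ---------------------------------------------------------------------------

# Activity-burst couplings: each Poisson burst carries an a.u. amplitude
# that bleeds into BP and HR with exponential decay, reproducing the large
# activity-linked BP excursions seen in raw telemetry traces.
BURST_DECAY_TAU_S = 120.0
BURST_BP_COUPLING = 10.0  # mmHg per a.u.
BURST_DBP_FRACTION = 0.6
BURST_HR_COUPLING = 30.0  # bpm per a.u.


def _activity_bursts(
    rng: np.random.Generator, t: np.ndarray, rate_per_hour: float
) -> np.ndarray:
    """Poisson-timed exponentially decaying activity excursions (a.u.)."""
    out = np.zeros_like(t)
    if rate_per_hour <= 0 or t.size == 0:
        return out
    duration_h = (t[-1] - t[0]) / SECONDS_PER_HOUR
    n_events = rng.poisson(rate_per_hour * duration_h)
    if n_events == 0:
        return out
    onsets = np.sort(rng.uniform(t[0], t[-1], size=n_events))
    amps = rng.exponential(1.0, size=n_events)
    cadence = t[1] - t[0] if t.size > 1 else 30.0
    tail = int(10 * BURST_DECAY_TAU_S / cadence) + 1
    for onset, amp in zip(onsets, amps):
        i0 = int(np.searchsorted(t, onset))
        i1 = min(i0 + tail, t.size)
        out[i0:i1] += amp * np.exp(-(t[i0:i1] - onset) / BURST_DECAY_TAU_S)
    return out


def simulate_telemetry(
    animal: AnimalConfig,
    circadian: CircadianProfile,
    schedule: PumpSchedule,
    kinetics: PressorKinetics,
    days: float,
    cadence_s: float = 30.0,
    treatment_start_day: float = 0.0,
) -> TelemetryRecording:
    """Simulate a multi-day telemetry recording at 30-s cadence.

    SBP(t) = baseline + circadian + delta_sbp * effect(t) + burst coupling
    + Gaussian noise; DBP analogous; MAP = DBP + PP/3 and PP = SBP - DBP by
    construction.  HR couples to the SBP deviation from its circadian
    baseline through the (possibly day-by-day blunted) reflex gain.
    Identical config + seed gives a bit-identical recording.
    """
    if days < 1:
        raise ValueError("days must be >= 1")
    rng = np.random.default_rng(animal.seed)
    t = np.arange(0.0, days * SECONDS_PER_DAY, cadence_s)

    effect = pressor_effect_trace(
        schedule, kinetics, t, active_from_hour=treatment_start_day * 24.0
    )
    mod = circadian.modulation(t)
    bursts = _activity_bursts(rng, t, animal.activity_burst_rate)

    sbp = (
        animal.baseline_sbp
        + circadian.phase_increment_sbp * mod
        + kinetics.delta_sbp * effect
        + BURST_BP_COUPLING * bursts
        + rng.normal(0.0, animal.noise_sd_bp, t.size)
    )
    dbp = (
        animal.baseline_dbp
        + circadian.phase_increment_dbp * mod
        + kinetics.delta_dbp * effect
        + BURST_DBP_FRACTION * BURST_BP_COUPLING * bursts
        + rng.normal(0.0, animal.noise_sd_bp, t.size)
    )

    # physiological clamps: DBP > 0 and SBP strictly above DBP
    n_neg = int(np.sum(dbp < 1.0))
    dbp = np.maximum(dbp, 1.0)
    bad = sbp <= dbp
    n_clamped = int(bad.sum())
    if n_clamped or n_neg:
        logger.warning(
            "%s: clamped %d records with SBP<=DBP and %d with DBP<1 mmHg",
            animal.animal_id,
            n_clamped,
            n_neg,
        )
    sbp = np.where(bad, dbp + 0.1, sbp)

    pp = sbp - dbp
    map_ = dbp + pp / 3.0

    # reflex gain, linearly blunted over treatment days, floored at 0
    days_elapsed = np.maximum(t / SECONDS_PER_DAY - treatment_start_day, 0.0)
    gain = kinetics.hr_gain * np.maximum(
        1.0 - kinetics.gain_decline_per_day * days_elapsed, 0.0
    )
    sbp_phase_baseline = animal.baseline_sbp + circadian.phase_increment_sbp * mod
    hr = (
        animal.baseline_hr
        + circadian.phase_increment_hr * mod
        + gain * (sbp - sbp_phase_baseline)
        + BURST_HR_COUPLING * bursts
        + rng.normal(0.0, animal.noise_sd_hr, t.size)
    )

    activity = circadian.phase_increment_activity * mod + bursts

    data = pd.DataFrame(
        {
            "time_s": t,
            "sbp": sbp,
            "dbp": dbp,
            "map": map_,
            "pp": pp,
            "hr": hr,
            "activity": activity,
            "pump_on": schedule.pump_on(t),
        }
    )
    return TelemetryRecording(
        data=data,
        cadence_s=cadence_s,
        animal_id=animal.animal_id,
        group=animal.group,
        lights_on_clock_hour=circadian.lights_on_clock_hour,
        treatment_start_day=int(treatment_start_day),
    )


def simulate_study_cohort(
    n_control: int = 4,
    n_bpv: int = 4,
    baseline_days: int = 5,
    treatment_days: int = 10,
    cycle_hours: float = 3.0,
    kinetics: PressorKinetics | None = None,
    circadian: CircadianProfile | None = None,
    seed: int = 0,
    noise_sd_bp: float = 6.0,
    noise_sd_hr: float = 20.0,
    activity_burst_rate: float = 2.0,
) -> list[TelemetryRecording]:
    """Simulate the two-arm study: saline controls vs pulsed-pressor (BPV).

    Both arms carry pumps running for the whole recording; the control
    arm's infusate stays saline while the BPV arm switches to the pressor
    after ``baseline_days``.  Per-animal seeds are spawned deterministically
    from ``seed``.
    """
    kinetics = kinetics or PressorKinetics()
    circadian = circadian or CircadianProfile()
    days = baseline_days + treatment_days
    schedule = build_pump_schedule(cycle_hours, 1.0, days, infusate="angII")
    saline_schedule = replace(schedule, infusate="saline")
    seeds = np.random.SeedSequence(seed).generate_state(n_control + n_bpv)
    recordings = []
    for i in range(n_control + n_bpv):
        is_bpv = i >= n_control
        animal = AnimalConfig(
            animal_id=f"{'bpv' if is_bpv else 'ctl'}{i + 1:02d}",
            group="BPV" if is_bpv else "control",
            noise_sd_bp=noise_sd_bp,
            noise_sd_hr=noise_sd_hr,
            activity_burst_rate=activity_burst_rate,
            seed=int(seeds[i] % (2**31)),
        )
        recordings.append(
            simulate_telemetry(
                animal,
                circadian,
                schedule if is_bpv else saline_schedule,
                kinetics if is_bpv else SALINE_KINETICS,
                days=days,
                treatment_start_day=baseline_days,
            )
        )
    return recordings


# ---------------------------------------------------------------------------
# arteriole imaging runs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class VascularModel:
    """Static autoregulation curve plus NVC response of one arteriole.

    The diameter-pressure relation is piecewise linear with breakpoints at
    the lower and upper autoregulatory limits (default 50 and 100 mmHg);
    slopes are in um/mmHg.  NVC dilations are expressed in % of baseline
    diameter and recover exponentially at ``recovery_k`` (1/s, negative).
    """

    baseline_diameter: float = 18.8
    ref_pressure: float = 70.0
    break_lo: float = 50.0
    break_hi: float = 100.0
    slope_low: float = -0.08
    slope_mid: float = -0.03
    slope_high: float = -0.02
    nvc_amp_lowbp: float = 8.0
    nvc_amp_highbp: float = 14.0
    recovery_k: float = -0.20
    diameter_noise_sd: float = 0.15
    transient_dilation_rate: float = 0.0  # events/min
    high_bp_threshold: float = 85.0

    def __post_init__(self) -> None:
        if self.baseline_diameter <= 0:
            raise ValueError("baseline_diameter must be positive")
        if not self.break_lo < self.break_hi:
            raise ValueError("require break_lo < break_hi")

    def autoreg_offset(self, map_mmHg: np.ndarray) -> np.ndarray:
        """Diameter change (um) vs the reference pressure, integrating the
        piecewise-linear slope field from ``ref_pressure`` to each MAP."""
        p = np.asarray(map_mmHg, dtype=float)
        lo, hi, ref = self.break_lo, self.break_hi, self.ref_pressure

        def seg_int(pv: np.ndarray) -> np.ndarray:
            # antiderivative of slope(p) dp anchored at ref (ref in mid bin)
            below = np.minimum(pv, lo)
            mid = np.clip(pv, lo, hi)
            above = np.maximum(pv, hi)
            return (
                self.slope_low * (below - lo) * (pv < lo)
                + self.slope_mid * (mid - ref)
                + self.slope_high * (above - hi) * (pv > hi)
            )

        return seg_int(p)


# group-default vascular models: chronic BPV steepens the plateau-range
# constriction and flips the high-pressure response to dilation, while the
# control arteriole keeps its tone
CONTROL_VASCULAR = VascularModel(
    baseline_diameter=18.6,
    slope_low=-0.08,
    slope_mid=-0.03,
    slope_high=-0.02,
    nvc_amp_lowbp=8.0,
    nvc_amp_highbp=14.0,
    recovery_k=-0.20,
)
BPV_VASCULAR = VascularModel(
    baseline_diameter=19.0,
    slope_low=-0.01,
    slope_mid=-0.06,
    slope_high=0.03,
    nvc_amp_lowbp=8.0,
    nvc_amp_highbp=8.0,
    recovery_k=-0.45,
)


@dataclass(frozen=True)
class StimulusProtocol:
    """Whisker-stimulation protocol of an imaging run."""

    stim_rate_hz: float = 10.0
    stim_duration_s: float = 20.0
    n_events: int = 6
    inter_event_gap_s: float = 90.0
    fps: float = 3.75
    lead_in_s: float = 60.0

    def __post_init__(self) -> None:
        if self.n_events < 1:
            raise ValueError("n_events must be >= 1")
        for name in ("stim_rate_hz", "stim_duration_s", "inter_event_gap_s", "fps"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def onsets_s(self) -> np.ndarray:
        period = self.stim_duration_s + self.inter_event_gap_s
        return self.lead_in_s + period * np.arange(self.n_events)

    @property
    def duration_s(self) -> float:
        return float(self.onsets_s()[-1] + self.stim_duration_s + self.inter_event_gap_s)


@dataclass(frozen=True)
class DiameterRun:
    """Frame-indexed arteriole diameter with simultaneous MAP and stimuli."""

    time_s: np.ndarray
    diameter_um: np.ndarray
    map_mmHg: np.ndarray
    stim_on: np.ndarray
    stim_onsets_s: np.ndarray
    fps: float
    group_mode: str = "control"
    bp_state: str = "low"


def simulate_arteriole_run(
    vasc: VascularModel,
    map_trace: np.ndarray,
    protocol: StimulusProtocol,
    group_mode: str = "control",
    seed: int = 0,
    bp_state: str | None = None,
) -> DiameterRun:
    """Simulate a two-photon diameter run at imaging cadence.

    ``map_trace`` must cover the run duration (one value per frame).  NVC
    events dilate by ``nvc_amp_highbp`` % only when the pre-stimulus MAP is
    above ``high_bp_threshold`` *and* ``group_mode == 'control'`` — the
    pressure-dependent potentiation that chronic BPV abolishes — and by
    ``nvc_amp_lowbp`` % otherwise, decaying at ``recovery_k`` after offset.
    """
    rng = np.random.default_rng(seed)
    map_trace = np.asarray(map_trace, dtype=float)
    n = int(round(protocol.duration_s * protocol.fps))
    if map_trace.size < n:
        raise ValueError(
            f"map_trace ({map_trace.size} frames) does not cover run ({n} frames)"
        )
    map_trace = map_trace[:n]
    t = np.arange(n) / protocol.fps

    diameter = vasc.baseline_diameter + vasc.autoreg_offset(map_trace)

    onsets = protocol.onsets_s()
    stim_on = np.zeros(n, dtype=bool)
    rise_tau = 2.0  # s, dilation onset time constant
    for onset in onsets:
        pre = (t >= onset - 8.0) & (t < onset)
        epoch_map = float(map_trace[pre].mean()) if pre.any() else float(map_trace[0])
        if group_mode == "control" and epoch_map > vasc.high_bp_threshold:
            amp_pct = vasc.nvc_amp_highbp
        else:
            amp_pct = vasc.nvc_amp_lowbp
        amp_um = vasc.baseline_diameter * amp_pct / 100.0
        during = (t >= onset) & (t < onset + protocol.stim_duration_s)
        stim_on |= during
        diameter[during] += amp_um * (1.0 - np.exp(-(t[during] - onset) / rise_tau))
        off = onset + protocol.stim_duration_s
        level = amp_um * (1.0 - math.exp(-protocol.stim_duration_s / rise_tau))
        after = t >= off
        diameter[after] += level * np.exp(vasc.recovery_k * (t[after] - off))

    if vasc.transient_dilation_rate > 0:
        n_events = rng.poisson(vasc.transient_dilation_rate * t[-1] / 60.0)
        for _ in range(n_events):
            t0 = rng.uniform(0.0, t[-1])
            amp = rng.exponential(1.5)
            diameter += amp * np.exp(-(((t - t0) / 4.0) ** 2))

    diameter = diameter + rng.normal(0.0, vasc.diameter_noise_sd, n)
    n_clamped = int(np.sum(diameter < 0.1))
    if n_clamped:
        logger.warning("clamped %d non-physiological diameter frames", n_clamped)
    diameter = np.maximum(diameter, 0.1)

    if bp_state is None:
        bp_state = "high" if map_trace.mean() > vasc.high_bp_threshold else "low"
    return DiameterRun(
        time_s=t,
        diameter_um=diameter,
        map_mmHg=map_trace,
        stim_on=stim_on,
        stim_onsets_s=onsets,
        fps=protocol.fps,
        group_mode=group_mode,
        bp_state=bp_state,
    )


def pulse_map_trace(
    n_frames: int,
    fps: float = 3.75,
    low_map: float = 70.0,
    high_map: float = 100.0,
    on_start_s: float | None = None,
    on_end_s: float | None = None,
    tau_rise_s: float = 120.0,
    tau_fall_s: float = 150.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """MAP trace for an imaging run spanning a pump on/off transition."""
    rng = np.random.default_rng(seed)
    t = np.arange(n_frames) / fps
    m = np.full(n_frames, low_map, dtype=float)
    if on_start_s is not None:
        rise = t >= on_start_s
        m[rise] = low_map + (high_map - low_map) * (
            1.0 - np.exp(-(t[rise] - on_start_s) / tau_rise_s)
        )
        if on_end_s is not None:
            level = low_map + (high_map - low_map) * (
                1.0 - math.exp(-max(on_end_s - on_start_s, 0.0) / tau_rise_s)
            )
            fall = t >= on_end_s
            m[fall] = low_map + (level - low_map) * np.exp(
                -(t[fall] - on_end_s) / tau_fall_s
            )
    if noise_sd > 0:
        m += rng.normal(0.0, noise_sd, n_frames)
    return m


# ---------------------------------------------------------------------------
# behavior cohorts
# ---------------------------------------------------------------------------


def simulate_behavior_cohort(
    n_mice: int,
    ri_baseline: float = 0.65,
    ri_treated: float = 0.50,
    alt_baseline: float = 65.0,
    alt_treated: float = 60.0,
    noise: float = 0.05,
    seed: int = 0,
    total_exploration_s: float = 30.0,
    n_entries: int = 25,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw NOR trials and Y-maze sessions at two timepoints.

    Exploration-time pairs are drawn so the expected recognition index per
    timepoint equals the requested value; arm-entry sequences are drawn so
    the expected spontaneous-alternation percentage matches the requested
    value (each eligible triplet completes an alternation with that
    probability).
    """
    if n_mice < 1:
        raise ValueError("n_mice must be >= 1")
    for ri in (ri_baseline, ri_treated):
        if not 0.0 <= ri <= 1.0:
            raise ValueError("recognition indices must lie in [0, 1]")
    for alt in (alt_baseline, alt_treated):
        if not 0.0 <= alt <= 100.0:
            raise ValueError("alternation percentages must lie in [0, 100]")
    rng = np.random.default_rng(seed)
    arms = np.array(list("ABC"))
    nor_rows, ym_rows = [], []
    for i in range(n_mice):
        aid = f"b{i + 1:02d}"
        for timepoint, ri, alt in (
            ("baseline", ri_baseline, alt_baseline),
            ("treated", ri_treated, alt_treated),
        ):
            ri_i = float(np.clip(ri + noise * rng.standard_normal(), 0.0, 1.0))
            t_novel = total_exploration_s * ri_i
            nor_rows.append(
                {
                    "animal_id": aid,
                    "timepoint": timepoint,
                    "t_novel_s": t_novel,
                    "t_familiar_s": total_exploration_s - t_novel,
                }
            )
            q = float(np.clip(alt / 100.0 + noise * rng.standard_normal(), 0.0, 1.0))
            seq = list(rng.choice(arms, size=2, replace=False))
            while len(seq) < n_entries:
                prev2, prev1 = seq[-2], seq[-1]
                others = [a for a in arms if a != prev1]
                third = [a for a in others if a != prev2]
                if third and rng.uniform() < q:
                    seq.append(third[0])
                else:
                    non_alt = [a for a in others if a == prev2] or others
                    seq.append(str(rng.choice(non_alt)))
            ym_rows.append(
                {"animal_id": aid, "timepoint": timepoint, "entry_sequence": "".join(seq)}
            )
    return pd.DataFrame(nor_rows), pd.DataFrame(ym_rows)
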