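"""Stimulus-locked neurovascular-coupling (NVC) analysis.

Whisker-stimulation runs are reduced to an event matrix (one row per
stimulus), normalized to the pre-stimulus baseline, averaged, and
summarized: magnitude of the evoked dilation (% change over the stimulus
window), raw pre/post diameter means, and a one-phase exponential fit of
the post-stimulus recovery, y(t) = plateau + span * exp(k * t) with k < 0.

Window conventions (at 3.75 frames/s): baseline = 30 frames (8 s) before
onset; stimulus-response = 100 frames covering the 20-s stimulus (75
frames) plus the first ~6.7 s post-stimulus; recovery fit spans the first
30 s after stimulus offset.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

logger = logging.getLogger(__name__)

DEFAULT_FPS = 3.75
BASELINE_FRAMES = 30
RESPONSE_FRAMES = 100
STIMULUS_FRAMES = 75  # 20 s at 3.75 fps


@dataclass(frozen=True)
class NVCEventMatrix:
    """events x frames diameter array with its windowing parameters."""

    events: np.ndarray  # (n_events, baseline_frames + response_frames) um
    fps: float
    baseline_frames: int
    response_frames: int
    onset_times_s: np.ndarray

    @property
    def n_events(self) -> int:
        return int(self.events.shape[0])

    @property
    def n_frames(self) -> int:
        return self.baseline_frames + self.response_frames


@dataclass(frozen=True)
class RecoveryFit:
    k_per_s: float
    plateau_pct: float
    span_pct: float


@dataclass(frozen=True)
class NVCResult:
    """Per-run summary of the stimulus-locked response."""

    mean_trace_pct: np.ndarray
    sem_trace_pct: np.ndarray
    magnitude_pct: float
    peak_pct: float
    pre_mean_um: float
    post_mean_um: float
    recovery: RecoveryFit | None
    n_events: int
    bp_state: str | None = None


def extract_events(
    diameter_trace,
    stim_onsets_s,
    fps: float = DEFAULT_FPS,
    baseline_frames: int = BASELINE_FRAMES,
    response_frames: int = RESPONSE_FRAMES,
) -> NVCEventMatrix:
    """Cut per-event segments ``[onset - baseline, onset + response)``.

    Events whose windows are truncated by the trace bounds are dropped
    with a log entry.
    """
    d = np.asarray(diameter_trace, dtype=float)
    onsets = np.sort(np.asarray(stim_onsets_s, dtype=float))
    rows, kept = [], []
    for onset in onsets:
        i0 = int(round(onset * fps))
        lo, hi = i0 - baseline_frames, i0 + response_frames
        if lo < 0 or hi > d.size:
            logger.info("event at %.1f s truncated by trace bounds; dropped", onset)
            continue
        rows.append(d[lo:hi])
        kept.append(onset)
    events = (
        np.vstack(rows)
        if rows
        else np.empty((0, baseline_frames + response_frames))
    )
    return NVCEventMatrix(
        events=events,
        fps=fps,
        baseline_frames=baseline_frames,
        response_frames=response_frames,
        onset_times_s=np.asarray(kept),
    )


def average_response(matrix: NVCEventMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Baseline-normalized mean response trace with per-frame SEM.

    Each event is expressed as 100 * (D - mean(baseline)) / mean(baseline);
    events with a non-positive baseline mean are excluded with a warning.
    Returns ``(mean_pct, sem_pct)`` over the full event window.
    """
    if matrix.n_events < 1:
        raise ValueError("need at least one event to average")
    normalized = []
    for row in matrix.events:
        base = float(row[: matrix.baseline_frames].mean())
        if base <= 0:
            logger.warning("event with non-positive baseline mean excluded")
            continue
        normalized.append(100.0 * (row - base) / base)
    if not normalized:
        raise ValueError("all events excluded (non-positive baselines)")
    norm = np.vstack(normalized)
    mean = norm.mean(axis=0)
    sem = (
        norm.std(axis=0, ddof=1) / np.sqrt(norm.shape[0])
        if norm.shape[0] > 1
        else np.zeros_like(mean)
    )
    return mean, sem


def response_metrics(
    mean_trace_pct: np.ndarray,
    raw_trace,
    onset_frames,
    fps: float = DEFAULT_FPS,
    baseline_frames: int = BASELINE_FRAMES,
    stimulus_frames: int = STIMULUS_FRAMES,
    flank_s: float = 30.0,
) -> tuple[float, float, float, float]:
    """Magnitude and flanking-diameter summaries of the evoked response.

    Magnitude is the mean % change of the normalized trace over the
    stimulus window (its peak is also returned); ``pre`` / ``post`` are
    ``flank_s``-second window means of the *raw* diameter immediately
    before each stimulus onset and after each stimulus end, averaged over
    events (windows clipped to the trace are used as available).

    Returns ``(magnitude_pct, peak_pct, pre_mean_um, post_mean_um)``.
    """
    trace = np.asarray(mean_trace_pct, dtype=float)
    stim = trace[baseline_frames : baseline_frames + stimulus_frames]
    magnitude = float(stim.mean())
    peak = float(stim.max())
    d = np.asarray(raw_trace, dtype=float)
    w = int(round(flank_s * fps))
    pre_vals, post_vals = [], []
    for i0 in np.asarray(onset_frames, dtype=int):
        pre = d[max(i0 - w, 0) : i0]
        post = d[i0 + stimulus_frames : i0 + stimulus_frames + w]
        if pre.size:
            pre_vals.append(pre.mean())
        if post.size:
            post_vals.append(post.mean())
    pre_mean = float(np.mean(pre_vals)) if pre_vals else float("nan")
    post_mean = float(np.mean(post_vals)) if post_vals else float("nan")
    return magnitude, peak, pre_mean, post_mean


def fit_recovery(
    post_stimulus_trace_pct,
    fps: float = DEFAULT_FPS,
    duration_s: float = 30.0,
) -> RecoveryFit | None:
    """One-phase exponential decay fit of the post-stimulus recovery.

    Nonlinear least squares of y(t) = plateau + span * exp(k * t) with
    t = 0 at stimulus offset and k constrained negative.  Returns None
    (with a diagnostic) when fewer than 10 frames are available, the fit
    fails to converge, or the fitted span is not positive.
    """
    y = np.asarray(post_stimulus_trace_pct, dtype=float)
    n = min(int(round(duration_s * fps)), y.size)
    y = y[:n]
    if y.size < 10:
        logger.warning("recovery fit needs >= 10 frames, got %d", y.size)
        return None
    t = np.arange(y.size) / fps

    def model(tt, plateau, span, k):
        return plateau + span * np.exp(k * tt)

    span0 = y[0] - y[-1]
    if span0 <= 1e-9:
        logger.info("non-decaying post-stimulus trace; recovery fit missing")
        return None
    try:
        popt, _ = curve_fit(
            model,
            t,
            y,
            p0=(float(y[-1]), float(span0), -0.2),
            bounds=([-np.inf, 1e-12, -20.0], [np.inf, np.inf, -1e-6]),
            maxfev=10000,
        )
    except (RuntimeError, ValueError) as exc:
        logger.warning("recovery fit did not converge: %s", exc)
        return None
    plateau, span, k = popt
    if span <= 0:
        logger.info("fitted span <= 0; recovery fit missing")
        return None
    return RecoveryFit(k_per_s=float(k), plateau_pct=float(plateau), span_pct=float(span))


def mask_transient_dilations(
    diameter_trace,
    fps: float = DEFAULT_FPS,
    z_threshold: float = 2.0,
    min_duration_s: float = 5.0,
    stim_onsets_s=None,
    stim_duration_s: float = 20.0,
    median_window_s: float = 30.0,
) -> np.ndarray:
    """Flag spontaneous transient dilations outside stimulus windows.

    Marks excursions above a rolling median by more than ``z_threshold``
    robust SDs (1.4826 * MAD of the residual) that last at least
    ``min_duration_s``.  Frames inside stimulus windows are never masked:
    evoked dilations are the signal, not artifacts.  Returns a boolean
    mask (True = transient dilation).
    """
    d = np.asarray(diameter_trace, dtype=float)
    if d.size / fps < 60.0:
        raise ValueError("trace must span at least 60 s")
    w = max(int(round(median_window_s * fps)) | 1, 3)
    half = w // 2
    padded = np.pad(d, half, mode="edge")
    med = np.array(
        [np.median(padded[i : i + w]) for i in range(d.size)]
    )
    resid = d - med
    mad = np.median(np.abs(resid - np.median(resid)))
    robust_sd = 1.4826 * mad
    above = resid > z_threshold * robust_sd if robust_sd > 0 else resid > 0
    # keep only runs lasting >= min_duration_s
    min_frames = max(int(round(min_duration_s * fps)), 1)
    mask = np.zeros(d.size, dtype=bool)
    i = 0
    while i < d.size:
        if above[i]:
            j = i
            while j < d.size and above[j]:
                j += 1
            if j - i >= min_frames:
                mask[i:j] = True
            i = j
        else:
            i += 1
    if stim_onsets_s is not None:
        t = np.arange(d.size) / fps
        for onset in np.asarray(stim_onsets_s, dtype=float):
            mask[(t >= onset) & (t < onset + stim_duration_s)] = False
    return mask


def analyze_run(
    diameter_trace,
    stim_onsets_s,
    fps: float = DEFAULT_FPS,
    baseline_frames: int = BASELINE_FRAMES,
    response_frames: int = RESPONSE_FRAMES,
    stimulus_frames: int = STIMULUS_FRAMES,
    recovery_duration_s: float = 30.0,
    bp_state: str | None = None,
) -> NVCResult:
    """Full per-run pipeline: extract -> normalize/average -> metrics -> fit."""
    matrix = extract_events(
        diameter_trace, stim_onsets_s, fps, baseline_frames, response_frames
    )
    mean_pct, sem_pct = average_response(matrix)
    onset_frames = np.round(matrix.onset_times_s * fps).astype(int)
    magnitude, peak, pre_um, post_um = response_metrics(
        mean_pct, diameter_trace, onset_frames, fps, baseline_frames, stimulus_frames
    )
    # offset-locked recovery: the 30-s window outlasts the event matrix,
    # so normalize it per event straight from the raw trace
    d = np.asarray(diameter_trace, dtype=float)
    rec_frames = int(round(recovery_duration_s * fps))
    segments = []
    for i0 in onset_frames:
        base = float(d[i0 - baseline_frames : i0].mean()) if i0 >= baseline_frames else 0.0
        seg = d[i0 + stimulus_frames : i0 + stimulus_frames + rec_frames]
        if base > 0 and seg.size == rec_frames:
            segments.append(100.0 * (seg - base) / base)
    recovery = (
        fit_recovery(np.mean(segments, axis=0), fps, recovery_duration_s)
        if segments
        else None
    )
    return NVCResult(
        mean_trace_pct=mean_pct,
        sem_trace_pct=sem_pct,
        magnitude_pct=magnitude,
        peak_pct=peak,
        pre_mean_um=pre_um,
        post_mean_um=post_um,
        recovery=recovery,
        n_events=matrix.n_events,
        bp_state=bp_state,
    )
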