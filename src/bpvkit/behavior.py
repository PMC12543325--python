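"""Behavioral indices: novel-object recognition and Y-maze alternation.

NOR trials are scored by the recognition index RI = t_novel / (t_novel +
t_familiar) and the discrimination index DI = (t_novel - t_familiar) /
(t_novel + t_familiar), after an inclusion filter (minimum per-object and
total exploration times).  Y-maze sessions are scored by spontaneous
alternation: the percentage of consecutive arm-entry triplets that visit
three distinct arms, out of (entries - 2) possible triplets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class NORTrial:
    animal_id: str
    timepoint: str  # baseline | treated
    t_novel_s: float
    t_familiar_s: float

    def __post_init__(self) -> None:
        if self.t_novel_s < 0 or self.t_familiar_s < 0:
            raise ValueError("exploration times must be non-negative")


@dataclass(frozen=True)
class YMazeSession:
    animal_id: str
    timepoint: str
    entry_sequence: str  # string over {A, B, C}; immediate re-entries allowed

    def __post_init__(self) -> None:
        bad = set(self.entry_sequence) - set("ABC")
        if bad:
            raise ValueError(f"invalid arm labels {sorted(bad)}")


def nor_inclusion(
    trial: NORTrial,
    min_per_object_s: float = 4.0,
    min_total_s: float = 10.0,
    per_object_rule: str = "each",
) -> tuple[bool, str]:
    """Inclusion filter for a NOR trial.

    Default strict reading: *each* object must be explored for at least
    ``min_per_object_s`` and the total must reach ``min_total_s``.
    ``per_object_rule='any'`` relaxes the first criterion to at least one
    object (the criterion's phrasing admits both readings).
    Returns ``(included, reason)``.
    """
    if per_object_rule not in ("each", "any"):
        raise ValueError("per_object_rule must be 'each' or 'any'")
    times = (trial.t_novel_s, trial.t_familiar_s)
    if sum(times) < min_total_s:
        return False, "total exploration minimum not met"
    per_object_ok = (
        all(t >= min_per_object_s for t in times)
        if per_object_rule == "each"
        else any(t >= min_per_object_s for t in times)
    )
    if not per_object_ok:
        return False, "per-object minimum not met"
    return True, "included"


def recognition_index(trial: NORTrial) -> float:
    """RI = t_novel / (t_novel + t_familiar), in [0, 1]; NaN for zero total."""
    total = trial.t_novel_s + trial.t_familiar_s
    if total == 0:
        return float("nan")
    return trial.t_novel_s / total


def discrimination_index(trial: NORTrial) -> float:
    """DI = (t_novel - t_familiar) / (t_novel + t_familiar), in [-1, 1]."""
    total = trial.t_novel_s + trial.t_familiar_s
    if total == 0:
        return float("nan")
    return (trial.t_novel_s - trial.t_familiar_s) / total


def percent_alternation(session: YMazeSession) -> tuple[float, int, int]:
    """Spontaneous alternation percentage with its counts.

    Slides a window of three over the arm-entry sequence and counts windows
    whose labels are pairwise distinct (true alternations); the maximum is
    entries - 2.  Immediate re-entries stay in the sequence: they consume
    triplet positions and can never score.  Returns ``(percent,
    n_true_alternations, n_max_alternations)``; percent is NaN with fewer
    than three entries.
    """
    seq = session.entry_sequence
    n = len(seq)
    if n < 3:
        return float("nan"), 0, max(n - 2, 0)
    true_alt = sum(len({seq[i], seq[i + 1], seq[i + 2]}) == 3 for i in range(n - 2))
    max_alt = n - 2
    return 100.0 * true_alt / max_alt, true_alt, max_alt


def score_nor(
    trials: pd.DataFrame,
    min_per_object_s: float = 4.0,
    min_total_s: float = 10.0,
    per_object_rule: str = "each",
) -> pd.DataFrame:
    """Score a NOR trial table (animal_id, timepoint, t_novel_s,
    t_familiar_s) into per-trial indices with inclusion flags."""
    rows = []
    for rec in trials.itertuples(index=False):
        trial = NORTrial(rec.animal_id, rec.timepoint, rec.t_novel_s, rec.t_familiar_s)
        included, reason = nor_inclusion(
            trial, min_per_object_s, min_total_s, per_object_rule
        )
        rows.append(
            {
                "animal_id": trial.animal_id,
                "timepoint": trial.timepoint,
                "included": included,
                "reason": reason,
                "recognition_index": recognition_index(trial) if included else np.nan,
                "discrimination_index": (
                    discrimination_index(trial) if included else np.nan
                ),
            }
        )
    return pd.DataFrame(rows)


def score_ymaze(sessions: pd.DataFrame) -> pd.DataFrame:
    """Score a Y-maze session table (animal_id, timepoint, entry_sequence)."""
    rows = []
    for rec in sessions.itertuples(index=False):
        session = YMazeSession(rec.animal_id, rec.timepoint, rec.entry_sequence)
        pct, n_true, n_max = percent_alternation(session)
        rows.append(
            {
                "animal_id": session.animal_id,
                "timepoint": session.timepoint,
                "percent_alternation": pct,
                "n_true_alternations": n_true,
                "n_max_alternations": n_max,
                "n_entries": len(session.entry_sequence),
            }
        )
    return pd.DataFrame(rows)
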