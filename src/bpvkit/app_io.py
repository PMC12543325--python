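"""File formats, configuration, pipeline assembly and logging.

All interchange is delimited text (CSV, UTF-8, '.' decimal, seconds from
recording start).  Telemetry files carry the columns
``time_s, sbp_mmHg, dbp_mmHg, map_mmHg, pp_mmHg, hr_bpm, activity_au,
pump_on``; diameter runs ``frame, time_s, diameter_um, map_mmHg, stim_on``.
Every pipeline run writes a manifest recording the resolved configuration
hash, per-stage seeds and output checksums so a rerun with the same config
and seed reproduces the tables byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .simulate import (
    CircadianProfile,
    DiameterRun,
    PressorKinetics,
    PumpSchedule,
    StimulusProtocol,
    TelemetryRecording,
    BPV_VASCULAR,
    CONTROL_VASCULAR,
    build_pump_schedule,
    pulse_map_trace,
    simulate_arteriole_run,
    simulate_behavior_cohort,
    simulate_study_cohort,
)
from . import behavior as behavior_mod
from . import indices as indices_mod
from . import nvc as nvc_mod
from . import pressure_response as pr_mod
from . import timeseries as ts_mod

logger = logging.getLogger(__name__)

TELEMETRY_COLUMNS = [
    "time_s",
    "sbp_mmHg",
    "dbp_mmHg",
    "map_mmHg",
    "pp_mmHg",
    "hr_bpm",
    "activity_au",
    "pump_on",
]
_CHANNEL_TO_COLUMN = {
    "sbp": "sbp_mmHg",
    "dbp": "dbp_mmHg",
    "map": "map_mmHg",
    "pp": "pp_mmHg",
    "hr": "hr_bpm",
    "activity": "activity_au",
}
DIAMETER_COLUMNS = ["frame", "time_s", "diameter_um", "map_mmHg", "stim_on"]

PP_TOLERANCE = 1e-9


class TelemetryValidationError(ValueError):
    """Raised when a telemetry file violates the recording invariants."""


def write_telemetry(recording: TelemetryRecording, path) -> None:
    """Write a recording to CSV with a commented metadata header."""
    path = Path(path)
    df = recording.data.rename(
        columns={k: v for k, v in _CHANNEL_TO_COLUMN.items()}
    )[TELEMETRY_COLUMNS]
    meta = (
        f"# animal_id={recording.animal_id} group={recording.group} "
        f"cadence_s={recording.cadence_s:g} "
        f"lights_on_clock_hour={recording.lights_on_clock_hour} "
        f"treatment_start_day={recording.treatment_start_day}\n"
    )
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(meta)
        df.to_csv(fh, index=False, float_format="%.9f")


def read_telemetry(path) -> TelemetryRecording:
    """Read and validate a telemetry CSV.

    Checks the schema (missing columns are an error, unknown extras a
    warning), cadence uniformity, the PP = SBP - DBP identity and the
    DBP <= MAP <= SBP ordering, reporting offending row numbers.
    """
    path = Path(path)
    meta = {}
    with open(path, encoding="utf-8") as fh:
        first = fh.readline()
        if first.startswith("#"):
            for tok in first[1:].split():
                if "=" in tok:
                    k, v = tok.split("=", 1)
                    meta[k] = v
            df = pd.read_csv(fh)
        else:
            fh.seek(0)
            df = pd.read_csv(fh)
    if df.empty:
        raise TelemetryValidationError(f"{path}: empty telemetry file")
    missing = [c for c in TELEMETRY_COLUMNS if c not in df.columns]
    if missing:
        raise TelemetryValidationError(f"{path}: missing columns {missing}")
    extra = [c for c in df.columns if c not in TELEMETRY_COLUMNS]
    if extra:
        warnings.warn(f"{path}: ignoring unknown columns {extra}", stacklevel=2)

    t = df["time_s"].to_numpy(dtype=float)
    cadence = float(meta.get("cadence_s", t[1] - t[0] if t.size > 1 else 30.0))
    if t.size > 1:
        steps = np.diff(t)
        bad = np.flatnonzero(np.abs(steps - cadence) > 1e-6)
        if bad.size:
            raise TelemetryValidationError(
                f"{path}: non-uniform cadence at data row(s) {list(bad[:5] + 2)}"
            )
    pp_err = np.abs(
        df["pp_mmHg"].to_numpy() - (df["sbp_mmHg"] - df["dbp_mmHg"]).to_numpy()
    )
    bad = np.flatnonzero(pp_err > max(PP_TOLERANCE, 1e-8))
    # 1e-8 floor accommodates the 9-decimal text round-trip
    if bad.size:
        raise TelemetryValidationError(
            f"{path}: PP != SBP - DBP at data row(s) {list(bad[:5] + 1)}"
        )
    order_bad = np.flatnonzero(
        (df["dbp_mmHg"] > df["map_mmHg"] + 1e-6)
        | (df["map_mmHg"] > df["sbp_mmHg"] + 1e-6)
    )
    if order_bad.size:
        raise TelemetryValidationError(
            f"{path}: DBP <= MAP <= SBP violated at data row(s) {list(order_bad[:5] + 1)}"
        )
    data = pd.DataFrame(
        {
            "time_s": t,
            "sbp": df["sbp_mmHg"].to_numpy(dtype=float),
            "dbp": df["dbp_mmHg"].to_numpy(dtype=float),
            "map": df["map_mmHg"].to_numpy(dtype=float),
            "pp": df["pp_mmHg"].to_numpy(dtype=float),
            "hr": df["hr_bpm"].to_numpy(dtype=float),
            "activity": df["activity_au"].to_numpy(dtype=float),
            "pump_on": df["pump_on"].astype(bool).to_numpy(),
        }
    )
    return TelemetryRecording(
        data=data,
        cadence_s=cadence,
        animal_id=meta.get("animal_id", path.stem),
        group=meta.get("group", "control"),
        lights_on_clock_hour=int(meta.get("lights_on_clock_hour", 6)),
        treatment_start_day=int(meta.get("treatment_start_day", 0)),
    )


def write_diameter_run(run: DiameterRun, path) -> None:
    df = pd.DataFrame(
        {
            "frame": np.arange(run.time_s.size),
            "time_s": run.time_s,
            "diameter_um": run.diameter_um,
            "map_mmHg": run.map_mmHg,
            "stim_on": run.stim_on,
        }
    )
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(
            f"# fps={run.fps:g} group_mode={run.group_mode} bp_state={run.bp_state} "
            f"stim_onsets_s={','.join(f'{x:g}' for x in run.stim_onsets_s)}\n"
        )
        df.to_csv(fh, index=False, float_format="%.9f")


def read_diameter_run(path) -> DiameterRun:
    path = Path(path)
    meta = {}
    with open(path, encoding="utf-8") as fh:
        first = fh.readline()
        if first.startswith("#"):
            for tok in first[1:].split():
                if "=" in tok:
                    k, v = tok.split("=", 1)
                    meta[k] = v
            df = pd.read_csv(fh)
        else:
            fh.seek(0)
            df = pd.read_csv(fh)
    missing = [c for c in DIAMETER_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    onsets = meta.get("stim_onsets_s", "")
    return DiameterRun(
        time_s=df["time_s"].to_numpy(dtype=float),
        diameter_um=df["diameter_um"].to_numpy(dtype=float),
        map_mmHg=df["map_mmHg"].to_numpy(dtype=float),
        stim_on=df["stim_on"].astype(bool).to_numpy(),
        stim_onsets_s=np.array(
            [float(x) for x in onsets.split(",") if x], dtype=float
        ),
        fps=float(meta.get("fps", nvc_mod.DEFAULT_FPS)),
        group_mode=meta.get("group_mode", "control"),
        bp_state=meta.get("bp_state", "low"),
    )


# ---------------------------------------------------------------------------
# configuration and pipeline
# ---------------------------------------------------------------------------


def default_config() -> dict:
    """Demo configuration exercising every pipeline stage at desk scale."""
    return {
        "seed": 0,
        "cohort": {
            "n_control": 2,
            "n_bpv": 2,
            "baseline_days": 5,
            "treatment_days": 6,
            "cycle_hours": 3.0,
        },
        "kinetics": dataclasses.asdict(PressorKinetics()),
        "circadian": dataclasses.asdict(CircadianProfile()),
        "analysis": {
            "block_days": 2,
            "baseline_days": 5,
            "window_min": 5.0,
            "early_days": [3, 5],
            "late_days": [5, 6],
        },
        "imaging": {"enabled": True, "n_events": 6},
        "behavior": {
            "enabled": True,
            "n_mice": 10,
            "ri_baseline": 0.65,
            "ri_treated": 0.50,
            "alt_baseline": 65.0,
            "alt_treated": 60.0,
            "noise": 0.05,
        },
    }


def load_config(path) -> dict:
    with open(path, encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a mapping")
    merged = default_config()
    for key, val in cfg.items():
        if isinstance(val, dict) and isinstance(merged.get(key), dict):
            merged[key].update(val)
        else:
            merged[key] = val
    return merged


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def _file_checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(cfg: dict, out_dir, stages: tuple[str, ...] | None = None) -> dict:
    """Execute the requested stages in dependency order and write a manifest.

    Stages: simulate -> summaries -> bpv -> reflex -> autoreg -> nvc ->
    behavior.  Later stages consume the in-memory products of earlier ones;
    all tables land as CSV under ``out_dir``.  Returns the manifest dict.
    """
    all_stages = ("simulate", "summaries", "bpv", "reflex", "autoreg", "nvc", "behavior")
    stages = tuple(stages) if stages else all_stages
    unknown = set(stages) - set(all_stages)
    if unknown:
        raise ValueError(f"unknown stages {sorted(unknown)}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg.get("seed", 0))
    seeds = {
        name: int(s % (2**31))
        for name, s in zip(
            all_stages, np.random.SeedSequence(seed).generate_state(len(all_stages))
        )
    }
    manifest = {
        "config_hash": config_hash(cfg),
        "seed": seed,
        "stage_seeds": {s: seeds[s] for s in stages},
        "software_version": __version__,
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "outputs": {},
        "status": "running",
    }
    (out / "config_resolved.yaml").write_text(yaml.safe_dump(cfg), encoding="utf-8")

    co = cfg["cohort"]
    an = cfg["analysis"]
    kin = PressorKinetics(**cfg["kinetics"])
    circ = CircadianProfile(**cfg["circadian"])
    recordings = None
    hourly = None
    try:
        if "simulate" in stages or set(stages) & {"summaries", "bpv", "reflex"}:
            recordings = simulate_study_cohort(
                n_control=co["n_control"],
                n_bpv=co["n_bpv"],
                baseline_days=co["baseline_days"],
                treatment_days=co["treatment_days"],
                cycle_hours=co["cycle_hours"],
                kinetics=kin,
                circadian=circ,
                seed=seeds["simulate"],
            )
        if "simulate" in stages:
            tele_dir = out / "telemetry"
            tele_dir.mkdir(exist_ok=True)
            manifest_rows = []
            for rec in recordings:
                p = tele_dir / f"{rec.animal_id}.csv"
                write_telemetry(rec, p)
                manifest["outputs"][str(p.relative_to(out))] = _file_checksum(p)
                manifest_rows.append(
                    {
                        "animal_id": rec.animal_id,
                        "group": rec.group,
                        "seed": seeds["simulate"],
                        "config_hash": manifest["config_hash"],
                    }
                )
            pd.DataFrame(manifest_rows).to_csv(tele_dir / "cohort_manifest.csv", index=False)

        if set(stages) & {"summaries", "bpv"}:
            hourly = ts_mod.hourly_table(recordings)

        if "summaries" in stages:
            phases = ts_mod.phase_split(
                hourly, circ.lights_on_clock_hour, co["baseline_days"]
            )
            per_animal, cohort = ts_mod.block_summaries(
                phases, an["block_days"], an["baseline_days"]
            )
            phases.to_csv(out / "phase_summaries.csv", index=False)
            per_animal.to_csv(out / "blocks_per_animal.csv", index=False)
            cohort.to_csv(out / "blocks_cohort.csv", index=False)
            schedule = build_pump_schedule(
                co["cycle_hours"], 1.0, co["baseline_days"] + co["treatment_days"]
            )
            epochs = []
            for rec in recordings:
                e = ts_mod.pump_epoch_deltas(rec, schedule, an["window_min"])
                e.insert(0, "animal_id", rec.animal_id)
                e.insert(1, "group", rec.group)
                epochs.append(e)
            pd.concat(epochs, ignore_index=True).to_csv(
                out / "pump_epoch_deltas.csv", index=False
            )

        if "bpv" in stages:
            daily, per_animal_bpv, cohort_bpv = indices_mod.bpv_timecourse(
                hourly,
                circ.lights_on_clock_hour,
                co["baseline_days"],
                an["block_days"],
                an["baseline_days"],
            )
            daily.to_csv(out / "bpv_daily.csv", index=False)
            per_animal_bpv.to_csv(out / "bpv_blocks_per_animal.csv", index=False)
            cohort_bpv.to_csv(out / "bpv_blocks_cohort.csv", index=False)

        if "reflex" in stages:
            schedule = build_pump_schedule(
                co["cycle_hours"], 1.0, co["baseline_days"] + co["treatment_days"]
            )
            rows = []
            for rec in recordings:
                if rec.group != "BPV":
                    continue
                for w in pr_mod.pulse_windows(
                    rec, schedule, tuple(an["early_days"]), tuple(an["late_days"])
                ):
                    if w.epoch is None or w.onset_s < rec.treatment_start_day * 86400:
                        continue
                    fit = pr_mod.baroreflex_slope(rec, w)
                    rows.append(
                        {
                            "animal_id": rec.animal_id,
                            "analysis": "baroreflex",
                            "window": f"{w.epoch}/{w.phase}",
                            "slope": fit.slope,
                            "intercept": fit.intercept,
                            "r2": fit.r_squared,
                            "p": fit.p_value_slope,
                            "n": fit.n_points,
                        }
                    )
            pd.DataFrame(rows).to_csv(out / "baroreflex_slopes.csv", index=False)

        if set(stages) & {"autoreg", "nvc"} and cfg["imaging"]["enabled"]:
            protocol = StimulusProtocol(n_events=cfg["imaging"]["n_events"])
            rng = np.random.default_rng(seeds["nvc"])
            rows_auto, rows_nvc = [], []
            run_dir = out / "diameter_runs"
            run_dir.mkdir(exist_ok=True)
            n_frames = int(round(protocol.duration_s * protocol.fps))
            for mode, vasc in (("control", CONTROL_VASCULAR), ("bpv", BPV_VASCULAR)):
                for state, (lo, hi) in (("low", (70.0, 70.0)), ("high", (70.0, 100.0))):
                    m = pulse_map_trace(
                        n_frames,
                        protocol.fps,
                        low_map=lo,
                        high_map=hi,
                        on_start_s=0.0 if state == "high" else None,
                        tau_rise_s=30.0,
                        seed=int(rng.integers(2**31)),
                    )
                    run = simulate_arteriole_run(
                        vasc, m, protocol, mode, seed=int(rng.integers(2**31)),
                        bp_state=state,
                    )
                    p = run_dir / f"{mode}_{state}.csv"
                    write_diameter_run(run, p)
                    if "nvc" in stages:
                        res = nvc_mod.analyze_run(
                            run.diameter_um, run.stim_onsets_s, run.fps,
                            bp_state=state,
                        )
                        rows_nvc.append(
                            {
                                "group_mode": mode,
                                "bp_state": state,
                                "magnitude_pct": res.magnitude_pct,
                                "peak_pct": res.peak_pct,
                                "pre_um": res.pre_mean_um,
                                "post_um": res.post_mean_um,
                                "k_per_s": res.recovery.k_per_s if res.recovery else np.nan,
                                "plateau_pct": (
                                    res.recovery.plateau_pct if res.recovery else np.nan
                                ),
                                "n_events": res.n_events,
                            }
                        )
                if "autoreg" in stages:
                    # ramp run spanning the full autoregulation range
                    ramp = np.linspace(45.0, 122.0, 2000)
                    dchg = vasc.autoreg_offset(ramp)
                    fits = pr_mod.segmented_slopes(ramp, dchg)
                    for bin_name, fit in fits.items():
                        rows_auto.append(
                            {
                                "group_mode": mode,
                                "analysis": f"segmented_{bin_name}",
                                "slope": fit.slope if fit else np.nan,
                                "r2": fit.r_squared if fit else np.nan,
                                "n": fit.n_points if fit else 0,
                            }
                        )
            if "autoreg" in stages:
                pd.DataFrame(rows_auto).to_csv(out / "autoreg_slopes.csv", index=False)
            if "nvc" in stages:
                pd.DataFrame(rows_nvc).to_csv(out / "nvc_results.csv", index=False)
        elif set(stages) & {"autoreg", "nvc"}:
            raise ValueError(
                "stages autoreg/nvc requested but imaging.enabled is false "
                "and no diameter inputs are configured"
            )

        if "behavior" in stages and cfg["behavior"]["enabled"]:
            b = cfg["behavior"]
            nor, ymaze = simulate_behavior_cohort(
                b["n_mice"],
                b["ri_baseline"],
                b["ri_treated"],
                b["alt_baseline"],
                b["alt_treated"],
                b["noise"],
                seed=seeds["behavior"],
            )
            nor.to_csv(out / "nor_trials.csv", index=False)
            ymaze.to_csv(out / "ymaze_sessions.csv", index=False)
            behavior_mod.score_nor(nor).to_csv(out / "nor_scores.csv", index=False)
            behavior_mod.score_ymaze(ymaze).to_csv(out / "ymaze_scores.csv", index=False)
    except Exception:
        manifest["status"] = "failed"
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise

    for p in sorted(out.rglob("*.csv")):
        manifest["outputs"][str(p.relative_to(out))] = _file_checksum(p)
    manifest["status"] = "ok"
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
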