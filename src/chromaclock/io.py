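"""File formats, configuration defaults, run manifests, and the pipeline.

Formats are deliberately plain: two-column CSV for spectra, a fixed-dialect
CSV for activity records (``timestamp, count``, ISO-8601 UTC timestamps),
and a wide CSV for light schedules. Every stochastic stage records its seed
in a :class:`RunManifest` so a finished run can be reproduced byte for byte.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__ as _version
from .light_schedules import LightTimeline
from .rhythm_analysis import ActivityRecord

__all__ = [
    "read_activity_csv",
    "write_activity_csv",
    "read_schedule_csv",
    "write_schedule_csv",
    "read_spd_csv",
    "write_spd_csv",
    "RunManifest",
    "default_config",
    "run_pipeline",
]

_SCHEDULE_COLUMNS = ["time_min", "logflux_S", "logflux_L", "logflux_mel",
                     "logflux_rod", "color", "block_label"]


class FormatError(ValueError):
    """Malformed input file; the message carries the offending line."""


# ---------------------------------------------------------------------------
# Activity records
# ---------------------------------------------------------------------------


def write_activity_csv(record: ActivityRecord, path) -> None:
    df = pd.DataFrame(
        {"timestamp": record.timestamps().strftime("%Y-%m-%dT%H:%M:%S"),
         "count": record.counts}
    )
    df.to_csv(path, index=False)


def read_activity_csv(path) -> ActivityRecord:
    """Read a ``timestamp,count`` CSV into an ActivityRecord.

    Bin width is inferred from the timestamps and must be uniform (both the
    60-s wheel and 600-s PIR dialects parse); a varying step or a malformed
    row is rejected with its line number.
    """
    df = pd.read_csv(path)
    if list(df.columns[:2]) != ["timestamp", "count"]:
        raise FormatError(f"{path}: expected header 'timestamp,count'")
    try:
        ts = pd.to_datetime(df["timestamp"])
    except (ValueError, TypeError) as e:
        raise FormatError(f"{path}: unparseable timestamp: {e}") from e
    counts = pd.to_numeric(df["count"], errors="coerce")
    bad = np.flatnonzero(counts.isna() | (counts < 0))
    if bad.size:
        raise FormatError(
            f"{path}: invalid count at line {bad[0] + 2}"  # header + 1-based
        )
    steps = ts.diff().dropna().dt.total_seconds()
    if len(steps) == 0:
        raise FormatError(f"{path}: need at least two rows")
    if steps.nunique() != 1:
        line = int(np.flatnonzero(steps.to_numpy() != steps.iloc[0])[0]) + 3
        raise FormatError(f"{path}: non-uniform bin width at line {line}")
    return ActivityRecord(start=ts.iloc[0], bin_seconds=int(steps.iloc[0]),
                          counts=counts.to_numpy(dtype=np.int64))


# ---------------------------------------------------------------------------
# Schedules and spectra
# ---------------------------------------------------------------------------


def write_schedule_csv(timeline: LightTimeline, path) -> None:
    pd.DataFrame({
        "time_min": timeline.time_min,
        "logflux_S": timeline.log_S,
        "logflux_L": timeline.log_L,
        "logflux_mel": timeline.log_mel,
        "logflux_rod": timeline.log_rod,
        "color": timeline.color,
        "block_label": timeline.labels,
    }).to_csv(path, index=False)


def read_schedule_csv(path) -> LightTimeline:
    df = pd.read_csv(path)
    missing = [c for c in _SCHEDULE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    return LightTimeline(
        time_min=df["time_min"].to_numpy(float),
        log_S=df["logflux_S"].to_numpy(float),
        log_L=df["logflux_L"].to_numpy(float),
        log_mel=df["logflux_mel"].to_numpy(float),
        log_rod=df["logflux_rod"].to_numpy(float),
        color=df["color"].to_numpy(float),
        labels=df["block_label"].to_numpy(object),
    )


def write_spd_csv(spd, path) -> None:
    pd.DataFrame({"wavelength_nm": spd.wavelengths,
                  "photon_flux_density": spd.flux_density}).to_csv(path, index=False)


def read_spd_csv(path):
    from .photometry import SpectralPowerDistribution

    df = pd.read_csv(path)
    if list(df.columns[:2]) != ["wavelength_nm", "photon_flux_density"]:
        raise FormatError(
            f"{path}: expected header 'wavelength_nm,photon_flux_density'"
        )
    return SpectralPowerDistribution(df["wavelength_nm"].to_numpy(float),
                                     df["photon_flux_density"].to_numpy(float))


# ---------------------------------------------------------------------------
# Manifest, config, pipeline
# ---------------------------------------------------------------------------


def _sha256(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


@dataclass
class RunManifest:
    """Provenance for one pipeline run: seeds, config, file checksums."""

    version: str = _version
    created_utc: str = ""
    config: dict = field(default_factory=dict)
    seeds: dict = field(default_factory=dict)
    inputs: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)

    def record_file(self, role: str, path, output: bool = True) -> None:
        target = self.outputs if output else self.inputs
        target[role] = {"path": str(path), "sha256": _sha256(path)}

    def write(self, path) -> None:
        self.created_utc = datetime.now(timezone.utc).isoformat()
        Path(path).write_text(json.dumps(asdict(self), indent=2, sort_keys=True))


def default_config() -> dict:
    """Full default configuration for the umbrella pipeline."""
    return {
        "photometry": {
            "primaries_nm": [385.0, 460.0, 630.0],
            "fwhm_nm": 20.0,
            "primary_total_flux": 1.0e15,
            "lambda_max": {"S": 365.0, "L": 556.0, "mel": 480.0, "rod": 498.0},
            "lens": "mouse_default",
            "target_melrod_log10": 12.7,
        },
        "schedule": {
            "paradigm": "natural",
            "days": 14,
            "photoperiod_h": 16.0,
            "epochs": 5,
            "block_days": 3,
            "step_min": 1.0,
            "twilight": {"day_log_intensity": 13.5, "intensity_slope": 0.25,
                         "day_color": 0.6, "color_ramp": 0.6},
            "clouds": {"correlation_time_min": 30.0, "mean": 0.45,
                       "scale": 0.28, "cap": 1.2},
        },
        "simulate": {
            "genotype": "redcone",
            "tau0": 23.6,
            "k_tau": 0.3,
            "prc_amplitude": 0.01,
            "color_weight": 0.5,
            "alpha0": 0.5,
            "alpha_slope": 0.03,
            "rate_active": 20.0,
            "rate_rest": 1.0,
            "bin_seconds": 600,
        },
        "analyze": {
            "period_range_h": [20.0, 28.0],
            "significance": 0.001,
            "night_start_hour": 20.0,
            "night_hours": 8.0,
        },
    }


def load_config(path=None) -> dict:
    """Default config, with an optional YAML file deep-merged on top."""
    cfg = default_config()
    if path is not None:
        user = yaml.safe_load(Path(path).read_text()) or {}

        def merge(base, extra):
            for k, v in extra.items():
                if isinstance(v, dict) and isinstance(base.get(k), dict):
                    merge(base[k], v)
                else:
                    base[k] = v

        merge(cfg, user)
    return cfg


def _build_timeline(cfg: dict, seed: int) -> LightTimeline:
    from . import light_schedules as ls

    sched = cfg["schedule"]
    paradigm = sched["paradigm"]
    step = sched["step_min"]
    if paradigm == "natural":
        return ls.make_natural_paradigm(
            seed=seed, epochs=sched["epochs"], block_days=sched["block_days"],
            twilight=ls.TwilightModel(**sched["twilight"]),
            clouds=ls.CloudModel(**sched["clouds"]),
            photoperiod_h=sched["photoperiod_h"], step_min=step,
        )
    if paradigm == "intensity-only":
        nat = ls.make_natural_block(
            sched["block_days"], ls.TwilightModel(**sched["twilight"]),
            ls.CloudModel(**sched["clouds"]), seed=seed,
            photoperiod_h=sched["photoperiod_h"], step_min=step)
        return ls.make_intensity_only_block(nat)
    blue, yellow = ls.default_blue_yellow_states()
    if paradigm == "ld":
        return ls.make_ld_cycle(sched["days"], yellow, step_min=step)
    if paradigm == "constant":
        return ls.make_constant(sched["days"], yellow, step_min=step)
    if paradigm == "jetlag":
        return ls.make_jetlag(7, sched["days"] - 7, +6.0, yellow, step_min=step)
    if paradigm == "color-cycle":
        return ls.make_color_cycle(sched["days"], blue, yellow, step_min=step)
    if paradigm == "melrod":
        hi, lo = ls.default_melrod_states()
        return ls.make_melrod_cycle(sched["days"], hi, lo, step_min=step)
    if paradigm == "colmel":
        hi, lo = ls.default_melrod_states()
        bright = ls.LightState(hi.log_S - 0.6, hi.log_L + 0.6,
                               hi.log_mel, hi.log_rod, hi.color + 1.2)
        dim = ls.LightState(lo.log_S + 0.6, lo.log_L - 0.6,
                            lo.log_mel, lo.log_rod, lo.color - 1.2)
        return ls.make_colmel_cycle(sched["days"], bright, dim, step_min=step)
    raise ValueError(f"unknown paradigm {paradigm!r}")


def run_pipeline(config: dict, out_dir, seed: int = 0,
                 log=print) -> RunManifest:
    """Run schedule -> simulate -> analyze, writing outputs and a manifest.

    Stages run in order; a failure aborts the run with the failing stage
    named. All randomness derives from ``seed`` (schedule clouds use
    ``seed``, the simulator ``seed + 1``).
    """
    from . import behavior_sim as bs
    from . import rhythm_analysis as ra

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=config,
                           seeds={"schedule": seed, "simulate": seed + 1})
    stage = "make-schedule"
    try:
        timeline = _build_timeline(config, seed)
        write_schedule_csv(timeline, out / "schedule.csv")
        manifest.record_file("schedule", out / "schedule.csv")
        log(f"[{stage}] wrote schedule.csv "
            f"({timeline.duration_min/1440:.1f} days)")

        stage = "simulate"
        sim_cfg = dict(config["simulate"])
        bin_seconds = sim_cfg.pop("bin_seconds")
        if sim_cfg.get("genotype") == "coneless":
            sim_cfg["color_weight"] = 0.0
        params = bs.OscillatorParams(**sim_cfg)
        sim = bs.simulate(timeline, params, seed=seed + 1,
                          bin_seconds=bin_seconds)
        write_activity_csv(sim.record, out / "activity.csv")
        (out / "activity.manifest.json").write_text(
            json.dumps(sim.manifest(), indent=2))
        manifest.record_file("activity", out / "activity.csv")
        log(f"[{stage}] wrote activity.csv ({len(sim.record.counts)} bins)")

        stage = "analyze"
        results = {}
        if config["schedule"]["paradigm"] == "natural":
            metrics = ra.analyze_paradigm(
                sim.record, timeline,
                night_start_hour=config["analyze"]["night_start_hour"],
                night_hours=config["analyze"]["night_hours"])
            results = {k: v.as_dict() for k, v in metrics.items()}
        else:
            pg = ra.chi_square_periodogram(
                sim.record, tuple(config["analyze"]["period_range_h"]),
                config["analyze"]["significance"])
            results["period_h"] = pg.best_period_h
            if pg.best_period_h:
                results["alpha"] = ra.estimate_alpha(sim.record,
                                                     pg.best_period_h)
        (out / "metrics.json").write_text(json.dumps(results, indent=2))
        manifest.record_file("metrics", out / "metrics.json")
        log(f"[{stage}] wrote metrics.json")
    except Exception as e:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {e}") from e

    manifest.write(out / "manifest.json")
    return manifest
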