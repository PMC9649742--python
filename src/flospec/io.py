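"""File I/O, scenario configuration and pipeline orchestration.

Fixed table schemas (CSV, UTF-8, "." decimal, >= 9 significant digits):

* tracks:   bead_id, frame, t_s, x_um, y_um, area_px
* ruptures: bead_id, channel_index, rupture_flow_rate, loading_rate_pn_s
            (+ optional rupture_force_pn, censored)
* survival: bead_id, removal_time_s, censored
* force-extension: force_pn, extension_nm

Movies are multi-page 16-bit TIFF, one page per frame.  Scenario files are
YAML with every numeric key carrying a unit suffix (width_um, q0_mm3_s,
...), which keeps the mm/µm unit traps out of the configs.

Randomness policy: a single scenario seed is expanded into per-stage seeds
through ``numpy.random.SeedSequence([seed, stage_index])`` with a fixed
stage numbering, so any stage can be re-run in isolation and reproduce its
artifacts byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import __version__
from .calibration import CalibrationModel, force_from_flow_rate
from .core import (UL_PER_MIN_TO_MM3_PER_S, ChipLayout, EnergyLandscape,
                   Environment, LoadingProtocol, LoadingRate)
from .dfs import RuptureDataset, analyze_rupture_datasets
from .synthetic import simulate_rupture_experiment
from .tracking import BeadTrack

logger = logging.getLogger(__name__)

__all__ = [
    "read_movie", "write_movie",
    "read_tracks_csv", "write_tracks_csv",
    "read_ruptures_csv", "write_ruptures_csv",
    "read_survival_csv", "write_survival_csv",
    "load_scenario", "stage_seed", "run_pipeline",
    "write_results_json",
]

_FLOAT_FORMAT = "%.10g"  # >= 9 significant digits round-trips float32-scale data

_STAGE_INDEX = {"simulate": 0, "render": 1, "track": 2, "select": 3,
                "ruptures": 4, "calibrate": 5, "fit": 6}

TRACK_COLUMNS = ["bead_id", "frame", "t_s", "x_um", "y_um", "area_px"]
RUPTURE_COLUMNS = ["bead_id", "channel_index", "rupture_flow_rate",
                   "loading_rate_pn_s"]
SURVIVAL_COLUMNS = ["bead_id", "removal_time_s", "censored"]


class SchemaError(ValueError):
    """A table or config file does not match its declared schema."""


def _check_columns(df: pd.DataFrame, required: list[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} is missing required columns: {missing}")


# ---------------------------------------------------------------- movies

def write_movie(path, movie: np.ndarray) -> None:
    movie = np.asarray(movie)
    if movie.ndim != 3:
        raise ValueError("movie must be a (frames, H, W) stack")
    tifffile.imwrite(str(path), movie.astype(np.uint16))


def read_movie(path) -> np.ndarray:
    return tifffile.imread(str(path))


# ---------------------------------------------------------------- tables

def write_tracks_csv(path, tracks: list[BeadTrack]) -> None:
    rows = []
    for t in tracks:
        for k in range(t.frame_times.size):
            rows.append((t.bead_id, k, t.frame_times[k],
                         t.x_um[k], t.y_um[k], t.areas[k]))
    df = pd.DataFrame(rows, columns=TRACK_COLUMNS)
    df.to_csv(path, index=False, float_format=_FLOAT_FORMAT)


def read_tracks_csv(path, pixel_size_nm: float) -> list[BeadTrack]:
    df = pd.read_csv(path)
    _check_columns(df, TRACK_COLUMNS, f"track table {path}")
    tracks = []
    for bead_id, grp in df.groupby("bead_id", sort=True):
        grp = grp.sort_values("frame")
        um_to_px = 1e3 / pixel_size_nm
        tracks.append(BeadTrack(
            bead_id=int(bead_id),
            frame_times=grp["t_s"].to_numpy(),
            x_px=grp["x_um"].to_numpy() * um_to_px,
            y_px=grp["y_um"].to_numpy() * um_to_px,
            areas=grp["area_px"].to_numpy(),
            pixel_size_nm=pixel_size_nm))
    return tracks


def write_ruptures_csv(path, table: pd.DataFrame) -> None:
    _check_columns(table, RUPTURE_COLUMNS, "rupture table")
    table.to_csv(path, index=False, float_format=_FLOAT_FORMAT)


def read_ruptures_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _check_columns(df, RUPTURE_COLUMNS, f"rupture table {path}")
    return df


def write_survival_csv(path, record) -> None:
    df = pd.DataFrame({
        "bead_id": np.arange(record.removal_times.size),
        "removal_time_s": record.removal_times,
        "censored": record.censored.astype(bool),
    })
    df.to_csv(path, index=False, float_format=_FLOAT_FORMAT)


def read_survival_csv(path, applied_force: float = 0.0, label: str = ""):
    from .synthetic import SurvivalRecord
    df = pd.read_csv(path)
    _check_columns(df, SURVIVAL_COLUMNS, f"survival table {path}")
    times = df["removal_time_s"].to_numpy(float)
    horizon = float(times.max()) if times.size else 0.0
    return SurvivalRecord(removal_times=times,
                          censored=df["censored"].to_numpy(bool),
                          applied_force=applied_force,
                          observation_time=horizon, label=label)


# ---------------------------------------------------------------- config

_REQUIRED_SCENARIO_KEYS = {
    "chip": {"widths_um", "height_um"},
    "protocol": {"ramp_slope_mm3_s2", "duration_s"},
    "calibration": {"slope_pn_s_per_mm", "bead_radius_nm", "tether_length_nm"},
    "landscape": {"k_off_per_s", "delta_x_nm"},
    "simulate": {"n_beads_per_channel"},
}


def load_scenario(path) -> dict:
    """Load and schema-validate a scenario YAML file."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise SchemaError(f"scenario file {path} must be a YAML mapping")
    return validate_scenario(raw)


def validate_scenario(config: dict) -> dict:
    for section, keys in _REQUIRED_SCENARIO_KEYS.items():
        if section not in config:
            raise SchemaError(f"scenario is missing section '{section}'")
        if not isinstance(config[section], dict):
            raise SchemaError(f"scenario section '{section}' must be a mapping")
        missing = keys - set(config[section])
        if missing:
            raise SchemaError(
                f"scenario section '{section}' is missing keys: {sorted(missing)}")
    config.setdefault("environment", {})
    config.setdefault("fit", {})
    config["environment"].setdefault("thermal_energy_pn_nm", 4.114)
    config["environment"].setdefault("viscosity_pa_s", 1.0e-3)
    config["fit"].setdefault("n_serial", 1)
    config["fit"].setdefault("subgroups", 3)
    config["fit"].setdefault("method", "exact")
    config.setdefault("seed", 0)
    return config


def _num(value, key: str) -> float:
    # YAML 1.1 reads "1.0e6" (no sign) as a string; accept it as a number
    try:
        return float(value)
    except (TypeError, ValueError):
        raise SchemaError(f"scenario key '{key}' must be numeric, "
                          f"got {value!r}") from None


def _scenario_objects(config: dict):
    chip = ChipLayout.from_widths(
        [_num(w, "chip.widths_um") for w in config["chip"]["widths_um"]],
        _num(config["chip"]["height_um"], "chip.height_um"))
    proto = config["protocol"]
    slope = _num(proto["ramp_slope_mm3_s2"], "protocol.ramp_slope_mm3_s2")
    if "ramp_slope_ul_min_per_s" in proto:
        slope = _num(proto["ramp_slope_ul_min_per_s"],
                     "protocol.ramp_slope_ul_min_per_s") * UL_PER_MIN_TO_MM3_PER_S
    protocol = LoadingProtocol(
        ramp_slope=slope,
        duration=_num(proto["duration_s"], "protocol.duration_s"),
        q0=_num(proto.get("q0_mm3_s", 0.0), "protocol.q0_mm3_s"))
    cal = config["calibration"]
    calibration = CalibrationModel(
        slope=_num(cal["slope_pn_s_per_mm"], "calibration.slope_pn_s_per_mm"),
        valid_bead_radius_nm=_num(cal["bead_radius_nm"],
                                  "calibration.bead_radius_nm"),
        valid_tether_length_nm=_num(cal["tether_length_nm"],
                                    "calibration.tether_length_nm"),
        valid_channel_height_um=_num(cal.get("channel_height_um",
                                             config["chip"]["height_um"]),
                                     "calibration.channel_height_um"))
    env = Environment.from_thermal_energy(
        _num(config["environment"]["thermal_energy_pn_nm"],
             "environment.thermal_energy_pn_nm"),
        viscosity=_num(config["environment"]["viscosity_pa_s"],
                       "environment.viscosity_pa_s"))
    landscape = EnergyLandscape(
        k_off=_num(config["landscape"]["k_off_per_s"], "landscape.k_off_per_s"),
        delta_x=_num(config["landscape"]["delta_x_nm"], "landscape.delta_x_nm"))
    return chip, calibration, protocol, env, landscape


def stage_seed(scenario_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    if stage not in _STAGE_INDEX:
        raise ValueError(f"unknown stage {stage!r}")
    ss = np.random.SeedSequence([int(scenario_seed), _STAGE_INDEX[stage]])
    return int(ss.generate_state(1, dtype=np.uint64)[0] % (2 ** 31))


def config_hash(config: dict) -> str:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_results_json(path, payload: dict, config: dict | None = None,
                       seed: int | None = None) -> None:
    """Write a results JSON with provenance; stable byte-for-byte on re-runs."""
    out = {"flospec_version": __version__, "results": payload}
    if config is not None:
        out["config_sha256_16"] = config_hash(config)
    if seed is not None:
        out["seed"] = int(seed)
    Path(path).write_text(json.dumps(out, indent=2, sort_keys=True) + "\n",
                          encoding="utf-8")


# ---------------------------------------------------------------- pipeline

def run_pipeline(config: dict, outdir, stages=("simulate", "fit")) -> dict:
    """Run the simulate → fit orchestration described by a scenario config.

    ``stages`` is a subset of {"simulate", "fit"}.  "simulate" writes the
    per-chip rupture table (ruptures.csv); "fit" reads it back, converts
    rupture flow rates to forces through the calibration and channel
    geometry, runs the per-rate CDF fits, subgroup statistics and the
    global landscape regression, and writes dfs.json.  Deterministic for a
    fixed scenario seed.
    """
    config = validate_scenario(dict(config))
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages = list(stages)
    unknown = set(stages) - {"simulate", "fit"}
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    chip, calibration, protocol, env, landscape = _scenario_objects(config)
    seed = int(config["seed"])
    results: dict = {}

    ruptures_path = outdir / "ruptures.csv"
    if "simulate" in stages:
        table = simulate_rupture_experiment(
            chip, calibration, protocol, landscape, env,
            n_beads_per_channel=int(config["simulate"]["n_beads_per_channel"]),
            seed=stage_seed(seed, "simulate"))
        write_ruptures_csv(ruptures_path, table)
        counts = table.groupby("channel_index")["censored"].agg(["size", "sum"])
        for ch, row in counts.iterrows():
            logger.info("channel %d: %d beads simulated, %d censored",
                        ch, int(row["size"]), int(row["sum"]))
        results["simulate"] = {
            "n_beads": int(table.shape[0]),
            "n_censored": int(table["censored"].sum()),
        }

    if "fit" in stages:
        if not ruptures_path.exists():
            raise FileNotFoundError(
                f"stage 'fit' needs {ruptures_path}; run the 'simulate' stage "
                "first or place a rupture table there")
        table = read_ruptures_csv(ruptures_path)
        datasets = []
        for ch_index, grp in table.groupby("channel_index", sort=True):
            channel = chip.channels[int(ch_index)]
            if "censored" in grp.columns:
                n_censored = int(grp["censored"].sum())
                if n_censored:
                    logger.info("channel %d: excluding %d censored beads from "
                                "the CDF fit", ch_index, n_censored)
                grp = grp[~grp["censored"].astype(bool)]
            forces = force_from_flow_rate(grp["rupture_flow_rate"].to_numpy(),
                                          calibration, channel)
            datasets.append(RuptureDataset(
                rupture_forces=forces,
                loading_rate=LoadingRate(float(grp["loading_rate_pn_s"].iloc[0])),
                channel=int(ch_index)))
        fit = analyze_rupture_datasets(
            datasets, env, n_serial=int(config["fit"]["n_serial"]),
            n_groups=int(config["fit"]["subgroups"]),
            seed=stage_seed(seed, "fit"), method=config["fit"]["method"])
        results["fit"] = {
            "per_rate": [
                {"f_dot_pn_s": rf.loading_rate.f_dot,
                 "f_star_pn": rf.f_star,
                 "f_star_mean_pn": sg.f_star_mean,
                 "f_star_sd_pn": sg.f_star_sd,
                 "k_off_per_s": rf.landscape.k_off,
                 "delta_x_nm": rf.landscape.delta_x}
                for rf, sg in zip(fit.per_rate, fit.subgroups)
            ],
            "global": {
                "k_off_per_s": fit.global_fit.landscape.k_off,
                "k_off_sd_per_s": fit.global_fit.k_off_sd,
                "delta_x_nm": fit.global_fit.landscape.delta_x,
                "delta_x_sd_nm": fit.global_fit.delta_x_sd,
                "n_serial": fit.n_serial,
            },
        }
        write_results_json(outdir / "dfs.json", results["fit"],
                           config=config, seed=seed)
    return results
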