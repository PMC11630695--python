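"""End-to-end orchestration: simulate → register → kinematics → design.

One validated config drives the whole run; every output file carries the
hash of the normalized config it came from, and identical configs produce
bit-identical outputs.  Stages can be disabled individually, and each stage
remains usable on its own through the library API or the CLI subcommands.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import PipelineStageError, ValidationError
from .kinematics import build_wing_frame_from_landmarks, make_report, write_report
from .mechanism import (
    SynthesisOptions,
    check_actuation_limits,
    default_geometry,
    default_routings,
    falcon_targets,
    optimize_joints,
    tendon_excursion,
)
from .registration import FitOptions, fit_all, fits_to_frame
from .synthetic import (
    DEFAULT_LANDMARKS,
    compose_chain,
    default_specs,
    make_table1_poses,
    pose_clouds,
    generate_bone_cloud,
    write_manifest,
)

#: full default config; every run normalizes against this tree.  The
#: top-level seed has no default — reproducibility demands it be explicit.
DEFAULTS = {
    "seed": None,
    "output_dir": "wingkin_run",
    "write_clouds": False,
    "cloud_format": "ply",
    "synthetic": {
        "noise_sigma_mm": 0.2,
        "overlap_fraction": 0.8,
        "subsample": 1,
    },
    "landmarks_file": None,
    "registration": {
        "n_starts": 24,
        "max_rotation_deg": 90.0,
        "polish": True,
    },
    "mechanism": {
        "enabled": True,
        "n_starts": 32,
        "center_box_mm": 25.0,
        "axis_cone_deg": 30.0,
        "target_source": "table1",
    },
    "tendon": {
        "enabled": True,
        "sweep_stop_deg": 38.83,
        "sweep_step_deg": 1.0,
    },
}


def _merge(defaults, supplied, path, problems):
    out = {}
    for key, default in defaults.items():
        if isinstance(default, dict):
            sub = supplied.get(key, {})
            if not isinstance(sub, dict):
                problems.append(f"'{path}{key}' must be a mapping")
                sub = {}
            out[key] = _merge(default, sub, f"{path}{key}.", problems)
        else:
            out[key] = supplied.get(key, default)
    for key in supplied:
        if key not in defaults:
            problems.append(f"unknown key '{path}{key}'")
    return out


def validate_config(config: dict) -> dict:
    """Normalize a config: fill defaults, reject unknown keys.

    Raises :class:`ValidationError` listing every problem at once.  The
    normalized config re-validates to itself.
    """
    if not isinstance(config, dict):
        raise ValidationError(["config must be a mapping"])
    problems: list[str] = []
    norm = _merge(DEFAULTS, config, "", problems)
    if norm["seed"] is None:
        problems.append("missing required key 'seed'")
    elif not isinstance(norm["seed"], int):
        problems.append("'seed' must be an integer")
    if norm["landmarks_file"] is not None and not Path(norm["landmarks_file"]).exists():
        problems.append(f"landmarks_file does not exist: {norm['landmarks_file']}")
    if norm["cloud_format"] not in ("ply", "csv"):
        problems.append("'cloud_format' must be 'ply' or 'csv'")
    if norm["synthetic"]["subsample"] < 1:
        problems.append("'synthetic.subsample' must be >= 1")
    if problems:
        raise ValidationError(problems)
    return norm


def load_config(path) -> dict:
    """Read a YAML or JSON config file and validate it."""
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    return validate_config(data or {})


def config_hash(norm_config: dict) -> str:
    blob = json.dumps(norm_config, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _write_csv(df: pd.DataFrame, path, chash: str):
    with open(path, "w") as fh:
        fh.write(f"# config_hash: {chash}\n")
        df.to_csv(fh, index=False, float_format="%.6f")


def run_pipeline(config: dict, outdir=None) -> dict:
    """Execute all enabled stages; returns a machine-readable run report.

    Writes ``fits.csv``, ``table1.csv`` (kinematics), ``recovery.csv``
    (ground-truth comparison), and — when the mechanism stage is enabled —
    ``mechanism.json``, ``table2.csv`` and ``excursions.csv`` /
    ``routing_selection.csv``, plus a config echo and a run log.  On stage
    failure, partial outputs are retained and
    :class:`PipelineStageError` names the failing stage.
    """
    norm = validate_config(config)
    outdir = Path(outdir if outdir is not None else norm["output_dir"])
    outdir.mkdir(parents=True, exist_ok=True)
    chash = config_hash(norm)
    (outdir / "config_echo.json").write_text(
        json.dumps({"config_hash": chash, "config": norm}, indent=2, sort_keys=True))
    seed = norm["seed"]
    log: list[str] = []
    report = {"config_hash": chash, "version": __version__, "seed": seed,
              "stages": {}}

    def _log(msg):
        log.append(f"[{time.strftime('%H:%M:%S')}] {msg}")

    def _finish():
        (outdir / "run_log.txt").write_text("\n".join(log) + "\n")
        (outdir / "run_report.json").write_text(json.dumps(report, indent=2))

    # --- simulate ---------------------------------------------------------
    try:
        _log("stage simulate: generating synthetic skeleton")
        syn = norm["synthetic"]
        specs = default_specs(noise_sigma_mm=syn["noise_sigma_mm"],
                              overlap_fraction=syn["overlap_fraction"],
                              seed=seed, subsample=syn["subsample"])
        truth_rel = make_table1_poses()
        truth_abs = compose_chain(truth_rel)
        base = {b: generate_bone_cloud(s) for b, s in specs.items()}
        clouds = pose_clouds(base, truth_abs,
                             overlap_fraction=syn["overlap_fraction"], seed=seed)
        if norm["write_clouds"]:
            write_manifest(clouds, truth_abs, outdir / "clouds",
                           fmt=norm["cloud_format"])
        report["stages"]["simulate"] = {
            "bones": {b: len(c["extension"]) for b, c in clouds.items()}}
    except Exception as exc:  # noqa: BLE001 - stage boundary
        _log(f"simulate FAILED: {exc}")
        _finish()
        raise PipelineStageError("simulate", exc) from exc

    # --- register ---------------------------------------------------------
    try:
        _log("stage register: multi-start rigid registration")
        if norm["landmarks_file"]:
            landmarks = json.loads(Path(norm["landmarks_file"]).read_text())
        else:
            landmarks = DEFAULT_LANDMARKS
        frame = build_wing_frame_from_landmarks(landmarks)
        to_wing = frame.to_frame()
        wing_clouds = {
            bone: {p: c.with_points(to_wing.apply(c.points))
                   for p, c in per.items()}
            for bone, per in clouds.items()}
        reg = norm["registration"]
        fits = fit_all(wing_clouds, FitOptions(
            n_starts=reg["n_starts"], seed=seed,
            max_rotation_deg=reg["max_rotation_deg"], polish=reg["polish"]))
        fits_df = fits_to_frame(fits)
        _write_csv(fits_df, outdir / "fits.csv", chash)
        report["stages"]["register"] = {
            "max_residual_mm": float(fits_df["residual_mm"].max())}
    except Exception as exc:  # noqa: BLE001
        _log(f"register FAILED: {exc}")
        _finish()
        raise PipelineStageError("register", exc) from exc

    # --- kinematics -------------------------------------------------------
    try:
        _log("stage kinematics: axis-angle report")
        table1 = make_report(fits)
        write_report(table1, outdir / "table1.csv", config_hash=chash)
        truth_report = make_report(
            {b: {p: gt.transform for p, gt in per.items()}
             for b, per in truth_abs.items()})
        recovery = table1.merge(truth_report, on="bone",
                                suffixes=("_recovered", "_truth"))
        recovery["theta_half_err_deg"] = (
            recovery["theta_half_deg_recovered"] - recovery["theta_half_deg_truth"]).abs()
        recovery["theta_flex_err_deg"] = (
            recovery["theta_flex_deg_recovered"] - recovery["theta_flex_deg_truth"]).abs()
        _write_csv(recovery, outdir / "recovery.csv", chash)
        max_err = float(recovery[["theta_half_err_deg", "theta_flex_err_deg"]]
                        .to_numpy().max())
        report["stages"]["kinematics"] = {"max_angle_error_deg": max_err}
        _log(f"kinematics: max recovered-angle error {max_err:.3f} deg")
    except Exception as exc:  # noqa: BLE001
        _log(f"kinematics FAILED: {exc}")
        _finish()
        raise PipelineStageError("kinematics", exc) from exc

    # --- mechanism --------------------------------------------------------
    if norm["mechanism"]["enabled"]:
        try:
            _log("stage design: joint-placement synthesis")
            mech = norm["mechanism"]
            targets = falcon_targets(mech["target_source"])
            geometry, table2 = optimize_joints(
                default_geometry(), targets,
                SynthesisOptions(n_starts=mech["n_starts"], seed=seed,
                                 center_box_mm=mech["center_box_mm"],
                                 axis_cone_deg=mech["axis_cone_deg"],
                                 target_source=mech["target_source"]))
            (outdir / "mechanism.json").write_text(
                json.dumps({"config_hash": chash, **geometry.to_dict()}, indent=2))
            _write_csv(table2, outdir / "table2.csv", chash)
            max_dev = float(table2["deviation_deg"].abs().max())
            report["stages"]["design"] = {"max_deviation_deg": max_dev}
            _log(f"design: max |angle deviation| {max_dev:.3f} deg")
        except Exception as exc:  # noqa: BLE001
            _log(f"design FAILED: {exc}")
            _finish()
            raise PipelineStageError("design", exc) from exc

        # --- tendon -------------------------------------------------------
        if norm["tendon"]["enabled"]:
            try:
                _log("stage tendon: excursion sweep and routing selection")
                td = norm["tendon"]
                angles = np.arange(
                    0.0, td["sweep_stop_deg"] + 1e-9, td["sweep_step_deg"])
                tables = {r.name: tendon_excursion(geometry, r, angles)
                          for r in default_routings(geometry)}
                _write_csv(pd.concat(tables.values(), ignore_index=True),
                           outdir / "excursions.csv", chash)
                selection = check_actuation_limits(tables)
                _write_csv(selection, outdir / "routing_selection.csv", chash)
                report["stages"]["tendon"] = {
                    "n_routings": len(selection),
                    "n_within_band": int(selection["within_band"].sum())}
            except Exception as exc:  # noqa: BLE001
                _log(f"tendon FAILED: {exc}")
                _finish()
                raise PipelineStageError("tendon", exc) from exc

    _log("pipeline complete")
    _finish()
    return report
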