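"""End-to-end orchestration: simulate → features → train → evaluate.

One call (or ``rotometry run``) reproduces the full synthetic experiment —
dataset generation, feature extraction, an 80/20 split, model fits and the
evaluation battery — from a single structured config, and records a
:class:`RunManifest` with every seed, hyperparameter and output digest so a
run can be reproduced byte-for-byte. Stage outputs already on disk whose
recorded config and input digests match are reused instead of recomputed.
"""

from __future__ import annotations

import copy
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import ConfigError
from .evaluate import build_report, save_report
from .features import extract_feature_table
from .landmarks import read_landmark_table, write_landmark_table
from .models import ModelSpec, canonical_algorithm, fit, split
from .simulate import (
    CameraModel,
    SimulationPlan,
    SkeletonConfig,
    nominal_angle_from_clip_id,
    simulate,
)

DEFAULT_CONFIG: dict = {
    "simulation": {
        "n_subjects": 10,
        "angles_deg": [float(a) for a in range(-50, 51, 10)],
        "frames_per_clip": 96,
        "landmark_noise_sd": 0.002,
        "anthropometric_cv": 0.05,
        "angle_hold_sd_deg": 1.0,
        "seed": 42,
    },
    "skeleton": {"stature_m": 1.683},
    "camera": {
        "distance_m": 2.0,
        "height_m": 1.5,
        "projection": "pinhole",
        "horizontal_fov_deg": 65.0,
        "image_aspect": 1080.0 / 1920.0,
    },
    "split": {"fraction_test": 0.2, "seed": 7, "unit": "frame"},
    "models": ["ordinary_least_squares", "gradient_boosted_trees"],
    "model_seed": 0,
    "plots": True,
}


@dataclass
class RunManifest:
    """Reproducibility record of one pipeline run."""

    config: dict
    seeds: dict
    software_version: str
    started_at: str
    finished_at: str = ""
    digests: dict = field(default_factory=dict)
    counts: dict = field(default_factory=dict)
    hyperparameters: dict = field(default_factory=dict)
    metrics: dict = field(default_factory=dict)

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.__dict__, fh, indent=2, default=str)
        return path


def load_config(path: str | Path) -> dict:
    with open(path, encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ConfigError(f"{path}: config must be a mapping")
    return cfg


def _merge(base: dict, override: dict, prefix: str = "") -> dict:
    out = copy.deepcopy(base)
    for k, v in override.items():
        if k not in base:
            raise ConfigError(f"unknown config field {prefix}{k!r}")
        if isinstance(base[k], dict):
            if not isinstance(v, dict):
                raise ConfigError(f"config field {prefix}{k!r} must be a mapping")
            out[k] = _merge(base[k], v, prefix=f"{prefix}{k}.")
        else:
            out[k] = v
    return out


def validate_config(config: dict | None) -> dict:
    """Merge onto defaults and validate; raises ConfigError naming the field."""
    cfg = _merge(DEFAULT_CONFIG, config or {})
    sim = cfg["simulation"]
    if not sim.get("angles_deg"):
        raise ConfigError("config field 'simulation.angles_deg' must be a nonempty list")
    for fld in ("n_subjects", "frames_per_clip"):
        if int(sim[fld]) < 1:
            raise ConfigError(f"config field 'simulation.{fld}' must be >= 1")
    if not cfg["models"]:
        raise ConfigError("config field 'models' must name at least one algorithm")
    cfg["models"] = [canonical_algorithm(m) for m in cfg["models"]]
    if not (0.0 < float(cfg["split"]["fraction_test"]) < 1.0):
        raise ConfigError("config field 'split.fraction_test' must be in (0, 1)")
    return cfg


def _plan(cfg: dict) -> SimulationPlan:
    s = cfg["simulation"]
    return SimulationPlan(
        n_subjects=int(s["n_subjects"]),
        angles_deg=tuple(float(a) for a in s["angles_deg"]),
        frames_per_clip=int(s["frames_per_clip"]),
        landmark_noise_sd=float(s["landmark_noise_sd"]),
        anthropometric_cv=float(s["anthropometric_cv"]),
        angle_hold_sd_deg=float(s["angle_hold_sd_deg"]),
        seed=int(s["seed"]),
    )


def _skeleton(cfg: dict) -> SkeletonConfig:
    sk = cfg["skeleton"]
    if "stature_m" in sk and len(sk) == 1:
        return SkeletonConfig.from_stature(float(sk["stature_m"]))
    fields = {k: float(v) for k, v in sk.items() if k != "stature_m"}
    return SkeletonConfig(**fields)


def _camera(cfg: dict) -> CameraModel:
    return CameraModel(**{k: (v if k == "projection" else float(v))
                          for k, v in cfg["camera"].items()})


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _config_digest(obj) -> str:
    return hashlib.sha256(json.dumps(obj, sort_keys=True).encode()).hexdigest()


def run_pipeline(config: dict | None, out_dir: str | Path) -> RunManifest:
    """Execute every stage under ``out_dir`` and return the manifest.

    Raises :class:`~rotometry.errors.ConfigError` before any stage runs if
    the config is invalid; any stage failure aborts the run with the stage
    named in the exception chain.
    """
    cfg = validate_config(config)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        config=cfg,
        seeds={
            "simulation": cfg["simulation"]["seed"],
            "split": cfg["split"]["seed"],
            "model": cfg["model_seed"],
        },
        software_version=__version__,
        started_at=time.strftime("%Y-%m-%dT%H:%M:%S"),
    )
    stage_meta_path = out_dir / "stage_digests.json"
    stage_meta = {}
    if stage_meta_path.exists():
        stage_meta = json.loads(stage_meta_path.read_text())

    # ---- stage: simulate ------------------------------------------------
    landmarks_path = out_dir / "landmarks.csv"
    sim_cfg_digest = _config_digest(
        {k: cfg[k] for k in ("simulation", "skeleton", "camera")}
    )
    if (
        landmarks_path.exists()
        and stage_meta.get("simulate", {}).get("config") == sim_cfg_digest
        and stage_meta.get("simulate", {}).get("output") == _sha256(landmarks_path)
    ):
        table = read_landmark_table(landmarks_path)
    else:
        try:
            table = simulate(_plan(cfg), _skeleton(cfg), _camera(cfg))
            write_landmark_table(table, landmarks_path)
        except Exception as exc:
            raise type(exc)(f"stage 'simulate' failed: {exc}") from exc
        stage_meta["simulate"] = {
            "config": sim_cfg_digest,
            "output": _sha256(landmarks_path),
        }
    manifest.counts["frames"] = len(table)
    manifest.digests["landmarks.csv"] = _sha256(landmarks_path)

    # ---- stage: features ------------------------------------------------
    features_path = out_dir / "features.csv"
    try:
        feats = extract_feature_table(table)
        feats.to_csv(features_path, index=False)
    except Exception as exc:
        raise type(exc)(f"stage 'features' failed: {exc}") from exc
    manifest.counts["feature_rows"] = len(feats)
    manifest.counts["degenerate_frames"] = feats.attrs.get("n_degenerate", 0)
    manifest.digests["features.csv"] = _sha256(features_path)

    # ---- stage: split + train + evaluate -------------------------------
    ds = split(
        feats,
        fraction_test=float(cfg["split"]["fraction_test"]),
        seed=int(cfg["split"]["seed"]),
        unit=cfg["split"]["unit"],
    )
    manifest.counts["train_rows"] = len(ds.train)
    manifest.counts["test_rows"] = len(ds.test)
    nominal = np.array(
        [nominal_angle_from_clip_id(c) for c in ds.test["clip_id"]], dtype=float
    )
    models_dir = out_dir / "models"
    models_dir.mkdir(exist_ok=True)
    for algo in cfg["models"]:
        spec = ModelSpec(algorithm=algo, seed=int(cfg["model_seed"]))
        try:
            model = fit(spec, ds.train)
        except Exception as exc:
            raise type(exc)(f"stage 'train:{algo}' failed: {exc}") from exc
        model_path = models_dir / f"{algo}.joblib"
        model.save(model_path)
        manifest.hyperparameters[algo] = _estimator_params(model)
        try:
            report = build_report(model, ds.test, nominal=nominal)
            save_report(report, out_dir / "report" / algo, plots=bool(cfg["plots"]))
        except Exception as exc:
            raise type(exc)(f"stage 'evaluate:{algo}' failed: {exc}") from exc
        manifest.metrics[algo] = {
            "pearson_r": report.pearson_r,
            "mae_deg": report.mae_deg,
        }
        manifest.digests[f"report/{algo}/report.json"] = _sha256(
            out_dir / "report" / algo / "report.json"
        )
    manifest.finished_at = time.strftime("%Y-%m-%dT%H:%M:%S")
    stage_meta_path.write_text(json.dumps(stage_meta, indent=2))
    manifest.save(out_dir / "manifest.json")
    return manifest


def _estimator_params(model) -> dict:
    try:
        params = model.estimator.get_params()
    except AttributeError:
        params = dict(model.spec.resolved_hyperparameters())
    return {k: v for k, v in params.items() if _jsonable(v)}


def _jsonable(v) -> bool:
    return isinstance(v, (str, int, float, bool, type(None)))
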