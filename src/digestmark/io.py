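"""File formats: chemistry/spectra CSV dialects, flat config files, model
serialization and run manifests.

The configuration format is a flat key-value text file (YAML-parseable) with
dotted namespaces, e.g.::

    cohort.n_sheep: 8
    cohort.recovery_mean.uNDF: 0.795
    spectra.noise_sd: 0.002
    calibration.max_lf: 10
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import yaml

from .chemometrics import CalibrationConfig, CalibrationModel
from .pretreat import PretreatmentSpec
from .profiles import MarkerKind
from .synthetic import CohortConfig, SpectraConfig

MODEL_SCHEMA_VERSION = 1

__all__ = [
    "load_config",
    "cohort_config_from",
    "spectra_config_from",
    "calibration_config_from",
    "stage_seed",
    "sha256_file",
    "write_manifest",
    "model_to_json",
    "model_from_json",
]


def load_config(path: str | Path) -> dict:
    """Read a flat dotted-key config file; returns {} for a missing path=None."""
    if path is None:
        return {}
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError(f"config file {path} must be a flat key-value mapping")
    return {str(k): v for k, v in data.items()}


def _apply_flat(obj, flat: dict, namespace: str) -> None:
    prefix = namespace + "."
    valid = {f.name: f for f in dataclasses.fields(obj)}
    for key, value in flat.items():
        if not key.startswith(prefix):
            continue
        rest = key[len(prefix):].split(".")
        name = rest[0]
        if name not in valid:
            raise ValueError(f"unknown config key {key!r} ({namespace}.{name})")
        current = getattr(obj, name)
        if len(rest) == 1:
            if isinstance(current, tuple):
                value = tuple(value)
            setattr(obj, name, value)
        elif len(rest) == 2 and isinstance(current, dict):
            sub = rest[1]
            marker_keys = {m.value: m for m in MarkerKind}
            k = marker_keys.get(sub, sub) if any(
                isinstance(x, MarkerKind) for x in current
            ) else sub
            current[k] = value
        else:
            raise ValueError(f"cannot interpret config key {key!r}")


def cohort_config_from(flat: dict, seed: int | None = None) -> CohortConfig:
    cfg = CohortConfig()
    _apply_flat(cfg, flat, "cohort")
    if seed is not None:
        cfg.seed = seed
    return cfg


def spectra_config_from(flat: dict, seed: int | None = None) -> SpectraConfig:
    cfg = SpectraConfig()
    _apply_flat(cfg, flat, "spectra")
    if seed is not None:
        cfg.seed = seed
    return cfg


def calibration_config_from(flat: dict, seed: int | None = None) -> CalibrationConfig:
    cfg = CalibrationConfig()
    _apply_flat(cfg, flat, "calibration")
    if seed is not None:
        cfg.seed = seed
    return cfg


def stage_seed(master_seed: int, stage: int) -> int:
    """Per-stage seed fan-out: child ``stage`` of the master seed sequence."""
    ss = np.random.SeedSequence(master_seed, spawn_key=(stage,))
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(out_dir: str | Path, *, config: dict, seeds: dict,
                   files: list[str | Path]) -> Path:
    """Record config snapshot, seeds, package version and output checksums."""
    from . import __version__

    out_dir = Path(out_dir)
    manifest = {
        "package": "digestmark",
        "version": __version__,
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "config": config,
        "seeds": seeds,
        "files": {
            str(Path(f).name): sha256_file(f) for f in files
        },
    }
    path = out_dir / "manifest.json"
    tmp = path.with_suffix(".json.tmp")
    tmp.write_text(json.dumps(manifest, indent=2, default=str))
    tmp.rename(path)
    return path


def model_to_json(model: CalibrationModel, path: str | Path) -> None:
    """Serialize a calibration model to a self-describing JSON file."""
    payload = {
        "schema_version": MODEL_SCHEMA_VERSION,
        "pretreatment": model.pretreatment.label,
        "msc_reference": None if model.msc_reference is None
        else model.msc_reference.tolist(),
        "wavelengths": model.wavelengths.tolist(),
        "x_mean": model.x_mean.tolist(),
        "y_mean": model.y_mean,
        "weights": model.weights.tolist(),
        "loadings": model.loadings.tolist(),
        "q": model.q.tolist(),
        "x_scales": model.x_scales.tolist(),
        "y_scales": model.y_scales.tolist(),
        "n_factors": model.n_factors,
        "sec": model.sec,
        "n_train": model.n_train,
        "modified": model.modified,
    }
    Path(path).write_text(json.dumps(payload))


def model_from_json(path: str | Path) -> CalibrationModel:
    payload = json.loads(Path(path).read_text())
    if payload.get("schema_version") != MODEL_SCHEMA_VERSION:
        raise ValueError(
            f"unsupported model schema version {payload.get('schema_version')}"
        )
    return CalibrationModel(
        pretreatment=PretreatmentSpec.parse(payload["pretreatment"]),
        msc_reference=None if payload["msc_reference"] is None
        else np.array(payload["msc_reference"]),
        wavelengths=np.array(payload["wavelengths"]),
        x_mean=np.array(payload["x_mean"]),
        y_mean=float(payload["y_mean"]),
        weights=np.array(payload["weights"]),
        loadings=np.array(payload["loadings"]),
        q=np.array(payload["q"]),
        x_scales=np.array(payload["x_scales"]),
        y_scales=np.array(payload["y_scales"]),
        n_factors=int(payload["n_factors"]),
        sec=float(payload["sec"]),
        n_train=int(payload["n_train"]),
        modified=bool(payload["modified"]),
    )
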