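"""Config and table I/O: flat YAML/JSON configs, CSV trial tables, manifests.

All interchange formats are plain text. Angles are degrees everywhere at the
interface; trial tables are CSV with a fixed header; configurations are flat
key-value mappings mirroring the dataclass field names so every default is
overridable from a file.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, fields, replace
from pathlib import Path
from typing import Optional, Union

import pandas as pd
import yaml

from .linking import ModelConfig
from .observer import DesignSpec, GroundTruth, _CELLS
from .population import ModelParams
from .psychometrics import TRIAL_COLUMNS

__all__ = [
    "read_trial_table",
    "write_trial_table",
    "load_model_config",
    "dump_model_config",
    "load_design_spec",
    "load_ground_truth",
    "dump_ground_truth",
    "write_manifest",
]

_TRIAL_DTYPES = {
    "subject": "int64",
    "session": "int64",
    "cue_type": "string",
    "validity": "string",
    "coherence": "float64",
    "cued_direction": "float64",
    "sample_direction": "float64",
    "test_direction": "float64",
    "change_sign": "string",
    "response": "string",
}


def read_trial_table(path: Union[str, Path],
                     declared_levels: Optional[list[float]] = None) -> pd.DataFrame:
    """Read a trial table CSV, validating its schema.

    Unknown columns are preserved. If ``declared_levels`` is given, coherence
    values outside that set raise a validation warning listing the
    offenders. Response-less tables (design only) are accepted.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    t = pd.read_csv(path)
    required = [c for c in TRIAL_COLUMNS if c != "response"]
    missing = [c for c in required if c not in t.columns]
    if missing:
        raise ValueError(f"trial table {path} is missing column(s): {missing}")
    for col, dt in _TRIAL_DTYPES.items():
        if col in t.columns:
            try:
                t[col] = t[col].astype(dt)
            except (TypeError, ValueError) as err:
                raise ValueError(f"column {col!r} cannot be read as {dt}") from err
    if declared_levels is not None and len(t):
        bad = sorted(set(t["coherence"]) - set(float(v) for v in declared_levels))
        if bad:
            warnings.warn(f"coherence values outside the declared levels: {bad}")
    return t


def write_trial_table(trials: pd.DataFrame, path: Union[str, Path]) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    trials.to_csv(path, index=False)
    return path


def _load_mapping(path: Union[str, Path]) -> dict:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    with open(path) as fh:
        data = json.load(fh) if path.suffix == ".json" else yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ValueError(f"config {path} must be a flat mapping")
    return data


def model_config_from_dict(data: dict) -> ModelConfig:
    """Build a ModelConfig from a flat mapping; unknown keys raise."""
    data = dict(data)
    par_names = {f.name for f in fields(ModelParams)}
    cfg_names = {f.name for f in fields(ModelConfig)} - {"params"}
    par_kw = {k: data.pop(k) for k in list(data) if k in par_names}
    cfg_kw = {k: data.pop(k) for k in list(data) if k in cfg_names}
    if data:
        raise ValueError(f"unknown model-config key(s): {sorted(data)}")
    for key in ("component_directions", "coherences"):
        if key in cfg_kw:
            cfg_kw[key] = tuple(cfg_kw[key])
    return ModelConfig(params=ModelParams(**par_kw), **cfg_kw)


def load_model_config(path: Union[str, Path]) -> ModelConfig:
    return model_config_from_dict(_load_mapping(path))


def dump_model_config(config: ModelConfig, path: Union[str, Path]) -> Path:
    flat = {k: v for k, v in asdict(config).items() if k != "params"}
    flat.update(asdict(config.params))
    for key in ("component_directions", "coherences"):
        flat[key] = list(flat[key])
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(flat, fh, sort_keys=True)
    return path


def load_design_spec(path: Union[str, Path]) -> DesignSpec:
    data = _load_mapping(path)
    for key in ("coherence_levels", "cue_types", "reference_directions"):
        if key in data:
            data[key] = tuple(data[key])
    return DesignSpec(**data)


def load_ground_truth(path: Union[str, Path]) -> GroundTruth:
    """Read generator curves from a mapping with per-cell dmax/c50 keys.

    Expected keys: ``<cue_type>_<validity>_dmax`` and ``..._c50`` for the
    four cells, plus ``exponent`` and optional ``bias``.
    """
    data = _load_mapping(path)
    curves = {}
    for ct, val in _CELLS:
        try:
            curves[(ct, val)] = (float(data.pop(f"{ct}_{val}_dmax")),
                                 float(data.pop(f"{ct}_{val}_c50")))
        except KeyError as err:
            raise ValueError(f"ground truth file lacks key {err}") from err
    return GroundTruth(curves=curves, exponent=float(data.pop("exponent", 1.5)),
                       bias=float(data.pop("bias", 0.0)))


def dump_ground_truth(truth: GroundTruth, path: Union[str, Path]) -> Path:
    flat: dict = {"exponent": truth.exponent, "bias": truth.bias}
    for (ct, val), (dmax, c50) in truth.curves.items():
        flat[f"{ct}_{val}_dmax"] = float(dmax)
        flat[f"{ct}_{val}_c50"] = float(c50)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(flat, fh, sort_keys=True)
    return path


def write_manifest(out_dir: Union[str, Path], seed: int, config: dict) -> Path:
    """Write a reproducibility manifest (config hash, seed, version) to out_dir."""
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    manifest = {
        "seed": seed,
        "config_sha256": hashlib.sha256(blob).hexdigest(),
        "package_version": __version__,
        "config": config,
    }
    path = out_dir / "manifest.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return path
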