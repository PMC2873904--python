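"""Reference configuration: loading and validation of parameter files.

All numeric model constants are configuration, not code.  The packaged
``data/reference_params.yaml`` holds the reference transcription; user
files with the same layout can be loaded with :func:`load_config`.
"""

from __future__ import annotations

import functools
import hashlib
import importlib.resources
import json
from pathlib import Path
from typing import Any

import yaml

from .receptor import ReceptorComplexParams

__all__ = [
    "load_config",
    "reference_config",
    "reference_receptor_params",
    "reference_adaptation_defaults",
    "strain_preset",
    "receptor_params_from_config",
    "config_hash",
]

_RECEPTOR_KEYS = {
    "nu_a", "nu_s", "K_off_a", "K_on_a", "K_off_s", "K_on_s",
    "fm_intercept", "fm_slope", "size_intercept", "size_slope",
}
_ADAPTATION_KEYS = {"g_R", "K_R", "K_B", "M_max", "m_c"}
_STRAIN_KEYS = {"a", "model", "dt_sample", "k_rise", "k_fall", "alpha"}


def _validate(cfg: dict[str, Any], source: str) -> None:
    problems: list[str] = []
    for section, keys in (("receptor", _RECEPTOR_KEYS), ("adaptation", _ADAPTATION_KEYS)):
        if section not in cfg:
            problems.append(f"missing section {section!r}")
            continue
        missing = keys - set(cfg[section])
        if missing:
            problems.append(f"section {section!r} missing keys: {sorted(missing)}")
    for strain, entry in cfg.get("strains", {}).items():
        missing = _STRAIN_KEYS - set(entry)
        if missing:
            problems.append(f"strain {strain!r} missing keys: {sorted(missing)}")
    if problems:
        raise ValueError(f"invalid configuration {source}: " + "; ".join(problems))


def load_config(path: str | Path) -> dict[str, Any]:
    """Load and validate a YAML/JSON parameter file."""
    path = Path(path)
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"configuration {path} is not a mapping")
    _validate(cfg, str(path))
    return cfg


@functools.lru_cache(maxsize=1)
def reference_config() -> dict[str, Any]:
    """The packaged reference parameter set."""
    text = (
        importlib.resources.files("chemomwc")
        .joinpath("data/reference_params.yaml")
        .read_text()
    )
    cfg = yaml.safe_load(text)
    _validate(cfg, "reference_params.yaml")
    return cfg


def receptor_params_from_config(cfg: dict[str, Any]) -> ReceptorComplexParams:
    sec = cfg["receptor"]
    return ReceptorComplexParams(**{k: float(sec[k]) for k in _RECEPTOR_KEYS})


def reference_receptor_params() -> ReceptorComplexParams:
    return receptor_params_from_config(reference_config())


def reference_adaptation_defaults() -> dict[str, float]:
    return {k: float(v) for k, v in reference_config()["adaptation"].items()}


def strain_preset(name: str, cfg: dict[str, Any] | None = None) -> dict[str, Any]:
    """Preset (a, model, dt_sample, flow constants, alpha) for a strain."""
    cfg = cfg or reference_config()
    strains = cfg["strains"]
    if name not in strains:
        raise KeyError(f"unknown strain {name!r}; known: {sorted(strains)}")
    return dict(strains[name])


def config_hash(cfg: dict[str, Any]) -> str:
    """Short deterministic digest of a configuration, for output provenance."""
    blob = json.dumps(cfg, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
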