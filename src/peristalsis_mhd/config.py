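"""Configuration handling: YAML/JSON files and flat key mappings.

Config files are flat mappings whose keys match the
:class:`~peristalsis_mhd.params.DimensionlessParams` field names plus a small
set of run keys (``F``, ``window``, ``mode``, ``degrees``, grid settings,
``seed``).  Unknown keys are warned about, never silently dropped.  The
legacy geometry key ``d`` plays no role in the reduced system and is accepted
but ignored, with a warning.
"""

from __future__ import annotations

import json
import math
import warnings
from pathlib import Path

import yaml

from .params import DimensionlessParams

__all__ = ["load_config", "params_from_mapping", "RUN_KEYS"]

PARAM_KEYS = set(DimensionlessParams.field_names())
RUN_KEYS = {"F", "window", "mode", "degrees", "nx", "ny", "n_levels",
            "n_points", "seed", "output", "dpdx", "x", "n", "tol"}
IGNORED_KEYS = {"d"}
ANGLE_KEYS = {"beta", "alpha"}


def load_config(path) -> dict:
    """Load a YAML or JSON config file into a flat dict."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        cfg = json.loads(text)
    else:
        cfg = yaml.safe_load(text)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a flat mapping")
    return cfg


def params_from_mapping(cfg: dict, degrees: bool = False) -> tuple[DimensionlessParams, dict]:
    """Build validated parameters from a flat mapping.

    Returns ``(params, run)`` where ``run`` holds the non-parameter run keys.
    Angles are radians unless ``degrees`` is true (or the mapping itself sets
    ``degrees: true``).
    """
    cfg = dict(cfg)
    degrees = bool(cfg.pop("degrees", degrees))
    for key in IGNORED_KEYS & cfg.keys():
        warnings.warn(
            f"config key {key!r} plays no role in the reduced long-wavelength "
            "system and is ignored", stacklevel=2)
        cfg.pop(key)
    unknown = set(cfg) - PARAM_KEYS - RUN_KEYS
    if unknown:
        warnings.warn(
            f"unknown config keys ignored: {sorted(unknown)}", stacklevel=2)
        for key in unknown:
            cfg.pop(key)
    kw = {k: float(cfg.pop(k)) for k in list(cfg) if k in PARAM_KEYS}
    if degrees:
        for key in ANGLE_KEYS & kw.keys():
            kw[key] = math.radians(kw[key])
    return DimensionlessParams(**kw), cfg
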