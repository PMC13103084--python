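"""Pipeline configuration: layered defaults + optional YAML/JSON overrides."""

from __future__ import annotations

import copy
from pathlib import Path

import yaml

from .pools import ONE_POOL_DEFAULTS, TWO_POOL_DEFAULTS
from .sic import SIC_DEFAULTS
from .thresholds import THRESHOLD_DEFAULTS

__all__ = ["DEFAULTS", "load_config"]

DEFAULTS: dict = {
    "seed": 0,
    "curve": {
        "baseline": 0.0,
        "rise_start": 1955.0,
        "peak_year": 1964.0,
        "peak_amp": 700.0,
        "decay_efold": 16.0,
        "end_level": 0.0,
        "end_year": 2020.0,
    },
    "sic": dict(SIC_DEFAULTS),
    "mixing": {
        "young_from_atmosphere": True,
    },
    "one_pool": dict(ONE_POOL_DEFAULTS),
    "two_pool": dict(TWO_POOL_DEFAULTS),
    "thresholds": {
        **THRESHOLD_DEFAULTS,
        # (response, predictor) pairs fitted on the per-site table
        "pairs": [["delta14c_bulk", "aridity"]],
    },
}


def _merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for key, val in override.items():
        if isinstance(val, dict) and isinstance(out.get(key), dict):
            out[key] = _merge(out[key], val)
        else:
            out[key] = copy.deepcopy(val)
    return out


def load_config(source=None) -> dict:
    """Resolve a full config from defaults plus an optional override.

    ``source`` may be None, a mapping, or a path to a YAML (or JSON — valid
    YAML) file. Unknown keys are kept, so module-specific extras pass
    through.
    """
    if source is None:
        return copy.deepcopy(DEFAULTS)
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            data = yaml.safe_load(fh) or {}
    elif isinstance(source, dict):
        data = source
    else:
        raise TypeError("config source must be None, a mapping, or a path")
    if not isinstance(data, dict):
        raise ValueError("config file must contain a mapping at top level")
    return _merge(DEFAULTS, data)
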