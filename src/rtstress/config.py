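"""Single YAML configuration governing every pipeline stage.

Every tolerance and threshold used by the signal-processing, scoring
and analysis modules is a named key with its default here, so a whole
run is reproducible from one file plus a seed.  ``load_config`` merges
a user YAML over the defaults (nested keys merge, scalars override).
"""

from __future__ import annotations

import copy
from pathlib import Path
from typing import Any, Optional

import yaml

__all__ = ["default_config", "load_config"]


def default_config() -> dict:
    return {
        "seed": 0,
        "cohort": {
            "n_patients": 41,
            "days_per_patient": [1, 5],
            "sex_ratio": 0.66,
            "age_range": [47.0, 80.0],
            "p_stress": 0.5,
            "shift_magnitude": 0.2,
            "resp_slope": 0.286,
            "resp_intercept": 10.0,
            "patient_sd": 2.0,
            "noise_sd": 1.5,
        },
        "ppg": {
            "fs": 100.0,
            "band": [0.5, 8.0],
            "sg_window_s": 0.13,
            "refractory_s": 0.3,
            "prominence_frac": 2.5,
            "flatline_window_s": 2.0,
            "clip_run": 3,
            "z_max": 5.0,
        },
        "hrv": {
            "fs_resample": 4.0,
            "estimator": "welch",
            "lf_band": [0.04, 0.15],
            "hf_band": [0.15, 0.4],
            "tp_band": [0.004, 0.4],
        },
        "resp": {
            "smooth_s": 0.5,
            "min_separation_s": 1.5,
            "prominence_frac": 0.1,
            "amplitude_mode": "values",
        },
        "predict": {
            "dataset_type": 8,
            "model": "forest",
            "folds": 10,
            "grouped": True,
        },
    }


def _merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = copy.deepcopy(v)
    return out


def load_config(path: Optional[str | Path] = None, **overrides: Any) -> dict:
    """Defaults, optionally merged with a YAML file and kwargs."""
    cfg = default_config()
    if path is not None:
        user = yaml.safe_load(Path(path).read_text()) or {}
        cfg = _merge(cfg, user)
    if overrides:
        cfg = _merge(cfg, overrides)
    return cfg
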