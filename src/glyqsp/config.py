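"""Run configuration: nested defaults, YAML I/O, validation, seed fan-out."""

from __future__ import annotations

import copy
import hashlib
import json
from pathlib import Path
from typing import Any

import numpy as np
import yaml

__all__ = [
    "default_config",
    "load_config",
    "save_config",
    "validate_config",
    "stage_seed",
    "config_hash",
    "STAGES",
]

#: pipeline stages, each drawing its own child seed from the global seed
STAGES = (
    "network",
    "striatum",
    "bold",
    "fixtures",
    "calibration",
    "sensitivity",
)


def default_config() -> dict:
    """Nested default configuration covering every pipeline stage.

    Pharmacodynamic defaults are the lumped NR2A/B (e-e) and NR2C/D (e-i)
    Hill parameters of the example beneficial-U setting; network and
    striatum defaults mirror the corresponding dataclass defaults.
    """
    return {
        "seed": 0,
        "pharmacodynamics": {
            "ee": {"ec50_uM": 0.35, "slope": 1.84},
            "ei": {"ec50_uM": 0.25, "slope": 1.1},
            "gmax_ee": 1.0,
            "gmax_ei": 1.0,
            # surface-expression loss at high glycine; null disables
            "internalization_ee": None,
            "internalization_ei": None,
        },
        "pathology": {
            "nmda_reduction": 0.3,
            "gaba_reduction": 0.3,
            "da_deficit": 0.3,
            "noise_increase": 0.3,
        },
        "network": {},  # overrides of cortical.NetworkConfig fields
        "striatum": {
            "n_sp_d1": 2,
            "n_enk_d2": 2,
            "n_dual": 1,
            "drive_gain": 0.6,
            "reference_rate_hz": 15.0,
            "duration_ms": 2000.0,
            "gate_onset_ms": 200.0,
            "params": {},  # overrides of striatum.MSNParams fields
            "modulation": {},  # overrides of striatum.ModulationState fields
        },
        "bold": {"params": {}, "summary": "peak"},
        "calibration": {"w_cortical": 0.4, "w_striatal": 0.6},
        "transporter": {
            "na_in_mM": [10.0, 20.0],
            "cl_in_mM": [6.0, 12.0],
            "gly_in_mM": [0.5, 5.0],
            "vm_mV": [-75.0, -40.0],
            "na_out_mM": 140.0,
            "cl_out_mM": 120.0,
            "temperature_K": 310.0,
        },
        "dose_response": {
            "glycine_grid_uM": [0.1, 0.3, 1.0, 3.0, 10.0, 30.0, 100.0],
            "n_seeds": 5,
        },
        "sensitivity": {"lo_frac": -0.2, "hi_frac": 0.2, "n": 3, "n_seeds": 2},
    }


def validate_config(cfg: dict) -> None:
    """Schema check: required sections present, key physical constraints."""
    missing = set(default_config()) - set(cfg)
    if missing:
        raise ValueError(f"config missing section(s): {sorted(missing)}")
    pdc = cfg["pharmacodynamics"]
    for cls in ("ee", "ei"):
        if not (pdc[cls]["ec50_uM"] > 0 and pdc[cls]["slope"] > 0):
            raise ValueError(f"pharmacodynamics.{cls}: ec50 and slope must be positive")
    grid = cfg["dose_response"]["glycine_grid_uM"]
    if len(grid) < 1 or any(g <= 0 for g in grid) or list(grid) != sorted(grid):
        raise ValueError("dose_response.glycine_grid_uM must be positive and increasing")
    w = cfg["calibration"]
    if w["w_cortical"] < 0 or w["w_striatal"] < 0:
        raise ValueError("calibration weights must be >= 0")
    if not isinstance(cfg["seed"], int):
        raise ValueError("seed must be an integer")


def load_config(path: str | Path) -> dict:
    """Load a YAML config, overlaying the defaults (missing keys filled in)."""
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    cfg = _deep_merge(default_config(), user)
    validate_config(cfg)
    return cfg


def save_config(cfg: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)


def _deep_merge(base: dict, overlay: dict) -> dict:
    out = copy.deepcopy(base)
    for k, v in overlay.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _deep_merge(out[k], v)
        else:
            out[k] = copy.deepcopy(v)
    return out


def stage_seed(global_seed: int, stage: str, index: int = 0) -> int:
    """Deterministic per-stage child seed (< 2**31) from the global seed.

    A counter-based fan-out: each (stage, index) pair owns an independent
    stream, so stages can be re-run in isolation.
    """
    if stage not in STAGES:
        raise KeyError(f"unknown stage {stage!r}; stages: {STAGES}")
    ss = np.random.SeedSequence([int(global_seed), STAGES.index(stage), int(index)])
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31 - 1))


def config_hash(cfg: dict) -> str:
    """Stable short hash of a config for run manifests."""
    blob = json.dumps(cfg, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]
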