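"""YAML configuration with documented defaults for every stage."""

from __future__ import annotations

import copy
import hashlib
import json
from pathlib import Path

import yaml

DEFAULTS: dict = {
    "simulate": {
        "modality": "both",  # "nlo" | "qpi" | "both"
        "nlo": {
            "time_points": ["0h", "12h", "24h", "72h", "7d"],
            "plates_per_condition": 5,
            "fovs_per_plate": 2,
        },
        "qpi": {
            "time_points": ["0h", "24h", "48h", "72h", "7d"],
            "dishes_per_condition": 2,
            "tomograms_per_dish": 3,
        },
    },
    "preprocess": {
        "outlier_z_thresh": 5.0,
        "max_shift_px": 10,
        "even_rows_reversed": True,
    },
    "nlo": {
        "tpef_threshold": 0.25,  # a.u.
        "srs_threshold": 2.2e-4,  # ΔI/I
        "min_area_px": 5,
        "circularity_range": [0.3, 1.0],
        "connectivity": 8,
        "closing_radius_px": 2,
        "min_cell_component_px": 50,
    },
    "coloc": {
        "pairs": [["SRS", "FCARS"], ["ECARS", "TPEF"]],
        # fixed thresholds by channel; channels not listed use in-mask Otsu
        "thresholds": {"TPEF": 0.25, "SRS": 2.2e-4},
        "n_rand": 200,
        "block_px": 1,
    },
    "qpi": {
        "delta_n": 0.003,
        "min_voxels": 100,
        "alpha_cell": 0.19,  # ml/g
        "alpha_lipid": 0.135,  # ml/g
        "lipid_ri_range": [1.40, 1.46],
    },
    "stats": {
        "alpha": 0.05,
        "baseline": "0h",
        "min_n": 3,
        "bh_correction": False,
    },
}


def _deep_merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _deep_merge(out[k], v)
        else:
            out[k] = copy.deepcopy(v)
    return out


def load_config(path: str | Path | None = None) -> dict:
    """Defaults, optionally overridden by a YAML file (deep merge)."""
    cfg = copy.deepcopy(DEFAULTS)
    if path is not None:
        user = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(user, dict):
            raise ValueError(f"config {path} must be a mapping")
        cfg = _deep_merge(cfg, user)
    return cfg


def config_hash(cfg: dict) -> str:
    """Stable short hash of a config for provenance logs."""
    return hashlib.sha256(json.dumps(cfg, sort_keys=True).encode()).hexdigest()[:16]
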