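"""Run configuration and provenance.

The whole pipeline is driven by one YAML file.  Unknown keys are rejected
(typos should fail loudly, not silently fall back to defaults), and every
effective parameter — defaults included — is printed into the provenance
record emitted alongside the results.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__

__all__ = ["RunConfig", "load_config", "build_provenance"]

_DEFAULTS: dict = {
    "seed": 1,
    "output_dir": "results",
    "stages": {
        "simulate": True,
        "flux": True,
        "scoc": True,
        "radiolysis": True,
        "artifacts": True,
        "voltage": True,
        "stats": True,
    },
    "chamber": {
        "n_chambers": 6,
        "dop_true": [2.4, 3.1, 4.2, 5.6, 7.0, 8.7],
        "treatments": [
            "algal",
            "DIC+NH4",
            "filtered seawater",
            "algal",
            "DIC+NH4",
            "control",
        ],
        "scoc_true": 0.7,
        "initial_o2_mean": 185.2,
        "initial_o2_sd": 2.9,
        "saturation_shape": 1.0,
        "chamber_area": 484.0,
        "water_depth": 10.0,
        "stir_off_interval": 1.0,
        "syringe_times": [28.0, 38.0, 47.0],
        "syringe_volume": 50.0,
        "ambient_o2": 185.2,
        "noise_sd": 0.5,
        "drift_rate": 0.27,
        "log_interval": 10.0,
        "duration_h": 47.0,
    },
    "profile": {
        "true_flux": 0.7,
        "porosity": 0.8,
        "diffusivity": 8.159e-6,
        "overlying_o2": 185.2,
        "penetration_depth_mm": 4.0,
        "surface_depth_offset_mm": 2.0,
        "step_mm": 0.05,
        "noise_sd": 0.5,
    },
    "flux": {
        "dilution_correction": False,
        "initial_window_s": 300.0,
        "max_window_s": 300.0,
    },
    "scoc": {"porosity": 0.8, "window_mm": 0.5},
    "radiolysis": {
        "inventory_table": None,  # packaged illustrative inventory when None
        "volume_l": 4.84,
        "t_h": 48.0,
        "sediment_o2_rate_umol_l_d": 1.5e-4,
    },
    "artifacts": {
        "dop_reference": 3.5,
        "water_depths_cm": [4.375, 12.5],
        "bubble_radius_mm": 1.0,
        "site_depth_m": 4000.0,
        "leak_rates": {"shipboard": 0.14, "laboratory": 0.11},
    },
    "voltage": {
        "n_surveys": 3,
        "n_sites": 20,
        "mean_v": [0.25, 0.45, 0.08],
        "sd_v": 0.12,
        "background_v": 0.003,
        "overpotential_v": 0.37,
        "mechanism_reduction_v": 0.0,
    },
    "stats": {"n_taxa": 8, "correlated_taxon_rho": 0.47},
}


def _merge(defaults: dict, user: dict, path: str = "") -> dict:
    out = {}
    for key, value in user.items():
        if key not in defaults:
            raise ValueError(f"unknown configuration key {path + key!r}")
    for key, dval in defaults.items():
        if key in user and isinstance(dval, dict) and isinstance(user[key], dict):
            out[key] = _merge(dval, user[key], path + key + ".")
        elif key in user:
            out[key] = user[key]
        else:
            out[key] = dval
    return out


@dataclass
class RunConfig:
    """Fully resolved pipeline configuration (defaults applied)."""

    values: dict = field(default_factory=lambda: _merge(_DEFAULTS, {}))

    def __getitem__(self, key):
        return self.values[key]

    @property
    def seed(self) -> int:
        return int(self.values["seed"])

    @property
    def output_dir(self) -> Path:
        return Path(self.values["output_dir"])

    def stage_enabled(self, name: str) -> bool:
        return bool(self.values["stages"].get(name, False))


def load_config(path=None, overrides: dict | None = None) -> RunConfig:
    """Load a YAML config, apply defaults and reject unknown keys."""
    user: dict = {}
    if path is not None:
        with open(path, "r", encoding="utf-8") as fh:
            user = yaml.safe_load(fh) or {}
    if overrides:
        user = _merge(_merge(_DEFAULTS, user), overrides)
    return RunConfig(_merge(_DEFAULTS, user))


def _digest(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def build_provenance(
    config: RunConfig, inputs: list | None = None, timestamp: str | None = None
) -> dict:
    """Provenance record: version, config snapshot, input digests."""
    return {
        "package": "darkox",
        "version": __version__,
        "config": config.values,
        "input_digests": {str(p): _digest(p) for p in (inputs or [])},
        "timestamp": timestamp,
    }


def write_provenance(record: dict, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(record, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
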