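"""Run configuration: defaults for every stage, TOML loading, archiving.

Every tunable that the analysis stages expose lives here with its default,
grouped by pipeline stage.  A run's effective configuration is the stage
defaults overlaid with the user's TOML file; :func:`archive_config` writes
the merged result next to the outputs so any run can be regenerated.
"""

from __future__ import annotations

import copy
import json
import tomllib
from pathlib import Path
from typing import Any

#: Stage-by-stage defaults.  The geometry mirrors a 17 mm x 17 mm field of
#: view imaged at 100 x 100 pixels and 3000 frames/s.
DEFAULTS: dict[str, dict[str, Any]] = {
    "synthetic": {
        "grid_rows": 100,
        "grid_cols": 100,
        "pixel_size_mm": 0.17,
        "frame_rate_hz": 3000.0,
        "n_frames": 1500,
        "base_speed_mps": 0.5,
        "source": "left",
        "upstroke_ms": 2.0,
        "apd_ms": 100.0,
        # camera noise / drift are not constrained by any measurement we
        # emulate; both are exposed here and logged with every run
        "noise_sd": 0.05,
        "drift_per_s": 0.1,
        "inactive_border_px": 0,
        "seed": 0,
    },
    "preprocess": {
        "kernel_size": 3,
        "filter_low_hz": 0.0,
        "filter_high_hz": 100.0,
        "filter_order": 4,
        "drift_poly_order": 2,
        "drift_window_ms": 200.0,
        "snr_threshold": 3.0,
        "snr_smooth_ms": 20.0,
    },
    "activation": {
        "method": "max_dvdt",  # or "level50"
        "amplitude_floor": 0.2,
        "window_ms": None,
    },
    "velocity": {
        "fit_radius_px": 3,
        "poly_order": 2,
        "speed_cap_mps": 2.0,
        "gradient_floor_s_per_m": 1e-6,
    },
    "regions": {
        "threshold_mps": 0.2,
        "min_component_px": 2,
    },
    "stats": {
        "ess_rounding": "nearest",
    },
}


def default_config() -> dict[str, dict[str, Any]]:
    """A deep copy of the stage defaults."""
    return copy.deepcopy(DEFAULTS)


def load_config(path: str | Path | None = None) -> dict[str, dict[str, Any]]:
    """Merge a TOML config file over the defaults.

    Unknown sections or keys raise ``ValueError`` so typos never silently
    fall back to a default.
    """
    cfg = default_config()
    if path is None:
        return cfg
    with open(path, "rb") as fh:
        user = tomllib.load(fh)
    for section, values in user.items():
        if section not in cfg:
            raise ValueError(f"unknown config section [{section}]")
        if not isinstance(values, dict):
            raise ValueError(f"config section [{section}] must be a table")
        for key, val in values.items():
            if key not in cfg[section]:
                raise ValueError(f"unknown config key [{section}] {key}")
            cfg[section][key] = val
    return cfg


def archive_config(cfg: dict[str, Any], out_dir: str | Path, seed: int | None = None) -> Path:
    """Write the effective config (plus the seed used) into ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    payload = copy.deepcopy(cfg)
    if seed is not None:
        payload["synthetic"]["seed"] = seed
    path = out_dir / "run_config.json"
    path.write_text(json.dumps(payload, indent=2, default=str))
    return path
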