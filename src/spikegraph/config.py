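"""Declarative run configuration.

A single YAML file mirrors every pipeline parameter; unspecified keys
fall back to the defaults below, and every run writes the fully resolved
configuration next to its outputs for provenance.
"""

from __future__ import annotations

from pathlib import Path

import yaml

__all__ = ["DEFAULTS", "load_config", "save_config"]

DEFAULTS: dict = {
    "data": {
        "dtype": "int16",
        "n_channels_total": None,       # inferred from the probe file
        "sampling_rate": 30000.0,
        "gain": 1.0,
    },
    "batch": {
        "N_T": 60000,                   # samples per batch
        "n_t": 61,                      # waveform length / batch padding
    },
    "preprocessing": {
        "highpass_hz": 300.0,
        "butterworth_order": 3,
        "whitening_neighbors": 32,
        "whitening_epsilon": None,      # 1e-6 * mean eigenvalue if None
        "bad_channel_variance_threshold": None,   # off by default
    },
    "drift": {
        "enabled": True,
        "rigid_only": False,
        "bin_size_s": 2.0,
        "n_blocks": 6,
        "kriging_sigma_um": 20.0,
        "kriging_lambda": 0.01,
    },
    "detection": {
        "universal_threshold": 9.0,     # on |W^T D|, whitened-norm units
        "learned_threshold": 8.0,       # V_explained > threshold^2
        "n_shapes": 6,
        "n_sizes": 5,
        "n_pcs": 6,
    },
    "deconvolution": {
        "enabled": True,
        "n_rounds": 50,
        "feature_deconvolution": True,
    },
    "clustering": {
        "recluster": True,
        "n_sub": 25000,
        "knn": 10,
        "n_init": 200,
        "n_iter": 30,
        "section_um": 40.0,
        "bimod_threshold": 0.5,
        "modularity_floor": 0.2,
        "use_ccg": True,
    },
}


def _merge(base: dict, over: dict) -> dict:
    out = dict(base)
    for k, v in over.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def load_config(path: str | Path | None = None,
                overrides: dict | None = None) -> dict:
    """Defaults, overlaid with a YAML file, overlaid with ``overrides``."""
    cfg = DEFAULTS
    if path is not None:
        with open(path) as fh:
            cfg = _merge(cfg, yaml.safe_load(fh) or {})
    if overrides:
        cfg = _merge(cfg, overrides)
    return cfg


def save_config(cfg: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)
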