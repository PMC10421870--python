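"""Single structured run configuration for the pipeline stages."""

from __future__ import annotations

import copy

import yaml

__all__ = ["DEFAULT_CONFIG", "default_config", "load_config", "dump_default"]

# Every pipeline constant appears exactly once here.
DEFAULT_CONFIG: dict = {
    "simulate": {
        "n_recordings": 22,       # cohort size emulated by default
        "duration_s": 5400.0,     # 90-minute sessions
        "sample_rate_hz": 100.0,
        "episode_rate_per_hour": 6.0,
        "episode_duration_range_s": [20.0, 60.0],
        "fixation_duration_multiplier": 2.0,
        "saccade_amplitude_multiplier": 2.0,
        "blink_rate_multiplier": 2.0,
        "pupil_shift_mm": 0.5,
    },
    "windows": {
        "window_length": 500,     # samples per window (5 s at 100 Hz)
        "overlap": 100,           # samples shared by adjacent windows
        "min_overlap_fraction": 0.5,  # episode overlap needed for a positive label
    },
    "events": {
        "dispersion_threshold_px": 30.0,
        "min_fixation_duration_s": 0.1,
        "min_blink_duration_s": 0.05,
        "max_blink_duration_s": 0.5,
    },
    "features": {
        "sequence_length": 6,     # events per classified sequence
        "global_local_threshold_px": 100.0,
        "grid": [4, 4],
    },
    "model": {
        "conv_channels": 64,      # kernels per convolution layer
        "conv_layers": 3,
        "kernel": 2,              # temporal extent of each kernel
        "lstm_hidden": 128,       # recurrent width
        "lstm_layers": 3,
    },
    "training": {
        "learning_rate": 0.0001,
        "epochs": 100,
        "batch_size": 64,
        "folds": 5,
        "methods": ["hybrid", "conv_only", "recurrent_only", "logistic"],
        "balance": True,
    },
}


def default_config() -> dict:
    return copy.deepcopy(DEFAULT_CONFIG)


def _merge(base: dict, override: dict, path: str = "") -> dict:
    out = copy.deepcopy(base)
    for key, value in override.items():
        here = f"{path}.{key}" if path else key
        if key not in base:
            raise KeyError(f"unknown config key: {here}")
        if isinstance(base[key], dict):
            if not isinstance(value, dict):
                raise KeyError(f"config key {here} must be a mapping")
            out[key] = _merge(base[key], value, here)
        else:
            out[key] = value
    return out


def load_config(path=None) -> dict:
    """Defaults overlaid with the YAML file at ``path``; unknown keys error."""
    if path is None:
        return default_config()
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    if not isinstance(user, dict):
        raise KeyError(f"config file {path} must contain a mapping")
    return _merge(DEFAULT_CONFIG, user)


def dump_default(path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(DEFAULT_CONFIG, fh, sort_keys=False)
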