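"""Run configuration: a plain, serializable mapping with validation.

Every tolerance or threshold that affects results lives here so a run is
reproducible from the config file plus the master seed alone.
"""

from __future__ import annotations

import copy
import hashlib
import json
from pathlib import Path

import yaml

__all__ = ["default_config", "load_config", "save_config", "validate_config", "config_hash"]


def default_config() -> dict:
    return {
        "out_dir": "ssvep_run",
        "seed": 0,
        "cohort": {
            "n_participants": 12,
            # multiplicative spread of per-participant true thresholds
            # (log10 decades on native units) and the latent correlation
            # between EEG and behavioural sensitivity
            "between_sd": 0.15,
            "eeg_psy_correlation": 0.5,
        },
        "simulate": {
            "montage": "biosemi64",
            "srate": 250.0,
            "n_trials_per_direction": 6,
            "conditions": ["contrast", "spatial_frequency", "orientation"],
            "noise": {"white_sd": 1.5, "pink_exponent": 1.0, "pink_scale": 3.0, "blink_rate": 0.0},
        },
        "preprocess": {
            "target_srate": 250.0,
            "lowpass_hz": 45.0,
            "ptp_limit_uv": 150.0,
            "reference": "occipital_mean",
            "bad_channels": [],
        },
        "spectrum": {
            "analysis_freq": 20.0,
            "resolution": 1.0,
            "n_neighbors_per_side": 6,
            "skip_adjacent": 1,
        },
        "selection": {
            "z_criterion": 2.33,
            "run_window": 4,
            "run_min_sig": 3,
            "reg_snr_onset": 3.0,
            "increasing_rule": "mirrored",
        },
        "quest": {
            "n_trials": 60,
            "target_p": 0.75,
            "n_alternatives": 2,
            "assumed_beta": 0.3,
            "observer_beta": 0.15,
            "prior_sd": 0.5,
        },
        "stats": {"retest_pairing": "directions"},
    }


def _merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for key, val in override.items():
        if isinstance(val, dict) and isinstance(out.get(key), dict):
            out[key] = _merge(out[key], val)
        else:
            out[key] = copy.deepcopy(val)
    return out


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> dict:
    """Defaults, overlaid with a YAML file and/or an override mapping."""
    cfg = default_config()
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(loaded, dict):
            raise ValueError(f"config file {path} must hold a mapping")
        cfg = _merge(cfg, loaded)
    if overrides:
        cfg = _merge(cfg, overrides)
    return cfg


def save_config(cfg: dict, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg, sort_keys=True))


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(json.dumps(cfg, sort_keys=True).encode()).hexdigest()[:16]


def validate_config(cfg: dict) -> list[str]:
    """All invariant violations as human-readable strings; empty = runnable."""
    issues: list[str] = []

    def get(*keys, default=None):
        node = cfg
        for key in keys:
            if not isinstance(node, dict) or key not in node:
                return default
            node = node[key]
        return node

    sel_window = get("selection", "run_window", default=4)
    sel_min = get("selection", "run_min_sig", default=3)
    if sel_min > sel_window:
        issues.append(f"selection.run_min_sig ({sel_min}) exceeds run_window ({sel_window})")
    if get("selection", "z_criterion", default=2.33) <= 0:
        issues.append("selection.z_criterion must be positive")
    if get("selection", "increasing_rule", default="mirrored") not in (
        "mirrored",
        "first_significant",
        "swapped",
    ):
        issues.append(
            "selection.increasing_rule must be 'mirrored', 'first_significant' or 'swapped'"
        )

    n_alt = get("quest", "n_alternatives", default=2)
    target = get("quest", "target_p", default=0.75)
    if n_alt < 2:
        issues.append("quest.n_alternatives must be at least 2")
    elif not (1.0 / n_alt < target < 1.0):
        issues.append(
            f"quest.target_p ({target}) must lie strictly between the guess "
            f"rate {1.0 / n_alt:g} and 1"
        )
    if get("quest", "n_trials", default=60) < 1:
        issues.append("quest.n_trials must be positive")

    srate = get("simulate", "srate", default=250.0)
    if srate < 100:
        issues.append(f"simulate.srate ({srate}) must be at least 100 Hz")
    target_srate = get("preprocess", "target_srate", default=250.0)
    if target_srate > srate:
        issues.append("preprocess.target_srate exceeds the simulated rate")
    if get("preprocess", "lowpass_hz", default=45.0) >= target_srate / 2:
        issues.append("preprocess.lowpass_hz must be below the post-downsampling Nyquist")
    if get("preprocess", "ptp_limit_uv", default=150.0) <= 0:
        issues.append("preprocess.ptp_limit_uv must be positive")

    if get("cohort", "n_participants", default=12) < 3:
        issues.append("cohort.n_participants must be at least 3 for the statistics")
    rho = get("cohort", "eeg_psy_correlation", default=0.5)
    if not -1 <= rho <= 1:
        issues.append("cohort.eeg_psy_correlation must be in [-1, 1]")
    if get("simulate", "n_trials_per_direction", default=6) < 1:
        issues.append("simulate.n_trials_per_direction must be positive")
    for cond in get("simulate", "conditions", default=[]):
        if cond not in ("contrast", "spatial_frequency", "orientation"):
            issues.append(f"unknown condition {cond!r}")
    return issues
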