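"""End-to-end orchestration: simulate → preprocess → spectral → thresholds → stats.

A run simulates a cohort of participants.  Each participant contributes:

* EEG: six increasing and six decreasing sweep trials per condition,
  with a per-participant true threshold drawn around the population
  value; the Sig- and Reg-method thresholds per direction become the two
  EEG "repetitions" (test-retest pairing between directions by default);
* behaviour: two QUEST sessions per condition against a simulated
  observer whose sensitivity is latently correlated with the same
  participant's EEG threshold.

Outputs are plain CSV plus a provenance record; rerunning with the same
config reproduces them bit-identically.  Per-stage seeds are derived
from the master seed through numpy's SeedSequence spawn keys, so any
stage can be rerun in isolation.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import config_hash, default_config, validate_config
from .design import Condition, Direction, make_sweep_design
from .montage import montage_labels
from .preprocess import (
    detrend_lowpass,
    downsample,
    epoch,
    interpolate_channels,
    reject_epochs,
    rereference,
)
from .quest import Observer, SessionConfig, run_session
from .simulate import NoiseModel, default_response_model, simulate_sweep_recording
from .spectral import SpectrumConfig, build_spectral_table, pooled_periodogram
from .stats import battery_frame, correlation_battery
from .thresholds import SelectionConfig, reg_threshold, sig_threshold

__all__ = ["run_pipeline", "derive_seed", "preprocess_recording", "select_electrode_pooled"]

#: Psychophysics working-unit scale per condition: work = sign·log10(native).
#: Spatial frequency is negated so that larger working values are easier.
_PSY_SIGN = {
    Condition.CONTRAST: 1.0,
    Condition.SPATIAL_FREQUENCY: -1.0,
    Condition.ORIENTATION: 1.0,
}
_PSY_BASE_ALPHA = {  # population-mean observer threshold, working units
    Condition.CONTRAST: np.log10(0.4),
    Condition.SPATIAL_FREQUENCY: -np.log10(30.0),
    Condition.ORIENTATION: np.log10(0.5),
}
_PSY_BOUNDS = {
    Condition.CONTRAST: (-3.0, 2.0),
    Condition.SPATIAL_FREQUENCY: (-4.0, 1.0),
    Condition.ORIENTATION: (-3.0, 2.0),
}
_PSY_MIN_TESTABLE = {Condition.ORIENTATION: np.log10(0.25)}


def derive_seed(master: int, *key: int) -> int:
    """Stable per-stage seed below 2**31."""
    ss = np.random.SeedSequence(int(master), spawn_key=tuple(int(k) for k in key))
    return int(ss.generate_state(1)[0] % (2**31))


def preprocess_recording(rec, designs, pre_cfg: dict):
    """The standard chain on one recording; returns the clean EpochSet."""
    target = float(pre_cfg.get("target_srate", 250.0))
    if target < rec.srate:
        rec = downsample(rec, target)
    rec = detrend_lowpass(rec, float(pre_cfg.get("lowpass_hz", 45.0)))
    eps = epoch(rec, designs)
    eps = reject_epochs(eps, float(pre_cfg.get("ptp_limit_uv", 150.0)))
    bad = list(pre_cfg.get("bad_channels", []))
    if bad:
        eps = interpolate_channels(eps, bad)
    return rereference(eps, pre_cfg.get("reference", "occipital_mean"))


def select_electrode_pooled(tables: dict, designs: dict, cfg: SelectionConfig) -> str:
    """One analysis electrode per condition: highest mean easy-half z
    pooled over the increasing and decreasing tables."""
    from .thresholds import SelectionError, _easy_mask

    scores: dict[str, list[float]] = {}
    label_order: list[str] = []
    for direction, table in tables.items():
        design = designs[direction]
        easy = set(np.flatnonzero(_easy_mask(design, cfg)))
        sel = table[table.step_index.isin(easy)]
        for lab in dict.fromkeys(table.electrode):
            if lab not in label_order:
                label_order.append(lab)
            z = sel.loc[sel.electrode == lab, "z"].to_numpy(dtype=float)
            z = z[np.isfinite(z)]
            if z.size:
                scores.setdefault(lab, []).append(float(z.mean()))
    best, best_score = None, -np.inf
    for lab in label_order:
        if lab in scores:
            score = float(np.mean(scores[lab]))
            if score > best_score:
                best, best_score = lab, score
    if best is None:
        raise SelectionError("z undefined for every electrode in both directions")
    return best


def _participant_eeg(cfg, pid, latents, out_rows, thr_rows, periodogram_sink):
    sim = cfg["simulate"]
    montage = sim["montage"]
    labels = montage_labels(montage) if isinstance(montage, str) else tuple(montage)
    noise = NoiseModel(**sim.get("noise", {}))
    sel_cfg = SelectionConfig(
        z_criterion=cfg["selection"]["z_criterion"],
        run_window=cfg["selection"]["run_window"],
        run_min_sig=cfg["selection"]["run_min_sig"],
        reg_snr_onset=cfg["selection"]["reg_snr_onset"],
        increasing_rule=cfg["selection"]["increasing_rule"],
    )
    spec_cfg = SpectrumConfig(**cfg["spectrum"])
    between_sd = float(cfg["cohort"]["between_sd"])

    for ci, cond_name in enumerate(sim["conditions"]):
        cond = Condition(cond_name)
        base = default_response_model(cond)
        # multiplicative participant spread in native units
        true_threshold = float(
            base.true_threshold * 10.0 ** (between_sd * latents[(pid, cond, "eeg")])
        )
        response = default_response_model(cond, true_threshold=true_threshold)

        designs, tables = {}, {}
        for di, direction in enumerate((Direction.INCREASING, Direction.DECREASING)):
            design = make_sweep_design(cond, direction)
            rec = simulate_sweep_recording(
                design,
                response,
                noise,
                montage=labels,
                srate=float(sim["srate"]),
                seed=derive_seed(cfg["seed"], 1, pid, ci, di),
                n_trials=int(sim["n_trials_per_direction"]),
            )
            eps = preprocess_recording(rec, {(cond, direction): design}, cfg["preprocess"])
            tables[direction] = build_spectral_table(eps, spec_cfg)
            designs[direction] = design
            if periodogram_sink is not None and cond is Condition.CONTRAST:
                periodogram_sink.append(pooled_periodogram(eps))

        electrode = select_electrode_pooled(tables, designs, sel_cfg)
        for rep, direction in ((1, Direction.INCREASING), (2, Direction.DECREASING)):
            table = tables[direction]
            design = designs[direction]
            rows = table[(table.electrode == electrode)]
            z = (
                rows.sort_values("step_index")
                .set_index("step_index")
                .z.reindex(range(design.n_steps))
                .to_numpy(dtype=float)
            )
            from .thresholds import significance_mask

            sig = sig_threshold(
                significance_mask(z, sel_cfg.z_criterion), design, sel_cfg, electrode
            )
            reg = reg_threshold(rows, design, sel_cfg, electrode)
            for res in (sig, reg):
                thr_rows.append(
                    dict(
                        participant=pid,
                        condition=cond.value,
                        method=res.method,
                        direction=direction.value,
                        electrode=electrode,
                        step_index=res.step_index,
                        threshold_value=res.threshold_value,
                        valid=res.valid,
                        reason=res.diagnostics.get("reason", ""),
                        true_threshold=true_threshold,
                    )
                )
            out_rows.append(
                dict(
                    participant=pid,
                    method="eeg",
                    test=cond.value,
                    repetition=rep,
                    score=sig.threshold_value if sig.valid else np.nan,
                    valid=bool(sig.valid),
                )
            )


def _participant_behaviour(cfg, pid, latents, out_rows):
    qcfg = cfg["quest"]
    between_sd = float(cfg["cohort"]["between_sd"])
    for ci, cond_name in enumerate(cfg["simulate"]["conditions"]):
        cond = Condition(cond_name)
        alpha = _PSY_BASE_ALPHA[cond] + _PSY_SIGN[cond] * between_sd * latents[
            (pid, cond, "psy")
        ]
        observer = Observer(
            alpha=float(alpha),
            beta=float(qcfg.get("observer_beta", 0.15)),
            gamma=1.0 / int(qcfg["n_alternatives"]),
        )
        session = SessionConfig(
            n_trials=int(qcfg["n_trials"]),
            target_p=float(qcfg["target_p"]),
            n_alternatives=int(qcfg["n_alternatives"]),
            level_bounds=_PSY_BOUNDS[cond],
            min_testable=_PSY_MIN_TESTABLE.get(cond),
            assumed_beta=float(qcfg.get("assumed_beta", 0.3)),
        )
        for rep in (1, 2):
            est, _ = run_session(
                observer,
                session,
                seed=derive_seed(cfg["seed"], 2, pid, ci, rep),
                prior_mean=float(_PSY_BASE_ALPHA[cond]),
                prior_sd=float(qcfg.get("prior_sd", 0.5)),
            )
            sign = _PSY_SIGN[cond]
            score = float(10.0 ** (sign * est)) if sign < 0 else float(10.0**est)
            out_rows.append(
                dict(
                    participant=pid,
                    method="psychophysics",
                    test=cond.value,
                    repetition=rep,
                    score=score,
                    valid=True,
                )
            )


def run_pipeline(cfg: dict | None = None, out_dir: str | Path | None = None) -> Path:
    """Execute the full pipeline; returns the run directory."""
    if cfg is None:
        cfg = default_config()
    issues = validate_config(cfg)
    if issues:
        raise ValueError("invalid config:\n" + "\n".join(f"- {s}" for s in issues))
    out = Path(out_dir if out_dir is not None else cfg["out_dir"])
    out.mkdir(parents=True, exist_ok=True)

    n = int(cfg["cohort"]["n_participants"])
    rho = float(cfg["cohort"]["eeg_psy_correlation"])
    conditions = [Condition(c) for c in cfg["simulate"]["conditions"]]

    rng = np.random.default_rng(derive_seed(cfg["seed"], 0))
    latents = {}
    for pid in range(1, n + 1):
        for cond in conditions:
            u = rng.standard_normal()
            v = rng.standard_normal()
            latents[(pid, cond, "eeg")] = u
            latents[(pid, cond, "psy")] = rho * u + np.sqrt(max(0.0, 1 - rho**2)) * v

    score_rows: list[dict] = []
    thr_rows: list[dict] = []
    periodograms: list[pd.DataFrame] = []
    for pid in range(1, n + 1):
        sink = periodograms if pid == 1 else None
        _participant_eeg(cfg, pid, latents, score_rows, thr_rows, sink)
        _participant_behaviour(cfg, pid, latents, score_rows)

    scores = pd.DataFrame(score_rows)
    thresholds = pd.DataFrame(thr_rows)
    scores.to_csv(out / "scores.csv", index=False)
    thresholds.to_csv(out / "thresholds.csv", index=False)
    if periodograms:
        mean_pg = periodograms[0].copy()
        mean_pg["power"] = np.mean([p.power.to_numpy() for p in periodograms], axis=0)
        mean_pg.to_csv(out / "periodogram_contrast_p1.csv", index=False)

    reports = correlation_battery(scores)
    battery_frame(reports).to_csv(out / "battery.csv", index=False)

    provenance = {
        "config_hash": config_hash(cfg),
        "seed": int(cfg["seed"]),
        "version": __version__,
        "n_participants": n,
    }
    (out / "provenance.json").write_text(json.dumps(provenance, indent=1))
    (out / "config_used.yaml").write_text(
        __import__("yaml").safe_dump(cfg, sort_keys=True)
    )
    return out
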