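"""Electrode selection and sweep threshold rules.

Two rules extract a threshold from the per-step spectral quantities at a
single analysis electrode:

Sig method
    A step is *significant* when its noise-normalized z exceeds 2.33
    (one-sided p ≈ 0.01).  For a sweep whose perceptual intensity
    decreases over time, the threshold is the last non-significant step
    that has at least three significant steps among the four immediately
    preceding it.  For increasing-intensity sweeps the default rule is
    the exact time-mirror: the first non-significant step with at least
    three significant steps among the four that follow, which makes the
    two sweep directions agree exactly on clean data.

Reg method
    Ordinary least squares of raw 20 Hz amplitude against the condition's
    fit axis (log % contrast, linear cycles/degree, log degrees tilt),
    fitted from the first amplitude peak with SNR ≥ 3 down to where the
    amplitude drops below the noise floor; the threshold is the zero
    crossing of the fitted line, valid only if the slope declines toward
    harder stimuli and the phase behaves (constant or gradually leading
    for contrast, lagging for spatial frequency, constant for tilt).

The analysis electrode is the one with the highest mean z over the
easiest half of tested intensities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import (
    Condition,
    Direction,
    StimulusSweep,
    easiness,
    intensity_increasing,
)

__all__ = [
    "SelectionConfig",
    "ThresholdResult",
    "select_electrode",
    "significance_mask",
    "sig_threshold",
    "reg_threshold",
    "phase_check",
    "combine_directions",
    "SelectionError",
]


class SelectionError(ValueError):
    """No electrode can be selected (all z undefined)."""


#: Easiest-half stimulus ranges per condition (native units, inclusive).
EASY_HALF_RANGES: dict[Condition, tuple[float, float]] = {
    Condition.CONTRAST: (2.05, 30.0),
    Condition.SPATIAL_FREQUENCY: (2.7, 11.2),
    Condition.ORIENTATION: (0.34, 4.96),
}


@dataclass(frozen=True)
class SelectionConfig:
    z_criterion: float = 2.33
    easy_half: dict = field(default_factory=lambda: dict(EASY_HALF_RANGES))
    run_window: int = 4
    run_min_sig: int = 3
    reg_snr_onset: float = 3.0
    phase_tolerance: float = np.pi / 4
    increasing_rule: str = "mirrored"  # or "first_significant" / "swapped"

    def __post_init__(self) -> None:
        if self.run_min_sig > self.run_window:
            raise ValueError("run_min_sig cannot exceed run_window")
        if self.z_criterion <= 0:
            raise ValueError("z criterion must be positive")


@dataclass(frozen=True)
class ThresholdResult:
    method: str  # "sig" | "reg"
    condition: Condition
    direction: Direction
    electrode: str | None
    step_index: int | None
    threshold_value: float | None
    valid: bool
    diagnostics: dict = field(default_factory=dict)


def _easy_mask(design: StimulusSweep, cfg: SelectionConfig, rel_tol: float = 0.02):
    lo, hi = cfg.easy_half[Condition(design.condition)]
    vals = np.asarray(design.step_values)
    return (vals >= lo * (1 - rel_tol)) & (vals <= hi * (1 + rel_tol))


def select_electrode(
    table: pd.DataFrame, design: StimulusSweep, cfg: SelectionConfig = SelectionConfig()
) -> str:
    """Electrode with the highest mean z over the easiest half of steps.

    Ties break toward the earlier electrode in the table's label order.
    """
    cond = Condition(design.condition).value
    dirn = Direction(design.direction).value
    sel = table[(table.condition == cond) & (table.direction == dirn)]
    if sel.empty:
        raise SelectionError(f"no spectral rows for {cond}/{dirn}")
    easy_steps = set(np.flatnonzero(_easy_mask(design, cfg)))
    sel = sel[sel.step_index.isin(easy_steps)]
    labels = list(dict.fromkeys(table.electrode))
    best_label, best_score = None, -np.inf
    for lab in labels:
        z = sel.loc[sel.electrode == lab, "z"].to_numpy(dtype=float)
        z = z[np.isfinite(z)]
        if z.size == 0:
            continue
        score = z.mean()
        if score > best_score:
            best_label, best_score = lab, score
    if best_label is None:
        raise SelectionError("z undefined for every candidate electrode")
    return best_label


def significance_mask(z_by_step, criterion: float = 2.33) -> np.ndarray:
    """Strict z > criterion per step; undefined (NaN) counts as not significant."""
    z = np.asarray(z_by_step, dtype=float)
    return np.where(np.isfinite(z), z > criterion, False)


def _run_candidates(mask: np.ndarray, window: int, min_count: int, target: bool):
    """Steps equal to ``not target`` ... see sig_threshold.

    Candidates are indices ``t`` where ``mask[t] != target`` and at least
    ``min_count`` of the up-to-``window`` preceding steps equal ``target``.
    """
    out = []
    for t in range(len(mask)):
        if bool(mask[t]) == target:
            continue
        prev = mask[max(0, t - window) : t]
        if int(np.sum(prev == target)) >= min_count:
            out.append(t)
    return out


def sig_threshold(
    mask,
    design: StimulusSweep,
    cfg: SelectionConfig = SelectionConfig(),
    electrode: str | None = None,
) -> ThresholdResult:
    """Run-rule threshold from the per-step significance mask.

    The mask is in sweep-time order.  Intensity direction is derived from
    the design (note a *decreasing*-intensity sweep is e.g. contrast
    decreasing or spatial frequency increasing).
    """
    mask = np.asarray(mask, dtype=bool)
    if len(mask) != design.n_steps:
        raise ValueError(
            f"mask length {len(mask)} != design steps {design.n_steps}"
        )
    inc = intensity_increasing(design)
    diag = {"mask": mask.tolist(), "intensity_increasing": inc}
    if not inc:
        # Intensity fades: last non-significant step preceded by >=3/4 significant.
        cands = _run_candidates(mask, cfg.run_window, cfg.run_min_sig, target=True)
        pick = cands[-1] if cands else None
    elif cfg.increasing_rule == "mirrored":
        # Exact time-reversal of the fading rule: run it on the reversed
        # mask and map the pick back.  Equivalently: the FIRST
        # non-significant step with >=3/4 significant among the four
        # *following* steps.  This is the only reading that makes the two
        # sweep directions agree exactly on clean data.
        rev = _run_candidates(mask[::-1], cfg.run_window, cfg.run_min_sig, target=True)
        cands = [len(mask) - 1 - t for t in reversed(rev)]
        pick = cands[0] if cands else None
    elif cfg.increasing_rule == "first_significant":
        # Looser mirror: first significant step preceded by >=3/4 non-significant.
        cands = _run_candidates(~mask, cfg.run_window, cfg.run_min_sig, target=True)
        pick = cands[0] if cands else None
    elif cfg.increasing_rule == "swapped":
        # Literal reading with only the sig/non-sig roles swapped:
        # last significant step with >=3/4 non-significant preceding.
        cands = _run_candidates(mask, cfg.run_window, cfg.run_min_sig, target=False)
        pick = cands[-1] if cands else None
    else:
        raise ValueError(f"unknown increasing_rule {cfg.increasing_rule!r}")
    diag["candidates"] = cands
    if pick is None:
        return ThresholdResult(
            "sig", design.condition, design.direction, electrode, None, None, False, diag
        )
    return ThresholdResult(
        "sig",
        design.condition,
        design.direction,
        electrode,
        int(pick),
        float(design.step_values[pick]),
        True,
        diag,
    )


def phase_check(phases_in_window, condition, tolerance: float = np.pi / 4) -> bool:
    """Validity check on the fit window's phases.

    Phases are unwrapped first.  "Constant": every phase within
    ``tolerance`` of the window mean.  Contrast additionally accepts a
    gradually *leading* phase (per-step increments in [0, tolerance]);
    spatial frequency accepts a gradually *lagging* one (increments in
    [−tolerance, 0]); orientation accepts only the constant case.
    """
    condition = Condition(condition)
    phi = np.unwrap(np.asarray(phases_in_window, dtype=float))
    if phi.size == 0:
        return False
    constant = bool(np.max(np.abs(phi - phi.mean())) <= tolerance)
    if phi.size < 2:
        return constant
    inc = np.diff(phi)
    if condition is Condition.CONTRAST:
        return constant or bool(np.all((inc >= 0) & (inc <= tolerance)))
    if condition is Condition.SPATIAL_FREQUENCY:
        return constant or bool(np.all((inc <= 0) & (inc >= -tolerance)))
    return constant


def _fit_axis(condition: Condition, values: np.ndarray) -> np.ndarray:
    """Regression axis: log10 % contrast, linear cpd, log10 degrees."""
    if condition is Condition.SPATIAL_FREQUENCY:
        return values.astype(float)
    return np.log10(values)


def _axis_to_native(condition: Condition, x: float) -> float:
    if condition is Condition.SPATIAL_FREQUENCY:
        return float(x)
    return float(10.0**x)


def reg_threshold(
    rows: pd.DataFrame,
    design: StimulusSweep,
    cfg: SelectionConfig = SelectionConfig(),
    electrode: str | None = None,
) -> ThresholdResult:
    """Linear-extrapolation threshold for one electrode's spectral rows.

    ``rows`` must contain step_index, amp, noise_mean, snr, phase for one
    (condition, direction, electrode).
    """
    condition = Condition(design.condition)
    rows = rows.sort_values("step_index")
    steps = rows.step_index.to_numpy()
    values = np.asarray(design.step_values)[steps]
    ease = easiness(condition, values)
    order = np.argsort(-ease, kind="stable")  # easy -> hard
    amp = rows.amp.to_numpy(dtype=float)[order]
    nmean = rows.noise_mean.to_numpy(dtype=float)[order]
    snr = rows.snr.to_numpy(dtype=float)[order]
    phase = rows.phase.to_numpy(dtype=float)[order]
    axis = _fit_axis(condition, values)[order]
    step_ids = steps[order]

    def invalid(reason):
        return ThresholdResult(
            "reg",
            condition,
            design.direction,
            electrode,
            None,
            None,
            False,
            {"reason": reason},
        )

    n = len(amp)
    if n < 2 or not np.all(np.isfinite(amp)):
        return invalid("insufficient-or-nonfinite-amplitudes")

    # Onset: first local maximum (plateau counts, leftmost) with SNR >= 3.
    onset = None
    for i in range(n):
        left_ok = i == 0 or amp[i] >= amp[i - 1]
        right_ok = i == n - 1 or amp[i] >= amp[i + 1]
        if left_ok and right_ok and np.isfinite(snr[i]) and snr[i] >= cfg.reg_snr_onset:
            onset = i
            break
    if onset is None:
        return invalid("no-onset")

    # Offset: the fit ends where the curve drops below the noise floor
    # (that step is already outside the responsive regime and is not part
    # of the declining segment), else at the last step.
    offset = n - 1
    for j in range(onset + 1, n):
        if amp[j] < nmean[j]:
            offset = j - 1
            break
    window = slice(onset, offset + 1)
    x = axis[window]
    y = amp[window]
    if len(x) < 2 or np.ptp(x) == 0:
        return invalid("window-too-small")
    slope, intercept = np.polyfit(x, y, 1)
    if not np.isfinite(slope) or slope == 0:
        return invalid("degenerate-fit")

    # The fitted line must decline toward harder stimuli.
    hard_sign = np.sign(x[-1] - x[0])  # axis direction of increasing difficulty
    if slope * hard_sign >= 0:
        return invalid("slope-wrong-sign")
    x0 = -intercept / slope
    # Zero crossing must lie on the hard side of the fit onset.
    if not np.isfinite(x0) or (x0 - x[0]) * hard_sign <= 0:
        return invalid("crossing-on-wrong-side")
    # Phase validity is judged where there is a response to carry a phase:
    # window steps with SNR >= the onset criterion.  Near and below the
    # noise floor the measured phase is that of the noise.
    resp = np.isfinite(snr[window]) & (snr[window] >= cfg.reg_snr_onset)
    phases = phase[window][resp] if resp.any() else phase[window]
    if not phase_check(phases, condition, cfg.phase_tolerance):
        return invalid("phase-check-failed")

    threshold = _axis_to_native(condition, x0)
    diag = {
        "onset_step": int(step_ids[onset]),
        "offset_step": int(step_ids[offset]),
        "slope": float(slope),
        "intercept": float(intercept),
        "axis_zero": float(x0),
        "phase_ok": True,
    }
    return ThresholdResult(
        "reg", condition, design.direction, electrode, None, threshold, True, diag
    )


@dataclass(frozen=True)
class CombinedScore:
    value: float
    n_valid: int
    flagged: bool


def combine_directions(
    inc: ThresholdResult, dec: ThresholdResult, condition=None
) -> CombinedScore:
    """Average the two sweep directions on the condition's spacing scale.

    Geometric mean in native units for contrast and orientation (log
    spacing), arithmetic mean for spatial frequency.  A single valid
    input passes through flagged; both invalid raises ValueError.
    """
    condition = Condition(condition or inc.condition)
    valids = [r for r in (inc, dec) if r.valid and r.threshold_value is not None]
    if not valids:
        raise ValueError("both directions invalid; no combined score")
    vals = np.array([r.threshold_value for r in valids], dtype=float)
    if condition is Condition.SPATIAL_FREQUENCY:
        score = float(vals.mean())
    else:
        score = float(np.exp(np.mean(np.log(vals))))
    return CombinedScore(value=score, n_valid=len(valids), flagged=len(valids) < 2)
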