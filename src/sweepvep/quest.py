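"""Bayesian adaptive staircase (QUEST) and psychometric fitting.

An observer's probability of a correct response at stimulus level x is a
cumulative Gaussian with a guessing floor and lapse ceiling:

    p(x) = gamma + (1 - gamma - lambda) * Phi((x - alpha) / beta)

where gamma is 1/n_alternatives for a forced-choice task and alpha is the
threshold — the function's steepest point, which for a lapse-free 2AFC
observer sits at 75 % correct and for 4AFC at 62.5 %.  The staircase
maintains a posterior over candidate thresholds on a discrete grid,
places each trial at the posterior mean (clipped to bounds and to the
minimum testable level), and reports the final posterior mean.

Levels are in whatever working units the caller chooses — typically
log10 stimulus units so that the Gaussian spread is scale-free.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from scipy.stats import norm

__all__ = [
    "Observer",
    "SessionConfig",
    "QuestState",
    "quest_init",
    "quest_update",
    "quest_next",
    "run_session",
    "simulate_observer_response",
    "fit_psychometric",
    "PsychometricFitError",
]


class PsychometricFitError(RuntimeError):
    """Degenerate data: the cumulative-Gaussian MLE is unidentified."""


@dataclass(frozen=True)
class Observer:
    """Cumulative-Gaussian observer."""

    alpha: float  # threshold location (steepest point), working units
    beta: float  # spread of the cumulative Gaussian
    gamma: float = 0.5  # guess rate: 0.5 for 2AFC, 0.25 for 4AFC
    lapse: float = 0.0

    def __post_init__(self) -> None:
        if not (0 <= self.gamma < 1):
            raise ValueError("gamma must be in [0, 1)")
        if not (0 <= self.lapse < 0.5):
            raise ValueError("lapse must be in [0, 0.5)")
        if self.beta <= 0:
            raise ValueError("beta must be positive")

    def p_correct(self, level):
        return psychometric(level, self.alpha, self.beta, self.gamma, self.lapse)


def psychometric(level, alpha, beta, gamma, lapse):
    phi = norm.cdf((np.asarray(level, dtype=float) - alpha) / beta)
    return gamma + (1.0 - gamma - lapse) * phi


@dataclass(frozen=True)
class SessionConfig:
    n_trials: int = 60
    target_p: float = 0.75
    n_alternatives: int = 2
    level_bounds: tuple[float, float] = (-3.0, 3.0)
    initial_level: float | None = None
    min_testable: float | None = None
    grid_size: int = 201
    assumed_beta: float = 0.3
    assumed_lapse: float = 0.0

    @property
    def gamma(self) -> float:
        return 1.0 / self.n_alternatives

    def __post_init__(self) -> None:
        if not (self.gamma < self.target_p < 1 - self.assumed_lapse):
            raise ValueError(
                f"target_p {self.target_p} must lie strictly between the guess "
                f"rate {self.gamma} and 1 - lapse"
            )
        if self.level_bounds[0] >= self.level_bounds[1]:
            raise ValueError("level_bounds must be increasing")


@dataclass
class QuestState:
    grid: np.ndarray
    log_posterior: np.ndarray
    cfg: SessionConfig
    history: list = field(default_factory=list)

    @property
    def posterior(self) -> np.ndarray:
        p = np.exp(self.log_posterior - self.log_posterior.max())
        return p / p.sum()

    @property
    def mean(self) -> float:
        return float(np.sum(self.grid * self.posterior))


def quest_init(cfg: SessionConfig, prior_mean: float, prior_sd: float) -> QuestState:
    """Gaussian prior over the candidate-threshold grid.

    The grid spans ``cfg.level_bounds`` and must cover prior_mean ± 4 SD;
    a grid that truncates the prior that hard is a configuration error.
    """
    if prior_sd <= 0:
        raise ValueError("prior_sd must be positive")
    lo, hi = cfg.level_bounds
    if cfg.grid_size < 3 or lo >= hi:
        raise ValueError("degenerate grid")
    if prior_mean - 4 * prior_sd < lo or prior_mean + 4 * prior_sd > hi:
        raise ValueError(
            "grid does not cover prior_mean ± 4 SD; widen level_bounds or "
            "tighten the prior"
        )
    grid = np.linspace(lo, hi, cfg.grid_size)
    logp = -0.5 * ((grid - prior_mean) / prior_sd) ** 2
    logp -= np.log(np.sum(np.exp(logp - logp.max()))) + logp.max()
    return QuestState(grid=grid, log_posterior=logp, cfg=cfg)


def quest_update(state: QuestState, level: float, correct: bool) -> QuestState:
    """Bayes update of the posterior after one trial."""
    cfg = state.cfg
    p = psychometric(level, state.grid, cfg.assumed_beta, cfg.gamma, cfg.assumed_lapse)
    like = p if correct else 1.0 - p
    logp = state.log_posterior + np.log(np.maximum(like, 1e-300))
    logp -= np.log(np.sum(np.exp(logp - logp.max()))) + logp.max()
    return QuestState(
        grid=state.grid,
        log_posterior=logp,
        cfg=cfg,
        history=state.history + [(float(level), bool(correct))],
    )


def quest_next(state: QuestState) -> float:
    """Next test level: posterior-mean threshold shifted to the target point.

    For the canonical designs (75 % 2AFC, 62.5 % 4AFC with no lapse) the
    target sits exactly at the threshold, so the shift is zero.  The
    result is clipped to the level bounds and the minimum testable level.
    """
    cfg = state.cfg
    shift = cfg.assumed_beta * norm.ppf(
        (cfg.target_p - cfg.gamma) / (1.0 - cfg.gamma - cfg.assumed_lapse)
    )
    level = state.mean + float(shift)
    lo, hi = state.cfg.level_bounds
    level = float(np.clip(level, lo, hi))
    if state.cfg.min_testable is not None:
        level = max(level, state.cfg.min_testable)
    return level


def simulate_observer_response(
    observer: Observer, level: float, rng: np.random.Generator
) -> bool:
    """One Bernoulli trial at ``level``."""
    if not np.isfinite(level):
        raise ValueError("level must be finite")
    return bool(rng.random() < observer.p_correct(level))


def run_session(
    observer: Observer,
    cfg: SessionConfig,
    seed: int | None = None,
    prior_mean: float | None = None,
    prior_sd: float = 0.5,
):
    """Run one adaptive session; returns (threshold_estimate, trial_log).

    The trial log is a list of (level, correct) pairs; the estimate is
    the final posterior mean in working units.
    """
    if abs(observer.gamma - cfg.gamma) > 1e-9:
        raise ValueError(
            f"observer guess rate {observer.gamma} inconsistent with "
            f"{cfg.n_alternatives}-AFC"
        )
    rng = np.random.default_rng(seed)
    if prior_mean is None:
        prior_mean = cfg.initial_level
    if prior_mean is None:
        prior_mean = 0.5 * (cfg.level_bounds[0] + cfg.level_bounds[1])
    state = quest_init(cfg, prior_mean, prior_sd)
    if cfg.initial_level is not None:
        level = float(cfg.initial_level)
    else:
        level = quest_next(state)
    for _ in range(cfg.n_trials):
        correct = simulate_observer_response(observer, level, rng)
        state = quest_update(state, level, correct)
        level = quest_next(state)
    return state.mean, state.history


def fit_psychometric(levels, responses, gamma: float, lapse: float = 0.0):
    """Maximum-likelihood cumulative-Gaussian fit with fixed gamma, lapse.

    Returns (alpha, beta).  alpha is the threshold: the steepest point,
    where p = gamma + (1 - gamma - lapse)/2 (0.75 for lapse-free 2AFC).
    """
    x = np.asarray(levels, dtype=float)
    y = np.asarray(responses, dtype=bool)
    if x.shape != y.shape or x.size < 2:
        raise PsychometricFitError("need paired levels/responses, at least two")
    if np.unique(x).size < 2:
        raise PsychometricFitError("need at least two distinct levels")
    if y.all() or (~y).all():
        raise PsychometricFitError("both response outcomes must be present")

    def nll(params):
        alpha, log_beta = params
        p = psychometric(x, alpha, np.exp(log_beta), gamma, lapse)
        p = np.clip(p, 1e-9, 1 - 1e-9)
        return -np.sum(np.where(y, np.log(p), np.log(1.0 - p)))

    alpha0 = float(np.median(x))
    beta0 = max(float(np.std(x)), 1e-3)
    res = optimize.minimize(
        nll, [alpha0, np.log(beta0)], method="Nelder-Mead",
        options={"xatol": 1e-7, "fatol": 1e-10, "maxiter": 2000},
    )
    if not res.success and res.status != 2:  # status 2: maxiter, still usable
        raise PsychometricFitError(f"fit failed: {res.message}")
    alpha, log_beta = res.x
    return float(alpha), float(np.exp(log_beta))
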