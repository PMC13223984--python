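"""Reliability and correlation battery.

The battery reproduces a standard individual-differences workflow for
threshold scores measured twice per participant by two methods:

* pairwise outlier removal by the modified z-score of absolute score
  differences, Zdiff = 0.6745·(diff − median(diff)) / MAD, excluding
  Zdiff > 3;
* test-retest reliability as ICC(3,1) — two-way mixed effects,
  consistency, single measure — between the two repetitions;
* Spearman rank correlations between tests (within a method) and between
  methods (per test), on repetition-averaged scores;
* Cohen's interpretation bands (0.1 / 0.3 / 0.5 → small / medium / large).

p values are reported unadjusted.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations, permutations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .design import Condition

__all__ = [
    "zdiff_outliers",
    "icc31",
    "spearman",
    "aggregate_scores",
    "correlation_battery",
    "interpret_cohen",
    "CorrelationReport",
]

ZDIFF_CONSTANT = 0.6745
ZDIFF_CUTOFF = 3.0


@dataclass(frozen=True)
class CorrelationReport:
    pair: str
    kind: str  # "icc" or "spearman"
    coefficient: float
    p_value: float
    n: int
    interpretation: str
    excluded: tuple = ()
    note: str = ""

    def as_dict(self) -> dict:
        d = dict(
            pair=self.pair,
            kind=self.kind,
            coefficient=self.coefficient,
            p_value=self.p_value,
            n=self.n,
            interpretation=self.interpretation,
            excluded=";".join(str(e) for e in self.excluded),
            note=self.note,
        )
        return d


def zdiff_outliers(a, b):
    """Modified-z outlier mask on absolute pairwise differences.

    Returns ``(keep_mask, zdiff)``.  With MAD = 0 (all differences equal)
    no exclusion is possible; a warning is emitted and everything is kept.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("score vectors must be aligned")
    diff = np.abs(a - b)
    med = np.median(diff)
    mad = np.median(np.abs(diff - med))
    if mad == 0:
        warnings.warn("MAD of score differences is zero; no outliers excluded")
        return np.ones_like(diff, dtype=bool), np.zeros_like(diff)
    z = ZDIFF_CONSTANT * (diff - med) / mad
    return z <= ZDIFF_CUTOFF, z


def icc31(x, y):
    """ICC(3,1): two-way mixed effects, consistency, single measure.

    From the two-way ANOVA decomposition with k = 2 raters/occasions:
    r = (MSR − MSE) / (MSR + (k−1)·MSE); the p value comes from
    F = MSR/MSE with (n−1, (n−1)(k−1)) degrees of freedom.
    Returns ``(r, p, n)``; r and p are NaN when the between-subject
    variance is zero.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired score vectors must be aligned")
    data = np.column_stack([x, y])
    n, k = data.shape
    if n < 3:
        raise ValueError("need at least three paired observations")
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((data - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    if msr <= 0:
        warnings.warn("zero between-subject variance; ICC undefined")
        return float("nan"), float("nan"), n
    r = (msr - mse) / (msr + (k - 1) * mse)
    if mse == 0:
        return 1.0, 0.0, n
    f = msr / mse
    p = float(sps.f.sf(f, n - 1, (n - 1) * (k - 1)))
    return float(r), p, n


def _rank(v: np.ndarray) -> np.ndarray:
    return sps.rankdata(v, method="average")


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    denom = math.sqrt((xc @ xc) * (yc @ yc))
    return float(xc @ yc / denom) if denom > 0 else float("nan")


def spearman(x, y):
    """Spearman rank correlation: Pearson of mid-ranks.

    p value: exact two-sided permutation test for n ≤ 9, otherwise the
    t approximation t = rho·sqrt((n−2)/(1−rho²)).  Returns (rho, p, n).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired vectors must be aligned")
    n = x.size
    if n < 3:
        raise ValueError("need at least three pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("constant vector; Spearman undefined")
        return float("nan"), float("nan"), n
    rx, ry = _rank(x), _rank(y)
    rho = _pearson(rx, ry)
    if n <= 9:
        perms = np.array(list(permutations(ry)), dtype=float)
        pc = perms - perms.mean(axis=1, keepdims=True)
        rxc = rx - rx.mean()
        denom = np.sqrt((rxc @ rxc) * np.sum(pc * pc, axis=1))
        rhos = (pc @ rxc) / denom
        p = float(np.mean(np.abs(rhos) >= abs(rho) - 1e-12))
    else:
        if abs(rho) >= 1.0:
            p = 0.0
        else:
            t = rho * math.sqrt((n - 2) / (1.0 - rho**2))
            p = 2.0 * float(sps.t.sf(abs(t), n - 2))
    return float(rho), float(p), n


def interpret_cohen(r: float) -> str:
    """Cohen's bands for correlation magnitude (0.1 / 0.3 / 0.5)."""
    r = abs(r)
    if r >= 0.5:
        return "large"
    if r >= 0.3:
        return "medium"
    return "small"


def _combine_reps(values: np.ndarray, test: str) -> float:
    """Repetition average on the test's spacing scale."""
    try:
        cond = Condition(test)
    except ValueError:
        cond = None
    if cond is Condition.SPATIAL_FREQUENCY or cond is None:
        return float(np.mean(values))
    if np.any(values <= 0):  # scores on an already-log or z scale
        return float(np.mean(values))
    return float(np.exp(np.mean(np.log(values))))


def aggregate_scores(table: pd.DataFrame, mode: str = "mean_of_repetitions") -> pd.DataFrame:
    """One score per participant, method, and test.

    Valid repetition scores are averaged on the condition's spacing scale
    (geometric for contrast/orientation when scores are positive,
    arithmetic otherwise).  Participants with no valid repetition for a
    test are dropped for that test; single-repetition aggregates are
    flagged in the ``n_reps`` column.
    """
    if mode not in ("mean_of_repetitions", "inc_dec_pairing"):
        raise ValueError(f"unknown aggregation mode {mode!r}")
    rows = []
    for (pid, method, test), grp in table.groupby(["participant", "method", "test"]):
        vals = grp.loc[grp.valid.astype(bool), "score"].to_numpy(dtype=float)
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            continue
        rows.append(
            dict(
                participant=pid,
                method=method,
                test=test,
                score=_combine_reps(vals, test),
                n_reps=int(vals.size),
            )
        )
    return pd.DataFrame(rows, columns=["participant", "method", "test", "score", "n_reps"])


def _paired(table: pd.DataFrame, sel_a: dict, sel_b: dict, value="score"):
    """Align two selections by participant; returns (ids, a, b)."""

    def pick(sel):
        sub = table
        for col, val in sel.items():
            sub = sub[sub[col] == val]
        return sub.set_index("participant")[value]

    a = pick(sel_a)
    b = pick(sel_b)
    ids = sorted(set(a.index) & set(b.index))
    return (
        np.asarray(ids),
        a.loc[ids].to_numpy(dtype=float),
        b.loc[ids].to_numpy(dtype=float),
    )


def _report_pair(ids, a, b, pair: str, kind: str) -> CorrelationReport | None:
    keep, _ = zdiff_outliers(a, b)
    excluded = tuple(ids[~keep])
    a, b = a[keep], b[keep]
    if a.size < 3:
        return CorrelationReport(
            pair, kind, float("nan"), float("nan"), int(a.size), "", excluded,
            note="fewer than 3 pairs after exclusions",
        )
    if kind == "icc":
        r, p, n = icc31(a, b)
    else:
        r, p, n = spearman(a, b)
    return CorrelationReport(
        pair, kind, r, p, n, interpret_cohen(r) if np.isfinite(r) else "", excluded
    )


def correlation_battery(scores: pd.DataFrame) -> list[CorrelationReport]:
    """Full battery on a long-format score table.

    Per method and test: ICC(3,1) between repetitions 1 and 2 (after
    pairwise Zdiff exclusion).  Within each method: Spearman between each
    test pair on repetition-averaged scores.  Between methods: Spearman
    per test.  Pairs with fewer than three participants after exclusion
    are reported with a note and NaN coefficient.
    """
    reports: list[CorrelationReport] = []
    methods = list(dict.fromkeys(scores.method))
    tests = list(dict.fromkeys(scores.test))
    valid = scores[scores.valid.astype(bool)]

    for method in methods:
        for test in tests:
            ids, a, b = _paired(
                valid,
                dict(method=method, test=test, repetition=1),
                dict(method=method, test=test, repetition=2),
            )
            if ids.size:
                reports.append(_report_pair(ids, a, b, f"{method}:{test} retest", "icc"))

    agg = aggregate_scores(valid)
    for method in methods:
        for t1, t2 in combinations(tests, 2):
            ids, a, b = _paired(
                agg, dict(method=method, test=t1), dict(method=method, test=t2)
            )
            if ids.size:
                reports.append(
                    _report_pair(ids, a, b, f"{method}: {t1} vs {t2}", "spearman")
                )
    if len(methods) >= 2:
        for m1, m2 in combinations(methods, 2):
            for test in tests:
                ids, a, b = _paired(
                    agg, dict(method=m1, test=test), dict(method=m2, test=test)
                )
                if ids.size:
                    reports.append(
                        _report_pair(ids, a, b, f"{m1} vs {m2}: {test}", "spearman")
                    )
    return reports


def battery_frame(reports) -> pd.DataFrame:
    return pd.DataFrame([r.as_dict() for r in reports])
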