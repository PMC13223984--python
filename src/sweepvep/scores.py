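"""Synthetic threshold score tables with controlled reliability structure.

Scores are generated from a latent-variable model: each participant has a
vector of true test scores drawn from a multivariate normal whose
correlation matrix encodes the requested between-test associations, and
each repetition adds independent occasion noise scaled so that the
expected test-retest ICC(3,1) hits its target:

    ICC = var(true) / (var(true) + var(noise))  =>  sd_noise = sqrt((1-ICC)/ICC)

Because rank correlations of bivariate normals are attenuated relative to
the Pearson parameter (Spearman = 6/pi * arcsin(rho/2)) and repetition
averaging only partially cancels occasion noise, the latent Pearson
correlations are inflated by both factors so that the *observed*
between-test Spearman of repetition-averaged scores matches the target.
An infeasible request (the inflated matrix is no longer positive
definite, or a required correlation exceeds 1) raises StructureError.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["make_score_table", "StructureError", "SCORE_COLUMNS"]

SCORE_COLUMNS = ["participant", "method", "test", "repetition", "score", "valid"]

DEFAULT_TESTS = ("contrast", "spatial_frequency", "orientation")


class StructureError(ValueError):
    """Requested reliability/correlation structure is not realizable."""


def _spearman_to_pearson(rho_s: np.ndarray) -> np.ndarray:
    return 2.0 * np.sin(np.pi * np.asarray(rho_s, dtype=float) / 6.0)


def make_score_table(
    n_participants: int,
    n_tests: int = 3,
    icc_targets=0.7,
    rho_targets=0.0,
    seed: int | None = None,
    n_repetitions: int = 2,
    test_names=None,
    method: str = "psychophysics",
) -> pd.DataFrame:
    """Long-format score table (participant, method, test, repetition, score).

    Parameters
    ----------
    icc_targets
        Scalar or per-test sequence of target test-retest ICC(3,1) values
        in (0, 1].
    rho_targets
        Scalar (common off-diagonal) or full n_tests × n_tests matrix of
        target between-test Spearman correlations of repetition-averaged
        scores, in [-1, 1].
    """
    if n_participants < 2:
        raise ValueError("need at least two participants")
    icc = np.broadcast_to(np.asarray(icc_targets, dtype=float), (n_tests,)).copy()
    if np.any((icc <= 0) | (icc > 1)):
        raise StructureError("ICC targets must lie in (0, 1]")
    rho = np.asarray(rho_targets, dtype=float)
    if rho.ndim == 0:
        mat = np.full((n_tests, n_tests), float(rho))
        np.fill_diagonal(mat, 1.0)
        rho = mat
    if rho.shape != (n_tests, n_tests):
        raise StructureError(f"rho_targets must be scalar or {n_tests}x{n_tests}")
    if np.any(np.abs(rho) > 1) or not np.allclose(rho, rho.T):
        raise StructureError("rho targets must form a symmetric matrix in [-1, 1]")

    noise_sd = np.sqrt((1.0 - icc) / icc)
    # Inflate the latent Pearson correlations for rank attenuation and
    # residual occasion noise in the repetition means.
    atten = np.sqrt(1.0 + noise_sd**2 / n_repetitions)
    latent = _spearman_to_pearson(rho) * np.outer(atten, atten)
    np.fill_diagonal(latent, 1.0)
    if np.any(np.abs(latent) > 1):
        raise StructureError(
            "requested between-test correlations are unreachable at the "
            "requested reliabilities"
        )
    try:
        chol = np.linalg.cholesky(latent)
    except np.linalg.LinAlgError as exc:
        raise StructureError("latent correlation matrix is not positive definite") from exc

    rng = np.random.default_rng(seed)
    true_scores = rng.standard_normal((n_participants, n_tests)) @ chol.T
    names = list(test_names) if test_names is not None else list(DEFAULT_TESTS)[:n_tests]
    if len(names) != n_tests:
        names = [f"test{i + 1}" for i in range(n_tests)]
    records = []
    for rep in range(1, n_repetitions + 1):
        noise = rng.standard_normal((n_participants, n_tests)) * noise_sd
        obs = true_scores + noise
        for p in range(n_participants):
            for t in range(n_tests):
                records.append(
                    dict(
                        participant=p + 1,
                        method=method,
                        test=names[t],
                        repetition=rep,
                        score=float(obs[p, t]),
                        valid=True,
                    )
                )
    return pd.DataFrame.from_records(records, columns=SCORE_COLUMNS)
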