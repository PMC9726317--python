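"""Maximum-likelihood logistic regression by Newton-Raphson.

Hand-rolled rather than delegated so that the convergence and divergence
contracts (score-norm tolerance, separation detection) are explicit and
testable against closed-form and grid-search oracles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

SCORE_TOL = 1e-8
LOGLIK_RELTOL = 1e-10
MAX_ITER = 100
#: any |coefficient| beyond this during iteration is treated as divergence
#: from complete or quasi-complete separation
DIVERGENCE_BOUND = 15.0


class SeparationError(ValueError):
    """Raised when the MLE diverges (complete/quasi-complete separation)."""


class RankDeficientError(ValueError):
    """Raised when the design matrix is not full column rank."""


@dataclass(frozen=True)
class FittedLogistic:
    """ML estimates with Wald standard errors.

    ``coef`` holds the intercept first, then one entry per design column.
    Standard errors come from the inverse observed information at the
    optimum.
    """

    coef: np.ndarray
    se: np.ndarray
    loglik: float
    converged: bool
    n_iter: int

    def __post_init__(self) -> None:
        if self.coef.shape != self.se.shape:
            raise ValueError("coef and se lengths disagree")
        if self.loglik > 1e-12:
            raise ValueError("log-likelihood of a Bernoulli model cannot be positive")


def _log_likelihood(eta: np.ndarray, y: np.ndarray) -> float:
    # log L = sum(y*eta - log(1 + exp(eta))), stable via logaddexp
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def fit_logistic_ml(
    design: np.ndarray,
    outcome: np.ndarray,
    add_intercept: bool = True,
) -> FittedLogistic:
    """Fit a logistic regression by Newton-Raphson with step halving.

    Parameters
    ----------
    design:
        (n, p) matrix of covariates.  A leading column of ones is prepended
        unless ``add_intercept`` is False.
    outcome:
        length-n 0/1 vector.

    Raises
    ------
    ValueError
        Constant outcome or shape mismatch.
    RankDeficientError
        Design (with intercept) not of full column rank.
    SeparationError
        Iterates diverge, indicating (quasi-)complete separation.
    """
    X = np.asarray(design, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(outcome, dtype=float).ravel()
    if X.shape[0] != y.size:
        raise ValueError("design and outcome lengths disagree")
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("outcome must be 0/1")
    if y.min() == y.max():
        raise ValueError("outcome is constant; logistic model is undefined")
    if add_intercept:
        X = np.column_stack([np.ones(X.shape[0]), X])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise RankDeficientError("design matrix is rank deficient")

    beta = np.zeros(X.shape[1])
    eta = X @ beta
    loglik = _log_likelihood(eta, y)
    converged = False
    iteration = 0
    for iteration in range(1, MAX_ITER + 1):
        p = 1.0 / (1.0 + np.exp(-eta))
        score = X.T @ (y - p)
        w = p * (1.0 - p)
        hessian = X.T @ (w[:, None] * X)
        try:
            step = np.linalg.solve(hessian, score)
        except np.linalg.LinAlgError as exc:
            raise SeparationError(
                "information matrix singular during iteration (separation)"
            ) from exc
        # step halving keeps the likelihood monotone
        new_loglik = -np.inf
        for _ in range(30):
            candidate = beta + step
            new_eta = X @ candidate
            new_loglik = _log_likelihood(new_eta, y)
            if new_loglik >= loglik - 1e-12:
                break
            step = step / 2.0
        beta = beta + step
        eta = X @ beta
        if np.max(np.abs(beta)) > DIVERGENCE_BOUND:
            raise SeparationError(
                "coefficient magnitude exceeded "
                f"{DIVERGENCE_BOUND}; data are (quasi-)completely separated"
            )
        delta = new_loglik - loglik
        loglik = new_loglik
        if np.max(np.abs(score)) < SCORE_TOL or abs(delta) < LOGLIK_RELTOL * (
            abs(loglik) + 1.0
        ):
            converged = True
            break

    p = 1.0 / (1.0 + np.exp(-eta))
    w = p * (1.0 - p)
    hessian = X.T @ (w[:, None] * X)
    covariance = np.linalg.inv(hessian)
    se = np.sqrt(np.diag(covariance))
    return FittedLogistic(
        coef=beta, se=se, loglik=loglik, converged=converged, n_iter=iteration
    )
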