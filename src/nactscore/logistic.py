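"""Maximum-likelihood logistic regression by iteratively reweighted least
squares, with Wald inference.

This is deliberately a small, fast, dependency-light fitter: the association
analyses fit many thousands of small logistic models (Monte-Carlo recovery
and coverage studies, exhaustive 2x2 validation grids), where the per-call
overhead of a full GLM framework dominates.  Convergence is declared when
the maximum absolute score (gradient) falls below 1e-8 or the relative
log-likelihood change falls below 1e-10; the Wald covariance is the inverse
observed information at the MLE.  Agreement with an independent GLM
implementation is verified in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit
from scipy.stats import norm

from .errors import (
    ConvergenceError,
    DegenerateOutcomeError,
    RankDeficientError,
    SeparationError,
)

GRADIENT_TOL = 1e-8
RELATIVE_LL_TOL = 1e-10
MAX_ITER = 100
_MAX_ABS_ETA = 30.0  # |linear predictor| beyond this signals separation
_COND_LIMIT = 1e12


@dataclass
class LogisticFit:
    """MLE of a logistic regression: coefficients, Wald covariance, fit info."""

    params: np.ndarray
    cov: np.ndarray
    loglik: float
    converged: bool
    n_iter: int
    names: list[str] | None = None

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov))

    def wald_summary(self, ci_level: float = 0.95) -> dict[str, np.ndarray]:
        """Odds ratios, Wald confidence limits and two-sided p per coefficient."""
        zcrit = norm.ppf(0.5 + ci_level / 2.0)
        se = self.se
        zstat = self.params / se
        # a quasi-separated nuisance dummy (e.g. a zero-event cohort) has a
        # huge coefficient; its CI overflowing to inf is honest, not an error
        with np.errstate(over="ignore"):
            return self._summary(zcrit, se, zstat)

    def _summary(self, zcrit, se, zstat) -> dict[str, np.ndarray]:
        return {
            "coef": self.params,
            "se": se,
            "or": np.exp(self.params),
            "ci_low": np.exp(self.params - zcrit * se),
            "ci_high": np.exp(self.params + zcrit * se),
            "p": 2.0 * norm.sf(np.abs(zstat)),
        }


def _loglik(y: np.ndarray, eta: np.ndarray, w: np.ndarray) -> float:
    # numerically stable: log(1+exp(eta)) via logaddexp
    return float(np.sum(w * (y * eta - np.logaddexp(0.0, eta))))


def fit_logistic(
    y: np.ndarray,
    X: np.ndarray,
    freq_weights: np.ndarray | None = None,
    names: list[str] | None = None,
    max_iter: int = MAX_ITER,
) -> LogisticFit:
    """Fit y ~ X by IRLS.

    Parameters
    ----------
    y:
        Binary outcome vector (0/1).
    X:
        Design matrix including the intercept column.
    freq_weights:
        Optional frequency weights (counts); lets aggregated data, e.g. a
        2x2 table expressed as 4 rows, be fitted exactly.

    Raises
    ------
    DegenerateOutcomeError
        if the outcome is constant.
    RankDeficientError
        if the (weighted) design is numerically rank deficient.
    SeparationError
        if the linear predictor diverges (perfect separation: no MLE).
    ConvergenceError
        if IRLS does not converge within ``max_iter`` iterations.
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("X must be 2-D with one row per outcome")
    w = (
        np.ones_like(y)
        if freq_weights is None
        else np.asarray(freq_weights, dtype=float).ravel()
    )
    ybar = float(np.sum(w * y) / np.sum(w))
    if ybar <= 0.0 or ybar >= 1.0:
        raise DegenerateOutcomeError(
            "degenerate outcome: all observations are in one class"
        )

    p = X.shape[1]
    beta = np.zeros(p)
    if np.all(X[:, 0] == 1.0):  # warm-start the intercept at the marginal log-odds
        beta[0] = np.log(ybar / (1.0 - ybar))
    ll = _loglik(y, X @ beta, w)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = X @ beta
        if np.max(np.abs(eta)) > _MAX_ABS_ETA:
            raise SeparationError(
                "perfect separation detected: linear predictor diverging "
                f"(max |eta| = {np.max(np.abs(eta)):.1f}); the MLE does not exist"
            )
        mu = expit(eta)
        grad = X.T @ (w * (y - mu))
        wt = w * mu * (1.0 - mu)
        info = X.T @ (X * wt[:, None])
        if it == 1 and np.linalg.cond(info) > _COND_LIMIT:
            raise RankDeficientError("design matrix is numerically rank deficient")
        try:
            if p == 2:  # closed-form 2x2 solve; avoids LAPACK overhead in
                # the many small fits of the Monte-Carlo studies
                det = info[0, 0] * info[1, 1] - info[0, 1] * info[1, 0]
                if det <= 0 or not np.isfinite(det):
                    raise RankDeficientError("singular information matrix")
                step = np.array(
                    [
                        (info[1, 1] * grad[0] - info[0, 1] * grad[1]) / det,
                        (info[0, 0] * grad[1] - info[1, 0] * grad[0]) / det,
                    ]
                )
            else:
                step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError as exc:
            raise RankDeficientError(f"singular information matrix: {exc}") from exc
        # step-halving guards against Newton overshoot on near-degenerate
        # tables (a decreasing log-likelihood is never accepted)
        ll_new = _loglik(y, X @ (beta + step), w)
        halvings = 0
        while ll_new < ll and halvings < 30:
            step = step / 2.0
            ll_new = _loglik(y, X @ (beta + step), w)
            halvings += 1
        beta = beta + step
        if np.max(np.abs(grad)) < GRADIENT_TOL:
            converged = True
            break
        if abs(ll_new - ll) < RELATIVE_LL_TOL * (abs(ll) + 1e-300):
            converged = True
            ll = ll_new
            break
        ll = ll_new
    else:
        raise ConvergenceError(f"IRLS did not converge in {max_iter} iterations")

    # one extra Newton step past the stopping rule: quadratic convergence
    # polishes the estimate to near machine precision at negligible cost
    eta = X @ beta
    mu = expit(eta)
    grad = X.T @ (w * (y - mu))
    wt = w * mu * (1.0 - mu)
    info = X.T @ (X * wt[:, None])
    try:
        beta = beta + np.linalg.solve(info, grad)
    except np.linalg.LinAlgError:  # pragma: no cover - caught earlier in loop
        pass
    eta = X @ beta
    mu = expit(eta)
    wt = w * mu * (1.0 - mu)
    info = X.T @ (X * wt[:, None])
    cov = np.linalg.inv(info)
    return LogisticFit(
        params=beta,
        cov=cov,
        loglik=_loglik(y, eta, w),
        converged=converged,
        n_iter=it,
        names=list(names) if names is not None else None,
    )
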