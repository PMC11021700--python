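"""Weighted logistic regression by Newton-Raphson, plus restricted cubic splines.

The inverse-probability-weighting pipeline refits its selection, treatment,
censoring and pooled-logistic hazard models inside a person-level bootstrap
(hundreds of refits per effect estimate), so the fitting engine is a lean
numpy/scipy Newton solver with warm starts and optional aggregated
(grouped-binomial) responses. Point estimates agree with a standard GLM fit
to near machine precision; the test suite cross-checks against statsmodels.

Responses may be fractional (grouped proportions) when paired with case
weights, which makes collapsing person-month tables over identical covariate
patterns exact for maximum likelihood.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.special import expit


class ConvergenceError(RuntimeError):
    """Newton iterations failed to converge; message carries the trace."""


@dataclass
class LogitFit:
    coef: np.ndarray          #: coefficients, same order as design columns
    llf: float                #: weighted log-likelihood at the optimum
    aic: float                #: 2k - 2 llf
    n_iter: int
    cov: np.ndarray | None = None  #: inverse observed information

    def predict(self, X: np.ndarray) -> np.ndarray:
        return expit(X @ self.coef)


def _loglik_eta(y, eta, w):
    # y*eta - log(1 + e^eta), numerically stable for large |eta|
    return float(np.sum(w * (y * eta - np.logaddexp(0.0, eta))))


def fit_logistic(X: np.ndarray, y: np.ndarray, weights: np.ndarray | None = None,
                 start: np.ndarray | None = None, tol: float = 1e-9,
                 max_iter: int = 60, compute_cov: bool = False,
                 line_search: bool = True) -> LogitFit:
    """Maximise the weighted Bernoulli/binomial log-likelihood.

    Parameters
    ----------
    X : (n, k) design matrix including any intercept column.
    y : response in [0, 1]; fractional values are grouped proportions.
    weights : non-negative case weights (group sizes or IP weights).
    start : warm-start coefficients (e.g. the full-sample fit inside a
        bootstrap loop); defaults to zeros.
    tol : step-size convergence threshold (also scales the relative
        log-likelihood stopping rule); bootstrap replicates may loosen it.
    line_search : with ``False``, runs plain damped IRLS without
        log-likelihood evaluations (``llf``/``aic`` are then NaN) — meant
        for warm-started bootstrap refits where the saved evaluations
        matter and the start point is already near the optimum.
    """
    # single precision is honoured (bootstrap refits at loose tolerance);
    # everything else runs in double
    dt = np.float32 if (hasattr(X, "dtype") and X.dtype == np.float32
                        and not line_search) else np.float64
    X = np.asarray(X, dtype=dt)
    y = np.asarray(y, dtype=dt)
    n, k = X.shape
    w = np.ones(n, dtype=dt) if weights is None else np.asarray(weights, dtype=dt)
    beta = np.zeros(k, dtype=dt) if start is None else \
        np.asarray(start, dtype=dt).copy()

    eta = X @ beta
    ll = _loglik_eta(y, eta, w) if line_search else np.nan
    trace = [ll]
    for it in range(1, max_iter + 1):
        p = expit(eta)
        grad = X.T @ (w * (y - p))
        wgt = w * p * (1.0 - p)
        H = (X * wgt[:, None]).T @ X
        try:
            step = cho_solve(cho_factor(H), grad)
        except np.linalg.LinAlgError:
            step = cho_solve(cho_factor(H + 1e-8 * np.eye(k)), grad)
        if line_search:
            # step-halving on the log-likelihood
            scale = 1.0
            for _ in range(30):
                cand = beta + scale * step
                eta_new = X @ cand
                ll_new = _loglik_eta(y, eta_new, w)
                if ll_new >= ll - 1e-12:
                    break
                scale *= 0.5
            beta, eta, ll_prev, ll = cand, eta_new, ll, ll_new
            trace.append(ll)
            if np.max(np.abs(scale * step)) < tol or \
                    abs(ll - ll_prev) < 0.1 * tol * (abs(ll) + 1.0):
                break
        else:
            # damped IRLS: cap very large steps instead of searching
            mx = np.max(np.abs(step))
            if mx > 4.0:
                step *= 4.0 / mx
            beta = beta + step
            eta = X @ beta
            if mx < tol or it >= 4:
                # warm-started damped Newton is near-quadratic, so two
                # passes reach well past the step tolerance except under
                # quasi-separation, where the likelihood is flat and any
                # finite damped solution is acceptable for a bootstrap
                # replicate
                break
    else:
        raise ConvergenceError(
            f"logistic fit did not converge in {max_iter} iterations; "
            f"log-likelihood trace: {[round(t, 4) for t in trace[-6:]]}")

    cov = None
    if compute_cov:
        p = expit(eta)
        wgt = w * p * (1.0 - p)
        H = (X * wgt[:, None]).T @ X
        cov = np.linalg.inv(H)
    return LogitFit(coef=beta, llf=ll, aic=2.0 * k - 2.0 * ll if line_search else np.nan,
                    n_iter=it, cov=cov)


def rcs_basis(x: np.ndarray, knots: np.ndarray) -> np.ndarray:
    """Restricted cubic spline basis (natural spline, linear in the tails).

    With k knots returns k-2 columns; callers add the linear term themselves.
    Standard truncated-power construction normalised by the outer knot span.
    """
    x = np.asarray(x, dtype=np.float64)
    t = np.asarray(knots, dtype=np.float64)
    k = t.size
    if k < 3:
        return np.empty((x.size, 0))
    span2 = (t[-1] - t[0]) ** 2

    def cube(u):
        return np.clip(u, 0.0, None) ** 3

    cols = []
    for j in range(k - 2):
        term = (cube(x - t[j])
                - cube(x - t[k - 2]) * (t[k - 1] - t[j]) / (t[k - 1] - t[k - 2])
                + cube(x - t[k - 1]) * (t[k - 2] - t[j]) / (t[k - 1] - t[k - 2]))
        cols.append(term / span2)
    return np.column_stack(cols)


def default_knots(x: np.ndarray, quantiles=(0.05, 0.35, 0.65, 0.95)) -> np.ndarray:
    """Knot placement at the conventional four quantiles; collapses duplicate
    knots away (degenerate for near-constant covariates)."""
    q = np.quantile(np.asarray(x, dtype=np.float64), quantiles)
    return np.unique(q)
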