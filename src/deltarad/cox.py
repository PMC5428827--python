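"""Cox proportional-hazards fitting via Newton-Raphson on the partial likelihood.

Breslow tie handling throughout. This solver is deliberately small and
vectorized: the leave-one-out stepwise-AIC model search refits thousands of
small models per cohort, which rules out heavier general-purpose fitters in
the inner loop (lifelines is used as an independent cross-check in the test
suite, never in the hot path).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

_MAX_ITER = 60
_TOL = 1e-9
#: coefficient magnitude beyond which the partial likelihood is treated as
#: monotone (perfect separation) and the fit flagged divergent; a genuine
#: log-hazard ratio of this size is not plausible on standardized covariates
_DIVERGE = 15.0


class CoxError(RuntimeError):
    pass


@dataclass
class CoxFit:
    """A fitted Cox model: coefficients, log partial likelihood, AIC."""

    covariates: tuple
    coef: np.ndarray
    loglik: float
    null_loglik: float
    converged: bool
    diverged: bool = False
    n: int = 0
    n_events: int = 0
    meta: dict = field(default_factory=dict)

    @property
    def aic(self) -> float:
        return -2.0 * self.loglik + 2.0 * len(self.coef)

    def lrt_vs_null(self) -> float:
        """Likelihood-ratio p-value of this model against the empty model."""
        if len(self.coef) == 0:
            return 1.0
        stat = max(0.0, 2.0 * (self.loglik - self.null_loglik))
        return float(stats.chi2.sf(stat, df=len(self.coef)))

    def predict(self, X) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if len(self.coef) == 0:
            return np.zeros(X.shape[0])
        return X @ self.coef


def _prepare(time, event):
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=bool)
    order = np.argsort(-time, kind="stable")  # descending time
    t = time[order]
    # tie-group ends: risk set for an event at t_i = all with time >= t_i,
    # i.e. the descending-order prefix through the last index tied with t_i
    _, inv = np.unique(-t, return_inverse=True)
    ends = np.cumsum(np.bincount(inv)) - 1
    group_end = ends[inv]
    return order, t, event[order], group_end


def _loglik_grad_hess(X, d, group_end, beta, want_derivs=True):
    eta = X @ beta
    eta = eta - eta.max()  # guard exp overflow; constant cancels in ratios
    w = np.exp(eta)
    cw = np.cumsum(w)
    S0 = cw[group_end]
    with np.errstate(divide="ignore"):  # S0 underflow -> ll = -inf, rejected by step halving
        ll = float((eta[d] - np.log(S0[d])).sum())
    if not want_derivs:
        return ll, None, None
    wX = w[:, None] * X
    cwX = np.cumsum(wX, axis=0)
    S1 = cwX[group_end]
    m = S1 / S0[:, None]
    grad = (X[d] - m[d]).sum(axis=0)
    wXX = np.einsum("i,ij,ik->ijk", w, X, X)
    S2 = np.cumsum(wXX, axis=0)[group_end]
    V = S2 / S0[:, None, None] - np.einsum("ij,ik->ijk", m, m)
    hess = -V[d].sum(axis=0)
    return ll, grad, hess


class PreparedCox:
    """Pre-sorted survival data for many fits over column subsets of one X.

    Sorting, tie-grouping and the null log-likelihood are computed once; each
    `fit(col_idx)` then runs pure Newton-Raphson. This is what makes the
    stepwise-inside-LOOCV search affordable.
    """

    def __init__(self, X, time, event):
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        order, t, d, group_end = _prepare(time, event)
        if not d.any():
            raise CoxError("no events")
        self.Xs = X[order]
        self.d = d
        self.group_end = group_end
        self.n = X.shape[0]
        self.n_events = int(d.sum())
        self.null_loglik, _, _ = _loglik_grad_hess(
            self.Xs[:, :0], d, group_end, np.zeros(0), want_derivs=False
        )

    def fit(self, col_idx, covariates=None, beta0=None) -> CoxFit:
        col_idx = list(col_idx)
        names = tuple(covariates) if covariates is not None else tuple(col_idx)
        return _newton_fit(self.Xs[:, col_idx], self.d, self.group_end,
                           self.null_loglik, names, self.n, self.n_events, beta0)


def _newton_fit(Xs, d, group_end, ll0, names, n, n_events, beta0=None) -> CoxFit:
    p = Xs.shape[1]
    if p == 0:
        return CoxFit(names, np.zeros(0), ll0, ll0, True, False, n, n_events)
    beta = np.zeros(p) if beta0 is None else np.asarray(beta0, dtype=float).copy()
    ll = ll0
    converged = False
    for _ in range(_MAX_ITER):
        ll_cur, grad, hess = _loglik_grad_hess(Xs, d, group_end, beta)
        try:
            step = np.linalg.solve(-hess + 1e-10 * np.eye(p), grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(-hess, grad, rcond=None)[0]
        # step halving
        new_beta, new_ll = beta, ll_cur
        scale = 1.0
        for _ in range(30):
            cand = beta + scale * step
            ll_cand, _, _ = _loglik_grad_hess(Xs, d, group_end, cand, want_derivs=False)
            if np.isfinite(ll_cand) and ll_cand >= ll_cur - 1e-12:
                new_beta, new_ll = cand, ll_cand
                break
            scale *= 0.5
        if np.abs(new_beta - beta).max() < _TOL or abs(new_ll - ll_cur) < _TOL * (abs(ll_cur) + 1):
            beta, ll = new_beta, new_ll
            converged = True
            break
        beta, ll = new_beta, new_ll
    diverged = bool(np.abs(beta).max() > _DIVERGE)
    return CoxFit(names, beta, ll, ll0, converged, diverged, n, n_events)


def fit_cox(X, time, event, covariates=None) -> CoxFit:
    """Fit a Cox model by Newton-Raphson with step halving (Breslow ties).

    X may have zero columns (the null model). Monotone-likelihood divergence
    (runaway coefficients) is flagged rather than raised.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    prep = PreparedCox(X, time, event)
    names = tuple(covariates) if covariates is not None else tuple(range(X.shape[1]))
    return prep.fit(range(X.shape[1]), covariates=names)


def cox_lrt_pvalue(x, time, event) -> float:
    """Univariate likelihood-ratio screen p-value; degenerate inputs give 1."""
    x = np.asarray(x, dtype=float)
    if np.nanstd(x) == 0 or not np.isfinite(x).all():
        return 1.0
    fit = fit_cox(x[:, None], time, event)
    if fit.diverged or not fit.converged:
        return 1.0
    return fit.lrt_vs_null()
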