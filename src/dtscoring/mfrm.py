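"""Many-Facet Rasch Model for polytomous ratings.

Decomposes the category-step predictor into person trait, task
difficulty, rater severity, and shared category thresholds:
``P(X = k) ∝ exp( sum_{v<=k} (theta - delta_t - lambda_j - tau_v) )``.
The Rasch slope is fixed at 1, so the trait SD ``sigma`` is estimated;
rater severities and thresholds are identified by sum-to-zero
constraints, and task difficulties by the zero-mean trait prior.
Estimated by marginal maximum likelihood on a quadrature grid.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import logsumexp
from sklearn.base import BaseEstimator

from .rating_data import RatingTable, WideMatrix, to_wide

_TINY = 1e-300


def mfrm_category_probs(theta, rater_severity: float, task_difficulty: float,
                        thresholds) -> np.ndarray:
    """Category probabilities 1..K at given trait values.

    ``thresholds`` are the K-1 shared category step parameters tau_2..
    tau_K.  Increasing the rater's severity by c is equivalent to
    lowering every trait value by c.
    """
    theta = np.asarray(theta, dtype=float)
    tau = np.asarray(thresholds, dtype=float)
    eta = theta - task_difficulty - rater_severity
    steps = eta[..., None] - tau
    s = np.concatenate([np.zeros(theta.shape + (1,)), np.cumsum(steps, axis=-1)], axis=-1)
    s -= s.max(axis=-1, keepdims=True)
    e = np.exp(s)
    return e / e.sum(axis=-1, keepdims=True)


class ManyFacetRaschModel(BaseEstimator):
    """MFRM with person, rater, and task facets, fit by marginal ML.

    ``fit(X, tasks)`` takes a units x raters wide frame (NaN = missing)
    and the task id of each unit.

    Attributes
    ----------
    severities_ : pd.Series (sum-to-zero rater severities, lambda)
    task_difficulties_ : pd.Series (delta)
    thresholds_ : np.ndarray (sum-to-zero category steps, tau)
    theta_sd_ : float (estimated trait SD sigma)
    loglik_, n_params_, aic_, bic_, converged_, n_iter_ : fit summary
    """

    def __init__(self, K=5, n_quad=101, quad_range=(-6.0, 6.0), max_iter=500,
                 tol=1e-6):
        self.K = K
        self.n_quad = n_quad
        self.quad_range = quad_range
        self.max_iter = max_iter
        self.tol = tol

    def fit(self, X, tasks, y=None):
        if isinstance(X, WideMatrix):
            frame = X.values
        else:
            frame = pd.DataFrame(X)
        tasks = pd.Series(tasks, index=frame.index).astype(str)
        keep = []
        for rid in frame.columns:
            cats = frame[rid].dropna().unique()
            if len(cats) < 2:
                warnings.warn(f"rater {rid!r} has <2 observed categories; dropped")
                continue
            keep.append(rid)
        if len(keep) < 2:
            raise ValueError("need >= 2 identifiable raters")
        frame = frame[keep]
        informative = frame.notna().any(axis=1)
        frame, tasks = frame[informative], tasks[informative]
        raters = list(frame.columns)
        task_ids = sorted(tasks.unique())
        J, T, K = len(raters), len(task_ids), self.K
        Xv = frame.to_numpy(dtype=float)
        # collapse identical (task, response-pattern) rows for speed
        codes = np.column_stack([
            np.searchsorted(task_ids, tasks.to_numpy()),
            np.nan_to_num(Xv, nan=0.0).astype(int)])
        patterns, counts = np.unique(codes, axis=0, return_counts=True)
        Xu = np.where(patterns[:, 1:] == 0, np.nan, patterns[:, 1:]).astype(float)
        task_groups = {t: np.flatnonzero(patterns[:, 0] == t_idx)
                       for t_idx, t in enumerate(task_ids)}

        z = np.linspace(self.quad_range[0], self.quad_range[1], self.n_quad)
        w = np.exp(-0.5 * z ** 2)
        logw = np.log(w / w.sum())

        def unpack(x):
            lam = np.concatenate([x[:J - 1], [-np.sum(x[:J - 1])]])
            delta = x[J - 1:J - 1 + T]
            tau_free = x[J - 1 + T:J - 1 + T + K - 2]
            tau = np.concatenate([tau_free, [-np.sum(tau_free)]])
            sigma = np.exp(np.clip(x[-1], -5, 3))
            return lam, delta, tau, sigma

        cache = {}

        def nll(x):
            key = x.tobytes()
            if key in cache:
                return cache[key]
            lam, delta, tau, sigma = unpack(x)
            nodes = sigma * z
            L = np.zeros((Xu.shape[0], len(z)))
            for t_idx, t in enumerate(task_ids):
                rows = task_groups[t]
                if not len(rows):
                    continue
                for j in range(J):
                    col = Xu[rows, j]
                    obs = ~np.isnan(col)
                    if not obs.any():
                        continue
                    p = mfrm_category_probs(nodes, lam[j], delta[t_idx], tau)
                    logp = np.log(np.clip(p, _TINY, None))  # (Q, K)
                    cat = col[obs].astype(int) - 1
                    L[rows[obs]] += logp[:, cat].T
            ll = logsumexp(L + logw, axis=1)
            cache.clear()
            cache[key] = -float(counts @ np.maximum(ll, np.log(_TINY)))
            return cache[key]

        x0 = np.zeros((J - 1) + T + (K - 2) + 1)
        trace = [-nll(x0)]

        def cb(xk):
            trace.append(-nll(xk))

        res = minimize(nll, x0, method="L-BFGS-B", callback=cb,
                       options={"maxiter": self.max_iter, "ftol": self.tol * 1e-2})
        lam, delta, tau, sigma = unpack(res.x)
        self.severities_ = pd.Series(lam, index=raters, name="severity")
        self.task_difficulties_ = pd.Series(delta, index=task_ids, name="difficulty")
        self.thresholds_ = tau
        self.theta_sd_ = float(sigma)
        self.loglik_ = -float(res.fun)
        self.loglik_trace_ = trace
        self.n_iter_ = int(res.nit)
        self.converged_ = bool(res.success) and self.loglik_ >= trace[0] - 1e-4
        self.n_params_ = (J - 1) + T + (K - 2) + 1
        self.n_units_ = int(Xv.shape[0])
        self.aic_ = -2 * self.loglik_ + 2 * self.n_params_
        self.bic_ = -2 * self.loglik_ + self.n_params_ * np.log(max(self.n_units_, 1))
        return self


def fit_mfrm(table: RatingTable, **kwargs) -> ManyFacetRaschModel:
    """Fit the MFRM to a rating table, reading each unit's task facet."""
    wide = to_wide(table)
    tasks = wide.meta["task_id"].reindex(wide.values.index)
    model = ManyFacetRaschModel(K=table.K, **kwargs)
    return model.fit(wide.values, tasks)
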