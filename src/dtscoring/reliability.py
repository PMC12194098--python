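"""Internal-consistency coefficients for task-score indicators.

Cronbach's alpha, McDonald's omega and Hancock's H (the latter two from a
maximum-likelihood one-factor model), with seeded percentile-bootstrap
confidence intervals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from sklearn.base import BaseEstimator

_PSI_FLOOR = 1e-6


def cronbach_alpha(data) -> float:
    """alpha = k/(k-1) * (1 - sum item variances / total-score variance)."""
    X = np.asarray(pd.DataFrame(data).dropna(), dtype=float)
    k = X.shape[1]
    if k < 2:
        raise ValueError("alpha needs >= 2 indicator columns")
    total_var = X.sum(axis=1).var(ddof=1)
    if total_var <= 0:
        raise ValueError("zero total-score variance")
    return float(k / (k - 1) * (1.0 - X.var(axis=0, ddof=1).sum() / total_var))


def _ml_discrepancy(S, sigma):
    sign, logdet_sigma = np.linalg.slogdet(sigma)
    if sign <= 0:
        return np.inf
    _, logdet_s = np.linalg.slogdet(S)
    return float(logdet_sigma + np.trace(S @ np.linalg.inv(sigma)) - logdet_s - S.shape[0])


class OneFactorCFA(BaseEstimator):
    """Maximum-likelihood one-factor model (congeneric indicators).

    Fits ``Sigma = lambda lambda' + diag(psi)`` by minimizing the ML
    discrepancy ``F = log|Sigma| + tr(S Sigma^-1) - log|S| - k``.  The
    factor variance is fixed at 1, so the loadings are on the indicator
    scale.  Residual variances are floored at 1e-6 (Heywood guard, with a
    warning).

    Attributes: ``loadings_``, ``residuals_``, ``discrepancy_``,
    ``converged_``, ``n_obs_``, ``cov_``.
    """

    def __init__(self, max_iter=500):
        self.max_iter = max_iter

    def fit(self, X, y=None):
        X = pd.DataFrame(X).dropna()
        return self.fit_cov(np.cov(X.to_numpy(dtype=float), rowvar=False, ddof=1),
                            n_obs=len(X))

    def fit_cov(self, S, n_obs=None):
        """Fit directly from a covariance (or correlation) matrix."""
        S = np.asarray(S, dtype=float)
        k = S.shape[0]
        if k < 3:
            raise ValueError("one-factor model needs >= 3 indicators")
        diag = np.diag(S)
        # principal-axis start
        eva, eve = np.linalg.eigh(S)
        lam0 = eve[:, -1] * np.sqrt(max(eva[-1], 1e-3))
        if lam0.sum() < 0:
            lam0 = -lam0
        psi0 = np.clip(diag - lam0 ** 2, 0.1 * diag, None)
        x0 = np.concatenate([lam0, np.log(psi0)])
        bounds = [(None, None)] * k + [(np.log(_PSI_FLOOR), None)] * k

        def objective(x):
            lam = x[:k]
            psi = np.exp(x[k:])
            return _ml_discrepancy(S, np.outer(lam, lam) + np.diag(psi))

        res = minimize(objective, x0, method="L-BFGS-B", bounds=bounds,
                       options={"maxiter": self.max_iter, "ftol": 1e-14, "gtol": 1e-10})
        lam = res.x[:k]
        if lam.sum() < 0:
            lam = -lam
        psi = np.exp(res.x[k:])
        if np.any(psi <= _PSI_FLOOR * 1.01):
            warnings.warn("Heywood case: residual variance at its lower bound")
        self.loadings_ = lam
        self.residuals_ = psi
        self.discrepancy_ = float(res.fun)
        self.converged_ = bool(res.success)
        self.n_obs_ = n_obs
        self.cov_ = S
        return self


def omega(fit: OneFactorCFA) -> float:
    """McDonald's omega: (sum lambda)^2 / ((sum lambda)^2 + sum psi)."""
    s = fit.loadings_.sum()
    return float(s ** 2 / (s ** 2 + fit.residuals_.sum()))


def hancock_h(fit: OneFactorCFA) -> float:
    """Hancock's H on standardized loadings: maximal construct reliability."""
    sd = np.sqrt(fit.loadings_ ** 2 + fit.residuals_)
    lam = fit.loadings_ / sd
    psi = np.clip(1.0 - lam ** 2, _PSI_FLOOR, None)
    ratio = (lam ** 2 / psi).sum()
    return float(ratio / (1.0 + ratio))


@dataclass
class ReliabilityReport:
    """Point estimates and bootstrap CIs for one indicator set."""

    alpha: float
    omega: float
    hancock_h: float
    ci: dict  # name -> (low, high)


def bootstrap_ci(statistic, data, B: int = 1000, seed: int = 0, level: float = 0.95):
    """Seeded percentile bootstrap CI over row resamples.

    A resample on which the statistic fails is redrawn (up to 10 tries)
    and the failure logged as a warning.
    """
    if B < 100:
        raise ValueError("B must be >= 100")
    df = pd.DataFrame(data).dropna()
    n = len(df)
    rng = np.random.default_rng(seed)
    vals = np.empty(B)
    for b in range(B):
        for attempt in range(10):
            idx = rng.integers(0, n, size=n)
            try:
                vals[b] = statistic(df.iloc[idx])
                break
            except Exception as exc:  # noqa: BLE001 - redraw is the contract
                if attempt == 9:
                    raise
                warnings.warn(f"bootstrap resample failed ({exc}); redrawn")
    lo = (1 - level) / 2
    return float(np.quantile(vals, lo)), float(np.quantile(vals, 1 - lo))


def reliability_report(data, B: int = 1000, seed: int = 0) -> ReliabilityReport:
    """alpha, omega and H with percentile-bootstrap 95% CIs."""
    df = pd.DataFrame(data).dropna()

    def w(frame):
        return omega(OneFactorCFA().fit(frame))

    def h(frame):
        return hancock_h(OneFactorCFA().fit(frame))

    fit = OneFactorCFA().fit(df)
    ci = {"alpha": bootstrap_ci(cronbach_alpha, df, B, seed),
          "omega": bootstrap_ci(w, df, B, seed + 1),
          "hancock_h": bootstrap_ci(h, df, B, seed + 2)}
    return ReliabilityReport(cronbach_alpha(df), omega(fit), hancock_h(fit), ci)
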