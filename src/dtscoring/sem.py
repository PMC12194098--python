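"""Two-factor latent models for the originality-fluency confound.

Each factor loads on three task-level indicators (one per task); the two
factors are standardized (variance 1, free loadings) so their covariance
IS the latent correlation, and same-task indicator pairs get a free
residual covariance because an originality score and a fluency count from
the same task share task-specific variance.  Estimation is maximum
likelihood on the sample covariance (listwise complete rows).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from sklearn.base import BaseEstimator

from .reliability import _ml_discrepancy

_PSI_FLOOR = 1e-6


@dataclass
class LatentCorrelationResult:
    """Output of a two-factor fit: the latent correlation and context."""

    latent_corr: float
    loadings: pd.DataFrame          # indicator x factor
    residual_cov: np.ndarray        # 6x6 residual (co)variance matrix
    fit_indices: dict               # chisq, df, pvalue, cfi, rmsea, srmr
    converged: bool


class TwoFactorCFA(BaseEstimator):
    """ML two-factor model with same-task residual covariances.

    ``fit(X)`` expects six columns ordered as three indicators of the
    first factor followed by three of the second, with indicator ``i``
    and indicator ``i+3`` coming from the same task.

    Attributes: ``latent_corr_``, ``loadings_``, ``residual_cov_``,
    ``fit_indices_``, ``converged_``.
    """

    def __init__(self, residual_pairs=True, max_iter=1000):
        self.residual_pairs = residual_pairs
        self.max_iter = max_iter

    def _sigma(self, x):
        # residual structure is parameterized through per-task 2x2
        # Cholesky factors so the model covariance stays positive
        # definite for every parameter vector (keeps the optimizer away
        # from infinite discrepancies)
        lam1, lam2 = x[0:3], x[3:6]
        r = np.tanh(x[6])
        L = np.zeros((6, 2))
        L[0:3, 0] = lam1
        L[3:6, 1] = lam2
        phi = np.array([[1.0, r], [r, 1.0]])
        resid = np.zeros((6, 6))
        if self.residual_pairs:
            for t in range(3):
                l11 = np.exp(np.clip(x[7 + 3 * t], -8, 8))
                l21 = x[8 + 3 * t]
                l22 = np.exp(np.clip(x[9 + 3 * t], -8, 8))
                resid[t, t] = l11 ** 2 + _PSI_FLOOR
                resid[t, t + 3] = resid[t + 3, t] = l11 * l21
                resid[t + 3, t + 3] = l21 ** 2 + l22 ** 2 + _PSI_FLOOR
        else:
            psi = np.exp(np.clip(x[7:13], np.log(_PSI_FLOOR), 10))
            resid[np.diag_indices(6)] = psi
        return L @ phi @ L.T + resid, L, r, resid

    def fit(self, X, y=None):
        df = pd.DataFrame(X).dropna()
        if df.shape[1] != 6:
            raise ValueError("expected 6 indicator columns (3 per factor)")
        S = np.cov(df.to_numpy(dtype=float), rowvar=False, ddof=1)
        if np.linalg.eigvalsh(S).min() <= 0:
            raise ValueError("sample covariance is not positive definite")
        n = len(df)
        diag = np.diag(S)
        r0 = np.arctanh(np.clip(np.corrcoef(df.iloc[:, :3].mean(axis=1),
                                            df.iloc[:, 3:].mean(axis=1))[0, 1],
                                -0.95, 0.95))
        if self.residual_pairs:
            resid0 = np.concatenate([
                [0.5 * np.log(0.5 * diag[t]), 0.0, 0.5 * np.log(0.5 * diag[t + 3])]
                for t in range(3)])
        else:
            resid0 = np.log(0.5 * diag)
        x0 = np.concatenate([0.7 * np.sqrt(diag[:3]), 0.7 * np.sqrt(diag[3:]),
                             [r0], resid0])

        def objective(x):
            sigma = self._sigma(x)[0]
            return _ml_discrepancy(S, sigma)

        # tight tolerances: near-perfect indicators make S ill-conditioned
        # and the default ftol stops far from the optimum
        res = minimize(objective, x0, method="L-BFGS-B",
                       options={"maxiter": self.max_iter, "ftol": 1e-14,
                                "gtol": 1e-10})
        sigma, L, r, resid = self._sigma(res.x)
        # orient both factors so their loading sums are positive
        for f in range(2):
            if L[:, f].sum() < 0:
                L[:, f] = -L[:, f]
                r = -r if f == 0 else -r
        self.columns_ = list(df.columns)
        self.latent_corr_ = float(r)
        self.loadings_ = pd.DataFrame(L, index=df.columns, columns=["f1", "f2"])
        self.residual_cov_ = resid
        self.converged_ = bool(res.success)
        self.fit_indices_ = self._indices(S, sigma, n, res.fun)
        self.discrepancy_ = float(res.fun)
        return self

    def _indices(self, S, sigma, n, fmin):
        p = S.shape[0]
        n_free = 13 + (3 if self.residual_pairs else 0)
        df_m = p * (p + 1) // 2 - n_free
        chisq = max((n - 1) * fmin, 0.0)
        # independence baseline: Sigma = diag(S)
        f_base = _ml_discrepancy(S, np.diag(np.diag(S)))
        chisq_b = max((n - 1) * f_base, 0.0)
        df_b = p * (p - 1) // 2
        num = max(chisq - df_m, 0.0)
        den = max(chisq_b - df_b, num, 1e-12)
        cfi = 1.0 - num / den
        rmsea = float(np.sqrt(num / (df_m * (n - 1)))) if df_m > 0 else 0.0
        dS = np.sqrt(np.diag(S))
        rs = S / np.outer(dS, dS)
        dM = np.sqrt(np.diag(sigma))
        rm = sigma / np.outer(dM, dM)
        tri = np.tril_indices(p)
        srmr = float(np.sqrt(np.mean((rs[tri] - rm[tri]) ** 2)))
        from scipy.stats import chi2
        pval = float(chi2.sf(chisq, df_m)) if df_m > 0 else float("nan")
        return {"chisq": float(chisq), "df": int(df_m), "pvalue": pval,
                "cfi": float(cfi), "rmsea": rmsea, "srmr": srmr}

    def result(self) -> LatentCorrelationResult:
        return LatentCorrelationResult(self.latent_corr_, self.loadings_,
                                       self.residual_cov_, self.fit_indices_,
                                       self.converged_)


def fit_orig_fluency(originality: pd.DataFrame, fluency: pd.DataFrame,
                     standardized: bool = True) -> LatentCorrelationResult:
    """Latent correlation between an originality factor (3 task scores)
    and a fluency factor (3 task counts), with same-task residual
    covariances."""
    both = pd.concat([pd.DataFrame(originality), pd.DataFrame(fluency)], axis=1).dropna()
    if standardized:
        both = (both - both.mean()) / both.std(ddof=1)
    model = TwoFactorCFA().fit(both)
    return model.result()


def scheme_correlation_table(scheme_scores: dict, fluency: pd.DataFrame = None) -> pd.DataFrame:
    """Pairwise latent correlations between scoring schemes.

    ``scheme_scores`` maps scheme name -> participant x task frame (the
    three task columns are the factor's indicators).  Every scheme pair
    is fit as its own two-factor model; if ``fluency`` is given, one
    extra row holds each scheme's latent correlation with fluency,
    estimated separately per scheme.
    """
    names = list(scheme_scores)
    if len(names) < 2:
        raise ValueError("need >= 2 schemes")
    table = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
    for i, a in enumerate(names):
        for j in range(i + 1, len(names)):
            b = names[j]
            try:
                res = fit_orig_fluency(scheme_scores[a], scheme_scores[b])
                table.loc[a, b] = table.loc[b, a] = res.latent_corr
            except Exception as exc:  # noqa: BLE001 - per-cell failure contract
                warnings.warn(f"latent model {a} vs {b} failed: {exc}")
                table.loc[a, b] = table.loc[b, a] = np.nan
    if fluency is not None:
        row = {}
        for a in names:
            try:
                row[a] = fit_orig_fluency(scheme_scores[a], fluency).latent_corr
            except Exception as exc:  # noqa: BLE001
                warnings.warn(f"fluency model for {a} failed: {exc}")
                row[a] = np.nan
        table.loc["fluency"] = pd.Series(row)
    return table
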