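"""Rater-level and scale-level diagnostics.

Infit/outfit mean-squares per rater (residuals anchored at the EAP trait
estimate), judge category curves, parallel-analysis unidimensionality
checks with the first/second eigenvalue ratio, and ICC(3,k) inter-rater
reliability from the two-way ANOVA decomposition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .irt import RaterIRT, category_probs
from .rating_data import WideMatrix

#: conventional acceptability band for rater mean-square fit
FIT_RANGE = (0.6, 1.4)


def infit_outfit(model: RaterIRT, data, abilities=None) -> pd.DataFrame:
    """Outfit (unweighted) and infit (information-weighted) mean-squares.

    With ``E_ij`` and ``W_ij`` the conditional mean and variance of rater
    j's rating at unit i's EAP trait estimate:
    ``outfit_j = mean_i (x_ij - E_ij)^2 / W_ij`` and
    ``infit_j = sum_i (x_ij - E_ij)^2 / sum_i W_ij``.
    Values near 1 indicate the rater behaves as the model expects; the
    ``acceptable`` flag marks the conventional 0.6-1.4 band.
    """
    work = model._conform(data)
    if abilities is None:
        abilities = model.eap(data)
    theta = abilities.theta_eap.to_numpy()
    X = work.to_numpy(dtype=float)
    rows = []
    for j, params in enumerate(model.rater_params_):
        col = X[:, j]
        obs = ~np.isnan(col)
        p = category_probs(params, theta[obs])          # (n_obs, K)
        k = np.arange(1, p.shape[1] + 1, dtype=float)
        E = p @ k
        W = p @ k ** 2 - E ** 2
        ok = W > 1e-12
        if not ok.all():
            warnings.warn(f"rater {params.rater_id!r}: {int((~ok).sum())} units with "
                          "near-zero conditional variance excluded from fit statistics")
        resid2 = (col[obs][ok] - E[ok]) ** 2
        outfit = float(np.mean(resid2 / W[ok]))
        infit = float(resid2.sum() / W[ok].sum())
        rows.append({"rater_id": params.rater_id, "outfit": outfit, "infit": infit,
                     "acceptable": FIT_RANGE[0] <= outfit <= FIT_RANGE[1]
                     and FIT_RANGE[0] <= infit <= FIT_RANGE[1]})
    return pd.DataFrame(rows).set_index("rater_id")


def jcc(model, rater_id, grid=None) -> pd.DataFrame:
    """Judge category curves: P(category | theta) for one rater on a grid.

    The frame carries one column per category plus the grid; ``attrs
    ['sorted']`` records whether the rater's graded intercepts are
    strictly decreasing (sorted curves = meaningfully ordered categories).
    """
    params_list = model.rater_params_ if isinstance(model, RaterIRT) else list(model)
    by_id = {p.rater_id: p for p in params_list}
    params = by_id[rater_id]
    grid = np.arange(-4.0, 4.0001, 0.01) if grid is None else np.asarray(grid, dtype=float)
    probs = category_probs(params, grid)
    out = pd.DataFrame(probs, columns=[f"P{k}" for k in range(1, probs.shape[1] + 1)])
    out.insert(0, "theta", grid)
    out.attrs["sorted"] = params.sorted_curves
    return out


@dataclass
class DimensionalityReport:
    """Observed vs simulated eigenvalues of the rater correlation matrix."""

    eigenvalues: np.ndarray
    reference: np.ndarray
    n_retained: int
    ratio_1_2: float


def parallel_analysis(data, n_sim: int = 100, seed: int = 0) -> DimensionalityReport:
    """Horn-style parallel analysis on the rater columns.

    Observed eigenvalues come from the Pearson correlation matrix of the
    rater columns (pairwise-complete); the reference is the mean
    eigenvalue profile of ``n_sim`` standard-normal datasets of identical
    shape.  A factor is retained while its observed eigenvalue exceeds
    the reference, stopping at the first failure; the first/second
    eigenvalue ratio (> 4 conventionally read as unidimensional) is also
    reported.
    """
    df = data.values if isinstance(data, WideMatrix) else pd.DataFrame(data)
    n, k = df.shape
    if k < 3:
        raise ValueError("parallel analysis needs >= 3 rater columns")
    if len(df.dropna()) < 10:
        raise ValueError("fewer than 10 complete rows")
    corr = df.corr().to_numpy()
    eig = np.sort(np.linalg.eigvalsh(corr))[::-1]
    rng = np.random.default_rng(seed)
    ref = np.zeros(k)
    for _ in range(n_sim):
        sim = rng.standard_normal((n, k))
        ref += np.sort(np.linalg.eigvalsh(np.corrcoef(sim, rowvar=False)))[::-1]
    ref /= n_sim
    n_retained = 0
    for o, r in zip(eig, ref):
        if o > r:
            n_retained += 1
        else:
            break
    denom = eig[1] if abs(eig[1]) > 1e-12 else 1e-12
    return DimensionalityReport(eig, ref, n_retained, float(eig[0] / denom))


def icc_3k(data, alpha: float = 0.05):
    """ICC(3,k): two-way mixed, consistency, average measures.

    Complete rows only.  From the row x rater ANOVA decomposition,
    ``ICC = (MS_rows - MS_error) / MS_rows`` with an F-based confidence
    interval.  Returns ``(icc, (low, high))``.
    """
    df = data.values if isinstance(data, WideMatrix) else pd.DataFrame(data)
    X = df.dropna().to_numpy(dtype=float)
    n, k = X.shape
    if k < 2 or n < 3:
        raise ValueError("need >= 2 raters and >= 3 complete rows")
    grand = X.mean()
    row_means = X.mean(axis=1)
    col_means = X.mean(axis=0)
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_total = ((X - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    ms_rows = ss_rows / (n - 1)
    ms_err = ss_err / ((n - 1) * (k - 1))
    if ms_rows <= 1e-12:
        raise ValueError("zero between-row variance; ICC undefined")
    icc = (ms_rows - ms_err) / ms_rows
    F = ms_rows / max(ms_err, 1e-300)
    df1, df2 = n - 1, (n - 1) * (k - 1)
    fl = F / stats.f.ppf(1 - alpha / 2, df1, df2)
    fu = F * stats.f.ppf(1 - alpha / 2, df2, df1)
    return float(icc), (float(1 - 1 / fl), float(1 - 1 / fu))
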