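"""Polytomous IRT with raters as items: probability models, marginal
maximum likelihood, EAP scoring, information functions, model comparison.

The latent trait (originality of a response or of an ideational pool) is
fixed to a standard-normal prior for identification; every rater gets its
own slope (discrimination) and threshold (severity) parameters, depending
on the family:

========== ===============================================================
family     structure
========== ===============================================================
``grm``    graded response: rater slope + K-1 ordered intercepts
``cgrm``   graded response with one slope shared by all raters
``grsm``   graded rating-scale: rater slope + location, shared step shape
``cgrsm``  grsm with a single shared slope
``gpcm``   generalized partial credit: rater slope + K-1 step parameters
``pcm``    partial credit (slope fixed at 1)
``rsm``    rating scale (slope 1, rater location + shared steps)
========== ===============================================================

Estimation maximizes the marginal likelihood on a fixed equally spaced
quadrature grid with renormalized normal-density weights; for smooth
integrands with Gaussian tails this trapezoid-type rule converges
superalgebraically, which the EAP fine-grid oracle tests exploit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import logsumexp, expit
from sklearn.base import BaseEstimator

from .rating_data import WideMatrix

GRM_FAMILIES = ("grm", "cgrm", "grsm", "cgrsm")
PC_FAMILIES = ("pcm", "gpcm", "rsm")
FAMILIES = GRM_FAMILIES + PC_FAMILIES

_TINY = 1e-300


@dataclass(frozen=True)
class RaterParams:
    """Parameters of one rater under a polytomous IRT family.

    GRM-type raters carry intercepts ``d`` (cumulative-boundary
    intercepts, strictly decreasing when category curves are sorted);
    partial-credit-type raters carry step parameters ``b``.
    """

    rater_id: str
    a: float
    d: tuple = None
    b: tuple = None
    family: str = "grm"

    def __post_init__(self):
        if self.d is not None:
            object.__setattr__(self, "d", tuple(float(x) for x in self.d))
        if self.b is not None:
            object.__setattr__(self, "b", tuple(float(x) for x in self.b))
        if (self.d is None) == (self.b is None):
            raise ValueError("exactly one of d (graded) or b (partial credit) required")

    @property
    def n_categories(self) -> int:
        thr = self.d if self.d is not None else self.b
        return len(thr) + 1

    @property
    def sorted_curves(self) -> bool:
        """True when the graded intercepts are strictly decreasing."""
        if self.d is None:
            return True
        return bool(np.all(np.diff(self.d) < 0))


def grm_cumulative(a: float, d, theta):
    """Boundary probabilities P*_2..P*_K of a graded-response rater.

    ``P*_k(theta) = logistic(a*theta + d_{k-1})`` is the probability of
    scoring in category k or above; implicitly P*_1 = 1 and P*_{K+1} = 0.
    Returns an array of shape ``theta.shape + (K-1,)``.
    """
    theta = np.asarray(theta, dtype=float)
    d = np.asarray(d, dtype=float)
    return expit(a * theta[..., None] + d)


def category_probs(params: RaterParams, theta):
    """Probability of each category 1..K at the given trait values.

    Shape ``theta.shape + (K,)``; rows sum to 1.  Unsorted graded
    intercepts are accepted (negative "probabilities" are clipped to 0 and
    renormalized) because unsorted curves are diagnostically meaningful;
    use :attr:`RaterParams.sorted_curves` to detect them.
    """
    theta = np.asarray(theta, dtype=float)
    if params.d is not None:
        pstar = grm_cumulative(params.a, params.d, theta)
        ones = np.ones(theta.shape + (1,))
        zeros = np.zeros(theta.shape + (1,))
        bounds = np.concatenate([ones, pstar, zeros], axis=-1)
        probs = bounds[..., :-1] - bounds[..., 1:]
        if not params.sorted_curves:
            probs = np.clip(probs, 0.0, None)
            probs = probs / probs.sum(axis=-1, keepdims=True)
        return probs
    b = np.asarray(params.b, dtype=float)
    K = len(b) + 1
    k = np.arange(K)
    # cumulative logits: s_k = sum_{v<=k} a*(theta - b_v), s_0 = 0
    steps = params.a * (theta[..., None] - b)
    s = np.concatenate([np.zeros(theta.shape + (1,)), np.cumsum(steps, axis=-1)], axis=-1)
    s = s - s.max(axis=-1, keepdims=True)
    e = np.exp(s)
    return e / e.sum(axis=-1, keepdims=True)


def _log_category_probs(params: RaterParams, theta):
    p = category_probs(params, theta)
    return np.log(np.clip(p, _TINY, None))


def quadrature(n_nodes: int = 101, rng=(-6.0, 6.0), sd: float = 1.0):
    """Equally spaced nodes with renormalized normal(0, sd) weights."""
    nodes = np.linspace(rng[0] * sd, rng[1] * sd, n_nodes)
    w = np.exp(-0.5 * (nodes / sd) ** 2)
    return nodes, w / w.sum()


def _as_values(data) -> np.ndarray:
    if isinstance(data, WideMatrix):
        return data.values.to_numpy(dtype=float)
    if isinstance(data, pd.DataFrame):
        return data.to_numpy(dtype=float)
    return np.asarray(data, dtype=float)


def _loglik_rows(params_list, X, nodes):
    """N x Q matrix of per-unit conditional log-likelihoods on the grid."""
    N = X.shape[0]
    L = np.zeros((N, len(nodes)))
    for j, params in enumerate(params_list):
        col = X[:, j]
        obs = ~np.isnan(col)
        if not obs.any():
            continue
        logp = _log_category_probs(params, nodes)  # (Q, K)
        codes = col[obs].astype(int) - 1
        L[obs] += logp[:, codes].T
    return L


def marginal_loglik(params_list, data, n_quad: int = 101, quad_range=(-6.0, 6.0),
                    per_unit: bool = False):
    """Marginal log-likelihood of a wide rating matrix under given rater
    parameters, integrating the trait over a standard-normal prior.

    Missing cells contribute nothing; an all-missing unit contributes
    ``log 1 = 0``.
    """
    X = _as_values(data)
    nodes, w = quadrature(n_quad, quad_range)
    L = _loglik_rows(params_list, X, nodes)
    ll = logsumexp(L + np.log(w), axis=1)
    ll = np.maximum(ll, np.log(_TINY))
    return ll if per_unit else float(ll.sum())


@dataclass
class AbilityEstimates:
    """EAP trait estimates per unit with posterior SDs."""

    theta_eap: pd.Series
    psd: pd.Series
    empirical_reliability: float

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame({"theta_eap": self.theta_eap, "psd": self.psd})


def _eap_from_rows(L, nodes, w):
    logpost = L + np.log(w)
    logpost -= logpost.max(axis=1, keepdims=True)
    post = np.exp(logpost)
    post /= post.sum(axis=1, keepdims=True)
    mean = post @ nodes
    second = post @ (nodes ** 2)
    var = np.maximum(second - mean ** 2, 0.0)
    return mean, np.sqrt(var)


def eap_scores(model, data, n_quad: int = None, quad_range=None) -> AbilityEstimates:
    """Expected-a-posteriori trait scores under a fitted model.

    ``model`` may be a fitted :class:`RaterIRT` or a plain list of
    :class:`RaterParams`.  Units with no observed ratings get the prior
    mean 0 and SD 1.
    """
    if isinstance(model, RaterIRT):
        params_list = model.rater_params_
        n_quad = n_quad or model.n_quad
        quad_range = quad_range or model.quad_range
        data = model._conform(data)
    else:
        params_list = list(model)
        n_quad = n_quad or 101
        quad_range = quad_range or (-6.0, 6.0)
    X = _as_values(data)
    index = data.values.index if isinstance(data, WideMatrix) else (
        data.index if isinstance(data, pd.DataFrame) else pd.RangeIndex(X.shape[0]))
    nodes, w = quadrature(n_quad, quad_range)
    L = _loglik_rows(params_list, X, nodes)
    mean, psd = _eap_from_rows(L, nodes, w)
    var_hat = float(np.var(mean))
    rel = var_hat / (var_hat + float(np.mean(psd ** 2))) if len(mean) else float("nan")
    return AbilityEstimates(pd.Series(mean, index=index, name="theta_eap"),
                            pd.Series(psd, index=index, name="psd"), rel)


def item_information(params: RaterParams, theta):
    """Samejima item information of one rater at the given trait values.

    For graded raters ``I(theta) = a^2 * sum_k [P*_k q*_k - P*_{k+1}
    q*_{k+1}]^2 / P_k`` with ``q* = 1 - P*``; partial-credit raters use
    the score-variance form ``a^2 * Var(k | theta)``.
    """
    theta = np.asarray(theta, dtype=float)
    if params.d is not None:
        pstar = grm_cumulative(params.a, params.d, theta)
        ones = np.ones(theta.shape + (1,))
        zeros = np.zeros(theta.shape + (1,))
        bounds = np.concatenate([ones, pstar, zeros], axis=-1)
        w = bounds * (1.0 - bounds)
        num = (w[..., :-1] - w[..., 1:]) ** 2
        den = bounds[..., :-1] - bounds[..., 1:]
        terms = np.where(den > _TINY, num / np.maximum(den, _TINY), 0.0)
        return params.a ** 2 * terms.sum(axis=-1)
    p = category_probs(params, theta)
    k = np.arange(p.shape[-1], dtype=float)
    m1 = p @ k
    m2 = p @ k ** 2
    return params.a ** 2 * np.maximum(m2 - m1 ** 2, 0.0)


def tif(model, grid):
    """Test information function: rater informations summed pointwise."""
    params_list = model.rater_params_ if isinstance(model, RaterIRT) else list(model)
    grid = np.asarray(grid, dtype=float)
    return sum(item_information(p, grid) for p in params_list)


# ---------------------------------------------------------------------------
# estimation


def _cumlogit_starts(col, K):
    """Intercept starts from observed cumulative logits of one rater."""
    obs = col[~np.isnan(col)].astype(int)
    d = []
    n = len(obs)
    for k in range(2, K + 1):
        p = np.clip((obs >= k).mean(), 1.0 / (n + 2), 1 - 1.0 / (n + 2))
        d.append(np.log(p / (1 - p)))
    d = np.asarray(d)
    # enforce strict decrease for the ordered parameterization
    for i in range(1, len(d)):
        d[i] = min(d[i], d[i - 1] - 0.05)
    return d


def _ordered_from_raw(raw):
    """(d1, s2..s_{K-1}) -> strictly decreasing intercepts."""
    d1 = raw[0]
    if len(raw) == 1:
        return np.array([d1])
    decs = np.exp(np.clip(raw[1:], -30, 30))
    return np.concatenate([[d1], d1 - np.cumsum(decs)])


def _raw_from_ordered(d):
    d = np.asarray(d, dtype=float)
    if len(d) == 1:
        return d.copy()
    decs = np.maximum(-np.diff(d), 1e-3)
    return np.concatenate([[d[0]], np.log(decs)])


def _centered_steps(u, K):
    """K-2 free params -> K-1 decreasing, mean-zero shared intercept steps."""
    if K == 2:
        return np.zeros(1)
    t = np.concatenate([[0.0], -np.cumsum(np.exp(np.clip(u, -30, 30)))])
    return t - t.mean()


def _zero_sum(u):
    """m free params -> m+1 values summing to zero."""
    return np.concatenate([u, [-np.sum(u)]])


class _FamilyCodec:
    """Pack/unpack the free parameter vector for one model family."""

    def __init__(self, family, rater_ids, K_eff):
        self.family = family
        self.rater_ids = list(rater_ids)
        self.K_eff = list(K_eff)
        self.J = len(self.rater_ids)
        self.K = max(K_eff)

    @property
    def n_params(self) -> int:
        J, K = self.J, self.K
        if self.family == "grm":
            return sum(1 + (k - 1) for k in self.K_eff)
        if self.family == "cgrm":
            return 1 + sum(k - 1 for k in self.K_eff)
        if self.family == "grsm":
            return 2 * J + (K - 2)
        if self.family == "cgrsm":
            return 1 + J + (K - 2)
        if self.family == "pcm":
            return sum(k - 1 for k in self.K_eff)
        if self.family == "gpcm":
            return sum(k for k in self.K_eff)
        if self.family == "rsm":
            return J + K - 2
        raise ValueError(self.family)

    def start(self, X) -> np.ndarray:
        xs = []
        if self.family in ("cgrm", "cgrsm"):
            xs.append([0.0])  # shared log a
        for j, k in enumerate(self.K_eff):
            if self.family == "grm":
                xs.append([0.0])
                xs.append(_raw_from_ordered(_cumlogit_starts(X[:, j], k)))
            elif self.family == "cgrm":
                xs.append(_raw_from_ordered(_cumlogit_starts(X[:, j], k)))
            elif self.family == "grsm":
                d = _cumlogit_starts(X[:, j], k)
                xs.append([0.0, float(np.mean(d))])
            elif self.family == "cgrsm":
                d = _cumlogit_starts(X[:, j], k)
                xs.append([float(np.mean(d))])
            elif self.family == "pcm":
                xs.append(np.zeros(k - 1))
            elif self.family == "gpcm":
                xs.append(np.zeros(k))
            elif self.family == "rsm":
                xs.append([0.0])
        if self.family in ("grsm", "cgrsm"):
            xs.append(np.full(self.K - 2, np.log(1.5)))
        elif self.family == "rsm":
            xs.append(np.zeros(self.K - 2))
        return np.concatenate([np.atleast_1d(np.asarray(x, dtype=float)) for x in xs])

    def unpack(self, x) -> list:
        """Free vector -> list of RaterParams (one per rater)."""
        fam = self.family
        pos = 0
        out = []
        shared_a = None
        if fam in ("cgrm", "cgrsm"):
            shared_a = np.exp(np.clip(x[0], -10, 10))
            pos = 1
        if fam in ("grsm", "cgrsm"):
            tail = self.K - 2
            steps = _centered_steps(x[len(x) - tail:] if tail else np.empty(0), self.K)
            stop = len(x) - tail
        elif fam == "rsm":
            tail = self.K - 2
            tau = _zero_sum(x[len(x) - tail:]) if tail else np.zeros(1)
            stop = len(x) - tail
        for j, (rid, k) in enumerate(zip(self.rater_ids, self.K_eff)):
            if fam == "grm":
                a = np.exp(np.clip(x[pos], -10, 10))
                d = _ordered_from_raw(x[pos + 1:pos + k])
                pos += k
                out.append(RaterParams(rid, float(a), d=tuple(d)))
            elif fam == "cgrm":
                d = _ordered_from_raw(x[pos:pos + k - 1])
                pos += k - 1
                out.append(RaterParams(rid, float(shared_a), d=tuple(d)))
            elif fam == "grsm":
                a = np.exp(np.clip(x[pos], -10, 10))
                c = x[pos + 1]
                pos += 2
                out.append(RaterParams(rid, float(a), d=tuple(c + steps)))
            elif fam == "cgrsm":
                c = x[pos]
                pos += 1
                out.append(RaterParams(rid, float(shared_a), d=tuple(c + steps)))
            elif fam == "pcm":
                b = x[pos:pos + k - 1]
                pos += k - 1
                out.append(RaterParams(rid, 1.0, b=tuple(b), family="pcm"))
            elif fam == "gpcm":
                a = np.exp(np.clip(x[pos], -10, 10))
                b = x[pos + 1:pos + k]
                pos += k
                out.append(RaterParams(rid, float(a), b=tuple(b), family="gpcm"))
            elif fam == "rsm":
                beta = x[pos]
                pos += 1
                out.append(RaterParams(rid, 1.0, b=tuple(beta + tau), family="rsm"))
        return out


@dataclass
class ModelSpec:
    """Declarative description of one IRT fit."""

    family: str = "grm"
    K: int = 5
    n_quad: int = 101
    quad_range: tuple = (-6.0, 6.0)
    max_iter: int = 500
    tol: float = 1e-6


class RaterIRT(BaseEstimator):
    """Raters-as-items polytomous IRT model, fit by marginal ML.

    Parameters
    ----------
    family : str
        One of ``grm, cgrm, grsm, cgrsm, gpcm, pcm, rsm``.
    K : int
        Number of ordinal categories on the rating scale.
    n_quad, quad_range : int, (float, float)
        Quadrature nodes and range for the standard-normal trait prior.
    max_iter, tol : int, float
        Optimizer controls (L-BFGS on the negative marginal loglik).

    Attributes
    ----------
    rater_params_ : list of RaterParams
    loglik_, aic_, bic_, n_params_, n_units_ : floats / ints
    converged_ : bool
    n_iter_ : int
    loglik_trace_ : list of marginal logliks at accepted outer iterates
    dropped_raters_ : raters removed for having a single observed category
    collapsed_ : dict rater_id -> sorted observed categories, for raters
        whose unused categories were collapsed before fitting
    """

    def __init__(self, family="grm", K=5, n_quad=101, quad_range=(-6.0, 6.0),
                 max_iter=500, tol=1e-6):
        self.family = family
        self.K = K
        self.n_quad = n_quad
        self.quad_range = quad_range
        self.max_iter = max_iter
        self.tol = tol

    # -- helpers -----------------------------------------------------------
    def _conform(self, data):
        """Recode a wide matrix onto the fitted roster / collapsed codes."""
        if isinstance(data, WideMatrix):
            vals = data.values[self.raters_]
        elif isinstance(data, pd.DataFrame):
            vals = data[self.raters_]
        else:
            return np.asarray(data, dtype=float)
        X = vals.to_numpy(dtype=float).copy()
        for j, rid in enumerate(self.raters_):
            if rid in self.collapsed_:
                cats = self.collapsed_[rid]
                remap = {c: i + 1 for i, c in enumerate(cats)}
                col = X[:, j]
                obs = ~np.isnan(col)
                X[obs, j] = np.array([remap[int(v)] for v in col[obs]])
        return pd.DataFrame(X, index=vals.index, columns=self.raters_)

    def fit(self, X, y=None):
        """Fit the model to a units x raters wide matrix (NaN = missing)."""
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        if isinstance(X, WideMatrix):
            frame = X.values
        elif isinstance(X, pd.DataFrame):
            frame = X
        else:
            arr = np.asarray(X, dtype=float)
            frame = pd.DataFrame(arr, columns=[f"r{j+1}" for j in range(arr.shape[1])])
        vals = frame.to_numpy(dtype=float)
        if np.nanmax(vals) > self.K or np.nanmin(vals) < 1:
            raise ValueError(f"ratings outside 1..{self.K}")

        keep, dropped, collapsed, K_eff = [], [], {}, []
        per_rater_collapsible = self.family in ("grm", "cgrm", "pcm", "gpcm")
        for j, rid in enumerate(frame.columns):
            col = vals[:, j]
            cats = np.unique(col[~np.isnan(col)]).astype(int)
            if len(cats) < 2:
                dropped.append(rid)
                warnings.warn(f"rater {rid!r} has <2 observed categories; dropped")
                continue
            keep.append(rid)
            if per_rater_collapsible and len(cats) < self.K:
                collapsed[rid] = [int(c) for c in cats]
                K_eff.append(len(cats))
            else:
                K_eff.append(self.K)
        if len(keep) < 2:
            raise ValueError("need >= 2 identifiable raters")
        self.raters_ = list(keep)
        self.dropped_raters_ = dropped
        self.collapsed_ = collapsed
        work = self._conform(WideMatrix(values=frame[keep], meta=None, K=self.K,
                                        level="response"))
        Xw = work.to_numpy(dtype=float)
        # drop all-missing rows from the fit (they contribute log 1 = 0)
        informative = ~np.all(np.isnan(Xw), axis=1)
        Xfit = Xw[informative]

        codec = _FamilyCodec(self.family, keep, K_eff)
        nodes, w = quadrature(self.n_quad, self.quad_range)
        logw = np.log(w)

        # collapse identical response patterns: with J raters and K
        # categories there are at most (K+1)^J distinct rows, so the
        # likelihood cost is independent of the number of units
        codes = np.nan_to_num(Xfit, nan=0.0).astype(int)
        patterns, counts = np.unique(codes, axis=0, return_counts=True)
        Xu = np.where(patterns == 0, np.nan, patterns).astype(float)

        cache = {}

        def nll(x):
            key = x.tobytes()
            if key not in cache:
                params = codec.unpack(x)
                L = _loglik_rows(params, Xu, nodes)
                ll = logsumexp(L + logw, axis=1)
                cache.clear()
                cache[key] = -float(counts @ np.maximum(ll, np.log(_TINY)))
            return cache[key]

        x0 = codec.start(Xfit)
        trace = [-nll(x0)]

        def cb(xk):
            trace.append(-nll(xk))

        res = minimize(nll, x0, method="L-BFGS-B", callback=cb,
                       options={"maxiter": self.max_iter, "ftol": self.tol * 1e-2,
                                "gtol": 1e-6})
        self.rater_params_ = codec.unpack(res.x)
        self.loglik_ = -float(res.fun)
        self.loglik_trace_ = trace
        self.n_iter_ = int(res.nit)
        self.converged_ = bool(res.success) and self.loglik_ >= trace[0] - 1e-4
        self.n_params_ = codec.n_params
        self.n_units_ = int(Xfit.shape[0])
        self.aic_ = -2.0 * self.loglik_ + 2.0 * self.n_params_
        self.bic_ = -2.0 * self.loglik_ + self.n_params_ * np.log(max(self.n_units_, 1))
        return self

    def transform(self, X):
        """EAP trait score and posterior SD per unit, as an (N, 2) frame."""
        return self.eap(X).frame()

    def eap(self, X) -> AbilityEstimates:
        return eap_scores(self, X)

    def score(self, X, y=None):
        """Mean per-unit marginal log-likelihood (model selection helper)."""
        data = self._conform(X)
        ll = marginal_loglik(self.rater_params_, data, self.n_quad, self.quad_range,
                             per_unit=True)
        return float(np.mean(ll))

    @property
    def spec(self) -> ModelSpec:
        return ModelSpec(self.family, self.K, self.n_quad, self.quad_range,
                         self.max_iter, self.tol)


def fit(spec: ModelSpec, data) -> RaterIRT:
    """Fit one model described by a :class:`ModelSpec` to a wide matrix."""
    est = RaterIRT(family=spec.family, K=spec.K, n_quad=spec.n_quad,
                   quad_range=spec.quad_range, max_iter=spec.max_iter, tol=spec.tol)
    return est.fit(data)


def compare_models(specs, data) -> pd.DataFrame:
    """Fit several families to the same data; table sorted by AIC.

    One row per requested spec with loglik, parameter count, AIC, BIC and
    flags marking the AIC-best and BIC-best rows (they may differ).  A fit
    failure is recorded in its row rather than aborting the table.
    """
    rows = []
    fits = {}
    for spec in specs:
        spec = spec if isinstance(spec, ModelSpec) else ModelSpec(family=str(spec))
        try:
            m = fit(spec, data)
            fits[spec.family] = m
            rows.append({"family": spec.family, "loglik": m.loglik_,
                         "n_params": m.n_params_, "aic": m.aic_, "bic": m.bic_,
                         "converged": m.converged_, "error": ""})
        except Exception as exc:  # noqa: BLE001 - per-row failure is the contract
            rows.append({"family": spec.family, "loglik": np.nan, "n_params": np.nan,
                         "aic": np.nan, "bic": np.nan, "converged": False,
                         "error": str(exc)})
    table = pd.DataFrame(rows).sort_values("aic", na_position="last").reset_index(drop=True)
    table["aic_best"] = False
    table["bic_best"] = False
    if table["aic"].notna().any():
        table.loc[table["aic"].idxmin(), "aic_best"] = True
        table.loc[table["bic"].idxmin(), "bic_best"] = True
    table.attrs["fits"] = fits
    return table
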