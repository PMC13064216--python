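"""Covariance-based maximum-likelihood SEM with a latent gender factor.

The model is parameterized in reticular (RAM) form over the stacked vector of
observed and latent variables ``v``:

    v = A v + e,    Cov(e) = S,
    Sigma(theta) = F (I - A)^{-1} S (I - A)^{-T} F',

where ``A`` holds factor loadings and regression coefficients, ``S`` holds
residual variances plus the (fixed-at-sample) covariance block of observed
exogenous covariates, and ``F`` selects the observed variables.  Estimates
minimize the maximum-likelihood discrepancy

    F_ML = ln|Sigma| - ln|S_obs| + tr(S_obs Sigma^{-1}) - p

by quasi-Newton iteration with an analytic gradient; standard errors come
from the inverse observed information ``(2/(n-1)) H^{-1}`` at the optimum.

Observed exogenous covariates are handled lavaan-style (``fixed.x``): their
variances and covariances are fixed at sample values, so they fit exactly and
do not enter the free parameter count; degrees of freedom subtract both the
free parameters and the fixed exogenous moments.

The latent is identified during estimation by fixing one anchor loading to 1
with latent mean 0; the interpretable 0/1 sex-anchored scale (mean gender 1
for female, 0 for male persons) is imposed afterwards by an affine transform
of factor scores and gender-scale parameters (:func:`rescale_gender`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .dag import SemSpecification

__all__ = [
    "FitIndices",
    "GenderScores",
    "SemFit",
    "RamModel",
    "model_implied_covariance",
    "ml_discrepancy",
    "fit_sem",
    "fit_indices",
    "factor_scores",
    "rescale_gender",
    "weighted_covariance",
]

Z95 = 1.959963984540054  # Phi^{-1}(0.975); the |t| > 1.96 decision rule


@dataclass
class FitIndices:
    loglik: float
    fmin: float
    chi2: float
    df: int
    rmsea: float
    srmr: float
    aic: float
    n: float
    converged: bool
    iterations: int

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in (
            "loglik", "fmin", "chi2", "df", "rmsea", "srmr", "aic", "n",
            "converged", "iterations")}


@dataclass
class GenderScores:
    raw: np.ndarray
    rescaled: np.ndarray | None = None
    transform: tuple[float, float] | None = None  # rescaled = a*raw + b


@dataclass
class SemFit:
    """Parameter estimates, fit indices and the fitted model state."""

    params: pd.DataFrame
    indices: FitIndices
    model: "RamModel"
    theta: np.ndarray
    sample_cov: np.ndarray
    sample_means: np.ndarray
    observed: list[str]
    n: float
    scale_factor: float = 1.0  # bookkeeping for sex-anchored rescaling

    @property
    def converged(self) -> bool:
        return self.indices.converged

    def estimate(self, name: str) -> float:
        row = self.params.loc[self.params["name"] == name]
        if row.empty:
            raise KeyError(name)
        return float(row["estimate"].iloc[0])

    def implied_cov_all(self) -> np.ndarray:
        """Model-implied covariance over observed *and* latent variables."""
        A, Smat = self.model.matrices(self.theta)
        B = np.linalg.inv(np.eye(A.shape[0]) - A)
        return B @ Smat @ B.T


class RamModel:
    """Compiled free-parameter table and matrix builder for a specification."""

    def __init__(self, spec: SemSpecification, data_columns=None):
        self.spec = spec
        indicators = [ind for inds in spec.latents.values() for ind, _ in inds]
        latent_names = list(spec.latents)
        endo = [
            y for y, _ in spec.structural
            if y not in latent_names and y not in indicators
        ]
        used = set(indicators) | set(endo)
        predictors: list[str] = []
        for _, covs in spec.indicator_regressions:
            predictors.extend(covs)
        for _, preds in spec.structural:
            predictors.extend(preds)
        exog = [
            v for v in spec.exogenous
            if v in predictors and v not in used
        ]
        self.observed = indicators + endo + exog
        if data_columns is not None:
            missing = set(self.observed) - set(data_columns)
            if missing:
                raise ValueError(f"data lacks model variables: {sorted(missing)}")
        self.latents = latent_names
        self.exog = exog
        self.all_vars = self.observed + self.latents
        self.idx = {v: i for i, v in enumerate(self.all_vars)}
        self.p = len(self.observed)
        self.q = len(exog)
        nall = len(self.all_vars)

        self._A0 = np.zeros((nall, nall))
        self._S0 = np.zeros((nall, nall))
        # free parameters: (name, kind, matrix, (i, j), lower_bound)
        self.free: list[tuple[str, str, str, tuple[int, int], float]] = []
        for lat, inds in spec.latents.items():
            j = self.idx[lat]
            for ind, fixed in inds:
                i = self.idx[ind]
                if fixed is None:
                    self.free.append((f"{lat}=~{ind}", "loading", "A", (i, j), -np.inf))
                else:
                    self._A0[i, j] = fixed
        for ind, covs in spec.indicator_regressions:
            i = self.idx[ind]
            for c in covs:
                self.free.append((f"{ind}~{c}", "regression", "A", (i, self.idx[c]), -np.inf))
        for y, preds in spec.structural:
            i = self.idx[y]
            for x in preds:
                self.free.append((f"{y}~{x}", "regression", "A", (i, self.idx[x]), -np.inf))
        # residual variances: all non-exogenous variables (latents included)
        for v in self.all_vars:
            if v in exog:
                continue
            i = self.idx[v]
            self.free.append((f"var({v})", "variance", "S", (i, i), 1e-8))
        self.param_names = [f[0] for f in self.free]
        if len(self.param_names) != len(set(self.param_names)):
            raise ValueError("duplicate free parameter")
        self.k_free = len(self.free)
        self._exog_idx = np.array([self.idx[v] for v in exog], dtype=int)

    def set_exog_cov(self, cov: np.ndarray) -> None:
        ix = self._exog_idx
        self._S0[np.ix_(ix, ix)] = cov

    def matrices(self, theta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        A = self._A0.copy()
        Smat = self._S0.copy()
        for val, (_, _, mat, (i, j), _) in zip(theta, self.free):
            if mat == "A":
                A[i, j] = val
            else:
                Smat[i, j] = val
        return A, Smat

    def implied_cov(self, theta: np.ndarray) -> np.ndarray:
        A, Smat = self.matrices(theta)
        B = np.linalg.inv(np.eye(A.shape[0]) - A)
        C = B @ Smat @ B.T
        return C[: self.p, : self.p]

    def objective_and_grad(self, theta, S_obs, logdet_S):
        nall = len(self.all_vars)
        p = self.p
        A, Smat = self.matrices(theta)
        B = np.linalg.inv(np.eye(nall) - A)
        C = B @ Smat @ B.T
        Sigma = C[:p, :p]
        try:
            L = np.linalg.cholesky(Sigma)
        except np.linalg.LinAlgError:
            return 1e10, np.zeros(self.k_free)
        logdet = 2.0 * np.sum(np.log(np.diag(L)))
        Sigma_inv = np.linalg.inv(Sigma)
        f = logdet - logdet_S + float(np.trace(S_obs @ Sigma_inv)) - p
        W = Sigma_inv - Sigma_inv @ S_obs @ Sigma_inv  # dF = tr(W dSigma)
        M = np.zeros((nall, nall))
        M[:p, :p] = W
        MB = M @ B
        G1 = B.T @ MB          # for S-matrix entries
        T1 = C @ MB            # for A-matrix entries
        grad = np.empty(self.k_free)
        for k, (_, _, mat, (i, j), _) in enumerate(self.free):
            if mat == "A":
                grad[k] = 2.0 * T1[j, i]
            elif i == j:
                grad[k] = G1[i, i]
            else:
                grad[k] = 2.0 * G1[i, j]
        return f, grad

    def start_values(self, S_obs: np.ndarray) -> np.ndarray:
        """Data-driven starting values: anchor-scaled loadings, zero slopes,
        half-variances."""
        svar = np.diag(S_obs)
        obs_idx = {v: i for i, v in enumerate(self.observed)}
        anchors = {}
        for lat, inds in self.spec.latents.items():
            fixed = [ind for ind, fx in inds if fx is not None]
            anchors[lat] = fixed[0] if fixed else inds[0][0]
        theta0 = np.empty(self.k_free)
        for k, (name, kind, _, (i, j), _) in enumerate(self.free):
            if kind == "loading":
                lat = self.all_vars[j]
                a = obs_idx[anchors[lat]]
                denom = S_obs[a, a] if S_obs[a, a] > 0 else 1.0
                theta0[k] = S_obs[obs_idx[self.all_vars[i]], a] / denom
            elif kind == "regression":
                theta0[k] = 0.0
            else:
                v = self.all_vars[i]
                if v in obs_idx:
                    theta0[k] = max(0.5 * svar[obs_idx[v]], 1e-4)
                else:  # latent residual variance
                    lat_anchor = obs_idx[anchors.get(v, self.observed[0])]
                    theta0[k] = max(0.5 * svar[lat_anchor], 1e-4)
        return theta0


def model_implied_covariance(
    spec: SemSpecification,
    theta: dict[str, float],
    exog_cov: np.ndarray | None = None,
) -> pd.DataFrame:
    """Model-implied covariance of the observed variables for given values.

    ``theta`` maps free-parameter names (``lat=~ind``, ``y~x``, ``var(v)``)
    to values; residual variances must be non-negative.
    """
    model = RamModel(spec)
    if model.q:
        if exog_cov is None:
            raise ValueError("spec has exogenous variables; exog_cov required")
        model.set_exog_cov(np.asarray(exog_cov, dtype=float))
    missing = set(model.param_names) - set(theta)
    if missing:
        raise ValueError(f"missing parameter values: {sorted(missing)}")
    for name, val in theta.items():
        if name.startswith("var(") and val < 0:
            raise ValueError(f"negative residual variance for {name}")
    vec = np.array([theta[name] for name in model.param_names])
    Sigma = model.implied_cov(vec)
    Sigma = (Sigma + Sigma.T) / 2.0
    if np.linalg.eigvalsh(Sigma).min() < -1e-10:
        raise ValueError("implied covariance not positive semi-definite")
    return pd.DataFrame(Sigma, index=model.observed, columns=model.observed)


def ml_discrepancy(S: np.ndarray, Sigma: np.ndarray) -> float:
    """Maximum-likelihood fit function; zero iff ``S == Sigma``."""
    S = np.asarray(S, dtype=float)
    Sigma = np.asarray(Sigma, dtype=float)
    if S.shape != Sigma.shape:
        raise ValueError("dimension mismatch")
    p = S.shape[0]
    sign, logdet_Sig = np.linalg.slogdet(Sigma)
    if sign <= 0:
        raise np.linalg.LinAlgError("singular model covariance")
    _, logdet_S = np.linalg.slogdet(S)
    return float(logdet_Sig - logdet_S + np.trace(S @ np.linalg.inv(Sigma)) - p)


def fit_indices(
    chi2: float, df: int, n: float, S: np.ndarray, Sigma: np.ndarray,
    k_free: int, loglik: float,
) -> dict:
    """RMSEA, SRMR and AIC from the fitted and sample moments."""
    if df < 0:
        raise ValueError("negative degrees of freedom: over-parameterized model")
    rmsea = 0.0
    if df > 0 and chi2 > df:
        rmsea = float(np.sqrt((chi2 - df) / (df * (n - 1))))
    d = np.sqrt(np.diag(S))
    resid = (S - Sigma) / np.outer(d, d)
    iu = np.triu_indices_from(resid)
    srmr = float(np.sqrt(np.mean(resid[iu] ** 2)))
    aic = -2.0 * loglik + 2.0 * k_free
    return {"rmsea": rmsea, "srmr": srmr, "aic": aic}


def _finite_diff_hessian(grad_fn, theta, rel_step=1e-5):
    k = len(theta)
    H = np.empty((k, k))
    for i in range(k):
        h = rel_step * max(1.0, abs(theta[i]))
        tp = theta.copy(); tp[i] += h
        tm = theta.copy(); tm[i] -= h
        H[i] = (grad_fn(tp) - grad_fn(tm)) / (2.0 * h)
    return (H + H.T) / 2.0


def fit_sem(
    spec: SemSpecification,
    data: pd.DataFrame | None = None,
    S: np.ndarray | None = None,
    n: float | None = None,
    means: np.ndarray | None = None,
    weights: np.ndarray | None = None,
    max_iter: int = 500,
    gtol: float = 1e-6,
) -> SemFit:
    """Fit the SEM by minimizing F_ML; deterministic given fixed starts.

    Either ``data`` (one row per person, columns covering every model
    variable) or a precomputed covariance ``S`` with sample size ``n`` must be
    supplied.  With ``weights``, the weighted covariance and effective sample
    size are used.
    """
    model = RamModel(spec, data_columns=None if data is None else data.columns)
    if data is not None:
        X = data[model.observed].to_numpy(dtype=float)
        if np.isnan(X).any():
            raise ValueError("missing values in model variables; impute first")
        if weights is not None:
            S, means, n = weighted_covariance(X, weights)
        else:
            S = np.cov(X, rowvar=False, ddof=1)
            means = X.mean(axis=0)
            n = X.shape[0]
    else:
        if S is None or n is None:
            raise ValueError("provide data, or S and n")
        S = np.asarray(S, dtype=float)
        means = np.zeros(model.p) if means is None else np.asarray(means, float)
    if n <= model.k_free:
        raise ValueError(f"n={n} too small for {model.k_free} free parameters")

    if model.q:
        ex = [model.observed.index(v) for v in model.exog]
        model.set_exog_cov(S[np.ix_(ex, ex)])
    _, logdet_S = np.linalg.slogdet(S)

    bounds = [(lo, None) if np.isfinite(lo) else (None, None)
              for *_, lo in model.free]

    def fun(theta):
        return model.objective_and_grad(theta, S, logdet_S)

    theta0 = model.start_values(S)
    res = optimize.minimize(
        fun, theta0, jac=True, method="L-BFGS-B", bounds=bounds,
        options={"maxiter": max_iter, "gtol": gtol, "ftol": 1e-12})
    converged = bool(res.success) or np.linalg.norm(res.jac, np.inf) < 1e-4
    if not converged:
        # one restart from perturbed starting values
        rng = np.random.default_rng(0)
        theta1 = theta0 * (1 + 0.2 * rng.standard_normal(len(theta0)))
        theta1 = np.clip(theta1, [b[0] if b[0] is not None else -np.inf for b in bounds], None)
        res2 = optimize.minimize(
            fun, theta1, jac=True, method="L-BFGS-B", bounds=bounds,
            options={"maxiter": max_iter, "gtol": gtol, "ftol": 1e-12})
        if res2.fun < res.fun:
            res = res2
        converged = bool(res.success) or np.linalg.norm(res.jac, np.inf) < 1e-4

    theta = res.x
    fmin = float(res.fun)
    # Newton polish: quadratic convergence near the optimum sharpens the
    # solution well past the quasi-Newton stopping tolerance
    lower = np.array([b[0] if b[0] is not None else -np.inf for b in bounds])
    for _ in range(5):
        f_cur, g_cur = fun(theta)
        if np.linalg.norm(g_cur, np.inf) < 1e-12:
            break
        Hp = _finite_diff_hessian(lambda t: fun(t)[1], theta)
        try:
            step = np.linalg.solve(Hp, g_cur)
        except np.linalg.LinAlgError:
            break
        cand = np.maximum(theta - step, lower + 1e-12)
        f_new, _ = fun(cand)
        if f_new <= f_cur:
            theta, fmin = cand, float(f_new)
        else:
            break
    fmin = max(fmin, 0.0)

    H = _finite_diff_hessian(lambda t: fun(t)[1], theta)
    try:
        acov = (2.0 / (n - 1)) * np.linalg.pinv(H)
        se = np.sqrt(np.clip(np.diag(acov), 0.0, None))
        se[np.diag(acov) <= 0] = np.nan
    except np.linalg.LinAlgError:
        se = np.full(model.k_free, np.nan)

    Sigma = model.implied_cov(theta)
    # standardized estimates from the model-implied joint covariance
    A, Smat = model.matrices(theta)
    B = np.linalg.inv(np.eye(len(model.all_vars)) - A)
    C = B @ Smat @ B.T
    sd_all = np.sqrt(np.clip(np.diag(C), 0.0, None))

    rows = []
    for k, (name, kind, mat, (i, j), _) in enumerate(model.free):
        est = theta[k]
        s = se[k]
        t = est / s if s and np.isfinite(s) and s > 0 else np.nan
        p_val = 2.0 * stats.norm.sf(abs(t)) if np.isfinite(t) else np.nan
        if kind in ("loading", "regression") and sd_all[i] > 0:
            std = est * sd_all[j] / sd_all[i]
        elif kind == "variance" and sd_all[i] > 0:
            std = est / sd_all[i] ** 2
        else:
            std = np.nan
        rows.append({
            "name": name, "kind": kind, "estimate": est, "se": s, "t": t,
            "p": p_val, "ci_low": est - Z95 * s, "ci_high": est + Z95 * s,
            "std_estimate": std,
        })
    params = pd.DataFrame(rows)

    p = model.p
    chi2 = (n - 1) * fmin
    df = p * (p + 1) // 2 - model.q * (model.q + 1) // 2 - model.k_free
    loglik = -0.5 * (n - 1) * (
        p * np.log(2 * np.pi) + np.log(np.linalg.det(Sigma))
        + np.trace(S @ np.linalg.inv(Sigma)))
    fx = fit_indices(chi2, df, n, S, Sigma, model.k_free, loglik)
    indices = FitIndices(
        loglik=float(loglik), fmin=fmin, chi2=float(chi2), df=int(df),
        rmsea=fx["rmsea"], srmr=fx["srmr"], aic=fx["aic"], n=float(n),
        converged=converged, iterations=int(res.nit))
    return SemFit(
        params=params, indices=indices, model=model, theta=theta,
        sample_cov=S, sample_means=np.asarray(means, float),
        observed=model.observed, n=float(n))


def factor_scores(
    fit: SemFit, data: pd.DataFrame, latent: str | None = None,
    method: str = "regression",
) -> GenderScores:
    """Per-person estimates of the latent variable from a converged fit.

    ``regression`` scores condition on all observed model variables (the
    conditional mean of the latent given the observed vector under the fitted
    model); ``bartlett`` scores are the GLS solution over the indicator block
    only and are conditionally unbiased given the latent.
    """
    if not fit.converged:
        raise RuntimeError("factor scores require a converged fit")
    if latent is None:
        latent = fit.model.latents[0]
    X = data[fit.observed].to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("factor scores need complete rows; impute first")
    Xc = X - fit.sample_means
    C = fit.implied_cov_all()
    li = fit.model.idx[latent]
    p = fit.model.p
    if method == "regression":
        cov_lo = C[li, :p]
        w = np.linalg.solve(C[:p, :p], cov_lo)
        raw = Xc @ w
    elif method == "bartlett":
        spec = fit.model.spec
        inds = [ind for ind, _ in spec.latents[latent]]
        cols = [fit.observed.index(i) for i in inds]
        lam = np.empty(len(inds))
        theta_d = np.empty(len(inds))
        pmap = dict(zip(fit.model.param_names, fit.theta))
        fixed = {ind: fx for ind, fx in spec.latents[latent] if fx is not None}
        for a, ind in enumerate(inds):
            lam[a] = fixed.get(ind, pmap.get(f"{latent}=~{ind}", np.nan))
            theta_d[a] = pmap[f"var({ind})"]
        wi = lam / np.clip(theta_d, 1e-12, None)
        raw = (Xc[:, cols] @ wi) / (lam @ wi)
    else:
        raise ValueError(f"unknown scoring method {method!r}")
    return GenderScores(raw=np.asarray(raw, dtype=float))


def rescale_gender(
    scores: GenderScores,
    female: np.ndarray,
    params: pd.DataFrame | None = None,
    latent: str = "gender",
) -> tuple[GenderScores, pd.DataFrame | None]:
    """Sex-anchored affine rescaling of the latent: female mean 1, male 0.

    The map ``a*raw + b`` with ``a = 1/(mu_F - mu_M)``, ``b = -mu_M*a`` is
    applied to scores; parameter estimates on the gender scale are transformed
    consistently (coefficients *of* gender divided by ``a``, paths *into*
    gender multiplied by ``a``, the gender variance by ``a**2``) so fitted
    values are unchanged.
    """
    female = np.asarray(female, dtype=bool)
    if female.all() or (~female).all():
        raise ValueError("both sex groups must be non-empty")
    mu_f = float(scores.raw[female].mean())
    mu_m = float(scores.raw[~female].mean())
    if mu_f == mu_m:
        raise ValueError("female and male score means coincide; scale undefined")
    a = 1.0 / (mu_f - mu_m)
    b = -mu_m * a
    rescaled = a * scores.raw + b
    out_scores = GenderScores(raw=scores.raw, rescaled=rescaled, transform=(a, b))
    if params is None:
        return out_scores, None
    new = params.copy()
    scale_cols = ["estimate", "se", "ci_low", "ci_high"]
    for idx, row in new.iterrows():
        name = row["name"]
        fac = None
        if name.endswith(f"~{latent}") or name.startswith(f"{latent}=~"):
            fac = 1.0 / a          # gender is the predictor / the factor
        elif name.startswith(f"{latent}~"):
            fac = a                # path into gender
        elif name == f"var({latent})":
            fac = a * a
        if fac is not None:
            new.loc[idx, scale_cols] = row[scale_cols].to_numpy(dtype=float) * fac
    if a < 0:  # keep CI ordered if orientation flipped
        lo = new["ci_low"].copy()
        new["ci_low"] = np.minimum(lo, new["ci_high"])
        new["ci_high"] = np.maximum(lo, new["ci_high"])
        new["se"] = new["se"].abs()
    return out_scores, new


def weighted_covariance(
    data: np.ndarray | pd.DataFrame, weights: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Weight-normalized mean/covariance and Kish effective sample size.

    Returns ``(S_w, means, n_eff)`` with ``n_eff = (sum w)^2 / sum w^2``.
    Equal weights reproduce the unweighted ddof-1 covariance; zero-weight rows
    contribute nothing.
    """
    X = np.asarray(data, dtype=float)
    w = np.asarray(weights, dtype=float)
    if (w < 0).any():
        raise ValueError("negative weights")
    sw = w.sum()
    if sw <= 0:
        raise ValueError("all weights are zero")
    mean = (w[:, None] * X).sum(axis=0) / sw
    Xc = X - mean
    denom = sw - (w ** 2).sum() / sw  # unbiased for reliability weights
    Sw = (w[:, None] * Xc).T @ Xc / denom
    n_eff = sw ** 2 / (w ** 2).sum()
    return Sw, mean, n_eff
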