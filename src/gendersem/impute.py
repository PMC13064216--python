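"""Multiple imputation by chained equations and Rubin's-rules pooling.

Incomplete variables are imputed in rotation from conditional models:
predictive mean matching (PMM) for continuous variables, logistic regression
draws for dichotomous ones, and proportional-odds logistic regression draws
for ordinal ones; m completed datasets are produced from independent random
streams.  Analyses run on each completed dataset are combined with Rubin's
rules:

    Qbar = mean(Q_i),  Wbar = mean(se_i^2),  B = var(Q_i),
    T = Wbar + (1 + 1/m) B,   se_pool = sqrt(T).

Conditional fits include a proper-imputation parameter draw (posterior draw
of the regression coefficients) so between-imputation variance is propagated.
Outcome (incidence) columns are never imputed: incidence is defined by
observed response switches only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ImputationSet",
    "PooledEstimates",
    "impute_mice",
    "pmm_impute_variable",
    "pool_rubin",
    "infer_method_map",
]

Z95 = 1.959963984540054


@dataclass
class ImputationSet:
    m: int
    datasets: list[pd.DataFrame]
    method_map: dict[str, str]
    seed: int
    iterations: int = 10

    def manifest(self) -> dict:
        return {"m": self.m, "seed": self.seed, "iterations": self.iterations,
                "methods": self.method_map}


@dataclass
class PooledEstimates:
    table: pd.DataFrame  # name, estimate, within, between, total, se, t, p, CI
    m: int


def infer_method_map(table: pd.DataFrame, exclude=()) -> dict[str, str]:
    """Default conditional-model choice per variable: binary -> logistic,
    few-level integer-coded -> proportional odds, otherwise PMM."""
    method = {}
    for col in table.columns:
        if col in exclude or not pd.api.types.is_numeric_dtype(table[col]):
            method[col] = "none"
            continue
        vals = table[col].dropna().unique()
        if len(vals) <= 1:
            method[col] = "none"
        elif set(np.unique(vals)) <= {0.0, 1.0}:
            method[col] = "logistic"
        elif len(vals) <= 7 and np.allclose(vals, np.round(vals)):
            method[col] = "proportional-odds"
        else:
            method[col] = "pmm"
    return method


def _design(table: pd.DataFrame, target: str, predictors: list[str]) -> np.ndarray:
    X = table[[c for c in predictors if c != target]].to_numpy(dtype=float)
    return np.column_stack([np.ones(len(X)), X])


def pmm_impute_variable(
    y: np.ndarray,
    X: np.ndarray,
    missing: np.ndarray,
    donors: int = 5,
    rng: np.random.Generator | None = None,
    posterior_draw: bool = True,
) -> np.ndarray:
    """Predictive mean matching: impute each missing cell with an observed
    donor value whose predicted mean is among the ``donors`` nearest.

    ``X`` must include an intercept column.  With ``posterior_draw`` the
    predictions for missing cells use a posterior draw of the regression
    coefficients (proper imputation); observed-cell predictions use the
    least-squares fit, the standard type-1 matching scheme.
    """
    y = np.asarray(y, dtype=float)
    obs = ~missing
    n_obs = int(obs.sum())
    if n_obs < X.shape[1]:
        raise ValueError(
            f"{n_obs} observed cells cannot support {X.shape[1]} coefficients")
    if not missing.any():
        return y.copy()
    rng = rng or np.random.default_rng()
    yo, Xo = y[obs], X[obs]
    beta, *_ = np.linalg.lstsq(Xo, yo, rcond=None)
    pred_obs = Xo @ beta
    if posterior_draw and n_obs > X.shape[1]:
        resid = yo - pred_obs
        dfree = n_obs - X.shape[1]
        sigma2 = resid @ resid / stats.chi2.rvs(dfree, random_state=rng)
        XtX_inv = np.linalg.pinv(Xo.T @ Xo)
        beta_star = rng.multivariate_normal(beta, sigma2 * XtX_inv,
                                            method="svd")
    else:
        beta_star = beta
    pred_mis = X[missing] @ beta_star

    order = np.argsort(pred_obs, kind="stable")
    sorted_pred = pred_obs[order]
    sorted_y = yo[order]
    k = min(donors, n_obs)
    pos = np.searchsorted(sorted_pred, pred_mis)
    out = y.copy()
    lo = np.clip(pos - k, 0, n_obs - k)
    # candidate window of 2k around the insertion point, pick k nearest
    idx = lo[:, None] + np.arange(2 * k)[None, :]
    idx = np.clip(idx, 0, n_obs - 1)
    dist = np.abs(sorted_pred[idx] - pred_mis[:, None])
    nearest = np.argsort(dist, axis=1, kind="stable")[:, :k]
    pick = nearest[np.arange(len(pred_mis)), rng.integers(0, k, len(pred_mis))]
    out[missing] = sorted_y[idx[np.arange(len(pred_mis)), pick]]
    return out


def _logistic_impute(y, X, missing, rng):
    import statsmodels.api as sm
    obs = ~missing
    out = y.copy()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.GLM(y[obs], X[obs], family=sm.families.Binomial()).fit()
            beta = rng.multivariate_normal(
                res.params, res.cov_params(), method="svd")
        p = 1.0 / (1.0 + np.exp(-(X[missing] @ beta)))
    except Exception:
        p = np.full(int(missing.sum()), y[obs].mean())
    out[missing] = (rng.random(len(p)) < p).astype(float)
    return out


def _propodds_impute(y, X, missing, rng):
    """Proportional-odds logistic draw; falls back to observed-frequency
    draws if the ordinal fit fails."""
    from statsmodels.miscmodels.ordinal_model import OrderedModel
    obs = ~missing
    out = y.copy()
    levels = np.sort(np.unique(y[obs]))
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            # OrderedModel adds its own thresholds; drop intercept column
            mod = OrderedModel(y[obs], X[obs][:, 1:], distr="logit")
            res = mod.fit(method="bfgs", disp=False, maxiter=200)
            probs = res.model.predict(res.params, exog=X[missing][:, 1:])
        cum = np.cumsum(probs, axis=1)
        u = rng.random(len(cum))
        pick = (u[:, None] > cum).sum(axis=1)
    except Exception:
        freq = np.array([(y[obs] == lv).mean() for lv in levels])
        pick = rng.choice(len(levels), size=int(missing.sum()), p=freq / freq.sum())
    out[missing] = levels[np.clip(pick, 0, len(levels) - 1)]
    return out


def impute_mice(
    table: pd.DataFrame,
    m: int = 20,
    method_map: dict[str, str] | None = None,
    seed: int = 0,
    iterations: int = 10,
    donors: int = 5,
    predictors: list[str] | None = None,
    protect: tuple[str, ...] = (),
) -> ImputationSet:
    """Chained-equation multiple imputation producing ``m`` completed tables.

    Variables are visited in ascending order of missingness fraction;
    ``protect`` columns (e.g. derived incidence flags) must be complete and
    are never imputed.  Observed cells are returned untouched.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    if method_map is None:
        method_map = infer_method_map(table)
    missing_cols = [c for c in table.columns if table[c].isna().any()]
    for c in missing_cols:
        if c in protect:
            raise ValueError(f"protected column {c!r} has missing cells")
        if table[c].isna().all():
            raise ValueError(f"variable {c!r} is entirely missing")
        if method_map.get(c, "none") == "none":
            raise ValueError(f"variable {c!r} has missing cells but no method")
    if predictors is None:
        predictors = [
            c for c in table.columns
            if pd.api.types.is_numeric_dtype(table[c])
            and c not in ("person_id", "weight")
        ]
    order = sorted(missing_cols, key=lambda c: table[c].isna().mean())

    datasets = []
    root = np.random.SeedSequence(seed)
    for child in root.spawn(m):
        rng = np.random.default_rng(child)
        work = table.copy()
        # initial fill: random draws from the observed values
        for c in missing_cols:
            mis = work[c].isna().to_numpy()
            obs_vals = work.loc[~work[c].isna(), c].to_numpy(dtype=float)
            work.loc[mis, c] = rng.choice(obs_vals, size=int(mis.sum()))
        for _ in range(iterations):
            for c in order:
                mis = table[c].isna().to_numpy()
                X = _design(work, c, predictors)
                y = work[c].to_numpy(dtype=float)
                y[mis] = np.nan
                kind = method_map[c]
                if kind == "pmm":
                    filled = pmm_impute_variable(y, X, mis, donors=donors, rng=rng)
                elif kind == "logistic":
                    filled = _logistic_impute(y, X, mis, rng)
                elif kind == "proportional-odds":
                    filled = _propodds_impute(y, X, mis, rng)
                else:  # pragma: no cover - guarded above
                    raise ValueError(f"unknown method {kind!r}")
                work[c] = filled
        datasets.append(work)
    return ImputationSet(m=m, datasets=datasets, method_map=method_map,
                         seed=seed, iterations=iterations)


def pool_rubin(estimates: list[pd.DataFrame], m: int | None = None) -> PooledEstimates:
    """Rubin's rules over per-imputation estimate tables.

    Each input table needs columns ``name``, ``estimate``, ``se`` with
    identical parameter lists in identical order.
    """
    if not estimates:
        raise ValueError("no estimates to pool")
    m = m if m is not None else len(estimates)
    names = estimates[0]["name"].tolist()
    for est in estimates[1:]:
        if est["name"].tolist() != names:
            raise ValueError("mismatched parameter names across imputations")
    Q = np.column_stack([e["estimate"].to_numpy(dtype=float) for e in estimates])
    SE = np.column_stack([e["se"].to_numpy(dtype=float) for e in estimates])
    qbar = Q.mean(axis=1)
    wbar = (SE ** 2).mean(axis=1)
    b = Q.var(axis=1, ddof=1) if m > 1 else np.zeros_like(qbar)
    total = wbar + (1.0 + 1.0 / m) * b
    se = np.sqrt(total)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = qbar / se
    p = 2.0 * stats.norm.sf(np.abs(t))
    table = pd.DataFrame({
        "name": names, "estimate": qbar, "within": wbar, "between": b,
        "total": total, "se": se, "t": t, "p": p,
        "ci_low": qbar - Z95 * se, "ci_high": qbar + Z95 * se,
    })
    if "kind" in estimates[0].columns:
        table.insert(1, "kind", estimates[0]["kind"].to_numpy())
    return PooledEstimates(table=table, m=m)
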