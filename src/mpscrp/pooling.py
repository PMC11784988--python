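"""Cross-array pooling and missing-data machinery.

Per-array estimates are combined by inverse-variance-weighted
fixed-effects meta-analysis (both strata are Z-scored internally, which
is what makes pooling scale-coherent).  Missing covariates and item-level
exposure indicators are filled by multiple imputation with chained
equations — Bayesian linear regression draws for continuous variables,
logistic draws for binary, ordered-logit draws for ordinal — after which
the cumulative exposure scores are passively re-derived inside each
completed dataset.  Fits across completed datasets are combined by
Rubin's rules.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from mpscrp.errors import SchemaError

logger = logging.getLogger(__name__)


def ivw_meta(estimates: pd.DataFrame) -> pd.DataFrame:
    """Fixed-effects inverse-variance meta-analysis, one pooled row per term.

    ``estimates`` needs columns ``term``, ``beta``, ``se`` (and
    optionally ``n``, ``tier``); weights are ``1/se^2``, the pooled SE is
    ``(sum w)^(-1/2)`` and the p-value comes from a two-sided normal.
    Cochran's Q is reported informationally.  Output is invariant to
    stratum ordering.
    """
    for col in ("term", "beta", "se"):
        if col not in estimates.columns:
            raise SchemaError(f"estimates lack '{col}'")
    if (estimates["se"] <= 0).any() or not np.isfinite(estimates["se"]).all():
        raise SchemaError("all standard errors must be positive and finite")
    group_cols = ["term"] + [c for c in ("tier", "form", "outcome", "aim") if c in estimates]
    rows = []
    for key, grp in estimates.groupby(group_cols, sort=True):
        w = 1.0 / grp["se"].to_numpy() ** 2
        b = grp["beta"].to_numpy()
        beta = float(np.sum(w * b) / np.sum(w))
        se = float(np.sum(w) ** -0.5)
        z = beta / se
        q_stat = float(np.sum(w * (b - beta) ** 2))
        row = dict(zip(group_cols, key if isinstance(key, tuple) else (key,)))
        row.update({
            "beta": beta, "se": se, "p": float(2 * stats.norm.sf(abs(z))),
            "k_strata": int(len(grp)), "q_het": q_stat,
            "n": int(grp["n"].sum()) if "n" in grp else np.nan,
            "stratum": "pooled",
        })
        rows.append(row)
    return pd.DataFrame(rows)


def rubin_pool(fits: pd.DataFrame) -> pd.DataFrame:
    """Rubin's rules over m completed-dataset fits, one pooled row per term.

    Pooled estimate is the mean; total variance ``T = W + (1 + 1/m) B``
    with ``W`` the mean within-imputation variance and ``B`` the
    between-imputation variance; degrees of freedom follow the classic
    small-sample formula ``(m - 1)(1 + W / ((1 + 1/m) B))^2``, shrunk by
    the Barnard-Rubin observed-data adjustment when the fits carry a
    ``df_resid`` column with the complete-data residual df.
    """
    for col in ("term", "beta", "se"):
        if col not in fits.columns:
            raise SchemaError(f"fits lack '{col}'")
    group_cols = ["term"] + [
        c for c in ("tier", "form", "outcome", "aim", "stratum") if c in fits
    ]
    rows = []
    for key, grp in fits.groupby(group_cols, sort=True):
        m = len(grp)
        if m < 2:
            raise SchemaError("Rubin pooling needs m >= 2 fits per term")
        b = grp["beta"].to_numpy(dtype=float)
        w_i = grp["se"].to_numpy(dtype=float) ** 2
        beta = float(b.mean())
        W = float(w_i.mean())
        B = float(b.var(ddof=1))
        T = W + (1 + 1 / m) * B
        se = float(np.sqrt(T))
        if B > 0:
            lam = (1 + 1 / m) * B / T
            df = (m - 1) / lam**2
            if "df_resid" in grp.columns and np.isfinite(grp["df_resid"]).all():
                df_com = float(grp["df_resid"].min())
                df_obs = (df_com + 1) / (df_com + 3) * df_com * (1 - lam)
                df = df * df_obs / (df + df_obs)
            p = float(2 * stats.t.sf(abs(beta / se), df))
        else:
            df = np.inf
            p = float(2 * stats.norm.sf(abs(beta / se))) if se > 0 else np.nan
        row = dict(zip(group_cols, key if isinstance(key, tuple) else (key,)))
        row.update({
            "beta": beta, "se": se, "p": p, "df": df, "m": m,
            "within_var": W, "between_var": B,
            "n": int(grp["n"].max()) if "n" in grp else np.nan,
        })
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class ImputationSet:
    """Chained-equations settings.

    ``variables`` maps each imputable column to its conditional-model
    type: ``"continuous"``, ``"binary"`` or ``"ordinal"``.  The profile
    score and brain outcomes are never imputable.  Defaults follow the
    emulated analysis (m = 30 datasets, 60 iterations); tests run far
    smaller settings.
    """

    variables: dict = field(default_factory=dict)
    m: int = 30
    iterations: int = 60
    predictors: list | None = None  # defaults to all declared variables + extras
    seed: int = 0

    def __post_init__(self) -> None:
        if self.m < 2:
            raise SchemaError("need m >= 2 completed datasets for pooling")
        ok = {"continuous", "binary", "ordinal"}
        bad = {v for v in self.variables.values()} - ok
        if bad:
            raise SchemaError(f"unknown conditional model types: {bad}")


def _design(df: pd.DataFrame, cols: list[str]) -> np.ndarray:
    X = [np.ones(len(df))]
    for c in cols:
        X.append(df[c].to_numpy(dtype=float))
    M = np.column_stack(X)
    # drop collinear columns (keep earliest), logged
    keep = [0]
    for j in range(1, M.shape[1]):
        trial = M[:, keep + [j]]
        if np.linalg.matrix_rank(trial) == len(keep) + 1:
            keep.append(j)
        else:
            logger.info("mice: dropping collinear predictor '%s'", cols[j - 1])
    return M[:, keep]


def _bayes_linear_draw(rng, X, y, x_new):
    n, p = X.shape
    XtX = X.T @ X + 1e-8 * np.eye(p)
    coef = np.linalg.solve(XtX, X.T @ y)
    resid = y - X @ coef
    dof = max(n - p, 2)
    sigma2 = (resid @ resid) / stats.chi2.rvs(dof, random_state=rng)
    cov = sigma2 * np.linalg.inv(XtX) + 1e-12 * np.eye(p)
    beta_star = rng.multivariate_normal(coef, cov)
    return x_new @ beta_star + rng.normal(0, np.sqrt(sigma2), size=len(x_new))

def _logistic_draw(rng, X, y, x_new):
    import warnings

    import statsmodels.api as sm

    try:
        with warnings.catch_warnings(), np.errstate(divide="ignore", over="ignore"):
            warnings.simplefilter("ignore")
            fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
            params, cov = fit.params, fit.cov_params()
        if not np.all(np.isfinite(cov)):
            raise ValueError("non-finite covariance")
    except Exception:  # separation etc. -> ridge-regularized fallback
        with warnings.catch_warnings(), np.errstate(divide="ignore", over="ignore"):
            warnings.simplefilter("ignore")
            fit = sm.Logit(y, X).fit_regularized(alpha=1.0, disp=0)
        params = np.asarray(fit.params)
        cov = np.eye(X.shape[1]) * 0.25
    cov = np.asarray(cov)
    cov = (cov + cov.T) / 2 + 1e-10 * np.eye(X.shape[1])
    beta_star = rng.multivariate_normal(np.asarray(params), cov, check_valid="ignore")
    lin = np.clip(x_new @ beta_star, -35, 35)
    pr = 1.0 / (1.0 + np.exp(-lin))
    return (rng.random(len(x_new)) < pr).astype(float)


def _ordinal_draw(rng, X, y, x_new):
    # latent-scale draws against observed category quantiles: fit a linear
    # model on the rank-normal transform, draw, then map back to the
    # nearest observed category (ordered-logit-style conditional)
    cats = np.sort(np.unique(y))
    if len(cats) <= 2:
        return _logistic_draw(rng, X, (y == cats[-1]).astype(float), x_new) * (
            cats[-1] - cats[0]
        ) + cats[0]
    ranks = stats.rankdata(y) / (len(y) + 1)
    z = stats.norm.ppf(ranks)
    draws = _bayes_linear_draw(rng, X, z, x_new)
    qs = np.quantile(z, np.linspace(0, 1, len(cats) + 1)[1:-1])
    return cats[np.searchsorted(qs, draws)]


def mice_impute(
    cohort: pd.DataFrame,
    spec: ImputationSet,
    passive: "callable | None" = None,
) -> list[pd.DataFrame]:
    """Chained-equations multiple imputation.

    Returns ``spec.m`` completed copies of ``cohort``.  Each chain starts
    from random draws of the observed values, then cycles variable-wise
    conditional draws for ``spec.iterations`` rounds.  If ``passive`` is
    given it is called on each completed dataset (e.g. to re-derive the
    exposure scores from imputed items) and its return value is kept.
    """
    imputable = [c for c in spec.variables if c in cohort.columns]
    for c in imputable:
        if cohort[c].notna().sum() == 0:
            raise SchemaError(f"'{c}' has no observed values to impute from")
    incomplete = [c for c in imputable if cohort[c].isna().any()]
    if not incomplete:
        out = [cohort.copy() for _ in range(spec.m)]
        return [passive(d) if passive else d for d in out]

    predictors = spec.predictors or imputable
    rng_master = np.random.default_rng(spec.seed)
    completed = []
    for _ in range(spec.m):
        rng = np.random.default_rng(rng_master.integers(2**31))
        df = cohort.copy()
        for c in incomplete:
            obs = df[c].dropna().to_numpy(dtype=float)
            df.loc[df[c].isna(), c] = rng.choice(obs, size=df[c].isna().sum())
        for _ in range(spec.iterations):
            for c in incomplete:
                miss_mask = cohort[c].isna().to_numpy()
                preds = [p for p in predictors if p != c and p in df.columns
                         and df[p].notna().all()]
                X_all = _design(df, preds)
                X_obs, X_mis = X_all[~miss_mask], X_all[miss_mask]
                y_obs = df.loc[~miss_mask, c].to_numpy(dtype=float)
                kind = spec.variables[c]
                if np.unique(y_obs).size < 2:
                    # a constant observed column carries no sampling
                    # uncertainty worth modelling
                    draws = np.full(int(miss_mask.sum()), y_obs[0])
                elif kind == "continuous":
                    draws = _bayes_linear_draw(rng, X_obs, y_obs, X_mis)
                elif kind == "binary":
                    draws = _logistic_draw(rng, X_obs, y_obs, X_mis)
                else:
                    draws = _ordinal_draw(rng, X_obs, y_obs, X_mis)
                df.loc[miss_mask, c] = draws
        completed.append(passive(df) if passive else df)
    return completed
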