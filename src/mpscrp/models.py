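"""Association models: predictors of the score and longitudinal outcomes.

Aim 1 regresses the Z-scored profile score on the five (pruned)
cumulative prenatal inflammatory scores jointly, with child sex, batch
(plate), estimated cell-type proportions, household income and maternal
education as covariates; the polygenic score is fitted in a separate
model with identical covariates because the prenatal scores could sit on
its causal path.  Aims 2 and 3 fit restricted-maximum-likelihood linear
mixed models with a participant random intercept, in three forms: score
main effect, score x age, and score x age x gestational age (gestational
age continuous), on 10 brain outcomes (2 occasions) and 3 CBCL scales
(5 occasions, square-root transformed).  Continuous predictors and
outcomes are Z-scored so coefficients are standardized betas; age is
centered at the per-outcome mean occasion age.

FDR control is Benjamini-Hochberg within each (aim, model-form) family
across outcomes.  The variance partition of the score over predictor
groups uses the LMG / Shapley decomposition of the linear-model R^2 with
exact enumeration over subsets.
"""

from __future__ import annotations

import logging
import warnings
from itertools import combinations
from math import factorial

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.multitest import multipletests

from mpscrp.errors import DegenerateDesignError, SchemaError

logger = logging.getLogger(__name__)

KEY_TERMS = {
    "main": "mps_z",
    "by_age": "mps_z:age_c",
    "by_age_by_ga": "mps_z:age_c:ga_c",
}

AIM1_BASE_COVARIATES = "C(sex) + C(plate) + income_high + C(education)"
AIM23_EXTRA_COVARIATES = "maternal_age + C(smoking) + parity"


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = np.nanstd(x, ddof=1)
    if not np.isfinite(sd) or sd == 0:
        raise DegenerateDesignError("cannot Z-score a constant column")
    return (x - np.nanmean(x)) / sd


def _cell_terms(cell_cols: tuple[str, ...]) -> str:
    # one cell type dropped to break the simplex collinearity
    return " + ".join(cell_cols[1:]) if len(cell_cols) > 1 else ""


def _check_full_rank(fit) -> None:
    X = fit.model.exog
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        names = fit.model.exog_names
        raise DegenerateDesignError(
            f"design rank {rank} < {X.shape[1]} columns; check {names}"
        )


def fit_aim1(
    data: pd.DataFrame,
    score_cols: list[str],
    stratum: str,
    cell_cols: tuple[str, ...] = (),
    adjust_cells: bool = True,
    pgs_col: str | None = "pgs_residualized",
) -> pd.DataFrame:
    """Multivariate prenatal-score regression plus the separate PGS model.

    ``data`` is one array stratum with columns ``mps_z``, the retained
    score columns, covariates (``sex``, ``plate``, ``income_high``,
    ``education``) and cell-proportion columns.  Scores are Z-scored so
    estimates are standardized betas.  Returns tidy effect rows.
    """
    df = data.copy()
    rhs_scores, used_scores = [], []
    for c in score_cols:
        vals = df[c].to_numpy(dtype=float)
        if np.nanstd(vals, ddof=1) == 0:
            # a score with no variation in this stratum carries no
            # information; the term is estimated from the other stratum
            logger.warning("fit_aim1: '%s' constant in stratum '%s', skipped",
                           c, stratum)
            continue
        df[f"{c}_z"] = _zscore(vals)
        rhs_scores.append(f"{c}_z")
        used_scores.append(c)
    if not rhs_scores:
        raise DegenerateDesignError(f"all score columns constant in '{stratum}'")
    score_cols = used_scores
    covs = AIM1_BASE_COVARIATES
    if adjust_cells and cell_cols:
        ct = _cell_terms(cell_cols)
        covs = f"{covs} + {ct}" if ct else covs
    rows = []

    formula = f"mps_z ~ {' + '.join(rhs_scores)} + {covs}"
    fit = smf.ols(formula, data=df.dropna(subset=["mps_z", *score_cols])).fit()
    _check_full_rank(fit)
    for c in score_cols:
        t = f"{c}_z"
        rows.append({
            "term": c, "beta": float(fit.params[t]), "se": float(fit.bse[t]),
            "p": float(fit.pvalues[t]), "n": int(fit.nobs), "stratum": stratum,
            "aim": "aim1", "form": "multivariate",
        })

    if pgs_col and pgs_col in df.columns and df[pgs_col].notna().any():
        sub = df.dropna(subset=["mps_z", pgs_col])
        fitp = smf.ols(f"mps_z ~ {pgs_col} + {covs}", data=sub).fit()
        _check_full_rank(fitp)
        rows.append({
            "term": "pgs", "beta": float(fitp.params[pgs_col]),
            "se": float(fitp.bse[pgs_col]), "p": float(fitp.pvalues[pgs_col]),
            "n": int(fitp.nobs), "stratum": stratum, "aim": "aim1", "form": "pgs",
        })
    return pd.DataFrame(rows)


def fit_longitudinal(
    data_long: pd.DataFrame,
    outcome: str,
    form: str = "main",
    transform: str = "none",
    stratum: str = "",
    aim: str = "aim2",
    cell_cols: tuple[str, ...] = (),
    adjust_cells: bool = True,
    include_icv: bool = False,
    reml: bool = True,
) -> pd.DataFrame:
    """Random-intercept mixed model for one repeated outcome.

    ``data_long`` holds one row per (participant, occasion) with the
    outcome, ``age``, ``mps_z``, ``gestational_age`` and the covariate
    and cell-proportion columns.  The outcome is square-root transformed
    first when ``transform='sqrt'`` (CBCL count scales) and then
    Z-scored; age is centered at the sample mean occasion age.  Fixed
    effects are reported for every term; non-convergence is flagged in
    the ``converged`` column, never silently dropped.
    """
    if form not in KEY_TERMS:
        raise ValueError(f"form must be one of {sorted(KEY_TERMS)}")
    if transform not in ("none", "sqrt"):
        raise ValueError("transform must be 'none' or 'sqrt'")
    needed = [outcome, "age", "mps_z", "gestational_age", "sex", "plate",
              "income_high", "education", "maternal_age", "smoking", "parity"]
    if adjust_cells:
        needed += list(cell_cols[1:])
    if include_icv:
        needed.append("icv")
    needed = [c for c in needed if c in data_long.columns]
    df = data_long.dropna(subset=needed).copy()
    if df.empty or df["sample_id"].nunique() < 10:
        raise DegenerateDesignError(f"too few participants for '{outcome}'")
    y = df[outcome].to_numpy(dtype=float)
    if transform == "sqrt":
        if (y < 0).any():
            raise SchemaError("sqrt transform requires nonnegative outcomes")
        y = np.sqrt(y)
    df["y"] = _zscore(y)
    df["age_c"] = df["age"] - df["age"].mean()
    df["ga_c"] = df["gestational_age"] - df["gestational_age"].mean()

    if form == "main":
        fe = "mps_z + age_c"
    elif form == "by_age":
        fe = "mps_z * age_c"
    else:
        fe = "mps_z * age_c * ga_c"
    covs = AIM1_BASE_COVARIATES + " + " + AIM23_EXTRA_COVARIATES
    if adjust_cells and cell_cols:
        ct = _cell_terms(cell_cols)
        covs = f"{covs} + {ct}" if ct else covs
    if include_icv:
        covs += " + icv"
    formula = f"y ~ {fe} + {covs}"

    converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(formula, data=df, groups=df["sample_id"])
        try:
            fit = model.fit(reml=reml)
            converged = bool(getattr(fit, "converged", True))
        except np.linalg.LinAlgError as exc:  # pragma: no cover - diagnostic path
            raise DegenerateDesignError(f"mixed model failed for '{outcome}': {exc}")

    rows = []
    fe_names = [t for t in fit.params.index if t not in ("Group Var",)]
    for t in fe_names:
        rows.append({
            "term": t, "beta": float(fit.params[t]), "se": float(fit.bse[t]),
            "p": float(fit.pvalues[t]), "n": int(len(df)),
            "n_groups": int(df["sample_id"].nunique()), "stratum": stratum,
            "aim": aim, "form": form, "outcome": outcome, "converged": converged,
            "re_var": float(fit.cov_re.iloc[0, 0]) if fit.cov_re.size else 0.0,
        })
    return pd.DataFrame(rows)


def key_term(form: str) -> str:
    """Name of the focal fixed effect for a model form."""
    return KEY_TERMS[form]


def fdr_adjust(
    estimates: pd.DataFrame,
    family_cols: tuple[str, ...] = ("aim", "form"),
) -> pd.DataFrame:
    """Benjamini-Hochberg q-values within each (aim, model-form) family.

    The step-up rule ``q_(i) = min_{j >= i} p_(j) m / j`` (capped at 1)
    is applied across outcomes within each family.
    """
    if "p" not in estimates.columns:
        raise SchemaError("estimates lack a 'p' column")
    out = estimates.copy()
    out["q"] = np.nan
    cols = [c for c in family_cols if c in out.columns]
    grouping = out.groupby(cols).groups.items() if cols else [((), out.index)]
    for _, idx in grouping:
        p = out.loc[idx, "p"].to_numpy(dtype=float)
        if np.isnan(p).any():
            raise SchemaError("p-values must be defined before FDR adjustment")
        out.loc[idx, "q"] = multipletests(p, method="fdr_bh")[1]
    return out


def variance_partition(
    data: pd.DataFrame,
    groups: dict[str, list[str]],
    outcome: str = "mps_z",
    max_exact_groups: int = 10,
    seed: int | None = None,
    n_perm: int = 2000,
) -> pd.DataFrame:
    """LMG / Shapley decomposition of the linear-model R^2 over predictor groups.

    Each group's share is its average incremental R^2 over all orderings
    of the groups; the residual component is ``1 - R^2_full`` so the
    fractions sum to one.  Exact enumeration is used up to
    ``max_exact_groups`` groups; beyond that a seeded permutation sample
    is required.
    """
    names = list(groups)
    k = len(names)
    cols_flat = [c for g in names for c in groups[g]]
    if len(set(cols_flat)) != len(cols_flat):
        raise SchemaError("predictor groups must be disjoint")
    df = data.dropna(subset=[outcome, *cols_flat])
    y = df[outcome].to_numpy(dtype=float)
    y = y - y.mean()
    tss = float(y @ y)
    if tss == 0:
        raise DegenerateDesignError("outcome has zero variance")

    def r2(subset: frozenset) -> float:
        cols = [c for g in subset for c in groups[g]]
        if not cols:
            return 0.0
        X = np.column_stack([np.ones(len(df))] + [df[c].to_numpy(dtype=float) for c in cols])
        resid = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]
        return 1.0 - float(resid @ resid) / tss

    cache: dict[frozenset, float] = {}

    def v(subset: frozenset) -> float:
        if subset not in cache:
            cache[subset] = r2(subset)
        return cache[subset]

    shares = dict.fromkeys(names, 0.0)
    if k <= max_exact_groups:
        for g in names:
            others = [x for x in names if x != g]
            for r in range(k):
                wgt = factorial(r) * factorial(k - r - 1) / factorial(k)
                for S in combinations(others, r):
                    fs = frozenset(S)
                    shares[g] += wgt * (v(fs | {g}) - v(fs))
    else:
        if seed is None:
            raise DegenerateDesignError(
                f"{k} groups exceed exact enumeration; pass a seed for sampling"
            )
        rng = np.random.default_rng(seed)
        for _ in range(n_perm):
            order = rng.permutation(names)
            acc: frozenset = frozenset()
            for g in order:
                shares[g] += (v(acc | {g}) - v(acc)) / n_perm
                acc = acc | {g}
    full = v(frozenset(names))
    rows = [{"component": g, "fraction": shares[g]} for g in names]
    rows.append({"component": "residual", "fraction": 1.0 - full})
    return pd.DataFrame(rows)


def sensitivity_child_outcomes(
    data: pd.DataFrame,
    stratum: str,
    cell_cols: tuple[str, ...] = (),
    adjust_cells: bool = True,
) -> pd.DataFrame:
    """Childhood inflammatory outcomes: logistic (asthma/allergy/eczema), linear (BMI-SDS)."""
    covs = AIM1_BASE_COVARIATES
    if adjust_cells and cell_cols:
        ct = _cell_terms(cell_cols)
        covs = f"{covs} + {ct}" if ct else covs
    rows = []
    for out_name, kind in (
        ("asthma", "logistic"), ("allergy", "logistic"),
        ("eczema", "logistic"), ("bmi_sds", "linear"),
    ):
        if out_name not in data.columns:
            continue
        sub = data.dropna(subset=[out_name, "mps_z"])
        formula = f"{out_name} ~ mps_z + {covs}"
        separation = False
        try:
            if kind == "logistic":
                if sub[out_name].nunique() < 2:
                    raise DegenerateDesignError(
                        f"'{out_name}' has a single level (prevalence 0 or 1)"
                    )
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    fit = smf.logit(formula, data=sub).fit(disp=0, maxiter=200)
                separation = not bool(fit.mle_retvals.get("converged", True))
            else:
                fit = smf.ols(formula, data=sub).fit()
        except (np.linalg.LinAlgError, sm.tools.sm_exceptions.PerfectSeparationError):
            rows.append({"term": "mps_z", "outcome": out_name, "beta": np.nan,
                         "se": np.nan, "p": np.nan, "n": len(sub),
                         "stratum": stratum, "aim": "sensitivity",
                         "form": kind, "separation": True})
            continue
        rows.append({
            "term": "mps_z", "outcome": out_name, "beta": float(fit.params["mps_z"]),
            "se": float(fit.bse["mps_z"]), "p": float(fit.pvalues["mps_z"]),
            "n": int(fit.nobs), "stratum": stratum, "aim": "sensitivity",
            "form": kind, "separation": separation,
        })
    return pd.DataFrame(rows)
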