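"""Cumulative prenatal clinical inflammatory scores and the PC-residualized PGS.

Five item-level panels are scored: prenatal infection (10 infection
types reported once per trimester, averaged across pregnancy), prenatal
stress (52 binary items in four domains: life events, contextual,
parental, interpersonal), lifestyle pro-inflammatory factors (6 items),
pregnancy-related inflammatory conditions (6 items) and inflammatory
medical conditions (5 items).  Each panel is a cumulative count of
present risks; missing items propagate to a missing score, to be
resolved by multiple imputation at item level followed by passive
re-derivation of the scores.

The polygenic score of CRP enters as a numeric column computed
elsewhere; here it is Z-scored and residualized on the first ten genetic
principal components within each genotyping subsample, then
standardized, so batch structure is removed before subsamples merge.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from mpscrp.errors import DegenerateDesignError, SchemaError

logger = logging.getLogger(__name__)

INFECTION_TYPES = (
    "upper_resp",
    "lower_resp",
    "gastro",
    "cystitis",
    "dermatitis",
    "eye",
    "herpes_zoster",
    "std",
    "flu",
    "fever",
)
TRIMESTERS = (1, 2, 3)

STRESS_DOMAINS = {
    "life_events": 12,
    "contextual": 14,
    "parental": 14,
    "interpersonal": 12,
}  # 52 items total

LIFESTYLE_ITEMS = (
    "obesity",          # pre-pregnancy BMI > 30
    "tobacco",          # any tobacco use before/during pregnancy
    "diet_high",        # diet sum score above the third quartile
    "psychotropic",     # psychotropic medication use
    "antiinflammatory", # anti-inflammatory / anti-infective medication
    "corticosteroid",
)
PREGNANCY_ITEMS = (
    "preeclampsia",
    "hypertension",
    "gest_diabetes",
    "prom",             # premature rupture of membranes
    "hellp",
    "caesarean",
)
MEDICAL_ITEMS = (
    "diabetes",
    "intestinal",
    "arthritis",
    "ms",
    "thyroid",
)

#: declared priority for collinearity pruning; later entries drop first
SCORE_PRIORITY = (
    "stress_score",
    "infection_score",
    "lifestyle_score",
    "pregnancy_score",
    "medical_score",
)


def infection_item_columns() -> list[str]:
    return [f"inf_{t}_t{tr}" for tr in TRIMESTERS for t in INFECTION_TYPES]


def stress_item_columns() -> list[str]:
    return [f"stress_{d}_{i + 1}" for d, n in STRESS_DOMAINS.items() for i in range(n)]


def lifestyle_item_columns() -> list[str]:
    return [f"life_{t}" for t in LIFESTYLE_ITEMS]


def pregnancy_item_columns() -> list[str]:
    return [f"preg_{t}" for t in PREGNANCY_ITEMS]


def medical_item_columns() -> list[str]:
    return [f"med_{t}" for t in MEDICAL_ITEMS]


def infection_score(items: pd.DataFrame) -> pd.Series:
    """Mean across trimesters of the per-trimester infection counts.

    Within each trimester the count sums the non-missing indicators; a
    trimester contributes to the mean only if at least one of its items
    was observed.  Dyads with no observed infection item in any
    trimester score missing.
    """
    per_tri = []
    for tr in TRIMESTERS:
        cols = [f"inf_{t}_t{tr}" for t in INFECTION_TYPES]
        _check_columns(items, cols)
        block = items[cols]
        s = block.sum(axis=1, min_count=1)  # NaN when nothing observed
        per_tri.append(s)
    tri = pd.concat(per_tri, axis=1)
    return tri.mean(axis=1).rename("infection_score")


def stress_score(items: pd.DataFrame) -> pd.Series:
    """Cumulative prenatal stress: four domain sums, then their total.

    Equivalent to the direct sum of all 52 items; any missing item makes
    the score missing (imputation happens upstream at item level).
    """
    domain_sums = []
    for d, n in STRESS_DOMAINS.items():
        cols = [f"stress_{d}_{i + 1}" for i in range(n)]
        _check_columns(items, cols)
        domain_sums.append(items[cols].sum(axis=1, skipna=False))
    return sum(domain_sums).rename("stress_score")


def cumulative_binary_score(
    indicators: pd.DataFrame, expected_len: int, name: str = "score"
) -> pd.Series:
    """Integer count of present (1) indicators over a fixed-length panel."""
    if indicators.shape[1] != expected_len:
        raise SchemaError(
            f"{name}: expected {expected_len} indicator columns, got {indicators.shape[1]}"
        )
    vals = indicators.to_numpy(dtype=float)
    ok = np.isnan(vals) | np.isin(vals, (0.0, 1.0))
    if not ok.all():
        raise SchemaError(f"{name}: indicators must be 0/1 or missing")
    return indicators.sum(axis=1, skipna=False).rename(name)


def derive_exposure_scores(items: pd.DataFrame) -> pd.DataFrame:
    """All five cumulative scores from an item-level wide table."""
    return pd.concat(
        [
            infection_score(items),
            stress_score(items),
            cumulative_binary_score(items[lifestyle_item_columns()], 6, "lifestyle_score"),
            cumulative_binary_score(items[pregnancy_item_columns()], 6, "pregnancy_score"),
            cumulative_binary_score(items[medical_item_columns()], 5, "medical_score"),
        ],
        axis=1,
    )


def residualize_pgs(
    gs: pd.DataFrame,
    pgs_col: str = "pgs_raw",
    pc_cols: tuple[str, ...] | None = None,
    subsample_col: str = "subsample",
) -> pd.DataFrame:
    """Z-score the PGS and residualize it on 10 genetic PCs per subsample.

    Within each genotyping subsample the raw PGS is standardized,
    regressed on the principal components (with intercept), and the
    residuals — re-standardized to unit variance — replace the score.
    The result is orthogonal to every PC within subsample, mean 0, and
    the operation is idempotent.
    """
    if pc_cols is None:
        pc_cols = tuple(f"pc{i}" for i in range(1, 11))
    out = gs.copy()
    resid_all = pd.Series(np.nan, index=gs.index, dtype=float)
    for sub, grp in gs.groupby(subsample_col):
        if len(grp) < len(pc_cols) + 2:
            raise DegenerateDesignError(
                f"subsample '{sub}' too small to residualize on {len(pc_cols)} PCs"
            )
        y = grp[pgs_col].to_numpy(dtype=float)
        y = (y - y.mean()) / y.std(ddof=1)
        X = np.column_stack([np.ones(len(grp))] + [grp[c].to_numpy(dtype=float) for c in pc_cols])
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise DegenerateDesignError(f"PC design singular in subsample '{sub}'")
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        r = y - X @ coef
        sd = r.std(ddof=1)
        # a near-zero residual SD means the PCs explain the PGS exactly;
        # rescaling would only amplify floating-point noise
        resid_all.loc[grp.index] = r / sd if sd > 1e-10 else r
    out["pgs_residualized"] = resid_all
    return out


def collinearity_prune(
    scores: pd.DataFrame,
    threshold: float = 0.9,
    priority: tuple[str, ...] = SCORE_PRIORITY,
) -> list[str]:
    """Drop the lower-priority member of any score pair with |r| > threshold.

    Returns the retained score names in priority order.  Mirrors the
    analytic choice of omitting the medical-conditions score when it
    tracks the pregnancy-conditions score almost perfectly.
    """
    if not (0 < threshold < 1):
        raise ValueError("threshold must be in (0, 1)")
    cols = [c for c in priority if c in scores.columns]
    if len(cols) < 2:
        return cols
    retained = list(cols)
    changed = True
    while changed:
        changed = False
        corr = scores[retained].corr().abs()
        for a_i in range(len(retained)):
            for b_i in range(a_i + 1, len(retained)):
                a, b = retained[a_i], retained[b_i]
                if corr.loc[a, b] > threshold:
                    logger.info(
                        "collinearity_prune: |r(%s, %s)| = %.3f > %.2f, dropping %s",
                        a, b, corr.loc[a, b], threshold, b,
                    )
                    retained.remove(b)  # b is later in priority order
                    changed = True
                    break
            if changed:
                break
    return retained


def _check_columns(df: pd.DataFrame, cols: list[str]) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"missing item columns: {missing[:5]}{'...' if len(missing) > 5 else ''}")
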