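"""Validation of the methylation profile score against serum CRP.

Serum CRP in cord blood is left-censored at the assay detection limit
(0.2 mg/L); censored observations are recorded at the limit with a
below-LOD flag.  Validation proceeds by (i) binarizing CRP at the
clinical neonatal-infection cut-off (> 1 mg/L) and computing the exact
Mann-Whitney ROC AUC of the Z-scored profile score against those labels,
per array subcohort; (ii) rank or product-moment correlations between
the score and CRP at each measurement occasion (below-LOD values enter
at the LOD constant, creating midrank-handled ties); (iii) tiered linear
regressions of the score on the CRP indicator (univariate, + batch,
+ batch + cell proportions) per array, suitable for inverse-variance
pooling; and (iv) per-CpG univariate screens with FDR control.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from mpscrp.errors import DegenerateDesignError, SchemaError
from mpscrp.scoring import MethylationMatrix, WeightTable

ADJUST_TIERS = ("univariate", "+batch", "+batch+cells")


@dataclass
class RocResult:
    auc: float
    n_pos: int
    n_neg: int
    se: float                 # Hanley-McNeil standard error
    threshold_rule: str = "value > cutoff (below-LOD = negative)"

    @property
    def ci95(self) -> tuple[float, float]:
        lo = self.auc - 1.959963984540054 * self.se
        hi = self.auc + 1.959963984540054 * self.se
        return (max(0.0, lo), min(1.0, hi))

    def p_greater_than_half(self) -> float:
        """One-sided normal p-value for AUC > 0.5."""
        if self.se == 0:
            return 0.0 if self.auc > 0.5 else 1.0
        return float(stats.norm.sf((self.auc - 0.5) / self.se))


def binarize_crp(crp: pd.DataFrame, cutoff: float = 1.0) -> pd.Series:
    """Binary labels: 1 iff CRP value exceeds the cutoff (strict).

    Below-LOD observations are labelled 0.  ``crp`` must carry
    ``value_mg_per_l``, ``below_lod`` and ``lod`` columns.
    """
    for col in ("value_mg_per_l", "below_lod", "lod"):
        if col not in crp.columns:
            raise SchemaError(f"CRP table lacks '{col}'")
    lod = float(crp["lod"].max())
    if cutoff <= lod:
        raise ValueError(f"cutoff {cutoff} must exceed the detection limit {lod}")
    labels = (crp["value_mg_per_l"].to_numpy(dtype=float) > cutoff) & ~crp[
        "below_lod"
    ].to_numpy(dtype=bool)
    out = pd.Series(labels.astype(int), name="crp_high")
    if "sample_id" in crp.columns:
        out.index = pd.Index(crp["sample_id"], name="sample_id")
    else:
        out.index = crp.index
    return out


def roc_auc(score, labels) -> RocResult:
    """Exact ROC AUC via the midrank Mann-Whitney statistic.

    ``AUC = P(score_pos > score_neg) + 0.5 P(tie)``, invariant under any
    strictly increasing transform of the score.
    """
    s = np.asarray(score, dtype=float)
    y = np.asarray(labels, dtype=int)
    if s.shape != y.shape:
        raise SchemaError("score and labels must align")
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise DegenerateDesignError("AUC undefined: one class is empty")
    ranks = stats.rankdata(s)
    auc = (ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
    # Hanley & McNeil (1982) variance approximation
    q1 = auc / (2 - auc)
    q2 = 2 * auc**2 / (1 + auc)
    var = (
        auc * (1 - auc) + (n_pos - 1) * (q1 - auc**2) + (n_neg - 1) * (q2 - auc**2)
    ) / (n_pos * n_neg)
    return RocResult(float(auc), n_pos, n_neg, float(np.sqrt(max(var, 0.0))))


def correlate_occasions(
    mps: pd.DataFrame, crp: pd.DataFrame, method: str = "spearman", min_pairs: int = 10
) -> pd.DataFrame:
    """Score-CRP correlation per measurement occasion (pairwise complete).

    Censored values enter at the LOD constant; ties are handled by
    midranks in the Spearman path, mirroring the skew caveat that the
    cord occasion carries.
    """
    if method not in ("spearman", "pearson"):
        raise ValueError("method must be 'spearman' or 'pearson'")
    rows = []
    for occ, grp in crp.groupby("occasion"):
        merged = grp.set_index("sample_id").join(mps[["z_score"]], how="inner").dropna(
            subset=["z_score", "value_mg_per_l"]
        )
        if len(merged) < min_pairs:
            continue
        x = merged["z_score"].to_numpy()
        y = merged["value_mg_per_l"].to_numpy()
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            raise DegenerateDesignError(f"constant vector at occasion '{occ}'")
        if method == "spearman":
            r, p = stats.spearmanr(x, y)
        else:
            r, p = stats.pearsonr(x, y)
        rows.append({"occasion": occ, "method": method, "estimate": float(r),
                     "p": float(p), "n": len(merged)})
    return pd.DataFrame(rows)


def mps_on_crp_regression(
    mps: pd.DataFrame,
    labels: pd.Series,
    adjust_tier: str = "univariate",
    plate: pd.Series | None = None,
    cells: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """OLS of the Z-scored score on the binary CRP indicator, tiered covariates.

    Tiers: ``univariate``; ``+batch`` adds plate dummies; ``+batch+cells``
    additionally adds cell proportions (one reference type dropped to
    avoid the simplex collinearity).  Returns one effect row per array
    stratum for downstream meta-analysis.
    """
    import statsmodels.api as sm

    if adjust_tier not in ADJUST_TIERS:
        raise ValueError(f"adjust_tier must be one of {ADJUST_TIERS}")
    rows = []
    for lab, grp in mps.groupby("array_label"):
        idx = grp.index.intersection(labels.index)
        y = grp.loc[idx, "z_score"].to_numpy(dtype=float)
        lab_vec = labels.loc[idx].to_numpy(dtype=float)
        if len(np.unique(lab_vec)) < 2:
            raise DegenerateDesignError(f"CRP indicator constant in stratum '{lab}'")
        X = [lab_vec]
        names = ["crp_high"]
        if adjust_tier in ("+batch", "+batch+cells"):
            if plate is None:
                raise SchemaError("plate labels required for batch adjustment")
            d = pd.get_dummies(plate.loc[idx], drop_first=True, dtype=float)
            for c in d.columns:
                X.append(d[c].to_numpy())
                names.append(f"plate[{c}]")
        if adjust_tier == "+batch+cells":
            if cells is None:
                raise SchemaError("cell proportions required for cell adjustment")
            cc = cells.loc[idx].iloc[:, 1:]  # drop the first (reference) cell type
            for c in cc.columns:
                X.append(cc[c].to_numpy(dtype=float))
                names.append(f"cell[{c}]")
        design = sm.add_constant(np.column_stack(X))
        if np.linalg.matrix_rank(design) < design.shape[1]:
            raise DegenerateDesignError(f"rank-deficient design in stratum '{lab}'")
        fit = sm.OLS(y, design).fit()
        rows.append({
            "term": "crp_high", "tier": adjust_tier, "beta": float(fit.params[1]),
            "se": float(fit.bse[1]), "p": float(fit.pvalues[1]),
            "n": int(len(idx)), "stratum": lab,
        })
    return pd.DataFrame(rows)


def per_cpg_screen(
    strata: list[tuple[MethylationMatrix, pd.Series]],
    weights: WeightTable,
) -> pd.DataFrame:
    """Univariate per-CpG regressions of methylation on the CRP indicator.

    Restricted to score probes available in every stratum (the common
    450K/EPIC set).  Per-stratum estimates are pooled by inverse-variance
    fixed effects and BH-adjusted over the probe family.  Zero-variance
    probes are flagged and excluded from the family.
    """
    import statsmodels.api as sm
    from statsmodels.stats.multitest import multipletests

    from mpscrp.pooling import ivw_meta

    common = set(weights.weights.index)
    for mat, _ in strata:
        common &= set(mat.cpg_ids)
    common = sorted(common)
    per_stratum = []
    flagged = []
    for mat, labels in strata:
        idx = mat.sample_ids.intersection(labels.index)
        lab_vec = labels.loc[idx].to_numpy(dtype=float)
        if np.unique(lab_vec).size < 2:
            # no CRP-positive samples in this stratum; nothing estimable
            continue
        design = sm.add_constant(lab_vec)
        for cg in common:
            y = mat.betas.loc[idx, cg].to_numpy(dtype=float)
            if np.ptp(y) == 0:
                flagged.append({"cpg_id": cg, "stratum": mat.array_label})
                continue
            yz = (y - y.mean()) / y.std(ddof=1)
            fit = sm.OLS(yz, design).fit()
            per_stratum.append({
                "term": cg, "beta": float(fit.params[1]), "se": float(fit.bse[1]),
                "p": float(fit.pvalues[1]), "n": len(idx), "stratum": mat.array_label,
            })
    if not per_stratum:
        return pd.DataFrame(columns=["term", "beta", "se", "p", "q", "n", "excluded"])
    df = pd.DataFrame(per_stratum)
    excluded = {f["cpg_id"] for f in flagged}
    pooled = ivw_meta(df[~df["term"].isin(excluded)])
    pooled = pooled.copy()
    pooled["q"] = multipletests(pooled["p"], method="fdr_bh")[1]
    pooled["excluded"] = False
    for cg in sorted(excluded):
        pooled = pd.concat(
            [pooled, pd.DataFrame([{"term": cg, "excluded": True}])], ignore_index=True
        )
    return pooled
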