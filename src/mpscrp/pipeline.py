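"""End-to-end orchestration: generate -> score -> validate -> analyze -> report.

Stages run in the order of the study's analysis overview: cohort
generation (or ingest), probe-level KNN imputation, profile-score
construction and per-array standardization, cell-type deconvolution,
exposure-score derivation and PGS residualization, validation against
serum CRP, chained-equations imputation feeding the aim-1 regressions
(Rubin-pooled per array, then inverse-variance meta-analyzed across
arrays), the aim-2/aim-3 mixed models in three forms, FDR adjustment
within each (aim, form) family, the variance partition, and the
sensitivity suite (no-cell-adjustment refits, childhood inflammatory
outcomes, extended-score rerun).

A single global seed fans out to per-stage derived seeds so each stage
is independently reproducible; all outputs are delimited text plus a
JSON manifest with per-file checksums.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from mpscrp import io as mio
from mpscrp import models, pooling, validation
from mpscrp import exposures as xp
from mpscrp.errors import ConfigError, MpsCrpError
from mpscrp.scoring import (
    MethylationMatrix,
    WeightTable,
    compute_mps,
    estimate_cell_proportions,
    knn_impute_probes,
    standardize_by_array,
)
from mpscrp.synthetic import (
    BRAIN_OUTCOMES,
    BRAIN_VOLUME_OUTCOMES,
    CBCL_OUTCOMES,
    GeneratorConfig,
    SyntheticCohort,
    generate_cohort,
    load_extended_weights,
    load_main_weights,
)

logger = logging.getLogger(__name__)

COVARIATE_COLS = (
    "sex", "plate", "income_high", "education", "maternal_age", "smoking",
    "parity", "gestational_age",
)


@dataclass
class RunConfig:
    """Configuration for one pipeline run (generator xor file input)."""

    generator: GeneratorConfig | None = None
    input_dir: str | None = None
    panel: str = "both"            # main | extended | both
    adjust_cells: bool = True
    seed: int = 0
    outdir: str = "mpscrp_run"
    knn_k: int = 10
    knn_rowmax: float = 0.5
    knn_colmax: float = 0.8
    mice_m: int = 5
    mice_iterations: int = 10
    crp_cutoff: float = 1.0
    collinearity_threshold: float = 0.9
    run_sensitivity: bool = True
    run_icv_sensitivity: bool = True
    run_extended_rerun: bool = True
    stages: str = "full"           # full | validate (stop after validation)
    verbosity: int = 1

    def __post_init__(self) -> None:
        if (self.generator is None) == (self.input_dir is None):
            raise ConfigError("specify exactly one input source: generator or input_dir")
        if self.panel not in ("main", "extended", "both"):
            raise ConfigError("panel must be main, extended or both")
        if self.stages not in ("full", "validate"):
            raise ConfigError("stages must be 'full' or 'validate'")


def stage_seed(base_seed: int, stage: str) -> int:
    """Per-stage seed derived from the global seed and the stage name."""
    return int((base_seed * 1000003 + zlib.crc32(stage.encode())) % 2**31)


def _analysis_frame(cohort: SyntheticCohort, mps: pd.DataFrame, cells: pd.DataFrame,
                    scores: pd.DataFrame, pgs: pd.Series | None) -> pd.DataFrame:
    df = cohort.pheno.copy()
    df["mps_z"] = mps["z_score"]
    df = df.join(cells.add_prefix("cell_"))
    df = df.join(scores)
    if pgs is not None:
        df["pgs_residualized"] = pgs
    return df


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns a dict of result tables plus the manifest."""
    t0 = time.time()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict = {}
    stage = "setup"
    try:
        # ---- ingest / generate --------------------------------------------
        stage = "generate"
        if config.generator is not None:
            gen_cfg = config.generator
            matrices, cohort, truth = generate_cohort(gen_cfg)
            results["ground_truth"] = truth
        else:
            matrices, cohort = _read_inputs(config.input_dir)
            truth = None

        # ---- probe imputation ---------------------------------------------
        stage = "impute_probes"
        for lab in list(matrices):
            if matrices[lab].betas.isna().to_numpy().any():
                matrices[lab] = knn_impute_probes(
                    matrices[lab], k=config.knn_k, rowmax=config.knn_rowmax,
                    colmax=config.knn_colmax,
                )

        # ---- scoring -------------------------------------------------------
        stage = "score"
        w_main = load_main_weights()
        w_ext = load_extended_weights() if config.panel in ("extended", "both") else None
        mps_main = None
        if config.panel in ("main", "both"):
            mps_main = standardize_by_array(
                pd.concat([compute_mps(m, w_main) for m in matrices.values()])
            )
        mps_ext = None
        if w_ext is not None:
            mps_ext = standardize_by_array(
                pd.concat([compute_mps(m, w_ext) for m in matrices.values()])
            )
        mps = mps_main if mps_main is not None else mps_ext
        results["mps"] = mps
        results["mps_extended"] = mps_ext

        # ---- cell proportions ---------------------------------------------
        stage = "cell_proportions"
        cells = pd.concat(
            [estimate_cell_proportions(m, cohort.reference) for m in matrices.values()]
        ).reindex(cohort.pheno.index)
        results["cell_proportions"] = cells
        cell_cols = tuple(f"cell_{c}" for c in cells.columns)

        # ---- exposure & genetic scores ------------------------------------
        stage = "exposure_scores"
        scores = xp.derive_exposure_scores(cohort.pheno)
        pgs = None
        if "pgs_raw" in cohort.pheno.columns:
            pgs = xp.residualize_pgs(cohort.pheno)["pgs_residualized"]
        retained = xp.collinearity_prune(scores, threshold=config.collinearity_threshold)
        results["retained_scores"] = retained
        frame = _analysis_frame(cohort, mps, cells, scores, pgs)

        # ---- validation ----------------------------------------------------
        stage = "validate"
        results["validation"] = _run_validation(config, matrices, cohort, mps, mps_ext,
                                                cells, frame)

        # ---- multiple imputation + aim 1 ----------------------------------
        if config.stages == "validate":
            stage = "report"
            _write_outputs(out, config, cohort, results)
            report = render_report(results)
            (out / "report.md").write_text(report)
            results["report"] = report
            results["manifest"] = _build_manifest(out, config, t0)
            with open(out / "manifest.json", "w") as f:
                json.dump(results["manifest"], f, indent=1, sort_keys=True)
            return results

        stage = "aim1"
        results["aim1"], completed = _run_aim1(config, frame, retained, cell_cols)

        stage = "variance_partition"
        results["variance_partition"] = _run_variance_partition(
            frame, completed, retained, cell_cols
        )

        # ---- aims 2 and 3 --------------------------------------------------
        stage = "aim2"
        results["aim2"] = _run_longitudinal(
            config, frame, cohort.brain, BRAIN_OUTCOMES, "aim2", "none", cell_cols
        )
        if config.run_icv_sensitivity and not cohort.brain.empty:
            results["aim2_icv"] = _run_longitudinal(
                config, frame, cohort.brain, BRAIN_VOLUME_OUTCOMES, "aim2_icv", "none",
                cell_cols, forms=("main", "by_age"), include_icv=True,
            )
        stage = "aim3"
        results["aim3"] = _run_longitudinal(
            config, frame, cohort.cbcl, CBCL_OUTCOMES, "aim3", "sqrt", cell_cols
        )

        # ---- sensitivity suite --------------------------------------------
        stage = "sensitivity"
        if config.run_sensitivity:
            results["sensitivity"] = _run_sensitivity(
                config, frame, cohort, retained, cell_cols, mps_ext
            )

        # ---- report & manifest --------------------------------------------
        stage = "report"
        _write_outputs(out, config, cohort, results)
        report = render_report(results)
        (out / "report.md").write_text(report)
        results["report"] = report
        results["manifest"] = _build_manifest(out, config, t0)
        with open(out / "manifest.json", "w") as f:
            json.dump(results["manifest"], f, indent=1, sort_keys=True)
    except MpsCrpError as exc:
        raise MpsCrpError(
            f"stage '{stage}' failed: {exc}. "
            f"Check the inputs listed in the config for this stage."
        ) from exc
    return results


def _read_inputs(input_dir) -> tuple[dict, SyntheticCohort]:
    d = Path(input_dir)
    matrices = {}
    for lab in ("450k", "epic"):
        p = d / f"betas_{lab}.csv"
        if p.exists():
            matrices[lab] = mio.read_beta_matrix(p, lab)
    if not matrices:
        raise ConfigError(f"no beta matrices found under {d}")
    cohort = SyntheticCohort(
        pheno=pd.read_csv(d / "pheno_wide.csv", index_col=0),
        crp=pd.read_csv(d / "crp_long.csv"),
        brain=pd.read_csv(d / "brain_long.csv"),
        cbcl=pd.read_csv(d / "cbcl_long.csv"),
        reference=mio.read_reference(d / "cell_reference.csv"),
    )
    return matrices, cohort


def _run_validation(config, matrices, cohort, mps, mps_ext, cells, frame) -> dict:
    res: dict = {}
    cord = cohort.crp[cohort.crp["occasion"] == "cord_birth"]
    labels = validation.binarize_crp(cord, cutoff=config.crp_cutoff)

    roc_rows = []
    for score_name, score_df in (("main", mps), ("extended", mps_ext)):
        if score_df is None:
            continue
        aucs = []
        for lab, grp in score_df.groupby("array_label"):
            idx = grp.index.intersection(labels.index)
            y = labels.loc[idx]
            if y.nunique() < 2:
                continue
            r = validation.roc_auc(grp.loc[idx, "z_score"], y)
            aucs.append(r.auc)
            roc_rows.append({"score": score_name, "stratum": lab, "auc": r.auc,
                             "se": r.se, "n_pos": r.n_pos, "n_neg": r.n_neg,
                             "p_vs_chance": r.p_greater_than_half()})
        if aucs:
            roc_rows.append({"score": score_name, "stratum": "average",
                             "auc": float(np.mean(aucs)), "se": np.nan,
                             "n_pos": np.nan, "n_neg": np.nan, "p_vs_chance": np.nan})
    res["roc"] = pd.DataFrame(roc_rows)

    res["correlations"] = validation.correlate_occasions(mps, cohort.crp, "spearman")

    from mpscrp.errors import DegenerateDesignError

    tiers = []
    for tier in validation.ADJUST_TIERS:
        if tier == "+batch+cells" and not config.adjust_cells:
            continue
        per_stratum = []
        for lab in mps["array_label"].unique():
            sub = mps[mps["array_label"] == lab]
            try:
                per_stratum.append(validation.mps_on_crp_regression(
                    sub, labels, adjust_tier=tier,
                    plate=cohort.pheno["plate"], cells=cells,
                ))
            except DegenerateDesignError as exc:
                logger.warning("validation tier '%s' skipped in '%s': %s",
                               tier, lab, exc)
        if per_stratum:
            est = pd.concat(per_stratum, ignore_index=True)
            tiers.append(est)
            tiers.append(pooling.ivw_meta(est))
    res["regression_tiers"] = (
        pd.concat(tiers, ignore_index=True) if tiers else pd.DataFrame()
    )

    strata = [(m, labels) for m in matrices.values()]
    res["per_cpg"] = validation.per_cpg_screen(strata, load_main_weights())

    if mps_ext is not None and mps is not mps_ext:
        from scipy import stats as sps

        r, p = sps.pearsonr(mps["z_score"], mps_ext["z_score"].reindex(mps.index))
        res["main_extended_pearson"] = {"r": float(r), "p": float(p), "n": len(mps)}
    return res


def _aim1_imputables(frame: pd.DataFrame) -> dict:
    cand = {
        "maternal_age": "continuous",
        "income_high": "binary",
        "education": "ordinal",
        "smoking": "ordinal",
        "parity": "ordinal",
    }
    for c in xp.lifestyle_item_columns() + xp.medical_item_columns():
        cand[c] = "binary"
    return {c: k for c, k in cand.items() if c in frame.columns}


def _run_aim1(config, frame, retained, cell_cols):
    imputable = _aim1_imputables(frame)
    needs_mi = any(frame[c].isna().any() for c in imputable)
    item_cols = [c for c in frame.columns if c.startswith(("inf_", "stress_", "life_",
                                                          "preg_", "med_"))]

    def passive(df):
        sc = xp.derive_exposure_scores(df)
        for c in sc.columns:
            df[c] = sc[c]
        return df

    per_stratum_rows = []
    completed_sets: dict[str, list[pd.DataFrame]] = {}
    for lab, grp in frame.groupby("array_label"):
        if needs_mi:
            spec = pooling.ImputationSet(
                variables=imputable, m=config.mice_m,
                iterations=config.mice_iterations,
                predictors=list(imputable) + ["mps_z", "sex", "gestational_age"],
                seed=stage_seed(config.seed, f"mice_{lab}"),
            )
            completed = pooling.mice_impute(grp, spec, passive=passive)
        else:
            completed = [grp]
        completed_sets[lab] = completed
        fits = pd.concat(
            [models.fit_aim1(d, retained, lab, cell_cols, config.adjust_cells)
             for d in completed],
            ignore_index=True,
        )
        if len(completed) > 1:
            pooled = pooling.rubin_pool(fits)
        else:
            pooled = fits
        per_stratum_rows.append(pooled)
    per_stratum = pd.concat(per_stratum_rows, ignore_index=True)
    meta = pooling.ivw_meta(per_stratum)
    meta = models.fdr_adjust(meta, family_cols=("aim", "form"))
    return {"per_stratum": per_stratum, "pooled": meta}, completed_sets


def _run_variance_partition(frame, completed_sets, retained, cell_cols):
    parts = []
    for lab, completed in completed_sets.items():
        df = completed[0]
        groups = {s: [s] for s in retained if df[s].notna().all()}
        if "pgs_residualized" in df.columns and df["pgs_residualized"].notna().all():
            groups["pgs"] = ["pgs_residualized"]
        groups["cell_proportions"] = list(cell_cols[1:])
        vp = models.variance_partition(df, groups, outcome="mps_z")
        vp["stratum"] = lab
        parts.append(vp)
    return pd.concat(parts, ignore_index=True)


def _run_longitudinal(config, frame, long_table, outcomes, aim, transform, cell_cols,
                      forms=("main", "by_age", "by_age_by_ga"), include_icv=False,
                      adjust_cells=None, mps_col="mps_z"):
    if long_table.empty:
        return {"per_stratum": pd.DataFrame(), "pooled": pd.DataFrame()}
    adjust_cells = config.adjust_cells if adjust_cells is None else adjust_cells
    keep = ["mps_z", "gestational_age", *COVARIATE_COLS, *cell_cols]
    if mps_col != "mps_z":
        keep = [c for c in keep if c != "mps_z"]
    base_cols = [c for c in dict.fromkeys(keep) if c in frame.columns]
    wide = frame[base_cols + ([mps_col] if mps_col not in base_cols else [])].copy()
    if mps_col != "mps_z":
        wide = wide.rename(columns={mps_col: "mps_z"})
    rows = []
    for lab, grp in frame.groupby("array_label"):
        merged = long_table.merge(
            wide.loc[grp.index].reset_index().rename(columns={"index": "sample_id"}),
            on="sample_id", how="inner",
        )
        if merged.empty:
            continue
        for outcome in outcomes:
            for form in forms:
                try:
                    fit = models.fit_longitudinal(
                        merged, outcome, form=form, transform=transform, stratum=lab,
                        aim=aim, cell_cols=cell_cols, adjust_cells=adjust_cells,
                        include_icv=include_icv,
                    )
                except MpsCrpError as exc:
                    logger.warning("%s %s/%s in %s skipped: %s", aim, outcome, form,
                                   lab, exc)
                    continue
                key = models.key_term(form)
                rows.append(fit[fit["term"] == key])
    if not rows:
        return {"per_stratum": pd.DataFrame(), "pooled": pd.DataFrame()}
    per_stratum = pd.concat(rows, ignore_index=True)
    meta = pooling.ivw_meta(per_stratum)
    meta = models.fdr_adjust(meta, family_cols=("aim", "form"))
    return {"per_stratum": per_stratum, "pooled": meta}


def _run_sensitivity(config, frame, cohort, retained, cell_cols, mps_ext) -> dict:
    sens: dict = {}
    # (i) refits without cell-type adjustment
    nocell_aim1 = pd.concat(
        [models.fit_aim1(grp.dropna(subset=retained), retained, lab, cell_cols,
                         adjust_cells=False)
         for lab, grp in frame.groupby("array_label")],
        ignore_index=True,
    )
    sens["aim1_nocell"] = models.fdr_adjust(pooling.ivw_meta(nocell_aim1),
                                            family_cols=("aim", "form"))
    sens["aim2_nocell"] = _run_longitudinal(
        config, frame, cohort.brain, BRAIN_OUTCOMES, "aim2_nocell", "none", cell_cols,
        adjust_cells=False,
    )["pooled"]
    sens["aim3_nocell"] = _run_longitudinal(
        config, frame, cohort.cbcl, CBCL_OUTCOMES, "aim3_nocell", "sqrt", cell_cols,
        adjust_cells=False,
    )["pooled"]

    # (ii) childhood inflammatory outcomes
    child = pd.concat(
        [models.sensitivity_child_outcomes(grp, lab, cell_cols, config.adjust_cells)
         for lab, grp in frame.groupby("array_label")],
        ignore_index=True,
    )
    sens["child_outcomes"] = child

    # (iii) extended-score rerun
    if config.run_extended_rerun and mps_ext is not None:
        frame_ext = frame.copy()
        frame_ext["mps_z"] = mps_ext["z_score"].reindex(frame.index)
        ext_aim1 = pd.concat(
            [models.fit_aim1(grp.dropna(subset=retained), retained, lab, cell_cols,
                             config.adjust_cells)
             for lab, grp in frame_ext.groupby("array_label")],
            ignore_index=True,
        )
        sens["aim1_extended"] = models.fdr_adjust(pooling.ivw_meta(ext_aim1),
                                                  family_cols=("aim", "form"))
        sens["aim2_extended"] = _run_longitudinal(
            config, frame_ext, cohort.brain, BRAIN_OUTCOMES, "aim2_ext", "none",
            cell_cols,
        )["pooled"]
        sens["aim3_extended"] = _run_longitudinal(
            config, frame_ext, cohort.cbcl, CBCL_OUTCOMES, "aim3_ext", "sqrt",
            cell_cols,
        )["pooled"]
    return sens


def _write_outputs(out: Path, config, cohort, results) -> None:
    cohort.write(out / "inputs")
    results["mps"].to_csv(out / "mps_scores.csv")
    if results.get("mps_extended") is not None:
        results["mps_extended"].to_csv(out / "mps_scores_extended.csv")
    results["cell_proportions"].to_csv(out / "cell_proportions.csv")
    val = results.get("validation", {})
    for name in ("roc", "correlations", "regression_tiers", "per_cpg"):
        if name in val and isinstance(val[name], pd.DataFrame):
            val[name].to_csv(out / f"validation_{name}.csv", index=False)
    for aim in ("aim1", "aim2", "aim2_icv", "aim3"):
        block = results.get(aim)
        if isinstance(block, dict):
            for part, df in block.items():
                if isinstance(df, pd.DataFrame) and not df.empty:
                    df.to_csv(out / f"{aim}_{part}.csv", index=False)
    if isinstance(results.get("variance_partition"), pd.DataFrame):
        results["variance_partition"].to_csv(out / "variance_partition.csv", index=False)
    for name, df in (results.get("sensitivity") or {}).items():
        if isinstance(df, pd.DataFrame) and not df.empty:
            df.to_csv(out / f"sensitivity_{name}.csv", index=False)


def _build_manifest(out: Path, config, t0: float) -> dict:
    cfg = asdict(config)
    cfg.pop("outdir", None)   # run location must not change the config identity
    cfg.pop("input_dir", None)
    if cfg.get("generator"):
        cfg["generator"] = {k: (list(v) if isinstance(v, tuple) else v)
                            for k, v in cfg["generator"].items()}
    cfg_text = json.dumps(cfg, sort_keys=True, default=str)
    checksums = {}
    counts = {}
    for p in sorted(out.rglob("*.csv")):
        rel = str(p.relative_to(out))
        data = p.read_bytes()
        checksums[rel] = hashlib.sha256(data).hexdigest()
        counts[rel] = data.count(b"\n")
    return {
        "config_hash": hashlib.sha256(cfg_text.encode()).hexdigest(),
        "seed": config.seed,
        "started_at": time.strftime("%Y-%m-%dT%H:%M:%S", time.gmtime(t0)),
        "checksums": checksums,
        "row_counts": counts,
        "weight_tables": {"main": "weights_main7_synthetic",
                          "extended": "weights_extended150_synthetic"},
        "elapsed_s": round(time.time() - t0, 2),
    }


def render_report(results: dict) -> str:
    """Human-readable summary of a completed run (markdown)."""
    lines = ["# MPS-CRP pipeline report", ""]
    val = results.get("validation", {})
    if "roc" in val and not val["roc"].empty:
        lines += ["## Validation: ROC against cord CRP (> 1 mg/L)", "",
                  val["roc"].to_string(index=False), ""]
    if "correlations" in val and not val["correlations"].empty:
        lines += ["## Score-CRP correlations by occasion", "",
                  val["correlations"].to_string(index=False), ""]
    if "main_extended_pearson" in val:
        r = val["main_extended_pearson"]
        lines += [f"Main vs extended score: Pearson r = {r['r']:.3f} (n = {r['n']})", ""]
    for aim, title in (("aim1", "Aim 1: prenatal predictors"),
                       ("aim2", "Aim 2: brain outcomes"),
                       ("aim3", "Aim 3: behavioral outcomes")):
        block = results.get(aim)
        if isinstance(block, dict) and isinstance(block.get("pooled"), pd.DataFrame) \
                and not block["pooled"].empty:
            cols = [c for c in ("term", "outcome", "form", "beta", "se", "p", "q")
                    if c in block["pooled"].columns]
            lines += [f"## {title} (pooled)", "",
                      block["pooled"][cols].round(4).to_string(index=False), ""]
    vp = results.get("variance_partition")
    if isinstance(vp, pd.DataFrame) and not vp.empty:
        lines += ["## Variance partition of the score", "",
                  vp.round(4).to_string(index=False), ""]
    sens = results.get("sensitivity")
    if sens:
        lines += ["## Sensitivity analyses", ""]
        for name, df in sens.items():
            if isinstance(df, pd.DataFrame) and not df.empty:
                lines.append(f"- {name}: {len(df)} rows")
        lines.append("")
    else:
        lines += ["## Sensitivity analyses", "", "(section skipped)", ""]
    return "\n".join(lines)
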