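"""Synthetic birth-cohort generator with known ground truth.

Emulates the statistical structure of a large population-based
mother-child cohort in which cord-blood DNA methylation was assayed on
two non-overlapping array subcohorts (450K and EPIC): a latent
inflammation factor loads on the CRP-score CpGs and on log-normal serum
CRP left-censored at the assay detection limit (0.2 mg/L, ~94 % of cord
samples below it); Dirichlet cell-type proportions perturb beta values
through a reference-profile mixture; plate effects add batch structure;
item-level prenatal exposures feed cumulative risk scores; and brain /
behavioral outcomes follow random-intercept models with configurable
score-linked slopes.

Every stochastic quantity derives from a single seeded generator, so a
fixed seed reproduces the cohort byte for byte.  Effect sizes are
specified on the scale on which the analysis reports them (standardized
betas per SD of the Z-scored profile score), and the generator
calibrates its internal loadings so those targets hold by construction,
making parameter-recovery tests meaningful.
"""

from __future__ import annotations

import importlib.resources
import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

from mpscrp import exposures as xp
from mpscrp.errors import ConfigError
from mpscrp.scoring import (
    ARRAY_450K,
    ARRAY_EPIC,
    CORD_CELL_TYPES,
    MethylationMatrix,
    WeightTable,
)

BRAIN_VOLUME_OUTCOMES = (
    "total_brain_volume",
    "gray_matter_volume",
    "white_matter_volume",
    "brain_stem_volume",
    "hippocampus_volume",
    "amygdala_volume",
    "lateral_ventricles_volume",
    "cerebellum_volume",
)
BRAIN_DTI_OUTCOMES = ("global_md", "global_fa")
BRAIN_OUTCOMES = BRAIN_VOLUME_OUTCOMES + BRAIN_DTI_OUTCOMES
CBCL_OUTCOMES = ("cbcl_total", "cbcl_internalizing", "cbcl_externalizing")
CRP_OCCASIONS = ("maternal_t1", "maternal_t2", "cord_birth", "child_5y")


def load_main_weights() -> WeightTable:
    """Packaged 7-probe weight table (synthetic stand-in for the published weights)."""
    path = importlib.resources.files("mpscrp.data") / "weights_main7_synthetic.tsv"
    return WeightTable.from_file(path, source_tag="main7")


def load_extended_weights() -> WeightTable:
    """Packaged 150-probe extended panel stand-in (6/7 main probes shared)."""
    path = importlib.resources.files("mpscrp.data") / "weights_extended150_synthetic.tsv"
    return WeightTable.from_file(path, source_tag="extended150")


@dataclass
class GeneratorConfig:
    """Study conditions for one synthetic cohort draw.

    Defaults mirror the emulated study: 2,338 dyads split 1,367 / 971
    between the 450K and EPIC subcohorts, cord CRP censored at
    0.2 mg/L with 94 % below the limit, a 7-probe main score plus a
    150-probe extended stand-in panel, 7 cord-blood cell types, and the
    reported standardized effect sizes as generating defaults (lifestyle
    score -> MPS 0.033; MPS x age on global FA -0.014 SD/yr, amygdala
    0.016, cerebellum -0.007; MPS main effect on cerebellum -0.085).
    """

    n_total: int = 2338
    array_split: float = 1367 / 2338
    n_plates: int = 12
    n_filler: int = 40
    n_reference: int = 200
    n_celltypes: int = 7
    dirichlet_alpha: tuple[float, ...] | None = None  # granulocyte-dominant default
    use_extended: bool = True

    # beta-value variance components
    score_cell_sd: float = 0.15   # spread of score/filler probe means across cell types
    plate_sd: float = 0.01
    probe_noise_sd: float = 0.02

    # latent-inflammation share of the raw main (extended) score variance
    inflammation_score_r2: float = 0.2
    extended_score_r2: float = 0.08

    # serum CRP model
    crp_lod: float = 0.2
    below_lod_target: float = 0.94
    crp_log_sd: float = 3.0
    crp_log_mean: float | None = None  # derived from below_lod_target when None
    inflammation_crp_loading: float = 0.7
    pgs_crp_loading: float = 0.25      # maternal / child-5y CRP on the PGS
    maternal_log_mean: float = 1.2
    maternal_log_sd: float = 0.8
    child_log_mean: float = 0.3
    child_log_sd: float = 1.0

    # standardized effects on the Z-scored MPS (per SD of each Z-scored predictor)
    score_effects: dict = field(
        default_factory=lambda: {
            "stress_score": 0.0,
            "infection_score": 0.0,
            "lifestyle_score": 0.033,
            "pregnancy_score": 0.0,
            "medical_score": 0.0,
        }
    )
    pgs_mps_effect: float = 0.0

    # longitudinal outcomes: standardized main effects and per-year age interactions
    brain_main_effects: dict = field(default_factory=lambda: {"cerebellum_volume": -0.085})
    brain_age_effects: dict = field(
        default_factory=lambda: {
            "global_fa": -0.014,
            "amygdala_volume": 0.016,
            "cerebellum_volume": -0.007,
        }
    )
    cbcl_main_effects: dict = field(default_factory=dict)
    cbcl_age_effects: dict = field(default_factory=dict)
    child_outcome_effects: dict = field(default_factory=dict)  # logit / linear slopes

    include_brain: bool = True
    include_cbcl: bool = True
    include_child_outcomes: bool = True
    brain_fraction: float = 0.62
    brain_ages: tuple = ((9.8, 0.5), (13.8, 0.5))
    brain_occasion_dropout: tuple = (0.12, 0.22)
    cbcl_ages: tuple = (1.5, 3.0, 6.0, 10.0, 14.0)
    cbcl_missing_rate: float = 0.2
    random_intercept_var: float = 0.5
    brain_age_slope: float = 0.05      # secular change, SD/yr
    cbcl_age_slope: float = -0.08      # sqrt-scale change per year

    # exposure item prevalences
    infection_prev: float = 0.08
    stress_prev: float = 0.10
    lifestyle_prev: tuple = (0.10, 0.25, 0.25, 0.03, 0.30, 0.04)
    pregnancy_prev: tuple = (0.02, 0.04, 0.01, 0.03, 0.005, 0.14)
    medical_prev: tuple = (0.01, 0.02, 0.01, 0.002, 0.03)

    # missingness injected at the end of generation (MCAR)
    probe_missing_rate: float = 0.0
    covariate_missing_rate: float = 0.0

    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.array_split < 1):
            raise ConfigError("array_split must be in (0, 1)")
        if not (0 < self.below_lod_target < 1):
            raise ConfigError("below_lod_target must be in (0, 1)")
        for name in ("probe_missing_rate", "covariate_missing_rate", "cbcl_missing_rate",
                     "brain_fraction", "infection_prev", "stress_prev"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ConfigError(f"{name} must be in [0, 1]")
        if not (0 <= self.inflammation_score_r2 < 1):
            raise ConfigError("inflammation_score_r2 must be in [0, 1)")
        if self.inflammation_score_r2 == 0 and any(v != 0 for v in self.score_effects.values()):
            raise ConfigError(
                "score_effects require a nonzero inflammation_score_r2 to be expressible"
            )
        if self.crp_log_mean is not None:
            implied = stats.norm.cdf(
                (np.log(self.crp_lod) - self.crp_log_mean) / self.crp_log_sd
            )
            if abs(implied - self.below_lod_target) > 0.02:
                raise ConfigError(
                    f"crp_log_mean implies a below-LOD fraction of {implied:.3f}, "
                    f"inconsistent with below_lod_target={self.below_lod_target}"
                )
        if self.n_celltypes < 2:
            raise ConfigError("need at least 2 cell types")
        if self.dirichlet_alpha is not None and len(self.dirichlet_alpha) != self.n_celltypes:
            raise ConfigError("dirichlet_alpha length must equal n_celltypes")


@dataclass
class GroundTruth:
    """Hidden generating quantities kept aside for recovery tests."""

    latent_inflammation: pd.Series
    true_cell_proportions: pd.DataFrame
    mps_z: pd.Series              # generator's own Z-scored main score (outcome driver)
    true_effects: dict

    def to_json(self, path) -> None:
        payload = {
            "true_effects": self.true_effects,
            "latent_inflammation": self.latent_inflammation.round(6).to_dict(),
        }
        with open(path, "w") as f:
            json.dump(payload, f, indent=1, sort_keys=True)


@dataclass
class SyntheticCohort:
    """Phenotype bundle: wide per-dyad table plus long repeated-measure tables."""

    pheno: pd.DataFrame       # per dyad: covariates, exposure items, PGS, child outcomes
    crp: pd.DataFrame         # long: sample_id, occasion, value_mg_per_l, below_lod, lod
    brain: pd.DataFrame       # long: sample_id, occasion, age, icv, 10 outcomes
    cbcl: pd.DataFrame        # long: sample_id, occasion, age, 3 scales
    reference: pd.DataFrame   # CpG x cell type mean-beta reference panel

    def write(self, outdir) -> None:
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.pheno.to_csv(outdir / "pheno_wide.csv")
        self.crp.to_csv(outdir / "crp_long.csv", index=False)
        self.brain.to_csv(outdir / "brain_long.csv", index=False)
        self.cbcl.to_csv(outdir / "cbcl_long.csv", index=False)
        self.reference.to_csv(outdir / "cell_reference.csv")


def _default_alpha(n_celltypes: int) -> np.ndarray:
    # granulocyte-dominant cord blood; concentration ~40 gives realistic spread
    base = np.array([22.0, 3.5, 2.0, 4.5, 2.5, 1.5, 4.0])
    if n_celltypes == 7:
        return base
    if n_celltypes < 7:
        return base[:n_celltypes]
    extra = np.full(n_celltypes - 7, 1.0)
    return np.concatenate([base, extra])


def _safe_z(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=1)
    if not np.isfinite(sd) or sd == 0:
        return np.zeros_like(x, dtype=float)
    return (x - x.mean()) / sd


def generate_cohort(
    config: GeneratorConfig,
) -> tuple[dict[str, MethylationMatrix], SyntheticCohort, GroundTruth]:
    """Draw one full synthetic cohort.

    Returns per-array methylation matrices, the phenotype bundle, and
    the ground truth used in generation.
    """
    cfg = config
    rng = np.random.default_rng(cfg.rng_seed)
    n = cfg.n_total
    ids = pd.Index([f"id_{i + 1:06d}" for i in range(n)], name="sample_id")
    n_a = int(round(n * cfg.array_split))
    array_label = np.array([ARRAY_450K] * n_a + [ARRAY_EPIC] * (n - n_a))
    plate = np.array([f"plate{p:02d}" for p in rng.integers(0, cfg.n_plates, size=n)])

    celltypes = list(CORD_CELL_TYPES[: cfg.n_celltypes]) + [
        f"cell{i}" for i in range(max(0, cfg.n_celltypes - len(CORD_CELL_TYPES)))
    ]
    alpha = np.asarray(cfg.dirichlet_alpha if cfg.dirichlet_alpha is not None
                       else _default_alpha(cfg.n_celltypes), dtype=float)
    P = rng.dirichlet(alpha, size=n)  # n x c

    # ---- probe panel -------------------------------------------------------
    w_main = load_main_weights()
    main_ids = list(w_main.weights.index)
    if cfg.use_extended:
        w_ext = load_extended_weights()
        ext_ids = list(w_ext.weights.index)
    else:
        w_ext, ext_ids = None, []
    ext_only = [c for c in ext_ids if c not in main_ids]
    ref_ids = [f"cg_r{i + 1:07d}" for i in range(cfg.n_reference)]
    fill_ids = [f"cg_f{i + 1:07d}" for i in range(cfg.n_filler)]
    panel = main_ids + ext_only + ref_ids + fill_ids
    J = len(panel)

    # cell-type mean-beta profiles: reference probes get strongly
    # discriminating profiles (well-posed deconvolution); score and
    # filler probes vary more gently around a common mean
    c = cfg.n_celltypes
    profiles = np.empty((J, c))
    n_sc = len(main_ids) + len(ext_only)
    base = rng.uniform(0.3, 0.7, size=n_sc + cfg.n_filler)
    gentle = np.clip(
        base[:, None] + rng.normal(0, cfg.score_cell_sd, size=(n_sc + cfg.n_filler, c)),
        0.02, 0.98,
    )
    profiles[:n_sc] = gentle[:n_sc]
    profiles[n_sc + cfg.n_reference:] = gentle[n_sc:]
    profiles[n_sc: n_sc + cfg.n_reference] = rng.uniform(0.05, 0.95, size=(cfg.n_reference, c))
    reference = pd.DataFrame(profiles[n_sc: n_sc + cfg.n_reference], index=ref_ids,
                             columns=celltypes)

    # ---- beta components ---------------------------------------------------
    mix = P @ profiles.T                                    # n x J cell-mixture means
    plate_levels = sorted(set(plate))
    plate_fx = rng.normal(0, cfg.plate_sd, size=(len(plate_levels), J))
    plate_idx = np.searchsorted(plate_levels, plate)
    noise = rng.normal(0, cfg.probe_noise_sd, size=(n, J))
    betas = mix + plate_fx[plate_idx] + noise

    # ---- exposures, PGS, covariates ---------------------------------------
    items = _draw_exposure_items(rng, n, cfg, ids)
    scores = xp.derive_exposure_scores(items)
    subsample = np.where(rng.random(n) < 0.5, "g1", "g2")
    pgs_raw = rng.normal(0, 1, size=n) + np.where(subsample == "g1", 0.15, -0.15)
    pcs = rng.normal(0, 1, size=(n, 10))

    # ---- latent inflammation ----------------------------------------------
    r2 = cfg.inflammation_score_r2
    b = {}
    if r2 > 0:
        for s, t in cfg.score_effects.items():
            b[s] = t / np.sqrt(r2)
        b["pgs"] = cfg.pgs_mps_effect / np.sqrt(r2)
    else:
        b = {s: 0.0 for s in cfg.score_effects} | {"pgs": 0.0}
    lin = np.zeros(n)
    for s, coef in b.items():
        if coef == 0.0:
            continue
        col = _safe_z(pgs_raw) if s == "pgs" else _safe_z(scores[s].to_numpy(dtype=float))
        lin += coef * col
    resid_var = max(1.0 - float(np.sum([v**2 for v in b.values()])), 1e-6)
    eta = lin + np.sqrt(resid_var) * rng.normal(0, 1, size=n)

    # calibrate CpG loadings so latent inflammation owns the configured
    # share of raw-score variance: a = sqrt(r2/(1-r2)) * sd(noise part)
    w = w_main.weights.to_numpy(dtype=float)
    col_ix = [panel.index(cg) for cg in main_ids]
    M = betas[:, col_ix] @ w
    sd_m = M.std(ddof=1)
    if r2 > 0:
        a = np.sqrt(r2 / (1.0 - r2)) * sd_m
        loadings = a * w / float(w @ w)
        betas[:, col_ix] += np.outer(eta, loadings)
    else:
        a, loadings = 0.0, np.zeros_like(w)

    if cfg.use_extended and cfg.extended_score_r2 > 0 and ext_only:
        we = w_ext.weights.loc[ext_only].to_numpy(dtype=float)
        eix = [panel.index(cg) for cg in ext_only]
        Me = betas[:, eix] @ we
        ae = np.sqrt(cfg.extended_score_r2 / (1 - cfg.extended_score_r2)) * Me.std(ddof=1)
        betas[:, eix] += np.outer(eta, ae * we / float(we @ we))

    betas = np.clip(betas, 0.0, 1.0)

    # generator's own view of the analysis score (drives the outcomes)
    raw_score = betas[:, col_ix] @ w
    mps_z = np.empty(n)
    for lab in (ARRAY_450K, ARRAY_EPIC):
        m = array_label == lab
        if m.sum() >= 2:
            mps_z[m] = _safe_z(raw_score[m])
        else:
            mps_z[m] = 0.0

    # ---- serum CRP ---------------------------------------------------------
    crp = _draw_crp(rng, cfg, eta, _safe_z(pgs_raw), ids)

    # ---- covariates (baseline demographics) -------------------------------
    pheno = pd.DataFrame(index=ids)
    pheno["array_label"] = array_label
    pheno["plate"] = plate
    pheno["sex"] = rng.binomial(1, 0.505, size=n)                      # 1 = female
    pheno["gestational_age"] = np.clip(rng.normal(40.1, 1.5, size=n), 25, 43)
    pheno["maternal_age"] = rng.normal(31.5, 4.3, size=n)
    pheno["parity"] = rng.choice([0, 1, 2], size=n, p=[0.55, 0.30, 0.15])
    pheno["smoking"] = rng.choice([0, 1, 2], size=n, p=[0.751, 0.094, 0.155])
    pheno["income_high"] = rng.binomial(1, 0.744, size=n)
    pheno["education"] = rng.choice([0, 1, 2], size=n, p=[0.031, 0.347, 0.622])
    pheno = pd.concat([pheno, items], axis=1)
    pheno["subsample"] = subsample
    pheno["pgs_raw"] = pgs_raw
    for i in range(10):
        pheno[f"pc{i + 1}"] = pcs[:, i]

    head_size = rng.normal(0, 1, size=n)

    # ---- longitudinal outcomes --------------------------------------------
    brain = _draw_brain(rng, cfg, ids, mps_z, head_size) if cfg.include_brain else pd.DataFrame(
        columns=["sample_id", "occasion", "age", "icv", *BRAIN_OUTCOMES]
    )
    cbcl = _draw_cbcl(rng, cfg, ids, mps_z) if cfg.include_cbcl else pd.DataFrame(
        columns=["sample_id", "occasion", "age", *CBCL_OUTCOMES]
    )

    if cfg.include_child_outcomes:
        eff = cfg.child_outcome_effects
        for name, prev in (("asthma", 0.08), ("allergy", 0.25), ("eczema", 0.15)):
            logit = np.log(prev / (1 - prev)) + eff.get(name, 0.0) * mps_z
            pheno[name] = rng.binomial(1, 1 / (1 + np.exp(-logit)))
        pheno["bmi_sds"] = eff.get("bmi_sds", 0.0) * mps_z + rng.normal(0, 1, size=n)

    # ---- assemble methylation matrices ------------------------------------
    bdf = pd.DataFrame(betas, index=ids, columns=panel)
    matrices: dict[str, MethylationMatrix] = {}
    for lab in (ARRAY_450K, ARRAY_EPIC):
        m = array_label == lab
        matrices[lab] = MethylationMatrix(
            bdf.loc[m], lab, pd.Series(plate[m], index=ids[m], name="plate")
        )

    truth = GroundTruth(
        latent_inflammation=pd.Series(eta, index=ids, name="latent_inflammation"),
        true_cell_proportions=pd.DataFrame(P, index=ids, columns=celltypes),
        mps_z=pd.Series(mps_z, index=ids, name="mps_z_true"),
        true_effects={
            "score_effects": dict(cfg.score_effects),
            "pgs_mps_effect": cfg.pgs_mps_effect,
            "brain_main_effects": dict(cfg.brain_main_effects),
            "brain_age_effects": dict(cfg.brain_age_effects),
            "cbcl_main_effects": dict(cfg.cbcl_main_effects),
            "cbcl_age_effects": dict(cfg.cbcl_age_effects),
            "inflammation_score_r2": r2,
            "inflammation_crp_loading": cfg.inflammation_crp_loading,
            "score_loading_sum": float(a),
        },
    )
    cohort = SyntheticCohort(pheno=pheno, crp=crp, brain=brain, cbcl=cbcl, reference=reference)

    # optional MCAR missingness, injected last so the truth stays complete
    if cfg.probe_missing_rate > 0:
        for lab in matrices:
            matrices[lab] = inject_missingness(
                matrices[lab], cfg.probe_missing_rate, seed=rng.integers(2**31)
            )
    if cfg.covariate_missing_rate > 0:
        cols = ["maternal_age", "parity", "smoking", "income_high", "education"]
        cols += xp.lifestyle_item_columns() + xp.medical_item_columns()
        cohort.pheno = inject_covariate_missingness(
            cohort.pheno, cfg.covariate_missing_rate, cols, seed=rng.integers(2**31)
        )

    return matrices, cohort, truth


def _draw_exposure_items(rng, n, cfg, ids) -> pd.DataFrame:
    cols, vals = [], []
    for col in xp.infection_item_columns():
        cols.append(col)
        vals.append(rng.binomial(1, cfg.infection_prev, size=n))
    for col in xp.stress_item_columns():
        cols.append(col)
        vals.append(rng.binomial(1, cfg.stress_prev, size=n))
    for col, p in zip(xp.lifestyle_item_columns(), cfg.lifestyle_prev):
        cols.append(col)
        vals.append(rng.binomial(1, p, size=n))
    for col, p in zip(xp.pregnancy_item_columns(), cfg.pregnancy_prev):
        cols.append(col)
        vals.append(rng.binomial(1, p, size=n))
    for col, p in zip(xp.medical_item_columns(), cfg.medical_prev):
        cols.append(col)
        vals.append(rng.binomial(1, p, size=n))
    return pd.DataFrame(dict(zip(cols, vals)), index=ids).astype(float)


def _draw_crp(rng, cfg, eta, pgs_z, ids) -> pd.DataFrame:
    n = len(ids)
    rho = cfg.inflammation_crp_loading
    mu = (cfg.crp_log_mean if cfg.crp_log_mean is not None
          else np.log(cfg.crp_lod) - cfg.crp_log_sd * stats.norm.ppf(cfg.below_lod_target))
    z = rho * eta + np.sqrt(max(1 - rho**2, 0.0)) * rng.normal(0, 1, size=n)
    rows = []
    cord = np.exp(mu + cfg.crp_log_sd * z)
    rows.append(("cord_birth", cord))
    g = cfg.pgs_crp_loading
    for occ, lm, ls in (("maternal_t1", cfg.maternal_log_mean, cfg.maternal_log_sd),
                        ("maternal_t2", cfg.maternal_log_mean, cfg.maternal_log_sd),
                        ("child_5y", cfg.child_log_mean, cfg.child_log_sd)):
        zz = g * pgs_z + np.sqrt(max(1 - g**2, 0.0)) * rng.normal(0, 1, size=n)
        rows.append((occ, np.exp(lm + ls * zz)))
    frames = []
    for occ, val in rows:
        below = val < cfg.crp_lod
        frames.append(pd.DataFrame({
            "sample_id": ids,
            "occasion": occ,
            "value_mg_per_l": np.where(below, cfg.crp_lod, val),
            "below_lod": below,
            "lod": cfg.crp_lod,
        }))
    return pd.concat(frames, ignore_index=True)


def _draw_brain(rng, cfg, ids, mps_z, head_size) -> pd.DataFrame:
    n = len(ids)
    in_brain = rng.random(n) < cfg.brain_fraction
    tau2 = cfg.random_intercept_var
    ages = [rng.normal(m, s, size=n) for m, s in cfg.brain_ages]
    avail = [
        in_brain & (rng.random(n) >= dr) for dr in cfg.brain_occasion_dropout
    ]
    any_row = avail[0] | avail[1]
    mean_age = np.concatenate(
        [ages[k][avail[k]] for k in range(2)]
    ).mean() if any_row.any() else 12.0

    recs = {"sample_id": [], "occasion": [], "age": [], "icv": []}
    out_vals = {o: [] for o in BRAIN_OUTCOMES}
    icv_obs = 0.95 * head_size + np.sqrt(1 - 0.95**2) * rng.normal(0, 1, size=n)
    u = {o: rng.normal(0, np.sqrt(tau2), size=n) for o in BRAIN_OUTCOMES}
    for k in range(2):
        sel = np.where(avail[k])[0]
        recs["sample_id"].extend(ids[sel])
        recs["occasion"].extend([k + 1] * len(sel))
        recs["age"].extend(ages[k][sel])
        recs["icv"].extend(icv_obs[sel])
        ac = ages[k][sel] - mean_age
        for o in BRAIN_OUTCOMES:
            is_vol = o in BRAIN_VOLUME_OUTCOMES
            head_share = 0.15 if is_vol else 0.0
            e_var = max(1.0 - tau2 - head_share, 0.05)
            y = (
                u[o][sel]
                + cfg.brain_age_slope * ac
                + cfg.brain_main_effects.get(o, 0.0) * mps_z[sel]
                + cfg.brain_age_effects.get(o, 0.0) * mps_z[sel] * ac
                + np.sqrt(head_share) * head_size[sel]
                + rng.normal(0, np.sqrt(e_var), size=len(sel))
            )
            out_vals[o].extend(y)
    df = pd.DataFrame(recs)
    for o in BRAIN_OUTCOMES:
        df[o] = out_vals[o]
    return df.sort_values(["sample_id", "occasion"], ignore_index=True)


def _draw_cbcl(rng, cfg, ids, mps_z) -> pd.DataFrame:
    n = len(ids)
    tau2 = cfg.random_intercept_var
    mu0, mean_age = 4.0, float(np.mean(cfg.cbcl_ages))
    u = {o: rng.normal(0, np.sqrt(tau2), size=n) for o in CBCL_OUTCOMES}
    frames = []
    for k, age0 in enumerate(cfg.cbcl_ages):
        keep = rng.random(n) >= cfg.cbcl_missing_rate
        sel = np.where(keep)[0]
        age = age0 + rng.uniform(-0.2, 0.2, size=len(sel))
        ac = age - mean_age
        rec = {"sample_id": ids[sel], "occasion": k + 1, "age": age}
        for o in CBCL_OUTCOMES:
            s = (
                mu0
                + u[o][sel]
                + cfg.cbcl_age_slope * ac
                + cfg.cbcl_main_effects.get(o, 0.0) * mps_z[sel]
                + cfg.cbcl_age_effects.get(o, 0.0) * mps_z[sel] * ac
                + rng.normal(0, np.sqrt(max(1 - tau2, 0.05)), size=len(sel))
            )
            rec[o] = np.clip(s, 0.1, None) ** 2
        frames.append(pd.DataFrame(rec))
    return pd.concat(frames, ignore_index=True).sort_values(
        ["sample_id", "occasion"], ignore_index=True
    )


def inject_missingness(
    matrix: MethylationMatrix,
    rates: float | pd.Series,
    seed: int | None = None,
) -> MethylationMatrix:
    """Apply a missing-completely-at-random mask to beta values.

    ``rates`` is a scalar cell-wise rate or a per-probe Series.  The
    input matrix is left untouched, so callers can score imputation
    error against it.
    """
    rng = np.random.default_rng(seed)
    B = matrix.betas.copy()
    if np.isscalar(rates):
        if not (0 <= rates <= 1):
            raise ConfigError("missingness rate must be in [0, 1]")
        if rates > 0:
            mask = rng.random(B.shape) < rates
            B.values[mask] = np.nan
    else:
        r = pd.Series(rates).reindex(B.columns).fillna(0.0)
        if (r < 0).any() or (r > 1).any():
            raise ConfigError("missingness rates must be in [0, 1]")
        mask = rng.random(B.shape) < r.to_numpy()[None, :]
        B.values[mask] = np.nan
    return MethylationMatrix(B, matrix.array_label, matrix.plate)


def inject_covariate_missingness(
    pheno: pd.DataFrame, rate: float, columns: list[str], seed: int | None = None
) -> pd.DataFrame:
    """MCAR missingness on selected phenotype columns."""
    if not (0 <= rate <= 1):
        raise ConfigError("missingness rate must be in [0, 1]")
    rng = np.random.default_rng(seed)
    out = pheno.copy()
    for c in columns:
        if c not in out.columns:
            continue
        mask = rng.random(len(out)) < rate
        out[c] = out[c].astype(float).mask(mask)
    return out
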