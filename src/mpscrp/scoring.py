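"""Methylation matrices, probe imputation, CRP profile scoring and deconvolution.

The methylation profile score (MPS) is a weighted sum of beta values,
``score_i = sum_j w_j * beta_ij``, with per-CpG weights taken from an
external epigenome-wide association study of serum CRP — the epigenetic
analogue of a polygenic score.  Scores are computed per array dialect
(450K or EPIC) over whichever weight probes the array carries and are
standardized to Z-scores within each array subcohort so that the two
non-overlapping subcohorts can be analysed in parallel and pooled by
meta-analysis downstream.

Missing probes are filled by k-nearest-neighbour imputation in probe
space; cell-type composition is estimated from a cord-blood reference
panel by simplex-constrained least squares.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from mpscrp.errors import (
    DegenerateMatrixError,
    ScoreIncomputableError,
    SchemaError,
    UnidentifiableMixtureError,
)

logger = logging.getLogger(__name__)

ARRAY_450K = "450k"
ARRAY_EPIC = "epic"

#: canonical cord-blood cell types (reference panel column order)
CORD_CELL_TYPES = (
    "granulocytes",
    "monocytes",
    "bcells",
    "cd4t",
    "cd8t",
    "nk",
    "nrbc",
)


@dataclass
class MethylationMatrix:
    """Sample x CpG beta-value matrix for one array subcohort.

    Parameters
    ----------
    betas
        DataFrame indexed by sample id with CpG ids as columns.  Values
        are methylation fractions in ``[0, 1]``; ``NaN`` marks a missing
        (e.g. detection-failed) cell.
    array_label
        Array dialect, ``"450k"`` or ``"epic"``.
    plate
        Optional per-sample batch (bisulfite plate) labels, aligned with
        ``betas.index``.
    """

    betas: pd.DataFrame
    array_label: str
    plate: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.betas.index.has_duplicates:
            raise SchemaError("duplicate sample ids in methylation matrix")
        if self.betas.columns.has_duplicates:
            raise SchemaError("duplicate CpG ids in methylation matrix")
        vals = self.betas.to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            if np.nanmin(vals, initial=0.0) < -1e-12 or np.nanmax(vals, initial=1.0) > 1 + 1e-12:
                raise SchemaError("beta values must lie in [0, 1]")
        if self.plate is not None and not self.plate.index.equals(self.betas.index):
            self.plate = self.plate.reindex(self.betas.index)

    @property
    def sample_ids(self) -> pd.Index:
        return self.betas.index

    @property
    def cpg_ids(self) -> pd.Index:
        return self.betas.columns

    def copy(self) -> "MethylationMatrix":
        return MethylationMatrix(
            self.betas.copy(),
            self.array_label,
            None if self.plate is None else self.plate.copy(),
        )


@dataclass
class WeightTable:
    """CpG -> EWAS regression weight map defining a profile score."""

    weights: pd.Series  # index: cpg_id, values: regression weights
    source_tag: str = "main7"

    def __post_init__(self) -> None:
        if self.weights.index.has_duplicates:
            raise SchemaError("duplicate CpG ids in weight table")
        w = self.weights.to_numpy(dtype=float)
        if not np.all(np.isfinite(w)):
            raise SchemaError("weights must be finite")
        if np.allclose(w, 0.0):
            raise SchemaError("weight table is identically zero")

    def __len__(self) -> int:
        return len(self.weights)

    @classmethod
    def from_file(cls, path, source_tag: str | None = None) -> "WeightTable":
        """Read a 2-column delimited file (cpg_id, weight) with a header."""
        df = pd.read_csv(path, sep=None, engine="python")
        if df.shape[1] < 2:
            raise SchemaError(f"weight file {path} needs two columns (cpg_id, weight)")
        s = pd.Series(df.iloc[:, 1].astype(float).to_numpy(), index=df.iloc[:, 0].astype(str))
        return cls(s, source_tag or str(path))

    def to_file(self, path) -> None:
        pd.DataFrame({"cpg_id": self.weights.index, "weight": self.weights.to_numpy()}).to_csv(
            path, sep="\t", index=False
        )


def knn_impute_probes(
    matrix: MethylationMatrix,
    k: int = 10,
    rowmax: float = 0.5,
    colmax: float = 0.8,
    seed: int | None = None,
) -> MethylationMatrix:
    """Impute missing beta values by k-nearest-neighbour probes.

    Missing CpG measurements are filled per sample with the mean of the
    ``k`` probes nearest in Euclidean distance, computed over
    pairwise-complete samples.  Probes missing in every sample, or in
    more than a fraction ``colmax`` of samples, are dropped rather than
    imputed.  Samples whose missingness exceeds ``rowmax`` are filled
    from the per-probe column means instead of neighbour averages.

    The procedure is deterministic (ties broken by probe order); the
    ``seed`` argument exists for interface symmetry and is unused.

    Returns a new :class:`MethylationMatrix` with no missing cells among
    the retained probes.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if not (0 < rowmax <= 1) or not (0 < colmax <= 1):
        raise ValueError("rowmax and colmax must be in (0, 1]")

    B = matrix.betas
    miss = B.isna()
    if not miss.to_numpy().any():
        return matrix.copy()

    col_frac = miss.mean(axis=0)
    keep = col_frac.index[(col_frac < 1.0) & (col_frac <= colmax)]
    dropped = B.shape[1] - len(keep)
    if dropped:
        logger.info("knn_impute_probes: dropping %d probes (all-missing or > colmax)", dropped)
    B = B[keep]

    X = B.to_numpy(dtype=float).copy()  # n x J
    n, J = X.shape
    if J == 0:
        raise DegenerateMatrixError("no probes retained after missingness filtering")
    if k > J - 1:
        raise DegenerateMatrixError(f"k={k} exceeds the {J - 1} available neighbour probes")

    present = ~np.isnan(X)
    col_means = np.nanmean(X, axis=0)

    # heavily missing samples: plain column-mean fill
    row_frac = 1.0 - present.mean(axis=1)
    heavy = row_frac > rowmax
    if heavy.any():
        logger.info("knn_impute_probes: %d samples above rowmax, mean-imputed", int(heavy.sum()))
        for i in np.where(heavy)[0]:
            gaps = ~present[i]
            X[i, gaps] = col_means[gaps]
            present[i, gaps] = True

    # pairwise-complete squared Euclidean distances between probes,
    # scaled by overlap (mean squared difference) to compare fairly
    P = present.astype(float)
    Q = np.where(present, X, 0.0)
    cross = Q.T @ Q
    sq = (Q**2).T @ P
    counts = P.T @ P
    with np.errstate(invalid="ignore", divide="ignore"):
        d2 = (sq + sq.T - 2.0 * cross) / counts
    d2[counts == 0] = np.inf
    np.fill_diagonal(d2, np.inf)

    rows_todo, cols_todo = np.where(~present)
    for i, j in zip(rows_todo, cols_todo):
        candidates = np.where(present[i])[0]
        candidates = candidates[np.isfinite(d2[j, candidates])]
        if candidates.size == 0:
            X[i, j] = col_means[j]
            continue
        order = candidates[np.argsort(d2[j, candidates], kind="stable")]
        X[i, j] = X[i, order[: min(k, order.size)]].mean()

    X = np.clip(X, 0.0, 1.0)
    out = pd.DataFrame(X, index=B.index, columns=B.columns)
    return MethylationMatrix(out, matrix.array_label, matrix.plate)


def compute_mps(matrix: MethylationMatrix, weights: WeightTable) -> pd.DataFrame:
    """Weighted sum of beta values over the probes shared with the weight table.

    Returns a DataFrame indexed by sample id with columns ``raw_score``,
    ``n_probes_used`` and ``array_label``.  Weight probes absent from the
    array are skipped (the score uses the maximum number of CpGs
    available on each array); no re-weighting of the remainder is done
    and no intercept enters the score.
    """
    shared = matrix.cpg_ids.intersection(weights.weights.index)
    if len(shared) == 0:
        raise ScoreIncomputableError(
            f"no overlap between matrix probes and '{weights.source_tag}' weight probes"
        )
    skipped = len(weights) - len(shared)
    if skipped:
        logger.info(
            "compute_mps: %d/%d '%s' probes absent from %s array, skipped",
            skipped, len(weights), weights.source_tag, matrix.array_label,
        )
    sub = matrix.betas[shared]
    if sub.isna().to_numpy().any():
        raise DegenerateMatrixError("missing beta values among score probes; impute first")
    w = weights.weights.loc[shared].to_numpy(dtype=float)
    raw = sub.to_numpy(dtype=float) @ w
    return pd.DataFrame(
        {
            "raw_score": raw,
            "n_probes_used": len(shared),
            "array_label": matrix.array_label,
        },
        index=matrix.sample_ids,
    )


def standardize_by_array(scores: pd.DataFrame) -> pd.DataFrame:
    """Z-standardize raw scores within each array subcohort.

    ``scores`` must carry ``raw_score`` and ``array_label`` columns (the
    output of :func:`compute_mps`, possibly concatenated over arrays).
    Adds a ``z_score`` column with per-array mean 0 and SD 1 (n-1
    denominator); the raw score is retained.
    """
    if "raw_score" not in scores or "array_label" not in scores:
        raise SchemaError("scores need 'raw_score' and 'array_label' columns")
    out = scores.copy()
    z = np.empty(len(out))
    for label, grp in out.groupby("array_label"):
        x = grp["raw_score"].to_numpy(dtype=float)
        if x.size < 2:
            raise DegenerateMatrixError(f"array '{label}' has fewer than 2 samples")
        sd = x.std(ddof=1)
        if sd == 0:
            raise DegenerateMatrixError(f"zero score variance in array '{label}'")
        z[out["array_label"].to_numpy() == label] = (x - x.mean()) / sd
    out["z_score"] = z
    return out


def _simplex_lstsq_single(G: np.ndarray, Ry: np.ndarray) -> np.ndarray:
    """Active-set solver for min ||Rp - y||^2 s.t. sum(p)=1, p >= 0."""
    c = len(Ry)
    free = np.ones(c, dtype=bool)
    p = np.full(c, 1.0 / c)
    for _ in range(4 * c + 8):
        idx = np.where(free)[0]
        m = idx.size
        K = np.zeros((m + 1, m + 1))
        K[:m, :m] = 2.0 * G[np.ix_(idx, idx)]
        K[:m, m] = -1.0
        K[m, :m] = 1.0
        rhs = np.concatenate([2.0 * Ry[idx], [1.0]])
        sol = np.linalg.solve(K, rhs)
        p_f, lam = sol[:m], sol[m]
        if p_f.min() < -1e-10:
            free[idx[np.argmin(p_f)]] = False
            continue
        p = np.zeros(c)
        p[idx] = np.clip(p_f, 0.0, None)
        # dual feasibility of the zeroed coordinates
        mu = 2.0 * (G @ p - Ry) - lam
        zeroed = np.where(~free)[0]
        if zeroed.size and mu[zeroed].min() < -1e-8:
            free[zeroed[np.argmin(mu[zeroed])]] = True
            continue
        break
    return p / p.sum()


def estimate_cell_proportions(
    matrix: MethylationMatrix, reference: pd.DataFrame
) -> pd.DataFrame:
    """Reference-based cell-type deconvolution under simplex constraints.

    For each sample, solves ``min || beta_ref - R p ||^2`` subject to
    ``p >= 0`` and ``sum(p) = 1``, where ``R`` is the cord-blood
    reference panel of mean beta values (rows: CpGs, columns: cell
    types).  Returns a samples x cell-types DataFrame of proportions.
    """
    shared = matrix.cpg_ids.intersection(reference.index)
    ncell = reference.shape[1]
    if len(shared) < ncell:
        raise DegenerateMatrixError(
            f"only {len(shared)} reference probes present; need >= {ncell}"
        )
    R = reference.loc[shared].to_numpy(dtype=float)
    if np.linalg.matrix_rank(R) < ncell:
        raise UnidentifiableMixtureError("reference matrix is rank deficient")
    Y = matrix.betas[shared].to_numpy(dtype=float)
    if np.isnan(Y).any():
        raise DegenerateMatrixError("missing values among reference probes; impute first")

    G = R.T @ R
    RY = Y @ R  # n x c, rows are R^T y_i

    # fast path: equality-constrained solution for all samples at once
    n = Y.shape[0]
    K = np.zeros((ncell + 1, ncell + 1))
    K[:ncell, :ncell] = 2.0 * G
    K[:ncell, ncell] = -1.0
    K[ncell, :ncell] = 1.0
    rhs = np.vstack([2.0 * RY.T, np.ones(n)])
    sol = np.linalg.solve(K, rhs)
    P = sol[:ncell].T  # n x c

    bad = np.where(P.min(axis=1) < -1e-10)[0]
    for i in bad:
        P[i] = _simplex_lstsq_single(G, RY[i])
    P = np.clip(P, 0.0, None)
    P /= P.sum(axis=1, keepdims=True)
    return pd.DataFrame(P, index=matrix.sample_ids, columns=reference.columns)
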