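"""Profile scoring, KNN probe imputation and cell-type deconvolution."""

import numpy as np
import pandas as pd
import pytest

from mpscrp.errors import (
    DegenerateMatrixError,
    ScoreIncomputableError,
    SchemaError,
    UnidentifiableMixtureError,
)
from mpscrp.scoring import (
    MethylationMatrix,
    WeightTable,
    compute_mps,
    estimate_cell_proportions,
    knn_impute_probes,
    standardize_by_array,
)


def _wt(values, ids=None):
    ids = ids or [f"cg{j:02d}" for j in range(len(values))]
    return WeightTable(pd.Series(values, index=ids, dtype=float))


class TestMethylationMatrix:
    def test_rejects_out_of_range_betas(self):
        df = pd.DataFrame({"cg00": [0.1, 1.4]}, index=["a", "b"])
        with pytest.raises(SchemaError):
            MethylationMatrix(df, "450k")

    def test_rejects_duplicate_ids(self):
        df = pd.DataFrame(
            [[0.1, 0.2], [0.3, 0.4]], index=["a", "a"], columns=["cg00", "cg01"]
        )
        with pytest.raises(SchemaError):
            MethylationMatrix(df, "450k")


class TestKnnImpute:
    def test_complete_matrix_is_identity(self, tiny_matrix):
        out = knn_impute_probes(tiny_matrix, k=3)
        pd.testing.assert_frame_equal(out.betas, tiny_matrix.betas)

    def test_all_missing_probe_dropped(self, tiny_matrix):
        m = tiny_matrix.copy()
        m.betas["cg05"] = np.nan
        out = knn_impute_probes(m, k=3)
        assert "cg05" not in out.cpg_ids
        assert not out.betas.isna().to_numpy().any()

    def test_colmax_drops_heavily_missing_probe(self, tiny_matrix):
        m = tiny_matrix.copy()
        m.betas.iloc[:18, 2] = np.nan  # 90 % missing > colmax 0.8
        out = knn_impute_probes(m, k=3, colmax=0.8)
        assert m.cpg_ids[2] not in out.cpg_ids

    def test_single_cell_matches_bruteforce_neighbours(self, tiny_matrix):
        m = tiny_matrix.copy()
        m.betas.iloc[4, 7] = np.nan
        out = knn_impute_probes(m, k=3)

        # oracle: exhaustive pairwise-complete distances between probe 7
        # and every other probe, mean of the 3 nearest at sample 4
        X = m.betas.to_numpy()
        dists = {}
        for j in range(X.shape[1]):
            if j == 7:
                continue
            mask = ~np.isnan(X[:, 7]) & ~np.isnan(X[:, j])
            dists[j] = np.mean((X[mask, 7] - X[mask, j]) ** 2)
        nearest = sorted(dists, key=dists.get)[:3]
        expected = X[4, nearest].mean()
        assert out.betas.iloc[4, 7] == pytest.approx(expected, abs=1e-12)

    def test_heavy_sample_mean_imputed(self, tiny_matrix):
        m = tiny_matrix.copy()
        m.betas.iloc[0, :6] = np.nan  # 60 % of this sample missing > rowmax 0.5
        out = knn_impute_probes(m, k=3, rowmax=0.5)
        expected = m.betas.iloc[1:, 0].mean()
        # column mean over the remaining (observed) samples
        assert out.betas.iloc[0, 0] == pytest.approx(expected, rel=1e-6)

    def test_k_too_large_raises(self, tiny_matrix):
        m = tiny_matrix.copy()
        m.betas.iloc[0, 0] = np.nan
        with pytest.raises(DegenerateMatrixError):
            knn_impute_probes(m, k=50)


class TestComputeMps:
    def test_zero_betas_give_zero_score(self):
        df = pd.DataFrame(0.0, index=["a", "b"], columns=["cg00", "cg01"])
        res = compute_mps(MethylationMatrix(df, "450k"), _wt([0.5, -0.2]))
        assert (res["raw_score"] == 0).all()

    def test_single_probe_identity(self):
        df = pd.DataFrame({"cg00": [1.0]}, index=["a"])
        res = compute_mps(MethylationMatrix(df, "epic"), _wt([-0.35], ["cg00"]))
        assert res["raw_score"].iloc[0] == pytest.approx(-0.35)

    def test_matches_double_loop_oracle(self, rng):
        w = _wt(list(rng.normal(0, 0.2, size=7)))
        betas = rng.uniform(0, 1, size=(5, 7))
        df = pd.DataFrame(betas, index=[f"s{i}" for i in range(5)],
                          columns=w.weights.index)
        res = compute_mps(MethylationMatrix(df, "450k"), w)
        for i in range(5):
            acc = 0.0
            for j, cg in enumerate(w.weights.index):
                acc += betas[i, j] * w.weights[cg]
            assert res["raw_score"].iloc[i] == pytest.approx(acc, abs=1e-12)

    def test_absent_probes_skipped_not_reweighted(self, tiny_matrix):
        w = _wt([0.5, -0.2, 0.1], ["cg00", "cg01", "cg_absent"])
        res = compute_mps(tiny_matrix, w)
        assert (res["n_probes_used"] == 2).all()
        manual = tiny_matrix.betas[["cg00", "cg01"]].to_numpy() @ np.array([0.5, -0.2])
        np.testing.assert_allclose(res["raw_score"], manual, atol=1e-12)

    def test_empty_intersection_raises(self, tiny_matrix):
        with pytest.raises(ScoreIncomputableError):
            compute_mps(tiny_matrix, _wt([0.3], ["cg_other"]))

    def test_linearity_in_betas(self, rng):
        w = _wt(list(rng.normal(0, 0.2, size=6)), [f"cg{j:02d}" for j in range(6)])
        b1 = rng.uniform(0, 1, size=(8, 6))
        b2 = rng.uniform(0, 1, size=(8, 6))
        cols = w.weights.index
        idx = [f"s{i}" for i in range(8)]
        for a in (0.0, 0.3, 1.0):
            mixed = a * b1 + (1 - a) * b2
            s_mix = compute_mps(
                MethylationMatrix(pd.DataFrame(mixed, idx, cols), "450k"), w
            )["raw_score"]
            s1 = compute_mps(
                MethylationMatrix(pd.DataFrame(b1, idx, cols), "450k"), w
            )["raw_score"]
            s2 = compute_mps(
                MethylationMatrix(pd.DataFrame(b2, idx, cols), "450k"), w
            )["raw_score"]
            np.testing.assert_allclose(s_mix, a * s1 + (1 - a) * s2, atol=1e-12)

    def test_sample_permutation_permutes_scores(self, tiny_matrix, rng):
        w = _wt([0.4, -0.1, 0.2], ["cg00", "cg01", "cg02"])
        res = compute_mps(tiny_matrix, w)
        perm = rng.permutation(tiny_matrix.sample_ids)
        shuffled = MethylationMatrix(tiny_matrix.betas.loc[perm], "450k")
        res_p = compute_mps(shuffled, w)
        pd.testing.assert_series_equal(
            res_p["raw_score"], res["raw_score"].loc[perm], check_names=False
        )


class TestStandardize:
    def test_three_values_closed_form(self):
        scores = pd.DataFrame(
            {"raw_score": [1.0, 2.0, 3.0], "array_label": "450k"},
            index=["a", "b", "c"],
        )
        z = standardize_by_array(scores)["z_score"]
        np.testing.assert_allclose(z, [-1, 0, 1])

    def test_per_array_moments(self, rng):
        scores = pd.DataFrame({
            "raw_score": rng.normal(5, 2, size=40),
            "array_label": ["450k"] * 25 + ["epic"] * 15,
        })
        z = standardize_by_array(scores)
        for _, grp in z.groupby("array_label"):
            assert grp["z_score"].mean() == pytest.approx(0, abs=1e-8)
            assert grp["z_score"].std(ddof=1) == pytest.approx(1, abs=1e-8)

    def test_arrays_are_independent(self, rng):
        a = pd.DataFrame({"raw_score": rng.normal(size=20), "array_label": "450k"})
        b = pd.DataFrame({"raw_score": rng.normal(size=15), "array_label": "epic"})
        joint = standardize_by_array(pd.concat([a, b], ignore_index=True))
        alone = standardize_by_array(a)
        np.testing.assert_allclose(
            joint[joint["array_label"] == "450k"]["z_score"].to_numpy(),
            alone["z_score"].to_numpy(),
        )

    def test_zero_variance_raises(self):
        scores = pd.DataFrame({"raw_score": [1.0, 1.0], "array_label": "450k"})
        with pytest.raises(DegenerateMatrixError):
            standardize_by_array(scores)


def _reference(rng, n_probes, celltypes):
    return pd.DataFrame(
        rng.uniform(0.05, 0.95, size=(n_probes, len(celltypes))),
        index=[f"cg_r{j}" for j in range(n_probes)],
        columns=celltypes,
    )


class TestDeconvolution:
    def test_vertex_sample_recovers_unit_proportion(self, rng):
        ref = _reference(rng, 30, ["gran", "mono", "nk"])
        betas = pd.DataFrame([ref["mono"].to_numpy()], index=["s0"], columns=ref.index)
        p = estimate_cell_proportions(MethylationMatrix(betas, "450k"), ref)
        assert p.loc["s0", "mono"] == pytest.approx(1.0, abs=1e-6)
        assert p.loc["s0", ["gran", "nk"]].max() == pytest.approx(0.0, abs=1e-6)

    def test_noiseless_mixture_recovered(self, rng):
        ref = _reference(rng, 40, ["a", "b", "c"])
        p_true = np.array([0.6, 0.3, 0.1])
        betas = pd.DataFrame([ref.to_numpy() @ p_true], index=["s0"], columns=ref.index)
        p = estimate_cell_proportions(MethylationMatrix(betas, "450k"), ref)
        np.testing.assert_allclose(p.loc["s0"].to_numpy(), p_true, atol=1e-4)

    def test_rows_are_simplex(self, small_cohort):
        matrices, cohort, _ = small_cohort
        p = estimate_cell_proportions(matrices["450k"], cohort.reference)
        assert (p.to_numpy() >= 0).all()
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-6)

    def test_matches_grid_search_oracle(self, rng):
        ref = _reference(rng, 25, ["a", "b", "c"])
        p_true = np.array([0.5, 0.2, 0.3])
        y = ref.to_numpy() @ p_true + rng.normal(0, 0.03, size=25)
        betas = pd.DataFrame([np.clip(y, 0, 1)], index=["s0"], columns=ref.index)
        p = estimate_cell_proportions(MethylationMatrix(betas, "450k"), ref)

        # dense simplex grid, step 0.01
        best, best_sse = None, np.inf
        R = ref.to_numpy()
        yv = betas.to_numpy()[0]
        for i in range(101):
            for j in range(101 - i):
                cand = np.array([i, j, 100 - i - j]) / 100
                sse = np.sum((yv - R @ cand) ** 2)
                if sse < best_sse:
                    best, best_sse = cand, sse
        np.testing.assert_allclose(p.loc["s0"].to_numpy(), best, atol=0.01)

    def test_rank_deficient_reference_raises(self, rng):
        ref = _reference(rng, 30, ["a", "b", "c"])
        ref["c"] = ref["a"]
        betas = pd.DataFrame([ref["a"].to_numpy()], index=["s0"], columns=ref.index)
        with pytest.raises(UnidentifiableMixtureError):
            estimate_cell_proportions(MethylationMatrix(betas, "450k"), ref)


def test_weight_table_rejects_all_zero():
    with pytest.raises(SchemaError):
        WeightTable(pd.Series([0.0, 0.0], index=["cg00", "cg01"]))
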