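"""Aim-1/2/3 model fits, FDR, variance partition, sensitivity fits."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mpscrp import models
from mpscrp.errors import DegenerateDesignError, SchemaError


def _aim1_frame(rng, n=300, effect=0.0):
    df = pd.DataFrame({
        "stress_score": rng.normal(size=n),
        "lifestyle_score": rng.poisson(1.2, size=n).astype(float),
        "sex": rng.integers(0, 2, size=n),
        "plate": rng.choice(["p1", "p2", "p3"], size=n),
        "income_high": rng.integers(0, 2, size=n),
        "education": rng.integers(0, 3, size=n),
    }, index=[f"s{i}" for i in range(n)])
    ls = df["lifestyle_score"]
    df["mps_z"] = effect * (ls - ls.mean()) / ls.std(ddof=1) + rng.normal(size=n)
    return df


class TestFitAim1:
    def test_standardized_beta_recovered(self, rng):
        df = _aim1_frame(rng, n=4000, effect=0.3)
        out = models.fit_aim1(df, ["stress_score", "lifestyle_score"], "450k",
                              pgs_col=None)
        b = out[out["term"] == "lifestyle_score"]["beta"].iloc[0]
        assert b == pytest.approx(0.3, abs=0.06)

    def test_duplicated_predictor_raises(self, rng):
        df = _aim1_frame(rng)
        df["stress_score"] = df["lifestyle_score"]
        with pytest.raises(DegenerateDesignError):
            models.fit_aim1(df, ["stress_score", "lifestyle_score"], "450k",
                            pgs_col=None)


def _long_frame(rng, n=150, re_sd=0.7, slope=0.0, balanced=True):
    rows = []
    u = rng.normal(0, re_sd, size=n)
    mps = rng.normal(size=n)
    ga = rng.normal(40, 1.5, size=n)
    covs = {
        "sex": rng.integers(0, 2, size=n),
        "plate": rng.choice(["p1", "p2"], size=n),
        "income_high": rng.integers(0, 2, size=n),
        "education": rng.integers(0, 3, size=n),
        "maternal_age": rng.normal(31, 4, size=n),
        "smoking": rng.integers(0, 3, size=n),
        "parity": rng.integers(0, 3, size=n),
    }
    for occ, age0 in enumerate((10.0, 14.0)):
        for i in range(n):
            age = age0 if balanced else age0 + rng.uniform(-0.5, 0.5)
            y = u[i] + slope * mps[i] * (age - 12.0) + rng.normal(0, 0.7)
            rows.append({"sample_id": f"s{i}", "age": age, "y_out": y,
                         "mps_z": mps[i], "gestational_age": ga[i],
                         **{k: v[i] for k, v in covs.items()}})
    return pd.DataFrame(rows)


class TestFitLongitudinal:
    def test_reduces_to_ols_when_no_group_variance(self, rng):
        df = _long_frame(rng, n=120, re_sd=0.0)
        out = models.fit_longitudinal(df, "y_out", form="by_age", stratum="450k")

        import statsmodels.formula.api as smf

        d = df.copy()
        y = d["y_out"]
        d["y"] = (y - y.mean()) / y.std(ddof=1)
        d["age_c"] = d["age"] - d["age"].mean()
        ols = smf.ols(
            "y ~ mps_z * age_c + C(sex) + C(plate) + income_high + C(education)"
            " + maternal_age + C(smoking) + parity",
            data=d,
        ).fit()
        key = out[out["term"] == "mps_z:age_c"]["beta"].iloc[0]
        assert key == pytest.approx(ols.params["mps_z:age_c"], abs=1e-6)
        # every fixed effect coincides with OLS in the balanced design
        for term in ("mps_z", "age_c"):
            assert out[out["term"] == term]["beta"].iloc[0] == pytest.approx(
                ols.params[term], abs=1e-6
            )

    def test_near_constant_within_person_outcome_splits_variance(self, rng):
        df = _long_frame(rng, n=100, re_sd=1.0)
        # make the outcome almost person-constant: the random intercept
        # should absorb nearly all variance, leaving the score term null
        first = df.groupby("sample_id")["y_out"].transform("first")
        df["y_out"] = first + rng.normal(0, 0.05, size=len(df))
        out = models.fit_longitudinal(df, "y_out", form="main", stratum="450k")
        mps_row = out[out["term"] == "mps_z"]
        assert out["re_var"].iloc[0] > 0.8  # of a unit-variance outcome
        assert mps_row["p"].iloc[0] > 0.01

    def test_interaction_slope_recovered(self, rng):
        df = _long_frame(rng, n=800, slope=-0.10, balanced=False)
        out = models.fit_longitudinal(df, "y_out", form="by_age", stratum="450k")
        key = out[out["term"] == "mps_z:age_c"]
        # outcome z-scoring rescales by total SD (~1.22 here); compare on
        # the model's own standardized scale
        sd_y = df["y_out"].std(ddof=1)
        assert key["beta"].iloc[0] == pytest.approx(-0.10 / sd_y, abs=0.012)

    def test_sqrt_transform_requires_nonnegative(self, rng):
        df = _long_frame(rng, n=50)
        with pytest.raises(SchemaError):
            models.fit_longitudinal(df, "y_out", form="main", transform="sqrt")


class TestFdrAdjust:
    def test_single_p_passthrough(self):
        df = pd.DataFrame({"p": [0.03], "aim": "a", "form": "m"})
        assert models.fdr_adjust(df)["q"].iloc[0] == pytest.approx(0.03)

    def test_hand_stepup_example(self):
        df = pd.DataFrame({"p": [0.01, 0.02, 0.03], "aim": "a", "form": "m"})
        np.testing.assert_allclose(models.fdr_adjust(df)["q"], [0.03, 0.03, 0.03])

    def test_matches_bruteforce_oracle(self, rng):
        for _ in range(50):
            m = int(rng.integers(1, 51))
            p = rng.random(m)
            df = pd.DataFrame({"p": p, "aim": "a", "form": "m"})
            got = models.fdr_adjust(df)["q"].to_numpy()

            # exhaustive step-up definition
            order = np.argsort(p)
            q = np.empty(m)
            running = 1.0
            for rank in range(m, 0, -1):
                i = order[rank - 1]
                running = min(running, p[i] * m / rank)
                q[i] = running
            np.testing.assert_allclose(got, q, atol=1e-15)

    def test_families_are_separate(self):
        df = pd.DataFrame({
            "p": [0.04, 0.04], "aim": ["a", "a"], "form": ["m1", "m2"],
        })
        out = models.fdr_adjust(df)
        np.testing.assert_allclose(out["q"], [0.04, 0.04])

    def test_q_monotone_and_bounded(self, rng):
        p = rng.random(30)
        df = pd.DataFrame({"p": p, "aim": "a", "form": "m"})
        out = models.fdr_adjust(df).sort_values("p")
        q = out["q"].to_numpy()
        assert (np.diff(q) >= -1e-15).all()
        assert (q >= out["p"].to_numpy() - 1e-15).all()
        assert (q <= 1).all()

    @given(
        st.lists(st.floats(min_value=1e-12, max_value=1.0), min_size=1, max_size=40)
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_q_invariants_hold_for_arbitrary_p_vectors(self, p):
        df = pd.DataFrame({"p": p, "aim": "a", "form": "m"})
        out = models.fdr_adjust(df)
        q = out["q"].to_numpy()
        assert (q <= 1 + 1e-12).all()
        assert (q >= np.asarray(p) - 1e-12).all()
        srt = out.sort_values("p")["q"].to_numpy()
        assert (np.diff(srt) >= -1e-12).all()


class TestVariancePartition:
    def test_single_group_fraction_is_r2(self, rng):
        n = 2000
        x = rng.normal(size=n)
        y = np.sqrt(0.3) * x + np.sqrt(0.7) * rng.normal(size=n)
        df = pd.DataFrame({"mps_z": y, "x": x})
        out = models.variance_partition(df, {"g": ["x"]})
        frac = out.set_index("component")["fraction"]
        r2_direct = np.corrcoef(x, y)[0, 1] ** 2
        assert frac["g"] == pytest.approx(r2_direct, abs=1e-10)
        assert frac["residual"] == pytest.approx(1 - r2_direct, abs=1e-10)

    def test_orthogonal_groups_get_marginal_r2(self, rng):
        n = 3000
        x1 = rng.normal(size=n)
        x2 = rng.normal(size=n)
        x1 -= x1.mean()
        x2 -= x2.mean() + x1 * (x1 @ x2) / (x1 @ x1)  # exactly orthogonal
        y = 0.5 * x1 + 0.3 * x2 + rng.normal(size=n)
        df = pd.DataFrame({"mps_z": y, "x1": x1, "x2": x2})
        out = models.variance_partition(df, {"a": ["x1"], "b": ["x2"]})
        frac = out.set_index("component")["fraction"]

        def marginal(x):
            return np.corrcoef(x, y)[0, 1] ** 2

        assert frac["a"] == pytest.approx(marginal(x1), abs=1e-10)
        assert frac["b"] == pytest.approx(marginal(x2), abs=1e-10)

    def test_permutation_invariant_and_sums_to_one(self, rng):
        n = 500
        df = pd.DataFrame(rng.normal(size=(n, 4)), columns=["mps_z", "a", "b", "c"])
        df["mps_z"] += 0.4 * df["a"] - 0.2 * df["c"]
        g1 = {"a": ["a"], "b": ["b"], "c": ["c"]}
        g2 = {"c": ["c"], "a": ["a"], "b": ["b"]}
        o1 = models.variance_partition(df, g1).set_index("component")["fraction"]
        o2 = models.variance_partition(df, g2).set_index("component")["fraction"]
        for g in ("a", "b", "c"):
            assert o1[g] == pytest.approx(o2[g], abs=1e-12)
        assert o1.sum() == pytest.approx(1.0, abs=1e-9)
        assert (o1 >= -1e-12).all()

    def test_overlapping_groups_rejected(self, rng):
        df = pd.DataFrame(rng.normal(size=(50, 3)), columns=["mps_z", "a", "b"])
        with pytest.raises(SchemaError):
            models.variance_partition(df, {"g1": ["a"], "g2": ["a", "b"]})


class TestSensitivityChildOutcomes:
    def test_prevalence_zero_flagged(self, rng):
        df = _aim1_frame(rng, n=200)
        df["asthma"] = 0
        with pytest.raises(DegenerateDesignError):
            models.sensitivity_child_outcomes(df, "450k")

    def test_linear_and_logistic_paths(self, rng):
        df = _aim1_frame(rng, n=400)
        df["asthma"] = rng.binomial(1, 0.1, size=400)
        df["bmi_sds"] = 0.2 * df["mps_z"] + rng.normal(size=400)
        out = models.sensitivity_child_outcomes(df, "450k")
        assert set(out["outcome"]) == {"asthma", "bmi_sds"}
        bmi = out[out["outcome"] == "bmi_sds"].iloc[0]
        assert bmi["beta"] == pytest.approx(0.2, abs=3 * bmi["se"])
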