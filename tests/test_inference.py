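"""Regression, permutation inference, correlation, paired and mixed models."""

import numpy as np
import pandas as pd
import pytest

from noxsense import (GenerativeConfig, fit_intervention_model,
                      fit_mixed_immunisation, gen_cohort, paired_t,
                      pearson_perm, permutation_p)

# a small fixed cohort used across closed-form checks
FIXTURE = pd.DataFrame({
    "subject_id": [f"s{i}" for i in range(6)],
    "x": [0.30, 0.95, 1.60, 0.45, 1.10, 1.75],
    "y": [0.12, 1.71, 3.55, 0.08, 1.30, 3.10],
    "group": ["control"] * 3 + ["intervention"] * 3,
})


def _normal_equations(X, y):
    """Independent closed-form least squares (explicit inverse)."""
    XtX = X.T @ X
    beta = np.linalg.inv(XtX) @ X.T @ y
    resid = y - X @ beta
    s2 = resid @ resid / (len(y) - X.shape[1])
    se = np.sqrt(np.diag(s2 * np.linalg.inv(XtX)))
    return beta, se


class TestInterventionModel:
    @pytest.mark.parametrize("adjusted", [False, True])
    def test_matches_normal_equation_oracle(self, adjusted):
        res = fit_intervention_model(FIXTURE, adjusted=adjusted)
        g = (FIXTURE["group"] == "intervention").to_numpy(float)
        cols = [np.ones(6), g] + ([FIXTURE["x"].to_numpy()] if adjusted else [])
        beta, se = _normal_equations(np.column_stack(cols),
                                     FIXTURE["y"].to_numpy())
        assert res.b0 == pytest.approx(beta[0], abs=1e-10)
        assert res.b1 == pytest.approx(beta[1], abs=1e-10)
        if adjusted:
            assert res.b2 == pytest.approx(beta[2], abs=1e-10)
        assert res.t_stats["intervention"] == pytest.approx(
            beta[1] / se[1], abs=1e-10)

    def test_identical_groups_null_coefficient(self):
        df = FIXTURE.copy()
        df["y"] = 1.0
        df["y"] += df["x"]          # same relation in both groups
        res = fit_intervention_model(df, adjusted=True)
        assert res.b1 == pytest.approx(0.0, abs=1e-10)

    def test_perfect_group_separation(self):
        df = FIXTURE.copy()
        df["y"] = (df["group"] == "intervention").astype(float)
        res = fit_intervention_model(df, adjusted=False)
        assert res.b1 == pytest.approx(1.0, abs=1e-12)
        assert res.b0 == pytest.approx(0.0, abs=1e-12)

    def test_normal_equations_gradient_zero(self):
        res = fit_intervention_model(FIXTURE, adjusted=True)
        g = (FIXTURE["group"] == "intervention").to_numpy(float)
        X = np.column_stack([np.ones(6), g, FIXTURE["x"]])
        resid = FIXTURE["y"].to_numpy() - X @ np.array(
            [res.b0, res.b1, res.b2])
        np.testing.assert_allclose(X.T @ resid, 0.0, atol=1e-9)

    def test_constant_covariate_rejected(self):
        df = FIXTURE.copy()
        df["x"] = 1.0
        with pytest.raises(ValueError):
            fit_intervention_model(df, adjusted=True)

    def test_too_few_rows_rejected(self):
        with pytest.raises(ValueError):
            fit_intervention_model(FIXTURE.iloc[:4], adjusted=True)


class TestPermutation:
    def test_enumeration_granularity(self):
        # 4 + 4 rows: C(8,4) = 70 distinct relabelings
        df = gen_cohort(GenerativeConfig(n_per_group=4, seed=3))
        p = permutation_p(df, adjusted=False, n_perm=1000)
        assert p == pytest.approx(round(p * 70) / 70, abs=1e-12)
        assert p >= 1 / 70

    def test_agrees_with_parametric_under_normality(self):
        df = gen_cohort(GenerativeConfig(n_per_group=20, effect=0.3, seed=8))
        res = fit_intervention_model(df, adjusted=False)
        p_perm = permutation_p(df, adjusted=False, n_perm=2000, seed=1)
        se = np.sqrt(res.p_param * (1 - res.p_param) / 2000)
        assert abs(p_perm - res.p_param) < max(4 * se, 0.01)

    def test_freedman_lane_null_rejection_rate(self):
        # full pipeline type-I: null cohorts -> adjusted fit -> permutation p
        hits, n_rep = 0, 120
        rng = np.random.default_rng(10)
        for _ in range(n_rep):
            df = gen_cohort(GenerativeConfig(n_per_group=10, effect=0.0), rng)
            p = permutation_p(df, adjusted=True, n_perm=199, seed=rng)
            hits += p < 0.05
        from scipy.stats import binom
        assert binom.ppf(0.005, n_rep, 0.05) <= hits <= \
            binom.ppf(0.995, n_rep, 0.05)

    def test_affine_rescaling_invariance(self):
        df = gen_cohort(GenerativeConfig(n_per_group=6, seed=5))
        p1 = permutation_p(df, adjusted=False, n_perm=500, seed=7)
        df2 = df.copy()
        df2["y"] = 3.5 * df2["y"] - 11.0
        p2 = permutation_p(df2, adjusted=False, n_perm=500, seed=7)
        assert p1 == p2

    def test_adjusted_more_powerful_than_unadjusted(self):
        # matched-seed power advantage of the baseline covariate
        rng = np.random.default_rng(2)
        adj_sig = unadj_sig = 0
        for _ in range(60):
            df = gen_cohort(GenerativeConfig(n_per_group=12, effect=0.4), rng)
            adj_sig += fit_intervention_model(df, True).p_param < 0.05
            unadj_sig += fit_intervention_model(df, False).p_param < 0.05
        assert adj_sig > unadj_sig


class TestPearson:
    def test_perfect_correlation(self):
        out = pearson_perm([1, 2, 3, 4], [1, 2, 3, 4], n_perm=100)
        assert out["r"] == pytest.approx(1.0) and out["R2"] == pytest.approx(1.0)

    def test_affine_anticorrelation(self):
        x = np.array([0.1, 0.9, 2.0, 3.3, 4.4])
        out = pearson_perm(x, -2 * x + 7, n_perm=100)
        assert out["r"] == pytest.approx(-1.0)

    def test_nine_pair_fixture_matches_covariance_formula(self):
        x = np.array([0.2, 0.5, 0.7, 1.1, 1.3, 1.4, 1.6, 1.7, 1.8])
        y = np.array([0.1, 1.2, 0.8, 1.9, 2.6, 2.4, 3.0, 3.3, 3.1])
        out = pearson_perm(x, y, n_perm=100)
        r_direct = (np.mean(x * y) - x.mean() * y.mean()) / (
            x.std() * y.std())
        assert out["r"] == pytest.approx(r_direct, abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pearson_perm([1, 1, 1], [1, 2, 3])


class TestPairedT:
    def test_no_change_zero_t(self):
        res = paired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.t == 0.0 and res.p == 1.0 and res.degenerate

    def test_constant_shift_degenerate(self):
        res = paired_t([0.0, 0.0, 0.0, 0.0], [1.0, 1.0, 1.0, 1.0])
        assert res.degenerate and res.t == np.inf and res.p == 0.0

    def test_matches_textbook_formula(self):
        before = np.array([0.31, 0.58, 0.92, 0.44, 0.71])
        after = np.array([0.25, 0.50, 0.60, 0.48, 0.52])
        res = paired_t(before, after)
        d = after - before
        t_direct = d.mean() / (d.std(ddof=1) / np.sqrt(d.size))
        assert res.t == pytest.approx(t_direct, abs=1e-12)


class TestMixedModel:
    def _simulate(self, rng, n_per_group=10, n_imm=3, fixed=-0.5,
                  subject_sd=0.3, resid_sd=0.2):
        n = 2 * n_per_group
        subs = np.repeat([f"s{i}" for i in range(n)], n_imm)
        grp = np.repeat(["control"] * n_per_group +
                        ["intervention"] * n_per_group, n_imm)
        u = rng.normal(0, subject_sd, n)
        mag = (0.9 + fixed * (grp == "intervention")
               + u[np.repeat(np.arange(n), n_imm)]
               + rng.normal(0, resid_sd, n * n_imm))
        return pd.DataFrame({"subject": subs, "group": grp,
                             "immunisation_index": np.tile(
                                 np.arange(1, n_imm + 1), n),
                             "magnitude": mag})

    def test_parameter_recovery(self, rng):
        ests = [fit_mixed_immunisation(self._simulate(rng)).fixed_effect
                for _ in range(12)]
        se = np.std(ests, ddof=1) / np.sqrt(len(ests))
        assert abs(np.mean(ests) - (-0.5)) < 3 * se + 1e-9

    def test_degenerate_single_observation_reduces_to_ols(self, rng):
        df = self._simulate(rng, n_imm=1, subject_sd=0.0)
        res = fit_mixed_immunisation(df)
        diff = (df.loc[df.group == "intervention", "magnitude"].mean()
                - df.loc[df.group == "control", "magnitude"].mean())
        assert res.fixed_effect == pytest.approx(diff, abs=1e-4)

    def test_fixed_coding_variant(self, rng):
        res = fit_mixed_immunisation(self._simulate(rng), imm_coding="fixed")
        assert np.isfinite(res.p)
        assert "subject" in res.random_sds

    def test_too_few_subjects_rejected(self):
        df = pd.DataFrame({"subject": ["a", "b"], "group": ["control"] * 2,
                           "immunisation_index": [1, 1],
                           "magnitude": [0.1, 0.2]})
        with pytest.raises(ValueError):
            fit_mixed_immunisation(df)
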