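"""Dyadic regression fitters and restricted permutation null models."""

import itertools

import numpy as np
import pandas as pd
import pytest

from flocknet import inference


class TestScale2sd:
    def test_sd_half_unchanged(self):
        v = np.array([0.0, 1.0] * 50)  # sd (ddof=1) ~= 0.5025
        scaled, div = inference.scale_2sd(v)
        assert div == pytest.approx(2 * v.std(ddof=1))

    def test_divisor_and_postcondition(self):
        rng = np.random.default_rng(0)
        v = rng.normal(3, 2, 500)
        scaled, div = inference.scale_2sd(v)
        assert div == pytest.approx(2 * v.std(ddof=1))
        assert scaled.std(ddof=1) == pytest.approx(0.5)

    def test_zero_sd_rejected_with_name(self):
        with pytest.raises(ValueError, match="flat_covariate"):
            inference.scale_2sd(np.ones(10), name="flat_covariate")


class TestLogisticFit:
    def test_two_by_two_matches_closed_form_odds_ratio(self):
        # 40 exposed (30 events), 60 unexposed (12 events)
        x = np.concatenate([np.ones(40), np.zeros(60)])
        y = np.concatenate([np.ones(30), np.zeros(10), np.ones(12), np.zeros(48)])
        fit = inference.fit_logistic(x.reshape(-1, 1), y)
        odds_ratio = (30 / 10) / (12 / 48)
        assert fit.coef[1] == pytest.approx(np.log(odds_ratio), rel=1e-6)
        assert fit.coef[0] == pytest.approx(np.log(12 / 48), rel=1e-6)
        assert fit.exp_coef[1] == pytest.approx(odds_ratio, rel=1e-6)

    def test_matches_statsmodels_glm(self):
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(5)
        X = rng.normal(size=(400, 3))
        eta = -1.0 + X @ np.array([0.8, -0.5, 0.0])
        y = (rng.random(400) < 1 / (1 + np.exp(-eta))).astype(float)
        fit = inference.fit_logistic(X, y)
        ref = sm.GLM(y, sm.add_constant(X), family=sm.families.Binomial()).fit()
        assert np.allclose(fit.coef, ref.params, atol=1e-6)

    def test_duplicating_every_row_leaves_estimates_unchanged(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(150, 2))
        y = (rng.random(150) < 0.3).astype(float)
        a = inference.fit_logistic(X, y)
        b = inference.fit_logistic(np.vstack([X, X]), np.concatenate([y, y]))
        assert np.allclose(a.coef, b.coef, atol=1e-7)

    def test_independent_covariate_coefficient_near_zero(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(5000, 1))
        y = (rng.random(5000) < 0.4).astype(float)
        fit = inference.fit_logistic(X, y)
        assert abs(fit.coef[1]) < 0.1

    def test_complete_separation_flagged(self):
        x = np.concatenate([np.full(20, -1.0), np.full(20, 1.0)])
        y = np.concatenate([np.zeros(20), np.ones(20)])
        fit = inference.fit_logistic(x.reshape(-1, 1), y)
        assert fit.separated

    def test_degenerate_response_rejected(self):
        with pytest.raises(ValueError):
            inference.fit_logistic(np.zeros((5, 1)), np.ones(5))


class TestLinearFit:
    def test_exact_linear_function_recovered(self):
        x = np.linspace(0, 1, 30)
        beta, names = inference.fit_linear(x.reshape(-1, 1), 2.0 + 3.0 * x)
        assert np.allclose(beta, [2.0, 3.0])

    def test_orthogonal_covariates_equal_simple_regressions(self):
        rng = np.random.default_rng(1)
        a = np.tile([1.0, -1.0], 50)
        b = np.repeat([1.0, -1.0], 50)
        y = rng.normal(size=100) + 0.5 * a - 0.2 * b
        full, _ = inference.fit_linear(np.column_stack([a, b]), y)
        sa, _ = inference.fit_linear(a.reshape(-1, 1), y)
        sb, _ = inference.fit_linear(b.reshape(-1, 1), y)
        assert full[1] == pytest.approx(sa[1])
        assert full[2] == pytest.approx(sb[1])

    def test_matches_normal_equations(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(80, 3))
        y = rng.normal(size=80)
        beta, _ = inference.fit_linear(X, y)
        Xd = np.column_stack([np.ones(80), X])
        ref = np.linalg.solve(Xd.T @ Xd, Xd.T @ y)
        assert np.allclose(beta, ref, rtol=1e-6)

    def test_rank_deficiency_names_collinear_columns(self):
        x = np.linspace(0, 1, 20)
        X = np.column_stack([x, 2 * x])
        with pytest.raises(ValueError, match="collinear"):
            inference.fit_linear(X, x, names=["a", "a_doubled"])


class TestWithinOrderPermutation:
    def make_table(self, seed=0, n=60):
        rng = np.random.default_rng(seed)
        return pd.DataFrame(
            {
                "strength": rng.random(n),
                "order": rng.choice([1, 2, 3], n).astype(float),
                "social_pair": rng.random(n) < 0.1,
            }
        )

    def test_stratum_multisets_conserved(self):
        tab = self.make_table()
        out = inference.permute_strength_within_order(tab, np.random.default_rng(1))
        pooled = tab["social_pair"] | (tab["order"] == 1)
        assert sorted(out.loc[pooled, "strength"]) == pytest.approx(
            sorted(tab.loc[pooled, "strength"])
        )
        for k in (2, 3):
            mask = (tab["order"] == k) & ~tab["social_pair"]
            assert sorted(out.loc[mask, "strength"]) == pytest.approx(
                sorted(tab.loc[mask, "strength"])
            )

    def test_social_pairs_pool_with_first_order(self):
        tab = pd.DataFrame(
            {
                "strength": [0.9, 0.1, 0.2, 0.5],
                "order": [0.0, 1.0, 1.0, 2.0],
                "social_pair": [True, False, False, False],
            }
        )
        seen = set()
        for seed in range(40):
            out = inference.permute_strength_within_order(tab, np.random.default_rng(seed))
            assert out.loc[3, "strength"] == 0.5  # singleton stratum fixed
            seen.add(tuple(out["strength"][:3]))
        assert len(seen) > 1  # pooled stratum of 3 really shuffles

    def test_single_stratum_is_plain_permutation(self):
        tab = pd.DataFrame(
            {"strength": [1.0, 2.0, 3.0], "order": [2.0, 2.0, 2.0], "social_pair": False}
        )
        out = inference.permute_strength_within_order(tab, np.random.default_rng(3))
        assert sorted(out["strength"]) == [1.0, 2.0, 3.0]


class TestNodePermutation:
    def test_all_distinct_feeders_is_identity(self):
        rng = np.random.default_rng(0)
        mat = rng.random((4, 4))
        ids = ["a", "b", "c", "d"]
        lf = {t: f"F{i}" for i, t in enumerate(ids)}
        out = inference.permute_nodes_by_last_feeder(ids, mat, lf, np.random.default_rng(1))
        assert np.array_equal(out, mat)

    def test_degree_sequence_invariant(self):
        rng = np.random.default_rng(4)
        mat = rng.random((6, 6))
        mat = (mat + mat.T) / 2
        np.fill_diagonal(mat, 0)
        ids = list("abcdef")
        lf = {t: "F1" for t in ids}
        out = inference.permute_nodes_by_last_feeder(ids, mat, lf, np.random.default_rng(5))
        assert sorted(out.sum(axis=1)) == pytest.approx(sorted(mat.sum(axis=1)))

    def test_shared_feeder_pair_swaps_half_the_time(self):
        mat = np.arange(16, dtype=float).reshape(4, 4)
        ids = ["a", "b", "c", "d"]
        lf = {"a": "F1", "b": "F1", "c": "F2", "d": "F3"}
        swaps = 0
        for seed in range(1000):
            out = inference.permute_nodes_by_last_feeder(
                ids, mat, lf, np.random.default_rng(seed)
            )
            if not np.array_equal(out, mat):
                swaps += 1
        # Binomial(1000, 0.5): +-4 sd band
        assert 437 <= swaps <= 563

    def test_missing_label_rejected(self):
        with pytest.raises(ValueError, match="b"):
            inference.permute_nodes_by_last_feeder(
                ["a", "b"], np.zeros((2, 2)), {"a": "F1"}, np.random.default_rng(0)
            )


class TestPermutationTest:
    def test_constant_statistic_gives_p_one(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(100, 1))
        y = (rng.random(100) < 0.4).astype(float)

        def null_draw(_rng):
            return X  # identical design every time

        res = inference.permutation_test(
            y, X, ["x"], null_draw, n_perm=50, seed=1, family="logistic"
        )
        assert (res["p_empirical"] == 1.0).all()
        assert not res["significant"].any()

    def test_p_values_in_unit_interval_and_null_band_reported(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(120, 1))
        y = (rng.random(120) < 0.3).astype(float)

        def null_draw(r):
            return r.permutation(X)

        res = inference.permutation_test(
            y, X, ["x"], null_draw, n_perm=99, seed=3, family="logistic"
        )
        assert ((res["p_empirical"] > 0) & (res["p_empirical"] <= 1)).all()
        assert (res["null_low95"] <= res["null_high95"]).all()

    def test_p_distribution_close_to_uniform_across_seeds(self):
        # empirical p is seed-stable in distribution: across seeds the
        # spread stays within Monte-Carlo error of a fixed quantity
        rng = np.random.default_rng(7)
        X = rng.normal(size=(150, 1))
        y = (rng.random(150) < 0.35).astype(float)
        ps = []
        for seed in range(20):
            res = inference.permutation_test(
                y,
                X,
                ["x"],
                lambda r: r.permutation(X),
                n_perm=200,
                seed=seed,
                family="logistic",
            )
            ps.append(res.loc[res.term == "x", "p_empirical"].iloc[0])
        ps = np.array(ps)
        mc_se = np.sqrt(ps.mean() * (1 - ps.mean()) / 200)
        assert ps.std() < 3 * mc_se + 1e-9


class TestCategoryMeanTest:
    def test_identical_distributions_give_zero_diff_p_one(self):
        values = np.array([0.2, 0.4, 0.6, 0.2, 0.4, 0.6])
        labels = np.array(["a", "a", "a", "b", "b", "b"])
        res = inference.category_mean_test(values, labels, n_perm=50, seed=0)
        assert res["diff"].iloc[0] == 0.0
        assert res["p_empirical"].iloc[0] == 1.0

    def test_number_of_rows_is_pairs_of_categories(self):
        rng = np.random.default_rng(1)
        values = rng.random(40)
        labels = rng.choice(["a", "b", "c", "d"], 40)
        res = inference.category_mean_test(values, labels, n_perm=20, seed=0)
        assert len(res) == 6

    def test_small_n_agrees_with_exhaustive_enumeration(self):
        values = np.array([1.0, 2.0, 4.0, 8.0, 16.0, 32.0])
        labels = np.array(["a", "a", "a", "b", "b", "b"])
        obs = values[:3].mean() - values[3:].mean()
        # exact two-sided p over all 6!/(3!3!) label assignments
        hits = total = 0
        for combo in itertools.combinations(range(6), 3):
            sel = np.zeros(6, bool)
            sel[list(combo)] = True
            d = values[sel].mean() - values[~sel].mean()
            total += 1
            if abs(d) >= abs(obs) - 1e-12:
                hits += 1
        exact_p = hits / total
        res = inference.category_mean_test(values, labels, n_perm=4000, seed=2)
        assert res["p_empirical"].iloc[0] == pytest.approx(exact_p, abs=0.02)
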