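"""PCA reduction, multinomial fits, AICc ranking and deviance partitioning."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from bioregionize import (
    DEFAULT_GROUPS,
    aicc,
    aicc_value,
    akaike_weights,
    build_predictor_table,
    dredge_models,
    fit_multinomial,
    group_pca,
    historical_difference,
    partition_deviance,
    pc_variable_correlations,
    percent_deviance_explained,
)
from bioregionize.datasets import AMAZONIAN_DRIVER_DELTA_AICC


def simulate_multinomial(rng, X_design, B_true):
    """Draw classes from softmax probabilities with reference logit 0."""
    n = X_design.shape[0]
    Z = np.column_stack([np.zeros(n), X_design @ B_true.T])
    P = np.exp(Z - Z.max(axis=1, keepdims=True))
    P /= P.sum(axis=1, keepdims=True)
    u = rng.random(n)
    return (u[:, None] > P.cumsum(axis=1)).sum(axis=1)


class TestGroupPCA:
    def test_perfectly_correlated_pair_is_rank_one(self, rng):
        x = rng.normal(size=50)
        res = group_pca(pd.DataFrame({"a": x, "b": 3 * x + 1}), n_axes=2)
        assert res.variance_fractions[0] == pytest.approx(1.0)
        assert abs(res.loadings.iloc[0, 0]) == pytest.approx(
            abs(res.loadings.iloc[1, 0])
        )

    def test_uncorrelated_variables_have_near_unit_eigenvalues(self, rng):
        X = pd.DataFrame(rng.normal(size=(4000, 4)), columns=list("abcd"))
        res = group_pca(X, n_axes=4)
        # eigenvalues of a 4-var correlation matrix sum to 4; with iid input
        # each is 1 + O(1/sqrt(n))
        assert np.allclose(res.variance_fractions * 4, 1.0, atol=0.15)

    def test_full_axes_reconstruct_standardized_data(self, rng):
        X = pd.DataFrame(rng.normal(size=(30, 3)), columns=list("abc"))
        res = group_pca(X, n_axes=3)
        z = (X - X.mean()) / X.std(ddof=1)
        recon = res.scores.to_numpy() @ res.loadings.to_numpy().T
        assert np.allclose(recon, z.to_numpy(), atol=1e-8)

    def test_sign_convention_largest_loading_positive(self, rng):
        X = pd.DataFrame(rng.normal(size=(40, 5)))
        X.columns = [f"v{j}" for j in range(5)]
        res = group_pca(X, n_axes=2)
        for axis in res.loadings.columns:
            lo = res.loadings[axis].to_numpy()
            assert lo[np.argmax(np.abs(lo))] > 0

    def test_scores_centered(self, rng):
        X = pd.DataFrame(rng.normal(size=(25, 4)) + 7.0)
        X.columns = list("abcd")
        res = group_pca(X)
        assert np.allclose(res.scores.mean().to_numpy(), 0.0, atol=1e-10)

    def test_errors(self, rng):
        X = pd.DataFrame(rng.normal(size=(10, 2)), columns=["a", "b"])
        with pytest.raises(ValueError):
            group_pca(X, n_axes=3)
        with pytest.raises(ValueError):
            group_pca(X.iloc[:2])


class TestPearsonCorrelations:
    def test_axis_correlates_perfectly_with_itself(self, rng):
        scores = pd.DataFrame({"PC1": rng.normal(size=20)})
        out = pc_variable_correlations(scores, scores.rename(columns={"PC1": "v"}))
        assert out.loc[0, "r"] == pytest.approx(1.0)

    def test_hand_computed_five_points(self):
        x = pd.DataFrame({"v": [1.0, 2.0, 3.0, 4.0, 5.0]})
        s = pd.DataFrame({"PC1": [2.0, 1.0, 4.0, 3.0, 5.0]})
        out = pc_variable_correlations(s, x)
        # textbook Pearson: r = 0.8 for this configuration
        assert out.loc[0, "r"] == pytest.approx(0.8)
        assert 0 < out.loc[0, "p"] < 1

    def test_zero_variance_reported_missing(self, rng):
        scores = pd.DataFrame({"PC1": rng.normal(size=10)})
        out = pc_variable_correlations(scores, pd.DataFrame({"v": np.ones(10)}))
        assert np.isnan(out.loc[0, "r"])


class TestHistoricalDifference:
    def test_identical_field_gives_zeros(self):
        cur = pd.Series([1.0, 2.0], index=["a", "b"])
        assert (historical_difference(cur, cur.to_frame("m1")) == 0).all()

    def test_symmetric_models_cancel(self):
        cur = pd.Series([10.0, 20.0], index=["a", "b"])
        lgm = pd.DataFrame({"m1": cur - 1, "m2": cur + 1})
        assert (historical_difference(cur, lgm) == 0).all()

    def test_matches_loop_oracle(self, rng):
        idx = [f"c{i}" for i in range(30)]
        cur = pd.Series(rng.normal(size=30), index=idx)
        lgm = pd.DataFrame(
            {f"m{k}": rng.normal(size=30) for k in range(3)}, index=idx
        )
        out = historical_difference(cur, lgm)
        for cid in idx:
            expect = cur[cid] - (lgm.loc[cid, "m0"] + lgm.loc[cid, "m1"]
                                 + lgm.loc[cid, "m2"]) / 3
            assert out[cid] == pytest.approx(expect)

    def test_misaligned_cells_rejected(self):
        cur = pd.Series([1.0], index=["a"])
        lgm = pd.DataFrame({"m1": [1.0]}, index=["b"])
        with pytest.raises(ValueError):
            historical_difference(cur, lgm)


class TestFitMultinomial:
    def test_intercept_only_matches_closed_form(self, rng):
        y = rng.choice(list("abc"), size=90, p=[0.5, 0.3, 0.2])
        fit = fit_multinomial(pd.DataFrame(index=range(90)), y)
        counts = pd.Series(y).value_counts()
        expected = -2 * sum(c * np.log(c / 90) for c in counts)
        assert fit.deviance == pytest.approx(expected, abs=1e-6)
        probs = fit.predict_proba()
        for cls, freq in (counts / 90).items():
            assert probs[0, fit.classes.index(cls)] == pytest.approx(freq, abs=1e-5)

    def test_binary_case_matches_statsmodels_mle(self, rng):
        X = pd.DataFrame({"x1": rng.normal(size=80), "x2": rng.normal(size=80)})
        eta = 1.2 * X.x1 - 0.8 * X.x2
        y = np.where(rng.random(80) < 1 / (1 + np.exp(-eta)), "B", "A")
        fit = fit_multinomial(X, y)
        D = np.column_stack([
            np.ones(80),
            (X.x1 - X.x1.mean()) / X.x1.std(ddof=0),
            (X.x2 - X.x2.mean()) / X.x2.std(ddof=0),
        ])
        oracle = sm.MNLogit((pd.Series(y) == fit.classes[1]).astype(int), D).fit(
            disp=0
        )
        assert fit.log_likelihood == pytest.approx(oracle.llf, abs=1e-5)
        assert np.allclose(
            fit.coefficients.to_numpy().ravel(), oracle.params.to_numpy().ravel(),
            atol=1e-4,
        )

    def test_parameter_count_seven_classes_ten_level_categorical(self, rng):
        n = 800
        X = pd.DataFrame(
            {f"x{j}": rng.normal(size=n) for j in range(6)}
            | {"RIVERS": rng.choice([f"r{k}" for k in range(10)], size=n)}
        )
        y = rng.choice([f"BR{k}" for k in range(1, 8)], size=n)
        fit = fit_multinomial(X, y, ridge_lambda=1e-4)
        # (K-1) x (intercept + 6 continuous + 9 dummies) = 6 x 16 = 96
        assert fit.n_params == 96

    def test_probabilities_sum_to_one(self, rng):
        X = pd.DataFrame({"x": rng.normal(size=60)})
        y = rng.choice(list("abcd"), size=60)
        fit = fit_multinomial(X, y)
        assert np.allclose(fit.predict_proba().sum(axis=1), 1.0, atol=1e-9)

    def test_coefficient_recovery_within_three_se(self):
        # planted coefficients, n = 2000, unpenalized fit; at least 95% of
        # coefficients across seeds within 3 SE of truth
        total = within = 0
        B_true = np.array(
            [[0.5, 1.0, -0.8, 0.4, 0.0], [-0.3, -0.6, 0.9, 0.0, 0.7]]
        )
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            X = rng.normal(size=(2000, 4))
            D = np.column_stack([np.ones(2000), X])
            y = simulate_multinomial(rng, D, B_true)
            fit = fit_multinomial(
                pd.DataFrame(X, columns=list("abcd")),
                pd.Series([f"k{v}" for v in y]),
                reference_class="k0",
            )
            se = fit.standard_errors()
            for ci, cls in enumerate(["k1", "k2"]):
                est_row = fit.coefficients.loc[cls]
                se_row = se.loc[cls]
                for pi, term in enumerate(["(intercept)", "a", "b", "c", "d"]):
                    total += 1
                    within += (
                        abs(est_row[term] - B_true[ci, pi]) <= 3 * se_row[term]
                    )
        assert within / total >= 0.95

    def test_separation_with_ridge_stays_finite(self):
        X = pd.DataFrame({"g": ["a"] * 10 + ["b"] * 10})
        y = ["r1"] * 10 + ["r2"] * 10
        fit = fit_multinomial(X, y, ridge_lambda=1e-3)
        assert np.isfinite(fit.coefficients.to_numpy()).all()
        assert fit.deviance < 1.0  # near-perfect classification

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            fit_multinomial(pd.DataFrame(index=range(5)), ["a"] * 5)


class TestInformationCriteria:
    def test_aicc_closed_form(self):
        assert aicc_value(-100.0, 5, 50) == pytest.approx(210 + 60 / 44)

    def test_aicc_approaches_aic_for_large_n(self):
        assert aicc_value(-100.0, 5, 10**6) == pytest.approx(210.0, abs=1e-3)

    def test_aicc_monotone_in_params_at_equal_deviance(self):
        assert aicc_value(-50.0, 4, 100) < aicc_value(-50.0, 6, 100)

    def test_aicc_rejects_oversized_models(self):
        with pytest.raises(ValueError):
            aicc_value(-10.0, 10, 11)

    def test_matches_closed_form_on_random_triples(self, rng):
        for _ in range(50):
            ll = float(-rng.uniform(10, 500))
            k = int(rng.integers(1, 20))
            n = int(rng.integers(k + 2, 1000))
            expect = -2 * ll + 2 * k + 2 * k * (k + 1) / (n - k - 1)
            assert aicc_value(ll, k, n) == pytest.approx(expect)

    def test_published_delta_series_weights(self):
        w = akaike_weights(np.asarray(AMAZONIAN_DRIVER_DELTA_AICC))
        assert round(float(w[0]), 2) == 0.95
        assert round(float(w[2]), 3) == 0.009
        assert round(float(w[3]), 3) == 0.001

    def test_weight_conventions(self):
        assert akaike_weights([123.4]) == pytest.approx([1.0])
        assert akaike_weights([5.0, 5.0]) == pytest.approx([0.5, 0.5])

    def test_weights_shift_invariant_and_normalized(self, rng):
        vals = rng.uniform(100, 200, size=8)
        w1 = akaike_weights(vals)
        w2 = akaike_weights(vals + 57.3)
        assert np.allclose(w1, w2)
        assert w1.sum() == pytest.approx(1.0)

    def test_percent_deviance_explained(self, rng):
        y = rng.choice(list("ab"), size=40)
        null = fit_multinomial(pd.DataFrame(index=range(40)), y)
        assert percent_deviance_explained(null, null) == pytest.approx(0.0)

        class Fake:
            deviance = 40.0

        class FakeNull:
            deviance = 200.0

        assert percent_deviance_explained(Fake(), FakeNull()) == pytest.approx(80.0)


class TestDredge:
    def test_two_terms_enumerate_four_models(self, rng):
        X = pd.DataFrame(
            {"a": rng.normal(size=50), "b": rng.normal(size=50)}
        )
        y = rng.choice(["u", "v"], size=50)
        rank = dredge_models(X, y)
        assert len(rank.table) == 4
        assert set(rank.table["terms"]) == {"1", "a", "b", "a + b"}
        assert rank.table["waicc"].sum() == pytest.approx(1.0)
        assert rank.table.loc[0, "delta_aicc"] == 0.0

    def test_recovers_generating_terms(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(200 + seed)
            n = 400
            X = pd.DataFrame(
                {
                    "a": rng.normal(size=n),
                    "b": rng.normal(size=n),
                    "RIVERS": rng.choice(["r1", "r2", "r3"], size=n),
                }
            )
            eta1 = 2.0 * X.a + np.where(X.RIVERS == "r2", 2.5, 0) - np.where(
                X.RIVERS == "r3", 1.5, 0
            )
            eta2 = -1.5 * X.a + np.where(X.RIVERS == "r3", 2.5, 0)
            y = simulate_multinomial(
                rng, np.column_stack([eta1, eta2]), np.eye(2)
            )
            rank = dredge_models(X, pd.Series([f"g{v}" for v in y]))
            hits += {"a", "RIVERS"} <= set(rank.best_terms)
        assert hits >= 18  # >= 90% of seeds

    def test_aicc_sorted_and_null_present(self, rng):
        X = pd.DataFrame({"a": rng.normal(size=60)})
        y = rng.choice(["u", "v", "w"], size=60)
        rank = dredge_models(X, y)
        vals = rank.table["aicc"].to_numpy()
        assert (np.diff(vals) >= 0).all()
        null_row = rank.table[rank.table["terms"] == "1"]
        assert null_row["pct_deviance_explained"].iloc[0] == pytest.approx(0.0)


class TestPartitionDeviance:
    def test_rivers_only_signal_attributed_uniquely(self):
        # other predictor groups are pure noise: unique(R) carries (almost)
        # the whole explained deviance, every other unique fraction ~ 0
        for seed in range(10):
            rng = np.random.default_rng(300 + seed)
            n = 240
            X = pd.DataFrame(
                {
                    "CURE.PC1": rng.normal(size=n),
                    "CURE.PC2": rng.normal(size=n),
                    "HDT": rng.normal(size=n),
                    "HDP": rng.normal(size=n),
                    "TOPO.PC1": rng.normal(size=n),
                    "TOPO.PC2": rng.normal(size=n),
                    "VEGE.PC1": rng.normal(size=n),
                    "VEGE.PC2": rng.normal(size=n),
                    "RIVERS": rng.choice(["r1", "r2", "r3", "r4"], size=n),
                }
            )
            y = X["RIVERS"].str.replace("r", "BR")
            part = partition_deviance(DEFAULT_GROUPS, X, y, ridge_lambda=1e-3)
            uniques = {g: part.fractions[g] for g in "CTRV"}
            assert uniques["R"] == max(uniques.values())
            assert uniques["R"] >= part.pct_de_full - 10.0
            for g in "CTV":
                assert abs(uniques[g]) <= 2.0

    def test_redundant_groups_share_everything(self, rng):
        n = 150
        x = rng.normal(size=n)
        X = pd.DataFrame({"g1": x, "g2": x + rng.normal(0, 1e-6, size=n)})
        y = np.where(x + rng.normal(0, 0.5, size=n) > 0, "hi", "lo")
        part = partition_deviance(
            {"A": ["g1"], "B": ["g2"]}, X, y, ridge_lambda=1e-4
        )
        assert abs(part.fractions["A"]) < 2.0
        assert abs(part.fractions["B"]) < 2.0
        assert part.fractions["A&B"] > 10.0

    def test_fractions_sum_to_full_model_de(self, rng):
        n = 120
        X = pd.DataFrame(
            {
                "a": rng.normal(size=n),
                "b": rng.normal(size=n),
                "c": rng.normal(size=n),
            }
        )
        y = rng.choice(["u", "v", "w"], size=n)
        part = partition_deviance(
            {"A": ["a"], "B": ["b"], "C": ["c"]}, X, y
        )
        assert sum(part.fractions.values()) == pytest.approx(
            part.pct_de_full, abs=1e-9
        )
        assert part.unexplained == pytest.approx(100 - part.pct_de_full)

    def test_empty_groups_contribute_zero(self, rng):
        n = 100
        X = pd.DataFrame({"a": rng.normal(size=n), "b": rng.normal(size=n)})
        y = rng.choice(["u", "v"], size=n)
        part = partition_deviance(
            {"A": ["a"], "B": ["b"], "C": []}, X, y
        )
        assert part.fractions["C"] == 0.0
        assert part.fractions["A&C"] == 0.0


class TestPredictorAssembly:
    def test_build_predictor_table_columns(self, four_block_landscape):
        lat, env, _, _ = four_block_landscape
        pred, pcas = build_predictor_table(lat, env)
        expected = {
            "CURE.PC1", "CURE.PC2", "TOPO.PC1", "TOPO.PC2",
            "VEGE.PC1", "VEGE.PC2", "HDT", "HDP", "RIVERS",
        }
        assert set(pred.columns) == expected
        assert set(pcas) == {"CURE", "TOPO", "VEGE"}
        # HDT expectation: current is LGM + 4 by construction
        assert pred["HDT"].mean() == pytest.approx(4.0, abs=0.2)
        assert pred["RIVERS"].nunique() == lat.n_blocks
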