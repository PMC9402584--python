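"""PGLS regression: OLS limit, numeric-ML oracle, GVIF, LOO, prediction."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize, stats

from paleofin._phylo import node_depths
from paleofin.errors import DesignError
from paleofin.io import read_newick_string
from paleofin.pgls_speed import (
    bm_covariance,
    build_design,
    fit_pgls,
    gvif,
    loo_cross_validate,
    predict_speed,
    record_tip_labels,
    resolve_record_polytomies,
    select_models,
)

from conftest import random_tree_newick


def star_frame(rng, n=30):
    """Records on a star phylogeny (one per species, equal depths)."""
    df = pd.DataFrame(
        {
            "species": [f"t{i}" for i in range(n)],
            "Length": rng.uniform(5, 100, n),
            "HeWiCF": rng.uniform(0.5, 3.0, n),
            "Mode": rng.choice(["burst", "cruising"], n),
            "Cond": rng.choice(["free", "non-free"], n),
        }
    )
    df["speed"] = (
        4.0 - 0.02 * df.Length + 0.5 * df.HeWiCF
        - 1.0 * (df.Mode == "cruising") + rng.normal(0, 0.3, n)
    )
    newick = "(" + ",".join(f"t{i}:1" for i in range(n)) + ");"
    return df, read_newick_string(newick)


def test_pgls_on_star_tree_equals_ols(rng):
    df, tree = star_frame(rng)
    fit = fit_pgls(df, tree, ("Length", "Mode", "HeWiCF"))
    X, _, _, _ = build_design(df, ("Length", "Mode", "HeWiCF"))
    ols = np.linalg.lstsq(X, df.speed.to_numpy(), rcond=None)[0]
    np.testing.assert_allclose(fit.beta, ols, atol=1e-8)


class TestCovariance:
    def test_star_tree_is_diagonal(self):
        tree = read_newick_string("(A:1,B:1,C:1);")
        C = bm_covariance(tree, ["A", "B", "C"])
        np.testing.assert_allclose(C, np.eye(3))

    def test_matches_path_enumeration_oracle(self, rng):
        """Shared root-to-MRCA path length via independent parent-chain walk."""
        for _ in range(5):
            tree = read_newick_string(random_tree_newick(7, rng))
            tips = [l.taxon.label for l in tree.leaf_node_iter()]
            C = bm_covariance(tree, tips)
            leaves = {l.taxon.label: l for l in tree.leaf_node_iter()}

            def ancestors(node):
                chain = []
                while node is not None:
                    chain.append(node)
                    node = node.parent_node
                return chain

            depths = node_depths(tree)
            for i, a in enumerate(tips):
                for j, b in enumerate(tips):
                    common = [n for n in ancestors(leaves[a]) if n in ancestors(leaves[b])]
                    mrca_depth = max(depths[n] for n in common)
                    assert C[i, j] == pytest.approx(mrca_depth, abs=1e-9)

    def test_root_edge_counted_as_shared_path(self):
        tree = read_newick_string("((A:1,B:1):1);")
        C = bm_covariance(tree, ["A", "B"])
        assert C[0, 1] == pytest.approx(1.0)
        assert C[0, 0] == pytest.approx(2.0)


class TestNumericMLOracle:
    def _numeric_oracle(self, X, y, C):
        """Maximize the multivariate-normal likelihood numerically over (beta, log s2)."""
        n = len(y)
        Ci = np.linalg.inv(C)
        sign, logdetC = np.linalg.slogdet(C)

        def negll(params):
            beta, logs2 = params[:-1], params[-1]
            r = y - X @ beta
            s2 = np.exp(logs2)
            return 0.5 * (n * np.log(2 * np.pi * s2) + logdetC + r @ Ci @ r / s2)

        x0 = np.concatenate([np.linalg.lstsq(X, y, rcond=None)[0], [0.0]])
        res = optimize.minimize(negll, x0, method="Nelder-Mead",
                                options={"xatol": 1e-12, "fatol": 1e-14, "maxiter": 20000})
        return res.x[:-1], -res.fun

    def test_four_tip_worked_case(self, rng):
        tree = read_newick_string("((A:1.0,B:1.5):0.5,(C:0.7,D:2.0):1.0);")
        df = pd.DataFrame(
            {
                "species": list("ABCD"),
                "speed": [1.2, 2.0, 1.6, 3.1],
                "Length": [10.0, 20.0, 15.0, 40.0],
            }
        )
        fit = fit_pgls(df, tree, ("Length",))
        C = bm_covariance(tree, list("ABCD"))
        X, _, _, _ = build_design(df, ("Length",))
        beta_o, logL_o = self._numeric_oracle(X, df.speed.to_numpy(), C)
        np.testing.assert_allclose(fit.beta, beta_o, atol=1e-6)
        assert fit.logL == pytest.approx(logL_o, abs=1e-6)


class TestPolytomyResolution:
    def _records(self, species):
        return pd.DataFrame(
            {"species": species, "speed": np.ones(len(species)),
             "Length": np.ones(len(species))}
        )

    def test_three_records_share_parent_depth(self):
        tree = read_newick_string("((A:1,B:1):1,C:2);")
        df = self._records(["A", "A", "A", "B", "C"])
        rt = resolve_record_polytomies(tree, df, seed=0, epsilon=1e-6)
        labels = record_tip_labels(df)
        C = bm_covariance(rt, labels)
        # the three A-record tips share (almost) the full depth of tip A
        for i in range(3):
            for j in range(i + 1, 3):
                assert C[i, j] == pytest.approx(2.0, abs=1e-5)
            assert C[i, i] == pytest.approx(2.0, abs=1e-5)

    def test_all_singletons_leave_tree_unchanged(self):
        tree = read_newick_string("((A:1,B:1):1,C:2);")
        df = self._records(["A", "B", "C"])
        rt = resolve_record_polytomies(tree, df, seed=0)
        assert {l.taxon.label for l in rt.leaf_node_iter()} == {"A", "B", "C"}

    def test_deterministic_given_seed(self):
        tree = read_newick_string("((A:1,B:1):1,C:2);")
        df = self._records(["A"] * 5 + ["B", "C"])
        t1 = resolve_record_polytomies(tree, df, seed=42)
        t2 = resolve_record_polytomies(tree, df, seed=42)
        assert t1.as_string(schema="newick") == t2.as_string(schema="newick")


class TestModelSelection:
    def test_identical_formulas_share_weight(self, rng):
        df, tree = star_frame(rng)
        fits = select_models(df, tree, [("Length",), ("Length",)])
        assert fits[0].waic == pytest.approx(0.5, abs=1e-12)
        assert sum(f.waic for f in fits) == pytest.approx(1.0, abs=1e-12)
        assert fits[0].delta_aic == 0.0

    def test_true_smaller_model_usually_wins_aic(self, rng):
        """Data generated from Speed ~ Length: adding a spurious term should
        lose on AIC most of the time at n = 200."""
        wins = 0
        n_sim = 100
        newick = "(" + ",".join(f"t{i}:1" for i in range(200)) + ");"
        tree = read_newick_string(newick)
        for _ in range(n_sim):
            df = pd.DataFrame(
                {
                    "species": [f"t{i}" for i in range(200)],
                    "Length": rng.uniform(5, 100, 200),
                    "HeWiCF": rng.uniform(0.5, 3.0, 200),
                }
            )
            df["speed"] = 4.0 + 0.02 * df.Length + rng.normal(0, 0.3, 200)
            fits = select_models(df, tree, [("Length",), ("Length", "HeWiCF")])
            if fits[0].formula == ("Length",):
                wins += 1
        assert wins >= 80


class TestGvif:
    def test_orthogonal_predictors_are_unity(self):
        n = 64
        df = pd.DataFrame(
            {
                "species": [f"s{i}" for i in range(n)],
                "speed": np.ones(n),
                "Length": np.tile([1.0, 2.0], n // 2),
                "HeWiCF": np.repeat([1.0, 2.0], n // 2),
            }
        )
        table = gvif(df, ("Length", "HeWiCF"))
        np.testing.assert_allclose(table["GVIF^(1/(2Df))"], 1.0, atol=1e-9)

    def test_exact_collinearity_raises(self, rng):
        df, _ = star_frame(rng)
        df["AR"] = df["HeWiCF"]  # duplicated continuous predictor
        with pytest.raises(DesignError):
            gvif(df, ("HeWiCF", "AR"))

    def test_two_predictor_closed_form(self, rng):
        """For two predictors with correlation rho, VIF = 1 / (1 - rho^2)."""
        n = 4000
        z = rng.normal(size=n)
        x1 = z + rng.normal(scale=np.sqrt(1 / 0.81 - 1), size=n)
        # construct exact rho = 0.9 by Gram-Schmidt
        x1 = (x1 - x1.mean()) / x1.std()
        e = rng.normal(size=n)
        e = e - e.mean()
        e -= x1 * (e @ x1) / (x1 @ x1)
        e /= np.linalg.norm(e)
        x2 = 0.9 * x1 / np.linalg.norm(x1) + np.sqrt(1 - 0.81) * e
        df = pd.DataFrame(
            {"species": [f"s{i}" for i in range(n)], "speed": np.ones(n),
             "Length": x1, "HeWiCF": x2}
        )
        table = gvif(df, ("Length", "HeWiCF")).set_index("term")
        vif = 1 / (1 - 0.9**2)
        assert table.loc["Length", "GVIF"] == pytest.approx(vif, rel=1e-6)
        assert table.loc["Length", "GVIF^(1/(2Df))"] == pytest.approx(np.sqrt(vif), rel=1e-6)
        assert bool(table.loc["Length", "flagged"])


class TestLeaveOneOut:
    def test_noiseless_linear_data_predicts_perfectly(self, rng):
        df, tree = star_frame(rng)
        df["speed"] = 4.0 - 0.02 * df.Length + 0.5 * df.HeWiCF
        _, r2 = loo_cross_validate(df, tree, ("Length", "HeWiCF"))
        assert r2 == pytest.approx(1.0, abs=1e-9)

    def test_pure_noise_has_no_predictive_power(self, rng):
        r2s = []
        newick = "(" + ",".join(f"t{i}:1" for i in range(100)) + ");"
        tree = read_newick_string(newick)
        for _ in range(20):
            df = pd.DataFrame(
                {
                    "species": [f"t{i}" for i in range(100)],
                    "Length": rng.uniform(5, 100, 100),
                    "speed": rng.normal(2.0, 0.5, 100).clip(0.1),
                }
            )
            _, r2 = loo_cross_validate(df, tree, ("Length",))
            r2s.append(r2)
        assert np.median(r2s) < 0.15


class TestPrediction:
    def test_training_mean_row_gives_fitted_mean(self, rng):
        df, tree = star_frame(rng)
        fit = fit_pgls(df, tree, ("Length", "HeWiCF"))
        pred = predict_speed(
            fit,
            {"total_length": df.Length.mean(), "metrics": {"he_wi": df.HeWiCF.mean()}},
        )
        X, _, _, _ = build_design(df, ("Length", "HeWiCF"))
        assert pred == pytest.approx(float(X.mean(axis=0) @ fit.beta), abs=1e-10)

    def test_unknown_categorical_level_raises(self, rng):
        from paleofin.errors import PredictionError

        df, tree = star_frame(rng)
        fit = fit_pgls(df, tree, ("Length", "Mode"))
        with pytest.raises(PredictionError):
            predict_speed(fit, {"total_length": 10.0, "mode": "warp-drive", "metrics": {}})

    def test_prediction_is_linear_in_continuous_terms(self, rng):
        df, tree = star_frame(rng)
        fit = fit_pgls(df, tree, ("Length", "HeWiCF"))

        def p(length, hewi):
            return predict_speed(fit, {"total_length": length, "metrics": {"he_wi": hewi}})

        lhs = p(10, 1.0) + p(20, 2.0) - p(0 + 1e-300, 0 + 1e-300)
        assert lhs == pytest.approx(p(30, 3.0), abs=1e-8)
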