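"""Screening cascade, blocks, nested CV, calibration, and LOCO validation."""

import warnings

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from sklearn.linear_model import LogisticRegression

from pnetrad import prediction as P


def _logistic_only(seed=0):
    return {"logistic": LogisticRegression(max_iter=1000)}


class TestCorrelationCluster:
    def test_duplicated_feature_single_cluster(self):
        gen = np.random.default_rng(0)
        x = gen.normal(size=50)
        df = pd.DataFrame({"a": x, "a_copy": x, "b": gen.normal(size=50)})
        clusters, reps = P.correlation_cluster(df)
        assert sorted(map(tuple, clusters)) == [("a", "a_copy"), ("b",)]
        assert len(reps) == 2

    def test_independent_features_mostly_singletons(self):
        gen = np.random.default_rng(1)
        df = pd.DataFrame(gen.normal(size=(500, 12)), columns=[f"v{i}" for i in range(12)])
        clusters, _ = P.correlation_cluster(df)
        assert len(clusters) == 12  # |rho| >= 0.8 at n=500 has negligible chance

    def test_components_match_networkx_oracle(self):
        gen = np.random.default_rng(2)
        base = gen.normal(size=(60, 5))
        cols = {}
        for j in range(5):
            cols[f"g{j}a"] = base[:, j]
            cols[f"g{j}b"] = base[:, j] + gen.normal(scale=0.1, size=60)
        for j in range(10):
            cols[f"ind{j}"] = gen.normal(size=60)
        df = pd.DataFrame(cols)
        clusters, _ = P.correlation_cluster(df, threshold=0.8)
        rho = df.corr(method="spearman").abs()
        G = nx.Graph()
        G.add_nodes_from(df.columns)
        for i, a in enumerate(df.columns):
            for b in df.columns[i + 1:]:
                if rho.loc[a, b] >= 0.8:
                    G.add_edge(a, b)
        oracle = sorted(sorted(c) for c in nx.connected_components(G))
        assert sorted(map(list, clusters)) == oracle

    def test_all_missing_feature_dropped(self):
        df = pd.DataFrame({"a": [1.0, 2, 3, 4], "bad": [np.nan] * 4})
        with pytest.warns(UserWarning, match="all-missing"):
            clusters, _ = P.correlation_cluster(df)
        assert clusters == [["a"]]


class TestScreening:
    def test_candidate_equal_to_baseline_variable_uninformative(self):
        gen = np.random.default_rng(3)
        base = pd.DataFrame({"x": gen.normal(size=80)})
        y = (base["x"] + gen.normal(scale=0.5, size=80) > 0).astype(float)
        p = P.baseline_adjusted_lrt(base["x"].to_numpy(), base, y)
        assert p > 0.5

    def test_null_candidates_type_one_error_calibrated(self):
        gen = np.random.default_rng(4)
        n_sim, hits, pvals = 250, 0, []
        for _ in range(n_sim):
            base = pd.DataFrame({"x": gen.normal(size=60)})
            y = gen.integers(0, 2, 60).astype(float)
            cand = gen.normal(size=60)
            p = P.baseline_adjusted_lrt(cand, base, y)
            pvals.append(p)
            hits += int(p < 0.05)
        rate = hits / n_sim
        assert abs(rate - 0.05) < 0.045  # ~3 binomial SDs
        # roughly uniform p-values
        assert abs(np.mean(pvals) - 0.5) < 0.08

    def test_strong_candidate_detected(self):
        gen = np.random.default_rng(5)
        n = 100
        signal = gen.normal(size=n)
        y = (signal + gen.normal(scale=0.4, size=n) > 0).astype(float)
        base = pd.DataFrame({"noise": gen.normal(size=n)})
        cands = pd.DataFrame({"signal": signal, "junk": gen.normal(size=n)})
        res = P.screen_candidates(cands, base, y)
        res = res.set_index("candidate")
        assert res.loc["signal", "q"] < 0.10
        assert res.loc["signal", "selected"]

    def test_stability_selection_strong_vs_noise(self):
        gen = np.random.default_rng(6)
        n = 90
        signal = gen.normal(size=n)
        y = (signal + gen.normal(scale=0.3, size=n) > 0).astype(float)
        base = pd.DataFrame({"age": gen.normal(size=n)})
        cands = pd.DataFrame({"strong": signal, "noise": gen.normal(size=n)})
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            freq, selected = P.stability_selection(cands, base, y, B=40, seed=7)
        assert freq["strong"] >= 0.9
        assert freq["noise"] < 0.6
        assert "strong" in selected

    def test_stability_selection_reproducible(self):
        gen = np.random.default_rng(8)
        base = pd.DataFrame({"x": gen.normal(size=50)})
        cands = pd.DataFrame({"a": gen.normal(size=50), "b": gen.normal(size=50)})
        y = gen.integers(0, 2, 50).astype(float)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            f1, _ = P.stability_selection(cands, base, y, B=15, seed=42)
            f2, _ = P.stability_selection(cands, base, y, B=15, seed=42)
        assert f1.equals(f2)


class TestBlocks:
    def test_higher_grade_exclusions(self):
        blocks = P.assemble_blocks("higher_grade")
        ma = blocks["MA"].variables
        mb = blocks["MB"].variables
        assert all(s in ma for s in ("A1", "A2", "A5", "A6"))
        assert all(s not in ma for s in ("A3", "A4", "A7"))
        assert set(mb) & {"B1", "B2", "B3"} == {"B1", "B2"}
        assert "grade" not in blocks["M0"].variables
        assert len(blocks["M0"].variables) == 5

    def test_progression_blocks_complete(self):
        blocks = P.assemble_blocks("progression")
        assert set(P.A_SIGNATURES) <= set(blocks["MA"].variables)
        assert set(P.B_SIGNATURES) <= set(blocks["MB"].variables)
        assert "grade" in blocks["M0"].variables

    def test_unknown_target_errors(self):
        with pytest.raises(ValueError, match="unknown target"):
            P.assemble_blocks("mortality")


class TestNestedCV:
    def test_perfect_predictor_auc_one(self):
        gen = np.random.default_rng(9)
        n = 60
        y = np.repeat([0.0, 1.0], n // 2)
        X = pd.DataFrame({
            "perfect": y * 10 + gen.normal(scale=0.01, size=n),
            "noise1": gen.normal(size=n),
            "noise2": gen.normal(size=n),
        })
        block = P.BlockSpec("M0", "progression", tuple(X.columns))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = P.nested_cv(block, X, y, classifiers=_logistic_only(), seed=0, n_boot=50)
        assert res["logistic"].auc == pytest.approx(1.0)
        assert res["logistic"].brier <= 0.05
        assert all(k in (2, 3) for k in res["logistic"].chosen_k)

    def test_oof_predictions_cover_every_evaluable_patient(self):
        gen = np.random.default_rng(10)
        X = pd.DataFrame(gen.normal(size=(44, 5)), columns=list("abcde"))
        y = gen.integers(0, 2, 44).astype(float)
        y[3] = np.nan  # one non-evaluable patient
        block = P.BlockSpec("M0", "progression", tuple(X.columns))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = P.nested_cv(block, X, y, classifiers=_logistic_only(), seed=1, n_boot=20)
        r = res["logistic"]
        assert len(r.oof_probabilities) == 43
        assert np.all((r.oof_probabilities > 0) & (r.oof_probabilities < 1))

    def test_deterministic_given_seed(self):
        gen = np.random.default_rng(11)
        X = pd.DataFrame(gen.normal(size=(40, 4)), columns=list("abcd"))
        y = gen.integers(0, 2, 40).astype(float)
        block = P.BlockSpec("M0", "progression", tuple(X.columns))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            r1 = P.nested_cv(block, X, y, classifiers=_logistic_only(), seed=5, n_boot=30)
            r2 = P.nested_cv(block, X, y, classifiers=_logistic_only(), seed=5, n_boot=30)
        np.testing.assert_array_equal(r1["logistic"].oof_probabilities,
                                      r2["logistic"].oof_probabilities)
        assert r1["logistic"].auc_ci == r2["logistic"].auc_ci


class TestCalibration:
    def test_well_calibrated_predictions_recovered(self):
        gen = np.random.default_rng(12)
        p = gen.uniform(0.05, 0.95, 2000)
        y = gen.binomial(1, p)
        m = P.calibration_metrics(y, p, n_boot=100, seed=0)
        assert m["slope"] == pytest.approx(1.0, abs=0.1)
        assert m["intercept"] == pytest.approx(0.0, abs=0.1)
        assert m["slope_ci"][0] < 1.0 < m["slope_ci"][1]

    def test_sharpened_logits_halve_the_slope(self):
        gen = np.random.default_rng(13)
        p = gen.uniform(0.05, 0.95, 2000)
        y = gen.binomial(1, p)
        logit = np.log(p / (1 - p))
        p_sharp = 1 / (1 + np.exp(-2 * logit))
        m = P.calibration_metrics(y, p_sharp, n_boot=0)
        assert m["slope"] == pytest.approx(0.5, abs=0.1)

    def test_constant_predictions_error(self):
        y = np.array([0, 1, 0, 1])
        with pytest.raises(ValueError, match="constant predictions"):
            P.calibration_metrics(y, np.full(4, 0.4))

    def test_intercept_fixed_slope_variant_reported(self):
        gen = np.random.default_rng(14)
        p = gen.uniform(0.1, 0.9, 500)
        y = gen.binomial(1, np.clip(p * 1.2, 0, 1))
        m = P.calibration_metrics(y, p, n_boot=0)
        assert "intercept_fixed" in m and np.isfinite(m["intercept_fixed"])


class TestLoco:
    def test_center_specific_signal_does_not_transfer(self):
        gen = np.random.default_rng(15)
        n = 120
        centers = np.array(["C1"] * (n // 2) + ["C2"] * (n // 2))
        y = gen.integers(0, 2, n).astype(float)
        # predictor = center label (plus jitter): within-center it is constant
        X = pd.DataFrame({
            "leak": (centers == "C2").astype(float) + gen.normal(scale=0.01, size=n),
            "noise": gen.normal(size=n),
        })
        block = P.BlockSpec("M0", "progression", tuple(X.columns))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            auc, ci, _, _ = P.loco_cv(block, X, y, centers, seed=0, n_boot=50)
        assert abs(auc - 0.5) < 0.12

    def test_homogeneous_strong_signal_transfers(self):
        gen = np.random.default_rng(16)
        n = 120
        centers = np.array(["C1", "C2"] * (n // 2))
        signal = gen.normal(size=n)
        y = (signal + gen.normal(scale=0.5, size=n) > 0).astype(float)
        X = pd.DataFrame({"signal": signal, "noise": gen.normal(size=n)})
        block = P.BlockSpec("M0", "progression", tuple(X.columns))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            auc, ci, _, _ = P.loco_cv(block, X, y, centers, seed=1, n_boot=50)
        assert auc > 0.8

    def test_center_missing_a_class_warns_nan(self):
        gen = np.random.default_rng(17)
        n = 40
        centers = np.array(["C1"] * 20 + ["C2"] * 20)
        y = np.concatenate([gen.integers(0, 2, 20).astype(float), np.zeros(20)])
        X = pd.DataFrame({"a": gen.normal(size=n), "b": gen.normal(size=n)})
        block = P.BlockSpec("M0", "progression", tuple(X.columns))
        with pytest.warns(UserWarning, match="lacks both outcome classes"):
            auc, _, _, _ = P.loco_cv(block, X, y, centers, seed=0)
        assert np.isnan(auc)
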