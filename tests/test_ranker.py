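"""Pair extraction, rank-SVM training, scoring, CV and baselines."""

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.stats import pearsonr, spearmanr

from mqaprank.features import FeatureMatrix
from mqaprank.ranker import (
    RankModel,
    TrainingPairSet,
    build_training_pairs,
    cross_validate,
    extract_pairs,
    score_decoys,
    train_classification_baseline,
    train_rank_svm,
    train_regression_baseline,
)
from mqaprank.synthetic import FeatureSpec, simulate_feature_benchmark


def _fm(values, target="T1", names=None):
    values = np.atleast_2d(np.asarray(values, float))
    names = names or [f"f{j}" for j in range(values.shape[1])]
    ids = [f"d{i:02d}" for i in range(values.shape[0])]
    return FeatureMatrix(target, ids, names, values)


class TestExtractPairs:
    def test_all_ordered_pairs(self):
        fm = _fm([[1.0], [2.0], [3.0]])
        q = {"d00": 80.0, "d01": 70.0, "d02": 60.0}
        ps = extract_pairs(fm, q)
        assert ps.n_pairs == 3
        # every difference vector points from better to worse: positive here
        np.testing.assert_array_equal(np.sign(ps.X @ np.array([-1.0])) > 0, [True] * 3)

    def test_ties_skipped(self):
        fm = _fm([[1.0], [2.0], [3.0]])
        ps = extract_pairs(fm, {"d00": 80.0, "d01": 80.0, "d02": 60.0}, tie_tol=0.0)
        assert ps.n_pairs == 2

    def test_cap_subsample_deterministic(self):
        rng = np.random.default_rng(0)
        fm = _fm(rng.normal(size=(100, 2)))
        q = {d: float(i) for i, d in enumerate(fm.decoy_ids)}
        a = extract_pairs(fm, q, cap_per_target=50, seed=7)
        b = extract_pairs(fm, q, cap_per_target=50, seed=7)
        assert a.n_pairs == 50
        np.testing.assert_array_equal(a.X, b.X)

    def test_single_decoy_warns_empty(self):
        fm = _fm([[1.0]])
        with pytest.warns(UserWarning):
            ps = extract_pairs(fm, {"d00": 1.0})
        assert ps.n_pairs == 0

    def test_missing_quality_rejected(self):
        fm = _fm([[1.0], [2.0]])
        with pytest.raises(ValueError):
            extract_pairs(fm, {"d00": 1.0})


class TestTrainRankSvm:
    def test_separable_single_feature(self):
        """Feature equal to quality: positive weight, no violated pairs."""
        fm = _fm([[60.0], [70.0], [80.0]])
        q = {d: float(fm.values[i, 0]) for i, d in enumerate(fm.decoy_ids)}
        ps = extract_pairs(fm, q)
        m = train_rank_svm(ps, C=10.0)
        assert m.omega[0] > 0
        assert m.slack_sum == pytest.approx(0.0, abs=1e-6)

    def test_invalid_inputs(self):
        ps = TrainingPairSet(X=np.ones((2, 1)), target_ids=["t", "t"], feature_names=["f"])
        with pytest.raises(ValueError):
            train_rank_svm(ps, C=-1.0)
        empty = TrainingPairSet(X=np.empty((0, 1)), target_ids=[], feature_names=["f"])
        with pytest.raises(ValueError):
            train_rank_svm(empty)

    @pytest.mark.parametrize("C", [0.1, 1.0, 10.0])
    def test_objective_matches_generic_qp_oracle(self, rng, C):
        """Objective within 1e-4 of an independent constrained-QP solution."""
        n, d = 30, 3
        X = rng.normal(size=(n, d)) + 0.2
        ps = TrainingPairSet(X=X, target_ids=["t"] * n, feature_names=list("abc"))
        m = train_rank_svm(ps, C=C)
        oracle = _qp_oracle(X, C)
        assert m.objective_V == pytest.approx(oracle, abs=1e-4)

    def test_slack_vanishes_on_separable_data_as_C_grows(self, rng):
        # well-spaced qualities so a finite-norm weight separates all pairs
        q = rng.permutation(20) * 5.0
        X = (q[:, None] * [1.0, -0.5])
        fm = _fm(X)
        quality = {d: float(q[i]) for i, d in enumerate(fm.decoy_ids)}
        slacks = []
        for C in (0.01, 1.0, 100.0):
            m = train_rank_svm(extract_pairs(fm, quality), C=C)
            slacks.append(m.slack_sum)
        assert slacks[-1] < 1e-6
        assert slacks[0] >= slacks[-1]


def _qp_oracle(X, C):
    """Generic inequality-constrained QP in (w, xi) via SLSQP."""
    n, d = X.shape

    def f(z):
        return 0.5 * z[:d] @ z[:d] + C * z[d:].sum()

    cons = [
        {"type": "ineq", "fun": (lambda z, k=k: z[d + k] - 1.0 + X[k] @ z[:d])}
        for k in range(n)
    ]
    cons.append({"type": "ineq", "fun": lambda z: z[d:]})
    z0 = np.concatenate([np.zeros(d), np.ones(n)])
    res = minimize(f, z0, constraints=cons, method="SLSQP",
                   options={"maxiter": 2000, "ftol": 1e-12})
    return float(res.fun)


class TestScoring:
    def test_dot_product_ranking(self):
        m = RankModel(omega=np.array([1.0, 0.0]), feature_names=["a", "b"], C=1.0, tol=1e-6)
        fm = _fm([[2.0, 9.0], [1.0, 9.0]], names=["a", "b"])
        est = score_decoys(m, fm)
        assert list(est.rank) == [1, 2]
        np.testing.assert_allclose(est.reciprocal_rank, [1.0, 0.5])

    def test_zero_weights_tie_break_by_decoy_id(self):
        m = RankModel(omega=np.zeros(1), feature_names=["a"], C=1.0, tol=1e-6)
        est = score_decoys(m, _fm([[5.0], [1.0], [3.0]], names=["a"]))
        assert list(est.rank) == [1, 2, 3]  # lexicographic d00 < d01 < d02

    def test_feature_mismatch_lists_difference(self):
        m = RankModel(omega=np.zeros(2), feature_names=["a", "b"], C=1.0, tol=1e-6)
        with pytest.raises(ValueError, match="model-only.*'b'"):
            score_decoys(m, _fm([[1.0, 2.0]], names=["a", "c"]))

    def test_input_order_invariance(self, rng):
        values = rng.normal(size=(10, 3))
        m = RankModel(omega=rng.normal(size=3), feature_names=["a", "b", "c"], C=1.0, tol=1e-6)
        fm = _fm(values, names=["a", "b", "c"])
        est = score_decoys(m, fm)
        perm = rng.permutation(10)
        fm_p = FeatureMatrix("T1", [fm.decoy_ids[i] for i in perm],
                             fm.feature_names, values[perm])
        est_p = score_decoys(m, fm_p)
        for d in fm.decoy_ids:
            i = est.decoy_ids.index(d)
            j = est_p.decoy_ids.index(d)
            assert est.rank[i] == est_p.rank[j]

    def test_ranking_consistent_with_reciprocal_rank(self, rng):
        m = RankModel(omega=rng.normal(size=2), feature_names=["a", "b"], C=1.0, tol=1e-6)
        est = score_decoys(m, _fm(rng.normal(size=(8, 2)), names=["a", "b"]))
        by_score = np.argsort(-est.raw_score, kind="stable")
        by_rr = np.argsort(-est.reciprocal_rank, kind="stable")
        np.testing.assert_array_equal(est.rank[by_score], sorted(est.rank))
        np.testing.assert_array_equal(est.rank[by_rr], sorted(est.rank))

    def test_scale_equivariance_of_ranking(self, rng):
        """Multiplying all features by a constant leaves rankings unchanged."""
        bench = simulate_feature_benchmark(n_targets=4, n_decoys=15, seed=3)
        sets = bench.ranking_sets()
        m = train_rank_svm(build_training_pairs(sets), C=1.0)
        fm, _ = sets[0]
        est = score_decoys(m, fm)
        scaled_sets = [
            (FeatureMatrix(f.target_id, f.decoy_ids, f.feature_names, f.values * 7.5), q)
            for f, q in sets
        ]
        m2 = train_rank_svm(build_training_pairs(scaled_sets), C=1.0)
        est2 = score_decoys(m2, scaled_sets[0][0])
        np.testing.assert_array_equal(est.rank, est2.rank)

    def test_model_save_load_roundtrip(self, tmp_path, rng):
        m = RankModel(omega=rng.normal(size=3), feature_names=["a", "b", "c"],
                      C=2.0, tol=1e-6, norm_stats={"a": (0.5, 2.0), "b": (0.0, 1.0),
                                                   "c": (-1.0, 3.0)},
                      objective_V=12.5, slack_sum=0.25, seed=42)
        m.save(tmp_path / "model.txt")
        back = RankModel.load(tmp_path / "model.txt")
        np.testing.assert_allclose(back.omega, m.omega, rtol=0, atol=0)
        assert back.norm_stats == m.norm_stats
        assert back.C == m.C and back.seed == m.seed


class TestRecovery:
    def test_noise_free_features_give_perfect_heldout_spearman(self):
        spec = [FeatureSpec("f0", 1.0, 0.0), FeatureSpec("f1", -2.0, 0.0)]
        bench = simulate_feature_benchmark(n_targets=6, n_decoys=30, feature_spec=spec, seed=5)
        sets = bench.ranking_sets()
        m = train_rank_svm(build_training_pairs(sets[:4]), C=1.0)
        for fm, q in sets[4:]:
            est = score_decoys(m, fm)
            truth = [q[d] for d in est.decoy_ids]
            rho = spearmanr(est.raw_score, truth)[0]
            assert rho == 1.0

    def test_heldout_correlation_degrades_with_noise(self):
        """Test-set correlation decreases monotonically along a noise grid."""
        sigmas = [0.0, 20.0, 80.0, 300.0]
        mean_r = []
        for sigma in sigmas:
            rs = []
            for rep in range(20):
                spec = [FeatureSpec(f"f{j}", 1.0, sigma) for j in range(2)]
                bench = simulate_feature_benchmark(
                    n_targets=3, n_decoys=25, feature_spec=spec, seed=1000 * rep + int(sigma)
                )
                sets = bench.ranking_sets()
                m = train_rank_svm(build_training_pairs(sets[:2]), C=1.0)
                fm, q = sets[2]
                est = score_decoys(m, fm)
                rs.append(spearmanr(est.raw_score, [q[d] for d in est.decoy_ids])[0])
            mean_r.append(np.mean(rs))
        assert all(a > b for a, b in zip(mean_r, mean_r[1:]))


class TestCrossValidate:
    def test_single_C_returned(self):
        bench = simulate_feature_benchmark(n_targets=6, n_decoys=10, seed=2)
        best, table = cross_validate(bench.ranking_sets(), C_grid=[0.5], n_folds=3, seed=0)
        assert best == 0.5

    def test_deterministic_winner(self):
        bench = simulate_feature_benchmark(n_targets=8, n_decoys=12, seed=4)
        sets = bench.ranking_sets()
        b1, _ = cross_validate(sets, C_grid=[0.01, 1.0, 100.0], n_folds=4, seed=9)
        b2, _ = cross_validate(sets, C_grid=[0.01, 1.0, 100.0], n_folds=4, seed=9)
        assert b1 == b2

    def test_fold_partition_by_target(self):
        bench = simulate_feature_benchmark(n_targets=7, n_decoys=8, seed=6)
        sets = bench.ranking_sets()
        _, table = cross_validate(sets, C_grid=[1.0], n_folds=3, seed=1)
        assert {row["fold"] for row in table} == {0, 1, 2}

    def test_too_few_targets_rejected(self):
        bench = simulate_feature_benchmark(n_targets=3, n_decoys=8, seed=6)
        with pytest.raises(ValueError):
            cross_validate(bench.ranking_sets(), n_folds=5)


class TestBaselines:
    def test_classification_separable_toy(self):
        fms = []
        for t in range(3):
            fm = _fm(np.zeros((4, 1)), target=f"T{t}")
            fms.append((fm, np.array([1.0])))
        m = train_classification_baseline(fms, C=10.0)
        assert m.omega[0] > 0
        assert m.kind == "classification_baseline"

    def test_classification_missing_native_rejected(self):
        fm = _fm(np.zeros((4, 2)))
        with pytest.raises(ValueError):
            train_classification_baseline([(fm, np.array([1.0]))])

    def test_classification_scoring_interface(self):
        fm = _fm(np.random.default_rng(0).normal(size=(5, 1)))
        m = train_classification_baseline([(fm, np.array([3.0]))], C=1.0)
        est = score_decoys(m, fm)
        assert sorted(est.rank) == [1, 2, 3, 4, 5]

    def test_regression_recovers_exact_linear_relation(self):
        rng = np.random.default_rng(3)
        sets = []
        for t in range(3):
            x = rng.uniform(0, 50, size=(10, 1))
            fm = _fm(x, target=f"T{t}")
            sets.append((fm, {d: float(2.0 * x[i, 0]) for i, d in enumerate(fm.decoy_ids)}))
        m = train_regression_baseline(sets, mode="ols")
        assert m.omega[0] == pytest.approx(2.0, abs=1e-6)
        assert m.intercept == pytest.approx(0.0, abs=1e-6)

    def test_regression_constant_quality_flagged(self):
        fm = _fm(np.random.default_rng(1).normal(size=(5, 1)))
        with pytest.warns(UserWarning, match="constant quality"):
            train_regression_baseline([(fm, {d: 50.0 for d in fm.decoy_ids})], mode="ols")
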