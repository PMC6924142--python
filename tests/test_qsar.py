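import numpy as np
import pandas as pd
import pytest

from ltip.errors import DegenerateVarianceError, ValidationError
from ltip.qsar import (
    BenchmarkConfig,
    EvalRecord,
    FeatureTable,
    QSARDataset,
    build_estimator,
    concatenate_features,
    evaluate_holdout,
    loocv_grid_search,
    pearson_cc,
    run_benchmark,
    split_train_test,
    summarize_mean_rank,
)


class TestPearsonCC:
    def test_perfect_linear_and_antilinear(self):
        x = np.array([1.0, 2.0, 5.0, 7.0])
        assert pearson_cc(x, 2 * x + 1) == pytest.approx(1.0)
        assert pearson_cc(x, -x) == pytest.approx(-1.0)

    def test_hand_computed_value(self):
        # product-moment formula on (1,2,3) vs (1,3,2) gives exactly 1/2
        assert pearson_cc([1, 2, 3], [1, 3, 2]) == pytest.approx(0.5)

    def test_constant_vector_raises(self):
        with pytest.raises(DegenerateVarianceError):
            pearson_cc([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_length_mismatch(self):
        with pytest.raises(ValidationError):
            pearson_cc([1.0, 2.0], [1.0, 2.0, 3.0])


class TestSplitTrainTest:
    def test_default_partition_sizes(self):
        ids = [f"c{i}" for i in range(144)]
        train, test = split_train_test(ids, n_test=20, seed=5)
        assert len(train) == 124 and len(test) == 20
        assert set(train) | set(test) == set(ids)
        assert not set(train) & set(test)

    def test_seed_reproducibility(self):
        ids = [f"c{i}" for i in range(30)]
        assert split_train_test(ids, 5, seed=9) == split_train_test(ids, 5, seed=9)
        assert split_train_test(ids, 5, seed=9) != split_train_test(ids, 5, seed=10)

    @pytest.mark.parametrize("n_test", [0, 30, 31])
    def test_out_of_range_n_test(self, n_test):
        with pytest.raises(ValidationError):
            split_train_test([f"c{i}" for i in range(30)], n_test)


def linear_dataset(n=30, d=2, seed=0, feature_name="lin", cell_line="CL"):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, d))
    y = X @ np.array([2.0, -1.0][:d]) + 0.5
    ids = [f"c{i}" for i in range(n)]
    return QSARDataset(X, y, ids, feature_name, cell_line)


class TestLoocvGridSearch:
    def test_single_point_grid_is_returned(self):
        ds = linear_dataset()
        params, _ = loocv_grid_search(ds, "KNR", {"n_neighbors": [3]})
        assert params == {"n_neighbors": 3}

    def test_sane_grid_point_beats_wild_one(self):
        # exact linear response on collinear points: 1-NN interpolates well,
        # while a huge neighborhood collapses predictions to the global mean
        X = np.linspace(0, 1, 12)[:, None]
        y = 3.0 * X.ravel()
        ds = QSARDataset(X, y, [f"c{i}" for i in range(12)], "f", "cl")
        params, score = loocv_grid_search(ds, "KNR", {"n_neighbors": [1, 11]})
        assert params == {"n_neighbors": 1}
        assert score < 0.1

    def test_deterministic_selection(self):
        ds = linear_dataset(seed=3)
        grid = {"n_neighbors": [2, 4], "weights": ["uniform", "distance"]}
        assert loocv_grid_search(ds, "KNR", grid, seed=1) == loocv_grid_search(
            ds, "KNR", grid, seed=1
        )

    def test_empty_grid_rejected(self):
        with pytest.raises(ValidationError):
            loocv_grid_search(linear_dataset(), "KNR", {})


class TestEvaluateHoldout:
    def test_linear_signal_recovered(self):
        train = linear_dataset(n=60, seed=1)
        test = linear_dataset(n=20, seed=2)
        test.chemical_ids = [f"t{i}" for i in range(20)]
        record = evaluate_holdout(train, test, "SVR", {"kernel": "linear", "C": 10.0})
        assert record.pcc >= 0.99

    def test_permuted_response_has_no_signal(self):
        rng = np.random.default_rng(7)
        pccs = []
        for rep in range(50):
            train = linear_dataset(n=60, seed=100 + rep)
            test = linear_dataset(n=20, seed=200 + rep)
            test.chemical_ids = [f"t{i}" for i in range(20)]
            train.response = rng.permutation(train.response)
            test.response = rng.permutation(test.response)
            record = evaluate_holdout(train, test, "KNR", {"n_neighbors": 5})
            pccs.append(record.pcc)
        assert abs(np.mean(pccs)) <= 0.25

    def test_overlapping_ids_rejected(self):
        train = linear_dataset(n=10)
        test = linear_dataset(n=10)
        with pytest.raises(ValidationError):
            evaluate_holdout(train, test, "KNR", {"n_neighbors": 3})

    def test_constant_prediction_reported_undefined(self):
        train = linear_dataset(n=10, seed=4)
        train.response = np.zeros(10)  # SVR on constant target predicts a constant
        test = linear_dataset(n=5, seed=5)
        test.chemical_ids = [f"t{i}" for i in range(5)]
        record = evaluate_holdout(train, test, "SVR", {"kernel": "linear", "C": 1.0})
        assert record.undefined and record.pcc is None


class TestStandardizationContract:
    def test_scaler_statistics_come_from_training_data_only(self):
        train = linear_dataset(n=40, seed=6)
        pipeline = build_estimator("SVR", {"kernel": "linear", "C": 1.0})
        pipeline.fit(train.features, train.response)
        scaler = pipeline.named_steps["scale"]
        assert np.allclose(scaler.mean_, train.features.mean(axis=0))
        # predicting shifted test features must not touch the fitted statistics
        pipeline.predict(train.features + 100.0)
        assert np.allclose(scaler.mean_, train.features.mean(axis=0))

    def test_tree_models_consume_raw_features(self):
        est = build_estimator("RF", {"n_estimators": 5})
        assert not hasattr(est, "named_steps")


class TestConcatenateFeatures:
    def test_widths_add(self):
        a = FeatureTable("A", np.ones((3, 2)), ["x", "y", "z"])
        b = FeatureTable("B", np.zeros((3, 4)), ["x", "y", "z"])
        out = concatenate_features(a, b)
        assert out.matrix.shape == (3, 6) and out.name == "A+B"

    def test_rows_realigned_by_id(self):
        a = FeatureTable("A", np.array([[1.0], [2.0]]), ["x", "y"])
        b = FeatureTable("B", np.array([[20.0], [10.0]]), ["y", "x"])
        out = concatenate_features(a, b)
        assert out.matrix.tolist() == [[1.0, 10.0], [2.0, 20.0]]

    def test_disjoint_ids_rejected(self):
        a = FeatureTable("A", np.ones((1, 1)), ["x"])
        b = FeatureTable("B", np.ones((1, 1)), ["q"])
        with pytest.raises(ValidationError):
            concatenate_features(a, b)


def records(entries):
    return [
        EvalRecord(cell, feat, model, pcc, {}, 10, 5)
        for cell, feat, model, pcc in entries
    ]


class TestRankSummary:
    def test_forced_ranking(self):
        recs = records(
            [
                ("cl1", "A", "KNR", 0.9),
                ("cl1", "B", "KNR", 0.2),
                ("cl2", "A", "KNR", 0.8),
                ("cl2", "B", "KNR", 0.1),
            ]
        )
        ranks = summarize_mean_rank(recs)
        assert ranks.loc["A", "KNR"] == 1.0
        assert ranks.loc["B", "KNR"] == 2.0

    def test_ties_average(self):
        recs = records(
            [
                ("cl1", "A", "KNR", 0.5),
                ("cl1", "B", "KNR", 0.5),
                ("cl2", "A", "KNR", 0.9),
                ("cl2", "B", "KNR", 0.1),
            ]
        )
        ranks = summarize_mean_rank(recs)
        assert ranks.loc["A", "KNR"] == pytest.approx(1.25)
        assert ranks.loc["B", "KNR"] == pytest.approx(1.75)

    def test_undefined_pcc_ranked_worst(self):
        recs = records(
            [
                ("cl1", "A", "KNR", None),
                ("cl1", "B", "KNR", 0.1),
                ("cl1", "C", "KNR", 0.2),
            ]
        )
        ranks = summarize_mean_rank(recs)
        assert ranks.loc["A", "KNR"] == 3.0

    def test_invariant_to_monotone_transform(self):
        rng = np.random.default_rng(8)
        entries = [
            (f"cl{c}", feat, "KNR", float(rng.uniform(-1, 1)))
            for c in range(4)
            for feat in "ABC"
        ]
        base = summarize_mean_rank(records(entries))
        warped = summarize_mean_rank(
            records([(c, f, m, float(np.tanh(3 * p))) for c, f, m, p in entries])
        )
        pd.testing.assert_frame_equal(base, warped)


class TestRunBenchmark:
    def test_informative_features_outrank_noise(self):
        rng = np.random.default_rng(11)
        n = 40
        ids = [f"c{i}" for i in range(n)]
        signal = rng.normal(size=(n, 3))
        noise = rng.normal(size=(n, 3))
        frames = []
        for cl in ("cl1", "cl2"):
            y = signal @ rng.normal(size=3)
            frames.append(pd.DataFrame({"chemical_id": ids, "cell_line": cl, "auc": y}))
        config = BenchmarkConfig(
            features={
                "SIG": FeatureTable("SIG", signal, ids),
                "NOISE": FeatureTable("NOISE", noise, ids),
            },
            responses=pd.concat(frames, ignore_index=True),
            models=["KNR"],
            grids={"KNR": {"n_neighbors": [3, 5]}},
            n_test=8,
            split_seeds=[0],
        )
        recs, mean_pcc, mean_rank = run_benchmark(config)
        assert len(recs) == 4
        assert mean_pcc.loc["SIG", "KNR"] > mean_pcc.loc["NOISE", "KNR"]
        assert mean_rank.loc["SIG", "KNR"] < mean_rank.loc["NOISE", "KNR"]

    def test_reproducible_given_seeds(self):
        rng = np.random.default_rng(12)
        ids = [f"c{i}" for i in range(25)]
        X = rng.normal(size=(25, 2))
        resp = pd.DataFrame(
            {"chemical_id": ids, "cell_line": "cl1", "auc": X @ np.ones(2)}
        )
        config = BenchmarkConfig(
            features={"F": FeatureTable("F", X, ids)},
            responses=resp,
            models=["KNR"],
            grids={"KNR": {"n_neighbors": [3]}},
            n_test=5,
            split_seeds=[3],
        )
        a = run_benchmark(config)[0]
        b = run_benchmark(config)[0]
        assert [r.pcc for r in a] == [r.pcc for r in b]
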