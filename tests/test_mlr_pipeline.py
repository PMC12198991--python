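import numpy as np
import pytest

from thermogav.gav_model import GroupVector, estimate
from thermogav.mlr_pipeline import (
    DatasetRow,
    ThermoDataset,
    fit_mlr,
    load_dataset_csv,
    metrics,
    run_pipeline,
    save_dataset_csv,
    split_holdout,
)
from thermogav.synthetic_data import GeneratorConfig, generate


def toy_dataset(n=10, seed=0, labels=("A-x", "B-x"), noise=0.0):
    """Tiny dataset with opaque labels and a known linear truth."""
    rng = np.random.default_rng(seed)
    truth = {"A-x": 2.0, "B-x": -3.0}
    rows = []
    for i in range(n):
        counts = {lab: int(rng.integers(0, 4)) for lab in labels}
        y = 5.0 + sum(truth[l] * c for l, c in counts.items()) + rng.normal(0, noise)
        rows.append(DatasetRow(f"m{i}", GroupVector(counts), {"S": y}))
    return ThermoDataset(rows=rows, group_universe=list(labels))


class TestSplitHoldout:
    def test_sizes_and_disjointness(self):
        ds = toy_dataset(10)
        train, test = split_holdout(ds, 0.7, seed=1)
        assert len(train) == 7 and len(test) == 3
        assert not set(train.ids) & set(test.ids)
        assert set(train.ids) | set(test.ids) == set(ds.ids)

    def test_deterministic_given_seed(self):
        ds = toy_dataset(20)
        s1 = split_holdout(ds, 0.7, seed=9)
        s2 = split_holdout(ds, 0.7, seed=9)
        assert s1[0].ids == s2[0].ids and s1[1].ids == s2[1].ids
        s3 = split_holdout(ds, 0.7, seed=10)
        assert s3[0].ids != s1[0].ids

    def test_reference_size_arithmetic(self):
        ds = toy_dataset(77)
        train, test = split_holdout(ds, 0.7, seed=0)
        assert len(train) == 53 and len(test) == 24

    def test_too_small_dataset_rejected(self):
        with pytest.raises(ValueError):
            split_holdout(toy_dataset(1), 0.7, seed=0)
        with pytest.raises(ValueError):
            split_holdout(toy_dataset(10), 1.2, seed=0)


class TestMetrics:
    def test_perfect_prediction(self):
        m = metrics([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert m == (1.0, 0.0, 0.0)

    def test_mean_prediction_gives_zero_r2(self):
        obs = [1.0, 2.0, 3.0, 6.0]
        m = metrics([3.0] * 4, obs)
        assert m.r2 == pytest.approx(0.0)

    def test_hand_computed_errors(self):
        m = metrics([4.0, 6.0], [1.0, 2.0])  # errors {3, 4}
        assert m.mae == pytest.approx(3.5)
        assert m.rmse == pytest.approx(3.5355, abs=1e-4)

    def test_zero_variance_is_an_error_not_nan(self):
        with pytest.raises(ValueError):
            metrics([1.0, 2.0], [5.0, 5.0])

    def test_rmse_at_least_mae(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            p, o = rng.normal(size=8), rng.normal(size=8)
            m = metrics(p, o)
            assert m.rmse >= m.mae >= 0.0


class TestFitMlr:
    def test_noiseless_recovery(self):
        ds = toy_dataset(30, noise=0.0)
        fit = fit_mlr(ds, "S")
        assert fit.coefficients["A-x"] == pytest.approx(2.0, abs=1e-6)
        assert fit.coefficients["B-x"] == pytest.approx(-3.0, abs=1e-6)
        assert fit.intercept == pytest.approx(5.0, abs=1e-6)

    def test_matches_sklearn_on_full_rank_design(self):
        sklearn = pytest.importorskip("sklearn.linear_model")
        ds = toy_dataset(40, noise=1.0, seed=3)
        fit = fit_mlr(ds, "S")
        X = ds.design_matrix(with_intercept=False)
        y = ds.observed_vector("S")
        ref = sklearn.LinearRegression().fit(X, y)
        np.testing.assert_allclose(
            [fit.coefficients[g] for g in ds.group_universe], ref.coef_, atol=1e-8
        )
        assert fit.intercept == pytest.approx(ref.intercept_, abs=1e-8)

    def test_all_zero_design_fits_mean(self):
        rows = [
            DatasetRow(f"m{i}", GroupVector({}), {"S": float(i)}) for i in range(5)
        ]
        ds = ThermoDataset(rows=rows, group_universe=["A-x"])
        with pytest.warns(UserWarning, match="rank-deficient"):
            fit = fit_mlr(ds, "S")
        assert fit.intercept == pytest.approx(2.0)  # mean of 0..4

    def test_duplicated_column_warns_and_predicts_identically(self):
        rng = np.random.default_rng(5)
        rows, rows_dedup = [], []
        for i in range(15):
            a = int(rng.integers(0, 4))
            y = 1.0 + 4.0 * a + rng.normal(0, 0.1)
            # two labels always occurring together == duplicated column
            rows.append(DatasetRow(f"m{i}", GroupVector({"A-x": a, "B-x": a}), {"S": y}))
            rows_dedup.append(DatasetRow(f"m{i}", GroupVector({"A-x": a}), {"S": y}))
        ds = ThermoDataset(rows=rows, group_universe=["A-x", "B-x"])
        ds_dedup = ThermoDataset(rows=rows_dedup, group_universe=["A-x"])
        with pytest.warns(UserWarning, match="B-x"):
            fit = fit_mlr(ds, "S")
        fit_dedup = fit_mlr(ds_dedup, "S")
        np.testing.assert_allclose(fit.predict(ds), fit_dedup.predict(ds_dedup), atol=1e-8)

    def test_empty_training_set_rejected(self):
        ds = ThermoDataset(rows=[], group_universe=["A-x"])
        with pytest.raises(ValueError):
            fit_mlr(ds, "S")


class TestRunPipeline:
    def test_noiseless_pipeline_has_perfect_test_r2(self):
        ds, _ = generate(GeneratorConfig(n_molecules=150, noise_sd={}, seed=2))
        _, fits = run_pipeline(ds, seed=4)
        for fit in fits.values():
            assert fit.test_metrics.r2 == pytest.approx(1.0, abs=1e-9)

    def test_shared_split_across_properties(self):
        ds, _ = generate(GeneratorConfig(n_molecules=120, seed=6))
        _, fits = run_pipeline(ds, seed=8)
        splits = {tuple(f.train_ids) for f in fits.values()}
        assert len(splits) == 1

    def test_fitted_table_reproduces_training_predictions(self):
        ds, _ = generate(
            GeneratorConfig(n_molecules=150, noise_sd={"S": 3.0, "dfG": 3.0}, seed=9)
        )
        table, fits = run_pipeline(ds, seed=1)
        train = ds.subset(fits["S"].train_ids)
        preds = fits["S"].predict(train)
        via_table = [estimate(r.groups, table, "S") for r in train.rows]
        np.testing.assert_allclose(via_table, preds, atol=1e-8)

    def test_train_r2_beats_test_r2_in_expectation(self):
        # repeated seeds; noisy generation makes the train fit optimistic
        diffs = []
        for seed in range(5):
            ds, _ = generate(
                GeneratorConfig(n_molecules=120, noise_sd={"S": 8.0, "dfG": 8.0}, seed=seed)
            )
            _, fits = run_pipeline(ds, properties=("S",), seed=seed)
            diffs.append(fits["S"].train_metrics.r2 - fits["S"].test_metrics.r2)
        assert np.mean(diffs) > 0


def test_dataset_csv_roundtrip(tmp_path):
    ds, _ = generate(GeneratorConfig(n_molecules=25, seed=3))
    path = tmp_path / "ds.csv"
    save_dataset_csv(ds, path)
    back = load_dataset_csv(path)
    assert back.ids == ds.ids
    assert set(back.group_universe) == set(ds.group_universe)
    for a, b in zip(back.rows, ds.rows):
        assert a.groups.all_counts() == b.groups.all_counts()
        for prop in ("S", "dfS", "dfG"):
            assert a.observed[prop] == pytest.approx(b.observed[prop], rel=1e-12)


def test_duplicate_molecule_ids_rejected():
    rows = [
        DatasetRow("m", GroupVector({"A-x": 1}), {"S": 1.0}),
        DatasetRow("m", GroupVector({"A-x": 2}), {"S": 2.0}),
    ]
    with pytest.raises(ValueError):
        ThermoDataset(rows=rows, group_universe=["A-x"])
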