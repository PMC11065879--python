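import numpy as np
import pandas as pd
import pytest

from phenomigrate.classify import (
    ClassifierConfig,
    SoybeanClassifier,
    choose_tree_count,
    export_soybean_map,
    majority_filter,
    split_train_test,
)
from phenomigrate.raster import Raster


def _curve(values):
    return dict(zip(range(50, 501, 50), values))


class TestSplit:
    def test_half_half_disjoint_complete(self):
        ids = [f"s{i}" for i in range(100)]
        labels = ["soybean"] * 40 + ["non_soybean"] * 60
        train, test = split_train_test(ids, labels, seed=1)
        assert len(train) + len(test) == 100
        assert not set(train) & set(test)
        assert abs(len(train) - len(test)) <= 2

    def test_same_seed_same_split(self):
        ids = list(range(50))
        labels = ["a"] * 25 + ["b"] * 25
        assert split_train_test(ids, labels, seed=5) == \
            split_train_test(ids, labels, seed=5)

    def test_stratification_within_one_sample(self):
        ids = list(range(90))
        labels = ["soybean"] * 30 + ["non_soybean"] * 60
        train, test = split_train_test(ids, labels, seed=2)
        n_soy_train = sum(1 for i in train if labels[i] == "soybean")
        assert abs(n_soy_train - 15) <= 1

    def test_per_region_stratification(self):
        ids = list(range(40))
        labels = (["a"] * 10 + ["b"] * 10) * 2
        regions = ["R1"] * 20 + ["R2"] * 20
        train, _ = split_train_test(ids, labels, regions, seed=0)
        for r, lab in (("R1", "a"), ("R2", "b")):
            n = sum(1 for i in train
                    if regions[i] == r and labels[i] == lab)
            assert n == 5

    def test_single_class_errors(self):
        with pytest.raises(ValueError):
            split_train_test([1, 2], ["a", "a"])


class TestChooseTreeCount:
    def test_plateau_after_rise(self):
        acc = _curve([0.80, 0.85, 0.90, 0.92, 0.92, 0.92, 0.92, 0.92,
                      0.92, 0.92])
        assert choose_tree_count(acc) == 200

    def test_strictly_increasing_returns_500_with_warning(self):
        acc = _curve(np.linspace(0.5, 0.9, 10))
        with pytest.warns(UserWarning, match="500"):
            assert choose_tree_count(acc) == 500

    def test_maximum_at_100_is_skipped(self):
        # local max at 100 (trees <= 100 excluded), dip, next local max 250
        acc = _curve([0.80, 0.95, 0.70, 0.75, 0.90, 0.85, 0.86, 0.84,
                      0.83, 0.82])
        assert choose_tree_count(acc) == 250

    def test_incomplete_curve_errors(self):
        with pytest.raises(ValueError, match="missing"):
            choose_tree_count({50: 0.9, 100: 0.91})


def _separable_table(n=120, seed=0, flip=0.0):
    rng = np.random.default_rng(seed)
    y = np.array(["soybean"] * (n // 2) + ["non_soybean"] * (n // 2))
    x0 = np.where(y == "soybean", 2.0, -2.0) + rng.normal(0, 0.2, n)
    df = pd.DataFrame({
        "f0": x0,
        "f1": rng.normal(size=n),
        "f2": rng.normal(size=n),
    }, index=[f"s{i}" for i in range(n)])
    if flip:
        y = rng.permutation(y)
    return df, pd.Series(y, index=df.index)


class TestTrainRF:
    def test_separable_data_high_accuracy(self):
        df, y = _separable_table()
        res = SoybeanClassifier(df, y).fit()
        assert res.test_accuracy >= 0.99
        assert res.tree_count in range(150, 501, 50)
        # training rows reproduced
        pred = res.predict(df.loc[res.train_ids])
        assert (pred == y.loc[res.train_ids]).mean() >= 0.99

    def test_permuted_labels_chance_accuracy(self):
        df, y = _separable_table(flip=True, seed=3)
        res = SoybeanClassifier(df, y).fit()
        assert abs(res.test_accuracy - 0.5) < 0.15

    def test_identical_runs_identical_predictions(self):
        df, y = _separable_table(seed=5)
        r1 = SoybeanClassifier(df, y).fit()
        r2 = SoybeanClassifier(df, y).fit()
        assert (r1.predict(df) == r2.predict(df)).all()
        assert r1.accuracy_curve == r2.accuracy_curve

    def test_column_mismatch_reports_diff(self):
        df, y = _separable_table()
        res = SoybeanClassifier(df, y).fit()
        bad = df.rename(columns={"f1": "g1"})
        with pytest.raises(ValueError, match="missing \\['f1'\\]"):
            res.predict(bad)

    def test_raster_and_table_paths_agree(self):
        df, y = _separable_table(seed=7)
        res = SoybeanClassifier(df, y).fit()
        n = 10
        template = Raster(data=np.zeros((n, n)), y_origin=100.0,
                          cell_size=10.0)
        pick = np.random.default_rng(0).choice(len(df), n * n)
        stack = {c: df[c].to_numpy()[pick].reshape(n, n) for c in df.columns}
        r = res.predict_raster(stack, template)
        table_pred = res.predict(df.iloc[pick])
        assert np.array_equal(
            r.data.ravel() == 1, (table_pred == "soybean").to_numpy())

    def test_missing_feature_pixel_becomes_nodata(self):
        df, y = _separable_table()
        res = SoybeanClassifier(df, y).fit()
        template = Raster(data=np.zeros((2, 2)), y_origin=20.0)
        stack = {c: np.ones((2, 2)) for c in df.columns}
        stack["f0"][0, 0] = np.nan
        r = res.predict_raster(stack, template)
        assert r.data[0, 0] == template.nodata
        assert np.all(r.data.ravel()[1:] != template.nodata)


class TestMajorityFilter:
    def _raster(self, data):
        return Raster(data=np.asarray(data, float),
                      y_origin=len(data) * 10.0, nodata=-9999)

    def test_isolated_soybean_pixel_removed(self):
        data = np.zeros((5, 5))
        data[2, 2] = 1
        out = majority_filter(self._raster(data))
        assert out.data[2, 2] == 0

    def test_single_hole_filled(self):
        data = np.ones((5, 5))
        data[2, 2] = 0
        out = majority_filter(self._raster(data))
        assert out.data[2, 2] == 1

    def test_homogeneous_idempotent(self):
        data = np.ones((6, 6))
        r = self._raster(data)
        once = majority_filter(r)
        twice = majority_filter(once)
        assert np.array_equal(once.data, data)
        assert np.array_equal(twice.data, once.data)

    def test_tie_keeps_centre(self):
        # a 2x2 corner block: corner pixel sees 2 soy vs 2 non -> tie
        data = np.zeros((2, 2))
        data[0, 0] = data[0, 1] = 1
        out = majority_filter(self._raster(data))
        assert np.array_equal(out.data, data)

    def test_nodata_excluded_and_preserved(self):
        data = np.full((3, 3), -9999.0)
        data[1, 1] = 1
        out = majority_filter(self._raster(data))
        assert out.data[1, 1] == 1  # only valid voter is itself
        assert np.sum(out.data == -9999) == 8

    def test_never_creates_absent_class(self):
        rng = np.random.default_rng(1)
        data = (rng.random((20, 20)) < 0.5).astype(float)
        out = majority_filter(self._raster(data))
        assert set(np.unique(out.data)) <= {0.0, 1.0}

    def test_export_binary_map_encoding(self):
        data = np.array([[1.0, 0.0], [0.0, 1.0]])
        r = export_soybean_map(self._raster(data))
        assert set(np.unique(r.data)) == {1.0, -9999.0}


def test_classifier_summary_and_plot(tmp_path):
    import matplotlib
    matplotlib.use("Agg")
    df, y = _separable_table()
    res = SoybeanClassifier(df, y,
                            config=ClassifierConfig(split_seed=1)).fit()
    assert "chosen tree count" in res.summary()
    ax = res.plot_accuracy_curve()
    assert ax is not None
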