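import numpy as np
import pandas as pd
import pytest

from phenomigrate.features import (
    accumulated_evi,
    extract_features,
    feature_manifest,
    harmonic_fit,
    select_features,
    series_statistics,
    temporal_pca,
)
from phenomigrate.phenology import PhenologyDates, seasonal_integral

from conftest import gridded


class TestSeriesStatistics:
    def test_constant_series(self, grid):
        s = series_statistics(gridded(np.full(grid.n_bins, 3.0), grid))
        assert s == {"min": 3.0, "max": 3.0, "std": 0.0,
                     "p15": 3.0, "p50": 3.0, "p90": 3.0}

    def test_linear_interpolation_percentile(self):
        s = series_statistics(np.arange(1.0, 11.0))
        assert s["p50"] == pytest.approx(5.5)

    def test_order_statistics_invariant(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            s = series_statistics(rng.normal(size=30))
            assert s["min"] <= s["p15"] <= s["p50"] <= s["p90"] <= s["max"]

    def test_empty_series_errors(self):
        with pytest.raises(ValueError):
            series_statistics(np.array([]))


class TestHarmonicFit:
    def test_noiseless_parameter_recovery(self, grid):
        t = grid.centres
        w = 1.0 / 365.0
        y = 2.0 + 3.0 * np.cos(2 * np.pi * w * t) + 4.0 * np.sin(
            2 * np.pi * w * t)
        fit = harmonic_fit(t, y, M=2)
        assert fit.amplitude(1) == pytest.approx(5.0, abs=1e-6)
        assert fit.phase(1) == pytest.approx(np.arctan2(4, 3), abs=1e-6)
        assert fit.amplitude(2) == pytest.approx(0.0, abs=1e-6)
        assert fit.residual_rms < 1e-9

    def test_pure_trend_has_no_amplitude(self, grid):
        t = grid.centres
        fit = harmonic_fit(t, 0.01 * t, M=2)
        assert fit.amplitude(1) == pytest.approx(0.0, abs=1e-8)
        assert fit.b == pytest.approx(0.01, abs=1e-8)

    def test_noise_perturbs_amplitude_weakly(self, grid):
        rng = np.random.default_rng(4)
        t = grid.centres
        w = 1.0 / 365.0
        clean = 0.4 + 0.3 * np.cos(2 * np.pi * w * t)
        fit = harmonic_fit(t, clean + rng.normal(0, 0.01, t.size), M=2)
        assert abs(fit.amplitude(1) - 0.3) < 0.05

    def test_reconstruction_exact_for_model_basis(self, grid):
        rng = np.random.default_rng(5)
        t = grid.centres
        w = 1.0 / 365.0
        coefs = rng.normal(size=6)
        y = coefs[0] + coefs[1] * 0.001 * t
        for m in (1, 2):
            y = y + coefs[2 * m] * np.cos(2 * np.pi * m * w * t)
            y = y + coefs[2 * m + 1] * np.sin(2 * np.pi * m * w * t)
        fit = harmonic_fit(t, y, M=2)
        assert fit.predict(t) == pytest.approx(y, abs=1e-9)

    def test_too_few_observations(self):
        with pytest.raises(ValueError, match="observations"):
            harmonic_fit(np.arange(4.0), np.arange(4.0), M=2)


class TestAccumulatedEVI:
    def test_constant_curve_splits_by_phenophase(self, grid):
        g = gridded(np.full(grid.n_bins, 0.6), grid)
        phen = PhenologyDates(sos=120, pos=180, eos=300)
        green, sen = accumulated_evi(g, phen)
        assert green == pytest.approx(0.6 * 60)
        assert sen == pytest.approx(0.6 * 120)

    def test_symmetric_triangle_equal_halves(self, triangular_evi):
        phen = PhenologyDates(sos=150, pos=205, eos=260)
        green, sen = accumulated_evi(triangular_evi, phen)
        assert green == pytest.approx(sen)

    def test_halves_sum_to_season_integral(self, triangular_evi):
        phen = PhenologyDates(sos=152.5, pos=205, eos=251.0)
        green, sen = accumulated_evi(triangular_evi, phen)
        assert green + sen == pytest.approx(
            seasonal_integral(triangular_evi, phen))


class TestTemporalPCA:
    def test_rank_one_matrix_single_component(self):
        rng = np.random.default_rng(6)
        pattern = np.sin(np.linspace(0, 3, 12))
        weights = rng.normal(size=(40, 1))
        with pytest.warns(UserWarning, match="rank"):
            scores, explained = temporal_pca(weights @ pattern[None, :], k=3)
        assert scores.shape[1] == 1
        assert explained[0] == pytest.approx(1.0)

    def test_two_orthogonal_patterns_variance_split(self):
        rng = np.random.default_rng(7)
        n, t = 500, 16
        p1 = np.zeros(t); p1[:8] = 1.0
        p2 = np.zeros(t); p2[8:] = 1.0
        a = rng.normal(0, 2.0, (n, 1))
        b = rng.normal(0, 1.0, (n, 1))
        X = a @ p1[None, :] + b @ p2[None, :]
        with pytest.warns(UserWarning, match="rank"):
            scores, explained = temporal_pca(X, k=3)
        assert explained[0] == pytest.approx(4 / 5, abs=0.05)
        assert explained[1] == pytest.approx(1 / 5, abs=0.05)

    def test_deterministic_sign_rule(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(30, 10))
        s1, _ = temporal_pca(X, k=3)
        s2, _ = temporal_pca(X.copy(), k=3)
        assert np.array_equal(s1, s2)

    def test_gap_rejected(self):
        X = np.ones((5, 4))
        X[0, 0] = np.nan
        with pytest.raises(ValueError):
            temporal_pca(X)


class TestSelectFeatures:
    def _table(self, n=200, seed=0):
        rng = np.random.default_rng(seed)
        y = np.repeat(["a", "b"], n // 2)
        df = pd.DataFrame(
            {f"noise_{i}": rng.normal(size=n) for i in range(9)}
        )
        df["signal"] = (y == "a").astype(float) + rng.normal(0, 0.05, n)
        return df, y

    def test_informative_feature_ranked_first(self):
        df, y = self._table()
        kept = select_features(df, y, fraction=0.1, seed=1)
        assert kept == ["signal"]

    def test_fraction_one_keeps_all(self):
        df, y = self._table()
        assert set(select_features(df, y, fraction=1.0, seed=1)) == \
            set(df.columns)

    def test_same_seed_same_selection(self):
        df, y = self._table()
        assert select_features(df, y, 0.5, seed=3) == \
            select_features(df, y, 0.5, seed=3)

    def test_single_class_errors(self):
        df, _ = self._table()
        with pytest.raises(ValueError, match="two classes"):
            select_features(df, ["a"] * len(df), 0.5)


class TestExtractFeatures:
    def test_feature_inventory_counts(self, small_scene):
        ids = list(small_scene.optical)[:12]
        table = extract_features(ids, small_scene.optical, small_scene.sar)
        manifest = feature_manifest(table)
        assert manifest["n_optical"] == 69
        assert manifest["n_sar"] == 50
        assert manifest["n_features"] == 119
        assert table.shape == (12, 119)
        assert np.isfinite(table.to_numpy()).all()

    def test_percentile_ordering_within_table(self, small_scene):
        ids = list(small_scene.optical)[:8]
        table = extract_features(ids, small_scene.optical, small_scene.sar)
        for stem in ("evi", "b6", "sar_rvi"):
            assert (table[f"{stem}_min"] <= table[f"{stem}_p15"]).all()
            assert (table[f"{stem}_p15"] <= table[f"{stem}_p50"]).all()
            assert (table[f"{stem}_p50"] <= table[f"{stem}_p90"]).all()
            assert (table[f"{stem}_p90"] <= table[f"{stem}_max"]).all()
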