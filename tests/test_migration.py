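import numpy as np
import pytest
from scipy import stats

from phenomigrate.migration import (
    CandidateRecord,
    GaussianGroupModel,
    MigrationConfig,
    SoybeanMigration,
    SurveySet,
    classify_candidate,
    compute_cci,
    fit_group_model,
    mahalanobis,
    sample_cropland,
    select_reference_set,
)
from phenomigrate.phenology import PhenologyDates
from phenomigrate.points import SamplePoint
from phenomigrate.raster import Raster
from phenomigrate.synthetic import ARCHETYPES, simulate_series

from conftest import gridded


def _model(mu, sigma, soy=1.5, nonsoy=2.5):
    return GaussianGroupModel(
        group="high", mu=np.asarray(mu, float), sigma=np.asarray(sigma, float),
        p50=0.02, r50=1.54, d_soy_thresh=soy, d_nonsoy_thresh=nonsoy,
        n_fit=100, n_mc=1000, seed=0,
    )


class TestCCI:
    # season dates on bin centres so linear interpolation is exact
    PHEN = PhenologyDates(sos=145, pos=205, eos=265)

    def _ratio(self, grid, sos_v, pos_v, eos_v):
        # piecewise-linear curve hitting the three values at bin centres
        t = grid.centres
        values = np.interp(t, [95, 145, 205, 265, 315],
                           [sos_v, sos_v, pos_v, eos_v, eos_v])
        return gridded(values, grid)

    def test_concave_curve_negative(self, grid):
        r = self._ratio(grid, 0.5, 0.1, 0.5)
        assert compute_cci(r, self.PHEN) == pytest.approx(-0.8)

    def test_constant_curve_zero(self, grid):
        r = gridded(np.full(grid.n_bins, 0.37), grid)
        assert compute_cci(r, self.PHEN) == pytest.approx(0.0)

    def test_convex_curve_positive(self, grid):
        r = self._ratio(grid, 0.1, 0.5, 0.1)
        assert compute_cci(r, self.PHEN) == pytest.approx(0.8)

    def test_gappy_ratio_rejected(self, grid):
        v = np.full(grid.n_bins, 0.2)
        v[5] = np.nan
        with pytest.raises(ValueError, match="missing"):
            compute_cci(gridded(v, grid), self.PHEN)


class TestMahalanobis:
    def test_distance_at_mean_is_zero(self):
        m = _model([1.0, 2.0, 3.0], np.eye(3))
        assert mahalanobis([1.0, 2.0, 3.0], m) == 0.0

    def test_identity_covariance_reduces_to_euclidean(self):
        m = _model([0.0, 0.0, 0.0], np.eye(3))
        assert mahalanobis([3.0, 4.0, 0.0], m) == pytest.approx(5.0)

    def test_diagonal_covariance_hand_example(self):
        m = _model([0.0, 0.0, 0.0], np.diag([4.0, 1.0, 1.0]))
        assert mahalanobis([2.0, 0.0, 0.0], m) == pytest.approx(1.0)

    def test_matches_explicit_inverse_on_random_spd(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            A = rng.normal(size=(3, 3))
            sigma = A @ A.T + 0.05 * np.eye(3)
            mu = rng.normal(size=3)
            x = rng.normal(size=3)
            m = _model(mu, sigma)
            brute = np.sqrt((x - mu) @ np.linalg.inv(sigma) @ (x - mu))
            assert mahalanobis(x, m) == pytest.approx(brute, abs=1e-8)

    def test_affine_invariance(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            A = rng.normal(size=(3, 3))
            sigma = A @ A.T + 0.1 * np.eye(3)
            mu = rng.normal(size=3)
            x = rng.normal(size=3)
            B = rng.normal(size=(3, 3)) + 2 * np.eye(3)
            c = rng.normal(size=3)
            m1 = _model(mu, sigma)
            m2 = _model(B @ mu + c, B @ sigma @ B.T)
            assert mahalanobis(B @ x + c, m2) == pytest.approx(
                mahalanobis(x, m1), abs=1e-8)

    def test_non_finite_input_rejected(self):
        m = _model([0, 0, 0], np.eye(3))
        with pytest.raises(ValueError):
            mahalanobis([np.nan, 0, 0], m)


class TestFitGroupModel:
    def test_chi2_median_oracle_standard_gaussian(self):
        """Monte-Carlo p50/r50 converge to the chi-square(3) closed form."""
        rng = np.random.default_rng(5)
        X = rng.standard_normal((4000, 3))
        m = fit_group_model(X, "high", n_mc=100_000, seed=1)
        r50_true = np.sqrt(stats.chi2.ppf(0.5, df=3))
        p50_true = (2 * np.pi) ** -1.5 * np.exp(-0.5 * r50_true**2)
        assert m.r50 == pytest.approx(r50_true, rel=0.02)
        assert m.p50 == pytest.approx(p50_true, rel=0.05)

    def test_robust_set_is_inside_r50_sphere(self):
        rng = np.random.default_rng(6)
        X = rng.standard_normal((500, 3)) * [1.0, 2.0, 0.5]
        m = fit_group_model(X, "high", n_mc=20_000, seed=2)
        d = m.mahalanobis(X)
        robust = m.pdf(X) > m.p50
        assert np.array_equal(robust, d < m.r50)
        # roughly half of an exact Gaussian sample is robust
        assert abs(robust.mean() - 0.5) < 0.07

    def test_threshold_ordering(self):
        rng = np.random.default_rng(8)
        X = rng.multivariate_normal([5, 10, 2], np.diag([2.0, 1.0, 0.5]), 300)
        m = fit_group_model(X, "low", n_mc=20_000, seed=3)
        assert 0 < m.d_soy_thresh <= m.r50
        assert m.d_nonsoy_thresh >= m.d_soy_thresh

    def test_minimum_reference_count_enforced(self):
        X = np.random.default_rng(0).standard_normal((29, 3))
        with pytest.raises(ValueError, match="at least 30"):
            fit_group_model(X, "high")

    def test_degenerate_covariance_regularized(self):
        rng = np.random.default_rng(9)
        base = rng.standard_normal((60, 1))
        X = np.hstack([base, base * 2.0, rng.standard_normal((60, 1))])
        m = fit_group_model(X, "high", n_mc=5_000, seed=4)
        assert np.all(np.linalg.eigvalsh(m.sigma) > 0)

    def test_model_json_roundtrip(self, tmp_path):
        rng = np.random.default_rng(10)
        m = fit_group_model(rng.standard_normal((80, 3)), "high",
                            n_mc=5_000, seed=5)
        m.save(tmp_path / "m.json")
        m2 = GaussianGroupModel.load(tmp_path / "m.json")
        x = np.array([0.3, -0.2, 1.0])
        assert m2.mahalanobis(x) == pytest.approx(m.mahalanobis(x))


class TestClassifyCandidate:
    def _rec(self, cci, d_high, d_low):
        p = SamplePoint(id="c", lon=0, lat=0, year=2019)
        return CandidateRecord(point=p, cci=cci, d_high=d_high, d_low=d_low)

    def test_decision_rules(self):
        high = _model([0, 0, 0], np.eye(3), soy=1.5, nonsoy=2.5)
        low = _model([0, 0, 0], np.eye(3), soy=1.4, nonsoy=2.6)
        # negative CCI, both below soy thresholds
        assert classify_candidate(self._rec(-0.5, 1.0, 1.0), high, low) == \
            "soybean"
        # conjunction fails on one distance
        assert classify_candidate(self._rec(-0.5, 1.6, 1.0), high, low) == \
            "cropland_unknown"
        # both distances beyond the non-soy thresholds, any CCI
        assert classify_candidate(self._rec(-0.9, 3.0, 3.0), high, low) == \
            "non_soybean"
        assert classify_candidate(self._rec(0.4, 3.0, 3.0), high, low) == \
            "non_soybean"
        # CCI >= 0 can never be soybean
        assert classify_candidate(self._rec(0.0, 0.1, 0.1), high, low) == \
            "cropland_unknown"

    def test_negative_distance_rejected(self):
        high = _model([0, 0, 0], np.eye(3))
        with pytest.raises(ValueError):
            classify_candidate(self._rec(-0.5, -1.0, 0.5), high, high)


class TestSampleCropland:
    def _raster(self, fill=40, size=40):
        return Raster(data=np.full((size, size), fill), x_origin=0,
                      y_origin=size * 10.0, cell_size=10.0)

    def test_uniform_cropland_retains_all(self):
        pts = sample_cropland(self._raster(), hex_spacing=150.0,
                              points_per_hex=2, seed=1)
        assert len(pts) > 0
        assert all(p.label == "cropland_unknown" for p in pts)

    def test_mixed_buffer_below_purity_discarded(self):
        # left half cropland, right half trees: points near the boundary
        # have ~50 % purity and must be dropped; deep-left points survive
        r = self._raster()
        r.data[:, 20:] = 10
        pts = sample_cropland(r, hex_spacing=120.0, points_per_hex=3, seed=2)
        assert len(pts) > 0
        for p in pts:
            assert p.lon * 111_000.0 < 200.0  # all on the cropland side

    def test_determinism_under_seed(self):
        a = sample_cropland(self._raster(), hex_spacing=150.0, seed=7)
        b = sample_cropland(self._raster(), hex_spacing=150.0, seed=7)
        assert [(p.lon, p.lat) for p in a] == [(p.lon, p.lat) for p in b]

    def test_no_cropland_code_errors(self):
        with pytest.raises(ValueError, match="cropland code"):
            sample_cropland(self._raster(fill=10))

    def test_purity_validation(self):
        with pytest.raises(ValueError, match="purity"):
            sample_cropland(self._raster(), purity=0.3)


class TestSelectReferenceSet:
    def test_same_region_prefers_temporal(self):
        inv = [SurveySet("R1", 2020)]
        chosen, strategy = select_reference_set("R1", 2021, inv)
        assert strategy == "temporal" and chosen.year == 2020

    def test_same_year_prefers_spatial(self):
        inv = [SurveySet("R1", 2020), SurveySet("R1", 2019)]
        chosen, strategy = select_reference_set("R2", 2020, inv)
        assert (chosen.region, chosen.year) == ("R1", 2020)
        assert strategy == "spatial"

    def test_own_region_year_is_zero_delta_temporal(self):
        inv = [SurveySet("R3", 2019), SurveySet("R2", 2021)]
        chosen, strategy = select_reference_set("R2", 2021, inv)
        assert strategy == "temporal"
        assert (chosen.region, chosen.year) == ("R2", 2021)

    def test_spatiotemporal_nearest_year_then_zone(self):
        inv = [SurveySet("R5", 2017, climate_zone=1.0),
               SurveySet("R6", 2019, climate_zone=9.0)]
        chosen, strategy = select_reference_set(
            "R9", 2020, inv, target_climate_zone=1.0)
        assert strategy == "spatiotemporal"
        assert chosen.region == "R6"  # nearest year beats nearest zone

    def test_tie_breaks_lexicographic(self):
        inv = [SurveySet("RB", 2020), SurveySet("RA", 2020)]
        chosen, _ = select_reference_set("R9", 2020, inv)
        assert chosen.region == "RA"

    def test_empty_inventory(self):
        with pytest.raises(ValueError, match="empty"):
            select_reference_set("R1", 2020, [])


class TestMigrationEndToEnd:
    def test_small_scene_precision(self, small_scene):
        res = SoybeanMigration.from_scene(
            small_scene, MigrationConfig(n_mc=20_000)
        ).fit(seed=3)
        prec = res.precision_against(small_scene.truth)
        assert prec["soybean"] >= 0.95
        assert prec["non_soybean"] >= 0.95
        # audit table covers every screened candidate
        assert len(res.audit_table) == res.stage_counts["candidate_total"] \
            - res.stage_counts["candidate_failed"]

    def test_candidate_at_group_mean_is_soybean(self, small_scene):
        res = SoybeanMigration.from_scene(
            small_scene, MigrationConfig(n_mc=20_000)
        ).fit(seed=3)
        p = SamplePoint(id="mean", lon=0, lat=0, year=2019)
        rec = CandidateRecord(point=p, cci=-0.1, d_high=0.0, d_low=0.0)
        assert classify_candidate(rec, res.high_model, res.low_model) == \
            "soybean"

    def test_empty_candidate_list_gives_models_only(self, small_scene):
        ref = {i: small_scene.optical[i] for i in small_scene.reference_ids}
        res = SoybeanMigration(ref, [], {},
                               MigrationConfig(n_mc=10_000)).fit(seed=1)
        assert res.records == []
        assert res.high_model.n_fit >= 30
        assert res.labelled_points == []

    def test_determinism(self, small_scene):
        cfg = MigrationConfig(n_mc=10_000)
        r1 = SoybeanMigration.from_scene(small_scene, cfg).fit(seed=9)
        r2 = SoybeanMigration.from_scene(small_scene, cfg).fit(seed=9)
        assert r1.audit_table.equals(r2.audit_table)
        assert r1.high_model.to_dict() == r2.high_model.to_dict()

    def test_summary_mentions_counts(self, small_scene):
        res = SoybeanMigration.from_scene(
            small_scene, MigrationConfig(n_mc=10_000)).fit(seed=3)
        text = res.summary()
        assert "labelled soybean" in text and "r50" in text
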