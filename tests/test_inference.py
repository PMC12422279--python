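"""Training-set construction, RF matching, CIs, reliability, areas."""

import math

import numpy as np
import pandas as pd
import pytest
from sklearn.neighbors import KNeighborsRegressor

from camtrapdensity import (DensityEstimate, DensityModel, EventTable,
                            RFConfig, SimConfig, TrainingSet, build_training,
                            check_reliability, effective_area, estimate_density,
                            make_uniform_grid, region_for_grid)
from camtrapdensity.inference import _is_unimodal
from conftest import make_records


def event_table(counts, site="site-1", species="Lycalopex spp."):
    cams = [f"C{i + 1:02d}" for i in range(len(counts))]
    return EventTable(site=site, species=species,
                      counts=pd.Series(counts, index=cams))


class TestEffectiveArea:
    def test_closed_form_for_study_grid(self, study_grid):
        """2 x 5 grid at 1,000 m with a 2 km² home range: the buffered
        bounding box is (4 + 2·0.798) x (1 + 2·0.798) km ~ 14.53 km²."""
        from camtrapdensity import MovementParams
        params = MovementParams("fox", 13.18, 17.31, 26.31, 5000,
                                home_range_km2=2.0)
        r = math.sqrt(2e6 / math.pi)
        expected = (4000 + 2 * r) * (1000 + 2 * r) / 1e6
        assert effective_area(study_grid, params) == pytest.approx(expected)
        assert expected == pytest.approx(14.53, abs=0.01)

    def test_single_camera_tiny_home_range_limit(self):
        from camtrapdensity import CameraDeployment, CameraGrid, MovementParams
        grid = CameraGrid("A", (CameraDeployment("A", "C01", (0, 0), 0.0),))
        params = MovementParams("x", 1, 1, 1, 10, home_range_km2=1e-6)
        assert effective_area(grid, params) < 1e-5

    def test_monotone_in_home_range(self, study_grid):
        from camtrapdensity import MovementParams
        areas = [effective_area(study_grid,
                                MovementParams("x", 1, 1, 1, 10, hr))
                 for hr in (0.5, 2.0, 5.31, 12.0)]
        assert areas == sorted(areas)
        # region used for simulation must match the area exactly
        params = MovementParams("x", 1, 1, 1, 10, 5.31)
        assert region_for_grid(study_grid, params).area_km2 == pytest.approx(
            effective_area(study_grid, params))


class TestEstimateDensity:
    def test_constant_labels_predict_constant(self):
        rng = np.random.default_rng(1)
        training = TrainingSet(features=rng.poisson(5, size=(50, 10)).astype(float),
                               labels=np.full(50, 7.0),
                               camera_order=[f"C{i + 1:02d}" for i in range(10)])
        est = estimate_density(training, event_table([3] * 10),
                               RFConfig(n_trees=100, seed=0), area_km2=10.0)
        assert est.n_hat == pytest.approx(7.0)
        assert est.ci_low == est.ci_high == pytest.approx(0.7)

    def test_separated_classes_recover_label_exactly(self):
        """Zero-noise fixture with widely separated abundance classes: the
        forest must agree with an independent 1-NN oracle and return the
        exact class label."""
        labels = np.repeat([2.0, 6.0, 12.0], 30)
        features = labels[:, None] * 50.0 + np.tile(
            np.linspace(0, 1, 30), 3)[:, None]
        features = np.repeat(features, 10, axis=1)[:, :10]
        training = TrainingSet(features=features, labels=labels,
                               camera_order=[f"C{i + 1:02d}" for i in range(10)])
        observed = event_table([300.5] * 10)
        est = estimate_density(training, observed,
                               RFConfig(n_trees=200, seed=3), area_km2=1.0)
        knn = KNeighborsRegressor(n_neighbors=1).fit(features, labels)
        expected = knn.predict(observed.feature_vector(training.camera_order)
                               .reshape(1, -1))[0]
        assert expected == 6.0
        assert est.n_hat == pytest.approx(expected)

    def test_camera_mismatch_raises(self):
        training = TrainingSet(features=np.zeros((4, 3)),
                               labels=np.arange(4.0),
                               camera_order=["C01", "C02", "C03"])
        bad = EventTable(site="site-1", species="x",
                         counts=pd.Series([1, 2, 3],
                                          index=["C01", "C02", "C99"]))
        with pytest.raises(ValueError, match="C99"):
            estimate_density(training, bad, RFConfig(n_trees=10), area_km2=1.0)

    def test_ci_brackets_point_estimate(self):
        rng = np.random.default_rng(5)
        labels = np.repeat(np.arange(1, 6, dtype=float), 10)
        features = rng.poisson(labels[:, None] * 2, size=(50, 4)).astype(float)
        training = TrainingSet(features=features, labels=labels,
                               camera_order=["C01", "C02", "C03", "C04"])
        est = estimate_density(training, event_table([4.0] * 4),
                               RFConfig(n_trees=100, seed=1), area_km2=2.0)
        assert est.ci_low <= est.density <= est.ci_high


class TestBuildTraining:
    def test_row_count_and_zero_abundance_rows(self, fast_params, study_grid):
        sim = SimConfig(abundance_grid=(0, 1, 2), replicates_per_abundance=2,
                        months=1, base_seed=3)
        training = build_training(fast_params, study_grid, sim)
        assert training.features.shape == (6, 10)
        assert (training.features[:2] == 0).all()  # no animals, no detections
        assert list(training.labels) == [0, 0, 1, 1, 2, 2]

    def test_deterministic(self, fast_params, study_grid):
        sim = SimConfig(abundance_grid=(1, 3), replicates_per_abundance=2,
                        months=1, base_seed=11)
        a = build_training(fast_params, study_grid, sim)
        b = build_training(fast_params, study_grid, sim)
        np.testing.assert_array_equal(a.features, b.features)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            SimConfig(abundance_grid=())
        with pytest.raises(ValueError):
            SimConfig(abundance_grid=(3, 2))
        with pytest.raises(ValueError):
            SimConfig(replicates_per_abundance=0)
        with pytest.raises(ValueError):
            RFConfig(n_trees=0)


class TestReliability:
    def good_estimate(self, rng, ci_low=0.5):
        preds = rng.normal(10, 1.5, size=2000)
        return DensityEstimate(species="x", site="s", n_hat=10.0, density=1.0,
                               ci_low=ci_low, ci_high=1.4,
                               tree_predictions=preds,
                               effective_area_km2=10.0)

    def test_clean_case_is_reliable(self, rng):
        est = check_reliability(self.good_estimate(rng), n_events=500)
        assert est.reliable and est.reasons == []

    def test_ci_touching_zero_unreliable(self, rng):
        est = check_reliability(self.good_estimate(rng, ci_low=-0.1),
                                n_events=500)
        assert not est.reliable
        assert any("CI lower bound" in r for r in est.reasons)

    def test_too_few_events_unreliable(self, rng):
        est = check_reliability(self.good_estimate(rng), n_events=38)
        assert not est.reliable
        assert any("insufficient events" in r for r in est.reasons)

    def test_bimodal_distribution_unreliable(self, rng):
        preds = np.concatenate([rng.normal(4, 0.5, 1000),
                                rng.normal(14, 0.5, 1000)])
        est = DensityEstimate(species="x", site="s", n_hat=9.0, density=0.9,
                              ci_low=0.3, ci_high=1.5, tree_predictions=preds,
                              effective_area_km2=10.0)
        out = check_reliability(est, n_events=500)
        assert not out.reliable
        assert any("bell-shaped" in r for r in out.reasons)

    def test_empty_tree_predictions_rejected(self):
        est = DensityEstimate(species="x", site="s", n_hat=1, density=1,
                              ci_low=0.5, ci_high=1.5,
                              tree_predictions=np.array([]))
        with pytest.raises(ValueError):
            check_reliability(est, n_events=500)

    def test_unimodality_heuristic(self, rng):
        assert _is_unimodal(rng.normal(0, 1, 5000))
        assert not _is_unimodal(np.concatenate([rng.normal(-5, 0.3, 2000),
                                                rng.normal(5, 0.3, 2000)]))
        assert _is_unimodal(np.full(100, 3.0))  # degenerate single bin


class TestDensityModel:
    def test_from_records_end_to_end(self, fast_params, study_grid):
        rec = pd.concat([make_records([0, 100, 300], site="site-1",
                                      camera="C01"),
                         make_records([50], site="site-1", camera="C07")],
                        ignore_index=True)
        sim = SimConfig(abundance_grid=(1, 2, 3), replicates_per_abundance=2,
                        months=1, base_seed=5)
        model = DensityModel.from_records(
            rec, study_grid, "Lycalopex spp.", fast_params,
            sim_config=sim, rf_config=RFConfig(n_trees=50, seed=2))
        assert model.observed.n_events == 4
        res = model.fit()
        assert res.conf_int()[0] <= res.density <= res.conf_int()[1]
        assert "Density" in res.summary()
        # refit with the cached training set is identical
        res2 = model.fit()
        assert res2.n_hat == res.n_hat

    def test_site_mismatch_rejected(self, fast_params, study_grid):
        obs = event_table([0] * 10, site="elsewhere")
        with pytest.raises(ValueError):
            DensityModel(obs, study_grid, fast_params)
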