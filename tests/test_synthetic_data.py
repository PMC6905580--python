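"""Determinism, generative structure and channel composition of the
synthetic landscape / survey / elicitation generators."""

import numpy as np
import pandas as pd
import pytest
import shapely
from scipy.special import expit

import sdmfusion as sf


class TestLandscape:
    def test_same_seed_identical(self):
        a = sf.generate_landscape(50, seed=5)
        b = sf.generate_landscape(50, seed=5)
        pd.testing.assert_frame_equal(a, b)

    def test_zero_sites(self):
        assert len(sf.generate_landscape(0, seed=1)) == 0

    def test_fpc_declines_away_from_river(self):
        cov = sf.generate_landscape(10_000, seed=3)
        assert np.corrcoef(cov["fpc"], cov["dist_water"])[0, 1] < 0

    def test_rev_probability_increases_with_fpc(self):
        cov = sf.generate_landscape(10_000, seed=3)
        lo = cov[cov["fpc"] < cov["fpc"].median()]["rev"].mean()
        hi = cov[cov["fpc"] >= cov["fpc"].median()]["rev"].mean()
        assert hi > lo

    def test_degenerate_region_rejected(self):
        line = shapely.Polygon([(0, 0), (1, 1), (2, 2)])
        with pytest.raises(ValueError, match="degenerate"):
            sf.generate_landscape(5, seed=1, region=line)

    def test_sites_inside_region(self):
        cov, (region, _, _) = sf.generate_landscape(200, seed=8, return_geometry=True)
        pts = shapely.points(cov[["longitude", "latitude"]].to_numpy())
        assert shapely.contains(region, pts).all()


class TestSurveys:
    def test_same_seed_identical(self, small_landscape):
        truth = sf.TruthParameters()
        a = sf.simulate_surveys(small_landscape, truth, seed=11)
        b = sf.simulate_surveys(small_landscape, truth, seed=11)
        pd.testing.assert_frame_equal(a, b)

    def test_perfect_detection_recovers_occupied_set(self):
        cov = sf.generate_landscape(80, seed=21)
        truth = sf.TruthParameters(observer_bias=0.0)
        config = sf.SurveyConfig(ground_detect0=0.0, thermal_detect=1.0)
        obs = sf.simulate_surveys(cov, truth, seed=13, config=config)
        # replay the documented stream order: occupancy is the first draw
        rng = np.random.default_rng(13)
        occ = rng.random(len(cov)) < sf.occupancy_probability(cov, truth)
        presences = set(obs.loc[obs["y"] == 1, "site_id"])
        assert presences == set(cov.loc[occ, "site_id"])

    def test_balanced_presences_and_absences(self, study):
        obs = study.observations
        assert (obs["y"] == 1).sum() == (obs["y"] == 0).sum()

    def test_absences_weighted_090(self, study):
        assert (study.observations.loc[study.observations["y"] == 0, "weight"] == 0.9).all()

    def test_channel_composition_mimics_study(self):
        # target ground:thermal:absent = 17:24:41
        fracs = []
        for s in range(6):
            obs = sf.simulate_study(seed=200 + s).observations
            pres = obs[obs["y"] == 1]
            fracs.append((pres["source"] == "ground").mean())
        assert 0.30 < np.mean(fracs) < 0.53

    def test_ground_detection_declines_with_path_distance(self):
        """Empirical per-decile ground-detection frequency matches the
        analytic curve p_occ * g0 * exp(-bias * dist_path)."""
        cov = sf.generate_landscape(250, seed=31)
        truth = sf.TruthParameters(observer_bias=0.004)
        config = sf.SurveyConfig(ground_detect0=0.52)
        counts = np.zeros(len(cov))
        n_rep = 300
        sid_pos = pd.Series(np.arange(len(cov)), index=cov["site_id"])
        for r in range(n_rep):
            obs = sf.simulate_surveys(cov, truth, seed=5_000 + r, config=config)
            hit = obs[(obs["y"] == 1) & (obs["source"] == "ground")]["site_id"]
            counts[sid_pos[hit].to_numpy()] += 1
        p_occ = sf.occupancy_probability(cov, truth)
        expected = p_occ * config.ground_detect0 * np.exp(
            -truth.observer_bias * cov["dist_path"].to_numpy()
        )
        decile = pd.qcut(cov["dist_path"], 10, labels=False)
        emp = pd.Series(counts / n_rep).groupby(decile).mean()
        theo = pd.Series(expected).groupby(decile).mean()
        n_per = pd.Series(expected).groupby(decile).size()
        mc_se = np.sqrt(theo * (1 - theo) / (n_per * n_rep))
        assert (np.abs(emp - theo) < 5 * mc_se + 1e-3).all()


class TestElicitation:
    def test_six_experts_ten_sites_sixty_records(self, small_landscape):
        sites = small_landscape.head(10)
        elic = sf.simulate_elicitation(sites, sf.TruthParameters(), 6, seed=4)
        assert len(elic) == 60
        assert elic["expert_id"].nunique() == 6

    def test_degenerate_noise_recovers_mean(self, small_landscape):
        truth = sf.TruthParameters(sigma_expert=0.0, phi=1e7)
        elic = sf.simulate_elicitation(small_landscape, truth, 3, seed=4)
        ref = sf.compute_reference_scaling(small_landscape)
        z = sf.standardize(small_landscape, ref)
        X = np.column_stack([np.ones(len(z)), z.to_numpy()])
        mu = expit(X @ truth.beta_suit_true)
        for e in range(1, 4):
            got = elic.loc[elic["expert_id"] == e, "p_suitability"].to_numpy()
            np.testing.assert_allclose(got, mu, atol=2e-3)

    def test_site_means_match_quadrature_oracle(self):
        """Sample mean of p_suitability per site approaches the Gaussian
        mixture of Beta means E_u[expit(eta + u)] (20-node quadrature)."""
        cov = sf.generate_landscape(5, seed=17)
        truth = sf.TruthParameters(sigma_expert=0.5, phi=30.0)
        n_experts = 400  # 2,000 records
        elic = sf.simulate_elicitation(cov, truth, n_experts, seed=23)
        ref = sf.compute_reference_scaling(cov)
        X = np.column_stack([np.ones(5), sf.standardize(cov, ref).to_numpy()])
        eta = X @ truth.beta_suit_true
        nodes, w = np.polynomial.hermite.hermgauss(20)
        oracle = np.array(
            [np.sum(w * expit(e + np.sqrt(2) * truth.sigma_expert * nodes)) / np.sqrt(np.pi) for e in eta]
        )
        emp = elic.groupby("site_id")["p_suitability"].mean()
        emp = emp.loc[cov["site_id"]].to_numpy()
        # per-site SD of p_suitability is below 0.2; 4 MC SEs of n=400
        assert np.abs(emp - oracle).max() < 4 * 0.2 / np.sqrt(n_experts)

    def test_confidence_mix_skewed_toward_sure(self, study):
        conf = study.elicitations["suitability_confidence"]
        assert (conf != "not_very_sure").mean() > 0.9

    def test_weights_match_categories(self, study):
        expected = study.elicitations["suitability_confidence"].map(
            {"not_very_sure": 0.5, "quite_sure": 0.75, "very_sure": 1.0}
        )
        np.testing.assert_array_equal(study.elicitations["weight"], expected)

    def test_presence_probabilities_ordered(self, study):
        e = study.elicitations
        assert (e["p_min"] <= e["p_mode"]).all() and (e["p_mode"] <= e["p_max"]).all()


class TestPredictionGrid:
    def test_default_size_636(self):
        assert len(sf.generate_prediction_grid(seed=2)) == 636

    def test_all_points_inside_region(self):
        region, river = sf.default_study_region()
        grid = sf.generate_prediction_grid(region, n=200, seed=2, river=river)
        pts = shapely.points(grid[["longitude", "latitude"]].to_numpy())
        assert shapely.contains(region, pts).all()

    def test_uniform_spacing_within_rows(self):
        grid = sf.generate_prediction_grid(seed=2)
        for _, row in grid.groupby("latitude"):
            xs = np.sort(row["longitude"].to_numpy())
            if len(xs) > 1:
                assert np.allclose(np.diff(xs), np.diff(xs)[0], atol=1e-9)


class TestStudyBundle:
    def test_deterministic(self):
        a = sf.simulate_study(seed=9)
        b = sf.simulate_study(seed=9)
        pd.testing.assert_frame_equal(a.observations, b.observations)
        pd.testing.assert_frame_equal(a.elicitations, b.elicitations)
        pd.testing.assert_frame_equal(a.grid, b.grid)

    def test_each_expert_views_one_site_per_cluster(self, study):
        n_clusters = study.cluster_labels.nunique()
        for _, sub in study.elicitations.groupby("expert_id"):
            assert len(sub) == n_clusters
            viewed_clusters = study.cluster_labels.loc[sub["site_id"]]
            assert viewed_clusters.nunique() == n_clusters
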