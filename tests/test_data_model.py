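"""Weight mapping, reference standardization, distances and table I/O."""

import numpy as np
import pandas as pd
import pytest
import shapely
from hypothesis import given
from hypothesis import strategies as st

import sdmfusion as sf
from sdmfusion.data_model import (
    COVARIATE_COLUMNS,
    WEIGHT_TABLE,
    SchemaError,
    ValidationError,
)


class TestAssignWeight:
    @pytest.mark.parametrize(
        "source, category, expected",
        [
            ("ground", "presence", 1.00),
            ("thermal", "hotspot_confirmed_certain", 1.00),
            ("thermal", "hotspot_confirmed_uncertain", 0.90),
            ("thermal", "hotspot_unconfirmed", 0.50),
            ("ground", "absence", 0.90),
            ("expert", "not_very_sure", 0.50),
            ("expert", "quite_sure", 0.75),
            ("expert", "very_sure", 1.00),
        ],
    )
    def test_confidence_table_values(self, source, category, expected):
        assert sf.assign_weight(source, category) == expected

    def test_total_and_surjective(self):
        values = {sf.assign_weight(s, c) for s, c in WEIGHT_TABLE}
        assert values == {0.50, 0.75, 0.90, 1.00}

    def test_unknown_pair_lists_valid_ones(self):
        with pytest.raises(KeyError, match="ground/presence"):
            sf.assign_weight("satellite", "presence")


class TestReferenceScaling:
    def test_mean_and_sample_sd(self):
        cov = pd.DataFrame({c: [1.0, 2.0, 3.0] for c in COVARIATE_COLUMNS})
        ref = sf.compute_reference_scaling(cov)
        assert np.allclose(ref.mean, 2.0)
        assert np.allclose(ref.sd, 1.0)  # n-1 denominator

    def test_self_standardization_gives_unit_moments(self, small_landscape):
        ref = sf.compute_reference_scaling(small_landscape)
        z = sf.standardize(small_landscape, ref)
        assert np.allclose(z.mean(), 0.0, atol=1e-12)
        assert np.allclose(z.std(ddof=1), 1.0, atol=1e-12)

    def test_held_out_table_matches_brute_force(self, small_landscape, rng):
        ref = sf.compute_reference_scaling(small_landscape)
        other = sf.generate_landscape(15, seed=99)
        z = sf.standardize(other, ref)
        for c in COVARIATE_COLUMNS:
            m = small_landscape[c].to_numpy().mean()
            s = small_landscape[c].to_numpy().std(ddof=1)
            expected = (other[c].to_numpy() - m) / s
            np.testing.assert_allclose(z[c].to_numpy(), expected, atol=1e-12)

    def test_constant_covariate_rejected(self):
        cov = pd.DataFrame({c: [1.0, 2.0, 3.0] for c in COVARIATE_COLUMNS})
        cov["rev"] = 1.0
        with pytest.raises(ValidationError, match="rev"):
            sf.compute_reference_scaling(cov)

    @given(st.integers(0, 2**31 - 1))
    def test_roundtrip_identity(self, seed):
        rng = np.random.default_rng(seed)
        cov = pd.DataFrame(
            rng.normal(size=(8, len(COVARIATE_COLUMNS))), columns=COVARIATE_COLUMNS
        )
        ref = sf.compute_reference_scaling(cov)
        back = sf.unstandardize(sf.standardize(cov, ref), ref)
        np.testing.assert_allclose(back.to_numpy(), cov.to_numpy(), atol=1e-12)

    def test_unit_offsets(self):
        cov = pd.DataFrame({c: [0.0, 2.0] for c in COVARIATE_COLUMNS})
        ref = sf.compute_reference_scaling(cov)
        at_mean = pd.DataFrame({c: [1.0] for c in COVARIATE_COLUMNS})
        z = sf.standardize(at_mean, ref)
        assert np.allclose(z.to_numpy(), 0.0)
        plus_sd = pd.DataFrame({c: [1.0 + ref.sd[c]] for c in COVARIATE_COLUMNS})
        assert np.allclose(sf.standardize(plus_sd, ref).to_numpy(), 1.0)


class TestDistanceToFeatures:
    def test_point_on_segment_is_zero(self):
        seg = shapely.LineString([(0, 0), (4, 0)])
        assert sf.distance_to_features((2.0, 0.0), seg) == 0.0

    def test_three_four_five_triangles(self):
        seg = shapely.LineString([(0, 0), (4, 0)])
        assert sf.distance_to_features((4.0, 3.0), seg) == pytest.approx(3.0)
        assert sf.distance_to_features((8.0, 3.0), seg) == pytest.approx(5.0)

    def test_matches_exhaustive_per_segment_minimum(self, rng):
        segs = [
            shapely.LineString(rng.uniform(-10, 10, size=(2, 2))) for _ in range(100)
        ]
        pt = rng.uniform(-10, 10, size=2)
        got = sf.distance_to_features(tuple(pt), segs)
        brute = min(shapely.Point(pt).distance(s) for s in segs)
        assert got == pytest.approx(brute, abs=1e-12)

    def test_rigid_motion_invariance(self, rng):
        segs = rng.uniform(-5, 5, size=(20, 2, 2))
        pt = rng.uniform(-5, 5, size=2)
        base = sf.distance_to_features(
            tuple(pt), [shapely.LineString(s) for s in segs]
        )
        theta, shift = 0.7, np.array([3.0, -2.0])
        R = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        moved = sf.distance_to_features(
            tuple(R @ pt + shift),
            [shapely.LineString(s @ R.T + shift) for s in segs],
        )
        assert moved == pytest.approx(base, abs=1e-9)

    def test_polygon_distance_is_to_boundary(self):
        poly = shapely.Polygon([(0, 0), (10, 0), (10, 10), (0, 10)])
        assert sf.distance_to_features((5.0, 5.0), poly) == pytest.approx(5.0)

    def test_empty_feature_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            sf.distance_to_features((0.0, 0.0), [])


class TestObservationIO:
    def _table(self, study):
        obs, cov = study.observations, study.covariates
        return obs.merge(cov, on="site_id")

    def test_roundtrip_identity(self, study, tmp_path):
        df = self._table(study)
        path = tmp_path / "obs.csv"
        df.to_csv(path, index=False)
        obs, cov = sf.load_observations(path)
        pd.testing.assert_frame_equal(
            obs, study.observations.reset_index(drop=True), check_dtype=False
        )
        got_cov = cov.set_index("site_id").sort_index()
        want_cov = (
            study.covariates.set_index("site_id")
            .loc[got_cov.index]
            .sort_index()
        )
        pd.testing.assert_frame_equal(got_cov, want_cov, check_dtype=False)

    def test_header_only_file(self, study, tmp_path):
        path = tmp_path / "empty.csv"
        self._table(study).head(0).to_csv(path, index=False)
        obs, cov = sf.load_observations(path)
        assert len(obs) == 0 and len(cov) == 0

    def test_missing_column_named(self, study, tmp_path):
        path = tmp_path / "bad.csv"
        self._table(study).drop(columns=["weight"]).to_csv(path, index=False)
        with pytest.raises(SchemaError, match="weight"):
            sf.load_observations(path)

    def test_out_of_range_value_names_row(self, study, tmp_path):
        df = self._table(study)
        df.loc[3, "fpc"] = 120.0
        path = tmp_path / "bad.csv"
        df.to_csv(path, index=False)
        with pytest.raises(ValidationError, match="fpc"):
            sf.load_observations(path)

    def test_column_mapping(self, study, tmp_path):
        df = self._table(study).rename(columns={"y": "presence", "fpc": "cover"})
        path = tmp_path / "mapped.csv"
        df.to_csv(path, index=False)
        obs, _ = sf.load_observations(path, column_map={"y": "presence", "fpc": "cover"})
        np.testing.assert_array_equal(obs["y"], study.observations["y"])

    def test_elicitation_roundtrip(self, study, tmp_path):
        path = tmp_path / "elic.csv"
        study.elicitations.to_csv(path, index=False)
        back = sf.load_elicitations(path)
        pd.testing.assert_frame_equal(
            back, study.elicitations.reset_index(drop=True), check_dtype=False
        )

    def test_unordered_presence_probabilities_rejected(self, study, tmp_path):
        df = study.elicitations.copy()
        df.loc[0, "p_min"] = df.loc[0, "p_max"] + 0.1
        path = tmp_path / "elic.csv"
        df.to_csv(path, index=False)
        with pytest.raises(ValidationError, match="ordered"):
            sf.load_elicitations(path)
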