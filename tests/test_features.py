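"""Radiomic feature engine: discretization, texture matrices, rosters."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hipporad.features import (
    DiscretizedROI,
    discretize,
    extract_feature_vector,
    feature_names,
    glcm_features,
    glcm_matrix,
    gldzm_features,
    glrlm_features,
    glrlm_matrix,
    glszm_features,
    glszm_matrix,
    ngldm_features,
    ngldm_matrix,
    roster_manifest,
)
from hipporad.features.texture import gldzm_matrix

import oracles


def _strip(levels_1d):
    """A 1x1xN discretized strip with the given levels."""
    arr = np.asarray(levels_1d, dtype=np.int32).reshape(1, 1, -1)
    return DiscretizedROI(arr, int(arr.max()), (0.0, 1.0))


AXIAL = ((0, 0, 1),)


class TestDiscretize:
    def test_constant_roi_maps_to_level_one(self):
        img = np.full((3, 3, 3), 7.0)
        mask = np.ones((3, 3, 3), bool)
        d = discretize(img, mask, 8)
        assert (d.levels[mask] == 1).all()

    def test_linear_ramp_fills_bins_evenly(self):
        img = np.linspace(0, 1, 512).reshape(8, 8, 8)
        mask = np.ones((8, 8, 8), bool)
        d = discretize(img, mask, 8)
        counts = np.bincount(d.levels[mask], minlength=9)[1:]
        assert counts.sum() == 512
        # each level holds ~1/8 of the voxels
        assert np.all(np.abs(counts - 64) <= 1)

    def test_monotone_affine_invariance(self, rng):
        img = rng.normal(size=(5, 5, 5))
        mask = rng.random((5, 5, 5)) > 0.3
        a = discretize(img, mask, 16)
        b = discretize(3.5 * img + 11.0, mask, 16)
        assert np.array_equal(a.levels, b.levels)

    def test_nan_inside_roi_rejected(self):
        img = np.zeros((2, 2, 2))
        img[0, 0, 0] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            discretize(img, np.ones((2, 2, 2), bool), 4)


class TestWorkedExamples:
    def test_glcm_alternating_strip_single_direction(self):
        d = _strip([1, 2, 1, 2])
        p = glcm_matrix(d, AXIAL)
        assert p[0, 1] == pytest.approx(0.5)
        assert p[1, 0] == pytest.approx(0.5)
        f = glcm_features(d, AXIAL)
        assert f["Entropy"] == pytest.approx(1.0)

    def test_glcm_constant_image_entropy_zero_correlation_one(self):
        d = _strip([1, 1, 1, 1])
        f = glcm_features(d, AXIAL)
        assert f["Entropy"] == pytest.approx(0.0)
        assert f["Correlation"] == 1.0

    def test_glrlm_two_runs_of_two(self):
        d = _strip([1, 1, 2, 2])
        counts = glrlm_matrix(d, AXIAL)
        assert counts[0, 1] == 1 and counts[1, 1] == 1
        f = glrlm_features(d, AXIAL)
        assert f["RLN"] == pytest.approx(2.0**2 / 2)
        assert f["RLV"] == pytest.approx(0.0)  # all runs equal length

    def test_glrlm_constant_strip_single_run(self):
        f = glrlm_features(_strip([1] * 6), AXIAL)
        assert f["RLN"] == pytest.approx(1.0)

    def test_glszm_two_zones(self):
        d = _strip([1, 1, 2, 2])
        f = glszm_features(d)
        assert f["GLN"] == pytest.approx((1 + 1) / 2)

    def test_glszm_constant_roi_single_zone(self):
        d = _strip([1, 1, 1])
        counts = glszm_matrix(d)
        assert counts.sum() == 1
        assert glszm_features(d)["GLN"] == pytest.approx(1.0)


class TestOracleEquivalence:
    """Vectorized matrices/features vs naive enumeration on random ROIs."""

    N_INSTANCES = 100

    @pytest.fixture(scope="class")
    def instances(self, rng):
        import conftest

        out = []
        for _ in range(self.N_INSTANCES):
            lv = conftest.random_levels(rng)
            out.append(DiscretizedROI(lv, 4, (0.0, 1.0)))
        return out

    def test_glcm_features_match_oracle(self, instances):
        for d in instances:
            p_oracle = oracles.naive_glcm(d.levels, d.n_levels)
            np.testing.assert_allclose(glcm_matrix(d), p_oracle, rtol=1e-12, atol=1e-15)
            expected = oracles.oracle_glcm_features(p_oracle, d.n_levels)
            got = glcm_features(d)
            for name, val in expected.items():
                assert got[name] == pytest.approx(val, rel=1e-10, abs=1e-12), name

    def test_glrlm_features_match_oracle(self, instances):
        for d in instances:
            counts = oracles.naive_glrlm(d.levels, d.n_levels)
            np.testing.assert_array_equal(glrlm_matrix(d), counts)
            expected = oracles.oracle_rl_features(counts, d.n_voxels, 13)
            got = glrlm_features(d)
            for name, val in expected.items():
                assert got[name] == pytest.approx(val, rel=1e-10, abs=1e-12), name

    def test_glszm_features_match_oracle(self, instances):
        for d in instances:
            counts = oracles.naive_glszm(d.levels, d.n_levels)
            np.testing.assert_array_equal(glszm_matrix(d), counts)
            expected = oracles.oracle_zone_features(counts, d.n_voxels)
            got = glszm_features(d)
            for name, val in expected.items():
                assert got[name] == pytest.approx(val, rel=1e-10, abs=1e-12), name

    def test_gldzm_matrix_matches_flood_fill_oracle(self, instances):
        for d in instances[:40]:
            np.testing.assert_array_equal(
                gldzm_matrix(d), oracles.naive_gldzm(d.levels, d.n_levels)
            )

    def test_ngldm_matrix_matches_neighbor_count_oracle(self, instances):
        for d in instances[:40]:
            ours = ngldm_matrix(d)
            theirs = oracles.naive_ngldm(d.levels, d.n_levels)
            np.testing.assert_array_equal(ours, theirs[:, : ours.shape[1]])
            assert theirs[:, ours.shape[1]:].sum() == 0

    def test_zone_count_equals_flood_fill_count(self, instances):
        for d in instances:
            assert glszm_matrix(d).sum() == len(oracles.flood_fill_zones(d.levels))


class TestInvariants:
    def test_glcm_symmetric_and_normalized(self, rng):
        import conftest

        for _ in range(10):
            d = DiscretizedROI(conftest.random_levels(rng, (5, 5, 5)), 4, (0, 1))
            p = glcm_matrix(d)
            assert p.sum() == pytest.approx(1.0)
            np.testing.assert_allclose(p, p.T)
            f = glcm_features(d)
            assert -1.0 - 1e-12 <= f["Correlation"] <= 1.0 + 1e-12
            assert 0.0 <= f["Entropy"] <= 2 * np.log2(d.n_levels)

    def test_translation_invariance(self, rng):
        img = rng.normal(size=(10, 10, 10))
        mask = np.zeros((10, 10, 10), bool)
        mask[1:5, 1:5, 1:5] = True
        v1 = extract_feature_vector(img, mask)
        shifted_img = np.roll(img, (3, 2, 4), axis=(0, 1, 2))
        shifted_mask = np.roll(mask, (3, 2, 4), axis=(0, 1, 2))
        v2 = extract_feature_vector(shifted_img, shifted_mask)
        np.testing.assert_allclose(v1.to_numpy(), v2.to_numpy(), rtol=1e-12)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(
        scale=st.floats(0.1, 50.0),
        offset=st.floats(-100.0, 100.0),
        seed=st.integers(0, 2**16),
    )
    def test_texture_features_invariant_to_affine_intensity(self, scale, offset, seed):
        r = np.random.default_rng(seed)
        img = r.normal(size=(6, 6, 6))
        mask = r.random((6, 6, 6)) > 0.3
        mask[0, 0, 0] = True
        v1 = extract_feature_vector(img, mask, n_bins=8)
        v2 = extract_feature_vector(scale * img + offset, mask, n_bins=8)
        texture = [n for n in v1.index if "Intensity" not in n]
        np.testing.assert_allclose(
            v1[texture].to_numpy(), v2[texture].to_numpy(), rtol=1e-9, atol=1e-12
        )


class TestRosterContract:
    def test_101_features_13_intensity_88_textural(self):
        m = roster_manifest()
        assert m["n_features"] == 101
        assert m["n_intensity"] == 13
        assert m["n_textural"] == 88

    def test_names_unique_and_modality_prefixed(self):
        names = feature_names("ALFF")
        assert len(names) == len(set(names)) == 101
        assert all(n.startswith("ALFF_") for n in names)
        # the features highlighted in hippocampal radiomics reports exist
        for required in ("ALFF_GLCM_Correlation", "ALFF_GLCM_Entropy",
                        "ALFF_GLRLM_RLN", "ALFF_GLRLM_RLV", "ALFF_GLSZM_GLN"):
            assert required in names

    def test_extraction_deterministic_and_finite(self, rng):
        img = rng.normal(size=(8, 8, 8))
        mask = rng.random((8, 8, 8)) > 0.4
        v1 = extract_feature_vector(img, mask)
        v2 = extract_feature_vector(img.copy(), mask.copy())
        assert (v1 == v2).all()
        assert np.isfinite(v1.to_numpy()).all()


class TestIntensityFeatures:
    def test_constant_roi(self):
        from hipporad.features import intensity_features

        f = intensity_features(np.full((3, 3, 3), 4.2), np.ones((3, 3, 3), bool))
        for stat in ("Mean", "Median", "Min", "Max"):
            assert f[stat] == pytest.approx(4.2)
        assert f["Variance"] == 0.0
        assert f["Skewness"] == 0.0 and f["Kurtosis"] == 0.0
        assert len(f) == 13

    def test_symmetric_sample_has_near_zero_skewness(self, rng):
        from hipporad.features import intensity_features

        x = rng.normal(size=4096)
        sym = np.concatenate([x, -x]).reshape(8, 32, 32)  # exactly symmetric
        f = intensity_features(sym, np.ones(sym.shape, bool))
        assert f["Skewness"] == pytest.approx(0.0, abs=1e-12)
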