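import numpy as np
import pytest

import oracles as o
from conftest import make_dvol, random_dvol
from radtex.texture_matrices import (
    NGTDMTriple,
    TextureMatrix,
    directions_3d,
    glcm,
    glcm_features,
    gldm,
    gldm_features,
    glrlm,
    glrlm_features,
    glszm,
    glszm_features,
    ngtdm,
    ngtdm_features,
    texture_features,
)


class TestGLCM:
    def test_hand_enumeration_2x2(self):
        d = make_dvol([[1, 1], [2, 2]])
        m = glcm(d, (1, 0, 0), symmetric=True)
        # ordered pairs along axis 0: (1,2), (1,2); symmetric adds transpose
        expected = np.array([[0.0, 2.0], [2.0, 0.0]])
        np.testing.assert_array_equal(m.counts, expected)

    def test_constant_slice_single_entry(self):
        n, mcols = 4, 5
        d = make_dvol(np.ones((n, mcols), dtype=int))
        m = glcm(d, (1, 0, 0), symmetric=True)
        assert m.counts[0, 0] == 2 * (n - 1) * mcols

    def test_symmetric_equals_transpose(self, rng):
        for _ in range(10):
            d = random_dvol(rng)
            for direction in directions_3d():
                m = glcm(d, direction, symmetric=True)
                np.testing.assert_array_equal(m.counts, m.counts.T)

    def test_thin_mask_warns_and_zero_matrix(self):
        d = make_dvol(np.array([[1]]))
        with pytest.warns(UserWarning, match="no valid"):
            m = glcm(d, (1, 0, 0))
        assert m.total == 0

    def test_matches_brute_force_all_directions(self, rng):
        for _ in range(10):
            d = random_dvol(rng)
            for direction in directions_3d():
                for sym in (True, False):
                    got = glcm(d, direction, symmetric=sym).counts
                    exp = o.bf_glcm(d.levels, direction, 1, symmetric=sym)
                    a, b = o.pad_to_match(got, exp)
                    np.testing.assert_array_equal(a, b)


class TestGLCMFeatures:
    def test_point_mass(self):
        counts = np.zeros((3, 3))
        counts[1, 1] = 4.0
        f = glcm_features(TextureMatrix(kind="GLCM", counts=counts, ng=3))
        assert f["energy"] == pytest.approx(1.0)
        assert f["joint_entropy"] == pytest.approx(0.0, abs=1e-9)
        assert f["contrast"] == 0.0

    def test_uniform_two_level(self):
        counts = np.ones((2, 2))
        f = glcm_features(TextureMatrix(kind="GLCM", counts=counts, ng=2))
        assert f["joint_entropy"] == pytest.approx(2.0, abs=1e-9)
        assert f["energy"] == pytest.approx(0.25)

    def test_zero_total_raises(self):
        m = TextureMatrix(kind="GLCM", counts=np.zeros((2, 2)), ng=2)
        with pytest.raises(ValueError, match="empty"):
            glcm_features(m)


class TestGLSZM:
    def test_hand_labeling(self):
        d = make_dvol([[1, 1], [1, 2]])
        m = glszm(d, connectivity=8)
        assert m.counts[0, 2] == 1  # zone of level 1, size 3
        assert m.counts[1, 0] == 1  # zone of level 2, size 1

    def test_constant_mask_single_zone(self):
        d = make_dvol(np.ones((3, 4), dtype=int))
        m = glszm(d)
        assert m.counts[0, 11] == 1
        assert m.counts.sum() == 1

    def test_voxel_conservation(self, rng):
        for _ in range(10):
            d = random_dvol(rng)
            m = glszm(d)
            sizes = np.arange(1, m.counts.shape[1] + 1)
            assert (m.counts * sizes).sum() == d.n_masked

    @pytest.mark.parametrize("conn", [6, 18, 26])
    def test_matches_brute_force(self, rng, conn):
        for _ in range(8):
            d = random_dvol(rng)
            got = glszm(d, connectivity=conn).counts
            exp = o.bf_glszm(d.levels, d.ng, connectivity=conn)
            a, b = o.pad_to_match(got, exp)
            np.testing.assert_array_equal(a, b)


class TestGLSZMFeatures:
    def test_single_unit_zone(self):
        counts = np.zeros((2, 2))
        counts[0, 0] = 1
        f = glszm_features(TextureMatrix(kind="GLSZM", counts=counts, ng=2))
        assert f["small_area_emphasis"] == 1.0
        assert f["large_area_emphasis"] == 1.0

    def test_size_two_zone(self):
        counts = np.zeros((1, 2))
        counts[0, 1] = 1
        f = glszm_features(TextureMatrix(kind="GLSZM", counts=counts, ng=1))
        assert f["small_area_emphasis"] == pytest.approx(0.25)


class TestGLRLM:
    def test_hand_run_coding(self):
        d = make_dvol(np.array([[1, 1, 1, 2]]))
        m = glrlm(d, (0, 1, 0))
        assert m.counts[0, 2] == 1  # run of 1s, length 3
        assert m.counts[1, 0] == 1  # run of 2s, length 1
        assert m.counts.sum() == 2

    def test_constant_row_single_run(self):
        d = make_dvol(np.ones((1, 6), dtype=int))
        m = glrlm(d, (0, 1, 0))
        assert m.counts[0, 5] == 1
        assert m.counts.sum() == 1

    def test_runs_partition_voxels(self, rng):
        for _ in range(10):
            d = random_dvol(rng)
            for direction in directions_3d():
                m = glrlm(d, direction)
                r = np.arange(1, m.counts.shape[1] + 1)
                assert (m.counts * r).sum() == d.n_masked

    def test_matches_brute_force_all_directions(self, rng):
        for _ in range(8):
            d = random_dvol(rng)
            for direction in directions_3d():
                got = glrlm(d, direction).counts
                exp = o.bf_glrlm(d.levels, direction, d.ng)
                a, b = o.pad_to_match(got, exp)
                np.testing.assert_array_equal(a, b)


class TestGLRLMFeatures:
    def test_all_unit_runs(self):
        counts = np.zeros((2, 1))
        counts[:, 0] = [3, 4]
        f = glrlm_features(TextureMatrix(kind="GLRLM", counts=counts, ng=2), n_masked=7)
        assert f["short_run_emphasis"] == 1.0
        assert f["long_run_emphasis"] == 1.0
        assert f["run_percentage"] == 1.0

    def test_single_long_run(self):
        counts = np.zeros((1, 4))
        counts[0, 3] = 1
        f = glrlm_features(TextureMatrix(kind="GLRLM", counts=counts, ng=1), n_masked=4)
        assert f["long_run_emphasis"] == 16.0
        assert f["run_percentage"] == pytest.approx(0.25)


class TestNGTDM:
    def test_constant_image_zero_differences(self):
        d = make_dvol(np.ones((3, 3), dtype=int))
        t = ngtdm(d, radius=1)
        assert t.s[0] == 0.0
        assert t.n[0] == 9

    def test_hand_neighborhood_means_on_row(self):
        d = make_dvol(np.array([[1, 2, 3]]))
        t = ngtdm(d, radius=1)
        # center (level 2): neighbors {1,3}, mean 2 -> contributes 0
        # ends: |1-2| and |3-2| -> s_1 = s_3 = 1
        assert t.s[1] == pytest.approx(0.0)
        assert t.s[0] == pytest.approx(1.0)
        assert t.s[2] == pytest.approx(1.0)

    def test_matches_brute_force(self, rng):
        for _ in range(10):
            d = random_dvol(rng)
            t = ngtdm(d, radius=1)
            n_exp, s_exp = o.bf_ngtdm(d.levels, d.ng, radius=1)
            np.testing.assert_array_equal(t.n, n_exp)
            np.testing.assert_allclose(t.s, s_exp, atol=1e-10)

    def test_isolated_voxels_raise(self):
        lev = np.zeros((5, 5, 5), dtype=int)
        lev[0, 0, 0] = 1
        lev[4, 4, 4] = 2
        with pytest.raises(ValueError, match="neighbor"):
            ngtdm(make_dvol(lev, ng=2), radius=1)


class TestNGTDMFeatures:
    def test_flat_texture_coarseness_sentinel(self):
        t = NGTDMTriple(n=np.array([9.0]), s=np.array([0.0]), ng=1)
        f = ngtdm_features(t)
        assert f["coarseness"] == 1e6

    def test_single_level_conventions(self):
        t = NGTDMTriple(n=np.array([5.0, 0.0]), s=np.array([0.4, 0.0]), ng=2)
        f = ngtdm_features(t)
        assert f["contrast"] == 0.0
        assert f["busyness"] == 0.0


class TestGLDM:
    def test_constant_3x3_neighbor_counts(self):
        d = make_dvol(np.ones((3, 3), dtype=int))
        m = gldm(d, radius=1, gamma=0)
        assert m.counts[0, 8] == 1  # center with 8 dependent neighbors
        assert m.counts[0, 5] == 4  # edges
        assert m.counts[0, 3] == 4  # corners

    def test_each_voxel_classified_once(self, rng):
        for _ in range(10):
            d = random_dvol(rng)
            m = gldm(d, radius=1, gamma=0)
            assert m.counts.sum() == d.n_masked

    def test_checkerboard_matches_brute_force(self):
        lev = np.indices((6, 6)).sum(axis=0) % 2 + 1
        d = make_dvol(lev)
        got = gldm(d, radius=1, gamma=0).counts
        exp = o.bf_gldm(d.levels, d.ng, radius=1, gamma=0)
        a, b = o.pad_to_match(got, exp)
        np.testing.assert_array_equal(a, b)

    @pytest.mark.parametrize("gamma", [0, 1])
    def test_matches_brute_force(self, rng, gamma):
        for _ in range(8):
            d = random_dvol(rng)
            got = gldm(d, radius=1, gamma=gamma).counts
            exp = o.bf_gldm(d.levels, d.ng, radius=1, gamma=gamma)
            a, b = o.pad_to_match(got, exp)
            np.testing.assert_array_equal(a, b)


class TestGLDMFeatures:
    def test_all_isolated_voxels(self):
        counts = np.zeros((1, 1))
        counts[0, 0] = 10  # every voxel has dependence 0
        f = gldm_features(TextureMatrix(kind="GLDM", counts=counts, ng=1))
        assert f["large_dependence_emphasis"] == 1.0  # (0+1)^2

    def test_single_cell_high_dependence(self):
        counts = np.zeros((1, 9))
        counts[0, 8] = 1
        f = gldm_features(TextureMatrix(kind="GLDM", counts=counts, ng=1))
        assert f["large_dependence_emphasis"] == 81.0  # (8+1)^2


class TestFeatureFormulaOracles:
    """Every named feature matches an independent direct-summation oracle."""

    N_MATRICES = 50

    def test_glcm_features_match_oracle(self, rng):
        for _ in range(self.N_MATRICES):
            counts = rng.integers(0, 20, size=(5, 5)).astype(float)
            counts = counts + counts.T  # symmetric-mode matrix
            got = glcm_features(TextureMatrix(kind="GLCM", counts=counts, ng=5))
            exp = o.o_glcm_features(counts)
            for k, v in exp.items():
                assert got[k] == pytest.approx(v, rel=1e-10, abs=1e-10), k

    def test_glszm_features_match_oracle(self, rng):
        for _ in range(self.N_MATRICES):
            counts = rng.integers(0, 10, size=(4, 6)).astype(float)
            counts[0, 0] += 1
            got = glszm_features(TextureMatrix(kind="GLSZM", counts=counts, ng=4))
            exp = o.o_glszm_features(counts)
            for k, v in exp.items():
                assert got[k] == pytest.approx(v, rel=1e-10), k

    def test_glrlm_features_match_oracle(self, rng):
        for _ in range(self.N_MATRICES):
            counts = rng.integers(0, 10, size=(4, 5)).astype(float)
            counts[0, 0] += 1
            n_masked = int((counts * np.arange(1, 6)).sum())
            got = glrlm_features(
                TextureMatrix(kind="GLRLM", counts=counts, ng=4), n_masked=n_masked
            )
            exp = o.o_glrlm_features(counts, n_masked)
            for k, v in exp.items():
                assert got[k] == pytest.approx(v, rel=1e-10), k

    def test_ngtdm_features_match_oracle(self, rng):
        for _ in range(self.N_MATRICES):
            n = rng.integers(0, 30, size=5).astype(float)
            if n.sum() == 0:
                n[0] = 1
            s = rng.uniform(0, 10, size=5) * (n > 0)
            got = ngtdm_features(NGTDMTriple(n=n, s=s, ng=5))
            exp = o.o_ngtdm_features(n, s)
            for k, v in exp.items():
                assert got[k] == pytest.approx(v, rel=1e-10, abs=1e-12), k

    def test_gldm_features_match_oracle(self, rng):
        for _ in range(self.N_MATRICES):
            counts = rng.integers(0, 10, size=(4, 7)).astype(float)
            counts[0, 0] += 1
            got = gldm_features(TextureMatrix(kind="GLDM", counts=counts, ng=4))
            exp = o.o_gldm_features(counts)
            for k, v in exp.items():
                assert got[k] == pytest.approx(v, rel=1e-10), k


class TestAggregation:
    def test_rotation_invariance_of_direction_averaged_features(self, rng):
        """90-degree in-plane rotation permutes directional matrices, leaving
        direction-averaged GLCM/GLRLM features unchanged (square slices)."""
        lev = rng.integers(1, 5, size=(7, 7, 3))
        a = texture_features(make_dvol(lev, ng=4), mode_2d=True)
        b = texture_features(make_dvol(np.rot90(lev, axes=(0, 1)).copy(), ng=4), mode_2d=True)
        for k in a:
            if k.startswith(("glcm_", "glrlm_")):
                assert a[k] == pytest.approx(b[k], rel=1e-9), k

    def test_full_texture_feature_count(self, rng):
        lev = rng.integers(1, 5, size=(8, 8, 8))
        feats = texture_features(make_dvol(lev, ng=4))
        prefixes = {k.split("_")[0] for k in feats}
        assert prefixes == {"glcm", "glszm", "glrlm", "ngtdm", "gldm"}
        assert len([k for k in feats if k.startswith("glcm_")]) == 14
        assert len([k for k in feats if k.startswith("glrlm_")]) == 16
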