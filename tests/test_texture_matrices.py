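"""GLCM / NGTDM / RLM builders and features against brute-force oracles."""

import numpy as np
import pytest

from deltarad.features import (
    DIRECTIONS_13,
    DegenerateMatrixError,
    build_glcm,
    build_ngtdm,
    build_rlm,
    glcm_features,
    ngtdm_features,
    rlm_features,
)
from deltarad.features.ngtdm import EPS
from deltarad.synthetic import FIXTURE_NAMES, generate_fixture

from oracles import brute_glcm_counts, brute_ngtdm, brute_rlm_counts, direct_glcm_features


# --------------------------------------------------------------------- GLCM

class TestGLCM:
    def test_hand_enumerated_2x2(self):
        """[[1,1],[2,2]] with the in-row offset: P(1,1)=P(2,2)=1/2."""
        lv = np.array([[[1, 1], [2, 2]]])
        tm = build_glcm(lv, np.ones_like(lv, bool), offsets=[(0, 0, 1)], n_levels=2)
        assert np.allclose(tm.matrix, [[0.5, 0.0], [0.0, 0.5]])
        f = glcm_features(tm)
        assert f["energy"] == pytest.approx(0.5)
        assert f["contrast"] == pytest.approx(0.0)

    def test_constant_region_single_entry(self):
        lv = np.full((3, 3, 3), 2)
        tm = build_glcm(lv, np.ones_like(lv, bool), n_levels=3)
        assert tm.matrix[1, 1] == pytest.approx(1.0)
        f = glcm_features(tm)
        assert f["energy"] == pytest.approx(1.0)
        assert f["entropy"] == pytest.approx(0.0)

    @pytest.mark.parametrize("name", list(FIXTURE_NAMES))
    def test_matches_brute_force_on_fixtures(self, name):
        """Exact integer pair counts on every fixture, all 13 offsets."""
        img, mask, _ = generate_fixture(name)
        lv = np.asarray(img) + (1 if img.min() == 0 else 0)  # tones start at 1
        k = int(lv[mask].max())
        tm = build_glcm(lv, mask, n_levels=k)
        expected = brute_glcm_counts(lv, mask, DIRECTIONS_13, k)
        assert np.array_equal(tm.meta["counts"], expected)

    def test_features_match_direct_summation(self):
        img, mask, _ = generate_fixture("haralick4x4")
        tm = build_glcm(img, mask, n_levels=4)
        got = glcm_features(tm)
        want = direct_glcm_features(tm.matrix)
        for key, val in want.items():
            assert got[key] == pytest.approx(val, abs=1e-12), key

    def test_uniform_matrix_energy(self):
        from deltarad.features import TextureMatrix

        K = 5
        tm = TextureMatrix("GLCM", K, np.full((K, K), 1.0 / K**2), 1.0)
        assert glcm_features(tm)["energy"] == pytest.approx(1.0 / K**2)

    def test_diagonal_matrix_zero_contrast(self):
        from deltarad.features import TextureMatrix

        tm = TextureMatrix("GLCM", 3, np.diag([0.2, 0.3, 0.5]), 1.0)
        f = glcm_features(tm)
        assert f["contrast"] == 0.0
        assert f["dissimilarity"] == 0.0

    def test_transpose_invariance(self, rng):
        lv = rng.integers(1, 5, size=(4, 5, 6))
        mask = rng.random((4, 5, 6)) > 0.2
        a = glcm_features(build_glcm(lv, mask, n_levels=4))
        b = glcm_features(build_glcm(lv.transpose(0, 2, 1), mask.transpose(0, 2, 1), n_levels=4))
        for key in a:
            assert a[key] == pytest.approx(b[key], rel=1e-12), key

    def test_inplane_rotation_invariance(self, rng):
        lv = rng.integers(1, 5, size=(3, 6, 6))
        mask = np.ones_like(lv, bool)
        a = glcm_features(build_glcm(lv, mask, n_levels=4))
        rot = np.rot90(lv, axes=(1, 2))
        b = glcm_features(build_glcm(rot, np.ones_like(rot, bool), n_levels=4))
        for key in a:
            assert a[key] == pytest.approx(b[key], rel=1e-12), key

    def test_degenerate_mask_raises(self):
        lv = np.ones((3, 3, 3), int)
        mask = np.zeros((3, 3, 3), bool)
        mask[1, 1, 1] = True  # no neighbor pairs
        with pytest.raises(DegenerateMatrixError):
            build_glcm(lv, mask, n_levels=1)


# -------------------------------------------------------------------- NGTDM

class TestNGTDM:
    def test_constant_region_degenerate_conventions(self):
        lv = np.full((4, 4, 4), 3)
        tm = build_ngtdm(lv, np.ones_like(lv, bool), n_levels=3)
        f = ngtdm_features(tm)
        assert f["strength"] == pytest.approx(0.0)
        assert f["coarseness"] == pytest.approx(1.0 / EPS)

    @pytest.mark.parametrize("name", ["checker2", "haralick4x4", "sphere_r10"])
    def test_matches_brute_force(self, name):
        img, mask, _ = generate_fixture(name)
        lv = np.asarray(img) + (1 if img.min() == 0 else 0)
        k = int(lv[mask].max())
        tm = build_ngtdm(lv, mask, n_levels=k)
        n_i, p_i, s_i, n_valid = brute_ngtdm(lv, mask, k)
        assert tm.norm == n_valid
        assert np.allclose(tm.matrix[:, 0], n_i)
        assert np.allclose(tm.matrix[:, 1], p_i)
        assert np.allclose(tm.matrix[:, 2], s_i, atol=1e-9)

    def test_checkerboard_s_matches_hand_count(self):
        """In the 3D parity checkerboard every voxel differs from its
        neighborhood mean by a computable amount; spot-check s_i."""
        img, mask, _ = generate_fixture("checker2")
        tm = build_ngtdm(img, mask, n_levels=2)
        _, _, s_i, _ = brute_ngtdm(img, mask, 2)
        assert np.allclose(tm.matrix[:, 2], s_i)
        assert (s_i > 0).all()  # both tones see contrasting neighborhoods

    def test_empty_raises(self):
        with pytest.raises(DegenerateMatrixError):
            build_ngtdm(np.ones((2, 2, 2), int), np.zeros((2, 2, 2), bool))


# ---------------------------------------------------------------------- RLM

class TestRLM:
    def test_single_row_hand_enumeration(self):
        """[1,1,1,2,2] along one direction: runs {(1,3), (2,2)}."""
        lv = np.array([[[1, 1, 1, 2, 2]]])
        tm = build_rlm(lv, np.ones_like(lv, bool), directions=[(0, 0, 1)], n_levels=2)
        assert tm.matrix[0, 2] == 1 and tm.matrix[1, 1] == 1
        assert tm.matrix.sum() == 2
        f = rlm_features(tm)
        assert f["sre"] == pytest.approx((1 / 9 + 1 / 4) / 2)
        assert f["gln"] == pytest.approx(1.0)

    def test_constant_region_gln_equals_run_count(self):
        lv = np.full((1, 4, 6), 2)
        tm = build_rlm(lv, np.ones_like(lv, bool), directions=[(0, 0, 1)], n_levels=2)
        n_runs = tm.matrix.sum()
        assert n_runs == 4  # one run per row
        assert rlm_features(tm)["gln"] == pytest.approx(n_runs)

    @pytest.mark.parametrize("name", list(FIXTURE_NAMES))
    def test_run_length_conservation(self, name):
        """Sum of l * r(g, l) over one direction equals the in-mask voxel count."""
        img, mask, _ = generate_fixture(name)
        lv = np.asarray(img) + (1 if img.min() == 0 else 0)
        k = int(lv[mask].max())
        tm = build_rlm(lv, mask, directions=[(1, 0, 0)], n_levels=k)
        lengths = np.arange(1, tm.matrix.shape[1] + 1)
        assert (tm.matrix * lengths).sum() == mask.sum()

    @pytest.mark.parametrize("name", ["checker2", "haralick4x4", "cube_s10"])
    def test_matches_brute_force(self, name):
        img, mask, _ = generate_fixture(name)
        lv = np.asarray(img) + (1 if img.min() == 0 else 0)
        k = int(lv[mask].max())
        tm = build_rlm(lv, mask, n_levels=k)
        expected = brute_rlm_counts(lv, mask, DIRECTIONS_13, k, tm.matrix.shape[1])
        assert np.array_equal(tm.matrix, expected)

    def test_runs_break_at_mask_boundary(self):
        lv = np.array([[[1, 1, 1, 1, 1]]])
        mask = np.array([[[True, True, False, True, True]]])
        tm = build_rlm(lv, mask, directions=[(0, 0, 1)], n_levels=1)
        assert tm.matrix[0, 1] == 2  # two runs of length 2

    def test_rotation_invariance(self, rng):
        lv = rng.integers(1, 4, size=(3, 5, 5))
        mask = np.ones_like(lv, bool)
        a = rlm_features(build_rlm(lv, mask, n_levels=3))
        rot = np.rot90(lv, axes=(1, 2))
        b = rlm_features(build_rlm(rot, np.ones_like(rot, bool), n_levels=3))
        for key in a:
            assert a[key] == pytest.approx(b[key], rel=1e-12), key
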