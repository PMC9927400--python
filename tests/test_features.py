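"""Texture, first-order and shape feature tests: hand examples, brute-force
oracle equivalence, and invariants."""

import numpy as np
import pytest

from oracles import (
    gldm_bruteforce,
    glcm_bruteforce,
    glrlm_bruteforce,
    random_discrete_volume,
)
from rfa_radiomics.features import (
    DiscretizedVolume,
    discretize,
    extract_features,
    firstorder_features,
    glcm_features,
    glcm_matrix,
    gldm_features,
    gldm_matrix,
    glrlm_features,
    glrlm_matrix,
    shape_features,
)


def _dv(labels, mask=None):
    labels = np.asarray(labels, dtype=np.int32)
    if mask is None:
        mask = labels > 0
    return DiscretizedVolume(labels=labels, n_levels=int(labels.max()), mask=mask)


@pytest.fixture
def run_1124():
    """The 1x1x4 volume [1,1,2,2]."""
    return _dv(np.array([1, 1, 2, 2]).reshape(1, 1, 4))


class TestDiscretize:
    def test_uniform_quartiles(self, rng):
        vals = rng.uniform(size=(10, 10, 10))
        dv = discretize(vals, np.ones(vals.shape, bool), n_bins=4)
        occ = np.bincount(dv.labels[dv.mask], minlength=5)[1:] / vals.size
        assert np.all(np.abs(occ - 0.25) < 0.05)

    def test_constant_region(self):
        dv = discretize(np.full((3, 3, 3), 0.7), np.ones((3, 3, 3), bool))
        assert dv.n_levels == 1
        assert np.all(dv.labels[dv.mask] == 1)

    def test_two_values_two_bins(self):
        cube = np.array([0.1, 0.9, 0.1, 0.9]).reshape(1, 1, 4)
        dv = discretize(cube, np.ones(cube.shape, bool), n_bins=2)
        assert set(dv.labels[dv.mask]) == {1, 2}

    def test_empty_mask_raises(self):
        with pytest.raises(ValueError):
            discretize(np.zeros((3, 3, 3)), np.zeros((3, 3, 3), bool))


class TestGLCM:
    def test_hand_pair_enumeration(self, run_1124):
        p = glcm_matrix(run_1124)
        expected = np.array([[1 / 3, 1 / 6], [1 / 6, 1 / 3]])
        np.testing.assert_allclose(p, expected, atol=1e-12)

    def test_constant_cube(self):
        dv = _dv(np.ones((3, 3, 3), dtype=int))
        p = glcm_matrix(dv)
        assert p.shape == (1, 1) and p[0, 0] == 1.0

    def test_idmn_hand_value(self, run_1124):
        f = glcm_features(glcm_matrix(run_1124), run_1124.n_levels)
        assert f["Idmn"] == pytest.approx(14 / 15, abs=1e-12)

    def test_inverse_variance_hand_value(self, run_1124):
        f = glcm_features(glcm_matrix(run_1124), run_1124.n_levels)
        assert f["InverseVariance"] == pytest.approx(1 / 3, abs=1e-12)

    def test_constant_degenerate_features(self):
        dv = _dv(np.ones((3, 3, 3), dtype=int))
        f = glcm_features(glcm_matrix(dv), dv.n_levels)
        assert f["Idmn"] == 1.0
        assert f["ClusterShade"] == 0.0
        assert f["InverseVariance"] == 0.0
        assert f["Imc1"] == 0.0 and f["Imc2"] == 0.0

    def test_matches_bruteforce(self, rng):
        for _ in range(5):
            labels, mask = random_discrete_volume(rng)
            dv = _dv(labels, mask)
            np.testing.assert_allclose(
                glcm_matrix(dv), glcm_bruteforce(labels), atol=1e-12
            )

    def test_matrix_symmetric_sums_to_one(self, rng):
        labels, mask = random_discrete_volume(rng, shape=(6, 6, 6))
        p = glcm_matrix(_dv(labels, mask))
        assert p.sum() == pytest.approx(1.0)
        np.testing.assert_allclose(p, p.T)


class TestGLRLM:
    def test_single_axis_hand_runs(self, run_1124):
        mat = glrlm_matrix(run_1124, directions=[(0, 0, 1)])
        expected = np.zeros((2, 2))
        expected[0, 1] = 1  # level 1, length 2
        expected[1, 1] = 1  # level 2, length 2
        np.testing.assert_allclose(mat, expected)
        f = glrlm_features(run_1124, directions=[(0, 0, 1)])
        assert f["RunEntropy"] == pytest.approx(1.0, abs=1e-12)

    def test_constant_line_zero_entropy(self):
        dv = _dv(np.ones((1, 1, 4), dtype=int))
        f = glrlm_features(dv, directions=[(0, 0, 1)])
        assert f["RunEntropy"] == 0.0

    def test_matches_bruteforce(self, rng):
        for _ in range(5):
            labels, mask = random_discrete_volume(rng)
            got = glrlm_matrix(_dv(labels, mask))
            exp = glrlm_bruteforce(labels)
            np.testing.assert_allclose(got[:, : exp.shape[1]], exp, atol=1e-12)


class TestGLDM:
    def test_single_voxel(self):
        labels = np.zeros((3, 3, 3), dtype=np.int32)
        labels[1, 1, 1] = 1
        f = gldm_features(_dv(labels))
        assert f["DependenceEntropy"] == 0.0

    def test_line_of_three_hand_value(self):
        dv = _dv(np.ones((1, 1, 3), dtype=int))
        expected = -(2 / 3) * np.log2(2 / 3) - (1 / 3) * np.log2(1 / 3)
        f = gldm_features(dv, alpha=0)
        assert f["DependenceEntropy"] == pytest.approx(expected, abs=1e-12)

    def test_matches_bruteforce(self, rng):
        for _ in range(5):
            labels, mask = random_discrete_volume(rng)
            got = gldm_matrix(_dv(labels, mask))
            exp = gldm_bruteforce(labels)
            np.testing.assert_allclose(got[:, : exp.shape[1]], exp, atol=1e-12)


class TestShape:
    def _sphere_mask(self, radius_vox, shape=(24, 24, 24), spacing=(1, 1, 1)):
        coords = np.meshgrid(*(np.arange(s) for s in shape), indexing="ij")
        center = [(s - 1) / 2 for s in shape]
        r = sum(((c - m) * sp) ** 2 for c, m, sp in zip(coords, center, spacing))
        return r <= radius_vox**2

    def test_sphere_elongation(self):
        mask = self._sphere_mask(8.0)
        f = shape_features(mask, (1.0, 1.0, 1.0))
        assert f["Elongation"] == pytest.approx(1.0, abs=0.02)

    def test_ellipsoid_elongation(self):
        shape = (40, 40, 40)
        coords = np.meshgrid(*(np.arange(s) - 19.5 for s in shape), indexing="ij")
        mask = (coords[0] / 10) ** 2 + (coords[1] / 5) ** 2 + (coords[2] / 5) ** 2 <= 1
        f = shape_features(mask, (1.0, 1.0, 1.0))
        assert f["Elongation"] == pytest.approx(0.5, abs=0.03)

    def test_spacing_equivalence(self):
        # same physical ellipsoid sampled on an anisotropic grid
        shape = (80, 40, 40)
        coords = np.meshgrid(
            np.arange(shape[0]) * 0.5 - 19.75,
            np.arange(shape[1]) - 19.5,
            np.arange(shape[2]) - 19.5,
            indexing="ij",
        )
        mask_aniso = (coords[0] / 10) ** 2 + (coords[1] / 5) ** 2 + (coords[2] / 5) ** 2 <= 1
        f_aniso = shape_features(mask_aniso, (0.5, 1.0, 1.0))
        assert f_aniso["Elongation"] == pytest.approx(0.5, abs=0.03)

    def test_single_voxel_convention(self):
        mask = np.zeros((5, 5, 5), bool)
        mask[2, 2, 2] = True
        f = shape_features(mask, (1.0, 1.0, 1.0))
        assert f["Elongation"] == 1.0 and f["Flatness"] == 1.0


class TestFirstOrder:
    def test_constant_region(self):
        f = firstorder_features(np.full((3, 3, 3), 2.0), np.ones((3, 3, 3), bool))
        assert f["Variance"] == 0.0 and f["Entropy"] == 0.0

    def test_hand_values(self):
        cube = np.array([0.0, 0.0, 1.0, 1.0]).reshape(1, 1, 4)
        f = firstorder_features(cube, np.ones(cube.shape, bool))
        assert f["Mean"] == 0.5
        assert f["Variance"] == 0.25

    def test_matches_direct_formulas(self, rng):
        cube = rng.uniform(size=(6, 6, 6))
        mask = rng.uniform(size=cube.shape) < 0.7
        mask.flat[0] = True
        v = cube[mask]
        f = firstorder_features(cube, mask)
        assert f["Mean"] == pytest.approx(v.mean(), abs=1e-12)
        assert f["Variance"] == pytest.approx(v.var(), abs=1e-12)
        assert f["Energy"] == pytest.approx((v**2).sum(), abs=1e-12)
        assert f["RootMeanSquared"] == pytest.approx(np.sqrt((v**2).mean()), abs=1e-12)


class TestInvariantsAndBounds:
    @pytest.mark.parametrize("seed", [7, 11, 13])
    def test_oracle_equivalence_seeded(self, seed):
        rng = np.random.default_rng(seed)
        labels, mask = random_discrete_volume(rng)
        dv = _dv(labels, mask)
        np.testing.assert_allclose(glcm_matrix(dv), glcm_bruteforce(labels), atol=1e-12)
        exp_r = glrlm_bruteforce(labels)
        np.testing.assert_allclose(glrlm_matrix(dv)[:, : exp_r.shape[1]], exp_r)
        exp_d = gldm_bruteforce(labels)
        np.testing.assert_allclose(gldm_matrix(dv)[:, : exp_d.shape[1]], exp_d)

    def test_out_of_mask_values_irrelevant(self, rng):
        cube = rng.uniform(size=(8, 8, 8))
        mask = np.zeros(cube.shape, bool)
        mask[2:6, 2:6, 2:6] = True
        f1 = extract_features(cube, mask)
        cube2 = cube.copy()
        cube2[~mask] = rng.uniform(size=(~mask).sum()) * 100
        f2 = extract_features(cube2, mask)
        for k in f1:
            assert f1[k] == pytest.approx(f2[k], rel=1e-12), k

    def test_feature_bounds(self, rng):
        for _ in range(10):
            labels, mask = random_discrete_volume(rng, shape=(5, 5, 5))
            dv = _dv(labels, mask)
            f = glcm_features(glcm_matrix(dv), dv.n_levels)
            assert 0 < f["Idmn"] <= 1 + 1e-12
            assert 0 <= f["Imc2"] < 1
            assert f["InverseVariance"] >= 0
            s = shape_features(mask, (1.0, 1.0, 1.0))
            assert 0 < s["Elongation"] <= 1 + 1e-9
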