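import numpy as np
import pytest

from gliotex import (
    ExtractionConfig,
    RoiImage,
    aggregate_directions,
    compute_glcm,
    extract_all,
    glcm_features,
    glcm_marginals,
)
from gliotex.glcm import GlcmMatrix, NoPairsError
from gliotex.io import QuantizedRoi
from gliotex.phantoms import PhantomSpec, generate_phantom

from conftest import random_glcm
from _naive import naive_glcm, naive_glcm_features


def qroi(levels, mask=None, n_levels=None):
    levels = np.asarray(levels)
    if mask is None:
        mask = np.ones(levels.shape, bool)
    if n_levels is None:
        n_levels = int(levels.max()) + 1
    return QuantizedRoi(levels=levels, n_levels=max(n_levels, 2), mask=mask)


def matrix(p):
    p = np.asarray(p, float)
    return GlcmMatrix(p=p, d=1, theta=0, pair_count=1)


class TestComputeGlcm:
    def test_two_horizontal_pairs(self):
        m = compute_glcm(qroi([[0, 0], [1, 1]]), theta=0)
        np.testing.assert_allclose(m.p, [[0.5, 0.0], [0.0, 0.5]])
        assert m.pair_count == 4  # 2 pairs, both orders

    def test_two_vertical_pairs(self):
        m = compute_glcm(qroi([[0, 0], [1, 1]]), theta=90)
        np.testing.assert_allclose(m.p, [[0.0, 0.5], [0.5, 0.0]])

    def test_constant_roi_single_entry(self):
        m = compute_glcm(qroi(np.zeros((4, 4), int), n_levels=8), theta=45)
        assert m.p[0, 0] == 1.0
        assert m.p.sum() == 1.0

    def test_scattered_mask_raises_no_pairs(self):
        mask = np.zeros((5, 5), bool)
        mask[0, 0] = mask[4, 4] = True
        with pytest.raises(NoPairsError, match="theta=0"):
            compute_glcm(qroi(np.zeros((5, 5), int), mask=mask), theta=0)

    @pytest.mark.parametrize("theta", [0, 45, 90, 135])
    def test_matches_exhaustive_pair_counter(self, theta, rng):
        levels = rng.integers(0, 6, size=(16, 16))
        mask = rng.random((16, 16)) < 0.6
        mask[::3, ::2] = True
        q = qroi(levels, mask=mask, n_levels=6)
        m = compute_glcm(q, d=1, theta=theta)
        expected = naive_glcm(levels, mask, 6, 1, theta)
        np.testing.assert_allclose(m.p, expected, atol=1e-14)

    def test_symmetry_normalization_nonnegativity(self, rng):
        for _ in range(10):
            levels = rng.integers(0, 8, size=(12, 12))
            mask = rng.random((12, 12)) < 0.7
            mask[5:7, 5:7] = True
            m = compute_glcm(qroi(levels, mask, 8), theta=45)
            assert np.all(m.p >= 0)
            assert m.p.sum() == pytest.approx(1.0, abs=1e-12)
            np.testing.assert_allclose(m.p, m.p.T, atol=1e-15)

    def test_agrees_with_skimage_on_full_rectangle(self, rng):
        """Cross-check against scikit-image on an unmasked image."""
        from skimage.feature import graycomatrix

        levels = rng.integers(0, 5, size=(20, 20))
        q = qroi(levels, n_levels=5)
        # skimage angles: 0, 45, 90, 135 degrees with rows increasing down
        for theta, angle in [(0, 0), (90, np.pi / 2)]:
            m = compute_glcm(q, theta=theta)
            sk = graycomatrix(levels.astype(np.uint8), [1], [angle],
                              levels=5, symmetric=True, normed=True)
            np.testing.assert_allclose(m.p, sk[:, :, 0, 0], atol=1e-12)


class TestMarginals:
    def test_diagonal_matrix_hand_values(self):
        mg = glcm_marginals(matrix([[0.5, 0], [0, 0.5]]))
        assert mg.mu_x == pytest.approx(0.5)
        assert mg.mu_y == pytest.approx(0.5)
        assert mg.sigma_x == pytest.approx(0.5)
        assert mg.sigma_y == pytest.approx(0.5)
        np.testing.assert_allclose(mg.p_diff, [1.0, 0.0])
        np.testing.assert_allclose(mg.p_sum, [0.5, 0.0, 0.5])

    def test_symmetric_matrix_equal_marginals(self, rng):
        p = random_glcm(rng, 7)
        mg = glcm_marginals(matrix(p))
        np.testing.assert_allclose(mg.px, mg.py)
        assert mg.hx == pytest.approx(mg.hy)

    def test_uniform_matrix_entropies(self):
        G = 8
        mg = glcm_marginals(matrix(np.full((G, G), 1 / G**2)))
        assert mg.hxy == pytest.approx(2 * np.log2(G))
        assert mg.hxy1 == pytest.approx(2 * np.log2(G))

    def test_distributions_sum_to_one(self, rng):
        for G in (2, 5, 16):
            mg = glcm_marginals(matrix(random_glcm(rng, G, sparse=True)))
            for dist in (mg.px, mg.py, mg.p_sum, mg.p_diff):
                assert dist.sum() == pytest.approx(1.0, abs=1e-12)
            assert mg.hxy >= abs(mg.hx - mg.hy) - 1e-12


class TestFeatures:
    def test_diagonal_two_level_hand_values(self):
        f = glcm_features(matrix([[0.5, 0], [0, 0.5]]))
        assert f["glcm_contrast"] == 0.0
        assert f["glcm_dissimilarity"] == 0.0
        assert f["glcm_energy"] == pytest.approx(0.5)
        assert f["glcm_entropy"] == pytest.approx(1.0)  # bits
        assert f["glcm_homogeneity"] == pytest.approx(1.0)
        assert f["glcm_inverse_difference_moment"] == pytest.approx(1.0)
        assert f["glcm_correlation"] == pytest.approx(1.0)

    def test_antidiagonal_two_level_hand_values(self):
        f = glcm_features(matrix([[0, 0.5], [0.5, 0]]))
        assert f["glcm_contrast"] == pytest.approx(1.0)
        assert f["glcm_correlation"] == pytest.approx(-1.0)
        assert f["glcm_energy"] == pytest.approx(0.5)

    def test_single_entry_degenerate(self):
        p = np.zeros((4, 4))
        p[0, 0] = 1.0
        f = glcm_features(matrix(p))
        assert f["glcm_energy"] == 1.0
        assert f["glcm_entropy"] == 0.0
        assert f["glcm_contrast"] == 0.0
        assert f.degenerate
        assert f["glcm_correlation"] == 0.0

    def test_matches_naive_implementation(self, rng):
        """Whole canonical suite vs the cell-wise double-loop oracle."""
        for k in range(100):
            G = int(rng.integers(2, 12))
            p = random_glcm(rng, G, sparse=bool(k % 2))
            ours = glcm_features(matrix(p))
            theirs = naive_glcm_features(p.tolist())
            for name, v in theirs.items():
                assert ours[name] == pytest.approx(v, rel=1e-10, abs=1e-10), name

    def test_bounds_on_random_matrices(self, rng):
        for _ in range(30):
            G = int(rng.integers(2, 10))
            f = glcm_features(matrix(random_glcm(rng, G, sparse=True)))
            assert 0 < f["glcm_energy"] <= 1
            assert 0 <= f["glcm_entropy"] <= 2 * np.log2(G) + 1e-9
            assert f["glcm_contrast"] >= 0
            assert f["glcm_dissimilarity"] >= 0
            assert 0 < f["glcm_homogeneity"] <= 1 + 1e-12
            assert 0 < f["glcm_inverse_difference_normalized"] <= 1 + 1e-12
            assert 0 < f["glcm_inverse_difference_moment"] <= 1 + 1e-12
            assert -1 - 1e-9 <= f["glcm_correlation"] <= 1 + 1e-9

    def test_contrast_zero_iff_diagonal(self, rng):
        diag = np.diag(np.array([0.2, 0.3, 0.5]))
        assert glcm_features(matrix(diag))["glcm_contrast"] == 0.0
        p = random_glcm(rng, 4)
        if not np.allclose(p, np.diag(np.diag(p))):
            assert glcm_features(matrix(p))["glcm_contrast"] > 0

    def test_printed_dialect_differs_only_where_documented(self, rng):
        p = random_glcm(rng, 6)
        can = glcm_features(matrix(p), formula_dialect="canonical")
        pri = glcm_features(matrix(p), formula_dialect="printed")
        changed = {k for k in can.values
                   if can[k] != pytest.approx(pri[k], rel=1e-12)}
        assert changed <= {"glcm_autocorrelation", "glcm_homogeneity",
                           "glcm_difference_entropy"}
        assert pri["glcm_autocorrelation"] == pytest.approx(
            pri["glcm_correlation"])

    def test_printed_difference_variance_equals_contrast(self, rng):
        """The literal printed form collapses onto contrast."""
        p = random_glcm(rng, 8)
        f = glcm_features(matrix(p), difference_variance="printed")
        assert f["glcm_difference_variance"] == pytest.approx(
            f["glcm_contrast"], rel=1e-12)


class TestAggregate:
    def test_idempotent_on_identical_inputs(self):
        f = glcm_features(matrix([[0.5, 0], [0, 0.5]]))
        agg = aggregate_directions([f, f, f, f])
        for k in f.values:
            assert agg[k] == pytest.approx(f[k])

    def test_arithmetic_mean(self):
        from gliotex.glcm import GlcmFeatures

        feats = [GlcmFeatures(values={"glcm_contrast": c})
                 for c in (0.0, 1.0, 1.0, 2.0)]
        assert aggregate_directions(feats)["glcm_contrast"] == 1.0

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            aggregate_directions([])


class TestExtractAll:
    def test_heterogeneous_vs_smooth_ordering(self):
        """Speckled phantom: higher contrast/entropy, lower homogeneity."""
        smooth = generate_phantom(PhantomSpec(0, smoothness=5.0, seed=11))
        rough = generate_phantom(PhantomSpec(0, smoothness=0.5, seed=11))
        fs = extract_all(smooth).values
        fr = extract_all(rough).values
        assert fr["glcm_contrast"] > fs["glcm_contrast"]
        assert fr["glcm_entropy"] > fs["glcm_entropy"]
        assert fr["glcm_homogeneity"] < fs["glcm_homogeneity"]
        assert fr["glcm_energy"] < fs["glcm_energy"]

    def test_translation_invariance(self, rng):
        pix = rng.random((40, 40)) * 100
        mask = np.zeros((40, 40), bool)
        mask[5:20, 5:22] = True
        a = extract_all(RoiImage(pixels=pix, mask=mask))
        pix2 = np.roll(np.roll(pix, 3, axis=0), 5, axis=1)
        mask2 = np.roll(np.roll(mask, 3, axis=0), 5, axis=1)
        b = extract_all(RoiImage(pixels=pix2, mask=mask2))
        for k in a.values:
            assert a.values[k] == pytest.approx(b.values[k], rel=1e-12), k

    def test_deterministic_recomputation(self):
        img = generate_phantom(PhantomSpec(1, ring_contrast=0.9,
                                           core_fraction=0.4, seed=5))
        a = extract_all(img)
        b = extract_all(img)
        assert a.values == b.values

    def test_rotation_with_direction_relabeling(self, rng):
        """90-degree rotation swaps the 0/90 and 45/135 direction features."""
        pix = rng.random((30, 30)) * 50
        mask = np.zeros((30, 30), bool)
        mask[4:26, 6:24] = True
        img = RoiImage(pixels=pix, mask=mask)
        rot = RoiImage(pixels=np.rot90(pix), mask=np.rot90(mask))
        a = extract_all(img, verbose=True)
        b = extract_all(rot, verbose=True)
        for t1, t2 in [(0, 90), (90, 0), (45, 135), (135, 45)]:
            for k, v in a.per_direction[t1].items():
                assert v == pytest.approx(b.per_direction[t2][k],
                                          rel=1e-10, abs=1e-12), (t1, k)
        for k in a.values:  # direction-averaged features are invariant
            assert a.values[k] == pytest.approx(b.values[k], rel=1e-10,
                                                abs=1e-12)

    def test_isotropic_texture_directions_converge(self):
        """Direction spread of contrast shrinks as the ROI grows."""
        spreads = []
        for size, radius in [(24, 7.0), (48, 15.0), (96, 31.0)]:
            img = generate_phantom(PhantomSpec(
                0, image_size=size, roi_radius=radius, smoothness=1.5,
                seed=99))
            fv = extract_all(img, verbose=True)
            c = [fv.per_direction[t]["glcm_contrast"] for t in (0, 45, 90, 135)]
            spreads.append(np.std(c) / np.mean(c))
        assert spreads[-1] < spreads[0]

    def test_constant_roi_flagged_not_crashing(self):
        img = RoiImage(pixels=np.full((10, 10), 3.0),
                       mask=np.ones((10, 10), bool))
        fv = extract_all(img)
        assert "constant_roi" in fv.degenerate_flags
        assert "degenerate_glcm" in fv.degenerate_flags
        assert all(np.isfinite(v) for v in fv.values.values())
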