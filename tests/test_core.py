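import numpy as np
import pytest

from histoslice.core import (
    Affine2D,
    ControlPointField,
    DenseDisplacementField,
    Embed2Dto3D,
    FWHM_TO_SIGMA,
    ImageDomain,
    IsotropicScale,
    Rotation2D,
    Rotation3D,
    TensorImage,
    TransformChain,
    Translation,
    apply_chain,
    chain_jacobian,
    gaussian_downsample,
    pad_image,
    reorient_vectors,
    resample,
)
from histoslice.errors import ConfigurationError


def random_affine_chain(rng, n=3):
    members = []
    for _ in range(n):
        kind = rng.integers(4)
        if kind == 0:
            members.append(Rotation2D(rng.uniform(-180, 180),
                                      rng.uniform(-5, 5, 2)))
        elif kind == 1:
            members.append(IsotropicScale(rng.uniform(0.5, 2.0)))
        elif kind == 2:
            members.append(Translation(rng.uniform(-10, 10, 2)))
        else:
            members.append(Affine2D(np.eye(2) + rng.uniform(-0.3, 0.3, (2, 2)),
                                    rng.uniform(-5, 5, 2)))
    return TransformChain(members)


class TestApplyChain:
    def test_empty_chain_is_identity(self):
        out = apply_chain(TransformChain([]), [(3.5, -1.0)])
        np.testing.assert_array_equal(out, [[3.5, -1.0]])

    def test_quarter_turn(self):
        out = apply_chain(TransformChain([Rotation2D(90.0)]), [(1.0, 0.0)])
        np.testing.assert_allclose(out, [[0.0, 1.0]], atol=1e-12)

    def test_scale_then_translate(self):
        chain = TransformChain([IsotropicScale(2.0), Translation((3.0, 0.0))])
        np.testing.assert_allclose(chain.apply([(1.0, 1.0)]), [[5.0, 2.0]])

    def test_dimension_mismatch_names_pair(self):
        chain = TransformChain([Embed2Dto3D(), Rotation2D(10.0)])
        with pytest.raises(ConfigurationError, match="Rotation2D"):
            chain.apply([(0.0, 0.0)])

    def test_composition_associativity(self, rng):
        a = random_affine_chain(rng)
        b = random_affine_chain(rng)
        pts = rng.uniform(-10, 10, (100, 2))
        left = apply_chain(a + b, pts)
        right = apply_chain(b, apply_chain(a, pts))
        np.testing.assert_allclose(left, right, atol=1e-12)


class TestChainJacobian:
    def test_rotation_det_one(self, rng):
        pts = rng.uniform(-10, 10, (100, 2))
        for angle in (13.0, -77.0, 181.0):
            _, dets = chain_jacobian(TransformChain([Rotation2D(angle)]), pts)
            np.testing.assert_allclose(dets, 1.0, atol=1e-9)

    def test_isotropic_scale_det(self, rng):
        _, dets = chain_jacobian(TransformChain([IsotropicScale(2.0)]),
                                 rng.uniform(-5, 5, (10, 2)))
        np.testing.assert_allclose(dets, 4.0, atol=1e-12)

    def test_zero_dense_field_det_one(self, rng):
        field = DenseDisplacementField(np.zeros((8, 8, 2)), spacing=(1.0, 1.0))
        _, dets = chain_jacobian(TransformChain([field]),
                                 rng.uniform(0, 7, (50, 2)))
        np.testing.assert_allclose(dets, 1.0, atol=1e-9)

    def test_rigid_chain_det_one(self, rng):
        chain = TransformChain([Rotation2D(33.0, (1.0, 2.0)),
                                Translation((4.0, -1.0))])
        _, dets = chain_jacobian(chain, rng.uniform(-10, 10, (100, 2)))
        np.testing.assert_allclose(dets, 1.0, atol=1e-9)

    def test_composition_det_product(self, rng):
        a = TransformChain([IsotropicScale(1.5)])
        b = TransformChain([Affine2D([[1.0, 0.2], [0.0, 0.9]], [1.0, 1.0])])
        pts = rng.uniform(-5, 5, (20, 2))
        _, dets_ab = chain_jacobian(a + b, pts)
        _, dets_a = chain_jacobian(a, pts)
        _, dets_b = chain_jacobian(b, a.apply(pts))
        np.testing.assert_allclose(dets_ab, dets_a * dets_b, atol=1e-9)


class TestResample:
    def test_identity_bit_exact(self, rng):
        img = TensorImage(rng.random((12, 15)), resolution=(0.5, 0.5))
        for interp in ("nearest", "linear"):
            out = resample(img, img.domain, interp)
            assert np.array_equal(out.data, img.data)

    def test_linear_midpoint(self):
        src = TensorImage(np.array([[0.0, 10.0]]), resolution=(1.0, 1.0))
        target = ImageDomain.centred((1, 1), (1.0, 1.0))
        out = resample(src, target, "linear")
        np.testing.assert_allclose(out.data, [[5.0]])

    def test_half_turn_of_symmetric_image(self, rng):
        n = 21
        half = rng.random((n, n))
        data = 0.5 * (half + half[::-1, ::-1])  # point-symmetric
        img = TensorImage(data, resolution=(1.0, 1.0))
        target = img.domain.copy(external=TransformChain([Rotation2D(180.0)]))
        out = resample(img, target, "linear")
        np.testing.assert_allclose(out.data, data, atol=1e-9)

    def test_unknown_interpolation(self):
        img = TensorImage(np.zeros((4, 4)), resolution=1.0)
        with pytest.raises(ConfigurationError):
            resample(img, img.domain, "cubic-ish")


class TestReorientVectors:
    def test_identity(self, rng):
        vecs = rng.standard_normal((10, 3))
        pts = rng.standard_normal((10, 3))
        out = reorient_vectors(TransformChain([Translation((1.0, 2.0, 3.0))]),
                               pts, vecs)
        np.testing.assert_allclose(out, vecs, atol=1e-12)

    def test_quarter_turn_about_z(self):
        chain = TransformChain([Rotation3D((0.0, 0.0, 90.0))])
        out = reorient_vectors(chain, [(0.0, 0.0, 0.0)], [(1.0, 0.0, 0.0)])
        np.testing.assert_allclose(out, [[0.0, 1.0, 0.0]], atol=1e-12)

    def test_rigid_chain_preserves_norms(self, rng):
        chain = TransformChain([
            Rotation3D((12.0, -33.0, 71.0), centre=(1.0, 0.0, -2.0)),
            Translation((0.5, 1.5, -0.5)),
        ])
        pts = rng.standard_normal((50, 3))
        vecs = rng.standard_normal((50, 3))
        out = reorient_vectors(chain, pts, vecs)
        np.testing.assert_allclose(np.linalg.norm(out, axis=1),
                                   np.linalg.norm(vecs, axis=1), atol=1e-9)


class TestGaussianDownsample:
    def test_sigma_conversion(self):
        # sigma = FWHM / sqrt(8 ln 2), computed independently
        assert abs(6.25 / FWHM_TO_SIGMA - 2.65413) < 1e-4

    def test_constant_image_interior(self):
        img = TensorImage(np.full((40, 40), 7.0), resolution=(0.05, 0.05))
        out = gaussian_downsample(img, 6.25, 0.2)
        inner = out.data[3:-3, 3:-3]
        np.testing.assert_allclose(inner, 7.0, atol=1e-6)

    def test_shrink_factor(self):
        img = TensorImage(np.zeros((400, 200)), resolution=(0.05, 0.05))
        out = gaussian_downsample(img, 6.25, 0.2)
        assert out.shape == (100, 50)

    def test_upsampling_rejected(self):
        img = TensorImage(np.zeros((10, 10)), resolution=(0.5, 0.5))
        with pytest.raises(ConfigurationError):
            gaussian_downsample(img, 5.0, 0.25)


class TestPadImage:
    def test_sixth_padding_shape(self):
        img = TensorImage(np.zeros((600, 300)), resolution=(0.1, 0.1))
        out = pad_image(img, 1.0 / 6.0)
        assert out.shape == (800, 400)

    def test_zero_fraction_unchanged(self, rng):
        img = TensorImage(rng.random((9, 9)), resolution=1.0)
        out = pad_image(img, 0.0)
        assert np.array_equal(out.data, img.data)

    def test_physical_coordinates_preserved(self, rng):
        img = TensorImage(rng.random((30, 44)), resolution=(0.3, 0.2))
        out = pad_image(img, 1.0 / 6.0)
        pads = [round(s / 6.0) for s in img.shape]
        idx = img.domain.grid_indices()
        before = img.domain.index_to_physical(idx, external=False)
        after = out.domain.index_to_physical(idx + pads, external=False)
        assert np.abs(after - before).max() < 1e-12

    def test_mask_padded_with_zero(self):
        img = TensorImage(np.ones((12, 12)), resolution=1.0,
                          mask=np.ones((12, 12)))
        out = pad_image(img, 1.0 / 6.0)
        assert out.mask[0, 0] == 0.0 and out.mask[6, 6] == 1.0


class TestControlPointField:
    def test_exact_interpolation_single_point(self):
        f = ControlPointField([[0.0, 0.0, 0.0]], [[1.0, 0.0, 2.0]], sigma=2.0)
        np.testing.assert_allclose(
            f.map_points([(0.0, 0.0, 0.0)]), [[1.0, 0.0, 2.0]], atol=1e-12)

    def test_zero_values_zero_field(self, rng):
        pts = rng.uniform(-5, 5, (6, 2))
        f = ControlPointField(pts, np.zeros((6, 2)), sigma=3.0)
        q = rng.uniform(-10, 10, (30, 2))
        np.testing.assert_allclose(f.displacement(q), 0.0, atol=1e-12)

    def test_midpoint_against_direct_solve(self):
        # two mirror-symmetric control values; expected value from an
        # independent dense 2x2 kernel solve
        p = np.array([[-1.0, 0.0], [1.0, 0.0]])
        v = np.array([[1.0, 2.0], [-1.0, 2.0]])
        sigma = 1.3
        f = ControlPointField(p, v, sigma=sigma)
        k = np.exp(-((p[:, None, :] - p[None, :, :]) ** 2).sum(-1)
                   / (2 * sigma**2))
        w = np.linalg.solve(k, v)
        kq = np.exp(-((np.zeros(2) - p) ** 2).sum(-1) / (2 * sigma**2))
        expected = kq @ w
        np.testing.assert_allclose(
            f.displacement([(0.0, 0.0)])[0], expected, atol=1e-12)

    def test_duplicate_points_rejected(self):
        with pytest.raises(ConfigurationError, match="duplicate"):
            ControlPointField([[0.0, 0.0], [0.0, 0.0]], sigma=1.0)

    def test_exact_interpolation_many(self, rng):
        pts = rng.uniform(-5, 5, (8, 3))
        vals = rng.standard_normal((8, 3))
        f = ControlPointField(pts, vals, sigma=2.0)
        np.testing.assert_allclose(f.displacement(pts), vals, atol=1e-8)


class TestDenseField:
    def test_nearest_edge_extension(self):
        vec = np.zeros((4, 4, 2))
        vec[0, :, 0] = 5.0
        f = DenseDisplacementField(vec, spacing=(1.0, 1.0))
        # query far above the grid: takes the edge row's vector
        out = f.displacement([(-10.0, 1.0)])
        np.testing.assert_allclose(out, [[5.0, 0.0]], atol=1e-12)

    def test_non_finite_rejected(self):
        vec = np.zeros((3, 3, 2))
        vec[1, 1, 0] = np.nan
        with pytest.raises(ConfigurationError):
            DenseDisplacementField(vec, spacing=1.0)

    def test_embedding_variant(self):
        vec = np.zeros((4, 4, 3))
        vec[..., 2] = 1.5
        f = DenseDisplacementField(vec, spacing=(1.0, 1.0))
        out = f.map_points([(2.0, 2.0)])
        np.testing.assert_allclose(out, [[2.0, 2.0, 1.5]], atol=1e-12)
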