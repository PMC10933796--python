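import numpy as np
import pytest

from histoslice.core import Translation
from histoslice.errors import ConfigurationError
from histoslice.synthetic import (
    PhantomSpec,
    SliceSurface,
    invert_contrast,
    make_block_and_histology,
    make_phantom_volume,
    make_slab_photo,
    median_contour_distance,
    median_registration_error,
    perturb_pose,
    sample_surface_slices,
)


class TestPhantomVolume:
    def test_deterministic(self):
        spec = PhantomSpec(shape=(48, 48, 48), seed=9)
        a = make_phantom_volume(spec)
        b = make_phantom_volume(spec)
        assert np.array_equal(a.data, b.data)

    def test_zero_noise_is_structural_only(self):
        spec = PhantomSpec(shape=(48, 48, 48), seed=2, noise_sd=0.0,
                           texture_amplitude=0.0)
        vol = make_phantom_volume(spec)
        # pure structural model: a handful of distinct levels only
        assert len(np.unique(np.round(vol.data, 6))) <= 8

    def test_histogram_has_separated_modes(self, phantom_volume):
        """Foreground intensities split into >=2 well-separated clusters
        (independent 1-D k-means)."""
        values = phantom_volume.data[phantom_volume.data > 0.05]
        values = values[:: max(1, len(values) // 20000)]
        centres = np.array([values.min(), values.max()])
        for _ in range(50):
            assign = np.abs(values[:, None] - centres[None, :]).argmin(axis=1)
            new = np.array([values[assign == k].mean() for k in (0, 1)])
            if np.allclose(new, centres):
                break
            centres = new
        within = np.mean([values[assign == k].std() for k in (0, 1)])
        assert abs(centres[1] - centres[0]) > 2.0 * within

    def test_degenerate_shape_rejected(self):
        with pytest.raises(ConfigurationError):
            make_phantom_volume(PhantomSpec(shape=(16, 16, 16)))


class TestSurfaceSlices:
    def test_axis_plane_equals_volume_slice(self, phantom_volume):
        vol = phantom_volume  # 64^3 at 0.5 mm, centred
        k = 40
        offset = (k - (64 - 1) / 2.0) * 0.5
        surf = SliceSurface(order=1, offset=offset)
        (img, truth), = sample_surface_slices(
            vol, [surf], slice_shape=(64, 64), resolution=0.5)
        assert np.array_equal(img.data, vol.data[k])

    def test_tilted_normal_angle(self, phantom_volume):
        surf = SliceSurface(order=1, tilt=(0.0, 10.0, 0.0))
        (_, truth), = sample_surface_slices(
            phantom_volume, [surf], slice_shape=(40, 40), resolution=0.5)
        normal = truth.meta["frame"][:, 2]
        assert abs(np.dot(normal, [1.0, 0.0, 0.0])
                   - np.cos(np.radians(10.0))) < 1e-9

    def test_quadratic_deflection_matches_dense_evaluation(self, phantom_volume):
        coeffs = (0.004, 0.001, 0.002)
        surf = SliceSurface(order=2, coefficients=coeffs)
        shape = (40, 40)
        (img, truth), = sample_surface_slices(
            phantom_volume, [surf], slice_shape=shape, resolution=0.5)
        # z-deflection of truth points along the normal
        normal = truth.meta["frame"][:, 2]
        base = truth.meta["base"]
        z = (truth.points.reshape(-1, 3) - base) @ normal
        # independent dense evaluation of f over the slice extent
        half = (shape[0] - 1) / 2.0 * 0.5
        u = np.linspace(-half, half, 201)
        f = (coeffs[0] * u[:, None] ** 2 + coeffs[1] * u[:, None] * u[None, :]
             + coeffs[2] * u[None, :] ** 2)
        assert abs(np.abs(z).max() - np.abs(f).max()) < 1e-6

    def test_parallel_series_spacing(self, phantom_volume):
        surfs = [SliceSurface(order=1) for _ in range(3)]
        out = sample_surface_slices(phantom_volume, surfs, spacing=5.0,
                                    slice_shape=(40, 40), resolution=0.5)
        for (_, t1), (_, t2) in zip(out, out[1:]):
            sep = t2.points - t1.points
            normal = t1.meta["frame"][:, 2]
            dist = sep.reshape(-1, 3) @ normal
            assert np.abs(dist - 5.0).max() < 1e-9

    def test_surface_outside_volume_rejected(self, phantom_volume):
        with pytest.raises(ConfigurationError, match="exits the volume"):
            sample_surface_slices(phantom_volume,
                                  [SliceSurface(order=1, offset=100.0)],
                                  slice_shape=(40, 40), resolution=0.5)


class TestPerturbPose:
    def test_zero_ranges_identity(self, phantom_volume):
        (_, truth), = sample_surface_slices(
            phantom_volume, [SliceSurface(order=1)],
            slice_shape=(40, 40), resolution=0.5)
        out = perturb_pose(truth.chain, 0.0, 0.0, 0.0, seed=5)
        assert np.array_equal(out.params, truth.chain.params)

    def test_seed_reproducibility(self, phantom_volume):
        (_, truth), = sample_surface_slices(
            phantom_volume, [SliceSurface(order=1)],
            slice_shape=(40, 40), resolution=0.5)
        a = perturb_pose(truth.chain, 5.0, 2.0, 4.0, seed=3)
        b = perturb_pose(truth.chain, 5.0, 2.0, 4.0, seed=3)
        assert np.array_equal(a.params, b.params)

    def test_normal_offset_gives_mre_equal_to_offset(self, phantom_volume):
        (img, truth), = sample_surface_slices(
            phantom_volume, [SliceSurface(order=1)],
            slice_shape=(40, 40), resolution=0.5)
        d = 1.7
        normal = truth.meta["frame"][:, 2]
        shifted = truth.chain.copy()
        shifted.members.append(Translation(d * normal))
        mre = median_registration_error(shifted, truth.points, img.domain)
        assert abs(mre - d) < 1e-9


class TestMRE:
    def test_truth_chain_zero(self, phantom_volume):
        (img, truth), = sample_surface_slices(
            phantom_volume, [SliceSurface(order=1, tilt=(5.0, 3.0, 0.0))],
            slice_shape=(40, 40), resolution=0.5)
        assert median_registration_error(truth.chain, truth.points,
                                         img.domain) < 1e-9

    def test_matches_brute_force(self, phantom_volume, rng):
        (img, truth), = sample_surface_slices(
            phantom_volume, [SliceSurface(order=1)],
            slice_shape=(20, 20), resolution=0.5)
        for _ in range(20):
            chain = perturb_pose(truth.chain, 2.0, 1.0, 1.0,
                                 seed=int(rng.integers(1 << 30)))
            got = median_registration_error(chain, truth.points, img.domain)
            # independent loop implementation
            dists = []
            for i in range(20):
                for j in range(20):
                    px = img.domain.internal.apply(
                        np.array([[float(i), float(j)]]))
                    mapped = chain.apply(px)[0]
                    dists.append(np.sqrt(
                        ((mapped - truth.points[i, j]) ** 2).sum()))
            assert abs(got - float(np.median(dists))) < 1e-9


class TestMCD:
    def test_identical_contours(self, rng):
        c = rng.uniform(-5, 5, (12, 2))
        assert median_contour_distance(c, c) < 1e-12

    def test_parallel_segments(self):
        a = np.array([[0.0, 0.0], [10.0, 0.0]])
        b = np.array([[0.0, 1.5], [10.0, 1.5]])
        assert abs(median_contour_distance(a, b) - 1.5) < 1e-12

    def test_matches_brute_force(self, rng):
        def brute(a, b, step=0.05):
            # independent densify + exact point-to-segment minimum
            seg = np.diff(a, axis=0)
            lengths = np.linalg.norm(seg, axis=1)
            cum = np.concatenate([[0.0], np.cumsum(lengths)])
            n = max(int(np.ceil(cum[-1] / step)) + 1, 2)
            ts = np.linspace(0.0, cum[-1], n)
            pts = np.stack([np.interp(ts, cum, a[:, 0]),
                            np.interp(ts, cum, a[:, 1])], axis=1)
            dists = []
            for p in pts:
                best = np.inf
                for q0, q1 in zip(b[:-1], b[1:]):
                    d = q1 - q0
                    denom = (d**2).sum()
                    t = 0.0 if denom == 0 else np.clip(
                        np.dot(p - q0, d) / denom, 0.0, 1.0)
                    best = min(best, np.sqrt(((p - (q0 + t * d)) ** 2).sum()))
                dists.append(best)
            return float(np.median(dists))

        for _ in range(20):
            a = rng.uniform(-5, 5, (rng.integers(2, 7), 2))
            b = rng.uniform(-5, 5, (rng.integers(2, 7), 2))
            assert abs(median_contour_distance(a, b) - brute(a, b)) < 1e-9

    def test_empty_contour_rejected(self):
        with pytest.raises(Exception):
            median_contour_distance(np.zeros((0, 2)), np.zeros((2, 2)))


class TestBlockAndHistology:
    def test_identity_case_pixel_identical(self, slab_pair):
        slab, _ = slab_pair
        block, hist, _ = make_block_and_histology(
            slab, ((6.0, -15.0), 20.0, 24.0), deformation_amplitude_mm=0.0,
            contrast=None, depth_offset=0.0,
            histology_resolution=float(slab.resolution[0]),
            texture_amplitude=0.0, seed=1)
        assert np.array_equal(block.data, hist.data)

    def test_truth_field_reproduces_warp(self, slab_pair):
        slab, _ = slab_pair
        from scipy.ndimage import map_coordinates

        block, hist, truth = make_block_and_histology(
            slab, ((6.0, -15.0), 20.0, 24.0), deformation_amplitude_mm=0.4,
            contrast=None, histology_resolution=float(slab.resolution[0]),
            texture_amplitude=0.0, seed=4)
        warp = truth.meta["warp"]
        pts = hist.domain.physical_points(external=False)
        target = pts + warp.displacement(pts) + truth.site_centre
        idx = slab.domain.physical_to_index(target, external=False)
        expected = map_coordinates(slab.data, idx.T, order=1,
                                   mode="constant", cval=0.0)
        assert np.abs(expected.reshape(hist.shape) - hist.data).max() < 1e-9

    def test_mind_robust_to_contrast_inversion(self, slab_pair):
        """MIND ranks the contrast-inverted copy as the closer match; raw
        intensity SSD ranks it as the farther one."""
        from histoslice.similarity import descriptor_distance, mind_descriptor

        slab, _ = slab_pair
        block, _, _ = make_block_and_histology(
            slab, ((6.0, -15.0), 20.0, 24.0), deformation_amplitude_mm=0.0,
            contrast=None, histology_resolution=float(slab.resolution[0]),
            texture_amplitude=0.0, seed=5)
        inverted = invert_contrast(block.data)
        shifted = np.roll(block.data, 10, axis=1)  # misaligned same-contrast
        m_block = mind_descriptor(block.data)
        mind_inv = descriptor_distance(m_block, mind_descriptor(inverted))
        mind_shift = descriptor_distance(m_block, mind_descriptor(shifted))
        ssd_inv = float(((block.data - inverted) ** 2).mean())
        ssd_shift = float(((block.data - shifted) ** 2).mean())
        assert mind_inv < mind_shift
        assert ssd_inv > ssd_shift

    def test_rectangle_outside_slab_rejected(self, slab_pair):
        slab, _ = slab_pair
        with pytest.raises(ConfigurationError):
            make_block_and_histology(slab, ((0.0, 0.0), 500.0, 500.0))

    def test_slab_photo_deterministic(self):
        a, _ = make_slab_photo(seed=11)
        b, _ = make_slab_photo(seed=11)
        assert np.array_equal(a.data, b.data)
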