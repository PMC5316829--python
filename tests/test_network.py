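import dataclasses

import numpy as np
import pytest

from tsyslab.network import (DirectionalityHistogram, binarize_tubules, chord_angle_deg,
                             classify_segments, directionality_histogram,
                             longitudinal_radial_profile, score_segment_recovery,
                             skeletonize)
from tsyslab.phantom import PhantomSpec, generate_tsys_volume
from tsyslab.types import VoxelVolume

VS = (90.0, 90.0, 150.0)


class TestBinarize:
    def test_constant_volume_errors(self):
        with pytest.raises(ValueError):
            binarize_tubules(VoxelVolume(np.full((8, 8, 8), 3.0), VS))

    def test_phantom_otsu_within_30_percent(self, small_spec):
        # oracle: voxel count of the phantom truth mask (clean render,
        # threshold falls between background 0 and tubule intensity 1)
        vol, truth = generate_tsys_volume(small_spec)
        mask = binarize_tubules(vol, "otsu")
        measured = mask[truth.fibre_mask].sum() / truth.fibre_mask.sum() * 100
        assert measured == pytest.approx(truth.tubule_volume_fraction, rel=0.30)

    def test_binary_input_idempotent(self):
        rng = np.random.default_rng(0)
        binary = (rng.random((16, 16, 16)) > 0.9).astype(float)
        vol = VoxelVolume(binary, VS)
        assert np.array_equal(binarize_tubules(vol, "otsu"), binary.astype(bool))

    def test_percentile_and_value_methods(self, small_spec):
        vol, _ = generate_tsys_volume(small_spec)
        m1 = binarize_tubules(vol, "percentile:95")
        m2 = binarize_tubules(vol, "value:0.5")
        assert m1.any() and m2.any()

    def test_unknown_method_errors(self, small_spec):
        vol, _ = generate_tsys_volume(small_spec)
        with pytest.raises(ValueError):
            binarize_tubules(vol, "magic")


class TestSkeletonize:
    def test_straight_cylinder_single_central_segment(self):
        # oracle: analytic centreline of the generated cylinder (z=x=16)
        zz, yy, xx = np.indices((32, 64, 32))
        cyl = ((zz - 16) ** 2 + (xx - 16) ** 2) <= 16
        sk = skeletonize(cyl, (90.0, 90.0, 90.0))
        assert len(sk.segments) == 1
        pts_vox = sk.segments[0].points_nm / 90.0 - 0.5
        dev = np.sqrt((pts_vox[:, 0] - 16) ** 2 + (pts_vox[:, 2] - 16) ** 2)
        assert dev.max() < 1.0

    def test_crossing_cylinders_branch_node(self):
        # oracle: brute-force graph degrees near the intersection voxel
        zz, yy, xx = np.indices((32, 64, 32))
        a = ((zz - 16) ** 2 + (xx - 16) ** 2) <= 9
        b = ((zz - 16) ** 2 + (yy - 32) ** 2) <= 9
        sk = skeletonize(a | b, (90.0, 90.0, 90.0))
        assert len(sk.nodes_nm) > 0
        d = np.linalg.norm(sk.nodes_nm / 90.0 - 0.5 - np.array([16, 32, 16]), axis=1)
        assert d.min() < 3.0

    def test_empty_mask_errors(self):
        with pytest.raises(ValueError):
            skeletonize(np.zeros((8, 8, 8), bool), VS)

    def test_skeleton_inside_mask(self, small_spec):
        _, truth = generate_tsys_volume(small_spec)
        mask = truth.tsys_mask
        sk = skeletonize(mask, small_spec.voxel_size)
        assert np.all(mask[tuple(sk.voxels.T)])

    def test_border_mask_flagged(self):
        mask = np.zeros((16, 32, 16), bool)
        mask[8, :, 8] = True  # runs through the y borders
        sk = skeletonize(mask, VS)
        assert sk.provenance["touches_border"]

    def test_component_count_preserved_on_phantom(self, small_spec):
        from scipy import ndimage
        _, truth = generate_tsys_volume(small_spec)
        mask = truth.tsys_mask
        n_mask = ndimage.label(mask, structure=np.ones((3, 3, 3)))[1]
        sk = skeletonize(mask, small_spec.voxel_size)
        skel_grid = np.zeros_like(mask)
        skel_grid[tuple(sk.voxels.T)] = True
        n_skel = ndimage.label(skel_grid, structure=np.ones((3, 3, 3)))[1]
        assert n_skel == n_mask


class TestClassify:
    def _segment_skeleton(self, p0, p1, n=20):
        from tsyslab.network import Skeleton, SkeletonSegment
        pts = np.linspace(p0, p1, n)
        return Skeleton(segments=[SkeletonSegment(points_nm=pts)],
                        nodes_nm=np.empty((0, 3)), voxel_size=VS)

    def test_axial_segment_is_longitudinal_90deg(self):
        sk = classify_segments(self._segment_skeleton([0, 0, 0], [0, 5000, 0]))
        assert sk.segments[0].theta_deg == pytest.approx(90.0)
        assert sk.segments[0].label == "longitudinal"

    def test_in_plane_segment_is_transverse_0deg(self):
        sk = classify_segments(self._segment_skeleton([0, 0, 0], [3000, 0, 4000]))
        assert sk.segments[0].theta_deg == pytest.approx(0.0)
        assert sk.segments[0].label == "transverse"

    def test_exact_45_degrees_is_longitudinal(self):
        sk = classify_segments(self._segment_skeleton([0, 0, 0], [0, 3000, 3000]))
        assert sk.segments[0].theta_deg == pytest.approx(45.0)
        assert sk.segments[0].label == "longitudinal"

    def test_zero_length_segment_dropped_with_warning(self):
        sk = self._segment_skeleton([0, 0, 0], [0, 0, 0])
        with pytest.warns(UserWarning):
            out = classify_segments(sk)
        assert len(out.segments) == 0

    def test_chord_angle_validates(self):
        with pytest.raises(ValueError):
            chord_angle_deg(np.zeros(3))


def _stripes(shape=(128, 128), period=8, axis=0):
    idx = np.indices(shape)[axis]
    return np.sin(2 * np.pi * idx / period)


class TestDirectionality:
    def test_transverse_stripes_concentrate_near_zero(self):
        # stripes along x (intensity varies with y) -> orientation ~0 deg
        h = directionality_histogram(_stripes(axis=0), n_bins=18)
        centres = 0.5 * (h.bin_edges_deg[:-1] + h.bin_edges_deg[1:])
        assert h.percent[centres < 10].sum() >= 80.0

    def test_rotation_moves_mass_to_90(self):
        h = directionality_histogram(np.rot90(_stripes(axis=0)), n_bins=18)
        centres = 0.5 * (h.bin_edges_deg[:-1] + h.bin_edges_deg[1:])
        assert h.percent[centres > 80].sum() >= 80.0

    def test_rotation_equivariance_exact(self):
        img = _stripes(axis=0)
        h0 = directionality_histogram(img, n_bins=18)
        h90 = directionality_histogram(np.rot90(img), n_bins=18)
        assert h0.percent[0] == pytest.approx(h90.percent[-1], abs=1e-9)

    def test_percentages_sum_to_100(self):
        rng = np.random.default_rng(0)
        from scipy import ndimage
        img = ndimage.gaussian_filter(rng.normal(size=(96, 96)), 1.5)
        h = directionality_histogram(img, n_bins=9)
        assert h.percent.sum() == pytest.approx(100.0, abs=1e-6)

    def test_isotropic_noise_no_dominant_bin(self):
        # Monte-Carlo null: no bin above 3x the uniform expectation
        from scipy import ndimage
        n_bins = 9
        for seed in range(10):
            rng = np.random.default_rng(seed)
            img = ndimage.gaussian_filter(rng.normal(size=(128, 128)), 1.5)
            h = directionality_histogram(img, n_bins=n_bins)
            assert h.percent.max() < 3 * 100.0 / n_bins

    def test_constant_image_errors(self):
        with pytest.raises(ValueError):
            directionality_histogram(np.ones((32, 32)))

    def test_too_few_bins_errors(self):
        with pytest.raises(ValueError):
            directionality_histogram(_stripes(), n_bins=3)

    def test_signed_mode_covers_range(self):
        h = directionality_histogram(_stripes(axis=0), n_bins=18, signed=True)
        assert h.bin_edges_deg[0] == -90.0 and h.bin_edges_deg[-1] == 90.0
        assert h.percent.sum() == pytest.approx(100.0, abs=1e-6)

    def test_histogram_sum_invariant_enforced(self):
        with pytest.raises(ValueError):
            DirectionalityHistogram(bin_edges_deg=np.array([0.0, 45.0, 90.0]),
                                    percent=np.array([10.0, 10.0]))


def _classified_skeleton(spec):
    _, truth = generate_tsys_volume(spec)
    sk = skeletonize(truth.tsys_mask, spec.voxel_size)
    return classify_segments(sk), truth


class TestRadialProfile:
    def _profile(self, spec, n_shells=4):
        sk, _ = _classified_skeleton(spec)
        cz = spec.grid_shape[0] / 2 * spec.voxel_size[2]
        cx = spec.grid_shape[2] / 2 * spec.voxel_size[0]
        return longitudinal_radial_profile(sk, (cz, cx),
                                           spec.fibre_radius * 1000.0, n_shells)

    def test_peripheral_bias_recovered(self, small_spec):
        # generative bias k=4 -> outer-quartile density above inner quartile
        spec = dataclasses.replace(small_spec, longitudinal_radial_exponent=4.0)
        _, density = self._profile(spec)
        assert density[-1] > density[0]

    def test_uniform_placement_roughly_flat(self, small_spec):
        # Monte-Carlo null at k=0 over 10 seeds: mean inner vs outer density
        # within a factor 2 (shell volumes already normalized out)
        inner, outer = [], []
        for seed in range(10):
            spec = dataclasses.replace(small_spec, longitudinal_radial_exponent=0.0,
                                       rng_seed=seed)
            _, density = self._profile(spec, n_shells=2)
            inner.append(density[0])
            outer.append(density[1])
        ratio = np.mean(outer) / np.mean(inner)
        assert 0.5 < ratio < 2.0

    def test_no_longitudinal_gives_zero_profile(self):
        from tsyslab.network import Skeleton, SkeletonSegment
        pts = np.array([[0.0, 0.0, 0.0], [1000.0, 0.0, 0.0]])
        seg = SkeletonSegment(points_nm=pts, theta_deg=0.0, label="transverse")
        sk = Skeleton(segments=[seg], nodes_nm=np.empty((0, 3)), voxel_size=VS)
        _, density = longitudinal_radial_profile(sk, (0.0, 0.0), 2000.0)
        assert np.all(density == 0)


class TestRecoveryScoring:
    def test_perfect_recovery_on_clean_truth_mask(self, small_spec):
        sk, truth = _classified_skeleton(small_spec)
        score = score_segment_recovery(truth.centreline_segments, sk)
        assert score["recovered_fraction"] >= 0.95

    def test_unclassified_skeleton_rejected(self, small_spec):
        _, truth = generate_tsys_volume(small_spec)
        sk = skeletonize(truth.tsys_mask, small_spec.voxel_size)
        with pytest.raises(ValueError):
            score_segment_recovery(truth.centreline_segments, sk)
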