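import dataclasses

import numpy as np
import pytest

from tsyslab.calcium import CalibrationParams, calibrate
from tsyslab.phantom import (CompartmentParams, Epoch, NoiseModel, PhantomSpec,
                             SolutionProtocol, generate_bead_stack,
                             generate_tsys_volume, simulate_ca_protocol,
                             simulate_imaging)
from tsyslab.restoration import gaussian_psf, identity_psf
from tsyslab.types import VoxelVolume


class TestPhantomSpec:
    def test_invalid_fraction(self):
        with pytest.raises(ValueError):
            PhantomSpec(target_tsys_volume_fraction=0.0)

    def test_vacuole_axes_vs_fibre(self):
        with pytest.raises(ValueError):
            PhantomSpec(fibre_radius=0.4, vacuole_axes=(0.9, 1.0, 0.9))

    def test_vacuole_axes_vs_tubule_width(self):
        with pytest.raises(ValueError):
            PhantomSpec(vacuole_axes=(0.02, 1.0, 0.9), tubule_width=40.0)


class TestGenerateTsysVolume:
    def test_two_transverse_planes_per_sarcomere(self, small_spec):
        # 5 sarcomeres of 2 um within an 11.5 um fibre -> 10 lattice planes
        spec = dataclasses.replace(small_spec, fibre_length=10.0)
        _, truth = generate_tsys_volume(spec)
        ys = {round(float(pts[0, 1]), 3)
              for pts, label in truth.centreline_segments if label == "transverse"}
        assert len(ys) == 10

    def test_zero_vacuoles_zero_fraction(self, small_spec):
        _, truth = generate_tsys_volume(small_spec)
        assert truth.vacuole_volume_fraction == 0.0
        assert truth.vacuole_count == 0

    def test_target_fraction_hit(self, small_spec):
        # oracle: brute-force voxel count of the rendered tubule mask
        vol, truth = generate_tsys_volume(small_spec)
        n_fibre = truth.fibre_mask.sum()
        n_tub = (truth.tsys_mask & ~truth.vacuole_mask).sum()
        assert truth.tubule_volume_fraction == pytest.approx(100 * n_tub / n_fibre)
        assert abs(truth.tubule_volume_fraction - 1.0) <= 0.1

    def test_fractions_recomputable_exactly(self, small_spec):
        spec = dataclasses.replace(small_spec, vacuole_count=3)
        _, truth = generate_tsys_volume(spec)
        tub, vac = truth.recompute_fractions()
        assert tub == truth.tubule_volume_fraction
        assert vac == truth.vacuole_volume_fraction

    def test_masks_disjoint(self, small_spec):
        spec = dataclasses.replace(small_spec, vacuole_count=3)
        _, truth = generate_tsys_volume(spec)
        tubule = truth.tsys_mask & ~truth.vacuole_mask
        assert not np.any(tubule & truth.vacuole_mask)
        assert np.all(truth.tsys_mask[truth.vacuole_mask])

    def test_reproducibility(self, small_spec):
        v1, t1 = generate_tsys_volume(small_spec)
        v2, t2 = generate_tsys_volume(small_spec)
        assert np.array_equal(v1.data, v2.data)
        assert t1.tubule_volume_fraction == t2.tubule_volume_fraction
        assert len(t1.centreline_segments) == len(t2.centreline_segments)

    def test_different_seeds_differ(self, small_spec):
        v1, _ = generate_tsys_volume(small_spec)
        v2, _ = generate_tsys_volume(dataclasses.replace(small_spec, rng_seed=1))
        assert not np.array_equal(v1.data, v2.data)

    def test_vacuole_count_rendered(self, medium_spec):
        spec = dataclasses.replace(medium_spec, vacuole_count=5)
        _, truth = generate_tsys_volume(spec)
        assert truth.vacuole_count == 5
        assert truth.vacuole_volume_fraction > 0


class TestGenerateBeadStack:
    def test_fifteen_beads_fifteen_maxima(self, small_spec):
        psf = gaussian_psf((150, 150, 250), small_spec.voxel_size)
        stack = generate_bead_stack(15, 100.0, psf, small_spec)
        from scipy import ndimage
        data = stack.data
        maxed = ndimage.maximum_filter(data, size=5, mode="constant")
        peaks = np.argwhere((data == maxed) & (data > data.mean() + 5 * data.std()))
        assert len(peaks) == 15

    def test_single_bead_identity_psf_single_voxel(self, small_spec):
        stack = generate_bead_stack(1, 100.0, identity_psf(small_spec.voxel_size),
                                    small_spec, snap_to_voxel=True)
        assert (stack.data > stack.data.max() / 2).sum() == 1

    def test_known_sigma_fwhm(self, small_spec):
        # oracle: Gaussian FWHM = 2*sqrt(2 ln 2)*sigma
        sigma_nm = (180.0, 180.0, 300.0)
        psf = gaussian_psf(sigma_nm, small_spec.voxel_size)
        stack = generate_bead_stack(5, 100.0, psf, small_spec, snap_to_voxel=True)
        centres = np.asarray(stack.meta["bead_centres_vox"], dtype=int)
        expected_fwhm_vox = 2.3548 * sigma_nm[0] / small_spec.voxel_size[0]
        for c in centres:
            prof = stack.data[c[0], c[1], :].astype(float)
            prof = prof / prof.max()
            assert _fwhm(prof) == pytest.approx(expected_fwhm_vox, rel=0.10)

    def test_too_small_volume_errors(self, small_spec):
        spec = dataclasses.replace(small_spec, grid_shape=(12, 12, 12))
        psf = gaussian_psf((300, 300, 500), spec.voxel_size)
        with pytest.raises(ValueError):
            generate_bead_stack(50, 100.0, psf, spec)

    def test_n_beads_validation(self, small_spec):
        with pytest.raises(ValueError):
            generate_bead_stack(0, 100.0, identity_psf(small_spec.voxel_size), small_spec)


def _fwhm(profile):
    """Sub-sample FWHM by linear interpolation of the half-max crossings."""
    i = int(np.argmax(profile))
    half = 0.5

    def cross(idx_range):
        prev = i
        for j in idx_range:
            if profile[j] < half:
                frac = (profile[prev] - half) / (profile[prev] - profile[j])
                return prev + (j - prev) * frac
            prev = j
        raise AssertionError("no half-max crossing found")

    right = cross(range(i + 1, len(profile)))
    left = cross(range(i - 1, -1, -1))
    return right - left


class TestSimulateImaging:
    def test_identity_no_noise_is_identity(self, small_spec):
        vol, _ = generate_tsys_volume(small_spec)
        out = simulate_imaging(vol, identity_psf(small_spec.voxel_size))
        assert np.array_equal(out.data, vol.data)

    def test_unit_sum_psf_conserves_intensity(self, small_spec):
        vol, _ = generate_tsys_volume(small_spec)
        psf = gaussian_psf((150, 150, 250), small_spec.voxel_size)
        out = simulate_imaging(vol, psf)
        assert out.data.sum() == pytest.approx(vol.data.sum(), rel=1e-12)

    def test_blur_reduces_peak(self, small_spec):
        data = np.zeros((32, 32, 32))
        data[16, 16, 16] = 100.0
        vol = VoxelVolume(data, small_spec.voxel_size)
        out = simulate_imaging(vol, gaussian_psf((150, 150, 250), small_spec.voxel_size))
        assert out.data.max() < vol.data.max()

    def test_oversized_psf_errors(self, small_spec):
        vol = VoxelVolume(np.ones((4, 4, 4)), small_spec.voxel_size)
        psf = gaussian_psf((500, 500, 800), small_spec.voxel_size)
        with pytest.raises(ValueError):
            simulate_imaging(vol, psf)

    def test_noise_reproducible(self, small_spec):
        vol, _ = generate_tsys_volume(small_spec)
        psf = gaussian_psf((150, 150, 250), small_spec.voxel_size)
        nm = NoiseModel(photon_scale=200, read_noise_sd=0.01)
        a = simulate_imaging(vol, psf, nm, rng_seed=7)
        b = simulate_imaging(vol, psf, nm, rng_seed=7)
        assert np.array_equal(a.data, b.data)


class TestSimulateCaProtocol:
    def test_all_rates_zero_constant(self, calib):
        proto = SolutionProtocol([Epoch("a", 20.0, 1.0)])
        params = CompartmentParams(uptake_rate_tt=0, uptake_rate_vac=0,
                                   soce_conductance_tt=0, junction_permeability=0,
                                   leak_rate_tt=0, initial_ca_tt=0.7, initial_ca_vac=0.3)
        _, truth = simulate_ca_protocol(proto, params, calib=calib)
        assert np.allclose(truth["t_system"].ca_mm, 0.7)
        assert np.allclose(truth["vacuole"].ca_mm, 0.3)

    def test_caffeine_depletes_tt_not_vacuole(self, calib):
        proto = SolutionProtocol([Epoch("caff", 100.0, 0.2, caffeine=True)])
        params = CompartmentParams(uptake_rate_tt=0.0, uptake_rate_vac=0.01,
                                   soce_conductance_tt=0.05, junction_permeability=0.0,
                                   leak_rate_tt=0.0, initial_ca_tt=1.0, initial_ca_vac=1.0)
        _, truth = simulate_ca_protocol(proto, params, calib=calib)
        assert np.all(np.diff(truth["t_system"].ca_mm) < 0)
        assert np.all(np.diff(truth["vacuole"].ca_mm) >= 0)

    def test_matches_closed_form_exponential(self, calib):
        # oracle: d ca/dt = a - b*ca with a = u*act(1.3 uM), b = soce + leak
        # -> ca(t) = a/b + (ca0 - a/b) exp(-b t)
        u, soce, leak, ca0 = 0.03, 0.04, 0.01, 0.2
        proto = SolutionProtocol([Epoch("e", 120.0, 1.3, caffeine=True)])
        params = CompartmentParams(uptake_rate_tt=u, uptake_rate_vac=0.0,
                                   soce_conductance_tt=soce, junction_permeability=0.0,
                                   leak_rate_tt=leak, initial_ca_tt=ca0,
                                   activation_kd_um=0.5)
        _, truth = simulate_ca_protocol(proto, params, calib=calib)
        a = u * 1.3 / (0.5 + 1.3)
        b = soce + leak
        t = truth["t_system"].time_s
        expected = a / b + (ca0 - a / b) * np.exp(-b * t)
        assert np.allclose(truth["t_system"].ca_mm, expected, atol=1e-8)

    def test_steady_state_monotone_in_cyto(self, calib):
        params = CompartmentParams(uptake_rate_tt=0.03, leak_rate_tt=0.02)
        values = []
        for cyto in (0.1, 0.3, 0.6, 1.3):
            proto = SolutionProtocol([Epoch("e", 400.0, cyto)])
            _, truth = simulate_ca_protocol(proto, params, calib=calib)
            values.append(truth["t_system"].ca_mm[-1])
        assert np.all(np.diff(values) > 0)

    def test_forward_inverse_consistency(self, calib):
        proto = SolutionProtocol([Epoch("rest", 30.0, 0.028), Epoch("up", 60.0, 1.3)])
        params = CompartmentParams()
        trace, truth = simulate_ca_protocol(proto, params, calib=calib)
        ca = calibrate(trace)
        assert np.allclose(ca.ca_mm, truth["t_system"].ca_mm, atol=1e-9)

    def test_noise_only_on_fluorescence(self, calib):
        proto = SolutionProtocol([Epoch("a", 20.0, 0.5)])
        t1, g1 = simulate_ca_protocol(proto, CompartmentParams(), calib=calib,
                                      rng_seed=1, f_noise_sd=5.0)
        t2, g2 = simulate_ca_protocol(proto, CompartmentParams(), calib=calib,
                                      rng_seed=2, f_noise_sd=5.0)
        assert not np.array_equal(t1.f, t2.f)
        assert np.array_equal(g1["t_system"].ca_mm, g2["t_system"].ca_mm)

    def test_empty_protocol_errors(self):
        with pytest.raises(ValueError):
            SolutionProtocol([])

    def test_negative_rate_errors(self):
        with pytest.raises(ValueError):
            CompartmentParams(uptake_rate_tt=-0.1)

    def test_frame_interval_validation(self, calib):
        proto = SolutionProtocol([Epoch("a", 10.0, 0.5)])
        with pytest.raises(ValueError):
            simulate_ca_protocol(proto, CompartmentParams(), frame_interval=0.0,
                                 calib=calib)

    def test_default_sampling_is_0p8s(self, calib):
        proto = SolutionProtocol([Epoch("a", 8.0, 0.5)])
        trace, _ = simulate_ca_protocol(proto, CompartmentParams(), calib=calib)
        assert np.allclose(np.diff(trace.time_s), 0.8)
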