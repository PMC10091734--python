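"""Reconstruction chain oracles: gridding vs direct DFT, density weights,
coil maps, Roemer combination, phase correction, end-to-end recovery."""

import warnings

import numpy as np
import pytest

import teangio as tg
from teangio.phantom import (
    PhantomConfig,
    RadialTrajectory,
    dft_points,
    make_coil_maps,
    make_phantom,
    radial_trajectory,
    synthesize_kspace,
)
from teangio.recon import (
    GriddingOperator,
    adaptive_kernel_px,
    adjoint_grid,
    density_weights,
    estimate_coil_maps,
    phase_correct,
    roemer_combine,
)
from teangio.signal_model import SignalModelParams, simulate_decoded_timecourse


@pytest.fixture(scope="module")
def small_setup():
    m = 48
    traj = radial_trajectory(76, m, spokes_per_frame=4)
    op = GriddingOperator(traj.points(), m)
    return m, traj, op


class TestGriddingOracle:
    def test_forward_matches_direct_dft(self, small_setup):
        m, traj, op = small_setup
        rng = np.random.default_rng(0)
        img = rng.standard_normal((m, m)) + 1j * rng.standard_normal((m, m))
        exact = dft_points(img, traj.kx, traj.ky).ravel()
        approx = op.forward(img)
        assert np.linalg.norm(approx - exact) / np.linalg.norm(exact) < 1e-3

    def test_adjoint_matches_direct_adjoint_dft(self, small_setup):
        m, traj, op = small_setup
        rng = np.random.default_rng(1)
        pts = traj.points()
        samples = rng.standard_normal(pts.shape[0]) + 1j * rng.standard_normal(
            pts.shape[0]
        )
        x = np.arange(m) - m // 2
        rr, cc = np.meshgrid(x, x, indexing="ij")
        e = np.exp(
            2j
            * np.pi
            * (
                pts[:, 0][:, None] * cc.ravel()[None]
                + pts[:, 1][:, None] * rr.ravel()[None]
            )
        )
        exact = (samples @ e).reshape(m, m)
        approx = op.adjoint(samples)
        assert np.linalg.norm(approx - exact) / np.linalg.norm(exact) < 1e-3

    def test_inner_product_adjoint_identity(self, small_setup):
        m, traj, op = small_setup
        rng = np.random.default_rng(2)
        img = rng.standard_normal((m, m)) + 1j * rng.standard_normal((m, m))
        y = rng.standard_normal(op.n_points) + 1j * rng.standard_normal(op.n_points)
        lhs = np.vdot(y, op.forward(img))
        rhs = np.vdot(op.adjoint(y), img)
        assert abs(lhs - rhs) / abs(lhs) < 1e-8

    def test_center_delta_gives_constant_image(self):
        op = GriddingOperator(np.zeros((1, 2)), 32)
        img = op.adjoint(np.array([1.0 + 0j]))
        assert np.ptp(np.abs(img)) / np.abs(img).mean() < 1e-3

    def test_out_of_range_trajectory_rejected(self):
        with pytest.raises(ValueError, match="0.5"):
            GriddingOperator(np.array([[0.7, 0.0]]), 32)

    def test_disk_reconstruction_accuracy(self):
        """2x angularly oversampled radial adjoint recon of a disk is within
        5% RMSE of the true image."""
        m = 48
        n_spokes = int(np.ceil(np.pi * m))  # 2x the full-sampling count
        traj = radial_trajectory(n_spokes, m, spokes_per_frame=4)
        rr, cc = np.mgrid[0:m, 0:m]
        disk = (np.hypot(rr - m // 2, cc - m // 2) <= 9).astype(float)
        samples = dft_points(disk, traj.kx, traj.ky)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            w = density_weights(traj, m)
        recon = adjoint_grid(samples, traj, w, m)
        recon = recon * (disk.sum() / recon.real.sum())  # arbitrary DCF scale
        rmse = np.sqrt(np.mean(np.abs(recon - disk) ** 2))
        assert rmse < 0.05 * disk.max()


class TestDensityWeights:
    def test_full_radial_gives_ramp(self, small_setup):
        m, traj, op = small_setup
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            w = density_weights(traj, m, operator=op)
        r = np.abs((np.arange(m) - m // 2) / m)
        sel = (r > 0.1) & (r < 0.4)
        ratio = w[:, sel] / r[sel]
        assert ratio.std() / ratio.mean() < 0.05

    def test_cartesian_grid_gives_uniform_weights(self):
        m = 24
        k1 = (np.arange(m) - m // 2) / m
        kx, ky = np.meshgrid(k1, k1)
        traj = RadialTrajectory(
            angles=np.zeros(m), kx=kx, ky=ky, spokes_per_frame=m
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            w = density_weights(traj, m)
        interior = np.hypot(kx, ky) < 0.4
        vals = w[interior]
        assert vals.std() / vals.mean() < 0.05

    def test_spoke_density_scaling(self):
        """Doubling the spoke count leaves the unit-mean-normalized ramp
        unchanged (raw weights halve, i.e. equal up to normalization)."""
        m = 32
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            w1 = density_weights(radial_trajectory(50, m, spokes_per_frame=2), m)
            w2 = density_weights(radial_trajectory(100, m, spokes_per_frame=2), m)
        r = np.abs((np.arange(m) - m // 2) / m)
        sel = (r > 0.1) & (r < 0.4)
        assert np.allclose(w1[:, sel].mean(0), w2[:, sel].mean(0), rtol=0.05)


class TestCoilMaps:
    def test_recovery_of_known_maps(self):
        m = 64
        maps = make_coil_maps(m, 6)
        rng = np.random.default_rng(3)
        truth = 2.0 + rng.standard_normal((m, m)) * 0.2 + 0.3j
        est = estimate_coil_maps(maps * truth, kernel_px=9)
        num = np.abs(np.sum(est.conj() * maps, axis=0))
        den = np.linalg.norm(est, axis=0) * np.linalg.norm(maps, axis=0)
        ang = np.degrees(np.arccos(np.clip(num / den, 0.0, 1.0)))
        assert np.median(ang) < 5.0

    def test_single_coil_gives_unit_map(self):
        est = estimate_coil_maps(np.random.default_rng(0).standard_normal((1, 16, 16)))
        assert np.allclose(est, 1.0)

    def test_kernel_size_rule(self):
        assert adaptive_kernel_px(1.15) == 9
        assert adaptive_kernel_px(0.63) == 16

    def test_unit_norm_per_pixel(self):
        maps = make_coil_maps(32, 4)
        est = estimate_coil_maps(maps * 1.7, kernel_px=7)
        assert np.allclose(np.linalg.norm(est, axis=0), 1.0, atol=1e-10)


class TestRoemerCombine:
    def test_single_coil_identity(self):
        img = np.arange(9.0).reshape(1, 3, 3) + 0j
        assert np.allclose(roemer_combine(img, np.ones((1, 3, 3))), img[0])

    def test_noiseless_recovery_with_true_maps(self):
        m = 32
        maps = make_coil_maps(m, 5)
        unit = maps / np.linalg.norm(maps, axis=0, keepdims=True)
        rng = np.random.default_rng(4)
        truth = rng.standard_normal((m, m)) + 1j * rng.standard_normal((m, m))
        combined = roemer_combine(unit * truth, unit)
        assert np.allclose(combined, truth, atol=1e-10)

    def test_zero_maps_give_zero(self):
        out = roemer_combine(np.ones((2, 4, 4), complex), np.zeros((2, 4, 4)))
        assert np.allclose(out, 0.0)

    def test_combination_reduces_noise(self):
        """Roemer-combined white noise has SD no larger than any single
        coil's (weights are a unit-norm projection)."""
        m = 24
        maps = make_coil_maps(m, 6)
        unit = maps / np.linalg.norm(maps, axis=0, keepdims=True)
        rng = np.random.default_rng(5)
        sds = []
        for _ in range(50):
            noise = rng.standard_normal((6, m, m)) + 1j * rng.standard_normal(
                (6, m, m)
            )
            sds.append(np.std(roemer_combine(noise, unit)))
        assert np.mean(sds) <= 1.45  # per-coil complex SD is sqrt(2)


class TestPhaseCorrection:
    @pytest.fixture()
    def drift_free_kspace(self, seq_protocol, vfa108):
        phantom = make_phantom(PhantomConfig(matrix=48), seed=2)
        traj = radial_trajectory(48, 48)
        return synthesize_kspace(
            phantom, seq_protocol, vfa108, traj, n_coils=3, noise_sd=0.0
        )

    def test_known_global_phase_removed(self, drift_free_kspace):
        import dataclasses

        k = drift_free_kspace
        tampered = k.samples.copy()
        tampered[1:] *= np.exp(1j * 0.3)
        corrected = phase_correct(dataclasses.replace(k, samples=tampered))
        baseline = phase_correct(k)
        assert np.allclose(corrected.samples, baseline.samples, atol=1e-10)

    def test_reference_condition_unchanged(self, drift_free_kspace):
        corrected = phase_correct(drift_free_kspace)
        assert np.allclose(
            corrected.samples[0, 0], drift_free_kspace.samples[0, 0], atol=1e-12
        )

    def test_drift_artifacts_reduced(self, seq_protocol, vfa108):
        """On a drifting acquisition the per-spoke correction lowers the
        subtraction-artifact energy outside the head."""
        phantom = make_phantom(PhantomConfig(matrix=48), seed=2)
        traj = radial_trajectory(48, 48)
        k = synthesize_kspace(
            phantom,
            seq_protocol,
            vfa108,
            traj,
            n_coils=3,
            noise_sd=0.0,
            b0_drift_rate=0.05,
            n_averages=2,
            seed=6,
        )
        rois = tg.corner_noise_rois((48, 48), phantom.brain_mask)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            on = tg.reconstruct_series(k, phase_correction=True)
            off = tg.reconstruct_series(k, phase_correction=False)
        energy_on = np.sum(on.images[:, rois] ** 2)
        energy_off = np.sum(off.images[:, rois] ** 2)
        assert energy_on < 0.5 * energy_off


class TestReconstructSeries:
    @pytest.mark.parametrize("protocol_name", ["seq-ll", "tenc-ll"])
    def test_noiseless_vessel_timecourse_recovery(self, protocol_name):
        """End to end: the reconstructed vessel time-course matches the
        forward signal model (correlation > 0.99), which also pins the
        decoded block-to-timepoint ordering."""
        protocol = tg.build_protocol(protocol_name)
        schedule = tg.vfa_schedule(protocol.n_excitations, np.radians(30.0))
        phantom = make_phantom(
            PhantomConfig(matrix=64, vessel_radius_px=1.5), seed=3
        )
        traj = radial_trajectory(96, 64)
        k = synthesize_kspace(
            phantom, protocol, schedule, traj, n_coils=4, noise_sd=0.0
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            series = tg.reconstruct_series(k)
        assert series.images.shape[0] == 9
        assert np.allclose(series.timepoints, tg.effective_timepoints(protocol))
        for vessel, mask in zip(phantom.vessels, phantom.vessel_images()):
            truth = simulate_decoded_timecourse(
                protocol,
                schedule,
                SignalModelParams(
                    sharpness=vessel.sharpness,
                    time_to_peak=vessel.time_to_peak,
                    arrival_time=vessel.arrival_time,
                ),
            ).decoded
            measured = series.images[:, mask > 0].mean(axis=1)
            assert np.corrcoef(measured, truth)[0, 1] > 0.99

    def test_static_tissue_cancels(self, seq_protocol, vfa108):
        """A vessel-free acquisition decodes to (numerically) nothing
        relative to the static tissue image it contains."""
        phantom = make_phantom(
            PhantomConfig(matrix=48, vessel_amplitude=0.0), seed=4
        )
        traj = radial_trajectory(48, 48)
        k = synthesize_kspace(
            phantom, seq_protocol, vfa108, traj, n_coils=3, noise_sd=0.0
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            series = tg.reconstruct_series(k)
            w = density_weights(k.trajectory, 48)
        tissue_img = np.abs(
            adjoint_grid(k.samples[0, 0, 0], k.trajectory, w, 48)
        ).max()
        assert series.images.max() < 0.01 * tissue_img

    def test_missing_encoding_rejected(self, seq_protocol, vfa108):
        phantom = make_phantom(PhantomConfig(matrix=48), seed=4)
        traj = radial_trajectory(48, 48)
        k = synthesize_kspace(
            phantom, seq_protocol, vfa108, traj, n_coils=2, noise_sd=0.0
        )
        k.samples = k.samples[:1]
        with pytest.raises(ValueError, match="encoding"):
            tg.reconstruct_series(k)
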