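import numpy as np
import pytest

from rosettemrf.trajectory import (
    DegenerateTrajectoryError,
    GradientLimits,
    InvalidParameterError,
    UnsupportedSegmentError,
    check_gradient_feasibility,
    compute_dcf,
    compute_dcf_points,
    generate_rosette,
    load_trajectory,
    response_function,
    save_trajectory,
    split_into_echoes,
)


class TestGenerateRosette:
    def test_origin_at_t0(self, paper_rosette):
        assert paper_rosette.samples[0] == 0

    def test_kmax_never_exceeded(self, paper_rosette):
        assert np.all(np.abs(paper_rosette.samples) <= paper_rosette.kmax * (1 + 1e-12))

    def test_crossing_count_canonical(self, paper_rosette):
        # 23 lobes -> 24 k-space-center crossings including t=0
        assert paper_rosette.n_origin_crossings == 24

    def test_lobe_rotation_approximates_golden_angle(self, paper_rosette):
        assert paper_rosette.lobe_rotation_deg() == pytest.approx(117.39, abs=0.01)

    @pytest.mark.parametrize("bad", [
        dict(kmax=-1.0), dict(w1_cycles=0.0), dict(readout_ms=-5.0),
        dict(dt_us=0.0),
    ])
    def test_invalid_parameters_raise(self, bad):
        kw = dict(kmax=320.0, w1_cycles=11.5, w2_cycles=7.5,
                  readout_ms=18.4, dt_us=2.5)
        kw.update(bad)
        with pytest.raises(InvalidParameterError):
            generate_rosette(**kw)

    def test_crossings_match_envelope_zeros(self, paper_rosette):
        # numeric oracle: count sign changes of the radial envelope
        u = paper_rosette.t_ms / paper_rosette.readout_ms
        env = np.sin(2 * np.pi * paper_rosette.w1_cycles * u)
        zeros = np.sum(np.abs(env) < 1e-9)
        assert zeros == paper_rosette.n_origin_crossings

    def test_roundtrip_io(self, paper_rosette, tmp_path):
        path = str(tmp_path / "traj.h5")
        save_trajectory(path, paper_rosette)
        back = load_trajectory(path)
        assert np.allclose(back.samples, paper_rosette.samples)
        assert back.kmax == paper_rosette.kmax


class TestSplitIntoEchoes:
    def test_canonical_segmentation(self, paper_rosette):
        segs = split_into_echoes(paper_rosette)
        assert len(segs) == 24
        assert sum(s.is_full for s in segs) == 22
        assert not segs[0].is_full and not segs[-1].is_full

    def test_partition_is_exact(self, paper_rosette):
        segs = split_into_echoes(paper_rosette)
        idx = np.concatenate([np.arange(*s.sample_index_range) for s in segs])
        assert np.array_equal(idx, np.arange(paper_rosette.n_samples))

    def test_echo_times_locate_envelope_zeros(self, paper_rosette):
        # numeric oracle: echo n sits at n*T/(2*w1)
        segs = split_into_echoes(paper_rosette)
        expect = np.arange(24) * paper_rosette.readout_ms / 23.0
        got = np.array([s.echo_time_ms for s in segs])
        assert np.allclose(got, expect, atol=1e-9)

    def test_echo_spacing_uniform_within_dwell(self, paper_rosette):
        segs = split_into_echoes(paper_rosette)
        dte = np.diff([s.echo_time_ms for s in segs])
        assert np.ptp(dte) <= paper_rosette.dt_us * 1e-3

    def test_te1_offset_applied(self, paper_rosette):
        segs = split_into_echoes(paper_rosette, te1_ms=1.74)
        assert segs[0].echo_time_ms == pytest.approx(1.74)

    def test_toy_three_lobe_rosette(self):
        traj = generate_rosette(100.0, 1.5, 1.0, 3.0, 5.0)
        segs = split_into_echoes(traj)
        assert len(segs) == 4
        assert sum(s.is_full for s in segs) == 2

    def test_degenerate_trajectory_raises(self):
        traj = generate_rosette(100.0, 0.4, 1.0, 3.0, 5.0)
        with pytest.raises(DegenerateTrajectoryError):
            split_into_echoes(traj)


class TestResponseFunction:
    def test_on_resonance_is_one(self, paper_rosette):
        assert response_function(paper_rosette, 0.0) == pytest.approx(1.0)

    def test_small_offset_against_integral_oracle(self, paper_rosette):
        # unweighted full-readout response must match the closed-form
        # |sinc(f T)| of a uniform time average
        got = response_function(paper_rosette, 1.0, density_weighted=False,
                                full_echoes_only=False)
        t = paper_rosette.t_ms * 1e-3
        oracle = np.abs(np.trapezoid(np.exp(2j * np.pi * 1.0 * t), t)) / (t[-1] - t[0])
        assert got == pytest.approx(oracle, rel=1e-3)
        assert got == pytest.approx(1.0, abs=0.01)

    def test_fat_band_suppressed(self, paper_rosette):
        for f in (220.0, 300.0, 440.0):
            assert response_function(paper_rosette, f) < 0.1

    def test_bounded(self, paper_rosette):
        for f in (0.0, 50.0, 137.0, 220.0):
            assert 0.0 <= response_function(paper_rosette, f) <= 1.0


class TestDCF:
    def test_partial_segment_rejected(self, small_rosette):
        segs = split_into_echoes(small_rosette)
        with pytest.raises(UnsupportedSegmentError):
            compute_dcf(segs[0], small_rosette, 32)

    def test_weights_positive_and_anticorrelate_with_density(self, small_rosette):
        from rosettemrf.nufft import GriddingNUFFT

        segs = split_into_echoes(small_rosette)
        seg = [s for s in segs if s.is_full][0]
        w = compute_dcf(seg, small_rosette, 32, fov_m=0.3)
        assert np.all(w > 0)
        coords = small_rosette.coords[seg.slice()]
        plan = GriddingNUFFT(coords, 32, 0.3)
        dens = np.real(plan.P @ (plan.PH @ np.ones(coords.shape[0], dtype=complex)))
        # denser regions get smaller weights
        assert np.corrcoef(dens, w)[0, 1] < -0.5
        assert w[np.argmax(dens)] < w[np.argmin(dens)]

    def test_gridded_density_flat_after_compensation(self, small_rosette):
        """Compensated sampling density is flat along the sampled band."""
        from rosettemrf.nufft import GriddingNUFFT

        coords = small_rosette.coords
        w = compute_dcf_points(coords, 32, fov_m=0.3)
        plan = GriddingNUFFT(coords, 32, 0.3)
        dens = np.abs(plan.P @ (plan.PH @ w.astype(complex)))
        assert np.std(dens) / np.mean(dens) < 0.1

    def test_uniform_disk_reconstruction_flat(self, rng):
        """Adjoint gridding with DCF of a fully-sampled aggregate recovers a
        uniform disk flat to 10% over the central half-FOV."""
        from rosettemrf.nufft import GriddingNUFFT
        from rosettemrf.operators import default_rotations, _rotated_segment_coords
        from rosettemrf.trajectory import generate_rosette

        n = 32
        traj = generate_rosette(kmax=n / 0.6, w1_cycles=5.5, w2_cycles=3.5,
                                readout_ms=8.0, dt_us=8.0)
        seg = [s for s in split_into_echoes(traj) if s.is_full][2]
        coords = _rotated_segment_coords(traj, seg, default_rotations(80))
        w = compute_dcf_points(coords, n, fov_m=0.3)
        plan = GriddingNUFFT(coords, n, 0.3)
        yy, xx = np.indices((n, n))
        disk = (((yy - n / 2) ** 2 + (xx - n / 2) ** 2) < (0.35 * n) ** 2).astype(float)
        img = np.abs(plan.adjoint(w * plan.forward(disk)))
        # stay two voxels inside the disk edge to avoid Gibbs ringing
        from scipy.ndimage import binary_erosion
        inside = binary_erosion(disk > 0, iterations=2)
        vals = img[inside]
        assert np.all(np.abs(vals - vals.mean()) / vals.mean() < 0.1)

    def test_psf_peaks_at_center(self, small_rosette):
        from rosettemrf.nufft import GriddingNUFFT

        coords = small_rosette.coords
        w = compute_dcf_points(coords, 32, fov_m=0.3)
        plan = GriddingNUFFT(coords, 32, 0.3)
        psf = np.abs(plan.adjoint(w.astype(complex)))
        assert psf.max() == psf[16, 16]


class TestGradientFeasibility:
    def test_linear_ramp_constant_gradient(self):
        traj = generate_rosette(100.0, 1.5, 1.0, 3.0, 5.0)
        traj.samples = np.linspace(0, 100, traj.n_samples) + 0j
        rep = check_gradient_feasibility(traj, GradientLimits(gmax_mT_m=1000.0,
                                                              smax=1.0, smax_units="T/m/s"))
        assert rep.peak_slew_T_m_s == pytest.approx(0.0, abs=1e-6)
        assert rep.gradient_ok

    def test_paper_rosette_report(self, paper_rosette):
        rep = check_gradient_feasibility(paper_rosette, GradientLimits())
        # peak gradient fits the 43 mT/m system limit
        assert rep.gradient_ok
        assert rep.peak_gradient_mT_m < 43.0
        assert isinstance(rep.slew_ok, bool)

    def test_dwell_scaling_law(self, paper_rosette):
        fast = generate_rosette(320.0, 11.5, 7.5, 18.4, 2.5)
        slow = generate_rosette(320.0, 11.5, 7.5, 36.8, 5.0)
        lim = GradientLimits()
        r1 = check_gradient_feasibility(fast, lim)
        r2 = check_gradient_feasibility(slow, lim)
        assert r2.peak_gradient_mT_m == pytest.approx(r1.peak_gradient_mT_m / 2, rel=1e-3)

    def test_too_few_samples(self, paper_rosette):
        traj = generate_rosette(100.0, 1.5, 1.0, 3.0, 5.0)
        traj.samples = traj.samples[:2]
        traj.t_ms = traj.t_ms[:2]
        with pytest.raises(DegenerateTrajectoryError):
            check_gradient_feasibility(traj, GradientLimits())
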