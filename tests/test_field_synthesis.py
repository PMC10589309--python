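"""Field superposition, motion, exposure integration and the fast generator."""

import numpy as np
import pytest

import speckle_precision as sp
from speckle_precision.errors import DomainError, ParameterError

LAM = 0.785


def single_particle_cloud(z):
    return sp.ParticleCloud(
        positions=np.array([[5 * LAM, 5 * LAM, z]]),
        volume_extent=np.full(3, 10 * LAM),
    )


class TestSynthesizeFrame:
    def test_single_particle_inverse_square(self):
        """One on-axis particle: the central pixel intensity is 1/r^2."""
        cloud = single_particle_cloud(5 * LAM)
        sensor = sp.SensorGrid(n_rows=1, n_cols=1, pixel_pitch=5.0, distance=400.0)
        frame = sp.synthesize_frame(cloud, sensor)
        r = 400.0  # distance from the volume centre, where the particle sits
        assert frame[0, 0] == pytest.approx(1.0 / r**2, rel=1e-6)

    def test_half_wave_path_difference_cancels(self):
        """Two nearly equidistant sources lambda/2 apart interfere destructively."""
        z0 = 5 * LAM
        ext = np.full(3, 10 * LAM)
        cloud = sp.ParticleCloud(
            positions=np.array(
                [[5 * LAM, 5 * LAM, z0], [5 * LAM, 5 * LAM, z0 - LAM / 2]]
            ),
            volume_extent=ext,
        )
        sensor = sp.SensorGrid(n_rows=1, n_cols=1, pixel_pitch=5.0, distance=4000.0)
        frame = sp.synthesize_frame(cloud, sensor)
        one_source = 1.0 / 4000.0**2
        assert frame[0, 0] < 1e-5 * one_source

    def test_sensor_through_volume_is_domain_error(self):
        cloud = single_particle_cloud(5 * LAM)
        sensor = sp.SensorGrid(n_rows=1, n_cols=1, pixel_pitch=5.0,
                               distance=2 * LAM)
        with pytest.raises(DomainError):
            sp.synthesize_frame(cloud, sensor)

    def test_fully_developed_statistics(self):
        """Many random scatterers: unit contrast and exponential intensities."""
        cloud = sp.ParticleCloud.uniform_random(n_particles=500, seed=3)
        sensor = sp.design_geometry(
            cloud, target_fwhm_px=2.5, n_rows=64, n_cols=64
        )
        frame = sp.synthesize_frame(cloud, sensor)
        k = frame.std(ddof=1) / frame.mean()
        assert 0.95 <= k <= 1.05
        # exponential distribution: P(I > m) = exp(-1) ~ 0.368, skewness ~ 2
        frac_above_mean = (frame > frame.mean()).mean()
        assert abs(frac_above_mean - np.exp(-1)) < 0.05


class TestAdvance:
    def test_ordered_translation(self, small_cloud):
        motion = sp.MotionModel(kind="ordered", velocity=np.array([1.0, 0, 0]))
        out = sp.advance(small_cloud, motion, dt=2.0,
                         rng=np.random.default_rng(0))
        np.testing.assert_allclose(
            out.positions[:, 0],
            np.mod(small_cloud.positions[:, 0] + 2.0,
                   small_cloud.volume_extent[0]),
        )
        # transverse coordinates untouched for particles that did not wrap
        stayed = small_cloud.positions[:, 0] + 2.0 < small_cloud.volume_extent[0]
        np.testing.assert_array_equal(out.positions[stayed, 2],
                                      small_cloud.positions[stayed, 2])

    def test_zero_diffusion_identity(self, small_cloud):
        motion = sp.MotionModel(kind="unordered", diffusion_coefficient=0.0)
        out = sp.advance(small_cloud, motion, dt=5.0)
        np.testing.assert_array_equal(out.positions, small_cloud.positions)

    def test_diffusion_step_variance(self):
        """Unordered steps have per-axis displacement variance 2*D*dt."""
        # particles at the box centre: no wrap events for these step sizes
        cloud = sp.ParticleCloud(
            positions=np.full((20000, 3), 5e3), volume_extent=[1e4] * 3
        )
        d, dt = 0.05, 2.0
        motion = sp.MotionModel(kind="unordered", diffusion_coefficient=d)
        out = sp.advance(cloud, motion, dt, rng=np.random.default_rng(6))
        disp = out.positions - cloud.positions
        var = disp.var(axis=0)
        np.testing.assert_allclose(var, 2 * d * dt, rtol=0.05)

    def test_ordered_wrap_rerandomises_transverse(self):
        """Particles leaving along the flow re-enter with fresh y, z."""
        ext = np.full(3, 10.0)
        pos = np.tile([9.5, 5.0, 5.0], (50, 1))
        cloud = sp.ParticleCloud(positions=pos, volume_extent=ext)
        motion = sp.MotionModel(kind="ordered", velocity=np.array([1.0, 0, 0]))
        out = sp.advance(cloud, motion, dt=1.0, rng=np.random.default_rng(7))
        assert np.all(out.positions[:, 0] == pytest.approx(0.5))
        assert out.positions[:, 1].std() > 1.0  # no longer all at 5.0


class TestSimulateStack:
    def test_single_frame_matches_synthesize(self, small_cloud):
        sensor = sp.SensorGrid(16, 16, 5.0, 300.0)
        motion = sp.MotionModel(kind="ordered", velocity=np.zeros(3))
        stack = sp.simulate_stack(small_cloud, sensor, motion, 1, 1.0, seed=0)
        np.testing.assert_array_equal(
            stack.frames[0], sp.synthesize_frame(small_cloud, sensor)
        )
        assert stack.exposure_T == 0.0

    def test_seed_determinism(self, small_cloud):
        sensor = sp.SensorGrid(16, 16, 5.0, 300.0)
        motion = sp.MotionModel(kind="unordered", diffusion_coefficient=0.01)
        a = sp.simulate_stack(small_cloud, sensor, motion, 5, 1.0, seed=42)
        b = sp.simulate_stack(small_cloud, sensor, motion, 5, 1.0, seed=42)
        np.testing.assert_array_equal(a.frames, b.frames)

    def test_undersampling_warns(self, small_cloud):
        sensor = sp.SensorGrid(8, 8, 5.0, 300.0)
        motion = sp.MotionModel(kind="ordered", velocity=np.zeros(3))
        with pytest.warns(UserWarning, match="tau_c"):
            sp.simulate_stack(
                small_cloud, sensor, motion, 2, dt=5.0, seed=0, tau_c_hint=20.0
            )


class TestIntegrateExposure:
    def test_identity_and_pair_mean(self):
        frames = np.arange(2 * 4 * 4, dtype=np.float32).reshape(2, 4, 4)
        stack = sp.FrameStack(frames=frames, dt=1.0)
        same = sp.integrate_exposure(stack, 1.0)
        np.testing.assert_array_equal(same.frames, frames)
        pair = sp.integrate_exposure(stack, 2.0)
        assert pair.n_frames == 1
        np.testing.assert_allclose(pair.frames[0], frames.mean(0))
        assert pair.exposure_T == 2.0

    def test_sub_dt_exposure_rejected(self):
        stack = sp.FrameStack(frames=np.ones((4, 4, 4)), dt=2.0)
        with pytest.raises(ParameterError):
            sp.integrate_exposure(stack, 1.0)

    def test_contrast_decreases_with_exposure(self, ordered_system):
        """Longer exposures blur moving speckle: K drops monotonically."""
        _, stream = ordered_system
        tau_c = 20.0
        ks = []
        for x in (0.5, 5.0, 20.0):
            exposures = sp.integrate_exposure(stream, x * tau_c)
            ks.append(sp.global_contrast(exposures))
        assert ks[0] > ks[1] > ks[2]


class TestFastSpeckle:
    def test_fwhm_calibration_roundtrip(self):
        stack = sp.fast_speckle((128, 128), 4.0, 6, seed=2)
        measured = sp.speckle_size_fwhm(stack)
        assert measured == pytest.approx(4.0, rel=0.10)

    def test_beta_sets_contrast(self):
        full = sp.fast_speckle((128, 128), 2.0, 30, beta=1.0, seed=3)
        half = sp.fast_speckle((128, 128), 2.0, 30, beta=0.5, seed=3)
        assert sp.global_contrast(full) == pytest.approx(1.0, abs=0.04)
        assert sp.global_contrast(half) == pytest.approx(2**-0.5, abs=0.04)

    def test_seed_determinism(self):
        a = sp.fast_speckle((64, 64), 3.0, 3, seed=9)
        b = sp.fast_speckle((64, 64), 3.0, 3, seed=9)
        np.testing.assert_array_equal(a.frames, b.frames)

    def test_unreachable_size_rejected(self):
        with pytest.raises(ParameterError):
            sp.fast_speckle((64, 64), 0.4, 1, seed=0)


class TestRescaleSpeckle:
    def test_identity_and_constant(self):
        stack = sp.FrameStack(frames=np.full((2, 8, 8), 3.0), dt=1.0)
        assert sp.rescale_speckle(stack, 1) is stack
        out = sp.rescale_speckle(stack, 2)
        assert out.shape == (4, 4)
        np.testing.assert_allclose(out.frames, 3.0)

    def test_halves_speckle_size(self):
        stack = sp.fast_speckle((200, 200), 5.0, 6, seed=4)
        out = sp.rescale_speckle(stack, 2)
        assert sp.speckle_size_fwhm(out) == pytest.approx(2.5, rel=0.15)

    def test_indivisible_rejected(self):
        stack = sp.FrameStack(frames=np.ones((1, 9, 9)), dt=1.0)
        with pytest.raises(ParameterError):
            sp.rescale_speckle(stack, 2)


class TestUnpolarisedSum:
    def test_identical_channels_keep_contrast(self):
        a = sp.fast_speckle((64, 64), 2.0, 10, seed=5)
        out = sp.unpolarised_sum(a, a)
        assert sp.global_contrast(out) == pytest.approx(
            sp.global_contrast(a), rel=1e-6
        )

    def test_shape_mismatch_rejected(self):
        a = sp.FrameStack(frames=np.ones((1, 8, 8)), dt=1.0)
        b = sp.FrameStack(frames=np.ones((1, 4, 4)), dt=1.0)
        with pytest.raises(ParameterError):
            sp.unpolarised_sum(a, b)

    def test_constant_plus_speckle_mixing(self):
        """Adding a constant channel halves sigma and leaves the mean: K/2."""
        a = sp.fast_speckle((64, 64), 2.0, 10, seed=6)
        const = sp.FrameStack(
            frames=np.full_like(a.frames, a.frames.mean()), dt=a.dt
        )
        out = sp.unpolarised_sum(a, const)
        assert sp.global_contrast(out) == pytest.approx(
            sp.global_contrast(a) / 2, rel=1e-3
        )


def test_tiff_roundtrip(tmp_path):
    stack = sp.fast_speckle((32, 32), 2.0, 3, seed=7)
    path = tmp_path / "stack.tiff"
    stack.to_tiff(path)
    back = sp.FrameStack.from_tiff(path)
    np.testing.assert_allclose(back.frames, stack.frames, rtol=1e-6)
    assert back.units == "normalized"
    assert back.seed_record["seed"] == 7


def test_fast_generator_matches_particle_statistics():
    """Pupil-filtered and particle-superposition speckle agree statistically.

    At matched measured FWHM, global contrast and the 5x5 per-pixel error
    of independent instantaneous frames should be indistinguishable within
    Monte-Carlo error.
    """
    n_frames = 24
    base = sp.ParticleCloud.uniform_random(n_particles=300, seed=50)
    sensor = sp.design_geometry(base, 2.5, n_rows=64, n_cols=64)
    particle_frames = np.stack([
        sp.synthesize_frame(
            sp.ParticleCloud.uniform_random(n_particles=300, seed=51 + i),
            sensor,
        )
        for i in range(n_frames)
    ])
    fast = sp.fast_speckle((64, 64), 2.5, n_frames, seed=52)

    k_particle = sp.global_contrast(particle_frames)
    k_fast = sp.global_contrast(fast)
    assert k_particle == pytest.approx(k_fast, rel=0.05)

    err_particle = sp.per_pixel_error(
        sp.contrast_stack(particle_frames, 5), neighbourhood=5
    ).error_percent
    err_fast = sp.per_pixel_error(
        sp.contrast_stack(fast, 5), neighbourhood=5
    ).error_percent
    assert err_particle == pytest.approx(err_fast, rel=0.15)
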