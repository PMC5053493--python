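"""Pre-processing: reflectivity, retina shape, motion compensation, averaging."""

import numpy as np
import pytest

from mfoct.core import DualChannelVolume
from mfoct import preprocess as pp
from mfoct.phantom import PhantomSpec, control_scene, make_phantom


def _volume_from(sv, sh):
    return DualChannelVolume(sv=np.asarray(sv, dtype=complex),
                             sh=np.asarray(sh, dtype=complex))


class TestComputeReflectivity:
    @pytest.mark.parametrize(
        "sv, sh, expected",
        [(3 + 4j, 0, 25.0), (0, 0, 0.0), (1j, 2, 5.0)],
    )
    def test_modulus_arithmetic(self, sv, sh, expected):
        vol = _volume_from(np.full((2, 2, 2, 1), sv), np.full((2, 2, 2, 1), sh))
        refl = pp.compute_reflectivity(vol)
        assert np.allclose(refl.intensity, expected)

    def test_matches_elementwise_oracle_on_random_volume(self):
        rng = np.random.default_rng(0)
        shape = (4, 3, 2, 2)
        sv = rng.normal(size=shape) + 1j * rng.normal(size=shape)
        sh = rng.normal(size=shape) + 1j * rng.normal(size=shape)
        refl = pp.compute_reflectivity(_volume_from(sv, sh))
        oracle = np.empty(shape)
        for idx in np.ndindex(*shape):
            oracle[idx] = abs(sv[idx]) ** 2 + abs(sh[idx]) ** 2
        assert np.allclose(refl.intensity, oracle, rtol=1e-6)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            _volume_from(np.zeros((2, 2, 2, 1)), np.zeros((2, 2, 2, 2)))

    def test_commutes_with_repeat_averaging_for_identical_repeats(self):
        rng = np.random.default_rng(1)
        base = rng.normal(size=(8, 4, 2, 1)) + 1j * rng.normal(size=(8, 4, 2, 1))
        sv = np.repeat(base, 3, axis=3)
        refl = pp.compute_reflectivity(_volume_from(sv, sv))
        assert np.allclose(refl.intensity.mean(axis=3), refl.intensity[..., 0])


class TestEstimateRetinaShape:
    def test_step_edge(self):
        bscan = np.zeros((200, 4))
        bscan[50:] = 100.0
        assert np.all(pp.estimate_retina_shape(bscan) == 50)

    def test_constant_column_tie_breaks_to_smallest_z(self):
        assert np.all(pp.estimate_retina_shape(np.full((100, 3), 7.0)) == 0)

    def test_all_zero_column_is_missing(self):
        bscan = np.zeros((100, 2))
        bscan[40:, 0] = 5.0
        profile = pp.estimate_retina_shape(bscan)
        assert profile[0] == 40
        assert np.isnan(profile[1])

    def test_recovers_ilm_within_2px_at_snr20(self):
        spec = control_scene((256, 64, 16, 2), motion_amplitude_px=0,
                             curvature_px=2)
        volume, truth = make_phantom(spec, seed=1)
        refl = pp.compute_reflectivity(volume)
        errors = []
        for iy in range(16):
            profile = pp.estimate_retina_shape(refl.intensity[:, :, iy, 0])
            errors.append(profile - truth.surfaces["ilm"][:, iy])
        assert np.nanmean(np.abs(np.concatenate(errors))) <= 2.0


class TestFitRetinaSurface:
    def test_exact_plane_recovered(self):
        x = np.arange(32)[:, None]
        profiles = 100.0 + 0.1 * x * np.ones((1, 8))
        surface = pp.fit_retina_surface(profiles, degree=2)
        assert np.allclose(surface.grid(32, 8), profiles, atol=1e-6)

    def test_outliers_downweighted(self):
        rng = np.random.default_rng(2)
        x = np.arange(40)[:, None]
        clean = 80.0 + 0.2 * x * np.ones((1, 20))
        dirty = clean.copy()
        n_out = int(0.1 * dirty.size)
        flat_idx = rng.choice(dirty.size, n_out, replace=False)
        dirty.ravel()[flat_idx] += 100.0
        fit = pp.fit_retina_surface(dirty, degree=2).grid(40, 20)
        rms = np.sqrt(np.mean((fit - clean) ** 2))
        assert rms <= 2.0

    def test_constant_surface_gives_constant_polynomial(self):
        surface = pp.fit_retina_surface(np.full((10, 10), 55.0), degree=2)
        assert np.allclose(surface.grid(10, 10), 55.0, atol=1e-8)

    def test_insufficient_points_raise(self):
        profiles = np.full((5, 5), np.nan)
        profiles[0, 0] = 1.0
        with pytest.raises(ValueError):
            pp.fit_retina_surface(profiles, degree=2)


class TestMotionCompensation:
    def test_sinusoidal_shifts_recovered(self, processed_control):
        p = processed_control
        residual = p.motion.shifts - p.truth.shifts
        assert np.median(np.abs(residual)) <= 1.0

    def test_flattened_retina_is_flat(self, processed_control):
        p = processed_control
        refl_flat = pp.compute_reflectivity(p.flat)
        medians = []
        for iy in range(refl_flat.shape[2]):
            profile = pp.estimate_retina_shape(refl_flat.intensity[:, :, iy, 0])
            medians.append(np.nanmedian(profile))
        assert max(medians) - min(medians) <= 2.0

    def test_zero_motion_flat_retina_identity_up_to_offset(self):
        spec = PhantomSpec(dims=(224, 32, 8, 2), motion_amplitude_px=0,
                           curvature_px=0, bulk_phase=False)
        volume, _ = make_phantom(spec, seed=0)
        refl = pp.compute_reflectivity(volume)
        motion = pp.build_motion_model(refl)
        assert np.all(motion.shifts == 0)
        flat = pp.compensate_and_flatten(refl, motion)
        offset = motion.target_depth - int(
            round(pp.estimate_retina_shape(refl.intensity[:, :, 0, 0]).mean())
        )
        rolled = np.roll(refl.intensity, offset, axis=0)
        core = slice(abs(offset) + 2, 224 - abs(offset) - 2)
        assert np.allclose(flat.intensity[core], rolled[core])

    def test_flattening_is_shift_equivariant(self):
        """A constant axial offset of the input moves the recorded target
        depth, not the flattened content."""
        spec = PhantomSpec(dims=(224, 32, 8, 2), motion_amplitude_px=0,
                           curvature_px=2, bulk_phase=False)
        volume, _ = make_phantom(spec, seed=4)
        refl = pp.compute_reflectivity(volume)
        shifted = pp.ReflectivityVolume(
            intensity=np.roll(refl.intensity, 10, axis=0)
        )
        m1 = pp.build_motion_model(refl)
        m2 = pp.build_motion_model(shifted)
        assert m2.target_depth - m1.target_depth == 10
        f1 = pp.compensate_and_flatten(refl, m1).intensity
        f2 = pp.compensate_and_flatten(shifted, m2).intensity
        # content is unchanged relative to the (shifted) target depth
        core = slice(20, 200)
        assert np.allclose(np.roll(f2, -10, axis=0)[core], f1[core])


class TestAverageRepeats:
    def _refl(self, arr):
        return pp.ReflectivityVolume(intensity=np.asarray(arr, dtype=float))

    def test_identical_repeats_average_to_single_repeat(self):
        rng = np.random.default_rng(0)
        one = rng.random((16, 8, 2, 1))
        stack = np.repeat(one, 5, axis=3)
        out = pp.average_repeats(self._refl(stack), register=False)
        assert np.allclose(out.intensity, one[..., 0])

    def test_single_repeat_passthrough(self):
        one = np.random.default_rng(1).random((16, 8, 2, 1))
        out = pp.average_repeats(self._refl(one), register=False)
        assert np.allclose(out.intensity, one[..., 0])

    def test_noise_variance_reduced_by_repeat_count(self):
        """i.i.d. additive noise σ on a static scene, 5 repeats → residual
        variance ≈ σ²/5 (Monte Carlo, within 20%)."""
        rng = np.random.default_rng(2)
        sigma = 0.3
        scene = 5.0 + np.zeros((64, 64, 4, 1))
        noisy = scene + sigma * rng.standard_normal((64, 64, 4, 5))
        out = pp.average_repeats(self._refl(noisy), register=False)
        resid_var = np.var(out.intensity - scene[..., 0])
        assert resid_var == pytest.approx(sigma**2 / 5, rel=0.2)

    def test_all_repeats_excluded_marks_bscan_missing(self):
        arr = np.ones((8, 4, 2, 3))
        exclude = np.zeros((2, 3), dtype=bool)
        exclude[1] = True
        out = pp.average_repeats(self._refl(arr), register=False, exclude=exclude)
        assert np.isnan(out.intensity[:, :, 1]).all()
        assert out.meta["missing_bscans"] == [1]
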