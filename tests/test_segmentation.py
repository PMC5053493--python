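"""Layer segmentation: cost images, shortest paths, full-surface recovery."""


import numpy as np
import pytest

from mfoct.core import SURFACE_NAMES, SurfaceSet
from mfoct import segmentation as seg


def exhaustive_min_path(cost, max_step):
    """Enumerate every monotone left-to-right path (oracle for small images)."""
    nz, nx = cost.shape
    best_cost, best_path = np.inf, None
    for start in range(nz):
        stack = [(cost[start, 0], [start])]
        while stack:
            total, path = stack.pop()
            if len(path) == nx:
                if total < best_cost - 1e-12:
                    best_cost, best_path = total, path
                continue
            z = path[-1]
            for dz in range(-max_step, max_step + 1):
                nzz = z + dz
                if 0 <= nzz < nz:
                    stack.append((total + cost[nzz, len(path)], path + [nzz]))
    return best_cost, best_path


class TestBoundaryCost:
    def test_step_edge_minimum_at_edge_row(self):
        img = np.zeros((100, 16))
        img[50:] = 10.0
        cost = seg.boundary_cost(img, "dark_to_bright")
        assert np.all(np.argmin(cost, axis=0) == 50)

    def test_inverted_step_has_no_minimum_for_same_polarity(self):
        img = np.zeros((100, 16))
        img[:50] = 10.0
        cost = seg.boundary_cost(img, "dark_to_bright")
        assert cost[50].min() >= 0.5

    def test_bright_to_dark_polarity(self):
        img = np.zeros((100, 16))
        img[:50] = 10.0
        cost = seg.boundary_cost(img, "bright_to_dark")
        assert np.all(np.argmin(cost, axis=0) == 50)

    def test_cost_bounded_on_random_input(self):
        rng = np.random.default_rng(0)
        for scale in ("linear", "log"):
            cost = seg.boundary_cost(rng.random((64, 32)) + 0.01,
                                     "dark_to_bright", scale=scale)
            assert cost.min() >= 1e-3 - 1e-12
            assert cost.max() <= 1.0

    def test_unknown_polarity_rejected(self):
        with pytest.raises(ValueError):
            seg.boundary_cost(np.ones((4, 4)), "sideways")


class TestSegmentBoundary:
    def test_noiseless_two_layer_interface_found_exactly(self):
        img = np.zeros((60, 40))
        img[25:] = 5.0
        cost = seg.boundary_cost(img, "dark_to_bright")
        assert np.all(seg.segment_boundary(cost) == 25)

    def test_constant_cost_returns_flat_path_at_smallest_z(self):
        path = seg.segment_boundary(np.ones((20, 15)))
        assert np.all(path == 0)

    def test_band_confines_path(self):
        img = np.zeros((60, 10))
        img[25:] = 5.0
        cost = seg.boundary_cost(img, "dark_to_bright")
        path = seg.segment_boundary(cost, band=(np.full(10, 30), np.full(10, 50)))
        assert np.all(path >= 30) and np.all(path < 50)

    def test_empty_band_rejected(self):
        with pytest.raises(seg.InfeasibleBandError):
            seg.segment_boundary(np.ones((20, 5)), band=(10, 10))

    def test_monte_carlo_noise_keeps_mean_error_below_1px(self):
        rng = np.random.default_rng(1)
        errors = []
        for _ in range(100):
            img = np.zeros((40, 30))
            img[18:] = 5.0
            img += rng.normal(0, 0.5, size=img.shape)   # σ = 10% of contrast
            cost = seg.boundary_cost(img, "dark_to_bright")
            errors.append(np.abs(seg.segment_boundary(cost) - 18).mean())
        assert np.mean(errors) < 1.0

    @pytest.mark.parametrize("trial", range(10))
    def test_matches_exhaustive_enumeration_on_small_images(self, trial):
        rng = np.random.default_rng(100 + trial)
        nz, nx = rng.integers(3, 9), rng.integers(3, 9)
        cost = rng.random((nz, nx))
        for max_step in (1, 2, 3):
            path = seg.segment_boundary(cost, max_step=max_step)
            total = cost[path, np.arange(nx)].sum()
            oracle_cost, _ = exhaustive_min_path(cost, max_step)
            assert total == pytest.approx(oracle_cost, abs=1e-10)

    def test_intensity_scale_invariance(self):
        rng = np.random.default_rng(7)
        img = rng.random((50, 25)) + 0.05
        img[30:] += 3.0
        c1 = seg.boundary_cost(img, "dark_to_bright")
        c2 = seg.boundary_cost(4.2 * img, "dark_to_bright")
        assert np.array_equal(seg.segment_boundary(c1), seg.segment_boundary(c2))


class TestSegmentAllLayers:
    def test_recovers_all_surfaces_within_2px_at_snr20(self, processed_control):
        p = processed_control
        for name in SURFACE_NAMES:
            err = p.surfaces[name] - p.true_surface(name)
            assert np.sqrt(np.mean(err**2)) <= 2.0, name

    def test_ordering_invariant_everywhere(self, processed_control):
        assert not processed_control.surfaces.ordering_violations().any()

    def test_noiseless_phantom_recovered_within_1px(self):
        from mfoct.phantom import control_scene, make_phantom
        from mfoct import preprocess as pp

        spec = control_scene((256, 64, 16, 2), snr_db=np.inf,
                             motion_amplitude_px=0, curvature_px=2,
                             bulk_phase=False)
        volume, truth = make_phantom(spec, seed=0)
        averaged = pp.average_repeats(pp.compute_reflectivity(volume),
                                      register=False)
        surfaces = seg.segment_all_layers(averaged.intensity)
        for name in SURFACE_NAMES:
            err = surfaces[name] - truth.surfaces[name]
            assert np.abs(err).max() <= 1.0, name


class TestRefine3d:
    def _smooth_set(self):
        nx, ny = 20, 30
        base = {}
        for k, name in enumerate(SURFACE_NAMES):
            base[name] = np.full((nx, ny), 40.0 + 20 * k)
        return SurfaceSet(surfaces=base)

    def test_single_bscan_spike_removed(self):
        surfaces = self._smooth_set()
        surfaces.surfaces["rpe"][:, 12] += 20.0
        out = seg.refine_3d(surfaces)
        assert np.abs(out["rpe"][:, 12] - 120.0).max() <= 2.0
        assert out.interpolated["rpe"][:, 12].all()

    def test_smooth_surfaces_are_a_fixed_point(self):
        surfaces = self._smooth_set()
        out = seg.refine_3d(surfaces)
        for name in SURFACE_NAMES:
            assert np.abs(out[name] - surfaces[name]).max() <= 1.0

    def test_ordering_violations_projected_out(self):
        surfaces = self._smooth_set()
        surfaces.surfaces["ipl_inl"][:, 5] = 200.0   # far below the RPE
        out = seg.refine_3d(surfaces, max_dev=1e9)   # keep the outlier
        assert not out.ordering_violations().any()


class TestReferenceSurface:
    def test_flat_midline(self):
        rpe = np.full((30, 30), 200.0)
        ch = np.full((30, 30), 260.0)
        assert np.allclose(seg.fit_reference_surface(rpe, ch), 230.0)

    def test_lesion_bump_ignored(self):
        rng = np.random.default_rng(0)
        rpe = np.full((40, 40), 200.0)
        ch = np.full((40, 40), 260.0)
        bump = rng.random((40, 40)) < 0.05
        rpe_dirty = rpe - bump * 30.0                # lesion pushes RPE up
        ref = seg.fit_reference_surface(rpe_dirty, ch)
        assert np.abs(ref - 230.0).max() < 3.0

    def test_clamped_between_surfaces(self):
        rng = np.random.default_rng(1)
        rpe = 200.0 + rng.random((20, 20))
        ch = rpe + 2.0
        ref = seg.fit_reference_surface(rpe, ch)
        assert np.all(ref >= rpe) and np.all(ref <= ch)

    def test_insufficient_support_rejected(self):
        rpe = np.full((10, 10), np.nan)
        rpe[:2] = 100.0
        with pytest.raises(ValueError):
            seg.fit_reference_surface(rpe, rpe + 50)
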