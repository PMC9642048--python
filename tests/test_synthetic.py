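"""Simulator physics, surrogate scorer behaviour, and pick evaluation."""

import numpy as np
import pytest

from helipick.helix_geometry import FilamentTrace
from helipick.star_io import MicrographImage
from helipick.synthetic import (
    GroundTruth,
    SimulationSpec,
    evaluate_picks,
    simulate_micrograph,
    surrogate_score_map,
)


class TestSimulationSpec:
    def test_ribbon_forces_constant_width(self):
        spec = SimulationSpec(phenotype="ribbon", width_min_A=70, width_max_A=140)
        assert spec.width_min_A == spec.width_max_A == 140

    def test_invalid_widths_rejected(self):
        with pytest.raises(ValueError):
            SimulationSpec(width_min_A=200, width_max_A=100)

    def test_unknown_phenotype_rejected(self):
        with pytest.raises(ValueError):
            SimulationSpec(phenotype="wiggly")

    def test_negative_noise_rejected(self):
        with pytest.raises(ValueError):
            SimulationSpec(noise_sigma=-0.1)


class TestSimulateMicrograph:
    def test_bit_reproducible(self):
        spec = SimulationSpec(noise_sigma=0.4, rng_seed=11)
        mic1, truth1 = simulate_micrograph(spec)
        mic2, truth2 = simulate_micrograph(SimulationSpec(noise_sigma=0.4, rng_seed=11))
        np.testing.assert_array_equal(mic1.values, mic2.values)
        for p1, p2 in zip(truth1.polylines, truth2.polylines):
            np.testing.assert_array_equal(p1, p2)

    def test_noiseless_minimum_on_centreline_background_flat(self):
        spec = SimulationSpec(
            noise_sigma=0.0, n_filaments=1, curvature_max=0.0, rng_seed=3
        )
        mic, truth = simulate_micrograph(spec)
        iy, ix = np.unravel_index(np.argmin(mic.values), mic.values.shape)
        poly = truth.polylines[0]
        d = np.min(np.hypot(poly[:, 0] - ix, poly[:, 1] - iy))
        assert d <= 2.0
        # background far from the filament is exactly at background level
        far = np.ones(mic.values.shape, bool)
        yy, xx = np.mgrid[0:1024, 0:1024]
        for x, y in poly[::10]:
            far &= np.hypot(xx - x, yy - y) > 300
        if far.any():
            assert (mic.values[far] == 0.0).all()

    def test_polylines_within_bounds(self):
        spec = SimulationSpec(noise_sigma=0.2, rng_seed=5)
        mic, truth = simulate_micrograph(spec)
        h, w = spec.image_shape
        for poly in truth.polylines:
            assert (poly[:, 0] >= 0).all() and (poly[:, 0] <= w - 1).all()
            assert (poly[:, 1] >= 0).all() and (poly[:, 1] <= h - 1).all()

    def test_width_alternation_period_is_half_crossover(self):
        """Crossover 720 A -> depth (and width) modulation period 360 A."""
        spec = SimulationSpec(
            noise_sigma=0.0, n_filaments=1, curvature_max=0.0,
            crossover_A=720.0, rng_seed=1,
        )
        mic, truth = simulate_micrograph(spec)
        poly = truth.polylines[0]
        seg = np.hypot(*np.diff(poly, axis=0).T)
        s_A = np.concatenate([[0.0], np.cumsum(seg)]) * spec.pixel_size_A
        iy = np.clip(np.round(poly[:, 1]).astype(int), 0, 1023)
        ix = np.clip(np.round(poly[:, 0]).astype(int), 0, 1023)
        depth = -mic.values[iy, ix]
        # period of the depth profile from the spacing of its maxima
        from scipy.signal import find_peaks

        grid = np.arange(0.0, s_A[-1], 4.0)
        prof = np.interp(grid, s_A, depth)
        peaks, _ = find_peaks(prof, distance=int(200.0 / 4.0))
        spacings = np.diff(grid[peaks])
        assert np.median(spacings) == pytest.approx(360.0, rel=0.05)

    def test_ribbon_width_constant_along_axis(self):
        """Measured width variance along a ribbon < 1% of the mean width."""
        spec = SimulationSpec(
            phenotype="ribbon", noise_sigma=0.0, n_filaments=1,
            curvature_max=0.0, rng_seed=2,
        )
        mic, truth = simulate_micrograph(spec)
        poly = truth.polylines[0]
        p0, p1 = poly[0], poly[-1]
        u = (p1 - p0) / np.linalg.norm(p1 - p0)
        n = np.array([-u[1], u[0]])
        widths = []
        for frac in np.linspace(0.2, 0.8, 25):
            c = p0 + frac * (p1 - p0)
            offsets = np.linspace(-80, 80, 321)
            pts = c + offsets[:, None] * n
            ix = np.clip(np.round(pts[:, 0]).astype(int), 0, 1023)
            iy = np.clip(np.round(pts[:, 1]).astype(int), 0, 1023)
            profile = -mic.values[iy, ix]
            # second-moment width of the cross profile
            m0 = profile.sum()
            mu = (offsets * profile).sum() / m0
            var = ((offsets - mu) ** 2 * profile).sum() / m0
            widths.append(np.sqrt(var))
        widths = np.array(widths)
        assert widths.std() < 0.01 * widths.mean()


class TestSurrogateScoreMap:
    def test_blank_image_all_zero(self):
        mic = MicrographImage(np.zeros((256, 256)), pixel_size_A=2.0)
        sm = surrogate_score_map(mic, 120.0)
        assert (sm.values == 0.0).all()

    def test_argmax_on_centreline_noiseless(self):
        spec = SimulationSpec(
            noise_sigma=0.0, n_filaments=1, curvature_max=0.0, rng_seed=4
        )
        mic, truth = simulate_micrograph(spec)
        sm = surrogate_score_map(mic, 120.0)
        iy, ix = np.unravel_index(np.argmax(sm.values), sm.values.shape)
        x_mic = (ix + 0.5) * 4 - 0.5
        y_mic = (iy + 0.5) * 4 - 0.5
        poly = truth.polylines[0]
        d_ds = np.min(np.hypot(poly[:, 0] - x_mic, poly[:, 1] - y_mic)) / 4
        assert d_ds <= 1.0

    def test_on_centreline_scores_exceed_background(self):
        """With noise at SNR ~ 2 the centreline outshines the background."""
        spec = SimulationSpec(noise_sigma=0.5, rng_seed=6)
        mic, truth = simulate_micrograph(spec)
        sm = surrogate_score_map(mic, 120.0)
        on = []
        for poly in truth.polylines:
            ds = (poly + 0.5) / 4 - 0.5
            iy = np.clip(np.round(ds[:, 1]).astype(int), 0, sm.shape[0] - 1)
            ix = np.clip(np.round(ds[:, 0]).astype(int), 0, sm.shape[1] - 1)
            on.append(sm.values[iy, ix])
        on = np.concatenate(on)
        assert on.mean() > np.median(sm.values) + 5 * sm.values.std() / 5
        assert on.mean() > 1.0  # in pixel-noise units

    def test_width_below_pixel_warns_and_clamps(self):
        mic = MicrographImage(np.random.default_rng(0).normal(size=(64, 64)),
                              pixel_size_A=2.0)
        with pytest.warns(UserWarning, match="clamp"):
            surrogate_score_map(mic, 1.0, downsample_factor=4)

    def test_invalid_arguments(self):
        mic = MicrographImage(np.zeros((16, 16)))
        with pytest.raises(ValueError):
            surrogate_score_map(mic, -5.0)
        with pytest.raises(ValueError):
            surrogate_score_map(mic, 100.0, downsample_factor=0)


class TestEvaluatePicks:
    def straight_truth(self, *lines):
        polys = [
            np.column_stack([np.linspace(x1, x2, 200), np.linspace(y1, y2, 200)])
            for (x1, y1, x2, y2) in lines
        ]
        return GroundTruth(
            polylines=polys, filament_ids=list(range(1, len(polys) + 1)),
            params=[{} for _ in polys], pixel_size_A=1.0, image_shape=(512, 512),
        )

    def test_perfect_picks(self):
        truth = self.straight_truth((10, 10, 400, 10))
        traces = [FilamentTrace(10, 10, 400, 10, 1)]
        m = evaluate_picks(traces, truth, dist_tol_px=5, angle_tol_deg=5)
        assert m.precision == 1.0
        assert m.coverage == pytest.approx(1.0)
        assert m.recall_by_length == 1.0

    def test_empty_picks_convention(self):
        truth = self.straight_truth((10, 10, 400, 10))
        m = evaluate_picks([], truth, dist_tol_px=5, angle_tol_deg=5)
        assert m.precision == 1.0
        assert m.coverage == 0.0

    def test_partial_coverage_arithmetic(self):
        """Two filaments, picks covering only the first: coverage is
        l1 / (l1 + l2)."""
        truth = self.straight_truth((0, 10, 300, 10), (0, 100, 100, 100))
        traces = [FilamentTrace(0, 10, 300, 10, 1)]
        m = evaluate_picks(traces, truth, dist_tol_px=5, angle_tol_deg=5)
        assert m.coverage == pytest.approx(300.0 / 400.0, rel=1e-3)
        assert m.recall_by_length == pytest.approx(0.5)

    def test_wrong_angle_is_false_positive(self):
        truth = self.straight_truth((0, 10, 300, 10))
        traces = [FilamentTrace(0, 10, 290, 60, 1)]  # ~10 deg off, near line
        m = evaluate_picks(traces, truth, dist_tol_px=60, angle_tol_deg=5)
        assert m.precision == 0.0
        assert m.coverage == 0.0

    def test_empty_truth_rejected(self):
        truth = GroundTruth(polylines=[], filament_ids=[], params=[],
                            pixel_size_A=1.0, image_shape=(64, 64))
        with pytest.raises(ValueError):
            evaluate_picks([], truth, 5, 5)

    def test_invalid_tolerances_rejected(self):
        truth = self.straight_truth((0, 0, 10, 0))
        with pytest.raises(ValueError):
            evaluate_picks([], truth, -1, 5)
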