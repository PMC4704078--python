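"""EMC core: E/M formulas against brute-force Poisson oracles, round trips,
convergence behaviour and the gauge structure."""

import numpy as np
import pytest

from emcryst.emc import (
    EMCModel,
    IntensityModel,
    ProbabilityMatrix,
    SliceSet,
    compress,
    compute_probabilities,
    emc_iterate,
    expand,
    extend_resolution,
    maximize,
    rescale_to_photon_count,
    seed_intensity,
)
from emcryst.frames import FrameSet, SparseFrame
from emcryst.geometry import ReciprocalGrid, RotationSet, build_pixel_map
from emcryst.lattice import lattice_points_in_sphere
from emcryst.validate import assemble_reference, orientation_errors


def toy_frameset(pixel_counts, n_pixels=2):
    """Frames from a list of per-frame dense count vectors."""
    frames = []
    for counts in pixel_counts:
        counts = np.asarray(counts, dtype=float)
        nz = np.flatnonzero(counts)
        frames.append(SparseFrame(nz, counts[nz]) if nz.size else
                      SparseFrame(np.empty(0, int), np.empty(0)))
    return FrameSet.from_frames(frames, n_detector_pixels=n_pixels)


class TestProbabilities:
    def test_two_by_two_matches_poisson_oracle(self):
        W = np.array([[2.0, 0.1], [0.1, 2.0]])
        frames = toy_frameset([[3, 0]])
        P = compute_probabilities(SliceSet(W, np.array([0, 1])), frames)
        # brute force: P_j ~ prod_i W_ij^K_i exp(-W_ij)
        lik = np.array([
            W[0, 0] ** 3 * np.exp(-W[0].sum()),
            W[1, 0] ** 3 * np.exp(-W[1].sum()),
        ])
        expected = lik / lik.sum()
        assert np.allclose(P.P[:, 0], expected, rtol=1e-12, atol=1e-15)
        # evidence includes the uniform prior 1/J
        assert P.frame_log_evidence[0] == pytest.approx(np.log(lik.sum() / 2), rel=1e-12)

    def test_single_rotation_gives_certainty(self):
        W = np.array([[1.0, 2.0]])
        P = compute_probabilities(SliceSet(W, np.array([0, 1])), toy_frameset([[1, 0], [0, 2]]))
        assert np.allclose(P.P, 1.0)

    def test_zero_photon_frame_with_equal_totals_is_uniform(self):
        W = np.array([[2.0, 1.0], [1.5, 1.5], [0.5, 2.5]])
        P = compute_probabilities(SliceSet(W, np.array([0, 1])), toy_frameset([[0, 0]]))
        assert np.allclose(P.P[:, 0], 1.0 / 3.0, rtol=1e-12)

    def test_columns_normalized_tightly(self, emc_fit):
        colsums = emc_fit.probabilities.P.sum(axis=0)
        assert np.abs(colsums - 1.0).max() < 1e-9
        assert emc_fit.probabilities.P.min() >= 0

    def test_photon_on_unknown_pixel_rejected(self):
        W = np.array([[1.0]])
        frames = toy_frameset([[0, 2]])
        with pytest.raises(ValueError, match="outside the usable map"):
            compute_probabilities(SliceSet(W, np.array([0])), frames)


class TestMaximize:
    def test_two_by_two_matches_weighted_mean_oracle(self):
        frames = toy_frameset([[3, 0], [0, 2]])
        P = ProbabilityMatrix(np.array([[0.7, 0.2], [0.3, 0.8]]))
        out = maximize(P, frames, np.array([0, 1]))
        K = np.array([[3.0, 0.0], [0.0, 2.0]])  # frame x pixel
        for j in range(2):
            expected = (P.P[j] @ K) / P.P[j].sum()
            assert np.allclose(out.values[j], expected, rtol=1e-12)

    def test_uniform_probabilities_give_global_mean(self):
        frames = toy_frameset([[4, 0], [0, 2], [1, 1]])
        P = ProbabilityMatrix(np.full((5, 3), 1.0 / 5))
        out = maximize(P, frames, np.array([0, 1]))
        assert np.allclose(out.values, [[5 / 3, 1.0]] * 5, rtol=1e-12)

    def test_one_hot_rows_are_per_rotation_means(self):
        frames = toy_frameset([[4, 0], [2, 2]])
        P = ProbabilityMatrix(np.array([[1.0, 0.0], [0.0, 1.0], [0.0, 0.0]]))
        out = maximize(P, frames, np.array([0, 1]))
        assert np.allclose(out.values[0], [4, 0])
        assert np.allclose(out.values[1], [2, 2])
        assert not out.defined[2].any()  # no probability weight -> undefined

    def test_empty_frameset_rejected(self):
        fs = FrameSet(np.zeros(1, np.int64), np.empty(0, np.int64), np.empty(0), 4)
        with pytest.raises(ValueError):
            maximize(ProbabilityMatrix(np.ones((2, 0))), fs, np.array([0, 1]))


class TestExpandCompress:
    def test_expand_constant_model(self, geom, rotations, grid):
        pm = build_pixel_map(geom, rotations, grid)
        model = IntensityModel(np.full(grid.shape, 3.25), grid)
        sl = expand(model, pm)
        assert np.allclose(sl.values, 3.25, rtol=1e-6)

    def test_expand_grid_mismatch_rejected(self, geom, rotations, grid):
        pm = build_pixel_map(geom, rotations, grid)
        other = ReciprocalGrid(grid.voxel_size * 2, grid.extent)
        with pytest.raises(ValueError):
            expand(IntensityModel(np.zeros(other.shape), other), pm)

    def test_compress_constant_slices(self, geom, rotations, grid):
        pm = build_pixel_map(geom, rotations, grid)
        sl = SliceSet(np.full((rotations.count, pm.n_pixels), 2.5), pm.pixel_ids)
        out = compress(sl, pm, grid)
        obs = out.observed_mask()
        assert obs.any()
        assert np.allclose(out.values[obs], 2.5, rtol=1e-6)
        assert np.all(out.values[~obs] == 0)

    def test_single_slice_entry_lands_in_eight_voxels(self, geom, grid):
        rot = RotationSet.uniform(1)
        pm = build_pixel_map(geom, rot, grid)
        vals = np.zeros((1, pm.n_pixels))
        vals[0, pm.n_pixels // 3] = 7.0
        out = compress(SliceSet(vals, pm.pixel_ids), pm, grid)
        assert 1 <= np.count_nonzero(out.values) <= 8

    def test_round_trip_on_smooth_model(self, truth, geom, rotations, grid):
        # expand(compress(expand(M))) vs expand(M): relative RMS < 5%
        pm = build_pixel_map(geom, rotations, grid)
        smooth = IntensityModel(truth.background_map + 0.1, grid)
        sl = expand(smooth, pm)
        back = compress(sl, pm, grid)
        # compare where the round trip is defined
        sl2 = expand(back, pm)
        num = np.sqrt(np.mean((sl2.values - sl.values) ** 2))
        den = np.sqrt(np.mean(sl.values**2))
        assert num / den < 0.05
        obs = back.observed_mask()
        rms = np.sqrt(np.mean((back.values[obs] - smooth.values[obs]) ** 2))
        assert rms / np.sqrt(np.mean(smooth.values[obs] ** 2)) < 0.05


class TestSeed:
    def test_peak_count_matches_lattice_enumeration(self, cell, grid):
        model = seed_intensity(cell, grid, 0.13 * cell.a_star, rng_seed=3)
        pts = lattice_points_in_sphere(cell, grid.q_max)
        centers = np.round(grid.q_to_voxel(cell.hkl_to_q(pts))).astype(int)
        vals = model.values[centers[:, 2], centers[:, 1], centers[:, 0]]
        # every predicted position (forbidden ones included) carries a bump
        assert np.all(vals > 100 * 1e-10)

    def test_forbidden_reflections_are_seeded(self, cell, grid):
        # no symmetry imposed at seeding: 00l with l % 4 != 0 present
        model = seed_intensity(cell, grid, 0.13 * cell.a_star, rng_seed=3)
        q = cell.hkl_to_q(np.array([[0, 0, 1], [0, 0, 2], [1, 0, 0]]))
        c = np.round(grid.q_to_voxel(q)).astype(int)
        assert np.all(model.values[c[:, 2], c[:, 1], c[:, 0]] > 100 * 1e-10)

    def test_same_seed_identical(self, cell, grid):
        a = seed_intensity(cell, grid, 0.13 * cell.a_star, rng_seed=4)
        b = seed_intensity(cell, grid, 0.13 * cell.a_star, rng_seed=4)
        assert np.array_equal(a.values, b.values)


class TestIterate:
    def test_single_rotation_degenerates_to_mean_frame(self, geom, grid):
        rot = RotationSet.uniform(1)
        pm = build_pixel_map(geom, rot, grid)
        rng = np.random.default_rng(0)
        dense = rng.poisson(2.0, size=(30, geom.n_pixels)).astype(float)
        fs = toy_frameset(dense, n_pixels=geom.n_pixels)
        seed = IntensityModel(np.full(grid.shape, 1.0), grid)
        model, _, _, _ = emc_iterate(fs, geom, rot, seed, n_iter=1)
        mean_counts = dense[:, pm.pixel_ids].mean(axis=0)
        direct = compress(SliceSet(mean_counts[None, :], pm.pixel_ids), pm, grid)
        obs = model.observed_mask()
        assert np.allclose(model.values[obs], direct.values[obs], rtol=1e-9)

    def test_noise_free_frames_are_near_fixed_point(self, truth, geom, calibration):
        # frames carrying exactly the expected counts: one EMC iteration
        # changes the model only by the interpolation round trip
        rot = calibration.rotations
        rates = calibration.expected_rates(rot.angles)
        frames = []
        for j in range(rot.count):
            nz = np.flatnonzero(rates[j] > 1e-12)
            frames.append(SparseFrame(calibration.pixel_ids[nz], rates[j][nz],
                                      true_angle=float(rot.angles[j])))
        fs = FrameSet.from_frames(frames, geom.n_pixels)
        model, rms, _, _ = emc_iterate(fs, geom, rot, calibration.model, n_iter=2)
        assert rms[-1] < 0.05

    def test_rms_trace_decreases_and_loglik_ascends(self, emc_fit):
        rms = emc_fit.rms_trace
        assert np.all(np.isfinite(rms))
        assert rms[-1] < rms[0]
        ll = emc_fit.loglik_trace
        # EM ascent up to interpolation tolerance (0.1% of magnitude)
        assert np.all(np.diff(ll) >= -1e-3 * np.abs(ll[1:]))

    def test_gauge_roll_of_rotation_labels(self, emc_fit, frames, rotations):
        # relabeling rotations by a constant shift rolls P's rows; the
        # orientation report must recover the shift as the gauge offset
        P = emc_fit.probabilities
        k = 7
        rolled = ProbabilityMatrix(np.roll(P.P, k, axis=0))
        rep = orientation_errors(rolled, frames.true_angles, rotations, allow_flip=False)
        base = orientation_errors(P, frames.true_angles, rotations, allow_flip=False)
        assert rep.fraction_within == pytest.approx(base.fraction_within, abs=1e-12)
        assert (rep.offset - base.offset) % 360.0 == pytest.approx(
            (k * rotations.spacing) % 360.0)

    def test_non_finite_intensity_raises(self, frames, geom, rotations, grid):
        bad = IntensityModel(np.full(grid.shape, 1.0), grid)
        bad.values[0, 0, 0] = np.inf  # injected after construction
        with pytest.raises((ValueError, FloatingPointError)):
            emc_iterate(frames, geom, rotations, bad, n_iter=1)


class TestExtendAndRescale:
    def test_one_hot_extension_equals_reference_assembly(self, frames, geom, rotations, grid):
        idx = np.round(frames.true_angles / rotations.spacing).astype(int) % rotations.count
        P = np.zeros((rotations.count, len(frames)))
        P[idx, np.arange(len(frames))] = 1.0
        fine = ReciprocalGrid(grid.voxel_size * 63 / 81, 81)
        ext = extend_resolution(ProbabilityMatrix(P), frames, geom, rotations, fine)
        ref = assemble_reference(frames, geom, fine)
        assert np.allclose(ext.values, ref.values, rtol=1e-9, atol=1e-12)
        assert ext.values.shape == (81, 81, 81)

    def test_same_grid_extension_is_plain_m_step(self, frames, geom, rotations, grid, emc_fit):
        P = emc_fit.probabilities
        pm = build_pixel_map(geom, rotations, grid)
        fr = frames.restrict(pm.pixel_ids)
        direct = compress(maximize(P, fr, pm.pixel_ids), pm, grid)
        ext = extend_resolution(P, frames, geom, rotations, grid)
        assert np.allclose(ext.values, direct.values, rtol=1e-12)

    def test_size_mismatch_rejected(self, frames, geom, rotations, grid):
        P = ProbabilityMatrix(np.ones((rotations.count, len(frames) - 1)) / rotations.count)
        with pytest.raises(ValueError):
            extend_resolution(P, frames, geom, rotations, grid)

    def test_rescale_halves_doubled_model(self, frames, grid):
        target = frames.total_photons
        model = IntensityModel(np.full(grid.shape, 1.0), grid)
        out = rescale_to_photon_count(model, frames)
        assert out.total == pytest.approx(target, rel=1e-9)
        again = rescale_to_photon_count(out, frames)
        assert np.allclose(again.values, out.values, rtol=1e-12)

    def test_rescale_zero_model_rejected(self, frames, grid):
        with pytest.raises(ValueError):
            rescale_to_photon_count(IntensityModel(np.zeros(grid.shape), grid), frames)

    def test_rescaled_sum_matches_independent_count(self, truth, geom, rotations, grid, emc_fit):
        fs_total = sum(emc_fit.model.frames[k].n_photons
                       for k in range(len(emc_fit.model.frames)))
        out = emc_fit.rescaled()
        assert out.total == pytest.approx(fs_total, rel=1e-9)


class TestModelResults:
    def test_summary_reports_fit(self, emc_fit):
        s = emc_fit.summary()
        assert "iterations run" in s and "resolution limit" in s
        assert f"{emc_fit.n_iter:>12d}" in s

    def test_plot_convergence_returns_axes(self, emc_fit):
        import matplotlib
        matplotlib.use("Agg")
        ax = emc_fit.plot_convergence()
        assert ax.get_xlabel() == "iteration"

    def test_seed_requires_cell(self, frames, geom, rotations, grid):
        m = EMCModel(frames, geom, rotations, grid)
        with pytest.raises(ValueError):
            m.seed()
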