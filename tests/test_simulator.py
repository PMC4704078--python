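"""Ground-truth construction and sparse Poisson frame statistics."""

import numpy as np
import pytest
from scipy.stats import chisquare

from emcryst import ReciprocalGrid, RotationSet, UnitCell
from emcryst.frames import FrameSet, SparseFrame
from emcryst.lattice import lattice_points_in_sphere
from emcryst.simulate import (
    forbidden_by_rules,
    make_ground_truth,
    simulate_dataset,
    simulate_frame,
    DEFAULT_RULES,
)
from emcryst.validate import assemble_reference


def brute_force_lattice_count(cell, q_max):
    """Independent triple-loop enumeration of reciprocal points in a sphere."""
    n = 0
    hmax = int(q_max / cell.a_star) + 1
    lmax = int(q_max / cell.c_star) + 1
    for h in range(-hmax, hmax + 1):
        for k in range(-hmax, hmax + 1):
            for l in range(-lmax, lmax + 1):
                if h == k == l == 0:
                    continue
                if (h * cell.a_star) ** 2 + (k * cell.a_star) ** 2 + (l * cell.c_star) ** 2 <= q_max**2 + 1e-12:
                    n += 1
    return n


class TestLattice:
    def test_count_matches_brute_force(self, cell):
        for q_max in (0.08, 0.1384, 0.2):
            pts = lattice_points_in_sphere(cell, q_max)
            assert len(pts) == brute_force_lattice_count(cell, q_max)
            assert np.all(np.linalg.norm(pts * [cell.a_star, cell.a_star, cell.c_star],
                                         axis=1) <= q_max + 1e-12)

    def test_origin_excluded(self, cell):
        pts = lattice_points_in_sphere(cell, 0.1)
        assert not np.any(np.all(pts == 0, axis=1))


class TestGroundTruth:
    def test_space_group_rules_zero_forbidden_reflections(self, truth):
        tab = truth.peak_table
        hkl = tab[["h", "k", "l"]].to_numpy()
        forb = forbidden_by_rules(hkl, DEFAULT_RULES)
        assert forb.any()
        assert np.all(tab["height"].to_numpy()[forb] == 0.0)
        # the 00l rule specifically: l % 4 != 0 has zero true intensity
        on_l = (hkl[:, 0] == 0) & (hkl[:, 1] == 0) & (hkl[:, 2] % 4 != 0)
        assert np.all(tab["height"].to_numpy()[on_l] == 0.0)

    def test_rules_off_leaves_absences_populated(self, cell, grid):
        t = make_ground_truth(cell, grid, 0.13 * cell.a_star, rng_seed=5,
                              space_group_rules=False)
        hkl = t.peak_table[["h", "k", "l"]].to_numpy()
        forb = forbidden_by_rules(hkl, DEFAULT_RULES)
        heights = t.peak_table["height"].to_numpy()
        ratio = heights[forb].mean() / heights[~forb].mean()
        assert 0.2 < ratio < 5.0  # same Wilson-like population

    def test_friedel_symmetry_imposed(self, truth):
        tab = truth.peak_table.set_index(["h", "k", "l"])["height"]
        for (h, k, l), v in tab.sample(50, random_state=0).items():
            assert tab[(-h, -k, -l)] == pytest.approx(v)

    def test_zero_peaks_zero_background_gives_zero_model(self, cell, grid, geom, rotations):
        t = make_ground_truth(cell, grid, 0.13 * cell.a_star, rng_seed=2, n_peaks=0)
        calib = t.calibrate(geom, rotations, mean_photons=200.0, background_fraction=0.0)
        assert calib.model.total == 0.0

    def test_too_fine_resolution_rejected(self, cell, grid):
        with pytest.raises(ValueError):
            make_ground_truth(cell, grid, 0.13 * cell.a_star, rng_seed=1,
                              resolution_limit=0.5 * grid.resolution_limit)

    def test_determinism(self, cell, grid):
        a = make_ground_truth(cell, grid, 0.13 * cell.a_star, rng_seed=9)
        b = make_ground_truth(cell, grid, 0.13 * cell.a_star, rng_seed=9)
        assert np.array_equal(a.peak_map, b.peak_map)
        assert np.array_equal(a.orientation, b.orientation)


class TestSimulateFrames:
    def test_mean_photon_count_in_regime(self, truth, geom, rotations):
        # law of large numbers at the study's 200 photons/frame
        fs = simulate_dataset(truth, geom, rotations, 10000, 200.0, 0.8, rng_seed=3)
        se = np.sqrt(200.0 / 10000)
        assert abs(fs.mean_photons - 200.0) < 4 * se + 0.5

    def test_expected_totals_cycle_mode(self, truth, geom, rotations):
        # calibration averages over the rotation set, so a balanced cycle
        # dataset's summed expectations equal n_frames * mean_photons
        calib = truth.calibrate(geom, rotations, 150.0, 0.8)
        n = 2 * rotations.count
        rates = calib.expected_rates(rotations.angles)
        total_expected = 2 * rates.sum()
        assert total_expected == pytest.approx(n * 150.0, rel=1e-6)

    def test_background_share_of_photons(self, truth, geom, rotations, calibration):
        # fractional attribution of observed photons to the background
        # component should recover the 80% regime
        fs = simulate_dataset(truth, geom, rotations, 3000, 200.0, 0.8, rng_seed=4)
        lookup = np.full(geom.n_pixels, -1)
        lookup[calibration.pixel_ids] = np.arange(calibration.pixel_ids.size)
        bg3d = calibration.background_scale * truth.background_map
        share_sum = 0.0
        angles = np.unique(fs.true_angles)
        for ang in angles:
            sel = np.flatnonzero(fs.true_angles == ang)
            tot = calibration.expected_rates(ang)[0]
            bg = calibration._slice(bg3d, ang)[0]
            frac = np.divide(bg, tot, out=np.zeros_like(bg), where=tot > 0)
            for k in sel:
                f = fs[k]
                share_sum += (frac[lookup[f.pixels]] * f.counts).sum()
        assert share_sum / fs.total_photons == pytest.approx(0.8, abs=0.02)

    def test_true_angles_uniform_chi_square(self, truth, geom, rotations):
        fs = simulate_dataset(truth, geom, rotations, 20000, 50.0, 0.8,
                              rng_seed=6, angle_mode="continuous")
        counts, _ = np.histogram(fs.true_angles, bins=36, range=(0, 360))
        assert chisquare(counts).pvalue > 0.01

    def test_same_seed_identical_dataset(self, truth, geom, rotations):
        a = simulate_dataset(truth, geom, rotations, 300, 200.0, 0.8, rng_seed=7)
        b = simulate_dataset(truth, geom, rotations, 300, 200.0, 0.8, rng_seed=7)
        assert np.array_equal(a.offsets, b.offsets)
        assert np.array_equal(a.pixels, b.pixels)
        assert np.array_equal(a.counts, b.counts)
        assert np.array_equal(a.true_angles, b.true_angles)

    def test_empty_dataset(self, truth, geom, rotations):
        fs = simulate_dataset(truth, geom, rotations, 0)
        assert len(fs) == 0
        assert fs.total_photons == 0

    def test_single_frame_low_rate_mostly_empty(self, truth, geom, rotations, rng):
        empties = sum(
            simulate_frame(truth, geom, 30.0, 1e-4, 0.8, rng, rotations).n_photons == 0
            for _ in range(50)
        )
        assert empties >= 48

    def test_assembled_truth_correlates_with_model(self, cell, geom):
        # dense-photon dataset deposited at true angles converges to the
        # truth model pushed through the same trilinear sample/deposit pair
        # (narrow ~0.9-voxel peaks make the raw model itself differ by the
        # interpolation smear, so the expectation map is the fair oracle)
        from emcryst.emc import SliceSet, compress
        from emcryst.geometry import build_pixel_map

        grid = ReciprocalGrid.from_cell(cell.a_star, 7, 63)
        rot = RotationSet.uniform(120)
        t = make_ground_truth(cell, grid, 0.13 * cell.a_star, rng_seed=21)
        fs = simulate_dataset(t, geom, rot, 5200, 2000.0, 0.5, rng_seed=22)
        assert fs.total_photons >= 1e7
        ref = assemble_reference(fs, geom, grid)
        calib = t.calibrate(geom, rot, 2000.0, 0.5)
        pm = build_pixel_map(geom, rot, grid)
        expect = compress(SliceSet(calib.expected_rates(rot.angles), pm.pixel_ids), pm, grid)
        sel = ref.observed_mask() & (expect.values > 0.01 * expect.values.max())
        r = np.corrcoef(ref.values[sel], expect.values[sel])[0, 1]
        assert r > 0.99


class TestFrameContainers:
    def test_sparse_frame_validation(self):
        with pytest.raises(ValueError):
            SparseFrame(np.array([1, 2]), np.array([0.0, 1.0]))

    def test_frameset_round_trip_through_frames(self):
        fr = [SparseFrame(np.array([3, 7]), np.array([1.0, 2.0]), true_angle=10.0),
              SparseFrame(np.array([0]), np.array([4.0]), true_angle=20.0)]
        fs = FrameSet.from_frames(fr, n_detector_pixels=16)
        assert len(fs) == 2
        assert fs.total_photons == 7.0
        assert fs[1].pixels.tolist() == [0]
        assert fs[1].true_angle == 20.0

    def test_restrict_drops_outside_photons(self):
        fs = FrameSet(np.array([0, 2, 3]), np.array([1, 5, 2]),
                      np.array([1.0, 2.0, 3.0]), 8, np.array([0.0, 90.0]))
        out = fs.restrict(np.array([1, 2]))
        assert len(out) == 2
        assert out.total_photons == 4.0
        assert out.pixels.tolist() == [1, 2]

    def test_counts_matrix_integrity_error(self):
        fs = FrameSet(np.array([0, 1]), np.array([5]), np.array([1.0]), 8)
        with pytest.raises(ValueError, match="outside the usable map"):
            fs.counts_matrix(np.array([0, 1, 2]))
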