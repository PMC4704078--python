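"""Synthetic ground truths and sparse Poisson frames.

The generator emulates the statistical regime of a sparse single-axis
rotation experiment: a tetragonal crystal in a fixed, recorded orientation,
~200 photons per 10 ms-equivalent exposure, and ~80% of the expected photons
coming from smooth diffuse background (solvent, air, windows) rather than
Bragg peaks.  Every stage downstream (EMC, segmentation, integration,
validation) is testable against the recorded truth.

Ground-truth intensity = sum of isotropic 3D Gaussians at the reciprocal
lattice points of the (optionally space-group-censored, Friedel-symmetrized)
cell, with Wilson-like exponential peak intensities attenuated by a B factor,
plus an isotropic radial background.  Frames are independent Poisson draws
from trilinear slices of that model — the same interpolation the EMC
expansion step uses, so the simulator and the estimator share one forward
model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation as ScipyRotation

from .emc import IntensityModel
from .frames import FrameSet, SparseFrame
from .geometry import (
    DetectorGeometry,
    ReciprocalGrid,
    RotationSet,
    grid_pixel_selection,
    rotation_matrix,
    _trilinear_corners,
)
from .lattice import UnitCell, lattice_points_in_sphere, paint_gaussian_peaks

__all__ = [
    "UnitCell",
    "GroundTruth",
    "make_ground_truth",
    "simulate_frame",
    "simulate_dataset",
    "forbidden_by_rules",
    "DEFAULT_RULES",
]

#: reflection conditions of space group P4(3)2(1)2 as stated for the screw
#: and 2(1) axes: 00l present only for l = 4n, h00 only for h = 2n
DEFAULT_RULES = (
    {"zero_axes": (0, 1), "axis": 2, "modulus": 4},  # (0,0,l): l = 4n
    {"zero_axes": (1, 2), "axis": 0, "modulus": 2},  # (h,0,0): h = 2n
)


def forbidden_by_rules(hkl: np.ndarray, rules=DEFAULT_RULES) -> np.ndarray:
    """Boolean mask of reflections forbidden by axial reflection conditions."""
    hkl = np.asarray(hkl)
    forbidden = np.zeros(len(hkl), dtype=bool)
    for rule in rules:
        z0, z1 = rule["zero_axes"]
        on_axis = (hkl[:, z0] == 0) & (hkl[:, z1] == 0)
        forbidden |= on_axis & (hkl[:, rule["axis"]] % rule["modulus"] != 0)
    return forbidden


@dataclass
class GroundTruth:
    """Recorded simulation truth.

    ``peak_map`` and ``background_map`` are unscaled shapes on ``grid``; the
    absolute photon scale is fixed per (detector, rotation set, mean photon
    rate, background fraction) by :meth:`calibrate`.  ``peak_table`` records
    every reflection's Miller indices, random height and painted voxel sum
    (its true integrated intensity up to the calibration scale).
    """

    cell: UnitCell
    grid: ReciprocalGrid
    orientation: np.ndarray
    peak_sigma_q: float
    peak_table: pd.DataFrame
    peak_map: np.ndarray = field(repr=False)
    background_map: np.ndarray = field(repr=False)
    background_fraction: float = 0.8
    _calibrations: dict = field(default_factory=dict, repr=False)

    def intensity(self) -> IntensityModel:
        """Unscaled combined truth intensity (peaks + background)."""
        return IntensityModel(self.peak_map + self.background_map, self.grid)

    def calibrate(self, geom: DetectorGeometry, rotations: RotationSet,
                  mean_photons: float, background_fraction: float | None = None
                  ) -> "Calibration":
        bf = self.background_fraction if background_fraction is None else background_fraction
        key = (id(geom), rotations.angles.tobytes(), float(mean_photons), float(bf))
        if key not in self._calibrations:
            self._calibrations[key] = Calibration(self, geom, rotations, mean_photons, bf)
        return self._calibrations[key]


class Calibration:
    """Photon-scale calibration of a ground truth against a detector.

    Scales the peak and background maps so that, averaged over the rotation
    samples, the expected total photons per frame is ``mean_photons`` and the
    expected background share is ``background_fraction``.
    """

    def __init__(self, truth: GroundTruth, geom: DetectorGeometry,
                 rotations: RotationSet, mean_photons: float, background_fraction: float):
        if mean_photons < 0:
            raise ValueError("mean_photons must be nonnegative")
        if not 0.0 <= background_fraction <= 1.0:
            raise ValueError("background_fraction must lie in [0, 1]")
        self.truth = truth
        self.geom = geom
        self.rotations = rotations
        self.mean_photons = float(mean_photons)
        self.background_fraction = float(background_fraction)

        keep, q, self.n_dropped_pixels = grid_pixel_selection(geom, rotations.axis, truth.grid)
        self.pixel_ids = np.flatnonzero(keep)
        self.q_lab = q[keep]

        t_peak = self._mean_slice_total(truth.peak_map)
        t_bg = self._mean_slice_total(truth.background_map)
        signal = (1.0 - background_fraction) * mean_photons
        bg = background_fraction * mean_photons
        self.peak_scale = signal / t_peak if t_peak > 0 else 0.0
        self.background_scale = bg / t_bg if t_bg > 0 else 0.0
        self._model = IntensityModel(
            self.peak_scale * truth.peak_map + self.background_scale * truth.background_map,
            truth.grid,
        )

    def _slice(self, values3d: np.ndarray, angles) -> np.ndarray:
        """Trilinear slices of a 3D map at the given angles, (M, N)."""
        angles = np.atleast_1d(np.asarray(angles, dtype=float))
        grid = self.truth.grid
        out = np.empty((angles.size, self.q_lab.shape[0]))
        flat = values3d.ravel()
        for m, ang in enumerate(angles):
            R = rotation_matrix(self.rotations.axis, ang)
            frac = grid.q_to_voxel(self.q_lab @ R)  # rows: R^T q
            idx, wt = _trilinear_corners(frac, grid.extent)
            out[m] = np.einsum("nc,nc->n", flat[idx], wt.astype(np.float64))
        return out

    def _mean_slice_total(self, values3d: np.ndarray) -> float:
        return float(self._slice(values3d, self.rotations.angles).sum(axis=1).mean())

    @property
    def model(self) -> IntensityModel:
        """The calibrated true intensity in expected-photons units — the
        oracle model used for orientation-probability validation."""
        return self._model

    def expected_rates(self, angles) -> np.ndarray:
        """Expected photon counts per kept pixel at the given angle(s)."""
        return self._slice(self._model.values, angles)

    def peak_table(self) -> pd.DataFrame:
        """Truth peak table with calibrated integrated intensities."""
        tab = self.truth.peak_table.copy()
        tab["true_intensity"] = tab["painted"] * self.peak_scale
        return tab


def make_ground_truth(
    cell: UnitCell,
    grid: ReciprocalGrid,
    peak_sigma_q: float,
    rng_seed: int,
    resolution_limit: float | None = None,
    n_peaks: int | None = None,
    space_group_rules: bool = True,
    friedel: bool = True,
    orientation: np.ndarray | str = "random",
    b_factor: float = 25.0,
    background_fraction: float = 0.8,
) -> GroundTruth:
    """Build a recorded ground truth on ``grid``.

    Parameters
    ----------
    peak_sigma_q : float
        Gaussian peak width (std dev) in 1/Angstrom.
    resolution_limit : float, optional
        d_min in Angstrom for the peak lattice; defaults to the grid's own
        limit.  Must not be finer than the grid can hold.
    n_peaks : int, optional
        Keep only the first n lattice points (deterministic order) — for
        tiny test scenes.  None = full lattice within the resolution sphere.
    space_group_rules : bool
        Impose the axial reflection conditions (00l: l = 4n, h00: h = 2n):
        forbidden reflections get exactly zero true intensity.
    friedel : bool
        Impose I(hkl) = I(-h,-k,-l).
    orientation : 3x3 array or "random"
        Lattice orientation in the grid frame; "random" draws (and records)
        a uniform random rotation so lattice axes are not grid-aligned.
    b_factor : float
        Wilson-like intensity decay, I ~ Exp(1) * exp(-B |q|^2 / 2), in A^2.
    """
    rng = np.random.default_rng(rng_seed)
    if resolution_limit is None:
        q_max = grid.q_max
    else:
        if resolution_limit < grid.resolution_limit - 1e-12:
            raise ValueError(
                f"resolution limit {resolution_limit} A is finer than the grid "
                f"supports ({grid.resolution_limit:.3f} A)"
            )
        q_max = 1.0 / resolution_limit

    if isinstance(orientation, str):
        if orientation != "random":
            raise ValueError("orientation must be a matrix or 'random'")
        U = ScipyRotation.random(rng=rng).as_matrix()
    else:
        U = np.asarray(orientation, dtype=float)

    hkl = lattice_points_in_sphere(cell, q_max)
    # deterministic order so seeded runs are reproducible
    order = np.lexsort((hkl[:, 2], hkl[:, 1], hkl[:, 0]))
    hkl = hkl[order]
    if n_peaks is not None:
        hkl = hkl[:n_peaks]

    q_hkl = cell.hkl_to_q(hkl, U)
    q_norm = np.linalg.norm(q_hkl, axis=1)
    heights = rng.exponential(1.0, size=len(hkl)) * np.exp(-b_factor * q_norm**2 / 2.0)

    if friedel and len(hkl):
        # average each Friedel pair's draw so I(hkl) == I(-h,-k,-l)
        key = {tuple(x): i for i, x in enumerate(hkl)}
        for i, x in enumerate(hkl):
            j = key.get((-x[0], -x[1], -x[2]))
            if j is not None and j > i:
                heights[i] = heights[j] = 0.5 * (heights[i] + heights[j])
    if space_group_rules and len(hkl):
        heights[forbidden_by_rules(hkl)] = 0.0

    peak_map, painted = paint_gaussian_peaks(grid, q_hkl, heights, peak_sigma_q)

    # smooth isotropic diffuse background: wide radial Gaussian + pedestal
    qq = np.linalg.norm(grid.voxel_q_coords(), axis=-1)
    background_map = np.exp(-(qq**2) / (2 * (0.6 * grid.q_max) ** 2)) + 0.2

    table = pd.DataFrame({
        "h": hkl[:, 0] if len(hkl) else np.empty(0, int),
        "k": hkl[:, 1] if len(hkl) else np.empty(0, int),
        "l": hkl[:, 2] if len(hkl) else np.empty(0, int),
        "height": heights,
        "painted": painted,
        "q": q_norm,
    })
    return GroundTruth(
        cell=cell, grid=grid, orientation=U, peak_sigma_q=peak_sigma_q,
        peak_table=table, peak_map=peak_map, background_map=background_map,
        background_fraction=background_fraction,
    )


def simulate_frame(
    truth: GroundTruth,
    geom: DetectorGeometry,
    angle: float,
    mean_photons: float,
    background_fraction: float,
    rng: np.random.Generator,
    rotations: RotationSet | None = None,
) -> SparseFrame:
    """One Poisson frame at the given rotation angle (degrees, wrapped).

    ``rotations`` fixes the calibration average; defaults to 360 uniform
    samples.
    """
    rotations = rotations or RotationSet.uniform(360)
    calib = truth.calibrate(geom, rotations, mean_photons, background_fraction)
    rates = calib.expected_rates(angle % 360.0)[0]
    counts = rng.poisson(rates)
    nz = np.flatnonzero(counts)
    return SparseFrame(calib.pixel_ids[nz], counts[nz].astype(float),
                       true_angle=float(angle % 360.0))


def simulate_dataset(
    truth: GroundTruth,
    geom: DetectorGeometry,
    rotations: RotationSet,
    n_frames: int,
    mean_photons: float = 200.0,
    background_fraction: float | None = None,
    rng_seed: int = 0,
    angle_mode: str = "discrete",
) -> FrameSet:
    """Simulate a reproducible dataset of sparse frames.

    ``angle_mode``:

    * ``"discrete"`` — true angles drawn uniformly at random from the
      rotation samples (default);
    * ``"cycle"`` — deterministic round-robin over the rotation samples
      (exactly uniform coverage when n_frames is a multiple of the count);
    * ``"continuous"`` — uniform random angles in [0, 360), emulating a
      continuously rotating crystal.

    True angles are stored as hidden metadata for validation only.
    """
    if n_frames < 0:
        raise ValueError("n_frames must be >= 0")
    bf = truth.background_fraction if background_fraction is None else background_fraction
    calib = truth.calibrate(geom, rotations, mean_photons, bf)
    rng = np.random.default_rng(rng_seed)
    n_det = geom.n_pixels

    if n_frames == 0:
        return FrameSet(np.zeros(1, np.int64), np.empty(0, np.int64),
                        np.empty(0, np.float64), n_det, np.empty(0, np.float64))

    J = rotations.count
    if angle_mode == "discrete":
        angle_idx = rng.integers(0, J, size=n_frames)
        angles = rotations.angles[angle_idx]
    elif angle_mode == "cycle":
        angle_idx = np.arange(n_frames) % J
        angles = rotations.angles[angle_idx]
    elif angle_mode == "continuous":
        angle_idx = None
        angles = rng.uniform(0.0, 360.0, size=n_frames)
    else:
        raise ValueError(f"unknown angle_mode {angle_mode!r}")

    pixels_per_frame: list[np.ndarray] = [None] * n_frames  # type: ignore
    counts_per_frame: list[np.ndarray] = [None] * n_frames  # type: ignore

    def emit(frame_indices, count_matrix):
        rows, cols = np.nonzero(count_matrix)
        vals = count_matrix[rows, cols]
        split = np.searchsorted(rows, np.arange(1, len(frame_indices)))
        for local, (p, c) in enumerate(zip(np.split(cols, split), np.split(vals, split))):
            k = frame_indices[local]
            pixels_per_frame[k] = calib.pixel_ids[p]
            counts_per_frame[k] = c.astype(np.float64)

    if angle_idx is not None:
        rates_all = calib.expected_rates(rotations.angles)  # (J, N)
        for j in range(J):
            members = np.flatnonzero(angle_idx == j)
            if members.size == 0:
                continue
            emit(members, rng.poisson(rates_all[j], size=(members.size, rates_all.shape[1])))
    else:
        chunk = 256
        for lo in range(0, n_frames, chunk):
            sel = np.arange(lo, min(lo + chunk, n_frames))
            rates = calib.expected_rates(angles[sel])
            emit(sel, rng.poisson(rates))

    offsets = np.zeros(n_frames + 1, dtype=np.int64)
    np.cumsum([p.size for p in pixels_per_frame], out=offsets[1:])
    pixels = np.concatenate(pixels_per_frame) if offsets[-1] else np.empty(0, np.int64)
    counts = np.concatenate(counts_per_frame) if offsets[-1] else np.empty(0, np.float64)
    return FrameSet(offsets, pixels, counts, n_det, angles)
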