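"""Detector and reciprocal-space geometry for single-axis rotation diffraction.

Lab-frame convention (right handed): the incident beam travels along +z, the
rotation axis is +y (perpendicular to the beam), and the detector is a flat
panel normal to z at ``distance`` millimetres from the sample.  A pixel with
integer indices ``(fast, slow)`` has its centre at
``((fast + 0.5 - beam_center_fast) * pitch, (slow + 0.5 - beam_center_slow) * pitch)``
in the detector plane.  Elastic scattering places every measured spatial
frequency ``q = (s_hat - z_hat) / lambda`` on the Ewald sphere of radius
``1/lambda`` centred at ``-z_hat/lambda``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DetectorGeometry",
    "RotationSet",
    "ReciprocalGrid",
    "PixelMap",
    "pixel_to_q",
    "rotate_about_axis",
    "rotation_matrix",
    "build_pixel_map",
    "grid_pixel_selection",
]

BEAM_DIRECTION = np.array([0.0, 0.0, 1.0])
ROTATION_AXIS = np.array([0.0, 1.0, 0.0])


@dataclass(frozen=True)
class DetectorGeometry:
    """Flat single-panel detector.

    Parameters
    ----------
    n_fast, n_slow : int
        Pixel counts along the fast and slow readout directions.
    pixel_pitch : float
        Pixel pitch in mm (square pixels).
    distance : float
        Sample-to-detector distance in mm.
    wavelength : float
        X-ray wavelength in Angstrom.
    beam_center : (float, float)
        Direct-beam position in (fast, slow) pixel units.  May lie outside
        the active area (the experiment this emulates parked the beam in a
        detector corner to reach the highest resolution).
    mask : ndarray of bool, shape (n_slow, n_fast), optional
        True where the pixel is usable.  Defaults to all-usable.
    """

    n_fast: int
    n_slow: int
    pixel_pitch: float
    distance: float
    wavelength: float
    beam_center: tuple[float, float]
    mask: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self):
        if self.distance <= 0 or self.wavelength <= 0 or self.pixel_pitch <= 0:
            raise ValueError("distance, wavelength and pixel_pitch must be positive")
        if self.n_fast < 1 or self.n_slow < 1:
            raise ValueError("detector must have at least one pixel per axis")
        if self.mask is not None:
            mask = np.asarray(self.mask, dtype=bool)
            if mask.shape != (self.n_slow, self.n_fast):
                raise ValueError(
                    f"mask shape {mask.shape} != (n_slow, n_fast) = "
                    f"({self.n_slow}, {self.n_fast})"
                )
            object.__setattr__(self, "mask", mask)

    @property
    def n_pixels(self) -> int:
        return self.n_fast * self.n_slow

    def usable(self) -> np.ndarray:
        """Boolean usable-pixel map, shape (n_slow, n_fast)."""
        if self.mask is None:
            return np.ones((self.n_slow, self.n_fast), dtype=bool)
        return self.mask

    def pixel_indices(self) -> tuple[np.ndarray, np.ndarray]:
        """(fast, slow) index arrays for every pixel, flattened in C order
        over the (slow, fast) image."""
        slow, fast = np.indices((self.n_slow, self.n_fast))
        return fast.ravel(), slow.ravel()


def pixel_to_q(geom: DetectorGeometry, pixel) -> np.ndarray:
    """Map detector pixel(s) to scattering vector(s) q in 1/Angstrom.

    ``pixel`` is ``(fast, slow)`` where each may be a scalar or an array;
    fractional values address positions between pixel centres.  Returns an
    array of shape ``(..., 3)`` with q = (s_hat - z_hat)/lambda, so
    ``|q| = 2 sin(theta)/lambda`` and every q lies on the Ewald sphere.
    """
    fast, slow = np.asarray(pixel[0], dtype=float), np.asarray(pixel[1], dtype=float)
    if np.any(fast < 0) or np.any(fast > geom.n_fast) or np.any(slow < 0) or np.any(slow > geom.n_slow):
        raise IndexError("pixel index outside detector bounds")
    x = (fast + 0.5 - geom.beam_center[0]) * geom.pixel_pitch
    y = (slow + 0.5 - geom.beam_center[1]) * geom.pixel_pitch
    z = np.broadcast_to(geom.distance, x.shape)
    s = np.stack(np.broadcast_arrays(x, y, z), axis=-1)
    s_hat = s / np.linalg.norm(s, axis=-1, keepdims=True)
    return (s_hat - BEAM_DIRECTION) / geom.wavelength


def rotate_about_axis(q, axis, angle_deg) -> np.ndarray:
    """Rodrigues rotation of vector(s) ``q`` by ``angle_deg`` about ``axis``.

    ``axis`` must be a unit 3-vector; ``q`` has shape (..., 3).  The norm of
    q and its component along the axis are preserved exactly (up to floating
    point).
    """
    axis = np.asarray(axis, dtype=float)
    n = np.linalg.norm(axis)
    if n < 1e-12:
        raise ValueError("rotation axis must be nonzero")
    if abs(n - 1.0) > 1e-8:
        raise ValueError("rotation axis must be normalized")
    q = np.asarray(q, dtype=float)
    theta = np.deg2rad(angle_deg)
    c, s = np.cos(theta), np.sin(theta)
    cross = np.cross(np.broadcast_to(axis, q.shape), q)
    dot = (q @ axis)[..., None]
    return q * c + cross * s + axis * dot * (1.0 - c)


def rotation_matrix(axis, angle_deg) -> np.ndarray:
    """3x3 rotation matrix about ``axis`` by ``angle_deg``."""
    return rotate_about_axis(np.eye(3), axis, angle_deg).T


@dataclass(frozen=True)
class RotationSet:
    """Uniformly spaced one-dimensional rotation samples about a fixed axis.

    ``angles`` are degrees in [0, 360), strictly increasing with constant
    spacing; ``axis`` is a unit vector perpendicular to the beam within
    ``axis_tolerance_deg``.
    """

    axis: np.ndarray
    angles: np.ndarray
    axis_tolerance_deg: float = 0.5

    def __post_init__(self):
        axis = np.asarray(self.axis, dtype=float)
        n = np.linalg.norm(axis)
        if n < 1e-12:
            raise ValueError("rotation axis must be nonzero")
        object.__setattr__(self, "axis", axis / n)
        ang = np.asarray(self.angles, dtype=float)
        if ang.ndim != 1 or ang.size < 1:
            raise ValueError("angles must be a non-empty 1-D sequence")
        if np.any(ang < 0) or np.any(ang >= 360):
            raise ValueError("angles must lie in [0, 360)")
        if ang.size > 1:
            d = np.diff(ang)
            if np.any(d <= 0):
                raise ValueError("angles must be strictly increasing")
            if not np.allclose(d, d[0], atol=1e-9):
                raise ValueError("angles must be uniformly spaced")
        object.__setattr__(self, "angles", ang)
        perp = abs(float(self.axis @ BEAM_DIRECTION))
        if perp > np.sin(np.deg2rad(self.axis_tolerance_deg)):
            raise ValueError("rotation axis must be perpendicular to the beam")

    @classmethod
    def uniform(cls, count: int, axis=ROTATION_AXIS) -> "RotationSet":
        """``count`` samples at spacing 360/count starting at 0."""
        if count < 1:
            raise ValueError("count must be >= 1")
        return cls(axis=np.asarray(axis, float), angles=np.arange(count) * (360.0 / count))

    @property
    def count(self) -> int:
        return int(self.angles.size)

    @property
    def spacing(self) -> float:
        """Angular spacing in degrees (360 for a single sample)."""
        return float(self.angles[1] - self.angles[0]) if self.count > 1 else 360.0

    def matrices(self) -> np.ndarray:
        """Stack of rotation matrices, shape (J, 3, 3)."""
        return np.stack([rotation_matrix(self.axis, a) for a in self.angles])


@dataclass(frozen=True)
class ReciprocalGrid:
    """Cubic voxel grid over reciprocal space, centred on q = 0.

    ``voxel_size`` is the edge length in 1/Angstrom; ``extent`` the (odd)
    voxel count per axis so the origin voxel exists.  The fractional voxel
    coordinate of a vector q is ``q / voxel_size + half_extent``.
    """

    voxel_size: float
    extent: int

    def __post_init__(self):
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be positive")
        if self.extent < 3 or self.extent % 2 == 0:
            raise ValueError("extent must be odd and >= 3")

    @classmethod
    def from_cell(cls, a_star: float, divisor: int, extent: int) -> "ReciprocalGrid":
        """Grid with voxel size ``a*/divisor`` (the conventional way of
        stating the sampling rate relative to the reciprocal cell)."""
        return cls(voxel_size=a_star / divisor, extent=extent)

    @property
    def shape(self) -> tuple[int, int, int]:
        return (self.extent,) * 3

    @property
    def half_extent(self) -> int:
        return self.extent // 2

    @property
    def q_max(self) -> float:
        """Largest |q| fully inside the grid (inscribed sphere radius)."""
        return self.half_extent * self.voxel_size

    @property
    def resolution_limit(self) -> float:
        """d_min = 1/q_max in Angstrom."""
        return 1.0 / self.q_max

    def q_to_voxel(self, q: np.ndarray) -> np.ndarray:
        """Fractional voxel coordinates of q vectors, shape preserved."""
        return np.asarray(q, float) / self.voxel_size + self.half_extent

    def voxel_to_q(self, v: np.ndarray) -> np.ndarray:
        return (np.asarray(v, float) - self.half_extent) * self.voxel_size

    def voxel_q_coords(self) -> np.ndarray:
        """q coordinates of every voxel centre, shape (extent,)*3 + (3,)."""
        ax = (np.arange(self.extent) - self.half_extent) * self.voxel_size
        qz, qy, qx = np.meshgrid(ax, ax, ax, indexing="ij")
        # axis order (z, y, x) for the array, component order (x, y, z)
        return np.stack([qx, qy, qz], axis=-1)


class PixelMap:
    """Precomputed pixel -> reciprocal-grid mapping for every rotation.

    For each rotation j and each usable, in-range pixel i the map stores the
    fractional voxel coordinate of ``R(-angle_j) q_i`` (the crystal-frame
    spatial frequency sampled by that pixel when the crystal sits at
    ``angle_j``), together with the 8 trilinear corner voxel indices and
    weights used by both slice extraction (gather) and its adjoint
    (scatter).

    Attributes
    ----------
    pixel_ids : ndarray (N,)  flat indices of the usable in-range pixels
    coords : ndarray (J, N, 3)  fractional voxel coordinates (x, y, z order)
    corner_idx : ndarray (J, N, 8) int32 flat voxel indices into grid.shape
    corner_wt : ndarray (J, N, 8) float32 trilinear weights (sum to 1)
    n_dropped : int  usable pixels outside the grid at some rotation
    """

    def __init__(self, geom: DetectorGeometry, rotations: RotationSet, grid: ReciprocalGrid):
        self.geom = geom
        self.rotations = rotations
        self.grid = grid

        keep, q, n_dropped = grid_pixel_selection(geom, rotations.axis, grid)
        self.n_dropped = n_dropped
        self.pixel_ids = np.flatnonzero(keep)
        self.q_lab = q[keep]

        mats = rotations.matrices()  # (J, 3, 3); crystal frame: R(-a) q = R(a)^T q
        coords = np.einsum("jba,pb->jpa", mats, self.q_lab)
        self.coords = grid.q_to_voxel(coords)  # (J, N, 3)
        self.corner_idx, self.corner_wt = _trilinear_corners(self.coords, grid.extent)

    @property
    def n_pixels(self) -> int:
        return int(self.pixel_ids.size)

    @property
    def n_rotations(self) -> int:
        return self.rotations.count


def _trilinear_corners(frac: np.ndarray, extent: int):
    """Corner flat indices and weights for fractional coords (..., 3).

    Coordinates are (x, y, z); the voxel array is indexed [z, y, x] in C
    order, so flat index = (z * extent + y) * extent + x.
    """
    f0 = np.floor(frac).astype(np.int64)
    np.clip(f0, 0, extent - 2, out=f0)
    t = frac - f0  # in [0, 1]
    shape = frac.shape[:-1]
    idx = np.empty(shape + (8,), dtype=np.int32)
    wt = np.empty(shape + (8,), dtype=np.float32)
    k = 0
    for dz in (0, 1):
        for dy in (0, 1):
            for dx in (0, 1):
                x = f0[..., 0] + dx
                y = f0[..., 1] + dy
                z = f0[..., 2] + dz
                idx[..., k] = (z * extent + y) * extent + x
                wx = t[..., 0] if dx else 1.0 - t[..., 0]
                wy = t[..., 1] if dy else 1.0 - t[..., 1]
                wz = t[..., 2] if dz else 1.0 - t[..., 2]
                wt[..., k] = wx * wy * wz
                k += 1
    return idx, wt


def grid_pixel_selection(geom: DetectorGeometry, axis, grid: ReciprocalGrid):
    """Pixels that stay inside ``grid`` at *every* rotation about ``axis``.

    The criterion is rotation-set independent so the simulator and the
    reconstruction always agree on the set of live pixels: with r_axis the
    |q| component along the axis and r_perp the in-plane radius, the swept
    circle stays inside the cube iff both are <= half_extent * voxel_size.

    Returns (keep mask over flat pixels, q_lab (n_pixels, 3), n_dropped).
    """
    fast, slow = geom.pixel_indices()
    usable = geom.usable().ravel()
    q = pixel_to_q(geom, (fast, slow))
    axis = np.asarray(axis, dtype=float)
    q_axis = q @ axis
    r_perp = np.sqrt(np.maximum(np.einsum("pi,pi->p", q, q) - q_axis**2, 0.0))
    lim = grid.half_extent * grid.voxel_size * (1.0 - 1e-9)
    in_range = (np.abs(q_axis) <= lim) & (r_perp <= lim)
    keep = usable & in_range
    return keep, q, int(np.count_nonzero(usable & ~in_range))


def build_pixel_map(geom: DetectorGeometry, rotations: RotationSet, grid: ReciprocalGrid) -> PixelMap:
    """Precompute the per-(rotation, pixel) fractional voxel coordinates.

    Usable pixels whose rotated q falls outside the grid at any rotation are
    dropped (counted in ``PixelMap.n_dropped``); masked pixels are excluded.
    """
    return PixelMap(geom, rotations, grid)
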