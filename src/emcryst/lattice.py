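"""Tetragonal unit cell, reciprocal lattice enumeration, Gaussian peak painting."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import ReciprocalGrid

__all__ = ["UnitCell", "lattice_points_in_sphere", "paint_gaussian_peaks"]


@dataclass(frozen=True)
class UnitCell:
    """Tetragonal cell: a = b, all angles 90 degrees.

    Reciprocal constants are a* = 1/a and c* = 1/c (orthogonal axes), so a
    reflection (h, k, l) sits at q = U @ (h a*, k a*, l c*) for crystal
    orientation matrix U.
    """

    a: float
    c: float

    def __post_init__(self):
        if self.a <= 0 or self.c <= 0:
            raise ValueError("cell lengths must be positive")

    @property
    def b(self) -> float:
        return self.a

    @property
    def a_star(self) -> float:
        return 1.0 / self.a

    @property
    def c_star(self) -> float:
        return 1.0 / self.c

    def reciprocal_basis(self, orientation: np.ndarray | None = None) -> np.ndarray:
        """Columns are the reciprocal basis vectors in the lab/grid frame."""
        B = np.diag([self.a_star, self.a_star, self.c_star])
        if orientation is None:
            return B
        U = np.asarray(orientation, dtype=float)
        if U.shape != (3, 3) or not np.allclose(U @ U.T, np.eye(3), atol=1e-8):
            raise ValueError("orientation must be a 3x3 rotation matrix")
        return U @ B

    def hkl_to_q(self, hkl: np.ndarray, orientation: np.ndarray | None = None) -> np.ndarray:
        """Reciprocal-space positions, shape (..., 3), of Miller indices."""
        return np.asarray(hkl, dtype=float) @ self.reciprocal_basis(orientation).T

    def q_to_hkl(self, q: np.ndarray, orientation: np.ndarray | None = None) -> np.ndarray:
        """Fractional Miller indices of arbitrary q vectors."""
        Binv = np.linalg.inv(self.reciprocal_basis(orientation))
        return np.asarray(q, dtype=float) @ Binv.T


def lattice_points_in_sphere(cell: UnitCell, q_max: float, include_origin: bool = False) -> np.ndarray:
    """All integer (h, k, l) with |q_hkl| <= q_max, as an (M, 3) int array.

    The enumeration is orientation independent (rotations preserve |q|).
    The origin (0,0,0) is excluded by default — it is the direct beam, not a
    Bragg reflection.
    """
    if q_max <= 0:
        raise ValueError("q_max must be positive")
    hmax = int(np.floor(q_max / cell.a_star))
    lmax = int(np.floor(q_max / cell.c_star))
    h = np.arange(-hmax, hmax + 1)
    l = np.arange(-lmax, lmax + 1)
    H, K, L = np.meshgrid(h, h, l, indexing="ij")
    q2 = (H * cell.a_star) ** 2 + (K * cell.a_star) ** 2 + (L * cell.c_star) ** 2
    sel = q2 <= q_max**2 + 1e-12
    if not include_origin:
        sel &= ~((H == 0) & (K == 0) & (L == 0))
    return np.stack([H[sel], K[sel], L[sel]], axis=-1).astype(np.int64)


def paint_gaussian_peaks(
    grid: ReciprocalGrid,
    centers_q: np.ndarray,
    heights: np.ndarray,
    sigma_q: float,
    cutoff_sigmas: float = 4.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Sum of isotropic 3-D Gaussians on the voxel grid.

    Each peak m contributes ``heights[m] * exp(-|q - centers_q[m]|^2 / (2 sigma_q^2))``
    evaluated at voxel centres, truncated beyond ``cutoff_sigmas``.

    Returns ``(values, painted)`` where ``values`` has shape ``grid.shape``
    (array axes ordered [z, y, x]) and ``painted[m]`` is the actual voxel sum
    deposited for peak m (its true integrated intensity on this grid, in
    map-value * voxel units).
    """
    centers = grid.q_to_voxel(np.asarray(centers_q, dtype=float))
    heights = np.asarray(heights, dtype=float)
    sigma = sigma_q / grid.voxel_size  # in voxels
    n = grid.extent
    values = np.zeros((n, n, n), dtype=np.float64)
    painted = np.zeros(len(heights), dtype=np.float64)
    r = max(int(np.ceil(cutoff_sigmas * sigma)), 1)
    offs = np.arange(-r, r + 1)
    for m, (cx, cy, cz) in enumerate(centers):
        if heights[m] == 0.0:
            continue
        ix = int(round(cx))
        iy = int(round(cy))
        iz = int(round(cz))
        xs = offs + ix
        ys = offs + iy
        zs = offs + iz
        okx = (xs >= 0) & (xs < n)
        oky = (ys >= 0) & (ys < n)
        okz = (zs >= 0) & (zs < n)
        xs, ys, zs = xs[okx], ys[oky], zs[okz]
        gx = np.exp(-((xs - cx) ** 2) / (2 * sigma**2))
        gy = np.exp(-((ys - cy) ** 2) / (2 * sigma**2))
        gz = np.exp(-((zs - cz) ** 2) / (2 * sigma**2))
        patch = heights[m] * gz[:, None, None] * gy[None, :, None] * gx[None, None, :]
        values[np.ix_(zs, ys, xs)] += patch
        painted[m] = patch.sum()
    return values, painted
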