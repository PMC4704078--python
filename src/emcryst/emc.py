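"""Expand-maximize-compress (EMC) reconstruction of a 3D diffraction intensity.

The EMC algorithm treats each sparse frame's orientation as a hidden variable
and runs expectation-maximization on the Poisson likelihood of the photon
counts.  One iteration:

* **expand** — sample tomographic slices ``W_ij`` (expected photons at pixel
  i for rotation j) out of the current 3D intensity ``W(q)`` by trilinear
  interpolation along the Ewald sphere;
* **probabilities** — the conditional probability that frame k was taken at
  rotation j, with a uniform orientation prior,

  ``P_jk ∝ Π_i W_ij^{K_ik} exp(-W_ij)``,

  computed in the log domain (only the sparse nonzero counts enter the
  product; the exponential term is the slice total);
* **maximize** — the EM update ``W'_ij = Σ_k P_jk K_ik / Σ_k P_jk``;
* **compress** — scatter the updated slices back into the 3D grid with the
  adjoint trilinear weights and per-voxel weight normalization.

Because all rotations here are about one known axis, the reconstruction is
determined only up to a global rotation about that axis (the gauge); seeding
Gaussian bumps at the predicted Bragg positions both speeds convergence and
pins the gauge in practice.

The statsmodels-style front end is :class:`EMCModel` (data + design) whose
``fit`` returns :class:`EMCResults`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.special import logsumexp

from .frames import FrameSet
from .geometry import PixelMap, ReciprocalGrid, RotationSet, build_pixel_map
from .lattice import UnitCell, lattice_points_in_sphere, paint_gaussian_peaks

__all__ = [
    "IntensityModel",
    "SliceSet",
    "ProbabilityMatrix",
    "seed_intensity",
    "expand",
    "compute_probabilities",
    "maximize",
    "compress",
    "emc_iterate",
    "extend_resolution",
    "rescale_to_photon_count",
    "EMCModel",
    "EMCResults",
]

#: lower clamp on expected counts before logs; a photon observed where the
#: model is zero must not yield -inf
FLOOR = 1e-10


@dataclass
class IntensityModel:
    """3D voxel model of mean intensities W(q) in expected photons per pixel
    sample per frame.

    ``observed`` marks voxels that received any interpolation weight during
    compression (False = never visited, value 0 by convention).
    """

    values: np.ndarray
    grid: ReciprocalGrid
    observed: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != self.grid.shape:
            raise ValueError("values shape does not match grid extent")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("intensity values must be finite")
        if np.any(self.values < 0):
            raise ValueError("intensity values must be nonnegative")

    @property
    def total(self) -> float:
        return float(self.values.sum())

    def copy(self) -> "IntensityModel":
        obs = None if self.observed is None else self.observed.copy()
        return IntensityModel(self.values.copy(), self.grid, obs)

    def observed_mask(self) -> np.ndarray:
        if self.observed is None:
            return np.ones(self.grid.shape, dtype=bool)
        return self.observed


@dataclass
class SliceSet:
    """Expected photon counts W_ij per (rotation j, kept pixel i).

    ``pixel_ids`` are flat detector indices of the kept pixels, so a
    SliceSet can be matched against FrameSet photon lists.  ``defined``
    marks rows/entries with enough probability weight in an M-step.
    """

    values: np.ndarray  # (J, N)
    pixel_ids: np.ndarray  # (N,)
    defined: np.ndarray | None = None  # (J, N) bool or None = all

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("slice values must be 2-D (rotations x pixels)")
        if self.values.shape[1] != np.asarray(self.pixel_ids).size:
            raise ValueError("pixel_ids length must match slice width")

    @property
    def n_rotations(self) -> int:
        return self.values.shape[0]

    def defined_mask(self) -> np.ndarray:
        if self.defined is None:
            return np.ones(self.values.shape, dtype=bool)
        return self.defined


@dataclass
class ProbabilityMatrix:
    """Conditional orientation probabilities P_jk, shape (J, K).

    Columns (frames) sum to 1.  ``frame_log_evidence[k]`` is
    ``log Σ_j (1/J) Π_i Poisson(K_ik; W_ij)`` up to the frame-constant
    ``Σ_i log K_ik!`` term, so its sum is the EM objective being ascended.
    """

    P: np.ndarray
    frame_log_evidence: np.ndarray | None = None

    def __post_init__(self):
        self.P = np.asarray(self.P, dtype=np.float64)
        if self.P.ndim != 2:
            raise ValueError("P must be 2-D (rotations x frames)")

    @property
    def n_rotations(self) -> int:
        return self.P.shape[0]

    @property
    def n_frames(self) -> int:
        return self.P.shape[1]

    @property
    def total_log_likelihood(self) -> float:
        if self.frame_log_evidence is None:
            raise ValueError("log evidence was not recorded")
        return float(self.frame_log_evidence.sum())

    def most_probable(self) -> np.ndarray:
        """Per-frame argmax rotation index (ties -> lowest index/angle)."""
        return np.argmax(self.P, axis=0)


def seed_intensity(
    cell_estimate: UnitCell,
    grid: ReciprocalGrid,
    peak_sigma_q: float,
    rng_seed: int,
    orientation: np.ndarray | None = None,
    floor: float = FLOOR,
) -> IntensityModel:
    """Initial intensity: Gaussian bumps of random height at every predicted
    Bragg position inside the grid's resolution sphere, plus a uniform floor.

    No symmetry is imposed: forbidden reflections and both Friedel mates are
    seeded independently, so any symmetry in the converged result is evidence
    of successful orientation recovery rather than an input.

    ``orientation`` is the known lattice orientation in the grid frame (from
    indexing a coarse pass, or recorded simulation truth); identity if None.
    """
    rng = np.random.default_rng(rng_seed)
    hkl = lattice_points_in_sphere(cell_estimate, grid.q_max)
    centers = cell_estimate.hkl_to_q(hkl, orientation)
    heights = rng.uniform(0.1, 1.0, size=len(hkl))
    values, _ = paint_gaussian_peaks(grid, centers, heights, peak_sigma_q)
    values += floor
    return IntensityModel(values, grid)


def expand(model: IntensityModel, pixel_map: PixelMap, floor: float = FLOOR) -> SliceSet:
    """Sample slices W_ij of the model for every rotation by trilinear
    interpolation, clamped below at ``floor``."""
    if pixel_map.grid.shape != model.grid.shape or pixel_map.grid.voxel_size != model.grid.voxel_size:
        raise ValueError("pixel map was built on a different grid")
    flat = model.values.ravel()
    vals = flat[pixel_map.corner_idx]  # (J, N, 8)
    W = np.einsum("jnc,jnc->jn", vals, pixel_map.corner_wt.astype(np.float64))
    np.maximum(W, floor, out=W)
    return SliceSet(W, pixel_map.pixel_ids)


def _loglik_matrix(slices: SliceSet, K: sp.csr_matrix, floor: float) -> np.ndarray:
    """Per-(frame, rotation) Poisson log likelihood up to frame constants:
    ``Σ_i K_ik log W_ij − Σ_i W_ij``, shape (K, J)."""
    W = np.maximum(slices.values, floor)
    logW = np.log(W)
    ll = K @ logW.T  # (K_frames, J): only nonzero counts contribute
    ll -= W.sum(axis=1)[None, :]
    return ll


def compute_probabilities(
    slices: SliceSet, frames: FrameSet, floor: float = FLOOR
) -> ProbabilityMatrix:
    """Conditional orientation probabilities under independent Poisson
    counts and a uniform prior over the sampled rotations.

    Computed in the log domain with per-frame log-sum-exp normalization.
    A photon on a pixel absent from the slice set raises ValueError.
    """
    K = frames.counts_matrix(np.asarray(slices.pixel_ids))
    ll = _loglik_matrix(slices, K, floor)
    J = slices.n_rotations
    log_evidence = logsumexp(ll, axis=1) - np.log(J)  # (K,)
    Pt = np.exp(ll - (log_evidence[:, None] + np.log(J)))
    Pt /= Pt.sum(axis=1, keepdims=True)  # exact renormalization
    return ProbabilityMatrix(Pt.T.copy(), frame_log_evidence=log_evidence)


def maximize(
    P: ProbabilityMatrix,
    frames: FrameSet,
    pixel_ids: np.ndarray,
    weight_cutoff: float = 1e-12,
) -> SliceSet:
    """EM M-step: probability-weighted mean photon count per (rotation, pixel),
    ``W'_ij = Σ_k P_jk K_ik / Σ_k P_jk``.

    Rows whose total probability weight falls below ``weight_cutoff`` are
    flagged undefined (the caller decides what they inherit).
    """
    if len(frames) == 0:
        raise ValueError("cannot maximize over an empty frame set")
    K = frames.counts_matrix(np.asarray(pixel_ids))
    num = (K.T @ P.P.T).T  # (J, N)
    den = P.P.sum(axis=1)  # (J,)
    defined = den > weight_cutoff
    W = np.zeros_like(num)
    W[defined] = num[defined] / den[defined, None]
    return SliceSet(W, pixel_ids, defined=np.broadcast_to(defined[:, None], W.shape).copy())


def compress(
    slices: SliceSet,
    pixel_map: PixelMap,
    grid: ReciprocalGrid,
    weight_floor: float = 1e-8,
) -> IntensityModel:
    """Adjoint of expand: distribute each slice value to its 8 surrounding
    voxels with trilinear weights and form the per-voxel weighted average.

    Voxels that receive no weight are zero and flagged unobserved.
    """
    if pixel_map.grid.shape != grid.shape or pixel_map.grid.voxel_size != grid.voxel_size:
        raise ValueError("pixel map was built on a different grid")
    nvox = grid.extent**3
    wt = pixel_map.corner_wt.astype(np.float64)
    defined = slices.defined_mask()
    wt = wt * defined[:, :, None]
    idx = pixel_map.corner_idx.ravel()
    num = np.bincount(idx, weights=(slices.values[:, :, None] * wt).ravel(), minlength=nvox)
    den = np.bincount(idx, weights=wt.ravel(), minlength=nvox)
    observed = den > weight_floor
    values = np.zeros(nvox)
    values[observed] = num[observed] / den[observed]
    np.maximum(values, 0.0, out=values)
    return IntensityModel(values.reshape(grid.shape), grid, observed.reshape(grid.shape))


def rescale_to_photon_count(model: IntensityModel, frames: FrameSet) -> IntensityModel:
    """Rescale the model so its voxel sum equals the total recorded photons."""
    total = model.total
    if total <= 0:
        raise ValueError("cannot rescale an all-zero model")
    out = model.copy()
    out.values *= frames.total_photons / total
    return out


def extend_resolution(
    converged_P: ProbabilityMatrix,
    frames_full: FrameSet,
    geom,
    rotations: RotationSet,
    fine_grid: ReciprocalGrid,
    weight_cutoff: float = 1e-12,
) -> IntensityModel:
    """Resolution extension: one maximize+compress pass on a finer grid with
    the orientation probabilities frozen from a converged lower-resolution
    run, folding in all photons up to the fine grid's resolution limit."""
    if converged_P.n_frames != len(frames_full):
        raise ValueError("probability matrix and frame set disagree on frame count")
    if converged_P.n_rotations != rotations.count:
        raise ValueError("probability matrix and rotation set disagree on rotation count")
    fine_map = build_pixel_map(geom, rotations, fine_grid)
    frames_fine = frames_full.restrict(fine_map.pixel_ids)
    slices = maximize(converged_P, frames_fine, fine_map.pixel_ids, weight_cutoff)
    return compress(slices, fine_map, fine_grid)


def emc_iterate(
    frames: FrameSet,
    geom,
    rotations: RotationSet,
    seed_model: IntensityModel,
    n_iter: int,
    tol: float = 0.0,
    floor: float = FLOOR,
):
    """Run EMC iterations; see :class:`EMCModel` for the object front end.

    Returns ``(model, rms_trace, loglik_trace, final ProbabilityMatrix)``.
    ``rms_trace[t]`` is the RMS change of the 3D intensity at iteration t
    relative to the RMS of the previous model; iteration stops early when it
    drops below ``tol``.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    grid = seed_model.grid
    pixel_map = build_pixel_map(geom, rotations, grid)
    frames = frames.restrict(pixel_map.pixel_ids)
    model = seed_model.copy()

    # bring the seed onto the expected-photons scale so the first E-step's
    # Poisson totals are not wildly off
    slices0 = expand(model, pixel_map, floor)
    mean_total = slices0.values.sum(axis=1).mean()
    if mean_total > 0 and len(frames) > 0:
        model.values *= frames.mean_photons / mean_total

    rms_trace: list[float] = []
    loglik_trace: list[float] = []
    P = None
    for it in range(n_iter):
        slices = expand(model, pixel_map, floor)
        P = compute_probabilities(slices, frames, floor)
        loglik_trace.append(P.total_log_likelihood)
        new_slices = maximize(P, frames, pixel_map.pixel_ids)
        undef = ~new_slices.defined_mask()
        if undef.any():
            # orientations no frame supports keep their previous slices
            new_slices.values[undef] = slices.values[undef]
            new_slices.defined = None
        new_model = compress(new_slices, pixel_map, grid)
        if not np.all(np.isfinite(new_model.values)):
            raise FloatingPointError(f"non-finite intensity at iteration {it + 1}")
        prev_rms = float(np.sqrt(np.mean(model.values**2)))
        change = float(np.sqrt(np.mean((new_model.values - model.values) ** 2)))
        rel = change / prev_rms if prev_rms > 0 else np.inf
        rms_trace.append(rel)
        model = new_model
        if rel < tol:
            break
    return model, np.array(rms_trace), np.array(loglik_trace), P


class EMCModel:
    """EMC reconstruction problem: sparse frames + geometry + rotation grid.

    Parameters
    ----------
    frames : FrameSet
    geom : DetectorGeometry
    rotations : RotationSet
        The discrete 1-D rotation samples over which orientations are
        inferred (uniform prior).
    grid : ReciprocalGrid
        Reconstruction grid; photons mapping outside it are dropped.
    cell, orientation, peak_sigma_q :
        Approximate unit cell, lattice orientation in the grid frame and
        seed peak width, used when ``fit`` has to build its own seed.
    """

    def __init__(self, frames, geom, rotations, grid, cell=None, orientation=None,
                 peak_sigma_q=None, floor: float = FLOOR):
        self.frames = frames
        self.geom = geom
        self.rotations = rotations
        self.grid = grid
        self.cell = cell
        self.orientation = orientation
        self.peak_sigma_q = peak_sigma_q
        self.floor = floor

    def seed(self, rng_seed: int = 0) -> IntensityModel:
        if self.cell is None:
            raise ValueError("a cell estimate is required to build a seed")
        sigma = self.peak_sigma_q or 0.9 * self.grid.voxel_size
        return seed_intensity(self.cell, self.grid, sigma, rng_seed,
                              orientation=self.orientation, floor=self.floor)

    def fit(self, n_iter: int = 30, tol: float = 0.0, seed_model: IntensityModel | None = None,
            rng_seed: int = 0) -> "EMCResults":
        if seed_model is None:
            seed_model = self.seed(rng_seed)
        model, rms, loglik, P = emc_iterate(
            self.frames, self.geom, self.rotations, seed_model,
            n_iter=n_iter, tol=tol, floor=self.floor,
        )
        return EMCResults(self, model, P, rms, loglik)


class EMCResults:
    """Converged EMC reconstruction.

    Attributes
    ----------
    intensity : IntensityModel      the reconstructed 3D intensity
    probabilities : ProbabilityMatrix   final orientation probabilities
    rms_trace : ndarray             relative RMS intensity change per iteration
    loglik_trace : ndarray          EM objective per iteration (non-decreasing
                                    up to interpolation tolerance)
    """

    def __init__(self, model: EMCModel, intensity, probabilities, rms_trace, loglik_trace):
        self.model = model
        self.intensity = intensity
        self.probabilities = probabilities
        self.rms_trace = np.asarray(rms_trace)
        self.loglik_trace = np.asarray(loglik_trace)

    @property
    def n_iter(self) -> int:
        return len(self.rms_trace)

    def rescaled(self) -> IntensityModel:
        """Reconstruction rescaled so its voxel sum equals the total photon
        count — the conventional normalization for downstream integration."""
        return rescale_to_photon_count(self.intensity, self.model.frames)

    def extend(self, fine_grid: ReciprocalGrid) -> IntensityModel:
        """Fixed-probability resolution extension onto a finer/wider grid."""
        return extend_resolution(self.probabilities, self.model.frames,
                                 self.model.geom, self.model.rotations, fine_grid)

    def plot_convergence(self, ax=None):
        """Plot the RMS-change and log-likelihood traces (matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        it = np.arange(1, self.n_iter + 1)
        ax.semilogy(it, self.rms_trace, marker="o", label="relative RMS change")
        ax.set_xlabel("iteration")
        ax.set_ylabel("relative RMS change")
        ax2 = ax.twinx()
        ax2.plot(it, self.loglik_trace, color="C1", marker=".",
                 label="log-likelihood")
        ax2.set_ylabel("log-likelihood")
        ax.legend(loc="upper right")
        return ax

    def summary(self) -> str:
        m = self.model
        obs = self.intensity.observed_mask()
        lines = [
            "EMC reconstruction results",
            "=" * 40,
            f"frames                 {len(m.frames):>12d}",
            f"total photons          {m.frames.total_photons:>12.0f}",
            f"mean photons / frame   {m.frames.mean_photons:>12.2f}",
            f"rotation samples       {m.rotations.count:>12d}",
            f"rotation spacing (deg) {m.rotations.spacing:>12.4f}",
            f"grid extent            {m.grid.extent:>9d}^3",
            f"voxel size (1/A)       {m.grid.voxel_size:>12.6f}",
            f"resolution limit (A)   {m.grid.resolution_limit:>12.3f}",
            f"iterations run         {self.n_iter:>12d}",
            f"final RMS change       {self.rms_trace[-1]:>12.3e}",
            f"final log-likelihood   {self.loglik_trace[-1]:>12.6e}",
            f"observed voxels        {int(obs.sum()):>12d} / {obs.size}",
        ]
        return "\n".join(lines)
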