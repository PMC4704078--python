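"""Reconstruction quality metrics.

A reconstruction from non-oriented single-axis frames is only defined up to
a global rotation about the axis (the gauge), so every comparison against
truth first fits a global angular offset.  The metrics here are the ones a
sparse-frame merging experiment reports: a reference assembly from the true
orientations, the amplitude R factor between integrated reflection sets,
the per-frame orientation-assignment error distribution, space-group
reflection-condition checks, and the share of photons attributable to
diffuse background.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .emc import IntensityModel, ProbabilityMatrix
from .frames import FrameSet
from .geometry import (
    DetectorGeometry,
    ReciprocalGrid,
    RotationSet,
    _trilinear_corners,
    grid_pixel_selection,
    rotation_matrix,
)
from .peaks import ReflectionList, Segmentation, to_structure_factors

__all__ = [
    "assemble_reference",
    "r_factor",
    "orientation_errors",
    "check_reflection_conditions",
    "background_fraction",
    "OrientationReport",
]


def assemble_reference(
    frames: FrameSet,
    geom: DetectorGeometry,
    grid: ReciprocalGrid,
    axis=(0.0, 1.0, 0.0),
    weight_floor: float = 1e-8,
) -> IntensityModel:
    """Assemble the reference intensity from the hidden true orientations.

    Photons are deposited at their true-rotation reciprocal positions with
    trilinear weights and normalized by the accumulated weights — exactly
    one maximize+compress pass with a one-hot probability matrix at the true
    angles, which is what :func:`emcryst.emc.extend_resolution` reduces to
    in that limit.
    """
    if frames.true_angles is None:
        raise ValueError("reference assembly needs frames with true angles")
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    keep, q, _ = grid_pixel_selection(geom, axis, grid)
    pixel_ids = np.flatnonzero(keep)
    q_kept = q[keep]
    frames = frames.restrict(pixel_ids)

    nvox = grid.extent**3
    num = np.zeros(nvox)
    den = np.zeros(nvox)
    if len(frames) > 0:
        K = frames.counts_matrix(pixel_ids)
        angles, inverse = np.unique(frames.true_angles, return_inverse=True)
        group_n = np.bincount(inverse, minlength=angles.size).astype(float)
        # group-mean photon counts per unique true angle
        G = np.zeros((angles.size, pixel_ids.size))
        for g in range(angles.size):
            rows = np.flatnonzero(inverse == g)
            G[g] = np.asarray(K[rows].sum(axis=0)).ravel() / group_n[g]
        for g, ang in enumerate(angles):
            R = rotation_matrix(axis, float(ang))
            frac = grid.q_to_voxel(q_kept @ R)
            idx, wt = _trilinear_corners(frac, grid.extent)
            wt = wt.astype(np.float64)
            num += np.bincount(idx.ravel(), weights=(G[g][:, None] * wt).ravel(), minlength=nvox)
            den += np.bincount(idx.ravel(), weights=wt.ravel(), minlength=nvox)
    observed = den > weight_floor
    values = np.zeros(nvox)
    values[observed] = num[observed] / den[observed]
    return IntensityModel(values.reshape(grid.shape), grid, observed.reshape(grid.shape))


def _weighted_median(values: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(values)
    v, w = values[order], weights[order]
    cum = np.cumsum(w)
    return float(v[np.searchsorted(cum, 0.5 * cum[-1])])


def r_factor(
    reference: ReflectionList,
    reconstructed: ReflectionList,
    fit_scale: bool = True,
) -> float:
    """Amplitude R factor between two reflection lists on common (h,k,l).

    ``R = sum(| |F_ref| - s |F_rec| |) / sum(|F_ref|)`` with ``s`` the
    global scale minimizing the absolute residual (weighted median of the
    amplitude ratios); pass ``fit_scale=False`` to fix s = 1 when both sets
    are already on a common (e.g. photon-count) scale.  Only reflections
    accepted (non-partial) in both lists enter.  Asymmetric by construction:
    the denominator is the reference.
    """
    fr = to_structure_factors(ReflectionList(reference.accepted()))
    fc = to_structure_factors(ReflectionList(reconstructed.accepted()))
    merged = fr.merge(fc, on=["h", "k", "l"], suffixes=("_ref", "_rec"))
    if len(merged) == 0:
        raise ValueError("no common reflections between the two lists")
    F_ref = merged["F_ref"].to_numpy()
    F_rec = merged["F_rec"].to_numpy()
    s = 1.0
    if fit_scale:
        pos = F_rec > 0
        if pos.any():
            s = _weighted_median(F_ref[pos] / F_rec[pos], F_rec[pos])
    denom = F_ref.sum()
    if denom <= 0:
        raise ValueError("reference amplitudes sum to zero")
    return float(np.abs(F_ref - s * F_rec).sum() / denom)


@dataclass
class OrientationReport:
    """Per-frame orientation assignment versus truth, after gauge fitting.

    ``errors`` are signed wrapped differences in degrees in (-180, 180];
    ``offset`` (and ``flipped``) describe the fitted global gauge;
    ``tolerance`` is the "correct" threshold max(1 deg, spacing/2).
    """

    assigned: np.ndarray = field(repr=False)
    true_angles: np.ndarray = field(repr=False)
    errors: np.ndarray = field(repr=False)
    offset: float
    flipped: bool
    tolerance: float
    fraction_within: float

    def histogram(self, bin_width: float = 1.0) -> pd.DataFrame:
        edges = np.arange(-180.0, 180.0 + bin_width, bin_width)
        counts, edges = np.histogram(self.errors, bins=edges)
        return pd.DataFrame({"lo": edges[:-1], "hi": edges[1:], "count": counts})


def _wrap(deg: np.ndarray) -> np.ndarray:
    """Wrap to (-180, 180]."""
    return -((180.0 - np.asarray(deg)) % 360.0 - 180.0)


def orientation_errors(
    P: ProbabilityMatrix,
    true_angles: np.ndarray,
    rotations: RotationSet,
    allow_flip: bool = True,
) -> OrientationReport:
    """Most-probable-orientation errors with a fitted global gauge.

    Per frame the argmax rotation is taken (ties break to the lower angle);
    a single global offset on the rotation grid — optionally with a sense
    flip — is chosen to maximize the fraction of frames within
    ``max(1 deg, spacing/2)``, and errors are reported after that gauge.
    """
    true_angles = np.asarray(true_angles, dtype=float)
    if P.n_frames != true_angles.size:
        raise ValueError("probability matrix and true angles disagree on frame count")
    assigned = rotations.angles[P.most_probable()]
    tol = max(1.0, rotations.spacing / 2.0)

    def best_offset(pred):
        raw = _wrap(pred - true_angles)
        offs = rotations.angles
        within = np.abs(_wrap(raw[None, :] - offs[:, None])) <= tol + 1e-9
        fracs = within.mean(axis=1)
        i = int(np.argmax(fracs))
        return float(fracs[i]), float(offs[i]), _wrap(raw - offs[i])

    frac, off, err = best_offset(assigned)
    flipped = False
    if allow_flip:
        frac_f, off_f, err_f = best_offset(-assigned)
        if frac_f > frac:
            frac, off, err, flipped = frac_f, off_f, err_f, True
    return OrientationReport(
        assigned=assigned, true_angles=true_angles, errors=err,
        offset=off, flipped=flipped, tolerance=tol, fraction_within=frac,
    )


def check_reflection_conditions(
    reflections: ReflectionList,
    rules,
    ratio_threshold: float = 0.05,
) -> pd.DataFrame:
    """Systematic-absence check on an integrated reflection list.

    For each axial rule (see :data:`emcryst.simulate.DEFAULT_RULES`) the mean
    intensity of the allowed and forbidden classes is compared; the rule
    passes when the forbidden mean is below ``ratio_threshold`` times the
    allowed mean.  Negative intensities are clipped at zero for the means.
    A class with no reflections is reported as not testable.
    """
    tab = reflections.accepted()
    hkl = tab[["h", "k", "l"]].to_numpy()
    I = np.clip(tab["I"].to_numpy(dtype=float), 0.0, None)
    rows = []
    for rule in rules:
        z0, z1 = rule["zero_axes"]
        on_axis = (hkl[:, z0] == 0) & (hkl[:, z1] == 0)
        forb = on_axis & (hkl[:, rule["axis"]] % rule["modulus"] != 0)
        allow = on_axis & ~forb
        testable = forb.any() and allow.any()
        mean_allowed = float(I[allow].mean()) if allow.any() else np.nan
        mean_forbidden = float(I[forb].mean()) if forb.any() else np.nan
        ratio = mean_forbidden / mean_allowed if testable and mean_allowed > 0 else np.nan
        rows.append({
            "axis": "hkl"[rule["axis"]], "modulus": rule["modulus"],
            "n_allowed": int(allow.sum()), "n_forbidden": int(forb.sum()),
            "mean_allowed": mean_allowed, "mean_forbidden": mean_forbidden,
            "ratio": ratio, "testable": bool(testable),
            "passed": bool(testable and np.isfinite(ratio) and ratio < ratio_threshold),
        })
    return pd.DataFrame(rows)


def background_fraction(
    model: IntensityModel,
    segmentation: Segmentation,
    total_photons: float,
    consistency_tol: float = 0.01,
) -> float:
    """Share of recorded photons in background-labelled map regions.

    ``model`` must already be rescaled so its voxel sum equals the total
    recorded photon count (within ``consistency_tol`` relative); the
    estimate is the summed intensity over background voxels divided by the
    map total.
    """
    total = model.total
    if total_photons <= 0:
        raise ValueError("total_photons must be positive")
    if abs(total - total_photons) > consistency_tol * total_photons:
        raise ValueError(
            f"model sum {total:.6g} is not consistent with the recorded "
            f"photon count {total_photons:.6g}; rescale first"
        )
    bg = model.values[~segmentation.signal].sum()
    return float(bg / total)
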