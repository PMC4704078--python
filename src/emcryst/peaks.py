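"""Bragg peak segmentation, lattice refinement and reflection integration.

Works on the reconstructed 3D intensity map.  Segmentation classifies voxels
into signal/background by a local standard score z = (W - mu)/sigma computed
in an n x n x n window, iterated with a rising threshold schedule so that
peak voxels progressively stop contaminating the background statistics.
Lattice refinement grid-searches the reciprocal constants (a*, c*) for the
candidate whose predicted Bragg ellipsoids capture the most segmented signal.
Integration assigns voxels to reflections by proximity in fractional Miller
space — an ellipsoid with principal semi-axes proportional to (a*, a*, c*)
is a *sphere* of radius eps in fractional coordinates, with
eps = (3 f / 4 pi)^(1/3) for an ellipsoid occupying a fraction f of the
reciprocal cell — subtracts the local background mean, and flags partial
peaks (truncated by the map boundary, unobserved voxels or exclusion zones).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter

from .emc import IntensityModel
from .lattice import UnitCell

__all__ = [
    "Segmentation",
    "ReflectionList",
    "segment_peaks",
    "refine_lattice",
    "integrate_reflections",
    "to_structure_factors",
    "ellipsoid_radius",
]

DEFAULT_GAMMAS = (1.0, 1.7, 2.3, 3.0)  # linear-ish rise over 1 + 3 passes
DEFAULT_WINDOW = 15


def ellipsoid_radius(volume_fraction: float) -> float:
    """Fractional-space radius of an ellipsoid occupying the given fraction
    of the reciprocal unit cell (axes proportional to (a*, a*, c*))."""
    if not 0 < volume_fraction <= 1:
        raise ValueError("volume fraction must be in (0, 1]")
    return (3.0 * volume_fraction / (4.0 * np.pi)) ** (1.0 / 3.0)


@dataclass
class Segmentation:
    """Per-voxel signal/background classification.

    ``signal`` is True where a voxel was classified as Bragg signal; all
    other voxels are background.  ``valid`` marks voxels that took part in
    the statistics (observed map region); invalid voxels are background.
    """

    signal: np.ndarray
    window: int
    gammas: tuple
    valid: np.ndarray | None = field(default=None, repr=False)

    @property
    def n_signal(self) -> int:
        return int(self.signal.sum())


def _window_stats(values, include, window):
    """Mean and std over ``include``-masked voxels of each n^3 window."""
    inc = include.astype(np.float64)
    cnt = uniform_filter(inc, window, mode="constant")
    s1 = uniform_filter(values * inc, window, mode="constant")
    s2 = uniform_filter(values * values * inc, window, mode="constant")
    with np.errstate(invalid="ignore", divide="ignore"):
        mu = s1 / cnt
        var = s2 / cnt - mu * mu
    mu[cnt <= 0] = 0.0
    sigma = np.sqrt(np.clip(var, 0.0, None))
    sigma[cnt <= 0] = 0.0
    return mu, sigma


def segment_peaks(
    model: IntensityModel,
    window: int = DEFAULT_WINDOW,
    gammas=DEFAULT_GAMMAS,
    valid: np.ndarray | None = None,
) -> Segmentation:
    """Iterative z-score segmentation of Bragg peaks.

    Pass 1 computes mu/sigma from every (valid) voxel of the surrounding
    ``window``^3 cube; each later pass recomputes them from the voxels the
    previous pass left in the background, with the threshold gamma rising
    through ``gammas``.  A voxel is signal when z = (W - mu)/sigma > gamma;
    sigma = 0 windows classify as background.  Deterministic.
    """
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be odd and >= 3")
    if min(model.grid.shape) < window:
        raise ValueError("window exceeds map extent")
    if len(gammas) < 1 or np.any(np.diff(gammas) < 0):
        raise ValueError("gamma schedule must be non-empty and non-decreasing")
    W = model.values
    if valid is None:
        valid = model.observed_mask()
    background = valid.copy()  # stats source for the current pass
    signal = np.zeros_like(valid)
    for gamma in gammas:
        mu, sigma = _window_stats(W, background, window)
        with np.errstate(invalid="ignore", divide="ignore"):
            z = (W - mu) / sigma
        # sigma = 0 window: z is +inf for any voxel above the (constant)
        # background level, never signal at or below it
        above = (W - mu) > 1e-9 * (np.abs(W) + np.abs(mu))
        signal = valid & np.where(sigma > 0, z > gamma, above)
        background = valid & ~signal
    return Segmentation(signal=signal, window=window, gammas=tuple(gammas), valid=valid)


def _fractional_miller(model: IntensityModel, cell: UnitCell, orientation):
    """Fractional Miller coordinates of every voxel, shape grid.shape + (3,)."""
    q = model.grid.voxel_q_coords()
    return cell.q_to_hkl(q, orientation)


def refine_lattice(
    model: IntensityModel,
    segmentation: Segmentation,
    cell_estimate: UnitCell,
    orientation: np.ndarray | None = None,
    search_steps: int = 11,
    search_span: float = 0.02,
    ellipsoid_fraction: float = 0.01,
) -> UnitCell:
    """Grid search of the reciprocal-lattice constants.

    Candidates span ``cell +/- search_span`` (relative) in ``search_steps``
    per axis; each candidate scores the total segmented-signal intensity
    inside small ellipsoids (``ellipsoid_fraction`` of the reciprocal cell)
    centred on its predicted Bragg positions.  Highest total wins; ties go
    to the candidate closest to the estimate.
    """
    if segmentation.n_signal == 0:
        raise ValueError("cannot refine a lattice from an empty segmentation")
    sig = segmentation.signal
    q_sig = model.grid.voxel_q_coords()[sig]
    w_sig = model.values[sig]
    eps = ellipsoid_radius(ellipsoid_fraction)
    if search_steps == 1:
        rel = np.array([1.0])
    else:
        rel = np.linspace(1.0 - search_span, 1.0 + search_span, search_steps)
    U = orientation
    if U is not None:
        q_sig = q_sig @ np.asarray(U, float)  # U^T q: rotate into crystal axes
    best = (-np.inf, np.inf, cell_estimate)
    for fa in rel:
        for fc in rel:
            cand = UnitCell(cell_estimate.a / fa, cell_estimate.c / fc)
            m = q_sig / np.array([cand.a_star, cand.a_star, cand.c_star])
            d = m - np.round(m)
            inside = np.einsum("ij,ij->i", d, d) <= eps * eps
            total = float(w_sig[inside].sum())
            dist = (fa - 1.0) ** 2 + (fc - 1.0) ** 2
            if total > best[0] + 1e-12 or (abs(total - best[0]) <= 1e-12 and dist < best[1]):
                best = (total, dist, cand)
    return best[2]


@dataclass
class ReflectionList:
    """Integrated reflections.

    ``table`` columns: h, k, l, I (background-subtracted; NaN for partials),
    sigma, background, n_voxels, partial, fraction (ellipsoid volume
    fraction used).  Each (h, k, l) appears at most once.
    """

    table: pd.DataFrame

    def __post_init__(self):
        req = {"h", "k", "l", "I", "sigma", "background", "n_voxels", "partial", "fraction"}
        missing = req - set(self.table.columns)
        if missing:
            raise ValueError(f"reflection table missing columns {sorted(missing)}")
        if self.table.duplicated(subset=["h", "k", "l"]).any():
            raise ValueError("duplicate (h, k, l) rows")

    def __len__(self) -> int:
        return len(self.table)

    def accepted(self) -> pd.DataFrame:
        """Rows not flagged partial."""
        return self.table[~self.table["partial"]].reset_index(drop=True)


def integrate_reflections(
    model: IntensityModel,
    cell: UnitCell,
    orientation: np.ndarray | None = None,
    window_fractions=(0.10, 0.25, 0.50),
    segmentation: Segmentation | None = None,
    exclusion: np.ndarray | None = None,
) -> ReflectionList:
    """Ellipsoid-window integration of background-subtracted intensities.

    Every voxel is assigned to its nearest predicted Bragg position in
    fractional Miller space.  A reflection's ellipsoid uses the smallest
    fraction in ``window_fractions`` that captures all its segmented signal
    voxels (the smallest fraction when no segmentation is supplied); voxels
    outside every ellipsoid are background.  The local background mean —
    background voxels sharing the reflection's fractional cell — is
    subtracted per signal voxel before summing; intensities may come out
    negative and are retained.  Reflections touching the map boundary,
    unobserved voxels or ``exclusion`` zones are flagged partial and carry
    no intensity.
    """
    fracs = tuple(sorted(window_fractions))
    eps_list = np.array([ellipsoid_radius(f) for f in fracs])
    eps_max = eps_list[-1]
    if eps_max > 0.5:
        raise ValueError("largest window fraction exceeds the fractional cell")

    grid = model.grid
    m = _fractional_miller(model, cell, orientation)
    hkl_near = np.round(m).astype(np.int64)
    d = m - hkl_near
    r2 = np.einsum("...i,...i->...", d, d)

    ok = model.observed_mask().copy()
    if exclusion is not None:
        ok &= ~exclusion

    # reflections whose centre falls inside the observable sphere
    q_center = cell.hkl_to_q(hkl_near, orientation)
    center_in = np.einsum("...i,...i->...", q_center, q_center) <= grid.q_max**2
    origin = np.all(hkl_near == 0, axis=-1)

    # unique peak label per voxel
    flat_hkl = hkl_near.reshape(-1, 3)
    uniq, labels = np.unique(flat_hkl, axis=0, return_inverse=True)
    labels = labels.reshape(hkl_near.shape[:3])

    in_any = (r2 <= eps_max**2) & center_in & ~origin
    n_peaks = len(uniq)

    # per-peak tightest fraction capturing its segmented voxels; with no
    # segmentation every peak gets the largest (most conservative) window
    frac_idx = np.full(n_peaks, len(eps_list) - 1, dtype=np.int64)
    if segmentation is not None:
        frac_idx[:] = 0
        segsel = segmentation.signal & in_any
        if segsel.any():
            seg_lab = labels[segsel]
            seg_r2 = r2[segsel]
            max_r2 = np.zeros(n_peaks)
            np.maximum.at(max_r2, seg_lab, seg_r2)
            need = np.sqrt(max_r2)
            frac_idx = np.searchsorted(eps_list, need - 1e-12)
            frac_idx = np.clip(frac_idx, 0, len(eps_list) - 1)
    eps_peak = eps_list[frac_idx]

    is_signal = in_any & (r2 <= (eps_peak[labels]) ** 2)
    is_bg = ~is_signal

    lab_flat = labels.ravel()
    W = model.values.ravel()
    sigm = is_signal.ravel()
    bgm = (is_bg & ok).ravel() & center_in.ravel() & ~origin.ravel()
    okf = ok.ravel()

    def group_sum(mask, weights=None):
        w = weights[mask] if weights is not None else None
        return np.bincount(lab_flat[mask], weights=w, minlength=n_peaks)

    n_sig = group_sum(sigm)
    sum_sig = group_sum(sigm, W)
    n_bg = group_sum(bgm)
    sum_bg = group_sum(bgm, W)
    sum_bg2 = group_sum(bgm, W * W)
    bad_sig = group_sum(sigm & ~okf)  # signal voxels that are masked/unobserved

    with np.errstate(invalid="ignore", divide="ignore"):
        bg_mean = np.where(n_bg > 0, sum_bg / np.maximum(n_bg, 1), np.nan)
        bg_var = np.where(
            n_bg > 1, sum_bg2 / np.maximum(n_bg, 1) - bg_mean**2, 0.0
        )
    global_bg = W[bgm].mean() if bgm.any() else 0.0
    bg_mean = np.where(np.isnan(bg_mean), global_bg, bg_mean)
    bg_var = np.clip(bg_var, 0.0, None)

    # geometric truncation: does the peak's full ellipsoid fit inside the map?
    q_uniq = cell.hkl_to_q(uniq, orientation)
    a_max = max(cell.a_star, cell.c_star)
    margin_vox = eps_peak * a_max / grid.voxel_size
    c_frac = grid.q_to_voxel(q_uniq)
    lo_ok = np.all(c_frac - margin_vox[:, None] >= 0, axis=1)
    hi_ok = np.all(c_frac + margin_vox[:, None] <= grid.extent - 1, axis=1)
    inside_sphere = np.einsum("ij,ij->i", q_uniq, q_uniq) <= grid.q_max**2
    keep = inside_sphere & ~np.all(uniq == 0, axis=1)

    partial = (bad_sig > 0) | ~(lo_ok & hi_ok)
    I = sum_sig - n_sig * bg_mean
    sigma_I = np.sqrt(n_sig * bg_var * (1.0 + n_sig / np.maximum(n_bg, 1)))

    tab = pd.DataFrame({
        "h": uniq[:, 0], "k": uniq[:, 1], "l": uniq[:, 2],
        "I": np.where(partial, np.nan, I),
        "sigma": np.where(partial, np.nan, sigma_I),
        "background": bg_mean,
        "n_voxels": n_sig.astype(np.int64),
        "partial": partial,
        "fraction": np.array(fracs)[frac_idx],
    })
    tab = tab[keep].reset_index(drop=True)
    return ReflectionList(tab)


def to_structure_factors(reflections: ReflectionList) -> pd.DataFrame:
    """Structure-factor amplitudes |F| = sqrt(max(I, 0)).

    Returns a frame with h, k, l, F and a ``clipped`` flag marking rows whose
    negative intensity was clipped to zero; (h, k, l) order is preserved.
    """
    t = reflections.table
    I = t["I"].to_numpy(dtype=float)
    return pd.DataFrame({
        "h": t["h"], "k": t["k"], "l": t["l"],
        "F": np.sqrt(np.clip(I, 0.0, None)),
        "clipped": I < 0,
    })
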