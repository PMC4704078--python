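"""Sparse diffraction frame containers.

A *sparse frame* is a detector exposure holding so few photons (here ~200 on
average) that no Bragg peak is identifiable in it; it is stored as a list of
(pixel, count) pairs.  ``FrameSet`` holds many frames in flat ragged arrays
(CSR-style offsets), which is the only layout that stays practical for the
millions of frames this kind of experiment produces.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

__all__ = ["SparseFrame", "FrameSet"]


@dataclass(frozen=True)
class SparseFrame:
    """One exposure: photon pixel ids and counts, plus hidden truth metadata.

    ``true_angle`` (degrees about the rotation axis) exists only for
    simulated data and is never consulted by the reconstruction.
    """

    pixels: np.ndarray
    counts: np.ndarray
    frame_id: int = 0
    true_angle: float | None = None

    def __post_init__(self):
        pixels = np.asarray(self.pixels, dtype=np.int64)
        counts = np.asarray(self.counts, dtype=np.float64)
        if pixels.shape != counts.shape or pixels.ndim != 1:
            raise ValueError("pixels and counts must be matching 1-D arrays")
        if np.any(counts <= 0):
            raise ValueError("counts must be positive")
        object.__setattr__(self, "pixels", pixels)
        object.__setattr__(self, "counts", counts)

    @property
    def n_photons(self) -> float:
        return float(self.counts.sum())


class FrameSet:
    """Ragged collection of sparse frames.

    Attributes
    ----------
    offsets : int64 (K+1,)  CSR-style offsets into the flat arrays
    pixels : int64 (nnz,)   flat detector pixel indices
    counts : float64 (nnz,) photon counts (integers for measured data; the
        float type lets expected-count pseudo-frames flow through the same
        E/M machinery)
    true_angles : float64 (K,) or None   hidden simulation truth
    n_detector_pixels : int   size of the flat detector index space
    """

    def __init__(self, offsets, pixels, counts, n_detector_pixels, true_angles=None):
        self.offsets = np.asarray(offsets, dtype=np.int64)
        self.pixels = np.asarray(pixels, dtype=np.int64)
        self.counts = np.asarray(counts, dtype=np.float64)
        self.n_detector_pixels = int(n_detector_pixels)
        if self.offsets.ndim != 1 or self.offsets.size < 1 or self.offsets[0] != 0:
            raise ValueError("offsets must be 1-D and start at 0")
        if self.offsets[-1] != self.pixels.size or self.pixels.size != self.counts.size:
            raise ValueError("offsets inconsistent with flat arrays")
        if np.any(np.diff(self.offsets) < 0):
            raise ValueError("offsets must be non-decreasing")
        if self.pixels.size and (self.pixels.min() < 0 or self.pixels.max() >= self.n_detector_pixels):
            raise ValueError("pixel index outside detector")
        if true_angles is not None:
            true_angles = np.asarray(true_angles, dtype=np.float64)
            if true_angles.shape != (len(self),):
                raise ValueError("true_angles length must equal frame count")
        self.true_angles = true_angles

    def __len__(self) -> int:
        return self.offsets.size - 1

    def __getitem__(self, k: int) -> SparseFrame:
        if not (0 <= k < len(self)):
            raise IndexError(k)
        lo, hi = self.offsets[k], self.offsets[k + 1]
        angle = None if self.true_angles is None else float(self.true_angles[k])
        return SparseFrame(self.pixels[lo:hi], self.counts[lo:hi], frame_id=k, true_angle=angle)

    @property
    def total_photons(self) -> float:
        return float(self.counts.sum())

    @property
    def mean_photons(self) -> float:
        return self.total_photons / max(len(self), 1)

    @classmethod
    def from_frames(cls, frames, n_detector_pixels) -> "FrameSet":
        """Build from an iterable of SparseFrame."""
        frames = list(frames)
        offsets = np.zeros(len(frames) + 1, dtype=np.int64)
        for i, f in enumerate(frames):
            offsets[i + 1] = offsets[i] + f.pixels.size
        pixels = np.concatenate([f.pixels for f in frames]) if frames else np.empty(0, np.int64)
        counts = np.concatenate([f.counts for f in frames]) if frames else np.empty(0, np.float64)
        angles = None
        if frames and all(f.true_angle is not None for f in frames):
            angles = np.array([f.true_angle for f in frames])
        return cls(offsets, pixels, counts, n_detector_pixels, angles)

    def counts_matrix(self, pixel_subset: np.ndarray) -> sp.csr_matrix:
        """Sparse (K, len(pixel_subset)) matrix of counts restricted to the
        given flat pixel ids.

        Raises ValueError if any photon sits on a pixel outside the subset —
        a frame/geometry integrity failure.
        """
        lookup = np.full(self.n_detector_pixels, -1, dtype=np.int64)
        lookup[pixel_subset] = np.arange(pixel_subset.size)
        cols = lookup[self.pixels]
        if np.any(cols < 0):
            bad = int(self.pixels[cols < 0][0])
            raise ValueError(f"photon recorded at pixel {bad} outside the usable map")
        return sp.csr_matrix(
            (self.counts, cols, self.offsets), shape=(len(self), pixel_subset.size)
        )

    def restrict(self, pixel_subset: np.ndarray) -> "FrameSet":
        """Drop photons recorded outside ``pixel_subset`` (e.g. beyond a
        reconstruction grid's resolution limit), keeping the frame count.

        Returns self if nothing needs dropping.
        """
        lookup = np.zeros(self.n_detector_pixels, dtype=bool)
        lookup[pixel_subset] = True
        keep = lookup[self.pixels]
        if keep.all():
            return self
        frame_of = np.repeat(np.arange(len(self)), np.diff(self.offsets))
        frame_of = frame_of[keep]
        offsets = np.zeros(len(self) + 1, dtype=np.int64)
        np.cumsum(np.bincount(frame_of, minlength=len(self)), out=offsets[1:])
        return FrameSet(offsets, self.pixels[keep], self.counts[keep],
                        self.n_detector_pixels, self.true_angles)

    def subset(self, index) -> "FrameSet":
        """New FrameSet containing frames selected by an index array."""
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        parts_p, parts_c, offsets = [], [], [0]
        for k in index:
            lo, hi = self.offsets[k], self.offsets[k + 1]
            parts_p.append(self.pixels[lo:hi])
            parts_c.append(self.counts[lo:hi])
            offsets.append(offsets[-1] + (hi - lo))
        pixels = np.concatenate(parts_p) if parts_p else np.empty(0, np.int64)
        counts = np.concatenate(parts_c) if parts_c else np.empty(0, np.float64)
        angles = None if self.true_angles is None else self.true_angles[index]
        return FrameSet(np.array(offsets), pixels, counts, self.n_detector_pixels, angles)
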