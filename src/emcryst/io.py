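"""On-disk formats: frame container (HDF5), CCP4-style maps, SHELX hkl, CSV.

The frame container is one chunkable HDF5 file with named flat arrays
(CSR offsets, pixel ids, counts, optional true angles) plus the detector
geometry block — per-frame files are infeasible for millions of sparse
frames.  All writers are deterministic (no embedded timestamps), so
write -> read -> write reproduces identical bytes.
"""

from __future__ import annotations

import json
from pathlib import Path

import gemmi
import h5py
import numpy as np
import pandas as pd

from .emc import IntensityModel
from .frames import FrameSet
from .geometry import DetectorGeometry, ReciprocalGrid
from .peaks import ReflectionList

__all__ = [
    "write_frames", "read_frames",
    "write_map", "read_map",
    "write_hkl", "read_hkl",
    "write_reflections_csv", "read_reflections_csv",
    "write_report", "read_report",
]

FRAME_FORMAT = "emcryst-frames"
FRAME_VERSION = 1
_DSET_OPTS = dict(track_times=False)  # deterministic bytes


def write_frames(
    path,
    frames: FrameSet,
    geom: DetectorGeometry | None = None,
    orientation: np.ndarray | None = None,
) -> None:
    """Write a FrameSet (and optionally the geometry block and the true
    crystal orientation, which are simulation/bookkeeping metadata)."""
    with h5py.File(path, "w", track_order=False) as f:
        f.attrs["format"] = FRAME_FORMAT
        f.attrs["version"] = FRAME_VERSION
        f.attrs["n_detector_pixels"] = frames.n_detector_pixels
        f.create_dataset("offsets", data=frames.offsets, **_DSET_OPTS)
        f.create_dataset("pixels", data=frames.pixels.astype(np.int32), **_DSET_OPTS)
        f.create_dataset("counts", data=frames.counts, **_DSET_OPTS)
        if frames.true_angles is not None:
            f.create_dataset("true_angles", data=frames.true_angles, **_DSET_OPTS)
        if orientation is not None:
            f.create_dataset("orientation", data=np.asarray(orientation, float), **_DSET_OPTS)
        if geom is not None:
            g = f.create_group("geometry")
            g.attrs["n_fast"] = geom.n_fast
            g.attrs["n_slow"] = geom.n_slow
            g.attrs["pixel_pitch_mm"] = geom.pixel_pitch
            g.attrs["distance_mm"] = geom.distance
            g.attrs["wavelength_A"] = geom.wavelength
            g.attrs["beam_center_fast"] = geom.beam_center[0]
            g.attrs["beam_center_slow"] = geom.beam_center[1]
            if geom.mask is not None:
                g.create_dataset("mask", data=geom.mask, **_DSET_OPTS)


def read_frames(path):
    """Read a frame container.

    Returns ``(FrameSet, DetectorGeometry | None, orientation | None)``.
    Raises ValueError on a wrong magic/version.
    """
    with h5py.File(path, "r") as f:
        if f.attrs.get("format") != FRAME_FORMAT:
            raise ValueError(f"{path}: not an {FRAME_FORMAT} container")
        if int(f.attrs.get("version", -1)) != FRAME_VERSION:
            raise ValueError(f"{path}: unsupported container version")
        frames = FrameSet(
            f["offsets"][...], f["pixels"][...].astype(np.int64), f["counts"][...],
            int(f.attrs["n_detector_pixels"]),
            f["true_angles"][...] if "true_angles" in f else None,
        )
        orientation = f["orientation"][...] if "orientation" in f else None
        geom = None
        if "geometry" in f:
            g = f["geometry"]
            geom = DetectorGeometry(
                n_fast=int(g.attrs["n_fast"]), n_slow=int(g.attrs["n_slow"]),
                pixel_pitch=float(g.attrs["pixel_pitch_mm"]),
                distance=float(g.attrs["distance_mm"]),
                wavelength=float(g.attrs["wavelength_A"]),
                beam_center=(float(g.attrs["beam_center_fast"]),
                             float(g.attrs["beam_center_slow"])),
                mask=g["mask"][...] if "mask" in g else None,
            )
    return frames, geom, orientation


def write_map(path, model: IntensityModel) -> None:
    """Write the 3D intensity as a CCP4-convention map.

    The header "cell" carries ``extent * voxel_size`` per axis so the voxel
    size survives the round trip; the values are reciprocal-space
    intensities, not a density, and the nominal cell unit is 1/Angstrom.
    """
    grid = gemmi.FloatGrid(np.ascontiguousarray(model.values, dtype=np.float32))
    n = model.grid.extent
    edge = n * model.grid.voxel_size
    grid.unit_cell = gemmi.UnitCell(edge, edge, edge, 90, 90, 90)
    grid.spacegroup = gemmi.SpaceGroup("P1")
    m = gemmi.Ccp4Map()
    m.grid = grid
    m.update_ccp4_header()
    m.write_ccp4_map(str(path))


def read_map(path) -> IntensityModel:
    """Read a map written by :func:`write_map` (observed flags are not
    stored in the map format; zero voxels read back as unobserved)."""
    m = gemmi.read_ccp4_map(str(path))
    values = np.array(m.grid, copy=True).astype(np.float64)
    n = values.shape[0]
    voxel = m.grid.unit_cell.a / n
    grid = ReciprocalGrid(voxel_size=voxel, extent=n)
    return IntensityModel(values, grid, observed=values != 0)


def write_hkl(path, reflections: ReflectionList) -> float:
    """SHELX-style fixed-width reflection file (h k l I sigma, HKLF-4
    layout), terminated by the conventional all-zero record.

    Partial reflections are omitted (they carry no intensity).  Values are
    scaled to fit the 8.2f columns; the applied scale is returned and noted
    in no way inside the file (SHELX has no header), so keep the CSV export
    alongside when absolute scale matters.
    """
    tab = reflections.accepted()
    vals = np.concatenate([np.abs(tab["I"].to_numpy(float)), np.abs(tab["sigma"].to_numpy(float))])
    vmax = np.nanmax(vals) if len(vals) else 0.0
    scale = 9999.99 / vmax if vmax > 9999.99 else 1.0
    with open(path, "w") as fh:
        for _, r in tab.iterrows():
            fh.write(f"{int(r.h):4d}{int(r.k):4d}{int(r.l):4d}"
                     f"{r.I * scale:8.2f}{r.sigma * scale:8.2f}\n")
        fh.write(f"{0:4d}{0:4d}{0:4d}{0.0:8.2f}{0.0:8.2f}\n")
    return scale


def read_hkl(path) -> pd.DataFrame:
    """Read a SHELX-style hkl file back into (h, k, l, I, sigma)."""
    rows = []
    with open(path) as fh:
        for line in fh:
            if len(line.rstrip("\n")) < 28:
                continue
            h, k, l = int(line[0:4]), int(line[4:8]), int(line[8:12])
            I, sig = float(line[12:20]), float(line[20:28])
            if h == 0 and k == 0 and l == 0 and I == 0.0:
                break
            rows.append((h, k, l, I, sig))
    return pd.DataFrame(rows, columns=["h", "k", "l", "I", "sigma"])


def write_reflections_csv(path, reflections: ReflectionList) -> None:
    reflections.table.to_csv(path, index=False)


def read_reflections_csv(path) -> ReflectionList:
    tab = pd.read_csv(path)
    tab["partial"] = tab["partial"].astype(bool)
    return ReflectionList(tab)


def write_report(path, report: dict) -> None:
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")


def read_report(path) -> dict:
    return json.loads(Path(path).read_text())
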