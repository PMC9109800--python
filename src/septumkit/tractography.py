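"""FACT streamline tractography on the primary-eigenvector field.

Fiber assignment by continuous tracking: from each seed the track follows
the fixed per-voxel primary eigenvector (no interpolation), sign-aligned
with the running direction, advancing by a fixed step. Tracking is
bidirectional; each half is capped at half the maximum length so the
concatenated track respects the total cap. A track terminates when

* the local FA drops below the stopping threshold,
* the angle between consecutive steps exceeds the turning limit,
* it leaves the volume or the mask, or
* it reaches the maximum length.

Tracks shorter than the minimum length are discarded.
"""

from __future__ import annotations

import struct
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "TractographyParams",
    "fact_track",
    "color_streamlines",
    "streamline_length",
    "write_tck",
    "write_vtk_polylines",
]


@dataclass
class TractographyParams:
    """Stopping and stepping criteria (defaults per the reference protocol)."""

    fa_stop: float = 0.1
    max_turn_angle_deg: float = 60.0
    step_mm: float = 0.05
    max_length_mm: float = 40.0
    min_length_mm: float = 1.0

    def __post_init__(self) -> None:
        if not 0 < self.step_mm < self.min_length_mm <= self.max_length_mm:
            raise ValueError("require 0 < step < min_length <= max_length")
        if not 0 < self.max_turn_angle_deg < 90:
            raise ValueError("max turn angle must be in (0, 90) degrees")


def streamline_length(points: np.ndarray) -> float:
    return float(np.linalg.norm(np.diff(points, axis=0), axis=1).sum())


def _voxel_of(pos: np.ndarray, voxel_size: np.ndarray) -> tuple:
    return tuple(np.floor(pos / voxel_size).astype(int))


def fact_track(
    v1: np.ndarray,
    fa: np.ndarray,
    mask: np.ndarray,
    voxel_size,
    seeds: np.ndarray | None = None,
    params: TractographyParams | None = None,
) -> list[np.ndarray]:
    """Deterministic FACT tracking; returns a list of (n, 3) point arrays (mm).

    ``seeds`` defaults to the center of every in-mask voxel whose FA clears
    the stopping threshold. Seeds in excluded voxels are skipped (counted in
    a single warning). The set of streamlines does not depend on seed order.
    """
    params = params or TractographyParams()
    v1 = np.asarray(v1, dtype=float)
    fa = np.asarray(fa, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    h = np.asarray(voxel_size, dtype=float)
    shape = np.array(mask.shape)

    ok = mask & (fa >= params.fa_stop)
    if seeds is None:
        idx = np.argwhere(ok)
        seeds = (idx + 0.5) * h
    seeds = np.atleast_2d(np.asarray(seeds, dtype=float))

    cos_limit = np.cos(np.deg2rad(params.max_turn_angle_deg))
    half_steps = int(np.floor((params.max_length_mm / 2.0) / params.step_mm))

    def inside(vox) -> bool:
        return all(0 <= vox[d] < shape[d] for d in range(3))

    def march(pos0, direction):
        pts = []
        pos = pos0.copy()
        prev = direction.copy()
        for _ in range(half_steps):
            vox = _voxel_of(pos, h)
            if not inside(vox) or not ok[vox]:
                break
            d = v1[vox]
            nrm = np.linalg.norm(d)
            if nrm < 1e-12:
                break
            d = d / nrm
            if np.dot(d, prev) < 0:
                d = -d
            if np.dot(d, prev) < cos_limit:
                break
            pos = pos + params.step_mm * d
            pts.append(pos.copy())
            prev = d
        return pts

    streamlines = []
    skipped = 0
    for seed in seeds:
        vox = _voxel_of(seed, h)
        if not inside(vox) or not ok[vox]:
            skipped += 1
            continue
        d0 = v1[vox]
        nrm = np.linalg.norm(d0)
        if nrm < 1e-12:
            skipped += 1
            continue
        d0 = d0 / nrm
        fwd = march(seed, d0)
        bwd = march(seed, -d0)
        pts = bwd[::-1] + [seed.copy()] + fwd
        if len(pts) < 2:
            continue
        line = np.asarray(pts)
        if streamline_length(line) >= params.min_length_mm:
            streamlines.append(line)
    if skipped:
        warnings.warn(f"skipped {skipped} seeds outside the trackable mask", stacklevel=2)
    return streamlines


def color_streamlines(
    streamlines: list[np.ndarray],
    mode: str,
    maps: dict,
    voxel_size,
    mask: np.ndarray | None = None,
) -> list[np.ndarray]:
    """Per-point scalar (HA) or color (cFA) lookup by nearest voxel.

    Points falling outside the volume or the mask inherit the last valid
    value along the track (leading invalid points take the first valid one).
    """
    if mode not in ("HA", "cFA"):
        raise ValueError("mode must be 'HA' or 'cFA'")
    arr = np.asarray(maps[mode], dtype=float)
    h = np.asarray(voxel_size, dtype=float)
    shape = arr.shape[:3]
    ncomp = 1 if arr.ndim == 3 else arr.shape[3]

    out = []
    for line in streamlines:
        vals = np.full((len(line), ncomp), np.nan)
        for i, p in enumerate(line):
            vox = _voxel_of(p, h)
            if all(0 <= vox[d] < shape[d] for d in range(3)):
                if mask is None or mask[vox]:
                    v = arr[vox]
                    if np.all(np.isfinite(v)):
                        vals[i] = v
        good = np.flatnonzero(np.isfinite(vals[:, 0]))
        if good.size:
            for i in range(len(vals)):
                if not np.isfinite(vals[i, 0]):
                    prior = good[good < i]
                    vals[i] = vals[prior[-1]] if prior.size else vals[good[0]]
        out.append(vals[:, 0] if ncomp == 1 else vals)
    return out


def write_tck(streamlines: list[np.ndarray], path) -> None:
    """Write tracks in the MRtrix .tck format (Float32LE, NaN separators)."""
    path = Path(path)
    header = "mrtrix tracks\ndatatype: Float32LE\ncount: {n}\nfile: . {off}\nEND\n"
    n = len(streamlines)
    off = 0
    for _ in range(3):  # offset depends on its own digits; iterate to fix point
        text = header.format(n=n, off=off)
        off = len(text.encode())
    with open(path, "wb") as fh:
        fh.write(header.format(n=n, off=off).encode())
        for line in streamlines:
            fh.write(np.asarray(line, dtype="<f4").tobytes())
            fh.write(struct.pack("<3f", np.nan, np.nan, np.nan))
        fh.write(struct.pack("<3f", np.inf, np.inf, np.inf))


def write_vtk_polylines(
    streamlines: list[np.ndarray], path, scalars: list[np.ndarray] | None = None
) -> None:
    """Legacy-VTK ASCII polylines with optional per-point scalars."""
    pts = np.vstack(streamlines) if streamlines else np.zeros((0, 3))
    with open(Path(path), "w") as fh:
        fh.write("# vtk DataFile Version 3.0\nseptumkit streamlines\nASCII\n")
        fh.write("DATASET POLYDATA\n")
        fh.write(f"POINTS {len(pts)} float\n")
        if len(pts):
            np.savetxt(fh, pts, fmt="%.6g")
        sizes = [len(s) for s in streamlines]
        total = sum(sizes) + len(sizes)
        fh.write(f"LINES {len(streamlines)} {total}\n")
        start = 0
        for size in sizes:
            fh.write(" ".join([str(size)] + [str(start + i) for i in range(size)]) + "\n")
            start += size
        if scalars is not None and streamlines:
            flat = np.concatenate([np.asarray(s).reshape(len(s), -1) for s in scalars])
            fh.write(f"POINT_DATA {len(pts)}\n")
            if flat.shape[1] == 1:
                fh.write("SCALARS value float 1\nLOOKUP_TABLE default\n")
                np.savetxt(fh, flat, fmt="%.6g")
            else:
                fh.write("VECTORS color float\n")
                np.savetxt(fh, flat, fmt="%.6g")
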