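"""Render electrode locations into MNI-space NIfTI volumes.

Two products: per-subject point maps (one voxel per electrode) and the
cohort mean map, where each electrode's mean coordinate is convolved with a
sphere (default radius 4 mm) whose intensity encodes the electrode's
overall positional SD — a viewer-friendly summary of where electrodes sit
and how variable they are.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Sequence

import numpy as np

from .errors import ValidationError
from .io import ElectrodePoint
from .stats import ElectrodeSummary
from .volume import VolumeGrid

#: Intensity modes for the sphere map.
INTENSITY_OVERALL_SD = "overall_sd"
INTENSITY_CONSTANT = "constant"


def mni152_grid(dtype=np.float32) -> VolumeGrid:
    """An empty 2 mm isotropic 91x109x91 grid with the conventional MNI152 affine."""
    affine = np.array([
        [-2.0, 0.0, 0.0, 90.0],
        [0.0, 2.0, 0.0, -126.0],
        [0.0, 0.0, 2.0, -72.0],
        [0.0, 0.0, 0.0, 1.0],
    ])
    return VolumeGrid(np.zeros((91, 109, 91), dtype=dtype), affine)


def _empty_like_spec(grid: VolumeGrid) -> VolumeGrid:
    return VolumeGrid(np.zeros(grid.data.shape[:3], dtype=np.float32), grid.affine)


def render_points(points: Iterable[ElectrodePoint], grid: VolumeGrid | None = None) -> VolumeGrid:
    """Set each point's nearest voxel to 1 (counts accumulate on collision)."""
    out = _empty_like_spec(grid if grid is not None else mni152_grid())
    for p in points:
        v, inside = out.nearest_voxel(p.coord)
        if not inside:
            warnings.warn(
                f"point {p.subject_id}/{p.electrode_label} at {p.coord.tolist()} "
                "falls outside the rendering grid; skipped")
            continue
        out.data[tuple(v)] += 1.0
    return out


def sphere_voxels(grid: VolumeGrid, center_mm: np.ndarray, radius_mm: float) -> np.ndarray:
    """Indices (n, 3) of voxels whose centers lie within radius of center.

    The voxel-center inclusion rule (Euclidean distance <= radius) is the
    single geometry predicate shared by all mask/sphere rasterization here.
    """
    shape = np.array(grid.data.shape[:3])
    cv = grid.world_to_voxel(center_mm)[0]
    # conservative index bounding box from the affine's column norms
    step = np.linalg.norm(np.linalg.inv(grid.affine[:3, :3]), axis=1) * radius_mm
    lo = np.maximum(np.floor(cv - step - 1).astype(int), 0)
    hi = np.minimum(np.ceil(cv + step + 1).astype(int), shape - 1)
    if np.any(lo > hi):
        return np.empty((0, 3), dtype=int)
    ranges = [np.arange(lo[a], hi[a] + 1) for a in range(3)]
    ijk = np.stack(np.meshgrid(*ranges, indexing="ij"), axis=-1).reshape(-1, 3)
    world = grid.voxel_to_world_coords(ijk)
    keep = np.linalg.norm(world - np.asarray(center_mm, dtype=float), axis=1) <= radius_mm
    return ijk[keep]


def render_sphere_map(
    summaries: Sequence[ElectrodeSummary],
    radius_mm: float = 4.0,
    intensity: str = INTENSITY_OVERALL_SD,
    grid: VolumeGrid | None = None,
) -> VolumeGrid:
    """Sphere of ``radius_mm`` at each electrode's mean coordinate.

    Sphere voxels carry the electrode's overall deviation (or the constant
    1); overlapping spheres resolve to the maximum value.
    """
    if radius_mm <= 0:
        raise ValidationError("radius_mm must be positive")
    if intensity not in (INTENSITY_OVERALL_SD, INTENSITY_CONSTANT):
        raise ValidationError(f"unknown intensity mode {intensity!r}")
    out = _empty_like_spec(grid if grid is not None else mni152_grid())
    for s in summaries:
        value = 1.0 if intensity == INTENSITY_CONSTANT else s.overall_deviation
        ijk = sphere_voxels(out, s.mean, radius_mm)
        for v in ijk:
            t = tuple(v)
            out.data[t] = max(out.data[t], value)
    return out
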