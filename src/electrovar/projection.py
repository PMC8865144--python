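"""Scalp-to-cortex projection: peeled brain surface + nearest-point snap.

Neuronavigation software projects scalp targets onto a "curvilinear" brain
reconstruction peeled to a chosen depth. The proprietary snap algorithm is
not published; here the projection is defined as the nearest point (Euclidean)
on the outer boundary of the brain mask after metric erosion by the peel
depth. The surface is represented as the cloud of boundary voxel centers,
so the projection error is bounded by the voxel size — small against the
multi-millimetre placement effects this pipeline measures.

``slice_spacing_mm`` and ``end_depth_mm`` are accepted for interface parity
with the navigation software's reconstruction parameters but do not change
the geometry; only ``peel_depth_mm`` does.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .errors import ValidationError
from .io import CORTEX, ElectrodePoint
from .volume import VolumeGrid

_FACE_STRUCTURE = ndimage.generate_binary_structure(3, 1)  # 6-connectivity


@dataclass(frozen=True)
class ProjectionParams:
    slice_spacing_mm: float = 2.0
    end_depth_mm: float = 16.0
    peel_depth_mm: float = 0.0
    max_search_mm: float = 50.0

    def __post_init__(self) -> None:
        for name in ("slice_spacing_mm", "end_depth_mm", "peel_depth_mm", "max_search_mm"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")


def peel_surface(brain_mask: VolumeGrid, peel_depth_mm: float = 0.0) -> np.ndarray:
    """World coordinates (n, 3) of the peeled mask's outer boundary voxels.

    Metric erosion: voxels whose Euclidean distance to the background
    (voxel-size aware) is <= peel depth are removed; the boundary is every
    remaining voxel with at least one background face-neighbor. Peel depth 0
    returns the boundary of the original mask.
    """
    mask = np.asarray(brain_mask.data) > 0
    if mask.ndim != 3 or not mask.any():
        raise ValidationError("brain mask must be a non-empty 3-D binary volume")
    if peel_depth_mm > 0:
        dist = ndimage.distance_transform_edt(mask, sampling=brain_mask.voxel_size)
        eroded = dist > peel_depth_mm
    else:
        eroded = mask
    if not eroded.any():
        raise ValidationError(f"peel depth {peel_depth_mm} mm empties the brain mask")
    interior = ndimage.binary_erosion(eroded, structure=_FACE_STRUCTURE, border_value=0)
    boundary = eroded & ~interior
    ijk = np.argwhere(boundary)
    return brain_mask.voxel_to_world_coords(ijk)


class SurfaceSnapper:
    """Nearest-surface-point lookup with a deterministic tie-break.

    Ties at equal distance resolve to the smallest (x, y, z) lexicographic
    surface point. Distances within ``tie_tol_mm`` of the minimum count as
    tied, so exact geometric ties stay deterministic even after float32
    round-tripping of volume affines; the tolerance is far below voxel
    spacing, so generic (non-tied) queries are unaffected.
    """

    #: distances within this of the minimum are treated as tied (mm)
    tie_tol_mm = 1e-3

    def __init__(self, surface_points: np.ndarray, params: Optional[ProjectionParams] = None):
        pts = np.asarray(surface_points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] == 0:
            raise ValidationError("surface must be a non-empty (n, 3) point cloud")
        self.params = params or ProjectionParams()
        self.points = pts
        self._tree = cKDTree(pts)

    def snap(self, p: np.ndarray) -> Optional[np.ndarray]:
        """Nearest surface point, or None when beyond the search radius."""
        p = np.asarray(p, dtype=float)
        d, i = self._tree.query(p)
        if d > self.params.max_search_mm:
            return None
        candidates = sorted(self._tree.query_ball_point(p, d + self.tie_tol_mm))
        # lex-compare on coordinates rounded well below voxel spacing, so the
        # comparison is stable against float32 affine round-off
        best = min(candidates, key=lambda j: tuple(np.round(self.points[j], 2)))
        return self.points[best].copy()


def snap_to_cortex(scalp_point: np.ndarray, surface: np.ndarray,
                   params: Optional[ProjectionParams] = None) -> Optional[np.ndarray]:
    """One-shot nearest-point projection (builds a snapper per call)."""
    return SurfaceSnapper(surface, params).snap(scalp_point)


@dataclass
class ProjectionResult:
    cortex_points: list[ElectrodePoint]
    unprojectable: list[tuple[str, str]] = field(default_factory=list)  # (subject, electrode)


def project_cohort(
    scalp_points_by_subject: Mapping[str, Iterable[ElectrodePoint]],
    brain_masks: Mapping[str, VolumeGrid],
    params: Optional[ProjectionParams] = None,
) -> ProjectionResult:
    """Project every subject's scalp points onto their own peeled brain surface.

    Unprojectable electrodes (nearest surface point beyond the search
    radius) are recorded and excluded from the output.
    """
    params = params or ProjectionParams()
    result = ProjectionResult([])
    for sid, pts in scalp_points_by_subject.items():
        if sid not in brain_masks:
            raise ValidationError(f"no brain mask for subject {sid!r}")
        surface = peel_surface(brain_masks[sid], params.peel_depth_mm)
        snapper = SurfaceSnapper(surface, params)
        for pt in pts:
            snapped = snapper.snap(pt.coord)
            if snapped is None:
                result.unprojectable.append((sid, pt.electrode_label))
                continue
            result.cortex_points.append(
                ElectrodePoint(pt.subject_id, pt.electrode_label, CORTEX, pt.space, snapped))
    return result
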