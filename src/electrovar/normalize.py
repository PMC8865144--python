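"""Cohort-level spatial normalization: subject space -> MNI space."""

from __future__ import annotations

from typing import Iterable, Mapping

from .errors import ValidationError
from .io import CohortManifest, ElectrodePoint, read_affine, read_targets
from .transforms import MNI_SPACE, SUBJECT_SPACE, AffineTransform


def normalize_points(points: Iterable[ElectrodePoint],
                     affines: Mapping[str, AffineTransform]) -> list[ElectrodePoint]:
    """Map each subject-space point with its own subject's affine.

    Scalp and cortex surfaces are mapped independently (the map does not
    care about the surface tag); missing electrodes stay missing because
    absent points simply never appear. Subjects without an affine are an
    error naming the subject.
    """
    out: list[ElectrodePoint] = []
    missing = set()
    for p in points:
        if p.space != SUBJECT_SPACE:
            raise ValidationError(
                f"{p.subject_id}/{p.electrode_label}: expected subject-space input, got {p.space!r}")
        t = affines.get(p.subject_id)
        if t is None:
            missing.add(p.subject_id)
            continue
        out.append(p.with_coord(t.apply(p.coord), space=MNI_SPACE))
    if missing:
        raise ValidationError(f"no affine for subjects: {sorted(missing)}")
    return out


def load_cohort_points(manifest: CohortManifest, surface: str) -> list[ElectrodePoint]:
    """Read every subject's target file for one surface (subject space)."""
    from .io import CORTEX, SCALP  # local to keep the namespace tidy

    pts: list[ElectrodePoint] = []
    for rec in manifest.subjects:
        path = rec.scalp_targets if surface == SCALP else rec.cortex_targets
        if path is None:
            continue
        pts.extend(read_targets(path, rec.subject_id, surface))
    return pts


def load_cohort_affines(manifest: CohortManifest) -> dict[str, AffineTransform]:
    return {rec.subject_id: read_affine(rec.affine) for rec in manifest.subjects}


def normalize_cohort(manifest: CohortManifest, surface: str) -> list[ElectrodePoint]:
    """Read one surface's targets for all subjects and map them to MNI space."""
    points = load_cohort_points(manifest, surface)
    return normalize_points(points, load_cohort_affines(manifest))
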