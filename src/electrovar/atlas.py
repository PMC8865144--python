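"""Probabilistic-atlas lookup, highest-probability labeling, region tallies.

The labeling procedure mirrors a per-coordinate atlas query: each MNI
coordinate is mapped to its nearest voxel of a 4-D probabilistic atlas and
the region with the highest stored probability is taken as that subject's
label for that electrode. Exclusion rules:

* two or more regions sharing the exact (stored-precision) maximum
  probability -> the subject is excluded for that electrode (TIE);
* no region with positive probability at the voxel, or a coordinate outside
  the volume -> excluded (NONE).

Percentages per electrode are computed over the remaining usable subjects.
A separate labeled (integer) atlas supports nearest-label lookup at the
cohort mean coordinate, emulating a cytoarchitectonic (Brodmann-style)
assignment; points beyond a search radius get no label (e.g. positions over
the cerebellum in a cortex-only parcellation).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import nibabel as nib
import numpy as np

from .errors import ValidationError

NONE = "NONE"
TIE = "TIE"
REGION = "REGION"


@dataclass(frozen=True)
class ProbAtlas:
    """4-D probabilistic atlas: last axis indexes regions, values in [0, 100]."""

    data: np.ndarray
    affine: np.ndarray  # voxel -> world
    region_names: tuple[str, ...]

    def __post_init__(self) -> None:
        d = np.asarray(self.data)
        if d.ndim != 4:
            raise ValidationError(f"probabilistic atlas must be 4-D, got shape {d.shape}")
        if d.shape[3] != len(self.region_names):
            raise ValidationError(
                f"{d.shape[3]} volumes but {len(self.region_names)} region names")
        if not np.all(np.isfinite(d)) or np.any(d < 0):
            raise ValidationError("probabilities must be finite and >= 0")
        a = np.asarray(self.affine, dtype=float)
        if a.shape != (4, 4) or abs(np.linalg.det(a[:3, :3])) <= 1e-12:
            raise ValidationError("atlas affine must be an invertible 4x4 matrix")
        object.__setattr__(self, "data", d)
        object.__setattr__(self, "affine", a)
        object.__setattr__(self, "region_names", tuple(self.region_names))

    def save(self, nifti_path: str | Path, names_path: str | Path) -> None:
        nib.save(nib.Nifti1Image(np.asarray(self.data, dtype=np.int16), self.affine),
                 str(nifti_path))
        Path(names_path).write_text("".join(f"{n}\n" for n in self.region_names))

    @classmethod
    def load(cls, nifti_path: str | Path, names_path: str | Path) -> "ProbAtlas":
        img = nib.load(str(nifti_path))
        names = tuple(l for l in Path(names_path).read_text().splitlines() if l.strip())
        return cls(np.asarray(img.dataobj), np.asarray(img.affine), names)


@dataclass(frozen=True)
class LabeledAtlas:
    """3-D integer-labeled atlas (0 = unlabeled) with names per label value."""

    data: np.ndarray
    affine: np.ndarray
    label_names: Mapping[int, str]

    def __post_init__(self) -> None:
        d = np.asarray(self.data)
        if d.ndim != 3:
            raise ValidationError("labeled atlas must be 3-D")
        present = set(np.unique(d).tolist()) - {0}
        missing = present - set(int(k) for k in self.label_names)
        if missing:
            raise ValidationError(f"labels without names: {sorted(missing)}")
        object.__setattr__(self, "data", d.astype(int))
        object.__setattr__(self, "affine", np.asarray(self.affine, dtype=float))


@dataclass(frozen=True)
class LabelOutcome:
    """Highest-probability labeling outcome for one subject x electrode."""

    subject_id: str
    electrode_label: str
    outcome: str  # REGION | TIE | NONE
    region: Optional[str] = None

    def __post_init__(self) -> None:
        if self.outcome == REGION and not self.region:
            raise ValidationError("REGION outcome requires a region name")
        if self.outcome in (TIE, NONE) and self.region is not None:
            raise ValidationError(f"{self.outcome} outcome must not carry a region")


@dataclass(frozen=True)
class RegionTally:
    """Per-electrode percentage breakdown of labeled regions over usable subjects."""

    electrode_label: str
    usable_n: int
    rows: tuple[tuple[str, float], ...]  # (region, percent) sorted desc

    @property
    def flagged_empty(self) -> bool:
        return self.usable_n == 0


def _world_to_voxel_index(affine: np.ndarray, p: np.ndarray) -> np.ndarray:
    inv = np.linalg.inv(affine)
    return np.rint(np.asarray(p, dtype=float) @ inv[:3, :3].T + inv[:3, 3]).astype(int)


def query_prob_atlas(atlas: ProbAtlas, p: np.ndarray) -> list[tuple[str, float]]:
    """All regions with positive probability at the voxel nearest ``p``.

    Returns (name, probability) pairs sorted by descending probability then
    name; empty for points outside the grid or at all-zero voxels.
    """
    p = np.asarray(p, dtype=float)
    if p.shape != (3,) or not np.all(np.isfinite(p)):
        raise ValidationError(f"query point must be a finite 3-vector, got {p!r}")
    v = _world_to_voxel_index(atlas.affine, p)
    shape = np.array(atlas.data.shape[:3])
    if np.any(v < 0) or np.any(v >= shape):
        return []
    probs = np.asarray(atlas.data[tuple(v)], dtype=float)
    hits = [(atlas.region_names[i], float(probs[i])) for i in np.nonzero(probs > 0)[0]]
    hits.sort(key=lambda x: (-x[1], x[0]))
    return hits


def max_label(query_result: Sequence[tuple[str, float]],
              subject_id: str = "", electrode_label: str = "") -> LabelOutcome:
    """Highest-probability rule with tie/no-label exclusions.

    Ties use exact equality of stored-precision probabilities (atlas values
    are kept as integers), so a tie means the atlas genuinely reports the
    same maximum for several regions.
    """
    if not query_result:
        return LabelOutcome(subject_id, electrode_label, NONE)
    top = max(p for _, p in query_result)
    winners = [name for name, p in query_result if p == top]
    if len(winners) > 1:
        return LabelOutcome(subject_id, electrode_label, TIE)
    return LabelOutcome(subject_id, electrode_label, REGION, winners[0])


def tally_regions(outcomes: Sequence[LabelOutcome]) -> RegionTally:
    """Percentage of usable subjects per region for one electrode.

    TIE and NONE outcomes are excluded; percentages are over the remaining
    usable subjects and sum to 100 (within float rounding) whenever any
    subject is usable.
    """
    if not outcomes:
        raise ValidationError("tally_regions requires at least one outcome")
    labels = {o.electrode_label for o in outcomes}
    if len(labels) != 1:
        raise ValidationError(f"outcomes mix electrodes: {sorted(labels)}")
    counts: dict[str, int] = {}
    for o in outcomes:
        if o.outcome == REGION:
            counts[o.region] = counts.get(o.region, 0) + 1
    usable = sum(counts.values())
    if usable == 0:
        return RegionTally(next(iter(labels)), 0, ())
    rows = tuple(sorted(((r, 100.0 * c / usable) for r, c in counts.items()),
                        key=lambda x: (-x[1], x[0])))
    return RegionTally(next(iter(labels)), usable, rows)


def mean_usable(tallies: Sequence[RegionTally]) -> tuple[float, float]:
    """Mean and sample SD (n-1) of usable subject counts across electrodes."""
    if not tallies:
        raise ValidationError("mean_usable requires at least one tally")
    ns = np.array([t.usable_n for t in tallies], dtype=float)
    sd = float(np.std(ns, ddof=1)) if len(ns) > 1 else float("nan")
    return float(ns.mean()), sd


def nearest_label(atlas: LabeledAtlas, p: np.ndarray,
                  max_radius_mm: float = 10.0) -> Optional[str]:
    """Label at ``p``'s voxel, else the nearest labeled voxel within radius.

    Ties at equal distance resolve to the smaller label integer; returns
    None when no labeled voxel lies within ``max_radius_mm``.
    """
    p = np.asarray(p, dtype=float)
    if p.shape != (3,) or not np.all(np.isfinite(p)):
        raise ValidationError("query point must be a finite 3-vector")
    v = _world_to_voxel_index(atlas.affine, p)
    shape = np.array(atlas.data.shape)
    if np.all(v >= 0) and np.all(v < shape):
        val = int(atlas.data[tuple(v)])
        if val != 0:
            return atlas.label_names[val]
    labeled = np.argwhere(atlas.data != 0)
    if labeled.size == 0:
        return None
    world = labeled @ atlas.affine[:3, :3].T + atlas.affine[:3, 3]
    dists = np.linalg.norm(world - p, axis=1)
    values = atlas.data[tuple(labeled.T)]
    order = np.lexsort((values, dists))
    best = order[0]
    if dists[best] > max_radius_mm:
        return None
    return atlas.label_names[int(values[best])]


def hemisphere_of(mean_x: float, midline_mm: float = 2.0) -> str:
    """Mechanical hemisphere call from the sign of mean x (|x| small -> midline)."""
    if abs(mean_x) < midline_mm:
        return "midline"
    return "left" if mean_x < 0 else "right"


def label_cohort(
    atlas: ProbAtlas,
    points_by_subject: Mapping[str, Iterable],
) -> tuple[list[LabelOutcome], list[RegionTally]]:
    """Label every (subject, electrode) MNI point and tally per electrode."""
    outcomes: list[LabelOutcome] = []
    by_electrode: dict[str, list[LabelOutcome]] = {}
    for sid, pts in points_by_subject.items():
        for pt in pts:
            out = max_label(query_prob_atlas(atlas, pt.coord), sid, pt.electrode_label)
            outcomes.append(out)
            by_electrode.setdefault(pt.electrode_label, []).append(out)
    tallies = [tally_regions(v) for _, v in sorted(by_electrode.items())]
    return outcomes, tallies
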