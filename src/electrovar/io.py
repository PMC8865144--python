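"""On-disk formats: electrode target tables, affine matrices, manifests, CSVs.

Target files are plain-text tables, one electrode per row, in the minimal
dialect ``label, x, y, z`` (tab- or comma-separated, coordinates in mm).
Lines starting with ``#`` and a single optional header row are skipped on
read; extra trailing columns are tolerated (neuronavigation exports often
carry orientation vectors) but never written. Reads are permissive, writes
are strict.

Missing electrodes are simply absent rows — no sentinel coordinates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import IntegrityError, ParseError, ValidationError
from .transforms import MNI_SPACE, SUBJECT_SPACE, AffineTransform

SCALP = "scalp"
CORTEX = "cortex"
SURFACES = (SCALP, CORTEX)
SPACES = (SUBJECT_SPACE, MNI_SPACE)


@dataclass(frozen=True)
class ElectrodePoint:
    """One electrode's 3-D position for one subject, surface and space."""

    subject_id: str
    electrode_label: str
    surface: str  # "scalp" | "cortex"
    space: str  # "subject" | "mni"
    coord: np.ndarray  # (3,) mm

    def __post_init__(self) -> None:
        if not self.electrode_label:
            raise ValidationError("electrode_label must be non-empty")
        if self.surface not in SURFACES:
            raise ValidationError(f"surface must be one of {SURFACES}, got {self.surface!r}")
        if self.space not in SPACES:
            raise ValidationError(f"space must be one of {SPACES}, got {self.space!r}")
        c = np.asarray(self.coord, dtype=float)
        if c.shape != (3,) or not np.all(np.isfinite(c)):
            raise ValidationError(f"coord must be a finite 3-vector, got {self.coord!r}")
        object.__setattr__(self, "coord", c)

    def with_coord(self, coord: np.ndarray, space: Optional[str] = None) -> "ElectrodePoint":
        return replace(self, coord=np.asarray(coord, dtype=float), space=space or self.space)


@dataclass(frozen=True)
class SubjectRecord:
    """Per-subject entry of a cohort manifest (paths relative to the manifest)."""

    subject_id: str
    cap_size_cm: Optional[float]
    scalp_targets: Path
    cortex_targets: Optional[Path]
    affine: Path
    brain_mask: Optional[Path] = None


@dataclass(frozen=True)
class CohortManifest:
    subjects: tuple[SubjectRecord, ...]

    def __post_init__(self) -> None:
        ids = [s.subject_id for s in self.subjects]
        if len(set(ids)) != len(ids):
            raise IntegrityError("duplicate subject_ids in manifest")

    def subject(self, subject_id: str) -> SubjectRecord:
        for s in self.subjects:
            if s.subject_id == subject_id:
                return s
        raise KeyError(subject_id)


# ---------------------------------------------------------------------------
# electrode target tables


def _split_row(line: str) -> list[str]:
    sep = "\t" if "\t" in line else ","
    return [f.strip() for f in line.split(sep)]


def read_targets(path: str | Path, subject_id: str, surface: str,
                 space: str = SUBJECT_SPACE) -> list[ElectrodePoint]:
    """Read a target table into one :class:`ElectrodePoint` per data row.

    Comment lines (``#``) and one optional non-numeric header row are
    skipped. Rows with fewer than 4 fields raise :class:`ParseError` naming
    the line; duplicate labels raise :class:`IntegrityError`.
    """
    path = Path(path)
    points: list[ElectrodePoint] = []
    seen: set[str] = set()
    header_allowed = True
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = _split_row(line)
            if len(fields) < 4:
                raise ParseError(f"{path}:{lineno}: expected at least 4 fields, got {len(fields)}")
            try:
                coord = [float(fields[1]), float(fields[2]), float(fields[3])]
            except ValueError:
                if header_allowed:
                    header_allowed = False
                    continue
                raise ParseError(f"{path}:{lineno}: non-numeric coordinates {fields[1:4]!r}")
            header_allowed = False
            label = fields[0]
            if not label:
                raise ParseError(f"{path}:{lineno}: empty electrode label")
            if not all(math.isfinite(v) for v in coord):
                raise ParseError(f"{path}:{lineno}: non-finite coordinate")
            key = label.upper()
            if key in seen:
                raise IntegrityError(f"{path}:{lineno}: duplicate electrode label {label!r}")
            seen.add(key)
            points.append(ElectrodePoint(subject_id, label, surface, space, np.array(coord)))
    return points


def write_targets(points: Iterable[ElectrodePoint], path: str | Path) -> None:
    """Write a strict tab-separated ``label x y z`` table (full precision)."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("electrode\tx\ty\tz\n")
        for p in points:
            fh.write(f"{p.electrode_label}\t{p.coord[0]:.17g}\t{p.coord[1]:.17g}\t{p.coord[2]:.17g}\n")


# ---------------------------------------------------------------------------
# affine matrices


def read_affine(path: str | Path, from_space: str = SUBJECT_SPACE,
                to_space: str = MNI_SPACE) -> AffineTransform:
    """Read a whitespace-separated 4x4 affine; validates shape and invertibility."""
    path = Path(path)
    try:
        m = np.loadtxt(path, comments="#", ndmin=2)
    except ValueError as exc:
        raise ParseError(f"{path}: could not parse affine matrix: {exc}") from exc
    if m.shape != (4, 4):
        raise ValidationError(f"{path}: affine must be 4x4, got {m.shape}")
    try:
        return AffineTransform(m, from_space, to_space)
    except ValidationError as exc:
        raise ValidationError(f"{path}: {exc}") from exc


def write_affine(t: AffineTransform, path: str | Path) -> None:
    np.savetxt(path, t.matrix, fmt="%.17g")


# ---------------------------------------------------------------------------
# summary / tally CSVs (shapes of the published per-electrode tables)

SUMMARY_COLUMNS = [
    "electrode", "surface", "n",
    "mean_x", "mean_y", "mean_z",
    "sd_x", "sd_y", "sd_z",
    "skew_x", "skew_y", "skew_z",
    "overall_deviation",
]

TALLY_COLUMNS = ["electrode", "usable_n", "region", "percent"]


def write_summary_csv(summaries: Sequence, path: str | Path) -> None:
    """Write per-electrode summaries (mean/SD/skewness per axis + overall SD)."""
    if not summaries:
        raise ValidationError("no summaries to write")
    rows = []
    for s in sorted(summaries, key=lambda s: s.electrode_label):
        rows.append({
            "electrode": s.electrode_label,
            "surface": s.surface,
            "n": s.n,
            "mean_x": s.mean[0], "mean_y": s.mean[1], "mean_z": s.mean[2],
            "sd_x": s.sd[0], "sd_y": s.sd[1], "sd_z": s.sd[2],
            "skew_x": s.skewness[0], "skew_y": s.skewness[1], "skew_z": s.skewness[2],
            "overall_deviation": s.overall_deviation,
        })
    pd.DataFrame(rows, columns=SUMMARY_COLUMNS).to_csv(path, index=False, float_format="%.12g")


def read_summary_csv(path: str | Path, surface: Optional[str] = None) -> list:
    """Reload a summary CSV into :class:`~electrovar.stats.ElectrodeSummary` objects."""
    from .stats import ElectrodeSummary  # local import to avoid cycle

    df = pd.read_csv(path)
    out = []
    for _, r in df.iterrows():
        if surface is not None and r["surface"] != surface:
            continue
        out.append(ElectrodeSummary(
            electrode_label=str(r["electrode"]),
            surface=str(r["surface"]),
            n=int(r["n"]),
            mean=np.array([r["mean_x"], r["mean_y"], r["mean_z"]], dtype=float),
            sd=np.array([r["sd_x"], r["sd_y"], r["sd_z"]], dtype=float),
            skewness=np.array([r["skew_x"], r["skew_y"], r["skew_z"]], dtype=float),
        ))
    return out


def write_tally_csv(tallies: Sequence, path: str | Path) -> None:
    """Write per-electrode region percentage tallies (one region per row)."""
    if not tallies:
        raise ValidationError("no tallies to write")
    rows = []
    for t in sorted(tallies, key=lambda t: t.electrode_label):
        if not t.rows:
            rows.append({"electrode": t.electrode_label, "usable_n": t.usable_n,
                         "region": "", "percent": float("nan")})
        for region, percent in t.rows:
            rows.append({"electrode": t.electrode_label, "usable_n": t.usable_n,
                         "region": region, "percent": percent})
    pd.DataFrame(rows, columns=TALLY_COLUMNS).to_csv(path, index=False, float_format="%.12g")


# ---------------------------------------------------------------------------
# cohort manifest (YAML)


def _resolve(base: Path, p: Optional[str]) -> Optional[Path]:
    if p is None:
        return None
    q = Path(p)
    return q if q.is_absolute() else (base / q)


def read_manifest(path: str | Path, check_paths: bool = True) -> CohortManifest:
    """Load a YAML cohort manifest; referenced paths must exist."""
    path = Path(path)
    with path.open() as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "subjects" not in doc:
        raise ParseError(f"{path}: manifest must be a mapping with a 'subjects' list")
    base = path.parent
    subjects = []
    for entry in doc["subjects"]:
        try:
            rec = SubjectRecord(
                subject_id=str(entry["subject_id"]),
                cap_size_cm=(None if entry.get("cap_size_cm") is None
                             else float(entry["cap_size_cm"])),
                scalp_targets=_resolve(base, entry["scalp_targets"]),
                cortex_targets=_resolve(base, entry.get("cortex_targets")),
                affine=_resolve(base, entry["affine"]),
                brain_mask=_resolve(base, entry.get("brain_mask")),
            )
        except KeyError as exc:
            raise ParseError(f"{path}: manifest entry missing key {exc}") from exc
        if check_paths:
            for p in (rec.scalp_targets, rec.cortex_targets, rec.affine, rec.brain_mask):
                if p is not None and not p.exists():
                    raise IntegrityError(f"{path}: referenced path does not exist: {p}")
        subjects.append(rec)
    return CohortManifest(tuple(subjects))


def write_manifest(manifest: CohortManifest, path: str | Path) -> None:
    """Write a manifest with paths stored relative to the manifest file."""
    path = Path(path)
    base = path.parent.resolve()

    def rel(p: Optional[Path]) -> Optional[str]:
        if p is None:
            return None
        try:
            return str(Path(p).resolve().relative_to(base))
        except ValueError:
            return str(p)

    doc = {"subjects": [
        {"subject_id": s.subject_id,
         "cap_size_cm": s.cap_size_cm,
         "scalp_targets": rel(s.scalp_targets),
         "cortex_targets": rel(s.cortex_targets),
         "affine": rel(s.affine),
         "brain_mask": rel(s.brain_mask)}
        for s in manifest.subjects
    ]}
    with path.open("w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
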