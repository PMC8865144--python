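"""Synthetic multi-subject electrode cohorts with known ground truth.

Real inputs to this pipeline are neuronavigation target exports (electrode
positions marked on MRI-visible gel artifacts) plus per-subject affines to
MNI space. This module emulates that data so every downstream stage can be
tested end-to-end with known truth:

* a head is an axis-aligned ellipsoid pair (scalp outside, brain inside),
  scaled by cap-size category (54/56/58 cm circumference classes);
* electrode positions = montage directions, perturbed by a per-subject cap
  transform (small rotation + translation + scale: correlated "cap shift"
  variance), projected radially onto the scalp ellipsoid, plus per-electrode
  iid Gaussian jitter (independent placement variance);
* each subject's coordinates are expressed in a randomized subject frame,
  and the exact frame-to-template affine is returned/written — so spatial
  normalization is exercised nontrivially but invertibly;
* electrodes go missing independently at a configurable rate;
* random streams are keyed by (seed, subject, electrode), so missingness of
  one electrode never shifts another electrode's draws.

Synthetic atlas volumes (probabilistic blobs with a constructed tie voxel
and guaranteed background) stand in for real cortical atlases.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .atlas import ProbAtlas
from .errors import ConfigurationError, ValidationError
from .io import (
    SCALP,
    CohortManifest,
    ElectrodePoint,
    SubjectRecord,
    write_affine,
    write_manifest,
    write_targets,
)
from .montage import Montage, default_montage, ellipsoid_point
from .transforms import MNI_SPACE, SUBJECT_SPACE, AffineTransform
from .volume import VolumeGrid


@dataclass(frozen=True)
class HeadModel:
    """Ellipsoidal head: scalp and (strictly interior) brain surfaces."""

    center: np.ndarray  # (3,) mm
    scalp_semiaxes: np.ndarray  # (3,) mm
    brain_semiaxes: np.ndarray  # (3,) mm
    cap_size_cm: Optional[float] = None

    def __post_init__(self) -> None:
        c = np.asarray(self.center, dtype=float)
        s = np.asarray(self.scalp_semiaxes, dtype=float)
        b = np.asarray(self.brain_semiaxes, dtype=float)
        if s.shape != (3,) or b.shape != (3,) or c.shape != (3,):
            raise ValidationError("head model vectors must have length 3")
        if np.any(s <= 0) or np.any(b <= 0):
            raise ValidationError("semiaxes must be positive")
        if np.any(b >= s):
            raise ValidationError("brain semiaxes must be strictly inside scalp semiaxes")
        if self.cap_size_cm is not None and self.cap_size_cm <= 0:
            raise ValidationError("cap size must be positive")
        object.__setattr__(self, "center", c)
        object.__setattr__(self, "scalp_semiaxes", s)
        object.__setattr__(self, "brain_semiaxes", b)


#: Reference head (cap size 56 cm). Scalp chosen so the vertex sits near
#: z = 100 mm, matching typical adult MNI scalp extent.
DEFAULT_HEAD = HeadModel(
    center=np.array([0.0, -10.0, 15.0]),
    scalp_semiaxes=np.array([80.0, 98.0, 85.0]),
    brain_semiaxes=np.array([68.0, 85.0, 72.0]),
    cap_size_cm=56.0,
)

REFERENCE_CAP_CM = 56.0


def head_for_cap_size(cap_size_cm: Optional[float], base: HeadModel = DEFAULT_HEAD,
                      geometry_effect: float = 1.0) -> HeadModel:
    """Scale the reference head by cap circumference (missing size -> reference).

    ``geometry_effect`` attenuates the deterministic head-size difference
    between cap categories (0 = identical heads regardless of cap size).
    """
    scale = 1.0 if cap_size_cm is None else 1.0 + (cap_size_cm / REFERENCE_CAP_CM - 1.0) * geometry_effect
    return HeadModel(
        center=base.center,
        scalp_semiaxes=base.scalp_semiaxes * scale,
        brain_semiaxes=base.brain_semiaxes * scale,
        cap_size_cm=cap_size_cm,
    )


def assign_cap_sizes(n_subjects: int) -> list[Optional[float]]:
    """Cap-size categories for a cohort: 54/56/58 cm plus one unrecorded.

    At the default n=20 the split is exactly 4/12/3 with one unrecorded;
    other sizes use largest-remainder proportions of that split.
    """
    categories: list[Optional[float]] = [54.0, 56.0, 58.0, None]
    weights = np.array([4, 12, 3, 1], dtype=float) / 20.0
    exact = weights * n_subjects
    counts = np.floor(exact).astype(int)
    for _ in range(n_subjects - counts.sum()):
        i = int(np.argmax(exact - counts))
        counts[i] += 1
    out: list[Optional[float]] = []
    for cat, k in zip(categories, counts):
        out.extend([cat] * int(k))
    return out[:n_subjects]


@dataclass(frozen=True)
class SimulationConfig:
    """Noise model and cohort-size parameters for the generator.

    ``jitter_sd_mm`` is the per-axis SD of independent per-electrode
    placement error; the three ``cap_*`` parameters control the correlated
    per-subject cap perturbation (rotation SD in degrees, translation SD in
    mm, multiplicative scale SD).
    """

    n_subjects: int = 20
    jitter_sd_mm: tuple[float, float, float] = (3.0, 4.5, 5.5)
    cap_rotation_sd_deg: float = 2.0
    cap_translation_sd_mm: float = 1.5
    cap_scale_sd: float = 0.015
    missing_electrode_rate: float = 0.01
    cap_geometry_effect: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ConfigurationError("n_subjects must be positive")
        j = np.asarray(self.jitter_sd_mm, dtype=float)
        if j.shape != (3,) or np.any(j < 0):
            raise ConfigurationError("jitter_sd_mm must be a non-negative 3-vector")
        for name in ("cap_rotation_sd_deg", "cap_translation_sd_mm", "cap_scale_sd",
                     "cap_geometry_effect"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if not 0.0 <= self.missing_electrode_rate <= 1.0:
            raise ConfigurationError("missing_electrode_rate must be in [0, 1]")
        if self.seed < 0:
            raise ConfigurationError("seed must be a non-negative integer")

    def replace(self, **kw) -> "SimulationConfig":
        return dataclasses.replace(self, **kw)

    @classmethod
    def noiseless(cls, seed: int = 0, n_subjects: int = 20) -> "SimulationConfig":
        """Fully degenerate cohort: identical heads, no jitter, no missingness."""
        return cls(n_subjects=n_subjects, jitter_sd_mm=(0.0, 0.0, 0.0),
                   cap_rotation_sd_deg=0.0, cap_translation_sd_mm=0.0,
                   cap_scale_sd=0.0, missing_electrode_rate=0.0,
                   cap_geometry_effect=0.0, seed=seed)


def _rotation_from_vector(rotvec: np.ndarray) -> np.ndarray:
    """Rotation matrix from an axis-angle vector (Rodrigues)."""
    angle = float(np.linalg.norm(rotvec))
    if angle < 1e-15:
        return np.eye(3)
    k = rotvec / angle
    kx = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
    return np.eye(3) + np.sin(angle) * kx + (1 - np.cos(angle)) * (kx @ kx)


def _random_rigid_frame(rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """A uniformly random rotation (via normalized quaternion) + translation."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    rot = np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])
    trans = rng.uniform(-50.0, 50.0, size=3)
    return rot, trans


def simulate_subject(
    montage: Montage,
    head: HeadModel,
    config: SimulationConfig,
    subject_index: int,
) -> tuple[list[ElectrodePoint], AffineTransform]:
    """Simulate one subject's scalp electrode targets in a random subject frame.

    Returns the non-missing scalp points (subject space) and the exact
    affine mapping that subject space back to the canonical template space.
    With all noise parameters zero, applying the affine reproduces the
    canonical montage-on-scalp positions to numeric precision.
    """
    if subject_index < 0 or subject_index >= config.n_subjects:
        raise ConfigurationError(
            f"subject_index {subject_index} out of range for n_subjects={config.n_subjects}")
    subject_id = f"s{subject_index:02d}"
    rng_subject = np.random.default_rng(
        np.random.SeedSequence((config.seed, subject_index)))

    # correlated cap perturbation (fixed draw order)
    rotvec = np.deg2rad(rng_subject.normal(0.0, config.cap_rotation_sd_deg, size=3))
    cap_rot = _rotation_from_vector(rotvec)
    cap_shift = rng_subject.normal(0.0, config.cap_translation_sd_mm, size=3)
    cap_scale = max(1.0 + rng_subject.normal(0.0, config.cap_scale_sd), 0.2)

    # randomized subject frame: canonical -> subject is p' = R p + t
    frame_rot, frame_shift = _random_rigid_frame(rng_subject)
    # exact inverse rigid map: subject -> canonical template (MNI here)
    truth = np.eye(4)
    truth[:3, :3] = frame_rot.T
    truth[:3, 3] = -frame_rot.T @ frame_shift
    truth_affine = AffineTransform(truth, SUBJECT_SPACE, MNI_SPACE)

    jitter_sd = np.asarray(config.jitter_sd_mm, dtype=float)
    cap_center = head.center + cap_shift
    cap_semiaxes = head.scalp_semiaxes * cap_scale

    points: list[ElectrodePoint] = []
    for electrode_index, (label, direction) in enumerate(montage.entries):
        rng_e = np.random.default_rng(
            np.random.SeedSequence((config.seed, subject_index, electrode_index)))
        missing_draw = rng_e.random()
        jitter = rng_e.normal(0.0, 1.0, size=3) * jitter_sd
        if missing_draw < config.missing_electrode_rate:
            continue
        canonical = ellipsoid_point(cap_rot @ direction, cap_center, cap_semiaxes) + jitter
        subj = frame_rot @ canonical + frame_shift
        points.append(ElectrodePoint(subject_id, label, SCALP, SUBJECT_SPACE, subj))
    return points, truth_affine


# ---------------------------------------------------------------------------
# volumes


def _centered_affine(shape: Sequence[int], voxel_size: Sequence[float],
                     center: np.ndarray) -> np.ndarray:
    """Voxel->world affine for a grid whose physical center is ``center``."""
    shape = np.asarray(shape, dtype=int)
    vox = np.asarray(voxel_size, dtype=float)
    affine = np.eye(4)
    affine[:3, :3] = np.diag(vox)
    affine[:3, 3] = np.asarray(center, dtype=float) - vox * (shape - 1) / 2.0
    return affine


def _ellipsoid_mask(shape: Sequence[int], affine: np.ndarray,
                    center: np.ndarray, semiaxes: np.ndarray) -> np.ndarray:
    idx = np.indices(tuple(shape)).reshape(3, -1).T.astype(float)
    world = idx @ affine[:3, :3].T + affine[:3, 3]
    q = ((world - center) / semiaxes) ** 2
    return (q.sum(axis=1) <= 1.0).reshape(tuple(shape))


def make_head_volumes(
    head: HeadModel,
    shape: Sequence[int] = (96, 112, 96),
    voxel_size: Sequence[float] = (2.0, 2.0, 2.0),
) -> tuple[VolumeGrid, VolumeGrid]:
    """Voxelize the head: (scalp mask, brain mask), voxel-center-inside rule.

    The grid is centered on the head; an ellipsoid that does not fit inside
    the grid is an error.
    """
    shape = np.asarray(shape, dtype=int)
    vox = np.asarray(voxel_size, dtype=float)
    if np.any(shape <= 0) or np.any(vox <= 0):
        raise ValidationError("grid shape and voxel size must be positive")
    affine = _centered_affine(shape, vox, head.center)
    lo = affine[:3, 3]
    hi = lo + vox * (shape - 1)
    if np.any(head.center - head.scalp_semiaxes < lo) or np.any(head.center + head.scalp_semiaxes > hi):
        raise ValidationError("scalp ellipsoid exceeds the requested grid")
    scalp = _ellipsoid_mask(shape, affine, head.center, head.scalp_semiaxes)
    brain = _ellipsoid_mask(shape, affine, head.center, head.brain_semiaxes)
    return VolumeGrid(scalp, affine), VolumeGrid(brain, affine)


@dataclass(frozen=True)
class SyntheticProbAtlas:
    """A generated probabilistic atlas plus the ground truth used to build it."""

    atlas: ProbAtlas
    region_centers_world: np.ndarray  # (n_regions, 3)
    tie_voxel: Optional[tuple[int, int, int]]  # constructed two-way tie
    blob_radius_mm: float


def make_synthetic_prob_atlas(
    shape: Sequence[int],
    voxel_size: Sequence[float],
    n_regions: int,
    seed: int,
    center: Sequence[float] = (0.0, 0.0, 0.0),
) -> SyntheticProbAtlas:
    """Random contiguous probability blobs with a tie voxel and background.

    Probabilities are integers in [0, 100], radially decreasing within each
    spherical blob. When ``n_regions >= 2`` the first two blobs overlap and
    one voxel midway between their centers is forced to an exact two-way tie
    (both at 50); grid corners are guaranteed all-zero background.
    """
    shape = np.asarray(shape, dtype=int)
    vox = np.asarray(voxel_size, dtype=float)
    if np.any(shape <= 0):
        raise ValidationError("grid shape must be positive")
    if n_regions < 1:
        raise ValidationError("n_regions must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0xA71A5)))
    affine = _centered_affine(shape, vox, np.asarray(center, dtype=float))
    extent = vox * shape
    radius = 0.2 * float(extent.min())

    centers_vox = np.empty((n_regions, 3))
    centers_vox[0] = (shape - 1) * rng.uniform(0.35, 0.65, size=3)
    if n_regions >= 2:
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        centers_vox[1] = centers_vox[0] + (0.8 * radius) * direction / vox
    for i in range(2, n_regions):
        centers_vox[i] = (shape - 1) * rng.uniform(0.3, 0.7, size=3)

    idx = np.indices(tuple(shape)).reshape(3, -1).T.astype(float)
    data = np.zeros((*shape, n_regions), dtype=np.int16)
    for r in range(n_regions):
        dist = np.linalg.norm((idx - centers_vox[r]) * vox, axis=1)
        inside = dist <= radius
        prob = np.rint(100.0 * (1.0 - 0.9 * dist / radius)).astype(np.int16)
        vol = np.zeros(idx.shape[0], dtype=np.int16)
        vol[inside] = prob[inside]
        data[..., r] = vol.reshape(tuple(shape))

    tie_voxel: Optional[tuple[int, int, int]] = None
    if n_regions >= 2:
        mid = np.rint((centers_vox[0] + centers_vox[1]) / 2.0).astype(int)
        mid = np.clip(mid, 0, shape - 1)
        tie_voxel = tuple(int(v) for v in mid)
        data[tie_voxel] = 0
        data[tie_voxel + (0,)] = 50
        data[tie_voxel + (1,)] = 50

    names = tuple(f"region_{i:02d}" for i in range(n_regions))
    atlas = ProbAtlas(data, affine, names)
    centers_world = centers_vox @ affine[:3, :3].T + affine[:3, 3]
    return SyntheticProbAtlas(atlas, centers_world, tie_voxel, radius)


def make_single_region_atlas(
    head: HeadModel,
    shape: Sequence[int] = (64, 72, 64),
    voxel_size: Sequence[float] = (3.0, 3.0, 3.0),
    name: str = "synthetic_cortex",
    margin_mm: float = 8.0,
) -> ProbAtlas:
    """One region at probability 100 covering the brain ellipsoid (+margin).

    A controlled atlas for end-to-end runs: every cortical point of the head
    model falls inside the single region, so tallies should be 100%.
    """
    shape = np.asarray(shape, dtype=int)
    vox = np.asarray(voxel_size, dtype=float)
    affine = _centered_affine(shape, vox, head.center)
    mask = _ellipsoid_mask(shape, affine, head.center, head.brain_semiaxes + margin_mm)
    data = np.zeros((*shape, 1), dtype=np.int16)
    data[..., 0] = np.where(mask, 100, 0)
    return ProbAtlas(data, affine, (name,))


# ---------------------------------------------------------------------------
# cohort on disk


def simulate_cohort(
    config: SimulationConfig,
    out_dir: str | Path,
    montage: Optional[Montage] = None,
    write_masks: bool = True,
    mask_shape: Sequence[int] = (96, 112, 96),
    mask_voxel_mm: float = 2.0,
) -> CohortManifest:
    """Generate a full cohort on disk: targets, affines, masks, manifest.

    Writes, per subject, a scalp target table and the subject->MNI affine;
    brain-mask NIfTI volumes are expressed in each subject's own frame
    (shared voxel data per cap-size category, subject-specific affine).
    Returns the manifest (also written as ``manifest.yaml``).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    montage = montage or default_montage()
    caps = assign_cap_sizes(config.n_subjects)
    mask_cache: dict[Optional[float], tuple[np.ndarray, np.ndarray]] = {}

    records = []
    for i in range(config.n_subjects):
        head = head_for_cap_size(caps[i], geometry_effect=config.cap_geometry_effect)
        points, truth = simulate_subject(montage, head, config, i)
        sid = f"s{i:02d}"
        scalp_path = out_dir / f"{sid}_scalp.txt"
        affine_path = out_dir / f"{sid}_affine.txt"
        write_targets(points, scalp_path)
        write_affine(truth, affine_path)
        mask_path = None
        if write_masks:
            if caps[i] not in mask_cache:
                _, brain = make_head_volumes(head, mask_shape, (mask_voxel_mm,) * 3)
                mask_cache[caps[i]] = (brain.data, brain.affine)
            brain_data, canonical_affine = mask_cache[caps[i]]
            # canonical-grid mask re-expressed in the subject frame:
            # voxel -> subject-world = (MNI -> subject) @ (voxel -> MNI-world)
            subj_affine = truth.inverse().matrix @ canonical_affine
            mask_path = out_dir / f"{sid}_brain_mask.nii.gz"
            VolumeGrid(brain_data.astype(np.uint8), subj_affine).save(mask_path)
        records.append(SubjectRecord(
            subject_id=sid,
            cap_size_cm=caps[i],
            scalp_targets=scalp_path,
            cortex_targets=None,
            affine=affine_path,
            brain_mask=mask_path,
        ))
    manifest = CohortManifest(tuple(records))
    write_manifest(manifest, out_dir / "manifest.yaml")
    return manifest
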