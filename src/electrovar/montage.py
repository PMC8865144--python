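"""The 65-channel 10-10 electrode montage as unit directions on the head.

The 10-10 system places electrodes at 10%/5% proportional distances along
skull landmark arcs (nasion-inion and left-right preauricular). On an
idealized head, each 10% of the nasion-inion arc corresponds to an 18 deg
step of polar angle from the vertex (Cz). The montage here is built from
those angular proportions directly:

* the midline chain FPZ..AFZ..FZ..FCZ..CZ..CPZ..PZ..POZ..OZ at 18 deg steps;
* the 10% circumferential ring (FP1/2 .. O1/2) at 72 deg polar angle,
  azimuth steps of 18 deg;
* intermediate electrodes by spherical interpolation between the midline
  electrode and the ring electrode of the same coronal row;
* FT9/FT10 and TP9/TP10 one 10% step below the ring (polar 108 deg), so
  they sit below the equator and project near inferior temporal cortex and
  the cerebellum.

Directions are unit vectors in RAS orientation (+x right, +y anterior,
+z superior); actual positions are obtained by radial projection onto a
subject's scalp surface.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError

_RING_DEG = 72.0  # polar angle of the 10% ring
_STEP_DEG = 18.0  # one 10% step along a 180-degree arc


@dataclass(frozen=True)
class Montage:
    """Ordered (label, unit direction) pairs; labels unique."""

    entries: tuple[tuple[str, np.ndarray], ...]

    def __post_init__(self) -> None:
        labels = [lab for lab, _ in self.entries]
        if len(set(labels)) != len(labels):
            raise ValidationError("montage labels must be unique")
        for lab, d in self.entries:
            if not np.isclose(np.linalg.norm(d), 1.0, atol=1e-9):
                raise ValidationError(f"direction for {lab} is not unit length")

    @property
    def labels(self) -> list[str]:
        return [lab for lab, _ in self.entries]

    @property
    def directions(self) -> np.ndarray:
        return np.array([d for _, d in self.entries])

    def __len__(self) -> int:
        return len(self.entries)

    def direction(self, label: str) -> np.ndarray:
        for lab, d in self.entries:
            if lab == label:
                return d
        raise KeyError(label)


def _dir(polar_deg: float, azimuth_deg: float) -> np.ndarray:
    """Unit direction from polar angle (from +z) and azimuth.

    Azimuth is measured from anterior (+y), positive toward the right (+x).
    """
    th = np.deg2rad(polar_deg)
    ph = np.deg2rad(azimuth_deg)
    return np.array([np.sin(th) * np.sin(ph), np.sin(th) * np.cos(ph), np.cos(th)])


def _slerp(a: np.ndarray, b: np.ndarray, t: float) -> np.ndarray:
    """Spherical linear interpolation between unit vectors a and b."""
    dot = float(np.clip(a @ b, -1.0, 1.0))
    omega = np.arccos(dot)
    if omega < 1e-12:
        return a.copy()
    return (np.sin((1 - t) * omega) * a + np.sin(t * omega) * b) / np.sin(omega)


def default_montage() -> Montage:
    """The default 65-electrode montage (including ground FPZ-row/reference)."""
    entries: dict[str, np.ndarray] = {}

    # midline chain: polar angle grows in 18 deg steps away from CZ
    entries["CZ"] = _dir(0.0, 0.0)
    for i, lab in enumerate(["FCZ", "FZ", "AFZ", "FPZ"], start=1):
        entries[lab] = _dir(i * _STEP_DEG, 0.0)  # anterior
    for i, lab in enumerate(["CPZ", "PZ", "POZ", "OZ"], start=1):
        entries[lab] = _dir(i * _STEP_DEG, 180.0)  # posterior

    # 10% circumferential ring at polar 72 deg; azimuth from front midline.
    ring_right = ["FP2", "AF8", "F8", "FT8", "T8", "TP8", "P8", "PO8", "O2"]
    ring_left = ["FP1", "AF7", "F7", "FT7", "T7", "TP7", "P7", "PO7", "O1"]
    for i, lab in enumerate(ring_right, start=1):
        entries[lab] = _dir(_RING_DEG, i * _STEP_DEG)
    for i, lab in enumerate(ring_left, start=1):
        entries[lab] = _dir(_RING_DEG, -i * _STEP_DEG)

    # coronal rows: interpolate between midline and ring electrode.
    rows = {
        ("AFZ", "AF7", "AF8"): [("AF3", "AF4", 0.5)],
        ("FZ", "F7", "F8"): [("F1", "F2", 0.25), ("F3", "F4", 0.5), ("F5", "F6", 0.75)],
        ("FCZ", "FT7", "FT8"): [("FC1", "FC2", 0.25), ("FC3", "FC4", 0.5), ("FC5", "FC6", 0.75)],
        ("CZ", "T7", "T8"): [("C1", "C2", 0.25), ("C3", "C4", 0.5), ("C5", "C6", 0.75)],
        ("CPZ", "TP7", "TP8"): [("CP1", "CP2", 0.25), ("CP3", "CP4", 0.5), ("CP5", "CP6", 0.75)],
        ("PZ", "P7", "P8"): [("P1", "P2", 0.25), ("P3", "P4", 0.5), ("P5", "P6", 0.75)],
        ("POZ", "PO7", "PO8"): [("PO3", "PO4", 0.5)],
    }
    for (mid, left, right), members in rows.items():
        for lab_l, lab_r, t in members:
            entries[lab_l] = _slerp(entries[mid], entries[left], t)
            entries[lab_r] = _slerp(entries[mid], entries[right], t)

    # inferior temporal ring: one 10% step below the ring, below the equator
    for lab, ref in [("FT9", "FT7"), ("FT10", "FT8"), ("TP9", "TP7"), ("TP10", "TP8")]:
        polar = _RING_DEG + 2 * _STEP_DEG  # 108 deg -> z < 0
        az = np.rad2deg(np.arctan2(entries[ref][0], entries[ref][1]))
        entries[lab] = _dir(polar, az)

    ordered = tuple(
        (lab, entries[lab] / np.linalg.norm(entries[lab]))
        for lab in sorted(entries)
    )
    assert len(ordered) == 65
    return Montage(ordered)


def ellipsoid_point(direction: np.ndarray, center: np.ndarray, semiaxes: np.ndarray) -> np.ndarray:
    """Radial projection of a unit direction onto an axis-aligned ellipsoid."""
    d = np.asarray(direction, dtype=float)
    s = np.asarray(semiaxes, dtype=float)
    if np.any(s <= 0):
        raise ValidationError("semiaxes must be positive")
    t = 1.0 / np.sqrt(np.sum((d / s) ** 2))
    return np.asarray(center, dtype=float) + t * d
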