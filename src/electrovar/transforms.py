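"""Affine coordinate transforms between subject and MNI space.

Electrode coordinates live in one of two world coordinate frames: the
subject's native scanner frame or MNI template space. A per-subject 4x4
homogeneous affine (as produced by standard spatial-normalization software)
maps subject-space millimetre coordinates into MNI space. Only the affine
component of normalization is modelled — points are mapped exactly, there is
no resampling and no nonlinear warp.

World coordinates follow the NIfTI RAS+ convention: +x right, +y anterior,
+z superior, units mm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError

#: Canonical names for the two coordinate frames.
SUBJECT_SPACE = "subject"
MNI_SPACE = "mni"

_LAST_ROW_ATOL = 1e-9
_MIN_DET = 1e-12


@dataclass(frozen=True)
class AffineTransform:
    """A 4x4 homogeneous affine mapping ``from_space`` to ``to_space``.

    Invariants (checked at construction): last row is (0, 0, 0, 1) to within
    1e-9 and the upper-left 3x3 block is invertible (|det| > 1e-12).
    """

    matrix: np.ndarray
    from_space: str = SUBJECT_SPACE
    to_space: str = MNI_SPACE

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (4, 4):
            raise ValidationError(f"affine must be 4x4, got shape {m.shape}")
        if not np.all(np.isfinite(m)):
            raise ValidationError("affine contains non-finite entries")
        if not np.allclose(m[3], [0.0, 0.0, 0.0, 1.0], atol=_LAST_ROW_ATOL):
            raise ValidationError(
                f"affine last row must be (0, 0, 0, 1), got {m[3].tolist()}"
            )
        if abs(np.linalg.det(m[:3, :3])) <= _MIN_DET:
            raise ValidationError("affine is singular (3x3 determinant ~ 0)")
        object.__setattr__(self, "matrix", m)

    @classmethod
    def identity(cls, from_space: str = SUBJECT_SPACE, to_space: str = MNI_SPACE) -> "AffineTransform":
        return cls(np.eye(4), from_space, to_space)

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Map one (3,) point or an (n, 3) array of points.

        Exact homogeneous product: (upper 3x3) @ p + translation column.
        """
        p = np.asarray(points, dtype=float)
        if not np.all(np.isfinite(p)):
            raise ValidationError("cannot transform non-finite coordinates")
        single = p.ndim == 1
        p = np.atleast_2d(p)
        if p.shape[1] != 3:
            raise ValidationError(f"points must have 3 columns, got {p.shape}")
        out = p @ self.matrix[:3, :3].T + self.matrix[:3, 3]
        return out[0] if single else out

    def inverse(self) -> "AffineTransform":
        """The inverse transform (to_space back to from_space)."""
        return AffineTransform(np.linalg.inv(self.matrix), self.to_space, self.from_space)

    def compose(self, inner: "AffineTransform") -> "AffineTransform":
        """self ∘ inner: apply ``inner`` first, then ``self``.

        Defined only when ``inner.to_space == self.from_space``.
        """
        if inner.to_space != self.from_space:
            raise ValidationError(
                f"cannot compose: inner maps to {inner.to_space!r} but outer "
                f"expects {self.from_space!r}"
            )
        return AffineTransform(self.matrix @ inner.matrix, inner.from_space, self.to_space)

    def __matmul__(self, other: "AffineTransform") -> "AffineTransform":
        return self.compose(other)


def apply_affine(t: AffineTransform, p: np.ndarray) -> np.ndarray:
    """Functional alias for :meth:`AffineTransform.apply`."""
    return t.apply(p)


def invert(t: AffineTransform) -> AffineTransform:
    """Functional alias for :meth:`AffineTransform.inverse`."""
    return t.inverse()
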