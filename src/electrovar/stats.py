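"""Per-electrode and grand variability statistics of MNI electrode positions.

For each electrode (separately on the scalp and on the cortex) the cohort
yields one coordinate sample per subject; this module computes the per-axis
mean, sample SD (n-1 denominator), and Fisher-Pearson skewness g1, plus the
electrode's overall deviation (the mean of its three per-axis SDs). The
grand SD of a cohort is the unweighted mean over electrodes of the
per-electrode SDs, per axis — a mean of SDs, not a pooled SD.

Subjects missing an electrode are simply excluded from that electrode's
sample (n records the count actually used); with n = 1 the SD and skewness
are reported missing (NaN), never zero.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .errors import ValidationError
from .io import ElectrodePoint


@dataclass(frozen=True)
class ElectrodeSummary:
    """Cross-subject location statistics for one electrode on one surface."""

    electrode_label: str
    surface: str
    n: int
    mean: np.ndarray  # (3,) mm
    sd: np.ndarray  # (3,) mm, NaN when n < 2
    skewness: np.ndarray  # (3,), NaN when n < 2

    @property
    def overall_deviation(self) -> float:
        """Mean of the three per-axis SDs (mm)."""
        return float(np.mean(self.sd))


@dataclass(frozen=True)
class CapGroupSummary:
    cap_size_cm: Optional[float]
    n_subjects: int
    grand_sd: np.ndarray  # (3,), NaN for size-1 groups


@dataclass(frozen=True)
class GrandSummary:
    surface: str
    grand_sd: np.ndarray  # (3,) mm over all subjects
    n_subjects: int
    per_cap_size: tuple[CapGroupSummary, ...]


def _g1_skew(x: np.ndarray) -> float:
    """Fisher-Pearson g1 = m3 / m2^(3/2); 0 for degenerate (zero-variance) samples."""
    x = np.asarray(x, dtype=float)
    d = x - x.mean()
    m2 = np.mean(d ** 2)
    if m2 == 0.0:
        return 0.0
    return float(np.mean(d ** 3) / m2 ** 1.5)


def _g1_adjusted(x: np.ndarray) -> float:
    """Bias-adjusted skewness G1 = g1 * sqrt(n(n-1))/(n-2); requires n >= 3."""
    n = len(x)
    if n < 3:
        return float("nan")
    return _g1_skew(x) * math.sqrt(n * (n - 1)) / (n - 2)


def electrode_summary(points: Sequence[ElectrodePoint],
                      bias_adjusted_skew: bool = False) -> ElectrodeSummary:
    """Summarize one electrode's MNI sample across subjects."""
    if not points:
        raise ValidationError("electrode_summary requires at least one point")
    labels = {p.electrode_label for p in points}
    surfaces = {p.surface for p in points}
    if len(labels) != 1 or len(surfaces) != 1:
        raise ValidationError(
            f"points mix electrodes/surfaces: {sorted(labels)}, {sorted(surfaces)}")
    coords = np.array([p.coord for p in points])
    n = len(coords)
    mean = coords.mean(axis=0)
    if n < 2:
        sd = np.full(3, np.nan)
        skew = np.full(3, np.nan)
    else:
        sd = coords.std(axis=0, ddof=1)
        fn = _g1_adjusted if bias_adjusted_skew else _g1_skew
        skew = np.array([fn(coords[:, a]) for a in range(3)])
    return ElectrodeSummary(labels.pop(), surfaces.pop(), n, mean, sd, skew)


def summarize_cohort(points: Iterable[ElectrodePoint], surface: str,
                     bias_adjusted_skew: bool = False) -> list[ElectrodeSummary]:
    """Per-electrode summaries for one surface, sorted by electrode label."""
    groups: dict[str, list[ElectrodePoint]] = {}
    for p in points:
        if p.surface == surface:
            groups.setdefault(p.electrode_label, []).append(p)
    return [electrode_summary(groups[lab], bias_adjusted_skew)
            for lab in sorted(groups)]


def grand_sd(summaries: Sequence[ElectrodeSummary]) -> np.ndarray:
    """Unweighted mean over electrodes of the per-electrode SDs, per axis."""
    if not summaries:
        raise ValidationError("grand_sd requires at least one summary")
    usable = [s for s in summaries if not np.any(np.isnan(s.sd))]
    dropped = len(summaries) - len(usable)
    if dropped:
        warnings.warn(f"grand_sd: excluded {dropped} electrode(s) with missing SD")
    if not usable:
        return np.full(3, np.nan)
    return np.array([s.sd for s in usable]).mean(axis=0)


@dataclass(frozen=True)
class ExtremeReport:
    smallest_labels: tuple[str, ...]
    smallest_mean: float
    largest_labels: tuple[str, ...]
    largest_mean: float


def rank_extremes(summaries: Sequence[ElectrodeSummary], k: int) -> ExtremeReport:
    """The k electrodes with smallest / largest overall deviation.

    Ranking is by overall deviation with alphabetical tie-break; each
    extreme set is reported with the mean of its members' overall
    deviations.
    """
    if k <= 0:
        raise ValidationError("k must be positive")
    if k > len(summaries):
        raise ValidationError(f"k={k} exceeds {len(summaries)} summaries")
    ranked = sorted(summaries, key=lambda s: (s.overall_deviation, s.electrode_label))
    small = ranked[:k]
    large = sorted(ranked[-k:], key=lambda s: (-s.overall_deviation, s.electrode_label))
    return ExtremeReport(
        smallest_labels=tuple(s.electrode_label for s in small),
        smallest_mean=float(np.mean([s.overall_deviation for s in small])),
        largest_labels=tuple(s.electrode_label for s in large),
        largest_mean=float(np.mean([s.overall_deviation for s in large])),
    )


def group_by_cap_size(
    points: Iterable[ElectrodePoint],
    cap_sizes: Mapping[str, Optional[float]],
    surface: str,
) -> GrandSummary:
    """Grand SDs recomputed within each cap-size subgroup.

    Per-electrode SDs are recomputed from only the subjects in each group,
    then averaged over electrodes. Subjects with an unrecorded cap size
    contribute to the all-subjects row only.
    """
    points = [p for p in points if p.surface == surface]
    if not points:
        raise ValidationError("no points for requested surface")
    all_summaries = summarize_cohort(points, surface)
    subjects_seen = {p.subject_id for p in points}
    groups: dict[float, list[ElectrodePoint]] = {}
    for p in points:
        cap = cap_sizes.get(p.subject_id)
        if cap is not None:
            groups.setdefault(cap, []).append(p)
    per_cap = []
    for cap in sorted(groups):
        gpts = groups[cap]
        n_subj = len({p.subject_id for p in gpts})
        if n_subj < 2:
            gsd = np.full(3, np.nan)
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                gsd = grand_sd(summarize_cohort(gpts, surface))
        per_cap.append(CapGroupSummary(cap, n_subj, gsd))
    return GrandSummary(
        surface=surface,
        grand_sd=grand_sd(all_summaries),
        n_subjects=len(subjects_seen),
        per_cap_size=tuple(per_cap),
    )


def c4(n: int) -> float:
    """Unbiasing constant of the sample SD under normality.

    E[s] = c4(n) * sigma for an iid Gaussian sample of size n, with
    c4(n) = sqrt(2/(n-1)) * Gamma(n/2) / Gamma((n-1)/2).
    """
    from scipy.special import gammaln

    if n < 2:
        raise ValidationError("c4 requires n >= 2")
    return math.sqrt(2.0 / (n - 1)) * math.exp(gammaln(n / 2) - gammaln((n - 1) / 2))
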