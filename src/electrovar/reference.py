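"""Published per-electrode reference statistics (65-electrode, 20-subject cohort).

A packaged table of per-electrode MNI means and SDs from a published
20-participant EEG-fMRI study of electrode-position variability (10-10
montage, 65 electrodes including ground and reference), at the scalp and
projected to the cortex. It serves as fixed input for recomputing the
study-level summary statistics (grand SDs, extreme-electrode sets) and as
the authoritative electrode label set for the default montage.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

from .io import CORTEX, SCALP
from .stats import ElectrodeSummary

REFERENCE_N_SUBJECTS = 20


def load_reference_table() -> pd.DataFrame:
    """The raw reference table (one row per electrode)."""
    with resources.files("electrovar.data").joinpath("reference_mni_summary.csv").open() as fh:
        return pd.read_csv(fh)


def reference_labels() -> list[str]:
    return sorted(load_reference_table()["electrode"])


def load_reference_summaries(surface: str = SCALP) -> list[ElectrodeSummary]:
    """Reference rows as :class:`ElectrodeSummary` objects for one surface.

    Skewness is not part of the published per-electrode table and is NaN.
    """
    if surface not in (SCALP, CORTEX):
        raise ValueError(f"surface must be scalp or cortex, got {surface!r}")
    df = load_reference_table()
    out = []
    for _, r in df.iterrows():
        out.append(ElectrodeSummary(
            electrode_label=str(r["electrode"]),
            surface=surface,
            n=REFERENCE_N_SUBJECTS,
            mean=np.array([r[f"{surface}_mean_x"], r[f"{surface}_mean_y"], r[f"{surface}_mean_z"]]),
            sd=np.array([r[f"{surface}_sd_x"], r[f"{surface}_sd_y"], r[f"{surface}_sd_z"]]),
            skewness=np.full(3, np.nan),
        ))
    return sorted(out, key=lambda s: s.electrode_label)
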