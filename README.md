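# electrovar

Between-subject variability of EEG electrode positions and the brain
regions beneath them.

EEG caps place electrodes at proportional distances along skull landmarks
(the 10-10 system), and analyses routinely assume that a given electrode
sits over the same cortex in every participant. In practice, head shape,
cap fit and placement error move each electrode by several millimetres
between subjects. `electrovar` implements a complete, tested pipeline for
quantifying that variability from per-subject electrode coordinates (e.g.
neuronavigation target exports marked on MRI-visible gel artifacts):

1. **Spatial normalization** — per-subject electrode coordinates (scalp
   and cortex surfaces) are mapped to MNI space with each subject's 4×4
   affine, exactly: `p_MNI = A p + t`.
2. **Cortical projection** — scalp targets are snapped to the nearest
   point of a peeled brain-surface reconstruction (boundary of the brain
   mask after metric erosion by a peel depth).
3. **Variability statistics** — per electrode *e* and axis
   *a ∈ {x, y, z}*: cross-subject mean, sample SD *s*ₑₐ (n−1 denominator)
   and Fisher–Pearson skewness g₁; the electrode's *overall deviation*
   is (sₑₓ + sₑᵧ + sₑ_z)/3; the cohort's **grand SD** per axis is the
   unweighted mean over electrodes of the per-electrode SDs. Summaries are
   also grouped by cap size (54/56/58 cm).
4. **Atlas labeling** — each MNI coordinate is looked up in a 4-D
   probabilistic atlas (nearest voxel); the highest-probability region is
   that subject's label. Subjects with a tied maximum or no label are
   excluded, and per-electrode region percentages are computed over the
   remaining usable subjects. A labeled (Brodmann-style) atlas supports
   nearest-label lookup at the cohort mean coordinate.
5. **Rendering** — per-subject MNI point maps and a mean-position map in
   which each electrode's mean is convolved with a 4 mm sphere whose
   intensity encodes its overall SD (NIfTI, standard MNI152 grid).

A synthetic cohort generator (65-electrode 10-10 montage on ellipsoidal
heads, correlated cap perturbation + independent per-electrode jitter,
cap-size categories, missing electrodes, synthetic atlases) provides known
ground truth, so the full pipeline is testable without any imaging data.
The package is aimed at EEG/TMS researchers who want to audit electrode
position consistency in their own cohorts, and at anyone reusing the
published summary statistics.

## Worked example

Recompute the study-level statistics from the packaged reference table
(per-electrode MNI means and SDs of 65 electrodes across 20 subjects):

```
$ python analysis/01_reference_variability.py
scalp: grand SD = (3.94, 5.55, 7.17) mm
  least variable : F7, FC5, FT7, F5, FCZ (mean 4.47 mm)
  most variable  : P3, PO4, O1, PO3, POZ (mean 6.77 mm)
cortex: grand SD = (3.95, 5.09, 6.35) mm
  least variable : F7, F5, FC5, FCZ, FT7 (mean 4.34 mm)
  most variable  : FT10, PO4, O1, OZ, PO3 (mean 6.25 mm)
```

Electrodes wander by roughly 4–7 mm between subjects even in a fixed cap,
most along the z axis and at the back of the head; frontal electrodes are
the most reliable anchors. The same statistics can be computed for any
cohort from a manifest of target/affine files:

```
electrovar simulate --n-subjects 20 --seed 1 --out cohort/
electrovar run-all --manifest cohort/manifest.yaml --out out/
```

which writes per-electrode summary CSVs, cap-size grand-SD tables,
extreme-electrode rankings, region tallies (when an atlas is supplied via
`--atlas`/`--names`) and NIfTI maps. The numbered scripts under
`analysis/` run the same stages as a narrative: simulate a cohort, run the
pipeline, and verify that a known 5 mm placement jitter is recovered to
within a fraction of a percent of its closed-form expectation
c₄(20)·σ ≈ 4.93 mm.

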