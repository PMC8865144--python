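"""End-to-end orchestration: simulate -> normalize -> project -> summarize
-> label -> render, from a cohort manifest to output tables and volumes.

Every stage is a pure function of (inputs, config, seed); a failed stage
aborts the run, removes the partial outputs it created, and reports the
failing stage. A machine-readable run log records parameters and per-stage
record counts.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from . import __version__
from .atlas import LabeledAtlas, ProbAtlas, hemisphere_of, label_cohort, mean_usable, nearest_label
from .errors import ElectrovarError, PipelineError, ValidationError
from .io import (
    CORTEX,
    SCALP,
    read_manifest,
    write_summary_csv,
    write_tally_csv,
    write_targets,
)
from .normalize import load_cohort_affines, load_cohort_points, normalize_points
from .projection import ProjectionParams, project_cohort
from .rendering import INTENSITY_OVERALL_SD, mni152_grid, render_points, render_sphere_map
from .stats import group_by_cap_size, rank_extremes, summarize_cohort
from .volume import VolumeGrid


@dataclass(frozen=True)
class PipelineConfig:
    manifest: Path
    out_dir: Path
    surfaces: tuple[str, ...] = (SCALP, CORTEX)
    projection: ProjectionParams = field(default_factory=ProjectionParams)
    prob_atlas_path: Optional[Path] = None
    prob_atlas_names_path: Optional[Path] = None
    labeled_atlas_path: Optional[Path] = None
    atlas_surface: str = CORTEX
    k_extremes: int = 5
    sphere_radius_mm: float = 4.0
    render: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_extremes < 1:
            raise ValidationError("k_extremes must be >= 1")
        if not Path(self.manifest).exists():
            raise ValidationError(f"manifest does not exist: {self.manifest}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        with path.open() as fh:
            doc = yaml.safe_load(fh) or {}
        base = path.parent

        def _p(key):
            v = doc.get(key)
            if v is None:
                return None
            q = Path(v)
            return q if q.is_absolute() else base / q

        proj = ProjectionParams(**doc.get("projection", {}))
        return cls(
            manifest=_p("manifest"),
            out_dir=_p("out_dir") or base / "pipeline_out",
            surfaces=tuple(doc.get("surfaces", (SCALP, CORTEX))),
            projection=proj,
            prob_atlas_path=_p("prob_atlas"),
            prob_atlas_names_path=_p("prob_atlas_names"),
            labeled_atlas_path=_p("labeled_atlas"),
            atlas_surface=doc.get("atlas_surface", CORTEX),
            k_extremes=int(doc.get("k", 5)),
            sphere_radius_mm=float(doc.get("sphere_radius_mm", 4.0)),
            render=bool(doc.get("render", True)),
            seed=int(doc.get("seed", 0)),
        )


class _Run:
    """Tracks created files so a failing stage can clean up after itself."""

    def __init__(self, out_dir: Path):
        self.out_dir = out_dir
        self.created: list[Path] = []
        self.log: dict = {"version": __version__, "stages": []}

    def path(self, name: str) -> Path:
        p = self.out_dir / name
        self.created.append(p)
        return p

    def record(self, stage: str, **counts) -> None:
        self.log["stages"].append({"stage": stage, **counts})

    def abort(self, stage: str, exc: Exception) -> "PipelineError":
        for p in self.created:
            try:
                p.unlink(missing_ok=True)
            except OSError:
                pass
        return PipelineError(f"stage {stage!r} failed: {exc}")


def run_all(config: PipelineConfig) -> Path:
    """Run every configured stage; returns the output directory.

    Atlas stages are skipped with a logged notice when no atlas is
    configured, keeping the default (no external data) path green.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    run = _Run(out_dir)
    stage = "load"
    try:
        manifest = read_manifest(config.manifest)
        affines = load_cohort_affines(manifest)
        cap_sizes = {s.subject_id: s.cap_size_cm for s in manifest.subjects}
        run.record(stage, n_subjects=len(manifest.subjects))

        stage = "normalize"
        mni: dict[str, list] = {}
        mni[SCALP] = normalize_points(load_cohort_points(manifest, SCALP), affines)
        run.record("normalize[scalp]", n_points=len(mni[SCALP]))
        cortex_from_files = load_cohort_points(manifest, CORTEX)
        if cortex_from_files and CORTEX in config.surfaces:
            mni[CORTEX] = normalize_points(cortex_from_files, affines)
            run.record("normalize[cortex]", n_points=len(mni[CORTEX]))

        # project in MNI space (stage order: normalize, then project), with
        # each subject's brain mask re-expressed through its own affine
        stage = "project"
        if CORTEX in config.surfaces and CORTEX not in mni:
            masks = {}
            for s in manifest.subjects:
                if s.brain_mask is not None:
                    g = VolumeGrid.load(s.brain_mask)
                    masks[s.subject_id] = VolumeGrid(
                        g.data, affines[s.subject_id].matrix @ g.affine)
            if masks:
                by_subject: dict[str, list] = {}
                for p in mni[SCALP]:
                    by_subject.setdefault(p.subject_id, []).append(p)
                missing_mask = sorted(set(by_subject) - set(masks))
                if missing_mask:
                    raise ValidationError(f"no brain mask for subjects: {missing_mask}")
                result = project_cohort(by_subject, masks, config.projection)
                mni[CORTEX] = result.cortex_points
                run.record("project", n_projected=len(result.cortex_points),
                           n_unprojectable=len(result.unprojectable))
            else:
                run.record("project", skipped="no cortex targets and no brain masks")

        stage = "write-targets"
        for surface, pts in mni.items():
            by_subject = {}
            for p in pts:
                by_subject.setdefault(p.subject_id, []).append(p)
            for sid, pts_s in sorted(by_subject.items()):
                write_targets(pts_s, run.path(f"{sid}_{surface}_mni.txt"))

        stage = "summarize"
        summaries: dict[str, list] = {}
        for surface, pts in mni.items():
            summaries[surface] = summarize_cohort(pts, surface)
            write_summary_csv(summaries[surface], run.path(f"summary_{surface}.csv"))
            gs = group_by_cap_size(pts, cap_sizes, surface)
            rows = [{"cap_size_cm": g.cap_size_cm, "n": g.n_subjects,
                     "sd_x": g.grand_sd[0], "sd_y": g.grand_sd[1], "sd_z": g.grand_sd[2]}
                    for g in gs.per_cap_size]
            rows.append({"cap_size_cm": "all", "n": gs.n_subjects,
                         "sd_x": gs.grand_sd[0], "sd_y": gs.grand_sd[1], "sd_z": gs.grand_sd[2]})
            import pandas as pd
            pd.DataFrame(rows).to_csv(run.path(f"grand_sd_{surface}.csv"),
                                      index=False, float_format="%.12g")
            ext = rank_extremes(summaries[surface], min(config.k_extremes, len(summaries[surface])))
            with run.path(f"extremes_{surface}.json").open("w") as fh:
                json.dump({"smallest": list(ext.smallest_labels),
                           "smallest_mean_mm": ext.smallest_mean,
                           "largest": list(ext.largest_labels),
                           "largest_mean_mm": ext.largest_mean}, fh, indent=2)
            run.record(f"summarize[{surface}]", n_electrodes=len(summaries[surface]))

        stage = "label"
        if config.prob_atlas_path is not None:
            atlas = ProbAtlas.load(config.prob_atlas_path, config.prob_atlas_names_path)
            surf = config.atlas_surface if config.atlas_surface in mni else SCALP
            by_subject = {}
            for p in mni[surf]:
                by_subject.setdefault(p.subject_id, []).append(p)
            _, tallies = label_cohort(atlas, by_subject)
            write_tally_csv(tallies, run.path("region_tallies.csv"))
            mu, musd = mean_usable(tallies)
            run.record("label", surface=surf, n_electrodes=len(tallies),
                       mean_usable=mu, sd_usable=musd)
        else:
            run.record("label", skipped="no probabilistic atlas configured")

        if config.labeled_atlas_path is not None and config.atlas_surface in summaries:
            limg = VolumeGrid.load(config.labeled_atlas_path)
            names = {int(v): f"label_{int(v)}" for v in np.unique(limg.data) if v != 0}
            latlas = LabeledAtlas(limg.data, limg.affine, names)
            import pandas as pd
            rows = []
            for s in summaries[config.atlas_surface]:
                lab = nearest_label(latlas, s.mean)
                rows.append({"electrode": s.electrode_label,
                             "nearest_label": lab if lab is not None else "not applicable",
                             "hemisphere": hemisphere_of(float(s.mean[0]))})
            pd.DataFrame(rows).to_csv(run.path("nearest_labels.csv"), index=False)
            run.record("nearest_label", n_electrodes=len(rows))

        stage = "render"
        if config.render:
            grid = mni152_grid()
            for surface, pts in mni.items():
                by_subject = {}
                for p in pts:
                    by_subject.setdefault(p.subject_id, []).append(p)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    for sid, pts_s in sorted(by_subject.items()):
                        vol = render_points(pts_s, grid)
                        vol.save(run.path(f"{sid}_{surface}_points.nii.gz"))
                    sphere = render_sphere_map(summaries[surface], config.sphere_radius_mm,
                                               INTENSITY_OVERALL_SD, grid)
                sphere.save(run.path(f"mean_sd_spheres_{surface}.nii.gz"))
            run.record("render", n_volumes=len(run.created))

        with (out_dir / "run_log.json").open("w") as fh:
            json.dump(run.log, fh, indent=2, default=str)
        return out_dir
    except PipelineError:
        raise
    except ElectrovarError as exc:
        raise run.abort(stage, exc) from exc
    except Exception as exc:  # internal error: still clean up, then re-raise
        run.abort(stage, exc)
        raise
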