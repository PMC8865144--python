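"""Peeled-surface extraction and nearest-point cortical snapping."""

import numpy as np
import pytest

import electrovar as ev
from electrovar.errors import ValidationError
from electrovar.projection import ProjectionParams, SurfaceSnapper

from conftest import make_point


def _sphere_mask(radius_mm, voxel=1.0, pad=5):
    n = int(2 * (radius_mm + pad) / voxel) + 1
    head = ev.HeadModel(center=(0, 0, 0), scalp_semiaxes=(radius_mm + 2,) * 3,
                        brain_semiaxes=(radius_mm,) * 3)
    _, brain = ev.make_head_volumes(head, (n, n, n), (voxel,) * 3)
    return brain


class TestPeelSurface:
    def test_sphere_surface_at_nominal_radius(self):
        brain = _sphere_mask(20.0)
        surf = ev.peel_surface(brain, 0.0)
        radii = np.linalg.norm(surf, axis=1)
        diag = np.sqrt(3.0)  # one voxel diagonal at 1 mm
        assert radii.min() > 20.0 - diag - 1e-9
        assert radii.max() <= 20.0 + 1e-9

    def test_peel_depth_shrinks_surface_radius(self):
        brain = _sphere_mask(20.0)
        surf = ev.peel_surface(brain, 5.0)
        radii = np.linalg.norm(surf, axis=1)
        diag = np.sqrt(3.0)
        assert abs(radii.max() - 15.0) <= diag
        assert abs(radii.min() - 15.0) <= diag

    def test_peel_depth_matches_distance_transform_oracle(self):
        from scipy import ndimage
        brain = _sphere_mask(15.0, voxel=1.5)
        depth = 4.0
        surf = ev.peel_surface(brain, depth)
        # oracle: voxels with EDT > depth, minus their face-erosion
        mask = brain.data > 0
        dt = ndimage.distance_transform_edt(mask, sampling=brain.voxel_size)
        eroded = dt > depth
        interior = ndimage.binary_erosion(eroded, ndimage.generate_binary_structure(3, 1),
                                          border_value=0)
        expected = np.argwhere(eroded & ~interior)
        got = np.rint(brain.world_to_voxel(surf)).astype(int)
        assert {tuple(v) for v in got} == {tuple(v) for v in expected}

    def test_peel_deeper_than_radius_is_error(self):
        brain = _sphere_mask(10.0)
        with pytest.raises(ValidationError):
            ev.peel_surface(brain, 50.0)

    def test_empty_mask_rejected(self):
        grid = ev.VolumeGrid(np.zeros((5, 5, 5)), np.eye(4))
        with pytest.raises(ValidationError):
            ev.peel_surface(grid, 0.0)


class TestSnapToCortex:
    def test_concentric_spheres_snap_radially(self):
        brain = _sphere_mask(20.0)
        surf = ev.peel_surface(brain, 0.0)
        scalp_point = 30.0 * np.array([0.6, 0.64, 0.48])  # on radius-30 sphere
        snapped = ev.snap_to_cortex(scalp_point, surf)
        # same ray through the center, at the brain radius (voxel tolerance)
        cos = snapped @ scalp_point / (np.linalg.norm(snapped) * np.linalg.norm(scalp_point))
        assert cos > 0.995
        assert abs(np.linalg.norm(snapped) - 20.0) <= np.sqrt(3.0)

    def test_surface_member_snaps_to_itself(self):
        brain = _sphere_mask(15.0)
        surf = ev.peel_surface(brain, 0.0)
        member = surf[17]
        np.testing.assert_array_equal(ev.snap_to_cortex(member, surf), member)

    def test_snap_is_idempotent(self):
        brain = _sphere_mask(15.0)
        surf = ev.peel_surface(brain, 0.0)
        once = ev.snap_to_cortex(np.array([40.0, 1.0, 2.0]), surf)
        twice = ev.snap_to_cortex(once, surf)
        np.testing.assert_array_equal(once, twice)

    def test_matches_exhaustive_nearest_neighbor_on_random_points(self, rng):
        brain = _sphere_mask(18.0, voxel=1.5)
        surf = ev.peel_surface(brain, 0.0)
        snapper = SurfaceSnapper(surf)
        queries = rng.uniform(-35, 35, (1000, 3))
        for q in queries:
            d = np.linalg.norm(surf - q, axis=1)
            tied = np.nonzero(d <= d.min() + SurfaceSnapper.tie_tol_mm)[0]
            expected = min((surf[j] for j in tied), key=lambda p: tuple(np.round(p, 2)))
            np.testing.assert_array_equal(snapper.snap(q), expected)

    def test_beyond_search_radius_flagged_unprojectable(self):
        brain = _sphere_mask(10.0)
        surf = ev.peel_surface(brain, 0.0)
        params = ProjectionParams(max_search_mm=5.0)
        assert ev.snap_to_cortex(np.array([100.0, 0.0, 0.0]), surf, params) is None

    def test_empty_surface_rejected(self):
        with pytest.raises(ValidationError):
            ev.snap_to_cortex(np.zeros(3), np.empty((0, 3)))


class TestProjectCohort:
    def _cohort(self, montage, head, config, n):
        by_subject, masks, affines = {}, {}, {}
        _, brain = ev.make_head_volumes(head, (72, 84, 72), (2.5, 2.5, 2.5))
        for i in range(n):
            pts, aff = ev.simulate_subject(montage, head, config, i)
            sid = pts[0].subject_id
            # work in canonical space: map points through the truth affine
            by_subject[sid] = [p.with_coord(aff.apply(p.coord), space="mni") for p in pts]
            masks[sid] = brain
            affines[sid] = aff
        return by_subject, masks

    def test_zero_noise_identical_heads_give_identical_cortex_points(self, montage, head):
        config = ev.SimulationConfig.noiseless(seed=2, n_subjects=3)
        by_subject, masks = self._cohort(montage, head, config, 3)
        result = ev.project_cohort(by_subject, masks)
        coords = {}
        for p in result.cortex_points:
            coords.setdefault(p.electrode_label, []).append(p.coord)
        for lab, cs in coords.items():
            for c in cs[1:]:
                np.testing.assert_allclose(c, cs[0], atol=1e-9, err_msg=lab)

    def test_cortex_points_strictly_inside_scalp(self, montage, head):
        config = ev.SimulationConfig(n_subjects=2, seed=8)
        by_subject, masks = self._cohort(montage, head, config, 2)
        result = ev.project_cohort(by_subject, masks)
        assert result.cortex_points
        for p in result.cortex_points:
            q = ((p.coord - head.center) / head.scalp_semiaxes) ** 2
            assert q.sum() < 1.0
            assert p.surface == ev.CORTEX

    def test_scalp_to_cortex_displacement_matches_ellipsoid_gap(self, montage, head):
        """Snap distance ~ the scalp-brain gap along each electrode direction."""
        config = ev.SimulationConfig.noiseless(seed=2, n_subjects=1)
        by_subject, masks = self._cohort(montage, head, config, 1)
        result = ev.project_cohort(by_subject, masks)
        scalp = {p.electrode_label: p.coord for p in by_subject["s00"]}
        from electrovar.montage import ellipsoid_point
        for p in result.cortex_points:
            d = montage.direction(p.electrode_label)
            gap = np.linalg.norm(
                ellipsoid_point(d, head.center, head.scalp_semiaxes)
                - ellipsoid_point(d, head.center, head.brain_semiaxes))
            measured = np.linalg.norm(scalp[p.electrode_label] - p.coord)
            # equality up to the voxel diagonal of the 2.5 mm surface lattice
            assert abs(measured - gap) <= np.sqrt(3) * 2.5, p.electrode_label

    def test_missing_mask_is_an_error_naming_subject(self, montage, head):
        config = ev.SimulationConfig(n_subjects=1, seed=8)
        by_subject, _ = self._cohort(montage, head, config, 1)
        with pytest.raises(ValidationError, match="s00"):
            ev.project_cohort(by_subject, {})

    def test_radial_cap_noise_compressed_on_cortex(self, montage, head):
        """Pure cap-scale noise moves points radially; snapping to a fixed
        brain surface removes most of it, so cortex SD <= scalp SD."""
        config = ev.SimulationConfig(
            n_subjects=8, jitter_sd_mm=(0, 0, 0), cap_rotation_sd_deg=0,
            cap_translation_sd_mm=0, cap_scale_sd=0.04, missing_electrode_rate=0,
            cap_geometry_effect=0.0, seed=6)
        by_subject, masks = self._cohort(montage, head, config, 8)
        result = ev.project_cohort(by_subject, masks)
        scalp_pts = [p for pts in by_subject.values() for p in pts]
        scalp_sd = ev.grand_sd(ev.summarize_cohort(scalp_pts, ev.SCALP))
        cortex_sd = ev.grand_sd(ev.summarize_cohort(result.cortex_points, ev.CORTEX))
        assert cortex_sd.mean() <= scalp_sd.mean()
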