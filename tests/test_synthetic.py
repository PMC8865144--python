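"""Synthetic cohort generator: determinism, noise calibration, volumes, atlases."""

import numpy as np
import pytest

import electrovar as ev
from electrovar.errors import ConfigurationError, ValidationError
from electrovar.montage import ellipsoid_point
from electrovar.synthetic import make_synthetic_prob_atlas


class TestSimulateSubject:
    def test_zero_noise_reproduces_canonical_montage_positions(self, montage, head):
        config = ev.SimulationConfig.noiseless(seed=1)
        pts, aff = ev.simulate_subject(montage, head, config, 0)
        assert len(pts) == 65
        recovered = aff.apply(np.array([p.coord for p in pts]))
        expected = np.array([ellipsoid_point(d, head.center, head.scalp_semiaxes)
                             for _, d in montage.entries])
        np.testing.assert_allclose(recovered, expected, atol=1e-10)

    def test_same_seed_and_subject_give_identical_output(self, montage, head):
        config = ev.SimulationConfig(seed=42)
        a_pts, a_aff = ev.simulate_subject(montage, head, config, 3)
        b_pts, b_aff = ev.simulate_subject(montage, head, config, 3)
        assert len(a_pts) == len(b_pts)
        for pa, pb in zip(a_pts, b_pts):
            assert pa.electrode_label == pb.electrode_label
            assert np.array_equal(pa.coord, pb.coord)
        assert np.array_equal(a_aff.matrix, b_aff.matrix)

    def test_different_subjects_differ(self, montage, head):
        config = ev.SimulationConfig(seed=42)
        a_pts, _ = ev.simulate_subject(montage, head, config, 0)
        b_pts, _ = ev.simulate_subject(montage, head, config, 1)
        assert not np.allclose(a_pts[0].coord, b_pts[0].coord)

    def test_missingness_does_not_shift_other_electrodes(self, montage, head):
        """Per-electrode random streams: dropping electrodes leaves the rest intact."""
        base = ev.SimulationConfig(seed=9, missing_electrode_rate=0.0)
        lossy = base.replace(missing_electrode_rate=0.3)
        full, aff_full = ev.simulate_subject(montage, head, base, 2)
        part, aff_part = ev.simulate_subject(montage, head, lossy, 2)
        assert 0 < len(part) < len(full)
        full_by_label = {p.electrode_label: p.coord for p in full}
        for p in part:
            np.testing.assert_array_equal(p.coord, full_by_label[p.electrode_label])
        assert np.array_equal(aff_full.matrix, aff_part.matrix)

    def test_jitter_sd_recovered_in_canonical_space(self, montage, head):
        """Mean per-electrode sample SD tracks c4(n) * sigma for pure jitter."""
        sigma, n = 5.0, 20
        config = ev.SimulationConfig(
            n_subjects=n, jitter_sd_mm=(sigma,) * 3, cap_rotation_sd_deg=0,
            cap_translation_sd_mm=0, cap_scale_sd=0, missing_electrode_rate=0, seed=77)
        coords = {lab: [] for lab in montage.labels}
        for i in range(n):
            pts, aff = ev.simulate_subject(montage, head, config, i)
            canon = aff.apply(np.array([p.coord for p in pts]))
            for p, c in zip(pts, canon):
                coords[p.electrode_label].append(c)
        sds = np.array([np.std(np.array(v), axis=0, ddof=1) for v in coords.values()])
        # averaging 65 electrodes x 3 axes: mean sample SD ~ c4(20)*5 within ~2.5%
        assert abs(sds.mean() - ev.c4(n) * sigma) / (ev.c4(n) * sigma) < 0.025

    def test_invalid_config_rejected(self):
        with pytest.raises(ConfigurationError):
            ev.SimulationConfig(n_subjects=0)
        with pytest.raises(ConfigurationError):
            ev.SimulationConfig(missing_electrode_rate=1.5)
        with pytest.raises(ConfigurationError):
            ev.SimulationConfig(jitter_sd_mm=(-1, 0, 0))

    def test_subject_index_out_of_range(self, montage, head):
        with pytest.raises(ConfigurationError):
            ev.simulate_subject(montage, head, ev.SimulationConfig(n_subjects=2), 5)


def test_cap_size_split_matches_study_at_n20():
    caps = ev.assign_cap_sizes(20)
    assert caps.count(54.0) == 4
    assert caps.count(56.0) == 12
    assert caps.count(58.0) == 3
    assert caps.count(None) == 1


class TestHeadVolumes:
    def test_brain_mask_subset_of_scalp_mask(self, head):
        scalp, brain = ev.make_head_volumes(head, (72, 84, 72), (2.5, 2.5, 2.5))
        assert brain.data.sum() < scalp.data.sum()
        assert not np.any(brain.data & ~scalp.data)

    def test_sphere_voxel_count_matches_lattice_enumeration(self):
        r = 20.0
        sphere_head = ev.HeadModel(center=(0, 0, 0), scalp_semiaxes=(r, r, r),
                                   brain_semiaxes=(r - 8, r - 8, r - 8))
        _, brain = ev.make_head_volumes(sphere_head, (51, 51, 51), (1.0, 1.0, 1.0))
        # brute-force: integer lattice points within r-8 of the center
        g = np.arange(-25, 26)
        X, Y, Z = np.meshgrid(g, g, g, indexing="ij")
        expected = int((X**2 + Y**2 + Z**2 <= (r - 8) ** 2).sum())
        assert int(brain.data.sum()) == expected

    def test_voxel_to_world_maps_origin_index_to_grid_origin(self, head):
        scalp, _ = ev.make_head_volumes(head, (72, 84, 72), (2.5, 2.5, 2.5))
        origin = scalp.voxel_to_world_coords(np.array([[0, 0, 0]]))[0]
        np.testing.assert_allclose(origin, scalp.affine[:3, 3])

    def test_ellipsoid_exceeding_grid_rejected(self, head):
        with pytest.raises(ValidationError):
            ev.make_head_volumes(head, (20, 20, 20), (2.0, 2.0, 2.0))


class TestSyntheticProbAtlas:
    def test_probabilities_read_back_at_constructed_voxels(self):
        syn = make_synthetic_prob_atlas((40, 40, 40), (2.0, 2.0, 2.0), 3, seed=5)
        atlas = syn.atlas
        # read-back oracle: the query at a voxel's world coordinate must
        # reproduce exactly the values stored at that voxel
        voxel = np.rint(atlas.data.shape[0] * np.array([0.5, 0.5, 0.5])).astype(int)
        world = atlas.affine[:3, :3] @ voxel + atlas.affine[:3, 3]
        stored = {atlas.region_names[r]: float(atlas.data[(*voxel, r)])
                  for r in range(3) if atlas.data[(*voxel, r)] > 0}
        assert dict(ev.query_prob_atlas(atlas, world)) == stored
        # blob peaks are near 100 (continuous centers fall between voxels)
        assert all(atlas.data[..., r].max() > 90 for r in range(3))

    def test_constructed_tie_voxel_yields_tie_outcome(self):
        syn = make_synthetic_prob_atlas((40, 40, 40), (2.0, 2.0, 2.0), 2, seed=5)
        tie_world = syn.atlas.affine[:3, :3] @ np.array(syn.tie_voxel) + syn.atlas.affine[:3, 3]
        outcome = ev.max_label(ev.query_prob_atlas(syn.atlas, tie_world))
        assert outcome.outcome == "TIE"

    def test_background_voxel_yields_no_label(self):
        syn = make_synthetic_prob_atlas((40, 40, 40), (2.0, 2.0, 2.0), 2, seed=5)
        corner_world = syn.atlas.affine[:3, 3]
        assert ev.query_prob_atlas(syn.atlas, corner_world) == []

    def test_single_region_interior_query(self):
        syn = make_synthetic_prob_atlas((30, 30, 30), (2.0, 2.0, 2.0), 1, seed=2)
        hits = ev.query_prob_atlas(syn.atlas, syn.region_centers_world[0])
        assert hits and hits[0][0] == "region_00"

    def test_invalid_arguments_rejected(self):
        with pytest.raises(ValidationError):
            make_synthetic_prob_atlas((0, 10, 10), (2, 2, 2), 1, seed=1)
        with pytest.raises(ValidationError):
            make_synthetic_prob_atlas((10, 10, 10), (2, 2, 2), 0, seed=1)


def test_simulate_cohort_writes_complete_manifest(tmp_path):
    config = ev.SimulationConfig(n_subjects=3, seed=4)
    manifest = ev.simulate_cohort(config, tmp_path / "cohort",
                                  mask_shape=(60, 72, 60), mask_voxel_mm=3.0)
    assert len(manifest.subjects) == 3
    reloaded = ev.read_manifest(tmp_path / "cohort" / "manifest.yaml")
    assert [s.subject_id for s in reloaded.subjects] == ["s00", "s01", "s02"]
    for s in reloaded.subjects:
        assert s.scalp_targets.exists() and s.affine.exists() and s.brain_mask.exists()
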