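"""Phantom generation: analytic truth, rasterisation, artifacts."""

import numpy as np
import pytest
from skimage import measure

from vasccalc.phantom import (
    Bone,
    Calcification,
    PhantomSpec,
    apply_artifact,
    generate_phantom,
    make_cohort,
    random_spec,
)


def brute_force_calcium_count(spec, path, radii):
    """Independent point-in-region rasterisation (double loop)."""
    count = 0
    for s in range(spec.n_slices):
        cy, cx = path[s]
        r = radii[s]
        for row in range(spec.image_size):
            for col in range(spec.image_size):
                d2 = (row - cy) ** 2 + (col - cx) ** 2
                for c in spec.calcifications:
                    s0, s1 = c.slice_range
                    if not (s0 <= s < s1):
                        continue
                    if d2 > r * r or d2 < (r - c.radial_thickness) ** 2:
                        continue
                    theta = np.degrees(np.arctan2(row - cy, col - cx)) % 360.0
                    if (theta - c.angle_start_deg) % 360.0 < c.arc_extent_deg:
                        count += 1
                        break
    return count


def straight_vessel_spec(**kw):
    defaults = dict(
        image_size=64,
        n_slices=10,
        vessel_path=np.tile([32.0, 32.0], (10, 1)),
        vessel_radius_profile=np.full(10, 8.0),
        seed=7,
    )
    defaults.update(kw)
    return PhantomSpec(**defaults)


class TestTruth:
    def test_no_calcifications_means_zero_volume(self):
        _, truth = generate_phantom(straight_vessel_spec())
        assert truth.true_calcium_voxels == 0
        assert truth.true_calcium_volume == 0.0

    def test_determinism_bit_identical(self):
        spec = random_spec(42, noise_sigma=6.0)
        v1, t1 = generate_phantom(spec)
        v2, t2 = generate_phantom(spec)
        assert np.array_equal(v1.voxels, v2.voxels)
        assert np.array_equal(t1.vessel_mask.voxels, t2.vessel_mask.voxels)

    def test_known_arc_rasterises_to_400_mm3(self):
        # 106-degree arc, outer radius 8, radial thickness 3: exactly 40
        # voxel centres per slice fall inside (frozen via the brute-force
        # oracle below), so 10 slices at 1x1x1 mm give 400 mm^3.
        spec = straight_vessel_spec(
            calcifications=[Calcification((0, 10), 0.0, 106.0, 3.0, intensity=220)]
        )
        _, truth = generate_phantom(spec)
        assert truth.true_calcium_voxels == 400
        assert truth.true_calcium_volume == pytest.approx(400.0)
        oracle = brute_force_calcium_count(
            spec, np.asarray(spec.vessel_path), np.asarray(spec.vessel_radius_profile)
        )
        assert oracle == 400

    def test_truth_matches_brute_force_oracle_random_specs(self):
        for seed in (1, 2):
            spec = random_spec(seed, image_size=32, n_slices=4, noise_sigma=0.0)
            from vasccalc.phantom import _resolve_geometry

            path, radii = _resolve_geometry(spec)
            _, truth = generate_phantom(spec)
            assert truth.true_calcium_voxels == brute_force_calcium_count(spec, path, radii)

    def test_calcium_mask_inside_vessel_mask(self):
        for seed in range(5):
            _, truth = generate_phantom(random_spec(seed))
            assert np.all(truth.vessel_mask.voxels >= truth.calcium_mask.voxels)

    def test_noise_never_changes_truth(self):
        spec = random_spec(5, noise_sigma=0.0)
        _, t0 = generate_phantom(spec)
        spec_noisy = random_spec(5, noise_sigma=25.0)
        _, t1 = generate_phantom(spec_noisy)
        assert np.array_equal(t0.calcium_mask.voxels, t1.calcium_mask.voxels)
        assert t0.true_calcium_volume == t1.true_calcium_volume

    def test_volume_is_count_times_voxel_volume(self):
        spec = random_spec(3)
        spec.voxel_spacing = (0.5, 0.5, 2.0)
        _, truth = generate_phantom(spec)
        assert truth.true_calcium_volume == pytest.approx(truth.true_calcium_voxels * 0.5)


class TestRendering:
    def test_calcium_renders_above_threshold_at_zero_noise(self):
        spec = random_spec(9, noise_sigma=0.0)
        vol, truth = generate_phantom(spec)
        assert vol.voxels[truth.calcium_mask.voxels.astype(bool)].min() > 145

    def test_vessel_is_one_component_per_slice(self):
        vol, truth = generate_phantom(random_spec(11, noise_sigma=0.0))
        for s in range(vol.n_slices):
            n_comp = measure.label(truth.vessel_mask.voxels[s]).max()
            assert n_comp == 1

    def test_noise_clipped_to_8bit(self):
        vol, _ = generate_phantom(random_spec(2, noise_sigma=80.0))
        assert vol.voxels.min() >= 0 and vol.voxels.max() <= 255


class TestValidation:
    def test_path_exiting_frame_rejected(self):
        spec = straight_vessel_spec(vessel_path=np.tile([4.0, 32.0], (10, 1)))
        with pytest.raises(ValueError, match="frame"):
            generate_phantom(spec)

    def test_arc_thicker_than_wall_rejected(self):
        spec = straight_vessel_spec(
            calcifications=[Calcification((0, 5), 0.0, 90.0, radial_thickness=5.0)]
        )
        with pytest.raises(ValueError, match="wall"):
            generate_phantom(spec)

    def test_lumen_above_threshold_rejected(self):
        with pytest.raises(ValueError, match="lumen"):
            generate_phantom(straight_vessel_spec(lumen_intensity=150))

    def test_bone_overlapping_vessel_rejected(self):
        spec = straight_vessel_spec(bones=[Bone((32.0, 40.0), 6.0)])
        with pytest.raises(ValueError, match="bone"):
            generate_phantom(spec)

    def test_unknown_artifact_rejected(self):
        with pytest.raises(ValueError, match="artifact"):
            generate_phantom(straight_vessel_spec(artifact="ghost"))


class TestArtifacts:
    @pytest.fixture
    def phantom(self):
        return generate_phantom(random_spec(21, noise_sigma=0.0))

    def test_none_is_identity(self, phantom):
        vol, truth = phantom
        out = apply_artifact(vol, truth, "none")
        assert np.array_equal(out.voxels, vol.voxels)

    def test_no_contrast_lowers_lumen_mean(self, phantom):
        vol, truth = phantom
        out = apply_artifact(vol, truth, "no_contrast")
        vessel = truth.vessel_mask.voxels.astype(bool)
        assert out.voxels[vessel].mean() < vol.voxels[vessel].mean()

    def test_stent_adds_bright_voxels_outside_calcium(self, phantom):
        vol, truth = phantom
        out = apply_artifact(vol, truth, "stent")
        calc = truth.calcium_mask.voxels.astype(bool)
        assert np.any((out.voxels > 145) & ~calc)

    def test_metal_streak_saturates_voxels(self, phantom):
        vol, truth = phantom
        out = apply_artifact(vol, truth, "metal_streak")
        assert (out.voxels == 255).sum() > (vol.voxels == 255).sum()

    def test_artifacts_leave_truth_untouched(self, phantom):
        vol, truth = phantom
        before = truth.vessel_mask.voxels.copy()
        for kind in ("no_contrast", "metal_streak", "stent"):
            apply_artifact(vol, truth, kind)
        assert np.array_equal(truth.vessel_mask.voxels, before)

    def test_unknown_kind_rejected(self, phantom):
        vol, truth = phantom
        with pytest.raises(ValueError):
            apply_artifact(vol, truth, "blur")


class TestCohort:
    def test_cohort_patient_ids_and_independence(self):
        cohort = make_cohort(3, seed=50, image_size=32, n_slices=4)
        assert [v.patient_id for v, _ in cohort] == ["P00", "P01", "P02"]
        assert not np.array_equal(cohort[0][0].voxels, cohort[1][0].voxels)
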