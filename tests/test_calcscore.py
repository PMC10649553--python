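"""Calcium scoring: extraction, thresholded counting, volume conversion."""

import numpy as np
import pytest

from vasccalc.calcscore import (
    ScoreConfig,
    calcium_score,
    count_calcified,
    extract_vasculature,
)
from vasccalc.phantom import generate_phantom, random_spec
from vasccalc.volume import BinaryMask, CTVolume

from conftest import random_mask


def oracle_counts(voxels, threshold, inclusive=False):
    """Independent double-loop threshold scan."""
    out = []
    for s in voxels:
        n = 0
        for row in s:
            for v in row:
                if (v >= threshold) if inclusive else (v > threshold):
                    n += 1
        out.append(n)
    return out


class TestExtraction:
    def test_all_ones_mask_is_identity(self, rng):
        vox = rng.integers(0, 256, (2, 6, 6)).astype(np.int16)
        vol = CTVolume(vox, "8bit")
        out = extract_vasculature(vol, BinaryMask(np.ones_like(vox, dtype=np.uint8)))
        assert np.array_equal(out.voxels, vox)

    def test_all_zeros_mask_zeroes_volume(self, rng):
        vox = rng.integers(0, 256, (2, 6, 6)).astype(np.int16)
        out = extract_vasculature(
            CTVolume(vox, "8bit"), BinaryMask(np.zeros_like(vox, dtype=np.uint8))
        )
        assert out.voxels.max() == 0

    def test_phantom_vessel_extraction(self):
        vol, truth = generate_phantom(random_spec(4, noise_sigma=0.0))
        out = extract_vasculature(vol, truth.vessel_mask)
        outside = ~truth.vessel_mask.voxels.astype(bool)
        assert out.voxels[outside].max() == 0
        assert np.array_equal(
            out.voxels[~outside], vol.voxels[~outside]
        )

    def test_shape_and_scale_errors(self, rng):
        vol = CTVolume(rng.integers(0, 256, (2, 6, 6)).astype(np.int16), "8bit")
        with pytest.raises(ValueError):
            extract_vasculature(vol, BinaryMask(np.zeros((2, 4, 4), dtype=np.uint8)))
        hu = CTVolume(np.zeros((2, 6, 6), dtype=np.int16), "HU")
        with pytest.raises(ValueError):
            extract_vasculature(hu, BinaryMask(np.zeros((2, 6, 6), dtype=np.uint8)))


class TestCounting:
    def test_strict_inequality_at_threshold(self):
        vol = CTVolume(np.full((3, 4, 4), 145, dtype=np.int16), "8bit")
        assert count_calcified(vol).tolist() == [0, 0, 0]

    def test_one_above_threshold_counts_everything(self):
        vol = CTVolume(np.full((2, 4, 4), 146, dtype=np.int16), "8bit")
        assert count_calcified(vol).tolist() == [16, 16]

    def test_inclusive_flag_covers_geq_reading(self):
        vol = CTVolume(np.full((1, 4, 4), 145, dtype=np.int16), "8bit")
        assert count_calcified(vol, ScoreConfig(inclusive=True)).tolist() == [16]

    def test_matches_double_loop_oracle_random_slices(self, rng):
        vox = rng.integers(0, 256, (4, 8, 8)).astype(np.int16)
        vol = CTVolume(vox, "8bit")
        assert count_calcified(vol).tolist() == oracle_counts(vox, 145)

    def test_min_component_area_filter(self):
        s = np.zeros((1, 8, 8), dtype=np.int16)
        s[0, 0, 0] = 200                      # isolated single voxel
        s[0, 4, 2:7] = 200                    # five-voxel component
        vol = CTVolume(s, "8bit", spacing=(1.0, 1.0, 1.0))
        cfg = ScoreConfig(min_component_area_mm2=2.0)
        assert count_calcified(vol, cfg).tolist() == [5]
        assert count_calcified(vol).tolist() == [6]  # filter off by default

    def test_invalid_threshold_rejected(self):
        with pytest.raises(ValueError):
            ScoreConfig(threshold=300)


class TestScoring:
    def test_exact_recovery_on_noise_free_phantom(self):
        vol, truth = generate_phantom(random_spec(8, noise_sigma=0.0))
        report = calcium_score(vol, truth.vessel_mask)
        assert report.total_volume_mm3 == truth.true_calcium_volume
        assert report.total_count == truth.true_calcium_voxels

    def test_slice_range_excluding_calcification_scores_zero(self):
        from vasccalc.phantom import Calcification, PhantomSpec

        spec = PhantomSpec(
            image_size=64, n_slices=10,
            vessel_path=np.tile([32.0, 32.0], (10, 1)),
            vessel_radius_profile=np.full(10, 8.0),
            calcifications=[Calcification((5, 10), 0.0, 90.0, 3.0)],
        )
        vol, truth = generate_phantom(spec)
        report = calcium_score(vol, truth.vessel_mask, ScoreConfig(slice_range=(0, 5)))
        assert report.total_count == 0

    def test_doubling_dz_doubles_volume_not_counts(self):
        vol, truth = generate_phantom(random_spec(9, noise_sigma=0.0))
        r1 = calcium_score(vol, truth.vessel_mask)
        r2 = calcium_score(vol, truth.vessel_mask, spacing=(1.0, 1.0, 2.0))
        assert r2.per_slice_counts == r1.per_slice_counts
        assert r2.total_volume_mm3 == pytest.approx(2 * r1.total_volume_mm3)

    def test_empty_slice_range_rejected(self):
        vol, truth = generate_phantom(random_spec(10, noise_sigma=0.0))
        with pytest.raises(ValueError):
            calcium_score(vol, truth.vessel_mask, ScoreConfig(slice_range=(4, 4)))

    def test_report_internal_consistency(self):
        vol, truth = generate_phantom(random_spec(11, noise_sigma=4.0))
        report = calcium_score(vol, truth.vessel_mask)
        assert report.total_count == sum(report.per_slice_counts)
        assert report.total_volume_mm3 == pytest.approx(
            report.total_count * report.voxel_volume_mm3
        )
        frame = report.to_frame()
        assert frame["calcified_voxels"].sum() == report.total_count


class TestMonotonicity:
    def test_counts_non_increasing_in_threshold(self, rng):
        vox = rng.integers(0, 256, (3, 10, 10)).astype(np.int16)
        vol = CTVolume(vox, "8bit")
        prev = count_calcified(vol, ScoreConfig(threshold=100))
        for thr in (140, 180, 220):
            cur = count_calcified(vol, ScoreConfig(threshold=thr))
            assert np.all(cur <= prev)
            prev = cur

    def test_superset_mask_never_decreases_count(self, rng):
        vox = rng.integers(0, 256, (2, 10, 10)).astype(np.int16)
        vol = CTVolume(vox, "8bit")
        small = random_mask(rng, vox.shape, 0.3)
        big = np.clip(small + random_mask(rng, vox.shape, 0.3), 0, 1)
        r_small = calcium_score(vol, BinaryMask(small))
        r_big = calcium_score(vol, BinaryMask(big))
        assert r_big.total_count >= r_small.total_count

    def test_full_mask_upper_bounds_any_mask(self, rng):
        vox = rng.integers(0, 256, (2, 8, 8)).astype(np.int16)
        vol = CTVolume(vox, "8bit")
        full = calcium_score(vol, BinaryMask(np.ones_like(vox, dtype=np.uint8)))
        for _ in range(5):
            m = random_mask(rng, vox.shape, rng.uniform(0.2, 0.8))
            assert calcium_score(vol, BinaryMask(m)).total_count <= full.total_count
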