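"""Automated calcification scoring on segmented CTA volumes.

The scoring stage multiplies the 8-bit volume by the binary vessel mask
to extract the vascular system, counts the voxels whose intensity exceeds
a threshold of 145 on the 0–255 scale (strict inequality by default; an
inclusive comparison is available), and converts the count to a volume
with the conversion factor dx·dy·dz from the voxel spacing.  Counting is
per 2-D transverse slice over a half-open anatomical slice range — in the
clinical protocol, from immediately below the left renal artery to the
middle of the knees; the start slice is a human-chosen landmark, not
auto-detected.

An optional Agatston-style minimum-component-area filter (8-connected
2-D components below a given mm² discarded) is provided but off by
default: the automated protocol applies plain thresholding.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from skimage import measure

from .volume import BinaryMask, CTVolume

__all__ = [
    "ScoreConfig",
    "CalcificationReport",
    "extract_vasculature",
    "count_calcified",
    "calcium_score",
]

DEFAULT_THRESHOLD = 145


@dataclass(frozen=True)
class ScoreConfig:
    """Scoring parameters.

    ``threshold`` is on the 0–255 8-bit scale; ``inclusive=False`` means a
    voxel is calcified iff intensity > threshold.  ``slice_range`` is
    half-open ``[start, end)``; ``None`` means the full volume.
    """

    threshold: int = DEFAULT_THRESHOLD
    inclusive: bool = False
    min_component_area_mm2: float | None = None
    slice_range: tuple[int, int] | None = None

    def __post_init__(self):
        if not (0 <= self.threshold <= 255):
            raise ValueError("threshold must be on the 8-bit scale [0, 255]")
        if self.min_component_area_mm2 is not None and self.min_component_area_mm2 < 0:
            raise ValueError("minimum component area must be non-negative")


@dataclass
class CalcificationReport:
    """Per-slice calcified-voxel counts and their volumetric conversion."""

    patient_id: str
    slice_range: tuple[int, int]
    per_slice_counts: list[int]
    voxel_volume_mm3: float
    threshold: int
    inclusive: bool
    min_component_area_mm2: float | None

    @property
    def total_count(self) -> int:
        return int(sum(self.per_slice_counts))

    @property
    def total_volume_mm3(self) -> float:
        return self.total_count * self.voxel_volume_mm3

    def to_dict(self) -> dict:
        d = asdict(self)
        d["slice_range"] = list(d["slice_range"])
        d["total_count"] = self.total_count
        d["total_volume_mm3"] = self.total_volume_mm3
        return d

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    def to_frame(self) -> pd.DataFrame:
        start, end = self.slice_range
        return pd.DataFrame(
            {
                "patient_id": self.patient_id,
                "slice": np.arange(start, end),
                "calcified_voxels": self.per_slice_counts,
                "calcified_volume_mm3": np.asarray(self.per_slice_counts)
                * self.voxel_volume_mm3,
            }
        )


def extract_vasculature(vol8: CTVolume, mask: BinaryMask) -> CTVolume:
    """Voxelwise product of image and mask: zero everywhere outside the vessel."""
    if vol8.intensity_scale != "8bit":
        raise ValueError("extraction operates on the 8-bit scale")
    mask.check_locked_to(vol8)
    return CTVolume(
        vol8.voxels * mask.voxels, "8bit", vol8.spacing, vol8.patient_id
    )


def _slice_count(slice_img: np.ndarray, config: ScoreConfig, pixel_area_mm2: float) -> int:
    if config.inclusive:
        above = slice_img >= config.threshold
    else:
        above = slice_img > config.threshold
    if config.min_component_area_mm2 is None:
        return int(above.sum())
    labels = measure.label(above, connectivity=2)  # 8-connectivity
    count = 0
    for region in measure.regionprops(labels):
        if region.area * pixel_area_mm2 >= config.min_component_area_mm2:
            count += region.area
    return int(count)


def count_calcified(extracted: CTVolume, config: ScoreConfig | None = None) -> np.ndarray:
    """Per-slice count of voxels above the calcification threshold."""
    config = config or ScoreConfig()
    if extracted.intensity_scale != "8bit":
        raise ValueError("counting operates on the 8-bit scale")
    dx, dy, _ = extracted.spacing
    return np.array(
        [_slice_count(s, config, dx * dy) for s in extracted.voxels], dtype=int
    )


def calcium_score(
    vol8: CTVolume,
    mask: BinaryMask,
    config: ScoreConfig | None = None,
    spacing: tuple[float, float, float] | None = None,
) -> CalcificationReport:
    """Extract the vasculature, threshold, count and convert to volume.

    The report covers ``config.slice_range`` (half-open; full volume when
    unset); total volume is total voxel count × dx·dy·dz.
    """
    config = config or ScoreConfig()
    spacing = spacing or vol8.spacing
    start, end = config.slice_range if config.slice_range is not None else (0, vol8.n_slices)
    if not (0 <= start < end <= vol8.n_slices):
        raise ValueError(
            f"slice range [{start}, {end}) empty or outside the {vol8.n_slices}-slice volume"
        )
    extracted = extract_vasculature(vol8, mask)
    window = CTVolume(
        extracted.voxels[start:end], "8bit", spacing, vol8.patient_id
    )
    counts = count_calcified(window, config)
    dx, dy, dz = spacing
    return CalcificationReport(
        patient_id=vol8.patient_id,
        slice_range=(start, end),
        per_slice_counts=[int(c) for c in counts],
        voxel_volume_mm3=dx * dy * dz,
        threshold=config.threshold,
        inclusive=config.inclusive,
        min_component_area_mm2=config.min_component_area_mm2,
    )
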