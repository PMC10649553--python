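"""Volumetric containers and I/O for CT angiography data.

A study volume is an ordered stack of transverse slices indexed
``(slice, row, col)``, slice index 0-based, slice ranges half-open
``[start, end)``.  Two intensity scales are supported: calibrated
Hounsfield units (``"HU"``) and the 0–255 8-bit scale on which the
calcium-scoring threshold is defined.

Volumes round-trip through NIfTI (via nibabel) or through a directory of
per-slice 8-bit grayscale PNGs with a JSON sidecar carrying the voxel
spacing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import nibabel as nib
import numpy as np

__all__ = [
    "CTVolume",
    "BinaryMask",
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
    "hu_to_8bit",
]

_SIDECAR = "volume.json"


@dataclass
class CTVolume:
    """An ordered stack of transverse CT slices with voxel spacing.

    Parameters
    ----------
    voxels : ndarray, shape (n_slices, n_rows, n_cols)
        Integer intensity grid.
    intensity_scale : {"HU", "8bit"}
        Scale of ``voxels``; 8-bit volumes must lie in [0, 255].
    spacing : (dx, dy, dz)
        In-plane and inter-slice voxel spacing in millimetres.
    patient_id : str
        Free-form identifier used for per-patient reporting.
    """

    voxels: np.ndarray
    intensity_scale: str = "8bit"
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    patient_id: str = ""

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError(f"volume must be 3-D (slice,row,col); got {self.voxels.ndim}-D")
        if self.intensity_scale not in ("HU", "8bit"):
            raise ValueError(f"unknown intensity scale {self.intensity_scale!r}")
        if self.intensity_scale == "8bit":
            if self.voxels.min() < 0 or self.voxels.max() > 255:
                raise ValueError("8bit volume has values outside [0, 255]")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be three positive lengths; got {self.spacing}")

    @property
    def n_slices(self) -> int:
        return self.voxels.shape[0]

    @property
    def slice_shape(self) -> tuple[int, int]:
        return self.voxels.shape[1:]

    @property
    def voxel_volume_mm3(self) -> float:
        dx, dy, dz = self.spacing
        return dx * dy * dz


@dataclass
class BinaryMask:
    """Per-voxel vessel membership, geometry-locked to its parent volume."""

    voxels: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError("mask must be 3-D (slice,row,col)")
        vals = np.unique(self.voxels)
        if not np.all(np.isin(vals, (0, 1))):
            raise ValueError("mask values must be in {0, 1}")
        self.voxels = self.voxels.astype(np.uint8)
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive")

    @property
    def n_slices(self) -> int:
        return self.voxels.shape[0]

    def foreground_count(self) -> int:
        return int(self.voxels.sum())

    def check_locked_to(self, vol: CTVolume) -> None:
        if self.voxels.shape != vol.voxels.shape:
            raise ValueError(
                f"mask shape {self.voxels.shape} does not match volume {vol.voxels.shape}"
            )


def _round_half_up(x: np.ndarray) -> np.ndarray:
    # np.round is round-half-even; scoring contracts pin round-half-up.
    return np.floor(x + 0.5)


def hu_to_8bit(vol: CTVolume, window: tuple[float, float] | None = None) -> CTVolume:
    """Convert a Hounsfield-unit volume to the 0–255 8-bit scale.

    The window ``(lo, hi)`` is mapped linearly onto [0, 255] with clipping
    outside; values are rounded half-up.  The default window is the volume's
    own (min, max), the usual behaviour of an ImageJ-style 8-bit conversion.
    A constant volume (degenerate window) maps to all zeros.
    """
    if vol.intensity_scale != "HU":
        raise ValueError("hu_to_8bit expects a volume on the HU scale")
    x = vol.voxels.astype(np.float64)
    if window is None:
        lo, hi = float(x.min()), float(x.max())
        if lo == hi:
            out = np.zeros_like(x)
            return CTVolume(out.astype(np.int16), "8bit", vol.spacing, vol.patient_id)
    else:
        lo, hi = float(window[0]), float(window[1])
        if lo >= hi:
            raise ValueError(f"window lo must be < hi; got ({lo}, {hi})")
    y = (np.clip(x, lo, hi) - lo) / (hi - lo) * 255.0
    out = _round_half_up(y).astype(np.int16)
    return CTVolume(out, "8bit", vol.spacing, vol.patient_id)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def _nifti_dtype(vol_voxels: np.ndarray) -> np.dtype:
    if vol_voxels.min() >= 0 and vol_voxels.max() <= 255:
        return np.dtype(np.uint8)
    return np.dtype(np.int16)


def write_volume(vol: CTVolume, path: str | Path) -> Path:
    """Write a volume to NIfTI (``.nii``/``.nii.gz``) or a PNG slice directory.

    Any other path is treated as a directory of zero-padded per-slice PNGs
    plus a ``volume.json`` sidecar (spacing, scale, patient id); PNG export
    requires the 8-bit scale.
    """
    path = Path(path)
    if path.suffix in (".nii", ".gz") or path.name.endswith(".nii.gz"):
        data = vol.voxels.astype(_nifti_dtype(vol.voxels))
        # nibabel axis order is (x, y, z) = (col, row, slice)
        affine = np.diag([vol.spacing[0], vol.spacing[1], vol.spacing[2], 1.0])
        img = nib.Nifti1Image(data.transpose(2, 1, 0), affine)
        img.header["descrip"] = f"scale={vol.intensity_scale};pid={vol.patient_id}"[:80].encode()
        nib.save(img, str(path))
        return path
    if vol.intensity_scale != "8bit":
        raise ValueError("PNG slice stacks only support the 8bit scale; convert first")
    path.mkdir(parents=True, exist_ok=True)
    width = max(3, len(str(vol.n_slices)))
    for i in range(vol.n_slices):
        iio.imwrite(path / f"{i:0{width}d}.png", vol.voxels[i].astype(np.uint8))
    sidecar = {
        "spacing": list(vol.spacing),
        "intensity_scale": vol.intensity_scale,
        "patient_id": vol.patient_id,
    }
    (path / _SIDECAR).write_text(json.dumps(sidecar, indent=1))
    return path


def read_volume(path: str | Path) -> CTVolume:
    """Read a volume written by :func:`write_volume` (NIfTI or PNG stack)."""
    path = Path(path)
    if path.is_dir():
        sidecar_path = path / _SIDECAR
        if not sidecar_path.exists():
            raise FileNotFoundError(f"PNG stack {path} is missing its {_SIDECAR} sidecar")
        meta = json.loads(sidecar_path.read_text())
        files = sorted(p for p in path.iterdir() if p.suffix.lower() == ".png")
        if not files:
            raise FileNotFoundError(f"no PNG slices found in {path}")
        slices = [np.asarray(iio.imread(p)) for p in files]
        shapes = {s.shape for s in slices}
        if len(shapes) != 1:
            raise ValueError(f"mixed slice shapes in {path}: {sorted(shapes)}")
        vox = np.stack(slices).astype(np.int16)
        return CTVolume(
            vox,
            meta.get("intensity_scale", "8bit"),
            tuple(meta["spacing"]),
            meta.get("patient_id", ""),
        )
    img = nib.load(str(path))
    vox = np.asanyarray(img.dataobj).transpose(2, 1, 0)
    zooms = img.header.get_zooms()[:3]
    descrip = img.header["descrip"].tobytes().rstrip(b"\x00").decode(errors="replace")
    meta = dict(kv.split("=", 1) for kv in descrip.split(";") if "=" in kv)
    scale = meta.get("scale", "HU" if vox.min() < 0 else "8bit")
    return CTVolume(
        vox.astype(np.int16),
        scale,
        (float(zooms[0]), float(zooms[1]), float(zooms[2])),
        meta.get("pid", ""),
    )


def write_mask(mask: BinaryMask, path: str | Path) -> Path:
    """Write a binary mask (stored as unsigned 8-bit with values {0,1})."""
    vol = CTVolume(mask.voxels.astype(np.uint8), "8bit", mask.spacing)
    return write_volume(vol, path)


def read_mask(path: str | Path) -> BinaryMask:
    vol = read_volume(path)
    vox = vol.voxels
    # tolerate 0/255 PNG exports from external viewers
    if vox.max() > 1:
        vox = (vox > 0).astype(np.uint8)
    return BinaryMask(vox, vol.spacing)
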