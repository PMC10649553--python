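"""Synthetic CT-angiography phantoms with analytically known ground truth.

The proprietary patient scans behind the original study cannot be shared,
so validation runs on phantoms that emulate their structure: a square
transverse slice stack containing one contrast-bright vessel (a disk whose
centre drifts smoothly from slice to slice), a darker non-calcified wall
ring, hyperintense calcified arcs embedded in that wall, and bone-like disk
confounders whose intensity overlaps the calcifications.  Optional
artifacts reproduce the study's observed failure modes: missing contrast,
metal-streak distortion from a spinal screw, and a stent.

Everything is rasterised with a single rule — a voxel belongs to a region
iff its integer centre lies inside the analytic region — so the true
calcium volume (voxel count × dx·dy·dz) is exact by construction and never
depends on rendering or noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .volume import BinaryMask, CTVolume

__all__ = [
    "Calcification",
    "Bone",
    "PhantomSpec",
    "PhantomTruth",
    "generate_phantom",
    "apply_artifact",
    "random_spec",
    "make_cohort",
    "ARTIFACT_KINDS",
]

ARTIFACT_KINDS = ("none", "no_contrast", "metal_streak", "stent")

# Calcium-scoring threshold on the 8-bit scale; calcifications must render
# strictly above it at zero noise.
_SCORING_THRESHOLD = 145


@dataclass(frozen=True)
class Calcification:
    """A calcified arc in the vessel wall.

    Occupies, on every slice of the half-open ``slice_range``, the annulus
    sector with radius in ``[R − radial_thickness, R]`` (R the vessel's
    outer radius on that slice) and polar angle within
    ``[angle_start_deg, angle_start_deg + arc_extent_deg)``.
    """

    slice_range: tuple[int, int]
    angle_start_deg: float
    arc_extent_deg: float
    radial_thickness: float
    intensity: int = 220


@dataclass(frozen=True)
class Bone:
    """A bone-like disk confounder, constant across slices."""

    center: tuple[float, float]  # (row, col)
    radius: float
    intensity: int = 200


@dataclass
class PhantomSpec:
    """Full parameterisation of a synthetic CTA volume.

    ``vessel_path`` (per-slice centre, (row, col)) and
    ``vessel_radius_profile`` (per-slice outer radius in pixels) default to
    a smooth seeded drift and a gentle distal taper when left ``None``.
    Intensities are on the 0–255 8-bit scale the calcium scoring operates
    on.
    """

    image_size: int = 128
    n_slices: int = 40
    voxel_spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    vessel_path: np.ndarray | None = None
    vessel_radius_profile: np.ndarray | None = None
    wall_thickness: float = 3.0
    lumen_intensity: int = 130
    wall_intensity: int = 90
    background_intensity: int = 40
    calcifications: list[Calcification] = field(default_factory=list)
    bones: list[Bone] = field(default_factory=list)
    artifact: str = "none"
    noise_sigma: float = 0.0
    start_slice: int = 0
    seed: int = 0


@dataclass
class PhantomTruth:
    """Analytic ground truth for a generated phantom."""

    vessel_mask: BinaryMask
    calcium_mask: BinaryMask
    true_calcium_voxels: int
    true_calcium_volume: float  # mm^3
    start_slice: int = 0


def _default_path(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    n, s = spec.image_size, spec.n_slices
    t = np.arange(s)
    amp = 0.08 * n
    phase = rng.uniform(0, 2 * np.pi, size=2)
    freq = rng.uniform(0.5, 1.5, size=2)
    rows = n / 2 + amp * np.sin(2 * np.pi * freq[0] * t / max(s, 1) + phase[0])
    cols = n / 2 + amp * np.sin(2 * np.pi * freq[1] * t / max(s, 1) + phase[1])
    return np.stack([rows, cols], axis=1)

def _default_radii(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    base = spec.image_size * rng.uniform(0.10, 0.14)
    taper = np.linspace(1.0, rng.uniform(0.8, 1.0), spec.n_slices)
    return base * taper


def _resolve_geometry(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray]:
    rng = np.random.default_rng(spec.seed)
    path = spec.vessel_path if spec.vessel_path is not None else _default_path(spec, rng)
    radii = (
        spec.vessel_radius_profile
        if spec.vessel_radius_profile is not None
        else _default_radii(spec, rng)
    )
    path = np.asarray(path, dtype=float)
    radii = np.broadcast_to(np.asarray(radii, dtype=float), (spec.n_slices,)).copy()
    if path.shape != (spec.n_slices, 2):
        raise ValueError(f"vessel_path must have shape ({spec.n_slices}, 2); got {path.shape}")
    if np.any(radii <= 0):
        raise ValueError("vessel radius must be strictly positive on every slice")
    return path, radii


def _validate(spec: PhantomSpec, path: np.ndarray, radii: np.ndarray) -> None:
    n = spec.image_size
    lo = path - radii[:, None]
    hi = path + radii[:, None]
    if lo.min() < 0 or hi.max() > n - 1:
        raise ValueError("vessel path exits the image frame")
    if spec.wall_thickness <= 0 or np.any(radii <= spec.wall_thickness):
        raise ValueError("wall thickness must be positive and thinner than the vessel radius")
    if spec.lumen_intensity > _SCORING_THRESHOLD:
        raise ValueError(
            "lumen intensity must not exceed the scoring threshold "
            f"({_SCORING_THRESHOLD}): the threshold is defined to exclude "
            "contrast-filled lumen"
        )
    for c in spec.calcifications:
        s0, s1 = c.slice_range
        if not (0 <= s0 < s1 <= spec.n_slices):
            raise ValueError(f"calcification slice range {c.slice_range} outside the volume")
        if not (0 < c.radial_thickness <= spec.wall_thickness):
            raise ValueError("calcification arc lies outside the vessel wall")
        if not (0 < c.arc_extent_deg <= 360):
            raise ValueError("arc extent must be in (0, 360] degrees")
        if c.intensity <= _SCORING_THRESHOLD:
            raise ValueError(
                f"calcification intensity must exceed {_SCORING_THRESHOLD}; got {c.intensity}"
            )
    for b in spec.bones:
        d = np.hypot(path[:, 0] - b.center[0], path[:, 1] - b.center[1])
        if np.any(d <= radii + b.radius):
            raise ValueError("bone confounder overlaps the vessel")
    if spec.artifact not in ARTIFACT_KINDS:
        raise ValueError(f"unknown artifact kind {spec.artifact!r}")
    if not (0 <= spec.start_slice < spec.n_slices):
        raise ValueError("start_slice outside the volume")


def _slice_masks(spec: PhantomSpec, path: np.ndarray, radii: np.ndarray, s: int):
    """Boolean (vessel, lumen, per-calcification) masks for slice ``s``."""
    n = spec.image_size
    rr, cc = np.mgrid[0:n, 0:n]
    cy, cx = path[s]
    r = radii[s]
    d2 = (rr - cy) ** 2 + (cc - cx) ** 2
    vessel = d2 <= r**2
    lumen = d2 <= (r - spec.wall_thickness) ** 2
    calcs = []
    theta = np.degrees(np.arctan2(rr - cy, cc - cx)) % 360.0
    for c in spec.calcifications:
        s0, s1 = c.slice_range
        if not (s0 <= s < s1):
            calcs.append(np.zeros_like(vessel))
            continue
        radial = (d2 <= r**2) & (d2 >= (r - c.radial_thickness) ** 2)
        rel = (theta - c.angle_start_deg) % 360.0
        angular = rel < c.arc_extent_deg
        calcs.append(radial & angular)
    return vessel, lumen, calcs


def generate_phantom(spec: PhantomSpec) -> tuple[CTVolume, PhantomTruth]:
    """Render a phantom volume and its analytic truth.

    Deterministic for a fixed spec and seed.  At ``noise_sigma = 0`` every
    calcification voxel renders strictly above the scoring threshold and
    all other voxels at their specified intensities; the truth masks are
    independent of noise and artifacts.
    """
    path, radii = _resolve_geometry(spec)
    _validate(spec, path, radii)
    n, s_count = spec.image_size, spec.n_slices

    img = np.full((s_count, n, n), spec.background_intensity, dtype=float)
    vessel_mask = np.zeros((s_count, n, n), dtype=np.uint8)
    calcium_mask = np.zeros((s_count, n, n), dtype=np.uint8)

    rr, cc = np.mgrid[0:n, 0:n]
    for b in spec.bones:
        disk = (rr - b.center[0]) ** 2 + (cc - b.center[1]) ** 2 <= b.radius**2
        img[:, disk] = b.intensity

    for s in range(s_count):
        vessel, lumen, calcs = _slice_masks(spec, path, radii, s)
        img[s][vessel] = spec.wall_intensity
        img[s][lumen] = spec.lumen_intensity
        vessel_mask[s][vessel] = 1
        for c, region in zip(spec.calcifications, calcs):
            img[s][region] = c.intensity
            calcium_mask[s][region] = 1

    spacing = spec.voxel_spacing
    truth = PhantomTruth(
        vessel_mask=BinaryMask(vessel_mask, spacing),
        calcium_mask=BinaryMask(calcium_mask, spacing),
        true_calcium_voxels=int(calcium_mask.sum()),
        true_calcium_volume=float(calcium_mask.sum()) * spacing[0] * spacing[1] * spacing[2],
        start_slice=spec.start_slice,
    )

    vol = CTVolume(
        np.clip(np.floor(img + 0.5), 0, 255).astype(np.int16), "8bit", spacing,
        patient_id=f"phantom-{spec.seed}",
    )
    if spec.artifact != "none":
        vol = apply_artifact(vol, truth, spec.artifact)
    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed + 1)
        noisy = vol.voxels + rng.normal(0.0, spec.noise_sigma, vol.voxels.shape)
        vol = CTVolume(
            np.clip(np.floor(noisy + 0.5), 0, 255).astype(np.int16),
            "8bit", spacing, vol.patient_id,
        )
    return vol, truth


def apply_artifact(volume: CTVolume, truth: PhantomTruth, artifact: str) -> CTVolume:
    """Corrupt the image with one of the study's observed failure modes.

    Truth masks are untouched: artifacts corrupt the image, not the
    anatomy.  ``none`` is the identity.
    """
    if artifact not in ARTIFACT_KINDS:
        raise ValueError(f"unknown artifact kind {artifact!r}")
    vox = volume.voxels.astype(float).copy()
    vessel = truth.vessel_mask.voxels.astype(bool)
    calcium = truth.calcium_mask.voxels.astype(bool)

    if artifact == "none":
        pass
    elif artifact == "no_contrast":
        # pull non-calcified vessel intensities toward the background level
        bg = float(np.median(vox[~vessel]))
        region = vessel & ~calcium
        vox[region] = bg + 0.25 * (vox[region] - bg)
    elif artifact == "metal_streak":
        # saturated radial streaks emanating from the brightest extravascular
        # point (screw-like), drawn across all slices
        mid = vox.shape[0] // 2
        outside = np.where(~vessel[mid], vox[mid], -np.inf)
        cy, cx = np.unravel_index(np.argmax(outside), outside.shape)
        n = vox.shape[1]
        length = n // 2
        for ang in np.linspace(0.0, np.pi, 8, endpoint=False):
            t = np.arange(length, dtype=float)
            ry = np.clip(np.floor(cy + t * np.sin(ang) + 0.5), 0, vox.shape[1] - 1).astype(int)
            rx = np.clip(np.floor(cx + t * np.cos(ang) + 0.5), 0, vox.shape[2] - 1).astype(int)
            vox[:, ry, rx] = 255.0
            ry2 = np.clip(np.floor(cy - t * np.sin(ang) + 0.5), 0, vox.shape[1] - 1).astype(int)
            rx2 = np.clip(np.floor(cx - t * np.cos(ang) + 0.5), 0, vox.shape[2] - 1).astype(int)
            vox[:, ry2, rx2] = 255.0
    elif artifact == "stent":
        # hyperintense annulus straddling the vessel boundary
        for s in range(vox.shape[0]):
            v = vessel[s]
            ring = ndimage.binary_dilation(v, iterations=1) & ~ndimage.binary_erosion(
                v, iterations=2
            )
            vox[s][ring] = 230.0

    return CTVolume(
        np.clip(np.floor(vox + 0.5), 0, 255).astype(np.int16),
        volume.intensity_scale,
        volume.spacing,
        volume.patient_id,
    )


def random_spec(
    seed: int,
    image_size: int = 64,
    n_slices: int = 8,
    noise_sigma: float = 5.0,
    n_calcifications: tuple[int, int] = (1, 3),
    artifact: str = "none",
) -> PhantomSpec:
    """Draw a randomised phantom spec emulating one patient scan.

    Calcified-arc counts, extents and positions vary between seeds so a
    cohort spans a wide range of true calcium volumes; one bone confounder
    with calcification-overlapping intensity is always present.
    """
    rng = np.random.default_rng(seed)
    n_calc = int(rng.integers(n_calcifications[0], n_calcifications[1] + 1))
    calcs = []
    for _ in range(n_calc):
        s0 = int(rng.integers(0, max(n_slices - 2, 1)))
        s1 = int(rng.integers(s0 + 2, n_slices + 1))
        calcs.append(
            Calcification(
                slice_range=(s0, s1),
                angle_start_deg=float(rng.uniform(0, 360)),
                arc_extent_deg=float(rng.uniform(50, 170)),
                radial_thickness=float(rng.uniform(1.8, 3.0)),
                intensity=int(rng.integers(200, 246)),
            )
        )
    corner = rng.choice([0.18, 0.82])
    bone = Bone(
        center=(image_size * 0.84, image_size * float(corner)),
        radius=image_size * 0.10,
        intensity=200,
    )
    return PhantomSpec(
        image_size=image_size,
        n_slices=n_slices,
        calcifications=calcs,
        bones=[bone],
        noise_sigma=noise_sigma,
        artifact=artifact,
        seed=seed,
    )


def make_cohort(
    n_patients: int,
    seed: int = 0,
    **spec_kwargs,
) -> list[tuple[CTVolume, PhantomTruth]]:
    """Generate a cohort of independent phantom patients.

    Patient ``i`` uses seed ``seed + i``; volumes carry ids ``P00, P01, …``.
    """
    cohort = []
    for i in range(n_patients):
        spec = random_spec(seed + i, **spec_kwargs)
        vol, truth = generate_phantom(spec)
        vol.patient_id = f"P{i:02d}"
        cohort.append((vol, truth))
    return cohort
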