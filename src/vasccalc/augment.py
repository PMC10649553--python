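"""Stochastic training-time augmentation, applied jointly to image and mask.

Geometric transforms — horizontal flip (p = 0.25), grid distortion
(p = 0.70, 5×5 control grid, per-cell limit 0.3) and downscale-rescale
(scale in (0.60, 0.90), p = 0.30) — are applied identically to the image
and its mask, with nearest-neighbour resampling for the mask so it stays
binary.  Photometric transforms — histogram equalisation, CLAHE with clip
limit 0.4, box blur with kernel sampled from odd sizes up to 7, and
brightness/contrast jitter — touch only the image: equalising or
jittering a {0,1} mask is meaningless.

All randomness flows through one ``numpy.random.Generator``, so a fixed
seed reproduces the pipeline bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import exposure

__all__ = ["AugmentConfig", "augment_pair", "augment_dataset"]


@dataclass
class AugmentConfig:
    """Augmentation parameters; defaults follow the training recipe."""

    hflip_prob: float = 0.25
    grid_distort_prob: float = 0.70
    grid_distort_cells: int = 5
    grid_distort_limit: float = 0.3
    downscale_prob: float = 0.30
    downscale_range: tuple[float, float] = (0.60, 0.90)
    hist_eq: bool = True
    hist_eq_prob: float = 0.5
    clahe_clip: float = 0.4
    clahe_prob: float = 0.5
    blur_max_kernel: int = 7
    blur_prob: float = 0.5
    # brightness delta as a fraction of full scale; contrast factor range
    jitter_brightness: float = 0.2
    jitter_contrast: float = 0.2
    jitter_prob: float = 0.5
    seed: int = 0

    def __post_init__(self):
        for name in ("hflip_prob", "grid_distort_prob", "downscale_prob",
                     "hist_eq_prob", "clahe_prob", "blur_prob", "jitter_prob"):
            p = getattr(self, name)
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"{name} must be a probability; got {p}")
        lo, hi = self.downscale_range
        if not (0.0 < lo <= hi <= 1.0):
            raise ValueError(f"downscale_range must lie in (0, 1]; got {self.downscale_range}")
        if self.blur_max_kernel < 3 or self.blur_max_kernel % 2 == 0:
            raise ValueError("blur_max_kernel must be an odd integer >= 3")


def _check_pair(image: np.ndarray, mask: np.ndarray):
    image = np.asarray(image)
    mask = np.asarray(mask)
    if image.shape != mask.shape or image.ndim != 2:
        raise ValueError("image and mask must be 2-D arrays of identical shape")
    if not np.all(np.isin(np.unique(mask), (0, 1))):
        raise ValueError("mask must be binary {0, 1}")
    return image.astype(np.float64), mask.astype(np.uint8)


def _grid_distort(image, mask, cells, limit, rng):
    h, w = image.shape
    # random displacements at (cells+1)^2 control nodes, bilinearly
    # interpolated to a dense field; cell size bounds the shift
    nodes = cells + 1
    dy = rng.uniform(-limit, limit, size=(nodes, nodes)) * (h / cells)
    dx = rng.uniform(-limit, limit, size=(nodes, nodes)) * (w / cells)
    dense_dy = ndimage.zoom(dy, (h / nodes, w / nodes), order=1, mode="nearest")
    dense_dx = ndimage.zoom(dx, (h / nodes, w / nodes), order=1, mode="nearest")
    dense_dy = np.resize(dense_dy, (h, w))
    dense_dx = np.resize(dense_dx, (h, w))
    rr, cc = np.mgrid[0:h, 0:w].astype(np.float64)
    coords = np.array([rr + dense_dy, cc + dense_dx])
    img_out = ndimage.map_coordinates(image, coords, order=1, mode="reflect")
    msk_out = ndimage.map_coordinates(mask, coords, order=0, mode="reflect")
    return img_out, msk_out


def _downscale_rescale(image, mask, scale, rng):
    h, w = image.shape
    sh, sw = max(1, int(round(h * scale))), max(1, int(round(w * scale)))
    img_small = ndimage.zoom(image, (sh / h, sw / w), order=1)
    msk_small = ndimage.zoom(mask, (sh / h, sw / w), order=0)
    img_out = ndimage.zoom(img_small, (h / img_small.shape[0], w / img_small.shape[1]), order=1)
    msk_out = ndimage.zoom(msk_small, (h / msk_small.shape[0], w / msk_small.shape[1]), order=0)
    img_out = np.resize(img_out, (h, w))
    msk_out = np.resize(msk_out, (h, w))
    return img_out, msk_out


def augment_pair(
    image: np.ndarray,
    mask: np.ndarray,
    config: AugmentConfig | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Apply one stochastic augmentation draw to an (image, mask) pair.

    Returns an 8-bit image and a {0,1} mask of the same shape.
    Deterministic given the generator state.
    """
    config = config or AugmentConfig()
    rng = rng or np.random.default_rng(config.seed)
    img, msk = _check_pair(image, mask)

    # geometric: identical on image and mask
    if rng.random() < config.hflip_prob:
        img = img[:, ::-1].copy()
        msk = msk[:, ::-1].copy()
    if rng.random() < config.grid_distort_prob:
        img, msk = _grid_distort(
            img, msk, config.grid_distort_cells, config.grid_distort_limit, rng
        )
    if rng.random() < config.downscale_prob:
        scale = rng.uniform(*config.downscale_range)
        img, msk = _downscale_rescale(img, msk, scale, rng)

    # photometric: image only
    if config.hist_eq and rng.random() < config.hist_eq_prob:
        img = exposure.equalize_hist(img / 255.0) * 255.0
    if config.clahe_prob > 0 and rng.random() < config.clahe_prob:
        img = exposure.equalize_adapthist(
            np.clip(img, 0, 255) / 255.0, clip_limit=config.clahe_clip
        ) * 255.0
    if rng.random() < config.blur_prob:
        kernel = int(rng.choice(np.arange(3, config.blur_max_kernel + 1, 2)))
        img = ndimage.uniform_filter(img, size=kernel)
    if rng.random() < config.jitter_prob:
        brightness = rng.uniform(-config.jitter_brightness, config.jitter_brightness) * 255.0
        contrast = 1.0 + rng.uniform(-config.jitter_contrast, config.jitter_contrast)
        img = (img - img.mean()) * contrast + img.mean() + brightness

    img = np.clip(np.floor(img + 0.5), 0, 255).astype(np.uint8)
    return img, msk.astype(np.uint8)


def augment_dataset(
    images: np.ndarray,
    masks: np.ndarray,
    config: AugmentConfig | None = None,
    multiplicity: int = 3,
) -> tuple[np.ndarray, np.ndarray]:
    """Expand a (S, H, W) training set with ``multiplicity`` augmented
    copies of each slice, appended after the originals."""
    config = config or AugmentConfig()
    rng = np.random.default_rng(config.seed)
    out_i = [np.asarray(images, dtype=np.uint8)]
    out_m = [np.asarray(masks, dtype=np.uint8)]
    for _ in range(multiplicity):
        aug_i, aug_m = [], []
        for img, msk in zip(images, masks):
            ai, am = augment_pair(img, msk, config, rng)
            aug_i.append(ai)
            aug_m.append(am)
        out_i.append(np.stack(aug_i))
        out_m.append(np.stack(aug_m))
    return np.concatenate(out_i), np.concatenate(out_m)
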