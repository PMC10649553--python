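"""Encoder–decoder segmentation network for transverse CTA slices.

The architecture is a U-Net whose encoder is a residual-block (ResNet-34
family) feature extractor: a strided stem plus four residual stages, each
halving the spatial resolution, so input sides must be divisible by 2⁵.
Four skip connections (stem and the first three stages) feed a five-block
decoder; each decoder block upsamples ×2, concatenates the matching
encoder feature, and applies two conv→batch-norm→ReLU stages.  A final
1×1 convolution with a sigmoid yields a per-pixel vessel probability.

Grayscale inputs are duplicated into three channels inside the network,
mirroring the convention of encoders pretrained on RGB natural images.
The desk-scale default (one block per stage, 8 base channels) is
architecture-isomorphic to the full 34-layer configuration
(blocks (3, 4, 6, 3), 64 base channels), which trains in reasonable time
only on accelerator hardware.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from . import nn
from .volume import BinaryMask, CTVolume

__all__ = ["ModelConfig", "UNet", "build_model", "predict_volume", "save_model", "load_model"]


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters.

    ``blocks_per_stage=(3, 4, 6, 3)`` with ``base_channels=64`` is the full
    34-layer-family encoder; the defaults are a reduced desk-scale
    configuration with identical topology.
    """

    base_channels: int = 8
    blocks_per_stage: tuple[int, int, int, int] = (1, 1, 1, 1)
    input_channels: int = 3
    pretrained: bool = False
    seed: int = 0

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, text: str) -> "ModelConfig":
        d = json.loads(text)
        d["blocks_per_stage"] = tuple(d["blocks_per_stage"])
        return cls(**d)


class _Stage(nn.Module):
    def __init__(self, in_ch, out_ch, n_blocks, rng):
        super().__init__()
        self.blocks = [nn.ResidualBlock(in_ch, out_ch, stride=2, rng=rng)]
        self.blocks += [nn.ResidualBlock(out_ch, out_ch, rng=rng) for _ in range(n_blocks - 1)]

    def forward(self, x):
        for b in self.blocks:
            x = b(x)
        return x


class _DecoderBlock(nn.Module):
    """Upsample ×2, concatenate the skip (if any), then two conv-BN-ReLU."""

    def __init__(self, in_ch, skip_ch, out_ch, rng):
        super().__init__()
        self.conv1 = nn.ConvBNReLU(in_ch + skip_ch, out_ch, rng=rng)
        self.conv2 = nn.ConvBNReLU(out_ch, out_ch, rng=rng)

    def forward(self, x, skip=None):
        x = x.upsample2x()
        if skip is not None:
            x = nn.Tensor.concat([x, skip], axis=1)
        return self.conv2(self.conv1(x))


class UNet(nn.Module):
    def __init__(self, config: ModelConfig):
        super().__init__()
        if config.pretrained:
            raise NotImplementedError(
                "pretrained encoder weights are an optional external download; "
                "this build always initialises randomly"
            )
        self.config = config
        rng = np.random.default_rng(config.seed)
        c = config.base_channels
        nb = config.blocks_per_stage
        self.stem = nn.ConvBNReLU(config.input_channels, c, stride=2, rng=rng)  # H/2
        self.stage1 = _Stage(c, 2 * c, nb[0], rng)     # H/4
        self.stage2 = _Stage(2 * c, 4 * c, nb[1], rng)  # H/8
        self.stage3 = _Stage(4 * c, 8 * c, nb[2], rng)  # H/16
        self.stage4 = _Stage(8 * c, 8 * c, nb[3], rng)  # H/32 (bottleneck)
        self.dec4 = _DecoderBlock(8 * c, 8 * c, 4 * c, rng)  # consumes stage3 skip
        self.dec3 = _DecoderBlock(4 * c, 4 * c, 2 * c, rng)  # stage2 skip
        self.dec2 = _DecoderBlock(2 * c, 2 * c, c, rng)      # stage1 skip
        self.dec1 = _DecoderBlock(c, c, c, rng)              # stem skip
        self.dec0 = _DecoderBlock(c, 0, c, rng)              # back to full resolution
        self.head = nn.Conv2d(c, 1, kernel=1, padding=0, rng=rng)

    def forward(self, x: nn.Tensor) -> nn.Tensor:
        """Map (N, 1, H, W) grayscale in [0, 1] to (N, 1, H, W) probabilities."""
        h, w = x.shape[2], x.shape[3]
        if h % 32 or w % 32:
            raise ValueError(f"input sides must be divisible by 32; got {h}×{w}")
        if x.shape[1] == 1 and self.config.input_channels == 3:
            x = nn.Tensor.concat([x, x, x], axis=1)  # duplicate grayscale to 3 channels
        s1 = self.stem(x)
        s2 = self.stage1(s1)
        s3 = self.stage2(s2)
        s4 = self.stage3(s3)
        bottom = self.stage4(s4)
        y = self.dec4(bottom, s4)
        y = self.dec3(y, s3)
        y = self.dec2(y, s2)
        y = self.dec1(y, s1)
        y = self.dec0(y)
        return self.head(y).sigmoid()

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())


def build_model(config: ModelConfig | None = None) -> UNet:
    """Build a seeded, randomly initialised segmentation network."""
    return UNet(config or ModelConfig())


def _forward_slices(model: UNet, slices: np.ndarray, batch_size: int = 16) -> np.ndarray:
    """Run eval-mode inference on a (S, H, W) uint8 stack; returns probabilities."""
    model.eval()
    x = slices.astype(np.float32)[:, None] / 255.0
    probs = []
    for i in range(0, x.shape[0], batch_size):
        probs.append(model(nn.Tensor(x[i : i + batch_size])).data[:, 0])
    return np.concatenate(probs, axis=0)


def predict_volume(
    model: UNet,
    vol: CTVolume,
    binarize_threshold: float = 0.5,
    batch_size: int = 16,
) -> tuple[np.ndarray, BinaryMask]:
    """Slice-by-slice inference on a volume.

    Returns the per-voxel probability stack and the binary vessel mask
    obtained by thresholding at ``binarize_threshold`` (probability
    strictly greater), geometry-locked to the input volume.
    """
    if vol.intensity_scale != "8bit":
        raise ValueError("predict_volume expects an 8-bit volume; convert HU input first")
    if not (0.0 < binarize_threshold < 1.0):
        raise ValueError("binarize_threshold must lie in (0, 1)")
    probs = _forward_slices(model, vol.voxels, batch_size=batch_size)
    mask = BinaryMask((probs > binarize_threshold).astype(np.uint8), vol.spacing)
    return probs, mask


def save_model(model: UNet, path: str | Path) -> Path:
    """Save weights (.npz) with an explicit architecture-config JSON sidecar."""
    path = Path(path)
    state = model.state_dict()
    np.savez(path, *state)
    path.with_suffix(".json").write_text(model.config.to_json())
    return path


def load_model(path: str | Path) -> UNet:
    path = Path(path)
    config = ModelConfig.from_json(path.with_suffix(".json").read_text())
    model = UNet(config)
    with np.load(path if path.suffix == ".npz" else path.with_suffix(".npz")) as data:
        state = [data[k] for k in data.files]
    model.load_state_dict(state)
    return model
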