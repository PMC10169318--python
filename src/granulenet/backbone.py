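"""Five-stage residual feature extractor with a fine/coarse skip concatenation.

The architecture follows the 50-layer residual-network layout: a 7x7/stride-2
stem with 3x3/stride-2 max-pooling, then four stages of bottleneck residual
blocks.  Two block types exist:

* the *identity block*, ``H(x) = ReLU(F(x, {Wi}) + x)`` — the shortcut adds
  the unmodified input, so input and output channels must agree;
* the *convolutional block*, ``H(x) = ReLU(F(x, {Wi}) + Ws x)`` — the
  shortcut applies a learned 1x1 projection ``Ws`` (possibly strided), so
  channels and spatial size may change.

``F`` is the bottleneck main path: 1x1 -> 3x3 -> 1x1 convolutions, each
followed by batch-norm, with ReLU after the first two.

The classifier in this package does not consume the last stage alone: the
stage-2 feature map (fine, local detail — 56x56x256 at full scale) is
concatenated with the stage-5 map (coarse, global context — 7x7x2048) and
flattened into a single feature vector of length 56*56*256 + 7*7*2048 =
903,168.  Flatten order is channel-last row-major (C order on (H, W, C)) and
is part of the model contract, since SVM weights are tied to it.

A ``tiny`` scale (64x64 input, channels divided by 8) preserves the topology
— same stage count, same block counts, same stage-2 skip — for CPU-budget
experiments and tests.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from PIL import Image as PILImage
from skimage.transform import resize as _sk_resize

from .errors import ParameterError, ShapeError, StateError
from .layers import BatchNorm, Conv2D, max_pool, relu
from .synthetic import ImageSample

__all__ = [
    "ResidualBlockSpec",
    "BlockWeights",
    "BackboneSpec",
    "FeatureMapSet",
    "FeatureExtractor",
    "identity_block",
    "convolutional_block",
    "build_backbone",
    "extract_features",
    "export_feature_maps",
]

#: Bottleneck kernel sizes are fixed: 1x1, 3x3, 1x1.
BOTTLENECK_KERNELS = (1, 3, 1)


@dataclass(frozen=True)
class ResidualBlockSpec:
    """Shape contract of one residual block."""

    kind: Literal["identity", "convolutional"]
    filters: tuple[int, int, int]
    stride: int = 1
    name: str = "block"

    def __post_init__(self) -> None:
        if self.kind not in ("identity", "convolutional"):
            raise ParameterError(f"unknown block kind {self.kind!r}")
        if self.kind == "identity" and self.stride != 1:
            raise ParameterError("identity block cannot stride")
        if self.stride < 1:
            raise ParameterError("stride must be >= 1")


@dataclass
class BlockWeights:
    """Weights of one block: three main-path conv+BN pairs, optional shortcut."""

    convs: list[Conv2D]
    bns: list[BatchNorm]
    shortcut_conv: Conv2D | None = None
    shortcut_bn: BatchNorm | None = None

    @classmethod
    def random(cls, spec: ResidualBlockSpec, cin: int,
               rng: np.random.Generator) -> "BlockWeights":
        f1, f2, f3 = spec.filters
        convs = [
            Conv2D.he_init(1, 1, cin, f1, rng, stride=spec.stride),
            Conv2D.he_init(3, 3, f1, f2, rng),
            Conv2D.he_init(1, 1, f2, f3, rng),
        ]
        # Near-identity residual init: the last batch-norm of the branch
        # starts with a small scale, so each block perturbs rather than
        # overwrites its input.  Keeps activation variance controlled over
        # ~16 stacked blocks and preserves input signal in the extracted
        # features (the standard residual-network initialisation practice).
        bns = [BatchNorm.identity(f1), BatchNorm.identity(f2),
               BatchNorm(scale=np.full(f3, 0.2), shift=np.zeros(f3))]
        sc_conv = sc_bn = None
        if spec.kind == "convolutional":
            sc_conv = Conv2D.he_init(1, 1, cin, f3, rng, stride=spec.stride)
            sc_bn = BatchNorm.identity(f3)
        return cls(convs=convs, bns=bns, shortcut_conv=sc_conv, shortcut_bn=sc_bn)


def _main_path(x: np.ndarray, weights: BlockWeights) -> np.ndarray:
    """Bottleneck residual mapping F(x, {Wi}): conv-BN-ReLU twice, conv-BN."""
    h = relu(weights.bns[0](weights.convs[0](x)))
    h = relu(weights.bns[1](weights.convs[1](h)))
    return weights.bns[2](weights.convs[2](h))


def identity_block(x: np.ndarray, spec: ResidualBlockSpec,
                   weights: BlockWeights) -> np.ndarray:
    """H(x) = ReLU(F(x, {Wi}) + x); spatial dims and channels preserved."""
    if x.shape[-1] != spec.filters[2]:
        raise ShapeError(
            f"{spec.name}: identity block needs input channels == last filter "
            f"count ({spec.filters[2]}), got {x.shape[-1]}")
    return relu(_main_path(x, weights) + x)


def convolutional_block(x: np.ndarray, spec: ResidualBlockSpec,
                        weights: BlockWeights) -> np.ndarray:
    """H(x) = ReLU(F(x, {Wi}) + Ws x); the shortcut projects channels/stride."""
    if weights.shortcut_conv is None or weights.shortcut_bn is None:
        raise ShapeError(f"{spec.name}: convolutional block requires shortcut weights")
    if x.shape[-1] != weights.convs[0].w.shape[2]:
        raise ShapeError(
            f"{spec.name}: input has {x.shape[-1]} channels, block expects "
            f"{weights.convs[0].w.shape[2]}")
    shortcut = weights.shortcut_bn(weights.shortcut_conv(x))
    return relu(_main_path(x, weights) + shortcut)


# --------------------------------------------------------------------------
# Backbone specification

#: (identity blocks per stage, bottleneck filters) for stages 2..5 at full scale.
_FULL_STAGES: tuple[tuple[int, tuple[int, int, int]], ...] = (
    (2, (64, 64, 256)),
    (3, (128, 128, 512)),
    (5, (256, 256, 1024)),
    (2, (512, 512, 2048)),
)


@dataclass(frozen=True)
class BackboneSpec:
    """Stage layout of the extractor.

    ``full`` is the printed 50-layer configuration (224x224x3 input, 64-kernel
    stem, stages [64,64,256] x3 / [128,128,512] x4 / [256,256,1024] x6 /
    [512,512,2048] x3).  ``tiny`` divides every channel count by 8 and uses a
    64x64 input, keeping the stage/block topology identical.
    """

    scale: Literal["full", "tiny"] = "full"
    input_size: int = 224
    stem_filters: int = 64
    stages: tuple[tuple[int, tuple[int, int, int]], ...] = _FULL_STAGES

    @classmethod
    def full(cls) -> "BackboneSpec":
        return cls()

    @classmethod
    def tiny(cls) -> "BackboneSpec":
        stages = tuple((n, (f1 // 8, f2 // 8, f3 // 8))
                       for n, (f1, f2, f3) in _FULL_STAGES)
        return cls(scale="tiny", input_size=64, stem_filters=8, stages=stages)

    @classmethod
    def from_scale(cls, scale: str) -> "BackboneSpec":
        if scale == "full":
            return cls.full()
        if scale == "tiny":
            return cls.tiny()
        raise ParameterError(f"scale must be 'full' or 'tiny', got {scale!r}")


@dataclass
class FeatureMapSet:
    """Per-stage activations of one image plus the flattened skip features."""

    stage1: np.ndarray
    stage2: np.ndarray
    stage3: np.ndarray
    stage4: np.ndarray
    stage5: np.ndarray
    flat: np.ndarray = field(repr=False)

    @property
    def stages(self) -> tuple[np.ndarray, ...]:
        return (self.stage1, self.stage2, self.stage3, self.stage4, self.stage5)


def concat_flatten(stage2: np.ndarray, stage5: np.ndarray) -> np.ndarray:
    """flatten(stage-2) ++ flatten(stage-5), channel-last row-major order."""
    return np.concatenate([stage2.ravel(order="C"), stage5.ravel(order="C")])


class FeatureExtractor:
    """Built backbone: stem plus four residual stages, inference only."""

    def __init__(self, spec: BackboneSpec, seed: int = 0) -> None:
        self.spec = spec
        self.seed = seed
        rng = np.random.default_rng(seed)
        self.stem_conv = Conv2D.he_init(7, 7, 3, spec.stem_filters, rng, stride=2)
        self.stem_bn = BatchNorm.identity(spec.stem_filters)
        self.blocks: list[list[tuple[ResidualBlockSpec, BlockWeights]]] = []
        cin = spec.stem_filters
        for i, (n_identity, filters) in enumerate(spec.stages):
            stage_no = i + 2
            stride = 1 if stage_no == 2 else 2
            stage: list[tuple[ResidualBlockSpec, BlockWeights]] = []
            bspec = ResidualBlockSpec("convolutional", filters, stride,
                                      name=f"stage{stage_no}_conv")
            stage.append((bspec, BlockWeights.random(bspec, cin, rng)))
            cin = filters[2]
            for j in range(n_identity):
                ispec = ResidualBlockSpec("identity", filters,
                                          name=f"stage{stage_no}_id{j + 1}")
                stage.append((ispec, BlockWeights.random(ispec, cin, rng)))
            self.blocks.append(stage)
        self._built = True

    # -- forward ----------------------------------------------------------
    def prepare(self, pixels: np.ndarray) -> np.ndarray:
        """Resize (bilinear) to the spec input size and replicate 3 channels."""
        img = np.asarray(pixels, dtype=np.float64)
        if img.ndim == 3 and img.shape[2] == 1:
            img = img[:, :, 0]
        if img.ndim == 2:
            if img.shape != (self.spec.input_size, self.spec.input_size):
                img = _sk_resize(img, (self.spec.input_size, self.spec.input_size),
                                 order=1, anti_aliasing=False, preserve_range=True)
            img = np.repeat(img[:, :, None], 3, axis=2)
        elif img.ndim == 3 and img.shape[2] == 3:
            if img.shape[:2] != (self.spec.input_size, self.spec.input_size):
                img = _sk_resize(img, (self.spec.input_size, self.spec.input_size),
                                 order=1, anti_aliasing=False, preserve_range=True)
        else:
            raise ShapeError(f"cannot prepare image of shape {pixels.shape}")
        return img

    def forward_stages(self, x: np.ndarray) -> list[np.ndarray]:
        """Run all five stages; returns the per-stage output activations."""
        if x.shape != (self.spec.input_size, self.spec.input_size, 3):
            raise ShapeError(
                f"expected input {(self.spec.input_size, self.spec.input_size, 3)},"
                f" got {x.shape}")
        h = relu(self.stem_bn(self.stem_conv(x)))
        h = max_pool(h, kernel=3, stride=2)
        outs = [h]
        for stage in self.blocks:
            for bspec, w in stage:
                if bspec.kind == "convolutional":
                    h = convolutional_block(h, bspec, w)
                else:
                    h = identity_block(h, bspec, w)
            outs.append(h)
        return outs

    def extract(self, image: ImageSample | np.ndarray) -> FeatureMapSet:
        pixels = image.pixels if isinstance(image, ImageSample) else image
        outs = self.forward_stages(self.prepare(pixels))
        return FeatureMapSet(*outs, flat=concat_flatten(outs[1], outs[4]))

    @property
    def flat_dim(self) -> int:
        """Closed-form length of the concatenated stage-2 ++ stage-5 vector."""
        size = -(-self.spec.input_size // 4)  # stem conv + pool: /4
        s2 = size * size * self.spec.stages[0][1][2]
        s5_size = size
        for _ in range(3):
            s5_size = -(-s5_size // 2)
        s5 = s5_size * s5_size * self.spec.stages[3][1][2]
        return s2 + s5


def build_backbone(spec: BackboneSpec,
                   init: str = "random", seed: int = 0) -> FeatureExtractor:
    """Construct a seeded feature extractor.

    ``init="pretrained"`` is accepted in the interface but no offline weight
    source ships with the package, so it raises with advice to use random init.
    """
    if init == "pretrained":
        raise StateError(
            "pretrained weights are not bundled and no download source is "
            "configured; use init='random' with a fixed seed")
    if init != "random":
        raise ParameterError(f"init must be 'random' or 'pretrained', got {init!r}")
    return FeatureExtractor(spec, seed=seed)


def extract_features(extractor: FeatureExtractor,
                     image: ImageSample | np.ndarray) -> FeatureMapSet:
    """Feature maps + concatenated fine/coarse vector for one image."""
    if not getattr(extractor, "_built", False):
        raise StateError("extractor is not built")
    return extractor.extract(image)


def export_feature_maps(featmaps: FeatureMapSet, out_dir: str | os.PathLike,
                        prefix: str = "stage") -> list[str]:
    """Write per-stage channel-tiled grayscale montage PNGs.

    Channels of each (H, W, C) map are laid out on a near-square grid of
    HxW tiles (row-major by channel index); empty grid cells are filled with
    the stage minimum (rendered black).  Intensities are min-max scaled per
    stage to 8-bit.
    """
    os.makedirs(out_dir, exist_ok=True)
    paths = []
    for i, fm in enumerate(featmaps.stages, start=1):
        h, w, c = fm.shape
        ncols = int(np.ceil(np.sqrt(c)))
        nrows = -(-c // ncols)
        lo, hi = float(fm.min()), float(fm.max())
        montage = np.full((nrows * h, ncols * w), lo)
        for ch in range(c):
            r, col = divmod(ch, ncols)
            montage[r * h:(r + 1) * h, col * w:(col + 1) * w] = fm[:, :, ch]
        scaled = (montage - lo) / (hi - lo) if hi > lo else np.zeros_like(montage)
        img = PILImage.fromarray((scaled * 255).round().astype(np.uint8), mode="L")
        path = os.path.join(out_dir, f"{prefix}{i}.png")
        img.save(path)
        paths.append(path)
    return paths
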