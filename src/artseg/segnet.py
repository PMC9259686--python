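"""U-Net segmentation network producing per-pixel artifact probabilities.

Architecture contract (full preset): an encoder of 15 convolutional layers
(3x3 kernels, ReLU), with a 2x2 max-pooling layer and a skip connection
after every third layer; a 3-layer bottleneck; a symmetric decoder of 15
convolutional layers with a x2 upsampling layer after every third layer;
64 filters in every convolutional layer; and a single-channel 1x1
convolution + sigmoid output head. Skip connections merge by channel
concatenation; upsampling is nearest-neighbour followed by convolution.

The small preset keeps the every-third-layer pooling motif at test scale:
6 encoder + 6 decoder + 2 bottleneck layers, 16 filters, 2 pooling stages.

The network is trained either on ground-truth masks (strongly supervised
reference mode) or on binarised ScoreCAM pseudo-labels (the weakly
supervised mode the pipeline is built for).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from . import nn
from .weak_supervision import normalize_image


@dataclass(frozen=True)
class UNetConfig:
    """Preset-driven U-Net shape description."""

    preset: str = "small"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.preset not in ("small", "full"):
            raise ValueError("preset must be 'small' or 'full'")

    @property
    def filters_per_layer(self) -> int:
        return 64 if self.preset == "full" else 16

    @property
    def n_stages(self) -> int:
        return 5 if self.preset == "full" else 2

    @property
    def convs_per_stage(self) -> int:
        return 3

    @property
    def encoder_conv_layers(self) -> int:
        return self.n_stages * self.convs_per_stage

    @property
    def decoder_conv_layers(self) -> int:
        return self.encoder_conv_layers

    @property
    def bottleneck_conv_layers(self) -> int:
        return 3 if self.preset == "full" else 2

    @property
    def divisor(self) -> int:
        """Input sizes must be divisible by 2**n_stages."""
        return 2 ** self.n_stages


@dataclass
class ProbabilityMap:
    """Per-pixel artifact probability in [0, 1], aligned with its image."""

    values: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.values < 0) or np.any(self.values > 1):
            raise ValueError("probabilities must lie in [0, 1]")


class ConfigurationError(ValueError):
    pass


class UNet(nn.Model):
    def __init__(self, config: UNetConfig):
        self.config = config
        f = config.filters_per_layer
        rng = np.random.default_rng(config.seed)
        self.enc_stages: list[list[tuple[nn.Conv2D, nn.ReLU]]] = []
        cin = 1
        for _ in range(config.n_stages):
            stage = []
            for _ in range(config.convs_per_stage):
                stage.append((nn.Conv2D(cin, f, 3, rng), nn.ReLU()))
                cin = f
            self.enc_stages.append(stage)
        self.pools = [nn.MaxPool2() for _ in range(config.n_stages)]
        self.bottleneck = [(nn.Conv2D(f, f, 3, rng), nn.ReLU())
                           for _ in range(config.bottleneck_conv_layers)]
        self.ups = [nn.UpsampleNearest2() for _ in range(config.n_stages)]
        self.dec_stages: list[list[tuple[nn.Conv2D, nn.ReLU]]] = []
        for _ in range(config.n_stages):
            stage = [(nn.Conv2D(2 * f, f, 3, rng), nn.ReLU())]
            for _ in range(config.convs_per_stage - 1):
                stage.append((nn.Conv2D(f, f, 3, rng), nn.ReLU()))
            self.dec_stages.append(stage)
        self.head = nn.Conv2D(f, 1, 1, rng)
        convs = ([c for st in self.enc_stages for c, _ in st]
                 + [c for c, _ in self.bottleneck]
                 + [c for st in self.dec_stages for c, _ in st] + [self.head])
        self.layers = convs

    @property
    def conv_layer_count(self) -> int:
        """Convolutional layers before the output head."""
        return (self.config.encoder_conv_layers + self.config.bottleneck_conv_layers
                + self.config.decoder_conv_layers)

    def forward(self, x: np.ndarray) -> np.ndarray:
        """Logits (N, 1, H, W); H and W must be divisible by the preset divisor."""
        h, w = x.shape[2], x.shape[3]
        d = self.config.divisor
        if h % d or w % d:
            raise ConfigurationError(
                f"input {h}x{w} not divisible by {d}; reflect-pad to the next "
                f"multiple (see predict_proba) or resize")
        skips = []
        for stage, pool in zip(self.enc_stages, self.pools):
            for conv, relu in stage:
                x = relu.forward(conv.forward(x))
            skips.append(x)
            x = pool.forward(x)
        for conv, relu in self.bottleneck:
            x = relu.forward(conv.forward(x))
        # dec_stages[0] is the deepest decoder stage, consuming the deepest skip
        for up, stage, skip in zip(self.ups, self.dec_stages, reversed(skips)):
            x = up.forward(x)
            x = np.concatenate([x, skip], axis=1)
            for conv, relu in stage:
                x = relu.forward(conv.forward(x))
        return self.head.forward(x)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        f = self.config.filters_per_layer
        g = self.head.backward(grad)
        skip_grads: list[np.ndarray] = []   # collected shallowest-first
        for up, stage in zip(reversed(self.ups), reversed(self.dec_stages)):
            for conv, relu in reversed(stage):
                g = conv.backward(relu.backward(g))
            skip_grads.append(g[:, f:])
            g = up.backward(g[:, :f])
        for conv, relu in reversed(self.bottleneck):
            g = conv.backward(relu.backward(g))
        for stage, pool, sg in zip(reversed(self.enc_stages), reversed(self.pools),
                                   reversed(skip_grads)):
            g = pool.backward(g) + sg
            for conv, relu in reversed(stage):
                g = conv.backward(relu.backward(g))
        return g


def build_unet(config: UNetConfig) -> UNet:
    return UNet(config)


# ---------------------------------------------------------------------------
# training and inference
# ---------------------------------------------------------------------------

def _prepare(images: Sequence[np.ndarray]) -> np.ndarray:
    return np.stack([normalize_image(im) for im in images])[:, None].astype(np.float32)


def _prepare_masks(masks: Sequence[np.ndarray]) -> np.ndarray:
    return np.stack([np.asarray(m, dtype=np.float32) for m in masks])[:, None]


def train_segmenter(model: UNet,
                    train_images: Sequence[np.ndarray], train_masks: Sequence[np.ndarray],
                    val_images: Sequence[np.ndarray], val_masks: Sequence[np.ndarray],
                    train_config: nn.TrainConfig) -> nn.History:
    """Pixel-wise binary cross-entropy training with the shared Adam +
    plateau-schedule contract; returns the history, leaving the model at
    its best-validation-loss weights."""
    x_train, y_train = _prepare(train_images), _prepare_masks(train_masks)
    x_val, y_val = _prepare(val_images), _prepare_masks(val_masks)
    if x_train.shape[2:] != y_train.shape[2:]:
        raise ValueError("image/mask shape mismatch")

    def forward_loss(xb, yb):
        logits = model.forward(xb)
        loss, g = nn.sigmoid_bce(logits, yb)
        return loss, lambda: model.backward(g)

    def eval_loss(xb, yb):
        return nn.sigmoid_bce(model.forward(xb), yb)[0]

    return nn.fit(model, forward_loss, eval_loss,
                  x_train, y_train, x_val, y_val, train_config)


def predict_proba(model: UNet, image: np.ndarray, pad: bool = True) -> ProbabilityMap:
    """Per-pixel artifact probability for one raw image.

    Inputs whose sides are not divisible by the preset divisor are
    reflect-padded to the next multiple and the prediction cropped back.
    """
    x = normalize_image(image)
    h, w = x.shape
    d = model.config.divisor
    ph, pw = (-h) % d, (-w) % d
    if (ph or pw) and not pad:
        raise ConfigurationError(f"input {h}x{w} not divisible by {d} and pad disabled")
    if ph or pw:
        x = np.pad(x, ((0, ph), (0, pw)), mode="reflect")
    logits = model.forward(x[None, None])
    probs = nn.sigmoid(logits[0, 0].astype(np.float64))[:h, :w]
    return ProbabilityMap(values=probs.astype(np.float32))


def predict_proba_batch(model: UNet, images: Sequence[np.ndarray]) -> list[ProbabilityMap]:
    return [predict_proba(model, im) for im in images]
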