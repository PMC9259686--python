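"""Weak supervision: image-level classifier, ScoreCAM saliency, pseudo-labels.

The clean-vs-artifact classifier is a residual CNN trained with Adam on
cross-entropy from image-level labels alone. ScoreCAM then turns the
trained classifier into a localiser in four steps:

1. extract the activation maps of the last convolutional layer;
2. upscale each map to the input size (bilinear) and min-max normalise it
   to [0, 1];
3. multiply each normalised map with a copy of the input and score every
   projected input with the classifier, keeping the artifact-class
   probability as the map weight;
4. sum the weighted normalised maps, pass through ReLU, and min-max
   normalise the result to [0, 1].

Binarising the saliency maps (default threshold 0.05, or the value that
maximises validation IoU) yields pseudo-label masks used to train the
segmentation U-Net.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Protocol, Sequence

import numpy as np
from skimage.transform import resize

from . import nn
from .metrics import pixel_metrics

DEFAULT_PSEUDOLABEL_THRESHOLD = 0.05
DEFAULT_THRESHOLD_GRID = (0.01, 0.02, 0.05, 0.1, 0.15, 0.2, 0.3, 0.4, 0.5,
                          0.6, 0.7, 0.8, 0.9)

CLASS_NAMES = ("clean", "artifact")
ARTIFACT_CLASS = 1


# ---------------------------------------------------------------------------
# configuration and data types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ClassifierConfig:
    """Backbone choice for the clean/artifact classifier.

    ``small`` is a few-block residual CNN sized for CPU-scale data;
    ``full`` is a deeper residual backbone for larger images.
    """

    backbone_preset: str = "small"
    input_size: int = 96
    num_classes: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.backbone_preset not in ("small", "full"):
            raise ValueError("backbone_preset must be 'small' or 'full'")
        div = self.downsampling_divisor
        if self.input_size % div:
            raise ValueError(f"input_size must be divisible by {div}")

    @property
    def downsampling_divisor(self) -> int:
        n_stages = 2 if self.backbone_preset == "small" else 3
        return 2 ** (n_stages + 1)


@dataclass
class ActivationStack:
    """Activation maps of the model's last convolutional layer."""

    maps: np.ndarray            # (K, h, w)
    source_layer_id: str

    def __post_init__(self) -> None:
        if self.maps.ndim != 3 or self.maps.shape[0] < 1:
            raise ValueError("need at least one h x w activation map")


@dataclass
class SaliencyMap:
    """Per-pixel artifact saliency in [0, 1], aligned with its image."""

    values: np.ndarray
    target_class: int = ARTIFACT_CLASS

    def __post_init__(self) -> None:
        if np.any(self.values < 0) or np.any(self.values > 1):
            raise ValueError("saliency values must lie in [0, 1]")


class ScoreCAMModel(Protocol):
    """What scorecam_map needs: plain forward plus feature extraction."""

    def forward(self, x: np.ndarray) -> np.ndarray: ...
    def forward_features(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]: ...


# ---------------------------------------------------------------------------
# residual classifier
# ---------------------------------------------------------------------------

class _ResidualBlock:
    """conv-relu-conv plus (projected) identity, then ReLU."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        self.conv1 = nn.Conv2D(cin, cout, 3, rng)
        self.relu1 = nn.ReLU()
        self.conv2 = nn.Conv2D(cout, cout, 3, rng)
        self.proj = nn.Conv2D(cin, cout, 1, rng) if cin != cout else None
        self.relu_out = nn.ReLU()

    @property
    def sublayers(self) -> list[nn.Layer]:
        layers = [self.conv1, self.conv2]
        if self.proj is not None:
            layers.append(self.proj)
        return layers

    def forward(self, x: np.ndarray) -> np.ndarray:
        y = self.conv2.forward(self.relu1.forward(self.conv1.forward(x)))
        s = self.proj.forward(x) if self.proj is not None else x
        return self.relu_out.forward(y + s)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        g = self.relu_out.backward(grad)
        gx = self.conv1.backward(self.relu1.backward(self.conv2.backward(g)))
        gx += self.proj.backward(g) if self.proj is not None else g
        return gx


_PRESETS = {
    # stem filters, per-stage widths (one residual block per width entry)
    "small": {"stem": 8, "widths": [16, 16]},
    "full": {"stem": 16, "widths": [32, 64, 64, 128, 128, 256]},
}


class ResidualClassifier(nn.Model):
    """Stem conv + residual stages with 2x2 pooling, GAP head.

    The activation maps fed to ScoreCAM are the outputs of the final
    residual block, before the last pooling stage.
    """

    def __init__(self, config: ClassifierConfig):
        self.config = config
        preset = _PRESETS[config.backbone_preset]
        rng = np.random.default_rng(config.seed)
        self.stem = nn.Conv2D(1, preset["stem"], 3, rng)
        self.stem_relu = nn.ReLU()
        self.blocks: list[_ResidualBlock] = []
        cin = preset["stem"]
        # group widths into stages of 1 (small) or 2 (full) blocks
        per_stage = 1 if config.backbone_preset == "small" else 2
        widths = preset["widths"]
        self.stage_blocks: list[list[_ResidualBlock]] = []
        for s in range(0, len(widths), per_stage):
            stage = []
            for wdt in widths[s:s + per_stage]:
                stage.append(_ResidualBlock(cin, wdt, rng))
                cin = wdt
            self.stage_blocks.append(stage)
            self.blocks.extend(stage)
        self.pools = [nn.MaxPool2() for _ in range(len(self.stage_blocks) + 1)]
        self.gap = nn.GlobalAvgPool()
        self.head = nn.Dense(cin, config.num_classes, rng)
        self.feature_channels = cin
        self.layers = ([self.stem] + [l for b in self.blocks for l in b.sublayers]
                       + [self.head])

    def forward_features(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Logits plus the last-conv-layer activation maps (N, K, h, w)."""
        h = self.pools[0].forward(self.stem_relu.forward(self.stem.forward(x)))
        for i, stage in enumerate(self.stage_blocks):
            for block in stage:
                h = block.forward(h)
            if i < len(self.stage_blocks) - 1:
                h = self.pools[i + 1].forward(h)
        feats = h
        h = self.pools[-1].forward(h)
        logits = self.head.forward(self.gap.forward(h))
        return logits, feats

    def forward(self, x: np.ndarray) -> np.ndarray:
        return self.forward_features(x)[0]

    def backward(self, grad_logits: np.ndarray) -> np.ndarray:
        g = self.gap.backward(self.head.backward(grad_logits))
        g = self.pools[-1].backward(g)
        for i in range(len(self.stage_blocks) - 1, -1, -1):
            if i < len(self.stage_blocks) - 1:
                g = self.pools[i + 1].backward(g)
            for block in reversed(self.stage_blocks[i]):
                g = block.backward(g)
        g = self.pools[0].backward(g)
        return self.stem.backward(self.stem_relu.backward(g))


def build_classifier(config: ClassifierConfig) -> ResidualClassifier:
    return ResidualClassifier(config)


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def normalize_image(image: np.ndarray) -> np.ndarray:
    """Per-image min-max normalisation to [0, 1] (8- and 16-bit inputs coexist)."""
    img = np.asarray(image, dtype=np.float32)
    lo, hi = float(img.min()), float(img.max())
    if hi > lo:
        img = (img - lo) / (hi - lo)
    else:
        img = np.zeros_like(img)
    return img


def preprocess(images: Sequence[np.ndarray], input_size: int) -> np.ndarray:
    """Normalise and resize a batch to the network input contract (N,1,S,S)."""
    out = np.empty((len(images), 1, input_size, input_size), dtype=np.float32)
    for i, im in enumerate(images):
        x = normalize_image(im)
        if x.shape != (input_size, input_size):
            x = resize(x, (input_size, input_size), order=1,
                       anti_aliasing=True, preserve_range=True).astype(np.float32)
        out[i, 0] = x
    return out


def labels_to_ids(labels: Sequence[str]) -> np.ndarray:
    ids = []
    for lab in labels:
        if lab not in CLASS_NAMES:
            raise ValueError(f"unknown label {lab!r}")
        ids.append(CLASS_NAMES.index(lab))
    return np.asarray(ids, dtype=np.int64)


# ---------------------------------------------------------------------------
# training and inference
# ---------------------------------------------------------------------------

def train_classifier(train_images: Sequence[np.ndarray], train_labels: Sequence[str],
                     val_images: Sequence[np.ndarray], val_labels: Sequence[str],
                     config: ClassifierConfig,
                     train_config: nn.TrainConfig) -> tuple[ResidualClassifier, nn.History]:
    """Train the clean/artifact classifier; returns best-validation weights."""
    if len(train_images) == 0 or len(val_images) == 0:
        raise ValueError("train and validation splits must be nonempty")
    y_train = labels_to_ids(train_labels)
    y_val = labels_to_ids(val_labels)
    if len(set(y_train.tolist())) < 2:
        raise ValueError("training data must contain both classes")
    x_train = preprocess(train_images, config.input_size)
    x_val = preprocess(val_images, config.input_size)
    model = build_classifier(config)

    def forward_loss(xb, yb):
        logits = model.forward(xb)
        loss, g = nn.softmax_xent(logits, yb)
        return loss, lambda: model.backward(g)

    def eval_loss(xb, yb):
        return nn.softmax_xent(model.forward(xb), yb)[0]

    history = nn.fit(model, forward_loss, eval_loss,
                     x_train, y_train, x_val, y_val, train_config)
    return model, history


def classify(model: ResidualClassifier, image: np.ndarray) -> np.ndarray:
    """(p_clean, p_artifact) for one raw image."""
    x = preprocess([image], model.config.input_size)
    return nn.softmax(model.forward(x).astype(np.float64))[0]


def classify_batch(model: ResidualClassifier, images: Sequence[np.ndarray],
                   batch_size: int = 32) -> np.ndarray:
    x = preprocess(images, model.config.input_size)
    probs = []
    for s in range(0, x.shape[0], batch_size):
        probs.append(nn.softmax(model.forward(x[s:s + batch_size]).astype(np.float64)))
    return np.concatenate(probs)


# ---------------------------------------------------------------------------
# ScoreCAM
# ---------------------------------------------------------------------------

def minmax01(a: np.ndarray) -> np.ndarray:
    """Min-max normalise to [0, 1]; a constant array maps to all zeros
    (a constant map carries no localisation signal)."""
    lo, hi = float(a.min()), float(a.max())
    if hi > lo:
        return ((a - lo) / (hi - lo)).astype(np.float32)
    return np.zeros_like(a, dtype=np.float32)


def upscale_normalize(stack: ActivationStack, shape: tuple[int, int]) -> np.ndarray:
    """Step 2: bilinear upscale each map to the input size, min-max to [0,1]."""
    k = stack.maps.shape[0]
    out = np.empty((k, *shape), dtype=np.float32)
    for i in range(k):
        m = stack.maps[i].astype(np.float64)
        if m.shape != shape:
            m = resize(m, shape, order=1, preserve_range=True)
        out[i] = minmax01(m)
    return out


def combine_scorecam(normalized_maps: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Step 4: ReLU of the weighted sum, min-max normalised to [0, 1]."""
    total = np.tensordot(weights.astype(np.float64), normalized_maps.astype(np.float64),
                         axes=(0, 0))
    return minmax01(np.maximum(total, 0.0))


def scorecam_map(model: ScoreCAMModel, image: np.ndarray,
                 target_class: int = ARTIFACT_CLASS,
                 batch_size: int = 16,
                 input_size: int | None = None) -> SaliencyMap:
    """Full four-step ScoreCAM saliency for one image."""
    if input_size is None:
        input_size = getattr(getattr(model, "config", None), "input_size", None)
        if input_size is None:
            raise ValueError("input_size must be given for models without a config")
    x = preprocess([image], input_size)
    _, feats = model.forward_features(x)
    stack = ActivationStack(maps=np.asarray(feats[0]), source_layer_id="last_conv")
    norm_maps = upscale_normalize(stack, (input_size, input_size))
    k = norm_maps.shape[0]
    projected = norm_maps[:, None, :, :] * x[0:1]     # (K, 1, S, S)
    weights = np.empty(k, dtype=np.float64)
    for s in range(0, k, batch_size):
        logits = model.forward(projected[s:s + batch_size])
        weights[s:s + batch_size] = nn.softmax(logits.astype(np.float64))[:, target_class]
    values = combine_scorecam(norm_maps, weights)
    if values.shape != image.shape:
        values = minmax01(resize(values.astype(np.float64), image.shape,
                                 order=1, preserve_range=True))
    return SaliencyMap(values=values, target_class=target_class)


# ---------------------------------------------------------------------------
# thresholding and pseudo-labels
# ---------------------------------------------------------------------------

def binarize_map(saliency: SaliencyMap | np.ndarray, threshold: float) -> np.ndarray:
    """Strictly-greater-than binarisation of a [0, 1] map."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    values = saliency.values if isinstance(saliency, SaliencyMap) else np.asarray(saliency)
    return values > threshold


def select_threshold(maps: Sequence[SaliencyMap | np.ndarray],
                     gt_masks: Sequence[np.ndarray],
                     grid: Sequence[float] = DEFAULT_THRESHOLD_GRID
                     ) -> tuple[float, list[dict]]:
    """Grid threshold maximising mean per-image pixel IoU; ties -> smallest.

    Images where IoU is undefined at a given threshold (empty prediction
    and empty ground truth) are skipped in that threshold's mean.
    """
    if len(maps) == 0 or len(maps) != len(gt_masks):
        raise ValueError("need equally many nonempty maps and masks")
    if len(grid) == 0:
        raise ValueError("threshold grid is empty")
    table = []
    best_t, best_iou = None, -np.inf
    for t in sorted(grid):
        ious = []
        for m, g in zip(maps, gt_masks):
            r = pixel_metrics(binarize_map(m, t), g)
            if r.iou is not None:
                ious.append(r.iou)
        mean_iou = float(np.mean(ious)) if ious else float("-inf")
        table.append({"threshold": float(t), "mean_iou": mean_iou, "n_defined": len(ious)})
        if mean_iou > best_iou:            # strict: ties keep the smaller threshold
            best_iou = mean_iou
            best_t = float(t)
    return best_t, table


def make_pseudolabels(model: ScoreCAMModel, images: Sequence[np.ndarray],
                      labels: Sequence[str], threshold: float,
                      input_size: int | None = None) -> np.ndarray:
    """Pseudo-masks for segmenter training.

    Artifact-labelled images receive their binarised ScoreCAM map; images
    labelled clean receive an all-zero mask (they are known artifact-free
    and anchor the background class).
    """
    if len(images) != len(labels):
        raise ValueError("images and labels must align")
    labels_to_ids(labels)   # validates label values
    masks = []
    for im, lab in zip(images, labels):
        if lab == "artifact":
            sal = scorecam_map(model, im, input_size=input_size)
            masks.append(binarize_map(sal, threshold))
        else:
            masks.append(np.zeros(im.shape, dtype=bool))
    return np.stack(masks)
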