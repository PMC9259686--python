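"""Two-stage inference and end-to-end training orchestration.

Inference follows a classify-then-segment design: the image-level
classifier gates each image, and only images deemed artifactual are passed
to the U-Net; its probability map is binarised at the model-specific
cutoff and components smaller than a dataset-specific minimum size are
removed. Training distils the classifier's ScoreCAM saliency into
pseudo-label masks on which the U-Net is trained.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from skimage import morphology

from . import nn, weak_supervision as ws, segnet
from .metrics import aggregate_reports, image_level_f1, pixel_metrics
from .synthgen import LabeledDataset

# validation-selected binarisation cutoffs per model family
SCORECAM_CUTOFF = 0.001
SCORECAM_UNET_CUTOFF = 0.001
UNET_CUTOFF = 0.45

# operating cutoffs of the anomaly-detection baselines this pipeline is
# usually compared against; recorded for documentation only (the baseline
# models themselves are out of scope here)
BASELINE_CUTOFFS = {"autoencoder": 0.75, "padim": 0.3, "patch_svdd": 0.0005}

# minimum artifact object sizes (pixels) per dataset preset
MIN_OBJECT_SIZE_PRESETS = {
    "seven_cell_lines": 1000,
    "artseg_cho_m4r": 500,
    "lncap": 500,
    "synthetic_small": 30,   # scaled for 96x96 synthetic fields
}

DEFAULT_GATE_THRESHOLD = 0.5


@dataclass(frozen=True)
class PostProcessConfig:
    """Binarisation cutoff plus small-object filtering."""

    binarization_cutoff: float = SCORECAM_UNET_CUTOFF
    min_object_size: int = MIN_OBJECT_SIZE_PRESETS["synthetic_small"]
    connectivity: int = 8

    def __post_init__(self) -> None:
        if not 0.0 <= self.binarization_cutoff <= 1.0:
            raise ValueError("cutoff must lie in [0, 1]")
        if self.min_object_size < 0:
            raise ValueError("min_object_size must be >= 0")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")


@dataclass
class ArtifactMask:
    """Post-processed binary segmentation with its provenance."""

    values: np.ndarray
    provenance: dict = field(default_factory=dict)


def remove_small_objects(mask: np.ndarray, min_size: int,
                         connectivity: int = 8) -> np.ndarray:
    """Delete connected components with strictly fewer than min_size pixels."""
    mask = np.asarray(mask).astype(bool)
    if min_size <= 1:       # no component can have fewer than 1 pixel
        return mask.copy()
    # skimage connectivity: 1 = 4-connected, 2 = 8-connected; its max_size
    # removes components of size <= max_size, so strict < min_size needs -1
    conn = 2 if connectivity == 8 else 1
    return morphology.remove_small_objects(mask, max_size=min_size - 1,
                                           connectivity=conn)


def postprocess_map(prob_map: segnet.ProbabilityMap | np.ndarray,
                    post: PostProcessConfig) -> np.ndarray:
    values = prob_map.values if isinstance(prob_map, segnet.ProbabilityMap) else prob_map
    binary = values > post.binarization_cutoff
    return remove_small_objects(binary, post.min_object_size, post.connectivity)


def select_postprocess_cutoff(segmenter: segnet.UNet, images: Sequence[np.ndarray],
                              gt_masks: Sequence[np.ndarray],
                              grid: Sequence[float] = ws.DEFAULT_THRESHOLD_GRID
                              ) -> tuple[float, list[dict]]:
    """Validation-selected binarisation cutoff for a trained segmenter.

    Mirrors how the per-model reference cutoffs are obtained: sweep the
    grid and keep the cutoff maximising mean pixel IoU on validation
    images with ground-truth masks.
    """
    maps = [segnet.predict_proba(segmenter, im).values for im in images]
    return ws.select_threshold(maps, gt_masks, grid)


def predict(image: np.ndarray, classifier: ws.ResidualClassifier,
            segmenter: segnet.UNet, post: PostProcessConfig,
            gate_threshold: float = DEFAULT_GATE_THRESHOLD) -> ArtifactMask:
    """Gate with the classifier, then segment and post-process.

    Images whose artifact probability does not exceed the gate threshold
    receive an all-zero mask without running the segmenter.
    """
    provenance = {"cutoff": post.binarization_cutoff,
                  "min_object_size": post.min_object_size,
                  "connectivity": post.connectivity,
                  "gate_threshold": gate_threshold}
    p_art = float(ws.classify(classifier, image)[ws.ARTIFACT_CLASS])
    provenance["p_artifact"] = p_art
    if p_art <= gate_threshold:
        return ArtifactMask(values=np.zeros(image.shape, dtype=bool),
                            provenance=provenance)
    prob = segnet.predict_proba(segmenter, image)
    return ArtifactMask(values=postprocess_map(prob, post), provenance=provenance)


# ---------------------------------------------------------------------------
# end-to-end training
# ---------------------------------------------------------------------------

@dataclass
class PipelineResult:
    classifier: ws.ResidualClassifier
    segmenter: segnet.UNet
    threshold: float
    pseudo_masks: np.ndarray
    report: dict


def _stage(report: dict, name: str, t0: float, **info) -> None:
    report["stages"].append({"stage": name, "seconds": round(time.time() - t0, 2),
                             **info})


def run_full_training(dataset: LabeledDataset,
                      classifier_config: ws.ClassifierConfig | None = None,
                      unet_config: segnet.UNetConfig | None = None,
                      train_config: nn.TrainConfig | None = None,
                      threshold: float | str = "auto",
                      threshold_grid: Sequence[float] = ws.DEFAULT_THRESHOLD_GRID,
                      include_clean_in_unet: bool = True,
                      seed: int = 0) -> PipelineResult:
    """Train classifier -> ScoreCAM -> threshold -> pseudo-labels -> U-Net.

    ``threshold="auto"`` selects the pseudo-label binarisation threshold by
    validation-set IoU when the dataset carries pixel-level validation
    masks, and falls back to the default 0.05 otherwise.
    """
    classifier_config = classifier_config or ws.ClassifierConfig(seed=seed)
    unet_config = unet_config or segnet.UNetConfig(seed=seed + 1)
    train_config = train_config or nn.TrainConfig(seed=seed)

    tr, va = dataset.indices("train"), dataset.indices("val")
    if not tr or not va:
        raise ValueError("dataset must provide nonempty train and val splits")
    report: dict = {"seed": seed, "stages": [],
                    "configs": {"classifier": vars(classifier_config) | {},
                                "unet": {"preset": unet_config.preset, "seed": unet_config.seed},
                                "train": vars(train_config) | {}}}

    t0 = time.time()
    clf, clf_hist = ws.train_classifier(
        [dataset.fields[i].image for i in tr], [dataset.labels[i] for i in tr],
        [dataset.fields[i].image for i in va], [dataset.labels[i] for i in va],
        classifier_config, train_config)
    _stage(report, "train_classifier", t0,
           best_epoch=clf_hist.best_epoch,
           final_val_loss=clf_hist.val_loss[clf_hist.best_epoch])

    t0 = time.time()
    train_maps = {i: ws.scorecam_map(clf, dataset.fields[i].image)
                  for i in tr if dataset.labels[i] == "artifact"}
    _stage(report, "scorecam_train_maps", t0, n_maps=len(train_maps))

    t0 = time.time()
    val_art = [i for i in va if dataset.labels[i] == "artifact"]
    val_maps = {i: ws.scorecam_map(clf, dataset.fields[i].image) for i in val_art}
    have_val_masks = bool(val_art) and all(
        dataset.fields[i].artifact_mask is not None for i in val_art)
    if threshold == "auto":
        if have_val_masks:
            chosen, table = ws.select_threshold(
                [val_maps[i] for i in val_art],
                [dataset.fields[i].artifact_mask for i in val_art], threshold_grid)
            _stage(report, "select_threshold", t0, threshold=chosen, table=table)
        else:
            chosen = ws.DEFAULT_PSEUDOLABEL_THRESHOLD
            _stage(report, "select_threshold", t0, threshold=chosen,
                   note="no validation pixel masks; default threshold")
    else:
        chosen = float(threshold)
        _stage(report, "select_threshold", t0, threshold=chosen, note="configured")

    t0 = time.time()
    pseudo = {}
    for i in tr + va:
        if dataset.labels[i] != "artifact":
            pseudo[i] = np.zeros(dataset.fields[i].image.shape, dtype=bool)
        elif i in train_maps:
            pseudo[i] = ws.binarize_map(train_maps[i], chosen)
        else:
            pseudo[i] = ws.binarize_map(val_maps[i], chosen)
    _stage(report, "make_pseudolabels", t0,
           mean_positive_fraction=float(np.mean([m.mean() for m in pseudo.values()])))

    t0 = time.time()
    unet_train = tr if include_clean_in_unet else [i for i in tr
                                                   if dataset.labels[i] == "artifact"]
    model = segnet.build_unet(unet_config)
    seg_hist = segnet.train_segmenter(
        model,
        [dataset.fields[i].image for i in unet_train],
        [pseudo[i] for i in unet_train],
        [dataset.fields[i].image for i in va],
        [pseudo[i] for i in va],
        train_config)
    _stage(report, "train_segmenter", t0, best_epoch=seg_hist.best_epoch,
           final_val_loss=seg_hist.val_loss[seg_hist.best_epoch])

    report["threshold"] = chosen
    report["history"] = {"classifier": clf_hist.to_dict(), "segmenter": seg_hist.to_dict()}
    masks = np.stack([pseudo[i] for i in tr])
    return PipelineResult(classifier=clf, segmenter=model, threshold=chosen,
                          pseudo_masks=masks, report=report)


def evaluate_pipeline(result: PipelineResult, dataset: LabeledDataset,
                      post: PostProcessConfig | None = None,
                      split: str = "test",
                      gate_threshold: float = DEFAULT_GATE_THRESHOLD) -> dict:
    """Image-level and pixel-level held-out evaluation of a trained pipeline."""
    post = post or PostProcessConfig()
    idx = dataset.indices(split)
    pred_labels, true_labels, pix_reports = [], [], []
    for i in idx:
        f = dataset.fields[i]
        mask = predict(f.image, result.classifier, result.segmenter, post,
                       gate_threshold)
        pred_labels.append("artifact" if mask.values.any() else "clean")
        true_labels.append(dataset.labels[i])
        pix_reports.append(pixel_metrics(mask.values, f.artifact_mask))
    img_report = image_level_f1(pred_labels, true_labels)
    return {"split": split, "n_images": len(idx),
            "image_f1": img_report.f1,
            "image_counts": vars(img_report.counts),
            "pixel": aggregate_reports(pix_reports)}


def save_run(result: PipelineResult, directory: str | Path) -> None:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    result.classifier.save(d / "classifier",
                           meta={"config": vars(result.classifier.config) | {}})
    result.segmenter.save(d / "segmenter",
                          meta={"preset": result.segmenter.config.preset,
                                "seed": result.segmenter.config.seed})
    (d / "report.json").write_text(json.dumps(result.report, indent=2, default=float))


def load_run(directory: str | Path) -> tuple[ws.ResidualClassifier, segnet.UNet, dict]:
    d = Path(directory)
    report = json.loads((d / "report.json").read_text())
    clf_meta = json.loads((d / "classifier" / "model.json").read_text())["meta"]["config"]
    clf = ws.build_classifier(ws.ClassifierConfig(**clf_meta))
    clf.load_weights(d / "classifier")
    seg_meta = json.loads((d / "segmenter" / "model.json").read_text())["meta"]
    seg = segnet.build_unet(segnet.UNetConfig(**seg_meta))
    seg.load_weights(d / "segmenter")
    return clf, seg, report
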