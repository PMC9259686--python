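# artseg — weakly supervised artifact segmentation for brightfield microscopy

Brightfield cell microscopy images frequently contain visual artifacts —
dust, hairs, cell debris, contamination — that corrupt downstream
analyses such as nuclei segmentation, morphometry and fluorescence
quantification. Delineating artifacts pixel-by-pixel is accurate but
slow; flagging whole images as *clean* or *artifact* is roughly a
hundred times faster. `artseg` turns those cheap image-level labels into
pixel-level artifact masks:

1. a residual CNN classifier is trained to tell clean from artifactual
   images;
2. **ScoreCAM** converts the classifier into a localiser: each activation
   map `A_k` of the last convolutional layer is upscaled, min-max
   normalised, multiplied onto a copy of the input, and re-scored by the
   classifier; the saliency map is `minmax(ReLU(Σ_k w_k Â_k))` with `w_k`
   the artifact-class probability of the k-th projected input;
3. saliency maps are binarised (threshold chosen by validation IoU;
   default 0.05) into **pseudo-labels**, on which a **U-Net**
   (15+3+15 convolutional layers, 64 filters, pooling/upsampling every
   third layer in the full preset) is trained;
4. at inference, a classify-then-segment gate runs the U-Net only on
   images the classifier flags, binarises the probability map and removes
   small connected components.

The package also provides the clean-image synthesis procedure
(second-order 2-D polynomial background fit + zero-centred empirical
noise inpainting), the full evaluation suite (pixel / object / image
metrics, PR curves), Hill-equation ligand-affinity regression
(`Y = Bottom + (Top−Bottom)/(1+10^(X−LogIC50))`, slope −1), and a
synthetic data generator with exact ground truth so everything is
testable on one CPU. See `docs/methods.md` for the science in detail.

## Worked example

```python
from artseg import nn, pipeline, synthgen

# 200 synthetic 96x96 brightfield-like fields, half with artifacts
ds = synthgen.generate_dataset(200, 0.5, synthgen.FieldSpec(), seed=7)

train_cfg = nn.TrainConfig(epochs=10, lr_patience_epochs=3, batch_size=8, seed=0)
result = pipeline.run_full_training(ds, train_config=train_cfg, seed=0)
print("pseudo-label threshold:", result.threshold)

# pick the evaluation cutoff on validation IoU, then score the test split
val_art = [i for i in ds.indices("val") if ds.labels[i] == "artifact"]
cutoff, _ = pipeline.select_postprocess_cutoff(
    result.segmenter,
    [ds.fields[i].image for i in val_art],
    [ds.fields[i].artifact_mask for i in val_art])
post = pipeline.PostProcessConfig(binarization_cutoff=cutoff, min_object_size=30)
print(pipeline.evaluate_pipeline(result, ds, post))
```

Output (abridged; ~4 min on one CPU):

```
pseudo-label threshold: 0.6
{'split': 'test', 'n_images': 40, 'image_f1': 1.0,
 'image_counts': {'tp': 20, 'fp': 0, 'fn': 0, 'tn': 20},
 'pixel': {'precision': 0.784, 'recall': 0.838, 'f1': 0.803, 'iou': 0.677,
           'n_images': 40}}
```

Reading: the classifier separates clean from artifactual test images
perfectly (image-level F1 = 1.0), and the U-Net trained *only* on
ScoreCAM pseudo-labels recovers artifact pixels at IoU ≈ 0.68 — without
ever seeing a pixel-level annotation. A U-Net trained on the true masks
(strong supervision) reaches IoU ≈ 0.95 on the same data, the expected
ordering between supervision regimes.

The same workflow is available from the shell:

```bash
artseg synth --n-images 200 --out data/
artseg run --manifest data/labels.csv --epochs 10 --out run/
artseg predict --run run/ --images 'data/images/*.tiff' --out masks/
artseg clean --image img.tiff --mask masks/img_mask.tiff --out img_clean.tiff
```

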