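"""Synthetic brightfield-like data with known ground truth.

Every other module in the package is exercised against fields produced
here: a smooth second-order polynomial illumination surface, nuclei drawn
as smoothed low-contrast disks, sparse heterogeneous artifacts (ellipses
with speckle texture, dilated random-walk fibers, clumps of overlapping
disks), Gaussian sensor noise, and — for concentration-response plates —
a parallel fluorescence channel whose cell-specific intensity follows a
Hill curve of the competitive-ligand concentration.

Randomness is organised so that the artifact-free render of a field is
bit-identical to the artifactual one outside the injected artifact pixels:
nuclei, noise and each artifact draw from independent child streams of the
field seed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml
from scipy import ndimage as ndi
from skimage.morphology import dilation, disk as disk_footprint

INTENSITY_MAX = 65535.0

# default illumination surface on [-1, 1]^2 coordinates, 16-bit-like scale
DEFAULT_BACKGROUND_COEFFS = (30000.0, 2000.0, -1500.0, 800.0, 500.0, -600.0)


# ---------------------------------------------------------------------------
# specifications
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ArtifactSpec:
    """One artifact to inject: shape family, pixel geometry, contrast.

    ``texture_contrast`` is the intensity offset relative to the mean
    background level (0.35 means the artifact core sits ~35% below it).
    ``position`` is (row, col) of the artifact centre or ``"random"``.
    """

    shape: Literal["ellipse", "fiber", "clump"]
    size_params: dict
    texture_contrast: float = 0.35
    position: tuple[int, int] | str = "random"

    def __post_init__(self) -> None:
        if self.shape not in ("ellipse", "fiber", "clump"):
            raise ValueError(f"unknown artifact shape {self.shape!r}")
        if self.texture_contrast <= 0:
            raise ValueError("texture_contrast must be positive")


@dataclass(frozen=True)
class FieldSpec:
    """Recipe for one synthetic field of view."""

    height: int = 96
    width: int = 96
    background_poly_coeffs: tuple[float, ...] = DEFAULT_BACKGROUND_COEFFS
    noise_sd: float = 300.0
    nucleus_count: int = 12
    nucleus_radius_range: tuple[float, float] = (3.0, 6.0)
    artifact_specs: tuple[ArtifactSpec, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.height < 32 or self.width < 32:
            raise ValueError("field dimensions must be at least 32 px")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        lo, hi = self.nucleus_radius_range
        if lo <= 0 or hi < lo:
            raise ValueError("nucleus_radius_range must be a positive interval")
        if len(self.background_poly_coeffs) != 6:
            raise ValueError("background polynomial needs 6 coefficients")
        if self.nucleus_count < 0:
            raise ValueError("nucleus_count must be >= 0")
        object.__setattr__(self, "artifact_specs", tuple(self.artifact_specs))


@dataclass
class SyntheticField:
    """A rendered field with its ground truth."""

    image: np.ndarray                  # H x W float32 intensities
    artifact_mask: np.ndarray          # H x W bool
    nuclei_label_mask: np.ndarray      # H x W int32, 0 = background
    label: str                         # "clean" | "artifact"
    fluorescence: np.ndarray | None = None
    cell_mask: np.ndarray | None = None
    clean_image: np.ndarray | None = None   # artifact-free render, same seed


@dataclass(frozen=True)
class AssaySpec:
    """A competitive-binding plate layout with known affinity.

    The specific fluorescence of cell pixels at ligand concentration ``c``
    is ``bottom + (top - bottom) / (1 + 10**(log10(c) - logIC50_true))``
    (Hill slope fixed at -1). Each concentration is laid out in
    ``replicates_per_concentration`` wells with ``fields_per_well`` images.
    """

    logIC50_true: float = -7.0
    top: float = 8000.0
    bottom: float = 500.0
    concentrations: tuple[float, ...] = tuple(float(10.0 ** e) for e in
                                              np.arange(-10.0, -3.9, 0.75))
    replicates_per_concentration: int = 2
    fields_per_well: int = 2
    artifact_rate: float = 0.0
    noise_sd: float = 100.0
    fluor_background: float = 900.0
    artifact_fluor_offset: float = 12000.0
    ligand: str = "ligandA"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.top <= self.bottom:
            raise ValueError("top must exceed bottom")
        if any(c <= 0 for c in self.concentrations):
            raise ValueError("concentrations must be positive")
        if self.replicates_per_concentration < 1 or self.fields_per_well < 1:
            raise ValueError("replicates and fields per well must be >= 1")
        if not 0.0 <= self.artifact_rate <= 1.0:
            raise ValueError("artifact_rate must be in [0, 1]")


def hill_response(concentration: float | np.ndarray, logIC50: float,
                  top: float, bottom: float) -> float | np.ndarray:
    """Hill curve with slope -1 on log10 concentration."""
    x = np.log10(concentration)
    return bottom + (top - bottom) / (1.0 + 10.0 ** (x - logIC50))


# ---------------------------------------------------------------------------
# rasterisation helpers
# ---------------------------------------------------------------------------

def _normalized_grid(h: int, w: int) -> tuple[np.ndarray, np.ndarray]:
    y = np.linspace(-1.0, 1.0, h)[:, None]
    x = np.linspace(-1.0, 1.0, w)[None, :]
    return y, x


def polynomial_surface(coeffs: Sequence[float], h: int, w: int) -> np.ndarray:
    """Evaluate c0 + c1*x + c2*y + c3*x^2 + c4*x*y + c5*y^2 on [-1,1]^2."""
    c0, c1, c2, c3, c4, c5 = coeffs
    y, x = _normalized_grid(h, w)
    return (c0 + c1 * x + c2 * y + c3 * x * x + c4 * x * y + c5 * y * y).astype(np.float64)

def ellipse_mask(h: int, w: int, center: tuple[float, float],
                 a: float, b: float, angle: float = 0.0) -> np.ndarray:
    """Pixel centres (r, c) with ((c-cx)/a)^2 + ((r-cy)/b)^2 <= 1.

    ``a`` is the semi-axis along columns, ``b`` along rows; ``angle``
    rotates the ellipse (radians, counter-clockwise).
    """
    cy, cx = center
    rr, cc = np.mgrid[0:h, 0:w]
    dy = rr - cy
    dx = cc - cx
    if angle:
        ca, sa = np.cos(angle), np.sin(angle)
        dx, dy = ca * dx + sa * dy, -sa * dx + ca * dy
    return (dx / a) ** 2 + (dy / b) ** 2 <= 1.0


def _fiber_mask(h: int, w: int, rng: np.random.Generator, start: tuple[float, float],
                length: int, width: float) -> np.ndarray:
    """Rasterised random-walk curve dilated to the requested width."""
    mask = np.zeros((h, w), dtype=bool)
    r, c = float(start[0]), float(start[1])
    heading = rng.uniform(0, 2 * np.pi)
    for _ in range(length):
        ri, ci = int(round(r)), int(round(c))
        if 0 <= ri < h and 0 <= ci < w:
            mask[ri, ci] = True
        heading += rng.normal(0.0, 0.25)
        r += np.sin(heading)
        c += np.cos(heading)
    radius = max(1, int(round(width / 2)))
    return dilation(mask, disk_footprint(radius))


def _clump_mask(h: int, w: int, rng: np.random.Generator, center: tuple[float, float],
                radius: float, n_disks: int) -> np.ndarray:
    mask = np.zeros((h, w), dtype=bool)
    for _ in range(n_disks):
        cy = center[0] + rng.normal(0.0, radius * 0.6)
        cx = center[1] + rng.normal(0.0, radius * 0.6)
        r = rng.uniform(radius * 0.35, radius * 0.7)
        mask |= ellipse_mask(h, w, (cy, cx), r, r)
    return mask


def rasterize_artifact(spec: ArtifactSpec, h: int, w: int,
                       rng: np.random.Generator) -> np.ndarray:
    """Binary footprint of a single artifact, clipped to the image."""
    if spec.position == "random":
        pos = (rng.uniform(0.15 * h, 0.85 * h), rng.uniform(0.15 * w, 0.85 * w))
    else:
        pos = spec.position
    p = spec.size_params
    if spec.shape == "ellipse":
        mask = ellipse_mask(h, w, pos, p["a"], p["b"], p.get("angle", 0.0))
    elif spec.shape == "fiber":
        mask = _fiber_mask(h, w, rng, pos, int(p["length"]), p.get("width", 3.0))
    else:
        mask = _clump_mask(h, w, rng, pos, p["radius"], int(p.get("n_disks", 6)))
    if not mask.any():
        raise ValueError(f"artifact {spec.shape} rasterised to zero pixels")
    return mask


def random_artifact_specs(rng: np.random.Generator, h: int, w: int,
                          max_artifacts: int = 2) -> tuple[ArtifactSpec, ...]:
    """Sample 1..max_artifacts heterogeneous artifacts sized for an h x w field."""
    scale = min(h, w) / 96.0
    specs = []
    for _ in range(rng.integers(1, max_artifacts + 1)):
        shape = rng.choice(["ellipse", "fiber", "clump"])
        contrast = rng.uniform(0.25, 0.45)
        if shape == "ellipse":
            size = {"a": rng.uniform(9, 18) * scale, "b": rng.uniform(7, 14) * scale,
                    "angle": rng.uniform(0, np.pi)}
        elif shape == "fiber":
            size = {"length": int(rng.integers(40, 90) * scale),
                    "width": rng.uniform(3.0, 5.0) * scale}
        else:
            size = {"radius": rng.uniform(10, 17) * scale,
                    "n_disks": int(rng.integers(5, 9))}
        specs.append(ArtifactSpec(shape=shape, size_params=size,
                                  texture_contrast=contrast))
    return tuple(specs)


# ---------------------------------------------------------------------------
# field rendering
# ---------------------------------------------------------------------------

def _render_nuclei(h: int, w: int, spec: FieldSpec,
                   rng: np.random.Generator, bg_level: float) -> tuple[np.ndarray, np.ndarray]:
    """Smoothed darker disks; returns (intensity offset field, label mask)."""
    labels = np.zeros((h, w), dtype=np.int32)
    offset = np.zeros((h, w), dtype=np.float64)
    lo, hi = spec.nucleus_radius_range
    for i in range(spec.nucleus_count):
        r = rng.uniform(lo, hi)
        cy = rng.uniform(r, h - r)
        cx = rng.uniform(r, w - r)
        m = ellipse_mask(h, w, (cy, cx), r, r)
        labels[m] = i + 1
        offset[m] = -0.12 * bg_level
    if spec.nucleus_count:
        offset = ndi.gaussian_filter(offset, sigma=1.0)
    return offset, labels


def generate_field(spec: FieldSpec) -> SyntheticField:
    """Render one field of view together with all its ground truth.

    Deterministic given ``spec`` (including its seed); the returned
    ``clean_image`` is the render of the identical spec with no artifacts
    and is bit-identical to ``image`` outside the artifact mask.
    """
    h, w = spec.height, spec.width
    ss = np.random.SeedSequence(spec.seed)
    nuc_ss, art_ss, noise_ss = ss.spawn(3)

    background = polynomial_surface(spec.background_poly_coeffs, h, w)
    bg_level = float(background.mean())

    nuc_offset, nuclei_labels = _render_nuclei(h, w, spec, np.random.default_rng(nuc_ss), bg_level)
    base = background + nuc_offset

    artifact_mask = np.zeros((h, w), dtype=bool)
    art_offset = np.zeros((h, w), dtype=np.float64)
    art_rngs = art_ss.spawn(max(1, len(spec.artifact_specs)))
    for aspec, child in zip(spec.artifact_specs, art_rngs):
        arng = np.random.default_rng(child)
        m = rasterize_artifact(aspec, h, w, arng)
        core = aspec.texture_contrast * bg_level
        # dark core plus bounded speckle so every artifact pixel moves by
        # at least half the configured contrast
        speckle = arng.uniform(-0.5, 0.5, size=int(m.sum())) * core
        art_offset[m] = -(core + speckle)
        artifact_mask |= m

    noise = np.random.default_rng(noise_ss).normal(0.0, spec.noise_sd, size=(h, w)) \
        if spec.noise_sd > 0 else 0.0
    clean = np.clip(base + noise, 0.0, INTENSITY_MAX).astype(np.float32)
    image = np.clip(base + art_offset + noise, 0.0, INTENSITY_MAX).astype(np.float32)
    label = "artifact" if artifact_mask.any() else "clean"
    return SyntheticField(image=image, artifact_mask=artifact_mask,
                          nuclei_label_mask=nuclei_labels, label=label,
                          clean_image=clean)


# ---------------------------------------------------------------------------
# labelled datasets with splits
# ---------------------------------------------------------------------------

@dataclass
class LabeledDataset:
    fields: list[SyntheticField]
    labels: list[str]
    splits: list[str]                  # "train" | "val" | "test" per image

    def indices(self, split: str) -> list[int]:
        return [i for i, s in enumerate(self.splits) if s == split]

    def images(self, split: str | None = None) -> np.ndarray:
        idx = range(len(self.fields)) if split is None else self.indices(split)
        return np.stack([self.fields[i].image for i in idx])


def _split_sizes(n: int, ratios: Sequence[float]) -> list[int]:
    """Largest-remainder apportionment so sizes sum exactly to n."""
    if abs(sum(ratios) - 1.0) > 1e-6:
        raise ValueError("split ratios must sum to 1")
    raw = [n * r for r in ratios]
    sizes = [int(np.floor(v)) for v in raw]
    rem = n - sum(sizes)
    order = np.argsort([s - v for s, v in zip(sizes, raw)])
    for i in range(rem):
        sizes[order[i]] += 1
    return sizes


def generate_dataset(n_images: int, artifact_fraction: float,
                     field_template: FieldSpec = FieldSpec(),
                     split_ratios: Sequence[float] = (0.6, 0.2, 0.2),
                     seed: int = 0) -> LabeledDataset:
    """A labelled image set with exact artifact prevalence and disjoint splits.

    Exactly ``round(n_images * artifact_fraction)`` images carry artifacts.
    When the template has no artifact specs of its own, artifact images get
    randomly sampled heterogeneous artifacts. Splits are stratified by label
    so both classes appear in every split whenever sizes permit.
    """
    if not 0.0 <= artifact_fraction <= 1.0:
        raise ValueError("artifact_fraction must be in [0, 1]")
    if n_images < 5:
        raise ValueError("need at least 5 images")
    n_art = int(round(n_images * artifact_fraction))
    master = np.random.SeedSequence(seed)
    field_seeds = master.spawn(n_images)
    spec_rng = np.random.default_rng(master.spawn(1)[0])

    fields, labels = [], []
    for i in range(n_images):
        child_seed = int(field_seeds[i].generate_state(1)[0] % (2 ** 31))
        if i < n_art:
            specs = field_template.artifact_specs or random_artifact_specs(
                spec_rng, field_template.height, field_template.width)
        else:
            specs = ()
        fs = replace(field_template, artifact_specs=specs, seed=child_seed)
        f = generate_field(fs)
        fields.append(f)
        labels.append(f.label)

    sizes = _split_sizes(n_images, split_ratios)
    splits = [""] * n_images
    shuffle_rng = np.random.default_rng(master.spawn(1)[0])
    # stratified assignment: distribute each class across splits proportionally
    for cls in ("artifact", "clean"):
        idx = [i for i, l in enumerate(labels) if l == cls]
        shuffle_rng.shuffle(idx)
        n_cls = len(idx)
        cls_sizes = _split_sizes(n_cls, [s / n_images for s in sizes]) if n_cls else []
        pos = 0
        for name, k in zip(("train", "val", "test"), cls_sizes):
            for i in idx[pos:pos + k]:
                splits[i] = name
            pos += k
    # rounding inside strata can leave totals off by one; rebalance greedily
    for name, want in zip(("train", "val", "test"), sizes):
        have = splits.count(name)
        while have > want:
            for other, ow in zip(("train", "val", "test"), sizes):
                if splits.count(other) < ow:
                    splits[splits.index(name)] = other
                    have -= 1
                    break
    return LabeledDataset(fields=fields, labels=labels, splits=splits)


# ---------------------------------------------------------------------------
# concentration-response plates
# ---------------------------------------------------------------------------

@dataclass
class PlateImage:
    well_id: str
    ligand: str
    concentration: float
    replicate: int
    field: SyntheticField


@dataclass
class PlateDataset:
    images: list[PlateImage]
    assay: AssaySpec

    def table(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "well": im.well_id, "ligand": im.ligand,
            "concentration_M": im.concentration, "replicate": im.replicate,
        } for im in self.images])


def generate_plate(assay: AssaySpec,
                   field_template: FieldSpec = FieldSpec(nucleus_count=14)) -> PlateDataset:
    """Render a plate whose noise-free cell-specific fluorescence sits
    exactly on the Hill curve of ``assay``.

    The fluorescence channel is ``fluor_background`` everywhere plus the
    Hill response on cell pixels; injected artifacts add a bright offset
    inside their footprint (in the fluorescence channel) on a fraction
    ``artifact_rate`` of images. Cell masks are nuclei dilated by a few
    pixels, mimicking a cell-body segmentation.
    """
    master = np.random.SeedSequence(assay.seed)
    images: list[PlateImage] = []
    n_total = (len(assay.concentrations) * assay.replicates_per_concentration
               * assay.fields_per_well)
    seeds = iter(master.spawn(n_total + 1))
    layout_rng = np.random.default_rng(next(seeds))
    widx = 0
    for conc in assay.concentrations:
        response = float(hill_response(conc, assay.logIC50_true, assay.top, assay.bottom))
        for rep in range(assay.replicates_per_concentration):
            widx += 1
            well_id = f"W{widx:03d}"
            for _ in range(assay.fields_per_well):
                child = next(seeds)
                fseed = int(child.generate_state(1)[0] % (2 ** 31))
                with_artifact = layout_rng.uniform() < assay.artifact_rate
                specs = random_artifact_specs(layout_rng, field_template.height,
                                              field_template.width) if with_artifact else ()
                fs = replace(field_template, artifact_specs=specs, seed=fseed)
                f = generate_field(fs)
                h, w = f.image.shape
                cell_mask = dilation(f.nuclei_label_mask > 0, disk_footprint(3))
                fluor = np.full((h, w), assay.fluor_background, dtype=np.float64)
                fluor[cell_mask] += response
                if assay.noise_sd > 0:
                    frng = np.random.default_rng(child.spawn(1)[0])
                    fluor += frng.normal(0.0, assay.noise_sd, size=(h, w))
                if with_artifact:
                    fluor[f.artifact_mask] += assay.artifact_fluor_offset
                f.fluorescence = np.clip(fluor, 0.0, INTENSITY_MAX)
                f.cell_mask = cell_mask
                images.append(PlateImage(well_id=well_id, ligand=assay.ligand,
                                         concentration=conc, replicate=rep, field=f))
    return PlateDataset(images=images, assay=assay)


# ---------------------------------------------------------------------------
# on-disk export (16-bit TIFF images, 8-bit masks, CSV manifests, YAML specs)
# ---------------------------------------------------------------------------

def quantize16(image: np.ndarray) -> np.ndarray:
    return np.clip(np.round(image), 0, INTENSITY_MAX).astype(np.uint16)


def write_dataset(ds: LabeledDataset, directory: str | Path) -> pd.DataFrame:
    """Write images/masks as TIFF plus a labels.csv manifest; returns the manifest."""
    d = Path(directory)
    (d / "images").mkdir(parents=True, exist_ok=True)
    (d / "masks").mkdir(exist_ok=True)
    rows = []
    for i, (f, label, split) in enumerate(zip(ds.fields, ds.labels, ds.splits)):
        img_path = d / "images" / f"img_{i:04d}.tiff"
        mask_path = d / "masks" / f"img_{i:04d}_mask.tiff"
        tifffile.imwrite(img_path, quantize16(f.image))
        tifffile.imwrite(mask_path, (f.artifact_mask.astype(np.uint8) * 255))
        rows.append({"path": str(img_path), "label": label, "split": split,
                     "gt_mask": str(mask_path)})
    manifest = pd.DataFrame(rows)
    manifest.to_csv(d / "labels.csv", index=False)
    return manifest


def save_spec(spec: FieldSpec | AssaySpec, path: str | Path) -> None:
    data = {k: (list(v) if isinstance(v, tuple) else v)
            for k, v in spec.__dict__.items()}
    if isinstance(spec, FieldSpec):
        data["artifact_specs"] = [
            {"shape": a.shape, "size_params": a.size_params,
             "texture_contrast": a.texture_contrast,
             "position": list(a.position) if isinstance(a.position, tuple) else a.position}
            for a in spec.artifact_specs]
        data["kind"] = "field"
    else:
        data["kind"] = "assay"
    Path(path).write_text(yaml.safe_dump(data))


def load_spec(path: str | Path) -> FieldSpec | AssaySpec:
    data = yaml.safe_load(Path(path).read_text())
    kind = data.pop("kind")
    if kind == "field":
        arts = tuple(ArtifactSpec(shape=a["shape"], size_params=a["size_params"],
                                  texture_contrast=a["texture_contrast"],
                                  position=tuple(a["position"]) if isinstance(a["position"], list)
                                  else a["position"])
                     for a in data.pop("artifact_specs"))
        data["background_poly_coeffs"] = tuple(data["background_poly_coeffs"])
        data["nucleus_radius_range"] = tuple(data["nucleus_radius_range"])
        return FieldSpec(artifact_specs=arts, **data)
    data["concentrations"] = tuple(data["concentrations"])
    return AssaySpec(**data)
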