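"""Downstream impact of artifacts and of their removal.

Four analyses quantify what artifacts do to real pipelines:

* nuclei segmentation scored separately inside and outside artifact
  regions (pixel-wise and object-wise);
* nucleus morphometry (pixel area, solidity = area / convex-hull area);
* artifact-excluded specific fluorescence per well (mean cell-pixel
  intensity minus mean background-pixel intensity, artifact pixels
  contributing to neither, averaged over the images of a well);
* concentration-response regression with the Hill equation at slope -1,
    Y = Bottom + (Top - Bottom) / (1 + 10**(X - LogIC50)),  X = log10(conc),
  reporting LogIC50, Top, Bottom, the asymptotic SD of LogIC50 from the
  parameter covariance, and R^2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy.optimize import curve_fit
from scipy.stats import pearsonr
from skimage.measure import regionprops
from skimage.morphology import convex_hull_image

from .metrics import MetricsReport, object_f1, pixel_metrics
from .synthgen import PlateDataset, hill_response


# ---------------------------------------------------------------------------
# artifact-stratified nuclei segmentation scoring
# ---------------------------------------------------------------------------

@dataclass
class RegionStratifiedReport:
    region: str                       # inside_artifacts | outside_artifacts | all
    pixel_report: MetricsReport | None
    object_report: MetricsReport | None
    empty: bool = False


def _majority_region_mask(label_mask: np.ndarray, region: np.ndarray) -> np.ndarray:
    """Keep the objects whose pixels lie majority-inside `region` (ties inside)."""
    labels, n = ndi.label(label_mask > 0 if label_mask.dtype != bool else label_mask)
    out = np.zeros_like(region, dtype=bool)
    for i in range(1, n + 1):
        obj = labels == i
        inside = np.count_nonzero(obj & region)
        if inside * 2 >= np.count_nonzero(obj):
            out |= obj
    return out


def stratified_nuclei_eval(nuclei_pred_mask: np.ndarray, nuclei_gt_mask: np.ndarray,
                           artifact_mask: np.ndarray) -> dict[str, RegionStratifiedReport]:
    """Score a nuclei segmentation inside/outside artifact regions and overall.

    Pixel metrics restrict both prediction and ground truth to the region;
    object metrics evaluate the objects assigned to the region by majority
    pixel overlap (ties assigned inside).
    """
    pred = np.asarray(nuclei_pred_mask).astype(bool)
    gt = np.asarray(nuclei_gt_mask).astype(bool)
    art = np.asarray(artifact_mask).astype(bool)
    if not pred.shape == gt.shape == art.shape:
        raise ValueError("all masks must share one shape")
    reports = {}
    for name, region in (("inside_artifacts", art),
                         ("outside_artifacts", ~art),
                         ("all", np.ones_like(art))):
        if not region.any():
            reports[name] = RegionStratifiedReport(region=name, pixel_report=None,
                                                   object_report=None, empty=True)
            continue
        # count over region pixels only, so disjoint-region counts sum to
        # the whole-image counts
        pix = pixel_metrics(pred[region], gt[region])
        obj = object_f1(_majority_region_mask(pred, region),
                        _majority_region_mask(gt, region))
        reports[name] = RegionStratifiedReport(region=name, pixel_report=pix,
                                               object_report=obj)
    return reports


# ---------------------------------------------------------------------------
# morphometry
# ---------------------------------------------------------------------------

@dataclass
class MorphometryRecord:
    object_id: int
    area: int
    solidity: float


def morphometry(nuclei_label_mask: np.ndarray) -> list[MorphometryRecord]:
    """Pixel area and solidity per labelled object.

    Solidity is the object's pixel count divided by the pixel count of its
    rasterised convex hull: the hull polygon is taken over the object's
    pixel centres and a pixel belongs to the hull if its centre lies
    inside that polygon (discrete hulls admit variants; this is the
    convention used throughout the package).
    """
    labels = np.asarray(nuclei_label_mask)
    if not np.issubdtype(labels.dtype, np.integer):
        raise ValueError("expected an integer-labelled mask")
    records = []
    for prop in regionprops(labels):
        obj = prop.image
        area = int(prop.area)
        try:
            hull = convex_hull_image(obj, offset_coordinates=False)
            hull_area = max(int(hull.sum()), area)
        except Exception:   # degenerate (e.g. collinear) objects are convex
            hull_area = area
        records.append(MorphometryRecord(object_id=int(prop.label),
                                         area=area,
                                         solidity=area / hull_area))
    return records


def threshold_nuclei_segmenter(image: np.ndarray, percentile: float = 12.0,
                               min_size: int = 5) -> np.ndarray:
    """Naive intensity-threshold nuclei detector for synthetic fields.

    Nuclei render darker than the local background, so pixels below the
    given intensity percentile (after a mild smoothing) are called nuclei.
    Stands in for a trained nuclei segmentation model in downstream tests.
    """
    sm = ndi.gaussian_filter(np.asarray(image, dtype=np.float64), sigma=1.0)
    detrended = sm - ndi.uniform_filter(sm, size=25)
    mask = detrended < np.percentile(detrended, percentile)
    mask = ndi.binary_opening(mask, ndi.generate_binary_structure(2, 1))
    labels, n = ndi.label(mask)
    sizes = np.bincount(labels.ravel(), minlength=n + 1)
    keep = sizes >= min_size
    keep[0] = False
    return keep[labels]


# ---------------------------------------------------------------------------
# fluorescence quantification
# ---------------------------------------------------------------------------

@dataclass
class WellIntensityRecord:
    well_id: str
    ligand: str
    concentration: float
    mean_cell_intensity: float
    mean_background_intensity: float
    specific_intensity: float
    n_images_averaged: int
    flagged: bool = False             # True when no usable cell pixels


def image_specific_intensity(fluor_image: np.ndarray, cell_mask: np.ndarray,
                             artifact_mask: np.ndarray | None = None
                             ) -> tuple[float, float, float] | None:
    """(cell mean, background mean, difference) excluding artifact pixels.

    Background pixels are all non-cell pixels of the same image. Returns
    None when no usable cell or background pixels remain.
    """
    fluor = np.asarray(fluor_image, dtype=np.float64)
    cells = np.asarray(cell_mask).astype(bool)
    usable = np.ones_like(cells) if artifact_mask is None \
        else ~np.asarray(artifact_mask).astype(bool)
    cell_px = cells & usable
    bg_px = ~cells & usable
    if not cell_px.any() or not bg_px.any():
        return None
    cm = float(fluor[cell_px].mean())
    bm = float(fluor[bg_px].mean())
    return cm, bm, cm - bm


def well_specific_intensity(plate: PlateDataset,
                            artifact_masks: dict[int, np.ndarray] | None = None
                            ) -> list[WellIntensityRecord]:
    """Per-well specific fluorescence, averaging the per-image values.

    ``artifact_masks`` maps image index (position in ``plate.images``) to
    the artifact mask to exclude; None disables artifact removal.
    """
    by_well: dict[str, list[int]] = {}
    for idx, im in enumerate(plate.images):
        by_well.setdefault(im.well_id, []).append(idx)
    records = []
    for well_id, idxs in by_well.items():
        per_image = []
        first = plate.images[idxs[0]]
        for idx in idxs:
            f = plate.images[idx].field
            amask = None if artifact_masks is None else artifact_masks.get(idx)
            res = image_specific_intensity(f.fluorescence, f.cell_mask, amask)
            if res is not None:
                per_image.append(res)
        if not per_image:
            records.append(WellIntensityRecord(
                well_id=well_id, ligand=first.ligand,
                concentration=first.concentration,
                mean_cell_intensity=float("nan"),
                mean_background_intensity=float("nan"),
                specific_intensity=float("nan"),
                n_images_averaged=0, flagged=True))
            continue
        arr = np.array(per_image)
        records.append(WellIntensityRecord(
            well_id=well_id, ligand=first.ligand,
            concentration=first.concentration,
            mean_cell_intensity=float(arr[:, 0].mean()),
            mean_background_intensity=float(arr[:, 1].mean()),
            specific_intensity=float(arr[:, 2].mean()),
            n_images_averaged=len(per_image)))
    return records


# ---------------------------------------------------------------------------
# Hill regression
# ---------------------------------------------------------------------------

class HillFitError(RuntimeError):
    pass


@dataclass
class HillFit:
    logIC50: float
    top: float
    bottom: float
    sd_logIC50: float
    r2: float
    residuals: np.ndarray

    def predict(self, concentrations: np.ndarray) -> np.ndarray:
        return hill_response(np.asarray(concentrations, dtype=np.float64),
                             self.logIC50, self.top, self.bottom)


def fit_hill(concentrations, responses) -> HillFit:
    """Least-squares Hill fit with the slope fixed at -1.

    Initialisation: Top/Bottom from the response extremes, LogIC50 from
    the concentration whose response is nearest the midpoint; bounded so
    Top >= Bottom at convergence. The SD of LogIC50 is the asymptotic
    standard error from the parameter covariance at the optimum.
    """
    conc = np.asarray(concentrations, dtype=np.float64)
    resp = np.asarray(responses, dtype=np.float64)
    if conc.shape != resp.shape or conc.ndim != 1:
        raise ValueError("concentrations and responses must be equal-length 1-D")
    if np.any(conc <= 0):
        raise ValueError("concentrations must be positive")
    if np.unique(conc).size < 4:
        raise ValueError("need at least 4 distinct concentrations")
    x = np.log10(conc)

    def model(xv, logic50, top, bottom):
        return bottom + (top - bottom) / (1.0 + 10.0 ** (xv - logic50))

    top0, bot0 = float(resp.max()), float(resp.min())
    mid = (top0 + bot0) / 2.0
    logic0 = float(x[np.argmin(np.abs(resp - mid))])
    span = top0 - bot0 if top0 > bot0 else 1.0
    lo = [x.min() - 3.0, bot0 - 0.5 * span, bot0 - 10.0 * span]
    hi = [x.max() + 3.0, top0 + 10.0 * span, top0 + 0.5 * span]
    try:
        popt, pcov = curve_fit(model, x, resp, p0=[logic0, top0, bot0],
                               bounds=(lo, hi), maxfev=20000)
    except RuntimeError as exc:
        raise HillFitError(f"Hill regression did not converge: {exc}") from exc
    pred = model(x, *popt)
    residuals = resp - pred
    ss_res = float((residuals ** 2).sum())
    ss_tot = float(((resp - resp.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    sd = float(np.sqrt(pcov[0, 0])) if np.isfinite(pcov[0, 0]) else float("nan")
    return HillFit(logIC50=float(popt[0]), top=float(popt[1]),
                   bottom=float(popt[2]), sd_logIC50=sd, r2=r2,
                   residuals=residuals)


def fit_wells(records: list[WellIntensityRecord]) -> HillFit:
    """Hill fit over a list of per-well records (flagged wells skipped)."""
    ok = [r for r in records if not r.flagged]
    return fit_hill([r.concentration for r in ok],
                    [r.specific_intensity for r in ok])


# ---------------------------------------------------------------------------
# comparing artifact-removal strategies
# ---------------------------------------------------------------------------

def compare_removal(reference: dict[str, tuple[list[WellIntensityRecord], HillFit]],
                    alternative: dict[str, tuple[list[WellIntensityRecord], HillFit]]
                    ) -> dict:
    """Agreement between two artifact-removal strategies.

    Both inputs map curve id -> (per-well records, HillFit). Returns the
    per-curve |Delta LogIC50| and their mean, paired R^2 values, and the
    Pearson correlation of well specific intensities across all shared
    wells.
    """
    if set(reference) != set(alternative):
        raise ValueError("reference and alternative must cover the same curves")
    deltas, r2_pairs = {}, {}
    ref_int, alt_int = [], []
    for curve in reference:
        ref_recs, ref_fit = reference[curve]
        alt_recs, alt_fit = alternative[curve]
        ref_wells = {r.well_id: r for r in ref_recs if not r.flagged}
        alt_wells = {r.well_id: r for r in alt_recs if not r.flagged}
        if set(ref_wells) != set(alt_wells):
            raise ValueError(f"curve {curve}: well sets differ")
        deltas[curve] = abs(ref_fit.logIC50 - alt_fit.logIC50)
        r2_pairs[curve] = (ref_fit.r2, alt_fit.r2)
        for wid in sorted(ref_wells):
            ref_int.append(ref_wells[wid].specific_intensity)
            alt_int.append(alt_wells[wid].specific_intensity)
    r = float(pearsonr(ref_int, alt_int).statistic) if len(ref_int) > 1 else float("nan")
    return {"delta_logIC50": deltas,
            "mean_abs_delta_logIC50": float(np.mean(list(deltas.values()))),
            "r2_pairs": r2_pairs,
            "pearson_r_well_intensities": r}


def records_to_frame(records: list[WellIntensityRecord]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in records])
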