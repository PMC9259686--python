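"""Clean-image synthesis: polynomial background fit, noise profile, inpainting.

Artifact-containing brightfield images are converted to clean counterparts
by (1) least-squares fitting a two-dimensional second-order polynomial
intensity surface to the non-artifact pixels, (2) collecting a zero-centred
empirical noise profile from background pixels, and (3) replacing annotated
artifact pixels with the estimated background plus a draw from the noise
profile. Pixels outside the artifact mask are never touched.

Pixel coordinates are normalised to [-1, 1] on both axes before fitting:
raw indices in the thousands make the normal equations ill-conditioned.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


class DegenerateFitError(ValueError):
    """Background fit is under-determined (too few pixels or rank-deficient)."""


@dataclass
class BackgroundModel:
    """b(x, y) = c0 + c1 x + c2 y + c3 x^2 + c4 x y + c5 y^2 on [-1,1]^2 coords."""

    coeffs: np.ndarray          # shape (6,)
    fit_domain: tuple[int, int]  # (height, width) the normalisation refers to

    def __post_init__(self) -> None:
        self.coeffs = np.asarray(self.coeffs, dtype=np.float64)
        if self.coeffs.shape != (6,) or not np.all(np.isfinite(self.coeffs)):
            raise ValueError("need 6 finite coefficients")

    def evaluate(self) -> np.ndarray:
        """The background surface over the full fit domain."""
        h, w = self.fit_domain
        rows, cols = np.mgrid[0:h, 0:w]
        design = _design_matrix(rows.ravel(), cols.ravel(), h, w)
        return (design @ self.coeffs).reshape(h, w)


@dataclass
class NoiseProfile:
    """Mean-centred background residuals and their standard deviation."""

    residuals: np.ndarray
    summary_sd: float

    def __post_init__(self) -> None:
        self.residuals = np.asarray(self.residuals, dtype=np.float64)
        if self.residuals.size == 0:
            raise ValueError("noise profile needs at least one residual")


def _normalize_coords(rows: np.ndarray, cols: np.ndarray,
                      h: int, w: int) -> tuple[np.ndarray, np.ndarray]:
    y = 2.0 * rows / (h - 1) - 1.0
    x = 2.0 * cols / (w - 1) - 1.0
    return y, x


def _design_matrix(rows: np.ndarray, cols: np.ndarray, h: int, w: int) -> np.ndarray:
    y, x = _normalize_coords(rows.astype(np.float64), cols.astype(np.float64), h, w)
    return np.column_stack([np.ones_like(x), x, y, x * x, x * y, y * y])


def fit_background(image: np.ndarray,
                   exclude_mask: np.ndarray | None = None) -> BackgroundModel:
    """Least-squares second-order polynomial fit over non-excluded pixels.

    ``exclude_mask`` marks pixels (typically annotated artifacts) that must
    not influence the fit; excluding them provably reduces bias from bright
    or dark foreign objects.
    """
    image = np.asarray(image, dtype=np.float64)
    h, w = image.shape
    if exclude_mask is None:
        keep = np.ones((h, w), dtype=bool)
    else:
        exclude_mask = np.asarray(exclude_mask, dtype=bool)
        if exclude_mask.shape != image.shape:
            raise ValueError("exclude_mask shape must match image")
        keep = ~exclude_mask
    rows, cols = np.nonzero(keep)
    if rows.size < 6:
        raise DegenerateFitError(f"only {rows.size} usable pixels, need >= 6")
    design = _design_matrix(rows, cols, h, w)
    coeffs, _, rank, _ = np.linalg.lstsq(design, image[keep], rcond=None)
    if rank < 6:
        raise DegenerateFitError(f"design matrix rank {rank} < 6")
    return BackgroundModel(coeffs=coeffs, fit_domain=(h, w))


def estimate_noise_profile(image: np.ndarray, background: BackgroundModel,
                           background_mask: np.ndarray,
                           min_pixels: int = 100) -> NoiseProfile:
    """Zero-centred residuals of the image against the fitted background.

    ``background_mask`` selects the pixels regarded as pure background
    (non-artifact, and non-nucleus when a nuclei mask is available).
    """
    image = np.asarray(image, dtype=np.float64)
    background_mask = np.asarray(background_mask, dtype=bool)
    if background_mask.shape != image.shape:
        raise ValueError("background_mask shape must match image")
    n = int(background_mask.sum())
    if n < min_pixels:
        raise ValueError(f"only {n} background pixels, need >= {min_pixels}")
    surface = background.evaluate()
    residuals = image[background_mask] - surface[background_mask]
    residuals = residuals - residuals.mean()
    return NoiseProfile(residuals=residuals, summary_sd=float(residuals.std()))


def inpaint(image: np.ndarray, artifact_mask: np.ndarray,
            background: BackgroundModel, noise: NoiseProfile,
            seed: int = 0) -> np.ndarray:
    """Replace artifact pixels by background + resampled noise; leave the rest.

    Noise values are drawn with replacement from the empirical residual
    pool, which preserves any non-Gaussian tails of the sensor noise.
    """
    image = np.asarray(image)
    artifact_mask = np.asarray(artifact_mask, dtype=bool)
    if artifact_mask.shape != image.shape:
        raise ValueError("artifact_mask shape must match image")
    out = image.copy()
    n = int(artifact_mask.sum())
    if n == 0:
        return out
    rng = np.random.default_rng(seed)
    surface = background.evaluate()
    draws = rng.choice(noise.residuals, size=n, replace=True)
    out[artifact_mask] = (surface[artifact_mask] + draws).astype(out.dtype)
    return out


def clean_image(image: np.ndarray, artifact_mask: np.ndarray,
                nuclei_mask: np.ndarray | None = None, seed: int = 0) -> np.ndarray:
    """Full clean-image synthesis: fit, noise profile, inpaint."""
    bg = fit_background(image, exclude_mask=artifact_mask)
    background_mask = ~np.asarray(artifact_mask, dtype=bool)
    if nuclei_mask is not None:
        background_mask &= ~np.asarray(nuclei_mask, dtype=bool)
    noise = estimate_noise_profile(image, bg, background_mask)
    return inpaint(image, artifact_mask, bg, noise, seed=seed)
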