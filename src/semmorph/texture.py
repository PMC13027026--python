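"""Surface-texture quantification by second-order polynomial detrending.

SEM intensity over an intact coccus is dominated by smooth structure: the
global illumination gradient (specimen tilt, detector geometry) and the
gentle dome of the cell itself.  Both lie in the span of the quadratic
surface z = a0 + a1*x + a2*y + a3*x^2 + a4*y^2 + a5*xy.  Fitting that
surface by least squares to the [0, 1]-normalized intensities of an eroded
cell mask and taking the RMS residual isolates high-frequency deviations -
the roughness signature of a damaged cell envelope.  The mask is first
eroded (7x7 kernel, 2 iterations) so edge shading does not leak into the
residual.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

from .segmentation import Region

logger = logging.getLogger(__name__)

#: Minimum pixel count of the eroded region for a determinate, non-noise-
#: dominated 6-parameter fit.
MIN_ERODED_PIXELS = 50


@dataclass(frozen=True)
class PolySurfaceFit:
    """Least-squares quadratic surface over one region.

    Coefficients are reported in the centered/scaled coordinate frame used
    for conditioning (origin at the pixel centroid, unit half-width);
    residual statistics are frame-independent.
    """

    coefficients: np.ndarray  # (a0, a1, a2, a3, a4, a5)
    n_pixels: int
    rms_residual: float
    mean_abs_residual: float
    max_abs_residual: float
    valid: bool


@dataclass(frozen=True)
class TextureResult:
    texture_value: float       # RMS residual on the [0, 1] intensity scale
    mean_abs_residual: float   # secondary statistic, for sensitivity checks
    eroded_pixels: int
    valid: bool


INVALID_TEXTURE = TextureResult(np.nan, np.nan, 0, False)


def erode_mask(mask: np.ndarray, kernel_size: int = 7, iterations: int = 2) -> np.ndarray:
    """Binary erosion with a filled square structuring element.

    Each iteration trims (kernel_size - 1) / 2 pixels from every side; the
    result may be empty.
    """
    selem = np.ones((kernel_size, kernel_size), dtype=bool)
    return ndi.binary_erosion(np.asarray(mask, dtype=bool), structure=selem,
                              iterations=iterations)


def fit_poly_surface(coords: np.ndarray, intensities01: np.ndarray) -> PolySurfaceFit:
    """Ordinary least squares of z = a0 + a1 x + a2 y + a3 x^2 + a4 y^2 + a5 xy.

    ``coords`` is an (n, 2) array of (x, y) pixel coordinates and
    ``intensities01`` the matching intensities on [0, 1].  Coordinates are
    centered on their centroid and scaled to unit half-width before solving,
    which only changes the coefficient frame, not the residuals.  A rank-
    deficient design (e.g. collinear pixels) yields ``valid=False``.
    """
    coords = np.asarray(coords, dtype=float)
    z = np.asarray(intensities01, dtype=float)
    n = len(z)
    if n < 6:
        raise ValueError(f"need >=6 pixels for a determinate quadratic fit, got {n}")
    center = coords.mean(axis=0)
    half_width = np.abs(coords - center).max()
    scale = half_width if half_width > 0 else 1.0
    x, y = ((coords - center) / scale).T
    design = np.column_stack([np.ones(n), x, y, x * x, y * y, x * y])
    coef, _, rank, _ = np.linalg.lstsq(design, z, rcond=None)
    if rank < 6:
        return PolySurfaceFit(coef, n, np.nan, np.nan, np.nan, valid=False)
    resid = z - design @ coef
    return PolySurfaceFit(
        coefficients=coef,
        n_pixels=n,
        rms_residual=float(np.sqrt(np.mean(resid ** 2))),
        mean_abs_residual=float(np.mean(np.abs(resid))),
        max_abs_residual=float(np.max(np.abs(resid))),
        valid=True,
    )


def texture_value(
    region: Region,
    image: np.ndarray,
    kernel_size: int = 7,
    iterations: int = 2,
    min_pixels: int = MIN_ERODED_PIXELS,
) -> TextureResult:
    """Per-cell roughness: RMS residual of the quadratic surface fit.

    The region mask is eroded (default 7x7, 2 iterations); regions whose
    eroded footprint holds fewer than ``min_pixels`` pixels are flagged
    invalid and excluded from texture statistics.  Raw [0, 255] intensities
    are divided by 255 (global normalization, preserving cross-cell
    comparability) before the fit.
    """
    eroded = erode_mask(region.mask, kernel_size, iterations)
    n = int(eroded.sum())
    if n < min_pixels:
        logger.debug("label %d: eroded footprint %d px < %d, texture invalid",
                     region.label, n, min_pixels)
        return TextureResult(np.nan, np.nan, n, False)
    r0, _, c0, _ = region.bbox
    rows, cols = np.nonzero(eroded)
    coords = np.column_stack([cols + c0, rows + r0]).astype(float)  # (x, y)
    z = np.asarray(image, dtype=float)[rows + r0, cols + c0] / 255.0
    fit = fit_poly_surface(coords, z)
    if not fit.valid:
        return TextureResult(np.nan, np.nan, n, False)
    return TextureResult(fit.rms_residual, fit.mean_abs_residual, n, True)
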