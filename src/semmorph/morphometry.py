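"""Ellipse morphometry and the artifact-size exclusion rule.

Each segmented cell is fitted to an ellipse by a direct least-squares conic
fit to its outer contour, yielding center, major/minor axis lengths, area and
orientation.  Cells with fewer than five contour points or an area below
1000 px^2 (0.183 um^2 at the study calibration) are segmentation artifacts
and are excluded before any downstream statistics.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from skimage.measure import EllipseModel

from .segmentation import Region

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EllipseFit:
    """Least-squares ellipse for one cell.

    Axis lengths are full lengths (major >= minor); ``orientation_deg`` is the
    angle of the major axis against the image x-axis (toward +y = down rows),
    normalized to [0, 180).
    """

    center: tuple[float, float]
    major_axis_px: float
    minor_axis_px: float
    orientation_deg: float
    fit_ok: bool

    @property
    def semi_major(self) -> float:
        return self.major_axis_px / 2.0

    @property
    def semi_minor(self) -> float:
        return self.minor_axis_px / 2.0

    @property
    def ellipse_area_px2(self) -> float:
        return np.pi * self.semi_major * self.semi_minor


FAILED_FIT = EllipseFit(center=(np.nan, np.nan), major_axis_px=np.nan,
                        minor_axis_px=np.nan, orientation_deg=np.nan, fit_ok=False)


@dataclass(frozen=True)
class SizeFilterRule:
    """Artifact exclusion: strict '< 5 contour points' OR 'area < 1000 px^2'."""

    min_contour_points: int = 5
    min_area_px2: float = 1000.0


def fit_ellipse(region: Region) -> EllipseFit:
    """Direct least-squares ellipse fit to a region's outer contour.

    Requires >= 5 contour points (run :func:`size_filter` first).  Degenerate
    configurations (collinear contours, non-elliptical conics) return a fit
    with ``fit_ok=False``.
    """
    pts = np.asarray(region.contour, dtype=float)
    if len(pts) < 5:
        raise ValueError(
            f"region {region.label}: ellipse fit needs >=5 contour points, got "
            f"{len(pts)}; apply the size filter first"
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        model = EllipseModel.from_estimate(pts)
    if not model:
        return FAILED_FIT
    (xc, yc) = model.center
    a, b = model.axis_lengths  # semi-axes, descending
    theta = float(model.theta)
    if not (np.isfinite([xc, yc, a, b, theta]).all() and a > 0 and b > 0.5):
        # sub-pixel minor axis = degenerate (near-collinear) conic
        return FAILED_FIT
    orientation = float(np.rad2deg(theta)) % 180.0
    return EllipseFit(
        center=(float(xc), float(yc)),
        major_axis_px=2.0 * float(a),
        minor_axis_px=2.0 * float(b),
        orientation_deg=orientation,
        fit_ok=True,
    )


def size_filter(
    regions: list[Region], rule: SizeFilterRule = SizeFilterRule()
) -> tuple[list[Region], list[Region]]:
    """Split regions into (kept, excluded) under the artifact-size rule.

    A region is excluded iff it has strictly fewer contour points than
    ``min_contour_points`` or strictly smaller area than ``min_area_px2``.
    Exclusion reasons are recorded on ``region.extra['excluded_reason']``.
    """
    kept: list[Region] = []
    excluded: list[Region] = []
    for reg in regions:
        reasons = []
        if reg.n_contour_points < rule.min_contour_points:
            reasons.append(f"contour_points {reg.n_contour_points} < {rule.min_contour_points}")
        if reg.area_px2 < rule.min_area_px2:
            reasons.append(f"area {reg.area_px2} px2 < {rule.min_area_px2}")
        if reasons:
            reg.extra["excluded_reason"] = "; ".join(reasons)
            logger.debug("label %d excluded: %s", reg.label, reg.extra["excluded_reason"])
            excluded.append(reg)
        else:
            kept.append(reg)
    if excluded:
        logger.info("size filter excluded %d/%d regions", len(excluded), len(regions))
    return kept, excluded
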