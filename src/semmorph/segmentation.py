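"""Instance label masks -> per-cell regions.

The pipeline consumes instance masks produced by any external segmenter
(e.g. a pretrained deep-learning model run out-of-core); this module turns a
mask into per-cell regions with contours and defines the adapter contract
such a segmenter must satisfy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Protocol, runtime_checkable

import numpy as np
from scipy import ndimage as ndi
from skimage.measure import find_contours

from .image_io import MicrographPair

logger = logging.getLogger(__name__)


@runtime_checkable
class SegmenterAdapter(Protocol):
    """Contract for an external instance segmenter.

    Implementations return a non-negative integer label mask of the same
    shape as the input image (0 = background) and are deterministic for a
    fixed model and input.
    """

    name: str

    def segment(self, image: np.ndarray) -> np.ndarray: ...


@dataclass
class Region:
    """One segmented cell.

    ``mask`` is a boolean array local to ``bbox`` = (r0, r1, c0, c1) half-open
    in image coordinates; ``contour`` is the ordered outer boundary of the
    largest connected component as (x, y) = (col, row) sub-pixel points.
    """

    label: int
    mask: np.ndarray
    bbox: tuple[int, int, int, int]
    contour: np.ndarray
    area_px2: int
    centroid: tuple[float, float]  # (x, y) in full-image pixel coordinates
    edge: bool = False
    extra: dict = field(default_factory=dict)

    @property
    def n_contour_points(self) -> int:
        return len(self.contour)

    def full_mask(self, shape: tuple[int, int]) -> np.ndarray:
        """Place the local mask back onto a full-image canvas."""
        out = np.zeros(shape, dtype=bool)
        r0, r1, c0, c1 = self.bbox
        out[r0:r1, c0:c1] = self.mask
        return out


def _outer_contour(mask: np.ndarray, label: int) -> np.ndarray:
    """Ordered outer contour (x, y) of the largest connected component."""
    lab, n = ndi.label(mask)
    if n > 1:
        sizes = ndi.sum_labels(np.ones_like(mask, dtype=np.int64), lab, index=range(1, n + 1))
        keep = int(np.argmax(sizes)) + 1
        mask = lab == keep
        logger.warning("label %d has %d connected components; keeping largest", label, n)
    # pad so boundary-touching regions still yield closed contours
    padded = np.pad(mask.astype(float), 1)
    contours = find_contours(padded, 0.5)
    if not contours:
        return np.empty((0, 2))
    contour_rc = max(contours, key=len) - 1.0  # undo padding offset
    return contour_rc[:, ::-1].copy()  # (row, col) -> (x, y)


def labels_to_regions(pair: MicrographPair) -> list[Region]:
    """Extract one :class:`Region` per distinct nonzero label.

    Labels touching the image border are retained but flagged ``edge=True``;
    multi-component labels keep the largest component for the contour (the
    area still counts every pixel of the label).  An empty mask yields an
    empty list.
    """
    mask = pair.label_mask
    regions: list[Region] = []
    if mask.max() == 0:
        return regions
    h, w = mask.shape
    slices = ndi.find_objects(mask)
    for label, sl in enumerate(slices, start=1):
        if sl is None:
            continue
        local = mask[sl] == label
        area = int(local.sum())
        r0, c0 = sl[0].start, sl[1].start
        r1, c1 = sl[0].stop, sl[1].stop
        rows, cols = np.nonzero(local)
        cy = float(rows.mean()) + r0
        cx = float(cols.mean()) + c0
        contour = _outer_contour(local, label)
        contour = contour + np.array([c0, r0], dtype=float)
        edge = r0 == 0 or c0 == 0 or r1 == h or c1 == w
        regions.append(
            Region(
                label=label,
                mask=local,
                bbox=(r0, r1, c0, c1),
                contour=contour,
                area_px2=area,
                centroid=(cx, cy),
                edge=edge,
            )
        )
    return regions


def regions_to_labels(regions: list[Region], shape: tuple[int, int]) -> np.ndarray:
    """Reassemble regions into a label image (round-trip check helper)."""
    out = np.zeros(shape, dtype=np.int64)
    for reg in regions:
        r0, r1, c0, c1 = reg.bbox
        view = out[r0:r1, c0:c1]
        view[reg.mask] = reg.label
    return out
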