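"""Synthetic SEM-like scenes of ovoid cocci with known ground truth.

Real micrographs show chains of ovoid cells under a global illumination
gradient, each cell a bright dome fading toward its rim, with surface damage
appearing as high-frequency intensity texture, and some cells partially
hidden behind neighbors.  This generator renders that phenomenology onto a
pixel grid together with an exact instance label mask and a per-cell truth
table, so every downstream stage (region extraction, ellipse fitting, size
and neighbor filters, texture, group statistics) can be validated against
known parameters without the study's images.

Cells are filled ellipses shaded by the quadratic dome
``peak - (peak - rim) * q`` where ``q`` is the normalized ellipse quadratic
form; the dome plus the planar scene gradient both lie in the span of the
second-order surface the texture stage removes, so the per-cell texture
value of a noise-free cell is (up to 8-bit quantization) zero and a cell's
expected texture equals the roughness amplitude it was rendered with.

Occlusion is paint-over z-ordering: a hidden cell is drawn first and a
neighbor is drawn over it at an offset chosen (by bisection on rendered
pixel counts) so the visible remnant passes the artifact-size filter yet is
guaranteed below 0.7x the occluder's area - exactly the signature the
neighbor-based background filter removes.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .image_io import PIXEL_SIZE_UM

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SceneParams:
    """Generator settings; defaults emulate the study's imaging conditions.

    ``mean_area_um2``/``area_cv`` set the lognormal projected-area law
    (0.3703 um^2, CV 0.29: the untreated-population values), and
    ``roughness_amplitude`` is the std of the per-cell high-frequency
    intensity noise on the [0, 1] scale (0.021: the untreated-population
    texture level).
    """

    image_width_px: int = 1024
    image_height_px: int = 1024
    n_cells: int = 40
    mean_area_um2: float = 0.3703
    area_cv: float = 0.29
    aspect_ratio_range: tuple[float, float] = (1.1, 1.8)
    roughness_amplitude: float = 0.021
    gradient_slope: tuple[float, float] = (4e-5, 6e-5)
    background_noise_sd: float = 0.02
    occluded_fraction: float = 0.25
    chain_probability: float = 0.5
    pixel_size_um: float = PIXEL_SIZE_UM
    seed: int = 0

    def __post_init__(self) -> None:
        if self.image_width_px <= 0 or self.image_height_px <= 0:
            raise ValueError("image dimensions must be positive")
        if self.n_cells < 0:
            raise ValueError("n_cells must be >= 0")
        if not self.mean_area_um2 > 0:
            raise ValueError("mean_area_um2 must be > 0")
        if self.area_cv < 0:
            raise ValueError("area_cv must be >= 0")
        if min(self.aspect_ratio_range) < 1:
            raise ValueError("aspect ratios must be >= 1")
        for name in ("roughness_amplitude", "background_noise_sd",
                     "occluded_fraction", "chain_probability"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not self.pixel_size_um > 0:
            raise ValueError("pixel_size_um must be > 0")
        mean_px = self.mean_area_um2 / self.pixel_size_um ** 2
        diameter = 2.0 * np.sqrt(mean_px / np.pi)
        if diameter > min(self.image_width_px, self.image_height_px):
            raise ValueError("image too small for one mean-sized cell")

    @property
    def mean_area_px2(self) -> float:
        return self.mean_area_um2 / self.pixel_size_um ** 2


@dataclass
class Scene:
    """A rendered micrograph with exact ground truth."""

    image: np.ndarray          # uint8, [0, 255]
    label_mask: np.ndarray     # int32, 0 = background
    truth: pd.DataFrame        # one row per rendered cell
    params: SceneParams
    placement_shortfall: int = 0  # cells dropped after bounded retries

    def __post_init__(self) -> None:
        mask_labels = set(np.unique(self.label_mask)) - {0}
        truth_labels = set(self.truth["cell_id"]) if len(self.truth) else set()
        if mask_labels != truth_labels:
            raise AssertionError(
                f"truth/mask label mismatch: {mask_labels ^ truth_labels}"
            )


# shading constants, [0, 1] intensity scale
_BACKGROUND_LEVEL = 0.22
_DOME_PEAK = 0.68
_DOME_RIM = 0.42

_TRUTH_COLUMNS = [
    "cell_id", "x", "y", "major_axis_px", "minor_axis_px", "orientation_deg",
    "area_px2", "visible_area_px2", "area_um2", "visible_area_um2",
    "occluded", "roughness_amplitude",
]


@dataclass
class _CellSpec:
    x: float
    y: float
    a: float  # semi-major, px
    b: float  # semi-minor, px
    phi_deg: float
    z: int = 1          # paint order; lower painted first
    occluded: bool = False


def _ellipse_pixels(spec: _CellSpec, shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    """(rows, cols) of pixel centers inside the ellipse, clipped to ``shape``."""
    r_max = spec.a  # bounding radius
    r0 = max(int(np.floor(spec.y - r_max)) - 1, 0)
    r1 = min(int(np.ceil(spec.y + r_max)) + 2, shape[0])
    c0 = max(int(np.floor(spec.x - r_max)) - 1, 0)
    c1 = min(int(np.ceil(spec.x + r_max)) + 2, shape[1])
    rr, cc = np.mgrid[r0:r1, c0:c1]
    q = _quadratic_form(spec, cc, rr)
    inside = q <= 1.0
    return rr[inside], cc[inside]


def _quadratic_form(spec: _CellSpec, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    phi = np.deg2rad(spec.phi_deg)
    dx, dy = x - spec.x, y - spec.y
    u = dx * np.cos(phi) + dy * np.sin(phi)
    v = -dx * np.sin(phi) + dy * np.cos(phi)
    return (u / spec.a) ** 2 + (v / spec.b) ** 2


def _sample_area_px2(rng: np.random.Generator, params: SceneParams,
                     minimum: float = 0.0) -> float:
    """Lognormal projected area with the configured mean and CV."""
    if params.area_cv == 0:
        return max(params.mean_area_px2, minimum)
    sigma2 = np.log1p(params.area_cv ** 2)
    mu = np.log(params.mean_area_px2) - sigma2 / 2.0
    for _ in range(200):
        area = float(rng.lognormal(mu, np.sqrt(sigma2)))
        if area >= minimum:
            return area
    return max(params.mean_area_px2, minimum)


def _axes_from_area(area_px2: float, aspect: float) -> tuple[float, float]:
    a = np.sqrt(area_px2 * aspect / np.pi)
    return a, a / aspect


class _Placer:
    """Rejection-sampling placement keeping distinct cell groups separated."""

    #: clearance between ellipses of different groups; > the 5 px adjacency
    #: threshold so separated cells are never spurious neighbors
    SEPARATION_PX = 12.0

    def __init__(self, params: SceneParams, rng: np.random.Generator):
        self.params = params
        self.rng = rng
        self.placed: list[_CellSpec] = []  # all committed cells

    def _fits(self, specs: list[_CellSpec]) -> bool:
        h, w = self.params.image_height_px, self.params.image_width_px
        for s in specs:
            margin = s.a + 2.0
            if not (margin <= s.x <= w - margin and margin <= s.y <= h - margin):
                return False
        for s in specs:
            for p in self.placed:
                bound = s.a + p.a + self.SEPARATION_PX
                if (s.x - p.x) ** 2 + (s.y - p.y) ** 2 < bound ** 2:
                    return False
        return True

    def random_anchor(self, a: float) -> tuple[float, float]:
        h, w = self.params.image_height_px, self.params.image_width_px
        margin = a + 2.0
        return (
            float(self.rng.uniform(margin, w - margin)),
            float(self.rng.uniform(margin, h - margin)),
        )

    def commit(self, specs: list[_CellSpec]) -> None:
        self.placed.extend(specs)


def _build_chain(rng: np.random.Generator, params: SceneParams,
                 length: int) -> list[_CellSpec]:
    """Tip-to-tip chain of near-equal-area cells at the origin (unanchored).

    Chain members share one base area (jittered +-5%) so local-size
    comparisons within the chain never misclassify a genuine cell.
    """
    base_area = _sample_area_px2(rng, params)
    direction = float(rng.uniform(0, 180))
    specs: list[_CellSpec] = []
    x = y = 0.0
    prev_a = 0.0
    for k in range(length):
        area = base_area * float(rng.uniform(0.95, 1.05))
        aspect = float(rng.uniform(*params.aspect_ratio_range))
        a, b = _axes_from_area(area, aspect)
        phi = direction + float(rng.uniform(-8, 8))
        if k > 0:
            gap = float(rng.uniform(1.5, 3.5))  # < 5 px: chain members adjacent
            step = prev_a + gap + a
            x += step * np.cos(np.deg2rad(direction))
            y += step * np.sin(np.deg2rad(direction))
        specs.append(_CellSpec(x=x, y=y, a=a, b=b, phi_deg=phi))
        prev_a = a
    return specs


def _build_occlusion_pair(
    rng: np.random.Generator, params: SceneParams, min_visible_px2: float = 1000.0
) -> tuple[list[_CellSpec], bool]:
    """An occluder and a partially hidden cell at the origin (unanchored).

    The occluder is an ordinary unbiased draw from the area law; the hidden
    cell is 0.8x its area.  The occluder offset is bisected on rendered
    pixel counts until the hidden cell's visible remnant lies strictly
    between the artifact-size floor and 0.7x the occluder's own rendered
    area, so the remnant survives the size filter but is guaranteed removed
    by the neighbor filter.  When no offset can satisfy both bounds (small
    occluder, extreme aspect mismatch) the pair is returned separated with
    the occluded flag unset.
    """
    occ_area = _sample_area_px2(rng, params)
    occ_aspect = float(rng.uniform(*params.aspect_ratio_range))
    occ_a, occ_b = _axes_from_area(occ_area, occ_aspect)
    hid_area = 0.8 * occ_area
    hid_aspect = float(rng.uniform(*params.aspect_ratio_range))
    hid_a, hid_b = _axes_from_area(hid_area, hid_aspect)
    theta = float(rng.uniform(0, 360))
    phi_occ = float(rng.uniform(0, 180))
    phi_hid = float(rng.uniform(0, 180))

    pad = int(np.ceil(2 * (occ_a + hid_a))) + 4
    shape = (2 * pad, 2 * pad)
    hidden = _CellSpec(x=float(pad), y=float(pad), a=hid_a, b=hid_b, phi_deg=phi_hid)
    hid_rr, hid_cc = _ellipse_pixels(hidden, shape)
    hid_px = np.zeros(shape, dtype=bool)
    hid_px[hid_rr, hid_cc] = True
    occ_count = len(
        _ellipse_pixels(
            _CellSpec(x=float(pad), y=float(pad), a=occ_a, b=occ_b, phi_deg=phi_occ),
            shape,
        )[0]
    )
    # margins absorb the raster jitter of re-anchoring at sub-pixel offsets;
    # the post-render check in generate_scene re-verifies on final counts
    lo_target = 1.08 * min_visible_px2
    hi_target = 0.68 * occ_count
    if lo_target >= hi_target:
        return _separated_pair(rng, params, hidden, occ_a, occ_b, phi_occ, theta), False

    def visible_at(d: float) -> int:
        occ = _CellSpec(
            x=pad + d * np.cos(np.deg2rad(theta)),
            y=pad + d * np.sin(np.deg2rad(theta)),
            a=occ_a, b=occ_b, phi_deg=phi_occ,
        )
        rr, cc = _ellipse_pixels(occ, shape)
        canvas = hid_px.copy()
        canvas[rr, cc] = False
        return int(canvas.sum())

    d_lo, d_hi = 0.0, occ_a + hid_a  # visible(d) is nondecreasing in d
    target = 0.5 * (lo_target + hi_target)
    for _ in range(40):
        d_mid = 0.5 * (d_lo + d_hi)
        vis = visible_at(d_mid)
        if lo_target <= vis <= hi_target:
            occ = _CellSpec(
                x=hidden.x + d_mid * np.cos(np.deg2rad(theta)),
                y=hidden.y + d_mid * np.sin(np.deg2rad(theta)),
                a=occ_a, b=occ_b, phi_deg=phi_occ, z=2,
            )
            hidden.occluded = True
            # re-anchor pair to origin at the hidden cell
            occ.x -= hidden.x
            occ.y -= hidden.y
            hidden.x = hidden.y = 0.0
            return [hidden, occ], True
        if vis < target:
            d_lo = d_mid
        else:
            d_hi = d_mid
    return _separated_pair(rng, params, hidden, occ_a, occ_b, phi_occ, theta), False


def _separated_pair(rng: np.random.Generator, params: SceneParams,
                    hidden: _CellSpec, occ_a: float, occ_b: float,
                    phi_occ: float, theta: float) -> list[_CellSpec]:
    # the ex-hidden cell joins the genuine population, so its 0.8x-of-occluder
    # area is replaced by a fresh unbiased draw to keep the kept-cell area law
    area = _sample_area_px2(rng, params)
    aspect = float(rng.uniform(*params.aspect_ratio_range))
    hidden.a, hidden.b = _axes_from_area(area, aspect)
    d = hidden.a + occ_a + _Placer.SEPARATION_PX
    occ = _CellSpec(
        x=d * np.cos(np.deg2rad(theta)), y=d * np.sin(np.deg2rad(theta)),
        a=occ_a, b=occ_b, phi_deg=phi_occ,
    )
    hidden.x = hidden.y = 0.0
    hidden.occluded = False
    return [hidden, occ]


def generate_scene(params: SceneParams) -> Scene:
    """Render a deterministic synthetic scene for the given parameters.

    Identical parameters and seed reproduce a bit-identical scene.  If a
    cell group cannot be placed after bounded retries the scene is returned
    with fewer cells and ``placement_shortfall`` set.
    """
    rng = np.random.default_rng(params.seed)
    h, w = params.image_height_px, params.image_width_px
    placer = _Placer(params, rng)

    n_pairs = int(round(params.occluded_fraction * params.n_cells))
    n_pairs = min(n_pairs, params.n_cells // 2)
    n_loose = params.n_cells - 2 * n_pairs

    groups: list[list[_CellSpec]] = []
    for _ in range(n_pairs):
        specs, _ok = _build_occlusion_pair(rng, params)
        groups.append(specs)
    remaining = n_loose
    while remaining > 0:
        length = 1
        while length < remaining and rng.uniform() < params.chain_probability:
            length += 1
        length = min(length, 4, remaining)
        groups.append(_build_chain(rng, params, length))
        remaining -= length

    shortfall = 0
    committed: list[_CellSpec] = []
    pair_links: dict[int, int] = {}  # hidden committed idx -> occluder committed idx
    for specs in groups:
        placed_ok = False
        for _ in range(150):
            anchor_a = max(s.a + np.hypot(s.x, s.y) for s in specs)
            if 2 * anchor_a + 4 > min(h, w):
                break
            ax, ay = placer.random_anchor(anchor_a)
            trial = [
                _CellSpec(x=s.x + ax, y=s.y + ay, a=s.a, b=s.b,
                          phi_deg=s.phi_deg, z=s.z, occluded=s.occluded)
                for s in specs
            ]
            # within-group overlap is intended; only test against other groups
            if placer._fits(trial):
                base = len(committed)
                placer.commit(trial)
                committed.extend(trial)
                if len(trial) == 2 and trial[0].occluded:
                    pair_links[base] = base + 1
                placed_ok = True
                break
        if not placed_ok:
            shortfall += len(specs)
            logger.warning("dropped a group of %d cells after bounded retries", len(specs))

    # --- render ---------------------------------------------------------
    label = np.zeros((h, w), dtype=np.int32)
    intensity = np.full((h, w), _BACKGROUND_LEVEL, dtype=np.float64)
    order = sorted(range(len(committed)), key=lambda i: committed[i].z)
    cell_ids = {}
    for new_id, idx in enumerate(order, start=1):
        cell_ids[idx] = new_id
    for idx in order:
        spec = committed[idx]
        rr, cc = _ellipse_pixels(spec, (h, w))
        q = _quadratic_form(spec, cc.astype(float), rr.astype(float))
        label[rr, cc] = cell_ids[idx]
        intensity[rr, cc] = _DOME_PEAK - (_DOME_PEAK - _DOME_RIM) * q

    # per-cell high-frequency surface noise on the pixels each cell owns
    if params.roughness_amplitude > 0:
        noise = rng.normal(0.0, params.roughness_amplitude, size=(h, w))
        intensity[label > 0] += noise[label > 0]
    gy, gx = params.gradient_slope[1], params.gradient_slope[0]
    cols, rows = np.meshgrid(np.arange(w), np.arange(h))
    intensity += gx * cols + gy * rows
    if params.background_noise_sd > 0:
        bg_noise = rng.normal(0.0, params.background_noise_sd, size=(h, w))
        intensity[label == 0] += bg_noise[label == 0]
    image = np.clip(intensity, 0.0, 1.0)
    image = np.round(image * 255.0).astype(np.uint8)

    # --- truth ----------------------------------------------------------
    factor = params.pixel_size_um ** 2
    counts = np.bincount(label.ravel(), minlength=len(committed) + 1)
    rows_out = []
    for idx in order:
        spec = committed[idx]
        cid = cell_ids[idx]
        visible = int(counts[cid])
        if visible == 0:
            continue  # fully painted over; drop from truth and mask agree
        occluded = spec.occluded
        if occluded:
            # post-render check: remnant must still satisfy the removal signature
            occ_idx = pair_links.get(idx)
            occluder_area = int(counts[cell_ids[occ_idx]]) if occ_idx is not None else 0
            # the remnant must clear the artifact-size floor (else the size
            # filter removes it first) and sit strictly below 0.7x the
            # occluder, or the removal guarantee no longer holds
            if not (1000 <= visible < 0.7 * occluder_area):
                occluded = False
        full_area = np.pi * spec.a * spec.b
        rows_out.append({
            "cell_id": cid,
            "x": spec.x, "y": spec.y,
            "major_axis_px": 2 * spec.a, "minor_axis_px": 2 * spec.b,
            "orientation_deg": spec.phi_deg % 180.0,
            "area_px2": full_area,
            "visible_area_px2": visible,
            "area_um2": full_area * factor,
            "visible_area_um2": visible * factor,
            "occluded": occluded,
            "roughness_amplitude": params.roughness_amplitude,
        })
    truth = pd.DataFrame(rows_out, columns=_TRUTH_COLUMNS)
    return Scene(image=image, label_mask=label, truth=truth, params=params,
                 placement_shortfall=shortfall)


def truth_table(scene: Scene) -> pd.DataFrame:
    """Per-cell ground truth: one row per nonzero label, areas in px^2 and um^2."""
    return scene.truth.copy()


def write_scene(scene: Scene, outdir: str | Path, stem: str = "scene") -> dict:
    """Write image (8-bit PNG), mask (16-bit PNG), truth CSV, and a manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    image_path = outdir / f"{stem}_image.png"
    mask_path = outdir / f"{stem}_mask.png"
    truth_path = outdir / f"{stem}_truth.csv"
    manifest_path = outdir / f"{stem}_manifest.json"
    Image.fromarray(scene.image, mode="L").save(image_path)
    if scene.label_mask.max() > np.iinfo(np.uint16).max:
        raise ValueError("too many labels for a 16-bit mask")
    Image.fromarray(scene.label_mask.astype(np.uint16)).save(mask_path)
    scene.truth.to_csv(truth_path, index=False)
    manifest = {
        "params": asdict(scene.params),
        "placement_shortfall": scene.placement_shortfall,
        "files": {"image": image_path.name, "mask": mask_path.name,
                  "truth": truth_path.name},
    }
    manifest_path.write_text(json.dumps(manifest, indent=2))
    return manifest
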