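"""End-to-end orchestration: scenes or files -> per-cell table -> group report.

The stage order is fixed: region extraction, artifact-size filter, ellipse
fit, adjacency, neighbor-based background filter, texture, group statistics.
Identical thresholds are applied to every image in a run so any systematic
measurement bias cancels in between-group comparisons; all constants live in
:class:`RunConfig` and default to the study values.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .image_io import Calibration, MicrographPair, load_pair, px_area_to_um2
from .morphometry import SizeFilterRule, fit_ellipse
from .neighbors import NeighborFilterRule, build_adjacency, local_size_filter, neighbor_stats
from .segmentation import labels_to_regions
from .stats import summarize_groups, violin_figure
from .synthetic import SceneParams, Scene, generate_scene
from .texture import texture_value

logger = logging.getLogger(__name__)


@dataclass
class GroupSpec:
    """One treatment condition: label plus its inputs."""

    label: str
    # synthetic mode
    scene_params: dict = field(default_factory=dict)
    n_images: int = 1
    # files mode
    image_mask_pairs: list[tuple[str, str]] = field(default_factory=list)


@dataclass
class RunConfig:
    mode: str  # "synthetic" | "files"
    groups: list[GroupSpec]
    control: str
    output_dir: str = "semmorph_out"
    seed: int = 0
    calibration: Calibration = field(default_factory=Calibration)
    size_rule: SizeFilterRule = field(default_factory=SizeFilterRule)
    neighbor_rule: NeighborFilterRule = field(default_factory=NeighborFilterRule)
    erosion_kernel: int = 7
    erosion_iterations: int = 2
    min_texture_pixels: int = 50
    exclude_edge_cells: bool = True
    area_metric: str = "mask"  # "mask" (pixel count) or "ellipse" (fit area)
    crop_box: tuple[int, int, int, int] | None = None
    make_figures: bool = True

    def __post_init__(self) -> None:
        if self.mode not in {"synthetic", "files"}:
            raise ValueError(f"unknown mode {self.mode!r}")
        labels = [g.label for g in self.groups]
        if len(set(labels)) != len(labels):
            raise ValueError("group labels must be unique")
        if labels.count(self.control) != 1 or self.control not in labels:
            raise ValueError(f"exactly one control group required; got {self.control!r}")
        if self.area_metric not in {"mask", "ellipse"}:
            raise ValueError(f"area_metric must be 'mask' or 'ellipse'")


def measure_pair(
    pair: MicrographPair,
    size_rule: SizeFilterRule = SizeFilterRule(),
    neighbor_rule: NeighborFilterRule = NeighborFilterRule(),
    erosion_kernel: int = 7,
    erosion_iterations: int = 2,
    min_texture_pixels: int = 50,
    area_metric: str = "mask",
    image_id: str = "",
) -> tuple[pd.DataFrame, dict]:
    """Run the full single-image measurement chain on one image/mask pair.

    Returns a per-cell table (one row per segmented region, with filter
    flags rather than silent drops) and a stage-count dictionary.
    """
    regions = labels_to_regions(pair)
    from .morphometry import size_filter  # local to keep module import light

    kept, excluded = size_filter(regions, size_rule)

    rows: dict[int, dict] = {}
    for reg in regions:
        rows[reg.label] = {
            "image_id": image_id,
            "label": reg.label,
            "area_px2": reg.area_px2,
            "centroid_x": reg.centroid[0],
            "centroid_y": reg.centroid[1],
            "n_contour_points": reg.n_contour_points,
            "edge": reg.edge,
            "size_excluded": False,
            "size_excluded_reason": "",
            "fit_ok": False,
            "removed_by_background_filter": False,
            "neighbor_count": 0,
            "mean_neighbor_area_px2": np.nan,
            "texture_value": np.nan,
            "texture_mean_abs": np.nan,
            "eroded_pixels": 0,
            "texture_valid": False,
        }
    for reg in excluded:
        rows[reg.label]["size_excluded"] = True
        rows[reg.label]["size_excluded_reason"] = reg.extra.get("excluded_reason", "")

    fits = {}
    for reg in kept:
        fit = fit_ellipse(reg)
        fits[reg.label] = fit
        r = rows[reg.label]
        r["fit_ok"] = fit.fit_ok
        if fit.fit_ok:
            r.update(
                ellipse_x=fit.center[0], ellipse_y=fit.center[1],
                major_axis_px=fit.major_axis_px, minor_axis_px=fit.minor_axis_px,
                orientation_deg=fit.orientation_deg,
                ellipse_area_px2=fit.ellipse_area_px2,
            )

    areas = {reg.label: float(reg.area_px2) for reg in kept}
    fit_ok_cells = {lab: f for lab, f in fits.items() if f.fit_ok}
    graph = build_adjacency(fit_ok_cells, neighbor_rule)
    nstats = neighbor_stats(areas, graph)
    kept_ids, removed_ids = local_size_filter(areas, graph, neighbor_rule)
    for lab in graph.nodes:
        rows[lab]["neighbor_count"] = nstats[lab]["neighbor_count"]
        rows[lab]["mean_neighbor_area_px2"] = nstats[lab]["mean_neighbor_area_px2"]
    for lab in removed_ids:
        rows[lab]["removed_by_background_filter"] = True

    region_by_label = {reg.label: reg for reg in kept}
    n_texture_invalid = 0
    for lab in kept_ids:
        reg = region_by_label[lab]
        tex = texture_value(reg, pair.image, erosion_kernel, erosion_iterations,
                            min_texture_pixels)
        rows[lab]["texture_value"] = tex.texture_value
        rows[lab]["texture_mean_abs"] = tex.mean_abs_residual
        rows[lab]["eroded_pixels"] = tex.eroded_pixels
        rows[lab]["texture_valid"] = tex.valid
        n_texture_invalid += 0 if tex.valid else 1

    cells = pd.DataFrame(list(rows.values()))
    if len(cells):
        if area_metric == "ellipse" and "ellipse_area_px2" in cells.columns:
            reported = cells["ellipse_area_px2"].where(cells["fit_ok"], cells["area_px2"])
        else:
            reported = cells["area_px2"]
        cells["area_um2"] = px_area_to_um2(reported.to_numpy(dtype=float),
                                           pair.calibration)
        cells["kept"] = (
            ~cells["size_excluded"]
            & ~cells["removed_by_background_filter"]
            & cells["fit_ok"]
        )
    n_segmented = len(regions)
    counts = {
        "image_id": image_id,
        "n_segmented": n_segmented,
        "n_size_excluded": len(excluded),
        "n_after_size_filter": len(kept),
        "n_background_removed": len(removed_ids),
        "background_removed_fraction": (
            len(removed_ids) / n_segmented if n_segmented else 0.0
        ),
        "n_texture_invalid": n_texture_invalid,
    }
    return cells, counts


def _derived_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(child.generate_state(1)[0] % (2 ** 31)) for child in ss.spawn(n)]


def run(config: RunConfig) -> dict:
    """Execute a full run and write all artifacts to ``config.output_dir``.

    Returns a dict with the cell table, group summaries, comparisons, and
    the manifest.  Deterministic for a fixed config and seed.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    tasks = []  # (group label, image index)
    for g in config.groups:
        n = g.n_images if config.mode == "synthetic" else len(g.image_mask_pairs)
        for i in range(n):
            tasks.append((g.label, i))
    seeds = _derived_seeds(config.seed, len(tasks))

    all_cells, all_counts = [], []
    for (glabel, i), seed_i in zip(tasks, seeds):
        g = next(gr for gr in config.groups if gr.label == glabel)
        image_id = f"{glabel}/{i}"
        if config.mode == "synthetic":
            params = SceneParams(**{**g.scene_params, "seed": seed_i})
            scene = generate_scene(params)
            pair = MicrographPair(
                image=scene.image.astype(float), label_mask=scene.label_mask,
                calibration=Calibration(pixel_size_um=params.pixel_size_um),
            )
        else:
            image_path, mask_path = g.image_mask_pairs[i]
            try:
                pair = load_pair(image_path, mask_path, config.crop_box,
                                 config.calibration)
            except Exception as exc:
                raise RuntimeError(
                    f"stage load_pair failed for {image_id} "
                    f"({image_path}, {mask_path}): {exc}"
                ) from exc
        cells, counts = measure_pair(
            pair,
            size_rule=config.size_rule,
            neighbor_rule=config.neighbor_rule,
            erosion_kernel=config.erosion_kernel,
            erosion_iterations=config.erosion_iterations,
            min_texture_pixels=config.min_texture_pixels,
            area_metric=config.area_metric,
            image_id=image_id,
        )
        cells["group"] = glabel
        all_cells.append(cells)
        all_counts.append(counts)

    cells = pd.concat(all_cells, ignore_index=True) if all_cells else pd.DataFrame()
    analysis = cells[cells["kept"]] if len(cells) else cells
    if config.exclude_edge_cells and len(analysis):
        analysis = analysis[~analysis["edge"]]
    groups_df, comparisons_df = summarize_groups(analysis, control=config.control)

    cells.to_csv(outdir / "cells.csv", index=False)
    groups_df.to_csv(outdir / "groups.csv", index=False)
    comparisons_df.to_csv(outdir / "comparisons.csv", index=False)
    if config.make_figures:
        violin_figure(analysis, "area_um2", outdir / "violin_area.png",
                      ylabel="projected cell area (um^2)")
        violin_figure(analysis, "texture_value", outdir / "violin_texture.png",
                      ylabel="surface texture value")

    manifest = {
        "software_version": __version__,
        "seed": config.seed,
        "mode": config.mode,
        "control": config.control,
        "parameters": {
            "size_rule": asdict(config.size_rule),
            "neighbor_rule": asdict(config.neighbor_rule),
            "erosion_kernel": config.erosion_kernel,
            "erosion_iterations": config.erosion_iterations,
            "min_texture_pixels": config.min_texture_pixels,
            "pixel_size_um": config.calibration.pixel_size_um,
            "area_metric": config.area_metric,
            "exclude_edge_cells": config.exclude_edge_cells,
        },
        "per_image_counts": all_counts,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return {
        "cells": cells,
        "groups": groups_df,
        "comparisons": comparisons_df,
        "manifest": manifest,
    }
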