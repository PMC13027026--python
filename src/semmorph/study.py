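"""Reference dose-response study design for synthetic validation runs.

The pipeline was built around a ZnO-nanoparticle dose-response experiment on
*Streptococcus sanguinis*: an untreated control and four treatment
concentrations (25-200 ug/mL), six HR-SEM fields per condition.  Treated
populations swell (larger projected area) and roughen (higher surface
texture).  This module encodes those per-condition population parameters as
a ready-made synthetic run configuration, so an end-to-end run on generated
scenes reproduces the study's group structure and effect directions with
known ground truth.
"""

from __future__ import annotations

from .pipeline import GroupSpec, RunConfig

#: Per-condition population parameters: (label, mean projected area in um^2,
#: area coefficient of variation, surface-texture roughness amplitude).
#: The control row doubles as the generator's global defaults.
REFERENCE_CONDITIONS: tuple[tuple[str, float, float, float], ...] = (
    ("control", 0.3703, 0.288, 0.0212),
    ("ZnO-25", 0.3997, 0.311, 0.0203),
    ("ZnO-50", 0.5153, 0.497, 0.0260),
    ("ZnO-100", 0.4645, 0.334, 0.0249),
    ("ZnO-200", 0.4576, 0.307, 0.0279),
)

CONTROL_LABEL = "control"


def reference_run_config(
    output_dir: str,
    seed: int,
    n_images: int = 6,
    n_cells: int = 160,
    image_px: int = 2048,
    make_figures: bool = True,
) -> RunConfig:
    """Synthetic run mirroring the reference study's sampling design.

    Six images per condition by default; ``n_cells`` and ``image_px`` set
    the per-field density (dense fields approach the study's hundreds of
    cells per micrograph; smaller values trade precision for speed).
    """
    groups = [
        GroupSpec(
            label=label,
            scene_params=dict(
                n_cells=n_cells,
                image_width_px=image_px,
                image_height_px=image_px,
                mean_area_um2=mean_area,
                area_cv=cv,
                roughness_amplitude=amplitude,
            ),
            n_images=n_images,
        )
        for label, mean_area, cv, amplitude in REFERENCE_CONDITIONS
    ]
    return RunConfig(
        mode="synthetic",
        groups=groups,
        control=CONTROL_LABEL,
        output_dir=output_dir,
        seed=seed,
        make_figures=make_figures,
    )
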