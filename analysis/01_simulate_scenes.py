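"""Generate one example synthetic micrograph per treatment condition.

Writes, for each condition in the reference dose-response design, an 8-bit
image PNG, a 16-bit label-mask PNG, a ground-truth CSV and a manifest under
``results/scenes/<label>/``.  Downstream scripts can either re-generate
scenes in memory (03) or re-measure these files (02).
"""

import argparse
from pathlib import Path

from semmorph import SceneParams, generate_scene, write_scene
from semmorph.study import REFERENCE_CONDITIONS

ROOT = Path(__file__).resolve().parent.parent


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--n-cells", type=int, default=60)
    ap.add_argument("--image-px", type=int, default=1024)
    ap.add_argument("--out", type=Path, default=ROOT / "results" / "scenes")
    args = ap.parse_args()

    for i, (label, mean_area, cv, amplitude) in enumerate(REFERENCE_CONDITIONS):
        params = SceneParams(
            n_cells=args.n_cells,
            image_width_px=args.image_px,
            image_height_px=args.image_px,
            mean_area_um2=mean_area,
            area_cv=cv,
            roughness_amplitude=amplitude,
            seed=args.seed * 1000 + i,
        )
        scene = generate_scene(params)
        manifest = write_scene(scene, args.out / label, stem=label)
        print(f"{label:8s} {len(scene.truth):3d} cells -> {manifest['files']}")


if __name__ == "__main__":
    main()
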