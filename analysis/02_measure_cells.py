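"""Measure the scenes written by 01_simulate_scenes.py from their files.

Runs the full measurement chain (segmentation -> artifact-size filter ->
ellipse fit -> adjacency -> neighbor background filter -> texture) on each
image/mask pair under ``results/scenes/`` and writes one combined per-cell
table to ``results/cells_from_files.csv``.  This exercises the files-mode
path end to end: the same code measures real exported micrograph/mask pairs.
"""

import argparse
from pathlib import Path

from semmorph import GroupSpec, RunConfig, run

ROOT = Path(__file__).resolve().parent.parent


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--scenes", type=Path, default=ROOT / "results" / "scenes")
    ap.add_argument("--out", type=Path, default=ROOT / "results" / "from_files")
    ap.add_argument("--control", default="control")
    args = ap.parse_args()

    groups = []
    for gdir in sorted(p for p in args.scenes.iterdir() if p.is_dir()):
        label = gdir.name
        pairs = [
            (str(img), str(img.with_name(img.name.replace("_image", "_mask"))))
            for img in sorted(gdir.glob("*_image.png"))
        ]
        if pairs:
            groups.append(GroupSpec(label=label, image_mask_pairs=pairs))
    if not groups:
        raise SystemExit(f"no scenes found under {args.scenes}; run 01 first")

    config = RunConfig(mode="files", groups=groups, control=args.control,
                       output_dir=str(args.out), make_figures=False)
    result = run(config)
    print(result["groups"][["group", "n_cells", "area_um2_mean",
                            "texture_value_mean"]].to_string(index=False))
    print(f"wrote {args.out}/cells.csv")


if __name__ == "__main__":
    main()
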