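# Methods

This note documents the measurement model, the synthetic-scene generator,
the default constants, and the numerical choices behind `semmorph`. The
package quantifies single-cell morphology (projected area) and surface
texture of coccoid bacteria in high-resolution SEM micrographs, given a
per-cell instance segmentation, and compares treated populations against an
untreated control.

## Measurement chain

Every image/mask pair goes through a fixed stage order. No stage silently
drops data: each cell row carries flags recording which filter acted on it.

1. **Intensity normalization.** The grayscale image is optionally cropped
   (e.g. to remove an instrument banner) and min–max rescaled to
   [0, 255]. A constant image maps to zeros with a warning. Because the
   texture metric is residual-based and group comparisons use identical
   processing, the affine rescale does not bias between-group contrasts.
2. **Region extraction.** Each nonzero label in the mask becomes a region:
   pixel area, centroid, sub-pixel boundary contour (marching squares on
   the padded binary mask), and an image-edge flag. If a label has several
   connected components, the largest supplies the contour; the area counts
   all pixels of the label.
3. **Artifact-size filter.** Regions with fewer than 5 contour points or a
   pixel area below 1000 px² are flagged out (strict inequalities). At the
   working calibration this floor is ≈0.18 µm², well below a plausible
   cell; it removes debris and slivers.
4. **Ellipse fit.** A direct least-squares ellipse fit to the boundary
   contour yields center, full major/minor axis lengths, orientation in
   [0°, 180°), and the ellipse area. Degenerate fits (failed estimation or
   semi-minor axis below 0.5 px) are flagged `fit_ok = False`.
5. **Adjacency.** Each fitted ellipse perimeter is sampled at 100 equal
   parameter steps; two cells are adjacent when the minimum pairwise
   distance between their sample sets is strictly below 5 px. A k-d tree
   on centers prescreens candidate pairs; the screen radius is provably
   conservative, so the indexed graph equals the brute-force all-pairs
   graph (asserted in tests).
6. **Neighbor-based background filter.** In a single pass over the
   original adjacency graph, any cell whose pixel area is strictly below
   0.7× the mean area of its neighbors is removed. This targets partially
   occluded cells — ones peeking out from under a neighbor, whose visible
   area underestimates their true size. Isolated cells are kept.
7. **Texture.** The label mask is eroded twice with a 7×7 square
   structuring element (trimming ≈6 px of boundary, where edge shading
   dominates). If fewer than 50 pixels survive, the cell is flagged
   texture-invalid. Otherwise an ordinary-least-squares quadratic surface
   `z = a₀ + a₁x + a₂y + a₃x² + a₄y² + a₅xy` is fit to the eroded-pixel
   intensities on the [0, 1] scale (image/255), and the texture value is
   the RMS residual. The quadratic absorbs the cell's dome-shaped shading
   and any planar illumination gradient, leaving high-frequency surface
   roughness.
8. **Statistics.** Kept cells (size-filter pass, background-filter pass,
   valid ellipse; image-edge cells excluded by default) feed group
   summaries. Treatment vs control uses percent change of the group mean
   (rounded to one decimal) and Cliff's delta, the non-parametric effect
   size δ = P(X>Y) − P(X<Y), categorized with inclusive thresholds:
   large |δ| ≥ 0.474, medium ≥ 0.33, small ≥ 0.147, else not significant
   (figure convention: ***, **, *, ns). With thousands of cells per group,
   parametric p-values saturate; the effect size is the meaningful scale.

Cliff's delta is computed in O((nₓ+n_y) log n_y) via binary search on the
sorted second sample; an O(n²) all-pairs implementation is kept as an
independent cross-check and the two are asserted equal on random tied
samples.

## Calibration

The default pixel size is 0.0136 µm/px (a 0.068 µm scale bar spanning
5 px). An alternative constant, 0.013528 µm/px, is exposed as
`PIXEL_SIZE_UM_FROM_AREA`; it is back-derived from the convention that
1000 px² ↔ 0.183 µm². The two differ by ~0.5% in length (~1% in area); a
run uses one calibration throughout, so group contrasts are unaffected by
the choice.

## Synthetic-scene generator

Real micrographs with manual instance masks are scarce, so validation uses
a generator that renders the phenomenology the pipeline must measure, with
exact ground truth.

- **Population.** Per-cell areas are lognormal with a configurable mean
  (default 0.3703 µm²) and coefficient of variation (default 0.29);
  aspect ratios are uniform in [1.1, 1.8]; orientations uniform.
- **Shading.** Each cell carries a quadratic dome (peak 0.68 at center,
  0.42 at the rim, background 0.22, on the [0, 1] scale). Because the
  dome lies in the span of the texture model's polynomial, a smooth cell's
  texture reading is limited only by the 8-bit quantization floor
  1/(255·√12) ≈ 0.00113.
- **Roughness.** Per-pixel Gaussian noise with a configurable amplitude is
  added only on cell-owned pixels; this is the ground-truth texture knob.
- **Illumination and background.** A global planar gradient (defaults
  4·10⁻⁵/px and 6·10⁻⁵/px) tests the texture model's gradient invariance;
  independent Gaussian noise is added on background pixels only.
- **Chains.** Cocci often divide into short chains; with a configurable
  probability, cells are placed tip-to-tip with 1.5–3.5 px gaps. Chain
  members share a base area (±5% jitter), which guarantees no chain member
  trips the 0.7× neighbor rule.
- **Occlusion.** A configurable fraction of cells is planted partially
  hidden: a hidden cell is drawn first, then an occluder is painted over
  it. The occluder offset is found by bisection on rendered pixel counts
  so the remnant lies strictly between the 1000 px² artifact floor and
  0.7× the occluder's rendered area — i.e. it survives the size filter but
  is guaranteed removed by the background filter. Margins in the bisection
  window absorb sub-pixel re-anchoring raster jitter, and a post-render
  check on the final global counts unsets the occluded flag on any
  residual violation, so the ground-truth guarantee ("all flagged-occluded
  cells are removed, no genuine cell is removed") is exact. When no offset
  can satisfy both bounds (small occluder), the pair is placed separated
  instead and the ex-hidden cell's area is re-drawn from the full
  population law, keeping the kept-cell area distribution unbiased.
- **Placement.** Cell groups (singletons, chains, occlusion pairs) keep a
  12 px separation from other groups, so the only adjacencies are the
  planted ones. Placement retries are bounded; a crowded scene returns
  fewer cells with `placement_shortfall` set.

Everything is deterministic for a fixed parameter set and seed; per-image
seeds in a run are spawned from the run seed via `SeedSequence`.

### Generator realism limits

- Within a condition, all cells share one roughness amplitude, so the
  within-group texture spread is much narrower than in real micrographs.
  Between-group texture *means* behave correctly (monotone in amplitude),
  but texture effect sizes on synthetic runs saturate near |δ| = 1 and
  should not be compared to published effect sizes; area effect sizes,
  driven by realistic within-group variance, are comparable.
- Occlusion feasibility conditions slightly on occluder size (an occluder
  must exceed ≈1.5× the artifact floor for a compliant remnant to exist).
  Measured over 10 dense 2048 px scenes at the widest area distribution
  (CV ≈ 0.5), the kept-cell mean with occlusion enabled differs from the
  occlusion-free mean by only +0.2 percentage points, so the bias is
  negligible in practice.
- Chain members share a base area (±5% jitter), so per-image samples are
  clustered: the effective sample size for a group mean is several-fold
  smaller than the raw kept-cell count, and recovered per-condition means
  can deviate from the planted means by 5–8% in a single six-image run
  even though per-cell draws are unbiased. Effect-size *categories* and
  the dose ordering are robust to this; exact percent changes carry the
  clustered-sampling error.
- Cells are exact ellipses; real cocci have boundary noise, so ellipse-fit
  residuals on real data will be larger.

## Validation summary

The test suite checks: analytic texture cases (model-span fields give zero
residual; uniform ±ε noise gives ε/√3; planar gradients leave the residual
unchanged); erosion arithmetic on known squares; strict inequalities at
every filter boundary (999/1000 px², 4/5 contour points, 4.9/5.0 px gap,
69.9/70.0% of neighbor mean); Cliff's delta fast-vs-brute-force equality,
antisymmetry, and invariance under strictly increasing transforms;
recovery of planted area means and imposed shifts within Monte-Carlo error
at ≥200 cells per group; strict monotonicity of measured texture in
planted roughness; the occlusion removal guarantee; equality of indexed
and brute-force adjacency; and bit-identical artifacts on re-runs.
`scripts/acceptance.py` recomputes the headline quantities from scratch on
freshly generated scenes.
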