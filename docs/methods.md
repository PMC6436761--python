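# Methods

## Scope and model

`yeastseg` segments and tracks budding yeast growing in a monolayer,
imaged every few minutes in phase contrast (optionally bright-field or a
phase + cytoplasmic-fluorescence composite). The design assumptions are:

* cell boundaries (and the interstices between touching cells) are
  locally *brighter* than both background and cell interiors after
  modality prep — the phase-halo property;
* cells move moderately between frames (a few pixels), so a cell's mask
  in one frame is a usable seed for the adjacent frame;
* cells only appear by budding and never merge, so following every
  last-frame cell *backwards* until it disappears recovers all tracks
  and birth frames without any forward detection step.

Large inter-frame movements (flow, stage jumps) are out of design range:
accuracy degrades once displacement approaches the cell radius, which is
also why long seed-to-frame intervals (≥ 36 min at 90-min doubling)
produce errors.

## Pre-processing (`imageprep`)

* **Coarse colony mask** — local standard deviation (window
  `std_window` = 7 px) thresholded at `max(Otsu, 2·median)`; closed,
  hole-filled, small components removed, then eroded by 3 px so the
  activity margin around the colony does not count as cell area. The
  un-eroded, filled mask (*colony support*) is kept separately: tracked
  labels are confined to it.
* **Contour pixels** — `I > μ(7) + k·σ(7) + σ̂`, with `k = contour_k`
  (default 1.0) and `σ̂` the frame's median local standard deviation.
  The additive noise floor keeps flat regions from firing at their own
  noise scale (a pure z-score marks ~16% of any flat region at k = 1);
  it vanishes on noise-free images, preserving the constant-image
  contract. Marked components under `min_contour_size` = 4 px
  (8-connected — the one-pixel crest steps diagonally) are speckle and
  are dropped: left in place, each one splits a watershed basin.
* **Topography** — negated Euclidean distance to the contour set;
  h-minima suppression with h = 1 distance unit (the smallest
  intervention that removes discretization minima without erasing
  small-cell basins); background forced onto a plateau above all
  interior values. On dense mature colonies ≥ 95% of cell cores (2 px
  erosion) then hold exactly one regional minimum; remaining shallow
  pockets at raggedly detected interface arcs produce over-segmentation
  that the correction pass merges away.
* **Bright-field** — min–max rescale (absorbs the linear illumination
  gradient), complement, white top-hat (disk radius 4): thin dark rings
  become bright phase-like evidence. **Composite** —
  `(1−w)·norm(phase) + w·(1 − norm(fluor))` with w = 0.5 darkens
  interiors relative to the halo.
* **Scoring evidence** — the prepped frame is lightly blurred
  (Gaussian σ = 0.5 px, suppressing single-pixel crest dips that the
  path-barrier term is sensitive to), percentile-rescaled to [0, 1] over
  the colony, and saturated to 1 outside the support eroded by 2 px, so
  background can never look cell-like to the scorer. That saturation is
  what makes a bud's seed die at the frame before its birth instead of
  surviving as a phantom.

## Scoring subroutine (`subroutine`)

The per-cell score mixes three terms (weights `w_b/w_s/w_i` =
0.2/0.2/0.6, `accept_threshold` = 0.5, `reach_px` = 15, `n_rounds` = 5,
`smooth_radius` = 2):

* *boundary*: `1 − evidence(p)` — bright contour evidence argues against
  membership at `p`;
* *seed proximity*: `1 − d(p, seed)/reach_px`, clipped at 0, and the
  score is forced to 0 beyond `reach_px` (locality);
* *interior connectedness*: `1 − barrier(p)`, where `barrier` is the
  minimum over 4-connected paths from the seed core of the maximum
  evidence en route (grayscale reconstruction by erosion), then eroded
  by one pixel so the crest row itself — adjacent to low-barrier
  interior — still scores while everything beyond it does not.

Two details carry most of the robustness:

* the **seed core**: only the seed eroded by up to 60% of its inradius
  anchors the barrier. A seed taken from the adjacent (grown, drifted)
  frame overhangs the current boundary; un-eroded, the overhang would
  anchor the barrier in background and let the mask run away. The
  adaptive depth tolerates centroid drift up to roughly half the cell
  radius, which covers ≤ 24-minute intervals at colony-rim drift rates;
* the **connectedness weight** (0.6): proximity plus darkness alone
  score ~0.5 in flat background near the seed, so only the watertight
  path-barrier term separates "my interior" from "across the halo".
  These weights deviate from an earlier 0.5/0.3/0.2 draft for exactly
  that reason; all are configurable.

Refinement thresholds the score (ties inclusive), keeps the largest
connected component, fills holes, and smooths with opening/closing
(radius scaled down below ~100 px so a newborn bud is not eaten by its
own smoothing). Iteration feeds each mask back as the next seed and
stops early on a fixed point. Everything is deterministic; there is no
RNG anywhere in the segmentation path.

## Seeding corrections (`seeding`)

* *Under-segmentation*: contour detection re-run on the region crop at
  `contour_k` ∈ {0.5, 0.75, 1.0, 1.25, 1.5}; a pixel is a cell pixel
  when ≥ 3 thresholds agree; the voted mask's connected components
  (≥ max(4, min_cell_area/3) px — a bud's piece is just its few interior
  pixels) become separate putative cells.
* *Over-segmentation*: after iteration, pieces of one cell have
  converged onto the same boundary; pairs with
  `|A∩B|/min(|A|,|B|) > 0.5` are merged transitively (union–find).
* *Overlap distribution*: every pixel claimed by several cells goes to
  the highest score; ties to the lowest label id (which makes the
  subsequent centroid-distance tie-break unreachable — it is therefore
  not implemented). Claimed pixels are never discarded, so per-cell area
  gain versus discarding overlaps is nonnegative by construction.
* *Residual recovery*: colony-support components no converged cell
  claims (≥ min_cell_area = 15 px) are re-seeded and refined — these are
  typically newborn buds whose basin the watershed folded into the
  mother.
* *Background pockets*: hole-filling the colony mask swallows small
  background bays between cells; a seed converging there is enclosed by
  crests and segments "successfully". After distribution (only then has
  a pocket lost its bright crest fringe to the real neighbours), a
  candidate whose median intensity sits within 0.3·|background−interior|
  of the background level *and* whose 90th percentile carries no
  halo-bright pixels is rejected. The test disables itself when the
  prepped modality has no interior/background contrast (bright-field
  top-hat output).

## Tracking (`tracker`)

Backwards from the seed: each active label is refined independently on
its padded subimage (`pad` = 10 px), claims are reconciled by score
distribution — a pure map over cells, so the output is independent of
processing order — and a label absent (or < `min_cell_area` = 15 px) for
`lost_patience` = 1 backward step is born at the last frame it was
present. `min_cell_area` = 15 px is matched to the generator's bud birth
size so births are detected within the ±2-frame tolerance of the truth;
the practical segmentation floor is ~20–25 px (below that a cell is
nearly all halo crest with no interior for the barrier to anchor in).

## Evaluation (`evaluate`)

* `F = 2C/(R+G)` with C from **maximum-cardinality** bipartite matching
  of centroids within `d_max` = 8 px (an exact matching rather than
  greedy nearest-first: greedy is order-dependent and provably
  sub-optimal on adversarial configurations, and the matching count
  should be a property of the point sets);
* error classes from the symmetric correctness fraction
  `f = min(|P∩T|/|T|, |P∩T|/|P|)`: correct iff f > 0.95, minor iff
  0.90 ≤ f ≤ 0.95, else major. The symmetric form penalizes spillover
  into neighbours as much as omissions;
* periphery = mask minus its erosion by a disk of radius 2 (whole mask
  when erosion empties); percent quantification difference
  `100·|Q_w − Q_wo|/Q_w` (asymmetric by definition — normalized by the
  with-distribution value);
* seed perturbation removes a random angular sector around the mask
  centroid: contiguous removal, connected remainder for convex-ish
  cells, exact pixel count.

## Synthetic scenes (`synthgen`)

Cells are ellipses (axis ratio 1–1.25) with exponential area growth at
the stated doubling time (default 90 min). Buds appear adjacent to their
mothers at `bud_rate` (default 0.46 /cell/h ≈ one bud per 1.5 doubling
times) with birth radius 2.2 px (≈ 15 px², just at the tracker's
detection floor) and a fast early-growth phase (doubling every 15 min)
up to an adult size, emulating the rapid expansion of a new bud — and,
crucially, giving backwards tracking a gradual disappearance to detect.
Overlaps are relaxed by pairwise centroid repulsion with per-frame
displacement capped at 1 px (≈ 20 px/h): colonies spread laterally but
stay in the moderate-movement regime the tracker assumes; the residual
overlaps are resolved per-pixel by nearest-normalized-ellipse
assignment, so true labels never overlap.

The phase render places a Gaussian-profile halo (σ = halo_width/2
= 1 px, peak = background + 0.25) on the *boundary pixel set* — the
outermost pixel row of every cell, which at contacts is a two-pixel band
shared by both cells: touching cells therefore show a single fused
bright ridge, the false-boundary scenario. Interiors are darker
(0.35) than background (0.5); Gaussian noise σ = 0.02. Bright-field
renders the same geometry at half the contrast as dark rings with a
linear illumination gradient; the fluorescent channel fills interiors
(0.8 ± 20% per-cell jitter) over a near-dark background.

What the generator does **not** emulate: point-spread-function optics,
defocus, vignetting beyond a linear gradient, cell-internal texture
(vacuoles, lipid droplets), z-motion, and strongly irregular
morphologies (only low-order Fourier boundary perturbation is
available, off by default). Passing tests therefore demonstrate the
algorithm's logic — seeding, self-correction, scoring, distribution,
tracking — under controlled halo geometry, not performance on any real
microscope's data.

## Test and experiment scales

The robustness experiments run at desk scale: the perturbation
experiment uses four 288² fields (~225 cells total, 10 frames); the
interval experiment two 320² fields (~124 mature cells, 3-min frames,
intervals 3/12/24 min); seeding quality is scored on dense mature
colonies of ~60 touching cells per field. Newly emerged buds below
~25 px are at the render's resolving scale (a 15-px bud is nearly all
halo crest; Jaccard ≥ 0.9 would demand ≤ 2 px total error), so the
seeding-quality bar is evaluated on colonies of established cells while
bud handling is exercised by the tracking and birth-frame tests, and
recovery in the perturbation experiment is judged against the
unperturbed run (the deterministic fixed point), which is well-defined
at every cell size.

## Known limitations

* Sub-resolution buds (< ~20 px) cannot be segmented to tight overlap
  criteria and may flicker near the detection floor.
* Watershed-vs-flooding equivalence is exact away from inter-basin
  ridges; on ridge pixels and plateaus any flooding order is admissible
  and implementations may differ by one pixel.
* Bright-field accuracy is materially below phase (lower contrast, and
  the background-pocket test is unavailable there).
* Large inter-frame movement breaks the seed-overlap assumption by
  design; there is no motion model.
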