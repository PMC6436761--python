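# yeastseg

Marker-free segmentation and backwards-in-time tracking of budding yeast
(*Saccharomyces cerevisiae*) in phase-contrast, bright-field, or
composite time-lapse microscopy, for anyone quantifying single-cell
dynamics in dense colonies without dedicating a fluorescent channel to
segmentation.

Dense yeast colonies are hard to segment: phase optics paint a bright
halo around every cell, and where cells touch, the fused halos form
false boundaries; cells bud, grow exponentially (doubling ≈ 90 min in
glucose), and press against each other for hundreds of frames, so a
single uncorrected error propagates through the whole movie.

## The algorithm

**Automated seeding** of the last frame:

1. *Pre-processing & watershed.* Mean/standard-deviation filtering marks
   contour pixels (halo crests, interstices) — pixels with
   `I > μ_local + k·σ_local` inside the coarse colony mask. The negated
   distance transform of the contour set, with shallow minima suppressed
   (h-minima), is flooded by the watershed transform: one coarse region
   per basin.
2. *Correction & fine-tuning.* Each watershed region is tested for
   under-segmentation by re-running contour detection at several
   thresholds `k`; each threshold votes per pixel, and a majority-voted
   mask that falls apart splits the region. Every piece is then refined
   with an iterative scoring subroutine: the score of pixel `p` for a
   cell is

   ```
   score(p) = w_b·(1 − evidence(p)) + w_s·max(0, 1 − d(p, seed)/reach)
            + w_i·(1 − barrier(p))
   ```

   where `barrier(p)` is the lowest contour barrier on any path from the
   seed core to `p` (grayscale reconstruction). Thresholding the score
   and feeding the mask back as the next seed converges onto the cell
   boundary. Fragments of an over-segmented cell converge onto the *same*
   boundary, overlap heavily, and are merged; small overlaps between
   neighbours (fused halos) are distributed pixel-by-pixel to the cell
   with the higher score; residual unclaimed colony blobs are re-seeded
   (missed newborn buds) and background pockets are rejected by a
   cell/non-cell intensity test.
3. **Backwards tracking.** The seed is followed from the last frame to
   the first: each cell is re-segmented independently on a subimage using
   its mask from the adjacent later frame as seed, overlaps are
   redistributed, and a cell that disappears going backwards has been
   born — its label, birth frame, and per-frame geometry go into the
   track table.

Robustness is the design center: a seed with 40% of its area removed
recovers the true boundary within a few refinement rounds, so
segmentation errors self-correct instead of propagating.

Evaluation utilities implement the standard scores: `F = 2C/(R+G)` over
center-matched cells, correct/minor/major error classes (>95% /
90–95% of area correct), percent cell area gain
`100·(A_with − A_without)/A_with` from distributing overlaps, and mean
periphery fluorescence with its percent quantification difference.

A seeded synthetic colony generator (`yeastseg.synthgen`) renders
phase / bright-field / fluorescent stacks with ground-truth labels and
lineage, so the whole pipeline is testable without any data download.

## Worked example

```
$ cat scene.yaml
n_initial_cells: 25
frames: 10
frame_shape: [256, 256]
bud_rate: 1.0
rng_seed: 7

$ yeastseg synth --config scene.yaml --out-dir scene/
wrote scene with 38 cells, 10 frames to scene

$ yeastseg seed --input scene/phase.tif --modality phase --out seed_labels.tif
INFO yeastseg.seeding: autoseed: 57 watershed regions, 4 splits, 6 merges
INFO yeastseg.seeding: autoseed: rejected 21 background pockets
seeded 34 cells -> seed_labels.tif

$ yeastseg track --input scene/phase.tif --seed seed_labels.tif \
      --modality phase --out-labels labels.tif --out-tracks tracks.csv
tracked 34 cells over 10 frames

$ yeastseg evaluate --pred labels.tif --truth scene/truth_labels.tif \
      --report report.csv
mean F-measure 0.9701 over 10 frames
```

The seeding log is the self-correction at work: 57 raw watershed basins
are consolidated by 4 under-segmentation splits, 6 over-segmentation
merges, and 21 rejected interstitial background pockets into 34 cells
(the 38 ground-truth cells include a handful of just-emerged buds only a
few pixels across). `tracks.csv` holds one row per cell per frame —
label, birth frame, area, centroid, status:

```
frame,label,birth_frame,area,centroid_row,centroid_col,status
0,1,0,109,10.321,244.706,present
0,2,0,472,16.322,16.390,present
```

and `report.csv` the per-frame F-measure and error-class fractions
(frame 0 above: G=25 true cells, R=26 predicted, C=25 matched,
F=0.980).

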