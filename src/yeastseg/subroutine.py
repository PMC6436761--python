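"""The iterative seeded segmentation core.

Given a subimage and a seed mask, produce a per-cell score map — an image
of weights in [0, 1] expressing how likely each pixel belongs to the cell
— and a refined mask.  Iterating the refinement, feeding each output mask
back in as the next seed, converges a coarse or perturbed seed onto the
cell boundary: the mechanism behind boundary fine-tuning, recovery from
seed perturbation, and over-segmentation fragments converging onto the
same cell.

The score mixes three terms:

* a boundary term, ``1 - evidence``: bright contour evidence at a pixel
  argues against cell membership there (the boundary itself scores low);
* a seed-proximity term, ``1 - d(p, seed)/reach_px`` clipped at 0;
* an interior-connectedness term: one minus the lowest contour barrier on
  any path from the seed to the pixel (grayscale reconstruction by
  erosion), eroded by one pixel so the crest row itself — reachable from
  the interior — still scores, while everything beyond the crest does not.

The connectedness term carries half the weight: proximity and darkness
alone would let a cell bleed across a halo into its neighbour's interior,
and only the path-barrier term is watertight against that.

This module is deterministic and does no I/O.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.morphology import disk, reconstruction


@dataclass
class SubimageContext:
    """A crop around one cell's seed.

    ``origin`` is the (row, col) offset of the crop in the full frame;
    ``seed`` is crop-local.  ``pad`` should cover the expected one-frame
    boundary motion.
    """

    crop: np.ndarray
    origin: tuple[int, int]
    seed: np.ndarray
    pad: int = 10


@dataclass
class SubroutineParams:
    """Constants of the scoring subroutine.

    The three mixture weights sum to 1.  ``reach_px`` bounds how far from
    the seed a cell may claim pixels; ``accept_threshold`` is the score
    level at which a pixel is kept (inclusive).
    """

    n_rounds: int = 5
    reach_px: float = 15.0
    boundary_weight: float = 0.2
    seed_weight: float = 0.2
    interior_weight: float = 0.6
    accept_threshold: float = 0.5
    smooth_radius: int = 2

    def validate(self) -> None:
        if self.n_rounds < 1:
            raise ValueError("n_rounds must be >= 1")
        if self.reach_px < 1:
            raise ValueError("reach_px must be >= 1")
        total = (self.boundary_weight + self.seed_weight
                 + self.interior_weight)
        if not np.isclose(total, 1.0):
            raise ValueError("mixture weights must sum to 1")
        if not 0.0 < self.accept_threshold < 1.0:
            raise ValueError("accept_threshold must be in (0, 1)")


_CROSS = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


def _barrier_from_seed(evidence: np.ndarray, seed: np.ndarray) -> np.ndarray:
    """min over 4-connected paths from the seed of the max evidence along
    the path; 4-connectivity so a one-pixel contour crest is watertight."""
    marker = np.ones_like(evidence)
    marker[seed] = evidence[seed]
    marker = np.maximum(marker, evidence)  # reconstruction needs marker >= mask
    return reconstruction(marker, evidence, method="erosion",
                          footprint=_CROSS)


def compute_score(ctx: SubimageContext, prep: np.ndarray,
                  params: SubroutineParams) -> np.ndarray:
    """Score map for one cell: weights in [0, 1], zero beyond reach_px."""
    params.validate()
    seed = np.asarray(ctx.seed, dtype=bool)
    if not seed.any():
        raise ValueError("empty seed")
    evidence = np.clip(np.asarray(prep, dtype=np.float64), 0.0, 1.0)
    if evidence.shape != seed.shape:
        raise ValueError("prep/seed shape mismatch")

    dist = ndi.distance_transform_edt(~seed)
    proximity = np.clip(1.0 - dist / params.reach_px, 0.0, 1.0)

    # Only confidently-interior pixels may seed the path barrier: a seed
    # from the adjacent (grown, drifted) frame overhangs the crest by a
    # few pixels, and an overhanging marker would anchor the barrier in
    # the background and let the mask run away outward.
    core = seed
    inradius = float(ndi.distance_transform_edt(seed).max())
    start = int(np.clip(0.6 * inradius, 1, 8))
    for r in range(start, 0, -1):
        er = ndi.binary_erosion(seed, structure=disk(r))
        if int(er.sum()) >= (9 if r > 1 else 4):
            core = er
            break
    barrier = _barrier_from_seed(evidence, core)
    # erode: the crest row is adjacent to low-barrier interior, so it keeps a
    # high connectedness value; pixels past the crest see only barrier ~1
    conn = 1.0 - ndi.grey_erosion(barrier, footprint=_CROSS)

    score = (params.boundary_weight * (1.0 - evidence)
             + params.seed_weight * proximity
             + params.interior_weight * np.clip(conn, 0.0, 1.0))
    score = np.clip(score, 0.0, 1.0)
    score[dist > params.reach_px] = 0.0
    return score


def _largest_component(mask: np.ndarray) -> np.ndarray:
    lab, n = ndi.label(mask)
    if n == 0:
        return np.zeros_like(mask)
    if n == 1:
        return mask
    sizes = ndi.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
    return lab == (int(np.argmax(sizes)) + 1)


def refine_once(ctx: SubimageContext, prep: np.ndarray,
                params: SubroutineParams) -> tuple[np.ndarray, np.ndarray]:
    """One refinement round: threshold the score, keep the largest
    connected component, fill holes, smooth the boundary.

    An empty thresholded set returns an empty mask (cell loss)."""
    score = compute_score(ctx, prep, params)
    binary = score >= params.accept_threshold
    if not binary.any():
        return np.zeros_like(binary), score
    mask = _largest_component(binary)
    mask = ndi.binary_fill_holes(mask)
    if params.smooth_radius > 0:
        # scale the smoothing down for small cells (newborn buds): a
        # radius-2 opening would eat a third of a 30-pixel bud
        r = min(params.smooth_radius,
                max(1, round(np.sqrt(mask.sum()) / 6.0)))
        se = disk(r)
        opened = ndi.binary_opening(mask, structure=se)
        if opened.any():
            mask = ndi.binary_fill_holes(
                ndi.binary_closing(opened, structure=se))
            mask = _largest_component(mask)
    return mask, score


def iterate(ctx: SubimageContext, prep: np.ndarray,
            params: SubroutineParams) -> tuple[np.ndarray, np.ndarray]:
    """Run refine_once ``n_rounds`` times, feeding each mask back as the
    next seed; stops early when two successive masks agree.

    The output never extends beyond ``reach_px`` of the initial seed
    (locality contract), and an empty intermediate mask is final."""
    params.validate()
    seed0 = np.asarray(ctx.seed, dtype=bool)
    allowed = ndi.distance_transform_edt(~seed0) <= params.reach_px
    seed = seed0
    score = None
    for _ in range(params.n_rounds):
        round_ctx = SubimageContext(crop=ctx.crop, origin=ctx.origin,
                                    seed=seed, pad=ctx.pad)
        mask, score = refine_once(round_ctx, prep, params)
        mask &= allowed
        if not mask.any():
            return mask, score
        if np.array_equal(mask, seed):
            break
        seed = mask
    return seed, score
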