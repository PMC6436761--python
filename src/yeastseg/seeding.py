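"""Fully automated seeding of the last frame.

Watershed over the prepped topography gives one coarse region per basin;
the watershed lines do not mark exact boundaries and sometimes merge
several cells (under-segmentation) or split one cell (over-segmentation).
The correction pass fixes both automatically:

* under-segmentation — the contour detection is re-run on the region's
  subimage at several threshold multipliers; each threshold "votes" on
  every pixel, and the majority-voted cell mask splits into connected
  pieces when a stable internal contour exists;
* fine-tuning — every piece is refined with the iterative scoring
  subroutine, converging onto its cell boundary;
* over-segmentation — fragments of one cell converge onto the same
  boundary and therefore overlap heavily after iteration; pairs whose
  overlap exceeds ``merge_overlap_theta`` of the smaller piece are merged
  transitively;
* remaining small overlaps between neighbouring cells (fused phase
  halos) are distributed pixel-by-pixel to the cell with the highest
  score there.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage.morphology import local_minima
from skimage.segmentation import watershed

from . import imageprep, subroutine
from .imageprep import Modality, PrepParams
from .subroutine import SubimageContext, SubroutineParams

log = logging.getLogger(__name__)


@dataclass
class SeedingParams:
    """Constants of the correction pass.

    ``vote_thresholds`` are contour_k multipliers; a pixel is voted a cell
    pixel when at least ``vote_majority`` thresholds agree.  Overlaps above
    ``merge_overlap_theta`` (normalized by the smaller piece) trigger a
    merge; smaller ones are distributed by score.
    """

    vote_thresholds: tuple[float, ...] = (0.5, 0.75, 1.0, 1.25, 1.5)
    vote_majority: int = 3
    merge_overlap_theta: float = 0.5
    small_overlap_frac: float = 0.2
    min_cell_area: int = 15
    background_band: float = 0.3     # pocket rejection width, see autoseed

    def validate(self) -> None:
        if len(self.vote_thresholds) < 3:
            raise ValueError("need at least 3 vote thresholds")
        if self.vote_majority > len(self.vote_thresholds):
            raise ValueError("vote_majority exceeds threshold count")
        if not 0.0 < self.merge_overlap_theta <= 1.0:
            raise ValueError("merge_overlap_theta must be in (0, 1]")


def watershed_partition(topography: np.ndarray,
                        cellmask: np.ndarray) -> np.ndarray:
    """Flood the topography from its regional minima, restricted to the
    colony mask: every cellmask pixel gets exactly one label, one label
    per regional minimum, background 0."""
    cellmask = np.asarray(cellmask, dtype=bool)
    if not cellmask.any():
        return np.zeros(cellmask.shape, dtype=np.int32)
    minima = local_minima(topography) & cellmask
    markers, n = ndi.label(minima)
    if n == 0:
        return np.zeros(cellmask.shape, dtype=np.int32)
    labels = watershed(topography, markers=markers, mask=cellmask,
                       connectivity=1)
    leftover = cellmask & (labels == 0)
    if leftover.any():
        extra, m = ndi.label(leftover)
        labels = labels + np.where(leftover, extra + n, 0)
    return labels.astype(np.int32)


def split_undersegmented(region: SubimageContext, params: SeedingParams,
                         prep_params: PrepParams) -> list[np.ndarray]:
    """Threshold-voting under-segmentation test on one watershed region.

    ``region.crop`` must be the prepped intensity crop (contour evidence
    bright); ``region.seed`` the region's mask.  Contour detection is
    re-run per vote threshold; majority-voted cell pixels are split into
    connected components.  A single surviving component (or an empty vote)
    returns the region unchanged.
    """
    params.validate()
    seed = np.asarray(region.seed, dtype=bool)
    votes = np.zeros(seed.shape, dtype=np.int32)
    support = ndi.binary_dilation(seed, iterations=2)
    for k in params.vote_thresholds:
        contours = imageprep.detect_contour_pixels(
            region.crop, prep_params, cellmask=support, contour_k=k)
        votes += (seed & ~contours)
    voted = votes >= params.vote_majority
    if not voted.any():
        return [seed]
    lab, n = ndi.label(voted)
    pieces = []
    for i in range(1, n + 1):
        piece = lab == i
        # a newborn bud's voted piece is its few interior pixels; keep it
        # and let the scoring iteration grow it back onto the full bud
        if int(piece.sum()) >= max(4, params.min_cell_area // 3):
            pieces.append(piece)
    if len(pieces) <= 1:
        return [seed]
    return pieces


def merge_groups(masks: list[np.ndarray],
                 params: SeedingParams) -> list[list[int]]:
    """Transitive grouping of masks whose pairwise overlap exceeds
    ``merge_overlap_theta`` of the smaller mask (union-find)."""
    params.validate()
    n = len(masks)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    areas = [int(np.count_nonzero(m)) for m in masks]
    for i in range(n):
        for j in range(i + 1, n):
            if areas[i] == 0 or areas[j] == 0:
                continue
            inter = int(np.count_nonzero(masks[i] & masks[j]))
            if inter == 0:
                continue
            if inter / min(areas[i], areas[j]) > params.merge_overlap_theta:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[max(ri, rj)] = min(ri, rj)
    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    return [groups[r] for r in sorted(groups)]


def merge_oversegmented(masks: list[np.ndarray],
                        params: SeedingParams) -> list[np.ndarray]:
    """Union every transitive group of heavily overlapping masks."""
    out = []
    for group in merge_groups(masks, params):
        merged = masks[group[0]].copy()
        for i in group[1:]:
            merged |= masks[i]
        out.append(merged)
    return out


def distribute_overlaps(masks: list[np.ndarray],
                        scores: list[np.ndarray],
                        labels: list[int] | None = None,
                        shape: tuple[int, int] | None = None) -> np.ndarray:
    """Assign every disputed pixel to the single cell with the highest
    score there; pixels claimed by one mask keep their label; no claimed
    pixel is discarded or double-labeled.

    Ties (including all-zero scores) go to the lowest label id.  Masks and
    scores are index-aligned, frame-global arrays."""
    if len(masks) != len(scores):
        raise ValueError("masks/scores length mismatch")
    if labels is None:
        labels = list(range(1, len(masks) + 1))
    if shape is None:
        if not masks:
            raise ValueError("cannot infer shape from empty input")
        shape = masks[0].shape
    out = np.zeros(shape, dtype=np.int32)
    best = np.full(shape, -1.0, dtype=np.float64)
    order = np.argsort(np.asarray(labels, dtype=np.int64), kind="stable")
    for i in order:
        m = np.asarray(masks[i], dtype=bool)
        s = np.asarray(scores[i], dtype=np.float64)
        take = m & (s > best)
        out[take] = labels[i]
        best[take] = s[take]
    return out


def _background_pocket_filter(prepped: np.ndarray, support: np.ndarray,
                              band: float):
    """Classifier for interstitial background pockets.

    Hole-filling the coarse colony mask swallows small background bays
    between cells; a seed converging there looks segmentable (enclosed by
    halo crests) but is no cell.  Cells betray themselves by intensity:
    interiors are darker than the background and halo-dominated newborn
    buds brighter, while a pocket sits *at* background level.  Returns a
    predicate over masks, or None when the modality offers no
    interior/background contrast (then nothing is rejected).
    """
    outside = ~ndi.binary_dilation(support, iterations=3)
    if not outside.any() or band <= 0:
        return None
    bg_level = float(np.median(prepped[outside]))
    inside = prepped[support]
    interior_level = float(np.percentile(inside, 10))
    spread = abs(bg_level - interior_level)
    if spread < 1e-3:          # e.g. top-hat prepped bright-field
        return None

    def is_pocket(mask: np.ndarray) -> bool:
        vals = prepped[mask]
        med = float(np.median(vals))
        bright = float(np.percentile(vals, 90))
        # a cell is darker than background (interior) or much brighter
        # (halo-dominated newborn bud); a pocket is neither
        return (abs(med - bg_level) < band * spread
                and bright - bg_level < 2 * band * spread)

    return is_pocket


def _bbox_slices(mask: np.ndarray, pad: int,
                 shape: tuple[int, int]) -> tuple[slice, slice]:
    rows = np.any(mask, axis=1).nonzero()[0]
    cols = np.any(mask, axis=0).nonzero()[0]
    r0 = max(int(rows[0]) - pad, 0)
    r1 = min(int(rows[-1]) + pad + 1, shape[0])
    c0 = max(int(cols[0]) - pad, 0)
    c1 = min(int(cols[-1]) + pad + 1, shape[1])
    return slice(r0, r1), slice(c0, c1)


def _enforce_single_component(labels: np.ndarray,
                              masks: list[np.ndarray],
                              scores: list[np.ndarray],
                              ids: list[int]) -> np.ndarray:
    """Keep each label's largest component; orphan fragments fall to the
    next-best claimant or background."""
    out = labels.copy()
    by_id = {lid: i for i, lid in enumerate(ids)}
    for lid in np.unique(out):
        if lid == 0:
            continue
        m = out == lid
        lab, n = ndi.label(m)
        if n <= 1:
            continue
        sizes = ndi.sum_labels(np.ones_like(lab), lab,
                               index=np.arange(1, n + 1))
        keep = int(np.argmax(sizes)) + 1
        orphan = m & (lab != keep)
        out[orphan] = 0
        ys, xs = orphan.nonzero()
        for y, x in zip(ys, xs):
            best_s, best_l = 0.0, 0
            for oid in ids:
                if oid == lid:
                    continue
                i = by_id[oid]
                if masks[i][y, x] and scores[i][y, x] > best_s:
                    best_s, best_l = scores[i][y, x], oid
            out[y, x] = best_l
    return out


def autoseed(frame: np.ndarray, modality: Modality | str,
             prep_params: PrepParams | None = None,
             sub_params: SubroutineParams | None = None,
             seed_params: SeedingParams | None = None,
             fluor: np.ndarray | None = None,
             pad: int = 10) -> tuple[np.ndarray, list[np.ndarray]]:
    """Fully automated seeding of the last time point.

    prep -> watershed -> per-region threshold-vote splitting -> iterative
    per-piece refinement -> over-segmentation merging -> score-based
    overlap distribution; cells below ``min_cell_area`` are dropped.

    Returns the seed label mask and the per-cell score maps aligned with
    labels 1..n.
    """
    prep_params = prep_params or PrepParams()
    sub_params = sub_params or SubroutineParams()
    seed_params = seed_params or SeedingParams()
    seed_params.validate()

    prepped = imageprep.prep_frame(frame, modality, prep_params, fluor=fluor)
    cellmask = imageprep.coarse_cell_mask(prepped, prep_params)
    if not cellmask.any():
        warnings.warn("no colony found; empty seed", stacklevel=2)
        return np.zeros(prepped.shape, dtype=np.int32), []
    contours = imageprep.detect_contour_pixels(prepped, prep_params,
                                               cellmask=cellmask)
    topo = imageprep.make_topography(contours, cellmask)
    coarse = watershed_partition(topo, cellmask)
    evidence, _ = imageprep.scoring_evidence(prepped, prep_params)
    shape = prepped.shape

    masks: list[np.ndarray] = []
    scores: list[np.ndarray] = []
    n_splits = 0
    for lid in np.unique(coarse):
        if lid == 0:
            continue
        region_full = coarse == lid
        rs, cs = _bbox_slices(region_full, pad, shape)
        ctx = SubimageContext(crop=prepped[rs, cs], origin=(rs.start, cs.start),
                              seed=region_full[rs, cs], pad=pad)
        pieces = split_undersegmented(ctx, seed_params, prep_params)
        if len(pieces) > 1:
            n_splits += 1
        for piece in pieces:
            prs, pcs = _bbox_slices(piece, pad, ctx.crop.shape)
            sub_ctx = SubimageContext(
                crop=evidence[rs, cs][prs, pcs],
                origin=(rs.start + prs.start, cs.start + pcs.start),
                seed=piece[prs, pcs], pad=pad)
            mask, score = subroutine.iterate(sub_ctx, sub_ctx.crop, sub_params)
            if not mask.any():
                continue
            full_m = np.zeros(shape, dtype=bool)
            full_s = np.zeros(shape, dtype=np.float32)
            orr, occ = sub_ctx.origin
            full_m[orr:orr + mask.shape[0], occ:occ + mask.shape[1]] = mask
            full_s[orr:orr + mask.shape[0], occ:occ + mask.shape[1]] = \
                np.where(mask, score, 0.0)
            masks.append(full_m)
            scores.append(full_s)

    if not masks:
        warnings.warn("zero cells found", stacklevel=2)
        return np.zeros(shape, dtype=np.int32), []

    # residual recovery: colony pixels no converged cell claims are
    # usually a newborn bud whose basin the watershed folded into its
    # mother; treat each sufficiently large residual component as a
    # putative cell and refine it like any other piece
    evidence_sc, support_sc = imageprep.scoring_evidence(prepped, prep_params)
    claimed = np.zeros(shape, dtype=bool)
    for m in masks:
        claimed |= m
    residual = support_sc & ~claimed
    res_lab, n_res = ndi.label(residual)
    for i in range(1, n_res + 1):
        blob = res_lab == i
        if int(blob.sum()) < seed_params.min_cell_area:
            continue
        rs, cs = _bbox_slices(blob, pad, shape)
        sub_ctx = SubimageContext(crop=evidence_sc[rs, cs],
                                  origin=(rs.start, cs.start),
                                  seed=blob[rs, cs], pad=pad)
        mask, score = subroutine.iterate(sub_ctx, sub_ctx.crop, sub_params)
        if int(mask.sum()) < seed_params.min_cell_area:
            continue
        full_m = np.zeros(shape, dtype=bool)
        full_s = np.zeros(shape, dtype=np.float32)
        full_m[rs, cs] = mask
        full_s[rs, cs] = np.where(mask, score, 0.0)
        masks.append(full_m)
        scores.append(full_s)

    groups = merge_groups(masks, seed_params)
    merged_masks, merged_scores = [], []
    for group in groups:
        mm = masks[group[0]].copy()
        ss = scores[group[0]].copy()
        for i in group[1:]:
            mm |= masks[i]
            np.maximum(ss, scores[i], out=ss)
        merged_masks.append(mm)
        merged_scores.append(ss)
    n_merges = sum(1 for g in groups if len(g) > 1)
    log.info("autoseed: %d watershed regions, %d splits, %d merges",
             coarse.max(), n_splits, n_merges)

    ids = list(range(1, len(merged_masks) + 1))
    labels = distribute_overlaps(merged_masks, merged_scores, labels=ids)
    labels = _enforce_single_component(labels, merged_masks, merged_scores,
                                       ids)

    # drop runts and background pockets, relabel 1..n, keep score alignment
    # (pocket test runs after distribution: only then has a pocket lost its
    # bright crest fringe to the true neighbouring cells)
    is_pocket = _background_pocket_filter(prepped, support_sc,
                                          seed_params.background_band)
    final_masks, final_scores = [], []
    n_pockets = 0
    for i, lid in enumerate(ids):
        m = labels == lid
        if int(m.sum()) < seed_params.min_cell_area:
            continue
        if is_pocket is not None and is_pocket(m):
            n_pockets += 1
            continue
        final_masks.append(m)
        final_scores.append(merged_scores[i])
    if n_pockets:
        log.info("autoseed: rejected %d background pockets", n_pockets)
    out = np.zeros(shape, dtype=np.int32)
    for new_id, m in enumerate(final_masks, start=1):
        out[m] = new_id
    if not final_masks:
        warnings.warn("zero cells found", stacklevel=2)
    return out, final_scores
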