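"""Backwards-in-time segmentation and tracking.

Tracking runs from the last frame toward the first: every cell already
exists in the seed (the segmentation of the adjacent later frame), so a
cell only needs to be followed until it is born — i.e. until it
disappears going backwards.  Each cell is segmented independently on a
subimage around its seed (a pure map over cells; the result is
independent of per-cell execution order), then overlapping claims are
reconciled by score-based distribution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from . import imageprep, seeding, subroutine
from .imageprep import Modality, PrepParams
from .seeding import SeedingParams, _bbox_slices, distribute_overlaps
from .subroutine import SubimageContext, SubroutineParams

log = logging.getLogger(__name__)


@dataclass
class TrackerParams:
    """Birth/loss bookkeeping constants.

    A cell whose segmentation is absent (or below ``min_cell_area``) for
    ``lost_patience`` consecutive backward steps is declared born at the
    last frame it was present.  ``pad`` is the subimage margin and must
    cover the expected one-frame boundary motion.
    """

    min_cell_area: int = 15
    lost_patience: int = 1
    pad: int = 10

    def validate(self) -> None:
        if min(self.min_cell_area, self.lost_patience, self.pad) <= 0:
            raise ValueError("all tracker parameters must be positive")


def segment_frame(image: np.ndarray, prev_labels: np.ndarray,
                  modality: Modality | str,
                  prep_params: PrepParams | None = None,
                  sub_params: SubroutineParams | None = None,
                  params: TrackerParams | None = None,
                  fluor: np.ndarray | None = None,
                  ) -> tuple[np.ndarray, dict[int, np.ndarray]]:
    """Segment one frame, seeding every cell with its mask from the
    adjacent later frame.

    Each label is refined independently on its padded subimage; the claims
    are then reconciled with score-based overlap distribution, which makes
    the result independent of processing order.  A label whose mask
    empties is absent from the output (a candidate birth).

    Returns the label mask and the surviving cells' score maps.
    """
    prep_params = prep_params or PrepParams()
    sub_params = sub_params or SubroutineParams()
    params = params or TrackerParams()
    params.validate()
    prev_labels = np.asarray(prev_labels)
    if image.shape != prev_labels.shape:
        raise ValueError("image/seed shape mismatch")

    ids = [int(v) for v in np.unique(prev_labels) if v != 0]
    shape = image.shape
    if not ids:
        return np.zeros(shape, dtype=np.int32), {}

    prepped = imageprep.prep_frame(image, modality, prep_params, fluor=fluor)
    evidence, support = imageprep.scoring_evidence(prepped, prep_params)

    masks, scores, kept = [], [], []
    for lid in sorted(ids):
        seed_full = prev_labels == lid
        rs, cs = _bbox_slices(seed_full, params.pad, shape)
        ctx = SubimageContext(crop=evidence[rs, cs],
                              origin=(rs.start, cs.start),
                              seed=seed_full[rs, cs], pad=params.pad)
        mask, score = subroutine.iterate(ctx, ctx.crop, sub_params)
        if int(mask.sum()) < params.min_cell_area:
            continue
        full_m = np.zeros(shape, dtype=bool)
        full_s = np.zeros(shape, dtype=np.float32)
        full_m[rs, cs] = mask
        full_s[rs, cs] = np.where(mask, score, 0.0)
        masks.append(full_m)
        scores.append(full_s)
        kept.append(lid)

    if not kept:
        return np.zeros(shape, dtype=np.int32), {}
    labels = distribute_overlaps(masks, scores, labels=kept)
    labels = seeding._enforce_single_component(labels, masks, scores, kept)
    out_scores: dict[int, np.ndarray] = {}
    final = np.zeros(shape, dtype=np.int32)
    for i, lid in enumerate(kept):
        m = labels == lid
        if int(m.sum()) >= params.min_cell_area:
            final[m] = lid
            out_scores[lid] = scores[i]
    return final, out_scores


def _region_stats(labels: np.ndarray, lid: int):
    m = labels == lid
    area = int(m.sum())
    if area == 0:
        return 0, (np.nan, np.nan), (0, 0, 0, 0)
    ys, xs = m.nonzero()
    centroid = (float(ys.mean()), float(xs.mean()))
    bbox = (int(ys.min()), int(xs.min()), int(ys.max()) + 1, int(xs.max()) + 1)
    return area, centroid, bbox


def track_backwards(stack: list[np.ndarray] | np.ndarray, seed: np.ndarray,
                    modality: Modality | str,
                    prep_params: PrepParams | None = None,
                    sub_params: SubroutineParams | None = None,
                    params: TrackerParams | None = None,
                    fluor_stack: np.ndarray | None = None,
                    ) -> tuple[np.ndarray, pd.DataFrame]:
    """Track every seeded cell backwards from the last frame to its birth.

    The segmentation of each time point is used as the seed for the next
    (earlier) one.  Labels persist along a track; a cell absent for
    ``lost_patience`` consecutive backward steps is marked born at the
    last frame it was present and removed from earlier frames.

    Returns the label stack in forward frame order and a track table with
    one row per (frame, cell): frame, label, birth_frame, area,
    centroid_row, centroid_col, status.
    """
    params = params or TrackerParams()
    params.validate()
    stack = [np.asarray(f) for f in stack]
    T = len(stack)
    for t, f in enumerate(stack):
        if f.shape != stack[0].shape:
            raise ValueError(f"frame {t} shape mismatch")
    if seed.shape != stack[0].shape:
        raise ValueError("seed shape does not match the stack")

    labels = np.zeros((T,) + stack[0].shape, dtype=np.int32)
    labels[T - 1] = seed
    all_ids = [int(v) for v in np.unique(seed) if v != 0]
    last_seen = {lid: T - 1 for lid in all_ids}
    missing = {lid: 0 for lid in all_ids}
    birth = {lid: 0 for lid in all_ids}   # refined as cells disappear
    active = set(all_ids)

    for t in range(T - 2, -1, -1):
        if not active:
            break
        # seed with the adjacent later frame; a cell within its patience
        # window is re-seeded from the last frame it was present
        seed_t = np.where(np.isin(labels[t + 1], list(active)),
                          labels[t + 1], 0).astype(np.int32)
        for lid in list(active):
            if missing[lid] > 0:
                prev = labels[last_seen[lid]] == lid
                seed_t[prev & (seed_t == 0)] = lid
        fl = fluor_stack[t] if fluor_stack is not None else None
        labels[t], _ = segment_frame(stack[t], seed_t, modality,
                                     prep_params, sub_params, params,
                                     fluor=fl)
        present = set(int(v) for v in np.unique(labels[t]) if v != 0)
        for lid in list(active):
            if lid in present:
                missing[lid] = 0
                last_seen[lid] = t
            else:
                missing[lid] += 1
                if missing[lid] >= params.lost_patience:
                    birth[lid] = last_seen[lid]
                    active.discard(lid)
        log.debug("frame %d: %d cells present", t, len(present))

    for lid in active:
        birth[lid] = 0

    # scrub any residue before a confirmed birth
    for lid, bf in birth.items():
        if bf > 0:
            pre = labels[:bf] == lid
            labels[:bf][pre] = 0

    rows = []
    for t in range(T):
        for lid in all_ids:
            area, centroid, bbox = _region_stats(labels[t], lid)
            if t < birth[lid]:
                status = "born_after"
            elif area > 0:
                status = "present"
            else:
                status = "lost"
            rows.append((t, lid, birth[lid], area,
                         centroid[0], centroid[1], status))
    table = pd.DataFrame(rows, columns=[
        "frame", "label", "birth_frame", "area",
        "centroid_row", "centroid_col", "status"])
    return labels, table


def _jaccard(a: np.ndarray, b: np.ndarray) -> float:
    union = int(np.count_nonzero(a | b))
    if union == 0:
        return 1.0
    return int(np.count_nonzero(a & b)) / union


def recover_from_perturbation(stack, seed: np.ndarray,
                              perturbed_labels: np.ndarray,
                              modality: Modality | str,
                              prep_params: PrepParams | None = None,
                              sub_params: SubroutineParams | None = None,
                              params: TrackerParams | None = None,
                              jaccard_threshold: float = 0.95,
                              ) -> pd.DataFrame:
    """Re-run backwards tracking from a perturbed seed and score recovery.

    For each cell the perturbed run is compared frame-by-frame against the
    unperturbed reference run; the cell is fully recovered once their
    Jaccard index reaches ``jaccard_threshold``.  Returns one row per
    cell: label, recovered, frames_to_recovery (NaN when never recovered).
    """
    ref, _ = track_backwards(stack, seed, modality, prep_params,
                             sub_params, params)
    pert, _ = track_backwards(stack, perturbed_labels, modality,
                              prep_params, sub_params, params)
    T = ref.shape[0]
    rows = []
    for lid in (int(v) for v in np.unique(seed) if v != 0):
        frames_needed = np.nan
        recovered = False
        for k in range(T):
            t = T - 1 - k
            if _jaccard(ref[t] == lid, pert[t] == lid) >= jaccard_threshold:
                frames_needed = k
                break
        if not np.isnan(frames_needed):
            # recovered for good: still matching at the earliest frame
            recovered = _jaccard(ref[0] == lid,
                                 pert[0] == lid) >= jaccard_threshold
        rows.append((lid, recovered, frames_needed))
    return pd.DataFrame(rows,
                        columns=["label", "recovered", "frames_to_recovery"])
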