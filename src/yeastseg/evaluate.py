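"""Quantitative scoring of segmentation and tracking quality.

Implements the evaluation conventions used throughout the package:

* F-measure ``F = 2C / (R + G)`` over matched elements, where G counts
  ground-truth elements, R algorithm elements, and C correct matches;
* center-based matching of predictions to ground-truth cell centers;
* per-cell error classes: *correct* when more than 95% of the cell's
  area is segmented correctly, *minor* at 90-95%, *major* otherwise;
* percent cell area gain from distributing overlapping segmentations,
  ``100 * (A_with - A_without) / A_with``;
* mean fluorescence on the 2-pixel-thick cell periphery and the percent
  quantification difference ``100 * |Q_with - Q_without| / Q_with``;
* the robustness harnesses: random seed perturbation and inter-frame
  interval experiments.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy import sparse
from scipy.sparse import csgraph
from skimage.morphology import disk

from . import tracker
from .imageprep import Modality, PrepParams
from .subroutine import SubroutineParams
from .tracker import TrackerParams


@dataclass
class EvaluationCounts:
    """Element counts for the F-measure: ground truth G, algorithm R,
    correctly matched C."""

    G: int
    R: int
    C: int

    def __post_init__(self) -> None:
        if not 0 <= self.C <= min(self.G, self.R):
            raise ValueError("need 0 <= C <= min(G, R)")


def f_measure(counts: EvaluationCounts) -> float:
    """F = 2C / (R + G); combines recall C/G and precision C/R."""
    if counts.R + counts.G == 0:
        raise ValueError("F-measure undefined for R + G = 0")
    return 2.0 * counts.C / (counts.R + counts.G)


def label_centroids(labels: np.ndarray) -> dict[int, tuple[float, float]]:
    ids = [int(v) for v in np.unique(labels) if v != 0]
    if not ids:
        return {}
    cents = ndi.center_of_mass(np.ones_like(labels), labels, index=ids)
    return {lid: (float(r), float(c)) for lid, (r, c) in zip(ids, cents)}


def match_by_center(pred: np.ndarray | list[tuple[float, float]],
                    truth_centers: list[tuple[float, float]],
                    d_max: float = 8.0) -> EvaluationCounts:
    """Match predicted centroids to ground-truth centers within ``d_max``
    pixels; each element matches at most once.

    The match is a maximum-cardinality bipartite matching over all
    admissible (distance < d_max) pairs, so C is the best achievable
    count, independent of processing order."""
    if d_max <= 0:
        raise ValueError("d_max must be positive")
    if isinstance(pred, np.ndarray) and pred.ndim == 2 and pred.dtype != object:
        pred_centers = list(label_centroids(pred).values())
    else:
        pred_centers = [tuple(p) for p in pred]
    truth_centers = [tuple(t) for t in truth_centers]
    G, R = len(truth_centers), len(pred_centers)
    if G == 0 or R == 0:
        return EvaluationCounts(G=G, R=R, C=0)
    p = np.asarray(pred_centers, dtype=float)
    t = np.asarray(truth_centers, dtype=float)
    d = np.sqrt(((p[:, None, :] - t[None, :, :]) ** 2).sum(axis=2))
    adm = sparse.csr_matrix((d < d_max).astype(np.int8))
    match = csgraph.maximum_bipartite_matching(adm, perm_type="column")
    C = int((match >= 0).sum())
    return EvaluationCounts(G=G, R=R, C=C)


def correctness_fraction(pred: np.ndarray, truth: np.ndarray) -> float:
    """Symmetric per-cell correctness: the smaller of pixel recall and
    pixel precision, penalizing both omissions and invasions."""
    truth = np.asarray(truth, dtype=bool)
    pred = np.asarray(pred, dtype=bool)
    nt = int(truth.sum())
    if nt == 0:
        raise ValueError("empty ground-truth mask")
    npred = int(pred.sum())
    if npred == 0:
        return 0.0
    inter = int(np.count_nonzero(pred & truth))
    return min(inter / nt, inter / npred)


def classify_error(pred: np.ndarray, truth: np.ndarray) -> str:
    """correct iff over 95% of the cell's area is segmented correctly;
    minor at 90-95%; anything worse (including a lost cell) is major."""
    f = correctness_fraction(pred, truth)
    if f > 0.95:
        return "correct"
    if f >= 0.90:
        return "minor"
    return "major"


def pct_area_gain(area_with: float, area_without: float) -> float:
    """Percent cell area gained by distributing overlapping segmentations
    instead of discarding them: 100 * (A_with - A_without) / A_with."""
    if area_with <= 0:
        raise ValueError("area_with must be positive")
    return 100.0 * (area_with - area_without) / area_with


def periphery_mask(mask: np.ndarray, thickness: int = 2) -> np.ndarray:
    """The ``thickness``-pixel-thick rim of a cell mask: the mask minus
    its erosion by a disk of that radius; the whole mask when the erosion
    leaves nothing."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    interior = ndi.binary_erosion(mask, structure=disk(thickness))
    rim = mask & ~interior
    return rim if rim.any() else mask.copy()


def periphery_mean_intensity(mask: np.ndarray, fluor: np.ndarray,
                             thickness: int = 2) -> float:
    """Mean fluorescence over the cell-periphery rim."""
    rim = periphery_mask(mask, thickness)
    return float(np.asarray(fluor, dtype=np.float64)[rim].mean())


def pct_quant_difference(q_with: float, q_without: float) -> float:
    """100 * |Q_with - Q_without| / Q_with; asymmetric in its arguments
    (normalized by the with-distribution quantification)."""
    if q_with <= 0:
        raise ValueError("q_with must be positive")
    return 100.0 * abs(q_with - q_without) / q_with


def perturb_seed(mask: np.ndarray, fraction: float,
                 rng: np.random.Generator) -> np.ndarray:
    """Remove a contiguous random angular sector of ``fraction`` of the
    mask's area; the remainder stays connected for convex-ish cells.

    Deterministic given the rng state; fraction 0 returns a copy."""
    if not 0.0 <= fraction < 1.0:
        raise ValueError("fraction must be in [0, 1)")
    mask = np.asarray(mask, dtype=bool)
    n = int(mask.sum())
    if n == 0 or fraction == 0.0:
        return mask.copy()
    n_remove = int(round(fraction * n))
    if n_remove == 0:
        return mask.copy()
    ys, xs = mask.nonzero()
    cy, cx = ys.mean(), xs.mean()
    theta = rng.uniform(0.0, 2.0 * np.pi)
    ang = np.arctan2(ys - cy, xs - cx)
    # angular distance to the sector axis, in [0, pi]
    delta = np.abs((ang - theta + np.pi) % (2.0 * np.pi) - np.pi)
    order = np.argsort(delta, kind="stable")
    out = mask.copy()
    out[ys[order[:n_remove]], xs[order[:n_remove]]] = False
    return out


def interval_robustness_experiment(stack, truth_labels: np.ndarray,
                                   intervals: list[int],
                                   modality: Modality | str,
                                   prep_params: PrepParams | None = None,
                                   sub_params: SubroutineParams | None = None,
                                   params: TrackerParams | None = None,
                                   t: int | None = None) -> pd.DataFrame:
    """Seed frame t with its true labels and segment the frame ``delta``
    frames earlier, for each interval; classify every cell present at both
    times with :func:`classify_error`.

    Returns a table: interval, n_cells, frac_correct, frac_minor,
    frac_major.  Intervals exceeding the stack span are skipped with a
    warning; interval 0 scores the seed itself (identity).
    """
    stack = [np.asarray(f) for f in stack]
    truth_labels = np.asarray(truth_labels)
    T = len(stack)
    if t is None:
        t = T - 1
    seed = truth_labels[t]
    rows = []
    for delta in intervals:
        if delta > t:
            warnings.warn(f"interval {delta} exceeds stack span; skipped",
                          stacklevel=2)
            continue
        if delta == 0:
            pred = seed.copy()
        else:
            pred, _ = tracker.segment_frame(stack[t - delta], seed, modality,
                                            prep_params, sub_params, params)
        target = truth_labels[t - delta]
        counts = {"correct": 0, "minor": 0, "major": 0}
        n_cells = 0
        for lid in (int(v) for v in np.unique(seed) if v != 0):
            truth_mask = target == lid
            if not truth_mask.any():
                continue        # not yet born at t - delta
            n_cells += 1
            counts[classify_error(pred == lid, truth_mask)] += 1
        if n_cells == 0:
            continue
        rows.append((delta, n_cells,
                     counts["correct"] / n_cells,
                     counts["minor"] / n_cells,
                     counts["major"] / n_cells))
    return pd.DataFrame(rows, columns=[
        "interval", "n_cells", "frac_correct", "frac_minor", "frac_major"])
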