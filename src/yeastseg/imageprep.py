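"""Raw frame -> coarse colony mask + watershed-ready topography.

Phase-contrast cell boundaries (and interstices between touching cells)
are brighter than both the background and the cell interiors.  The prep
pipeline exploits this: mean/standard-deviation filtering marks contour
pixels, a distance transform of the contour set is negated into a height
map with one basin per cell interior, and shallow spurious minima are
suppressed with an h-minima transform before watershed.

Bright-field frames are first complemented and top-hat filtered so their
thin dark boundary rings become bright, phase-like contour evidence; a
composite blends phase with an inverted cytoplasmic fluorescent channel
to deepen the interior/boundary contrast.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu
from skimage.morphology import disk, reconstruction, white_tophat


class Modality(str, Enum):
    PHASE = "phase"
    BRIGHTFIELD = "brightfield"
    COMPOSITE = "composite"


@dataclass
class PrepParams:
    """Pre-processing constants.

    ``mean_window``/``std_window`` are the (odd) side lengths of the local
    mean and standard-deviation filters, in pixels at a 40X-like scale.
    ``contour_k`` is the threshold multiplier: a pixel is a contour pixel
    when it exceeds the local mean by ``contour_k`` local standard
    deviations (plus a global noise floor); marked components smaller
    than ``min_contour_size`` are dropped as speckle.  ``tophat_radius``
    is the structuring-disk radius of the bright-field top-hat.
    """

    mean_window: int = 7
    std_window: int = 7
    contour_k: float = 1.0
    min_contour_size: int = 4        # px; prune smaller marked components
    tophat_radius: int = 4
    composite_weight: float = 0.5
    min_colony_area: int = 64

    def validate(self) -> None:
        for w in (self.mean_window, self.std_window):
            if w < 3 or w % 2 == 0:
                raise ValueError("filter windows must be odd and >= 3")
        if self.tophat_radius < 1:
            raise ValueError("tophat_radius must be >= 1")
        if not 0.0 <= self.composite_weight <= 1.0:
            raise ValueError("composite_weight must be in [0, 1]")


def _remove_small(mask: np.ndarray, min_area: int) -> np.ndarray:
    # 8-connectivity: thin diagonal bands (halo crests) must stay whole
    lab, n = ndi.label(mask, structure=np.ones((3, 3), dtype=bool))
    if n == 0:
        return mask
    sizes = ndi.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
    keep = np.concatenate(([False], sizes >= min_area))
    return keep[lab]


def _check_image(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2:
        raise ValueError("expected a 2-D grayscale image")
    if not np.isfinite(image).all():
        raise ValueError("image contains non-finite pixels")
    return image


def rescale01(image: np.ndarray) -> np.ndarray:
    """Min-max rescale to [0, 1]; a constant image maps to zeros."""
    image = np.asarray(image, dtype=np.float64)
    lo, hi = float(image.min()), float(image.max())
    if hi <= lo:
        return np.zeros_like(image)
    return (image - lo) / (hi - lo)


def local_mean_std(image: np.ndarray, mean_window: int,
                   std_window: int) -> tuple[np.ndarray, np.ndarray]:
    """Local mean and standard deviation with uniform windows."""
    mean = ndi.uniform_filter(image, size=mean_window, mode="reflect")
    m = ndi.uniform_filter(image, size=std_window, mode="reflect")
    sq = ndi.uniform_filter(image * image, size=std_window, mode="reflect")
    var = np.maximum(sq - m * m, 0.0)
    return mean, np.sqrt(var)


def coarse_cell_mask(image: np.ndarray, params: PrepParams) -> np.ndarray:
    """Coarse cell/background split: colonies are the high-local-variance
    regions (halos, interstices), closed and hole-filled.

    Components smaller than ``min_colony_area`` are removed.  The mask is
    the superset constraint for all downstream labels.
    """
    params.validate()
    image = _check_image(image)
    if min(image.shape) < 64:
        raise ValueError("image must be at least 64x64")
    support = _colony_support(image, params)
    # pull the margin back toward the colony so background leakage stays low
    eroded = ndi.binary_erosion(support, structure=disk(3))
    return _remove_small(eroded, params.min_colony_area)


def _colony_support(image: np.ndarray, params: PrepParams) -> np.ndarray:
    """Filled high-activity regions with their full margin (no erosion);
    the loose superset used to confine tracked labels."""
    image = _check_image(image)
    _, std = local_mean_std(image, params.mean_window, params.std_window)
    if std.max() <= 0:
        return np.zeros(image.shape, dtype=bool)
    thr = threshold_otsu(std)
    noise_floor = 2.0 * float(np.median(std))
    active = std > max(thr, noise_floor)
    closed = ndi.binary_closing(active, structure=disk(2))
    filled = ndi.binary_fill_holes(closed)
    return _remove_small(filled, params.min_colony_area)


def detect_contour_pixels(image: np.ndarray, params: PrepParams,
                          cellmask: np.ndarray | None = None,
                          contour_k: float | None = None) -> np.ndarray:
    """Mark pixels brighter than their local surroundings.

    A pixel is a contour pixel iff
    ``image > local_mean + k * local_std + noise_floor`` where the noise
    floor is the median local standard deviation of the frame; it keeps
    flat noisy regions (cell interiors, background) from firing while
    leaving the strongly textured halo unaffected.  The marked set is
    restricted to a dilation of the coarse colony mask.
    """
    params.validate()
    image = _check_image(image)
    if max(params.mean_window, params.std_window) > min(image.shape):
        raise ValueError("filter window larger than image")
    k = params.contour_k if contour_k is None else contour_k
    mean, std = local_mean_std(image, params.mean_window, params.std_window)
    noise_floor = float(np.median(std))
    marked = image > mean + k * std + noise_floor
    if cellmask is None:
        cellmask = coarse_cell_mask(image, params)
    marked &= ndi.binary_dilation(cellmask, structure=disk(3))
    # single-pixel specks are noise, not contours, and each one would
    # split a watershed basin; real halo crests are long connected bands
    if params.min_contour_size > 1:
        marked = _remove_small(marked, params.min_contour_size)
    return marked


def make_topography(contours: np.ndarray, cellmask: np.ndarray,
                    h: float = 1.0) -> np.ndarray:
    """Negated distance-to-contour height map with one basin per interior.

    The distance to the nearest contour pixel is computed and negated so
    cell interiors become basins; shallow spurious minima (depth <= ``h``
    distance units) are suppressed by an h-minima transform, and the
    background is forced to a plateau above all interior values.
    """
    contours = np.asarray(contours, dtype=bool)
    cellmask = np.asarray(cellmask, dtype=bool)
    if contours.shape != cellmask.shape:
        raise ValueError("shape mismatch")
    if not cellmask.any():
        return np.zeros(contours.shape, dtype=np.float64)
    if contours.any():
        dist = ndi.distance_transform_edt(~contours)
    else:
        dist = np.zeros(contours.shape, dtype=np.float64)
    topo = -dist.astype(np.float64)
    if h > 0:
        topo = reconstruction(topo + h, topo, method="erosion")
    plateau = topo[cellmask].max() + 1.0 if cellmask.any() else 1.0
    topo = np.where(cellmask, topo, plateau)
    return topo


def brightfield_preprocess(image: np.ndarray, params: PrepParams) -> np.ndarray:
    """White top-hat of the complemented bright-field frame.

    The frame is min-max rescaled first (absorbing uneven illumination),
    complemented so dark boundary rings become bright, then top-hat
    filtered with a disk of ``tophat_radius`` so only thin bright features
    survive.  Output is nonnegative, phase-like contour evidence.
    """
    params.validate()
    image = _check_image(image)
    comp = 1.0 - rescale01(image)
    return white_tophat(comp, disk(params.tophat_radius))


def make_composite(phase: np.ndarray, fluor: np.ndarray,
                   w: float) -> np.ndarray:
    """Blend phase with the inverted fluorescent channel.

    ``composite = (1-w) * norm(phase) + w * (1 - norm(fluor))``: the
    cytoplasmic signal darkens interiors so the halo stays relatively
    bright, raising the interior/boundary contrast without a dedicated
    segmentation channel.
    """
    phase = _check_image(phase)
    fluor = _check_image(fluor)
    if phase.shape != fluor.shape:
        raise ValueError("phase/fluor shape mismatch")
    if not 0.0 <= w <= 1.0:
        raise ValueError("w must be in [0, 1]")
    return (1.0 - w) * rescale01(phase) + w * (1.0 - rescale01(fluor))


def prep_frame(image: np.ndarray, modality: Modality | str,
               params: PrepParams,
               fluor: np.ndarray | None = None) -> np.ndarray:
    """Modality dispatch: return the contour-evidence-bright prepped frame."""
    modality = Modality(modality)
    if modality is Modality.PHASE:
        return _check_image(image)
    if modality is Modality.BRIGHTFIELD:
        return brightfield_preprocess(image, params)
    if fluor is None:
        raise ValueError("composite modality requires a fluorescent channel")
    return make_composite(image, fluor, params.composite_weight)


def contour_evidence(prepped: np.ndarray,
                     cellmask: np.ndarray | None = None) -> np.ndarray:
    """Robust [0, 1] rescale of a prepped frame for the scoring subroutine.

    Percentile-based so stray extrema do not compress the halo range; the
    percentiles are taken over the colony region when a mask is given.
    A light Gaussian blur (sigma 0.5 px) suppresses single-pixel noise
    dips in the halo crest that the path-barrier scoring is sensitive to.
    """
    prepped = ndi.gaussian_filter(_check_image(prepped), 0.5)
    region = prepped[cellmask] if cellmask is not None and cellmask.any() \
        else prepped
    lo = float(np.percentile(region, 1.0))
    hi = float(np.percentile(region, 99.9))
    if hi <= lo:
        return np.zeros_like(prepped)
    return np.clip((prepped - lo) / (hi - lo), 0.0, 1.0)


def scoring_evidence(prepped: np.ndarray,
                     params: PrepParams) -> tuple[np.ndarray, np.ndarray]:
    """Evidence image for the scoring subroutine plus the colony support.

    Outside the colony support the evidence saturates to 1: non-colony
    pixels can never look cell-like, so a seed stranded in background
    (a bud followed past its birth) scores below threshold and is lost
    instead of persisting as a phantom.
    """
    support = _colony_support(prepped, params)
    evid = contour_evidence(prepped, support if support.any() else None)
    if support.any():
        # trim the activity margin back to the colony proper: the 2-3 px
        # band outside the halo crest is background and must not offer a
        # home to stranded seeds
        core = ndi.binary_erosion(support, structure=disk(2))
        evid = np.where(core, evid, 1.0)
        return evid, core
    return evid, support
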