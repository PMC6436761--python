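"""Seeded synthetic yeast-colony time-lapses with ground truth.

Emulates the imaging regimes the segmentation pipeline is built for:
elliptical cells with bright phase halos at their boundaries and darker
interiors, dense colonies with touching cells, exponential growth with
budding (doubling time ~90 min in glucose), low-contrast unevenly
illuminated bright-field rendering, and a partially cytoplasmic
fluorescent channel.  Every render is a deterministic function of the
scene parameters and the rng seed.

The generator is deliberately geometric, not optical: there is no
point-spread-function model, and irregular morphologies are approximated
by low-order Fourier perturbation of the ellipse radius.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi


@dataclass
class SceneParams:
    """Parameters of a synthetic colony scene.

    Intensities are arbitrary units on a [0, 1]-ish scale; lengths are
    pixels at a 40X-like magnification (cell radii ~8-15 px); times are
    minutes.
    """

    n_initial_cells: int = 10
    frames: int = 10
    frame_interval: float = 3.0       # min between frames
    doubling_time: float = 90.0       # min; budding yeast in glucose
    cell_radius_range: tuple[float, float] = (8.0, 15.0)   # initial radii, px
    bud_radius: float = 2.2           # radius of a bud at its birth frame, px
    bud_doubling: float = 15.0        # min; fast early growth of a new bud
    halo_width: float = 2.0           # 2*sigma of the halo cross-section, px
    halo_gain: float = 0.25           # phase halo peak above background, a.u.
    interior_level: float = 0.35      # phase cell interior, a.u.
    background_level: float = 0.5     # phase background, a.u.
    noise_sigma: float = 0.02         # additive Gaussian noise, a.u.
    illumination_gradient: float = 0.0005  # bright-field shading, a.u./px
    bud_rate: float = 0.46            # budding events / cell / hour
    max_step: float = 1.0             # px; cap on per-frame cell movement
    frame_shape: tuple[int, int] = (256, 256)
    aspect_range: tuple[float, float] = (1.0, 1.25)  # ellipse axis ratio
    irregularity: float = 0.0         # Fourier boundary perturbation amplitude
    fluor_interior: float = 0.8       # fluorescent channel interior mean, a.u.
    fluor_background: float = 0.002
    fluor_jitter: float = 0.2         # per-cell relative intensity spread
    rng_seed: int = 0

    def validate(self) -> None:
        if self.frames < 1:
            raise ValueError("frames must be >= 1")
        if min(self.cell_radius_range) <= 0 or self.bud_radius <= 0:
            raise ValueError("radii must be positive")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")


@dataclass
class GroundTruth:
    """Per-frame true label masks plus the budding lineage.

    ``labels`` has shape (frames, H, W); 0 is background, labels are
    persistent across frames.  ``lineage`` has one row per cell:
    (label, mother, birth_frame); initial cells carry mother 0.
    """

    labels: np.ndarray
    lineage: pd.DataFrame
    params: SceneParams

    @property
    def n_frames(self) -> int:
        return self.labels.shape[0]

    def halo_mask(self, frame: int) -> np.ndarray:
        """True boundary-crest pixels of the given frame."""
        return boundary_pixels(self.labels[frame])


@dataclass
class SyntheticScene:
    """A fully rendered scene: ground truth plus all three channels."""

    truth: GroundTruth
    phase: np.ndarray
    brightfield: np.ndarray
    fluor: np.ndarray


@dataclass
class _Cell:
    label: int
    mother: int
    birth_frame: int
    row: float
    col: float
    birth_area: float
    adult_area: float      # fast bud growth ends here; equals birth_area
                           # for cells present from frame 0
    aspect: float
    phi: float
    fourier: np.ndarray    # (n_harmonics, 2): amplitude, phase


def boundary_pixels(label_img: np.ndarray) -> np.ndarray:
    """Cell pixels 4-adjacent to a pixel with a different value.

    This is the set the phase halo crests on: the outermost pixel row of
    every cell, which at cell-cell contacts forms a two-pixel band shared
    by the touching cells (the fused-halo false boundary).
    """
    lab = label_img
    b = np.zeros(lab.shape, dtype=bool)
    b[:-1] |= lab[:-1] != lab[1:]
    b[1:] |= lab[1:] != lab[:-1]
    b[:, :-1] |= lab[:, :-1] != lab[:, 1:]
    b[:, 1:] |= lab[:, 1:] != lab[:, :-1]
    # frame edges count as "different" so border-touching cells stay closed
    b[0] = b[-1] = True
    b[:, 0] = b[:, -1] = True
    return b & (lab > 0)


def _growth_factor(params: SceneParams, dt_frames: int) -> float:
    minutes = dt_frames * params.frame_interval
    return 2.0 ** (minutes / params.doubling_time)


def _area_at(cell: _Cell, frame: int, params: SceneParams) -> float:
    """Exponential growth; new buds grow fast (bud_doubling) until they
    reach their adult area, then settle to the colony doubling time."""
    if frame < cell.birth_frame:
        return 0.0
    minutes = (frame - cell.birth_frame) * params.frame_interval
    if cell.adult_area <= cell.birth_area:
        return cell.birth_area * 2.0 ** (minutes / params.doubling_time)
    fast = cell.birth_area * 2.0 ** (minutes / params.bud_doubling)
    if fast < cell.adult_area:
        return fast
    t_cross = params.bud_doubling * np.log2(cell.adult_area / cell.birth_area)
    return cell.adult_area * 2.0 ** ((minutes - t_cross)
                                     / params.doubling_time)


def _effective_radius(area: float) -> float:
    return float(np.sqrt(area / np.pi))


def _relax_overlaps(cells: list[_Cell], areas: dict[int, float],
                    shape: tuple[int, int], n_iter: int = 60) -> None:
    """Pairwise centroid repulsion: colonies spread out laterally.

    Cells are treated as circles of their effective radius; overlapping
    pairs are pushed apart along the center line until (near) contact.
    """
    margin = 4.0
    radii = {c.label: _effective_radius(areas[c.label]) for c in cells}
    for _ in range(n_iter):
        moved = 0.0
        for i in range(len(cells)):
            for j in range(i + 1, len(cells)):
                a, b = cells[i], cells[j]
                ra, rb = radii[a.label], radii[b.label]
                dr, dc = b.row - a.row, b.col - a.col
                d = float(np.hypot(dr, dc))
                if d < 1e-6:
                    dr, dc, d = 1.0, 0.0, 1.0
                overlap = (ra + rb) - d
                if overlap > 0.05:
                    ur, uc = dr / d, dc / d
                    shift = overlap / 2.0
                    a.row -= ur * shift
                    a.col -= uc * shift
                    b.row += ur * shift
                    b.col += uc * shift
                    moved = max(moved, overlap)
        for c in cells:
            r = radii[c.label]
            c.row = float(np.clip(c.row, r + margin, shape[0] - 1 - r - margin))
            c.col = float(np.clip(c.col, r + margin, shape[1] - 1 - r - margin))
        if moved < 0.1:
            break


def _rasterize(cells: list[_Cell], areas: dict[int, float],
               shape: tuple[int, int], irregularity: float) -> np.ndarray:
    """Paint ellipses; disputed pixels go to the nearest cell in normalized
    ellipse distance, so true labels never overlap."""
    labels = np.zeros(shape, dtype=np.uint16)
    best = np.full(shape, np.inf, dtype=np.float64)
    for c in cells:
        area = areas[c.label]
        if area <= 0:
            continue
        a = np.sqrt(area * c.aspect / np.pi)   # semi-major
        b = a / c.aspect                       # semi-minor
        rmax = a * (1 + irregularity) + 1.5
        r0 = max(int(np.floor(c.row - rmax)), 0)
        r1 = min(int(np.ceil(c.row + rmax)) + 1, shape[0])
        c0 = max(int(np.floor(c.col - rmax)), 0)
        c1 = min(int(np.ceil(c.col + rmax)) + 1, shape[1])
        if r0 >= r1 or c0 >= c1:
            continue
        rr, cc = np.mgrid[r0:r1, c0:c1]
        dr = rr - c.row
        dc = cc - c.col
        cp, sp = np.cos(c.phi), np.sin(c.phi)
        u = (dr * cp + dc * sp) / a
        v = (-dr * sp + dc * cp) / b
        d = np.sqrt(u * u + v * v)
        if irregularity > 0:
            theta = np.arctan2(v, u)
            rho = np.ones_like(d)
            for k, (amp, ph) in enumerate(c.fourier, start=2):
                rho += amp * np.cos(k * theta + ph)
            d = d / np.maximum(rho, 0.5)
        sub_best = best[r0:r1, c0:c1]
        inside = (d <= 1.0) & (d < sub_best)
        sub_best[inside] = d[inside]
        labels[r0:r1, c0:c1][inside] = c.label
    return labels


def simulate_geometry(params: SceneParams) -> GroundTruth:
    """Simulate colony geometry: exponential growth, budding, lateral spread.

    Cells are ellipses whose area grows exponentially with the stated
    doubling time.  Buds appear adjacent to their mothers at ``bud_rate``
    and grow from ``bud_radius``.  Overlaps are resolved each frame by
    pairwise centroid repulsion.
    """
    params.validate()
    rng = np.random.default_rng([params.rng_seed, 0])
    shape = params.frame_shape
    cells: list[_Cell] = []
    next_label = 1

    def new_fourier() -> np.ndarray:
        amp = params.irregularity
        return np.column_stack([
            rng.uniform(0, amp, size=3),
            rng.uniform(0, 2 * np.pi, size=3),
        ])

    # place initial cells near the frame center in a loose spiral
    center = np.array(shape, dtype=float) / 2.0
    for i in range(params.n_initial_cells):
        r = rng.uniform(*params.cell_radius_range)
        spread = 2.2 * max(params.cell_radius_range) * np.sqrt(
            max(params.n_initial_cells, 1))
        pos = center + rng.uniform(-spread, spread, size=2)
        cells.append(_Cell(
            label=next_label, mother=0, birth_frame=0,
            row=float(pos[0]), col=float(pos[1]),
            birth_area=float(np.pi * r * r),
            adult_area=float(np.pi * r * r),
            aspect=float(rng.uniform(*params.aspect_range)),
            phi=float(rng.uniform(0, np.pi)),
            fourier=new_fourier(),
        ))
        next_label += 1

    bud_prob = params.bud_rate * params.frame_interval / 60.0
    frames_labels = np.zeros((params.frames,) + shape, dtype=np.uint16)
    crowded = False

    for t in range(params.frames):
        if t > 0 and not crowded:
            # budding events
            for mother in list(cells):
                if mother.birth_frame > t - 1:
                    continue
                if rng.uniform() >= bud_prob:
                    continue
                ang = rng.uniform(0, 2 * np.pi)
                m_area = _area_at(mother, t, params)
                rm = _effective_radius(m_area)
                rb = params.bud_radius
                r_adult = rng.uniform(*params.cell_radius_range) * 0.8
                cells.append(_Cell(
                    label=next_label, mother=mother.label, birth_frame=t,
                    row=mother.row + (rm + rb) * np.cos(ang),
                    col=mother.col + (rm + rb) * np.sin(ang),
                    birth_area=float(np.pi * rb * rb),
                    adult_area=float(np.pi * r_adult * r_adult),
                    aspect=float(rng.uniform(*params.aspect_range)),
                    phi=float(rng.uniform(0, np.pi)),
                    fourier=new_fourier(),
                ))
                next_label += 1

        areas = {c.label: _area_at(c, t, params) for c in cells}
        live = [c for c in cells if areas[c.label] > 0]
        total_r = np.sqrt(sum(areas[c.label] for c in live) / np.pi)
        if total_r > 0.42 * min(shape) and not crowded:
            crowded = True
            warnings.warn("colony approaching frame bounds; no further buds",
                          stacklevel=2)
        before = {c.label: (c.row, c.col) for c in live}
        _relax_overlaps(live, areas, shape)
        if t > 0:
            # colonies spread slowly: cap per-frame movement so inter-frame
            # drift stays in the moderate regime the tracker is built for
            # (residual overlaps are split per-pixel at rasterization)
            for c in live:
                if c.birth_frame == t:
                    continue
                r0, c0 = before[c.label]
                dr, dc = c.row - r0, c.col - c0
                step = float(np.hypot(dr, dc))
                if step > params.max_step:
                    f = params.max_step / step
                    c.row = r0 + dr * f
                    c.col = c0 + dc * f
        frames_labels[t] = _rasterize(live, areas, shape, params.irregularity)

    lineage = pd.DataFrame(
        [(c.label, c.mother, c.birth_frame) for c in cells],
        columns=["label", "mother", "birth_frame"],
    )
    return GroundTruth(labels=frames_labels, lineage=lineage, params=params)


def _noise(shape, sigma, rng):
    if sigma <= 0:
        return 0.0
    return rng.normal(0.0, sigma, size=shape)


def render_phase(truth: GroundTruth, params: SceneParams) -> np.ndarray:
    """Phase-contrast render: dark interiors, bright halo crest on the cell
    boundary set.  Touching cells share a fused two-pixel halo band."""
    rng = np.random.default_rng([params.rng_seed, 1])
    sigma = params.halo_width / 2.0
    peak = params.background_level + params.halo_gain
    out = np.empty(truth.labels.shape, dtype=np.float64)
    for t in range(truth.n_frames):
        lab = truth.labels[t]
        base = np.where(lab > 0, params.interior_level, params.background_level)
        crest = boundary_pixels(lab)
        if crest.any():
            d = ndi.distance_transform_edt(~crest)
            halo = peak * np.exp(-(d * d) / (2 * sigma * sigma))
            frame = np.maximum(base, halo)
        else:
            frame = base
        out[t] = frame + _noise(lab.shape, params.noise_sigma, rng)
    return out


def render_brightfield(truth: GroundTruth, params: SceneParams) -> np.ndarray:
    """Bright-field render: thin dark boundary rings on a background-level
    interior, linear illumination gradient, lower contrast than phase."""
    rng = np.random.default_rng([params.rng_seed, 2])
    sigma = params.halo_width / 2.0
    drop = 0.5 * params.halo_gain
    out = np.empty(truth.labels.shape, dtype=np.float64)
    H, W = truth.labels.shape[1:]
    cols = np.arange(W, dtype=np.float64)[None, :]
    shading = params.illumination_gradient * (cols - W / 2.0)
    for t in range(truth.n_frames):
        lab = truth.labels[t]
        base = np.full(lab.shape, params.background_level)
        crest = boundary_pixels(lab)
        if crest.any():
            d = ndi.distance_transform_edt(~crest)
            base = base - drop * np.exp(-(d * d) / (2 * sigma * sigma))
        out[t] = base + shading + _noise(lab.shape, params.noise_sigma, rng)
    return out


def render_fluor(truth: GroundTruth, params: SceneParams) -> np.ndarray:
    """Partially cytoplasmic fluorescent channel: bright interiors with
    per-cell intensity jitter, dark background."""
    rng = np.random.default_rng([params.rng_seed, 3])
    out = np.empty(truth.labels.shape, dtype=np.float64)
    max_label = int(truth.labels.max())
    gains = params.fluor_interior * (
        1.0 + params.fluor_jitter * rng.uniform(-1, 1, size=max_label + 1))
    gains[0] = params.fluor_background
    for t in range(truth.n_frames):
        lab = truth.labels[t]
        out[t] = gains[lab] + _noise(lab.shape, params.noise_sigma, rng)
    return out


def generate_scene(params: SceneParams) -> SyntheticScene:
    """Simulate geometry and render all three channels."""
    truth = simulate_geometry(params)
    return SyntheticScene(
        truth=truth,
        phase=render_phase(truth, params),
        brightfield=render_brightfield(truth, params),
        fluor=render_fluor(truth, params),
    )
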