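"""Seeding: watershed vs flooding oracle, vote splitting, merging,
overlap distribution, and the full autoseed pipeline."""

import heapq
import itertools

import numpy as np
import pytest
from scipy import ndimage as ndi

from yeastseg import imageprep, seeding, synthgen
from yeastseg.imageprep import PrepParams
from yeastseg.seeding import (SeedingParams, autoseed, distribute_overlaps,
                              merge_oversegmented, split_undersegmented,
                              watershed_partition)
from yeastseg.subroutine import SubimageContext, SubroutineParams
from conftest import jaccard


def flood_oracle(topo: np.ndarray, cellmask: np.ndarray) -> np.ndarray:
    """Independent priority-flood watershed: seed every regional-minimum
    plateau (8-connected plateaus, as regional minima are defined), then
    grow basins in increasing height order with 4-connectivity."""
    H, W = topo.shape
    labels = np.zeros((H, W), dtype=np.int32)
    # regional minima plateaus within the mask
    visited = np.zeros((H, W), dtype=bool)
    nlab = 0
    neigh8 = [(dy, dx) for dy in (-1, 0, 1) for dx in (-1, 0, 1)
              if (dy, dx) != (0, 0)]
    for sy in range(H):
        for sx in range(W):
            if visited[sy, sx] or not cellmask[sy, sx]:
                continue
            v = topo[sy, sx]
            stack, plateau, is_min = [(sy, sx)], [], True
            visited[sy, sx] = True
            while stack:
                y, x = stack.pop()
                plateau.append((y, x))
                for dy, dx in neigh8:
                    ny, nx = y + dy, x + dx
                    if not (0 <= ny < H and 0 <= nx < W):
                        continue
                    if topo[ny, nx] == v:
                        if not visited[ny, nx] and cellmask[ny, nx]:
                            visited[ny, nx] = True
                            stack.append((ny, nx))
                    elif topo[ny, nx] < v:
                        is_min = False
            if is_min:
                nlab += 1
                for y, x in plateau:
                    labels[y, x] = nlab
    if nlab == 0:
        return labels
    heap = []
    counter = itertools.count()
    for y, x in zip(*np.nonzero(labels)):
        heapq.heappush(heap, (topo[y, x], next(counter), y, x))
    while heap:
        _, _, y, x = heapq.heappop(heap)
        for dy, dx in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            ny, nx = y + dy, x + dx
            if not (0 <= ny < H and 0 <= nx < W):
                continue
            if cellmask[ny, nx] and labels[ny, nx] == 0:
                labels[ny, nx] = labels[y, x]
                heapq.heappush(heap, (topo[ny, nx], next(counter), ny, nx))
    return labels


def _match_partitions(a: np.ndarray, b: np.ndarray) -> dict:
    """Greedy bijection between the labels of two partitions."""
    mapping = {}
    for la in np.unique(a):
        if la == 0:
            continue
        vals, counts = np.unique(b[a == la], return_counts=True)
        mapping[la] = vals[np.argmax(counts)]
    return mapping


class TestWatershedPartition:
    def _pit_topography(self, centers, shape=(28, 28)):
        yy, xx = np.mgrid[:shape[0], :shape[1]]
        topo = np.full(shape, 10.0)
        for cy, cx in centers:
            d = np.sqrt((yy - cy) ** 2 + (xx - cx) ** 2)
            topo = np.minimum(topo, d)
        return topo

    def test_two_basins_match_flooding_oracle(self):
        topo = self._pit_topography([(8, 8), (20, 20)])
        cellmask = np.ones(topo.shape, bool)
        ws = watershed_partition(topo, cellmask)
        oracle = flood_oracle(topo, cellmask)
        assert len(np.unique(ws)) == len(np.unique(oracle)) == 2
        m = _match_partitions(oracle, ws)
        # exact agreement away from the inter-basin ridge of the oracle
        ridge = np.zeros(topo.shape, bool)
        o = oracle
        ridge[:-1] |= o[:-1] != o[1:]
        ridge[1:] |= o[1:] != o[:-1]
        ridge[:, :-1] |= o[:, :-1] != o[:, 1:]
        ridge[:, 1:] |= o[:, 1:] != o[:, :-1]
        interior = ~ridge
        for la, lb in m.items():
            assert np.array_equal((oracle == la) & interior,
                                  (ws == lb) & interior)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_random_topographies_match_oracle(self, seed):
        rng = np.random.default_rng(seed)
        topo = ndi.gaussian_filter(rng.normal(size=(24, 24)), 3)
        # unique values: no plateaus, so the flooding order is well defined
        topo = topo + np.arange(topo.size).reshape(topo.shape) * 1e-9
        cellmask = np.ones(topo.shape, bool)
        ws = watershed_partition(topo, cellmask)
        oracle = flood_oracle(topo, cellmask)
        assert len(np.unique(ws)) == len(np.unique(oracle))
        ridge = np.zeros(topo.shape, bool)
        o = oracle
        ridge[:-1] |= o[:-1] != o[1:]
        ridge[1:] |= o[1:] != o[:-1]
        ridge[:, :-1] |= o[:, :-1] != o[:, 1:]
        ridge[:, 1:] |= o[:, 1:] != o[:, :-1]
        m = _match_partitions(oracle, ws)
        assert len(set(m.values())) == len(m)          # bijective
        for la, lb in m.items():
            assert np.array_equal((oracle == la) & ~ridge,
                                  (ws == lb) & ~ridge)

    def test_single_basin_covers_mask(self):
        topo = self._pit_topography([(14, 14)])
        cellmask = np.zeros(topo.shape, bool)
        cellmask[4:24, 4:24] = True
        ws = watershed_partition(topo, cellmask)
        assert (ws[cellmask] == 1).all()
        assert (ws[~cellmask] == 0).all()

    def test_labels_partition_cellmask(self, small_scene):
        t = small_scene.truth.n_frames - 1
        params = PrepParams()
        frame = small_scene.phase[t]
        cellmask = imageprep.coarse_cell_mask(frame, params)
        contours = imageprep.detect_contour_pixels(frame, params, cellmask)
        topo = imageprep.make_topography(contours, cellmask)
        ws = watershed_partition(topo, cellmask)
        assert (ws[cellmask] > 0).all()
        assert (ws[~cellmask] == 0).all()

    def test_empty_mask_empty_labels(self):
        ws = watershed_partition(np.zeros((16, 16)),
                                 np.zeros((16, 16), bool))
        assert not ws.any()


class TestSplitUndersegmented:
    def _touching_pair_region(self):
        p = synthgen.SceneParams(n_initial_cells=2, frames=4,
                                 noise_sigma=0.015,
                                 cell_radius_range=(9.0, 11.0), bud_rate=0.0,
                                 frame_shape=(128, 128), rng_seed=2)
        scene = synthgen.generate_scene(p)
        lab = scene.truth.labels[-1]
        m1, m2 = lab == 1, lab == 2
        if not (ndi.binary_dilation(m1) & m2).any():
            pytest.skip("pair not touching in this geometry")
        return scene, lab

    def test_two_touching_cells_split(self):
        scene, lab = self._touching_pair_region()
        region = lab > 0
        rs = ndi.find_objects(region.astype(int))[0]
        pad = 8
        rsl = (slice(max(rs[0].start - pad, 0), rs[0].stop + pad),
               slice(max(rs[1].start - pad, 0), rs[1].stop + pad))
        ctx = SubimageContext(crop=scene.phase[-1][rsl], origin=(0, 0),
                              seed=region[rsl])
        pieces = split_undersegmented(ctx, SeedingParams(), PrepParams())
        assert len(pieces) == 2
        # each piece belongs to one true cell
        for piece in pieces:
            owners = np.unique(lab[rsl][piece])
            owners = owners[owners != 0]
            assert len(owners) == 1

    def test_single_cell_not_split(self, small_scene):
        lab = small_scene.truth.labels[-1]
        # pick an isolated cell
        for lid in np.unique(lab)[1:]:
            m = lab == lid
            others = (lab > 0) & ~m
            if not (ndi.binary_dilation(m, iterations=3) & others).any():
                break
        else:
            pytest.skip("no isolated cell")
        rs = ndi.find_objects(m.astype(int))[0]
        rsl = (slice(max(rs[0].start - 8, 0), rs[0].stop + 8),
               slice(max(rs[1].start - 8, 0), rs[1].stop + 8))
        ctx = SubimageContext(crop=small_scene.phase[-1][rsl], origin=(0, 0),
                              seed=m[rsl])
        pieces = split_undersegmented(ctx, SeedingParams(), PrepParams())
        assert len(pieces) == 1
        assert abs(int(pieces[0].sum()) - int(m.sum())) <= 0.05 * m.sum()

    def test_unanimous_votes_equal_single_threshold(self):
        rng = np.random.default_rng(3)
        crop = ndi.gaussian_filter(rng.uniform(size=(48, 48)), 2)
        seed = np.zeros((48, 48), bool)
        seed[10:38, 10:38] = True
        params = SeedingParams(vote_thresholds=(1.0, 1.0, 1.0),
                               vote_majority=3)
        pieces = split_undersegmented(
            SubimageContext(crop, (0, 0), seed), params, PrepParams())
        contours = imageprep.detect_contour_pixels(
            crop, PrepParams(), cellmask=ndi.binary_dilation(seed,
                                                             iterations=2),
            contour_k=1.0)
        voted = seed & ~contours
        union = np.zeros_like(seed)
        for piece in pieces:
            union |= piece
        # unanimity: pieces reproduce the single-threshold mask (or the
        # region itself when no split resulted)
        if len(pieces) > 1:
            lab, _ = ndi.label(voted)
            keep = np.zeros_like(seed)
            for i in range(1, lab.max() + 1):
                if (lab == i).sum() >= max(4, params.min_cell_area // 3):
                    keep |= lab == i
            assert np.array_equal(union, keep)
        else:
            assert np.array_equal(union, seed)


class TestMergeOversegmented:
    def test_fragments_of_one_cell_merge(self, small_scene):
        """Two converged halves of one cell overlap heavily after
        iteration and merge into one mask matching the cell."""
        from yeastseg.subroutine import iterate
        lab = small_scene.truth.labels[-1]
        params = imageprep.PrepParams()
        prepped = imageprep.prep_frame(small_scene.phase[-1], "phase", params)
        evidence, _ = imageprep.scoring_evidence(prepped, params)
        lid = max(np.unique(lab)[1:],
                  key=lambda v: (lab == v).sum())
        m = lab == lid
        rs = ndi.find_objects(m.astype(int))[0]
        rsl = (slice(max(rs[0].start - 10, 0), rs[0].stop + 10),
               slice(max(rs[1].start - 10, 0), rs[1].stop + 10))
        seedc = m[rsl]
        crop = evidence[rsl]
        cols = np.nonzero(seedc.any(axis=0))[0]
        mid = (cols[0] + cols[-1]) // 2
        left, right = seedc.copy(), seedc.copy()
        left[:, mid:] = False
        right[:, :mid] = False
        sp = SubroutineParams()
        ml, _ = iterate(SubimageContext(crop, (0, 0), left), crop, sp)
        mr, _ = iterate(SubimageContext(crop, (0, 0), right), crop, sp)
        merged = merge_oversegmented([ml, mr], SeedingParams())
        assert len(merged) == 1
        assert jaccard(merged[0], seedc) >= 0.9

    def test_distinct_adjacent_cells_not_merged(self):
        a = np.zeros((32, 32), bool)
        b = np.zeros((32, 32), bool)
        a[8:24, 4:16] = True
        b[8:24, 15:27] = True   # 1-column overlap, far below theta
        merged = merge_oversegmented([a, b], SeedingParams())
        assert len(merged) == 2

    def test_theta_one_no_merge_without_identity(self):
        a = np.zeros((16, 16), bool)
        b = np.zeros((16, 16), bool)
        a[2:10, 2:10] = True
        b[4:12, 4:12] = True
        params = SeedingParams(merge_overlap_theta=1.0)
        assert len(merge_oversegmented([a, b], params)) == 2


class TestDistributeOverlaps:
    def test_disputed_pixel_goes_to_higher_score(self):
        m = np.zeros((8, 8), bool)
        m[2:6, 2:6] = True
        s1 = np.full((8, 8), 0.8)
        s2 = np.full((8, 8), 0.3)
        out = distribute_overlaps([m, m.copy()], [s1, s2])
        assert (out[m] == 1).all()

    def test_disjoint_masks_identity(self):
        a = np.zeros((8, 8), bool)
        b = np.zeros((8, 8), bool)
        a[:4] = True
        b[6:] = True
        out = distribute_overlaps([a, b], [np.ones((8, 8)), np.ones((8, 8))])
        assert (out[a] == 1).all() and (out[b] == 2).all()
        assert (out[~a & ~b] == 0).all()

    def test_zero_score_tie_breaks_to_lower_label(self):
        m = np.zeros((6, 6), bool)
        m[1:4, 1:4] = True
        out = distribute_overlaps([m, m.copy()],
                                  [np.zeros((6, 6)), np.zeros((6, 6))])
        assert (out[m] == 1).all()

    @pytest.mark.parametrize("trial", range(10))
    def test_equivalence_with_pixel_argmax_oracle(self, trial):
        rng = np.random.default_rng(trial)
        shape = (rng.integers(8, 20), rng.integers(8, 20))
        n = int(rng.integers(2, 5))
        masks = [rng.random(shape) < 0.5 for _ in range(n)]
        scores = [np.where(m, rng.random(shape), 0.0)
                  for m in masks]
        out = distribute_overlaps(masks, scores)
        for y in range(shape[0]):
            for x in range(shape[1]):
                claim = [i for i in range(n) if masks[i][y, x]]
                if not claim:
                    assert out[y, x] == 0
                else:
                    best = max(claim, key=lambda i: (scores[i][y, x], -i))
                    assert out[y, x] == best + 1

    def test_pixel_conservation(self):
        rng = np.random.default_rng(9)
        masks = [rng.random((15, 15)) < 0.4 for _ in range(4)]
        scores = [np.where(m, rng.random((15, 15)), 0) for m in masks]
        out = distribute_overlaps(masks, scores)
        union = np.zeros((15, 15), bool)
        for m in masks:
            union |= m
        assert np.array_equal(out > 0, union)


class TestAutoseed:
    def test_dense_colony_segmented(self, dense_scene):
        truth = dense_scene.truth
        t = truth.n_frames - 1
        labels, scores = autoseed(dense_scene.phase[t], "phase")
        assert labels.max() == len(scores)
        ids = np.unique(truth.labels[t])
        good = 0
        for lid in ids[ids != 0]:
            tm = truth.labels[t] == lid
            over = np.bincount(labels[tm].ravel())
            best = 0.0
            for pid in np.nonzero(over)[0]:
                if pid:
                    best = max(best, jaccard(labels == pid, tm))
            good += best >= 0.90
        assert good / (len(ids) - 1) >= 0.95

    def test_blank_frame_empty(self):
        frame = np.full((96, 96), 0.5)
        with pytest.warns(UserWarning):
            labels, scores = autoseed(frame, "phase")
        assert not labels.any() and scores == []

    def test_deterministic(self, small_scene):
        t = small_scene.truth.n_frames - 1
        a, _ = autoseed(small_scene.phase[t], "phase")
        b, _ = autoseed(small_scene.phase[t], "phase")
        assert np.array_equal(a, b)

    def test_labels_disjoint_single_component(self, small_scene):
        t = small_scene.truth.n_frames - 1
        labels, _ = autoseed(small_scene.phase[t], "phase")
        for lid in np.unique(labels)[1:]:
            _, n = ndi.label(labels == lid)
            assert n == 1
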