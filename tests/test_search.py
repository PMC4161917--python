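"""Coarse cascade, fine ranking and mean-shift fusion."""

import math

import numpy as np
import pytest

import hahsearch as hs
from hahsearch.features import build_ring_partition, hah_fine
from hahsearch.geometry import PatchWindow, QueryPatch
from hahsearch.search import (
    RankedCandidates,
    SearchConfig,
    coarse_cascade,
    fine_rank,
    mean_shift_bandwidth,
    mean_shift_cluster,
    run_search,
)

from conftest import make_two_tone_patch


def tile_image(patches, cols):
    """Lay equally-sized patches on a grid; returns (image, windows)."""
    size = patches[0].shape[0]
    rows = math.ceil(len(patches) / cols)
    img = np.zeros((rows * size, cols * size, 3), dtype=np.uint8)
    windows = []
    for k, p in enumerate(patches):
        r, c = divmod(k, cols)
        img[r * size : (r + 1) * size, c * size : (c + 1) * size] = p
        windows.append(PatchWindow(r * size, c * size, size, size))
    return img, windows


@pytest.fixture()
def tiled_scene(rng):
    """A query patch tiled with 1 exact copy, 4 near-copies and 27 foils."""
    base = make_two_tone_patch(rng, size=24, colors=np.array([[200, 40, 60], [30, 180, 220]]))
    near = []
    for _ in range(4):
        p = base.copy()
        yy, xx = rng.integers(0, 24, size=(2, 8))
        p[yy, xx] = rng.integers(0, 256, size=3)
        near.append(p)
    foils = [make_two_tone_patch(rng, size=24) for _ in range(27)]
    patches = [base] + near + foils
    img, windows = tile_image(patches, cols=8)
    query = QueryPatch(img, windows[0])
    return img, windows, query


class TestCoarseCascade:
    def test_single_stage_retains_half(self, tiled_scene):
        img, windows, query = tiled_scene
        out = coarse_cascade(query, windows[:8], img, r=1)
        assert len(out) == 4

    def test_ceil_halving_chain(self, rng):
        # 100 candidates, r=3: 100 -> 50 -> 25 -> 13
        patches = [make_two_tone_patch(rng, size=12) for _ in range(100)]
        img, windows = tile_image(patches, cols=10)
        query = QueryPatch(img, windows[0])
        out = coarse_cascade(query, windows, img, r=3)
        assert len(out) == 13
        # histogram evaluations: 100 + 50 + 25 < 100 * 3
        assert out.stats["ring_histograms"] == 100 + 50 + 25

    def test_exact_copy_survives_at_rank_one(self, tiled_scene):
        img, windows, query = tiled_scene
        out = coarse_cascade(query, windows, img, r=3)
        assert out.entries[0][0] == windows[0]
        assert out.entries[0][1] == 0.0

    def test_empty_candidates_warn(self, tiled_scene, caplog):
        img, _, query = tiled_scene
        with caplog.at_level("WARNING"):
            out = coarse_cascade(query, [], img, r=2)
        assert len(out) == 0

    def test_distances_sorted_ascending(self, tiled_scene):
        img, windows, query = tiled_scene
        out = coarse_cascade(query, windows, img, r=2)
        d = out.distances
        assert (np.diff(d) >= 0).all()


class TestFineRank:
    def test_exact_copy_rank_one(self, tiled_scene):
        img, windows, query = tiled_scene
        coarse = coarse_cascade(query, windows, img, r=2)
        fine = fine_rank(query, coarse, img, r=2)
        assert fine.entries[0][0] == windows[0]
        assert fine.entries[0][1] == 0.0

    def test_single_survivor_passthrough(self, tiled_scene):
        img, windows, query = tiled_scene
        lone = RankedCandidates([(windows[3], 0.7)], stage="coarse", query=query)
        fine = fine_rank(query, lone, img, r=2)
        assert len(fine) == 1 and fine.entries[0][0] == windows[3]

    def test_octant_mirror_separated_by_fine_not_coarse(self):
        """Two patches identical per ring but with segment content mirrored
        tie under the coarse feature and separate under the fine one."""
        part = build_ring_partition(16, 16, 1)
        a = np.zeros((16, 16, 3), dtype=np.uint8)
        a[part.segment_label <= 4] = 240       # one half-plane bright
        b = np.zeros((16, 16, 3), dtype=np.uint8)
        b[part.segment_label > 4] = 240        # mirrored
        img, windows = tile_image([a, a, b], cols=3)
        query = QueryPatch(img, windows[0])
        # both survivors tie under the coarse (single-ring) feature:
        from hahsearch.features import hah_coarse

        d1 = np.linalg.norm(hah_coarse(a, 1) - hah_coarse(a, 1))
        d2 = np.linalg.norm(hah_coarse(a, 1) - hah_coarse(b, 1))
        assert d1 == d2 == pytest.approx(0.0)
        survivors = RankedCandidates(
            [(windows[1], 0.0), (windows[2], 0.0)], stage="coarse", query=query
        )
        fine = fine_rank(query, survivors, img, r=1)
        d_by_window = {id(w): d for w, d in fine.entries}
        assert d_by_window[id(windows[1])] == pytest.approx(0.0)
        assert d_by_window[id(windows[2])] > 0.5
        # oracle: direct fine-feature distance
        direct = float(np.linalg.norm(hah_fine(a, 1) - hah_fine(b, 1)))
        assert d_by_window[id(windows[2])] == pytest.approx(direct)


def brute_force_modes(points, b, tol=1e-6):
    """Reference flat-kernel mean-shift on few points."""
    points = np.asarray(points, dtype=float)
    out = []
    for p in points:
        p = p.copy()
        for _ in range(500):
            within = np.linalg.norm(points - p, axis=1) <= b
            newp = points[within].mean(axis=0)
            if np.linalg.norm(newp - p) < tol:
                break
            p = newp
        out.append(p)
    # unique up to b/2
    modes = []
    for p in out:
        if not any(np.linalg.norm(p - m) < b / 2 for m in modes):
            modes.append(p)
    return modes


def ranked_from_centers(centers, query, dists=None):
    entries = []
    for k, (r, c) in enumerate(centers):
        w = PatchWindow(int(r), int(c), query.h, query.w)
        entries.append((w, 0.1 * k if dists is None else dists[k]))
    return RankedCandidates(entries, stage="fine", query=query)


class TestMeanShift:
    @pytest.fixture()
    def query(self, rng):
        img = rng.integers(0, 256, (400, 400, 3), dtype=np.uint8)
        return QueryPatch(img, PatchWindow(0, 0, 30, 40))

    def test_bandwidth_is_half_query_diagonal(self, query):
        assert mean_shift_bandwidth(query) == pytest.approx(np.sqrt(30**2 + 40**2) / 2)

    def test_identical_centers_single_mode(self, query):
        top = ranked_from_centers([(50, 50)] * 6, query)
        out = mean_shift_cluster(top, query, fraction=1.0)
        assert len(out) == 1
        center = out.modes[0][0]
        assert center[0] == pytest.approx(50 + 29 / 2)  # window center, not origin

    def test_two_far_groups_two_modes(self, query):
        b = mean_shift_bandwidth(query)
        g1 = [(20 + dr, 20 + dc) for dr in (0, 3) for dc in (0, 3)]
        g2 = [(20 + 10 * b + dr, 20 + dc) for dr in (0, 3) for dc in (0, 3)]
        top = ranked_from_centers(g1 + g2, query)
        out = mean_shift_cluster(top, query, fraction=1.0)
        assert len(out) == 2
        # cross-check mode locations against the reference implementation
        pts = [w.center for w, _ in top.entries]
        ref = brute_force_modes(pts, b)
        got = sorted(m[0] for m in out.modes)
        ref = sorted(map(tuple, ref))
        assert np.allclose(got, ref, atol=1e-2)

    def test_every_window_in_exactly_one_mode(self, query, rng):
        centers = rng.integers(0, 300, size=(25, 2)).tolist()
        top = ranked_from_centers(centers, query)
        out = mean_shift_cluster(top, query, fraction=1.0)
        counted = sum(len(members) for _, members, _ in out.modes)
        assert counted == 25

    def test_invariant_to_input_ordering(self, query, rng):
        centers = rng.integers(0, 300, size=(15, 2)).tolist()
        dists = rng.uniform(0.2, 2.0, size=15).tolist()
        top = ranked_from_centers(centers, query, dists)
        perm = rng.permutation(15)
        shuffled = RankedCandidates(
            [top.entries[i] for i in perm], stage="fine", query=query
        )
        a = mean_shift_cluster(top, query, fraction=1.0)
        b = mean_shift_cluster(shuffled, query, fraction=1.0)
        assert sorted(m[0] for m in a.modes) == sorted(m[0] for m in b.modes)
        assert sorted((m[2] for m in a.modes), key=str) == sorted(
            (m[2] for m in b.modes), key=str
        )

    def test_representative_is_best_ranked_member(self, query):
        top = ranked_from_centers([(50, 50), (52, 51), (49, 53)], query,
                                  dists=[0.9, 0.2, 0.5])
        out = mean_shift_cluster(top, query, fraction=1.0)
        assert len(out) == 1
        assert out.modes[0][2].row0 == 52


class TestRunSearch:
    def test_planted_exact_copy_is_a_mode_representative(self, rng):
        base = make_two_tone_patch(rng, size=20, colors=np.array([[150, 40, 90], [240, 240, 240]]))
        img = np.full((200, 200, 3), 250, dtype=np.uint8)
        img[60:80, 100:120] = base
        img[140:160, 40:60] = base
        query = QueryPatch(img, PatchWindow(60, 100, 20, 20))
        cfg = SearchConfig(roi=hs.RoiConfig(min_foreground_fraction=0.05,
                                            overlap_ratio=0.75))
        res = run_search([img], query, cfg)[0]
        assert any(rep.iou(query.window) > 0.5 for rep in res.representatives)

    def test_recovers_most_planted_same_class_objects(self, small_smear):
        img, truth = small_smear
        query = hs.query_from_truth(img, truth, "neutrophil")
        res = run_search([img], query, SearchConfig())[0]
        neut = truth.of_class("neutrophil")
        hits = sum(
            1 for o in neut if any(r.iou(o.window) >= 0.25 for r in res.representatives)
        )
        assert hits / len(neut) >= 0.8

    def test_empty_foreground_yields_empty_result(self, rng):
        blank = np.full((150, 150, 3), 255, dtype=np.uint8)
        query = QueryPatch(rng.integers(0, 256, (150, 150, 3), dtype=np.uint8),
                           PatchWindow(0, 0, 20, 20))
        res = run_search([blank], query, SearchConfig())[0]
        assert len(res) == 0

    def test_end_to_end_deterministic(self, small_smear):
        img, truth = small_smear
        query = hs.query_from_truth(img, truth, "neutrophil")
        a = run_search([img], query, SearchConfig())[0]
        b = run_search([img], query, SearchConfig())[0]
        assert [m[0] for m in a.modes] == [m[0] for m in b.modes]
        assert a.representatives == b.representatives


def test_cascade_cost_below_full_feature_scoring(rng):
    """The cascade's histogram-evaluation count stays below scoring every
    candidate with the full r-ring feature."""
    patches = [make_two_tone_patch(rng, size=12) for _ in range(40)]
    img, windows = tile_image(patches, cols=8)
    query = QueryPatch(img, windows[0])
    for r in (2, 3, 4):
        out = coarse_cascade(query, windows, img, r=r)
        assert out.stats["ring_histograms"] < len(windows) * r
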