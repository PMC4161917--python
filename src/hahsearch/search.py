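"""Three-stage hierarchical retrieval: coarse cascade, fine ranking,
mean-shift fusion.

Scoring every candidate window with the full annular feature is wasteful:
most candidates look nothing like the query and can be rejected from the
innermost ring alone.  The coarse cascade therefore proceeds ring by ring,
accumulating the ring histograms into the coarse feature and keeping only
the top half of the surviving candidates at each ring, so half the pool is
eliminated after evaluating just one ring.  Survivors of the outermost ring
are re-ranked with the fine (per-octant) feature, and the best-ranked
fraction is fused into final detection sites by mean-shift clustering of
window centers.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .features import build_ring_partition, hah_fine, hah_ring_histogram
from .geometry import PatchWindow, QueryPatch, extract_patch, resize_to_query
from .roi import RoiConfig, compute_foreground_mask, generate_candidate_windows

logger = logging.getLogger(__name__)


@dataclass
class RankedCandidates:
    """An ordered retrieval list: ``entries[k] = (window, distance)`` with
    distances ascending, most similar first (ranks are 1-based).

    ``stats`` records bookkeeping such as the number of per-ring histogram
    evaluations spent, used to verify the cascade's cost advantage.
    """

    entries: list[tuple[PatchWindow, float]]
    stage: str
    query: QueryPatch | None = None
    stats: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def windows(self) -> list[PatchWindow]:
        return [w for w, _ in self.entries]

    @property
    def distances(self) -> np.ndarray:
        return np.array([d for _, d in self.entries])

    def to_records(self) -> list[dict]:
        return [
            {"rank": k + 1, "distance": d, **w.to_dict()}
            for k, (w, d) in enumerate(self.entries)
        ]


@dataclass
class ClusterResult:
    """Mean-shift fusion of top-ranked windows.

    ``modes`` is a list of ``(center, members, representative)`` where
    ``center`` is the converged (row, col) mode location, ``members`` the
    windows assigned to that mode, and ``representative`` the best-ranked
    member.  Every input window belongs to exactly one mode.
    """

    modes: list[tuple[tuple[float, float], list[PatchWindow], PatchWindow]]
    bandwidth: float

    def __len__(self) -> int:
        return len(self.modes)

    @property
    def representatives(self) -> list[PatchWindow]:
        return [rep for _, _, rep in self.modes]

    def to_records(self) -> list[dict]:
        return [
            {
                "center": list(center),
                "representative": rep.to_dict(),
                "n_members": len(members),
            }
            for center, members, rep in self.modes
        ]


def _candidate_pixels(
    image: np.ndarray, windows: Sequence[PatchWindow], query: QueryPatch
) -> list[np.ndarray]:
    """Extract each window and resample it to the query geometry."""
    return [
        resize_to_query(extract_patch(image, w), query.w, query.h) for w in windows
    ]


def coarse_cascade(
    query: QueryPatch,
    candidates: Sequence[PatchWindow],
    image: np.ndarray,
    r: int,
) -> RankedCandidates:
    """Ring-by-ring cascade ranking with 50% retention per stage.

    At stage ``i`` the cumulative coarse feature ``(h_1, ..., h_i)`` of the
    query is compared (Euclidean) with that of each surviving candidate and
    the top ``ceil(n_i / 2)`` are retained; the procedure runs from the
    innermost ring ``i = 1`` to the outermost ``i = r``, so the final
    survivors are ranked by the full coarse feature.  Ring histograms are
    computed lazily, so eliminated candidates never pay for outer rings.
    Ties in distance are broken by candidate list order.
    """
    if not candidates:
        logger.warning("coarse cascade called with no candidates")
        return RankedCandidates([], stage="coarse", query=query,
                                stats={"ring_histograms": 0})
    part = build_ring_partition(query.h, query.w, r)
    qpix = query.pixels
    q_rings = [hah_ring_histogram(qpix, part, i) for i in range(1, r + 1)]
    pixels = _candidate_pixels(image, candidates, query)

    alive = list(range(len(candidates)))
    d2 = np.zeros(len(candidates))
    n_hist = 0
    for i in range(1, r + 1):
        for k in alive:
            h = hah_ring_histogram(pixels[k], part, i)
            n_hist += 1
            diff = h - q_rings[i - 1]
            d2[k] += float(diff @ diff)
        alive.sort(key=lambda k: (d2[k], k))
        keep = math.ceil(len(alive) / 2)
        alive = alive[:keep]
    entries = [(candidates[k], math.sqrt(d2[k])) for k in alive]
    return RankedCandidates(
        entries, stage="coarse", query=query,
        stats={"ring_histograms": n_hist, "n_input": len(candidates)},
    )


def fine_rank(
    query: QueryPatch,
    survivors: RankedCandidates,
    image: np.ndarray,
    r: int,
) -> RankedCandidates:
    """Re-rank cascade survivors by the fine (eight-octant) feature.

    Euclidean distance between the per-ring-per-segment feature of the
    query and of each survivor; output sorted ascending, ties broken by
    incoming rank.
    """
    if not survivors.entries:
        return RankedCandidates([], stage="fine", query=query, stats=survivors.stats)
    part = build_ring_partition(query.h, query.w, r)
    qf = hah_fine(query.pixels, r, part)
    windows = survivors.windows
    pixels = _candidate_pixels(image, windows, query)
    dists = [float(np.linalg.norm(hah_fine(p, r, part) - qf)) for p in pixels]
    order = sorted(range(len(windows)), key=lambda k: (dists[k], k))
    entries = [(windows[k], dists[k]) for k in order]
    return RankedCandidates(entries, stage="fine", query=query, stats=survivors.stats)


def mean_shift_bandwidth(query: QueryPatch) -> float:
    """Bandwidth ``b = sqrt(w^2 + h^2) / 2`` — half the query diagonal, so
    detections whose centers overlap substantially are merged."""
    return math.sqrt(query.w ** 2 + query.h ** 2) / 2.0


def mean_shift_cluster(
    top: RankedCandidates,
    query: QueryPatch,
    fraction: float = 0.1,
) -> ClusterResult:
    """Fuse the best-ranked ``fraction`` of ``top`` into detection modes.

    Flat-kernel mean-shift on window center coordinates with bandwidth
    ``b = sqrt(w^2+h^2)/2``: each center iterates to the mean of centers
    within ``b`` until the shift drops below ``1e-3 * b`` or 100 iterations.
    Converged modes closer than ``b/2`` are merged (canonical row/col order,
    so the result is invariant to input ordering); each window joins the
    nearest merged mode and each mode's representative is its best-ranked
    member.
    """
    if not 0 < fraction <= 1:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    if not top.entries:
        raise ValueError("mean-shift requires a nonempty ranked list")
    n_keep = max(1, math.ceil(fraction * len(top.entries)))
    kept = top.entries[:n_keep]
    b = mean_shift_bandwidth(query)

    centers = np.array([w.center for w, _ in kept], dtype=np.float64)
    converged = centers.copy()
    for k in range(len(kept)):
        p = converged[k]
        for _ in range(100):
            within = np.linalg.norm(centers - p, axis=1) <= b
            newp = centers[within].mean(axis=0)
            if np.linalg.norm(newp - p) < 1e-3 * b:
                p = newp
                break
            p = newp
        converged[k] = p

    # merge converged points closer than b/2, scanning in canonical
    # (row, col) order so the mode set does not depend on input ordering
    order = sorted(range(len(kept)), key=lambda k: (converged[k][0], converged[k][1]))
    mode_centers: list[np.ndarray] = []
    for k in order:
        p = converged[k]
        if not any(np.linalg.norm(p - c) < b / 2 for c in mode_centers):
            mode_centers.append(p)
    # each window joins the nearest mode (ties to the canonically first)
    assign = np.array(
        [
            int(np.argmin([np.linalg.norm(converged[k] - c) for c in mode_centers]))
            for k in range(len(kept))
        ],
        dtype=int,
    )

    modes = []
    for m, c in enumerate(mode_centers):
        member_idx = [k for k in range(len(kept)) if assign[k] == m]
        members = [kept[k][0] for k in member_idx]
        # best-ranked member, keyed by distance (then position) so the
        # choice does not depend on the ordering of the input list
        best = min(member_idx, key=lambda k: (kept[k][1], kept[k][0].row0, kept[k][0].col0))
        modes.append(((float(c[0]), float(c[1])), members, kept[best][0]))
    return ClusterResult(modes=modes, bandwidth=b)


@dataclass(frozen=True)
class SearchConfig:
    """End-to-end search settings: ROI generation plus ring count and the
    top fraction passed to clustering."""

    roi: RoiConfig = field(default_factory=RoiConfig)
    r: int = 3
    fraction: float = 0.1


def run_search(
    images: Sequence[np.ndarray],
    query: QueryPatch,
    config: SearchConfig | None = None,
    image_ids: Sequence[str] | None = None,
) -> list[ClusterResult]:
    """Full pipeline per image: foreground mask -> sliding windows ->
    coarse cascade -> fine ranking -> mean-shift fusion.

    Deterministic end-to-end; an image with no foreground candidates yields
    an empty :class:`ClusterResult`.
    """
    config = config or SearchConfig()
    ids = list(image_ids) if image_ids is not None else [str(i) for i in range(len(images))]
    results = []
    for image, image_id in zip(images, ids):
        mask = compute_foreground_mask(image, config.roi, image_id=image_id)
        cands = generate_candidate_windows(mask, query, config.roi)
        if not cands:
            results.append(ClusterResult(modes=[], bandwidth=mean_shift_bandwidth(query)))
            continue
        coarse = coarse_cascade(query, cands, image, config.r)
        fine = fine_rank(query, coarse, image, config.r)
        results.append(mean_shift_cluster(fine, query, config.fraction))
    return results
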