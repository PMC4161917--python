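"""Seeded synthetic image fixtures with ground truth.

Two generators emulate the pipeline's two use cases so that every stage is
testable without clinical material:

* :func:`make_smear_fixture` — a blood-smear-like field: a pale background
  densely scattered with small pink erythrocyte-like distractor discs, plus
  planted leukocyte-like cells from five classes (neutrophil-, lymphocyte-,
  monocyte-, eosinophil- and basophil-like) that differ in cell size,
  nucleus shape (lobed vs round, drawn as composed ellipses) and stain
  color.  The default class mix follows the approximate adult differential
  (neutrophils ~60-70% of leukocytes).

* :func:`make_renal_fixture` — a tissue-like field: a textured pink
  background with large ring-like glomerulus structures in two states
  (intact: dense interior texture; degraded: pale fragmented interior),
  each planted at a scale drawn from the configured scale set.

The visuals are stylized, not photorealistic: retrieval behavior depends on
color and spatial statistics, which the generator controls explicitly.
Every planted object is recorded in a :class:`GroundTruth` so precision and
recall can be measured exactly.  Output is bit-identical for a fixed seed.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, replace

import numpy as np
from skimage.draw import disk as draw_disk, ellipse as draw_ellipse

from .geometry import PatchWindow, QueryPatch

SMEAR_CLASSES = ("neutrophil", "lymphocyte", "monocyte", "eosinophil", "basophil")
RENAL_CLASSES = ("intact", "degraded")

#: Approximate adult leukocyte differential (fractions of range midpoints
#: 60-70 / 20-25 / 3-8 / 2-4 / 0.5-1 percent, normalized).
DEFAULT_SMEAR_MIX = {
    "neutrophil": 65.0 / 96.75,
    "lymphocyte": 22.5 / 96.75,
    "monocyte": 5.5 / 96.75,
    "eosinophil": 3.0 / 96.75,
    "basophil": 0.75 / 96.75,
}

# per-class cell geometry and Giemsa-like colors:
# (cell radius, cytoplasm RGB, nucleus RGB, nucleus style)
_SMEAR_STYLE = {
    "neutrophil": (14, (208, 145, 185), (92, 62, 132), "lobed3"),
    "lymphocyte": (11, (140, 155, 215), (70, 52, 140), "round"),
    "monocyte": (16, (150, 162, 212), (112, 82, 152), "kidney"),
    "eosinophil": (14, (232, 120, 105), (100, 70, 140), "lobed2"),
    "basophil": (12, (96, 72, 136), (62, 44, 104), "round"),
}


class PlacementError(RuntimeError):
    """Objects could not be placed without overlap within bounded retries."""


@dataclass(frozen=True)
class PlantedObject:
    window: PatchWindow
    label: str
    scale: float = 1.0


@dataclass
class GroundTruth:
    """Locations, classes and scales of every planted object."""

    objects: list[PlantedObject]
    image_id: str
    seed: int

    def of_class(self, label: str) -> list[PlantedObject]:
        return [o for o in self.objects if o.label == label]

    def to_json(self, path: str | os.PathLike) -> None:
        records = [
            {"window": o.window.to_dict(), "label": o.label, "scale": o.scale}
            for o in self.objects
        ]
        with open(path, "w") as fh:
            json.dump({"image_id": self.image_id, "seed": self.seed,
                       "objects": records}, fh, indent=1)

    @classmethod
    def from_json(cls, path: str | os.PathLike) -> "GroundTruth":
        with open(path) as fh:
            d = json.load(fh)
        objs = [
            PlantedObject(PatchWindow.from_dict(o["window"]), o["label"], o["scale"])
            for o in d["objects"]
        ]
        return cls(objs, d["image_id"], d["seed"])


@dataclass(frozen=True)
class FixtureConfig:
    """Settings shared by both generators.

    ``class_mix`` fractions must sum to 1; object counts per class are
    allocated by largest remainder.  ``distractor_count`` only applies to
    the smear generator; ``scales``/``base_radius`` govern the renal one.
    ``noise_sd`` is the standard deviation of the additive Gaussian pixel
    noise in 8-bit gray levels.
    """

    height: int = 1000
    width: int = 1000
    n_objects: int = 8
    class_mix: dict = field(default_factory=lambda: dict(DEFAULT_SMEAR_MIX))
    distractor_count: int = 2400
    noise_sd: float = 2.0
    scales: tuple[float, ...] = (1.0,)
    base_radius: int = 45
    seed: int = 0
    min_separation: float = 3.0   # multiples of the largest object radius

    def __post_init__(self) -> None:
        total = sum(self.class_mix.values())
        if self.class_mix and abs(total - 1.0) > 1e-6:
            raise ValueError(f"class_mix fractions must sum to 1, got {total}")


def renal_config(**overrides) -> FixtureConfig:
    """Default renal-fixture settings: a quarter-linear-scale tissue field
    with intact/degraded glomeruli across the multi-scale set."""
    base = FixtureConfig(
        height=876, width=1256, n_objects=8,
        class_mix={"intact": 0.5, "degraded": 0.5},
        distractor_count=0, noise_sd=2.0,
        scales=(0.5, 1.0, 2.0), base_radius=45, seed=0,
    )
    return replace(base, **overrides)


def _allocate_counts(n: int, mix: dict, order: tuple[str, ...]) -> dict:
    """Largest-remainder allocation of ``n`` objects to classes."""
    labels = [c for c in order if c in mix]
    quotas = np.array([n * mix[c] for c in labels])
    counts = np.floor(quotas).astype(int)
    rem = quotas - counts
    for i in np.argsort(-rem, kind="stable")[: n - counts.sum()]:
        counts[i] += 1
    return dict(zip(labels, counts.tolist()))


def _place_centers(
    rng: np.random.Generator, n: int, height: int, width: int,
    margin: int, min_dist: float,
) -> list[tuple[int, int]]:
    centers: list[tuple[int, int]] = []
    for _ in range(n):
        for _attempt in range(400):
            r = int(rng.integers(margin, height - margin))
            c = int(rng.integers(margin, width - margin))
            if all((r - r0) ** 2 + (c - c0) ** 2 >= min_dist ** 2 for r0, c0 in centers):
                centers.append((r, c))
                break
        else:
            raise PlacementError(
                f"could not place object {len(centers) + 1} of {n} without overlap"
            )
    return centers


def _paint_disk(img, center, radius, color, jitter, rng) -> None:
    rr, cc = draw_disk(center, radius, shape=img.shape[:2])
    col = np.clip(np.asarray(color, float) + rng.normal(0, jitter, 3), 0, 255)
    img[rr, cc] = col


def _paint_ellipse(img, center, r_rad, c_rad, color, rot, rng, jitter=2.0) -> None:
    rr, cc = draw_ellipse(center[0], center[1], r_rad, c_rad,
                          shape=img.shape[:2], rotation=rot)
    col = np.clip(np.asarray(color, float) + rng.normal(0, jitter, 3), 0, 255)
    img[rr, cc] = col


def _draw_leukocyte(img, center, label, rng) -> int:
    """Draw one class-styled cell; returns the cell radius used."""
    base_radius, cyto, nuc, style = _SMEAR_STYLE[label]
    radius = base_radius + int(rng.integers(-1, 2))
    _paint_disk(img, center, radius, cyto, jitter=2.0, rng=rng)
    r0, c0 = center
    if style == "round":
        _paint_ellipse(img, (r0, c0), 0.70 * radius, 0.66 * radius, nuc,
                       rot=float(rng.uniform(0, np.pi)), rng=rng)
    elif style == "kidney":
        _paint_ellipse(img, (r0, c0), 0.62 * radius, 0.55 * radius, nuc,
                       rot=float(rng.uniform(0, np.pi)), rng=rng)
        # notch: repaint a cytoplasm-colored bite to suggest the indented nucleus
        _paint_ellipse(img, (r0 + 0.30 * radius, c0), 0.28 * radius, 0.30 * radius,
                       cyto, rot=0.0, rng=rng)
    else:  # lobed2 / lobed3
        lobes = 3 if style == "lobed3" else 2
        phase = float(rng.uniform(0, 2 * np.pi))
        for k in range(lobes):
            ang = phase + 2 * np.pi * k / lobes
            lr = r0 + 0.38 * radius * np.sin(ang)
            lc = c0 + 0.38 * radius * np.cos(ang)
            _paint_ellipse(img, (lr, lc), 0.34 * radius, 0.30 * radius, nuc,
                           rot=ang, rng=rng)
    return radius


def make_smear_fixture(
    config: FixtureConfig | None = None, image_id: str = "smear-0"
) -> tuple[np.ndarray, GroundTruth]:
    """Blood-smear-like field with planted leukocyte-like objects.

    Pale background, ``distractor_count`` pink erythrocyte-like discs, then
    the planted class objects drawn on top with small seeded jitter in size
    and color; Gaussian pixel noise last.  Each planted object's bounding
    window (cell radius + margin) goes into the ground truth.
    """
    cfg = config or FixtureConfig()
    rng = np.random.default_rng(cfg.seed)
    img = np.full((cfg.height, cfg.width, 3), (242, 236, 230), dtype=np.float64)

    for _ in range(cfg.distractor_count):
        center = (int(rng.integers(0, cfg.height)), int(rng.integers(0, cfg.width)))
        radius = int(rng.integers(7, 12))
        _paint_disk(img, center, radius, (226, 132, 140), jitter=4.0, rng=rng)
        # faint central pallor of an erythrocyte
        _paint_disk(img, center, max(2, radius // 2), (236, 180, 185), jitter=4.0, rng=rng)

    counts = _allocate_counts(cfg.n_objects, cfg.class_mix, SMEAR_CLASSES)
    labels = [lab for lab in SMEAR_CLASSES for _ in range(counts.get(lab, 0))]
    max_radius = max(_SMEAR_STYLE[c][0] for c in SMEAR_CLASSES)
    margin = max_radius + 8
    centers = _place_centers(rng, len(labels), cfg.height, cfg.width,
                             margin, cfg.min_separation * max_radius)

    objects: list[PlantedObject] = []
    for label, center in zip(labels, centers):
        radius = _draw_leukocyte(img, center, label, rng)
        half = radius + 6
        win = PatchWindow(center[0] - half, center[1] - half, 2 * half, 2 * half,
                          scale=1.0, image_id=image_id)
        objects.append(PlantedObject(win, label, 1.0))

    if cfg.noise_sd > 0:
        img += rng.normal(0, cfg.noise_sd, img.shape)
    image = np.clip(np.round(img), 0, 255).astype(np.uint8)
    return image, GroundTruth(objects, image_id, cfg.seed)


def _draw_glomerulus(img, center, radius, state, rng) -> None:
    r0, c0 = center
    # Bowman-capsule-like outer ring
    _paint_disk(img, center, radius, (206, 136, 150), jitter=2.0, rng=rng)
    inner = max(2, int(0.88 * radius))
    if state == "intact":
        _paint_disk(img, center, inner, (226, 192, 200), jitter=2.0, rng=rng)
        n_dots = max(6, int(2.2 * inner))
        for _ in range(n_dots):
            ang = rng.uniform(0, 2 * np.pi)
            rad = inner * np.sqrt(rng.uniform(0, 0.9))
            dot_r = max(1, int(round(inner * 0.09)))
            _paint_disk(img, (r0 + rad * np.sin(ang), c0 + rad * np.cos(ang)),
                        dot_r, (124, 74, 116), jitter=6.0, rng=rng)
    else:  # degraded: pale interior with sparse fragments
        _paint_disk(img, center, inner, (240, 222, 224), jitter=2.0, rng=rng)
        for _ in range(max(2, inner // 4)):
            ang = rng.uniform(0, 2 * np.pi)
            rad = inner * np.sqrt(rng.uniform(0, 0.8))
            _paint_ellipse(img, (r0 + rad * np.sin(ang), c0 + rad * np.cos(ang)),
                           max(1, 0.12 * inner), max(1, 0.05 * inner),
                           (198, 150, 164), rot=float(ang), rng=rng, jitter=5.0)


def make_renal_fixture(
    config: FixtureConfig | None = None, image_id: str = "renal-0"
) -> tuple[np.ndarray, GroundTruth]:
    """Tissue-like field with intact and degraded ring structures.

    Each planted object draws its scale from ``config.scales`` (the
    multi-scale search set); the realized scale and state are recorded in
    the ground truth.
    """
    cfg = config if config is not None else renal_config()
    for s in cfg.scales:
        if s not in (0.5, 1.0, 2.0, 3.0, 4.0):
            raise ValueError(f"renal scales must come from {{0.5, 1, 2, 3, 4}}, got {s}")
    rng = np.random.default_rng(cfg.seed)
    img = np.full((cfg.height, cfg.width, 3), (238, 218, 220), dtype=np.float64)
    # coarse background texture: smoothed blotches
    blotch = rng.normal(0, 1, (cfg.height // 8 + 1, cfg.width // 8 + 1))
    blotch = np.kron(blotch, np.ones((8, 8)))[: cfg.height, : cfg.width]
    img += (blotch * 4.0)[:, :, None]

    counts = _allocate_counts(cfg.n_objects, cfg.class_mix, RENAL_CLASSES)
    labels = [lab for lab in RENAL_CLASSES for _ in range(counts.get(lab, 0))]
    scales = [float(rng.choice(cfg.scales)) for _ in labels]
    max_radius = int(cfg.base_radius * max(cfg.scales)) if labels else cfg.base_radius
    margin = max_radius + 10
    if 2 * margin >= min(cfg.height, cfg.width):
        raise PlacementError("image too small for the largest configured scale")
    centers = _place_centers(rng, len(labels), cfg.height, cfg.width,
                             margin, cfg.min_separation * max_radius * 0.7)

    objects: list[PlantedObject] = []
    for label, scale, center in zip(labels, scales, centers):
        radius = max(3, int(round(cfg.base_radius * scale)) + int(rng.integers(-1, 2)))
        _draw_glomerulus(img, center, radius, label, rng)
        half = radius + 8
        win = PatchWindow(center[0] - half, center[1] - half, 2 * half, 2 * half,
                          scale=scale, image_id=image_id)
        objects.append(PlantedObject(win, label, scale))

    if cfg.noise_sd > 0:
        img += rng.normal(0, cfg.noise_sd, img.shape)
    image = np.clip(np.round(img), 0, 255).astype(np.uint8)
    return image, GroundTruth(objects, image_id, cfg.seed)


def query_from_truth(image: np.ndarray, truth: GroundTruth, label: str) -> QueryPatch:
    """Use the first planted object of ``label`` as the query patch."""
    objs = truth.of_class(label)
    if not objs:
        raise KeyError(f"no planted object of class {label!r} in {truth.image_id}")
    return QueryPatch(image=image, window=objs[0].window)
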