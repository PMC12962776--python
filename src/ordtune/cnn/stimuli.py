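"""Factorial snake-stimulus generation and image preprocessing.

Snakes are chains of white compartments (circles or rectangles) on a gray
background with a single red marker inside one compartment.  The snakes
carry no directional cue, so the ordinality of an image is counted from
the nearer end: ordinality = min(position, n_compartments + 1 - position),
giving a maximum ordinality of n/2 for an even compartment count.

Stimulus sets follow full factorial designs:

* straight snakes — repetitions x shapes x orientations x spacings x
  positions (e.g. 5 x 2 x 2 x 2 x 10 = 400 images, 80 per ordinality);
* irregularly ordered snakes — repetitions x shapes x positions
  (e.g. 20 x 2 x 16 = 640 for 16 compartments, 20 x 2 x 20 = 800 for 20);
* variable-length control — repetitions x positions (20 x 10 = 200),
  irregular layout with randomly drawn compartment lengths so that the
  along-chain distance to the marker decorrelates from ordinal position.

Image counts are pure functions of the configuration; the seed only moves
layouts.  Preprocessing resizes/crops to 224 x 224 and applies the
channel normalization of the classification training set.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ..design import (
    BACKGROUND_GRAY,
    MARKER_COLOR,
    _fill_shape,
    self_avoiding_chain,
)

__all__ = [
    "SnakeDatasetConfig",
    "generate_snake_dataset",
    "build_screening_dataset",
    "standard_config",
    "preprocess_images",
    "denormalize_images",
    "ordinality_of_position",
    "IMAGENET_MEAN",
    "IMAGENET_STD",
]

IMAGENET_MEAN = np.array([0.485, 0.456, 0.406], dtype=np.float32)
IMAGENET_STD = np.array([0.229, 0.224, 0.225], dtype=np.float32)

_WHITE = (255, 255, 255)


def ordinality_of_position(position: int, n_compartments: int) -> int:
    """Rank counted from the nearer end of an undirected snake."""
    if not 1 <= position <= n_compartments:
        raise ValueError(f"position {position} outside 1..{n_compartments}")
    return min(position, n_compartments + 1 - position)


@dataclass(frozen=True)
class SnakeDatasetConfig:
    """One factorial stimulus set."""

    n_compartments: int = 10
    order: str = "straight"  # "straight" | "irregular" | "variable"
    shapes: tuple = ("circle", "rectangle")
    orientations: tuple = ("horizontal", "vertical")  # straight only
    spacings: tuple = ("spaced", "uninterrupted")  # straight only
    repetitions: int = 5
    seed: int = 0
    canvas: int = 224

    def __post_init__(self):
        if self.n_compartments not in (10, 16, 20):
            raise ValueError("n_compartments must be one of 10, 16, 20")
        if self.order not in ("straight", "irregular", "variable"):
            raise ValueError(f"unknown order {self.order!r}")
        if self.repetitions < 1:
            raise ValueError("repetitions must be >= 1")

    @property
    def n_images(self) -> int:
        n = self.repetitions * self.n_compartments
        if self.order == "straight":
            return n * len(self.shapes) * len(self.orientations) * len(self.spacings)
        if self.order == "irregular":
            return n * len(self.shapes)
        return n  # variable-length control: repetitions x positions

    @property
    def max_ordinality(self) -> int:
        return (self.n_compartments + 1) // 2


def standard_config(name: str, seed: int = 0) -> SnakeDatasetConfig:
    """The named stimulus sets used throughout the analysis."""
    table = {
        "straight10": dict(n_compartments=10, order="straight", repetitions=5),
        "irregular10": dict(n_compartments=10, order="irregular", repetitions=20),
        "straight16": dict(n_compartments=16, order="straight", repetitions=5),
        "irregular16": dict(n_compartments=16, order="irregular", repetitions=20),
        "straight20": dict(n_compartments=20, order="straight", repetitions=5),
        "irregular20": dict(n_compartments=20, order="irregular", repetitions=20),
        "variable10": dict(n_compartments=10, order="variable", repetitions=20),
    }
    if name not in table:
        raise KeyError(f"unknown stimulus set {name!r}; choose from {sorted(table)}")
    return SnakeDatasetConfig(seed=seed, **table[name])


# ---------------------------------------------------------------------------
# rendering


def _render_straight(n, shape, orientation, spacing, position, rng, canvas):
    img = np.full((canvas, canvas, 3), BACKGROUND_GRAY, dtype=np.uint8)
    cell = (canvas - 24) // n
    half = cell // 2
    inset = max(cell // 8, 2) if spacing == "spaced" else 0
    length = n * cell
    lo = (canvas - length) // 2
    off_along = int(rng.integers(-lo + 4, lo - 3)) if lo > 4 else 0
    off_perp = int(rng.integers(-(canvas // 2 - cell), canvas // 2 - cell + 1))
    centers = []
    for i in range(n):
        along = lo + i * cell + half + off_along
        perp = canvas // 2 + off_perp
        cy, cx = (perp, along) if orientation == "horizontal" else (along, perp)
        centers.append((cy, cx))
        _fill_shape(img, cy, cx, half - inset, half - inset, shape, _WHITE)
        if i + 1 == position:
            m = max(int((half - inset) * 0.6), 1)
            _fill_shape(img, cy, cx, m, m, shape, MARKER_COLOR)
    return img, centers


def _render_irregular(n, shape, position, rng, canvas, scales=None):
    img = np.full((canvas, canvas, 3), BACKGROUND_GRAY, dtype=np.uint8)
    g = int(np.ceil(np.sqrt(2 * n))) + 1
    cell = (canvas - 16) // g
    chain = self_avoiding_chain(n, (g, g), rng)
    margin = (canvas - g * cell) // 2
    jitter = max(cell // 10, 1)
    gap = max(cell // 6, 2)
    centers = []
    for i, (r, c) in enumerate(chain):
        cy = margin + r * cell + cell // 2 + int(rng.integers(-jitter, jitter + 1))
        cx = margin + c * cell + cell // 2 + int(rng.integers(-jitter, jitter + 1))
        centers.append((cy, cx))
        s = 1.0 if scales is None else scales[i]
        half = max(int((cell // 2 - gap) * s), 2)
        _fill_shape(img, cy, cx, half, half, shape, _WHITE)
        if i + 1 == position:
            m = max(int(half * 0.6), 1)
            _fill_shape(img, cy, cx, m, m, shape, MARKER_COLOR)
    return img, centers


def _chain_distance(centers, position) -> float:
    """Along-chain center-to-center distance from the first compartment."""
    d = 0.0
    for i in range(position - 1):
        (y0, x0), (y1, x1) = centers[i], centers[i + 1]
        d += float(np.hypot(y1 - y0, x1 - x0))
    return d


def generate_snake_dataset(
    config: SnakeDatasetConfig, render: bool = True
):
    """Generate one stimulus set.

    Returns ``(images, labels)`` where ``images`` is a uint8 array of shape
    (n_images, canvas, canvas, 3) (or None with ``render=False``, which
    still produces the complete label table) and ``labels`` has one row
    per image: image_id, stimulus_set, shape, orientation, spacing,
    n_compartments, position, ordinality, distance_to_marker, repetition.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_compartments
    if config.order == "straight":
        cells = itertools.product(
            range(config.repetitions), config.shapes, config.orientations,
            config.spacings, range(1, n + 1),
        )
        rows = [
            dict(repetition=r, shape=sh, orientation=o, spacing=sp, position=p)
            for r, sh, o, sp, p in cells
        ]
    elif config.order == "irregular":
        cells = itertools.product(
            range(config.repetitions), config.shapes, range(1, n + 1)
        )
        rows = [
            dict(repetition=r, shape=sh, orientation="", spacing="", position=p)
            for r, sh, p in cells
        ]
    else:  # variable-length control: shape varies freely, not a factor
        cells = itertools.product(range(config.repetitions), range(1, n + 1))
        rows = [
            dict(repetition=r, shape=str(rng.choice(config.shapes)),
                 orientation="", spacing="", position=p)
            for r, p in cells
        ]

    images = np.empty((len(rows), config.canvas, config.canvas, 3),
                      dtype=np.uint8) if render else None
    set_name = config.order
    for i, row in enumerate(rows):
        scales = None
        if config.order == "variable":
            scales = rng.uniform(0.45, 1.0, n)
        if render or config.order == "variable":
            if config.order == "straight":
                img, centers = _render_straight(
                    n, row["shape"], row["orientation"], row["spacing"],
                    row["position"], rng, config.canvas,
                )
            else:
                img, centers = _render_irregular(
                    n, row["shape"], row["position"], rng, config.canvas,
                    scales=scales,
                )
            row["distance_to_marker"] = _chain_distance(centers, row["position"])
            if render:
                images[i] = img
        else:
            # layout not realized; along-chain distance is the analytic
            # center spacing for deterministic layouts only
            row["distance_to_marker"] = np.nan
        row["image_id"] = f"{set_name}{n}_{i:05d}"
        row["stimulus_set"] = set_name
        row["n_compartments"] = n
        row["ordinality"] = ordinality_of_position(row["position"], n)
    labels = pd.DataFrame(rows)[
        ["image_id", "stimulus_set", "shape", "orientation", "spacing",
         "n_compartments", "position", "ordinality", "distance_to_marker",
         "repetition"]
    ]
    return images, labels


def build_screening_dataset(
    seed: int = 0,
    reps_straight: int = 5,
    n_compartments: int = 10,
    render: bool = True,
):
    """Combined straight + irregular set with balanced ANOVA cells.

    Straight snakes contribute 16 images per ordinality per repetition
    (2 shapes x 2 orientations x 2 spacings x 2 mirror positions) while
    irregular snakes contribute 4, so the irregular set uses four times
    the repetitions to balance every (ordinality x stimulus-set) cell —
    the default (5, 20) reproduces the 400 + 400 screening set.
    """
    cfg_s = SnakeDatasetConfig(
        n_compartments=n_compartments, order="straight",
        repetitions=reps_straight, seed=seed,
    )
    cfg_i = SnakeDatasetConfig(
        n_compartments=n_compartments, order="irregular",
        repetitions=4 * reps_straight, seed=seed + 1,
    )
    img_s, lab_s = generate_snake_dataset(cfg_s, render=render)
    img_i, lab_i = generate_snake_dataset(cfg_i, render=render)
    labels = pd.concat([lab_s, lab_i], ignore_index=True)
    images = None if not render else np.concatenate([img_s, img_i], axis=0)
    return images, labels


# ---------------------------------------------------------------------------
# preprocessing


def _resize_center_crop(img: np.ndarray, size: int) -> np.ndarray:
    from PIL import Image

    h, w = img.shape[:2]
    if (h, w) == (size, size):
        return img
    scale = size / min(h, w)
    nh, nw = int(round(h * scale)), int(round(w * scale))
    pim = Image.fromarray(img).resize((nw, nh), Image.BILINEAR)
    arr = np.asarray(pim)
    top = (nh - size) // 2
    left = (nw - size) // 2
    return arr[top : top + size, left : left + size]


def preprocess_images(
    images: np.ndarray,
    size: int = 224,
    mean: np.ndarray = IMAGENET_MEAN,
    std: np.ndarray = IMAGENET_STD,
) -> np.ndarray:
    """RGB uint8 (N, H, W, 3) -> normalized float32 (N, 3, size, size)."""
    images = np.asarray(images)
    if images.ndim == 3:
        images = images[None]
    if images.ndim != 4 or images.shape[-1] != 3:
        raise ValueError("expected RGB images of shape (N, H, W, 3)")
    out = np.empty((images.shape[0], 3, size, size), dtype=np.float32)
    for i, img in enumerate(images):
        arr = _resize_center_crop(img, size).astype(np.float32) / 255.0
        out[i] = np.moveaxis((arr - mean) / std, -1, 0)
    return out


def denormalize_images(
    batch: np.ndarray,
    mean: np.ndarray = IMAGENET_MEAN,
    std: np.ndarray = IMAGENET_STD,
) -> np.ndarray:
    """Inverse of the normalization step; returns float pixels in [0, 1]."""
    arr = np.moveaxis(np.asarray(batch, dtype=np.float32), 1, -1)
    return arr * std + mean
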