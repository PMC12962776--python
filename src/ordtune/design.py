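"""Functional-run design and snake-stimulus rendering.

A functional run presents an elongated "snake" of connected compartments
while a marker steps through ordinal positions 1..7, ascending then
descending, with baseline epochs in between during which the marker sits at
the middle (15th) compartment.  The run design records the presented
ordinality at every TR; the pRF forward model consumes it directly.

The renderer draws a simplified snake as a seeded self-avoiding chain of
compartments on a jittered grid, with an optional directional color
gradient and a marker occupying one compartment.  Only layout variability,
chain connectivity, the gradient, and marker placement matter downstream.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

__all__ = [
    "DesignError",
    "RenderError",
    "RunDesign",
    "SnakeRenderSpec",
    "build_run_design",
    "render_snake_image",
    "save_png",
    "self_avoiding_chain",
]


class DesignError(ValueError):
    """Raised when run-timing parameters are mutually inconsistent."""


class RenderError(RuntimeError):
    """Raised when no valid snake layout can be placed on the canvas."""


@dataclass(frozen=True)
class RunDesign:
    """TR-locked sequence of presented ordinal positions for one run.

    Parameters
    ----------
    tr_seconds : float
        Sampling interval of the functional series.
    n_volumes : int
        Total acquired volumes, including the initial discarded frames.
    presented_ordinality : tuple of int
        Ordinal position shown at each volume (length ``n_volumes``).
        Baseline epochs are encoded as ``baseline_rank`` — the baseline
        marker position enters the forward model like any other rank.
    n_discard : int
        Initial volumes dropped before model fitting.
    cycle_count : int
        Number of ascending/descending presentation cycles per run.
    """

    tr_seconds: float
    n_volumes: int
    presented_ordinality: tuple
    n_discard: int
    cycle_count: int
    rank_min: int = 1
    rank_max: int = 7
    baseline_rank: int = 15

    def __post_init__(self):
        if self.tr_seconds <= 0:
            raise DesignError("tr_seconds must be positive")
        if len(self.presented_ordinality) != self.n_volumes:
            raise DesignError(
                f"presented_ordinality has length {len(self.presented_ordinality)} "
                f"but n_volumes={self.n_volumes}"
            )
        n_post = self.n_volumes - self.n_discard
        if n_post <= 0 or n_post % self.cycle_count:
            raise DesignError(
                f"post-discard length {n_post} not divisible by "
                f"cycle_count={self.cycle_count}"
            )
        for r in self.presented_ordinality:
            if r != self.baseline_rank and not (self.rank_min <= r <= self.rank_max):
                raise DesignError(
                    f"rank {r} outside [{self.rank_min}, {self.rank_max}] "
                    f"and not baseline ({self.baseline_rank})"
                )

    @property
    def duration_seconds(self) -> float:
        return self.n_volumes * self.tr_seconds

    @property
    def n_post_discard(self) -> int:
        return self.n_volumes - self.n_discard

    @property
    def ranks(self) -> np.ndarray:
        """Full presented-ordinality sequence as an array."""
        return np.asarray(self.presented_ordinality, dtype=float)

    @property
    def ranks_post_discard(self) -> np.ndarray:
        return self.ranks[self.n_discard:]

    def to_json(self) -> str:
        return json.dumps(
            {
                "tr_seconds": self.tr_seconds,
                "n_volumes": self.n_volumes,
                "presented_ordinality": list(self.presented_ordinality),
                "n_discard": self.n_discard,
                "cycle_count": self.cycle_count,
                "rank_min": self.rank_min,
                "rank_max": self.rank_max,
                "baseline_rank": self.baseline_rank,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "RunDesign":
        d = json.loads(text)
        d["presented_ordinality"] = tuple(d["presented_ordinality"])
        return cls(**d)


def build_run_design(
    tr_seconds: float = 1.5,
    volumes_per_rank: int = 2,
    baseline_seconds: float = 12.0,
    cycle_count: int = 4,
    n_discard: int = 8,
    rank_min: int = 1,
    rank_max: int = 7,
    baseline_rank: int = 15,
    n_volumes: int | None = None,
) -> RunDesign:
    """Construct the marker-sweep run design.

    One cycle is: ranks ``rank_min..rank_max`` ascending, each held for
    ``volumes_per_rank`` volumes; a baseline epoch of ``baseline_seconds``
    at the baseline position; the same ranks descending; a second baseline
    epoch.  Discarded frames precede cycle 1 and are encoded as baseline.

    The defaults reproduce the study timing: TR 1.5 s, 2 volumes per rank,
    12 s baselines, 4 cycles, 8 discarded frames — 184 volumes, 276 s.
    """
    if tr_seconds <= 0:
        raise DesignError("tr_seconds must be positive")
    if rank_max < rank_min:
        raise DesignError("empty rank range")
    if volumes_per_rank < 1:
        raise DesignError("volumes_per_rank must be >= 1")
    base_vol_f = baseline_seconds / tr_seconds
    baseline_volumes = int(round(base_vol_f))
    if abs(base_vol_f - baseline_volumes) > 1e-9:
        raise DesignError(
            f"baseline_seconds={baseline_seconds} is not a whole number of TRs"
        )
    ascending = [r for r in range(rank_min, rank_max + 1) for _ in range(volumes_per_rank)]
    baseline = [baseline_rank] * baseline_volumes
    cycle = ascending + baseline + ascending[::-1] + baseline
    seq = [baseline_rank] * n_discard + cycle * cycle_count
    if n_volumes is not None and n_volumes != len(seq):
        raise DesignError(
            f"cycle length {len(cycle)} x {cycle_count} cycles + {n_discard} "
            f"discard = {len(seq)} volumes, but n_volumes={n_volumes} was requested"
        )
    return RunDesign(
        tr_seconds=tr_seconds,
        n_volumes=len(seq),
        presented_ordinality=tuple(seq),
        n_discard=n_discard,
        cycle_count=cycle_count,
        rank_min=rank_min,
        rank_max=rank_max,
        baseline_rank=baseline_rank,
    )


# ---------------------------------------------------------------------------
# snake geometry and rendering

BACKGROUND_GRAY = 128
MARKER_COLOR = (255, 0, 0)


@dataclass(frozen=True)
class SnakeRenderSpec:
    """Parameters of one rendered snake image."""

    n_compartments: int = 30
    compartment_shape: str = "rectangle"  # or "circle"
    layout_seed: int = 0
    marker_rank: int = 1
    directional_gradient: bool = True
    canvas_pixels: tuple = (512, 512)
    compartment_lengths: tuple | None = None  # relative scales in (0, 1]

    def __post_init__(self):
        if not 1 <= self.marker_rank <= self.n_compartments:
            raise ValueError(
                f"marker_rank {self.marker_rank} outside 1..{self.n_compartments}"
            )
        if self.compartment_shape not in ("rectangle", "circle"):
            raise ValueError(f"unknown compartment shape {self.compartment_shape!r}")
        if self.compartment_lengths is not None:
            if len(self.compartment_lengths) != self.n_compartments:
                raise ValueError("compartment_lengths length mismatch")
            if any(not 0 < s <= 1 for s in self.compartment_lengths):
                raise ValueError("compartment_lengths must lie in (0, 1]")


def self_avoiding_chain(
    n: int,
    grid_shape: tuple,
    rng: np.random.Generator,
    max_attempts: int = 50,
    max_steps: int = 200_000,
) -> list:
    """Seeded self-avoiding walk of ``n`` cells on a grid.

    Randomized depth-first search with backtracking; each attempt restarts
    from a fresh random cell.  Returns a list of (row, col) cells in chain
    order, or raises :class:`RenderError` after bounded effort.
    """
    rows, cols = grid_shape
    if n > rows * cols:
        raise RenderError(f"{n} compartments cannot fit a {rows}x{cols} grid")
    moves = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    for _ in range(max_attempts):
        start = (int(rng.integers(rows)), int(rng.integers(cols)))
        path = [start]
        visited = {start}
        # stack of shuffled candidate moves per depth
        stacks = [list(rng.permutation(4))]
        steps = 0
        while path and steps < max_steps:
            steps += 1
            if len(path) == n:
                return path
            if stacks[-1]:
                d = moves[stacks[-1].pop()]
                r, c = path[-1][0] + d[0], path[-1][1] + d[1]
                if 0 <= r < rows and 0 <= c < cols and (r, c) not in visited:
                    path.append((r, c))
                    visited.add((r, c))
                    stacks.append(list(rng.permutation(4)))
            else:
                visited.discard(path.pop())
                stacks.pop()
    raise RenderError(
        f"failed to place a {n}-compartment self-avoiding chain on "
        f"{rows}x{cols} grid after {max_attempts} attempts"
    )


def _fill_shape(img, cy, cx, hh, hw, shape, color):
    """Paint a filled rectangle or inscribed ellipse centered at (cy, cx)."""
    y0, y1 = max(cy - hh, 0), min(cy + hh + 1, img.shape[0])
    x0, x1 = max(cx - hw, 0), min(cx + hw + 1, img.shape[1])
    if y0 >= y1 or x0 >= x1:
        return
    if shape == "rectangle":
        img[y0:y1, x0:x1] = color
    else:
        yy, xx = np.ogrid[y0:y1, x0:x1]
        mask = ((yy - cy) / max(hh, 1)) ** 2 + ((xx - cx) / max(hw, 1)) ** 2 <= 1.0
        img[y0:y1, x0:x1][mask] = color


def _gradient_color(i: int, n: int) -> tuple:
    """Directional gradient from deep red to yellow along the chain."""
    t = i / max(n - 1, 1)
    return (int(220 + 20 * t), int(40 + 180 * t), 40)


def render_snake_image(spec: SnakeRenderSpec) -> np.ndarray:
    """Render one snake stimulus; returns an (H, W, 3) uint8 array.

    Deterministic for a fixed ``layout_seed``.  Compartments sit in separate
    (non-touching) pixel regions but are chain-adjacent in layout order; the
    marker is drawn inside the marked compartment, leaving its rim visible.
    """
    rng = np.random.default_rng(spec.layout_seed)
    h, w = spec.canvas_pixels[1], spec.canvas_pixels[0]
    img = np.full((h, w, 3), BACKGROUND_GRAY, dtype=np.uint8)

    g = int(np.ceil(np.sqrt(2 * spec.n_compartments))) + 1
    cell = min(h, w) // (g + 1)
    if cell < 6:
        raise RenderError("canvas too small for the requested compartment count")
    chain = self_avoiding_chain(spec.n_compartments, (g, g), rng)
    margin_y = (h - g * cell) // 2
    margin_x = (w - g * cell) // 2
    jitter = max(cell // 12, 1)
    gap = max(cell // 6, 2)
    half = cell // 2 - gap

    for i, (r, c) in enumerate(chain):
        cy = margin_y + r * cell + cell // 2 + int(rng.integers(-jitter, jitter + 1))
        cx = margin_x + c * cell + cell // 2 + int(rng.integers(-jitter, jitter + 1))
        scale = 1.0
        if spec.compartment_lengths is not None:
            scale = spec.compartment_lengths[i]
        hh = max(int(half * scale), 2)
        hw = max(int(half * scale), 2)
        color = (
            _gradient_color(i, spec.n_compartments)
            if spec.directional_gradient
            else (255, 255, 255)
        )
        _fill_shape(img, cy, cx, hh, hw, spec.compartment_shape, color)
        if i + 1 == spec.marker_rank:
            mh = max(int(hh * 0.55), 1)
            mw = max(int(hw * 0.55), 1)
            _fill_shape(img, cy, cx, mh, mw, spec.compartment_shape, MARKER_COLOR)
    return img


def save_png(img: np.ndarray, path) -> None:
    from PIL import Image

    Image.fromarray(img).save(path)
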