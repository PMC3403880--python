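"""Two-pass rectangle layout engine for cloud diagrams.

The engine knows nothing about chemistry: it packs axis-aligned rectangles
(one per depicted structure) onto a canvas.  Pass one places rectangles
greedily, largest first, on a dense grid of candidate points, choosing at
each step the point with the lowest *overlap score* — a weighted sum of the
pairwise frame intersection areas and the pairwise center distances (the
distance term keeps the cloud compact).  Pass two is a derivative-free
hill-climbing refinement: each rectangle in turn tries short moves in the
eight compass directions and keeps the best one only if it lowers the total
score.  Mild repulsive potentials at the four canvas corners round the
cloud into an oval.

Everything is deterministic: ties are broken by scan order, not randomness.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "CloudItem",
    "LayoutConfig",
    "auto_grid",
    "pair_overlap_area",
    "placement_score",
    "corner_penalty",
    "total_score",
    "total_overlap_area",
    "greedy_place",
    "refine",
    "layout_svg",
]


@dataclass
class CloudItem:
    """A rectangle to place: identity, frame size, and mutable center position."""

    id: str
    width: float
    height: float
    x: float = 0.0
    y: float = 0.0
    pinned: bool = False

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValueError(f"item {self.id!r}: width and height must be positive")

    @property
    def area(self) -> float:
        return self.width * self.height


@dataclass(frozen=True)
class LayoutConfig:
    """Canvas geometry, candidate-grid density, score weights and refinement knobs.

    ``w_distance`` defaults to the reciprocal of the canvas diagonal so that a
    full-canvas center separation costs about as much as one unit square of
    overlap; pass 0 to disable compaction entirely.  ``step_size`` is the
    refinement move length in canvas units.  ``seed`` only matters when
    ``jitter`` is enabled; the algorithm itself is deterministic.
    """

    canvas_width: float = 2000.0
    canvas_height: float = 1400.0
    grid_nx: int = 80
    grid_ny: int = 56
    w_overlap: float = 1.0
    w_distance: float | None = None  # None -> 1 / canvas diagonal
    corner_strength: float = 0.0
    corner_eps_frac: float = 1e-6  # epsilon for corner repulsion, as fraction of diagonal
    step_size: float | None = None  # None -> grid pitch / 2
    step_floor_frac: float = 1.0 / 16.0  # floor for step halving, relative to initial step
    max_iterations: int = 500
    tolerance: float | None = None  # None -> 1e-6 * initial total score
    seed: int = 0
    jitter: float = 0.0

    def __post_init__(self) -> None:
        if self.canvas_width <= 0 or self.canvas_height <= 0:
            raise ValueError("canvas dimensions must be positive")
        if self.grid_nx < 2 or self.grid_ny < 2:
            raise ValueError("grid must be at least 2x2")
        if self.max_iterations < 0:
            raise ValueError("max_iterations must be >= 0")

    @property
    def diagonal(self) -> float:
        return math.hypot(self.canvas_width, self.canvas_height)

    @property
    def distance_weight(self) -> float:
        return 1.0 / self.diagonal if self.w_distance is None else self.w_distance

    @property
    def grid_points(self) -> np.ndarray:
        """Candidate centers, row-major (y rows scanned outer, x inner); shape (G, 2)."""
        xs = np.linspace(0.0, self.canvas_width, self.grid_nx)
        ys = np.linspace(0.0, self.canvas_height, self.grid_ny)
        gx, gy = np.meshgrid(xs, ys)  # row-major: y varies along axis 0
        return np.column_stack([gx.ravel(), gy.ravel()])


def auto_grid(items: list[CloudItem], canvas_width: float, canvas_height: float,
              pitch_fraction: float = 0.25, max_points: int = 200) -> tuple[int, int]:
    """Grid density from item sizes: pitch = ``pitch_fraction`` of the median
    item dimension, capped at ``max_points`` per axis."""
    dims = [d for it in items for d in (it.width, it.height)]
    pitch = max(float(np.median(dims)) * pitch_fraction, 1e-9) if dims else 1.0
    nx = int(min(max_points, max(2, round(canvas_width / pitch) + 1)))
    ny = int(min(max_points, max(2, round(canvas_height / pitch) + 1)))
    return nx, ny


def pair_overlap_area(a: CloudItem, b: CloudItem) -> float:
    """Intersection area of two axis-aligned frames; 0 when disjoint."""
    ox = min(a.x + a.width / 2, b.x + b.width / 2) - max(a.x - a.width / 2, b.x - b.width / 2)
    oy = min(a.y + a.height / 2, b.y + b.height / 2) - max(a.y - a.height / 2, b.y - b.height / 2)
    if ox <= 0 or oy <= 0:
        return 0.0
    return ox * oy


def _overlap_vec(x: np.ndarray, y: np.ndarray, w: float, h: float,
                 px: np.ndarray, py: np.ndarray, pw: np.ndarray, ph: np.ndarray) -> np.ndarray:
    """Overlap of a (w, h) frame at candidate centers (x, y) [shape (G, 1)]
    with placed frames (px, py, pw, ph) [shape (m,)]; returns (G, m)."""
    ox = np.minimum(x + w / 2, px + pw / 2) - np.maximum(x - w / 2, px - pw / 2)
    oy = np.minimum(y + h / 2, py + ph / 2) - np.maximum(y - h / 2, py - ph / 2)
    return np.clip(ox, 0.0, None) * np.clip(oy, 0.0, None)


def placement_score(candidate: CloudItem, placed: list[CloudItem], cfg: LayoutConfig) -> float:
    """Overlap score of one candidate placement against already placed items."""
    w_d = cfg.distance_weight
    s = 0.0
    for q in placed:
        s += cfg.w_overlap * pair_overlap_area(candidate, q)
        s += w_d * math.hypot(candidate.x - q.x, candidate.y - q.y)
    return s


def corner_penalty(item: CloudItem, cfg: LayoutConfig) -> float:
    """Repulsive potential from the four canvas corners: strength * sum 1/(eps + d)."""
    if cfg.corner_strength == 0.0:
        return 0.0
    eps = cfg.corner_eps_frac * cfg.diagonal
    w, h = cfg.canvas_width, cfg.canvas_height
    s = 0.0
    for cx, cy in ((0.0, 0.0), (w, 0.0), (0.0, h), (w, h)):
        s += 1.0 / (eps + math.hypot(item.x - cx, item.y - cy))
    return cfg.corner_strength * s


def total_score(items: list[CloudItem], cfg: LayoutConfig) -> float:
    """Full layout objective: pairwise overlap + pairwise distance + corner terms."""
    w_d = cfg.distance_weight
    s = 0.0
    for i in range(len(items)):
        a = items[i]
        for j in range(i + 1, len(items)):
            b = items[j]
            s += cfg.w_overlap * pair_overlap_area(a, b)
            s += w_d * math.hypot(a.x - b.x, a.y - b.y)
        s += corner_penalty(a, cfg)
    return s


def total_overlap_area(items: list[CloudItem]) -> float:
    """Sum of pairwise frame intersection areas (diagnostic)."""
    s = 0.0
    for i in range(len(items)):
        for j in range(i + 1, len(items)):
            s += pair_overlap_area(items[i], items[j])
    return s


def _inside(x: float, y: float, w: float, h: float, cfg: LayoutConfig) -> bool:
    return (x - w / 2 >= 0.0 and x + w / 2 <= cfg.canvas_width
            and y - h / 2 >= 0.0 and y + h / 2 <= cfg.canvas_height)


def greedy_place(items: list[CloudItem], cfg: LayoutConfig,
                 snapshot_after: tuple[int, ...] = (),
                 snapshots: list | None = None) -> list[CloudItem]:
    """First pass: sort by frame area (largest first), center the largest,
    then place each remaining item at the grid point with the lowest overlap
    score whose frame lies fully inside the canvas.

    Ties go to the first candidate in row-major grid scan order.  Optionally
    appends ``(count, placed-so-far, last_score)`` tuples to ``snapshots``
    after placing ``snapshot_after[i]`` items.

    Raises ``ValueError`` if any item is larger than the canvas.
    """
    for it in items:
        if it.width > cfg.canvas_width or it.height > cfg.canvas_height:
            raise ValueError(
                f"item {it.id!r} ({it.width:g}x{it.height:g}) does not fit the "
                f"canvas ({cfg.canvas_width:g}x{cfg.canvas_height:g})")

    order = sorted(items, key=lambda it: (-it.area, it.id))
    placed: list[CloudItem] = []
    grid = cfg.grid_points
    gx, gy = grid[:, 0], grid[:, 1]
    w_d = cfg.distance_weight
    snap_at = set(snapshot_after)
    last_score = 0.0

    rng = np.random.default_rng(cfg.seed) if cfg.jitter > 0 else None

    for it in order:
        it = replace(it)
        if not placed:
            it.x = cfg.canvas_width / 2.0
            it.y = cfg.canvas_height / 2.0
            last_score = 0.0
        else:
            feasible = ((gx - it.width / 2 >= 0.0) & (gx + it.width / 2 <= cfg.canvas_width)
                        & (gy - it.height / 2 >= 0.0) & (gy + it.height / 2 <= cfg.canvas_height))
            px = np.array([q.x for q in placed])
            py = np.array([q.y for q in placed])
            pw = np.array([q.width for q in placed])
            ph = np.array([q.height for q in placed])
            cx = gx[feasible, None]
            cy = gy[feasible, None]
            if cx.size == 0:
                # item fits the canvas but no grid point keeps it fully inside:
                # fall back to the canvas center
                it.x = cfg.canvas_width / 2.0
                it.y = cfg.canvas_height / 2.0
                last_score = placement_score(it, placed, cfg)
            else:
                ov = _overlap_vec(cx, cy, it.width, it.height, px, py, pw, ph)
                dist = np.hypot(cx - px, cy - py)
                scores = cfg.w_overlap * ov.sum(axis=1) + w_d * dist.sum(axis=1)
                best = int(np.argmin(scores))  # first minimum in row-major order
                it.x = float(cx[best, 0])
                it.y = float(cy[best, 0])
                last_score = float(scores[best])
        if rng is not None:
            it.x += float(rng.uniform(-cfg.jitter, cfg.jitter))
            it.y += float(rng.uniform(-cfg.jitter, cfg.jitter))
        placed.append(it)
        if snapshots is not None and len(placed) in snap_at:
            snapshots.append((len(placed), [replace(q) for q in placed], last_score))

    return placed


_DIRECTIONS = [(0.0, 0.0), (1.0, 0.0), (-1.0, 0.0), (0.0, 1.0), (0.0, -1.0),
               (1.0, 1.0), (1.0, -1.0), (-1.0, 1.0), (-1.0, -1.0)]


def _item_contribution(i: int, items: list[CloudItem], cfg: LayoutConfig) -> float:
    """Terms of the total score that change when item ``i`` moves."""
    it = items[i]
    w_d = cfg.distance_weight
    s = corner_penalty(it, cfg)
    for j, q in enumerate(items):
        if j == i:
            continue
        s += cfg.w_overlap * pair_overlap_area(it, q)
        s += w_d * math.hypot(it.x - q.x, it.y - q.y)
    return s


def refine(items: list[CloudItem], cfg: LayoutConfig,
           sweep_totals: list | None = None) -> list[CloudItem]:
    """Second pass: hill-climbing sweeps.

    Each sweep visits every item in order and tries nine candidates — stay
    put, or one step in each of the eight compass directions — accepting the
    best candidate only if it strictly lowers the total score (candidates
    leaving the canvas are skipped).  When a sweep improves the total by less
    than the tolerance, the step is halved once per stall down to a floor,
    after which refinement stops.  The total score is non-increasing by
    construction.  ``sweep_totals``, if given, collects the total score after
    every sweep.
    """
    items = [replace(it) for it in items]
    if cfg.max_iterations == 0 or len(items) < 2:
        if sweep_totals is not None and items:
            sweep_totals.append(total_score(items, cfg))
        return items

    total = total_score(items, cfg)
    tol = (1e-6 * abs(total)) if cfg.tolerance is None else cfg.tolerance
    pitch = cfg.canvas_width / max(cfg.grid_nx - 1, 1)
    step = (pitch / 2.0) if cfg.step_size is None else cfg.step_size
    floor = step * cfg.step_floor_frac

    for _ in range(cfg.max_iterations):
        sweep_start = total
        for i, it in enumerate(items):
            if it.pinned:
                continue
            base = _item_contribution(i, items, cfg)
            best_delta = 0.0
            best_pos = None
            x0, y0 = it.x, it.y
            for dx, dy in _DIRECTIONS[1:]:
                nx_, ny_ = x0 + dx * step, y0 + dy * step
                if not _inside(nx_, ny_, it.width, it.height, cfg):
                    continue
                it.x, it.y = nx_, ny_
                delta = _item_contribution(i, items, cfg) - base
                if delta < best_delta:
                    best_delta = delta
                    best_pos = (nx_, ny_)
            if best_pos is not None:
                it.x, it.y = best_pos
                total += best_delta
            else:
                it.x, it.y = x0, y0
        if sweep_totals is not None:
            sweep_totals.append(total)
        if sweep_start - total < tol:
            if step / 2.0 >= floor:
                step /= 2.0
            else:
                break
    return items


def layout_svg(items: list[CloudItem], cfg: LayoutConfig) -> str:
    """Debug rendering: the layout as bare SVG rectangles (id, x, y, w, h)."""
    parts = [
        f'<svg xmlns="http://www.w3.org/2000/svg" version="1.1" '
        f'width="{cfg.canvas_width:g}" height="{cfg.canvas_height:g}">',
        f'<rect x="0" y="0" width="{cfg.canvas_width:g}" height="{cfg.canvas_height:g}" '
        f'fill="white" stroke="#888"/>',
    ]
    for it in items:
        parts.append(
            f'<rect data-id="{it.id}" x="{it.x - it.width / 2:.3f}" '
            f'y="{it.y - it.height / 2:.3f}" width="{it.width:.3f}" '
            f'height="{it.height:.3f}" fill="none" stroke="#3366cc"/>')
    parts.append("</svg>")
    return "\n".join(parts)
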