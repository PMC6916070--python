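"""Muller-plot geometry: nested stacked-band layout of a clone forest.

Each clone occupies a horizontal band whose height at time *t* equals the
total abundance of its subtree.  A clone's own mass is split half below and
half above its children's bands, so a descendant clone visually *emerges from
within* its ancestor's polygon; siblings are stacked contiguously between the
two half-pads.  Rendering bands in ancestor-first paint order leaves exactly
the clone's own abundance visible at every time.

The vertical ordering of clones is deterministic: depth-first preorder with
roots (and, recursively, siblings) sorted by origin time, then total mass
descending, then identifier.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import PchipInterpolator, interp1d

from .core import FREQUENCY, SIZE, CloneHistory, validate
from .errors import ParameterError, ValidationError

__all__ = [
    "LayoutOptions",
    "MullerLayout",
    "subtree_sizes",
    "clone_order",
    "refine_grid",
    "compute_bands",
    "visible_thickness",
]

NEVER = np.inf  # origin-time sentinel for clones that never appear


@dataclass(frozen=True)
class LayoutOptions:
    """Knobs controlling grid refinement and band geometry.

    interpolation
        ``"none"`` keeps the observed grid; ``"linear"`` subdivides each
        interval; ``"monotone_spline"`` uses shape-preserving cubic (PCHIP)
        interpolation, which cannot overshoot between points.
    points_per_interval
        Number of equal sub-steps per observed interval (>= 1).
    emergence
        Where a clone's wedge opens: at the last observed zero before its
        first positive size (``"previous_point"``, default) or halfway
        between that point and the first positive one (``"midpoint"``).
    root_gap
        Vertical gap inserted between root bands, in data units.
    scale
        ``None`` (default) adopts the history's own scale; passing
        ``"frequency"`` explicitly asserts the history is normalized.
    """

    scale: str | None = None
    interpolation: str = "none"
    points_per_interval: int = 1
    emergence: str = "previous_point"
    root_gap: float = 0.0

    def __post_init__(self) -> None:
        if self.scale not in (None, SIZE, FREQUENCY):
            raise ParameterError(f"unknown scale {self.scale!r}")
        if self.interpolation not in ("none", "linear", "monotone_spline"):
            raise ParameterError(f"unknown interpolation {self.interpolation!r}")
        if self.points_per_interval < 1:
            raise ParameterError("points_per_interval must be >= 1")
        if self.emergence not in ("previous_point", "midpoint"):
            raise ParameterError(f"unknown emergence mode {self.emergence!r}")
        if self.root_gap < 0:
            raise ParameterError("root_gap must be non-negative")


@dataclass
class MullerLayout:
    """Band geometry of a Muller plot on a common time grid.

    ``bands[clone] = (lower, upper)`` arrays over ``time_grid``; the band
    height is the clone's subtree total.  ``paint_order`` lists ancestors
    before descendants; ``order_index`` is each clone's rank in the canonical
    vertical ordering.
    """

    time_grid: np.ndarray
    bands: dict[str, tuple[np.ndarray, np.ndarray]]
    paint_order: list[str]
    order_index: dict[str, int] = field(default_factory=dict)

    def band_height(self, clone: str) -> np.ndarray:
        lo, hi = self.bands[clone]
        return hi - lo

    def to_frame(self):
        """Long table (clone, time, lower, upper) for external plotting."""
        import pandas as pd

        rows = []
        for c in self.paint_order:
            lo, hi = self.bands[c]
            for t, l, u in zip(self.time_grid, lo, hi):
                rows.append((c, t, l, u))
        return pd.DataFrame(rows, columns=["clone_id", "time", "lower", "upper"])


def _check(history: CloneHistory) -> None:
    problems = validate(history)
    if problems:
        raise ValidationError("; ".join(problems))


def subtree_sizes(history: CloneHistory) -> np.ndarray:
    """Clone x time matrix of subtree totals (own size + all descendants)."""
    _check(history)
    out = history.sizes.copy()
    children = history.children_map()
    idx = {c: i for i, c in enumerate(history.clone_ids)}

    def visit(c: str) -> None:
        for d in children[c]:
            visit(d)
            out[idx[c]] += out[idx[d]]

    for r in history.roots():
        visit(r)
    return out


def origin_index(history: CloneHistory) -> dict[str, float]:
    """First time *index* with positive size per clone; inf if never positive."""
    out: dict[str, float] = {}
    for i, c in enumerate(history.clone_ids):
        pos = np.nonzero(history.sizes[i] > 0)[0]
        out[c] = float(pos[0]) if pos.size else NEVER
    return out


def clone_order(history: CloneHistory) -> list[str]:
    """Canonical depth-first preorder of the forest.

    Roots, and recursively each clone's children, are sorted by origin time
    (never-positive clones last), ties broken by total summed size descending,
    then lexicographically by id.  Deterministic for identical input.
    """
    _check(history)
    origin = origin_index(history)
    totals = {c: float(history.sizes[i].sum()) for i, c in enumerate(history.clone_ids)}
    children = history.children_map()

    def key(c: str):
        return (origin[c], -totals[c], c)

    out: list[str] = []

    def visit(c: str) -> None:
        out.append(c)
        for d in sorted(children[c], key=key):
            visit(d)

    for r in sorted(history.roots(), key=key):
        visit(r)
    return out


def refine_grid(history: CloneHistory, options: LayoutOptions) -> CloneHistory:
    """Interpolate clone trajectories onto a subdivided time grid.

    Each observed interval is split into ``points_per_interval`` equal steps
    and trajectories are interpolated (linear, or monotone cubic).  Values are
    pinned to exactly zero before each clone's emergence anchor, negatives are
    clipped, and on frequency scale each refined column is renormalized to
    sum 1.  ``interpolation="none"`` returns the history unchanged.
    """
    if options.interpolation == "none" or history.n_times < 2:
        return history
    _check(history)
    t = history.times
    m = options.points_per_interval
    grid = np.concatenate(
        [np.linspace(t[k], t[k + 1], m, endpoint=False) for k in range(t.size - 1)]
        + [t[-1:]]
    )

    new_sizes = np.zeros((history.n_clones, grid.size))
    for i in range(history.n_clones):
        y = history.sizes[i]
        if options.interpolation == "monotone_spline" and t.size >= 2:
            f = PchipInterpolator(t, y)
        else:
            f = interp1d(t, y, kind="linear")
        vals = np.asarray(f(grid), dtype=float)

        pos = np.nonzero(y > 0)[0]
        if pos.size and pos[0] > 0:
            j = int(pos[0])
            anchor = (
                t[j - 1]
                if options.emergence == "previous_point"
                else 0.5 * (t[j - 1] + t[j])
            )
            vals[grid < anchor] = 0.0
            # linear ramp from the anchor to the first positive observation
            seg = (grid >= anchor) & (grid < t[j])
            if np.any(seg):
                vals[seg] = y[j] * (grid[seg] - anchor) / (t[j] - anchor)
        elif not pos.size:
            vals[:] = 0.0
        new_sizes[i] = np.clip(vals, 0.0, None)

    if history.scale == FREQUENCY:
        totals = new_sizes.sum(axis=0)
        cols = totals > 0
        new_sizes[:, cols] = new_sizes[:, cols] / totals[cols]

    out = history.copy()
    out.times = grid
    out.sizes = new_sizes
    out.time_labels = None
    return out


def compute_bands(history: CloneHistory, options: LayoutOptions | None = None) -> MullerLayout:
    """Compute the nested band layout.

    Roots are stacked from zero (separated by ``root_gap``) in canonical
    order; within each clone's band the clone's own mass pads the bottom and
    top halves and the children fill the middle contiguously.  On frequency
    scale the history must already be normalized (each column sums to 1 or 0).
    """
    options = options or LayoutOptions()
    history = refine_grid(history, options)
    _check(history)
    effective_scale = options.scale or history.scale
    if effective_scale == FREQUENCY:
        sums = history.column_sums()
        bad = np.nonzero((sums > 1e-12) & (np.abs(sums - 1.0) > 1e-6))[0]
        if history.scale != FREQUENCY or bad.size:
            raise ParameterError(
                "frequency-scale layout requires a normalized frequency history "
                "(run normalize_frequencies first)"
            )

    order = clone_order(history)
    idx = {c: i for i, c in enumerate(history.clone_ids)}
    child_order = {c: [d for d in order if history.parent_of.get(d) == c] for c in history.clone_ids}
    n_t = history.n_times
    bands: dict[str, tuple[np.ndarray, np.ndarray]] = {}

    # sequential half-mass accumulation: lower pad, children, upper pad
    def place(c: str, lower: np.ndarray) -> np.ndarray:
        lo = lower.copy()
        cursor = lo + history.sizes[idx[c]] / 2.0
        for d in child_order[c]:
            cursor = place(d, cursor)
        hi = cursor + history.sizes[idx[c]] / 2.0
        bands[c] = (lo, hi)
        return hi

    base = np.zeros(n_t)
    for r in (c for c in order if history.parent_of.get(c) is None):
        base = place(r, base) + options.root_gap

    paint = order  # preorder: ancestors always precede descendants
    return MullerLayout(
        time_grid=history.times.copy(),
        bands=bands,
        paint_order=paint,
        order_index={c: k for k, c in enumerate(order)},
    )


def visible_thickness(layout: MullerLayout, history: CloneHistory) -> np.ndarray:
    """Clone x time matrix of the mass left visible after children overpaint.

    Equals each clone's band height minus its children's band heights, which
    by construction is exactly its own size at every time -- the conservation
    check for the layout.
    """
    children = history.children_map()
    out = np.zeros((history.n_clones, layout.time_grid.size))
    for i, c in enumerate(history.clone_ids):
        h = layout.band_height(c).copy()
        for d in children[c]:
            h -= layout.band_height(d)
        out[i] = h
    return out
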