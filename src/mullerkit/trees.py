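"""Tree-centric views of a clone history: origin-time dendrogram, Newick, DOT.

The *evogram* is a dendrogram whose horizontal axis is each clone's origin
time (the first time point at which its abundance is positive), so the
timing of clonal expansions is read directly off the x axis.  Vertical
positions reuse the Muller layout's canonical clone order so both views
stay visually consistent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np

from . import dotio
from .core import CloneHistory, validate
from .errors import ValidationError
from .layout import NEVER, clone_order

__all__ = ["EvogramLayout", "origin_times", "evogram_layout", "to_newick", "to_graph"]


@dataclass
class EvogramLayout:
    """Coordinates of the origin-time dendrogram.

    ``node_x`` is each clone's origin time; never-observed clones are placed
    at the last time point and listed in ``never_observed``.  ``edges`` are
    elbow polylines (lists of (x, y) vertices).  ``node_size`` is the clone's
    maximum abundance over the time course.
    """

    node_x: dict[str, float]
    node_y: dict[str, float]
    edges: list[tuple[str, str, list[tuple[float, float]]]]
    node_size: dict[str, float]
    never_observed: list[str]


def _check(history: CloneHistory) -> None:
    problems = validate(history)
    if problems:
        raise ValidationError("; ".join(problems))


def origin_times(history: CloneHistory) -> dict[str, float]:
    """First time with positive size per clone; ``inf`` if never positive."""
    _check(history)
    out: dict[str, float] = {}
    for i, c in enumerate(history.clone_ids):
        pos = np.nonzero(history.sizes[i] > 0)[0]
        out[c] = float(history.times[pos[0]]) if pos.size else NEVER
    return out


def evogram_layout(history: CloneHistory) -> EvogramLayout:
    """Lay out the clone forest as an origin-time dendrogram.

    x = origin time, y = rank in the canonical clone order (evenly spaced).
    Each parent-child edge is an elbow: a vertical connector at the parent's
    x from the parent's y to the child's y, then a horizontal segment at the
    child's y out to the child's x.  A child observed before its parent is
    geometrically possible in noisy reconstructions; it is kept as-is and a
    warning is emitted.
    """
    _check(history)
    origin = origin_times(history)
    order = clone_order(history)
    last_t = float(history.times[-1]) if history.n_times else 0.0
    never = [c for c in order if not np.isfinite(origin[c])]
    node_x = {c: (origin[c] if np.isfinite(origin[c]) else last_t) for c in order}
    node_y = {c: float(k) for k, c in enumerate(order)}
    edges = []
    for c in order:
        p = history.parent_of.get(c)
        if p is None:
            continue
        if node_x[c] < node_x[p]:
            warnings.warn(
                f"clone {c!r} observed before its parent {p!r} "
                f"({node_x[c]:g} < {node_x[p]:g})",
                stacklevel=2,
            )
        elbow = [
            (node_x[p], node_y[p]),
            (node_x[p], node_y[c]),
            (node_x[c], node_y[c]),
        ]
        edges.append((p, c, elbow))
    node_size = {
        c: float(history.sizes[history.index(c)].max()) if history.n_times else 0.0
        for c in order
    }
    return EvogramLayout(node_x, node_y, edges, node_size, never)


def _newick_escape(name: str) -> str:
    if any(ch in name for ch in " (),:;[]'\t\n"):
        return "'" + name.replace("'", "''") + "'"
    return name


def to_newick(history: CloneHistory) -> str:
    """Serialize the clone tree to Newick with origin-time branch lengths.

    Branch length of a clone is its origin time minus its parent's origin
    time; a root's branch length is its origin minus the first time point.
    Internal nodes are labelled (clones are observed taxa, not inferred
    ancestors).  A multi-root forest is wrapped under an artificial root of
    branch length 0 (with a warning); never-observed clones get branch
    length 0 (with a warning).
    """
    _check(history)
    origin = origin_times(history)
    t0 = float(history.times[0]) if history.n_times else 0.0
    order = clone_order(history)
    children = {c: [d for d in order if history.parent_of.get(d) == c] for c in history.clone_ids}

    never = [c for c in order if not np.isfinite(origin[c])]
    if never:
        warnings.warn(
            f"never-observed clones {never} assigned branch length 0", stacklevel=2
        )

    def branch_length(c: str) -> float:
        p = history.parent_of.get(c)
        ref = t0 if p is None else origin[p]
        bl = origin[c] - ref
        if not np.isfinite(bl):
            return 0.0
        return max(bl, 0.0)

    def fmt(x: float) -> str:
        return f"{x:g}"

    def render(c: str) -> str:
        label = _newick_escape(c) + ":" + fmt(branch_length(c))
        kids = children[c]
        if not kids:
            return label
        return "(" + ",".join(render(d) for d in kids) + ")" + label

    roots = [c for c in order if history.parent_of.get(c) is None]
    if len(roots) == 1:
        return render(roots[0]) + ";"
    warnings.warn(
        f"forest with {len(roots)} roots wrapped under artificial root", stacklevel=2
    )
    return "(" + ",".join(render(r) for r in roots) + ")root:0;"


def to_graph(
    history: CloneHistory, attribute: str | None = None
) -> tuple[nx.DiGraph, str]:
    """Directed parent->child graph plus its DOT serialization.

    Node attributes carry the requested per-clone attribute (if any); the
    DOT text labels every node with its clone id.
    """
    _check(history)
    g = nx.DiGraph()
    g.add_nodes_from(history.clone_ids)
    attrs: dict[str, dict[str, object]] = {}
    if attribute is not None:
        mapping = history.attributes.get(attribute, {})
        for c in history.clone_ids:
            if c in mapping:
                g.nodes[c][attribute] = mapping[c]
                attrs[c] = {attribute: mapping[c]}
    edges = [
        (history.parent_of[c], c)
        for c in history.clone_ids
        if history.parent_of.get(c) is not None
    ]
    g.add_edges_from(edges)
    dot = dotio.to_dot(edges, nodes=history.clone_ids, node_attrs=attrs)
    return g, dot
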