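"""Static and animated rendering of Muller plots and origin-time dendrograms.

SVG is the primary output (every clone polygon carries a ``clone-<id>`` group
id, so figures are inspectable and testable); PNG is available through the
same entry points.  Animations are emitted as zero-padded PNG frame sequences
with fixed global axes, optionally assembled into a GIF.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
matplotlib.rcParams["svg.hashsalt"] = "mullerkit"  # reproducible SVG ids

import matplotlib.pyplot as plt
import numpy as np
from matplotlib import colormaps
from matplotlib.colors import Normalize, hsv_to_rgb, to_hex

from .core import CloneHistory
from .errors import DegenerateInputError, ParameterError
from .layout import LayoutOptions, MullerLayout, compute_bands, visible_thickness
from .trees import EvogramLayout, evogram_layout

__all__ = [
    "StyleSpec",
    "render_muller",
    "render_evogram",
    "color_by_attribute",
    "clone_colors",
    "place_labels",
    "animate",
]


@dataclass(frozen=True)
class StyleSpec:
    """Appearance options for Muller and dendrogram figures.

    color_mode
        ``"by_clone"`` (hues spaced along the canonical clone order, the
        default), ``"by_attribute"`` (requires ``attribute_name``), or
        ``"custom_map"`` (requires ``palette`` to map every clone).
    palette
        For ``by_attribute``: a named matplotlib colormap (numeric
        attributes) or an ordered color list (categorical).  For
        ``custom_map``: a ``clone -> color`` mapping.
    label_mode
        ``"none"``, ``"all"``, or ``"listed"`` (label the clones in
        ``labels``).
    """

    color_mode: str = "by_clone"
    attribute_name: str | None = None
    palette: object = None
    label_mode: str = "none"
    labels: tuple = ()
    background: str = "white"
    xlabel: str = "time"
    ylabel: str | None = None
    figsize: tuple = (8.0, 4.0)
    edge_color: str = "white"
    edge_width: float = 0.3

    def __post_init__(self) -> None:
        if self.color_mode not in ("by_clone", "by_attribute", "custom_map"):
            raise ParameterError(f"unknown color_mode {self.color_mode!r}")
        if self.label_mode not in ("none", "all", "listed"):
            raise ParameterError(f"unknown label_mode {self.label_mode!r}")
        if self.color_mode == "by_attribute" and not self.attribute_name:
            raise ParameterError("color_mode='by_attribute' requires attribute_name")


def clone_colors(order: list[str]) -> dict[str, str]:
    """Default palette: evenly spaced hues along the canonical clone order."""
    n = max(len(order), 1)
    out = {}
    for k, c in enumerate(order):
        h = (k * 0.61803398875) % 1.0 if n > 12 else k / n
        out[c] = to_hex(hsv_to_rgb((h, 0.55, 0.85)))
    return out


def color_by_attribute(
    history: CloneHistory, attribute_name: str, palette=None
) -> dict[str, str]:
    """Deterministic clone -> hex color mapping from a per-clone attribute.

    Numeric attributes map monotonically onto a continuous colormap (equal
    values get equal colors; a constant attribute collapses to one color).
    Categorical attributes cycle an ordered palette in order of first
    appearance over ``clone_ids``.
    """
    mapping = history.attributes.get(attribute_name)
    if mapping is None:
        raise ParameterError(f"attribute {attribute_name!r} not present in history")
    missing = [c for c in history.clone_ids if c not in mapping]
    if missing:
        raise ParameterError(
            f"attribute {attribute_name!r} missing for clones {missing}"
        )
    values = [mapping[c] for c in history.clone_ids]
    numeric = all(isinstance(v, (int, float)) and not isinstance(v, bool) for v in values)
    if numeric:
        cmap = colormaps[palette if isinstance(palette, str) else "viridis"]
        lo, hi = float(min(values)), float(max(values))
        norm = Normalize(vmin=lo, vmax=hi if hi > lo else lo + 1.0)
        return {c: to_hex(cmap(norm(float(mapping[c])))) for c in history.clone_ids}
    categories = list(dict.fromkeys(str(v) for v in values))
    if isinstance(palette, (list, tuple)) and palette:
        colors = list(palette)
    else:
        cmap = colormaps["tab10"]
        colors = [to_hex(cmap(i % 10)) for i in range(len(categories))]
    cat_color = {cat: colors[i % len(colors)] for i, cat in enumerate(categories)}
    return {c: to_hex(cat_color[str(mapping[c])]) for c in history.clone_ids}


def _resolve_colors(
    layout: MullerLayout, history: CloneHistory, style: StyleSpec
) -> dict[str, str]:
    if style.color_mode == "by_attribute":
        return color_by_attribute(history, style.attribute_name, style.palette)
    if style.color_mode == "custom_map":
        mapping = dict(style.palette or {})
        missing = [c for c in history.clone_ids if c not in mapping]
        if missing:
            raise ParameterError(f"custom color map missing clones {missing}")
        return {c: to_hex(mapping[c]) for c in history.clone_ids}
    return clone_colors(layout.paint_order)


def place_labels(
    layout: MullerLayout, history: CloneHistory, clones: list[str] | None = None
) -> dict[str, tuple[float, float]]:
    """Label anchors: x at the time of maximum visible thickness (earliest
    tie), y at the band midpoint there.  Zero-mass clones are omitted."""
    clones = list(clones) if clones is not None else list(layout.paint_order)
    unknown = [c for c in clones if c not in layout.bands]
    if unknown:
        raise ParameterError(f"unknown clones {unknown}")
    children = history.children_map()
    out: dict[str, tuple[float, float]] = {}
    for c in clones:
        thickness = layout.band_height(c).copy()
        for d in children.get(c, []):
            if d in layout.bands:
                thickness -= layout.band_height(d)
        k = int(np.argmax(thickness))  # argmax takes the earliest tie
        if thickness[k] <= 0:
            continue
        lo, hi = layout.bands[c]
        out[c] = (float(layout.time_grid[k]), float(0.5 * (lo[k] + hi[k])))
    return out


def _draw_muller(
    ax, layout: MullerLayout, history: CloneHistory, style: StyleSpec
) -> None:
    colors = _resolve_colors(layout, history, style)
    idx = {c: i for i, c in enumerate(history.clone_ids)}
    x = layout.time_grid
    for z, c in enumerate(layout.paint_order):
        if history.sizes[idx[c]].max() <= 0:
            continue  # no visible mass, no path
        lo, hi = layout.bands[c]
        xs = np.concatenate([x, x[::-1]])
        ys = np.concatenate([lo, hi[::-1]])
        ax.fill(
            xs,
            ys,
            gid=f"clone-{c}",
            facecolor=colors[c],
            edgecolor=style.edge_color,
            linewidth=style.edge_width,
            zorder=2 + z,
        )
    wanted = None
    if style.label_mode == "all":
        wanted = list(layout.paint_order)
    elif style.label_mode == "listed":
        wanted = list(style.labels)
    if wanted:
        for c, (lx, ly) in place_labels(layout, history, wanted).items():
            ax.text(
                lx,
                ly,
                c,
                gid=f"label-{c}",
                ha="center",
                va="center",
                fontsize=8,
                zorder=2 + len(layout.paint_order) + 1,
            )


def _finish(fig, ax, history: CloneHistory, style: StyleSpec, out_path) -> Path:
    ax.set_xlabel(style.xlabel)
    ax.set_ylabel(
        style.ylabel if style.ylabel is not None else history.scale
    )
    if history.time_labels is not None and len(history.time_labels) <= 30:
        ax.set_xticks(history.times)
        ax.set_xticklabels(history.time_labels)
    fig.patch.set_facecolor(style.background)
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    fmt = out_path.suffix.lstrip(".") or "svg"
    metadata = {"Date": None} if fmt == "svg" else None
    fig.savefig(out_path, format=fmt, metadata=metadata)
    plt.close(fig)
    return out_path


def render_muller(
    layout: MullerLayout,
    history: CloneHistory,
    style: StyleSpec | None = None,
    out_path="muller.svg",
) -> Path:
    """Render a Muller plot to SVG or PNG (chosen by the file suffix).

    One filled polygon per clone with nonzero mass, painted ancestors-first;
    in SVG each polygon is a group with id ``clone-<id>`` and each label
    ``label-<id>``, so the output is machine-checkable.
    """
    style = style or StyleSpec()
    fig, ax = plt.subplots(figsize=style.figsize)
    _draw_muller(ax, layout, history, style)
    ax.set_xlim(float(layout.time_grid[0]), float(layout.time_grid[-1]))
    return _finish(fig, ax, history, style, out_path)


def render_evogram(
    history: CloneHistory,
    style: StyleSpec | None = None,
    out_path="evogram.svg",
    evo: EvogramLayout | None = None,
    max_marker: float = 600.0,
) -> Path:
    """Render the origin-time dendrogram (elbow edges, origin-time x axis).

    Marker areas scale with each clone's maximum abundance over time.
    """
    style = style or StyleSpec()
    evo = evo or evogram_layout(history)
    colors = _resolve_colors_evogram(history, style, evo)
    fig, ax = plt.subplots(figsize=style.figsize)
    for p, c, elbow in evo.edges:
        xs, ys = zip(*elbow)
        ax.plot(xs, ys, color="0.4", linewidth=1.0, zorder=1)
    top = max(evo.node_size.values()) if evo.node_size else 1.0
    top = top if top > 0 else 1.0
    for c in evo.node_x:
        ax.scatter(
            evo.node_x[c],
            evo.node_y[c],
            s=25.0 + max_marker * evo.node_size[c] / top,
            gid=f"clone-{c}",
            color=colors[c],
            zorder=2,
        )
        ax.annotate(c, (evo.node_x[c], evo.node_y[c]), textcoords="offset points",
                    xytext=(6, 6), fontsize=8)
    ax.set_yticks([])
    ax.invert_yaxis()
    return _finish(fig, ax, history, style, out_path)


def _resolve_colors_evogram(history, style, evo):
    if style.color_mode == "by_attribute":
        return color_by_attribute(history, style.attribute_name, style.palette)
    if style.color_mode == "custom_map":
        mapping = dict(style.palette or {})
        missing = [c for c in history.clone_ids if c not in mapping]
        if missing:
            raise ParameterError(f"custom color map missing clones {missing}")
        return {c: to_hex(mapping[c]) for c in history.clone_ids}
    return clone_colors(list(evo.node_x))


def animate(
    history: CloneHistory,
    options: LayoutOptions | None = None,
    style: StyleSpec | None = None,
    out_dir="frames",
    mode: str = "muller",
    gif_path=None,
    fps: float = 4.0,
) -> list[Path]:
    """Write one frame per time point, with fixed global axes.

    ``mode="muller"``: frame *k* shows the layout restricted to times <= t_k.
    ``mode="dendrogram"``: frame *k* shows only clones with origin <= t_k.
    Frames are ``frame_0000.png`` ... and can be assembled into a GIF.
    """
    if history.n_times < 2:
        raise DegenerateInputError("animation needs at least 2 time points")
    if mode not in ("muller", "dendrogram"):
        raise ParameterError(f"unknown animation mode {mode!r}")
    options = options or LayoutOptions()
    style = style or StyleSpec()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    full_layout = compute_bands(history, options)
    xlim = (float(history.times[0]), float(history.times[-1]))
    tops = [hi.max() for (_, hi) in full_layout.bands.values()]
    ylim = (0.0, max(tops) * 1.02 if tops else 1.0)
    evo_full = evogram_layout(history) if mode == "dendrogram" else None

    frames: list[Path] = []
    for k in range(history.n_times):
        path = out_dir / f"frame_{k:04d}.png"
        fig, ax = plt.subplots(figsize=style.figsize)
        if mode == "muller":
            partial = history.copy()
            partial.times = history.times[: k + 1]
            partial.sizes = history.sizes[:, : k + 1]
            if partial.time_labels is not None:
                partial.time_labels = partial.time_labels[: k + 1]
            layout_k = compute_bands(partial, options)
            _draw_muller(ax, layout_k, partial, style)
            ax.set_ylim(*ylim)
        else:
            t_k = float(history.times[k])
            shown = {c for c in evo_full.node_x if evo_full.node_x[c] <= t_k}
            colors = _resolve_colors_evogram(history, style, evo_full)
            for p, c, elbow in evo_full.edges:
                if p in shown and c in shown:
                    xs, ys = zip(*elbow)
                    ax.plot(xs, ys, color="0.4", linewidth=1.0, zorder=1)
            top = max(evo_full.node_size.values()) or 1.0
            for c in shown:
                ax.scatter(
                    evo_full.node_x[c],
                    evo_full.node_y[c],
                    s=25.0 + 600.0 * evo_full.node_size[c] / top,
                    gid=f"clone-{c}",
                    color=colors[c],
                    zorder=2,
                )
            ax.set_ylim(-1, len(evo_full.node_y))
            ax.invert_yaxis()
        ax.set_xlim(*xlim)
        ax.set_xlabel(style.xlabel)
        fig.savefig(path)
        plt.close(fig)
        frames.append(path)

    if gif_path is not None:
        import imageio.v3 as iio

        images = [iio.imread(p)[..., :3] for p in frames]  # GIF wants RGB
        iio.imwrite(Path(gif_path), images, duration=1000.0 / fps, loop=0)
    return frames
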