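"""Static rendering of the twelve graph types and composed pathway figures.

All output is produced through matplotlib's Agg backend.  SVG export is
byte-stable for identical input: the SVG hash salt is pinned and the
creation-date metadata is suppressed.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field

os.environ.setdefault("MPLBACKEND", "Agg")

import matplotlib

matplotlib.rcParams["svg.hashsalt"] = "isotrace"

import matplotlib.pyplot as plt
import numpy as np

from . import analytics
from .analytics import GroupStat
from .exceptions import MissingInputError
from .io import EscherMapView, MapNode, TraceDataset, map_data_to_nodes

logger = logging.getLogger(__name__)

GRAPH_TYPES = (
    "mid",
    "stacked_mid",
    "single_isotopologue_label",
    "kinetic_single_label",
    "abundance",
    "stacked_abundance",
    "single_isotopologue_abundance",
    "kinetic_single_abundance",
    "quantitative_abundance",
    "kinetic_total_abundance",
    "enrichment",
    "kinetic_enrichment",
)

#: Built-in color schemes; the largest default scheme has exactly 15 entries.
COLOR_SCHEMES: dict[str, list[str]] = {
    "default15": [
        "#1f77b4", "#ff7f0e", "#2ca02c", "#d62728", "#9467bd",
        "#8c564b", "#e377c2", "#7f7f7f", "#bcbd22", "#17becf",
        "#aec7e8", "#ffbb78", "#98df8a", "#ff9896", "#c5b0d5",
    ],
    "grayscale4": ["#222222", "#666666", "#999999", "#cccccc"],
}

__all__ = [
    "GRAPH_TYPES",
    "COLOR_SCHEMES",
    "GraphSpec",
    "GraphStats",
    "FigureLayout",
    "CarbonDiagram",
    "compute_graph_stats",
    "render_graph",
    "compute_layout",
    "render_pathway_figure",
    "render_carbon_diagram",
    "carbon_diagram_figure",
    "export",
]


@dataclass
class GraphSpec:
    """One graph: type, fragment, group selection, and presentation knobs."""

    graph_type: str
    fragment: str
    groups: list[str] | None = None  # None = all groups in dataset order
    isotopologue: int | None = None  # M-number for single-isotopologue types
    title: str | None = None
    ylabel: str | None = None
    plot_individual_values: bool = False
    color_scheme: str = "default15"

    def __post_init__(self) -> None:
        if self.graph_type not in GRAPH_TYPES:
            raise ValueError(
                f"unknown graph type {self.graph_type!r}; expected one of "
                f"{', '.join(GRAPH_TYPES)}"
            )


@dataclass
class GraphStats:
    """Statistics assembled for one graph, decoupled from drawing."""

    kind: str  # 'bar' | 'stacked' | 'line'
    categories: list[str]
    groups: list[str]
    stats: dict[str, list[GroupStat]] = field(default_factory=dict)
    series: dict[str, list[GroupStat]] = field(default_factory=dict)
    default_ylabel: str = ""


_KINETIC = {
    "kinetic_single_label": "isotopologue_fraction",
    "kinetic_single_abundance": "isotopologue_abundance",
    "kinetic_total_abundance": None,  # resolved against normalization state
    "kinetic_enrichment": "enrichment",
}


def _abundance_quantity(data: TraceDataset) -> str:
    return (
        "normalized_abundance" if data.normalized_abundance is not None else "abundance"
    )


def _selected_groups(data: TraceDataset, spec: GraphSpec):
    if spec.groups is None:
        return list(data.groups)
    return [data.group(name) for name in spec.groups]


def compute_graph_stats(data: TraceDataset, spec: GraphSpec) -> GraphStats:
    """Assemble the per-category / per-group statistics a graph type needs.

    Raises :class:`MissingInputError` naming the missing prerequisite (time
    points, quantitative standards, element count of tracer).
    """
    groups = _selected_groups(data, spec)
    group_names = [g.name for g in groups]
    frag = spec.fragment
    if frag not in data.fragments:
        raise KeyError(f"fragment {frag!r} not in dataset")
    keep = spec.plot_individual_values

    if spec.graph_type in _KINETIC:
        missing = [g.name for g in groups if g.time is None]
        if missing:
            raise MissingInputError(
                f"time points not entered for groups: {missing}"
            )
        quantity = _KINETIC[spec.graph_type] or _abundance_quantity(data)
        series: dict[str, list[GroupStat]] = {}
        values = analytics.sample_values(data, frag, quantity, spec.isotopologue)
        for g in sorted(groups, key=lambda g: (g.time, g.name)):
            series.setdefault(g.name, []).extend(
                analytics.group_stats(values, [g], keep)
            )
        label = {
            "kinetic_single_label": f"M{spec.isotopologue} fraction",
            "kinetic_single_abundance": f"M{spec.isotopologue} abundance",
            "kinetic_total_abundance": "abundance",
            "kinetic_enrichment": "enrichment",
        }[spec.graph_type]
        return GraphStats(
            kind="line", categories=[], groups=group_names, series=series,
            default_ylabel=label,
        )

    if spec.graph_type in ("mid", "stacked_mid", "stacked_abundance"):
        limit = data.display.isotopologue_limits.get(frag)
        n_channels = analytics.mid_frame(data, frag).shape[0]
        limit = n_channels if limit is None else min(limit, n_channels)
        quantity = (
            "isotopologue_fraction"
            if spec.graph_type != "stacked_abundance"
            else "isotopologue_abundance"
        )
        stats = {
            f"M{i}": analytics.group_stats(
                analytics.sample_values(data, frag, quantity, i), groups, keep
            )
            for i in range(limit)
        }
        kind = "bar" if spec.graph_type == "mid" else "stacked"
        ylabel = (
            "fraction of total pool"
            if quantity == "isotopologue_fraction"
            else "abundance (a.u.)"
        )
        return GraphStats(
            kind=kind, categories=[f"M{i}" for i in range(limit)],
            groups=group_names, stats=stats, default_ylabel=ylabel,
        )

    if spec.graph_type in ("single_isotopologue_label", "single_isotopologue_abundance"):
        if spec.isotopologue is None:
            raise MissingInputError("isotopologue index not set on graph spec")
        quantity = (
            "isotopologue_fraction"
            if spec.graph_type == "single_isotopologue_label"
            else "isotopologue_abundance"
        )
        cat = f"M{spec.isotopologue}"
        stats = {
            cat: analytics.group_stats(
                analytics.sample_values(data, frag, quantity, spec.isotopologue),
                groups, keep,
            )
        }
        return GraphStats(
            kind="bar", categories=[cat], groups=group_names, stats=stats,
            default_ylabel=f"{cat} " + (
                "fraction" if quantity == "isotopologue_fraction" else "abundance"
            ),
        )

    if spec.graph_type == "quantitative_abundance":
        if data.normalization is None or not data.normalization.standards:
            raise MissingInputError("quantitative standards not entered")
        values = analytics.sample_values(data, frag, "quantitative_abundance")
        stats = {frag: analytics.group_stats(values, groups, keep)}
        return GraphStats(
            kind="bar", categories=[frag], groups=group_names, stats=stats,
            default_ylabel="amount",
        )

    if spec.graph_type == "enrichment":
        values = analytics.sample_values(data, frag, "enrichment")
        stats = {frag: analytics.group_stats(values, groups, keep)}
        return GraphStats(
            kind="bar", categories=[frag], groups=group_names, stats=stats,
            default_ylabel="mole percent enrichment",
        )

    # abundance
    values = analytics.sample_values(data, frag, _abundance_quantity(data))
    stats = {frag: analytics.group_stats(values, groups, keep)}
    return GraphStats(
        kind="bar", categories=[frag], groups=group_names, stats=stats,
        default_ylabel="abundance (a.u.)",
    )


def group_colors(groups: list[str], scheme: str | list[str]) -> dict[str, str]:
    """Assign scheme colors to groups in order, cycling (with a warning) when
    there are more groups than scheme entries."""
    palette = COLOR_SCHEMES[scheme] if isinstance(scheme, str) else list(scheme)
    if len(groups) > len(palette):
        logger.warning(
            "%d groups exceed the %d-entry color scheme; colors will cycle",
            len(groups), len(palette),
        )
    return {g: palette[i % len(palette)] for i, g in enumerate(groups)}


def _draw_bar(ax, gstats: GraphStats, spec: GraphSpec, colors) -> None:
    n_groups = len(gstats.groups)
    width = 0.8 / max(n_groups, 1)
    for gi, group in enumerate(gstats.groups):
        xs, means, sds, pts = [], [], [], []
        for ci, cat in enumerate(gstats.categories):
            stat = gstats.stats[cat][gi]
            if stat.absent:
                continue
            x = ci + (gi - (n_groups - 1) / 2) * width
            xs.append(x)
            means.append(stat.mean)
            sds.append(stat.sd)
            if spec.plot_individual_values and stat.values:
                pts.extend((x, v) for v in stat.values)
        ax.bar(
            xs, means, width=width * 0.92, yerr=sds, capsize=2,
            color=colors[group], label=group,
            error_kw={"elinewidth": 0.8, "capthick": 0.8},
        )
        if pts:
            px, py = zip(*pts)
            ax.plot(px, py, linestyle="none", marker="o", markersize=2.0,
                    markerfacecolor="black", markeredgecolor="none", zorder=5)
    ax.set_xticks(range(len(gstats.categories)))
    ax.set_xticklabels(gstats.categories, fontsize=7)


def _draw_stacked(ax, gstats: GraphStats, spec: GraphSpec, colors) -> None:
    # one bar per group, one segment per isotopologue; SD whisker on the total
    for gi, group in enumerate(gstats.groups):
        bottom = 0.0
        var_total = 0.0
        for ci, cat in enumerate(gstats.categories):
            stat = gstats.stats[cat][gi]
            if stat.absent:
                continue
            shade = 1.0 - 0.55 * ci / max(len(gstats.categories) - 1, 1)
            ax.bar(
                [gi], [stat.mean], bottom=[bottom], width=0.7,
                color=colors[group], alpha=shade,
                label=cat if gi == 0 else None,
            )
            bottom += stat.mean
            var_total += stat.sd ** 2
        ax.errorbar(
            [gi], [bottom], yerr=[np.sqrt(var_total)], fmt="none",
            ecolor="black", elinewidth=0.8, capsize=2,
        )
    ax.set_xticks(range(len(gstats.groups)))
    ax.set_xticklabels(gstats.groups, fontsize=7, rotation=30, ha="right")


def _draw_line(ax, gstats: GraphStats, spec: GraphSpec, colors) -> None:
    for group in gstats.groups:
        stats = sorted(gstats.series[group], key=lambda s: (s.time, s.group))
        times = [s.time for s in stats if not s.absent]
        means = [s.mean for s in stats if not s.absent]
        sds = [s.sd for s in stats if not s.absent]
        ax.errorbar(
            times, means, yerr=sds, marker="o", markersize=3, capsize=2,
            color=colors[group], label=group, linewidth=1.2, elinewidth=0.8,
        )
        if spec.plot_individual_values:
            pts = [(s.time, v) for s in stats if s.values for v in s.values]
            if pts:
                px, py = zip(*pts)
                ax.plot(px, py, linestyle="none", marker="o", markersize=2.0,
                        markerfacecolor="black", markeredgecolor="none", zorder=5)
    ax.set_xlabel("time", fontsize=7)


def render_graph(
    data: TraceDataset,
    spec: GraphSpec,
    ax=None,
    legend: bool = True,
):
    """Render one graph; returns the matplotlib Figure.

    Group means are drawn with symmetric, capped +/- 1 SD error bars; each
    selected group appears in the legend exactly once, in insertion order.
    """
    gstats = compute_graph_stats(data, spec)
    if ax is None:
        fig, ax = plt.subplots(figsize=(3.2, 2.4), dpi=100)
    else:
        fig = ax.figure
    colors = group_colors(gstats.groups, spec.color_scheme)
    if gstats.kind == "bar":
        _draw_bar(ax, gstats, spec, colors)
    elif gstats.kind == "stacked":
        _draw_stacked(ax, gstats, spec, colors)
    else:
        _draw_line(ax, gstats, spec, colors)
    ax.set_title(spec.title if spec.title is not None else spec.fragment, fontsize=8)
    ax.set_ylabel(
        spec.ylabel if spec.ylabel is not None else gstats.default_ylabel, fontsize=7
    )
    ax.tick_params(labelsize=6)
    for side in ("top", "right"):
        ax.spines[side].set_visible(False)
    if legend:
        ax.legend(fontsize=5, frameon=False)
    return fig


# ---------------------------------------------------------------------------
# carbon diagrams


@dataclass(frozen=True)
class CarbonDiagram:
    """Row of atom circles: labeled positions filled, unlabeled open."""

    n_atoms: int
    labeled_positions: frozenset[int]
    x: float = 0.0  # map coordinates of the leftmost circle
    y: float = 0.0

    def __post_init__(self) -> None:
        bad = [p for p in self.labeled_positions if not 0 <= p < self.n_atoms]
        if bad:
            raise ValueError(
                f"labeled positions {sorted(bad)} out of range [0, {self.n_atoms})"
            )


def render_carbon_diagram(
    ax,
    n_atoms: int,
    labeled_positions,
    x: float = 0.0,
    y: float = 0.0,
    radius: float = 6.0,
    spacing: float = 16.0,
    color: str = "#d62728",
) -> list:
    """Draw a carbon-circle diagram on an axes; returns the circle patches.

    ``n_atoms == 0`` draws nothing (an empty element)."""
    diagram = CarbonDiagram(n_atoms, frozenset(labeled_positions), x, y)
    patches = []
    for i in range(diagram.n_atoms):
        filled = i in diagram.labeled_positions
        circle = plt.Circle(
            (x + i * spacing, y), radius,
            facecolor=color if filled else "white",
            edgecolor="black", linewidth=0.8,
        )
        ax.add_patch(circle)
        patches.append(circle)
    return patches


def carbon_diagram_figure(n_atoms: int, labeled_positions) -> "plt.Figure":
    """Standalone carbon-circle diagram figure."""
    fig, ax = plt.subplots(figsize=(max(n_atoms, 1) * 0.25, 0.3), dpi=100)
    render_carbon_diagram(ax, n_atoms, labeled_positions, radius=6.0, spacing=16.0)
    ax.set_xlim(-10, max(n_atoms - 1, 0) * 16 + 10)
    ax.set_ylim(-10, 10)
    ax.set_aspect("equal")
    ax.axis("off")
    return fig


# ---------------------------------------------------------------------------
# pathway figures


@dataclass
class Placement:
    node: MapNode
    x: float  # top-left corner, map coordinates
    y: float
    width: float
    height: float


@dataclass
class FigureLayout:
    """Deterministic placement of per-fragment graphs on the map canvas."""

    view: EscherMapView
    placements: dict[str, list[Placement]] = field(default_factory=dict)
    sidebar: list[tuple[str, Placement]] = field(default_factory=list)
    carbon_diagrams: list[CarbonDiagram] = field(default_factory=list)
    graph_width: float = 340.0
    graph_height: float = 240.0


def _overlaps(a: tuple[float, float, float, float], rects) -> bool:
    ax0, ay0, aw, ah = a
    for bx0, by0, bw, bh in rects:
        if ax0 < bx0 + bw and bx0 < ax0 + aw and ay0 < by0 + bh and by0 < ay0 + ah:
            return True
    return False


def compute_layout(
    data: TraceDataset,
    view: EscherMapView,
    ignore_compartment: bool = False,
    carbon_diagrams: list[CarbonDiagram] | None = None,
) -> FigureLayout:
    """Place one graph next to every mapped node (clockwise quadrant search
    on collision) and stack unmapped fragments in a left sidebar, in dataset
    order."""
    layout = FigureLayout(view=view, carbon_diagrams=list(carbon_diagrams or []))
    mapped, unmapped = map_data_to_nodes(data, view, ignore_compartment)
    show = data.display.metabolites_to_display
    w, h = layout.graph_width, layout.graph_height
    gap = 30.0
    occupied: list[tuple[float, float, float, float]] = []
    for name, nodes in mapped.items():
        if show is not None and name not in show:
            continue
        for node in nodes:
            # clockwise quadrant search: right, below, left, above
            candidates = [
                (node.x + gap, node.y - h / 2),
                (node.x - w / 2, node.y + gap),
                (node.x - w - gap, node.y - h / 2),
                (node.x - w / 2, node.y - h - gap),
            ]
            pos = next(
                (c for c in candidates if not _overlaps((*c, w, h), occupied)),
                None,
            )
            if pos is None:  # all quadrants busy: march right deterministically
                x, y = node.x + gap, node.y - h / 2
                while _overlaps((x, y, w, h), occupied):
                    x += w + gap
                pos = (x, y)
            x, y = pos
            occupied.append((x, y, w, h))
            layout.placements.setdefault(name, []).append(
                Placement(node, x, y, w, h)
            )
    x0 = view.canvas["x"] - w - 3 * gap
    y = view.canvas["y"]
    for name in unmapped:
        if show is not None and name not in show:
            continue
        layout.sidebar.append(
            (name, Placement(MapNode("", "", x0, y, x0, y), x0, y, w, h))
        )
        y += h + 2 * gap
    return layout


def render_pathway_figure(
    data: TraceDataset,
    layout: FigureLayout | EscherMapView,
    graph_type: str = "mid",
    groups: list[str] | None = None,
    plot_individual_values: bool = False,
    isotopologue: int | None = None,
    max_width_in: float = 16.0,
):
    """Compose the full pathway figure: per-node graphs, a sidebar of
    unmapped fragments, node markers and labels, and optional carbon
    diagrams; returns the Figure."""
    if isinstance(layout, EscherMapView):
        layout = compute_layout(data, layout)
    view = layout.view
    xs = [view.canvas["x"]] + [p.x for ps in layout.placements.values() for p in ps]
    xs += [p.x for _, p in layout.sidebar]
    x_min = min(xs) - 50
    x_max = view.canvas["x"] + view.canvas["width"] + 50
    y_min = view.canvas["y"] - 50
    y_max = view.canvas["y"] + view.canvas["height"] + 50
    if layout.sidebar:
        y_max = max(y_max, max(p.y + p.height for _, p in layout.sidebar) + 50)
    span_x, span_y = x_max - x_min, y_max - y_min
    scale = max_width_in / span_x
    fig = plt.figure(figsize=(span_x * scale, span_y * scale), dpi=100)

    bg = fig.add_axes([0, 0, 1, 1])
    bg.set_xlim(x_min, x_max)
    bg.set_ylim(y_max, y_min)  # Escher y grows downward
    bg.axis("off")
    for node in view.nodes:
        bg.plot([node.x], [node.y], marker="o", markersize=4,
                markerfacecolor="#a0a0a0", markeredgecolor="#606060")
        bg.annotate(node.bigg_id, (node.label_x, node.label_y), fontsize=6,
                    color="#303030")
    for cd in layout.carbon_diagrams:
        render_carbon_diagram(bg, cd.n_atoms, cd.labeled_positions, cd.x, cd.y)

    def to_fig(p: Placement) -> list[float]:
        return [
            (p.x - x_min) / span_x,
            1.0 - (p.y + p.height - y_min) / span_y,
            p.width / span_x,
            p.height / span_y,
        ]

    drawn = 0
    placed = list(layout.placements.items()) + [
        (name, [p]) for name, p_ in layout.sidebar for p in [p_]
    ]
    for name, placements in placed:
        for p in placements:
            ax = fig.add_axes(to_fig(p))
            spec = GraphSpec(
                graph_type=graph_type,
                fragment=name,
                groups=groups,
                isotopologue=isotopologue,
                plot_individual_values=plot_individual_values,
                color_scheme=data.display.color_scheme,
            )
            render_graph(data, spec, ax=ax, legend=(drawn == 0))
            drawn += 1
    return fig


def export(fig, fmt: str, path, dpi: int = 150) -> None:
    """Write a rendered figure as SVG (byte-stable) or PNG (at ``dpi``)."""
    fmt = fmt.lower()
    if fmt == "svg":
        fig.savefig(path, format="svg", metadata={"Date": None})
    elif fmt == "png":
        fig.savefig(path, format="png", dpi=dpi)
    else:
        raise ValueError(f"unsupported export format {fmt!r} (use 'svg' or 'png')")
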