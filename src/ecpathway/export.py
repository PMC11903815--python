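"""Result serialization: dense mapping CSV, pathway list CSV, SVG overlays.

The dense export flattens the whole mapping store to one row per
(item, sample, EC, pathway) combination so downstream tools can re-aggregate
freely; items that reached no EC or no pathway keep a row with empty columns
so totals reconcile with the upload. All CSV output is RFC 4180 (UTF-8,
header row, deterministic ordering), so re-exporting an identical index is
byte-identical.

The SVG overlay is a standalone vector image on a white canvas sized to the
pathway's bounding box (the source raster map is never fetched): node
outlines are drawn for orientation and highlighted nodes get colored
rectangles — equal vertical segments per matched group in the presence view,
a diverging-colormap fill plus a linear legend in the DA view.
"""

from __future__ import annotations

import csv
import io
import math
import xml.etree.ElementTree as ET
from dataclasses import dataclass
from typing import Mapping, Sequence

from .diffabund import NodeComparison, format_da
from .mapping import MappingIndex, RankedPathway

#: Diverging colormap stops (blue → white → red), conventional for
#: fold-change displays: RdBu endpoints with a white midpoint.
DIVERGING_STOPS = ("#2166AC", "#F7F7F7", "#B2182B")

#: Per-group presence colors (first five groups; cycles beyond).
GROUP_COLORS = ("#1B9E77", "#D95F02", "#7570B3", "#E7298A", "#66A61E")


def _hex_to_rgb(h: str) -> tuple[int, int, int]:
    h = h.lstrip("#")
    return int(h[0:2], 16), int(h[2:4], 16), int(h[4:6], 16)


def _rgb_to_hex(rgb: tuple[float, float, float]) -> str:
    return "#%02X%02X%02X" % tuple(int(round(c)) for c in rgb)


def diverging_color(value: float) -> str:
    """Color for a normalized DA value in [−1, 1]; 0 is the midpoint white."""
    if math.isnan(value):
        return "#BBBBBB"
    value = max(-1.0, min(1.0, value))
    low, mid, high = (_hex_to_rgb(s) for s in DIVERGING_STOPS)
    if value < 0:
        t = -value
        a, b = mid, low
    else:
        t = value
        a, b = mid, high
    return _rgb_to_hex(tuple(a[i] + (b[i] - a[i]) * t for i in range(3)))


def _csv(rows: Sequence[Sequence], header: Sequence[str]) -> str:
    buf = io.StringIO()
    writer = csv.writer(buf, lineterminator="\r\n", quoting=csv.QUOTE_MINIMAL)
    writer.writerow(header)
    writer.writerows(rows)
    return buf.getvalue()


def export_dense(index: MappingIndex) -> str:
    """Dense item→EC→pathway mapping as CSV content.

    Columns: item, sample_id, group, ec, map_id, pathway_name.  One row per
    (item, sample, EC, map) combination, ordered ascending on every column;
    unannotated items and pathway-less ECs keep rows with empty columns.
    """
    rows: list[tuple[str, str, str, str, str, str]] = []
    for item in index.items():
        ecs = sorted(index.item_to_ecs.get(item, ())) or [""]
        for sample_id, group in sorted(set(index.item_samples[item])):
            for ec in ecs:
                maps = sorted(index.item_ec_pathways.get(item, {}).get(ec, ())) or [""]
                for map_id in maps:
                    p = index.pathways.get(map_id)
                    rows.append(
                        (item, sample_id, group, ec, map_id, p.name if p else "")
                    )
    rows.sort()
    return _csv(rows, ["item", "sample_id", "group", "ec", "map_id", "pathway_name"])


def export_pathway_list(ranked: Sequence[RankedPathway]) -> str:
    """The ordered list of all pathways as CSV (descending match count)."""
    rows = [
        (r.map_id, r.name, r.category, _count_repr(r.count)) for r in ranked
    ]
    return _csv(rows, ["map_id", "name", "category", "match_count"])


def _count_repr(count: float) -> str:
    return str(int(count)) if float(count).is_integer() else repr(count)


def export_node_comparisons(
    map_id: str, comparisons: Sequence[NodeComparison]
) -> str:
    """Per-node DA table as CSV; sentinels serialize as +inf/-inf/NA."""
    rows = []
    for c in sorted(comparisons, key=lambda c: c.node.node_id):
        rows.append(
            (
                map_id,
                str(c.node.node_id),
                ";".join(sorted(c.node.ec_numbers)),
                _count_repr(c.counts.x),
                _count_repr(c.counts.p1),
                _count_repr(c.counts.y),
                _count_repr(c.counts.p2),
                format_da(c.da_raw),
                format_da(c.da_normalized) if c.da_normalized is not None else "NA",
            )
        )
    return _csv(
        rows,
        ["map_id", "node_id", "ec_numbers", "x", "p1", "y", "p2", "da_raw", "da_normalized"],
    )


def _rect_path(x: float, y: float, w: float, h: float) -> str:
    """A rectangle as an SVG path (outlines stay distinct from highlight rects)."""
    return f"M{x:g},{y:g} h{w:g} v{h:g} h{-w:g} Z"


def render_overlay(
    pathway,
    comparisons: Sequence[NodeComparison] | None = None,
    segments: Mapping[int, tuple[bool, ...]] | None = None,
    group_names: Sequence[str] = (),
) -> str:
    """Render a standalone SVG overlay for one pathway.

    Exactly one of ``comparisons`` (DA view) or ``segments`` (presence view)
    must be given.  Highlighted nodes are drawn as ``rect`` elements at
    (x − width/2, y − height/2): the presence view splits each node into
    equal vertical segments, one per matched group; the DA view fills the
    node from the diverging colormap at its normalized value and appends a
    linear gradient legend.  Nodes without geometry are skipped with a
    warning comment in the output.
    """
    if (comparisons is None) == (segments is None):
        raise ValueError("provide exactly one of comparisons or segments")
    w, h = pathway.bounding_box()
    legend_h = 60.0
    svg = ET.Element(
        "svg",
        {
            "xmlns": "http://www.w3.org/2000/svg",
            "version": "1.1",
            "width": f"{w + 20:g}",
            "height": f"{h + legend_h + 20:g}",
        },
    )
    ET.SubElement(
        svg, "path", {"d": _rect_path(0, 0, w + 20, h + legend_h + 20), "fill": "white"}
    )
    # faint outlines of every node with geometry, for orientation
    for node in pathway.nodes:
        if not node.has_geometry:
            continue
        ET.SubElement(
            svg,
            "path",
            {
                "d": _rect_path(
                    node.x - node.width / 2, node.y - node.height / 2, node.width, node.height
                ),
                "fill": "none",
                "stroke": "#CCCCCC",
                "stroke-width": "1",
            },
        )
        if node.label:
            text = ET.SubElement(
                svg,
                "text",
                {
                    "x": f"{node.x:g}",
                    "y": f"{node.y:g}",
                    "font-size": "9",
                    "text-anchor": "middle",
                    "dominant-baseline": "middle",
                    "fill": "#555555",
                },
            )
            text.text = node.label

    skipped: list[int] = []
    if segments is not None:
        n_groups = max(len(group_names), 1)
        for node_id in sorted(segments):
            flags = segments[node_id]
            node = pathway.node(node_id)
            if not node.has_geometry:
                skipped.append(node_id)
                continue
            seg_w = node.width / n_groups
            x0 = node.x - node.width / 2
            y0 = node.y - node.height / 2
            for gi, flag in enumerate(flags):
                if not flag:
                    continue
                ET.SubElement(
                    svg,
                    "rect",
                    {
                        "x": f"{x0 + gi * seg_w:g}",
                        "y": f"{y0:g}",
                        "width": f"{seg_w:g}",
                        "height": f"{node.height:g}",
                        "fill": GROUP_COLORS[gi % len(GROUP_COLORS)],
                        "fill-opacity": "0.75",
                        "class": "presence-segment",
                    },
                )
        # swatch legend: one rect per group
        for gi, gname in enumerate(group_names):
            ET.SubElement(
                svg,
                "rect",
                {
                    "x": f"{10 + gi * 120:g}",
                    "y": f"{h + 20:g}",
                    "width": "14",
                    "height": "14",
                    "fill": GROUP_COLORS[gi % len(GROUP_COLORS)],
                    "class": "legend",
                },
            )
            label = ET.SubElement(
                svg,
                "text",
                {"x": f"{28 + gi * 120:g}", "y": f"{h + 31:g}", "font-size": "11"},
            )
            label.text = gname
    else:
        for c in sorted(comparisons, key=lambda c: c.node.node_id):
            node = c.node
            if not node.has_geometry:
                skipped.append(node.node_id)
                continue
            value = c.da_normalized if c.da_normalized is not None else math.nan
            ET.SubElement(
                svg,
                "rect",
                {
                    "x": f"{node.x - node.width / 2:g}",
                    "y": f"{node.y - node.height / 2:g}",
                    "width": f"{node.width:g}",
                    "height": f"{node.height:g}",
                    "fill": diverging_color(value),
                    "fill-opacity": "0.85",
                    "class": "da-node",
                },
            )
        # linear legend: gradient bar from −1 to +1
        defs = ET.SubElement(svg, "defs")
        grad = ET.SubElement(
            defs, "linearGradient", {"id": "da-scale", "x1": "0", "x2": "1", "y1": "0", "y2": "0"}
        )
        for off, color in (("0", DIVERGING_STOPS[0]), ("0.5", DIVERGING_STOPS[1]), ("1", DIVERGING_STOPS[2])):
            ET.SubElement(grad, "stop", {"offset": off, "stop-color": color})
        ET.SubElement(
            svg,
            "rect",
            {
                "x": "10",
                "y": f"{h + 20:g}",
                "width": "200",
                "height": "12",
                "fill": "url(#da-scale)",
                "class": "legend",
            },
        )
        for x, anchor, lab in ((10, "start", "-1"), (110, "middle", "0"), (210, "end", "+1")):
            t = ET.SubElement(
                svg,
                "text",
                {"x": f"{x:g}", "y": f"{h + 45:g}", "font-size": "10", "text-anchor": anchor},
            )
            t.text = lab
    if skipped:
        svg.append(
            ET.Comment(
                "warning: nodes without geometry skipped: "
                + ", ".join(str(i) for i in skipped)
            )
        )
    return ET.tostring(svg, encoding="unicode")
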