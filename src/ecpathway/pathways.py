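"""Typed pathway graphs parsed from KGML-dialect XML plus EC link tables.

A metabolic pathway map is a directed cyclic graph made of four element
kinds: compound nodes ('C'-prefixed ids, drawn as circles), enzyme nodes
(rectangular EC-number boxes sitting on edges), reaction edges between
compounds, and map-link nodes/edges connecting neighbouring pathways.  This
module parses the subset of KGML 0.7.x needed to reconstruct that graph —
``entry``, ``graphics``, ``relation``, ``reaction`` — and can serialize it
back (round-trip safe).  Unknown elements are ignored for forward
compatibility.

Coordinates follow the KGML convention: ``x``/``y`` are box *centers* in
pixels with y increasing downward; the overlay renderer converts to corners.

EC numbers are the lingua franca of the whole pipeline, so every enzyme node
is indexed by its EC numbers (:func:`ec_node_index`), and link tables map
each EC onto its pathway maps, reactions and compounds.
"""

from __future__ import annotations

import logging
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .annotation import ec_matches, is_valid_ec

logger = logging.getLogger(__name__)

COMPOUND = "compound"
ENZYME = "enzyme"
MAPLINK = "maplink"

REACTION = "reaction"

_ENTRY_TYPE_TO_KIND = {
    "enzyme": ENZYME,
    "ortholog": ENZYME,
    "gene": ENZYME,
    "compound": COMPOUND,
    "map": MAPLINK,
}


class KgmlParseError(ValueError):
    """Raised on structural problems in a pathway document."""


@dataclass
class PathwayNode:
    """One node of a pathway graph; exactly its kind's fields are populated."""

    node_id: int
    kind: str
    ec_numbers: frozenset[str] = frozenset()
    compound_id: str | None = None
    linked_map_id: str | None = None
    ko_ids: frozenset[str] = frozenset()
    reaction_ids: frozenset[str] = frozenset()
    x: float | None = None
    y: float | None = None
    width: float | None = None
    height: float | None = None
    label: str = ""

    @property
    def has_geometry(self) -> bool:
        return None not in (self.x, self.y, self.width, self.height)


@dataclass(frozen=True)
class PathwayEdge:
    from_node: int
    to_node: int
    kind: str  # reaction | maplink
    direction: str = "directed"  # directed | bidirectional


@dataclass
class Pathway:
    """A parsed pathway map: typed nodes, edges, and display metadata."""

    map_id: str
    name: str
    category: str = ""
    nodes: list[PathwayNode] = field(default_factory=list)
    edges: list[PathwayEdge] = field(default_factory=list)

    def node(self, node_id: int) -> PathwayNode:
        for n in self.nodes:
            if n.node_id == node_id:
                return n
        raise KeyError(node_id)

    @property
    def enzyme_nodes(self) -> list[PathwayNode]:
        return [n for n in self.nodes if n.kind == ENZYME]

    @property
    def compound_ids(self) -> set[str]:
        return {n.compound_id for n in self.nodes if n.kind == COMPOUND and n.compound_id}

    @property
    def ec_numbers(self) -> set[str]:
        out: set[str] = set()
        for n in self.enzyme_nodes:
            out |= n.ec_numbers
        return out

    def bounding_box(self) -> tuple[float, float]:
        """(width, height) covering every node box, in pixels."""
        w = h = 0.0
        for n in self.nodes:
            if n.has_geometry:
                w = max(w, n.x + n.width / 2)
                h = max(h, n.y + n.height / 2)
        return w, h


@dataclass
class EcLinkTable:
    """EC → pathway-map / reaction / compound multimaps."""

    ec_to_maps: dict[str, set[str]] = field(default_factory=dict)
    ec_to_reactions: dict[str, set[str]] = field(default_factory=dict)
    ec_to_compounds: dict[str, set[str]] = field(default_factory=dict)

    def maps_for(self, ec: str) -> set[str]:
        """Map ids linked to an EC, honouring trailing-wildcard matching."""
        out: set[str] = set()
        for key, maps in self.ec_to_maps.items():
            if ec_matches(ec, key):
                out |= maps
        return out


def _strip_prefix(token: str) -> str:
    return token.split(":", 1)[1] if ":" in token else token


def parse_kgml(xml_text: str) -> Pathway:
    """Parse a KGML-dialect document into a :class:`Pathway`.

    Entry elements of type enzyme/ortholog/gene become enzyme nodes, whose
    name tokens are split on whitespace with ``ec:``/``ko:`` prefixes
    stripped; type ``compound`` becomes a compound node; type ``map`` a
    map-link node.  ``relation`` and ``reaction`` elements become edges.
    Entries without graphics keep null geometry (with a warning); an edge
    endpoint referring to no entry is a parse error naming the id.
    """
    try:
        root = ET.fromstring(xml_text)
    except ET.ParseError as exc:
        raise KgmlParseError(f"not well-formed XML: {exc}") from exc
    if root.tag != "pathway":
        raise KgmlParseError(f"root element is {root.tag!r}, expected 'pathway'")
    raw_name = root.get("name", "")
    map_id = _strip_prefix(raw_name) if raw_name else ""
    pathway = Pathway(
        map_id=map_id,
        name=root.get("title", ""),
        category=root.get("category", ""),
    )
    ids: set[int] = set()
    for entry in root.findall("entry"):
        etype = entry.get("type", "")
        kind = _ENTRY_TYPE_TO_KIND.get(etype)
        if kind is None:
            logger.debug("ignoring entry of unknown type %r", etype)
            continue
        node_id = int(entry.get("id"))
        tokens = [_strip_prefix(t) for t in entry.get("name", "").split()]
        node = PathwayNode(node_id=node_id, kind=kind)
        if kind == ENZYME:
            raw = entry.get("name", "").split()
            node.ec_numbers = frozenset(
                _strip_prefix(t) for t in raw if t.startswith("ec:") or is_valid_ec(_strip_prefix(t))
            )
            node.ko_ids = frozenset(_strip_prefix(t) for t in raw if t.startswith("ko:"))
        elif kind == COMPOUND:
            node.compound_id = tokens[0] if tokens else None
        elif kind == MAPLINK:
            node.linked_map_id = tokens[0] if tokens else None
        reaction_attr = entry.get("reaction", "")
        node.reaction_ids = frozenset(_strip_prefix(t) for t in reaction_attr.split() if t)
        graphics = entry.find("graphics")
        if graphics is None or graphics.get("x") is None:
            logger.warning("entry %d of %s has no graphics; geometry is null", node_id, map_id)
        else:
            node.x = float(graphics.get("x"))
            node.y = float(graphics.get("y"))
            node.width = float(graphics.get("width", 0))
            node.height = float(graphics.get("height", 0))
            node.label = graphics.get("name", "")
        pathway.nodes.append(node)
        ids.add(node_id)

    def _check_endpoint(node_id: int, context: str) -> int:
        if node_id not in ids:
            raise KgmlParseError(f"{context} refers to unknown entry id {node_id}")
        return node_id

    for rel in root.findall("relation"):
        e1 = _check_endpoint(int(rel.get("entry1")), "relation")
        e2 = _check_endpoint(int(rel.get("entry2")), "relation")
        kind = MAPLINK if rel.get("type") == "maplink" else REACTION
        direction = rel.get("direction", "directed")
        pathway.edges.append(
            PathwayEdge(from_node=e1, to_node=e2, kind=kind, direction=direction)
        )
    for rxn in root.findall("reaction"):
        direction = "bidirectional" if rxn.get("type") == "reversible" else "directed"
        substrates = [int(s.get("id")) for s in rxn.findall("substrate")]
        products = [int(p.get("id")) for p in rxn.findall("product")]
        for s in substrates:
            _check_endpoint(s, "reaction substrate")
            for p in products:
                _check_endpoint(p, "reaction product")
                pathway.edges.append(
                    PathwayEdge(from_node=s, to_node=p, kind=REACTION, direction=direction)
                )
    return pathway


def serialize_kgml(pathway: Pathway) -> str:
    """Serialize a :class:`Pathway` back to the KGML dialect.

    :func:`parse_kgml` of the output reconstructs an isomorphic graph.
    Relation-backed edges are written as ``relation`` elements; reaction
    edges created from ``reaction`` elements are written back as relations
    too (the graph, not the provenance, is what round-trips).
    """
    root = ET.Element(
        "pathway",
        {"name": f"path:{pathway.map_id}", "title": pathway.name},
    )
    if pathway.category:
        root.set("category", pathway.category)
    kind_to_type = {ENZYME: "enzyme", COMPOUND: "compound", MAPLINK: "map"}
    for n in pathway.nodes:
        if n.kind == ENZYME:
            name = " ".join(
                [f"ec:{e}" for e in sorted(n.ec_numbers)] + [f"ko:{k}" for k in sorted(n.ko_ids)]
            )
        elif n.kind == COMPOUND:
            name = f"cpd:{n.compound_id}" if n.compound_id else ""
        else:
            name = f"path:{n.linked_map_id}" if n.linked_map_id else ""
        attrs = {"id": str(n.node_id), "name": name, "type": kind_to_type[n.kind]}
        if n.reaction_ids:
            attrs["reaction"] = " ".join(f"rn:{r}" for r in sorted(n.reaction_ids))
        entry = ET.SubElement(root, "entry", attrs)
        if n.has_geometry:
            ET.SubElement(
                entry,
                "graphics",
                {
                    "name": n.label,
                    "x": _num(n.x),
                    "y": _num(n.y),
                    "width": _num(n.width),
                    "height": _num(n.height),
                },
            )
    for e in pathway.edges:
        rel_type = "maplink" if e.kind == MAPLINK else "ECrel"
        ET.SubElement(
            root,
            "relation",
            {
                "entry1": str(e.from_node),
                "entry2": str(e.to_node),
                "type": rel_type,
                "direction": e.direction,
            },
        )
    return ET.tostring(root, encoding="unicode")


def _num(v: float) -> str:
    return str(int(v)) if float(v).is_integer() else str(v)


def _load_two_column(tsv_text: str, label: str) -> dict[str, set[str]]:
    out: dict[str, set[str]] = {}
    for rowno, raw in enumerate(tsv_text.splitlines(), start=1):
        if not raw.strip():
            continue
        fields = raw.split("\t")
        if len(fields) < 2:
            raise ValueError(f"{label} row {rowno}: expected two columns")
        ec, target = _strip_prefix(fields[0].strip()), _strip_prefix(fields[1].strip())
        if not is_valid_ec(ec):
            raise ValueError(f"{label} row {rowno}: invalid EC number {ec!r}")
        out.setdefault(ec, set()).add(target)
    return out


def load_link_tables(
    ec_to_maps_tsv: str = "",
    ec_to_reactions_tsv: str = "",
    ec_to_compounds_tsv: str = "",
) -> EcLinkTable:
    """Load EC link tables from two-column (ec, target id) TSV content.

    Duplicate rows collapse under set semantics; a malformed EC key raises
    with its row number.
    """
    return EcLinkTable(
        ec_to_maps=_load_two_column(ec_to_maps_tsv, "ec→map"),
        ec_to_reactions=_load_two_column(ec_to_reactions_tsv, "ec→reaction"),
        ec_to_compounds=_load_two_column(ec_to_compounds_tsv, "ec→compound"),
    )


def ec_node_index(pathway: Pathway) -> dict[str, set[int]]:
    """Index enzyme nodes by each of their EC numbers.

    Compound and map-link nodes are excluded.  Query with
    :func:`query_ec_index` to honour trailing-wildcard ECs.
    """
    index: dict[str, set[int]] = {}
    for n in pathway.enzyme_nodes:
        for ec in n.ec_numbers:
            index.setdefault(ec, set()).add(n.node_id)
    return index


def query_ec_index(index: Mapping[str, set[int]], ec: str) -> set[int]:
    """All node ids whose EC overlaps ``ec`` (wildcards on either side)."""
    out: set[int] = set()
    for key, nodes in index.items():
        if ec_matches(ec, key):
            out |= nodes
    return out
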