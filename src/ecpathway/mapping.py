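"""The interlinked item↔EC↔node↔pathway↔taxon index, built once per upload.

Everything interactive — pathway ranking, filtering, per-node statistics,
taxonomic summaries — reads from a :class:`MappingIndex` so no recalculation
happens after upload.  The closure is transitive: an item reaches a pathway
iff one of its EC numbers matches an enzyme node of that pathway (trailing
EC wildcards match on either side).

Counting conventions:

* **pathway ranking** counts each item once per pathway it reaches,
  weighted by its peptide multiplicity (peptide mode) or once per accession
  (protein mode), aggregated across all samples and groups;
* **per-node statistics** (for differential abundance) count each item once
  per node it matches, per group; protein abundances are summed separately.

Taxonomic summaries reduce the taxa of the items matching a node to their
lowest common ancestor (LCA) over an NCBI-style taxonomy table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .annotation import AnnotationRecord, ec_matches
from .inputs import PEPTIDE_MODE, PROTEIN_MODE, SampleGroup
from .pathways import EcLinkTable, Pathway, ec_node_index, query_ec_index


@dataclass(frozen=True)
class TaxonNode:
    taxon_id: int
    parent_id: int
    rank: str
    name: str


class Taxonomy:
    """An NCBI-style taxonomy: flat (id, parent, rank, name) records.

    The root (id 1 by convention) is its own parent; every parent chain must
    terminate at the root.
    """

    def __init__(self, nodes: Iterable[TaxonNode]):
        self._nodes: dict[int, TaxonNode] = {n.taxon_id: n for n in nodes}
        for n in self._nodes.values():
            if n.parent_id not in self._nodes:
                raise ValueError(
                    f"taxon {n.taxon_id} has parent {n.parent_id} not in the taxonomy"
                )

    @classmethod
    def from_tsv(cls, tsv_text: str) -> "Taxonomy":
        """Parse columns taxon_id, parent_id, rank, name (header optional)."""
        nodes = []
        for raw in tsv_text.splitlines():
            if not raw.strip():
                continue
            fields = raw.split("\t")
            if fields[0].strip().lower() in ("taxon_id", "id"):
                continue
            nodes.append(
                TaxonNode(
                    taxon_id=int(fields[0]),
                    parent_id=int(fields[1]),
                    rank=fields[2].strip(),
                    name=fields[3].strip(),
                )
            )
        return cls(nodes)

    def __contains__(self, taxon_id: int) -> bool:
        return taxon_id in self._nodes

    def node(self, taxon_id: int) -> TaxonNode:
        try:
            return self._nodes[taxon_id]
        except KeyError:
            raise KeyError(f"taxon id {taxon_id} not present in the taxonomy") from None

    def lineage(self, taxon_id: int) -> list[int]:
        """Root-first chain of ancestors ending at ``taxon_id`` itself."""
        chain = [taxon_id]
        seen = {taxon_id}
        node = self.node(taxon_id)
        while node.parent_id != node.taxon_id:
            node = self.node(node.parent_id)
            if node.taxon_id in seen:
                raise ValueError(f"cycle in taxonomy at taxon {node.taxon_id}")
            seen.add(node.taxon_id)
            chain.append(node.taxon_id)
        return list(reversed(chain))

    def lca(self, taxa: Iterable[int]) -> int:
        """Lowest common ancestor of a non-empty taxon set."""
        taxa = list(taxa)
        if not taxa:
            raise ValueError("lca of an empty taxon set is undefined")
        lineages = [self.lineage(t) for t in taxa]
        lca = lineages[0][0]
        for level in range(min(len(l) for l in lineages)):
            ids = {l[level] for l in lineages}
            if len(ids) == 1:
                lca = ids.pop()
            else:
                break
        return lca


@dataclass
class MappingIndex:
    """The precomputed closure and all per-item bookkeeping."""

    mode: str
    groups: list[SampleGroup]
    pathways: dict[str, Pathway]
    item_to_ecs: dict[str, frozenset[str]] = field(default_factory=dict)
    ec_to_items: dict[str, set[str]] = field(default_factory=dict)
    ec_to_nodes: dict[str, dict[str, set[int]]] = field(default_factory=dict)
    item_to_pathways: dict[str, set[str]] = field(default_factory=dict)
    pathway_match_counts: dict[str, float] = field(default_factory=dict)
    item_to_taxon: dict[str, int] = field(default_factory=dict)
    # (item, group name) -> counting weight / abundance sum
    item_group_weight: dict[tuple[str, str], float] = field(default_factory=dict)
    item_group_abundance: dict[tuple[str, str], float] = field(default_factory=dict)
    # item -> [(sample_id, group name)] in deterministic order
    item_samples: dict[str, list[tuple[str, str]]] = field(default_factory=dict)
    # map_id -> node_id -> items matched to that node
    node_items: dict[str, dict[int, set[str]]] = field(default_factory=dict)
    # item -> ec -> map ids reached through that specific EC
    item_ec_pathways: dict[str, dict[str, set[str]]] = field(default_factory=dict)

    @property
    def group_names(self) -> list[str]:
        return [g.name for g in self.groups]

    def items(self) -> list[str]:
        return sorted(self.item_samples)


@dataclass(frozen=True)
class RankedPathway:
    map_id: str
    name: str
    category: str
    count: float
    pathway: Pathway | None = None


def build_index(
    groups: Sequence[SampleGroup],
    annotations: Mapping[str, AnnotationRecord],
    pathways: Iterable[Pathway],
    link_table: EcLinkTable | None = None,
    mode: str = PEPTIDE_MODE,
) -> MappingIndex:
    """Build the interlinked index from assembled groups and annotations.

    An item with several ECs matching nodes in the same pathway contributes
    its weight to that pathway's match count exactly once.  Items without
    annotations simply reach no pathway.  When a link table is supplied, map
    ids it links that are *absent* from the parsed collection still enter
    ``item_to_pathways`` and the match counts, so pathways known only
    through link files participate in ranking.
    """
    collection = {p.map_id: p for p in pathways}
    index = MappingIndex(mode=mode, groups=list(groups), pathways=collection)
    index.ec_to_nodes = {m: ec_node_index(p) for m, p in collection.items()}

    # per-item weights, samples, groups
    for group in groups:
        for sample_id in group.samples:
            for entry in group.entries.get(sample_id, []):
                item = entry.sequence if mode == PEPTIDE_MODE else entry.accession
                w = float(entry.multiplicity) if mode == PEPTIDE_MODE else 1.0
                key = (item, group.name)
                index.item_group_weight[key] = index.item_group_weight.get(key, 0.0) + w
                if mode == PROTEIN_MODE:
                    index.item_group_abundance[key] = (
                        index.item_group_abundance.get(key, 0.0) + float(entry.abundance)
                    )
                index.item_samples.setdefault(item, []).append((sample_id, group.name))

    index.pathway_match_counts = {m: 0.0 for m in collection}
    for item in index.item_samples:
        record = annotations.get(item)
        if record is None:
            continue
        index.item_to_ecs[item] = frozenset(record.ec_numbers)
        if record.taxon_id is not None:
            index.item_to_taxon[item] = record.taxon_id
        for ec in record.ec_numbers:
            index.ec_to_items.setdefault(ec, set()).add(item)
        total_weight = sum(
            index.item_group_weight.get((item, g.name), 0.0) for g in groups
        )
        reached: set[str] = set()
        per_ec: dict[str, set[str]] = {}
        for map_id, node_index in index.ec_to_nodes.items():
            for ec in record.ec_numbers:
                nodes = query_ec_index(node_index, ec)
                if nodes:
                    per_ec.setdefault(ec, set()).add(map_id)
                    reached.add(map_id)
                    bucket = index.node_items.setdefault(map_id, {})
                    for node_id in nodes:
                        bucket.setdefault(node_id, set()).add(item)
        if link_table is not None:
            for ec in record.ec_numbers:
                for map_id in link_table.maps_for(ec):
                    if map_id not in collection:
                        per_ec.setdefault(ec, set()).add(map_id)
                        reached.add(map_id)
        if reached:
            index.item_to_pathways[item] = reached
            index.item_ec_pathways[item] = per_ec
            for map_id in reached:
                index.pathway_match_counts[map_id] = (
                    index.pathway_match_counts.get(map_id, 0.0) + total_weight
                )
    return index


def rank_pathways(index: MappingIndex) -> list[RankedPathway]:
    """All known pathways ordered by descending match count, ties by map id.

    Zero-match pathways stay in the tail so the exported ordered list is
    complete.
    """
    rows = []
    for map_id, count in index.pathway_match_counts.items():
        p = index.pathways.get(map_id)
        rows.append(
            RankedPathway(
                map_id=map_id,
                name=p.name if p else "",
                category=p.category if p else "",
                count=count,
                pathway=p,
            )
        )
    return sorted(rows, key=lambda r: (-r.count, r.map_id))


def filter_pathways(
    ranked: Sequence[RankedPathway],
    text_query: str | None = None,
    required_ecs: Iterable[str] | None = None,
    required_compounds: Iterable[str] | None = None,
) -> list[RankedPathway]:
    """Conjunction of text / EC-content / compound-content filters.

    The text match is a case-insensitive substring over category, map id and
    name.  EC and compound criteria test what the pathway *contains* (its
    nodes), not what the user's data matched.  Relative order is preserved;
    an empty result is legal.
    """
    out = list(ranked)
    if text_query:
        q = text_query.lower()
        out = [
            r
            for r in out
            if q in r.map_id.lower() or q in r.name.lower() or q in r.category.lower()
        ]
    if required_ecs:
        req = list(required_ecs)
        out = [
            r
            for r in out
            if r.pathway is not None
            and all(
                any(ec_matches(e, node_ec) for node_ec in r.pathway.ec_numbers)
                for e in req
            )
        ]
    if required_compounds:
        req_c = set(required_compounds)
        out = [
            r
            for r in out
            if r.pathway is not None and req_c <= r.pathway.compound_ids
        ]
    return out


def available_filter_options(
    ranked: Sequence[RankedPathway],
) -> tuple[set[str], set[str]]:
    """(EC options, compound options) that each yield ≥ 1 pathway alone."""
    ecs: set[str] = set()
    compounds: set[str] = set()
    for r in ranked:
        if r.pathway is not None:
            ecs |= r.pathway.ec_numbers
            compounds |= r.pathway.compound_ids
    return ecs, compounds


def node_taxon_summary(
    map_id: str,
    node_id: int,
    index: MappingIndex,
    taxonomy: Taxonomy,
) -> tuple[str, str] | None:
    """Taxonomic (rank, name) of a node, from the LCA of its matched items.

    Returns None when no matched item carries a taxon; raises ``KeyError``
    when a carried taxon id is missing from the taxonomy.
    """
    items = index.node_items.get(map_id, {}).get(node_id, set())
    taxa = {index.item_to_taxon[i] for i in items if i in index.item_to_taxon}
    if not taxa:
        return None
    node = taxonomy.node(taxonomy.lca(taxa))
    return node.rank, node.name
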