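"""Two-group differential abundance (DA) per pathway node.

Peptide mode contrasts matched-peptide *proportions*:

    DA_peptides = Y/P2 − X/P1

where X and Y are the matched peptide counts of the node in group 1 and
group 2, and P1, P2 are the total peptide counts of each group.  Dividing by
the group totals prevents bias toward the larger group; the value is bounded
in [−1, 1], and positive values indicate a larger proportional abundance in
group 2 (the sign follows the formula above; see docs/methods.md for the
convention discussion).

Protein mode contrasts abundance *sums* with a log2 fold-change:

    DA_proteins = log2((Y/P2) / (X/P1))

with X, Y the sums of protein abundances matching the node and P1, P2 the
group abundance totals.  Zero numerators with pseudocount 0 produce explicit
±infinity sentinels (visually saturated, never hidden) and an all-zero node
is NaN ("undefined").

Because raw DA ranges are asymmetric, values shown together are normalized
onto a diverging scale: each side of the fixed midpoint is scaled by its own
maximum deviation so both ends reach ±1 and the midpoint stays at 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

from .inputs import PEPTIDE_MODE, PROTEIN_MODE
from .mapping import MappingIndex
from .pathways import ENZYME, PathwayNode

#: Serialized forms of the non-finite sentinels.
SENTINEL_LABELS = {math.inf: "+inf", -math.inf: "-inf"}


class UndefinedDenominatorError(ZeroDivisionError):
    """A group total of zero makes the DA formulas undefined."""


class UnsupportedDesignError(ValueError):
    """Raised for designs the two-group comparison cannot serve."""


@dataclass(frozen=True)
class GroupCounts:
    """Matched weights and totals: X/P1 for group 1, Y/P2 for group 2."""

    x: float
    p1: float
    y: float
    p2: float

    def swapped(self) -> "GroupCounts":
        return GroupCounts(x=self.y, p1=self.p2, y=self.x, p2=self.p1)


@dataclass
class NodeComparison:
    """Per-node DA result; ``da_normalized`` is set over a whole pathway."""

    node: PathwayNode
    counts: GroupCounts
    da_raw: float
    mode: str
    da_normalized: float | None = None


def da_peptides(counts: GroupCounts) -> float:
    """Proportion-difference DA for peptide counts; result in [−1, 1]."""
    if counts.p1 <= 0 or counts.p2 <= 0:
        raise UndefinedDenominatorError("group totals P1 and P2 must be positive")
    return counts.y / counts.p2 - counts.x / counts.p1


def da_proteins(counts: GroupCounts, pseudocount: float = 0.0) -> float:
    """Log2 fold-change DA for protein abundance sums.

    ``pseudocount`` is added to both X and Y before the ratio.  With
    pseudocount 0: X=0, Y>0 → ``+inf``; Y=0, X>0 → ``−inf``; X=Y=0 → NaN.
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    if counts.p1 <= 0 or counts.p2 <= 0:
        raise UndefinedDenominatorError("group totals P1 and P2 must be positive")
    x = counts.x + pseudocount
    y = counts.y + pseudocount
    if x == 0 and y == 0:
        return math.nan
    if x == 0:
        return math.inf
    if y == 0:
        return -math.inf
    return math.log2((y / counts.p2) / (x / counts.p1))


def normalize_diverging(values: Sequence[float], midpoint: float = 0.0) -> list[float]:
    """Scale values onto [−1, 1] around a fixed midpoint, per side.

    Two sequential scales are joined at the midpoint: finite values above it
    are divided by the maximum positive deviation, values below by the
    maximum negative deviation, so each populated side reaches ±1 and the
    midpoint maps to 0.  ±infinity sentinels map to ±1 and are excluded from
    scale estimation; NaN propagates.
    """
    if not math.isfinite(midpoint):
        raise ValueError("midpoint must be finite")
    deviations = [v - midpoint for v in values if math.isfinite(v)]
    pos_max = max((d for d in deviations if d > 0), default=0.0)
    neg_max = max((-d for d in deviations if d < 0), default=0.0)
    out: list[float] = []
    for v in values:
        if math.isnan(v):
            out.append(math.nan)
        elif v == math.inf:
            out.append(1.0)
        elif v == -math.inf:
            out.append(-1.0)
        else:
            d = v - midpoint
            if d > 0:
                out.append(d / pos_max)
            elif d < 0:
                out.append(-(-d / neg_max))
            else:
                out.append(0.0)
    return out


def _node_group_stats(
    index: MappingIndex, map_id: str, node_id: int
) -> dict[str, tuple[float, float]]:
    """Per group: (count weight, abundance sum) of items matching a node."""
    items = index.node_items.get(map_id, {}).get(node_id, set())
    stats: dict[str, tuple[float, float]] = {}
    for g in index.groups:
        w = sum(index.item_group_weight.get((i, g.name), 0.0) for i in items)
        a = sum(index.item_group_abundance.get((i, g.name), 0.0) for i in items)
        stats[g.name] = (w, a)
    return stats


def compare_pathway(
    map_id: str,
    index: MappingIndex,
    pseudocount: float = 0.0,
) -> list[NodeComparison]:
    """DA per enzyme node of one pathway, normalized over that pathway.

    Requires a two-group index (the presence view serves single-group
    analyses).  Each item counts once per node it matches, per group;
    protein abundances are summed per (item, node).  Only nodes with at
    least one matched item in either group are compared.
    """
    if len(index.groups) != 2:
        raise UnsupportedDesignError(
            "differential abundance requires exactly 2 groups; "
            "the presence view is available for single-group analyses"
        )
    pathway = index.pathways[map_id]
    g1, g2 = index.groups
    comparisons: list[NodeComparison] = []
    for node in pathway.enzyme_nodes:
        stats = _node_group_stats(index, map_id, node.node_id)
        (w1, a1), (w2, a2) = stats[g1.name], stats[g2.name]
        if w1 == 0 and w2 == 0:
            continue
        if index.mode == PEPTIDE_MODE:
            counts = GroupCounts(x=w1, p1=g1.total_count, y=w2, p2=g2.total_count)
            raw = da_peptides(counts)
        else:
            counts = GroupCounts(x=a1, p1=g1.total_count, y=a2, p2=g2.total_count)
            raw = da_proteins(counts, pseudocount)
        comparisons.append(
            NodeComparison(node=node, counts=counts, da_raw=raw, mode=index.mode)
        )
    normalized = normalize_diverging([c.da_raw for c in comparisons], midpoint=0.0)
    for c, v in zip(comparisons, normalized):
        c.da_normalized = v
    return comparisons


def presence_segments(
    map_id: str,
    index: MappingIndex,
) -> dict[int, tuple[bool, ...]]:
    """Per node: one matched/unmatched flag per group, in group order.

    Nodes matched by no group are omitted (only nodes with at least one
    match are highlighted).
    """
    if not index.groups:
        raise UnsupportedDesignError("at least one group is required")
    out: dict[int, tuple[bool, ...]] = {}
    for node_id, items in index.node_items.get(map_id, {}).items():
        flags = tuple(
            any(index.item_group_weight.get((i, g.name), 0.0) > 0 for i in items)
            for g in index.groups
        )
        if any(flags):
            out[node_id] = flags
    return out


def format_da(value: float) -> str:
    """Serialize a DA value; sentinels become "+inf"/"-inf"/"NA"."""
    if math.isnan(value):
        return "NA"
    if value == math.inf:
        return "+inf"
    if value == -math.inf:
        return "-inf"
    return repr(value)
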