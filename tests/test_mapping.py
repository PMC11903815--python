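"""Index closure vs a brute-force oracle; ranking, filtering, LCA summaries."""

import numpy as np
import pytest

import ecpathway as ep
from ecpathway.annotation import AnnotationRecord
from ecpathway.inputs import PeptideEntry
from ecpathway.pathways import ENZYME, Pathway, PathwayNode

# ---------------------------------------------------------------------------
# brute-force oracle machinery (independent of the MappingIndex code path)

_LETTERS = "ACDEFGHIKMNPQRSTVWY"


def _item_name(i: int) -> str:
    return "".join(_LETTERS[(i // len(_LETTERS) ** k) % len(_LETTERS)] for k in range(4))


def _prefix_match(a: str, b: str) -> bool:
    """Trailing-wildcard EC overlap, re-derived for the oracle."""
    for x, y in zip(a.split("."), b.split(".")):
        if x == "-" or y == "-":
            return True
        if x != y:
            return False
    return True


def random_instance(seed: int):
    """A random small mapping problem: items, weights, ECs, pathways."""
    rng = np.random.default_rng(seed)
    n_items = int(rng.integers(1, 11))
    n_ecs = int(rng.integers(1, 6))
    n_pathways = int(rng.integers(1, 4))
    ec_pool = [f"{i + 1}.1.1.{i + 1}" for i in range(n_ecs)]
    if rng.random() < 0.3:
        ec_pool[-1] = ec_pool[-1].rsplit(".", 1)[0] + ".-"  # throw in a wildcard

    items = {}
    for i in range(n_items):
        k = int(rng.integers(0, min(3, n_ecs) + 1))
        ecs = frozenset(rng.choice(ec_pool, size=k, replace=False)) if k else frozenset()
        items[_item_name(i)] = (ecs, int(rng.integers(1, 4)))  # (ECs, multiplicity)

    pathways = []
    for p in range(n_pathways):
        nodes = []
        for n in range(int(rng.integers(1, 4))):
            k = int(rng.integers(1, min(2, n_ecs) + 1))
            nodes.append(
                PathwayNode(
                    node_id=n + 1,
                    kind=ENZYME,
                    ec_numbers=frozenset(rng.choice(ec_pool, size=k, replace=False)),
                )
            )
        pathways.append(Pathway(map_id=f"map{p:05d}", name=f"p{p}", nodes=nodes))
    return items, pathways


def build_from_instance(items, pathways):
    """Run the real pipeline on an instance (two groups, split alternately)."""
    names = sorted(items)
    g1 = [n for i, n in enumerate(names) if i % 2 == 0]
    g2 = [n for i, n in enumerate(names) if i % 2 == 1]
    samples = {
        "s1": [PeptideEntry(n, "s1", items[n][1]) for n in g1],
        "s2": [PeptideEntry(n, "s2", items[n][1]) for n in g2],
    }
    groups = ep.assemble_groups(samples, {"s1": "G1", "s2": "G2"}, "peptide")
    annotations = {
        n: AnnotationRecord(item=n, ec_numbers=items[n][0]) for n in names if items[n][0]
    }
    return ep.build_index(groups, annotations, pathways, mode="peptide")


def brute_force_closure(items, pathways):
    """Triple-loop transitive closure: items × their ECs × pathway nodes."""
    item_to_pathways = {}
    counts = {p.map_id: 0.0 for p in pathways}
    node_items = {}
    for name, (ecs, weight) in items.items():
        reached = set()
        for ec in ecs:
            for p in pathways:
                for node in p.nodes:
                    if any(_prefix_match(ec, nec) for nec in node.ec_numbers):
                        reached.add(p.map_id)
                        node_items.setdefault(p.map_id, {}).setdefault(
                            node.node_id, set()
                        ).add(name)
        if reached:
            item_to_pathways[name] = reached
            for m in reached:
                counts[m] += weight
    return item_to_pathways, counts, node_items


class TestBuildIndex:
    def test_single_path_weighted_by_multiplicity(self, tiny_pathway):
        samples = {"s1": [PeptideEntry("AAKMR", "s1", 3)]}
        groups = ep.assemble_groups(samples, {"s1": "G1"}, "peptide")
        ann = {"AAKMR": AnnotationRecord("AAKMR", frozenset({"2.3.1.9"}))}
        index = ep.build_index(groups, ann, [tiny_pathway], mode="peptide")
        assert index.pathway_match_counts["map00650"] == 3.0

    def test_item_with_two_ecs_counts_once_per_pathway(self, tiny_pathway):
        samples = {"s1": [PeptideEntry("AAKMR", "s1", 2)]}
        groups = ep.assemble_groups(samples, {"s1": "G1"}, "peptide")
        ann = {"AAKMR": AnnotationRecord("AAKMR", frozenset({"2.3.1.9", "2.8.3.8"}))}
        index = ep.build_index(groups, ann, [tiny_pathway], mode="peptide")
        # both ECs hit map00650; the item's weight of 2 is added exactly once
        assert index.pathway_match_counts["map00650"] == 2.0

    def test_unannotated_items_reach_no_pathway(self, small_index):
        assert "GGHKR" not in small_index.item_to_pathways

    def test_link_table_adds_only_unparsed_maps(self, tiny_pathway):
        samples = {"s1": [PeptideEntry("AAKMR", "s1", 1)]}
        groups = ep.assemble_groups(samples, {"s1": "G1"}, "peptide")
        ann = {"AAKMR": AnnotationRecord("AAKMR", frozenset({"2.3.1.9"}))}
        link = ep.load_link_tables("2.3.1.9\tmap00650\n2.3.1.9\tmap00990\n")
        index = ep.build_index(groups, ann, [tiny_pathway], link, mode="peptide")
        assert index.item_to_pathways["AAKMR"] == {"map00650", "map00990"}
        assert index.pathway_match_counts["map00650"] == 1.0  # not double counted
        assert index.pathway_match_counts["map00990"] == 1.0

    @pytest.mark.parametrize("seed", range(60))
    def test_matches_brute_force_oracle(self, seed):
        items, pathways = random_instance(seed)
        index = build_from_instance(items, pathways)
        exp_paths, exp_counts, exp_node_items = brute_force_closure(items, pathways)
        assert index.item_to_pathways == exp_paths
        assert index.pathway_match_counts == exp_counts
        assert index.node_items == exp_node_items


class TestRankPathways:
    def _index_with_counts(self, counts):
        pathways = [Pathway(map_id=m, name=m) for m in counts]
        index = ep.MappingIndex(mode="peptide", groups=[], pathways={p.map_id: p for p in pathways})
        index.pathway_match_counts = dict(counts)
        return index

    def test_descending_by_count(self):
        ranked = ep.rank_pathways(self._index_with_counts({"mapA": 5, "mapB": 9}))
        assert [r.map_id for r in ranked] == ["mapB", "mapA"]

    def test_ties_broken_by_map_id(self):
        ranked = ep.rank_pathways(self._index_with_counts({"mapB": 5, "mapA": 5}))
        assert [r.map_id for r in ranked] == ["mapA", "mapB"]

    def test_zero_match_pathways_kept_in_tail(self, small_index):
        ranked = ep.rank_pathways(small_index)
        assert len(ranked) == len(small_index.pathways)
        counts = [r.count for r in ranked]
        assert counts == sorted(counts, reverse=True)

    def test_second_sample_never_decreases_counts(self, tiny_pathway):
        ann = {"AAKMR": AnnotationRecord("AAKMR", frozenset({"2.3.1.9"}))}
        one = ep.build_index(
            ep.assemble_groups(
                {"s1": [PeptideEntry("AAKMR", "s1", 1)]}, {"s1": "G"}, "peptide"
            ),
            ann,
            [tiny_pathway],
            mode="peptide",
        )
        two = ep.build_index(
            ep.assemble_groups(
                {
                    "s1": [PeptideEntry("AAKMR", "s1", 1)],
                    "s2": [PeptideEntry("AAKMR", "s2", 4)],
                },
                {"s1": "G", "s2": "G"},
                "peptide",
            ),
            ann,
            [tiny_pathway],
            mode="peptide",
        )
        for m in one.pathway_match_counts:
            assert two.pathway_match_counts[m] >= one.pathway_match_counts[m]


class TestFilterPathways:
    def test_text_filter_case_insensitive_over_all_fields(self, small_index):
        ranked = ep.rank_pathways(small_index)
        assert [r.map_id for r in ep.filter_pathways(ranked, text_query="butanoate")] == [
            "map00650"
        ]
        assert [r.map_id for r in ep.filter_pathways(ranked, text_query="00720")] == [
            "map00720"
        ]
        assert [
            r.map_id for r in ep.filter_pathways(ranked, text_query="ENERGY")
        ] == ["map00720"]

    def test_ec_filter_tests_pathway_content(self, small_index):
        ranked = ep.rank_pathways(small_index)
        got = ep.filter_pathways(ranked, required_ecs={"2.3.1.9"})
        assert [r.map_id for r in got] == ["map00650"]

    def test_compound_filter(self, small_index):
        ranked = ep.rank_pathways(small_index)
        got = ep.filter_pathways(ranked, required_compounds={"C00149"})
        assert [r.map_id for r in got] == ["map00720"]

    def test_conjunction_is_intersection_of_single_filters(self, small_index):
        ranked = ep.rank_pathways(small_index)
        both = ep.filter_pathways(ranked, text_query="map", required_ecs={"2.3.1.9"})
        text_only = {r.map_id for r in ep.filter_pathways(ranked, text_query="map")}
        ec_only = {r.map_id for r in ep.filter_pathways(ranked, required_ecs={"2.3.1.9"})}
        assert {r.map_id for r in both} == text_only & ec_only

    def test_no_filters_is_identity(self, small_index):
        ranked = ep.rank_pathways(small_index)
        assert ep.filter_pathways(ranked) == ranked

    def test_empty_result_is_legal(self, small_index):
        ranked = ep.rank_pathways(small_index)
        assert ep.filter_pathways(ranked, text_query="no such pathway") == []


class TestAvailableFilterOptions:
    def test_options_are_exactly_the_union_over_pathways(self, small_index):
        ranked = ep.rank_pathways(small_index)
        ecs, compounds = ep.available_filter_options(ranked)
        brute_ecs = set()
        brute_cpds = set()
        for r in ranked:
            if r.pathway:
                brute_ecs |= r.pathway.ec_numbers
                brute_cpds |= r.pathway.compound_ids
        assert ecs == brute_ecs
        assert compounds == brute_cpds

    def test_every_offered_option_yields_a_result(self, small_index):
        ranked = ep.rank_pathways(small_index)
        ecs, compounds = ep.available_filter_options(ranked)
        for ec in ecs:
            assert ep.filter_pathways(ranked, required_ecs={ec})
        for c in compounds:
            assert ep.filter_pathways(ranked, required_compounds={c})

    def test_unoffered_ec_yields_nothing(self, small_index):
        ranked = ep.rank_pathways(small_index)
        ecs, _ = ep.available_filter_options(ranked)
        assert "9.9.9.9" not in ecs
        assert ep.filter_pathways(ranked, required_ecs={"9.9.9.9"}) == []


class TestTaxonomyLca:
    def test_singleton(self, taxonomy):
        assert taxonomy.lca([4]) == 4

    def test_siblings_meet_at_parent(self, taxonomy):
        assert taxonomy.lca([4, 5]) == 3  # two Clostridium species -> genus

    def test_cross_genus_meets_at_domain(self, taxonomy):
        assert taxonomy.lca([4, 7]) == 2

    def test_idempotent_and_commutative(self, taxonomy):
        s = [4, 5, 7]
        lca = taxonomy.lca(s)
        assert taxonomy.lca(s + [lca]) == lca
        assert taxonomy.lca(list(reversed(s))) == lca

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_brute_force_lineage_intersection(self, seed):
        tax = ep.Taxonomy.from_tsv(ep.generate_taxonomy(seed=0))
        ids = ep.synthdata.species_taxon_ids() + [1, 2]
        rng = np.random.default_rng(seed)
        subset = list(rng.choice(ids, size=int(rng.integers(1, 5)), replace=True))
        common = set(tax.lineage(subset[0]))
        for t in subset[1:]:
            common &= set(tax.lineage(t))
        deepest = max(common, key=lambda t: len(tax.lineage(t)))
        assert tax.lca(subset) == deepest

    def test_missing_taxon_named_in_error(self, taxonomy):
        with pytest.raises(KeyError, match="99"):
            taxonomy.lineage(99)


class TestNodeTaxonSummary:
    def test_lca_of_matched_items(self, small_index, taxonomy):
        # node 2 of map00650 is matched by AAKMR (taxon 5) and MLKER (taxon 6)
        rank, name = ep.node_taxon_summary("map00650", 2, small_index, taxonomy)
        assert (rank, name) == ("superkingdom", "Bacteria")

    def test_single_item_gives_its_own_taxon(self, small_index, taxonomy):
        rank, name = ep.node_taxon_summary("map00650", 4, small_index, taxonomy)
        assert (rank, name) == ("species", "Clostridium butyricum")

    def test_absent_when_no_item_carries_a_taxon(self, small_index, taxonomy):
        assert ep.node_taxon_summary("map00650", 1, small_index, taxonomy) is None

    def test_unknown_taxon_id_raises_naming_it(self, small_index):
        tiny_tax = ep.Taxonomy.from_tsv("1\t1\tno rank\troot\n")
        with pytest.raises(KeyError, match="5"):
            ep.node_taxon_summary("map00650", 2, small_index, tiny_tax)
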