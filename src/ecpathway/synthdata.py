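"""Synthetic fixtures: pathways, samples with planted effects, taxonomies.

Everything the pipeline consumes can be generated offline and
deterministically from a seed, in exactly the file formats the real inputs
use, so every stage is testable without network access:

* :func:`generate_pathway` emits a connected alternating compound–enzyme
  chain as KGML-dialect XML plus matching EC link-table rows;
* :func:`generate_samples` draws two groups of peptide samples i.i.d. from
  an EC-labelled peptide pool, multiplying the group-2 draw rate of chosen
  target ECs by an enrichment factor (then renormalizing), and records the
  expected differential-abundance sign per EC as ground truth;
* :func:`generate_taxonomy` builds a small rooted taxonomy table;
* :func:`table1_fixture` loads the packaged 32-enzyme short-chain-fatty-acid
  reference set (butyrogenesis / propionogenesis / acetogenesis) used by the
  case-study runner.

Synthetic peptides are random 8–12-mers over the canonical alphabet and
unique across EC label pools, so no peptide is accidentally cross-annotated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np

from .inputs import CANONICAL_RESIDUES
from .pathways import (
    COMPOUND,
    ENZYME,
    Pathway,
    PathwayEdge,
    PathwayNode,
    serialize_kgml,
)

_ALPHABET = sorted(CANONICAL_RESIDUES)


@dataclass(frozen=True)
class PlantedEffect:
    """A ground-truth enrichment planted on one EC.

    ``enrichment_factor`` multiplies the group-2 draw rate of ``target_ec``
    before renormalization; a factor above 1 implies an expected positive
    differential abundance under the Y/P2 − X/P1 convention.
    """

    target_ec: str
    enrichment_factor: float
    baseline_rate: float

    def __post_init__(self) -> None:
        if self.enrichment_factor <= 0:
            raise ValueError("enrichment_factor must be positive")
        if not 0 < self.baseline_rate < 1:
            raise ValueError("baseline_rate must be a probability in (0, 1)")


@dataclass
class SyntheticPathway:
    kgml: str
    map_id: str
    ec_to_map_rows: list[tuple[str, str]]
    ec_to_reaction_rows: list[tuple[str, str]]
    ec_to_compound_rows: list[tuple[str, str]]

    def link_tsv(self) -> tuple[str, str, str]:
        def tsv(rows):
            return "".join(f"{a}\t{b}\n" for a, b in rows)

        return (
            tsv(self.ec_to_map_rows),
            tsv(self.ec_to_reaction_rows),
            tsv(self.ec_to_compound_rows),
        )


@dataclass
class SyntheticSamples:
    """Two groups of peptide sample files plus annotations and ground truth."""

    group_files: dict[str, dict[str, str]]  # group -> sample_id -> file text
    annotation_tsv: str
    expected_sign: dict[str, int]  # target EC -> expected sign of da_raw
    ec_peptides: dict[str, list[str]] = field(default_factory=dict)


def _random_ec(rng: np.random.Generator, used: set[str]) -> str:
    while True:
        ec = ".".join(
            str(int(v))
            for v in (
                rng.integers(1, 8),
                rng.integers(1, 100),
                rng.integers(1, 100),
                rng.integers(1, 300),
            )
        )
        if ec not in used:
            used.add(ec)
            return ec


def _random_peptide(rng: np.random.Generator, used: set[str]) -> str:
    while True:
        n = int(rng.integers(8, 13))
        pep = "".join(rng.choice(_ALPHABET, size=n))
        if pep not in used:
            used.add(pep)
            return pep


def generate_pathway(
    n_enzymes: int,
    n_compounds: int,
    seed: int,
    map_id: str | None = None,
    ec_numbers: list[str] | None = None,
) -> SyntheticPathway:
    """A connected alternating compound–enzyme chain with synthetic ECs.

    The chain has ``n_enzymes + n_compounds`` nodes and one reaction edge
    between each consecutive pair; node geometry sits on a grid.  Output is
    byte-identical for equal arguments, and parses back through the KGML
    parser.  ``ec_numbers`` pins the enzyme ECs (padded with random ones when
    shorter than ``n_enzymes``).
    """
    if n_enzymes < 1 or n_compounds < 1:
        raise ValueError("need at least one enzyme and one compound")
    rng = np.random.default_rng(seed)
    if map_id is None:
        map_id = f"map9{int(rng.integers(0, 10000)):04d}"
    used_ecs: set[str] = set(ec_numbers or [])
    ecs = list(ec_numbers or [])
    while len(ecs) < n_enzymes:
        ecs.append(_random_ec(rng, used_ecs))
    ecs = ecs[:n_enzymes]

    # interleave compounds and enzymes while both remain, then append leftovers
    kinds: list[str] = []
    ce, cc = n_enzymes, n_compounds
    want = COMPOUND
    while ce or cc:
        if want == COMPOUND and cc:
            kinds.append(COMPOUND)
            cc -= 1
            want = ENZYME
        elif want == ENZYME and ce:
            kinds.append(ENZYME)
            ce -= 1
            want = COMPOUND
        elif cc:
            kinds.append(COMPOUND)
            cc -= 1
        else:
            kinds.append(ENZYME)
            ce -= 1

    pathway = Pathway(
        map_id=map_id, name=f"synthetic pathway {map_id}", category="Synthetic"
    )
    ei = ci = 0
    compound_ids: list[str] = []
    for i, kind in enumerate(kinds):
        x = 60.0 + 90.0 * i
        if kind == ENZYME:
            node = PathwayNode(
                node_id=i + 1,
                kind=ENZYME,
                ec_numbers=frozenset({ecs[ei]}),
                reaction_ids=frozenset({f"R9{int(rng.integers(0, 10000)):04d}"}),
                x=x,
                y=120.0,
                width=46.0,
                height=17.0,
                label=ecs[ei],
            )
            ei += 1
        else:
            cid = f"C9{int(rng.integers(0, 10000)):04d}"
            compound_ids.append(cid)
            node = PathwayNode(
                node_id=i + 1,
                kind=COMPOUND,
                compound_id=cid,
                x=x,
                y=120.0,
                width=8.0,
                height=8.0,
                label=cid,
            )
            ci += 1
        pathway.nodes.append(node)
    for i in range(len(kinds) - 1):
        pathway.edges.append(
            PathwayEdge(from_node=i + 1, to_node=i + 2, kind="reaction")
        )

    map_rows = [(ec, map_id) for ec in ecs]
    rxn_rows = [
        (sorted(n.ec_numbers)[0], sorted(n.reaction_ids)[0])
        for n in pathway.enzyme_nodes
    ]
    cpd_rows = [(ec, compound_ids[i % len(compound_ids)]) for i, ec in enumerate(ecs)]
    return SyntheticPathway(
        kgml=serialize_kgml(pathway),
        map_id=map_id,
        ec_to_map_rows=map_rows,
        ec_to_reaction_rows=rxn_rows,
        ec_to_compound_rows=cpd_rows,
    )


def generate_taxonomy(n_species_per_genus: int = 3, n_genera: int = 4, seed: int = 0) -> str:
    """A small rooted taxonomy TSV: root → domain → genus → species."""
    rng = np.random.default_rng(seed)
    lines = ["taxon_id\tparent_id\trank\tname", "1\t1\tno rank\troot"]
    next_id = 2
    lines.append(f"{next_id}\t1\tsuperkingdom\tBacteria")
    domain = next_id
    next_id += 1
    for g in range(n_genera):
        genus = next_id
        lines.append(f"{genus}\t{domain}\tgenus\tGenus{g + 1}")
        next_id += 1
        for s in range(n_species_per_genus):
            lines.append(f"{next_id}\t{genus}\tspecies\tGenus{g + 1} species{s + 1}")
            next_id += 1
    return "\n".join(lines) + "\n"


def species_taxon_ids(n_species_per_genus: int = 3, n_genera: int = 4) -> list[int]:
    """Taxon ids of the species leaves of :func:`generate_taxonomy`."""
    out = []
    next_id = 3
    for _ in range(n_genera):
        genus = next_id
        next_id += 1
        for _ in range(n_species_per_genus):
            out.append(next_id)
            next_id += 1
    return out


def generate_samples(
    n_per_sample: int,
    effects: list[PlantedEffect],
    seed: int,
    n_samples_per_group: int = 1,
    group_names: tuple[str, str] = ("group1", "group2"),
    peptides_per_ec: int = 20,
    assign_taxa: bool = True,
) -> SyntheticSamples:
    """Draw two groups of peptide samples with planted EC enrichments.

    Each effect EC owns a pool of ``peptides_per_ec`` unique peptides; the
    remaining probability mass produces unannotated background peptides.
    Group 1 draws each effect EC at its ``baseline_rate``; in group 2 the
    rate is multiplied by the effect's ``enrichment_factor`` and the whole
    rate vector renormalized.  The expected sign of Y/P2 − X/P1 per EC is
    recorded as ground truth.
    """
    rates = [e.baseline_rate for e in effects]
    if sum(rates) > 1:
        raise ValueError("baseline rates must sum to at most 1")
    rng = np.random.default_rng(seed)
    used_peps: set[str] = set()
    ec_peptides = {
        e.target_ec: [_random_peptide(rng, used_peps) for _ in range(peptides_per_ec)]
        for e in effects
    }
    background = [_random_peptide(rng, used_peps) for _ in range(max(50, peptides_per_ec))]

    bg_rate = 1.0 - sum(rates)
    p1 = np.array(rates + [bg_rate])
    raw2 = np.array([r * e.enrichment_factor for r, e in zip(rates, effects)] + [bg_rate])
    p2 = raw2 / raw2.sum()

    expected_sign = {
        e.target_ec: int(np.sign(round(p2[i] - p1[i], 12)))
        for i, e in enumerate(effects)
    }

    categories = [e.target_ec for e in effects] + [None]
    group_files: dict[str, dict[str, str]] = {g: {} for g in group_names}
    for gi, (gname, probs) in enumerate(zip(group_names, (p1, p2))):
        for si in range(n_samples_per_group):
            draws = rng.choice(len(categories), size=n_per_sample, p=probs)
            lines = []
            for d in draws:
                pool = ec_peptides[categories[d]] if categories[d] else background
                lines.append(pool[int(rng.integers(0, len(pool)))])
            group_files[gname][f"{gname}_s{si + 1}"] = "\n".join(lines) + "\n"

    taxa = species_taxon_ids()
    ann_lines = ["item\tec_list\ttaxon_id\tko_list"]
    for i, e in enumerate(effects):
        taxon = taxa[i % len(taxa)] if assign_taxa else ""
        for pep in ec_peptides[e.target_ec]:
            ann_lines.append(f"{pep}\t{e.target_ec}\t{taxon}\t")
    annotation_tsv = "\n".join(ann_lines) + "\n"
    return SyntheticSamples(
        group_files=group_files,
        annotation_tsv=annotation_tsv,
        expected_sign=expected_sign,
        ec_peptides=ec_peptides,
    )


@dataclass(frozen=True)
class Table1Enzyme:
    """One row of the packaged 32-enzyme reference set."""

    process: str
    enzyme: str
    ec_numbers: tuple[str, ...]
    map_id: str | None
    section: str  # concordant | not_reported | discordant


def table1_fixture() -> list[Table1Enzyme]:
    """The packaged 32-row enzyme reference set (data, not code)."""
    text = (
        resources.files("ecpathway.data").joinpath("table1_enzymes.tsv").read_text()
    )
    rows: list[Table1Enzyme] = []
    for line in text.splitlines()[1:]:
        if not line.strip():
            continue
        process, enzyme, ecs, map_id, section = line.split("\t")
        rows.append(
            Table1Enzyme(
                process=process,
                enzyme=enzyme,
                ec_numbers=tuple(ecs.split(";")),
                map_id=None if map_id == "None" else map_id,
                section=section,
            )
        )
    return rows


#: Which group each metabolic process is expected to dominate in the
#: case-study design (group 1 = caloric restriction, group 2 = ad libitum):
#: caloric restriction boosts propionogenesis and limits butyrogenesis and
#: acetogenesis.
PROCESS_EXPECTED_HIGHER_GROUP = {
    "Butyrogenesis": 2,
    "Propionogenesis": 1,
    "Acetogenesis": 2,
}

#: ECs of the four reference enzymes the annotation service never reports
#: (the fifth "not reported"-section enzyme, 4.2.1.167, *is* reported — it is
#: excluded later for belonging to no pathway).
UNREPORTED_ENZYME_ECS = frozenset({"7.2.4.5", "1.1.1.61", "2.8.3.-", "2.8.3.1"})


def generate_casestudy(
    seed: int,
    n_per_sample: int = 2000,
    n_samples_per_group: int = 3,
    emulate_unreported: bool = True,
) -> tuple[SyntheticSamples, list[SyntheticPathway]]:
    """A synthetic end-to-end case study over the 32-enzyme reference set.

    Builds one synthetic pathway per reference map containing the reference
    ECs, and two peptide groups (group 1 emulating caloric restriction,
    group 2 ad libitum) with enrichments planted in the direction each
    metabolic process is expected to move.  With ``emulate_unreported`` the
    annotation table omits the four enzymes the reference marks as never
    reported, reproducing the "not reported" category.
    """
    enzymes = table1_fixture()
    included = [
        e
        for e in enzymes
        if not (
            emulate_unreported and set(e.ec_numbers) & UNREPORTED_ENZYME_ECS
        )
    ]
    effects = []
    for e in included:
        higher = PROCESS_EXPECTED_HIGHER_GROUP[e.process]
        factor = 2.5 if higher == 2 else 1 / 2.5
        for ec in e.ec_numbers:
            effects.append(
                PlantedEffect(
                    target_ec=ec,
                    enrichment_factor=factor,
                    baseline_rate=0.9 / (2 * len(included)),
                )
            )
    samples = generate_samples(
        n_per_sample=n_per_sample,
        effects=effects,
        seed=seed,
        n_samples_per_group=n_samples_per_group,
        group_names=("CR", "AL"),
    )
    by_map: dict[str, list[str]] = {}
    for e in enzymes:
        if e.map_id is None:
            continue
        for ec in e.ec_numbers:
            by_map.setdefault(e.map_id, []).append(ec)
    pathways = [
        generate_pathway(
            n_enzymes=len(ecs),
            n_compounds=len(ecs) + 1,
            seed=seed + i + 1,
            map_id=map_id,
            ec_numbers=ecs,
        )
        for i, (map_id, ecs) in enumerate(sorted(by_map.items()))
    ]
    return samples, pathways
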