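"""Shared fixtures: a tiny hand-written pathway and a small two-group run."""

import pytest

import ecpathway as ep

# A minimal pathway document written by hand (not by the serializer) so the
# parser is exercised against an independent artifact: two compounds joined
# through one enzyme box, plus a link to a neighbouring map.
TINY_KGML = """\
<pathway name="path:map00650" title="Butanoate metabolism" category="Carbohydrate metabolism">
  <entry id="1" name="cpd:C00246" type="compound">
    <graphics name="Butanoate" x="100" y="200" width="8" height="8"/>
  </entry>
  <entry id="2" name="ec:2.3.1.9" type="enzyme" reaction="rn:R00238">
    <graphics name="2.3.1.9" x="160" y="200" width="46" height="17"/>
  </entry>
  <entry id="3" name="cpd:C00332" type="compound">
    <graphics name="Acetoacetyl-CoA" x="220" y="200" width="8" height="8"/>
  </entry>
  <entry id="4" name="ec:2.8.3.8 ec:2.8.3.12" type="enzyme">
    <graphics name="2.8.3.8" x="160" y="260" width="46" height="17"/>
  </entry>
  <entry id="5" name="path:map00640" type="map">
    <graphics name="Propanoate metabolism" x="300" y="200" width="80" height="25"/>
  </entry>
  <reaction id="2" name="rn:R00238" type="reversible">
    <substrate id="1" name="cpd:C00246"/>
    <product id="3" name="cpd:C00332"/>
  </reaction>
  <relation entry1="3" entry2="5" type="maplink"/>
</pathway>
"""

SECOND_KGML = """\
<pathway name="path:map00720" title="Carbon fixation pathways in prokaryotes" category="Energy metabolism">
  <entry id="1" name="ec:1.1.1.37" type="enzyme">
    <graphics name="1.1.1.37" x="80" y="90" width="46" height="17"/>
  </entry>
  <entry id="2" name="cpd:C00149" type="compound">
    <graphics name="(S)-Malate" x="150" y="90" width="8" height="8"/>
  </entry>
</pathway>
"""

ANNOTATION_TSV = """\
item\tec_list\ttaxon_id\tko_list
AAKMR\t2.3.1.9\t5\tK00626
MLKER\t2.3.1.9;1.1.1.37\t6\t
TTWER\t2.8.3.8\t4\t
GGHKR\t\t7\t
"""

TAXONOMY_TSV = """\
taxon_id\tparent_id\trank\tname
1\t1\tno rank\troot
2\t1\tsuperkingdom\tBacteria
3\t2\tgenus\tClostridium
4\t3\tspecies\tClostridium butyricum
5\t3\tspecies\tClostridium acetobutylicum
6\t2\tgenus\tBacteroides
7\t6\tspecies\tBacteroides fragilis
"""


@pytest.fixture(scope="session")
def tiny_pathway():
    return ep.parse_kgml(TINY_KGML)


@pytest.fixture(scope="session")
def second_pathway():
    return ep.parse_kgml(SECOND_KGML)


@pytest.fixture(scope="session")
def taxonomy():
    return ep.Taxonomy.from_tsv(TAXONOMY_TSV)


@pytest.fixture()
def resolver():
    return ep.load_fixture_resolver(ANNOTATION_TSV, mode="peptide")


@pytest.fixture()
def small_index(tiny_pathway, second_pathway, resolver):
    """Two peptide samples in two groups mapped over both fixture pathways."""
    g1_text = "AAKMR\nMLKER\nAAKMR\nGGHKR\n"  # AAKMR x2, MLKER, GGHKR
    g2_text = "TTWER\nMLKER\nHHHHR\n"
    samples = {}
    assignment = {}
    for sid, text, group in (("s1", g1_text, "G1"), ("s2", g2_text, "G2")):
        entries, errors = ep.parse_peptides(text, sid)
        assert not errors
        samples[sid] = entries
        assignment[sid] = group
    groups = ep.assemble_groups(samples, assignment, "peptide")
    resolver_records = ep.annotate(
        sorted({e.sequence for es in samples.values() for e in es}), resolver
    )
    return ep.build_index(
        groups, resolver_records, [tiny_pathway, second_pathway], mode="peptide"
    )
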