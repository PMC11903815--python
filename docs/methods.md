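# Methods

This note documents the scientific and numerical choices behind
`ecpathway`: the model and its assumptions, the parameters that matter, what
the synthetic-data generator does and does not emulate, and the edge-case
behaviour of every computation.

## Inputs and counting conventions

Two input modes are supported and fixed for the whole analysis:

* **peptide mode** — plain-text peptide lists, one per sample. Repeated
  lines are merged into one entry with a `multiplicity`, and multiplicities
  are the counting weight throughout (a peptide seen 3 times contributes 3
  to its group total and to every match count). This occurrence-based
  default reflects how combined sample groups are usually totalled in
  peptide-centric studies; a `unique` switch collapses duplicates for
  workflows that count distinct sequences instead.
* **protein mode** — two-column tables (UniProtKB-style accession,
  abundance). Abundances may be areas, spectral counts or absolute counts;
  the pipeline only sums and ratios them, so the unit is the user's
  responsibility. For pathway *ranking* each accession counts once; its
  abundance is carried separately for the fold-change statistic.

Validation never aborts: every malformed line becomes a structured error
with its 1-based line number and reason, so problems at the end of a large
file surface before any expensive work. Header detection for protein tables
accepts a single leading line whose second field is non-numeric *and* whose
first field is not itself a valid accession — the second condition keeps a
data line with a corrupt abundance an error rather than silently dropping it
as a "header".

Isoleucine/leucine: both letters are legal and distinct at parse time.
Equivalence (the two are indistinguishable by mass spectrometry) is an
annotation-layer concern: the fixture resolver applies it only when
configured, while live peptide services typically equate them — the HTTP
client's docstring records this difference.

Designs with one or two groups are supported. The first group named in the
assignment is "group 1" of the DA formulas; order is preserved.

## EC numbers and wildcard matching

EC strings are validated against the four-field grammar with `-` permitted
only as a trailing run (`2.8.3.-`, `2.8.-.-`). A trailing wildcard matches
any value in that and later positions, **in either operand**: a peptide
annotated `2.8.3.-` matches a node labelled `2.8.3.8`, and a query
`2.8.3.-` retrieves all `2.8.3.*` nodes. Symmetric matching was chosen
because partial ECs occur both in annotations and on pathway maps.

## Pathway graphs

The KGML dialect covers `entry` (+`graphics`), `relation` and `reaction`
elements of KGML 0.7.x; unknown elements are ignored at debug level for
forward compatibility. Entry types enzyme/ortholog/gene become enzyme
nodes, compound → compound nodes, map → map-link nodes. `graphics` x/y are
box centers in pixels, y increasing downward; they are preserved verbatim
and converted to top-left corners only at render time. Real KGML carries no
pathway category; this dialect accepts an optional `category` attribute on
the root so category text filters are expressible, and the serializer
round-trips it. Serialization writes every edge as a `relation` element
with an explicit `direction` attribute: the graph (nodes, edges, kinds,
directions) round-trips; the provenance of an edge (relation vs reaction
element) deliberately does not.

A missing `graphics` block keeps the node with null geometry and a warning
(it still participates in matching and statistics; the renderer skips it).
A relation or reaction endpoint that names no entry is a hard parse error —
a dangling edge means the document is corrupt.

## The mapping index

`build_index` computes the transitive closure item→EC→node→pathway once.
Key decisions:

* **Once per item per pathway** for ranking: an item whose several ECs all
  hit the same pathway contributes its weight once. Ranking counts items
  ("peptides mapped to the pathway"), not annotation edges.
* **Once per item per node** for per-node statistics (DA); when one
  accession matches several ECs of the same node, its abundance counts once
  for that node.
* An EC→map link table, when supplied, additionally routes items to map ids
  *absent* from the parsed collection (pathways known only through link
  files still rank); for parsed pathways the node closure is authoritative
  and nothing is double counted.
* Zero-match pathways stay in the ranking tail (count 0, ties broken by map
  id ascending) so the exported ordered list is complete.

Filter semantics: the text filter is a case-insensitive substring over
category, map id and name; EC and compound filters test pathway *content*
(what the map contains), not what the user's data matched; all provided
criteria are conjoined and input order is preserved. The offered filter
options are exactly the union of node ECs / compound ids over the listed
pathways, which guarantees every offered option yields at least one result.

Per-node taxonomy is the LCA of the taxa of the items matched to that node
(node-level matching; adjacent reaction context is not pooled). Items
without a taxon are ignored; a node whose items carry no taxa has no
summary. Taxa are unweighted — abundance-weighted consensus is out of
scope.

## Differential abundance

* `da_peptides = Y/P2 − X/P1`, bounded in [−1, 1], antisymmetric under
  group swap. **Sign convention:** positive means a larger proportional
  abundance in group 2. The formula is taken as authoritative; prose
  descriptions of this statistic sometimes state the opposite polarity, so
  the convention is documented here and asserted by tests.
* `da_proteins = log2((Y/P2)/(X/P1))` after adding a pseudocount (default
  0) to X and Y. With pseudocount 0, zero numerators yield explicit ±inf
  sentinels and an all-zero node is NaN ("undefined"). Sentinels are
  preferred over clamping so absent-in-one-group nodes render saturated
  instead of vanishing; exports serialize them as `+inf`/`-inf`/`NA`. The
  statistic is invariant under rescaling all abundances by a common factor.
* Only enzyme nodes with at least one matched item in either group receive
  a comparison — the same "at least one match" rule the presence highlight
  uses; unmatched nodes have no evidence to contrast.
* `normalize_diverging` joins two sequential scales at a fixed midpoint
  (0 for both DA modes): each side is divided by its own maximum absolute
  deviation, so each populated side reaches ±1, the midpoint maps to 0, and
  the map is monotone per side. ±inf map to ±1 and are excluded from scale
  estimation; NaN propagates. Normalization scope is the selected pathway —
  the set of values displayed together — because a shared color range is
  only meaningful within one view.

No significance testing is attached to DA values; the statistic is
descriptive, and >2-group designs are rejected with a clear error.

## Rendering

The SVG overlay is standalone (the upstream raster map is never fetched): a
white canvas sized to the pathway bounding box, faint outlines for every
node with geometry, and `rect` elements reserved for highlights — equal
vertical segments per matched group in the presence view, one
diverging-colormap fill per compared node in the DA view plus a linear
gradient legend. Outlines are drawn as `path` elements precisely so the
rect count remains a checkable structural contract (highlighted nodes +
legend). The colormap interpolates `#2166AC` → `#F7F7F7` → `#B2182B`
(blue–white–red, midpoint white), conventional for fold-change displays;
NaN renders neutral grey.

## Synthetic data

The generator emulates the *statistical* structure the pipeline needs, not
mass-spectrometry reality:

* pathways are connected alternating compound–enzyme chains on a geometry
  grid — enough to exercise parsing, indexing and rendering, with none of
  the branching or cycles of real maps;
* samples are i.i.d. draws from an EC-labelled peptide pool: each planted
  effect EC owns `peptides_per_ec` unique random 8–12-mers (pools are
  disjoint by construction so no peptide is cross-annotated), the remaining
  probability mass produces unannotated background peptides. Group 2
  multiplies the target EC's rate by the enrichment factor and renormalizes
  the whole vector; the expected sign of Y/P2 − X/P1 per EC is recorded as
  ground truth. Defaults (baseline rate 0.1, factor 3, n=1000 per group)
  are the stated recovery conditions of the acceptance checks.

A green simulation test therefore establishes that the pipeline recovers
planted proportional shifts under ideal annotation — it says nothing about
resolver coverage, peptide detectability, shared peptides between taxa, or
abundance noise in real experiments.

The packaged 32-enzyme reference set (short-chain-fatty-acid metabolism:
butyrogenesis, propionogenesis, acetogenesis across four pathway maps) is
shipped as data, not code. The case-study runner categorizes each enzyme as
`not_reported` (none of its exact ECs among the annotations), `excluded`
(reported but member of no pathway), or `compared`, and scores the
three-way sign category (up/down/unaltered in group 2, with |DA| ≤ ε
counting as unaltered, ε default 0 since no threshold is standard) against
the direction its process is expected to move when group 1 is the
caloric-restriction-like condition: propionogenesis up in group 1,
butyrogenesis and acetogenesis up in group 2. The synthetic case study
plants factors 2.5 / 0.4 accordingly.

## Resolvers

Annotation is pluggable behind one contract: a batch of items in, one
record per *found* item out; unannotated items are absent, never errors
(they are tallied, since real community samples always contain large
unannotated fractions). Items are deduplicated, chunked into batches
(default 1000), and memoized per analysis session only — no on-disk cache,
to avoid staleness. Results are independent of batch size. The HTTP client
posts `{"peptides": [...]}` / `{"proteins": [...]}` and validates the JSON
payload field-by-field on receipt; transport failures carry the failed
batch for retry.

## Known limitations

* KO-only nodes (no EC) are parsed but unmatchable unless annotations carry
  ECs; EC numbers are the sole join key.
* Overview-map rendering conventions are ignored; geometry is taken as-is.
* The dense export enumerates (item, sample, EC, map) combinations; at
  metaproteome scale this file is large by design ("dense").
* Reconciling published group totals from supplementary peptide lists
  requires those files locally; the corresponding acceptance test states
  this and fails (honestly) when they are absent.
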