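"""Functional and taxonomic annotation of peptides and protein accessions.

Items are resolved to EC numbers, an NCBI-style taxon id, and optional KEGG
Orthology (KO) ids through a pluggable *resolver*.  Two resolvers are
provided behind the same contract:

* :class:`FixtureResolver` — offline, backed by a TSV table; the workhorse
  for testing and for any analysis with a precomputed annotation table.
* :class:`HttpResolver` — a thin JSON client mirroring batch
  peptide-info/protein-info endpoints (one POST per batch).  Note that the
  live peptide service equates isoleucine and leucine; the fixture resolver
  only does so when explicitly configured.

Unannotated items are *absent* from results, never errors: in community
samples a large fraction of peptides carries no enzymatic annotation and the
analysis must proceed regardless.
"""

from __future__ import annotations

import json
import re
import urllib.request
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Protocol, Sequence

#: EC number with optional trailing wildcard positions, e.g. "2.8.3.-".
_EC_SEGMENT_RE = re.compile(r"^(\d+)(\.(\d+|-)){3}$")

DEFAULT_BATCH_SIZE = 1000


def is_valid_ec(ec: str) -> bool:
    """True for a four-field EC string; '-' allowed only as a trailing run."""
    if not _EC_SEGMENT_RE.match(ec):
        return False
    parts = ec.split(".")
    seen_dash = False
    for p in parts:
        if p == "-":
            seen_dash = True
        elif seen_dash:
            return False
    return True


def ec_matches(query: str, target: str) -> bool:
    """Whether two EC strings denote overlapping enzyme classes.

    A trailing ``-`` segment matches any value in that and all later
    positions, in either operand: ``2.8.3.-`` matches ``2.8.3.8`` and
    vice versa.
    """
    for q, t in zip(query.split("."), target.split(".")):
        if q == "-" or t == "-":
            return True
        if q != t:
            return False
    return True


@dataclass(frozen=True)
class AnnotationRecord:
    """Annotations resolved for one input item."""

    item: str
    ec_numbers: frozenset[str]
    taxon_id: int | None = None
    ko_ids: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        for ec in self.ec_numbers:
            if not is_valid_ec(ec):
                raise ValueError(f"invalid EC number {ec!r}")


class ResolverError(RuntimeError):
    """Base class for resolver failures."""


class ResolverTransportError(ResolverError):
    """A batch could not be delivered; carries the failed batch for retry."""

    def __init__(self, message: str, batch: Sequence[str]):
        super().__init__(message)
        self.batch = list(batch)


class ResolverContractError(ResolverError):
    """The resolver answered with a payload violating the contract."""


class Resolver(Protocol):
    """Contract every resolver implements."""

    batch_size: int
    mode: str

    def resolve_batch(self, items: Sequence[str]) -> dict[str, AnnotationRecord]:
        """Return one record per item found; absent items are unannotated."""
        ...


class FixtureResolver:
    """Table-backed resolver for offline analyses and tests.

    The table maps item → (EC list, taxon id, KO list).  With
    ``il_equivalence`` enabled (peptide mode), isoleucine and leucine are
    treated as the same residue on lookup, emulating the live peptide
    service.
    """

    def __init__(
        self,
        table: Mapping[str, AnnotationRecord],
        mode: str,
        batch_size: int = DEFAULT_BATCH_SIZE,
        il_equivalence: bool = False,
    ):
        self.mode = mode
        self.batch_size = batch_size
        self.il_equivalence = il_equivalence and mode == "peptide"
        if self.il_equivalence:
            self._table = {self._key(k): v for k, v in table.items()}
        else:
            self._table = dict(table)

    def _key(self, item: str) -> str:
        return item.replace("I", "L") if self.il_equivalence else item

    def resolve_batch(self, items: Sequence[str]) -> dict[str, AnnotationRecord]:
        out: dict[str, AnnotationRecord] = {}
        for item in items:
            rec = self._table.get(self._key(item))
            if rec is not None:
                out[item] = AnnotationRecord(
                    item=item,
                    ec_numbers=rec.ec_numbers,
                    taxon_id=rec.taxon_id,
                    ko_ids=rec.ko_ids,
                )
        return out


def load_fixture_resolver(
    tsv_text: str,
    mode: str,
    *,
    batch_size: int = DEFAULT_BATCH_SIZE,
    il_equivalence: bool = False,
) -> FixtureResolver:
    """Build a :class:`FixtureResolver` from TSV content.

    Columns: ``item``, ``ec_list`` (semicolon-separated, may be empty),
    ``taxon_id`` (optional), ``ko_list`` (optional, semicolon-separated).
    A header line starting with ``item`` is skipped.  A malformed EC string
    raises a load-time error naming the offending row.
    """
    table: dict[str, AnnotationRecord] = {}
    for rowno, raw in enumerate(tsv_text.splitlines(), start=1):
        if not raw.strip():
            continue
        fields = raw.rstrip("\n").split("\t")
        if rowno == 1 and fields[0].strip().lower() == "item":
            continue
        item = fields[0].strip()
        ecs = frozenset(
            e.strip() for e in (fields[1].split(";") if len(fields) > 1 and fields[1].strip() else []) if e.strip()
        )
        for ec in ecs:
            if not is_valid_ec(ec):
                raise ValueError(f"row {rowno}: invalid EC number {ec!r}")
        taxon = None
        if len(fields) > 2 and fields[2].strip():
            taxon = int(fields[2])
        kos = frozenset(
            k.strip() for k in (fields[3].split(";") if len(fields) > 3 and fields[3].strip() else []) if k.strip()
        )
        table[item] = AnnotationRecord(item=item, ec_numbers=ecs, taxon_id=taxon, ko_ids=kos)
    return FixtureResolver(table, mode=mode, batch_size=batch_size, il_equivalence=il_equivalence)


class HttpResolver:
    """JSON batch client mirroring peptide-info/protein-info endpoints.

    Request body: ``{"peptides": [...]}`` or ``{"proteins": [...]}``.
    Response: a JSON list of objects with at least ``item`` (or
    ``peptide``/``protein``), ``ec`` (list of EC strings) and optionally
    ``taxon_id`` and ``ko`` fields.  Payloads are validated on receipt and a
    contract violation is raised with the offending detail.

    ``opener`` is injectable so the transport can be mocked offline.
    """

    def __init__(
        self,
        base_url: str,
        mode: str,
        batch_size: int = DEFAULT_BATCH_SIZE,
        opener=None,
        timeout: float = 60.0,
    ):
        self.base_url = base_url.rstrip("/")
        self.mode = mode
        self.batch_size = batch_size
        self.timeout = timeout
        self._opener = opener or urllib.request.urlopen

    @property
    def _endpoint(self) -> str:
        return f"{self.base_url}/{'peptinfo' if self.mode == 'peptide' else 'protinfo'}"

    def resolve_batch(self, items: Sequence[str]) -> dict[str, AnnotationRecord]:
        key = "peptides" if self.mode == "peptide" else "proteins"
        body = json.dumps({key: list(items)}).encode()
        req = urllib.request.Request(
            self._endpoint, data=body, headers={"Content-Type": "application/json"}
        )
        try:
            with self._opener(req, timeout=self.timeout) as resp:
                payload = json.loads(resp.read().decode())
        except (OSError, ValueError) as exc:
            raise ResolverTransportError(f"batch request failed: {exc}", items) from exc
        return self._parse_payload(payload)

    def _parse_payload(self, payload) -> dict[str, AnnotationRecord]:
        if not isinstance(payload, list):
            raise ResolverContractError(
                f"expected a JSON list of annotation objects, got {type(payload).__name__}"
            )
        out: dict[str, AnnotationRecord] = {}
        for i, obj in enumerate(payload):
            if not isinstance(obj, dict):
                raise ResolverContractError(f"entry {i} is not an object")
            item = obj.get("item") or obj.get("peptide") or obj.get("protein")
            if not isinstance(item, str):
                raise ResolverContractError(f"entry {i} lacks an item identifier")
            ecs = obj.get("ec", [])
            if not isinstance(ecs, list) or not all(isinstance(e, str) for e in ecs):
                raise ResolverContractError(f"entry {i}: 'ec' must be a list of strings")
            bad = [e for e in ecs if not is_valid_ec(e)]
            if bad:
                raise ResolverContractError(f"entry {i}: invalid EC number(s) {bad}")
            taxon = obj.get("taxon_id")
            if taxon is not None and not isinstance(taxon, int):
                raise ResolverContractError(f"entry {i}: 'taxon_id' must be an integer")
            kos = obj.get("ko", [])
            out[item] = AnnotationRecord(
                item=item,
                ec_numbers=frozenset(ecs),
                taxon_id=taxon,
                ko_ids=frozenset(kos),
            )
        return out


class Annotator:
    """Memoizing front end over a resolver.

    Items are deduplicated, chunked into batches of at most
    ``resolver.batch_size``, and each (mode, item) pair is queried at most
    once per analysis session.  The cache lives only for the lifetime of
    this object — no on-disk persistence, to avoid stale annotations.
    """

    def __init__(self, resolver: Resolver):
        self.resolver = resolver
        self._cache: dict[str, AnnotationRecord | None] = {}

    @property
    def unannotated_count(self) -> int:
        """How many queried items carried no annotation."""
        return sum(1 for v in self._cache.values() if v is None)

    def annotate(self, items: Iterable[str]) -> dict[str, AnnotationRecord]:
        todo: list[str] = []
        seen: set[str] = set()
        for item in items:
            if item in seen:
                continue
            seen.add(item)
            if item not in self._cache:
                todo.append(item)
        bs = self.resolver.batch_size
        for start in range(0, len(todo), bs):
            batch = todo[start : start + bs]
            found = self.resolver.resolve_batch(batch)
            for item in batch:
                self._cache[item] = found.get(item)
        return {i: self._cache[i] for i in seen if self._cache.get(i) is not None}


def annotate(items: Sequence[str], resolver: Resolver) -> dict[str, AnnotationRecord]:
    """One-shot annotation of an item list (see :class:`Annotator`)."""
    if not items:
        raise ValueError("items must be non-empty")
    return Annotator(resolver).annotate(items)
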