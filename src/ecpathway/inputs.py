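"""Sample input parsing and group assembly.

Two input formats are supported, mirroring the two ways metaproteomic
identifications are commonly reported:

* **peptide lists** — plain text, one peptide sequence per line, one file per
  sample.  Repeated sequences within a file are merged into a single entry
  whose ``multiplicity`` records the occurrence count, so spectral evidence
  is preserved (a ``unique`` switch collapses duplicates instead).
* **protein tables** — two columns (UniProtKB-style accession, numeric
  abundance), tab- or comma-separated, with an optional auto-detected header.

Validation never aborts early: every malformed line is reported as a
:class:`LineError` carrying the 1-based line number, the raw line, and a
human-readable reason, so a user learns about a bad last line before any
expensive processing starts.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

#: The 20 canonical amino-acid residue letters.
CANONICAL_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: UniProtKB-style accession: 6 or 10 alphanumerics, first character a letter.
ACCESSION_RE = re.compile(r"^[A-Z]([A-Z0-9]{5}|[A-Z0-9]{9})$")

PEPTIDE_MODE = "peptide"
PROTEIN_MODE = "protein"


@dataclass(frozen=True)
class PeptideEntry:
    """One distinct peptide sequence observed in one sample."""

    sequence: str
    sample_id: str
    multiplicity: int = 1

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("peptide sequence must be non-empty")
        if self.multiplicity < 1:
            raise ValueError("multiplicity must be a positive integer")


@dataclass(frozen=True)
class ProteinEntry:
    """One protein accession with its reported abundance in one sample.

    The abundance may be any non-negative quantification (area, spectral
    count, absolute count); its meaning is the user's, the pipeline only
    sums and ratios it.
    """

    accession: str
    abundance: float
    sample_id: str

    def __post_init__(self) -> None:
        if self.abundance < 0:
            raise ValueError("abundance must be non-negative")


@dataclass(frozen=True)
class LineError:
    """A rejected input line: where it was and why it was rejected."""

    line_number: int
    raw_line: str
    reason: str

    def __post_init__(self) -> None:
        if self.line_number < 1:
            raise ValueError("line_number is 1-based")
        if not self.reason:
            raise ValueError("reason must be non-empty")


@dataclass
class SampleGroup:
    """A named collection of samples plus its total item count.

    ``total_count`` is the group denominator of the differential-abundance
    formulas: summed peptide multiplicities in peptide mode, summed protein
    abundances in protein mode.  ``entries`` keeps the per-sample entries so
    downstream index construction does not need a second data structure.
    """

    name: str
    samples: list[str]
    total_count: float
    entries: dict[str, list] = field(default_factory=dict, repr=False)


class GroupAssemblyError(ValueError):
    """Raised when the sample→group assignment is inconsistent."""


def parse_peptides(
    text: str,
    sample_id: str,
    *,
    extra_residues: str = "",
    unique: bool = False,
) -> tuple[list[PeptideEntry], list[LineError]]:
    """Parse a peptide-list file into entries and per-line errors.

    Every non-blank line yields exactly one :class:`PeptideEntry` or one
    :class:`LineError`; blank lines are skipped silently.  Duplicate
    sequences are merged with their multiplicity incremented (or kept at 1
    when ``unique`` is set).  Sequences are upper-cased before validation;
    ``extra_residues`` widens the accepted alphabet (e.g. ``"UOBXZ"``).
    """
    if not sample_id:
        raise ValueError("sample_id must be non-empty")
    alphabet = CANONICAL_RESIDUES | set(extra_residues.upper())
    counts: dict[str, int] = {}
    errors: list[LineError] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        seq = raw.strip().upper()
        if not seq:
            continue
        bad = sorted(set(seq) - alphabet)
        if bad:
            errors.append(
                LineError(
                    line_number=lineno,
                    raw_line=raw,
                    reason="invalid character(s) %s: not canonical amino-acid residues"
                    % ", ".join(repr(c) for c in bad),
                )
            )
            continue
        counts[seq] = counts.get(seq, 0) + 1
    entries = [
        PeptideEntry(sequence=s, sample_id=sample_id, multiplicity=1 if unique else n)
        for s, n in counts.items()
    ]
    return entries, errors


def _split_protein_line(line: str) -> list[str] | None:
    """Split on tab if present, else on comma; None when neither works."""
    if "\t" in line:
        return [f.strip() for f in line.split("\t")]
    if "," in line:
        return [f.strip() for f in line.split(",")]
    return None


def _looks_like_header(line: str) -> bool:
    # a header has a non-numeric second field AND a first field that is not
    # itself an accession (a data line with a bad abundance must stay an error)
    fields = _split_protein_line(line)
    if not fields or len(fields) < 2:
        return False
    if ACCESSION_RE.match(fields[0].upper()):
        return False
    try:
        float(fields[1])
    except ValueError:
        return True
    return False


def parse_proteins(
    text: str, sample_id: str
) -> tuple[list[ProteinEntry], list[LineError]]:
    """Parse a two-column protein table (accession, abundance).

    The delimiter (tab or comma) is auto-detected per line.  A single
    leading line whose second field is non-numeric is treated as a header
    and skipped.  Lines with a malformed accession, a missing column, or a
    non-numeric / negative abundance yield :class:`LineError` values.
    """
    if not sample_id:
        raise ValueError("sample_id must be non-empty")
    entries: list[ProteinEntry] = []
    errors: list[LineError] = []
    lines = text.splitlines()
    start = 0
    # header detection only applies to the first non-blank line
    for i, raw in enumerate(lines):
        if raw.strip():
            if _looks_like_header(raw):
                start = i + 1
            break
    for lineno in range(start, len(lines)):
        raw = lines[lineno]
        if not raw.strip():
            continue
        fields = _split_protein_line(raw)
        if fields is None or len(fields) < 2:
            errors.append(
                LineError(lineno + 1, raw, "expected two columns (accession, abundance)")
            )
            continue
        accession, abundance_text = fields[0].upper(), fields[1]
        if not ACCESSION_RE.match(accession):
            errors.append(
                LineError(
                    lineno + 1,
                    raw,
                    f"{fields[0]!r} is not a UniProtKB-style accession "
                    "(6 or 10 alphanumerics, first character a letter)",
                )
            )
            continue
        try:
            abundance = float(abundance_text)
        except ValueError:
            errors.append(
                LineError(lineno + 1, raw, f"non-numeric abundance {abundance_text!r}")
            )
            continue
        if abundance != abundance or abundance < 0:  # NaN or negative
            errors.append(
                LineError(lineno + 1, raw, f"abundance must be a non-negative number, got {abundance_text!r}")
            )
            continue
        entries.append(ProteinEntry(accession=accession, abundance=abundance, sample_id=sample_id))
    return entries, errors


def entry_weight(entry, mode: str) -> float:
    """The counting weight of one entry: multiplicity or abundance."""
    if mode == PEPTIDE_MODE:
        return float(entry.multiplicity)
    if mode == PROTEIN_MODE:
        return float(entry.abundance)
    raise ValueError(f"unknown mode {mode!r}")


def assemble_groups(
    samples: Mapping[str, Sequence],
    assignment: Mapping[str, str],
    mode: str,
) -> list[SampleGroup]:
    """Assemble samples into 1 or 2 named groups with their denominators.

    ``total_count`` sums peptide multiplicities (peptide mode) or protein
    abundances (protein mode) over all entries of the member samples.
    Group order follows first appearance in ``assignment``, so the first
    group named is "group 1" of the differential-abundance formulas.
    """
    if mode not in (PEPTIDE_MODE, PROTEIN_MODE):
        raise ValueError(f"unknown mode {mode!r}")
    missing = [s for s in samples if s not in assignment]
    if missing:
        raise GroupAssemblyError(
            "sample(s) not assigned to any group: " + ", ".join(sorted(missing))
        )
    order: list[str] = []
    for sample_id in assignment:
        gname = assignment[sample_id]
        if gname not in order:
            order.append(gname)
    if len(order) > 2:
        raise GroupAssemblyError(
            f"{len(order)} groups given; only one- or two-group designs are supported"
        )
    groups = []
    for gname in order:
        member_ids = [s for s in assignment if assignment[s] == gname and s in samples]
        entries = {s: list(samples[s]) for s in member_ids}
        total = sum(
            entry_weight(e, mode) for es in entries.values() for e in es
        )
        groups.append(
            SampleGroup(name=gname, samples=member_ids, total_count=total, entries=entries)
        )
    return groups
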