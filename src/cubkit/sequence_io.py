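"""Reading CDS FASTA files and quality-screening the sequences.

A coding sequence enters the downstream statistics only if it looks like a
complete, clean open reading frame: length a multiple of three and at least
300 nt, unambiguous bases, an AUG start, a proper stop at the end and no
in-frame stop before it.  Sequences failing a rule are reported with the
first failing rule as the reason, never silently dropped.
"""

from __future__ import annotations

import csv
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, TextIO

from Bio import SeqIO

from .genetics import GENETIC_CODE, START_CODON, STOP_CODONS

__all__ = [
    "GeneRecord",
    "FilterReport",
    "parse_fasta",
    "filter_cds",
    "write_fasta",
    "write_filter_report",
    "REASON_CODES",
]

_VALID_BASES = frozenset("ACGU")

#: Screening rules in the order they are checked; the reason reported for a
#: rejected record is the first rule it fails.
REASON_CODES = (
    "length_not_multiple_of_3",
    "too_short",
    "invalid_base",
    "bad_start",
    "bad_stop",
    "internal_stop",
)


@dataclass(frozen=True)
class GeneRecord:
    """One CDS: an identifier plus its nucleotide sequence (RNA alphabet)."""

    id: str
    seq: str

    @property
    def length_nt(self) -> int:
        return len(self.seq)

    def codons(self) -> list[str]:
        """In-frame triplets, including start and terminal stop."""
        return [self.seq[i : i + 3] for i in range(0, len(self.seq) - 2, 3)]

    def translate(self) -> str:
        """Protein sequence, excluding the terminal stop if present."""
        aas = [GENETIC_CODE.get(c, "X") for c in self.codons()]
        if aas and aas[-1] == "*":
            aas = aas[:-1]
        return "".join(aas)


@dataclass
class FilterReport:
    """Outcome of screening a CDS set: kept records and per-reason rejects."""

    kept: list[GeneRecord]
    rejected: list[tuple[GeneRecord, str]]
    counts: Counter = field(default_factory=Counter)

    def __post_init__(self) -> None:
        if not self.counts:
            self.counts = Counter(reason for _, reason in self.rejected)

    @property
    def n_input(self) -> int:
        return len(self.kept) + len(self.rejected)


def _normalize(seq: str) -> str:
    return "".join(seq.split()).upper().replace("T", "U")


def parse_fasta(path: str | Path | TextIO) -> list[GeneRecord]:
    """Read a nucleotide FASTA into :class:`GeneRecord` objects.

    Whitespace inside sequences is stripped, case is normalised to upper
    and DNA ``T`` is converted to RNA ``U``.  An empty file or a duplicate
    identifier raises ``ValueError``.
    """
    records = [
        GeneRecord(rec.id, _normalize(str(rec.seq)))
        for rec in SeqIO.parse(path, "fasta")
    ]
    if not records:
        raise ValueError(f"no FASTA records found in {path!r}")
    seen: set[str] = set()
    for rec in records:
        if not rec.id:
            raise ValueError("empty sequence identifier")
        if rec.id in seen:
            raise ValueError(f"duplicate sequence id: {rec.id!r}")
        seen.add(rec.id)
    return records


def _first_failure(rec: GeneRecord, min_len: int) -> str | None:
    seq = rec.seq
    if len(seq) % 3 != 0:
        return "length_not_multiple_of_3"
    if len(seq) < min_len:
        return "too_short"
    if not _VALID_BASES.issuperset(seq):
        return "invalid_base"
    codons = rec.codons()
    if codons[0] != START_CODON:
        return "bad_start"
    if codons[-1] not in STOP_CODONS:
        return "bad_stop"
    if any(c in STOP_CODONS for c in codons[:-1]):
        return "internal_stop"
    return None


def filter_cds(records: Iterable[GeneRecord], min_len: int = 300) -> FilterReport:
    """Apply the CDS screening rules, reporting kept and rejected records.

    Rules, in order: (1) length divisible by 3; (2) length >= ``min_len``
    nt (start and stop included); (3) only unambiguous A/C/G/U bases;
    (4) AUG start codon; (5) UAA/UAG/UGA terminal codon; (6) no in-frame
    internal stop.  Each rejected record carries the first failing rule.
    """
    kept: list[GeneRecord] = []
    rejected: list[tuple[GeneRecord, str]] = []
    for rec in records:
        reason = _first_failure(rec, min_len)
        if reason is None:
            kept.append(rec)
        else:
            rejected.append((rec, reason))
    return FilterReport(kept=kept, rejected=rejected)


def write_fasta(records: Iterable[GeneRecord], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


def write_filter_report(report: FilterReport, path: str | Path) -> None:
    """TSV rejection report: id, length, reason."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["id", "length", "reason"])
        for rec, reason in report.rejected:
            writer.writerow([rec.id, rec.length_nt, reason])
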