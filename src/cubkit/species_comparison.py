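"""Cross-species comparison of codon usage frequency tables.

Tables use the Codon Usage Database ("Kazusa") flat format — codon,
frequency per 1000 codons and raw count — and two species are called
significantly different at a codon when the frequency ratio is >= 2 or
<= 0.5 (inclusive).
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from typing import Mapping

import pandas as pd

from .codon_metrics import CodonCountTable
from .genetics import CODONS, STOP_CODONS, SYNONYMOUS_CODONS

__all__ = ["FrequencyTable", "parse_kazusa", "table_from_counts", "usage_ratio", "RatioReport"]

_ENTRY_RE = re.compile(
    r"([ACGTUacgtu]{3})\s+(\d+(?:\.\d+)?)(?:\s*\(\s*(\d+)\s*\))?"
)


@dataclass(frozen=True)
class FrequencyTable:
    """Per-codon usage frequency (per 1000 codons) for one species."""

    species: str
    freq: Mapping[str, float]           # codon -> per-1000 frequency
    counts: Mapping[str, int] | None = None

    def __post_init__(self) -> None:
        missing = set(CODONS) - set(self.freq)
        if missing:
            raise ValueError(f"missing codons: {sorted(missing)}")
        if any(v < 0 for v in self.freq.values()):
            raise ValueError("negative frequency")


def parse_kazusa(text: str, species: str = "") -> FrequencyTable:
    """Parse a Kazusa-style flat codon usage table.

    Entries are ``codon  freq-per-1000 ( count )`` in any order; DNA or
    RNA codon spelling is accepted and normalised to RNA.  A counts-only
    table (bare ``codon  count`` pairs whose values clearly do not sum
    to ~1000) is converted to per-1000 frequencies.  Missing codons or
    no parseable entries raise ``ValueError``.
    """
    freq: dict[str, float] = {}
    counts: dict[str, int] = {}
    have_counts = True
    for m in _ENTRY_RE.finditer(text):
        codon = m.group(1).upper().replace("T", "U")
        if codon in freq:
            raise ValueError(f"duplicate codon entry: {codon}")
        freq[codon] = float(m.group(2))
        if m.group(3) is not None:
            counts[codon] = int(m.group(3))
        else:
            have_counts = False
    if not freq:
        raise ValueError("no codon entries found")
    missing = set(CODONS) - set(freq)
    if missing:
        raise ValueError(f"table incomplete; missing codons: {sorted(missing)}")
    total = sum(freq.values())
    if not have_counts and abs(total - 1000) > 50:
        # bare integers that do not behave like per-1000 frequencies:
        # treat the second field as raw counts and normalise
        counts = {c: int(v) for c, v in freq.items()}
        freq = {c: 1000 * v / total for c, v in freq.items()}
    return FrequencyTable(species=species, freq=freq, counts=counts or None)


def table_from_counts(counts: CodonCountTable, species: str = "") -> FrequencyTable:
    """Per-1000 frequency table from a pooled codon count table."""
    total = counts.total()
    if total == 0:
        raise ValueError("empty count table")
    return FrequencyTable(
        species=species,
        freq={c: 1000 * counts[c] / total for c in CODONS},
        counts={c: counts[c] for c in CODONS},
    )


@dataclass
class RatioReport:
    """Per-codon frequency ratios between two species with divergence flags."""

    species_a: str
    species_b: str
    table: pd.DataFrame  # index codon; ratio, flagged, synonymous

    @property
    def n_flagged(self) -> int:
        """Flagged codons among the 59 synonymous ones."""
        t = self.table
        return int((t["flagged"] & t["synonymous"]).sum())

    @property
    def verdict(self) -> str:
        return "similar" if self.n_flagged == 0 else "different"


def usage_ratio(a: FrequencyTable, b: FrequencyTable) -> RatioReport:
    """Per-codon usage ratio freq_a / freq_b with the >=2 / <=0.5 flag.

    A codon with zero frequency in one species but not the other is
    flagged as divergent (ratio ``inf`` or 0).  Stop codons are excluded
    from the table; AUG/UGG appear but are marked non-synonymous and do
    not enter the flag summary.
    """
    rows = []
    for c in CODONS:
        if c in STOP_CODONS:
            continue
        fa, fb = a.freq[c], b.freq[c]
        if fb == 0:
            ratio = math.inf if fa > 0 else math.nan
            flagged = fa > 0
        else:
            ratio = fa / fb
            flagged = ratio >= 2 or ratio <= 0.5
        rows.append(
            {
                "codon": c,
                "freq_a": fa,
                "freq_b": fb,
                "ratio": ratio,
                "flagged": flagged,
                "synonymous": c in SYNONYMOUS_CODONS,
            }
        )
    return RatioReport(
        species_a=a.species, species_b=b.species,
        table=pd.DataFrame(rows).set_index("codon"),
    )
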