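"""High-frequency codons, ENC-based expression groups and the delta-RSCU
screen for optimal codons.

A codon is *high-frequency* when its pooled-genome RSCU exceeds 1.  The
screen for *optimal* codons contrasts putative high- and low-expression
gene groups — the deciles of genes with the most and least biased codon
usage by ENC — and keeps codons with

    delta-RSCU = RSCU_high - RSCU_low >= 0.08   and   RSCU_high > 1

that are also high-frequency codons of the whole genome.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from functools import reduce
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .codon_metrics import CodonCountTable, rscu
from .genetics import GENETIC_CODE, SPLIT, SYNONYMOUS_CODONS, FamilyScheme

__all__ = [
    "high_frequency_codons",
    "ExpressionGroups",
    "expression_groups",
    "optimal_codons",
    "shared_codons",
    "ending_tally",
]


def high_frequency_codons(rscu_values: Mapping[str, float]) -> set[str]:
    """Codons with RSCU strictly greater than 1 (AUG/UGG never qualify)."""
    return {
        c for c in SYNONYMOUS_CODONS
        if not math.isnan(rscu_values.get(c, math.nan)) and rscu_values[c] > 1
    }


@dataclass(frozen=True)
class ExpressionGroups:
    """Gene ids of the putative high- and low-expression deciles."""

    high: tuple[str, ...]
    low: tuple[str, ...]
    fraction: float
    low_enc_is_high_expression: bool


def expression_groups(
    enc_by_gene: Mapping[str, float],
    fraction: float = 0.10,
    low_enc_is_high_expression: bool = True,
) -> ExpressionGroups:
    """Split genes into expression groups by their ENC extremes.

    By default the ``fraction`` of genes with the *lowest* ENC (strongest
    bias) is taken as the high-expression group and the highest-ENC
    fraction as low-expression, the usual extreme-ENC convention;
    ``low_enc_is_high_expression=False`` inverts the reading.  Ties at
    the cutoff are broken by gene id, so the split is deterministic.
    """
    items = [(gid, e) for gid, e in enc_by_gene.items() if not math.isnan(e)]
    n = len(items)
    if n < 2 / fraction:
        raise ValueError(f"need at least {math.ceil(2 / fraction)} genes, got {n}")
    size = math.ceil(fraction * n)
    items.sort(key=lambda t: (t[1], t[0]))
    if len({e for _, e in items}) == 1:
        warnings.warn("all ENC values equal; groups filled by gene id order")
    lowest = tuple(gid for gid, _ in items[:size])
    highest = tuple(gid for gid, _ in items[-size:])
    if low_enc_is_high_expression:
        high, low = lowest, highest
    else:
        high, low = highest, lowest
    return ExpressionGroups(
        high=high, low=low, fraction=fraction,
        low_enc_is_high_expression=low_enc_is_high_expression,
    )


def optimal_codons(
    high_counts: CodonCountTable,
    low_counts: CodonCountTable,
    pooled_rscu: Mapping[str, float],
    threshold: float = 0.08,
    scheme: FamilyScheme = SPLIT,
) -> pd.DataFrame:
    """Delta-RSCU screen: per-codon report with the optimal flag.

    Columns: amino acid, RSCU in each group, delta_rscu, the genome
    high-frequency flag and ``optimal`` — true when delta_rscu >= the
    threshold (inclusive), RSCU_high > 1 and the codon is a genome
    high-frequency codon.
    """
    r_high = rscu(high_counts, scheme)
    r_low = rscu(low_counts, scheme)
    hi_freq = high_frequency_codons(pooled_rscu)
    rows = []
    for c in SYNONYMOUS_CODONS:
        dr = r_high[c] - r_low[c]
        rows.append(
            {
                "codon": c,
                "amino_acid": GENETIC_CODE[c],
                "rscu_high": r_high[c],
                "rscu_low": r_low[c],
                "delta_rscu": dr,
                "high_frequency": c in hi_freq,
                "optimal": (
                    not math.isnan(dr)
                    and dr >= threshold
                    and r_high[c] > 1
                    and c in hi_freq
                ),
            }
        )
    return pd.DataFrame(rows).set_index("codon")


def shared_codons(sets: Sequence[Iterable[str]]) -> set[str]:
    """Plain intersection of two or more codon sets."""
    if len(sets) < 2:
        raise ValueError("need at least two sets")
    return reduce(lambda a, b: a & b, (set(s) for s in sets))


def ending_tally(codons: Iterable[str]) -> dict[str, int]:
    """Count codons ending in A/U versus C/G."""
    codons = list(codons)
    au = sum(1 for c in codons if c[2] in "AU")
    return {"AU_ending": au, "CG_ending": len(codons) - au}
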