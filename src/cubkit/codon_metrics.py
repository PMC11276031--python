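"""Codon-composition statistics: counts, RSCU, GC by position, ENC,
CAI/CBI/Fop and protein-level indices.

Relative synonymous codon usage (RSCU) for codon *j* of a family with
*n* synonymous codons is the observed count divided by the count expected
under uniform usage within the family,

    RSCU_j = x_j / ((1/n) * sum_k x_k),

so RSCU = 1 means no bias, > 1 a preferred codon.  The effective number of
codons (ENC) is Wright's statistic: per amino acid, a homozygosity
F = (n * sum p_i^2 - 1) / (n - 1) from its codon usage fractions p_i and
total count n; F is averaged within degeneracy classes (9 two-fold,
1 three-fold, 5 four-fold, 3 six-fold) and

    ENC = 2 + 9/F2 + 1/F3 + 5/F4 + 3/F6,

capped at 61.  A gene using one codon per amino acid scores 20 (maximal
bias); uniform usage scores 61 (none).
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .genetics import (
    AA_TO_CODONS,
    CODONS,
    GENETIC_CODE,
    SENSE_CODONS,
    SINGLE_CODONS,
    SPLIT,
    STANDARD,
    STOP_CODONS,
    SYNONYMOUS_CODONS,
    FamilyScheme,
)
from .sequence_io import GeneRecord

__all__ = [
    "CodonCountTable",
    "count_codons",
    "pool_counts",
    "rscu",
    "rscu_series",
    "positional_gc",
    "silent_site_composition",
    "enc",
    "build_cai_weights",
    "cai",
    "cbi_fop",
    "protein_indices",
    "metrics_table",
    "correlation_matrix",
    "KYTE_DOOLITTLE",
]

#: Kyte-Doolittle hydropathy values, used for the Gravy index.
KYTE_DOOLITTLE: dict[str, float] = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

AROMATIC = frozenset("FYW")


@dataclass(frozen=True)
class CodonCountTable:
    """Integer counts over all 64 codons, per gene or pooled over a set."""

    counts: Mapping[str, int]
    scope: str = "gene"  # "gene" | "pooled"

    def __post_init__(self) -> None:
        extra = set(self.counts) - set(CODONS)
        if extra:
            raise ValueError(f"unknown codons: {sorted(extra)}")
        if any(v < 0 for v in self.counts.values()):
            raise ValueError("negative codon count")

    def __getitem__(self, codon: str) -> int:
        return self.counts.get(codon, 0)

    def __add__(self, other: "CodonCountTable") -> "CodonCountTable":
        merged = Counter({c: self[c] for c in CODONS})
        merged.update({c: other[c] for c in CODONS})
        return CodonCountTable(dict(merged), scope="pooled")

    def total(self, codons: Iterable[str] = CODONS) -> int:
        return sum(self[c] for c in codons)

    def sense_total(self) -> int:
        return self.total(SENSE_CODONS)


def count_codons(gene: GeneRecord) -> CodonCountTable:
    """In-frame codon counts for one gene, terminal stop included."""
    if gene.length_nt % 3 != 0:
        raise ValueError(f"{gene.id}: length {gene.length_nt} not a multiple of 3")
    counts = Counter(gene.codons())
    extra = set(counts) - set(CODONS)
    if extra:
        raise ValueError(f"{gene.id}: non-standard codons {sorted(extra)}")
    return CodonCountTable(dict(counts), scope="gene")


def pool_counts(tables: Iterable[CodonCountTable]) -> CodonCountTable:
    """Sum per-gene count tables into a pooled genome table."""
    merged: Counter = Counter()
    for t in tables:
        merged.update({c: t[c] for c in CODONS if t[c]})
    return CodonCountTable(dict(merged), scope="pooled")


def rscu(counts: CodonCountTable, scheme: FamilyScheme = SPLIT) -> dict[str, float]:
    """RSCU per sense codon under the given family scheme.

    Families with zero total usage get ``nan`` (undefined, not zero);
    the single-codon families AUG and UGG are 1 by definition.
    """
    out: dict[str, float] = {"AUG": 1.0, "UGG": 1.0}
    for fam in scheme.families:
        if len(fam) == 1:
            continue
        total = sum(counts[c] for c in fam)
        n = len(fam)
        for c in fam:
            out[c] = counts[c] * n / total if total > 0 else math.nan
    return out


def rscu_series(counts: CodonCountTable, scheme: FamilyScheme = SPLIT) -> pd.Series:
    """RSCU as a Series indexed by codon, in fixed codon order."""
    vals = rscu(counts, scheme)
    return pd.Series({c: vals[c] for c in SENSE_CODONS}, name="rscu")


def positional_gc(counts: CodonCountTable) -> dict[str, float]:
    """G+C fraction at codon positions 1-3 over sense codons (stops excluded).

    Returns gc1, gc2, gc3 plus the derived gc12 = (gc1+gc2)/2 and
    gc_all = (gc1+gc2+gc3)/3.
    """
    total = counts.sense_total()
    if total == 0:
        raise ValueError("no sense codons")
    gc_pos = [0, 0, 0]
    for codon in SENSE_CODONS:
        x = counts[codon]
        if not x:
            continue
        for k in range(3):
            if codon[k] in "GC":
                gc_pos[k] += x
    gc1, gc2, gc3 = (g / total for g in gc_pos)
    return {
        "gc1": gc1,
        "gc2": gc2,
        "gc3": gc3,
        "gc12": (gc1 + gc2) / 2,
        "gc_all": (gc1 + gc2 + gc3) / 3,
    }


def silent_site_composition(counts: CodonCountTable) -> dict[str, float]:
    """Base composition at synonymous third positions (CodonW convention).

    Only codons of degenerate amino-acid families count (Met, Trp and
    stops excluded).  For each base B, the value is the number of
    synonymous codons ending in B divided by the number of synonymous
    codons whose family offers a B-ending alternative — so the four
    values need not sum to one.  ``gc3s`` is the plain G+C fraction over
    all synonymous third positions.
    """
    syn_total = counts.total(SYNONYMOUS_CODONS)
    if syn_total == 0:
        raise ValueError("no synonymous codons")
    out: dict[str, float] = {}
    for base, key in (("A", "a3s"), ("U", "t3s"), ("C", "c3s"), ("G", "g3s")):
        num = 0
        denom = 0
        for aa, codons in AA_TO_CODONS.items():
            if len(codons) < 2:
                continue
            if not any(c[2] == base for c in codons):
                continue
            fam_count = sum(counts[c] for c in codons)
            denom += fam_count
            num += sum(counts[c] for c in codons if c[2] == base)
        out[key] = num / denom if denom else math.nan
    gc3 = sum(counts[c] for c in SYNONYMOUS_CODONS if c[2] in "GC")
    out["gc3s"] = gc3 / syn_total
    return out


def _wright_class_means(counts: CodonCountTable) -> dict[int, float]:
    """Mean homozygosity F per degeneracy class over usable amino acids."""
    f_by_class: dict[int, list[float]] = {2: [], 3: [], 4: [], 6: []}
    for aa, codons in AA_TO_CODONS.items():
        k = len(codons)
        if k < 2:
            continue
        n = sum(counts[c] for c in codons)
        if n < 2:
            continue
        p2 = sum((counts[c] / n) ** 2 for c in codons)
        f = (n * p2 - 1) / (n - 1)
        f_by_class[k].append(f)
    return {k: float(np.mean(v)) for k, v in f_by_class.items() if v}


def enc(counts: CodonCountTable) -> float:
    """Wright's effective number of codons for one gene, in [20, 61].

    Class means of F use the standard degeneracy classes (Leu/Ser/Arg as
    six-fold).  A missing three-fold class mean is imputed as the average
    of the two- and four-fold means, a missing six-fold mean as the
    four-fold mean.  ``nan`` if fewer than two amino-acid families are
    usable or the two-/four-fold means are unavailable.
    """
    means = _wright_class_means(counts)
    if len(means) < 2 or 2 not in means or 4 not in means:
        return math.nan
    f2, f4 = means[2], means[4]
    f3 = means.get(3, (f2 + f4) / 2)
    f6 = means.get(6, f4)
    if min(f2, f3, f4, f6) <= 0:
        return math.nan
    value = 2 + 9 / f2 + 1 / f3 + 5 / f4 + 3 / f6
    return min(value, 61.0)


def build_cai_weights(
    reference: CodonCountTable, floor: float = 0.01
) -> dict[str, float]:
    """Relative adaptiveness w per codon from a reference codon table.

    w_j = x_j / max(x) within the codon's amino-acid family; zero counts
    are floored at ``floor`` so geometric means stay defined.  Met and
    Trp codons get weight 1.
    """
    weights: dict[str, float] = {}
    for aa, codons in AA_TO_CODONS.items():
        xmax = max(reference[c] for c in codons)
        for c in codons:
            if len(codons) == 1:
                weights[c] = 1.0
            elif xmax == 0:
                weights[c] = 1.0
            else:
                weights[c] = max(reference[c] / xmax, floor)
    return weights


def cai(counts: CodonCountTable, weights: Mapping[str, float]) -> float:
    """Codon adaptation index: geometric mean of w over synonymous codons.

    Met and Trp codons are excluded; computed in log domain.
    """
    log_sum = 0.0
    n = 0
    for c in SYNONYMOUS_CODONS:
        x = counts[c]
        if not x:
            continue
        w = weights[c]
        if w <= 0:
            w = 0.01
        log_sum += x * math.log(w)
        n += x
    if n == 0:
        return math.nan
    return math.exp(log_sum / n)


def cbi_fop(
    counts: CodonCountTable, optimal: Iterable[str]
) -> tuple[float, float]:
    """Codon bias index and frequency of optimal codons.

    Fop = N_opt / N_tot over synonymous codons.  CBI rescales the excess
    of optimal codons over the uniform-usage expectation N_rand:
    CBI = (N_opt - N_rand) / (N_tot - N_rand), so uniform usage scores 0
    and exclusive use of optimal codons scores 1.
    """
    optimal = set(optimal) & set(SYNONYMOUS_CODONS)
    n_tot = counts.total(SYNONYMOUS_CODONS)
    if n_tot == 0:
        return math.nan, math.nan
    n_opt = sum(counts[c] for c in optimal)
    n_rand = 0.0
    for aa, codons in AA_TO_CODONS.items():
        if len(codons) < 2:
            continue
        k_opt = sum(1 for c in codons if c in optimal)
        if k_opt:
            n_rand += counts.total(codons) * k_opt / len(codons)
    fop = n_opt / n_tot
    cbi_val = (n_opt - n_rand) / (n_tot - n_rand) if n_tot != n_rand else math.nan
    return cbi_val, fop


def protein_indices(gene: GeneRecord) -> dict[str, float]:
    """Gravy, aromaticity and length indices of the encoded protein.

    Gravy is the mean Kyte-Doolittle hydropathy; Aromo the fraction of
    Phe/Tyr/Trp residues; l_aa the residue count (stop excluded); l_sym
    the number of codons belonging to degenerate families.
    """
    protein = gene.translate()
    if not protein:
        raise ValueError(f"{gene.id}: empty protein")
    gravy = sum(KYTE_DOOLITTLE[a] for a in protein) / len(protein)
    aromo = sum(1 for a in protein if a in AROMATIC) / len(protein)
    l_sym = sum(1 for a in protein if a not in "MW")
    return {"gravy": gravy, "aromo": aromo, "l_sym": l_sym, "l_aa": len(protein)}


def metrics_table(
    genes: Sequence[GeneRecord],
    optimal: Iterable[str] | None = None,
    cai_weights: Mapping[str, float] | None = None,
    reference_fraction: float = 0.10,
) -> pd.DataFrame:
    """Per-gene index table: ENC, GC by position, silent-site composition,
    CAI, CBI, Fop, Gravy, Aromo and lengths; one row per gene.

    When no CAI weight table is supplied, the reference set defaults to
    the ``reference_fraction`` of genes with the lowest ENC (the most
    biased genes, a proxy for high expression).  When no optimal-codon
    set is supplied, codons with pooled RSCU > 1 are used for CBI/Fop.
    Genome-level summaries are arithmetic means of the per-gene columns
    (``DataFrame.mean()``).
    """
    if not genes:
        raise ValueError("no genes")
    tables = [count_codons(g) for g in genes]
    pooled = pool_counts(tables)

    rows: list[dict[str, float]] = []
    enc_vals = [enc(t) for t in tables]

    if cai_weights is None:
        order = sorted(
            range(len(genes)),
            key=lambda i: (math.inf if math.isnan(enc_vals[i]) else enc_vals[i],
                           genes[i].id),
        )
        n_ref = max(1, math.ceil(reference_fraction * len(genes)))
        reference = pool_counts(tables[i] for i in order[:n_ref])
        cai_weights = build_cai_weights(reference)

    if optimal is None:
        pooled_rscu = rscu(pooled, SPLIT)
        optimal = {
            c for c in SYNONYMOUS_CODONS
            if not math.isnan(pooled_rscu[c]) and pooled_rscu[c] > 1
        }
    optimal = set(optimal)

    for g, t, enc_val in zip(genes, tables, enc_vals):
        row: dict[str, float] = {"id": g.id, "enc": enc_val}
        row.update(positional_gc(t))
        row.update(silent_site_composition(t))
        row["cai"] = cai(t, cai_weights)
        cbi_val, fop_val = cbi_fop(t, optimal)
        row["cbi"] = cbi_val
        row["fop"] = fop_val
        row.update(protein_indices(g))
        rows.append(row)
    return pd.DataFrame(rows).set_index("id")


def correlation_matrix(
    table: pd.DataFrame, method: str = "pearson"
) -> pd.DataFrame:
    """Pairwise correlations among the numeric index columns.

    ``method`` is ``pearson`` or ``spearman``; constant columns yield
    ``nan`` entries (undefined correlation).
    """
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown method {method!r}")
    numeric = table.select_dtypes(include=[np.number])
    if len(numeric) < 2:
        raise ValueError("need at least two genes for correlations")
    return numeric.corr(method=method)
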