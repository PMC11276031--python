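"""Bundled reference data.

``pteridophyte_genome_codon_usage.tsv`` holds pooled codon counts from
the annotated coding sequences of four lycophyte and fern genome
assemblies — *Adiantum capillus-veneris* (GenBank GCA_014529385.2),
*Ceratopteris richardii* (GCA_020310875.1), *Diphasiastrum complanatum*
(GCA_029204225.1) and *Selaginella moellendorffii* (GCA_000143415.2) —
together with the published genome RSCU values for cross-checking.
Stop codons are not part of the table; RSCU for the single-codon
families AUG/UGG is 1 by definition.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .codon_metrics import CodonCountTable

__all__ = ["SPECIES", "load_codon_usage", "pooled_counts", "published_rscu"]

#: Species column keys in the bundled table.
SPECIES = (
    "A_capillus_veneris",
    "C_richardii",
    "D_complanatum",
    "S_moellendorffii",
)


def load_codon_usage() -> pd.DataFrame:
    """The bundled table: amino acid, codon, per-species counts and the
    published RSCU values (columns ``count_<species>``, ``rscu_<species>``)."""
    ref = resources.files("cubkit.data") / "pteridophyte_genome_codon_usage.tsv"
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t")


def pooled_counts(species: str) -> CodonCountTable:
    """Pooled genome codon counts for one of the four species."""
    if species not in SPECIES:
        raise ValueError(f"unknown species {species!r}; choose from {SPECIES}")
    df = load_codon_usage()
    counts = dict(zip(df["codon"], df[f"count_{species}"].astype(int)))
    return CodonCountTable(counts, scope="pooled")


def published_rscu(species: str) -> pd.Series:
    """Published RSCU values (as printed, 2-3 decimals) for one species."""
    if species not in SPECIES:
        raise ValueError(f"unknown species {species!r}; choose from {SPECIES}")
    df = load_codon_usage()
    return pd.Series(
        df[f"rscu_{species}"].to_numpy(), index=df["codon"], name=species
    )
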