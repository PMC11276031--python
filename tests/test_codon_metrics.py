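"""Codon counting, RSCU, positional GC, ENC, CAI/CBI/Fop and protein indices."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cubkit.codon_metrics import (
    CodonCountTable,
    KYTE_DOOLITTLE,
    build_cai_weights,
    cai,
    cbi_fop,
    correlation_matrix,
    count_codons,
    enc,
    metrics_table,
    pool_counts,
    positional_gc,
    protein_indices,
    rscu,
    silent_site_composition,
)
from cubkit.genetics import (
    AA_TO_CODONS,
    SENSE_CODONS,
    SPLIT,
    STANDARD,
    SYNONYMOUS_CODONS,
)
from cubkit.sequence_io import GeneRecord

from conftest import make_gene


class TestCountCodons:
    def test_minimal_gene(self):
        t = count_codons(GeneRecord("g", "AUGAAAUAA"))
        assert t["AUG"] == 1 and t["AAA"] == 1 and t["UAA"] == 1
        assert t.total() == 3

    def test_pooling_linearity(self):
        g = make_gene("g", "GCUGCA" * 60)
        t = count_codons(g)
        doubled = pool_counts([t, t])
        assert all(doubled[c] == 2 * t[c] for c in SENSE_CODONS)

    def test_pooled_equals_sum_of_per_gene(self):
        genes = [make_gene(f"g{i}", "GCU" * (100 + i)) for i in range(3)]
        tables = [count_codons(g) for g in genes]
        pooled = pool_counts(tables)
        for c in SENSE_CODONS:
            assert pooled[c] == sum(t[c] for t in tables)

    def test_frameshift_raises(self):
        with pytest.raises(ValueError):
            count_codons(GeneRecord("g", "AUGA"))


# Pooled Ala counts from a published fern genome survey (A. capillus-veneris).
_ALA_COUNTS = {"GCA": 328432, "GCC": 173863, "GCG": 91978, "GCU": 301610}
# Leu counts from the same genome.
_LEU_COUNTS = {
    "CUA": 114756, "CUC": 168150, "CUG": 182510, "CUU": 279707,
    "UUA": 123649, "UUG": 269356,
}


class TestRSCU:
    def test_published_alanine_value(self):
        t = CodonCountTable(_ALA_COUNTS)
        assert rscu(t, SPLIT)["GCA"] == pytest.approx(1.466, abs=5e-4)

    def test_equal_counts_give_unity(self):
        t = CodonCountTable({c: 7 for c in AA_TO_CODONS["A"]})
        vals = rscu(t, SPLIT)
        assert all(vals[c] == pytest.approx(1.0) for c in AA_TO_CODONS["A"])

    def test_sixfold_split_vs_standard(self):
        # Direct evaluation of the RSCU formula under both family schemes.
        t = CodonCountTable(_LEU_COUNTS)
        split_vals = rscu(t, SPLIT)
        assert split_vals["CUU"] == pytest.approx(1.502, abs=5e-4)
        assert split_vals["UUG"] == pytest.approx(1.371, abs=5e-4)
        std_vals = rscu(t, STANDARD)
        assert std_vals["CUU"] == pytest.approx(1.474, abs=6e-4)

    def test_zero_family_is_missing_not_zero(self):
        vals = rscu(CodonCountTable(_ALA_COUNTS), SPLIT)
        assert math.isnan(vals["UUU"])

    def test_single_codon_families_are_one(self):
        vals = rscu(CodonCountTable({}), SPLIT)
        assert vals["AUG"] == 1.0 and vals["UGG"] == 1.0

    @given(st.dictionaries(st.sampled_from(SENSE_CODONS),
                           st.integers(0, 1000), min_size=5))
    @settings(max_examples=50, deadline=None)
    def test_family_mean_normalisation(self, counts):
        t = CodonCountTable(counts)
        for scheme in (SPLIT, STANDARD):
            vals = rscu(t, scheme)
            for fam in scheme.families:
                if len(fam) > 1 and sum(t[c] for c in fam) > 0:
                    assert np.mean([vals[c] for c in fam]) == pytest.approx(1.0)


class TestPositionalGC:
    def test_all_ggg(self):
        g = positional_gc(CodonCountTable({"GGG": 50}))
        assert g["gc1"] == g["gc2"] == g["gc3"] == 1.0

    def test_alternating_au(self):
        g = positional_gc(CodonCountTable({"AUA": 30, "UAU": 30}))
        assert g["gc1"] == g["gc2"] == g["gc3"] == 0.0

    def test_identities_hold(self):
        t = CodonCountTable({c: i + 1 for i, c in enumerate(SENSE_CODONS)})
        g = positional_gc(t)
        assert g["gc12"] == pytest.approx((g["gc1"] + g["gc2"]) / 2, abs=1e-12)
        assert g["gc_all"] == pytest.approx(
            (g["gc1"] + g["gc2"] + g["gc3"]) / 3, abs=1e-12
        )

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            positional_gc(CodonCountTable({}))


class TestSilentSiteComposition:
    def test_single_family_gcg(self):
        comp = silent_site_composition(CodonCountTable({"GCG": 10}))
        assert comp["g3s"] == 1.0 and comp["gc3s"] == 1.0

    def test_uniform_usage_matches_enumeration_oracle(self):
        t = CodonCountTable({c: 6 for c in SYNONYMOUS_CODONS})
        comp = silent_site_composition(t)
        # brute-force oracle straight from the code table
        for base, key in (("A", "a3s"), ("U", "t3s"), ("C", "c3s"), ("G", "g3s")):
            num = denom = 0
            for codons in AA_TO_CODONS.values():
                if len(codons) < 2 or not any(c[2] == base for c in codons):
                    continue
                denom += 6 * len(codons)
                num += 6 * sum(1 for c in codons if c[2] == base)
            assert comp[key] == pytest.approx(num / denom)
        gc = sum(1 for c in SYNONYMOUS_CODONS if c[2] in "GC")
        assert comp["gc3s"] == pytest.approx(gc / len(SYNONYMOUS_CODONS))

    def test_fourfold_only_composition_sums_to_one(self):
        # restricted to four-fold families the "possible base" denominator
        # is the full synonymous count, so the four values sum to 1
        t = CodonCountTable({c: 3 for c in AA_TO_CODONS["A"] + AA_TO_CODONS["G"]})
        comp = silent_site_composition(t)
        assert comp["a3s"] + comp["t3s"] + comp["c3s"] + comp["g3s"] == pytest.approx(1.0)


class TestENC:
    def test_uniform_usage_hits_upper_limit(self, uniform_counts):
        assert enc(uniform_counts) == 61.0

    def test_one_codon_per_family_hits_lower_limit(self):
        t = CodonCountTable({min(codons): 20 for codons in AA_TO_CODONS.values()})
        assert enc(t) == pytest.approx(20.0)

    def test_hand_worked_two_family_gene(self):
        # F2 = 0.5 (Phe 3:1), F4 = 1/3 (Ala 2:2), F3 and F6 imputed
        t = CodonCountTable({"UUU": 3, "UUC": 1, "GCU": 2, "GCA": 2})
        assert enc(t) == pytest.approx(46.4, abs=1e-9)

    def test_undefined_for_single_family(self):
        assert math.isnan(enc(CodonCountTable({"UUU": 3, "UUC": 1})))

    def test_bias_gradient_monotone(self):
        # stronger concentration on one codon per family never raises ENC
        from cubkit.synthetic_cds import GenomeSpec, generate_genome
        from cubkit.codon_metrics import count_codons

        encs = []
        for bias in (0.0, 0.3, 0.6, 0.9):
            genes, _ = generate_genome(
                GenomeSpec(n_genes=30, min_codons=400, max_codons=400, bias=bias),
                seed=7,
            )
            encs.append(np.mean([enc(count_codons(g)) for g in genes]))
        assert all(a > b for a, b in zip(encs, encs[1:]))


class TestCAI:
    def test_family_maximal_usage_scores_one(self):
        ref = CodonCountTable({c: (9 if c == min(f) else 3)
                               for f in AA_TO_CODONS.values() for c in f})
        w = build_cai_weights(ref)
        gene = CodonCountTable({min(f): 5 for f in AA_TO_CODONS.values()})
        assert cai(gene, w) == pytest.approx(1.0)

    def test_two_codon_geometric_mean(self):
        w = {"GCU": 1.0, "GCA": 0.25}
        gene = CodonCountTable({"GCU": 1, "GCA": 1})
        assert cai(gene, w) == pytest.approx(0.5)

    def test_log_domain_oracle_on_random_gene(self):
        rng = np.random.default_rng(11)
        ref = CodonCountTable(
            {c: int(rng.integers(1, 500)) for c in SENSE_CODONS}
        )
        w = build_cai_weights(ref)
        codons = rng.choice(SYNONYMOUS_CODONS, size=100)
        gene = CodonCountTable(
            {c: int((codons == c).sum()) for c in set(codons)}
        )
        expected = math.exp(sum(math.log(w[c]) for c in codons) / len(codons))
        assert cai(gene, w) == pytest.approx(expected, rel=1e-12)

    def test_zero_weight_floored(self):
        ref = CodonCountTable({"GCU": 100})  # GCA/GCC/GCG unseen
        w = build_cai_weights(ref)
        assert w["GCA"] == 0.01


class TestCBIFop:
    def setup_method(self):
        self.optimal = {min(f) for f in AA_TO_CODONS.values() if len(f) > 1}

    def test_pure_optimal_usage(self):
        t = CodonCountTable({c: 10 for c in self.optimal})
        cbi_val, fop = cbi_fop(t, self.optimal)
        assert fop == 1.0 and cbi_val == pytest.approx(1.0)

    def test_no_optimal_usage(self):
        non_opt = [c for c in SYNONYMOUS_CODONS if c not in self.optimal]
        t = CodonCountTable({c: 5 for c in non_opt})
        _, fop = cbi_fop(t, self.optimal)
        assert fop == 0.0

    def test_uniform_usage_gives_zero_cbi(self):
        t = CodonCountTable({c: 12 for c in SYNONYMOUS_CODONS})
        cbi_val, _ = cbi_fop(t, self.optimal)
        assert cbi_val == pytest.approx(0.0, abs=1e-12)


class TestProteinIndices:
    def test_poly_ala_gravy(self):
        g = GeneRecord("g", "GCU" * 100 + "UAA")
        assert protein_indices(g)["gravy"] == pytest.approx(1.8)

    def test_aromatic_only(self):
        g = GeneRecord("g", "UUUUACUGG" * 34 + "UAA")
        assert protein_indices(g)["aromo"] == pytest.approx(1.0)

    def test_mixed_protein_table_lookup_oracle(self):
        codons = ["GCU", "CGU", "AAU", "GAU", "UGU",
                  "CAA", "GAA", "GGU", "CAU", "AUU"]
        g = GeneRecord("g", "".join(codons) + "UAA")
        expected = np.mean([KYTE_DOOLITTLE[a] for a in "ARNDCQEGHI"])
        idx = protein_indices(g)
        assert idx["gravy"] == pytest.approx(expected)
        assert idx["l_aa"] == idx["l_sym"] == 10  # no Met/Trp residues


class TestMetricsTable:
    def test_shape_and_genome_mean(self):
        genes = [make_gene(f"g{i}", "GCUGCAUUUAAA" * (25 + i)) for i in range(5)]
        table = metrics_table(genes)
        assert len(table) == 5
        assert table["gc_all"].mean() == pytest.approx(
            np.mean([positional_gc(count_codons(g))["gc_all"] for g in genes])
        )

    def test_identical_genes_have_undefined_correlations(self):
        genes = [make_gene(f"g{i}", "GCUGCAUUUAAA" * 30) for i in range(2)]
        corr = correlation_matrix(metrics_table(genes))
        assert corr.isna().all().all()

    def test_self_correlation_is_one(self, uniform_genome):
        genes, _ = uniform_genome
        corr = correlation_matrix(metrics_table(genes[:30]))
        assert np.allclose(np.diag(corr), 1.0)
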