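"""High-frequency codons, expression groups and the delta-RSCU screen."""

import math

import pytest

from cubkit.codon_metrics import CodonCountTable, count_codons, pool_counts, rscu
from cubkit.datasets import SPECIES, pooled_counts
from cubkit.genetics import AA_TO_CODONS, SPLIT
from cubkit.optimal_codon_screen import (
    ending_tally,
    expression_groups,
    high_frequency_codons,
    optimal_codons,
    shared_codons,
)
from cubkit.synthetic_cds import GenomeSpec, StrataSpec, generate_genome, planted_screen_spec
from cubkit.codon_metrics import enc


def _high_freq(species):
    return high_frequency_codons(rscu(pooled_counts(species), SPLIT))


class TestHighFrequencyCodons:
    @pytest.mark.parametrize(
        "species,expected",
        list(zip(SPECIES, [28, 28, 29, 31])),
    )
    def test_published_genome_counts(self, species, expected):
        assert len(_high_freq(species)) == expected

    def test_fern_set_contains_expected_members(self):
        s = _high_freq("A_capillus_veneris")
        assert {"GCA", "CUU"} <= s

    def test_uniform_usage_gives_empty_set(self):
        vals = rscu(CodonCountTable({c: 4 for f in AA_TO_CODONS.values()
                                     for c in f}), SPLIT)
        assert high_frequency_codons(vals) == set()

    def test_met_trp_never_included(self):
        for sp in SPECIES:
            assert not {"AUG", "UGG"} & _high_freq(sp)


class TestSharedCodons:
    def test_four_way_intersection(self):
        assert len(shared_codons([_high_freq(sp) for sp in SPECIES])) == 9

    def test_three_au_rich_species(self):
        three = shared_codons(
            [_high_freq(sp) for sp in SPECIES if sp != "S_moellendorffii"]
        )
        tally = ending_tally(three)
        assert len(three) == 24
        assert tally["AU_ending"] / len(three) == pytest.approx(0.875)

    def test_cg_ending_spikemoss_codons(self):
        tally = ending_tally(_high_freq("S_moellendorffii"))
        assert tally["CG_ending"] == 25

    def test_commutative_associative(self):
        a, b, c = {"GCA", "GCU"}, {"GCU", "AAA"}, {"GCU"}
        assert shared_codons([a, b]) == shared_codons([b, a])
        assert shared_codons([shared_codons([a, b]), c]) == shared_codons([a, b, c])

    def test_disjoint_sets_empty(self):
        assert shared_codons([{"GCA"}, {"AAA"}]) == set()


class TestExpressionGroups:
    def test_distinct_enc_deciles(self):
        encs = {f"g{i:03d}": 30.0 + i * 0.3 for i in range(100)}
        groups = expression_groups(encs)
        assert len(groups.high) == len(groups.low) == 10
        assert not set(groups.high) & set(groups.low)
        assert groups.high == tuple(f"g{i:03d}" for i in range(10))

    def test_all_ties_filled_by_id_order(self):
        encs = {f"g{i}": 45.0 for i in range(20)}
        with pytest.warns(UserWarning):
            groups = expression_groups(encs)
        assert groups.high == ("g0", "g1")

    def test_direction_flag_inverts(self):
        encs = {f"g{i:03d}": 30.0 + i for i in range(50)}
        default = expression_groups(encs)
        literal = expression_groups(encs, low_enc_is_high_expression=False)
        assert default.high == literal.low

    def test_too_few_genes_raises(self):
        with pytest.raises(ValueError):
            expression_groups({"a": 30.0, "b": 40.0}, fraction=0.10)

    def test_planted_low_enc_subpopulation_lands_in_high_group(self):
        spec = GenomeSpec(
            n_genes=100, min_codons=200, max_codons=300,
            strata=StrataSpec(fraction=0.10, bias=0.9),
        )
        genes, truth = generate_genome(spec, seed=9)
        tables = {g.id: count_codons(g) for g in genes}
        groups = expression_groups({g.id: enc(tables[g.id]) for g in genes})
        planted = {t["id"] for t in truth["genes"] if t["stratum"] == "high"}
        assert planted <= set(groups.high)


class TestOptimalCodons:
    def _screen(self, high, low, pooled):
        return optimal_codons(high, low, rscu(pooled, SPLIT))

    def test_identical_groups_find_nothing(self):
        t = pooled_counts("A_capillus_veneris")
        report = self._screen(t, t, t)
        assert report["delta_rscu"].abs().max() == pytest.approx(0.0)
        assert not report["optimal"].any()

    def test_threshold_is_inclusive(self):
        # construct delta-RSCU exactly 0.08 for GCA
        high = CodonCountTable({"GCA": 2700, "GCC": 2433, "GCG": 2433, "GCU": 2434})
        low = CodonCountTable({"GCA": 250, "GCC": 250, "GCG": 250, "GCU": 250})
        pooled = pool_counts([high, low])
        report = self._screen(high, low, pooled)
        assert report.loc["GCA", "delta_rscu"] == pytest.approx(0.08)
        assert bool(report.loc["GCA", "optimal"])

    def test_planted_truth_recovered_exactly(self):
        spec = planted_screen_spec()
        genes, truth = generate_genome(spec, seed=0)
        tables = {g.id: count_codons(g) for g in genes}
        pooled = pool_counts(tables.values())
        groups = expression_groups({g.id: enc(tables[g.id]) for g in genes})
        planted_ids = {t["id"] for t in truth["genes"] if t["stratum"] == "high"}
        assert set(groups.high) == planted_ids
        report = self._screen(
            pool_counts(tables[i] for i in groups.high),
            pool_counts(tables[i] for i in groups.low),
            pooled,
        )
        recovered = set(report.index[report["optimal"]])
        planted = {max(f) for f in SPLIT.families if len(f) > 1}
        assert recovered == planted

    def test_invariant_under_gene_reordering(self):
        genes, _ = generate_genome(planted_screen_spec(n_genes=60), seed=2)
        def run(gs):
            tables = {g.id: count_codons(g) for g in gs}
            pooled = pool_counts(tables.values())
            groups = expression_groups({g.id: enc(tables[g.id]) for g in gs})
            rep = self._screen(
                pool_counts(tables[i] for i in groups.high),
                pool_counts(tables[i] for i in groups.low),
                pooled,
            )
            return set(rep.index[rep["optimal"]])
        assert run(genes) == run(list(reversed(genes)))

    def test_unbiased_genome_yields_empty_set(self):
        # the empty-set property is asymptotic in gene length: long genes
        # shrink the sampling noise of group RSCU well below the 0.08
        # threshold, so no codon clears the screen by chance
        genes, _ = generate_genome(
            GenomeSpec(n_genes=120, min_codons=15000, max_codons=15000),
            seed=3,
        )
        tables = {g.id: count_codons(g) for g in genes}
        pooled = pool_counts(tables.values())
        groups = expression_groups({g.id: enc(tables[g.id]) for g in genes})
        report = self._screen(
            pool_counts(tables[i] for i in groups.high),
            pool_counts(tables[i] for i in groups.low),
            pooled,
        )
        assert not report["optimal"].any()
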