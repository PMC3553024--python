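import numpy as np
import pytest

from regevo.catalog import (
    GeneRecord,
    HomologyEvidence,
    apply_promoter_filters,
    classify_origin,
    extract_promoter,
    head_to_head_pairs,
)
from regevo.motifs import reverse_complement
from regevo.simulate import toy_bundle


def evidence(**kwargs):
    base = dict(
        gene_id="g1",
        has_cross_species_blast_hit=False,
        has_self_hit=True,
        expressed=True,
        in_ygob_or_orthomcl=False,
        max_identity_vs_six_species=0.40,
        has_paralog=False,
        ortholog_in_all_six=False,
    )
    base.update(kwargs)
    return HomologyEvidence(**base)


class TestClassifyOrigin:
    def test_species_specific_without_paralog_is_de_novo(self):
        assert classify_origin(evidence()) == "de_novo"

    def test_species_specific_with_paralog_is_duplicated_new(self):
        assert classify_origin(evidence(has_paralog=True)) == "duplicated_new"

    def test_high_identity_excluded_as_potential_ortholog(self):
        assert classify_origin(evidence(max_identity_vs_six_species=0.75)) == "other"

    def test_identity_at_exactly_seventy_percent_is_still_new(self):
        assert classify_origin(evidence(max_identity_vs_six_species=0.70)) == "de_novo"

    def test_orthologs_in_all_six_species(self):
        ev = evidence(
            has_cross_species_blast_hit=True, in_ygob_or_orthomcl=True,
            max_identity_vs_six_species=0.9, ortholog_in_all_six=True,
        )
        assert classify_origin(ev) == "orthologous"

    def test_missing_fields_reported_by_name(self):
        with pytest.raises(ValueError, match="expressed"):
            classify_origin(evidence(expressed=None))


class TestExtractPromoter:
    def _toy_genome(self):
        rng = np.random.default_rng(0)
        return {"c": "".join(rng.choice(list("ACGT"), 6000))}

    def test_bounded_by_upstream_neighbor(self):
        genome = self._toy_genome()
        gene = GeneRecord("a", "c", "+", 5000, [(5000, 5100)])
        neighbor = GeneRecord("b", "c", "+", 4400, [(4400, 4500)])
        prom = extract_promoter(gene, genome, [gene, neighbor])
        assert prom.length == 500
        assert prom.interval == (4500, 5000)
        assert prom.sequence == genome["c"][4500:5000]

    def test_capped_at_one_kilobase(self):
        genome = self._toy_genome()
        gene = GeneRecord("a", "c", "+", 5000, [(5000, 5100)])
        neighbor = GeneRecord("b", "c", "+", 2600, [(2600, 2700)])
        prom = extract_promoter(gene, genome, [gene, neighbor])
        assert prom.length == 1000 and prom.interval == (4000, 5000)

    def test_minus_strand_reverse_complement_round_trip(self):
        """Hand-built 60 bp chromosome: minus-strand promoter reads toward TSS."""
        genome = {"c": "ACGTACGTAC" * 6}
        gene = GeneRecord("a", "c", "-", 19, [(10, 20)])  # TSS base at 19
        neighbor = GeneRecord("b", "c", "+", 45, [(45, 55)])
        prom = extract_promoter(gene, genome, [gene, neighbor])
        assert prom.interval == (20, 45)
        assert prom.sequence == reverse_complement(genome["c"][20:45])
        # local index L-1 is the base adjacent to the TSS (genomic 20)
        assert prom.sequence[-1] == reverse_complement(genome["c"][20])

    def test_zero_upstream_space_gives_empty_promoter(self):
        genome = self._toy_genome()
        gene = GeneRecord("a", "c", "+", 0, [(0, 90)])
        prom = extract_promoter(gene, genome, [gene])
        assert prom.length == 0

    def test_tss_relative_mapping_has_no_zero(self):
        genome = self._toy_genome()
        gene = GeneRecord("a", "c", "+", 500, [(500, 600)])
        prom = extract_promoter(gene, genome, [gene])
        assert prom.tss_relative(prom.length - 1) == -1
        assert prom.tss_relative(0) == -prom.length


class TestHeadToHead:
    def test_divergent_pair_300bp_apart_shares_cores(self):
        g1 = GeneRecord("a", "c", "-", 1000, [(900, 1001)])
        g2 = GeneRecord("b", "c", "+", 1300, [(1300, 1400)])
        assert head_to_head_pairs([g1, g2]) == [("a", "b")]

    def test_distant_divergent_pair_does_not(self):
        g1 = GeneRecord("a", "c", "-", 1000, [(900, 1001)])
        g2 = GeneRecord("b", "c", "+", 1600, [(1600, 1700)])
        assert head_to_head_pairs([g1, g2]) == []

    def test_same_strand_neighbors_never_flagged(self):
        g1 = GeneRecord("a", "c", "+", 1000, [(1000, 1100)])
        g2 = GeneRecord("b", "c", "+", 1150, [(1150, 1250)])
        assert head_to_head_pairs([g1, g2]) == []


class TestFunnel:
    def test_toy_fixture_filters_match_hand_computation(self):
        bundle = toy_bundle()
        proms = {
            g.gene_id: extract_promoter(g, bundle.genome, bundle.genes)
            for g in bundle.genes
        }
        primary = {gid: a for (gid, sp), a in bundle.promoter_alignments.items()}
        retained, audit = apply_promoter_filters(bundle.genes, proms, primary)
        assert sorted(retained) == ["G05", "G06", "G07", "G08", "G09", "G10"]
        assert audit["removed"]["short_promoter"] == ["G01"]
        assert audit["removed"]["shared_core_promoter"] == ["G02", "G03"]
        assert audit["removed"]["poor_alignment"] == ["G04"]
        assert audit["funnel"] == [
            ("short_promoter", 9),
            ("shared_core_promoter", 7),
            ("poor_alignment", 6),
        ]

    def test_gap_rate_exactly_half_retained(self):
        """The poor-alignment rule is strictly 'greater than 50%'."""
        bundle = toy_bundle()
        from regevo.alignment import gap_rate

        assert gap_rate(bundle.promoter_alignments[("G05", "outgroup1")]) == 0.5
        assert gap_rate(bundle.promoter_alignments[("G04", "outgroup1")]) == 0.6

    def test_funnel_counts_monotone_non_increasing(self):
        bundle = toy_bundle()
        proms = {
            g.gene_id: extract_promoter(g, bundle.genome, bundle.genes)
            for g in bundle.genes
        }
        primary = {gid: a for (gid, sp), a in bundle.promoter_alignments.items()}
        _, audit = apply_promoter_filters(bundle.genes, proms, primary)
        counts = [audit["input"]] + [c for _, c in audit["funnel"]]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_missing_alignment_removed_by_filter_c(self):
        bundle = toy_bundle()
        proms = {
            g.gene_id: extract_promoter(g, bundle.genome, bundle.genes)
            for g in bundle.genes
        }
        primary = {gid: a for (gid, sp), a in bundle.promoter_alignments.items()}
        del primary["G07"]
        retained, audit = apply_promoter_filters(bundle.genes, proms, primary)
        assert "G07" in audit["removed"]["poor_alignment"]
        assert "G07" not in retained

    def test_toy_categories_decode_from_evidence(self):
        bundle = toy_bundle()
        for gene in bundle.genes:
            assert classify_origin(bundle.evidence[gene.gene_id]) == gene.category
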