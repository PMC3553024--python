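import numpy as np
import pytest

from regevo.config import CATEGORIES, ConfigError, SimulationConfig
from regevo.io import bundle_checksums, read_bundle
from regevo.motifs import PwmScanner, find_tata, pfm_to_pwm
from regevo.simulate import (
    plant_tata,
    simulate_cohort,
    simulate_to_dir,
    toy_bundle,
)
from regevo.turnover import corresponding_region

from conftest import make_promoter


def tiny_config(**overrides):
    base = dict(n_genes=20, motif_library_size=6, motifs_per_gene=3, seed=1)
    base.update(overrides)
    return SimulationConfig(**base)


class TestConfigValidation:
    def test_bad_group_fraction_names_field(self):
        cfg = tiny_config()
        cfg.group_fractions = {"de_novo": 0.7, "duplicated_new": 0.1,
                               "orthologous": 0.1, "other": 0.05}
        with pytest.raises(ConfigError, match="group_fractions"):
            cfg.validate()

    def test_fraction_out_of_range_names_field(self):
        cfg = tiny_config()
        cfg.tata_fraction_by_group = dict(cfg.tata_fraction_by_group, de_novo=1.2)
        with pytest.raises(ConfigError, match="tata_fraction_by_group"):
            cfg.validate()

    def test_substitution_rate_of_one_rejected(self):
        cfg = tiny_config()
        cfg.substitution_rate_by_group = {c: 1.0 for c in CATEGORIES}
        with pytest.raises(ConfigError, match="substitution_rate_by_group"):
            cfg.validate()

    def test_roundtrip_through_dict(self):
        cfg = tiny_config(seed=9)
        assert SimulationConfig.from_dict(cfg.to_dict()) == cfg


class TestDeterminism:
    def test_same_seed_gives_byte_identical_bundles(self, tmp_path):
        cfg = tiny_config()
        simulate_to_dir(cfg, tmp_path / "a")
        simulate_to_dir(cfg, tmp_path / "b")
        assert bundle_checksums(tmp_path / "a") == bundle_checksums(tmp_path / "b")

    def test_different_seed_changes_genome(self, tmp_path):
        b1 = simulate_cohort(tiny_config(seed=1))
        b2 = simulate_cohort(tiny_config(seed=2))
        assert b1.genome != b2.genome

    def test_file_round_trip_preserves_content(self, tmp_path):
        bundle = simulate_to_dir(tiny_config(), tmp_path / "x")
        back = read_bundle(tmp_path / "x")
        assert back.genome == bundle.genome
        assert back.curation == bundle.curation
        assert len(back.genes) == len(bundle.genes)
        assert {g.gene_id: g.tss for g in back.genes} == {
            g.gene_id: g.tss for g in bundle.genes
        }
        for key, aln in bundle.promoter_alignments.items():
            assert back.promoter_alignments[key].focal_row == aln.focal_row
            assert back.promoter_alignments[key].outgroup_row == aln.outgroup_row


class TestZeroRateIdentity:
    def test_orthologs_byte_identical_without_divergence_or_gains(self):
        cfg = tiny_config(
            substitution_rate_by_group={c: 0.0 for c in CATEGORIES},
            indel_rate=0.0,
            gained_fraction_by_group={c: 0.0 for c in CATEGORIES},
        )
        bundle = simulate_cohort(cfg)
        for gene in bundle.genes:
            for sp in cfg.outgroups:
                aln = bundle.promoter_alignments[(gene.gene_id, sp)]
                assert aln.focal_row == aln.outgroup_row


class TestTruthInvariants:
    def test_planted_motifs_lie_inside_their_promoters(self, small_bundle):
        lengths = small_bundle.truth.genes.set_index("gene_id")["promoter_length"]
        w = small_bundle.config.motif_width
        for row in small_bundle.truth.motifs.itertuples():
            L = lengths[row.gene_id]
            assert -L <= row.tss_relative_start <= -w

    def test_preexisting_words_present_in_outgroup_regions(self, small_bundle):
        cfg = small_bundle.config
        scanners = {
            p.tf_id: PwmScanner(pfm_to_pwm(p, cfg.background()), cfg.alpha,
                                cfg.background(), cfg.bin_width)
            for p in small_bundle.pfms
        }
        lengths = small_bundle.truth.genes.set_index("gene_id")["promoter_length"]
        pre = small_bundle.truth.motifs.query("turnover_truth == 'preexisting'")
        for row in pre.itertuples():
            local = row.tss_relative_start + lengths[row.gene_id]
            found = []
            for sp in cfg.outgroups:
                aln = small_bundle.promoter_alignments[(row.gene_id, sp)]
                region = corresponding_region(aln, (local, local + cfg.motif_width))
                found.append(
                    region is not None
                    and scanners[row.tf_id].has_passing_window(region.sequence)
                )
            assert any(found)

    def test_all_gained_config_leaves_no_outgroup_occurrence(self):
        """gained_fraction=1: brute scan of every corresponding region is clean."""
        cfg = tiny_config(
            gained_fraction_by_group={c: 1.0 for c in CATEGORIES}, seed=5
        )
        bundle = simulate_cohort(cfg)
        scanners = {
            p.tf_id: PwmScanner(pfm_to_pwm(p, cfg.background()), cfg.alpha,
                                cfg.background(), cfg.bin_width)
            for p in bundle.pfms
        }
        lengths = bundle.truth.genes.set_index("gene_id")["promoter_length"]
        assert (bundle.truth.motifs.turnover_truth == "gained").all()
        for row in bundle.truth.motifs.itertuples():
            local = row.tss_relative_start + lengths[row.gene_id]
            for sp in cfg.outgroups:
                aln = bundle.promoter_alignments[(row.gene_id, sp)]
                region = corresponding_region(aln, (local, local + cfg.motif_width))
                if region is not None:
                    assert not scanners[row.tf_id].has_passing_window(region.sequence)

    def test_curation_covers_all_planted_pairs(self, small_bundle):
        planted = {
            (r.tf_id, r.gene_id) for r in small_bundle.truth.motifs.itertuples()
        }
        assert planted <= small_bundle.curation


class TestPlantTata:
    def test_planted_word_matches_consensus(self):
        rng = np.random.default_rng(0)
        prom = "".join(rng.choice(list("CG"), 600))
        out, rel = plant_tata(prom, seed=3)
        local = rel + len(out)
        word = out[local : local + 8]
        assert word[:4] == "TATA" and word[4] in "AT" and word[5] == "A"
        assert word[6] in "AT" and word[7] in "AG"

    def test_planted_word_found_by_detector(self):
        rng = np.random.default_rng(1)
        prom = "".join(rng.choice(list("CG"), 600))
        out, rel = plant_tata(prom, seed=3)
        flag, positions = find_tata(make_promoter(out))
        assert flag and rel in positions

    def test_fixed_seed_fixed_position(self):
        prom = "C" * 600
        assert plant_tata(prom, seed=11) == plant_tata(prom, seed=11)

    def test_window_shorter_than_word_rejected(self):
        with pytest.raises(ValueError, match="shorter than 8"):
            plant_tata("C" * 600, window=(-60, -54), seed=0)

    def test_window_outside_promoter_rejected(self):
        with pytest.raises(ValueError, match="inside the promoter"):
            plant_tata("C" * 100, window=(-200, -50), seed=0)


class TestTataScrubbing:
    def test_tata_truth_decodes_exactly(self, clean_bundle):
        lengths = clean_bundle.truth.genes.set_index("gene_id")
        proms = {}
        from regevo.catalog import extract_promoter

        for gene in clean_bundle.genes:
            proms[gene.gene_id] = extract_promoter(gene, clean_bundle.genome,
                                                   clean_bundle.genes)
        for row in clean_bundle.truth.genes.itertuples():
            flag, _ = find_tata(proms[row.gene_id])
            assert flag == bool(row.tata_truth)


def test_toy_bundle_is_deterministic():
    a, b = toy_bundle(), toy_bundle()
    assert a.genome == b.genome
    assert {g.gene_id for g in a.genes} == {g.gene_id for g in b.genes}
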