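import math
import re

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from regevo.motifs import (
    MotifHit,
    PositionFrequencyMatrix,
    PwmScanner,
    exact_score_distribution,
    filter_by_curation,
    find_tata,
    pfm_to_pwm,
    read_pfms,
    reverse_complement,
    scan_promoter,
    summarize_regulation,
    threshold_for_pvalue,
    write_pfms,
)

from conftest import enumerate_distribution, make_promoter, oracle_threshold, random_pfm


class TestPfmToPwm:
    def test_uniform_column_scores_zero(self):
        pfm = PositionFrequencyMatrix("t", np.array([[25, 25, 25, 25]]))
        pwm = pfm_to_pwm(pfm, pseudocount=1.0)
        assert np.allclose(pwm.log_odds, 0.0)

    def test_dominant_column_log_odds(self):
        # (100,0,0,0), pseudocount 1, uniform background:
        # log2((100.25/101)/0.25) = 1.98896...
        pfm = PositionFrequencyMatrix("t", np.array([[100, 0, 0, 0]]))
        pwm = pfm_to_pwm(pfm, pseudocount=1.0)
        expected = math.log2((100.25 / 101) / 0.25)
        assert pwm.log_odds[0, 0] == pytest.approx(expected, abs=1e-12)

    def test_count_scaling_invariance_without_pseudocount(self):
        rng = np.random.default_rng(0)
        pfm = random_pfm(rng, 4)
        scaled = PositionFrequencyMatrix("t", pfm.counts * 10)
        a = pfm_to_pwm(pfm, pseudocount=0.0).log_odds
        b = pfm_to_pwm(scaled, pseudocount=0.0).log_odds
        assert np.allclose(a, b)

    def test_zero_column_total_rejected(self):
        with pytest.raises(ValueError):
            PositionFrequencyMatrix("t", np.array([[0, 0, 0, 0]]))


class TestScoreDistribution:
    def test_width_one_uniform_background(self):
        pfm = PositionFrequencyMatrix("t", np.array([[10, 20, 30, 40]]))
        dist = exact_score_distribution(pfm_to_pwm(pfm))
        assert np.isclose(dist.probabilities.sum(), 1.0, atol=1e-9)
        assert len(dist.qscores) == 4  # four distinct atoms of mass 0.25
        assert np.allclose(dist.probabilities, 0.25)

    @pytest.mark.parametrize("width", [1, 2, 3, 4, 5])
    @pytest.mark.parametrize("seed", [0, 1])
    def test_matches_exhaustive_enumeration(self, width, seed):
        rng = np.random.default_rng(seed)
        pwm = pfm_to_pwm(random_pfm(rng, width))
        dist = exact_score_distribution(pwm)
        support, probs = enumerate_distribution(pwm)
        assert np.array_equal(dist.qscores, support)
        assert np.allclose(dist.probabilities, probs, atol=1e-12)

    def test_tail_is_total_mass_at_min_support(self):
        rng = np.random.default_rng(3)
        dist = exact_score_distribution(pfm_to_pwm(random_pfm(rng, 4)))
        assert dist.tail()[0] == pytest.approx(1.0, abs=1e-9)


class TestThreshold:
    def test_width_one_selects_best_base(self):
        pfm = PositionFrequencyMatrix("t", np.array([[97, 1, 1, 1]]))
        pwm = pfm_to_pwm(pfm)
        dist = exact_score_distribution(pwm)
        thr = threshold_for_pvalue(dist, 0.3)  # only the top base: tail 0.25 < 0.3
        passing = [b for b in range(4) if pwm.quantize(0.01)[0, b] * 0.01 >= thr]
        assert passing == [0]

    def test_alpha_near_one_returns_min_support(self):
        rng = np.random.default_rng(5)
        dist = exact_score_distribution(pfm_to_pwm(random_pfm(rng, 3)))
        assert threshold_for_pvalue(dist, 1 - 1e-12) == dist.scores[0]

    def test_unattainable_alpha_returns_inf(self):
        pfm = PositionFrequencyMatrix("t", np.array([[25, 25, 25, 25]] * 3))
        dist = exact_score_distribution(pfm_to_pwm(pfm))
        assert threshold_for_pvalue(dist, 0.5) == math.inf

    @pytest.mark.parametrize("alpha", [0.05, 0.005])
    def test_stricter_alpha_raises_threshold(self, alpha):
        rng = np.random.default_rng(6)
        dist = exact_score_distribution(pfm_to_pwm(random_pfm(rng, 5)))
        assert threshold_for_pvalue(dist, alpha / 10) >= threshold_for_pvalue(dist, alpha)


def _polya_pwm(width=5):
    # width 5: the all-A word has exact p-value 1/1024 < 0.001; width 4
    # could never pass that cutoff (minimal attainable tail 1/256)
    counts = np.tile(np.array([[97.0, 1.0, 1.0, 1.0]]), (width, 1))
    return pfm_to_pwm(PositionFrequencyMatrix("polyA", counts))


class TestScan:
    def test_poly_a_promoter_forward_hits_every_window(self):
        pwm = _polya_pwm()
        hits = scan_promoter(pwm, make_promoter("A" * 30), alpha=0.001)
        fwd = [h for h in hits if h.strand == "+"]
        rev = [h for h in hits if h.strand == "-"]
        assert len(fwd) == 26 and not rev
        # TSS-relative starts: local i - length
        assert [h.tss_relative_start for h in fwd] == list(range(-30, -4))

    def test_promoter_shorter_than_width_yields_nothing(self):
        assert scan_promoter(_polya_pwm(), make_promoter("ACG")) == []

    def test_hit_pvalues_below_alpha(self, small_bundle):
        from regevo.pipeline import run_cohort  # hits produced under alpha=0.001

        pwm = _polya_pwm()
        hits = scan_promoter(pwm, make_promoter("A" * 30), alpha=0.001)
        assert all(h.p_value < 0.001 for h in hits)

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(st.integers(0, 10_000))
    def test_strand_symmetry(self, seed):
        """Scanning the reverse complement swaps strands and mirrors positions."""
        rng = np.random.default_rng(seed)
        pwm = pfm_to_pwm(random_pfm(rng, 5))
        seq = "".join(rng.choice(list("ACGT"), 60))
        fwd = scan_promoter(pwm, make_promoter(seq), alpha=0.05)
        rev = scan_promoter(pwm, make_promoter(reverse_complement(seq)), alpha=0.05)
        L, w = len(seq), pwm.width
        mapped = {
            (L - w - h.local_start(L), "-" if h.strand == "+" else "+", round(h.score, 6))
            for h in fwd
        }
        got = {(h.local_start(L), h.strand, round(h.score, 6)) for h in rev}
        assert mapped == got

    def test_stricter_alpha_gives_subset(self):
        rng = np.random.default_rng(8)
        pwm = pfm_to_pwm(random_pfm(rng, 4))
        prom = make_promoter("".join(rng.choice(list("ACGT"), 300)))
        loose = {(h.tss_relative_start, h.strand) for h in scan_promoter(pwm, prom, 0.05)}
        strict = {(h.tss_relative_start, h.strand) for h in scan_promoter(pwm, prom, 0.005)}
        assert strict <= loose

    @pytest.mark.parametrize("width", [2, 4, 6])
    def test_scan_matches_bruteforce_pvalue_scanner(self, width):
        """DP-thresholded scan equals a per-word exact-p-value oracle."""
        rng = np.random.default_rng(width)
        pwm = pfm_to_pwm(random_pfm(rng, width))
        support, probs = enumerate_distribution(pwm)
        tails = np.cumsum(probs[::-1])[::-1]
        tail_at = dict(zip(support.tolist(), tails.tolist()))
        q = pwm.quantize(0.01)
        q_rc = pwm.reverse_complement().quantize(0.01)
        seq = "".join(rng.choice(list("ACGT"), 200))
        enc = [("ACGT").index(c) for c in seq]
        alpha = 0.01
        expected = set()
        for i in range(len(seq) - width + 1):
            word = enc[i : i + width]
            for strand, mat in (("+", q), ("-", q_rc)):
                s = int(sum(mat[j, b] for j, b in enumerate(word)))
                if tail_at[s] < alpha:
                    expected.add((i, strand))
        got = {
            (h.local_start(len(seq)), h.strand)
            for h in scan_promoter(pwm, make_promoter(seq), alpha)
        }
        assert got == expected


class TestCurationAndSummary:
    def _hits(self):
        return [
            MotifHit("TF1", "g1", -50, "+", 5.0, 1e-4),
            MotifHit("TF1", "g1", -20, "-", 5.0, 1e-4),
            MotifHit("TF2", "g1", -80, "+", 5.0, 1e-4),
            MotifHit("TF2", "g2", -10, "+", 5.0, 1e-4),
        ]

    def test_empty_table_drops_everything(self):
        assert filter_by_curation(self._hits(), set()) == []

    def test_full_coverage_keeps_everything(self):
        table = {("TF1", "g1"), ("TF2", "g1"), ("TF2", "g2")}
        kept = filter_by_curation(self._hits(), table)
        assert len(kept) == 4 and all(h.curated for h in kept)

    def test_removing_one_pair_drops_exactly_its_hits(self):
        table = {("TF1", "g1"), ("TF2", "g2")}  # (TF2, g1) removed
        kept = filter_by_curation(self._hits(), table)
        assert {(h.tf_id, h.gene_id) for h in kept} == table
        assert len(kept) == 3

    def test_summarize_regulation_counts(self):
        table = {("TF1", "g1"), ("TF2", "g1"), ("TF2", "g2")}
        kept = filter_by_curation(self._hits(), table)
        df = summarize_regulation(kept, ["g1", "g2", "g3"])
        assert tuple(df.loc["g1"]) == (2, 3)  # 2 TFs, 3 TFBSs
        assert tuple(df.loc["g2"]) == (1, 1)
        assert tuple(df.loc["g3"]) == (0, 0)


class TestTata:
    def _with_word_at(self, rel, word="TATATAAA", length=1000):
        rng = np.random.default_rng(1)
        seq = list("".join(rng.choice(list("CG"), length)))  # no accidental matches
        local = rel + length
        seq[local : local + 8] = word
        return make_promoter("".join(seq))

    def test_consensus_match_inside_window(self):
        flag, positions = find_tata(self._with_word_at(-120))
        assert flag and positions == [-120]

    def test_match_downstream_of_window_ignored(self):
        flag, _ = find_tata(self._with_word_at(-40, "TATAAAAG"))
        assert not flag

    def test_position_two_must_be_A(self):
        flag, _ = find_tata(self._with_word_at(-120, "TGTAAATA"))
        assert not flag

    @pytest.mark.parametrize("rel,expected", [(-200, True), (-50, True), (-201, False), (-49, False)])
    def test_window_boundaries(self, rel, expected):
        flag, _ = find_tata(self._with_word_at(rel))
        assert flag is expected

    def test_equals_regex_oracle_on_random_sequences(self):
        pattern = re.compile("(?=(TATA[AT]A[AT][AG]))")
        rng = np.random.default_rng(11)
        for _ in range(300):
            seq = "".join(rng.choice(list("ACGT"), 400, p=[0.35, 0.15, 0.15, 0.35]))
            L = len(seq)
            oracle = any(
                -200 <= m.start() - L <= -50 for m in pattern.finditer(seq)
            )
            assert find_tata(make_promoter(seq))[0] is oracle


def test_pfm_file_roundtrip(tmp_path):
    rng = np.random.default_rng(2)
    pfms = [
        PositionFrequencyMatrix("TF000", np.rint(rng.uniform(1, 99, (6, 4)))),
        PositionFrequencyMatrix("TF001", np.rint(rng.uniform(1, 99, (8, 4)))),
    ]
    path = tmp_path / "motifs.pfm"
    write_pfms(pfms, path)
    back = read_pfms(path)
    assert [p.tf_id for p in back] == ["TF000", "TF001"]
    for a, b in zip(pfms, back):
        assert np.allclose(a.counts, b.counts)
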