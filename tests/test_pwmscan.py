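"""PWM construction, scanning, exact p-values, and BH q-values."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mamoscan import pwmscan
from mamoscan.pwmscan import (
    PWM,
    UNIFORM_BG,
    bh_fdr,
    consensus,
    exact_pvalues,
    pwm_from_consensus,
    reverse_complement,
    scan,
)

from conftest import random_dna


def brute_force_pvalue(pwm: PWM, word_score: float) -> float:
    """Independent oracle: exhaustive enumeration of all width-W words."""
    lom = pwm.log_odds()
    w = pwm.width
    total = 0.0
    for word in itertools.product(range(4), repeat=w):
        s = sum(lom[a, j] for j, a in enumerate(word))
        if s >= word_score - 1e-12:
            total += math.prod(pwm.background[a] for a in word)
    return total


class TestPwmFromConsensus:
    def test_printed_consensus_roundtrip(self):
        pwm = pwm_from_consensus("GTGCGTGGC", 0.97)
        assert pwm.width == 9
        assert consensus(pwm) == "GTGCGTGGC"

    @pytest.mark.parametrize(
        "cons,match_prob,expected_col0",
        [("A", 1.0, [1.0, 0.0, 0.0, 0.0]), ("ACGT", 0.4, [0.4, 0.2, 0.2, 0.2])],
    )
    def test_column_arithmetic(self, cons, match_prob, expected_col0):
        pwm = pwm_from_consensus(cons, match_prob)
        assert pwm.probs[:, 0] == pytest.approx(expected_col0)
        for j, c in enumerate(cons):
            col = pwm.probs[:, j]
            assert col.max() == pytest.approx(match_prob)
            others = np.delete(col, pwmscan._IDX[c])
            assert others == pytest.approx([(1 - match_prob) / 3] * 3)

    def test_rejects_ambiguous_letters_and_bad_match_prob(self):
        with pytest.raises(ValueError):
            pwm_from_consensus("GTNCG")
        with pytest.raises(ValueError):
            pwm_from_consensus("ACGT", 0.25)

    def test_columns_sum_to_one(self, mamo_pwm):
        assert np.allclose(mamo_pwm.probs.sum(axis=0), 1.0, atol=1e-9)


class TestConsensus:
    def test_tie_break_is_alphabetical(self):
        uniform = PWM("u", np.full((4, 2), 0.25))
        assert consensus(uniform) == "AA"

    def test_fixture_contains_emsa_core(self, mamo_pwm):
        assert "TGCGT" in consensus(mamo_pwm)


class TestScan:
    def test_planted_site_found_on_plus_strand(self, rng, mamo_pwm):
        background = random_dna(rng, 200)
        seq = background[:50] + "GTGCGTGGC" + background[59:]
        hits = scan(seq, mamo_pwm, p_threshold=1e-4)
        assert any(h.start == 50 and h.strand == "+" for h in hits)

    def test_planted_reverse_complement_found_on_minus_strand(self, rng, mamo_pwm):
        background = random_dna(rng, 200)
        seq = background[:50] + "GCCACGCAC" + background[59:]
        hits = scan(seq, mamo_pwm, p_threshold=1e-4)
        minus = [h for h in hits if h.strand == "-"]
        assert any(h.start == 50 for h in minus)
        assert minus[0].matched_seq == "GTGCGTGGC"

    def test_yellow_upstream_site_hit_under_genomic_background(
        self, mamo_pwm, genome_background
    ):
        # the site bound in vitro ~70 bp upstream of the yellow TSS carries
        # two mismatches to the consensus; in genome context (AT-rich
        # background) its exact p-value clears 1e-3
        hits = scan("CTGCGTGGT", mamo_pwm, p_threshold=1e-3,
                    background=genome_background)
        assert len(hits) == 1
        pwm_bg = mamo_pwm.with_background(genome_background)
        oracle_p = brute_force_pvalue(pwm_bg, hits[0].score)
        assert hits[0].pvalue == pytest.approx(oracle_p, abs=1e-12)
        assert hits[0].pvalue <= 1e-3

    def test_reverse_complement_symmetry(self, rng, mamo_pwm):
        seq = random_dna(rng, 300)
        fwd = scan(seq, mamo_pwm, p_threshold=1e-2)
        rev = scan(reverse_complement(seq), mamo_pwm, p_threshold=1e-2)
        w = mamo_pwm.width
        mirrored = {(len(seq) - w - h.start, "+-"["+-".index(h.strand) ^ 1], h.matched_seq)
                    for h in rev}
        assert {(h.start, h.strand, h.matched_seq) for h in fwd} == mirrored

    def test_hit_count_monotone_in_threshold(self, rng, mamo_pwm):
        seq = random_dna(rng, 5000)
        counts = [len(scan(seq, mamo_pwm, p_threshold=t))
                  for t in (1e-2, 1e-3, 1e-4)]
        assert counts == sorted(counts, reverse=True)

    def test_n_windows_skipped_and_bad_letters_rejected(self, mamo_pwm):
        assert scan("GTGCNTGGC", mamo_pwm, background=UNIFORM_BG) == []
        with pytest.raises(ValueError):
            scan("GTGCRTGGC", mamo_pwm)

    def test_width_longer_than_sequence_gives_empty(self, mamo_pwm):
        assert scan("ACGT", mamo_pwm) == []

    def test_hits_sorted(self, rng, mamo_pwm):
        seq = random_dna(rng, 4000)
        hits = scan(seq, mamo_pwm, p_threshold=5e-2)
        keys = [(h.seq_id, h.start, h.strand) for h in hits]
        assert keys == sorted(keys)


class TestExactPvalues:
    def test_single_column_top_score(self):
        pwm = PWM("one", np.array([[1.0], [0.0], [0.0], [0.0]]), pseudocount=0.25)
        dist = exact_pvalues(pwm)
        top = pwm.log_odds().max()
        assert dist.pvalue(top) == pytest.approx(0.25)

    @pytest.mark.parametrize("width", [2, 3, 4, 5, 6])
    def test_null_matches_exhaustive_enumeration(self, width):
        rng = np.random.default_rng(width)
        probs = rng.dirichlet(np.ones(4), size=width).T
        bg = rng.dirichlet(np.full(4, 5.0))
        pwm = PWM(f"w{width}", probs, background=bg)
        dist = exact_pvalues(pwm)
        lom = pwm.log_odds()
        for word in itertools.product(range(4), repeat=width):
            s = float(lom[list(word), np.arange(width)].sum())
            expected = brute_force_pvalue(pwm, s)
            got = dist.word_pvalue(np.array(word))
            assert got == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("width", [3, 5])
    def test_discretized_dp_agrees_with_enumeration_in_the_tail(self, width):
        # the DP path serves motifs too wide to enumerate; at high
        # granularity its tail p-values track the exact ones closely
        rng = np.random.default_rng(width + 50)
        pwm = PWM(f"w{width}", rng.dirichlet(np.ones(4), size=width).T)
        exact = exact_pvalues(pwm, method="exact")
        dp = exact_pvalues(pwm, granularity=20_000, method="dp")
        lom = pwm.log_odds()
        for word in itertools.product(range(4), repeat=width):
            s = float(lom[list(word), np.arange(width)].sum())
            p_exact = exact.pvalue(s)
            p_dp = dp.word_pvalue(np.array(word))
            assert p_dp == pytest.approx(p_exact, rel=0.02, abs=1e-6)

    def test_survival_properties(self, mamo_pwm):
        dist = exact_pvalues(mamo_pwm.with_background(UNIFORM_BG))
        assert dist.pvalue(-math.inf) == 1.0
        lom = mamo_pwm.with_background(UNIFORM_BG).log_odds()
        assert dist.pvalue(lom.min(axis=0).sum()) == pytest.approx(1.0)
        grid = np.linspace(lom.min(axis=0).sum(), lom.max(axis=0).sum(), 200)
        ps = dist.pvalues_for_scores(grid)
        assert (np.diff(ps) <= 1e-15).all()

    def test_zero_pseudocount_with_zero_cell_is_an_error(self):
        pwm = PWM("z", np.array([[1.0], [0.0], [0.0], [0.0]]), pseudocount=0.0)
        with pytest.raises(ValueError):
            exact_pvalues(pwm)

    def test_granularity_floor(self, mamo_pwm):
        with pytest.raises(ValueError):
            exact_pvalues(mamo_pwm, granularity=50)


class TestBhFdr:
    def test_step_up_hand_example(self):
        assert bh_fdr([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_edge_cases(self):
        assert bh_fdr([]) == []
        assert bh_fdr([1.0, 1.0]) == [1.0, 1.0]
        assert bh_fdr([0.2]) == [0.2]

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=1e-9, max_value=1.0), min_size=1,
                    max_size=40))
    def test_monotone_after_sorting_and_bounded(self, p):
        q = np.array(bh_fdr(p))
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()
        assert ((q >= np.asarray(p) - 1e-15) & (q <= 1.0)).all()


class TestMemeIO:
    def test_roundtrip(self, tmp_path, mamo_pwm):
        path = tmp_path / "m.meme"
        pwmscan.write_meme([mamo_pwm], path)
        (back,) = pwmscan.read_meme(path)
        assert back.id == mamo_pwm.id
        assert np.allclose(back.probs, mamo_pwm.probs, atol=1e-6)

    def test_biopython_reads_our_minimal_format(self, tmp_path, mamo_pwm):
        from Bio import motifs

        path = tmp_path / "m.meme"
        pwmscan.write_meme([mamo_pwm], path)
        with open(path) as fh:
            (m,) = motifs.parse(fh, "minimal")
        assert str(m.consensus) == "GTGCGTGGC"
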