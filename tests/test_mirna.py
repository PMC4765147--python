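"""miRNA duplex scoring, target scanning, expression anticorrelation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from phytonet.mirna import (
    expression_anticorrelation,
    scan_targets,
    score_duplex,
)
from phytonet.synthetic import (
    embed_site,
    gen_mirna_duplexes,
)

COMP = {"A": "U", "U": "A", "G": "C", "C": "G"}


def revcomp(seq: str) -> str:
    return "".join(COMP[b] for b in reversed(seq))


class TestScoreDuplex:
    def test_perfect_duplex_scores_zero(self):
        mirna = "UGACAGAAGAGAGUGAGCACA"
        assert score_duplex(mirna, revcomp(mirna)) == 0.0

    def test_gu_wobble_in_tail_scores_half(self):
        mirna = "A" * 17 + "G" + "AAA"  # G at position 18 (tail)
        site = list(revcomp(mirna))
        site[21 - 18] = "U"  # pairs G:U
        assert score_duplex(mirna, "".join(site)) == 0.5

    def test_two_core_mismatches_hit_the_boundary(self):
        mirna = "UGACAGAAGAGAGUGAGCACA"
        site = list(revcomp(mirna))
        for pos in (5, 9):  # core positions: penalty 1 doubled
            b = mirna[pos - 1]
            bad = next(x for x in "ACGU"
                       if x != COMP[b] and (b, x) not in {("G", "U"), ("U", "G")})
            site[21 - pos] = bad
        score = score_duplex(mirna, "".join(site))
        assert score == 4.0  # strict < 4 means NOT predicted

    def test_t_and_u_equivalent(self):
        mirna = "UGACAGAAGAGAGUGAGCACA"
        site = revcomp(mirna)
        assert score_duplex(mirna.replace("U", "T"), site) == \
            score_duplex(mirna, site)

    def test_empty_or_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError):
            score_duplex("", "A")
        with pytest.raises(ValueError):
            score_duplex("AAA", "AA")

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=50, derandomize=True)
    def test_adding_a_mismatch_never_decreases_score(self, seed):
        rng = np.random.default_rng(seed)
        mirna = "".join("ACGU"[i] for i in rng.integers(0, 4, 21))
        site = list(revcomp(mirna))
        base = score_duplex(mirna, "".join(site))
        pos = int(rng.integers(0, 21))
        site[pos] = "ACGU"[int(rng.integers(0, 4))]
        assert score_duplex(mirna, "".join(site)) >= base


class TestGeneratedDuplexes:
    @pytest.mark.parametrize(
        "plan, expected",
        [((0, 0, 0), 0.0), ((1, 0, 0), 2.0), ((0, 2, 1), 2.5), ((2, 0, 0), 4.0)],
    )
    def test_truth_scores_match_scoring_scheme(self, plan, expected):
        records, truth = gen_mirna_duplexes(3, [plan], seed=9)
        for rec in records:
            assert rec["truth_score"] == expected
            assert score_duplex(rec["mirna_seq"], rec["site_seq"]) == expected

    def test_infeasible_plan_rejected(self):
        with pytest.raises(ValueError, match="realizable"):
            gen_mirna_duplexes(1, [(13, 0, 0)], seed=0)


class TestScan:
    def test_embedded_perfect_site_found_at_offset(self):
        records, _ = gen_mirna_duplexes(1, [(0, 0, 0)], seed=2)
        transcript, offset = embed_site(records[0]["site_seq"], flank=30, seed=3)
        hits = scan_targets(records[0]["mirna_seq"], transcript)
        assert hits and hits[0].site_start == offset and hits[0].score == 0.0

    def test_planted_imperfect_site_reports_truth_score(self):
        records, _ = gen_mirna_duplexes(1, [(0, 2, 1)], seed=4)
        transcript, offset = embed_site(records[0]["site_seq"], flank=25, seed=5)
        hits = scan_targets(records[0]["mirna_seq"], transcript)
        best = hits[0]
        assert best.site_start == offset and best.score == 2.5 and best.predicted

    def test_scan_equals_per_window_oracle(self):
        rng = np.random.default_rng(3)
        mirna = "".join("ACGU"[i] for i in rng.integers(0, 4, 21))
        transcript = "".join("ACGU"[i] for i in rng.integers(0, 4, 120))
        hits = scan_targets(mirna, transcript, threshold=np.inf)
        oracle = {
            start: score_duplex(mirna, transcript[start:start + 21])
            for start in range(len(transcript) - 20)
        }
        assert {h.site_start: h.score for h in hits} == oracle

    def test_random_transcript_typically_empty_at_threshold(self):
        rng = np.random.default_rng(3)
        mirna = "".join("ACGU"[i] for i in rng.integers(0, 4, 21))
        transcript = "".join("ACGU"[i] for i in rng.integers(0, 4, 200))
        assert scan_targets(mirna, transcript) == []


class TestAnticorrelation:
    def test_perfectly_opposed_profiles(self):
        x = np.arange(12.0)
        assert expression_anticorrelation(x, -x) == pytest.approx(-1.0)

    def test_planted_anticorrelation_recovered(self):
        rng = np.random.default_rng(6)
        f = rng.normal(size=12)
        target = -0.7 * f + np.sqrt(1 - 0.49) * rng.normal(size=12)
        r = expression_anticorrelation(f, target)
        assert -0.95 <= r <= -0.4

    def test_independent_profiles_weak(self):
        rng = np.random.default_rng(6)
        r = expression_anticorrelation(rng.normal(size=12), rng.normal(size=12))
        assert abs(r) < 0.6

    def test_zero_variance_returns_nan(self):
        assert np.isnan(expression_anticorrelation(np.ones(5), np.arange(5.0)))
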