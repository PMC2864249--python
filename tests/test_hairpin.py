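"""Folding engine, stem-loop criteria, miRNA* geometry and novel calls."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mirnaome._seq import revcomp, to_dna
from mirnaome.hairpin import (Candidate, call_novel, evaluate_hairpin,
                              extract_candidates, find_star, fold)
from mirnaome.reads import collapse_and_filter
from mirnaome.simulate import make_hairpin

from _oracles import dinucleotide_shuffle, max_pairing_score

_VALID = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C"), ("G", "T"), ("T", "G")}


class TestFold:
    def test_unpairable_sequence_is_all_dots(self):
        fr = fold("AAAAAAAAAA")
        assert fr.structure == "." * 10 and fr.score == 0.0

    def test_perfect_short_stem(self):
        fr = fold("GGGGAAAACCCC")
        assert fr.score == 4.0
        assert fr.structure == "((((....))))"

    def test_invalid_characters_rejected(self):
        with pytest.raises(ValueError):
            fold("ACGTN")
        with pytest.raises(ValueError):
            fold("")

    def test_length_cap(self):
        with pytest.raises(ValueError):
            fold("A" * 401)

    def test_deterministic(self):
        seq = "GGCAUGCAUUAGCGCUAAUGCAUGCC"
        f1, f2 = fold(seq), fold(seq)
        assert f1.structure == f2.structure and f1.score == f2.score

    def test_score_equals_enumeration_oracle_on_random_sequences(self):
        rng = np.random.default_rng(42)
        nts = np.array(list("ACGU"))
        for _ in range(40):
            n = int(rng.integers(6, 15))
            seq = "".join(nts[rng.integers(0, 4, n)])
            assert fold(seq).score == max_pairing_score(seq)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.text(alphabet="ACGU", min_size=5, max_size=60))
    def test_structural_invariants(self, seq):
        fr = fold(seq)
        pm = fr.pair_map
        dna = to_dna(seq)
        open_stack = []
        for i, ch in enumerate(fr.structure):
            if ch == "(":
                open_stack.append(i)
            elif ch == ")":
                j = open_stack.pop()          # balanced + nested (no pseudoknots)
                assert pm[i] == j and pm[j] == i
        assert not open_stack
        for i in range(len(dna)):
            j = int(pm[i])
            if j >= 0:
                assert pm[j] == i              # symmetry
                if j > i:
                    assert (dna[i], dna[j]) in _VALID
                    assert j - i > 3           # min_loop


class TestEvaluate:
    def test_planted_hairpin_passes_with_correct_arm(self):
        rng = np.random.default_rng(1)
        mature = "TGACAGAAGAGAGTGAGCACA"
        pre, star, ms = make_hairpin(mature, 22, "AACAAACA", rng)
        fr = fold(pre)
        v = evaluate_hairpin(fr, ms, ms + len(mature))
        assert v.passed and v.mature_arm == "5p"

    def test_mature_on_three_prime_arm(self):
        rng = np.random.default_rng(1)
        mature = "TGACAGAAGAGAGTGAGCACA"
        pre, star, ms = make_hairpin(mature, 22, "AACAAACA", rng)
        fr = fold(pre)
        star_start = pre.find(star)
        v = evaluate_hairpin(fr, star_start, star_start + len(star))
        assert v.passed and v.mature_arm == "3p"

    def test_mature_centered_on_loop_fails(self):
        rng = np.random.default_rng(1)
        mature = "TGACAGAAGAGAGTGAGCACA"
        pre, star, ms = make_hairpin(mature, 22, "AACAAACA", rng)
        fr = fold(pre)
        center = ms + len(mature) + 4  # inside the terminal loop
        v = evaluate_hairpin(fr, center - 10, center + 10)
        assert not v.passed and v.reason == "spans_loop"

    def test_shuffled_precursors_rarely_pass(self, small_refs):
        rng = np.random.default_rng(8)
        n, npass = 0, 0
        for g in small_refs.planted:
            pre = to_dna(g.precursor_seq)
            ms, me = g.mature_start, g.mature_start + len(g.mature_seq)
            for _ in range(20):
                v = evaluate_hairpin(fold(dinucleotide_shuffle(pre, rng)), ms, me)
                n += 1
                npass += v.passed
        assert npass / n < 0.10

    def test_mature_span_validation(self):
        fr = fold("GGGGAAAACCCC")
        with pytest.raises(ValueError):
            evaluate_hairpin(fr, 5, 20)


class TestFindStar:
    def test_perfect_duplex_star_is_shifted_reverse_complement(self):
        rng = np.random.default_rng(2)
        mature = "GGACAGAAGAGAGTGAGCACAT"  # 22 nt
        pre, star, ms = make_hairpin(mature, 22, "AACAAACA", rng)
        fr = fold(pre)
        got, s0, s1 = find_star(fr, ms, ms + 22)
        assert to_dna(got) == star
        assert to_dna(got)[:-2] == revcomp(mature[:-2])
        assert len(got) == 22

    def test_bulged_mature_star_length_differs_by_one(self):
        rng = np.random.default_rng(3)
        b = "".join("ACGT"[i] for i in rng.integers(0, 4, 22))
        mature = "TGACAGAAGAGAGTGAGCACA"  # 21 nt
        m_del = mature[:10] + mature[11:]  # star arm misses partner of pos 10
        pre = b + mature + "AACAAACA" + revcomp(b + m_del[:-2])
        fr = fold(pre)
        ms = len(b)
        v = evaluate_hairpin(fr, ms, ms + 21)
        assert v.passed
        star, s0, s1 = find_star(fr, ms, ms + 21)
        assert len(star) == 20

    def test_unpaired_mature_has_no_star(self):
        fr = fold("A" * 40)
        with pytest.raises(ValueError):
            find_star(fr, 5, 26)


class TestCallNovel:
    def _setup(self, star_counts=(3, 1)):
        rng = np.random.default_rng(4)
        mature = "TGACAGAAGAGAGTGAGCACA"
        pre, star, ms = make_hairpin(mature, 22, "AACAAACA", rng)
        transcript = {"t1": "CA" * 20 + pre + "AC" * 20}  # inert, non-pairing flanks
        ins_a = [mature] * 30 + [star] * star_counts[0]
        ins_b = [mature] * 10 + [star] * star_counts[1]
        table = collapse_and_filter(ins_a, ins_b)
        return mature, star, transcript, table

    def test_sequenced_star_accepted(self):
        mature, star, tref, table = self._setup()
        cands = extract_candidates([mature], tref)
        calls = call_novel(cands, table)
        assert len(calls) == 1
        call = calls[0]
        assert call.accepted and to_dna(call.star_seq) == star
        assert (call.star_count_a, call.star_count_b) == (3, 1)

    def test_multiple_windows_collapse_to_one_call(self):
        mature, star, tref, table = self._setup()
        cands = extract_candidates([mature], tref)
        assert len(cands) >= 2  # several flank configurations
        assert len(call_novel(cands, table)) == 1

    def test_absent_star_gives_no_star_status(self):
        mature, star, tref, table = self._setup()
        table.counts = table.counts.drop(index=star)
        calls = call_novel(extract_candidates([mature], tref), table)
        assert calls[0].status == "no_star" and not calls[0].accepted

    def test_adding_star_reads_never_uncalls_the_locus(self):
        # acceptance is monotone in miRNA* evidence at duplex level
        mature, star, tref, table = self._setup(star_counts=(3, 0))
        calls1 = call_novel(extract_candidates([mature], tref), table)
        assert calls1[0].accepted
        table.counts.loc[star] = [25, 5]  # more star evidence
        calls2 = call_novel(extract_candidates([mature], tref), table)
        assert calls2[0].accepted

    def test_minor_arm_demoted_when_partner_dominates(self):
        mature, star, tref, table = self._setup()
        calls = call_novel(extract_candidates([star], tref), table)
        assert calls[0].status == "minor_arm"


class TestExtractCandidates:
    def test_hit_at_transcript_start_is_clipped(self):
        mature = "TGACAGAAGAGAGTGAGCACA"
        tref = {"t1": mature + "ACGT" * 30}
        cands = extract_candidates([mature], tref, flank_sets=[(100, 20)])
        assert len(cands) == 1
        c = cands[0]
        assert c.window_start == 0 and c.mature_offset == 0

    def test_no_perfect_hit_no_candidates(self):
        assert extract_candidates(["A" * 21], {"t1": "CG" * 100}) == []

    def test_reverse_complement_hits_are_oriented(self):
        mature = "TGACAGAAGAGAGTGAGCACA"
        tref = {"t1": "ACGT" * 15 + revcomp(mature) + "TGCA" * 15}
        cands = extract_candidates([mature], tref, flank_sets=[(20, 20)])
        assert cands and all(c.strand == "-" for c in cands)
        for c in cands:
            assert c.window_seq[c.mature_offset:c.mature_offset + len(mature)] == mature

    def test_planted_precursors_always_covered(self, small_refs):
        for g in small_refs.planted:
            cands = extract_candidates([to_dna(g.mature_seq)], small_refs.transcripts)
            # at least one window contains the full mature/star duplex
            assert any(to_dna(g.star_seq) in c.window_seq and
                       to_dna(g.mature_seq) in c.window_seq for c in cands)
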