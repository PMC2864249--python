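"""Complementarity scoring, target scanning and hotspot statistics."""

import numpy as np
import pytest

import mirnaome.targets as tg
from mirnaome._seq import revcomp, to_dna
from mirnaome.annotate import TranscriptMatch
from mirnaome.reads import collapse_and_filter
from mirnaome.targets import (HotspotSummary, antisense_cognate_fraction,
                              hotspot_stats, predict_targets, score_site)

from _oracles import oracle_site_score

MIRNA = "UGACAGAAGAGAGUGAGCAC"  # 20 nt


def perfect_site(mirna: str) -> str:
    return revcomp(to_dna(mirna))


class TestScoreSite:
    def test_perfect_complement_scores_zero(self):
        assert score_site(MIRNA, perfect_site(MIRNA)) == 0.0

    def test_gu_wobble_position_weighting(self):
        # miRNA position 15 holds a G; giving the site a U there makes a
        # G:U pair: 0.5 outside the doubled 2-13 window
        m = list(to_dna(MIRNA))
        assert m[14] == "G"
        site = list(perfect_site(MIRNA))
        site[len(m) - 15] = "T"  # paired base of miRNA position 15
        assert score_site("".join(m), "".join(site)) == 0.5
        # a G at position 5 paired with U costs double
        m5 = m.copy()
        m5[4] = "G"
        site5 = list(perfect_site("".join(m5)))
        site5[len(m) - 5] = "T"
        assert score_site("".join(m5), "".join(site5)) == 1.0

    def test_mismatch_doubled_in_seed_proximal_region(self):
        site = list(perfect_site(MIRNA))
        site[len(MIRNA) - 5] = "G"  # mismatch opposite miRNA position 5 (was A:T)
        assert score_site(MIRNA, "".join(site)) == 2.0
        site2 = list(perfect_site(MIRNA))
        site2[0] = "A"  # opposite miRNA position 20 (3' end, not doubled)
        assert score_site(MIRNA, "".join(site2)) == 1.0

    def test_bulged_site_base_costs_two(self):
        site = perfect_site(MIRNA)
        bulged = site[:2] + "C" + site[2:]  # extra base near the miRNA 3' end
        assert score_site(MIRNA, bulged) <= 2.0 * 2

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            score_site(MIRNA, "ACGT")

    def test_matches_oracle_on_random_pairs(self):
        rng = np.random.default_rng(13)
        nts = np.array(list("ACGT"))
        for _ in range(150):
            lm = int(rng.integers(19, 23))
            m = "".join(nts[rng.integers(0, 4, lm)])
            ls = lm + int(rng.integers(-1, 2))
            s = "".join(nts[rng.integers(0, 4, ls)])
            assert score_site(m, s) == oracle_site_score(m, s)

    def test_duplex_symmetry_without_positional_weighting(self, monkeypatch):
        # the same physical duplex scored from either strand's perspective
        # (the guide and the site swap roles; pairs are unchanged)
        monkeypatch.setattr(tg, "SEED_DOUBLE_RANGE", (1, 0))  # disable doubling
        rng = np.random.default_rng(3)
        nts = np.array(list("ACGT"))
        for _ in range(50):
            m = "".join(nts[rng.integers(0, 4, 21)])
            s = "".join(nts[rng.integers(0, 4, 21)])
            assert score_site(m, s) == score_site(s, m)


class TestPredictTargets:
    def test_planted_perfect_site_found_at_zero(self):
        site = perfect_site(MIRNA)
        tref = {"t1": "CCAA" * 8 + site + "GGTT" * 8}
        hits = predict_targets({"m1": MIRNA}, tref, cutoff=4.0)
        perfect = hits[hits["score"] == 0.0]
        assert len(perfect) == 1
        row = perfect.iloc[0]
        assert row["site_start"] == 32 and row["site_end"] == 32 + len(site)
        assert set(row["match_line"]) == {"|"}

    def test_cutoff_zero_keeps_only_perfect_sites(self):
        site = perfect_site(MIRNA)
        tref = {"t1": "CCAA" * 8 + site + "GGTT" * 8}
        hits = predict_targets({"m1": MIRNA}, tref, cutoff=0.0)
        assert (hits["score"] == 0.0).all() and len(hits) == 1

    def test_hit_set_monotone_in_cutoff(self):
        rng = np.random.default_rng(9)
        nts = np.array(list("ACGT"))
        tref = {f"t{i}": "".join(nts[rng.integers(0, 4, 300)]) for i in range(3)}
        prev: set = set()
        for cutoff in (0.0, 2.0, 4.0, 6.0):
            hits = predict_targets({"m1": MIRNA}, tref, cutoff=cutoff)
            cur = {(r.transcript_id, r.site_start) for r in hits.itertuples()}
            assert prev <= cur
            prev = cur

    def test_equals_bruteforce_window_oracle(self):
        rng = np.random.default_rng(31)
        nts = np.array(list("ACGT"))
        tref = {f"t{i}": "".join(nts[rng.integers(0, 4, 250)]) for i in range(4)}
        cutoff = 6.0
        hits = predict_targets({"m1": MIRNA}, tref, cutoff=cutoff)
        got = {(r.transcript_id, r.site_start): r.score for r in hits.itertuples()}
        m = to_dna(MIRNA)
        expected = {}
        for tid, tseq in tref.items():
            for start in range(len(tseq)):
                best = None
                for sl in (len(m) - 1, len(m), len(m) + 1):
                    if start + sl > len(tseq):
                        continue
                    sc = oracle_site_score(m, tseq[start:start + sl])
                    best = sc if best is None else min(best, sc)
                if best is not None and best <= cutoff:
                    expected[(tid, start)] = best
        assert got == expected

    def test_empty_transcriptome(self):
        assert len(predict_targets({"m1": MIRNA}, {}, 4.0)) == 0


def _hotspot_fixture():
    # gene A: sense sRNAs only; gene B: both; gene C: none
    asg = {
        "SIG1": TranscriptMatch(sense_ids=["A"]),
        "SIG2": TranscriptMatch(sense_ids=["B"], antisense_ids=["B"]),
    }
    table = collapse_and_filter(["ACGTACGTACGTACGTACGT"] * 3 +
                                ["TTTTCCCCGGGGAAAATTTT"] * 3, [])
    # remap signatures onto the table's sequences
    seqs = table.sequences
    asg = {seqs[0]: asg["SIG1"], seqs[1]: asg["SIG2"]}
    return asg, table


class TestHotspots:
    def test_small_fixture_counts(self):
        asg, table = _hotspot_fixture()
        out = hotspot_stats(["A", "B", "C"], asg, table)
        s = out["A"]
        assert s.n_targets == 3
        assert s.n_sense == 2       # inclusive of "both", Table-3 convention
        assert s.n_antisense == 1
        assert s.n_both == 1
        assert s.n_sense_only == 1 and s.n_antisense_only == 0
        assert s.n_total_either == 2
        assert s.pct(s.n_sense) == pytest.approx(100 * 2 / 3)

    def test_consistency_identity(self):
        s = HotspotSummary(n_targets=100, n_sense=65, n_antisense=55, n_both=44)
        assert s.n_sense_only + s.n_antisense_only + s.n_both == s.n_total_either
        assert s.n_both <= min(s.n_sense, s.n_antisense)
        assert s.n_total_either == 76

    def test_no_mapped_srnas_gives_zeros(self):
        table = collapse_and_filter(["ACGTACGTACGTACGTACGT"] * 3, [])
        out = hotspot_stats(["A", "B"], {}, table)
        assert out["A"].n_sense == 0 and out["A"].n_total_either == 0

    def test_counts_equal_bruteforce_rescan(self, small_run):
        refs, table = small_run["refs"], small_run["table"]
        asg = small_run["transcript_asg"]
        genes = sorted({tid.split()[0] for tid in refs.transcripts})[:50]
        out = hotspot_stats(genes, asg, table)
        # independent recount for library A
        sense, anti = set(), set()
        for sig, ca, cb in table.iter_rows():
            if ca == 0:
                continue
            rc = revcomp(sig)
            for header, tseq in refs.transcripts.items():
                tid = header.split()[0]
                if tid not in genes:
                    continue
                if sig in tseq:
                    sense.add(tid)
                if rc in tseq:
                    anti.add(tid)
        assert out["A"].n_sense == len(sense)
        assert out["A"].n_antisense == len(anti)
        assert out["A"].n_both == len(sense & anti)


class TestCognateFraction:
    def test_all_antisense_have_sense(self):
        asg, table = _hotspot_fixture()
        out = antisense_cognate_fraction(asg, table)
        assert out["A"] == 1.0  # the only antisense gene (B) also has sense

    def test_disjoint_sets(self):
        table = collapse_and_filter(["ACGTACGTACGTACGTACGT"] * 3, [])
        seq = table.sequences[0]
        asg = {seq: TranscriptMatch(antisense_ids=["X"])}
        assert antisense_cognate_fraction(asg, table)["A"] == 0.0

    def test_no_antisense_genes_returns_zero(self):
        table = collapse_and_filter(["ACGTACGTACGTACGTACGT"] * 3, [])
        assert antisense_cognate_fraction({}, table)["A"] == 0.0
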