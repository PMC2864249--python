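"""Plant miRNA target prediction and miRNA-target sRNA hotspot statistics.

Plant miRNAs recognize near-perfectly complementary sites, so candidate
sites are scored with an explicit complementarity penalty scheme in the
miRU/psRNATarget tradition: per aligned position a perfect pair costs 0, a
G:U wobble 0.5, a mismatch 1 and a bulged base 2, with penalties doubled
across miRNA positions 2-13 (5' seed-proximal region, counted from the
miRNA 5' end).  At most one single-nucleotide bulge per duplex is allowed
(on either strand); a site is reported when its total penalty is at most
the cutoff.  This is an explicit, configurable instantiation of the
published scheme — it does not claim identity with any web service's output.

The hotspot statistics ask which predicted target genes themselves produce
perfectly matching small RNAs, in sense and/or antisense orientation —
target loci acting as sRNA sources ("hotspots").
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from ._seq import to_dna, to_rna
from .annotate import TranscriptMatch
from .reads import SignatureTable

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}
# in reverse-complement space: miRNA char vs complement(site char)
_WOBBLE_RC = {("G", "A"), ("T", "C")}

SEED_DOUBLE_RANGE = (2, 13)  # 1-based miRNA positions with doubled penalties


def _mult(pos0: int) -> float:
    """Penalty multiplier for a 0-based miRNA position."""
    lo, hi = SEED_DOUBLE_RANGE
    return 2.0 if lo - 1 <= pos0 <= hi - 1 else 1.0


def _pair_penalty(m: str, t: str) -> float:
    """Penalty of miRNA base m (5'->3') opposite transcript base t."""
    rc = _COMP[t]
    if m == rc:
        return 0.0
    if (m, rc) in _WOBBLE_RC:
        return 0.5
    return 1.0


def score_site(mirna: str, site: str) -> float:
    """Penalty score of a miRNA against a candidate site (transcript 5'->3').

    The site must have the miRNA's length (ungapped duplex), one less (one
    miRNA base bulged) or one more (one site base bulged); the best
    admissible alignment is scored.  miRNA position i (from the 5' end)
    pairs the site base i positions from the site's 3' end.
    """
    m = to_dna(mirna)
    s = to_dna(site)
    lm, ls = len(m), len(s)
    if ls == lm:
        variants = [_score_variant(m, s, None, None)]
    elif ls == lm - 1:
        variants = [_score_variant(m, s, b, None) for b in range(lm)]
    elif ls == lm + 1:
        variants = [_score_variant(m, s, None, c) for c in range(ls)]
    else:
        raise ValueError("site length must be within 1 nt of the miRNA length")
    return min(variants)


def _score_variant(m: str, s: str, mirna_bulge: int | None, site_bulge: int | None) -> float:
    """Score one alignment variant; exactly one of the bulge args may be set."""
    lm = len(m)
    score = 0.0
    if mirna_bulge is not None:
        score += 2.0 * _mult(mirna_bulge)
        for i in range(lm):
            if i == mirna_bulge:
                continue
            r = i if i < mirna_bulge else i - 1
            score += _pair_penalty(m[i], s[len(s) - 1 - r]) * _mult(i)
    elif site_bulge is not None:
        c = site_bulge
        p0 = min(max(lm - 1 - c, 0), lm - 1)  # miRNA position flanking the bulge
        score += 2.0 * _mult(p0)
        for i in range(lm):
            k = lm - 1 - i          # site index among non-bulged, ascending
            sidx = k if k < c else k + 1
            score += _pair_penalty(m[i], s[sidx]) * _mult(i)
    else:
        for i in range(lm):
            score += _pair_penalty(m[i], s[len(s) - 1 - i]) * _mult(i)
    return score


def duplex_pseudo_energy(mirna: str, site: str) -> float:
    """Diagnostic weighted pair count of the best duplex (WC 1, G:U 0.5).

    A stand-in stability index, not a thermodynamic free energy.
    """
    m = to_dna(mirna)
    s = to_dna(site)
    if len(s) != len(m):
        return math.nan
    total = 0.0
    for i in range(len(m)):
        rc = _COMP[s[len(s) - 1 - i]]
        if m[i] == rc:
            total += 1.0
        elif (m[i], rc) in _WOBBLE_RC:
            total += 0.5
    return total


_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


def _penalty_matrix(m: str) -> np.ndarray:
    """P[i, t] = penalty of miRNA position i against transcript base t."""
    out = np.zeros((len(m), 4))
    for i, mc in enumerate(m):
        for t, ti in _BASE_INDEX.items():
            out[i, ti] = _pair_penalty(mc, t) * _mult(i)
    return out


def _scan_transcript(m: str, tarr: np.ndarray, pmat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Best score per site_start over all alignment variants.

    Returns (best_score, best_site_len) arrays indexed by site_start,
    minimizing score with ties resolved toward the ungapped (length L)
    variant, then the shorter site.  Starts where no variant fits are inf.
    """
    lm = len(m)
    n = len(tarr)
    n_starts = max(n - (lm - 1) + 1, 0)
    best_score = np.full(n_starts, np.inf)
    best_len = np.zeros(n_starts, dtype=np.int64)

    def _consider(scores: np.ndarray, site_len: int) -> None:
        ns = len(scores)
        improve = scores < best_score[:ns]
        best_score[:ns][improve] = scores[improve]
        best_len[:ns][improve] = site_len

    # preference order on ties: ungapped, then miRNA-bulge (shorter site),
    # then site-bulge — later variants replace only on strict improvement
    if n >= lm:
        ns = n - lm + 1
        sc = np.zeros(ns)
        for i in range(lm):
            sc += pmat[i, tarr[lm - 1 - i: lm - 1 - i + ns]]
        _consider(sc, lm)
    if n >= lm - 1:
        ns = n - (lm - 1) + 1
        mb = np.full(ns, np.inf)
        for b in range(lm):
            sc = np.full(ns, 2.0 * _mult(b))
            for i in range(lm):
                if i == b:
                    continue
                r = i if i < b else i - 1
                sc += pmat[i, tarr[lm - 2 - r: lm - 2 - r + ns]]
            np.minimum(mb, sc, out=mb)
        _consider(mb, lm - 1)
    if n >= lm + 1:
        ns = n - (lm + 1) + 1
        sb = np.full(ns, np.inf)
        for c in range(lm + 1):
            sc = np.full(ns, 2.0 * _mult(min(max(lm - 1 - c, 0), lm - 1)))
            for i in range(lm):
                k = lm - 1 - i
                sidx = k if k < c else k + 1
                sc += pmat[i, tarr[sidx: sidx + ns]]
            np.minimum(sb, sc, out=sb)
        _consider(sb, lm + 1)
    return best_score, best_len


def predict_targets(
    mirnas: Mapping[str, str],
    transcripts: Mapping[str, str],
    cutoff: float = 4.0,
) -> pd.DataFrame:
    """Scan every transcript window for complementarity sites.

    Windows of the miRNA length plus single-bulge variants are scored at
    every position; for each (miRNA, transcript, site_start) the best
    variant is kept and reported when its score is at most ``cutoff``.
    Rows are sorted by (score, mirna_id, transcript_id, site_start).
    Columns: mirna_id, transcript_id, site_start, site_end, score,
    mirna_align, match_line, site_align (site shown 3'->5').
    """
    t_items = [(tid, tseq, np.array([_BASE_INDEX[c] for c in tseq], dtype=np.int64))
               for tid, tseq in sorted((h.split()[0], to_dna(seq))
                                       for h, seq in transcripts.items())]
    rows = []
    for mid in sorted(mirnas):
        m = to_dna(mirnas[mid])
        pmat = _penalty_matrix(m)
        for tid, tseq, tarr in t_items:
            scores, lens = _scan_transcript(m, tarr, pmat)
            for start in np.nonzero(scores <= cutoff)[0]:
                score, site_len = float(scores[start]), int(lens[start])
                site = tseq[start:start + site_len]
                aln = _alignment_strings(m, site)
                rows.append((mid, tid, int(start), int(start) + site_len, score, *aln))
    df = pd.DataFrame(rows, columns=["mirna_id", "transcript_id", "site_start",
                                     "site_end", "score", "mirna_align",
                                     "match_line", "site_align"])
    return df.sort_values(["score", "mirna_id", "transcript_id", "site_start"],
                          kind="mergesort").reset_index(drop=True)


def _alignment_strings(m: str, site: str) -> tuple[str, str, str]:
    """Best-variant alignment as (miRNA 5'->3', match line, site 3'->5')."""
    lm, ls = len(m), len(site)
    srev = site[::-1]  # site 3'->5', aligned left-to-right with the miRNA
    if ls == lm:
        cols = list(zip(m, srev))
    elif ls == lm - 1:
        b = min(range(lm), key=lambda b: _score_variant(m, site, b, None))
        cols = []
        r = 0
        for i in range(lm):
            if i == b:
                cols.append((m[i], "-"))
            else:
                cols.append((m[i], srev[r]))
                r += 1
    else:
        c = min(range(ls), key=lambda c: _score_variant(m, site, None, c))
        crev = ls - 1 - c  # bulge index in 3'->5' orientation
        cols = []
        i = 0
        for k in range(ls):
            if k == crev:
                cols.append(("-", srev[k]))
            else:
                cols.append((m[i], srev[k]))
                i += 1
    mline = []
    for mc, tc in cols:
        if "-" in (mc, tc):
            mline.append(" ")
        elif _pair_penalty(mc, tc) == 0.0:
            mline.append("|")
        elif _pair_penalty(mc, tc) == 0.5:
            mline.append("o")
        else:
            mline.append(" ")
    top = "".join(to_rna(mc) if mc != "-" else "-" for mc, _ in cols)
    bot = "".join(to_rna(tc) if tc != "-" else "-" for _, tc in cols)
    return top, "".join(mline), bot


@dataclass
class HotspotSummary:
    """Per-library counts of target genes producing perfectly matching sRNAs.

    Inclusive tallies count genes with sense (or antisense) sRNAs whether or
    not the other orientation is also present; ``n_both`` counts genes with
    both, so sense-only = n_sense - n_both and
    n_total_either = (sense-only) + (antisense-only) + n_both.
    Percentages use the number of predicted target genes as denominator.
    """

    n_targets: int
    n_sense: int
    n_antisense: int
    n_both: int

    @property
    def n_sense_only(self) -> int:
        return self.n_sense - self.n_both

    @property
    def n_antisense_only(self) -> int:
        return self.n_antisense - self.n_both

    @property
    def n_total_either(self) -> int:
        return self.n_sense_only + self.n_antisense_only + self.n_both

    def pct(self, count: int) -> float:
        return 100.0 * count / self.n_targets if self.n_targets else 0.0

    def as_dict(self) -> dict[str, float]:
        return {
            "n_targets": self.n_targets,
            "n_sense": self.n_sense, "pct_sense": self.pct(self.n_sense),
            "n_antisense": self.n_antisense, "pct_antisense": self.pct(self.n_antisense),
            "n_both": self.n_both, "pct_both": self.pct(self.n_both),
            "n_total_either": self.n_total_either,
            "pct_total_either": self.pct(self.n_total_either),
            "n_sense_only": self.n_sense_only,
            "n_antisense_only": self.n_antisense_only,
        }


def _gene_orientation_sets(
    transcript_asg: Mapping[str, TranscriptMatch],
    table: SignatureTable,
    library: str,
) -> tuple[set[str], set[str]]:
    """(genes with sense sRNAs, genes with antisense sRNAs) in one library."""
    col = 0 if library == "A" else 1
    sense: set[str] = set()
    anti: set[str] = set()
    for sig, tm in transcript_asg.items():
        if table.get(sig)[col] > 0:
            sense.update(tm.sense_ids)
            anti.update(tm.antisense_ids)
    return sense, anti


def hotspot_stats(
    target_gene_ids: Iterable[str],
    transcript_asg: Mapping[str, TranscriptMatch],
    table: SignatureTable,
) -> dict[str, HotspotSummary]:
    """Hotspot summaries per library ("A", "B") over a set of target genes."""
    targets = set(target_gene_ids)
    out: dict[str, HotspotSummary] = {}
    for lib in ("A", "B"):
        sense, anti = _gene_orientation_sets(transcript_asg, table, lib)
        s = sense & targets
        a = anti & targets
        out[lib] = HotspotSummary(
            n_targets=len(targets), n_sense=len(s), n_antisense=len(a),
            n_both=len(s & a))
    return out


def antisense_cognate_fraction(
    transcript_asg: Mapping[str, TranscriptMatch],
    table: SignatureTable,
    gene_ids: Iterable[str] | None = None,
) -> dict[str, float]:
    """Per library: fraction of antisense-sRNA-bearing genes that also bear sense sRNAs.

    Restricted to ``gene_ids`` when given, else over all mapped genes.
    Returns 0.0 when no gene bears antisense sRNAs.
    """
    restrict = set(gene_ids) if gene_ids is not None else None
    out: dict[str, float] = {}
    for lib in ("A", "B"):
        sense, anti = _gene_orientation_sets(transcript_asg, table, lib)
        if restrict is not None:
            sense &= restrict
            anti &= restrict
        out[lib] = len(sense & anti) / len(anti) if anti else 0.0
    return out
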