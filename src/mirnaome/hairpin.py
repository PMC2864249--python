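"""Novel-miRNA discovery: candidate windows, folding, hairpin criteria, miRNA*.

Candidate precursors are windows around perfect transcript matches of
unannotated signatures.  Each window is folded with a maximum-weight nested
base-pairing dynamic program (Watson-Crick pairs weight 1, G:U wobble pairs
configurable, minimum hairpin loop length enforced) — a deterministic
stand-in for thermodynamic folding, sufficient to test the plant-miRNA
stem-loop criteria: the mature must sit on one arm of a single stem (not
spanning the terminal loop), be mostly paired against the opposite arm with
a bounded number of unpaired positions and no large asymmetric bulges.  The
miRNA* is the duplex partner of the mature with canonical 2-nt 3' overhangs;
a candidate is accepted as a novel miRNA only when its star sequence was
itself sequenced (present in the signature table).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from numba import njit

from ._seq import revcomp, to_dna, to_rna
from .reads import SignatureTable

DEFAULT_FLANK_SETS: tuple[tuple[int, int], ...] = ((100, 20), (20, 100), (60, 60))

MAX_FOLD_LEN = 400

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3, "U": 3}

# pair weights indexed by (base i, base j): WC pairs get 1, G-U wobble gets w
_WC = ((0, 3), (3, 0), (1, 2), (2, 1))
_WOBBLE = ((2, 3), (3, 2))


@dataclass
class FoldResult:
    """A nested secondary structure: dot-bracket, pair map and pair weight sum."""

    sequence: str            # RNA alphabet
    structure: str           # dot-bracket, same length
    pair_map: np.ndarray     # partner index per position, -1 if unpaired
    score: float

    def partner(self, i: int) -> int:
        return int(self.pair_map[i])


@njit(cache=False)
def _nussinov_dp(w: np.ndarray, min_loop: int) -> np.ndarray:
    n = w.shape[0]
    dp = np.zeros((n, n))
    for span in range(min_loop + 1, n):
        for i in range(n - span):
            j = i + span
            best = dp[i + 1, j]
            for k in range(i + min_loop + 1, j + 1):
                if w[i, k] > 0.0:
                    v = w[i, k] + dp[i + 1, k - 1]
                    if k < j:
                        v += dp[k + 1, j]
                    if v > best:
                        best = v
            dp[i, j] = best
    return dp


def _weight_matrix(idx: np.ndarray, wobble_weight: float) -> np.ndarray:
    n = len(idx)
    table = np.zeros((4, 4))
    for a, b in _WC:
        table[a, b] = 1.0
    for a, b in _WOBBLE:
        table[a, b] = wobble_weight
    return table[idx[:, None], idx[None, :]] * np.ones((n, n))


def fold(sequence: str, min_loop: int = 3, wobble_weight: float = 1.0) -> FoldResult:
    """Maximum-weight nested pairing with deterministic traceback.

    The traceback prefers pairing the 5'-most base with its 3'-most
    admissible partner, recursing left to right, so the structure is a
    deterministic function of the input.  Hairpin loops span at least
    ``min_loop`` unpaired bases.  Sequences up to ``MAX_FOLD_LEN`` nt.
    """
    seq = to_dna(sequence)
    if not seq or any(c not in _BASE_INDEX for c in seq):
        raise ValueError(f"invalid characters in sequence: {sequence!r}")
    if len(seq) > MAX_FOLD_LEN:
        raise ValueError(f"sequence longer than {MAX_FOLD_LEN} nt")
    idx = np.array([_BASE_INDEX[c] for c in seq], dtype=np.int64)
    w = _weight_matrix(idx, wobble_weight)
    dp = _nussinov_dp(w, min_loop)
    n = len(seq)
    pair_map = np.full(n, -1, dtype=np.int64)
    eps = 1e-9
    stack = [(0, n - 1)]
    while stack:
        i, j = stack.pop()
        if j - i <= min_loop:
            continue
        target = dp[i, j]
        paired = False
        for k in range(j, i + min_loop, -1):  # 3'-most admissible partner first
            if w[i, k] > 0.0:
                v = w[i, k] + dp[i + 1, k - 1] + (dp[k + 1, j] if k < j else 0.0)
                if abs(v - target) <= eps:
                    pair_map[i] = k
                    pair_map[k] = i
                    stack.append((i + 1, k - 1))
                    if k < j:
                        stack.append((k + 1, j))
                    paired = True
                    break
        if not paired:
            stack.append((i + 1, j))
    structure = "".join(
        "." if pair_map[i] < 0 else ("(" if pair_map[i] > i else ")") for i in range(n))
    return FoldResult(sequence=to_rna(seq), structure=structure,
                      pair_map=pair_map, score=float(dp[0, n - 1]))


@dataclass(frozen=True)
class Candidate:
    """A precursor window around a perfect transcript match of a signature."""

    mature_seq: str        # DNA
    transcript_id: str
    window_start: int      # 0-based half-open on the (oriented) transcript
    window_end: int
    mature_offset: int     # offset of the mature inside the window sequence
    strand: str            # '+' or '-'
    window_seq: str        # DNA, already reverse-complemented for '-' hits


def _occurrences(needle: str, haystack: str) -> Iterable[int]:
    i = haystack.find(needle)
    while i >= 0:
        yield i
        i = haystack.find(needle, i + 1)


def extract_candidates(
    signatures: Iterable[str],
    transcript_ref: dict[str, str],
    flank_sets: Sequence[tuple[int, int]] = DEFAULT_FLANK_SETS,
) -> list[Candidate]:
    """Candidate windows for every perfect transcript hit of each signature.

    One window per flank configuration (5' flank, 3' flank), clipped at
    transcript ends; reverse-complement hits are evaluated on the
    reverse-complemented window.  Duplicate windows are removed.
    """
    refs = sorted((h.split()[0], seq) for h, seq in transcript_ref.items())
    seen: set[tuple] = set()
    out: list[Candidate] = []
    for sig in signatures:
        sig = to_dna(sig)
        for rid, tseq in refs:
            for strand, needle, ref in (("+", sig, tseq), ("-", revcomp(sig), tseq)):
                for pos in _occurrences(needle, ref):
                    for f5, f3 in flank_sets:
                        # flanks are relative to the mature's own orientation
                        if strand == "+":
                            ws = max(0, pos - f5)
                            we = min(len(ref), pos + len(sig) + f3)
                            wseq = ref[ws:we]
                            moff = pos - ws
                        else:
                            ws = max(0, pos - f3)
                            we = min(len(ref), pos + len(sig) + f5)
                            wseq = revcomp(ref[ws:we])
                            moff = we - (pos + len(sig))
                        key = (sig, rid, ws, we, strand, moff)
                        if key in seen:
                            continue
                        seen.add(key)
                        out.append(Candidate(sig, rid, ws, we, moff, strand, wseq))
    return out


@dataclass
class HairpinVerdict:
    passed: bool
    reason: str            # "ok" or failure code
    mature_arm: str        # "5p", "3p" or ""


def evaluate_hairpin(
    fold_result: FoldResult,
    mature_start: int,
    mature_end: int,
    max_duplex_mm: int = 4,
    max_asym_bulge: int = 2,
    min_paired_frac: float = 0.60,
) -> HairpinVerdict:
    """Plant-miRNA stem-loop criteria on a folded candidate window.

    Passes iff the mature (a) lies on one arm of a single stem — all its
    partners on one side, in antiparallel (strictly decreasing) order, not
    spanning the terminal loop; (b) has at most ``max_duplex_mm`` unpaired
    positions against the opposite arm; (c) shows no asymmetric bulge larger
    than ``max_asym_bulge`` in the mature/star duplex; and (d) has a paired
    fraction of at least ``min_paired_frac``.
    """
    pm = fold_result.pair_map
    mlen = mature_end - mature_start
    if not (0 <= mature_start < mature_end <= len(pm)):
        raise ValueError("mature span outside window")
    paired = [(i, int(pm[i])) for i in range(mature_start, mature_end) if pm[i] >= 0]
    if not paired:
        return HairpinVerdict(False, "unpaired", "")
    partners = [p for _, p in paired]
    if any(mature_start <= p < mature_end for p in partners):
        return HairpinVerdict(False, "spans_loop", "")
    if all(p >= mature_end for p in partners):
        arm = "5p"
    elif all(p < mature_start for p in partners):
        arm = "3p"
    else:
        return HairpinVerdict(False, "spans_loop", "")
    # antiparallel single helix: partners strictly decreasing along the mature
    if any(partners[k + 1] >= partners[k] for k in range(len(partners) - 1)):
        return HairpinVerdict(False, "multi_stem", arm)
    unpaired = mlen - len(paired)
    if unpaired > max_duplex_mm:
        return HairpinVerdict(False, "too_many_mismatches", arm)
    if len(paired) / mlen < min_paired_frac:
        return HairpinVerdict(False, "low_paired_frac", arm)
    for (i1, p1), (i2, p2) in zip(paired, paired[1:]):
        gap_m = i2 - i1 - 1
        gap_s = p1 - p2 - 1
        if abs(gap_m - gap_s) > max_asym_bulge:
            return HairpinVerdict(False, "asym_bulge", arm)
    return HairpinVerdict(True, "ok", arm)


def find_star(fold_result: FoldResult, mature_start: int, mature_end: int) -> tuple[str, int, int]:
    """miRNA* span from the fold: duplex partner with 2-nt 3' overhangs.

    The star pairs the mature minus its 2-nt 3' overhang; the star's own 3'
    end extends 2 nt past the partner of the mature's 5' end.  Unpaired
    mature edge positions are compensated by extending from the outermost
    paired anchors.  Returns (star RNA sequence, start, end) on the window.
    """
    pm = fold_result.pair_map
    core = [i for i in range(mature_start, mature_end - 2) if pm[i] >= 0]
    if not core:
        raise ValueError("mature has no paired positions; no star defined")
    i1, i2 = core[0], core[-1]
    s_start = int(pm[i2]) - ((mature_end - 3) - i2)
    s_end = int(pm[i1]) + (i1 - mature_start) + 3
    s_start = max(0, s_start)
    s_end = min(len(pm), s_end)
    seq = to_dna(fold_result.sequence)[s_start:s_end]
    return to_rna(seq), s_start, s_end


@dataclass
class HairpinCall:
    """One novel-miRNA call (or rejected candidate) for a distinct mature."""

    mature_seq: str        # RNA
    transcript_id: str
    precursor_start: int   # 0-based half-open on the transcript (oriented window)
    precursor_end: int
    strand: str
    fold: FoldResult
    mature_arm: str
    star_seq: str          # RNA, "" when no structural duplex exists
    star_count_a: int
    star_count_b: int
    status: str            # accepted | no_star | bad_structure | minor_arm

    @property
    def accepted(self) -> bool:
        return self.status == "accepted"


def _star_counts(star_dna: str, table: SignatureTable, star_mm: int) -> tuple[int, int]:
    if star_mm == 0:
        return table.get(star_dna)
    ca = cb = 0
    for seq, a, b in table.iter_rows():
        if len(seq) == len(star_dna) and sum(x != y for x, y in zip(seq, star_dna)) <= star_mm:
            ca += a
            cb += b
    return ca, cb


def call_novel(
    candidates: Sequence[Candidate],
    table: SignatureTable,
    min_loop: int = 3,
    wobble_weight: float = 1.0,
    max_duplex_mm: int = 4,
    max_asym_bulge: int = 2,
    min_paired_frac: float = 0.60,
    star_mm: int = 0,
) -> list[HairpinCall]:
    """Fold and judge candidates; accept those whose miRNA* was sequenced.

    One call per distinct mature: among its windows the best-scoring
    structurally valid precursor is kept (acceptance first, then fold
    score).  Rejected matures are reported with status ``bad_structure`` or
    ``no_star``.  Acceptance requires the star sequence present in the
    signature table with count >= 1 in either library (exact match unless
    ``star_mm`` > 0).

    The mature miRNA is the *dominant* arm of the sequenced duplex: a
    structurally valid candidate whose duplex partner accumulates more
    reads than the candidate itself is that partner's star, not a distinct
    novel miRNA, and is reported with status ``minor_arm``.
    """
    per_mature: dict[str, HairpinCall] = {}
    for cand in candidates:
        fr = fold(cand.window_seq, min_loop=min_loop, wobble_weight=wobble_weight)
        m_start = cand.mature_offset
        m_end = m_start + len(cand.mature_seq)
        verdict = evaluate_hairpin(fr, m_start, m_end, max_duplex_mm,
                                   max_asym_bulge, min_paired_frac)
        if not verdict.passed:
            call = HairpinCall(to_rna(cand.mature_seq), cand.transcript_id,
                               cand.window_start, cand.window_end, cand.strand,
                               fr, verdict.mature_arm, "", 0, 0, "bad_structure")
        else:
            star_rna, _, _ = find_star(fr, m_start, m_end)
            ca, cb = _star_counts(to_dna(star_rna), table, star_mm)
            status = "accepted" if ca + cb >= 1 else "no_star"
            call = HairpinCall(to_rna(cand.mature_seq), cand.transcript_id,
                               cand.window_start, cand.window_end, cand.strand,
                               fr, verdict.mature_arm, star_rna, ca, cb, status)
        prev = per_mature.get(call.mature_seq)
        if prev is None or _call_rank(call) > _call_rank(prev):
            per_mature[call.mature_seq] = call
    out = []
    for seq in sorted(per_mature):
        call = per_mature[seq]
        if call.status == "accepted":
            ma, mb = table.get(to_dna(call.mature_seq))
            mc, sc = ma + mb, call.star_count_a + call.star_count_b
            if sc > mc or (sc == mc and call.star_seq < call.mature_seq):
                call.status = "minor_arm"
        out.append(call)
    return out


def _call_rank(call: HairpinCall) -> tuple[int, float]:
    status_rank = {"accepted": 2, "no_star": 1, "bad_structure": 0}[call.status]
    return (status_rank, call.fold.score)


def discover_novel(
    table: SignatureTable,
    candidate_seqs: Iterable[str],
    transcript_ref: dict[str, str],
    flank_sets: Sequence[tuple[int, int]] = DEFAULT_FLANK_SETS,
    **call_params,
) -> list[HairpinCall]:
    """End-to-end novel-miRNA discovery for a set of unannotated signatures."""
    candidates = extract_candidates(candidate_seqs, transcript_ref, flank_sets)
    return call_novel(candidates, table, **call_params)
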