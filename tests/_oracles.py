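"""Independent brute-force oracles used by the test suite.

Each oracle re-derives an expected value by exhaustive enumeration or naive
scanning, written independently of the implementation paths it checks.
"""

from __future__ import annotations

import collections

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}
_PAIRS_WC = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}
_PAIRS_GU = {("G", "T"), ("T", "G")}


def revcomp(s: str) -> str:
    return "".join(_COMP[c] for c in reversed(s))


def enumerate_structures(n: int, min_loop: int):
    """Yield every nested pairing of positions 0..n-1 as a frozenset of (i, j).

    Pure enumeration (exponential); intended for n <= 14.
    """

    def rec(positions: tuple[int, ...]):
        if not positions:
            yield frozenset()
            return
        i, rest = positions[0], positions[1:]
        # i unpaired
        for sub in rec(rest):
            yield sub
        # i paired with an admissible k; nestedness splits the remainder
        for idx, k in enumerate(rest):
            if k - i <= min_loop:
                continue
            inside = rest[:idx]
            outside = rest[idx + 1:]
            for s1 in rec(inside):
                for s2 in rec(outside):
                    yield s1 | s2 | {(i, k)}

    yield from rec(tuple(range(n)))


def max_pairing_score(seq: str, min_loop: int = 3, wobble_weight: float = 1.0) -> float:
    """Maximum total pair weight over all nested structures (brute force)."""
    seq = seq.upper().replace("U", "T")

    def weight(struct) -> float:
        total = 0.0
        for i, j in struct:
            pair = (seq[i], seq[j])
            if pair in _PAIRS_WC:
                total += 1.0
            elif pair in _PAIRS_GU:
                total += wobble_weight
            else:
                return float("-inf")
        return total

    best = 0.0
    for struct in enumerate_structures(len(seq), min_loop):
        w = weight(struct)
        if w > best:
            best = w
    return best


def count_multiset(items) -> dict:
    """Plain dictionary count."""
    out: dict = {}
    for x in items:
        out[x] = out.get(x, 0) + 1
    return out


def naive_transcript_tallies(signatures, transcripts: dict[str, str]):
    """{signature: (set of sense transcript ids, set of antisense ids)} by full scan."""
    out = {}
    for sig in signatures:
        rc = revcomp(sig)
        sense, anti = set(), set()
        for tid, tseq in transcripts.items():
            name = tid.split()[0]
            for start in range(len(tseq) - len(sig) + 1):
                window = tseq[start:start + len(sig)]
                if window == sig:
                    sense.add(name)
                if window == rc:
                    anti.add(name)
        out[sig] = (sense, anti)
    return out


def naive_sliding_distance(a: str, b: str) -> int:
    """Min over offsets of (overlap mismatches + both overhangs), via padding."""
    best = None
    la, lb = len(a), len(b)
    for off in range(-(lb - 1), la):
        cols = 0
        for pos in range(min(0, off), max(la, off + lb)):
            ca = a[pos] if 0 <= pos < la else None
            cb = b[pos - off] if 0 <= pos - off < lb else None
            if ca is None and cb is None:
                continue
            if ca is None or cb is None or ca != cb:
                cols += 1
        overlap = min(la, off + lb) - max(0, off)
        if overlap >= 1:
            best = cols if best is None else min(best, cols)
    return best


def _mirna_site_columns(mirna: str, site: str, gap_top: int | None, gap_bottom: int | None):
    """Alignment columns (mirna char or None, site-3'->5' char or None)."""
    srev = site[::-1]
    cols = []
    i = j = 0
    pos = 0
    total = len(mirna) + (1 if gap_top is not None else 0)
    while pos < total:
        if gap_top is not None and pos == gap_top:
            cols.append((None, srev[j]))
            j += 1
        elif gap_bottom is not None and pos == gap_bottom:
            cols.append((mirna[i], None))
            i += 1
        else:
            cols.append((mirna[i], srev[j]))
            i += 1
            j += 1
        pos += 1
    return cols


def oracle_site_score(mirna: str, site: str) -> float:
    """Best penalty of a miRNA/site duplex: explicit column-wise scoring.

    match 0, G:U 0.5, mismatch 1, bulged base 2; doubled where the governing
    miRNA position (1-based from the 5' end) lies in 2..13.  For a bulged
    site base the governing position is the miRNA base 5' of the bulge
    (clamped to the miRNA).
    """
    mirna = mirna.upper().replace("U", "T")
    site = site.upper().replace("U", "T")
    lm, ls = len(mirna), len(site)
    variants = []
    if ls == lm:
        variants.append(_mirna_site_columns(mirna, site, None, None))
    elif ls == lm + 1:
        for g in range(ls):
            variants.append(_mirna_site_columns(mirna, site, g, None))
    elif ls == lm - 1:
        for g in range(lm):
            variants.append(_mirna_site_columns(mirna, site, None, g))
    else:
        raise ValueError("length difference > 1")
    def doubled(pos0: int) -> float:
        return 2.0 if 1 <= pos0 <= 12 else 1.0

    best = None
    for cols in variants:
        score = 0.0
        consumed = 0  # miRNA bases consumed so far (left to right)
        for mc, sc in cols:
            if mc is None:
                # bulged site base: governed by the miRNA base 5' of the bulge
                gov = min(max(consumed - 1, 0), lm - 1)
                score += 2.0 * doubled(gov)
            elif sc is None:
                score += 2.0 * doubled(consumed)
                consumed += 1
            else:
                rc = _COMP[sc]
                if mc == rc:
                    pen = 0.0
                elif (mc, rc) in (("G", "A"), ("T", "C")):
                    pen = 0.5
                else:
                    pen = 1.0
                score += pen * doubled(consumed)
                consumed += 1
        if best is None or score < best:
            best = score
    return best


def dinucleotide_shuffle(seq: str, rng) -> str:
    """Dinucleotide-preserving shuffle (random Euler walk over 2-mer graph)."""
    edges = collections.defaultdict(list)
    for a, b in zip(seq, seq[1:]):
        edges[a].append(b)
    eds = {k: list(v) for k, v in edges.items()}
    for k in eds:
        rng.shuffle(eds[k])
    stack = [seq[0]]
    path = []
    while stack:
        v = stack[-1]
        if eds.get(v):
            stack.append(eds[v].pop())
        else:
            path.append(stack.pop())
    path.reverse()
    return "".join(path)
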