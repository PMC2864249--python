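"""Signature classification and known-miRNA assignment.

Every signature receives exactly one primary category, applying sequential
exclusion in the order the discovery workflow runs: non-coding RNA classes
(rRNA/tRNA/snRNA/snoRNA) first, then known miRNAs by bounded-mismatch
homology against a miRBase-like mature catalogue, then novel-miRNA
candidates (decided by the hairpin module), then perfect coding-gene matches
in sense or antisense orientation, and finally "other".  Coding matches are
exact substring matches; known-miRNA homology tolerates up to four
mismatches under an ungapped sliding alignment in which unaligned overhang
positions also count as mismatches.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import pandas as pd

from ._seq import revcomp, to_dna, to_rna
from .reads import SignatureTable

NCRNA_CLASSES = ("rRNA", "tRNA", "snRNA", "snoRNA")

CATEGORIES = NCRNA_CLASSES + (
    "known_miRNA", "novel_miRNA", "coding_sense", "coding_antisense", "other",
)


class ReferenceFormatError(ValueError):
    """Reference FASTA lacks the header tokens the matcher needs."""


def _header_id(header: str) -> str:
    return header.split()[0]


def parse_class_tag(header: str) -> str:
    m = re.search(r"class=(\w+)", header)
    if not m or m.group(1) not in NCRNA_CLASSES:
        raise ReferenceFormatError(
            f"ncRNA reference header lacks a class=rRNA|tRNA|snRNA|snoRNA tag: {header!r}")
    return m.group(1)


def match_ncrna(table: SignatureTable, ncrna_ref: dict[str, str],
                both_strands: bool = False) -> dict[str, tuple[str, str]]:
    """Assign ncRNA classes by exact substring match (forward strand by default).

    Returns {signature: (class, reference id)}.  A signature matching more
    than one record keeps the first by class precedence order
    rRNA > tRNA > snRNA > snoRNA, then reference id.
    """
    tagged = sorted(
        ((parse_class_tag(h), _header_id(h), seq) for h, seq in ncrna_ref.items()),
        key=lambda t: (NCRNA_CLASSES.index(t[0]), t[1]),
    )
    out: dict[str, tuple[str, str]] = {}
    for sig in table.sequences:
        rc = revcomp(sig)
        for cls, rid, refseq in tagged:
            if sig in refseq or (both_strands and rc in refseq):
                out[sig] = (cls, rid)
                break
    return out


@dataclass
class TranscriptMatch:
    """Perfect-match transcript hits of one signature, both orientations."""

    sense_ids: list[str] = field(default_factory=list)
    antisense_ids: list[str] = field(default_factory=list)

    @property
    def primary_strand(self) -> str | None:
        # a signature matching both orientations is tallied in both but
        # carries sense as its primary category
        if self.sense_ids:
            return "+"
        if self.antisense_ids:
            return "-"
        return None


def match_transcripts(table: SignatureTable,
                      transcript_ref: dict[str, str]) -> dict[str, TranscriptMatch]:
    """Perfect substring matches of signatures against transcripts, both strands.

    Sense: the signature occurs in the transcript; antisense: its reverse
    complement does (i.e. the signature matches the reverse-complement
    strand).  Returns a record for every signature with at least one hit.
    """
    refs = sorted((_header_id(h), seq) for h, seq in transcript_ref.items())
    out: dict[str, TranscriptMatch] = {}
    for sig in table.sequences:
        rc = revcomp(sig)
        tm = TranscriptMatch()
        for rid, refseq in refs:
            if sig in refseq:
                tm.sense_ids.append(rid)
            if rc in refseq:
                tm.antisense_ids.append(rid)
        if tm.sense_ids or tm.antisense_ids:
            out[sig] = tm
    return out


def sliding_distance(a: str, b: str) -> int:
    """Ungapped min-over-offsets distance; overhangs count as mismatches.

    For each relative offset with at least one aligned position, the
    distance is (mismatches within the overlap) + (unaligned positions of
    either sequence); the reported value is the minimum over offsets.
    """
    la, lb = len(a), len(b)
    best = la + lb
    for off in range(-(lb - 1), la):
        overlap = 0
        mm = 0
        for j in range(lb):
            i = off + j
            if 0 <= i < la:
                overlap += 1
                if a[i] != b[j]:
                    mm += 1
        if overlap:
            d = mm + (la - overlap) + (lb - overlap)
            if d < best:
                best = d
    return best


def mirna_family(ref_id: str) -> str:
    """Family token (e.g. miR156) from a miRBase-style id like ath-miR156a."""
    m = re.search(r"(miR\d+)", ref_id, flags=re.IGNORECASE)
    return m.group(1) if m else ref_id


def match_known_mirnas(table: SignatureTable, mature_ref: dict[str, str],
                       max_mm: int = 4) -> dict[str, tuple[str, int, str]]:
    """Assign signatures to known miRNAs within ``max_mm`` mismatches.

    Returns {signature: (reference id, mismatches, family)}.  Ties are
    broken by fewest mismatches, then lexicographically smallest reference
    id, so the assignment is stable under reference reordering.
    """
    refs = sorted((_header_id(h), to_dna(seq)) for h, seq in mature_ref.items())
    out: dict[str, tuple[str, int, str]] = {}
    for sig in table.sequences:
        best: tuple[int, str] | None = None
        for rid, refseq in refs:
            d = sliding_distance(sig, refseq)
            if d <= max_mm and (best is None or (d, rid) < best):
                best = (d, rid)
        if best is not None:
            out[sig] = (best[1], best[0], mirna_family(best[1]))
    return out


def categorize(
    table: SignatureTable,
    ncrna_asg: dict[str, tuple[str, str]],
    known_asg: dict[str, tuple[str, int, str]],
    transcript_asg: dict[str, TranscriptMatch],
    novel_matures: set[str] | frozenset[str] = frozenset(),
) -> pd.DataFrame:
    """One AnnotationRecord per signature, applying category precedence.

    Precedence: ncRNA class > known miRNA > novel miRNA > coding sense >
    coding antisense > other.  Returns a DataFrame with columns
    sequence (RNA), category, hit_id, mismatches, strand, count_a, count_b.
    """
    novel_dna = {to_dna(s) for s in novel_matures}
    rows = []
    for seq, ca, cb in table.iter_rows():
        hit_id, mm, strand = "", 0, ""
        if seq in ncrna_asg:
            category, hit_id = ncrna_asg[seq]
        elif seq in known_asg:
            category = "known_miRNA"
            hit_id, mm, _fam = known_asg[seq]
        elif seq in novel_dna:
            category = "novel_miRNA"
        elif seq in transcript_asg:
            tm = transcript_asg[seq]
            strand = tm.primary_strand or ""
            category = "coding_sense" if strand == "+" else "coding_antisense"
            hit_id = (tm.sense_ids or tm.antisense_ids)[0]
        else:
            category = "other"
        rows.append((to_rna(seq), category, hit_id, mm, strand, ca, cb))
    return pd.DataFrame(
        rows, columns=["sequence", "category", "hit_id", "mismatches",
                       "strand", "count_a", "count_b"])


def mean_frequency(total: float, distinct: int) -> float:
    """Mean frequency of a category: total signatures / distinct signatures."""
    if distinct == 0:
        return 0.0
    return total / distinct


def category_summary(records: pd.DataFrame) -> pd.DataFrame:
    """Per-category, per-library summary: distinct, total, mean frequency.

    A signature is distinct in a library iff its count there is positive.
    Percentages are of the per-library column totals.  A ``total`` row
    closes the table; mean frequency = total/distinct is an exact identity
    on the unrounded columns.
    """
    rows = []
    for cat in CATEGORIES:
        sub = records[records["category"] == cat]
        da = int((sub["count_a"] > 0).sum())
        db = int((sub["count_b"] > 0).sum())
        ta = int(sub.loc[sub["count_a"] > 0, "count_a"].sum())
        tb = int(sub.loc[sub["count_b"] > 0, "count_b"].sum())
        rows.append((cat, da, db, ta, tb, mean_frequency(ta, da), mean_frequency(tb, db)))
    df = pd.DataFrame(rows, columns=["category", "distinct_a", "distinct_b",
                                     "total_a", "total_b", "mean_freq_a", "mean_freq_b"])
    totals = df[["distinct_a", "distinct_b", "total_a", "total_b"]].sum()
    for col in ("distinct_a", "distinct_b", "total_a", "total_b"):
        denom = totals[col] or 1
        df[f"pct_{col}"] = 100.0 * df[col] / denom
    total_row = {"category": "total", **{c: int(totals[c]) for c in totals.index},
                 "mean_freq_a": mean_frequency(totals["total_a"], totals["distinct_a"]),
                 "mean_freq_b": mean_frequency(totals["total_b"], totals["distinct_b"]),
                 **{f"pct_{c}": 100.0 for c in totals.index}}
    return pd.concat([df, pd.DataFrame([total_row])], ignore_index=True)
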