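"""Raw-read processing: adapter trimming, collapsing and filtering.

Small-RNA reads carry the insert flanked by ligation adapters.  An insert is
extracted only when both adapter anchors are found — the last 7 nt of the
5' adapter and the first 7 nt of the 3' adapter — and the insert is the
substring strictly between them.  Retained inserts are collapsed into unique
*signatures* with per-library counts; signatures shorter than ``min_len``,
longer than ``max_len``, containing ambiguous characters, or seen fewer than
``min_count`` times in both libraries are discarded.  The resulting
:class:`SignatureTable` (sequences, per-library counts, library totals) is
the central currency of the downstream pipeline: the library totals are the
denominators of TPM normalization and of the two-proportion z test.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd
from Bio import SeqIO

from ._seq import is_unambiguous, to_dna, to_rna

ANCHOR_LEN = 7

#: trim_read rejection reason codes
REJECT_EMPTY = "empty"
REJECT_NO_5P = "no_5p_anchor"
REJECT_NO_3P = "no_3p_anchor"
REJECT_NO_INSERT = "no_insert"


def trim_read(read: str, adapter_5p: str, adapter_3p: str) -> tuple[str | None, str]:
    """Extract the insert between the two adapter anchors.

    The 5' anchor is the last ``ANCHOR_LEN`` nt of ``adapter_5p`` and the 3'
    anchor the first ``ANCHOR_LEN`` nt of ``adapter_3p``.  The first
    occurrence of the 5' anchor is located, then the first occurrence of the
    3' anchor after it; the insert is the substring strictly between them.

    Returns ``(insert, "ok")`` on success, else ``(None, reason)`` with
    ``reason`` one of ``empty``, ``no_5p_anchor``, ``no_3p_anchor``,
    ``no_insert``.

    Raises ``ValueError`` if either adapter is shorter than the anchor.
    """
    if len(adapter_5p) < ANCHOR_LEN or len(adapter_3p) < ANCHOR_LEN:
        raise ValueError(f"adapters must be at least {ANCHOR_LEN} nt")
    if not read:
        return None, REJECT_EMPTY
    read = to_dna(read)
    anchor5 = to_dna(adapter_5p)[-ANCHOR_LEN:]
    anchor3 = to_dna(adapter_3p)[:ANCHOR_LEN]
    i = read.find(anchor5)
    if i < 0:
        return None, REJECT_NO_5P
    start = i + ANCHOR_LEN
    j = read.find(anchor3, start)
    if j < 0:
        return None, REJECT_NO_3P
    if j == start:
        return None, REJECT_NO_INSERT
    return read[start:j], "ok"


def trim_reads(reads: Iterable[str], adapter_5p: str, adapter_3p: str) -> tuple[list[str], Counter]:
    """Trim a batch of reads; returns (inserts, Counter of rejection reasons)."""
    inserts: list[str] = []
    reasons: Counter = Counter()
    for read in reads:
        insert, status = trim_read(read, adapter_5p, adapter_3p)
        if insert is None:
            reasons[status] += 1
        else:
            inserts.append(insert)
    return inserts, reasons


@dataclass
class SignatureTable:
    """Collapsed unique small-RNA signatures with per-library counts.

    ``counts`` is indexed by DNA sequence with integer columns ``count_a``
    and ``count_b``; ``library_size_a/b`` are the retained read totals
    (recomputed after all filters), used as N1/N2 downstream.
    """

    counts: pd.DataFrame
    library_size_a: int
    library_size_b: int

    def __len__(self) -> int:
        return len(self.counts)

    def __contains__(self, seq: str) -> bool:
        return to_dna(seq) in self.counts.index

    def get(self, seq: str) -> tuple[int, int]:
        """Counts (count_a, count_b) for a sequence, (0, 0) if absent."""
        key = to_dna(seq)
        if key not in self.counts.index:
            return 0, 0
        row = self.counts.loc[key]
        return int(row["count_a"]), int(row["count_b"])

    @property
    def sequences(self) -> list[str]:
        """All signature sequences (DNA alphabet)."""
        return list(self.counts.index)

    def iter_rows(self) -> Iterator[tuple[str, int, int]]:
        for seq, ca, cb in self.counts.itertuples():
            yield seq, int(ca), int(cb)

    def to_tsv(self, path: str | Path) -> None:
        """Write as TSV with RNA-alphabet sequences."""
        out = self.counts.copy()
        out.index = [to_rna(s) for s in out.index]
        out.index.name = "sequence"
        with open(path, "w") as fh:
            fh.write(f"# library_size_a={self.library_size_a}\tlibrary_size_b={self.library_size_b}\n")
            out.to_csv(fh, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SignatureTable":
        with open(path) as fh:
            header = fh.readline()
            parts = dict(p.split("=") for p in header.lstrip("# ").split())
            df = pd.read_csv(fh, sep="\t", index_col="sequence")
        df.index = [to_dna(s) for s in df.index]
        return cls(df, int(parts["library_size_a"]), int(parts["library_size_b"]))


def collapse_and_filter(
    inserts_a: Iterable[str],
    inserts_b: Iterable[str],
    min_len: int = 18,
    max_len: int = 30,
    min_count: int = 3,
) -> SignatureTable:
    """Collapse inserts into a filtered signature table.

    Sequences with ambiguous characters are dropped; lengths outside
    ``[min_len, max_len]`` are dropped; a signature is kept iff its count in
    at least one library reaches ``min_count``.  Library sizes are the sums
    of retained counts.  An empty result is a valid (empty) table.
    """
    ca = Counter(to_dna(s) for s in inserts_a)
    cb = Counter(to_dna(s) for s in inserts_b)
    rows = []
    for seq in sorted(set(ca) | set(cb)):
        if not is_unambiguous(seq) or not (min_len <= len(seq) <= max_len):
            continue
        na, nb = ca.get(seq, 0), cb.get(seq, 0)
        if max(na, nb) >= min_count:
            rows.append((seq, na, nb))
    df = pd.DataFrame(rows, columns=["sequence", "count_a", "count_b"]).set_index("sequence")
    return SignatureTable(df, int(df["count_a"].sum()), int(df["count_b"].sum()))


def length_histogram(table: SignatureTable, min_len: int = 18, max_len: int = 30) -> pd.DataFrame:
    """Normalized length distributions by unique signatures and by total reads.

    Returns a DataFrame indexed by length with columns ``unique`` and
    ``reads``, each summing to 1.  Raises ``ValueError`` on an empty table.
    """
    if len(table) == 0:
        raise ValueError("length_histogram requires a non-empty table")
    lengths = table.counts.index.str.len()
    reads_w = table.counts["count_a"] + table.counts["count_b"]
    uniq = pd.Series(1, index=lengths).groupby(level=0).sum()
    reads = pd.Series(reads_w.to_numpy(), index=lengths).groupby(level=0).sum()
    idx = range(min_len, max_len + 1)
    out = pd.DataFrame(
        {
            "unique": uniq.reindex(idx, fill_value=0) / uniq.sum(),
            "reads": reads.reindex(idx, fill_value=0) / reads.sum(),
        },
        index=pd.Index(idx, name="length"),
    )
    return out


def read_fastq(path: str | Path) -> list[str]:
    """Read sequences from a FASTQ file (Phred+33)."""
    return [str(rec.seq) for rec in SeqIO.parse(str(path), "fastq")]


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into {id: DNA sequence}, keeping description tokens.

    The returned keys are the full description lines (id plus any
    ``key=value`` tokens used by the annotation module).
    """
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        out[rec.description] = to_dna(str(rec.seq))
    return out


def process_libraries(
    fastq_a: str | Path,
    fastq_b: str | Path,
    adapter_5p: str,
    adapter_3p: str,
    min_len: int = 18,
    max_len: int = 30,
    min_count: int = 3,
) -> tuple[SignatureTable, dict]:
    """FASTQ pair -> SignatureTable, with per-stage count logging info."""
    reads_a = read_fastq(fastq_a)
    reads_b = read_fastq(fastq_b)
    inserts_a, rej_a = trim_reads(reads_a, adapter_5p, adapter_3p)
    inserts_b, rej_b = trim_reads(reads_b, adapter_5p, adapter_3p)
    table = collapse_and_filter(inserts_a, inserts_b, min_len, max_len, min_count)
    stats = {
        "raw_reads_a": len(reads_a),
        "raw_reads_b": len(reads_b),
        "trimmed_a": len(inserts_a),
        "trimmed_b": len(inserts_b),
        "rejected_a": dict(rej_a),
        "rejected_b": dict(rej_b),
        "signatures": len(table),
        "retained_reads_a": table.library_size_a,
        "retained_reads_b": table.library_size_b,
    }
    return table, stats
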