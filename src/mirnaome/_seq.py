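"""Tiny sequence-alphabet helpers shared across modules.

Internal alphabet is DNA (A/C/G/T); user-facing reports emit RNA (U),
following the miRBase convention for mature miRNA sequences.
"""

from __future__ import annotations

_DNA_COMP = str.maketrans("ACGT", "TGCA")

DNA_ALPHABET = frozenset("ACGT")


def to_dna(seq: str) -> str:
    """Uppercase and normalize U->T. Does not validate."""
    return seq.upper().replace("U", "T")


def to_rna(seq: str) -> str:
    """Uppercase and normalize T->U."""
    return seq.upper().replace("T", "U")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string."""
    return seq.translate(_DNA_COMP)[::-1]


def is_unambiguous(seq: str) -> bool:
    """True iff every character is a plain A/C/G/T after U->T normalization."""
    return bool(seq) and set(seq) <= DNA_ALPHABET
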