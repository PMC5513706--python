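"""Low-level DNA/IUPAC helpers shared across modules.

Sequences are plain Python strings over the uppercase DNA alphabet; degenerate
primer positions use IUPAC one-letter codes. Hot loops encode sequences as
``numpy`` byte arrays so that window comparisons vectorise.
"""

from __future__ import annotations

import numpy as np
from Bio.Seq import Seq

#: IUPAC nucleotide codes mapped to the set of concrete bases each allows.
IUPAC_CODES: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("GC"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

DNA_BASES = "ACGT"


def is_dna(seq: str) -> bool:
    """True if *seq* is a nonempty string over {A,C,G,T}."""
    return len(seq) > 0 and all(c in "ACGT" for c in seq)


def is_iupac(seq: str) -> bool:
    """True if *seq* is a nonempty string of IUPAC nucleotide codes."""
    return len(seq) > 0 and all(c in IUPAC_CODES for c in seq)


def revcomp(seq: str) -> str:
    """Reverse complement (IUPAC-aware, via Biopython)."""
    return str(Seq(seq).reverse_complement())


def encode(seq: str) -> np.ndarray:
    """Encode a sequence as a uint8 array of ASCII codes."""
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def pattern_table(pattern: str) -> np.ndarray:
    """Boolean lookup table for an IUPAC pattern.

    Returns an ``(len(pattern), 256)`` boolean array where entry ``[i, b]`` is
    True iff ASCII byte ``b`` is a concrete base allowed at pattern position
    ``i``. Used for vectorised sliding-window mismatch counting.
    """
    if not is_iupac(pattern):
        raise ValueError(f"not an IUPAC DNA pattern: {pattern!r}")
    table = np.zeros((len(pattern), 256), dtype=bool)
    for i, code in enumerate(pattern):
        for base in IUPAC_CODES[code]:
            table[i, ord(base)] = True
    return table


def sliding_mismatches(table: np.ndarray, text: np.ndarray) -> np.ndarray:
    """Mismatch count of an IUPAC pattern at every placement in *text*.

    *table* is a :func:`pattern_table`; *text* an :func:`encode`-d sequence.
    Returns an int array of length ``len(text) - L + 1`` (empty if the text is
    shorter than the pattern).
    """
    L = table.shape[0]
    if text.size < L:
        return np.zeros(0, dtype=np.intp)
    windows = np.lib.stride_tricks.sliding_window_view(text, L)
    ok = table[np.arange(L)[None, :], windows]
    return L - ok.sum(axis=1)


def hamming(a: str, b: str) -> int:
    """Hamming distance between equal-length sequences."""
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal lengths")
    return sum(x != y for x, y in zip(a, b))
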