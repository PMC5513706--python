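"""Spacer recovery from repeat-anchored amplicon reads.

Each sequencing read of the short (single-spacer) amplicon carries the layout

    5'-tail .. forward repeat anchor .. SPACER .. reverse repeat anchor .. filler

where the anchors are the repeat-derived primer-binding sequences of one
CRISPR array class. Extraction locates both anchors with a bounded number of
mismatches (substitutions only — the anchors are short primer-derived
sequences), reports the intervening spacer, and preserves the strand on which
the layout was found. Dereplication then collapses the extracted spacers into
unique sequences with observation counts, greedily absorbing near-identical
(equal-length, small-Hamming-distance) variants attributable to sequencing
error into their more abundant neighbours.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from ._seq import (
    IUPAC_CODES,
    encode,
    is_dna,
    is_iupac,
    pattern_table,
    revcomp,
    sliding_mismatches,
)

__all__ = [
    "ArrayDefinition",
    "SpacerRecord",
    "SpacerPool",
    "PLATENSIS_IIID",
    "PLATENSIS_IIIB",
    "iupac_mismatches",
    "extract_spacer",
    "dereplicate",
    "extract_pool",
    "rank_key",
]


@dataclass(frozen=True)
class ArrayDefinition:
    """Anchor sequences and tolerances for one CRISPR array class.

    ``forward_anchor`` and ``reverse_anchor`` are written in read orientation:
    a plus-strand read contains ``forward_anchor + spacer + reverse_anchor``.
    Both may contain IUPAC degeneracy codes (the real repeat-derived primers
    do).
    """

    array_class: str
    forward_anchor: str
    reverse_anchor: str
    max_anchor_mismatches: int = 2
    spacer_len_bounds: tuple[int, int] = (25, 60)

    def __post_init__(self) -> None:
        for name in ("forward_anchor", "reverse_anchor"):
            anchor = getattr(self, name)
            if not is_iupac(anchor):
                raise ValueError(f"{name} must be a nonempty IUPAC DNA string")
        if self.max_anchor_mismatches < 0:
            raise ValueError("max_anchor_mismatches must be >= 0")
        lo, hi = self.spacer_len_bounds
        if not (0 < lo <= hi):
            raise ValueError("spacer_len_bounds must satisfy 0 < min <= max")

    @property
    def min_read_length(self) -> int:
        return (
            len(self.forward_anchor)
            + self.spacer_len_bounds[0]
            + len(self.reverse_anchor)
        )


# Repeat-matching regions of the published A. platensis spacer-sequencing
# primers (type III-D pair SS-4F/SS-4R, type III-B pair SS-19F/SS-19R); the
# reverse anchor is the reverse complement of the reverse primer's
# repeat-matching region, i.e. the sequence as it appears in a forward read.
PLATENSIS_IIID = ArrayDefinition(
    array_class="IIID",
    forward_anchor="CTTGCGGGGAATTGGTAGGG",
    reverse_anchor=revcomp("AATTCCCCGCAAGGGGACGG"),
)
PLATENSIS_IIIB = ArrayDefinition(
    array_class="IIIB",
    forward_anchor="TAACTTTCARAGAAGTYTAA",
    reverse_anchor=revcomp("TGAAAGTTAAACGTATGGAA"),
)


@dataclass
class SpacerRecord:
    """One dereplicated spacer: a unique sequence with its observation count."""

    sequence: str
    count: int
    array_class: str = ""
    strand: str = "+"
    sample_id: str = ""


@dataclass
class SpacerPool:
    """Dereplicated spacers from one sample and array class, with totals."""

    sample_id: str
    array_class: str
    records: list[SpacerRecord] = field(default_factory=list)
    total_reads_in: int = 0
    reads_extracted: int = 0

    def __post_init__(self) -> None:
        seqs = [r.sequence for r in self.records]
        if len(set(seqs)) != len(seqs):
            raise ValueError("pool records must have pairwise distinct sequences")

    @property
    def reads_rejected(self) -> int:
        return self.total_reads_in - self.reads_extracted

    @property
    def n_unique(self) -> int:
        return len(self.records)

    def counts(self) -> np.ndarray:
        return np.array([r.count for r in self.records], dtype=np.int64)

    def ranked_records(self) -> list[SpacerRecord]:
        """Records in abundance rank order (count desc, longer, lexicographic)."""
        return sorted(self.records, key=rank_key)


def rank_key(record: SpacerRecord) -> tuple:
    """Total order used everywhere a frequency ranking is needed.

    Higher count first; ties broken by longer sequence, then lexicographically
    — the ranking itself is the method's, the tie-break is ours, chosen so
    that every downstream greedy pass is deterministic.
    """
    return (-record.count, -len(record.sequence), record.sequence)


def iupac_mismatches(pattern: str, text: str) -> int:
    """Number of positions of *text* not covered by the IUPAC *pattern*.

    Both arguments must have equal length; *pattern* may contain degeneracy
    codes, *text* must be concrete DNA.
    """
    if len(pattern) != len(text):
        raise ValueError("pattern and text must have equal length")
    if not is_iupac(pattern):
        raise ValueError("pattern is not IUPAC DNA")
    if not is_dna(text):
        raise ValueError("text is not concrete DNA")
    return sum(t not in IUPAC_CODES[p] for p, t in zip(pattern, text))


class _AnchorScanner:
    """Cached pattern tables for one array definition (vectorised scans)."""

    def __init__(self, array_def: ArrayDefinition) -> None:
        self.array_def = array_def
        self.fwd_table = pattern_table(array_def.forward_anchor)
        self.rev_table = pattern_table(array_def.reverse_anchor)

    def best_placement(
        self, table: np.ndarray, text: np.ndarray, start: int = 0
    ) -> tuple[int, int] | None:
        """Leftmost minimal-mismatch placement of the anchor at or after *start*.

        Returns ``(position, mismatches)`` or None if no placement fits within
        the allowed mismatch budget.
        """
        mm = sliding_mismatches(table, text[start:])
        if mm.size == 0:
            return None
        best = int(mm.argmin())  # argmin is leftmost on ties
        if mm[best] > self.array_def.max_anchor_mismatches:
            return None
        return start + best, int(mm[best])


def _scan_one_strand(
    scanner: _AnchorScanner, seq: str, arr: np.ndarray
) -> str | None:
    adef = scanner.array_def
    fwd = scanner.best_placement(scanner.fwd_table, arr)
    if fwd is None:
        return None
    fpos, _ = fwd
    spacer_start = fpos + len(adef.forward_anchor)
    rev = scanner.best_placement(scanner.rev_table, arr, start=spacer_start)
    if rev is None:
        return None
    rpos, _ = rev
    spacer = seq[spacer_start:rpos]
    lo, hi = adef.spacer_len_bounds
    if not (lo <= len(spacer) <= hi):
        return None
    return spacer


def extract_spacer(
    read: str, array_def: ArrayDefinition, _scanner: _AnchorScanner | None = None
) -> tuple[str, str] | None:
    """Locate the anchor-flanked spacer in one read.

    The read and its reverse complement are scanned for the best (fewest
    mismatches, leftmost on ties) forward-anchor placement followed downstream
    by the best reverse-anchor placement, each within the array's mismatch
    budget. Returns ``(spacer, strand)`` with the spacer in array orientation,
    or None if no acceptable layout is found (the read is then tallied as
    rejected by :func:`extract_pool`).
    """
    if not is_dna(read):
        return None
    if len(read) < array_def.min_read_length:
        return None
    scanner = _scanner or _AnchorScanner(array_def)
    spacer = _scan_one_strand(scanner, read, encode(read))
    if spacer is not None:
        return spacer, "+"
    rc = revcomp(read)
    spacer = _scan_one_strand(scanner, rc, encode(rc))
    if spacer is not None:
        return spacer, "-"
    return None


def _segment_slices(length: int, n_segments: int) -> list[slice]:
    bounds = np.linspace(0, length, n_segments + 1).astype(int)
    return [slice(int(a), int(b)) for a, b in zip(bounds[:-1], bounds[1:])]


def dereplicate(
    raw_spacers: list[str] | list[tuple[str, str]],
    merge_mismatches: int = 1,
    sample_id: str = "",
    array_class: str = "",
    total_reads_in: int | None = None,
) -> SpacerPool:
    """Collapse raw spacer observations into a counted pool of unique sequences.

    Exact duplicates are counted first. The unique sequences are then ranked
    by abundance and swept greedily: a sequence within Hamming distance
    ``merge_mismatches`` (equal lengths only) of a higher-ranked retained
    sequence is absorbed into the highest-ranked such neighbour — the standard
    correction for point sequencing errors, which produce low-count satellites
    one or two substitutions away from a real spacer. Length variants are left
    alone here; end-trimming artifacts are the clustering module's job.

    *raw_spacers* items are sequences or ``(sequence, strand)`` pairs; the
    recorded strand of a unique sequence is its majority strand.
    """
    if merge_mismatches < 0:
        raise ValueError("merge_mismatches must be >= 0")

    counts: dict[str, int] = {}
    plus: dict[str, int] = {}
    n_obs = 0
    for item in raw_spacers:
        seq, strand = item if isinstance(item, tuple) else (item, "+")
        counts[seq] = counts.get(seq, 0) + 1
        plus[seq] = plus.get(seq, 0) + (1 if strand == "+" else 0)
        n_obs += 1

    records = [
        SpacerRecord(
            sequence=s,
            count=c,
            array_class=array_class,
            strand="+" if 2 * plus[s] >= c else "-",
            sample_id=sample_id,
        )
        for s, c in counts.items()
    ]
    records.sort(key=rank_key)

    # Pigeonhole index over merge_mismatches+1 segments: equal-length sequences
    # within Hamming distance m agree exactly on at least one segment.
    n_seg = merge_mismatches + 1
    index: dict[tuple[int, int, str], list[int]] = {}
    slices_cache: dict[int, list[slice]] = {}
    retained: list[SpacerRecord] = []

    for rec in records:
        L = len(rec.sequence)
        if L not in slices_cache:
            slices_cache[L] = _segment_slices(L, n_seg)
        slices = slices_cache[L]
        best: int | None = None
        if merge_mismatches > 0:
            seen: set[int] = set()
            for si, sl in enumerate(slices):
                key = (L, si, rec.sequence[sl])
                for ridx in index.get(key, ()):
                    if ridx in seen:
                        continue
                    seen.add(ridx)
                    parent = retained[ridx]
                    d = sum(
                        a != b for a, b in zip(parent.sequence, rec.sequence)
                    )
                    if d <= merge_mismatches and (best is None or ridx < best):
                        best = ridx
        if best is not None:
            retained[best].count += rec.count
        else:
            ridx = len(retained)
            retained.append(rec)
            for si, sl in enumerate(slices):
                index.setdefault((L, si, rec.sequence[sl]), []).append(ridx)

    retained.sort(key=rank_key)
    return SpacerPool(
        sample_id=sample_id,
        array_class=array_class,
        records=retained,
        total_reads_in=n_obs if total_reads_in is None else total_reads_in,
        reads_extracted=n_obs,
    )


def extract_pool(
    reads: list[str],
    array_def: ArrayDefinition,
    merge_mismatches: int = 1,
    sample_id: str = "",
) -> SpacerPool:
    """Full per-sample extraction: anchor-trim every read, then dereplicate.

    Unextractable reads are tallied; the returned pool satisfies
    ``reads_extracted + reads_rejected == total_reads_in``.
    """
    scanner = _AnchorScanner(array_def)
    hits: list[tuple[str, str]] = []
    for read in reads:
        res = extract_spacer(read, array_def, _scanner=scanner)
        if res is not None:
            hits.append(res)
    return dereplicate(
        hits,
        merge_mismatches=merge_mismatches,
        sample_id=sample_id,
        array_class=array_def.array_class,
        total_reads_in=len(reads),
    )
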