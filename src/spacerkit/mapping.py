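"""Protospacer search: greedy spacer assembly, reference mapping, and the
expected-random-match baseline.

Spacers sampled from the same source molecule can overlap; greedily merging
exact suffix–prefix overlaps yields longer query contigs and thereby more
statistical power per search. Mapping places spacers (or contigs) on both
strands of reference sequences with a bounded number of substitutions,
excluding hits inside annotated regions (native CRISPR arrays). The analytic
baseline gives the number of matches expected by chance alone on an iid
uniform-base genome, the yardstick against which observed hit counts are
judged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO
from scipy.stats import binom

from ._seq import encode, is_dna, revcomp

__all__ = [
    "Contig",
    "MatchHit",
    "greedy_assemble",
    "map_spacers",
    "expected_random_matches",
    "read_bed",
]


@dataclass
class Contig:
    """A merged run of overlapping spacers (or a singleton)."""

    sequence: str
    member_spacers: list[str] = field(default_factory=list)
    overlaps: list[int] = field(default_factory=list)


@dataclass(frozen=True)
class MatchHit:
    """One placement of a query on a reference (0-based half-open, forward
    strand coordinates; strand records the query orientation)."""

    spacer: str
    reference_id: str
    start: int
    end: int
    strand: str
    mismatches: int


def _suffix_prefix_overlap(a: str, b: str, min_overlap: int) -> int:
    """Longest k >= min_overlap with a's suffix equal to b's prefix (0 if none)."""
    for k in range(min(len(a), len(b)), min_overlap - 1, -1):
        if a.endswith(b[:k]):
            return k
    return 0


def greedy_assemble(spacers: list[str], min_overlap: int = 15) -> list[Contig]:
    """Merge spacers by their longest exact suffix–prefix overlaps.

    Repeatedly joins the contig pair (same orientation) with the longest
    exact overlap of at least *min_overlap* nt, ties broken by the pair's
    position in the current contig list, until no join remains. Merging is
    exact-match only — a mismatch-tolerant merge could chain unrelated
    spacers into chimeric contigs. Unmerged spacers come back as singleton
    contigs; every input spacer appears as an exact substring of its contig.
    """
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    for s in spacers:
        if not is_dna(s):
            raise ValueError(f"not a DNA sequence: {s!r}")
    contigs = [Contig(sequence=s, member_spacers=[s]) for s in spacers]
    while len(contigs) > 1:
        best_k, best_pair = 0, None
        for i, ca in enumerate(contigs):
            for j, cb in enumerate(contigs):
                if i == j:
                    continue
                k = _suffix_prefix_overlap(ca.sequence, cb.sequence, min_overlap)
                if k > best_k:
                    best_k, best_pair = k, (i, j)
        if best_pair is None:
            break
        i, j = best_pair
        ca, cb = contigs[i], contigs[j]
        merged = Contig(
            sequence=ca.sequence + cb.sequence[best_k:],
            member_spacers=ca.member_spacers + cb.member_spacers,
            overlaps=ca.overlaps + [best_k] + cb.overlaps,
        )
        contigs = [c for idx, c in enumerate(contigs) if idx not in (i, j)]
        contigs.append(merged)
    return contigs


def read_bed(path: str | Path) -> dict[str, list[tuple[int, int]]]:
    """Minimal 3+-column BED reader: 0-based half-open exclusion intervals."""
    out: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            chrom, start, end = line.split("\t")[:3]
            out.setdefault(chrom, []).append((int(start), int(end)))
    return out


def _load_references(reference) -> dict[str, str]:
    if isinstance(reference, dict):
        refs = dict(reference)
    elif isinstance(reference, (str, Path)):
        refs = {
            rec.id: str(rec.seq).upper()
            for rec in SeqIO.parse(str(reference), "fasta")
        }
        if not refs:
            raise ValueError(f"no FASTA records in {reference}")
    else:
        refs = {rec.id: str(rec.seq).upper() for rec in reference}
    for rid, seq in refs.items():
        if not is_dna(seq):
            raise ValueError(f"reference {rid!r} contains non-ACGT characters")
    return refs


def map_spacers(
    queries: list[str],
    reference,
    max_mismatches: int = 0,
    exclude_regions: dict[str, list[tuple[int, int]]] | None = None,
) -> list[MatchHit]:
    """Every placement of every query on either reference strand within the
    mismatch budget, minus placements intersecting excluded intervals.

    *reference* may be a FASTA path, a dict of ``{id: sequence}``, or an
    iterable of Biopython SeqRecords. The scan compares each query against
    all reference windows at once (vectorised), which is exhaustive —
    identical in contract to a naive position-by-position comparison.
    Coordinates are 0-based half-open on the forward strand; a '-' hit means
    the reverse complement of the query matches there.
    """
    if max_mismatches < 0:
        raise ValueError("max_mismatches must be >= 0")
    refs = _load_references(reference)
    exclude = exclude_regions or {}
    hits: list[MatchHit] = []
    enc_refs = {rid: encode(seq) for rid, seq in refs.items()}
    for query in queries:
        if not is_dna(query):
            raise ValueError(f"query is not DNA: {query!r}")
        L = len(query)
        for rid, ref_arr in enc_refs.items():
            if ref_arr.size < L:
                continue
            windows = np.lib.stride_tricks.sliding_window_view(ref_arr, L)
            for strand, q in (("+", query), ("-", revcomp(query))):
                mm = (windows != encode(q)[None, :]).sum(axis=1)
                for pos in np.nonzero(mm <= max_mismatches)[0]:
                    start, end = int(pos), int(pos) + L
                    if any(
                        start < e and s < end for s, e in exclude.get(rid, ())
                    ):
                        continue
                    hits.append(
                        MatchHit(
                            spacer=query,
                            reference_id=rid,
                            start=start,
                            end=end,
                            strand=strand,
                            mismatches=int(mm[pos]),
                        )
                    )
    return hits


def expected_random_matches(
    n_queries: int, query_len: int, genome_len: int, max_mismatches: int = 0
) -> float:
    """Expected number of chance placements under an iid uniform-base null.

    Each of the ``genome_len - query_len + 1`` placements on each strand
    matches a random query with probability
    ``sum_{i<=m} C(L, i) (3/4)^i (1/4)^(L-i)``; the expectation is that
    probability times the number of placements, both strands, all queries.
    Linear genomes (no wraparound); the edge effect is kept exact.
    """
    if query_len > genome_len:
        raise ValueError("query_len must not exceed genome_len")
    if max_mismatches < 0 or n_queries < 0:
        raise ValueError("n_queries and max_mismatches must be >= 0")
    m = min(max_mismatches, query_len)
    p_match = float(binom.cdf(m, query_len, 0.75))
    return n_queries * 2.0 * (genome_len - query_len + 1) * p_match
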