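"""Greedy frequency-ranked clustering of dereplicated spacers.

Unique spacers that differ by a handful of point mutations, or by missing
bases at either end, plausibly descend from a single acquisition event. The
clustering sweeps the pool in abundance rank order and absorbs each candidate
into the first (highest-ranked) retained parent that either

* differs at no more than ``max_diff_sites`` positions in the best ungapped
  end-gap-free alignment (overhangs free, overlap at least ``min_overlap``),
  or
* has been observed ``high_freq_threshold`` times or more and shares any
  exact ``kmer_len``-mer with the candidate (same orientation).

Candidates absorbed by neither rule become parents of new clusters. The
sweep is deterministic: the abundance ranking is totally ordered by
(count desc, length desc, sequence), so permuting the input cannot change
the outcome.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from ._seq import encode
from .extraction import SpacerPool, SpacerRecord, rank_key

__all__ = [
    "ClusteringParams",
    "Cluster",
    "ClusterSet",
    "overlap_mismatch",
    "shares_kmer",
    "cluster_spacers",
]

INF = math.inf


@dataclass(frozen=True)
class ClusteringParams:
    """Thresholds of the greedy clustering.

    ``max_diff_sites`` — maximal mismatches in the best end-gap-free overlap
    for two spacers to be merged (default 4). ``min_overlap`` — minimal
    overlap length for that comparison; an unbounded end-deletion rule
    degenerates (any two sequences eventually share a tiny perfect core), so
    roughly half a spacer is required by default. ``kmer_len`` and
    ``high_freq_threshold`` parameterise the conservative second rule: any
    spacer sharing an exact 12-mer with a parent seen 100+ times is treated
    as derived from it.
    """

    max_diff_sites: int = 4
    min_overlap: int = 20
    kmer_len: int = 12
    high_freq_threshold: int = 100

    def __post_init__(self) -> None:
        if self.max_diff_sites < 0:
            raise ValueError("max_diff_sites must be >= 0")
        if self.min_overlap < 1:
            raise ValueError("min_overlap must be >= 1")
        if self.kmer_len < 1:
            raise ValueError("kmer_len must be >= 1")
        if self.high_freq_threshold < 1:
            raise ValueError("high_freq_threshold must be >= 1")


@dataclass
class Cluster:
    parent: SpacerRecord
    members: list[SpacerRecord] = field(default_factory=list)
    rules: list[str] = field(default_factory=list)  # per member: 'sites'|'kmer'

    @property
    def total_count(self) -> int:
        return self.parent.count + sum(m.count for m in self.members)

    @property
    def size(self) -> int:
        return 1 + len(self.members)


@dataclass
class ClusterSet:
    clusters: list[Cluster]
    params: ClusteringParams

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    def parent_sequences(self) -> list[str]:
        return [c.parent.sequence for c in self.clusters]

    def membership(self) -> dict[str, str]:
        """Map every input sequence to its cluster's parent sequence."""
        out: dict[str, str] = {}
        for c in self.clusters:
            out[c.parent.sequence] = c.parent.sequence
            for m in c.members:
                out[m.sequence] = c.parent.sequence
        return out


def overlap_mismatch(
    seq_a: str, seq_b: str, min_overlap: int = 20
) -> tuple[float, int, int]:
    """Best ungapped end-gap-free placement of *seq_b* against *seq_a*.

    Slides *seq_b* over *seq_a* at every relative offset whose overlap is at
    least *min_overlap* (overhanging ends are free, modelling end-trimming
    artifacts) and returns ``(mismatches, overlap_len, offset)`` for the
    placement with the fewest mismatches. Offset is the position of
    ``seq_b[0]`` in *seq_a* coordinates (possibly negative). Ties prefer the
    longer overlap, then the smaller absolute offset, then the positive one.
    If no offset reaches *min_overlap*, ``(inf, 0, 0)`` is returned.
    """
    if not seq_a or not seq_b:
        raise ValueError("sequences must be nonempty")
    la, lb = len(seq_a), len(seq_b)
    a, b = encode(seq_a), encode(seq_b)
    best: tuple[float, int, int] | None = None
    for off in range(-(lb - min_overlap), la - min_overlap + 1):
        start_a = max(0, off)
        end_a = min(la, off + lb)
        ov = end_a - start_a
        if ov < min_overlap:
            continue
        mm = int((a[start_a:end_a] != b[start_a - off : end_a - off]).sum())
        key = (mm, -ov, abs(off), 0 if off >= 0 else 1)
        if best is None or key < best[0]:
            best = (key, ov, off)
    if best is None:
        return INF, 0, 0
    return float(best[0][0]), best[1], best[2]


def _min_overlap_mismatches(
    a: np.ndarray, b: np.ndarray, min_overlap: int, stop_at: int
) -> float:
    """Minimal mismatch count over valid offsets, early-exiting at *stop_at*."""
    la, lb = a.size, b.size
    best = INF
    for off in range(-(lb - min_overlap), la - min_overlap + 1):
        start_a = max(0, off)
        end_a = min(la, off + lb)
        if end_a - start_a < min_overlap:
            continue
        mm = int((a[start_a:end_a] != b[start_a - off : end_a - off]).sum())
        if mm < best:
            best = mm
            if best <= stop_at:
                return best
    return best


def shares_kmer(seq_a: str, seq_b: str, k: int = 12) -> bool:
    """True iff the two sequences share any exact length-*k* substring
    (same orientation — pools are strand-resolved)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if len(seq_a) < k or len(seq_b) < k:
        return False
    kmers = {seq_a[i : i + k] for i in range(len(seq_a) - k + 1)}
    return any(seq_b[i : i + k] in kmers for i in range(len(seq_b) - k + 1))


def cluster_spacers(
    pool: SpacerPool, params: ClusteringParams | None = None
) -> ClusterSet:
    """Greedy abundance-ranked clustering of a dereplicated pool.

    Records are swept in rank order; each candidate is absorbed by the first
    retained parent qualifying under the mismatch-sites rule or, for parents
    at or above the high-frequency threshold, the shared-k-mer rule (an
    inverted k-mer index over high-frequency parents keeps that rule cheap;
    its outcome is identical to the naive scan). The number of clusters is
    the number of parents.
    """
    params = params or ClusteringParams()
    ranked = pool.ranked_records()
    k = params.kmer_len

    parents: list[SpacerRecord] = []
    parent_enc: list[np.ndarray] = []
    clusters: list[Cluster] = []
    # k-mer -> rank of the first (highest-ranked) high-frequency parent
    # containing it; insertion order makes min() over hits the first parent.
    kmer_first_parent: dict[str, int] = {}

    for rec in ranked:
        enc = encode(rec.sequence)
        # earliest high-frequency parent reachable by the k-mer rule
        r_kmer: int | None = None
        if len(rec.sequence) >= k:
            for i in range(len(rec.sequence) - k + 1):
                hit = kmer_first_parent.get(rec.sequence[i : i + k])
                if hit is not None and (r_kmer is None or hit < r_kmer):
                    r_kmer = hit
        limit = len(parents) if r_kmer is None else r_kmer + 1
        assigned = False
        for ridx in range(limit):
            mm = _min_overlap_mismatches(
                parent_enc[ridx], enc, params.min_overlap, params.max_diff_sites
            )
            if mm <= params.max_diff_sites:
                clusters[ridx].members.append(rec)
                clusters[ridx].rules.append("sites")
                assigned = True
                break
        if not assigned and r_kmer is not None:
            clusters[r_kmer].members.append(rec)
            clusters[r_kmer].rules.append("kmer")
            assigned = True
        if not assigned:
            ridx = len(parents)
            parents.append(rec)
            parent_enc.append(enc)
            clusters.append(Cluster(parent=rec))
            if rec.count >= params.high_freq_threshold and len(rec.sequence) >= k:
                for i in range(len(rec.sequence) - k + 1):
                    kmer_first_parent.setdefault(rec.sequence[i : i + k], ridx)

    return ClusterSet(clusters=clusters, params=params)
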