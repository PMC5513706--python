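"""Shared fixtures and independent oracle helpers.

The oracles here are deliberately naive transcriptions of the procedures the
package implements with indexing/vectorisation — brute-force all-pairs and
all-offsets scans over plain Python strings — so that every optimised path
has an independent reference to agree with.
"""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from spacerkit.extraction import SpacerPool, SpacerRecord

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

BASES = "ACGT"


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, size=length))


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def make_pool(seq_counts, sample_id="s", array_class="IIID") -> SpacerPool:
    """Pool from {sequence: count} (or list of pairs); records pre-unique."""
    items = seq_counts.items() if isinstance(seq_counts, dict) else seq_counts
    records = [
        SpacerRecord(sequence=s, count=c, array_class=array_class,
                     strand="+", sample_id=sample_id)
        for s, c in items
    ]
    total = sum(r.count for r in records)
    return SpacerPool(
        sample_id=sample_id, array_class=array_class, records=records,
        total_reads_in=total, reads_extracted=total,
    )


# ---------------------------------------------------------------- oracles --

def oracle_overlap_mismatch(a: str, b: str, min_overlap: int):
    """Exhaustive scan over every relative offset; pure-string comparison.
    Uses the same tie-break (longest overlap, then smallest |offset|, then
    the positive one) so results are directly comparable."""
    best_key, best_out = None, None
    for off in range(-len(b) + 1, len(a)):
        lo, hi = max(0, off), min(len(a), off + len(b))
        ov = hi - lo
        if ov < min_overlap:
            continue
        mm = sum(a[i] != b[i - off] for i in range(lo, hi))
        key = (mm, -ov, abs(off), 0 if off >= 0 else 1)
        if best_key is None or key < best_key:
            best_key, best_out = key, (mm, ov, off)
    if best_out is None:
        return math.inf, 0, 0
    return best_out


def oracle_shares_kmer(a: str, b: str, k: int) -> bool:
    sa = {a[i:i + k] for i in range(len(a) - k + 1)}
    sb = {b[i:i + k] for i in range(len(b) - k + 1)}
    return bool(sa & sb)


def oracle_dereplicate(raw, m):
    """All-pairs transcription of the greedy equal-length Hamming merge."""
    counts = {}
    for s in raw:
        counts[s] = counts.get(s, 0) + 1
    ranked = sorted(counts, key=lambda s: (-counts[s], -len(s), s))
    retained: list[str] = []
    out: dict[str, int] = {}
    for s in ranked:
        home = None
        for r in retained:
            if len(r) == len(s) and sum(x != y for x, y in zip(r, s)) <= m:
                home = r
                break
        if home is None:
            retained.append(s)
            out[s] = counts[s]
        else:
            out[home] += counts[s]
    return out


def _oracle_min_overlap_mm(a: str, b: str, min_overlap: int) -> float:
    best = math.inf
    for off in range(-len(b) + 1, len(a)):
        lo, hi = max(0, off), min(len(a), off + len(b))
        if hi - lo < min_overlap:
            continue
        best = min(best, sum(a[i] != b[i - off] for i in range(lo, hi)))
    return best


def oracle_cluster(pool: SpacerPool, params):
    """Direct transcription of the greedy frequency-ranked clustering.

    No indexing: every candidate is compared against every retained parent in
    rank order, testing the mismatch-sites rule and, for high-frequency
    parents, the shared-k-mer rule. Returns (parent sequences in order,
    {candidate: (parent, rule)}).
    """
    ranked = sorted(
        pool.records, key=lambda r: (-r.count, -len(r.sequence), r.sequence)
    )
    parents: list = []
    assign: dict[str, tuple[str, str]] = {}
    for rec in ranked:
        placed = False
        for p in parents:
            if (
                _oracle_min_overlap_mm(p.sequence, rec.sequence, params.min_overlap)
                <= params.max_diff_sites
            ):
                assign[rec.sequence] = (p.sequence, "sites")
                placed = True
                break
            if p.count >= params.high_freq_threshold and oracle_shares_kmer(
                p.sequence, rec.sequence, params.kmer_len
            ):
                assign[rec.sequence] = (p.sequence, "kmer")
                placed = True
                break
        if not placed:
            parents.append(rec)
    return [p.sequence for p in parents], assign


def random_cluster_instance(rng: np.random.Generator, n_target: int):
    """Synthetic clustering instance: truth parents plus planted satellites
    (point mutations, end trims, and 12-mer sharers under high-count parents)."""
    from spacerkit.synthetic import mutate_spacer

    n_truth = max(1, n_target // 4)
    seqs: dict[str, int] = {}
    truth: list[str] = []
    while len(truth) < n_truth:
        s = random_dna(rng, int(rng.integers(30, 46)))
        if s not in seqs:
            count = int(rng.integers(1, 40))
            if rng.random() < 0.15:
                count = int(rng.integers(100, 400))  # exercise the k-mer rule
            seqs[s] = count
            truth.append(s)
    high = [s for s in truth if seqs[s] >= 100]
    attempts = 0
    while len(seqs) < n_target and attempts < 10 * n_target:
        attempts += 1
        parent = truth[int(rng.integers(len(truth)))]
        kind = rng.random()
        if kind < 0.45:  # point-mutation satellite
            sat = mutate_spacer(
                parent, int(rng.integers(0, 5)), seed=int(rng.integers(2**31))
            )
        elif kind < 0.8:  # end-trimmed (optionally mutated) satellite
            max_trim = max(0, len(parent) - 22)
            left = int(rng.integers(0, max_trim // 2 + 1))
            right = int(rng.integers(0, max_trim // 2 + 1))
            sat = mutate_spacer(
                parent, int(rng.integers(0, 3)), end_trim=(left, right),
                seed=int(rng.integers(2**31)),
            )
        elif high:  # shares a 12-mer with a high-count parent, otherwise random
            hp = high[int(rng.integers(len(high)))]
            i = int(rng.integers(0, len(hp) - 12 + 1))
            core = hp[i:i + 12]
            sat = random_dna(rng, 14) + core + random_dna(rng, 14)
        else:
            sat = random_dna(rng, int(rng.integers(30, 46)))
        if sat not in seqs:
            cap = max(2, seqs[parent])
            seqs[sat] = int(rng.integers(1, cap))
    return make_pool(seqs)
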