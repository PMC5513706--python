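"""Pairwise coincidence probability (co-clonality) between spacer samples.

The coincidence probability of two samples is the chance that one spacer
drawn at random from each (proportionally to observation counts) is the same
sequence — a cross-sample Simpson-type statistic. Replicates of the same
CRISPR locus share sequences and score high; samples from different loci are
disjoint and score zero, so the log-scale matrix exhibits block structure by
locus.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .extraction import SpacerPool

__all__ = ["CoincidenceMatrix", "coincidence_probability", "coincidence_matrix"]


@dataclass
class CoincidenceMatrix:
    """All pairwise coincidence probabilities, plus their log10 transform.

    ``P`` is symmetric with the within-sample collision probability
    ``sum(p_i^2)`` on the diagonal. ``logP`` holds ``log10(P)`` with NaN as
    the explicit no-coincidence sentinel where ``P == 0`` (never a fabricated
    floor value).
    """

    sample_ids: list[str]
    P: np.ndarray
    logP: np.ndarray


def _freqs(pool: SpacerPool) -> dict[str, float]:
    total = float(sum(r.count for r in pool.records))
    if total <= 0:
        raise ValueError(f"pool {pool.sample_id!r} has no observations")
    return {r.sequence: r.count / total for r in pool.records}


def coincidence_probability(pool_a: SpacerPool, pool_b: SpacerPool) -> float:
    """Probability that random draws from the two pools coincide exactly.

    ``sum over shared sequences s of p_a(s) * p_b(s)`` with observation-
    frequency weighting; sequence identity is exact (dereplicated sequences,
    not clusters).
    """
    fa, fb = _freqs(pool_a), _freqs(pool_b)
    if len(fb) < len(fa):
        fa, fb = fb, fa
    return float(sum(p * fb[s] for s, p in fa.items() if s in fb))


def coincidence_matrix(pools: list[SpacerPool]) -> CoincidenceMatrix:
    """Pairwise coincidence probabilities for two or more pools."""
    if len(pools) < 2:
        raise ValueError("need at least two pools")
    n = len(pools)
    freqs = [_freqs(p) for p in pools]
    P = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            fa, fb = freqs[i], freqs[j]
            if len(fb) < len(fa):
                fa, fb = fb, fa
            val = sum(p * fb[s] for s, p in fa.items() if s in fb)
            P[i, j] = P[j, i] = val
    with np.errstate(divide="ignore"):
        logP = np.where(P > 0, np.log10(np.where(P > 0, P, 1.0)), np.nan)
    ids = [p.sample_id for p in pools]
    return CoincidenceMatrix(sample_ids=ids, P=P, logP=logP)
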