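"""Repertoire richness and sampling-saturation summaries.

Chao-1 estimates how many distinct units (unique spacers, or clusters) a
sample's singleton/doubleton structure implies beyond those observed; the
saturation curve subsamples the sequenced observations in increments and
recounts distinct units, flattening once the repertoire is exhausted at the
achieved depth. Frequency and length histograms summarise the abundance and
size structure of a pool.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .clustering import ClusteringParams, cluster_spacers
from .extraction import SpacerPool, SpacerRecord

__all__ = [
    "Chao1Estimate",
    "RarefactionCurve",
    "chao1",
    "chao1_from_counts",
    "saturation_curve",
    "frequency_histogram",
    "length_histogram",
]


@dataclass(frozen=True)
class Chao1Estimate:
    """Bias-corrected Chao-1 richness estimate with a 95% lower bound.

    The point estimate is an approximate lower bound for the true number of
    distinct units; ``lower95`` is the lower end of the log-normal 95%
    confidence interval.
    """

    S_obs: int
    f1: int
    f2: int
    S_chao1: float
    variance: float
    lower95: float


def chao1(S_obs: int, f1: int, f2: int) -> Chao1Estimate:
    """Bias-corrected Chao-1 from observed richness and rare-unit counts.

    ``S_chao1 = S_obs + f1*(f1-1) / (2*(f2+1))`` — defined even when no
    doubletons exist, unlike the classical ``f1^2/(2 f2)`` form, which
    matters for singleton-dominated repertoires. The variance uses the
    standard bias-corrected forms (distinct branches for ``f2 > 0`` and
    ``f2 = 0``), and the 95% lower bound the usual log-normal construction
    on ``T = S_chao1 - S_obs``:

    ``lower95 = S_obs + T / C`` with
    ``C = exp(1.96 * sqrt(ln(1 + variance / T^2)))``.
    """
    if f1 < 0 or f2 < 0:
        raise ValueError("f1 and f2 must be >= 0")
    if f1 + f2 > S_obs:
        raise ValueError("f1 + f2 cannot exceed S_obs")

    T = f1 * (f1 - 1) / (2.0 * (f2 + 1))
    S = S_obs + T

    if f1 == 0:
        variance = 0.0
    elif f2 > 0:
        variance = (
            f1 * (f1 - 1) / (2.0 * (f2 + 1))
            + f1 * (2 * f1 - 1) ** 2 / (4.0 * (f2 + 1) ** 2)
            + f1**2 * f2 * (f1 - 1) ** 2 / (4.0 * (f2 + 1) ** 4)
        )
    else:  # f1 > 0, f2 == 0
        variance = (
            f1 * (f1 - 1) / 2.0
            + f1 * (2 * f1 - 1) ** 2 / 4.0
            - f1**4 / (4.0 * S)
        )
        variance = max(variance, 0.0)

    if T > 0 and variance > 0:
        C = math.exp(1.96 * math.sqrt(math.log(1.0 + variance / T**2)))
        lower95 = S_obs + T / C
    else:
        lower95 = float(S_obs)
    return Chao1Estimate(
        S_obs=S_obs, f1=f1, f2=f2, S_chao1=S, variance=variance, lower95=lower95
    )


def chao1_from_counts(counts) -> Chao1Estimate:
    """Chao-1 from per-unit observation counts (any iterable of ints)."""
    counts = np.asarray(list(counts), dtype=np.int64)
    counts = counts[counts > 0]
    return chao1(
        S_obs=int(counts.size),
        f1=int((counts == 1).sum()),
        f2=int((counts == 2).sum()),
    )


@dataclass
class RarefactionCurve:
    """Distinct-unit counts at increasing subsample fractions (averaged)."""

    fractions: list[float]
    unit_counts: list[float]
    count_mode: str  # 'unique' | 'clustered'
    seed: int
    replicates: int = 1

    def is_monotone(self) -> bool:
        return all(
            b >= a for a, b in zip(self.unit_counts[:-1], self.unit_counts[1:])
        )


def saturation_curve(
    pool: SpacerPool,
    params: ClusteringParams | None = None,
    increments: list[float] | None = None,
    count_mode: str = "unique",
    seed: int = 0,
    replicates: int = 1,
) -> RarefactionCurve:
    """Subsample observations in increments and recount distinct units.

    Each replicate shuffles the pool's sequenced observations (count mass,
    not distinct sequences) once and takes nested prefixes — progressively
    larger subsets of the same stream — of the requested fractions, so a
    single replicate's curve can only grow with depth. The distinct sequences
    in each prefix are counted directly (``unique`` mode) or re-clustered
    with the greedy algorithm first (``clustered`` mode). Counts are averaged
    over ``replicates`` shuffles; a fixed seed fixes the curve.
    """
    if count_mode not in ("unique", "clustered"):
        raise ValueError("count_mode must be 'unique' or 'clustered'")
    fractions = sorted(increments) if increments else [i / 10 for i in range(1, 11)]
    if any(not 0 < f <= 1 for f in fractions):
        raise ValueError("fractions must lie in (0, 1]")
    params = params or ClusteringParams()
    counts = pool.counts()
    total = int(counts.sum())
    rng = np.random.default_rng(seed)

    obs = np.repeat(np.arange(counts.size), counts)
    per_rep: list[list[int]] = []
    for _ in range(replicates):
        stream = rng.permutation(obs)
        vals = []
        for frac in fractions:
            depth = int(round(frac * total))
            sub = np.bincount(stream[:depth], minlength=counts.size)
            present = np.nonzero(sub)[0]
            if count_mode == "unique":
                vals.append(int(present.size))
            else:
                sub_records = [
                    SpacerRecord(
                        sequence=pool.records[i].sequence,
                        count=int(sub[i]),
                        array_class=pool.records[i].array_class,
                        strand=pool.records[i].strand,
                        sample_id=pool.sample_id,
                    )
                    for i in present
                ]
                sub_pool = SpacerPool(
                    sample_id=pool.sample_id,
                    array_class=pool.array_class,
                    records=sub_records,
                    total_reads_in=depth,
                    reads_extracted=depth,
                )
                vals.append(cluster_spacers(sub_pool, params).n_clusters)
        per_rep.append(vals)
    means = [float(np.mean([rep[i] for rep in per_rep]))
             for i in range(len(fractions))]
    return RarefactionCurve(
        fractions=fractions,
        unit_counts=means,
        count_mode=count_mode,
        seed=seed,
        replicates=replicates,
    )


def frequency_histogram(counts, top_bin: int = 100) -> dict[object, int]:
    """Observation-frequency histogram with a terminal open bin.

    Bins ``1 .. top_bin-1`` hold the number of units observed exactly that
    many times; the final ``f"{top_bin}+"`` bin pools everything at or above
    the threshold (the same threshold the clustering's k-mer rule uses).
    Accepts a pool, a cluster set, or a bare iterable of counts.
    """
    counts = _as_counts(counts)
    hist: dict[object, int] = {}
    top_key = f"{top_bin}+"
    for c in counts:
        key: object = top_key if c >= top_bin else int(c)
        hist[key] = hist.get(key, 0) + 1
    return hist


def length_histogram(pool: SpacerPool) -> dict[int, tuple[int, int]]:
    """Per-length spacer tallies: ``{length: (distinct, total_observations)}``."""
    out: dict[int, tuple[int, int]] = {}
    for rec in pool.records:
        L = len(rec.sequence)
        d, w = out.get(L, (0, 0))
        out[L] = (d + 1, w + rec.count)
    return out


def _as_counts(obj) -> np.ndarray:
    if isinstance(obj, SpacerPool):
        return obj.counts()
    if hasattr(obj, "clusters"):  # ClusterSet
        return np.array([c.total_count for c in obj.clusters], dtype=np.int64)
    return np.asarray(list(obj), dtype=np.int64)
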