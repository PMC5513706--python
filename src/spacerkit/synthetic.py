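"""Ground-truth spacer pools and simulated repeat-anchored amplicon reads.

The generator emulates the data the analysis consumes: a pool of unique
spacer sequences with heavy-tailed (Zipf-by-rank) abundances and
per-array-class length distributions, packaged into single-spacer amplicon
reads (random 5' tail, forward repeat anchor, spacer, reverse repeat anchor,
3' filler to a fixed read length) with iid per-base substitution errors.
Every read records which truth spacer it carries, so downstream stages can
be checked against exact provenance.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._seq import DNA_BASES, IUPAC_CODES, is_dna, revcomp
from .extraction import ArrayDefinition, PLATENSIS_IIIB, PLATENSIS_IIID

__all__ = [
    "TruthPool",
    "SimulatedRead",
    "DEFAULT_LENGTH_PARAMS",
    "DEFAULT_ARRAYS",
    "generate_truth_pool",
    "mutate_spacer",
    "simulate_amplicon_reads",
    "write_fastq",
    "write_truth_tsv",
]

#: Per-class spacer length distributions, Normal(mean, sd) in nt, rounded and
#: clamped to the bounds below. III-B spacers run shorter than III-D ones.
DEFAULT_LENGTH_PARAMS: dict[str, tuple[float, float]] = {
    "IIID": (40.0, 2.0),
    "IIIB": (36.0, 2.0),
}
LENGTH_CLAMP = (25, 60)

DEFAULT_ARRAYS: dict[str, ArrayDefinition] = {
    "IIID": PLATENSIS_IIID,
    "IIIB": PLATENSIS_IIIB,
}

READ_LENGTH = 150  # single 150-cycle read covers the whole short amplicon
TAIL_LENGTH = 5  # random 5' bases contributed by the N5 primer tail


@dataclass
class TruthPool:
    """Ground-truth spacers: (sequence, abundance weight, array class)."""

    sequences: list[str]
    weights: np.ndarray
    classes: list[str]
    seed: int
    length_params: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_LENGTH_PARAMS)
    )

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.sequences) != len(self.weights) or len(self.sequences) != len(
            self.classes
        ):
            raise ValueError("sequences, weights and classes must align")
        if len(set(self.sequences)) != len(self.sequences):
            raise ValueError("truth spacers must be unique")
        if not (self.weights > 0).all():
            raise ValueError("weights must be strictly positive")
        self.weights = self.weights / self.weights.sum()

    def __len__(self) -> int:
        return len(self.sequences)

    def subset(self, array_class: str) -> list[int]:
        return [i for i, c in enumerate(self.classes) if c == array_class]


@dataclass
class SimulatedRead:
    """One simulated amplicon read with its ground-truth provenance."""

    read_id: str
    sequence: str
    truth_spacer_index: int | None
    strand: str
    applied_errors: int


def _random_unique_seqs(
    rng: np.random.Generator, lengths: list[int], existing: set[str] | None = None
) -> list[str]:
    out: list[str] = []
    seen = set() if existing is None else set(existing)
    for L in lengths:
        while True:
            seq = "".join(rng.choice(list(DNA_BASES), size=L))
            if seq not in seen:
                seen.add(seq)
                out.append(seq)
                break
    return out


def generate_truth_pool(
    n_spacers: int,
    abundance_exponent: float = 1.5,
    length_params: dict[str, tuple[float, float]] | None = None,
    class_mix: float = 0.5,
    seed: int = 0,
) -> TruthPool:
    """Draw a pool of unique random spacers with Zipf-by-rank abundances.

    The weight of the rank-``r`` spacer is proportional to
    ``r ** -abundance_exponent``: exponent 0 gives a uniform pool, exponents
    above 1 give the singleton-dominated shape seen in deeply sequenced
    repertoires. ``class_mix`` is the fraction of spacers assigned to class
    IIIB (the rest are IIID); lengths are drawn from the per-class Normal
    parameters, rounded, and clamped to 25–60 nt.
    """
    if n_spacers < 1:
        raise ValueError("n_spacers must be >= 1")
    if abundance_exponent < 0:
        raise ValueError("abundance_exponent must be >= 0")
    if not 0.0 <= class_mix <= 1.0:
        raise ValueError("class_mix must be in [0, 1]")
    params = dict(DEFAULT_LENGTH_PARAMS if length_params is None else length_params)
    lo, hi = LENGTH_CLAMP
    if n_spacers > 4**lo:
        raise ValueError(
            f"cannot draw {n_spacers} unique sequences of minimum length {lo}"
        )

    rng = np.random.default_rng(seed)
    classes = [
        "IIIB" if u < class_mix else "IIID" for u in rng.random(n_spacers)
    ]
    lengths = []
    for c in classes:
        mean, sd = params[c]
        L = int(round(rng.normal(mean, sd)))
        lengths.append(min(hi, max(lo, L)))
    sequences = _random_unique_seqs(rng, lengths)

    ranks = np.arange(1, n_spacers + 1, dtype=float)
    weights = ranks**-abundance_exponent
    return TruthPool(
        sequences=sequences,
        weights=weights,
        classes=classes,
        seed=seed,
        length_params=params,
    )


def mutate_spacer(
    sequence: str,
    n_substitutions: int,
    end_trim: tuple[int, int] = (0, 0),
    seed: int = 0,
) -> str:
    """Apply end trims then exactly *n_substitutions* point changes.

    Models the two artifact classes the clustering is designed to absorb:
    end-trimmed length variants and point-mutated satellites. Each
    substituted base is guaranteed to differ from the original, so the
    Hamming distance of the output to the trimmed input is exactly
    *n_substitutions*.
    """
    if not is_dna(sequence):
        raise ValueError("sequence must be concrete DNA")
    left, right = end_trim
    if left < 0 or right < 0:
        raise ValueError("end trims must be >= 0")
    trimmed = sequence[left : len(sequence) - right if right else len(sequence)]
    if len(trimmed) < 1:
        raise ValueError("trims leave an empty sequence")
    if n_substitutions < 0 or n_substitutions > len(trimmed):
        raise ValueError("impossible number of substitutions")
    rng = np.random.default_rng(seed)
    positions = rng.choice(len(trimmed), size=n_substitutions, replace=False)
    out = list(trimmed)
    for pos in positions:
        alternatives = [b for b in DNA_BASES if b != out[pos]]
        out[pos] = alternatives[rng.integers(len(alternatives))]
    return "".join(out)


def _resolve_iupac(pattern: str, rng: np.random.Generator) -> str:
    """Instantiate every degeneracy code uniformly over its allowed bases."""
    out = []
    for code in pattern:
        allowed = sorted(IUPAC_CODES[code])
        out.append(allowed[rng.integers(len(allowed))] if len(allowed) > 1 else allowed[0])
    return "".join(out)


def _apply_errors(seq: str, per_base_error: float, rng: np.random.Generator) -> tuple[str, int]:
    if per_base_error <= 0:
        return seq, 0
    hits = np.nonzero(rng.random(len(seq)) < per_base_error)[0]
    if hits.size == 0:
        return seq, 0
    out = list(seq)
    for pos in hits:
        alternatives = [b for b in DNA_BASES if b != out[pos]]
        out[pos] = alternatives[rng.integers(len(alternatives))]
    return "".join(out), int(hits.size)


def simulate_amplicon_reads(
    pool: TruthPool,
    array_defs: dict[str, ArrayDefinition] | None = None,
    n_reads: int = 1000,
    per_base_error: float = 0.0,
    seed: int = 0,
    rc_fraction: float = 0.0,
    read_length: int = READ_LENGTH,
    fastq_path: str | Path | None = None,
    sample_id: str = "sim",
) -> list[SimulatedRead]:
    """Simulate single-spacer amplicon reads from a truth pool.

    Spacers are drawn with probability proportional to their weights; each
    read is the fixed-length sequence ``tail + forward_anchor + spacer +
    reverse_anchor + filler`` for the spacer's array class, with anchor
    degeneracies resolved uniformly and iid substitution errors applied at
    ``per_base_error`` across the entire read. A ``rc_fraction`` share of
    reads is emitted reverse-complemented (strand '-'). Optionally writes a
    standard 4-line FASTQ (constant quality 'I').
    """
    if not 0.0 <= per_base_error <= 0.1:
        raise ValueError("per_base_error must be in [0, 0.1]")
    if not 0.0 <= rc_fraction <= 1.0:
        raise ValueError("rc_fraction must be in [0, 1]")
    arrays = DEFAULT_ARRAYS if array_defs is None else array_defs
    rng = np.random.default_rng(seed)

    draws = rng.choice(len(pool), size=n_reads, p=pool.weights)
    reads: list[SimulatedRead] = []
    for i, idx in enumerate(draws):
        idx = int(idx)
        spacer = pool.sequences[idx]
        adef = arrays[pool.classes[idx]]
        tail = "".join(rng.choice(list(DNA_BASES), size=TAIL_LENGTH))
        body = (
            tail
            + _resolve_iupac(adef.forward_anchor, rng)
            + spacer
            + _resolve_iupac(adef.reverse_anchor, rng)
        )
        if len(body) < read_length:
            filler = "".join(
                rng.choice(list(DNA_BASES), size=read_length - len(body))
            )
            body += filler
        body = body[:read_length]
        strand = "-" if rng.random() < rc_fraction else "+"
        if strand == "-":
            body = revcomp(body)
        body, n_err = _apply_errors(body, per_base_error, rng)
        reads.append(
            SimulatedRead(
                read_id=f"{sample_id}:{i}",
                sequence=body,
                truth_spacer_index=idx,
                strand=strand,
                applied_errors=n_err,
            )
        )
    if fastq_path is not None:
        write_fastq(reads, fastq_path)
    return reads


def write_fastq(reads: list[SimulatedRead], path: str | Path) -> None:
    """Write reads as standard 4-line FASTQ with constant quality 'I'."""
    with open(path, "w") as fh:
        for read in reads:
            fh.write(
                f"@{read.read_id}\n{read.sequence}\n+\n{'I' * len(read.sequence)}\n"
            )


def write_truth_tsv(
    reads: list[SimulatedRead], pool: TruthPool, path: str | Path
) -> None:
    """Ground-truth provenance table: read_id, truth spacer, class, strand, errors."""
    with open(path, "w") as fh:
        fh.write("read_id\ttruth_spacer\tarray_class\tstrand\tn_errors\n")
        for read in reads:
            idx = read.truth_spacer_index
            spacer = "" if idx is None else pool.sequences[idx]
            cls = "" if idx is None else pool.classes[idx]
            fh.write(
                f"{read.read_id}\t{spacer}\t{cls}\t{read.strand}\t{read.applied_errors}\n"
            )


def write_manifest(path: str | Path, **params) -> None:
    """Echo generator parameters and seeds to a JSON run manifest."""
    with open(path, "w") as fh:
        json.dump(params, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
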