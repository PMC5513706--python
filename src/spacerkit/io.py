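"""Tabular I/O: spacer-pool, cluster, hit and matrix tables (TSV via pandas),
plus FASTQ reading (Biopython; gzip accepted)."""

from __future__ import annotations

import gzip
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from .clustering import ClusterSet
from .coincidence import CoincidenceMatrix
from .extraction import SpacerPool, SpacerRecord
from .mapping import MatchHit

__all__ = [
    "read_fastq_sequences",
    "write_pool_tsv",
    "read_pool_tsv",
    "write_clusters_tsv",
    "write_parent_fasta",
    "write_hits_tsv",
    "write_matrix_tsv",
]


def read_fastq_sequences(path: str | Path) -> list[str]:
    """Read sequences (uppercased) from a FASTQ file, gzipped or not."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        return [str(rec.seq).upper() for rec in SeqIO.parse(fh, "fastq")]


def pool_to_frame(pool: SpacerPool) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sequence": [r.sequence for r in pool.records],
            "count": [r.count for r in pool.records],
            "array_class": [r.array_class for r in pool.records],
            "strand": [r.strand for r in pool.records],
            "sample_id": [r.sample_id for r in pool.records],
        }
    )


def write_pool_tsv(pool: SpacerPool, path: str | Path) -> None:
    pool_to_frame(pool).to_csv(path, sep="\t", index=False)


def read_pool_tsv(path: str | Path, total_reads_in: int | None = None) -> SpacerPool:
    df = pd.read_csv(path, sep="\t", dtype={"sequence": str})
    records = [
        SpacerRecord(
            sequence=row.sequence,
            count=int(row.count),
            array_class=str(row.array_class),
            strand=str(row.strand),
            sample_id=str(row.sample_id),
        )
        for row in df.itertuples(index=False)
    ]
    sample_id = records[0].sample_id if records else ""
    array_class = records[0].array_class if records else ""
    n_obs = int(df["count"].sum()) if len(df) else 0
    return SpacerPool(
        sample_id=sample_id,
        array_class=array_class,
        records=records,
        total_reads_in=n_obs if total_reads_in is None else total_reads_in,
        reads_extracted=n_obs,
    )


def clusters_to_frame(cs: ClusterSet) -> pd.DataFrame:
    rows = []
    for c in cs.clusters:
        rows.append(
            {
                "parent_sequence": c.parent.sequence,
                "parent_count": c.parent.count,
                "cluster_total_count": c.total_count,
                "n_members": len(c.members),
                "member_sequence": "",
                "rule": "parent",
            }
        )
        for m, rule in zip(c.members, c.rules):
            rows.append(
                {
                    "parent_sequence": c.parent.sequence,
                    "parent_count": c.parent.count,
                    "cluster_total_count": c.total_count,
                    "n_members": len(c.members),
                    "member_sequence": m.sequence,
                    "rule": rule,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "parent_sequence",
            "parent_count",
            "cluster_total_count",
            "n_members",
            "member_sequence",
            "rule",
        ],
    )


def write_clusters_tsv(cs: ClusterSet, path: str | Path) -> None:
    clusters_to_frame(cs).to_csv(path, sep="\t", index=False)


def write_parent_fasta(cs: ClusterSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for i, c in enumerate(cs.clusters):
            fh.write(f">cluster_{i} count={c.total_count}\n{c.parent.sequence}\n")


def write_hits_tsv(hits: list[MatchHit], path: str | Path) -> None:
    pd.DataFrame(
        {
            "spacer": [h.spacer for h in hits],
            "reference_id": [h.reference_id for h in hits],
            "start": [h.start for h in hits],
            "end": [h.end for h in hits],
            "strand": [h.strand for h in hits],
            "mismatches": [h.mismatches for h in hits],
        }
    ).to_csv(path, sep="\t", index=False)


def write_matrix_tsv(cm: CoincidenceMatrix, path: str | Path) -> None:
    """Both P and log10(P) stacked in one TSV (column 'matrix' disambiguates)."""
    frames = []
    for name, mat in (("P", cm.P), ("log10P", cm.logP)):
        df = pd.DataFrame(mat, index=cm.sample_ids, columns=cm.sample_ids)
        df.insert(0, "matrix", name)
        frames.append(df)
    pd.concat(frames).to_csv(path, sep="\t", index_label="sample_id")
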