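"""Readers and writers for the plain-text formats the pipeline exchanges.

FASTA/FASTQ go through Biopython; gene models use a GFF-like TSV with
1-based inclusive coordinates (converted to the package's internal 0-based
half-open convention on read).
"""

from __future__ import annotations

import os
from typing import Iterable, Iterator

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .records import GeneModel, Read, ReadPair


def write_fasta(path: str | os.PathLike, records: Iterable[tuple[str, str]]) -> None:
    SeqIO.write(
        (SeqRecord(Seq(seq), id=name, description="") for name, seq in records),
        str(path),
        "fasta",
    )


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fastq(path: str | os.PathLike, reads: Iterable[Read]) -> None:
    with open(path, "w") as fh:
        for read in reads:
            qual = (np.asarray(read.qual, dtype=np.uint8) + 33).tobytes().decode()
            fh.write(f"@{read.id}\n{read.seq}\n+\n{qual}\n")


def read_fastq(path: str | os.PathLike) -> Iterator[Read]:
    """Parse a 4-line-record phred-33 FASTQ, validating record structure."""
    with open(path) as fh:
        idx = 0
        while True:
            header = fh.readline()
            if not header:
                return
            seq = fh.readline().rstrip("\n")
            plus = fh.readline()
            qual = fh.readline().rstrip("\n")
            if not header.startswith("@") or not plus.startswith("+") or not qual:
                raise ValueError(f"malformed FASTQ record at index {idx} in {path}")
            yield Read(
                id=header[1:].split()[0],
                seq=seq.upper(),
                qual=np.frombuffer(qual.encode(), dtype=np.uint8) - 33,
            )
            idx += 1


def read_fastq_pairs(path1, path2) -> Iterator[ReadPair]:
    for r1, r2 in zip(read_fastq(path1), read_fastq(path2), strict=True):
        yield ReadPair(r1, r2)


def write_gene_models(path: str | os.PathLike, models: Iterable[GeneModel]) -> None:
    rows = []
    for m in models:
        rows.append(
            {
                "scaffold": m.scaffold,
                "source": "diapipe",
                "feature": "gene",
                "start": m.start + 1,  # to 1-based inclusive
                "end": m.end,
                "score": ".",
                "strand": m.strand,
                "frame": ".",
                "attribute": f"gene_id={m.gene_id}",
            }
        )
    pd.DataFrame(
        rows,
        columns=[
            "scaffold",
            "source",
            "feature",
            "start",
            "end",
            "score",
            "strand",
            "frame",
            "attribute",
        ],
    ).to_csv(path, sep="\t", index=False)


def read_gene_models(path: str | os.PathLike) -> list[GeneModel]:
    df = pd.read_csv(path, sep="\t")
    models = []
    for row in df.itertuples(index=False):
        attrs = dict(kv.split("=", 1) for kv in str(row.attribute).split(";"))
        models.append(
            GeneModel(
                gene_id=attrs["gene_id"],
                scaffold=row.scaffold,
                start=int(row.start) - 1,  # to 0-based half-open
                end=int(row.end),
                strand=row.strand,
            )
        )
    return models


def read_design(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"library_id", "photoperiod", "bloodmeal", "replicate"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"design table missing columns: {sorted(missing)}")
    return df


def read_pathways(path: str | os.PathLike) -> dict[str, set[str]]:
    """Pathway-membership TSV (pathway_id, gene_id) -> id -> gene set."""
    df = pd.read_csv(path, sep="\t")
    out: dict[str, set[str]] = {}
    for row in df.itertuples(index=False):
        out.setdefault(str(row.pathway_id), set()).add(str(row.gene_id))
    return out


def write_pathways(path: str | os.PathLike, pathways: dict[str, set[str]]) -> None:
    rows = [
        {"pathway_id": pid, "gene_id": gid}
        for pid in sorted(pathways)
        for gid in sorted(pathways[pid])
    ]
    pd.DataFrame(rows, columns=["pathway_id", "gene_id"]).to_csv(
        path, sep="\t", index=False
    )
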