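"""Core record types shared across pipeline stages.

Coordinates are 0-based half-open everywhere inside the package; GFF-like
tables are converted to/from 1-based inclusive at the I/O boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class Read:
    """A single sequenced read with per-base phred qualities (uint8 array)."""

    id: str
    seq: str
    qual: np.ndarray

    def __post_init__(self) -> None:
        self.qual = np.asarray(self.qual, dtype=np.uint8)
        if len(self.qual) != len(self.seq):
            raise ValueError(
                f"read {self.id}: quality length {len(self.qual)} != "
                f"sequence length {len(self.seq)}"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class ReadPair:
    """Mate-linked pair; mates share a fragment and are screened together."""

    r1: Read
    r2: Read

    @property
    def id(self) -> str:
        return self.r1.id


@dataclass
class Contig:
    """Assembled sequence with life-stage provenance."""

    id: str
    seq: str
    stage: str = "synthetic"

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError(f"contig {self.id}: empty sequence")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class GeneModel:
    """Annotated gene locus on a genomic scaffold (0-based half-open)."""

    gene_id: str
    scaffold: str
    start: int
    end: int
    strand: str = "+"
    exons: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"gene model {self.gene_id}: bad interval")


@dataclass
class AlignmentHit:
    """Generic local alignment record shared by protein, genome and
    contaminant searches.

    ``query_start``/``query_end`` are 0-based half-open on the query
    nucleotide sequence; target coordinates are bp for nucleotide targets
    and aa for protein targets.  ``frame`` is 0 for nucleotide alignments,
    +1..+3 / -1..-3 for translated searches.
    """

    query_id: str
    target_id: str
    query_start: int
    query_end: int
    target_start: int
    target_end: int
    frame: int
    percent_identity: float
    aligned_length: int
    score: float
    e_value: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.percent_identity <= 1.0):
            raise ValueError("percent identity must be in [0, 1]")
        if self.e_value < 0:
            raise ValueError("e-value must be non-negative")

    @property
    def query_span(self) -> int:
        return self.query_end - self.query_start


UNIGENE_CATEGORIES = (
    "protein_annotated",
    "gene_model_annotated",
    "utr",
    "unannotated_genomic",
)


@dataclass
class Unigene:
    """Final-assembly transcript unit with exactly one annotation category."""

    id: str
    seq: str
    category: str
    reference_id: str
    annotation_identity: float

    def __post_init__(self) -> None:
        if self.category not in UNIGENE_CATEGORIES:
            raise ValueError(f"unknown unigene category {self.category!r}")

    def __len__(self) -> int:
        return len(self.seq)
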