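"""Read cleaning and digital normalization.

Three stages, matching the original study's order: (1) contaminant
screening against a vector database and the multiplexing adapters, with
pair-wise removal; (2) quality trimming to the longest contiguous
high-quality run; (3) one round of streaming digital normalization by
median k-mer abundance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from .align import smith_waterman
from .records import Read, ReadPair, revcomp


@dataclass
class ScreenPolicy:
    """Removal thresholds for the contaminant screen.

    A read is contaminated if it aligns locally to a database sequence at
    ``db_identity_min`` identity with score >= ``db_score_min`` (unit
    match/mismatch, gap -2), or to an adapter at 100% identity with the
    same score floor.  Contaminated reads take their mates with them.
    """

    db_identity_min: float = 0.95
    db_score_min: int = 18
    adapter_identity_min: float = 1.00
    adapter_score_min: int = 18
    remove_mate: bool = True

    def __post_init__(self):
        if not (0 <= self.db_identity_min <= 1 and 0 <= self.adapter_identity_min <= 1):
            raise ValueError("identity thresholds must be in [0, 1]")
        if self.db_score_min <= 0 or self.adapter_score_min <= 0:
            raise ValueError("score thresholds must be positive")


@dataclass
class TrimPolicy:
    """Keep the longest run of bases with phred strictly above
    ``min_phred``; discard reads whose best run is not strictly longer
    than ``min_len``."""

    min_len: int = 50
    min_phred: int = 30

    def __post_init__(self):
        if self.min_len < 1:
            raise ValueError("min_len must be >= 1")
        if not 0 <= self.min_phred <= 41:
            raise ValueError("min_phred must be in [0, 41]")


@dataclass
class DiginormPolicy:
    k: int = 20
    coverage_cutoff: int = 20

    def __post_init__(self):
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.coverage_cutoff < 1:
            raise ValueError("coverage_cutoff must be >= 1")


# ---------------------------------------------------------------------------
# contaminant screening


class _SeedFilter:
    """Exact shared-word prefilter in front of Smith-Waterman.

    Any alignment with >= 18 matching bases at >= 95% identity contains an
    exact run of >= 10 bases (a qualifying alignment of 20 columns tolerates
    one mismatch, splitting 19 matches into runs of at worst 9 and 10), so
    a 10-mer prefilter is lossless for the database rule.  Seeds carry
    their (strand, diagonal) so verification aligns the read against a
    short window of the database sequence rather than the whole thing.
    """

    def __init__(self, db: dict[str, str], word: int = 10):
        self.word = word
        self.db = dict(db)
        self.strand_seqs: dict[tuple[str, str], str] = {}
        self.index: dict[str, list[tuple[str, str, int]]] = {}
        for name, seq in self.db.items():
            for strand, strand_seq in (("+", seq), ("-", revcomp(seq))):
                self.strand_seqs[(name, strand)] = strand_seq
                for i in range(len(strand_seq) - word + 1):
                    self.index.setdefault(strand_seq[i : i + word], []).append(
                        (name, strand, i)
                    )

    def windows(self, read_seq: str) -> list[tuple[str, int]]:
        """(window, shift) pairs around seed diagonals: read position i
        corresponds to window position i + shift."""
        w = self.word
        bands: dict[tuple[str, str, int], int] = {}
        L = len(read_seq)
        for i in range(L - w + 1):
            for name, strand, pos in self.index.get(read_seq[i : i + w], ()):
                diag = pos - i
                bands[(name, strand, diag // 40)] = diag
        out = []
        for (name, strand, _), diag in bands.items():
            target = self.strand_seqs[(name, strand)]
            lo = max(diag - 30, 0)
            hi = min(diag + L + 30, len(target))
            out.append((target[lo:hi], diag - lo))
        return out


def _ungapped_qualify(read_seq: str, window: str, shift: int, policy: "ScreenPolicy"):
    """Exact search for a qualifying gap-free alignment on one diagonal.

    Returns (qualified, max_matches_in_any_segment).  All O(L^2) segments
    are scanned at once with prefix sums, so this is exact for ungapped
    alignments; the caller falls back to Smith-Waterman only when the
    diagonal comes close, which keeps gapped sensitivity without paying
    the DP cost on every spurious seed.
    """
    qoff = max(0, -shift)
    woff = max(0, shift)
    n = min(len(read_seq) - qoff, len(window) - woff)
    if n < policy.db_score_min:
        return False, 0
    a = np.frombuffer(read_seq[qoff : qoff + n].encode(), dtype=np.uint8)
    b = np.frombuffer(window[woff : woff + n].encode(), dtype=np.uint8)
    cs = np.concatenate(([0], np.cumsum(a == b)))
    starts = cs[:, None]  # cs[i]
    matches = cs[None, :] - starts  # [i, j] = matches in [i, j)
    cols = np.arange(n + 1)[None, :] - np.arange(n + 1)[:, None]
    at_identity = (cols > 0) & (matches >= policy.db_identity_min * cols)
    if not at_identity.any():
        return False, 0
    best = int(matches[at_identity].max())
    return best >= policy.db_score_min, best


# The removal rule asks whether ANY local alignment reaches the score floor
# at the identity floor.  The single optimal alignment under one scoring
# scheme can miss such alignments (flank extension buys score but dilutes
# identity), so each database sequence is tried under a permissive and a
# stringent scheme on both strands and the best qualifying alignment wins.
_SCREEN_SCHEMES = ((1, -1, -2), (1, -4, -6))


def _qualifying_db_alignment(read_seq: str, window: str, policy: "ScreenPolicy"):
    for match, mismatch, gap in _SCREEN_SCHEMES:
        aln = smith_waterman(read_seq, window, match, mismatch, gap)
        if aln.matches >= policy.db_score_min and aln.identity >= policy.db_identity_min:
            return aln
    return None


def _adapter_hit(read_seq: str, adapter_words: set[str], word: int) -> bool:
    return any(
        read_seq[i : i + word] in adapter_words
        for i in range(len(read_seq) - word + 1)
    )


def screen_contaminants(
    pairs: Iterable[ReadPair],
    vec_db: dict[str, str],
    adapters: dict[str, str],
    policy: ScreenPolicy | None = None,
) -> tuple[list[ReadPair], pd.DataFrame]:
    """Remove pairs where either mate hits the vector database or an
    adapter; returns retained pairs and a per-read removal log."""
    policy = policy or ScreenPolicy()
    seed = _SeedFilter(vec_db) if vec_db else None
    adapter_word = policy.adapter_score_min  # exact match of this length = score
    adapter_words: set[str] = set()
    for seq in adapters.values():
        for s in (seq, revcomp(seq)):
            for i in range(len(s) - adapter_word + 1):
                adapter_words.add(s[i : i + adapter_word])
    retained: list[ReadPair] = []
    log_rows: list[dict] = []

    def check(read: Read):
        seq = read.seq
        if adapter_words and _adapter_hit(seq, adapter_words, adapter_word):
            return ("adapter", 1.0, float(adapter_word))
        if seed is not None:
            for window, shift in seed.windows(seq):
                ok, max_matches = _ungapped_qualify(seq, window, shift, policy)
                if ok:
                    return ("vector", 1.0, float(max_matches))
                if max_matches >= policy.db_score_min - 6:
                    aln = _qualifying_db_alignment(seq, window, policy)
                    if aln is not None:
                        return ("vector", aln.identity, float(aln.matches))
        return None

    for pair in pairs:
        hit1 = check(pair.r1)
        hit2 = None if hit1 and policy.remove_mate else check(pair.r2)
        if hit1 or hit2:
            for read, hit in ((pair.r1, hit1), (pair.r2, hit2)):
                if hit:
                    log_rows.append(
                        {"read_id": read.id, "reason": hit[0], "identity": hit[1], "score": hit[2]}
                    )
            continue
        retained.append(pair)
    log = pd.DataFrame(log_rows, columns=["read_id", "reason", "identity", "score"])
    return retained, log


# ---------------------------------------------------------------------------
# quality trimming


def quality_trim(read: Read, policy: TrimPolicy | None = None) -> Read | None:
    """Longest contiguous run of bases with phred > min_phred; None if the
    best run is <= min_len.  Ties broken by the leftmost run."""
    policy = policy or TrimPolicy()
    qual = np.asarray(read.qual)
    if len(qual) != len(read.seq):
        raise ValueError(f"read {read.id}: quality/sequence length mismatch")
    good = qual > policy.min_phred
    if not good.any():
        return None
    # run boundaries
    padded = np.concatenate(([False], good, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    starts, ends = edges[0::2], edges[1::2]
    lengths = ends - starts
    best = int(np.argmax(lengths))  # argmax -> leftmost on ties
    if lengths[best] <= policy.min_len:
        return None
    s, e = int(starts[best]), int(ends[best])
    if s == 0 and e == len(read.seq):
        return read
    return Read(id=read.id, seq=read.seq[s:e], qual=qual[s:e])


def trim_pairs(
    pairs: Iterable[ReadPair], policy: TrimPolicy | None = None
) -> tuple[list[ReadPair], int]:
    """Trim both mates; a pair survives only if both mates do."""
    policy = policy or TrimPolicy()
    out = []
    dropped = 0
    for pair in pairs:
        t1 = quality_trim(pair.r1, policy)
        t2 = quality_trim(pair.r2, policy)
        if t1 is None or t2 is None:
            dropped += 1
            continue
        out.append(ReadPair(t1, t2))
    return out, dropped


# ---------------------------------------------------------------------------
# digital normalization


class KmerCounter:
    """Exact canonical k-mer counter (plain dict; desk-scale by design)."""

    def __init__(self, k: int):
        self.k = k
        self.counts: dict[str, int] = {}

    def kmers(self, seq: str) -> list[str]:
        k = self.k
        rc = revcomp(seq)
        L = len(seq)
        out = []
        for i in range(L - k + 1):
            fwd = seq[i : i + k]
            rev = rc[L - k - i : L - i]
            out.append(fwd if fwd <= rev else rev)
        return out

    def median_abundance(self, kmers: list[str]) -> float:
        counts = self.counts
        vals = sorted(counts.get(km, 0) for km in kmers)
        n = len(vals)
        mid = n // 2
        return float(vals[mid]) if n % 2 else (vals[mid - 1] + vals[mid]) / 2.0

    def add(self, kmers: list[str]) -> None:
        counts = self.counts
        for km in kmers:
            counts[km] = counts.get(km, 0) + 1


def digital_normalize(
    reads: Iterable[Read], policy: DiginormPolicy | None = None
) -> tuple[list[Read], pd.DataFrame]:
    """Streaming median-abundance normalization.

    A read is kept iff the median abundance of its k-mers in the running
    counter is below the cutoff at its decision time; kept reads' k-mers
    are then counted.  Order-dependent and deterministic.  Reads shorter
    than k are kept unconditionally and logged.
    """
    policy = policy or DiginormPolicy()
    counter = KmerCounter(policy.k)
    kept: list[Read] = []
    log_rows = []
    for read in reads:
        if len(read.seq) < policy.k:
            kept.append(read)
            log_rows.append({"read_id": read.id, "decision": "kept_short", "median": 0.0})
            continue
        kmers = counter.kmers(read.seq)
        med = counter.median_abundance(kmers)
        if med < policy.coverage_cutoff:
            kept.append(read)
            counter.add(kmers)
        else:
            log_rows.append({"read_id": read.id, "decision": "discarded", "median": med})
    log = pd.DataFrame(log_rows, columns=["read_id", "decision", "median"])
    return kept, log


def digital_normalize_pairs(
    pairs: Iterable[ReadPair], policy: DiginormPolicy | None = None
) -> tuple[list[ReadPair], pd.DataFrame]:
    """Pair-aware variant: keep the pair if EITHER mate is below cutoff,
    then count both mates' k-mers."""
    policy = policy or DiginormPolicy()
    counter = KmerCounter(policy.k)
    kept: list[ReadPair] = []
    log_rows = []
    for pair in pairs:
        medians = []
        all_kmers = []
        keep = False
        for read in (pair.r1, pair.r2):
            if len(read.seq) < policy.k:
                keep = True
                continue
            kmers = counter.kmers(read.seq)
            all_kmers.append(kmers)
            med = counter.median_abundance(kmers)
            medians.append(med)
            if med < policy.coverage_cutoff:
                keep = True
        if keep:
            kept.append(pair)
            for kmers in all_kmers:
                counter.add(kmers)
        else:
            log_rows.append(
                {"read_id": pair.id, "decision": "discarded", "median": min(medians)}
            )
    log = pd.DataFrame(log_rows, columns=["read_id", "decision", "median"])
    return kept, log
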