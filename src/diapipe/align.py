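"""Alignment primitives shared by screening, consolidation, annotation and
read mapping.

Three engines cover the pipeline's needs at desk scale:

* an exact Smith-Waterman (unit match/mismatch, linear gap) for the
  contaminant screen, where the removal rule is phrased directly in terms
  of a local alignment score;
* edit-distance alignment via ``edlib`` for nucleotide identity between
  contigs (global over the shorter sequence's span, the CD-HIT-EST
  convention) and for overlap verification during merging;
* Biopython's ``PairwiseAligner`` with BLOSUM62 and affine gaps for the
  translated (six-frame) protein search, with Karlin-Altschul e-values.

The spliced genome aligner chains exact seed matches colinearly, calls
target-side gaps introns, and rescores the implied exon alignment with an
edit-distance pass so percent identity is exact rather than seed-derived.
"""

from __future__ import annotations

from dataclasses import dataclass

import edlib
import numpy as np
from Bio.Align import PairwiseAligner, substitution_matrices

from .records import AlignmentHit, revcomp

# Karlin-Altschul parameters: standard gapped BLOSUM62 (open 11 / extend 1)
# for translated searches, and unit-score nucleotide values for DNA.
KA_PROTEIN = (0.267, 0.041)
KA_NUCLEOTIDE = (1.33, 0.621)


def karlin_altschul_evalue(
    score: float, query_len: int, db_len: int, params: tuple[float, float]
) -> float:
    lam, k = params
    return k * query_len * db_len * float(np.exp(-lam * score))


# ---------------------------------------------------------------------------
# Smith-Waterman


@dataclass
class LocalAlignment:
    score: int
    query_start: int
    query_end: int
    target_start: int
    target_end: int
    identity: float
    aligned_length: int
    matches: int = 0


def smith_waterman(
    query: str,
    target: str,
    match: int = 1,
    mismatch: int = -1,
    gap: int = -2,
) -> LocalAlignment:
    """Best local alignment under a unit scoring scheme.

    Each DP row is computed fully vectorized: with a linear gap penalty the
    chain of left moves from any source cell k contributes
    ``c[k] + gap * (j - k)``, so the row maximum over all left chains is a
    cumulative max of ``c[k] - gap_cost * k`` — no sequential inner loop.
    """
    n, m = len(query), len(target)
    if n == 0 or m == 0:
        return LocalAlignment(0, 0, 0, 0, 0, 0.0, 0)
    q = np.frombuffer(query.encode(), dtype=np.uint8)
    t = np.frombuffer(target.encode(), dtype=np.uint8)
    H = np.zeros((n + 1, m + 1), dtype=np.int32)
    g = -gap  # positive cost
    jidx = np.arange(m + 1, dtype=np.int32)
    gj = g * jidx
    for i in range(1, n + 1):
        sub = np.where(t == q[i - 1], match, mismatch)
        c = np.zeros(m + 1, dtype=np.int32)
        np.maximum(H[i - 1, :-1] + sub, H[i - 1, 1:] + gap, out=c[1:])
        np.maximum(c, 0, out=c)
        left_chain = np.maximum.accumulate(c + gj) - gj
        np.maximum(c, left_chain, out=H[i])
        H[i, 0] = 0
    end = np.unravel_index(int(np.argmax(H)), H.shape)
    score = int(H[end])
    # traceback
    i, j = int(end[0]), int(end[1])
    qe, te = i, j
    matches = 0
    cols = 0
    while i > 0 and j > 0 and H[i, j] > 0:
        sub = match if query[i - 1] == target[j - 1] else mismatch
        if H[i, j] == H[i - 1, j - 1] + sub:
            matches += query[i - 1] == target[j - 1]
            i, j = i - 1, j - 1
        elif H[i, j] == H[i - 1, j] + gap:
            i -= 1
        else:
            j -= 1
        cols += 1
    identity = matches / cols if cols else 0.0
    return LocalAlignment(score, i, qe, j, te, identity, cols, matches)


# ---------------------------------------------------------------------------
# k-mer utilities


def kmer_set(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def shares_kmer(a: str, b_kmers: set[str], k: int) -> bool:
    return any(a[i : i + k] in b_kmers for i in range(len(a) - k + 1))


CANON_K_TRANS = str.maketrans("ACGT", "TGCA")


def canonical_kmer(kmer: str) -> str:
    rc = kmer.translate(CANON_K_TRANS)[::-1]
    return kmer if kmer <= rc else rc


# ---------------------------------------------------------------------------
# Nucleotide identity (edlib-backed)


def identity_over_shorter(a: str, b: str) -> float:
    """Global identity over the alignable span of the shorter sequence.

    Matches the CD-HIT-EST convention for contained fragments: the shorter
    sequence is aligned as an infix of the longer one and identity is
    1 - edits / len(shorter).  Checked on both strands.
    """
    short, long_ = (a, b) if len(a) <= len(b) else (b, a)
    best = 0.0
    for q in (short, revcomp(short)):
        res = edlib.align(q, long_, mode="HW", task="distance")
        ident = 1.0 - res["editDistance"] / len(short)
        best = max(best, ident)
    return best


def global_identity(a: str, b: str) -> float:
    res = edlib.align(a, b, mode="NW", task="distance")
    return 1.0 - res["editDistance"] / max(len(a), len(b))


# ---------------------------------------------------------------------------
# Suffix-prefix / containment overlap detection (the CAP3-like primitive)


@dataclass
class Overlap:
    """left precedes right on the merged coordinate (or contains it)."""

    left: str  # contig id
    right: str
    offset: int  # start of right within left's coordinates
    length: int  # overlap length in bp
    identity: float
    containment: bool


def _overlap_candidates(a_seq: str, b_seq: str, k: int = 16) -> set[int]:
    """Candidate offsets of b relative to a, from shared exact k-mers."""
    index: dict[str, list[int]] = {}
    for i in range(len(a_seq) - k + 1):
        index.setdefault(a_seq[i : i + k], []).append(i)
    offsets: set[int] = set()
    for j in range(len(b_seq) - k + 1):
        for i in index.get(b_seq[j : j + k], ()):
            offsets.add(i - j)
    return offsets


def find_overlap(
    a_id: str,
    a_seq: str,
    b_id: str,
    b_seq: str,
    min_overlap: int,
    min_identity: float,
) -> Overlap | None:
    """Best qualifying suffix-prefix or containment overlap between two
    contigs (same strand).  Returns the longest overlap whose identity
    exceeds ``min_identity``, or None."""
    best: Overlap | None = None
    for left_id, left, right_id, right in (
        (a_id, a_seq, b_id, b_seq),
        (b_id, b_seq, a_id, a_seq),
    ):
        for off in _overlap_candidates(left, right):
            if off < 0:
                continue
            ov_len = min(len(left) - off, len(right))
            if ov_len < min_overlap:
                continue
            seg_left = left[off : off + ov_len]
            seg_right = right[:ov_len]
            ident = global_identity(seg_left, seg_right)
            if ident <= min_identity:
                continue
            cand = Overlap(
                left=left_id,
                right=right_id,
                offset=off,
                length=ov_len,
                identity=ident,
                containment=(off + len(right) <= len(left)),
            )
            if (
                best is None
                or cand.length > best.length
                or (cand.length == best.length and cand.identity > best.identity)
            ):
                best = cand
    return best


def merge_by_overlap(left_seq: str, right_seq: str, overlap: Overlap) -> str:
    """Consensus merge at a fixed offset.

    Per-column majority reduces, for two parents, to: agree -> the base;
    disagree -> the base from the longer parent.  Indels inside the overlap
    are resolved the same way via an edit-distance alignment path.
    """
    off = overlap.offset
    ov_len = min(len(left_seq) - off, len(right_seq))
    seg_left = left_seq[off : off + ov_len]
    seg_right = right_seq[:ov_len]
    longer_is_left = len(left_seq) >= len(right_seq)
    res = edlib.align(seg_right, seg_left, mode="NW", task="path")
    consensus = []
    i = j = 0  # i -> seg_right, j -> seg_left
    for n_ops, op in _parse_cigar(res["cigar"]):
        for _ in range(n_ops):
            if op == "=" or op == "M":
                cl, cr = seg_left[j], seg_right[i]
                consensus.append(cl if (cl == cr or longer_is_left) else cr)
                i += 1
                j += 1
            elif op == "X":
                consensus.append(seg_left[j] if longer_is_left else seg_right[i])
                i += 1
                j += 1
            elif op == "I":  # base in seg_right only
                if not longer_is_left:
                    consensus.append(seg_right[i])
                i += 1
            elif op == "D":  # base in seg_left only
                if longer_is_left:
                    consensus.append(seg_left[j])
                j += 1
    merged = left_seq[:off] + "".join(consensus)
    if off + len(right_seq) > len(left_seq):
        merged += right_seq[ov_len:]
    else:
        merged += left_seq[off + ov_len :]
    return merged


def _parse_cigar(cigar: str):
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            yield int(num), ch
            num = ""


# ---------------------------------------------------------------------------
# Translated protein search

_PROTEIN_ALIGNER: PairwiseAligner | None = None


def _protein_aligner() -> PairwiseAligner:
    global _PROTEIN_ALIGNER
    if _PROTEIN_ALIGNER is None:
        aligner = PairwiseAligner()
        aligner.mode = "local"
        aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
        aligner.open_gap_score = -11.0
        aligner.extend_gap_score = -1.0
        _PROTEIN_ALIGNER = aligner
    return _PROTEIN_ALIGNER


_CODON_TABLE: dict[str, str] = {}


def _build_codon_table() -> dict[str, str]:
    if not _CODON_TABLE:
        from Bio.Seq import Seq

        bases = "TCAG"
        for c1 in bases:
            for c2 in bases:
                for c3 in bases:
                    codon = c1 + c2 + c3
                    _CODON_TABLE[codon] = str(Seq(codon).translate())
    return _CODON_TABLE


def translate(seq: str) -> str:
    table = _build_codon_table()
    return "".join(
        table.get(seq[i : i + 3], "X") for i in range(0, len(seq) - 2, 3)
    )


def six_frame_translations(seq: str) -> list[tuple[int, str]]:
    """(frame, peptide) for frames +1..+3 and -1..-3."""
    out = []
    rc = revcomp(seq)
    for shift in range(3):
        out.append((shift + 1, translate(seq[shift:])))
        out.append((-(shift + 1), translate(rc[shift:])))
    return out


def local_protein_alignment(query_aa: str, target_aa: str):
    """(score, q_interval, t_interval, identity, aligned_cols) or None."""
    if not query_aa or not target_aa:
        return None
    aligner = _protein_aligner()
    alignments = aligner.align(query_aa, target_aa)
    if len(alignments) == 0 or alignments.score <= 0:
        return None
    aln = alignments[0]
    q_blocks, t_blocks = aln.aligned
    matches = 0
    cols = 0
    for (qs, qe), (ts, te) in zip(q_blocks, t_blocks):
        for qi, ti in zip(range(qs, qe), range(ts, te)):
            cols += 1
            matches += query_aa[qi] == target_aa[ti]
    if cols == 0:
        return None
    q_start, q_end = int(q_blocks[0][0]), int(q_blocks[-1][1])
    t_start, t_end = int(t_blocks[0][0]), int(t_blocks[-1][1])
    return float(aln.score), (q_start, q_end), (t_start, t_end), matches / cols, cols


def frame_to_query_interval(
    frame: int, aa_start: int, aa_end: int, seq_len: int
) -> tuple[int, int]:
    """Map an aa interval in a translated frame back to contig bp coords."""
    shift = abs(frame) - 1
    start_nt = shift + 3 * aa_start
    end_nt = shift + 3 * aa_end
    if frame > 0:
        return start_nt, min(end_nt, seq_len)
    # frame on the reverse complement: mirror back
    return max(seq_len - end_nt, 0), seq_len - start_nt


# ---------------------------------------------------------------------------
# Spliced alignment of a contig to a genomic scaffold


@dataclass
class SplicedAlignment:
    strand: str
    query_start: int
    query_end: int
    target_start: int
    target_end: int
    identity: float
    aligned_length: int
    matches: int


def _chain_anchors(anchors: list[tuple[int, int]], k: int) -> list[tuple[int, int]]:
    """Highest-coverage colinear chain (query and target both increasing)."""
    anchors = sorted(set(anchors))
    n = len(anchors)
    if n == 0:
        return []
    score = [k] * n
    back = [-1] * n
    for i in range(n):
        qi, ti = anchors[i]
        for j in range(max(0, i - 60), i):
            qj, tj = anchors[j]
            if qj < qi and tj < ti and ti - tj >= qi - qj - k:
                gain = min(k, qi - qj)
                if score[j] + gain > score[i]:
                    score[i] = score[j] + gain
                    back[i] = j
    best = int(np.argmax(score))
    chain = []
    while best != -1:
        chain.append(anchors[best])
        best = back[best]
    return chain[::-1]


def build_position_index(seq: str, k: int = 15) -> dict[str, list[int]]:
    index: dict[str, list[int]] = {}
    for i in range(len(seq) - k + 1):
        index.setdefault(seq[i : i + k], []).append(i)
    return index


def spliced_align(
    contig_seq: str,
    scaffold_seq: str,
    k: int = 15,
    min_intron: int = 30,
    index: dict[str, list[int]] | None = None,
) -> SplicedAlignment | None:
    """Align a transcript-derived contig to genomic sequence, treating long
    target-side gaps as introns.  Identity is recomputed by edit distance
    over the concatenated exon segments, so seed loss around SNPs does not
    depress it.  Pass a prebuilt ``build_position_index`` of the scaffold
    to amortize indexing across many queries."""
    if index is None:
        index = build_position_index(scaffold_seq, k)
    best: SplicedAlignment | None = None
    for strand in "+-":
        query = contig_seq if strand == "+" else revcomp(contig_seq)
        anchors = []
        for qpos in range(len(query) - k + 1):
            for tpos in index.get(query[qpos : qpos + k], ()):
                anchors.append((qpos, tpos))
            if len(anchors) > 20000:
                break
        chain = _chain_anchors(anchors, k)
        if not chain:
            continue
        q_start, t_start = chain[0]
        q_end, t_end = chain[-1][0] + k, chain[-1][1] + k
        # split the chain into exon blocks at intron-sized target gaps
        blocks: list[list[int]] = [[q_start, q_start + k, t_start, t_start + k]]
        for qpos, tpos in chain[1:]:
            b = blocks[-1]
            t_gap = tpos - (b[3] - k) - k + (k - 1)
            dq = qpos - (b[1] - k)
            dt = tpos - (b[3] - k)
            if dt - dq > min_intron:
                blocks.append([qpos, qpos + k, tpos, tpos + k])
            else:
                b[1] = qpos + k
                b[3] = tpos + k
        # rescore: edit distance of query span vs concatenated exon target
        target_exonic = "".join(scaffold_seq[b[2] : b[3]] for b in blocks)
        query_span = query[q_start:q_end]
        res = edlib.align(query_span, target_exonic, mode="NW", task="distance")
        cols = max(len(query_span), len(target_exonic))
        matches = cols - res["editDistance"]
        identity = matches / cols if cols else 0.0
        if strand == "-":
            q_start, q_end = len(contig_seq) - q_end, len(contig_seq) - q_start
        cand = SplicedAlignment(
            strand=strand,
            query_start=q_start,
            query_end=q_end,
            target_start=t_start,
            target_end=t_end,
            identity=identity,
            aligned_length=cols,
            matches=matches,
        )
        if best is None or cand.matches > best.matches:
            best = cand
    return best


def hit_from_spliced(
    query_id: str,
    target_id: str,
    aln: SplicedAlignment,
    db_len: int,
) -> AlignmentHit:
    score = float(aln.matches)
    e = karlin_altschul_evalue(score, aln.query_end - aln.query_start, db_len, KA_NUCLEOTIDE)
    return AlignmentHit(
        query_id=query_id,
        target_id=target_id,
        query_start=aln.query_start,
        query_end=aln.query_end,
        target_start=aln.target_start,
        target_end=aln.target_end,
        frame=0,
        percent_identity=aln.identity,
        aligned_length=aln.aligned_length,
        score=score,
        e_value=min(e, 1e300),
    )
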