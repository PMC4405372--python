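"""Hybrid protein- and genome-reference re-assembly and annotation.

The protein path aligns six-frame translations of each contig against a
non-redundant dipteran-style protein set (BLOSUM62, affine gaps,
Karlin-Altschul e-values), groups contigs by best reference, merges
overlapping group members, re-verifies the annotation of merged contigs,
and discards low-identity and chimeric products.  Contigs the protein
path does not retain continue to the genome path: seeded spliced
alignment to their best scaffold, a top-95%-by-identity retention filter
(whose realized cutoff is a per-dataset output, not a constant),
locus-wise merging, re-verification, chimera removal, and classification
into gene-model / UTR / unannotated-genomic categories.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .align import (
    KA_PROTEIN,
    frame_to_query_interval,
    hit_from_spliced,
    karlin_altschul_evalue,
    local_protein_alignment,
    six_frame_translations,
    spliced_align,
)
from .consolidation import merge_overlapping
from .records import AlignmentHit, Contig, GeneModel, Unigene, revcomp

E_VALUE_MAX = 1e-6
PROTEIN_IDENTITY_MIN = 0.70
OVERLAP_IDENTITY_MIN = 0.95
CHIMERA_MIN_OUTSIDE = 50
CHIMERA_IDENTITY_FRACTION = 0.80
UTR_MAX_DISTANCE = 1000
UTR_MIN_COVERAGE = 0.90
RETAIN_FRACTION = 0.95


@dataclass
class AssemblyStats:
    n_contigs: int
    n50: int
    mean_length: float
    median_length: float
    max_length: int
    mean_gc: float


def contig_stats(seqs: list[str]) -> AssemblyStats:
    """Summary statistics of an assembly (N50 by descending cumulative sum)."""
    if not seqs:
        raise ValueError("cannot compute statistics of an empty assembly")
    lengths = np.array(sorted((len(s) for s in seqs), reverse=True))
    cum = np.cumsum(lengths)
    n50 = int(lengths[np.searchsorted(cum, cum[-1] / 2.0)])
    gc = sum(s.count("G") + s.count("C") for s in seqs) / cum[-1]
    return AssemblyStats(
        n_contigs=len(seqs),
        n50=n50,
        mean_length=float(np.mean(lengths)),
        median_length=float(np.median(lengths)),
        max_length=int(lengths[0]),
        mean_gc=float(gc),
    )


# ---------------------------------------------------------------------------
# translated search

_AA_WORD = 6


class ProteinIndex:
    """Exact aa-word prefilter over the protein reference set.

    A protein becomes an alignment candidate when it shares at least two
    exact 6-aa words with the translated frame; a single shared word
    between unrelated sequences is common at desk-scale database sizes,
    two are not.
    """

    def __init__(self, proteins: dict[str, str], min_shared_words: int = 2):
        self.proteins = dict(proteins)
        self.min_shared_words = min_shared_words
        self.db_len = sum(len(p) for p in proteins.values())
        self.index: dict[str, list[str]] = {}
        for pid, seq in proteins.items():
            seen = set()
            for i in range(len(seq) - _AA_WORD + 1):
                word = seq[i : i + _AA_WORD]
                if word not in seen:
                    seen.add(word)
                    self.index.setdefault(word, []).append(pid)

    def candidates(self, peptide: str) -> set[str]:
        votes: dict[str, int] = {}
        seen: set[str] = set()
        for i in range(len(peptide) - _AA_WORD + 1):
            word = peptide[i : i + _AA_WORD]
            if word in seen:
                continue
            seen.add(word)
            for pid in self.index.get(word, ()):
                votes[pid] = votes.get(pid, 0) + 1
        return {pid for pid, v in votes.items() if v >= self.min_shared_words}


def translated_best_hits(
    contigs: list[Contig],
    proteins: dict[str, str],
    e_max: float = E_VALUE_MAX,
) -> tuple[dict[str, AlignmentHit], dict[str, list[AlignmentHit]], list[Contig]]:
    """Six-frame translated search of each contig against the protein set.

    Returns (best hit per contig, all retained hits per contig, unmatched
    contigs).  Best = lowest e-value, ties by score then target id.
    """
    index = ProteinIndex(proteins) if proteins else None
    best: dict[str, AlignmentHit] = {}
    all_hits: dict[str, list[AlignmentHit]] = {}
    unmatched: list[Contig] = []
    for contig in contigs:
        hits: list[AlignmentHit] = []
        if index is not None and len(contig.seq) >= 3:
            for frame, peptide in six_frame_translations(contig.seq):
                for pid in sorted(index.candidates(peptide)):
                    res = local_protein_alignment(peptide, index.proteins[pid])
                    if res is None:
                        continue
                    score, (qs, qe), (ts, te), ident, cols = res
                    e = karlin_altschul_evalue(score, len(peptide), index.db_len, KA_PROTEIN)
                    if e > e_max:
                        continue
                    nt_start, nt_end = frame_to_query_interval(frame, qs, qe, len(contig.seq))
                    hits.append(
                        AlignmentHit(
                            query_id=contig.id,
                            target_id=pid,
                            query_start=nt_start,
                            query_end=nt_end,
                            target_start=ts,
                            target_end=te,
                            frame=frame,
                            percent_identity=ident,
                            aligned_length=cols,
                            score=score,
                            e_value=e,
                        )
                    )
        if hits:
            hits.sort(key=lambda h: (h.e_value, -h.score, h.target_id))
            best[contig.id] = hits[0]
            all_hits[contig.id] = hits
        else:
            unmatched.append(contig)
    return best, all_hits, unmatched


# ---------------------------------------------------------------------------
# chimera rule


def detect_chimera(
    hits: list[AlignmentHit],
    min_outside: int = CHIMERA_MIN_OUTSIDE,
    identity_fraction: float = CHIMERA_IDENTITY_FRACTION,
    absolute_identity: float | None = None,
) -> bool:
    """True iff a non-primary hit extends > ``min_outside`` bp beyond the
    primary hit's query interval at sufficient identity.

    The identity condition is relative by default (> identity_fraction x
    primary identity); pass ``absolute_identity`` to use a flat floor
    instead.  Hits to the primary's own target are ignored: extra
    alignment to the same reference is extension, not chimerism.
    """
    if not hits:
        return False
    ordered = sorted(hits, key=lambda h: (h.e_value, -h.score, h.target_id))
    primary = ordered[0]
    if absolute_identity is not None:
        threshold = absolute_identity
    else:
        threshold = identity_fraction * primary.percent_identity
    for hit in ordered[1:]:
        if hit.target_id == primary.target_id:
            continue
        overlap = max(
            0,
            min(hit.query_end, primary.query_end) - max(hit.query_start, primary.query_start),
        )
        outside = (hit.query_end - hit.query_start) - overlap
        if outside > min_outside and hit.percent_identity > threshold:
            return True
    return False


# ---------------------------------------------------------------------------
# protein reference-based re-assembly


def protein_reassemble(
    contigs: list[Contig],
    proteins: dict[str, str],
    e_max: float = E_VALUE_MAX,
    identity_min: float = PROTEIN_IDENTITY_MIN,
    overlap_identity_min: float = OVERLAP_IDENTITY_MIN,
    min_overlap: int = 40,
) -> tuple[list[tuple[Contig, AlignmentHit]], pd.DataFrame, list[Contig]]:
    """Group by best reference, merge, re-verify, filter, drop chimeras.

    Returns (retained annotated contigs, discard log, contigs passed on to
    the genome path).  The pass-on set is the unmatched contigs plus those
    discarded for annotation change or low identity; chimeric contigs are
    dropped outright.
    """
    best, _, unmatched = translated_best_hits(contigs, proteins, e_max)
    groups: dict[str, list[Contig]] = {}
    for contig in contigs:
        hit = best.get(contig.id)
        if hit is not None:
            groups.setdefault(hit.target_id, []).append(contig)

    retained: list[tuple[Contig, AlignmentHit]] = []
    discards: list[dict] = []
    pass_on: list[Contig] = list(unmatched)
    for ref in sorted(groups):
        merged = merge_overlapping(groups[ref], overlap_identity_min, min_overlap)
        new_best, new_all, new_unmatched = translated_best_hits(merged, proteins, e_max)
        for contig in merged:
            hit = new_best.get(contig.id)
            if hit is None or hit.target_id != ref:
                discards.append({"contig_id": contig.id, "reason": "annotation_changed"})
                pass_on.append(contig)
                continue
            if hit.percent_identity <= identity_min:
                discards.append({"contig_id": contig.id, "reason": "low_identity"})
                pass_on.append(contig)
                continue
            if detect_chimera(new_all.get(contig.id, [])):
                discards.append({"contig_id": contig.id, "reason": "chimeric"})
                continue
            retained.append((contig, hit))
    log = pd.DataFrame(discards, columns=["contig_id", "reason"])
    return retained, log, pass_on


# ---------------------------------------------------------------------------
# genome reference-based re-assembly

_GENOME_WORD = 15


class ScaffoldIndex:
    def __init__(self, scaffolds: dict[str, str]):
        from .align import build_position_index

        self.scaffolds = dict(scaffolds)
        self.db_len = sum(len(s) for s in scaffolds.values())
        self.position_index = {
            name: build_position_index(seq, _GENOME_WORD) for name, seq in scaffolds.items()
        }
        self.index: dict[str, set[str]] = {}
        for name, positions in self.position_index.items():
            for word in positions:
                self.index.setdefault(word, set()).add(name)

    def best_scaffold(self, contig_seq: str) -> str | None:
        votes: dict[str, int] = {}
        for query in (contig_seq, revcomp(contig_seq)):
            for i in range(len(query) - _GENOME_WORD + 1):
                for name in self.index.get(query[i : i + _GENOME_WORD], ()):
                    votes[name] = votes.get(name, 0) + 1
        if not votes:
            return None
        return min(votes, key=lambda n: (-votes[n], n))


def _percentile_cutoff(identities: list[float], retain_frac: float) -> float:
    """Nearest-rank (1 - retain_frac) percentile; ties at the cutoff are
    retained by the caller's >= comparison."""
    ordered = sorted(identities, reverse=True)
    m = math.ceil(retain_frac * len(ordered))
    return ordered[m - 1]


def _align_to_genome(contig: Contig, index: ScaffoldIndex, e_max: float):
    scaffold = index.best_scaffold(contig.seq)
    if scaffold is None:
        return None
    aln = spliced_align(
        contig.seq,
        index.scaffolds[scaffold],
        k=_GENOME_WORD,
        index=index.position_index[scaffold],
    )
    if aln is None:
        return None
    hit = hit_from_spliced(contig.id, scaffold, aln, index.db_len)
    if hit.e_value > e_max:
        return None
    return hit, aln.strand


def _genome_chimera(contig: Contig, hit: AlignmentHit, index: ScaffoldIndex) -> bool:
    """Re-align any >50 bp unaligned tail; a strong hit elsewhere flags the
    contig as chimeric (same rule as the protein path, on the query axis)."""
    tails = []
    if hit.query_start > CHIMERA_MIN_OUTSIDE:
        tails.append((0, hit.query_start))
    if len(contig.seq) - hit.query_end > CHIMERA_MIN_OUTSIDE:
        tails.append((hit.query_end, len(contig.seq)))
    secondary: list[AlignmentHit] = [hit]
    for start, end in tails:
        tail_seq = contig.seq[start:end]
        res = _align_to_genome(Contig(id=f"{contig.id}:tail", seq=tail_seq, stage=contig.stage), index, 1.0)
        if res is None:
            continue
        tail_hit = res[0]
        same_locus = tail_hit.target_id == hit.target_id and not (
            tail_hit.target_end < hit.target_start - 2000
            or tail_hit.target_start > hit.target_end + 2000
        )
        if same_locus:
            continue
        secondary.append(
            AlignmentHit(
                query_id=contig.id,
                target_id=f"{tail_hit.target_id}:{tail_hit.target_start}",
                query_start=start + tail_hit.query_start,
                query_end=start + tail_hit.query_end,
                target_start=tail_hit.target_start,
                target_end=tail_hit.target_end,
                frame=0,
                percent_identity=tail_hit.percent_identity,
                aligned_length=tail_hit.aligned_length,
                score=tail_hit.score,
                e_value=tail_hit.e_value,
            )
        )
    return detect_chimera(secondary)


def _classify(
    contig: Contig, hit: AlignmentHit, gene_models: list[GeneModel]
) -> tuple[str, str]:
    """(category, reference_id) from genomic position.

    Overlap with a gene model span wins; otherwise a contig aligned within
    1 kb of a model with >= 90% of its length in the alignment is a
    potential UTR; otherwise unannotated genomic.  Distances are measured
    strand-agnostically from the alignment interval to the nearer model
    boundary.
    """
    models = [m for m in gene_models if m.scaffold == hit.target_id]
    overlaps = [
        m
        for m in models
        if min(hit.target_end, m.end) - max(hit.target_start, m.start) > 0
    ]
    if overlaps:
        ref = max(
            overlaps,
            key=lambda m: min(hit.target_end, m.end) - max(hit.target_start, m.start),
        )
        return "gene_model_annotated", ref.gene_id
    coverage = (hit.query_end - hit.query_start) / len(contig.seq)
    nearest = None
    nearest_dist = None
    for m in models:
        dist = m.start - hit.target_end if hit.target_end <= m.start else hit.target_start - m.end
        if nearest_dist is None or dist < nearest_dist:
            nearest, nearest_dist = m, dist
    if (
        nearest is not None
        and nearest_dist <= UTR_MAX_DISTANCE
        and coverage >= UTR_MIN_COVERAGE
    ):
        return "utr", nearest.gene_id
    return "unannotated_genomic", hit.target_id


def genome_reassemble(
    contigs: list[Contig],
    scaffolds: dict[str, str],
    gene_models: list[GeneModel],
    e_max: float = E_VALUE_MAX,
    retain_frac: float = RETAIN_FRACTION,
    overlap_identity_min: float = OVERLAP_IDENTITY_MIN,
    min_overlap: int = 40,
) -> tuple[list[tuple[Contig, AlignmentHit, str, str]], pd.DataFrame, dict]:
    """Genome path: seed-match, spliced-align, top-95% retention, locus
    merge, re-verification, second retention pass, chimera removal and
    classification.  Returns (categorized contigs, discard log, realized
    data-dependent thresholds)."""
    index = ScaffoldIndex(scaffolds)
    discards: list[dict] = []
    aligned: list[tuple[Contig, AlignmentHit]] = []
    for contig in contigs:
        res = _align_to_genome(contig, index, e_max)
        if res is None:
            discards.append({"contig_id": contig.id, "reason": "no_genomic_hit"})
            continue
        hit, strand = res
        if strand == "-":  # normalize to scaffold forward strand for merging
            flipped = Contig(id=contig.id, seq=revcomp(contig.seq), stage=contig.stage)
            span = len(contig.seq)
            hit = AlignmentHit(
                query_id=hit.query_id,
                target_id=hit.target_id,
                query_start=span - hit.query_end,
                query_end=span - hit.query_start,
                target_start=hit.target_start,
                target_end=hit.target_end,
                frame=0,
                percent_identity=hit.percent_identity,
                aligned_length=hit.aligned_length,
                score=hit.score,
                e_value=hit.e_value,
            )
            aligned.append((flipped, hit))
        else:
            aligned.append((contig, hit))

    realized: dict[str, float | None] = {"identity_cutoff_pass1": None, "identity_cutoff_pass2": None}
    if not aligned:
        return [], pd.DataFrame(discards, columns=["contig_id", "reason"]), realized

    cutoff1 = _percentile_cutoff([h.percent_identity for _, h in aligned], retain_frac)
    realized["identity_cutoff_pass1"] = cutoff1
    kept1 = []
    for contig, hit in aligned:
        if hit.percent_identity >= cutoff1:
            kept1.append((contig, hit))
        else:
            discards.append({"contig_id": contig.id, "reason": "below_identity_percentile"})

    # group by overlapping genomic locus (union of alignment intervals)
    loci: list[dict] = []  # {"scaffold", "start", "end", "members"}
    for contig, hit in sorted(kept1, key=lambda ch: (ch[1].target_id, ch[1].target_start)):
        placed = None
        for locus in loci:
            if locus["scaffold"] == hit.target_id and not (
                hit.target_end < locus["start"] or hit.target_start > locus["end"]
            ):
                placed = locus
                break
        if placed is None:
            loci.append(
                {"scaffold": hit.target_id, "start": hit.target_start, "end": hit.target_end, "members": [contig]}
            )
        else:
            placed["start"] = min(placed["start"], hit.target_start)
            placed["end"] = max(placed["end"], hit.target_end)
            placed["members"].append(contig)

    merged_aligned: list[tuple[Contig, AlignmentHit, dict]] = []
    for locus in loci:
        merged = merge_overlapping(locus["members"], overlap_identity_min, min_overlap)
        for contig in merged:
            res = _align_to_genome(contig, index, e_max)
            if res is None:
                discards.append({"contig_id": contig.id, "reason": "no_genomic_hit"})
                continue
            hit, _ = res
            same_locus = hit.target_id == locus["scaffold"] and not (
                hit.target_end < locus["start"] or hit.target_start > locus["end"]
            )
            if not same_locus:
                discards.append({"contig_id": contig.id, "reason": "annotation_changed"})
                continue
            merged_aligned.append((contig, hit, locus))

    if not merged_aligned:
        return [], pd.DataFrame(discards, columns=["contig_id", "reason"]), realized
    cutoff2 = _percentile_cutoff([h.percent_identity for _, h, _ in merged_aligned], retain_frac)
    realized["identity_cutoff_pass2"] = cutoff2

    categorized: list[tuple[Contig, AlignmentHit, str, str]] = []
    for contig, hit, _ in merged_aligned:
        if hit.percent_identity < cutoff2:
            discards.append({"contig_id": contig.id, "reason": "below_identity_percentile"})
            continue
        if _genome_chimera(contig, hit, index):
            discards.append({"contig_id": contig.id, "reason": "chimeric"})
            continue
        category, ref = _classify(contig, hit, gene_models)
        categorized.append((contig, hit, category, ref))
    log = pd.DataFrame(discards, columns=["contig_id", "reason"])
    return categorized, log, realized


# ---------------------------------------------------------------------------
# final assembly and gene-model accounting


def gene_model_intersection(n_path1: int, n_path2: int, n_union: int) -> int:
    """Inclusion-exclusion: models shared by both re-assembly paths."""
    return n_path1 + n_path2 - n_union


def gene_model_union_fraction(n_union: int, n_reference_models: int) -> float:
    return n_union / n_reference_models


def build_final_assembly(
    protein_retained: list[tuple[Contig, AlignmentHit]],
    genome_retained: list[tuple[Contig, AlignmentHit, str, str]],
    n_reference_models: int | None = None,
) -> tuple[list[Unigene], dict]:
    """Concatenate both paths into the final unigene set and account for
    the distinct gene models each path represents."""
    unigenes: list[Unigene] = []
    seen: set[str] = set()
    protein_genes: set[str] = set()
    genome_genes: set[str] = set()
    for contig, hit in protein_retained:
        if contig.id in seen:
            raise ValueError(f"duplicate unigene id {contig.id}")
        seen.add(contig.id)
        unigenes.append(
            Unigene(
                id=contig.id,
                seq=contig.seq,
                category="protein_annotated",
                reference_id=hit.target_id,
                annotation_identity=hit.percent_identity,
            )
        )
        protein_genes.add(hit.target_id.removeprefix("PROT_"))
    for contig, hit, category, ref in genome_retained:
        if contig.id in seen:
            raise ValueError(f"duplicate unigene id {contig.id}")
        seen.add(contig.id)
        unigenes.append(
            Unigene(
                id=contig.id,
                seq=contig.seq,
                category=category,
                reference_id=ref,
                annotation_identity=hit.percent_identity,
            )
        )
        if category in ("gene_model_annotated", "utr"):
            genome_genes.add(ref)
    union = protein_genes | genome_genes
    accounting = {
        "n_gene_models_protein_path": len(protein_genes),
        "n_gene_models_genome_path": len(genome_genes),
        "n_gene_models_union": len(union),
        "n_gene_models_intersection": gene_model_intersection(
            len(protein_genes), len(genome_genes), len(union)
        ),
    }
    if n_reference_models:
        accounting["union_fraction_of_reference"] = gene_model_union_fraction(
            len(union), n_reference_models
        )
    return unigenes, accounting
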