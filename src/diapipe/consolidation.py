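"""Within-stage redundancy elimination and the overlap-consensus merge
primitive shared by both re-assembly paths.

``cluster_within_stage`` is a greedy longest-first clusterer in the
CD-HIT-EST style: identity is computed globally over the alignable span of
the shorter sequence, so contained fragments cluster with their parents.
``merge_overlapping`` is the CAP3-like step: iteratively joins the best
suffix-prefix or containment overlap above an identity floor, taking a
per-column majority consensus (ties go to the longer parent).
"""

from __future__ import annotations

import pandas as pd

from .align import find_overlap, identity_over_shorter, merge_by_overlap
from .records import Contig, revcomp

_PREFILTER_K = 16


def cluster_within_stage(
    contigs: list[Contig], identity_threshold: float = 0.99
) -> tuple[list[Contig], pd.DataFrame]:
    """Greedy longest-first clustering; returns representatives and the
    cluster table (representative_id, member_id, identity)."""
    stages = {c.stage for c in contigs}
    if len(stages) > 1:
        raise ValueError(f"contigs span multiple stages: {sorted(stages)}")
    ids = [c.id for c in contigs]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate contig ids within a stage")

    ordered = sorted(contigs, key=lambda c: (-len(c), c.id))
    reps: list[Contig] = []
    rep_order: dict[str, int] = {}
    # shared-word index over representatives: k-mer -> rep ids
    index: dict[str, set[str]] = {}
    rows = []
    for contig in ordered:
        cand: set[str] = set()
        for query in (contig.seq, revcomp(contig.seq)):
            for i in range(0, len(query) - _PREFILTER_K + 1, 4):
                hit = index.get(query[i : i + _PREFILTER_K])
                if hit:
                    cand |= hit
        assigned = None
        for rep_id in sorted(cand, key=rep_order.__getitem__):
            rep = reps[rep_order[rep_id]]
            ident = identity_over_shorter(contig.seq, rep.seq)
            if ident >= identity_threshold:
                assigned = (rep_id, ident)
                break
        if assigned is None:
            rep_order[contig.id] = len(reps)
            reps.append(contig)
            for i in range(len(contig.seq) - _PREFILTER_K + 1):
                index.setdefault(contig.seq[i : i + _PREFILTER_K], set()).add(contig.id)
            rows.append(
                {"representative_id": contig.id, "member_id": contig.id, "identity": 1.0}
            )
        else:
            rows.append(
                {
                    "representative_id": assigned[0],
                    "member_id": contig.id,
                    "identity": assigned[1],
                }
            )
    table = pd.DataFrame(rows, columns=["representative_id", "member_id", "identity"])
    return reps, table


def merge_overlapping(
    group: list[Contig],
    overlap_identity_min: float = 0.95,
    min_overlap: int = 40,
) -> list[Contig]:
    """Iteratively merge the best-overlapping pair in a group to fixpoint.

    Both orientations are tried; when a reverse-complement overlap wins,
    the shorter-id contig's orientation is kept.  Contigs with no
    qualifying overlap pass through unchanged.  The merged contig inherits
    the id (and stage) of its longer parent, which keeps the operation
    idempotent and the output ids stable.
    """
    work = {c.id: c for c in sorted(group, key=lambda c: (-len(c), c.id))}
    while True:
        best = None  # (overlap, id_a, id_b, seq_a, seq_b)
        items = sorted(work.values(), key=lambda c: (-len(c), c.id))
        for i, a in enumerate(items):
            for b in items[i + 1 :]:
                for b_seq, flipped in ((b.seq, False), (revcomp(b.seq), True)):
                    ov = find_overlap(a.id, a.seq, b.id, b_seq, min_overlap, overlap_identity_min)
                    if ov is None:
                        continue
                    if best is None or (ov.length, ov.identity) > (
                        best[0].length,
                        best[0].identity,
                    ):
                        seqs = {a.id: a.seq, b.id: b_seq}
                        best = (ov, a, b, seqs)
        if best is None:
            break
        ov, a, b, seqs = best
        merged_seq = merge_by_overlap(seqs[ov.left], seqs[ov.right], ov)
        parent = a if len(a) >= len(b) else b
        del work[a.id]
        del work[b.id]
        work[parent.id] = Contig(id=parent.id, seq=merged_seq, stage=parent.stage)
    return sorted(work.values(), key=lambda c: c.id)
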