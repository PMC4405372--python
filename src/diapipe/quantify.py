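"""Read mapping to the final assembly and EM allocation of multi-mapping
pairs into unigene-level expected counts.

Allelic variants and isoform fragments that annotate to the same
reference gene collapse into one counting unit before the EM, so expected
counts are directly comparable to gene-level truth.  The EM itself is the
standard abundance model: a multi-mapping pair is assigned fractionally in
proportion to theta_u / effective_length_u over its candidates, with
expected counts conserved exactly.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .records import ReadPair, Unigene, revcomp

_MAP_WORD = 31


@dataclass
class CountMatrix:
    values: np.ndarray  # units x libraries, expected counts
    unigene_ids: list[str]
    library_ids: list[str]
    effective_lengths: np.ndarray
    lengths: np.ndarray | None = None  # unit lengths in bp

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.unigene_ids, columns=self.library_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, effective_lengths=None) -> "CountMatrix":
        eff = (
            np.asarray(effective_lengths, dtype=float)
            if effective_lengths is not None
            else np.ones(len(df))
        )
        return cls(
            values=df.to_numpy(dtype=float),
            unigene_ids=list(df.index),
            library_ids=list(df.columns),
            effective_lengths=eff,
        )


class UnigeneIndex:
    """Exact-word index over counting units.

    Unigenes whose annotation points at the same reference gene share a
    unit (the collapsing the unigene table defines); UTR and unannotated
    contigs count as themselves.
    """

    def __init__(self, unigenes: list[Unigene], insert_mean: int = 203):
        unit_of: dict[str, int] = {}
        self.unit_ids: list[str] = []
        self.unit_lengths: list[int] = []
        self.seqs: list[tuple[int, str]] = []  # (unit, sequence)
        for u in unigenes:
            if u.category == "protein_annotated":
                unit_key = u.reference_id.removeprefix("PROT_")
            elif u.category == "gene_model_annotated":
                unit_key = u.reference_id
            else:
                unit_key = u.id
            if unit_key not in unit_of:
                unit_of[unit_key] = len(self.unit_ids)
                self.unit_ids.append(unit_key)
                self.unit_lengths.append(0)
            unit = unit_of[unit_key]
            self.unit_lengths[unit] = max(self.unit_lengths[unit], len(u.seq))
            self.seqs.append((unit, u.seq))
        if not self.seqs:
            raise ValueError("cannot index an empty unigene set")
        self.effective_lengths = np.maximum(
            1, np.asarray(self.unit_lengths) - insert_mean + 1
        ).astype(float)
        self.index: dict[str, list[tuple[int, int]]] = {}
        for si, (unit, seq) in enumerate(self.seqs):
            for i in range(len(seq) - _MAP_WORD + 1):
                self.index.setdefault(seq[i : i + _MAP_WORD], []).append((si, i))

    def place_read(self, seq: str, max_mismatch: int) -> dict[tuple[int, str], int]:
        """{(seq_idx, orientation): position} of consistent placements."""
        out: dict[tuple[int, str], int] = {}
        for orient, q in (("+", seq), ("-", revcomp(seq))):
            L = len(q)
            if L < _MAP_WORD:
                continue
            for off in (0, L // 2, L - _MAP_WORD):
                hits = self.index.get(q[off : off + _MAP_WORD])
                if not hits:
                    continue
                for si, pos in hits:
                    start = pos - off
                    _, target = self.seqs[si]
                    if start < 0 or start + L > len(target):
                        continue
                    window = target[start : start + L]
                    if window == q or _hamming(window, q) <= max_mismatch:
                        key = (si, orient)
                        if key not in out:
                            out[key] = start
                break  # first seeding offset with index hits decides
        return out


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def map_pairs(
    pairs: list[ReadPair],
    index: UnigeneIndex,
    max_mismatch: int = 2,
    insert_range: tuple[int, int] = (50, 600),
) -> tuple[list[frozenset[int]], int]:
    """Concordant candidate unit sets per pair; unmapped pairs counted.

    A candidate requires both mates placed on the same indexed sequence in
    opposite orientations with an implied insert inside ``insert_range``.
    """
    lo, hi = insert_range
    candidate_sets: list[frozenset[int]] = []
    n_unmapped = 0
    for pair in pairs:
        p1 = index.place_read(pair.r1.seq, max_mismatch)
        p2 = index.place_read(pair.r2.seq, max_mismatch)
        units: set[int] = set()
        for (si, o1), s1 in p1.items():
            o2 = "-" if o1 == "+" else "+"
            s2 = p2.get((si, o2))
            if s2 is None:
                continue
            left, right = (s1, s2) if o1 == "+" else (s2, s1)
            insert = (right + (len(pair.r2.seq) if o1 == "+" else len(pair.r1.seq))) - left
            if lo <= insert <= hi:
                units.add(index.seqs[si][0])
        if units:
            candidate_sets.append(frozenset(units))
        else:
            n_unmapped += 1
    return candidate_sets, n_unmapped


def em_quantify(
    candidate_sets: list[frozenset[int]],
    effective_lengths: np.ndarray,
    n_units: int | None = None,
    tol: float = 1e-8,
    max_iter: int = 1000,
) -> np.ndarray:
    """Expected counts per unit from candidate sets via EM.

    E-step: each pair is split across its candidates proportionally to
    theta_u / effective_length_u; M-step re-estimates theta from the
    fractional counts.  Unique pairs are fixed points and counts are
    conserved to machine precision.
    """
    eff = np.asarray(effective_lengths, dtype=float)
    n = n_units if n_units is not None else len(eff)
    counts = np.zeros(n)
    if not candidate_sets:
        return counts
    classes = Counter(candidate_sets)
    class_units = [np.fromiter(c, dtype=int) for c in classes]
    class_counts = np.array(list(classes.values()), dtype=float)
    theta = np.full(n, 1.0 / n)
    for _ in range(max_iter):
        counts = np.zeros(n)
        for units, c in zip(class_units, class_counts):
            w = theta[units] / eff[units]
            total = w.sum()
            if total <= 0:
                w = np.full(len(units), 1.0 / len(units))
                total = 1.0
            counts[units] += c * w / total
        new_theta = counts / counts.sum()
        delta = np.max(np.abs(new_theta - theta))
        theta = new_theta
        if delta < tol:
            break
    return counts


def em_log_likelihood(
    candidate_sets: list[frozenset[int]], theta: np.ndarray, effective_lengths: np.ndarray
) -> float:
    ll = 0.0
    for units in candidate_sets:
        idx = np.fromiter(units, dtype=int)
        ll += float(np.log((theta[idx] / effective_lengths[idx]).sum() + 1e-300))
    return ll


def quantify_libraries(
    libraries: dict[str, list[ReadPair]],
    unigenes: list[Unigene],
    insert_mean: int = 203,
    max_mismatch: int = 2,
) -> tuple[CountMatrix, pd.DataFrame]:
    """Map and EM-quantify every library against one shared index."""
    index = UnigeneIndex(unigenes, insert_mean=insert_mean)
    n_units = len(index.unit_ids)
    columns = {}
    summary_rows = []
    for lib_id, pairs in libraries.items():
        candidate_sets, n_unmapped = map_pairs(pairs, index, max_mismatch=max_mismatch)
        counts = em_quantify(candidate_sets, index.effective_lengths, n_units)
        columns[lib_id] = counts
        n_total = len(pairs)
        summary_rows.append(
            {
                "library_id": lib_id,
                "total_pairs": n_total,
                "mapped_pairs": len(candidate_sets),
                "fraction_mapped": len(candidate_sets) / n_total if n_total else float("nan"),
            }
        )
    values = np.column_stack([columns[lib] for lib in libraries]) if columns else np.zeros((n_units, 0))
    matrix = CountMatrix(
        values=values,
        unigene_ids=list(index.unit_ids),
        library_ids=list(libraries),
        effective_lengths=index.effective_lengths,
        lengths=np.asarray(index.unit_lengths, dtype=float),
    )
    summary = pd.DataFrame(
        summary_rows, columns=["library_id", "total_pairs", "mapped_pairs", "fraction_mapped"]
    )
    return matrix, summary
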