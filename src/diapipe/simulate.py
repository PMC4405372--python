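"""Synthetic-data generator for the diapause-induction RNA-seq pipeline.

Emulates, at desk scale, the inputs the analysis consumes: genomic
scaffolds with intron-bearing gene models, a non-redundant protein
reference, multi-stage contig sets carrying redundancy / fragments /
UTR-only pieces / chimeras, and 16 paired-end libraries (2 photoperiods x
2 blood-meal states x 4 replicates) with negative-binomial gene counts,
planted photoperiod / blood-meal / interaction effects, vector and adapter
contamination, and 3'-degraded qualities.

Everything is a deterministic function of ``SimConfig.seed``; each phase
draws from its own child generator so stages can be re-run independently.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as dio
from .records import Contig, GeneModel, Read, ReadPair, revcomp

logger = logging.getLogger(__name__)

BASES = np.array(list("ACGT"))
CONDITIONS = ("LD_NB", "LD_BM", "SD_NB", "SD_BM")
STAGES = ("adult", "oocyte", "embryo", "pharate_larva")

# 3' end of the Illumina TruSeq indexed adapter; used as the multiplexing
# adapter the screening stage must remove at 100% identity.
ADAPTER_SEQ = "AGATCGGAAGAGCACACGTCTGAACTCCAGTCAC"


class ConfigError(ValueError):
    """Raised when a SimConfig field is out of range; names the field."""


@dataclass
class SimConfig:
    seed: int = 0
    n_scaffolds: int = 4
    n_genes: int = 200
    gene_length_range: tuple[int, int] = (600, 1800)  # CDS bp
    utr_length_range: tuple[int, int] = (100, 250)
    n_stages: int = 3
    contig_redundancy_rate: float = 0.3
    chimera_rate: float = 0.05
    n_libraries: int = 16
    mean_library_size: int = 20_000  # read pairs per library
    nb_dispersion: float = 0.1
    effect_log2fc: dict = field(
        default_factory=lambda: {"photoperiod": 2.0, "bloodmeal": 2.0, "interaction": 2.0}
    )
    frac_de: float = 0.1
    read_length: int = 101
    insert_mean: int = 203
    insert_sd: int = 20
    contamination_rate: float = 0.01
    # logistic phred decay along the read: q(i) = q3 + (q5-q3)/(1+exp(s*(i-mid)))
    quality_decay: dict = field(
        default_factory=lambda: {"q5": 39.0, "q3": 22.0, "midpoint": 85.0, "steepness": 0.15, "noise_sd": 2.0}
    )
    # contig-set texture
    fragment_rate: float = 0.4
    utr_contig_rate: float = 0.25
    intergenic_contigs_per_scaffold: int = 2
    allelic_snp_rate: float = 0.003
    max_introns: int = 2
    intron_length_range: tuple[int, int] = (50, 500)
    intergenic_gap: int = 2500
    n_replicates: int = 4

    def validate(self) -> None:
        for name in (
            "contig_redundancy_rate",
            "chimera_rate",
            "frac_de",
            "contamination_rate",
            "fragment_rate",
            "utr_contig_rate",
            "allelic_snp_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        for name in ("n_scaffolds", "n_stages", "read_length", "insert_mean"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be positive")
        if self.n_genes < 0:
            raise ConfigError("n_genes must be non-negative")
        if self.mean_library_size < 0:
            raise ConfigError("mean_library_size must be non-negative")
        if self.nb_dispersion < 0:
            raise ConfigError("nb_dispersion must be non-negative")
        if self.n_stages > len(STAGES):
            raise ConfigError(f"n_stages must be <= {len(STAGES)}")
        if self.n_libraries != 4 * self.n_replicates:
            raise ConfigError(
                "n_libraries must equal 4 * n_replicates (2x2 factorial design)"
            )

    def rng(self, phase: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, phase])


@dataclass
class TruthSet:
    """Ground truth behind every synthetic artifact."""

    scaffolds: dict[str, str]
    gene_models: list[GeneModel]
    transcripts: dict[str, str]  # gene_id -> mature mRNA (UTR5+CDS+UTR3)
    cds: dict[str, str]
    proteins: dict[str, str]  # protein_id ("PROT_<gene>") -> aa sequence
    condition_means: pd.DataFrame  # genes x CONDITIONS relative expression
    planted_lfc: pd.DataFrame  # genes x {photoperiod, bloodmeal, interaction}
    pathways: dict[str, set[str]]
    planted_pathway: str
    vectors: dict[str, str]
    adapters: dict[str, str]
    contig_labels: pd.DataFrame | None = None  # filled by generate_contig_sets
    true_counts: pd.DataFrame | None = None  # filled by generate_reads

    @property
    def gene_ids(self) -> list[str]:
        return list(self.transcripts)

    def gene_of_protein(self, protein_id: str) -> str:
        return protein_id.removeprefix("PROT_")


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(BASES[rng.integers(0, 4, size=length)])


_STOPS = {"TAA", "TAG", "TGA"}


def _random_cds(rng: np.random.Generator, length: int) -> str:
    """In-frame CDS: ATG, random non-stop codons, one stop codon."""
    n_codons = max(length // 3, 4)
    codons = ["ATG"]
    while len(codons) < n_codons - 1:
        codon = _random_seq(rng, 3)
        if codon not in _STOPS:
            codons.append(codon)
    codons.append("TAA")
    return "".join(codons)


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    arr = np.array(list(seq))
    hits = np.flatnonzero(rng.random(len(arr)) < rate)
    for i in hits:
        choices = [b for b in "ACGT" if b != arr[i]]
        arr[i] = choices[rng.integers(0, 3)]
    return "".join(arr)


# ---------------------------------------------------------------------------
# references


def generate_references(config: SimConfig) -> TruthSet:
    """Build scaffolds, gene models, proteins, transcripts, expression truth
    and the pathway map."""
    config.validate()
    rng = config.rng(1)
    from .align import translate

    scaffold_parts: dict[str, list[str]] = {
        f"scaffold_{i+1}": [] for i in range(config.n_scaffolds)
    }
    scaffold_pos = {s: 0 for s in scaffold_parts}
    gene_models: list[GeneModel] = []
    transcripts: dict[str, str] = {}
    cds_map: dict[str, str] = {}
    proteins: dict[str, str] = {}

    lo, hi = config.gene_length_range
    ulo, uhi = config.utr_length_range
    ilo, ihi = config.intron_length_range
    scaffold_names = list(scaffold_parts)
    for g in range(config.n_genes):
        gid = f"g{g+1:04d}"
        cds = _random_cds(rng, int(rng.integers(lo, hi + 1)))
        utr5 = _random_seq(rng, int(rng.integers(ulo, uhi + 1)))
        utr3 = _random_seq(rng, int(rng.integers(ulo, uhi + 1)))
        mrna = utr5 + cds + utr3
        # split mRNA into exons by inserting introns at random positions
        n_introns = int(rng.integers(0, config.max_introns + 1))
        cut_points = sorted(
            rng.choice(np.arange(50, len(mrna) - 50), size=n_introns, replace=False)
        ) if n_introns else []
        pre_mrna_parts = []
        prev = 0
        for cp in cut_points:
            pre_mrna_parts.append(mrna[prev:cp])
            pre_mrna_parts.append(_random_seq(rng, int(rng.integers(ilo, ihi + 1))))
            prev = cp
        pre_mrna_parts.append(mrna[prev:])
        locus = "".join(pre_mrna_parts)
        strand = "+" if rng.random() < 0.5 else "-"
        genomic = locus if strand == "+" else revcomp(locus)

        scaffold = scaffold_names[g % config.n_scaffolds]
        gap = _random_seq(rng, config.intergenic_gap)
        scaffold_parts[scaffold].append(gap)
        scaffold_pos[scaffold] += len(gap)
        start = scaffold_pos[scaffold]
        scaffold_parts[scaffold].append(genomic)
        scaffold_pos[scaffold] += len(genomic)
        gene_models.append(
            GeneModel(gene_id=gid, scaffold=scaffold, start=start, end=start + len(genomic), strand=strand)
        )
        transcripts[gid] = mrna
        cds_map[gid] = cds
        proteins[f"PROT_{gid}"] = translate(cds)[:-1]  # drop the stop

    for s in scaffold_parts:  # trailing gap so last genes are not at the edge
        scaffold_parts[s].append(_random_seq(rng, config.intergenic_gap))
    scaffolds = {s: "".join(parts) for s, parts in scaffold_parts.items()}

    gene_ids = list(transcripts)
    base_mean = np.exp(rng.normal(3.0, 1.0, size=len(gene_ids)))
    lfc = pd.DataFrame(
        0.0, index=gene_ids, columns=["photoperiod", "bloodmeal", "interaction"]
    )
    n_de = int(round(config.frac_de * len(gene_ids)))
    order = rng.permutation(len(gene_ids))
    slices = {
        "photoperiod": order[:n_de],
        "bloodmeal": order[n_de : 2 * n_de],
        "interaction": order[2 * n_de : 3 * n_de],
    }
    for effect, idx in slices.items():
        magnitude = config.effect_log2fc.get(effect, 0.0)
        signs = np.where(rng.random(len(idx)) < 0.7, 1.0, -1.0)
        lfc.iloc[idx, lfc.columns.get_loc(effect)] = magnitude * signs

    cond = pd.DataFrame(index=gene_ids, columns=list(CONDITIONS), dtype=float)
    for c in CONDITIONS:
        photo = 1.0 if c.startswith("SD") else 0.0
        blood = 1.0 if c.endswith("BM") else 0.0
        log2_mu = (
            np.log2(base_mean)
            + photo * lfc["photoperiod"].to_numpy()
            + blood * lfc["bloodmeal"].to_numpy()
            + photo * blood * lfc["interaction"].to_numpy()
        )
        cond[c] = 2.0 ** log2_mu

    pathways, planted = _build_pathways(rng, gene_ids, lfc)
    vectors = {f"vector_{i+1}": _random_seq(rng, 600) for i in range(3)}
    adapters = {"truseq_adapter": ADAPTER_SEQ}

    return TruthSet(
        scaffolds=scaffolds,
        gene_models=gene_models,
        transcripts=transcripts,
        cds=cds_map,
        proteins=proteins,
        condition_means=cond,
        planted_lfc=lfc,
        pathways=pathways,
        planted_pathway=planted,
        vectors=vectors,
        adapters=adapters,
    )


def _build_pathways(rng, gene_ids: list[str], lfc: pd.DataFrame):
    """Partition genes into pathway-sized sets; one pathway is packed with
    photoperiod-responsive genes so enrichment has a known positive."""
    if not gene_ids:
        return {}, ""
    photo_de = [g for g in gene_ids if lfc.at[g, "photoperiod"] != 0.0]
    non_de = [g for g in gene_ids if lfc.at[g, "photoperiod"] == 0.0]
    planted_members = photo_de[: min(12, len(photo_de))] + non_de[:4]
    pathways = {"path_planted": set(planted_members)}
    remaining = [g for g in gene_ids if g not in pathways["path_planted"]]
    rng.shuffle(remaining)
    i = 0
    pid = 1
    while i < len(remaining):
        size = int(rng.integers(8, 26))
        members = remaining[i : i + size]
        if len(members) >= 3:
            pathways[f"path_{pid:03d}"] = set(members)
            pid += 1
        i += size
    return pathways, "path_planted"


# ---------------------------------------------------------------------------
# contig sets


def generate_contig_sets(
    truth: TruthSet, config: SimConfig
) -> tuple[dict[str, list[Contig]], pd.DataFrame]:
    """Per-stage contig FASTA content plus truth labels.

    Each stage carries full-length transcript contigs, overlapping
    fragments, near-identical allelic duplicates, UTR-flank pieces placed
    within 1 kb of gene models, intergenic pieces, and two-gene chimeras at
    ``chimera_rate``.
    """
    config.validate()
    rng = config.rng(2)
    stages = list(STAGES[: config.n_stages])
    by_stage: dict[str, list[Contig]] = {s: [] for s in stages}
    labels: list[dict] = []
    gene_ids = truth.gene_ids
    model_by_gene = {m.gene_id: m for m in truth.gene_models}

    counter = 0

    def emit(stage, seq, kind, gene_id="", gene_id2=""):
        nonlocal counter
        counter += 1
        cid = f"{stage}_c{counter:05d}"
        by_stage[stage].append(Contig(id=cid, seq=seq, stage=stage))
        labels.append(
            {"contig_id": cid, "stage": stage, "kind": kind, "gene_id": gene_id, "gene_id2": gene_id2}
        )
        return cid

    for stage_i, stage in enumerate(stages):
        # the first stage (adult) carries every gene; later stages subsample
        present = gene_ids if stage_i == 0 else [
            g for g in gene_ids if rng.random() < 0.8
        ]
        for gid in present:
            mrna = truth.transcripts[gid]
            if rng.random() < config.fragment_rate and len(mrna) > 400:
                cut = int(len(mrna) * rng.uniform(0.45, 0.6))
                ov = int(rng.integers(80, 150))
                emit(stage, mrna[: cut + ov // 2], "fragment", gid)
                emit(stage, mrna[cut - ov // 2 :], "fragment", gid)
            else:
                emit(stage, mrna, "full", gid)
            if rng.random() < config.contig_redundancy_rate:
                emit(stage, _mutate(rng, mrna, config.allelic_snp_rate), "duplicate", gid)
            if rng.random() < config.utr_contig_rate:
                m = model_by_gene[gid]
                flank_len = int(rng.integers(150, 400))
                upstream = rng.random() < 0.5
                gap = int(rng.integers(10, 500))
                scaffold = truth.scaffolds[m.scaffold]
                if upstream:
                    end = max(m.start - gap, 0)
                    seq = scaffold[max(end - flank_len, 0) : end]
                else:
                    start = min(m.end + gap, len(scaffold))
                    seq = scaffold[start : start + flank_len]
                if len(seq) >= 100:
                    emit(stage, seq, "utr", gid)
        # chimeras: junction of two distinct genes, both segments > 150 bp
        n_chim = int(round(config.chimera_rate * len(present)))
        for _ in range(n_chim):
            if len(present) < 2:
                break
            ga, gb = rng.choice(present, size=2, replace=False)
            a, b = truth.transcripts[ga], truth.transcripts[gb]
            seg_a = a[: int(len(a) * rng.uniform(0.4, 0.6))]
            seg_b = b[int(len(b) * rng.uniform(0.4, 0.6)) :]
            emit(stage, seg_a + seg_b, "chimera", ga, gb)
        # unannotated genomic pieces from deep intergenic space
        for sname, sseq in truth.scaffolds.items():
            for _ in range(config.intergenic_contigs_per_scaffold):
                seq = _intergenic_segment(rng, sname, sseq, truth.gene_models, config)
                if seq:
                    emit(stage, seq, "intergenic", "")

    label_df = pd.DataFrame(
        labels, columns=["contig_id", "stage", "kind", "gene_id", "gene_id2"]
    )
    truth.contig_labels = label_df
    return by_stage, label_df


def _intergenic_segment(rng, sname, sseq, models, config, length=300, min_dist=1500):
    """A segment at least ``min_dist`` from every gene span on the scaffold."""
    spans = [(m.start, m.end) for m in models if m.scaffold == sname]
    for _ in range(20):
        start = int(rng.integers(0, max(len(sseq) - length, 1)))
        if all(start + length + min_dist <= s or start >= e + min_dist for s, e in spans):
            return sseq[start : start + length]
    return ""


# ---------------------------------------------------------------------------
# reads


def build_design(config: SimConfig) -> pd.DataFrame:
    rows = []
    for pp in ("SD", "LD"):
        for bm in ("BM", "NB"):
            for rep in range(1, config.n_replicates + 1):
                rows.append(
                    {
                        "library_id": f"{pp}_{bm}_{rep}",
                        "photoperiod": pp,
                        "bloodmeal": bm,
                        "replicate": rep,
                    }
                )
    return pd.DataFrame(rows)


def _quality_profile(rng, n_reads: int, read_len: int, decay: dict) -> np.ndarray:
    pos = np.arange(read_len, dtype=float)
    base = decay["q3"] + (decay["q5"] - decay["q3"]) / (
        1.0 + np.exp(decay["steepness"] * (pos - decay["midpoint"]))
    )
    noise = rng.normal(0.0, decay["noise_sd"], size=(n_reads, read_len))
    return np.clip(np.round(base[None, :] + noise), 2, 41).astype(np.uint8)


def draw_nb_counts(mu, dispersion: float, rng) -> np.ndarray:
    """Negative-binomial fragment counts with mean ``mu`` and variance
    mu + mu^2 * dispersion (Poisson when dispersion is zero)."""
    mu = np.asarray(mu, dtype=float)
    if dispersion > 0:
        n_param = 1.0 / dispersion
        return rng.negative_binomial(n_param, n_param / (n_param + mu))
    return rng.poisson(mu)


def usable_genes(truth: TruthSet, config: SimConfig) -> list[str]:
    return [g for g in truth.gene_ids if len(truth.transcripts[g]) >= config.insert_mean]


def draw_library_counts(
    truth: TruthSet, config: SimConfig, condition: str, lib_rng
) -> pd.Series:
    """Per-gene fragment counts for one library of the given condition."""
    usable = usable_genes(truth, config)
    counts = pd.Series(0, index=truth.gene_ids, dtype=int)
    if config.mean_library_size > 0 and usable:
        lib_size = int(round(config.mean_library_size * lib_rng.lognormal(0.0, 0.1)))
        mu_rel = truth.condition_means.loc[usable, condition].to_numpy()
        mu = mu_rel / mu_rel.sum() * lib_size
        counts.loc[usable] = draw_nb_counts(mu, config.nb_dispersion, lib_rng)
    return counts


def generate_library_reads(
    truth: TruthSet, config: SimConfig, library_id: str, condition: str, lib_rng
) -> tuple[list[ReadPair], pd.Series]:
    """Read pairs for one library plus the true per-gene fragment counts."""
    rl = config.read_length
    gene_ids = truth.gene_ids
    usable = usable_genes(truth, config)
    skipped = set(gene_ids) - set(usable)
    for g in sorted(skipped):
        logger.warning("library %s: transcript %s shorter than mean insert, skipped", library_id, g)

    true_counts = draw_library_counts(truth, config, condition, lib_rng)
    pairs: list[ReadPair] = []
    if config.mean_library_size > 0 and usable:
        for g in usable:
            c = int(true_counts[g])
            t = truth.transcripts[g]
            L = len(t)
            if c == 0:
                continue
            inserts = np.clip(
                np.round(lib_rng.normal(config.insert_mean, config.insert_sd, size=c)),
                rl,
                L,
            ).astype(int)
            starts = (lib_rng.random(c) * (L - inserts + 1)).astype(int)
            for i, (s, ins) in enumerate(zip(starts, inserts)):
                frag = t[s : s + ins]
                pairs.append(_make_pair(f"{library_id}:{g}:{i}", frag, rl))
        # contaminated pairs: half vector-derived, half adapter read-through
        n_cont = int(lib_rng.binomial(len(pairs), config.contamination_rate)) if pairs else 0
        vec_names = list(truth.vectors)
        for i in range(n_cont):
            if i % 2 == 0:
                vname = vec_names[int(lib_rng.integers(0, len(vec_names)))]
                vseq = truth.vectors[vname]
                s = int(lib_rng.integers(0, max(len(vseq) - config.insert_mean, 1)))
                frag = vseq[s : s + config.insert_mean]
                pairs.append(_make_pair(f"{library_id}:vector:{i}", frag, rl))
            else:
                gid = usable[int(lib_rng.integers(0, len(usable)))]
                t = truth.transcripts[gid]
                short = int(lib_rng.integers(40, rl - 20))
                s = int(lib_rng.integers(0, len(t) - short))
                frag = t[s : s + short]
                insert = frag + ADAPTER_SEQ
                r1 = (insert + ADAPTER_SEQ)[:rl]
                r2 = (revcomp(insert) + ADAPTER_SEQ)[:rl]
                pairs.append(
                    ReadPair(
                        Read(f"{library_id}:adapter:{i}/1", r1, np.full(rl, 38, np.uint8)),
                        Read(f"{library_id}:adapter:{i}/2", r2, np.full(rl, 38, np.uint8)),
                    )
                )
    # assign qualities in one vectorized draw
    quals = _quality_profile(lib_rng, 2 * len(pairs), rl, config.quality_decay)
    for idx, pair in enumerate(pairs):
        pair.r1.qual = quals[2 * idx][: len(pair.r1.seq)]
        pair.r2.qual = quals[2 * idx + 1][: len(pair.r2.seq)]
    return pairs, true_counts


def _make_pair(pair_id: str, frag: str, rl: int) -> ReadPair:
    r1 = frag[:rl]
    r2 = revcomp(frag)[:rl]
    q = np.full(rl, 38, dtype=np.uint8)
    return ReadPair(
        Read(f"{pair_id}/1", r1, q[: len(r1)]), Read(f"{pair_id}/2", r2, q[: len(r2)])
    )


def generate_reads(
    truth: TruthSet, config: SimConfig
) -> tuple[dict[str, list[ReadPair]], pd.DataFrame, pd.DataFrame]:
    """All libraries' read pairs, the design table, and true counts."""
    config.validate()
    design = build_design(config)
    libraries: dict[str, list[ReadPair]] = {}
    counts = {}
    for i, row in enumerate(design.itertuples(index=False)):
        condition = f"{row.photoperiod}_{row.bloodmeal}"
        lib_rng = np.random.default_rng([config.seed, 3, i])
        pairs, true_counts = generate_library_reads(
            truth, config, row.library_id, condition, lib_rng
        )
        libraries[row.library_id] = pairs
        counts[row.library_id] = true_counts
    truth.true_counts = pd.DataFrame(counts)
    return libraries, design, truth.true_counts


# ---------------------------------------------------------------------------
# writing everything to a directory


def simulate_to_dir(config: SimConfig, outdir: str | Path) -> TruthSet:
    """Generate every pipeline input under ``outdir`` (plain-text formats)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    truth = generate_references(config)
    dio.write_fasta(outdir / "scaffolds.fasta", truth.scaffolds.items())
    dio.write_gene_models(outdir / "gene_models.tsv", truth.gene_models)
    dio.write_fasta(outdir / "proteins.fasta", truth.proteins.items())
    dio.write_fasta(outdir / "transcripts.fasta", truth.transcripts.items())
    dio.write_fasta(outdir / "vectors.fasta", truth.vectors.items())
    dio.write_fasta(outdir / "adapters.fasta", truth.adapters.items())
    dio.write_pathways(outdir / "pathways.tsv", truth.pathways)

    by_stage, labels = generate_contig_sets(truth, config)
    for stage, contigs in by_stage.items():
        dio.write_fasta(outdir / f"contigs_{stage}.fasta", ((c.id, c.seq) for c in contigs))
    labels.to_csv(outdir / "contig_truth.tsv", sep="\t", index=False)

    libraries, design, true_counts = generate_reads(truth, config)
    design.to_csv(outdir / "design.tsv", sep="\t", index=False)
    true_counts.to_csv(outdir / "true_counts.tsv", sep="\t")
    for lib, pairs in libraries.items():
        dio.write_fastq(outdir / f"{lib}_R1.fastq", (p.r1 for p in pairs))
        dio.write_fastq(outdir / f"{lib}_R2.fastq", (p.r2 for p in pairs))
    return truth
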