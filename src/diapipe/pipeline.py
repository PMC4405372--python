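"""End-to-end orchestration: cleaning -> digital normalization ->
consolidation -> hybrid re-assembly/annotation -> quantification ->
differential expression -> pathway enrichment, with a machine-readable
manifest of every stage's parameters and realized data-dependent
thresholds.

Inputs come either from the synthetic generator (in-memory, the bundled
smoke configuration) or from a directory the generator previously wrote.
De novo assembly proper is out of scope: the generator's per-stage contig
sets stand in for the assembler's output, and the digital-normalization
stage is reported for the read streams that would feed it.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import io as dio
from .annotate import build_final_assembly, contig_stats, genome_reassemble, protein_reassemble
from .consolidation import cluster_within_stage
from .diffexpr import (
    estimate_dispersion,
    filter_low,
    mds_coordinates,
    run_all_contrasts,
    tmm_factors,
)
from .pathways import length_bias_enrichment
from .preprocess import (
    DiginormPolicy,
    ScreenPolicy,
    TrimPolicy,
    digital_normalize_pairs,
    screen_contaminants,
    trim_pairs,
)
from .quantify import quantify_libraries
from .simulate import SimConfig, generate_contig_sets, generate_reads, generate_references

logger = logging.getLogger(__name__)


def bundled_smoke_config(seed: int = 7) -> "PipelineConfig":
    """The bundled synthetic study configuration: 200 genes on 4 scaffolds
    and 16 libraries of ~20,000 read pairs under the 2x2x4 design."""
    return PipelineConfig(sim=SimConfig(seed=seed), enrichment_resamples=10_000)


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    sim: SimConfig = field(default_factory=SimConfig)
    input_dir: str | None = None  # pre-generated inputs instead of in-memory
    outdir: str | None = None
    screen: ScreenPolicy = field(default_factory=ScreenPolicy)
    trim: TrimPolicy = field(default_factory=TrimPolicy)
    diginorm: DiginormPolicy = field(default_factory=DiginormPolicy)
    run_diginorm: bool = True
    enrichment_resamples: int = 10_000
    enrichment_seed: int = 1

    REQUIRED_INPUTS = (
        "scaffolds.fasta",
        "gene_models.tsv",
        "proteins.fasta",
        "vectors.fasta",
        "adapters.fasta",
        "pathways.tsv",
        "design.tsv",
    )

    def validate(self) -> None:
        self.sim.validate()
        if self.input_dir is not None:
            base = Path(self.input_dir)
            for name in self.REQUIRED_INPUTS:
                if not (base / name).exists():
                    raise StageError("inputs", f"missing input file {base / name}")


@dataclass
class InputBundle:
    """Stage-zero inputs, either simulated in memory or loaded from disk."""

    scaffolds: dict
    gene_models: list
    proteins: dict
    vectors: dict
    adapters: dict
    pathways: dict
    contig_sets: dict
    libraries: dict
    design: pd.DataFrame
    truth: object | None = None


def load_inputs(input_dir: str | Path) -> InputBundle:
    base = Path(input_dir)
    design = dio.read_design(base / "design.tsv")
    contig_sets = {}
    from .records import Contig

    for path in sorted(base.glob("contigs_*.fasta")):
        stage = path.stem.removeprefix("contigs_")
        contig_sets[stage] = [
            Contig(id=cid, seq=seq, stage=stage) for cid, seq in dio.read_fasta(path).items()
        ]
    libraries = {}
    for lib in design["library_id"]:
        libraries[lib] = list(
            dio.read_fastq_pairs(base / f"{lib}_R1.fastq", base / f"{lib}_R2.fastq")
        )
    return InputBundle(
        scaffolds=dio.read_fasta(base / "scaffolds.fasta"),
        gene_models=dio.read_gene_models(base / "gene_models.tsv"),
        proteins=dio.read_fasta(base / "proteins.fasta"),
        vectors=dio.read_fasta(base / "vectors.fasta"),
        adapters=dio.read_fasta(base / "adapters.fasta"),
        pathways=dio.read_pathways(base / "pathways.tsv"),
        contig_sets=contig_sets,
        libraries=libraries,
        design=design,
    )


@dataclass
class PipelineResult:
    manifest: dict
    unigenes: list
    counts: pd.DataFrame
    filtered_counts: pd.DataFrame
    design: pd.DataFrame
    de_tables: dict[str, pd.DataFrame]
    enrichment: dict[str, pd.DataFrame]
    mapping_summary: pd.DataFrame
    accounting: dict
    mds: pd.DataFrame
    truth: object | None = None


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    config.validate()
    manifest: dict = {
        "seed": config.sim.seed,
        "stages": [],
        "policies": {
            "screen": vars(config.screen),
            "trim": vars(config.trim),
            "diginorm": vars(config.diginorm),
        },
    }

    def record(stage: str, **info):
        manifest["stages"].append({"stage": stage, **info})
        logger.info("stage %s: %s", stage, info)

    # --- inputs -----------------------------------------------------------
    if config.input_dir is not None:
        bundle = load_inputs(config.input_dir)
    else:
        truth = generate_references(config.sim)
        by_stage, _labels = generate_contig_sets(truth, config.sim)
        libraries, design, _true_counts = generate_reads(truth, config.sim)
        bundle = InputBundle(
            scaffolds=truth.scaffolds,
            gene_models=truth.gene_models,
            proteins=truth.proteins,
            vectors=truth.vectors,
            adapters=truth.adapters,
            pathways=truth.pathways,
            contig_sets=by_stage,
            libraries=libraries,
            design=design,
            truth=truth,
        )
    by_stage = bundle.contig_sets
    libraries = bundle.libraries
    design = bundle.design
    record(
        "inputs",
        n_gene_models=len(bundle.gene_models),
        n_scaffolds=len(bundle.scaffolds),
        n_contigs={s: len(c) for s, c in by_stage.items()},
        n_libraries=len(libraries),
    )

    # --- cleaning ---------------------------------------------------------
    cleaned: dict[str, list] = {}
    clean_stats = {}
    for lib, pairs in libraries.items():
        kept, screen_log = screen_contaminants(pairs, bundle.vectors, bundle.adapters, config.screen)
        trimmed, n_qc_dropped = trim_pairs(kept, config.trim)
        cleaned[lib] = trimmed
        clean_stats[lib] = {
            "input_pairs": len(pairs),
            "screened_out": len(pairs) - len(kept),
            "trim_dropped": n_qc_dropped,
            "clean_pairs": len(trimmed),
        }
    record("clean", per_library=clean_stats)

    # --- digital normalization (assembly input accounting only) -----------
    if config.run_diginorm:
        all_pairs = [p for lib in sorted(cleaned) for p in cleaned[lib]]
        dn_kept, dn_log = digital_normalize_pairs(all_pairs, config.diginorm)
        record(
            "diginorm",
            input_pairs=len(all_pairs),
            kept_pairs=len(dn_kept),
            discarded=len(dn_log),
        )

    # --- consolidation ----------------------------------------------------
    representatives = []
    cluster_info = {}
    for stage, contigs in by_stage.items():
        reps, table = cluster_within_stage(contigs)
        representatives.extend(reps)
        cluster_info[stage] = {"input": len(contigs), "representatives": len(reps)}
    record("consolidate", per_stage=cluster_info)

    # --- hybrid re-assembly -----------------------------------------------
    protein_retained, protein_log, pass_on = protein_reassemble(representatives, bundle.proteins)
    record(
        "protein_reassembly",
        retained=len(protein_retained),
        discarded=len(protein_log),
        passed_to_genome_path=len(pass_on),
    )
    genome_retained, genome_log, realized = genome_reassemble(
        pass_on, bundle.scaffolds, bundle.gene_models
    )
    record(
        "genome_reassembly",
        retained=len(genome_retained),
        discarded=len(genome_log),
        realized_identity_cutoffs=realized,
    )
    unigenes, accounting = build_final_assembly(
        protein_retained, genome_retained, n_reference_models=len(bundle.gene_models)
    )
    stats = contig_stats([u.seq for u in unigenes])
    record("final_assembly", n_unigenes=len(unigenes), accounting=accounting, stats=vars(stats))

    # --- quantification ----------------------------------------------------
    counts_matrix, mapping_summary = quantify_libraries(
        cleaned, unigenes, insert_mean=config.sim.insert_mean
    )
    counts = counts_matrix.to_frame()
    record(
        "quantify",
        n_units=len(counts),
        mean_mapped_fraction=float(mapping_summary["fraction_mapped"].mean()),
    )

    # --- differential expression -------------------------------------------
    factors = tmm_factors(counts)
    filtered, filter_report = filter_low(counts, factors=factors)
    if filtered.empty:
        raise StageError("diffexpr", "no genes pass the expression filter")
    _, dispersion = estimate_dispersion(filtered, design, factors.loc[filtered.columns])
    de_tables = run_all_contrasts(filtered, design, dispersion, factors)
    mds = mds_coordinates(filtered, factors)
    record(
        "diffexpr",
        filter=filter_report,
        n_de_per_contrast={name: int(t["is_de"].sum()) for name, t in de_tables.items() if "is_de" in t},
    )

    # --- pathway enrichment -------------------------------------------------
    lengths = pd.Series(counts_matrix.lengths, index=counts_matrix.unigene_ids)
    enrichment = {}
    for name in ("SDvsLD_NB", "SDvsLD_BM"):
        flags = de_tables[name]["is_de"]
        enrichment[name] = length_bias_enrichment(
            flags,
            lengths.reindex(flags.index),
            bundle.pathways,
            n_resamples=config.enrichment_resamples,
            seed=config.enrichment_seed,
        )
    record(
        "enrichment",
        enriched={name: list(t.index[t["enriched"]]) for name, t in enrichment.items()},
    )

    result = PipelineResult(
        manifest=manifest,
        unigenes=unigenes,
        counts=counts,
        filtered_counts=filtered,
        design=design,
        de_tables=de_tables,
        enrichment=enrichment,
        mapping_summary=mapping_summary,
        accounting=accounting,
        mds=mds,
        truth=bundle.truth,
    )
    if config.outdir:
        _write_outputs(config.outdir, result)
    return result


def _write_outputs(outdir: str | Path, result: PipelineResult) -> None:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    dio.write_fasta(out / "final_assembly.fasta", ((u.id, u.seq) for u in result.unigenes))
    pd.DataFrame(
        [
            {
                "unigene_id": u.id,
                "category": u.category,
                "reference_id": u.reference_id,
                "identity": u.annotation_identity,
            }
            for u in result.unigenes
        ]
    ).to_csv(out / "annotation.tsv", sep="\t", index=False)
    result.counts.to_csv(out / "counts.tsv", sep="\t")
    result.mapping_summary.to_csv(out / "mapping_summary.tsv", sep="\t", index=False)
    for name, table in result.de_tables.items():
        table.to_csv(out / f"de_{name}.tsv", sep="\t")
    for name, table in result.enrichment.items():
        table.to_csv(out / f"enrichment_{name}.tsv", sep="\t")
    result.mds.to_csv(out / "mds_coordinates.tsv", sep="\t")
    with open(out / "manifest.json", "w") as fh:
        json.dump(result.manifest, fh, indent=2, default=str)


def manifest_digest(manifest: dict) -> str:
    return hashlib.sha256(
        json.dumps(manifest, sort_keys=True, default=str).encode()
    ).hexdigest()
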