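"""Consolidate per-stage contigs and run the hybrid protein/genome
re-assembly and annotation, producing the final transcriptome assembly."""

import pandas as pd
from config import ASSEMBLY, INPUTS

from diapipe import io as dio
from diapipe.annotate import (
    build_final_assembly,
    contig_stats,
    genome_reassemble,
    protein_reassemble,
)
from diapipe.consolidation import cluster_within_stage
from diapipe.records import Contig

ASSEMBLY.mkdir(parents=True, exist_ok=True)
proteins = dio.read_fasta(INPUTS / "proteins.fasta")
scaffolds = dio.read_fasta(INPUTS / "scaffolds.fasta")
gene_models = dio.read_gene_models(INPUTS / "gene_models.tsv")

representatives = []
for path in sorted(INPUTS.glob("contigs_*.fasta")):
    stage = path.stem.removeprefix("contigs_")
    contigs = [Contig(cid, seq, stage) for cid, seq in dio.read_fasta(path).items()]
    reps, _ = cluster_within_stage(contigs)
    representatives.extend(reps)
    print(f"{stage}: {len(contigs)} contigs -> {len(reps)} non-redundant")

prot_ret, prot_log, pass_on = protein_reassemble(representatives, proteins)
gen_ret, gen_log, realized = genome_reassemble(pass_on, scaffolds, gene_models)
unigenes, accounting = build_final_assembly(
    prot_ret, gen_ret, n_reference_models=len(gene_models)
)

dio.write_fasta(ASSEMBLY / "final_assembly.fasta", ((u.id, u.seq) for u in unigenes))
pd.DataFrame(
    [
        {"unigene_id": u.id, "category": u.category, "reference_id": u.reference_id,
         "identity": round(u.annotation_identity, 4), "length": len(u.seq)}
        for u in unigenes
    ]
).to_csv(ASSEMBLY / "annotation.tsv", sep="\t", index=False)
pd.concat([prot_log, gen_log]).to_csv(ASSEMBLY / "discard_log.tsv", sep="\t", index=False)

stats = contig_stats([u.seq for u in unigenes])
print(f"\nfinal assembly: {stats.n_contigs} unigenes, N50 {stats.n50} bp, "
      f"mean {stats.mean_length:.0f} bp, GC {100 * stats.mean_gc:.1f}%")
print(f"realized top-95% identity cutoffs: {realized}")
print(f"gene-model accounting: {accounting}")
print(f"discards: protein path {prot_log['reason'].value_counts().to_dict()}, "
      f"genome path {gen_log['reason'].value_counts().to_dict()}")
pd.Series(accounting).to_csv(ASSEMBLY / "accounting.tsv", sep="\t", header=False)
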