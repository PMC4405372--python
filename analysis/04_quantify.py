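"""Map cleaned pairs to the final assembly and produce unigene-level
expected counts by EM."""

import pandas as pd
from config import ASSEMBLY, CLEANED, QUANT, STUDY

from diapipe import io as dio
from diapipe.quantify import quantify_libraries
from diapipe.records import Unigene

QUANT.mkdir(parents=True, exist_ok=True)
annotation = pd.read_csv(ASSEMBLY / "annotation.tsv", sep="\t")
seqs = dio.read_fasta(ASSEMBLY / "final_assembly.fasta")
unigenes = [
    Unigene(row.unigene_id, seqs[row.unigene_id], row.category, row.reference_id, row.identity)
    for row in annotation.itertuples(index=False)
]
design = dio.read_design(CLEANED.parent / "inputs" / "design.tsv")
libraries = {
    lib: list(dio.read_fastq_pairs(CLEANED / f"{lib}_R1.fastq", CLEANED / f"{lib}_R2.fastq"))
    for lib in design["library_id"]
}

counts, summary = quantify_libraries(libraries, unigenes, insert_mean=STUDY.insert_mean)
counts.to_frame().to_csv(QUANT / "counts.tsv", sep="\t")
pd.Series(counts.lengths, index=counts.unigene_ids, name="length").to_csv(
    QUANT / "unit_lengths.tsv", sep="\t"
)
summary.to_csv(QUANT / "mapping_summary.tsv", sep="\t", index=False)

print(summary.to_string(index=False))
print(f"\n{len(counts.unigene_ids)} counting units; "
      f"mean mapped fraction {100 * summary['fraction_mapped'].mean():.2f}%")
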