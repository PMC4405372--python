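"""Screen contaminants, trim by quality, and report one round of digital
normalization on the cleaned stream."""

import pandas as pd
from config import CLEANED, INPUTS

from diapipe import io as dio
from diapipe.preprocess import (
    DiginormPolicy,
    digital_normalize_pairs,
    screen_contaminants,
    trim_pairs,
)

CLEANED.mkdir(parents=True, exist_ok=True)
vectors = dio.read_fasta(INPUTS / "vectors.fasta")
adapters = dio.read_fasta(INPUTS / "adapters.fasta")
design = dio.read_design(INPUTS / "design.tsv")

rows = []
all_cleaned = []
for lib in design["library_id"]:
    pairs = list(dio.read_fastq_pairs(INPUTS / f"{lib}_R1.fastq", INPUTS / f"{lib}_R2.fastq"))
    kept, screen_log = screen_contaminants(pairs, vectors, adapters)
    trimmed, n_dropped = trim_pairs(kept)
    dio.write_fastq(CLEANED / f"{lib}_R1.fastq", (p.r1 for p in trimmed))
    dio.write_fastq(CLEANED / f"{lib}_R2.fastq", (p.r2 for p in trimmed))
    all_cleaned.extend(trimmed)
    rows.append(
        {
            "library_id": lib,
            "input_pairs": len(pairs),
            "screened_out": len(pairs) - len(kept),
            "trim_dropped": n_dropped,
            "clean_pairs": len(trimmed),
        }
    )
summary = pd.DataFrame(rows)
summary.to_csv(CLEANED / "cleaning_summary.tsv", sep="\t", index=False)

dn_kept, _ = digital_normalize_pairs(all_cleaned, DiginormPolicy())
print(summary.to_string(index=False))
pct = 100 * summary["screened_out"].sum() / summary["input_pairs"].sum()
print(f"\ncontamination removed: {pct:.2f}% of pairs")
print(f"digital normalization would keep {len(dn_kept)} of {len(all_cleaned)} "
      f"cleaned pairs for assembly")
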