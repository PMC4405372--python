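"""Length-bias-corrected pathway enrichment of the photoperiod contrasts,
plus the Z-score heat-map matrix for the enriched pathways."""

import pandas as pd
from config import DE, ENRICHMENT, INPUTS, QUANT, STUDY

from diapipe import io as dio
from diapipe.diffexpr import effective_lib_sizes, log2_cpm
from diapipe.pathways import length_bias_enrichment, zscore_matrix

ENRICHMENT.mkdir(parents=True, exist_ok=True)
pathways = dio.read_pathways(INPUTS / "pathways.tsv")
lengths = pd.read_csv(QUANT / "unit_lengths.tsv", sep="\t", index_col=0)["length"]
counts = pd.read_csv(QUANT / "counts.tsv", sep="\t", index_col=0)

for contrast in ("SDvsLD_NB", "SDvsLD_BM"):
    de = pd.read_csv(DE / f"de_{contrast}.tsv", sep="\t", index_col=0)
    result = length_bias_enrichment(
        de["is_de"].astype(bool),
        lengths.reindex(de.index),
        pathways,
        n_resamples=100_000,
        seed=STUDY.seed,
    )
    result.to_csv(ENRICHMENT / f"enrichment_{contrast}.tsv", sep="\t")
    enriched = list(result.index[result["enriched"]])
    print(f"{contrast}: {len(enriched)} enriched pathway(s): {enriched}")

    # Z-score heat-map matrix of the DE genes in enriched pathways
    for pid in enriched:
        members = [g for g in pathways[pid] if g in de.index and de.loc[g, "is_de"]]
        members = [g for g in members if g in counts.index]
        if len(members) < 2:
            continue
        lcpm = log2_cpm(counts.loc[members], effective_lib_sizes(counts), prior_count=0.5)
        z, row_order, col_order = zscore_matrix(lcpm)
        z.loc[row_order, col_order].to_csv(
            ENRICHMENT / f"heatmap_{contrast}_{pid}.tsv", sep="\t"
        )
        print(f"  heat-map matrix for {pid}: {len(members)} DE genes")
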