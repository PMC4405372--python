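"""TMM-normalize, filter, and test the four pairwise contrasts and the
photoperiod x blood-meal interaction; embed libraries by MDS."""

import pandas as pd
from config import DE, INPUTS, QUANT

from diapipe import io as dio
from diapipe.diffexpr import (
    estimate_dispersion,
    filter_low,
    mds_coordinates,
    run_all_contrasts,
    tmm_factors,
)

DE.mkdir(parents=True, exist_ok=True)
counts = pd.read_csv(QUANT / "counts.tsv", sep="\t", index_col=0)
design = dio.read_design(INPUTS / "design.tsv")

factors = tmm_factors(counts)
filtered, report = filter_low(counts, factors=factors)
common, dispersion = estimate_dispersion(filtered, design, factors)
tables = run_all_contrasts(filtered, design, dispersion, factors)
mds = mds_coordinates(filtered, factors)

factors.to_csv(DE / "tmm_factors.tsv", sep="\t")
mds.to_csv(DE / "mds_coordinates.tsv", sep="\t")
for name, table in tables.items():
    table.to_csv(DE / f"de_{name}.tsv", sep="\t")

print(f"filter: kept {report['n_kept']} of {report['n_input']} units")
print(f"common dispersion: {common:.4f}")
for name, table in tables.items():
    if "is_de" in table:
        n_up = int(((table["logFC"] > 0.5) & (table["FDR"] < 0.05)).sum())
        n_dn = int(((table["logFC"] < -0.5) & (table["FDR"] < 0.05)).sum())
        print(f"{name}: {n_up} up, {n_dn} down "
              f"(|log2FC| > 0.5, FDR < 0.05)")
    else:
        n_sig = int((table["FDR"] < 0.05).sum())
        print(f"{name}: {n_sig} genes with FDR < 0.05 (GLM likelihood-ratio test)")
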