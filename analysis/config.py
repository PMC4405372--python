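"""Shared settings for the numbered analysis scripts.

The analysis runs the full pipeline in stages over files under results/,
at a scale small enough that every script finishes in well under a minute.
"""

from pathlib import Path

from diapipe.simulate import SimConfig

RESULTS = Path(__file__).resolve().parent.parent / "results"
INPUTS = RESULTS / "inputs"
CLEANED = RESULTS / "cleaned"
ASSEMBLY = RESULTS / "assembly"
QUANT = RESULTS / "quant"
DE = RESULTS / "de"
ENRICHMENT = RESULTS / "enrichment"

STUDY = SimConfig(seed=7, n_genes=120, n_scaffolds=3, mean_library_size=6000)
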