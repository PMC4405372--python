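import logging

import numpy as np
import pandas as pd
import pytest

from diapipe.pipeline import PipelineConfig, run_pipeline
from diapipe.simulate import SimConfig, generate_contig_sets, generate_references

logging.getLogger("diapipe").setLevel(logging.ERROR)


def make_design(n_reps: int = 4) -> pd.DataFrame:
    rows = []
    for pp in ("SD", "LD"):
        for bm in ("BM", "NB"):
            for rep in range(1, n_reps + 1):
                rows.append(
                    {
                        "library_id": f"{pp}_{bm}_{rep}",
                        "photoperiod": pp,
                        "bloodmeal": bm,
                        "replicate": rep,
                    }
                )
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def design16() -> pd.DataFrame:
    return make_design()


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    return SimConfig(seed=11, n_genes=40, n_scaffolds=2, mean_library_size=1500)


@pytest.fixture(scope="session")
def small_truth(small_config):
    return generate_references(small_config)


@pytest.fixture(scope="session")
def small_contigs(small_truth, small_config):
    return generate_contig_sets(small_truth, small_config)


@pytest.fixture(scope="session")
def small_pipeline_result(small_config):
    """One end-to-end run on a compact configuration, shared by the smoke
    and invariant tests."""
    cfg = PipelineConfig(sim=small_config, enrichment_resamples=4000)
    return run_pipeline(cfg)


def nb_counts(rng, mu, dispersion, size=None):
    """Reference NB sampler used by test oracles (mean mu, var mu+mu^2*phi)."""
    mu = np.asarray(mu, dtype=float)
    if dispersion <= 0:
        return rng.poisson(mu, size=size)
    r = 1.0 / dispersion
    return rng.negative_binomial(r, r / (r + mu), size=size)
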