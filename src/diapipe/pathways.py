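"""Pathway-level statistics: length-bias-corrected enrichment, exact
proportion comparisons, Z-score matrices for heat maps, and the
diapause-incidence statistic.

The enrichment engine follows the probability-weighting idea: longer
transcripts are more likely to be called DE at equal expression, so the
null distribution of per-pathway DE counts is built by resampling gene
sets with inclusion probability proportional to an isotonic fit of
P(DE | length), rather than uniformly.  With equal lengths the procedure
converges to the hypergeometric tail.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.stats import fisher_exact
from sklearn.isotonic import IsotonicRegression

logger = logging.getLogger(__name__)

ENRICH_MIN_DE = 5
ENRICH_FDR = 0.05


def fit_length_bias(de_flags: pd.Series, gene_lengths: pd.Series) -> pd.Series:
    """Monotone non-decreasing P(DE | length) by isotonic regression."""
    genes = de_flags.index
    x = gene_lengths.reindex(genes).to_numpy(dtype=float)
    y = de_flags.reindex(genes).to_numpy(dtype=float)
    iso = IsotonicRegression(increasing=True, out_of_bounds="clip")
    fitted = iso.fit_transform(x, y)
    return pd.Series(fitted, index=genes, name="pwf")


def length_bias_enrichment(
    de_flags: pd.Series,
    gene_lengths: pd.Series,
    pathways: dict[str, set[str]],
    n_resamples: int = 100_000,
    seed: int = 1,
    chunk: int = 2000,
) -> pd.DataFrame:
    """Over-representation p-values per pathway under a length-aware null.

    For each resample a gene set of the observed genome-wide DE size is
    drawn without replacement with inclusion probability proportional to
    the fitted weighting function (exponential-race sampling); the
    pathway's p-value is the +1-corrected fraction of resamples with at
    least the observed DE count.  Enriched requires >= 5 DE members and
    BH FDR < 0.05.
    """
    missing = set(gene_lengths.index) ^ set(de_flags.index)
    if missing:
        raise ValueError("every measured gene needs both a DE flag and a length")
    genes = list(de_flags.index)
    gene_pos = {g: i for i, g in enumerate(genes)}
    flags = de_flags.to_numpy(dtype=bool)
    n_de = int(flags.sum())

    rows = []
    memberships = {}
    for pid, members in pathways.items():
        measured = [gene_pos[g] for g in members if g in gene_pos]
        if not measured:
            logger.warning("pathway %s has no measured members; skipped", pid)
            continue
        idx = np.array(measured)
        memberships[pid] = idx
        rows.append(
            {
                "pathway_id": pid,
                "n_pathway": len(idx),
                "n_de_in_pathway": int(flags[idx].sum()),
            }
        )
    result = pd.DataFrame(rows).set_index("pathway_id") if rows else pd.DataFrame(
        columns=["n_pathway", "n_de_in_pathway", "p_over", "fdr", "enriched"]
    )
    if not rows:
        return result

    if n_de == 0:
        result["p_over"] = 1.0
    else:
        weights = fit_length_bias(de_flags, gene_lengths).to_numpy(dtype=float)
        weights = np.maximum(weights, 1e-8)
        rng = np.random.default_rng(seed)
        exceed = {pid: 0 for pid in memberships}
        indicator = {
            pid: np.isin(np.arange(len(genes)), idx) for pid, idx in memberships.items()
        }
        observed = {pid: int(flags[idx].sum()) for pid, idx in memberships.items()}
        done = 0
        while done < n_resamples:
            size = min(chunk, n_resamples - done)
            keys = rng.exponential(size=(size, len(genes))) / weights[None, :]
            chosen = np.argpartition(keys, n_de - 1, axis=1)[:, :n_de]
            sel = np.zeros((size, len(genes)), dtype=bool)
            sel[np.arange(size)[:, None], chosen] = True
            for pid, ind in indicator.items():
                counts = sel[:, ind].sum(axis=1)
                exceed[pid] += int((counts >= observed[pid]).sum())
            done += size
        result["p_over"] = [
            (exceed[pid] + 1.0) / (n_resamples + 1.0) for pid in result.index
        ]
    from .diffexpr import bh_adjust

    result["fdr"] = bh_adjust(result["p_over"].to_numpy())
    result["enriched"] = (result["n_de_in_pathway"] >= ENRICH_MIN_DE) & (
        result["fdr"] < ENRICH_FDR
    )
    return result


def fisher_proportion_test(k1: int, n1: int, k2: int, n2: int) -> float:
    """Two-sided Fisher's exact p for comparing proportions k1/n1 vs k2/n2
    (minimum-likelihood two-sided convention, as in R's fisher.test)."""
    for v in (k1, n1, k2, n2):
        if v < 0:
            raise ValueError("counts must be non-negative")
    if k1 > n1 or k2 > n2:
        raise ValueError("successes cannot exceed totals")
    table = [[k1, n1 - k1], [k2, n2 - k2]]
    return float(fisher_exact(table, alternative="two-sided")[1])


def zscore_matrix(expr: pd.DataFrame) -> tuple[pd.DataFrame, list[str], list[str]]:
    """Row-standardized expression plus deterministic dendrogram leaf
    orders (complete linkage, Euclidean).  Constant rows map to zero."""
    if expr.shape[1] < 2:
        raise ValueError("need >= 2 libraries to standardize")
    values = expr.to_numpy(dtype=float)
    means = values.mean(axis=1, keepdims=True)
    sds = values.std(axis=1, ddof=1, keepdims=True)
    z = np.where(sds > 0, (values - means) / np.where(sds > 0, sds, 1.0), 0.0)
    zdf = pd.DataFrame(z, index=expr.index, columns=expr.columns)
    row_order = (
        [expr.index[i] for i in leaves_list(linkage(z, method="complete", metric="euclidean"))]
        if len(expr) > 1
        else list(expr.index)
    )
    col_order = (
        [expr.columns[i] for i in leaves_list(linkage(z.T, method="complete", metric="euclidean"))]
        if expr.shape[1] > 1
        else list(expr.columns)
    )
    return zdf, row_order, col_order


def diapause_incidence(hatched: int, embryonated_unhatched: int) -> float:
    """DI = embryonated-unhatched / (hatched + embryonated-unhatched)."""
    if hatched < 0 or embryonated_unhatched < 0:
        raise ValueError("egg counts must be non-negative")
    total = hatched + embryonated_unhatched
    if total == 0:
        raise ValueError("diapause incidence undefined with no eggs")
    return embryonated_unhatched / total
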