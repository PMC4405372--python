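"""edgeR-style differential expression for the 2x2 factorial design.

Implements TMM between-library normalization, the low-expression filter,
conditional-likelihood dispersion estimation with shrinkage, the
negative-binomial exact test (minimum-likelihood two-sided convention, so
it collapses to the exact binomial test in the Poisson limit), a GLM
likelihood-ratio test for the photoperiod x blood-meal interaction, BH
correction, and classical MDS of voom-style transformed counts.

The DE call rule throughout: |log2 fold-change| > 0.5 and BH FDR < 0.05.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import gammaln
from scipy.stats import nbinom, poisson

logger = logging.getLogger(__name__)

LFC_THRESHOLD = 0.5
FDR_THRESHOLD = 0.05

CONTRASTS = {
    "BMvsNB_LD": ("LD_BM", "LD_NB"),
    "BMvsNB_SD": ("SD_BM", "SD_NB"),
    "SDvsLD_NB": ("SD_NB", "LD_NB"),
    "SDvsLD_BM": ("SD_BM", "LD_BM"),
}


def condition_labels(design: pd.DataFrame) -> pd.Series:
    labels = (design["photoperiod"].astype(str) + "_" + design["bloodmeal"].astype(str)).to_numpy()
    return pd.Series(labels, index=design["library_id"].astype(str).to_numpy())


# ---------------------------------------------------------------------------
# TMM


def tmm_factors(
    counts: pd.DataFrame,
    log_ratio_trim: float = 0.30,
    abs_expr_trim: float = 0.05,
) -> pd.Series:
    """Trimmed-mean-of-M-values normalization factors, geometric mean 1.

    The reference library is the one whose upper-quartile CPM is closest
    to the mean upper quartile; per-gene M-values are weighted by the
    inverse asymptotic binomial variance and doubly trimmed (30% per tail
    of M, 5% per tail of A).
    """
    values = counts.to_numpy(dtype=float)
    lib_sizes = values.sum(axis=0)
    if np.any(lib_sizes <= 0):
        bad = counts.columns[lib_sizes <= 0][0]
        raise ValueError(f"library {bad} has zero total counts")
    rates = values / lib_sizes
    f75 = np.array([np.quantile(rates[:, j][values[:, j] >= 0], 0.75) for j in range(values.shape[1])])
    ref = int(np.argmin(np.abs(f75 - f75.mean())))

    factors = np.ones(values.shape[1])
    yr = values[:, ref]
    Nr = lib_sizes[ref]
    for j in range(values.shape[1]):
        if j == ref:
            continue
        yk = values[:, j]
        Nk = lib_sizes[j]
        ok = (yk > 0) & (yr > 0)
        if ok.sum() == 0:
            continue
        M = np.log2((yk[ok] / Nk) / (yr[ok] / Nr))
        A = 0.5 * np.log2((yk[ok] / Nk) * (yr[ok] / Nr))
        w = (Nk - yk[ok]) / (Nk * yk[ok]) + (Nr - yr[ok]) / (Nr * yr[ok])
        if np.max(np.abs(M)) < 1e-10:
            continue
        n = len(M)
        lo_m, hi_m = np.floor(n * log_ratio_trim) + 1, n - np.floor(n * log_ratio_trim)
        lo_a, hi_a = np.floor(n * abs_expr_trim) + 1, n - np.floor(n * abs_expr_trim)
        rank_m = pd.Series(M).rank().to_numpy()
        rank_a = pd.Series(A).rank().to_numpy()
        keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
        if keep.sum() == 0 or w[keep].sum() == 0:
            continue
        factors[j] = 2.0 ** (np.sum(M[keep] / w[keep]) / np.sum(1.0 / w[keep]))
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns, name="tmm_factor")


def effective_lib_sizes(counts: pd.DataFrame, factors: pd.Series | None = None) -> pd.Series:
    sizes = counts.sum(axis=0)
    if factors is None:
        factors = tmm_factors(counts)
    return sizes * factors


def log2_cpm(counts: pd.DataFrame, eff_sizes: pd.Series, prior_count: float = 0.25) -> pd.DataFrame:
    """log2 counts-per-million on effective library sizes with a
    library-size-adjusted prior count."""
    L = eff_sizes.to_numpy(dtype=float)
    pc = prior_count * L / L.mean()
    values = counts.to_numpy(dtype=float)
    return pd.DataFrame(
        np.log2((values + pc[None, :]) / (L + 2 * pc)[None, :] * 1e6),
        index=counts.index,
        columns=counts.columns,
    )


# ---------------------------------------------------------------------------
# filtering


def filter_low(
    counts: pd.DataFrame,
    min_log2_cpm: float = 1.0,
    min_libraries: int = 4,
    factors: pd.Series | None = None,
    literal: bool = False,
) -> tuple[pd.DataFrame, dict]:
    """Remove genes too rare for DE testing.

    Default rule: keep a gene iff log2 CPM >= ``min_log2_cpm`` in at least
    ``min_libraries`` libraries (the smallest group size).  ``literal=True``
    applies the verbatim alternative — discard genes with log CPM below the
    threshold in at least that many libraries — which discards nearly
    everything and exists only for comparison.

    The CPM used here carries no prior count: a prior sized for
    million-read libraries swamps the threshold at small library sizes and
    would keep genes with zero counts everywhere, which must fall below
    any expression floor.
    """
    eff = effective_lib_sizes(counts, factors)
    L = eff.to_numpy(dtype=float)
    with np.errstate(divide="ignore"):
        lcpm = pd.DataFrame(
            np.log2(counts.to_numpy(dtype=float) / L[None, :] * 1e6),
            index=counts.index,
            columns=counts.columns,
        )
    if literal:
        discard = (lcpm < min_log2_cpm).sum(axis=1) >= min_libraries
        keep = ~discard
    else:
        keep = (lcpm >= min_log2_cpm).sum(axis=1) >= min_libraries
    report = {"n_input": len(counts), "n_kept": int(keep.sum()), "n_discarded": int((~keep).sum())}
    return counts.loc[keep], report


# ---------------------------------------------------------------------------
# dispersion


def _pseudo_counts(counts: pd.DataFrame, eff_sizes: pd.Series) -> tuple[np.ndarray, float]:
    """Counts linearly rescaled to the geometric-mean effective library
    size, approximating edgeR's quantile adjustment at desk scale."""
    L = eff_sizes.to_numpy(dtype=float)
    common = float(np.exp(np.mean(np.log(L))))
    return counts.to_numpy(dtype=float) * (common / L)[None, :], common


def _cond_loglik(pseudo: np.ndarray, groups: list[np.ndarray], phi: np.ndarray) -> np.ndarray:
    """Per-gene conditional log-likelihood (given group sums) at each phi.

    pseudo: genes x libraries; phi: vector of candidate dispersions.
    Returns genes x len(phi).
    """
    r = 1.0 / np.maximum(phi, 1e-10)  # size parameter
    total = np.zeros((pseudo.shape[0], len(r)))
    for idx in groups:
        y = pseudo[:, idx]
        n = len(idx)
        z = y.sum(axis=1)
        term = (
            gammaln(y[:, :, None] + r[None, None, :]).sum(axis=1)
            + gammaln(n * r)[None, :]
            - gammaln(z[:, None] + n * r[None, :])
            - n * gammaln(r)[None, :]
        )
        total += term
    return total


def estimate_dispersion(
    counts: pd.DataFrame,
    design: pd.DataFrame,
    factors: pd.Series | None = None,
    prior_weight: float = 10.0,
    grid_size: int = 81,
) -> tuple[float, pd.Series]:
    """Common and shrunk per-gene NB dispersions by conditional maximum
    likelihood over a dispersion grid; per-gene values maximize the gene's
    own likelihood plus ``prior_weight`` times the average (common)
    likelihood."""
    cond = condition_labels(design)
    eff = effective_lib_sizes(counts, factors)
    pseudo, _ = _pseudo_counts(counts, eff)
    cols = list(counts.columns)
    groups = [
        np.array([cols.index(lib) for lib in cond.index[cond == c]])
        for c in sorted(cond.unique())
    ]
    groups = [g for g in groups if len(g) >= 2]
    if not groups:
        logger.warning("no group with >= 2 replicates; falling back to dispersion 0")
        return 0.0, pd.Series(0.0, index=counts.index)
    phi_grid = np.concatenate([[1e-6], np.logspace(-4, np.log10(5.0), grid_size - 1)])
    ll = _cond_loglik(pseudo, groups, phi_grid)  # genes x grid
    common_idx = int(np.argmax(ll.sum(axis=0)))
    common = float(phi_grid[common_idx])
    shrunk_idx = np.argmax(ll + prior_weight * ll.mean(axis=0)[None, :], axis=1)
    tagwise = pd.Series(phi_grid[shrunk_idx], index=counts.index, name="dispersion")
    return common, tagwise


# ---------------------------------------------------------------------------
# exact test


def _exact_nb_pvalue(s1: float, s2: float, n1: int, n2: int, phi: float) -> float:
    """Two-sided exact NB test for group sums conditional on the total.

    Group sums of n iid NB(mu, phi) are NB(n mu, phi / n).  Two-sidedness
    by the minimum-likelihood rule: sum the conditional probabilities of
    all splits no more likely than the observed one.  At phi -> 0 this is
    the exact binomial test on the total.
    """
    # round group sums independently so the test is symmetric under a
    # label swap, then condition on their integer total
    s1 = int(round(s1))
    s2 = int(round(s2))
    t = s1 + s2
    if t == 0:
        return 1.0
    mu = t / (n1 + n2)
    a = np.arange(t + 1)
    if phi <= 1e-8:
        logp1 = poisson.logpmf(a, n1 * mu)
        logp2 = poisson.logpmf(t - a, n2 * mu)
    else:
        r1, r2 = n1 / phi, n2 / phi
        logp1 = nbinom.logpmf(a, r1, r1 / (r1 + n1 * mu))
        logp2 = nbinom.logpmf(t - a, r2, r2 / (r2 + n2 * mu))
    joint = logp1 + logp2
    joint -= joint.max()
    probs = np.exp(joint)
    probs /= probs.sum()
    p_obs = probs[min(s1, t)]
    return float(min(probs[probs <= p_obs * (1 + 1e-10)].sum(), 1.0))


def nb_pairwise_test(
    counts: pd.DataFrame,
    design: pd.DataFrame,
    contrast: tuple[str, str],
    dispersion: float | pd.Series | None = None,
    factors: pd.Series | None = None,
    prior_count: float = 0.125,
) -> pd.DataFrame:
    """Exact-test DE table for one pairwise contrast of condition labels
    (e.g. ``("SD_NB", "LD_NB")``; positive log2FC = up in the first)."""
    cond = condition_labels(design)
    for group in contrast:
        if group not in set(cond):
            raise ValueError(f"unknown group label {group!r}")
    if factors is None:
        factors = tmm_factors(counts)
    eff = effective_lib_sizes(counts, factors)
    pseudo, common_size = _pseudo_counts(counts, eff)
    cols = list(counts.columns)
    idx1 = [cols.index(lib) for lib in cond.index[cond == contrast[0]]]
    idx2 = [cols.index(lib) for lib in cond.index[cond == contrast[1]]]
    if len(idx1) < 2 or len(idx2) < 2:
        raise ValueError("each contrast group needs >= 2 libraries")
    if dispersion is None:
        _, dispersion = estimate_dispersion(counts, design, factors)
    phi = (
        dispersion.reindex(counts.index).to_numpy()
        if isinstance(dispersion, pd.Series)
        else np.full(len(counts), float(dispersion))
    )

    s1 = pseudo[:, idx1].sum(axis=1)
    s2 = pseudo[:, idx2].sum(axis=1)
    m1 = s1 / len(idx1)
    m2 = s2 / len(idx2)
    lfc = np.log2((m1 + prior_count) / (m2 + prior_count))
    lcpm = np.log2((m1 + m2) / 2.0 / common_size * 1e6 + 1e-12)
    pvals = np.array(
        [
            _exact_nb_pvalue(a, b, len(idx1), len(idx2), p)
            for a, b, p in zip(s1, s2, phi)
        ]
    )
    fdr = bh_adjust(pvals)
    result = pd.DataFrame(
        {
            "unigene_id": counts.index,
            "logFC": lfc,
            "logCPM": lcpm,
            "PValue": pvals,
            "FDR": fdr,
        }
    ).set_index("unigene_id")
    result["is_de"] = (result["logFC"].abs() > LFC_THRESHOLD) & (result["FDR"] < FDR_THRESHOLD)
    return result


# ---------------------------------------------------------------------------
# interaction GLM


def interaction_test(
    counts: pd.DataFrame,
    design: pd.DataFrame,
    dispersion: float | pd.Series | None = None,
    factors: pd.Series | None = None,
) -> pd.DataFrame:
    """Likelihood-ratio test of the photoperiod x blood-meal interaction in
    a per-gene NB log-linear model with library-size offsets."""
    if factors is None:
        factors = tmm_factors(counts)
    eff = effective_lib_sizes(counts, factors)
    lib_order = list(counts.columns)
    d = design.set_index("library_id").loc[lib_order]
    photo = (d["photoperiod"] == "SD").astype(float).to_numpy()
    blood = (d["bloodmeal"] == "BM").astype(float).to_numpy()
    X_full = np.column_stack([np.ones_like(photo), photo, blood, photo * blood])
    X_null = X_full[:, :3]
    offset = np.log(eff.to_numpy(dtype=float))
    if dispersion is None:
        _, dispersion = estimate_dispersion(counts, design, factors)
    phi = (
        dispersion.reindex(counts.index).to_numpy()
        if isinstance(dispersion, pd.Series)
        else np.full(len(counts), float(dispersion))
    )

    from scipy.stats import chi2

    pvals = np.full(len(counts), np.nan)
    lfc_int = np.full(len(counts), np.nan)
    values = counts.to_numpy(dtype=float)
    for g in range(len(counts)):
        y = values[g]
        alpha = max(float(phi[g]), 1e-8)
        family = sm.families.NegativeBinomial(alpha=alpha)
        try:
            full = sm.GLM(y, X_full, family=family, offset=offset).fit(maxiter=100)
            null = sm.GLM(y, X_null, family=family, offset=offset).fit(maxiter=100)
            if not (full.converged and null.converged):
                raise ValueError("IRLS did not converge")
            lrt = 2.0 * (full.llf - null.llf)
            pvals[g] = float(chi2.sf(max(lrt, 0.0), df=1))
            lfc_int[g] = float(full.params[3] / np.log(2.0))
        except Exception:
            logger.warning("interaction GLM failed for gene %s", counts.index[g])
    fdr = np.full_like(pvals, np.nan)
    ok = ~np.isnan(pvals)
    fdr[ok] = bh_adjust(pvals[ok])
    return pd.DataFrame(
        {
            "unigene_id": counts.index,
            "log2_interaction": lfc_int,
            "PValue": pvals,
            "FDR": fdr,
        }
    ).set_index("unigene_id")


# ---------------------------------------------------------------------------
# BH


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adjusted, 1.0)
    return out


# ---------------------------------------------------------------------------
# MDS


def mds_coordinates(
    counts: pd.DataFrame,
    factors: pd.Series | None = None,
    n_top: int = 500,
) -> pd.DataFrame:
    """Classical (Torgerson) MDS of libraries from voom-style log2-CPM.

    Transform with prior count 0.5 on effective library sizes, Euclidean
    distances over the ``n_top`` most variable genes, double-centering and
    the top-2 eigenvectors.  Signs are fixed so each axis's largest-
    magnitude loading is positive.
    """
    if counts.shape[1] < 3:
        raise ValueError("MDS needs at least 3 libraries")
    eff = effective_lib_sizes(counts, factors)
    lcpm = log2_cpm(counts, eff, prior_count=0.5)
    variances = lcpm.var(axis=1)
    top = variances.sort_values(ascending=False).index[: min(n_top, len(variances))]
    X = lcpm.loc[top].to_numpy().T  # libraries x genes
    sq = ((X[:, None, :] - X[None, :, :]) ** 2).sum(axis=2)
    n = sq.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ sq @ J
    eigvals, eigvecs = np.linalg.eigh(B)
    order = np.argsort(eigvals)[::-1]
    coords = np.zeros((n, 2))
    for dim in range(2):
        lam = eigvals[order[dim]]
        if lam <= 1e-12:
            logger.warning("distance matrix rank < 2; coordinate %d zeroed", dim + 1)
            continue
        v = eigvecs[:, order[dim]] * np.sqrt(lam)
        if v[np.argmax(np.abs(v))] < 0:
            v = -v
        coords[:, dim] = v
    return pd.DataFrame(coords, index=counts.columns, columns=["dim1", "dim2"])


# ---------------------------------------------------------------------------
# convenience: all contrasts


def run_all_contrasts(
    counts: pd.DataFrame,
    design: pd.DataFrame,
    dispersion: float | pd.Series | None = None,
    factors: pd.Series | None = None,
) -> dict[str, pd.DataFrame]:
    if factors is None:
        factors = tmm_factors(counts)
    if dispersion is None:
        _, dispersion = estimate_dispersion(counts, design, factors)
    tables = {
        name: nb_pairwise_test(counts, design, contrast, dispersion, factors)
        for name, contrast in CONTRASTS.items()
    }
    tables["interaction"] = interaction_test(counts, design, dispersion, factors)
    return tables
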