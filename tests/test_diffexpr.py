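"""Normalization and testing: TMM, the expression filter, dispersion
estimation, the NB exact test, the interaction GLM, BH, and MDS."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from diapipe.diffexpr import (
    _exact_nb_pvalue,
    bh_adjust,
    estimate_dispersion,
    filter_low,
    interaction_test,
    log2_cpm,
    mds_coordinates,
    nb_pairwise_test,
    tmm_factors,
)
from tests.conftest import make_design, nb_counts


def _counts(rng, mu, libs, dispersion=0.1):
    return pd.DataFrame(
        {l: nb_counts(rng, mu, dispersion) for l in libs},
        index=[f"g{i}" for i in range(len(mu))],
    )


class TestTMM:
    def test_identical_libraries_get_unit_factors(self):
        rng = np.random.default_rng(0)
        col = rng.poisson(rng.lognormal(4, 1, 500))
        counts = pd.DataFrame({"a": col, "b": col})
        assert np.allclose(tmm_factors(counts), [1.0, 1.0])

    def test_doubled_library_is_absorbed_by_library_size(self):
        rng = np.random.default_rng(1)
        col = rng.poisson(rng.lognormal(4, 1, 500)) + 1
        counts = pd.DataFrame({"a": col, "b": 2 * col})
        assert np.allclose(tmm_factors(counts), [1.0, 1.0], atol=1e-12)

    def test_geometric_mean_is_one(self):
        rng = np.random.default_rng(2)
        counts = _counts(rng, rng.lognormal(4, 1, 800), [f"l{i}" for i in range(6)])
        f = tmm_factors(counts).to_numpy()
        assert abs(np.exp(np.mean(np.log(f))) - 1.0) < 1e-12

    def test_doubled_subset_matches_direct_recomputation(self):
        rng = np.random.default_rng(3)
        mu = rng.lognormal(5, 0.7, 1000)
        a = rng.poisson(mu) + 1
        b = rng.poisson(mu) + 1
        b[:200] *= 2  # 20% of genes doubled in library b
        counts = pd.DataFrame({"a": a, "b": b})
        got = tmm_factors(counts)

        # direct recomputation of the doubly trimmed weighted mean of M
        Na, Nb = a.sum(), b.sum()
        rates = counts.to_numpy() / np.array([Na, Nb])
        f75 = np.quantile(rates, 0.75, axis=0)
        ref = int(np.argmin(np.abs(f75 - f75.mean())))
        yk, yr = (b, a) if ref == 0 else (a, b)
        Nk, Nr = (Nb, Na) if ref == 0 else (Na, Nb)
        M = np.log2((yk / Nk) / (yr / Nr))
        A = 0.5 * np.log2((yk / Nk) * (yr / Nr))
        w = (Nk - yk) / (Nk * yk) + (Nr - yr) / (Nr * yr)
        n = len(M)
        rm = stats.rankdata(M)
        ra = stats.rankdata(A)
        keep = (
            (rm >= np.floor(n * 0.3) + 1) & (rm <= n - np.floor(n * 0.3))
            & (ra >= np.floor(n * 0.05) + 1) & (ra <= n - np.floor(n * 0.05))
        )
        f_other = 2 ** (np.sum(M[keep] / w[keep]) / np.sum(1.0 / w[keep]))
        expected = np.array([1.0, f_other]) if ref == 0 else np.array([f_other, 1.0])
        expected = expected / np.exp(np.mean(np.log(expected)))
        assert np.allclose(got.to_numpy(), expected, rtol=1e-10)

    def test_all_zero_library_is_an_error(self):
        counts = pd.DataFrame({"a": [1, 2, 3], "b": [0, 0, 0]})
        with pytest.raises(ValueError, match="b"):
            tmm_factors(counts)


class TestFilter:
    design = make_design()

    def _frame(self, rows):
        return pd.DataFrame(rows, columns=[f"lib{i}" for i in range(16)])

    def test_zero_everywhere_is_discarded(self):
        counts = self._frame(np.vstack([np.zeros(16), np.full(16, 50)]))
        counts.index = ["zero", "ok"]
        kept, report = filter_low(counts)
        assert list(kept.index) == ["ok"]
        assert report["n_discarded"] == 1

    def test_expressed_in_exactly_four_libraries_is_kept(self):
        row = np.zeros(16)
        row[:4] = 200  # clearly above threshold in exactly 4 libraries
        counts = self._frame(np.vstack([row, np.full(16, 50)]))
        counts.index = ["boundary", "ok"]
        kept, _ = filter_low(counts)
        assert "boundary" in kept.index

    def test_expressed_in_three_libraries_is_discarded(self):
        row = np.zeros(16)
        row[:3] = 200
        counts = self._frame(np.vstack([row, np.full(16, 50)]))
        counts.index = ["rare", "ok"]
        kept, _ = filter_low(counts)
        assert "rare" not in kept.index


class TestDispersion:
    design = make_design()
    libs8 = [l for l in design["library_id"] if l.startswith("SD")]

    def test_poisson_data_estimates_near_zero(self):
        rng = np.random.default_rng(4)
        counts = _counts(rng, rng.lognormal(4.5, 0.8, 2000), self.libs8, dispersion=0.0)
        common, _ = estimate_dispersion(counts, self.design[self.design.library_id.isin(self.libs8)])
        assert common < 0.05

    def test_nb_dispersion_is_recovered(self):
        rng = np.random.default_rng(5)
        counts = _counts(rng, rng.lognormal(4.5, 0.8, 2000), self.libs8, dispersion=0.2)
        common, tagwise = estimate_dispersion(
            counts, self.design[self.design.library_id.isin(self.libs8)]
        )
        assert 0.15 <= common <= 0.25
        assert 0.1 <= tagwise.median() <= 0.3

    def test_identical_replicates_hit_the_lower_boundary(self):
        col = np.random.default_rng(6).poisson(100, 300)
        counts = pd.DataFrame({l: col for l in self.libs8})
        common, _ = estimate_dispersion(
            counts, self.design[self.design.library_id.isin(self.libs8)]
        )
        assert common <= 1e-4


class TestExactTest:
    design = make_design()
    libs8 = [l for l in make_design()["library_id"] if l.startswith("SD")]

    def test_poisson_limit_matches_exact_binomial(self):
        rng = np.random.default_rng(7)
        for _ in range(60):
            s1, s2 = int(rng.integers(0, 80)), int(rng.integers(0, 80))
            if s1 + s2 == 0:
                continue
            n1, n2 = 4, 4
            p_nb = _exact_nb_pvalue(s1, s2, n1, n2, 0.0)
            p_binom = stats.binomtest(s1, s1 + s2, n1 / (n1 + n2)).pvalue
            assert p_nb == pytest.approx(p_binom, rel=1e-9)

    def test_identical_groups_call_nothing(self):
        rng = np.random.default_rng(8)
        mu = rng.lognormal(4, 1, 300)
        cols = {l: nb_counts(rng, mu, 0.05) for l in self.libs8[:4]}
        counts = pd.DataFrame(cols, index=[f"g{i}" for i in range(300)])
        for l_bm, l_nb in zip(self.libs8[:4], self.libs8[4:]):
            counts[l_nb] = counts[l_bm]
        d = self.design[self.design.library_id.isin(self.libs8)]
        res = nb_pairwise_test(counts, d, ("SD_BM", "SD_NB"), dispersion=0.05)
        assert res["is_de"].sum() == 0
        assert res["logFC"].abs().max() < 1e-8

    def test_label_swap_flips_sign_and_preserves_p(self):
        rng = np.random.default_rng(9)
        mu = rng.lognormal(4, 1, 200)
        counts = _counts(rng, mu, self.libs8)
        d = self.design[self.design.library_id.isin(self.libs8)]
        fwd = nb_pairwise_test(counts, d, ("SD_BM", "SD_NB"), dispersion=0.1)
        rev = nb_pairwise_test(counts, d, ("SD_NB", "SD_BM"), dispersion=0.1)
        assert np.allclose(fwd["logFC"], -rev["logFC"])
        assert np.allclose(fwd["PValue"], rev["PValue"])

    def test_unknown_group_label_raises(self):
        rng = np.random.default_rng(10)
        counts = _counts(rng, np.full(20, 50.0), self.libs8)
        d = self.design[self.design.library_id.isin(self.libs8)]
        with pytest.raises(ValueError, match="unknown group"):
            nb_pairwise_test(counts, d, ("XX_YY", "SD_NB"), dispersion=0.1)


class TestInteraction:
    def test_planted_interaction_is_detected_and_null_is_calibrated(self):
        rng = np.random.default_rng(11)
        design = make_design()
        ng = 300
        mu = rng.lognormal(4.5, 0.8, ng)
        hot = rng.choice(ng, 30, replace=False)
        cols = {}
        for _, row in design.iterrows():
            m = mu.copy()
            if row.photoperiod == "SD" and row.bloodmeal == "BM":
                m[hot] *= 4
            cols[row.library_id] = nb_counts(rng, m, 0.1)
        counts = pd.DataFrame(cols, index=[f"g{i}" for i in range(ng)])
        _, tagwise = estimate_dispersion(counts, design)
        res = interaction_test(counts, design, tagwise)
        truth = np.zeros(ng, bool)
        truth[hot] = True
        detected = (res["FDR"] < 0.05).to_numpy()
        assert detected[truth].mean() >= 0.70
        null_p = res["PValue"].to_numpy()[~truth]
        assert 0.01 <= (null_p < 0.05).mean() <= 0.09


class TestBH:
    def test_textbook_example(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_single_and_degenerate_inputs(self):
        assert bh_adjust([0.37]) == pytest.approx([0.37])
        assert np.allclose(bh_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])

    def test_matches_brute_force_on_small_permutations(self):
        # direct step-up definition: adj_i = min over j with p_j >= p_i of p_j*n/rank_j
        def oracle(p):
            n = len(p)
            order = np.argsort(p, kind="mergesort")
            out = np.empty(n)
            for pos, idx in enumerate(order):
                candidates = [
                    p[order[k]] * n / (k + 1) for k in range(pos, n)
                ]
                out[idx] = min(1.0, min(candidates))
            return out

        base = [0.01, 0.2, 0.04, 0.9, 0.5, 0.04]
        for perm in itertools.permutations(base[:5]):
            assert np.allclose(bh_adjust(list(perm)), oracle(list(perm)))

    def test_adjusted_never_below_raw(self):
        rng = np.random.default_rng(12)
        p = rng.random(200)
        assert (bh_adjust(p) >= p - 1e-15).all()


class TestMDS:
    def test_identical_libraries_sit_at_distance_zero(self):
        rng = np.random.default_rng(13)
        col = rng.poisson(rng.lognormal(4, 1, 600))
        counts = pd.DataFrame({"a": col, "b": col, "c": rng.poisson(rng.lognormal(4, 1, 600))})
        coords = mds_coordinates(counts)
        assert np.linalg.norm(coords.loc["a"] - coords.loc["b"]) < 1e-9

    def test_three_libraries_embed_their_distances_exactly(self):
        rng = np.random.default_rng(14)
        counts = pd.DataFrame(
            {l: rng.poisson(rng.lognormal(4, 1, 600)) for l in "abc"}
        )
        eff = counts.sum(axis=0) * tmm_factors(counts)
        lcpm = log2_cpm(counts, eff, prior_count=0.5)
        top = lcpm.var(axis=1).sort_values(ascending=False).index[:500]
        X = lcpm.loc[top].to_numpy().T
        want = np.linalg.norm(X[:, None, :] - X[None, :, :], axis=2)
        coords = mds_coordinates(counts).to_numpy()
        got = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=2)
        assert np.allclose(got, want, atol=1e-9)

    def test_too_few_libraries_rejected(self):
        counts = pd.DataFrame({"a": [1, 2], "b": [2, 3]})
        with pytest.raises(ValueError):
            mds_coordinates(counts)
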