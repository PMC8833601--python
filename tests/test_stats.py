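import itertools
import math

import numpy as np
import pytest
from scipy import stats as sps

from tilspatial.stats import (
    TestResult as RankTestResult,
    compare_groups,
    compare_paired_regions,
    mann_whitney_u,
    wilcoxon_signed_rank_pratt,
    ward_clustering,
)

import pandas as pd


# ---------------------------------------------------------------------------
# brute-force oracles


def mw_permutation_p(x, y):
    """Two-sided exact Mann-Whitney p by enumerating group assignments of
    the pooled values (independent of any ranking shortcut)."""
    pooled = list(x) + list(y)
    n1 = len(x)

    # U = #{(i,j): x_i > y_j} + 0.5 per tie, computed directly from values
    def u_direct(g1, g2):
        return sum((a > b) + 0.5 * (a == b) for a in g1 for b in g2)

    u_obs = u_direct(x, y)
    us = []
    idx = range(len(pooled))
    for combo in itertools.combinations(idx, n1):
        g1 = [pooled[i] for i in combo]
        g2 = [pooled[i] for i in idx if i not in combo]
        us.append(u_direct(g1, g2))
    us = np.array(us)
    return min(1.0, 2.0 * min((us <= u_obs).mean(), (us >= u_obs).mean()))


def wilcoxon_signflip_p(diffs):
    """Two-sided exact signed-rank p by enumerating sign flips of |d|."""
    d = np.asarray(diffs, float)
    ranks = sps.rankdata(np.abs(d))
    nz = d != 0
    r = ranks[nz]
    w_obs = r[d[nz] > 0].sum()
    ws = []
    for signs in itertools.product((0, 1), repeat=len(r)):
        ws.append(float(np.dot(signs, r)))
    ws = np.array(ws)
    return min(1.0, 2.0 * min((ws <= w_obs).mean(), (ws >= w_obs).mean()))


# ---------------------------------------------------------------------------


class TestMannWhitney:
    def test_separated_pairs_exact_p(self):
        res = mann_whitney_u([1, 2], [3, 4])
        assert res.statistic == 0
        assert res.p_value == pytest.approx(2 / 6)
        assert "exact" in res.method

    def test_identical_groups_give_p_one(self):
        res = mann_whitney_u([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.p_value == pytest.approx(1.0, abs=1e-9)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])

    def test_all_values_identical_p_one(self):
        assert mann_whitney_u([2, 2, 2], [2, 2]).p_value == 1.0

    def test_exact_matches_permutation_oracle_tie_free(self):
        rng = np.random.default_rng(0)
        for n1 in range(1, 5):
            for n2 in range(1, 9 - n1):
                for _ in range(20):
                    x = rng.normal(size=n1)
                    y = rng.normal(size=n2)
                    got = mann_whitney_u(x, y).p_value
                    want = mw_permutation_p(list(x), list(y))
                    assert got == pytest.approx(want, abs=1e-12)

    def test_matches_scipy_exact_on_tie_free_data(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(size=5), rng.normal(size=6)
        got = mann_whitney_u(x, y)
        ref = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        assert got.p_value == pytest.approx(ref.pvalue, abs=1e-12)

    def test_normal_approx_close_to_exact_at_n20(self):
        rng = np.random.default_rng(9)
        for _ in range(5):
            x = rng.normal(size=20)
            y = rng.normal(size=20)
            approx = mann_whitney_u(x, y).p_value
            exact = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact").pvalue
            assert abs(approx - exact) < 0.01

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(5)
        x = rng.gamma(2, size=15)
        y = rng.gamma(3, size=12)
        p0 = mann_whitney_u(x, y).p_value
        assert mann_whitney_u(np.log(x), np.log(y)).p_value == pytest.approx(p0)
        assert mann_whitney_u(x**3, y**3).p_value == pytest.approx(p0)

    def test_one_sided_alternatives_are_coherent(self):
        res_g = mann_whitney_u([5, 6, 7, 8], [1, 2, 3, 4], alternative="greater")
        res_l = mann_whitney_u([5, 6, 7, 8], [1, 2, 3, 4], alternative="less")
        assert res_g.p_value == pytest.approx(1 / 70)  # fully separated, C(8,4)=70
        assert res_l.p_value > 0.9


class TestWilcoxonPratt:
    def test_all_positive_diffs_exact_p(self):
        res = wilcoxon_signed_rank_pratt([1, 2, 3])
        assert res.statistic == 6
        assert res.p_value == pytest.approx(2 / 8)
        assert "exact" in res.method

    def test_all_zero_diffs_give_p_one(self):
        assert wilcoxon_signed_rank_pratt([0.0, 0.0, 0.0]).p_value == 1.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_signed_rank_pratt([])

    def test_antisymmetry(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            d = rng.normal(size=7)
            assert wilcoxon_signed_rank_pratt(d).p_value == pytest.approx(
                wilcoxon_signed_rank_pratt(-d).p_value
            )

    def test_exact_matches_signflip_oracle_tie_free(self):
        rng = np.random.default_rng(1)
        for n in range(1, 9):
            for _ in range(20):
                d = rng.normal(size=n)
                got = wilcoxon_signed_rank_pratt(d).p_value
                want = wilcoxon_signflip_p(d)
                assert got == pytest.approx(want, abs=1e-12)

    def test_zeros_ranked_then_dropped_matches_scipy_pratt(self):
        d = [0.0, 1.0, -2.0, 3.0, 4.0, -1.5, 0.0, 2.5]
        got = wilcoxon_signed_rank_pratt(d)
        ref = sps.wilcoxon(d, zero_method="pratt", correction=True, method="approx")
        # scipy reports W = min(W+, W-); ours is W+; p-values must agree
        assert got.p_value == pytest.approx(ref.pvalue, rel=1e-6)


class TestWardClustering:
    def test_separated_clouds_are_split(self):
        rng = np.random.default_rng(4)
        a = rng.normal(0, 1, size=(10, 3))
        b = rng.normal(100, 1, size=(10, 3))
        labels = ward_clustering(np.vstack([a, b]), k=2)
        assert len(set(labels[:10])) == 1
        assert len(set(labels[10:])) == 1
        assert labels[0] != labels[-1]

    def test_k_edges(self):
        X = np.random.default_rng(0).normal(size=(6, 2))
        assert len(set(ward_clustering(X, 1))) == 1
        assert len(set(ward_clustering(X, 6))) == 6
        with pytest.raises(ValueError):
            ward_clustering(X, 7)

    def test_nan_features_imputed_by_column_median(self):
        X = np.array([[0.0, np.nan], [0.1, 1.0], [10.0, 1.2], [10.1, np.nan]])
        labels = ward_clustering(X, 2)
        assert labels[0] == labels[1] and labels[2] == labels[3]
        assert labels[0] != labels[2]

    def test_merge_heights_nondecreasing(self):
        from scipy.cluster.hierarchy import linkage

        X = np.random.default_rng(8).normal(size=(15, 4))
        Z = linkage(X, method="ward")
        assert (np.diff(Z[:, 2]) >= -1e-12).all()


class TestBatchInterfaces:
    def _zone_table(self):
        rng = np.random.default_rng(0)
        rows = []
        for i in range(8):
            sid = f"s{i}"
            for subset in ("CD8_total", "CD4_total"):
                for zone in range(2):
                    shift = 5.0 if (i < 4 and subset == "CD8_total") else 0.0
                    rows.append(
                        {
                            "sample_id": sid,
                            "measure": "A",
                            "subset": subset,
                            "zone": zone,
                            "density_per_mm2": rng.gamma(5) + shift,
                        }
                    )
        return pd.DataFrame(rows)

    def test_compare_groups_strata_and_labels(self):
        table = self._zone_table()
        labels = {f"s{i}": "dHGP" if i < 4 else "ndHGP" for i in range(8)}
        out = compare_groups(table, labels)
        assert len(out) == 4  # 2 subsets x 2 zones
        assert (out["n_dhgp"] == 4).all() and (out["n_ndhgp"] == 4).all()
        cd8 = out[out.subset == "CD8_total"]
        cd4 = out[out.subset == "CD4_total"]
        assert (cd8["median_dhgp"] > cd8["median_ndhgp"]).all()
        assert cd8["p_value"].mean() < cd4["p_value"].mean()

    def test_compare_groups_missing_label_is_an_error(self):
        table = self._zone_table()
        with pytest.raises(ValueError, match="without growth-pattern label"):
            compare_groups(table, {"s0": "dHGP"})

    def test_bh_adjustment_adds_monotone_q_values(self):
        table = self._zone_table()
        labels = {f"s{i}": "dHGP" if i < 4 else "ndHGP" for i in range(8)}
        out = compare_groups(table, labels, adjust="bh")
        assert (out["q_value"] >= out["p_value"] - 1e-12).all()

    def test_paired_regions_detects_consistent_shift(self):
        rows = []
        rng = np.random.default_rng(6)
        for i in range(10):
            base = rng.gamma(5)
            for region, d in (("CENTRAL", 3.0), ("PERIPHERY", 0.0)):
                rows.append(
                    {
                        "sample_id": f"s{i}",
                        "region": region,
                        "compartment": "TOTAL",
                        "subset": "CD8_total",
                        "density_per_mm2": base + d + rng.normal(0, 0.1),
                    }
                )
        out = compare_paired_regions(pd.DataFrame(rows))
        assert out.iloc[0]["p_value"] < 0.01
        assert out.iloc[0]["median_diff"] > 0


def test_result_validates_p_range():
    with pytest.raises(ValueError):
        RankTestResult(statistic=1.0, p_value=1.5, method="x", n1=2, n2=2)
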