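import math
from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import rankdata

from tmeprofiler import (
    adjust_pvalues,
    compare_hgp,
    generate_cohort,
    mann_whitney_pratt,
    spearman_matrix,
    spearman_rho,
)
from tmeprofiler.density_metrics import DensityMatrix
from tmeprofiler.errors import DataError, SchemaError

from conftest import make_clinical, small_sim_config


def permutation_pvalue(x, y):
    """Independent oracle: exact two-sided permutation p over all labelings."""
    x, y = list(x), list(y)
    pooled = x + y
    n1, n = len(x), len(x) + len(y)
    ranks = rankdata(pooled)
    mu = n1 * (n - n1) / 2.0
    obs = abs(sum(ranks[:n1]) - n1 * (n1 + 1) / 2.0 - mu)
    hits = total = 0
    for idx in combinations(range(n), n1):
        u = sum(ranks[i] for i in idx) - n1 * (n1 + 1) / 2.0
        hits += abs(u - mu) >= obs - 1e-12
        total += 1
    return hits / total


class TestMannWhitneyPratt:
    def test_fully_separated_triples(self):
        res = mann_whitney_pratt((1, 2, 3), (4, 5, 6))
        assert res.u == 0
        assert res.exact
        assert res.p_raw == pytest.approx(0.1, abs=1e-12)  # 2 / C(6,3)

    def test_identical_multisets_give_p_one(self):
        res = mann_whitney_pratt((1, 2, 2, 3), (1, 2, 2, 3))
        assert res.p_raw == 1.0

    def test_all_identical_is_degenerate(self):
        res = mann_whitney_pratt((5, 5, 5), (5, 5))
        assert res.degenerate and res.p_raw == 1.0

    def test_zero_inflated_matches_permutation_oracle(self):
        x, y = (0, 0, 0, 5), (0, 0, 7, 9)
        res = mann_whitney_pratt(x, y)
        assert res.exact
        assert res.p_raw == pytest.approx(permutation_pvalue(x, y), abs=1e-9)

    def test_zeros_are_ranked_not_dropped(self):
        # dropping zeros would change n1/n2; Pratt-style retention keeps them
        res = mann_whitney_pratt((0, 0, 1), (0, 2, 3))
        assert (res.n1, res.n2) == (3, 3)
        assert res.tie_correction_applied

    def test_large_sample_uses_normal_approximation(self, rng):
        x = rng.gamma(2, 1, 40)
        y = rng.gamma(2, 1, 40) + 1.0
        res = mann_whitney_pratt(x, y)
        assert not res.exact
        assert res.p_raw < 0.01
        assert res.z < 0  # group 1 smaller

    def test_empty_group_rejected(self):
        with pytest.raises(DataError):
            mann_whitney_pratt([], [1.0])

    @settings(max_examples=150, deadline=None)
    @given(st.lists(st.sampled_from([0, 0, 1, 2, 5]), min_size=1, max_size=5),
           st.lists(st.sampled_from([0, 0, 1, 2, 5]), min_size=1, max_size=5))
    def test_exact_branch_equals_enumeration(self, x, y):
        res = mann_whitney_pratt(x, y)
        assert res.p_raw == pytest.approx(permutation_pvalue(x, y), abs=1e-9)


class TestAdjustPvalues:
    def test_holm_worked_example(self):
        # step-down by hand: sorted (.01,.03,.04) -> (3*.01, 2*.03, 1*.04)
        # running max -> (.03,.06,.06); restore input order
        got = adjust_pvalues([0.01, 0.04, 0.03], "holm")
        np.testing.assert_allclose(got, [0.03, 0.06, 0.06])

    def test_bh_worked_example(self):
        # step-up by hand: (.01*3/1, .02*3/2, .03*3/3) -> min from top = .03 each
        got = adjust_pvalues([0.01, 0.02, 0.03], "bh")
        np.testing.assert_allclose(got, [0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        for method in ("holm", "bh"):
            np.testing.assert_allclose(adjust_pvalues([0.2], method), [0.2])

    def test_out_of_range_rejected(self):
        with pytest.raises(SchemaError):
            adjust_pvalues([0.5, 1.5], "holm")

    def test_nan_passthrough(self):
        got = adjust_pvalues([0.01, np.nan, 0.04], "holm")
        assert np.isnan(got[1])
        # family size excludes the NaN entry
        np.testing.assert_allclose(got[[0, 2]], [0.02, 0.04])

    @settings(max_examples=100, deadline=None)
    @given(st.lists(st.floats(min_value=0, max_value=1, allow_nan=False),
                    min_size=1, max_size=20),
           st.sampled_from(["holm", "bh"]))
    def test_properties(self, pvals, method):
        adj = adjust_pvalues(pvals, method)
        assert (adj <= 1.0 + 1e-15).all()
        assert (adj >= np.asarray(pvals) - 1e-15).all()  # adjusted >= raw
        # order preservation: sorting inputs sorts outputs identically
        order = np.argsort(pvals, kind="stable")
        assert (np.diff(adj[order]) >= -1e-12).all()

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(min_value=0, max_value=1, allow_nan=False),
                    min_size=2, max_size=12),
           st.randoms(use_true_random=False),
           st.sampled_from(["holm", "bh"]))
    def test_permutation_equivariance(self, pvals, rand, method):
        perm = list(range(len(pvals)))
        rand.shuffle(perm)
        adj = adjust_pvalues(pvals, method)
        adj_perm = adjust_pvalues([pvals[i] for i in perm], method)
        np.testing.assert_allclose(adj_perm, adj[perm])


class TestSpearman:
    def test_monotone_pair(self):
        rho, p = spearman_rho([1, 2, 3, 4], [10, 20, 30, 40])
        assert rho == 1.0 and p == 0.0

    def test_anti_monotone_pair(self):
        rho, _ = spearman_rho([1, 2, 3, 4], [4, 3, 2, 1])
        assert rho == -1.0

    def test_tied_data_matches_midrank_pearson_oracle(self, rng):
        x = rng.integers(0, 10, 200).astype(float)
        y = rng.integers(0, 10, 200).astype(float)
        rho, _ = spearman_rho(x, y)
        rx, ry = rankdata(x), rankdata(y)
        oracle = np.corrcoef(rx, ry)[0, 1]
        assert rho == pytest.approx(oracle, abs=1e-12)

    def test_monotone_transform_invariance(self, rng):
        x = rng.gamma(2, 1, 50)
        y = rng.gamma(2, 1, 50)
        rho1, _ = spearman_rho(x, y)
        rho2, _ = spearman_rho(np.exp(x), y ** 3)
        assert rho1 == pytest.approx(rho2, abs=1e-12)

    def test_constant_column_is_missing(self):
        rho, p = spearman_rho([1, 1, 1, 1], [1, 2, 3, 4])
        assert math.isnan(rho) and math.isnan(p)

    def test_matrix_symmetry_and_diagonal(self):
        per_sample = []
        rng = np.random.default_rng(0)
        for i in range(12):
            for pheno in ("A", "B", "C"):
                per_sample.append({"sample_id": f"S{i}", "phenotype": pheno,
                                   "demarcation": "stroma",
                                   "density": float(rng.gamma(2, 5))})
        per_sample = pd.DataFrame(per_sample)
        dm = DensityMatrix(per_core=per_sample.assign(core_id="C1", count=np.nan,
                                                      area_mm2=np.nan),
                           per_sample=per_sample)
        clinical = make_clinical([(f"S{i}", "dHGP", 10.0, 1) for i in range(12)])
        cm = spearman_matrix(dm, clinical, "dHGP", scope="stroma")
        np.testing.assert_allclose(cm.rho, cm.rho.T)
        np.testing.assert_allclose(np.diag(cm.rho), 1.0)
        assert ((cm.rho.to_numpy() >= -1) & (cm.rho.to_numpy() <= 1)).all()


class TestCompareHgp:
    def test_single_test_family_leaves_p_unadjusted(self):
        bundle = generate_cohort(small_sim_config(seed=1))
        from tmeprofiler import apply_thresholds, compute_densities, fit_thresholds
        thr = fit_thresholds(bundle.cells, ["CD8"])
        calls = apply_thresholds(bundle.cells, thr)
        pheno = pd.DataFrame({"CD8_pos": calls["CD8"]}, index=bundle.cells.index)
        dm = compute_densities(bundle.cells, pheno, bundle.areas,
                               demarcations=["stroma"])
        report = compare_hgp(dm, bundle.clinical)
        assert len(report) == 1
        assert report["p_holm"].iloc[0] == pytest.approx(report["p_raw"].iloc[0])

    def test_direction_reflects_generator_effect(self):
        cfg = small_sim_config(seed=2, n_per_group=25,
                               effect_table={("CD8", "tumor_nest"): 3.0})
        bundle = generate_cohort(cfg)
        from tmeprofiler import apply_thresholds, compute_densities, fit_thresholds
        thr = fit_thresholds(bundle.cells, ["CD8"])
        calls = apply_thresholds(bundle.cells, thr)
        pheno = pd.DataFrame({"CD8_pos": calls["CD8"]}, index=bundle.cells.index)
        dm = compute_densities(bundle.cells, pheno, bundle.areas,
                               demarcations=["tumor_nest"])
        report = compare_hgp(dm, bundle.clinical)
        assert report["direction"].iloc[0] == "dHGP"
        assert report["p_holm"].iloc[0] < 0.05

    def test_small_group_errors(self):
        per_sample = pd.DataFrame([
            {"sample_id": "S1", "phenotype": "A", "demarcation": "stroma", "density": 1.0},
            {"sample_id": "S2", "phenotype": "A", "demarcation": "stroma", "density": 2.0},
        ])
        dm = DensityMatrix(per_core=per_sample.assign(core_id="C1", count=np.nan,
                                                      area_mm2=np.nan),
                           per_sample=per_sample)
        clinical = make_clinical([("S1", "dHGP", 1.0, 1), ("S2", "non_dHGP", 1.0, 1)])
        with pytest.raises(DataError):
            compare_hgp(dm, clinical)
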