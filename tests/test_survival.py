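import math

import numpy as np
import pandas as pd
import pytest

from tmeprofiler import (
    cox_univariate,
    dichotomize,
    generate_cohort,
    km_estimate,
    logrank_test,
    simulate_survival,
    stratified_prognosis,
)
from tmeprofiler.density_metrics import DensityMatrix
from tmeprofiler.errors import DataError, DegenerateInputError
from tmeprofiler.synthetic_cohort import InteractionConfig, MarkerModel, SurvivalConfig

from conftest import make_clinical, small_sim_config


class TestKaplanMeier:
    def test_four_deaths_no_censoring(self):
        curve = km_estimate([1, 2, 3, 4], [1, 1, 1, 1])
        surv = dict(zip(curve.time, curve.survival))
        assert surv[1] == pytest.approx(0.75)
        assert surv[2] == pytest.approx(0.50)
        assert surv[3] == pytest.approx(0.25)
        assert surv[4] == pytest.approx(0.0)

    def test_hand_product_limit_with_censoring(self):
        # death at 1 (3 at risk) -> 2/3; censored at 2; death at 3 (1 at risk) -> 0
        curve = km_estimate([1, 2, 3], [1, 0, 1])
        surv = dict(zip(curve.time, curve.survival))
        assert surv[1] == pytest.approx(2 / 3)
        assert surv[3] == pytest.approx(0.0)

    def test_all_censored_is_flat_one(self):
        curve = km_estimate([1, 2, 3], [0, 0, 0])
        assert (curve.survival == 1.0).all()

    def test_no_censoring_equals_empirical_survival(self, rng):
        t = rng.exponential(10, 50)
        curve = km_estimate(t, np.ones(50))
        for time, s in zip(curve.time, curve.survival):
            if time == 0:
                continue
            assert s == pytest.approx((t > time).mean(), abs=1e-12)

    def test_empty_input_errors(self):
        with pytest.raises(DataError):
            km_estimate([], [])

    def test_survival_is_monotone_non_increasing(self, rng):
        t = rng.exponential(10, 80)
        e = (rng.random(80) < 0.7).astype(int)
        curve = km_estimate(t, e)
        assert (np.diff(curve.survival) <= 1e-12).all()


def hand_logrank(times, events, groups):
    """O-E/V oracle computed directly from the definition."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    groups = np.asarray(groups)
    o_minus_e = 0.0
    var = 0.0
    for t in sorted(set(times[events == 1])):
        at_risk = times >= t
        n = at_risk.sum()
        n1 = (at_risk & (groups == groups[0])).sum()
        d = ((times == t) & (events == 1)).sum()
        d1 = ((times == t) & (events == 1) & (groups == groups[0])).sum()
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return o_minus_e ** 2 / var


class TestLogrank:
    def test_identical_patterns_give_zero(self):
        t = [1, 2, 3, 1, 2, 3]
        e = [1, 1, 1, 1, 1, 1]
        g = ["a", "a", "a", "b", "b", "b"]
        res = logrank_test(t, e, g)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_matches_hand_computation_on_six_subjects(self):
        t = [1, 3, 5, 2, 4, 6]
        e = [1, 1, 0, 1, 1, 1]
        g = ["a", "a", "a", "b", "b", "b"]
        res = logrank_test(t, e, g)
        assert res.statistic == pytest.approx(hand_logrank(t, e, g), rel=1e-9)

    def test_relabeling_invariance(self, rng):
        t = rng.exponential(10, 40)
        e = (rng.random(40) < 0.8).astype(int)
        g = rng.choice(["x", "y"], 40)
        r1 = logrank_test(t, e, g)
        swapped = np.where(g == "x", "y", "x")
        r2 = logrank_test(t, e, swapped)
        assert r1.statistic == pytest.approx(r2.statistic, rel=1e-12)

    def test_power_under_strong_hazard_ratio(self, rng):
        hits = 0
        for seed in range(10):
            r = np.random.default_rng(seed)
            h = np.r_[np.full(200, 1 / 40), np.full(200, 3 / 40)]
            t, e = simulate_survival(h, 0.2, r)
            g = np.r_[np.zeros(200), np.ones(200)]
            hits += logrank_test(t, e, g).p < 0.001
        assert hits >= 9


def grid_search_cox_beta(times, events, x):
    """Brute-force partial likelihood maximiser (no ties assumed)."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    x = np.asarray(x, float)

    def logpl(beta):
        ll = 0.0
        for i in np.flatnonzero(events):
            risk = times >= times[i]
            ll += beta * x[i] - math.log(np.exp(beta * x[risk]).sum())
        return ll

    grid = np.linspace(-5, 5, 100_001)
    vals = [logpl(b) for b in grid]
    return grid[int(np.argmax(vals))]


class TestCox:
    def test_constant_covariate_is_no_information(self):
        fit = cox_univariate([1, 2, 3, 4], [1, 1, 0, 1], [2, 2, 2, 2])
        assert fit.beta == 0.0 and fit.hr == 1.0 and fit.degenerate

    def test_eight_subject_grid_search_oracle(self):
        times = [1.0, 2.5, 3.0, 4.5, 5.0, 6.5, 7.0, 8.5]
        events = [1, 1, 1, 0, 1, 1, 0, 1]
        x = [0, 1, 0, 1, 0, 1, 0, 1]
        fit = cox_univariate(times, events, x)
        oracle = grid_search_cox_beta(times, events, x)
        assert fit.beta == pytest.approx(oracle, abs=1e-4)

    def test_parameter_recovery_exponential(self, rng):
        n = 600
        z = np.r_[np.zeros(n // 2), np.ones(n // 2)]
        h = np.where(z == 1, 2.83 / 40, 1 / 40)
        t, e = simulate_survival(h, 0.3, rng)
        fit = cox_univariate(t, e, z)
        assert 2.3 <= fit.hr <= 3.5
        assert fit.ci_low <= fit.hr <= fit.ci_high

    def test_needs_event(self):
        with pytest.raises(DataError):
            cox_univariate([1, 2], [0, 0], [0, 1])


class TestDichotomize:
    def test_mean_rule_two_values(self):
        assert dichotomize([1.0, 3.0]).tolist() == ["low", "high"]

    def test_exactly_at_mean_goes_low(self):
        assert dichotomize([0.0, 2.0, 4.0]).tolist() == ["low", "low", "high"]

    def test_nine_distinct_tertiles(self):
        labels = dichotomize(np.arange(9.0), rule="tertiles")
        assert labels.tolist() == ["T1"] * 3 + ["T2"] * 3 + ["T3"] * 3

    def test_constant_errors(self):
        with pytest.raises(DegenerateInputError):
            dichotomize([2.0, 2.0, 2.0])

    def test_random_vector_matches_rule_oracle(self, rng):
        v = rng.gamma(2, 1, 50)
        labels = dichotomize(v)
        expected = np.where(v > v.mean(), "high", "low")
        assert (labels == expected).all()

    def test_tertile_sizes_balanced(self, rng):
        v = rng.random(100)
        labels = dichotomize(v, rule="tertiles")
        counts = pd.Series(labels).value_counts()
        assert counts.max() - counts.min() <= 1
        # ranked thirds: every T1 value <= every T3 value
        assert v[labels == "T1"].max() <= v[labels == "T3"].min()


def interaction_config(seed):
    return small_sim_config(
        seed=seed,
        n_per_group=75,
        cells_per_core=80.0,
        marker_models={"CD68": MarkerModel(), "Calprotectin": MarkerModel()},
        survival=SurvivalConfig(hgp_hazard_ratio=1.0, censor_fraction=0.2),
        interaction=InteractionConfig(calprotectin_protective_hr=0.35),
    )


def run_stratified(bundle):
    from tmeprofiler import apply_thresholds, compute_densities, fit_thresholds

    thr = fit_thresholds(bundle.cells, bundle.markers)
    calls = apply_thresholds(bundle.cells, thr)
    pheno = pd.DataFrame({"CD68_total": calls["CD68"],
                          "Calprotectin_total": calls["Calprotectin"]},
                         index=bundle.cells.index)
    dm = compute_densities(bundle.cells, pheno, bundle.areas, demarcations=["stroma"])
    return stratified_prognosis(dm, bundle.clinical, "Calprotectin_total", "CD68_total")


class TestStratifiedPrognosis:
    def test_interaction_detected_only_in_high_stratum(self):
        rep = run_stratified(generate_cohort(interaction_config(seed=11)))
        assert rep.strata["high"].evaluable
        assert rep.strata["high"].p < 0.05
        assert rep.strata["low"].p > 0.05

    def test_no_interaction_is_null_in_both(self):
        cfg = interaction_config(seed=21)
        cfg.interaction = InteractionConfig(calprotectin_protective_hr=1.0)
        rep = run_stratified(generate_cohort(cfg))
        assert rep.strata["high"].evaluable and rep.strata["low"].evaluable

    def test_constant_stratifier_reported_not_raised(self):
        per_sample = []
        rng = np.random.default_rng(0)
        for i in range(10):
            per_sample.append({"sample_id": f"S{i}", "phenotype": "marker",
                               "demarcation": "stroma", "density": float(rng.random())})
            per_sample.append({"sample_id": f"S{i}", "phenotype": "strat",
                               "demarcation": "stroma", "density": 5.0})
        per_sample = pd.DataFrame(per_sample)
        dm = DensityMatrix(per_core=per_sample.assign(core_id="C1", count=np.nan,
                                                      area_mm2=np.nan),
                           per_sample=per_sample)
        clinical = make_clinical([(f"S{i}", "dHGP", 10.0 + i, 1) for i in range(10)])
        rep = stratified_prognosis(dm, clinical, "marker", "strat")
        assert not rep.strata["high"].evaluable
        assert "dichotomization failed" in rep.strata["high"].reason

    def test_tiny_stratum_not_evaluable(self):
        per_sample = []
        for i in range(6):
            per_sample.append({"sample_id": f"S{i}", "phenotype": "marker",
                               "demarcation": "stroma", "density": float(i)})
            per_sample.append({"sample_id": f"S{i}", "phenotype": "strat",
                               "demarcation": "stroma", "density": 100.0 if i == 0 else 1.0})
        per_sample = pd.DataFrame(per_sample)
        dm = DensityMatrix(per_core=per_sample.assign(core_id="C1", count=np.nan,
                                                      area_mm2=np.nan),
                           per_sample=per_sample)
        clinical = make_clinical([(f"S{i}", "dHGP", 10.0 + i, 1) for i in range(6)])
        rep = stratified_prognosis(dm, clinical, "marker", "strat")
        assert not rep.strata["high"].evaluable
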