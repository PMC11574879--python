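"""Kaplan-Meier, log-rank and univariate Cox machinery plus the
dichotomization and interaction-stratified prognosis workflows.

Estimation is delegated to lifelines (product-limit estimator, chi-square
log-rank, Cox partial likelihood with Efron tie handling) behind small
typed wrappers; the dichotomization rules and the stratified workflow are
package-owned.

Conventions: the mean cutoff is computed over the entire cohort by default
and values exactly at the mean go to "low" (same boundary convention as the
intensity gating).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import multivariate_logrank_test

from .density_metrics import DensityMatrix
from .errors import ConvergenceFailure, DataError, DegenerateInputError

LOW, HIGH = "low", "high"


@dataclass
class SurvivalCurve:
    """Product-limit estimate: S(t), at-risk counts and censoring marks."""

    time: np.ndarray
    at_risk: np.ndarray
    survival: np.ndarray
    censor_times: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time": self.time, "n_risk": self.at_risk,
                             "S": self.survival})


@dataclass(frozen=True)
class LogrankResult:
    statistic: float
    p: float
    df: int


@dataclass(frozen=True)
class CoxFit:
    beta: float
    hr: float
    ci_low: float
    ci_high: float
    se: float
    p: float
    n: int
    n_events: int
    converged: bool
    degenerate: bool = False


@dataclass
class StratumResult:
    name: str
    evaluable: bool
    reason: str = ""
    n: int = 0
    n_high: int = 0
    n_low: int = 0
    statistic: float = float("nan")
    p: float = float("nan")
    curves: dict = field(default_factory=dict)


@dataclass
class StratifiedReport:
    marker: str
    stratifier: str
    rule: str
    demarcation: str
    unstratified: StratumResult | None
    strata: dict[str, StratumResult] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# core estimators
# ---------------------------------------------------------------------------

def _check_surv(times, events) -> tuple[np.ndarray, np.ndarray]:
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=float)
    if t.size == 0:
        raise DataError("empty survival input")
    if (t < 0).any() or not np.isfinite(t).all():
        raise DataError("times must be finite and >= 0")
    if not np.isin(e, (0.0, 1.0)).all():
        raise DataError("events must be binary")
    return t, e.astype(int)


def km_estimate(times: Sequence[float], events: Sequence[int]) -> SurvivalCurve:
    """Kaplan-Meier product-limit estimator."""
    t, e = _check_surv(times, events)
    kmf = KaplanMeierFitter()
    kmf.fit(t, event_observed=e)
    table = kmf.event_table
    surv = kmf.survival_function_["KM_estimate"].reindex(table.index)
    return SurvivalCurve(
        time=table.index.to_numpy(dtype=float),
        at_risk=table["at_risk"].to_numpy(dtype=float),
        survival=surv.to_numpy(dtype=float),
        censor_times=np.sort(t[e == 0]),
    )


def logrank_test(times: Sequence[float], events: Sequence[int],
                 groups: Sequence) -> LogrankResult:
    """k-group log-rank test (chi-square with k-1 df)."""
    t, e = _check_surv(times, events)
    g = np.asarray(groups)
    if g.size != t.size:
        raise DataError("groups must match times in length")
    labels, counts = np.unique(g, return_counts=True)
    if labels.size < 2:
        raise DataError("log-rank needs at least 2 non-empty groups")
    if e.sum() < 1:
        raise DataError("log-rank needs at least 1 event")
    res = multivariate_logrank_test(t, g, e)
    return LogrankResult(statistic=float(res.test_statistic),
                         p=float(res.p_value), df=int(labels.size - 1))


def cox_univariate(times: Sequence[float], events: Sequence[int],
                   covariate: Sequence[float]) -> CoxFit:
    """Univariate Cox regression (Efron ties), Wald CI and p.

    A constant covariate carries no information: beta = 0, HR = 1 with the
    degenerate flag set.  Non-convergence or monotone likelihood raises
    :class:`ConvergenceFailure`.
    """
    t, e = _check_surv(times, events)
    x = np.asarray(covariate, dtype=float)
    if x.size != t.size:
        raise DataError("covariate must match times in length")
    if e.sum() < 1:
        raise DataError("Cox regression needs at least 1 event")
    if np.ptp(x) == 0:
        return CoxFit(beta=0.0, hr=1.0, ci_low=0.0, ci_high=np.inf, se=np.inf,
                      p=1.0, n=int(t.size), n_events=int(e.sum()),
                      converged=True, degenerate=True)
    df = pd.DataFrame({"time": t, "event": e, "x": x})
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df, duration_col="time", event_col="event")
    except ConvergenceError as exc:
        raise ConvergenceFailure(f"Cox fit failed to converge: {exc}") from exc
    beta = float(cph.params_["x"])
    se = float(cph.standard_errors_["x"])
    if not np.isfinite(beta) or not np.isfinite(se):
        raise ConvergenceFailure("Cox fit produced non-finite estimates "
                                 "(possible complete separation)")
    ci = np.exp([beta - 1.959963984540054 * se, beta + 1.959963984540054 * se])
    p = float(cph.summary.loc["x", "p"])
    return CoxFit(beta=beta, hr=float(np.exp(beta)), ci_low=float(ci[0]),
                  ci_high=float(ci[1]), se=se, p=p, n=int(t.size),
                  n_events=int(e.sum()), converged=True)


# ---------------------------------------------------------------------------
# dichotomization
# ---------------------------------------------------------------------------

def dichotomize(values: Sequence[float], rule: str = "mean") -> np.ndarray:
    """Split a biomarker into prognostic groups.

    rule "mean": {low: value <= mean, high: value > mean}.
    rule "tertiles": three groups T1 < T2 < T3 by ranked thirds (stable
    argsort, remainder spread over the lower tertiles).
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0 or not np.isfinite(v).all():
        raise DataError("values must be finite and non-empty")
    if np.ptp(v) == 0:
        raise DegenerateInputError("all values identical; no cutoff exists")
    if rule == "mean":
        if v.size < 2:
            raise DataError("mean rule needs >= 2 values")
        cut = v.mean()
        return np.where(v > cut, HIGH, LOW)
    if rule == "tertiles":
        if v.size < 3:
            raise DataError("tertile rule needs >= 3 values")
        order = np.argsort(v, kind="stable")
        labels = np.empty(v.size, dtype=object)
        for tname, chunk in zip(("T1", "T2", "T3"), np.array_split(order, 3)):
            labels[chunk] = tname
        return labels.astype(str)
    raise DataError(f"unknown dichotomization rule {rule!r}")


# ---------------------------------------------------------------------------
# stratified prognosis workflow
# ---------------------------------------------------------------------------

def _marker_logrank(sub: pd.DataFrame, name: str, min_group: int) -> StratumResult:
    n_high = int((sub["marker_group"] == HIGH).sum())
    n_low = int((sub["marker_group"] == LOW).sum())
    res = StratumResult(name=name, evaluable=False, n=len(sub),
                        n_high=n_high, n_low=n_low)
    if min(n_high, n_low) < min_group:
        res.reason = (f"needs >= {min_group} subjects per marker group, "
                      f"got high={n_high}, low={n_low}")
        return res
    if sub["event"].sum() < 1:
        res.reason = "no events in stratum"
        return res
    lr = logrank_test(sub["os_months"], sub["event"], sub["marker_group"])
    res.evaluable = True
    res.statistic, res.p = lr.statistic, lr.p
    for g in (LOW, HIGH):
        gsub = sub[sub["marker_group"] == g]
        if len(gsub):
            res.curves[g] = km_estimate(gsub["os_months"], gsub["event"])
    return res


def stratified_prognosis(
    dm: DensityMatrix,
    clinical: pd.DataFrame,
    marker: str,
    stratifier: str,
    rule: str = "mean",
    demarcation: str = "stroma",
    min_group: int = 2,
) -> StratifiedReport:
    """Marker prognosis inside stratifier-high and -low subsets.

    Both the stratifier and the marker are dichotomized over the entire
    cohort (mean rule by default).  Within each stratum a log-rank test
    compares marker-high vs marker-low; strata with fewer than ``min_group``
    subjects per marker group are reported as not-evaluable, never raised.
    """
    marker_dens = dm.get(marker, demarcation)
    strat_dens = dm.get(stratifier, demarcation)
    clin = clinical.copy()
    clin["sample_id"] = clin["sample_id"].astype(str)
    merged = clin.set_index("sample_id").join(
        pd.DataFrame({"marker_value": marker_dens, "strat_value": strat_dens}),
        how="inner")
    merged = merged.dropna(subset=["marker_value", "strat_value", "os_months", "event"])
    if len(merged) < 2 * min_group:
        raise DataError("too few samples with both densities and clinical data")

    report = StratifiedReport(marker=marker, stratifier=stratifier, rule=rule,
                              demarcation=demarcation, unstratified=None)
    try:
        merged["marker_group"] = dichotomize(merged["marker_value"], rule)
    except DegenerateInputError as exc:
        for name in (HIGH, LOW, "unstratified"):
            res = StratumResult(name=name, evaluable=False,
                                reason=f"marker dichotomization failed: {exc}")
            if name == "unstratified":
                report.unstratified = res
            else:
                report.strata[name] = res
        return report

    report.unstratified = _marker_logrank(merged, "unstratified", min_group)

    try:
        merged["stratum"] = dichotomize(merged["strat_value"], rule)
    except DegenerateInputError as exc:
        for name in (HIGH, LOW):
            report.strata[name] = StratumResult(
                name=name, evaluable=False,
                reason=f"stratifier dichotomization failed: {exc}")
        return report

    for name in (HIGH, LOW):
        sub = merged[merged["stratum"] == name]
        if len(sub) == 0:
            report.strata[name] = StratumResult(name=name, evaluable=False,
                                                reason="empty stratum")
            continue
        report.strata[name] = _marker_logrank(sub, name, min_group)
    return report
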