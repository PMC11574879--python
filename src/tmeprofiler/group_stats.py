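"""Two-group rank tests, multiplicity control and co-infiltration matrices.

The group comparison is a Mann-Whitney U test in which zero observations
are retained in the pooled mid-ranking ("Pratt-style" handling of
zero-inflated density data) and the variance of the normal approximation is
tie-corrected.  For small pooled sizes the two-sided p-value comes from
exact enumeration of all group labelings, which sidesteps the
approximation entirely.

Adjustment offers Holm-Bonferroni (step-down, family-wise error) and
Benjamini-Hochberg (step-up, false discovery rate); both preserve input
order and cap at 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .density_metrics import DensityMatrix
from .errors import DataError, SchemaError

EXACT_MAX_N = 10


@dataclass(frozen=True)
class TestResult:
    u: float
    z: float
    p_raw: float
    n1: int
    n2: int
    exact: bool
    tie_correction_applied: bool
    degenerate: bool
    median1: float
    median2: float
    mean1: float
    mean2: float
    iqr1: float
    iqr2: float


def _iqr(a: np.ndarray) -> float:
    if a.size == 0:
        return float("nan")
    q75, q25 = np.percentile(a, [75, 25])
    return float(q75 - q25)


def mann_whitney_pratt(
    x: Sequence[float],
    y: Sequence[float],
    exact_max_n: int = EXACT_MAX_N,
) -> TestResult:
    """Two-sided Mann-Whitney U test retaining zeros, with tie correction.

    Mid-ranks are computed over the pooled sample with zeros included.  For
    pooled N <= ``exact_max_n`` the p-value is the exact permutation tail
    probability P(|U - n1 n2 / 2| >= |u_obs - n1 n2 / 2|) over all
    C(N, n1) labelings.  Otherwise a continuity-corrected normal
    approximation with tie-corrected variance

        sigma^2 = (n1 n2 / 12) * [(N + 1) - sum(t^3 - t) / (N (N - 1))]

    is used.  Identical pooled values give p = 1 with the degenerate flag.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = x.size, y.size
    if n1 < 1 or n2 < 1:
        raise DataError("both groups need at least one observation")
    pooled = np.concatenate([x, y])
    n = n1 + n2
    ranks = sps.rankdata(pooled)  # mid-ranks; zeros retained
    r1 = float(ranks[:n1].sum())
    u = r1 - n1 * (n1 + 1) / 2.0  # U statistic of group 1, in [0, n1*n2]
    mu = n1 * n2 / 2.0

    summaries = dict(
        median1=float(np.median(x)), median2=float(np.median(y)),
        mean1=float(np.mean(x)), mean2=float(np.mean(y)),
        iqr1=_iqr(x), iqr2=_iqr(y),
    )

    _, tie_counts = np.unique(pooled, return_counts=True)
    has_ties = bool((tie_counts > 1).any())

    if np.ptp(pooled) == 0:
        return TestResult(u=u, z=0.0, p_raw=1.0, n1=n1, n2=n2, exact=False,
                          tie_correction_applied=has_ties, degenerate=True,
                          **summaries)

    if n <= exact_max_n:
        obs_dev = abs(u - mu)
        base = n1 * (n1 + 1) / 2.0
        hits = 0
        total = 0
        for idx in combinations(range(n), n1):
            u_perm = ranks[list(idx)].sum() - base
            if abs(u_perm - mu) >= obs_dev - 1e-12:
                hits += 1
            total += 1
        p = hits / total
        return TestResult(u=u, z=float("nan"), p_raw=float(p), n1=n1, n2=n2,
                          exact=True, tie_correction_applied=has_ties,
                          degenerate=False, **summaries)

    tie_term = float(((tie_counts ** 3) - tie_counts).sum())
    sigma2 = (n1 * n2 / 12.0) * ((n + 1) - tie_term / (n * (n - 1)))
    sigma = math.sqrt(sigma2)
    z = max(abs(u - mu) - 0.5, 0.0) / sigma  # continuity correction
    p = min(1.0, 2.0 * sps.norm.sf(z))
    z_signed = math.copysign(z, u - mu) if u != mu else 0.0
    return TestResult(u=u, z=z_signed, p_raw=float(p), n1=n1, n2=n2,
                      exact=False, tie_correction_applied=has_ties,
                      degenerate=False, **summaries)


def adjust_pvalues(pvalues: Sequence[float], method: str = "holm") -> np.ndarray:
    """Holm step-down or Benjamini-Hochberg step-up adjustment.

    Input order is preserved; outputs are capped at 1 and monotone in the
    sorted order.  NaN entries stay NaN and do not count toward the family
    size.
    """
    p = np.asarray(pvalues, dtype=float)
    valid = ~np.isnan(p)
    if ((p[valid] < 0) | (p[valid] > 1)).any():
        raise SchemaError("p-values must lie in [0, 1]")
    out = np.full(p.shape, np.nan)
    pv = p[valid]
    m = pv.size
    if m == 0:
        return out
    order = np.argsort(pv, kind="stable")
    sorted_p = pv[order]
    if method == "holm":
        adj = np.maximum.accumulate((m - np.arange(m)) * sorted_p)
    elif method == "bh":
        adj = (m / (np.arange(m) + 1.0)) * sorted_p
        adj = np.minimum.accumulate(adj[::-1])[::-1]
    else:
        raise SchemaError(f"unknown adjustment method {method!r}")
    adj = np.minimum(adj, 1.0)
    restored = np.empty(m)
    restored[order] = adj
    out[valid] = restored
    return out


# ---------------------------------------------------------------------------
# Spearman machinery
# ---------------------------------------------------------------------------

def spearman_rho(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rho as Pearson correlation of mid-ranks, with t-approx p.

    Pairs with a missing member are dropped (pairwise-complete); constant
    input yields (nan, nan).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    mask = np.isfinite(x) & np.isfinite(y)
    x, y = x[mask], y[mask]
    n = x.size
    if n < 3 or np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan"), float("nan")
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = math.sqrt(float((rx ** 2).sum() * (ry ** 2).sum()))
    rho = float((rx * ry).sum() / denom)
    rho = max(-1.0, min(1.0, rho))
    if abs(rho) == 1.0:
        return rho, 0.0
    t = rho * math.sqrt((n - 2) / (1.0 - rho ** 2))
    p = float(2.0 * sps.t.sf(abs(t), df=n - 2))
    return rho, min(1.0, p)


@dataclass
class CorrMatrix:
    """Phenotype x phenotype Spearman rho and p for one group and scope."""

    rho: pd.DataFrame
    p: pd.DataFrame
    group: str
    scope: str

    def to_long(self) -> pd.DataFrame:
        rows = []
        for a in self.rho.index:
            for b in self.rho.columns:
                rows.append({"group": self.group, "scope": self.scope,
                             "pheno_a": a, "pheno_b": b,
                             "rho": self.rho.loc[a, b], "p": self.p.loc[a, b]})
        return pd.DataFrame(rows)


def spearman_matrix(
    dm: DensityMatrix,
    clinical: pd.DataFrame,
    group: str,
    scope: str = "total_excluding_liver",
    phenotypes: Sequence[str] | None = None,
) -> CorrMatrix:
    """Pairwise co-infiltration correlations within one growth-pattern group."""
    wide = dm.wide(scope)
    samples = clinical.loc[clinical["hgp"] == group, "sample_id"].astype(str)
    wide = wide.loc[wide.index.intersection(samples)]
    if len(wide) < 3:
        raise DataError(f"group {group!r} has fewer than 3 samples in scope {scope!r}")
    if phenotypes is not None:
        wide = wide[list(phenotypes)]
    cols = list(wide.columns)
    k = len(cols)
    rho = np.full((k, k), np.nan)
    pmat = np.full((k, k), np.nan)
    for i in range(k):
        rho[i, i], pmat[i, i] = 1.0, 0.0
        for j in range(i + 1, k):
            r, pv = spearman_rho(wide[cols[i]].to_numpy(), wide[cols[j]].to_numpy())
            rho[i, j] = rho[j, i] = r
            pmat[i, j] = pmat[j, i] = pv
    return CorrMatrix(rho=pd.DataFrame(rho, index=cols, columns=cols),
                      p=pd.DataFrame(pmat, index=cols, columns=cols),
                      group=group, scope=scope)


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def compare_hgp(
    dm: DensityMatrix,
    clinical: pd.DataFrame,
    ratios: pd.DataFrame | None = None,
    phenotypes: Sequence[str] | None = None,
    demarcations: Sequence[str] | None = None,
    groups: tuple[str, str] = ("dHGP", "non_dHGP"),
    family_by: str = "demarcation",
) -> pd.DataFrame:
    """One tie-corrected rank test per phenotype x demarcation (and ratio).

    Holm and BH adjustments are applied within families; the default family
    is one per demarcation (per-panel figure-style families can be obtained
    by filtering phenotypes before the call).  Ratio metrics form their own
    family; their missing values (zero denominators) are dropped pairwise.
    """
    g1, g2 = groups
    sample_groups = clinical.set_index(clinical["sample_id"].astype(str))["hgp"]
    for g in groups:
        if int((sample_groups == g).sum()) < 2:
            raise DataError(f"group {g!r} has fewer than 2 samples")

    rows: list[dict] = []
    phenos = phenotypes if phenotypes is not None else dm.phenotypes
    dems = demarcations if demarcations is not None else dm.demarcations
    for dem in dems:
        wide = dm.wide(dem)
        grp = sample_groups.reindex(wide.index)
        for pheno in phenos:
            if pheno not in wide.columns:
                raise SchemaError(f"unknown phenotype {pheno!r}")
            vals = wide[pheno]
            rows.append(_one_row(pheno, dem, vals, grp, g1, g2))

    if ratios is not None:
        grp = sample_groups.reindex(ratios.index.astype(str))
        for name in ratios.columns:
            rows.append(_one_row(name, "(ratio)", ratios[name], grp, g1, g2))

    report = pd.DataFrame(rows)
    report["p_holm"] = np.nan
    report["p_fdr"] = np.nan
    family = report[family_by] if family_by in report.columns else pd.Series(
        ["all"] * len(report))
    for _, idx in report.groupby(family, observed=True).groups.items():
        report.loc[idx, "p_holm"] = adjust_pvalues(report.loc[idx, "p_raw"], "holm")
        report.loc[idx, "p_fdr"] = adjust_pvalues(report.loc[idx, "p_raw"], "bh")
    return report


def _one_row(pheno: str, dem: str, vals: pd.Series, grp: pd.Series,
             g1: str, g2: str) -> dict:
    mask = vals.notna() & grp.notna()
    x = vals[mask & (grp == g1)].to_numpy(dtype=float)
    y = vals[mask & (grp == g2)].to_numpy(dtype=float)
    if x.size < 1 or y.size < 1:
        return {"phenotype": pheno, "demarcation": dem, "n1": x.size, "n2": y.size,
                "u": np.nan, "z": np.nan, "p_raw": np.nan, "direction": "none",
                f"mean_{g1}": np.nan, f"mean_{g2}": np.nan,
                f"median_{g1}": np.nan, f"median_{g2}": np.nan,
                f"iqr_{g1}": np.nan, f"iqr_{g2}": np.nan,
                "tie_correction_applied": False, "degenerate": True}
    res = mann_whitney_pratt(x, y)
    if res.mean1 > res.mean2:
        direction = g1
    elif res.mean1 < res.mean2:
        direction = g2
    else:
        direction = "none"
    return {"phenotype": pheno, "demarcation": dem, "n1": res.n1, "n2": res.n2,
            "u": res.u, "z": res.z, "p_raw": res.p_raw, "direction": direction,
            f"mean_{g1}": res.mean1, f"mean_{g2}": res.mean2,
            f"median_{g1}": res.median1, f"median_{g2}": res.median2,
            f"iqr_{g1}": res.iqr1, f"iqr_{g2}": res.iqr2,
            "tie_correction_applied": res.tie_correction_applied,
            "degenerate": res.degenerate}
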