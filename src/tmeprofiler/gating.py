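"""Marker positivity thresholds and intensity tiers.

Continuous marker intensities become boolean positive/negative calls via a
per-marker threshold, fitted cohort-wide by default.  The ``kde_valley``
method places the cutoff at the density minimum between the two largest
modes of a Gaussian kernel density estimate on log-intensities.  Tiered
markers are further split into high/low at the arithmetic mean intensity of
the positive cells.

Boundary conventions (frozen):

* positivity is ``intensity >= threshold``;
* the high tier is ``intensity > mean-of-positives`` — a cell exactly at
  the mean is "low".
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

from .datamodel_io import MARKER_SUFFIX
from .errors import DegenerateInputError, NoValleyError, SchemaError

KDE_GRID_SIZE = 512
KDE_MIN_N = 50

TIER_HIGH = "high"
TIER_LOW = "low"
TIER_NEGATIVE = "negative"


@dataclass(frozen=True)
class Threshold:
    """A positivity cutoff for one marker, with fit provenance."""

    marker: str
    value: float
    method: str
    params: dict = field(default_factory=dict)
    diagnostics: dict = field(default_factory=dict)


def _as_finite_array(values: Sequence[float]) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    arr = arr[np.isfinite(arr)]
    if arr.size == 0:
        raise DegenerateInputError("no finite intensity values")
    return arr


def _kde_valley(arr: np.ndarray, bandwidth: float | None, grid_size: int) -> tuple[float, int]:
    """Density minimum between the two largest KDE modes on the log scale.

    Returns (threshold on the original scale, number of modes found).
    """
    pos = arr[arr > 0]
    if pos.size < KDE_MIN_N:
        raise DegenerateInputError(
            f"kde_valley needs >= {KDE_MIN_N} positive values, got {pos.size}")
    log_x = np.log(pos)
    if np.ptp(log_x) == 0:
        raise DegenerateInputError("constant intensities; no threshold exists")
    kde = gaussian_kde(log_x, bw_method=bandwidth if bandwidth is not None else "silverman")
    grid = np.linspace(log_x.min(), log_x.max(), grid_size)
    dens = kde(grid)

    # interior local maxima; flat plateaus collapse to their last point
    peaks = [i for i in range(1, grid_size - 1)
             if dens[i] >= dens[i - 1] and dens[i] > dens[i + 1]]
    # endpoints can carry a mode truncated by the data range
    if dens[0] > dens[1]:
        peaks.insert(0, 0)
    if dens[-1] > dens[-2]:
        peaks.append(grid_size - 1)
    if len(peaks) < 2:
        raise NoValleyError(
            f"found {len(peaks)} mode(s); distribution appears unimodal")
    top2 = sorted(sorted(peaks, key=lambda i: dens[i], reverse=True)[:2])
    lo, hi = top2
    valley = lo + int(np.argmin(dens[lo:hi + 1]))
    return float(np.exp(grid[valley])), len(peaks)


def fit_threshold(
    values: Sequence[float],
    method: str = "kde_valley",
    *,
    bandwidth: float | None = None,
    grid_size: int = KDE_GRID_SIZE,
    quantile: float | None = None,
    value: float | None = None,
    marker: str = "",
) -> Threshold:
    """Fit a positivity threshold for one marker's intensities.

    method "kde_valley": minimum-density point between the two largest KDE
    modes (Gaussian kernel, Silverman bandwidth unless pinned, 512-point
    grid on the log scale).  Raises :class:`NoValleyError` on unimodal
    input so the caller can fall back to "quantile" or "fixed".

    method "quantile": the stated quantile of the values.

    method "fixed": echoes the user-supplied ``value``.
    """
    if method == "fixed":
        if value is None:
            raise SchemaError("method 'fixed' requires value=")
        return Threshold(marker=marker, value=float(value), method="fixed",
                         diagnostics={"n_cells": len(values)})

    arr = _as_finite_array(values)
    if np.ptp(arr) == 0:
        raise DegenerateInputError("constant intensities; no threshold exists")

    if method == "quantile":
        if quantile is None:
            raise SchemaError("method 'quantile' requires quantile=")
        if not 0.0 <= quantile <= 1.0:
            raise SchemaError(f"quantile must be in [0, 1], got {quantile}")
        # paper-style gating wants the quantile attainable as a cutoff, so use
        # the plain empirical quantile (linear interpolation, numpy default)
        thr = float(np.quantile(arr, quantile))
        return Threshold(marker=marker, value=thr, method="quantile",
                         params={"quantile": quantile},
                         diagnostics={"n_cells": int(arr.size)})

    if method == "kde_valley":
        thr, modes = _kde_valley(arr, bandwidth, grid_size)
        return Threshold(marker=marker, value=thr, method="kde_valley",
                         params={"bandwidth": bandwidth, "grid_size": grid_size},
                         diagnostics={"n_cells": int(arr.size), "modes_found": modes})

    raise SchemaError(f"unknown threshold method {method!r}")


def fit_thresholds(
    cells: pd.DataFrame,
    markers: Sequence[str],
    method: str = "kde_valley",
    fallback_quantile: float = 0.95,
    **kwargs,
) -> dict[str, Threshold]:
    """Fit one threshold per marker over the whole cohort.

    A unimodal marker under "kde_valley" falls back to the
    ``fallback_quantile`` empirical quantile (recorded in the method field).
    """
    out: dict[str, Threshold] = {}
    for m in markers:
        col = m + MARKER_SUFFIX
        if col not in cells.columns:
            raise SchemaError(f"marker {m!r}: column {col!r} not in cell table")
        vals = cells[col].to_numpy(dtype=float)
        try:
            out[m] = fit_threshold(vals, method=method, marker=m, **kwargs)
        except NoValleyError:
            out[m] = fit_threshold(vals, method="quantile",
                                   quantile=fallback_quantile, marker=m)
    return out


def apply_thresholds(
    cells: pd.DataFrame,
    thresholds: Mapping[str, Threshold | float],
    markers: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Boolean positive/negative calls, one column per marker.

    A call is ``intensity >= threshold``.  When ``markers`` is given, every
    listed marker must have a threshold (error names the first one missing).
    """
    wanted = list(markers) if markers is not None else list(thresholds)
    calls = pd.DataFrame(index=cells.index)
    for m in wanted:
        if m not in thresholds:
            raise SchemaError(f"marker {m!r} has no threshold")
        thr = thresholds[m]
        cut = thr.value if isinstance(thr, Threshold) else float(thr)
        col = m + MARKER_SUFFIX
        if col not in cells.columns:
            raise SchemaError(f"marker {m!r}: column {col!r} not in cell table")
        calls[m] = cells[col].to_numpy(dtype=float) >= cut
    return calls


def split_intensity_tiers(
    cells: pd.DataFrame,
    marker: str,
    calls: pd.DataFrame,
) -> pd.Series:
    """Split a marker's positive cells into high/low at their mean intensity.

    The cutoff is the arithmetic mean intensity over marker-positive cells,
    cohort-wide.  Cells strictly above the mean are "high"; positives at or
    below it are "low"; negative cells stay "negative".
    """
    if marker not in calls.columns:
        raise SchemaError(f"marker {marker!r} has no positivity calls")
    col = marker + MARKER_SUFFIX
    pos = calls[marker].to_numpy(dtype=bool)
    if not pos.any():
        raise DegenerateInputError(f"no positive cells for marker {marker!r}")
    intens = cells[col].to_numpy(dtype=float)
    cutoff = float(intens[pos].mean())
    tiers = np.where(~pos, TIER_NEGATIVE, np.where(intens > cutoff, TIER_HIGH, TIER_LOW))
    out = pd.Series(tiers, index=cells.index, name=marker)
    out.attrs["cutoff"] = cutoff
    return out


def thresholds_to_frame(thresholds: Mapping[str, Threshold]) -> pd.DataFrame:
    rows = [{"marker": t.marker or m, "value": t.value, "method": t.method,
             "params": repr(t.params)} for m, t in thresholds.items()]
    return pd.DataFrame(rows, columns=["marker", "value", "method", "params"])


def write_thresholds(thresholds: Mapping[str, Threshold], path: str | Path) -> None:
    thresholds_to_frame(thresholds).to_csv(path, sep="\t", index=False)


def read_thresholds(path: str | Path) -> dict[str, Threshold]:
    """Read a threshold TSV back; rows become method="fixed" cutoffs."""
    df = pd.read_csv(path, sep="\t")
    for col in ("marker", "value"):
        if col not in df.columns:
            raise SchemaError(f"threshold table missing column {col!r}")
    return {str(r.marker): Threshold(marker=str(r.marker), value=float(r.value),
                                     method="fixed")
            for r in df.itertuples(index=False)}
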