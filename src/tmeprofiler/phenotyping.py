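"""Declarative marker-combination phenotypes and combination enumeration.

Panels are data, not code: a YAML file lists phenotype definitions
(required-positive markers, required-negative markers, optional tier
constraints, and an ``exclusive_single`` flag meaning "negative for every
other panel marker").  Three panel files covering the lymphoid, myeloid and
fibroblast compartments ship with the package.

The module also enumerates the full mutually-exclusive combination lattice
over a marker set (tiered markers expand into their high/low levels) and
applies the minimum-fraction retention rule used to pick combination
subsets worth analysing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import CombinationGuardError, SchemaError
from .gating import TIER_HIGH, TIER_LOW, TIER_NEGATIVE

MAX_COMBINATION_MARKERS = 12


@dataclass(frozen=True)
class PhenotypeDef:
    """A boolean marker-combination rule naming one phenotype."""

    name: str
    positive: frozenset[str] = frozenset()
    negative: frozenset[str] = frozenset()
    tiers: Mapping[str, str] = field(default_factory=dict)
    exclusive_single: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "positive", frozenset(self.positive))
        object.__setattr__(self, "negative", frozenset(self.negative))
        if self.positive & self.negative:
            raise SchemaError(
                f"phenotype {self.name!r}: markers {sorted(self.positive & self.negative)} "
                "are both required-positive and required-negative")
        for m, t in self.tiers.items():
            if t not in (TIER_HIGH, TIER_LOW):
                raise SchemaError(f"phenotype {self.name!r}: invalid tier {t!r} for {m!r}")


@dataclass
class Panel:
    """A named list of phenotype definitions over a fixed marker set."""

    name: str
    markers: tuple[str, ...]
    phenotypes: list[PhenotypeDef]
    tiered_markers: tuple[str, ...] = ()
    #: (parent phenotype, [mutually exclusive parts]) pairs for audit sums
    partitions: list[tuple[str, list[str]]] = field(default_factory=list)

    def __post_init__(self) -> None:
        known = set(self.markers)
        for p in self.phenotypes:
            bad = (p.positive | p.negative | set(p.tiers)) - known
            if bad:
                raise SchemaError(
                    f"panel {self.name!r}: phenotype {p.name!r} references unknown "
                    f"markers {sorted(bad)}")

    def phenotype_names(self) -> list[str]:
        return [p.name for p in self.phenotypes]


@dataclass
class PhenotypeCalls:
    """Boolean cell x phenotype matrix plus the panel's audit partitions."""

    matrix: pd.DataFrame
    panel: Panel

    def counts(self) -> pd.Series:
        return self.matrix.sum(axis=0)


def load_panel(path: str | Path) -> Panel:
    """Load a panel definition from YAML."""
    raw = yaml.safe_load(Path(path).read_text())
    try:
        phenos = [
            PhenotypeDef(
                name=d["name"],
                positive=frozenset(d.get("positive", [])),
                negative=frozenset(d.get("negative", [])),
                tiers=dict(d.get("tiers", {})),
                exclusive_single=bool(d.get("exclusive_single", False)),
            )
            for d in raw["phenotypes"]
        ]
        panel = Panel(
            name=raw["name"],
            markers=tuple(raw["markers"]),
            phenotypes=phenos,
            tiered_markers=tuple(raw.get("tiered_markers", [])),
            partitions=[(p["parent"], list(p["parts"])) for p in raw.get("partitions", [])],
        )
    except KeyError as exc:  # pragma: no cover - defensive
        raise SchemaError(f"panel file {path}: missing key {exc}") from exc
    return panel


def builtin_panel(name: str) -> Panel:
    """Load one of the shipped panels: 'lymphoid', 'myeloid' or 'caf'."""
    ref = resources.files("tmeprofiler").joinpath("panels", f"{name}.yaml")
    with resources.as_file(ref) as path:
        return load_panel(path)


def _match(defn: PhenotypeDef, calls: pd.DataFrame, tiers: pd.DataFrame | None,
           panel_markers: Sequence[str]) -> np.ndarray:
    for m in defn.positive | defn.negative | set(defn.tiers):
        if m not in calls.columns:
            raise SchemaError(f"phenotype {defn.name!r} references marker {m!r} "
                              "absent from the marker calls")
    mask = np.ones(len(calls), dtype=bool)
    for m in defn.positive:
        mask &= calls[m].to_numpy(dtype=bool)
    negatives = set(defn.negative)
    if defn.exclusive_single:
        negatives |= set(panel_markers) - defn.positive
    for m in negatives:
        if m not in calls.columns:
            raise SchemaError(f"phenotype {defn.name!r} requires marker {m!r} "
                              "absent from the marker calls")
        mask &= ~calls[m].to_numpy(dtype=bool)
    for m, wanted in defn.tiers.items():
        if tiers is None or m not in tiers.columns:
            raise SchemaError(f"phenotype {defn.name!r} needs tier calls for {m!r}")
        mask &= (tiers[m].to_numpy() == wanted)
    return mask


def assign_phenotypes(
    calls: pd.DataFrame,
    tiers: pd.DataFrame | None,
    panel: Panel,
) -> PhenotypeCalls:
    """Evaluate every panel definition against the boolean marker calls.

    A cell matches a definition iff all positivity, negativity and tier
    constraints hold; cells may match several non-exclusive definitions.
    """
    matrix = pd.DataFrame(index=calls.index)
    for defn in panel.phenotypes:
        matrix[defn.name] = _match(defn, calls, tiers, panel.markers)
    return PhenotypeCalls(matrix=matrix, panel=panel)


# ---------------------------------------------------------------------------
# combination lattice
# ---------------------------------------------------------------------------

def signature_of(tokens: Sequence[str]) -> str:
    return "&".join(tokens)


def enumerate_combinations(
    calls: pd.DataFrame,
    tiers: pd.DataFrame | None,
    markers: Sequence[str],
    denominator: PhenotypeDef | pd.Series,
    sample_ids: pd.Series,
    tiered: Sequence[str] = (),
) -> pd.DataFrame:
    """Per-sample fractions over the exclusive marker-combination lattice.

    Every denominator cell maps to exactly one signature string (tiered
    markers contribute ``<m>_high`` / ``<m>_low`` / ``<m>-`` levels, plain
    markers ``<m>+`` / ``<m>-``).  Fractions are computed over the sample's
    denominator count; samples with an empty denominator get missing rows.
    """
    markers = list(markers)
    if len(markers) > MAX_COMBINATION_MARKERS:
        raise CombinationGuardError(
            f"{len(markers)} markers would enumerate {3 ** len(markers)}+ signatures; "
            f"limit is {MAX_COMBINATION_MARKERS}")
    if isinstance(denominator, PhenotypeDef):
        denom_mask = _match(denominator, calls, tiers, markers)
    else:
        denom_mask = denominator.to_numpy(dtype=bool)

    tiered = set(tiered)
    token_cols = []
    for m in markers:
        if m in tiered:
            if tiers is None or m not in tiers.columns:
                raise SchemaError(f"tiered marker {m!r} has no tier calls")
            lvl = tiers[m].to_numpy()
            tok = np.where(lvl == TIER_NEGATIVE, m + "-", m + "_" + lvl)
        else:
            tok = np.where(calls[m].to_numpy(dtype=bool), m + "+", m + "-")
        token_cols.append(tok)
    sig = np.array([signature_of(t) for t in zip(*token_cols)]) if token_cols else np.array([])

    df = pd.DataFrame({
        "sample_id": sample_ids.to_numpy(),
        "signature": sig,
        "in_denom": denom_mask,
    })
    denom_counts = df.groupby("sample_id", observed=True)["in_denom"].sum()
    hits = (df[df["in_denom"]]
            .groupby(["sample_id", "signature"], observed=True)
            .size()
            .unstack(fill_value=0))
    # all samples present, even those with no denominator cells
    hits = hits.reindex(denom_counts.index, fill_value=0)
    frac = hits.div(denom_counts.replace(0, np.nan), axis=0)
    frac.index.name = "sample_id"
    frac.columns.name = "signature"
    return frac


def filter_combinations(
    table: pd.DataFrame,
    min_fraction: float = 0.15,
) -> list[str]:
    """Signatures whose maximum per-sample fraction exceeds ``min_fraction``.

    Output is sorted by maximum fraction, descending.  ``min_fraction=0``
    therefore retains every signature observed in at least one sample.
    """
    if table.empty:
        raise SchemaError("empty combination-fraction table")
    max_frac = table.max(axis=0, skipna=True)
    kept = max_frac[max_frac > min_fraction]
    return list(kept.sort_values(ascending=False).index)
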