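"""Compartment-stratified cell densities and ratio metrics.

Per core, a density is (cells matching the phenotype within the
demarcation) / (demarcation area in mm2).  Derived demarcations pool counts
and areas over their base compartments *before* dividing, so the tumor-area
density is (n_nest + n_stroma) / (a_nest + a_stroma), not a mean of the two
compartment densities.  The sample-level value is the unweighted mean over
the sample's cores (TMA convention; two cores per patient by default).

Ratio metrics divide two sample-level densities; a zero denominator yields
a missing value rather than infinity or a pseudocounted ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .datamodel_io import BASE_COMPARTMENTS, DEMARCATIONS, DERIVED_DEMARCATIONS
from .errors import DataError, SchemaError
from .phenotyping import PhenotypeCalls


@dataclass
class DensityMatrix:
    """Sample x (phenotype, demarcation) densities with per-core detail."""

    per_core: pd.DataFrame  # sample_id, core_id, phenotype, demarcation, count, area_mm2, density
    per_sample: pd.DataFrame  # sample_id, phenotype, demarcation, density

    @property
    def phenotypes(self) -> list[str]:
        return sorted(self.per_sample["phenotype"].unique())

    @property
    def demarcations(self) -> list[str]:
        return sorted(self.per_sample["demarcation"].unique())

    def wide(self, demarcation: str) -> pd.DataFrame:
        """Samples x phenotypes density table for one demarcation."""
        sub = self.per_sample[self.per_sample["demarcation"] == demarcation]
        return sub.pivot(index="sample_id", columns="phenotype", values="density")

    def get(self, phenotype: str, demarcation: str) -> pd.Series:
        sub = self.per_sample[
            (self.per_sample["phenotype"] == phenotype)
            & (self.per_sample["demarcation"] == demarcation)
        ]
        return sub.set_index("sample_id")["density"]

    def to_tsv(self, path: str | Path) -> None:
        self.per_sample.to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class RatioSpec:
    """numerator density / denominator density, both at sample level."""

    name: str
    numerator: tuple[str, str]  # (phenotype, demarcation)
    denominator: tuple[str, str]


def default_ratio_specs(demarcations: Sequence[str] = ("tumor_nest", "stroma")) -> list[RatioSpec]:
    """The shipped ratio metrics.

    SIA variants divide CD8 density by an immunosuppressive myeloid
    population, stromal compartment by default; the exclusion ratio divides
    intraepithelial (tumor-nest) CD8 by stromal CD8.
    """
    specs = [
        RatioSpec("SIA_M2", ("CD8_total", "stroma"), ("M2", "stroma")),
        RatioSpec("SIA_myeloid_nonmac", ("CD8_total", "stroma"),
                  ("myeloid_nonmacrophage", "stroma")),
        RatioSpec("SIA_calprotectin", ("CD8_total", "stroma"),
                  ("Calprotectin_total", "stroma")),
        RatioSpec("CD8tumor_over_CD8stroma", ("CD8_total", "tumor_nest"),
                  ("CD8_total", "stroma")),
        RatioSpec("CD8tumor_over_CD4stroma", ("CD8_total", "tumor_nest"),
                  ("CD4_total", "stroma")),
    ]
    for dem in demarcations:
        specs.append(RatioSpec(f"CD8_over_CD4_{dem}", ("CD8_total", dem), ("CD4_total", dem)))
    return specs


def compute_densities(
    cells: pd.DataFrame,
    pheno: PhenotypeCalls | pd.DataFrame,
    areas: pd.DataFrame,
    demarcations: Sequence[str] = DEMARCATIONS,
) -> DensityMatrix:
    """Count/area densities per core and their per-sample means.

    Cores are taken from the area table, so a core with zero matching cells
    still contributes a zero density.  A nonzero count over a missing or
    non-positive area raises :class:`DataError`.
    """
    matrix = pheno.matrix if isinstance(pheno, PhenotypeCalls) else pheno
    for dem in demarcations:
        if dem not in DEMARCATIONS:
            raise SchemaError(f"unknown demarcation {dem!r}")

    key = cells[["sample_id", "core_id", "compartment"]].astype(
        {"sample_id": str, "core_id": str})
    counts = (
        matrix.astype(int)
        .groupby([key["sample_id"], key["core_id"], key["compartment"]], observed=True)
        .sum()
    )

    base = areas[areas["demarcation"].isin(BASE_COMPARTMENTS)]
    area_map: dict[tuple[str, str, str], float] = {
        (str(r.sample_id), str(r.core_id), r.demarcation): float(r.area_mm2)
        for r in base.itertuples(index=False)
    }
    cores = sorted({(str(r.sample_id), str(r.core_id)) for r in areas.itertuples(index=False)})

    phenotypes = list(matrix.columns)
    rows: list[dict] = []
    for sid, cid in cores:
        for dem in demarcations:
            comps = DERIVED_DEMARCATIONS.get(dem, (dem,))
            area_terms = [area_map.get((sid, cid, c)) for c in comps]
            count_vec = np.zeros(len(phenotypes))
            for c in comps:
                if (sid, cid, c) in counts.index:
                    count_vec += counts.loc[(sid, cid, c)].to_numpy(dtype=float)
            if any(a is None for a in area_terms):
                if count_vec.any():
                    raise DataError(
                        f"cells counted in ({sid}, {cid}, {dem}) but base area missing")
                continue
            area = float(sum(area_terms))
            if area <= 0:
                if count_vec.any():
                    raise DataError(
                        f"cells counted in ({sid}, {cid}, {dem}) but area is {area}")
                continue
            for p, n in zip(phenotypes, count_vec):
                rows.append({"sample_id": sid, "core_id": cid, "phenotype": p,
                             "demarcation": dem, "count": n, "area_mm2": area,
                             "density": n / area})

    per_core = pd.DataFrame(rows, columns=["sample_id", "core_id", "phenotype",
                                           "demarcation", "count", "area_mm2", "density"])
    per_sample = (
        per_core.groupby(["sample_id", "phenotype", "demarcation"], observed=True)["density"]
        .mean()
        .reset_index()
    )
    return DensityMatrix(per_core=per_core, per_sample=per_sample)


def compute_ratios(dm: DensityMatrix, specs: Sequence[RatioSpec]) -> pd.DataFrame:
    """Samples x ratio_name table; zero denominators become missing (NaN)."""
    known = set(dm.per_sample["phenotype"].unique())
    out: dict[str, pd.Series] = {}
    for spec in specs:
        for pheno, dem in (spec.numerator, spec.denominator):
            if pheno not in known:
                raise SchemaError(f"ratio {spec.name!r}: unknown phenotype {pheno!r}")
            if dem not in set(dm.per_sample["demarcation"].unique()):
                raise SchemaError(f"ratio {spec.name!r}: demarcation {dem!r} not computed")
        num = dm.get(*spec.numerator)
        den = dm.get(*spec.denominator)
        out[spec.name] = num / den.replace(0.0, np.nan)
    table = pd.DataFrame(out)
    table.index.name = "sample_id"
    return table
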