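"""Domain types and delimited-text I/O for cohort bundles.

A cohort is carried as three flat tables:

* **cells** — one row per segmented cell with identifiers, position,
  base-compartment label and one ``<MARKER>_int`` column per marker;
* **areas** — one row per (sample, core, demarcation) with the area in mm2;
* **clinical** — one row per sample with growth-pattern class, overall
  survival in months and the event flag.

All downstream modules consume :class:`CohortBundle`.  Compartments are
stored at the three base labels only; the wider demarcations are derived
views computed on demand (see :data:`DERIVED_DEMARCATIONS`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import LinkageError, SchemaError

#: Compartment labels a cell row may carry.
BASE_COMPARTMENTS: tuple[str, ...] = ("tumor_nest", "stroma", "liver")

#: All demarcations densities can be reported over.
DEMARCATIONS: tuple[str, ...] = (
    "total_tissue",
    "total_excluding_liver",
    "tumor_area",
    "tumor_nest",
    "stroma",
    "liver",
)

#: Derived demarcation -> base compartments whose counts/areas are pooled.
DERIVED_DEMARCATIONS: dict[str, tuple[str, ...]] = {
    "total_tissue": ("tumor_nest", "stroma", "liver"),
    "total_excluding_liver": ("tumor_nest", "stroma"),
    "tumor_area": ("tumor_nest", "stroma"),
}

MARKER_SUFFIX = "_int"

CELL_ID_COLUMNS = ["sample_id", "core_id", "cell_id"]
CELL_BASE_COLUMNS = CELL_ID_COLUMNS + ["x_um", "y_um", "compartment"]
AREA_COLUMNS = ["sample_id", "core_id", "demarcation", "area_mm2"]
CLINICAL_COLUMNS = ["sample_id", "hgp", "os_months", "event"]

HGP_LABELS = ("dHGP", "non_dHGP")

#: Relative tolerance for area-additivity checks.
AREA_RTOL = 1e-6


# ---------------------------------------------------------------------------
# record-level types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CellRecord:
    """A single segmented cell (row-level view onto the cells table)."""

    sample_id: str
    core_id: str
    cell_id: str
    x_um: float
    y_um: float
    compartment: str
    intensities: Mapping[str, float]


@dataclass(frozen=True)
class GeneSet:
    """A named list of unique gene symbols (GMT record)."""

    name: str
    genes: tuple[str, ...]
    description: str = ""

    def __post_init__(self) -> None:
        if not self.genes:
            raise SchemaError(f"gene set {self.name!r} is empty")
        if len(set(self.genes)) != len(self.genes):
            raise SchemaError(f"gene set {self.name!r} has duplicate symbols")


@dataclass
class CohortBundle:
    """Validated container for the three cohort tables plus provenance."""

    cells: pd.DataFrame
    areas: pd.DataFrame
    clinical: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    @property
    def markers(self) -> list[str]:
        return marker_names(self.cells)

    @property
    def sample_ids(self) -> list[str]:
        return sorted(self.clinical["sample_id"].astype(str).unique())

    def iter_cells(self) -> Iterator[CellRecord]:
        cols = self.markers
        for row in self.cells.itertuples(index=False):
            d = row._asdict()
            yield CellRecord(
                sample_id=d["sample_id"],
                core_id=d["core_id"],
                cell_id=d["cell_id"],
                x_um=d["x_um"],
                y_um=d["y_um"],
                compartment=d["compartment"],
                intensities={m: d[m + MARKER_SUFFIX] for m in cols},
            )


@dataclass(frozen=True)
class Finding:
    kind: str
    message: str


@dataclass
class ValidationReport:
    findings: list[Finding] = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return not self.findings

    def add(self, kind: str, message: str) -> None:
        self.findings.append(Finding(kind, message))

    def summary(self) -> str:
        if self.passed:
            return "OK: no violations"
        return "\n".join(f"[{f.kind}] {f.message}" for f in self.findings)


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def marker_columns(cells: pd.DataFrame) -> list[str]:
    """Columns of *cells* holding marker intensities (``_int`` suffix)."""
    return [c for c in cells.columns if c.endswith(MARKER_SUFFIX)]


def marker_names(cells: pd.DataFrame) -> list[str]:
    return [c[: -len(MARKER_SUFFIX)] for c in marker_columns(cells)]


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def _read_table(path: str | Path, required: Sequence[str], table: str) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=_sep_for(path), float_precision="round_trip")
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"{table} table {path} is missing required column {col!r}")
    return df


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_cohort(
    cell_path: str | Path,
    area_path: str | Path,
    clinical_path: str | Path,
) -> CohortBundle:
    """Read and cross-validate the three cohort tables.

    Marker columns are auto-detected by the ``_int`` suffix.  Hard schema or
    value problems raise immediately; soft invariants are the business of
    :func:`validate_bundle`.
    """
    cells = _read_table(cell_path, CELL_BASE_COLUMNS, "cell")
    areas = _read_table(area_path, AREA_COLUMNS, "area")
    clinical = _read_table(clinical_path, CLINICAL_COLUMNS, "clinical")

    for key in CELL_ID_COLUMNS:
        cells[key] = cells[key].astype(str)
    areas["sample_id"] = areas["sample_id"].astype(str)
    areas["core_id"] = areas["core_id"].astype(str)
    clinical["sample_id"] = clinical["sample_id"].astype(str)

    mcols = marker_columns(cells)
    if not mcols:
        raise SchemaError(f"cell table {cell_path} has no '*{MARKER_SUFFIX}' marker column")

    bad_comp = ~cells["compartment"].isin(BASE_COMPARTMENTS)
    if bad_comp.any():
        labels = sorted(cells.loc[bad_comp, "compartment"].unique())
        raise SchemaError(f"unknown compartment labels {labels}; expected {list(BASE_COMPARTMENTS)}")

    for col in mcols:
        vals = pd.to_numeric(cells[col], errors="coerce")
        neg = vals < 0
        if neg.any():
            idx = int(np.flatnonzero(neg.to_numpy())[0])
            raise ValueError(f"negative intensity in column {col!r} at row {idx}")
        cells[col] = vals

    neg_area = pd.to_numeric(areas["area_mm2"], errors="coerce") < 0
    if neg_area.any():
        idx = int(np.flatnonzero(neg_area.to_numpy())[0])
        raise ValueError(f"negative area_mm2 at row {idx}")

    bad_dem = ~areas["demarcation"].isin(DEMARCATIONS)
    if bad_dem.any():
        labels = sorted(areas.loc[bad_dem, "demarcation"].unique())
        raise SchemaError(f"unknown demarcation labels {labels}")

    clinical_samples = set(clinical["sample_id"])
    area_samples = set(areas["sample_id"])
    for sid in pd.unique(cells["sample_id"]):
        if sid not in clinical_samples:
            raise LinkageError(f"sample {sid!r} present in cells but absent from clinical")
        if sid not in area_samples:
            raise LinkageError(f"sample {sid!r} present in cells but absent from areas")

    return CohortBundle(cells=cells, areas=areas, clinical=clinical,
                        provenance={"source": {"cells": str(cell_path),
                                               "areas": str(area_path),
                                               "clinical": str(clinical_path)}})


def write_cohort(bundle: CohortBundle, outdir: str | Path, prefix: str = "cohort") -> dict[str, Path]:
    """Write the three tables as TSV; returns the written paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "cells": outdir / f"{prefix}_cells.tsv",
        "areas": outdir / f"{prefix}_areas.tsv",
        "clinical": outdir / f"{prefix}_clinical.tsv",
    }
    # %.17g guarantees binary64 round-trip through text
    bundle.cells.to_csv(paths["cells"], sep="\t", index=False, float_format="%.17g")
    bundle.areas.to_csv(paths["areas"], sep="\t", index=False, float_format="%.17g")
    bundle.clinical.to_csv(paths["clinical"], sep="\t", index=False, float_format="%.17g")
    return paths


def read_gmt(path: str | Path) -> list[GeneSet]:
    """Parse a GMT file: ``name<TAB>description<TAB>gene1<TAB>gene2...``."""
    sets: list[GeneSet] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line:
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise SchemaError(f"GMT line {lineno}: expected name, description and >=1 gene")
        genes = tuple(g for g in parts[2:] if g)
        sets.append(GeneSet(name=parts[0], description=parts[1], genes=genes))
    if not sets:
        raise SchemaError(f"GMT file {path} contains no gene sets")
    return sets


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

def validate_bundle(bundle: CohortBundle) -> ValidationReport:
    """Report every invariant violation; never raises.

    An empty report is equivalent to the bundle passing all invariants:
    finite non-negative intensities, valid compartments, unique cell keys,
    sample linkage, clinical value ranges, positive areas where cells exist
    and area additivity to relative tolerance ``AREA_RTOL``.
    """
    rep = ValidationReport()
    cells, areas, clinical = bundle.cells, bundle.areas, bundle.clinical

    # --- cells
    bad_comp = ~cells["compartment"].isin(BASE_COMPARTMENTS)
    for idx in np.flatnonzero(bad_comp.to_numpy()):
        rep.add("compartment", f"cells row {idx}: unknown compartment "
                               f"{cells['compartment'].iloc[idx]!r}")

    for col in marker_columns(cells):
        vals = cells[col].to_numpy(dtype=float)
        for idx in np.flatnonzero(~np.isfinite(vals)):
            rep.add("intensity", f"cells row {idx}: non-finite intensity in {col}")
        for idx in np.flatnonzero(vals < 0):
            rep.add("intensity", f"cells row {idx}: negative intensity in {col}")

    dup = cells.duplicated(subset=CELL_ID_COLUMNS, keep="first")
    for idx in np.flatnonzero(dup.to_numpy()):
        key = tuple(cells.loc[cells.index[idx], CELL_ID_COLUMNS])
        rep.add("duplicate", f"cells row {idx}: duplicate cell key {key}")

    # --- linkage
    clinical_samples = set(clinical["sample_id"].astype(str))
    area_samples = set(areas["sample_id"].astype(str))
    for sid in pd.unique(cells["sample_id"].astype(str)):
        if sid not in clinical_samples:
            rep.add("linkage", f"sample {sid!r} in cells but not in clinical")
        if sid not in area_samples:
            rep.add("linkage", f"sample {sid!r} in cells but not in areas")

    # --- clinical
    for idx, row in clinical.iterrows():
        if pd.isna(row["hgp"]) or str(row["hgp"]) == "":
            rep.add("clinical", f"clinical row {idx}: missing hgp")
        os_m = row["os_months"]
        if not (isinstance(os_m, (int, float, np.integer, np.floating))
                and math.isfinite(float(os_m)) and float(os_m) >= 0):
            rep.add("clinical", f"clinical row {idx}: os_months must be finite and >= 0")
        if row["event"] not in (0, 1, 0.0, 1.0):
            rep.add("clinical", f"clinical row {idx}: event must be 0 or 1")

    # --- areas: positivity where cells exist
    area_map: dict[tuple[str, str, str], float] = {}
    dup_area = areas.duplicated(subset=["sample_id", "core_id", "demarcation"], keep="first")
    for idx in np.flatnonzero(dup_area.to_numpy()):
        row = areas.iloc[idx]
        rep.add("duplicate", f"areas row {idx}: duplicate key "
                             f"({row['sample_id']}, {row['core_id']}, {row['demarcation']})")
    for row in areas.itertuples(index=False):
        area_map.setdefault((str(row.sample_id), str(row.core_id), row.demarcation),
                            float(row.area_mm2))

    counts = cells.groupby(["sample_id", "core_id", "compartment"], observed=True).size()
    for (sid, cid, comp), n in counts.items():
        if n == 0:
            continue
        area = area_map.get((str(sid), str(cid), comp))
        if area is None:
            rep.add("area", f"{n} cells in ({sid}, {cid}, {comp}) but no area row")
        elif not (area > 0):
            rep.add("area", f"{n} cells in ({sid}, {cid}, {comp}) but area_mm2 = {area}")

    # --- area additivity
    relations = [
        ("tumor_nest + stroma = tumor_area", ("tumor_nest", "stroma"), "tumor_area"),
        ("tumor_area + liver = total_tissue", ("tumor_area", "liver"), "total_tissue"),
        ("total_excluding_liver = tumor_area", ("total_excluding_liver",), "tumor_area"),
    ]
    cores = {(str(r.sample_id), str(r.core_id)) for r in areas.itertuples(index=False)}
    for sid, cid in sorted(cores):
        for label, lhs_terms, rhs_term in relations:
            lhs_vals = [area_map.get((sid, cid, t)) for t in lhs_terms]
            rhs = area_map.get((sid, cid, rhs_term))
            if any(v is None for v in lhs_vals) or rhs is None:
                continue  # relation only checked when all terms are stored
            lhs = sum(lhs_vals)
            if abs(lhs - rhs) > AREA_RTOL * max(1.0, abs(rhs)):
                rep.add("additivity",
                        f"({sid}, {cid}): {label} violated ({lhs:.9g} vs {rhs:.9g})")
    return rep
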