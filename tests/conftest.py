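import numpy as np
import pandas as pd
import pytest

from tmeprofiler import (
    CohortBundle,
    MarkerModel,
    SimConfig,
    SurvivalConfig,
    generate_cohort,
)


def make_cells(rows):
    """Build a cells frame from (sample, core, cell, compartment, {marker: v})."""
    records = []
    markers = sorted({m for *_ignored, intens in rows for m in intens})
    for sample, core, cell, comp, intens in rows:
        rec = {"sample_id": sample, "core_id": core, "cell_id": cell,
               "x_um": 0.0, "y_um": 0.0, "compartment": comp}
        for m in markers:
            rec[f"{m}_int"] = float(intens.get(m, 0.0))
        records.append(rec)
    return pd.DataFrame(records)


def make_areas(entries):
    """entries: (sample, core, demarcation, area)."""
    return pd.DataFrame(
        [{"sample_id": s, "core_id": c, "demarcation": d, "area_mm2": a}
         for s, c, d, a in entries])


def make_clinical(entries):
    """entries: (sample, hgp, os_months, event)."""
    return pd.DataFrame(
        [{"sample_id": s, "hgp": h, "os_months": t, "event": e}
         for s, h, t, e in entries])


def full_areas(sample, core, nest, stroma, liver):
    tumor = nest + stroma
    return [
        (sample, core, "tumor_nest", nest),
        (sample, core, "stroma", stroma),
        (sample, core, "liver", liver),
        (sample, core, "tumor_area", tumor),
        (sample, core, "total_excluding_liver", tumor),
        (sample, core, "total_tissue", tumor + liver),
    ]


@pytest.fixture
def toy_bundle():
    """Three cells, one sample, consistent areas and clinical."""
    cells = make_cells([
        ("S1", "C1", "1", "tumor_nest", {"CD8": 10.0, "CD4": 0.5}),
        ("S1", "C1", "2", "stroma", {"CD8": 0.2, "CD4": 8.0}),
        ("S1", "C1", "3", "liver", {"CD8": 0.1, "CD4": 0.1}),
    ])
    areas = make_areas(full_areas("S1", "C1", 0.5, 0.3, 0.2))
    clinical = make_clinical([("S1", "dHGP", 24.0, 1)])
    return CohortBundle(cells=cells, areas=areas, clinical=clinical)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def small_sim_config(seed=0, **overrides):
    """A light cohort: 3 markers, small cores — fast enough for loops."""
    defaults = dict(
        n_per_group=10,
        cores_per_sample=2,
        cells_per_core=120.0,
        marker_models={m: MarkerModel() for m in ("CD8", "CD68", "Calprotectin")},
        effect_table={},
        survival=SurvivalConfig(hgp_hazard_ratio=1.0, censor_fraction=0.2),
        seed=seed,
    )
    defaults.update(overrides)
    return SimConfig(**defaults)


@pytest.fixture
def small_bundle():
    return generate_cohort(small_sim_config(seed=42))
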