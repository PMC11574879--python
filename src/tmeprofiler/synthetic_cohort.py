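"""Synthetic cohort and expression-matrix generators.

The generator emulates the data structure the analysis assumes: two
growth-pattern groups, cores with compartment areas, per-cell marker
intensities drawn from two-component log-normal mixtures (the mixture
weight — not the mode location — carries the group effect), exponential
survival with a configurable group hazard ratio and uniform administrative
censoring, and an optional protective marker effect confined to the
macrophage-high stratum.

Everything is deterministic given the seed; generated bundles pass
:func:`tmeprofiler.datamodel_io.validate_bundle` with zero findings.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .datamodel_io import (
    BASE_COMPARTMENTS,
    CohortBundle,
    GeneSet,
    MARKER_SUFFIX,
)
from .errors import ConfigError

DEFAULT_MARKERS = (
    "CD8", "CD4", "CD45R0", "CD20", "FoxP3",
    "CD68", "CD163", "Calprotectin", "MARCO",
    "aSMA", "FAP", "CD90", "NGFR", "COL1A1",
)


@dataclass(frozen=True)
class MarkerModel:
    """Two-component log-normal intensity mixture for one marker."""

    neg_mean: float = 1.0
    pos_mean: float = 30.0
    log_sd: float = 0.4
    baseline_pos_fraction: float = 0.15

    def validate(self, marker: str) -> None:
        if self.pos_mean <= self.neg_mean:
            raise ConfigError(
                f"marker {marker!r}: pos_mean ({self.pos_mean}) must exceed "
                f"neg_mean ({self.neg_mean})")
        if self.neg_mean <= 0 or self.log_sd <= 0:
            raise ConfigError(f"marker {marker!r}: means and sd must be positive")
        if not 0.0 < self.baseline_pos_fraction < 1.0:
            raise ConfigError(f"marker {marker!r}: baseline_pos_fraction in (0,1)")


@dataclass(frozen=True)
class SurvivalConfig:
    baseline_median_months: float = 40.0
    hgp_hazard_ratio: float = 2.83  # non-desmoplastic vs desmoplastic
    censor_fraction: float = 0.3

    def validate(self) -> None:
        if self.baseline_median_months <= 0 or self.hgp_hazard_ratio <= 0:
            raise ConfigError("median survival and hazard ratio must be positive")
        if not 0.0 <= self.censor_fraction < 1.0:
            raise ConfigError("censor_fraction must lie in [0, 1)")


@dataclass(frozen=True)
class InteractionConfig:
    """Protective marker hazard confined to the stratifier-high stratum."""

    calprotectin_protective_hr: float = 1.0  # 1.0 disables the interaction
    marker: str = "Calprotectin"
    stratifier: str = "CD68"
    compartment: str = "stroma"

    def validate(self) -> None:
        if self.calprotectin_protective_hr <= 0:
            raise ConfigError("protective hazard ratio must be positive")


def default_marker_models() -> dict[str, MarkerModel]:
    return {m: MarkerModel() for m in DEFAULT_MARKERS}


def default_effect_table() -> dict[tuple[str, str], float]:
    """Multiplicative positive-fraction effects of the desmoplastic group.

    Values > 1 raise the desmoplastic positive fraction in that compartment;
    values < 1 lower it (i.e. the non-desmoplastic group is higher).
    """
    return {
        ("CD8", "tumor_nest"): 2.5,
        ("CD8", "liver"): 0.4,
        ("CD45R0", "liver"): 0.5,
        ("CD20", "liver"): 0.5,
        ("CD68", "stroma"): 0.4,
        ("CD163", "stroma"): 0.4,
        ("Calprotectin", "stroma"): 0.4,
        ("Calprotectin", "tumor_nest"): 0.4,
        ("COL1A1", "stroma"): 2.0,
        ("aSMA", "stroma"): 0.7,
    }


@dataclass
class SimConfig:
    n_per_group: int = 30
    cores_per_sample: int = 2
    cells_per_core: float = 400.0
    compartment_area_means: dict[str, float] = field(
        default_factory=lambda: {"tumor_nest": 0.30, "stroma": 0.25, "liver": 0.20})
    area_cv: float = 0.10
    marker_models: dict[str, MarkerModel] = field(default_factory=default_marker_models)
    effect_table: dict[tuple[str, str], float] = field(default_factory=default_effect_table)
    survival: SurvivalConfig = field(default_factory=SurvivalConfig)
    interaction: InteractionConfig = field(default_factory=InteractionConfig)
    seed: int = 0

    def validate(self) -> None:
        if self.n_per_group < 1 or self.cores_per_sample < 1:
            raise ConfigError("n_per_group and cores_per_sample must be >= 1")
        if self.cells_per_core <= 0:
            raise ConfigError("cells_per_core must be positive")
        for comp in BASE_COMPARTMENTS:
            if self.compartment_area_means.get(comp, 0) <= 0:
                raise ConfigError(f"compartment_area_means[{comp!r}] must be positive")
        for m, model in self.marker_models.items():
            model.validate(m)
        for (m, comp), eff in self.effect_table.items():
            if eff <= 0:
                raise ConfigError(f"effect for ({m}, {comp}) must be positive")
            if comp not in BASE_COMPARTMENTS:
                raise ConfigError(f"effect table compartment {comp!r} unknown")
        self.survival.validate()
        self.interaction.validate()

    def describe(self) -> dict:
        d = asdict(self)
        d["effect_table"] = {f"{m}:{c}": v for (m, c), v in self.effect_table.items()}
        return d


def sim_config_from_dict(raw: Mapping) -> SimConfig:
    """Build a :class:`SimConfig` from a plain (YAML/JSON) mapping.

    Marker models are nested mappings keyed by marker; effect-table keys use
    the ``"marker:compartment"`` convention.
    """
    kwargs: dict = {}
    simple = ("n_per_group", "cores_per_sample", "cells_per_core",
              "compartment_area_means", "area_cv", "seed")
    for key in simple:
        if key in raw:
            kwargs[key] = raw[key]
    if "marker_models" in raw:
        kwargs["marker_models"] = {
            m: MarkerModel(**mm) for m, mm in raw["marker_models"].items()}
    if "effect_table" in raw:
        table = {}
        for key, val in raw["effect_table"].items():
            try:
                marker, comp = key.split(":")
            except ValueError as exc:
                raise ConfigError(
                    f"effect_table key {key!r} must be 'marker:compartment'") from exc
            table[(marker, comp)] = float(val)
        kwargs["effect_table"] = table
    if "survival" in raw:
        kwargs["survival"] = SurvivalConfig(**raw["survival"])
    if "interaction" in raw:
        kwargs["interaction"] = InteractionConfig(**raw["interaction"])
    unknown = set(raw) - set(simple) - {"marker_models", "effect_table",
                                        "survival", "interaction"}
    if unknown:
        raise ConfigError(f"unknown simulate keys: {sorted(unknown)}")
    return SimConfig(**kwargs)


# ---------------------------------------------------------------------------
# survival primitives
# ---------------------------------------------------------------------------

def censoring_horizon(hazards: np.ndarray, censor_fraction: float) -> float:
    """Administrative horizon b so E[fraction censored] matches the target.

    Censoring times are Uniform(0, b); for an exponential subject with
    hazard h, P(censored) = (1 - exp(-h b)) / (h b).
    """
    if not 0.0 < censor_fraction < 1.0:
        raise ConfigError("censor_fraction must lie in (0, 1) to solve a horizon")

    def expected(b: float) -> float:
        hb = hazards * b
        return float(np.mean((1.0 - np.exp(-hb)) / hb))

    return brentq(lambda b: expected(b) - censor_fraction, 1e-9, 1e9, xtol=1e-10)


def simulate_survival(
    hazards: Sequence[float],
    censor_fraction: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Exponential event times with independent uniform censoring.

    Returns (observed time, event flag).
    """
    h = np.asarray(hazards, dtype=float)
    if (h <= 0).any():
        raise ConfigError("hazards must be positive")
    t = rng.exponential(1.0 / h)
    if censor_fraction <= 0:
        return t, np.ones(h.size, dtype=int)
    b = censoring_horizon(h, censor_fraction)
    c = rng.uniform(0.0, b, size=h.size)
    event = (t <= c).astype(int)
    return np.minimum(t, c), event


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

def generate_cohort(config: SimConfig) -> CohortBundle:
    """Generate a full cohort bundle with the configured group structure."""
    config.validate()
    rng = np.random.default_rng(config.seed)

    n_samples = 2 * config.n_per_group
    sample_ids = [f"S{i + 1:03d}" for i in range(n_samples)]
    groups = np.array(["dHGP"] * config.n_per_group + ["non_dHGP"] * config.n_per_group)
    core_ids = [f"C{j + 1}" for j in range(config.cores_per_sample)]

    comp_means = np.array([config.compartment_area_means[c] for c in BASE_COMPARTMENTS])
    total_mean_area = float(comp_means.sum())
    base_density = config.cells_per_core / total_mean_area

    n_cores = n_samples * config.cores_per_sample
    # areas: log-normal around the compartment means, mild between-core noise
    area_noise = rng.normal(0.0, config.area_cv, size=(n_cores, len(BASE_COMPARTMENTS)))
    areas_mat = comp_means[None, :] * np.exp(area_noise)

    counts = rng.poisson(base_density * areas_mat)  # cells per (core, compartment)

    # flat per-cell frame skeleton
    core_sample = np.repeat(np.arange(n_samples), config.cores_per_sample)
    cell_sample_idx = []
    cell_core_idx = []
    cell_comp_idx = []
    for core in range(n_cores):
        for ci, _comp in enumerate(BASE_COMPARTMENTS):
            k = counts[core, ci]
            cell_sample_idx.append(np.full(k, core_sample[core]))
            cell_core_idx.append(np.full(k, core))
            cell_comp_idx.append(np.full(k, ci))
    cell_sample_idx = np.concatenate(cell_sample_idx) if cell_sample_idx else np.empty(0, int)
    cell_core_idx = np.concatenate(cell_core_idx)
    cell_comp_idx = np.concatenate(cell_comp_idx)
    n_cells = cell_sample_idx.size

    comp_labels = np.array(BASE_COMPARTMENTS)[cell_comp_idx]
    is_dhgp_cell = groups[cell_sample_idx] == "dHGP"

    # positions: uniform inside a square of the compartment's area (plumbing)
    side_um = np.sqrt(areas_mat[cell_core_idx, cell_comp_idx]) * 1000.0
    x_um = rng.uniform(0.0, 1.0, n_cells) * side_um
    y_um = rng.uniform(0.0, 1.0, n_cells) * side_um

    cells = pd.DataFrame({
        "sample_id": np.array(sample_ids)[cell_sample_idx],
        "core_id": np.array(core_ids)[cell_core_idx % config.cores_per_sample],
        "cell_id": "",
        "x_um": x_um,
        "y_um": y_um,
        "compartment": comp_labels,
    })
    # cell ids unique within core
    cells["cell_id"] = cells.groupby(["sample_id", "core_id"]).cumcount().add(1).astype(str)

    truth: dict[str, np.ndarray] = {}
    for marker in config.marker_models:
        model = config.marker_models[marker]
        p = np.full(n_cells, model.baseline_pos_fraction)
        for ci, comp in enumerate(BASE_COMPARTMENTS):
            eff = config.effect_table.get((marker, comp))
            if eff is not None:
                mask = is_dhgp_cell & (cell_comp_idx == ci)
                p[mask] *= eff
        p = np.clip(p, 1e-6, 0.995)
        pos = rng.random(n_cells) < p
        mode = np.where(pos, model.pos_mean, model.neg_mean)
        cells[marker + MARKER_SUFFIX] = mode * np.exp(
            model.log_sd * rng.standard_normal(n_cells))
        truth[marker] = pos

    # area table with all derived demarcations (exactly additive)
    area_rows = []
    for core in range(n_cores):
        sid = sample_ids[core_sample[core]]
        cid = core_ids[core % config.cores_per_sample]
        a = dict(zip(BASE_COMPARTMENTS, areas_mat[core]))
        a["tumor_area"] = a["tumor_nest"] + a["stroma"]
        a["total_excluding_liver"] = a["tumor_area"]
        a["total_tissue"] = a["tumor_area"] + a["liver"]
        for dem, val in a.items():
            area_rows.append({"sample_id": sid, "core_id": cid,
                              "demarcation": dem, "area_mm2": val})
    areas = pd.DataFrame(area_rows)

    hazards = _sample_hazards(config, cells, truth, sample_ids, groups,
                              areas_mat, cell_sample_idx, cell_comp_idx)
    os_months, event = simulate_survival(hazards, config.survival.censor_fraction, rng)

    clinical = pd.DataFrame({
        "sample_id": sample_ids,
        "hgp": groups,
        "os_months": os_months,
        "event": event,
    })

    return CohortBundle(
        cells=cells, areas=areas, clinical=clinical,
        provenance={"synthetic": True, "seed": config.seed,
                    "config": config.describe()},
    )


def _sample_hazards(
    config: SimConfig,
    cells: pd.DataFrame,
    truth: Mapping[str, np.ndarray],
    sample_ids: Sequence[str],
    groups: np.ndarray,
    areas_mat: np.ndarray,
    cell_sample_idx: np.ndarray,
    cell_comp_idx: np.ndarray,
) -> np.ndarray:
    lam0 = math.log(2.0) / config.survival.baseline_median_months
    hazards = np.where(groups == "non_dHGP",
                       lam0 * config.survival.hgp_hazard_ratio, lam0)

    inter = config.interaction
    if inter.calprotectin_protective_hr != 1.0:
        if inter.marker not in truth or inter.stratifier not in truth:
            raise ConfigError(
                "interaction requires both its marker and stratifier in marker_models")
        comp_idx = list(BASE_COMPARTMENTS).index(inter.compartment)
        n_samples = len(sample_ids)

        def sample_density(marker: str) -> np.ndarray:
            in_comp = cell_comp_idx == comp_idx
            pos = truth[marker] & in_comp
            dens = np.zeros(n_samples)
            cores_per = areas_mat.shape[0] // n_samples
            pos_sample = np.bincount(cell_sample_idx[pos], minlength=n_samples)
            # pooled-core density per sample (counts over summed area)
            area_per_sample = areas_mat[:, comp_idx].reshape(n_samples, cores_per).sum(axis=1)
            dens = pos_sample / area_per_sample
            return dens

        strat = sample_density(inter.stratifier)
        mark = sample_density(inter.marker)
        protected = (strat > strat.mean()) & (mark > mark.mean())
        hazards = np.where(protected,
                           hazards * inter.calprotectin_protective_hr, hazards)
    return hazards


# ---------------------------------------------------------------------------
# expression generation
# ---------------------------------------------------------------------------

@dataclass
class ExprConfig:
    n_cells: int = 2000
    n_genes: int = 200
    signature_genes: GeneSet | None = None
    anchor_gene: str = "ACTA2"
    anti_correlation_strength: float = 0.8
    noise_sd: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        if self.signature_genes is None:
            raise ConfigError("signature_genes is required")
        if self.anchor_gene in self.signature_genes.genes:
            raise ConfigError(
                f"anchor gene {self.anchor_gene!r} must not be inside the signature "
                "(would confound the anti-correlation)")
        if not 0.0 <= self.anti_correlation_strength <= 1.0:
            raise ConfigError("anti_correlation_strength must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")
        if self.n_genes < len(self.signature_genes.genes) + 2:
            raise ConfigError("n_genes too small to host signature + anchor + background")


def generate_expression(config: ExprConfig) -> tuple[pd.DataFrame, pd.Series]:
    """Cells x genes non-negative matrix plus the per-cell anchor values.

    A latent per-cell factor loads positively on the anchor gene and
    negatively on every signature gene with the configured strength, so the
    anchor is anti-correlated with the signature's single-sample score.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    sig = list(config.signature_genes.genes)
    n_bg = config.n_genes - len(sig) - 1
    genes = sig + [config.anchor_gene] + [f"BG{i + 1:04d}" for i in range(n_bg)]

    z = rng.standard_normal(config.n_cells)
    base = rng.normal(0.0, 0.3, size=config.n_genes)
    loadings = np.zeros(config.n_genes)
    loadings[: len(sig)] = -config.anti_correlation_strength
    loadings[len(sig)] = config.anti_correlation_strength

    log_expr = (base[None, :]
                + z[:, None] * loadings[None, :]
                + config.noise_sd * rng.standard_normal((config.n_cells, config.n_genes)))
    expr = pd.DataFrame(np.exp(log_expr),
                        index=[f"cell{i + 1:05d}" for i in range(config.n_cells)],
                        columns=genes)
    return expr, expr[config.anchor_gene].copy()
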