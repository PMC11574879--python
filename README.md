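# tmeprofiler

Quantitative tumor-microenvironment profiling from segmented multiplex-IHC
cell tables: per-cell marker gating, combinatorial phenotyping,
compartment-stratified density and ratio metrics, two-group comparison with
zero/tie-corrected rank tests and multiplicity control, survival
stratification (including an interaction subgroup workflow), and
single-sample gene-set scoring — all exercised against a built-in synthetic
cohort generator, so nothing requires external data.

## Inputs

Three delimited text tables (TSV, or CSV by extension):

| table    | columns |
|----------|---------|
| cells    | `sample_id, core_id, cell_id, x_um, y_um, compartment, <MARKER>_int ...` |
| areas    | `sample_id, core_id, demarcation, area_mm2` |
| clinical | `sample_id, hgp, os_months, event` |

Compartments are stored at three base labels (`tumor_nest`, `stroma`,
`liver`); the wider demarcations (`tumor_area`, `total_excluding_liver`,
`total_tissue`) are derived views that pool counts and areas before
dividing. Marker columns are auto-detected via the `_int` suffix. Gene sets
use GMT; expression matrices are dense TSV (cells x genes).

## CLI

Every stage runs standalone on intermediate TSVs:

```bash
tmeprofiler simulate --outdir sim/ --seed 1
tmeprofiler gate     --cells sim/simulated_cells.tsv --areas sim/simulated_areas.tsv \
                     --clinical sim/simulated_clinical.tsv --out thresholds.tsv
tmeprofiler density  --cells ... --thresholds thresholds.tsv --panel myeloid --out density.tsv
tmeprofiler compare  --density density.tsv --clinical sim/simulated_clinical.tsv --out report.tsv
tmeprofiler survive  --density density.tsv --clinical ... \
                     --marker Calprotectin_total --stratifier CD68_total --out surv.json
tmeprofiler ssgsea   --expr expr.tsv --set iCAF --anchor ACTA2 --out scores.tsv
```

or drive everything from one YAML config:

```yaml
seed: 1
simulate: {n_per_group: 20, cells_per_core: 200}   # or inputs: {cells:..., areas:..., clinical:...}
panels: [lymphoid, myeloid, caf]
demarcations: [tumor_nest, stroma, total_excluding_liver]
ratios: default
spearman: {groups: [dHGP, non_dHGP], scopes: [total_excluding_liver, stroma]}
survival_analyses:
  - {marker: Calprotectin_total, stratifier: CD68_total, demarcation: stroma}
```

```bash
tmeprofiler run-all --config config.yaml --outdir out/
```

Exit codes: 0 ok, 1 data error, 2 config error. The manifest written to the
output directory records the config hash and seed; deterministic stages
reproduce byte-for-byte.

## Panels and conventions

Phenotype panels are YAML data (`src/tmeprofiler/panels/`): each phenotype
lists required-positive markers, required-negative markers, optional tier
constraints, and an `exclusive_single` flag ("negative for every other
panel marker"). Frozen boundary conventions: positivity is
`intensity >= threshold`; the high tier is strictly above the mean
intensity of positive cells; subjects exactly at a mean survival cutoff go
to "low".

The shipped iCAF/myCAF gene lists
(`src/tmeprofiler/genesets/caf_signatures.gmt`) are literature-derived
placeholders — swap in study-specific GMT files via `--gmt`.

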