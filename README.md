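# ssgblup

Single-step GBLUP with weighted SNP-window association scans, for pedigreed
populations with partially genotyped animals.

The package implements the full analysis chain used in weighted single-step
genomic association studies of ordinal conformation/defect scores:

* **pedigree** — pedigree reading/validation, inbreeding coefficients, the
  numerator relationship matrix `A`, its sparse inverse (Henderson rules with
  inbreeding), and the genotyped block `A22`.
* **genotypes** — PLINK text and binary readers/writers, merging of two
  genotyping panels on common markers, call-rate QC (SNPs below 95% call rate
  discarded), centred gene content, and the (weighted) genomic relationship
  matrix `G = Z D Z' / Σ 2p(1−p)` with blending/tuning against `A22`.
* **hmatrix** — the single-step inverse `H⁻¹ = A⁻¹ + [0 0; 0 G*⁻¹ − A22⁻¹]`.
* **mixed_model** — design matrices for a multi-trait animal model with fixed
  factors (sex, age class, coat, area), an inbreeding covariate and optional
  permanent environment; Henderson's mixed-model equations; EM-REML (monotone)
  with an average-information accelerator; heritability and genetic
  correlations.
* **wssgwas** — back-solving GEBVs into SNP effects (`ĝ = D Z' G⁻¹ û / k`),
  quadratic SNP re-weighting (`w = ĝ² 2p(1−p)`, mean-normalised), iterative
  weighting rounds, 1-Mb overlapping window variance scans, >1% region
  selection, and Manhattan-plot export.
* **simulate** — synthetic pedigree / gene-dropped genotype / correlated
  zero-inflated ordinal phenotype generator so the whole pipeline is testable
  offline.
* **pipeline / cli** — YAML-configured end-to-end orchestration.

## Command line

```bash
# generate a synthetic dataset (pedigree CSV, PLINK ped/map, phenotype TSV)
ssgblup simulate --config sim.yaml --outdir data/

# full analysis: QC -> A/G/H matrices -> REML -> weighting rounds -> windows
ssgblup run --pedigree data/pedigree.csv --genotypes data/genotypes \
            --phenotypes data/phenotypes.tsv --outdir out/

# human-readable summary (heritabilities, genetic correlations, regions)
ssgblup report out/
```

`ssgblup run` writes `regions.tsv` (significant merged regions),
`windows_<trait>.tsv`, `snp_effects_<trait>.tsv`, `gebv.tsv`,
`fit_report.json`, a Manhattan figure per trait, and the resolved
`run_config.yaml`. Defaults follow the method's stated constants: call-rate
threshold 0.95, 1 Mb windows, 1% significance, two weighting rounds.

A minimal `sim.yaml`:

```yaml
n_founders: 120
n_generations: 3
n_snps: 1000
traits: [VE, VM, VN]
h2_targets: [0.17, 0.13, 0.28]
pe_variance: [0.0, 0.0, 0.0]
seed: 1
```

## Python API

```python
from ssgblup import (SimConfig, simulate_dataset, a_inverse, a22,
                     blend_tune, g_matrix, h_inverse, ModelSpec, reml)

ds = simulate_dataset(SimConfig(seed=1))
# ... see tests/ for complete worked examples of every stage
```

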