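# twinwell

Biometric and co-twin control analyses of social factors and wellbeing in
adult twin cohorts, exercised end-to-end on synthetic data with known
generating truth.

The package implements a two-fold analysis strategy:

1. **Biometric (Cholesky) twin models** — multivariate decomposition of trait
   (co)variance into additive genetic (A), shared environmental (C) and
   non-shared environmental (E) components, fitted by full-information
   maximum likelihood over MZ/DZ twin pairs (genetic cross-twin correlation
   1.0 / 0.5, shared environment 1.0), with AIC model comparison (ACE / AE /
   E), standardized components (h², c², e²) and genetic / environmental
   correlation matrices (rg, re).
2. **Co-twin control** — random-intercept mixed models regressing wellbeing
   on a social factor: pooled full-sample association, and the MZ within-pair
   / between-pair decomposition (β_W on the pair-centered deviation, β_B on
   the pair mean), with attenuation summaries that classify confounding.

Since registry twin data are not public, a first-class simulator generates
cohorts with Cholesky-structured A/C/E covariance, a wellbeing outcome mixing
direct-causal and genetically confounded pathways, Likert item generation,
incomplete pairs, and outcome-dependent wave-2 attrition — so every estimator
is validated against generating truth.

## Modules

| module | contents |
| --- | --- |
| `twinwell.twin_data` | long-CSV cohort I/O, validation, long↔wide conversion |
| `twinwell.scales` | scale scoring, Cronbach's alpha, disruption composite, age/sex residualization, attrition comparison |
| `twinwell.biometric` | Cholesky ACE/AE/E models: FIML likelihood, fitting, standardization, rg/re, AIC comparison, twin correlations |
| `twinwell.cotwin` | within/between decomposition, profiled-REML mixed models, attenuation summary, effect-size labels, estimate panels |
| `twinwell.synthetic` | cohort simulator + canned scenarios (causal / confounded / mixed / null) |
| `twinwell.cli` | `twinwell` command with subcommands and the `run-study` pipeline |

## CLI

```bash
# simulate a cohort with a known causal + confounded wellbeing pathway
twinwell simulate --scenario mixed --n-mz 1000 --n-dz 1000 --seed 1 \
    --out cohort.csv --truth truth.json

# fit an AE Cholesky model (residualizes on age and sex first)
twinwell fit-biometric --input cohort.csv --traits social --model AE \
    --seed 1 --out fit.json

# co-twin control: MZ within/between model
twinwell cotwin --input cohort.csv --exposure social --outcome wellbeing_w1 \
    --sample mz --out cotwin.json

# full estimates panel (full-sample + MZ within, concurrent + lagged)
twinwell panel --input cohort.csv --exposures social --out panel.csv

# whole pipeline with manifest
twinwell run-study --config run.yaml --out results/ --seed 1
```

`run.yaml` keys: `input` (or `scenario`/`n_mz_pairs`/`n_dz_pairs`), `traits`,
`models`, `exposures`, `concurrent_outcome`, `lagged_outcome`.

Default scale definitions (SWLS, RSS, ECR-N12 subscales, UCLA-3, Trust) ship
in `src/twinwell/data/scales.yaml`; reverse-keyed items are explicit
configuration there.

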