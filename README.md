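# nectarclim

Thermal response of nectar secretion: a tested pipeline that simulates
stepped-temperature climate-chamber experiments, derives per-plant-day
nectar traits, fits quadratic mixed-effects temperature-response models,
computes 5%-band optimal temperature ranges, and compares trait optima of
early- vs late-flowering species against baseline and projected climates.

## What it does

1. **`nectarclim.simulate`** — generates per-flower nectar measurements and
   per-plant flower counts for a stepped day-temperature schedule (night
   held 6 °C below day; 24-h mean = day − 6·dark/24), with a parallel
   control group, per-plant random intercepts, shared time drift, and a
   separate zero-inflation process for empty flowers. Deterministic per-plant
   substreams: adding plants never reshuffles existing ones.
2. **`nectarclim.preprocess`** — the five analysis traits (volume per
   flower, sugar concentration, sugar content per flower and per plant,
   flowers per plant), sucrose-density sugar calculation, within-plant-day
   concentration imputation, log/logit transforms and z-standardization.
3. **`nectarclim.models`** — random-intercept LMMs (per-plant; plant nested
   within species for combined fits) for the quadratic temperature response,
   the time×group control validation, and the temperature×flowering-group
   contrast; marginal/conditional R²; ML-based AIC selection of linear vs
   quadratic trends; zero-inflated negative-binomial models for empty-flower
   counts (optional plant random intercept via Gauss–Hermite quadrature).
4. **`nectarclim.optima`** — shape classification (∩, ∪, /, \\, flat),
   vertex optimum in °C, and the closed-form optimal range: the interval
   where the fitted curve stays within 5% of the observed trait-value range
   below its maximum, `x* ± sqrt(delta/|b2|)`.
5. **`nectarclim.climate`** — monthly baseline temperatures plus seasonal
   warming increments (75th-percentile and maximal levels ship as defaults;
   median increments must be supplied explicitly), and paired t-tests of
   group optima against each scenario level.
6. **`nectarclim.pipeline` / CLI** — end-to-end orchestration with a JSON
   manifest recording the seed and every surfaced analysis decision.

## CLI

```bash
nectarclim simulate --seed 1 --outdir out            # synthetic dataset
nectarclim preprocess --input out/flowers.csv --counts out/counts.csv --outdir out
nectarclim fit --plant-day out/plant_day.csv --stage groups --outdir out
nectarclim optima --plant-day out/plant_day.csv --outdir out
nectarclim compare --optima out/table_optima.csv --outdir out
nectarclim all --seed 1 --outdir out                 # everything at once
```

### Median ("p50") projection increments

Only the 75th-percentile and maximal seasonal warming increments are
published, so those ship as defaults; median increments are deliberately
absent and must be supplied in a scenario YAML (`increments: {p50: {winter:
…, spring: …, summer: …}}`). If you have published "50% projection" t
statistics, the increments can be recovered as a validation exercise by
solving `paired_t(optima, baselines + inc(season)) = t_published` for the
per-season increments — but recovered values are estimates, not
configuration defaults, and the package will never substitute them
silently.

Each stage writes tidy UTF-8 CSV; `all` additionally writes `manifest.json`.
Exit codes: 0 success, 1 validation failure, 2 runtime failure. A YAML
config (`--config`) can set seeds, scenario files, standardization scopes,
the range-truncation flag and the scenario levels; requesting the median
("p50") projection level without configured increments fails loudly.

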