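# quadmed

Quadratic moderated-mediation path analysis for longitudinal panel data:
full-information maximum-likelihood (FIML) estimation of recursive path
models with missing data, asymmetric Monte Carlo confidence intervals for
indirect effects, characterization of inverted-U ("hormesis") curves into
strengthening / buffering / toxic zones, and a bootstrapped
regions-of-significance procedure for the curve's instantaneous slope.
A synthetic three-wave family-panel generator makes every stage testable
without any external data.

## Modules

| module | what it does |
| --- | --- |
| `quadmed.synthetic` | three-wave panel generator (truncated-normal adversity composite, quadratic structural effects, autoregression, correlated residuals, MCAR masking) |
| `quadmed.composites` | reverse scoring, mean / standardize-and-average composites, Cronbach's alpha |
| `quadmed.path_fiml` | casewise FIML for recursive path models, fit indices (chi-square / CFI / RMSEA), Little's MCAR test |
| `quadmed.mediation` | Monte Carlo product-distribution CIs for indirect effects, pairwise path-comparison z tests |
| `quadmed.zones` | vertex, resilience inflection point, zone membership, curve profiles and plots |
| `quadmed.ros` | covariate residualization and bootstrapped regions of significance for `b1 + 2*b2*x` |
| `quadmed.pipeline` / `quadmed.cli` | config-driven orchestration with JSON/CSV artifacts and a `quadmed` CLI |

## CLI

```bash
# simulate a dataset, then inspect it
quadmed simulate --n 238 --seed 1 --out data.csv
quadmed describe data.csv

# fit a path model with a centered + squared predictor
quadmed fit data.csv --quadratic adversity_w1 \
    -e "ec_w2 ~ ec_w1 + adversity_w1_c + adversity_w1_c2 + sex + age + income"

# indirect-effect interval from estimates
quadmed mediate --a 0.05 --se-a 0.02 --b -0.26 --se-b 0.09

# zone geometry from a fitted quadratic
quadmed zones --b1 0.28 --b2 -0.52 --x-mean 4.62 --x-sd 1.04

# regions of significance
quadmed ros data.csv --outcome ec_w2 --predictor adversity_w1 \
    -c ec_w1 -c int_w1 -c ext_w1 -c sex -c age -c income --boot 1000

# the whole pipeline (demo config when --config is omitted)
quadmed run --seed 1 --out results_dir
```

`quadmed run` writes `report.json` plus CSV artifacts (dataset,
coefficient table, RoS grids, curve profiles) under the output
directory; reports are byte-identical across reruns with the same config
and seed. Configs are YAML or JSON; see
`quadmed.pipeline.default_config()` for the full schema.

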