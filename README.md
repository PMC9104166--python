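# iaqscreen

Screening tools for indoor air quality (IAQ) assessment in air-conditioned
offices. Full IAQ certification measures nine pollutants (CO₂, CO, RSP, NO₂,
O₃, HCHO, TVOC, radon, airborne bacteria) against a scheme of 8-h exposure
limits; an office is *satisfactory* only if every pollutant is within its
limit. Measuring all nine is expensive, so screening practice uses three
easily monitored surrogates — CO₂, RSP and TVOC — summarized by the IAQ
index

    θ = (Φ*_CO₂ + Φ*_RSP + Φ*_TVOC) / 3,      Φ*_j = Φ_j / Φ_j,e

the mean *fractional dose*: each surrogate's level Φ_j over its reference
limit Φ_j,e (1000 ppm, 180 µg/m³, 600 µg/m³). A five-level screening table
maps θ bins to likelihood ratios LR = P(bin | unsatisfactory) /
P(bin | satisfactory); with a pre-test probability of unsatisfactory IAQ,
LR gives the post-test probability by odds multiplication.

The package is built for the question that arises when an exposure standard
is tightened (as the Hong Kong scheme was: CO 8.7→6.1 ppm, RSP 180→100 µg/m³,
radon 200→167 Bq/m³): how should an existing screening table be updated
without waiting years for a resurvey? Its answer, end to end:

- **`core`** — pollutant records, the two bundled schemes, satisfaction
  assessment and the IAQ index (also as a sklearn-style transformer);
- **`synthetic`** — a seeded generator of office surveys with the group-wise
  statistical structure of a 525-office Hong Kong survey (truncated
  log-normal surrogates under a Gaussian copula, calibrated to the group
  means/sds, with a configurable fraction of "hidden" failures that pass all
  surrogates);
- **`backends`** — nine classifiers (four SVM kernels, kNN, logistic
  regression, decision tree, random forest, MLP) behind one fit/predict
  contract with deterministic hyperparameter grids;
- **`harness`** — the 16-condition evaluation design (r_d × K × scheme),
  trained vs. grid-search-retrained stages, baseline-accuracy flagging and
  best-model tallies;
- **`screening`** — Monte-Carlo sampling of the surrogate space, ensemble
  satisfaction prediction, per-bin likelihood ratios from fitted normal θ
  distributions, relative impact ratios r₂,₁ = LR₂/LR₁ and the updated
  table LR₂ = r₂,₁ · LR₁;
- **`cli`/`io`** — the `iaqscreen` command with `simulate`, `assess`,
  `index`, `evaluate`, `update-screening` and `run` subcommands.

## Worked example

```python
from iaqscreen import SCHEME_1, SCHEME_2, SurrogateTriple, iaq_index
from iaqscreen.synthetic import GeneratorConfig, generate_offices, summarize
from iaqscreen import harness, screening

# The index at the survey's overall mean surrogate levels
print(iaq_index(SurrogateTriple(co2=658, rsp=30, tvoc=358)).theta)
# 0.4737…  → the survey's mean index (θ is linear, so the index of the
#            means is the mean of the indices)

# A synthetic survey with the published group structure
dataset = generate_offices(
    GeneratorConfig.for_scheme(SCHEME_1, n_offices=2000, seed=1), SCHEME_1
)
print(summarize(dataset, SCHEME_1)["overall"].loc["mean", "theta"])
# ≈ 0.475  (survey: 0.473)

# Classifier comparison and the screening-table update
results = harness.run_evaluation(dataset.frame, master_seed=1, keep_models=True)
update = screening.run_screening_update(
    screening.select_best_models(results, "scheme1", 4),
    screening.select_best_models(results, "scheme2", 4),
)
print(update.table)
```

The final table has one row per θ bin (`<0.32`, `0.32-0.42`, `0.43-0.53`,
`0.54-0.64`, `>=0.65`) with the published Scheme-1 likelihood ratios
(0.1, 0.4, 0.8, 1.7, 25), the impact ratio of the tightened scheme for each
bin (typically 1.0–1.6: stricter limits make every bin riskier), and the
updated LR₂ with its display rounding. A bin with LR₂ > 1 flags offices
whose surrogate index alone already indicates elevated risk of failing the
updated standard.

Or from the shell:

```sh
iaqscreen simulate --n 2000 --seed 1 --out offices.csv
iaqscreen evaluate --data offices.csv --seed 1 --out eval/
iaqscreen update-screening --data offices.csv --seed 1 --out screening/
iaqscreen run --seed 1 --out run1/        # all of the above in one go
```

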