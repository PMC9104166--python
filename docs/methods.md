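# Methods

## The screening model

An office's IAQ is *satisfactory* under an assessment scheme iff all nine
pollutant levels are at or below the scheme's 8-h exposure limits. Levels
exactly at a limit pass: the limits are stated as limits *of satisfactory*
air, and the satisfactory-group maxima of the survey the package emulates
sit exactly at or just below the limits (CO₂ 998/1000 ppm, TVOC 597/600
µg/m³), which is only consistent with the ≤ convention. The survey itself
does not state how boundary ties were handled; this is the package's choice
and it is applied uniformly.

The screening statistic is the IAQ index θ, the arithmetic mean of the three
surrogate fractional doses Φ*_j = Φ_j/Φ_j,e over CO₂, RSP and TVOC. The
reference limits Φ_j,e are **always Scheme 1's** (1000 ppm, 180 µg/m³,
600 µg/m³), regardless of which scheme labels satisfaction — otherwise index
values would not be comparable across a standard update, which is the whole
point of the update procedure. An override exists (`iaq_index(...,
reference=...)`) but is off by default.

θ is linear in the surrogate levels, so the index of a group's mean levels
equals the group's mean index. Several tests and the acceptance script rely
on this identity.

## Synthetic surveys

The generator emulates the group-wise statistics of a 525-office
cross-sectional Hong Kong survey: satisfactory proportion 358/525 (352/525
under the tightened scheme), and per-group mean/sd/min/max of the three
surrogates. Defaults ship in `SURVEY_GROUP_STATS`.

**Marginals.** Pollutant concentrations are non-negative and right-skewed
(the survey TVOC maximum, 3144 µg/m³, is five sds above the mean), so each
surrogate is truncated log-normal, truncated at the group's observed
min–max. **Dependence** is a Gaussian copula with a single pairwise
correlation, default 0.3 — the surrogates are known to be correlated but no
coefficient is published, so this is a config knob, not a constant.

**Hidden failures.** A fraction `hidden_failure_fraction` (default 0.2) of
unsatisfactory offices fail *only* on a non-surrogate pollutant while all
three surrogates pass. These offices are indistinguishable from satisfactory
ones in surrogate space up to distributional differences, and are what keeps
any surrogate-only classifier below perfect accuracy. The default is a
tuning choice of this package (it yields a realistic accuracy ceiling of
roughly 0.92–0.94 under the default mixture), not a surveyed quantity.
Non-surrogate levels carry no information beyond pass/fail: passing offices
get a uniform 5–85% of each limit, a hidden failure exceeds one uniformly
chosen non-surrogate limit by 5–50%.

**Calibration.** Truncation and the pass/fail conditioning both distort
moments: with the default statistics, naive moment-matched log-normals
would miss the unsatisfactory-group TVOC mean by over 30%, because
conditioning on "fails at least one surrogate limit" up-weights the upper
tail. The generator therefore calibrates the underlying (μ, σ) per pollutant
and group by damped simulation-based moment matching *on the same
conditional sampling path used for generation* (45 iterations of 6000 draws;
σ updates only in the first 30 iterations, μ-only polishing afterwards).
Calibrated parameters land the generated group means within ~3% of the
configured targets and sds within ~6%; means are prioritized because the
conditioning distorts them most and downstream checks depend on them.
Calibration uses a fixed internal seed, making the calibrated parameters a
deterministic function of the targets alone; generation draws then derive
entirely from the config seed, so identical config + seed reproduce a
byte-identical dataset. Each record's intended label is re-verified with the
assessor before the dataset is returned; rejection sampling is capped (1000
rounds) and an infeasible configuration (e.g. a satisfactory-group mean
above a limit) raises a calibration error.

**What the generator does not emulate:** sampling density and floor-area
structure, measurement error, within-office temporal variation, seasonal
effects, and any real dependence between surrogate and non-surrogate
pollutants beyond the pass/fail coupling. Tests passing on synthetic data
therefore demonstrate that the pipeline's logic and statistics behave as
designed under the published group structure — not that a given classifier
would reach any particular accuracy on new field data.

## Classifier comparison harness

Features are the three raw surrogate levels, min-max scaled to [0,1] **on
the training split only** (the same affine map is applied, unclipped, to
test data — fitting the scaler on all data would leak test information).
The test fraction r_d is the fraction of the *total* dataset
(|test| = round(r_d·N)); the design crosses r_d ∈ {0.2, 0.3, 0.4, 0.5},
K-fold depth K ∈ {5, 10} and the two schemes into 16 conditions, each
algorithm contributing a *trained* (untuned) and *retrained* (grid-searched)
result — 32 result sets per algorithm.

Untuned defaults are the midpoint element of every grid dimension — the
"no prior knowledge" center of the search space. Grid search maximizes mean
K-fold held-out accuracy with folds computed once per condition and shared
across all algorithms and grid points; ties resolve to the earliest point in
the grid's declared order, and every stochastic component (split shuffle,
fold shuffle, forest/MLP initialization) is seeded from one master seed via
`master_seed + condition_index`.

For the SVM and logistic backends the regularization factor C is sklearn's
inverse regularization strength (larger C → closer fit). A cost-function
formulation in which larger C penalizes coefficients more would predict
accuracy *decreasing* in C; the observed behaviour of these classifiers
(accuracy improving up to C ≈ 2 and beyond) matches the inverse convention,
which is what the implementation uses throughout.

The shipped *reduced* grids (see `data/grids.yaml`) are deterministic
subsets of the full published test ranges, sized so the complete 16 × 9
design runs in minutes on one CPU at surveys of a few thousand offices; the
full ranges remain available via `grids(reduced=False)` or the CLI flag
`--full-grids`. The 60-configuration MLP architecture enumeration
(`mlp_architecture_table`) is a deterministic reconstruction from the full
cross-product (neuron totals × layer ratios × activations × solvers ×
learning-rate schedules), truncated to 60 in grid order; neuron totals are
split over hidden layers proportionally to the ratio pattern with floor
rounding and the remainder assigned to the first layer.

Baseline accuracy is mode(N)/N, the accuracy of always predicting the
majority class; models scoring below it are flagged unsatisfactory in the
results and logs.

## Screening-table update

Surrogate space is sampled uniformly (defaults CO₂ 400–1400 ppm, RSP 1–120
µg/m³, TVOC 0–1500 µg/m³ — the observable office ranges; n = 100,000,
seeded). An ensemble of the best fitted classifiers per scheme — by default
the top 4 distinct algorithms by test accuracy across both stages, mirroring
the practice of averaging a handful of best models — votes on each sample;
the majority label is used, with exact ties resolved to *unsatisfactory*
(the conservative screening outcome). The per-model spread of bin-wise
satisfaction fractions is logged as an agreement diagnostic.

Normal distributions are fitted (sample mean/sd) to the θ values of the
predicted satisfactory and unsatisfactory groups; the studentized range
u = (max − min)/s is logged per group as a normality diagnostic rather than
enforced, since the update procedure proceeds under the normality
assumption by design. Each bin's LR is the ratio of normal CDF masses. Bin
edges deserve a note: printed bin labels ("0.32–0.42", "0.43–0.53") have
gaps because they round θ to 2 decimals; the implementation bins raw θ on
the contiguous half-open intervals (−∞, 0.315), [0.315, 0.425),
[0.425, 0.535), [0.535, 0.645), [0.645, ∞), which reproduce the printed
labels under 2-dp rounding. The first bin is open below so the partition
covers the whole axis and the union-of-bins LR is exactly 1; θ itself is
non-negative, so this changes no data assignment.

Both schemes see the *same* Monte-Carlo sample (shared seed), so the
relative impact r₂,₁ = LR₂/LR₁ per bin isolates the effect of the scheme
change; running the update with identical ensembles yields r₂,₁ = 1 exactly
in every bin, which is asserted in the tests. The updated table stores
LR₂ = r₂,₁·LR₁ unrounded alongside a display rounding (one decimal below
10, integer at ≥10, round-half-up). Two fitting modes exist for the group
distributions: the primary mode fits them to the model-predicted labels on
the Monte-Carlo θ sample; `fit_index_distributions` applied to a real
labelled survey's θ values supports the survey-anchored reading instead.
Post-test probabilities follow standard diagnostic odds algebra:
post-odds = LR × pre-odds.

## Problem sizes and numerical choices

- Default synthetic survey for the full-design tests: n = 2000, one fixed
  seed; the acceptance-style structural checks run the complete 16-condition
  × 9-algorithm design at the reduced grids.
- Moment-recovery checks use n = 10,000 (5% tolerance on group means);
  estimator-agreement checks use n = 10⁵ (10% tolerance between counting
  and normal-CDF likelihood ratios).
- An LR whose satisfactory-group bin mass falls below 10⁻¹² is reported as
  +∞ rather than divided out; impact ratios over zero or infinite LRs are
  flagged undefined (NaN) with a warning.
- MLP training uses lbfgs with max_iter = 2000 and a per-spec fixed seed;
  logistic regression max_iter = 5000.

## Known limitations

- The generator matches first and second moments and the support of each
  group, not higher moments or the full dependence structure of real
  surveys; published per-classifier accuracy values are not reproduction
  targets for this reason.
- The grid-search winner is selected on CV accuracy alone; no
  one-standard-error rule or statistical comparison between classifiers is
  implemented.
- The w/s normality diagnostic is logged, not tested against critical
  bounds; strongly non-normal predicted θ groups would make the normal-CDF
  LRs approximate (the counting estimator is available as a cross-check).
- Unit handling is fixed to the scheme-table unit system (ppm, µg/m³,
  Bq/m³, CFU/m³); there is no conversion layer.
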