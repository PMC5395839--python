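# Methods

## Scope and data situation

The package evaluates screening strategies for persistent albuminuria in a
high-risk adult population, in two parts: diagnostic validity of
conjunction rules over five spot-urine ACR samples against a three-month
gold standard, and a decision-analytic model of the long-term costs and
QALYs of screening with each rule. The original cohort (157 analyzable
patients, 82 with persistent albuminuria) is available only as aggregate
results — strategy-level confusion counts and demographic summaries — so
patient-level computation runs on synthetic cohorts; the published
confusion counts themselves (`albuscreen.sensitivity.TABLE_COUNTS`) are
treated as fixed inputs wherever the original analysis used them (the
economic model, distribution parameterization).

## Synthetic cohort generator

For subject *i* with latent class persistent/transient (prevalence 82/157),
sample *j*:

    log ACR_ij = log m_class + b_i + delta_j + sigma_j eps_ij,   eps ~ N(0,1)

* `m_class`: median set-point, 106.7 mg/g for persistent subjects (the
  study's persistent-group baseline median) and 26 mg/g (calibrated) for
  transient subjects — near/below the 30 mg/g threshold, matching a
  population recruited on a *prior* elevated ACR that is nonetheless
  gold-standard negative.
* `b_i ~ N(0, s_class)`: between-subject spread, s = 0.8 / 0.45 (log scale).
* `sigma_j`: within-person noise converted from a coefficient of variation
  via `sigma^2 = ln(1+cv^2)`; day-to-day CV 0.5 for the four first-morning
  samples, with an extra intraday CV of 0.4 (added in log-variance) for the
  afternoon random spot.
* `delta_j = ln(1.5)` for the random spot only: first-morning urine is the
  lowest-excretion void of the day, so daytime spots run systematically
  higher. Without this shift the random-spot strategy cannot be
  simultaneously *more* sensitive-like (more positives among cases) and
  *less* specific (more positives among non-cases) than the morning sample,
  which is the empirical pattern.

The lognormal form is the standard model for urinary analytes and
guarantees positivity; urinary creatinine is not modelled separately
because only the ratio is analyzed. Dropout is not simulated
(`n_patients` is the analyzable count), and no covariates (diabetes status,
eGFR trajectories) or missingness mechanisms are generated — passing tests
therefore demonstrate recovery of the *marginal* strategy-level operating
characteristics, not realism of any joint covariate structure.

Defaults were frozen by a grid search (`scripts/calibrate_cohort.py`)
minimizing squared z-scores (binomial SEs at the study's denominators,
n=82 cases / 75 non-cases) of: gold-standard prevalence, and each
strategy's sensitivity and specificity. At the frozen defaults every
target sits within ~1 SE. The within-person CV literature value for
day-to-day microalbuminuria variation (±170%) is definitionally ambiguous
(CV vs range) and was treated as motivation, not as a verbatim input.

## Validity metrics

Strategies are pure conjunctions (`ACR >= threshold` on every required
sample; the threshold comparison is inclusive at 30 mg/g). Confusion
tables are built against the gold standard on the same records. The five
standard proportions plus FP/FN rates are computed at full precision;
display rounding is decimal half-up. Zero-denominator metrics are reported
as *undefined* (`None`), never NaN-propagated.

Confidence intervals are exact Clopper–Pearson, from beta quantiles
(`scipy.stats.beta.ppf`): lower = B(α/2; k, n−k+1), upper =
B(1−α/2; k+1, n−k), with the conventional endpoints at k=0 and k=n. The
choice of the exact method is identifiable from the published bounds: for
82/82 the printed lower bound 95.6 equals (α/2)^(1/82), and 52/75 →
57.6–79.5 is wider than a Wilson interval; a test documents this
back-calculation, and `statsmodels.stats.proportion.proportion_confint
(method="beta")` serves as an independent oracle in the test suite.

eGFR uses the Chinese-modified MDRD equation,
`175·SCr^-1.234·age^-0.179·(0.79 if female)`, SCr in mg/dL, with a
µmol/L overload (÷ 88.4).

## Decision tree and Markov model

The published model has four health states (Negative urine test, Positive
urine test/treated, Symptomatic CKD, Dead). Four states cannot carry truth
status, treatment status and discontinuation simultaneously — each changes
mortality or cost — so the engine expands to seven substates (documented in
`albuscreen.markov`) and the four-state aggregate is recoverable by
summation. Initial occupancy is the decision-tree allocation:
prevalence×sens (treated case), prevalence×(1−sens) (undetected case),
(1−prev)×spec (true negative), (1−prev)×(1−spec) (treated false positive).

Transitions per annual cycle:

* Death from any state. Non-cases (true negatives, treated false
  positives) die at the general annual probability p0 = 0.0119; untreated
  and symptomatic cases at relative risk RR = 1.63; treated cases at
  RR×(1−RRR) with RRR = 0.24. Relative risks compose on the survival-rate
  scale, `p = 1−(1−p0)^RR`, which stays in [0,1] for any RR; a plain
  multiplicative rule is switchable (`mortality_composition`).
* Treated cases discontinue at 25% in the first model cycle and 2%/yr
  thereafter, never restart, keep case mortality without the treatment
  reduction, and stop accruing drug cost. False negatives redetected at a
  later annual retest face the 25% *at treatment entry*: the early loss is
  a side-effect phenomenon of starting therapy, and tying it to calendar
  cycle 1 only would make being missed by screening beneficial (late
  entrants would dodge it), inverting the monotonicity of QALYs in
  sensitivity.
* Discontinuing *false* positives simply return to the negative state: the
  discontinued pool carries case-level mortality, which a non-case must not
  inherit.
* Undetected cases are redetected at the annual retest with probability
  equal to the strategy's own sensitivity (`p_fn_redetect=None` default),
  or become symptomatic at `p_progress_symptomatic`.
* Treated false positives revert to negative (`p_fp_revert`); treated true
  cases may remit to negative (`p_recover`).
* Symptomatic CKD is absorbing except for death; no retesting or
  re-confirmation of positives is modelled.

Rewards accrue at cycle end on the post-transition occupancy, discounted by
(1+r)^−t, r = 5%/yr, over a 30-year horizon; an optional half-cycle
correction (off by default, the common cohort-model default) averages
start- and end-of-cycle occupancy. Negative-state occupants pay the
strategy's screening cost each cycle (annual retest); the whole cohort is
additionally charged one screening round at allocation (`charge_initial_
screen`, on by default). Treated states pay ¥2867.2/yr (RAS inhibitor),
symptomatic CKD ¥34,205/yr. Utilities: 1.0 for non-cases (including treated
false positives, whose decrement is economic, not health-related, in this
model), 0.899 for all case states, 0 for dead. Currency is abstract ¥ with
no inflation adjustment.

### Assumption-based parameters

Four transition probabilities and the population prevalence are modelling
assumptions, not study-reported inputs; they are flagged `assumption` in
the run manifest and logged when defaulted:

| parameter | default | rationale |
|---|---|---|
| `prevalence_albuminuria` | 0.095 | population prevalence of albuminuria among screened high-risk adults; placeholder, overridable |
| `p_fn_redetect` | strategy sensitivity | annual retest re-applies the same test |
| `p_progress_symptomatic` | 0.10/yr | untreated persistent albuminuria progressing to symptomatic stage 3–5 care |
| `p_fp_revert` | 0.10/yr | de-diagnosis of treated false positives at follow-up is uncommon; calibrated (see below) |
| `p_recover` | 0.05/yr | treatment-induced remission to normoalbuminuria |

The qualitative calibration target for these defaults is the published
ordering at the ¥100,000/QALY threshold: the three-sample strategy should
have the highest probability of being cost-effective. At the frozen
defaults it does (≈50% of PSA draws), through its lowest false-positive
treatment burden. Two published quantitative features are *not*
reproduced and are deliberately out of the package's claims: the absolute
costs/QALYs/ICERs (they depend on the four unstated probabilities, and the
published incremental-cost row is internally inconsistent with its own
absolute costs), and the claim that the three-sample strategy has the
highest *effectiveness* — under the stated reward structure (false
positives keep background utility and mortality) total QALYs are
necessarily monotone in sensitivity, so the perfectly sensitive
single-morning-sample strategy ranks highest in QALYs.

## Economic analysis

`incremental_analysis` reports both presentations explicitly: raw pairwise
incrementals vs a fixed comparator (DAY1), and a cost-sorted frontier
analysis (strict dominance: no costlier and at least as effective with one
strict inequality; extended dominance: frontier ICER exceeding that of a
more effective option, with ICER recomputation after each removal).
Dominated strategies carry a dominance flag instead of a negative ICER.
NMB is λ·effect − cost; ties in NMB-argmax are split equally (CEAC).

## Sensitivity analysis

Distribution families follow convention: lognormal for mortality and
relative risks (median at the central value, σ from the range read as a
95% interval), gamma for costs (moment-matched, σ = 0.25·mean/1.96 for a
"±25%" spread), beta for the CKD utility (moment-matched, σ = 0.145/1.96;
infeasible moment pairs are rejected with a diagnostic). The treatment RRR
is sampled on the RR = 1−RRR scale over (0.63, 0.92) so draws stay in
(0,1). Probability-type draws are clipped into [0,1] and clip events
counted. The alternative readings (σ = 0.25·mean; σ = 0.145) are one
constructor argument away and the choice is documented here because
"±spread" plus a family name has no unique parameterization.

The PSA samples all distributions jointly-independently, plus each
strategy's sensitivity and specificity from Jeffreys Beta(k+½, n−k+½)
posteriors of its confusion counts (the study names validity rates as model
parameters without stating distributions; without sampling them the
acceptability curves collapse to 0/1 steps). All strategies are evaluated
on the same draw (common random numbers). The four assumption-based
transition probabilities stay fixed in the PSA by default, having no stated
uncertainty. The tornado varies every distribution-carrying parameter plus
the discount rate (0–10%) one at a time, clipping range bounds into the
parameter's domain, and sorts by incremental-NMB swing (ICER swings are
unstable near zero incremental effect).

## Numerical conventions and problem sizes

Transition rows are verified row-stochastic to 1e-12 at construction; state
occupancy is conserved to 1e-9 over all cycles (tested across 1,000 random
parameter sets). Frontier logic is tested against an exhaustive
NMB-breakpoint oracle on 1,000 random instances. The acceptance script uses
n=10,000 synthetic patients and 10,000 PSA draws; the test suite uses
smaller PSA sizes (≤2,000) chosen as adequate for the Monte-Carlo
tolerances asserted. All randomness flows from a single seed through named
substreams, so stages reproduce independently and output files are
byte-stable given (config, seed).

## Known limitations

* Mortality and CKD progression are age-constant; no staging below
  "symptomatic", no microsimulation, no correlated parameter sampling, no
  value-of-information analysis.
* The generator emulates marginal strategy-level rates only; it is not a
  patient-level digital twin of the cohort.
* True negatives are never re-false-positive at later retests (the
  published state diagram has no such arrow); in reality annual retesting
  of a noisy biomarker would regenerate false positives.
* `prevalence_albuminuria` is a placeholder; results scale with it and it
  should be set to a population-specific value for any applied use.
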