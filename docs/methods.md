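# Methods

## Model overview

`osteocea` implements a Markov microsimulation (individual-level
state-transition model) of fracture prevention in postmenopausal women with
hormone-receptor-positive early breast cancer who receive five years of
aromatase-inhibitor (AI) therapy. Each simulated woman is followed in 1-year
cycles from the initiation age (60 by default) to death or age 100, through
two interacting processes:

* **Breast-cancer progression** over four health states — disease-free,
  locoregional recurrence, contralateral recurrence, distant metastasis —
  with time-dependent transition probabilities derived from parametric
  survival curves. The per-cycle probability of staying in a state through
  cycle *t* is S(t)/S(t−1); the engine consumes the complement,
  1 − S(t)/S(t−1). Each state carries its own clock: the time index resets on
  entry, so transition probabilities depend on time-in-state, not model time.
  Mortality in the distant-metastasis state comes from its fitted survival
  curve; all other states face age-specific background mortality, multiplied
  (on the hazard scale, p = 1 − (1−q)^HR) by an age-indexed hazard ratio
  after a hip fracture. A configurable distant-metastasis hazard ratio on
  background mortality defaults to 1 because metastatic excess mortality is
  already carried by the fitted curve; setting both would double-count it.

* **Fracture incidence** at three sites (hip, vertebral, other). The annual
  rate for a site is an age curve a·exp(b·(age − 60)) at the age-matched
  reference bone density, multiplied by a gradient-of-risk adjustment
  g^(−Z) — the standard osteoporosis convention of a relative risk g per SD
  of femoral-neck Z-score — and, for women with any prior fragility
  fracture, by a repeat-fracture relative risk at non-vertebral sites
  (vertebral fractures are exempt from the repeat multiplier). Rates convert
  to per-cycle probabilities by p = 1 − e^(−r·t). Each site can fracture at
  most once per cycle; two or more sites in one cycle count as a complex
  fracture. A hip fracture triggers a Bernoulli transition to a bedridden
  state, after which no further fractures are modelled.

Bone density is tracked as a femoral-neck T-score. During AI therapy it
falls at a constant drug-induced rate (0.13 SD/year, the T-score equivalent
of roughly 10% BMD loss per 5 years at the young-adult SD); afterwards it
follows an age-specific natural-loss table. T-scores convert to Z-scores
through young-adult and age-matched reference means/SDs, so the same woman
becomes *less* unusual for her age as the reference population ages with
her, unless AI therapy outpaces the population decline.

## Within-cycle event order and accounting

Results of a state-transition model depend on the within-cycle order, which
we fix and document (the model description itself is silent on it):

1. strategy decision (screening, treatment start; DXA and drug costs);
2. cancer transition (including death from distant metastasis);
3. fracture events (skipped if the cancer transition was fatal, or if
   bedridden), then the bedridden draw;
4. death from background mortality with excess hazard ratios;
5. bone-density update;
6. accrual: discount factor 1/(1.05)^t, cycle 0 undiscounted. Death during
   a cycle forfeits that cycle's utility and life-year but keeps event costs
   already incurred (DXA, drug, acute fracture). Recurring costs
   (post-fracture management, long-term care, societal indirect costs)
   accrue only if the cycle is survived. No half-cycle correction is
   applied, matching the full-cycle accrual default of individual-level
   state-transition tools.

Utility in a cycle is the age-specific population utility × a cancer-state
multiplier × fracture multipliers (first-year multiplier for sites fractured
this cycle, a smaller persistent multiplier for previously fractured sites),
applied multiplicatively; the bedridden state overrides this with a flat
long-term-care utility. The multiplicative composition is a documented
choice — the alternative (additive decrements) is exercised in sensitivity
ranges rather than as a switch.

## Common random numbers

Every stochastic event belongs to a named channel (baseline BMD, adherence,
each cancer transition, each fracture site, bedridden, death). Channel *c*
is an independent counter-based generator keyed by (seed, c), and every
channel draws one uniform per patient per cycle regardless of state.
Consequently two runs that differ only in strategy reuse identical
pre-decision event histories patient-by-patient, and incremental costs and
QALYs of order 0.01 QALY are estimable at n = 10⁵ without being swamped by
Monte-Carlo noise. This is verified exactly in the tests: a treatment
stripped of effect and cost reproduces the no-intervention trajectories
bit-for-bit.

## Strategies

Six base strategies: no intervention; one-time DXA screening with selective
therapy at T ≤ −2.5 (osteoporosis) or T ≤ −1.0 (osteopenia); annual DXA
screening at either threshold; universal therapy without screening. Scenario
variants use biennial/quinquennial screening or substitute denosumab
(5-year course, no residual effect by default) or zoledronate (3-year
course) for alendronate (5-year course). Screening measures the model
T-score without error; periodic screening runs on cycles 0, k, 2k, … while
AI therapy is ongoing (through its final year) — the screening programme
targets AI-induced loss, so we do not continue scans indefinitely — and
stops once treatment starts; one treatment course per lifetime.

Adherence is all-or-nothing: a Bernoulli(adherence) draw at treatment
initiation. Non-adherent women fill one year of prescription (costs, no
effect); adherent women take the full course and retain a residual
(offset) effect for bisphosphonates, with the relative risk returning
linearly to 1 over a period equal to the treatment duration (continuous at
the stop time, exactly 1 at the end of the offset).

## Survival-curve machinery

Cancer transition curves are meant to be refit from digitized Kaplan–Meier
coordinates: `reconstruct_ipd` performs a Guyot-style allocation of events
and censorings consistent with the numbers-at-risk table (censor counts per
interval are iterated until the implied number at risk — after the events
allocated at the next interval's first digitized time — matches the
published count; survivors past the last digitized time are
administratively censored). Six parametric families (exponential, Weibull,
Gompertz, log-logistic, log-normal, generalized gamma) are fit by maximum
likelihood — five through lifelines, Gompertz by a small Nelder–Mead MLE
since no installed fitter provides it — and selected by AIC, ties broken by
parsimony then a fixed name order. The generalized gamma uses the
(μ, σ, Q) parameterization with Q = 1 reducing to a Weibull member and
Q → 0 to the log-normal; both reductions are tested numerically.

Digitization density matters: with a 0.25-year grid the time-discretization
of reconstructed event times biases AIC toward the flexible generalized
gamma; at a 0.1-year grid the generating family is recovered in most cases
(the shipped recovery test requires ≥ 4 of 6 at n = 2000). Fixture defaults
(n = 2000, administrative censoring at 12 years, 0.1-year grid) are stated
choices, not inferred from any source.

## Synthetic default parameters

No machine-readable source table accompanies the analysis, so the shipped
fixture is generated programmatically with every value tagged in a
provenance manifest. Design-level constants are set exactly: 5% annual
discount rate, willingness-to-pay threshold $38 223/QALY (3 × 2022 China
GDP per capita; $50 964 for 4×), drug courses 5/5/3 years, initiation age
60, five years of AI therapy, healthcare perspective in the base case, 2022
USD. Everything else is a synthetic stand-in of realistic magnitude:
Chinese female background mortality is approximated by a Gompertz-like
schedule q(a) = 0.0068·e^(0.098(a−60)); fracture-incidence curve
coefficients were chosen once so that the untreated cohort's 10-year
any-fracture cumulative incidence falls near 13% (the published range for
this population is 12.23–14.2%), with 5-/10-year overall survival near
95.7%/88.7%; treatment relative risks, costs and utilities take typical
values from the osteoporosis health-economics literature (e.g. alendronate
RR 0.60/0.55/0.81 for hip/vertebral/other; generic alendronate ≈ $65/year;
DXA ≈ $26 per scan; hip-fracture acute cost ≈ $4 900).

What the synthetic fixture does and does not show: the pipeline reproduces
the *qualitative* structure of the analysis — all interventions add QALYs
and cost; one-time osteoporosis screening is cost-effective at the
threshold; cost-effectiveness improves with initiation age through 70–74;
lower adherence and a 10-year horizon worsen ICERs — but the *numeric*
ICERs depend on cost and utility stand-ins and are several-fold lower than
would be obtained with the unpublished source table (averted fracture costs
nearly offset the cheap generic drug). Passing tests therefore validate the
simulation and economic machinery, not the specific published dollar
figures. One directional difference is expected by construction: including
societal indirect costs here *lowers* the screening ICER (prevention averts
caregiver costs), since the stand-in indirect costs attach only to fracture
sequelae.

PSA distributions follow health-economics convention — beta for
probabilities and utilities, gamma for costs and rates, log-normal for
relative risks — with hyperparameters moment-matched to the point estimates
(coefficient of variation ≈ 20% for gammas). The PSA re-runs a reduced
first-order cohort per outer draw with common random numbers rather than a
cohort approximation.

## Problem sizes and numerics

Default first-order runs use n = 100 000 trials (the acceptance script's
choice as well); the microsimulation is vectorized over patients, so a
lifetime run at n = 10⁵ takes about a second. The PSA in the acceptance
script uses 500 outer draws × 4 000 inner trials; the CEAC grid spans
0–80 000 $/QALY in $80 steps plus the two landmark thresholds. The
cohort-Markov oracle comparison runs at n = 50 000 and 3 Monte-Carlo
standard errors. Probability tables are precomputed per age/cycle;
transition probabilities are clipped to [0, 1]; an S(t−1) = 0 state raises
an absorbed-state error rather than dividing by zero.

## Known limitations

* Screening has no measurement error, and treatment initiation is a single
  lifetime decision; sequential or repeat courses are out of scope.
* Breast-cancer treatment costs are excluded by design; the model prices
  only osteoporosis-related resources.
* The repeat-fracture multiplier uses a single any-prior flag, not counts.
* The bedridden state is absorbing for fractures and uses a flat utility.
* Scenario "history of prior fracture" seeds the any-prior flag (raising
  subsequent-fracture risk) without assigning a site history, so it carries
  no utility or management-cost legacy for the pre-existing fracture.
* All default values other than the design constants are synthetic
  stand-ins; conclusions drawn from the shipped fixture are structural, not
  quantitative.
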