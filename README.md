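# osteocea

Cost-effectiveness microsimulation of fracture-prevention strategies for
postmenopausal women with hormone-receptor-positive early breast cancer on
aromatase-inhibitor (AI) therapy.

AI therapy accelerates bone-mineral-density (BMD) loss and raises fracture
risk. In resource-constrained settings the question is not *whether* to
protect bone health but *how*: screen everyone with DXA and treat
selectively, screen repeatedly, or treat universally without screening?
`osteocea` answers this with a Markov microsimulation: individual women are
simulated in 1-year cycles over a lifetime horizon through a combined
breast-cancer state space (disease-free → locoregional/contralateral
recurrence → distant metastasis) and a fracture process (hip, vertebral,
other; post-fracture and bedridden states), accumulating discounted costs
(2022 USD) and quality-adjusted life-years (QALYs).

The package is aimed at health-economics researchers and modellers who want
a transparent, fully tested, scriptable re-implementation of this class of
analysis — including the survival-curve machinery (Kaplan–Meier pseudo-IPD
reconstruction, six-distribution parametric fitting with AIC selection),
probabilistic sensitivity analysis with acceptability curves, tornado
diagrams and scenario grids.

## Model core

Breast-cancer transitions are time-dependent: from a fitted survival curve
S(t) (log-normal in the default configuration,
S(t) = 1 − Φ((ln t − μ)/σ)), the per-cycle probability of remaining in the
state is S(t)/S(t−1) and of leaving it 1 − S(t)/S(t−1), with a clock that
resets on state entry.

Fracture incidence at site *s* for a woman of age *a* with femoral-neck
Z-score *Z* is

    r_s(a, Z) = A_s · exp(B_s (a − 60)) · g_s^(−Z) · RR_repeat

with gradient-of-risk g_s (relative risk per SD of BMD), a repeat-fracture
multiplier after any prior fracture (vertebral site exempt), and
per-cycle probability p = 1 − e^(−r t). Anti-resorptive therapy multiplies
rates by a drug/site relative risk, with a linear post-bisphosphonate
residual (offset) effect decaying to 1 over a period equal to the treatment
course. Mortality combines age-specific background rates with excess
hazards after hip fracture and in distant metastasis.

Strategies are compared by incremental cost-effectiveness ratio
ICER = ΔC/ΔE on the efficiency frontier (strict and extended dominance
removed), against a willingness-to-pay threshold of $38 223/QALY
(3 × 2022 China GDP per capita). All strategies share common random
numbers: every stochastic event channel draws per patient per cycle from a
(seed, channel)-keyed stream, so incremental effects of order 0.01 QALY are
resolvable at n = 10⁵.

## Worked example

```python
import osteocea as oc

params, manifest = oc.make_default_params()   # synthetic default fixture
outs = [oc.run_cohort(100_000, s, params, seed=1, keep_patients=False)
        for s in oc.builtin_strategies()]
for o in outs:
    print(f"{o.strategy:20s}  cost ${o.mean_cost:8.2f}  QALY {o.mean_qaly:.4f}")
cea = oc.frontier(outs, wtp=params.wtp)
print(cea.cost_effective)
```

prints (seed 1):

```
no_intervention       cost $ 1469.57  QALY 10.4136
once_osteoporosis     cost $ 1478.61  QALY 10.4229
once_osteopenia       cost $ 1515.22  QALY 10.4422
annual_osteoporosis   cost $ 1563.24  QALY 10.4330
annual_osteopenia     cost $ 1582.36  QALY 10.4467
universal             cost $ 1572.99  QALY 10.4476
universal
```

Reading the numbers: every intervention adds QALYs over no intervention at
extra cost; annual screening is strictly dominated by cheaper, more
effective alternatives on this fixture; the frontier runs
no-intervention → one-time screening (osteoporosis, ICER ≈ $970/QALY) →
one-time screening (osteopenia, ≈ $1 900/QALY) → universal therapy
(≈ $10 700/QALY), all below the $38 223/QALY threshold. The untreated
cohort's validation statistics are a 95.8%/88.6% 5-/10-year overall
survival and a 13.7% 10-year any-fracture cumulative incidence (inside the
12.23–14.2% range reported for this population). Absolute dollar figures
depend on the synthetic stand-in costs/utilities shipped with the package —
see `docs/methods.md` for what the fixture does and does not represent.

The same analyses are available from a shell:

```sh
osteocea run --n 100000 --seed 1 --out results/
osteocea psa --n-outer 1000 --n-inner 10000 --seed 1
osteocea tornado --reference no_intervention --strategy once_osteoporosis
osteocea scenario --age-band 70-74 --horizon 10y
```

## Layout

* `src/osteocea/params.py` — parameter schema, YAML I/O, PSA sampling
* `src/osteocea/survival.py` — KM reconstruction, parametric fits, AIC
* `src/osteocea/fracture.py` — fracture rates, BMD, treatment effects
* `src/osteocea/strategies.py` — screening/treatment decision rules
* `src/osteocea/engine.py` — vectorized microsimulation with CRN
* `src/osteocea/economics.py` — ICERs, frontier, PSA/CEAC, tornado
* `src/osteocea/scenarios.py` — scenario grid
* `src/osteocea/synthetic.py` — fixture generator, synthetic KM curves
* `docs/methods.md` — full model description, assumptions, limitations
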