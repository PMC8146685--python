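# Methods

## The decision problem

Somatostatin analogues (SSAs, e.g. octreotide LAR) slow tumour growth and
control symptoms in metastatic gastroenteropancreatic neuroendocrine
tumours (GEP-NETs), but cost roughly $4,000 per month and, once started,
are continued for life. Guidelines leave open whether to start the drug
at diagnosis of stage IV disease or to observe and start it at first
progression. This package frames that choice as a cost–utility analysis
between two strategies:

* **SSA** — start the analogue immediately at diagnosis;
* **DELAY** — observe, and start the analogue at first progression.

In both arms a serious drug complication stops the SSA permanently, and
progression on (or off) the analogue leads to peptide receptor
radionuclide therapy (PRRT), after which patients remain in a post-PRRT
state until death.

## Model structure

A deterministic Markov cohort model with monthly cycles follows patients
from age 60 until death or age 100 (480 cycles). The state union is:

| state | utility | monthly cost | exits |
|---|---|---|---|
| StableUntreated (DELAY start) | 0.79 | 0 | NET death (18 mo median), progression (6 mo) → ProgressedOnSSA, background death |
| StableOnSSA (SSA start) | 0.79 | $4,121 | NET death (39 mo), progression (14 mo) → PRRT, complication → OffSSAComplication, background death |
| OffSSAComplication | 0.32 | 0 | NET death (18 mo), progression (6 mo) → PRRT (no-SSA chain), background death |
| ProgressedOnSSA | 0.72 | $4,121 | NET death (39 mo), progression (14 mo) → PRRT, complication → PRRT (no-SSA), background death |
| PRRT1–4 (tunnel) | 0.72 | $51,300 + SSA | NET death (39 mo), background death, else advance |
| PostPRRT | 0.72 | SSA | NET death (39 mo), background death |
| DeadNET / DeadOther | 0 | 0 | absorbing |

The PRRT tunnel forces exactly four monthly treatment cycles (totalling
$205,200). Patients whose SSA was stopped for toxicity traverse a
parallel no-SSA tunnel and post-PRRT state with no drug cost; everyone
else continues the analogue through and after PRRT. Tracking NET-related
and other-cause death separately makes the cause-of-death split an
observable output.

**SSA dose on the PRRT pathway.** Stable patients receive octreotide LAR
20 mg per 28 days ($4,121/month); on and after PRRT the dose is 60 mg,
so the monthly drug cost on that pathway is scaled by
`ssa_prrt_dose_multiplier` (default 3.0, the dose ratio). This
escalation is load-bearing: without it, lifetime costs come out at
roughly 55% of the intended level, because most of the cohort's drug
exposure happens on the PRRT pathway.

## Transition probabilities

* **Medians to monthly probabilities.** All disease inputs are median
  times-to-event. Under a constant-hazard (exponential) reading — the
  only one the data support — a median of `m` months gives a monthly
  probability `1 − 0.5^(1/m)`. Disease transitions are therefore
  memoryless; the only time-dependence is background mortality through
  age.
* **Interval risks.** The 1% serious-complication risk over 96 weeks
  (= 96·12/52 ≈ 22.15 months) converts the same way to ≈ 4.54 × 10⁻⁴
  per month.
* **Background mortality.** The annual life-table probability at age
  `floor(60 + t/12)` is converted to monthly via
  `1 − (1 − q)^(1/12)` and applied additively in every alive state,
  without subtracting tumour deaths (they are negligible in national
  all-cause rates).
* **Competing risks.** Simultaneous exits from a state (NET death,
  progression, complication, background death) are combined by
  converting each marginal monthly probability to a rate
  `r = −ln(1 − p)`, computing the joint exit probability
  `P = 1 − exp(−Σr)`, and apportioning `P` in proportion to the rates.
  This is standard decision-modelling practice; adjusted rows can never
  exceed 1.

## Outcomes

Costs are discounted at 3% per year with the factor `1.03^(−t/12)` at
cycle `t`, accruing on start-of-cycle occupancy (a month's drug is
dispensed to those alive at the start of the month — no half-cycle
correction for costs). QALYs are utility-weighted occupancy, half-cycle
corrected by trapezoidal averaging of consecutive trace rows, and
discounted the same way. Life-years are the undiscounted trapezoid of
alive-state occupancy. The half-cycle choice is isolated behind a single
flag (`accumulate_rewards(..., half_cycle_correction=)`) so the
alternative convention is a one-line change.

The incremental cost-effectiveness ratio (ICER) is Δcost/ΔQALY of the
higher-QALY strategy over the lower, computed on unrounded totals, with
dominance (more QALYs for less money) flagged instead of a ratio.
Cost-effectiveness is judged against a willingness-to-pay (WTP) of
$100,000 per QALY; net monetary benefit is `WTP·QALY − cost`.

## Sensitivity analyses

* **Tornado (one-way).** Each parameter with a sensitivity range
  (costs half-to-double; medians and complication rate ±25%; utilities
  ±0.1) is set to its low and high bound with everything else at base,
  and both arms are re-run; bars are sorted by |ICER_high − ICER_low|.
* **Threshold price.** Brent root-finding of the monthly SSA cost on
  [0, base price] such that the ICER equals the WTP, to $0.01. The ICER
  is affine in any single cost parameter, so the bracket check at the
  endpoints and midpoint suffices for monotonicity.
* **PSA.** Every parameter is drawn independently per iteration: gamma
  for costs, beta for utilities and for monthly probabilities (medians
  and the interval complication risk are converted to probabilities
  first, drawn, and converted back). Moments are matched so each mean is
  the base value and each SD equals the sensitivity range divided by
  3.92 (the range read as a 95% interval) — the published analysis names
  the distribution families but not their spreads, so this is the
  package's choice, kept in one place (`sensitivity.RANGE_TO_SD`).
  Infeasible beta moments are shrunk to 99% of the feasibility bound and
  logged. The acceptability curve reports, per WTP value, the fraction
  of iterations with positive incremental net monetary benefit. Because
  incremental cost and incremental QALY are strongly positively
  correlated (longer survival means more months of an expensive drug),
  the cost-effective fraction at $100,000/QALY comes out near zero
  under these spreads; that fraction is the output most sensitive to
  the variance convention, which is why the convention is kept
  configurable.

## Background-mortality data

The model needs a period life table (annual death probability `q_x` by
age). The package bundles a **synthetic** Gompertz–Makeham table
(`data/us_like_synthetic_lifetable.csv`, hazard `a·e^{bx} + c` with
a = 2.0 × 10⁻⁵, b = 0.10, c = 6 × 10⁻⁴) calibrated to approximate anchor
values of recent US both-sex tables (q₆₀ ≈ 0.009, q₇₀ ≈ 0.023,
q₈₀ ≈ 0.061, q₉₀ ≈ 0.157; remaining life expectancy at 60 ≈ 21.7 years;
≈1.3% of 60-year-olds reach 100). It is not a published national table;
any real table can be supplied as a two-column `age,qx` CSV
(`--life-table PATH`). Because ~94% of modelled deaths are
tumour-related, results are insensitive to residual differences between
this table and an official one. What passing tests on the synthetic
table do **not** establish is calibration to any particular national
population's cause-deleted mortality.

## Numerical choices and edge cases

* Horizon truncation: the model stops at age 100; survivors (≈1% of a
  disease-free cohort, ~0 with disease) accrue nothing beyond. The
  life-expectancy validation oracle integrates the annual table with a
  within-year trapezoid; agreement with the monthly engine is expected
  to ~0.015 years for a disease-free cohort, the residual being
  within-year discretisation plus the truncated tail.
* A certain event (p = 1) competing with any other positive-probability
  event is rejected as undefined; the engine never generates one because
  cohort ages stay at or below 99 where q < 1.
* QALY ties in strategy comparison are broken by lower cost and flagged
  (`tie=True`, ICER undefined) rather than reported as a ratio.
* Problem sizes: the base case is one pair of 480-cycle runs
  (milliseconds); the tornado is 26 pairs; the PSA default in the
  analysis scripts is 10,000 iterations (a few minutes on one core),
  with the iteration count a flag, and 100,000 available via
  `gepnet-cea psa --iterations 100000`.
* Seeds: all Monte Carlo (PSA, microsimulation oracle) is driven by
  explicit integer seeds through `numpy.random.default_rng`; identical
  seeds give bit-identical outputs.

## Known limitations

* No progression event after PRRT, no repeat PRRT, and no alternative
  salvage therapies (everolimus, surgery, embolisation) — both arms
  would use them identically, so their omission mostly cancels in the
  increments.
* Untreated NET death and off-SSA progression act as simultaneous
  competing risks; to the extent the source trials' placebo
  progression-free-survival already embeds deaths, some double counting
  is possible.
* Utilities map four published values onto states (uncontrolled-symptom
  utility only in the post-complication, pre-PRRT state); other mappings
  are defensible but the tornado shows the model is nearly indifferent
  to that utility.
* The DELAY arm starts the analogue in the same monthly transition as
  first progression; no treatment-free progressed interval is modelled.
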