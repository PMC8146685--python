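# gepnet-cea

Cost-effectiveness analysis of **when to start somatostatin analogues
(SSAs)** in metastatic gastroenteropancreatic neuroendocrine tumours
(GEP-NETs): immediately at diagnosis, or only once the disease
progresses.

SSAs (octreotide LAR, lanreotide) delay tumour progression and control
symptoms, but cost ≈ $4,121/month for life. This package implements a
monthly-cycle Markov cohort model (age 60 → 100) comparing the two
strategies, for health-economics researchers and modellers who want a
fully scripted, testable version of this class of TreeAge-style
analysis.

## The model in brief

Health states: stable (untreated / on SSA), off-SSA after a serious
complication, progressed on SSA, a four-month PRRT (peptide receptor
radionuclide therapy) tunnel at $51,300/cycle, a post-PRRT state, and
separate absorbing states for NET-related and other-cause death.

* Median times-to-event *m* (months) become monthly probabilities
  `p = 1 − 0.5^(1/m)` (constant hazard).
* Simultaneous exits combine as competing risks via rates
  `r = −ln(1−p)`: total exit `1 − e^(−Σr)`, apportioned ∝ `r`.
* Background mortality comes from a period life table
  (`1 − (1−q_x)^(1/12)` per month, age `x = ⌊60 + t/12⌋`).
* Outcomes: discounted costs (3%/yr, factor `1.03^(−t/12)`), discounted
  half-cycle-corrected QALYs, undiscounted life-years;
  `ICER = Δcost/ΔQALY`, judged at a willingness-to-pay of
  $100,000/QALY; `NMB = WTP·QALY − cost`.

Full details, conventions and limitations: [docs/methods.md](docs/methods.md).

## Worked example

```bash
$ gepnet-cea run --out results
SSA vs DELAY: ICER $408,404/QALY -> not cost-effective at WTP $100,000/QALY
```

`results/base_case.csv` then holds the outcome table (abridged):

| strategy | cost | LY | QALY | ΔQALY | ICER | NET deaths |
|---|---|---|---|---|---|---|
| SSA | $604,258 | 4.42 | 2.91 | 0.40 | $408,404/QALY | 93.7% |
| DELAY | $442,359 | 3.86 | 2.51 | — | — | 94.5% |

Read: starting the analogue immediately buys 0.56 life-years
(0.40 QALYs) at an extra $161,899 — about $408k per QALY, four times the
conventional US threshold, so immediate initiation is **not**
cost-effective; observation with SSA at progression is the preferred
strategy at $100,000/QALY. Nearly all deaths in both arms are
tumour-related. And

```bash
$ gepnet-cea threshold --out results
cost_ssa_month must fall to 88.84 to meet WTP $100,000/QALY
```

i.e. the monthly drug price would have to drop from $4,121 to ≈ $89
(−98%) before immediate initiation meets the threshold.

Other commands: `gepnet-cea tornado` (one-way sensitivity bars) and
`gepnet-cea psa --iterations 10000` (probabilistic sensitivity analysis
+ acceptability curve). All accept `--config params.yaml`,
`--set key=value`, `--life-table PATH|gompertz:a,b,c`, `--seed N`. The
numbered scripts in `analysis/` run the same four steps in order and
narrate what they find.

Background mortality defaults to a bundled **synthetic** US-like
Gompertz–Makeham life table (see `docs/methods.md`); supply any real
`age,qx` CSV to replace it.

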