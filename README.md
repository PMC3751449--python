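# quitcea

A lifetime Markov cohort model for the cost-effectiveness of text-message
smoking-cessation support, from a UK NHS perspective.

Mobile-phone text support roughly doubles biochemically verified quitting
at 6 months (relative risk 2.20, 95% CI 1.80–2.68, against a 4.9% control
quit rate). This package estimates what that is worth over a lifetime: a
cohort of 1,000 enrolled smokers is propagated in 6-month cycles through
three mutually exclusive states — smoker, former smoker, dead — while
accruing the costs and utility losses of five smoking-related diseases
(lung cancer, stroke, myocardial infarction, COPD, coronary heart
disease). Quitters face a 21% relapse between 6 and 12 months and a 30%
lifetime relapse thereafter; all smokers quit spontaneously at 2% per
year. Costs and effects are discounted at 3.5% per year.

Status-specific mortality and disease probabilities are derived from
general-population tables by inverting the prevalence mix

```
M_gen = M_s·P_s + M_f·P_f + M_n·P_n,   M_s = RR_s·M_n,  M_f = RR_f·M_n
⇒  M_n = M_gen / (RR_s·P_s + RR_f·P_f + P_n)
```

per age and gender. The incremental comparison yields Δcost, ΔLY, ΔQALY
and the ICERs (flagged "dominant" when the intervention improves health
and saves money); one-way sensitivity analysis and a 1,000-iteration
second-order Monte Carlo PSA (lognormal relative risk, beta
probabilities/utilities, gamma costs) give net-monetary-benefit
acceptability curves over £0–£4,000 per QALY.

The national tables behind the original analysis are not redistributable,
so the package ships a synthetic UK-like generator (Gompertz mortality,
logistic smoking-prevalence decline, exponential disease-prevalence
growth, banded relative risks) with the right orders of magnitude; see
`docs/methods.md`.

## Worked example

```bash
quitcea synth --out epi_tables.csv
quitcea cea --epi epi_tables.csv --out-dir results/
```

prints, for the packaged base case on the default synthetic tables:

```
incremental_cost_gbp: -7898.29
incremental_life_years: 31.5969
incremental_qalys: 39.8859
additional_quitters_6m: 58.6788
cost_per_quitter: dominant
cost_per_life_year: dominant
cost_per_qaly: dominant
```

Per 1,000 enrolled smokers, text support yields ~59 additional 6-month
quitters; over their lifetimes the avoided disease treatment costs exceed
the £16,120 programme cost by about £7,900, while adding ~32 discounted
life years and ~40 discounted QALYs — the intervention *dominates* current
practice (better health, lower cost), which is why no ICER is reported.

```bash
quitcea psa --epi epi_tables.csv --out-dir results/ -n 1000 --seed 20120909
# probability_cost_saving: 0.966
```

96.6% of the 1,000 parameter draws leave the intervention cost saving;
`results/ceac.csv` holds the acceptability curve. `quitcea dsa` writes the
one-way sensitivity table and `quitcea simulate` the per-stratum cohort
outcomes. Every run writes a `manifest.json` recording inputs, outputs,
seed and package version.

The same API is available in Python:

```python
import quitcea as qc

epi = qc.generate_default()
inputs = qc.load_base_case(epi)
inc = qc.incremental(qc.run_weighted(inputs, qc.Arm.INTERVENTION),
                     qc.run_weighted(inputs, qc.Arm.CONTROL))
print(inc.d_cost, inc.d_qaly, str(inc.cost_per_qaly))
```

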