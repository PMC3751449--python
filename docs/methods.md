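# Methods

## Model structure

The model is a deterministic Markov cohort simulation with a 6-month cycle
and a lifetime horizon (age 100). A cohort enters entirely as smokers at
its stratum's starting age and occupies three mutually exclusive states:
smoker, former smoker, dead. Internally the former state is split into
`former_recent` (quit during the previous cycle) and `former_long` (past
the 12-month boundary); both carry former-smoker risks, the split exists
only to implement the relapse schedule. The trial population is
represented by six strata — starting ages 24, 35, 48 (weights 0.30, 0.31,
0.39) crossed with gender (male 0.55, female 0.45) — and overall results
are the weighted average of the per-stratum results per 1,000 enrollees.

Within each cycle events are ordered **death → quit → relapse**:

1. each alive fraction dies at its status- and age-specific 6-month
   probability;
2. surviving smokers quit with the scheduled probability: in cycle 1 the
   control quit rate (4.9%) times, in the intervention arm, the quit
   relative risk (2.20); in every later cycle the background quit rate
   (2%/year, converted to 6 months) in both arms;
3. surviving recent quitters relapse at 21% (the 6–12 month rate);
   survivors of that draw then face the 30% lifetime relapse as a one-off
   at the 12-month boundary before entering `former_long`, which apart
   from death is absorbing.

The one-off treatment of the lifetime relapse makes the long-run net quit
fraction exactly `quit_prob × 0.79 × 0.70` and is the default; setting
`lifetime_relapse_mode = "spread"` instead applies the 30% as a constant
per-cycle hazard over the first 10 years of abstinence (20 cycles of
`1 − 0.70^(1/20)`), tracked by time-since-quit bins. Background quitters
follow the same relapse schedule as trial quitters. Both modes conserve
occupancy to 1e-12 per cycle.

## Epidemiological derivation

Inputs are age (16–100) by gender tables of general-population annual
mortality `m_gen`, smoking-status prevalences (summing to 1), annual
disease probabilities for the five diseases, and banded relative risks
(> 0) for death and disease in smokers and former smokers versus
never-smokers. Status-specific rates are recovered by inverting the
prevalence mix:

```
M_n = M_gen / (RR_s·P_s + RR_f·P_f + P_n),  M_s = RR_s·M_n,  M_f = RR_f·M_n
```

identically for each disease. Re-mixing by prevalence reproduces the
general-population rates to 1e-10 (property-tested). Annual probabilities
become 6-month probabilities under a constant hazard,
`p½ = 1 − (1 − p)^½` — exact for exponential waiting times and standard in
cohort modelling (not `p/2`). Former smokers keep `RR_former` regardless
of abstinence duration; excess risk does not decay further with time
quit.

Disease probabilities are treated as per-cycle event probabilities:
within a cycle an individual experiences exactly one disease, or none, or
dies (mutually exclusive events; the derivation validates that the
per-status probabilities sum to ≤ 1). Diseases do not persist as chronic
states across cycles.

## Rewards, discounting, costs

Rewards accrue to the state at cycle start: 0.5 life years per alive
fraction; disease events earn the disease utility (lung cancer 0.58,
stroke 0.48, CHD/MI 0.80, COPD 0.73) and half the annual treatment cost
(£5,921 / £2,218 / £2,341 / £997 / £1,144, 2009–10 prices); the
disease-free remainder earns the status utility (smoker 0.75, former
0.78). No half-cycle correction is applied; the discount factor
`(1+r)^(−0.5(t−1))` (r = 3.5% for both costs and effects) is indexed at
cycle start. These conventions are deliberate and documented so results
are exactly reproducible.

The intervention arm pays the one-off programme cost (£16.12 per enrolled
smoker, optionally plus a royalty/management charge) at t = 0,
undiscounted; costs identical in both arms (the "current practice"
services themselves) cancel in the incremental comparison and are
omitted.

## Synthetic tables

The national data behind the original tables are not redistributable, so
`synthetic_epi` generates tables with the same statistical structure.
Functional forms (the simplest reproducing the qualitative shapes):

* mortality: Gompertz `m(a) = a₀·exp(b·(a−16))`; defaults a₀ = 4.0e-4 /
  2.8e-4 (male/female), b = 0.080 / 0.082 — within a factor of ~2 of
  recent UK life tables across ages 30–90;
* smoker prevalence: logistic decline `0.26 / (1 + exp(0.08·(a − 62)))`
  (≈ 25% in young adults, ≈ 9% at 70); former-smoker prevalence a linear
  ramp from 5% at 16 capped at 40%; never-smokers the remainder;
* disease probabilities: exponential growth `base·exp(g·(a−16))` with a
  gender factor (male 1.10, female 0.90), anchored to published UK
  prevalence magnitudes — CHD ≈ 9% at 65, COPD ≈ 5.5% at 70, stroke ≈ 5%
  at 72, MI ≈ 3.5% at 70, lung cancer ≈ 0.3% at 70. Prevalence-scale
  (rather than incidence-scale) probabilities follow the modelling
  tradition this analysis adopts, in which each prevalent case accrues
  the annual average treatment cost;
* relative risks: constant within age bands 16–34 / 35–69 / 70+; smoker
  death RR 1.6 / 2.2 / 1.5, large excesses for lung cancer (10–12) and
  COPD (6), moderate (≈ 2) for the cardiovascular diseases, attenuating
  toward 1 beyond 70.

Noise is multiplicative lognormal jitter (default sd 2%) so probabilities
stay positive; the prevalence triple is renormalised; probabilities are
clipped at 0.9 (with a warning). The packaged spec is seeded (20120909)
and bitwise reproducible.

What the synthetic tables do **not** emulate: the wobble and cohort
effects of real survey data, disease-specific mortality, gender-specific
relative risks, and the exact magnitudes of the original appendix tables.
Consequently absolute lifetime costs/LYs/QALYs per stratum are *not*
comparable with the published per-age-group table, and tests assert
structural properties (conservation, reconstruction, oracle agreement,
dominance patterns) plus the published desk-arithmetic quantities rather
than absolute totals.

## Sensitivity analysis

One-way analysis re-runs the model at each end of a range with everything
else fixed. Default ranges: quit RR 1.80–2.68; lifetime relapse 21–50%;
background quit 1.2–2.8%/yr; intervention cost £6.70–£62.30; royalty/
management £1–£35.

The PSA (default 1,000 iterations) samples, independently: the quit RR —
lognormal with μ = ln 2.20 and σ = (ln 2.68 − ln 1.80)/(2·1.96) from the
published CI; the lifetime relapse rate, background quit rate and the
seven health-state values — beta by method of moments; the five disease
unit costs and the intervention cost — gamma by method of moments. The
source analysis names these families but no dispersions; the package
defaults every beta/gamma sd to 10% of the mean (`sd_frac`,
config-overridable) — the largest single assumption in the package. The
6-month control quit rate is held fixed; "baseline quit rate" is read as
the background rate, matching the one-way table. Mortality and prevalence
tables are not sampled. Draws for iteration *i* come from substream *i*
of the seed, so the vectorised batch evaluation is bitwise-equivalent to
sequential runs and parallelisable without changing results. Draws that
would violate hard constraints (e.g. RR × control quit > 1) are redrawn,
capped at 100 attempts.

Because utilities are sampled independently, an iteration can draw a
former-smoker utility below the smoker utility (the constructor warns but
allows it); such iterations can have negative QALY gains, which makes the
acceptability curve non-monotone at high willingness-to-pay even when
most iterations are cost saving. NMB ties count as not cost-effective;
the CEAC grid is £0–£4,000 in £50 steps.

## Numerical choices and edge cases

* Age grid: integer years 16–100; a cohort aging past the table raises a
  validation error rather than extrapolating.
* The engine validates per-status disease-probability sums ≤ 1, derived
  probabilities ≤ 1 (naming age/gender/rate), and non-negative occupancy.
* Incremental ratios: "dominant" iff Δcost < 0 and the effect > 0;
  Δeffect = 0 with Δcost ≠ 0 is "undefined"; 0/0 reports 0.
* CSV round-trips are exact (shortest-repr floats, round-trip parsing).
* Problem sizes: lifetime runs are 104–152 cycles per stratum; the PSA
  evaluates all iterations as one vectorised batch (~1 s for 1,000); the
  person-level validation oracle uses 200,000 individuals over a 10-year
  horizon.

## Known limitations

Diseases carry no persistent (chronic-state) costs; relative risks do not
decay with abstinence duration; no half-cycle correction; passive smoking,
short-term benefits of quitting and non-smoking-related medical costs are
out of scope; the synthetic tables support structural validation and
order-of-magnitude results, not calibration to the original data.
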