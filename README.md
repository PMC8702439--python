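# delaydisc

Does a good mood make people grab the money now? `delaydisc` is an analysis
pipeline for a two-study design on **intertemporal choice (IC)** under
incidental affect: participants primed into a positive or neutral mood
choose between a smaller-sooner (SS) and a larger-later (LL) reward, with
the SS option either available *today* or only in 15 days. The package is
written for computational cognitive modellers who want to reproduce,
stress-test, or extend the full analysis chain on synthetic cohorts (the
original participant-level data are not public).

The core quantities:

- **Staircase titration.** Each block bisects the SS amount inside
  [0, 200] CNY until the interval is ≤ 5 CNY (six responses), locating the
  indifference point against a fixed LL of CNY 200.
- **Hyperbolic discounting, fitted hierarchically.** V = A/(1 + k·t),
  choice rule P(LL) = logistic(τ·(V_LL − V_SS)), with
  log k_i[,c] ~ N(μ_k[c], σ_k) and log τ_i ~ N(μ_τ, σ_τ) per group. Joint
  vs condition-split k structures are compared by WAIC (lower is better;
  ΔWAIC > 10 decisive); convergence requires Gelman–Rubin R̂ < 1.1 for
  every parameter.
- **Subjective time.** Line-scale judgments are anchored on the mean
  one-week length and fitted per participant/condition with the power law
  T = α·t^β (α = overall time contraction, β = diminishing time
  sensitivity). Refitting the discount model with t replaced by T tests
  whether group differences in k are carried by time perception.
- **Group statistics.** 2×2 mixed (split-plot) ANOVA with partial η² and
  Bonferroni post-hocs, two-sample t with Cohen's d, Pearson χ² on 2×2
  counts with r = sqrt(χ²/N), and the proportion-of-SS dependent variable.

The expected signature result is a *disjunction* pattern: the affect groups
differ in discount rate only when the SS option is immediate, and the
difference vanishes once perceived time replaces objective time in the
model.

## Worked example

```python
from delaydisc import cohort, inference, perception, stats

pos, neu = cohort.paper_scenario(n_per_group=31)   # shared subjective k, alpha 2:1
people = cohort.sample_cohort(pos, neu, seed=1)
data = cohort.simulate_study1(people, seed=1, time_basis="subjective")

fit = inference.fit_hierarchical(
    data["choices"][data["choices"].group == "positive"],
    inference.DiscountModelSpec(k_structure="split_by_condition"),
    inference.McmcConfig(n_chains=4, n_samples_per_chain=1000, n_warmup=1000, seed=1),
)
k = inference.extract_k_estimates(fit)             # posterior-mean k per person/condition
```

Running the numbered drivers in `analysis/` on this default cohort
(seed 1) prints, among others:

```
positive: WAIC split 2085.3 vs joint 2403.9 (delta 318.6)
neutral:  WAIC split 2104.0 vs joint 2332.8 (delta 228.8)

objective k cell means      immediate  non_immediate
  positive                   0.083      0.008
  neutral                    0.042      0.006
group:condition interaction  F(1,60) = 12.67, p = 0.0007

alpha (time contraction)    group effect F(1,60) = 49.37, p < 1e-8
subjective-basis k          group effect F(1,60) = 0.47,  p = 0.50

first_attention             chi2(1) = 20.18, p < 0.0001, r = 0.42
```

Read: the split-by-condition model wins decisively in both groups; on
objective time the positive group discounts the immediate option about
twice as steeply (0.083 vs 0.042 per day) while the non-immediate
condition barely separates; the positive group's time contraction α is
roughly double; and once subjective time enters the model the group
difference in k is gone — the disjunction effect, carried by time
perception. In the larger second-study sample the positive group also
attends to the delay attribute first far more often (r ≈ 0.42).

The same chain is available as one command:

```
delaydisc reproduce --seed 1 --out results/run1     # or: simulate / fit / perceive / stats
```

## Layout

```
src/delaydisc/      task_engine, cohort, inference, perception, stats,
                    pipeline, io, cli
analysis/           01_simulate_cohort ... 05_study2_choice_and_attention
tests/              unit + property + acceptance suites
docs/methods.md     model, calibration, numerical choices, limitations
```
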