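# Methods

`delaydisc` implements, end to end, a computational analysis of how
incidental affect changes intertemporal choice (IC): adaptive titration of
choices between a smaller-sooner (SS) and a larger-later (LL) reward,
hierarchical Bayesian estimation of hyperbolic discount rates split by
delay condition, power-law modelling of subjective time, refitting of the
discount model on subjective durations, and the group-level frequentist
statistics. Because no participant-level data are public for this design,
the package ships a synthetic-cohort generator whose defaults encode the
study conditions; every downstream stage is tested against the generator's
known truth.

## Task model

**Staircase titration.** Each block fixes the LL reward at CNY 200 (delay 7,
15, 30, 80 or 140 days in the *immediate* condition; everything shifted 15
days later in the *non-immediate* condition, so the SS option sits at 15
days instead of today). The SS amount starts at CNY 100 inside the interval
[0, 200]; an LL choice raises the interval's lower bound to the current SS
amount, an SS choice lowers the upper bound, and the next SS amount is the
interval midpoint. The block stops when the interval is ≤ 5 CNY wide, which
from width 200 always takes exactly six responses (width halves each
trial: 100, 50, 25, 12.5, 6.25, 3.125). The behavioral indifference point
is defined as the midpoint of the terminal interval — the estimator is not
dictated by the procedure itself; the midpoint minimizes worst-case error
and is within the terminal width of any deterministic threshold. SS amounts
are kept as exact binary fractions so traces are reproducible bit for bit.
A practice block can be generated but is flagged and excluded from analysis.

**Fixed battery.** The second study replaces titration with ten preset
pairs per condition (LL CNY 200 at 85 or 105 days; SS rewards 100–194 CNY,
taken as ten equally spaced integers: 100, 110, …, 194 — the design states
only the range and count). The dependent variable is the proportion of SS
choices. The attribute-attention probe presents four masked boxes (shorter
delay, longer delay, smaller reward, larger reward); the *full* condition
classifies the first-opened attribute (delay vs reward), the *constrained*
condition forces a choice of exactly three boxes and classifies the
majority attribute.

## Discounting model

Present value is hyperbolic, V = A / (1 + k·t), with k a per-day discount
rate. Choices follow a logistic (softmax) rule,
P(LL) = 1 / (1 + exp(−τ·(V_LL − V_SS))), with participant-level inverse
temperature τ on the CNY value-difference scale. Participant parameters are
partially pooled within a group:

    log k_i[,c] ~ Normal(μ_k[c], σ_k)    log τ_i ~ Normal(μ_τ, σ_τ)

The *joint* structure gives each participant one k; the *split* structure
one k per delay condition. Groups are fitted separately (the analysis
pattern reports one model comparison per group). Hyper-priors are weakly
informative and configurable: μ_k ~ Normal(log 0.05, 1.5²),
μ_τ ~ Normal(0, 1), half-normal(1) scales. Under the *subjective* time
basis every delay t in the likelihood is replaced by the perceived duration
T = α̂·t^β̂ from that participant-condition's perception fit (t = 0 maps to
T = 0).

**Sampling.** The posterior is explored with an adaptive
Metropolis-within-Gibbs scheme written for this model: participant-level
parameters are updated by vectorized random-walk Metropolis (participants
are conditionally independent given the hypers), hyper-means by exact
conjugate Gibbs draws, hyper-scales by random-walk Metropolis on the log
scale, plus a parameter-expansion move that rescales a hyper-scale jointly
with its residuals — this breaks the funnel that otherwise slows mixing for
participants whose temperature is weakly identified (e.g. near-deterministic
responders). Proposal scales adapt toward 0.44 acceptance during warm-up
and are frozen afterwards. The default geometry is 4 chains × 1,000
retained draws after 1,000 warm-up iterations; a reduced profile
(4 × 500/500) is used in tests. Convergence is assessed per parameter with
the classic (unsplit) Gelman–Rubin factor, R̂ = sqrt(Var⁺/W) with
Var⁺ = ((n−1)/n)·W + B/n; any R̂ ≥ 1.1 flags the fit (and, in the strict
pipeline, aborts the report). Model comparison uses WAIC computed from the
pointwise log-likelihood matrix — lppd via log-mean-exp over draws,
penalty p_WAIC as the per-observation posterior variance of the
log-likelihood (S−1 denominator), WAIC = −2(lppd − p_WAIC) — with the
lower-is-better rule and ΔWAIC > 10 treated as decisive. Point estimates
passed downstream are posterior means of k (per condition for split fits).

## Time perception

Line-scale judgments (a 28.5 cm line; "extremely short" to "extremely
long") are converted to subjective days by anchoring: T = 7·L / L̄_week,
where L̄_week is the mean one-week line length across the cohort (default)
or within the participant (sensitivity option). The wording of the source
procedure is ambiguous between the two; both are implemented and
cohort-mean anchoring — being scale-free under common rescaling of all
lengths — is the default. The power law T = α·t^β is then fitted per
participant and condition by OLS on log T = log α + β·log t, the natural
estimator under multiplicative (Weber-like) judgment noise; nonlinear least
squares is available as an option and agrees on noiseless data. Zero-length
judgments are dropped with a logged warning; fits require ≥ 3 usable points.
Condition membership of the nine measured durations follows the batteries:
immediate fits use {7, 15, 30, 80, 140}, non-immediate fits
{15, 22, 30, 45, 95, 155} (the 15-day duration serves both, as it appears
in both conditions' option sets); their union is the nine durations in
7–160 days.

## Group statistics

The 2 (group, between) × 2 (condition, within) design is analyzed with a
split-plot ANOVA coded directly from the sums-of-squares decomposition:
between-subjects error = subjects within groups; within-subjects error =
condition × subjects within groups; unequal group sizes are supported
(error df = N − 2). Partial η² (SS_eff / (SS_eff + SS_err)) is reported
alongside classic η². Post-hoc simple effects compare groups within each
condition with Bonferroni adjustment (m = 2) and adjusted-coverage CIs.
Two-sample t-tests report Cohen's d on the pooled SD (so
d = t·sqrt(1/n₁ + 1/n₂) for the student variant); a Welch variant is
available, auto-selected on a Levene pre-check only when requested.
Contingency analyses use the uncorrected Pearson chi-square on 2×2 counts
with effect size r = sqrt(χ²/N) — the uncorrected statistic is what makes
printed χ²/r pairs internally consistent.

## Synthetic cohorts

Each participant carries per-condition log discount rates (bivariate normal
with configurable within-participant correlation, default 0.7), a log
temperature, power-law perception parameters α (truncated to (0, 10]) and
β (truncated to (0, 2]), and two attention propensities. Judgments are
generated as L = (anchor/7)·α·t^β·exp(ε), ε ~ Normal(0, 0.2), clipped to
the physical line [0, 28.5 cm]; attention outcomes are independent
Bernoulli draws. Temperature hyper-parameters are shared between groups.

Two scenarios are provided. The **mechanistic scenario** (default) gives
both groups one common subjective-time discount rate
(μ_log k = −1.46 per subjective day) and carries the whole group difference
in α: 2.0 (positive) vs 1.0 (neutral), with β ≈ 0.4 in both. Fitted on
objective delays this produces immediate-condition discount rates near
0.08 vs 0.04 per day and a group × condition interaction; refitted on
subjective durations the group difference disappears — the disjunction
pattern arises from time perception alone. The calibration follows from
k_obj ≈ k_subj·α·t^(β−1) averaged over the immediate-condition delays; β
is kept near 0.4 because the 28.5 cm line and the 155-day maximum duration
jointly force β ≲ 0.5 if judgments are to stay on the scale (steeper
curves saturate the line and censor the perception fits). The **direct-k
scenario** instead injects the differences straight into objective rates
(immediate 0.08 vs 0.04; non-immediate 0.045 in both groups) and is used
for parameter- and model-recovery testing. Attention propensities
(first-attended: 0.79 vs 0.38; majority: 0.71 vs 0.49) are set so the 2×2
chi-squares have expected effect sizes r ≈ 0.41 and r ≈ 0.22 at N = 115.

**What the generator does not emulate.** Real response times, trial order
and fatigue, affect induction itself (group labels are taken as given),
within-session drift, and any misfit of the hyperbolic/softmax family. A
passing recovery suite therefore shows that the estimators are correct and
well calibrated under the assumed generative family at the study's sample
sizes — not that the substantive conclusions hold for new empirical data.

## Numerical choices and known limitations

- Likelihood evaluations use the stable −softplus form; WAIC uses
  log-sum-exp. The WAIC penalty uses the variance form. R̂ is computed
  without chain splitting (callers may pre-split).
- Reproducibility: every stochastic step takes an explicit seed;
  per-participant streams are derived via CRC32-stable SeedSequence keys,
  so cohorts and fits are bit-reproducible across processes.
- Problem sizes: recovery and model-comparison suites run 16 participants
  per group at the reduced MCMC profile; the analysis scripts run the full
  31 (+57/58) cohorts at 4 × 1,000. These sizes give stable diagnostics
  while keeping the whole suite quick to run.
- Perception estimates enter the subjective-basis refit as plug-in values;
  their sampling noise is not propagated. This errors-in-variables step can
  induce a small spurious *condition* effect in subjective-basis discount
  rates (detectable in a minority of seeds at n = 31 per group) even though
  the group effect — the quantity of scientific interest — reliably
  disappears. Fitting with the true generating α, β removes the artifact
  entirely, confirming its origin.
- Line saturation: judgments clip at 28.5 cm, censoring extreme
  contraction/duration combinations (< 1% of judgments at default
  settings). High-α cohorts would be biased; the generator defaults avoid
  that regime.
- The fixed battery's SS rewards (half the LL reward and up) make SS
  choices common; immediate-condition proportions run near ceiling in the
  default scenario. Orderings (positive > neutral, immediate >
  non-immediate) are the tested pattern, not the absolute proportions.
- The staircase quantizes each block's information to the terminal 3.125
  CNY interval; participant-level k estimates inherit that resolution.
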