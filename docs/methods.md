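# Methods

## The race model and its exact likelihood

A CombiTVA display shows up to six letters in six fixed placeholders,
three per hemifield.  The model assumes every displayed item races for
encoding with an independent exponential finishing time; item *x*'s rate
is `v_x = C · w_x / Σ w`, so the rates always sum to the total processing
rate *C*.  Attentional weights factor into a hemifield share (*w_index*
to the left side, `1 − w_index` to the right, split equally among the
displayed items of that side) and a role factor (1 for targets, *α* for
distractors).  Sensory-evidence and bias terms of the general theory are
not separately identifiable from report scores and are absorbed into *C*
and the relative weights; only the five printed parameters are estimated.

Encoding is capacity-limited: with trial capacity *k*, the encoded set is
the first min(*k*, #finishers) items to finish within the effective
exposure `τ = max(0, t − t0)/1000` seconds.  Capacity varies across
trials with distribution *pK* on {1, …, 6}; there is no K = 0 state.
Reported letters are exactly the encoded targets — encoded distractors
occupy VSTM but are never reported, and the fitted model contains no
guessing process (guessing lives only in the generator, below).

Two event classes partition the outcome space for each *k*:

* fewer than *k* items finish: `P(exactly S finishes by τ)`
  `= Π_{x∈S}(1 − e^{−v_x τ}) · Π_{y∉S} e^{−v_y τ}`;
* the first *k* finishers are the set S and the k-th finishes by τ.
  Conditioning on the minimum `U ~ Exp(R_out)` of the items outside S
  (`R_out = Σ_{y∉S} v_y`) and expanding the CDF of `max_S` by
  inclusion–exclusion gives the closed form
  `P = Σ_{∅≠B⊆S} (−1)^{|B|+1} V_B/(V_B+R_out) · (1 − e^{−(V_B+R_out)τ})`
  with `V_B = Σ_{x∈B} v_x`.

This closed form needs no partial-fraction expansion, so tied rates — the
common case, since items within a hemifield share a weight — cost nothing
in accuracy; it also vectorises over the six exposure durations, which is
what makes full maximum-likelihood fitting fast (one likelihood
evaluation ≈ 0.3 ms).  The test suite cross-checks it against two
independent oracles: a per-ordering sum using the hypoexponential CDF
computed via the matrix exponential of the bidiagonal stage-rate
generator, and a 200,000-draw Monte-Carlo race simulator.  Items with
zero rate (e.g. distractors at α = 0) are removed from the subset
machinery before computation, so their encoding probability is exactly
zero rather than zero up to rounding.

## The sufficient statistic and the fit

Because all trials of a (display type, exposure) condition share one
display geometry, the per-condition counts of the report score are a
sufficient statistic of the session likelihood.  The score is kept
resolved by hemifield — the joint (#correct-left, #correct-right) — for
an identifiability reason: the total-score distribution of a
left/right-balanced display is invariant under mirroring the spatial bias
(`w_index ↔ 1 − w_index`), so total scores alone cannot identify the
sign, and barely the magnitude, of *w_index*.  The joint hemifield counts
restore full identifiability while remaining a sufficient statistic.

The 9 free degrees of freedom (5 for *pK*, plus *C*, t₀, *w_index*, *α*)
are optimised on an unconstrained scale: softmax for *pK* with the K = 6
logit pinned at zero, log for *C*, scaled logits for t₀ within its bounds
(default [0, 100] ms; whether t₀ may go negative is an open choice in the
literature and the lower bound is configurable), for *w_index* in [0, 1]
and for *α* in [0, alpha_max] (default 1).  L-BFGS-B runs from a fixed
ten-point Latin-style start grid spanning E[K] ∈ [2, 5], C ∈ [30, 90],
t₀ ∈ [5, 40], w ∈ [0.4, 0.6], α ∈ [0.2, 0.9]; starts after the first get
a small seeded jitter (SD 0.05 on the unconstrained scale), so a fit is
deterministic given (data, config, seed).  Convergence uses a relative
objective tolerance of 1e-8 with at most 2,000 evaluations per start; if
no start reports convergence the best incumbent is still returned,
flagged.  Probabilities are floored at 1e-12 inside the log so
guess-inflated scores the model assigns ~zero probability keep the
objective finite.

Goodness of fit compares observed and predicted mean scores over the 18
conditions: `rmse = sqrt(Σ_c (obs_c − pred_c)²/18)`, the Pearson
correlation, and its square as `r_squared`.  Because
"variance accounted for" is ambiguous between the squared correlation and
`1 − SS_res/SS_tot`, both are reported (`r_squared`, `r_squared_vaf`);
the squared correlation is the default headline value, consistent with a
separately reported Pearson r.

## CPT indices

Responses later than the 1 s window count as no-response.  d′ uses the
equal-variance Gaussian model, `Φ⁻¹(H) − Φ⁻¹(FA)`, with a log-linear
correction by default (+0.5 to each count, +1 to each denominator) so
ceiling and floor rates stay finite — standard practice where the
original computation is underspecified; the uncorrected estimator is
available.  d′-change splits the session at the midpoint by trial index
(90/90 in the 180-trial design; a time-based split would be uneven under
the jittered ISI) and reports `100·(d′₂ − d′₁)/d′₁`, signed, positive =
improvement.  RT-SD is the sample SD of hit reaction times only —
false-alarm RTs are excluded.  The false-alarm rate divides by distractor
trials (not all trials), for both task variants.

## What the generators emulate

**CombiTVA.**  The default session is the full 3 × 6 crossing of display
type and exposure with 18 repetitions (324 trials in 9 blocks of 36),
shuffled — the stated design properties (random order, equal duration
distribution) leave the joint allocation open, and the crossing is the
configurable default.  Target placement is balanced, one target per
hemifield in two-target displays (partial report adds 2 + 2 distractors);
this is what makes the condition cell a single geometry and the count
table sufficient.  Letters are drawn without replacement from the
20-letter alphabet.  Each trial draws `k ~ pK`, races the items, and
reports the encoded targets; with probability `guess_rate` (default 0.05,
consistent with instructed accuracy of 80–90%) one uniformly random
non-displayed letter is appended.  Guesses are never correct by
construction, so they produce the error counts the per-duration report
statistics need without perturbing the score likelihood; real sessions
could in principle contain lucky guesses, which the generator does not
emulate.

**CPT.**  An equal-variance Gaussian observer: target evidence
`N(d′_half, 1)`, distractor evidence `N(0, 1)`, respond iff evidence
exceeds a fixed criterion (default 1.0, unbiased for d′ = 2).  Hit RTs
come from a lognormal (median 450 ms, log-SD 0.25) truncated to the
window by inverse-CDF sampling; the analysis consumes only RT-SD, so any
positive seeded RT model would do.  Distractor subtypes (colour-similar,
shape-similar, unrelated) are balanced.  The generator does not emulate
sequential dependencies, lapses of responding, or RT–difficulty coupling.

**Cohorts.**  125 participants by default (DBH 444 G/A groups A/A 42,
G/A 36, G/G 47; COMT Val158Met groups Val/Val 42, Val/Met 40, Met/Met 43),
genotypes paired by a seeded shuffle.  Individual parameters are base
values (E[K] 3.5 ± 0.5, C 50 ± 8 letters/s, t₀ 16 ± 8 ms, w 0.5 ± 0.03,
α 0.4 ± 0.10, d′ 2.0 ± 0.25; mean ± between-subject SD) plus additive
genotype deltas, clipped to bounds.  The per-subject *pK* comes from a
one-parameter binomial family, `K = 1 + Binomial(5, (E[K]−1)/5)`.  The
injected-effect scenario (`CohortConfig.with_effects()`) applies
−2.5 ms t₀ per Val allele — about a quarter of the between-subject SD per
allele, a realistic single-SNP effect that is nonetheless sign-detectable
at n = 125 — and a +20% second-half d′ gain for DBH heterozygotes, the
heterozygote-advantage pattern.  Effect defaults of the plain config are
zero (a null cohort).  Child seeds derive from the master seed, so
cohorts are byte-identical across re-runs.

The group-analysis suites take the TVA measures from the generator truth
table (between-subject variation only) and the CPT measures from the
actually generated sessions.  This decouples the statistical stage's
calibration from fit runtime; the fit's estimation error is covered
separately by the parameter-recovery suite.  Consequently the calibration
results say nothing about bias introduced by TVA estimation error — at
324 trials that error is small (median |Δt₀| ≈ 1 ms) and approximately
symmetric, but it is not in the calibration loop.

## Statistical stage

Genotypes enter the regression as numeric allele doses (COMT: Val count
0/1/2; DBH: G count 0/1/2) — a single coefficient per gene; step 1 fits
both doses, step 2 adds their product.  "Stepwise" here means nested OLS
fits; no automated variable deletion.  The mixed-design Genotype × Half
ANOVA exploits the two-level within factor: its interaction F equals the
between-group F of an (AN)COVA on per-subject half differences, which is
how it is computed (the other genotype's dose enters as a covariate);
partial η² = SS_effect/(SS_effect + SS_error).  The test suite verifies
the equivalence against an independent mixed-ANOVA implementation.
Post-hoc t-tests are pooled-variance by default (df = n₁ + n₂ − 2; Welch
optional), with Bonferroni-corrected α = α/m (displayed to 3 decimals).
The linear trend contrast uses weights (−1, 0, +1) on the dose-ordered
group means against the pooled within-group error with df = (1, N − 3).
If the half differences have exactly zero variance the interaction is
reported as F = 0, p = 1 rather than 0/0.

## Problem sizes and numerical checks

The validation suites run at these sizes: oracle equivalence with 200,000
Monte-Carlo races per setting (5 settings spanning display types and
binding/slack capacity, tolerance max |Δp| < 0.005); parameter recovery
with 20 simulated participants × 324 trials at the default conditions;
the SDT round trip over 100 sessions (per-half d′ within ±0.25); null
calibration over 500 reduced-size cohorts (20 per genotype level,
Kolmogorov–Smirnov uniformity at the 0.01 level); and power/direction
checks over 40 full-size cohorts.  Exact distributions are validated to
sum to 1 within 1e-8; the closed form agrees with the per-ordering
hypoexponential oracle to 1e-10.

## Known limitations

* No letter-confusion structure: a reported letter is either a displayed
  target or an intrusion; perceptual confusions between visually similar
  letters are not modelled.
* *C* is exposure-independent and mask interruption is reduced to the
  effective-exposure cutoff.
* Distractors are assumed never reported (they differ from targets by
  colour); the α > 0 case only lets them occupy capacity.
* No hierarchical pooling across participants and no bootstrap or
  profile-likelihood uncertainty on the fitted parameters.
* The two-half d′-change summarises time-on-task; no finer vigilance
  time-series is modelled.
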