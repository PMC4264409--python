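# Methods

`cuemem` models memory retrieval during sentence comprehension as
feature-based cue redintegration, and packages everything needed to study
that model end to end: the retrieval arithmetic itself, an
encoding-interference extension for noun phrases, a synthetic
self-paced-reading (SPR) generator whose retrieval effects come from the
model, and the standard SPR preprocessing and hierarchical Bayesian
inference chain. This note records the model assumptions, the parameter
choices and their rationale, the numerical decisions, and what the
synthetic studies do and do not establish.

## 1. The retrieval model

Memory items are ordered vectors of symbolic features, e.g.
`[C C 2 3 1]`. A retrieval probe `X` is compared slot by slot against
every candidate trace `E_i`:

- distance `d(X, E_i)` = number of mismatching features / number of
  compared features, so `d ∈ [0, 1]`;
- similarity `s(X, E_i) = exp(-d)`, so `s ∈ [e^-1, 1]`;
- sampling probability `Pr(E_i | X) = s(X, E_i) / Σ_j s(X, E_j)`
  (a Luce choice ratio).

Two asymmetries define "compared features":

- **The probe sets the denominator.** Comparison runs over the probe's
  slots only: a probe slot with no counterpart in a candidate counts as a
  mismatch, while candidate features beyond the probe's length are
  ignored. Slot-aligned comparison (not set overlap) is essential — set
  overlap would score the permuted competitor `[C C 3 1 2]` as identical
  to the probe `[C C 2 3 1]`.
- **Wildcard policy.** A `"?"` probe slot marks a degraded (blurry) cue.
  By default it counts as a mismatch against everything, so similarity
  degrades monotonically as a probe blurs; an alternative policy excludes
  the slot from the comparison (shrinking the denominator). The choice is
  an argument on every distance/similarity function because neither
  convention is forced by the theory; only probes, never stored traces,
  may carry `"?"`.

**Printed-table convention.** `printed_table` reports similarities rounded
to 2 d.p. and probabilities normalized *from those rounded similarities* —
the convention worked similarity tables are typeset with. The two differ
visibly in the elaborated reference scenario: the exact target probability
is `1/(1 + 2 e^{-6/8}) = 0.514`, while normalizing the rounded
similarities gives `1/(1 + 2 · 0.47) = 0.515 → 0.52`. All computation in
the package uses the exact `sampling_probabilities`; `printed_table`
exists so published tables can be checked cell for cell.

**Sweeps.** `distinctiveness_sweep` and `competitor_sweep` evaluate the
target's sampling probability on grids of `m` (probe features shared with
every competitor), `u` (features unique to the target) and `n`
(competitor count). Under slot-aligned comparison each grid point is
deterministic — the target's probability is
`1 / (1 + n · exp(-u/(m+u)))` — so the tables hold exact values with no
averaging. Closed-form consequences used as test oracles: `u = 0` gives
`1/(n+1)`; the two-competitor curve asymptotes at `1/(1 + 2e^{-1}) ≈
0.576` as `u → ∞`; the curve is increasing and concave in `u`; and with
two competitors the `m = 2` and `m = 10` curves never differ by more than
about 0.094 — shared-feature count matters far less than competitor
count, which halves retrieval probability from one to three competitors.
Default grids are `m ∈ {2..10}`, `u ∈ {0..20}`, `n ∈ {1..10}`,
configurable via `SweepSpec`.

## 2. Noun phrases, encoding interference, condition predictions

`encode_np` maps a noun phrase to a vector: `base_form_features` shared
syntactic-frame tokens (default 2, identical across all NPs), one unique
head-noun token, and `features_per_modifier` unique semantic tokens per
prenominal modifier (default 1). These counts are conventions, not
measurements; the qualitative predictions below hold across a wide range
of them (the tests exercise the defaults; the granularity is exposed in
`EncodingConfig`).

**Feature overwriting.** Encoding interference is modelled as loss of
binding between shared form features and individual traces. For every
pair of NPs that *match in form* — operationalised as having the same
modifier count, hence the same syntactic frame — each shared form feature
is lost in each member of the pair independently with probability
`overwrite_probability` (default 0.3). Keeping base form tokens identical
across all NPs while gating overwriting on full form match preserves an
exact invariance: with overwriting off, a non-target's elaboration cannot
change the target's sampling probability at all, because non-target
features beyond the probe's length never enter the comparison.

**The retrieval scenario.** At the retrieval site the probe is the
feature specification of the target's *original* encoding (the
subcategorising verb itself contributes no form cues). The target
candidate is its current, degraded trace: every slot whose binding was
captured by a neighbour mismatches its own cues. Competitors enter with
their form match to the probe intact: an overwritten shared feature is
misbound, not erased — some form-matched trace still carries it — so
losing it to a neighbour does not make a competitor less confusable with
the probe's shared form cues. This asymmetry is a substantive modelling
choice, and the decisive one: if degradation is instead placed in the
probe (or competitors' losses are scored as probe mismatches), the lost
slots either cancel in the Luce ratio — shared features mismatch every
candidate equally — or actively help the target by weakening competitors,
and encoding interference then has no effect or the wrong sign. Only
trace-side target degradation yields the observed phenomenology:
elaborating a *non-target* helps retrieval exactly when the target is
simple (it removes one source of overwriting), and never when the target
is already elaborated.

With the defaults (`p = 0.3`), the per-condition target sampling
probabilities for the 2×2 complexity design are approximately:
simple–simple 0.334, complex–simple 0.365, complex–complex 0.447,
simple–complex 0.477 (condition labels are NP1–NP2; exact values by
enumeration, reproduced by the Monte-Carlo in `predict_conditions`, which
reports a Monte-Carlo SE over `n_reps` replicates, default 10,000). No
constraint is imposed on complex–complex relative to the singly-complex
conditions; that ordering is sensitive to the granularity conventions.

## 3. The synthetic SPR generator

`generate_exp1` emulates a 2×2 complexity experiment: 52 participants ×
28 items in a four-list Latin square, 70 structure-free filler trials,
word-by-word presentation. Per word,

```
log RT = μ + β_len·length + β_pos·log(position) + participant/item
         random effects + region offset + encoding cost + retrieval cost + ε
```

exponentiated to milliseconds. Defaults, all on the natural-log-ms scale:

| parameter | default | rationale |
|---|---|---|
| `mu_log_rt` | 5.75 | ≈ 314 ms per word, typical SPR pace |
| `beta_length` | 0.02/char | standard length slowdown |
| `beta_logpos` | −0.04 | practice speed-up over the session |
| `sd_participant_intercept` | 0.15 | large between-reader rate differences |
| `sd_participant_slope`, `sd_item_slope` | 0.02, 0.01 | modest effect heterogeneity |
| `sd_item_intercept` | 0.05 | item difficulty |
| `sd_residual` | 0.22 | within the 0.2–0.35 range typical of log SPR RTs |
| `encoding_cost` | 0.04 per extra target feature | ≈ +0.08 at a doubly-modified NP head |
| `kappa` | 0.28 | see below |
| `carryover` | 1.0 | the spillover effect is empirically as strong as at the verb |
| `contamination_rate` | 0.001 | matches the ~0.1% of words removed by trimming |
| `accuracy` | 0.84 | overall comprehension accuracy emulated |

**Retrieval linkage.** The cost at the embedded verb is surprisal-style,
`kappa · (−log p_target)`, with `p_target` taken per condition from
`predict_conditions` — monotone in retrieval difficulty and unbounded as
the sampling probability vanishes. With the interference defaults the
spread of `−log p_target` implies a sum-coded NP2-complexity coefficient
of about −0.039 at the verb, at the top of the few-hundredths band such
analyses report. That size, together with `sd_residual = 0.22`, makes the
effect reliably detectable in the package's own 20-participant
simulation studies while leaving the NP1 main effect (generated with no
direct reading-time term) undetected — the regime the model is meant to
occupy.

`generate_exp2` emulates a 2×2 colour-congruence design (44 participants,
32 items, 60 fillers, textually identical conditions): an incongruently
coloured noun adds `noun_color_cost` (0.08) at the noun, an incongruent
verb adds `verb_color_cost` (0.06) at the verb, and — reflecting the null
finding this design probes — noun colour has *no* effect at the verb
unless the optional `reinstatement` interaction (default 0) is enabled.

**What the generator does not emulate:** real lexical material (words are
random letter strings with plausible lengths), sentence-final wrap-up,
fatigue or speed–accuracy coupling (question accuracy is independent
Bernoulli by default), correlations among random effects, and any
dependence of later trials on feedback. Passing recovery tests on these
data therefore shows the pipeline is correct and well calibrated under
the generating model, not that real reading times satisfy that model.

## 4. The analysis pipeline

1. **Trimming**: raw RTs outside [100, 5000] ms are removed (defaults of
   `TrimRule`); the removed fraction is reported. No accuracy-based
   exclusion — failed retrievals are data.
2. **Residualization**: log RT is regressed on word length and log list
   position with by-participant intercept adjustments, fit on all trials
   *including fillers*; the residuals are the dependent variable
   downstream. Two estimators: `"mixed"` (random intercepts with
   shrinkage, via REML; the default) and `"fixed"` (one dummy per
   participant, exact zero-mean residuals). With hundreds of words per
   participant the two agree to well under 1% relative RMSE; the tests
   enforce this. Intercept-only adjustment is deliberate; by-participant
   nuisance *slopes* are not modelled.
3. **Sum coding**: two-level factors map to ±1 with the elaborated /
   incongruent level (`complex`, `green`) coded +1, so facilitation
   appears as a negative coefficient and P(β < 0) reads as evidence for
   speed-up. Interactions are products of main-effect columns. Factors
   with more than two levels are rejected.
4. **Region fits**: residual log RT at one region is modelled with fixed
   effects for the two factors and their interaction, and by-participant
   and by-item random intercepts plus random slopes for all three fixed
   effects. Each region is fit independently; no multiplicity correction
   is applied across regions or effects.

**Sampler.** The hierarchical model is estimated by a blocked Gibbs
sampler written for this package: all location parameters (fixed effects
and every random effect) are drawn jointly from their exact Gaussian full
conditional given the variances — eliminating the fixed-effect/random-mean
autocorrelation that cripples one-at-a-time updates — followed by
conjugate inverse-gamma updates of the residual and random-effect
variances. Random-effect columns are independent within each grouping
factor (a diagonal covariance, as in `lme4`'s `||` syntax); modelling
random-effect correlations is out of scope. Priors: Normal(0, 1) on each
fixed effect (the response is residual log RT, magnitudes ≪ 1),
InvGamma(0.01, 0.01) on the residual variance, InvGamma(0.5, 0.005) on
each random-effect variance — weakly informative on this scale, and
conjugate, which is what makes the exact joint location draw possible.
All priors are configurable via `Priors`.

Defaults are 4 chains × 5000 iterations with 2500 warm-up;
`RegressionSpec.scaled_down()` (2 × 1000, 500 warm-up) is used in
simulation studies and the examples. Because location draws are exact
joint samples, effective sample sizes are close to the number of kept
draws. Every fit reports split-R̂ and bulk ESS (via `arviz`) per fixed
effect; a fit with any R̂ ≥ 1.01 or ESS ≤ 400 is flagged `converged =
False` (with a warning) but still returned. P(β < 0) is the fraction of
posterior draws below zero. Fixed data plus a fixed sampler seed give
bit-identical draws; independent seeds agree on P(β < 0) to within ±0.02
at the scaled-down settings.

**Covariate check.** `covariate_check` refits a region with the previous
region's residual log RT as a centred fixed covariate (random slopes are
kept for the factorial terms only). A constant covariate is dropped with
a warning, making the fit identical to the plain one. Pure spillover
attenuates P(β < 0) toward 0.5 under this check; a genuine region effect
survives.

## 5. Simulation-study sizes and numerical conventions

The package's own recovery and calibration studies use deliberately
modest problem sizes: power is assessed on 50 replicate 20-participant
experiments at default effect sizes (detection criterion
P(β_NP2 < 0) > 0.95 at the verb, required in ≥ 80% of replicates), and
null calibration on 100 replicate 12-participant × 16-item experiments
with all effects at zero (two-sided 0.025/0.975 tail rate compatible with
5%, posterior sign probabilities approximately uniform), both with the
scaled-down sampler. These sizes give stable pass/fail behaviour from
the binomial arithmetic while keeping a full run of the suite short.

Other conventions: probability normalization is checked to 1e-12;
monotonicity and concavity of the sweeps to 1e-12 slack; the Monte-Carlo
tolerance on interference expectations is ±0.01 at 10,000 replicates;
equality claims ("exactly invariant", "byte-identical CSV") are asserted
exactly. Degenerate inputs fail loudly: empty probes, all-wildcard
probes under the exclude policy, single-participant or
constant-predictor residualizations, unknown regions, >2-level factors.

## 6. Known limitations

- Feature vectors are symbolic and unweighted; no continuous similarity,
  no learning of features from text.
- The form-match gate for overwriting is binary (same modifier count);
  graded structural similarity is not modelled.
- The misbinding asymmetry of §2 is a modelling commitment, supported
  here by the phenomenology it reproduces rather than by direct evidence.
- The generator's retrieval linkage (`kappa·(−log p)`) is one convenient
  monotone choice; the theory constrains only the direction.
- Posterior inference assumes the diagonal random-effect structure; with
  strongly correlated slopes the reported intervals would understate
  uncertainty.
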