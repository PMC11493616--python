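# Methods

This note documents the models behind `aphidcascade`, the calibration of
the synthetic-data generators, and the numerical and design choices that
were genuinely open.

## Age-stage two-sex life table

A birth cohort of *Aphis gossypii* is tracked daily from birth to death.
With age `x` in days (age 0 = day of birth) and stage `j` in the pooled
set {nymph, adult}, the cohort tallies give

* `s_xj` — the probability a newborn is alive and in stage `j` at age `x`,
* `f_xj` — mean offspring per stage-`j` individual at age `x`,
* `l_x = Σ_j s_xj` and `m_x = Σ_j s_xj f_xj / Σ_j s_xj`.

The growth parameters are `R0 = Σ_x l_x m_x`, the intrinsic rate `r`
solving `Σ_x exp(−r(x+1)) l_x m_x = 1`, the finite rate `λ` solving the
same equation in `λ^−(x+1)` over `Σ_j f_xj s_xj`, and `T = ln(R0)/r`.
The `(x+1)` exponent is deliberate: reproduction observed on day `x` is
credited at the end of that day, the convention used by the dedicated
two-sex life-table software this module re-implements.  Cotton aphids
are parthenogenetic, so the cohort is all-female and the two-sex
bookkeeping degenerates gracefully; pre-adult deaths stay in `s_xj` as
zero-fecundity survival mass.

Numerics: the Euler–Lotka left side is strictly decreasing in `r`
(`λ`), so the root is unique.  We bracket on `r ∈ [−5, 5]` per day
(widened automatically) and solve by Brent's method to machine
precision, rejecting any solution whose residual exceeds 1e−10.
Bisection-style bracketing was chosen over Newton for guaranteed
convergence on the stiff, nearly-flat tails.  `intrinsic_rate` and
`finite_rate` are two independent solvers; their agreement through
`λ = exp(r)` (within 1e−9) is a tested contract.

Standard errors are bootstrap SDs over `B = 2000` individual-level
resamples (configurable).  The source study does not state its SE
method or `B`; bootstrap is the convention of the two-sex life-table
software, so we adopt it and document the assumption.  Resamples with
`R0 = 0` have undefined parameters and are skipped with a recorded skip
count.  Inside resamples `λ` is evaluated as `exp(r)` (the two-solver
contract makes a second root search redundant); the full-cohort point
estimate is solved independently.

Group summaries define: nymph period = age at the adult molt; adult
longevity = days alive as an adult; reproductive days = number of days
with ≥ 1 offspring (the stricter reading, not the first-to-last span);
fecundity = lifetime offspring.  Each trait averages only individuals
for which it is defined; a cohort with no adults reports NaN and
`n_adult = 0`.

## Cohort generator

Per individual: nymph duration `D` and adult longevity `L` are rounded
truncated normals (≥ 1 day), lifetime fecundity `F` a rounded truncated
normal (≥ 0), a pre-adult survival Bernoulli decides death on a
uniformly chosen nymph day, and reproduction occupies the first
`R = min(R_draw, L, F)` adult days: one guaranteed offspring per
reproductive day plus the remaining `F − R` allocated multinomially
under a discretized gamma (shape 2) early-peak schedule.

Calibration choices:

* Every truncated-normal location is solved (Brent) so the *discretized,
  truncated* distribution has exactly the published treatment mean;
  reported SEs (n = 30) are converted to per-individual SDs.
* `R_draw` is additionally compensated for the `min()` against `L` and
  `F`, via `E[min] = Σ_k P(R≥k)P(L≥k)P(F≥k)`, so the expected count of
  reproductive days also sits exactly on its target.
* Pre-adult survival is not published directly; it is derived as
  `R0 / fecundity`, which equals ≈ 0.857 for every treatment — the two
  published summary tables are mutually consistent under that identity.
* The within-adult schedule shape is the one free parameter (totals and
  period lengths are pinned).  The gamma scale 0.5·R makes the control
  profile's generating schedule reproduce the published control growth
  parameters (r 0.321 vs 0.32, λ 1.378 vs 1.38, T 10.51 vs 10.59 d).

`expected_schedule` computes the exact expected `l_x` and net fecundity
of this generative process by enumerating the discrete distributions —
no Monte-Carlo error — so parameter-recovery tests compare a simulated
cohort's `r` against the generating schedule's true `r`.

What the generator does *not* emulate: instar structure (the study
reports a pooled nymph period), censoring/escape (assumed absent),
between-individual correlation of traits beyond the `min()` coupling,
and any treatment effect pathway — treatments differ only through their
calibrated marginals.  Passing tests therefore demonstrate correct
bookkeeping and solver behaviour, not biological realism of daily
fecundity trajectories.

## EPG surrogate and parameter extraction

A continuous-time semi-Markov chain over {Np, C, Pd, E1, E2, G}
replaces real waveform annotation: exponential sojourns at per-state
means, transition weights with self-transitions forbidden, start in Np,
final bout truncated at the 8-h recording end.  Only the event-log
*format* and the parameter arithmetic must match real EPG practice; the
chain has no waveform biophysics.  Per-state sojourn means and
transition weights are unpublished for this study, so the defaults are
placeholders whose stress trend (longer non-probing, shorter phloem
ingestion under heavier stress) follows the reported qualitative
contrasts.  Sojourns are floored at 2 s, and a trailing remainder
shorter than the floor is absorbed into the final bout, so every bout is
resolvable on a 1-s grid — this makes the brute-force grid-tally oracle
an exact count check and a ≤ 1 s × count duration check.

Parameters per recording: maximal-bout counts, per-waveform total
durations (they conserve the recording duration exactly), and times to
first E1/E2.  Latency is measured from recording start by default
(`latency_from="first-probe"` switches the origin to the first stylet
contact) — the study does not state its convention.  The leading
pre-probe Np bout is counted like any other maximal bout.  Recordings
without E1/E2 are excluded from latency means, not imputed at 8 h.

## Count series

The latent per-plant expectation rises logistically from the initial
infestation (5 nymphs/plant in the control) toward a carrying capacity,
then decays multiplicatively after day 35 — placing the mean peak inside
the reported 30–45-day window.  Observed counts are negative-binomial
(variance `μ + μ²/k`, default `k = 5`).  Treatment curves are
amplitude-scaled copies of the control curve, so the *population*
percent-of-control mean abundance equals the calibrated ratio exactly;
calibrated ratios are the published percentages (86, 59.6, 45.4,
19.1%).  Only the range 20.3–32.7% is published for the three mixed
treatments; the endpoints are assigned by r_m ordering (Sm_Ah 32.7,
Sh_Am 20.3) with the midpoint as a placeholder for Sm_Am.  The control
carrying capacity (400 aphids/plant) is itself a placeholder — absolute
abundances appear only in figures — so only ratios are meaningful.
Mean abundance is the grand mean over replicate × day cells; missing
cells (dead plants) are excluded, not imputed.

## Piecewise path analysis

The cascade model is a set of linked OLS regressions on standardized
variables over a DAG, with two composite predictors: *plant growth*
(leaf area, root volume) and *physiochemistry* (water potential,
tannin).  A composite is a loading-weighted sum of standardized
indicators, re-standardized; loadings are the coefficients of an OLS
regression of the composite's designated response on its indicators
(the standard piecewise-SEM construction), frozen before the structural
fits.  The default model is

    r_m       ~ plant_growth (0.820) + physiochemistry (−0.068)
    abundance ~ plant_growth (0.544) + r_m (0.408)
    plant_growth ~~ physiochemistry (r = 0.838)

with loadings 0.407/0.535 (growth, against abundance) and 0.553/−0.336
(physiochemistry, against r_m).  A structural note: these published
effects are *not* jointly representable as direct edges of a
unit-variance linear DAG (the implied explained variances exceed 1);
under the composite topology above they are exactly consistent, and the
implied population R² values — 0.584 for r_m and 0.801 for abundance —
match the published 0.58 and 0.80 to the printed precision.  That
agreement is why this topology is the package default.

Global fit uses the d-separation basis set: one claim per non-adjacent
node pair, ordered so the first element is not a descendant of the
second, conditioned on the union of both nodes' parents (correlated
pairs count as adjacent).  Claims are tested by the partial slope
t-test; p-values combine into Fisher's `C = −2 Σ ln p`, `df = 2k`, with
`p > 0.05` indicating adequate fit.  An empty basis set gives `C = 0`,
`p = 1`.  Model selection proposes removing the single least-significant
edge (largest p; ties by smaller |β|, then label) and accepts only if
`AIC = C + 2K` drops, where `K` counts fitted slopes plus intercepts
across component regressions — the study does not define `K`; this is a
documented choice.  The accepted-model AIC trace is strictly decreasing
by construction.

## Cascade generator

The generator samples the composite scores first — `p ~ N(0,1)`,
`g = ρp + √(1−ρ²)η` — and builds each indicator pair around its score by
an orthogonal-complement construction: for loadings `(w1, w2)` and an
independent disturbance `d`,

    i1 = a1·s + w2·κ·d,      i2 = a2·s − w1·κ·d,

so the loading-weighted sum `w1·i1 + w2·i2 = (w1·a1 + w2·a2)·s`
reproduces the score exactly (the disturbance cancels).  The scale
`(a1, a2, κ)` is solved (Brent) so each indicator has unit variance and
`w1·a1 + w2·a2` equals the population slope of the composite's response
on its score — which makes the population OLS regression of the
response on the *raw indicators* return exactly the calibrated
loadings.  Generation and fitting are thus mutually consistent: at
n = 10,000 every coefficient (structural paths, the composite
correlation, and all four loadings) is recovered within sampling error.
Endogenous nodes receive Gaussian noise scaled so their marginal
variance is exactly 1.  A second entry point (`gen_linear_dag`) samples
arbitrary edge-weighted DAGs with the same unit-variance convention and
rejects coefficient sets whose implied variance exceeds 1.

The generated indicator correlations are a consequence of this
construction, not a model of field covariances (e.g. tannin and water
potential come out nearly uncorrelated); the cascade table is a
statistical testbed for the fitting machinery, not a cotton dataset.

## Problem sizes

Default problem sizes used by the test suite and the acceptance script:
cohorts of 3,000–10,000 individuals for calibration checks and 20–30
for bookkeeping identities (1,000 replicate cohorts); 100 × 8-h EPG
recordings for the grid oracle; 200 replicate count series for
percent-of-control round trips; n = 10,000 for coefficient recovery and
500 replicates of n = 300 for Fisher's C calibration; B = 2,000
bootstrap resamples.  These sizes put Monte-Carlo error well inside
every asserted tolerance while keeping the default run in minutes.

## Known limitations

* Stage resolution is nymph/adult only; instar-level demography and
  age-stage reproductive value / life expectancy matrices are out of
  scope.
* No ANOVA/Tukey, GLMM, or PCA layers — those are routine off-the-shelf
  statistics; the package emits the descriptive tables they would
  consume.
* The EPG surrogate cannot test waveform classification, only the
  event-log arithmetic downstream of annotation.
* Treatment effects enter the generators only through calibrated
  marginal distributions; there is no mechanistic plant–aphid coupling.
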