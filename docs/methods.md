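# Methods

## The detection problem

Examinations assembled from a partially reused item pool are vulnerable to
*item pre-knowledge*: some students have seen (or memorised) the reused
items beforehand and score on them above their actual proficiency. Given a
binary response matrix `Y` (M students × I items) and a known per-item
exposure flag `G` (1 = reused/compromised, 0 = first-use/secure), the
package estimates, for every student, the posterior probability of
pre-knowledge, classifies students at a cut-off, calibrates the resulting
detector's sensitivity and specificity by simulation, and converts the
fraction of flagged students (apparent prevalence) into an estimate of the
true prevalence of pre-knowledge.

## The gated two-component 1-PL mixture

Each student carries two latent abilities on the logit scale: a *true
ability* θ_t and a *cheating ability* θ_c. A student is a cheater exactly
when θ_t < θ_c; the indicator T = 1{θ_t < θ_c} is deterministic given the
ability pair (this is the "deterministic gate"). Responses follow a
one-parameter logistic model with common discrimination fixed at 1,

    P(y = 1 | θ, b) = 1 / (1 + exp(−(θ − b))),

where the effective ability is θ_c only for cheaters answering exposed
items, and θ_t in the three other (T, G) combinations. Equivalently, the
success probability is the single mixture expression
`P_t^(1−T) · [(1−G) P_t + G P_c]^T`.

A note on the sign convention: sources sometimes print the 1-PL kernel with
the exponent `θ − b`, which would make ability *harmful*. The package uses
the standard increasing form throughout; a globally consistent sign flip is
isomorphic (map θ → −θ, b → −b), so nothing of substance depends on this
choice.

### Priors and estimation

The posterior of (θ_t, θ_c, b) is sampled by Metropolis-within-Gibbs with
priors

* θ_t ~ N(0, 1), b ~ N(0, 1),
* θ_c ~ N(1, 2) in mean/variance form.

The θ_c prior is deliberately informative: for honest students θ_c is
identified only through the ~20% exposed items (and, in states with
θ_t ≥ θ_c, not at all), so the prior carries real weight in the per-student
cheating probability. Because normal priors are often quoted in precision
form, `theta_c_prior_variance` is a constructor argument
(`DeterministicGatedIRT`), default 2.0; setting 0.5 reproduces the
precision-2 reading. In pilot comparisons the variance-2 reading gives a
detector whose honest false-flag rate at the design conditions (~22-24%
below, all-honest cohort) matches the published calibration at its weakest
scenario, while the precision reading collapses specificity; variance 2 is
therefore the default.

Each block (all θ_t, all θ_c, all b) is updated with vectorised
random-walk normal proposals. Per-coordinate proposal scales start at 0.5
and adapt every 50 burn-in iterations by a factor
`exp(0.5·(acceptance − 0.37))`, targeting the 30-45% acceptance band; the
scales are frozen at the end of burn-in so the retained chain satisfies
detailed balance. T is recomputed from (θ_t, θ_c) at every draw; the
per-student cheating probability `p_cheater` is the fraction of retained
draws with θ_t < θ_c. Item difficulties may instead be fixed
(`fixed_difficulty`) when items are pre-calibrated; this also makes the fit
invariant to item order and is how the sampler is validated against a dense
2-D quadrature posterior on single-student problems (agreement well within
0.02).

Chain defaults follow the reference protocol: 110,000 iterations, 10,000
burn-in, thinning by 100 (1,000 retained draws). The scenario-study runner
defaults to the desk-scale `REDUCED_CHAIN` (6,000 / 1,000 / 5), which
retains the same 1,000 draws at higher autocorrelation; on the problems in
the test suite the two give materially identical operating characteristics.
Convergence is reported (split-chain R-hat and effective sample size via
arviz, on the retained chain split in half) but not gated on: the model is
fitted with an informative prior and a deterministic gate, and no hard
convergence criterion is imposed.

### Identification and degenerate inputs

At least two secure and two exposed items are required; with no exposed
items the model is unidentified and fitting raises. All-zero or all-one
response columns are permitted — the N(0,1) prior on b regularises them.
Missing responses and polytomous items are out of scope.

## Synthetic examinations

The generator reproduces the calibration study's design, which mirrors the
motivating examination conditions:

* 200 students, 100 items, 20 exposed items (exposed positions uniform at
  random; only the count is fixed by the design);
* item difficulties and true abilities i.i.d. standard normal;
* a fixed fraction of cheaters — exactly `round(prop · M)` students, chosen
  uniformly — with prevalence levels 5, 10, 35, 70% in the presets;
* effective gain Δ ~ 3·Beta(9, 4) (high-effective, mean ≈ 2.08) or
  3·Beta(5, 5) (low-effective, mean 1.5); honest students have Δ = 0 and
  θ_c = θ_t. θ_c = θ_t + Δ, and responses are independent Bernoulli draws
  from the gated mixture.

Fixing the cheater count (rather than drawing it Bernoulli per student)
makes the true prevalence exact in every replicate, which stabilises the
sensitivity/specificity estimates; the reference design does not state
which it used. Replicate r of a scenario with master seed s draws from the
deterministic sub-stream `SeedSequence((s, r))`, so replicates are
independent but individually reproducible.

What the generator does *not* emulate: repeat test-takers, multi-year item
reuse chains, answer copying between students, item-level guessing (no 3-PL
lower asymptote), and ability-dependent gain (in real cohorts
low-ability students appear to gain more from memorisation; in the
generator Δ is independent of θ_t). Passing calibration tests therefore
demonstrate correctness of the machinery under the stated design, not
detector performance on real examinations.

## Classification and calibration

Students are flagged when `p_cheater` strictly exceeds the cut-off (default
0.90; the strict inequality is the conservative choice for honest students
at the boundary). The alternative data-driven cut-off minimises the
child-weighted binary entropy of the truth labels over all midpoints
between consecutive distinct probabilities — a depth-one classification
tree; ties are resolved towards the largest candidate, again favouring
specificity. The study runner reports both the per-replicate cut-off
distribution and a pooled cut-off computed on all replicates'
(probability, truth) pairs, since a single per-scenario value is wanted and
pooling is the stabler choice.

Confusion metrics per replicate: sensitivity, specificity, PPV, NPV,
absolute agreement, apparent prevalence AP = (TP+FP)/M, and Cohen's kappa
with marginal-product expected agreement. Undefined ratios (empty classes)
are NaN, never exceptions, and NaN cells are excluded from across-replicate
means. The identity AP = prev·SEN + (1−prev)·(1−SPE) holds exactly per
confusion table and is tested exactly.

### Reproduction of the published calibration table

The published study reports, at the 0.90 cut-off and over 100 replicates,
specificity rising from 77.8% (5% prevalence) to 98.0% (70%), sensitivity
from 69.8% to 90.8% (high-efficacy), and apparent prevalences of 24.5% and
64.1% at 5% and 70% true prevalence. The package's scaled-down study (15-16
replicates, reduced chain) reproduces the specificity/PPV/NPV levels and
the qualitative gradient — specificity rises with prevalence, AP strongly
overestimates a 5% prevalence and underestimates 70% under low efficacy —
but its sensitivity *decreases* with prevalence (≈82% at 5%-high, ≈75% at
70%-high), where the published table increases. This is a property of the
exact posterior, not of chain length (the full 110k-iteration chain gives
the same answer, and the sampler matches brute-force quadrature on toy
problems): under the gated likelihood, high-ability cheaters are close to
the ceiling on exposed items and carry little signal, and at high
prevalence the exposed-item difficulty estimates absorb part of the mean
gain. A variant in which exposed items are *always* modelled through θ_c
(the gate applying only to the flag, not the likelihood) shows the opposite
trade-off — it reproduces the published 70%-scenario values closely but
grossly over-flags honest students at 5% prevalence. The reference
implementation (a WinBUGS script in an unavailable supplement) evidently
differs from the model as printed in some respect that cannot be recovered
from the text; this package implements the gated mixture as specified and
reports its true operating characteristics.

## True prevalence from apparent prevalence

For a detector with known accuracy, E[AP] = TP·SEN + (1−TP)·(1−SPE).
The closed-form (Rogan-Gladen-type) estimate inverts this:
TP = (AP + SPE − 1)/(SEN + SPE − 1), truncated to [0,1], defined only for
informative detectors (SEN + SPE > 1). The Bayesian estimator places
TP ~ U(0,1), SEN ~ U(sen_bounds), SPE ~ U(spe_bounds) and
`n_flagged ~ Binomial(n, AP)`, and computes the TP marginal on a
deterministic tensor grid (default 400 midpoints per axis) — exact to grid
resolution, no Monte Carlo noise; it matches an independent sampling oracle
within 0.02 and collapses to the Beta-Binomial conjugate answer for a
perfect test. Default accuracy bounds are the minimum and maximum
across-scenario mean SEN (0.603-0.9075) and SPE (0.7782-0.98) of the
calibration study at the 0.90 cut-off; the bounds are configurable because
published summaries of the same study round them differently, and because a
user recalibrating under other conditions should derive their own.

## Psychometric descriptives and model validation

The CTT layer computes per-item difficulty (proportion correct), the
biserial discrimination of each item with its rest score (point-biserial
corrected by √(p(1−p))/φ(Φ⁻¹(p)); undefined for zero-variance items or
rest scores), and Cronbach's alpha. Category labels follow the
conventional printed ranges, interpreted upper-inclusive on the proportion
scale: difficulty [0, .30] difficult, (.30, .80] medium, (.80, 1] easy;
discrimination ≤ −.19 negative, (−.19, .19] weak, (.19, .29] sufficient,
(.29, .39] good, above very good.

The 1-PL and 2-PL logistic models are fitted by marginal maximum likelihood
with an EM algorithm: standard-normal ability integrated by 61-node
Gauss-Hermite quadrature; the M-step is a weighted logistic regression per
item solved by damped Newton steps in slope-intercept form (the 1-PL
alternates per-item intercepts with the common slope). EM stops when the
marginal log-likelihood changes by less than 1e-5 (cap 500 iterations;
non-convergence is flagged, not raised). Parameter counts are I+1 (1-PL,
common discrimination estimated) and 2I (2-PL); AIC = −2ℓ + 2k,
BIC = −2ℓ + k·ln(M). The EM optimum agrees with direct numerical
maximisation of the marginal likelihood to 1e-3 on toy data.

CHull model comparison retains the models on the upper convex hull of
(complexity, log-likelihood) and computes interior scree ratios
st = slope_in / slope_out; boundary models have no defined ratio. With
exactly two hull models the elbow is degenerate: zero-fit-gain
pseudo-endpoints assign ratio 0 to the simpler and ∞ to the better-fitting
model, so CHull then reduces to "does the extra complexity buy any fit at
all" — for nested 1-PL/2-PL pairs this favours the larger model, and the
AIC/BIC columns are the informative criteria. Published per-model CHull
values for such two-model comparisons do not correspond to any standard
formulation and are not claimed to be reproduced.

## Problem sizes used by the shipped studies

The test suite and the acceptance script run the calibration study at 15-16
replicates per scenario with the reduced chain — scenario means of
percent-scale metrics then carry a Monte-Carlo standard error of roughly
SD/√15, i.e. 0.5-4 points depending on the metric — and validate the
sampler, cut-off search and prevalence estimators against independent
oracles at small sizes where those oracles are exact. The full published
protocol (100 replicates, 110k-iteration chains) is available through the
same interfaces (`ScenarioConfig(n_replicates=100)`, `PAPER_CHAIN`).

## Known limitations

* The detector's specificity is prior-sensitive (see the θ_c prior note):
  with ~20 exposed items the data cannot overwhelm the prior for honest
  students, and the honest false-flag rate at the 0.90 cut-off is ~15-25%
  at low prevalence. Flagged students are *candidates* for review, not
  proven cheaters.
* Sensitivity degrades for high-ability cheaters (ceiling on exposed
  items) and at high prevalence (difficulty absorption) — see the
  reproduction note above.
* The entropy cut-off requires truth labels and is therefore a
  calibration-time tool, not applicable to real cohorts directly.
* Exposure flags are assumed known and correct; misclassified item reuse
  propagates directly into the abilities.
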