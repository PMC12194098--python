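# Methods

`dtscoring` models ordinal creativity ratings of divergent-thinking (DT)
responses as the output of rater-specific measurement processes, so that
severity and discrimination differences between raters can be quantified
and, where desired, removed from the scores.  This note documents the
statistical models, the synthetic study generator that stands in for real
rating data, and the numerical choices that matter.

## Measurement models

**Raters as items.**  Each rated unit — a single response in individual
scoring, or a participant x task ideational pool in snapshot scoring —
carries a latent originality value θ, fixed to a standard-normal prior
for identification.  A rater j is an "item" with a discrimination
(slope) a_j and K−1 category thresholds.  In the graded-response (GRM)
family the probability of awarding category k or higher is the
cumulative logit

    P*_jk(θ) = logistic(a_j θ + d_{j,k−1}),    k = 2..K,

with category probabilities P_k = P*_k − P*_{k+1}.  Lower (more
negative) intercepts mean the rater demands more originality before
granting the next category — higher severity.  The partial-credit family
(PCM, GPCM, RSM) instead builds adjacent-category logits
P_k ∝ exp(Σ_{v≤k} a(θ − b_v)).  Constrained and rating-scale variants
share the slope and/or the threshold shape across raters:

| family  | free parameters (J raters, K categories)          | count        |
|---------|---------------------------------------------------|--------------|
| grm     | a_j; d_j1..d_j,K−1                                | J·K          |
| cgrm    | shared a; d_j·                                    | 1 + J(K−1)   |
| grsm    | a_j, location c_j; shared steps (mean 0)          | 2J + K−2     |
| cgrsm   | shared a; c_j; shared steps                       | 1 + J + K−2  |
| gpcm    | a_j; b_j·                                         | J·K          |
| pcm     | b_j· (a ≡ 1)                                      | J(K−1)       |
| rsm     | location β_j; shared steps τ (sum 0), a ≡ 1       | J + K−2      |

Counts shrink when a rater never uses a category: for families with
rater-specific thresholds the unused category is collapsed (K_eff < K)
and noted on the fitted model.  A rater with a single observed category
is dropped with a warning — its parameters are unidentifiable.

**Estimation.**  Marginal maximum likelihood: the trait is integrated
out on 101 equally spaced quadrature nodes over [−6, 6] with
renormalized normal-density weights.  For integrands with Gaussian tails
this trapezoid-type rule converges superalgebraically, which is why the
package's EAP scores agree with a 10⁵-point brute-force grid to better
than 10⁻⁴.  The negative marginal log-likelihood is minimized by L-BFGS
with finite-difference gradients; thresholds are parameterized as
ordered (d₁ free, subsequent intercepts decrease by exponentiated
decrements) and slopes as exp(·) > 0, so fitted category curves are
sorted and positively oriented by construction.  Identical response
patterns are collapsed before evaluation, making the cost per iteration
independent of the number of units.  Missing ratings simply drop out of
the likelihood product; an all-missing unit contributes log 1 = 0.
AIC = −2ℓ + 2p and BIC = −2ℓ + p·ln N with N the number of units (rows),
the common convention in IRT software.

**EAP scores.**  The IRT-adjusted score of a unit is the posterior mean
of θ given its observed ratings, with the posterior SD as its
uncertainty; a unit with no ratings receives the prior (0, 1).  Empirical
reliability is Var(θ̂)/(Var(θ̂) + mean psd²).

**Many-facet Rasch model.**  For multi-task designs the MFRM decomposes
the step predictor into person trait, task difficulty δ_t, rater
severity λ_j and shared category thresholds τ_v, with the Rasch slope
fixed at 1 and the trait SD σ estimated.  Identification: Σλ = 0,
Στ = 0; δ is pinned by the zero-mean trait prior.  Free parameters:
(J−1) + T + (K−2) + 1.

**Information.**  Samejima's item information is accumulated across
raters into the test information function (TIF); its peak marks the
trait range where the rater panel discriminates best.  With the packaged
individual-scoring presets the TIF peaks at θ ≈ 0.5 (grid argmax at one
decimal), i.e. the panel is most precise just above average originality
and loses precision below θ ≈ −1.5.

## Rater and scale diagnostics

Infit/outfit mean-squares residualize each rating against the
conditional mean at the unit's EAP estimate; 0.6–1.4 is flagged as the
conventional acceptability band.  Two caveats are deliberate design
notes rather than bugs.  First, because the rater's own rating enters
the EAP it is residualized against, the null expectation of the
mean-square is deflated by roughly that rater's share of the posterior
information — with three highly discriminating raters, model-consistent
data produce values around 0.6–0.8, not 1.  Calibration claims about the
statistics concentrating near 1 therefore use rosters where every
rater's information share is small.  Second, refitting the model after
replacing a rater by pure noise largely absorbs the noise through a
near-zero fitted slope; misfit detection is only sharp when statistics
for suspect data are computed against a fit obtained on trusted data.

Unidimensionality is checked by Horn-style parallel analysis (Pearson
correlations of rater columns, mean reference eigenvalues over 100
seeded standard-normal replicates) plus the first/second eigenvalue
ratio with the conventional 4:1 reading.  Inter-rater reliability is
ICC(3,k) — two-way mixed, consistency, average measures — from the
row x rater ANOVA decomposition with an F-based confidence interval,
computed per task on complete cases.

## Aggregation schemes

From response-level ratings: average (mean of response means per task),
summative (sum; equal to average x fluency and therefore fluency-
confounded by construction), max-n (mean of the n highest-rated
responses, ties broken by original response order; participants with
fewer than n responses are scored on what they gave, so a three-response
participant has identical max-3/4/5 scores), and fluency (response
count).  Snapshot scores are missing-robust means over the pool raters.
IRT-adjusted scores average response EAPs per task (unweighted;
precision weighting was considered and rejected as the default because
it changes the score's meaning when fluency varies).  Cross-task
composites are unweighted means over tasks with data; a participant
missing two or more tasks is dropped from composites.

## Reliability and the fluency confound

Internal consistency of each scheme's three task scores: Cronbach's α,
McDonald's ω and Hancock's H, the latter two from a maximum-likelihood
one-factor fit (factor variance 1; residual variances floored at 10⁻⁶
with a Heywood warning).  Confidence intervals are percentile bootstrap
over participant resamples (B = 1000 by default, seeded).

The originality–fluency confound is estimated in a two-factor ML model:
each factor loads on its three task indicators, factor variances are
fixed at 1 so the factor covariance is the latent correlation, and each
same-task (originality, fluency) indicator pair gets a free residual
covariance because both derive from the same task.  The residual
structure is parameterized through per-task 2x2 Cholesky factors, which
keeps the model covariance positive definite everywhere — without this
the optimizer stalls on near-singular samples.  Scheme-by-scheme latent
correlations reuse the same model pairwise.  Fit statistics (χ², CFI,
RMSEA, SRMR) are reported but not gated.

## Synthetic study generator

The generator reproduces the data structure the pipeline assumes, at the
scale of a realistic three-task Alternate-Uses study:

* 201 participants x 3 tasks; per-cell response counts negative binomial
  (dispersion 8, minimum 1) with marginal mean 7.88 responses — about
  4.75 thousand responses in expectation — modulated by a log-normal
  person effect (κ = 0.5) driven by a fluency propensity factor;
* the fluency propensity and latent originality are bivariate standard
  normal with correlation ρ = 0.3 (the confound the latent models must
  recover; between the near-zero average-scoring and ~0.5–0.6 max-n
  correlations reported for such designs);
* response qualities are θ + N(0, σ²) with σ = 1, standardized by
  √(1+σ²) so the response-level trait is unit variance;
* individual ratings come from three packaged graded-response raters
  with realistic severity spread (one rater's top threshold at −8.14);
* the pool-level latent for snapshot scoring is the mean of the top 3
  response qualities (standardized), reflecting that holistic raters
  weigh a pool's best ideas; five packaged snapshot raters score it.

All randomness flows from one seed through named sub-streams, so tables
are byte-identical across runs.  What the generator does **not** emulate:
response text, rater drift over time, category-usage styles beyond the
GRM (e.g. central tendency as a separate process), and task-specific
difficulty in the rating process (tasks differ only through their
response draws).  Passing recovery tests on these data therefore show
that the estimators are correct for the assumed measurement model, not
that real raters follow it.

## Planned-missingness designs

An m-of-J design retains a uniformly random subset of m raters per unit.
The subset is keyed by a hash of the unit id together with the design
seed, so the assignment is invariant to row order and exactly m ratings
survive per unit (missing fraction exactly 1 − m/J: 33% for 2-of-3, 60%
for 2-of-5).  The robustness experiment applies the design, refits the
same model family selected on complete data, rescores all schemes, and
reports full-vs-reduced Pearson correlations of composites alongside
complete/reduced reliability coefficients.  On the default synthetic
study the 2-of-3 design preserves average-score composites at r ≈ 0.98
while reliability drops by a few hundredths — score rankings are robust
to planned missingness even though precision is lost.

## Problem sizes and determinism

Recovery checks run at the scale where their tolerances are meaningful:
GRM slope recovery uses 20 000 response units (3 seeds), MFRM severity
5000 units, latent-correlation recovery N = 2000 with 20 replicates per
condition, and study-scale robustness the default 201 x 3 design.
Pattern collapsing keeps each IRT fit under a second at these sizes.
All stochastic tests fix seeds; end-to-end pipeline runs with the same
configuration and seed produce byte-identical outputs.

## Known limitations

* No multidimensional IRT, MCMC estimation, person-fit, or DIF.
* The MFRM and the rater-only models are compared on the same units by
  AIC/BIC, but their likelihoods condition on different structure
  (task facet vs none); comparability follows common practice rather
  than strict nesting.
* Listwise completion in the CFA stages (no FIML); SEM features beyond
  the two-factor model (mean structures, grouping) are out of scope.
* Max-n scoring is never IRT-adjusted: selecting responses by observed
  mean rating would distort the measurement model.
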