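# Methods

This note records the model, the analysis choices that a short methods
section typically leaves open, the numerical machinery, what the synthetic
cohort generator does and does not emulate, and the problem sizes the test
suite and acceptance script use.

## The panel GVAR model

Observed scores for person *i* at wave *t* (p items, 3+ equally spaced
waves) are modelled as

    y_it = nu_t + b_i + e_it,      b_i ~ N(0, Sigma_B),
    e_it = B e_i,t-1 + zeta_it,    zeta_it ~ N(0, Sigma_zeta),

with e_i1 drawn from the stationary distribution Sigma* solving the
discrete Lyapunov equation Sigma* = B Sigma* B' + Sigma_zeta. Stationarity
(one B and one Sigma_zeta for every transition) encodes the assumption that
the lag-1 dynamics are the same across the study window; it requires the
spectral radius of B to be below 1. The estimands are reported as three
networks: the temporal coefficients themselves (directed, on standardized
scores), and the partial correlations implied by the two precision matrices
K_zeta = Sigma_zeta^-1 and K_between = Sigma_B^-1 (undirected). The stacked
3p-variate normal has covariance blocks Cov(y_t, y_s) = B^(t-s) Sigma* +
Sigma_B for t >= s; the FIML log-likelihood evaluates each person on their
observed cells only, grouped by missingness pattern through per-pattern
sufficient statistics (count, mean, scatter), which makes a likelihood
evaluation O(#patterns) rather than O(#persons).

Wave means nu_t are estimated freely per wave even though detrending makes
them nearly zero; this keeps the model honest when users skip detrending.
With 3 waves and p = 9 the saturated model has 9^2 + 2(9 + 36) + 27 = 198
free parameters against 405 saturated-MVN moments, so it is testable with
207 degrees of freedom.

## Preprocessing conventions

- **Detrending** removes a *pooled* per-item OLS line of score on wave
  index (a fixed effect, not per-person lines — with 3 waves a per-person
  line would absorb nearly all within-person variance).
- **Standardization** z-scores each item with mean and SD pooled across
  all waves jointly (denominator n-1), so wave-mean differences are
  preserved for the trend/mean structure to handle. Order is detrend then
  standardize; both are config flags.
- **Variance screening** drops items whose pooled modal-category share
  exceeds 0.95 (configurable). On data calibrated to the published
  mothers' item moments this excludes exactly the near-constant
  suicidal-ideation analogue (98.8% zeros). On the fathers' calibration
  the crying item (mean .042, ~96% zeros) also crosses the threshold,
  whereas the original analysis kept it; the published criterion for "lack
  of variation" is not stated, so the threshold is exposed rather than
  reverse-engineered.
- Ordinal 0-3 scores are treated as continuous throughout, as is standard
  in this literature.

## Estimation and inference

The optimizer is L-BFGS-B on the per-person mean negative log-likelihood
with **analytic gradients**, derived by the adjoint chain: MVN pattern
derivatives with respect to the stacked covariance are pushed through the
block-Toeplitz structure, through the Lyapunov equation via the adjoint
Lyapunov solve (Lambda = B' Lambda B + G), and through the
precision-to-covariance inversions. The gradient is verified against
central finite differences in the tests. Invalid proposals (spectral
radius >= 1, non-PD precision) are rejected with a penalty value during
line search, which keeps exact zero-constraints expressible (precisions
are parameterized by their free elements, not Cholesky factors).

Convergence requires gradient max-norm < 1e-5 on the per-person scale.
Saturated models at small n are weakly identified (the 3-wave data barely
separate intercept variance from strong autoregression), leaving
near-zero-curvature directions where L-BFGS-B stalls just above
tolerance; a damped-Newton polish using the finite-differenced analytic
gradient as Hessian, with eigenvalues floored at 1e-4 of the largest,
finishes convergence. Non-convergence never raises — the fitted model
carries a flag, which the stability protocol depends on.

Standard errors invert the observed information (central finite
differences of the analytic gradient, step 1e-5 scaled, with a 1e-4 and
1e-6 retry). Between-person variance can legitimately collapse to the PD
boundary; numerically tiny negative information eigenvalues (below 1e-6 of
the largest in magnitude) are clipped rather than treated as
non-identification.

**Pruning** fixes every edge parameter with two-sided Wald p > alpha to
zero simultaneously and refits; alpha defaults to 0.01 (the ecosystem
convention; 0.05 is the plausible alternative and is a config key).
Autoregressive self-loops are pruned like any edge (an exemption flag
exists); means and precision diagonals never are. **Model search** then
greedily re-introduces the single zeroed edge whose refit most decreases
BIC (candidates enumerated in deterministic matrix/row/column order, so
ties resolve lexically), re-prunes, and stops when BIC stops improving or
a pattern repeats. Search is off by default in the pipeline config because
pruning alone already reaches a BIC-favored model in the regimes tested.

**Fit indices** compare against (a) the saturated MVN model — closed form
for complete data, EM under missingness (tolerance 1e-9 relative) — and
(b) an independence baseline (free means and variances, diagonal
covariance, closed form under FIML). chi2 = 2(LL_sat − LL_model), df =
k_sat − k_model; CFI, TLI (truncated at 1) and RMSEA use the standard
formulas with N = number of persons contributing data and N−1 in RMSEA;
BIC = −2LL + k ln(N). All of these conventions (N per person, RMSEA
denominator, baseline definition) are stated here because the indices
depend on them.

## Case-drop stability

Each replicate draws floor(0.75 n) persons *without replacement* (a
subsample, not a bootstrap), re-runs preprocessing (standardization
statistics recomputed on the subsample — the conservative choice), refits,
re-prunes, optionally re-searches, and codes each edge 1 if free-and-
nonzero in the final pattern. A non-converged replicate contributes 0 to
every edge. Replicate r uses an independent random stream spawned from
(seed, r), so results are bit-reproducible and independent of execution
order.

## Synthetic cohort generator

The generator produces the regime the estimator claims to handle:

1. **Ground truth**: sparse B (autoregressive diagonal plus random
   cross-lagged entries, rescaled so the spectral radius hits its target
   exactly) and sparse diagonally dominant precisions.
2. **Latent panel**: exact simulation from the model (intercepts, then the
   stationary initial deviation, then the lag-1 recursion).
3. **Ordinalization**: per-item normal-quantile thresholds cut the latent
   scores into 4 categories. Thresholds are calibrated so the categorical
   mean and SD match published item moments within 0.01; with three
   thresholds and two moment targets the system is underdetermined by one
   degree of freedom, pinned down by a small regularizer toward equal
   threshold spacing. Infeasible targets raise an error reporting the
   attainable SD interval; a mean-only fallback (geometric category
   profile) exists for boundary cases.
4. **Attrition**: at each wave transition, dropout probability is
   logistic(logit(base) + slope * previous-wave total) and dropout is
   permanent (monotone), so missingness is MAR given observed history.
   The study-sized presets use slope 0.08 per total-score point and
   intercepts offset so the marginal rates land near the published
   cumulative dropout percentages (mothers 11.74% by wave 2, 15.30% by
   wave 3; fathers 4.84%/10.36%).

The presets fix the ground truth with an internal seed — the truth is part
of the scenario; the user seed varies only the sampled data. Cross-lagged
truth weights are drawn in [0.3, 0.45] so that "strong edge" checks
(|weight| >= 0.3) have qualifying edges after the spectral-radius rescale.

**What the generator does not emulate.** Items are conditionally
independent given the network structure, so marginal inter-item
correlations are much weaker than on a real depression scale. As a result
Cronbach's alpha (~0.1 vs published ~0.8), total-score SD (~1.8 vs ~3.4)
and above-cut-off prevalence are *not* matched — only item-level margins
and dropout behaviour are. Passing tests therefore demonstrate that the
pipeline recovers known network structure under the study's measurement
regime (4-point skewed ordinal items, MAR attrition, 3 waves), not that
synthetic cohorts are distributionally indistinguishable from real ones.
There is also no item-level (non-monotone) missingness: attrition removes
whole waves.

## Problem sizes used by the automated checks

Chosen to exercise each claim at single-CPU desk scale: oracle
equivalences at p = 3–5; parameter recovery and Wald coverage on 20
datasets (p = 6, n = 500, continuous, complete); pruning sensitivity/FDP
on 20 datasets at n = 1000; the ordinal-attrition regime at p = 9 + 1
screened item, n = 600, 12 seeds (tests) / 10 seeds (acceptance script);
stability at 50 replicates, p = 4, n = 1000. The full study-sized pipeline
(n = 869) runs once in the acceptance script for the fit indices and BIC
comparison.

## Known limitations

- Only equal wave spacing; a single B is shared across transitions.
- No polychoric/threshold likelihood: ordinal scores enter as continuous,
  matching the target literature but biasing partial correlations toward
  zero for very skewed items.
- Greedy BIC search explores single-edge additions only.
- The EM saturated fit and the structured fit use different optimizers;
  their log-likelihood difference is reliable to ~1e-6, which bounds the
  resolution of chi-square-based indices.
- Saturated fits below n ≈ 200 at p = 9 are close to non-identified; the
  optimizer reports honest non-convergence rather than forcing an answer.
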