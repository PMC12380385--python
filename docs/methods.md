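# Methods

## The model

`phmm` fits a three-layer hidden Markov model to longitudinal data from
clusters whose members each report several outcomes — the motivating design
is a two-arm behavioural trial following parent–child dyads over five
visits, with each member reporting a task-involvement score (DFR) and a
log-scale conflict score (PCC).

**Layer 1 — cluster chain.** Cluster `i` in arm `s` carries a latent state
sequence `Z_i1..Z_in` on `{1..C}` with arm-specific initial probabilities
`π^s` and transition matrices `P^s` (first-order, time-homogeneous). By
default the initial distribution is shared across arms (`share_initial`),
because randomization at baseline precedes any arm effect; arm-specific
initial rows are available.

**Layer 2 — perception.** Member `m` perceives the cluster state through a
row-stochastic perception matrix: `P(Z_itm = j | Z_it = k) = Q_m[k, j]`,
independently across members given the cluster state. Three modes:
`identity` (the mixed HMM: member states equal cluster states), `shared`
(member-specific, arm-common `Q_m`), and `arm_specific` (`Q_m^s`).

**Layer 3 — emissions.** Outcome `j` of member `m` given member state `k`
is Gaussian with mean `u_k'τ_j^m + X_it'β_j^m + b_ie` and variance
`u_k'γ_j^m`, where `u_k` has ones in its first `k` entries (state means and
variances are prefix sums of increments), `X_it` are cluster-visit
covariates, and `b_i ~ N(0, Σ)` is a cluster random effect with one entry
per outcome series (`r = Σ_m J_m`). Missing outcome cells contribute no
emission factor; because cells are conditionally independent given states
and `b`, cell-wise omission is exact.

The per-visit likelihood enters the chain through the diagonal mixture
matrix `G(y_it)` with entries
`g_h = Π_m Σ_k [Π_j f(y_ijt^m | k)] Q_m[h, k]`:
one member state drives all of a member's outcomes at a visit, so the sum
over the member state sits outside the product over that member's outcomes.
The variant with the product outside the sum (each outcome independently
mixed) is available as `mixture_form="outcome"` for comparison; it
corresponds to a model in which each outcome has its own perceived state
and is not the default because it contradicts the layer-2 structure.

## Estimation

Conjugate priors: `Dir(1)` rows for `π`, `P`, `Q`; inverse-Gamma
(0.001, 0.0002) for variance parameters; flat prior on `(τ, β)`;
inverse-Wishart(r+1, I) for `Σ`. The Gibbs sampler alternates:

1. cluster paths by forward-filtering backward-sampling (scaled forward
   recursion; the per-visit scaling constants are the one-step-ahead
   predictive likelihoods and are stored as WAIC pointwise units);
2. member states from their exact conditionals;
3. Dirichlet draws for `π`, `P`, `Q` from counts;
4. a joint Gaussian draw of `(τ, β)` from the weighted-least-squares
   conditional (cumulative state encoding ‖ covariates; ridge fallback with
   logged jitter if a state was never visited);
5. state variances — two parameterizations (below);
6. exact Gaussian conditionals for each `b_i`;
7. inverse-Wishart for `Σ`.

**Variance parameterizations.** The inverse-Gamma prior on the variance
*increments* forces nondecreasing state variances — a real structural
constraint, and jointly non-conjugate: increments mode uses one
Metropolis-within-Gibbs log-random-walk sweep per increment (step 0.4,
rejections counted). Direct mode instead treats each per-state variance as
a free conjugate inverse-Gamma parameter and reports the (possibly
negative) increments. Direct mode is faster and fully conjugate; increments
mode is the faithful prior and, by excluding spurious wide-variance states,
noticeably improves state recovery on the scenario presets. The sampler
default is `direct` (conjugacy, speed); the simulation-study driver in
`scripts/acceptance.py` uses `increments`.

**Schedule.** Two phases: a pilot chain whose post-burn-in posterior mean
re-initializes a production chain (defaults 4000/3000 and 40000/30000 with
thinning 10). Reduced schedules for tests and the acceptance script are
stated below. Initialization: cluster states by quantile-binning a
composite standardized outcome score, member states equal to cluster
states, `b = 0`, `Σ = I`, emission moments from the binned groups.

**Label switching.** Each retained draw is mapped to a canonical labelling:
the reference member's states (the parent) are ordered by decreasing
state mean of its first outcome — the parent task-involvement ordering,
which is strictly monotone (Discordant > Harmonious > Indifferent) — then
cluster states are aligned through the dominant diagonal of the parent's
perception matrix (Hungarian assignment), then each other member through
its own perception diagonal. For simulation studies,
`summaries.align_draws_to_truth` instead aligns fitted states to the
generating states by Hungarian matching of the posterior-mean emission
state-mean vectors — the natural convention for recovery/bias reporting,
since a misspecified fit's states need not respect the canonical ordering.

**WAIC.** Pointwise unit: cluster-visit one-step-ahead log-likelihood,
conditional on the draw's random effects (stored during sampling);
`waic = -2(lppd - p_waic)`. A marginal flavor (Monte-Carlo integration
over `b`, pointwise unit: cluster) is available.

**Goodness of fit.** Posterior predictive checks simulate full panels
(fresh latent states and random effects, observed design and missingness
preserved) from randomly chosen retained draws and place the observed mean
and variance of each outcome series within the predictive distribution
(default statistics: the 2r means/variances; placements outside
[0.01, 0.99] are flagged). Pseudo-residuals are forecast (one-step-ahead)
normal quantile transforms of the predictive CDF per cell, averaged over
draws on the probability scale before the quantile transform, clipped to
(1e-10, 1-1e-10); under a correct model they are standard normal.
Convergence diagnostics split the stored chain into segments and tabulate
rank-based ESS and split-Rhat per scalar parameter via arviz.

## The scenario generator

Three presets emulate a 390-cluster, five-visit, two-arm dyadic trial with
three relationship states (Discordant, Harmonious, Indifferent):

- initial probabilities (0.76, 0.18, 0.06), shared across arms;
- usual-care rows ((0.58,0.37,0.05),(0.03,0.47,0.50),(0.01,0.01,0.98)) and
  intervention rows ((0.48,0.47,0.05),(0.03,0.65,0.32),(0.02,0.02,0.96));
- perception matrices: child ((0.52,0.44,0.04),(0.06,0.75,0.19),
  (0.02,0.26,0.72)), parent ((0.75,0.23,0.02),(0.02,0.94,0.04),
  (0.01,0.02,0.96)) with the last parent row normalized from its printed
  2-decimal values (sum 0.99);
- state means: child DFR (33.90, 34.29, 30.63), child log-conflict
  (3.33, 3.19, 3.09), parent DFR (38.87, 36.93, 33.75), parent
  log-conflict (3.32, 3.22, 3.23);
- covariates: gender ~ Bernoulli(0.49) and baseline age ~ N(12.5, 1.5²)
  truncated to [8, 17] (the age spread is our choice, spanning
  pre-adolescence/adolescence); emission β = 0 in the presets since the
  reference estimates report state intercepts only;
- arms: fixed 50/50 margins by default (independent Bernoulli and an
  explicit 201/189 split are options).

Scenario 1 uses identity perception, scenario 2 the matrices above,
scenario 3 arm-specific perception (usual care: the matrices above;
intervention: a 50/50 blend with the identity — the generating matrices of
the arm-specific variant are not published, so a distinct second arm is
constructed).

**Variance calibration.** State variances and `Σ` are not published. They
are pinned by two published summaries. (1) The observed marginal variances
of the four series (21.21, 0.05, 21.19, 0.05) equal between-state +
within-state + random-effect variance; the between-state part follows from
the state means and the average state occupancy. (2) The reference
conditional WAIC of the 3-state fit (13,577.2) fixes the one-step
predictive log-density, which determines how the post-between-state
remainder splits: the common within-state share is the value (0.2817) at
which the conditional predictive log-likelihood of the true model on a
generated 390×5 panel equals −WAIC_ref/2, solved by bisection with the
forward recursion (a closed-form Gaussian approximation that ignores the
state-mixture entropy gives 0.37 and produces visibly under-separated
states). Random-effect correlations: 0.3 within member, 0.2 across
members (a priori). The resulting within-state variances are ≈5.2 (DFR)
and ≈0.012 (log-conflict); random-effect variances ≈13.2/12.2 (DFR) and
≈0.031/0.030 (log-conflict).

What the generator does not emulate: real missing-visit patterns (panels
are complete by default; the containers and likelihood handle missing cells
natively), non-Gaussian tails, time-varying transitions, and covariate
effects in emissions. Passing recovery tests therefore demonstrate
correctness of the machinery under the stated conditions, not robustness
to those departures.

## Problem sizes used in tests and the acceptance script

Full-schedule runs (4000/3000 + 40000/30000) are appropriate for real
analyses. The simulation-study driver (`scripts/acceptance.py`) uses
390×5 panels with a reduced two-phase schedule (800/400 pilot,
6000/3000 production, thinning 4 → 750 retained draws), increments-mode
variances, 5 replications for the recovery and misspecification runs and
3 for the state-count WAIC comparison; comparison runs at the full
schedule changed the headline posterior means by less than the
replication spread. The test suite runs the same machinery at smaller
sizes (150–390 clusters, a few hundred to a few thousand iterations); the
joint-distribution (Geweke-style) check uses C=2, N=20, n=3 with 15,000
successive-conditional cycles.

## Known limitations

- At the calibrated noise level the scenario-2 posterior is broad: with
  only five visits and heavily overlapping emission distributions, some
  perception entries (notably the parent's Harmonious diagonal) are
  recovered with attenuation at reduced MCMC scale.
- Unequal per-member state counts are supported only as a common member
  state count `C_m` (possibly ≠ C); fully member-specific counts are not.
- The increments-mode Metropolis step uses a fixed proposal scale; no
  adaptation is performed.
- Reducible transition-matrix draws are excluded from stationary-contrast
  summaries (counted), not repaired.
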