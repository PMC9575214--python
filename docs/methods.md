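# Methods

## The statistical problem

Two groups of subjects (e.g. patients and controls) each contribute a
functional-connectivity network: a symmetric `V x V` matrix of Fisher-z
transformed Pearson correlations between the resting-state time series of
`V` brain regions.  The analysis unit is the *edge* — an unordered region
pair — so each subject reduces to a vector of `E = V(V-1)/2` edge values,
modelled as multivariate normal.  Two features of such data drive the
design:

1. **Edges are correlated through network topology, not distance.**  Two
   edges whose four endpoint regions all belong to the same functional
   community co-vary strongly; other edge pairs share only a weak
   baseline dependence.  With `E` in the hundreds the unstructured edge
   covariance has far more parameters than subjects, so the community
   structure is used to reduce it.
2. **Subjects are heterogeneous.**  Even within a group, individual
   networks differ in overall connectivity level; ignoring this inflates
   or deflates test statistics.

## Model

### Topology-structured edge covariance

Let `omega_i` be the latent cluster label of region `i`.  The edge
correlation matrix is

```
Lambda[e_ij, e_i'j'] = rho_k   if omega_i = omega_j = omega_i' = omega_j' = k
                       rho_0   otherwise,         diagonal = 1
```

A Dirichlet process with concentration `alpha` is the prior over the
partition (marginally, Chinese-restaurant-process conditionals with
weights `m_{-ik} / (V-1+alpha)` for existing clusters and
`alpha / (V-1+alpha)` for a new one), and `rho_0`, `rho_k` carry
independent normal priors.  Given per-group centred residuals
`R_n ~ MVN(0, Lambda)`, the posterior kernel is
`exp{-N/2 (log|Lambda| + tr(H Lambda^{-1}))} p(partition) p(rho)` with
`H` the correlation-standardised residual cross-product
`H0 = R'R/(N-p)`.

`Lambda` is a block-equicorrelation matrix plus a rank-one baseline term
`rho_0 11'`, so every determinant, inverse and trace in the sampler uses
per-block closed forms (equicorrelation eigenvalues `1+(m-1)c`, `1-c`)
and one Sherman–Morrison step — no dense factorisations.  Positive
definiteness is checked in closed form per state; invalid states get log
posterior `-inf`.

The sampler alternates (a) a Gibbs scan of region labels in ascending
index order, drawing the factor of a proposed new cluster from its prior
(Neal's algorithm-8 style with one auxiliary draw), and (b) one Gaussian
random-walk Metropolis step per correlation factor.  The point estimate
is the retained draw with the highest log posterior kernel (ties broken
by the earliest draw), with factors averaged over retained draws sharing
that partition; if that average ever leaves the positive-definite region
the maximising draw's own factors are used.  The covariance handed to
the next stage is `Sigma_hat = Diag(H0)^{1/2} Lambda_hat Diag(H0)^{1/2}`,
i.e. the correlation structure rescaled by residual variances (in the
simulation design these are ~1, so `Sigma_hat ~ Lambda_hat`).

Defaults (all exposed in configuration): `alpha = 1`; factor priors
`N(0, 0.25)`; 2000 sweeps with 1000 burn-in; proposal s.d. 0.05; a single
seeded generator per chain so estimates are bitwise reproducible.  The
chain is initialised with all regions in one cluster and factors at their
prior means; on two-cluster data the mode is typically reached within a
few dozen sweeps.

### Heterogeneity and effects

Subject edge vectors within a group follow
`Y_n ~ MVN(X_n' beta, Sigma + psi)` with independent subjects.  `psi` is
either `sigma^2 I` (scaled identity) or compound symmetry (diagonal
`sigma^2`, off-diagonal `b`).  Because all subjects share one weight
matrix, GLS for `beta` collapses to OLS — with the default intercept-only
design, per-edge group means — while the weight survives in
`var(beta_hat) = (Sigma_hat + psi)/N`.  This Kronecker reading is the
only dimensionally coherent version of the stacked-GLS estimator and is
what the two-sample statistic below consumes.

`sigma^2` and `b` are moment estimators: the average diagonal and average
off-diagonal of `Omega_hat - Sigma_hat`, where `Omega_hat` is the mean
outer product of residual vectors.  `sigma^2` is floored at 0 and `b`
clipped to `[-sigma^2/(E-1) + 1e-10, sigma^2]` so `psi` stays positive
semidefinite (the clamp state is recorded in the fit).  `beta` and `psi`
alternate until the change in `(sigma^2, b)` drops below `1e-6` (at most
100 iterations; intercept-only designs reach the fixed point on the
second pass because `beta` does not depend on `psi`).

### Tests

*Whole network*: Hotelling-type quadratic form
`(b1-b2)' (V1+V2)^{-1} (b1-b2)` with identity contrast, `Vg` the fitted
`(Sigma_hat_g + psi_g)/N_g`.  *Single edges*: squared two-sample z-scores
with plug-in variances.  Both are referred to a permutation null: group
labels are re-randomised (sizes preserved), `beta` and `psi` are
re-estimated per relabelling, and p-values use the add-one estimator
`(1 + #{perm >= obs})/(B + 1)`.  Edge-wise p-values use each edge's own
permutation distribution and are Benjamini–Hochberg adjusted
(statsmodels implementation).  The nominal level is 0.05.

Re-running the covariance MCMC inside every permutation would multiply
the cost by the permutation count for no clear benefit — only the
"interest parameters" `beta` and `psi` are re-estimated per relabelling —
so each group's `Sigma_hat` is frozen at its observed-label estimate and
the first pseudo-group always pairs with the first group's estimate.
This choice is flagged in the output metadata.  `Sigma_hat` is estimated
per group rather than pooled, matching the `var(b1) + var(b2)` form of
the network statistic.

## Synthetic data generator

The generator *is* the study design, not a test fixture: two equal latent
clusters (first cluster takes the extra region when `V` is odd),
within-cluster correlation `rho in {0.3, 0.5, 0.7}`, between-cluster
correlation 0, per-subject scalar `u_n ~ Uniform(-delta, delta)` added to
all diagonal entries of the edge covariance (`delta = 0.15` low, `0.3`
high heterogeneity), groups of 10 or 25 subjects, and a control-group
mean shift of `d = 0.8` at `round(0.05 E)` edges drawn once per scenario
without replacement.  Type-I experiments are the same code path with
`d = 0`.  Power / type-I error is the rejection proportion over
replicates; each replicate's data, chain and permutation seeds derive
deterministically from the scenario seed, so an experiment is a pure
function of its configuration.

What the generator does **not** emulate: temporal autocorrelation of the
underlying time series (edge vectors are drawn directly), non-Gaussian
tails, motion or acquisition artefacts, and region-specific variance
profiles.  Passing tests therefore demonstrate correctness of the
statistical machinery under its own model, not robustness to real fMRI
preprocessing effects.

## Problem sizes used in the shipped experiments

Full-scale cells (100 replicates x 500 permutations, 2000-sweep chains)
are supported but the shipped tests and the acceptance script use the
package's reduced-replication mode: 50 replicates x 200 permutations
with 400-sweep chains (200 burn-in), and 200 replicates for the null
calibration check in oracle mode (true structure injected, isolating the
inference layer from MCMC noise).  On the simulated structures the
partition mode is found within a few dozen sweeps, so the shorter chains
change estimates negligibly while Monte-Carlo tolerances widen to match
(binomial s.e. ~0.04 at 50 replicates).

## Numerical choices and edge cases

- Asymmetric input matrices are rejected above `1e-8` relative tolerance
  and symmetrised below it; stored diagonals are zero and never read.
- `E = V(V-1)/2` everywhere; edge order is lexicographic in `(i, j)`,
  `i < j`, 0-based internally, 1-based in output tables.
- Equicorrelation blocks of a single edge have no off-diagonal, so their
  factor is unidentified; it simply samples its prior and never affects
  the likelihood.
- A numerically singular variance sum in the network statistic receives
  a ridge of `1e-8 tr/E` once, with a logged warning.
- Degenerate edges (zero residual variance) raise a named error rather
  than propagating NaNs.
- Cluster labels are kept contiguous (relabelled by first occurrence);
  all point estimates are invariant to relabelling.

## Known limitations

- Covariates beyond the intercept are accepted by the design-matrix
  plumbing for the effect estimate but the variance path (and therefore
  the tests) supports intercept-only fits.
- No split–merge moves: the Gibbs scan can mix slowly on large `V` with
  weak correlations, though recovery is reliable at the study's sizes.
- Posterior uncertainty in `Sigma_hat` is not propagated into the test
  statistics; a plug-in point estimate is used.
- Beyond ~30 regions (435 edges) the `E x E` operations make the
  permutation experiments expensive; single analyses remain practical.
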