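# Methods

## Model

`lcvar` fits latent class vector autoregressive (LCVAR) models to
multi-person intensive longitudinal data (e.g., EMA emotion ratings).
Each person i belongs to exactly one of K latent clusters; cluster k is
described by a VAR(p_k) model on the m outcome variables:

    y_t = mu_k + beta_k x_t + w_t
    w_t = sum_{a=1}^{p_k} Phi_{k,a} w_{t-a} + u_t,   u_t ~ N(0, Sigma_k)

with means mu_k (interpreted at x = 0 when covariates are present),
immediate covariate effects beta_k (m × q; continuous covariates such as
a linear time trend, or treatment-coded factor dummies), lagged-effects
matrices Phi_{k,a} (autoregressions on the diagonal, cross-lagged
effects off it), and innovation covariance Sigma_k.  Persons in the same
cluster share all parameters exactly — person-to-person variation within
a cluster is, deliberately, not part of the model; the simulator (below)
exists to probe what happens when that assumption is violated.

Assumptions: Gaussian, serially independent innovations; weak
stationarity of each cluster's process; equidistant measurement
occasions.  The equidistance assumption drives the data handling: a time
point enters the likelihood only if it is *predictable*, i.e., fully
observed together with its p_k immediately preceding occasions
(consecutive beeps, same day when a day indicator is supplied — the
first beep of a day is never predicted from the previous evening).  A
gap in beep numbering is treated as a missing occasion, the conservative
reading of equidistance.  No imputation is performed; rows with any
missing outcome or used covariate are excluded wholly, both as targets
and as lag predecessors.

## Estimation

The complete-data problem treats the person-level cluster indicators
z_{ik} as missing and is solved by EM:

* **E-step.**  pi_{ik} = tau_k exp(l_{ik}) / sum_k' tau_k' exp(l_{ik'}),
  where l_{ik} is person i's log-likelihood over their predictable rows
  under cluster k.  Computed with a log-sum-exp shift: l_{ik} sums
  hundreds of log densities and naive exponentiation underflows.
* **M-step.**  tau_k is the posterior column mean.  Each cluster's VAR
  parameters maximize the posterior-weighted Gaussian likelihood, all
  rows of person i entering cluster k with weight pi_{ik} (membership is
  a person-level, not row-level, attribute).  Without covariates the
  conditional mean is a pure reparameterization of an intercept form, so
  the maximizer is exact: weighted least squares of y_t on (1, lagged
  y), then mu = (I − sum_a Phi_a)^{−1} c and Sigma from weighted
  residuals.  With covariates the problem is bilinear in (mu, beta) and
  Phi, so the M-step takes one pass of two exact conditional blocks —
  (Phi, Sigma) given the mean structure, then (mu, beta) by generalized
  least squares given (Phi, Sigma) — making the algorithm a generalized
  EM.  Either way the observed-data log-likelihood is monotone
  non-decreasing, which the test suite checks on every fixture.

Convergence is declared when the relative log-likelihood improvement
falls below `conv_tol` (default 1e-6) within `max_iter` (default 100)
iterations; a start that exhausts `max_iter` is reported non-converged
but still eligible as a (flagged) winner.  Degeneracies are handled
explicitly rather than silently: a cluster whose prior proportion drops
below 1/(10N), or with effective weight below m(p+1)+q, aborts the start
("cluster collapse"); a near-singular Sigma (condition number > 1e12)
gets a 1e-8 diagonal jitter and errors if still singular.

**Starts.**  Default 50 random partitions (redrawn until every cluster
receives at least ceil(N/4K) persons, so no start begins collapsed),
plus a deterministic "rational" start — k-means on standardized
per-person features (outcome means and lag-1 per-person OLS VAR
coefficients) — plus optionally the modal partition of a previous fit.
The winner is the start with the highest final log-likelihood, ties
broken by start index, so results are reproducible given the seed and
independent of execution order.  The landscape is genuinely multimodal
for small panels (we observe ~15-nat gaps between basins at N≈15), which
is why the default number of starts is generous.

## Model selection

Likelihoods of models with different lag orders are computed over
different effective samples and are never compared; the two selection
problems are therefore handled separately, each with lower-is-better
criteria:

* **Lag-order combination at fixed K** — cluster-weighted
  Hannan–Quinn and Schwarz criteria.  Cluster k contributes
  log det(Sigma_k) plus a penalty on its d_k = p_k m² lag parameters
  scaled by its posterior-weighted effective time points
  T_k = sum_i pi_{ik} T_{ik}; terms are weighted by tau_k:
  HQ = sum_k tau_k [log det Sigma_k + 2 d_k log log T_k / T_k], SC the
  same with log T_k.  For K = 1 both reduce to the classical
  single-series formulas (oracle-tested).  Ties go to fewer total lags.
* **Number of clusters at a fixed common lag** — BIC = −2ℓ + d log
  T_eff with d counting every free parameter (each cluster's mu, beta,
  Phi, Sigma entries plus K−1 proportions) and T_eff the total effective
  time points; ICL = BIC + 2·entropy(posterior), which additionally
  penalizes uncertain classifications, so ICL ≥ BIC with equality
  exactly at 0/1 posteriors.  Ties go to smaller K.

The CLI encodes the recommended order: select K at lag 1 first, then
the lag combination at that K.

## Simulator

`SimDesign` fixes the study conditions: K ∈ {1,2,3}, p ∈ {1,2},
N_subj ∈ {50, 200}, N_T ∈ {50, 100, 200}, m = 6, equal mixing, Sigma
with 1 on the diagonal and 0.5 off it, within-cluster SD ∈
{0, 0.03, 0.0424, 0.085}, and the locus of between-cluster differences
(phi or mu).  Note the SD levels: squared they give 0.0018 and 0.0072,
the variance values under which over-extraction of clusters switches on.

Base parameters are the package's own fixed choices, made once to
resemble emotion-dynamics VARs (autoregressions near 0.4, small positive
within-valence cross-lags) while honoring the design contracts:
lag-1 Phi has 0.4 on the diagonal and 0.1 on the first superdiagonal;
phi-locus conditions space the autoregressive diagonal in steps of 0.3
centered on 0.4 (K=2: 0.25 vs 0.55); mu-locus conditions space all
means in steps of 0.6 centered on 0 (K=2: ±0.3); lag-2 conditions add a
common 0.1·I lag-2 matrix carrying no between-cluster differences and
no within-cluster variance.  All base matrices are stable by
construction and verified at run time.

Person-level parameters add independent N(0, SD²) noise to mu and the
lag-1 Phi entries, redrawn (≤100 times) until the companion spectral
radius is below 1.  Series are generated from a zero state with a
500-step burn-in — validated against the closed-form stationary AR(1)
variance sigma²/(1−phi²) and the discrete Lyapunov autocovariance.

What the generator does *not* emulate about real EMA data: missing
observations, day/night gaps, floor effects and discreteness of rating
scales, covariate-driven trends, and innovation-covariance differences
between clusters.  Passing recovery tests on generator output therefore
demonstrates correctness of the estimator under the model's own
assumptions (plus Gaussian parameter heterogeneity), not robustness to
those real-data features.

## Study problem sizes

The full factorial design (288 cells × 100 replications × 50+ starts)
is cluster-scale; the shipped configurations are desk-scale replicates
chosen to preserve the qualitative claims: the headline runs use the
zero within-cluster-variance condition with K_true=2, lag 1, N_subj=50,
N_T=100, fitting K ∈ {1..4} with 11 starts (10 random + rational) over
20 replications for cluster-number recovery, 10 replications for
membership recovery, and a single N=200/T=200 replication for parameter
recovery.  Under these conditions ICL never over-extracts clusters,
modal memberships reproduce the generating partition exactly (ARI 1),
and aligned MADs of means and lagged effects stay below 0.05 — the same
qualitative picture the full-scale design paints for low within-cluster
variance.

## Numerical and design choices

* Tie-breaks: modal assignment ties go to the lowest cluster index;
  selection ties to the smaller model.  Documented because ARI and
  reports depend on them.
* MAD pools parameter entries with equal weight across clusters, after
  resolving label switching by exhaustive best-permutation alignment
  (K ≤ 6).
* R² is one-step-ahead on predictable rows only, using the person's
  modal cluster parameters including any covariate contribution;
  negative values are reported as-is, and persons with fewer than 3
  predictable rows get NaN.
* Estimated Phi stability is reported (companion spectral radius), not
  enforced; the simulator does enforce it.
* Factor covariates use treatment coding with the first sorted level as
  reference.
* Days and beeps are 1-based user-facing; internal row indices 0-based.

## Limitations

* No within-cluster random effects: data with substantial continuous
  heterogeneity will push BIC/ICL toward too many clusters (visible in
  the simulator at SD ≥ 0.0424); treat criteria as one input among
  several, alongside cluster proportions and interpretability.
* No standard errors or bootstrap intervals for cluster parameters.
* No moving-average terms, no covariate effects on Sigma, no
  continuous-time handling of unequal spacing beyond row exclusion.
* The two-block M-step with covariates is a generalized (not full) EM;
  it shares the monotonicity guarantee but may need a few more
  iterations than an exact joint maximizer would.
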