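# Methods

## Models

Binary responses `y_ij` of person `i` to item `j` are modeled on the logit
scale.  Items are partitioned into `K` mutually exclusive, exhaustive
testlets; `d(j)` is the testlet of item `j`, `S_d` its item set, `n_d = |S_d|`.

* **2PL** (local independence): `logit p_ij = a_j (theta_i - b_j)`.
* **t2pltm** (random-effects testlet model):
  `logit p_ij = a_j (theta_i - b_j + eta_{i,d(j)})`.
* **n2pltm** (testlet-discrimination model):
  `logit p_ij = a_j (theta_i - b_j) + alpha_{d(j)} eta_{i,d(j)}`, where
  `alpha_d = (1/n_d) sum_{j in S_d} a_j` is the *testlet discrimination* —
  the testlet effect is loaded by the average discrimination of the whole
  testlet rather than by each item's own slope.

`theta_i` is the latent ability, `eta_ik` a person-by-testlet random effect
whose variance `sigma2_eta_k` measures the amount of local dependence in
testlet `k`.  When every item in a testlet shares one discrimination the
n2pltm and t2pltm coincide cellwise; when all `eta = 0` both collapse to the
2PL.

Identification: `theta_i ~ N(0,1)`, and the first item is pinned at
`a_1 = 1`, `b_1 = 0` (removing the location and scale trade-offs among
`theta`, `b` and `eta`).

Priors: `a_j ~ N(mu_a, sigma2_a) I(0, inf)`, `b_j ~ N(mu_b, sigma2_b)`,
`eta_ik ~ N(0, sigma2_eta_k)`, with inverse-gamma hyperpriors
IG(0.001, 0.001) on the variances; all prior means default to 0.  The item
prior variances can be *hierarchical* (sampled each sweep — the default) or
*fixed* (the prior-sensitivity study's Type I fixes them at 1, Type II at
100), or the item priors can be flat: Type III uses `a ~ U(0, 100)` and
`b ~ U(-100, 100)`.  The uniform support for `b` is symmetric by design: a
one-sided `U(0, 100)` support would exclude the negative true difficulties
the studies simulate.

## Sampler

The sampler augments each cell with a uniform slice variable:
`lambda_ij ~ U(0, p_ij)` where `y = 1`, `phi_ij ~ U(0, q_ij)` where `y = 0`.
Conditional on these, the joint density is the prior restricted to the slice
region, so every parameter's full conditional is its prior truncated to an
interval obtained by solving the linear (in that parameter) inequalities

    y=1:  linear predictor >= logit(lambda_ij)
    y=0:  linear predictor <= log((1 - phi_ij) / phi_ij)

over the constraining cells.  Sweep order: slice variables; `a_j` for every
non-pinned item; `b_j`; `theta_i`; `eta_ik`; variances (exact conjugate
inverse-gamma draws).  No proposal is ever rejected and no step size is
tuned.

Two structural points deserve emphasis because the truncation sets are
easy to get wrong:

* under the n2pltm, `a_j` appears in every *sibling* item's predictor
  through `alpha_d`, so all cells of the testlet truncate `a_j` (its own
  column with coefficient `theta_i - b_j + eta_ik / n_d`, sibling columns
  with coefficient `eta_ik / n_d`);
* all items of testlet `k` truncate `eta_ik` simultaneously (max of the
  y=1 candidates, min of the y=0 candidates).

Omitting either set breaks the slice invariant (the region no longer
contains the updated state) and the chain stops targeting the posterior.
A debug mode (`MCMCConfig(validate=True)`) runs a pure-numpy reference
implementation that asserts every slice indicator after every sub-step.

### Numerical choices

* Cell probabilities are clamped to `[1e-12, 1 - 1e-12]` before logs and
  slice draws; the slice indicators need strictly positive `p` and `q`.
* Truncated-normal draws use inverse-CDF sampling on the normal-CDF scale.
  Once a standardized bound exceeds 5 SDs into a tail (where the CDF
  difference underflows) they fall back to exponential rejection
  (Robert 1995), with a uniform-rejection fallback for extremely narrow
  far-tail intervals.  The numba kernel uses Acklam's normal-quantile
  approximation plus one Halley refinement; the numpy path uses
  `scipy.special.ndtri`.
* Cells whose coefficient for the updated parameter is exactly zero impose
  no constraint (a measure-zero event that preserves the slice invariant).
* A truncation-interval inversion (numerically `hi < lo`) keeps the current,
  still-valid value and is counted; any nonzero count aborts the run with
  an error.  Healthy runs report zero.
* Initialization: `a = 1, b = 0, theta = 0, eta = 0`, variances 1.
  Multi-chain runs start chains 2+ at that state jittered by +-2 prior SDs
  ("overdispersed" starts).  Chains are deterministic given their seed;
  per-chain seeds derive from one root `SeedSequence`.

The production path is a numba kernel; the reference path is the oracle.
Correctness is established against a fine-grid numerical posterior on a
2-person x 2-item problem with a single free parameter (Kolmogorov-Smirnov
distance < 0.02 at 50,000 draws, checked per parameter block during
development and for the difficulty block in the acceptance suite).

## Model assessment

* **DIC** uses the conditional parameterization: the deviance
  `D = -2 log p(y | a, b, theta, eta)` is evaluated given all sampled
  quantities, the plug-in point is the posterior mean of each, and
  `DIC = D_bar + p_D` with `p_D = D_bar - D_hat`.  Person parameters are
  sampled parameters in this framework, so they are part of the plug-in
  state; `p_D` is accordingly large (hundreds) and is reported.
* **Pseudo-Bayes factor**: each cell's cross-validation predictive density
  is the harmonic mean of its per-draw Bernoulli likelihoods, accumulated
  by a streaming log-sum-exp over draws so reciprocal likelihoods cannot
  overflow.  Models are compared by `sum_ij log CVPD_ij` (larger is
  better); the marginal-likelihood Bayes factor itself is not computed.
  Replication summaries use linear-interpolation (inclusive) quantiles.

## Convergence

Classic Gelman-Rubin R-hat (point estimate, no Brooks-Gelman df correction):
`R = sqrt(((T-1)/T W + B/T) / W)`; identical constant chains return 1 by
convention.  The convergence rule is max R-hat over all monitored scalars
< 1.1.  Posterior summaries report EAP (mean), SD and the shortest
contiguous 95% interval (HPDI).

## Synthetic data and study harnesses

The generator draws `a_j ~ N(0,1)I(0,inf)` (half-normal) with `a_1 = 1`,
`b_j ~ N(0,1)` with `b_1 = 0`, `theta_i ~ N(0,1)`,
`eta_ik ~ N(0, sigma2_eta)`, and Bernoulli responses under the n2pltm.
Truth is redrawn each replication by default; a fixed-truth mode exists.
The default study condition is N = 500 persons, K = 4 testlets of 5 items,
`sigma2_eta = 0.25`.

Accuracy is summarized by Bias and MSE per parameter across replications
(so `MSE >= Bias^2` identically); identification-pinned items are recovered
exactly, reported as zeros, and excluded from item averages.  Averages are
taken per item over replications first, then over non-fixed items.

What the generator does *not* emulate: guessing behavior, missing
responses, person misfit, and — importantly — any screening of item
parameters.  A half-normal discrimination routinely produces items with
`a_j < 0.2` whose difficulties are close to unidentified (posterior
variance near the prior's); recovery summaries under this generator are
therefore dominated by those items, and passing or failing a recovery bound
says as much about the generating distribution as about the sampler.  This
is discussed further under Limitations.

### Problem sizes

Routine runs use scaled-down sizes chosen as desk-scale defaults: chains of
5,000 iterations (2,500 burn-in, single chain) for study replications;
S = 25 recovery replications, 10 model-selection replications, S = 20 for
the prior-type comparison; the convergence check uses 4 overdispersed
chains of 20,000 iterations (10,000 burn-in).  The full protocol (S = 50,
20,000/10,000, 4 chains everywhere) is available by overriding
`StudyCondition`.  The test suite uses further-reduced replication counts
(documented in each test) to keep the default run short.

## Limitations

* Single-site slice-Gibbs mixes slowly for weakly identified parameters:
  items with tiny discriminations and the variance of a testlet whose
  discriminations are all small (the `sigma2_eta -> 0` funnel).  Max R-hat
  over *all* parameters on half-normal truths can remain above 1.1 even at
  the full chain length, driven by those parameters.
* Conditional DIC (plug-in at sampled latents) is one of several DIC
  variants; marginal DIC over `eta` is not computed.
* The harmonic-mean CVPD estimator is consistent but high-variance; with
  few draws the per-cell estimates are noisy.
* The 2PL reduction keeps `eta` frozen at zero rather than removing the
  parameters, so its draw files carry constant eta columns.
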