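# Methods

## Model and estimands

For two groups — a *reference* group (advantaged; in the demonstration
setting, university-educated men) and a *comparison* group (disadvantaged)
— the conditional quantiles of a continuous outcome are modelled linearly
in covariates, group by group:

    Q_y(tau | x, g) = x' beta_g(tau),  tau in (0, 1),

with `x = (1, x_1, ..., x_p)`. Each `beta_g(tau)` is the minimiser of the
check loss `sum_i rho_tau(y_i - x_i'b)`, `rho_tau(u) = u (tau - 1[u<0])`,
estimated on a grid of quantiles (default: 99 equispaced points
0.01–0.99; the grid is the user's resolution/runtime dial and only needs
to be dense enough for the marginal construction below).

The marginal quantile function implied by coefficients of group *j* and
covariates of group *k* pools the full prediction surface
`x_i' beta_j(tau_m)` over all rows of group *k*'s covariate sample and all
grid points, takes empirical quantiles of the pooled values (linear
interpolation of order statistics — the package-wide convention, which
matters only for small pools), and repairs any quantile crossing by
monotone rearrangement (sorting; the pre-rearrangement curve is kept for
diagnostics). This is a Machado–Mata-type construction made deterministic:
the exhaustive covariate sample and a uniform tau grid replace random
draws, so point estimates involve no resampling.

With `Q_ref = Q<ref|ref>`, `Q_cmp = Q<cmp|cmp>`, `Q_cf = Q<ref|cmp>`:

    difference        = Q_ref - Q_cmp
    covariates part   = Q_ref - Q_cf     (composition of risk levels)
    coefficients part = Q_cf  - Q_cmp    (response heterogeneity)

Additivity is an identity of the construction and is asserted to 1e-9 in
the tests. The counterfactual direction is fixed by convention —
coefficients donated by the reference group, covariates from the
comparison group — and is configurable by swapping the roles.

Two known limitations of the construction: quantiles of the pooled
surface outside the grid's span are compressed toward the span (so an
estimation grid must extend beyond the most extreme reported quantile;
the default 0.01–0.99 grid comfortably covers reports at 0.10–0.90), and
the linear-in-x model is taken at face value (no causal claim).

### Per-covariate detail

The aggregate parts are distributional objects; per-covariate attribution
uses mean-covariate Oaxaca-style terms at each reported tau:

    covariates detail_k  = (xbar_ref,k - xbar_cmp,k) * beta_ref,k(tau)
    coefficients detail_k = xbar_cmp,k * (beta_ref,k - beta_cmp,k)(tau)

with one explicit remainder per part absorbing the gap between the
mean-based sums and the distributional aggregates. The remainder is
reported, never hidden: means cannot reproduce a quantile-level
decomposition exactly, and its size tells the reader how good the
approximation is at that tau. The intercept's covariates detail is
identically zero; its coefficients detail is the raw intercept gap.

## Solver

The check-loss problem is solved two ways:

- `solver="exact"`: the standard LP formulation via
  `scipy.optimize.linprog(method="highs")`. Vertex solutions satisfy the
  subgradient counts `#{r<0} <= n*tau <= #{r<=0}` exactly. Used for
  verification and available everywhere; ~25 ms per fit at n≈600.
- `solver="irls"` (default): clipped iteratively-reweighted least squares
  (weights `|tau - 1[r<0]| / max(|r|, eps)` with `eps = 1e-6 * max|y|`),
  the same smoothing family statsmodels' QuantReg uses, implemented
  *batched* over an arbitrary set of (row-weight, tau) problems sharing
  one design. Each batch cell is frozen as soon as its coefficient change
  drops below `1e-9 * max|y|`, so a cell's trajectory is independent of
  what else is in the batch and batched results equal single fits
  bit-for-bit. Iteration cap 300 by default.

Batching is the load-bearing choice: a bootstrap replicate drawn within a
group is an integer row-multiplicity vector on the same design, so all
replicates x all grid points fit in one vectorised loop (~7 ms per
iteration for 101 replicates x 9 quantiles at n=575). At convergence the
two solvers agree with each other and with statsmodels to ~1e-4 in
coefficients; the tests assert loss optimality against a brute-force
lattice oracle and the subgradient counts with a small slack for the
smoothed route. On flat optima (even-n medians, degenerate resamples) any
minimiser is acceptable; determinism — same inputs, same settings, same
output — is guaranteed by the fixed initialisation (least squares) and
iteration rule.

## Bootstrap inference

Percentile pointwise intervals from resampling with replacement *within*
each group (groups are strata; sizes fixed), re-running quantile fits,
aggregate and detailed decomposition per replicate; default 100
replications at level 0.95. One root `SeedSequence` spawns a child stream
per replicate, so raising the replication count extends the replicate set
without reshuffling earlier draws. Replicates with rank-deficient
resampled designs are dropped and counted; above 10% failures the
procedure refuses. The percentile method (not BCa or
normal-approximation) is the declared convention. Raw draws are retained
on the result object, so intervals at other levels can be recomputed from
the same draws (and nest monotonically by construction).

## Strategy layer

Declared conventions (the underlying reasoning is qualitative, so the
package fixes explicit constants rather than inferring thresholds):

- *significant* = the part's pointwise CI excludes 0 at the configured
  level; *dominant* = larger absolute contribution share (>50%).
- Indication per reported quantile follows significance: both parts
  significant → `combined`; covariates only → `proportionate_universalism`;
  coefficients only → `targeted`; neither → `none`. Dominance is recorded
  alongside but does not override significance (a significant covariates
  part at a quantile where coefficients dominate still indicates a
  *supplementary* universalist component — hence classification by
  significance). Without bootstrap intervals (reps = 0) the indication
  falls back to the dominant part.
- A covariate is *countervailing* when its covariates and coefficients
  details both carry the gap's sign and both exceed a noise floor
  (default 1% of the absolute difference at that tau): equalising its
  level would close part of the gap, but the comparison group's weaker
  response would blunt a level-raising intervention; the flag recommends
  response-modifying (structural) intervention. The intercept is never
  flagged (not intervenable) but triggers an "unmeasured factors" caveat
  when it drives more than half of the coefficients part.

Classification is invariant to positive rescaling of the outcome, and an
indication can only change when a CI endpoint crosses 0 or a share
crosses 50%.

## Synthetic data and ground truth

Groups are generated from the location-scale model
`y = x' beta + (x' gamma) eps` with `x' gamma > 0` enforced (checked by
sampling at construction and again at generation), so conditional
quantiles are exactly `x' beta + (x' gamma) F_eps^{-1}(tau)`. Noise
families are standard Gaussian and Uniform(0,1) — both with closed-form
quantiles, keeping truths exact and cheap. Covariates mimic the
measurement types of a capital-based dietary-disparity analysis:
lognormal income-like (unit: arbitrary currency, mean ≈ 5–6), Poisson
network-size-like (λ ≈ 6–7 ties), and bounded beta support/literacy-like
scores (0–10 and 1–5). They do not claim to match any real survey's
marginals; outcome values land in a plausible range for energy-adjusted
intake per 1000 kcal (medians ≈ 100–130, spread ≈ 40).

Five named scenarios fix the study conditions: `null` (identical groups),
`location_shift` (comparison intercept lowered by 10 units → coefficients
part ≡ 10, covariates part ≡ 0), `covariate_shift` (shared coefficients,
disadvantaged covariate profile → coefficients part ≡ 0),
`response_heterogeneity` (shared covariates, attenuated comparison
slopes → covariates part ≡ 0), and `mixed` (both). The demonstration
fixture uses `mixed` at group sizes 575/249 (the demonstration study's
sizes) with heterogeneity concentrated in the coefficients: its true
coefficients-part share is ≈ 80% at every reported quantile, and the
income covariate has the countervailing pattern (positive level gap,
positive response gap).

The Monte-Carlo oracle simulates the three marginal distributions
(reference, comparison, counterfactual) directly from the generators —
default 1e6 draws, standard errors by 20-way chunking — and is the
independent route against which the estimation pipeline is validated.

## Validation studies and problem sizes

- *Oracle equivalence*: the pooled marginal quantile function from a
  fitted process at n=2000 agrees with a 1e6-draw simulation at eleven
  quantiles 0.1–0.9, within 3x the combined estimation + MC standard
  error (asymptotic quantile variance `tau(1-tau)/(n f(q)^2)` with the
  density estimated from the oracle draws).
- *Parameter recovery* uses a deliberately unit-scale DGP
  (`beta = (1, 0.5, 0.3)`, `gamma = (0.3, 0.05, 0.05)`, uniform and beta
  covariates) so a fixed 0.1 sup-norm tolerance is meaningful: the
  sup-norm error of `beta_hat(tau)` against `beta + gamma Phi^{-1}(tau)`
  decreases across n = 500/2000/8000 and is below 0.1 at n=8000.
- *Null studies* estimate the sampling sd of a part from 12 independent
  datasets at n=5000/group (19-point grid) and require the assessed
  estimate to sit within 3 sd of zero at every reported quantile.
- *Coverage*: 200 demonstration-sized datasets (575/249) from the `mixed`
  scenario, 100 bootstrap replications each, estimation grid of 9
  quantiles 0.1–0.9 and an 80-iteration solver budget (measured to
  perturb the pooled median by well under the bootstrap sd; the 9-point
  grid reproduces the pooled median to <0.01 outcome units against a
  1999-point grid). Empirical coverage of the 95% interval for the median
  difference is required to lie in [0.90, 0.99]. Runs in ~3 minutes on
  one CPU.

Passing these studies shows the pipeline is correct and calibrated *under
the generator's assumptions* — linear conditional quantiles,
location-scale errors, independent complete-case rows. Real data can
violate all three (non-linearity, non-location-scale heteroskedasticity,
measurement error, informative missingness), and the studies say nothing
about causal interpretation of the covariates.

## Numerical and design conventions

- Empirical quantiles everywhere use numpy's linear interpolation of
  order statistics.
- Display tables round half-up to one decimal; machine-readable outputs
  keep full precision (printed tables rounded this way can show 0.1-unit
  additivity slippage, which is why the full-precision file exists).
- Zero total difference makes contribution shares undefined: reported as
  NaN / "undefined", never an exception.
- The intercept is always prepended by the package; users supply
  covariates only (prevents double-intercept errors).
- Outlier handling is opt-in quantile trimming on the outcome pooled over
  both analysis groups (no default trimming: any threshold would be an
  undeclared analysis choice). Missing data: complete-case deletion only.
- The group variable is restricted to exactly two analysis levels; other
  levels are dropped and logged.
- Bootstrap draws, seeds and failure counts are stored on the result;
  the run manifest echoes the full configuration, input digest and output
  list so a run can be reproduced from the manifest alone.
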