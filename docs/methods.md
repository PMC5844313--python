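# Methods

## The problem

In clonal evaluation trials (the motivating crop is cassava, planted in
single-row plots without border rows), the phenotype of a plot is not
determined by its own clone alone: neighbouring plots compete for light,
water and nutrients. Ignoring that competition inflates the error of
genomic predictions. `interplot` implements a genomic-selection (GBLUP)
framework in which competition enters through modified incidence
matrices, at two levels:

* **interclonal competition** — a second genetic effect per clone, its
  *competitive ability* `c`, incident on the neighbouring plots;
* **competition error** — a plot-level, non-genetic influence `p` on
  neighbours (e.g. propagule vigour), with zero self-incidence.

## Models

With `y` the n-vector of plot phenotypes, `Z1` the n x g design matrix
of clones and `K` the additive genomic relationship matrix:

| model | linear predictor | random-effect covariance |
|---|---|---|
| Base | mu + Z1 g + e | g ~ N(0, K sg2), e ~ N(0, I se2) |
| 1 | mu + Z1 g + Z2 c + e | [g; c] ~ N(0, [[sg2, sgc], [sgc, sc2]] ⊗ K) |
| 2 | mu + Z1 g + II p + r | [p; r] ~ N(0, [[sp2, spr], [spr, sr2]] ⊗ I) |
| 3 | both extensions | both blocks |
| 4 | Base + s | s ~ N(0, S ss2) |
| 5 | selected competition model + s | as above |

`Z2` (n x g) maps neighbouring clones onto a plot with distance-decay
weights and `II` (n x n, zero diagonal) does the same for neighbouring
plots. The intercept is the only fixed effect; check clones are treated
as ordinary genotypes, not as fixed effects.

## Distance and decay functions

Plots are `plot_width x plot_length` rectangles on a Range x Column
grid. The centre spacing across the axis that shares the *long* plot
edge equals `plot_width` and across the other axis equals
`plot_length`; diagonal distances are Euclidean. With the default
2 m x 1 m plots and the long edge shared between Ranges, long-edge
neighbours are 1 m apart and short-edge neighbours 2 m.

Weights, all equal to 1 for adjacent long-edge neighbours:

* `NN-long`: 1 for long-edge neighbours, else 0;
* `NN-all`: 1 / 0.5 / 0.2 for long-edge / short-edge / diagonal;
* `FD(k)`: `w = k / (D + k - 1)`, `k` on a default grid
  {0.1, 0.2, 0.4, 1, 2}; `k = 0.4` approximates `1/D^2` and `k = 1` is
  exactly `1/D` (so the "proportional to inverse distance" variant needs
  no separate implementation);
* `SD(c, b, Dmax)`: `w = 1 / (c + b^(1/D))` for `D <= Dmax`, else 0,
  with `c + b = 1`, default `b` grid {0.1, 0.01, 0.001} and `Dmax` in
  {5, 10} m. The form is a modified logistic in `1/D`: it equals 1 at
  adjacency, decays slowly towards `1/(c+1)`, and keeps >60% intensity
  at 5 m for every default `(c, b)` pair. (The algebraically tempting
  alternative `1/(c + b/D)` *increases* with distance and exceeds 1, so
  it cannot be a decay rule; the adopted reading is the one consistent
  with a slow decay that is terminated at a cutoff.)

All plot pairs with positive weight and `D <= Dmax` contribute,
including pairs of plots carrying the same clone (self-competition
across plots is real competition for resources). Missing grid cells
simply contribute nothing; no reweighting is applied for missing or
dead plants — such deviations are what the competition error term is
for.

## REML estimation

The marginal covariance is a linear combination of precomputable
matrices,

    V = sg2 Z1KZ1' + sgc (Z1KZ2' + Z2KZ1') + sc2 Z2KZ2'
      + sp2 II II' + spr (II + II') + ss2 S + sr2 I,

so one likelihood evaluation costs one n x n Cholesky factorisation.
The restricted log-likelihood (intercept profiled out by GLS, all
constants kept so nested models are comparable) is maximised with
L-BFGS-B on transformed coordinates: `log sigma2` for variances and
`atanh(rho)` (bounded at |rho| < 0.999) for the two block correlations,
which keeps both 2 x 2 covariance blocks positive definite by
construction. Defaults: 5 starting points (one variance-equipartition
heuristic plus seeded perturbations), convergence tolerance 1e-6 on the
log-likelihood, variances floored at 1e-10 (a fit at the floor reads as
"effectively zero" — residual variance can legitimately collapse when
competition absorbs nearly everything). Proposals where V is not
positive definite are rejected with a large penalty. Degenerate inputs
(constant response, all restarts failing) return a result flagged
`converged=False`; the evaluation layer counts such failures instead of
raising.

BLUPs are `u_hat = Cov(u, y) V^-1 (y - mu_hat)`. When a fit is
restricted to a training subset of plots (cross-validation), held-out
plots are predicted as
`mu + Z1 g_hat + Z2 c_hat + II[test, train] p_hat + s_hat`, i.e.
competition-error and spatial effects propagate from training plots
through the cross incidence.

Model comparison uses the chi-square likelihood-ratio test at
alpha = 0.1 with the conventional thresholds 2.706 (1 extra component)
and 4.605 (2 extra components); no boundary mixture correction is
applied. REML likelihoods are comparable because the fixed-effect part
(intercept only) is identical across the nested models.

## Kinship

`K` is the centred cross-product (VanRaden method 1)
`W W' / (2 sum p(1-p))` from SNP dosages after discarding markers with
minor allele frequency <= 1% (strictly-greater retention) and
mean-imputing missing dosages per marker. A 1e-6 ridge is added to the
diagonal wherever `K` must be factored.

## Evaluation machinery

* **Outlier screening**: one pass; plots whose Base-model residual
  `y - (mu + Z1 g_hat)` exceeds 2.5 estimated error SDs are dropped
  before any model comparison.
* **Cross-validation**: 10 folds, 5 repeats by default. Folds partition
  *plots* (in a largely unreplicated trial plot folds and clone folds
  nearly coincide, and checks appear in several folds by design); the
  partition is a seeded permutation, identical for every candidate.
  `pRMSE` and `pCOR` pool all held-out predictions over folds and
  repeats. Constant predictions give `pCOR = 0` with a warning.
* **Relative changes**: `100 (pRMSE_base - pRMSE_model)/pRMSE_base` and
  `100 (pCOR_model - pCOR_base)/(1 - pCOR_base)`.
* **Heritability**: Cullis `h2 = 1 - Vbar_Delta / (2 sg2)` with
  `Vbar_Delta` the mean over genotype pairs of the prediction-error
  variance of BLUP differences, computed from the PEV matrix
  `sg2 K - C P C'` (the route is a design choice; clipped to [0, 1]).
* **Selection**: lowest pooled pRMSE wins (ties break towards Base,
  then candidate order); the winner gets an LRT against Base on the
  full data plus both heritabilities and per-model total phenotypic
  variance (sum of active variance components, covariances excluded).
* **Workflow order for the spatial extension**: fit Model 4; if its
  spatial component is significant against Base, refit the selected
  competition model with the spatial term added (Model 5), re-estimating
  all components jointly. Structure selection for `S` itself is out of
  scope; exponential-isotropic, AR1xAR1 and user matrices are provided.

## Simulation engine

Phenotypes are built as `Y = Z1 g + Z2 c + II p + r` (zero mean) with
effects drawn by applying the Cholesky factor of the 2 x 2 covariance
block and then of `K` to i.i.d. standard normals. Scenario parameters,
with `sg2 = 1` fixed:

* `gr = sg2 / (sg2 + sc2 + se2)` in {0.3, 0.7}: the direct-genetic
  share, so `se2 = (1 - gr)/gr - sc2` (configurations leaving
  `se2 <= 0` are rejected by name);
* `sc2` grids {0.1, 0.2, 0.3, 0.4} at `gr = 0.7` and
  {0.1, 0.25, 0.5, 0.75, 1} at `gr = 0.3` (end points as in the study design, with
  steps chosen evenly);
* `Gcor` in {0, 0.4}, applied as `sgc = Gcor sqrt(sg2 sc2)` so it is a
  genuine correlation;
* `Ecor` in {0, 0.8} and `fraE` in {0.3, 0.5, 0.7, 0.9}:
  `sp2 = fraE se2`, `sr2 = (1 - fraE) se2`;
* generating `Z2` function: NN-long or SD(b = 0.1, Dmax = 5) — the SD
  parameter pair is a package default (the first pair of the grid); `II`
  always uses NN-long; plots are 2 m x 1 m;
* replication: checks twice plus tests once / a random half of tests
  twice / everything twice; plots filled row-major in seeded random
  order on a roughly square field (a package default; any real layout
  can be supplied instead).

The default pool is 829 genotypes including 11 checks, with kinship
from synthetic Hardy-Weinberg markers (1000 markers, allele frequencies
uniform in [0.05, 0.5], optional full-sib family blocks). The synthetic
generator reproduces the *structure* of a breeding trial (unreplicated
tests, interspersed checks, marker-derived kinship, family blocks) but
not linkage disequilibrium, selection history or the spatial trends of
real fields — so passing tests demonstrate correct model behaviour
under the assumed generative process, not field-trial realism.

## Scaled-down study reproduction

The full study grid (9 `sc2` x 2 `Gcor` x 2 `Ecor` x 4
`fraE` x 3 replication levels, 20 replicates, 829 genotypes) is
runnable via `scenario_grid()` but deliberately not the default. The
package's study configuration (`reduced_scenario_grid()`) keeps the
axes that drive direct-effect accuracy — both `gr` levels with their
full `sc2` grids and both `Gcor` levels — and fixes `Ecor = 0`,
`fraE = 0.5`, unreplicated layout, 400 genotypes, 5 replicates. On this
grid the matched NN analysis of NN-simulated data gains a median ~6%
accuracy over Base. For SD-simulated data the matched-model gain is far
larger (median ~55%, and larger still with replicated layouts): with
`Dmax = 5` on 2 x 1 m plots every plot has ~30-40 neighbours at weight
>= 0.65, so the competitive term dominates the phenotypic variance,
Base accuracy collapses, and the relative recovery is large. This is a
faithful consequence of the generative recipe under a synthetic
kinship; with a real trial's geometry and kinship the magnitude can be
substantially smaller.

## Known limitations

* Single-trait models only; no AR1-residual competition structures and
  no Bayesian estimation.
* No within-plot (intraplot) competition and no non-rectangular fields.
* The FD family only drops below 25% intensity beyond 5 m for small
  `k` (at `k = 2`, `w(5) = 1/3`); the grid end points are kept anyway
  since the family is defined by its formula, not by that rule of
  thumb.
* Numerical REML: multi-start L-BFGS-B is robust in practice but not
  guaranteed global; nesting tests tolerate 1e-4 slack in the
  log-likelihood.
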