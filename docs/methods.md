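# Methods

## The problem

A continuous functional trait (the motivating case is leaf mass per area,
analyzed as the per-species mean of log-transformed records, `l`) is observed
at the tips of a dated phylogeny. The questions are (i) how much phylogenetic
signal the trait carries relative to a phylogeny-independent null and to
Brownian-motion expectation, (ii) whether its evolution is better described
by drift alone or by drift plus stabilizing selection toward one or several
clade-specific optima, and (iii) at which nodes trait divergence between
daughter clades was unusually large (diversifying) or small (conservative).

## Tree model and dating

A `Phylogeny` is a rooted tree with polytomies; after dating, every node
carries an absolute age in Myr (tips at 0) and branch lengths are *derived*
as parent age minus child age, never stored independently. Pairwise
divergence time between two species is defined as the age of their most
recent common ancestor, so the Brownian covariance structure is
`V_ij = root_age − mrca_age(i, j)` (shared time from the root).

**bladj-style interpolation.** Anchored internal nodes (matched by internal
label, case-sensitive; duplicate labels are an error) keep their ages
exactly; the root must be anchored. Interpolation proceeds in preorder: when
an undated node with a dated parent is reached, the maximal chain of undated
nodes from it down to the nearest dated descendant — choosing, when several
exist, the path with the most intervening nodes, which is the even-spacing /
minimum-branch-length-variance intent — is assigned evenly spaced ages
between the two dated endpoints and those ages then act as anchors for any
side branches. We chose this sequential-chain rule over assigning each node
independently against its own deepest path because the independent variant
can invert ages where a branching undated region is flanked by dated
descendants of different ages; the sequential rule is monotone by
construction. Anchor-forced zero-length branches are permitted with a
warning. Re-running the interpolation with the same anchors is a no-op.

## Treewise signal statistics

All three statistics work directly on the tree covariance matrix, so
polytomies need no resolution.

- **Blomberg's K** = (MSE0/MSE) / E_BM[MSE0/MSE], with the GLS ancestral mean,
  MSE0 the ordinary and MSE the phylogenetically weighted mean square, and
  the Brownian expectation `(tr V − n/(1'V⁻¹1))/(n−1)`. Significance is a
  one-tailed tip-permutation test with (r+1)/(B+1) smoothing; the default is
  999 permutations.
- **Pagel's λ** multiplies the off-diagonal of V. The profile log-likelihood
  (mean and σ² concentrated out) is maximized on [0, 1] with a bounded scalar
  search (tolerance 1e-6); λ > 1 can be allowed explicitly but is off by
  default because V(λ) need not stay positive definite. For ultrametric trees
  V(λ) = λV + (1−λ)T·I shares eigenvectors with V, so one eigendecomposition
  makes each likelihood evaluation O(n); non-constant diagonals fall back to
  a Cholesky per evaluation. Likelihood-ratio tests against λ = 0 and λ = 1
  are reported with χ²(1) p-values (anticonservative at the λ = 1 boundary;
  the statistics are reported so users can recalibrate).
- **Moran's I** = (n/S0)·Σ w_ij z_i z_j / Σ z_i², null expectation −1/(n−1).
  The overall statistic uses inverse-divergence-time weights w_ij = 1/d_ij;
  the correlogram uses binary class-membership weights. The field does not
  agree on a single weighting, so both modes are exposed and recorded in the
  result object.

**Correlogram classes.** Default bins are equal-width in divergence time on
(0, root age], merged left-to-right until each class holds at least the
target pair count (default 100). We deliberately do not use equal-pair-count
(quantile) bins: on supertree-shaped phylogenies most pairs coalesce at a few
deep nodes, so quantile edges collapse onto the root age and destroy exactly
the recent-time resolution where similarity decays fastest. Each unordered
pair falls in exactly one class (lo, hi].

**Decay shape.** Linear `I(t) = a + b·t` and exponential
`I(t) = a·e^(−b·t) + c` fits are least squares on class midpoints; Gaussian
log-likelihoods come from the residual sums of squares. Because the
exponential carries one parameter more, it is preferred only when
2ΔlogLik > χ²(1) at the 5% level; with equal RSS the comparison degenerates
to the higher likelihood. A linear decline of similarity with time is the
Brownian expectation; an exponential decline indicates drift plus
stabilizing selection. A non-converged exponential fit falls back to linear
with a flag.

## Trait-evolution models

The OU process `dl = −α(l − θ)dt + σ dB` has tip expectation
`E[l_i] = e^(−αT)·θ_root + Σ_branches θ_b (e^(−α·age_end) − e^(−α·age_start))`
(path weights summing to 1) and covariance
`Cov_ij = σ²/(2α)·e^(−α d_ij)(1 − e^(−2α t_a))` with t_a the shared time and
d_ij the tip-to-tip time distance; both reduce to the BM limit as α → 0
(computed through `expm1`, so small α is numerically safe). Regimes are
painted per branch and switch only at nodes; a repainted clade's stem branch
carries the new regime (the OUCH convention). The root state is fixed at the
root regime's optimum — one parameter fewer, and the natural choice when the
root regime is the background — with a `free_root` option.

**Fitting.** Optima are profiled out by GLS and σ² concentrated, leaving a
1-D likelihood in α maximized on a 24-point log grid over [1e-6, 10] Myr⁻¹
followed by bounded refinement (tolerance 1e-8; the procedure is
deterministic). Single-regime fits also evaluate the exact α = 0 boundary so
that the likelihood nesting logLik(OUk) ≥ logLik(OU1) ≥ logLik(BM) holds
sharply. Parameter counts: PI and BM 2, OUk k + 2. BIC = k·ln(n) − 2·logLik.
Phylogenetic half-life is t½ = ln 2 / α (infinite at α = 0). Percent of null
deviance explained is the variance-based form
`100·(1 − Σ(l − Ê[l])²/Σ(l − l̄)²)` on the fitted expectations; logLik is
reported alongside so a likelihood-based version can be reconstructed. All
covariance algebra is dense (O(n³) per likelihood evaluation), which is the
intended regime for trees up to a few thousand tips; no pruning-based fast
path is provided.

## Node-level divergence

Ancestral means follow the Felsenstein averaging scheme generalized to
polytomies: post-order, each internal node's value is the average of its
child values weighted by inverse child branch length (zero-length branches
capped at weight 1/ε with ε = 1e-8 × root age). The divergence width DW at a
node is the sample standard deviation (k − 1 denominator) of its k child
values, unstandardized by default — consistent with DW ≈ 0 at equal child
means — with an option to divide by √(mean child branch length) to discount
the spread expected from longer branches.

Significance is a permutation test against the PI null: trait values are
shuffled across tips and all nodes are evaluated in one vectorized pass per
shuffle. Two one-tailed, (r+1)/(B+1)-smoothed p-values are kept per node
(diversifying: DW_perm ≥ DW_obs; conservative: ≤), each family is
Benjamini–Hochberg adjusted separately, and nodes are labelled at the chosen
FDR (smaller q wins if both directions pass; an exact tie is ns with a
warning). An exhaustive mode enumerates all n! assignments on tiny trees and
is what the test-suite oracle compares against. Note the BH floor: with B
permutations and m nodes the smallest attainable q is m/(B+1), so genome- or
phylogeny-wide scans need B ≫ 20·m — the default of 10³ permutations is for
interactive use, and the CLI default of 10⁵ is the serious setting.

## Synthetic data: what it does and does not emulate

The generator reproduces the statistical structure the analysis assumes, at
defaults chosen once to mirror a large vascular-plant LMA compilation:

| parameter | default | rationale |
|---|---|---|
| n_tips | 200 | desk-scale stand-in for a multi-thousand-species tree |
| root_age | 100 Myr | order of angiosperm crown ages |
| polytomy_fraction | 0.42 | supertrees resolve roughly 58% of nodes as bifurcations |
| α | 0.05 Myr⁻¹ | half-life ≈ 14 Myr, weak stabilizing selection |
| σ | 1 (log units · Myr⁻½) | stationary SD σ/√(2α) ≈ 3.2 log units |
| θ | 4 (log g·m⁻²) | ≈ 55 g·m⁻², mid-range LMA |
| regime↔growth-form match | 0.9 | growth form strongly tracks selective regime |
| replicates / within-SD | 3 × 0.15 | among-species variance ≫ within-species |

Tree shapes are Yule (or Kingman-coalescent) draws rescaled to the root age;
the requested fraction of internal nodes is collapsed into polytomies,
shortest internal branches first. The simulator stops birth–death growth one
tip late and prunes the newest tip, because stopping exactly at the n-th
speciation leaves a zero-length terminal cherry (singular covariance,
undefined inverse-time weights). Trait values are exact multivariate-Gaussian
draws from the model covariance (Cholesky), not Euler SDE paths, so
parameter-recovery tests are sharp; an Euler integrator appears only as a
test oracle for the OU expectation. Replicates add iid log-scale noise and
are stored on the raw scale.

Not emulated: diversification with extinction, sampling biases of real trait
compilations (phylogenetically clustered missingness, site effects
correlated with climate), measurement error structure beyond iid log-normal
replicates, and realistic taxonomy. Passing calibration and recovery tests
on these simulations therefore shows the estimators are correct and well
calibrated under the stated model, not that real data satisfy that model.

## Pipeline conventions

Variance partition is on raw-scale values: V_among is the variance of
species means, V_within the mean of per-species variances (single-record
species count as 0); this is the plain descriptive decomposition, not pooled
ANOVA mean squares. Family summaries keep families with more than 10 sampled
species and report OLS r² of family mean trait vs woody proportion and of
herbaceous vs woody family means; degenerate regressions (zero predictor
variance) are flagged rather than computed. Signal and model computations
always use the log scale; descriptive summaries the raw scale. Growth-form
subset analyses prune the tree to the subset and re-run the signal stack
with PI/BM/OU1 fits; multi-optimum paintings are defined on the full tree
and are not automatically re-painted onto subsets.

## Problem sizes used in the checks

The test suite and `scripts/acceptance.py` run on simulated trees of 200–300
tips with 50–1000 replicate datasets per check and 999–9999 permutations per
test (9999 where BH-corrected recovery is asserted, see the BH floor above).
These sizes keep every distributional check well inside its Monte-Carlo
tolerance while remaining desk-scale.

## Known limitations

- Dense linear algebra bounds practical tree size (~few thousand tips).
- λ̂ is reported on [0, 1] by default; traits with λ > 1 structure hit the
  boundary.
- LRT p-values at parameter-space boundaries (λ, α at 0) use χ²(1) and are
  conservative-to-anticonservative depending on the boundary; permutation
  tests are provided where calibration matters.
- The DW statistic is unstandardized by default; on very unbalanced branch
  lengths the standardized option changes which nodes rank as extreme.
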