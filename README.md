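# traitevo

Phylogenetic comparative analysis of continuous trait evolution across large
plant phylogenies — built around the kind of question asked of leaf mass per
area (LMA, g·m⁻²): is a functional trait evolutionarily labile, or conserved
along lineages under stabilizing selection, and does that differ between
growth forms?

The package is aimed at comparative ecologists and macroevolution researchers
who work with supertree-style phylogenies (polytomies, sparse age anchors)
and species-level trait compilations with replicate records. It provides:

- **Tree handling and dating** — Newick I/O with polytomies, phylocom-style
  *bladj* age interpolation (undated nodes spaced evenly between dated
  anchors and tips of age 0), pairwise divergence times as MRCA ages, and
  growth-form subsetting by tree pruning.
- **Treewise phylogenetic signal** — Blomberg's *K* (K ≈ 1 under Brownian
  motion, K > 1 for stronger conservatism), Pagel's *λ* (0 = phylogeny
  independent, 1 = Brownian), and Moran's *I* with null expectation
  −1/(n−1), plus correlograms of *I* across divergence-time classes with
  linear-vs-exponential decay comparison.
- **Models of trait evolution** — maximum-likelihood fits of a
  phylogeny-independent (PI) null, Brownian motion (dl = σ dB), and
  Ornstein–Uhlenbeck processes dl = −α(l − θ)dt + σ dB with one or several
  clade-specific optima θ painted on branches; BIC ranking, phylogenetic
  half-life t½ = ln 2⁄α, and percent of null deviance explained.
- **Node-level divergence analysis** — Felsenstein ancestral means, the
  divergence-width statistic DW (SD of child-clade means), permutation tests
  against the PI null, Benjamini–Hochberg correction, and classification of
  nodes as diversifying or conservative.
- **Synthetic data** — dated ultrametric trees with a realistic polytomy
  share, traits drawn from the exact model covariance, growth forms
  correlated with selective regimes, and within-species replicates.

## Worked example

Simulate a 200-species dated phylogeny and an LMA-like log-trait evolving
under stabilizing selection (α = 0.05 Myr⁻¹, σ = 1, θ = 4), then quantify
signal and compare models:

```python
import traitevo as te

tree = te.simulate_tree(n_tips=200, root_age=100.0, seed=42)
traits, _ = te.simulate_trait(tree, trait_model="OU", alpha=0.05,
                              sigma=1.0, thetas=(4.0,), seed=42)

k   = te.blomberg_k(tree, traits, n_perm=999, seed=0)
lam = te.pagel_lambda(tree, traits)
i   = te.moran_i(te.divergence_time_matrix(tree), traits, n_perm=999, seed=0)
print(f"K = {k.estimate:.3f} (p = {k.p_value:.3f}), lambda = {lam.estimate:.3f}, "
      f"I = {i.estimate:.4f} (E[I] = {i.null_expectation:.4f})")

fits = [te.fit_model(tree, traits, m) for m in ("PI", "BM", "OU1")]
print(te.compare_models(fits).round(2))
ou1 = fits[2]
print(f"alpha = {ou1.alpha:.4f} /Myr, half-life = {ou1.half_life:.1f} Myr")
```

prints

```
K = 0.182 (p = 0.001), lambda = 0.670, I = 0.0772 (E[I] = -0.0050)
  model  k  loglik     bic  delta_bic
0   OU1  3 -450.33  916.56       0.00
1    PI  2 -476.14  962.87      46.31
2    BM  2 -477.86  966.32      49.76
alpha = 0.0641 /Myr, half-life = 10.8 Myr
```

The low K with a significant permutation p and a positive Moran's I say the
trait is weakly but significantly conserved; the OU1 fit beating both the
star-phylogeny null and Brownian motion by ~46–50 BIC points says the pattern
is better described by drift plus attraction to an optimum than by drift
alone, and the fitted α corresponds to a ~11 Myr half-life — close to the
generating value ln 2 / 0.05 ≈ 13.9 Myr.

A command-line interface mirrors the library:

```bash
traitevo date-tree --tree t.nwk --ages ages.txt --out dated.nwk
traitevo signal --tree dated.nwk --traits lma.csv --perms 999 --seed 42 --out signal.json
traitevo fit --tree dated.nwk --traits lma.csv --models PI,BM,OU1 --out fits.json
traitevo divergences --tree dated.nwk --traits lma.csv --perms 100000 --seed 7 --out dw.csv
traitevo run --config analysis.yaml --out report/
```

## Layout

```
src/traitevo/phylo.py       tree model, Newick/ages I/O, bladj dating, divergence times
src/traitevo/traits.py      trait tables (raw records + per-species log means)
src/traitevo/signal.py      K, lambda, Moran's I, correlograms, decay fits
src/traitevo/models.py      PI/BM/OU likelihoods, regime paintings, BIC
src/traitevo/divergence.py  ancestral means, DW, permutation tests, FDR classes
src/traitevo/simulate.py    synthetic trees, paintings, traits, benchmark suite
src/traitevo/pipeline.py    variance partition, family summaries, full analysis
src/traitevo/cli.py         `traitevo` command-line entry point
docs/methods.md             model and design notes
```
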