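"""Synthetic trees, regime paintings, traits, growth forms and replicates.

The generator emulates the data structure the analysis assumes: a dated
ultrametric phylogeny with a realistic share of polytomies, log-trait values
evolved under PI / BM / multi-regime OU, a growth-form covariate correlated
with the regime painting, and within-species replicate records whose variance
is small relative to the among-species variance.  Trait values are drawn from
the exact multivariate Gaussian implied by the model (Cholesky of the model
covariance), not from an SDE discretization, so parameter-recovery tests are
sharp.
"""
from __future__ import annotations

import json
import random
from dataclasses import asdict, dataclass
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from .models import RegimePainting, _ou_structure, auto_clade_painting, ou_moments
from .phylo import Phylogeny, _from_dendropy, divergence_time_matrix, subset_tips, write_newick
from .traits import TraitTable

__all__ = ["SimConfig", "simulate_tree", "simulate_trait", "planted_shift_dataset", "make_benchmark_suite"]


@dataclass
class SimConfig:
    """Study conditions for the synthetic generator.

    Defaults mirror the structure of a large comparative LMA dataset: a dated
    ultrametric tree with 42% of internal nodes polytomous, log-scale trait
    values around θ = 4 (≈ 55 g·m⁻²), OU attraction α = 0.05 Myr⁻¹
    (half-life ≈ 14 Myr), drift σ = 1, a growth-form covariate matching the
    selective regime 90% of the time, and 3 within-species records whose
    log-scale spread (0.15) is far below the among-species spread.
    """

    seed: int = 0
    n_tips: int = 200
    tree_model: str = "yule"  # or "coalescent"
    root_age: float = 100.0
    polytomy_fraction: float = 0.42
    trait_model: str = "BM"  # PI | BM | OU
    n_regimes: int = 1
    alpha: float = 0.05
    sigma: float = 1.0
    thetas: tuple[float, ...] = (4.0,)
    regime_form_match_prob: float = 0.9
    n_replicates: int = 3
    within_sd: float = 0.15

    def __post_init__(self):
        if not 0.0 <= self.polytomy_fraction <= 0.5:
            raise ValueError("polytomy_fraction must lie in [0, 0.5]")
        if self.alpha < 0 or self.sigma < 0 or self.within_sd < 0:
            raise ValueError("rates and spreads must be >= 0")
        if self.trait_model == "OU" and len(self.thetas) != self.n_regimes:
            raise ValueError("need one theta per regime")


def simulate_tree(
    n_tips: int = 200,
    root_age: float = 100.0,
    polytomy_fraction: float = 0.42,
    tree_model: str = "yule",
    seed: int | None = None,
) -> Phylogeny:
    """Dated ultrametric tree with the requested polytomy share.

    A Yule (pure-birth) or Kingman-coalescent shape is drawn, root depth is
    rescaled to ``root_age``, and the requested fraction of internal nodes is
    collapsed into polytomies, shortest internal branches first.
    """
    if n_tips < 3:
        raise ValueError("need at least 3 tips")
    if not 0.0 <= polytomy_fraction <= 0.5:
        raise ValueError("polytomy_fraction must lie in [0, 0.5]")
    pyrng = random.Random(None if seed is None else int(seed))
    if tree_model == "yule":
        # one extra tip: the simulator stops at the n-th speciation, which
        # leaves a zero-length terminal cherry; the newest tip is pruned below
        dtree = dendropy.model.birthdeath.birth_death_tree(
            birth_rate=1.0,
            death_rate=0.0,
            num_extant_tips=n_tips + 1,
            rng=pyrng,
        )
    elif tree_model == "coalescent":
        taxa = dendropy.TaxonNamespace([f"s{i:04d}" for i in range(1, n_tips + 1)])
        dtree = dendropy.simulate.treesim.pure_kingman_tree(
            taxon_namespace=taxa, pop_size=1.0, rng=pyrng
        )
    else:
        raise ValueError(f"unknown tree model {tree_model!r}")
    tree = _from_dendropy(dtree)
    for i, tip in enumerate(tree.tips, start=1):
        tip.label = f"tmp{i}"
    for node in tree.internal_nodes:
        node.label = None
    tree.date_from_branch_lengths(tol=1e-3)
    if tree.n_tips > n_tips:
        newest = min(tree.tips, key=lambda t: (t.parent.age, t.label))
        tree = subset_tips(tree, [t.label for t in tree.tips if t is not newest])
    for i, tip in enumerate(tree.tips, start=1):
        tip.label = f"s{i:04d}"
    scale = root_age / tree.root_age
    for node in tree.preorder():
        node.age *= scale
    tree.set_lengths_from_ages()

    n_internal = len(tree.internal_nodes)
    n_collapse = round(polytomy_fraction * n_internal)
    if n_collapse > n_internal - 1:
        raise ValueError("polytomy fraction leaves no internal structure")
    if n_collapse:
        collapsible = sorted(
            (n for n in tree.internal_nodes if not n.is_root),
            key=lambda nd: (nd.parent.age - nd.age, nd.index),
        )
        for node in collapsible[:n_collapse]:
            parent = node.parent
            i = parent.children.index(node)
            parent.children[i : i + 1] = node.children
            for c in node.children:
                c.parent = parent
        tree.reindex()
        tree.set_lengths_from_ages()
    return tree


def _assign_growth_forms(
    painting: RegimePainting, match_prob: float, rng: np.random.Generator
) -> pd.Series:
    """Growth form per tip, matching the tip's regime class with probability
    ``match_prob``.  Even regimes map to the woody class, odd to herbaceous."""
    tip_regimes = painting.tip_regimes()
    forms = {}
    for label, regime in tip_regimes.items():
        woody = regime % 2 == 0
        if rng.random() >= match_prob:
            woody = not woody
        pool = ("shrub", "tree") if woody else ("forb", "graminoid")
        forms[label] = pool[rng.integers(2)]
    return pd.Series(forms)


def simulate_trait(
    tree: Phylogeny,
    config: SimConfig | None = None,
    painting: RegimePainting | None = None,
    seed: int | None = None,
    **overrides,
) -> tuple[TraitTable, RegimePainting]:
    """Trait table (with growth forms and replicates) simulated on ``tree``.

    Species-level log values are exact draws from the model's multivariate
    Gaussian; replicate records add iid within-species noise on the log scale
    and are stored on the raw (exponentiated) scale.
    """
    if config is None:
        config = SimConfig(**overrides)
    elif overrides:
        config = SimConfig(**{**asdict(config), **overrides})
    rng = np.random.default_rng(
        np.random.SeedSequence([config.seed if seed is None else int(seed)])
    )
    n = tree.n_tips
    if painting is None:
        if config.trait_model == "OU" and config.n_regimes > 1:
            painting = auto_clade_painting(tree, config.n_regimes, config.thetas)
        else:
            painting = RegimePainting.single(tree, config.thetas[0])
    if config.trait_model == "PI":
        l = config.thetas[0] + config.sigma * rng.standard_normal(n)
    elif config.trait_model == "BM":
        V = config.sigma**2 * _ou_structure(tree, 0.0)
        l = config.thetas[0] + np.linalg.cholesky(V) @ rng.standard_normal(n)
    elif config.trait_model == "OU":
        mu, V = ou_moments(tree, config.alpha, config.sigma, painting)
        L = np.linalg.cholesky(V + 1e-12 * np.eye(n))
        l = mu + L @ rng.standard_normal(n)
    else:
        raise ValueError(f"unknown trait model {config.trait_model!r}")

    forms = _assign_growth_forms(painting, config.regime_form_match_prob, rng)
    rows = []
    labels = tree.tip_labels
    reps = max(config.n_replicates, 1)
    noise = rng.normal(0.0, config.within_sd, size=(n, reps)) if reps > 1 else np.zeros((n, 1))
    for i, sp in enumerate(labels):
        for j in range(reps):
            rows.append(
                {
                    "species": sp,
                    "value": float(np.exp(l[i] + noise[i, j])),
                    "growth_form": forms[sp],
                    "site": f"site{j + 1}",
                }
            )
    return TraitTable(pd.DataFrame(rows)), painting


def planted_shift_dataset(
    n_tips: int = 200,
    shift_sds: float = 3.0,
    alpha: float = 0.05,
    sigma: float = 1.0,
    theta: float = 4.0,
    root_age: float = 100.0,
    seed: int = 0,
    tree: Phylogeny | None = None,
):
    """OU dataset with a single ancient regime shift of ``shift_sds`` stationary
    SDs planted on the branch to a deterministic internal node (the oldest
    non-root node whose clade holds 20–50% of the tips).

    Returns (tree, traits, painting, divergence node) — the divergence node is
    the *parent* of the repainted clade, i.e. the node whose daughter clades
    evolve toward different optima and whose DW should flag as diversifying.
    """
    if tree is None:
        tree = simulate_tree(n_tips=n_tips, root_age=root_age, seed=seed)
    sizes: dict = {}
    for node in tree.postorder():
        sizes[node] = 1 if node.is_tip else sum(sizes[c] for c in node.children)
    n = tree.n_tips
    candidates = [
        nd
        for nd in tree.internal_nodes
        if not nd.is_root and 0.2 * n <= sizes[nd] <= 0.5 * n
    ]
    if not candidates:
        candidates = [nd for nd in tree.internal_nodes if not nd.is_root]
    shift_node = max(candidates, key=lambda nd: (nd.age, -nd.index))
    sd_stat = sigma / np.sqrt(2 * alpha)
    painting = RegimePainting.from_clades(
        tree,
        [(shift_node, 1)],
        thetas={0: theta, 1: theta + shift_sds * sd_stat},
    )
    traits, _ = simulate_trait(
        tree, trait_model="OU", n_regimes=2, alpha=alpha, sigma=sigma,
        thetas=(theta, theta + shift_sds * sd_stat), painting=painting, seed=seed,
    )
    return tree, traits, painting, shift_node.parent


SUITE_VERSION = "1"


def make_benchmark_suite(seed: int, out_dir: str | Path) -> Path:
    """Write a versioned directory of small text fixtures for every stage.

    Contents: a 10-tip hand-checkable tree with traits and its divergence-time
    table; 200-tip BM / OU1 / OU3 datasets (tree + traits + regimes); a
    planted-divergence dataset; and an undated tree plus ages file exercising
    chain interpolation.  Regenerating with the same seed reproduces the files
    byte for byte.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": SUITE_VERSION, "seed": int(seed), "files": []}

    def save(name: str, text: str) -> None:
        (out / name).write_text(text)
        manifest["files"].append(name)

    # 10-tip hand-checkable fixture
    small = simulate_tree(n_tips=10, root_age=10.0, polytomy_fraction=0.2, seed=seed)
    small_traits, _ = simulate_trait(small, trait_model="BM", seed=seed, n_replicates=1)
    save("small_tree.nwk", write_newick(small) + "\n")
    save("small_traits.csv", small_traits.data.to_csv(index=False))
    save(
        "small_divergence_times.csv",
        divergence_time_matrix(small).round(6).to_csv(),
    )

    # 200-tip model datasets
    sd_stat = 1.0 / np.sqrt(2 * 0.05)
    specs = {
        "bm200": dict(trait_model="BM"),
        "ou1_200": dict(trait_model="OU", n_regimes=1, thetas=(4.0,)),
        "ou3_200": dict(
            trait_model="OU",
            n_regimes=3,
            thetas=(4.0, 4.0 + 2 * sd_stat, 4.0 - 2 * sd_stat),
        ),
    }
    for i, (name, kw) in enumerate(specs.items()):
        tree = simulate_tree(n_tips=200, root_age=100.0, seed=seed + i)
        traits, painting = simulate_trait(tree, seed=seed + i, **kw)
        save(f"{name}_tree.nwk", write_newick(tree) + "\n")
        save(f"{name}_traits.csv", traits.data.to_csv(index=False))
        if painting.n_regimes > 1:
            lines = ["# node_index\tregime\ttheta"]
            for idx, reg in sorted(painting.branch_regime.items()):
                lines.append(f"{idx}\t{reg}\t{painting.thetas[reg]:.6f}")
            save(f"{name}_regimes.tsv", "\n".join(lines) + "\n")

    # planted divergence
    tree, traits, painting, node = planted_shift_dataset(seed=seed)
    save("planted_tree.nwk", write_newick(tree) + "\n")
    save("planted_traits.csv", traits.data.to_csv(index=False))
    save("planted_shift_node.txt", f"node_index\t{node.index}\n")

    # bladj exercise: fixed topology with deliberate undated chains
    save(
        "bladj_tree.nwk",
        "((((A,B)n4,C)n3,D)n2,((E,F)n6,G)n5)root;\n",
    )
    save("bladj_ages.txt", "# label age\nroot 10\nn4 2\n")

    manifest["files"].sort()
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return out
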