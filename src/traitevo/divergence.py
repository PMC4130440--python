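"""Node-level trait divergence: ancestral means, divergence width (DW),
permutation nulls against phylogenetic independence, and FDR classification
of nodes as diversifying or conservative.
"""
from __future__ import annotations

import itertools
import math
import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .phylo import Node, Phylogeny
from .traits import aligned_values

__all__ = [
    "ancestral_means",
    "divergence_width",
    "dw_permutation_test",
    "bh_adjust",
    "classify_divergences",
]


def _node_name(node: Node) -> str:
    return node.label if node.label is not None else f"node{node.index}"


def _weights_structure(tree: Phylogeny, eps_factor: float = 1e-8):
    """Flattened post-order structure for vectorized ancestral-mean passes.

    Returns (internal nodes in post-order, per-node child row indices into the
    combined [tips | internals] value array, per-node inverse-branch-length
    weights, per-node clade sizes).  Zero-length child branches get weight
    1/ε with ε = ``eps_factor`` × root age.
    """
    tips = tree.tips
    tip_row = {t: i for i, t in enumerate(tips)}
    internals = [n for n in tree.postorder() if not n.is_tip]
    int_row = {n: len(tips) + j for j, n in enumerate(internals)}
    scale = tree.root_age if tree.is_dated else 1.0
    eps = eps_factor * max(scale, 1e-300)
    child_rows, child_weights, clade_sizes = [], [], []
    size: dict[Node, int] = {t: 1 for t in tips}
    for node in internals:
        rows = []
        wts = []
        for c in node.children:
            rows.append(tip_row[c] if c.is_tip else int_row[c])
            bl = (node.age - c.age) if tree.is_dated else (c.length or 0.0)
            if bl < 0:
                raise ValueError("negative branch length")
            wts.append(1.0 / max(bl, eps))
        child_rows.append(np.array(rows, dtype=np.intp))
        child_weights.append(np.array(wts) / np.sum(wts))
        size[node] = sum(size[c] for c in node.children)
        clade_sizes.append(size[node])
    return internals, child_rows, child_weights, clade_sizes


def _means_matrix(structure, X: np.ndarray) -> np.ndarray:
    """Ancestral means for each column of X (tips × B) → internals × B."""
    internals, child_rows, child_weights, _ = structure
    vals = np.empty((X.shape[0] + len(internals), X.shape[1]))
    vals[: X.shape[0]] = X
    base = X.shape[0]
    for j in range(len(internals)):
        vals[base + j] = child_weights[j] @ vals[child_rows[j]]
    return vals[base:]


def _dw_matrix(structure, X: np.ndarray) -> np.ndarray:
    """DW (sample SD of child-clade values, ddof=1) per internal node/column."""
    internals, child_rows, child_weights, _ = structure
    means = _means_matrix(structure, X)
    vals = np.vstack([X, means])
    out = np.empty((len(internals), X.shape[1]))
    for j in range(len(internals)):
        out[j] = np.std(vals[child_rows[j]], axis=0, ddof=1)
    return out


def ancestral_means(tree: Phylogeny, traits) -> dict[Node, float]:
    """Felsenstein-style ancestral means, generalized to polytomies.

    Post-order pass: each internal node's value is the weighted average of its
    child values, weights inversely proportional to the child branch lengths.
    Tips carry their own (log-scale) values.
    """
    x = aligned_values(traits, tree)
    structure = _weights_structure(tree)
    means = _means_matrix(structure, x[:, None])[:, 0]
    out: dict[Node, float] = {t: float(v) for t, v in zip(tree.tips, x)}
    out.update({n: float(means[j]) for j, n in enumerate(structure[0])})
    return out


def divergence_width(tree: Phylogeny, traits, standardize: bool = False) -> dict[Node, float]:
    """Divergence width per internal node: sample SD (k−1 denominator) of the
    node's child-clade ancestral means.  Equal child means give DW = 0.

    ``standardize=True`` divides by √(mean child branch length), discounting
    the divergence expected from longer branches under BM.
    """
    x = aligned_values(traits, tree)
    structure = _weights_structure(tree)
    dw = _dw_matrix(structure, x[:, None])[:, 0]
    internals = structure[0]
    if standardize:
        for j, node in enumerate(internals):
            bls = [
                (node.age - c.age) if tree.is_dated else (c.length or 0.0)
                for c in node.children
            ]
            dw[j] /= math.sqrt(max(np.mean(bls), 1e-300))
    return {n: float(dw[j]) for j, n in enumerate(internals)}


def dw_permutation_test(
    tree: Phylogeny,
    traits,
    n_perm: int = 1000,
    seed: int | None = None,
    exhaustive: bool = False,
) -> pd.DataFrame:
    """Two one-tailed permutation tests of DW per node against the PI null.

    Trait values are shuffled across tips; every node is evaluated in one pass
    per shuffle.  p_div = Pr(DW_perm ≥ DW_obs), p_cons = Pr(DW_perm ≤ DW_obs),
    each with (r + 1)/(B + 1) smoothing.  ``exhaustive=True`` enumerates all
    n! tip assignments instead (exact p-values, tiny trees only).
    """
    x = aligned_values(traits, tree)
    structure = _weights_structure(tree)
    internals, _, _, clade_sizes = structure
    dw_obs = _dw_matrix(structure, x[:, None])[:, 0]
    n = x.size
    if exhaustive:
        if n > 8:
            raise ValueError("exhaustive enumeration is limited to <= 8 tips")
        perms = np.array(list(itertools.permutations(range(n))))
        X = x[perms.T]
        dw_perm = _dw_matrix(structure, X)
        p_div = np.mean(dw_perm >= dw_obs[:, None], axis=1)
        p_cons = np.mean(dw_perm <= dw_obs[:, None], axis=1)
        n_used = perms.shape[0]
    else:
        if n_perm < 99:
            raise ValueError("n_perm must be >= 99")
        rng = np.random.default_rng(seed)
        ge = np.zeros(len(internals))
        le = np.zeros(len(internals))
        chunk = 1000
        done = 0
        while done < n_perm:
            b = min(chunk, n_perm - done)
            X = rng.permuted(np.tile(x, (b, 1)), axis=1).T
            dw_perm = _dw_matrix(structure, X)
            ge += np.sum(dw_perm >= dw_obs[:, None], axis=1)
            le += np.sum(dw_perm <= dw_obs[:, None], axis=1)
            done += b
        p_div = (ge + 1) / (n_perm + 1)
        p_cons = (le + 1) / (n_perm + 1)
        n_used = n_perm
    return pd.DataFrame(
        {
            "node_label": [_node_name(nd) for nd in internals],
            "age": [nd.age for nd in internals],
            "clade_size": clade_sizes,
            "dw": dw_obs,
            "p_div": p_div,
            "p_cons": p_cons,
        },
        index=[nd.index for nd in internals],
    ).assign(n_perm=n_used)


def bh_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (input order preserved)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def classify_divergences(records: pd.DataFrame, fdr: float = 0.05) -> pd.DataFrame:
    """Label nodes diversifying / conservative / ns at the given FDR level.

    The two one-tailed p-value families are BH-adjusted separately.  A node
    significant in both directions takes the smaller q (exact tie → ns, with
    a warning).
    """
    out = records.copy()
    out["q_div"] = bh_adjust(out["p_div"].to_numpy())
    out["q_cons"] = bh_adjust(out["p_cons"].to_numpy())
    labels = []
    for q_d, q_c in zip(out["q_div"], out["q_cons"]):
        sig_d, sig_c = q_d <= fdr, q_c <= fdr
        if sig_d and sig_c:
            if q_d == q_c:
                warnings.warn("node significant in both directions with tied q; labelled ns")
                labels.append("ns")
            else:
                labels.append("diversifying" if q_d < q_c else "conservative")
        elif sig_d:
            labels.append("diversifying")
        elif sig_c:
            labels.append("conservative")
        else:
            labels.append("ns")
    out["class"] = labels
    return out
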