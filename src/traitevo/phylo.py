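"""Tree data model, Newick / ages-file I/O, bladj-style node dating and divergence times.

The :class:`Phylogeny` container is deliberately small: nodes carry a label,
parent/child links, a branch length (Myr) and, once the tree has been dated, an
absolute age (Myr before present, tips at 0).  Polytomies are first-class.
Newick parsing is delegated to dendropy; everything downstream works on this
container.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Iterator, Mapping

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "Node",
    "Phylogeny",
    "TreeStats",
    "NewickParseError",
    "AnchorError",
    "read_newick",
    "write_newick",
    "read_ages",
    "bladj_date",
    "divergence_time_matrix",
    "mrca_age_matrix",
    "vcv_matrix",
    "subset_tips",
    "tree_stats",
]


class NewickParseError(ValueError):
    """Raised when a Newick string cannot be parsed into a rooted tree."""


class AnchorError(ValueError):
    """Raised for unresolvable or mutually inconsistent age anchors."""


class Node:
    __slots__ = ("label", "parent", "children", "length", "age", "index")

    def __init__(self, label: str | None = None, length: float | None = None):
        self.label = label
        self.parent: Node | None = None
        self.children: list[Node] = []
        self.length = length
        self.age: float | None = None
        self.index: int = -1

    @property
    def is_tip(self) -> bool:
        return not self.children

    @property
    def is_root(self) -> bool:
        return self.parent is None

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    def __repr__(self) -> str:  # pragma: no cover
        kind = "tip" if self.is_tip else f"internal({len(self.children)})"
        return f"<Node {self.label!r} {kind} age={self.age}>"


class Phylogeny:
    """Rooted phylogeny with optional node ages (Myr, tips = 0)."""

    def __init__(self, root: Node):
        self.root = root
        self._validate()
        self.reindex()

    # -- construction / bookkeeping ------------------------------------
    def _validate(self) -> None:
        if self.root.parent is not None:
            raise ValueError("root must not have a parent")
        seen_labels: set[str] = set()
        for node in self.preorder():
            if not node.is_tip and not node.is_root and len(node.children) < 2:
                raise ValueError("internal non-root nodes must have >= 2 children")
            if node.is_tip:
                if node.label is None:
                    raise ValueError("every tip needs a label")
                if node.label in seen_labels:
                    raise ValueError(f"duplicate tip label {node.label!r}")
                seen_labels.add(node.label)
        if len(self.root.children) == 1:
            raise ValueError("degree-1 root not supported")

    def reindex(self) -> None:
        for i, node in enumerate(self.preorder()):
            node.index = i

    # -- traversal -----------------------------------------------------
    def preorder(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def postorder(self) -> Iterator[Node]:
        out: list[Node] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return iter(reversed(out))

    # -- views ---------------------------------------------------------
    @property
    def tips(self) -> list[Node]:
        return [n for n in self.preorder() if n.is_tip]

    @property
    def tip_labels(self) -> list[str]:
        return [n.label for n in self.tips]  # type: ignore[misc]

    @property
    def internal_nodes(self) -> list[Node]:
        return [n for n in self.preorder() if not n.is_tip]

    @property
    def n_tips(self) -> int:
        return sum(1 for n in self.preorder() if n.is_tip)

    @property
    def is_dated(self) -> bool:
        return all(n.age is not None for n in self.preorder())

    @property
    def root_age(self) -> float:
        if self.root.age is None:
            raise ValueError("tree is not dated")
        return float(self.root.age)

    def node_by_label(self, label: str) -> Node:
        hits = [n for n in self.preorder() if n.label == label]
        if not hits:
            raise KeyError(f"no node labelled {label!r}")
        if len(hits) > 1:
            raise KeyError(f"label {label!r} is not unique")
        return hits[0]

    # -- mutation helpers ----------------------------------------------
    def copy(self) -> "Phylogeny":
        def clone(node: Node) -> Node:
            new = Node(node.label, node.length)
            new.age = node.age
            for c in node.children:
                new.add_child(clone(c))
            return new

        return Phylogeny(clone(self.root))

    def set_lengths_from_ages(self) -> None:
        if not self.is_dated:
            raise ValueError("tree is not dated")
        self.root.length = None
        for node in self.preorder():
            for c in node.children:
                c.length = node.age - c.age  # type: ignore[operator]

    def date_from_branch_lengths(self, tol: float = 1e-6) -> None:
        """Assign node ages from branch lengths, assuming contemporaneous tips.

        Requires the root-to-tip path lengths to agree to relative ``tol``;
        tips are forced to age exactly 0.
        """
        depth: dict[Node, float] = {self.root: 0.0}
        for node in self.preorder():
            if node.is_root:
                continue
            if node.length is None:
                raise ValueError("branch lengths missing; cannot date tree")
            depth[node] = depth[node.parent] + float(node.length)
        tip_depths = [depth[t] for t in self.tips]
        dmax = max(tip_depths)
        if dmax <= 0:
            raise ValueError("tree has zero height")
        if (dmax - min(tip_depths)) > tol * dmax:
            raise ValueError("tree is not ultrametric within tolerance")
        for node in self.preorder():
            node.age = max(dmax - depth[node], 0.0)
        for t in self.tips:
            t.age = 0.0
        self.set_lengths_from_ages()

    def __repr__(self) -> str:  # pragma: no cover
        dated = "dated" if self.is_dated else "undated"
        return f"<Phylogeny {self.n_tips} tips, {dated}>"


# ----------------------------------------------------------------------
# Newick I/O
# ----------------------------------------------------------------------

def _from_dendropy(dtree: dendropy.Tree) -> Phylogeny:
    root = Node()
    stack = [(dtree.seed_node, root)]
    while stack:
        dnode, node = stack.pop()
        node.label = dnode.taxon.label if dnode.taxon is not None else dnode.label
        node.length = None if dnode.edge.length is None else float(dnode.edge.length)
        for child in dnode.child_nodes():
            stack.append((child, node.add_child(Node())))
    root.length = None
    return Phylogeny(root)


def read_newick(text: str) -> Phylogeny:
    """Parse a rooted Newick string (polytomies and internal labels allowed)."""
    if "[&U]" in text.upper().replace(" ", ""):
        raise NewickParseError("unrooted trees ([&U]) are not supported")
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
            rooting="default-rooted",
        )
    except Exception as exc:  # dendropy raises several error types
        raise NewickParseError(f"malformed Newick: {exc}") from None
    return _from_dendropy(dtree)


def _format_label(label: str | None) -> str:
    if label is None:
        return ""
    if any(ch in label for ch in "()[]:;, '\t\n"):
        return "'" + label.replace("'", "''") + "'"
    return label


def write_newick(tree: Phylogeny, digits: int = 8) -> str:
    """Serialize to Newick; branch lengths keep >= 6 significant digits."""
    fmt = f"%.{max(digits, 6)}g"

    def ser(node: Node) -> str:
        if node.is_tip:
            s = _format_label(node.label)
        else:
            s = "(" + ",".join(ser(c) for c in node.children) + ")" + _format_label(node.label)
        if node.length is not None:
            s += ":" + fmt % node.length
        return s

    return ser(tree.root) + ";"


def read_ages(path_or_text: str) -> dict[str, float]:
    """Read a phylocom-style ages file: whitespace-delimited ``label age`` lines.

    ``#`` starts a comment.  Accepts a filesystem path or the raw text itself.
    """
    try:
        with open(path_or_text) as fh:
            text = fh.read()
    except (OSError, ValueError):
        text = path_or_text
    ages: dict[str, float] = {}
    for lineno, raw in enumerate(text.splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) != 2:
            raise AnchorError(f"ages file line {lineno}: expected 'label age', got {raw!r}")
        label, age = parts[0], float(parts[1])
        if label in ages:
            raise AnchorError(f"duplicate anchor label {label!r}")
        ages[label] = age
    return ages


# ----------------------------------------------------------------------
# bladj-style dating
# ----------------------------------------------------------------------

def bladj_date(tree: Phylogeny, anchors: Mapping[str, float]) -> Phylogeny:
    """Even-spacing interpolation of node ages between dated anchors.

    Anchored internal nodes keep their ages exactly; every undated node
    receives an age by spacing the nodes of its maximal undated chain evenly
    between the nearest dated ancestor and the nearest dated descendant (tips
    count as dated, age 0).  Returns a new dated tree with branch lengths
    recomputed as parent age minus child age.
    """
    out = tree.copy()
    label_map: dict[str, list[Node]] = {}
    for node in out.preorder():
        if not node.is_tip and node.label is not None:
            label_map.setdefault(node.label, []).append(node)
    for node in out.preorder():
        node.age = None
    for tip in out.tips:
        tip.age = 0.0

    for label, age in anchors.items():
        if label not in label_map:
            raise AnchorError(f"anchor label {label!r} does not match any internal node")
        if len(label_map[label]) > 1:
            raise AnchorError(f"anchor label {label!r} matches several internal nodes")
        if age <= 0:
            raise AnchorError(f"anchor {label!r}: age must be > 0, got {age}")
        label_map[label][0].age = float(age)

    if out.root.age is None:
        raise AnchorError("the root must carry an age anchor")

    # consistency: each anchored node must be younger than its nearest anchored ancestor
    for node in out.preorder():
        if node.is_root or node.age is None or node.is_tip:
            continue
        anc = node.parent
        while anc is not None and anc.age is None:
            anc = anc.parent
        if anc is not None and anc.age <= node.age:
            raise AnchorError(
                f"anchor inversion: node {node.label!r} (age {node.age}) is not younger "
                f"than its dated ancestor {anc.label!r} (age {anc.age})"
            )

    def best_chain(start: Node) -> tuple[list[Node], Node]:
        # deepest undated chain from `start` down to the first dated node
        best: tuple[list[Node], Node] | None = None
        stack: list[tuple[Node, list[Node]]] = [(start, [start])]
        while stack:
            node, path = stack.pop()
            for child in node.children:
                if child.age is None:
                    stack.append((child, path + [child]))
                elif best is None or len(path) > len(best[0]):
                    best = (path, child)
        assert best is not None  # tips are dated, so a dated descendant exists
        return best

    for node in out.preorder():
        if node.age is not None:
            continue
        parent = node.parent
        assert parent is not None and parent.age is not None
        chain, below = best_chain(node)
        step = (parent.age - below.age) / (len(chain) + 1)  # type: ignore[operator]
        for j, member in enumerate(chain, start=1):
            member.age = parent.age - j * step

    for node in out.preorder():
        if not node.is_root and node.age >= node.parent.age:  # type: ignore[operator]
            if math.isclose(node.age, node.parent.age):  # anchor-forced tie
                warnings.warn(
                    f"zero-length branch forced by anchors at node {node.label!r}",
                    stacklevel=2,
                )
                node.age = node.parent.age
            else:  # pragma: no cover - guarded by the anchor checks above
                raise AnchorError("age inversion produced during interpolation")
    out.set_lengths_from_ages()
    return out


# ----------------------------------------------------------------------
# divergence times and covariance structure
# ----------------------------------------------------------------------

def _tip_index(tree: Phylogeny) -> dict[Node, int]:
    return {tip: i for i, tip in enumerate(tree.tips)}

def mrca_age_matrix(tree: Phylogeny) -> np.ndarray:
    """Dense matrix of pairwise MRCA ages (diagonal 0), tips in tree order."""
    if not tree.is_dated:
        raise ValueError("tree is not dated; run bladj_date or date_from_branch_lengths")
    idx = _tip_index(tree)
    n = len(idx)
    M = np.zeros((n, n))
    below: dict[Node, np.ndarray] = {}
    for node in tree.postorder():
        if node.is_tip:
            below[node] = np.array([idx[node]], dtype=np.intp)
            continue
        groups = [below.pop(c) for c in node.children]
        for a in range(len(groups)):
            for b in range(a + 1, len(groups)):
                M[np.ix_(groups[a], groups[b])] = node.age
                M[np.ix_(groups[b], groups[a])] = node.age
        below[node] = np.concatenate(groups)
    return M


def divergence_time_matrix(tree: Phylogeny) -> pd.DataFrame:
    """Pairwise divergence times: entry (i, j) is the age of MRCA(i, j) in Myr."""
    M = mrca_age_matrix(tree)
    labels = tree.tip_labels
    return pd.DataFrame(M, index=labels, columns=labels)


def vcv_matrix(tree: Phylogeny) -> np.ndarray:
    """Brownian-motion covariance structure: shared time from the root."""
    M = mrca_age_matrix(tree)
    T = tree.root_age
    V = T - M
    np.fill_diagonal(V, T)
    return V


# ----------------------------------------------------------------------
# pruning and summaries
# ----------------------------------------------------------------------

def subset_tips(tree: Phylogeny, keep: Iterable[str]) -> Phylogeny:
    """Induced subtree on ``keep``; unary nodes suppressed, ages preserved."""
    keep_set = set(keep)
    if len(keep_set) < 2:
        raise ValueError("need at least 2 tips to keep")
    missing = keep_set - set(tree.tip_labels)
    if missing:
        raise ValueError(f"tips not in tree: {sorted(missing)}")
    src = tree.copy()

    def prune(node: Node) -> Node | None:
        if node.is_tip:
            return node if node.label in keep_set else None
        kept = [k for k in (prune(c) for c in node.children) if k is not None]
        if not kept:
            return None
        if len(kept) == 1:
            child = kept[0]
            if node.length is not None or child.length is not None:
                child.length = (node.length or 0.0) + (child.length or 0.0)
            return child
        node.children = kept
        for c in kept:
            c.parent = node
        return node

    new_root = prune(src.root)
    assert new_root is not None
    new_root.parent = None
    new_root.length = None
    out = Phylogeny(new_root)
    if out.is_dated:
        out.set_lengths_from_ages()
    return out


@dataclass(frozen=True)
class TreeStats:
    n_tips: int
    n_internal: int
    pct_bifurcating: float
    root_age: float | None


def tree_stats(tree: Phylogeny) -> TreeStats:
    internal = tree.internal_nodes
    n_bif = sum(1 for n in internal if len(n.children) == 2)
    return TreeStats(
        n_tips=tree.n_tips,
        n_internal=len(internal),
        pct_bifurcating=100.0 * n_bif / len(internal) if internal else float("nan"),
        root_age=tree.root.age,
    )
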