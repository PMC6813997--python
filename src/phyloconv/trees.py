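"""Rooted time-calibrated phylogenies and their covariance structures.

A :class:`Tree` is a compact array-backed rooted tree with branch lengths in
time units (e.g. Myr).  Everything downstream — Brownian-motion and
Ornstein-Uhlenbeck likelihoods, phylogenetic signal, the Wheatsheaf
correction — consumes the two matrices this module produces:

* the phylogenetic covariance ``C`` with ``C[i, j] = s_ij``, the shared
  root-to-MRCA path length of tips *i* and *j*;
* the patristic distance matrix ``d_ij`` (path length between tips).

Newick text is parsed and written through dendropy; polytomies are
preserved and internal node labels ignored.
"""
from __future__ import annotations

import dataclasses
import io
from typing import Iterable, Sequence

import dendropy
import numpy as np

__all__ = [
    "Tree",
    "PhyloCov",
    "TreeError",
    "read_newick",
    "prune",
    "phylo_cov",
    "patristic",
]

#: relative tolerance on root-to-tip depth spread for the ultrametric check
ULTRAMETRIC_RTOL = 1e-6


class TreeError(ValueError):
    """Raised for malformed Newick input or invalid tree structure."""


@dataclasses.dataclass(frozen=True)
class PhyloCov:
    """Phylogenetic covariance structure of a tree.

    Attributes
    ----------
    matrix:
        ``(n_tips, n_tips)`` matrix of shared root-to-MRCA path lengths
        ``s_ij``; the diagonal holds each tip's depth.
    tip_order:
        Tip labels indexing the rows/columns.
    depth:
        Tree depth ``T`` (maximum root-to-tip path length).
    """

    matrix: np.ndarray
    tip_order: tuple[str, ...]
    depth: float


class Tree:
    """Array-backed rooted phylogeny with branch lengths.

    Nodes are integers ``0..n_nodes-1`` with node 0 the root.  Tips are the
    childless nodes; their labels are unique strings.  Non-root branches
    must have strictly positive length.
    """

    def __init__(
        self,
        parent: Sequence[int],
        blen: Sequence[float],
        labels: dict[int, str],
    ) -> None:
        self.parent = np.asarray(parent, dtype=np.int64)
        self.blen = np.asarray(blen, dtype=float)
        self.labels = dict(labels)
        n = self.parent.size
        if n == 0:
            raise TreeError("empty tree")
        roots = np.flatnonzero(self.parent < 0)
        if roots.size != 1:
            raise TreeError(f"tree must have exactly one root, found {roots.size}")
        self.root = int(roots[0])
        self.children: list[list[int]] = [[] for _ in range(n)]
        for v in range(n):
            p = int(self.parent[v])
            if p >= 0:
                self.children[p].append(v)
        bad = [
            v
            for v in range(n)
            if v != self.root and not (np.isfinite(self.blen[v]) and self.blen[v] > 0)
        ]
        if bad:
            raise TreeError(
                "non-root branches must have positive finite length; offending "
                f"nodes: {bad[:5]}"
            )
        self.tips = tuple(v for v in self._preorder() if not self.children[v])
        missing = [v for v in self.tips if v not in self.labels]
        if missing:
            raise TreeError(f"unlabelled tips: {missing}")
        labs = [self.labels[v] for v in self.tips]
        if len(set(labs)) != len(labs):
            dups = sorted({l for l in labs if labs.count(l) > 1})
            raise TreeError(f"duplicate tip labels: {dups}")
        self.tip_labels = tuple(labs)
        self._tip_index = {lab: i for i, lab in enumerate(self.tip_labels)}
        # depths from root
        d = np.zeros(n)
        for v in self._preorder():
            if v != self.root:
                d[v] = d[int(self.parent[v])] + self.blen[v]
        self.depths = d
        self.depth = float(d[list(self.tips)].max())

    # ------------------------------------------------------------------
    # traversal
    def _preorder(self) -> list[int]:
        order: list[int] = []
        stack = [self.root]
        while stack:
            v = stack.pop()
            order.append(v)
            # reversed keeps children in insertion order
            stack.extend(reversed(self.children[v]))
        return order

    def preorder(self) -> list[int]:
        """Nodes in pre-order (parents before children)."""
        return self._preorder()

    def postorder(self) -> list[int]:
        """Nodes in post-order (children before parents)."""
        return self._preorder()[::-1]

    @property
    def n_nodes(self) -> int:
        return self.parent.size

    @property
    def n_tips(self) -> int:
        return len(self.tips)

    def tip_index(self, label: str) -> int:
        """Row index of a tip label in covariance/trait ordering."""
        try:
            return self._tip_index[label]
        except KeyError:
            raise TreeError(f"unknown tip label: {label!r}") from None

    def is_ultrametric(self, rtol: float = ULTRAMETRIC_RTOL) -> bool:
        """True if all root-to-tip depths agree to relative tolerance."""
        d = self.depths[list(self.tips)]
        return bool((d.max() - d.min()) <= rtol * max(self.depth, 1e-300))

    def subtree_nodes(self, node: int) -> list[int]:
        """All nodes of the clade rooted at ``node`` (pre-order)."""
        out: list[int] = []
        stack = [node]
        while stack:
            v = stack.pop()
            out.append(v)
            stack.extend(reversed(self.children[v]))
        return out

    def subtree_tip_rows(self, node: int) -> np.ndarray:
        """Tip row indices below (or at) ``node``."""
        rows = [
            self._tip_index[self.labels[v]]
            for v in self.subtree_nodes(node)
            if not self.children[v]
        ]
        return np.asarray(sorted(rows), dtype=np.int64)

    def mrca_depth_matrix(self) -> np.ndarray:
        """``(n_nodes, n_nodes)`` matrix of MRCA depths between all nodes.

        Entry ``(u, v)`` is the depth of the most recent common ancestor of
        nodes *u* and *v* (``depth[u]`` when *u* is an ancestor of *v*).
        Used by ancestral-state reconstruction.
        """
        n = self.n_nodes
        S = np.zeros((n, n))
        for w in self.postorder():
            groups = [self.subtree_nodes(c) for c in self.children[w]]
            dw = self.depths[w]
            for a in range(len(groups)):
                ga = np.asarray(groups[a])
                S[w, ga] = dw
                S[ga, w] = dw
                for b in range(a + 1, len(groups)):
                    gb = np.asarray(groups[b])
                    S[np.ix_(ga, gb)] = dw
                    S[np.ix_(gb, ga)] = dw
            S[w, w] = dw
        return S

    # ------------------------------------------------------------------
    # serialisation
    def to_newick(self) -> str:
        """Serialise to a Newick string with branch lengths on all edges."""

        def emit(v: int) -> str:
            if not self.children[v]:
                base = _quote_label(self.labels[v])
            else:
                base = "(" + ",".join(emit(c) for c in self.children[v]) + ")"
            if v == self.root:
                return base
            return f"{base}:{self.blen[v]:.17g}"

        return emit(self.root) + ";"

    def __repr__(self) -> str:  # pragma: no cover - debugging nicety
        return f"<Tree {self.n_tips} tips, depth {self.depth:.4g}>"


def _quote_label(label: str) -> str:
    if any(ch in label for ch in "(),:;[] '\t\n"):
        return "'" + label.replace("'", "''") + "'"
    return label


# ----------------------------------------------------------------------
# construction


def read_newick(text: str, normalise_underscores: bool = False) -> Tree:
    """Parse a Newick string into a :class:`Tree`.

    Branch lengths are mandatory on every non-root edge; internal node
    labels are permitted and ignored; polytomies are preserved.

    Parameters
    ----------
    text:
        Newick string (a trailing semicolon is expected).
    normalise_underscores:
        If True, underscores in tip labels are converted to spaces
        (matching trait tables that use spaces).
    """
    try:
        dt = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise TreeError(f"Newick parse error: {exc}") from exc

    parent: list[int] = []
    blen: list[float] = []
    labels: dict[int, str] = {}
    index: dict[int, int] = {}
    for nd in dt.preorder_node_iter():
        my_id = len(parent)
        index[id(nd)] = my_id
        if nd.parent_node is None:
            parent.append(-1)
            blen.append(0.0)
        else:
            if nd.edge.length is None:
                name = _node_name(nd)
                raise TreeError(f"missing branch length on edge above node {name}")
            parent.append(index[id(nd.parent_node)])
            blen.append(float(nd.edge.length))
        if nd.is_leaf():
            if nd.taxon is None or nd.taxon.label is None:
                raise TreeError(f"unlabelled tip at node index {my_id}")
            lab = nd.taxon.label
            if normalise_underscores:
                lab = lab.replace("_", " ")
            labels[my_id] = lab
    return Tree(parent, blen, labels)


def read_newick_file(path, **kw) -> Tree:
    """Read a Newick tree from a file path."""
    with open(path) as fh:
        return read_newick(fh.read(), **kw)


def _node_name(nd) -> str:
    if nd.taxon is not None and nd.taxon.label:
        return repr(nd.taxon.label)
    if nd.label:
        return repr(nd.label)
    return "<internal>"


# ----------------------------------------------------------------------
# operations


def prune(tree: Tree, keep: Iterable[str]) -> Tree:
    """Induced subtree on the tip set ``keep``.

    Unary internal nodes created by the pruning are suppressed and their
    branch lengths summed, so root-to-tip depths of kept tips are
    unchanged.
    """
    keep = set(keep)
    unknown = sorted(keep - set(tree.tip_labels))
    if unknown:
        raise TreeError(f"unknown tip labels in keep set: {unknown}")
    if len(keep) < 2:
        raise TreeError("keep set must contain at least 2 tips")

    keep_nodes = {v for v in tree.tips if tree.labels[v] in keep}

    kept_cache: dict[int, bool] = {}

    def _has_kept(v: int) -> bool:
        if v not in kept_cache:
            if not tree.children[v]:
                kept_cache[v] = v in keep_nodes
            else:
                kept_cache[v] = any(_has_kept(c) for c in tree.children[v])
        return kept_cache[v]

    parent_out: list[int] = []
    blen_out: list[float] = []
    labels_out: dict[int, str] = {}

    def build(v: int, extra_len: float, parent_id: int) -> None:
        """Copy the induced subtree at v; extra_len accumulates suppressed edges."""
        if not tree.children[v]:
            my = len(parent_out)
            parent_out.append(parent_id)
            blen_out.append(tree.blen[v] + extra_len)
            labels_out[my] = tree.labels[v]
            return
        kept_children = [c for c in tree.children[v] if _has_kept(c)]
        if len(kept_children) == 1:
            # unary internal node: suppress it, pushing its length down
            build(kept_children[0], tree.blen[v] + extra_len, parent_id)
            return
        my = len(parent_out)
        parent_out.append(parent_id)
        blen_out.append(tree.blen[v] + extra_len)
        for c in kept_children:
            build(c, 0.0, my)

    # The original root is always retained (it carries no branch), so
    # root-to-tip depths of kept tips never change.
    parent_out.append(-1)
    blen_out.append(0.0)
    for c in tree.children[tree.root]:
        if _has_kept(c):
            build(c, 0.0, 0)
    return Tree(parent_out, blen_out, labels_out)


def phylo_cov(tree: Tree) -> PhyloCov:
    """Shared root-to-MRCA path lengths ``s_ij`` between all tip pairs."""
    n = tree.n_tips
    S = np.zeros((n, n))
    tip_rows: dict[int, np.ndarray] = {}
    for v in tree.postorder():
        if not tree.children[v]:
            tip_rows[v] = np.asarray([tree.tip_index(tree.labels[v])])
            S[tip_rows[v][0], tip_rows[v][0]] = tree.depths[v]
            continue
        groups = [tip_rows.pop(c) for c in tree.children[v]]
        dv = tree.depths[v]
        for a in range(len(groups)):
            for b in range(a + 1, len(groups)):
                S[np.ix_(groups[a], groups[b])] = dv
                S[np.ix_(groups[b], groups[a])] = dv
        tip_rows[v] = np.concatenate(groups)
    return PhyloCov(matrix=S, tip_order=tree.tip_labels, depth=tree.depth)


def patristic(tree: Tree) -> np.ndarray:
    """Patristic distance matrix ``d_ij = depth_i + depth_j - 2 s_ij``."""
    cov = phylo_cov(tree)
    d = np.diag(cov.matrix)
    return d[:, None] + d[None, :] - 2.0 * cov.matrix
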