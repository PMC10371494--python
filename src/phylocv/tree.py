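"""Phylogenies with branch lengths: newick I/O and the array form pruning uses.

Trees are unrooted (substitution models here are time-reversible, so the
likelihood does not depend on root placement).  Internally a tree is stored
rooted at an arbitrary internal node purely as a computational convention;
:meth:`Phylogeny.rerooted` re-expresses the same unrooted tree from another
vantage point, which tests use to confirm root-placement invariance.

Rooted newick input with a degree-2 root is unrooted by suppressing the
root and summing the two root-adjacent branch lengths into one edge.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np


class TreeError(ValueError):
    """Malformed tree input (missing branch lengths, leaf-set mismatch)."""


@dataclass
class Phylogeny:
    """An unrooted phylogeny stored in child-array form.

    ``parent[i]`` is the parent of node ``i`` under the internal rooting
    (-1 for the root), ``lengths[i]`` the length of the edge above ``i``
    (0 for the root), ``names[i]`` the taxon label for leaves and ``None``
    for internal nodes.
    """

    parent: np.ndarray
    children: list[list[int]]
    lengths: np.ndarray
    names: list[str | None]
    root: int
    _postorder: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.parent = np.asarray(self.parent, dtype=int)
        self.lengths = np.asarray(self.lengths, dtype=float)
        if np.any(self.lengths < 0):
            raise TreeError("branch lengths must be non-negative")
        if self._postorder is None:
            self._postorder = self._compute_postorder()

    def _compute_postorder(self) -> np.ndarray:
        order: list[int] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            order.append(node)
            stack.extend(self.children[node])
        return np.array(order[::-1], dtype=int)

    @property
    def n_nodes(self) -> int:
        return len(self.names)

    @property
    def postorder(self) -> np.ndarray:
        return self._postorder

    @property
    def leaf_indices(self) -> list[int]:
        return [i for i in range(self.n_nodes) if not self.children[i]]

    @property
    def leaf_names(self) -> list[str]:
        return [self.names[i] for i in self.leaf_indices]  # type: ignore[misc]

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_indices)

    @property
    def branch_nodes(self) -> np.ndarray:
        """Indices of nodes carrying a branch (everything but the root)."""
        return np.array([i for i in range(self.n_nodes) if i != self.root], dtype=int)

    @property
    def total_length(self) -> float:
        return float(self.lengths[self.branch_nodes].sum())

    def with_branch_lengths(self, lengths: np.ndarray) -> "Phylogeny":
        """Copy of the tree with a new branch-length vector (root entry ignored)."""
        new = np.asarray(lengths, dtype=float).copy()
        new[self.root] = 0.0
        return Phylogeny(self.parent.copy(), [list(c) for c in self.children],
                         new, list(self.names), self.root, self._postorder)

    def rerooted(self, new_root: int) -> "Phylogeny":
        """The same unrooted tree re-expressed from another internal node."""
        if self.children[new_root] == []:
            raise TreeError("cannot root at a leaf")
        n = self.n_nodes
        adj: list[list[tuple[int, float]]] = [[] for _ in range(n)]
        for i in range(n):
            p = self.parent[i]
            if p >= 0:
                adj[i].append((p, self.lengths[i]))
                adj[p].append((i, self.lengths[i]))
        parent = np.full(n, -1, dtype=int)
        lengths = np.zeros(n)
        children: list[list[int]] = [[] for _ in range(n)]
        seen = np.zeros(n, dtype=bool)
        stack = [new_root]
        seen[new_root] = True
        while stack:
            u = stack.pop()
            for v, w in adj[u]:
                if not seen[v]:
                    seen[v] = True
                    parent[v] = u
                    lengths[v] = w
                    children[u].append(v)
                    stack.append(v)
        return Phylogeny(parent, children, lengths, list(self.names), new_root)

    def to_newick(self) -> str:
        def fmt(node: int) -> str:
            if not self.children[node]:
                return f"{self.names[node]}"
            inner = ",".join(
                f"{fmt(c)}:{self.lengths[c]:.12g}" for c in self.children[node]
            )
            return f"({inner})"
        return fmt(self.root) + ";"


def _from_dendropy(tree: dendropy.Tree) -> Phylogeny:
    dnodes = list(tree.preorder_node_iter())
    index = {id(nd): i for i, nd in enumerate(dnodes)}
    n = len(dnodes)
    parent = np.full(n, -1, dtype=int)
    lengths = np.zeros(n)
    children: list[list[int]] = [[] for _ in range(n)]
    names: list[str | None] = [None] * n
    for nd in dnodes:
        i = index[id(nd)]
        if nd.is_leaf():
            if nd.taxon is None or not nd.taxon.label:
                raise TreeError("leaf without a label")
            names[i] = nd.taxon.label
        if nd.parent_node is not None:
            p = index[id(nd.parent_node)]
            parent[i] = p
            children[p].append(i)
            if nd.edge.length is None:
                where = names[i] or "an internal node"
                raise TreeError(f"missing branch length on the edge above {where}")
            lengths[i] = float(nd.edge.length)
    phylo = Phylogeny(parent, children, lengths, names, 0)
    return _suppress_degree_two_root(phylo)


def _suppress_degree_two_root(phylo: Phylogeny) -> Phylogeny:
    """Unroot a rooted-binary input by merging the two root-adjacent edges."""
    kids = phylo.children[phylo.root]
    if len(kids) != 2:
        return phylo
    a, b = kids
    internal = [k for k in (a, b) if phylo.children[k]]
    if not internal:
        return phylo  # two-taxon tree: nothing to suppress
    new_root = internal[0]
    other = b if new_root == a else a
    parent = phylo.parent.copy()
    lengths = phylo.lengths.copy()
    children = [list(c) for c in phylo.children]
    parent[other] = new_root
    lengths[other] = lengths[a] + lengths[b]
    children[new_root].append(other)
    parent[new_root] = -1
    lengths[new_root] = 0.0
    old_root = phylo.root
    children[old_root] = []
    # the old root node lingers as an orphan leaf-shaped node; drop it
    keep = [i for i in range(phylo.n_nodes) if i != old_root]
    remap = {old: new for new, old in enumerate(keep)}
    return Phylogeny(
        parent=np.array([remap[parent[i]] if parent[i] >= 0 else -1 for i in keep]),
        children=[[remap[c] for c in children[i]] for i in keep],
        lengths=lengths[keep],
        names=[phylo.names[i] for i in keep],
        root=remap[new_root],
    )


def read_tree(path, alignment=None) -> Phylogeny:
    """Read a newick tree; optionally check its leaf set against an alignment."""
    text = Path(path).read_text()
    return tree_from_newick(text, alignment=alignment)


def tree_from_newick(newick: str, alignment=None) -> Phylogeny:
    dtree = dendropy.Tree.get(data=newick, schema="newick",
                              preserve_underscores=True)
    phylo = _from_dendropy(dtree)
    if alignment is not None:
        check_leaf_match(phylo, alignment)
    return phylo


def check_leaf_match(tree: Phylogeny, alignment) -> None:
    """Raise :class:`TreeError` listing the symmetric difference of leaf sets."""
    tree_set = set(tree.leaf_names)
    aln_set = set(alignment.taxon_names)
    if tree_set != aln_set:
        diff = sorted(tree_set ^ aln_set)
        raise TreeError(f"tree and alignment taxa differ: {set(diff)}")


def write_tree(tree: Phylogeny, path) -> None:
    Path(path).write_text(tree.to_newick() + "\n")


def random_tree(taxon_names: list[str], rng: np.random.Generator,
                mean_branch: float = 0.1) -> Phylogeny:
    """A uniformly assembled unrooted binary topology with Exp(mean) branch lengths.

    Built by random sequential joins; the last three lineages attach to the
    root, giving the degree-3 root of an unrooted binary tree.
    """
    if len(taxon_names) < 2:
        raise TreeError("need at least two taxa")
    nodes: list[tuple[int, list[int], float]] = []
    parent_list: list[int] = []
    children: list[list[int]] = []
    lengths: list[float] = []
    names: list[str | None] = []

    def new_node(name: str | None) -> int:
        parent_list.append(-1)
        children.append([])
        lengths.append(0.0)
        names.append(name)
        return len(names) - 1

    active = [new_node(t) for t in taxon_names]
    while len(active) > 3:
        i, j = sorted(rng.choice(len(active), size=2, replace=False))
        a, b = active[i], active[j]
        joint = new_node(None)
        for child in (a, b):
            parent_list[child] = joint
            children[joint].append(child)
            lengths[child] = float(rng.exponential(mean_branch))
        active = [x for x in active if x not in (a, b)] + [joint]
    root = new_node(None)
    for child in active:
        parent_list[child] = root
        children[root].append(child)
        lengths[child] = float(rng.exponential(mean_branch))
    return Phylogeny(np.array(parent_list), children, np.array(lengths),
                     names, root)
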