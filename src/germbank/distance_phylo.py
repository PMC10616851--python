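"""Genetic distances, canonical neighbor-joining, and Newick I/O.

Distances are Euclidean on 0/1/2 dosage calls over pairwise-complete loci,
rescaled by ``sqrt(L / L_ab)`` so missingness does not deflate distances.
Neighbor joining is the canonical O(n^3) Saitou-Nei agglomeration with the
Q-criterion; it is exact on additive matrices (the returned tree reproduces
every pairwise distance). Trees are unrooted, anchored at an internal
trifurcation for serialization.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypeMatrix, ParseError, ValidationError

logger = logging.getLogger("germbank")


# ---------------------------------------------------------------------------
# Distance matrix
# ---------------------------------------------------------------------------

@dataclass
class DistanceMatrix:
    """Symmetric non-negative distances with zero diagonal."""

    labels: list[str]
    values: np.ndarray
    n_loci_used: np.ndarray | None = None  # per-pair complete-locus counts

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValidationError(f"distance matrix shape {self.values.shape} != ({n}, {n})")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValidationError("distance matrix not symmetric")
        if np.any(self.values < -1e-12):
            raise ValidationError("negative distances")
        if not np.allclose(np.diag(self.values), 0.0, atol=1e-12):
            raise ValidationError("nonzero diagonal")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("non-finite distances")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def to_phylip(self, path: str | Path, precision: int = 6) -> None:
        with open(path, "w") as fh:
            fh.write(f"{len(self.labels)}\n")
            for lab, row in zip(self.labels, self.values):
                fh.write(lab + "  " + " ".join(f"{v:.{precision}f}" for v in row) + "\n")


def genetic_distance(
    G: GenotypeMatrix, scaling: str = "pairwise-complete-euclidean"
) -> DistanceMatrix:
    """Euclidean genotype distance with pairwise-complete rescaling.

    ``d(a,b) = sqrt((L / L_ab) * sum_{l complete} (g_al - g_bl)^2)`` where the
    sum runs over loci non-missing in both accessions, ``L_ab`` counts them
    and ``L`` is the total locus count. Accessions with all calls missing,
    and pairs with no complete locus, raise an error naming the offender.
    """
    if scaling != "pairwise-complete-euclidean":
        raise ValidationError(f"unknown scaling {scaling!r}")
    if G.n_accessions < 2:
        raise ValidationError("need at least two accessions")
    present = (G.calls != MISSING)
    empty = np.where(~present.any(axis=1))[0]
    if empty.size:
        raise ValidationError(f"accession {G.accession_ids[empty[0]]!r} has no called loci")
    P = present.astype(np.float64)
    X = np.where(present, G.calls, 0).astype(np.float64)
    cross = X @ X.T
    sq = (X * X) @ P.T  # sum_l x_al^2 over loci called in both (x is 0 where a missing)
    ssq = sq + sq.T - 2.0 * cross
    np.clip(ssq, 0.0, None, out=ssq)
    L_ab = P @ P.T
    off = ~np.eye(G.n_accessions, dtype=bool)
    if np.any(L_ab[off] == 0):
        i, j = np.argwhere((L_ab == 0) & off)[0]
        raise ValidationError(
            f"no complete loci between {G.accession_ids[i]!r} and {G.accession_ids[j]!r}"
        )
    d = np.sqrt(G.n_loci / L_ab * ssq)
    np.fill_diagonal(d, 0.0)
    d = 0.5 * (d + d.T)  # enforce exact symmetry against fp noise
    return DistanceMatrix(list(G.accession_ids), d, n_loci_used=L_ab.astype(np.int64))


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------

class Node:
    """Tree node; ``children`` is a list of ``(child, branch_length)``."""

    __slots__ = ("name", "children")

    def __init__(self, name: str | None = None,
                 children: list[tuple["Node", float]] | None = None) -> None:
        self.name = name
        self.children: list[tuple[Node, float]] = children or []

    @property
    def is_leaf(self) -> bool:
        return not self.children


class PhyloTree:
    """Unrooted tree anchored at an internal node for traversal/serialization."""

    def __init__(self, anchor: Node) -> None:
        self.anchor = anchor

    # -- traversal ----------------------------------------------------------

    def iter_nodes(self) -> Iterator[Node]:
        stack = [self.anchor]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(child for child, _ in node.children)

    def leaf_names(self) -> list[str]:
        return sorted(n.name for n in self.iter_nodes() if n.is_leaf)

    def _edges(self) -> list[tuple[Node, Node, float]]:
        return [
            (parent, child, length)
            for parent in self.iter_nodes()
            for child, length in parent.children
        ]

    def copy(self) -> "PhyloTree":
        def clone(node: Node) -> Node:
            return Node(node.name, [(clone(c), l) for c, l in node.children])

        return PhyloTree(clone(self.anchor))

    # -- metrics ------------------------------------------------------------

    def distance_matrix(self) -> DistanceMatrix:
        """Leaf-to-leaf path-length matrix (labels sorted)."""
        adj: dict[int, list[tuple[int, float]]] = {}
        leaves: dict[str, int] = {}
        for parent, child, length in self._edges():
            a, b = id(parent), id(child)
            adj.setdefault(a, []).append((b, length))
            adj.setdefault(b, []).append((a, length))
        for node in self.iter_nodes():
            if node.is_leaf:
                leaves[node.name] = id(node)
            adj.setdefault(id(node), [])
        labels = sorted(leaves)
        n = len(labels)
        out = np.zeros((n, n))
        for i, lab in enumerate(labels):
            dist = {leaves[lab]: 0.0}
            stack = [leaves[lab]]
            while stack:
                u = stack.pop()
                for v, w in adj[u]:
                    if v not in dist:
                        dist[v] = dist[u] + w
                        stack.append(v)
            for j, other in enumerate(labels):
                out[i, j] = dist[leaves[other]]
        out = 0.5 * (out + out.T)
        np.fill_diagonal(out, 0.0)
        return DistanceMatrix(labels, np.maximum(out, 0.0))

    def bipartitions(self) -> set[frozenset[str]]:
        """Non-trivial splits, each given as the smaller (tie: lexicographically
        first) leaf set of the corresponding internal edge."""
        all_leaves = frozenset(self.leaf_names())

        def side(node: Node) -> frozenset[str]:
            if node.is_leaf:
                return frozenset([node.name])
            return frozenset().union(*(side(c) for c, _ in node.children))

        splits: set[frozenset[str]] = set()
        for _, child, _ in self._edges():
            s = side(child)
            if 1 < len(s) < len(all_leaves) - 1:
                comp = all_leaves - s
                key = min(s, comp, key=lambda x: (len(x), tuple(sorted(x))))
                splits.add(key)
        return splits


def rf_distance(a: PhyloTree, b: PhyloTree) -> int:
    """Robinson-Foulds (symmetric-difference) distance between unrooted trees."""
    if a.leaf_names() != b.leaf_names():
        raise ValidationError("trees have different leaf sets")
    return len(a.bipartitions() ^ b.bipartitions())


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------

def neighbor_joining(D: DistanceMatrix) -> PhyloTree:
    """Canonical Saitou-Nei neighbor joining.

    Agglomerates with the Q-criterion
    ``Q(i,j) = (m-2) d(i,j) - r_i - r_j`` (``r`` = row sums over the ``m``
    active nodes), breaking ties at the lowest (row, column) index pair of
    the current matrix. Exact on additive matrices; branch lengths may come
    out negative and are retained (see :func:`write_newick` for clamping).
    """
    n = len(D.labels)
    if n < 3:
        raise ValidationError("neighbor joining requires at least three labels")
    d = D.values.astype(float).copy()
    nodes: list[Node] = [Node(lab) for lab in D.labels]
    while len(nodes) > 3:
        m = len(nodes)
        r = d.sum(axis=1)
        Q = (m - 2) * d - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        flat = int(np.argmin(Q))  # row-major => lowest (row, col) among minima
        i, j = divmod(flat, m)
        if i > j:
            i, j = j, i
        dij = d[i, j]
        li = 0.5 * dij + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = dij - li
        new = Node(children=[(nodes[i], li), (nodes[j], lj)])
        du = 0.5 * (d[i, :] + d[j, :] - dij)
        keep = [k for k in range(m) if k not in (i, j)]
        d_new = np.empty((m - 1, m - 1))
        d_new[:-1, :-1] = d[np.ix_(keep, keep)]
        d_new[-1, :-1] = du[keep]
        d_new[:-1, -1] = du[keep]
        d_new[-1, -1] = 0.0
        d = d_new
        nodes = [nodes[k] for k in keep] + [new]
    # final trifurcation: three-point formulas
    dab, dac, dbc = d[0, 1], d[0, 2], d[1, 2]
    la = 0.5 * (dab + dac - dbc)
    lb = 0.5 * (dab + dbc - dac)
    lc = 0.5 * (dac + dbc - dab)
    anchor = Node(children=[(nodes[0], la), (nodes[1], lb), (nodes[2], lc)])
    return PhyloTree(anchor)


# ---------------------------------------------------------------------------
# Newick I/O
# ---------------------------------------------------------------------------

_NEEDS_QUOTES = set(" \t()[]':;,")


def _quote(label: str) -> str:
    if label and not (_NEEDS_QUOTES & set(label)):
        return label
    return "'" + label.replace("'", "''") + "'"


def _clamp_negative(tree: PhyloTree) -> PhyloTree:
    """Zero negative branch lengths, transferring the deficit to the child's
    outgoing edges so leaf-to-leaf paths through the parent are preserved
    where possible (leaf edges are simply clamped)."""
    tree = tree.copy()

    def visit(node: Node) -> None:
        for idx, (child, length) in enumerate(node.children):
            if length < 0.0:
                if child.children:
                    child.children = [(g, gl + length) for g, gl in child.children]
                node.children[idx] = (child, 0.0)
            visit(child)

    visit(tree.anchor)
    # a transfer can push a grandchild edge negative in turn; clamp leftovers
    for node in tree.iter_nodes():
        node.children = [(c, max(l, 0.0)) for c, l in node.children]
    return tree


def write_newick(
    T: PhyloTree, precision: int = 6, clamp_negative: bool = True
) -> str:
    """Serialize to Newick with branch lengths at the given precision.

    Negative NJ branch lengths are clamped to zero on output (the deficit
    moved to the adjacent edges) unless ``clamp_negative`` is False.
    """
    tree = _clamp_negative(T) if clamp_negative else T

    def fmt(node: Node, length: float | None) -> str:
        if node.is_leaf:
            body = _quote(node.name)
        else:
            body = "(" + ",".join(fmt(c, l) for c, l in node.children) + ")"
        if length is None:
            return body
        return f"{body}:{length:.{precision}g}"

    return fmt(tree.anchor, None) + ";"


def read_newick(text: str) -> PhyloTree:
    """Parse a Newick string (single-quoted labels supported)."""
    import dendropy

    try:
        t = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:
        raise ParseError(f"malformed Newick: {exc}") from exc

    def convert(dnode) -> Node:
        if dnode.is_leaf():
            name = dnode.taxon.label if dnode.taxon is not None else (dnode.label or "")
            return Node(name)
        return Node(
            dnode.label,
            [(convert(c), float(c.edge.length or 0.0)) for c in dnode.child_nodes()],
        )

    return PhyloTree(convert(t.seed_node))


# ---------------------------------------------------------------------------
# Random additive trees (testing / simulation support)
# ---------------------------------------------------------------------------

def random_additive_tree(
    rng: np.random.Generator,
    n_leaves: int,
    min_length: float = 0.1,
    max_length: float = 2.0,
    labels: Sequence[str] | None = None,
) -> PhyloTree:
    """Random unrooted binary tree with positive branch lengths.

    Built by sequential leaf attachment: each new leaf splits a uniformly
    chosen existing edge. The path-length matrix of the result is additive by
    construction, so it is a fixed point of :func:`neighbor_joining`.
    """
    if n_leaves < 3:
        raise ValidationError("need at least three leaves")
    if labels is None:
        labels = [f"t{i}" for i in range(n_leaves)]

    def rand_len() -> float:
        return float(rng.uniform(min_length, max_length))

    anchor = Node(children=[(Node(labels[k]), rand_len()) for k in range(3)])
    tree = PhyloTree(anchor)
    for k in range(3, n_leaves):
        edges = tree._edges()
        parent, child, length = edges[int(rng.integers(len(edges)))]
        split = float(rng.uniform(0.05, 0.95))
        mid = Node(children=[(child, length * (1.0 - split)), (Node(labels[k]), rand_len())])
        idx = [c for c, _ in parent.children].index(child)
        parent.children[idx] = (mid, length * split)
    return tree
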