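"""Distances over recovered DBDs, neighbor-joining inference, clade assignment.

Distances are Poisson-corrected p-distances (``-ln(1 - p)``) computed from
pairwise global alignments; the tree is inferred with the Saitou-Nei
neighbor-joining agglomeration, which recovers the true topology and branch
lengths exactly whenever the input matrix is additive — that consistency
property is the module's primary correctness oracle.  Query leaves are
assigned to reference clades (the three RFX groups plus the fungal clade)
by nearest reference along tree paths.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .align import SubstitutionScheme, global_align
from .exceptions import ParameterError
from .io_formats import log

#: Distance cap applied at p >= P_CAP (keeps NJ stable for saturated pairs).
P_CAP = 0.95
MAX_DISTANCE = -math.log(1.0 - P_CAP)

UNASSIGNED = "UNASSIGNED"


@dataclass(frozen=True)
class DistanceMatrix:
    labels: tuple
    d: np.ndarray

    def __post_init__(self):
        d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if d.shape != (n, n):
            raise ParameterError("distance matrix shape does not match labels")
        if not np.isfinite(d).all() or (d < 0).any():
            raise ParameterError("distances must be finite and non-negative")
        if not np.allclose(d, d.T) or not np.allclose(np.diag(d), 0.0):
            raise ParameterError("distance matrix must be symmetric with zero diagonal")
        object.__setattr__(self, "d", d)
        object.__setattr__(self, "labels", tuple(self.labels))


class TreeNode:
    """Node of an unrooted tree stored as a rooted structure (root may be
    trifurcating); ``length`` is the branch to the parent."""

    __slots__ = ("label", "length", "children", "parent")

    def __init__(self, label=None, length=0.0):
        self.label = label
        self.length = length
        self.children: list[TreeNode] = []
        self.parent: TreeNode | None = None

    def add(self, child: "TreeNode", length: float):
        child.length = length
        child.parent = self
        self.children.append(child)


@dataclass
class Tree:
    root: TreeNode

    def leaves(self):
        out = []

        def walk(node):
            if not node.children:
                out.append(node)
            for c in node.children:
                walk(c)

        walk(self.root)
        return out

    @property
    def leaf_labels(self):
        return tuple(leaf.label for leaf in self.leaves())

    def total_length(self) -> float:
        total = 0.0

        def walk(node):
            nonlocal total
            for c in node.children:
                total += c.length
                walk(c)

        walk(self.root)
        return total

    def newick(self) -> str:
        def fmt(node):
            if not node.children:
                return f"{node.label}:{node.length:.10g}"
            inner = ",".join(fmt(c) for c in node.children)
            if node is self.root:
                return f"({inner})"
            return f"({inner}):{node.length:.10g}"

        return fmt(self.root) + ";"

    def write_newick(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.newick() + "\n")

    def leaf_distance_matrix(self) -> DistanceMatrix:
        """Path-length distances between all leaves."""
        leaves = self.leaves()
        n = len(leaves)
        # depth and parent chains from the (possibly trifurcating) root
        depth = {}
        order = {}

        def walk(node, d, chain):
            depth[id(node)] = d
            order[id(node)] = chain
            for c in node.children:
                walk(c, d + c.length, chain + (id(node),))

        walk(self.root, 0.0, ())
        d = np.zeros((n, n))
        for i in range(n):
            ai = set(order[id(leaves[i])] + (id(leaves[i]),))
            for j in range(i + 1, n):
                # walk up from leaf j until hitting an ancestor of leaf i
                node = leaves[j]
                dist = 0.0
                while id(node) not in ai:
                    dist += node.length
                    node = node.parent
                lca_depth = depth[id(node)]
                d[i, j] = d[j, i] = dist + depth[id(leaves[i])] - lca_depth
        return DistanceMatrix(tuple(leaf.label for leaf in leaves), d)


def p_distance(a: str, b: str, scheme: SubstitutionScheme) -> float:
    """Proportion of mismatched residue columns in the global alignment of a, b.

    Gap columns are excluded from both numerator and denominator; 'X' never
    counts as identical.  Arguments are ordered canonically before aligning
    so the result is exactly symmetric even when co-optimal alignments with
    different column compositions exist.
    """
    if b < a:
        a, b = b, a
    aln = global_align(a, b, scheme)
    residue_cols = 0
    mismatches = 0
    for qa, qb in zip(aln.aligned_query, aln.aligned_target):
        if qa == "-" or qb == "-":
            continue
        residue_cols += 1
        if qa != qb or qa == "X":
            mismatches += 1
    if residue_cols == 0:
        return 1.0
    return mismatches / residue_cols


def dbd_distance(a: str, b: str, scheme: SubstitutionScheme) -> float:
    """Poisson-corrected alignment distance ``-ln(1 - p)``, capped at p=0.95."""
    p = p_distance(a, b, scheme)
    if p >= P_CAP:
        log.warning("p-distance %.3f at/above cap; returning capped distance", p)
        return MAX_DISTANCE
    return -math.log(1.0 - p)


def distance_matrix(sequences: dict, scheme: SubstitutionScheme) -> DistanceMatrix:
    """All-pairs dbd_distance over a {label: sequence} mapping."""
    labels = tuple(sequences)
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = dbd_distance(sequences[labels[i]],
                                             sequences[labels[j]], scheme)
    return DistanceMatrix(labels, d)


def nj_tree(dm: DistanceMatrix) -> Tree:
    """Saitou-Nei neighbor joining with deterministic tie-breaking.

    The pair minimising the Q-criterion is joined at each step (ties: lowest
    index pair in the current node ordering).  Negative branch lengths are
    set to zero with the deficit moved to the sibling branch, preserving the
    joined pair's distance.  Returns an unrooted tree (trifurcating root).
    """
    n = len(dm.labels)
    if n < 3:
        raise ParameterError("neighbor joining requires at least 3 labels")
    nodes = [TreeNode(label=lab) for lab in dm.labels]
    d = dm.d.copy()
    active = list(range(n))

    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        # lowest-index tie-break: argmin of row-major scan
        flat = int(np.argmin(q))
        i, j = divmod(flat, m)
        if i > j:
            i, j = j, i
        dij = sub[i, j]
        li = 0.5 * dij + (r[i] - r[j]) / (2 * (m - 2))
        lj = dij - li
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        li, lj = max(li, 0.0), max(lj, 0.0)
        parent = TreeNode()
        parent.add(nodes[active[i]], li)
        parent.add(nodes[active[j]], lj)
        # distances from the new node to every other active node
        new_row = np.zeros(d.shape[0] + 1)
        gi, gj = active[i], active[j]
        for pos, g in enumerate(active):
            if pos in (i, j):
                continue
            new_row[g] = 0.5 * (d[gi, g] + d[gj, g] - dij)
        d = np.pad(d, ((0, 1), (0, 1)))
        d[-1, :-1] = new_row[:-1]
        d[:-1, -1] = new_row[:-1]
        nodes.append(parent)
        active = [g for g in active if g not in (gi, gj)] + [len(nodes) - 1]

    # final three nodes: trifurcating root with three-point branch lengths
    a, b, c = active
    la = 0.5 * (d[a, b] + d[a, c] - d[b, c])
    lb = 0.5 * (d[a, b] + d[b, c] - d[a, c])
    lc = 0.5 * (d[a, c] + d[b, c] - d[a, b])
    root = TreeNode()
    root.add(nodes[a], max(la, 0.0))
    root.add(nodes[b], max(lb, 0.0))
    root.add(nodes[c], max(lc, 0.0))
    return Tree(root=root)


def assign_clades(tree: Tree, references: dict, tol: float = 1e-9) -> dict:
    """Label each non-reference leaf with its nearest reference's group.

    ``references`` maps reference leaf labels to group names; each group
    needs at least two references.  A query leaf equidistant (within ``tol``)
    from references of different groups is UNASSIGNED.
    """
    labels = set(tree.leaf_labels)
    missing = sorted(set(references) - labels)
    if missing:
        raise ParameterError(f"reference leaves missing from tree: {missing}")
    by_group: dict[str, int] = {}
    for g in references.values():
        by_group[g] = by_group.get(g, 0) + 1
    thin = [g for g, c in by_group.items() if c < 2]
    if thin:
        raise ParameterError(f"reference group(s) with fewer than 2 members: {thin}")
    pdm = tree.leaf_distance_matrix()
    index = {lab: k for k, lab in enumerate(pdm.labels)}
    assignment = {}
    for leaf in pdm.labels:
        if leaf in references:
            continue
        dists = [(pdm.d[index[leaf], index[ref]], ref) for ref in references]
        dists.sort()
        best_d, best_ref = dists[0]
        best_group = references[best_ref]
        tied = {references[ref] for dd, ref in dists if dd <= best_d + tol}
        assignment[leaf] = best_group if tied == {best_group} else UNASSIGNED
    return assignment
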