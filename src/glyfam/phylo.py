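"""Distance-based phylogeny machinery: p-distance matrices, the
Saitou-Nei neighbor-joining algorithm, and column-resampling bootstrap
support, with Newick output.

NJ is exact on additive distance matrices: it recovers the generating
topology and branch lengths.  Negative branch-length estimates (possible
on non-additive input) are clamped to zero, the deficit moved to the
sibling edge, and flagged.  Gap handling in p-distances is pairwise
deletion: a column is skipped for a pair only when either sequence has a
gap there.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DistanceMatrix",
    "TreeNode",
    "PhyloTree",
    "p_distance_matrix",
    "neighbor_joining",
    "bootstrap_support",
]

GAP_CHARS = set("-.")


@dataclass
class DistanceMatrix:
    labels: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix not symmetric")
        if np.any(np.diag(self.d) != 0):
            raise ValueError("nonzero diagonal")
        if np.any(self.d < 0):
            raise ValueError("negative distances")


@dataclass
class TreeNode:
    name: str = ""
    length: float = 0.0
    support: float | None = None
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out


@dataclass
class PhyloTree:
    root: TreeNode  # unrooted tree stored with a trifurcating root
    negative_branches_clamped: int = 0

    @property
    def leaf_names(self) -> list[str]:
        return [lf.name for lf in self.root.leaves()]

    def to_newick(self) -> str:
        def fmt(node: TreeNode) -> str:
            if node.is_leaf:
                return f"{node.name}:{node.length:.6g}"
            inner = ",".join(fmt(c) for c in node.children)
            label = "" if node.support is None else f"{node.support:g}"
            return f"({inner}){label}:{node.length:.6g}"

        inner = ",".join(fmt(c) for c in self.root.children)
        return f"({inner});"

    def bipartitions(self) -> set[frozenset[str]]:
        """Non-trivial bipartitions, each as the smaller-side leaf set
        (canonicalized by the lexicographically sorted frozenset)."""
        all_leaves = frozenset(self.leaf_names)
        parts: set[frozenset[str]] = set()

        def walk(node: TreeNode) -> frozenset[str]:
            if node.is_leaf:
                return frozenset([node.name])
            below = frozenset().union(*(walk(c) for c in node.children))
            if node is not self.root and 1 < len(below) < len(all_leaves) - 1:
                other = all_leaves - below
                parts.add(min(below, other, key=lambda s: (len(s), sorted(s))))
            return below

        walk(self.root)
        return parts

    def path_lengths(self) -> DistanceMatrix:
        """Pairwise leaf-to-leaf path-length matrix (additivity check)."""
        leaves = sorted(self.leaf_names)
        idx = {name: i for i, name in enumerate(leaves)}
        n = len(leaves)
        d = np.zeros((n, n))

        def walk(node: TreeNode) -> dict[str, float]:
            if node.is_leaf:
                return {node.name: 0.0}
            sub = [walk(c) for c in node.children]
            for a in range(len(sub)):
                for b in range(a + 1, len(sub)):
                    for la, da in sub[a].items():
                        for lb, db in sub[b].items():
                            da2 = da + node.children[a].length
                            db2 = db + node.children[b].length
                            d[idx[la], idx[lb]] = d[idx[lb], idx[la]] = da2 + db2
            merged = {}
            for child, dists in zip(node.children, sub):
                for name, dist in dists.items():
                    merged[name] = dist + child.length
            return merged

        walk(self.root)
        return DistanceMatrix(leaves, d)


def p_distance_matrix(alignment: dict[str, str]) -> DistanceMatrix:
    """p-distances (mismatch proportion, pairwise gap deletion) over a
    multiple protein alignment given as label -> aligned sequence."""
    labels = list(alignment)
    if len(labels) < 2:
        raise ValueError("need at least 2 sequences")
    lengths = {len(s) for s in alignment.values()}
    if len(lengths) != 1:
        raise ValueError("aligned sequences differ in length")
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a, b = alignment[labels[i]], alignment[labels[j]]
            comparable = mismatch = 0
            for ca, cb in zip(a, b):
                if ca in GAP_CHARS or cb in GAP_CHARS:
                    continue
                comparable += 1
                if ca != cb:
                    mismatch += 1
            if comparable == 0:
                raise ValueError(
                    f"no comparable columns between {labels[i]} and {labels[j]}"
                )
            d[i, j] = d[j, i] = mismatch / comparable
    return DistanceMatrix(labels, d)


def neighbor_joining(dm: DistanceMatrix) -> PhyloTree:
    """Saitou-Nei neighbor joining with deterministic tie-breaking
    (lowest label-index pair wins)."""
    n = len(dm.labels)
    if n < 3:
        raise ValueError("need at least 3 labels")
    nodes: list[TreeNode] = [TreeNode(name=lbl) for lbl in dm.labels]
    d = dm.d.copy()
    active = list(range(n))
    clamped = 0

    while len(active) > 3:
        m = len(active)
        r = {i: sum(d[i, j] for j in active if j != i) for i in active}
        best = None
        best_q = np.inf
        for ai in range(m):
            for bi in range(ai + 1, m):
                i, j = active[ai], active[bi]
                q = (m - 2) * d[i, j] - r[i] - r[j]
                if q < best_q - 1e-12:
                    best_q = q
                    best = (i, j)
        i, j = best
        li = 0.5 * d[i, j] + (r[i] - r[j]) / (2 * (m - 2))
        lj = d[i, j] - li
        # clamp negative estimates, moving the deficit to the sibling
        if li < 0:
            lj += li
            li = 0.0
            clamped += 1
        if lj < 0:
            li += lj
            lj = 0.0
            clamped += 1
        nodes[i].length = li
        nodes[j].length = lj
        parent = TreeNode(children=[nodes[i], nodes[j]])
        new = len(nodes)
        nodes.append(parent)
        d = np.pad(d, ((0, 1), (0, 1)))
        for k in active:
            if k in (i, j):
                continue
            d[new, k] = d[k, new] = 0.5 * (d[i, k] + d[j, k] - d[i, j])
        active = [k for k in active if k not in (i, j)] + [new]

    i, j, k = active
    # three-point formulas for the final trifurcation
    li = 0.5 * (d[i, j] + d[i, k] - d[j, k])
    lj = 0.5 * (d[i, j] + d[j, k] - d[i, k])
    lk = 0.5 * (d[i, k] + d[j, k] - d[i, j])
    for idx, length in ((i, li), (j, lj), (k, lk)):
        if length < 0:
            length = 0.0
            clamped += 1
        nodes[idx].length = length
    root = TreeNode(children=[nodes[i], nodes[j], nodes[k]])
    return PhyloTree(root, negative_branches_clamped=clamped)


def bootstrap_support(
    alignment: dict[str, str], n_reps: int, seed: int
) -> PhyloTree:
    """NJ tree on the full alignment with bipartition support (%) from
    column-resampled replicates."""
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    tree = neighbor_joining(p_distance_matrix(alignment))
    length = len(next(iter(alignment.values())))
    rng = np.random.default_rng(seed)
    counts: dict[frozenset[str], int] = {p: 0 for p in tree.bipartitions()}
    for _ in range(n_reps):
        cols = rng.integers(0, length, size=length)
        resampled = {
            lbl: "".join(seq[c] for c in cols) for lbl, seq in alignment.items()
        }
        try:
            rep = neighbor_joining(p_distance_matrix(resampled))
        except ValueError:  # replicate with an all-gap pair
            continue
        for part in rep.bipartitions():
            if part in counts:
                counts[part] += 1

    def annotate(node: TreeNode, all_leaves: frozenset[str]) -> frozenset[str]:
        if node.is_leaf:
            return frozenset([node.name])
        below = frozenset().union(
            *(annotate(c, all_leaves) for c in node.children)
        )
        if node is not tree.root and 1 < len(below) < len(all_leaves) - 1:
            key = min(
                below, all_leaves - below, key=lambda s: (len(s), sorted(s))
            )
            node.support = 100.0 * counts[key] / n_reps
        return below

    annotate(tree.root, frozenset(tree.leaf_names))
    return tree
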