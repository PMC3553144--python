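"""Distance-based phylogenetics: Jukes–Cantor protein distances with
pairwise deletion, Saitou–Nei neighbor joining, nonparametric bootstrap
supports and outgroup rooting.

The Jukes–Cantor correction uses the 20-state amino-acid form,
``d = -(19/20) * ln(1 - (20/19) * p)``; observed proportions at or above
the 19/20 saturation point are flagged and clamped to a configurable
ceiling.  Neighbor joining uses the Studier–Keppler Q-criterion with
deterministic tie-breaking and reproduces additive distances exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .io_formats import Alignment
from .tree import Tree, TreeNode, TreeError

__all__ = [
    "DistanceMatrix",
    "jc_distance",
    "nj_tree",
    "bootstrap_support",
    "root_with_outgroup",
]

JC_FACTOR = 19.0 / 20.0
MISSING = {"-", "X", "?"}


@dataclass
class DistanceMatrix:
    taxa: list[str]
    d: np.ndarray
    comparable_sites: np.ndarray | None = None
    saturated: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.taxa)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape disagrees with taxa")
        if not np.allclose(self.d, self.d.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(self.d) != 0):
            raise ValueError("distance matrix diagonal must be zero")
        if np.any(self.d < 0):
            raise ValueError("negative distances")


def jc_distance(msa: Alignment, *, saturation_ceiling: float = 5.0) -> DistanceMatrix:
    """Jukes–Cantor protein distances with pairwise deletion.

    For each pair, columns where either row carries a gap, ``X`` or ``?``
    are excluded; ``p`` is the mismatch proportion over the remaining
    comparable sites.
    """
    mat = msa.to_array()
    n, L = mat.shape
    ok = ~np.isin(mat, sorted(MISSING))
    d = np.zeros((n, n))
    comp = np.zeros((n, n), dtype=int)
    sat = np.zeros((n, n), dtype=bool)
    np.fill_diagonal(comp, L)
    for i in range(n):
        for j in range(i + 1, n):
            both = ok[i] & ok[j]
            m = int(both.sum())
            if m == 0:
                raise ValueError(
                    f"no comparable sites between {msa.taxa[i]!r} "
                    f"and {msa.taxa[j]!r}"
                )
            p = float(np.sum(mat[i, both] != mat[j, both])) / m
            comp[i, j] = comp[j, i] = m
            if p >= JC_FACTOR:
                d[i, j] = d[j, i] = saturation_ceiling
                sat[i, j] = sat[j, i] = True
            else:
                d[i, j] = d[j, i] = -JC_FACTOR * math.log(1.0 - p / JC_FACTOR)
    return DistanceMatrix(list(msa.taxa), d, comp, sat)


def nj_tree(D: DistanceMatrix) -> Tree:
    """Saitou–Nei neighbor joining (Studier–Keppler Q-criterion).

    Returns an unrooted tree represented with a trifurcating root.
    Additive input distances are reproduced exactly on the output tree.
    Negative branch-length estimates are clamped to zero with the
    deficit transferred to the sibling edge.  Q-ties are broken by the
    smallest (i, j) pair in the current node ordering.
    """
    n = len(D.taxa)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    d = D.d.copy()
    nodes: list[TreeNode] = [TreeNode(label=t) for t in D.taxa]
    active = list(range(n))

    while len(active) > 3:
        r = len(active)
        sub = d[np.ix_(active, active)]
        R = sub.sum(axis=1)
        q = (r - 2) * sub - R[:, None] - R[None, :]
        np.fill_diagonal(q, np.inf)
        # deterministic argmin: first (i,j) in row-major order
        flat = np.argmin(q)
        ai, aj = divmod(int(flat), r)
        if ai > aj:
            ai, aj = aj, ai
        i, j = active[ai], active[aj]
        dij = d[i, j]
        li = 0.5 * dij + (R[ai] - R[aj]) / (2 * (r - 2))
        lj = dij - li
        # clamp negatives, moving the deficit onto the sibling edge
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        parent = TreeNode()
        nodes[i].length = li
        nodes[j].length = lj
        parent.add(nodes[i])
        parent.add(nodes[j])
        # new distances
        dk = 0.5 * (d[i, :] + d[j, :] - dij)
        d = np.vstack([d, dk])
        d = np.hstack([d, np.append(dk, 0.0)[:, None]])
        nodes.append(parent)
        k = d.shape[0] - 1
        active = [x for x in active if x not in (i, j)] + [k]

    # resolve the final three nodes with the three-point formulas
    a, b, c = active
    la = 0.5 * (d[a, b] + d[a, c] - d[b, c])
    lb = 0.5 * (d[a, b] + d[b, c] - d[a, c])
    lc = 0.5 * (d[a, c] + d[b, c] - d[a, b])
    root = TreeNode()
    for idx, ln in ((a, la), (b, lb), (c, lc)):
        nodes[idx].length = max(ln, 0.0)
        root.add(nodes[idx])
    return Tree(root)


def bootstrap_support(
    msa: Alignment,
    *,
    replicates: int = 1000,
    seed: int = 0,
    saturation_ceiling: float = 5.0,
) -> Tree:
    """Nonparametric bootstrap supports on the point-estimate NJ tree.

    Columns are resampled with replacement (one seeded generator, indices
    drawn replicate-major); each replicate rebuilds the JC distances and
    the NJ tree, and the support of every bipartition of the point tree
    is the percentage of replicates containing it.  Replicates whose
    distance computation degenerates are skipped and counted on the
    returned tree as ``tree.skipped_replicates``.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    point = nj_tree(jc_distance(msa, saturation_ceiling=saturation_ceiling))
    target_splits = point.bipartitions()
    counts = {s: 0 for s in target_splits}
    rng = np.random.default_rng(seed)
    L = msa.length
    skipped = 0
    for _ in range(replicates):
        cols = rng.integers(0, L, size=L)
        try:
            rep = msa.resample_columns(cols)
            rep_tree = nj_tree(
                jc_distance(rep, saturation_ceiling=saturation_ceiling)
            )
        except ValueError:
            skipped += 1
            continue
        rep_splits = rep_tree.bipartitions()
        for s in target_splits:
            if s in rep_splits:
                counts[s] += 1
    used = replicates - skipped
    all_taxa = frozenset(point.leaf_names)
    anchor = min(all_taxa)
    for node in point.root.walk():
        if node is self_or_trivial(node, point, all_taxa):
            continue
        below = frozenset(leaf.label for leaf in node.leaves())
        side = all_taxa - below if anchor in below else below
        if side in counts and used > 0:
            node.support = 100.0 * counts[side] / used
    point.skipped_replicates = skipped
    return point


def self_or_trivial(node: TreeNode, tree: Tree, all_taxa: frozenset):
    """Helper: returns the node itself when its edge carries no
    nontrivial bipartition (root edge or pendant edge)."""
    if node is tree.root or node.is_leaf:
        return node
    below = frozenset(leaf.label for leaf in node.leaves())
    if len(below) < 2 or len(below) > len(all_taxa) - 2:
        return node
    return None


def root_with_outgroup(tree: Tree, outgroup) -> Tree:
    """Root on the edge subtending the outgroup (branch split 50/50)."""
    if isinstance(outgroup, str):
        outgroup = {outgroup}
    outgroup = frozenset(outgroup)
    all_taxa = frozenset(tree.leaf_names)
    unknown = outgroup - all_taxa
    if unknown:
        raise TreeError(f"unknown outgroup taxa: {sorted(unknown)}")
    if outgroup == all_taxa:
        raise TreeError("outgroup cannot contain every taxon")
    for node in tree.root.walk():
        if node is tree.root:
            continue
        below = frozenset(leaf.label for leaf in node.leaves())
        if below == outgroup:
            return tree.reroot_on_node(node, fraction=0.5)
    # the outgroup might be the complement side of an edge
    for node in tree.root.walk():
        if node is tree.root:
            continue
        below = frozenset(leaf.label for leaf in node.leaves())
        if all_taxa - below == outgroup:
            return tree.reroot_on_node(node, fraction=0.5)
    raise TreeError(
        "outgroup is not monophyletic in the unrooted tree: "
        f"{sorted(outgroup)}"
    )
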