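"""Phylogenetic tree container with Newick round-tripping.

The container is intentionally small: nodes with parent links, branch
lengths in substitutions/site, leaf labels and optional per-internal-node
bootstrap support in percent.  Newick text is parsed through dendropy and
converted; writing is a direct recursive serialization so that canonical
trees round-trip bit-identically.

An unrooted tree is represented with a (possibly trifurcating) root; its
bipartition set is the rooting-independent description used by bootstrap
counting and topology comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy

__all__ = ["TreeNode", "Tree", "TreeError"]


class TreeError(ValueError):
    pass


@dataclass
class TreeNode:
    label: str | None = None
    length: float | None = None
    support: float | None = None
    children: list["TreeNode"] = field(default_factory=list)
    parent: "TreeNode | None" = None

    def add(self, child: "TreeNode") -> "TreeNode":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def walk(self):
        """Preorder traversal."""
        stack = [self]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def leaves(self):
        return [n for n in self.walk() if n.is_leaf]


class Tree:
    def __init__(self, root: TreeNode):
        self.root = root
        labels = [leaf.label for leaf in root.leaves()]
        if any(lab is None or lab == "" for lab in labels):
            raise TreeError("every leaf must carry a label")
        if len(set(labels)) != len(labels):
            raise TreeError("duplicate leaf labels")

    # -- structure ---------------------------------------------------------

    @property
    def leaf_names(self) -> list[str]:
        return [leaf.label for leaf in self.root.leaves()]

    def nodes(self):
        return list(self.root.walk())

    def find_leaf(self, label: str) -> TreeNode:
        for leaf in self.root.leaves():
            if leaf.label == label:
                return leaf
        raise KeyError(label)

    def copy(self) -> "Tree":
        def clone(node: TreeNode) -> TreeNode:
            c = TreeNode(node.label, node.length, node.support)
            for child in node.children:
                c.add(clone(child))
            return c

        return Tree(clone(self.root))

    # -- bipartitions ------------------------------------------------------

    def bipartitions(self, *, nontrivial_only: bool = True) -> set[frozenset]:
        """Rooting-independent splits, each canonicalized as the side not
        containing the lexicographically smallest taxon."""
        all_taxa = frozenset(self.leaf_names)
        anchor = min(all_taxa)
        splits = set()
        for node in self.root.walk():
            if node is self.root:
                continue
            below = frozenset(leaf.label for leaf in node.leaves())
            side = all_taxa - below if anchor in below else below
            if nontrivial_only and (len(side) < 2 or len(side) > len(all_taxa) - 2):
                continue
            splits.add(side)
        return splits

    def is_monophyletic(self, taxa) -> bool:
        """True when ``taxa`` form one side of some edge in the unrooted tree."""
        taxa = frozenset(taxa)
        all_taxa = frozenset(self.leaf_names)
        if not taxa <= all_taxa:
            raise TreeError(f"unknown taxa: {sorted(taxa - all_taxa)}")
        if len(taxa) == 1 or taxa == all_taxa:
            return len(taxa) == 1
        for node in self.root.walk():
            if node is self.root:
                continue
            below = frozenset(leaf.label for leaf in node.leaves())
            if below == taxa or (all_taxa - below) == taxa:
                return True
        # the clade around the root: union of all-but-one root child
        return False

    def path_lengths(self) -> dict[tuple[str, str], float]:
        """Leaf-to-leaf distances along the tree (additivity checks)."""
        import itertools

        dist: dict[tuple[str, str], float] = {}

        def below(node):
            out = {}
            if node.is_leaf:
                out[node.label] = 0.0
                return out
            child_maps = []
            for child in node.children:
                cmap = {
                    lab: d + (child.length or 0.0)
                    for lab, d in below(child).items()
                }
                child_maps.append(cmap)
            for m1, m2 in itertools.combinations(child_maps, 2):
                for a, da in m1.items():
                    for b, db in m2.items():
                        key = (a, b) if a < b else (b, a)
                        dist[key] = da + db
            for cmap in child_maps:
                out.update(cmap)
            return out

        below(self.root)
        return dist

    # -- rooting -----------------------------------------------------------

    def reroot_on_node(self, node: TreeNode, fraction: float = 0.5) -> "Tree":
        """Return a new tree rooted on the edge above ``node``.

        The edge's branch length is split ``fraction`` (below the new
        root, on the target side) / ``1 - fraction``.
        """
        if node.parent is None:
            raise TreeError("cannot root on the root's own edge")
        tree = self.copy()
        # refind the corresponding node in the copy by leafset identity
        target_leaves = frozenset(leaf.label for leaf in node.leaves())
        target = None
        for cand in tree.root.walk():
            if cand.parent is None:
                continue
            if frozenset(l.label for l in cand.leaves()) == target_leaves:
                target = cand
                break
        if target is None:
            raise TreeError("edge not found")
        edge_len = target.length if target.length is not None else 0.0
        old_parent = target.parent
        old_parent.children.remove(target)
        new_root = TreeNode()
        new_root.add(target)
        target.length = edge_len * fraction
        # reverse the parent chain above the old attachment point
        carry_len = edge_len * (1.0 - fraction)
        carry_support = target.support
        node_ = old_parent
        prev = new_root
        while node_ is not None:
            parent_next = node_.parent
            len_next = node_.length
            sup_next = node_.support
            if parent_next is not None:
                parent_next.children.remove(node_)
            node_.parent = None
            node_.length = carry_len
            node_.support = carry_support
            prev.add(node_)
            prev = node_
            carry_len = len_next
            carry_support = sup_next
            node_ = parent_next
        tree2 = Tree(_suppress_unifurcations(new_root))
        return tree2

    def unrooted(self) -> "Tree":
        """Collapse a bifurcating root into a trifurcation (merge the two
        root edges), yielding the canonical unrooted representation."""
        tree = self.copy()
        root = tree.root
        if len(root.children) != 2:
            return tree
        a, b = root.children
        keep, fold = (a, b) if not a.is_leaf else (b, a)
        if keep.is_leaf:
            return tree  # two-leaf tree: nothing to collapse
        root.children.remove(keep)
        merged = (keep.length or 0.0) + (fold.length or 0.0)
        for child in list(keep.children):
            root.add(child)
        fold.length = merged
        keep.children = []
        root.children.remove(fold) if fold in root.children else None
        root.add(fold)
        return Tree(root)

    # -- newick ------------------------------------------------------------

    def to_newick(self) -> str:
        def fmt_len(x: float | None) -> str:
            return "" if x is None else f":{x + 0.0:g}"

        def rec(node: TreeNode) -> str:
            if node.is_leaf:
                return f"{node.label}{fmt_len(node.length)}"
            inner = ",".join(rec(c) for c in node.children)
            label = ""
            if node.support is not None:
                label = f"{node.support:g}"
            elif node.label:
                label = node.label
            return f"({inner}){label}{fmt_len(node.length)}"

        return rec(self.root) + ";"

    @classmethod
    def from_newick(cls, text: str) -> "Tree":
        dtree = dendropy.Tree.get(
            data=text, schema="newick", suppress_internal_node_taxa=True
        )

        def convert(dnode) -> TreeNode:
            if dnode.is_leaf():
                label = dnode.taxon.label if dnode.taxon else dnode.label
                return TreeNode(label=label, length=dnode.edge.length)
            node = TreeNode(length=dnode.edge.length)
            if dnode.label is not None:
                try:
                    node.support = float(dnode.label)
                except ValueError:
                    node.label = dnode.label
            for child in dnode.child_nodes():
                node.add(convert(child))
            return node

        return cls(convert(dtree.seed_node))


def _suppress_unifurcations(root: TreeNode) -> TreeNode:
    """Remove internal nodes with a single child, merging branch lengths."""

    def fix(node: TreeNode) -> TreeNode:
        node.children = [fix(c) for c in node.children]
        for c in node.children:
            c.parent = node
        if len(node.children) == 1 and node.parent is not None:
            child = node.children[0]
            child.length = (child.length or 0.0) + (node.length or 0.0)
            if child.support is None:
                child.support = node.support
            return child
        return node

    root = fix(root)
    while len(root.children) == 1 and not root.children[0].is_leaf:
        root = root.children[0]
        root.parent = None
        root.length = None
    return root


def write_newick(tree: Tree, path) -> None:
    """Serialize ``tree`` to a Newick file (supports as internal labels)."""
    with open(path, "w") as out:
        out.write(tree.to_newick() + "\n")


def read_newick(path) -> Tree:
    with open(path) as handle:
        return Tree.from_newick(handle.read())
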