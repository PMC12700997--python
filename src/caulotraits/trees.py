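"""Rooted phylogeny container used by the parsimony and screening code.

The tree is deliberately minimal: a rooted (possibly multifurcating) node
hierarchy with string node ids, where tips carry genome identifiers. Newick
parsing and serialization are delegated to :mod:`dendropy`; internal node
ids are assigned deterministically in post-order so that identical Newick
inputs always yield identical ids.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import dendropy
import numpy as np

__all__ = ["Phylogeny", "random_coalescent_tree"]


@dataclass
class Phylogeny:
    """Rooted tree with unique string node ids.

    Tips are identified by their label (the genome id); internal nodes get
    synthetic ids ``n0, n1, ...`` in post-order. Edges are identified by
    their child node id, as usual for rooted trees.
    """

    root: str
    children: dict[str, tuple[str, ...]]
    parent: dict[str, str | None]
    branch_lengths: dict[str, float] = field(default_factory=dict)

    # ------------------------------------------------------------------ basics
    @property
    def nodes(self) -> list[str]:
        return list(self.postorder())

    @property
    def tips(self) -> list[str]:
        return [n for n in self.postorder() if not self.children.get(n)]

    def is_tip(self, node: str) -> bool:
        return not self.children.get(node)

    def postorder(self) -> Iterator[str]:
        stack: list[tuple[str, bool]] = [(self.root, False)]
        while stack:
            node, expanded = stack.pop()
            if expanded or self.is_tip(node):
                yield node
            else:
                stack.append((node, True))
                for child in reversed(self.children[node]):
                    stack.append((child, False))

    def preorder(self) -> Iterator[str]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            for child in reversed(self.children.get(node, ())):
                stack.append(child)

    # -------------------------------------------------------------- clade ops
    def tips_below(self, node: str) -> frozenset[str]:
        """Set of tip labels in the subtree rooted at *node*."""
        out: set[str] = set()
        stack = [node]
        while stack:
            n = stack.pop()
            kids = self.children.get(n, ())
            if kids:
                stack.extend(kids)
            else:
                out.add(n)
        return frozenset(out)

    def clade_map(self) -> dict[str, frozenset[str]]:
        """node id -> tips below, for every node (one post-order pass)."""
        below: dict[str, frozenset[str]] = {}
        for node in self.postorder():
            kids = self.children.get(node, ())
            if not kids:
                below[node] = frozenset((node,))
            else:
                s: set[str] = set()
                for k in kids:
                    s |= below[k]
                below[node] = frozenset(s)
        return below

    def mrca(self, tip_set: Iterable[str]) -> str:
        """Most recent common ancestor of the given tips."""
        wanted = set(tip_set)
        if not wanted:
            raise ValueError("mrca of an empty tip set is undefined")
        missing = wanted - set(self.tips)
        if missing:
            raise KeyError(f"unknown tips: {sorted(missing)}")
        below = self.clade_map()
        best = self.root
        # deepest node whose clade covers the set
        for node in self.preorder():
            if wanted <= below[node]:
                best = node
        return best

    def is_ancestor(self, anc: str, desc: str) -> bool:
        """True if *anc* lies on the path from *desc* to the root (strictly)."""
        node = self.parent.get(desc)
        while node is not None:
            if node == anc:
                return True
            node = self.parent.get(node)
        return False

    # ---------------------------------------------------------------- newick
    @classmethod
    def from_dendropy(cls, tree: dendropy.Tree) -> "Phylogeny":
        labels = [lf.taxon.label if lf.taxon else None for lf in tree.leaf_node_iter()]
        if any(l is None for l in labels):
            raise ValueError("all tips must be labeled")
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate tip labels in tree")
        ids: dict[int, str] = {}
        counter = 0
        children: dict[str, tuple[str, ...]] = {}
        parent: dict[str, str | None] = {}
        blen: dict[str, float] = {}
        for node in tree.postorder_node_iter():
            if node.is_leaf():
                nid = node.taxon.label
            else:
                nid = f"n{counter}"
                counter += 1
            ids[id(node)] = nid
            children[nid] = tuple(ids[id(c)] for c in node.child_nodes())
            if node.edge.length is not None:
                blen[nid] = float(node.edge.length)
        root_id = ids[id(tree.seed_node)]
        parent[root_id] = None
        for node in tree.postorder_node_iter():
            nid = ids[id(node)]
            for c in node.child_nodes():
                parent[ids[id(c)]] = nid
        return cls(root=root_id, children=children, parent=parent, branch_lengths=blen)

    @classmethod
    def from_newick(cls, newick: str) -> "Phylogeny":
        try:
            tree = dendropy.Tree.get(
                data=newick, schema="newick", preserve_underscores=True
            )
        except Exception as exc:
            if "Duplicate taxon" in str(exc) or "Multiple occurrences" in str(exc):
                raise ValueError("duplicate tip labels in tree") from exc
            raise
        return cls.from_dendropy(tree)

    def to_newick(self) -> str:
        def render(node: str) -> str:
            kids = self.children.get(node, ())
            bl = self.branch_lengths.get(node)
            suffix = f":{bl:g}" if bl is not None else ""
            if not kids:
                label = node
                if any(c in label for c in " (),:;'"):
                    label = "'" + label.replace("'", "''") + "'"
                return label + suffix
            return "(" + ",".join(render(k) for k in kids) + ")" + suffix

        return render(self.root) + ";"


def random_coalescent_tree(
    n_tips: int,
    rng: np.random.Generator,
    tip_prefix: str = "g",
) -> Phylogeny:
    """Random rooted binary tree by successive random pair joins.

    Tips are labeled ``{tip_prefix}000 ...``; the topology is drawn uniformly
    over labeled coalescent join orders, which is ample for screens whose
    behavior does not depend on the topology distribution.
    """
    if n_tips < 2:
        raise ValueError("need at least 2 tips")
    width = max(3, len(str(n_tips - 1)))
    lineages = [f"{tip_prefix}{i:0{width}d}" for i in range(n_tips)]
    children: dict[str, tuple[str, ...]] = {t: () for t in lineages}
    parent: dict[str, str | None] = {}
    counter = 0
    while len(lineages) > 1:
        i, j = sorted(rng.choice(len(lineages), size=2, replace=False))
        a, b = lineages[i], lineages[j]
        nid = f"n{counter}"
        counter += 1
        children[nid] = (a, b)
        parent[a] = nid
        parent[b] = nid
        lineages[i] = nid
        lineages.pop(j)
    root = lineages[0]
    parent[root] = None
    return Phylogeny(root=root, children=children, parent=parent)
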