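"""Phylogenetic tree container used by every tree-producing module.

A deliberately small rooted-tree structure: nodes carry branch lengths,
optional bootstrap support, and an optional *foreground* mark used by the
branch-site selection models.  Newick parsing is delegated to dendropy;
writing is done here so that round-trips preserve branch lengths to 10
significant digits.  The foreground mark uses the widespread ``#1`` label
suffix on the child node of the marked branch.
"""

from __future__ import annotations

from typing import Iterator

import dendropy


class TreeNode:
    __slots__ = ("children", "parent", "length", "label", "support", "foreground")

    def __init__(self, label: str | None = None, length: float | None = None):
        self.children: list[TreeNode] = []
        self.parent: TreeNode | None = None
        self.length = length
        self.label = label
        self.support: float | None = None
        self.foreground = False

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def add_child(self, node: "TreeNode") -> "TreeNode":
        node.parent = self
        self.children.append(node)
        return node

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"TreeNode({self.label!r}, len={self.length}, n_children={len(self.children)})"


class PhyloTree:
    """Rooted tree with branch lengths, supports, and a foreground mark."""

    def __init__(self, root: TreeNode):
        self.root = root

    # ------------------------------------------------------------------ traversal
    def postorder(self) -> Iterator[TreeNode]:
        stack, out = [self.root], []
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return iter(reversed(out))

    def preorder(self) -> Iterator[TreeNode]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def leaves(self) -> list[TreeNode]:
        return [n for n in self.postorder() if n.is_leaf]

    def leaf_labels(self) -> list[str]:
        return [n.label for n in self.leaves()]

    def n_leaves(self) -> int:
        return len(self.leaves())

    # ------------------------------------------------------------------ edits
    def copy(self) -> "PhyloTree":
        def _copy(node: TreeNode) -> TreeNode:
            new = TreeNode(node.label, node.length)
            new.support = node.support
            new.foreground = node.foreground
            for c in node.children:
                new.add_child(_copy(c))
            return new

        return PhyloTree(_copy(self.root))

    def mark_foreground(self, labels: set[str] | str, *, clade: bool = True) -> None:
        """Mark foreground branch(es) for branch-site models.

        ``labels`` names one leaf (string) or a set of leaves.  With
        ``clade=True`` the stem branch of their MRCA and every branch inside
        the clade are marked; with ``clade=False`` only the stem branch.

        If the labels are not a clade under the current rooting but do form
        a split of the unrooted topology (typical for neighbor-joining
        trees), the tree is first rerooted on that split.
        """
        if isinstance(labels, str):
            labels = {labels}
        mrca = self.mrca(labels)
        if frozenset(_leafset(mrca)) != frozenset(labels) and len(labels) > 1:
            self.reroot_on_split(labels)
            mrca = self.mrca(labels)
            if frozenset(_leafset(mrca)) != frozenset(labels):
                raise ValueError(f"{sorted(labels)} is not a clade or split "
                                 "of this tree; cannot mark a foreground branch")
        for n in self.postorder():
            n.foreground = False
        mrca.foreground = True
        if clade:
            stack = list(mrca.children)
            while stack:
                n = stack.pop()
                n.foreground = True
                stack.extend(n.children)

    def mrca(self, labels: set[str]) -> TreeNode:
        unknown = labels - set(self.leaf_labels())
        if unknown:
            raise ValueError(f"unknown leaf labels: {sorted(unknown)}")
        # smallest node whose leaf set covers the labels
        best = self.root
        improved = True
        while improved:
            improved = False
            for c in best.children:
                if labels <= set(_leafset(c)):
                    best = c
                    improved = True
                    break
        return best

    def reroot_on_split(self, labels: set[str]) -> None:
        """Reroot (in place) on the edge separating ``labels`` from the rest.

        Raises ``ValueError`` when no edge of the unrooted topology induces
        that bipartition.
        """
        want = frozenset(labels)
        complement = frozenset(self.leaf_labels()) - want
        target = None
        for node in self.postorder():
            if node is self.root:
                continue
            ls = frozenset(_leafset(node))
            if ls == want or ls == complement:
                target = node
                break
        if target is None:
            raise ValueError(f"no edge splits off {sorted(labels)}")
        self._reroot_above(target)

    def _reroot_above(self, target: TreeNode) -> None:
        if target.parent is None:
            return
        half = (target.length or 0.0) / 2.0
        new_root = TreeNode()
        old_parent = target.parent
        old_parent.children.remove(target)
        new_root.add_child(target)
        target.length = half
        prev: TreeNode = new_root
        carry = half
        node: TreeNode | None = old_parent
        while node is not None:
            parent = node.parent
            length_up = node.length
            if parent is not None:
                parent.children.remove(node)
            node.parent = None
            prev.add_child(node)
            node.length = carry
            carry = length_up
            prev = node
            node = parent
        self.root = new_root
        self._suppress_unifurcations()

    def _suppress_unifurcations(self) -> None:
        for node in list(self.postorder()):
            if node is self.root or len(node.children) != 1:
                continue
            child = node.children[0]
            child.length = (child.length or 0.0) + (node.length or 0.0)
            parent = node.parent
            parent.children[parent.children.index(node)] = child
            child.parent = parent

    # ------------------------------------------------------------------ metrics
    def total_length(self) -> float:
        return sum(n.length or 0.0 for n in self.postorder() if n is not self.root)

    def leaf_depths(self) -> dict[str, float]:
        depths: dict[str, float] = {}

        def walk(node: TreeNode, d: float) -> None:
            d += node.length or 0.0
            if node.is_leaf:
                depths[node.label] = d
            for c in node.children:
                walk(c, d)

        walk(self.root, -(self.root.length or 0.0))
        return depths

    def bipartitions(self) -> set[frozenset[str]]:
        """Non-trivial unrooted bipartitions, each as its canonical side.

        The side not containing the lexicographically smallest leaf is used,
        so the representation is rooting-invariant.
        """
        all_leaves = frozenset(self.leaf_labels())
        ref = min(all_leaves)
        splits: set[frozenset[str]] = set()
        for node in self.postorder():
            if node is self.root or node.is_leaf:
                continue
            side = frozenset(_leafset(node))
            if ref in side:
                side = all_leaves - side
            if 1 < len(side) < len(all_leaves) - 1:
                splits.add(side)
        return splits

    def robinson_foulds(self, other: "PhyloTree") -> int:
        a, b = set(self.leaf_labels()), set(other.leaf_labels())
        if a != b:
            raise ValueError(f"leaf-set mismatch: {sorted(a ^ b)}")
        return len(self.bipartitions() ^ other.bipartitions())

    # ------------------------------------------------------------------ newick
    def to_newick(self, *, support: bool = True, mark_foreground: bool = False) -> str:
        def fmt_len(x: float | None) -> str:
            return "" if x is None else f":{x:.10g}"

        def fmt(node: TreeNode) -> str:
            if node.is_leaf:
                lab = node.label or ""
                if mark_foreground and node.foreground:
                    lab += "#1"
                return f"{lab}{fmt_len(node.length)}"
            inner = ",".join(fmt(c) for c in node.children)
            lab = ""
            if support and node.support is not None:
                lab = f"{node.support:g}"
            elif node.label:
                lab = node.label
            if mark_foreground and node.foreground:
                lab += "#1"
            return f"({inner}){lab}{fmt_len(node.length)}"

        return fmt(self.root) + ";"

    @classmethod
    def from_newick(cls, text: str) -> "PhyloTree":
        """Parse a Newick string; ``#1`` label suffixes become foreground marks."""
        try:
            dtree = dendropy.Tree.get(
                data=text, schema="newick", suppress_internal_node_taxa=True
            )
        except Exception as exc:  # dendropy error messages carry the position
            raise ValueError(f"Newick parse error: {exc}") from exc

        def convert(dnode: dendropy.Node) -> TreeNode:
            raw = dnode.taxon.label if dnode.taxon is not None else dnode.label
            node = TreeNode(length=dnode.edge.length)
            if raw is not None:
                if raw.endswith("#1"):
                    node.foreground = True
                    raw = raw[:-2] or None
                if raw is not None and not dnode.is_leaf():
                    try:
                        node.support = float(raw)
                        raw = None
                    except ValueError:
                        pass
                node.label = raw
            for child in dnode.child_nodes():
                node.add_child(convert(child))
            return node

        root = convert(dtree.seed_node)
        return cls(root)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PhyloTree):
            return NotImplemented
        return _node_key(self.root) == _node_key(other.root)

    def __repr__(self) -> str:  # pragma: no cover
        return f"PhyloTree({self.to_newick()})"


def _leafset(node: TreeNode) -> list[str]:
    out, stack = [], [node]
    while stack:
        n = stack.pop()
        if n.is_leaf:
            out.append(n.label)
        stack.extend(n.children)
    return out


def _node_key(node: TreeNode):
    # lengths compared at the writer's 10-significant-digit precision
    L = -1.0 if node.length is None else float(f"{node.length:.10g}")
    if node.is_leaf:
        return ("leaf", node.label or "", L)
    return ("node", tuple(sorted(_node_key(c) for c in node.children)), L)


def random_yule_tree(n_leaves: int, rng, *, labels: list[str] | None = None,
                     branch_scale: float = 0.1) -> PhyloTree:
    """Random Yule (pure-birth) tree with exponential branch lengths."""
    if labels is None:
        labels = [f"t{i + 1}" for i in range(n_leaves)]
    nodes = [TreeNode(lab) for lab in labels]
    for n in nodes:
        n.length = float(rng.exponential(branch_scale))
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = TreeNode(length=float(rng.exponential(branch_scale)))
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [parent]
    root = nodes[0]
    root.length = None
    return PhyloTree(root)


def compare_trees(t1: PhyloTree, t2: PhyloTree) -> tuple[int, list[frozenset[str]]]:
    """Robinson–Foulds distance plus the list of shared non-trivial bipartitions."""
    rf = t1.robinson_foulds(t2)
    shared = sorted(t1.bipartitions() & t2.bipartitions(), key=sorted)
    return rf, shared
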