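"""Rooted cladograms with polytomies.

A :class:`Cladogram` is a rooted tree over taxon labels.  The root stands for
the hypothetical ancestor carrying the plesiomorphic state of every
character; branch lengths are meaningless and are discarded on input.
Newick parsing is delegated to dendropy.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import dendropy

__all__ = [
    "Cladogram",
    "Node",
    "parse_tree",
    "format_tree",
    "tree_from_clades",
    "rf_distance",
    "strict_consensus",
]


class Node:
    """Tree node: leaves carry a taxon ``label``, internal nodes children."""

    __slots__ = ("label", "children")

    def __init__(self, label: str | None = None, children: Sequence["Node"] = ()):
        self.label = label
        self.children = list(children)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.label]
        out: list[str] = []
        stack = [self]
        while stack:
            node = stack.pop()
            if node.is_leaf:
                out.append(node.label)
            else:
                stack.extend(reversed(node.children))
        return out


class Cladogram:
    """Rooted tree over unique taxon labels; internal nodes have >=2 children."""

    def __init__(self, root: Node):
        self.root = root
        self._validate()

    def _validate(self) -> None:
        labels = self.root.leaves()
        if len(set(labels)) != len(labels):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise ValueError(f"duplicate leaf labels: {dupes}")
        for node in self.postorder():
            if not node.is_leaf and len(node.children) < 2 and node is not self.root:
                raise ValueError("internal node with a single child")
            if node.is_leaf and not node.label:
                raise ValueError("unlabeled leaf")
        # collapse a unary root quietly (artifact of some Newick strings)
        while not self.root.is_leaf and len(self.root.children) == 1:
            self.root = self.root.children[0]

    @property
    def taxa(self) -> frozenset[str]:
        return frozenset(self.root.leaves())

    @property
    def n_leaves(self) -> int:
        return len(self.root.leaves())

    def postorder(self) -> Iterable[Node]:
        stack, out = [self.root], []
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return reversed(out)

    def clades(self, nontrivial: bool = True) -> set[frozenset[str]]:
        """Leaf sets below each internal node.

        With ``nontrivial=True`` only clades with ``2 <= size < n`` are
        returned (singletons and the full leaf set carry no grouping
        information)."""
        n = self.n_leaves
        below: dict[int, frozenset[str]] = {}
        out: set[frozenset[str]] = set()
        for node in self.postorder():
            if node.is_leaf:
                below[id(node)] = frozenset((node.label,))
            else:
                clade = frozenset().union(*(below[id(c)] for c in node.children))
                below[id(node)] = clade
                if not nontrivial or 2 <= len(clade) < n:
                    out.add(clade)
        return out

    def newick(self) -> str:
        return format_tree(self)

    def is_binary(self) -> bool:
        return all(
            node.is_leaf or len(node.children) == 2 for node in self.postorder()
        )

    def __eq__(self, other: object) -> bool:
        """Topological identity: same leaf set and same clade set."""
        if not isinstance(other, Cladogram):
            return NotImplemented
        return self.taxa == other.taxa and self.clades() == other.clades()

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"Cladogram({self.newick()!r})"


def parse_tree(newick: str) -> Cladogram:
    """Parse a Newick string; branch lengths are ignored."""
    try:
        dtree = dendropy.Tree.get(
            data=newick,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:
        raise ValueError(f"malformed Newick: {exc}") from exc

    def convert(dnode) -> Node:
        children = dnode.child_nodes()
        if not children:
            label = dnode.taxon.label if dnode.taxon else dnode.label
            if label is None:
                raise ValueError("malformed Newick: unlabeled leaf")
            return Node(label=label.replace(" ", "_"))
        return Node(children=[convert(c) for c in children])

    return Cladogram(convert(dtree.seed_node))


def format_tree(tree: Cladogram) -> str:
    """Newick serialization (no branch lengths)."""

    def fmt(node: Node) -> str:
        if node.is_leaf:
            return node.label
        return "(" + ",".join(fmt(c) for c in node.children) + ")"

    return fmt(tree.root) + ";"


def tree_from_clades(
    clades: Iterable[frozenset[str]], taxa: Sequence[str]
) -> Cladogram:
    """Build the minimal rooted tree whose nontrivial clades are exactly
    ``clades``; taxa contained in no clade attach at the root.

    Requires the clades to be pairwise compatible (nested or disjoint).
    """
    taxa = list(taxa)
    taxon_set = frozenset(taxa)
    clade_list = sorted(
        {frozenset(c) for c in clades if 2 <= len(c) < len(taxa)},
        key=lambda c: (-len(c), sorted(c)[0]),
    )
    for i, a in enumerate(clade_list):
        if not a <= taxon_set:
            raise ValueError(f"clade {sorted(a)} outside the taxon set")
        for b in clade_list[i + 1 :]:
            if a & b and not (a <= b or b <= a):
                raise ValueError(
                    f"incompatible clades {sorted(a)} / {sorted(b)}"
                )

    order = {t: i for i, t in enumerate(taxa)}

    def build(members: frozenset[str], inner: list[frozenset[str]]) -> Node:
        top = [c for c in inner if not any(c < d for d in inner)]
        children: list[Node] = []
        covered: set[str] = set()
        for clade in sorted(top, key=lambda c: min(order[t] for t in c)):
            covered |= clade
            children.append(build(clade, [c for c in inner if c < clade]))
        for t in sorted(members - covered, key=order.get):
            children.append(Node(label=t))
        children.sort(key=lambda n: min(order[t] for t in n.leaves()))
        if len(children) == 1:
            return children[0]
        return Node(children=children)

    root = build(taxon_set, clade_list)
    if root.is_leaf:
        root = Node(children=[root])
    return Cladogram(root)


def _require_same_leaves(a: Cladogram, b: Cladogram) -> None:
    if a.taxa != b.taxa:
        only_a = sorted(a.taxa - b.taxa)
        only_b = sorted(b.taxa - a.taxa)
        raise ValueError(
            f"leaf sets differ: only in first {only_a}, only in second {only_b}"
        )


def rf_distance(a: Cladogram, b: Cladogram) -> int:
    """Rooted Robinson-Foulds distance: symmetric difference of the
    nontrivial clade sets.  Polytomies contribute only the clades they
    actually contain."""
    _require_same_leaves(a, b)
    return len(a.clades() ^ b.clades())


def strict_consensus(trees: Sequence[Cladogram]) -> Cladogram:
    """Tree containing exactly the clades present in every input tree."""
    trees = list(trees)
    if not trees:
        raise ValueError("strict consensus of an empty tree set")
    for t in trees[1:]:
        _require_same_leaves(trees[0], t)
    shared = set.intersection(*(t.clades() for t in trees))
    taxa = sorted(trees[0].taxa)
    return tree_from_clades(shared, taxa)
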