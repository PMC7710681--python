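"""Independent brute-force oracles for the parsimony tests.

Deliberately naive: tree length by exhaustive enumeration of internal-node
state assignments (the hypothetical ancestor above the root edge is fixed
plesiomorphic), and tree-space minima by enumerating every rooted binary
topology through recursive bipartition.  Nothing here shares code with the
package's dynamic programs.
"""

from __future__ import annotations

import itertools

from morphoclad import Cladogram, Node
from morphoclad.states import StateCode


def _nested(tree: Cladogram):
    def conv(node: Node):
        if node.is_leaf:
            return node.label
        return tuple(conv(c) for c in node.children)

    return conv(tree.root)


def _leaf_state_map(matrix, char_index):
    row = matrix.cells[char_index]
    out = {}
    for taxon, state in zip(matrix.taxa, row):
        out[taxon] = {
            StateCode.PLESIOMORPHIC: 0,
            StateCode.APOMORPHIC: 1,
            StateCode.MISSING: None,
        }[state]
    return out


def brute_force_char_length(tree: Cladogram, matrix, char_index: int) -> int:
    """Minimum changes for one character by enumerating every assignment of
    states to internal nodes and missing leaves; ancestor above the root
    edge is plesiomorphic."""
    nested = _nested(tree)
    states = _leaf_state_map(matrix, char_index)

    free: list = []  # internal nodes and missing leaves, in discovery order

    def collect(node):
        if isinstance(node, str):
            if states[node] is None:
                free.append(node)
            return
        free.append(node)
        for child in node:
            collect(child)

    collect(nested)

    best = None
    for assign in itertools.product((0, 1), repeat=len(free)):
        value = dict(zip(map(id, free), assign))

        def state_of(node):
            if isinstance(node, str) and states[node] is not None:
                return states[node]
            return value[id(node)]

        def changes(node, parent_state):
            s = state_of(node)
            total = int(s != parent_state)
            if not isinstance(node, str):
                total += sum(changes(child, s) for child in node)
            return total

        cost = changes(nested, 0)  # ancestor above the root edge is 0
        if best is None or cost < best:
            best = cost
    return best


def brute_force_length(tree: Cladogram, matrix) -> int:
    return sum(
        brute_force_char_length(tree, matrix, i)
        for i in range(matrix.n_characters)
    )


def all_rooted_binary_trees(labels: list[str]):
    """Every rooted binary topology, by recursive bipartition (the first
    label anchors one side so each split is produced once)."""
    if len(labels) == 1:
        yield Node(label=labels[0])
        return
    first, rest = labels[0], labels[1:]
    for r in range(len(rest)):
        for side in itertools.combinations(rest, r):
            left_labels = [first, *side]
            right_labels = [l for l in rest if l not in side]
            if not right_labels:
                continue
            for left in all_rooted_binary_trees(left_labels):
                for right in all_rooted_binary_trees(right_labels):
                    yield Node(children=[left, right])


def fitch_char_length(root: Node, states: dict[str, int | None]) -> int:
    """Classic Fitch set counting on a binary tree, plus one step if the
    root state set excludes the plesiomorphic ancestor above the root edge.
    Used (instead of assignment enumeration) where whole tree spaces are
    swept; cross-validated against :func:`brute_force_char_length`."""
    steps = 0

    def down(node: Node) -> set[int]:
        nonlocal steps
        if node.is_leaf:
            s = states[node.label]
            return {0, 1} if s is None else {s}
        left, right = (down(c) for c in node.children)
        meet = left & right
        if meet:
            return meet
        steps += 1
        return left | right

    root_set = down(root)
    if 0 not in root_set:
        steps += 1
    return steps


def fitch_length(tree: Cladogram, matrix) -> int:
    return sum(
        fitch_char_length(tree.root, _leaf_state_map(matrix, i))
        for i in range(matrix.n_characters)
    )


def brute_force_search(matrix) -> tuple[int, int]:
    """(minimum length over all rooted binary trees, number of optima)."""
    state_maps = [
        _leaf_state_map(matrix, i) for i in range(matrix.n_characters)
    ]
    best, count = None, 0
    for root in all_rooted_binary_trees(list(matrix.taxa)):
        score = sum(fitch_char_length(root, sm) for sm in state_maps)
        if best is None or score < best:
            best, count = score, 1
        elif score == best:
            count += 1
    return best, count
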