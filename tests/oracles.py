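"""Independent brute-force oracles used by the test suite.

The parsimony oracle enumerates every internal-node state assignment
explicitly (tips resolve independently given their parent, which is exact
for additive per-edge costs) and reports the minimum total cost plus the
set of states each node takes in at least one optimal assignment.  It is
deliberately independent of the package's dynamic-programming implementation.
"""

from __future__ import annotations

import itertools

import numpy as np

from disparitree.io_formats import INAPPLICABLE, MISSING, CharacterMatrix, DatedTree


def cost_matrix(k: int, ordered: bool) -> np.ndarray:
    s = np.arange(k)
    return (
        np.abs(s[:, None] - s[None, :]).astype(float)
        if ordered
        else (s[:, None] != s[None, :]).astype(float)
    )


def _allowed(cell, k: int) -> list[int]:
    if cell is MISSING or cell is INAPPLICABLE:
        return list(range(k))
    if isinstance(cell, int):
        return [cell]
    return sorted(cell)


def brute_force_mpr(
    tree: DatedTree, matrix: CharacterMatrix, char_index: int
) -> tuple[int, dict[str, frozenset]]:
    """Exhaustive minimum tree length and per-node MPR sets for one character."""
    universe = matrix.state_universe(char_index)
    k = len(universe)
    C = cost_matrix(k, matrix.ordered_flags[char_index])
    internal = [nd for nd in tree.nodes if not nd.is_tip]
    tips = tree.tips
    idx = {nd.id: i for i, nd in enumerate(internal)}
    allowed = {t.id: _allowed(matrix.cell(t.label, char_index), k) for t in tips}

    # per tip: minimum edge cost and argmin set as a function of parent state
    tip_min = {}
    tip_arg = {}
    for t in tips:
        a = allowed[t.id]
        sub = C[:, a]
        tip_min[t.id] = sub.min(axis=1)
        tip_arg[t.id] = [
            frozenset(a[j] for j in np.flatnonzero(sub[s] == sub[s].min()))
            for s in range(k)
        ]

    assignments = np.array(
        list(itertools.product(range(k), repeat=len(internal))), dtype=int
    )
    costs = np.zeros(len(assignments))
    for nd in internal:
        if nd.parent is not None:
            costs += C[assignments[:, idx[nd.parent.id]], assignments[:, idx[nd.id]]]
    for t in tips:
        costs += tip_min[t.id][assignments[:, idx[t.parent.id]]]

    best = costs.min()
    opt = assignments[costs <= best + 1e-9]
    sets: dict[str, frozenset] = {}
    for nd in internal:
        sets[nd.id] = frozenset(int(s) for s in np.unique(opt[:, idx[nd.id]]))
    for t in tips:
        acc: set[int] = set()
        for ps in np.unique(opt[:, idx[t.parent.id]]):
            acc |= tip_arg[t.id][ps]
        sets[t.id] = frozenset(acc)
    return int(round(best)), sets


def random_mpr_instance(rng: np.random.Generator):
    """Random small tree + single-character matrix with missing/polymorphic cells."""
    from disparitree.io_formats import TreeNode

    n_tips = int(rng.integers(2, 9))
    k = int(rng.integers(2, 5))
    ordered = bool(rng.random() < 0.5)
    labels = [f"t{i}" for i in range(n_tips)]

    # random topology by sequential attachment; occasional polytomies
    nodes = [TreeNode(label=labels[0]), TreeNode(label=labels[1])]
    root = TreeNode()
    for nd in nodes:
        root.add_child(nd)
    internals = [root]
    for lbl in labels[2:]:
        tip = TreeNode(label=lbl)
        if rng.random() < 0.3:  # attach to an existing internal -> polytomy
            rng.choice(internals).add_child(tip)
        else:
            host = rng.choice(internals)
            child = host.children[int(rng.integers(len(host.children)))]
            mid = TreeNode()
            host.children.remove(child)
            host.add_child(mid)
            mid.add_child(child)
            mid.add_child(tip)
            internals.append(mid)

    # ages: tips 0, internals by depth
    def set_ages(nd, depth=0):
        maxd = depth
        for c in nd.children:
            maxd = max(maxd, set_ages(c, depth + 1))
        return maxd

    height = set_ages(root) + 1

    def assign(nd, depth=0):
        nd.age = 0.0 if nd.is_tip else float(height - depth)
        for c in nd.children:
            assign(c, depth + 1)

    assign(root)
    tree = DatedTree(root)

    cells = []
    for _ in range(n_tips):
        u = rng.random()
        if u < 0.15:
            cells.append(MISSING)
        elif u < 0.25 and k > 2:
            size = int(rng.integers(2, k))
            cells.append(frozenset(int(s) for s in rng.choice(k, size, replace=False)))
        else:
            cells.append(int(rng.integers(k)))
    # ensure the state universe spans k states so both routes agree on range
    cells[0] = k - 1
    matrix = CharacterMatrix(labels, ["c1"], [[c] for c in cells], [ordered])
    return tree, matrix
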