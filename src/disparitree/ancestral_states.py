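"""Parsimony ancestral-state reconstruction and the phylogenetically
adjusted sample.

MPR sets (all states appearing in at least one most-parsimonious
reconstruction) are computed with a generalized Sankoff dynamic program:
a postorder pass accumulates subtree costs per state and a preorder pass
accumulates the cost of the rest of the tree, so the per-node MPR set is
simply the argmin of their sum.  One code path covers unordered (unit
cost) and ordered (linear |a-b| cost) characters, hard polytomies,
missing/inapplicable tips (uninformative, cost 0 everywhere) and
polymorphic tips (cost 0 on their state set).

The phylogenetically adjusted ("augmented") sample applies three
corrections commonly used for patchy fossil records: missing tip cells are
replaced by unambiguously reconstructed states, taxa are carried through
time by their ghost ranges, and internal branches enter the sample as
hypothetical ancestors with their reconstructed morphologies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_formats import (
    INAPPLICABLE,
    MISSING,
    Cell,
    CharacterMatrix,
    DatedTree,
    LineageDuration,
    TreeNode,
)

__all__ = ["MPRResult", "AugmentedSample", "mpr_sets", "build_augmented_sample"]

_INF = np.inf


@dataclass
class MPRResult:
    """MPR state sets for one character on a dated tree."""

    character: str
    node_sets: dict[str, frozenset]  # node id -> states in >=1 MPR
    length: int  # minimum total cost (unit or linear steps)


def _cost_matrix(k: int, ordered: bool) -> np.ndarray:
    states = np.arange(k)
    if ordered:
        return np.abs(states[:, None] - states[None, :]).astype(float)
    return (states[:, None] != states[None, :]).astype(float)


def _tip_allowed(cell: Cell, k: int) -> np.ndarray:
    """Zero/inf cost vector encoding a tip's observation."""
    cost = np.full(k, _INF)
    if cell is MISSING or cell is INAPPLICABLE:
        cost[:] = 0.0
    elif isinstance(cell, int):
        if cell >= k:
            raise ValueError(f"state {cell} exceeds declared state range 0..{k - 1}")
        cost[cell] = 0.0
    else:  # polymorphic set: partial information, any member state is free
        for s in cell:
            if s >= k:
                raise ValueError(f"state {s} exceeds declared state range 0..{k - 1}")
            cost[s] = 0.0
    return cost


def mpr_sets(
    tree: DatedTree,
    matrix: CharacterMatrix,
    char_index: int,
    *,
    tip_overrides: dict[str, Cell] | None = None,
) -> MPRResult:
    """MPR state sets and minimum tree length for one character.

    ``tip_overrides`` replaces individual tip observations (used when
    estimating a tip's own state with its cell treated as unknown).
    """
    universe = matrix.state_universe(char_index)
    k = len(universe)
    ordered = matrix.ordered_flags[char_index]
    C = _cost_matrix(k, ordered)
    overrides = tip_overrides or {}

    # postorder subtree costs S[v][s]
    post: list[TreeNode] = list(reversed(tree.nodes))  # preorder reversed = postorder
    S: dict[str, np.ndarray] = {}
    down_msg: dict[str, np.ndarray] = {}  # min_t(C[s,t] + S_child[t]) per child
    for nd in post:
        if nd.is_tip:
            cell = overrides.get(nd.label, matrix.cell(nd.label, char_index))
            S[nd.id] = _tip_allowed(cell, k)
        else:
            total = np.zeros(k)
            for child in nd.children:
                msg = (C + S[child.id][None, :]).min(axis=1)
                down_msg[child.id] = msg
                total = total + msg
            S[nd.id] = total

    length = float(S[tree.root.id].min())

    # preorder rest-of-tree costs U[v][s]
    U: dict[str, np.ndarray] = {tree.root.id: np.zeros(k)}
    for nd in tree.nodes:  # preorder
        if nd.is_tip:
            continue
        base = U[nd.id] + S[nd.id]
        for child in nd.children:
            # parent-state cost excluding this child's subtree
            excl = base - down_msg[child.id]
            U[child.id] = (C + excl[:, None]).min(axis=0)

    node_sets: dict[str, frozenset] = {}
    for nd in tree.nodes:
        total = S[nd.id] + U[nd.id]
        best = total.min()
        node_sets[nd.id] = frozenset(
            int(universe[s]) for s in np.flatnonzero(total <= best + 1e-9)
        )
    return MPRResult(
        character=matrix.characters[char_index],
        node_sets=node_sets,
        length=int(round(length)),
    )


@dataclass
class AugmentedSample:
    """Observed taxa (ancestrally filled) plus hypothetical ancestors.

    ``matrix`` rows are the observed taxa first (same order as the input
    matrix restricted to tree tips) followed by one ``HA_<node id>`` row
    per internal branch; ``durations`` is aligned with the rows.
    """

    matrix: CharacterMatrix
    durations: list[LineageDuration]
    n_observed: int

    @property
    def ids(self) -> list[str]:
        return self.matrix.taxa

    def missing_fraction(self) -> float:
        cells = [c for row in self.matrix.rows for c in row]
        n_bad = sum(1 for c in cells if c is MISSING or c is INAPPLICABLE)
        return n_bad / len(cells)


def build_augmented_sample(
    tree: DatedTree,
    matrix: CharacterMatrix,
    durations: list[LineageDuration],
) -> AugmentedSample:
    """Build the phylogenetically adjusted sample.

    For every internal branch the hypothetical ancestor takes the branch's
    child-node MPR state where that set is a singleton, otherwise the cell
    stays missing ("only unambiguously reconstructed states").  Missing
    observed cells are filled with the tip's own MPR estimate (computed
    with the cell unknown) under the same singleton rule; observed states,
    including polymorphisms, are never overwritten.
    """
    by_id = {d.lineage_id: d for d in durations}
    tip_labels = tree.tip_labels
    missing_branches = [
        nd.id for nd in tree.branches() if nd.id not in by_id
    ]
    if missing_branches:
        raise ValueError(
            f"durations missing for branches: {sorted(missing_branches)[:5]}"
        )
    ancestor_nodes = [nd for nd in tree.branches() if not nd.is_tip]

    obs_rows: list[list[Cell]] = [
        [matrix.cell(t, j) for j in range(matrix.n_characters)] for t in tip_labels
    ]
    anc_rows: list[list[Cell]] = [
        [MISSING] * matrix.n_characters for _ in ancestor_nodes
    ]

    for j in range(matrix.n_characters):
        res = mpr_sets(tree, matrix, j)
        for i, t in enumerate(tip_labels):
            cell = obs_rows[i][j]
            if cell is MISSING or cell is INAPPLICABLE:
                tip_set = res.node_sets[t]
                if len(tip_set) == 1:
                    obs_rows[i][j] = next(iter(tip_set))
        for i, nd in enumerate(ancestor_nodes):
            node_set = res.node_sets[nd.id]
            if len(node_set) == 1:
                anc_rows[i][j] = next(iter(node_set))

    ids = list(tip_labels) + [f"HA_{nd.id}" for nd in ancestor_nodes]
    aug = CharacterMatrix(
        taxa=ids,
        characters=list(matrix.characters),
        rows=obs_rows + anc_rows,
        ordered_flags=list(matrix.ordered_flags),
        symbols=matrix.symbols,
    )
    aligned = [by_id[t] for t in tip_labels] + [by_id[nd.id] for nd in ancestor_nodes]
    return AugmentedSample(matrix=aug, durations=aligned, n_observed=len(tip_labels))
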