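"""Synthetic data with known truth: fossilized birth-death trees,
uncorrelated relaxed-clock branch rates, and Mk(+Gamma) discrete characters.

The generator emulates the shape of a total-evidence mysticete-style
dataset: a dated tree with both extant and fossil tips over ~38 Ma,
a few hundred discrete characters (a small fraction ordered), heavy
missing data, gamma rate heterogeneity across characters and branches,
and an early-burst epoch of elevated rates.  Every stochastic choice
flows from the single config seed, so identical configs reproduce
byte-identical fixtures.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field

import numpy as np
import yaml

from .io_formats import (
    MISSING,
    CharacterMatrix,
    DatedTree,
    StratRecord,
    TreeNode,
    write_character_matrix,
    write_newick,
    write_strat_ranges,
)

__all__ = [
    "SimConfig",
    "SimTruth",
    "simulate_fbd_tree",
    "simulate_branch_rates",
    "simulate_characters",
    "simulate_dataset",
    "effective_relative_rates",
    "generate_fixture",
]


@dataclass
class SimConfig:
    """Parameters of the full generative model (rates per lineage per Ma)."""

    birth_rate: float = 0.3
    death_rate: float = 0.22
    fossil_rate: float = 0.7  # fossil-recovery rate psi on extinct terminal branches
    origin_age: float = 38.0
    min_tips: int = 60  # rejection-sample until the sampled tip count is in range
    max_tips: int | None = 130
    clock_mean: float = 0.01  # expected changes/character/Ma
    clock_sd: float = 0.1  # clock drawn from N(mean, sd) truncated > 0
    igr_variance: float = 0.1  # variance nu of mean-1 gamma branch multipliers
    n_characters: int = 272
    n_states_unordered: int = 2
    n_states_ordered: int = 4
    ordered_fraction: float = 25 / 272
    gamma_shape: float = 1.0  # across-character rate heterogeneity
    missing_fraction: float = 0.43
    strat_window: float = 2.0  # width of the uniform tip-age uncertainty window, Ma
    # (older, younger, multiplier) windows applied to all characters
    epoch_multipliers: list[tuple[float, float, float]] = field(
        default_factory=lambda: [(38.0, 30.0, 5.0)]
    )
    taxon_biased_missing: bool = False  # fragmentary-fossil style deletion
    seed: int = 0

    def __post_init__(self) -> None:
        if self.birth_rate <= 0 or self.death_rate < 0 or self.fossil_rate < 0:
            raise ValueError("rates must be non-negative (birth strictly positive)")
        if not 0 <= self.missing_fraction <= 1:
            raise ValueError("missing_fraction must be in [0, 1]")
        if not 0 <= self.ordered_fraction <= 1:
            raise ValueError("ordered_fraction must be in [0, 1]")
        if self.origin_age <= 0:
            raise ValueError("origin_age must be positive")
        if self.seed is None:
            raise ValueError("seed is mandatory")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["epoch_multipliers"] = [list(e) for e in self.epoch_multipliers]
        return d


@dataclass
class SimTruth:
    """Ground truth of one simulated dataset."""

    tree_newick: str
    multipliers: dict[str, float]  # branch id -> relative-rate multiplier
    clock_rate: float
    character_factors: list[float]  # per-character gamma factors
    root_states: list[int]
    ordered_indices: list[int]
    tip_ages: dict[str, float]  # absolute tip ages for re-anchoring the newick
    # per character: list of (branch id, age, from_state, to_state)
    histories: list[list[tuple[str, float, int, int]]]
    masked_cells: list[tuple[str, int]]  # (taxon, character index) deleted cells

    def to_dict(self) -> dict:
        return {
            "tree_newick": self.tree_newick,
            "multipliers": self.multipliers,
            "clock_rate": self.clock_rate,
            "character_factors": self.character_factors,
            "root_states": self.root_states,
            "ordered_indices": self.ordered_indices,
            "tip_ages": self.tip_ages,
            "histories": [
                [[b, a, s, t] for b, a, s, t in h] for h in self.histories
            ],
            "masked_cells": [[t, j] for t, j in self.masked_cells],
        }


# ---------------------------------------------------------------------------
# Fossilized birth-death tree
# ---------------------------------------------------------------------------


class _Lineage:
    __slots__ = ("start", "end", "children", "extinct", "occurrences", "label")

    def __init__(self, start: float):
        self.start = start  # age at which the lineage begins (older)
        self.end = 0.0  # age at which it ends (speciation, extinction or present)
        self.children: list["_Lineage"] = []
        self.extinct = False
        self.occurrences: list[float] = []
        self.label: str | None = None


def _grow(cfg: SimConfig, rng: np.random.Generator) -> _Lineage:
    """Forward birth-death simulation from one lineage at the origin age."""
    root = _Lineage(cfg.origin_age)
    active = [root]
    total_rate = cfg.birth_rate + cfg.death_rate
    while active:
        lin = active.pop()
        wait = rng.exponential(1.0 / total_rate) if total_rate > 0 else np.inf
        event_age = lin.start - wait
        if event_age <= 0:
            lin.end = 0.0
            continue
        lin.end = event_age
        if rng.random() < cfg.birth_rate / total_rate:
            for _ in range(2):
                child = _Lineage(event_age)
                lin.children.append(child)
                active.append(child)
        else:
            lin.extinct = True
    return root


def simulate_fbd_tree(
    cfg: SimConfig, rng: np.random.Generator | None = None
) -> tuple[DatedTree, list[StratRecord]]:
    """Simulate a dated tree with extant and fossil tips plus strat records.

    Extant survivors become age-0 tips.  Extinct terminal lineages are
    recovered as fossil tips when they carry at least one Poisson(psi)
    fossil occurrence; the dated tip sits at the *oldest* occurrence, any
    younger occurrences become the taxon's observed range and younger
    referred material.  Stratigraphic records get a uniform uncertainty
    window of width ``strat_window`` centred on the tip age.  The draw is
    rejected until at least two sampled tips survive the pruning.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    for _attempt in range(1000):
        root = _grow(cfg, rng)
        # fossil occurrences on extinct terminal lineages
        sampled: list[_Lineage] = []

        def visit(lin: _Lineage) -> None:
            if lin.children:
                for c in lin.children:
                    visit(c)
            elif lin.extinct:
                span = lin.start - lin.end
                n_occ = rng.poisson(cfg.fossil_rate * span)
                if n_occ > 0:
                    lin.occurrences = sorted(
                        lin.end + rng.random(n_occ) * span, reverse=True
                    )
                    sampled.append(lin)
            else:
                sampled.append(lin)

        visit(root)
        lo = max(cfg.min_tips, 2)
        hi = cfg.max_tips if cfg.max_tips is not None else np.inf
        if lo <= len(sampled) <= hi:
            break
    else:
        raise RuntimeError(
            "1000 rejected birth-death draws; increase birth/fossil rates or origin age"
        )

    keep = set(map(id, sampled))

    def prune(lin: _Lineage) -> TreeNode | None:
        """Convert to TreeNode keeping sampled tips, suppressing unifurcations."""
        if not lin.children:
            if id(lin) not in keep:
                return None
            nd = TreeNode(age=lin.occurrences[0] if lin.occurrences else 0.0)
            nd._lineage = lin  # type: ignore[attr-defined]
            return nd
        kids = [prune(c) for c in lin.children]
        kids = [k for k in kids if k is not None]
        if not kids:
            return None
        if len(kids) == 1:
            return kids[0]
        nd = TreeNode(age=lin.end)
        for k in kids:
            nd.add_child(k)
        return nd

    proot = prune(root)
    while proot is not None and len(proot.children) == 1:  # pragma: no cover
        proot = proot.children[0]

    # label tips and build strat records
    records: list[StratRecord] = []
    n_extant = n_fossil = 0
    for nd in _preorder(proot):
        if nd.children:
            continue
        lin = nd._lineage  # type: ignore[attr-defined]
        if lin.occurrences:
            n_fossil += 1
            nd.label = f"F{n_fossil}"
            half = cfg.strat_window / 2
            oldest = nd.age + half
            youngest = max(nd.age - half, 0.0)
            younger_mat = None
            if lin.occurrences[-1] < youngest - 1e-9:
                younger_mat = lin.occurrences[-1]
            records.append(StratRecord(nd.label, oldest, youngest, younger_mat))
        else:
            n_extant += 1
            nd.label = f"T{n_extant}"
            records.append(StratRecord(nd.label, 0.0, 0.0, None))
        del nd._lineage  # type: ignore[attr-defined]
    tree = DatedTree(proot)
    order = {t: i for i, t in enumerate(tree.tip_labels)}
    records.sort(key=lambda r: order[r.taxon])
    return tree, records


def _preorder(root: TreeNode):
    stack = [root]
    while stack:
        nd = stack.pop()
        yield nd
        stack.extend(reversed(nd.children))


# ---------------------------------------------------------------------------
# Branch rates and characters
# ---------------------------------------------------------------------------


def simulate_branch_rates(
    tree: DatedTree, nu: float, seed: int | None = None, rng: np.random.Generator | None = None
) -> dict[str, float]:
    """i.i.d. mean-1 gamma branch-rate multipliers (variance nu); nu=0 -> strict clock."""
    if nu < 0:
        raise ValueError("igr variance must be non-negative")
    if rng is None:
        rng = np.random.default_rng(seed)
    mult: dict[str, float] = {}
    for nd in tree.branches():
        mult[nd.id] = float(rng.gamma(1.0 / nu, nu)) if nu > 0 else 1.0
        nd.rate = mult[nd.id]
    return mult


def _epoch_rate(age: float, cfg: SimConfig) -> float:
    for older, younger, m in cfg.epoch_multipliers:
        if older >= age > younger:
            return m
    return 1.0


def _epoch_breaks(start: float, end: float, cfg: SimConfig) -> list[tuple[float, float]]:
    """Split the branch interval [start, end] (start older) at epoch boundaries."""
    cuts = {start, end}
    for older, younger, _ in cfg.epoch_multipliers:
        for edge in (older, younger):
            if start > edge > end:
                cuts.add(edge)
    ages = sorted(cuts, reverse=True)
    return list(zip(ages[:-1], ages[1:]))


def effective_relative_rates(
    tree: DatedTree, multipliers: dict[str, float], cfg: SimConfig
) -> dict[str, float]:
    """True time-averaged relative rate per branch (multiplier x epoch factor).

    This is what a relaxed-clock analysis would ideally recover as the
    branch's relative rate when epoch windows modulate the clock: the
    igr multiplier scaled by the duration-weighted mean epoch multiplier
    over the branch's interval.  Zero-duration branches take the epoch
    factor at their age.
    """
    eff: dict[str, float] = {}
    for nd in tree.branches():
        start, end = nd.parent.age, nd.age
        if start - end <= 0:
            factor = _epoch_rate(start, cfg)
        else:
            weighted = sum(
                (s - e) * _epoch_rate((s + e) / 2, cfg)
                for s, e in _epoch_breaks(start, end, cfg)
            )
            factor = weighted / (start - end)
        eff[nd.id] = multipliers[nd.id] * factor
    return eff


def simulate_characters(
    tree: DatedTree,
    multipliers: dict[str, float],
    cfg: SimConfig,
    rng: np.random.Generator | None = None,
    clock_rate: float | None = None,
) -> tuple[CharacterMatrix, SimTruth]:
    """Evolve discrete characters along the tree and mask cells.

    Each character gets a mean-1 gamma rate factor; along a branch the
    total change rate is ``clock x branch multiplier x character factor x
    epoch multiplier``.  Unordered characters jump to a uniformly chosen
    other state; ordered characters take +/-1 steps (reflecting at the end
    states).  Cells are then deleted at the configured missing fraction and
    the full change history is recorded.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    if cfg.n_states_unordered < 2 or cfg.n_states_ordered < 2:
        raise ValueError("characters need at least 2 states")
    if clock_rate is None:
        if cfg.clock_sd > 0:
            clock_rate = 0.0
            while clock_rate <= 1e-6:
                clock_rate = float(rng.normal(cfg.clock_mean, cfg.clock_sd))
        else:
            clock_rate = cfg.clock_mean

    p = cfg.n_characters
    n_ordered = int(round(cfg.ordered_fraction * p))
    ordered_idx = sorted(
        int(i) for i in rng.choice(p, size=n_ordered, replace=False)
    )
    ordered_set = set(ordered_idx)
    factors = rng.gamma(cfg.gamma_shape, 1.0 / cfg.gamma_shape, size=p)

    tip_labels = tree.tip_labels
    rows: dict[str, list[int | object]] = {t: [0] * p for t in tip_labels}
    root_states: list[int] = []
    histories: list[list[tuple[str, float, int, int]]] = []

    for j in range(p):
        ordered = j in ordered_set
        k = cfg.n_states_ordered if ordered else cfg.n_states_unordered
        root_state = int(rng.integers(k))
        root_states.append(root_state)
        history: list[tuple[str, float, int, int]] = []
        state_at: dict[str, int] = {tree.root.id: root_state}
        for nd in tree.nodes:
            if nd.parent is None:
                continue
            state = state_at[nd.parent.id]
            base = clock_rate * multipliers[nd.id] * factors[j]
            for seg_start, seg_end in _epoch_breaks(nd.parent.age, nd.age, cfg):
                rate = base * _epoch_rate((seg_start + seg_end) / 2, cfg)
                t = seg_start
                while rate > 0:
                    t = t - rng.exponential(1.0 / rate)
                    if t <= seg_end:
                        break
                    old = state
                    if ordered:
                        if state == 0:
                            state = 1
                        elif state == k - 1:
                            state = k - 2
                        else:
                            state = state + (1 if rng.random() < 0.5 else -1)
                    else:
                        step = int(rng.integers(k - 1))
                        state = step if step < state else step + 1
                    history.append((nd.id, float(t), old, state))
            state_at[nd.id] = state
            if nd.is_tip:
                rows[nd.label][j] = state
        histories.append(history)

    # missing-data mask
    masked: list[tuple[str, int]] = []
    n_tips = len(tip_labels)
    if cfg.missing_fraction > 0:
        if cfg.taxon_biased_missing:
            # fragmentary-fossil emulation: per-taxon deletion probabilities
            # drawn from a beta with the configured mean
            a = 2.0
            b = a * (1 - cfg.missing_fraction) / cfg.missing_fraction
            per_taxon = rng.beta(a, b, size=n_tips)
            for i, t in enumerate(tip_labels):
                hit = rng.random(p) < per_taxon[i]
                for j in np.flatnonzero(hit):
                    masked.append((t, int(j)))
        else:
            flat = rng.random((n_tips, p)) < cfg.missing_fraction
            for i, t in enumerate(tip_labels):
                for j in np.flatnonzero(flat[i]):
                    masked.append((t, int(j)))
    cells: list[list] = []
    masked_set = set(masked)
    for t in tip_labels:
        cells.append(
            [MISSING if (t, j) in masked_set else rows[t][j] for j in range(p)]
        )
    matrix = CharacterMatrix(
        taxa=list(tip_labels),
        characters=[f"char{j + 1}" for j in range(p)],
        rows=cells,
        ordered_flags=[j in ordered_set for j in range(p)],
    )
    truth = SimTruth(
        tree_newick=write_newick(tree),
        multipliers=dict(multipliers),
        clock_rate=float(clock_rate),
        character_factors=[float(f) for f in factors],
        root_states=root_states,
        ordered_indices=ordered_idx,
        tip_ages={t.label: float(t.age) for t in tree.tips},
        histories=histories,
        masked_cells=masked,
    )
    return matrix, truth


def simulate_dataset(
    cfg: SimConfig,
) -> tuple[DatedTree, list[StratRecord], CharacterMatrix, SimTruth]:
    """Full simulation: tree + strat records + branch rates + characters."""
    rng = np.random.default_rng(cfg.seed)
    tree, records = simulate_fbd_tree(cfg, rng)
    multipliers = simulate_branch_rates(tree, cfg.igr_variance, rng=rng)
    matrix, truth = simulate_characters(tree, multipliers, cfg, rng=rng)
    return tree, records, matrix, truth


# ---------------------------------------------------------------------------
# Fixture on disk
# ---------------------------------------------------------------------------

FIXTURE_FILES = ("tree.nwk", "matrix.nex", "strat.csv", "truth.json", "config.yaml")


def generate_fixture(cfg: SimConfig, outdir: str, force: bool = False) -> list[str]:
    """Write a complete synthetic dataset (5 files) to ``outdir``.

    Re-running with the same config produces byte-identical files.
    """
    if os.path.exists(outdir) and os.listdir(outdir) and not force:
        raise FileExistsError(f"{outdir} exists and is not empty (use force=True)")
    os.makedirs(outdir, exist_ok=True)
    tree, records, matrix, truth = simulate_dataset(cfg)
    paths = [os.path.join(outdir, f) for f in FIXTURE_FILES]
    write_newick(tree, paths[0])
    write_character_matrix(matrix, paths[1])
    write_strat_ranges(records, paths[2])
    with open(paths[3], "w", encoding="utf-8") as fh:
        json.dump(truth.to_dict(), fh, sort_keys=True, separators=(",", ":"))
        fh.write("\n")
    with open(paths[4], "w", encoding="utf-8") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=True)
    return paths
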