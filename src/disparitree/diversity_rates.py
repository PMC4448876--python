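"""Lineage-through-time diversity and absolute evolutionary-rate curves.

Diversity is counted on the dated tree itself (fossil tips included), so
the curve can decline — unlike extant-only lineage-through-time plots.
Rates start from per-branch *relative* clock-rate multipliers (e.g. the
median rates reported on a relaxed-clock consensus tree) and are converted
to absolute percent change per Ma by multiplying with the overall clock
rate (expected changes per character per Ma) times 100.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .disparity import BinSeries, make_bins
from .io_formats import DatedTree, LineageDuration, lineage_durations

__all__ = ["BranchRates", "ltt_curve", "absolute_branch_rates", "binned_rate_curve"]


# ---------------------------------------------------------------------------
# Lineage-through-time
# ---------------------------------------------------------------------------


def _alive_at(duration: LineageDuration, age: float) -> bool:
    # terminal ranges are closed at their younger end (a taxon still counts at
    # its last appearance); ghost lineages hand over to their descendants at
    # the split, so they are half-open at the younger end.
    if duration.kind == "ghost_lineage":
        return duration.start >= age > duration.end
    return duration.start >= age >= duration.end


def ltt_curve(
    durations: list[LineageDuration],
    bins: list[tuple[float, float]] | None = None,
    mode: str = "boundary",
) -> BinSeries:
    """Lineage counts through time in 1-Ma steps.

    ``boundary`` mode (default) counts lineages alive at each bin boundary
    age and reports the count at the bin's older edge plus a terminal
    [youngest, youngest] entry; ``overlap`` mode counts lineages whose
    duration overlaps each bin with positive length.  Ages above the root
    simply count zero.
    """
    if bins is None:
        bins = make_bins()
    if mode == "boundary":
        boundaries = [older for older, _ in bins] + [bins[-1][1]]
        out_bins = [(b, b) for b in boundaries]
        counts = np.array(
            [sum(1 for d in durations if _alive_at(d, b)) for b in boundaries]
        )
    elif mode == "overlap":
        out_bins = list(bins)
        counts = np.array(
            [
                sum(1 for d in durations if d.overlaps(older, younger))
                for older, younger in bins
            ]
        )
    else:
        raise ValueError(f"unknown LTT mode {mode!r}")
    vals = counts.astype(float)
    return BinSeries(out_bins, vals, vals.copy(), vals.copy(), counts, "diversity")


# ---------------------------------------------------------------------------
# Absolute rates
# ---------------------------------------------------------------------------


@dataclass
class BranchRates:
    """Per-branch relative and absolute evolutionary rates.

    ``absolute = relative * clock_rate * 100`` gives percent change per Ma
    when ``clock_rate`` is the overall expected change per character per Ma
    (e.g. a posterior-median clock rate of 0.0018 makes a relative rate of
    1.0 equal 0.18 %/Ma).
    """

    branch_ids: list[str]
    relative: np.ndarray
    clock_rate: float
    absolute: np.ndarray

    def rate_of(self, branch_id: str) -> float:
        return float(self.absolute[self.branch_ids.index(branch_id)])

    def to_tsv(self, tree: DatedTree, path: str | None = None) -> str:
        lines = ["branch\tparent_age\tchild_age\trelative\tabsolute_pct_per_ma"]
        for bid, rel, ab in zip(self.branch_ids, self.relative, self.absolute):
            nd = tree.node(bid)
            lines.append(
                f"{bid}\t{nd.parent.age:.10g}\t{nd.age:.10g}\t{rel:.10g}\t{ab:.10g}"
            )
        out = "\n".join(lines) + "\n"
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(out)
        return out


def absolute_branch_rates(tree: DatedTree, clock_rate: float) -> BranchRates:
    """Convert per-branch relative rate annotations to absolute %/Ma."""
    if clock_rate <= 0:
        raise ValueError("clock_rate must be positive")
    missing = [nd.id for nd in tree.branches() if nd.rate is None]
    if missing:
        raise ValueError(f"branches without rate annotation: {sorted(missing)[:10]}")
    ids = [nd.id for nd in tree.branches()]
    rel = np.array([tree.node(b).rate for b in ids], dtype=float)
    if (rel < 0).any():
        raise ValueError("negative relative rates")
    return BranchRates(ids, rel, clock_rate, rel * clock_rate * 100.0)


def binned_rate_curve(
    tree: DatedTree,
    rates: BranchRates,
    bins: list[tuple[float, float]] | None = None,
    *,
    durations: list[LineageDuration] | None = None,
    membership: str = "overlap",
    weighted: bool = False,
) -> BinSeries:
    """Lineage-averaged absolute rate per 1-Ma bin, band = mean +/- SEM.

    Branch membership uses the branch's own duration (no younger-material
    extensions: a branch's change is in place by its tip's oldest
    occurrence).  ``membership='midpoint'`` assigns each branch to the bin
    holding its temporal midpoint; ``weighted=True`` weights branch rates
    by their overlap length instead of counting each branch once.
    Single-branch bins report SEM 0; empty bins stay undefined.
    """
    if bins is None:
        bins = make_bins()
    if durations is None:
        durations = lineage_durations(tree, use_extensions=False)
    by_id = {d.lineage_id: d for d in durations}
    rate_by_id = dict(zip(rates.branch_ids, rates.absolute))

    nb = len(bins)
    values = np.full(nb, np.nan)
    lower = np.full(nb, np.nan)
    upper = np.full(nb, np.nan)
    counts = np.zeros(nb, dtype=int)
    for b, (older, younger) in enumerate(bins):
        member_rates: list[float] = []
        weights: list[float] = []
        for bid, rate in rate_by_id.items():
            d = by_id.get(bid)
            if d is None:
                continue
            if membership == "overlap":
                ov = min(d.start, older) - max(d.end, younger)
                hit = ov > 0 or (d.span == 0 and older >= d.start > younger)
            elif membership == "midpoint":
                mid = (d.start + d.end) / 2
                hit = older > mid >= younger or (mid == older == bins[0][0])
                ov = 1.0
            else:
                raise ValueError(f"unknown membership mode {membership!r}")
            if hit:
                member_rates.append(rate)
                weights.append(max(ov, 0.0) if weighted else 1.0)
        n = len(member_rates)
        counts[b] = n
        if n == 0:
            continue
        arr = np.asarray(member_rates)
        w = np.asarray(weights)
        mean = float(np.average(arr, weights=w))
        sem = float(arr.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0
        values[b] = mean
        lower[b] = mean - sem
        upper[b] = mean + sem
    return BinSeries(bins, values, lower, upper, counts, "rate")
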