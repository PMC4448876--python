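"""Morphological disparity through time.

The pipeline is: discrete character sample -> pairwise distance matrix ->
principal coordinates analysis (PCoA) -> per-time-bin sum of axis-score
variances, with bootstrap confidence bands and an optional fixed-n
rarefaction.

Distances follow the Wills convention for incomplete discrete matrices:
per-character differences are |a-b| for ordered and 0/1 for unordered
characters (polymorphic cells take the minimum difference over cross-set
pairs), summed over the characters scored in both rows and rescaled by
``C_total / |shared|`` before the square root so that patchy rows are not
systematically drawn towards the origin.  With complete data this reduces
to the ordinary Euclidean distance on state vectors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .io_formats import (
    INAPPLICABLE,
    MISSING,
    CharacterMatrix,
    LineageDuration,
)
from .ancestral_states import AugmentedSample

__all__ = [
    "DistanceMatrix",
    "Ordination",
    "BinSeries",
    "make_bins",
    "pairwise_distances",
    "pcoa",
    "disparity_curve",
    "rarefied_disparity_curve",
    "sum_of_variances",
]


# ---------------------------------------------------------------------------
# Time bins
# ---------------------------------------------------------------------------


def make_bins(oldest: float = 37.0, youngest: float = 0.0, step: float = 1.0) -> list[tuple[float, float]]:
    """Half-open [older, younger) 1-Ma bins from ``oldest`` down to ``youngest``."""
    if step <= 0:
        raise ValueError("bin step must be positive")
    if oldest <= youngest:
        raise ValueError("oldest must exceed youngest")
    n = int(np.ceil((oldest - youngest) / step - 1e-9))
    edges = oldest - step * np.arange(n)
    return [(float(e), float(max(e - step, youngest))) for e in edges]


@dataclass
class BinSeries:
    """A per-bin curve: point value, uncertainty band and membership count.

    Undefined bins keep ``nan`` values and ``defined=False`` rather than
    being zero-filled.
    """

    bins: list[tuple[float, float]]
    values: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    counts: np.ndarray
    metric: str
    defined: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        if self.defined is None:
            self.defined = ~np.isnan(np.asarray(self.values, dtype=float))
        for name in ("values", "lower", "upper"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        self.counts = np.asarray(self.counts, dtype=int)

    def to_tsv(self, path: str | None = None) -> str:
        lines = ["bin_older\tbin_younger\tn\tvalue\tlo\thi"]
        for (older, younger), n, v, lo, hi in zip(
            self.bins, self.counts, self.values, self.lower, self.upper
        ):
            fmt = lambda x: "NA" if np.isnan(x) else format(x, ".10g")
            lines.append(f"{older:g}\t{younger:g}\t{n}\t{fmt(v)}\t{fmt(lo)}\t{fmt(hi)}")
        out = "\n".join(lines) + "\n"
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(out)
        return out

    def to_dict(self) -> dict:
        clean = lambda a: [None if np.isnan(x) else float(x) for x in a]
        return {
            "metric": self.metric,
            "bin_older": [b[0] for b in self.bins],
            "bin_younger": [b[1] for b in self.bins],
            "n": [int(c) for c in self.counts],
            "value": clean(self.values),
            "lo": clean(self.lower),
            "hi": clean(self.upper),
        }


# ---------------------------------------------------------------------------
# Distances
# ---------------------------------------------------------------------------


@dataclass
class DistanceMatrix:
    ids: list[str]
    values: np.ndarray  # symmetric, zero diagonal
    comparable: np.ndarray  # per-pair shared-character counts
    incomparable_pairs: list[tuple[str, str]]
    dropped_ids: list[str] = field(default_factory=list)

    @property
    def n(self) -> int:
        return len(self.ids)

    def to_tsv(self, path: str | None = None) -> str:
        lines = ["\t".join([""] + self.ids)]
        for i, rid in enumerate(self.ids):
            lines.append(
                "\t".join([rid] + [format(v, ".10g") for v in self.values[i]])
            )
        out = "\n".join(lines) + "\n"
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(out)
        return out


def _encode(matrix: CharacterMatrix):
    """Single-state cells to an int array (-1 observed-missing); polymorphic cells listed aside."""
    n, p = matrix.n_taxa, matrix.n_characters
    codes = np.full((n, p), -1, dtype=float)
    poly: dict[tuple[int, int], frozenset] = {}
    for i, row in enumerate(matrix.rows):
        for j, c in enumerate(row):
            if isinstance(c, int):
                codes[i, j] = c
            elif isinstance(c, frozenset):
                poly[(i, j)] = c
    return codes, poly


def pairwise_distances(
    sample: AugmentedSample | CharacterMatrix, *, rescale: bool = True
) -> DistanceMatrix:
    """Pairwise morphological distances between sample rows.

    ``rescale=False`` gives the raw pairwise-deletion variant
    ``sqrt(sum delta^2)`` without the ``C_total/|shared|`` factor.  Rows
    involved in pairs sharing no scored characters are dropped from the
    result (greedily, most-incomparable first) with a warning; if more
    than 5% of pairs are incomparable that is a hard error.
    """
    matrix = sample.matrix if isinstance(sample, AugmentedSample) else sample
    if matrix.n_taxa < 2:
        raise ValueError("need at least two rows")
    codes, poly = _encode(matrix)
    n, p = codes.shape
    ordered = np.asarray(matrix.ordered_flags, dtype=bool)

    observed = codes >= 0
    for (i, j) in poly:
        observed[i, j] = True

    D2 = np.zeros((n, n))
    shared = np.zeros((n, n), dtype=int)
    for i in range(n):
        both = observed[i] & observed  # (n, p)
        diff = np.abs(codes[i][None, :] - codes)  # nan-free where both single
        delta = np.where(ordered[None, :], diff, (diff > 0).astype(float))
        delta = np.where(both & (codes[i][None, :] >= 0) & (codes >= 0), delta, 0.0)
        D2[i] = np.sum(delta**2, axis=1)
        shared[i] = both.sum(axis=1)

    # patch pairs involving polymorphic cells: delta = min over cross-set pairs
    for (i, j), states in poly.items():
        for other in range(n):
            if other == i or not observed[other, j]:
                continue
            if (other, j) in poly and other < i:
                continue  # poly-poly pair handled once, from the lower row index
            cell = matrix.rows[other][j]
            other_states = {cell} if isinstance(cell, int) else cell
            if ordered[j]:
                d = min(abs(a - b) for a in states for b in other_states)
            else:
                d = 0.0 if states & frozenset(other_states) else 1.0
            D2[i, other] += d**2
            D2[other, i] += d**2

    with np.errstate(divide="ignore", invalid="ignore"):
        if rescale:
            D = np.sqrt(np.where(shared > 0, p / np.maximum(shared, 1) * D2, np.nan))
        else:
            D = np.sqrt(np.where(shared > 0, D2, np.nan))
    np.fill_diagonal(D, 0.0)
    np.fill_diagonal(shared, p)

    iu = np.triu_indices(n, k=1)
    bad = np.isnan(D[iu])
    incomparable = [
        (matrix.taxa[iu[0][k]], matrix.taxa[iu[1][k]]) for k in np.flatnonzero(bad)
    ]
    ids = list(matrix.taxa)
    dropped: list[str] = []
    if incomparable:
        if len(incomparable) > 0.05 * len(iu[0]):
            raise ValueError(
                f"{len(incomparable)} of {len(iu[0])} pairs share no characters"
            )
        warnings.warn(
            f"dropping rows involved in incomparable pairs: {incomparable[:10]}",
            stacklevel=2,
        )
        keep = np.ones(n, dtype=bool)
        while np.isnan(D[np.ix_(keep, keep)]).any():
            nan_counts = np.where(keep, np.nansum(np.isnan(D) & keep[None, :], axis=1), -1)
            worst = int(np.argmax(nan_counts))
            keep[worst] = False
            dropped.append(matrix.taxa[worst])
        ids = [t for t, k in zip(matrix.taxa, keep) if k]
        D = D[np.ix_(keep, keep)]
        shared = shared[np.ix_(keep, keep)]
    return DistanceMatrix(ids, D, shared, incomparable, dropped)


# ---------------------------------------------------------------------------
# PCoA
# ---------------------------------------------------------------------------


@dataclass
class Ordination:
    """Principal-coordinates embedding of a distance matrix.

    ``coords`` spans the retained (positive-eigenvalue) axes in descending
    eigenvalue order, scaled so the sum of squared scores on axis m equals
    its eigenvalue; percent variance is computed over positive eigenvalues
    only (negative eigenvalues are discarded, no Cailliez/Lingoes shift).
    """

    ids: list[str]
    coords: np.ndarray  # (n, k_pos)
    eigenvalues: np.ndarray  # all n, descending
    proportion: np.ndarray  # per retained axis, sums to 1

    @property
    def n_axes(self) -> int:
        return self.coords.shape[1]

    def axes_for_threshold(self, variance_threshold: float) -> int:
        """Smallest k whose cumulative percent variance reaches the threshold."""
        cum = np.cumsum(self.proportion)
        return int(np.searchsorted(cum, variance_threshold - 1e-12) + 1)


def pcoa(dm: DistanceMatrix, *, tolerance: float = 1e-10) -> Ordination:
    """Classical (Gower) PCoA of a complete symmetric distance matrix."""
    D = np.asarray(dm.values, dtype=float)
    if np.isnan(D).any():
        raise ValueError("distance matrix contains incomparable (NaN) pairs")
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    B = (B + B.T) / 2
    eigval, eigvec = scipy.linalg.eigh(B)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    lam_max = eigval[0] if eigval.size else 0.0
    if lam_max <= tolerance:
        raise ValueError("degenerate distances: no positive eigenvalue")
    pos = eigval > tolerance * lam_max
    coords = eigvec[:, pos] * np.sqrt(eigval[pos])[None, :]
    proportion = eigval[pos] / eigval[pos].sum()
    return Ordination(list(dm.ids), coords, eigval, proportion)


def sum_of_variances(scores: np.ndarray, ddof: int = 1) -> float:
    """Sum over axes of the sample variance of scores (rows = members)."""
    if scores.shape[0] <= ddof:
        return float("nan")
    return float(np.var(scores, axis=0, ddof=ddof).sum())


# ---------------------------------------------------------------------------
# Binned disparity
# ---------------------------------------------------------------------------


def _align_durations(
    ids: list[str], durations: list[LineageDuration]
) -> list[LineageDuration]:
    by_id = {d.lineage_id: d for d in durations}
    out = []
    for rid in ids:
        key = rid[3:] if rid.startswith("HA_") else rid
        if key not in by_id:
            raise KeyError(f"no duration for sample row {rid!r}")
        out.append(by_id[key])
    return out


def _bin_members(
    bins: list[tuple[float, float]],
    durations: list[LineageDuration],
    membership: str,
) -> list[np.ndarray]:
    members = []
    for older, younger in bins:
        if membership == "overlap":
            sel = [i for i, d in enumerate(durations) if d.overlaps(older, younger)]
        elif membership == "midpoint":
            sel = [
                i
                for i, d in enumerate(durations)
                if older > (d.start + d.end) / 2 >= younger
            ]
        else:
            raise ValueError(f"unknown membership mode {membership!r}")
        members.append(np.asarray(sel, dtype=int))
    return members


def disparity_curve(
    ordination: Ordination,
    durations: list[LineageDuration],
    bins: list[tuple[float, float]] | None = None,
    *,
    k_axes: int | None = None,
    variance_threshold: float = 0.95,
    n_boot: int = 1000,
    ci_level: float = 0.95,
    seed: int,
    membership: str = "overlap",
    ddof: int = 1,
) -> BinSeries:
    """Sum-of-variances disparity per time bin with bootstrap CIs.

    Bin membership is any positive-length overlap of a row's duration with
    the half-open bin.  The per-bin value sums, over the retained axes, the
    sample variance of member scores; the band is a percentile bootstrap
    (resampling members with replacement) clipped to bracket the point
    value.  Bins with fewer than two members are undefined.
    """
    if bins is None:
        bins = make_bins()
    if not bins:
        raise ValueError("empty bin set")
    k = k_axes if k_axes is not None else ordination.axes_for_threshold(variance_threshold)
    if k > ordination.n_axes:
        raise ValueError(f"k_axes={k} exceeds retained axes {ordination.n_axes}")
    scores = ordination.coords[:, :k]
    aligned = _align_durations(ordination.ids, durations)
    members = _bin_members(bins, aligned, membership)
    rng = np.random.default_rng(seed)
    alpha = (1 - ci_level) / 2

    nb = len(bins)
    values = np.full(nb, np.nan)
    lower = np.full(nb, np.nan)
    upper = np.full(nb, np.nan)
    counts = np.zeros(nb, dtype=int)
    for b, sel in enumerate(members):
        counts[b] = sel.size
        if sel.size < 2:
            continue
        values[b] = sum_of_variances(scores[sel], ddof=ddof)
        reps = np.empty(n_boot)
        for r in range(n_boot):
            draw = rng.choice(sel, size=sel.size, replace=True)
            reps[r] = sum_of_variances(scores[draw], ddof=ddof)
        reps = reps[~np.isnan(reps)]
        if reps.size:
            lower[b] = min(np.quantile(reps, alpha), values[b])
            upper[b] = max(np.quantile(reps, 1 - alpha), values[b])
        else:  # all-resample-degenerate (tiny bins)
            lower[b] = upper[b] = values[b]
    return BinSeries(bins, values, lower, upper, counts, "disparity")


def rarefied_disparity_curve(
    ordination: Ordination,
    durations: list[LineageDuration],
    bins: list[tuple[float, float]] | None = None,
    *,
    n_sub: int = 8,
    n_boot: int = 1000,
    ci_level: float = 0.95,
    k_axes: int | None = None,
    variance_threshold: float = 0.95,
    seed: int,
    membership: str = "overlap",
    ddof: int = 1,
) -> BinSeries:
    """Fixed-n (default n=8) subsampled disparity per bin.

    Each defined bin is subsampled without replacement to ``n_sub`` rows
    ``n_boot`` times; the reported value is the mean over draws with a
    percentile band.  Bins with fewer than ``n_sub`` members are flagged
    undefined rather than extrapolated.
    """
    if n_sub < 2:
        raise ValueError("n_sub must be at least 2")
    if bins is None:
        bins = make_bins()
    k = k_axes if k_axes is not None else ordination.axes_for_threshold(variance_threshold)
    scores = ordination.coords[:, :k]
    aligned = _align_durations(ordination.ids, durations)
    members = _bin_members(bins, aligned, membership)
    rng = np.random.default_rng(seed)
    alpha = (1 - ci_level) / 2

    nb = len(bins)
    values = np.full(nb, np.nan)
    lower = np.full(nb, np.nan)
    upper = np.full(nb, np.nan)
    counts = np.zeros(nb, dtype=int)
    for b, sel in enumerate(members):
        counts[b] = sel.size
        if sel.size < n_sub:
            continue
        reps = np.empty(n_boot)
        for r in range(n_boot):
            draw = rng.choice(sel, size=n_sub, replace=False)
            reps[r] = sum_of_variances(scores[draw], ddof=ddof)
        values[b] = reps.mean()
        lower[b] = min(np.quantile(reps, alpha), values[b])
        upper[b] = max(np.quantile(reps, 1 - alpha), values[b])
    return BinSeries(bins, values, lower, upper, counts, "disparity")
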