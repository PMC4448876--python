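"""Readers, writers and audits for dated trees, discrete character matrices
and stratigraphic-range tables.

All ages are in Ma before present; time bins elsewhere in the package are
half-open ``[older, younger)`` intervals.  Trees are rooted, node ages are
absolute (fossil tips may sit above 0 Ma) and branch durations are
``parent_age - child_age``.

Character matrices hold discrete states 0-9 with explicit missing (``?``)
and inapplicable (``-``) tokens and polymorphic cells stored as state sets.
For every downstream computation inapplicable is treated like missing; the
two are kept distinct in storage and reported separately by the audit.
"""

from __future__ import annotations

import csv
import io
import re
import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

import dendropy

__all__ = [
    "MISSING",
    "INAPPLICABLE",
    "CharacterMatrix",
    "DatedTree",
    "TreeNode",
    "StratRecord",
    "LineageDuration",
    "MatrixAudit",
    "read_character_matrix",
    "write_character_matrix",
    "read_dated_tree",
    "write_newick",
    "audit_matrix",
    "load_strat_ranges",
    "write_strat_ranges",
    "lineage_durations",
]


class _Token(Enum):
    MISSING = "?"
    INAPPLICABLE = "-"

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return self.name


MISSING = _Token.MISSING
INAPPLICABLE = _Token.INAPPLICABLE

#: a cell is an int state, a frozenset of int states (polymorphism), or a token
Cell = int | frozenset | _Token


class FormatError(ValueError):
    """Raised for malformed or inconsistent input files."""


# ---------------------------------------------------------------------------
# Character matrix
# ---------------------------------------------------------------------------


@dataclass
class CharacterMatrix:
    """Taxa x discrete-character matrix.

    ``rows[i][j]`` is the cell for taxon ``taxa[i]`` and character
    ``characters[j]``.  ``ordered_flags[j]`` marks characters whose states
    form a morphocline (linear |a-b| step cost); everything else is
    unordered (unit cost).
    """

    taxa: list[str]
    characters: list[str]
    rows: list[list[Cell]]
    ordered_flags: list[bool]
    partition_labels: list[str] | None = None
    symbols: str = "0123456789"

    def __post_init__(self) -> None:
        if len(set(self.taxa)) != len(self.taxa):
            dupes = sorted({t for t in self.taxa if self.taxa.count(t) > 1})
            raise FormatError(f"duplicate taxon labels: {dupes}")
        if len(self.rows) != len(self.taxa):
            raise FormatError("row count does not match taxon count")
        for label, row in zip(self.taxa, self.rows):
            if len(row) != len(self.characters):
                raise FormatError(
                    f"taxon {label!r}: {len(row)} cells, expected {len(self.characters)}"
                )
        if len(self.ordered_flags) != len(self.characters):
            raise FormatError("ordered_flags length does not match character count")

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_characters(self) -> int:
        return len(self.characters)

    def taxon_index(self, label: str) -> int:
        try:
            return self.taxa.index(label)
        except ValueError:
            raise KeyError(f"unknown taxon {label!r}") from None

    def cell(self, taxon: str, char_index: int) -> Cell:
        return self.rows[self.taxon_index(taxon)][char_index]

    def observed_state_union(self, char_index: int) -> frozenset:
        """Union of observed states (singles and polymorphic sets) in a column."""
        states: set[int] = set()
        for row in self.rows:
            c = row[char_index]
            if isinstance(c, int):
                states.add(c)
            elif isinstance(c, frozenset):
                states.update(c)
        return frozenset(states)

    def state_universe(self, char_index: int) -> tuple[int, ...]:
        """States 0..max observed for a column (declared symbols if nothing observed)."""
        observed = self.observed_state_union(char_index)
        if observed:
            return tuple(range(max(observed) + 1))
        return tuple(range(len(self.symbols)))

    def subset(self, taxa: Sequence[str]) -> "CharacterMatrix":
        idx = [self.taxon_index(t) for t in taxa]
        return CharacterMatrix(
            taxa=list(taxa),
            characters=list(self.characters),
            rows=[list(self.rows[i]) for i in idx],
            ordered_flags=list(self.ordered_flags),
            partition_labels=list(self.partition_labels) if self.partition_labels else None,
            symbols=self.symbols,
        )


def _cell_to_symbol(cell: Cell) -> str:
    if cell is MISSING:
        return "?"
    if cell is INAPPLICABLE:
        return "-"
    if isinstance(cell, int):
        return str(cell)
    return "{" + "".join(str(s) for s in sorted(cell)) + "}"


def _parse_ranges(spec: str) -> list[int]:
    """Parse NEXUS-style 1-based index lists like ``1-3 5 8-9`` into 0-based indices."""
    out: list[int] = []
    for item in spec.split():
        if "-" in item:
            lo, hi = item.split("-")
            out.extend(range(int(lo) - 1, int(hi)))
        else:
            out.append(int(item) - 1)
    return out


_TYPESET_RE = re.compile(
    r"TYPESET\b[^=;]*=\s*([^;]+);", re.IGNORECASE | re.DOTALL
)
_ASSUMPTIONS_RE = re.compile(
    r"BEGIN\s+ASSUMPTIONS\s*;(.*?)END\s*;", re.IGNORECASE | re.DOTALL
)


def _parse_ordered_flags(text: str, nchar: int) -> list[bool]:
    flags = [False] * nchar
    m = _ASSUMPTIONS_RE.search(text)
    if not m:
        return flags
    ts = _TYPESET_RE.search(m.group(1))
    if not ts:
        return flags
    for clause in ts.group(1).split(","):
        if ":" not in clause:
            continue
        ctype, indices = clause.split(":", 1)
        is_ordered = ctype.strip().lower() in ("ord", "ordered")
        for i in _parse_ranges(indices.strip()):
            if not 0 <= i < nchar:
                raise FormatError(f"TYPESET index {i + 1} outside 1..{nchar}")
            flags[i] = is_ordered
    return flags


def read_character_matrix(
    path: str | None = None,
    *,
    data: str | None = None,
    ordered_characters: Iterable[int] | None = None,
) -> CharacterMatrix:
    """Read a NEXUS (or TSV fallback) discrete character matrix.

    Ordered characters are taken from a NEXUS ``ASSUMPTIONS``/``TYPESET``
    block when present; ``ordered_characters`` (0-based column indices)
    overrides as a sidecar configuration.
    """
    if (path is None) == (data is None):
        raise ValueError("provide exactly one of path or data")
    if data is None:
        with open(path, "r", encoding="utf-8") as fh:
            data = fh.read()
    text = data.lstrip()
    if text.upper().startswith("#NEXUS"):
        matrix = _read_nexus_matrix(text)
    else:
        matrix = _read_tsv_matrix(text)
    if ordered_characters is not None:
        flags = [False] * matrix.n_characters
        for i in ordered_characters:
            flags[i] = True
        matrix.ordered_flags = flags
    return matrix


def _read_nexus_matrix(text: str) -> CharacterMatrix:
    try:
        dm = dendropy.StandardCharacterMatrix.get(data=text, schema="nexus")
    except Exception as exc:  # dendropy raises several error types
        raise FormatError(f"cannot parse NEXUS matrix: {exc}") from exc
    taxa = [t.label for t in dm.taxon_namespace]
    if len(set(taxa)) != len(taxa):
        raise FormatError("duplicate taxon labels in NEXUS matrix")
    rows: list[list[Cell]] = []
    nchar = None
    for t in dm.taxon_namespace:
        row: list[Cell] = []
        for c in dm[t]:
            sym = c.symbol
            if sym == "?":
                row.append(MISSING)
            elif sym == "-":
                row.append(INAPPLICABLE)
            elif c.state_denomination == 0:  # fundamental single state
                row.append(int(sym))
            else:  # polymorphic {..} or ambiguous (..)
                members = frozenset(
                    int(s.symbol) for s in c.member_states if s.symbol not in "?-"
                )
                if not members:
                    row.append(MISSING)
                elif len(members) == 1:
                    row.append(next(iter(members)))
                else:
                    row.append(members)
        if nchar is None:
            nchar = len(row)
        rows.append(row)
    # declared dimensions cross-check
    dim = re.search(r"NCHAR\s*=\s*(\d+)", text, re.IGNORECASE)
    if dim and int(dim.group(1)) != nchar:
        raise FormatError(
            f"declared NCHAR={dim.group(1)} but matrix has {nchar} columns"
        )
    dim = re.search(r"NTAX\s*=\s*(\d+)", text, re.IGNORECASE)
    if dim and int(dim.group(1)) != len(taxa):
        raise FormatError(
            f"declared NTAX={dim.group(1)} but matrix has {len(taxa)} rows"
        )
    sym = re.search(r'SYMBOLS\s*=\s*"([^"]+)"', text, re.IGNORECASE)
    symbols = sym.group(1).replace(" ", "") if sym else "0123456789"
    characters = [f"char{i + 1}" for i in range(nchar or 0)]
    flags = _parse_ordered_flags(text, nchar or 0)
    return CharacterMatrix(taxa, characters, rows, flags, symbols=symbols)


def _read_tsv_matrix(text: str) -> CharacterMatrix:
    """TSV fallback: header row of character ids, one row per taxon.

    Multi-digit cells denote polymorphism (``01`` = states {0,1}).
    """
    reader = csv.reader(io.StringIO(text), delimiter="\t")
    rows_raw = [r for r in reader if r]
    if len(rows_raw) < 2:
        raise FormatError("TSV matrix needs a header and at least one taxon row")
    characters = rows_raw[0][1:]
    taxa, rows = [], []
    for raw in rows_raw[1:]:
        if len(raw) != len(characters) + 1:
            raise FormatError(f"taxon {raw[0]!r}: wrong number of columns")
        taxa.append(raw[0])
        row: list[Cell] = []
        for tok in raw[1:]:
            if tok == "?":
                row.append(MISSING)
            elif tok == "-":
                row.append(INAPPLICABLE)
            elif len(tok) == 1:
                row.append(int(tok))
            else:
                row.append(frozenset(int(ch) for ch in tok))
        rows.append(row)
    return CharacterMatrix(taxa, characters, rows, [False] * len(characters))


def write_character_matrix(matrix: CharacterMatrix, path: str | None = None) -> str:
    """Write a matrix as NEXUS with an ASSUMPTIONS block for ordered characters.

    Returns the NEXUS text; also writes it to ``path`` when given.  Writing
    then reading reproduces the matrix cell-exactly.
    """
    max_state = 0
    for row in matrix.rows:
        for c in row:
            if isinstance(c, int):
                max_state = max(max_state, c)
            elif isinstance(c, frozenset):
                max_state = max(max_state, max(c))
    symbols = "".join(str(i) for i in range(max_state + 1))
    width = max(len(t) for t in matrix.taxa) + 2
    lines = [
        "#NEXUS",
        "BEGIN DATA;",
        f"DIMENSIONS NTAX={matrix.n_taxa} NCHAR={matrix.n_characters};",
        f'FORMAT DATATYPE=STANDARD SYMBOLS="{symbols}" MISSING=? GAP=-;',
        "MATRIX",
    ]
    for label, row in zip(matrix.taxa, matrix.rows):
        safe = label.replace(" ", "_")
        lines.append(safe.ljust(width) + "".join(_cell_to_symbol(c) for c in row))
    lines.append(";")
    lines.append("END;")
    ordered = [i + 1 for i, f in enumerate(matrix.ordered_flags) if f]
    if ordered:
        unordered = [i + 1 for i, f in enumerate(matrix.ordered_flags) if not f]
        clause = "ord: " + " ".join(str(i) for i in ordered)
        if unordered:
            clause += ", unord: " + " ".join(str(i) for i in unordered)
        lines += ["BEGIN ASSUMPTIONS;", f"TYPESET * default = {clause};", "END;"]
    out = "\n".join(lines) + "\n"
    if path is not None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(out)
    return out


# ---------------------------------------------------------------------------
# Dated tree
# ---------------------------------------------------------------------------


@dataclass
class TreeNode:
    """Node of a :class:`DatedTree`; the edge above the node belongs to it."""

    label: str | None = None
    age: float = 0.0
    length: float | None = None  # duration of the edge above, Ma
    rate: float | None = None  # relative clock rate of the edge above
    parent: "TreeNode | None" = None
    children: list["TreeNode"] = field(default_factory=list)
    id: str = ""

    @property
    def is_tip(self) -> bool:
        return not self.children

    def add_child(self, child: "TreeNode") -> "TreeNode":
        child.parent = self
        self.children.append(child)
        return child


class DatedTree:
    """Rooted phylogeny with absolute node ages (Ma before present).

    Tips may be fossils (age > 0).  Branch ``i`` is identified by its child
    node: tip branches use the tip label as id, internal branches get stable
    preorder ids ``N1, N2, ...``.
    """

    def __init__(self, root: TreeNode, root_edge_length: float | None = None):
        self.root = root
        self.root_edge_length = root_edge_length
        self._index()
        self._validate()

    def _index(self) -> None:
        self.nodes: list[TreeNode] = []
        counter = 0
        stack = [self.root]
        while stack:
            nd = stack.pop()
            if nd.is_tip:
                if not nd.label:
                    raise FormatError("unlabeled tip")
                nd.id = nd.label
            else:
                counter += 1
                nd.id = f"N{counter}"
            self.nodes.append(nd)
            stack.extend(reversed(nd.children))
        self.tips = [nd for nd in self.nodes if nd.is_tip]
        self.internal = [nd for nd in self.nodes if not nd.is_tip]
        self._by_id = {nd.id: nd for nd in self.nodes}
        if len(self._by_id) != len(self.nodes):
            raise FormatError("duplicate tip labels in tree")

    def _validate(self) -> None:
        for nd in self.nodes:
            if nd.parent is not None and nd.parent.age < nd.age - 1e-9:
                raise FormatError(
                    f"node {nd.id}: age {nd.age} exceeds parent age {nd.parent.age}"
                )

    def node(self, node_id: str) -> TreeNode:
        return self._by_id[node_id]

    @property
    def root_age(self) -> float:
        return self.root.age

    @property
    def tip_labels(self) -> list[str]:
        return [t.label for t in self.tips]

    def branches(self) -> list[TreeNode]:
        """All non-root nodes, i.e. all branches (child-node convention)."""
        return [nd for nd in self.nodes if nd.parent is not None]

    def total_branch_length(self) -> float:
        return sum(nd.parent.age - nd.age for nd in self.branches())


_RATE_RE = re.compile(r"rate\s*=\s*([0-9.eE+-]+)")


def read_dated_tree(
    path: str | None = None,
    *,
    data: str | None = None,
    anchor: float | Mapping[str, float] | None = None,
    tolerance: float = 1e-6,
) -> DatedTree:
    """Read a Newick tree with branch lengths in Ma and resolve absolute ages.

    ``anchor`` fixes absolute ages: a float places the *youngest* tip at
    that age (default 0 Ma); a mapping of tip label to age must be
    consistent with path-length differences to within ``tolerance`` Ma.
    Bracket comments of the form ``[&rate=x]`` on branches are preserved as
    per-branch relative clock rates.
    """
    if (path is None) == (data is None):
        raise ValueError("provide exactly one of path or data")
    if data is None:
        with open(path, "r", encoding="utf-8") as fh:
            data = fh.read()
    dtree = dendropy.Tree.get(
        data=data,
        schema="newick",
        suppress_internal_node_taxa=True,
        extract_comment_metadata=False,
    )

    def convert(dnode: dendropy.Node) -> TreeNode:
        label = dnode.taxon.label if dnode.taxon else dnode.label
        nd = TreeNode(label=label, length=dnode.edge.length)
        for comment in dnode.comments:
            m = _RATE_RE.search(comment)
            if m:
                nd.rate = float(m.group(1))
        for child in dnode.child_nodes():
            nd.add_child(convert(child))
        return nd

    root = convert(dtree.seed_node)
    root_edge = root.length
    root.length = None

    # depths from root, then ages from the anchor
    depths: dict[int, float] = {id(root): 0.0}
    order: list[TreeNode] = []
    stack = [root]
    while stack:
        nd = stack.pop()
        order.append(nd)
        for child in nd.children:
            if child.length is None:
                raise FormatError(f"branch above {child.label or 'internal node'} has no length")
            if child.length < 0:
                raise FormatError(
                    f"negative branch length {child.length} above {child.label or 'internal node'}"
                )
            depths[id(child)] = depths[id(nd)] + child.length
            stack.append(child)
    tips = [nd for nd in order if nd.is_tip]

    if isinstance(anchor, Mapping):
        implied = {}
        for tip in tips:
            if tip.label not in anchor:
                raise FormatError(f"tip {tip.label!r} missing from tip-age table")
            implied[tip.label] = depths[id(tip)] + anchor[tip.label]
        root_age = sum(implied.values()) / len(implied)
        bad = [
            lbl for lbl, ra in implied.items() if abs(ra - root_age) > tolerance
        ]
        if bad:
            raise FormatError(
                "tip-age table inconsistent with path lengths for tips: "
                + ", ".join(sorted(bad))
            )
    else:
        youngest_age = 0.0 if anchor is None else float(anchor)
        root_age = max(depths[id(t)] for t in tips) + youngest_age

    for nd in order:
        nd.age = root_age - depths[id(nd)]
        if abs(nd.age) < 1e-12:
            nd.age = 0.0
    return DatedTree(root, root_edge_length=root_edge)


def _fmt(x: float) -> str:
    return format(x, ".12g")


def write_newick(tree: DatedTree, path: str | None = None, include_rates: bool = True) -> str:
    """Serialize a dated tree as Newick (lengths = branch durations in Ma)."""

    def render(nd: TreeNode) -> str:
        if nd.is_tip:
            core = nd.label.replace(" ", "_")
        else:
            core = "(" + ",".join(render(c) for c in nd.children) + ")"
        if nd.parent is not None:
            core += ":" + _fmt(nd.parent.age - nd.age)
            if include_rates and nd.rate is not None:
                core += f"[&rate={_fmt(nd.rate)}]"
        return core

    out = render(tree.root) + ";\n"
    if path is not None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(out)
    return out


# ---------------------------------------------------------------------------
# Stratigraphic ranges
# ---------------------------------------------------------------------------


@dataclass
class StratRecord:
    """Observed stratigraphic range of one taxon (ages in Ma)."""

    taxon: str
    oldest_age: float
    youngest_age: float
    younger_material_age: float | None = None

    def __post_init__(self) -> None:
        if self.oldest_age < self.youngest_age:
            raise FormatError(
                f"{self.taxon}: oldest age {self.oldest_age} < youngest {self.youngest_age}"
            )
        if self.youngest_age < 0:
            raise FormatError(f"{self.taxon}: negative youngest age")
        if (
            self.younger_material_age is not None
            and self.younger_material_age > self.youngest_age
        ):
            raise FormatError(
                f"{self.taxon}: younger material ({self.younger_material_age} Ma) "
                f"predates youngest occurrence ({self.youngest_age} Ma)"
            )


def load_strat_ranges(
    path: str | None = None, *, data: str | None = None, tree: DatedTree | None = None
) -> list[StratRecord]:
    """Load a CSV stratigraphic table ``taxon,oldest,youngest[,younger_material]``."""
    if (path is None) == (data is None):
        raise ValueError("provide exactly one of path or data")
    if data is None:
        with open(path, "r", encoding="utf-8", newline="") as fh:
            data = fh.read()
    reader = csv.reader(io.StringIO(data))
    rows = [r for r in reader if r and any(f.strip() for f in r)]
    if not rows:
        raise FormatError("empty stratigraphic table")
    header = [h.strip().lower() for h in rows[0]]
    if header[0] != "taxon":
        raise FormatError("stratigraphic table must start with a 'taxon' header column")
    records = []
    for row in rows[1:]:
        younger = None
        if len(row) >= 4 and row[3].strip():
            younger = float(row[3])
        records.append(
            StratRecord(row[0].strip(), float(row[1]), float(row[2]), younger)
        )
    if tree is not None:
        unknown = sorted({r.taxon for r in records} - set(tree.tip_labels))
        if unknown:
            warnings.warn(
                f"stratigraphic records for taxa absent from the tree: {unknown}",
                stacklevel=2,
            )
    return records


def write_strat_ranges(records: Sequence[StratRecord], path: str | None = None) -> str:
    lines = ["taxon,oldest,youngest,younger_material"]
    for r in records:
        younger = _fmt(r.younger_material_age) if r.younger_material_age is not None else ""
        lines.append(f"{r.taxon},{_fmt(r.oldest_age)},{_fmt(r.youngest_age)},{younger}")
    out = "\n".join(lines) + "\n"
    if path is not None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(out)
    return out


# ---------------------------------------------------------------------------
# Lineage durations
# ---------------------------------------------------------------------------


@dataclass
class LineageDuration:
    """Temporal extent of one lineage (tip or internal branch), Ma."""

    lineage_id: str
    start: float  # older bound
    end: float  # younger bound
    kind: str  # observed_tip | ghost_range_extension | ghost_lineage

    def __post_init__(self) -> None:
        if self.start < self.end:
            raise FormatError(
                f"{self.lineage_id}: duration start {self.start} younger than end {self.end}"
            )

    @property
    def span(self) -> float:
        return self.start - self.end

    def overlaps(self, older: float, younger: float) -> bool:
        """Positive-length overlap with the half-open bin [older, younger)."""
        return min(self.start, older) - max(self.end, younger) > 0


def lineage_durations(
    tree: DatedTree,
    strat_records: Sequence[StratRecord] | None = None,
    use_extensions: bool = False,
) -> list[LineageDuration]:
    """Per-branch temporal durations for binning.

    Terminal branches span from their origin node's age down to the tip age
    (the taxon's ghost range + observed range); with ``use_extensions`` the
    range is carried further down to any younger referred material recorded
    in the stratigraphic table (diversity/disparity convention).  Internal
    branches become ghost-lineage durations.  The stem edge above the root,
    if present, is ignored.
    """
    by_taxon = {r.taxon: r for r in (strat_records or [])}
    out: list[LineageDuration] = []
    for nd in tree.branches():
        start = nd.parent.age
        if nd.is_tip:
            end = nd.age
            kind = "observed_tip"
            rec = by_taxon.get(nd.label)
            if rec is not None and rec.younger_material_age is not None:
                if rec.younger_material_age > nd.age + 1e-9:
                    raise FormatError(
                        f"{nd.label}: younger material age {rec.younger_material_age} "
                        f"predates the dated tip age {nd.age}"
                    )
                if use_extensions:
                    end = rec.younger_material_age
                    kind = "ghost_range_extension"
            out.append(LineageDuration(nd.label, start, end, kind))
        else:
            out.append(LineageDuration(nd.id, start, nd.age, "ghost_lineage"))
    return out


# ---------------------------------------------------------------------------
# Matrix audit
# ---------------------------------------------------------------------------


@dataclass
class MatrixAudit:
    """Completeness and informativeness summary of a character matrix."""

    n_taxa: int
    n_characters: int
    n_characters_by_partition: dict[str, int]
    missing_fraction: float  # MISSING + INAPPLICABLE over all cells
    missing_fraction_question_only: float  # MISSING only
    invariant_character_ids: list[str]


def audit_matrix(
    matrix: CharacterMatrix, taxa: Sequence[str] | None = None
) -> MatrixAudit:
    """Audit a matrix (optionally over a taxon subset).

    A character is invariant when the union of its observed state sets over
    the subset contains at most one state; polymorphic cells contribute
    their whole set, so a column with cells ``{0}`` and ``{0,1}`` is
    variant.  Both missing conventions (counting inapplicable as missing or
    not) are reported.
    """
    sub = matrix if taxa is None else matrix.subset(taxa)
    if sub.n_taxa == 0:
        raise ValueError("empty taxon subset")
    total = sub.n_taxa * sub.n_characters
    n_missing = sum(1 for row in sub.rows for c in row if c is MISSING)
    n_inapp = sum(1 for row in sub.rows for c in row if c is INAPPLICABLE)
    invariant = [
        sub.characters[j]
        for j in range(sub.n_characters)
        if len(sub.observed_state_union(j)) <= 1
    ]
    by_partition: dict[str, int] = {}
    if sub.partition_labels:
        for lbl in sub.partition_labels:
            by_partition[lbl] = by_partition.get(lbl, 0) + 1
    return MatrixAudit(
        n_taxa=sub.n_taxa,
        n_characters=sub.n_characters,
        n_characters_by_partition=by_partition,
        missing_fraction=(n_missing + n_inapp) / total if total else 0.0,
        missing_fraction_question_only=n_missing / total if total else 0.0,
        invariant_character_ids=invariant,
    )
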