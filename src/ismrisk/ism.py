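"""Interpretive Structural Modelling (ISM) engine.

ISM turns an expert pairwise-comparison matrix over a set of elements into
a levelled hierarchy of influence. The stages implemented here:

1. **SSIM** — the structural self-interaction matrix. For each ordered
   pair of elements (i before j in the listed order) experts record one
   symbol: ``V`` (i leads to j), ``A`` (j leads to i), ``X`` (mutual) or
   ``O`` (no relation).
2. **Initial reachability matrix** — the SSIM converted to binary:
   V sets cell (i, j); A sets cell (j, i); X sets both; O neither. The
   diagonal is set to 1 (every element reaches itself).
3. **Final reachability matrix** — the transitive closure of the initial
   matrix. Cells switched on by transitivity rather than by a direct
   expert judgement keep a ``derived`` flag (the audit trail behind the
   conventional "1*" notation; the matrix itself stores plain 1s).
4. **Level partition** — iterative extraction: among the elements not yet
   levelled, element i belongs to the current level when its reachability
   set R(i) (restricted to remaining elements) satisfies
   R(i) ∩ A(i) = R(i), where A(i) is the restricted antecedent set.
   Level 1 is the first extraction: the most dependent, least driving
   tier. Reports also carry the reversed "depth" numbering, under which
   the root drivers sit at depth 1.
5. **Hierarchy digraph** — strongly connected groups (mutually reachable
   elements), the acyclic condensation between them, and its transitive
   reduction for drawing.

Symbol glyph tolerance: printed SSIMs often mix the letter ``O`` with the
digit ``0`` and vary in case; both are canonicalized by default, each
substitution raising a :class:`~ismrisk.errors.GlyphSubstitutionWarning`.
"""

from __future__ import annotations

import io
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, TextIO

import networkx as nx
import numpy as np
import pandas as pd

from .errors import (
    FormatError,
    GlyphSubstitutionWarning,
    IsmRiskError,
    ValidationError,
)
from .register import code_sort_key, sniff_delimiter

VALID_SYMBOLS = frozenset("VAXO")
_CANONICAL = {"0": "O"}


def canonical_symbol(raw: str, *, cell: str = "") -> tuple[str, bool]:
    """Return (canonical symbol, whether a substitution happened)."""
    s = raw.strip()
    subst = False
    if s != s.upper():
        s, subst = s.upper(), True
    if s in _CANONICAL:
        s, subst = _CANONICAL[s], True
    if s not in VALID_SYMBOLS:
        where = f" at {cell}" if cell else ""
        raise FormatError(f"invalid SSIM symbol {raw!r}{where}; expected one of V, A, X, O")
    return s, subst


class SSIM:
    """Structural self-interaction matrix over an ordered element list.

    Symbols are stored for the upper triangle only: one symbol per
    unordered pair, keyed by positions (i, j) with i < j.
    """

    def __init__(self, elements: Iterable[str], symbols: Mapping[tuple[int, int], str]) -> None:
        self.elements: tuple[str, ...] = tuple(elements)
        n = len(self.elements)
        if len(set(self.elements)) != n:
            raise ValidationError("duplicate element codes in SSIM")
        expected = {(i, j) for i in range(n) for j in range(i + 1, n)}
        got = set(symbols)
        if got != expected:
            missing = sorted(expected - got)[:3]
            extra = sorted(got - expected)[:3]
            raise ValidationError(
                f"SSIM needs exactly one symbol per pair i<j; missing {missing}, unexpected {extra}"
            )
        canon: dict[tuple[int, int], str] = {}
        for key, sym in symbols.items():
            s, _ = canonical_symbol(sym)
            canon[key] = s
        self.symbols = canon

    @property
    def n(self) -> int:
        return len(self.elements)

    def symbol(self, a: str, b: str) -> str:
        """Symbol for the pair (a, b) as recorded with a earlier in the order."""
        i, j = self.elements.index(a), self.elements.index(b)
        if i == j:
            raise KeyError("no self-pair symbol")
        if i > j:
            raise KeyError(f"{a!r} comes after {b!r}; query symbol({b!r}, {a!r})")
        return self.symbols[(i, j)]

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, SSIM)
            and self.elements == other.elements
            and self.symbols == other.symbols
        )


def parse_ssim(source: str | Path | TextIO) -> SSIM:
    """Read an SSIM from a square delimited layout.

    The first row and first column carry the element codes; the upper
    triangle is authoritative and the lower triangle, if present, is
    ignored. Tolerated glyph variants (digit ``0`` for ``O``, lower case)
    are canonicalized with a warning naming the cell.
    """
    text = Path(source).read_text(encoding="utf-8") if isinstance(source, (str, Path)) else source.read()
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise FormatError("empty SSIM input")
    delim = sniff_delimiter(lines[0])
    header = [c.strip() for c in lines[0].split(delim)]
    elements = [c for c in header[1:] if c]
    n = len(elements)
    if len(lines) - 1 != n:
        raise FormatError(f"SSIM layout is not square: {n} columns but {len(lines) - 1} rows")
    symbols: dict[tuple[int, int], str] = {}
    for i, ln in enumerate(lines[1:]):
        cells = [c.strip() for c in ln.split(delim)]
        row_code = cells[0]
        if row_code != elements[i]:
            raise FormatError(f"row {i + 1} labelled {row_code!r}, expected {elements[i]!r}")
        body = cells[1:]
        for j in range(i + 1, n):
            if j >= len(body) or body[j] == "":
                raise FormatError(f"missing SSIM cell ({elements[i]}, {elements[j]})")
            addr = f"({elements[i]}, {elements[j]})"
            sym, subst = canonical_symbol(body[j], cell=addr)
            if subst:
                warnings.warn(
                    f"SSIM cell {addr}: glyph {body[j]!r} read as {sym!r}",
                    GlyphSubstitutionWarning,
                    stacklevel=2,
                )
            symbols[(i, j)] = sym
    return SSIM(elements, symbols)


def write_ssim(ssim: SSIM, dest: str | Path | TextIO, *, delimiter: str = ",") -> None:
    """Write the square SSIM layout (upper triangle populated, diagonal blank)."""
    rows = [delimiter.join(["", *ssim.elements])]
    for i, code in enumerate(ssim.elements):
        cells = [code]
        for j in range(ssim.n):
            cells.append(ssim.symbols[(i, j)] if i < j else "")
        rows.append(delimiter.join(cells))
    out = "\n".join(rows) + "\n"
    if isinstance(dest, (str, Path)):
        Path(dest).write_text(out, encoding="utf-8")
    else:
        dest.write(out)


class ReachabilityMatrix:
    """Square binary reflexive matrix over ordered elements.

    ``derived`` marks cells that were switched on by transitivity rather
    than directly; it is all-False on an initial matrix.
    """

    def __init__(
        self,
        elements: Iterable[str],
        values: np.ndarray,
        derived: np.ndarray | None = None,
    ) -> None:
        self.elements: tuple[str, ...] = tuple(elements)
        n = len(self.elements)
        vals = np.asarray(values, dtype=bool)
        if vals.shape != (n, n):
            raise ValidationError(f"matrix shape {vals.shape} does not match {n} elements")
        if not vals.diagonal().all():
            raise ValidationError("reachability matrix must be reflexive (unit diagonal)")
        self.values = vals
        self.derived = (
            np.zeros((n, n), dtype=bool) if derived is None else np.asarray(derived, dtype=bool)
        )
        if self.derived.shape != (n, n):
            raise ValidationError("derived-flag matrix shape mismatch")
        if (self.derived & ~self.values).any():
            raise ValidationError("derived flag set on a zero cell")

    @property
    def n(self) -> int:
        return len(self.elements)

    def _idx(self, code: str) -> int:
        try:
            return self.elements.index(code)
        except ValueError as exc:
            raise KeyError(code) from exc

    def cell(self, row: str, col: str) -> int:
        return int(self.values[self._idx(row), self._idx(col)])

    def is_derived(self, row: str, col: str) -> bool:
        return bool(self.derived[self._idx(row), self._idx(col)])

    def is_closed(self) -> bool:
        m = self.values
        return bool((((m @ m) & ~m).sum()) == 0)

    def reachability_set(self, code: str) -> frozenset[str]:
        i = self._idx(code)
        return frozenset(self.elements[j] for j in np.nonzero(self.values[i])[0])

    def antecedent_set(self, code: str) -> frozenset[str]:
        i = self._idx(code)
        return frozenset(self.elements[j] for j in np.nonzero(self.values[:, i])[0])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values.astype(int), index=list(self.elements), columns=list(self.elements)
        )

    def derived_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.derived.astype(int), index=list(self.elements), columns=list(self.elements)
        )

    def to_csv(self, dest: str | Path, *, flags_dest: str | Path | None = None) -> None:
        self.to_frame().to_csv(dest)
        if flags_dest is not None:
            self.derived_frame().to_csv(flags_dest)

    @classmethod
    def from_csv(cls, source: str | Path | TextIO) -> "ReachabilityMatrix":
        text = (
            Path(source).read_text(encoding="utf-8")
            if isinstance(source, (str, Path))
            else source.read()
        )
        delim = sniff_delimiter(text.splitlines()[0])
        df = pd.read_csv(io.StringIO(text), sep=delim, index_col=0)
        if list(df.index.astype(str)) != list(df.columns.astype(str)):
            raise FormatError("reachability table must be square with matching labels")
        vals = df.to_numpy()
        if not np.isin(vals, (0, 1)).all():
            raise FormatError("reachability entries must be 0 or 1")
        return cls([str(c) for c in df.index], vals.astype(bool))

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, ReachabilityMatrix)
            and self.elements == other.elements
            and bool((self.values == other.values).all())
        )

    def __repr__(self) -> str:
        state = "closed" if self.is_closed() else "open"
        return f"ReachabilityMatrix({self.n} elements, {int(self.values.sum())} ones, {state})"


def ssim_to_initial(ssim: SSIM) -> ReachabilityMatrix:
    """Convert SSIM symbols to the binary initial reachability matrix.

    V → cell(i, j) = 1; A → cell(j, i) = 1; X → both; O → neither.
    The diagonal is 1. No derived flags are set.
    """
    n = ssim.n
    m = np.eye(n, dtype=bool)
    for (i, j), sym in ssim.symbols.items():
        if sym == "V":
            m[i, j] = True
        elif sym == "A":
            m[j, i] = True
        elif sym == "X":
            m[i, j] = m[j, i] = True
    return ReachabilityMatrix(ssim.elements, m)


def initial_to_ssim(matrix: ReachabilityMatrix) -> SSIM:
    """Inverse of :func:`ssim_to_initial`; off-diagonal cells map back to symbols."""
    m = matrix.values
    symbols: dict[tuple[int, int], str] = {}
    for i in range(matrix.n):
        for j in range(i + 1, matrix.n):
            fwd, back = m[i, j], m[j, i]
            symbols[(i, j)] = "X" if (fwd and back) else "V" if fwd else "A" if back else "O"
    return SSIM(matrix.elements, symbols)


def transitive_closure(matrix: ReachabilityMatrix) -> ReachabilityMatrix:
    """Smallest transitively closed superset of the input matrix.

    Boolean fixpoint: repeatedly OR the matrix with its boolean square
    until nothing changes (O(log n) squarings). Cells that flip 0 → 1 get
    the ``derived`` flag; flags already set on the input are preserved.
    Idempotent: closing a closed matrix returns an equal matrix.
    """
    m = matrix.values.copy()
    while True:
        nxt = m | (m @ m)
        if (nxt == m).all():
            break
        m = nxt
    derived = matrix.derived | (m & ~matrix.values)
    return ReachabilityMatrix(matrix.elements, m, derived)


@dataclass(frozen=True)
class LevelRecord:
    """Audit record for one element's level assignment.

    ``reachability``, ``antecedent`` and ``intersection`` are the sets
    used in the iteration that assigned the element, restricted to the
    elements still unassigned at that point.
    """

    code: str
    level: int
    reachability: frozenset[str]
    antecedent: frozenset[str]
    intersection: frozenset[str]


@dataclass(frozen=True)
class LevelPartition:
    """Outcome of the iterative level extraction.

    ``levels`` maps each element to its level, 1 = the first-extracted
    (most dependent) top tier. ``audit`` holds one record per element in
    assignment order.
    """

    levels: dict[str, int]
    audit: tuple[LevelRecord, ...] = field(default_factory=tuple)

    @property
    def n_levels(self) -> int:
        return max(self.levels.values(), default=0)

    def members(self, level: int) -> frozenset[str]:
        return frozenset(c for c, lv in self.levels.items() if lv == level)

    def depth_levels(self) -> dict[str, int]:
        """Reversed numbering: root drivers (last extracted) at depth 1."""
        top = self.n_levels
        return {c: top - lv + 1 for c, lv in self.levels.items()}

    def as_lists(self) -> list[list[str]]:
        return [
            sorted(self.members(k), key=code_sort_key) for k in range(1, self.n_levels + 1)
        ]


def level_partition(final: ReachabilityMatrix) -> LevelPartition:
    """Partition a closed reachability matrix into dependence levels.

    In each iteration, every remaining element i with
    R(i) ∩ A(i) = R(i) — equivalently R(i) ⊆ A(i) — receives the current
    level; all qualifying elements are extracted simultaneously. On a
    genuinely closed matrix every iteration extracts at least one element
    (each terminal strongly connected component of the remaining
    subgraph qualifies); a stalled iteration therefore signals an
    unclosed input and raises.
    """
    if not final.is_closed():
        raise ValidationError("level partition requires a transitively closed matrix")
    remaining = list(final.elements)
    levels: dict[str, int] = {}
    audit: list[LevelRecord] = []
    k = 0
    while remaining:
        k += 1
        rem = set(remaining)
        extracted: list[LevelRecord] = []
        for code in remaining:
            reach = final.reachability_set(code) & rem
            ante = final.antecedent_set(code) & rem
            inter = reach & ante
            if inter == reach:
                extracted.append(LevelRecord(code, k, reach, ante, inter))
        if not extracted:
            raise IsmRiskError(
                "level extraction stalled; the matrix is not a transitive closure"
            )
        for rec in extracted:
            levels[rec.code] = k
            remaining.remove(rec.code)
            audit.append(rec)
    return LevelPartition(levels, tuple(audit))


def strongly_connected_groups(final: ReachabilityMatrix) -> list[frozenset[str]]:
    """Mutual-reachability groups: i, j share a group iff both cells are 1.

    Returned in order of each group's earliest element in the matrix's
    element order.
    """
    m = final.values
    mutual = m & m.T
    seen: set[str] = set()
    groups: list[frozenset[str]] = []
    for i, code in enumerate(final.elements):
        if code in seen:
            continue
        members = frozenset(final.elements[j] for j in np.nonzero(mutual[i])[0])
        seen |= members
        groups.append(members)
    return groups


class HierarchyDigraph:
    """Acyclic between-group digraph of the ISM hierarchy.

    Nodes are the strongly connected groups; an edge g → h means the
    members of g reach (influence) the members of h, so h sits at a
    smaller level number (more dependent, nearer the top of the drawn
    model). Edges are the transitive reduction of between-group
    reachability.
    """

    def __init__(
        self,
        groups: list[frozenset[str]],
        edges: set[tuple[int, int]],
        group_levels: list[int],
    ) -> None:
        self.groups = list(groups)
        self.edges = set(edges)
        self.group_levels = list(group_levels)
        dag = nx.DiGraph()
        dag.add_nodes_from(range(len(groups)))
        dag.add_edges_from(edges)
        if not nx.is_directed_acyclic_graph(dag):
            raise ValidationError("between-group digraph must be acyclic")
        self._dag = dag

    def group_of(self, code: str) -> int:
        for gi, members in enumerate(self.groups):
            if code in members:
                return gi
        raise KeyError(code)

    def level_of(self, code: str) -> int:
        return self.group_levels[self.group_of(code)]

    def group_label(self, gi: int) -> str:
        return "+".join(sorted(self.groups[gi], key=code_sort_key))

    def between_group_reachability(self) -> dict[tuple[int, int], bool]:
        """Transitive closure of the reduced edges, per ordered group pair."""
        closure = nx.transitive_closure_dag(self._dag)
        return {
            (a, b): closure.has_edge(a, b)
            for a in range(len(self.groups))
            for b in range(len(self.groups))
            if a != b
        }

    def to_element_matrix(self) -> "ReachabilityMatrix":
        """Expand the hierarchy back to a full element-level closed matrix."""
        order = sorted(
            (c for g in self.groups for c in g), key=code_sort_key
        )
        idx = {c: i for i, c in enumerate(order)}
        n = len(order)
        m = np.eye(n, dtype=bool)
        reach = self.between_group_reachability()
        for gi, g in enumerate(self.groups):
            for a in g:
                for b in g:
                    m[idx[a], idx[b]] = True
            for gj, h in enumerate(self.groups):
                if gi != gj and reach.get((gi, gj), False):
                    for a in g:
                        for b in h:
                            m[idx[a], idx[b]] = True
        return ReachabilityMatrix(order, m)

    def to_dot(self, path: str | Path | None = None) -> str:
        lines = ["digraph hierarchy {", "  rankdir=BT;"]
        for gi in range(len(self.groups)):
            lines.append(
                f'  g{gi} [label="{self.group_label(gi)}" level={self.group_levels[gi]}];'
            )
        for a, b in sorted(self.edges):
            lines.append(f"  g{a} -> g{b};")
        lines.append("}")
        text = "\n".join(lines) + "\n"
        if path is not None:
            Path(path).write_text(text, encoding="utf-8")
        return text

    def to_graphml(self, path: str | Path) -> None:
        g = nx.DiGraph()
        for gi in range(len(self.groups)):
            g.add_node(self.group_label(gi), level=self.group_levels[gi])
        for a, b in self.edges:
            g.add_edge(self.group_label(a), self.group_label(b))
        nx.write_graphml(g, path)

    def to_json(self) -> str:
        payload = {
            "groups": [sorted(g, key=code_sort_key) for g in self.groups],
            "levels": self.group_levels,
            "edges": sorted([list(e) for e in self.edges]),
        }
        return json.dumps(payload, indent=2)


def build_hierarchy(final: ReachabilityMatrix, partition: LevelPartition) -> HierarchyDigraph:
    """Condense a closed matrix into its levelled group digraph.

    Groups are the strongly connected components; between-group edges are
    the transitive reduction of the condensation, so re-closing them
    reproduces exactly the off-group part of the final matrix.
    """
    if set(partition.levels) != set(final.elements):
        raise ValidationError("partition elements do not match matrix elements")
    groups = strongly_connected_groups(final)
    gindex = {c: gi for gi, g in enumerate(groups) for c in g}
    cond = nx.DiGraph()
    cond.add_nodes_from(range(len(groups)))
    m = final.values
    for i, a in enumerate(final.elements):
        for j, b in enumerate(final.elements):
            if m[i, j] and gindex[a] != gindex[b]:
                cond.add_edge(gindex[a], gindex[b])
    reduced = nx.transitive_reduction(cond)
    group_levels = []
    for g in groups:
        lvls = {partition.levels[c] for c in g}
        if len(lvls) != 1:
            raise ValidationError(f"group {sorted(g)} spans multiple levels {sorted(lvls)}")
        group_levels.append(lvls.pop())
    return HierarchyDigraph(groups, set(reduced.edges()), group_levels)
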