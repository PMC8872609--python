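"""Risk-relation network, degree centrality, and key-risk selection.

The screening stage treats risks as nodes of a relation network elicited
from experts. Importance is measured by degree centrality — the number of
relations a risk has with other risks — and the key risks carried into the
structural-modelling stage are those whose degree clears a cutoff, either
an explicit threshold or an upper quantile of the degree distribution.

Because published case studies often report the per-risk degrees without
the underlying relation matrix, the stage accepts either an adjacency
input (degrees are computed) or a ready-made degree table.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, TextIO

import networkx as nx
import numpy as np
import pandas as pd

from .errors import FormatError, SelfLoopWarning, ValidationError
from .register import code_sort_key, sniff_delimiter


class RelationNetwork:
    """Simple risk-relation graph with an explicit node order.

    Undirected by default (a relation between two risks is one link);
    directed mode is available for influence-style elicitation.
    """

    def __init__(self, nodes: Iterable[str], edges: Iterable[tuple[str, str]], *, directed: bool = False) -> None:
        self.nodes: tuple[str, ...] = tuple(nodes)
        if len(set(self.nodes)) != len(self.nodes):
            raise ValidationError("duplicate node codes in network")
        self.directed = directed
        g: nx.Graph = nx.DiGraph() if directed else nx.Graph()
        g.add_nodes_from(self.nodes)
        node_set = set(self.nodes)
        for a, b in edges:
            if a == b:
                raise ValidationError(f"self-loop on {a!r} not allowed")
            if a not in node_set or b not in node_set:
                raise ValidationError(f"edge ({a!r}, {b!r}) references unknown node")
            g.add_edge(a, b)
        self.graph = g

    @property
    def edges(self) -> frozenset[tuple[str, str]]:
        """Edges; undirected pairs are canonical (lexicographically smaller code first)."""
        if self.directed:
            return frozenset(self.graph.edges())
        return frozenset(tuple(sorted(e, key=code_sort_key)) for e in self.graph.edges())

    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def to_graphml(self, path: str | Path, degrees: "CentralityTable | None" = None) -> None:
        g = self.graph.copy()
        scores = (degrees or degree_centrality(self)).scores
        nx.set_node_attributes(g, {c: int(d) for c, d in scores.items()}, "degree")
        nx.write_graphml(g, path)

    def to_dot(self, path: str | Path, degrees: "CentralityTable | None" = None) -> None:
        """Plain DOT export with a ``degree`` node attribute for size-by-centrality rendering."""
        scores = (degrees or degree_centrality(self)).scores
        kind = "digraph" if self.directed else "graph"
        arrow = "->" if self.directed else "--"
        lines = [f"{kind} risks {{"]
        for c in self.nodes:
            lines.append(f'  "{c}" [degree={scores[c]}];')
        for a, b in sorted(self.edges, key=lambda e: (code_sort_key(e[0]), code_sort_key(e[1]))):
            lines.append(f'  "{a}" {arrow} "{b}";')
        lines.append("}")
        Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


class CentralityTable:
    """Per-risk non-negative integer degree scores, in a fixed code order."""

    def __init__(self, scores: Mapping[str, int]) -> None:
        self.scores: dict[str, int] = {}
        for code, val in scores.items():
            v = int(val)
            if v < 0:
                raise ValidationError(f"negative degree for {code!r}")
            if code in self.scores:
                raise ValidationError(f"duplicate code {code!r} in centrality table")
            self.scores[code] = v
        if not self.scores:
            raise ValidationError("centrality table is empty")

    def __len__(self) -> int:
        return len(self.scores)

    def __getitem__(self, code: str) -> int:
        return self.scores[code]

    def max_code(self) -> str:
        """Code attaining the maximum score (first such code in table order)."""
        return max(self.scores, key=self.scores.__getitem__)

    def as_series(self) -> pd.Series:
        return pd.Series(self.scores, name="degree")


def build_network(
    adjacency: pd.DataFrame | Iterable[tuple[str, str]],
    *,
    nodes: Iterable[str] | None = None,
    directed: bool = False,
) -> RelationNetwork:
    """Build a relation network from a 0/1 adjacency table or an edge list.

    Adjacency input must be square with matching row/column labels and
    binary entries. Diagonal entries are ignored with a warning (a risk
    does not relate to itself). In undirected mode the matrix is
    symmetrized by OR.
    """
    if isinstance(adjacency, pd.DataFrame):
        if list(adjacency.index) != list(adjacency.columns):
            raise FormatError("adjacency table must be square with matching row/column labels")
        vals = adjacency.to_numpy()
        if not np.isin(vals, (0, 1)).all():
            raise FormatError("adjacency entries must be 0 or 1")
        a = vals.astype(bool)
        if a.diagonal().any():
            warnings.warn("self-relations on the diagonal are ignored", SelfLoopWarning, stacklevel=2)
            np.fill_diagonal(a, False)
        codes = [str(c) for c in adjacency.index]
        if not directed:
            a = a | a.T
        idx = zip(*np.nonzero(a if directed else np.triu(a)))
        edges = [(codes[i], codes[j]) for i, j in idx]
        return RelationNetwork(codes, edges, directed=directed)
    edges = list(adjacency)
    if nodes is None:
        nodes = sorted({c for e in edges for c in e}, key=code_sort_key)
    return RelationNetwork(nodes, edges, directed=directed)


def load_adjacency(source: str | Path | TextIO) -> pd.DataFrame:
    """Read a square delimited 0/1 table whose first row and column are codes."""
    text = Path(source).read_text(encoding="utf-8") if isinstance(source, (str, Path)) else source.read()
    delim = sniff_delimiter(text.splitlines()[0])
    df = pd.read_csv(io.StringIO(text), sep=delim, index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return df


def degree_centrality(network: RelationNetwork, direction: str = "total") -> CentralityTable:
    """Count incident edges per node.

    ``direction`` is one of ``total``, ``in``, ``out``; the latter two
    require a directed network.
    """
    g = network.graph
    if direction == "total":
        deg = dict(g.degree())
    elif direction == "in":
        if not network.directed:
            raise ValidationError("in-degree requires a directed network")
        deg = dict(g.in_degree())
    elif direction == "out":
        if not network.directed:
            raise ValidationError("out-degree requires a directed network")
        deg = dict(g.out_degree())
    else:
        raise ValidationError(f"unknown direction {direction!r}")
    return CentralityTable({c: deg[c] for c in network.nodes})


def load_centrality(source: str | Path | TextIO) -> CentralityTable:
    """Read a two-column (code, degree) delimited table."""
    text = Path(source).read_text(encoding="utf-8") if isinstance(source, (str, Path)) else source.read()
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise FormatError("empty centrality table")
    delim = sniff_delimiter(lines[0])
    first = [f.strip().lower() for f in lines[0].split(delim)]
    body = lines[1:] if first[:1] == ["code"] or "degree" in first else lines
    scores: dict[str, int] = {}
    for ln in body:
        parts = [p.strip() for p in ln.split(delim)]
        if len(parts) < 2:
            raise FormatError(f"expected (code, degree) row, got {ln!r}")
        code, raw = parts[0], parts[1]
        try:
            val = int(raw)
        except ValueError as exc:
            raise FormatError(f"non-integer degree {raw!r} for {code!r}") from exc
        if code in scores:
            raise ValidationError(f"duplicate code {code!r} in centrality table")
        if val < 0:
            raise ValidationError(f"negative degree for {code!r}")
        scores[code] = val
    return CentralityTable(scores)


def write_centrality(table: CentralityTable, dest: str | Path | TextIO) -> None:
    out = "code,degree\n" + "\n".join(f"{c},{d}" for c, d in table.scores.items()) + "\n"
    if isinstance(dest, (str, Path)):
        Path(dest).write_text(out, encoding="utf-8")
    else:
        dest.write(out)


@dataclass(frozen=True)
class SelectionRule:
    """Cutoff rule for key-risk selection: explicit threshold or upper quantile."""

    mode: str  # "threshold" | "quantile"
    threshold: float | None = None
    quantile: float | None = None
    quantile_method: str = "linear"

    def __post_init__(self) -> None:
        if self.mode == "threshold":
            if self.threshold is None:
                raise ValidationError("threshold mode requires a threshold value")
        elif self.mode == "quantile":
            if self.quantile is None or not (0.0 < self.quantile < 1.0):
                raise ValidationError("quantile must be strictly between 0 and 1")
        else:
            raise ValidationError(f"unknown selection mode {self.mode!r}")

    @classmethod
    def explicit(cls, threshold: float) -> "SelectionRule":
        return cls(mode="threshold", threshold=threshold)

    @classmethod
    def upper_quantile(cls, q: float, method: str = "linear") -> "SelectionRule":
        return cls(mode="quantile", quantile=q, quantile_method=method)

    def cutoff(self, scores: Iterable[int]) -> float:
        if self.mode == "threshold":
            return float(self.threshold)  # type: ignore[arg-type]
        return float(np.quantile(np.asarray(list(scores), dtype=float), self.quantile, method=self.quantile_method))


def select_key_risks(table: CentralityTable, rule: SelectionRule) -> list[str]:
    """Codes with score >= cutoff, ordered by descending score then code.

    Ties at the cutoff are all included, so the selection is monotone in
    the cutoff: raising it never adds a code.
    """
    cut = rule.cutoff(table.scores.values())
    chosen = [c for c, d in table.scores.items() if d >= cut]
    return sorted(chosen, key=lambda c: (-table.scores[c], code_sort_key(c)))
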