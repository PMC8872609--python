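"""Synthetic instances with a planted, recoverable hierarchy.

The generator plants the ground truth the ISM stages are supposed to
recover: a partition of the elements into strongly connected groups and
an acyclic influence DAG between the groups. From that truth it induces
an SSIM (and reachability matrix), so every downstream stage can be
checked against the planted answer. A degree-profile generator emulates
the shape of real screening tables — an integer bulk with a small heavy
upper tail — so quantile selection carves out a meaningful key set.

All generators are deterministic functions of their seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import ValidationError
from .ism import SSIM, ReachabilityMatrix
from .network import CentralityTable
from .register import Risk, RiskRegister


@dataclass(frozen=True)
class PlantedHierarchy:
    """Ground truth: element groups plus an acyclic between-group DAG.

    ``groups`` partition the elements; ``dag_edges`` hold (i, j) group
    indices meaning group i influences group j. Group indices are a
    topological order by construction (edges only go i < j).
    """

    elements: tuple[str, ...]
    groups: tuple[tuple[str, ...], ...]
    dag_edges: frozenset[tuple[int, int]]
    seed: int
    density: float

    @property
    def n(self) -> int:
        return len(self.elements)

    @property
    def k(self) -> int:
        return len(self.groups)

    def group_of(self, code: str) -> int:
        for gi, g in enumerate(self.groups):
            if code in g:
                return gi
        raise KeyError(code)

    def group_reachability(self) -> np.ndarray:
        """k×k boolean closure of the planted DAG (diagonal False)."""
        k = self.k
        m = np.zeros((k, k), dtype=bool)
        for a, b in self.dag_edges:
            m[a, b] = True
        while True:
            nxt = m | (m @ m)
            if (nxt == m).all():
                return m
            m = nxt

    def reachability(self, element_order: Sequence[str] | None = None) -> ReachabilityMatrix:
        """Element-level closed reachability matrix implied by the truth."""
        order = tuple(element_order) if element_order is not None else self.elements
        if sorted(order) != sorted(self.elements):
            raise ValidationError("element_order must be a permutation of the elements")
        greach = self.group_reachability()
        n = len(order)
        m = np.eye(n, dtype=bool)
        gi = [self.group_of(c) for c in order]
        for i in range(n):
            for j in range(n):
                if i != j and (gi[i] == gi[j] or greach[gi[i], gi[j]]):
                    m[i, j] = True
        return ReachabilityMatrix(order, m)


def generate_hierarchy(
    n: int, k_groups: int, density: float, seed: int
) -> PlantedHierarchy:
    """Plant a hierarchy: random partition + random DAG over the groups.

    ``density`` is the probability of each forward group pair (i, j),
    i < j in the topological order, carrying a direct edge. Group sizes
    come from a random composition of n into k_groups parts of at least 1.
    """
    if not (1 <= k_groups <= n):
        raise ValidationError("need 1 <= k_groups <= n")
    if not (0.0 <= density <= 1.0):
        raise ValidationError("density must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    # composition of n into k parts >= 1 via sorted cut points
    cuts = np.sort(rng.choice(np.arange(1, n), size=k_groups - 1, replace=False)) if k_groups > 1 else np.array([], dtype=int)
    bounds = np.concatenate(([0], cuts, [n]))
    sizes = np.diff(bounds)
    codes = [f"E{i + 1}" for i in range(n)]
    perm = rng.permutation(n)
    groups: list[tuple[str, ...]] = []
    pos = 0
    for s in sizes:
        groups.append(tuple(codes[perm[pos + t]] for t in range(s)))
        pos += s
    edges = {
        (i, j)
        for i in range(k_groups)
        for j in range(i + 1, k_groups)
        if rng.random() < density
    }
    return PlantedHierarchy(tuple(codes), tuple(groups), frozenset(edges), seed, density)


def hierarchy_to_ssim(
    h: PlantedHierarchy,
    element_order: Sequence[str] | None = None,
    *,
    sparse: bool = False,
) -> SSIM:
    """Induce the SSIM a perfectly consistent expert panel would produce.

    Dense mode (default) emits the full planted relation for every pair —
    within-group pairs as X, reachable between-group pairs as V or A
    depending on the pair's position order, unrelated pairs as O — so the
    initial matrix is already closed. Sparse mode emits only a spanning
    chain of X within each group and V/A only for the transitive
    reduction of the group DAG (one representative pair per reduced
    edge), leaving the rest to the transitivity check; its closure still
    recovers the planted reachability exactly.
    """
    order = tuple(element_order) if element_order is not None else h.elements
    if sorted(order) != sorted(h.elements):
        raise ValidationError("element_order must be a permutation of the elements")
    greach = h.group_reachability()
    gi = {c: h.group_of(c) for c in order}
    n = len(order)
    symbols: dict[tuple[int, int], str] = {
        (i, j): "O" for i in range(n) for j in range(i + 1, n)
    }

    def set_pair(a: str, b: str, forward: bool) -> None:
        """Record a directed relation a→b (forward) as V or A per position order."""
        i, j = order.index(a), order.index(b)
        if i < j:
            symbols[(i, j)] = "V" if forward else "A"
        else:
            symbols[(j, i)] = "A" if forward else "V"

    if not sparse:
        for i in range(n):
            for j in range(i + 1, n):
                a, b = order[i], order[j]
                if gi[a] == gi[b]:
                    symbols[(i, j)] = "X"
                elif greach[gi[a], gi[b]]:
                    symbols[(i, j)] = "V"
                elif greach[gi[b], gi[a]]:
                    symbols[(i, j)] = "A"
        return SSIM(order, symbols)

    # sparse mode: chain of X within each group
    for g in h.groups:
        members = [c for c in order if c in g]
        for a, b in zip(members, members[1:]):
            i, j = order.index(a), order.index(b)
            symbols[(i, j)] = "X"
    # transitive reduction of the DAG: keep (a,b) with no intermediate path
    reduced = []
    for a, b in h.dag_edges:
        via = any(
            greach[a, m] and greach[m, b] for m in range(h.k) if m not in (a, b)
        )
        if not via:
            reduced.append((a, b))
    for a, b in reduced:
        set_pair(h.groups[a][0], h.groups[b][0], forward=True)
    return SSIM(order, symbols)


def generate_degree_profile(
    register_size: int, tail_fraction: float = 0.17, seed: int = 0
) -> CentralityTable:
    """Integer degree scores with a bulk and a designated upper tail.

    The bulk is uniform on 5..39 (the typical range of screened relation
    counts in a ~100-risk register) and round(size × tail_fraction)
    elements form a tail uniform on 42..55, so an upper-quantile cutoff
    separates a small key set. Deterministic per seed.
    """
    if register_size < 1:
        raise ValidationError("register_size must be positive")
    if register_size > 1 and not (0.0 < tail_fraction < 1.0):
        raise ValidationError("tail_fraction must lie strictly between 0 and 1")
    rng = np.random.default_rng(seed)
    n_tail = int(round(register_size * tail_fraction)) if register_size > 1 else 1
    n_tail = min(max(n_tail, 1), register_size)
    scores = rng.integers(5, 40, size=register_size)
    tail_idx = rng.choice(register_size, size=n_tail, replace=False)
    scores[tail_idx] = rng.integers(42, 56, size=n_tail)
    return CentralityTable({f"R{i + 1}": int(scores[i]) for i in range(register_size)})


_SEGMENTS = (
    "Collection", "Processing", "Testing", "Storage", "Distribution",
    "Suppliers", "Environment", "Workforce",
)


def generate_register(n: int, seed: int = 0) -> RiskRegister:
    """Synthetic register of n coded risks over a few generic segments."""
    rng = np.random.default_rng(seed)
    segs = rng.integers(0, len(_SEGMENTS), size=n)
    return RiskRegister(
        Risk(f"R{i + 1}", f"Synthetic risk {i + 1}", _SEGMENTS[segs[i]]) for i in range(n)
    )
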