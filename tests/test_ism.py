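import io

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ismrisk import (
    SSIM,
    FormatError,
    IsmRiskError,
    ReachabilityMatrix,
    ValidationError,
    build_hierarchy,
    initial_to_ssim,
    level_partition,
    parse_ssim,
    ssim_to_initial,
    strongly_connected_groups,
    transitive_closure,
    write_ssim,
)
from ismrisk.errors import GlyphSubstitutionWarning

from conftest import TEN_RISK_GROUP


def closure_by_powers(m: np.ndarray) -> np.ndarray:
    """Independent oracle: OR of boolean matrix powers up to n."""
    n = m.shape[0]
    acc = m.copy()
    p = m.copy()
    for _ in range(n):
        p = (p @ m) > 0
        acc = acc | p
    return acc


def random_reflexive(n: int, seed: int, density: float = 0.25) -> ReachabilityMatrix:
    rng = np.random.default_rng(seed)
    m = rng.random((n, n)) < density
    np.fill_diagonal(m, True)
    return ReachabilityMatrix([f"E{i}" for i in range(n)], m)


class TestParseSsim:
    def test_case_study_order_and_size(self, bsc_ssim):
        assert bsc_ssim.elements == tuple(
            "R98 R7 R100 R102 R67 R13 R40 R11 R35 R62 R49 R1 R5 R63 R16 R20 R87".split()
        )
        assert len(bsc_ssim.symbols) == 17 * 16 // 2

    def test_digit_zero_glyph_reads_as_O(self, bsc_ssim):
        # the printed matrix uses the digit 0 in the (R11, R5) cell
        assert bsc_ssim.symbol("R11", "R5") == "O"

    def test_glyph_substitution_warns_with_cell_address(self):
        src = ",A,B\nA,,0\nB,,\n"
        with pytest.warns(GlyphSubstitutionWarning, match=r"\(A, B\)"):
            s = parse_ssim(io.StringIO(src))
        assert s.symbol("A", "B") == "O"

    def test_two_element_file(self):
        s = parse_ssim(io.StringIO(",A,B\nA,,O\nB,,\n"))
        assert s.n == 2 and s.symbol("A", "B") == "O"

    def test_lower_triangle_ignored(self):
        # contradictory lower triangle must not override the upper
        s = parse_ssim(io.StringIO(",A,B\nA,,V\nB,X,\n"))
        assert s.symbol("A", "B") == "V"

    def test_invalid_symbol_names_cell(self):
        with pytest.raises(FormatError, match=r"\(A, B\)"):
            parse_ssim(io.StringIO(",A,B\nA,,Q\nB,,\n"))

    def test_missing_cell_is_format_error(self):
        with pytest.raises(FormatError, match="missing"):
            parse_ssim(io.StringIO(",A,B,C\nA,,V,\nB,,,O\nC,,,\n"))

    def test_round_trip(self, bsc_ssim, tmp_path):
        path = tmp_path / "ssim.csv"
        write_ssim(bsc_ssim, path)
        assert parse_ssim(path) == bsc_ssim


class TestInitialMatrix:
    def test_symbol_semantics(self):
        order = ["A", "B", "C", "D", "E"]
        # pairs: (A,B)=V (A,C)=A (A,D)=X (A,E)=O, rest O
        symbols = {(i, j): "O" for i in range(5) for j in range(i + 1, 5)}
        symbols[(0, 1)] = "V"
        symbols[(0, 2)] = "A"
        symbols[(0, 3)] = "X"
        m = ssim_to_initial(SSIM(order, symbols))
        assert (m.cell("A", "B"), m.cell("B", "A")) == (1, 0)
        assert (m.cell("A", "C"), m.cell("C", "A")) == (0, 1)
        assert (m.cell("A", "D"), m.cell("D", "A")) == (1, 1)
        assert (m.cell("A", "E"), m.cell("E", "A")) == (0, 0)
        assert not m.derived.any()

    def test_all_O_gives_identity(self):
        symbols = {(i, j): "O" for i in range(4) for j in range(i + 1, 4)}
        m = ssim_to_initial(SSIM(list("ABCD"), symbols))
        assert (m.values == np.eye(4, dtype=bool)).all()

    def test_case_study_direct_cells(self, bsc_ssim):
        m = ssim_to_initial(bsc_ssim)
        assert bsc_ssim.symbol("R98", "R67") == "V"
        assert (m.cell("R98", "R67"), m.cell("R67", "R98")) == (1, 0)
        # no direct relation recorded between R98 and R35
        assert bsc_ssim.symbol("R98", "R35") == "O"
        assert m.cell("R98", "R35") == 0

    @pytest.mark.parametrize("seed", range(5))
    def test_ssim_matrix_round_trip(self, seed):
        rng = np.random.default_rng(seed)
        n = 8
        syms = {
            (i, j): "VAXO"[rng.integers(4)]
            for i in range(n)
            for j in range(i + 1, n)
        }
        s = SSIM([f"E{i}" for i in range(n)], syms)
        assert initial_to_ssim(ssim_to_initial(s)) == s


class TestClosure:
    def test_transitivity_fills_R98_to_R35_with_derived_flag(self, bsc_ssim):
        final = transitive_closure(ssim_to_initial(bsc_ssim))
        assert final.cell("R98", "R35") == 1
        assert final.is_derived("R98", "R35")
        # directly recorded cells never get the flag
        assert not final.is_derived("R98", "R67")

    def test_identity_closure_is_identity(self):
        m = ReachabilityMatrix(list("ABC"), np.eye(3, dtype=bool))
        c = transitive_closure(m)
        assert (c.values == np.eye(3, dtype=bool)).all()
        assert not c.derived.any()

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_boolean_power_oracle(self, seed):
        m = random_reflexive(12, seed)
        c = transitive_closure(m)
        assert (c.values == closure_by_powers(m.values)).all()

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_networkx_closure(self, seed):
        m = random_reflexive(10, seed, density=0.2)
        g = nx.from_numpy_array(m.values, create_using=nx.DiGraph)
        tc = nx.transitive_closure(g, reflexive=True)
        expect = nx.to_numpy_array(tc, nodelist=range(10)).astype(bool)
        np.fill_diagonal(expect, True)
        assert (transitive_closure(m).values == expect).all()

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000), st.integers(min_value=2, max_value=12))
    def test_closure_properties(self, seed, n):
        """Closure is monotone (input subset), reflexive, idempotent."""
        m = random_reflexive(n, seed)
        c = transitive_closure(m)
        assert (m.values <= c.values).all()
        assert c.values.diagonal().all()
        again = transitive_closure(c)
        assert again == c
        assert (again.derived == c.derived).all()
        assert c.is_closed()

    def test_derived_flags_only_on_new_cells(self):
        m = random_reflexive(9, seed=3)
        c = transitive_closure(m)
        assert ((c.derived) == (c.values & ~m.values)).all()


class TestLevelPartition:
    def test_case_study_top_levels(self, bsc_final):
        part = level_partition(bsc_final)
        assert part.members(1) == {"R40"}
        assert part.members(2) == {"R35"}
        assert part.members(3) == {"R1", "R16"}

    def test_identity_all_level_one(self):
        m = ReachabilityMatrix(list("ABCD"), np.eye(4, dtype=bool))
        part = level_partition(m)
        assert set(part.levels.values()) == {1}

    def test_unclosed_matrix_rejected(self):
        vals = np.eye(3, dtype=bool)
        vals[0, 1] = vals[1, 2] = True  # missing 0->2
        with pytest.raises((ValidationError, IsmRiskError)):
            level_partition(ReachabilityMatrix(list("ABC"), vals))

    def test_audit_records_cover_all_elements(self, bsc_final):
        part = level_partition(bsc_final)
        assert {r.code for r in part.audit} == set(bsc_final.elements)
        for rec in part.audit:
            assert rec.intersection == rec.reachability

    def test_depth_numbering_reverses(self, bsc_final):
        part = level_partition(bsc_final)
        depth = part.depth_levels()
        assert depth["R40"] == part.n_levels
        assert min(depth.values()) == 1

    @pytest.mark.parametrize("seed", range(10))
    def test_reachability_vs_level_ordering(self, seed):
        """cell(i,j)=1 implies level(j) <= level(i), strict across groups."""
        final = transitive_closure(random_reflexive(10, seed))
        part = level_partition(final)
        for i, a in enumerate(final.elements):
            for j, b in enumerate(final.elements):
                if i != j and final.values[i, j]:
                    assert part.levels[b] <= part.levels[a]
                    if not final.values[j, i]:
                        assert part.levels[b] < part.levels[a]

    @pytest.mark.parametrize("seed", range(10))
    def test_levels_contiguous_from_one(self, seed):
        part = level_partition(transitive_closure(random_reflexive(9, seed)))
        assert set(part.levels.values()) == set(range(1, part.n_levels + 1))


class TestGroupsAndHierarchy:
    def test_case_study_ten_risk_group(self, bsc_final):
        groups = strongly_connected_groups(bsc_final)
        assert TEN_RISK_GROUP in groups

    def test_identity_gives_singletons(self):
        m = ReachabilityMatrix(list("ABC"), np.eye(3, dtype=bool))
        assert strongly_connected_groups(m) == [{"A"}, {"B"}, {"C"}]

    @pytest.mark.parametrize("seed", range(8))
    def test_groups_match_pairwise_scan(self, seed):
        final = transitive_closure(random_reflexive(11, seed))
        groups = {frozenset(g) for g in strongly_connected_groups(final)}
        # brute-force: mutual-reachability scan per element
        expect = set()
        for i, a in enumerate(final.elements):
            members = {
                final.elements[j]
                for j in range(final.n)
                if final.values[i, j] and final.values[j, i]
            }
            expect.add(frozenset(members))
        assert groups == expect

    def test_case_study_hierarchy_edges(self, bsc_final):
        part = level_partition(bsc_final)
        h = build_hierarchy(bsc_final, part)
        big = h.group_of("R98")
        r35 = h.group_of("R35")
        r40 = h.group_of("R40")
        r1 = h.group_of("R1")
        # reduction keeps only the shortest chain: group -> R1/R16 -> R35 -> R40
        assert (r35, r40) in h.edges
        assert (big, r1) in h.edges and (r1, r35) in h.edges
        assert (big, r35) not in h.edges and (big, r40) not in h.edges
        # reachability is nevertheless preserved
        reach = h.between_group_reachability()
        assert reach[(big, r35)] and reach[(big, r40)]

    def test_identity_hierarchy_edgeless(self):
        m = ReachabilityMatrix(list("ABC"), np.eye(3, dtype=bool))
        h = build_hierarchy(m, level_partition(m))
        assert h.edges == set()

    @pytest.mark.parametrize("seed", range(8))
    def test_reduction_round_trips_between_group_reachability(self, seed):
        final = transitive_closure(random_reflexive(10, seed))
        h = build_hierarchy(final, level_partition(final))
        assert h.to_element_matrix().to_frame().sort_index().sort_index(axis=1).equals(
            final.to_frame().sort_index().sort_index(axis=1)
        )

    def test_mismatched_partition_rejected(self, bsc_final):
        m = ReachabilityMatrix(list("AB"), np.eye(2, dtype=bool))
        with pytest.raises(ValidationError):
            build_hierarchy(bsc_final, level_partition(m))

    def test_dot_and_graphml_exports(self, bsc_final, tmp_path):
        h = build_hierarchy(bsc_final, level_partition(bsc_final))
        dot = h.to_dot(tmp_path / "h.dot")
        assert "level=1" in dot
        h.to_graphml(tmp_path / "h.graphml")
        g = nx.read_graphml(tmp_path / "h.graphml")
        assert g.number_of_nodes() == len(h.groups)
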