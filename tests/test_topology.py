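import itertools
import math

import pytest
from hypothesis import given
from hypothesis import strategies as st

from parafold import topology as T
from parafold.errors import ResourceLimitError, SchemaError, UnsupportedOrientationError

perm_strategy = st.integers(2, 6).flatmap(
    lambda n: st.permutations(list(range(1, n + 1)))
)


class TestParsing:
    @pytest.mark.parametrize(
        "text,occ",
        [
            ("2↑1↑3↑", (2, 1, 3)),
            ("123", (1, 2, 3)),
            ("2-1-3", (2, 1, 3)),
            ("1↑3↑2↑", (1, 3, 2)),
            ("4-3-2-1-5", (4, 3, 2, 1, 5)),
        ],
    )
    def test_accepted_dialects(self, text, occ):
        assert T.parse_topology(text).occupants == occ

    def test_format_round_trip(self):
        t = T.parse_topology("2-1-3")
        assert t.format() == "2↑1↑3↑"
        assert T.parse_topology(t.format()) == t
        assert t.format("ascii") == "2-1-3"

    @pytest.mark.parametrize("bad", ["2↑2↑3↑", "124", "1-2-2", ""])
    def test_schema_errors(self, bad):
        with pytest.raises(SchemaError):
            T.parse_topology(bad)

    def test_down_arrow_rejected(self):
        with pytest.raises(UnsupportedOrientationError):
            T.parse_topology("2↓3↓1↓")


class TestCanonicalization:
    @pytest.mark.parametrize(
        "occ,canon",
        [((3, 1, 2), (2, 1, 3)), ((1, 2, 3), (1, 2, 3)), ((2, 3, 1), (1, 3, 2))],
    )
    def test_examples(self, occ, canon):
        assert T.canonicalize(T.SheetTopology(occ)).occupants == canon

    @given(perm_strategy)
    def test_idempotent_and_flip_stable(self, perm):
        t = T.SheetTopology(tuple(perm))
        c = T.canonicalize(t)
        assert T.canonicalize(c) == c
        assert T.canonicalize(t.flipped()) == c


class TestEnumeration:
    def test_n3_classes(self):
        occ = {t.occupants for t in T.enumerate_topologies(3, 3)}
        assert occ == {(1, 2, 3), (1, 3, 2), (2, 1, 3)}

    @pytest.mark.parametrize("n", [2, 3, 4, 5, 6])
    def test_count_is_half_factorial(self, n):
        assert len(T.enumerate_topologies(n, n)) == math.factorial(n) // 2

    def test_total_3_to_6(self, topologies_3_6):
        assert len(topologies_3_6) == 435

    def test_resource_guard(self):
        with pytest.raises(ResourceLimitError):
            T.enumerate_topologies(3, T.MAX_ENUMERATION_N + 1)


class TestConnectionGeometry:
    def test_mixed_faces(self):
        conns = T.connection_geometry(T.SheetTopology((2, 1, 3)))
        assert (conns[0].delta, conns[0].face) == (-1, "back")
        assert (conns[1].delta, conns[1].face) == (2, "front")

    def test_sequential_ladder(self):
        conns = T.connection_geometry(T.SheetTopology((1, 2, 3)))
        assert all(c.delta == 1 and c.face == "front" for c in conns)
        assert not any(c.long_distance for c in conns)

    def test_long_distance_crossover(self):
        conns = T.connection_geometry(T.SheetTopology((4, 3, 2, 1, 5)))
        assert abs(conns[3].delta) == 4 and conns[3].long_distance


class TestClashDetection:
    def test_all_three_strand_topologies_clash_free(self):
        assert all(T.is_clash_free(t) for t in T.enumerate_topologies(3, 3))

    def test_nested_same_face_spans_clash(self):
        # connections 1->2 (span 1..4, front) and 3->4 (span 2..3, front)
        assert not T.is_clash_free(T.SheetTopology((1, 3, 4, 2)))

    def test_clash_free_census(self, topologies_3_6):
        assert sum(T.is_clash_free(t) for t in topologies_3_6) == 167

    def test_arc_crossing_oracle(self, topologies_3_6):
        """Literal geometric check: same-face crossover arcs descend from the
        C-terminal top of one strand to the N-terminal bottom of the next;
        two open segments crossing in the face plane = clash."""

        def segments_cross(a, b):
            # a, b: ((x1, 1), (x2, 0)) descending segments; param t in (0,1)
            # x_a(t) = a0 + t*(a1-a0), heights equal at equal t
            a0, a1 = a
            b0, b1 = b
            # they cross iff the horizontal order at the top differs from
            # the order at the bottom (strictly)
            return (a0 - b0) * (a1 - b1) < 0

        for t in topologies_3_6:
            if t.n_strands > 4:
                continue  # small-n oracle is enough to pin the rule
            p = t.positions
            by_face = {"front": [], "back": []}
            for c in T.connection_geometry(t):
                by_face[c.face].append((p[c.strand - 1], p[c.strand]))
            clash = any(
                segments_cross(a, b)
                for segs in by_face.values()
                for a, b in itertools.combinations(segs, 2)
            )
            assert T.is_clash_free(t) == (not clash), t


class TestCounts:
    @pytest.mark.parametrize(
        "occ,nj", [((1, 2, 3), 0), ((2, 1, 3), 1), ((3, 2, 1, 4, 5), 1)]
    )
    def test_jumps(self, occ, nj):
        assert T.count_jumps(T.SheetTopology(occ)) == nj

    @pytest.mark.parametrize(
        "occ,nf", [((2, 1, 3), 0), ((1, 3, 2), 1), ((1, 2, 3), 0)]
    )
    def test_fabp(self, occ, nf):
        assert T.count_fabp(T.SheetTopology(occ)) == nf

    @pytest.mark.parametrize(
        "occ,rev",
        [
            ((2, 1, 3), (1, 3, 2)),
            ((1, 2, 3), (1, 2, 3)),
            ((3, 2, 1, 4, 5), (1, 2, 5, 4, 3)),
        ],
    )
    def test_reverse(self, occ, rev):
        assert T.reverse_topology(T.SheetTopology(occ)).occupants == rev

    def test_reverse_is_involution(self, topologies_3_6):
        for t in topologies_3_6:
            assert T.reverse_topology(T.reverse_topology(t)) == t

    @pytest.mark.parametrize(
        "occ,val",
        [((1, 2, 3), 1 / 3), ((2, 1, 3), 0.5), ((1, 2, 3, 4, 5), 1 / 5)],
    )
    def test_beta_rco(self, occ, val):
        assert T.beta_rco(T.SheetTopology(occ)) == pytest.approx(val)

    def test_beta_rco_bounds(self, topologies_3_6):
        for t in topologies_3_6:
            n = t.n_strands
            assert 1 / n <= T.beta_rco(t) <= (n - 1) / n


class TestClassification:
    def test_three_strand_examples(self):
        c = T.classify_topology(T.SheetTopology((2, 1, 3)))
        assert c.frustration_free and c.n_jumps == 1 and c.n_fabp == 0
        assert c.c_term_edge and not c.n_term_edge
        assert T.classify_topology(T.SheetTopology((1, 3, 2))).n_fabp == 1
        ladder = T.classify_topology(T.SheetTopology((1, 2, 3)))
        assert ladder.n_term_edge and ladder.c_term_edge

    @given(perm_strategy)
    def test_flip_invariance(self, perm):
        """All classifier outputs agree on a representative and its mirror."""
        a = T.SheetTopology(tuple(perm))
        b = a.flipped()
        assert T.count_jumps(a) == T.count_jumps(b)
        assert T.count_fabp(a) == T.count_fabp(b)
        assert T.is_clash_free(a) == T.is_clash_free(b)
        assert T.beta_rco(a) == pytest.approx(T.beta_rco(b))

    def test_reversal_invariants(self, topologies_3_6):
        for t in topologies_3_6:
            r = T.reverse_topology(t)
            assert T.count_jumps(t) == T.count_jumps(r)
            assert T.is_clash_free(t) == T.is_clash_free(r)


class TestSummary:
    def test_edge_percentages(self, clash_free_summary):
        assert clash_free_summary.n_term_edge_pct == 37.1
        assert clash_free_summary.c_term_edge_pct == 37.1

    def test_frustration_free_membership(self, clash_free_summary):
        free = {t.occupants for t in clash_free_summary.frustration_free}
        assert len(free) == 14
        superfolds = {
            (2, 1, 3),
            (1, 2, 3),
            (2, 1, 3, 4),
            (3, 2, 1, 4, 5),
            (2, 1, 3, 4, 5),
            (3, 2, 1, 4, 5, 6),
        }
        assert superfolds <= free

    def test_pair_count(self, clash_free_summary):
        assert clash_free_summary.n_reverse_asymmetric_pairs == 23
        for free, frus in clash_free_summary.reverse_asymmetric_pairs:
            assert T.count_fabp(free) == 0 and T.count_fabp(frus) > 0
            assert T.reverse_topology(free) == frus

    def test_grid_totals(self, clash_free_summary, topologies_3_6):
        assert sum(map(sum, clash_free_summary.grid)) == 167
        full = T.summarize_topology_set(topologies_3_6)
        assert sum(map(sum, full.grid)) + full.grid_overflow == 435

    def test_edge_symmetry_on_reversal_closed_set(self, topologies_3_6):
        """Chain reversal swaps the terminal-edge flags, so on any
        reversal-closed set the two edge fractions coincide."""
        full = T.summarize_topology_set(topologies_3_6)
        assert full.n_term_edge_pct == full.c_term_edge_pct

    def test_nj_filter(self, topologies_3_6):
        s = T.summarize_topology_set(topologies_3_6, clash_free_only=True, max_jumps=1)
        assert s.n_topologies == 30

    def test_empty_selection(self, topologies_3_6):
        s = T.summarize_topology_set(
            topologies_3_6, clash_free_only=True, max_fabp=0, max_jumps=0
        )
        assert s.n_topologies == 4  # the sequential ladders
        s0 = T.summarize_topology_set([])
        assert s0.n_topologies == 0 and sum(map(sum, s0.grid)) == 0

    def test_table_columns(self, clash_free_summary):
        assert list(clash_free_summary.table.columns) == [
            "topology", "n_strands", "clash_free", "n_jumps", "n_fabp",
            "beta_rco", "n_term_edge", "c_term_edge", "reverse_topology",
            "long_distance",
        ]
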