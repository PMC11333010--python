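import numpy as np
import pytest

from parafold import lattice as LT
from parafold.errors import ResourceLimitError, SchemaError, TemplateValidationError

from _naive import (
    naive_class,
    naive_contacts,
    naive_designability,
    naive_enumerate,
)


def penalty_paths():
    return [list(t.path) for t in LT.default_templates().penalties]


class TestEnumeration:
    @pytest.mark.parametrize("L,count", [(2, 1), (3, 2), (4, 5), (5, 13)])
    def test_small_counts(self, L, count):
        assert len(LT.enumerate_conformations(L)) == count

    @pytest.mark.parametrize("L", [4, 6, 8])
    def test_matches_naive_enumeration(self, L):
        """Symmetry-pruned DFS agrees with brute force + explicit dedup."""
        confs = LT.enumerate_conformations(L)
        oracle = naive_enumerate(L)
        ours = {naive_class(confs.points[i].tolist()) for i in range(len(confs))}
        assert ours == oracle

    def test_walks_are_canonical(self):
        confs = LT.enumerate_conformations(7)
        for c in confs:
            assert c.canonical() == c

    def test_resource_guard(self):
        with pytest.raises(ResourceLimitError):
            LT.enumerate_conformations(LT.MAX_ENUMERATION_L + 1)


class TestContactsAndRco:
    def test_straight_chain_no_contacts(self):
        c = LT.Conformation.from_turns("SSSSSS")
        assert LT.contact_map(c) == frozenset()
        assert LT.rco(c) is None

    def test_u_shape_single_contact(self):
        c = LT.Conformation(((0, 0), (1, 0), (1, 1), (0, 1)))
        assert LT.contact_map(c) == frozenset({(0, 3)})
        assert LT.rco(c) == pytest.approx(0.75)

    def test_compact_hamiltonian_contact_count(self):
        from parafold.synth import _hamiltonian_4x4

        assert len(LT.contact_map(_hamiltonian_4x4())) == 9

    def test_contact_parity(self, l10_sets):
        confs, _ = l10_sets
        for i in range(0, len(confs), 97):
            for a, b in LT.contact_map(confs[i]):
                assert b - a >= 3 and (b - a) % 2 == 1

    def test_rco_range(self, l10_sets):
        confs, ann = l10_sets
        vals = ann.rco_values()
        defined = vals[~np.isnan(vals)]
        assert ((defined > 0) & (defined <= 1)).all()
        assert np.isnan(vals[ann.n_c == 0]).all()


class TestMotifs:
    def test_fixture_annotations(self):
        from parafold.synth import generate_lattice_fixtures

        for L in (10, 16):
            fixtures, _ = generate_lattice_fixtures(L=L, seed=1)
            for f in fixtures:
                got = LT.count_motifs(f.conformation)
                assert got == f.expected, f.name
                assert len(LT.contact_map(f.conformation)) == f.expected_n_c, f.name

    def test_short_chain_has_no_motifs(self):
        c = LT.Conformation(((0, 0), (1, 0), (1, 1)))
        assert LT.count_motifs(c) == LT.MotifCounts(0, 0)

    def test_count_against_naive_matcher(self, l10_sets):
        confs, ann = l10_sets
        from _naive import naive_count_penalties

        for i in range(0, len(confs), 59):
            pts = [tuple(p) for p in confs.points[i].tolist()]
            assert ann.n_penalty[i] == naive_count_penalties(pts, penalty_paths())

    def test_direction_matters(self):
        """An interior straight-then-turn is an FLS; turn-then-straight
        (its chain reversal) is not."""
        fls_like = LT.Conformation.from_turns("SLL")
        rev = LT.reverse_conformation(fls_like)
        assert LT.count_motifs(fls_like).n_fls == 1
        assert LT.count_motifs(rev).n_fls == 0

    def test_nonoverlapping_counting_never_exceeds(self, l10_sets):
        confs, _ = l10_sets
        for i in range(0, len(confs), 151):
            c = confs[i]
            a = LT.count_motifs(c, overlapping=True)
            b = LT.count_motifs(c, overlapping=False)
            assert b.n_penalty <= a.n_penalty and b.n_fls <= a.n_fls


class TestTemplateValidation:
    def test_default_templates_pass(self):
        report = LT.verify_fls_frustration()
        assert report.passed
        report.raise_if_failed()

    def test_straight_fls_substitute_fails(self):
        bad = LT.MotifTemplateSet(
            penalties=LT.default_templates().penalties,
            fls=LT.MotifTemplate("FLS", ((0, 0), (1, 0), (2, 0), (3, 0))),
        )
        report = LT.verify_fls_frustration(bad)
        assert not report.passed
        with pytest.raises(TemplateValidationError):
            report.raise_if_failed()

    def test_scan_refuses_invalid_templates(self):
        bad = LT.MotifTemplateSet(
            penalties=LT.default_templates().penalties,
            fls=LT.MotifTemplate("FLS", ((0, 0), (1, 0), (2, 0), (3, 0))),
        )
        with pytest.raises(TemplateValidationError):
            LT.designability_scan(6, templates=bad)


class TestEnergy:
    def test_all_polar_sequence(self):
        c = LT.Conformation.from_turns("SLS")  # one penalty motif
        assert LT.energy("P" * 5, c) == pytest.approx(2.0)
        assert LT.energy("P" * 5, c, LT.EnergyParams(1.0, 0.5)) == pytest.approx(0.5)

    def test_hh_contact_reward(self):
        c = LT.Conformation(((0, 0), (1, 0), (1, 1), (0, 1)))
        assert LT.energy("HPPH", c) == pytest.approx(-1.0)
        assert LT.energy("HPPP", c) == pytest.approx(0.0)

    def test_length_mismatch(self):
        with pytest.raises(SchemaError):
            LT.energy("HP", LT.Conformation.from_turns("SS"))

    def test_integer_scaling(self):
        assert LT.EnergyParams(1.0, 2.0).as_integers() == (1, 2)
        assert LT.EnergyParams(1.0, 0.1).as_integers() == (10, 1)
        assert LT.EnergyParams(1.0, 0.5).as_integers() == (2, 1)


class TestReversal:
    def test_straight_chain_self_reverse(self):
        c = LT.Conformation.from_turns("SSSS")
        assert LT.reverse_conformation(c) == c

    def test_involution_full_set(self):
        confs = LT.enumerate_conformations(8)
        rev = confs.reverse_indices()
        assert (rev[rev] == np.arange(len(confs))).all()

    def test_contact_count_preserved(self):
        confs = LT.enumerate_conformations(12)
        ann = LT.annotate_conformations(confs)
        rev = confs.reverse_indices()
        assert (ann.n_c == ann.n_c[rev]).all()
        rco = ann.rco_values()
        both = ~np.isnan(rco)
        assert np.allclose(rco[both], rco[rev][both])


class TestDesignability:
    def test_grouped_scan_matches_naive(self, l10_sets):
        """The class-grouped integer scan equals a per-conformation
        float-energy census at L = 10."""
        confs, ann = l10_sets
        result = LT.designability_scan(annotations=ann)
        pts = [[tuple(p) for p in confs.points[i].tolist()] for i in range(len(confs))]
        pl, n_s, min_e = naive_designability(pts, penalty_paths(), 1.0, 2.0)
        assert result.protein_like_count == pl
        assert (result.n_s == n_s).all()
        assert np.allclose(result.min_energy / result.energy_scale, min_e)

    def test_pure_hp_limit(self, l10_sets):
        """eps_penalty = 0 reduces the model to the original HP model."""
        confs, ann = l10_sets
        result = LT.designability_scan(
            annotations=ann, params=LT.EnergyParams(1.0, 0.0)
        )
        pts = [[tuple(p) for p in confs.points[i].tolist()] for i in range(len(confs))]
        pl, n_s, min_e = naive_designability(pts, penalty_paths(), 1.0, 0.0)
        assert result.protein_like_count == pl
        assert (result.n_s == n_s).all()

    def test_ns_sums_to_protein_like(self, l10_sets):
        _, ann = l10_sets
        for eps in (0.0, 0.5, 2.0, 4.0):
            r = LT.designability_scan(annotations=ann, params=LT.EnergyParams(1.0, eps))
            assert int(r.n_s.sum()) == r.protein_like_count

    def test_scan_resource_guard(self):
        with pytest.raises(ResourceLimitError):
            LT.designability_scan(LT.MAX_SCAN_L + 1)

    def test_sequence_string(self, l10_sets):
        _, ann = l10_sets
        r = LT.designability_scan(annotations=ann)
        assert r.sequence_string(0b1) == "H" + "P" * 9
        assert r.sequence_string((1 << 10) - 1) == "H" * 10


class TestGridSummary:
    def test_grid_partitions_structures(self, l10_sets):
        _, ann = l10_sets
        r = LT.designability_scan(annotations=ann)
        g = LT.grid_summary(r, threshold=10)
        assert g.counts_all.sum() + g.overflow_all == len(ann.conformations)
        assert (g.counts_high <= g.counts_all).all()

    def test_infinite_threshold_empties_grid(self, l10_sets):
        _, ann = l10_sets
        r = LT.designability_scan(annotations=ann)
        g = LT.grid_summary(r, threshold=10**9)
        assert g.counts_high.sum() == 0 and g.overflow_high == 0


class TestArchive:
    def test_round_trip(self, tmp_path):
        confs = LT.enumerate_conformations(6)
        path = tmp_path / "walks.csv.gz"
        LT.write_conformation_archive(path, confs)
        back = LT.read_conformation_archive(path)
        assert (back.points == confs.points).all()
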