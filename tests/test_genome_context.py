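"""Operon segmentation, context tables, co-presence, saturation curves."""

import itertools
from fractions import Fraction

import numpy as np
import pytest

from helpers import brute_force_operon_blocks

from arcp450.errors import LinkageError
from arcp450.ferredoxin import FdxType, assign_fdx_type, find_ofor, scan_fes_motifs
from arcp450.genome_context import (
    copresence_counts,
    family_saturation,
    p450_operon_context,
    predict_operons,
    replicon_family_comparison,
)
from arcp450.io_formats import GeneFeature, RepliconMeta, RepliconType, Strand
from arcp450.nomenclature import FamilyAssignment
from arcp450.p450_screen import screen_proteome


def _gene(gid, start, end, strand="+", replicon="chr1", protein=None):
    return GeneFeature(
        gene_id=gid,
        protein_id=protein or gid,
        replicon_id=replicon,
        start=start,
        end=end,
        strand=Strand(strand),
    )


def _assign(pid, family):
    return FamilyAssignment(pid, family, "A", None, 0.0, True)


class TestPredictOperons:
    def test_small_gap_joins(self):
        ops = predict_operons([_gene("g1", 1, 100), _gene("g2", 150, 300)])
        assert len(ops) == 1
        assert ops[0].gene_ids == ("g1", "g2")

    def test_strand_flip_splits(self):
        ops = predict_operons([_gene("g1", 1, 100, "+"), _gene("g2", 120, 300, "-")])
        assert [o.gene_ids for o in ops] == [("g1",), ("g2",)]

    def test_mixed_gaps_segment_as_derived(self):
        # gaps between consecutive genes: 50, 500, 10, 10 -> blocks of 2 and 3
        genes = [
            _gene("g1", 1, 100),
            _gene("g2", 151, 250),
            _gene("g3", 751, 850),
            _gene("g4", 861, 960),
            _gene("g5", 971, 1070),
        ]
        ops = predict_operons(genes)
        assert [o.gene_ids for o in ops] == [("g1", "g2"), ("g3", "g4", "g5")]

    def test_overlapping_same_strand_treated_as_gap_zero(self, caplog):
        ops = predict_operons([_gene("g1", 1, 100), _gene("g2", 80, 200)])
        assert len(ops) == 1

    def test_matches_brute_force_on_random_layouts(self):
        rng = np.random.default_rng(31)
        for _ in range(100):
            pos, genes = 1, []
            for i in range(int(rng.integers(2, 12))):
                length = int(rng.integers(50, 900))
                genes.append(
                    (f"g{i}", pos, pos + length - 1, "+" if rng.random() < 0.5 else "-")
                )
                pos += length + int(rng.integers(0, 400))
            features = [_gene(g, s, e, st) for g, s, e, st in genes]
            expected = brute_force_operon_blocks(genes, 150)
            got = [o.gene_ids for o in predict_operons(features, 150)]
            assert got == expected

    def test_partition_and_monotonicity(self):
        rng = np.random.default_rng(32)
        pos, features = 1, []
        for i in range(30):
            length = int(rng.integers(50, 500))
            features.append(_gene(f"g{i}", pos, pos + length - 1,
                                  "+" if rng.random() < 0.5 else "-"))
            pos += length + int(rng.integers(0, 300))
        counts = []
        for gap in (0, 50, 150, 500, 10_000):
            ops = predict_operons(features, gap)
            all_genes = [g for o in ops for g in o.gene_ids]
            assert sorted(all_genes) == sorted(f.gene_id for f in features)
            counts.append(len(ops))
        assert counts == sorted(counts, reverse=True)


class TestOperonContext:
    def test_demo_study_flags_planted_redox_partner(self, demo_study):
        records = list(demo_study.records)
        features = list(demo_study.features)
        report = screen_proteome(records)
        fdx_calls = [
            c
            for c in (
                assign_fdx_type(r.id, scan_fes_motifs(r.sequence)) for r in records
                if demo_study.truth.roles[r.id] == "ferredoxin"
            )
            if c.fdx_type is not FdxType.UNCLASSIFIED
        ]
        ofor_calls = find_ofor(records, features)
        operons = predict_operons(features)
        table = p450_operon_context(operons, features, report.calls, fdx_calls, ofor_calls)
        # planted blocks with a P450 and a ferredoxin -> flagged; others not
        fdx_genes = {f"g_{pid}" for pid, role in demo_study.truth.roles.items()
                     if role == "ferredoxin"}
        gene_lists = {
            o.operon_id: set(o.gene_ids) for o in operons
        }
        assert len(table) > 0
        for _, row in table.iterrows():
            expected = bool(gene_lists[row.operon_id] & fdx_genes)
            assert row.has_ferredoxin == expected
        assert table.has_ferredoxin.any()  # the planted co-operon case exists
        assert not table.has_ofor.any()  # OFOR genes were planted outside P450 operons

    def test_no_p450_operons_gives_empty_table(self):
        features = [_gene("g1", 1, 100)]
        table = p450_operon_context(predict_operons(features), features, [])
        assert table.empty

    def test_unlinked_p450_raises(self, demo_study):
        report = screen_proteome(list(demo_study.records))
        with pytest.raises(LinkageError):
            p450_operon_context([], [], report.calls)


class TestCopresence:
    def test_worked_example(self):
        assignments = [
            _assign("p1", "CYP109"), _assign("p2", "CYP197"),
            _assign("p3", "CYP109"),
            _assign("p4", "CYP109"), _assign("p5", "CYP197"),
        ]
        species = {"p1": "S1", "p2": "S1", "p3": "S2", "p4": "S3", "p5": "S3"}
        m = copresence_counts(assignments, species)
        assert m.loc["CYP109", "CYP197"] == 2
        assert m.loc["CYP109", "CYP109"] == 3
        assert m.loc["CYP197", "CYP197"] == 2

    def test_symmetry_and_diagonal_bound_on_random_inputs(self):
        rng = np.random.default_rng(33)
        families = [f"F{i}" for i in range(6)]
        assignments, species = [], {}
        for i in range(60):
            pid = f"p{i}"
            assignments.append(_assign(pid, families[int(rng.integers(6))]))
            species[pid] = f"S{int(rng.integers(8))}"
        m = copresence_counts(assignments, species)
        assert (m.values == m.values.T).all()
        for f in m.index:
            for g in m.columns:
                assert m.loc[f, g] <= min(m.loc[f, f], m.loc[g, g])

    def test_missing_species_raises(self):
        with pytest.raises(LinkageError):
            copresence_counts([_assign("p1", "F1")], {})


class TestRepliconComparison:
    META = [
        RepliconMeta("chr1", "S1", RepliconType.CHROMOSOME),
        RepliconMeta("pl1", "S1", RepliconType.PLASMID),
    ]

    def test_split_counts(self):
        assignments = [_assign(f"p{i}", "F1") for i in range(5)]
        replicon_of = {"p0": "pl1", "p1": "chr1", "p2": "chr1", "p3": "chr1", "p4": "pl1"}
        table = replicon_family_comparison(assignments, replicon_of, self.META)
        row = table[table.family == "F1"].iloc[0]
        assert (row.plasmid_count, row.chromosome_count) == (2, 3)

    def test_column_sums_conserve_totals(self):
        rng = np.random.default_rng(34)
        assignments, replicon_of = [], {}
        for i in range(40):
            pid = f"p{i}"
            assignments.append(_assign(pid, f"F{int(rng.integers(4))}"))
            replicon_of[pid] = "pl1" if rng.random() < 0.3 else "chr1"
        table = replicon_family_comparison(assignments, replicon_of, self.META)
        assert table.plasmid_count.sum() + table.chromosome_count.sum() == 40

    def test_all_chromosomal_zero_plasmid_column(self):
        assignments = [_assign("p1", "F1")]
        table = replicon_family_comparison(assignments, {"p1": "chr1"}, self.META)
        assert (table.plasmid_count == 0).all()

    def test_unresolvable_replicon_raises(self):
        with pytest.raises(LinkageError):
            replicon_family_comparison([_assign("p1", "F1")], {}, self.META)


class TestSaturation:
    WORKED = (
        [_assign("p1", "A"), _assign("p2", "B"), _assign("p3", "B"), _assign("p4", "C")],
        {"p1": "S1", "p2": "S1", "p3": "S2", "p4": "S3"},
    )

    @staticmethod
    def _enumeration_oracle(families_by_species):
        """Mean cumulative distinct families over every species ordering."""
        species = sorted(families_by_species)
        n = len(species)
        totals = [Fraction(0)] * n
        orders = list(itertools.permutations(species))
        for order in orders:
            seen = set()
            for k, sp in enumerate(order):
                seen |= families_by_species[sp]
                totals[k] += len(seen)
        return [t / len(orders) for t in totals]

    def test_worked_example_matches_enumeration(self):
        assignments, species = self.WORKED
        oracle = self._enumeration_oracle({"S1": {"A", "B"}, "S2": {"B"}, "S3": {"C"}})
        assert oracle == [Fraction(4, 3), Fraction(7, 3), Fraction(3)]
        curve = family_saturation(assignments, species, exhaustive=True)
        assert [Fraction(v).limit_denominator(1000) for v in curve.mean_cumulative_families] == oracle

    def test_monte_carlo_approaches_enumeration(self):
        assignments, species = self.WORKED
        exact = family_saturation(assignments, species, exhaustive=True)
        mc = family_saturation(assignments, species, n_permutations=4000, seed=7)
        for a, b in zip(mc.mean_cumulative_families, exact.mean_cumulative_families):
            assert abs(a - b) < 0.05

    def test_flat_when_all_species_share_one_family(self):
        assignments = [_assign(f"p{i}", "A") for i in range(3)]
        species = {f"p{i}": f"S{i}" for i in range(3)}
        curve = family_saturation(assignments, species, n_permutations=10, seed=0)
        assert curve.mean_cumulative_families == (1.0, 1.0, 1.0)

    def test_diagonal_when_each_species_unique(self):
        assignments = [_assign(f"p{i}", f"F{i}") for i in range(4)]
        species = {f"p{i}": f"S{i}" for i in range(4)}
        curve = family_saturation(assignments, species, n_permutations=10, seed=0)
        assert curve.mean_cumulative_families == (1.0, 2.0, 3.0, 4.0)

    def test_non_decreasing_and_ends_at_total(self, demo_study):
        truth = demo_study.truth
        assignments = [
            _assign(pid, fam) for pid, fam in truth.family_of.items()
        ]
        curve = family_saturation(assignments, truth.species_of, n_permutations=50, seed=3)
        values = curve.mean_cumulative_families
        assert all(a <= b + 1e-12 for a, b in zip(values, values[1:]))
        assert values[-1] == len(set(truth.family_of.values()))

    def test_deterministic_given_seed(self):
        assignments, species = self.WORKED
        c1 = family_saturation(assignments, species, n_permutations=20, seed=5)
        c2 = family_saturation(assignments, species, n_permutations=20, seed=5)
        assert c1 == c2
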