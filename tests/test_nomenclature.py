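"""CYP name parsing, reference assignment, de novo clustering, counting."""

import numpy as np
import pytest

from arcp450.errors import ConfigurationError, NamingError
from arcp450.identity import IdentityMatrix
from arcp450.io_formats import ProteinRecord
from arcp450.nomenclature import (
    ClassifierParams,
    FamilyAssignment,
    ReferenceDB,
    assign_against_reference,
    cluster_novel_families,
    cluster_subfamilies,
    count_families,
    name_assignments,
    parse_cyp_name,
)
from arcp450.synthetic_data import mutate_to_identity, random_sequence


def fake_matrix(ids, entries):
    """Symmetric identity matrix from {(a, b): percent} with diagonal 100."""
    n = len(ids)
    values = np.full((n, n), 0.0)
    np.fill_diagonal(values, 100.0)
    index = {id_: i for i, id_ in enumerate(ids)}
    for (a, b), pid in entries.items():
        values[index[a], index[b]] = values[index[b], index[a]] = pid
    return IdentityMatrix(ids=tuple(ids), values=values)


def brute_components(ids, matrix, threshold):
    """Oracle: connected components by explicit graph traversal."""
    index = {id_: matrix.ids.index(id_) for id_ in ids}
    seen, comps = set(), []
    for start in ids:
        if start in seen:
            continue
        comp, frontier = set(), [start]
        while frontier:
            node = frontier.pop()
            if node in comp:
                continue
            comp.add(node)
            for other in ids:
                if other not in comp and matrix.values[index[node], index[other]] >= threshold:
                    frontier.append(other)
        seen |= comp
        comps.append(sorted(comp))
    return sorted(comps)


class TestParseCypName:
    @pytest.mark.parametrize(
        "label,family,subfamily,member",
        [
            ("CYP147A1", "CYP147", "A", 1),
            ("CYP109G24", "CYP109", "G", 24),
            ("CYP1002B4", "CYP1002", "B", 4),
            ("CYP174AB12", "CYP174", "AB", 12),
        ],
    )
    def test_valid_names(self, label, family, subfamily, member):
        name = parse_cyp_name(label)
        assert (name.family, name.subfamily, name.member) == (family, subfamily, member)

    @pytest.mark.parametrize("label", ["CYP", "P450x", "CYPA1", "cyp109g2x"])
    def test_invalid_names_rejected(self, label):
        with pytest.raises(ValueError):
            parse_cyp_name(label)


@pytest.fixture(scope="module")
def setup():
    rng = np.random.default_rng(11)
    ref_seq = random_sequence(rng, 400)
    far_seq = random_sequence(rng, 400)
    refdb = ReferenceDB.from_records(
        [
            ProteinRecord(id="CYP147A1", sequence=ref_seq),
            ProteinRecord(id="CYP109G2", sequence=far_seq),
        ]
    )
    return rng, ref_seq, far_seq, refdb


class TestAssignAgainstReference:

    def test_identical_query_inherits_family_and_subfamily(self, setup):
        _, ref_seq, _, refdb = setup
        query = ProteinRecord(id="q", sequence=ref_seq)
        a = assign_against_reference(query, refdb)
        assert (a.family, a.subfamily) == ("CYP147", "A")
        assert a.best_identity == 100.0
        assert not a.novel_family

    def test_family_level_hit_leaves_subfamily_open(self, setup):
        rng, _, far_seq, refdb = setup
        query_seq = mutate_to_identity(far_seq, (44.0, 48.0), frozenset(), rng)
        a = assign_against_reference(ProteinRecord(id="q", sequence=query_seq), refdb)
        assert a.family == "CYP109"
        assert a.subfamily == ""
        assert 40.0 <= a.best_identity < 55.0
        assert not a.novel_family

    def test_distant_query_founds_novel_family(self, setup):
        rng, *_ , refdb = setup
        query = ProteinRecord(id="q", sequence=random_sequence(rng, 400))
        a = assign_against_reference(query, refdb)
        assert a.novel_family
        assert a.best_identity < 40.0

    def test_two_family_hits_flag_conflict(self):
        rng = np.random.default_rng(12)
        seed = random_sequence(rng, 400)
        near = mutate_to_identity(seed, (80.0, 85.0), frozenset(), rng)
        refdb = ReferenceDB.from_records(
            [
                ProteinRecord(id="CYP147A1", sequence=seed),
                ProteinRecord(id="CYP200A1", sequence=near),
            ]
        )
        query_seq = mutate_to_identity(seed, (70.0, 75.0), frozenset(), rng)
        a = assign_against_reference(ProteinRecord(id="q", sequence=query_seq), refdb)
        assert a.conflict

    def test_empty_reference_rejected(self):
        empty = ReferenceDB(records=(), names={})
        with pytest.raises(ConfigurationError):
            assign_against_reference(
                ProteinRecord(id="q", sequence="MKTAYIAKQR"), empty
            )


class TestClustering:
    def test_three_way_chain_is_one_family(self):
        m = fake_matrix(
            ["A", "B", "C"], {("A", "B"): 45.0, ("B", "C"): 45.0, ("A", "C"): 20.0}
        )
        comps = cluster_novel_families(["A", "B", "C"], m)
        assert comps == [["A", "B", "C"]]
        assert comps == brute_components(["A", "B", "C"], m, 40.0)

    def test_all_distant_gives_singletons(self):
        m = fake_matrix(["A", "B", "C"], {})
        assert cluster_novel_families(["A", "B", "C"], m) == [["A"], ["B"], ["C"]]

    def test_matches_brute_force_on_random_matrices(self):
        rng = np.random.default_rng(13)
        for _ in range(25):
            n = int(rng.integers(2, 9))
            ids = [f"s{i}" for i in range(n)]
            values = rng.uniform(0, 100, size=(n, n))
            values = (values + values.T) / 2
            np.fill_diagonal(values, 100.0)
            m = IdentityMatrix(ids=tuple(ids), values=values)
            assert sorted(cluster_novel_families(ids, m)) == brute_components(ids, m, 40.0)
            assert sorted(cluster_subfamilies(ids, m)) == brute_components(ids, m, 55.0)

    def test_subfamily_blocks_split(self):
        ids = ["A1", "A2", "B1", "B2"]
        m = fake_matrix(
            ids,
            {
                ("A1", "A2"): 80.0, ("B1", "B2"): 80.0,
                ("A1", "B1"): 45.0, ("A1", "B2"): 45.0,
                ("A2", "B1"): 45.0, ("A2", "B2"): 45.0,
            },
        )
        assert cluster_subfamilies(ids, m) == [["A1", "A2"], ["B1", "B2"]]

    def test_raising_threshold_never_merges(self):
        rng = np.random.default_rng(14)
        n = 10
        ids = [f"s{i}" for i in range(n)]
        values = rng.uniform(0, 100, size=(n, n))
        values = (values + values.T) / 2
        np.fill_diagonal(values, 100.0)
        m = IdentityMatrix(ids=tuple(ids), values=values)
        counts = [
            len(
                cluster_novel_families(
                    ids, m, ClassifierParams(family_threshold=t, subfamily_threshold=99.0)
                )
            )
            for t in (10.0, 30.0, 50.0, 70.0, 90.0)
        ]
        assert counts == sorted(counts)


def _novel(pid):
    return FamilyAssignment(
        protein_id=pid, family="", subfamily="", best_ref_id=None,
        best_identity=0.0, novel_family=True,
    )


class TestNaming:
    def test_two_novel_families_numbered_in_order(self):
        ids = ["a1", "a2", "b1"]
        m = fake_matrix(ids, {("a1", "a2"): 70.0})
        named = name_assignments([_novel(i) for i in ids], m)
        by_id = {a.protein_id: a for a in named}
        assert by_id["a1"].family == by_id["a2"].family == "CYPN1"
        assert by_id["b1"].family == "CYPN2"

    def test_members_numbered_within_subfamily(self):
        ids = ["a1", "a2", "a3"]
        m = fake_matrix(ids, {(x, y): 80.0 for x in ids for y in ids if x < y})
        named = name_assignments([_novel(i) for i in ids], m)
        assert sorted(a.member for a in named) == [1, 2, 3]
        assert {a.subfamily for a in named} == {"A"}
        assert len({a.label for a in named}) == 3

    def test_collision_with_reference_label_rejected(self):
        ids = ["a1"]
        m = fake_matrix(ids, {})
        with pytest.raises(NamingError):
            name_assignments([_novel("a1")], m, reference_family_labels={"CYPN1"})

    def test_partition_property(self):
        """Every sequence lands in exactly one family and one subfamily."""
        rng = np.random.default_rng(15)
        n = 12
        ids = [f"s{i}" for i in range(n)]
        values = rng.uniform(0, 100, size=(n, n))
        values = (values + values.T) / 2
        np.fill_diagonal(values, 100.0)
        m = IdentityMatrix(ids=tuple(ids), values=values)
        named = name_assignments([_novel(i) for i in ids], m)
        assert len(named) == n
        assert all(a.family and a.subfamily and a.member for a in named)
        assert len({a.protein_id for a in named}) == n


class TestCountFamilies:
    def test_counts_and_ordering(self):
        assignments = [
            FamilyAssignment(f"p{i}", fam, "A", None, 0.0, True)
            for i, fam in enumerate(["F1", "F1", "F1", "F2", "F2"])
        ]
        table = count_families(assignments)
        assert list(table.family) == ["F1", "F2"]
        assert list(table.members) == [3, 2]
        assert table.members.sum() == 5

    def test_subfamily_counts(self):
        assignments = [
            FamilyAssignment("p1", "F1", "A", None, 0.0, True),
            FamilyAssignment("p2", "F1", "B", None, 0.0, True),
            FamilyAssignment("p3", "F1", "B", None, 0.0, True),
        ]
        table = count_families(assignments)
        assert int(table.loc[0, "subfamilies"]) == 2
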