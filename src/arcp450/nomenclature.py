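"""Family and subfamily assignment under P450 nomenclature identity rules.

The nomenclature convention: sequences with >40% identity share a family,
with >55% identity share a subfamily; below 40% to everything named, a
sequence founds a new family.  Because exactly-40 is left undefined by the
stated rule, this package applies the thresholds inclusively (>= 40, >= 55).

Assignment against a reference set of named P450s (headers like CYP147A1)
inherits family/subfamily from the best hit; sequences placed in no named
family are partitioned de novo by single-linkage clustering at the family
threshold, then lettered into subfamilies at the subfamily threshold.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .errors import ConfigurationError, DuplicateIdError, NamingError
from .identity import AlignParams, IdentityMatrix, pairwise_identity
from .io_formats import ProteinRecord

logger = logging.getLogger(__name__)

_CYP_NAME_RE = re.compile(r"^CYP(\d+)([A-Z]+)(\d+)?$")


@dataclass(frozen=True)
class CypName:
    family: str  # e.g. "CYP147"
    subfamily: str  # e.g. "A"
    member: int | None  # e.g. 1


def parse_cyp_name(label: str) -> CypName:
    """Parse a CYP label like CYP147A1 into (family CYP147, subfamily A, member 1)."""
    m = _CYP_NAME_RE.match(label.strip())
    if not m:
        raise ValueError(f"not a parseable CYP name: {label!r}")
    fam_num, subfam, member = m.groups()
    return CypName(
        family=f"CYP{fam_num}",
        subfamily=subfam,
        member=int(member) if member else None,
    )


@dataclass(frozen=True)
class ReferenceDB:
    """Named P450 reference sequences with parsed CYP labels."""

    records: tuple[ProteinRecord, ...]
    names: Mapping[str, CypName]

    @classmethod
    def from_records(cls, records: Sequence[ProteinRecord]) -> "ReferenceDB":
        names = {}
        for rec in records:
            # the CYP label is the record id, or the first token of it
            names[rec.id] = parse_cyp_name(rec.id.split("|")[0])
        return cls(records=tuple(records), names=names)

    @property
    def family_labels(self) -> set[str]:
        return {n.family for n in self.names.values()}


@dataclass(frozen=True)
class ClassifierParams:
    family_threshold: float = 40.0
    subfamily_threshold: float = 55.0
    novel_family_prefix: str = "CYPN"

    def __post_init__(self) -> None:
        if not (0 < self.family_threshold < self.subfamily_threshold < 100):
            raise ValueError("need 0 < family_threshold < subfamily_threshold < 100")


@dataclass(frozen=True)
class FamilyAssignment:
    protein_id: str
    family: str
    subfamily: str
    best_ref_id: str | None
    best_identity: float
    novel_family: bool
    conflict: bool = False
    member: int | None = None

    @property
    def label(self) -> str:
        if self.member is None:
            return f"{self.family}{self.subfamily}"
        return f"{self.family}{self.subfamily}{self.member}"


def assign_against_reference(
    query: ProteinRecord,
    refdb: ReferenceDB,
    params: ClassifierParams = ClassifierParams(),
    align_params: AlignParams = AlignParams(),
) -> FamilyAssignment:
    """Place one screened P450 against the named reference set.

    Best reference by percent identity decides: >= subfamily threshold
    inherits family and subfamily; >= family threshold inherits the family
    with the subfamily left to de novo lettering; below the family
    threshold the query founds a novel family.  ``conflict`` flags a query
    above the family threshold to references of two different families.
    """
    if not refdb.records:
        raise ConfigurationError("reference database is empty")
    best_id, best_pid = None, -1.0
    families_above = set()
    for ref in refdb.records:
        pid = pairwise_identity(query.sequence, ref.sequence, align_params)
        if pid >= params.family_threshold:
            families_above.add(refdb.names[ref.id].family)
        if pid > best_pid:
            best_id, best_pid = ref.id, pid
    conflict = len(families_above) > 1
    if conflict:
        logger.warning(
            "query %s above family threshold to multiple families: %s",
            query.id, sorted(families_above),
        )
    best_name = refdb.names[best_id]
    if best_pid >= params.subfamily_threshold:
        return FamilyAssignment(
            protein_id=query.id, family=best_name.family, subfamily=best_name.subfamily,
            best_ref_id=best_id, best_identity=best_pid, novel_family=False,
            conflict=conflict,
        )
    if best_pid >= params.family_threshold:
        return FamilyAssignment(
            protein_id=query.id, family=best_name.family, subfamily="",
            best_ref_id=best_id, best_identity=best_pid, novel_family=False,
            conflict=conflict,
        )
    return FamilyAssignment(
        protein_id=query.id, family="", subfamily="",
        best_ref_id=best_id, best_identity=best_pid, novel_family=True,
        conflict=conflict,
    )


def _components_at(
    ids: Sequence[str], matrix: IdentityMatrix, threshold: float
) -> list[list[str]]:
    """Single-linkage connected components of ids at identity >= threshold.

    Components come back sorted by their smallest member id; members sorted
    within each component.
    """
    idx = [matrix.ids.index(i) for i in ids]
    sub = matrix.values[np.ix_(idx, idx)]
    adj = csr_matrix(sub >= threshold)
    _, labels = connected_components(adj, directed=False)
    groups: dict[int, list[str]] = {}
    for id_, lab in zip(ids, labels):
        groups.setdefault(int(lab), []).append(id_)
    comps = [sorted(members) for members in groups.values()]
    comps.sort(key=lambda c: c[0])
    return comps


def cluster_novel_families(
    unassigned_ids: Sequence[str],
    matrix: IdentityMatrix,
    params: ClassifierParams = ClassifierParams(),
) -> list[list[str]]:
    """Partition unplaced sequences into de novo families.

    Single linkage at the family threshold: the nomenclature rule is
    pairwise and transitively applied in practice.  A warning is logged
    when chaining drags a component's minimum internal identity below the
    threshold.
    """
    comps = _components_at(unassigned_ids, matrix, params.family_threshold)
    for comp in comps:
        if len(comp) > 1:
            idx = [matrix.ids.index(i) for i in comp]
            sub = matrix.values[np.ix_(idx, idx)]
            min_internal = sub[~np.eye(len(idx), dtype=bool)].min()
            if min_internal < params.family_threshold:
                logger.warning(
                    "family component %s chained: min internal identity %.1f < %.1f",
                    comp[0], min_internal, params.family_threshold,
                )
    return comps


def cluster_subfamilies(
    family_member_ids: Sequence[str],
    matrix: IdentityMatrix,
    params: ClassifierParams = ClassifierParams(),
) -> list[list[str]]:
    """Partition one family into subfamilies at the subfamily threshold."""
    return _components_at(family_member_ids, matrix, params.subfamily_threshold)


def _subfamily_letters() -> "map":
    # A..Z then AA, AB, ... — matches how nomenclature extends past Z
    import itertools
    import string

    def gen():
        for size in itertools.count(1):
            for combo in itertools.product(string.ascii_uppercase, repeat=size):
                yield "".join(combo)

    return gen()


def name_assignments(
    assignments: Sequence[FamilyAssignment],
    matrix: IdentityMatrix | None,
    params: ClassifierParams = ClassifierParams(),
    reference_family_labels: set[str] | None = None,
) -> list[FamilyAssignment]:
    """Finalize CYP labels: letter subfamilies, number members, name novel families.

    Novel families get ``novel_family_prefix`` + sequential integer in
    deterministic (smallest member id) order.  Raises ``NamingError`` if a
    generated family label collides with a reference family label.
    """
    reference_family_labels = reference_family_labels or set()
    out: dict[str, FamilyAssignment] = {a.protein_id: a for a in assignments}
    if len(out) != len(assignments):
        raise DuplicateIdError("duplicate protein ids in assignments")

    # 1. novel families: cluster all novel sequences de novo
    novel_ids = sorted(a.protein_id for a in assignments if a.novel_family)
    if novel_ids:
        if matrix is None:
            raise ConfigurationError("identity matrix required to name novel families")
        for fam_index, comp in enumerate(
            cluster_novel_families(novel_ids, matrix, params), start=1
        ):
            label = f"{params.novel_family_prefix}{fam_index}"
            if label in reference_family_labels:
                raise NamingError(f"novel family label {label} collides with reference")
            for pid in comp:
                out[pid] = replace(out[pid], family=label)

    # 2. subfamilies: families with members lacking a subfamily are lettered
    by_family: dict[str, list[str]] = {}
    for a in out.values():
        by_family.setdefault(a.family, []).append(a.protein_id)
    for family, members in sorted(by_family.items()):
        unlettered = sorted(pid for pid in members if out[pid].subfamily == "")
        if not unlettered:
            continue
        if matrix is None:
            raise ConfigurationError("identity matrix required to letter subfamilies")
        taken = {out[pid].subfamily for pid in members if out[pid].subfamily}
        letters = (s for s in _subfamily_letters() if s not in taken)
        for comp in cluster_subfamilies(unlettered, matrix, params):
            letter = next(letters)
            for pid in comp:
                out[pid] = replace(out[pid], subfamily=letter)

    # 3. member numbers within each (family, subfamily)
    by_subfamily: dict[tuple[str, str], list[str]] = {}
    for a in out.values():
        by_subfamily.setdefault((a.family, a.subfamily), []).append(a.protein_id)
    for _, members in sorted(by_subfamily.items()):
        for number, pid in enumerate(sorted(members), start=1):
            out[pid] = replace(out[pid], member=number)

    finalized = [out[a.protein_id] for a in assignments]
    labels = [a.label for a in finalized]
    if len(set(labels)) != len(labels):
        raise NamingError("finalized CYP labels are not unique")
    return finalized


def count_families(assignments: Sequence[FamilyAssignment]) -> pd.DataFrame:
    """Family-level member and subfamily counts, sorted by descending members.

    Columns: family, members, subfamilies.  Member counts sum to the number
    of assigned P450s.
    """
    df = pd.DataFrame(
        {
            "family": [a.family for a in assignments],
            "subfamily": [a.subfamily for a in assignments],
        }
    )
    table = (
        df.groupby("family")
        .agg(members=("family", "size"), subfamilies=("subfamily", "nunique"))
        .reset_index()
        .sort_values(["members", "family"], ascending=[False, True], kind="stable")
        .reset_index(drop=True)
    )
    return table
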