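"""Pairwise global alignment and percent identity.

Family and subfamily membership in P450 nomenclature is decided on pairwise
percent identity, but the nomenclature convention does not pin down the
alignment recipe.  This module fixes one, explicitly and configurably:
global alignment with affine gaps (BLOSUM62, gap open 10, gap extend 0.5),
terminal gaps free, and identity computed over scored columns — i.e. the
alignment columns between the first and last column in which both sequences
are present, so terminal overhangs are excluded but internal gaps count.
This is the convention closest to EMBOSS-needle practice in nomenclature
work; every choice is a knob on :class:`AlignParams`.

A gap run of length L costs ``gap_open + gap_extend * L``.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from functools import lru_cache
from itertools import combinations
from typing import Sequence

import numpy as np
from Bio.Align import PairwiseAligner, substitution_matrices

from .errors import DuplicateIdError
from .io_formats import ProteinRecord


class IdentityDenominator(str, Enum):
    SCORED_COLUMNS = "scored_columns"
    SHORTER_SEQ = "shorter_seq"
    ALIGNMENT_LENGTH = "alignment_length"


@dataclass(frozen=True)
class AlignParams:
    substitution_table: str = "BLOSUM62"
    gap_open: float = 10.0
    gap_extend: float = 0.5
    terminal_gaps_free: bool = True
    identity_denominator: IdentityDenominator = IdentityDenominator.SCORED_COLUMNS

    def __post_init__(self) -> None:
        if self.gap_open < 0 or self.gap_extend < 0:
            raise ValueError("gap penalties must be >= 0")


@dataclass(frozen=True)
class AlignmentResult:
    aligned_a: str
    aligned_b: str
    score: float
    n_identical: int
    n_columns_scored: int


@dataclass(frozen=True)
class IdentityMatrix:
    ids: tuple[str, ...]
    values: np.ndarray  # symmetric, percent in [0, 100], diagonal 100

    def loc(self, id_a: str, id_b: str) -> float:
        i, j = self.ids.index(id_a), self.ids.index(id_b)
        return float(self.values[i, j])


@lru_cache(maxsize=8)
def _make_aligner(params: AlignParams) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(params.substitution_table)
    # Biopython scores the first residue of a gap with the open score and the
    # rest with the extend score; fold our open+extend convention into that.
    aligner.open_gap_score = -(params.gap_open + params.gap_extend)
    aligner.extend_gap_score = -params.gap_extend
    if params.terminal_gaps_free:
        aligner.open_end_insertion_score = 0.0
        aligner.extend_end_insertion_score = 0.0
        aligner.open_end_deletion_score = 0.0
        aligner.extend_end_deletion_score = 0.0
    return aligner


def _scored_span(aligned_a: str, aligned_b: str) -> tuple[int, int]:
    """Column range [first, last) in which both sequences are present."""
    first_a = next(i for i, c in enumerate(aligned_a) if c != "-")
    first_b = next(i for i, c in enumerate(aligned_b) if c != "-")
    last_a = max(i for i, c in enumerate(aligned_a) if c != "-") + 1
    last_b = max(i for i, c in enumerate(aligned_b) if c != "-") + 1
    return max(first_a, first_b), min(last_a, last_b)


def global_align(a: str, b: str, params: AlignParams = AlignParams()) -> AlignmentResult:
    """Optimal global alignment of two protein sequences.

    Raises ``ValueError`` on an empty sequence.  When several alignments are
    optimal, the aligner's canonical traceback yields a deterministic one.
    """
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    aligner = _make_aligner(params)
    aln = aligner.align(a, b)[0]
    aligned_a, aligned_b = str(aln[0]), str(aln[1])
    lo, hi = _scored_span(aligned_a, aligned_b)
    n_identical = sum(
        1
        for x, y in zip(aligned_a, aligned_b)
        if x == y and x != "-"
    )
    return AlignmentResult(
        aligned_a=aligned_a,
        aligned_b=aligned_b,
        score=float(aln.score),
        n_identical=n_identical,
        n_columns_scored=hi - lo,
    )


def percent_identity(alignment: AlignmentResult, params: AlignParams = AlignParams()) -> float:
    """Percent identity of an alignment, to 0.1 precision.

    The denominator is configurable; the default counts scored columns
    (terminal overhangs excluded, internal gap columns included).
    """
    denom_kind = params.identity_denominator
    if denom_kind is IdentityDenominator.SCORED_COLUMNS:
        denominator = alignment.n_columns_scored
    elif denom_kind is IdentityDenominator.SHORTER_SEQ:
        denominator = min(
            len(alignment.aligned_a.replace("-", "")),
            len(alignment.aligned_b.replace("-", "")),
        )
    else:
        denominator = len(alignment.aligned_a)
    if denominator == 0:
        raise ValueError("identity denominator is zero")
    return round(100.0 * alignment.n_identical / denominator, 1)


def pairwise_identity(a: str, b: str, params: AlignParams = AlignParams()) -> float:
    """Convenience: align and report percent identity in one call."""
    return percent_identity(global_align(a, b, params), params)


def identity_matrix(
    records: Sequence[ProteinRecord], params: AlignParams = AlignParams()
) -> IdentityMatrix:
    """All-vs-all percent identity; each unordered pair aligned once."""
    if len(records) < 2:
        raise ValueError("need at least 2 records")
    ids = tuple(r.id for r in records)
    if len(set(ids)) != len(ids):
        raise DuplicateIdError("duplicate protein ids in identity matrix input")
    n = len(records)
    values = np.full((n, n), 100.0)
    for i, j in combinations(range(n), 2):
        pid = pairwise_identity(records[i].sequence, records[j].sequence, params)
        values[i, j] = values[j, i] = pid
    return IdentityMatrix(ids=ids, values=values)
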