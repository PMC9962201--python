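"""Motif-based detection of cytochrome P450 candidates and fragment filtering.

Two short signatures identify a P450 fold from primary sequence alone: the
ExxR tetrad of the K-helix and the CxG tripeptide around the heme-ligating
cysteine near the C-terminus.  A candidate carrying both signatures at full
length (>= 350 aa by default) is a classifiable P450; a candidate failing
any condition is a fragment and is excluded from family assignment.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

from .io_formats import ProteinRecord


class MotifName(str, Enum):
    EXXR = "EXXR"
    CXG = "CXG"


class P450Status(str, Enum):
    FULL_LENGTH = "full_length"
    FRAGMENT = "fragment"
    NOT_P450 = "not_p450"


@dataclass(frozen=True)
class MotifHit:
    motif_name: MotifName
    start: int  # 0-based position in the protein
    matched: str


@dataclass(frozen=True)
class ScreenParams:
    """Knobs of the motif screen.

    min_length
        Full-length cut in amino acids; shorter candidates are fragments.
    cxg_search_region
        Fraction of the sequence, anchored at the C-terminus, in which the
        heme-ligating CxG is accepted (it sits near the C-terminus in real
        P450s; 0.4 keeps the default permissive).
    require_order
        When true, some ExxR hit must precede some CxG hit.
    """

    min_length: int = 350
    exxr_pattern: str = "E..R"
    cxg_pattern: str = "C.G"
    cxg_search_region: float = 0.4
    require_order: bool = True

    def __post_init__(self) -> None:
        if self.min_length <= 0:
            raise ValueError("min_length must be positive")
        if not (0 < self.cxg_search_region <= 1):
            raise ValueError("cxg_search_region must be in (0, 1]")


@dataclass(frozen=True)
class P450Call:
    protein_id: str
    status: P450Status
    motif_hits: tuple[MotifHit, ...]
    length: int
    reasons: tuple[str, ...] = ()


@dataclass(frozen=True)
class ScreenReport:
    calls: tuple[P450Call, ...]
    summary: dict[P450Status, int]

    def full_length_ids(self) -> list[str]:
        return [c.protein_id for c in self.calls if c.status is P450Status.FULL_LENGTH]


def _find_all(pattern: str, sequence: str, region_start: int = 0) -> list[tuple[int, str]]:
    """All (possibly overlapping) matches at positions >= region_start."""
    out = []
    for m in re.finditer(f"(?=({pattern}))", sequence):
        if m.start() >= region_start:
            out.append((m.start(), m.group(1)))
    return out


def scan_p450_motifs(sequence: str, params: ScreenParams = ScreenParams()) -> list[MotifHit]:
    """Find all ExxR hits anywhere and all CxG hits in the C-terminal region.

    Overlapping occurrences are all reported; hits come back sorted by
    position.  An empty list is a valid result.
    """
    if not sequence:
        raise ValueError("sequence must be non-empty")
    cxg_region_start = int(len(sequence) * (1 - params.cxg_search_region))
    hits = [
        MotifHit(MotifName.EXXR, pos, matched)
        for pos, matched in _find_all(params.exxr_pattern, sequence)
    ]
    hits += [
        MotifHit(MotifName.CXG, pos, matched)
        for pos, matched in _find_all(params.cxg_pattern, sequence, cxg_region_start)
    ]
    hits.sort(key=lambda h: (h.start, h.motif_name.value))
    return hits


def classify_p450(
    record: ProteinRecord,
    params: ScreenParams = ScreenParams(),
    is_candidate: bool = False,
) -> P450Call:
    """Apply the motif and length rules to one protein.

    ``full_length``: both motifs present (in order, when required) and
    length >= ``min_length``.  ``fragment``: motif evidence exists (or the
    record was pre-flagged as a short P450 candidate) but a condition fails.
    ``not_p450``: no motif evidence and not pre-flagged.
    """
    hits = scan_p450_motifs(record.sequence, params)
    exxr = [h for h in hits if h.motif_name is MotifName.EXXR]
    cxg = [h for h in hits if h.motif_name is MotifName.CXG]
    reasons: list[str] = []
    if not exxr:
        reasons.append("missing EXXR")
    if not cxg:
        reasons.append("missing CXG")
    if exxr and cxg and params.require_order:
        if min(h.start for h in exxr) >= max(h.start for h in cxg):
            reasons.append("EXXR does not precede CXG")
    if len(record) < params.min_length:
        reasons.append(f"length<{params.min_length}")

    if not reasons:
        status = P450Status.FULL_LENGTH
        reasons_out: tuple[str, ...] = ()
    elif exxr or cxg:
        status = P450Status.FRAGMENT
        reasons_out = tuple(reasons)
    elif is_candidate and len(record) < params.min_length:
        # pre-selected candidates with no motifs and a short sequence still
        # count as P450 fragments
        status = P450Status.FRAGMENT
        reasons_out = tuple(reasons)
    else:
        status = P450Status.NOT_P450
        reasons_out = tuple(reasons)
    return P450Call(
        protein_id=record.id,
        status=status,
        motif_hits=tuple(hits),
        length=len(record),
        reasons=reasons_out,
    )


def screen_proteome(
    records: Sequence[ProteinRecord],
    params: ScreenParams = ScreenParams(),
    candidates: Iterable[str] | None = None,
) -> ScreenReport:
    """Screen a whole proteome; per-record calls plus summary counts.

    ``candidates`` optionally restricts motif-free short proteins that still
    count as fragments (mimicking an upstream domain-based candidate list).
    The three summary counts always sum to the number of inputs.
    """
    if not records:
        raise ValueError("records must be non-empty")
    candidate_set = set(candidates) if candidates is not None else set()
    calls = tuple(
        classify_p450(r, params, is_candidate=r.id in candidate_set) for r in records
    )
    counts = Counter(c.status for c in calls)
    summary = {status: counts.get(status, 0) for status in P450Status}
    return ScreenReport(calls=calls, summary=summary)
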