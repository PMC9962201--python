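"""Ferredoxin Fe-S cluster typing by cysteine-spacing grammars, plus OFOR detection.

Ferredoxins ligate their iron-sulfur clusters through cysteines whose
spacing along the sequence is characteristic of the cluster type: a
bacterial-type 4Fe-4S motif reads C-x2-C-x2-C-...-C, a plant/adrenodoxin
2Fe-2S motif C-x4-6-C-x2-C-...-C, and a 3Fe-4S motif lacks the second
cysteine of the 4Fe-4S arrangement.  Composite proteins carrying two motifs
form the 7Fe-8S (one 3Fe-4S + one 4Fe-4S) and 2[4Fe-4S] (two 4Fe-4S)
types; the Alvin-type variant of the latter is recognised here by the long
extended loop before the final cysteine of its second cluster motif.

The exact spacing windows are deliberately a declarative, user-editable
rule table (:class:`FeSRules`); the defaults encode the canonical grammars
above.  Subtype identity is the ordered spacing signature itself, e.g.
``C-2-C-2-C-4-C``; a registry maps signatures to stable subtype numbers and
can be seeded from a legacy numbering table.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .errors import ConfigurationError
from .io_formats import GeneFeature, ProteinRecord

SIGNATURE_RE = re.compile(r"^C(-\d+-C)+$")


class ClusterClass(str, Enum):
    CLUSTER_2FE2S = "2Fe-2S"
    CLUSTER_3FE4S = "3Fe-4S"
    CLUSTER_4FE4S = "4Fe-4S"


class FdxType(str, Enum):
    FDX_2FE2S = "2Fe-2S"
    FDX_3FE4S = "3Fe-4S"
    FDX_4FE4S = "4Fe-4S"
    FDX_7FE8S = "7Fe-8S"
    FDX_2X4FE4S = "2[4Fe-4S]"
    FDX_2X4FE4S_ALV = "2[4Fe-4S]Alv"
    UNCLASSIFIED = "unclassified"


def serialize_signature(spacings: Sequence[int]) -> str:
    return "C-" + "-C-".join(str(s) for s in spacings) + "-C"


def parse_signature(signature: str) -> tuple[int, ...]:
    if not SIGNATURE_RE.match(signature):
        raise ValueError(f"malformed spacing signature: {signature!r}")
    return tuple(int(tok) for tok in signature.split("-") if tok.isdigit())


@dataclass(frozen=True)
class FeSMotif:
    cys_positions: tuple[int, ...]  # 0-based
    cluster_class: ClusterClass

    @property
    def spacings(self) -> tuple[int, ...]:
        return tuple(
            b - a - 1 for a, b in zip(self.cys_positions, self.cys_positions[1:])
        )

    @property
    def signature(self) -> str:
        return serialize_signature(self.spacings)


@dataclass(frozen=True)
class MotifRule:
    cluster_class: ClusterClass
    spacing_ranges: tuple[tuple[int, int], ...]  # (lo, hi) per inter-cysteine gap

    @property
    def n_cys(self) -> int:
        return len(self.spacing_ranges) + 1

    def admits(self, spacings: Sequence[int]) -> bool:
        return len(spacings) == len(self.spacing_ranges) and all(
            lo <= s <= hi for s, (lo, hi) in zip(spacings, self.spacing_ranges)
        )


#: default grammar; order = matching priority (most specific first)
DEFAULT_RULES: tuple[MotifRule, ...] = (
    MotifRule(ClusterClass.CLUSTER_2FE2S, ((4, 6), (2, 2), (20, 40))),
    MotifRule(ClusterClass.CLUSTER_4FE4S, ((2, 2), (2, 2), (3, 40))),
    MotifRule(ClusterClass.CLUSTER_3FE4S, ((2, 8), (3, 40))),
)


@dataclass(frozen=True)
class FeSRules:
    rules: tuple[MotifRule, ...] = DEFAULT_RULES
    #: a second 4Fe-4S motif whose final spacing reaches this marks the
    #: Alvin-type extended loop
    alv_min_final_spacing: int = 15

    def __post_init__(self) -> None:
        for rule in self.rules:
            for lo, hi in rule.spacing_ranges:
                if not (0 <= lo <= hi):
                    raise ConfigurationError(
                        f"rule {rule.cluster_class.value}: bad spacing range ({lo},{hi})"
                    )
            if rule.n_cys < 2:
                raise ConfigurationError("motif rules need at least 2 cysteines")


@dataclass(frozen=True)
class FerredoxinCall:
    protein_id: str
    fdx_type: FdxType
    motifs: tuple[FeSMotif, ...]
    subtype_id: str = ""

    @property
    def signature_key(self) -> str:
        """Registry key: ordered motif signatures joined with '+'."""
        return "+".join(m.signature for m in self.motifs)


def _match_rule_at(
    rule: MotifRule, cys_positions: Sequence[int], start_index: int
) -> tuple[int, ...] | None:
    """Greedily match one rule starting at cys_positions[start_index].

    For each spacing window the nearest following cysteine whose gap falls
    inside the window is taken; cysteines closer than the window minimum are
    skipped (they would break the grammar, not serve as ligands).
    """
    chosen = [cys_positions[start_index]]
    search_from = start_index + 1
    for lo, hi in rule.spacing_ranges:
        current = chosen[-1]
        picked = None
        for k in range(search_from, len(cys_positions)):
            gap = cys_positions[k] - current - 1
            if gap > hi:
                break
            if gap >= lo:
                picked = k
                break
        if picked is None:
            return None
        chosen.append(cys_positions[picked])
        search_from = picked + 1
    return tuple(chosen)


def scan_fes_motifs(sequence: str, rules: FeSRules = FeSRules()) -> list[FeSMotif]:
    """Find non-overlapping Fe-S cluster motifs, left to right, greedily.

    At each unconsumed cysteine the rule classes are tried in priority
    order; on a match the motif's cysteines are consumed and scanning
    resumes after the motif.  Deterministic by construction.
    """
    if not sequence:
        raise ValueError("sequence must be non-empty")
    cys_positions = [i for i, ch in enumerate(sequence) if ch == "C"]
    motifs: list[FeSMotif] = []
    i = 0
    while i < len(cys_positions):
        matched = None
        for rule in rules.rules:
            positions = _match_rule_at(rule, cys_positions, i)
            if positions is not None:
                matched = FeSMotif(cys_positions=positions, cluster_class=rule.cluster_class)
                break
        if matched is None:
            i += 1
            continue
        motifs.append(matched)
        last = matched.cys_positions[-1]
        while i < len(cys_positions) and cys_positions[i] <= last:
            i += 1
    return motifs


def assign_fdx_type(
    protein_id: str, motifs: Sequence[FeSMotif], rules: FeSRules = FeSRules()
) -> FerredoxinCall:
    """Resolve motifs into one ferredoxin type.

    Composite types first: two 4Fe-4S motifs make 2[4Fe-4S] (Alvin-type
    when the second motif's final spacing shows the extended loop); one
    3Fe-4S plus one 4Fe-4S make 7Fe-8S.  A single motif gives its own
    class; no motif, or an arrangement outside the grammar, is unclassified.
    """
    motifs = tuple(motifs)
    classes = [m.cluster_class for m in motifs]
    if len(motifs) == 2 and classes == [ClusterClass.CLUSTER_4FE4S] * 2:
        final_spacing = motifs[1].spacings[-1]
        fdx_type = (
            FdxType.FDX_2X4FE4S_ALV
            if final_spacing >= rules.alv_min_final_spacing
            else FdxType.FDX_2X4FE4S
        )
        return FerredoxinCall(protein_id, fdx_type, motifs)
    if len(motifs) == 2 and set(classes) == {
        ClusterClass.CLUSTER_3FE4S,
        ClusterClass.CLUSTER_4FE4S,
    }:
        return FerredoxinCall(protein_id, FdxType.FDX_7FE8S, motifs)
    if len(motifs) == 1:
        single = {
            ClusterClass.CLUSTER_2FE2S: FdxType.FDX_2FE2S,
            ClusterClass.CLUSTER_3FE4S: FdxType.FDX_3FE4S,
            ClusterClass.CLUSTER_4FE4S: FdxType.FDX_4FE4S,
        }[classes[0]]
        return FerredoxinCall(protein_id, single, motifs)
    return FerredoxinCall(protein_id, FdxType.UNCLASSIFIED, motifs)


class SubtypeRegistry:
    """Stable mapping (fdx_type, spacing signature) -> subtype number.

    Novel signatures receive the next sequential number for their type, so
    numbering can continue an existing published series when the registry
    is seeded from a legacy table.
    """

    def __init__(self, entries: Mapping[tuple[str, str], int] | None = None) -> None:
        self._map: dict[tuple[str, str], int] = dict(entries or {})

    def _next_id(self, fdx_type: str) -> int:
        existing = [n for (t, _), n in self._map.items() if t == fdx_type]
        return max(existing, default=0) + 1

    def get_or_assign(self, call: FerredoxinCall) -> int:
        if call.fdx_type is FdxType.UNCLASSIFIED:
            raise ValueError("cannot assign a subtype to an unclassified ferredoxin")
        key = (call.fdx_type.value, call.signature_key)
        if key not in self._map:
            self._map[key] = self._next_id(call.fdx_type.value)
        return self._map[key]

    def __len__(self) -> int:
        return len(self._map)

    def items(self):
        return sorted(self._map.items())

    @classmethod
    def load(cls, path: str | Path) -> "SubtypeRegistry":
        entries: dict[tuple[str, str], int] = {}
        with open(path, newline="") as fh:
            reader = csv.DictReader(fh, delimiter="\t")
            for row in reader:
                entries[(row["fdx_type"], row["signature"])] = int(row["subtype_id"])
        return cls(entries)

    def save(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
            writer.writerow(["fdx_type", "signature", "subtype_id"])
            for (fdx_type, signature), number in self.items():
                writer.writerow([fdx_type, signature, number])


def assign_subtype(call: FerredoxinCall, registry: SubtypeRegistry) -> FerredoxinCall:
    """Attach the registry subtype number to a typed ferredoxin call."""
    number = registry.get_or_assign(call)
    return FerredoxinCall(
        protein_id=call.protein_id,
        fdx_type=call.fdx_type,
        motifs=call.motifs,
        subtype_id=f"{call.fdx_type.value}ST{number}",
    )


class OFORSubunit(str, Enum):
    ALPHA = "alpha"
    BETA = "beta"


@dataclass(frozen=True)
class OFORKeywords:
    """Annotation-keyword rules for OFOR subunit detection."""

    base_pattern: str = r"(2-?oxoacid.{0,3})?ferredoxin\s+oxidoreductase"
    alpha_pattern: str = r"\balpha\b"
    beta_pattern: str = r"\bbeta\b"


@dataclass(frozen=True)
class OFORCall:
    protein_id: str
    subunit: OFORSubunit
    partner_protein_id: str | None = None
    adjacent: bool = False


def find_ofor(
    records: Sequence[ProteinRecord],
    features: Sequence[GeneFeature] = (),
    keyword_rules: OFORKeywords = OFORKeywords(),
    max_gene_gap: int = 1,
) -> list[OFORCall]:
    """Detect OFOR alpha/beta subunits from annotation text; flag adjacency.

    A subunit is 'adjacent' when a subunit of the other kind lies within
    ``max_gene_gap`` gene positions on the same replicon (gene order taken
    from the features' start coordinates).
    """
    base_re = re.compile(keyword_rules.base_pattern, re.IGNORECASE)
    alpha_re = re.compile(keyword_rules.alpha_pattern, re.IGNORECASE)
    beta_re = re.compile(keyword_rules.beta_pattern, re.IGNORECASE)

    subunits: dict[str, OFORSubunit] = {}
    for rec in records:
        if not base_re.search(rec.description):
            continue
        if alpha_re.search(rec.description):
            subunits[rec.id] = OFORSubunit.ALPHA
        elif beta_re.search(rec.description):
            subunits[rec.id] = OFORSubunit.BETA

    # gene rank per replicon
    rank: dict[str, tuple[str, int]] = {}
    by_replicon: dict[str, list[GeneFeature]] = {}
    for f in features:
        by_replicon.setdefault(f.replicon_id, []).append(f)
    for replicon_id, feats in by_replicon.items():
        for i, f in enumerate(sorted(feats, key=lambda f: f.start)):
            rank[f.protein_id] = (replicon_id, i)

    calls = []
    for pid in sorted(subunits):
        subunit = subunits[pid]
        partner, adjacent = None, False
        if pid in rank:
            replicon_id, pos = rank[pid]
            best_gap = None
            for other, other_subunit in subunits.items():
                if other == pid or other_subunit is subunit or other not in rank:
                    continue
                other_replicon, other_pos = rank[other]
                gap = abs(other_pos - pos)
                if other_replicon == replicon_id and gap <= max_gene_gap:
                    if best_gap is None or gap < best_gap:
                        partner, adjacent, best_gap = other, True, gap
        calls.append(OFORCall(pid, subunit, partner, adjacent))
    return calls
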