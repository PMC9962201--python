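"""Synthetic study generator with exact ground truth for every pipeline stage.

The generator emulates the shape of a multi-species archaeal input corpus:
per-replicon proteomes containing P450 families planted at controlled
identity bands (with intact ExxR/CxG motifs), truncated P450 fragments,
ferredoxins built residue-by-residue from stated cysteine-spacing
signatures, OFOR alpha/beta annotation pairs, motif-free decoys, and gene
layouts with known operon structure on chromosomes and plasmids.

Identity bands are achieved by rejection sampling on *measured* identity —
the identity module itself is the oracle — rather than by analytic
mutation-rate formulas; exactness matters more than speed at desk scale.
All randomness flows from a single integer seed through one generator.

Deliberately not emulated: phylogenetically realistic evolution (no
substitution model, no indel process within families), codon-level DNA,
and annotation noise.  Tests passing on this material show the pipeline's
rules are applied exactly, not that the rules themselves are complete for
real proteomes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import GenerationError
from .ferredoxin import (
    ClusterClass,
    FdxType,
    FeSRules,
    MotifRule,
    parse_signature,
)
from .identity import AlignParams, pairwise_identity
from .io_formats import (
    GeneFeature,
    ProteinRecord,
    RepliconMeta,
    RepliconType,
    Strand,
    write_fasta,
    write_gff3,
    write_replicon_table,
)
from .p450_screen import P450Status, ScreenParams, classify_p450

AA20 = "ACDEFGHIKLMNPQRSTVWY"
#: decoys can contain neither an ExxR (no R) nor a CxG or Fe-S motif (no C)
DECOY_ALPHABET = "".join(c for c in AA20 if c not in "CR")
#: ferredoxin backgrounds carry cysteines only at planted motif positions and
#: can form neither P450 motif (no C outside motifs, no G for CxG, no R for ExxR)
NO_CYS_ALPHABET = "".join(c for c in AA20 if c not in "CGR")


def random_sequence(rng: np.random.Generator, length: int, alphabet: str = AA20) -> str:
    return "".join(rng.choice(list(alphabet), size=length))


# ---------------------------------------------------------------------------
# P450 generation


@dataclass(frozen=True)
class P450FamilySpec:
    """One planted family: a seed sequence theme plus member placements."""

    name: str
    n_members: int
    identity_band: tuple[float, float] = (75.0, 85.0)  # member vs family seed
    length: int = 420
    n_fragments: int = 0
    fragment_length: int = 300
    #: (species, replicon_id) per member, cycled if shorter than n_members
    placements: tuple[tuple[str, str], ...] = ()

    def __post_init__(self) -> None:
        lo, hi = self.identity_band
        if not (0 < lo <= hi <= 100):
            raise GenerationError(f"family {self.name}: bad identity band {self.identity_band}")
        if self.n_members < 1:
            raise GenerationError(f"family {self.name}: need >= 1 member")


#: fixed relative positions for the planted motifs (EALR instantiates ExxR,
#: CIG instantiates CxG inside the C-terminal 40%)
EXXR_OFFSET = 150
CXG_OFFSET_FROM_END = 60


def _p450_seed_sequence(rng: np.random.Generator, length: int) -> tuple[str, frozenset[int]]:
    if length < EXXR_OFFSET + CXG_OFFSET_FROM_END + 10:
        raise GenerationError(f"P450 length {length} too short to plant motifs")
    seq = list(random_sequence(rng, length))
    cxg_start = length - CXG_OFFSET_FROM_END
    seq[EXXR_OFFSET:EXXR_OFFSET + 4] = "EALR"
    seq[cxg_start:cxg_start + 3] = "CIG"
    protected = frozenset(range(EXXR_OFFSET, EXXR_OFFSET + 4)) | frozenset(
        range(cxg_start, cxg_start + 3)
    )
    return "".join(seq), protected


def mutate_to_identity(
    seed_sequence: str,
    target_band: tuple[float, float],
    protected_positions: frozenset[int] | set[int],
    rng: np.random.Generator,
    align_params: AlignParams = AlignParams(),
    max_tries: int = 40,
) -> str:
    """Substitute residues until measured identity to the seed is in the band.

    Protected positions are never touched.  The returned sequence's percent
    identity to the seed (as the identity module measures it) lies within
    the band widened by 2 points either side; substitution counts are
    adjusted between attempts.  Same rng state -> same output.
    """
    lo, hi = target_band
    length = len(seed_sequence)
    if lo >= 100.0:
        return seed_sequence
    free = np.array(sorted(set(range(length)) - set(protected_positions)))
    target = (lo + hi) / 2.0
    n_mut = int(round((1 - target / 100.0) * length))
    if n_mut > len(free):
        raise GenerationError("identity band unreachable with protected positions")
    for _ in range(max_tries):
        n_mut = min(max(n_mut, 1), len(free))
        positions = rng.choice(free, size=n_mut, replace=False)
        mutant = list(seed_sequence)
        for pos in positions:
            original = mutant[pos]
            choices = [c for c in AA20 if c != original]
            mutant[pos] = choices[rng.integers(len(choices))]
        candidate = "".join(mutant)
        pid = pairwise_identity(seed_sequence, candidate, align_params)
        if lo - 2.0 <= pid <= hi + 2.0:
            return candidate
        n_mut += max(1, int(abs(pid - target) / 100.0 * length)) * (1 if pid > target else -1)
    raise GenerationError(
        f"could not hit identity band {target_band} in {max_tries} attempts"
    )


@dataclass(frozen=True)
class P450FamilyTruth:
    family: str
    member_ids: tuple[str, ...]
    fragment_ids: tuple[str, ...]
    seed_sequence: str


def generate_p450_family(
    spec: P450FamilySpec,
    rng: np.random.Generator,
    previous_seeds: Sequence[str] = (),
    max_cross_identity: float = 35.0,
    align_params: AlignParams = AlignParams(),
    screen_params: ScreenParams = ScreenParams(),
    max_tries: int = 20,
) -> tuple[list[ProteinRecord], P450FamilyTruth]:
    """Generate one P450 family: members in-band, fragments truncated.

    The family seed is re-drawn until it sits below ``max_cross_identity``
    to every previously generated family seed.  Every member is verified to
    pass the motif screen as full-length; fragments are verified to screen
    as fragments.
    """
    seed_seq = None
    protected: frozenset[int] = frozenset()
    for _ in range(max_tries):
        candidate, protected = _p450_seed_sequence(rng, spec.length)
        if all(
            pairwise_identity(candidate, prev, align_params) <= max_cross_identity
            for prev in previous_seeds
        ):
            seed_seq = candidate
            break
    if seed_seq is None:
        raise GenerationError(
            f"family {spec.name}: cannot place seed below {max_cross_identity}% "
            "to previous families"
        )

    records: list[ProteinRecord] = []
    member_ids, fragment_ids = [], []
    for i in range(spec.n_members):
        seq = mutate_to_identity(seed_seq, spec.identity_band, protected, rng, align_params)
        pid = f"{spec.name}_m{i + 1}"
        rec = ProteinRecord(id=pid, sequence=seq, description="cytochrome P450")
        call = classify_p450(rec, screen_params)
        if call.status is not P450Status.FULL_LENGTH:
            raise GenerationError(f"{pid}: generated member fails screen: {call.reasons}")
        records.append(rec)
        member_ids.append(pid)
    for i in range(spec.n_fragments):
        seq = mutate_to_identity(seed_seq, spec.identity_band, protected, rng, align_params)
        frag_seq = seq[: spec.fragment_length]
        pid = f"{spec.name}_frag{i + 1}"
        rec = ProteinRecord(id=pid, sequence=frag_seq, description="cytochrome P450 fragment")
        call = classify_p450(rec, screen_params)
        if call.status is not P450Status.FRAGMENT:
            raise GenerationError(f"{pid}: truncated member does not screen as fragment")
        records.append(rec)
        fragment_ids.append(pid)
    truth = P450FamilyTruth(
        family=spec.name,
        member_ids=tuple(member_ids),
        fragment_ids=tuple(fragment_ids),
        seed_sequence=seed_seq,
    )
    return records, truth


# ---------------------------------------------------------------------------
# Ferredoxin generation

#: which motif classes, in order, compose each ferredoxin type
_TYPE_COMPOSITION: dict[FdxType, tuple[ClusterClass, ...]] = {
    FdxType.FDX_2FE2S: (ClusterClass.CLUSTER_2FE2S,),
    FdxType.FDX_3FE4S: (ClusterClass.CLUSTER_3FE4S,),
    FdxType.FDX_4FE4S: (ClusterClass.CLUSTER_4FE4S,),
    FdxType.FDX_7FE8S: (ClusterClass.CLUSTER_3FE4S, ClusterClass.CLUSTER_4FE4S),
    FdxType.FDX_2X4FE4S: (ClusterClass.CLUSTER_4FE4S, ClusterClass.CLUSTER_4FE4S),
    FdxType.FDX_2X4FE4S_ALV: (ClusterClass.CLUSTER_4FE4S, ClusterClass.CLUSTER_4FE4S),
}


def _rule_for(rules: FeSRules, cluster_class: ClusterClass) -> MotifRule:
    for rule in rules.rules:
        if rule.cluster_class is cluster_class:
            return rule
    raise ValueError(f"no rule for cluster class {cluster_class.value}")


def generate_ferredoxin(
    fdx_type: FdxType,
    signatures: Sequence[str],
    rng: np.random.Generator,
    protein_id: str = "fdx",
    rules: FeSRules = FeSRules(),
) -> ProteinRecord:
    """Build a ferredoxin whose scan recovers exactly the stated signatures.

    Each signature must conform to the rule of its motif class; for the
    Alvin-type 2[4Fe-4S] the second signature's final spacing must reach
    the configured extended-loop minimum (and stay below it for the plain
    type).  Raises ``ValueError`` on non-conforming signatures.
    """
    composition = _TYPE_COMPOSITION.get(fdx_type)
    if composition is None:
        raise ValueError(f"cannot generate type {fdx_type.value}")
    if len(signatures) != len(composition):
        raise ValueError(
            f"{fdx_type.value} needs {len(composition)} signature(s), got {len(signatures)}"
        )
    spacing_lists = [parse_signature(sig) for sig in signatures]
    for spacings, cluster_class in zip(spacing_lists, composition):
        rule = _rule_for(rules, cluster_class)
        if not rule.admits(spacings):
            raise ValueError(
                f"signature {serialize(spacings)} outside {cluster_class.value} rule"
            )
    if fdx_type is FdxType.FDX_2X4FE4S and spacing_lists[1][-1] >= rules.alv_min_final_spacing:
        raise ValueError("plain 2[4Fe-4S] requires a short final spacing in motif 2")
    if fdx_type is FdxType.FDX_2X4FE4S_ALV and spacing_lists[1][-1] < rules.alv_min_final_spacing:
        raise ValueError("Alvin-type requires an extended final spacing in motif 2")

    parts = [random_sequence(rng, int(rng.integers(3, 15)), NO_CYS_ALPHABET)]
    for m, spacings in enumerate(spacing_lists):
        if m > 0:
            parts.append(random_sequence(rng, int(rng.integers(10, 16)), NO_CYS_ALPHABET))
        motif = ["C"]
        for gap in spacings:
            motif.append(random_sequence(rng, gap, NO_CYS_ALPHABET))
            motif.append("C")
        parts.append("".join(motif))
    parts.append(random_sequence(rng, int(rng.integers(5, 20)), NO_CYS_ALPHABET))
    return ProteinRecord(
        id=protein_id, sequence="".join(parts), description="ferredoxin"
    )


def serialize(spacings: Sequence[int]) -> str:
    from .ferredoxin import serialize_signature

    return serialize_signature(spacings)


#: one representative signature set per type, conforming to DEFAULT_RULES
DEFAULT_SIGNATURES: dict[FdxType, tuple[str, ...]] = {
    FdxType.FDX_2FE2S: ("C-5-C-2-C-29-C",),
    FdxType.FDX_3FE4S: ("C-5-C-28-C",),
    FdxType.FDX_4FE4S: ("C-2-C-2-C-28-C",),
    FdxType.FDX_7FE8S: ("C-7-C-15-C", "C-2-C-2-C-10-C"),
    FdxType.FDX_2X4FE4S: ("C-2-C-2-C-3-C", "C-2-C-2-C-9-C"),
    FdxType.FDX_2X4FE4S_ALV: ("C-2-C-2-C-3-C", "C-2-C-2-C-21-C"),
}


# ---------------------------------------------------------------------------
# Whole-study generation


@dataclass(frozen=True)
class RepliconSpec:
    replicon_id: str
    replicon_type: RepliconType
    accession: str = ""


@dataclass(frozen=True)
class SpeciesSpec:
    name: str
    replicons: tuple[RepliconSpec, ...]


@dataclass(frozen=True)
class FerredoxinPlacement:
    fdx_type: FdxType
    signatures: tuple[str, ...]
    species: str
    replicon_id: str
    count: int = 1


@dataclass(frozen=True)
class OFORPairSpec:
    species: str
    alpha_replicon_id: str
    beta_replicon_id: str  # same replicon -> genes placed adjacently


@dataclass(frozen=True)
class StudySpec:
    seed: int
    species: tuple[SpeciesSpec, ...]
    families: tuple[P450FamilySpec, ...]
    ferredoxins: tuple[FerredoxinPlacement, ...] = ()
    ofor_pairs: tuple[OFORPairSpec, ...] = ()
    decoys_per_replicon: int = 3
    #: place the first ferredoxin of this replicon into the same operon as a
    #: P450, to exercise the redox-partner-in-operon context flag
    p450_fdx_operon_replicon: str | None = None
    #: intra-operon and inter-operon intergenic gaps (bp)
    operon_gap_bp: tuple[int, int] = (20, 120)
    spacer_gap_bp: tuple[int, int] = (400, 1200)


@dataclass(frozen=True)
class GroundTruth:
    """Per-protein planted roles and structures, covering every protein once."""

    roles: dict[str, str]  # p450_full | p450_fragment | ferredoxin | ofor_alpha | ofor_beta | decoy
    family_of: dict[str, str]  # full-length P450s -> planted family
    fdx_type_of: dict[str, str]
    fdx_signature_of: dict[str, str]
    species_of: dict[str, str]
    replicon_of: dict[str, str]
    operon_blocks: tuple[tuple[str, ...], ...]  # gene ids planted as one operon


@dataclass(frozen=True)
class StudyData:
    spec: StudySpec
    records: tuple[ProteinRecord, ...]
    features: tuple[GeneFeature, ...]
    replicon_meta: tuple[RepliconMeta, ...]
    truth: GroundTruth

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "fasta": out / "proteins.fasta",
            "gff": out / "genes.gff3",
            "replicons": out / "replicons.tsv",
            "truth": out / "truth.tsv",
        }
        write_fasta(self.records, paths["fasta"])
        write_gff3(self.features, paths["gff"])
        write_replicon_table(self.replicon_meta, paths["replicons"])
        with open(paths["truth"], "w") as fh:
            fh.write("protein_id\trole\tfamily\tfdx_type\tfdx_signature\tspecies\treplicon_id\n")
            for pid in sorted(self.truth.roles):
                fh.write(
                    "\t".join(
                        [
                            pid,
                            self.truth.roles[pid],
                            self.truth.family_of.get(pid, ""),
                            self.truth.fdx_type_of.get(pid, ""),
                            self.truth.fdx_signature_of.get(pid, ""),
                            self.truth.species_of[pid],
                            self.truth.replicon_of[pid],
                        ]
                    )
                    + "\n"
                )
        return paths


def generate_study(spec: StudySpec) -> StudyData:
    """Generate a full synthetic study from one spec, deterministically.

    All proteins are assigned to replicons, genes are laid out left to
    right with planted operon blocks (linked genes share a strand and sit
    within small gaps; blocks are separated by large gaps), and every
    planted element is recorded in the ground truth exactly once.
    """
    rng = np.random.default_rng(spec.seed)
    valid_replicons = {
        (sp.name, r.replicon_id) for sp in spec.species for r in sp.replicons
    }

    records: list[ProteinRecord] = []
    roles: dict[str, str] = {}
    family_of: dict[str, str] = {}
    fdx_type_of: dict[str, str] = {}
    fdx_signature_of: dict[str, str] = {}
    species_of: dict[str, str] = {}
    replicon_of: dict[str, str] = {}
    #: per replicon: list of blocks; each block is a list of protein ids
    layout: dict[tuple[str, str], list[list[str]]] = {
        key: [] for key in sorted(valid_replicons)
    }

    def place(pid: str, species: str, replicon_id: str, block: list[str] | None = None) -> None:
        if (species, replicon_id) not in valid_replicons:
            raise GenerationError(f"unknown placement {species}/{replicon_id} for {pid}")
        species_of[pid] = species
        replicon_of[pid] = replicon_id
        if block is not None:
            block.append(pid)
        else:
            layout[(species, replicon_id)].append([pid])

    # P450 families
    seeds: list[str] = []
    for fam in spec.families:
        if not fam.placements:
            raise GenerationError(f"family {fam.name}: placements required in a study")
        fam_records, fam_truth = generate_p450_family(fam, rng, previous_seeds=seeds)
        seeds.append(fam_truth.seed_sequence)
        records.extend(fam_records)
        all_ids = list(fam_truth.member_ids) + list(fam_truth.fragment_ids)
        for i, pid in enumerate(all_ids):
            sp_name, replicon_id = fam.placements[i % len(fam.placements)]
            place(pid, sp_name, replicon_id)
        for pid in fam_truth.member_ids:
            roles[pid] = "p450_full"
            family_of[pid] = fam.name
        for pid in fam_truth.fragment_ids:
            roles[pid] = "p450_fragment"

    # ferredoxins
    fdx_index = 0
    for placement in spec.ferredoxins:
        for _ in range(placement.count):
            fdx_index += 1
            pid = f"fdx{fdx_index}"
            rec = generate_ferredoxin(
                placement.fdx_type, placement.signatures, rng, protein_id=pid
            )
            records.append(rec)
            roles[pid] = "ferredoxin"
            fdx_type_of[pid] = placement.fdx_type.value
            fdx_signature_of[pid] = "+".join(placement.signatures)
            place(pid, placement.species, placement.replicon_id)

    # OFOR pairs
    for i, pair in enumerate(spec.ofor_pairs, start=1):
        alpha_id, beta_id = f"ofor{i}a", f"ofor{i}b"
        records.append(
            ProteinRecord(
                id=alpha_id,
                sequence=random_sequence(rng, 620, DECOY_ALPHABET),
                description="2-oxoacid:ferredoxin oxidoreductase subunit alpha",
            )
        )
        records.append(
            ProteinRecord(
                id=beta_id,
                sequence=random_sequence(rng, 310, DECOY_ALPHABET),
                description="2-oxoacid:ferredoxin oxidoreductase subunit beta",
            )
        )
        roles[alpha_id], roles[beta_id] = "ofor_alpha", "ofor_beta"
        if pair.alpha_replicon_id == pair.beta_replicon_id:
            block: list[str] = []
            place(alpha_id, pair.species, pair.alpha_replicon_id, block)
            place(beta_id, pair.species, pair.beta_replicon_id, block)
            layout[(pair.species, pair.alpha_replicon_id)].append(block)
        else:
            place(alpha_id, pair.species, pair.alpha_replicon_id)
            place(beta_id, pair.species, pair.beta_replicon_id)

    # decoys
    decoy_index = 0
    for sp in spec.species:
        for rep in sp.replicons:
            for _ in range(spec.decoys_per_replicon):
                decoy_index += 1
                pid = f"decoy{decoy_index}"
                length = int(rng.integers(180, 420))
                records.append(
                    ProteinRecord(
                        id=pid,
                        sequence=random_sequence(rng, length, DECOY_ALPHABET),
                        description="hypothetical protein",
                    )
                )
                roles[pid] = "decoy"
                place(pid, sp.name, rep.replicon_id)

    # optionally fuse one P450 and one ferredoxin into a shared operon block
    if spec.p450_fdx_operon_replicon is not None:
        for key, blocks in layout.items():
            if key[1] != spec.p450_fdx_operon_replicon:
                continue
            p450_block = next(
                (b for b in blocks if roles.get(b[0]) == "p450_full"), None
            )
            fdx_block = next(
                (b for b in blocks if roles.get(b[0]) == "ferredoxin"), None
            )
            if p450_block and fdx_block:
                p450_block.extend(fdx_block)
                blocks.remove(fdx_block)
            break

    # gene layout: blocks in deterministic shuffled order per replicon
    features: list[GeneFeature] = []
    operon_blocks: list[tuple[str, ...]] = []
    lo_gap, hi_gap = spec.operon_gap_bp
    lo_spacer, hi_spacer = spec.spacer_gap_bp
    seq_by_id = {r.id: r.sequence for r in records}
    for (sp_name, replicon_id) in sorted(layout):
        blocks = layout[(sp_name, replicon_id)]
        if not blocks:
            continue
        order = rng.permutation(len(blocks))
        pos = 1 + int(rng.integers(100, 500))
        for bi in order:
            block = blocks[bi]
            strand = Strand.FORWARD if rng.random() < 0.5 else Strand.REVERSE
            gene_ids = []
            for pid in block:
                gene_len = 3 * (len(seq_by_id[pid]) + 1)
                gene_id = f"g_{pid}"
                features.append(
                    GeneFeature(
                        gene_id=gene_id,
                        protein_id=pid,
                        replicon_id=replicon_id,
                        start=pos,
                        end=pos + gene_len - 1,
                        strand=strand,
                    )
                )
                gene_ids.append(gene_id)
                pos += gene_len + int(rng.integers(lo_gap, hi_gap + 1))
            operon_blocks.append(tuple(gene_ids))
            pos += int(rng.integers(lo_spacer, hi_spacer + 1))

    replicon_meta = tuple(
        RepliconMeta(
            replicon_id=r.replicon_id,
            species=sp.name,
            replicon_type=r.replicon_type,
            accession=r.accession,
        )
        for sp in spec.species
        for r in sp.replicons
    )
    truth = GroundTruth(
        roles=roles,
        family_of=family_of,
        fdx_type_of=fdx_type_of,
        fdx_signature_of=fdx_signature_of,
        species_of=species_of,
        replicon_of=replicon_of,
        operon_blocks=tuple(operon_blocks),
    )
    if set(roles) != {r.id for r in records}:
        raise GenerationError("ground-truth closure violated")
    return StudyData(
        spec=spec,
        records=tuple(records),
        features=tuple(features),
        replicon_meta=tuple(replicon_meta),
        truth=truth,
    )


def default_study_spec(seed: int = 17) -> StudySpec:
    """The demo study: 3 species, 2 plasmids, 4 P450 families, 10 ferredoxins.

    Identity bands sit well away from the 40/55 nomenclature thresholds so
    recovery of the planted structure is unambiguous.
    """
    sp1 = SpeciesSpec(
        "Halarchaeum synthetica S1",
        (
            RepliconSpec("s1_chr", RepliconType.CHROMOSOME, "SYN_001"),
            RepliconSpec("s1_pl", RepliconType.PLASMID, "SYN_002"),
        ),
    )
    sp2 = SpeciesSpec(
        "Halarchaeum synthetica S2",
        (
            RepliconSpec("s2_chr", RepliconType.CHROMOSOME, "SYN_003"),
            RepliconSpec("s2_pl", RepliconType.PLASMID, "SYN_004"),
        ),
    )
    sp3 = SpeciesSpec(
        "Methanoculleus syntheticus S3",
        (RepliconSpec("s3_chr", RepliconType.CHROMOSOME, "SYN_005"),),
    )
    families = (
        P450FamilySpec(
            "FamA", 4,
            placements=(
                (sp1.name, "s1_chr"), (sp1.name, "s1_chr"),
                (sp2.name, "s2_chr"), (sp1.name, "s1_pl"),
            ),
        ),
        P450FamilySpec(
            "FamB", 3, n_fragments=1,
            placements=(
                (sp1.name, "s1_chr"), (sp2.name, "s2_pl"), (sp3.name, "s3_chr"),
                (sp2.name, "s2_chr"),
            ),
        ),
        P450FamilySpec(
            "FamC", 2,
            placements=((sp2.name, "s2_chr"), (sp3.name, "s3_chr")),
        ),
        P450FamilySpec("FamD", 1, placements=((sp3.name, "s3_chr"),)),
    )
    sig = DEFAULT_SIGNATURES
    ferredoxins = (
        FerredoxinPlacement(FdxType.FDX_2FE2S, sig[FdxType.FDX_2FE2S], sp1.name, "s1_chr", 2),
        FerredoxinPlacement(FdxType.FDX_3FE4S, sig[FdxType.FDX_3FE4S], sp1.name, "s1_pl", 1),
        FerredoxinPlacement(FdxType.FDX_4FE4S, sig[FdxType.FDX_4FE4S], sp2.name, "s2_chr", 2),
        FerredoxinPlacement(FdxType.FDX_7FE8S, sig[FdxType.FDX_7FE8S], sp2.name, "s2_pl", 1),
        FerredoxinPlacement(FdxType.FDX_2X4FE4S, sig[FdxType.FDX_2X4FE4S], sp3.name, "s3_chr", 2),
        FerredoxinPlacement(
            FdxType.FDX_2X4FE4S_ALV, sig[FdxType.FDX_2X4FE4S_ALV], sp3.name, "s3_chr", 2
        ),
    )
    ofor_pairs = (
        OFORPairSpec(sp1.name, "s1_chr", "s1_chr"),  # adjacent pair
        OFORPairSpec(sp2.name, "s2_chr", "s2_pl"),  # split across replicons
    )
    return StudySpec(
        seed=seed,
        species=(sp1, sp2, sp3),
        families=families,
        ferredoxins=ferredoxins,
        ofor_pairs=ofor_pairs,
        decoys_per_replicon=3,
        p450_fdx_operon_replicon="s1_chr",
    )
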