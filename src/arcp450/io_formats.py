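"""Readers and writers for every external format the pipeline touches.

Conventions enforced here, once, for the whole package:

* FASTA protein sequences are uppercased, terminal ``*`` stops are stripped,
  and the rare non-standard letters B, Z, U, O and J are mapped to ``X``
  (public proteomes contain them; rejecting whole records would lose data).
* GFF3 coordinates are kept 1-based inclusive on disk, exactly as in the
  file.  Any 0-based half-open arithmetic is internal to the modules that
  need it (see :func:`to_half_open` / :func:`to_one_based`).
* Replicon metadata travels in a separate TSV sidecar rather than being
  parsed out of FASTA headers, because JGI and NCBI header dialects differ.
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import CoordinateError, DuplicateIdError, FormatError

logger = logging.getLogger(__name__)

STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWYX")
#: letters tolerated on input but normalised to X
AMBIGUOUS_AA = set("BZUOJ")


class RepliconType(str, Enum):
    CHROMOSOME = "chromosome"
    PLASMID = "plasmid"
    UNKNOWN = "unknown"


class Strand(str, Enum):
    FORWARD = "+"
    REVERSE = "-"


@dataclass(frozen=True)
class ProteinRecord:
    """One protein with its source species and replicon context."""

    id: str
    sequence: str
    description: str = ""
    species: str = ""
    replicon_id: str = ""
    replicon_type: RepliconType = RepliconType.UNKNOWN

    def __post_init__(self) -> None:
        if not self.sequence:
            raise FormatError(f"record {self.id!r}: empty sequence")
        if not self.sequence.isupper():
            raise FormatError(f"record {self.id!r}: sequence must be uppercase")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class GeneFeature:
    """A gene/CDS with 1-based inclusive nucleotide coordinates."""

    gene_id: str
    protein_id: str
    replicon_id: str
    start: int
    end: int
    strand: Strand

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise CoordinateError(
                f"feature {self.gene_id!r}: require 1 <= start <= end, "
                f"got {self.start}..{self.end}"
            )


@dataclass(frozen=True)
class RepliconMeta:
    replicon_id: str
    species: str
    replicon_type: RepliconType
    accession: str = ""


def to_half_open(start: int, end: int) -> tuple[int, int]:
    """1-based inclusive -> 0-based half-open."""
    return start - 1, end


def to_one_based(start0: int, end0: int) -> tuple[int, int]:
    """0-based half-open -> 1-based inclusive."""
    return start0 + 1, end0


def _normalise_sequence(raw: str, rec_id: str) -> str:
    seq = raw.upper()
    if seq.endswith("*"):
        seq = seq[:-1]
    if "*" in seq:
        raise FormatError(f"record {rec_id!r}: internal stop codon '*'")
    cleaned = []
    for ch in seq:
        if ch in STANDARD_AA:
            cleaned.append(ch)
        elif ch in AMBIGUOUS_AA:
            logger.warning("record %r: non-standard residue %r mapped to X", rec_id, ch)
            cleaned.append("X")
        else:
            raise FormatError(f"record {rec_id!r}: invalid residue {ch!r}")
    return "".join(cleaned)


def read_fasta(
    path: str | Path,
    replicon_meta: Sequence[RepliconMeta] | None = None,
    fasta_to_replicon: dict[str, str] | None = None,
) -> list[ProteinRecord]:
    """Read a protein FASTA file into :class:`ProteinRecord` objects.

    Parameters
    ----------
    path
        FASTA text file; one proteome, typically one replicon.
    replicon_meta
        Optional sidecar metadata; when given together with
        ``fasta_to_replicon`` (mapping record id -> replicon_id), the species
        and replicon fields are populated.  Otherwise they are left unknown.
    """
    path = Path(path)
    meta_by_id = {m.replicon_id: m for m in (replicon_meta or [])}
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    try:
        parsed = list(SeqIO.parse(str(path), "fasta"))
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from exc
    for rec in parsed:
        if not rec.id:
            raise FormatError(f"{path}: record with empty id")
        if rec.id in seen:
            raise DuplicateIdError(f"{path}: duplicate record id {rec.id!r}")
        seen.add(rec.id)
        seq = _normalise_sequence(str(rec.seq), rec.id)
        if not seq:
            raise FormatError(f"{path}: record {rec.id!r} has empty sequence")
        replicon_id = (fasta_to_replicon or {}).get(rec.id, "")
        meta = meta_by_id.get(replicon_id)
        records.append(
            ProteinRecord(
                id=rec.id,
                sequence=seq,
                description=rec.description[len(rec.id):].strip(),
                species=meta.species if meta else "",
                replicon_id=replicon_id,
                replicon_type=meta.replicon_type if meta else RepliconType.UNKNOWN,
            )
        )
    if not records:
        # distinguish "no > lines at all" from a readable empty file
        text = path.read_text()
        if text.strip() and not text.lstrip().startswith(">"):
            raise FormatError(f"{path}: not FASTA (first non-blank line is not a header)")
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    seq_records = [
        SeqRecord(Seq(r.sequence), id=r.id, description=r.description) for r in records
    ]
    SeqIO.write(seq_records, str(path), "fasta")


_GFF_ATTR_RE = re.compile(r"(\w+)=([^;]+)")


def read_gff3(path: str | Path, feature_types: tuple[str, ...] = ("CDS", "gene")) -> list[GeneFeature]:
    """Parse CDS/gene features from a GFF3 file.

    Coordinates are kept 1-based inclusive exactly as on disk.  The protein
    id is taken from the ``protein_id`` attribute when present, else ``ID``.
    Output is sorted by (replicon_id, start).
    """
    path = Path(path)
    features: list[GeneFeature] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise FormatError(f"{path}:{lineno}: expected 9 tab-separated columns")
            seqid, _source, ftype, start_s, end_s, _score, strand_s, _phase, attrs_s = parts
            if ftype not in feature_types:
                continue
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start > end:
                raise CoordinateError(f"{path}:{lineno}: start {start} > end {end}")
            if strand_s not in ("+", "-"):
                raise FormatError(f"{path}:{lineno}: missing or invalid strand {strand_s!r}")
            attrs = dict(_GFF_ATTR_RE.findall(attrs_s))
            gene_id = attrs.get("ID")
            if gene_id is None:
                raise FormatError(f"{path}:{lineno}: feature without ID attribute")
            protein_id = attrs.get("protein_id", gene_id)
            features.append(
                GeneFeature(
                    gene_id=gene_id,
                    protein_id=protein_id,
                    replicon_id=seqid,
                    start=start,
                    end=end,
                    strand=Strand(strand_s),
                )
            )
    features.sort(key=lambda f: (f.replicon_id, f.start, f.gene_id))
    return features


def write_gff3(features: Iterable[GeneFeature], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in sorted(features, key=lambda f: (f.replicon_id, f.start, f.gene_id)):
            attrs = f"ID={f.gene_id};protein_id={f.protein_id}"
            fh.write(
                f"{f.replicon_id}\t.\tCDS\t{f.start}\t{f.end}\t.\t{f.strand.value}\t0\t{attrs}\n"
            )


_REPLICON_COLUMNS = ("replicon_id", "species", "replicon_type", "accession")


def read_replicon_table(path: str | Path) -> list[RepliconMeta]:
    """Read the tab-separated replicon metadata sidecar.

    Columns: replicon_id, species, replicon_type (chromosome|plasmid,
    case-insensitive), accession.
    """
    path = Path(path)
    metas: list[RepliconMeta] = []
    seen: set[str] = set()
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        missing = set(_REPLICON_COLUMNS) - set(reader.fieldnames or [])
        if missing:
            raise FormatError(f"{path}: missing columns {sorted(missing)}")
        for row in reader:
            rid = row["replicon_id"].strip()
            if rid in seen:
                raise DuplicateIdError(f"{path}: duplicate replicon_id {rid!r}")
            seen.add(rid)
            token = row["replicon_type"].strip().lower()
            try:
                rtype = RepliconType(token)
            except ValueError as exc:
                raise ValueError(
                    f"{path}: unknown replicon_type {row['replicon_type']!r} "
                    f"(expected chromosome or plasmid)"
                ) from exc
            if rtype is RepliconType.UNKNOWN:
                raise ValueError(f"{path}: replicon_type may not be 'unknown' in metadata")
            metas.append(
                RepliconMeta(
                    replicon_id=rid,
                    species=row["species"].strip(),
                    replicon_type=rtype,
                    accession=row["accession"].strip(),
                )
            )
    return metas


def write_replicon_table(metas: Iterable[RepliconMeta], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_REPLICON_COLUMNS)
        for m in metas:
            writer.writerow([m.replicon_id, m.species, m.replicon_type.value, m.accession])


_NEWICK_UNSAFE = re.compile(r"[\s()\[\]:;,']")


def _quote_label(label: str) -> str:
    if _NEWICK_UNSAFE.search(label):
        return "'" + label.replace("'", "''") + "'"
    return label


def write_newick(tree) -> str:
    """Serialize a scikit-bio ``TreeNode`` to a Newick string.

    Labels containing Newick metacharacters or whitespace are single-quoted
    (with internal quotes doubled), so the output round-trips through any
    conformant Newick parser.
    """
    if tree is None or (tree.is_tip() and tree.name is None):
        raise ValueError("cannot serialize an empty tree")

    def emit(node) -> str:
        if node.is_tip():
            label = _quote_label(node.name or "")
        else:
            children = ",".join(emit(c) for c in node.children)
            label = f"({children})" + (_quote_label(node.name) if node.name else "")
        if node.length is not None:
            label += f":{float(node.length)}"
        return label

    if tree.is_tip():
        raise ValueError("cannot serialize a single-leaf tree")
    return emit(tree) + ";"
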