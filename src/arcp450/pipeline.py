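"""End-to-end orchestration: inputs -> screen -> classify -> annotate -> compare.

One declarative :class:`RunConfig` drives every stage; the run writes a
fixed set of TSV tables plus a Newick tree and a manifest recording the
config hash and seed, so a run is reproducible and self-describing.
Re-running with identical config and inputs reproduces identical files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import __version__
from .errors import ArcP450Error, ConfigurationError
from .ferredoxin import (
    FdxType,
    FeSRules,
    SubtypeRegistry,
    assign_fdx_type,
    assign_subtype,
    find_ofor,
    scan_fes_motifs,
)
from .genome_context import (
    copresence_counts,
    family_saturation,
    p450_operon_context,
    predict_operons,
    replicon_family_comparison,
)
from .identity import AlignParams, identity_matrix
from .io_formats import (
    read_fasta,
    read_gff3,
    read_replicon_table,
    write_newick,
)
from .nomenclature import (
    ClassifierParams,
    FamilyAssignment,
    ReferenceDB,
    assign_against_reference,
    count_families,
    name_assignments,
)
from .p450_screen import P450Status, ScreenParams, screen_proteome
from .phylo import identity_to_distance, nj_tree

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    fasta: str
    gff: str
    replicons: str
    out_dir: str
    refdb: str | None = None
    candidates: str | None = None
    registry: str | None = None
    seed: int = 0
    screen: ScreenParams = field(default_factory=ScreenParams)
    align: AlignParams = field(default_factory=AlignParams)
    classifier: ClassifierParams = field(default_factory=ClassifierParams)
    fes_rules: FeSRules = field(default_factory=FeSRules)
    max_gap_bp: int = 150
    max_gene_gap: int = 1
    saturation_permutations: int = 100

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict[str, Any]) -> "RunConfig":
        kwargs = dict(raw)
        if "screen" in kwargs:
            kwargs["screen"] = ScreenParams(**kwargs["screen"])
        if "align" in kwargs:
            kwargs["align"] = AlignParams(**kwargs["align"])
        if "classifier" in kwargs:
            kwargs["classifier"] = ClassifierParams(**kwargs["classifier"])
        kwargs.pop("fes_rules", None)  # rule tables are code-level config
        return cls(**kwargs)

    def to_dict(self) -> dict[str, Any]:
        def unwrap(value):
            if dataclasses.is_dataclass(value) and not isinstance(value, type):
                return {k: unwrap(v) for k, v in dataclasses.asdict(value).items()}
            if isinstance(value, (list, tuple)):
                return [unwrap(v) for v in value]
            if hasattr(value, "value"):
                return value.value
            return value

        return {f.name: unwrap(getattr(self, f.name)) for f in dataclasses.fields(self)}


def _config_hash(config: RunConfig) -> str:
    canon = json.dumps(config.to_dict(), sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Run every stage; returns a map of output name -> written path.

    Input paths are validated before any compute; a stage failure aborts
    with the failing stage named.
    """
    for name in ("fasta", "gff", "replicons", "refdb", "candidates", "registry"):
        value = getattr(config, name)
        if value is not None and not Path(value).exists():
            raise ConfigurationError(f"input path for {name!r} does not exist: {value}")
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}

    def stage(name):
        def wrap(fn):
            try:
                return fn()
            except ArcP450Error:
                raise
            except Exception as exc:  # pragma: no cover - defensive
                raise ArcP450Error(f"stage {name!r} failed: {exc}") from exc
        return wrap

    # --- inputs
    replicon_meta = read_replicon_table(config.replicons)
    features = read_gff3(config.gff)
    replicon_by_protein = {f.protein_id: f.replicon_id for f in features}
    records = read_fasta(
        config.fasta, replicon_meta=replicon_meta, fasta_to_replicon=replicon_by_protein
    )
    species_by_replicon = {m.replicon_id: m.species for m in replicon_meta}
    species_map = {
        r.id: species_by_replicon.get(replicon_by_protein.get(r.id, ""), "")
        for r in records
    }
    candidate_ids = None
    if config.candidates:
        candidate_ids = [
            line.strip()
            for line in Path(config.candidates).read_text().splitlines()
            if line.strip()
        ]

    # --- screen
    report = stage("screen")(lambda: screen_proteome(records, config.screen, candidate_ids))
    screen_df = pd.DataFrame(
        {
            "protein_id": [c.protein_id for c in report.calls],
            "status": [c.status.value for c in report.calls],
            "length": [c.length for c in report.calls],
            "n_motif_hits": [len(c.motif_hits) for c in report.calls],
            "reasons": [";".join(c.reasons) for c in report.calls],
        }
    )
    outputs["screen"] = out_dir / "screen.tsv"
    screen_df.to_csv(outputs["screen"], sep="\t", index=False)

    full_length = [r for r in records if r.id in set(report.full_length_ids())]

    # --- identity + classification
    matrix = None
    if len(full_length) >= 2:
        matrix = stage("identity")(lambda: identity_matrix(full_length, config.align))

    def classify():
        if config.refdb:
            refdb = ReferenceDB.from_records(read_fasta(config.refdb))
            assignments = [
                assign_against_reference(q, refdb, config.classifier, config.align)
                for q in full_length
            ]
            ref_labels = refdb.family_labels
        else:
            assignments = [
                FamilyAssignment(
                    protein_id=r.id, family="", subfamily="", best_ref_id=None,
                    best_identity=0.0, novel_family=True,
                )
                for r in full_length
            ]
            ref_labels = set()
        if len(full_length) == 1:
            only = assignments[0]
            if only.novel_family:
                assignments = [
                    dataclasses.replace(
                        only, family=f"{config.classifier.novel_family_prefix}1",
                        subfamily="A", member=1, novel_family=True,
                    )
                ]
            return assignments
        return name_assignments(assignments, matrix, config.classifier, ref_labels)

    assignments = stage("classify")(classify) if full_length else []
    assign_df = pd.DataFrame(
        {
            "protein_id": [a.protein_id for a in assignments],
            "label": [a.label for a in assignments],
            "family": [a.family for a in assignments],
            "subfamily": [a.subfamily for a in assignments],
            "best_ref_id": [a.best_ref_id or "" for a in assignments],
            "best_identity": [a.best_identity for a in assignments],
            "novel_family": [a.novel_family for a in assignments],
            "conflict": [a.conflict for a in assignments],
        }
    )
    outputs["assignments"] = out_dir / "assignments.tsv"
    assign_df.to_csv(outputs["assignments"], sep="\t", index=False)

    outputs["family_counts"] = out_dir / "family_counts.tsv"
    count_families(assignments).to_csv(outputs["family_counts"], sep="\t", index=False) \
        if assignments else pd.DataFrame(
            columns=["family", "members", "subfamilies"]
        ).to_csv(outputs["family_counts"], sep="\t", index=False)

    # --- ferredoxins (motif scan over everything not called a P450)
    p450_ids = {
        c.protein_id for c in report.calls if c.status is not P450Status.NOT_P450
    }
    registry = (
        SubtypeRegistry.load(config.registry) if config.registry else SubtypeRegistry()
    )

    def annotate_fdx():
        calls = []
        for rec in records:
            if rec.id in p450_ids:
                continue
            motifs = scan_fes_motifs(rec.sequence, config.fes_rules)
            call = assign_fdx_type(rec.id, motifs, config.fes_rules)
            if call.fdx_type is not FdxType.UNCLASSIFIED:
                calls.append(assign_subtype(call, registry))
        return calls

    fdx_calls = stage("ferredoxin")(annotate_fdx)
    fdx_df = pd.DataFrame(
        {
            "protein_id": [c.protein_id for c in fdx_calls],
            "fdx_type": [c.fdx_type.value for c in fdx_calls],
            "signature": [c.signature_key for c in fdx_calls],
            "subtype_id": [c.subtype_id for c in fdx_calls],
        }
    )
    outputs["fdx"] = out_dir / "fdx.tsv"
    fdx_df.to_csv(outputs["fdx"], sep="\t", index=False)
    outputs["registry"] = out_dir / "registry.tsv"
    registry.save(outputs["registry"])

    # --- OFOR
    ofor_calls = stage("ofor")(
        lambda: find_ofor(records, features, max_gene_gap=config.max_gene_gap)
    )
    ofor_df = pd.DataFrame(
        {
            "protein_id": [c.protein_id for c in ofor_calls],
            "subunit": [c.subunit.value for c in ofor_calls],
            "partner_protein_id": [c.partner_protein_id or "" for c in ofor_calls],
            "adjacent": [c.adjacent for c in ofor_calls],
        }
    )
    outputs["ofor"] = out_dir / "ofor.tsv"
    ofor_df.to_csv(outputs["ofor"], sep="\t", index=False)

    # --- operons and context
    operons = stage("operons")(lambda: predict_operons(features, config.max_gap_bp))
    operon_df = pd.DataFrame(
        {
            "operon_id": [o.operon_id for o in operons],
            "replicon_id": [o.replicon_id for o in operons],
            "strand": [o.strand.value for o in operons],
            "n_genes": [len(o) for o in operons],
            "gene_ids": [",".join(o.gene_ids) for o in operons],
        }
    )
    outputs["operons"] = out_dir / "operons.tsv"
    operon_df.to_csv(outputs["operons"], sep="\t", index=False)

    annotations = {}
    desc_by_protein = {r.id: r.description for r in records}
    for f in features:
        annotations[f.gene_id] = desc_by_protein.get(f.protein_id) or f.protein_id
    context = stage("context")(
        lambda: p450_operon_context(
            operons, features, report.calls, fdx_calls, ofor_calls, annotations
        )
    )
    outputs["operon_context"] = out_dir / "operon_context.tsv"
    context.to_csv(outputs["operon_context"], sep="\t", index=False)

    # --- comparative statistics
    copresence = stage("copresence")(lambda: copresence_counts(assignments, species_map))
    outputs["copresence"] = out_dir / "copresence.tsv"
    copresence.to_csv(outputs["copresence"], sep="\t")

    replicon_of = {
        a.protein_id: replicon_by_protein.get(a.protein_id, "") for a in assignments
    }
    comparison = stage("replicon_comparison")(
        lambda: replicon_family_comparison(assignments, replicon_of, replicon_meta)
    )
    outputs["replicon_comparison"] = out_dir / "replicon_comparison.tsv"
    comparison.to_csv(outputs["replicon_comparison"], sep="\t", index=False)

    curve = stage("saturation")(
        lambda: family_saturation(
            assignments, species_map, config.saturation_permutations, config.seed
        )
    )
    saturation_df = pd.DataFrame(
        {
            "n_species": curve.n_species,
            "mean_cumulative_families": curve.mean_cumulative_families,
        }
    )
    outputs["saturation"] = out_dir / "saturation.tsv"
    saturation_df.to_csv(outputs["saturation"], sep="\t", index=False)

    # --- tree
    outputs["tree"] = out_dir / "tree.nwk"
    if matrix is not None and len(matrix.ids) >= 3:
        tree = stage("tree")(lambda: nj_tree(identity_to_distance(matrix)))
        outputs["tree"].write_text(write_newick(tree) + "\n")
    else:
        outputs["tree"].write_text(";\n")

    manifest = {
        "package_version": __version__,
        "config": config.to_dict(),
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "n_records": len(records),
        "outputs": {k: str(v.name) for k, v in outputs.items()},
    }
    outputs["manifest"] = out_dir / "manifest.json"
    outputs["manifest"].write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return outputs
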