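"""Operon prediction and replicon-aware comparative statistics.

Operons are predicted with a transparent heuristic: maximal runs of
same-strand genes on one replicon with intergenic gaps no larger than a
threshold (default 150 bp).  That is deliberately simpler than full
transcription-unit modelling but answers the comparative questions asked
here — which genes travel with P450s, and whether redox partners sit in
P450 operons.

The comparative statistics all key on species (so multi-replicon species
aggregate correctly) or on replicon type (chromosome vs plasmid):
family-by-family co-presence counts, plasmid/chromosome member splits, and
a family saturation curve (mean cumulative distinct families over random
species orderings — a species-accumulation curve for gene families).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import LinkageError
from .ferredoxin import FerredoxinCall, OFORCall
from .io_formats import GeneFeature, RepliconMeta, RepliconType, Strand
from .nomenclature import FamilyAssignment
from .p450_screen import P450Call, P450Status

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Operon:
    operon_id: str
    replicon_id: str
    strand: Strand
    gene_ids: tuple[str, ...]  # ordered by start

    def __len__(self) -> int:
        return len(self.gene_ids)


def predict_operons(features: Sequence[GeneFeature], max_gap_bp: int = 150) -> list[Operon]:
    """Segment genes into operons: same strand, intergenic gap <= max_gap_bp.

    Every gene lands in exactly one operon (singletons allowed).  Genes
    overlapping on the same strand are treated as gap 0 with a warning.
    """
    if max_gap_bp < 0:
        raise ValueError("max_gap_bp must be >= 0")
    by_replicon: dict[str, list[GeneFeature]] = {}
    for f in features:
        by_replicon.setdefault(f.replicon_id, []).append(f)

    operons: list[Operon] = []
    counter = 0
    for replicon_id in sorted(by_replicon):
        feats = sorted(by_replicon[replicon_id], key=lambda f: (f.start, f.gene_id))
        run: list[GeneFeature] = []
        for f in feats:
            if run and f.strand is run[-1].strand:
                gap = f.start - run[-1].end - 1
                if gap < 0:
                    logger.warning(
                        "overlapping same-strand genes %s/%s on %s; treating gap as 0",
                        run[-1].gene_id, f.gene_id, replicon_id,
                    )
                    gap = 0
                if gap <= max_gap_bp:
                    run.append(f)
                    continue
            if run:
                counter += 1
                operons.append(
                    Operon(f"OP{counter}", replicon_id, run[0].strand,
                           tuple(g.gene_id for g in run))
                )
            run = [f]
        if run:
            counter += 1
            operons.append(
                Operon(f"OP{counter}", replicon_id, run[0].strand,
                       tuple(g.gene_id for g in run))
            )
    return operons


def p450_operon_context(
    operons: Sequence[Operon],
    features: Sequence[GeneFeature],
    p450_calls: Sequence[P450Call],
    fdx_calls: Sequence[FerredoxinCall] = (),
    ofor_calls: Sequence[OFORCall] = (),
    feature_annotations: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """One row per P450-containing operon, with redox-partner flags.

    Columns: operon_id, replicon_id, genes (oriented arrow string),
    p450_ids, has_ferredoxin, has_ofor.  Raises ``LinkageError`` when a
    full-length P450 call has no gene feature.
    """
    feature_by_protein = {f.protein_id: f for f in features}
    feature_by_gene = {f.gene_id: f for f in features}
    annotations = dict(feature_annotations or {})

    p450_genes = set()
    for call in p450_calls:
        if call.status is P450Status.FULL_LENGTH:
            feat = feature_by_protein.get(call.protein_id)
            if feat is None:
                raise LinkageError(f"P450 call {call.protein_id} has no gene feature")
            p450_genes.add(feat.gene_id)
    fdx_genes = {
        feature_by_protein[c.protein_id].gene_id
        for c in fdx_calls
        if c.protein_id in feature_by_protein
    }
    ofor_genes = {
        feature_by_protein[c.protein_id].gene_id
        for c in ofor_calls
        if c.protein_id in feature_by_protein
    }

    rows = []
    for operon in operons:
        hits = [g for g in operon.gene_ids if g in p450_genes]
        if not hits:
            continue
        arrow = "→" if operon.strand is Strand.FORWARD else "←"
        genes = arrow.join(
            annotations.get(g, g) for g in operon.gene_ids
        )
        rows.append(
            {
                "operon_id": operon.operon_id,
                "replicon_id": operon.replicon_id,
                "genes": genes,
                "p450_ids": ",".join(
                    feature_by_gene[g].protein_id for g in hits
                ),
                "has_ferredoxin": bool(set(operon.gene_ids) & fdx_genes),
                "has_ofor": bool(set(operon.gene_ids) & ofor_genes),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["operon_id", "replicon_id", "genes", "p450_ids",
                 "has_ferredoxin", "has_ofor"],
    )


def copresence_counts(
    assignments: Sequence[FamilyAssignment],
    species_map: Mapping[str, str],
) -> pd.DataFrame:
    """Family x family species co-presence matrix.

    Entry (f, g) counts species containing at least one member of both f
    and g; the diagonal counts species containing f.  Symmetric, and every
    off-diagonal entry is bounded by the smaller diagonal.
    """
    families = sorted({a.family for a in assignments})
    species_sets: dict[str, set[str]] = {f: set() for f in families}
    for a in assignments:
        try:
            species = species_map[a.protein_id]
        except KeyError as exc:
            raise LinkageError(f"no species for protein {a.protein_id}") from exc
        species_sets[a.family].add(species)
    n = len(families)
    counts = np.zeros((n, n), dtype=int)
    for i, f in enumerate(families):
        for j, g in enumerate(families):
            counts[i, j] = len(species_sets[f] & species_sets[g])
    return pd.DataFrame(counts, index=families, columns=families)


def replicon_family_comparison(
    assignments: Sequence[FamilyAssignment],
    replicon_of: Mapping[str, str],
    replicon_meta: Sequence[RepliconMeta],
) -> pd.DataFrame:
    """Per-family member counts split by replicon type.

    Columns: family, plasmid_count, chromosome_count; sorted by total
    descending.  Column sums equal the number of assigned P450s.
    """
    meta_by_id = {m.replicon_id: m for m in replicon_meta}
    rows = []
    for a in assignments:
        replicon_id = replicon_of.get(a.protein_id)
        if replicon_id is None or replicon_id not in meta_by_id:
            raise LinkageError(f"cannot resolve replicon for protein {a.protein_id}")
        rows.append((a.family, meta_by_id[replicon_id].replicon_type))
    df = pd.DataFrame(rows, columns=["family", "replicon_type"])
    table = (
        df.assign(
            plasmid=(df.replicon_type == RepliconType.PLASMID).astype(int),
            chromosome=(df.replicon_type == RepliconType.CHROMOSOME).astype(int),
        )
        .groupby("family")
        .agg(plasmid_count=("plasmid", "sum"), chromosome_count=("chromosome", "sum"))
        .reset_index()
    )
    table["total"] = table.plasmid_count + table.chromosome_count
    table = (
        table.sort_values(["total", "family"], ascending=[False, True], kind="stable")
        .drop(columns="total")
        .reset_index(drop=True)
    )
    return table


@dataclass(frozen=True)
class SaturationCurve:
    n_species: tuple[int, ...]
    mean_cumulative_families: tuple[float, ...]
    n_permutations: int
    seed: int


def family_saturation(
    assignments: Sequence[FamilyAssignment],
    species_map: Mapping[str, str],
    n_permutations: int = 100,
    seed: int = 0,
    exhaustive: bool = False,
) -> SaturationCurve:
    """Species-accumulation curve for P450 families.

    For each k in 1..N, the mean (over random species orderings) number of
    distinct families seen in the first k species.  Non-decreasing, and
    ends at the global family count for every seed.  With ``exhaustive``
    the mean is taken over all N! orderings exactly (N <= 8 only).
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    families_by_species: dict[str, set[str]] = {}
    for a in assignments:
        species = species_map.get(a.protein_id)
        if species is None:
            raise LinkageError(f"no species for protein {a.protein_id}")
        families_by_species.setdefault(species, set()).add(a.family)
    species = sorted(families_by_species)
    n = len(species)
    if exhaustive:
        if n > 8:
            raise ValueError("exhaustive enumeration limited to <= 8 species")
        import itertools
        import math

        orders = list(itertools.permutations(range(n)))
        n_used = math.factorial(n)
    else:
        rng = np.random.default_rng(seed)
        orders = [rng.permutation(n) for _ in range(n_permutations)]
        n_used = n_permutations
    totals = np.zeros(n)
    for order in orders:
        seen: set[str] = set()
        for k, idx in enumerate(order):
            seen |= families_by_species[species[idx]]
            totals[k] += len(seen)
    means = totals / n_used
    return SaturationCurve(
        n_species=tuple(range(1, n + 1)),
        mean_cumulative_families=tuple(float(x) for x in means),
        n_permutations=n_used,
        seed=seed,
    )
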