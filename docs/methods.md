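# Methods

`arcp450` re-implements, as a tested desk-scale pipeline, the comparative
annotation workflow used in genome surveys of cytochrome P450s (CYPs) and
their ferredoxin/OFOR redox partners in prokaryotes: motif-based P450
detection with a fragment filter, identity-threshold family and subfamily
assignment, cysteine-spacing classification of ferredoxin Fe-S cluster
types and subtypes, OFOR alpha/beta subunit detection, operon-context
analysis, and replicon-aware comparative statistics, plus a distance-based
phylogeny stage.

## P450 screening

A protein is a classifiable (full-length) P450 when it carries both
signature motifs and is long enough:

* **ExxR** (K-helix tetrad), matched anywhere in the sequence as the
  pattern `E..R`;
* **CxG** (around the heme-ligating cysteine), matched as `C.G` within the
  C-terminal 40% of the sequence (`cxg_search_region`, default 0.4 —
  the heme ligand sits near the C-terminus; set to 1.0 to disable);
* length ≥ `min_length` (default **350 aa**), applied as
  strictly-less-than-350 ⇒ fragment;
* by default some ExxR hit must precede some CxG hit (`require_order`).

A candidate failing any condition but showing motif evidence is a
**fragment** and is excluded from classification.  Proteins with no motif
evidence are **not_p450** unless they were pre-flagged by an upstream
candidate list (mirroring a domain-based pre-selection), in which case a
short motif-free candidate is still counted as a fragment.  One motif of
each kind suffices; all (including overlapping) occurrences are reported.

Surveys that use this rule pre-select candidates with a profile/domain
search before motif checking.  This package makes the motif screen itself
the selector (plus the optional candidate list), because the motifs and
the length cut are the decisive published filters and need no external
service.

## Percent identity

Nomenclature thresholds are defined on pairwise percent identity, but the
convention does not pin down an alignment recipe.  The package fixes one
and makes every choice a parameter (`AlignParams`):

* global alignment, affine gaps: a gap run of length L costs
  `gap_open + gap_extend·L` with defaults 10 and 0.5, BLOSUM62 scores;
* terminal gaps free by default (so fragments and length differences are
  not charged);
* identity = `100 · identical columns / scored columns`, where scored
  columns run from the first to the last alignment column in which both
  sequences are present — terminal overhangs excluded, internal gap
  columns included.  Alternative denominators (shorter sequence, full
  alignment length) are selectable.  Values are reported to 0.1.

This is the convention closest to EMBOSS-needle practice in nomenclature
work.  With these penalties the optimal free-end alignment of unrelated
~400-aa proteins still spans most of both sequences, so unrelated pairs
measure ~15–20% identity, far below the family threshold; this was checked
empirically, since a scored-columns denominator would misbehave if the
optimizer preferred tiny overlaps.

Alignment is performed by Biopython's `PairwiseAligner`; when several
alignments are optimal, its canonical traceback gives a deterministic one.
Tests verify score optimality against an independent exhaustive
enumeration, which is the contract that matters; the identity of the
particular co-optimal alignment returned is not relied on anywhere.

## Family and subfamily assignment

The nomenclature rule — >40% identity ⇒ same family, >55% ⇒ same
subfamily, <40% to everything named ⇒ new family — leaves exactly-40
undefined; the package applies both thresholds **inclusively** (≥40, ≥55)
and logs the choice.

* **Against a reference set** of named P450s (FASTA with CYP labels as
  ids): the best hit by identity decides.  ≥55% inherits family and
  subfamily; ≥40% inherits the family with the subfamily left for de novo
  lettering; otherwise the query founds a novel family.  A query ≥40% to
  references of two different families keeps the best hit but is flagged
  `conflict`.
* **De novo**: unplaced sequences are partitioned by single-linkage
  connected components at the family threshold, then lettered into
  subfamilies at the subfamily threshold.  Single linkage matches the
  pairwise, transitively-applied practice of the rule; the known chaining
  risk is logged whenever a component's minimum internal identity falls
  below the threshold.
* Novel families are labelled `CYPN1, CYPN2, …` in deterministic
  (smallest-member-id) order rather than guessing official CYP numbers,
  which only the nomenclature committee can allocate; subfamilies are
  lettered A, B, …; members numbered within subfamily.  Collisions with
  reference family labels are an error.

## Ferredoxin typing

Ferredoxins are classified from the spacing pattern of the cysteines that
ligate their Fe-S cluster.  The grammar is a declarative rule table
(`FeSRules`), one rule per cluster class, giving the allowed residue gaps
between consecutive motif cysteines.  Defaults:

| class  | cysteines | spacing windows |
|--------|-----------|-----------------|
| 2Fe-2S | 4 | (4–6, 2, 20–40) |
| 4Fe-4S | 4 | (2, 2, 3–40) |
| 3Fe-4S | 3 | (2–8, 3–40) |

Scanning is greedy and left-to-right: at each unconsumed cysteine the
classes are tried in the priority order above (most specific first); on a
match the motif's cysteines are consumed.  Within a spacing window the
nearest conforming cysteine is taken; closer cysteines below the window
minimum are skipped.  This is deterministic, and real Fe-S motifs do not
overlap.

Motif combinations resolve to types: two 4Fe-4S motifs ⇒ **2[4Fe-4S]**,
one 3Fe-4S + one 4Fe-4S ⇒ **7Fe-8S**, a single motif ⇒ its own class, no
motif ⇒ unclassified.  The **Alvin-type 2[4Fe-4S]** variant is recognised
by the extended loop before the final cysteine of the second cluster
motif: final spacing ≥ `alv_min_final_spacing` (default 15).  That
operational cutoff is this package's own definition (the published
subtype catalogues define the variant structurally) and is configurable.

The ordered spacing signature (e.g. `C-2-C-2-C-4-C`, composite types keyed
on the `+`-joined pair) *is* the subtype identity.  A registry maps
(type, signature) to stable subtype numbers, assigning the next sequential
number per type to novel signatures; seeding the registry from a legacy
TSV lets numbering continue a published series.  Comparative outputs key
on signatures, so legacy numbers are presentation only.

In the pipeline, ferredoxin scanning is applied to proteins **not** called
P450s: cysteine-rich P450 sequences can incidentally satisfy the loose
3Fe-4S window, and the published workflows likewise pre-select Fe-S
protein candidates before spacing classification.

## OFOR detection

2-oxoacid:ferredoxin oxidoreductase subunits are detected from annotation
text (configurable keyword patterns for the enzyme name and the
alpha/beta token), mirroring the manual proteome searches used in the
surveys.  A subunit is *adjacent* when a subunit of the other kind lies
within `max_gene_gap` gene positions (default 1) on the same replicon.

## Operons and context

Operons are maximal runs of same-strand genes on one replicon with
intergenic gaps ≤ `max_gap_bp` (default **150 bp**); every gene belongs to
exactly one operon, singletons allowed, same-strand overlaps count as gap
0 with a warning.  This transparent heuristic replaces web-service operon
predictors; it is adequate for the qualitative question asked of it —
which genes travel with P450s and whether redox partners are co-operonic —
and the threshold is a flag.  Exact operon boundaries from other tools may
differ.

The context table lists, per P450-containing operon, the oriented gene
run and flags `has_ferredoxin` / `has_ofor`.

## Comparative statistics

All statistics key on species (via the replicon metadata sidecar, so
multi-replicon species aggregate) or replicon type:

* **Co-presence**: entry (f, g) counts species containing ≥1 member of
  both families; diagonal = species carrying f; symmetric, off-diagonal
  bounded by the smaller diagonal.
* **Plasmid/chromosome split**: per-family member counts by replicon type;
  column sums conserve the assigned total.
* **Family saturation**: mean cumulative distinct families after k
  species, over random species orderings (default 100 permutations,
  explicit seed).  An `exhaustive` mode enumerates all N! orderings
  (N ≤ 8) for exact small cases.  The curve is non-decreasing and ends at
  the global family count.

## Phylogeny stage

Distances are `d = 1 − identity/100`; trees come from classical
neighbor-joining (scikit-bio's implementation behind the module surface),
which recovers additive matrices exactly.  Negative branch-length
estimates are clamped to zero with a warning.  Multiple alignment and
model-based inference are deliberately out of scope: the NJ tree is a
transparent, testable companion to the tables, and topology claims are
illustrative, not load-bearing.

## Synthetic studies

The generator (`synthetic_data`) emulates the *shape* of a multi-species
archaeal corpus with exact ground truth: P450 families mutated from seed
sequences to controlled identity bands (motif residues protected; bands
achieved by rejection sampling on identity measured with the identity
module itself, not by mutation-rate formulas), truncated fragments,
ferredoxins built residue-by-residue from stated spacing signatures over
cysteine-free backgrounds, OFOR annotation pairs, motif-free decoys (drawn
from an alphabet lacking C and R, so neither P450 motif can form), and
gene layouts whose planted operon blocks are recoverable by construction
(intra-block gaps 20–120 bp, inter-block spacers 400–1200 bp).  All
randomness flows from one integer seed through a single generator; the
same seed reproduces byte-identical files.

Deliberately **not** emulated: realistic sequence evolution (no
substitution model, no indels within families), codon-level DNA, and
annotation noise.  Tests passing on this material demonstrate that the
pipeline applies its rules exactly — not that the rules are complete for
real proteomes, where motif variants (e.g. ExxR deviations) and
non-canonical ferredoxins occur.

Default demo study: 3 species, 5 replicons (2 plasmids), 4 P450 families
(10 members + 1 fragment), 10 ferredoxins across all six types, 2 OFOR
pairs (one adjacent, one split across replicons), 3 decoys per replicon,
and one planted P450+ferredoxin operon.  Identity bands sit away from the
40/55 thresholds so recovery is unambiguous.

## Verification problem sizes

The test suite and `scripts/acceptance.py` run at desk scale: alignment
scores against exhaustive-enumeration oracles on all pairs up to length 2
plus 10⁴ seeded random pairs up to length 6 over a 4-letter alphabet; six
planted families × 8 members (within-family pairwise identity ≥60%,
between ≤30%) re-clustered to Rand index 1.0; a 50/10/20
full/fragment/decoy screen counted exactly; 100 ferredoxins across all six
types round-tripped; 100 random additive matrices (4–8 taxa) recovered by
NJ; saturation checked against full 3! enumeration; and 1,000 random gene
layouts segmented identically to a direct rule application.

## Known limitations

* Motif patterns are fixed regular expressions; highly diverged P450s
  whose ExxR/CxG deviate are missed, as in the published rule.
* The indel-adjusted identity comparisons occasionally quoted in survey
  discussions ("if one indel is removed …") are not implemented; reported
  identities are raw, so such cases remain auditable.
* Single-linkage clustering can chain families through intermediates; the
  condition is detected and logged, not prevented.
* The 2[4Fe-4S]Alv cutoff is an operational spacing rule, not a
  structural classification.
* Operon predictions are heuristic; use them comparatively, not as
  transcription-unit ground truth.
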