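# Methods

## Scope and model

`bovitf` identifies transcription factors (TFs) in an annotated genome
by the presence of a reliable sequence-specific DNA-binding domain
(DBD), then curates candidates into evidence classes against a human
reference census. The pipeline is deterministic end to end: given the
same input tables it produces the same compendium, cofactor list,
conservation groups and expression summaries. Randomness exists only in
the synthetic-data generator.

The underlying assumptions are worth stating plainly:

- *DBD presence defines candidacy.* A gene with no annotated reliable
  DBD is never considered, so the compendium inherits the completeness
  of the upstream domain annotation (InterPro entries on an assembled
  genome).
- *Orthology transfers evidence.* A candidate's class is largely decided
  by the census class of its human orthologue, gated by domain-
  arrangement agreement. This deliberately refuses plain orthology
  transfer: an orthologue whose architecture has diverged demotes the
  candidate rather than confirming it.
- *Flat GO usage.* Cofactor screening uses GO annotations as directly
  asserted, with no ancestor-closure over the ontology graph: the term
  lists are flat, and propagating them would change the meaning of the
  nucleus anchor term. Closure can be enabled explicitly when an
  ontology file is supplied.

## The curation cascade

Screened candidates receive exactly one class in {a, b, c, y} from an
ordered rule list (see `curation.assign_class`). Two points were
genuinely open and are resolved as follows:

- *Orthologues absent from the census.* A candidate whose human
  orthologue exists but is not a census member cannot inherit census
  evidence; it routes through the no-orthologue branch, where a curated
  literature update can still promote it to `a`. This matches how such
  genes are handled in practice — by manual literature inspection.
- *Similar-to-non-TF candidates.* Candidates whose only human evidence
  is sequence similarity to a known non-TF are assigned class `c`
  (rationale `similar_to_non_tf`) rather than being dropped from the
  output, so that {a, b, c, y} partitions the screened set and every
  stage count is auditable.

The override by literature evidence is applied after all other rules,
so curated experimental evidence always wins; this also makes
`assign_class` monotone in the similarity threshold (raising the
threshold can only demote, never promote — a property the test suite
asserts).

### Domain arrangements and similarity

A gene's arrangement is its domain accessions ordered by start
coordinate with *consecutive* duplicates collapsed: a tandem repeat of
one domain is one token, but alternations of distinct domains (A B A)
are preserved. Arrangement similarity is the optimal global alignment
score with match = 1 and mismatch/indel = 0 — equivalently the longest
common subsequence — normalized by the longer arrangement. This keeps
the identical (1.0) / highly-similar (≥ threshold) / diverged
(< threshold) trichotomy used during curation while remaining symmetric,
bounded in [0, 1] and trivially auditable. The default threshold is 0.8;
it is a parameter of every entry point and is recorded in the run
manifest. A more elaborate significance-based domain-alignment statistic
could substitute here without touching the cascade.

## Registry compilation

The reliable-DBD registry begins with the reference census DBD list and
is extended by database-intersection rounds: for one species, genes
present in *all* snapshots of the additional TF databases — after
removing genes the census marks `x`, and excluding genes the census
contains at all — contribute their domains. Contributed domains must be
flagged sequence-specific in a curated domain-function table (the check
is inherently manual, so the pipeline consumes it as an input rather
than parsing free text), and domains found on any census-`x` gene are
blacklisted. When a domain occurs on both a TF and a non-TF gene the
blacklist wins; this conservative tie rule is recorded in provenance.
Registry addition is idempotent and commutative over rounds (asserted
in tests), and the summary always satisfies
`total = n_domain + n_family`.

## Conservation grouping

Presence of a TF in a species is defined as ≥ 1 orthology relation of
any homology type to that species. The focal species is excluded from
every denominator (its presence is trivially true). The group is the
smallest clade of the nested chain Mammalia ⊂ Vertebrata ⊂ Metazoa ⊂
Eukaryota containing at least a fraction τ of the species where the TF
is present; within Mammalia, fraction 1.0 gives `mammal_only` and
anything in [τ, 1) gives `mammal_predominant`. "Predominantly" has no
canonical definition, so τ is a parameter (default 0.9) recorded in the
group report. A TF with no orthologue outside the focal species is
vacuously `mammal_only`. Clustering of the presence matrix uses Jaccard
distance with average linkage — the natural choice for binary profiles —
with rows and columns canonically sorted first so the result is
invariant to input permutation; both metric and linkage are
configurable, and results sensitive to them should be treated as
configuration-dependent.

## Cofactor confidence classes

Candidate cofactors are interaction partners of compendium TFs
(covalent-binding MI:0195, direct-interaction MI:0407 or
physical-association MI:0915 records only; TF–TF pairs and
self-interactions contribute nothing), filtered sequentially by GO:
nucleus (CC GO:0005634), then a transcription-related biological
process, then a transcription-related molecular function. Confidence is
then decided by evidence codes (EXP, IDA, IMP, IGI, IEP, IPI count as
experimental): experimental nucleus *and* experimental
transcription-related MF ⇒ high confidence; MF only ⇒ hypothetical I;
nucleus only ⇒ hypothetical II; neither ⇒ hypothetical III. BP
annotations gate the filter but deliberately do not affect the class:
the confidence statement is about *function*, and the MF set is the
functional one. Because interaction databases key records by protein
accession while the pipeline works in gene space, an explicit
protein-to-gene mapping table is a required input — it is never
inferred.

## Expression

Gene-level FPKM is the maximum over the gene's isoforms (a
presence-oriented collapse; `sum` is available). "Expressed" means
FPKM > threshold with threshold 0 by default — any signal counts —
matching the coexpression rule: a TF–cofactor pair is coexpressed in a
tissue where both genes are expressed. Pairs with a member absent from
the matrix are reported separately, not silently dropped. No biological
replication is modeled; the matrix is treated as a single-animal
snapshot, so no correlation-based coexpression is attempted.

Percentages everywhere are computed by `expression.pct`: exact decimal
arithmetic, rounded half-away-from-zero at the requested precision.

## The synthetic-data generator

`synthetic_data.generate_world` emits every input the pipeline consumes
— gene/domain tables for the focal and reference species, census and
update tables, orthology, TF-database snapshots, PSI-MITAB interactions,
GAF annotations, an FPKM matrix, pair lists, a clade map, family map and
alternative TF sets — from a single `WorldConfig`. Generation is
*truth-first*: the intended label of every gene, cofactor, TF and pair
is fixed first and the records are synthesized to be consistent with it,
so pipeline recovery is exact rather than statistical. Identical
configurations produce byte-identical bundles.

Two presets define the study conditions:

- `tiny` (~200 genes, 42 screened, 23-TF compendium, 12 cofactors) for
  fast unit tests — it runs the full pipeline in about a second.
- `paper_scale` (24,616 genes, 1,525 screened, an 865-TF compendium of
  704 `a` + 161 `b`, 62 diverged / 95 arrangement-unavailable / 24
  orphan genes, a 133-entry registry of 76 domain + 57 family entries, a
  94-entry census update, conservation groups 59/55/202/467/82 over 21
  species, 781 cofactors split 248/52/214/267 across the confidence
  classes, 31,799 interaction records of which 16,608 + 1,241 + 1 carry
  allowed MI types, 14 tissues with 680 TFs and 609 cofactors expressed,
  and 3,267 TF–cofactor pairs of which 2,514 are measurable and 1,937
  coexpressed). These magnitudes mirror a published bovine compendium
  and exercise every branch of every stage at realistic scale; the full
  generate-plus-run cycle takes a few seconds on one CPU.

What the generator does *not* emulate — and therefore what passing tests
do not show about real data: annotation errors and missing domain calls
(every planted TF carries its intended DBDs exactly), assembly artifacts
that truncate or split genes, disagreement between interaction
databases, GO annotations that are wrong rather than merely
non-experimental, and expression noise or replicate variance (presence
patterns are planted, FPKM magnitudes are decorative log-normal draws).
The recovery tests certify the *logic* of the pipeline, not the quality
of any particular annotation release.

Some structural choices inside the generator, fixed once:

- The 21-species clade map has 12 mammals (11 non-focal), 4 additional
  vertebrates, 2 additional metazoans and 3 non-metazoan eukaryotes —
  sizes chosen so that, at τ = 0.9, all five conservation groups are
  realizable and a TF present in every species classifies as
  `eukaryote` (its non-focal metazoan fraction is 17/20 = 0.85 < τ).
- Tissue-presence sets are prefix/suffix intervals over the tissue
  panel, which lets pair-level coexpression breadths be planted exactly
  (prefix ∩ prefix = shorter prefix; prefix ∩ suffix can be empty).
  A side effect is that per-tissue expression counts decline
  monotonically across the panel — harmless for the planted tallies,
  unrealistic as a tissue atlas.
- GO-filter attrition at study scale is planted as 1,200 candidates →
  1,000 in the nucleus → 900 with a listed process → 781 with a listed
  function. These stage sizes are the generator's own: because TF–TF
  partners are excluded *before* the GO filter, intermediate pool sizes
  that include TFs are not meaningful here.
- The arrangement-eligible count at study scale is 1,013 (856 confirmed
  via orthologues + 62 diverged + 95 unavailable); together with 5
  similarity-rescued and 4 literature-promoted genes this yields the
  865-gene compendium while keeping every stage count internally
  consistent.

## Numerical and degenerate-input choices

- Readers validate eagerly: missing columns name the column; malformed
  coordinates name the 1-based line; unparseable MITAB lines are
  skipped, warned about and counted, never silently dropped.
- Empty vs empty arrangements compare as identical (similarity 1.0);
  empty vs non-empty as 0.0.
- A constant presence matrix (all-true or all-false) cannot be
  clustered; the canonical sorted order is returned with a warning.
- Ties among equally similar orthologues are broken by census class
  (`a` before `b` before `other`) then lexicographic gene id, making
  `assign_class` fully deterministic.
- `pct` refuses a zero denominator rather than returning a sentinel.

## Known limitations

- The arrangement-similarity statistic is a normalized alignment score,
  not a significance test; candidates near the threshold deserve manual
  review, and the threshold itself is a tunable with no claim of
  optimality.
- Class `y` (reliable DBD, no orthologue, no described function) is a
  holding state, not a verdict; the same applies to arrangement-diverged
  class-`c` genes, whose divergence may be an assembly artifact of a
  draft genome rather than biology.
- The conservation grouping depends on the completeness of the input
  orthology table; absence of a relation is read as absence of the gene.
- Expression conclusions are bounded by the single-snapshot FPKM design:
  presence/absence only, no differential or correlation analysis.
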