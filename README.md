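# bovitf

A curation pipeline for building a compendium of sequence-specific
DNA-binding transcription factors (TFs) in cattle — and, around it, a
transcription-cofactor (TcoF) screen, cross-species conservation grouping,
and tissue-expression summaries.

Gene-regulation studies in livestock have usually borrowed the human TF
census wholesale, which misses lineage-specific regulators and imports
false positives whose domain architecture has diverged. `bovitf`
implements the alternative: identify TFs in the annotated *Bos taurus*
genome from first principles — the defining property of a TF being a
sequence-specific DNA-binding domain (DBD) — and then curate each
candidate against the evidence for its human orthologue.

The package is aimed at researchers in regulatory genomics who work from
standard annotation exports (BioMart-style domain tables, Compara-style
orthology, PSI-MITAB interactions, GAF annotations, FPKM matrices) and
want a reproducible, testable version of this curation workflow.

## The method

**1. Census update.** The human reference TF census carries evidence
classes: `a` (experimental evidence of TF function), `b` (domain
arrangement equivalent to an `a`-class TF), `c` (possible TF, no
functional evidence), `other` (unclassified DBD source), `x` (known
non-TF). Curated literature updates reclassify entries upward
(`b/c/other → a`).

**2. Reliable DBDs.** The registry of reliable DBDs (InterPro entries,
typed `domain` or `family`) starts from the census and is extended by
intersecting snapshots of additional TF databases: genes shared by every
snapshot of one species but absent from the census contribute their
domains, kept only if curated as sequence-specific DNA binders and not
found on known non-TF genes.

**3. Screening.** Every annotated gene carrying at least one registry
DBD becomes a candidate TF.

**4. Curation cascade.** Each candidate is assigned a class by fixed
rules, in order: pseudogenes → `c`; an orthologue the census marks `x`
→ `c`; an orthologue marked `c` → `c`; otherwise the best-matching
`a`/`b`/`other` orthologue decides — the candidate's *domain
arrangement* (the ordered sequence of its DBD accessions) is aligned
against the orthologue's, and a normalized global-alignment similarity
`s = LCS(x, y) / max(|x|, |y|)` at or above a threshold (default 0.8)
confirms the class (`a` for census-`a`, else `b`), while a lower score
demotes to `c` (diverged). Candidates without a census orthologue can be
rescued to `b` by a sequence-similarity hit to an `a`/`b` human gene
with a matching arrangement, demoted for similarity to a non-TF, or kept
as class `y` (reliable DBD, no orthologue, no described regulatory
function). Curated literature evidence overrides everything, last.
Classes `a` and `b` form the compendium.

The compendium is then characterized: DBD structural families
(multi-DBD TFs belong to every family they touch; families under five
members collapse into "other"), a TF × species orthologue
presence/absence matrix clustered with Jaccard distance and average
linkage plus a clade conservation group per TF (mammal-only,
mammal-predominant, vertebrate, metazoa, eukaryote — the smallest clade
holding ≥ τ of the species where the TF is present, τ = 0.9 by default),
a cofactor screen (interaction partners of TFs filtered to
covalent-binding / direct-interaction / physical-association records,
then to nucleus-localized, transcription-associated proteins by GO, and
classified high-confidence or hypothetical I/II/III by experimental GO
evidence codes), and expression summaries over an FPKM matrix (a gene is
expressed where its best isoform has FPKM > 0; a TF–TcoF pair is
coexpressed where both are expressed simultaneously).

Because the real inputs are large release-pinned database exports, the
package ships a first-class synthetic-data generator
(`bovitf.synthetic_data`) that emits every input format with planted
ground truth — intended class per gene, confidence class per cofactor,
conservation group per TF, coexpression breadth per pair — so the entire
pipeline is exercised and verified end-to-end without downloads.

## Worked example

Generate a small synthetic world and run the full pipeline:

```bash
bovitf synthesize --preset tiny --seed 4 --out demo/bundle
bovitf run-all --config demo/bundle/pipeline_config.yaml --out demo/run
```

The run prints the per-stage manifest; abridged:

```json
{
  "census_update": {"in": 133, "reclassified": 94},
  "build_registry": {"n_reference": 10, "human_novel_genes": 3,
                     "human_new_dbds": 1, "mouse_new_dbds": 5,
                     "n_domain": 11, "n_family": 5, "total": 16},
  "screen": {"in": 200, "out": 42},
  "curate": {"n_screened": 42, "n_post_removal": 34,
             "n_compendium": 23,
             "by_class": {"a": 13, "b": 10, "c": 15, "y": 4}}
}
```

Reading it: 94 census entries were reclassified to `a` on literature
evidence; the DBD registry grew from 10 reference entries to 16 via the
human (+1) and mouse (+5) database-intersection rounds; 42 of 200 genes
carry a reliable DBD; after the cascade, 23 form the compendium (13 `a`
+ 10 `b`), 15 were demoted to `c` (pseudogenes, non-TF orthologues,
diverged arrangements, …) and 4 are orphans (`y`). `demo/run/` holds the
per-gene tables (`candidates.tsv`, `compendium.tsv`, `tcofs.tsv`,
`coexpression.tsv`, `conservation_groups.tsv`, newick dendrograms) and
`manifest.json`.

Because the world is synthetic with planted truth, every one of these
numbers is checked against the plant — see
`bovitf.synthetic_data.recover_truth`.

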