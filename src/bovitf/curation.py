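"""DBD screening and manual-curation cascade for candidate TFs.

Screened genes (those carrying at least one registry DBD) are assigned a
final evidence class {a, b, c, y} by a fixed decision cascade over
biotype, orthology to the human reference census, domain-arrangement
similarity, and a sequence-similarity fallback for genes without
orthologues. Curated literature evidence, supplied as update records,
overrides the cascade last so that experimental evidence always wins.

Domain arrangements are ordered token sequences of InterPro accessions
(consecutive duplicates collapsed); similarity is a global token
alignment scoring 1 per match and 0 per mismatch/indel, normalized by the
longer arrangement — a configurable stand-in preserving the
identical / highly-similar / diverged trichotomy used during curation.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

from bovitf.census import Census
from bovitf.errors import ValidationError
from bovitf.records import (
    CandidateTF,
    EvidenceUpdate,
    GeneRecord,
    OrthologyRelation,
    SimilarityHit,
)

#: Default similarity above which arrangements count as identical/highly similar.
DEFAULT_THRESHOLD = 0.8

#: Homology types eligible for orthology-based curation.
QUALIFYING_HOMOLOGY = ("one2one", "one2many")


@dataclass(frozen=True)
class DomainArrangement:
    """Ordered InterPro accessions along a protein, tandem repeats collapsed."""

    tokens: tuple[str, ...]

    def __len__(self):
        return len(self.tokens)

    def __bool__(self):
        return bool(self.tokens)


def screen_for_dbds(genes: list[GeneRecord], registry) -> list[GeneRecord]:
    """Genes carrying at least one reliable DBD, input order preserved."""
    if not len(registry):
        raise ValidationError("cannot screen against an empty DBD registry")
    return [g for g in genes if any(h.interpro_id in registry for h in g.domain_hits)]


def arrangement_of(gene: GeneRecord) -> DomainArrangement:
    """Domain arrangement of a gene: accessions ordered by start coordinate,
    consecutive identical accessions collapsed to a single token (tandem
    repeats of one domain are one token; alternations of distinct domains
    are preserved)."""
    tokens: list[str] = []
    for hit in gene.domain_hits:  # already sorted by start
        if not tokens or tokens[-1] != hit.interpro_id:
            tokens.append(hit.interpro_id)
    return DomainArrangement(tuple(tokens))


def arrangement_similarity(x: DomainArrangement, y: DomainArrangement) -> float:
    """Normalized global-alignment similarity of two arrangements in [0, 1].

    Match scores 1, mismatch and indel score 0, so the optimal global
    alignment score equals the longest common subsequence; the score is
    normalized by max(|x|, |y|). Symmetric; 1.0 iff the token sequences
    are identical; 0.0 if exactly one side is empty.
    """
    a, b = x.tokens, y.tokens
    if not a and not b:
        return 1.0
    if not a or not b:
        return 0.0
    # LCS dynamic programme, O(|a|*|b|); arrangements are short.
    prev = [0] * (len(b) + 1)
    for ai in a:
        cur = [0]
        for j, bj in enumerate(b, start=1):
            cur.append(prev[j - 1] + 1 if ai == bj else max(prev[j], cur[-1]))
        prev = cur
    return prev[-1] / max(len(a), len(b))


def _class_preference(census_class: str) -> int:
    # tie-break preference when several orthologues share the best similarity
    return {"a": 0, "b": 1, "other": 2}.get(census_class, 3)


def assign_class(
    candidate: GeneRecord,
    orthologues: list[OrthologyRelation],
    census: Census,
    human_genes: dict[str, GeneRecord],
    evidence_updates: list[EvidenceUpdate] | None = None,
    hits: list[SimilarityHit] | None = None,
    threshold: float = DEFAULT_THRESHOLD,
    non_tf_exclusion: set[str] | None = None,
    reference_species: str = "homo_sapiens",
) -> CandidateTF:
    """Assign the final evidence class to one screened candidate.

    The cascade, applied in order:

    1. pseudogenes -> c ("pseudogene");
    2. any qualifying (one2one/one2many) orthologue of census class 'x'
       -> c ("non_tf_function");
    3. any qualifying orthologue of census class 'c' -> c ("orthologue_class_c");
    4. orthologues of class a/b/other: the best-similarity orthologue
       decides — similarity >= threshold gives class a (census 'a') or b
       (census 'b'/'other'); below threshold gives c ("arrangement_diverged");
       no orthologue with domain data gives c ("arrangement_unavailable");
    5. no census orthologue: a similarity hit to a census-a/b gene with
       arrangement similarity >= threshold rescues to b ("similarity_rescue");
       a hit to a census-'x' gene (or a gene on the manual exclusion list)
       gives c ("similar_to_non_tf"); otherwise y ("no_orthologue");
    6. an evidence update naming the candidate overrides to a
       ("literature_evidence") — applied last so curated evidence wins.

    Orthologues whose census class is 'absent' (gene not in the census at
    all) do not qualify for steps 2-4 and route the candidate through the
    no-orthologue branch, where literature evidence can still rescue it.

    Raises:
        ValidationError: if an orthologue or hit references a human gene
            absent from ``human_genes``.
    """
    evidence_updates = evidence_updates or []
    hits = hits or []
    non_tf_exclusion = non_tf_exclusion or set()

    override = next((u for u in evidence_updates if u.gene_id == candidate.gene_id), None)

    def finish(cls: str, rationale: str, orth: str | None = None, sim: float | None = None):
        if override is not None:
            return CandidateTF(candidate.gene_id, "a", "literature_evidence", orth, sim)
        return CandidateTF(candidate.gene_id, cls, rationale, orth, sim)

    # 1. pseudogenes never enter the compendium
    if candidate.biotype == "pseudogene":
        return finish("c", "pseudogene")

    qualifying = [
        r
        for r in orthologues
        if r.source_gene == candidate.gene_id
        and r.homology_type in QUALIFYING_HOMOLOGY
        and r.target_species == reference_species
    ]
    for r in qualifying:
        if r.target_gene not in human_genes:
            raise ValidationError(
                f"orthologue {r.target_gene} of {candidate.gene_id} is not a known human gene"
            )

    classes = {r.target_gene: census.classify(r.target_gene) for r in qualifying}

    # 2-3. orthologues flagged non-TF or unconfirmed in the census
    if any(c == "x" for c in classes.values()):
        return finish("c", "non_tf_function")
    if any(c == "c" for c in classes.values()):
        return finish("c", "orthologue_class_c")

    evidential = sorted(
        {g for g, c in classes.items() if c in ("a", "b", "other")}
    )
    if evidential:
        # 4. arrangement comparison against census orthologues with domain data
        own = arrangement_of(candidate)
        comparable = [g for g in evidential if human_genes[g].domain_hits]
        if not comparable:
            return finish("c", "arrangement_unavailable")
        scored = [
            (arrangement_similarity(own, arrangement_of(human_genes[g])), g)
            for g in comparable
        ]
        best_sim = max(s for s, _ in scored)
        best_gene = min(
            (g for s, g in scored if s == best_sim),
            key=lambda g: (_class_preference(census.classify(g)), g),
        )
        if best_sim >= threshold:
            cls = "a" if census.classify(best_gene) == "a" else "b"
            return finish(cls, "arrangement_conserved", best_gene, best_sim)
        return finish("c", "arrangement_diverged", best_gene, best_sim)

    # 5. no census orthologue: similarity-hit fallback
    own = arrangement_of(candidate)
    my_hits = sorted(
        (h for h in hits if h.query_gene == candidate.gene_id),
        key=lambda h: (-h.score, h.subject_gene),
    )
    for h in my_hits:
        if h.subject_gene not in human_genes:
            raise ValidationError(
                f"similarity hit subject {h.subject_gene} is not a known human gene"
            )
    rescue_sims = [
        arrangement_similarity(own, arrangement_of(human_genes[h.subject_gene]))
        for h in my_hits
        if census.classify(h.subject_gene) in ("a", "b")
        and human_genes[h.subject_gene].domain_hits
    ]
    if rescue_sims and max(rescue_sims) >= threshold:
        return finish("b", "similarity_rescue", None, max(rescue_sims))
    if any(
        census.classify(h.subject_gene) == "x" or h.subject_gene in non_tf_exclusion
        for h in my_hits
    ):
        return finish("c", "similar_to_non_tf")
    return finish("y", "no_orthologue")


def curate(
    screened: list[GeneRecord],
    orthology: list[OrthologyRelation],
    census: Census,
    human_genes: dict[str, GeneRecord],
    evidence_updates: list[EvidenceUpdate] | None = None,
    hits: list[SimilarityHit] | None = None,
    threshold: float = DEFAULT_THRESHOLD,
    non_tf_exclusion: set[str] | None = None,
    reference_species: str = "homo_sapiens",
) -> list[CandidateTF]:
    """Run the cascade over every screened gene (deterministic, order-stable)."""
    by_source: dict[str, list[OrthologyRelation]] = {}
    for r in orthology:
        by_source.setdefault(r.source_gene, []).append(r)
    by_query: dict[str, list[SimilarityHit]] = {}
    for h in hits or []:
        by_query.setdefault(h.query_gene, []).append(h)
    return [
        assign_class(
            g,
            by_source.get(g.gene_id, []),
            census,
            human_genes,
            evidence_updates,
            by_query.get(g.gene_id, []),
            threshold,
            non_tf_exclusion,
            reference_species,
        )
        for g in screened
    ]


def compendium(candidates: list[CandidateTF]) -> tuple[list[CandidateTF], dict]:
    """Final TF set (classes a and b) plus a partition report.

    The report gives counts per class and per rationale; class counts sum
    to the number of screened candidates, and the post-removal count
    (survivors of the pseudogene / non-TF-function / orthologue-'c'
    removals) and the arrangement-eligible count are both reported.
    """
    by_class = Counter(c.assigned_class for c in candidates)
    by_rationale = Counter(c.rationale for c in candidates)
    removed = (
        by_rationale["pseudogene"]
        + by_rationale["non_tf_function"]
        + by_rationale["orthologue_class_c"]
    )
    eligible = (
        by_rationale["arrangement_conserved"]
        + by_rationale["arrangement_diverged"]
        + by_rationale["arrangement_unavailable"]
    )
    final = [c for c in candidates if c.assigned_class in ("a", "b")]
    report = {
        "n_screened": len(candidates),
        "n_post_removal": len(candidates) - removed,
        "n_arrangement_eligible": eligible,
        "n_compendium": len(final),
        "by_class": dict(sorted(by_class.items())),
        "by_rationale": dict(sorted(by_rationale.items())),
    }
    return final, report
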