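"""Core record types shared across pipeline stages.

Records are lightweight frozen dataclasses; tables of records are moved
around as plain lists and converted to :class:`pandas.DataFrame` at I/O
boundaries only.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from bovitf.errors import ValidationError

#: Legal evidence classes of the human reference census.
CENSUS_CLASSES = frozenset({"a", "b", "c", "x", "other"})

#: Classes assigned to screened candidate TFs during curation.
CANDIDATE_CLASSES = frozenset({"a", "b", "c", "y"})

#: Legal homology types of comparative-genomics orthology tables.
HOMOLOGY_TYPES = frozenset({"one2one", "one2many", "many2many"})

#: Confidence classes for transcription cofactors.
TCOF_CLASSES = frozenset(
    {"high_confidence", "hypothetical_I", "hypothetical_II", "hypothetical_III"}
)

_IPR_RE = re.compile(r"^IPR\d{6}$")
_MI_RE = re.compile(r"^MI:\d{4}$")


def is_interpro_accession(acc: str) -> bool:
    """True for a syntactically valid InterPro accession (IPR + 6 digits)."""
    return bool(_IPR_RE.match(acc))


def is_mi_code(code: str) -> bool:
    """True for a syntactically valid molecular-interaction type code."""
    return bool(_MI_RE.match(code))


@dataclass(frozen=True, order=True)
class DomainHit:
    """One InterPro match on a protein, 1-based inclusive amino-acid coordinates."""

    interpro_id: str
    entry_type: str  # "domain" | "family"
    start: int
    end: int

    def __post_init__(self):
        if self.start < 1 or self.end < self.start:
            raise ValidationError(
                f"invalid domain interval [{self.start}, {self.end}] for {self.interpro_id}"
            )


@dataclass(frozen=True)
class GeneRecord:
    """A gene with biotype and ordered InterPro domain hits."""

    gene_id: str
    biotype: str  # "protein_coding" | "pseudogene" | "other"
    species: str = "bos_taurus"
    domain_hits: tuple[DomainHit, ...] = ()

    def __post_init__(self):
        if not self.gene_id:
            raise ValidationError("empty gene_id")
        ordered = tuple(sorted(self.domain_hits, key=lambda h: (h.start, h.end, h.interpro_id)))
        object.__setattr__(self, "domain_hits", ordered)

    @property
    def interpro_ids(self) -> set[str]:
        return {h.interpro_id for h in self.domain_hits}


@dataclass(frozen=True)
class CensusEntry:
    """Human reference census entry with its evidence class."""

    gene_id: str
    evidence_class: str
    note: str = ""

    def __post_init__(self):
        if self.evidence_class not in CENSUS_CLASSES:
            raise ValidationError(
                f"illegal census class {self.evidence_class!r} for {self.gene_id}"
            )


@dataclass(frozen=True)
class EvidenceUpdate:
    """Literature-derived reclassification of a census or candidate gene."""

    gene_id: str
    new_class: str
    citation: str = ""

    def __post_init__(self):
        if self.new_class not in CENSUS_CLASSES:
            raise ValidationError(f"illegal update class {self.new_class!r} for {self.gene_id}")


@dataclass(frozen=True)
class DbdEntry:
    """A reliable DNA-binding domain (InterPro entry) in the registry."""

    interpro_id: str
    entry_type: str  # "domain" | "family"
    provenance: str  # "reference_census" | "human_intersection" | "mouse_intersection"
    sequence_specific: bool = True

    def __post_init__(self):
        if not is_interpro_accession(self.interpro_id):
            raise ValidationError(f"malformed InterPro accession {self.interpro_id!r}")
        if self.entry_type not in ("domain", "family"):
            raise ValidationError(f"illegal entry_type {self.entry_type!r}")


@dataclass(frozen=True)
class OrthologyRelation:
    """A cross-species gene correspondence."""

    source_gene: str
    target_gene: str
    homology_type: str
    target_species: str

    def __post_init__(self):
        if self.homology_type not in HOMOLOGY_TYPES:
            raise ValidationError(f"illegal homology type {self.homology_type!r}")


@dataclass(frozen=True)
class SimilarityHit:
    """A sequence-similarity hit of a query gene against a human gene."""

    query_gene: str
    subject_gene: str
    score: float

    def __post_init__(self):
        if self.score < 0:
            raise ValidationError("similarity score must be >= 0")


@dataclass(frozen=True)
class CandidateTF:
    """A screened gene with its assigned curation class and rationale."""

    gene_id: str
    assigned_class: str
    rationale: str
    orthologue: str | None = None
    arrangement_similarity: float | None = None

    def __post_init__(self):
        if self.assigned_class not in CANDIDATE_CLASSES:
            raise ValidationError(f"illegal candidate class {self.assigned_class!r}")
        if self.rationale == "arrangement_diverged" and self.assigned_class != "c":
            raise ValidationError("arrangement_diverged rationale requires class c")


@dataclass(frozen=True)
class InteractionRecord:
    """A protein-protein interaction with its MI interaction-type code."""

    id_a: str
    id_b: str
    mi_type: str
    source: str = ""

    def __post_init__(self):
        if not is_mi_code(self.mi_type):
            raise ValidationError(f"malformed MI code {self.mi_type!r}")


@dataclass(frozen=True)
class GoAnnotation:
    """A GO annotation with aspect and evidence code."""

    protein_id: str
    go_id: str
    aspect: str  # "CC" | "MF" | "BP"
    evidence_code: str

    def __post_init__(self):
        if self.aspect not in ("CC", "MF", "BP"):
            raise ValidationError(f"illegal aspect {self.aspect!r}")


@dataclass(frozen=True)
class TcofRecord:
    """A putative transcription cofactor with confidence class and TF partners."""

    protein_id: str
    confidence_class: str
    interacting_tfs: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self):
        if self.confidence_class not in TCOF_CLASSES:
            raise ValidationError(f"illegal TcoF class {self.confidence_class!r}")
        if not self.interacting_tfs:
            raise ValidationError(f"TcoF {self.protein_id} has no TF partners")
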