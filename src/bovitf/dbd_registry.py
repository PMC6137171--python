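"""Compilation of the reliable DNA-binding-domain (DBD) registry.

The registry starts from the DBDs implied by the reference census and is
extended by two intersection rounds over snapshots of additional TF
databases: genes common to all snapshots of one species that are entirely
absent from the census are inspected, and their domains — if curated as
having sequence-specific DNA-binding function and not occurring on known
non-TF genes — are added as novel reliable DBDs.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from bovitf.errors import ValidationError
from bovitf.census import Census
from bovitf.records import DbdEntry


@dataclass
class TfDatabaseSnapshot:
    """A snapshot of one external TF database for one species."""

    name: str
    species: str  # "human" | "mouse"
    gene_ids: set[str]
    gene_to_domains: dict[str, set[str]]
    domain_types: dict[str, str]  # interpro_id -> "domain" | "family"

    def __post_init__(self):
        referenced = set().union(*self.gene_to_domains.values()) if self.gene_to_domains else set()
        untyped = referenced - set(self.domain_types)
        if untyped:
            raise ValidationError(
                f"snapshot {self.name}: domains without entry_type: {', '.join(sorted(untyped))}"
            )


@dataclass
class DbdRegistry:
    """The reliable-DBD list, keyed by InterPro accession."""

    entries: list[DbdEntry] = field(default_factory=list)

    def __post_init__(self):
        self._index = {e.interpro_id for e in self.entries}
        if len(self._index) != len(self.entries):
            raise ValidationError("registry contains duplicated accessions")

    def __contains__(self, interpro_id: str) -> bool:
        return interpro_id in self._index

    def __len__(self):
        return len(self.entries)

    @property
    def accessions(self) -> set[str]:
        return set(self._index)

    def add(self, entries: list[DbdEntry]) -> int:
        """Add entries, ignoring accessions already present; returns count added."""
        n = 0
        for e in entries:
            if e.interpro_id not in self._index:
                self.entries.append(e)
                self._index.add(e.interpro_id)
                n += 1
        return n


def intersect_novel_genes(
    snapshots: list[TfDatabaseSnapshot], census: Census
) -> set[str]:
    """Genes common to all snapshots but entirely absent from the census.

    Genes the census marks 'x' (known non-TFs) are removed from every
    snapshot before intersecting; genes present in the census under any
    class are then excluded from the result.
    """
    if len(snapshots) < 2:
        raise ValidationError("need at least two database snapshots to intersect")
    species = {s.species for s in snapshots}
    if len(species) != 1:
        raise ValidationError(f"snapshots of mixed species: {sorted(species)}")
    cleaned = [
        {g for g in s.gene_ids if census.classify(g) != "x"} for s in snapshots
    ]
    common = set.intersection(*cleaned)
    return {g for g in common if g not in census}


def derive_blacklist(
    snapshots: list[TfDatabaseSnapshot], census: Census, extra: set[str] | None = None
) -> set[str]:
    """Domains occurring on any census-'x' gene in the snapshots, plus extras.

    Blacklist-wins: a domain seen on both a TF and a known non-TF gene is
    blacklisted (the conservative rule; recorded in entry provenance).
    """
    blacklist = set(extra or ())
    for s in snapshots:
        for gene, domains in s.gene_to_domains.items():
            if census.classify(gene) == "x":
                blacklist |= domains
    return blacklist


def extract_candidate_dbds(
    novel_genes: set[str],
    snapshots: list[TfDatabaseSnapshot],
    sequence_specific: dict[str, bool],
    blacklist: set[str] | None = None,
    provenance: str = "human_intersection",
) -> list[DbdEntry]:
    """Candidate reliable DBDs on the novel genes.

    The union of domains annotated on the novel genes across snapshots,
    minus blacklisted accessions, restricted to domains the curated
    function table flags as sequence-specific DNA binders. Domains absent
    from the function table are treated as not sequence-specific.

    Raises:
        ValidationError: if a candidate domain has no declared entry_type
            in any snapshot.
    """
    blacklist = blacklist or set()
    candidate: set[str] = set()
    types: dict[str, str] = {}
    for s in snapshots:
        for g in novel_genes:
            for d in s.gene_to_domains.get(g, ()):
                candidate.add(d)
                if d in s.domain_types:
                    types[d] = s.domain_types[d]
    untyped = candidate - set(types)
    if untyped:
        raise ValidationError(f"domains without entry_type: {', '.join(sorted(untyped))}")
    kept = sorted(
        d for d in candidate if d not in blacklist and sequence_specific.get(d, False)
    )
    return [DbdEntry(d, types[d], provenance, True) for d in kept]


def registry_summary(registry: DbdRegistry) -> tuple[int, int, int]:
    """Counts by entry type: (n_domain, n_family, total)."""
    counts = Counter(e.entry_type for e in registry.entries)
    n_domain = counts.get("domain", 0)
    n_family = counts.get("family", 0)
    return n_domain, n_family, n_domain + n_family
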