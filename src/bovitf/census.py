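"""The human reference TF census and its literature-evidence updates.

The census divides high-confidence human TFs into evidence classes:
'a' (experimental evidence for regulatory function in a mammal), 'b'
(domain arrangement equivalent to an 'a'-class TF), 'c' (potential TF
without functional evidence), 'other' (unclassified DNA-binding domain
sources) and 'x' (known not to be a TF). Curated literature evidence can
reclassify entries, normally only towards more evidence (b/c/other -> a).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from bovitf.errors import ValidationError
from bovitf.records import CensusEntry, EvidenceUpdate

#: Moves permitted without force=True: only towards experimental evidence.
_UPWARD_MOVES = {("b", "a"), ("c", "a"), ("other", "a")}


@dataclass
class Census:
    """An in-memory census with O(1) class lookup."""

    entries: list[CensusEntry]
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self):
        self._index = {e.gene_id: i for i, e in enumerate(self.entries)}
        if len(self._index) != len(self.entries):
            raise ValidationError("census contains duplicated gene ids")

    def __len__(self):
        return len(self.entries)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._index

    def classify(self, gene_id: str) -> str:
        """Evidence class of a gene, or ``"absent"`` for ids not in the census."""
        i = self._index.get(gene_id)
        return self.entries[i].evidence_class if i is not None else "absent"

    def genes_of_class(self, evidence_class: str) -> set[str]:
        return {e.gene_id for e in self.entries if e.evidence_class == evidence_class}


def apply_updates(
    census: Census, updates: list[EvidenceUpdate], force: bool = False
) -> tuple[Census, int]:
    """Apply curated evidence updates to a census.

    Returns the updated census and the number of entries whose class
    actually changed. Membership is invariant: classes change, the gene set
    does not, and re-applying the same updates is a no-op.

    By default only upward moves (b -> a, c -> a, other -> a) are permitted,
    mirroring reclassification on new experimental evidence; ``force=True``
    permits arbitrary moves.

    Raises:
        ValidationError: if any update names a gene absent from the census,
            or (without force) requests a non-upward move.
    """
    unknown = sorted({u.gene_id for u in updates if u.gene_id not in census})
    if unknown:
        raise ValidationError(f"updates for unknown census genes: {', '.join(unknown)}")
    new_entries = list(census.entries)
    n_changed = 0
    for u in updates:
        i = census._index[u.gene_id]
        old = new_entries[i]
        if old.evidence_class == u.new_class:
            continue
        if not force and (old.evidence_class, u.new_class) not in _UPWARD_MOVES:
            raise ValidationError(
                f"non-upward reclassification {old.evidence_class} -> {u.new_class} "
                f"for {u.gene_id} requires force=True"
            )
        new_entries[i] = CensusEntry(old.gene_id, u.new_class, u.citation or old.note)
        n_changed += 1
    return Census(new_entries), n_changed


def classify_lookup(census: Census, gene_id: str) -> str:
    """Functional alias of :meth:`Census.classify`."""
    return census.classify(gene_id)
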