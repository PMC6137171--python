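"""Classification of compendium TFs into DBD structural families.

The family scheme is a curated input table (InterPro accession -> family
name, e.g. C2H2 zinc-finger, Homeodomain, bZIP, HLH). A TF with DBDs in
several families is a member of each (multi-membership), and families
with fewer than five members are collapsed into "other".
"""

from __future__ import annotations

from bovitf.errors import ValidationError
from bovitf.records import GeneRecord

OTHER_FAMILY = "other"


def classify_families(
    tfs: list[GeneRecord],
    family_map: dict[str, str],
    registry=None,
) -> dict[str, set[str]]:
    """Map family name -> set of TF gene ids (sets may overlap).

    Only registry DBDs are classified when a registry is given; otherwise
    every hit with a mapped accession counts. A registry DBD carried by a
    TF but missing from the family map is an error.
    """
    missing: set[str] = set()
    families: dict[str, set[str]] = {}
    for tf in tfs:
        accessions = tf.interpro_ids
        if registry is not None:
            accessions = {a for a in accessions if a in registry}
        for acc in accessions:
            fam = family_map.get(acc)
            if fam is None:
                if registry is not None:
                    missing.add(acc)
                continue
            families.setdefault(fam, set()).add(tf.gene_id)
    if missing:
        raise ValidationError(
            f"registry DBDs missing from the family map: {', '.join(sorted(missing))}"
        )
    return families


def collapse_small_families(
    family_sets: dict[str, set[str]], min_size: int = 5
) -> dict[str, set[str]]:
    """Merge families with fewer than ``min_size`` members into "other".

    Members are preserved (the total membership multiset is unchanged up
    to the merged family names) and the operation is idempotent: "other"
    itself is never re-collapsed.
    """
    out: dict[str, set[str]] = {}
    for fam, members in family_sets.items():
        if fam != OTHER_FAMILY and len(members) < min_size:
            out.setdefault(OTHER_FAMILY, set()).update(members)
        else:
            out.setdefault(fam, set()).update(members)
    return out


def family_distribution(family_sets: dict[str, set[str]]) -> list[tuple[str, int]]:
    """(family, n_members) sorted by decreasing size then name."""
    return sorted(((f, len(m)) for f, m in family_sets.items()), key=lambda t: (-t[1], t[0]))
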