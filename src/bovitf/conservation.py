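"""Cross-species conservation of the TF compendium.

A TF x species boolean presence matrix (one orthologue anywhere in the
species suffices) is hierarchically clustered (Jaccard distance, average
linkage — the natural choice for binary profiles; both configurable) and
each TF is assigned a clade conservation group from the smallest clade of
a nested chain (Mammalia < Vertebrata < Metazoa < Eukaryota) that
contains at least a fraction tau of the species where the TF is present.
The focal species is excluded from all fraction denominators, since its
own presence is trivially true.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from bovitf.errors import ValidationError
from bovitf.records import OrthologyRelation

logger = logging.getLogger(__name__)

#: Conservation group labels, innermost clade first.
GROUPS = ("mammal_only", "mammal_predominant", "vertebrate", "metazoa", "eukaryote")


@dataclass
class CladeMap:
    """Nested clade chain and each species' innermost clade.

    ``chain`` lists clades smallest-first (e.g. Mammalia, Vertebrata,
    Metazoa, Eukaryota); ``species_clade`` maps every species to its
    innermost clade. Membership of a clade includes all species of
    smaller clades (the chain is nested).
    """

    chain: tuple[str, ...]
    species_clade: dict[str, str]

    def __post_init__(self):
        bad = {s for s, c in self.species_clade.items() if c not in self.chain}
        if bad:
            raise ValidationError(f"species with unknown clade: {sorted(bad)}")

    def members(self, clade: str) -> set[str]:
        idx = self.chain.index(clade)
        return {
            s
            for s, c in self.species_clade.items()
            if self.chain.index(c) <= idx
        }


def build_presence(
    tf_ids: list[str],
    orthology: list[OrthologyRelation],
    species_list: list[str],
    focal_species: str = "bos_taurus",
) -> pd.DataFrame:
    """Boolean TF x species orthologue presence matrix.

    Cell (t, s) is True iff at least one orthology relation links t to any
    gene of species s. The focal species column, if listed, is all True.
    Relations to species outside ``species_list`` are ignored with a warning.
    """
    if not species_list:
        raise ValidationError("species_list must be non-empty")
    mat = pd.DataFrame(False, index=list(tf_ids), columns=list(species_list))
    tf_set = set(tf_ids)
    ignored = set()
    for r in orthology:
        if r.source_gene not in tf_set:
            continue
        if r.target_species not in mat.columns:
            ignored.add(r.target_species)
            continue
        mat.loc[r.source_gene, r.target_species] = True
    if focal_species in mat.columns:
        mat[focal_species] = True
    if ignored:
        logger.warning("orthology relations to species outside the matrix ignored: %s",
                       sorted(ignored))
    return mat


def _linkage_to_newick(Z: np.ndarray, labels: list[str]) -> str:
    """Serialize a SciPy linkage matrix as a newick string with branch lengths."""
    n = len(labels)
    heights = {i: 0.0 for i in range(n)}

    def node(i: int) -> str:
        if i < n:
            return labels[i]
        a, b, h, _ = Z[i - n]
        left, right = int(a), int(b)
        return (
            f"({node(left)}:{h - heights[left]:.6g},"
            f"{node(right)}:{h - heights[right]:.6g})"
        )

    for k, row in enumerate(Z):
        heights[n + k] = row[2]
    return node(n + len(Z) - 1) + ";"


def cluster_presence(
    matrix: pd.DataFrame,
    metric: str = "jaccard",
    method: str = "average",
) -> dict:
    """Hierarchically cluster rows and columns of a presence matrix.

    Rows (and columns) are sorted lexicographically before clustering so
    the result is invariant to input permutation; remaining ties in the
    dendrogram are resolved by SciPy's deterministic agglomeration order
    on that canonical input. Returns row/column leaf orders, linkage
    matrices, and newick serializations of both dendrograms.

    A constant matrix (all True or all False) cannot be clustered; the
    canonical (sorted) order is returned with a warning.
    """
    if matrix.shape[0] < 2:
        raise ValidationError("need at least two rows to cluster")
    canon = matrix.sort_index(axis=0).sort_index(axis=1)
    values = canon.to_numpy(dtype=bool)
    if values.all() or not values.any():
        warnings.warn("constant presence matrix; returning input order unclustered")
        return {
            "row_order": list(canon.index),
            "col_order": list(canon.columns),
            "row_linkage": None,
            "col_linkage": None,
            "row_newick": None,
            "col_newick": None,
        }

    def _one_axis(vals: np.ndarray, labels: list[str]):
        dist = pdist(vals, metric=metric)
        Z = hierarchy.linkage(dist, method=method)
        order = hierarchy.leaves_list(Z)
        return [labels[i] for i in order], Z, _linkage_to_newick(Z, labels)

    row_order, row_Z, row_nwk = _one_axis(values, list(canon.index))
    col_order, col_Z, col_nwk = _one_axis(values.T, list(canon.columns))
    return {
        "row_order": row_order,
        "col_order": col_order,
        "row_linkage": row_Z,
        "col_linkage": col_Z,
        "row_newick": row_nwk,
        "col_newick": col_nwk,
    }


def assign_group(
    row: pd.Series,
    clade_map: CladeMap,
    tau: float = 0.9,
    focal_species: str = "bos_taurus",
) -> str:
    """Conservation group of one TF from its presence profile.

    The group is the label of the smallest clade containing a fraction
    >= tau of the (non-focal) species where the TF is present; within the
    innermost clade, full presence concentration (fraction 1.0) gives
    "mammal_only" and partial gives "mammal_predominant". A TF with no
    orthologue outside the focal species is vacuously "mammal_only".
    """
    if row.empty:
        raise ValidationError("empty presence vector")
    present = {s for s, v in row.items() if v and s != focal_species}
    if not present:
        return GROUPS[0]
    labels = {0: None, 1: GROUPS[2], 2: GROUPS[3], 3: GROUPS[4]}
    for i, clade in enumerate(clade_map.chain):
        frac = len(present & clade_map.members(clade)) / len(present)
        if frac >= tau:
            if i == 0:
                return GROUPS[0] if frac == 1.0 else GROUPS[1]
            if i == len(clade_map.chain) - 1:
                return GROUPS[4]
            return labels.get(i, clade)
    return GROUPS[4]


def group_assignments(
    matrix: pd.DataFrame,
    clade_map: CladeMap,
    tau: float = 0.9,
    focal_species: str = "bos_taurus",
) -> pd.Series:
    """Group per TF; groups partition the TF set."""
    return pd.Series(
        {t: assign_group(matrix.loc[t], clade_map, tau, focal_species) for t in matrix.index},
        name="group",
    )


def conservation_tallies(
    matrix: pd.DataFrame, focal_species: str = "bos_taurus"
) -> dict:
    """Special tallies over the presence matrix.

    present_in_all: TFs present in every species column;
    exactly_two_species: TFs present in exactly two species (the focal
    species counts as one of the two when its column is in the matrix);
    absent_from_human_and_mouse: TFs with no orthologue in either.
    """
    counts = matrix.sum(axis=1)
    human_mouse = [s for s in ("homo_sapiens", "mus_musculus") if s in matrix.columns]
    absent_hm = (
        int((~matrix[human_mouse].any(axis=1)).sum()) if human_mouse else None
    )
    return {
        "present_in_all": int((counts == matrix.shape[1]).sum()),
        "exactly_two_species": int((counts == 2).sum()),
        "absent_from_human_and_mouse": absent_hm,
    }
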