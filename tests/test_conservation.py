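"""Presence matrix, binary-profile clustering, clade conservation groups."""

import itertools

import numpy as np
import pandas as pd
import pytest

from bovitf.conservation import (
    CladeMap,
    assign_group,
    build_presence,
    cluster_presence,
    conservation_tallies,
    group_assignments,
)
from bovitf.records import OrthologyRelation

CLADES = CladeMap(
    ("Mammalia", "Vertebrata", "Metazoa", "Eukaryota"),
    {
        **{f"mam{i}": "Mammalia" for i in range(10)},
        "bos_taurus": "Mammalia",
        "chicken": "Vertebrata",
        "zebrafish": "Vertebrata",
        "fly": "Metazoa",
        "yeast": "Eukaryota",
        "fission_yeast": "Eukaryota",
        "arabidopsis": "Eukaryota",
    },
)
SPECIES = sorted(CLADES.species_clade)


def rel(tf, sp, i=0):
    return OrthologyRelation(tf, f"{sp}_g{i}", "one2one", sp)


class TestBuildPresence:
    def test_cells_follow_relations(self):
        m = build_presence(["t1"], [rel("t1", "mam0"), rel("t1", "fly")], SPECIES)
        assert m.loc["t1", "mam0"] and m.loc["t1", "fly"]
        assert m.loc["t1", "bos_taurus"]  # focal column always true
        assert m.loc["t1"].sum() == 3

    def test_no_relations_gives_focal_only_row(self):
        m = build_presence(["t1"], [], SPECIES)
        assert m.loc["t1"].sum() == 1

    def test_matches_brute_force_cell_evaluation(self):
        rng = np.random.default_rng(5)
        tfs = [f"t{i}" for i in range(15)]
        relations = [
            rel(tfs[int(rng.integers(15))], SPECIES[int(rng.integers(len(SPECIES)))], k)
            for k in range(80)
        ]
        m = build_presence(tfs, relations, SPECIES)
        for t, s in itertools.product(tfs, SPECIES):
            expected = s == "bos_taurus" or any(
                r.source_gene == t and r.target_species == s for r in relations
            )
            assert bool(m.loc[t, s]) == expected

    def test_unknown_species_ignored_with_warning(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING):
            m = build_presence(["t1"], [rel("t1", "mars")], SPECIES)
        assert m.loc["t1"].sum() == 1
        assert "mars" in caplog.text


def naive_average_linkage(vectors):
    """Oracle: naive agglomerative clustering with Jaccard distance and
    average linkage; returns the sorted multiset of merge heights."""

    def jaccard(a, b):
        union = np.logical_or(a, b).sum()
        if union == 0:
            return 0.0
        return np.logical_xor(a, b).sum() / union

    clusters = {i: [i] for i in range(len(vectors))}
    dist = {
        (i, j): jaccard(vectors[i], vectors[j])
        for i in clusters
        for j in clusters
        if i < j
    }
    heights = []
    next_id = len(vectors)
    while len(clusters) > 1:
        (i, j), h = min(dist.items(), key=lambda kv: (kv[1], kv[0]))
        heights.append(h)
        merged = clusters.pop(i) + clusters.pop(j)
        dist = {k: v for k, v in dist.items() if i not in k and j not in k}
        for k, members in clusters.items():
            # unweighted average over all original-leaf pairs
            d = float(
                np.mean([jaccard(vectors[a], vectors[b]) for a in merged for b in members])
            )
            dist[(min(k, next_id), max(k, next_id))] = d
        clusters[next_id] = merged
        next_id += 1
    return sorted(heights)


class TestClustering:
    def test_identical_rows_adjacent_at_distance_zero(self):
        m = pd.DataFrame(
            [[1, 1, 0], [0, 0, 1], [1, 1, 0]],
            index=["a", "b", "c"],
            columns=["s1", "s2", "s3"],
        ).astype(bool)
        res = cluster_presence(m)
        order = res["row_order"]
        assert abs(order.index("a") - order.index("c")) == 1
        assert res["row_linkage"][0, 2] == 0.0

    def test_hand_computed_jaccard(self):
        from scipy.spatial.distance import pdist

        d = pdist(np.array([[1, 1, 0], [0, 0, 1]], dtype=bool), metric="jaccard")
        assert d[0] == 1.0

    def test_linkage_heights_match_naive_oracle(self):
        rng = np.random.default_rng(12)
        values = rng.random((20, 12)) < 0.45
        values[0] = True  # avoid all-false rows
        m = pd.DataFrame(values, index=[f"t{i:02d}" for i in range(20)],
                         columns=[f"s{i}" for i in range(12)])
        res = cluster_presence(m)
        got = sorted(res["row_linkage"][:, 2])
        expected = naive_average_linkage([values[i] for i in range(20)])
        assert np.allclose(got, expected)

    def test_row_permutation_invariance(self):
        rng = np.random.default_rng(3)
        values = rng.random((12, 8)) < 0.5
        idx = [f"t{i:02d}" for i in range(12)]
        m = pd.DataFrame(values, index=idx, columns=[f"s{i}" for i in range(8)])
        shuffled = m.sample(frac=1, random_state=9)
        r1, r2 = cluster_presence(m), cluster_presence(shuffled)
        assert r1["row_order"] == r2["row_order"]
        assert r1["row_newick"] == r2["row_newick"]

    def test_constant_matrix_warns_and_keeps_order(self):
        m = pd.DataFrame(True, index=["a", "b"], columns=["s1", "s2"])
        with pytest.warns(UserWarning, match="constant"):
            res = cluster_presence(m)
        assert res["row_order"] == ["a", "b"]

    def test_newick_parses_with_all_leaves(self):
        from io import StringIO

        from Bio import Phylo

        rng = np.random.default_rng(8)
        m = pd.DataFrame(
            rng.random((6, 5)) < 0.5,
            index=[f"t{i}" for i in range(6)],
            columns=[f"s{i}" for i in range(5)],
        )
        res = cluster_presence(m)
        tree = Phylo.read(StringIO(res["row_newick"]), "newick")
        assert {leaf.name for leaf in tree.get_terminals()} == set(m.index)


def presence_row(present):
    return pd.Series({s: s in present or s == "bos_taurus" for s in SPECIES})


class TestAssignGroup:
    def test_all_species_is_eukaryote(self):
        row = presence_row(set(SPECIES))
        assert assign_group(row, CLADES) == "eukaryote"

    def test_only_mammals_is_mammal_only(self):
        row = presence_row({f"mam{i}" for i in range(10)})
        assert assign_group(row, CLADES) == "mammal_only"

    def test_nine_of_ten_mammals_plus_fish_is_predominant(self):
        row = presence_row({f"mam{i}" for i in range(9)} | {"zebrafish"})
        # 9 of 10 present species are mammals: fraction 0.9 >= tau, < 1.0
        assert assign_group(row, CLADES, tau=0.9) == "mammal_predominant"

    def test_vertebrate_and_metazoa_groups(self):
        verts = {f"mam{i}" for i in range(5)} | {"chicken", "zebrafish"}
        assert assign_group(presence_row(verts), CLADES) == "vertebrate"
        assert assign_group(presence_row(verts | {"fly"}), CLADES) == "metazoa"

    def test_focal_only_row_is_vacuous_mammal_only(self):
        assert assign_group(presence_row(set()), CLADES) == "mammal_only"

    def test_tau_one_only_full_concentration(self):
        row = presence_row({f"mam{i}" for i in range(9)} | {"zebrafish"})
        # at tau=1.0 the mammal fraction 0.9 fails; escalate to full vertebrates
        assert assign_group(row, CLADES, tau=1.0) == "vertebrate"

    def test_groups_partition_tf_set(self):
        rng = np.random.default_rng(4)
        rows = {}
        for i in range(25):
            present = {s for s in SPECIES if s != "bos_taurus" and rng.random() < 0.5}
            rows[f"t{i}"] = presence_row(present)
        m = pd.DataFrame(rows).T
        groups = group_assignments(m, CLADES)
        assert len(groups) == 25
        assert set(groups.unique()) <= {
            "mammal_only", "mammal_predominant", "vertebrate", "metazoa", "eukaryote"
        }


class TestTallies:
    def test_tallies_match_brute_force(self):
        rng = np.random.default_rng(21)
        cols = ["bos_taurus", "homo_sapiens", "mus_musculus", "ovis_aries", "fly"]
        values = rng.random((30, 5)) < 0.5
        values[:, 0] = True
        m = pd.DataFrame(values, index=[f"t{i}" for i in range(30)], columns=cols)
        t = conservation_tallies(m)
        assert t["present_in_all"] == sum(1 for i in range(30) if values[i].all())
        assert t["exactly_two_species"] == sum(
            1 for i in range(30) if values[i].sum() == 2
        )
        assert t["absent_from_human_and_mouse"] == sum(
            1 for i in range(30) if not values[i, 1] and not values[i, 2]
        )
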