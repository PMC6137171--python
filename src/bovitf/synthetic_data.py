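"""Seeded synthetic annotation worlds with planted ground truth.

The generator emulates every input the pipeline consumes — BioMart-style
gene/domain tables, a human reference census with literature updates,
Compara-style orthology, TF-database snapshots, IntAct-style PSI-MITAB
interactions, GAF annotations and FPKM matrices — from a single
configuration. Truth is sampled first (each gene's intended curation
class, each cofactor's intended confidence class, each TF's intended
conservation group, each pair's intended coexpression breadth) and the
files are derived from it, so pipeline recovery is exact rather than
statistical: the classification cascade is deterministic and noise
enters only through the planted data.

Two presets are provided: ``tiny`` (a ~200-gene world for unit tests)
and ``paper_scale`` (a ~25k-gene world whose planted magnitudes follow
the bovine compendium study: 1,525 screened genes, an 865-gene TF
compendium, 781 cofactors in four confidence classes, 21 species, 14
tissues). Identical seeds yield byte-identical bundles.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from bovitf import data_io
from bovitf.census import Census
from bovitf.conservation import CladeMap
from bovitf.dbd_registry import TfDatabaseSnapshot
from bovitf.errors import ConfigError
from bovitf.records import (
    CensusEntry,
    DbdEntry,
    DomainHit,
    EvidenceUpdate,
    GeneRecord,
    GoAnnotation,
    InteractionRecord,
    OrthologyRelation,
    SimilarityHit,
)

# the six novel reliable DBD accessions added by the database-intersection
# rounds (one from the human round, five from the mouse round)
HUMAN_ROUND_DBD = "IPR013087"
MOUSE_ROUND_DBDS = ("IPR001523", "IPR008122", "IPR008123", "IPR017114", "IPR007087")
MOUSE_ROUND_TYPES = {
    "IPR001523": "family",
    "IPR008122": "domain",
    "IPR008123": "domain",
    "IPR017114": "domain",
    "IPR007087": "domain",
}

FOCAL = "bos_taurus"

#: 21 species: 12 mammals (focal included), +4 vertebrates, +2 metazoans, +3 other eukaryotes
SPECIES_CLADES = {
    FOCAL: "Mammalia",
    "homo_sapiens": "Mammalia",
    "mus_musculus": "Mammalia",
    "ovis_aries": "Mammalia",
    "sus_scrofa": "Mammalia",
    "canis_familiaris": "Mammalia",
    "equus_caballus": "Mammalia",
    "felis_catus": "Mammalia",
    "rattus_norvegicus": "Mammalia",
    "macaca_mulatta": "Mammalia",
    "pan_troglodytes": "Mammalia",
    "monodelphis_domestica": "Mammalia",
    "gallus_gallus": "Vertebrata",
    "xenopus_tropicalis": "Vertebrata",
    "danio_rerio": "Vertebrata",
    "anolis_carolinensis": "Vertebrata",
    "drosophila_melanogaster": "Metazoa",
    "caenorhabditis_elegans": "Metazoa",
    "saccharomyces_cerevisiae": "Eukaryota",
    "schizosaccharomyces_pombe": "Eukaryota",
    "arabidopsis_thaliana": "Eukaryota",
}
CLADE_CHAIN = ("Mammalia", "Vertebrata", "Metazoa", "Eukaryota")

TISSUES = (
    "ampulla", "white_blood_cells", "cerebral_cortex", "car_con", "car_ips",
    "gallbladder", "heart", "jejunum", "kidney", "liver", "lymph_nodes",
    "pons", "muscle", "spleen",
)

_EXP_CODES = ("IDA", "IMP", "IPI", "EXP", "IGI", "IEP")
_NONEXP_CODES = ("IEA", "ISS", "TAS")


@dataclass
class WorldConfig:
    """Full specification of a synthetic world; all counts are planted exactly."""

    seed: int
    n_genes: int
    n_tissues: int = 14

    # curation route counts (sum = screened genes)
    n_class_a_orth: int = 12
    n_class_b_orth: int = 8
    n_literature: int = 1
    n_rescue: int = 2
    n_diverged: int = 3
    n_unavailable: int = 2
    n_orth_c: int = 2
    n_non_tf: int = 3
    n_pseudogene: int = 3
    n_similar_non_tf: int = 2
    n_y: int = 4

    # census extras
    n_census_updates_b: int = 86
    n_census_updates_c: int = 8
    n_census_other: int = 5

    # registry
    n_reference_domain: int = 6
    n_reference_family: int = 4
    n_human_novel_genes: int = 3
    n_mouse_shared_genes: int = 5

    # conservation groups over the compendium (rescue genes are forced into
    # mammal_only: they have no human/mouse orthologue)
    group_counts: dict = field(default_factory=lambda: {
        "mammal_only": 4, "mammal_predominant": 3, "vertebrate": 5,
        "metazoa": 8, "eukaryote": 3,
    })
    n_metazoa_full: int = 2
    n_eukaryote_all: int = 1

    # DBD family plan: (family, start, end) half-open intervals over
    # compendium indices; intervals may overlap (multi-DBD TFs)
    family_plan: tuple = (
        ("C2H2 zinc-finger", 0, 14),
        ("Homeodomain", 6, 18),
        ("bZIP", 18, 21),
        ("HLH", 21, 23),
    )

    # cofactor screen
    tcof_class_counts: dict = field(default_factory=lambda: {
        "high_confidence": 4, "hypothetical_I": 2,
        "hypothetical_II": 3, "hypothetical_III": 3,
    })
    n_fail_nucleus: int = 2
    n_fail_bp: int = 2
    n_fail_mf: int = 2
    kept_type_counts: dict = field(default_factory=lambda: {
        "MI:0915": 40, "MI:0407": 8, "MI:0195": 1,
    })
    n_disallowed_records: int = 20
    n_tf_tf_records: int = 4

    # expression strata (TF: ubiquitous/single/intermediate; TcoF adds the
    # broad-prefix / narrow-prefix / suffix pools used for pair planting)
    tf_expr: dict = field(default_factory=lambda: {
        "ubiquitous": 4, "single": 3, "intermediate": 8,
    })
    tcof_expr: dict = field(default_factory=lambda: {
        "ubiquitous": 3, "single": 1, "broad": 2, "narrow": 2, "suffix": 2,
    })
    n_tf_isoforms: int = 18
    n_tcof_isoforms: int = 12

    # TF-TcoF pair strata
    pair_counts: dict = field(default_factory=lambda: {
        "all_tissues": 6, "broad": 4, "some": 5, "none": 3, "unmeasured": 4,
    })
    n_unmeasured_tf_pool: int = 4
    broad_cutoff: int = 10

    # database comparison
    n_in_all: int = 14
    n_in_two: int = 4
    n_in_one: int = 3
    n_reverse_non_tf: int = 2
    n_reverse_diverged: int = 1

    # ------------------------------------------------------------------
    @property
    def n_screened(self) -> int:
        return (
            self.n_class_a_orth + self.n_class_b_orth + self.n_literature
            + self.n_rescue + self.n_diverged + self.n_unavailable
            + self.n_orth_c + self.n_non_tf + self.n_pseudogene
            + self.n_similar_non_tf + self.n_y
        )

    @property
    def n_compendium(self) -> int:
        return self.n_class_a_orth + self.n_class_b_orth + self.n_literature + self.n_rescue

    @property
    def n_tcofs(self) -> int:
        return sum(self.tcof_class_counts.values())

    @property
    def n_registry(self) -> int:
        return self.n_reference_domain + self.n_reference_family + 6

    def validate(self) -> None:
        if self.n_genes < self.n_screened:
            raise ConfigError("n_genes smaller than the planted screened-gene count")
        if sum(self.group_counts.values()) != self.n_compendium:
            raise ConfigError("conservation group counts must sum to the compendium size")
        if self.group_counts.get("mammal_only", 0) < self.n_rescue:
            raise ConfigError("rescue genes are planted mammal_only; quota too small")
        covered = set()
        for _, start, end in self.family_plan:
            covered.update(range(start, end))
        if covered != set(range(self.n_compendium)):
            raise ConfigError("family plan must cover every compendium index exactly")
        n_edges = sum(v for k, v in self.pair_counts.items())
        n_kept = sum(self.kept_type_counts.values())
        n_fail = self.n_fail_nucleus + self.n_fail_bp + self.n_fail_mf
        if n_kept < n_edges + n_fail + self.n_tf_tf_records:
            raise ConfigError("kept_type_counts too small for planted edges")
        exp = self.tf_expr
        if exp["ubiquitous"] + exp["single"] + exp["intermediate"] > self.n_compendium:
            raise ConfigError("more expressed TFs than compendium members")
        if sum(self.tcof_expr.values()) > self.n_tcofs:
            raise ConfigError("more expressed TcoFs than TcoFs")
        if self.n_tf_isoforms < exp["ubiquitous"] + exp["single"] + exp["intermediate"]:
            raise ConfigError("fewer TF isoforms than expressed TF genes")
        if self.n_in_all + self.n_in_two + self.n_in_one > self.n_compendium:
            raise ConfigError("database-overlap buckets exceed the compendium")
        if self.n_reverse_non_tf > self.n_non_tf or self.n_reverse_diverged > self.n_diverged:
            raise ConfigError("reverse-comparison plants exceed available genes")
        if self.n_tissues != len(TISSUES):
            raise ConfigError("n_tissues must match the tissue panel")
        if self.broad_cutoff >= self.n_tissues - 1:
            raise ConfigError("broad_cutoff leaves no broad stratum")

    # ------------------------------------------------------------------
    @classmethod
    def tiny(cls, seed: int = 0) -> "WorldConfig":
        """A ~200-gene world for fast unit tests."""
        return cls(seed=seed, n_genes=200)

    @classmethod
    def paper_scale(cls, seed: int = 0) -> "WorldConfig":
        """A world at the magnitudes of the bovine compendium study."""
        return cls(
            seed=seed,
            n_genes=24616,
            n_class_a_orth=700,
            n_class_b_orth=156,
            n_literature=4,
            n_rescue=5,
            n_diverged=62,
            n_unavailable=95,
            n_orth_c=59,
            n_non_tf=100,
            n_pseudogene=60,
            n_similar_non_tf=260,
            n_y=24,
            n_census_updates_b=86,
            n_census_updates_c=8,
            n_census_other=20,
            n_reference_domain=71,
            n_reference_family=56,
            n_human_novel_genes=26,
            n_mouse_shared_genes=1162,
            group_counts={
                "mammal_only": 59, "mammal_predominant": 55, "vertebrate": 202,
                "metazoa": 467, "eukaryote": 82,
            },
            n_metazoa_full=83,
            n_eukaryote_all=15,
            family_plan=(
                ("C2H2 zinc-finger", 0, 596),
                ("Homeodomain", 253, 665),
                ("bZIP", 0, 83),
                ("HLH", 83, 160),
                ("NHR", 665, 705),
                ("Forkhead", 705, 735),
                ("HMG", 735, 760),
                ("ETS", 760, 785),
                ("POU", 785, 805),
                ("IRF", 805, 820),
                ("PAX", 820, 832),
                ("STAT", 832, 844),
                ("ZNF-GATA", 844, 854),
                ("HTH", 854, 861),
                ("DM", 861, 864),
                ("CP2", 864, 865),
            ),
            tcof_class_counts={
                "high_confidence": 248, "hypothetical_I": 52,
                "hypothetical_II": 214, "hypothetical_III": 267,
            },
            n_fail_nucleus=200,
            n_fail_bp=100,
            n_fail_mf=119,
            kept_type_counts={"MI:0915": 16608, "MI:0407": 1241, "MI:0195": 1},
            n_disallowed_records=13949,
            n_tf_tf_records=300,
            tf_expr={"ubiquitous": 156, "single": 60, "intermediate": 464},
            tcof_expr={"ubiquitous": 248, "single": 16, "broad": 120,
                       "narrow": 150, "suffix": 75},
            n_tf_isoforms=714,
            n_tcof_isoforms=635,
            pair_counts={"all_tissues": 278, "broad": 720, "some": 939,
                         "none": 577, "unmeasured": 753},
            n_unmeasured_tf_pool=285,
            n_in_all=720,
            n_in_two=92,
            n_in_one=36,
            n_reverse_non_tf=92,
            n_reverse_diverged=35,
        )


@dataclass
class WorldTruth:
    """Intended labels, generated before the data files are derived."""

    gene_class: dict  # bovine gene id -> (class, rationale)
    tcof_class: dict  # protein id -> confidence class
    tf_group: dict  # compendium gene id -> conservation group
    pair_coexpression: dict  # "tf|tcof" -> intended n coexpressed tissues
    expected: dict  # headline tallies derivable from the config

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, sort_keys=True) + "\n")

    @classmethod
    def from_json(cls, path) -> "WorldTruth":
        return cls(**json.loads(Path(path).read_text()))


def _plant_pairs(tfs: list[str], tcofs: list[str], n: int) -> list[tuple[str, str]]:
    """n distinct (tf, tcof) pairs covering both pools (requires n >= max sizes)."""
    a, b = len(tfs), len(tcofs)
    if n == 0:
        return []
    if n > a * b:
        raise ConfigError(f"cannot plant {n} distinct pairs from {a}x{b} pools")
    if n < max(a, b):
        raise ConfigError(f"{n} pairs cannot cover pools of {a} and {b}")
    out: list[tuple[str, str]] = []
    if a >= b:
        for offset in range(b):
            for i in range(a):
                out.append((tfs[i], tcofs[(i + offset) % b]))
                if len(out) == n:
                    return out
    else:
        for offset in range(a):
            for j in range(b):
                out.append((tfs[(j + offset) % a], tcofs[j]))
                if len(out) == n:
                    return out
    raise AssertionError("unreachable")


class WorldBuilder:
    """Derives a complete, mutually consistent input bundle from a config."""

    def __init__(self, config: WorldConfig):
        config.validate()
        self.cfg = config
        self.rng = np.random.default_rng(config.seed)
        self.tissues = list(TISSUES[: config.n_tissues])
        self._build_ids()
        self._build_registry()
        self._build_census()
        self._build_families()
        self._build_bovine_genes()
        self._build_human_genes()
        self._build_orthology()
        self._build_snapshots()
        self._build_tcofs()
        self._build_expression()
        self._build_alt_sets()
        self._build_truth()

    # -- identifiers ----------------------------------------------------
    def _build_ids(self):
        c = self.cfg
        gid = iter(f"BOV{i:05d}" for i in range(c.n_genes))
        take = lambda n: [next(gid) for _ in range(n)]
        self.ids_a_orth = take(c.n_class_a_orth)
        self.ids_b_orth = take(c.n_class_b_orth)
        self.ids_literature = take(c.n_literature)
        self.ids_rescue = take(c.n_rescue)
        self.ids_diverged = take(c.n_diverged)
        self.ids_unavailable = take(c.n_unavailable)
        self.ids_orth_c = take(c.n_orth_c)
        self.ids_non_tf = take(c.n_non_tf)
        self.ids_pseudo = take(c.n_pseudogene)
        self.ids_similar_non_tf = take(c.n_similar_non_tf)
        self.ids_y = take(c.n_y)
        self.ids_background = list(gid)
        self.compendium_ids = (
            self.ids_a_orth + self.ids_b_orth + self.ids_literature + self.ids_rescue
        )
        self.screened_ids = (
            self.compendium_ids + self.ids_diverged + self.ids_unavailable
            + self.ids_orth_c + self.ids_non_tf + self.ids_pseudo
            + self.ids_similar_non_tf + self.ids_y
        )

    # -- DBD registry ---------------------------------------------------
    def _build_registry(self):
        c = self.cfg
        self.ref_dbds = [
            DbdEntry(f"IPR{100000 + i}", "domain" if i < c.n_reference_domain else "family",
                     "reference_census", True)
            for i in range(c.n_reference_domain + c.n_reference_family)
        ]
        self.registry_accs = (
            [e.interpro_id for e in self.ref_dbds] + [HUMAN_ROUND_DBD] + list(MOUSE_ROUND_DBDS)
        )
        self.decoy_accs = [f"IPR{200000 + i}" for i in range(20)]
        self.filler_accs = [f"IPR{300000 + i}" for i in range(4)]
        self.domain_function = {a: True for a in self.registry_accs}
        self.domain_function.update({a: False for a in self.decoy_accs + self.filler_accs})

    # -- census ---------------------------------------------------------
    def _build_census(self):
        c = self.cfg
        mk = lambda prefix, n: [f"{prefix}{i:04d}" for i in range(n)]
        self.hsa_a = mk("HSA_A", c.n_class_a_orth)
        self.hsa_b = mk("HSA_B", c.n_class_b_orth)
        self.hsa_div = mk("HSA_D", c.n_diverged)
        self.hsa_unav = mk("HSA_U", c.n_unavailable)
        self.hsa_c = mk("HSA_C", c.n_orth_c)
        self.hsa_x = mk("HSA_X", c.n_non_tf)
        self.hsa_rescue = mk("HSA_R", c.n_rescue)
        self.hsa_x_subjects = mk("HSA_XS", max(1, min(3, c.n_similar_non_tf)))
        self.hsa_upd_b = mk("HSA_UB", c.n_census_updates_b)
        self.hsa_upd_c = mk("HSA_UC", c.n_census_updates_c)
        self.hsa_other = mk("HSA_O", c.n_census_other)
        self.hsa_literature = mk("HSA_L", c.n_literature)  # NOT census members
        self.census_entries = (
            [CensusEntry(g, "a") for g in self.hsa_a + self.hsa_div + self.hsa_unav
             + self.hsa_rescue]
            + [CensusEntry(g, "b") for g in self.hsa_b + self.hsa_upd_b]
            + [CensusEntry(g, "c") for g in self.hsa_c + self.hsa_upd_c]
            + [CensusEntry(g, "x") for g in self.hsa_x + self.hsa_x_subjects]
            + [CensusEntry(g, "other") for g in self.hsa_other]
        )
        self.census_updates = (
            [EvidenceUpdate(g, "a", "new experimental evidence") for g in self.hsa_upd_b]
            + [EvidenceUpdate(g, "a", "new experimental evidence") for g in self.hsa_upd_c]
        )
        self.candidate_updates = [
            EvidenceUpdate(g, "a", "experimental TF evidence for the orthologue")
            for g in self.ids_literature
        ]

    # -- DBD families & compendium domain architecture ------------------
    def _build_families(self):
        c = self.cfg
        names = [f for f, _, _ in c.family_plan]
        pools = {f: self.registry_accs[i :: len(names)] for i, f in enumerate(names)}
        for f, pool in pools.items():
            if not pool:
                raise ConfigError(f"no registry accession available for family {f}")
        self.family_map = {}
        for f, pool in pools.items():
            for acc in pool:
                self.family_map[acc] = f
        # arrangement (ordered accession tuple) per compendium index
        self.arrangements: dict[str, tuple[str, ...]] = {}
        for idx, gene in enumerate(self.compendium_ids):
            tokens = [
                pools[f][idx % len(pools[f])]
                for f, start, end in c.family_plan
                if start <= idx < end
            ]
            self.arrangements[gene] = tuple(tokens)
        # non-compendium screened genes carry a single registry DBD
        others = (
            self.ids_diverged + self.ids_unavailable + self.ids_orth_c
            + self.ids_non_tf + self.ids_pseudo + self.ids_similar_non_tf + self.ids_y
        )
        for i, gene in enumerate(others):
            self.arrangements[gene] = (self.registry_accs[i % len(self.registry_accs)],)

    def _hits_for(self, tokens: tuple[str, ...], types: dict[str, str]) -> tuple[DomainHit, ...]:
        return tuple(
            DomainHit(acc, types.get(acc, "domain"), 1 + 100 * i, 80 + 100 * i)
            for i, acc in enumerate(tokens)
        )

    # -- bovine gene table ----------------------------------------------
    def _build_bovine_genes(self):
        types = {e.interpro_id: e.entry_type for e in self.ref_dbds}
        types[HUMAN_ROUND_DBD] = "domain"
        types.update(MOUSE_ROUND_TYPES)
        self.domain_types = types
        genes = []
        for gene in self.screened_ids:
            biotype = "pseudogene" if gene in set(self.ids_pseudo) else "protein_coding"
            genes.append(
                GeneRecord(gene, biotype, FOCAL, self._hits_for(self.arrangements[gene], types))
            )
        # background genes: most have no annotated domains, some carry decoys
        draws = self.rng.random(len(self.ids_background))
        for gene, u in zip(self.ids_background, draws):
            if u < 0.3:
                acc = self.decoy_accs[int(u * 1000) % len(self.decoy_accs)]
                hits = (DomainHit(acc, "domain", 1, 80),)
            else:
                hits = ()
            genes.append(GeneRecord(gene, "protein_coding", FOCAL, hits))
        self.bovine_genes = genes

    # -- human gene table -----------------------------------------------
    def _build_human_genes(self):
        types = self.domain_types
        records = {}

        def add(gene_id, tokens):
            records[gene_id] = GeneRecord(
                gene_id, "protein_coding", "homo_sapiens", self._hits_for(tokens, types)
            )

        for bov, hsa in zip(self.ids_a_orth, self.hsa_a):
            add(hsa, self.arrangements[bov])
        for bov, hsa in zip(self.ids_b_orth, self.hsa_b):
            add(hsa, self.arrangements[bov])
        for bov, hsa in zip(self.ids_diverged, self.hsa_div):
            add(hsa, self.arrangements[bov] + tuple(self.filler_accs))
        for hsa in self.hsa_unav:
            add(hsa, ())  # no domain data: arrangement not comparable
        for bov, hsa in zip(self.ids_rescue, self.hsa_rescue):
            add(hsa, self.arrangements[bov])
        for bov, hsa in zip(self.ids_literature, self.hsa_literature):
            add(hsa, self.arrangements[bov])
        for hsa in (
            self.hsa_c + self.hsa_x + self.hsa_x_subjects + self.hsa_upd_b
            + self.hsa_upd_c + self.hsa_other
        ):
            add(hsa, (self.decoy_accs[0],))
        self.human_genes = records

    # -- orthology (curation + conservation) ----------------------------
    def _group_species(self, group: str, rescue_rank: int | None) -> list[str]:
        mammals = [s for s, c in SPECIES_CLADES.items() if c == "Mammalia" and s != FOCAL]
        verts = mammals + [s for s, c in SPECIES_CLADES.items() if c == "Vertebrata"]
        metaz = verts + [s for s, c in SPECIES_CLADES.items() if c == "Metazoa"]
        euk = metaz + [s for s, c in SPECIES_CLADES.items() if c == "Eukaryota"]
        if rescue_rank is not None:
            # no human/mouse orthologue; first few span exactly two species
            return ["ovis_aries"] if rescue_rank < max(1, self.cfg.n_rescue - 1) else [
                "ovis_aries", "sus_scrofa"
            ]
        if group == "mammal_only":
            return mammals
        if group == "mammal_predominant":
            kept = [m for m in mammals if m != "monodelphis_domestica"]
            return kept + ["gallus_gallus"]
        if group == "vertebrate":
            return verts
        if group == "metazoa_full":
            return metaz
        if group == "metazoa":
            return [s for s in metaz if s != "anolis_carolinensis"]
        if group == "eukaryote_all":
            return euk
        if group == "eukaryote":
            drop = {"caenorhabditis_elegans", "arabidopsis_thaliana"}
            return [s for s in euk if s not in drop]
        raise AssertionError(group)

    def _build_orthology(self):
        c = self.cfg
        relations: list[OrthologyRelation] = []

        def human_rel(bov, hsa, i):
            htype = "one2many" if i % 5 == 4 else "one2one"
            relations.append(OrthologyRelation(bov, hsa, htype, "homo_sapiens"))

        for i, (bov, hsa) in enumerate(zip(self.ids_a_orth, self.hsa_a)):
            human_rel(bov, hsa, i)
        for i, (bov, hsa) in enumerate(zip(self.ids_b_orth, self.hsa_b)):
            human_rel(bov, hsa, i)
        for i, (bov, hsa) in enumerate(zip(self.ids_literature, self.hsa_literature)):
            human_rel(bov, hsa, i)
        for i, (bov, hsa) in enumerate(zip(self.ids_diverged, self.hsa_div)):
            human_rel(bov, hsa, i)
        for i, (bov, hsa) in enumerate(zip(self.ids_unavailable, self.hsa_unav)):
            human_rel(bov, hsa, i)
        for i, (bov, hsa) in enumerate(zip(self.ids_orth_c, self.hsa_c)):
            human_rel(bov, hsa, i)
        for i, (bov, hsa) in enumerate(zip(self.ids_non_tf, self.hsa_x)):
            human_rel(bov, hsa, i)
        # many2many relations are ignored by curation; plant a few on y genes
        if self.hsa_a:
            for bov in self.ids_y[: min(5, len(self.ids_y))]:
                relations.append(
                    OrthologyRelation(bov, self.hsa_a[0], "many2many", "homo_sapiens")
                )

        # conservation groups (assigned over the compendium; rescue forced
        # into mammal_only since they lack human/mouse orthologues)
        rescue_set = list(self.ids_rescue)
        non_rescue = [g for g in self.compendium_ids if g not in set(rescue_set)]
        groups: dict[str, str] = {g: "mammal_only" for g in rescue_set}
        quota = dict(c.group_counts)
        quota["mammal_only"] -= len(rescue_set)
        order = ["mammal_only", "mammal_predominant", "vertebrate", "metazoa", "eukaryote"]
        it = iter(non_rescue)
        for grp in order:
            for _ in range(quota[grp]):
                groups[next(it)] = grp
        self.tf_group = groups

        metazoa_ids = [g for g in self.compendium_ids if groups[g] == "metazoa"]
        eukaryote_ids = [g for g in self.compendium_ids if groups[g] == "eukaryote"]
        metazoa_full = set(metazoa_ids[: c.n_metazoa_full])
        eukaryote_all = set(eukaryote_ids[: c.n_eukaryote_all])
        self._metazoa_full = metazoa_full
        self._eukaryote_all = eukaryote_all

        human_linked = set(
            self.ids_a_orth + self.ids_b_orth + self.ids_literature
        )
        for gene in self.compendium_ids:
            grp = groups[gene]
            if gene in set(rescue_set):
                species = self._group_species(grp, rescue_set.index(gene))
            elif gene in metazoa_full:
                species = self._group_species("metazoa_full", None)
            elif gene in eukaryote_all:
                species = self._group_species("eukaryote_all", None)
            else:
                species = self._group_species(grp, None)
            for sp in species:
                if sp == "homo_sapiens" and gene in human_linked:
                    continue  # already linked via the census orthologue
                relations.append(
                    OrthologyRelation(gene, f"{sp.upper()}_{gene}", "one2one", sp)
                )
        self.orthology = relations

        self.hits = [
            SimilarityHit(bov, hsa, 95.0)
            for bov, hsa in zip(self.ids_rescue, self.hsa_rescue)
        ] + [
            SimilarityHit(bov, self.hsa_x_subjects[i % len(self.hsa_x_subjects)], 88.0)
            for i, bov in enumerate(self.ids_similar_non_tf)
        ]

    # -- TF database snapshots ------------------------------------------
    def _build_snapshots(self):
        c = self.cfg
        novel = [f"HNOV{i:04d}" for i in range(c.n_human_novel_genes)]
        shared_census = self.hsa_a[: min(10, len(self.hsa_a))]
        shared_x = self.hsa_x_subjects[:2]
        blk_domain = self.decoy_accs[1]
        self.human_snapshots = []
        for k, name in enumerate(("DBDdb", "AnimalTFDB", "CisBP")):
            gene_ids = set(novel) | set(shared_census) | set(shared_x) | {f"H{k}_U0"}
            g2d = {g: {HUMAN_ROUND_DBD} for g in novel}
            g2d.update({g: {self.registry_accs[0]} for g in shared_census})
            g2d.update({g: {blk_domain} for g in shared_x})
            g2d[f"H{k}_U0"] = {self.decoy_accs[2]}
            types = {
                HUMAN_ROUND_DBD: "domain",
                self.registry_accs[0]: "domain",
                blk_domain: "domain",
                self.decoy_accs[2]: "domain",
            }
            self.human_snapshots.append(
                TfDatabaseSnapshot(name, "human", gene_ids, g2d, types)
            )
        mshared = [f"MNOV{i:04d}" for i in range(c.n_mouse_shared_genes)]
        self.mouse_snapshots = []
        for k, name in enumerate(("DBDdb", "AnimalTFDB", "CisBP")):
            gene_ids = set(mshared) | {f"M{k}_U0"}
            g2d = {
                g: {MOUSE_ROUND_DBDS[i % len(MOUSE_ROUND_DBDS)]}
                for i, g in enumerate(mshared)
            }
            g2d[f"M{k}_U0"] = {self.decoy_accs[3]}
            types = dict(MOUSE_ROUND_TYPES)
            types[self.decoy_accs[3]] = "domain"
            self.mouse_snapshots.append(
                TfDatabaseSnapshot(name, "mouse", gene_ids, g2d, types)
            )

    # -- cofactors: interactions + GO -----------------------------------
    def _build_tcofs(self):
        c = self.cfg
        self.tcof_ids = []
        self.tcof_class = {}
        i = 0
        for cls, n in c.tcof_class_counts.items():
            for _ in range(n):
                pid = f"TCOF{i:04d}"
                self.tcof_ids.append(pid)
                self.tcof_class[pid] = cls
                i += 1
        self.fail_nucleus = [f"FNUC{i:04d}" for i in range(c.n_fail_nucleus)]
        self.fail_bp = [f"FBP{i:04d}" for i in range(c.n_fail_bp)]
        self.fail_mf = [f"FMF{i:04d}" for i in range(c.n_fail_mf)]

        # expression strata for TFs and TcoFs drive the pair plants
        t = c.tf_expr
        comp = self.compendium_ids
        self.tf_ubiq = comp[: t["ubiquitous"]]
        self.tf_single = comp[t["ubiquitous"]: t["ubiquitous"] + t["single"]]
        n_expr = t["ubiquitous"] + t["single"] + t["intermediate"]
        self.tf_intermediate = comp[t["ubiquitous"] + t["single"]: n_expr]
        self.tf_unexpressed = comp[n_expr:]

        s = c.tcof_expr
        cuts = np.cumsum([s["ubiquitous"], s["single"], s["broad"], s["narrow"], s["suffix"]])
        tc = self.tcof_ids
        self.tcof_ubiq = tc[: cuts[0]]
        self.tcof_single = tc[cuts[0]: cuts[1]]
        self.tcof_broad = tc[cuts[1]: cuts[2]]
        self.tcof_narrow = tc[cuts[2]: cuts[3]]
        self.tcof_suffix = tc[cuts[3]: cuts[4]]
        self.tcof_unexpressed = tc[cuts[4]:]

        p = c.pair_counts
        pairs: list[tuple[str, str]] = []
        pairs += _plant_pairs(self.tf_ubiq, self.tcof_ubiq, p["all_tissues"])
        pairs += _plant_pairs(self.tf_ubiq, self.tcof_broad, p["broad"])
        pairs += _plant_pairs(self.tf_ubiq, self.tcof_narrow + self.tcof_single, p["some"])
        pairs += _plant_pairs(self.tf_single, self.tcof_suffix, p["none"])
        pool = (self.tf_unexpressed + self.tf_intermediate)[: c.n_unmeasured_tf_pool]
        pairs += _plant_pairs(pool, self.tcof_unexpressed, p["unmeasured"])
        if len(set(pairs)) != len(pairs):
            raise ConfigError("pair plants collided; adjust strata sizes")
        self.edges = pairs

        # kept records: edges + GO-filter casualties + TF-TF + duplicates
        kept: list[tuple[str, str]] = list(pairs)
        fails = self.fail_nucleus + self.fail_bp + self.fail_mf
        kept += [(comp[j % len(comp)], f) for j, f in enumerate(fails)]
        kept += [
            (comp[j % len(comp)], comp[(j + 1) % len(comp)])
            for j in range(c.n_tf_tf_records)
        ]
        n_dup = sum(c.kept_type_counts.values()) - len(kept)
        kept += [pairs[j % len(pairs)] for j in range(n_dup)]
        types = (
            ["MI:0195"] * c.kept_type_counts.get("MI:0195", 0)
            + ["MI:0407"] * c.kept_type_counts.get("MI:0407", 0)
            + ["MI:0915"] * c.kept_type_counts.get("MI:0915", 0)
        )
        records = [
            InteractionRecord(a, b, t, "intact") for (a, b), t in zip(kept, types)
        ]
        bad_types = ["MI:0403", "MI:0914"]
        records += [
            InteractionRecord(f"BGP{j:05d}", comp[j % len(comp)], bad_types[j % 2], "intact")
            for j in range(c.n_disallowed_records)
        ]
        order = self.rng.permutation(len(records))
        self.interactions = [records[int(k)] for k in order]
        self.id_mapping = {pid: pid for pid in self.tcof_ids}

        # GO annotations
        ann: list[GoAnnotation] = []
        mf_terms = sorted(
            {"GO:0003713", "GO:0003712", "GO:0003714", "GO:0001221",
             "GO:0001222", "GO:0001223", "GO:0033613", "GO:0070491"}
        )
        bp_terms = sorted(
            {"GO:0006351", "GO:0045892", "GO:0045893", "GO:0006355", "GO:0009299"}
        )
        for j, pid in enumerate(self.tcof_ids):
            cls = self.tcof_class[pid]
            cc_exp = cls in ("high_confidence", "hypothetical_II")
            mf_exp = cls in ("high_confidence", "hypothetical_I")
            cc_code = _EXP_CODES[j % len(_EXP_CODES)] if cc_exp else _NONEXP_CODES[j % 3]
            mf_code = _EXP_CODES[(j + 1) % len(_EXP_CODES)] if mf_exp else _NONEXP_CODES[j % 3]
            ann.append(GoAnnotation(pid, "GO:0005634", "CC", cc_code))
            ann.append(GoAnnotation(pid, mf_terms[j % len(mf_terms)], "MF", mf_code))
            ann.append(GoAnnotation(pid, bp_terms[j % len(bp_terms)], "BP", "IEA"))
        for j, pid in enumerate(self.fail_nucleus):
            ann.append(GoAnnotation(pid, mf_terms[j % len(mf_terms)], "MF", "IDA"))
            ann.append(GoAnnotation(pid, bp_terms[j % len(bp_terms)], "BP", "IEA"))
        for j, pid in enumerate(self.fail_bp):
            ann.append(GoAnnotation(pid, "GO:0005634", "CC", "IDA"))
            ann.append(GoAnnotation(pid, mf_terms[j % len(mf_terms)], "MF", "IDA"))
        for j, pid in enumerate(self.fail_mf):
            ann.append(GoAnnotation(pid, "GO:0005634", "CC", "IDA"))
            ann.append(GoAnnotation(pid, bp_terms[j % len(bp_terms)], "BP", "IEA"))
        self.annotations = ann
        # NOT-qualified nucleus rows for a few nucleus-failing candidates;
        # written into the GAF and excluded by the reader
        self.not_qualified = [
            GoAnnotation(pid, "GO:0005634", "CC", "IDA")
            for pid in self.fail_nucleus[: min(5, len(self.fail_nucleus))]
        ]

    # -- expression -----------------------------------------------------
    def _presence_sets(self) -> dict[str, list[int]]:
        T = self.cfg.n_tissues
        cut = self.cfg.broad_cutoff
        sets: dict[str, list[int]] = {}
        for g in self.tf_ubiq + self.tcof_ubiq:
            sets[g] = list(range(T))
        for g in self.tf_single:
            sets[g] = [0]
        for g in self.tcof_single:
            sets[g] = [T - 1]
        for j, g in enumerate(self.tf_intermediate):
            k = 2 + j % (T - 2)  # prefix breadth 2..T-1
            sets[g] = list(range(k))
        for j, g in enumerate(self.tcof_broad):
            k = cut + 1 + j % (T - 1 - cut)  # prefix breadth cut+1..T-1
            sets[g] = list(range(k))
        for j, g in enumerate(self.tcof_narrow):
            k = 2 + j % (cut - 1)  # prefix breadth 2..cut
            sets[g] = list(range(k))
        for j, g in enumerate(self.tcof_suffix):
            b = 2 + j % (T - 2)  # suffix breadth 2..T-1 (never tissue 0)
            sets[g] = list(range(T - b, T))
        return sets

    def _build_expression(self):
        c = self.cfg
        sets = self._presence_sets()
        self.presence_sets = sets
        expressed_tfs = self.tf_ubiq + self.tf_single + self.tf_intermediate
        expressed_tcofs = (
            self.tcof_ubiq + self.tcof_single + self.tcof_broad
            + self.tcof_narrow + self.tcof_suffix
        )
        rows = []  # (isoform_id, gene_id, fpkm per tissue)

        def add_gene(gene, iso_idx, second: bool):
            vals = np.zeros(c.n_tissues)
            draws = self.rng.lognormal(mean=2.0, sigma=1.2, size=len(sets[gene]))
            for t, v in zip(sets[gene], draws):
                vals[t] = max(0.01, round(float(v), 2))
            rows.append((f"ISO{iso_idx:05d}", gene, vals))
            if second:
                rows.append((f"ISO{iso_idx + 50000:05d}", gene, np.round(vals * 0.5, 2)))

        n_second_tf = c.n_tf_isoforms - len(expressed_tfs)
        for j, gene in enumerate(expressed_tfs):
            add_gene(gene, j, j < n_second_tf)
        n_second_tcof = c.n_tcof_isoforms - len(expressed_tcofs)
        for j, gene in enumerate(expressed_tcofs):
            add_gene(gene, 10000 + j, j < n_second_tcof)
        self.expression_rows = rows

    # -- alternative database comparison --------------------------------
    def _build_alt_sets(self):
        c = self.cfg
        comp = self.compendium_ids
        sets: list[set[str]] = [set(), set(), set()]
        for g in comp[: c.n_in_all]:
            for s in sets:
                s.add(g)
        duos = [(0, 1), (1, 2), (0, 2)]
        for j, g in enumerate(comp[c.n_in_all: c.n_in_all + c.n_in_two]):
            a, b = duos[j % 3]
            sets[a].add(g)
            sets[b].add(g)
        start = c.n_in_all + c.n_in_two
        for j, g in enumerate(comp[start: start + c.n_in_one]):
            sets[j % 3].add(g)
        reverse = (
            self.ids_non_tf[: c.n_reverse_non_tf]
            + self.ids_diverged[: c.n_reverse_diverged]
        )
        for j, g in enumerate(reverse):
            sets[j % 3].add(g)
        self.alt_sets = {"DBDdb": sets[0], "AnimalTFDB": sets[1], "CisBP": sets[2]}

    # -- truth ----------------------------------------------------------
    def _build_truth(self):
        c = self.cfg
        gene_class: dict[str, list[str]] = {}
        for g in self.ids_a_orth:
            gene_class[g] = ["a", "arrangement_conserved"]
        for g in self.ids_b_orth:
            gene_class[g] = ["b", "arrangement_conserved"]
        for g in self.ids_literature:
            gene_class[g] = ["a", "literature_evidence"]
        for g in self.ids_rescue:
            gene_class[g] = ["b", "similarity_rescue"]
        for g in self.ids_diverged:
            gene_class[g] = ["c", "arrangement_diverged"]
        for g in self.ids_unavailable:
            gene_class[g] = ["c", "arrangement_unavailable"]
        for g in self.ids_orth_c:
            gene_class[g] = ["c", "orthologue_class_c"]
        for g in self.ids_non_tf:
            gene_class[g] = ["c", "non_tf_function"]
        for g in self.ids_pseudo:
            gene_class[g] = ["c", "pseudogene"]
        for g in self.ids_similar_non_tf:
            gene_class[g] = ["c", "similar_to_non_tf"]
        for g in self.ids_y:
            gene_class[g] = ["y", "no_orthologue"]

        T = c.n_tissues
        pair_coexpr = {}
        for tf, tcof in self.edges:
            a = set(self.presence_sets.get(tf, []))
            b = set(self.presence_sets.get(tcof, []))
            if tf in set(self.tf_unexpressed) or tcof in set(self.tcof_unexpressed):
                pair_coexpr[f"{tf}|{tcof}"] = -1  # not measurable
            else:
                pair_coexpr[f"{tf}|{tcof}"] = len(a & b)

        measurable = [v for v in pair_coexpr.values() if v >= 0]
        expected = {
            "n_screened": c.n_screened,
            "n_post_removal": c.n_screened - c.n_pseudogene - c.n_non_tf - c.n_orth_c,
            "n_arrangement_eligible": (
                c.n_class_a_orth + c.n_class_b_orth + c.n_diverged + c.n_unavailable
            ),
            "n_compendium": c.n_compendium,
            "class_counts": {
                "a": c.n_class_a_orth + c.n_literature,
                "b": c.n_class_b_orth + c.n_rescue,
                "c": (c.n_diverged + c.n_unavailable + c.n_orth_c + c.n_non_tf
                      + c.n_pseudogene + c.n_similar_non_tf),
                "y": c.n_y,
            },
            "registry": {
                "n_domain": c.n_reference_domain + 5,
                "n_family": c.n_reference_family + 1,
                "total": c.n_registry,
            },
            "census_reclassified": c.n_census_updates_b + c.n_census_updates_c,
            "group_counts": dict(c.group_counts),
            "present_in_all": c.n_eukaryote_all,
            "exactly_two_species": max(1, c.n_rescue - 1) if c.n_rescue else 0,
            "absent_from_human_and_mouse": c.n_rescue,
            "tcof_class_counts": dict(c.tcof_class_counts),
            "n_tcofs": c.n_tcofs,
            "n_tf_tcof_edges": len(self.edges),
            "n_interacting_tfs": len({tf for tf, _ in self.edges}),
            "mi_type_counts": dict(c.kept_type_counts),
            "go_stage_counts": {
                "candidates": (c.n_tcofs + c.n_fail_nucleus + c.n_fail_bp + c.n_fail_mf),
                "cc_nucleus": c.n_tcofs + c.n_fail_bp + c.n_fail_mf,
                "bp_transcription": c.n_tcofs + c.n_fail_mf,
                "mf_transcription": c.n_tcofs,
            },
            "n_tf_expressed": sum(c.tf_expr.values()),
            "n_tcof_expressed": sum(c.tcof_expr.values()),
            "tf_ubiquitous": c.tf_expr["ubiquitous"],
            "tf_single_tissue": c.tf_expr["single"],
            "tcof_ubiquitous": c.tcof_expr["ubiquitous"],
            "tcof_single_tissue": c.tcof_expr["single"],
            "n_pairs_total": len(self.edges),
            "n_pairs_analyzed": len(measurable),
            "coexpressed_any": sum(1 for v in measurable if v > 0),
            "coexpressed_all_tissues": sum(1 for v in measurable if v == T),
            "coexpressed_gt_cutoff": sum(1 for v in measurable if v > c.broad_cutoff),
            "compare_in_all": c.n_in_all,
            "compare_in_two": c.n_in_two,
            "compare_in_one": c.n_in_one,
            "compare_exclusive": c.n_compendium - c.n_in_all - c.n_in_two - c.n_in_one,
        }
        self.truth = WorldTruth(
            gene_class=gene_class,
            tcof_class=dict(self.tcof_class),
            tf_group=dict(self.tf_group),
            pair_coexpression=pair_coexpr,
            expected=expected,
        )


def generate_world(config: WorldConfig, out_dir) -> tuple[dict, WorldTruth]:
    """Emit the complete input bundle for a synthetic world.

    Returns (paths, truth); identical configs (including seed) produce
    byte-identical bundles. Every emitted file passes its data_io reader.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    b = WorldBuilder(config)
    import pandas as pd

    paths = {
        "genes": out / "genes.tsv",
        "human_genes": out / "human_genes.tsv",
        "census": out / "census.tsv",
        "census_updates": out / "census_updates.tsv",
        "candidate_updates": out / "candidate_updates.tsv",
        "orthology": out / "orthology.tsv",
        "hits": out / "hits.tsv",
        "reference_dbds": out / "reference_dbds.tsv",
        "domain_function": out / "domain_function.tsv",
        "family_map": out / "family_map.tsv",
        "clade_map": out / "clade_map.yaml",
        "interactions": out / "interactions.mitab",
        "annotations": out / "annotations.gaf",
        "id_mapping": out / "id_mapping.tsv",
        "expression": out / "expression.tsv",
        "pairs": out / "pairs.tsv",
        "truth": out / "truth.json",
    }
    data_io.write_gene_domains(b.bovine_genes, paths["genes"])
    data_io.write_gene_domains(list(b.human_genes.values()), paths["human_genes"])
    data_io.write_census(b.census_entries, paths["census"])
    data_io.write_updates(b.census_updates, paths["census_updates"])
    data_io.write_updates(b.candidate_updates, paths["candidate_updates"])
    data_io.write_orthology(b.orthology, paths["orthology"])
    data_io.write_similarity_hits(b.hits, paths["hits"])
    data_io.write_registry(b.ref_dbds, paths["reference_dbds"])
    data_io.write_domain_function(b.domain_function, paths["domain_function"])
    data_io.write_family_map(b.family_map, paths["family_map"])
    data_io.write_clade_map(CladeMap(CLADE_CHAIN, dict(SPECIES_CLADES)), paths["clade_map"])
    data_io.write_mitab(b.interactions, paths["interactions"])
    _write_gaf_with_not_rows(b, paths["annotations"])
    data_io.write_id_mapping(b.id_mapping, paths["id_mapping"])
    expr = pd.DataFrame(
        {
            "gene_id": [g for _, g, _ in b.expression_rows],
            **{
                t: [vals[i] for _, _, vals in b.expression_rows]
                for i, t in enumerate(b.tissues)
            },
        },
        index=pd.Index([iso for iso, _, _ in b.expression_rows], name="isoform_id"),
    )
    data_io.write_expression_matrix(expr, paths["expression"])
    data_io.write_pairs(b.edges, paths["pairs"])
    for name, genes in b.alt_sets.items():
        p = out / f"altdb_{name}.tsv"
        paths[f"altdb_{name}"] = p
        data_io.write_gene_set(genes, p)
    for kind, snaps in (("human", b.human_snapshots), ("mouse", b.mouse_snapshots)):
        for s in snaps:
            p = out / f"snapshot_{kind}_{s.name}.tsv"
            paths[f"snapshot_{kind}_{s.name}"] = p
            data_io.write_snapshot(s, p)
    b.truth.to_json(paths["truth"])
    return {k: str(v) for k, v in paths.items()}, b.truth


def _write_gaf_with_not_rows(b: WorldBuilder, path) -> None:
    data_io.write_gaf(b.annotations, path)
    with open(path, "a") as fh:
        for a in b.not_qualified:
            fields = [
                "UniProtKB", a.protein_id, a.protein_id, "NOT|located_in",
                a.go_id, "PMID:0000001", a.evidence_code, "", "C",
                a.protein_id, "", "protein", "taxon:9606", "20170101", "UniProt",
            ]
            fh.write("\t".join(fields) + "\n")


def recover_truth(truth: WorldTruth, outputs: dict) -> dict:
    """Compare pipeline outputs against the planted truth.

    ``outputs`` is the dictionary returned by
    :func:`bovitf.pipeline.run_pipeline`. Deterministic stages must agree
    exactly; the report lists agreement fractions and any mismatches.
    """
    report: dict = {}

    assigned = {c.gene_id: (c.assigned_class, c.rationale) for c in outputs["candidates"]}
    mismatch = {
        g: {"expected": truth.gene_class[g], "got": list(assigned.get(g, ("missing",) * 2))}
        for g in truth.gene_class
        if tuple(truth.gene_class[g]) != assigned.get(g)
    }
    report["gene_class_agreement"] = 1 - len(mismatch) / max(1, len(truth.gene_class))
    report["gene_class_mismatches"] = mismatch

    got_tcof = {r.protein_id: r.confidence_class for r in outputs["tcofs"]}
    tc_mismatch = {
        p: {"expected": c, "got": got_tcof.get(p, "missing")}
        for p, c in truth.tcof_class.items()
        if got_tcof.get(p) != c
    }
    report["tcof_class_agreement"] = 1 - len(tc_mismatch) / max(1, len(truth.tcof_class))
    report["tcof_class_mismatches"] = tc_mismatch

    got_groups = outputs["groups"]
    gr_mismatch = {
        g: {"expected": grp, "got": got_groups.get(g, "missing")}
        for g, grp in truth.tf_group.items()
        if got_groups.get(g) != grp
    }
    report["group_agreement"] = 1 - len(gr_mismatch) / max(1, len(truth.tf_group))
    report["group_mismatches"] = gr_mismatch

    got_pairs = {
        f"{r.tf_gene}|{r.tcof_gene}": r.n_tissues for r in outputs["coexpression"]
    }
    pr_mismatch = {}
    for key, n in truth.pair_coexpression.items():
        got = got_pairs.get(key, -1)  # -1: pair not measurable
        if got != n:
            pr_mismatch[key] = {"expected": n, "got": got}
    report["pair_agreement"] = 1 - len(pr_mismatch) / max(1, len(truth.pair_coexpression))
    report["pair_mismatches"] = pr_mismatch

    report["exact"] = not (mismatch or tc_mismatch or gr_mismatch or pr_mismatch)
    return report
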