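"""End-to-end orchestration of the compendium pipeline.

Stages run in the identification order — census update, reliable-DBD
registry compilation, DBD screening, curation — followed by the
characterization stages: DBD families, conservation grouping, cofactor
screening, expression and coexpression, and comparison against
alternative TF sets. A run manifest records every stage's input and
output counts; the analysis pipeline itself is deterministic and
seed-free (randomness exists only in the synthetic-data generator).
"""

from __future__ import annotations

import logging
from collections import Counter
from pathlib import Path

from bovitf import __version__, census as census_mod, curation, data_io
from bovitf import conservation as conservation_mod
from bovitf import domain_families, expression as expression_mod, tcof_screen
from bovitf.census import Census
from bovitf.dbd_registry import (
    DbdRegistry,
    derive_blacklist,
    extract_candidate_dbds,
    intersect_novel_genes,
    registry_summary,
)
from bovitf.errors import StageError

logger = logging.getLogger(__name__)

REQUIRED_INPUTS = (
    "genes", "human_genes", "census", "census_updates", "candidate_updates",
    "orthology", "hits", "reference_dbds", "domain_function", "family_map",
    "clade_map", "interactions", "annotations", "id_mapping", "expression",
    "pairs",
)


def build_registry(
    reference_dbds,
    human_snapshots,
    mouse_snapshots,
    census: Census,
    domain_function: dict[str, bool],
) -> tuple[DbdRegistry, dict]:
    """Compile the reliable-DBD registry: reference list + two intersection rounds."""
    registry = DbdRegistry(list(reference_dbds))
    report = {"n_reference": len(registry)}
    for species, snaps, provenance in (
        ("human", human_snapshots, "human_intersection"),
        ("mouse", mouse_snapshots, "mouse_intersection"),
    ):
        if not snaps:
            continue
        novel = intersect_novel_genes(snaps, census)
        blacklist = derive_blacklist(snaps, census)
        added = extract_candidate_dbds(
            novel, snaps, domain_function, blacklist, provenance
        )
        n_added = registry.add(added)
        report[f"{species}_novel_genes"] = len(novel)
        report[f"{species}_new_dbds"] = n_added
    n_domain, n_family, total = registry_summary(registry)
    report.update({"n_domain": n_domain, "n_family": n_family, "total": total})
    return registry, report


def compare_sets(
    compendium_ids: list[str],
    alternative_sets: dict[str, set[str]],
    rationale: dict[str, str] | None = None,
) -> dict:
    """Overlap partition of the compendium against alternative TF sets.

    Buckets (membership in k of the n alternatives) partition the
    compendium; the reverse list collects genes present in at least one
    alternative but absent from the compendium, joined with their
    curation rationale when available.
    """
    if not alternative_sets:
        raise StageError("compare", "need at least one alternative set")
    n = len(alternative_sets)
    rationale = rationale or {}
    counts = {g: sum(g in s for s in alternative_sets.values()) for g in compendium_ids}
    buckets = Counter(counts.values())
    comp = set(compendium_ids)
    union_alt = set().union(*alternative_sets.values())
    reverse = sorted(union_alt - comp)
    return {
        "n_alternatives": n,
        "in_all": buckets.get(n, 0),
        "by_membership": {str(k): v for k, v in sorted(buckets.items())},
        "exclusive": buckets.get(0, 0),
        "reverse": [
            {"gene_id": g, "rationale": rationale.get(g, "unknown")} for g in reverse
        ],
    }


def run_pipeline(config: dict, out_dir=None, tau: float = 0.9,
                 threshold: float = curation.DEFAULT_THRESHOLD,
                 expression_threshold: float = 0.0) -> tuple[dict, dict]:
    """Run every stage on the input bundle described by ``config``.

    ``config`` maps input names (see ``REQUIRED_INPUTS``, plus optional
    ``snapshot_human_*`` / ``snapshot_mouse_*`` and ``altdb_*`` entries)
    to file paths. Returns (outputs, manifest); when ``out_dir`` is given
    the result tables and the manifest are also written there.

    Any stage failure aborts with the stage name attached.
    """
    missing = [k for k in REQUIRED_INPUTS if k not in config]
    if missing:
        raise StageError("configure", f"missing inputs: {', '.join(missing)}")
    for key in REQUIRED_INPUTS:
        if not Path(config[key]).exists():
            raise StageError("configure", f"input file not found: {config[key]} ({key})")

    outputs: dict = {}
    manifest: dict = {"version": __version__, "tau": tau, "threshold": threshold,
                      "stages": {}}
    if "seed" in config:
        manifest["seed"] = config["seed"]

    def stage(name):
        def deco(fn):
            try:
                result = fn()
            except StageError:
                raise
            except Exception as exc:
                raise StageError(name, str(exc)) from exc
            manifest["stages"][name] = result
            return result
        return deco

    # 1. census update
    @stage("census_update")
    def _():
        cen = Census(data_io.read_census(config["census"]))
        updates = data_io.read_updates(config["census_updates"])
        updated, n_changed = census_mod.apply_updates(cen, updates)
        outputs["census"] = updated
        return {"in": len(cen), "reclassified": n_changed}

    # 2. reliable-DBD registry
    @stage("build_registry")
    def _():
        reference = data_io.read_registry(config["reference_dbds"])
        func = data_io.read_domain_function(config["domain_function"])
        human_snaps = [
            data_io.read_snapshot(config[k], k.split("_", 2)[2], "human")
            for k in sorted(config) if k.startswith("snapshot_human_")
        ]
        mouse_snaps = [
            data_io.read_snapshot(config[k], k.split("_", 2)[2], "mouse")
            for k in sorted(config) if k.startswith("snapshot_mouse_")
        ]
        registry, report = build_registry(
            reference, human_snaps, mouse_snaps, outputs["census"], func
        )
        outputs["registry"] = registry
        return report

    # 3. DBD screening
    @stage("screen")
    def _():
        genes = data_io.read_gene_domains(config["genes"])
        screened = curation.screen_for_dbds(genes, outputs["registry"])
        outputs["screened"] = screened
        return {"in": len(genes), "out": len(screened)}

    # 4. curation cascade
    @stage("curate")
    def _():
        orthology = data_io.read_orthology(config["orthology"])
        human_genes = {
            g.gene_id: g
            for g in data_io.read_gene_domains(config["human_genes"], species="homo_sapiens")
        }
        updates = data_io.read_updates(config["candidate_updates"])
        hits = data_io.read_similarity_hits(config["hits"])
        candidates = curation.curate(
            outputs["screened"], orthology, outputs["census"], human_genes,
            updates, hits, threshold,
        )
        final, report = curation.compendium(candidates)
        outputs["candidates"] = candidates
        outputs["compendium"] = final
        outputs["orthology"] = orthology
        return report

    # 5. DBD families
    @stage("families")
    def _():
        fam_map = data_io.read_family_map(config["family_map"])
        comp_ids = {c.gene_id for c in outputs["compendium"]}
        tf_records = [g for g in outputs["screened"] if g.gene_id in comp_ids]
        fams = domain_families.classify_families(tf_records, fam_map, outputs["registry"])
        collapsed = domain_families.collapse_small_families(fams)
        outputs["families"] = collapsed
        return {
            "n_families": len(collapsed),
            "distribution": dict(domain_families.family_distribution(collapsed)),
        }

    # 6. conservation
    @stage("conservation")
    def _():
        clade_map = data_io.read_clade_map(config["clade_map"])
        species = sorted(clade_map.species_clade)
        comp_ids = [c.gene_id for c in outputs["compendium"]]
        matrix = conservation_mod.build_presence(comp_ids, outputs["orthology"], species)
        groups = conservation_mod.group_assignments(matrix, clade_map, tau)
        clustering = (
            conservation_mod.cluster_presence(matrix) if len(matrix) >= 2 else None
        )
        outputs["presence"] = matrix
        outputs["groups"] = groups.to_dict()
        outputs["clustering"] = clustering
        tallies = conservation_mod.conservation_tallies(matrix)
        return {
            "group_counts": dict(Counter(groups)),
            **tallies,
        }

    # 7. cofactor screen
    @stage("tcof")
    def _():
        mitab = data_io.read_mitab(config["interactions"])
        annotations = data_io.read_gaf(config["annotations"])
        id_mapping = data_io.read_id_mapping(config["id_mapping"])
        tf_set = {c.gene_id for c in outputs["compendium"]}
        tcofs, report = tcof_screen.screen_tcofs(
            mitab.records, tf_set, annotations, id_mapping=id_mapping
        )
        outputs["tcofs"] = tcofs
        report["mitab_skipped"] = mitab.n_skipped
        return report

    # 8. expression and coexpression
    @stage("expression")
    def _():
        matrix = data_io.read_expression_matrix(config["expression"])
        pairs = data_io.read_pairs(config["pairs"])
        expr = expression_mod.gene_expression(matrix, threshold=expression_threshold)
        outputs["gene_expression"] = expr
        comp_ids = {c.gene_id for c in outputs["compendium"]}
        tcof_ids = {t.protein_id for t in outputs["tcofs"]}
        tf_expressed = comp_ids & set(expr.presence.index[expr.presence.any(axis=1)])
        tcof_expressed = tcof_ids & set(expr.presence.index[expr.presence.any(axis=1)])
        results, summary = expression_mod.coexpression(pairs, expr)
        outputs["coexpression"] = results
        outputs["coexpression_summary"] = summary
        tf_tally = {
            "n_tf_expressed": len(tf_expressed),
            "n_tcof_expressed": len(tcof_expressed),
            "tf_ubiquitous": int(
                expr.presence.loc[sorted(comp_ids & set(expr.presence.index))]
                .all(axis=1).sum()
            ),
            "tf_single_tissue": int(
                (expr.presence.loc[sorted(comp_ids & set(expr.presence.index))]
                 .sum(axis=1) == 1).sum()
            ),
            "tcof_ubiquitous": int(
                expr.presence.loc[sorted(tcof_ids & set(expr.presence.index))]
                .all(axis=1).sum()
            ),
            "tcof_single_tissue": int(
                (expr.presence.loc[sorted(tcof_ids & set(expr.presence.index))]
                 .sum(axis=1) == 1).sum()
            ),
        }
        pair_summary = {
            k: summary[k]
            for k in ("n_pairs_total", "n_pairs_analyzed", "coexpressed_any",
                      "coexpressed_all_tissues", "coexpressed_gt_cutoff")
        }
        return {**tf_tally, **pair_summary}

    # 9. comparison to alternative TF sets
    alt_keys = sorted(k for k in config if k.startswith("altdb_"))
    if alt_keys:
        @stage("compare")
        def _():
            alt_sets = {
                k.split("_", 1)[1]: data_io.read_gene_set(config[k]) for k in alt_keys
            }
            rationale = {c.gene_id: c.rationale for c in outputs["candidates"]}
            report = compare_sets(
                [c.gene_id for c in outputs["compendium"]], alt_sets, rationale
            )
            outputs["comparison"] = report
            return {k: v for k, v in report.items() if k != "reverse"}

    if out_dir is not None:
        _write_outputs(outputs, manifest, Path(out_dir))
    return outputs, manifest


def _write_outputs(outputs: dict, manifest: dict, out: Path) -> None:
    import pandas as pd

    out.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        [
            (c.gene_id, c.assigned_class, c.rationale, c.orthologue or "",
             "" if c.arrangement_similarity is None else f"{c.arrangement_similarity:.4f}")
            for c in outputs["candidates"]
        ],
        columns=["gene_id", "class", "rationale", "orthologue", "similarity"],
    ).to_csv(out / "candidates.tsv", sep="\t", index=False)
    pd.DataFrame(
        [(c.gene_id, c.assigned_class) for c in outputs["compendium"]],
        columns=["gene_id", "class"],
    ).to_csv(out / "compendium.tsv", sep="\t", index=False)
    pd.DataFrame(
        sorted((f, len(m), ",".join(sorted(m))) for f, m in outputs["families"].items()),
        columns=["family", "n_members", "members"],
    ).to_csv(out / "families.tsv", sep="\t", index=False)
    outputs["presence"].astype(int).to_csv(out / "presence_matrix.tsv", sep="\t")
    pd.Series(outputs["groups"], name="group").rename_axis("gene_id").to_csv(
        out / "conservation_groups.tsv", sep="\t"
    )
    if outputs.get("clustering") and outputs["clustering"]["row_newick"]:
        (out / "presence_rows.nwk").write_text(outputs["clustering"]["row_newick"] + "\n")
        (out / "presence_cols.nwk").write_text(outputs["clustering"]["col_newick"] + "\n")
    pd.DataFrame(
        [
            (t.protein_id, t.confidence_class, len(t.interacting_tfs),
             ",".join(sorted(t.interacting_tfs)))
            for t in outputs["tcofs"]
        ],
        columns=["protein_id", "class", "n_tf_partners", "partners"],
    ).to_csv(out / "tcofs.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            (r.tf_gene, r.tcof_gene, r.n_tissues, ",".join(sorted(r.tissues_coexpressed)))
            for r in outputs["coexpression"]
        ],
        columns=["tf_gene", "tcof_gene", "n_tissues", "tissues"],
    ).to_csv(out / "coexpression.tsv", sep="\t", index=False)
    data_io.write_run_summary(manifest, out / "manifest.json")
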