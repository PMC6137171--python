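"""Readers and writers for every external format the pipeline touches.

All tabular inputs are plain TSV; interaction data is PSI-MITAB 2.5-2.7
(only the first 15 columns are read) and GO annotations are GAF 2.1/2.2.
Every reader is total on files its paired writer produces (round-trip
identity), and no reader silently drops a well-formed row: skipped rows
are counted and reported.

Coordinates in gene-domain tables are 1-based inclusive amino-acid
positions, the convention of BioMart protein-domain exports.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from bovitf.errors import FormatError, RowError
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

logger = logging.getLogger(__name__)

_MI_FIELD_RE = re.compile(r'psi-mi:"(MI:\d{4})"')


def _read_tsv(path, required: list[str], name: str) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise FormatError(f"{name}: file {path} is empty or has no header")
    for col in required:
        if col not in df.columns:
            raise FormatError(f"{name}: missing required column '{col}' in {path}")
    if len(set(df.columns)) != len(df.columns):
        raise FormatError(f"{name}: duplicated column names in {path}")
    return df


# ---------------------------------------------------------------------------
# gene-domain tables

GENE_DOMAIN_COLUMNS = ["gene_id", "biotype", "interpro_id", "entry_type", "start", "end"]


def read_gene_domains(path, species: str = "bos_taurus") -> list[GeneRecord]:
    """Read a BioMart-style gene/InterPro-domain TSV into GeneRecords.

    One record per gene_id, domain hits sorted by start coordinate. Rows
    with an empty ``interpro_id`` declare a gene with no domain hits.
    """
    df = _read_tsv(path, GENE_DOMAIN_COLUMNS, "gene_domains")
    hits: dict[str, list[DomainHit]] = {}
    biotypes: dict[str, str] = {}
    order: list[str] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        gid = row.gene_id
        if not gid:
            raise RowError("empty gene_id", line=i)
        if gid not in biotypes:
            biotypes[gid] = row.biotype
            hits[gid] = []
            order.append(gid)
        if row.interpro_id == "":
            continue
        try:
            start, end = int(row.start), int(row.end)
        except ValueError:
            raise RowError(
                f"non-integer coordinate ({row.start!r}, {row.end!r}) for {gid}", line=i
            )
        if end < start or start < 1:
            raise RowError(f"invalid interval [{start}, {end}] for {gid}", line=i)
        hits[gid].append(DomainHit(row.interpro_id, row.entry_type, start, end))
    return [
        GeneRecord(gid, biotypes[gid], species=species, domain_hits=tuple(hits[gid]))
        for gid in order
    ]


def write_gene_domains(genes: list[GeneRecord], path) -> None:
    rows = []
    for g in genes:
        if not g.domain_hits:
            rows.append((g.gene_id, g.biotype, "", "", "", ""))
        for h in g.domain_hits:
            rows.append((g.gene_id, g.biotype, h.interpro_id, h.entry_type, h.start, h.end))
    pd.DataFrame(rows, columns=GENE_DOMAIN_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# census and evidence updates

def read_census(path) -> list[CensusEntry]:
    df = _read_tsv(path, ["gene_id", "evidence_class"], "census")
    note = df["note"] if "note" in df.columns else [""] * len(df)
    entries = [
        CensusEntry(g, c, n)
        for g, c, n in zip(df["gene_id"], df["evidence_class"], note)
    ]
    seen = set()
    for e in entries:
        if e.gene_id in seen:
            raise FormatError(f"census: duplicated gene_id {e.gene_id}")
        seen.add(e.gene_id)
    return entries


def write_census(entries: list[CensusEntry], path) -> None:
    pd.DataFrame(
        [(e.gene_id, e.evidence_class, e.note) for e in entries],
        columns=["gene_id", "evidence_class", "note"],
    ).to_csv(path, sep="\t", index=False)


def read_updates(path) -> list[EvidenceUpdate]:
    df = _read_tsv(path, ["gene_id", "new_class"], "updates")
    citation = df["citation"] if "citation" in df.columns else [""] * len(df)
    return [
        EvidenceUpdate(g, c, cit)
        for g, c, cit in zip(df["gene_id"], df["new_class"], citation)
    ]


def write_updates(updates: list[EvidenceUpdate], path) -> None:
    pd.DataFrame(
        [(u.gene_id, u.new_class, u.citation) for u in updates],
        columns=["gene_id", "new_class", "citation"],
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# orthology

ORTHOLOGY_COLUMNS = ["source_gene", "target_gene", "homology_type", "target_species"]


def read_orthology(path) -> list[OrthologyRelation]:
    df = _read_tsv(path, ORTHOLOGY_COLUMNS, "orthology")
    return [
        OrthologyRelation(s, t, h, sp)
        for s, t, h, sp in zip(
            df["source_gene"], df["target_gene"], df["homology_type"], df["target_species"]
        )
    ]


def write_orthology(relations: list[OrthologyRelation], path) -> None:
    pd.DataFrame(
        [(r.source_gene, r.target_gene, r.homology_type, r.target_species) for r in relations],
        columns=ORTHOLOGY_COLUMNS,
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# DBD registry

REGISTRY_COLUMNS = ["interpro_id", "entry_type", "provenance", "sequence_specific"]


def read_registry(path) -> list[DbdEntry]:
    df = _read_tsv(path, REGISTRY_COLUMNS, "registry")
    return [
        DbdEntry(i, t, p, s.lower() in ("true", "1", "yes"))
        for i, t, p, s in zip(
            df["interpro_id"], df["entry_type"], df["provenance"], df["sequence_specific"]
        )
    ]


def write_registry(entries: list[DbdEntry], path) -> None:
    pd.DataFrame(
        [(e.interpro_id, e.entry_type, e.provenance, str(e.sequence_specific)) for e in entries],
        columns=REGISTRY_COLUMNS,
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# similarity hits

def read_similarity_hits(path) -> list[SimilarityHit]:
    df = _read_tsv(path, ["query_gene", "subject_gene", "score"], "similarity_hits")
    return [
        SimilarityHit(q, s, float(sc))
        for q, s, sc in zip(df["query_gene"], df["subject_gene"], df["score"])
    ]


def write_similarity_hits(hits: list[SimilarityHit], path) -> None:
    pd.DataFrame(
        [(h.query_gene, h.subject_gene, h.score) for h in hits],
        columns=["query_gene", "subject_gene", "score"],
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# PSI-MITAB

@dataclass
class MitabResult:
    """Parsed MITAB file: records plus the count of skipped malformed lines."""

    records: list[InteractionRecord]
    n_skipped: int = 0

    def __iter__(self):
        return iter(self.records)

    def __len__(self):
        return len(self.records)


def _mitab_identifier(field: str) -> str:
    """Extract the accession from a ``db:accession`` MITAB identifier field.

    Multiple alternatives (pipe-separated) resolve to the first; the default
    namespace is the stable accession after the database prefix.
    """
    first = field.split("|")[0].strip()
    if ":" in first:
        return first.split(":", 1)[1].strip('"')
    return first


def read_mitab(path) -> MitabResult:
    """Parse a PSI-MITAB 2.5-2.7 file (first 15 columns only).

    The interaction-type MI code is extracted as a bare ``MI:NNNN`` from the
    standard ``psi-mi:"MI:NNNN"(label)`` syntax. Lines whose type field is
    unparseable are skipped with a logged warning and counted.
    """
    records: list[InteractionRecord] = []
    n_skipped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")[:15]
            if lineno == 1 and fields[0].lower().startswith(("id(s) interactor", "#id")):
                continue  # optional header line
            if len(fields) < 13:
                logger.warning("mitab: line %d has %d columns, skipped", lineno, len(fields))
                n_skipped += 1
                continue
            m = _MI_FIELD_RE.search(fields[11])
            if not m:
                logger.warning("mitab: line %d has unparseable interaction type, skipped", lineno)
                n_skipped += 1
                continue
            id_a = _mitab_identifier(fields[0])
            id_b = _mitab_identifier(fields[1])
            if not id_a or not id_b:
                logger.warning("mitab: line %d has empty interactor id, skipped", lineno)
                n_skipped += 1
                continue
            source = _mitab_identifier(fields[12]) if len(fields) > 12 else ""
            records.append(InteractionRecord(id_a, id_b, m.group(1), source))
    return MitabResult(records, n_skipped)


_MI_LABELS = {
    "MI:0195": "covalent binding",
    "MI:0407": "direct interaction",
    "MI:0915": "physical association",
    "MI:0403": "colocalization",
    "MI:0914": "association",
}


def write_mitab(records: list[InteractionRecord], path) -> None:
    """Write minimal 15-column MITAB 2.5 the paired reader round-trips."""
    with open(path, "w") as fh:
        for r in records:
            label = _MI_LABELS.get(r.mi_type, "interaction type")
            fields = [
                f"uniprotkb:{r.id_a}",
                f"uniprotkb:{r.id_b}",
                "-", "-", "-", "-",
                'psi-mi:"MI:0018"(two hybrid)',
                "-", "-",
                "taxid:9913(Bos taurus)",
                "taxid:9913(Bos taurus)",
                f'psi-mi:"{r.mi_type}"({label})',
                f"psi-mi:{r.source}" if r.source else "psi-mi:intact",
                "-", "-",
            ]
            fh.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# GAF

_ASPECT_MAP = {"C": "CC", "F": "MF", "P": "BP"}
_ASPECT_UNMAP = {"CC": "C", "MF": "F", "BP": "P"}


def read_gaf(path) -> list[GoAnnotation]:
    """Parse a GAF 2.1/2.2 file.

    Aspect letters C/F/P map to CC/MF/BP; evidence codes are preserved
    verbatim; NOT-qualified annotations are excluded.
    """
    annotations: list[GoAnnotation] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("!"):
                continue
            fields = line.split("\t")
            if len(fields) < 15:
                raise RowError(f"GAF row has {len(fields)} columns (expected >= 15)", line=lineno)
            qualifier = fields[3]
            if "NOT" in qualifier.split("|"):
                continue
            aspect = fields[8]
            if aspect not in _ASPECT_MAP:
                raise RowError(f"unknown GO aspect {aspect!r}", line=lineno)
            annotations.append(GoAnnotation(fields[1], fields[4], _ASPECT_MAP[aspect], fields[6]))
    return annotations


def write_gaf(annotations: list[GoAnnotation], path) -> None:
    with open(path, "w") as fh:
        fh.write("!gaf-version: 2.2\n")
        for a in annotations:
            fields = [
                "UniProtKB", a.protein_id, a.protein_id, "enables" if a.aspect == "MF" else
                ("located_in" if a.aspect == "CC" else "involved_in"),
                a.go_id, "PMID:0000001", a.evidence_code, "",
                _ASPECT_UNMAP[a.aspect], a.protein_id, "", "protein",
                "taxon:9606", "20170101", "UniProt",
            ]
            fh.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# expression matrices

def read_expression_matrix(path) -> pd.DataFrame:
    """Read an isoform x tissue FPKM matrix.

    Layout: columns ``isoform_id``, ``gene_id`` then one float column per
    tissue. Returns a DataFrame indexed by isoform_id with a ``gene_id``
    column; FPKM values are validated finite and non-negative.
    """
    df = _read_tsv(path, ["isoform_id", "gene_id"], "expression")
    tissues = [c for c in df.columns if c not in ("isoform_id", "gene_id")]
    if not tissues:
        raise FormatError("expression: no tissue columns")
    if df["isoform_id"].duplicated().any():
        raise FormatError("expression: duplicated isoform_id")
    out = df.set_index("isoform_id")
    try:
        out[tissues] = out[tissues].astype(float)
    except ValueError as exc:
        raise FormatError(f"expression: non-numeric FPKM value ({exc})")
    vals = out[tissues].to_numpy()
    import numpy as np

    if not np.isfinite(vals).all():
        raise FormatError("expression: non-finite FPKM value")
    if (vals < 0).any():
        raise FormatError("expression: negative FPKM value")
    return out


def write_expression_matrix(df: pd.DataFrame, path) -> None:
    df.reset_index().rename(columns={"index": "isoform_id"}).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# misc small tables

def read_id_mapping(path) -> dict[str, str]:
    """protein/interactor id -> gene id mapping table."""
    df = _read_tsv(path, ["protein_id", "gene_id"], "id_mapping")
    return dict(zip(df["protein_id"], df["gene_id"]))


def write_id_mapping(mapping: dict[str, str], path) -> None:
    pd.DataFrame(sorted(mapping.items()), columns=["protein_id", "gene_id"]).to_csv(
        path, sep="\t", index=False
    )


def read_family_map(path) -> dict[str, str]:
    df = _read_tsv(path, ["interpro_id", "family"], "family_map")
    return dict(zip(df["interpro_id"], df["family"]))


def write_family_map(mapping: dict[str, str], path) -> None:
    pd.DataFrame(sorted(mapping.items()), columns=["interpro_id", "family"]).to_csv(
        path, sep="\t", index=False
    )


def read_pairs(path) -> list[tuple[str, str]]:
    df = _read_tsv(path, ["tf_gene", "tcof_gene"], "pairs")
    return list(zip(df["tf_gene"], df["tcof_gene"]))


def write_pairs(pairs: list[tuple[str, str]], path) -> None:
    pd.DataFrame(pairs, columns=["tf_gene", "tcof_gene"]).to_csv(path, sep="\t", index=False)


def read_snapshot(path, name: str, species: str):
    """Read a TF-database snapshot TSV (gene_id, interpro_id, entry_type).

    Rows with empty interpro_id declare a gene with no domain annotation.
    """
    from bovitf.dbd_registry import TfDatabaseSnapshot

    df = _read_tsv(path, ["gene_id", "interpro_id", "entry_type"], "snapshot")
    gene_ids: set[str] = set()
    gene_to_domains: dict[str, set[str]] = {}
    domain_types: dict[str, str] = {}
    for row in df.itertuples(index=False):
        gene_ids.add(row.gene_id)
        if row.interpro_id:
            gene_to_domains.setdefault(row.gene_id, set()).add(row.interpro_id)
            domain_types[row.interpro_id] = row.entry_type
    return TfDatabaseSnapshot(name, species, gene_ids, gene_to_domains, domain_types)


def write_snapshot(snapshot, path) -> None:
    rows = []
    for g in sorted(snapshot.gene_ids):
        domains = sorted(snapshot.gene_to_domains.get(g, ()))
        if not domains:
            rows.append((g, "", ""))
        for d in domains:
            rows.append((g, d, snapshot.domain_types[d]))
    pd.DataFrame(rows, columns=["gene_id", "interpro_id", "entry_type"]).to_csv(
        path, sep="\t", index=False
    )


def read_domain_function(path) -> dict[str, bool]:
    """Curated table flagging sequence-specific DNA-binding domains."""
    df = _read_tsv(path, ["interpro_id", "sequence_specific"], "domain_function")
    return {
        i: s.lower() in ("true", "1", "yes")
        for i, s in zip(df["interpro_id"], df["sequence_specific"])
    }


def write_domain_function(flags: dict[str, bool], path) -> None:
    pd.DataFrame(
        sorted((i, str(v)) for i, v in flags.items()),
        columns=["interpro_id", "sequence_specific"],
    ).to_csv(path, sep="\t", index=False)


def read_clade_map(path):
    """Read a YAML clade map: {chain: [clades smallest-first], species: {name: clade}}."""
    import yaml

    from bovitf.conservation import CladeMap

    data = yaml.safe_load(Path(path).read_text())
    return CladeMap(tuple(data["chain"]), dict(data["species"]))


def write_clade_map(clade_map, path) -> None:
    import yaml

    data = {"chain": list(clade_map.chain), "species": dict(sorted(clade_map.species_clade.items()))}
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def read_gene_set(path) -> set[str]:
    """One gene id per line (an alternative-database TF list)."""
    return {
        line.strip()
        for line in Path(path).read_text().splitlines()
        if line.strip() and not line.startswith("#")
    }


def write_gene_set(genes: set[str], path) -> None:
    Path(path).write_text("\n".join(sorted(genes)) + "\n")


def write_run_summary(summary: dict, path) -> None:
    Path(path).write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")


def read_run_summary(path) -> dict:
    return json.loads(Path(path).read_text())
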