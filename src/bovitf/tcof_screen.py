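"""Transcription-cofactor (TcoF) screening from interaction and GO data.

Candidate TcoFs are proteins physically interacting with at least one
compendium TF (TF-TF pairs contribute no candidates), restricted to
covalent-binding, direct-interaction and physical-association records
(MI:0195, MI:0407, MI:0915). Candidates are then filtered by directly
asserted GO annotation — nuclear localization (CC anchor GO:0005634),
then a transcription-related biological process, then a
transcription-related molecular function — and finally classified by GO
evidence: experimental codes (EXP, IDA, IMP, IGI, IEP, IPI) for both
nuclear localization and transcription-related molecular function give
high confidence; the three hypothetical classes cover the remaining
combinations. Transcription-function evidence is judged on the MF term
set only; BP terms gate the filter but not the confidence class.

Annotations are used as asserted, without ancestor-closure propagation
over the ontology graph (the term lists are flat); closure over a
supplied ontology can be enabled explicitly.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from bovitf.errors import ConfigError
from bovitf.records import GoAnnotation, InteractionRecord, TcofRecord

#: Interaction types retained for TcoF screening.
DEFAULT_MI_TYPES = frozenset({"MI:0195", "MI:0407", "MI:0915"})

#: GO evidence codes counted as experimental.
EXPERIMENTAL_CODES = frozenset({"EXP", "IDA", "IMP", "IGI", "IEP", "IPI"})

#: Nuclear localization anchor term.
CC_NUCLEUS = "GO:0005634"

#: Transcription-related molecular functions.
DEFAULT_MF_TERMS = frozenset(
    {
        "GO:0003713", "GO:0003712", "GO:0003714", "GO:0001221",
        "GO:0001222", "GO:0001223", "GO:0033613", "GO:0070491",
    }
)

#: Transcription-related biological processes.
DEFAULT_BP_TERMS = frozenset(
    {"GO:0006351", "GO:0045892", "GO:0045893", "GO:0006355", "GO:0009299"}
)


@dataclass(frozen=True)
class TermConfig:
    """GO term sets and codes driving the TcoF screen."""

    cc_anchor: str = CC_NUCLEUS
    mf_terms: frozenset[str] = DEFAULT_MF_TERMS
    bp_terms: frozenset[str] = DEFAULT_BP_TERMS
    experimental_codes: frozenset[str] = EXPERIMENTAL_CODES
    mi_types: frozenset[str] = DEFAULT_MI_TYPES

    def __post_init__(self):
        if not self.cc_anchor or not self.mf_terms or not self.bp_terms:
            raise ConfigError("term config requires a CC anchor and non-empty MF/BP sets")


def filter_interactions(
    records: list[InteractionRecord],
    allowed_types: frozenset[str] = DEFAULT_MI_TYPES,
) -> tuple[list[InteractionRecord], dict[str, int]]:
    """Keep records whose MI type is allowed; report per-type kept counts."""
    kept = [r for r in records if r.mi_type in allowed_types]
    return kept, dict(Counter(r.mi_type for r in kept))


def candidate_tcofs(
    filtered: list[InteractionRecord],
    tf_set: set[str],
    id_mapping: dict[str, str] | None = None,
) -> dict[str, set[str]]:
    """Interaction partners of TFs that are not themselves TFs.

    Returns candidate protein id -> set of interacting TF gene ids.
    Interactor ids are translated through ``id_mapping`` when given (the
    mapping from interaction-database accessions to gene ids is a required
    input; it is never inferred). TF-TF pairs and self-interactions
    contribute no candidates.
    """
    if not tf_set:
        raise ConfigError("tf_set must be non-empty")
    mapping = id_mapping or {}
    partners: dict[str, set[str]] = {}
    for r in filtered:
        a = mapping.get(r.id_a, r.id_a)
        b = mapping.get(r.id_b, r.id_b)
        for tf, other in ((a, b), (b, a)):
            if tf in tf_set and other not in tf_set:
                partners.setdefault(other, set()).add(tf)
    return partners


def go_filter(
    candidates: dict[str, set[str]],
    annotations: list[GoAnnotation],
    config: TermConfig = TermConfig(),
) -> tuple[dict[str, set[str]], dict[str, int]]:
    """Sequential GO screen: nucleus CC, then listed BP, then listed MF.

    Returns surviving candidates (with their TF partner sets) and the
    per-stage survivor counts; counts are monotone non-increasing.
    """
    by_protein: dict[str, list[GoAnnotation]] = {}
    for a in annotations:
        by_protein.setdefault(a.protein_id, []).append(a)

    def has(protein: str, aspect: str, terms: set[str] | frozenset[str]) -> bool:
        return any(
            a.aspect == aspect and a.go_id in terms for a in by_protein.get(protein, ())
        )

    stage_counts = {"candidates": len(candidates)}
    nucleus = {p for p in candidates if has(p, "CC", {config.cc_anchor})}
    stage_counts["cc_nucleus"] = len(nucleus)
    bp = {p for p in nucleus if has(p, "BP", config.bp_terms)}
    stage_counts["bp_transcription"] = len(bp)
    mf = {p for p in bp if has(p, "MF", config.mf_terms)}
    stage_counts["mf_transcription"] = len(mf)
    survivors = {p: candidates[p] for p in sorted(mf)}
    return survivors, stage_counts


def classify_evidence(
    protein_id: str,
    annotations: list[GoAnnotation],
    config: TermConfig = TermConfig(),
) -> str:
    """Confidence class of one screened TcoF from its GO evidence codes.

    N: some nucleus CC annotation carries an experimental code.
    T: some listed-MF annotation carries an experimental code.
    high_confidence = N and T; hypothetical_I = T only;
    hypothetical_II = N only; hypothetical_III = neither.
    """
    mine = [a for a in annotations if a.protein_id == protein_id]
    n = any(
        a.aspect == "CC"
        and a.go_id == config.cc_anchor
        and a.evidence_code in config.experimental_codes
        for a in mine
    )
    t = any(
        a.aspect == "MF"
        and a.go_id in config.mf_terms
        and a.evidence_code in config.experimental_codes
        for a in mine
    )
    if n and t:
        return "high_confidence"
    if t:
        return "hypothetical_I"
    if n:
        return "hypothetical_II"
    return "hypothetical_III"


def screen_tcofs(
    interactions: list[InteractionRecord],
    tf_set: set[str],
    annotations: list[GoAnnotation],
    config: TermConfig = TermConfig(),
    id_mapping: dict[str, str] | None = None,
) -> tuple[list[TcofRecord], dict]:
    """Full TcoF screen; returns records and a stage/class report."""
    filtered, type_counts = filter_interactions(interactions, config.mi_types)
    candidates = candidate_tcofs(filtered, tf_set, id_mapping)
    survivors, stage_counts = go_filter(candidates, annotations, config)
    records = [
        TcofRecord(p, classify_evidence(p, annotations, config), frozenset(tfs))
        for p, tfs in survivors.items()
    ]
    class_counts = dict(Counter(r.confidence_class for r in records))
    n_edges = sum(len(r.interacting_tfs) for r in records)
    interacting_tfs = set().union(*(r.interacting_tfs for r in records)) if records else set()
    report = {
        "mi_type_counts": type_counts,
        "stage_counts": stage_counts,
        "class_counts": class_counts,
        "n_tcofs": len(records),
        "n_tf_tcof_edges": n_edges,
        "n_interacting_tfs": len(interacting_tfs),
    }
    return records, report
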