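"""Tissue expression and TF-TcoF coexpression summaries from FPKM matrices.

Isoform-level FPKM is collapsed to gene level by the maximum over the
gene's isoforms (a presence-oriented choice; summing is available), a
gene is "expressed" in a tissue when its FPKM exceeds a threshold
(default 0, i.e. any signal), and a TF-TcoF pair is coexpressed when
both genes are simultaneously expressed in at least one tissue. The
matrix is a single-animal snapshot: no replication is modeled and no
correlation-based coexpression is computed.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import pandas as pd

from bovitf.errors import ValidationError


def pct(numerator: int, denominator: int, decimals: int = 1) -> float:
    """Percentage 100*numerator/denominator, rounded half-away-from-zero.

    >>> pct(680, 865, 1)
    78.6
    """
    if denominator == 0:
        raise ValidationError("pct: zero denominator")
    value = Decimal(100) * Decimal(numerator) / Decimal(denominator)
    sign = -1 if value < 0 else 1
    q = Decimal(1).scaleb(-decimals)
    return float(sign * abs(value).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class GeneExpression:
    """Gene-level FPKM and presence with derived tallies."""

    fpkm: pd.DataFrame  # gene x tissue
    presence: pd.DataFrame  # gene x tissue, bool
    threshold: float

    @property
    def tissues(self) -> list[str]:
        return list(self.fpkm.columns)

    def tissues_expressed(self) -> pd.Series:
        return self.presence.sum(axis=1)

    def tallies(self) -> dict:
        n_tissues = len(self.tissues)
        k = self.tissues_expressed()
        return {
            "n_genes": int(len(self.fpkm)),
            "n_tissues": n_tissues,
            "expressed_anywhere": int((k > 0).sum()),
            "ubiquitous": int((k == n_tissues).sum()),
            "single_tissue": int((k == 1).sum()),
            "per_tissue": {t: int(self.presence[t].sum()) for t in self.tissues},
        }


def gene_expression(
    matrix: pd.DataFrame,
    threshold: float = 0.0,
    collapse: str = "max",
) -> GeneExpression:
    """Collapse an isoform x tissue matrix to gene level.

    ``matrix`` is the frame returned by
    :func:`bovitf.data_io.read_expression_matrix` (isoform index, a
    ``gene_id`` column, one float column per tissue). ``collapse`` is
    "max" (default) or "sum".
    """
    if "gene_id" not in matrix.columns:
        raise ValidationError("expression matrix lacks gene_id column")
    if (matrix["gene_id"] == "").any():
        raise ValidationError("isoform with unknown parent gene")
    tissues = [c for c in matrix.columns if c != "gene_id"]
    grouped = matrix.groupby("gene_id")[tissues]
    fpkm = grouped.max() if collapse == "max" else grouped.sum()
    fpkm = fpkm.sort_index()
    return GeneExpression(fpkm, fpkm > threshold, threshold)


@dataclass(frozen=True)
class CoexpressionResult:
    """Tissues in which a TF-TcoF pair is simultaneously expressed."""

    tf_gene: str
    tcof_gene: str
    tissues_coexpressed: frozenset[str]

    @property
    def n_tissues(self) -> int:
        return len(self.tissues_coexpressed)


def coexpression(
    pairs: list[tuple[str, str]],
    expr: GeneExpression,
    broad_cutoff: int = 10,
) -> tuple[list[CoexpressionResult], dict]:
    """Per-pair coexpressed tissue sets and summary counts.

    Pairs with a member absent from the expression table are not scored;
    they are reported separately in the summary. The summary counts pairs
    coexpressed in >= 1 tissue, in all tissues, and in more than
    ``broad_cutoff`` tissues, plus per-TF and per-TcoF partner
    coexpression percentages.
    """
    present_genes = set(expr.presence.index)
    n_tissues = len(expr.tissues)
    results: list[CoexpressionResult] = []
    unmeasured: list[tuple[str, str]] = []
    for tf, tcof in pairs:
        if tf not in present_genes or tcof not in present_genes:
            unmeasured.append((tf, tcof))
            continue
        both = expr.presence.loc[tf] & expr.presence.loc[tcof]
        results.append(
            CoexpressionResult(tf, tcof, frozenset(t for t, v in both.items() if v))
        )

    def _per_partner(key_idx: int) -> dict[str, float]:
        partners: dict[str, list[int]] = {}
        for r in results:
            key = (r.tf_gene, r.tcof_gene)[key_idx]
            partners.setdefault(key, []).append(r.n_tissues)
        return {
            k: pct(sum(1 for n in v if n > 0), len(v), 2) for k, v in sorted(partners.items())
        }

    summary = {
        "n_pairs_total": len(pairs),
        "n_pairs_analyzed": len(results),
        "n_pairs_unmeasured": len(unmeasured),
        "coexpressed_any": sum(1 for r in results if r.n_tissues > 0),
        "coexpressed_all_tissues": sum(1 for r in results if r.n_tissues == n_tissues),
        "coexpressed_gt_cutoff": sum(1 for r in results if r.n_tissues > broad_cutoff),
        "broad_cutoff": broad_cutoff,
        "per_tf_pct": _per_partner(0),
        "per_tcof_pct": _per_partner(1),
    }
    return results, summary
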