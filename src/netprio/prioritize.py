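"""Composite gene prioritization score, top-k ranking, and target gate.

The score combines pathway significance, expression abundance, and pathway
relevance with fixed weights:

    Score = 0.5 * (-log10(p_adjust)) + 0.3 * log2(FPKM + 1) + 0.2 * relevance

Genes are ranked by descending score; equal scores are broken by |log2FC|
descending and then gene id ascending (a stable documented convention — the
source ranking does not disclose its tie rule).  The final target gate keeps
genes that are simultaneously significantly differentially expressed
(FDR < 0.05, |log2FC| >= 0.5), ranked within the top-k, and flagged as having
documented functional involvement — the last criterion is not computable and
is supplied externally as a boolean annotation per gene.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError

logger = logging.getLogger(__name__)

DEFAULT_WEIGHTS = (0.5, 0.3, 0.2)


@dataclass(frozen=True)
class TargetGateCriteria:
    """Multi-criteria gate for final target selection."""

    fdr_max: float = 0.05
    abs_lfc_min: float = 0.5
    top_k: int = 20

    def __post_init__(self) -> None:
        if self.top_k < 1:
            raise ValidationError("top_k must be >= 1")


def composite_score(p_adjust, fpkm, relevance,
                    weights: tuple[float, float, float] = DEFAULT_WEIGHTS):
    """Evaluate the composite prioritization score (scalar or vectorized)."""
    p = np.asarray(p_adjust, dtype=float)
    f = np.asarray(fpkm, dtype=float)
    r = np.asarray(relevance, dtype=float)
    if np.any(p <= 0) or np.any(p > 1):
        raise ValidationError("p_adjust must lie in (0, 1]")
    if np.any(f < 0):
        raise ValidationError("fpkm must be non-negative")
    w_p, w_e, w_r = weights
    score = w_p * (-np.log10(p)) + w_e * np.log2(f + 1.0) + w_r * r
    return float(score) if score.ndim == 0 else score


def rank_genes(records: pd.DataFrame, k: int = 20,
               weights: tuple[float, float, float] = DEFAULT_WEIGHTS) -> pd.DataFrame:
    """Score and rank genes, returning the top-k rows with a ``rank`` column.

    ``records`` must carry p_adjust, fpkm, relevance and (for tie-breaking)
    log2fc, indexed by gene id.  Sort order: score descending, |log2fc|
    descending, gene id ascending; ranks run 1..k.
    """
    if len(records) == 0:
        raise ValidationError("at least one record is required")
    for col in ("p_adjust", "fpkm", "relevance"):
        if col not in records.columns:
            raise ValidationError(f"records must carry a {col!r} column")
    out = records.copy()
    out["score"] = composite_score(out["p_adjust"], out["fpkm"], out["relevance"], weights)
    abs_lfc = out["log2fc"].abs() if "log2fc" in out.columns else pd.Series(0.0, index=out.index)
    order = sorted(out.index,
                   key=lambda g: (-out.at[g, "score"], -abs_lfc[g], str(g)))
    if k > len(out):
        logger.warning("k=%d exceeds the %d available records; returning all", k, len(out))
        k = len(out)
    top = out.loc[order[:k]].copy()
    top["rank"] = np.arange(1, k + 1)
    return top


def select_targets(ranked: pd.DataFrame, de_records: pd.DataFrame,
                   annotation_flags: dict[str, bool],
                   criteria: TargetGateCriteria | None = None) -> list[str]:
    """Final target gate over the ranked table.

    A gene passes iff fdr < fdr_max AND |log2fc| >= abs_lfc_min AND
    rank <= top_k AND its externally supplied annotation flag is true.
    Missing flags count as false (with a warning).  ``de_records`` supplies
    fdr and log2fc where the ranked table lacks them.
    """
    criteria = criteria or TargetGateCriteria()
    selected = []
    for gene in ranked.index:
        rank = int(ranked.at[gene, "rank"])
        source = ranked if "fdr" in ranked.columns else de_records
        try:
            fdr = float(source.at[gene, "fdr"])
            lfc = float(source.at[gene, "log2fc"])
        except KeyError as exc:
            raise ValidationError(f"gene {gene}: missing fdr/log2fc") from exc
        if gene not in annotation_flags:
            logger.warning("gene %s has no annotation flag; treated as false", gene)
        flag = bool(annotation_flags.get(gene, False))
        if (fdr < criteria.fdr_max and abs(lfc) >= criteria.abs_lfc_min
                and rank <= criteria.top_k and flag):
            selected.append(gene)
    return selected


def round3(score: float) -> float:
    """Half-away-from-zero rounding to 3 decimals, as printed score columns use."""
    return math.floor(abs(score) * 1000 + 0.5) / 1000 * (1 if score >= 0 else -1)
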