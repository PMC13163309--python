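"""Pathway over-representation analysis and pathway-relevance weighting.

The test is the standard one-sided hypergeometric (Fisher exact upper tail):
for a universe of N genes containing K pathway members, drawing n DEGs and
observing k in the pathway, p = P(X >= k).  Adjusted p-values reuse the
shared Benjamini–Hochberg routine, pathways are ranked by adjusted p, and
genes receive the relevance weight entering the composite score: 1.0 for
membership in a top-five significant pathway, 0.5 for membership in any other
significant pathway, 0.0 otherwise (such genes are dropped before scoring).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from scipy.stats import hypergeom

from .diffexpr import bh_adjust
from .errors import ValidationError

logger = logging.getLogger(__name__)

SIGNIFICANCE_LEVEL = 0.05
TOP_PATHWAYS = 5


@dataclass(frozen=True)
class PathwaySet:
    pathway_id: str
    name: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValidationError(f"pathway {self.pathway_id} has no members")


@dataclass
class EnrichmentResult:
    pathway_id: str
    k_overlap: int
    K_set_size: int
    n_draw: int
    N_universe: int
    p_value: float
    p_adjust: float | None = None
    rank: int | None = None
    significant: bool = False
    overlap_genes: frozenset[str] = field(default_factory=frozenset)


def read_gmt(path: str | Path) -> list[PathwaySet]:
    """Read gene sets from a GMT file (id, description, members...)."""
    pathways = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValidationError(f"GMT line {lineno}: expected >= 3 tab-separated fields")
        pathways.append(PathwaySet(parts[0], parts[1], frozenset(g for g in parts[2:] if g)))
    return pathways


def ora_test(deg_set: set[str], pathway: PathwaySet, universe: set[str]) -> EnrichmentResult:
    """Upper-tail hypergeometric over-representation p-value for one pathway.

    The pathway is intersected with the universe before counting, and the DEG
    set must be a subset of the universe.
    """
    if not universe:
        raise ValidationError("universe is empty")
    deg_set = set(deg_set)
    if not deg_set <= set(universe):
        raise ValidationError("deg_set must be a subset of the universe")
    members = pathway.members & set(universe)
    overlap = deg_set & members
    N, K, n, k = len(universe), len(members), len(deg_set), len(overlap)
    p = float(hypergeom.sf(k - 1, N, K, n)) if k > 0 else 1.0
    return EnrichmentResult(pathway.pathway_id, k, K, n, N, min(p, 1.0),
                            overlap_genes=frozenset(overlap))


def enrich_all(deg_set: set[str], pathways: list[PathwaySet],
               universe: set[str],
               significance: float = SIGNIFICANCE_LEVEL) -> list[EnrichmentResult]:
    """Test every pathway, adjust with BH, and assign deterministic ranks.

    Results are sorted by (p_adjust, p_value, pathway_id) and ranked 1..m;
    significance is p_adjust < 0.05.
    """
    if not pathways:
        raise ValidationError("at least one pathway is required")
    results = [ora_test(deg_set, pw, universe) for pw in pathways]
    adjusted = bh_adjust([r.p_value for r in results])
    for r, adj in zip(results, adjusted):
        r.p_adjust = float(adj)
        r.significant = r.p_adjust < significance
    results.sort(key=lambda r: (r.p_adjust, r.p_value, r.pathway_id))
    for i, r in enumerate(results, start=1):
        r.rank = i
    return results


def assign_relevance(gene_id: str, enrichment_results: list[EnrichmentResult],
                     pathway_membership: dict[str, frozenset[str]],
                     top_k: int = TOP_PATHWAYS) -> float:
    """Pathway-relevance weight for one gene: 1.0 / 0.5 / 0.0.

    1.0 if the gene belongs to any of the top ``top_k`` significant pathways
    (smallest adjusted p), 0.5 if it belongs to any other significant
    pathway, 0.0 otherwise.  ``pathway_membership`` maps pathway_id to its
    member genes.
    """
    known = set().union(*pathway_membership.values()) if pathway_membership else set()
    if gene_id not in known:
        logger.warning("gene %s not found in any supplied pathway; relevance 0.0", gene_id)
        return 0.0
    significant = [r for r in sorted(enrichment_results, key=lambda r: r.rank or 0)
                   if r.significant]
    top = significant[:top_k]
    if any(gene_id in pathway_membership.get(r.pathway_id, frozenset()) for r in top):
        return 1.0
    if any(gene_id in pathway_membership.get(r.pathway_id, frozenset())
           for r in significant[top_k:]):
        return 0.5
    return 0.0


def results_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    """Tabular view of enrichment results, ordered by rank."""
    rows = [{"pathway_id": r.pathway_id, "rank": r.rank, "k": r.k_overlap,
             "K": r.K_set_size, "n": r.n_draw, "N": r.N_universe,
             "p_value": r.p_value, "p_adjust": r.p_adjust,
             "significant": r.significant} for r in results]
    return pd.DataFrame(rows).sort_values("rank").reset_index(drop=True)
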