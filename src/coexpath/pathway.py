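"""Over-representation analysis and the pathway-expression matrix.

Enrichment is a one-sided hypergeometric upper-tail test of the DCEG query
against each gene set, restricted to the tested universe, with BH
correction across the retained sets.  Pathway expression is the per-sample
arithmetic mean of an enriched set's annotated genes (by default restricted
to the DCEG union); the gene list actually averaged is persisted so a
validation cohort reuses identical lists.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd
from scipy import stats

from .diffexpr import bh_adjust
from .io_formats import ExpressionMatrix, GeneSetCollection

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PathwayExpressionMatrix:
    """Pathway × sample means over the recorded per-pathway gene lists."""

    data: pd.DataFrame  # pathways × samples
    gene_lists: dict[str, tuple[str, ...]]

    @property
    def pathway_names(self) -> list[str]:
        return list(self.data.index)


def enrich(
    query: set[str],
    universe: set[str],
    sets: GeneSetCollection,
    alpha: float = 0.05,
    use_adjusted: bool = True,
) -> pd.DataFrame:
    """Hypergeometric over-representation of ``query`` within ``universe``.

    Sets with zero overlap with the universe are dropped (logged).  The
    ``enriched`` flag uses BH-adjusted p < alpha by default; ``use_adjusted
    = False`` switches to raw p (both conventions appear in practice).
    """
    if not query:
        raise ValueError("empty query gene set")
    if not universe:
        raise ValueError("empty universe")
    stray = query - universe
    if stray:
        raise ValueError(
            f"query gene(s) outside the universe, e.g. {sorted(stray)[:3]}"
        )
    m = len(universe)
    n_query = len(query)
    rows = []
    for name, gs in sets.sets.items():
        in_universe = gs.genes & universe
        if not in_universe:
            logger.info("set %s has no overlap with the universe; dropped", name)
            continue
        k_set = len(in_universe)
        overlap = len(in_universe & query)
        # P(X >= overlap), X ~ Hypergeom(M=m, K=k_set, N=n_query)
        p = float(stats.hypergeom.sf(overlap - 1, m, k_set, n_query))
        rows.append((name, overlap, k_set, n_query, m, min(max(p, 0.0), 1.0)))
    if not rows:
        return pd.DataFrame(
            columns=[
                "overlap_count", "set_size_in_universe", "query_size",
                "universe_size", "p_value", "p_adjusted", "enriched",
            ]
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "set_name", "overlap_count", "set_size_in_universe",
            "query_size", "universe_size", "p_value",
        ],
    ).set_index("set_name")
    table["p_adjusted"] = bh_adjust(table["p_value"].to_numpy())
    crit = table["p_adjusted"] if use_adjusted else table["p_value"]
    table["enriched"] = crit < alpha
    return table


def merge_comparison_pathways(tables: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Union of enriched sets across comparisons, de-duplicated by name,
    with provenance recording which comparison(s) contributed."""
    if not tables:
        raise ValueError("need at least one enrichment table")
    provenance: dict[str, list[str]] = {}
    for comparison, table in tables.items():
        if "enriched" not in table.columns:
            raise ValueError("enrichment table lacks an 'enriched' column")
        for name in table.index[table["enriched"]]:
            provenance.setdefault(str(name), []).append(comparison)
    rows = [
        (name, ";".join(comps), len(comps)) for name, comps in provenance.items()
    ]
    return pd.DataFrame(
        rows, columns=["pathway", "comparisons", "n_comparisons"]
    ).set_index("pathway")


def build_pathway_expression(
    expr: ExpressionMatrix,
    enriched_names: list[str] | pd.Index,
    sets: GeneSetCollection,
    restrict_to: set[str] | str = "all",
) -> PathwayExpressionMatrix:
    """Pathway × sample matrix of mean expression over each enriched set's
    annotated genes.

    The averaged list for a pathway is ``set members ∩ restrict_to ∩ genes
    present in expr`` (``restrict_to="all"`` places no restriction, the
    convention for validation cohorts reusing frozen discovery lists goes
    through :func:`pathway_expression_from_lists` instead).  Sets with an
    empty list are dropped with a log note; dropping everything is an error.
    """
    expr_genes = set(expr.data.index)
    if isinstance(restrict_to, str):
        if restrict_to != "all":
            raise ValueError("restrict_to must be a gene set or 'all'")
        allowed = expr_genes
    else:
        allowed = set(restrict_to)
    gene_lists: dict[str, tuple[str, ...]] = {}
    for name in enriched_names:
        gs = sets[name]
        genes = sorted(gs.genes & allowed & expr_genes)
        if not genes:
            logger.info("pathway %s has no usable genes; dropped", name)
            continue
        gene_lists[name] = tuple(genes)
    if not gene_lists:
        raise ValueError("every pathway lost all its genes under the restriction")
    return pathway_expression_from_lists(expr, gene_lists, require_fraction=0.0)


def pathway_expression_from_lists(
    expr: ExpressionMatrix,
    gene_lists: dict[str, tuple[str, ...]],
    require_fraction: float = 0.5,
) -> PathwayExpressionMatrix:
    """Rebuild pathway expression from persisted gene lists (the frozen-list
    route for validation cohorts).  A pathway keeps its row only if at least
    ``require_fraction`` of its frozen list is present in ``expr``; the list
    is restricted to the available genes, never extended."""
    expr_genes = set(expr.data.index)
    rows = {}
    used_lists: dict[str, tuple[str, ...]] = {}
    for name, genes in gene_lists.items():
        present = tuple(g for g in genes if g in expr_genes)
        if not genes or len(present) / len(genes) < require_fraction or not present:
            logger.info(
                "pathway %s: %d/%d frozen genes present; dropped",
                name, len(present), len(genes),
            )
            continue
        rows[name] = expr.data.loc[list(present)].mean(axis=0)
        used_lists[name] = present
    if not rows:
        raise ValueError("no pathway retained enough genes")
    data = pd.DataFrame(rows).T
    data.columns = expr.data.columns
    return PathwayExpressionMatrix(data, used_lists)
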