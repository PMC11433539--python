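"""End-to-end orchestration of the discovery analysis.

Order of operations, per the study design: low-count filter and
normalization on the whole cohort; for each of the three pairwise
comparisons, NB Wald differential expression, a per-comparison
hypervariable-gene co-expression network with module detection,
eigengene–trait selection and DCEG derivation, and hypergeometric
enrichment of the DCEG union; then the enriched pathways are merged across
comparisons, a pathway-expression matrix (DCEG-restricted) is built on the
full cohort, a three-class random forest ranks pathways by out-of-bag
permutation importance, and the selected signatures are evaluated
(t-tests, severity correlation where scores exist, ROC/AUC).

Every stage degrades gracefully on empty upstream results (no DE genes,
no selected modules, no enriched pathways) so a global-null cohort flows
through to an empty signature list rather than an error.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import coexpression, diffexpr, evaluate, ml_rank, pathway, preprocess
from .io_formats import (
    COMPARISONS,
    CountMatrix,
    ExpressionMatrix,
    GeneSetCollection,
    PipelineConfig,
    SampleAnnotations,
)

logger = logging.getLogger(__name__)

#: fewer network genes than this and the scale-free fit / module detection
#: are meaningless; the comparison's network is skipped
MIN_NETWORK_GENES = 100


@dataclass
class ComparisonResult:
    """Everything computed for one pairwise comparison."""

    name: str
    reference: str
    case: str
    de_table: pd.DataFrame
    n_significant: int
    network_genes: list[str] = field(default_factory=list)
    beta: int | None = None
    fit_table: pd.DataFrame | None = None
    modules: coexpression.ModuleAssignment | None = None
    eigengenes: pd.DataFrame | None = None
    trait_table: pd.DataFrame | None = None
    dcegs_by_module: dict[str, set[str]] = field(default_factory=dict)
    dceg_union: set[str] = field(default_factory=set)
    enrichment: pd.DataFrame | None = None


@dataclass
class PipelineResult:
    config: PipelineConfig
    expression: ExpressionMatrix
    comparisons: dict[str, ComparisonResult]
    merged_pathways: pd.DataFrame
    pathway_expression: pathway.PathwayExpressionMatrix | None
    forest: ml_rank.ForestModel | None
    importance: pd.DataFrame | None
    signatures: list[str]
    group_tests: pd.DataFrame | None
    severity: dict[str, pd.DataFrame]
    diagnostics: pd.DataFrame | None

    @property
    def dceg_union_all(self) -> set[str]:
        out: set[str] = set()
        for comp in self.comparisons.values():
            out |= comp.dceg_union
        return out


def run_comparison(
    counts: CountMatrix,
    expr: ExpressionMatrix,
    annotations: SampleAnnotations,
    name: str,
    config: PipelineConfig,
) -> ComparisonResult:
    """Differential expression + network + DCEGs for one pairwise comparison."""
    ref, case = COMPARISONS[name]
    samples = annotations.samples_in(ref, case)
    samples = [s for s in counts.sample_ids if s in set(samples)]
    groups = [annotations.group_of(s) for s in samples]
    sub_counts = counts.subset_samples(samples)

    de_table = diffexpr.run_de(
        sub_counts, groups, ref, case,
        alpha=config.alpha, lfc_threshold=config.lfc_threshold,
    )
    result = ComparisonResult(
        name=name,
        reference=ref,
        case=case,
        de_table=de_table,
        n_significant=int(de_table["significant"].sum()),
    )

    # per-comparison hypervariable genes and network
    sub_expr = expr.subset_samples(samples)
    try:
        hv_expr, _ = preprocess.select_hypervariable(sub_expr, config.cv_threshold)
    except ValueError:
        logger.warning("%s: no hypervariable genes; network skipped", name)
        return result
    # constant genes have no correlation; drop defensively
    sd = hv_expr.data.std(axis=1)
    hv_expr = ExpressionMatrix(hv_expr.data.loc[sd > 0], hv_expr.transform_tag)
    if hv_expr.data.shape[0] < MIN_NETWORK_GENES:
        logger.warning(
            "%s: only %d hypervariable genes (<%d); network skipped",
            name, hv_expr.data.shape[0], MIN_NETWORK_GENES,
        )
        return result
    result.network_genes = list(hv_expr.data.index)

    sim = coexpression.similarity(hv_expr)
    beta, fit_table = coexpression.pick_soft_threshold(
        sim,
        powers=range(config.power_min, config.power_max + 1),
        fit_target=config.fit_target,
    )
    result.beta, result.fit_table = beta, fit_table
    adj = coexpression.adjacency(sim, beta)
    tom_m = coexpression.tom(adj)
    modules = coexpression.detect_modules(
        tom_m.dissimilarity, min_size=config.min_module_size,
        cut_quantile=config.cut_quantile, expr=hv_expr,
    )
    result.modules = modules
    if not modules.module_names:
        return result
    mes = coexpression.module_eigengenes(hv_expr, modules)
    result.eigengenes = mes
    trait = coexpression.module_trait(
        mes, annotations, (ref, case),
        r_threshold=config.trait_r_threshold, alpha=config.alpha,
    )
    result.trait_table = trait
    result.dcegs_by_module, result.dceg_union = coexpression.derive_dcegs(
        de_table, modules, trait
    )
    return result


def run_pipeline(
    counts: CountMatrix,
    annotations: SampleAnnotations,
    gene_sets: GeneSetCollection,
    config: PipelineConfig | None = None,
    seed: int | None = None,
) -> PipelineResult:
    """Run the full discovery analysis.  ``seed`` drives the random forest
    (the only stochastic stage); it defaults to ``config.seed``."""
    config = config or PipelineConfig()
    seed = config.seed if seed is None else seed
    annotations.require_match(counts.sample_ids)

    filtered = preprocess.filter_low_counts(counts, config.min_total)
    expr = preprocess.normalize_vst(filtered)

    comparisons: dict[str, ComparisonResult] = {}
    enrichment_tables: dict[str, pd.DataFrame] = {}
    for name in COMPARISONS:
        comp = run_comparison(filtered, expr, annotations, name, config)
        comparisons[name] = comp
        if comp.dceg_union:
            universe = set(filtered.gene_ids)
            comp.enrichment = pathway.enrich(
                comp.dceg_union, universe, gene_sets, alpha=config.alpha
            )
            enrichment_tables[name] = comp.enrichment

    merged = (
        pathway.merge_comparison_pathways(enrichment_tables)
        if enrichment_tables
        else pd.DataFrame(columns=["comparisons", "n_comparisons"])
    )

    result = PipelineResult(
        config=config,
        expression=expr,
        comparisons=comparisons,
        merged_pathways=merged,
        pathway_expression=None,
        forest=None,
        importance=None,
        signatures=[],
        group_tests=None,
        severity={},
        diagnostics=None,
    )
    if merged.empty:
        logger.info("no enriched pathways; ranking and evaluation skipped")
        return result

    dceg_all = result.dceg_union_all
    try:
        p_matrix = pathway.build_pathway_expression(
            expr, list(merged.index), gene_sets, restrict_to=dceg_all
        )
    except ValueError:
        logger.warning("pathway expression empty after DCEG restriction")
        return result
    result.pathway_expression = p_matrix

    y = [annotations.group_of(s) for s in p_matrix.data.columns]
    forest = ml_rank.train_forest(
        p_matrix.data.T, y, n_trees=config.n_trees, seed=seed
    )
    importance = ml_rank.permutation_importance(
        forest, p_matrix.data.T, y,
        n_repeats=config.importance_repeats,
        seed=seed + 1,
    )
    result.forest = forest
    result.importance = importance
    result.signatures = ml_rank.select_signatures(
        importance, config.importance_threshold
    )

    result.group_tests = evaluate.group_ttests(p_matrix, annotations)
    for index in ("easi", "scorad"):
        sev = annotations.data[index]
        usable = sev[np.isfinite(sev.to_numpy(dtype=float))]
        if len(usable) >= 5:
            result.severity[index] = evaluate.severity_correlation(
                p_matrix, annotations, index
            )
    result.diagnostics = evaluate.diagnostics_table(
        p_matrix.data, annotations, cohort="discovery"
    )
    return result
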