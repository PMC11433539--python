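"""Weighted gene co-expression network construction and module analysis.

The stages follow the standard weighted-network recipe: a Pearson
similarity matrix S, an unsigned soft-thresholded adjacency A = |S|^beta
with beta chosen by the scale-free topology criterion, the topological
overlap matrix (TOM) and its dissimilarity 1 - TOM, average-linkage
hierarchical clustering with a static quantile tree cut and a minimum
module size, module eigengenes (first principal component of the
standardized module submatrix), Spearman module–trait selection, and
finally the overlap of significant DE genes with selected modules — the
differentially co-expressed genes (DCEGs).

The network is unsigned: cor^beta with odd beta would produce negative
adjacencies, so |cor|^beta is the consistent convention.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .io_formats import ExpressionMatrix, SampleAnnotations

logger = logging.getLogger(__name__)

#: Size-ordered color aliases for reporting (largest module first), matching
#: the conventional weighted-network palette ordering.
MODULE_COLORS = (
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan", "midnightblue",
    "lightcyan", "grey60", "lightgreen", "lightyellow", "royalblue",
)

UNASSIGNED = "unassigned"


@dataclass(frozen=True)
class SimilarityMatrix:
    """Symmetric Pearson gene–gene correlation matrix with unit diagonal."""

    data: pd.DataFrame

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)


@dataclass(frozen=True)
class AdjacencyMatrix:
    """Unsigned soft-thresholded adjacency |S|^beta, values in [0, 1]."""

    data: pd.DataFrame
    power_beta: int


@dataclass(frozen=True)
class TomMatrix:
    """Topological overlap matrix; ``dissimilarity`` is 1 - TOM."""

    data: pd.DataFrame

    @property
    def dissimilarity(self) -> pd.DataFrame:
        return 1.0 - self.data


@dataclass(frozen=True)
class ModuleAssignment:
    """Gene → module label partition; labels "M1", "M2", ... by decreasing
    size, plus the ``unassigned`` bucket for genes in no module of at least
    ``min_size`` members."""

    labels: pd.Series  # index: gene ids; values: "M1", ..., or UNASSIGNED
    min_size: int

    @property
    def module_names(self) -> list[str]:
        names = [l for l in self.labels.unique() if l != UNASSIGNED]
        return sorted(names, key=lambda l: int(l[1:]))

    def members(self, module: str) -> list[str]:
        return list(self.labels.index[self.labels == module])

    def color_alias(self, module: str) -> str:
        i = int(module[1:]) - 1
        return MODULE_COLORS[i] if i < len(MODULE_COLORS) else f"module{i + 1}"


def similarity(expr: ExpressionMatrix) -> SimilarityMatrix:
    """Pairwise Pearson correlation of gene expression profiles across the
    samples.  Constant genes have no defined correlation and are an error —
    the CV filter upstream is expected to have removed them."""
    values = expr.data.to_numpy(dtype=float)
    if values.shape[1] < 4:
        raise ValueError("similarity needs at least 4 samples")
    sd = values.std(axis=1)
    if np.any(sd == 0):
        gene = expr.data.index[int(np.argmax(sd == 0))]
        raise ValueError(f"constant gene {gene!r} has no defined correlation")
    s = np.corrcoef(values)
    s = np.clip(s, -1.0, 1.0)
    np.fill_diagonal(s, 1.0)
    df = pd.DataFrame(s, index=expr.data.index, columns=expr.data.index)
    return SimilarityMatrix(df)


def pick_soft_threshold(
    s: SimilarityMatrix,
    powers: range | list[int] = range(1, 21),
    fit_target: float = 0.85,
    n_bins: int = 10,
    min_connectivity: float = 1.0,
) -> tuple[int, pd.DataFrame]:
    """Pick the smallest power whose signed scale-free fit R² reaches
    ``fit_target``; if none qualifies, the power with the best fit is used
    with a warning.

    For each power: connectivity k_i = sum_{j != i} |S_ij|^beta; the
    degree distribution is binned and log10(bin frequency) regressed on
    log10(mean bin connectivity); signed R² = R² × (−sign(slope)), so a
    decreasing (scale-free-like) degree distribution scores positively.
    Powers that crush the network below ``min_connectivity`` mean edges per
    gene are excluded from the search (a vanishing network fits a power law
    trivially but carries no topology worth clustering).
    """
    abs_s = np.abs(s.data.to_numpy(dtype=float))
    np.fill_diagonal(abs_s, 0.0)
    if abs_s.shape[0] < 100:
        logger.warning(
            "only %d genes: scale-free fit is unreliable below ~100 genes",
            abs_s.shape[0],
        )
    rows = []
    for beta in powers:
        k = (abs_s**beta).sum(axis=1)
        rows.append((int(beta), *_scale_free_fit(k, n_bins)))
    table = pd.DataFrame(rows, columns=["power", "signed_r2", "mean_connectivity"])
    usable = table[table["mean_connectivity"] >= min_connectivity]
    if usable.empty:
        usable = table
    if fit_target <= 0:  # no fit requirement: every power qualifies
        qualifying = usable
    else:
        qualifying = usable[usable["signed_r2"] >= fit_target]
    if len(qualifying):
        beta = int(qualifying["power"].iloc[0])
    else:
        beta = int(usable.loc[usable["signed_r2"].idxmax(), "power"])
        logger.warning(
            "no power reached signed R^2 >= %.2f; using best power %d (R^2=%.3f)",
            fit_target,
            beta,
            float(usable["signed_r2"].max()),
        )
    return beta, table


def _scale_free_fit(k: np.ndarray, n_bins: int) -> tuple[float, float]:
    """Signed R² of the log-log degree-distribution regression, plus mean
    connectivity.

    The connectivity range is split into ``n_bins`` equal-width bins; the
    proportion of genes per bin (the empirical degree frequency) is
    regressed on the bin's mean connectivity, both log10.  Under a
    scale-free (power-law) degree distribution the regression is linear
    with negative slope, so signed R² = R² × (−sign(slope)) is high.
    """
    mean_k = float(k.mean())
    kmax = float(k.max())
    if kmax <= 0:
        return 0.0, mean_k
    edges = np.linspace(0.0, kmax, n_bins + 1)
    which = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    xs, ys = [], []
    for b in range(n_bins):
        mask = which == b
        if not mask.any():
            continue
        mk = float(k[mask].mean())
        if mk <= 0:
            continue
        xs.append(np.log10(mk))
        ys.append(np.log10(mask.sum() / len(k)))
    if len(set(np.round(xs, 12))) < 2:
        raise ValueError("fewer than 2 distinct non-empty connectivity bins")
    slope, _, r, _, _ = stats.linregress(xs, ys)
    signed_r2 = float(r**2 * (-np.sign(slope)) if slope != 0 else 0.0)
    return signed_r2, mean_k


def adjacency(s: SimilarityMatrix, beta: int) -> AdjacencyMatrix:
    """Unsigned adjacency A_ij = |S_ij|^beta."""
    if not 1 <= int(beta) <= 20:
        raise ValueError("beta must be in 1..20")
    a = np.abs(s.data.to_numpy(dtype=float)) ** int(beta)
    df = pd.DataFrame(a, index=s.data.index, columns=s.data.columns)
    return AdjacencyMatrix(df, int(beta))


def tom(a: AdjacencyMatrix) -> TomMatrix:
    """Topological overlap:
    TOM_ij = (l_ij + A_ij) / (min(k_i, k_j) + 1 − A_ij) for i ≠ j, with
    l_ij = Σ_u≠i,j A_iu A_uj and k_i = Σ_u≠i A_iu; TOM_ii = 1."""
    adj = a.data.to_numpy(dtype=float).copy()
    np.fill_diagonal(adj, 0.0)
    k = adj.sum(axis=1)
    l = adj @ adj  # includes u = i and u = j terms, but diagonal is 0 so ok
    num = l + adj
    min_k = np.minimum.outer(k, k)
    denom = min_k + 1.0 - adj
    with np.errstate(invalid="ignore", divide="ignore"):
        t = np.where(denom > 0, num / denom, 0.0)
    np.fill_diagonal(t, 1.0)
    t = np.clip(t, 0.0, 1.0)
    return TomMatrix(pd.DataFrame(t, index=a.data.index, columns=a.data.columns))


def detect_modules(
    dissim: pd.DataFrame,
    min_size: int = 50,
    cut_quantile: float | None = None,
    expr: ExpressionMatrix | None = None,
    membership_alpha: float = 0.05,
) -> ModuleAssignment:
    """Detect co-expression modules from the TOM dissimilarity by
    average-linkage hierarchical clustering; clusters smaller than
    ``min_size`` become ``unassigned``; surviving modules are labeled
    "M1", "M2", ... by decreasing size.

    Default (two-stage) procedure: the merge sequence is scanned for the
    earliest partition with the maximal number of clusters of at least
    ``min_size`` members — these tight, early-forming branches are the
    module *cores*.  When ``expr`` is supplied, membership is then
    completed by module-eigengene correlation: every network gene is
    assigned to the core whose eigengene it correlates with most strongly
    in absolute value, provided that correlation is significant under a
    Bonferroni-controlled test at ``membership_alpha`` (genes failing the
    test stay unassigned, so background genes are not absorbed by
    proximity alone).  Without ``expr`` the cores themselves are the
    modules.

    Passing ``cut_quantile`` bypasses the two-stage procedure and cuts the
    tree at that quantile of the merge heights (a simple static-height
    convention, useful when the expected cut height is known).
    """
    genes = list(dissim.index)
    d = dissim.to_numpy(dtype=float)
    d = (d + d.T) / 2.0
    np.fill_diagonal(d, 0.0)
    condensed = squareform(d, checks=False)
    z = linkage(condensed, method="average")
    heights = z[:, 2]
    if cut_quantile is not None:
        cut = float(np.quantile(heights, cut_quantile))
        raw = fcluster(z, t=cut, criterion="distance")
    else:
        raw = _core_partition(z, len(genes), min_size)
    labels = _label_by_size(raw, genes, min_size)
    assignment = ModuleAssignment(labels, min_size)
    if cut_quantile is None and expr is not None and assignment.module_names:
        assignment = _complete_membership(
            assignment, expr, min_size, membership_alpha
        )
    if not assignment.module_names:
        logger.warning(
            "no cluster reached min_size=%d; all %d genes unassigned",
            min_size,
            len(genes),
        )
    return assignment


def _label_by_size(
    raw: np.ndarray, genes: list[str], min_size: int, sentinel: int | None = None
) -> pd.Series:
    """Relabel raw cluster ids as "M1", "M2", ... by decreasing size
    (ties broken by first-gene position); small clusters, and the
    ``sentinel`` id if given, become unassigned."""
    labels = pd.Series(UNASSIGNED, index=pd.Index(genes), dtype=object)
    sizes = pd.Series(raw).value_counts()
    big = sizes[sizes >= min_size]
    if sentinel is not None and sentinel in big.index:
        big = big.drop(sentinel)
    order = sorted(
        big.index,
        key=lambda c: (-int(big[c]), int(np.argmax(raw == c))),
    )
    for rank, cluster_id in enumerate(order, start=1):
        labels.iloc[np.where(raw == cluster_id)[0]] = f"M{rank}"
    return labels


def _core_partition(z: np.ndarray, n: int, min_size: int) -> np.ndarray:
    """Replay the merge sequence with union–find and return the flat
    clustering of the earliest state with the maximal number of clusters
    of at least ``min_size`` members.

    Early states keep branches tight (background genes attach higher in
    the tree), so the winning state contains pure module cores.  States
    inside a tie block of equal merge heights are not valid cut points and
    are skipped.  If no cluster ever reaches ``min_size`` the all-singleton
    state is returned (everything later becomes unassigned).
    """
    parent = list(range(n + len(z)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    size = [1] * n + [0] * len(z)
    n_big = n if min_size <= 1 else 0
    best_n_big, best_step = n_big, -1
    heights = z[:, 2]
    for i in range(len(z)):
        a, b = find(int(z[i, 0])), find(int(z[i, 1]))
        node = n + i
        parent[a] = parent[b] = node
        size[node] = size[a] + size[b]
        n_big += int(size[node] >= min_size)
        n_big -= int(size[a] >= min_size) + int(size[b] >= min_size)
        if i + 1 == len(z):
            continue  # all-merged state: one giant cluster, never a module cut
        if heights[i + 1] - heights[i] <= 1e-12:
            continue
        if n_big > best_n_big:
            best_n_big, best_step = n_big, i
    parent = list(range(n + len(z)))
    for i in range(best_step + 1):
        a, b = find(int(z[i, 0])), find(int(z[i, 1]))
        parent[a] = parent[b] = n + i
    return np.array([find(g) for g in range(n)])


def _complete_membership(
    cores: ModuleAssignment,
    expr: ExpressionMatrix,
    min_size: int,
    alpha: float,
) -> ModuleAssignment:
    """Assign every network gene to the core whose eigengene it correlates
    with most strongly, requiring Bonferroni significance of that
    correlation; re-apply the minimum-size rule afterwards."""
    genes = list(cores.labels.index)
    x = expr.data.loc[genes].to_numpy(dtype=float)
    n_samples = x.shape[1]
    core_names = cores.module_names
    mes = np.column_stack(
        [module_eigengene(expr, cores.members(m)).to_numpy() for m in core_names]
    )
    # correlation of every gene with every core eigengene
    xs = (x - x.mean(axis=1, keepdims=True))
    xn = xs / np.linalg.norm(xs, axis=1, keepdims=True)
    ms = mes - mes.mean(axis=0, keepdims=True)
    mn = ms / np.linalg.norm(ms, axis=0, keepdims=True)
    r = xn @ mn  # genes × cores
    n_tests = r.size
    t_crit = stats.t.ppf(1.0 - (alpha / n_tests) / 2.0, df=n_samples - 2)
    r_crit = np.sqrt(t_crit**2 / (t_crit**2 + n_samples - 2))
    best = np.argmax(np.abs(r), axis=1)
    best_r = np.abs(r)[np.arange(len(genes)), best]
    raw = np.where(best_r >= r_crit, best, -1)
    labels = _label_by_size(raw, genes, min_size, sentinel=-1)
    return ModuleAssignment(labels, min_size)


def module_eigengene(expr: ExpressionMatrix, members: set[str] | list[str]) -> pd.Series:
    """Module eigengene: first right singular vector of the standardized
    (zero mean, unit variance per gene) member submatrix, unit norm, sign
    aligned so its correlation with the member-wise mean profile is >= 0."""
    members = list(members)
    if len(members) < 2:
        raise ValueError("a module eigengene needs at least 2 member genes")
    missing = [g for g in members if g not in expr.data.index]
    if missing:
        raise KeyError(f"module member {missing[0]!r} absent from the expression matrix")
    x = expr.data.loc[members].to_numpy(dtype=float)
    mean = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=1, keepdims=True)
    if np.any(sd == 0):
        gene = members[int(np.argmax(sd.ravel() == 0))]
        raise ValueError(f"constant member gene {gene!r} cannot be standardized")
    zmat = (x - mean) / sd
    _, _, vt = np.linalg.svd(zmat, full_matrices=False)
    me = vt[0]
    mean_profile = zmat.mean(axis=0)
    if np.dot(me, mean_profile) < 0:
        me = -me
    return pd.Series(me, index=expr.data.columns)


def module_eigengenes(
    expr: ExpressionMatrix, modules: ModuleAssignment
) -> pd.DataFrame:
    """Eigengenes of every named module, samples × modules."""
    out = {}
    for name in modules.module_names:
        out[name] = module_eigengene(expr, modules.members(name))
    return pd.DataFrame(out, index=expr.data.columns)


def _spearman_binary(me: np.ndarray, trait: np.ndarray) -> float:
    r = stats.spearmanr(me, trait).statistic
    return float(r) if np.isfinite(r) else 0.0


def module_trait(
    mes: pd.DataFrame,
    annotations: SampleAnnotations,
    comparison: tuple[str, str],
    r_threshold: float = 0.5,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Spearman correlation of each module eigengene with the binary
    phenotype (reference group coded 0, case group 1).

    Two-sided p from the t approximation; for fewer than 10 samples the p
    is an exact permutation p over all case/control assignments.  A module
    is ``selected`` when |R| > ``r_threshold`` and p < ``alpha``.
    """
    ref, case = comparison
    samples = [
        s for s in mes.index if annotations.group_of(s) in (ref, case)
    ]
    if len(samples) < 5:
        raise ValueError("module-trait correlation needs at least 5 samples")
    trait = np.array(
        [1.0 if annotations.group_of(s) == case else 0.0 for s in samples]
    )
    if trait.min() == trait.max():
        raise ValueError("both comparison groups must be present")
    rows = []
    for module in mes.columns:
        me = mes.loc[samples, module].to_numpy(dtype=float)
        r = _spearman_binary(me, trait)
        if len(samples) < 10:
            p = _exact_permutation_p(me, trait, r)
        else:
            p = float(stats.spearmanr(me, trait).pvalue)
        rows.append((module, r, p, abs(r) > r_threshold and p < alpha))
    return pd.DataFrame(
        rows, columns=["module", "spearman_r", "p_value", "selected"]
    ).set_index("module")


def _exact_permutation_p(me: np.ndarray, trait: np.ndarray, r_obs: float) -> float:
    """Exact two-sided permutation p for a binary trait: enumerate every
    assignment of the case labels."""
    n = len(trait)
    n_case = int(trait.sum())
    count = 0
    total = 0
    for combo in itertools.combinations(range(n), n_case):
        t = np.zeros(n)
        t[list(combo)] = 1.0
        r = _spearman_binary(me, t)
        total += 1
        if abs(r) >= abs(r_obs) - 1e-12:
            count += 1
    return count / total


def derive_dcegs(
    de: pd.DataFrame,
    modules: ModuleAssignment,
    trait: pd.DataFrame,
) -> tuple[dict[str, set[str]], set[str]]:
    """Differentially co-expressed genes: significant DE genes intersected
    with each selected (phenotype-correlated) module; returns the per-module
    sets and their union."""
    sig = set(de.index[de["significant"]])
    per_module: dict[str, set[str]] = {}
    union: set[str] = set()
    for module in trait.index[trait["selected"]]:
        members = set(modules.members(module))
        dcegs = sig & members
        per_module[module] = dcegs
        union |= dcegs
    return per_module, union
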