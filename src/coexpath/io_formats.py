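"""Readers, writers and validated domain containers for every external format
the pipeline touches.

All downstream stages consume the validated types defined here — a raw
integer count matrix (``CountMatrix``), per-sample clinical annotations
(``SampleAnnotations``), a GMT gene-set collection (``GeneSetCollection``)
and a normalized expression matrix (``ExpressionMatrix``).  Files are plain
TSV (genes in rows, samples in columns, the GEO series-matrix convention)
or standard GMT; run configuration is YAML with every analysis threshold
defaulted to the published values.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

#: Allowed clinical group labels, in the conventional reporting order.
GROUPS = ("lesional", "non_lesional", "healthy")

#: The three pairwise comparisons, each as (reference group, case group).
#: Fold changes are case over reference.
COMPARISONS: dict[str, tuple[str, str]] = {
    "lesional_vs_healthy": ("healthy", "lesional"),
    "lesional_vs_non_lesional": ("non_lesional", "lesional"),
    "non_lesional_vs_healthy": ("healthy", "non_lesional"),
}


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


def _check_unique(ids: Iterable[str], what: str) -> None:
    seen: set[str] = set()
    for x in ids:
        if x in seen:
            raise FormatError(f"duplicate {what} identifier: {x!r}")
        seen.add(x)


@dataclass(frozen=True)
class CountMatrix:
    """Raw integer gene × sample counts.

    Invariants: unique gene and sample identifiers, all values integral and
    non-negative, at least two samples.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        _check_unique(df.index, "gene")
        _check_unique(df.columns, "sample")
        if df.shape[1] < 2:
            raise FormatError("a count matrix needs at least 2 samples")
        values = df.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            bad = df.columns[[not np.issubdtype(t, np.number) for t in df.dtypes]]
            raise FormatError(f"non-numeric count column(s): {list(bad)}")
        if np.any(values < 0) or np.any(values != np.floor(values)):
            i, j = next(
                zip(*np.where((values < 0) | (values != np.floor(values))))
            )
            raise FormatError(
                f"count for gene {df.index[i]!r}, sample {df.columns[j]!r} "
                f"is not a non-negative integer: {values[i, j]!r}"
            )
        if not np.issubdtype(values.dtype, np.integer):
            object.__setattr__(self, "data", df.astype(np.int64))

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    def subset_samples(self, sample_ids: Iterable[str]) -> "CountMatrix":
        return CountMatrix(self.data.loc[:, list(sample_ids)])


@dataclass(frozen=True)
class SampleAnnotations:
    """Per-sample clinical annotations: group label plus optional EASI and
    SCORAD severity scores (missing encoded as NaN, never 0)."""

    data: pd.DataFrame  # index: sample_id; columns: group, easi, scorad

    def __post_init__(self) -> None:
        df = self.data
        _check_unique(df.index, "sample")
        if "group" not in df.columns:
            raise FormatError("annotations need a 'group' column")
        bad = sorted(set(df["group"]) - set(GROUPS))
        if bad:
            raise FormatError(
                f"unknown group label(s) {bad}; allowed: {list(GROUPS)}"
            )
        for col in ("easi", "scorad"):
            if col not in df.columns:
                df = df.assign(**{col: np.nan})
        vals = df[["easi", "scorad"]].to_numpy(dtype=float)
        if np.any(vals[np.isfinite(vals)] < 0):
            raise FormatError("severity scores must be non-negative")
        object.__setattr__(
            self, "data", df[["group", "easi", "scorad"]].copy()
        )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    def group_of(self, sample_id: str) -> str:
        return str(self.data.loc[sample_id, "group"])

    def samples_in(self, *groups: str) -> list[str]:
        for g in groups:
            if g not in GROUPS:
                raise ValueError(f"unknown group {g!r}; allowed: {list(GROUPS)}")
        mask = self.data["group"].isin(groups)
        return list(self.data.index[mask])

    def require_match(self, sample_ids: Iterable[str]) -> None:
        """Assert this annotation covers exactly the companion matrix's samples."""
        want = set(sample_ids)
        have = set(self.data.index)
        if want != have:
            missing = sorted(want - have)
            extra = sorted(have - want)
            raise FormatError(
                f"annotation/sample mismatch; missing={missing} extra={extra}"
            )


@dataclass(frozen=True)
class GeneSet:
    name: str
    description: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.genes:
            raise FormatError(f"gene set {self.name!r} has no members")


@dataclass(frozen=True)
class GeneSetCollection:
    """Named gene sets (the open substitute for a proprietary pathway
    catalogue).  Set names are unique; member sets are non-empty."""

    sets: dict[str, GeneSet]

    def __post_init__(self) -> None:
        for name, gs in self.sets.items():
            if name != gs.name:
                raise FormatError(f"key {name!r} does not match set name {gs.name!r}")

    @property
    def names(self) -> list[str]:
        return list(self.sets)

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> GeneSet:
        return self.sets[name]


@dataclass(frozen=True)
class ExpressionMatrix:
    """Normalized real-valued gene × sample matrix.

    ``transform_tag`` records the normalization applied (provenance for the
    filter-then-normalize ordering assertion).
    """

    data: pd.DataFrame
    transform_tag: str = "raw"

    def __post_init__(self) -> None:
        _check_unique(self.data.index, "gene")
        _check_unique(self.data.columns, "sample")
        if self.data.isna().any().any():
            raise FormatError("expression matrix contains missing values")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    def subset_samples(self, sample_ids: Iterable[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data.loc[:, list(sample_ids)], self.transform_tag)

    def subset_genes(self, gene_ids: Iterable[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data.loc[list(gene_ids)], self.transform_tag)


# ---------------------------------------------------------------------------
# readers / writers


def read_counts(path: str | Path) -> CountMatrix:
    """Read a genes × samples TSV of raw counts (first column gene ids)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = pd.Index([str(g) for g in df.index])
    df.columns = [str(s) for s in df.columns]
    dup = df.index[df.index.duplicated()]
    if len(dup):
        raise FormatError(f"duplicate gene identifier: {dup[0]!r}")
    return CountMatrix(df)


def write_counts(counts: CountMatrix, path: str | Path) -> None:
    counts.data.to_csv(path, sep="\t", index_label="gene_id")


def read_annotations(path: str | Path) -> SampleAnnotations:
    """Read a sample annotation TSV: sample_id, group, optional easi/scorad."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    if "sample_id" not in df.columns:
        raise FormatError("annotation file needs a 'sample_id' column")
    df = df.set_index("sample_id")
    df.index = pd.Index([str(s) for s in df.index])
    return SampleAnnotations(df)


def write_annotations(ann: SampleAnnotations, path: str | Path) -> None:
    ann.data.to_csv(path, sep="\t", index_label="sample_id")


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a standard GMT file (name, description, members; tab-separated).

    Duplicate members within a set are collapsed; empty member fields are
    dropped; a duplicate set name or a line with fewer than three fields is a
    hard error.
    """
    sets: dict[str, GeneSet] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line has {len(fields)} field(s), needs >= 3"
                )
            name, desc = fields[0], fields[1]
            members = frozenset(g for g in fields[2:] if g.strip())
            if name in sets:
                raise FormatError(f"{path}:{lineno}: duplicate set name {name!r}")
            sets[name] = GeneSet(name, desc, members)
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for gs in collection.sets.values():
            fh.write("\t".join([gs.name, gs.description, *sorted(gs.genes)]) + "\n")


def read_expression(path: str | Path) -> ExpressionMatrix:
    """Read a normalized expression TSV; a leading ``# transform:`` comment
    line restores the transform tag."""
    tag = "unknown"
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("# transform:"):
            tag = first.split(":", 1)[1].strip()
            df = pd.read_csv(fh, sep="\t", index_col=0)
        else:
            fh.seek(0)
            df = pd.read_csv(fh, sep="\t", index_col=0)
    df.index = pd.Index([str(g) for g in df.index])
    df.columns = [str(s) for s in df.columns]
    return ExpressionMatrix(df.astype(float), tag)


def write_expression(expr: ExpressionMatrix, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# transform: {expr.transform_tag}\n")
        expr.data.to_csv(fh, sep="\t", index_label="gene_id")


def write_table(df: pd.DataFrame, path: str | Path, index_label: str = "id") -> None:
    """Write a result table as TSV with a fixed column order (as given)."""
    df.to_csv(path, sep="\t", index_label=index_label)


# ---------------------------------------------------------------------------
# run configuration


@dataclass(frozen=True)
class PipelineConfig:
    """Analysis thresholds, defaulted to the published values.

    min_total        — low-count filter: drop genes with fewer total reads.
    cv_threshold     — hypervariable-gene cutoff, percent CV.
    lfc_threshold    — |log2 fold change| required for DE significance.
    alpha            — BH-adjusted significance level (DE, ORA, module-trait).
    power_min/max    — soft-threshold search range.
    fit_target       — scale-free topology R² target.
    min_module_size  — smallest reportable co-expression module.
    trait_r_threshold— |Spearman R| gate for module–phenotype association.
    importance_threshold — mean-decrease-accuracy cutoff (percentage points).
    n_trees, importance_repeats, cut_quantile — algorithmic knobs.
    """

    min_total: int = 10
    cv_threshold: float = 15.0
    lfc_threshold: float = 1.0
    alpha: float = 0.05
    power_min: int = 1
    power_max: int = 20
    fit_target: float = 0.85
    min_module_size: int = 50
    trait_r_threshold: float = 0.5
    importance_threshold: float = 4.0
    n_trees: int = 500
    importance_repeats: int = 20
    #: None = automatic best-partition tree cut; a float cuts at that
    #: quantile of the dendrogram merge heights instead
    cut_quantile: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.min_total < 0:
            raise ValueError("min_total must be >= 0")
        if self.cv_threshold < 0:
            raise ValueError("cv_threshold must be >= 0")
        if self.lfc_threshold < 0:
            raise ValueError("lfc_threshold must be >= 0")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if not 1 <= self.power_min <= self.power_max <= 20:
            raise ValueError("power range must satisfy 1 <= min <= max <= 20")
        if not 0 < self.fit_target <= 1:
            raise ValueError("fit_target must be in (0, 1]")
        if self.min_module_size < 2:
            raise ValueError("min_module_size must be >= 2")
        if not 0 <= self.trait_r_threshold <= 1:
            raise ValueError("trait_r_threshold must be in [0, 1]")
        if self.n_trees < 1 or self.importance_repeats < 1:
            raise ValueError("n_trees and importance_repeats must be >= 1")
        if self.cut_quantile is not None and not 0 < self.cut_quantile <= 1:
            raise ValueError("cut_quantile must be in (0, 1] or null")


def load_config(path: str | Path | None = None, **overrides) -> PipelineConfig:
    """Load a YAML config; unknown keys are rejected, defaults fill the rest.

    The resolved configuration is echoed to the log so a run records the
    thresholds it actually used.
    """
    values: dict = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, dict):
            raise FormatError("config file must be a YAML mapping")
        values.update(loaded)
    values.update(overrides)
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = sorted(set(values) - known)
    if unknown:
        raise FormatError(f"unknown config key(s): {unknown}; allowed: {sorted(known)}")
    cfg = PipelineConfig(**values)
    logger.info("resolved configuration: %s", dataclasses.asdict(cfg))
    return cfg
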