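"""Synthetic three-group skin-transcriptome cohorts with planted structure.

The generator emulates the shape of a bulk RNA-seq case/control skin study:
three clinical groups (lesional, non-lesional, healthy) at configurable
sizes, negative-binomial counts with log-normal library-size factors,
planted differentially expressed genes, planted co-expression modules whose
latent factors may carry group-dependent means (so the modules correlate
with the phenotype), gene sets overlapping the planted genes, and severity
scores generated from planted pathway activity.  Every planted fact is
recorded in a :class:`SyntheticTruth` so downstream recovery can be scored.

Mechanism: each gene g has a baseline log2 mean ``b_g``; module members add
``lambda_g * z_m(sample)`` where ``z_m`` is a per-sample latent Gaussian
factor (group-shifted for association-flagged modules) and the loading
``lambda_g`` is calibrated from the NB noise variance so the average
pairwise Pearson correlation on the log scale hits the requested
``intra_module_cor``.  Counts are NB(mean = libsize * 2**logmu, dispersion)
via the gamma–Poisson mixture.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .io_formats import (
    COMPARISONS,
    GROUPS,
    CountMatrix,
    GeneSet,
    GeneSetCollection,
    SampleAnnotations,
)

_LN2 = math.log(2.0)

#: Default group-mean shift (in latent-factor SD units) for modules planted
#: with a phenotype association.  Three SD separates the groups clearly —
#: the regime where a module–trait screen fires — and induces member-gene
#: log2 fold changes of roughly 1–1.5, so associated-module genes are bona
#: fide DE genes at the conventional |log2FC| > 1 cutoff.
DEFAULT_ASSOC_SHIFT = 3.0


@dataclass
class ModuleSpec:
    """One planted co-expression module."""

    module_id: int
    genes: tuple[str, ...]
    loadings: dict[str, float]
    #: group -> latent-factor mean shift (groups absent from the mapping sit at 0)
    group_means: dict[str, float]

    @property
    def association_sign(self) -> int:
        if not self.group_means:
            return 0
        v = next(iter(self.group_means.values()))
        return int(np.sign(v))


@dataclass
class SyntheticTruth:
    """Ground-truth record of everything the generator planted."""

    seed: int
    group_sizes: tuple[int, int, int]
    #: comparison name -> {gene: true log2 fold change (case over reference)}
    de_genes: dict[str, dict[str, float]]
    modules: list[ModuleSpec]
    #: per-sample latent factors, samples × modules (column "module_<id>")
    latent: pd.DataFrame
    #: baseline log2 mean per gene (the fixed gene-level parameters)
    baseline_log2: pd.Series
    #: explicit DE genes: gene -> (target group, log2 shift applied there)
    de_assignment: dict[str, tuple[str, float]]
    #: NB dispersion used to synthesize counts
    dispersion: float
    #: gene-set name -> module_id, filled by generate_gene_sets
    informative_pathways: dict[str, int] = field(default_factory=dict)
    #: filled by generate_severity
    severity_model: dict[str, float] = field(default_factory=dict)

    def de_set(self, comparison: str, min_abs_lfc: float = 0.0) -> set[str]:
        """Genes with a planted |log2FC| above ``min_abs_lfc`` in a comparison."""
        return {
            g
            for g, lfc in self.de_genes[comparison].items()
            if abs(lfc) > min_abs_lfc
        }

    @property
    def module_genes(self) -> set[str]:
        return {g for m in self.modules for g in m.genes}


def _nb_log2_sd(mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Approximate SD of log2(count) for NB(mean, dispersion), delta method."""
    var_log = (1.0 / np.maximum(mean, 1e-9) + dispersion) / (_LN2**2)
    return np.sqrt(var_log)


def generate_cohort(
    n_genes: int = 5000,
    group_sizes: tuple[int, int, int] = (27, 27, 38),
    n_modules: int = 3,
    module_size: int = 100,
    intra_module_cor: float = 0.6,
    de_fraction: float = 0.05,
    lfc: float = 2.0,
    dispersion: float = 0.2,
    seed: int = 0,
    assoc_shift: float = DEFAULT_ASSOC_SHIFT,
    libsize_sd: float = 0.15,
) -> tuple[CountMatrix, SampleAnnotations, SyntheticTruth]:
    """Generate a three-group NB count cohort with planted DE genes and
    planted phenotype-associated co-expression modules.

    ``group_sizes`` is (lesional, non_lesional, healthy).  Planted DE genes
    are drawn outside the modules and shifted by ``2**lfc`` in their
    assigned group; module members acquire fold changes implicitly through
    the group-shifted latent factor, and those induced log2 fold changes are
    recorded in the truth as well.
    """
    if any(n < 3 for n in group_sizes):
        raise ValueError("each group needs at least 3 samples")
    if n_modules * module_size > n_genes:
        raise ValueError(
            f"{n_modules} modules of {module_size} genes exceed {n_genes} genes"
        )
    if not 0 <= intra_module_cor < 1:
        raise ValueError("intra_module_cor must be in [0, 1)")
    if not 0 <= de_fraction < 1:
        raise ValueError("de_fraction must be in [0, 1)")
    if dispersion <= 0:
        raise ValueError("dispersion must be positive")

    rng = np.random.default_rng(seed)
    gene_ids = [f"G{i + 1:05d}" for i in range(n_genes)]

    # baseline log2 means: moderately expressed transcriptome
    baseline = pd.Series(rng.normal(5.0, 1.5, size=n_genes), index=gene_ids)

    # --- planted modules -------------------------------------------------
    gene_order = rng.permutation(n_genes)
    modules: list[ModuleSpec] = []
    # association patterns cycle: +lesional, -lesional, +non_lesional
    patterns = [
        {"lesional": +assoc_shift},
        {"lesional": -assoc_shift},
        {"non_lesional": +assoc_shift},
    ]
    n_les, n_nonles, n_healthy = group_sizes
    n_samples = n_les + n_nonles + n_healthy
    group_frac = {
        "lesional": n_les / n_samples,
        "non_lesional": n_nonles / n_samples,
        "healthy": n_healthy / n_samples,
    }
    used = 0
    for m in range(n_modules):
        members_idx = gene_order[used : used + module_size]
        used += module_size
        pattern = patterns[m % len(patterns)] if assoc_shift != 0 else {}
        member_genes = tuple(gene_ids[i] for i in members_idx)
        # loading calibrated so cor on the log scale ~= intra_module_cor:
        # rho = lambda^2 Var(z) / (lambda^2 Var(z) + sigma_nb^2), where
        # Var(z) = 1 + between-group variance of the planted mean shifts
        sigma = _nb_log2_sd(2.0 ** baseline.iloc[members_idx].to_numpy(), dispersion)
        mean_shift = sum(group_frac[g] * v for g, v in pattern.items())
        var_between = sum(
            group_frac[g] * (pattern.get(g, 0.0) - mean_shift) ** 2
            for g in GROUPS
        )
        var_z = 1.0 + var_between
        if intra_module_cor > 0:
            lam = (
                np.sqrt(intra_module_cor / (1.0 - intra_module_cor))
                * sigma
                / np.sqrt(var_z)
            )
        else:
            lam = np.zeros_like(sigma)
        modules.append(
            ModuleSpec(
                module_id=m + 1,
                genes=member_genes,
                loadings={g: float(l) for g, l in zip(member_genes, lam)},
                group_means=pattern,
            )
        )

    # --- planted DE genes (outside modules) ------------------------------
    n_de = int(round(de_fraction * n_genes))
    free_idx = gene_order[used:]
    if n_de > len(free_idx):
        raise ValueError("de_fraction leaves no room outside planted modules")
    de_assignment: dict[str, tuple[str, float]] = {}
    for rank, gi in enumerate(free_idx[:n_de]):
        target = "lesional" if rank % 3 != 2 else "non_lesional"
        sign = 1.0 if rng.random() < 0.5 else -1.0
        de_assignment[gene_ids[gi]] = (target, sign * lfc)

    # --- true log2 fold changes per comparison ---------------------------
    de_genes: dict[str, dict[str, float]] = {name: {} for name in COMPARISONS}
    for name, (ref, case) in COMPARISONS.items():
        for g, (target, shift) in de_assignment.items():
            delta = shift * ((case == target) - (ref == target))
            if delta != 0:
                de_genes[name][g] = float(delta)
        for spec in modules:
            d_z = spec.group_means.get(case, 0.0) - spec.group_means.get(ref, 0.0)
            if d_z != 0:
                for g in spec.genes:
                    de_genes[name][g] = de_genes[name].get(g, 0.0) + float(
                        spec.loadings[g] * d_z
                    )

    count_df, ann_df, latent = _synthesize(
        baseline, modules, de_assignment, group_sizes, dispersion, libsize_sd,
        rng, sample_prefix="S",
    )
    truth = SyntheticTruth(
        seed=seed,
        group_sizes=tuple(group_sizes),
        de_genes=de_genes,
        modules=modules,
        latent=latent,
        baseline_log2=baseline,
        de_assignment=de_assignment,
        dispersion=dispersion,
    )
    return CountMatrix(count_df), SampleAnnotations(ann_df), truth


def _synthesize(
    baseline: pd.Series,
    modules: list[ModuleSpec],
    de_assignment: dict[str, tuple[str, float]],
    group_sizes: tuple[int, int, int],
    dispersion: float,
    libsize_sd: float,
    rng: np.random.Generator,
    sample_prefix: str,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Draw one cohort (counts, annotations, latent factors) from fixed
    gene-level parameters — shared by the discovery and validation
    generators so both cohorts realize the same planted truth."""
    gene_ids = list(baseline.index)
    gene_pos = {g: i for i, g in enumerate(gene_ids)}
    n_les, n_nonles, n_healthy = group_sizes
    n_samples = n_les + n_nonles + n_healthy
    groups = np.array(
        ["lesional"] * n_les + ["non_lesional"] * n_nonles + ["healthy"] * n_healthy
    )
    sample_ids = [f"{sample_prefix}{i + 1:03d}" for i in range(n_samples)]
    log_mu = np.tile(baseline.to_numpy()[:, None], (1, n_samples)).astype(float)
    latent = pd.DataFrame(index=sample_ids)
    for spec in modules:
        mu_z = np.array([spec.group_means.get(g, 0.0) for g in groups])
        z = mu_z + rng.normal(0.0, 1.0, size=n_samples)
        latent[f"module_{spec.module_id}"] = z
        idx = [gene_pos[g] for g in spec.genes]
        lam = np.array([spec.loadings[g] for g in spec.genes])
        log_mu[idx, :] += lam[:, None] * z[None, :]
    for g, (target, shift) in de_assignment.items():
        log_mu[gene_pos[g], :] += shift * (groups == target)

    libsize = np.exp(rng.normal(0.0, libsize_sd, size=n_samples))
    mean = libsize[None, :] * (2.0**log_mu)
    # NB via gamma-Poisson: shape 1/alpha, scale mean*alpha
    lam = rng.gamma(1.0 / dispersion, mean * dispersion)
    counts = rng.poisson(lam).astype(np.int64)
    count_df = pd.DataFrame(counts, index=gene_ids, columns=sample_ids)
    ann_df = pd.DataFrame(
        {"group": groups, "easi": np.nan, "scorad": np.nan}, index=sample_ids
    )
    return count_df, ann_df, latent


def generate_validation_cohort(
    truth: SyntheticTruth,
    group_sizes: tuple[int, int, int] = (29, 40, 39),
    seed: int = 1,
    libsize_sd: float = 0.15,
) -> tuple[CountMatrix, SampleAnnotations, pd.DataFrame]:
    """Draw an independent cohort realizing the same planted truth (same
    genes, modules, loadings and DE assignments; fresh samples, latent
    factors and counting noise).

    Default group sizes mirror a typical microarray replication cohort
    (29 lesional / 40 non-lesional / 39 healthy).  Returns the counts,
    annotations and the validation cohort's own latent factors (needed to
    generate validation severity scores).
    """
    rng = np.random.default_rng(seed)
    count_df, ann_df, latent = _synthesize(
        truth.baseline_log2, truth.modules, truth.de_assignment, group_sizes,
        truth.dispersion, libsize_sd, rng, sample_prefix="V",
    )
    return CountMatrix(count_df), SampleAnnotations(ann_df), latent


def generate_gene_sets(
    truth: SyntheticTruth,
    n_decoy_sets: int = 50,
    set_size_range: tuple[int, int] = (10, 40),
    seed: int = 0,
    informative_fraction: float = 0.8,
    universe: Sequence[str] | None = None,
) -> GeneSetCollection:
    """Build a GMT-style collection: one informative set per planted
    associated module (members drawn mostly from the module) plus
    ``n_decoy_sets`` random decoys from the whole gene universe.

    Truth status is recorded only in ``truth.informative_pathways`` — the
    set names themselves carry no flag.
    """
    lo, hi = set_size_range
    if lo < 2:
        raise ValueError("set size lower bound must be >= 2")
    if hi < lo:
        raise ValueError("set_size_range must be (low, high) with low <= high")
    rng = np.random.default_rng(seed)
    if universe is None:
        # fallback: reconstruct the known gene ids from the truth record
        ids = {g for m in truth.modules for g in m.genes}
        for comp in truth.de_genes.values():
            ids.update(comp)
        universe = sorted(ids)
    universe = list(universe)
    non_module = sorted(set(universe) - truth.module_genes)

    sets: dict[str, GeneSet] = {}
    truth.informative_pathways = {}
    counter = 0
    for spec in truth.modules:
        if not spec.group_means:
            continue  # unassociated modules plant no informative pathway
        counter += 1
        name = f"GS{counter:04d}"
        size = int(rng.integers(lo, hi + 1))
        n_in = max(5, int(round(informative_fraction * size)))
        n_in = min(n_in, len(spec.genes), size)
        members = list(
            rng.choice(list(spec.genes), size=n_in, replace=False)
        )
        n_out = size - n_in
        if n_out > 0 and non_module:
            members += list(
                rng.choice(non_module, size=min(n_out, len(non_module)), replace=False)
            )
        sets[name] = GeneSet(name, f"synthetic informative set {counter}", frozenset(members))
        truth.informative_pathways[name] = spec.module_id
    module_genes = sorted(truth.module_genes)
    for d in range(n_decoy_sets):
        counter += 1
        name = f"GS{counter:04d}"
        size = int(rng.integers(lo, hi + 1))
        # decoys carry at most ~10% planted-module genes so they never share
        # substantial membership with any planted module
        n_mod = min(int(round(0.1 * size)), len(module_genes))
        members = list(rng.choice(non_module, size=min(size - n_mod, len(non_module)),
                                  replace=False))
        if n_mod:
            members += list(rng.choice(module_genes, size=n_mod, replace=False))
        sets[name] = GeneSet(name, "synthetic decoy set", frozenset(members))
    return GeneSetCollection(sets)


def generate_severity(
    truth: SyntheticTruth,
    annotations: SampleAnnotations,
    noise_sd: float = 4.0,
    seed: int = 0,
    easi_intercept: float = 10.0,
    easi_slope: float = 8.0,
    scorad_intercept: float = 25.0,
    scorad_slope: float = 10.0,
    latent: pd.DataFrame | None = None,
) -> SampleAnnotations:
    """Fill EASI/SCORAD for lesional samples as a positive linear function of
    the planted informative-pathway latent activity plus Gaussian noise,
    truncated at zero.  Non-lesional and healthy severity stays missing.

    The activity driving severity is the latent factor of the first module
    planted with a positive lesional association (the canonical
    "disease-activity" module); the coefficients are recorded in
    ``truth.severity_model``.  ``latent`` defaults to the discovery
    cohort's factors; pass a validation cohort's factors to score that
    cohort instead.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    lesional = annotations.samples_in("lesional")
    if not lesional:
        raise ValueError("no lesional samples to assign severity to")
    driver = None
    for spec in truth.modules:
        if spec.group_means.get("lesional", 0.0) > 0:
            driver = spec
            break
    if driver is None and truth.modules:
        driver = truth.modules[0]
    if driver is None:
        raise ValueError("truth has no planted modules to drive severity")
    rng = np.random.default_rng(seed)
    if latent is None:
        latent = truth.latent
    z = latent[f"module_{driver.module_id}"].loc[lesional].to_numpy()
    easi = easi_intercept + easi_slope * z + rng.normal(0.0, noise_sd, len(z))
    scorad = (
        scorad_intercept
        + scorad_slope * z
        + rng.normal(0.0, noise_sd * scorad_slope / easi_slope, len(z))
    )
    df = annotations.data.copy()
    df.loc[lesional, "easi"] = np.maximum(easi, 0.0)
    df.loc[lesional, "scorad"] = np.maximum(scorad, 0.0)
    truth.severity_model = {
        "driver_module": float(driver.module_id),
        "easi_intercept": easi_intercept,
        "easi_slope": easi_slope,
        "scorad_intercept": scorad_intercept,
        "scorad_slope": scorad_slope,
        "noise_sd": noise_sd,
    }
    return SampleAnnotations(df)


# ---------------------------------------------------------------------------
# truth (de)serialization — structured text for the `simulate` CLI


def write_truth(truth: SyntheticTruth, path: str | Path) -> None:
    payload = {
        "seed": truth.seed,
        "group_sizes": list(truth.group_sizes),
        "de_genes": truth.de_genes,
        "modules": [
            {
                "module_id": m.module_id,
                "genes": list(m.genes),
                "loadings": m.loadings,
                "group_means": m.group_means,
            }
            for m in truth.modules
        ],
        "latent": {
            "index": list(truth.latent.index),
            "columns": list(truth.latent.columns),
            "values": truth.latent.to_numpy().tolist(),
        },
        "baseline_log2": {
            "index": list(truth.baseline_log2.index),
            "values": truth.baseline_log2.to_numpy().tolist(),
        },
        "de_assignment": {
            g: [target, shift] for g, (target, shift) in truth.de_assignment.items()
        },
        "dispersion": truth.dispersion,
        "informative_pathways": truth.informative_pathways,
        "severity_model": truth.severity_model,
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_truth(path: str | Path) -> SyntheticTruth:
    payload = json.loads(Path(path).read_text())
    latent = pd.DataFrame(
        np.asarray(payload["latent"]["values"], dtype=float),
        index=payload["latent"]["index"],
        columns=payload["latent"]["columns"],
    )
    return SyntheticTruth(
        seed=int(payload["seed"]),
        group_sizes=tuple(payload["group_sizes"]),
        de_genes={k: dict(v) for k, v in payload["de_genes"].items()},
        modules=[
            ModuleSpec(
                module_id=int(m["module_id"]),
                genes=tuple(m["genes"]),
                loadings={k: float(v) for k, v in m["loadings"].items()},
                group_means={k: float(v) for k, v in m["group_means"].items()},
            )
            for m in payload["modules"]
        ],
        latent=latent,
        baseline_log2=pd.Series(
            np.asarray(payload["baseline_log2"]["values"], dtype=float),
            index=payload["baseline_log2"]["index"],
        ),
        de_assignment={
            g: (str(v[0]), float(v[1]))
            for g, v in payload["de_assignment"].items()
        },
        dispersion=float(payload["dispersion"]),
        informative_pathways={
            k: int(v) for k, v in payload["informative_pathways"].items()
        },
        severity_model={k: float(v) for k, v in payload["severity_model"].items()},
    )
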