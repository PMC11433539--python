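"""Validation statistics for pathway and gene signatures.

Welch t-tests on pathway expression across the pairwise group comparisons
(with the conventional significance stars), Pearson correlation of pathway
expression with the clinical severity indices (EASI, SCORAD), and
diagnostic ROC/AUC from a univariate logistic model.  Because the logistic
score is monotone in the feature, its AUC equals the feature's own rank
(Mann–Whitney) AUC — asserted as an internal cross-check.  A replication
helper rebuilds pathway expression on an independent cohort from the frozen
discovery gene lists and re-runs the tests.
"""

from __future__ import annotations

import logging
import warnings
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .io_formats import COMPARISONS, ExpressionMatrix, SampleAnnotations
from .pathway import PathwayExpressionMatrix, pathway_expression_from_lists

logger = logging.getLogger(__name__)

#: significance-star bands, checked from largest p to smallest
STAR_BANDS = ((0.0001, "****"), (0.001, "***"), (0.01, "**"), (0.05, "*"))


def stars(p: float) -> str:
    for cut, s in STAR_BANDS:
        if p < cut:
            return s
    return ""


def group_ttests(
    p_matrix: PathwayExpressionMatrix,
    annotations: SampleAnnotations,
    comparisons: dict[str, tuple[str, str]] | None = None,
) -> pd.DataFrame:
    """Two-sided Welch t-test per pathway per pairwise comparison.

    Returns rows (pathway, comparison) with group means, t, p and the star
    code.  Identical constant groups give p = 1 (logged)."""
    comparisons = comparisons or COMPARISONS
    rows = []
    for comp_name, (ref, case) in comparisons.items():
        ref_samples = [s for s in annotations.samples_in(ref) if s in p_matrix.data.columns]
        case_samples = [s for s in annotations.samples_in(case) if s in p_matrix.data.columns]
        if len(ref_samples) < 3 or len(case_samples) < 3:
            raise ValueError(
                f"comparison {comp_name}: each group needs at least 3 samples"
            )
        a = p_matrix.data[ref_samples].to_numpy(dtype=float)
        b = p_matrix.data[case_samples].to_numpy(dtype=float)
        for i, name in enumerate(p_matrix.data.index):
            if np.var(a[i]) == 0 and np.var(b[i]) == 0:
                if a[i].mean() == b[i].mean():
                    logger.info("pathway %s constant in both groups; p=1", name)
                    t, p = 0.0, 1.0
                else:
                    t, p = np.inf * np.sign(b[i].mean() - a[i].mean()), 0.0
            else:
                res = stats.ttest_ind(b[i], a[i], equal_var=False)
                t, p = float(res.statistic), float(res.pvalue)
            rows.append(
                (name, comp_name, float(a[i].mean()), float(b[i].mean()), t, p, stars(p))
            )
    return pd.DataFrame(
        rows,
        columns=["pathway", "comparison", "mean_a", "mean_b", "t_stat", "p_value", "stars"],
    )


def severity_correlation(
    p_matrix: PathwayExpressionMatrix,
    annotations: SampleAnnotations,
    index: str,
) -> pd.DataFrame:
    """Pearson correlation of each pathway's expression with a severity
    index over samples with non-missing severity."""
    index = index.lower()
    if index not in ("easi", "scorad"):
        raise ValueError("severity index must be 'easi' or 'scorad'")
    sev = annotations.data[index]
    usable = [
        s for s in p_matrix.data.columns if s in sev.index and np.isfinite(sev[s])
    ]
    if len(usable) < 5:
        raise ValueError(
            f"fewer than 5 samples with non-missing {index.upper()}"
        )
    y = sev.loc[usable].to_numpy(dtype=float)
    rows = []
    for name in p_matrix.data.index:
        x = p_matrix.data.loc[name, usable].to_numpy(dtype=float)
        if np.std(x) == 0 or np.std(y) == 0:
            r, p = 0.0, 1.0
        else:
            res = stats.pearsonr(x, y)
            r, p = float(res.statistic), float(res.pvalue)
        rows.append((name, r, p, len(usable)))
    return pd.DataFrame(
        rows, columns=["pathway", "pearson_r", "p_value", "n"]
    ).set_index("pathway")


def rank_auc(feature: np.ndarray, labels: np.ndarray) -> float:
    """Raw (unoriented) AUC by the Mann–Whitney rank formula with the 1/2
    tie correction: probability a random positive outranks a random
    negative."""
    feature = np.asarray(feature, dtype=float)
    labels = np.asarray(labels).astype(int)
    n1 = int(labels.sum())
    n0 = len(labels) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    ranks = stats.rankdata(feature)
    u = ranks[labels == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def roc_auc(feature, labels) -> tuple[float, str]:
    """Diagnostic AUC of a single feature via a univariate logistic model.

    Fits intercept + slope by maximum likelihood and computes the AUC of the
    fitted scores by the rank formula; since the logistic score is monotone
    in the feature, this equals the feature's own rank AUC (cross-checked).
    Complete separation is flagged and the rank AUC used directly.  The
    returned AUC is oriented (>= 0.5) with a direction flag: "positive" if
    higher values indicate the case class, else "negative".
    """
    feature = np.asarray(feature, dtype=float)
    labels = np.asarray(labels).astype(int)
    raw = rank_auc(feature, labels)
    if np.std(feature) > 0:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                design = sm.add_constant(feature)
                fit = sm.Logit(labels, design).fit(disp=0, maxiter=200)
                params = np.asarray(fit.params, dtype=float)
                # a vanishing or non-finite slope gives no ordering to check
                if np.isfinite(params).all() and abs(params[1]) > 1e-12:
                    score = design @ params
                    score_auc = rank_auc(np.asarray(score), labels)
                    expected = raw if params[1] > 0 else 1.0 - raw
                    if abs(score_auc - expected) > 1e-9:
                        raise AssertionError(
                            "logistic-score AUC disagrees with rank AUC: "
                            f"{score_auc} vs {expected}"
                        )
            except (np.linalg.LinAlgError, PerfectSeparationError):
                logger.info("logistic fit failed (separation); rank AUC used")
    direction = "positive" if raw >= 0.5 else "negative"
    return (max(raw, 1.0 - raw), direction)


def diagnostics_table(
    features: pd.DataFrame,
    annotations: SampleAnnotations,
    cohort: str,
    comparisons: dict[str, tuple[str, str]] | None = None,
) -> pd.DataFrame:
    """Oriented AUC per feature (row of ``features``) per pairwise
    comparison.  ``features`` is feature × sample."""
    comparisons = comparisons or COMPARISONS
    rows = []
    for comp_name, (ref, case) in comparisons.items():
        samples = [
            s
            for s in features.columns
            if annotations.group_of(s) in (ref, case)
        ]
        labels = np.array(
            [1 if annotations.group_of(s) == case else 0 for s in samples]
        )
        if labels.sum() == 0 or labels.sum() == len(labels):
            continue
        for name in features.index:
            auc, direction = roc_auc(
                features.loc[name, samples].to_numpy(dtype=float), labels
            )
            rows.append((name, comp_name, cohort, auc, direction))
    return pd.DataFrame(
        rows, columns=["feature", "comparison", "cohort", "auc", "direction"]
    )


def replicate(
    selected: Sequence[str],
    gene_lists: dict[str, tuple[str, ...]],
    validation_expr: ExpressionMatrix,
    validation_annotations: SampleAnnotations,
    discovery_tests: pd.DataFrame,
    alpha: float = 0.05,
    min_fraction: float = 0.5,
) -> dict:
    """Re-test selected pathways on an independent cohort using the frozen
    discovery gene lists.

    A pathway replicates in a comparison when it is significant (p < alpha)
    with the same direction of change in both cohorts.  Returns the
    validation GroupTestTable, the validation DiagnosticsTable and a
    replication summary.
    """
    lists = {name: gene_lists[name] for name in selected if name in gene_lists}
    if not lists:
        raise ValueError("no frozen gene lists for the selected pathways")
    p_val = pathway_expression_from_lists(
        validation_expr, lists, require_fraction=min_fraction
    )
    tests = group_ttests(p_val, validation_annotations)
    diag = diagnostics_table(p_val.data, validation_annotations, cohort="validation")

    disc = discovery_tests.set_index(["pathway", "comparison"])
    rows = []
    for _, row in tests.iterrows():
        key = (row["pathway"], row["comparison"])
        if key not in disc.index:
            continue
        d = disc.loc[key]
        same_direction = np.sign(row["mean_b"] - row["mean_a"]) == np.sign(
            d["mean_b"] - d["mean_a"]
        )
        replicated = (
            row["p_value"] < alpha and d["p_value"] < alpha and bool(same_direction)
        )
        rows.append((row["pathway"], row["comparison"], bool(replicated)))
    summary = pd.DataFrame(rows, columns=["pathway", "comparison", "replicated"])
    return {
        "pathway_expression": p_val,
        "group_tests": tests,
        "diagnostics": diag,
        "replication": summary,
    }
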