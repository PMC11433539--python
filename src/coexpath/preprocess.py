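"""Low-count filtering, normalization and hypervariable-gene selection.

The pipeline always filters first and then normalizes; the provenance is
recorded in ``ExpressionMatrix.transform_tag``.  Normalization is
median-of-ratios size factors followed by log2(count / size_factor + 1) —
a variance-stabilizing monotone transform whose output feeds correlation-,
mean- and rank-based stages only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .diffexpr import estimate_size_factors
from .io_formats import CountMatrix, ExpressionMatrix

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CvReport:
    """Per-gene coefficient-of-variation report (mean, sd, cv_percent,
    selected flag) at a given threshold."""

    data: pd.DataFrame  # columns: mean, sd, cv_percent, selected
    threshold_percent: float


def filter_low_counts(counts: CountMatrix, min_total: int = 10) -> CountMatrix:
    """Drop genes with total count across all samples below ``min_total``.

    Survivor order is preserved.  Removing every gene is an error (the
    threshold is almost certainly wrong for the library depth).
    """
    totals = counts.data.sum(axis=1)
    keep = totals >= min_total
    if not keep.any():
        raise ValueError(
            f"low-count filter at min_total={min_total} removed every gene; "
            "review the threshold against the library depth"
        )
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("low-count filter removed %d/%d genes", n_dropped, len(keep))
    return CountMatrix(counts.data.loc[keep])


def normalize_vst(counts: CountMatrix) -> ExpressionMatrix:
    """Median-of-ratios size factors, then log2(count/size_factor + 1).

    A sample with all-zero counts has no defined size factor and is a hard
    error.
    """
    zero_samples = counts.data.columns[(counts.data == 0).all(axis=0)]
    if len(zero_samples):
        raise ValueError(f"sample {zero_samples[0]!r} has all-zero counts")
    sf = estimate_size_factors(counts)
    normalized = counts.data.to_numpy(dtype=float) / sf.to_numpy()[None, :]
    values = np.log2(normalized + 1.0)
    df = pd.DataFrame(values, index=counts.data.index, columns=counts.data.columns)
    tag = "median_of_ratios+log2p1"
    return ExpressionMatrix(df, transform_tag=tag)


def select_hypervariable(
    expr: ExpressionMatrix, cv_threshold_percent: float = 15.0
) -> tuple[ExpressionMatrix, CvReport]:
    """Select genes with CV = 100·sd/mean above the threshold on the
    normalized scale, over the samples currently in ``expr``.

    Genes with non-positive mean have no meaningful CV and are excluded
    (flagged not-selected).  Selecting zero genes is an error.
    """
    if expr.data.shape[1] < 3:
        raise ValueError("CV selection needs at least 3 samples")
    mean = expr.data.mean(axis=1)
    sd = expr.data.std(axis=1, ddof=1)
    cv = pd.Series(np.nan, index=expr.data.index)
    pos = mean > 0
    cv[pos] = 100.0 * sd[pos] / mean[pos]
    selected = pos & (cv > cv_threshold_percent)
    report = CvReport(
        pd.DataFrame(
            {"mean": mean, "sd": sd, "cv_percent": cv, "selected": selected}
        ),
        threshold_percent=cv_threshold_percent,
    )
    if not selected.any():
        raise ValueError(
            f"no gene exceeds CV {cv_threshold_percent}% — nothing to network"
        )
    sub = ExpressionMatrix(expr.data.loc[selected], expr.transform_tag)
    return sub, report
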