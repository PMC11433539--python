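"""Pairwise negative-binomial differential expression.

A two-group closed-form NB Wald test: median-of-ratios size factors,
method-of-moments gene-wise dispersions shrunk toward a mean–dispersion
trend, per-group NB means with a moderation constant for zero-safety, a
delta-method standard error for the log2 fold change, a normal-reference
two-sided p, and Benjamini–Hochberg correction.  A gene is significant when
its BH-adjusted p is below ``alpha`` and its |log2FC| exceeds
``lfc_threshold`` (defaults 0.05 and 1).
"""

from __future__ import annotations

import logging
import math
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import CountMatrix

logger = logging.getLogger(__name__)

_LN2 = math.log(2.0)
#: floor for dispersion estimates (Poisson limit)
DISPERSION_FLOOR = 1e-8
#: moderation constant (normalized counts) for fold-change stability at zero
MODERATION = 0.5


def _as_frame(counts: CountMatrix | pd.DataFrame) -> pd.DataFrame:
    return counts.data if isinstance(counts, CountMatrix) else counts


def estimate_size_factors(counts: CountMatrix | pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors, rescaled to geometric mean 1.

    The reference is the gene-wise geometric mean over samples, computed on
    genes with no zero count.  If no zero-free gene exists the ratios fall
    back to zero-excluded geometric means with a logged warning.
    """
    df = _as_frame(counts)
    values = df.to_numpy(dtype=float)
    if values.shape[1] == 1:
        return pd.Series([1.0], index=df.columns)
    zero_free = (values > 0).all(axis=1)
    if zero_free.any():
        v = values[zero_free]
        log_ref = np.mean(np.log(v), axis=1)
        ratios = np.log(v) - log_ref[:, None]
    else:
        logger.warning(
            "no zero-free gene; size factors use zero-excluded ratios"
        )
        with np.errstate(divide="ignore"):
            logv = np.where(values > 0, np.log(values), np.nan)
        n_pos = np.sum(values > 0, axis=1)
        usable = n_pos >= 2
        if not usable.any():
            raise ValueError("cannot estimate size factors: counts too sparse")
        log_ref = np.nanmean(logv[usable], axis=1)
        ratios = logv[usable] - log_ref[:, None]
    log_sf = np.nanmedian(ratios, axis=0)
    log_sf = log_sf - np.mean(log_sf)  # geometric mean 1
    return pd.Series(np.exp(log_sf), index=df.columns)


def genewise_dispersion(
    counts: CountMatrix | pd.DataFrame,
    size_factors: pd.Series,
    groups: Sequence[str],
) -> pd.Series:
    """Raw method-of-moments dispersion: alpha = max(eps, (s2 - mu) / mu^2)
    with s2 the pooled within-group variance of normalized counts and mu the
    grand mean."""
    df = _as_frame(counts)
    y = df.to_numpy(dtype=float) / size_factors.loc[df.columns].to_numpy()[None, :]
    groups = np.asarray(groups)
    ss = np.zeros(df.shape[0])
    dof = 0
    for g in np.unique(groups):
        sub = y[:, groups == g]
        if sub.shape[1] >= 2:
            ss += np.var(sub, axis=1, ddof=1) * (sub.shape[1] - 1)
            dof += sub.shape[1] - 1
    if dof == 0:
        raise ValueError("dispersion estimation needs >= 2 samples in a group")
    s2 = ss / dof
    mu = y.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = (s2 - mu) / mu**2
    alpha = np.where(np.isfinite(alpha), alpha, DISPERSION_FLOOR)
    return pd.Series(np.maximum(alpha, DISPERSION_FLOOR), index=df.index)


def estimate_dispersions(
    counts: CountMatrix | pd.DataFrame,
    size_factors: pd.Series,
    groups: Sequence[str],
    shrink: bool = True,
) -> pd.Series:
    """Gene-wise MoM dispersions, optionally shrunk 50/50 (on the log scale)
    toward a log-linear trend of dispersion on the gene's mean normalized
    count.  Genes at the floor are excluded from the trend fit."""
    df = _as_frame(counts)
    raw = genewise_dispersion(df, size_factors, groups)
    if not shrink:
        return raw
    y = df.to_numpy(dtype=float) / size_factors.loc[df.columns].to_numpy()[None, :]
    mu = y.mean(axis=1)
    ok = (raw.to_numpy() > DISPERSION_FLOOR * 10) & (mu > 0)
    if ok.sum() >= 10:
        lx = np.log(mu[ok])
        ly = np.log(raw.to_numpy()[ok])
        slope, intercept = np.polyfit(lx, ly, 1)
        with np.errstate(divide="ignore"):
            trend = np.exp(intercept + slope * np.log(np.maximum(mu, 1e-9)))
    else:
        trend = np.full(len(raw), max(float(np.median(raw)), DISPERSION_FLOOR))
    trend = np.maximum(trend, DISPERSION_FLOOR)
    shrunk = np.exp(0.5 * np.log(raw.to_numpy()) + 0.5 * np.log(trend))
    return pd.Series(np.maximum(shrunk, DISPERSION_FLOOR), index=df.index)


def bh_adjust(p_values: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values.

    Classic definition: sort ascending, multiply p_(i) by m/i, enforce
    monotonicity from the largest rank down, cap at 1, restore input order.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("bh_adjust needs a non-empty 1-D vector")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    scaled = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(scaled[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(m)
    out[order] = adjusted
    return out


def nb_wald_test(
    counts: CountMatrix | pd.DataFrame,
    size_factors: pd.Series,
    dispersions: pd.Series,
    groups: Sequence[str],
    group_a: str | None = None,
    group_b: str | None = None,
    alpha: float = 0.05,
    lfc_threshold: float = 1.0,
) -> pd.DataFrame:
    """Two-group NB Wald test on normalized counts.

    Per gene: group means mu_A, mu_B of normalized counts;
    log2FC = log2((mu_B + c) / (mu_A + c)) with moderation c;
    Var(mu_hat_g) = (1/n_g^2) * sum_i (mu_g / s_i + alpha_g * mu_g^2);
    SE(log2FC) via the delta method; two-sided normal p; BH over all genes.

    Returns a DeTable DataFrame indexed by gene with columns ``base_mean``,
    ``log2_fold_change`` (B over A), ``wald_stat``, ``p_value``,
    ``p_adjusted`` and ``significant``.
    """
    df = _as_frame(counts)
    groups = np.asarray([str(g) for g in groups])
    labels = list(dict.fromkeys(groups))
    if group_a is None or group_b is None:
        if len(labels) != 2:
            raise ValueError("specify group_a/group_b when labels are not binary")
        group_a, group_b = labels
    for g, name in ((group_a, "group_a"), (group_b, "group_b")):
        if (groups == g).sum() < 2:
            raise ValueError(f"{name}={g!r} needs at least 2 samples")
    sf = size_factors.loc[df.columns].to_numpy(dtype=float)
    y = df.to_numpy(dtype=float) / sf[None, :]
    alpha_g = dispersions.loc[df.index].to_numpy(dtype=float)

    mask_a = groups == group_a
    mask_b = groups == group_b
    mu_a = y[:, mask_a].mean(axis=1)
    mu_b = y[:, mask_b].mean(axis=1)
    c = MODERATION
    lfc = np.log2((mu_b + c) / (mu_a + c))

    def _var_mean(mu: np.ndarray, mask: np.ndarray) -> np.ndarray:
        n = mask.sum()
        inv_s = np.sum(1.0 / sf[mask])
        return (mu * inv_s + n * alpha_g * mu**2) / n**2

    var_a = _var_mean(mu_a, mask_a)
    var_b = _var_mean(mu_b, mask_b)
    var_lfc = (var_a / (mu_a + c) ** 2 + var_b / (mu_b + c) ** 2) / _LN2**2
    se = np.sqrt(var_lfc)
    with np.errstate(divide="ignore", invalid="ignore"):
        wald = np.where(se > 0, lfc / se, 0.0)
    p = 2.0 * stats.norm.sf(np.abs(wald))
    p = np.clip(p, 0.0, 1.0)
    padj = bh_adjust(p)
    significant = (padj < alpha) & (np.abs(lfc) > lfc_threshold)
    return pd.DataFrame(
        {
            "base_mean": y.mean(axis=1),
            "log2_fold_change": lfc,
            "wald_stat": wald,
            "p_value": p,
            "p_adjusted": padj,
            "significant": significant,
        },
        index=df.index,
    )


def run_de(
    counts: CountMatrix,
    groups: Sequence[str],
    group_a: str,
    group_b: str,
    alpha: float = 0.05,
    lfc_threshold: float = 1.0,
) -> pd.DataFrame:
    """Convenience wrapper: size factors + shrunk dispersions + Wald test on
    the samples belonging to the two requested groups."""
    groups = np.asarray([str(g) for g in groups])
    keep = np.isin(groups, [group_a, group_b])
    sub = CountMatrix(counts.data.loc[:, counts.data.columns[keep]])
    sub_groups = groups[keep]
    sf = estimate_size_factors(sub)
    disp = estimate_dispersions(sub, sf, sub_groups)
    return nb_wald_test(
        sub, sf, disp, sub_groups, group_a, group_b, alpha, lfc_threshold
    )
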