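"""Negative-binomial Wald test for two-condition differential expression.

This is a deliberately transparent NB test in the DESeq2 family of models:
median-of-ratios size factors, per-feature method-of-moments dispersion
moderated toward the genome-wide trend, a delta-method Wald statistic on the
log2 fold change, and Benjamini-Hochberg FDR over the tested features.
Externally produced DE tables in the same schema can be slotted in instead.

Model: counts K_gs ~ NB(mean = s_s * q_gc, variance = mu + alpha_g * mu^2)
where s_s is the sample size factor and q_gc the condition mean. The log2
fold change is oriented second-named condition over first (``SD1_vs_SD2``
reports SD2/SD1), with a pseudo-count of 0.5 on the normalized means.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .models import SampleSheet

PSEUDOCOUNT = 0.5
DISPERSION_FLOOR = 1e-8
#: prior degrees of freedom pulling per-feature dispersions to the trend
DISPERSION_PRIOR_DF = 20.0
DEFAULT_FDR = 0.05
DEFAULT_MIN_ABS_LOG2FC = 1.0

DE_COLUMNS = [
    "feature_id", "comparison", "base_mean", "log2fc", "p_value", "fdr", "direction",
]


@dataclass(frozen=True)
class DEResult:
    feature_id: str
    comparison: str
    base_mean: float
    log2fc: float
    p_value: float
    fdr: float
    direction: str


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors, rescaled to geometric mean 1.

    For every feature with strictly positive counts in all samples, the
    ratio of each sample's count to the feature's geometric mean across
    samples is formed; the per-sample median of those ratios is the factor.
    """
    mat = counts.to_numpy(dtype=float)
    all_positive = (mat > 0).all(axis=1)
    if not all_positive.any():
        raise ValueError(
            "no feature has positive counts in every sample; a pseudo-reference "
            "fallback (e.g. geometric mean over positive counts only) is needed"
        )
    sub = mat[all_positive]
    log_geo = np.mean(np.log(sub), axis=1, keepdims=True)
    ratios = sub / np.exp(log_geo)
    factors = np.median(ratios, axis=0)
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns, name="size_factor")


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def parse_comparison(comparison: str) -> tuple[str, str]:
    parts = comparison.split("_vs_")
    if len(parts) != 2:
        raise ValueError(f"comparison must look like 'A_vs_B', got {comparison!r}")
    return parts[0], parts[1]


def _moment_dispersion(
    norm: np.ndarray, groups: list[np.ndarray], inv_sf_mean: float
) -> np.ndarray:
    """Per-feature method-of-moments dispersion pooled across conditions.

    Within each condition the NB relation Var(K/s) ~= mu * E[1/s] + alpha*mu^2
    is solved for alpha; per-condition estimates are averaged with their
    residual degrees of freedom and then shrunk toward the genome-wide trend
    (the mean of the per-feature values) with DISPERSION_PRIOR_DF prior df.
    """
    n_features = norm.shape[0]
    num = np.zeros(n_features)
    den = np.zeros(n_features)
    for cols in groups:
        sub = norm[:, cols]
        n = sub.shape[1]
        if n < 2:
            continue
        mu = sub.mean(axis=1)
        var = sub.var(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            alpha_c = (var - mu * inv_sf_mean) / np.square(mu)
        alpha_c = np.where(np.isfinite(alpha_c), alpha_c, 0.0)
        df = n - 1
        num += df * alpha_c
        den += df
    raw = np.where(den > 0, num / np.maximum(den, 1), 0.0)
    raw = np.maximum(raw, 0.0)
    trend = float(np.mean(raw)) if n_features else 0.0
    shrunk = (den * raw + DISPERSION_PRIOR_DF * trend) / (den + DISPERSION_PRIOR_DF)
    return np.maximum(shrunk, DISPERSION_FLOOR)


def nb_wald_test(
    counts: pd.DataFrame,
    samples: SampleSheet,
    comparison: str,
    fdr_threshold: float = DEFAULT_FDR,
    min_abs_log2fc: float = DEFAULT_MIN_ABS_LOG2FC,
) -> pd.DataFrame:
    """Two-condition NB Wald test; returns one row per tested feature.

    Features with zero counts in every sample of the comparison are excluded
    from testing and from the BH family. ``direction`` is ``up`` when
    fdr < fdr_threshold and log2fc >= min_abs_log2fc, ``down`` for the
    mirrored case, otherwise ``ns``.
    """
    cond_a, cond_b = parse_comparison(comparison)
    cols_a = samples.samples_for(cond_a)
    cols_b = samples.samples_for(cond_b)
    if len(cols_a) < 2 or len(cols_b) < 2:
        raise ValueError(
            f"comparison {comparison} needs >= 2 replicates per condition "
            f"(got {len(cols_a)} and {len(cols_b)})"
        )
    used_cols = cols_a + cols_b
    sf = size_factors(counts)
    sub = counts[used_cols]
    tested = sub.sum(axis=1) > 0
    sub = sub.loc[tested]

    sf_used = sf[used_cols].to_numpy()
    norm = sub.to_numpy(dtype=float) / sf_used[None, :]
    idx_a = np.arange(len(cols_a))
    idx_b = np.arange(len(cols_a), len(used_cols))
    inv_sf_mean = float(np.mean(1.0 / sf_used))

    mu_a = norm[:, idx_a].mean(axis=1)
    mu_b = norm[:, idx_b].mean(axis=1)
    alpha = _moment_dispersion(norm, [idx_a, idx_b], inv_sf_mean)

    log2fc = np.log2((mu_b + PSEUDOCOUNT) / (mu_a + PSEUDOCOUNT))
    # delta method: Var(log2 mu_hat) = (CV^2 / n) / ln(2)^2, CV^2 = E[1/s]/mu + alpha
    var_ln_a = (inv_sf_mean / (mu_a + PSEUDOCOUNT) + alpha) / len(cols_a)
    var_ln_b = (inv_sf_mean / (mu_b + PSEUDOCOUNT) + alpha) / len(cols_b)
    se = np.sqrt(var_ln_a + var_ln_b) / np.log(2)
    with np.errstate(divide="ignore", invalid="ignore"):
        wald = np.where(se > 0, log2fc / se, 0.0)
    p = 2.0 * stats.norm.sf(np.abs(wald))
    fdr = bh_adjust(p)

    direction = np.where(
        (fdr < fdr_threshold) & (log2fc >= min_abs_log2fc),
        "up",
        np.where((fdr < fdr_threshold) & (log2fc <= -min_abs_log2fc), "down", "ns"),
    )
    return pd.DataFrame(
        {
            "feature_id": sub.index,
            "comparison": comparison,
            "base_mean": (mu_a + mu_b) / 2.0,
            "log2fc": log2fc,
            "p_value": p,
            "fdr": fdr,
            "direction": direction,
        }
    ).reset_index(drop=True)


def de_summary(results: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Per-comparison up/down/total census of significant features."""
    rows = []
    for comparison, df in results.items():
        up = int((df["direction"] == "up").sum())
        down = int((df["direction"] == "down").sum())
        rows.append(
            {"comparison": comparison, "up": up, "down": down, "total": up + down}
        )
    return pd.DataFrame(rows, columns=["comparison", "up", "down", "total"])
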