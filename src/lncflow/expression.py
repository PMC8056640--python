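"""FPKM normalization, expressed-feature thresholds and sample-level QC.

FPKM here uses the column sum of the supplied count matrix as the
"million fragments mapped" denominator; externally determined library totals
can be supplied instead.
"""
from __future__ import annotations

from itertools import combinations
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .models import SampleSheet

#: expressed-feature thresholds on the mean FPKM of a condition's replicates
DEFAULT_THRESHOLDS = {"lncRNA": 0.1, "mRNA": 1.0}


def compute_fpkm(
    counts: pd.DataFrame,
    lengths: Mapping[str, float] | pd.Series,
    library_totals: pd.Series | None = None,
) -> pd.DataFrame:
    """FPKM[g, s] = counts[g, s] * 1e9 / (length[g] * total[s])."""
    lengths = pd.Series(lengths).reindex(counts.index)
    if lengths.isna().any():
        missing = lengths.index[lengths.isna()].tolist()
        raise ValueError(f"missing feature lengths for {missing[:5]}")
    if (lengths <= 0).any():
        bad = lengths.index[lengths <= 0].tolist()
        raise ValueError(f"non-positive feature length for {bad[:5]}")
    totals = counts.sum(axis=0) if library_totals is None else library_totals
    totals = totals.reindex(counts.columns)
    zero = totals.index[(totals <= 0) | totals.isna()].tolist()
    if zero:
        raise ValueError(f"zero/missing library total for samples {zero}")
    fpkm = counts.to_numpy(dtype=float) * 1e9
    fpkm /= lengths.to_numpy(dtype=float)[:, None]
    fpkm /= totals.to_numpy(dtype=float)[None, :]
    return pd.DataFrame(fpkm, index=counts.index, columns=counts.columns)


def expressed_sets(
    fpkm: pd.DataFrame,
    samples: SampleSheet,
    feature_kind: str,
    threshold: float | None = None,
) -> dict:
    """Per-condition expressed sets and the Venn partition over conditions.

    A feature counts as expressed in a condition when the mean FPKM over that
    condition's replicates is strictly greater than the threshold (0.1 for
    lncRNAs, 1 for mRNAs by default).
    """
    if threshold is None:
        if feature_kind not in DEFAULT_THRESHOLDS:
            raise ValueError(f"unknown feature_kind {feature_kind!r}")
        threshold = DEFAULT_THRESHOLDS[feature_kind]
    elif feature_kind not in DEFAULT_THRESHOLDS:
        raise ValueError(f"unknown feature_kind {feature_kind!r}")

    conditions = samples.conditions
    per_condition: dict[str, set[str]] = {}
    for cond in conditions:
        cols = samples.samples_for(cond)
        means = fpkm[cols].mean(axis=1)
        per_condition[cond] = set(fpkm.index[means > threshold])

    # Venn partition: region key = sorted tuple of member conditions
    regions: dict[tuple[str, ...], set[str]] = {}
    for r in range(1, len(conditions) + 1):
        for combo in combinations(conditions, r):
            members = set.intersection(*(per_condition[c] for c in combo))
            for other in conditions:
                if other not in combo:
                    members -= per_condition[other]
            regions[tuple(combo)] = members
    return {
        "threshold": threshold,
        "per_condition": per_condition,
        "venn": regions,
        "venn_counts": {"+".join(k): len(v) for k, v in regions.items()},
    }


def sample_correlation(fpkm: pd.DataFrame) -> pd.DataFrame:
    """Sample x sample Spearman rank correlation (average ranks on ties).

    A constant column has undefined correlation and is reported as NaN
    off-diagonal; the diagonal is always 1.
    """
    if len(fpkm) < 2:
        raise ValueError("need at least 2 features for sample correlation")
    ncol = fpkm.shape[1]
    rho = stats.spearmanr(fpkm.to_numpy(), axis=0).statistic
    if ncol == 2:  # scipy collapses the 2-sample case to a scalar
        rho = np.array([[1.0, float(rho)], [float(rho), 1.0]])
    np.fill_diagonal(rho, 1.0)
    return pd.DataFrame(rho, index=fpkm.columns, columns=fpkm.columns)
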