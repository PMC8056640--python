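"""Cis (genomic window) and trans (expression correlation) target prediction.

A protein-coding gene is a *cis* target of a lncRNA when their genomic spans
lie within 100 kb of each other on the same chromosome (strand-agnostic,
inclusive at the boundary; overlapping spans count as distance 0). A *trans*
target is a gene whose expression profile over the 9 samples correlates with
the lncRNA's at |PCC| > 0.9 with two-sided P < 0.01 (both strict).

Correlations are computed on log10(FPKM + 0.01) by default; a raw-scale
switch is provided.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .models import AnnotationSet, TranscriptModel

logger = logging.getLogger(__name__)

DEFAULT_CIS_WINDOW_BP = 100_000
DEFAULT_PCC_CUTOFF = 0.9
DEFAULT_P_CUTOFF = 0.01
LOG_PSEUDO_FPKM = 0.01


@dataclass(frozen=True)
class TargetPair:
    """One lncRNA-mRNA edge, either cis (distance) or trans (PCC, p)."""

    lncrna_id: str
    mrna_id: str
    mode: str
    distance_bp: int | None = None
    pcc: float | None = None
    p_value: float | None = None

    def __post_init__(self) -> None:
        if self.mode == "cis":
            if self.distance_bp is None or self.distance_bp < 0:
                raise ValueError(f"cis pair needs distance_bp >= 0 ({self})")
        elif self.mode == "trans":
            if self.pcc is None or not -1.0 <= self.pcc <= 1.0:
                raise ValueError(f"trans pair needs pcc in [-1, 1] ({self})")
            if self.p_value is None or not 0.0 <= self.p_value <= 1.0:
                raise ValueError(f"trans pair needs p_value in [0, 1] ({self})")
        else:
            raise ValueError(f"unknown mode {self.mode!r}")


def span_distance(
    start_a: int, end_a: int, start_b: int, end_b: int
) -> int:
    """Bases separating two half-open spans; 0 when they touch or overlap."""
    return max(0, start_b - end_a, start_a - end_b)


def cis_targets(
    lncrnas: Iterable[TranscriptModel],
    ref: AnnotationSet,
    window_bp: int = DEFAULT_CIS_WINDOW_BP,
) -> list[TargetPair]:
    """All (lncRNA, gene) pairs with span gap <= window_bp, same chromosome.

    The window is anchored on full transcript/gene spans and strand-agnostic;
    host genes of sense/intronic lncRNAs therefore pair at distance 0.
    """
    gene_spans = {g: ref.gene_span(g) for g in ref.gene_index}
    pairs: list[TargetPair] = []
    for t in lncrnas:
        hits: dict[str, int] = {}
        # widen the tree query by 1 bp so spans exactly window_bp away
        # (touching the half-open query bound) are not missed
        for other in ref.overlapping(
            t.chrom, t.start - window_bp - 1, t.end + window_bp + 1
        ):
            g = other.gene_id
            if g in hits:
                continue
            chrom, gs, ge = gene_spans[g]
            if chrom != t.chrom:
                continue
            d = span_distance(t.start, t.end, gs, ge)
            if d <= window_bp:
                hits[g] = d
        for g in sorted(hits):
            pairs.append(
                TargetPair(lncrna_id=t.transcript_id, mrna_id=g, mode="cis",
                           distance_bp=hits[g])
            )
    return pairs


def pearson_test(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Sample Pearson r with a two-sided p from the exact t reference.

    t = r * sqrt((n - 2) / (1 - r^2)) on n - 2 degrees of freedom;
    r = +/-1 gives p = 0. Constant input is undefined and raises.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d of equal length")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    r = float(np.corrcoef(x, y)[0, 1])
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        return r, 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    return r, float(p)


def _correlation_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Row-wise Pearson correlation between two standardized matrices."""
    az = (a - a.mean(axis=1, keepdims=True))
    bz = (b - b.mean(axis=1, keepdims=True))
    a_sd = np.sqrt((az * az).sum(axis=1))
    b_sd = np.sqrt((bz * bz).sum(axis=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (az @ bz.T) / np.outer(a_sd, b_sd)
    return r


def trans_targets(
    lncrna_expr: pd.DataFrame,
    mrna_expr: pd.DataFrame,
    pcc_cutoff: float = DEFAULT_PCC_CUTOFF,
    p_cutoff: float = DEFAULT_P_CUTOFF,
    log_scale: bool = True,
) -> list[TargetPair]:
    """All lncRNA x mRNA pairs with |r| strictly > pcc_cutoff and two-sided
    p strictly < p_cutoff over the shared samples.

    Constant profiles (undefined correlation) are skipped with a logged count.
    """
    shared = [s for s in lncrna_expr.columns if s in set(mrna_expr.columns)]
    if not shared:
        raise ValueError("expression matrices share no sample columns")
    a = lncrna_expr[shared].to_numpy(dtype=float)
    b = mrna_expr[shared].to_numpy(dtype=float)
    if log_scale:
        a = np.log10(a + LOG_PSEUDO_FPKM)
        b = np.log10(b + LOG_PSEUDO_FPKM)
    n = len(shared)
    if n < 3:
        raise ValueError("need at least 3 shared samples")

    const_a = np.ptp(a, axis=1) == 0
    const_b = np.ptp(b, axis=1) == 0
    n_const = int(const_a.sum()) + int(const_b.sum())
    if n_const:
        logger.info("trans_targets: skipped %d constant profiles", n_const)

    r = _correlation_matrix(a, b)
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.abs(r) == 1.0, 0.0, p)

    ok = (np.abs(r) > pcc_cutoff) & (p < p_cutoff)
    ok[const_a, :] = False
    ok[:, const_b] = False
    lnc_ids = list(lncrna_expr.index)
    mrna_ids = list(mrna_expr.index)
    pairs = []
    for i, j in zip(*np.nonzero(ok)):
        pairs.append(
            TargetPair(
                lncrna_id=lnc_ids[i], mrna_id=mrna_ids[j], mode="trans",
                pcc=float(r[i, j]), p_value=float(p[i, j]),
            )
        )
    pairs.sort(key=lambda pr: (pr.lncrna_id, pr.mrna_id))
    return pairs


def pairs_to_frame(pairs: Sequence[TargetPair]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "lncrna_id": p.lncrna_id,
                "mrna_id": p.mrna_id,
                "mode": p.mode,
                "distance_bp": p.distance_bp,
                "pcc": p.pcc,
                "p_value": p.p_value,
            }
            for p in pairs
        ],
        columns=["lncrna_id", "mrna_id", "mode", "distance_bp", "pcc", "p_value"],
    )
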