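"""Hypergeometric over-representation analysis against user gene-set tables.

The test is the standard upper-tail hypergeometric: with a universe of N
genes of which K belong to a term, and a query of n genes with k hits,
p = P(X >= k) for X ~ Hypergeometric(N, K, n). Corrected p-values come from
Benjamini-Hochberg over all tested terms; a term is significant at
corrected p < 0.05.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import pandas as pd
from scipy import stats

from .de import bh_adjust

DEFAULT_ENRICH_ALPHA = 0.05


@dataclass(frozen=True)
class EnrichmentResult:
    term_id: str
    term_name: str
    k: int
    K: int
    n: int
    N: int
    p_value: float
    corrected_p: float

    @property
    def significant(self) -> bool:
        return self.corrected_p < DEFAULT_ENRICH_ALPHA


def hypergeom_test(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail P(X >= k) under Hypergeometric(N, K, n)."""
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"inconsistent arguments K={K}, n={n}, N={N}")
    if not (0 <= k <= min(K, n)):
        raise ValueError(f"k={k} outside [0, min(K={K}, n={n})]")
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def enrich(
    query: set[str],
    universe: set[str],
    gene_sets: Mapping[str, dict],
) -> list[EnrichmentResult]:
    """Test every term with at least one universe gene against the query.

    ``gene_sets`` maps term_id to ``{"name": str, "genes": set}`` (the shape
    :func:`lncflow.io.read_gene_sets` returns). Terms are intersected with
    the universe before testing; results are sorted by corrected p, then
    term_id.
    """
    stray = query - universe
    if stray:
        raise ValueError(f"query genes outside universe: {sorted(stray)[:10]}")
    N = len(universe)
    n = len(query)
    rows = []
    for term_id in sorted(gene_sets):
        term_genes = set(gene_sets[term_id]["genes"]) & universe
        if not term_genes:
            continue
        K = len(term_genes)
        k = len(term_genes & query)
        rows.append(
            (term_id, gene_sets[term_id]["name"], k, K, hypergeom_test(k, K, n, N))
        )
    if not rows:
        return []
    corrected = bh_adjust([r[4] for r in rows])
    results = [
        EnrichmentResult(term_id, name, k, K, n, N, p, float(q))
        for (term_id, name, k, K, p), q in zip(rows, corrected)
    ]
    results.sort(key=lambda r: (r.corrected_p, r.term_id))
    return results


def results_to_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "term_id": r.term_id, "term_name": r.term_name,
                "k": r.k, "K": r.K, "n": r.n, "N": r.N,
                "p_value": r.p_value, "corrected_p": r.corrected_p,
                "significant": r.significant,
            }
            for r in results
        ],
        columns=[
            "term_id", "term_name", "k", "K", "n", "N",
            "p_value", "corrected_p", "significant",
        ],
    )
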