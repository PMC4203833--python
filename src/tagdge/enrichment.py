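"""Hypergeometric GO/KO-style term enrichment over a DE gene set.

For a universe of N annotated genes of which n are differentially
expressed, a term annotating M genes with m of them DE is scored by the
hypergeometric upper tail

    P = P(X >= m) = sum_{i=m}^{min(n,M)} C(M,i) C(N-M,n-i) / C(N,n),

equivalently 1 minus the cumulative sum up to m-1.  P-values are adjusted
across terms by Benjamini-Hochberg and flagged at a configurable alpha.
Term membership is flat: no ontology-graph ancestor propagation.
"""

from __future__ import annotations

import math
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from tagdge.diffexpr import bh_fdr

# Cached log-factorial table, grown on demand: logC via three lookups is
# much cheaper than per-call gammaln when sweeping many configurations.
_LOGFACT = np.zeros(1)


def _logfact(upto: int) -> np.ndarray:
    global _LOGFACT
    if upto >= len(_LOGFACT):
        start = len(_LOGFACT)
        tail = _LOGFACT[-1] + np.cumsum(np.log(np.arange(start, upto + 1, dtype=float)))
        _LOGFACT = np.concatenate([_LOGFACT, tail])
    return _LOGFACT


def hypergeom_upper_tail(N: int, M: int, n: int, m: int) -> float:
    """P(X >= m) for X ~ Hypergeometric(N, M, n), summed in log space."""
    if not (0 <= M <= N and 0 <= n <= N):
        raise ValueError(f"inconsistent population: N={N}, M={M}, n={n}")
    if not 0 <= m <= min(n, M):
        raise ValueError(f"m={m} outside [0, min(n={n}, M={M})]")
    if m == 0:
        return 1.0
    lf = _logfact(N)
    i = np.arange(m, min(n, M) + 1)
    log_terms = (
        lf[M] - lf[i] - lf[M - i]
        + lf[N - M] - lf[n - i] - lf[N - M - n + i]
        - (lf[N] - lf[n] - lf[N - n])
    )
    peak = log_terms.max()
    return float(min(1.0, math.exp(peak) * np.exp(log_terms - peak).sum()))


def enrich(
    annotation: Mapping[str, Iterable[str]] | pd.DataFrame,
    de_genes: Iterable[str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Score every annotated term for over-representation among DE genes.

    ``annotation`` is either a gene -> terms mapping or a two-column
    (gene_id, term_id) DataFrame.  The universe N is the set of annotated
    genes; unannotated DE genes are ignored, as is standard for
    annotation-restricted enrichment.  Terms with no DE member are
    reported with P = 1.  Returns a DataFrame with columns term_id, N, n,
    M, m, P, corrected_P, significant, sorted by corrected_P then term_id.
    """
    if isinstance(annotation, pd.DataFrame):
        pairs = annotation[["gene_id", "term_id"]].drop_duplicates()
    else:
        pairs = pd.DataFrame(
            [(g, t) for g, terms in annotation.items() for t in terms],
            columns=["gene_id", "term_id"],
        ).drop_duplicates()
    universe = set(pairs["gene_id"])
    N = len(universe)
    if N == 0:
        raise ValueError("annotation is empty")
    de = set(de_genes) & universe
    n = len(de)

    rows = []
    for term_id, members in sorted(pairs.groupby("term_id")["gene_id"].apply(set).items()):
        M = len(members)
        m = len(members & de)
        if m > min(n, M):
            raise ValueError(f"term {term_id}: m={m} exceeds min(n={n}, M={M})")
        rows.append((term_id, N, n, M, m, hypergeom_upper_tail(N, M, n, m)))

    result = pd.DataFrame(rows, columns=["term_id", "N", "n", "M", "m", "P"])
    result["corrected_P"] = bh_fdr(result["P"].to_numpy())
    result["significant"] = result["corrected_P"] < alpha
    return result.sort_values(["corrected_P", "term_id"], kind="mergesort").reset_index(drop=True)
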