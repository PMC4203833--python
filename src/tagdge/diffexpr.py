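"""TPM normalization and Audic-Claverie two-library differential expression.

The Audic-Claverie test asks, for one gene observed ``x`` times among
``N1`` clean tags in library 1 and ``y`` times among ``N2`` tags in
library 2, how surprising ``y`` is under the null of equal underlying
proportions.  Conditioning on ``x`` (flat prior on the common rate) gives

    p(y | x) = r^y (x+y)! / (x! y! (1+r)^(x+y+1)),   r = N2/N1,

which is a negative-binomial law in ``y`` with ``x+1`` "successes" and
success probability ``1/(1+r)``.  Tail probabilities are evaluated by
direct log-space summation of this pmf -- no normal approximation -- with
the smaller tail summed explicitly and the other obtained from the exact
complement, so cancellation never degrades the reported p-value.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp


@dataclass
class ExpressionTable:
    """Per-gene unambiguous tag counts and TPM for one library.

    TPM here is the tag-profiling convention -- transcript copies per
    million clean tags, count * 1e6 / clean_total -- not the modern
    length-normalized RNA-seq TPM.
    """

    data: pd.DataFrame  # index gene_id, columns ["count", "tpm"]
    clean_total: int
    library_id: str = "library"

    @property
    def counts(self) -> pd.Series:
        return self.data["count"]

    @property
    def tpm(self) -> pd.Series:
        return self.data["tpm"]

    def to_tsv(self, path: str | os.PathLike) -> None:
        self.data.to_csv(path, sep="\t")


def tpm_normalize(counts: Mapping[str, int] | pd.Series, clean_total: int, library_id: str = "library") -> ExpressionTable:
    """Scale per-gene tag counts to transcripts per million clean tags."""
    if clean_total <= 0:
        raise ValueError(f"clean-tag total must be positive, got {clean_total}")
    series = pd.Series(counts, dtype=float).sort_index()
    if (series < 0).any():
        raise ValueError("negative tag counts")
    df = pd.DataFrame({"count": series.astype(int), "tpm": series * 1e6 / clean_total})
    df.index.name = "gene_id"
    return ExpressionTable(data=df, clean_total=int(clean_total), library_id=library_id)


def _ac_logpmf(k: np.ndarray, x: int, log_r: float, log_1pr: float) -> np.ndarray:
    return (
        k * log_r
        + gammaln(x + k + 1.0)
        - gammaln(x + 1.0)
        - gammaln(k + 1.0)
        - (x + k + 1.0) * log_1pr
    )


def _sum_pmf(lo: int, hi: int, x: int, log_r: float, log_1pr: float) -> float:
    if hi < lo:
        return 0.0
    k = np.arange(lo, hi + 1, dtype=float)
    return float(np.exp(logsumexp(_ac_logpmf(k, x, log_r, log_1pr))))


def audic_claverie_pmf(y: int, x: int, n1: int, n2: int) -> float:
    """p(y|x) = r^y (x+y)! / (x! y! (1+r)^(x+y+1)) with r = N2/N1."""
    if x < 0 or y < 0:
        raise ValueError(f"counts must be non-negative, got x={x}, y={y}")
    if n1 <= 0 or n2 <= 0:
        raise ValueError("library totals must be positive")
    r = n2 / n1
    return float(np.exp(_ac_logpmf(np.array([float(y)]), x, math.log(r), math.log1p(r))[0]))


def _ac_tails(x: int, y: int, r: float, rtol: float) -> tuple[float, float]:
    """(P(Y<=y|x), P(Y>=y|x)): the smaller tail is summed explicitly, the
    other follows from the exact complement (total mass is 1)."""
    log_r = math.log(r)
    log_1pr = math.log1p(r)
    mean = (x + 1) * r  # negative-binomial mean of the conditional law
    sd = math.sqrt((x + 1) * r * (1 + r))
    point = float(np.exp(_ac_logpmf(np.array([float(y)]), x, log_r, log_1pr)[0]))
    if y <= mean:
        lower = _sum_pmf(0, y, x, log_r, log_1pr)
        upper = min(1.0, 1.0 - lower + point)
    else:
        hi = int(y + 10 * sd + 50)
        upper = _sum_pmf(y, hi, x, log_r, log_1pr)
        while True:
            ext = _sum_pmf(hi + 1, hi * 2 + 50, x, log_r, log_1pr)
            if ext <= rtol * upper:
                break
            upper += ext
            hi = hi * 2 + 50
        lower = min(1.0, 1.0 - upper + point)
    return lower, upper


def audic_claverie_p(
    x: int,
    y: int,
    n1: int,
    n2: int,
    tail: str = "doubled",
    rtol: float = 1e-12,
) -> float:
    """Two-sided Audic-Claverie p-value for counts ``x`` vs ``y``.

    ``tail="doubled"`` (default) doubles the smaller of the two
    orientation-natural lower tails, P(Y<=y|x) and P(X<=x|y), and caps at
    1.  Each orientation conditions on the other library's count, so the
    result is exactly invariant under the joint swap (x<->y, N1<->N2) --
    the call must not depend on which library is listed first.
    ``tail="conditional"`` doubles the smaller of P(Y<=y|x) and P(Y>=y|x),
    conditioning on ``x`` only (order-dependent); ``tail="minlike"`` sums
    p(y'|x) over outcomes no more likely than the observed one.  Tail
    summation stops once the remainder is below ``rtol`` of the sum.
    """
    if x < 0 or y < 0:
        raise ValueError(f"counts must be non-negative, got x={x}, y={y}")
    if n1 <= 0 or n2 <= 0:
        raise ValueError("library totals must be positive")
    r = n2 / n1

    if tail == "doubled":
        # ratios computed directly from the totals so the swap
        # (x<->y, N1<->N2) is bit-for-bit invariant
        y_low, _ = _ac_tails(x, y, n2 / n1, rtol)
        x_low, _ = _ac_tails(y, x, n1 / n2, rtol)
        return min(1.0, 2.0 * min(y_low, x_low))
    if tail == "conditional":
        lower, upper = _ac_tails(x, y, r, rtol)
        return min(1.0, 2.0 * min(lower, upper))
    if tail == "minlike":
        log_r = math.log(r)
        log_1pr = math.log1p(r)
        mean = (x + 1) * r
        sd = math.sqrt((x + 1) * r * (1 + r))
        hi = int(max(y, mean) + 10 * sd + 50)
        k = np.arange(0, hi + 1, dtype=float)
        logp = _ac_logpmf(k, x, log_r, log_1pr)
        log_obs = _ac_logpmf(np.array([float(y)]), x, log_r, log_1pr)[0]
        keep = logp <= log_obs + 1e-9
        return min(1.0, float(np.exp(logsumexp(logp[keep]))))
    raise ValueError(f"unknown tail construction: {tail!r}")


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p-values must be one-dimensional")
    if len(p) == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    n = len(p)
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.clip(adjusted, 0.0, 1.0)
    out = np.empty_like(adjusted)
    out[order] = adjusted
    return out


#: Fixed output columns of a two-library comparison table.
DE_COLUMNS = ["gene_id", "x", "y", "TPM1", "TPM2", "log2_ratio", "p", "fdr", "call"]


def call_de(
    expr1: ExpressionTable,
    expr2: ExpressionTable,
    fdr_threshold: float = 0.001,
    lfc_threshold: float = 1.0,
    pseudocount: float = 0.001,
    tail: str = "doubled",
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Audic-Claverie differential calls between two libraries.

    ``log2_ratio`` is log2((TPM2 + pseudocount) / (TPM1 + pseudocount)),
    i.e. positive when the gene is higher in library 2.  Genes observed in
    neither library are reported but excluded from testing (p and fdr are
    NaN, call "unchanged"); BH-FDR is computed across the tested genes of
    this comparison.  A gene is called up when fdr < fdr_threshold and
    log2_ratio >= lfc_threshold, down symmetrically.
    """
    if list(expr1.data.index) != list(expr2.data.index):
        raise ValueError("expression tables cover different gene universes")
    genes = expr1.data.index
    x = expr1.counts.to_numpy(dtype=int)
    y = expr2.counts.to_numpy(dtype=int)
    tpm1 = expr1.tpm.to_numpy()
    tpm2 = expr2.tpm.to_numpy()
    log2_ratio = np.log2((tpm2 + pseudocount) / (tpm1 + pseudocount))

    tested = (x + y) > 0
    p = np.full(len(genes), np.nan)
    for i in np.nonzero(tested)[0]:
        p[i] = audic_claverie_p(int(x[i]), int(y[i]), expr1.clean_total, expr2.clean_total, tail=tail)
    fdr = np.full(len(genes), np.nan)
    if tested.any():
        fdr[tested] = bh_fdr(p[tested])

    call = np.full(len(genes), "unchanged", dtype=object)
    sig = tested & (fdr < fdr_threshold)
    call[sig & (log2_ratio >= lfc_threshold)] = "up"
    call[sig & (log2_ratio <= -lfc_threshold)] = "down"

    result = pd.DataFrame(
        {
            "gene_id": genes,
            "x": x,
            "y": y,
            "TPM1": tpm1,
            "TPM2": tpm2,
            "log2_ratio": log2_ratio,
            "p": p,
            "fdr": fdr,
            "call": call,
        }
    )
    summary = {
        "n_up": int((call == "up").sum()),
        "n_down": int((call == "down").sum()),
        "n_total": int(len(genes)),
    }
    return result, summary
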