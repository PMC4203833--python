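"""Comparative-CT (2^-ddCT) qPCR quantification.

Relative expression of a target gene, normalized to a housekeeping
reference gene (an rp49 analogue) and to a control group:

    dCT  = mean CT_target - mean CT_reference      (per group)
    ddCT = dCT_treated - dCT_control
    fold = 2 ** -ddCT

Replicates are averaged on the CT scale; per-replicate fold changes are
also returned so callers can report dispersion.  No amplification-
efficiency correction is applied (the pure 2^-ddCT form).
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

REQUIRED_COLUMNS = ["sample_id", "gene_id", "replicate", "ct", "group"]


def load_ct_table(path: str | os.PathLike) -> pd.DataFrame:
    """Read a CT table (TSV with sample_id, gene_id, replicate, ct, group)."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"CT table missing columns: {missing}")
    validate_ct_table(df)
    return df


def validate_ct_table(table: pd.DataFrame) -> None:
    if (table["ct"] <= 0).any():
        bad = table.loc[table["ct"] <= 0, "sample_id"].iloc[0]
        raise ValueError(f"non-positive CT value in sample {bad!r}")


@dataclass
class DdctResult:
    """One comparative-CT quantification."""

    target: str
    reference: str
    treated: str
    control: str
    dct_treated: float
    dct_control: float
    ddct: float
    fold_change: float
    replicate_fold_changes: np.ndarray

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"{self.target} vs {self.reference}: fold change "
            f"{self.fold_change:.4g} (ddCT {self.ddct:+.3f}, "
            f"{self.treated} vs {self.control})"
        )


def _group_ct(table: pd.DataFrame, group: str, gene: str, role: str) -> pd.Series:
    sub = table[(table["group"] == group) & (table["gene_id"] == gene)]
    if sub.empty:
        raise ValueError(f"missing {role} gene {gene!r} in group {group!r}")
    return sub["ct"].astype(float)


def ddct_fold_change(
    table: pd.DataFrame,
    target: str,
    reference: str,
    treated: str,
    control: str,
) -> DdctResult:
    """2^-ddCT fold change of ``target`` in ``treated`` relative to ``control``.

    ``table`` must contain CT rows for both genes in both groups; a sample
    lacking the reference gene raises an error naming that sample.
    """
    validate_ct_table(table)
    for group in (treated, control):
        for sample_id, sample in table[table["group"] == group].groupby("sample_id"):
            if reference not in set(sample["gene_id"]):
                raise ValueError(
                    f"sample {sample_id!r} (group {group!r}) has no reference gene {reference!r}"
                )

    ct_t_treated = _group_ct(table, treated, target, "target")
    ct_r_treated = _group_ct(table, treated, reference, "reference")
    ct_t_control = _group_ct(table, control, target, "target")
    ct_r_control = _group_ct(table, control, reference, "reference")

    dct_treated = ct_t_treated.mean() - ct_r_treated.mean()
    dct_control = ct_t_control.mean() - ct_r_control.mean()
    ddct = dct_treated - dct_control

    # Per-replicate spread: each treated target replicate against the
    # group-mean reference, relative to the control-group dCT.
    rep_ddct = (ct_t_treated - ct_r_treated.mean()) - dct_control
    return DdctResult(
        target=target,
        reference=reference,
        treated=treated,
        control=control,
        dct_treated=float(dct_treated),
        dct_control=float(dct_control),
        ddct=float(ddct),
        fold_change=float(2.0 ** -ddct),
        replicate_fold_changes=np.asarray(2.0 ** -rep_ddct, dtype=float),
    )
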