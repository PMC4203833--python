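"""Published eight-library tag ledger and its internal-consistency check.

The packaged fixture holds the per-library tag-analysis statistics of a
published silkworm pheromone-gland DGE experiment (eight libraries: mated
and virgin females sampled 1, 3, 24 and 48 h after mating), exactly as
printed: raw/clean tag counts, gene- and genome-mapped counts, unknown
tags, and the percentage rows derived from them.  Two printed percentage
cells appear on the 0-1 scale in the source and are stored here multiplied
by 100; a few distinct-tag counts are half-integers in the source
(presumably lane averages) and are kept verbatim.

:func:`consistency_report` recomputes every clean-tag-denominated
percentage row from the printed counts with this package's rounding rule
(half-up, two decimals) and tabulates printed vs recomputed values.  The
gene-denominated rows (marked ``**``) cannot be recomputed because the
reference gene count is not part of the ledger.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from tagdge.preprocess import round_pct

#: Percentage row -> count row whose share of the clean-tag total it is.
_PCT_TO_COUNT = {
    "All Tag Mapping to Gene*": "All Tag Mapping to Gene",
    "Distinct AllTag Mappingto Gene*": "Distinct AllTag Mappingto Gene",
    "Unambiguous Tag Mappingto Gene*": "Unambiguous Tag Mappingto Gene",
    "Distinct Unambiguous Tag Mappingto Gene*": "Distinct Unambiguous Tag Mappingto Gene",
    "Mapping to Genome*": "Mapping to Genome",
    "Distinct Mapping to Genome*": "Distinct Mapping to Genome",
    "Unknown Tag*": "Unknown Tag",
    "Distinct Unknown Tag*": "Distinct Unknown Tag",
}

LIBRARIES = ["V1", "M1", "V3", "M3", "V24", "M24", "V48", "M48"]


def load_published_stats() -> pd.DataFrame:
    """The packaged ledger, indexed by statistic name (columns: libraries)."""
    with resources.files("tagdge.data").joinpath("bmori_pg_library_stats.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t", index_col="statistic")
    return df


def consistency_report(stats: pd.DataFrame | None = None) -> pd.DataFrame:
    """Printed vs recomputed percentages for every ``*`` row and library.

    Returns a tidy DataFrame with columns statistic, library, printed,
    recomputed, abs_diff.  Distinct-tag rows whose printed counts are
    half-integers still recompute exactly (the ratio is what matters).
    """
    if stats is None:
        stats = load_published_stats()
    clean = stats.loc["Clean tag"]
    rows = []
    for pct_row, count_row in _PCT_TO_COUNT.items():
        for lib in LIBRARIES:
            recomputed = round_pct(float(stats.loc[count_row, lib]), float(clean[lib]))
            printed = float(stats.loc[pct_row, lib])
            rows.append((pct_row, lib, printed, recomputed, abs(printed - recomputed)))
    return pd.DataFrame(rows, columns=["statistic", "library", "printed", "recomputed", "abs_diff"])


def clean_tag_fractions(stats: pd.DataFrame | None = None) -> pd.Series:
    """Clean-tag share of raw tags per library, in percent (unrounded)."""
    if stats is None:
        stats = load_published_stats()
    return 100.0 * stats.loc["Clean tag"].astype(float) / stats.loc["Raw Tag"].astype(float)
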