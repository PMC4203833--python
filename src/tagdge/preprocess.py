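"""Raw tag reads -> clean distinct-tag count tables and library statistics.

Cleaning applies, in order: removal of adaptor-only (empty) reads, removal
of reads containing an undetermined base 'N', removal of reads that do not
fit the CATG+17 tag anatomy after adaptor trimming, and finally removal of
distinct tags observed exactly once (most likely sequencing errors).  The
filter order matters: a tag whose copies are split between an intact read
and an N-containing read would be a singleton only after the N filter.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from tagdge.io import ANCHOR, TAG_LEN, DEFAULT_ADAPTOR, iter_reads

_ACGT = frozenset("ACGT")


def round_pct(numerator: float, denominator: float) -> float | None:
    """100 * numerator / denominator, rounded half-up to 2 decimals.

    Returns None for a zero denominator (undefined, e.g. an empty library).
    """
    if denominator == 0:
        return None
    frac = Decimal(str(numerator)) * 100 / Decimal(str(denominator))
    return float(frac.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass
class TagCountTable:
    """Distinct clean tag -> copy number for one library, with provenance.

    ``filter_ledger`` records how many raw reads each cleaning step
    removed; the ledger plus ``clean_tag_total`` always sums back to
    ``raw_tag_total``.
    """

    library_id: str
    counts: dict[str, int]
    raw_tag_total: int = 0
    distinct_raw_total: int = 0
    clean_tag_total: int = 0
    distinct_clean_total: int = 0
    filter_ledger: dict[str, int] = field(default_factory=dict)

    def to_tsv(self, path: str | os.PathLike) -> None:
        df = pd.DataFrame(sorted(self.counts.items()), columns=["tag", "count"])
        df.to_csv(path, sep="\t", index=False)

    def stats_json(self) -> str:
        payload = {
            "library_id": self.library_id,
            "raw_tag_total": self.raw_tag_total,
            "distinct_raw_total": self.distinct_raw_total,
            "clean_tag_total": self.clean_tag_total,
            "distinct_clean_total": self.distinct_clean_total,
            "filter_ledger": self.filter_ledger,
        }
        return json.dumps(payload, indent=1, sort_keys=True)

    @classmethod
    def from_tsv(cls, path: str | os.PathLike, library_id: str = "library") -> "TagCountTable":
        df = pd.read_csv(path, sep="\t", dtype={"tag": str, "count": int})
        counts = dict(zip(df["tag"], df["count"]))
        total = int(df["count"].sum())
        return cls(
            library_id=library_id,
            counts=counts,
            raw_tag_total=total,
            distinct_raw_total=len(counts),
            clean_tag_total=total,
            distinct_clean_total=len(counts),
        )


def _is_adaptor_only(read: str, adaptor: str) -> bool:
    """Empty reads: the bare adaptor, or too short to contain a tag."""
    if read == adaptor:
        return True
    trimmed = read[len(adaptor):] if read.startswith(adaptor) else read
    return len(trimmed) < TAG_LEN


def _extract_tag(read: str, adaptor: str) -> str | None:
    """Trim a leading adaptor and return the 21-nt tag, or None if the
    read does not fit the CATG+17 anatomy."""
    if read.startswith(adaptor):
        read = read[len(adaptor):]
    tag = read[:TAG_LEN]
    if len(tag) != TAG_LEN or not tag.startswith(ANCHOR) or not _ACGT.issuperset(tag):
        return None
    return tag


def clean_tags(
    reads,
    adaptor_sequence: str = DEFAULT_ADAPTOR,
    library_id: str = "library",
) -> TagCountTable:
    """Filter raw reads into a clean distinct-tag count table.

    ``reads`` may be a FASTQ/text path, an iterable of sequences, or
    Bio.SeqRecord objects.  Empty input yields an empty table with zero
    totals.
    """
    adaptor = adaptor_sequence.upper()
    raw_total = 0
    raw_seqs: dict[str, int] = {}
    counts: dict[str, int] = {}
    ledger = {"adaptor_only": 0, "n_containing": 0, "malformed": 0, "singleton": 0}

    for read in iter_reads(reads):
        raw_total += 1
        raw_seqs[read] = raw_seqs.get(read, 0) + 1
        if _is_adaptor_only(read, adaptor):
            ledger["adaptor_only"] += 1
            continue
        if "N" in read:
            ledger["n_containing"] += 1
            continue
        tag = _extract_tag(read, adaptor)
        if tag is None:
            ledger["malformed"] += 1
            continue
        counts[tag] = counts.get(tag, 0) + 1

    singletons = [t for t, c in counts.items() if c == 1]
    ledger["singleton"] = len(singletons)
    for t in singletons:
        del counts[t]

    clean_total = sum(counts.values())
    return TagCountTable(
        library_id=library_id,
        counts=counts,
        raw_tag_total=raw_total,
        distinct_raw_total=len(raw_seqs),
        clean_tag_total=clean_total,
        distinct_clean_total=len(counts),
        filter_ledger=ledger,
    )


#: Row labels of the per-library statistics ledger, in output order.
STATS_ROWS = [
    "Raw Tag",
    "Distinct raw tag",
    "Clean tag",
    "Distinct Clean tag",
    "All Tag Mapping to Gene",
    "All Tag Mapping to Gene*",
    "Distinct AllTag Mappingto Gene",
    "Distinct AllTag Mappingto Gene*",
    "Unambiguous Tag Mappingto Gene",
    "Unambiguous Tag Mappingto Gene*",
    "Distinct Unambiguous Tag Mappingto Gene",
    "Distinct Unambiguous Tag Mappingto Gene*",
    "All Tag-mapped Genes",
    "All Tag-mapped Genes**",
    "Unambiguous Tag-mapped Genes",
    "Unambiguous Tag-mapped Genes**",
    "Mapping to Genome",
    "Mapping to Genome*",
    "Distinct Mapping to Genome",
    "Distinct Mapping to Genome*",
    "Unknown Tag",
    "Unknown Tag*",
    "Distinct Unknown Tag",
    "Distinct Unknown Tag*",
]


@dataclass
class LibraryStats:
    """The per-library analysis ledger (counts plus derived percentages).

    Tag percentages (rows marked ``*``) are shares of the clean-tag total;
    gene percentages (rows marked ``**``) are shares of the reference gene
    count.  Clean tags partition into gene-mapped + genome-mapped +
    unknown.
    """

    library_id: str
    raw_tag: int
    distinct_raw_tag: int
    clean_tag: int
    distinct_clean_tag: int
    all_tag_mapped_gene: int
    distinct_all_tag_mapped_gene: int
    unambiguous_tag_mapped_gene: int
    distinct_unambiguous_tag_mapped_gene: int
    all_tag_mapped_genes: int
    unambiguous_tag_mapped_genes: int
    mapped_to_genome: int
    distinct_mapped_to_genome: int
    unknown_tag: int
    distinct_unknown_tag: int
    reference_gene_count: int

    def percentages(self) -> dict[str, float | None]:
        c, g = self.clean_tag, self.reference_gene_count
        return {
            "All Tag Mapping to Gene*": round_pct(self.all_tag_mapped_gene, c),
            "Distinct AllTag Mappingto Gene*": round_pct(self.distinct_all_tag_mapped_gene, c),
            "Unambiguous Tag Mappingto Gene*": round_pct(self.unambiguous_tag_mapped_gene, c),
            "Distinct Unambiguous Tag Mappingto Gene*": round_pct(self.distinct_unambiguous_tag_mapped_gene, c),
            "All Tag-mapped Genes**": round_pct(self.all_tag_mapped_genes, g),
            "Unambiguous Tag-mapped Genes**": round_pct(self.unambiguous_tag_mapped_genes, g),
            "Mapping to Genome*": round_pct(self.mapped_to_genome, c),
            "Distinct Mapping to Genome*": round_pct(self.distinct_mapped_to_genome, c),
            "Unknown Tag*": round_pct(self.unknown_tag, c),
            "Distinct Unknown Tag*": round_pct(self.distinct_unknown_tag, c),
        }

    def as_rows(self) -> dict[str, float | int | None]:
        pct = self.percentages()
        return {
            "Raw Tag": self.raw_tag,
            "Distinct raw tag": self.distinct_raw_tag,
            "Clean tag": self.clean_tag,
            "Distinct Clean tag": self.distinct_clean_tag,
            "All Tag Mapping to Gene": self.all_tag_mapped_gene,
            "All Tag Mapping to Gene*": pct["All Tag Mapping to Gene*"],
            "Distinct AllTag Mappingto Gene": self.distinct_all_tag_mapped_gene,
            "Distinct AllTag Mappingto Gene*": pct["Distinct AllTag Mappingto Gene*"],
            "Unambiguous Tag Mappingto Gene": self.unambiguous_tag_mapped_gene,
            "Unambiguous Tag Mappingto Gene*": pct["Unambiguous Tag Mappingto Gene*"],
            "Distinct Unambiguous Tag Mappingto Gene": self.distinct_unambiguous_tag_mapped_gene,
            "Distinct Unambiguous Tag Mappingto Gene*": pct["Distinct Unambiguous Tag Mappingto Gene*"],
            "All Tag-mapped Genes": self.all_tag_mapped_genes,
            "All Tag-mapped Genes**": pct["All Tag-mapped Genes**"],
            "Unambiguous Tag-mapped Genes": self.unambiguous_tag_mapped_genes,
            "Unambiguous Tag-mapped Genes**": pct["Unambiguous Tag-mapped Genes**"],
            "Mapping to Genome": self.mapped_to_genome,
            "Mapping to Genome*": pct["Mapping to Genome*"],
            "Distinct Mapping to Genome": self.distinct_mapped_to_genome,
            "Distinct Mapping to Genome*": pct["Distinct Mapping to Genome*"],
            "Unknown Tag": self.unknown_tag,
            "Unknown Tag*": pct["Unknown Tag*"],
            "Distinct Unknown Tag": self.distinct_unknown_tag,
            "Distinct Unknown Tag*": pct["Distinct Unknown Tag*"],
        }

    def to_tsv(self, path: str | os.PathLike) -> None:
        rows = self.as_rows()
        with open(path, "w") as fh:
            fh.write(f"Summary\t{self.library_id}\n")
            for label in STATS_ROWS:
                value = rows[label]
                if value is None:
                    text = "NA"
                elif label.endswith("*"):
                    text = f"{value:.2f}%"
                else:
                    text = str(value)
                fh.write(f"{label}\t{text}\n")


def library_stats(table: TagCountTable, assignment) -> LibraryStats:
    """Fill the library ledger from a clean table and its tag assignment.

    ``assignment`` is the :class:`~tagdge.catalogue.TagAssignment` produced
    by mapping ``table`` against the virtual tag catalogues.
    """
    agg = assignment.aggregates
    return LibraryStats(
        library_id=table.library_id,
        raw_tag=table.raw_tag_total,
        distinct_raw_tag=table.distinct_raw_total,
        clean_tag=table.clean_tag_total,
        distinct_clean_tag=table.distinct_clean_total,
        all_tag_mapped_gene=agg["all_mapped_total"],
        distinct_all_tag_mapped_gene=agg["all_mapped_distinct"],
        unambiguous_tag_mapped_gene=agg["unambiguous_total"],
        distinct_unambiguous_tag_mapped_gene=agg["unambiguous_distinct"],
        all_tag_mapped_genes=agg["all_tag_mapped_genes"],
        unambiguous_tag_mapped_genes=agg["unambiguous_tag_mapped_genes"],
        mapped_to_genome=agg["genome_total"],
        distinct_mapped_to_genome=agg["genome_distinct"],
        unknown_tag=agg["unknown_total"],
        distinct_unknown_tag=agg["unknown_distinct"],
        reference_gene_count=assignment.reference_gene_count,
    )


def copy_number_distribution(
    table: TagCountTable,
    bin_edges: Sequence[float] = (2, 5, 10, 100),
) -> pd.DataFrame:
    """Copy-number histogram of clean tags, total- and distinct-weighted.

    ``bin_edges`` are the left edges of half-open bins; the last bin is
    unbounded above.  With the default edges the bins are [2,5), [5,10),
    [10,100) and [100,inf).  Both weightings each sum to 1.
    """
    edges = list(bin_edges)
    if sorted(edges) != edges or len(set(edges)) != len(edges):
        raise ValueError(f"bin edges must be strictly increasing, got {bin_edges}")
    if not table.counts:
        raise ValueError("empty tag table has no copy-number distribution")

    counts = np.array(list(table.counts.values()), dtype=float)
    full_edges = np.array(edges + [np.inf], dtype=float)
    labels = [
        f"[{int(a) if float(a).is_integer() else a},{'inf' if np.isinf(b) else (int(b) if float(b).is_integer() else b)})"
        for a, b in zip(full_edges[:-1], full_edges[1:])
    ]
    which = np.digitize(counts, full_edges[1:-1], right=False)
    total_w = np.zeros(len(labels))
    distinct_w = np.zeros(len(labels))
    for b in range(len(labels)):
        mask = which == b
        total_w[b] = counts[mask].sum()
        distinct_w[b] = mask.sum()
    return pd.DataFrame(
        {
            "bin": labels,
            "total_share": total_w / counts.sum(),
            "distinct_share": distinct_w / len(counts),
        }
    )
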