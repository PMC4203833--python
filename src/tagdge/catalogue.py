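"""Virtual CATG+17 tag catalogues and clean-tag-to-gene assignment.

A catalogue enumerates every possible 21-nt tag a reference sequence set
can produce: each CATG occurrence with at least 17 nt downstream yields
one entry.  Clean tags are then assigned by an exact -> one-mismatch
ladder against the transcript catalogue, with ambiguity (multiple genes at
the winning tier) filtered out, and the leftovers tried against a
genome-derived catalogue before being declared unknown.

Mismatches are only permitted in the 17 variable positions: the CATG
anchor is fixed by the restriction enzyme, so a read without an intact
anchor would never have survived cleaning.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple

import pandas as pd
from Bio.SeqRecord import SeqRecord

from tagdge.io import ANCHOR, TAG_LEN, VARIABLE_LEN

_ALLOWED = frozenset("ACGTN")


class TagSite(NamedTuple):
    gene_id: str
    position: int  # 0-based offset of the CATG start on the source sequence
    is_three_prime_most: bool


@dataclass
class VirtualTagCatalogue:
    """All candidate tags of a reference, indexed by tag sequence."""

    entries: dict[str, list[TagSite]]
    source: str  # "transcript" or "genome"
    reference_gene_count: int
    gene_ids: tuple[str, ...] = ()

    def genes_of(self, tag: str) -> set[str]:
        return {site.gene_id for site in self.entries.get(tag, ())}

    def __len__(self) -> int:
        return len(self.entries)

    def to_tsv(self, path: str | os.PathLike) -> None:
        rows = []
        for tag in sorted(self.entries):
            for site in self.entries[tag]:
                rows.append((tag, site.gene_id, site.position, int(site.is_three_prime_most)))
        pd.DataFrame(rows, columns=["tag", "gene_id", "position", "is_3prime_most"]).to_csv(
            path, sep="\t", index=False
        )


def build_catalogue(records: Iterable[SeqRecord], source: str = "transcript") -> VirtualTagCatalogue:
    """Enumerate all CATG+17 tags of a reference sequence set.

    Rejects duplicate record identifiers and characters outside ACGTN;
    candidate tags containing N are skipped.  The 3'-most valid site of
    each record is flagged (the site the NlaIII/MmeI protocol dominantly
    captures).
    """
    records = list(records)
    ids = [rec.id for rec in records]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate sequence identifiers: {dupes}")

    entries: dict[str, list[TagSite]] = {}
    for rec in records:
        seq = str(rec.seq).upper()
        bad = set(seq) - _ALLOWED
        if bad:
            raise ValueError(f"sequence {rec.id} contains invalid characters: {sorted(bad)}")
        sites = []
        start = seq.find(ANCHOR)
        while start != -1:
            if start + TAG_LEN <= len(seq):
                tag = seq[start:start + TAG_LEN]
                if "N" not in tag:
                    sites.append((start, tag))
            start = seq.find(ANCHOR, start + 1)
        for i, (pos, tag) in enumerate(sites):
            entries.setdefault(tag, []).append(
                TagSite(rec.id, pos, is_three_prime_most=(i == len(sites) - 1))
            )
    return VirtualTagCatalogue(
        entries=entries,
        source=source,
        reference_gene_count=len(records),
        gene_ids=tuple(ids),
    )


def one_mismatch_neighbors(tag: str) -> Iterable[str]:
    """The 51 tags differing from ``tag`` at one of the 17 variable
    positions (the CATG anchor is never mutated)."""
    for i in range(len(ANCHOR), TAG_LEN):
        for b in "ACGT":
            if b != tag[i]:
                yield tag[:i] + b + tag[i + 1:]


class TagOutcome(NamedTuple):
    category: str  # "gene" | "ambiguous" | "genome_only" | "unknown"
    gene_ids: tuple[str, ...]  # matched genes, sorted; empty for genome_only/unknown
    match_type: str | None  # "exact" | "one_mismatch" | None


def _match_tier(tag: str, catalogue: VirtualTagCatalogue) -> tuple[set[str], str] | None:
    """Exact-first, then one-mismatch; ambiguity judged within the tier."""
    genes = catalogue.genes_of(tag)
    if genes:
        return genes, "exact"
    genes = set()
    for nb in one_mismatch_neighbors(tag):
        genes |= catalogue.genes_of(nb)
    if genes:
        return genes, "one_mismatch"
    return None


@dataclass
class TagAssignment:
    """Per-tag mapping outcomes plus the aggregate ledger for one library."""

    outcomes: dict[str, TagOutcome]
    aggregates: dict[str, int]
    reference_gene_count: int
    catalogue_gene_ids: tuple[str, ...] = ()

    def to_tsv(self, path: str | os.PathLike, table=None) -> None:
        counts = table.counts if table is not None else {}
        rows = []
        for tag in sorted(self.outcomes):
            out = self.outcomes[tag]
            rows.append(
                (
                    tag,
                    counts.get(tag, ""),
                    out.category,
                    ";".join(out.gene_ids),
                    out.match_type or "",
                )
            )
        pd.DataFrame(rows, columns=["tag", "count", "outcome", "gene_id", "match_type"]).to_csv(
            path, sep="\t", index=False
        )


def assign_tags(
    table,
    catalogue: VirtualTagCatalogue,
    genome_catalogue: VirtualTagCatalogue | None = None,
) -> TagAssignment:
    """Assign each clean tag to a gene, ambiguous, genome-only or unknown.

    Ladder per tag: exact gene-catalogue match; else one-mismatch gene
    match; a winning tier matching more than one gene is ambiguous; tags
    without any gene-tier match are tried against the genome catalogue
    with the same exact -> one-mismatch ladder (genome_only); the rest are
    unknown.  Aggregates are reported over both total tag copies and
    distinct tags; "mapped to gene" includes ambiguous tags, while the
    unambiguous rows exclude them.
    """
    outcomes: dict[str, TagOutcome] = {}
    agg = {
        "all_mapped_total": 0,
        "all_mapped_distinct": 0,
        "unambiguous_total": 0,
        "unambiguous_distinct": 0,
        "genome_total": 0,
        "genome_distinct": 0,
        "unknown_total": 0,
        "unknown_distinct": 0,
    }
    all_genes: set[str] = set()
    unambiguous_genes: set[str] = set()

    for tag in sorted(table.counts):
        count = table.counts[tag]
        hit = _match_tier(tag, catalogue)
        if hit is not None:
            genes, tier = hit
            all_genes |= genes
            agg["all_mapped_total"] += count
            agg["all_mapped_distinct"] += 1
            if len(genes) == 1:
                gene = next(iter(genes))
                unambiguous_genes.add(gene)
                outcomes[tag] = TagOutcome("gene", (gene,), tier)
                agg["unambiguous_total"] += count
                agg["unambiguous_distinct"] += 1
            else:
                outcomes[tag] = TagOutcome("ambiguous", tuple(sorted(genes)), tier)
            continue
        if genome_catalogue is not None:
            genome_hit = _match_tier(tag, genome_catalogue)
            if genome_hit is not None:
                outcomes[tag] = TagOutcome("genome_only", (), genome_hit[1])
                agg["genome_total"] += count
                agg["genome_distinct"] += 1
                continue
        outcomes[tag] = TagOutcome("unknown", (), None)
        agg["unknown_total"] += count
        agg["unknown_distinct"] += 1

    agg["all_tag_mapped_genes"] = len(all_genes)
    agg["unambiguous_tag_mapped_genes"] = len(unambiguous_genes)
    return TagAssignment(
        outcomes=outcomes,
        aggregates=agg,
        reference_gene_count=catalogue.reference_gene_count,
        catalogue_gene_ids=tuple(sorted(catalogue.gene_ids)),
    )


def count_gene_tags(assignment: TagAssignment, table) -> pd.Series:
    """Per-gene unambiguous tag counts (genes without tags appear as 0)."""
    counts = {g: 0 for g in assignment.catalogue_gene_ids}
    for tag, out in assignment.outcomes.items():
        if out.category == "gene":
            counts[out.gene_ids[0]] = counts.get(out.gene_ids[0], 0) + table.counts.get(tag, 0)
    series = pd.Series(counts, dtype=int).sort_index()
    series.index.name = "gene_id"
    series.name = "count"
    return series
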