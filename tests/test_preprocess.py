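"""Cleaning filters, the library ledger, and copy-number histograms."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tagdge.io import DEFAULT_ADAPTOR, write_reads, TagFormatError, iter_reads
from tagdge.preprocess import (
    clean_tags,
    copy_number_distribution,
    library_stats,
    round_pct,
    TagCountTable,
)
from tagdge.catalogue import build_catalogue, assign_tags
from tagdge.simulate import SimConfig, simulate_transcriptome, simulate_tag_libraries

from _helpers import literal_clean_filter

TAG_X = "CATG" + "A" * 17
TAG_Y = "CATG" + "C" * 17
TAG_N = "CATG" + "N" + "A" * 16


def test_three_filters_applied_in_order():
    reads = [TAG_X] * 3 + [TAG_Y] + [TAG_N] * 2 + [DEFAULT_ADAPTOR] * 4
    table = clean_tags(reads)
    assert table.counts == {TAG_X: 3}
    assert table.raw_tag_total == 10
    assert table.clean_tag_total == 3
    assert table.distinct_clean_total == 1
    assert table.filter_ledger == {
        "adaptor_only": 4, "n_containing": 2, "malformed": 0, "singleton": 1,
    }


def test_all_identical_reads():
    table = clean_tags([TAG_X] * 5)
    assert table.distinct_raw_total == 1
    assert table.distinct_clean_total == 1
    assert table.clean_tag_total == 5


def test_empty_input_gives_zero_totals():
    table = clean_tags([])
    assert table.raw_tag_total == 0
    assert table.clean_tag_total == 0
    assert table.counts == {}


def test_adaptor_prefix_is_trimmed():
    table = clean_tags([DEFAULT_ADAPTOR + TAG_X] * 2)
    assert table.counts == {TAG_X: 2}


def test_non_anchored_reads_are_malformed():
    table = clean_tags(["AATG" + "A" * 17] * 3)
    assert table.counts == {}
    assert table.filter_ledger["malformed"] == 3


def test_cleaning_is_idempotent():
    reads = [TAG_X] * 3 + [TAG_Y] * 2 + [TAG_N] * 2 + [DEFAULT_ADAPTOR] * 4
    first = clean_tags(reads)
    expanded = [t for t, c in first.counts.items() for _ in range(c)]
    second = clean_tags(expanded)
    assert second.counts == first.counts
    assert second.clean_tag_total == first.clean_tag_total


def test_copy_number_filter_runs_after_read_filters():
    # Tag Z appears twice, but one copy carries an N: after the N filter it
    # is a singleton and must be removed.  Filtering singletons first (on
    # raw reads) would have kept it.
    tag_z = "CATG" + "G" * 17
    reads = [tag_z, tag_z[:10] + "N" + tag_z[11:], TAG_X, TAG_X]
    table = clean_tags(reads)
    assert tag_z not in table.counts
    assert table.counts == {TAG_X: 2}


@given(
    st.lists(
        st.one_of(
            st.sampled_from([TAG_X, TAG_Y, TAG_N, DEFAULT_ADAPTOR, "CATGTT", "TTTT" + "A" * 17]),
            st.text(alphabet="ACGTN", min_size=21, max_size=21).map(lambda s: "CATG" + s[4:]),
        ),
        max_size=60,
    )
)
@settings(max_examples=200, deadline=None)
def test_ledger_conservation(reads):
    table = clean_tags(reads)
    assert table.raw_tag_total == len(reads)
    assert table.clean_tag_total + sum(table.filter_ledger.values()) == table.raw_tag_total
    assert table.clean_tag_total == sum(table.counts.values())
    assert table.distinct_clean_total == len(table.counts)
    assert all(c >= 2 for c in table.counts.values())
    assert all(t.startswith("CATG") and len(t) == 21 and "N" not in t for t in table.counts)


def test_clean_matches_independent_literal_recount():
    # Deeply covered toy library so recurrent error tags survive the
    # copy-number filter; the module must agree exactly with a naive
    # transcription of the filter definitions.
    cfg = dataclasses.replace(
        SimConfig(), n_genes=10, transcript_length_range=(100, 500), n_de_genes=0,
        library_depth=10_000, error_rate=0.01, seed=3,
    )
    bundle = simulate_transcriptome(cfg)
    libraries, _ = simulate_tag_libraries(cfg, bundle)
    table = clean_tags(libraries.mated)
    expected, raw = literal_clean_filter(libraries.mated, DEFAULT_ADAPTOR)
    assert table.counts == expected
    assert table.raw_tag_total == raw
    assert table.clean_tag_total / table.raw_tag_total >= 0.9


def test_fastq_roundtrip_and_malformed_error(tmp_path):
    path = tmp_path / "reads.fastq"
    write_reads([TAG_X, TAG_Y], path)
    assert list(iter_reads(path)) == [TAG_X, TAG_Y]
    bad = tmp_path / "bad.fastq"
    bad.write_text("@r0\n" + TAG_X + "\n+\nIII\n")  # quality length mismatch
    with pytest.raises(TagFormatError, match="record 0"):
        list(iter_reads(bad))


def test_percentage_rounding_is_half_up_2dp():
    assert round_pct(2174138, 3564408) == 61.00
    assert round_pct(2246229, 3606840) == 62.28
    assert round_pct(523464, 3564408) == 14.69
    assert round_pct(530125, 3606840) == 14.70
    assert round_pct(1, 0) is None
    assert round_pct(125, 1000) == 12.50  # exact .5 rounds up at the cut digit
    assert round_pct(1005, 100000) == 1.01


def test_library_stats_partitions_clean_tags(small_pair, small_bundle):
    libraries, _ = small_pair
    table = clean_tags(libraries.mated, library_id="M1")
    gene_cat = build_catalogue(small_bundle.transcripts)
    genome_cat = build_catalogue([small_bundle.genome], source="genome")
    stats = library_stats(table, assign_tags(table, gene_cat, genome_cat))
    assert stats.all_tag_mapped_gene + stats.mapped_to_genome + stats.unknown_tag == stats.clean_tag
    assert stats.unambiguous_tag_mapped_gene <= stats.all_tag_mapped_gene
    assert stats.unambiguous_tag_mapped_genes <= stats.all_tag_mapped_genes
    pct = stats.percentages()
    assert pct["All Tag Mapping to Gene*"] == round_pct(stats.all_tag_mapped_gene, stats.clean_tag)
    assert stats.reference_gene_count == len(small_bundle.transcripts)


def test_library_stats_tsv_uses_ledger_row_labels(tmp_path, small_pair, small_bundle):
    libraries, _ = small_pair
    table = clean_tags(libraries.virgin, library_id="V1")
    gene_cat = build_catalogue(small_bundle.transcripts)
    stats = library_stats(table, assign_tags(table, gene_cat, None))
    out = tmp_path / "stats.tsv"
    stats.to_tsv(out)
    text = out.read_text()
    for label in ("Raw Tag", "Distinct Clean tag", "Unambiguous Tag Mappingto Gene*",
                  "Mapping to Genome", "Unknown Tag*"):
        assert f"\n{label}\t" in text or text.startswith(f"{label}\t")


def test_zero_depth_library_stats():
    table = clean_tags([])
    cat = build_catalogue([], source="transcript")
    stats = library_stats(table, assign_tags(table, cat, None))
    assert stats.clean_tag == 0
    assert all(v is None for v in stats.percentages().values())


def test_copy_number_two_tag_arithmetic():
    table = TagCountTable("t", {"CATG" + "A" * 17: 2, "CATG" + "C" * 17: 200},
                          raw_tag_total=202, distinct_raw_total=2,
                          clean_tag_total=202, distinct_clean_total=2)
    dist = copy_number_distribution(table).set_index("bin")
    assert dist.loc["[100,inf)", "distinct_share"] == 0.5
    assert dist.loc["[100,inf)", "total_share"] == pytest.approx(200 / 202)
    assert dist["total_share"].sum() == pytest.approx(1.0, abs=1e-9)
    assert dist["distinct_share"].sum() == pytest.approx(1.0, abs=1e-9)


def test_copy_number_single_tag():
    table = TagCountTable("t", {"CATG" + "A" * 17: 7}, 7, 1, 7, 1)
    dist = copy_number_distribution(table).set_index("bin")
    assert dist.loc["[5,10)", "total_share"] == 1.0
    assert dist.loc["[5,10)", "distinct_share"] == 1.0


def test_unsorted_bin_edges_rejected():
    table = TagCountTable("t", {"CATG" + "A" * 17: 7}, 7, 1, 7, 1)
    with pytest.raises(ValueError, match="increasing"):
        copy_number_distribution(table, bin_edges=(5, 2, 10))
    with pytest.raises(ValueError, match="empty"):
        copy_number_distribution(TagCountTable("t", {}, 0, 0, 0, 0))


def test_heavy_tail_low_copy_bin_dominates_distinct_share():
    # Long-tailed abundances: rare tags dominate the distinct-tag
    # distribution while abundant tags dominate the total distribution.
    cfg = dataclasses.replace(
        SimConfig(), n_genes=200, transcript_length_range=(100, 1000), n_de_genes=0,
        library_depth=100_000, base_expression_dispersion=2.0, seed=5,
    )
    bundle = simulate_transcriptome(cfg)
    libraries, _ = simulate_tag_libraries(cfg, bundle)
    table = clean_tags(libraries.virgin)
    dist = copy_number_distribution(table).set_index("bin")
    # independent brute-force histogram
    counts = np.array(list(table.counts.values()))
    low_distinct = (counts < 5).mean()
    low_total = counts[counts < 5].sum() / counts.sum()
    assert dist.loc["[2,5)", "distinct_share"] == pytest.approx(low_distinct)
    assert dist.loc["[2,5)", "total_share"] == pytest.approx(low_total)
    assert dist.loc["[2,5)", "distinct_share"] > dist.loc["[2,5)", "total_share"]
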