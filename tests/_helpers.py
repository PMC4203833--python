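"""Independent oracles and small pipeline drivers shared across tests.

Everything here is deliberately written *differently* from the package:
rational arithmetic, linear scans and literal filter transcriptions, so
that agreement with the implementation is evidence rather than tautology.
"""

from __future__ import annotations

import dataclasses
from fractions import Fraction

from tagdge.simulate import SimConfig, simulate_transcriptome, simulate_tag_libraries
from tagdge.preprocess import clean_tags
from tagdge.catalogue import build_catalogue, assign_tags, count_gene_tags
from tagdge.diffexpr import tpm_normalize, call_de

TAG_LEN = 21
ANCHOR = "CATG"


def ac_lower_tail_exact(x: int, y: int, r: Fraction) -> Fraction:
    """P(Y <= y | x) as an exact rational.

    pmf(k) = r^k C(x+k,k) / (1+r)^(x+k+1); successive terms satisfy
    p_k / p_{k-1} = r (x+k) / (k (1+r)).
    """
    p = Fraction(1, 1) / (1 + r) ** (x + 1)
    total = p
    for k in range(1, y + 1):
        p = p * r * (x + k) / (k * (1 + r))
        total += p
    return total


def ac_p_exact(x: int, y: int, r: Fraction) -> Fraction:
    """Two-sided exact rational: doubled smaller orientation-lower-tail.

    The complement needs no tail truncation because the conditional law
    has total mass exactly 1.
    """
    t1 = ac_lower_tail_exact(x, y, r)
    t2 = ac_lower_tail_exact(y, x, 1 / r)
    return min(Fraction(1), 2 * min(t1, t2))


def literal_clean_filter(reads, adaptor: str):
    """Line-by-line transcription of the cleaning rules, kept naive on
    purpose: returns (kept tag -> count, raw_total)."""
    survivors = []
    raw = 0
    for read in reads:
        read = str(read).upper()
        raw += 1
        trimmed = read[len(adaptor):] if read.startswith(adaptor) else read
        if read == adaptor or len(trimmed) < TAG_LEN:
            continue  # empty / adaptor-only
        if "N" in read:
            continue
        tag = trimmed[:TAG_LEN]
        if not tag.startswith(ANCHOR) or len(tag) != TAG_LEN or set(tag) - set("ACGT"):
            continue
        survivors.append(tag)
    counts = {}
    for tag in survivors:
        counts[tag] = counts.get(tag, 0) + 1
    return {t: c for t, c in counts.items() if c >= 2}, raw


def linear_scan_match(tag: str, catalogue) -> tuple[set[str], str] | None:
    """Brute-force exact-then-one-mismatch lookup by scanning every
    catalogue tag and counting disagreements (anchor must match)."""
    exact, near = set(), set()
    for cat_tag, sites in catalogue.entries.items():
        if cat_tag[:4] != tag[:4]:
            continue
        mismatches = sum(a != b for a, b in zip(cat_tag[4:], tag[4:]))
        if mismatches == 0:
            exact.update(s.gene_id for s in sites)
        elif mismatches == 1:
            near.update(s.gene_id for s in sites)
    if exact:
        return exact, "exact"
    if near:
        return near, "one_mismatch"
    return None


def run_pair(config: SimConfig):
    """simulate -> clean -> map -> count -> DE for one library pair."""
    bundle = simulate_transcriptome(config)
    libraries, truth = simulate_tag_libraries(config, bundle)
    gene_cat = build_catalogue(bundle.transcripts)
    genome_cat = build_catalogue([bundle.genome], source="genome")
    expr = {}
    tables = {}
    for name, reads in (("virgin", libraries.virgin), ("mated", libraries.mated)):
        table = clean_tags(reads, library_id=name)
        assignment = assign_tags(table, gene_cat, genome_cat)
        expr[name] = tpm_normalize(count_gene_tags(assignment, table), table.clean_tag_total)
        tables[name] = table
    de, summary = call_de(expr["virgin"], expr["mated"])
    return de, summary, truth, tables


def scaled_config(**overrides) -> SimConfig:
    """The scaled-down study conditions used throughout the tests:
    200 genes, 20 spike-ins at log2fc = 2, 1e5 tags per library."""
    base = dict(
        n_genes=200,
        transcript_length_range=(100, 1000),
        n_de_genes=20,
        de_log2fc=2.0,
        library_depth=100_000,
        base_expression_dispersion=2.0,
    )
    base.update(overrides)
    return dataclasses.replace(SimConfig(), **base)
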