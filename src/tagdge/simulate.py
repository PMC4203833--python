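"""Synthetic DGE study generator.

Emulates a paired "mated"/"virgin" tag-profiling experiment: a toy
transcriptome in which every gene carries at least one NlaIII (CATG) site
with the 17 nt that MmeI releases downstream, a genome built by
concatenating the transcripts with random intergenic spacers, a flat
gene->term annotation table, and per-condition 21-bp tag libraries drawn
multinomially from log-normal gene abundances with spiked fold changes,
per-base substitution errors, N-containing reads and adaptor-only reads.

The generator is fully seeded: an identical :class:`SimConfig` reproduces
byte-identical FASTA/read output.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict, replace
from typing import Mapping

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from tagdge.io import ANCHOR, TAG_LEN, VARIABLE_LEN, DEFAULT_ADAPTOR

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

#: Minimal transcript length able to host a CATG anchor plus 17 nt: the
#: anchor itself needs 4 nt and a few nt of context upstream.
_MIN_TRANSCRIPT_LEN = 25


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one synthetic paired-library experiment.

    Defaults reflect a deep tag-profiling run: libraries of 3.5 million
    21-bp tags over a transcriptome-scale reference, a per-base error rate
    low enough that ~98% of raw tags survive cleaning, and a long-tailed
    (log-normal, sigma=2) abundance distribution.  Tests and calibration
    runs pass scaled-down copies via :func:`dataclasses.replace`.
    """

    n_genes: int = 14623
    transcript_length_range: tuple[int, int] = (300, 3000)
    n_de_genes: int = 200
    de_log2fc: float = 2.0
    library_depth: int = 3_500_000
    error_rate: float = 0.001
    n_read_fraction: float = 0.002
    adaptor_only_fraction: float = 0.002
    base_expression_dispersion: float = 2.0
    alt_site_fraction: float = 0.0
    max_spike_share: float = 0.01
    seed: int = 0

    def validate(self) -> None:
        lo, hi = self.transcript_length_range
        if lo < _MIN_TRANSCRIPT_LEN:
            raise ValueError(
                f"transcript_length_range lower bound {lo} < {_MIN_TRANSCRIPT_LEN}: "
                f"too short to host a CATG+{VARIABLE_LEN} tag site"
            )
        if hi < lo:
            raise ValueError("transcript_length_range upper bound below lower bound")
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")
        if not 0 <= self.n_de_genes <= self.n_genes:
            raise ValueError("n_de_genes must lie in [0, n_genes]")
        if self.library_depth < 1:
            raise ValueError("library_depth must be >= 1")
        for name in ("error_rate", "n_read_fraction", "adaptor_only_fraction", "alt_site_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if not 0.0 < self.max_spike_share <= 1.0:
            raise ValueError("max_spike_share must lie in (0, 1]")
        if self.base_expression_dispersion <= 0:
            raise ValueError("base_expression_dispersion must be positive")


@dataclass
class ReferenceBundle:
    """Reference side of a simulation: transcripts, genome, annotation."""

    transcripts: list[SeqRecord]
    genome: SeqRecord
    annotation: pd.DataFrame  # columns: gene_id, term_id

    @property
    def gene_ids(self) -> list[str]:
        return [rec.id for rec in self.transcripts]


@dataclass
class LibraryPair:
    """Raw read sets for one mated/virgin library pair."""

    mated: list[str]
    virgin: list[str]


@dataclass
class GroundTruth:
    """True per-gene abundances and the spiked differential structure."""

    abundance: pd.DataFrame  # index gene_id, columns ["mated", "virgin"]
    de_gene_ids: set[str] = field(default_factory=set)
    true_log2fc: dict[str, float] = field(default_factory=dict)

    def expected_counts(self, condition: str, depth: int) -> pd.Series:
        """Expected tag count per gene at a given sequencing depth."""
        a = self.abundance[condition]
        return depth * a / a.sum()

    def to_json(self, path: str | os.PathLike) -> None:
        payload = {
            "abundance": {g: {"mated": float(row["mated"]), "virgin": float(row["virgin"])}
                          for g, row in self.abundance.iterrows()},
            "de_gene_ids": sorted(self.de_gene_ids),
            "true_log2fc": {g: self.true_log2fc[g] for g in sorted(self.true_log2fc)},
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | os.PathLike) -> "GroundTruth":
        with open(path) as fh:
            payload = json.load(fh)
        abundance = pd.DataFrame.from_dict(payload["abundance"], orient="index")
        abundance.index.name = "gene_id"
        return cls(
            abundance=abundance[["mated", "virgin"]],
            de_gene_ids=set(payload["de_gene_ids"]),
            true_log2fc={g: float(v) for g, v in payload["true_log2fc"].items()},
        )


def _rng(config: SimConfig, stream: int) -> np.random.Generator:
    """Independent, reproducible substream for one stage of the simulation."""
    return np.random.default_rng(np.random.SeedSequence(entropy=config.seed, spawn_key=(stream,)))


def _random_dna(rng: np.random.Generator, length: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=length)]


def _codes_to_str(codes: np.ndarray) -> str:
    return codes.tobytes().decode("ascii")


def valid_tag_sites(sequence: str) -> list[int]:
    """0-based CATG start positions with >= 17 nt downstream of the anchor."""
    sites = []
    start = sequence.find(ANCHOR)
    while start != -1:
        if start + TAG_LEN <= len(sequence):
            sites.append(start)
        start = sequence.find(ANCHOR, start + 1)
    return sites


def simulate_transcriptome(config: SimConfig) -> ReferenceBundle:
    """Generate transcripts, a concatenated genome, and a gene->term table.

    Every transcript is guaranteed at least one CATG site with 17 nt
    downstream; when the random sequence lacks one, a CATG anchor is
    written 21 nt from the 3' end.  The genome interleaves the transcripts
    with random 50-200 nt intergenic spacers.  Each gene receives 1-5
    synthetic GO-like terms from a shared pool.
    """
    config.validate()
    rng = _rng(config, 0)
    lo, hi = config.transcript_length_range
    width = max(4, len(str(config.n_genes)))

    transcripts: list[SeqRecord] = []
    for i in range(config.n_genes):
        length = int(rng.integers(lo, hi + 1))
        codes = _random_dna(rng, length)
        seq = _codes_to_str(codes)
        if not valid_tag_sites(seq):
            pos = length - TAG_LEN
            codes[pos:pos + len(ANCHOR)] = np.frombuffer(ANCHOR.encode(), dtype=np.uint8)
            seq = _codes_to_str(codes)
        gene_id = f"G{i + 1:0{width}d}"
        transcripts.append(SeqRecord(Seq(seq), id=gene_id, description=""))

    pieces = []
    for rec in transcripts:
        pieces.append(_codes_to_str(_random_dna(rng, int(rng.integers(50, 201)))))
        pieces.append(str(rec.seq))
    pieces.append(_codes_to_str(_random_dna(rng, int(rng.integers(50, 201)))))
    genome = SeqRecord(Seq("".join(pieces)), id="genome", description="")

    n_terms = max(10, config.n_genes // 5)
    term_ids = [f"T{j + 1:04d}" for j in range(n_terms)]
    rows = []
    for rec in transcripts:
        k = int(rng.integers(1, 6))
        for t in sorted(rng.choice(n_terms, size=k, replace=False)):
            rows.append((rec.id, term_ids[t]))
    annotation = pd.DataFrame(rows, columns=["gene_id", "term_id"])

    return ReferenceBundle(transcripts=transcripts, genome=genome, annotation=annotation)


def _gene_tag_matrix(bundle: ReferenceBundle) -> tuple[np.ndarray, list[list[int]]]:
    """Per-gene 3'-most tag (uint8 codes) and all valid site offsets."""
    n = len(bundle.transcripts)
    tags = np.empty((n, TAG_LEN), dtype=np.uint8)
    all_sites: list[list[int]] = []
    for i, rec in enumerate(bundle.transcripts):
        seq = str(rec.seq).upper()
        sites = valid_tag_sites(seq)
        if not sites:
            raise ValueError(f"gene {rec.id} has no valid CATG+{VARIABLE_LEN} tag site")
        pos = sites[-1]  # 3'-most
        tags[i] = np.frombuffer(seq[pos:pos + TAG_LEN].encode(), dtype=np.uint8)
        all_sites.append(sites)
    return tags, all_sites


def _emit_library(
    rng: np.random.Generator,
    config: SimConfig,
    bundle: ReferenceBundle,
    proportions: np.ndarray,
    tags_3p: np.ndarray,
    all_sites: list[list[int]],
) -> list[str]:
    depth = config.library_depth
    n_adaptor = int(rng.binomial(depth, config.adaptor_only_fraction))
    n_tag_reads = depth - n_adaptor
    counts = rng.multinomial(n_tag_reads, proportions)

    gene_of_read = np.repeat(np.arange(len(counts)), counts)
    reads = tags_3p[gene_of_read].copy()

    if config.alt_site_fraction > 0:
        offsets = np.concatenate([[0], np.cumsum(counts)])
        for g, sites in enumerate(all_sites):
            if len(sites) < 2 or counts[g] == 0:
                continue
            n_alt = int(rng.binomial(counts[g], config.alt_site_fraction))
            if n_alt == 0:
                continue
            rows = offsets[g] + rng.choice(counts[g], size=n_alt, replace=False)
            seq = str(bundle.transcripts[g].seq).upper()
            alt = rng.choice(len(sites) - 1, size=n_alt)  # among non-3'-most sites
            for row, a in zip(rows, alt):
                pos = sites[a]
                reads[row] = np.frombuffer(seq[pos:pos + TAG_LEN].encode(), dtype=np.uint8)

    # Per-base substitution errors (uniform over the three other bases).
    if config.error_rate > 0 and len(reads):
        mask = rng.random(reads.shape) < config.error_rate
        n_err = int(mask.sum())
        if n_err:
            base_idx = np.searchsorted(_BASES, reads[mask])
            shifted = (base_idx + rng.integers(1, 4, size=n_err)) % 4
            reads[mask] = _BASES[shifted]

    # A fraction of reads carry one undetermined base.
    if config.n_read_fraction > 0 and len(reads):
        k = int(rng.binomial(len(reads), config.n_read_fraction))
        if k:
            rows = rng.choice(len(reads), size=k, replace=False)
            cols = rng.integers(0, TAG_LEN, size=k)
            reads[rows, cols] = ord("N")

    out = [row.tobytes().decode("ascii") for row in reads]
    out.extend([DEFAULT_ADAPTOR] * n_adaptor)
    order = rng.permutation(len(out))
    return [out[i] for i in order]


def simulate_tag_libraries(
    config: SimConfig, bundle: ReferenceBundle
) -> tuple[LibraryPair, GroundTruth]:
    """Draw one mated/virgin library pair with known ground truth.

    Per-gene baseline abundances are log-normal (sigma =
    ``base_expression_dispersion``) and shared between conditions; the
    spiked genes' abundance is multiplied by ``2**de_log2fc`` in the
    "mated" condition.  Reads are the genes' 3'-most CATG+17 tags (an
    optional fraction from alternative upstream sites), with substitution
    errors, N bases and adaptor-only reads added per the config, each
    library totalling exactly ``library_depth`` reads.
    """
    config.validate()
    rng = _rng(config, 1)
    gene_ids = bundle.gene_ids
    tags_3p, all_sites = _gene_tag_matrix(bundle)

    base = rng.lognormal(mean=0.0, sigma=config.base_expression_dispersion, size=config.n_genes)
    # Spike-ins are drawn from genes holding at most ``max_spike_share`` of
    # the baseline library mass: the total spiked mass then stays small, so
    # boosting it leaves the relative abundance of unspiked genes nearly
    # unchanged and the ground-truth labels remain valid under
    # per-million (TPM) normalization of the fixed-depth libraries.
    shares = base / base.sum()
    if config.n_de_genes:
        eligible = np.nonzero(shares <= config.max_spike_share)[0]
        if len(eligible) < config.n_de_genes:
            eligible = np.argsort(shares)[: config.n_de_genes]
        de_idx = np.sort(rng.choice(eligible, size=config.n_de_genes, replace=False))
    else:
        de_idx = np.array([], dtype=int)
    mated = base.copy()
    mated[de_idx] *= 2.0 ** config.de_log2fc

    abundance = pd.DataFrame({"mated": mated, "virgin": base}, index=pd.Index(gene_ids, name="gene_id"))
    de_gene_ids = {gene_ids[i] for i in de_idx}
    truth = GroundTruth(
        abundance=abundance,
        de_gene_ids=de_gene_ids,
        true_log2fc={g: (config.de_log2fc if g in de_gene_ids else 0.0) for g in gene_ids},
    )

    mated_reads = _emit_library(rng, config, bundle, mated / mated.sum(), tags_3p, all_sites)
    virgin_reads = _emit_library(rng, config, bundle, base / base.sum(), tags_3p, all_sites)
    return LibraryPair(mated=mated_reads, virgin=virgin_reads), truth
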