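"""End-to-end orchestration: simulate -> clean -> map -> test -> enrich.

Reproduces the structure of a paired mated/virgin tag-profiling study:
one reference transcriptome, one library pair per time point (e.g. M1/V1,
M3/V3, M24/V24, M48/V48), per-library cleaning and mapping ledgers, one
Audic-Claverie comparison per pair with an up/down summary, and term
enrichment over each comparison's DE genes.  Given the same config and
seed the whole report bundle is byte-identical between runs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from tagdge._version import __version__
from tagdge.simulate import SimConfig, simulate_transcriptome, simulate_tag_libraries
from tagdge.preprocess import clean_tags, library_stats, copy_number_distribution
from tagdge.catalogue import build_catalogue, assign_tags, count_gene_tags
from tagdge.diffexpr import tpm_normalize, call_de
from tagdge.enrichment import enrich
from tagdge.io import write_fasta, write_reads

logger = logging.getLogger(__name__)

DEFAULT_COMPARISONS = ("M1:V1", "M3:V3", "M24:V24", "M48:V48")


@dataclass
class PipelineConfig:
    """Thresholds, comparisons and seeding for one full run.

    Each comparison names a mated and a virgin library ("M1:V1"); one
    library pair is simulated per comparison from a shared transcriptome.
    The significance knobs default to FDR < 0.001 with |log2 ratio| >= 1
    for differential calls and corrected P < 0.05 for enrichment.
    """

    outdir: Path
    sim: SimConfig = field(default_factory=SimConfig)
    comparisons: tuple[str, ...] = DEFAULT_COMPARISONS
    fdr_threshold: float = 0.001
    lfc_threshold: float = 1.0
    enrichment_alpha: float = 0.05
    pseudocount: float = 0.001
    tail: str = "doubled"
    seed: int = 0

    def validate(self) -> None:
        for knob in ("fdr_threshold", "lfc_threshold", "enrichment_alpha"):
            if getattr(self, knob) <= 0:
                raise ValueError(f"{knob} must be positive")
        for comp in self.comparisons:
            parts = comp.split(":")
            if len(parts) != 2 or not all(parts):
                raise ValueError(f"comparison {comp!r} must name two libraries as 'LIB1:LIB2'")
        self.sim.validate()

    def to_json(self, path: str | os.PathLike) -> None:
        payload = dataclasses.asdict(self)
        payload["outdir"] = str(self.outdir)
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | os.PathLike) -> "PipelineConfig":
        with open(path) as fh:
            payload = json.load(fh)
        sim_payload = payload.pop("sim", {})
        if "transcript_length_range" in sim_payload:
            sim_payload["transcript_length_range"] = tuple(sim_payload["transcript_length_range"])
        payload["comparisons"] = tuple(payload.get("comparisons", DEFAULT_COMPARISONS))
        return cls(outdir=Path(payload.pop("outdir")), sim=SimConfig(**sim_payload), **payload)


def _sha256(path: Path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            digest.update(chunk)
    return digest.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full analysis and write the report bundle to ``config.outdir``.

    Returns the manifest (also written as ``manifest.json``): package
    version, thresholds, per-stage tag ledgers, the per-comparison up/down
    summary, and a checksum of every written file.
    """
    config.validate()
    out = Path(config.outdir)
    for sub in ("reference", "reads", "truth", "clean", "stats", "de", "enrich"):
        (out / sub).mkdir(parents=True, exist_ok=True)

    # Independent, reproducible sub-seeds (kept below 2**31).
    state = np.random.SeedSequence(config.seed).generate_state(1 + len(config.comparisons))
    sub_seeds = [int(s % (2 ** 31)) for s in state]

    bundle = simulate_transcriptome(replace(config.sim, seed=sub_seeds[0]))
    write_fasta(bundle.transcripts, out / "reference" / "transcripts.fasta")
    write_fasta([bundle.genome], out / "reference" / "genome.fasta")
    bundle.annotation.to_csv(out / "reference" / "annotation.tsv", sep="\t", index=False)

    gene_cat = build_catalogue(bundle.transcripts, source="transcript")
    genome_cat = build_catalogue([bundle.genome], source="genome")
    logger.info(
        "reference: %d genes, %d distinct transcript tags, %d distinct genome tags",
        gene_cat.reference_gene_count, len(gene_cat), len(genome_cat),
    )

    config_echo = dataclasses.asdict(config)
    config_echo.pop("outdir", None)  # keep manifests path-independent
    manifest: dict = {
        "package_version": __version__,
        "config": json.loads(json.dumps(config_echo, default=str)),
        "reference": {
            "n_genes": gene_cat.reference_gene_count,
            "n_transcript_tags": len(gene_cat),
            "n_genome_tags": len(genome_cat),
        },
        "libraries": {},
        "comparisons": {},
    }

    summary_rows = []
    for comp, pair_seed in zip(config.comparisons, sub_seeds[1:]):
        lib_m, lib_v = comp.split(":")
        libraries, truth = simulate_tag_libraries(replace(config.sim, seed=pair_seed), bundle)
        truth.to_json(out / "truth" / f"{lib_m}_vs_{lib_v}.json")

        expr = {}
        for lib_id, reads in ((lib_m, libraries.mated), (lib_v, libraries.virgin)):
            write_reads(reads, out / "reads" / f"{lib_id}.txt")
            table = clean_tags(reads, library_id=lib_id)
            if table.clean_tag_total + sum(table.filter_ledger.values()) != table.raw_tag_total:
                raise RuntimeError(f"clean stage ledger does not balance for {lib_id}")
            table.to_tsv(out / "clean" / f"{lib_id}_tags.tsv")
            (out / "clean" / f"{lib_id}_stats.json").write_text(table.stats_json() + "\n")

            assignment = assign_tags(table, gene_cat, genome_cat)
            assignment.to_tsv(out / "stats" / f"{lib_id}_assignment.tsv", table)
            stats = library_stats(table, assignment)
            stats.to_tsv(out / "stats" / f"{lib_id}_library_stats.tsv")
            if table.distinct_clean_total:
                copy_number_distribution(table).to_csv(
                    out / "stats" / f"{lib_id}_copy_number.tsv", sep="\t", index=False
                )
            counts = count_gene_tags(assignment, table)
            expr[lib_id] = tpm_normalize(counts, table.clean_tag_total, library_id=lib_id)
            agg = assignment.aggregates
            logger.info(
                "%s: raw %d  clean %d  gene-mapped %d  genome %d  unknown %d",
                lib_id, table.raw_tag_total, table.clean_tag_total,
                agg["all_mapped_total"], agg["genome_total"], agg["unknown_total"],
            )
            logger.debug("%s filter ledger: %s", lib_id, table.filter_ledger)
            manifest["libraries"][lib_id] = {
                "raw_tag_total": table.raw_tag_total,
                "clean_tag_total": table.clean_tag_total,
                "distinct_clean_total": table.distinct_clean_total,
                "filter_ledger": table.filter_ledger,
                "aggregates": agg,
            }

        # log2 ratio is mated over virgin: expr1 = virgin, expr2 = mated.
        de_table, summary = call_de(
            expr[lib_v],
            expr[lib_m],
            fdr_threshold=config.fdr_threshold,
            lfc_threshold=config.lfc_threshold,
            pseudocount=config.pseudocount,
            tail=config.tail,
        )
        comp_name = f"{lib_m}_vs_{lib_v}"
        de_table.to_csv(out / "de" / f"{comp_name}.tsv", sep="\t", index=False)
        (out / "de" / f"{comp_name}_summary.json").write_text(
            json.dumps(summary, indent=1, sort_keys=True) + "\n"
        )
        de_genes = de_table.loc[de_table["call"] != "unchanged", "gene_id"].tolist()
        enrichment = enrich(bundle.annotation, de_genes, alpha=config.enrichment_alpha)
        enrichment.to_csv(out / "enrich" / f"{comp_name}.tsv", sep="\t", index=False)
        logger.info("%s: %d up, %d down of %d genes", comp_name, summary["n_up"], summary["n_down"], summary["n_total"])
        summary_rows.append((comp_name, summary["n_up"], summary["n_down"], summary["n_total"]))
        manifest["comparisons"][comp_name] = summary

    pd.DataFrame(summary_rows, columns=["comparison", "n_up", "n_down", "n_total"]).to_csv(
        out / "de_summary.tsv", sep="\t", index=False
    )

    checksums = {}
    for path in sorted(out.rglob("*")):
        if path.is_file() and path.name != "manifest.json":
            checksums[str(path.relative_to(out))] = _sha256(path)
    manifest["checksums"] = checksums
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True) + "\n")
    return manifest
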