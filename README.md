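# tagdge

Tag-based digital gene expression (DGE/SAGE) analysis in Python.

Before full-length RNA-seq became routine, transcriptomes were quantified
by counting short restriction-anchored cDNA tags: each mRNA is cut at its
3′-most **NlaIII** site (`CATG`), **MmeI** releases the 17 nt downstream,
and the resulting 21-bp tag is sequenced millions of times per library.
The number of times a tag is seen is a direct digital measurement of its
transcript's abundance.  `tagdge` implements the complete analysis stack
for this kind of experiment — for example paired "mated" vs "virgin"
*Bombyx mori* pheromone-gland libraries sampled at several time points —
together with a fully seeded synthetic-data generator, so every stage can
be exercised and calibrated without access to the original sequencing
runs.

## What it computes

1. **Clean-tag filtering** (`tagdge.preprocess`): raw reads are stripped of
   adaptor-only (empty) reads, reads containing `N`, reads that do not fit
   the `CATG`+17 anatomy, and distinct tags seen only once (likely
   sequencing errors).  Every removal is ledgered so `raw = clean +
   filtered` holds exactly, and per-library statistics (mapping
   percentages, copy-number distributions) are reported.
2. **Virtual tag mapping** (`tagdge.catalogue`): all possible `CATG`+17
   tags are enumerated from the reference transcripts (and genome).  Clean
   tags are assigned by an exact → one-mismatch ladder (mismatches allowed
   only in the 17 variable positions), tags matching several genes at the
   winning tier are set aside as ambiguous, and leftovers fall back to the
   genome catalogue before being declared unknown.
3. **Quantification and differential expression** (`tagdge.diffexpr`):
   per-gene unambiguous tag counts are scaled to transcripts per million
   clean tags, `TPM = 10^6 · x / N`, and two libraries are compared with
   the Audic–Claverie exact test.  For a gene with `x` tags among `N1` and
   `y` among `N2`, the conditional law

   p(y | x) = r^y (x+y)! / ( x! y! (1+r)^(x+y+1) ),  r = N2/N1

   is summed in log space (no normal approximation); the two-sided p-value
   doubles the smaller orientation tail and is exactly invariant under
   swapping the libraries.  Benjamini–Hochberg FDR and a fold-change
   threshold (defaults: FDR < 0.001, |log2 ratio| ≥ 1) yield up/down calls.
4. **Term enrichment** (`tagdge.enrichment`): DE gene sets are scored per
   GO/KO-style term by the hypergeometric upper tail
   `P = Σ_{i≥m} C(M,i)·C(N−M,n−i)/C(N,n)` with BH correction
   (significant at corrected P < 0.05 by default).
5. **qPCR quantification** (`tagdge.qpcr`): comparative-CT fold changes
   `2^−ΔΔCT` with housekeeping (rp49-style) normalization.
6. **Simulation** (`tagdge.simulate`): seeded generator for toy
   transcriptomes, genomes, annotation tables and paired tag libraries
   with spiked fold changes, substitution errors, `N` bases and
   adaptor-only reads — byte-identical output for identical configs.

A `click` CLI (`tagdge`) exposes each stage (`simulate`, `clean`,
`build-ref`, `assign`, `de`, `enrich`, `qpcr`, `stats`) and an end-to-end
`run-all` that writes a deterministic report bundle.

## Worked example

Simulate four paired mated/virgin libraries (200 genes, 100 000 tags per
library, 20 genes spiked four-fold in the mated condition) and run the
whole pipeline:

```sh
$ tagdge run-all --outdir run --seed 11 --n-genes 200 --depth 100000 --n-de-genes 20
M1_vs_V1: 16 up, 0 down (of 200)
M3_vs_V3: 15 up, 0 down (of 200)
M24_vs_V24: 16 up, 0 down (of 200)
M48_vs_V48: 19 up, 0 down (of 200)
```

Each comparison recovers most of the 20 spiked genes — the remainder are
spike-ins whose baseline expression is too low to reach significance at
this depth — and calls no unspiked gene.  `run/de/M1_vs_V1.tsv` holds the
per-gene table; the top up-calls for the first comparison look like

```text
gene_id   x    y        TPM1         TPM2  log2_ratio             p           fdr call
  G0013 737 2767 7486.565830 28116.489859    1.909040 1.980913e-274 1.941295e-272   up
  G0024 179  738 1818.311104  7499.085477    2.044115  1.816064e-81  8.898711e-80   up
  G0031   8   57   81.265301   579.197659    2.833329  1.780983e-10  2.053369e-09   up
```

where `x`/`y` are virgin/mated tag counts, TPM their per-million scaling,
and the log2 ratio is mated over virgin.  The bundle also contains
per-library ledgers (`stats/*_library_stats.tsv`), enrichment tables
(`enrich/*.tsv`), the ground truth of the simulation (`truth/*.json`) and
a checksummed `manifest.json`; rerunning with the same seed reproduces
every file byte for byte.

A qPCR check of a knockdown, from a CT table with `sample_id, gene_id,
replicate, ct, group` columns:

```sh
$ tagdge qpcr ct.tsv --target met1 --reference rp49 --treated treated --control control
fold_change=4 ddct=-2.0000 dct_treated=2.0000 dct_control=4.0000
```

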