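# Methods

This note records the models, conventions and design decisions behind
`tagdge`, in the spirit of a statistical-methods appendix.  Nothing here
states a number that the test suite or `scripts/acceptance.py` does not
itself compute.

## Tag anatomy and cleaning

A tag is the NlaIII anchor `CATG` plus the 17 nt that MmeI releases
downstream: 21 bp total.  Cleaning applies four filters in a fixed order:

1. *empty reads* — reads equal to the sequencing adaptor, or shorter than
   21 nt after trimming a leading adaptor.  "Empty" is read as
   adaptor-only because no other interpretation yields a tag;
2. *N-containing reads*;
3. *anatomy* — after adaptor trimming, the first 21 nt must start with
   `CATG` and contain only `ACGT`;
4. *copy-number-1 removal* — distinct tags observed exactly once are
   deleted together with their single occurrence (they are predominantly
   sequencing errors).  This runs **after** the read-level filters: a tag
   whose two copies are split between an intact and an N-containing read
   is a singleton only once the N copy is gone, and the ledger tests pin
   this order.

The filter ledger is conserved exactly: raw = clean + empty + N +
malformed + singleton occurrences.  Library percentages are reported as
shares of the clean-tag total (tag rows) or of the reference gene count
(gene rows), rounded half-up to two decimals — the rounding rule is
validated against the arithmetically consistent cells of the packaged
published eight-library ledger (see `tagdge.published`).  That ledger
contains half-integer distinct-tag counts (presumably lane averages in
the source); they are kept verbatim in the fixture, while this package's
own tables emit integers only.

The three mapping blocks (gene-mapped, genome-mapped, unknown) are
treated as a **partition** of clean tags: "mapped to gene" includes
ambiguous tags, "mapped to genome" means not gene-assignable but matching
a genome-derived tag, "unknown" is the rest.  The source ledger does not
state whether its blocks overlap; the partition is this package's
convention and is asserted in the pipeline.

## Virtual catalogue and assignment

The catalogue enumerates *every* `CATG` occurrence with ≥ 17 nt
downstream, per reference sequence, flagging the 3′-most site (the one
the protocol dominantly captures).  Assignment is a two-tier ladder:

* exact match against the transcript catalogue;
* else a one-mismatch match — substitutions are permitted only in the 17
  variable positions, never in the anchor, because a read without an
  intact `CATG` cannot have survived cleaning and the enzyme fixes the
  anchor biochemically;
* ambiguity (more than one gene) is judged within the winning tier only;
  exact matches are never displaced by one-mismatch candidates of other
  genes.  Multiple sites of the *same* gene are not ambiguous;
* unmatched tags are tried against the genome catalogue with the same
  ladder (genome-only), and the remainder is unknown.

Matching is sense-strand only, as tags derive from the mRNA 3′ end.
Assignment outcomes are independent of catalogue iteration order, and a
linear-scan brute-force matcher in the tests serves as the oracle for the
neighborhood logic.

## Quantification and the two-library exact test

Expression is transcripts per million clean tags, `TPM = 10^6 x / N` —
the historical tag-counting convention, *not* the length-normalized
RNA-seq TPM; no transcript-length correction applies because each
transcript contributes one dominant tag site.

Differential expression between two libraries uses the Audic–Claverie
conditional law: given `x` tags among `N1`, the count `y` among `N2`
follows

    p(y | x) = r^y (x+y)! / ( x! y! (1+r)^(x+y+1) ),   r = N2 / N1,

a negative-binomial distribution with `x+1` successes and success
probability `1/(1+r)`.  Tails are computed by direct log-space summation
of this pmf with a relative stopping tolerance of 1e-12; the smaller tail
is summed explicitly and the larger obtained from the exact complement,
so catastrophic cancellation cannot occur.  No normal approximation is
used anywhere.

**Two-sided construction.**  Doubling the smaller of P(Y≤y|x) and
P(Y≥y|x) — both tails conditioned on `x` — is *not* invariant under
swapping the libraries (numerically, p(5,15,N,N) ≈ 0.041 vs p(15,5,N,N)
≈ 0.027), because conditioning on x=5 and on x=15 are different
experiments.  A differential call must not depend on which library is
listed first, so the default (`tail="doubled"`) doubles the smaller of
the two *orientation-natural lower tails*, P(Y≤y|x) and P(X≤x|y), each
conditioning on the other library's count.  This is exactly
swap-invariant, agrees with the closed forms (x=y=0 at r=1 gives
p(0|0)=1/2 and a two-sided p of 1), and matches a big-rational oracle to
better than 1e-10 relative error over the tested grid.  The literal
x-conditioned form remains available as `tail="conditional"` and a
minimum-likelihood form as `tail="minlike"`.

Genes absent from both libraries are reported but not tested.  BH-FDR is
computed per comparison over the tested genes, and a gene is called up
(down) when FDR < 0.001 and log2 ratio ≥ 1 (≤ −1); both knobs are
configuration.  Where the source conventions state the threshold both as
"FDR < 0.001" and "p ≤ 0.001", the FDR form is taken as operative.  The
log2 ratio uses a pseudocount (default 0.001 TPM) so zero-count genes
stay finite without dominating the ranking.

## Enrichment

Term enrichment is the hypergeometric upper tail
`P(X ≥ m) = Σ_{i=m}^{min(n,M)} C(M,i) C(N−M, n−i) / C(N,n)` over a
universe of `N` annotated genes, `n` of them differentially expressed,
`M` per term and `m` DE per term, computed in log space from a cached
log-factorial table; `m = 0` gives P = 1 by the empty sum.  `m` counts
*DE* genes in the term — the only reading under which the formula is a
valid enrichment tail.  Correction is BH across terms for both GO-style
and KO-style annotations (the stated KO rule is an FDR, and using BH for
both keeps the two analyses consistent); significance defaults to
corrected P < 0.05.  Membership is flat: no ontology-graph ancestor
propagation, which the flat-count formula could not absorb anyway.

## qPCR

The comparative-CT method: ΔCT = mean CT(target) − mean CT(reference)
per group, ΔΔCT = ΔCT(treated) − ΔCT(control), fold change `2^−ΔΔCT`.
Replicates are averaged on the CT (cycle) scale, which makes the fold
change the geometric mean of the per-replicate fold changes that are
returned for dispersion estimates.  No amplification-efficiency
correction is applied (the pure `2^−ΔΔCT` form).  Exact properties —
reciprocity under group swap and invariance to a constant CT offset —
are asserted in the tests.

## Synthetic data generator

The generator emulates a paired-library tag-profiling study:

* **Transcriptome** — `n_genes` random `ACGT` transcripts, lengths
  uniform over `transcript_length_range` (minimum 25 nt so a tag site
  fits); a `CATG` anchor is force-written 21 nt before the 3′ end if the
  random sequence lacks a valid site.  The genome concatenates the
  transcripts with random 50–200 nt spacers.  Each gene gets 1–5 terms
  from a synthetic pool (one fifth as many terms as genes, minimum 10).
* **Abundance** — per-gene baselines are log-normal with sigma
  `base_expression_dispersion` (default 2), giving the long-tailed
  copy-number distribution typical of these libraries: most genes in a
  handful of copies, a few genes extremely abundant.
* **Differential structure** — `n_de_genes` spike-ins have their
  abundance multiplied by `2^de_log2fc` in the mated condition.
  Spike-ins are drawn only from genes holding at most `max_spike_share`
  (default 1%) of the baseline library mass.  Without this cap a
  heavy-tailed baseline occasionally places a library-dominating gene
  among the spike-ins; boosting it at fixed sequencing depth shifts the
  relative abundance of *every* other gene, so per-million-normalized
  calls contradict the per-gene truth labels.  Capping the spiked mass —
  standard practice in DE-benchmark simulators — keeps relative and
  absolute fold changes interchangeable for unspiked genes, which is the
  assumption the ground-truth labels encode.
* **Reads** — library counts are multinomial over gene proportions at
  fixed total depth (lane output is a design constant); each read is the
  gene's 3′-most tag (optionally, a configurable fraction from upstream
  sites to exercise multi-site code paths), with independent per-base
  substitution errors (no indels — tag length is fixed by construction),
  a fraction of reads carrying one `N`, and a fraction of adaptor-only
  reads.  Identical configs reproduce byte-identical output.

Default scale mirrors a deep study: 14 623 genes and 3.5 million tags
per library, with `error_rate = 0.001`, `n_read_fraction = 0.002` and
`adaptor_only_fraction = 0.002` chosen once so that ~98% of raw tags
survive cleaning and roughly half of the distinct raw tags are
error-derived singletons, the structure seen in published ledgers of
this library type.  The noise model is a stand-in — the original studies
do not state theirs — and the generator has no PCR-duplication model,
no quality-score realism and no paired-end structure.  Tests and the
acceptance script run a scaled-down copy of these conditions (200 genes,
100 000 tags per library, 20 spike-ins at log2 fold change 2), which
keeps every calibration run in seconds; passing them demonstrates
correctness and calibration of the machinery under the stated model, not
performance on real sequencing data.

## Calibration conventions

Null calibration simulates pairs with `de_log2fc = 0` and requires the
fraction of tested genes at p ≤ 0.001, pooled over ten seeded runs, to
stay below 0.005 (per-run fractions on ~200 genes are 0 or ~1/200 by
discreteness, so pooling is the meaningful statistic; residual
super-nominal behaviour reflects the error/singleton noise the test's
pure-multinomial null does not model).  Power requires ≥ 90% of
adequately covered spike-ins — expected mean count ≥ 50 across the two
libraries — to be called with the correct sign at FDR < 0.001, again
pooled over ten seeds, with at most two false calls among unspiked genes
per comparison.

## Pipeline determinism

All randomness flows from one seed through `numpy` `SeedSequence`
substreams (generator stage, per-pair libraries); outputs are written in
sorted order with fixed formats, and the manifest excludes paths and
timestamps, so two identically seeded runs produce byte-identical
bundles — asserted file-by-file via SHA-256 in the tests.

## Known limitations

* Single library per condition: no replicate-aware dispersion modelling
  (negative-binomial GLMs of modern RNA-seq are out of scope), so
  biological variability beyond counting noise is not captured.
* Antisense tags, spliced genome alignment and quality-aware trimming
  are not modelled; genome "mapping" is tag-catalogue membership, not
  read alignment.
* The published-ledger fixture can validate only arithmetic consistency
  (percentage rounding, totals); the underlying raw libraries were never
  deposited, so their headline DE counts are not reproducible and are
  not targeted.
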