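# Methods

## Data model and conventions

All coordinates inside the toolkit are 1-based inclusive, the convention of
the HapMap flat files and Ensembl.  UCSC tables are 0-based half-open; the
annotation loader converts on ingest (`txStart t → t+1`, ends unchanged),
which preserves interval lengths and is bijective on valid rows.  Chromosome
labels are stored verbatim and compared through a normaliser that equates
`2` and `chr2`.  Genotypes are normalised at the parse boundary: calls on
reverse-strand rows are complemented to the forward strand and the strand
field rewritten to `+`, so every downstream computation is strand-agnostic;
within a cell, alleles are stored in alphabetical order (`AG`, never `GA`).
Any genotype token containing `N` is treated as missing — the HapMap
convention is `NN`, and tolerant matching avoids silent data loss from
variants like `NA`.

The column layouts of the bulk dialects are declarative maps rather than
hard-coded offsets, because header tokens drifted between releases (e.g.
`QCcode` vs `QC_code`); the phase-2 and phase-3 layouts ship as named
dialects and callers may register more.

Frequency records always carry integer counts, and the stored frequencies
are recomputed as `count / total` so that the consistency invariants
(`ref_count + other_count = total_count`, frequencies summing to 1) are
exact integer arithmetic.  A printed frequency that disagrees with its
counts by more than 5e-3 (HapMap printed 3 decimals) rejects the row; a row
with `total_count = 0` is retained with zero frequencies and flagged
`monomorphic_no_data`, since dropping it would silently change interval
counts.

## The store

The cache is an embedded sqlite database behind a three-method backend
contract (execute / query / transaction); tables are partitioned by
(dataset kind, phase), a registry table records every ingested slice with
its source, row count and sha256, and genotype cells are stored as
2-character strings, which keeps the database trivially auditable against
the source files.  `ensure_available` is idempotent: a second call with the
same key performs no fetch and no re-ingest, leaving the database file
byte-identical.  Because the original distribution service is retired, the
default fetch strategy resolves keys against a local mirror directory with
a documented naming convention
(`{kind}_chr{chrom}_{POP}_phase{N}_b{build}.txt`; pedigrees are
per-population only); URL-template fetching and arbitrary fetcher callables
are opt-in.  Interval queries are inclusive at both endpoints and an
unavailable scope raises an availability error naming the known
populations — never a silently empty result.

## Gene annotation and builds

The knownGene table identifies transcripts, not gene symbols, so symbol
lookup goes through an optional two-column alias table (transcript id →
symbol), mirroring UCSC's companion cross-reference without requiring it.
When a gene has several transcripts, the pipeline collapses them with the
`longest-transcript` policy by default (a single deterministic interval,
ties broken by transcript id); a `union` policy (min start, max end, merged
exons) is available.  Build tags are resolved through an alias map
(36 ≡ hg18 ≡ ncbi_b36, 37 ≡ hg19 ≡ grch37, 38 ≡ hg38); a build mismatch is
always an error and never a lift-over, because coordinates are not
comparable across builds and silent coercion is the classic integration
mistake with these sources.

## Estimation

`wc_fst_locus` implements the Weir–Cockerham (1984) variance components for
a biallelic locus from per-population allele counts and observed
heterozygote counts, and `wc_fst_multilocus` aggregates by the ratio of
summed components.  Numerical choices:

* θ̂ is undefined (reported as `None`) exactly when a + b + c = 0 — e.g. a
  locus monomorphic in every sample — and when fewer than two populations
  carry any called individuals, or the mean sample size is ≤ 1;
* negative estimates are reported unmodified; clamping at zero would bias
  multi-locus sums;
* loci with more than two observed alleles are rejected with an error
  rather than silently recoded;
* populations with zero called individuals at a locus are dropped from
  that locus only.

An independent scalar transcription of the same component formulas lives in
`tests/_wc_reference.py` and the suite requires agreement to 1e-10 on
randomized count configurations, so the vectorised implementation and the
reference are two separate routes to the statistic.

Founder filtering drops every individual with a recorded parent — not only
trio offspring — because relatives violate the independence the estimator
assumes.  It is ON by default in the F<sub>ST</sub> pipeline and OFF in raw
frequency reports, which stay faithful to the files.

## The synthetic generator

`synthetic_data.SimSpec` fixes the study conditions for every fixture: per
SNP an ancestral frequency p ~ U(0.05, 0.95) (or a fixed list); per
population an allele frequency from the Balding–Nichols model,
Beta(p(1−F)/F, (1−p)(1−F)/F), under which the expected multi-locus θ̂
between populations is ≈ F; founder genotypes in Hardy–Weinberg
proportions; trio offspring by per-locus Mendelian transmission from two
designated founder parents; missing data i.i.d. over genotype cells.  All
randomness derives from the single spec seed through labelled child
generators, so emission is byte-deterministic.

Deliberate generator choices:

* frequency fixtures are computed from the realized founder non-missing
  genotype counts, not the latent frequencies, so cross-format consistency
  checks are exact equalities;
* the missing mask applies to genotype files only; phased fixtures carry
  the founders' complete haplotypes (the phased and genotype releases were
  distinct datasets), and the cross-format check compares collapsed
  haplotypes to genotype cells wherever a call exists;
* trio children are appended after founders with ids encoding family
  membership, making founder-filtering tests deterministic;
* LD fixtures are format-valid (bounds, ordering) but not model-derived —
  the toolkit ingests LD, it does not compute it;
* default conditions model the headline comparison this class of analysis
  was built for: two populations (CEU- and YRI-labelled) of 30 founders, 20
  SNPs in an LCT-sized window of chromosome 2, divergence F = 0.1, 2%
  missing data.

What passing tests on these fixtures do **not** show: real HapMap files
carry QC-flagged rows, monomorphic-no-data records, linkage structure
between loci and genotyping error, none of which the generator models
(QC codes are parsed and exposed but never filtered on; loci are simulated
independently).  Results on real files therefore depend on upstream QC in
ways the synthetic suite cannot certify.

## Problem sizes

The test and acceptance runs use desk-scale instances chosen to make every
check exact or statistically calibrated: round-trip suites over 20
randomized bundles of 5–20 SNPs and 1–3 populations; estimator/oracle
agreement over 1,000 random 2–5-population count configurations at 1e-10;
parameter recovery at F ∈ {0.01, 0.05, 0.1, 0.2} with 20 replicates of 200
loci × 2 populations × 50 founders, asserting the replicate mean lies
within 3 Monte-Carlo standard errors of F; 1,000 random intervals for the
coordinate converter and 100 for interval-query equivalence.

## Known limitations

CNV files, VCF import, live UCSC/Ensembl/NCBI connections, lift-over,
haplotype-based statistics, LD computation from genotypes, exact tests and
p-values are all out of scope.  The embedded backend is single-writer; no
schema-migration tooling is provided.  The `threshold` option of the gene
scan only annotates θ̂ above a user-supplied value (the literature's ≈0.45
rule of thumb for outlier candidates is one possible input); single-locus
θ̂ is noisy, and the toolkit deliberately renders no selection verdicts.
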