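# hapmapkit

A self-contained Python toolkit for HapMap-style population-genomics data.
The HapMap project catalogued human SNP variation across population samples
(phase 2: 4 populations; phase 3: 11) and distributed it as bulk
whitespace-separated flat files — genotype matrices, allele-frequency
tables, pairwise linkage-disequilibrium records, phased haplotypes and
linkage-style pedigree files — with no programmatic or relational
interface, and its download service is long retired.  hapmapkit gives that
class of data a clean local workflow:

* **formats** — parsers for the bulk flat-file dialects (phase-2/phase-3
  column layouts ship as named, user-extensible dialects), with strand
  normalisation to the forward strand and `NN`-style missing handling at
  the parse boundary;
* **store** — a download-once cache over an embedded sqlite database:
  each (kind, phase, population, chromosome) slice is ingested at most
  once from a local mirror directory (or an opt-in URL template) and all
  queries — including inclusive-interval SNP queries — run against the
  database; the backend is a three-method adapter, so an external
  relational engine can be plugged in;
* **annotation** — UCSC knownGene and Ensembl-style gene tables, with
  UCSC's 0-based half-open coordinates converted to the toolkit-wide
  1-based inclusive convention on ingest, and genome-build guards
  (`36`/`hg18` vs `37`/`hg19`) that refuse, never convert, mismatched
  builds;
* **popgen** — allele frequencies, trio founder filtering, Genepop export
  and import (2-digit-per-allele coding, missing = `0000`), and a native
  Weir–Cockerham (1984) θ estimator of F<sub>ST</sub>;
* **pipeline** — two end-to-end workflows: a per-gene F<sub>ST</sub> scan
  between two populations and a region allele-frequency report;
* **synthetic_data** — a generator of complete fixture bundles with known
  ground truth, so everything above is testable offline;
* **cli** — a `hapmapkit` command wrapping all of it with tab-separated
  output.

## The statistic

For a biallelic locus observed in *r* populations with sample sizes
*n<sub>i</sub>*, allele frequencies *p̂<sub>i</sub>* and observed
heterozygote proportions *ĥ<sub>i</sub>*, Weir & Cockerham's estimator
decomposes the allele-frequency variance into components *a* (among
populations), *b* (among individuals within populations) and *c* (between
gametes within individuals), and estimates

  θ̂ = a / (a + b + c).

Fixed differences give θ̂ = 1 exactly (equal sample sizes); a locus with no
variance anywhere has an undefined θ̂; slightly negative estimates are
legitimate and are never clamped.  Multi-locus estimates are the ratio of
summed components, Σa / Σ(a+b+c) — not the mean of per-locus ratios.
Because trio offspring duplicate parental chromosomes, the F<sub>ST</sub>
pipeline drops every individual with a recorded parent by default.

## Worked example

The classic use case: scan a gene for allele-frequency differentiation
between two populations (lactase persistence made LCT between CEU and YRI
the textbook example).  With a synthetic fixture standing in for the
retired download service:

```sh
hapmapkit gen-fixtures --spec spec.json --out mirror        # fixture bundle
hapmapkit ingest --cache cache --mirror mirror --kind genotype \
    --chromosome chr2 --population CEU --population YRI
hapmapkit ingest --cache cache --mirror mirror --kind pedigree \
    --population CEU --population YRI
hapmapkit fst-gene --cache cache --gene LCT \
    --population CEU --population YRI \
    --annotation knownGene.txt --aliases aliases.txt --build 36 \
    --genepop-out lct.gen
```

prints, on stdout (report) and stderr (summary):

```
snp_id	position	theta	in_exon
rs1000003	136556477	0.0821027499225743	False
rs1000004	136559603	0.11943707261118133	True
rs1000005	136561826	0.017857142857142856	True
rs1000006	136561880	-0.00687407169584834	True
...
LCT: 14 SNPs (14 defined, 0 skipped), multilocus theta 0.154908
```

One row per SNP inside the gene span, sorted by position: the per-locus θ̂
(negative values are sampling noise around zero) and whether the SNP falls
in an exon — exactly the columns needed to plot θ̂ along the gene with exon
boxes.  The multi-locus θ̂ summarises differentiation over the whole gene;
`lct.gen` is a Genepop file of the founder-filtered genotypes for use with
external population-genetics software.  Had the annotation been loaded for
build 37 while the genotypes are build 36, the scan would have aborted
before touching any data.

The frequency side of the API is one call (or `hapmapkit freq`):

```
snp_id	position	allele1	freq1	allele2	freq2	total_alleles
rs1000003	136556477	C	0.1	T	0.9	60
rs1000004	136559603	A	0.4	G	0.6	60
```

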