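"""The two end-to-end workflows: per-gene Fst scan and region frequency report.

``gene_fst_scan`` strings the toolkit together the way an analyst comparing
two populations over a candidate gene (the classic example being lactase
persistence: CEU vs YRI over LCT) would by hand:

1. guard that annotation and genotype data share a genome build,
2. resolve the gene to a single span and exon set,
3. load both populations' genotypes on that chromosome, windowed to the span,
4. drop trio offspring (founders only) unless told otherwise,
5. render a Genepop file as the interoperability side artifact,
6. compute per-locus and multi-locus Weir–Cockerham theta natively,
7. emit a plot-ready table of (snp, position, theta, exon membership).

The function is a pure composition of the module operations it names — its
report is reproducible by chaining those calls manually with the same
options.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .annotation import AnnotationSet, GeneModel, check_build_consistency, gene_span
from .errors import ArgumentError, AvailabilityError
from .popgen import (
    allele_counts,
    export_genepop,
    founders_only,
    wc_fst_locus,
    wc_fst_multilocus,
    FstResult,
)
from .store import HapmapStore


@dataclass
class GeneFstReport:
    """Plot-ready per-gene Fst scan."""

    gene_name: str
    chromosome: str
    start: int
    end: int
    exons: tuple[tuple[int, int], ...]
    populations: tuple[str, str]
    rows: list[tuple[str, int, float | None, bool]]  # (snp_id, position, theta, in_exon)
    multilocus_theta: float | None
    n_total: int
    n_defined: int
    n_skipped: int
    genepop_text: str = ""
    per_locus: list[FstResult] = field(default_factory=list)
    threshold: float | None = None

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.rows, columns=["snp_id", "position", "theta", "in_exon"]
        )
        if self.threshold is not None:
            df["above_threshold"] = df["theta"].gt(self.threshold).fillna(False)
        return df

    def to_tsv(self) -> str:
        df = self.to_frame()
        return df.to_csv(sep="\t", index=False, na_rep="UNDEFINED")


def _in_any_exon(position: int, exons) -> bool:
    return any(s <= position <= e for (s, e) in exons)


def gene_fst_scan(
    gene_name: str,
    pop1: str,
    pop2: str,
    annotation: AnnotationSet,
    store: HapmapStore,
    *,
    phase: int = 3,
    founders: bool = True,
    span_policy: str = "longest-transcript",
    genepop_path: str | Path | None = None,
    title: str | None = None,
    threshold: float | None = None,
) -> GeneFstReport:
    """Scan all SNPs of a gene for differentiation between two populations.

    Aborts with :class:`BuildMismatchError` before touching genotype data if
    the store's build for either population disagrees with the annotation
    build.  A gene span containing no SNPs yields an empty report (counts
    0/0/0, multilocus theta undefined), not an error.
    """
    models = annotation.find_gene(gene_name)
    chromosome, start, end, exons = gene_span(models, span_policy)

    # build guard before any data load (registry metadata only)
    for pop in (pop1, pop2):
        ds_build = store.dataset_build("genotype", phase, pop, chromosome)
        check_build_consistency(ds_build, annotation.build)

    tables = [
        store.get_genotypes(pop, chromosome, (start, end), phase=phase)
        for pop in (pop1, pop2)
    ]
    if founders:
        filtered = []
        for t in tables:
            try:
                pedigree = store.get_pedigree(t.population, phase=phase)
            except AvailabilityError:
                pedigree = []  # nothing recorded: everyone is a founder
            filtered.append(founders_only(t, pedigree))
        tables = filtered

    if tables[0].n_snps == 0:
        return GeneFstReport(
            gene_name=gene_name, chromosome=chromosome, start=start, end=end,
            exons=exons, populations=(tables[0].population, tables[1].population),
            rows=[], multilocus_theta=None, n_total=0, n_defined=0, n_skipped=0,
            genepop_text="", per_locus=[], threshold=threshold,
        )

    genepop_text = export_genepop(
        tables, title or f"{gene_name} {pop1}/{pop2} {chromosome}"
    )
    if genepop_path is not None:
        Path(genepop_path).write_text(genepop_text)

    counts = allele_counts(tables)
    per_locus = [wc_fst_locus(c) for c in counts]
    defined = [r for r in per_locus if r.defined]
    multilocus = wc_fst_multilocus(per_locus) if defined else None

    rows = [
        (r.snp.snp_id, r.snp.position, r.theta, _in_any_exon(r.snp.position, exons))
        for r in per_locus
    ]
    rows.sort(key=lambda row: row[1])
    return GeneFstReport(
        gene_name=gene_name,
        chromosome=chromosome,
        start=start,
        end=end,
        exons=exons,
        populations=(tables[0].population, tables[1].population),
        rows=rows,
        multilocus_theta=multilocus,
        n_total=len(per_locus),
        n_defined=len(defined),
        n_skipped=len(per_locus) - len(defined),
        genepop_text=genepop_text,
        per_locus=per_locus,
        threshold=threshold,
    )


def region_frequency_report(
    population: str,
    chromosome: str,
    start: int,
    end: int,
    store: HapmapStore,
    *,
    phase: int = 3,
) -> pd.DataFrame:
    """Allele frequencies of every SNP in a chromosome window.

    A thin view over the store's frequency query: one row per SNP in
    [start, end], sorted by position, with both alleles, their frequencies
    (recomputed exactly from counts) and the total called-allele count.
    """
    records = store.get_frequencies(population, chromosome, (start, end), phase=phase)
    return pd.DataFrame(
        [
            (
                r.snp.snp_id, r.snp.position,
                r.ref_allele, r.ref_freq,
                r.other_allele, r.other_freq,
                r.total_count,
            )
            for r in records
        ],
        columns=[
            "snp_id", "position", "allele1", "freq1", "allele2", "freq2",
            "total_alleles",
        ],
    )
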