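"""Population-genetic computation on genotype tables.

The centrepiece is the Weir & Cockerham (1984) theta estimator of Fst for a
biallelic locus, computed from its three variance components:

* ``a`` — variance among populations,
* ``b`` — variance among individuals within populations,
* ``c`` — variance between gametes within individuals,

with ``theta = a / (a + b + c)``.  Multi-locus estimates aggregate by the
ratio of summed components (sum of ``a`` over the sum of ``a + b + c``),
never by averaging per-locus ratios.  Negative per-locus estimates are
reported unmodified — clamping would bias multi-locus sums — and a locus
whose components sum to zero (e.g. monomorphic in every sample) has an
undefined theta, reported as ``None``.

The module also provides Genepop text export/import in the 2-digit-per-allele
coding (A=01, C=02, G=03, T=04; missing = 0000), the interoperability surface
towards the wider population-genetics software ecosystem, and founder
filtering for the HapMap populations sampled as mother-father-offspring
trios, whose offspring violate the independence the estimator assumes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .errors import (
    AlignmentError,
    ArgumentError,
    IntegrityError,
    ParseError,
    UndefinedResultError,
    UnsupportedDialectError,
)
from .formats import (
    MISSING,
    GenotypeTable,
    PedigreeRecord,
    SnpMeta,
    normalize_call,
    open_text,
)

# Genepop allele coding.
ALLELE_CODES = {"A": "01", "C": "02", "G": "03", "T": "04"}
CODE_ALLELES = {v: k for k, v in ALLELE_CODES.items()}
GENEPOP_MISSING = "0000"


# ---------------------------------------------------------------------------
# allele frequencies and founder filtering
# ---------------------------------------------------------------------------


def allele_frequencies(
    table: GenotypeTable,
) -> list[tuple[SnpMeta, float, float, int]]:
    """Per-SNP frequencies of the SNP's two alleles.

    Missing calls are excluded from denominators.  Returns, per SNP,
    ``(snp, freq_allele1, freq_allele2, called_alleles)``; a SNP with zero
    calls is flagged by ``called_alleles == 0`` (frequencies reported as 0).
    """
    if table.n_samples < 1:
        raise ArgumentError("genotype table has no samples")
    out = []
    for i, snp in enumerate(table.snps):
        a1, a2 = snp.alleles
        n1 = n2 = 0
        for call in table.calls[i]:
            if call == MISSING:
                continue
            n1 += call.count(a1)
            n2 += call.count(a2)
        total = n1 + n2
        if total:
            out.append((snp, n1 / total, n2 / total, total))
        else:
            out.append((snp, 0.0, 0.0, 0))
    return out


def founders_only(
    table: GenotypeTable, pedigree: Sequence[PedigreeRecord]
) -> GenotypeTable:
    """Drop every individual with a recorded parent.

    Individuals absent from the pedigree are treated as founders, so an
    empty pedigree returns the table unchanged.
    """
    with_parent = {r.individual_id for r in pedigree if r.has_recorded_parent}
    keep = [sid for sid in table.sample_ids if sid not in with_parent]
    if len(keep) == table.n_samples:
        return table
    return table.select_samples(keep)


# ---------------------------------------------------------------------------
# Genepop export / import
# ---------------------------------------------------------------------------


def _encode_call(call: str, alleles: tuple[str, str], snp_id: str) -> str:
    if call == MISSING:
        return GENEPOP_MISSING
    codes = sorted(ALLELE_CODES[c] for c in call)
    return codes[0] + codes[1]


def export_genepop(tables: Sequence[GenotypeTable], title: str) -> str:
    """Render one or more populations as Genepop text.

    Line 1 is the title; then one locus (rs id) per line; then, per
    population, a ``Pop`` line followed by ``sampleid ,  XXYY...`` rows.
    Alleles are coded A=01, C=02, G=03, T=04 (emitted in sorted code order
    within a genotype); missing calls become ``0000``.
    """
    if not tables:
        raise ArgumentError("no genotype tables to export")
    ref = [s.snp_id for s in tables[0].snps]
    for t in tables[1:]:
        ids = [s.snp_id for s in t.snps]
        if ids != ref:
            diff = sorted(set(ids) ^ set(ref))
            raise AlignmentError(
                f"populations do not share a SNP list; symmetric difference: {diff}"
            )
    lines = [title]
    lines.extend(ref)
    for t in tables:
        lines.append("Pop")
        for j, sid in enumerate(t.sample_ids):
            tokens = [
                _encode_call(t.calls[i, j], t.snps[i].alleles, t.snps[i].snp_id)
                for i in range(t.n_snps)
            ]
            lines.append(f"{sid} ,  " + " ".join(tokens))
    return "\n".join(lines) + "\n"


def parse_genepop(source) -> list[GenotypeTable]:
    """Parse 4-digit-genotype Genepop text back into genotype tables.

    Locus names become rs ids; Genepop carries no locus coordinates, so
    SNP metadata is synthesised (chromosome ``chrUn``, position = locus
    rank).  Populations are named ``POP1``, ``POP2``, ... in file order.
    """
    stream = open_text(source)
    lines = [ln.rstrip("\n") for ln in stream]
    if not lines:
        raise ParseError("empty Genepop stream")
    title = lines[0]
    loci: list[str] = []
    idx = 1
    while idx < len(lines) and lines[idx].strip().lower() != "pop":
        name = lines[idx].strip()
        if name:
            if "," in name:
                loci.extend(x.strip() for x in name.split(",") if x.strip())
            else:
                loci.append(name)
        idx += 1
    if not loci:
        raise ParseError("Genepop file declares no loci")
    if idx >= len(lines):
        raise ParseError('missing "Pop" line')

    pops: list[list[tuple[str, list[str]]]] = []
    current: list[tuple[str, list[str]]] | None = None
    for lineno, line in enumerate(lines[idx:], start=idx + 1):
        if not line.strip():
            continue
        if line.strip().lower() == "pop":
            current = []
            pops.append(current)
            continue
        if current is None:
            raise ParseError(f'line {lineno}: sample row before any "Pop" line')
        if "," not in line:
            raise ParseError(f"line {lineno}: malformed sample row (no comma)")
        sid, geno_part = line.split(",", 1)
        tokens = geno_part.split()
        if len(tokens) != len(loci):
            raise ParseError(
                f"line {lineno}: expected {len(loci)} genotype tokens, "
                f"found {len(tokens)}"
            )
        for tok in tokens:
            if len(tok) in (2, 6):
                raise UnsupportedDialectError(
                    f"line {lineno}: token {tok!r} is not the 2-digit-per-allele "
                    "(4-character) genotype coding"
                )
            if len(tok) != 4 or not tok.isdigit():
                raise ParseError(f"line {lineno}: malformed genotype token {tok!r}")
        current.append((sid.strip(), tokens))

    # Decode allele pairs per locus from the observed codes.
    observed: list[set[str]] = [set() for _ in loci]
    for pop in pops:
        for _, tokens in pop:
            for i, tok in enumerate(tokens):
                for code in (tok[:2], tok[2:]):
                    if code != "00":
                        if code not in CODE_ALLELES:
                            raise ParseError(f"unknown allele code {code!r} at locus {loci[i]}")
                        observed[i].add(CODE_ALLELES[code])
    padding = ("A", "C", "G", "T")
    snps: list[SnpMeta] = []
    for i, name in enumerate(loci):
        obs = sorted(observed[i])
        if len(obs) > 2:
            raise ParseError(f"locus {name}: more than two alleles observed")
        while len(obs) < 2:
            obs.append(next(p for p in padding if p not in obs))
        snps.append(
            SnpMeta(
                snp_id=name,
                chromosome="chrUn",
                position=i + 1,
                strand="+",
                alleles=(obs[0], obs[1]),
            )
        )

    tables: list[GenotypeTable] = []
    for p, pop in enumerate(pops, start=1):
        sample_ids = [sid for sid, _ in pop]
        calls = np.full((len(loci), len(sample_ids)), MISSING, dtype="U2")
        for j, (_, tokens) in enumerate(pop):
            for i, tok in enumerate(tokens):
                if tok == GENEPOP_MISSING:
                    continue
                c1, c2 = tok[:2], tok[2:]
                if "00" in (c1, c2):
                    raise ParseError(
                        f"locus {loci[i]}: half-missing genotype {tok!r} unsupported"
                    )
                calls[i, j] = normalize_call(CODE_ALLELES[c1] + CODE_ALLELES[c2])
        tables.append(
            GenotypeTable(
                population=f"POP{p}",
                build="",
                sample_ids=sample_ids,
                snps=list(snps),
                calls=calls,
            )
        )
    if not tables:
        raise ParseError('missing "Pop" line')
    # keep the title reachable for round-trip checks
    for t in tables:
        t.title = title  # type: ignore[attr-defined]
    return tables


# ---------------------------------------------------------------------------
# Weir-Cockerham theta
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PopCounts:
    """Genotype summary of one population at one locus."""

    n_allele1: int
    n_allele2: int
    n_heterozygotes: int
    n_called: int

    def __post_init__(self):
        if self.n_allele1 + self.n_allele2 != 2 * self.n_called:
            raise IntegrityError(
                f"allele counts {self.n_allele1}+{self.n_allele2} != "
                f"2 x {self.n_called} called individuals"
            )
        if self.n_heterozygotes > self.n_called:
            raise IntegrityError("more heterozygotes than called individuals")


@dataclass(frozen=True)
class AlleleCounts:
    """Per-population genotype summaries for one SNP."""

    snp: SnpMeta
    per_pop: dict[str, PopCounts]


@dataclass(frozen=True)
class FstResult:
    """Weir-Cockerham variance components and theta for one locus."""

    snp: SnpMeta
    a: float
    b: float
    c: float
    theta: float | None

    @property
    def defined(self) -> bool:
        return self.theta is not None


def allele_counts(tables: Sequence[GenotypeTable]) -> list[AlleleCounts]:
    """Summarise aligned genotype tables into per-locus allele counts.

    Tables must share their SNP list.  Loci with more than two observed
    alleles across all populations are rejected — HapMap SNPs are biallelic
    and silent multi-allelic handling invites coding bugs.
    """
    if not tables:
        raise ArgumentError("no genotype tables")
    ref = [(s.snp_id, s.alleles) for s in tables[0].snps]
    for t in tables[1:]:
        if [(s.snp_id, s.alleles) for s in t.snps] != ref:
            diff = sorted({s.snp_id for s in t.snps} ^ {s.snp_id for s in tables[0].snps})
            raise AlignmentError(
                f"populations do not share a SNP list; symmetric difference: {diff}"
            )
    out: list[AlleleCounts] = []
    for i, snp in enumerate(tables[0].snps):
        a1, a2 = snp.alleles
        per_pop: dict[str, PopCounts] = {}
        for t in tables:
            n1 = n2 = het = called = 0
            for call in t.calls[i]:
                if call == MISSING:
                    continue
                for c in call:
                    if c == a1:
                        n1 += 1
                    elif c == a2:
                        n2 += 1
                    else:
                        raise IntegrityError(
                            f"{snp.snp_id}: allele {c!r} outside pair {a1}/{a2} "
                            "(more than two alleles observed)"
                        )
                called += 1
                if call[0] != call[1]:
                    het += 1
            per_pop[t.population] = PopCounts(n1, n2, het, called)
        out.append(AlleleCounts(snp=snp, per_pop=per_pop))
    return out


def wc_fst_locus(counts: AlleleCounts) -> FstResult:
    """Weir-Cockerham variance components and theta for one biallelic locus.

    With r populations of sample size n_i, allele-1 frequency p_i and
    observed heterozygote proportion h_i, the components use the weighted
    means n-bar, p-bar, h-bar, the squeezed sample size n_c and the
    among-population variance s^2.  Populations with no called individuals
    are dropped; if fewer than two populations carry data, or every term
    vanishes, theta is undefined (None).  Negative estimates are returned
    as-is.
    """
    if len(counts.per_pop) < 2:
        raise ArgumentError(
            f"{counts.snp.snp_id}: Fst needs >= 2 populations, got {len(counts.per_pop)}"
        )
    pops = [pc for pc in counts.per_pop.values() if pc.n_called > 0]
    undefined = FstResult(snp=counts.snp, a=0.0, b=0.0, c=0.0, theta=None)
    r = len(pops)
    if r < 2:
        return undefined
    n = np.array([pc.n_called for pc in pops], dtype=float)
    p = np.array([pc.n_allele1 / (2.0 * pc.n_called) for pc in pops])
    h = np.array([pc.n_heterozygotes / pc.n_called for pc in pops])

    n_total = n.sum()
    nbar = n_total / r
    if nbar <= 1.0:
        return undefined
    nc = (n_total - (n * n).sum() / n_total) / (r - 1.0)
    if nc == 0.0:
        return undefined
    pbar = float((n * p).sum() / n_total)
    s2 = float((n * (p - pbar) ** 2).sum() / ((r - 1.0) * nbar))
    hbar = float((n * h).sum() / n_total)

    a = (nbar / nc) * (
        s2 - (pbar * (1.0 - pbar) - (r - 1.0) / r * s2 - hbar / 4.0) / (nbar - 1.0)
    )
    b = (nbar / (nbar - 1.0)) * (
        pbar * (1.0 - pbar) - (r - 1.0) / r * s2 - (2.0 * nbar - 1.0) / (4.0 * nbar) * hbar
    )
    c = hbar / 2.0
    denom = a + b + c
    theta = a / denom if denom != 0.0 else None
    return FstResult(snp=counts.snp, a=a, b=b, c=c, theta=theta)


def wc_fst_multilocus(results: Iterable[FstResult]) -> float:
    """Multi-locus theta: ratio of summed components over defined loci.

    theta = sum(a) / sum(a + b + c), NOT the mean of per-locus ratios.
    """
    results = list(results)
    if not results:
        raise ArgumentError("no per-locus results")
    defined = [r for r in results if r.defined]
    if not defined:
        raise UndefinedResultError("theta undefined at every locus")
    num = math.fsum(r.a for r in defined)
    den = math.fsum(r.a + r.b + r.c for r in defined)
    if den == 0.0:
        raise UndefinedResultError("variance components sum to zero across loci")
    return num / den
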