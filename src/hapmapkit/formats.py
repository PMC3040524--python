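"""Readers for the HapMap bulk-release flat-file dialects.

The HapMap project distributed its catalogue as whitespace-separated text
files — per-chromosome genotype matrices, allele-frequency tables, pairwise
linkage-disequilibrium records, phased haplotypes and linkage-style pedigree
(sample-info) files.  The project never shipped a formal schema, and header
tokens drifted between the phase-2 and phase-3 releases, so every parser here
is driven by a *dialect*: a declarative column map.  The documented phase-2
and phase-3 layouts ship as named dialects and users may register their own.

Conventions applied uniformly at the parse boundary:

* all positions are 1-based inclusive;
* genotypes on the ``-`` strand are complemented to the forward strand at
  parse time and the strand field rewritten to ``+``, so downstream
  frequency and Fst code never needs to think about strand;
* any genotype token containing an ``N`` maps to :data:`MISSING`;
* chromosome labels are stored verbatim but compared through
  :func:`normalize_chromosome`, which equates ``"2"`` and ``"chr2"``.

All parsers accept either a filesystem path (``str`` / ``Path``, gzip
transparently handled via a ``.gz`` suffix) or an open text stream.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np

from .errors import ArgumentError, IntegrityError, ParseError

#: Sentinel stored for a genotype call with no data.
MISSING = "NN"

NUCLEOTIDES = ("A", "C", "G", "T")

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

#: Strand tokens accepted on input; the ASCII hyphen and the typographic
#: minus both denote the reverse strand.
_MINUS_TOKENS = {"-", "−"}
_PLUS_TOKENS = {"+"}


def complement_allele(allele: str) -> str:
    try:
        return _COMPLEMENT[allele]
    except KeyError:
        raise ArgumentError(f"not a nucleotide symbol: {allele!r}") from None


def normalize_chromosome(label: str) -> str:
    """Canonical chromosome key: strips a ``chr`` prefix, upper-cases."""
    s = str(label).strip()
    if s.lower().startswith("chr"):
        s = s[3:]
    return s.upper()


def _chromosome_sort_key(label: str):
    norm = normalize_chromosome(label)
    return (0, int(norm), "") if norm.isdigit() else (1, 0, norm)


def normalize_call(call: str) -> str:
    """Canonical unordered genotype: alleles in alphabetical order."""
    if call == MISSING:
        return MISSING
    return "".join(sorted(call))


def open_text(source) -> io.TextIOBase:
    """Open ``source`` (path or stream) for reading text."""
    if isinstance(source, (str, Path)):
        path = Path(source)
        if path.suffix == ".gz":
            return io.TextIOWrapper(gzip.open(path, "rb"), encoding="utf-8")
        return open(path, "rt", encoding="utf-8")
    return source


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SnpMeta:
    """Identity of one SNP: rs id, locus, strand, allele pair, QC code."""

    snp_id: str
    chromosome: str
    position: int
    strand: str = "+"
    alleles: tuple[str, str] = ("A", "C")
    qc_code: str = ""

    def __post_init__(self):
        if self.position < 1:
            raise ArgumentError(f"{self.snp_id}: position must be >= 1, got {self.position}")
        if self.strand in _MINUS_TOKENS:
            object.__setattr__(self, "strand", "-")
        if self.strand not in ("+", "-"):
            raise ArgumentError(f"{self.snp_id}: strand must be + or -, got {self.strand!r}")
        a1, a2 = self.alleles
        if a1 == a2:
            raise ArgumentError(f"{self.snp_id}: alleles must be distinct, got {self.alleles}")
        for a in (a1, a2):
            if a not in NUCLEOTIDES:
                raise ArgumentError(f"{self.snp_id}: unknown allele symbol {a!r}")


@dataclass
class GenotypeTable:
    """Diploid calls for one population on one chromosome.

    ``calls`` is an ``(n_snps, n_samples)`` array of 2-character strings;
    each cell is an unordered allele pair in alphabetical order, or
    :data:`MISSING`.  SNPs are sorted by (chromosome, position).
    """

    population: str
    build: str
    sample_ids: list[str]
    snps: list[SnpMeta]
    calls: np.ndarray

    def __post_init__(self):
        self.calls = np.asarray(self.calls, dtype="U2").reshape(
            len(self.snps), len(self.sample_ids)
        )

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def restrict(self, start: int, end: int) -> "GenotypeTable":
        """Sub-table with SNPs whose position lies in [start, end] inclusive."""
        if start > end:
            raise ArgumentError(f"inverted interval: start {start} > end {end}")
        keep = [i for i, s in enumerate(self.snps) if start <= s.position <= end]
        return GenotypeTable(
            population=self.population,
            build=self.build,
            sample_ids=list(self.sample_ids),
            snps=[self.snps[i] for i in keep],
            calls=self.calls[keep, :] if keep else np.empty((0, self.n_samples), dtype="U2"),
        )

    def select_samples(self, sample_ids: Sequence[str]) -> "GenotypeTable":
        wanted = set(sample_ids)
        keep = [j for j, sid in enumerate(self.sample_ids) if sid in wanted]
        return GenotypeTable(
            population=self.population,
            build=self.build,
            sample_ids=[self.sample_ids[j] for j in keep],
            snps=list(self.snps),
            calls=self.calls[:, keep] if keep else np.empty((self.n_snps, 0), dtype="U2"),
        )


@dataclass(frozen=True)
class FrequencyRecord:
    """Reference/other allele frequencies and counts for one SNP."""

    snp: SnpMeta
    ref_allele: str
    ref_freq: float
    ref_count: int
    other_allele: str
    other_freq: float
    other_count: int
    total_count: int

    def __post_init__(self):
        if self.ref_count + self.other_count != self.total_count:
            raise IntegrityError(
                f"{self.snp.snp_id}: ref_count {self.ref_count} + other_count "
                f"{self.other_count} != total_count {self.total_count}"
            )
        for f in (self.ref_freq, self.other_freq):
            if not (0.0 <= f <= 1.0):
                raise ParseError(f"{self.snp.snp_id}: frequency {f} outside [0, 1]")

    @property
    def monomorphic_no_data(self) -> bool:
        return self.total_count == 0


@dataclass(frozen=True)
class LdRecord:
    """One pairwise linkage-disequilibrium measurement."""

    pos1: int
    pos2: int
    population: str
    snp_id1: str
    snp_id2: str
    d_prime: float
    r_squared: float
    lod: float

    def __post_init__(self):
        if not self.pos1 < self.pos2:
            raise ParseError(
                f"{self.snp_id1}/{self.snp_id2}: pos1 {self.pos1} must be < pos2 {self.pos2}"
            )
        if not (0.0 <= self.d_prime <= 1.0):
            raise ParseError(f"{self.snp_id1}/{self.snp_id2}: D' {self.d_prime} outside [0, 1]")
        if not (0.0 <= self.r_squared <= 1.0):
            raise ParseError(f"{self.snp_id1}/{self.snp_id2}: r^2 {self.r_squared} outside [0, 1]")


@dataclass(frozen=True)
class PedigreeRecord:
    """One individual in a linkage-style sample-info file."""

    family_id: str
    individual_id: str
    father_id: str | None
    mother_id: str | None
    sex: str  # "male" | "female" | "unknown"
    population: str

    @property
    def is_offspring(self) -> bool:
        return self.father_id is not None and self.mother_id is not None

    @property
    def has_recorded_parent(self) -> bool:
        return self.father_id is not None or self.mother_id is not None


@dataclass
class PhasedHaplotypes:
    """Phased single-allele matrix: two haplotype rows per individual.

    ``haplotypes`` has shape ``(2 * n_samples, n_snps)``; rows ``2i`` and
    ``2i + 1`` belong to ``sample_ids[i]`` (labelled A and B in the file
    header).
    """

    population: str
    build: str
    sample_ids: list[str]
    snps: list[SnpMeta]
    haplotypes: np.ndarray

    def __post_init__(self):
        self.haplotypes = np.asarray(self.haplotypes, dtype="U1").reshape(
            2 * len(self.sample_ids), len(self.snps)
        )

    def collapse(self) -> GenotypeTable:
        """Fold each individual's two haplotypes into unordered genotypes."""
        n_snps, n_samples = len(self.snps), len(self.sample_ids)
        calls = np.empty((n_snps, n_samples), dtype="U2")
        for j in range(n_samples):
            for i in range(n_snps):
                calls[i, j] = normalize_call(
                    self.haplotypes[2 * j, i] + self.haplotypes[2 * j + 1, i]
                )
        return GenotypeTable(
            population=self.population,
            build=self.build,
            sample_ids=list(self.sample_ids),
            snps=list(self.snps),
            calls=calls,
        )


# ---------------------------------------------------------------------------
# dialects
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GenotypeDialect:
    """Column map for a HapMap genotype bulk file.

    ``meta_columns`` is the ordered tuple of fixed metadata column headers;
    sample-id columns follow.  The ``*_col`` fields name the semantic columns
    inside ``meta_columns``.
    """

    name: str
    meta_columns: tuple[str, ...]
    rs_col: str = "rs#"
    alleles_col: str = "alleles"
    chrom_col: str = "chrom"
    pos_col: str = "pos"
    strand_col: str = "strand"
    build_col: str = "assembly#"
    qc_col: str = "QCcode"

    def index(self, col: str) -> int:
        return self.meta_columns.index(col)


@dataclass(frozen=True)
class FrequencyDialect:
    name: str
    columns: tuple[str, ...]
    rs_col: str = "rs#"
    chrom_col: str = "chrom"
    pos_col: str = "pos"
    strand_col: str = "strand"
    build_col: str = "build"
    qc_col: str = "QC_code"
    ref_allele_col: str = "refallele"
    ref_freq_col: str = "refallele_freq"
    ref_count_col: str = "refallele_count"
    other_allele_col: str = "otherallele"
    other_freq_col: str = "otherallele_freq"
    other_count_col: str = "otherallele_count"
    total_col: str = "totalcount"

    def index(self, col: str) -> int:
        return self.columns.index(col)


_P3_GENO_META = (
    "rs#", "alleles", "chrom", "pos", "strand", "assembly#",
    "center", "protLSID", "assayLSID", "panelLSID", "QCcode",
)
_P2_GENO_META = _P3_GENO_META[:-1] + ("QC_code",)

PHASE3_GENOTYPE = GenotypeDialect(name="phase3", meta_columns=_P3_GENO_META)
PHASE2_GENOTYPE = GenotypeDialect(name="phase2", meta_columns=_P2_GENO_META, qc_col="QC_code")

_FREQ_COLUMNS = (
    "rs#", "chrom", "pos", "strand", "build", "center",
    "protLSID", "assayLSID", "panelLSID", "QC_code",
    "refallele", "refallele_freq", "refallele_count",
    "otherallele", "otherallele_freq", "otherallele_count", "totalcount",
)
PHASE3_FREQUENCY = FrequencyDialect(name="phase3", columns=_FREQ_COLUMNS)
PHASE2_FREQUENCY = FrequencyDialect(name="phase2", columns=_FREQ_COLUMNS)

#: User-extensible dialect registries, keyed by name.
GENOTYPE_DIALECTS: dict[str, GenotypeDialect] = {
    "phase2": PHASE2_GENOTYPE,
    "phase3": PHASE3_GENOTYPE,
}
FREQUENCY_DIALECTS: dict[str, FrequencyDialect] = {
    "phase2": PHASE2_FREQUENCY,
    "phase3": PHASE3_FREQUENCY,
}


def _resolve(dialect, registry, cls):
    if isinstance(dialect, cls):
        return dialect
    try:
        return registry[dialect]
    except KeyError:
        raise ArgumentError(
            f"unknown dialect {dialect!r}; known: {sorted(registry)}"
        ) from None


# ---------------------------------------------------------------------------
# parsers
# ---------------------------------------------------------------------------


def _is_missing_token(token: str) -> bool:
    return "N" in token.upper()


def parse_genotype_file(
    source,
    dialect: GenotypeDialect | str = "phase3",
    *,
    population: str = "",
    build: str | None = None,
) -> GenotypeTable:
    """Parse a HapMap genotype bulk file into a :class:`GenotypeTable`.

    Reverse-strand rows are complemented to the forward strand; missing
    tokens (anything containing ``N``) become :data:`MISSING`; rows are
    sorted by (chromosome, position).  The population code is not recorded
    inside HapMap genotype files (it lives in the file name), so it is passed
    by the caller; ``build`` defaults to the file's assembly column.
    """
    d = _resolve(dialect, GENOTYPE_DIALECTS, GenotypeDialect)
    n_meta = len(d.meta_columns)
    stream = open_text(source)
    header = stream.readline()
    if not header.strip():
        raise ParseError("genotype file has no header row")
    header_tokens = header.split()
    if len(header_tokens) < n_meta:
        raise ParseError(
            f"genotype header has {len(header_tokens)} columns; "
            f"dialect {d.name!r} expects at least {n_meta} metadata columns"
        )
    sample_ids = header_tokens[n_meta:]
    width = n_meta + len(sample_ids)

    i_rs, i_all = d.index(d.rs_col), d.index(d.alleles_col)
    i_chr, i_pos = d.index(d.chrom_col), d.index(d.pos_col)
    i_str, i_bld, i_qc = d.index(d.strand_col), d.index(d.build_col), d.index(d.qc_col)

    snps: list[SnpMeta] = []
    rows: list[list[str]] = []
    seen: set[str] = set()
    file_build = build
    for lineno, line in enumerate(stream, start=2):
        if not line.strip():
            continue
        tokens = line.split()
        if len(tokens) != width:
            raise ParseError(
                f"line {lineno}: expected {width} columns, found {len(tokens)}"
            )
        rs = tokens[i_rs]
        if rs in seen:
            raise ParseError(f"line {lineno}: duplicate rs id {rs}")
        seen.add(rs)
        try:
            a1, a2 = tokens[i_all].split("/")
        except ValueError:
            raise ParseError(
                f"line {lineno}: malformed allele pair {tokens[i_all]!r}"
            ) from None
        strand = tokens[i_str]
        minus = strand in _MINUS_TOKENS
        if not minus and strand not in _PLUS_TOKENS:
            raise ParseError(f"line {lineno}: unknown strand token {strand!r}")
        if minus:
            a1, a2 = complement_allele(a1), complement_allele(a2)
        for a in (a1, a2):
            if a not in NUCLEOTIDES:
                raise ParseError(f"line {lineno}: unknown allele symbol {a!r}")
        try:
            pos = int(tokens[i_pos])
        except ValueError:
            raise ParseError(f"line {lineno}: unparseable position {tokens[i_pos]!r}") from None
        snp = SnpMeta(
            snp_id=rs,
            chromosome=tokens[i_chr],
            position=pos,
            strand="+",
            alleles=(a1, a2),
            qc_code=tokens[i_qc],
        )
        if file_build is None:
            file_build = tokens[i_bld]
        allowed = {a1, a2}
        calls: list[str] = []
        for tok in tokens[n_meta:]:
            if _is_missing_token(tok):
                calls.append(MISSING)
                continue
            if len(tok) != 2:
                raise ParseError(f"line {lineno}: malformed genotype token {tok!r}")
            g1, g2 = tok[0], tok[1]
            if minus:
                g1, g2 = complement_allele(g1), complement_allele(g2)
            if g1 not in allowed or g2 not in allowed:
                raise ParseError(
                    f"line {lineno}: genotype {tok!r} uses symbols outside the "
                    f"allele pair {a1}/{a2} of {rs}"
                )
            calls.append(normalize_call(g1 + g2))
        snps.append(snp)
        rows.append(calls)

    order = sorted(
        range(len(snps)),
        key=lambda i: (_chromosome_sort_key(snps[i].chromosome), snps[i].position),
    )
    snps = [snps[i] for i in order]
    matrix = (
        np.array([rows[i] for i in order], dtype="U2")
        if rows
        else np.empty((0, len(sample_ids)), dtype="U2")
    )
    return GenotypeTable(
        population=population,
        build=file_build or "",
        sample_ids=sample_ids,
        snps=snps,
        calls=matrix,
    )


#: Printed frequencies are accepted if they agree with the exact count ratio
#: to this tolerance (HapMap prints 3 decimals); the stored value is always
#: recomputed from the integer counts.
FREQ_PRINT_TOLERANCE = 5e-3


def parse_frequency_file(
    source, dialect: FrequencyDialect | str = "phase3"
) -> list[FrequencyRecord]:
    """Parse a HapMap allele-frequency file.

    Frequencies are recomputed from the integer counts (exact arithmetic);
    a printed frequency that disagrees with its counts beyond
    :data:`FREQ_PRINT_TOLERANCE`, or counts that do not sum to the total,
    reject the row.
    """
    d = _resolve(dialect, FREQUENCY_DIALECTS, FrequencyDialect)
    stream = open_text(source)
    header = stream.readline()
    if not header.strip():
        raise ParseError("frequency file has no header row")
    width = len(d.columns)
    records: list[FrequencyRecord] = []
    for lineno, line in enumerate(stream, start=2):
        if not line.strip():
            continue
        t = line.split()
        if len(t) != width:
            raise ParseError(f"line {lineno}: expected {width} columns, found {len(t)}")
        rs = t[d.index(d.rs_col)]
        try:
            pos = int(t[d.index(d.pos_col)])
            ref_count = int(t[d.index(d.ref_count_col)])
            other_count = int(t[d.index(d.other_count_col)])
            total = int(t[d.index(d.total_col)])
            ref_freq_printed = float(t[d.index(d.ref_freq_col)])
            other_freq_printed = float(t[d.index(d.other_freq_col)])
        except ValueError:
            raise ParseError(f"line {lineno}: unparseable numeric field") from None
        for f in (ref_freq_printed, other_freq_printed):
            if not (0.0 <= f <= 1.0):
                raise ParseError(f"line {lineno} ({rs}): frequency {f} outside [0, 1]")
        if ref_count + other_count != total:
            raise IntegrityError(
                f"{rs}: ref_count {ref_count} + other_count {other_count} "
                f"!= total_count {total}"
            )
        if total > 0:
            ref_freq = ref_count / total
            other_freq = other_count / total
            if (
                abs(ref_freq - ref_freq_printed) > FREQ_PRINT_TOLERANCE
                or abs(other_freq - other_freq_printed) > FREQ_PRINT_TOLERANCE
            ):
                raise IntegrityError(
                    f"{rs}: printed frequencies ({ref_freq_printed}, "
                    f"{other_freq_printed}) disagree with counts "
                    f"{ref_count}/{other_count}/{total}"
                )
        else:
            ref_freq = other_freq = 0.0
        strand = t[d.index(d.strand_col)]
        minus = strand in _MINUS_TOKENS
        ref_allele = t[d.index(d.ref_allele_col)]
        other_allele = t[d.index(d.other_allele_col)]
        if minus:
            ref_allele = complement_allele(ref_allele)
            other_allele = complement_allele(other_allele)
        snp = SnpMeta(
            snp_id=rs,
            chromosome=t[d.index(d.chrom_col)],
            position=pos,
            strand="+",
            alleles=(ref_allele, other_allele),
            qc_code=t[d.index(d.qc_col)],
        )
        records.append(
            FrequencyRecord(
                snp=snp,
                ref_allele=ref_allele,
                ref_freq=ref_freq,
                ref_count=ref_count,
                other_allele=other_allele,
                other_freq=other_freq,
                other_count=other_count,
                total_count=total,
            )
        )
    return records


def parse_ld_file(source) -> list[LdRecord]:
    """Parse a HapMap LD file: pos1 pos2 pop rs1 rs2 D' r^2 LOD."""
    stream = open_text(source)
    records: list[LdRecord] = []
    for lineno, line in enumerate(stream, start=1):
        if not line.strip() or line.startswith("#"):
            continue
        t = line.split()
        if len(t) != 8:
            raise ParseError(f"line {lineno}: expected 8 columns, found {len(t)}")
        try:
            rec = LdRecord(
                pos1=int(t[0]),
                pos2=int(t[1]),
                population=t[2],
                snp_id1=t[3],
                snp_id2=t[4],
                d_prime=float(t[5]),
                r_squared=float(t[6]),
                lod=float(t[7]),
            )
        except ValueError:
            raise ParseError(f"line {lineno}: unparseable numeric field") from None
        except ParseError as exc:
            raise ParseError(f"line {lineno}: {exc}") from None
        records.append(rec)
    return records


_SEX_CODES = {
    "1": "male", "2": "female", "0": "unknown",
    "M": "male", "F": "female", "U": "unknown",
}
_NO_PARENT = {"0", "", ".", "NA"}


def parse_pedigree_file(source) -> list[PedigreeRecord]:
    """Parse a linkage-style sample-info file.

    Columns: family_id, individual_id, father_id, mother_id, sex,
    population.  ``0`` denotes an absent parent.  An optional header line
    beginning with ``family`` is skipped.  Parent references are checked
    against the whole file.
    """
    stream = open_text(source)
    records: list[PedigreeRecord] = []
    seen: set[str] = set()
    for lineno, line in enumerate(stream, start=1):
        if not line.strip():
            continue
        if lineno == 1 and line.split()[0].lower().startswith("family"):
            continue
        t = line.split()
        if len(t) != 6:
            raise ParseError(f"line {lineno}: expected 6 columns, found {len(t)}")
        fam, ind, father, mother, sex_tok, pop = t
        if ind in seen:
            raise ParseError(f"line {lineno}: individual {ind} listed twice")
        seen.add(ind)
        sex = _SEX_CODES.get(sex_tok.upper())
        if sex is None:
            raise ParseError(f"line {lineno}: unknown sex code {sex_tok!r}")
        records.append(
            PedigreeRecord(
                family_id=fam,
                individual_id=ind,
                father_id=None if father in _NO_PARENT else father,
                mother_id=None if mother in _NO_PARENT else mother,
                sex=sex,
                population=pop,
            )
        )
    ids = {r.individual_id for r in records}
    for r in records:
        for parent in (r.father_id, r.mother_id):
            if parent is not None and parent not in ids:
                raise IntegrityError(
                    f"{r.individual_id}: parent id {parent} not present in file"
                )
    return records


def parse_phased_file(
    source, *, population: str = "", build: str = ""
) -> PhasedHaplotypes:
    """Parse a phased-haplotype file.

    Header: ``rs# chrom pos`` followed by two columns per individual
    labelled ``<id>_A`` and ``<id>_B``.  Data rows carry one allele symbol
    per haplotype column.  Allele pairs for the SNP metadata are taken from
    the observed symbols (padded deterministically when monomorphic).
    """
    stream = open_text(source)
    header = stream.readline()
    if not header.strip():
        raise ParseError("phased file has no header row")
    tokens = header.split()
    if len(tokens) < 3:
        raise ParseError("phased header must start with rs# chrom pos")
    hap_labels = tokens[3:]
    if len(hap_labels) % 2 != 0:
        raise ParseError(
            f"odd number of haplotype columns ({len(hap_labels)}); "
            "expected two per individual"
        )
    sample_ids: list[str] = []
    for k in range(0, len(hap_labels), 2):
        la, lb = hap_labels[k], hap_labels[k + 1]
        if not (la.endswith("_A") and lb.endswith("_B") and la[:-2] == lb[:-2]):
            raise ParseError(f"haplotype column pair mismatch: {la!r} / {lb!r}")
        sample_ids.append(la[:-2])

    width = 3 + len(hap_labels)
    snps: list[SnpMeta] = []
    columns: list[list[str]] = []
    for lineno, line in enumerate(stream, start=2):
        if not line.strip():
            continue
        t = line.split()
        if len(t) != width:
            raise ParseError(f"line {lineno}: expected {width} columns, found {len(t)}")
        symbols = t[3:]
        for s in symbols:
            if s not in NUCLEOTIDES:
                raise ParseError(f"line {lineno}: unknown allele symbol {s!r}")
        observed = sorted(set(symbols))
        if len(observed) > 2:
            raise ParseError(f"line {lineno}: more than two alleles observed")
        if len(observed) == 2:
            alleles = (observed[0], observed[1])
        elif len(observed) == 1:
            pad = next(n for n in NUCLEOTIDES if n != observed[0])
            alleles = tuple(sorted((observed[0], pad)))
        else:
            alleles = ("A", "C")
        try:
            pos = int(t[2])
        except ValueError:
            raise ParseError(f"line {lineno}: unparseable position {t[2]!r}") from None
        snps.append(
            SnpMeta(snp_id=t[0], chromosome=t[1], position=pos, strand="+", alleles=alleles)
        )
        columns.append(symbols)

    if columns:
        haps = np.array(columns, dtype="U1").T  # (2*n_samples, n_snps)
    else:
        haps = np.empty((2 * len(sample_ids), 0), dtype="U1")
    return PhasedHaplotypes(
        population=population,
        build=build,
        sample_ids=sample_ids,
        snps=snps,
        haplotypes=haps,
    )
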