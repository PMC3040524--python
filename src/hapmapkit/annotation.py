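"""Gene-annotation adapters: UCSC Known Genes and Ensembl-style tables.

UCSC distributes the knownGene table with 0-based half-open coordinates and
comma-terminated exon lists; Ensembl exports are 1-based inclusive.  Both are
converted on ingest to the toolkit-wide convention (1-based inclusive), so a
knownGene ``txStart`` of 1000 becomes an internal start of 1001 while the
interval length is preserved.

The knownGene table identifies transcripts by UCSC ids, not gene symbols; an
optional two-column alias table (UCSC id -> symbol) supplies symbols the way
UCSC's companion cross-reference table does.

Genome-build hygiene is enforced by :func:`check_build_consistency`: HapMap
data is frozen on NCBI build 36 (hg18) while annotation services moved on to
build 37 (hg19), and silently mixing coordinate systems between builds is the
classic integration error in this domain — a mismatch is always an error,
never a conversion.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .errors import (
    AmbiguityError,
    ArgumentError,
    BuildMismatchError,
    IntegrityError,
    NotFoundError,
    ParseError,
)
from .formats import normalize_chromosome, open_text

# ---------------------------------------------------------------------------
# genome builds
# ---------------------------------------------------------------------------

#: Accepted spellings for each NCBI human reference build.
BUILD_ALIASES: dict[str, str] = {}
for canonical, aliases in {
    "36": ("36", "b36", "ncbi36", "ncbi_b36", "hg18"),
    "37": ("37", "b37", "ncbi37", "ncbi_b37", "grch37", "hg19"),
    "38": ("38", "b38", "grch38", "hg38"),
}.items():
    for a in aliases:
        BUILD_ALIASES[a] = canonical


def canonical_build(tag: str) -> str:
    """Resolve a build tag ("36", "hg18", "NCBI_B36", ...) to its canonical form."""
    key = str(tag).strip().lower()
    try:
        return BUILD_ALIASES[key]
    except KeyError:
        raise ArgumentError(
            f"unknown genome-build tag {tag!r}; known: {sorted(set(BUILD_ALIASES))}"
        ) from None


def check_build_consistency(dataset_build: str, annotation_build: str) -> bool:
    """Assert two build tags denote the same reference assembly.

    Returns True when equivalent under the alias map; raises
    :class:`BuildMismatchError` otherwise.  Never coerces coordinates.
    """
    a = canonical_build(dataset_build)
    b = canonical_build(annotation_build)
    if a != b:
        raise BuildMismatchError(
            f"genome build mismatch: dataset is build {dataset_build!r} (NCBI {a}) "
            f"but annotation is build {annotation_build!r} (NCBI {b})"
        )
    return True


# ---------------------------------------------------------------------------
# gene models
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneModel:
    """One transcript: span and exon structure, 1-based inclusive."""

    gene_name: str
    transcript_id: str
    chromosome: str
    strand: str
    start: int
    end: int
    exons: tuple[tuple[int, int], ...]
    build: str
    source: str  # "ucsc-knowngene" | "ensembl"

    def __post_init__(self):
        if self.start > self.end:
            raise ArgumentError(f"{self.transcript_id}: start {self.start} > end {self.end}")
        if not self.exons:
            raise ArgumentError(f"{self.transcript_id}: at least one exon required")
        prev_end = None
        for (s, e) in self.exons:
            if s > e:
                raise ArgumentError(f"{self.transcript_id}: inverted exon ({s}, {e})")
            if s < self.start or e > self.end:
                raise ArgumentError(
                    f"{self.transcript_id}: exon ({s}, {e}) outside span "
                    f"[{self.start}, {self.end}]"
                )
            if prev_end is not None and s <= prev_end:
                raise ArgumentError(
                    f"{self.transcript_id}: exons overlap or are unsorted at ({s}, {e})"
                )
            prev_end = e

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def contains(self, position: int) -> bool:
        return self.start <= position <= self.end

    def in_exon(self, position: int) -> bool:
        return any(s <= position <= e for (s, e) in self.exons)


class AnnotationSet:
    """In-memory collection of transcripts with symbol lookup."""

    def __init__(self, models: Iterable[GeneModel], build: str):
        self.models: list[GeneModel] = list(models)
        self.build = build
        self._by_symbol: dict[str, list[GeneModel]] = {}
        for m in self.models:
            self._by_symbol.setdefault(m.gene_name.lower(), []).append(m)

    def __len__(self) -> int:
        return len(self.models)

    def symbols(self) -> list[str]:
        return sorted({m.gene_name for m in self.models})

    def find_gene(self, name: str) -> list[GeneModel]:
        """All transcripts whose gene symbol matches, case-insensitively."""
        if not name:
            raise ArgumentError("empty gene name")
        hits = self._by_symbol.get(name.lower(), [])
        if not hits:
            raise NotFoundError(f"no gene named {name!r} in annotation set")
        return sorted(hits, key=lambda m: m.transcript_id)


def find_gene(name: str, annotation: AnnotationSet) -> list[GeneModel]:
    return annotation.find_gene(name)


# ---------------------------------------------------------------------------
# loading
# ---------------------------------------------------------------------------


def load_alias_table(source) -> dict[str, str]:
    """Two-column tab-separated id -> symbol cross-reference."""
    aliases: dict[str, str] = {}
    with open_text(source) as stream:
        for lineno, line in enumerate(stream, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 2:
                raise ParseError(f"alias table line {lineno}: expected 2 columns")
            aliases[parts[0]] = parts[1]
    return aliases


def _parse_comma_list(text: str, lineno: int) -> list[int]:
    # knownGene exon lists are comma-terminated: "1000,2000,"
    items = [x for x in text.strip().split(",") if x != ""]
    try:
        return [int(x) for x in items]
    except ValueError:
        raise ParseError(f"line {lineno}: unparseable coordinate in list {text!r}") from None


def _load_knowngene(stream, build: str, aliases: dict[str, str]) -> list[GeneModel]:
    models: list[GeneModel] = []
    for lineno, line in enumerate(stream, start=1):
        if not line.strip() or line.startswith("#"):
            continue
        t = line.rstrip("\n").split("\t")
        if len(t) < 10:
            raise ParseError(f"line {lineno}: knownGene rows need >= 10 columns, found {len(t)}")
        name, chrom, strand = t[0], t[1], t[2]
        try:
            tx_start, tx_end = int(t[3]), int(t[4])
            exon_count = int(t[7])
        except ValueError:
            raise ParseError(f"line {lineno}: unparseable coordinate") from None
        exon_starts = _parse_comma_list(t[8], lineno)
        exon_ends = _parse_comma_list(t[9], lineno)
        if len(exon_starts) != exon_count or len(exon_ends) != exon_count:
            raise IntegrityError(
                f"{name}: exonCount {exon_count} does not match exon list length "
                f"({len(exon_starts)} starts, {len(exon_ends)} ends)"
            )
        # UCSC half-open 0-based -> 1-based inclusive: start+1, end unchanged.
        exons = tuple((s + 1, e) for s, e in zip(exon_starts, exon_ends))
        models.append(
            GeneModel(
                gene_name=aliases.get(name, name),
                transcript_id=name,
                chromosome=chrom,
                strand=strand,
                start=tx_start + 1,
                end=tx_end,
                exons=exons,
                build=build,
                source="ucsc-knowngene",
            )
        )
    return models


def _load_ensembl(stream, build: str) -> list[GeneModel]:
    # Flat export: gene_id, symbol, chromosome, strand, start, end, exons
    # where exons = "s1-e1,s2-e2,..." in 1-based inclusive coordinates.
    models: list[GeneModel] = []
    for lineno, line in enumerate(stream, start=1):
        if not line.strip() or line.startswith("#"):
            continue
        t = line.rstrip("\n").split("\t")
        if len(t) != 7:
            raise ParseError(f"line {lineno}: expected 7 columns, found {len(t)}")
        gene_id, symbol, chrom, strand, start_s, end_s, exon_s = t
        try:
            start, end = int(start_s), int(end_s)
            exons = tuple(
                (int(p.split("-")[0]), int(p.split("-")[1]))
                for p in exon_s.split(",")
                if p
            )
        except (ValueError, IndexError):
            raise ParseError(f"line {lineno}: unparseable coordinate") from None
        models.append(
            GeneModel(
                gene_name=symbol,
                transcript_id=gene_id,
                chromosome=chrom,
                strand=strand,
                start=start,
                end=end,
                exons=exons,
                build=build,
                source="ensembl",
            )
        )
    return models


def load_annotation_table(
    source,
    dialect: str,
    build: str,
    *,
    alias_table=None,
) -> AnnotationSet:
    """Load a gene-annotation table into an :class:`AnnotationSet`.

    ``dialect`` is ``"ucsc-knowngene"`` (0-based half-open, converted on
    ingest) or ``"ensembl"`` (1-based inclusive, taken verbatim).
    ``alias_table`` maps transcript ids to gene symbols for the knownGene
    dialect (path/stream or a pre-built dict).
    """
    canonical_build(build)  # validate tag early
    aliases: dict[str, str]
    if alias_table is None:
        aliases = {}
    elif isinstance(alias_table, dict):
        aliases = alias_table
    else:
        aliases = load_alias_table(alias_table)
    with open_text(source) as stream:
        if dialect == "ucsc-knowngene":
            models = _load_knowngene(stream, build, aliases)
        elif dialect == "ensembl":
            models = _load_ensembl(stream, build)
        else:
            raise ArgumentError(
                f"unknown annotation dialect {dialect!r}; "
                "known: ['ensembl', 'ucsc-knowngene']"
            )
    return AnnotationSet(models, build=build)


# ---------------------------------------------------------------------------
# span policies
# ---------------------------------------------------------------------------


def merge_intervals(intervals: Sequence[tuple[int, int]]) -> tuple[tuple[int, int], ...]:
    """Merge 1-based inclusive intervals into a sorted disjoint cover."""
    if not intervals:
        return ()
    ordered = sorted(intervals)
    merged = [list(ordered[0])]
    for s, e in ordered[1:]:
        if s <= merged[-1][1] + 1:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return tuple((s, e) for s, e in merged)


def gene_span(
    models: Sequence[GeneModel], policy: str = "longest-transcript"
) -> tuple[str, int, int, tuple[tuple[int, int], ...]]:
    """Collapse a gene's transcripts to one (chromosome, start, end, exons).

    ``longest-transcript`` picks the model maximising end - start (ties by
    transcript id); ``union`` takes the min start, max end and merged exons.
    """
    if not models:
        raise ArgumentError("no gene models given")
    chroms = {normalize_chromosome(m.chromosome) for m in models}
    if len(chroms) > 1:
        raise AmbiguityError(f"gene models span multiple chromosomes: {sorted(chroms)}")
    if policy == "longest-transcript":
        best = max(models, key=lambda m: (m.end - m.start, m.transcript_id))
        return (best.chromosome, best.start, best.end, best.exons)
    if policy == "union":
        start = min(m.start for m in models)
        end = max(m.end for m in models)
        exons = merge_intervals([iv for m in models for iv in m.exons])
        return (models[0].chromosome, start, end, exons)
    raise ArgumentError(f"unknown span policy {policy!r}")
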