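"""Synthetic HapMap-style fixtures with known ground truth.

The original bulk-download service for this kind of data is long retired, so
every other module is exercised against generated fixtures whose truth is
known exactly.  The generator draws, per SNP, an ancestral allele frequency
``p``; per population, an allele frequency from the Balding–Nichols model —
``Beta(p(1-F)/F, (1-p)(1-F)/F)`` for divergence ``F > 0``, or exactly ``p``
when ``F = 0`` — under which the expected multi-locus Weir–Cockerham theta
between populations is approximately ``F``.  Founder genotypes are drawn in
Hardy–Weinberg proportions from the population frequency; trio offspring are
formed by Mendelian transmission from two designated founder parents; a
missing-data mask is applied i.i.d. to genotype calls.  All randomness flows
from the spec's single seed.

Frequency fixtures are derived from the *realized founder genotype counts*
(not the latent frequencies) so cross-format consistency checks are exact
equalities rather than stochastic ones.  Phased fixtures carry the founders'
complete underlying haplotypes; the genotype-file missing mask does not
apply to them, mirroring the fact that the phased and genotype releases were
distinct datasets.
"""

from __future__ import annotations

import hashlib
import json
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .annotation import GeneModel
from .errors import ArgumentError
from .formats import (
    MISSING,
    FrequencyRecord,
    GenotypeTable,
    LdRecord,
    PedigreeRecord,
    PhasedHaplotypes,
    SnpMeta,
    normalize_call,
)
from .store import DataKey, mirror_filename

_NUCS = ("A", "C", "G", "T")


@dataclass(frozen=True)
class PopulationSpec:
    """One simulated population: founders plus optional trios.

    Each trio designates two founders as parents (so ``n_founders`` must be
    at least ``2 * n_trios``) and appends one offspring formed by Mendelian
    transmission.
    """

    code: str
    n_founders: int
    n_trios: int = 0

    def __post_init__(self):
        if self.n_founders < 1:
            raise ArgumentError(f"{self.code}: need at least one founder")
        if self.n_trios < 0 or 2 * self.n_trios > self.n_founders:
            raise ArgumentError(
                f"{self.code}: {self.n_trios} trios need {2 * self.n_trios} "
                f"founder parents but only {self.n_founders} founders exist"
            )


@dataclass(frozen=True)
class GeneLayout:
    """Span and exon structure for one synthetic gene."""

    symbol: str
    start: int
    end: int
    n_exons: int = 1
    n_transcripts: int = 1

    def __post_init__(self):
        if self.start > self.end:
            raise ArgumentError(f"{self.symbol}: start > end")
        if self.n_exons < 1 or self.n_transcripts < 1:
            raise ArgumentError(f"{self.symbol}: need >= 1 exon and transcript")


@dataclass(frozen=True)
class SimSpec:
    """Ground-truth parameters for one fixture bundle."""

    populations: tuple[PopulationSpec, ...] = (
        PopulationSpec("CEU", 30, 0),
        PopulationSpec("YRI", 30, 0),
    )
    n_snps: int = 20
    chromosome: str = "chr2"
    position_range: tuple[int, int] = (136_545_000, 136_595_000)
    ancestral: str | tuple[float, ...] = "uniform"
    divergence_F: float = 0.1
    missing_rate: float = 0.02
    seed: int = 0
    build: str = "36"
    phase: int = 3
    genes: tuple[GeneLayout, ...] = ()

    def __post_init__(self):
        object.__setattr__(self, "populations", tuple(self.populations))
        object.__setattr__(self, "genes", tuple(self.genes))
        if isinstance(self.ancestral, (list, tuple)):
            object.__setattr__(self, "ancestral", tuple(float(x) for x in self.ancestral))
        if self.n_snps < 1:
            raise ArgumentError("n_snps must be >= 1")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ArgumentError(f"missing_rate must be in [0, 1), got {self.missing_rate}")
        if not (0.0 <= self.divergence_F < 1.0):
            raise ArgumentError(
                f"divergence_F must be in [0, 1) (F = 1 degenerates the Beta), "
                f"got {self.divergence_F}"
            )
        if not self.populations:
            raise ArgumentError("at least one population required")
        lo, hi = self.position_range
        if hi - lo + 1 < self.n_snps:
            raise ArgumentError("position_range too narrow for n_snps distinct positions")
        if isinstance(self.ancestral, tuple) and len(self.ancestral) != self.n_snps:
            raise ArgumentError("fixed ancestral frequency list must have n_snps entries")

    @classmethod
    def from_json(cls, source) -> "SimSpec":
        if isinstance(source, Path) or (
            isinstance(source, str) and not source.lstrip().startswith("{")
        ):
            data = json.loads(Path(source).read_text())
        else:
            data = json.loads(source)
        data["populations"] = tuple(
            PopulationSpec(**p) if isinstance(p, dict) else PopulationSpec(*p)
            for p in data.get("populations", ())
        ) or cls.populations
        data["genes"] = tuple(
            GeneLayout(**g) if isinstance(g, dict) else GeneLayout(*g)
            for g in data.get("genes", ())
        )
        if "position_range" in data:
            data["position_range"] = tuple(data["position_range"])
        if isinstance(data.get("ancestral"), list):
            data["ancestral"] = tuple(data["ancestral"])
        return cls(**data)

    def to_json(self) -> str:
        d = asdict(self)
        return json.dumps(d, indent=2, sort_keys=True)


@dataclass
class PopulationTruth:
    spec: PopulationSpec
    freqs: np.ndarray  # latent allele-1 frequency per SNP
    sample_ids: list[str]  # founders then children
    founder_ids: list[str]
    child_ids: list[str]
    haplotypes: np.ndarray  # (2 * n_individuals, n_snps), 'U1', pre-missing
    calls: np.ndarray  # (n_snps, n_individuals), 'U2', missing mask applied
    calls_unmasked: np.ndarray
    pedigree: list[PedigreeRecord]


@dataclass
class Bundle:
    """Everything simulate_truth knows about one fixture."""

    spec: SimSpec
    snps: list[SnpMeta]
    ancestral_freqs: np.ndarray
    populations: dict[str, PopulationTruth]
    ld: dict[str, list[LdRecord]]
    gene_models: list[GeneModel]

    def genotype_table(self, code: str) -> GenotypeTable:
        pt = self.populations[code]
        return GenotypeTable(
            population=code,
            build=self.spec.build,
            sample_ids=list(pt.sample_ids),
            snps=list(self.snps),
            calls=pt.calls.copy(),
        )

    def founder_frequency_records(self, code: str) -> list[FrequencyRecord]:
        """Frequency truth: realized founder non-missing genotype counts."""
        pt = self.populations[code]
        n_founders = len(pt.founder_ids)
        out = []
        for i, snp in enumerate(self.snps):
            a1, a2 = snp.alleles
            n1 = n2 = 0
            for call in pt.calls[i, :n_founders]:
                if call == MISSING:
                    continue
                n1 += call.count(a1)
                n2 += call.count(a2)
            total = n1 + n2
            out.append(
                FrequencyRecord(
                    snp=snp,
                    ref_allele=a1,
                    ref_freq=(n1 / total if total else 0.0),
                    ref_count=n1,
                    other_allele=a2,
                    other_freq=(n2 / total if total else 0.0),
                    other_count=n2,
                    total_count=total,
                )
            )
        return out

    def phased(self, code: str) -> PhasedHaplotypes:
        """Founders' complete haplotypes (no missing mask)."""
        pt = self.populations[code]
        n_f = len(pt.founder_ids)
        return PhasedHaplotypes(
            population=code,
            build=self.spec.build,
            sample_ids=list(pt.founder_ids),
            snps=list(self.snps),
            haplotypes=pt.haplotypes[: 2 * n_f].copy(),
        )

    def pedigree(self, code: str) -> list[PedigreeRecord]:
        return list(self.populations[code].pedigree)


def _sub_rng(seed: int, *labels) -> np.random.Generator:
    """Deterministic child generator derived from the spec seed."""
    tag = zlib.crc32("/".join(str(x) for x in labels).encode())
    return np.random.default_rng((int(seed) % (2**31), tag))


def simulate_truth(spec: SimSpec) -> Bundle:
    """Draw a full ground-truth bundle from a :class:`SimSpec`."""
    rng = _sub_rng(spec.seed, "snps")
    lo, hi = spec.position_range
    positions = np.sort(
        rng.choice(np.arange(lo, hi + 1, dtype=np.int64), size=spec.n_snps, replace=False)
    )
    snps: list[SnpMeta] = []
    for i, pos in enumerate(positions):
        pair = tuple(sorted(rng.choice(_NUCS, size=2, replace=False)))
        snps.append(
            SnpMeta(
                snp_id=f"rs{1_000_000 + i}",
                chromosome=spec.chromosome,
                position=int(pos),
                strand="+",
                alleles=pair,  # type: ignore[arg-type]
                qc_code="QC+",
            )
        )

    if spec.ancestral == "uniform":
        ancestral = rng.uniform(0.05, 0.95, size=spec.n_snps)
    else:
        ancestral = np.asarray(spec.ancestral, dtype=float)

    F = spec.divergence_F
    populations: dict[str, PopulationTruth] = {}
    for pspec in spec.populations:
        prng = _sub_rng(spec.seed, "pop", pspec.code)
        if F > 0:
            freqs = prng.beta(ancestral * (1 - F) / F, (1 - ancestral) * (1 - F) / F)
        else:
            freqs = ancestral.copy()

        n_f, n_t = pspec.n_founders, pspec.n_trios
        founder_ids = [f"{pspec.code}_{i:04d}" for i in range(n_f)]
        child_ids = [f"{pspec.code}_C{t:03d}" for t in range(n_t)]
        sample_ids = founder_ids + child_ids
        n_ind = n_f + n_t

        # founder haplotypes: Bernoulli(freq) picks allele 1
        is_a1 = prng.random((2 * n_f, spec.n_snps)) < freqs[np.newaxis, :]
        haps = np.empty((2 * n_ind, spec.n_snps), dtype="U1")
        a1 = np.array([s.alleles[0] for s in snps])
        a2 = np.array([s.alleles[1] for s in snps])
        haps[: 2 * n_f] = np.where(is_a1, a1[np.newaxis, :], a2[np.newaxis, :])

        # trio offspring: one random haplotype per parent per locus
        for t in range(n_t):
            father, mother = 2 * t, 2 * t + 1  # founder indices
            for parent_rank, parent in enumerate((father, mother)):
                pick = prng.integers(0, 2, size=spec.n_snps)
                src = np.where(
                    pick == 0,
                    haps[2 * parent],
                    haps[2 * parent + 1],
                )
                haps[2 * (n_f + t) + parent_rank] = src

        calls_unmasked = np.empty((spec.n_snps, n_ind), dtype="U2")
        for j in range(n_ind):
            for i in range(spec.n_snps):
                calls_unmasked[i, j] = normalize_call(haps[2 * j, i] + haps[2 * j + 1, i])
        calls = calls_unmasked.copy()
        if spec.missing_rate > 0:
            mask = prng.random((spec.n_snps, n_ind)) < spec.missing_rate
            calls[mask] = MISSING

        pedigree: list[PedigreeRecord] = []
        trio_parent = {}
        child_sex = prng.integers(1, 3, size=n_t)
        for t in range(n_t):
            trio_parent[founder_ids[2 * t]] = (f"FAM{t:03d}", "male")
            trio_parent[founder_ids[2 * t + 1]] = (f"FAM{t:03d}", "female")
        for i, fid in enumerate(founder_ids):
            fam, sex = trio_parent.get(fid, (fid, "unknown"))
            pedigree.append(
                PedigreeRecord(
                    family_id=f"{pspec.code}_{fam}",
                    individual_id=fid,
                    father_id=None,
                    mother_id=None,
                    sex=sex,
                    population=pspec.code,
                )
            )
        for t, cid in enumerate(child_ids):
            pedigree.append(
                PedigreeRecord(
                    family_id=f"{pspec.code}_FAM{t:03d}",
                    individual_id=cid,
                    father_id=founder_ids[2 * t],
                    mother_id=founder_ids[2 * t + 1],
                    sex="male" if child_sex[t] == 1 else "female",
                    population=pspec.code,
                )
            )

        populations[pspec.code] = PopulationTruth(
            spec=pspec,
            freqs=freqs,
            sample_ids=sample_ids,
            founder_ids=founder_ids,
            child_ids=child_ids,
            haplotypes=haps,
            calls=calls,
            calls_unmasked=calls_unmasked,
            pedigree=pedigree,
        )

    # LD rows: format-valid records over adjacent SNP pairs (not model-derived)
    ld: dict[str, list[LdRecord]] = {}
    for pspec in spec.populations:
        lrng = _sub_rng(spec.seed, "ld", pspec.code)
        records = []
        for i in range(spec.n_snps - 1):
            dp = float(f"{lrng.uniform(0, 1):.4f}")
            r2 = float(f"{lrng.uniform(0, 1):.4f}")
            lod = float(f"{lrng.uniform(-2, 10):.4f}")
            records.append(
                LdRecord(
                    pos1=snps[i].position,
                    pos2=snps[i + 1].position,
                    population=pspec.code,
                    snp_id1=snps[i].snp_id,
                    snp_id2=snps[i + 1].snp_id,
                    d_prime=dp,
                    r_squared=r2,
                    lod=lod,
                )
            )
        ld[pspec.code] = records

    gene_models = _gene_models(spec)
    return Bundle(
        spec=spec,
        snps=snps,
        ancestral_freqs=ancestral,
        populations=populations,
        ld=ld,
        gene_models=gene_models,
    )


def _gene_models(spec: SimSpec) -> list[GeneModel]:
    models = []
    counter = 1
    for g in spec.genes:
        for j in range(g.n_transcripts):
            # alternative transcripts trim the 3' end so lengths differ
            step = (g.end - g.start) // (4 * g.n_transcripts) if g.n_transcripts > 1 else 0
            end = g.end - j * step
            start = g.start
            length = end - start + 1
            k = min(g.n_exons, max(1, length // 2))
            segment = length // k
            exons = []
            for e in range(k):
                ex_start = start + e * segment
                ex_end = ex_start + max(0, segment // 2 - 1)
                exons.append((ex_start, min(ex_end, end)))
            models.append(
                GeneModel(
                    gene_name=g.symbol,
                    transcript_id=f"uc{counter:06d}.1",
                    chromosome=spec.chromosome,
                    strand="+",
                    start=start,
                    end=end,
                    exons=tuple(exons),
                    build=spec.build,
                    source="ucsc-knowngene",
                )
            )
            counter += 1
    return models


# ---------------------------------------------------------------------------
# emitters
# ---------------------------------------------------------------------------

_LSID = "urn:lsid:synthetic"
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


def _minus_rows(bundle: Bundle, code: str, fraction: float) -> np.ndarray:
    if fraction <= 0:
        return np.zeros(len(bundle.snps), dtype=bool)
    rng = _sub_rng(bundle.spec.seed, "minus", code)
    return rng.random(len(bundle.snps)) < fraction


def emit_genotype_file(
    bundle: Bundle, code: str, dialect: str = "phase3", *, minus_strand_fraction: float = 0.0
) -> str:
    """Render one population's genotypes in the HapMap bulk dialect.

    ``minus_strand_fraction`` marks a deterministic subset of rows as
    reverse-strand (alleles and calls complemented, strand ``-``) to
    exercise the parser's strand normalisation; the parsed table is the
    same either way.
    """
    spec = bundle.spec
    pt = bundle.populations[code]
    qc_header = "QCcode" if dialect == "phase3" else "QC_code"
    header = (
        f"rs# alleles chrom pos strand assembly# center protLSID assayLSID "
        f"panelLSID {qc_header} " + " ".join(pt.sample_ids)
    )
    minus = _minus_rows(bundle, code, minus_strand_fraction)
    lines = [header]
    for i, snp in enumerate(bundle.snps):
        a1, a2 = snp.alleles
        strand = "+"
        calls = list(pt.calls[i])
        if minus[i]:
            strand = "-"
            a1, a2 = _COMPLEMENT[a1], _COMPLEMENT[a2]
            calls = [
                c if c == MISSING else _COMPLEMENT[c[0]] + _COMPLEMENT[c[1]]
                for c in calls
            ]
        lines.append(
            f"{snp.snp_id} {a1}/{a2} {snp.chromosome} {snp.position} {strand} "
            f"ncbi_b{spec.build} synthgen {_LSID} {_LSID} {_LSID} {snp.qc_code} "
            + " ".join(calls)
        )
    return "\n".join(lines) + "\n"


def emit_frequency_file(bundle: Bundle, code: str, dialect: str = "phase3") -> str:
    spec = bundle.spec
    records = bundle.founder_frequency_records(code)
    header = (
        "rs# chrom pos strand build center protLSID assayLSID panelLSID QC_code "
        "refallele refallele_freq refallele_count otherallele otherallele_freq "
        "otherallele_count totalcount"
    )
    lines = [header]
    for rec in records:
        lines.append(
            f"{rec.snp.snp_id} {rec.snp.chromosome} {rec.snp.position} + "
            f"ncbi_b{spec.build} synthgen {_LSID} {_LSID} {_LSID} {rec.snp.qc_code} "
            f"{rec.ref_allele} {rec.ref_freq:.6f} {rec.ref_count} "
            f"{rec.other_allele} {rec.other_freq:.6f} {rec.other_count} {rec.total_count}"
        )
    return "\n".join(lines) + "\n"


def emit_ld_file(bundle: Bundle, code: str) -> str:
    lines = [
        f"{r.pos1} {r.pos2} {r.population} {r.snp_id1} {r.snp_id2} "
        f"{r.d_prime:.4f} {r.r_squared:.4f} {r.lod:.4f}"
        for r in bundle.ld[code]
    ]
    return "\n".join(lines) + ("\n" if lines else "")


_SEX_OUT = {"male": "1", "female": "2", "unknown": "0"}


def emit_pedigree_file(bundle: Bundle, code: str) -> str:
    lines = ["family individual father mother sex population"]
    for r in bundle.pedigree(code):
        lines.append(
            f"{r.family_id} {r.individual_id} {r.father_id or '0'} "
            f"{r.mother_id or '0'} {_SEX_OUT[r.sex]} {r.population}"
        )
    return "\n".join(lines) + "\n"


def emit_phased_file(bundle: Bundle, code: str) -> str:
    ph = bundle.phased(code)
    labels = " ".join(f"{sid}_A {sid}_B" for sid in ph.sample_ids)
    lines = [f"rs# chrom pos {labels}"]
    for i, snp in enumerate(ph.snps):
        lines.append(
            f"{snp.snp_id} {snp.chromosome} {snp.position} "
            + " ".join(ph.haplotypes[:, i])
        )
    return "\n".join(lines) + "\n"


def emit_known_genes_table(bundle: Bundle) -> str:
    """knownGene rows (0-based half-open, comma-terminated exon lists)."""
    lines = []
    for m in bundle.gene_models:
        exon_starts = "".join(f"{s - 1}," for s, _ in m.exons)
        exon_ends = "".join(f"{e}," for _, e in m.exons)
        lines.append(
            "\t".join(
                [
                    m.transcript_id, m.chromosome, m.strand,
                    str(m.start - 1), str(m.end),
                    str(m.start - 1), str(m.end),
                    str(len(m.exons)), exon_starts, exon_ends,
                    "", m.transcript_id,
                ]
            )
        )
    return "\n".join(lines) + ("\n" if lines else "")


def emit_alias_table(bundle: Bundle) -> str:
    lines = [f"{m.transcript_id}\t{m.gene_name}" for m in bundle.gene_models]
    return "\n".join(lines) + ("\n" if lines else "")


def write_bundle(
    bundle: Bundle, out_dir, *, minus_strand_fraction: float = 0.0
) -> list[Path]:
    """Write a bundle as a mirror-layout directory tree plus a manifest.

    File names follow :func:`hapmapkit.store.mirror_filename`, so the
    directory is directly usable as a store ``mirror_root``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    spec = bundle.spec
    written: list[Path] = []

    def _write(name: str, text: str):
        path = out / name
        path.write_text(text)
        written.append(path)

    for pspec in spec.populations:
        code = pspec.code
        for kind, text in (
            ("genotype", emit_genotype_file(bundle, code, minus_strand_fraction=minus_strand_fraction)),
            ("frequency", emit_frequency_file(bundle, code)),
            ("ld", emit_ld_file(bundle, code)),
            ("phased", emit_phased_file(bundle, code)),
        ):
            key = DataKey(kind, spec.phase, code, spec.chromosome, spec.build)
            _write(mirror_filename(key), text)
        key = DataKey("pedigree", spec.phase, code, "ALL", spec.build)
        _write(mirror_filename(key), emit_pedigree_file(bundle, code))
    if bundle.gene_models:
        _write(f"knownGene_b{spec.build}.txt", emit_known_genes_table(bundle))
        _write(f"knownGene_b{spec.build}_aliases.txt", emit_alias_table(bundle))

    digest = hashlib.sha256()
    for path in sorted(written):
        digest.update(path.name.encode())
        digest.update(path.read_bytes())
    manifest = {
        "spec": json.loads(spec.to_json()),
        "files": [p.name for p in sorted(written)],
        "sha256": digest.hexdigest(),
    }
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    written.append(manifest_path)
    return written
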