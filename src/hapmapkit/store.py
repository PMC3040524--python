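"""Download-once local cache over an embedded relational database.

HapMap data was distributed as bulk per-chromosome, per-population flat
files.  This module ingests those files once into an embedded sqlite
database and answers all subsequent queries from it, so a workflow touching
the same (population, chromosome) slice twice never re-reads (or re-fetches)
the source.  The original distribution service is long retired, so the
shipped fetch strategy resolves :class:`DataKey` values against a local
mirror directory laid out by :func:`mirror_filename`; fetching over HTTP via
a ``url_template`` is opt-in, and arbitrary fetchers can be plugged in.

The backend is an adapter (:class:`Backend`) with an execute/query/
transaction contract; :class:`SqliteBackend` is the zero-administration
default, and an external relational engine can be attached by implementing
the same three methods.  Tables are partitioned by (dataset kind, phase).
"""

from __future__ import annotations

import hashlib
import json
import os
import sqlite3
from contextlib import contextmanager
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np

from . import formats
from .errors import (
    ArgumentError,
    AvailabilityError,
    IntegrityError,
    TransportError,
)
from .formats import (
    MISSING,
    FrequencyRecord,
    GenotypeTable,
    LdRecord,
    PedigreeRecord,
    PhasedHaplotypes,
    SnpMeta,
    normalize_chromosome,
)

DATASET_KINDS = ("genotype", "frequency", "ld", "phased", "pedigree")

#: Dataset kinds that are chromosome-partitioned; pedigree files are
#: per-population only.
_CHROMOSOME_KINDS = {"genotype", "frequency", "ld", "phased"}


@dataclass(frozen=True)
class DataKey:
    """Identity of one ingestible data slice."""

    dataset_kind: str
    phase: int
    population: str
    chromosome: str = "ALL"
    build: str = "36"

    def __post_init__(self):
        if self.dataset_kind not in DATASET_KINDS:
            raise ArgumentError(
                f"unknown dataset kind {self.dataset_kind!r}; known: {DATASET_KINDS}"
            )
        if self.phase not in (2, 3):
            raise ArgumentError(f"phase must be 2 or 3, got {self.phase!r}")
        object.__setattr__(self, "population", self.population.upper())
        object.__setattr__(self, "chromosome", normalize_chromosome(self.chromosome))


@dataclass
class StoreConfig:
    """Where the cache lives and where missing data may come from."""

    cache_root: Path
    mirror_root: Path | None = None
    url_template: str | None = None
    backend: str = "embedded"
    dsn: str | None = None

    def __post_init__(self):
        self.cache_root = Path(self.cache_root)
        if self.mirror_root is not None:
            self.mirror_root = Path(self.mirror_root)

    @classmethod
    def from_file(cls, path) -> "StoreConfig":
        """Read a key=value config file; environment variables override.

        Recognised keys: cache_root, mirror_root, url_template, backend,
        dsn.  Environment overrides: HAPMAPKIT_CACHE_ROOT,
        HAPMAPKIT_MIRROR_ROOT, HAPMAPKIT_URL_TEMPLATE, HAPMAPKIT_BACKEND.
        """
        values: dict[str, str] = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#") or "=" not in line:
                    continue
                k, v = line.split("=", 1)
                values[k.strip()] = v.strip()
        for key, env in (
            ("cache_root", "HAPMAPKIT_CACHE_ROOT"),
            ("mirror_root", "HAPMAPKIT_MIRROR_ROOT"),
            ("url_template", "HAPMAPKIT_URL_TEMPLATE"),
            ("backend", "HAPMAPKIT_BACKEND"),
            ("dsn", "HAPMAPKIT_DSN"),
        ):
            if env in os.environ:
                values[key] = os.environ[env]
        if "cache_root" not in values:
            raise ArgumentError(f"config {path}: cache_root is required")
        return cls(
            cache_root=Path(values["cache_root"]),
            mirror_root=Path(values["mirror_root"]) if values.get("mirror_root") else None,
            url_template=values.get("url_template") or None,
            backend=values.get("backend", "embedded"),
            dsn=values.get("dsn") or None,
        )


@dataclass(frozen=True)
class IngestReceipt:
    """Outcome of ensure_available: where the data came from, how much."""

    key: DataKey
    source: str  # "cache-hit" | "mirror" | "fetched"
    rows_ingested: int
    checksum: str | None = None


def mirror_filename(key: DataKey) -> str:
    """Mirror-directory naming convention for a data slice.

    ``{kind}_chr{chromosome}_{POP}_phase{N}_b{build}.txt`` for the
    chromosome-partitioned kinds and ``pedigree_{POP}_phase{N}.txt`` for
    pedigrees.  A ``.gz`` twin of any file is also recognised.
    """
    if key.dataset_kind == "pedigree":
        return f"pedigree_{key.population}_phase{key.phase}.txt"
    return (
        f"{key.dataset_kind}_chr{key.chromosome}_{key.population}"
        f"_phase{key.phase}_b{key.build}.txt"
    )


# ---------------------------------------------------------------------------
# backend adapter
# ---------------------------------------------------------------------------


class Backend:
    """Minimal relational-backend contract: execute, query, transaction."""

    def execute(self, sql: str, params: Sequence = ()) -> None:
        raise NotImplementedError

    def query(self, sql: str, params: Sequence = ()) -> list[tuple]:
        raise NotImplementedError

    def transaction(self):
        raise NotImplementedError


class SqliteBackend(Backend):
    """Embedded sqlite backend (the zero-administration default)."""

    def __init__(self, db_path: Path | str):
        self.db_path = Path(db_path)
        self.db_path.parent.mkdir(parents=True, exist_ok=True)
        self._conn = sqlite3.connect(str(self.db_path))

    def execute(self, sql: str, params: Sequence = ()) -> None:
        self._conn.execute(sql, tuple(params))

    def executemany(self, sql: str, rows: Iterable[Sequence]) -> None:
        self._conn.executemany(sql, rows)

    def query(self, sql: str, params: Sequence = ()) -> list[tuple]:
        return list(self._conn.execute(sql, tuple(params)))

    @contextmanager
    def transaction(self):
        try:
            yield self
            self._conn.commit()
        except Exception:
            self._conn.rollback()
            raise

    def close(self) -> None:
        self._conn.close()


# ---------------------------------------------------------------------------
# schema
# ---------------------------------------------------------------------------

_REGISTRY_DDL = """
CREATE TABLE IF NOT EXISTS datasets (
    id INTEGER PRIMARY KEY,
    dataset_kind TEXT NOT NULL,
    phase INTEGER NOT NULL,
    population TEXT NOT NULL,
    chromosome TEXT NOT NULL,
    build TEXT NOT NULL,
    source TEXT NOT NULL,
    row_count INTEGER NOT NULL,
    checksum TEXT,
    UNIQUE (dataset_kind, phase, population, chromosome)
)
"""


def _partition(kind: str, phase: int) -> str:
    return f"{kind}_phase{phase}"


def _partition_ddl(kind: str, phase: int) -> list[str]:
    t = _partition(kind, phase)
    if kind == "genotype":
        return [
            f"""CREATE TABLE IF NOT EXISTS {t} (
                dataset_id INTEGER NOT NULL, idx INTEGER NOT NULL,
                snp_id TEXT NOT NULL, chromosome TEXT NOT NULL,
                chrom_norm TEXT NOT NULL, position INTEGER NOT NULL,
                strand TEXT NOT NULL, allele1 TEXT NOT NULL,
                allele2 TEXT NOT NULL, qc_code TEXT NOT NULL,
                calls TEXT NOT NULL)""",
            f"""CREATE TABLE IF NOT EXISTS {t}_samples (
                dataset_id INTEGER NOT NULL, idx INTEGER NOT NULL,
                sample_id TEXT NOT NULL)""",
            f"CREATE INDEX IF NOT EXISTS ix_{t}_pos ON {t} (dataset_id, position)",
        ]
    if kind == "frequency":
        return [
            f"""CREATE TABLE IF NOT EXISTS {t} (
                dataset_id INTEGER NOT NULL, idx INTEGER NOT NULL,
                snp_id TEXT NOT NULL, chromosome TEXT NOT NULL,
                chrom_norm TEXT NOT NULL, position INTEGER NOT NULL,
                strand TEXT NOT NULL, qc_code TEXT NOT NULL,
                ref_allele TEXT NOT NULL, ref_count INTEGER NOT NULL,
                other_allele TEXT NOT NULL, other_count INTEGER NOT NULL,
                total_count INTEGER NOT NULL)""",
            f"CREATE INDEX IF NOT EXISTS ix_{t}_pos ON {t} (dataset_id, position)",
        ]
    if kind == "ld":
        return [
            f"""CREATE TABLE IF NOT EXISTS {t} (
                dataset_id INTEGER NOT NULL, idx INTEGER NOT NULL,
                pos1 INTEGER NOT NULL, pos2 INTEGER NOT NULL,
                population TEXT NOT NULL, snp_id1 TEXT NOT NULL,
                snp_id2 TEXT NOT NULL, d_prime REAL NOT NULL,
                r_squared REAL NOT NULL, lod REAL NOT NULL)""",
        ]
    if kind == "phased":
        return [
            f"""CREATE TABLE IF NOT EXISTS {t} (
                dataset_id INTEGER NOT NULL, idx INTEGER NOT NULL,
                snp_id TEXT NOT NULL, chromosome TEXT NOT NULL,
                chrom_norm TEXT NOT NULL, position INTEGER NOT NULL,
                allele1 TEXT NOT NULL, allele2 TEXT NOT NULL,
                haplotypes TEXT NOT NULL)""",
            f"""CREATE TABLE IF NOT EXISTS {t}_samples (
                dataset_id INTEGER NOT NULL, idx INTEGER NOT NULL,
                sample_id TEXT NOT NULL)""",
        ]
    if kind == "pedigree":
        return [
            f"""CREATE TABLE IF NOT EXISTS {t} (
                dataset_id INTEGER NOT NULL, idx INTEGER NOT NULL,
                family_id TEXT NOT NULL, individual_id TEXT NOT NULL,
                father_id TEXT, mother_id TEXT,
                sex TEXT NOT NULL, population TEXT NOT NULL)""",
        ]
    raise ArgumentError(f"unknown dataset kind {kind!r}")


# ---------------------------------------------------------------------------
# the store
# ---------------------------------------------------------------------------


class HapmapStore:
    """Ingest-on-demand cache with interval queries.

    Parameters
    ----------
    config:
        A :class:`StoreConfig`, or a bare path usable as ``cache_root``.
    backend:
        Optional pre-built :class:`Backend`; defaults to sqlite at
        ``cache_root/hapmapkit.db``.
    """

    def __init__(self, config: StoreConfig | str | Path, backend: Backend | None = None):
        if not isinstance(config, StoreConfig):
            config = StoreConfig(cache_root=Path(config))
        self.config = config
        if backend is None:
            backend = SqliteBackend(config.cache_root / "hapmapkit.db")
        self.backend = backend
        with self.backend.transaction():
            self.backend.execute(_REGISTRY_DDL)

    # -- registry -----------------------------------------------------------

    def _dataset_row(self, key: DataKey):
        rows = self.backend.query(
            "SELECT id, build, row_count, checksum, source FROM datasets "
            "WHERE dataset_kind=? AND phase=? AND population=? AND chromosome=?",
            (key.dataset_kind, key.phase, key.population, key.chromosome),
        )
        return rows[0] if rows else None

    def _find_dataset(self, kind: str, phase: int, population: str, chromosome: str):
        key = DataKey(kind, phase, population, chromosome)
        row = self._dataset_row(key)
        if row is None:
            known = sorted(
                {r[0] for r in self.backend.query(
                    "SELECT population FROM datasets WHERE dataset_kind=? AND phase=?",
                    (kind, phase),
                )}
            )
            raise AvailabilityError(
                f"no {kind} data ingested for population {key.population!r} "
                f"chromosome {key.chromosome!r} (phase {phase}); "
                f"known populations for this kind: {known}"
            )
        return key, row

    def dataset_build(self, kind: str, phase: int, population: str, chromosome: str) -> str:
        """Genome build recorded for an ingested slice (metadata only)."""
        _, row = self._find_dataset(kind, phase, population, chromosome)
        return row[1]

    def list_populations(self, dataset_kind: str | None = None, phase: int | None = None) -> list[str]:
        sql = "SELECT DISTINCT population FROM datasets"
        clauses, params = [], []
        if dataset_kind is not None:
            clauses.append("dataset_kind=?")
            params.append(dataset_kind)
        if phase is not None:
            clauses.append("phase=?")
            params.append(phase)
        if clauses:
            sql += " WHERE " + " AND ".join(clauses)
        return sorted({r[0] for r in self.backend.query(sql, params)})

    # -- ingestion ----------------------------------------------------------

    def _locate_source(self, key: DataKey):
        """Resolve a key to (text, origin) via mirror then url_template."""
        if self.config.mirror_root is not None:
            base = self.config.mirror_root / mirror_filename(key)
            for candidate in (base, base.with_suffix(base.suffix + ".gz")):
                if candidate.exists():
                    with formats.open_text(candidate) as fh:
                        return fh.read(), "mirror"
        if self.config.url_template is not None:
            url = self.config.url_template.format(
                dataset_kind=key.dataset_kind,
                phase=key.phase,
                population=key.population,
                chromosome=key.chromosome,
                build=key.build,
            )
            import urllib.error
            import urllib.request

            try:
                with urllib.request.urlopen(url) as resp:
                    return resp.read().decode("utf-8"), "fetched"
            except (urllib.error.URLError, OSError) as exc:
                raise TransportError(
                    f"fetch of {url} failed ({exc}); check connectivity and retry"
                ) from exc
        raise AvailabilityError(
            f"no source configured for {key}: not in cache, no mirror file "
            f"{mirror_filename(key)!r}, no url_template"
        )

    def ensure_available(
        self,
        key: DataKey,
        *,
        fetcher: Callable[[DataKey], str] | None = None,
        verify: bool = False,
    ) -> IngestReceipt:
        """Make a data slice queryable, fetching and ingesting at most once.

        A second call with the same key is a pure cache hit: no fetch, no
        re-ingest, byte-identical database state.  With ``verify=True`` a
        cache hit re-reads the source (when reachable) and raises
        :class:`IntegrityError` if its checksum or row count changed.
        """
        existing = self._dataset_row(key)
        if existing is not None:
            if verify:
                try:
                    text, _ = self._locate_source(key) if fetcher is None else (fetcher(key), "fetcher")
                except AvailabilityError:
                    text = None
                if text is not None:
                    checksum = hashlib.sha256(text.encode()).hexdigest()
                    if existing[3] is not None and checksum != existing[3]:
                        raise IntegrityError(
                            f"source for {key} changed since ingestion "
                            f"(checksum {checksum[:12]} != {existing[3][:12]})"
                        )
            return IngestReceipt(key=key, source="cache-hit", rows_ingested=0, checksum=existing[3])

        if fetcher is not None:
            text, origin = fetcher(key), "fetched"
        else:
            text, origin = self._locate_source(key)
        checksum = hashlib.sha256(text.encode()).hexdigest()
        n_rows = self._ingest(key, text)
        with self.backend.transaction():
            self.backend.execute(
                "INSERT INTO datasets (dataset_kind, phase, population, chromosome, "
                "build, source, row_count, checksum) VALUES (?,?,?,?,?,?,?,?)",
                (key.dataset_kind, key.phase, key.population, key.chromosome,
                 key.build, origin, n_rows, checksum),
            )
        return IngestReceipt(key=key, source=origin, rows_ingested=n_rows, checksum=checksum)

    def _next_dataset_id(self) -> int:
        rows = self.backend.query("SELECT COALESCE(MAX(id), 0) + 1 FROM datasets")
        return rows[0][0]

    def _ingest(self, key: DataKey, text: str) -> int:
        import io

        for ddl in _partition_ddl(key.dataset_kind, key.phase):
            with self.backend.transaction():
                self.backend.execute(ddl)
        ds_id = self._next_dataset_id()
        t = _partition(key.dataset_kind, key.phase)
        kind = key.dataset_kind
        stream = io.StringIO(text)
        with self.backend.transaction():
            if kind == "genotype":
                dialect = "phase2" if key.phase == 2 else "phase3"
                table = formats.parse_genotype_file(
                    stream, dialect, population=key.population, build=key.build
                )
                for j, sid in enumerate(table.sample_ids):
                    self.backend.execute(
                        f"INSERT INTO {t}_samples VALUES (?,?,?)", (ds_id, j, sid)
                    )
                for i, snp in enumerate(table.snps):
                    self.backend.execute(
                        f"INSERT INTO {t} VALUES (?,?,?,?,?,?,?,?,?,?,?)",
                        (ds_id, i, snp.snp_id, snp.chromosome,
                         normalize_chromosome(snp.chromosome), snp.position,
                         snp.strand, snp.alleles[0], snp.alleles[1], snp.qc_code,
                         " ".join(table.calls[i])),
                    )
                return len(table.snps)
            if kind == "frequency":
                records = formats.parse_frequency_file(stream, "phase2" if key.phase == 2 else "phase3")
                for i, rec in enumerate(records):
                    self.backend.execute(
                        f"INSERT INTO {t} VALUES (?,?,?,?,?,?,?,?,?,?,?,?,?)",
                        (ds_id, i, rec.snp.snp_id, rec.snp.chromosome,
                         normalize_chromosome(rec.snp.chromosome), rec.snp.position,
                         rec.snp.strand, rec.snp.qc_code,
                         rec.ref_allele, rec.ref_count,
                         rec.other_allele, rec.other_count, rec.total_count),
                    )
                return len(records)
            if kind == "ld":
                records = formats.parse_ld_file(stream)
                for i, rec in enumerate(records):
                    self.backend.execute(
                        f"INSERT INTO {t} VALUES (?,?,?,?,?,?,?,?,?,?)",
                        (ds_id, i, rec.pos1, rec.pos2, rec.population,
                         rec.snp_id1, rec.snp_id2, rec.d_prime, rec.r_squared, rec.lod),
                    )
                return len(records)
            if kind == "phased":
                ph = formats.parse_phased_file(
                    stream, population=key.population, build=key.build
                )
                for j, sid in enumerate(ph.sample_ids):
                    self.backend.execute(
                        f"INSERT INTO {t}_samples VALUES (?,?,?)", (ds_id, j, sid)
                    )
                for i, snp in enumerate(ph.snps):
                    self.backend.execute(
                        f"INSERT INTO {t} VALUES (?,?,?,?,?,?,?,?,?)",
                        (ds_id, i, snp.snp_id, snp.chromosome,
                         normalize_chromosome(snp.chromosome), snp.position,
                         snp.alleles[0], snp.alleles[1],
                         " ".join(ph.haplotypes[:, i])),
                    )
                return len(ph.snps)
            if kind == "pedigree":
                records = formats.parse_pedigree_file(stream)
                for i, rec in enumerate(records):
                    self.backend.execute(
                        f"INSERT INTO {t} VALUES (?,?,?,?,?,?,?,?)",
                        (ds_id, i, rec.family_id, rec.individual_id,
                         rec.father_id, rec.mother_id, rec.sex, rec.population),
                    )
                return len(records)
        raise ArgumentError(f"unknown dataset kind {kind!r}")

    # -- queries ------------------------------------------------------------

    @staticmethod
    def _check_interval(start: int, end: int) -> None:
        if start > end:
            raise ArgumentError(f"inverted interval: start {start} > end {end}")

    def snps_in_interval(
        self,
        chromosome: str,
        start: int,
        end: int,
        *,
        population: str,
        phase: int = 3,
        dataset_kind: str = "genotype",
    ) -> list[SnpMeta]:
        """SNPs with start <= position <= end, ordered by position."""
        self._check_interval(start, end)
        key, row = self._find_dataset(dataset_kind, phase, population, chromosome)
        t = _partition(dataset_kind, phase)
        if dataset_kind == "genotype":
            rows = self.backend.query(
                f"SELECT snp_id, chromosome, position, strand, allele1, allele2, qc_code "
                f"FROM {t} WHERE dataset_id=? AND position BETWEEN ? AND ? ORDER BY position",
                (row[0], start, end),
            )
            return [
                SnpMeta(snp_id=r[0], chromosome=r[1], position=r[2], strand=r[3],
                        alleles=(r[4], r[5]), qc_code=r[6])
                for r in rows
            ]
        if dataset_kind == "frequency":
            rows = self.backend.query(
                f"SELECT snp_id, chromosome, position, strand, ref_allele, other_allele, qc_code "
                f"FROM {t} WHERE dataset_id=? AND position BETWEEN ? AND ? ORDER BY position",
                (row[0], start, end),
            )
            return [
                SnpMeta(snp_id=r[0], chromosome=r[1], position=r[2], strand=r[3],
                        alleles=(r[4], r[5]), qc_code=r[6])
                for r in rows
            ]
        raise ArgumentError(f"interval queries unsupported for kind {dataset_kind!r}")

    def get_genotypes(
        self,
        population: str,
        chromosome: str,
        interval: tuple[int, int] | None = None,
        *,
        phase: int = 3,
    ) -> GenotypeTable:
        """Genotype table for one population/chromosome, optionally windowed."""
        key, ds = self._find_dataset("genotype", phase, population, chromosome)
        t = _partition("genotype", phase)
        samples = [
            r[0] for r in self.backend.query(
                f"SELECT sample_id FROM {t}_samples WHERE dataset_id=? ORDER BY idx",
                (ds[0],),
            )
        ]
        if interval is None:
            where, params = "dataset_id=?", [ds[0]]
        else:
            self._check_interval(*interval)
            where = "dataset_id=? AND position BETWEEN ? AND ?"
            params = [ds[0], interval[0], interval[1]]
        rows = self.backend.query(
            f"SELECT snp_id, chromosome, position, strand, allele1, allele2, qc_code, calls "
            f"FROM {t} WHERE {where} ORDER BY position",
            params,
        )
        snps = [
            SnpMeta(snp_id=r[0], chromosome=r[1], position=r[2], strand=r[3],
                    alleles=(r[4], r[5]), qc_code=r[6])
            for r in rows
        ]
        calls = (
            np.array([r[7].split(" ") for r in rows], dtype="U2")
            if rows
            else np.empty((0, len(samples)), dtype="U2")
        )
        return GenotypeTable(
            population=key.population, build=ds[1], sample_ids=samples,
            snps=snps, calls=calls,
        )

    def get_frequencies(
        self,
        population: str,
        chromosome: str,
        interval: tuple[int, int] | None = None,
        *,
        phase: int = 3,
    ) -> list[FrequencyRecord]:
        """Frequency records for one population/chromosome, optionally windowed."""
        key, ds = self._find_dataset("frequency", phase, population, chromosome)
        t = _partition("frequency", phase)
        if interval is None:
            where, params = "dataset_id=?", [ds[0]]
        else:
            self._check_interval(*interval)
            where = "dataset_id=? AND position BETWEEN ? AND ?"
            params = [ds[0], interval[0], interval[1]]
        rows = self.backend.query(
            f"SELECT snp_id, chromosome, position, strand, qc_code, ref_allele, "
            f"ref_count, other_allele, other_count, total_count "
            f"FROM {t} WHERE {where} ORDER BY position",
            params,
        )
        out = []
        for r in rows:
            total = r[9]
            snp = SnpMeta(snp_id=r[0], chromosome=r[1], position=r[2], strand=r[3],
                          alleles=(r[5], r[7]), qc_code=r[4])
            out.append(
                FrequencyRecord(
                    snp=snp,
                    ref_allele=r[5], ref_freq=(r[6] / total if total else 0.0), ref_count=r[6],
                    other_allele=r[7], other_freq=(r[8] / total if total else 0.0), other_count=r[8],
                    total_count=total,
                )
            )
        return out

    def get_pedigree(self, population: str, *, phase: int = 3) -> list[PedigreeRecord]:
        """Pedigree records for one population (chromosome-independent)."""
        key, ds = self._find_dataset("pedigree", phase, population, "ALL")
        t = _partition("pedigree", phase)
        rows = self.backend.query(
            f"SELECT family_id, individual_id, father_id, mother_id, sex, population "
            f"FROM {t} WHERE dataset_id=? ORDER BY idx",
            (ds[0],),
        )
        return [
            PedigreeRecord(family_id=r[0], individual_id=r[1], father_id=r[2],
                           mother_id=r[3], sex=r[4], population=r[5])
            for r in rows
        ]

    def get_ld(self, population: str, chromosome: str, *, phase: int = 3) -> list[LdRecord]:
        key, ds = self._find_dataset("ld", phase, population, chromosome)
        t = _partition("ld", phase)
        rows = self.backend.query(
            f"SELECT pos1, pos2, population, snp_id1, snp_id2, d_prime, r_squared, lod "
            f"FROM {t} WHERE dataset_id=? ORDER BY idx",
            (ds[0],),
        )
        return [
            LdRecord(pos1=r[0], pos2=r[1], population=r[2], snp_id1=r[3],
                     snp_id2=r[4], d_prime=r[5], r_squared=r[6], lod=r[7])
            for r in rows
        ]

    def get_phased(self, population: str, chromosome: str, *, phase: int = 3) -> PhasedHaplotypes:
        key, ds = self._find_dataset("phased", phase, population, chromosome)
        t = _partition("phased", phase)
        samples = [
            r[0] for r in self.backend.query(
                f"SELECT sample_id FROM {t}_samples WHERE dataset_id=? ORDER BY idx",
                (ds[0],),
            )
        ]
        rows = self.backend.query(
            f"SELECT snp_id, chromosome, position, allele1, allele2, haplotypes "
            f"FROM {t} WHERE dataset_id=? ORDER BY position",
            (ds[0],),
        )
        snps = [
            SnpMeta(snp_id=r[0], chromosome=r[1], position=r[2], strand="+",
                    alleles=(r[3], r[4]))
            for r in rows
        ]
        haps = (
            np.array([r[5].split(" ") for r in rows], dtype="U1").T
            if rows
            else np.empty((2 * len(samples), 0), dtype="U1")
        )
        return PhasedHaplotypes(
            population=key.population, build=ds[1], sample_ids=samples,
            snps=snps, haplotypes=haps,
        )
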