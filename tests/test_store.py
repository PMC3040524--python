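"""Embedded store: download-once semantics, interval queries, parse equivalence."""

import numpy as np
import pytest

from hapmapkit import (
    ArgumentError,
    AvailabilityError,
    DataKey,
    HapmapStore,
    StoreConfig,
    mirror_filename,
)
from hapmapkit import synthetic_data as sd

from conftest import build_store


def geno_key(bundle, code):
    spec = bundle.spec
    return DataKey("genotype", spec.phase, code, spec.chromosome, spec.build)


class TestEnsureAvailable:
    def test_second_call_is_cache_hit_with_identical_database(self, trio_bundle, tmp_path):
        mirror = tmp_path / "mirror"
        sd.write_bundle(trio_bundle, mirror)
        cfg = StoreConfig(cache_root=tmp_path / "cache", mirror_root=mirror)
        key = geno_key(trio_bundle, "CEU")

        store = HapmapStore(cfg)
        first = store.ensure_available(key)
        store.backend.close()
        snapshot = (tmp_path / "cache" / "hapmapkit.db").read_bytes()

        store = HapmapStore(cfg)
        second = store.ensure_available(key)
        store.backend.close()
        assert first.source == "mirror"
        assert second.source == "cache-hit"
        assert second.rows_ingested == 0
        assert (tmp_path / "cache" / "hapmapkit.db").read_bytes() == snapshot

    def test_mirror_ingest_row_count_is_file_lines_minus_header(self, trio_bundle, tmp_path):
        mirror = tmp_path / "mirror"
        sd.write_bundle(trio_bundle, mirror)
        store = HapmapStore(StoreConfig(cache_root=tmp_path / "cache", mirror_root=mirror))
        key = geno_key(trio_bundle, "YRI")
        receipt = store.ensure_available(key)
        fixture = mirror / mirror_filename(key)
        n_lines = len(fixture.read_text().splitlines())
        assert receipt.rows_ingested == n_lines - 1

    def test_absent_key_without_source_is_availability_error(self, tmp_path):
        store = HapmapStore(StoreConfig(cache_root=tmp_path / "cache"))
        with pytest.raises(AvailabilityError, match="no source configured"):
            store.ensure_available(DataKey("genotype", 3, "CEU", "chr2", "36"))


class TestIntervalQueries:
    def test_empty_scope_is_error_not_empty_list(self, tmp_path):
        store = HapmapStore(StoreConfig(cache_root=tmp_path / "cache"))
        with pytest.raises(AvailabilityError):
            store.snps_in_interval("chr2", 1, 10, population="CEU")

    def test_endpoints_inclusive(self, trio_bundle, trio_store):
        snp = trio_bundle.snps[3]
        hits = store_hits = trio_store.snps_in_interval(
            snp.chromosome, snp.position, snp.position, population="CEU"
        )
        assert [s.snp_id for s in hits] == [snp.snp_id]

    def test_matches_bruteforce_linear_scan(self, tmp_path):
        spec = sd.SimSpec(
            seed=42, n_snps=500, position_range=(1, 50_000), missing_rate=0.0,
            populations=(sd.PopulationSpec("CEU", 2),), divergence_F=0.0,
        )
        bundle = sd.simulate_truth(spec)
        store = build_store(bundle, tmp_path)
        rng = np.random.default_rng(7)
        for _ in range(100):
            a, b = sorted(rng.integers(1, 50_001, size=2))
            got = store.snps_in_interval("chr2", int(a), int(b), population="CEU")
            expected = [s for s in bundle.snps if a <= s.position <= b]
            assert got == expected


class TestGetGenotypes:
    def test_empty_interval_keeps_full_sample_list(self, trio_bundle, trio_store):
        lo = trio_bundle.spec.position_range[0]
        t = trio_store.get_genotypes("CEU", "chr2", (1, lo - 1))
        assert t.n_snps == 0
        assert t.sample_ids == trio_bundle.populations["CEU"].sample_ids

    def test_full_table_equals_generator_truth(self, trio_bundle, trio_store):
        for code in trio_bundle.populations:
            t = trio_store.get_genotypes(code, "chr2")
            truth = trio_bundle.genotype_table(code)
            assert t.sample_ids == truth.sample_ids
            assert t.snps == truth.snps
            assert (t.calls == truth.calls).all()

    def test_repeated_reads_are_identical(self, trio_store):
        t1 = trio_store.get_genotypes("CEU", "chr2")
        t2 = trio_store.get_genotypes("CEU", "chr2")
        assert t1.snps == t2.snps and (t1.calls == t2.calls).all()

    def test_unknown_population_lists_known_codes(self, trio_store):
        with pytest.raises(AvailabilityError, match="CEU"):
            trio_store.get_genotypes("MKK", "chr2")

    def test_chromosome_label_normalisation(self, trio_store):
        assert trio_store.get_genotypes("CEU", "2").n_snps == 15


class TestGetFrequencies:
    def test_window_record_matches_generator_truth(self, trio_bundle, trio_store):
        truth = trio_bundle.founder_frequency_records("CEU")
        target = truth[0]
        got = trio_store.get_frequencies(
            "CEU", "chr2", (target.snp.position, target.snp.position)
        )
        assert got == [target]

    def test_inverted_interval_is_argument_error(self, trio_store):
        with pytest.raises(ArgumentError, match="inverted"):
            trio_store.get_frequencies("CEU", "chr2", (100, 10))

    def test_full_chromosome_count_equals_fixture(self, trio_bundle, trio_store):
        lo, hi = trio_bundle.spec.position_range
        recs = trio_store.get_frequencies("YRI", "chr2", (lo, hi))
        assert len(recs) == trio_bundle.spec.n_snps
        assert recs == trio_bundle.founder_frequency_records("YRI")


class TestOtherQueries:
    def test_pedigree_ld_phased_roundtrip(self, trio_bundle, trio_store):
        for code in trio_bundle.populations:
            assert trio_store.get_pedigree(code) == trio_bundle.pedigree(code)
            assert trio_store.get_ld(code, "chr2") == trio_bundle.ld[code]
            ph = trio_store.get_phased(code, "chr2")
            truth = trio_bundle.phased(code)
            assert ph.sample_ids == truth.sample_ids
            assert (ph.haplotypes == truth.haplotypes).all()
            assert [s.snp_id for s in ph.snps] == [s.snp_id for s in truth.snps]

    def test_list_populations(self, trio_store, tmp_path):
        assert trio_store.list_populations() == ["CEU", "YRI"]
        assert trio_store.list_populations("genotype", 3) == ["CEU", "YRI"]
        empty = HapmapStore(StoreConfig(cache_root=tmp_path / "empty"))
        assert empty.list_populations() == []

    def test_reingesting_same_population_keeps_one_entry(self, trio_bundle, trio_store):
        trio_store.ensure_available(geno_key(trio_bundle, "CEU"))
        assert trio_store.list_populations() == ["CEU", "YRI"]
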