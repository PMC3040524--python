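"""Flat-file dialect parsers: trivial contracts, error paths, generator round trips."""

import io

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hapmapkit import (
    MISSING,
    IntegrityError,
    ParseError,
    parse_frequency_file,
    parse_genotype_file,
    parse_ld_file,
    parse_pedigree_file,
    parse_phased_file,
)
from hapmapkit import synthetic_data as sd
from hapmapkit.formats import normalize_chromosome

META = "rs# alleles chrom pos strand assembly# center protLSID assayLSID panelLSID QCcode"


def geno_text(rows, samples=("NA1", "NA2", "NA3")):
    return META + " " + " ".join(samples) + "\n" + "".join(r + "\n" for r in rows)


class TestParseGenotype:
    def test_header_only_yields_empty_table(self):
        t = parse_genotype_file(io.StringIO(geno_text([])), "phase3")
        assert t.n_snps == 0
        assert t.sample_ids == ["NA1", "NA2", "NA3"]

    def test_nn_token_is_missing(self):
        row = "rs1 A/G chr2 100 + ncbi_b36 c p a p QC+ AA NN AG"
        t = parse_genotype_file(io.StringIO(geno_text([row])), "phase3")
        assert list(t.calls[0]) == ["AA", MISSING, "AG"]

    def test_strand_normalization_involution(self):
        # the same SNP written on + and - strands parses identically
        plus = "rs1 A/G chr2 100 + ncbi_b36 c p a p QC+ AA AG GG"
        minus = "rs1 T/C chr2 100 - ncbi_b36 c p a p QC+ TT TC CC"
        t_plus = parse_genotype_file(io.StringIO(geno_text([plus])), "phase3")
        t_minus = parse_genotype_file(io.StringIO(geno_text([minus])), "phase3")
        assert t_plus.snps == t_minus.snps
        assert (t_plus.calls == t_minus.calls).all()
        assert t_minus.snps[0].strand == "+"

    def test_rows_sorted_by_position(self):
        rows = [
            "rs2 A/G chr2 500 + b c p a p QC+ AA AA AA",
            "rs1 C/T chr2 100 + b c p a p QC+ CC CC CC",
        ]
        t = parse_genotype_file(io.StringIO(geno_text(rows)), "phase3")
        assert [s.snp_id for s in t.snps] == ["rs1", "rs2"]

    @pytest.mark.parametrize(
        "row, message",
        [
            ("rs1 A/G chr2 100 + b c p a p QC+ AA AA", "expected 14 columns"),
            ("rs1 A/Z chr2 100 + b c p a p QC+ AA AA AA", "unknown allele"),
            ("rs1 A/G chr2 100 + b c p a p QC+ AA AC AA", "outside the allele pair"),
        ],
    )
    def test_malformed_rows_name_the_line(self, row, message):
        with pytest.raises(ParseError, match="line 2"):
            parse_genotype_file(io.StringIO(geno_text([row])), "phase3")

    def test_duplicate_rs_id_rejected(self):
        rows = [
            "rs1 A/G chr2 100 + b c p a p QC+ AA AA AA",
            "rs1 A/G chr2 200 + b c p a p QC+ AA AA AA",
        ]
        with pytest.raises(ParseError, match="duplicate rs id rs1"):
            parse_genotype_file(io.StringIO(geno_text(rows)), "phase3")

    @pytest.mark.parametrize("minus_fraction", [0.0, 0.5])
    def test_roundtrip_against_generator_truth(self, trio_bundle, minus_fraction):
        for code in trio_bundle.populations:
            text = sd.emit_genotype_file(
                trio_bundle, code, minus_strand_fraction=minus_fraction
            )
            table = parse_genotype_file(io.StringIO(text), "phase3", population=code)
            truth = trio_bundle.genotype_table(code)
            assert table.sample_ids == truth.sample_ids
            assert table.snps == truth.snps
            assert (table.calls == truth.calls).all()

    def test_phase2_dialect_header_token(self, trio_bundle):
        text = sd.emit_genotype_file(trio_bundle, "CEU", dialect="phase2")
        table = parse_genotype_file(io.StringIO(text), "phase2", population="CEU")
        assert table.n_snps == trio_bundle.spec.n_snps


FREQ_META = (
    "rs# chrom pos strand build center protLSID assayLSID panelLSID QC_code "
    "refallele refallele_freq refallele_count otherallele otherallele_freq "
    "otherallele_count totalcount"
)


def freq_text(rows):
    return FREQ_META + "\n" + "".join(r + "\n" for r in rows)


class TestParseFrequency:
    def test_counts_force_frequency(self):
        row = "rs1 chr2 100 + b c p a p QC+ A 0.75 3 G 0.25 1 4"
        (rec,) = parse_frequency_file(io.StringIO(freq_text([row])))
        assert rec.ref_freq == 0.75
        assert rec.other_freq == 0.25
        assert not rec.monomorphic_no_data

    def test_zero_total_flagged_monomorphic_no_data(self):
        row = "rs1 chr2 100 + b c p a p QC+ A 0 0 G 0 0 0"
        (rec,) = parse_frequency_file(io.StringIO(freq_text([row])))
        assert rec.monomorphic_no_data
        assert rec.ref_freq == 0.0 and rec.other_freq == 0.0

    def test_count_mismatch_names_rs_id(self):
        row = "rs77 chr2 100 + b c p a p QC+ A 0.75 3 G 0.25 2 4"
        with pytest.raises(IntegrityError, match="rs77"):
            parse_frequency_file(io.StringIO(freq_text([row])))

    def test_frequency_outside_unit_interval_rejected(self):
        row = "rs1 chr2 100 + b c p a p QC+ A 1.75 3 G 0.25 1 4"
        with pytest.raises(ParseError, match="outside"):
            parse_frequency_file(io.StringIO(freq_text([row])))

    def test_roundtrip_against_generator_truth(self, trio_bundle):
        for code in trio_bundle.populations:
            text = sd.emit_frequency_file(trio_bundle, code)
            records = parse_frequency_file(io.StringIO(text))
            assert records == trio_bundle.founder_frequency_records(code)

    def test_consistency_invariant_on_parsed_records(self, trio_bundle):
        for rec in parse_frequency_file(
            io.StringIO(sd.emit_frequency_file(trio_bundle, "CEU"))
        ):
            assert rec.ref_count + rec.other_count == rec.total_count
            if rec.total_count:
                assert abs(rec.ref_freq + rec.other_freq - 1.0) <= 1e-9


class TestParseLd:
    def test_empty_stream(self):
        assert parse_ld_file(io.StringIO("")) == []

    def test_closed_bounds_accepted(self):
        (rec,) = parse_ld_file(io.StringIO("100 200 CEU rs1 rs2 1.0 1.0 3.2\n"))
        assert rec.d_prime == 1.0 and rec.r_squared == 1.0

    @pytest.mark.parametrize(
        "line",
        [
            "200 100 CEU rs1 rs2 0.5 0.5 1.0",  # pos1 >= pos2
            "100 200 CEU rs1 rs2 1.5 0.5 1.0",  # D' out of range
            "100 200 CEU rs1 rs2 0.5 -0.1 1.0",  # r^2 out of range
        ],
    )
    def test_invalid_rows_rejected(self, line):
        with pytest.raises(ParseError):
            parse_ld_file(io.StringIO(line + "\n"))

    def test_roundtrip_preserves_order_and_values(self, trio_bundle):
        text = sd.emit_ld_file(trio_bundle, "YRI")
        assert parse_ld_file(io.StringIO(text)) == trio_bundle.ld["YRI"]


PED_HEADER = "family individual father mother sex population"


class TestParsePedigree:
    def test_single_founder(self):
        text = f"{PED_HEADER}\nF1 NA1 0 0 1 CEU\n"
        (rec,) = parse_pedigree_file(io.StringIO(text))
        assert not rec.is_offspring
        assert rec.sex == "male"

    def test_trio_child_carries_both_parents(self):
        text = (
            f"{PED_HEADER}\nF1 DAD 0 0 1 CEU\nF1 MOM 0 0 2 CEU\nF1 KID DAD MOM 2 CEU\n"
        )
        recs = parse_pedigree_file(io.StringIO(text))
        kid = next(r for r in recs if r.individual_id == "KID")
        assert kid.father_id == "DAD" and kid.mother_id == "MOM"
        assert kid.is_offspring

    def test_dangling_parent_is_integrity_error(self):
        text = f"{PED_HEADER}\nF1 KID GHOST 0 1 CEU\n"
        with pytest.raises(IntegrityError, match="GHOST"):
            parse_pedigree_file(io.StringIO(text))

    def test_duplicate_individual_rejected(self):
        text = f"{PED_HEADER}\nF1 NA1 0 0 1 CEU\nF2 NA1 0 0 1 CEU\n"
        with pytest.raises(ParseError, match="twice"):
            parse_pedigree_file(io.StringIO(text))

    def test_roundtrip_against_generator_truth(self, trio_bundle):
        for code in trio_bundle.populations:
            text = sd.emit_pedigree_file(trio_bundle, code)
            assert parse_pedigree_file(io.StringIO(text)) == trio_bundle.pedigree(code)


class TestParsePhased:
    def test_single_snp_collapses_to_unordered_genotype(self):
        text = "rs# chrom pos NA1_A NA1_B\nrs1 chr2 100 A G\n"
        ph = parse_phased_file(io.StringIO(text))
        assert ph.collapse().calls[0, 0] == "AG"

    def test_empty_body(self):
        ph = parse_phased_file(io.StringIO("rs# chrom pos NA1_A NA1_B\n"))
        assert len(ph.snps) == 0
        assert ph.haplotypes.shape == (2, 0)

    def test_odd_haplotype_columns_rejected(self):
        with pytest.raises(ParseError, match="odd number"):
            parse_phased_file(io.StringIO("rs# chrom pos NA1_A NA1_B NA2_A\n"))

    def test_cross_format_consistency_with_genotype_fixture(self, trio_bundle):
        # collapsing founder haplotypes reproduces the genotype file wherever
        # the genotype file has a call (the missing mask applies only there)
        for code in trio_bundle.populations:
            ph = parse_phased_file(
                io.StringIO(sd.emit_phased_file(trio_bundle, code)), population=code
            )
            geno = parse_genotype_file(
                io.StringIO(sd.emit_genotype_file(trio_bundle, code)),
                "phase3",
                population=code,
            )
            collapsed = ph.collapse()
            col = {sid: j for j, sid in enumerate(geno.sample_ids)}
            for j, sid in enumerate(collapsed.sample_ids):
                g = geno.calls[:, col[sid]]
                c = collapsed.calls[:, j]
                called = g != MISSING
                assert (c[called] == g[called]).all()


@given(label=st.sampled_from(["2", "chr2", "CHR2", "X", "chrX", "MT"]))
def test_chromosome_normalizer_equates_prefixed_labels(label):
    assert normalize_chromosome(label) == normalize_chromosome("chr" + label.lower().removeprefix("chr"))
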