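"""Domain types and file I/O: coordinate conventions, round trips, errors."""

from __future__ import annotations

import pytest

from cnvburden.core import (
    Algorithm,
    CnvCall,
    CnvState,
    GeneModel,
    GenomicInterval,
    MaskName,
    RegionMask,
    normalize_chrom,
    state_from_copy_number,
)
from cnvburden import io as cnv_io
from cnvburden.io import FormatError

from conftest import make_call


class TestGenomicInterval:
    def test_rejects_degenerate_intervals(self):
        with pytest.raises(ValueError):
            GenomicInterval("1", 100, 100)
        with pytest.raises(ValueError):
            GenomicInterval("1", 200, 100)
        with pytest.raises(ValueError):
            GenomicInterval("1", -5, 100)

    def test_length_and_overlap(self):
        a = GenomicInterval("1", 100, 300)
        b = GenomicInterval("1", 200, 400)
        assert a.length() == 200
        assert a.overlap_len(b) == 100
        assert a.overlap_len(GenomicInterval("2", 100, 300)) == 0

    def test_union_span_requires_same_chromosome(self):
        a = GenomicInterval("1", 100, 300)
        assert a.union_span(GenomicInterval("1", 250, 500)) == GenomicInterval("1", 100, 500)
        with pytest.raises(ValueError):
            a.union_span(GenomicInterval("2", 250, 500))


class TestChromNormalization:
    @pytest.mark.parametrize("raw,expected", [
        ("chr1", "1"), ("15", "15"), ("chrX", "X"), ("23", "X"),
    ])
    def test_accepted_labels(self, raw, expected):
        assert normalize_chrom(raw) == expected

    @pytest.mark.parametrize("raw", ["Y", "chrY", "MT", "chrM", "26", "foo"])
    def test_rejected_labels(self, raw):
        with pytest.raises(ValueError):
            normalize_chrom(raw)


class TestCnvCallInvariants:
    def test_state_copy_number_consistency(self):
        with pytest.raises(ValueError):
            make_call(state=CnvState.DEL).__class__(
                sample_id="S1",
                interval=GenomicInterval("1", 0, 100),
                state=CnvState.DEL,
                copy_number=3,
                n_probes=5,
                confidence=1.0,
                algorithm=Algorithm.PENNCNV,
            )

    def test_copy_number_mapping(self):
        assert state_from_copy_number(0) is CnvState.DEL
        assert state_from_copy_number(1) is CnvState.DEL
        assert state_from_copy_number(3) is CnvState.DUP
        assert state_from_copy_number(6) is CnvState.DUP
        with pytest.raises(ValueError):
            state_from_copy_number(2)

    def test_probe_count_must_be_positive(self):
        with pytest.raises(ValueError):
            make_call(n_probes=0)


class TestPlinkDialect:
    def test_plink_row_coordinate_conversion(self, tmp_path):
        """1-based inclusive file coordinates become 0-based half-open."""
        p = tmp_path / "calls.cnv"
        p.write_text("F1 S1 15 20300000 20770000 3 20 80\n")
        (call,) = cnv_io.read_calls(p, "plink_cnv", algorithm=Algorithm.QUANTISNP)
        assert call.sample_id == "S1"
        assert call.interval == GenomicInterval("15", 20_299_999, 20_770_000)
        assert call.state is CnvState.DUP
        assert call.confidence == 20
        assert call.n_probes == 80
        # internal length equals file_end - file_start + 1
        assert call.length == 20_770_000 - 20_300_000 + 1

    def test_plink_requires_algorithm(self, tmp_path):
        p = tmp_path / "calls.cnv"
        p.write_text("F1 S1 1 100 200 1 5 10\n")
        with pytest.raises(ValueError):
            cnv_io.read_calls(p, "plink_cnv")

    def test_diploid_type_token_is_error(self, tmp_path):
        p = tmp_path / "calls.cnv"
        p.write_text("F1 S1 1 1000 200000 2 5 10\n")
        with pytest.raises(FormatError, match="1"):
            cnv_io.read_calls(p, "plink_cnv", algorithm=Algorithm.PENNCNV)


class TestCallsTsv:
    def _write(self, tmp_path, rows):
        p = tmp_path / "calls.tsv"
        header = "sample_id\tchrom\tstart\tend\tstate\tcopy_number\tn_probes\tconfidence\talgorithm"
        p.write_text("\n".join([header] + rows) + "\n")
        return p

    def test_integer_state_token_maps_by_copy_number(self, tmp_path):
        p = self._write(tmp_path, ["S1\t1\t1000001\t1200000\t1\t\t12\t25\tPennCNV"])
        (call,) = cnv_io.read_calls(p)
        assert call.state is CnvState.DEL
        assert call.copy_number == 1

    def test_end_before_start_is_error_with_line_number(self, tmp_path):
        p = self._write(tmp_path, ["S1\t1\t500000\t400000\tdup\t3\t12\t25\tiPattern"])
        with pytest.raises(FormatError, match=":2"):
            cnv_io.read_calls(p)

    def test_unknown_state_token_is_error(self, tmp_path):
        p = self._write(tmp_path, ["S1\t1\t1\t100000\tamplified\t\t12\t25\tiPattern"])
        with pytest.raises(FormatError):
            cnv_io.read_calls(p)

    def test_chry_rows_skipped_with_warning(self, tmp_path, caplog):
        p = self._write(tmp_path, [
            "S1\tY\t1000\t200000\tdup\t3\t12\t25\tiPattern",
            "S1\t2\t1000\t200000\tdup\t3\t12\t25\tiPattern",
        ])
        calls = cnv_io.read_calls(p)
        assert len(calls) == 1
        assert calls[0].interval.chrom == "2"


@pytest.mark.parametrize("dialect", ["tsv", "plink_cnv"])
class TestRoundTrip:
    def _calls(self):
        return [
            make_call(sample="A", chrom="1", start=100_000, end=300_000,
                      state=CnvState.DEL, algorithm=Algorithm.PENNCNV,
                      confidence=12.5),
            make_call(sample="A", chrom="X", start=5_000_000, end=5_600_000,
                      state=CnvState.DUP, algorithm=Algorithm.QUANTISNP,
                      confidence=42.0),
            make_call(sample="B", chrom="22", start=9_999, end=222_222,
                      state=CnvState.DUP, algorithm=Algorithm.IPATTERN),
        ]

    def test_write_read_reproduces_coordinates(self, tmp_path, dialect):
        calls = self._calls()
        path = cnv_io.write_calls(calls, tmp_path / "out", dialect=dialect)
        algo = Algorithm.IPATTERN if dialect == "plink_cnv" else None
        back = cnv_io.read_calls(path, dialect, algorithm=algo)
        assert [(c.sample_id, c.interval, c.state) for c in back] == [
            (c.sample_id, c.interval, c.state) for c in calls
        ]

    def test_second_write_is_byte_stable(self, tmp_path, dialect):
        calls = self._calls()
        algo = Algorithm.IPATTERN if dialect == "plink_cnv" else None
        p1 = cnv_io.write_calls(calls, tmp_path / "a", dialect=dialect)
        back = cnv_io.read_calls(p1, dialect, algorithm=algo)
        p2 = cnv_io.write_calls(back, tmp_path / "b", dialect=dialect)
        assert p1.read_bytes() == p2.read_bytes()


class TestMasks:
    def test_overlapping_regions_merge(self, tmp_path):
        p = tmp_path / "mask.bed"
        p.write_text("chr1\t100\t200\nchr1\t150\t300\n")
        mask = cnv_io.read_mask(p, MaskName.SEGDUP)
        assert mask.regions == (GenomicInterval("1", 100, 300),)

    def test_empty_file_gives_empty_mask(self, tmp_path):
        p = tmp_path / "mask.bed"
        p.write_text("")
        assert cnv_io.read_mask(p).regions == ()

    def test_two_column_line_is_error(self, tmp_path):
        p = tmp_path / "mask.bed"
        p.write_text("chr1\t100\n")
        with pytest.raises(FormatError):
            cnv_io.read_mask(p)

    def test_mask_overlap_len_sums_disjoint_regions(self):
        mask = RegionMask.from_intervals(MaskName.SEGDUP, [
            GenomicInterval("1", 0, 100), GenomicInterval("1", 200, 300),
        ])
        assert mask.overlap_len(GenomicInterval("1", 50, 250)) == 100


class TestGenesBed12:
    def test_bed12_exons_round_trip(self, tmp_path):
        gene = GeneModel(
            gene_name="G1",
            span=GenomicInterval("2", 1000, 9000),
            exons=(GenomicInterval("2", 1000, 2000), GenomicInterval("2", 6000, 9000)),
        )
        path = cnv_io.write_genes([gene], tmp_path / "genes.bed")
        (back,) = cnv_io.read_genes(path)
        assert back == gene

    def test_exon_outside_span_rejected(self):
        with pytest.raises(ValueError):
            GeneModel(
                gene_name="bad",
                span=GenomicInterval("1", 1000, 2000),
                exons=(GenomicInterval("1", 500, 900),),
            )

    def test_unsorted_exons_rejected(self):
        with pytest.raises(ValueError):
            GeneModel(
                gene_name="bad",
                span=GenomicInterval("1", 0, 10_000),
                exons=(GenomicInterval("1", 5000, 6000), GenomicInterval("1", 1000, 2000)),
            )


class TestSamplesTsv:
    def test_round_trip_and_phenotype_coding(self, tmp_path):
        p = tmp_path / "samples.tsv"
        p.write_text(
            "sample_id\tphenotype\tsex\tcall_rate\tlrr_sd\tbaf_sd\twave_factor\n"
            "S1\t2\tF\t0.99\t0.15\t0.05\t-0.01\n"
            "S2\t1\tM\t0.98\t0.2\t0.1\t0.02\n"
        )
        samples = cnv_io.read_samples(p)
        assert [s.phenotype.value for s in samples] == ["CASE", "CONTROL"]
        p2 = cnv_io.write_samples(samples, tmp_path / "out.tsv")
        assert cnv_io.read_samples(p2) == samples
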