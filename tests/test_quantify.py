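import math

import numpy as np
import pandas as pd
import pytest

import telomark as tm
from telomark.quantify import NO_BARCODE, LibrarySummary
from telomark.motif import ReadMotifResult
from telomark.seqio import SequencingRecord
from helpers_oracles import brute_average_ranks


def _result(telo: bool) -> ReadMotifResult:
    run = 3 if telo else 0
    return ReadMotifResult("r", run, 0, telo)


class TestComputeNta:
    @pytest.mark.parametrize("telo,total,expected", [(0, 1000, 0.0), (250, 1000, 0.25), (1, 4, 0.25)])
    def test_exact_quotient(self, telo, total, expected):
        assert tm.compute_nta(telo, total) == expected

    def test_zero_total_is_undefined_not_zero(self):
        assert math.isnan(tm.compute_nta(0, 0))

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError):
            tm.compute_nta(5, 4)

    def test_rpm_scaling(self):
        summary = LibrarySummary(total_reads=1_000_000, telomere_like_reads=3)
        assert summary.rpm == 3.0
        assert summary.nta == 3e-6

    def test_summary_invariant(self):
        with pytest.raises(ValueError):
            LibrarySummary(total_reads=10, telomere_like_reads=11)


class TestRankTransform:
    def test_examples(self):
        assert tm.rank_transform([0.1, 0.2, 0.3]).tolist() == [0.0, 0.5, 1.0]
        assert tm.rank_transform([1, 1, 2]).tolist() == [0.25, 0.25, 1.0]

    def test_degenerate_inputs(self):
        assert tm.rank_transform([7.0]).tolist() == [0.5]
        assert tm.rank_transform([2, 2, 2, 2]).tolist() == [0.5] * 4
        with pytest.raises(ValueError):
            tm.rank_transform([])

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(3)
        values = rng.random(40)
        perm = rng.permutation(40)
        out = tm.rank_transform(values)
        assert np.allclose(tm.rank_transform(values[perm]), out[perm])

    def test_matches_average_rank_oracle(self):
        rng = np.random.default_rng(17)
        for _ in range(200):
            values = rng.integers(0, 10, size=int(rng.integers(2, 15))).astype(float)
            expected = (brute_average_ranks(values) - 1) / (len(values) - 1)
            assert np.allclose(tm.rank_transform(values), expected)


class TestPerCellCounts:
    def test_tally_by_barcode(self):
        stream = [
            ("AAA", _result(True)),
            ("AAA", _result(False)),
            ("AAA", _result(False)),
            ("BBB", _result(False)),
            ("BBB", _result(False)),
        ]
        table = tm.per_cell_counts(stream)
        df = table.cells.set_index("barcode")
        assert df.loc["AAA", "total"] == 3 and df.loc["AAA", "telomere_like"] == 1
        assert df.loc["AAA", "nta"] == pytest.approx(1 / 3)
        assert df.loc["BBB", "total"] == 2 and df.loc["BBB", "nta"] == 0.0

    def test_barcodeless_records_go_to_reserved_row(self):
        table = tm.per_cell_counts([(None, _result(True)), (None, _result(False))])
        assert table.cells.empty
        assert table.no_barcode_total == 2
        assert table.no_barcode_telomere_like == 1

    def test_column_sums_conserve_input(self):
        rng = np.random.default_rng(5)
        barcodes = [f"BC{i:02d}" for i in range(50)]
        stream = [
            (barcodes[int(rng.integers(0, 50))], _result(bool(rng.random() < 0.1)))
            for _ in range(10_000)
        ]
        table = tm.per_cell_counts(stream)
        assert table.cells["total"].sum() == 10_000
        assert table.cells["telomere_like"].sum() == sum(r.is_telomere_like for _, r in stream)
        assert table.cells["barcode"].is_unique
        ranks = table.cells["rank_nta"].dropna()
        assert ((ranks >= 0) & (ranks <= 1)).all()


class TestCountRecords:
    def _records(self, spec):
        # spec: list of (barcode, telomere_like, contig)
        out = []
        for i, (bc, telo, contig) in enumerate(spec):
            seq = "TTAGGG" * 3 if telo else "ACGTAC" * 3
            out.append(
                SequencingRecord(
                    read_id=f"r{i}", sequence=seq, barcode=bc, contig=contig,
                    is_unmapped=contig is None,
                )
            )
        return out

    def test_merge_order_independence(self):
        rng = np.random.default_rng(9)
        spec = [
            (f"BC{int(rng.integers(0, 5))}", bool(rng.random() < 0.3), None)
            for _ in range(200)
        ]
        perm = list(rng.permutation(len(spec)))
        recs = self._records(spec)
        b_summary, b_table, _ = tm.count_records([recs[i] for i in perm])
        summary, table, _ = tm.count_records(self._records(spec))
        assert (summary.total_reads, summary.telomere_like_reads) == (
            b_summary.total_reads,
            b_summary.telomere_like_reads,
        )
        pd.testing.assert_frame_equal(table.cells, b_table.cells)

    def test_per_contig_conservation_and_unmapped(self):
        spec = (
            [("BC0", True, "chr1")] * 3
            + [("BC0", False, "chr2")] * 4
            + [("BC1", True, None)] * 2
        )
        summary, _, contigs = tm.count_records(self._records(spec))
        assert contigs["chr1"] == (3, 3)
        assert contigs["chr2"] == (4, 0)
        assert contigs["unmapped"] == (2, 2)
        assert sum(t for t, _ in contigs.values()) == summary.total_reads
        assert sum(k for _, k in contigs.values()) == summary.telomere_like_reads

    def test_unmapped_telomere_reads_count_in_library_nta(self):
        spec = [("BC0", False, "chr1")] * 9 + [("BC0", True, None)]
        summary, _, _ = tm.count_records(self._records(spec))
        assert summary.nta == pytest.approx(0.1)

    def test_secondary_and_supplementary_excluded(self):
        recs = self._records([("BC0", True, "chr1")] * 4)
        recs[1].is_secondary = True
        recs[2].is_supplementary = True
        summary, _, _ = tm.count_records(recs)
        assert summary.total_reads == 2

    def test_paired_fragment_counted_once_if_either_mate_qualifies(self):
        rec = SequencingRecord("r0", "ACGTAC" * 4, mate_sequence="TTAGGG" * 3, barcode="BC0")
        summary, table, _ = tm.count_records([rec])
        assert summary.mode == "fragments"
        assert (summary.total_reads, summary.telomere_like_reads) == (1, 1)

    def test_per_contig_counts_helper(self):
        stream = [("chr1", _result(True)), ("chr1", _result(False)), (None, _result(True))]
        counts = tm.per_contig_counts(stream)
        assert counts == {"chr1": (2, 1), "unmapped": (1, 1)}


class TestWriters:
    def test_cell_table_header_and_digits(self, tmp_path):
        stream = [("AAA", _result(True))] + [("AAA", _result(False))] * 6 + [(None, _result(False))]
        table = tm.per_cell_counts(stream)
        path = tmp_path / "cells.tsv"
        table.to_tsv(path)
        lines = path.read_text().splitlines()
        assert lines[0] == "barcode\ttotal\ttelomere_like\tnta\trank_nta"
        fields = lines[1].split("\t")
        assert fields[0] == "AAA" and fields[3] == "0.142857"  # 6 significant digits
        assert lines[2].startswith(NO_BARCODE)

    def test_library_summary_file(self, tmp_path):
        path = tmp_path / "summary.txt"
        LibrarySummary(total_reads=1000, telomere_like_reads=250).to_file(path)
        content = dict(line.split("=") for line in path.read_text().splitlines())
        assert content["nta"] == "0.25"
        assert content["rpm"] == "250000"
        assert content["total_reads"] == "1000"
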