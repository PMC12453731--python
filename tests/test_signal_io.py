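"""Round-trips and error contracts for WFDB, CSV and archive I/O."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cardiofuse import (
    SynthParams,
    build_dataset,
    dataset_census,
    read_reference,
    read_s1_annotations,
    read_segment_archive,
    read_wfdb_record,
    synth_dataset,
    synth_record,
    write_dataset,
    write_segment_archive,
    write_wfdb,
)
from cardiofuse.errors import (
    EmptyAnnotationError,
    FormatError,
    ModalityMissingError,
    SchemaVersionError,
)
from cardiofuse.preprocessing import SegmentDataset
from cardiofuse.signal_io import SyncRecord, write_s1_annotations


class TestWfdb:
    def test_round_trip_within_quantization(self, tmp_path, default_params):
        rec = synth_record(default_params)
        write_wfdb(rec, tmp_path)
        back = read_wfdb_record(tmp_path / f"{rec.record_id}.hea")
        assert back.fs == 2000
        for a, b in ((rec.ecg, back.ecg), (rec.pcg, back.pcg)):
            step = np.max(np.abs(a)) / 32000
            assert np.max(np.abs(a - b)) <= step

    def test_channel_selection_by_name_is_order_independent(self, tmp_path):
        rng = np.random.default_rng(0)
        rec = SyncRecord("r1", rng.standard_normal(400),
                         rng.standard_normal(400) * 3, 2000.0)
        write_wfdb(rec, tmp_path)  # writes PCG first, ECG second
        back = read_wfdb_record(tmp_path / "r1")
        assert np.corrcoef(back.ecg, rec.ecg)[0, 1] > 0.999
        assert np.corrcoef(back.pcg, rec.pcg)[0, 1] > 0.999

    def test_pcg_only_record_raises_modality_missing(self, tmp_path):
        (tmp_path / "x1.hea").write_text(
            "x1 1 2000 100\nx1.dat 16 200(0)/mV 16 0 0 0 0 PCG\n"
        )
        (tmp_path / "x1.dat").write_bytes(b"\x00\x00" * 100)
        with pytest.raises(ModalityMissingError, match="x1"):
            read_wfdb_record(tmp_path / "x1.hea")

    def test_resamples_other_rates_to_2000(self, tmp_path, default_params):
        rec = synth_record(default_params)
        hea = write_wfdb(rec, tmp_path)
        # rewrite the header claiming 4000 Hz
        lines = hea.read_text().splitlines()
        head = lines[0].split()
        head[2] = "4000"
        hea.write_text("\n".join([" ".join(head)] + lines[1:]) + "\n")
        back = read_wfdb_record(hea)
        assert back.fs == 2000
        assert len(back) == -(-len(rec) // 2)  # ceil(n / 2)

    def test_garbage_header_is_a_format_error(self, tmp_path):
        (tmp_path / "bad.hea").write_text("bad\n")
        with pytest.raises(FormatError):
            read_wfdb_record(tmp_path / "bad.hea")


class TestReference:
    def test_dialect(self, tmp_path):
        p = tmp_path / "REFERENCE.csv"
        p.write_text("a0001,1\na0002,-1\n")
        assert read_reference(p) == {"a0001": 1, "a0002": 0}

    def test_unknown_token_reports_line(self, tmp_path):
        p = tmp_path / "REFERENCE.csv"
        p.write_text("a0001,1\na0003,2\n")
        with pytest.raises(FormatError, match=":2"):
            read_reference(p)


class TestAnnotations:
    def test_filters_to_s1_rows(self, tmp_path):
        p = tmp_path / "ann.csv"
        p.write_text("sample,label\n0,S1\n800,S2\n1900,S1\n")
        assert read_s1_annotations(p).tolist() == [0, 1900]

    def test_seconds_column_converted_with_fs(self, tmp_path):
        p = tmp_path / "ann.csv"
        p.write_text("time,label\n0.0,S1\n0.95,S1\n")
        assert read_s1_annotations(p, fs=2000).tolist() == [0, 1900]

    def test_tsv_dialect_accepted(self, tmp_path):
        p = tmp_path / "ann.tsv"
        p.write_text("sample\tstate\n10\tS1\n500\tS1\n")
        assert read_s1_annotations(p).tolist() == [10, 500]

    def test_no_s1_rows_is_an_error(self, tmp_path):
        p = tmp_path / "ann.csv"
        p.write_text("sample,label\n800,S2\n")
        with pytest.raises(EmptyAnnotationError):
            read_s1_annotations(p)

    def test_writer_reader_inverse(self, tmp_path):
        onsets = np.array([5, 1200, 3033])
        write_s1_annotations(onsets, tmp_path / "a.csv")
        assert read_s1_annotations(tmp_path / "a.csv").tolist() == [5, 1200, 3033]


class TestArchive:
    def _dataset(self, n_records=3):
        recs = synth_dataset(n_records, seed=5)
        return build_dataset(recs)

    def test_round_trip_bit_identical(self, tmp_path):
        ds = self._dataset()
        ds.fold_of = np.arange(len(ds)) % 5
        path = tmp_path / "segments.npz"
        write_segment_archive(ds, path)
        back = read_segment_archive(path)
        assert len(back) == len(ds)
        assert np.array_equal(back.fold_of, ds.fold_of)
        for a, b in zip(ds.segments, back.segments):
            assert np.array_equal(a.ecg, b.ecg)
            assert np.array_equal(a.pcg, b.pcg)
            assert (a.label, a.record_id, a.beat_index) == \
                (b.label, b.record_id, b.beat_index)

    def test_empty_collection_round_trips(self, tmp_path):
        ds = SegmentDataset(segments=[])
        path = tmp_path / "empty.npz"
        write_segment_archive(ds, path)
        assert len(read_segment_archive(path)) == 0

    def test_newer_schema_version_rejected(self, tmp_path):
        ds = self._dataset(1)
        path = tmp_path / "segments.npz"
        write_segment_archive(ds, path)
        data = dict(np.load(path, allow_pickle=False))
        data["schema_version"] = np.int64(99)
        np.savez_compressed(path, **data)
        with pytest.raises(SchemaVersionError):
            read_segment_archive(path)


class TestDatasetLayout:
    def test_write_dataset_census(self, tmp_path):
        recs = synth_dataset(3, seed=8)
        manifest = write_dataset(recs, tmp_path)
        assert manifest["n_records"] == 6
        ref = read_reference(tmp_path / "REFERENCE.csv")
        census = dataset_census(tmp_path, ref)
        assert census["records"] == 6
        assert census["synchronized_pairs"] == 6
        assert census["abnormal_pairs"] == 3
        # a PCG-only record counts as a record but not as a pair
        (tmp_path / "z9.hea").write_text(
            "z9 1 2000 10\nz9.dat 16 200(0)/mV 16 0 0 0 0 PCG\n"
        )
        census2 = dataset_census(tmp_path)
        assert census2["records"] == 7
        assert census2["synchronized_pairs"] == 6

    @given(st.integers(0, 2**16))
    @settings(max_examples=10, deadline=None)
    def test_readers_total_over_writer_output(self, tmp_path_factory, seed):
        tmp = tmp_path_factory.mktemp("fuzz")
        rec = synth_record(SynthParams(seed=seed, n_beats=3))
        write_wfdb(rec, tmp)
        write_s1_annotations(rec.s1_onsets, tmp / "s1.csv")
        back = read_wfdb_record(tmp / f"{rec.record_id}.hea")
        onsets = read_s1_annotations(tmp / "s1.csv")
        assert len(back) == len(rec)
        assert np.array_equal(onsets, rec.s1_onsets)
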