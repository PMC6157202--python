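import numpy as np
import pytest

from msld_sampen import (
    LabeledSignalSet,
    Signal,
    SignalIOError,
    read_feature_table,
    read_labeled_set,
    read_signal,
    scan_class_directories,
    write_feature_table,
    write_signal,
)


def write_record(path, values):
    path.write_text("".join(f"{v}\n" for v in values))


class TestReadSignal:
    def test_reads_samples_in_file_order(self, tmp_path):
        f = tmp_path / "rec.txt"
        f.write_text("1\n2\n3\n")
        sig = read_signal(f)
        np.testing.assert_array_equal(sig.samples, [1.0, 2.0, 3.0])
        assert sig.record_id == "rec"
        assert sig.fs == pytest.approx(173.61)

    def test_full_length_record(self, tmp_path):
        f = tmp_path / "full.txt"
        write_record(f, np.arange(4096))
        sig = read_signal(f, label="normal")
        assert len(sig) == 4096
        assert sig.duration == pytest.approx(23.6, abs=0.05)
        assert sig.label == "normal"

    def test_blank_lines_and_floats_tolerated(self, tmp_path):
        f = tmp_path / "r.txt"
        f.write_text(" 1.5 \n\n-2\n\n  3e-1\n")
        np.testing.assert_array_equal(read_signal(f).samples, [1.5, -2.0, 0.3])

    def test_empty_file_is_degenerate(self, tmp_path):
        f = tmp_path / "empty.txt"
        f.write_text("")
        with pytest.raises(SignalIOError, match="degenerate"):
            read_signal(f)

    def test_non_numeric_line_reports_line_number(self, tmp_path):
        f = tmp_path / "bad.txt"
        f.write_text("1\n2\noops\n4\n")
        with pytest.raises(SignalIOError, match="line 3"):
            read_signal(f)

    def test_missing_file(self, tmp_path):
        with pytest.raises(SignalIOError, match="no such"):
            read_signal(tmp_path / "nope.txt")


class TestSignalInvariants:
    def test_rejects_short_nonfinite_and_bad_fs(self):
        with pytest.raises(ValueError):
            Signal(np.array([1.0]))
        with pytest.raises(ValueError):
            Signal(np.array([1.0, np.nan]))
        with pytest.raises(ValueError):
            Signal(np.array([1.0, 2.0]), fs=0)


class TestLabeledSet:
    def test_manifest_order_preserved(self, tmp_path):
        f1, f2 = tmp_path / "a.txt", tmp_path / "b.txt"
        write_record(f1, [1, 2, 3])
        write_record(f2, [4, 5, 6])
        ls = read_labeled_set({"A": [f1], "B": [f2]})
        assert ls.class_names == ["A", "B"]
        assert [s.label for s in ls.signals] == ["A", "B"]

    def test_three_by_many_collection(self, tmp_path):
        manifest = {}
        for label in ("ictal", "interictal", "normal"):
            paths = []
            for i in range(4):
                p = tmp_path / f"{label}{i}.txt"
                write_record(p, [i, i + 1, i + 2])
                paths.append(p)
            manifest[label] = paths
        ls = read_labeled_set(manifest)
        assert len(ls) == 12
        assert ls.class_counts() == {"ictal": 4, "interictal": 4, "normal": 4}

    def test_empty_class_rejected(self, tmp_path):
        with pytest.raises(ValueError, match="no files"):
            read_labeled_set({"A": []})

    def test_unreadable_file_aborts_with_path(self, tmp_path):
        f1 = tmp_path / "ok.txt"
        write_record(f1, [1, 2])
        with pytest.raises(SignalIOError, match="missing.txt"):
            read_labeled_set({"A": [f1, tmp_path / "missing.txt"]})

    def test_single_class_invalid_for_classification(self, tmp_path):
        f1 = tmp_path / "a.txt"
        write_record(f1, [1, 2])
        ls = read_labeled_set({"A": [f1]})
        with pytest.raises(ValueError, match=">= 2"):
            ls.validate_for_classification()


class TestFeatureTableCSV:
    def test_round_trip_is_exact(self, tmp_path, small_feature_table):
        path = tmp_path / "features.csv"
        write_feature_table(small_feature_table, path)
        again = read_feature_table(path)
        assert again == small_feature_table

    def test_header_shape(self, tmp_path, small_feature_table):
        path = tmp_path / "features.csv"
        write_feature_table(small_feature_table, path)
        header = path.read_text().splitlines()[0]
        assert header.split(",")[:2] == ["record_id", "label"]
        assert header.split(",")[2:] == [f"sampen_d{d}" for d in range(1, 11)]
        assert len(path.read_text().splitlines()) == len(small_feature_table) + 1

    def test_signal_round_trip(self, tmp_path, rng):
        sig = Signal(rng.standard_normal(100), record_id="x")
        p = tmp_path / "x.txt"
        write_signal(sig, p)
        np.testing.assert_array_equal(read_signal(p).samples, sig.samples)

    def test_scan_class_directories(self, tmp_path):
        for label in ("a", "b"):
            d = tmp_path / label
            d.mkdir()
            write_record(d / "r0.txt", [1, 2, 3])
        manifest = scan_class_directories(tmp_path)
        assert sorted(manifest) == ["a", "b"]
        empty = tmp_path / "a" / "sub"
        empty.mkdir()
        with pytest.raises(SignalIOError):
            scan_class_directories(empty)
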