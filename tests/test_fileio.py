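import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fpevent import (FileFormatError, RecordingFormatSpec, SubjectBlockID,
                     parse_data_filename, read_raw_recording,
                     read_trial_stats, write_trial_stats)


class TestFilenameParsing:
    @pytest.mark.parametrize("name, expected", [
        ("exp1_fp_subj001_block001.txt", SubjectBlockID(1, 1)),
        ("exp1_subj001.csv", SubjectBlockID(1, None)),
        ("subj42_block7.txt", SubjectBlockID(42, 7)),
        ("a/b/dir_subj003_block010.tsv", SubjectBlockID(3, 10)),
        ("block2_subj5.txt", SubjectBlockID(5, 2)),
    ])
    def test_examples(self, name, expected):
        assert parse_data_filename(name) == expected

    @pytest.mark.parametrize("name", [
        "exp1_block001.txt", "subject1.txt", "Subj1.txt", "data.csv",
    ])
    def test_missing_subject_tag_rejected(self, name):
        with pytest.raises(FileFormatError, match="subj"):
            parse_data_filename(name)

    @given(subject=st.integers(1, 999), block=st.integers(1, 99),
           pad=st.integers(1, 4))
    @settings(max_examples=50, deadline=None)
    def test_zero_padding_ignored(self, subject, block, pad):
        name = f"exp_subj{subject:0{pad}d}_block{block:0{pad}d}.txt"
        assert parse_data_filename(name) == SubjectBlockID(subject, block)


def _write_raw(path, delimiter, header_lines=0, trigger_col=True):
    """Hand-written 3-sample file: time, Mx, My, trigger (or 8 pins)."""
    rows = [
        [0.0, 1.5, -2.0, 128],
        [1.0, 1.6, -2.1, 128],
        [2.0, 1.7, -2.2, 1],
    ]
    lines = ["junk header"] * header_lines
    for r in rows:
        if trigger_col:
            lines.append(delimiter.join(str(v) for v in r))
        else:
            code = int(r[3])
            pins = [5.0 if (code >> p) & 1 else 0.0 for p in range(8)]
            lines.append(delimiter.join(str(v) for v in r[:3] + pins))
    path.write_text("\n".join(lines) + "\n")


class TestReadRawRecording:
    def spec(self, delimiter="\t", header_lines=0, pins=False):
        return RecordingFormatSpec(
            sampling_rate=1000.0, delimiter=delimiter,
            header_lines=header_lines, time_column=0,
            channel_columns={"Mx": 1, "My": 2},
            **({"pin_columns": list(range(3, 11))} if pins
               else {"trigger_column": 3}))

    def test_roundtrip_of_handwritten_fixture(self, tmp_path):
        path = tmp_path / "subj001.txt"
        _write_raw(path, "\t")
        rec = read_raw_recording(path, self.spec())
        assert rec.n_samples == 3
        assert rec.id == SubjectBlockID(1, None)
        np.testing.assert_allclose(rec.channels["Mx"], [1.5, 1.6, 1.7])
        np.testing.assert_allclose(rec.channels["My"], [-2.0, -2.1, -2.2])
        np.testing.assert_array_equal(rec.trigger_codes, [128, 128, 1])
        np.testing.assert_allclose(rec.time, [0.0, 1.0, 2.0])

    def test_header_skipping_yields_identical_recording(self, tmp_path):
        plain, headed = tmp_path / "a_subj1.txt", tmp_path / "b_subj1.txt"
        _write_raw(plain, "\t")
        _write_raw(headed, "\t", header_lines=2)
        a = read_raw_recording(plain, self.spec())
        b = read_raw_recording(headed, self.spec(header_lines=2))
        np.testing.assert_array_equal(a.channels["Mx"], b.channels["Mx"])
        np.testing.assert_array_equal(a.trigger_codes, b.trigger_codes)

    @pytest.mark.parametrize("delimiter", ["\t", ",", ";"])
    def test_delimiter_invariance(self, tmp_path, delimiter):
        path = tmp_path / "subj001.txt"
        _write_raw(path, delimiter)
        rec = read_raw_recording(path, self.spec(delimiter=delimiter))
        np.testing.assert_allclose(rec.channels["Mx"], [1.5, 1.6, 1.7])

    def test_pin_columns_decoded_against_per_row_summation(self, tmp_path):
        path = tmp_path / "subj001.txt"
        _write_raw(path, "\t", trigger_col=False)
        rec = read_raw_recording(path, self.spec(pins=True))
        # independent oracle: sum 2**p over pins written high
        np.testing.assert_array_equal(rec.trigger_codes, [128, 128, 1])

    def test_constant_code_128_on_every_row(self, tmp_path):
        path = tmp_path / "subj002.txt"
        pins = "\t".join(["5.0" if p == 7 else "0.0" for p in range(8)])
        body = "\n".join(f"{i}.0\t0.1\t0.2\t{pins}" for i in range(5))
        path.write_text(body + "\n")
        rec = read_raw_recording(path, self.spec(pins=True))
        assert (rec.trigger_codes == 128).all()

    def test_empty_body_rejected(self, tmp_path):
        path = tmp_path / "subj001.txt"
        path.write_text("junk\n")
        with pytest.raises(FileFormatError, match="empty"):
            read_raw_recording(path, self.spec(header_lines=1))

    def test_non_numeric_channel_cell_rejected(self, tmp_path):
        path = tmp_path / "subj001.txt"
        path.write_text("0.0\tabc\t1.0\t0\n")
        with pytest.raises(FileFormatError, match="non-numeric"):
            read_raw_recording(path, self.spec())

    def test_ragged_row_rejected_with_line_number(self, tmp_path):
        path = tmp_path / "subj001.txt"
        path.write_text("0.0\t1.0\t2.0\t0\n1.0\t1.1\n2.0\t1.0\t2.0\t0\n")
        with pytest.raises(FileFormatError, match="line 2"):
            read_raw_recording(path, self.spec())

    def test_time_synthesized_from_sampling_rate(self, tmp_path):
        path = tmp_path / "subj001.txt"
        path.write_text("1.0\t2.0\t0\n1.1\t2.1\t0\n")
        spec = RecordingFormatSpec(
            sampling_rate=500.0, delimiter="\t",
            channel_columns={"Mx": 0, "My": 1}, trigger_column=2)
        rec = read_raw_recording(path, spec)
        np.testing.assert_allclose(rec.time, [0.0, 2.0])  # ms at 500 Hz


class TestTrialStatsRoundTrip:
    def table(self):
        return pd.DataFrame({
            "subject": pd.array([1, 1], dtype="Int64"),
            "block": pd.array([1, 1], dtype="Int64"),
            "trial": pd.array([1, 2], dtype="Int64"),
            "Mx_[-150,0)_mean": [0.123456789012345, np.nan],
            "cond_stimulus": ["left-A", "right-B"],
        })

    def test_roundtrip_exact(self, tmp_path):
        path = tmp_path / "stats.csv"
        t = self.table()
        write_trial_stats(t, path)
        back = read_trial_stats(path)
        pd.testing.assert_frame_equal(t, back, check_dtype=False)

    def test_missing_value_roundtrips_as_missing(self, tmp_path):
        path = tmp_path / "stats.csv"
        write_trial_stats(self.table(), path)
        assert np.isnan(read_trial_stats(path)["Mx_[-150,0)_mean"].iloc[1])

    def test_empty_table_roundtrip(self, tmp_path):
        path = tmp_path / "stats.csv"
        write_trial_stats(self.table().iloc[:0], path)
        back = read_trial_stats(path)
        assert len(back) == 0
        assert list(back.columns) == list(self.table().columns)

    def test_duplicate_keys_rejected(self, tmp_path):
        t = self.table()
        t.loc[1, "trial"] = 1
        with pytest.raises(ValueError, match="duplicate"):
            write_trial_stats(t, tmp_path / "stats.csv")

    def test_missing_key_columns_rejected(self, tmp_path):
        with pytest.raises(ValueError, match="key columns"):
            write_trial_stats(pd.DataFrame({"x": [1]}), tmp_path / "s.csv")
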