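import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from usv44.calltable_io import (
    CallContour,
    CallRecord,
    CallTableFormatError,
    CallType,
    MotionSeries,
    RowValidationError,
    SessionMeta,
    Subtype,
    attach_contours,
    read_call_table,
    read_contours,
    read_motion_series,
    read_session_meta,
    write_call_table,
    write_contours,
    write_motion_series,
    write_session_meta,
)
from tests.conftest import flat_contour, make_record


class TestDomainTypes:
    def test_offset(self):
        rec = make_record(onset=1.25, duration=0.5)
        assert rec.offset == pytest.approx(1.75)

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(duration=0.0),
            dict(duration=-1.0),
            dict(peak_frequency=0.0),
            dict(peak_frequency=130_000.0),  # above Nyquist at 250 kHz
            dict(onset=-0.1),
        ],
    )
    def test_invalid_record(self, kwargs):
        with pytest.raises(ValueError):
            make_record(**kwargs)

    def test_subtype_only_for_fortyfour(self):
        with pytest.raises(ValueError):
            make_record(call_type=CallType.LONG22, subtype=Subtype.FLAT)
        rec = make_record(
            peak_frequency=42_000.0, call_type=CallType.FORTYFOUR, subtype=Subtype.FLAT
        )
        assert rec.subtype is Subtype.FLAT

    def test_contour_validation(self):
        with pytest.raises(ValueError):
            CallContour(times=[0.0], frequencies=[25_000.0])
        with pytest.raises(ValueError):
            CallContour(times=[0.0, 0.0], frequencies=[25_000.0, 25_000.0])
        with pytest.raises(ValueError):
            CallContour(times=[0.1, 0.2], frequencies=[25_000.0, 25_000.0])  # first != 0
        with pytest.raises(ValueError):
            CallContour(times=[0.0, 0.1], frequencies=[25_000.0, 130_000.0])

    def test_session_meta_validation(self):
        with pytest.raises(ValueError):
            SessionMeta(rat_id="r", session_id="s", shock_times=(10.0, 5.0))
        with pytest.raises(ValueError):
            SessionMeta(rat_id="r", session_id="s", shock_times=(5000.0,), session_length=100.0)
        with pytest.raises(ValueError):
            SessionMeta(
                rat_id="r",
                session_id="s",
                attenuation_profile=((40_000.0, 10.0), (20_000.0, 0.0)),
            )

    def test_motion_series_validation(self):
        with pytest.raises(ValueError):
            MotionSeries(values=np.array([1.0, -2.0]))
        assert MotionSeries(values=np.zeros(300)).duration == pytest.approx(10.0)


class TestReadCallTable:
    def test_native_roundtrip_identity(self, tmp_path):
        records = [
            make_record(call_id=f"c{i}", onset=i * 1.0, peak_frequency=25_000.0 + i)
            for i in range(3)
        ]
        path = tmp_path / "calls.csv"
        write_call_table(records, path)
        back, _ = read_call_table(path)
        assert len(back) == 3
        assert [r.onset for r in back] == sorted(r.onset for r in back)
        assert back == records

    def test_avisoft_unit_conversion(self, tmp_path):
        path = tmp_path / "avi.csv"
        path.write_text(
            "id,start_ms,duration_ms,peakfreq_khz,meanpower_db\n" "a1,1000,250,42.4,-50\n"
        )
        records, _ = read_call_table(path, dialect="avisoft_like")
        assert records[0].duration == pytest.approx(0.250)
        assert records[0].peak_frequency == pytest.approx(42_400.0)
        assert records[0].onset == pytest.approx(1.0)

    def test_deepsqueak_units(self, tmp_path):
        path = tmp_path / "ds.csv"
        path.write_text(
            "ID,Begin Time (s),Call Length (s),Peak Freq (kHz),Mean Power (dB/Hz)\n"
            "1,2.5,0.3,44.1,-60\n"
        )
        records, _ = read_call_table(path, dialect="deepsqueak_like")
        assert records[0].onset == pytest.approx(2.5)
        assert records[0].peak_frequency == pytest.approx(44_100.0)

    def test_unsorted_input_sorted_stably(self, tmp_path):
        # hand-sorted oracle: rows at onsets 5, 1, 3, 1, 2 -> 1(row2), 1(row4), 2, 3, 5
        path = tmp_path / "unsorted.csv"
        rows = [("a", 5.0), ("b", 1.0), ("c", 3.0), ("d", 1.0), ("e", 2.0)]
        path.write_text(
            "call_id,rat_id,session_id,onset_s,duration_s,peak_freq_hz,mean_power_db,call_type,subtype\n"
            + "".join(f"{cid},r,s,{t},0.1,25000,,unknown,\n" for cid, t in rows)
        )
        records, _ = read_call_table(path)
        assert [r.call_id for r in records] == ["b", "d", "e", "c", "a"]

    def test_missing_column_names_it(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("call_id,onset_s,peak_freq_hz\nc1,0.0,25000\n")
        with pytest.raises(CallTableFormatError, match="duration_s"):
            read_call_table(path)

    def test_negative_duration_row_error(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text(
            "call_id,rat_id,session_id,onset_s,duration_s,peak_freq_hz,mean_power_db,call_type,subtype\n"
            "c1,r,s,0.0,-0.5,25000,,unknown,\n"
        )
        with pytest.raises(RowValidationError, match="row 0"):
            read_call_table(path)

    def test_non_numeric_row_error(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text(
            "call_id,rat_id,session_id,onset_s,duration_s,peak_freq_hz,mean_power_db,call_type,subtype\n"
            "c1,r,s,0.0,abc,25000,,unknown,\n"
        )
        with pytest.raises(RowValidationError, match="non-numeric"):
            read_call_table(path)

    def test_unknown_columns_preserved(self, tmp_path):
        path = tmp_path / "extra.csv"
        path.write_text(
            "call_id,rat_id,session_id,onset_s,duration_s,peak_freq_hz,mean_power_db,call_type,subtype,note\n"
            "c1,r,s,0.0,0.5,25000,,unknown,,hello\n"
        )
        records, _ = read_call_table(path)
        assert records[0].annotations["note"] == "hello"
        out = tmp_path / "out.csv"
        write_call_table(records, out)
        back, _ = read_call_table(out)
        assert back[0].annotations["note"] == "hello"


class TestWriteCallTable:
    def test_empty_header_only(self, tmp_path):
        path = tmp_path / "empty.csv"
        write_call_table([], path)
        lines = path.read_text().strip().splitlines()
        assert len(lines) == 1
        assert lines[0].startswith("call_id,")

    def test_single_record_roundtrip(self, tmp_path):
        rec = make_record(mean_power=-52.5, call_type=CallType.LONG22)
        path = tmp_path / "one.csv"
        write_call_table([rec], path)
        back, _ = read_call_table(path)
        assert back == [rec]

    def test_repeated_writes_byte_identical(self, tmp_path, small_cohort):
        records = [r for r in small_cohort.sessions[0][1][:100]]
        p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
        write_call_table(records, p1)
        write_call_table(records, p2)
        assert p1.read_bytes() == p2.read_bytes()


# hypothesis: native-dialect round-trip identity on arbitrary valid records
_valid_record = st.builds(
    make_record,
    call_id=st.text(alphabet="abcdefgh0123456789", min_size=1, max_size=8),
    onset=st.floats(min_value=0.0, max_value=3000.0, allow_nan=False),
    duration=st.floats(min_value=1e-3, max_value=5.0, allow_nan=False),
    peak_frequency=st.floats(min_value=1.0, max_value=124_999.0, allow_nan=False),
    mean_power=st.one_of(st.none(), st.floats(min_value=-120, max_value=0, allow_nan=False)),
)


@settings(max_examples=25, deadline=None)
@given(records=st.lists(_valid_record, max_size=8))
def test_native_roundtrip_property(tmp_path_factory, records):
    # distinct ids keep the comparison well-defined after the stable sort
    records = [
        make_record(
            call_id=f"id{i}",
            onset=r.onset,
            duration=r.duration,
            peak_frequency=r.peak_frequency,
            mean_power=r.mean_power,
        )
        for i, r in enumerate(records)
    ]
    path = tmp_path_factory.mktemp("rt") / "calls.csv"
    write_call_table(records, path)
    back, _ = read_call_table(path)
    assert back == sorted(records, key=lambda r: r.onset)


class TestContourSidecar:
    def test_roundtrip(self, tmp_path):
        c = flat_contour(25_000.0, jitter=100.0, seed=3)
        rec = make_record(contour=c)
        path = tmp_path / "contours.csv"
        write_contours([rec, make_record(call_id="c1")], path)
        back = read_contours(path)
        assert set(back) == {"c0"}
        assert np.allclose(back["c0"].times, c.times)
        assert np.allclose(back["c0"].frequencies, c.frequencies)

    def test_attach(self, tmp_path):
        c = flat_contour(25_000.0)
        recs = attach_contours([make_record()], {"c0": c})
        assert recs[0].contour == c


class TestMotionSeries:
    def test_zeros(self, tmp_path):
        path = tmp_path / "m.csv"
        path.write_text("0\n" * 300)
        series = read_motion_series(path, frame_rate=30.0)
        assert len(series) == 300
        assert series.duration == pytest.approx(10.0)
        assert np.all(series.values == 0)

    def test_alternating_preserved(self, tmp_path):
        path = tmp_path / "m.csv"
        path.write_text("0\n100\n" * 5)
        series = read_motion_series(path)
        assert np.array_equal(series.values, np.tile([0.0, 100.0], 5))

    def test_blank_line_error_names_line(self, tmp_path):
        path = tmp_path / "m.csv"
        path.write_text("0\n1\n\n2\n")
        with pytest.raises(RowValidationError, match="line 3"):
            read_motion_series(path)

    def test_negative_error(self, tmp_path):
        path = tmp_path / "m.csv"
        path.write_text("0\n-5\n")
        with pytest.raises(RowValidationError, match="negative"):
            read_motion_series(path)

    def test_write_read_roundtrip(self, tmp_path):
        series = MotionSeries(values=np.array([0.0, 17.5, 100.0]), frame_rate=30.0)
        path = tmp_path / "m.csv"
        write_motion_series(series, path)
        back = read_motion_series(path)
        assert np.array_equal(back.values, series.values)


class TestSessionMetaIO:
    def test_roundtrip(self, tmp_path, simple_meta):
        path = tmp_path / "session.cfg"
        write_session_meta(simple_meta, path)
        back = read_session_meta(path)
        assert back == simple_meta

    def test_missing_key(self, tmp_path):
        path = tmp_path / "session.cfg"
        path.write_text("rat_id=r1\n")
        with pytest.raises(CallTableFormatError, match="session_id"):
            read_session_meta(path)
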