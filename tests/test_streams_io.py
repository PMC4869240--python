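import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from awarelift import (DailySeries, normalize_series, read_panel,
                       validate_series, write_panel)
from awarelift.errors import (DegenerateInputError, PanelFormatError,
                              StreamDataError)


class TestNormalize:
    def test_per_million(self):
        s = normalize_series([5, 10], [1_000_000, 2_000_000], "per_million")
        assert np.allclose(s.values, [5.0, 5.0])

    def test_rsv_rescales_max_to_100(self):
        s = normalize_series([0.001, 0.002, 0.004], kind="rsv")
        assert np.allclose(s.values, [25.0, 50.0, 100.0])

    def test_raw_count_identity(self):
        s = normalize_series([12, 0, 7], kind="raw_count")
        assert list(s.values) == [12, 0, 7]

    def test_proportion(self):
        s = normalize_series([1, 2], [10, 10], "proportion")
        assert np.allclose(s.values, [0.1, 0.2])

    def test_raw_count_rejects_denominator(self):
        with pytest.raises(ValueError, match="no denominator"):
            normalize_series([1], [1], "raw_count")

    def test_zero_denominator_names_the_day(self):
        dates = pd.date_range("2020-03-01", periods=3, freq="D")
        with pytest.raises(StreamDataError, match="2020-03-02"):
            normalize_series([1, 1, 1], [5, 0, 5], "proportion", dates=dates)

    def test_all_zero_rsv_is_degenerate(self):
        with pytest.raises(DegenerateInputError):
            normalize_series([0, 0, 0], kind="rsv")

    def test_rsv_integer_dialect(self):
        s = normalize_series([1, 2, 3], kind="rsv", round_rsv=True)
        assert list(s.values) == [33.0, 67.0, 100.0]

    @given(st.floats(min_value=1e-6, max_value=1e6),
           st.lists(st.floats(min_value=1e-9, max_value=1.0), min_size=2, max_size=20))
    @settings(deadline=None, max_examples=50)
    def test_rsv_scale_invariance(self, c, props):
        a = normalize_series(props, kind="rsv").values
        b = normalize_series([c * p for p in props], kind="rsv").values
        assert np.allclose(a, b, rtol=1e-9)


class TestValidate:
    def test_proportion_out_of_range(self):
        dates = pd.date_range("2020-01-01", periods=2, freq="D")
        s = DailySeries(dates, [0.5, 0.9], "raw_count", "x")
        bad = DailySeries(dates, [0.5, 0.9], "proportion", "x")
        assert validate_series(s).ok and validate_series(bad).ok
        forced = DailySeries.__new__(DailySeries)
        object.__setattr__(forced, "dates", dates)
        object.__setattr__(forced, "values", np.array([0.5, 1.2]))
        object.__setattr__(forced, "kind", "proportion")
        object.__setattr__(forced, "label", "x")
        report = validate_series(forced)
        assert not report.ok and "proportion out of [0,1]" in report.message

    def test_rsv_max_must_be_100(self):
        dates = pd.date_range("2020-01-01", periods=2, freq="D")
        ok = DailySeries(dates, [50.0, 100.0], "rsv", "x")
        assert validate_series(ok).ok
        with pytest.raises(StreamDataError, match="rsv maximum"):
            DailySeries(dates, [50.0, 90.0], "rsv", "x")

    def test_gap_is_reported_with_first_missing_date(self):
        forced = DailySeries.__new__(DailySeries)
        object.__setattr__(forced, "dates",
                           pd.DatetimeIndex(["2020-01-01", "2020-01-03"]))
        object.__setattr__(forced, "values", np.array([1.0, 2.0]))
        object.__setattr__(forced, "kind", "raw_count")
        object.__setattr__(forced, "label", "x")
        report = validate_series(forced)
        assert not report.ok and "2020-01-02" in report.message


class TestPanelIO:
    def _write(self, tmp_path, rows):
        path = tmp_path / "panel.csv"
        path.write_text("date,stream,kind,value\n" + "\n".join(rows) + "\n")
        return path

    def test_two_streams_three_days(self, tmp_path):
        rows = [f"2020-01-0{d},{s},raw_count,{v}"
                for d, v in [(1, 3), (2, 4), (3, 5)] for s in ("a", "b")]
        panel = read_panel(self._write(tmp_path, rows))
        assert set(panel) == {"a", "b"}
        assert all(len(s) == 3 for s in panel.values())

    def test_gap_rejected(self, tmp_path):
        path = self._write(tmp_path, ["2020-01-01,a,raw_count,1",
                                      "2020-01-03,a,raw_count,2"])
        with pytest.raises(StreamDataError, match="2020-01-02"):
            read_panel(path)

    def test_negative_value_rejected(self, tmp_path):
        path = self._write(tmp_path, ["2020-01-01,a,raw_count,-1"])
        with pytest.raises(StreamDataError, match="negative"):
            read_panel(path)

    def test_duplicate_rejected(self, tmp_path):
        path = self._write(tmp_path, ["2020-01-01,a,raw_count,1",
                                      "2020-01-01,a,raw_count,2"])
        with pytest.raises(StreamDataError, match="duplicate"):
            read_panel(path)

    def test_missing_column_is_format_error(self, tmp_path):
        path = tmp_path / "panel.csv"
        path.write_text("date,stream,value\n2020-01-01,a,1\n")
        with pytest.raises(PanelFormatError, match="kind"):
            read_panel(path)

    def test_round_trip_preserves_full_precision(self, tmp_path):
        dates = pd.date_range("2020-01-01", periods=5, freq="D")
        values = np.array([1 / 3, 2 / 7, 1e-9, 0.123456789012345, 5.0])
        panel = {"x": DailySeries(dates, values, "raw_count", "x")}
        path = tmp_path / "panel.csv"
        write_panel(panel, path)
        again = read_panel(path)
        assert np.array_equal(again["x"].values, values)
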