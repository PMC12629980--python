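import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dendrodate.series_io import (
    Chronology,
    RingSeries,
    SeriesFormatError,
    SeriesValidationError,
    read_series,
    write_series,
    year_span,
)

# Hand-written Tucson fixture: 12 rings, 1500-1511, 0.01 mm storage.
# Decoded by hand against the decade-row layout: the first row carries the
# decade 1500-1509, the second row 1510-1511 followed by the 999 stop marker.
RWL_FIXTURE = """\
TST     1500   100   110   120   130   140   150   160   170   180   190
TST     1510   200   210   999
"""

RWL_THOUSANDTH = """\
DEEP    1795   321   280   305   299   310
DEEP    1800   415   399   402   388   371   365   342   330   311   305
DEEP    1810   301 -9999
"""


class TestTucson:
    def test_hand_decoded_fixture(self, tmp_path):
        p = tmp_path / "t.rwl"
        p.write_text(RWL_FIXTURE)
        (s,) = read_series(p)
        assert s.n == 12
        assert (s.first_ring_year, s.last_ring_year) == (1500, 1511)
        assert s.units_raw == 0.01
        np.testing.assert_allclose(s.widths[0], 1.00)
        np.testing.assert_allclose(s.widths[-1], 2.10)

    def test_thousandth_marker_sets_unit(self, tmp_path):
        p = tmp_path / "t.rwl"
        p.write_text(RWL_THOUSANDTH)
        (s,) = read_series(p)
        assert s.units_raw == 0.001
        assert s.n == 16
        assert (s.first_ring_year, s.last_ring_year) == (1795, 1810)
        np.testing.assert_allclose(s.widths[0], 0.321)

    def test_999_is_data_under_explicit_thousandth_unit(self, tmp_path):
        p = tmp_path / "t.rwl"
        p.write_text("X       1500   999   500   400 -9999\n")
        (s,) = read_series(p, unit=0.001)
        assert s.n == 3
        np.testing.assert_allclose(s.widths[0], 0.999)

    def test_missing_marker_is_ambiguous(self, tmp_path):
        p = tmp_path / "t.rwl"
        p.write_text("X       1500   100   110   120\n")
        with pytest.raises(SeriesFormatError, match="unit"):
            read_series(p)
        (s,) = read_series(p, unit=0.01)
        assert s.n == 3

    def test_broken_decade_continuity_names_line(self, tmp_path):
        p = tmp_path / "t.rwl"
        p.write_text(
            "X       1500   100   110   120   130   140   150   160   170   180   190\n"
            "X       1520   200   999\n"
        )
        with pytest.raises(SeriesFormatError, match="line 2"):
            read_series(p)

    def test_non_positive_width_rejected(self, tmp_path):
        p = tmp_path / "t.rwl"
        p.write_text("X       1500   100     0   120   999\n")
        with pytest.raises(SeriesValidationError, match="non-positive"):
            read_series(p)

    def test_wide_value_refused_in_hundredth_storage(self, tmp_path):
        s = RingSeries("BIG", np.array([1.0, 2.0, 12.5]), 1502, units_raw=0.01)
        with pytest.raises(SeriesValidationError, match="0.001"):
            write_series([s], tmp_path / "t.rwl")

    def test_year_capacity(self, tmp_path):
        s = RingSeries("FAR", np.ones(5), 10001)
        with pytest.raises(SeriesValidationError, match="capacity"):
            write_series([s], tmp_path / "t.rwl")


@pytest.mark.parametrize("fmt,unit", [("rwl", 0.01), ("rwl", 0.001),
                                      ("heidelberg", 0.01), ("heidelberg", 0.001),
                                      ("csv", 0.01)])
def test_round_trip_exact(tmp_path, fmt, unit):
    rng = np.random.default_rng(5)
    raw = rng.integers(20, 400, size=37)
    s = RingSeries("RT1", raw * unit, 1650, n_sapwood=9 if fmt == "heidelberg" else 0,
                   units_raw=unit)
    path = tmp_path / f"rt.{ {'rwl': 'rwl', 'heidelberg': 'fh', 'csv': 'csv'}[fmt] }"
    write_series([s], path, format=fmt)
    (back,) = read_series(path, format=fmt)
    np.testing.assert_allclose(back.widths, s.widths)
    assert back.last_ring_year == s.last_ring_year
    assert back.n == s.n
    if fmt == "heidelberg":
        assert back.n_sapwood == 9


@settings(max_examples=30, derandomize=True, deadline=None)
@given(
    n=st.integers(5, 120),
    start=st.integers(1000, 1900),
    unit=st.sampled_from([0.01, 0.001]),
    data=st.data(),
)
def test_round_trip_property(tmp_path_factory, n, start, unit, data):
    """Write-then-read preserves widths exactly at the source precision."""
    vals = data.draw(st.lists(st.integers(1, 900), min_size=n, max_size=n))
    s = RingSeries("PROP", np.array(vals) * unit, start + n - 1, units_raw=unit)
    path = tmp_path_factory.mktemp("rt") / "p.rwl"
    write_series([s], path)
    (back,) = read_series(path)
    np.testing.assert_allclose(back.widths, s.widths)
    assert back.first_ring_year == start
    assert year_span(back.first_ring_year, back.last_ring_year) == back.n


def test_empty_list_round_trips(tmp_path):
    p = tmp_path / "e.rwl"
    write_series([], p)
    assert read_series(p) == []


def test_replication_series_spans(tmp_path):
    """A 99-ring series 1503-1601 and a 210-row CSV 1397-1606 decode with the
    stated inclusive spans."""
    s = RingSeries("MH", np.linspace(0.5, 2.0, 99), 1601)
    write_series([s], tmp_path / "mh.rwl")
    (back,) = read_series(tmp_path / "mh.rwl")
    assert back.n == 99 and back.first_ring_year == 1503

    years = np.arange(1397, 1607)
    lines = ["year,width_mm"] + [f"{y},{1 + 0.001 * i}" for i, y in enumerate(years)]
    p = tmp_path / "gnm.csv"
    p.write_text("\n".join(lines) + "\n")
    (c,) = read_series(p)
    assert c.n == 210
    assert (c.first_ring_year, c.last_ring_year) == (1397, 1606)


def test_csv_rejects_gaps(tmp_path):
    p = tmp_path / "g.csv"
    p.write_text("year,width_mm\n1500,1.0\n1502,1.1\n")
    with pytest.raises(SeriesFormatError, match="consecutive"):
        read_series(p)


@pytest.mark.parametrize(
    "first,last,expected", [(1397, 1606, 210), (1503, 1601, 99), (1850, 1850, 1)]
)
def test_year_span(first, last, expected):
    assert year_span(first, last) == expected


def test_year_span_reversed():
    with pytest.raises(ValueError):
        year_span(1606, 1397)


class TestValidation:
    def test_border_flag_excludes_sapwood(self):
        with pytest.raises(SeriesValidationError):
            RingSeries("X", np.ones(10), 1600, n_sapwood=3,
                       hw_sw_border_is_last_ring=True)

    def test_sapwood_bounded_by_length(self):
        with pytest.raises(SeriesValidationError):
            RingSeries("X", np.ones(10), 1600, n_sapwood=11)

    def test_chronology_depth_length(self):
        with pytest.raises(SeriesValidationError):
            Chronology("C", np.ones(10), 1600, replication_depth=np.ones(9, dtype=int))
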