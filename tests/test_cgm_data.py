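import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from glucast.cgm_data import (
    GlucoseSeries,
    SplitSpec,
    chronological_split,
    concat_windows,
    make_windows,
    read_csv,
    read_ohio_xml,
    scale,
    unscale,
    window_values,
    write_csv,
)

from conftest import brute_force_window_starts, random_gapped_series


def _write_xml(tmp_path, events, patient="559"):
    rows = "\n".join(f'    <event ts="{ts}" value="{v}"/>' for ts, v in events)
    path = tmp_path / "patient.xml"
    path.write_text(
        f'<patient id="{patient}">\n  <glucose_level>\n{rows}\n'
        "  </glucose_level>\n</patient>\n"
    )
    return path


class TestOhioXML:
    def test_reads_events_in_order(self, tmp_path):
        path = _write_xml(tmp_path, [
            ("07-12-2021 01:00:00", "100"),
            ("07-12-2021 01:05:00", "110"),
            ("07-12-2021 01:10:00", "120"),
        ])
        series = read_ohio_xml(path)
        assert series.patient_id == "559"
        assert len(series) == 3
        np.testing.assert_array_equal(series.values, [100, 110, 120])
        np.testing.assert_array_equal(series.step_seconds, [300, 300])

    def test_sorts_out_of_order_events(self, tmp_path):
        path = _write_xml(tmp_path, [
            ("07-12-2021 01:10:00", "120"),
            ("07-12-2021 01:00:00", "100"),
            ("07-12-2021 01:05:00", "110"),
        ])
        series = read_ohio_xml(path)
        np.testing.assert_array_equal(series.values, [100, 110, 120])

    @pytest.mark.parametrize("bad_value", ["abc", "-17", "0"])
    def test_rejects_bad_values(self, tmp_path, bad_value):
        path = _write_xml(tmp_path, [("07-12-2021 01:00:00", bad_value)])
        with pytest.raises(ValueError):
            read_ohio_xml(path)

    def test_malformed_xml_names_problem(self, tmp_path):
        path = tmp_path / "broken.xml"
        path.write_text("<patient><glucose_level><event")
        with pytest.raises(ValueError, match="malformed XML"):
            read_ohio_xml(path)

    def test_empty_series_rejected(self, tmp_path):
        path = _write_xml(tmp_path, [])
        with pytest.raises(ValueError, match="no glucose events"):
            read_ohio_xml(path)


class TestSeriesAndScaling:
    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            GlucoseSeries.from_values([100, 0, 120])  # non-positive
        with pytest.raises(ValueError):
            GlucoseSeries.from_values([100, 700])  # above 600
        ts = np.array(["2024-01-01T00:05", "2024-01-01T00:00"], dtype="datetime64[s]")
        with pytest.raises(ValueError, match="strictly increasing"):
            GlucoseSeries(patient_id="x", timestamps=ts, values=np.array([100.0, 110.0]))

    def test_scale_is_hundredth(self):
        assert scale(np.array([100.0]))[0] == pytest.approx(1.0)

    def test_scale_roundtrip_exact(self):
        vals = np.array([87.0, 342.0])
        np.testing.assert_allclose(unscale(scale(vals)), vals, rtol=1e-15)

    def test_csv_roundtrip(self, tmp_path):
        series = GlucoseSeries.from_values([90, 110, 130], patient_id="p1")
        path = tmp_path / "p1.csv"
        write_csv(series, path)
        back = read_csv(path, patient_id="p1")
        np.testing.assert_array_equal(back.values, series.values)
        np.testing.assert_array_equal(back.timestamps, series.timestamps)


class TestWindowing:
    def test_gap_free_counts(self):
        series = GlucoseSeries.from_values(np.linspace(80, 200, 20))
        ds = make_windows(series, history_minutes=60, horizon_minutes=30)
        assert len(ds) == 3  # n - h - d + 1 = 20 - 12 - 6 + 1
        assert ds.X.shape == (3, 12)

    def test_too_short_series_yields_empty(self):
        series = GlucoseSeries.from_values(np.full(17, 100.0))
        ds = make_windows(series, 60, 30)
        assert len(ds) == 0

    def test_window_contents_and_scaling(self):
        series = GlucoseSeries.from_values(np.arange(100, 120, dtype=float))
        ds = make_windows(series, 60, 30)
        # first window: samples 0..11 history, target at index 17
        np.testing.assert_allclose(ds.X[0], np.arange(100, 112) * 0.01)
        assert ds.y[0] == pytest.approx(117 * 0.01)
        assert ds.target_raw[0] == 117
        assert ds.last_history_raw[0] == pytest.approx(111)

    def test_gap_drops_crossing_windows(self, ):
        rng = np.random.default_rng(7)
        n = 30
        steps = np.full(n - 1, 300, np.int64)
        steps[15] = 600  # 10-minute hole between samples 15 and 16
        ts = np.datetime64("2024-01-01", "s") + np.concatenate(
            [[0], np.cumsum(steps)]).astype("timedelta64[s]")
        series = GlucoseSeries("p", ts, rng.uniform(80, 200, n))
        ds = make_windows(series, 60, 30)
        expected = brute_force_window_starts(series, 12, 6)
        assert len(ds) == len(expected)

    @pytest.mark.parametrize("case_seed", range(25))
    def test_matches_brute_force_on_random_gapped_series(self, case_seed):
        rng = np.random.default_rng(1000 + case_seed)
        series = random_gapped_series(rng, n=int(rng.integers(40, 120)))
        h_min, d_min = 30, 15
        ds = make_windows(series, h_min, d_min)
        starts = brute_force_window_starts(series, h_min // 5, d_min // 5)
        assert len(ds) == len(starts)
        for row, s in zip(ds.X, starts):
            np.testing.assert_allclose(row, series.values[s : s + 6] * 0.01)

    def test_emitted_windows_have_no_bad_interval(self):
        rng = np.random.default_rng(5)
        series = random_gapped_series(rng, n=200)
        ds = make_windows(series, 60, 30)
        sec = series.timestamps.astype("int64")
        lookup = {int(t): i for i, t in enumerate(sec)}
        for t_time in ds.target_times:
            t_idx = lookup[int(t_time.astype("int64"))]
            span = sec[t_idx - 17 : t_idx + 1]
            assert np.all(np.abs(np.diff(span) - 300) <= 60)

    def test_inserting_gap_never_increases_count(self):
        rng = np.random.default_rng(11)
        values = rng.uniform(80, 200, 60)
        series = GlucoseSeries.from_values(values)
        base = len(make_windows(series, 60, 30))
        for pos in (5, 20, 40):
            steps = np.full(59, 300, np.int64)
            steps[pos] = 1800
            ts = np.datetime64("2024-01-01", "s") + np.concatenate(
                [[0], np.cumsum(steps)]).astype("timedelta64[s]")
            gapped = GlucoseSeries("p", ts, values)
            assert len(make_windows(gapped, 60, 30)) <= base

    @given(n=st.integers(1, 80), h=st.integers(1, 8), d=st.integers(1, 6))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_gap_free_closed_form(self, n, h, d):
        series = GlucoseSeries.from_values(np.full(n, 120.0))
        ds = make_windows(series, 5 * h, 5 * d)
        assert len(ds) == max(0, n - h - d + 1)

    @pytest.mark.parametrize("bad", [(-5, 30), (0, 30), (7, 30), (60, -5)])
    def test_bad_arguments_rejected(self, bad):
        series = GlucoseSeries.from_values(np.full(30, 120.0))
        with pytest.raises(ValueError):
            make_windows(series, bad[0], bad[1])

    def test_negative_tolerance_rejected(self):
        series = GlucoseSeries.from_values(np.full(30, 120.0))
        with pytest.raises(ValueError, match="tolerance"):
            make_windows(series, 60, 30, tolerance_seconds=-1)

    def test_window_values_matches_make_windows_on_gap_free(self):
        vals = np.arange(100, 140, dtype=float)
        ds_a = window_values(vals, 12, 6, scale_factor=0.01)
        ds_b = make_windows(GlucoseSeries.from_values(vals), 60, 30)
        np.testing.assert_allclose(ds_a.X, ds_b.X)
        np.testing.assert_allclose(ds_a.y, ds_b.y)


class TestSplit:
    def test_60_20_20_counts(self):
        series = GlucoseSeries.from_values(np.full(100, 120.0))
        segs = chronological_split(series, SplitSpec((0.6, 0.2, 0.2)))
        assert [len(s) for s in segs] == [60, 20, 20]

    def test_remainder_goes_to_last_segment(self):
        series = GlucoseSeries.from_values(np.full(101, 120.0))
        segs = chronological_split(series, SplitSpec((0.8, 0.2)))
        assert [len(s) for s in segs] == [80, 21]

    def test_empty_segment_is_an_error(self):
        series = GlucoseSeries.from_values(np.full(3, 120.0))
        with pytest.raises(ValueError, match="empty segment"):
            chronological_split(series, SplitSpec((0.6, 0.2, 0.2)))

    def test_split_spec_validation(self):
        with pytest.raises(ValueError):
            SplitSpec((0.5, 0.2))
        with pytest.raises(ValueError):
            SplitSpec((1.2, -0.2))

    def test_pooling_preserves_per_patient_chronology(self):
        rng = np.random.default_rng(3)
        patients = [
            GlucoseSeries.from_values(rng.uniform(80, 200, 100),
                                      start="2024-01-01", patient_id="a"),
            GlucoseSeries.from_values(rng.uniform(80, 200, 90),
                                      start="2024-02-01", patient_id="b"),
        ]
        spec = SplitSpec((0.6, 0.2, 0.2))
        pooled = [
            concat_windows([make_windows(chronological_split(p, spec)[0], 30, 15)
                            for p in patients])
        ][0]
        for pid in ("a", "b"):
            times = pooled.target_times[pooled.patient_ids == pid]
            assert np.all(np.diff(times).astype("timedelta64[s]").astype(int) > 0)

    def test_windows_do_not_straddle_split_boundary(self):
        series = GlucoseSeries.from_values(np.arange(60, 160, dtype=float))
        segs = chronological_split(series, SplitSpec((0.6, 0.2, 0.2)))
        n_total = sum(len(make_windows(s, 30, 15)) for s in segs)
        # three segments of 60/20/20 each lose h+d-1 = 8 window positions
        assert n_total == (60 - 8) + (20 - 8) + (20 - 8)
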