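import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fogkit import (DetectionParams, Episode, FiSeries, FogcParams,
                    FogcSeries, detect_events, make_stride, match_events,
                    report_table)
from fogkit.events import report_from_csv, report_to_csv


def fi_series(fi, hop=0.1, threshold=0.1, flagged=None):
    fi = np.asarray(fi, float)
    t = 3.0 + hop * np.arange(len(fi))
    if flagged is None:
        flagged = np.zeros(len(fi), dtype=bool)
    return FiSeries(t=t, fi=fi, flagged=flagged, window_s=6.0,
                    threshold=threshold)


def brute_force_fi_events(series, threshold, merge_gap_s, min_duration_s):
    """Independent run-scan: literal loop over points, then merge, then drop."""
    hop = series.t[1] - series.t[0] if len(series.t) > 1 else 0.0
    runs, cur = [], None
    for i in range(len(series.t)):
        hit = series.fi[i] > threshold and not series.flagged[i]
        if hit and cur is None:
            cur = [series.t[i] - hop / 2, series.t[i] + hop / 2]
        elif hit:
            cur[1] = series.t[i] + hop / 2
        elif cur is not None:
            runs.append(cur)
            cur = None
    if cur is not None:
        runs.append(cur)
    merged = []
    for r in runs:
        if merged and r[0] - merged[-1][1] < merge_gap_s:
            merged[-1][1] = r[1]
        else:
            merged.append(r)
    return [tuple(r) for r in merged if r[1] - r[0] >= min_duration_s]


class TestDetectFi:
    def test_all_below_threshold_gives_no_events(self):
        assert detect_events(fi_series([0.01] * 50)) == []

    def test_single_run_becomes_one_event(self):
        fi = np.full(100, 0.01)
        fi[30:50] = 1.0  # t in [6.0, 7.9]
        events = detect_events(fi_series(fi))
        assert len(events) == 1
        assert events[0].start == pytest.approx(5.95)
        assert events[0].end == pytest.approx(7.95)
        assert events[0].source == "FI"
        assert events[0].peak_value == pytest.approx(1.0)

    def test_nearby_runs_merge(self):
        fi = np.full(120, 0.01)
        fi[20:40] = 1.0
        fi[43:70] = 1.0  # 0.3 s gap < merge_gap 0.5
        events = detect_events(fi_series(fi),
                               params=DetectionParams(merge_gap_s=0.5))
        assert len(events) == 1

    def test_sub_minimum_duration_dropped(self):
        fi = np.full(100, 0.01)
        fi[30:32] = 1.0  # 0.2 s event < 0.5 s floor
        assert detect_events(fi_series(fi)) == []

    def test_flagged_windows_never_become_events(self):
        fi = np.full(80, 5.0)
        flagged = np.ones(80, dtype=bool)
        assert detect_events(fi_series(fi, flagged=flagged)) == []

    @given(st.data())
    @settings(max_examples=50, deadline=None)
    def test_equivalence_with_brute_force_scan(self, data):
        n = data.draw(st.integers(min_value=1, max_value=300))
        fi = np.array(data.draw(st.lists(
            st.sampled_from([0.0, 0.05, 0.2, 1.0]), min_size=n, max_size=n)))
        series = fi_series(fi)
        # off-grid values avoid float ties at run boundaries
        params = DetectionParams(merge_gap_s=0.55, min_duration_s=0.55)
        got = [(e.start, e.end) for e in detect_events(series, params=params)]
        want = brute_force_fi_events(series, 0.1, 0.55, 0.55)
        assert len(got) == len(want)
        for g, w in zip(got, want):
            assert g[0] == pytest.approx(w[0])
            assert g[1] == pytest.approx(w[1])

    def test_large_array_matches_brute_force(self):
        rng = np.random.default_rng(42)
        fi = rng.choice([0.0, 1.0], size=100_000, p=[0.7, 0.3])
        series = fi_series(fi)
        # off-grid values avoid float ties at run boundaries
        params = DetectionParams(merge_gap_s=0.55, min_duration_s=0.55)
        got = [(e.start, e.end) for e in detect_events(series, params=params)]
        want = brute_force_fi_events(series, 0.1, 0.55, 0.55)
        assert np.allclose(np.asarray(got), np.asarray(want))


class TestDetectFogc:
    def test_single_above_threshold_stride_is_an_event(self):
        from fogkit import compute_fogc_series
        strides = [make_stride(0, 100, 100.0, L_n=2.0),
                   make_stride(100, 150, 100.0, L_n=0.01),
                   make_stride(150, 250, 100.0, L_n=2.0)]
        series = compute_fogc_series(strides, FogcParams())
        events = detect_events(series)
        assert len(events) == 1
        assert events[0].start == pytest.approx(1.0)
        assert events[0].end == pytest.approx(1.5)
        assert events[0].source == "FOGC"

    def test_freeze_gap_after_threshold_crossing_is_bridged(self):
        from fogkit import compute_fogc_series
        fs = 100.0
        strides = [make_stride(0, 100, fs, L_n=2.0),
                   make_stride(100, 150, fs, L_n=0.01),  # fires, then 5 s gap
                   make_stride(650, 750, fs, L_n=2.0)]
        series = compute_fogc_series(strides, FogcParams())
        events = detect_events(series)
        assert len(events) == 1
        assert events[0].end == pytest.approx(6.5)  # start of the next stride

    def test_terminal_gap_extends_to_end_of_data(self):
        from fogkit import compute_fogc_series
        strides = [make_stride(0, 100, 100.0, L_n=0.01)]
        series = compute_fogc_series(strides, FogcParams())
        events = detect_events(series, t_end=10.0)
        assert len(events) == 1
        assert events[0].end == pytest.approx(10.0)

    def test_gap_after_quiet_stride_not_bridged(self):
        from fogkit import compute_fogc_series
        strides = [make_stride(0, 100, 100.0, L_n=0.01),
                   make_stride(100, 200, 100.0, L_n=2.0)]
        series = compute_fogc_series(strides, FogcParams())
        events = detect_events(series, t_end=30.0)
        assert len(events) == 1
        assert events[0].end == pytest.approx(1.0)


def ann(start, end, severity, etype="fog"):
    return Episode(start, end, etype, severity, "annotation")


def det(start, end, source="FI"):
    return Episode(start, end, "detection", None, source)


class TestMatching:
    def test_overlapping_detection_counts(self):
        rep = match_events([det(2.0, 2.5)], [ann(1, 3, "red")], tol_s=1.0)
        assert rep.n_detected["FI"]["red"] == 1
        assert rep.n_annotated["red"] == 1
        assert rep.false_positives["FI"] == 0

    def test_distant_detection_is_false_positive(self):
        rep = match_events([det(10, 11)], [ann(1, 3, "red")], tol_s=1.0)
        assert rep.n_detected["FI"]["red"] == 0
        assert rep.false_positives["FI"] == 1

    def test_one_detection_credits_both_overlapped_annotations(self):
        rep = match_events([det(2.0, 6.0)],
                           [ann(1, 3, "red"), ann(5, 7, "orange")], tol_s=0.0)
        assert rep.n_detected["FI"]["red"] == 1
        assert rep.n_detected["FI"]["orange"] == 1
        assert rep.false_positives["FI"] == 0

    @given(st.data())
    @settings(max_examples=60, deadline=None)
    def test_counts_match_all_pairs_brute_force(self, data):
        def intervals(n):
            out = []
            for _ in range(n):
                s = data.draw(st.floats(min_value=0, max_value=50))
                d = data.draw(st.floats(min_value=0.1, max_value=10))
                out.append((s, s + d))
            return out
        anns = [ann(s, e, data.draw(st.sampled_from(["green", "orange", "red"])))
                for s, e in intervals(data.draw(st.integers(0, 6)))]
        dets = [det(s, e) for s, e in intervals(data.draw(st.integers(0, 6)))]
        tol = data.draw(st.sampled_from([0.0, 0.5, 1.0, 2.0]))
        rep = match_events(dets, anns, tol_s=tol)
        for sev in ("green", "orange", "red"):
            expect = sum(
                1 for a in anns if a.severity == sev and any(
                    d.start <= a.end + tol and d.end >= a.start - tol
                    for d in dets))
            got = rep.n_detected.get("FI", {}).get(sev, 0)
            assert got == expect
        fp_expect = sum(
            1 for d in dets if not any(
                d.start <= a.end + tol and d.end >= a.start - tol for a in anns))
        if dets:
            assert rep.false_positives["FI"] == fp_expect
        else:
            assert rep.false_positives == {}

    def test_conservation_detected_plus_missed(self):
        anns = [ann(1, 3, "red"), ann(5, 6, "red"), ann(10, 12, "green")]
        rep = match_events([det(1.5, 2.0), det(20, 21)], anns, tol_s=0.5)
        for sev in ("green", "orange", "red"):
            n_det = rep.n_detected["FI"][sev]
            missed = rep.n_annotated[sev] - n_det
            assert missed >= 0
            assert n_det + missed == rep.n_annotated[sev]

    def test_widening_tolerance_never_loses_detections(self):
        anns = [ann(1, 3, "red"), ann(8, 9, "orange"), ann(15, 16, "green")]
        dets = [det(3.5, 4.0), det(7.0, 7.4), det(20, 22)]
        prev = None
        for tol in (0.0, 0.5, 1.0, 2.0, 5.0):
            rep = match_events(dets, anns, tol_s=tol)
            counts = [rep.n_detected["FI"][s] for s in ("green", "orange", "red")]
            if prev is not None:
                assert all(c >= p for c, p in zip(counts, prev))
            prev = counts


class TestReportTable:
    def test_empty_report_has_header_rows_only(self):
        rep = match_events([], [], tol_s=1.0)
        df = report_table(rep)
        assert list(df.columns) == ["Video"]
        assert df["Video"].sum() == 0

    def test_row_sums_conserve_annotations(self):
        anns = [ann(1, 3, "red"), ann(5, 6, "orange"), ann(10, 12, "green")]
        dets = [det(1.5, 2.0, "FI"), det(5.2, 5.8, "FOGC")]
        df = report_table(match_events(dets, anns, tol_s=0.5))
        sev_rows = df.loc[["Green", "Orange", "Red"]]
        assert sev_rows["Video"].sum() == len(anns)
        assert (sev_rows[["FI", "FOGC"]].to_numpy()
                <= sev_rows[["Video", "Video"]].to_numpy()).all()

    def test_csv_round_trip(self):
        anns = [ann(1, 3, "red"), ann(5, 6, "orange")]
        dets = [det(1.5, 2.0, "FI"), det(5.2, 5.8, "FOGC"), det(30, 31, "FI")]
        rep = match_events(dets, anns, tol_s=0.5)
        df = report_table(rep)
        back = report_from_csv(report_to_csv(rep))
        assert (back.to_numpy() == df.to_numpy()).all()
        assert list(back.columns) == list(df.columns)
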