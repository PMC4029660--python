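"""Turning detector series into events and scoring them against annotations.

FI events are maximal runs of above-threshold, unflagged windows; runs
separated by less than ``merge_gap_s`` are merged and events shorter than
``min_duration_s`` dropped (spectral blips).  FOGC events are runs of
above-threshold strides; a stride-free gap following an above-threshold
stride — gait has stopped right after the criterion fired, i.e. a complete
freeze — is bridged into the event, up to the next detected stride or the
end of the data.  FOGC events may be single strides (no duration floor).

Scoring is overlap-based: an annotated episode counts as detected if any
detection overlaps it once widened by ``tol_s`` on both sides; detections
overlapping no annotation are false positives.  Counts are stratified by
the clinician's severity label (green/orange/red).
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .errors import ValidationError
from .fogc import FogcSeries
from .freeze_index import FiSeries
from .io import SEVERITIES, Episode


@dataclass
class DetectionParams:
    """Event extraction and matching tunables (seconds)."""

    merge_gap_s: float = 0.5
    min_duration_s: float = 0.5
    freeze_gap_min_s: float = 1.0
    tol_s: float = 1.0


@dataclass
class EvaluationReport:
    """Severity-stratified detection accounting for one or more detectors."""

    n_annotated: dict = field(default_factory=dict)      # severity -> count
    n_detected: dict = field(default_factory=dict)       # detector -> severity -> count
    false_positives: dict = field(default_factory=dict)  # detector -> count
    matching_tolerance_s: float = 1.0

    def validate(self) -> None:
        for det, per_sev in self.n_detected.items():
            for sev in SEVERITIES:
                n_det = per_sev.get(sev, 0)
                n_ann = self.n_annotated.get(sev, 0)
                if not (0 <= n_det <= n_ann):
                    raise ValidationError(
                        f"{det}/{sev}: detected {n_det} of {n_ann} annotated"
                    )
        if any(v < 0 for v in self.false_positives.values()):
            raise ValidationError("false-positive counts must be non-negative")


def _merge_intervals(intervals: list[list], merge_gap_s: float) -> list[list]:
    """Merge [start, end, peak] triples whose gaps are below merge_gap_s."""
    if not intervals:
        return []
    merged = [intervals[0]]
    for start, end, peak in intervals[1:]:
        if start - merged[-1][1] < merge_gap_s:
            merged[-1][1] = max(merged[-1][1], end)
            merged[-1][2] = max(merged[-1][2], peak)
        else:
            merged.append([start, end, peak])
    return merged


def _detect_fi(series: FiSeries, threshold: float,
               params: DetectionParams) -> list[Episode]:
    above = (series.fi > threshold) & ~series.flagged
    if not above.any():
        return []
    hop = float(np.median(np.diff(series.t))) if len(series.t) > 1 else 0.0
    intervals = []
    idx = np.flatnonzero(above)
    run_start = idx[0]
    prev = idx[0]
    for i in list(idx[1:]) + [None]:
        if i is None or i != prev + 1:
            intervals.append([
                float(series.t[run_start]) - hop / 2.0,
                float(series.t[prev]) + hop / 2.0,
                float(series.fi[run_start:prev + 1].max()),
            ])
            run_start = i
        prev = i if i is not None else prev
    intervals = _merge_intervals(intervals, params.merge_gap_s)
    return [
        Episode(start=max(s, 0.0), end=e, etype="detection", source="FI",
                peak_value=p)
        for s, e, p in intervals
        if e - s >= params.min_duration_s
    ]


def _detect_fogc(series: FogcSeries, threshold: float, params: DetectionParams,
                 t_end: Optional[float]) -> list[Episode]:
    strides = series.strides
    above = series.fogc > threshold
    intervals: list[list] = []
    run: Optional[list] = None
    for n, stride in enumerate(strides):
        if above[n]:
            if run is None:
                run = [stride.t_start, stride.t_end, float(series.fogc[n])]
            else:
                run[1] = stride.t_end
                run[2] = max(run[2], float(series.fogc[n]))
            # bridge a trailing stride-free gap: gait stopped after the
            # criterion fired -> complete freeze, part of the same event
            nxt = strides[n + 1] if n + 1 < len(strides) else None
            if nxt is not None:
                gap = nxt.t_start - stride.t_end
                if gap >= params.freeze_gap_min_s:
                    run[1] = nxt.t_start
                    intervals.append(run)
                    run = None
            elif t_end is not None and t_end - stride.t_end >= params.freeze_gap_min_s:
                run[1] = t_end
        else:
            if run is not None:
                intervals.append(run)
                run = None
    if run is not None:
        intervals.append(run)
    intervals = _merge_intervals(intervals, params.merge_gap_s)
    return [
        Episode(start=s, end=e, etype="detection", source="FOGC", peak_value=p)
        for s, e, p in intervals
    ]


def detect_events(series: Union[FiSeries, FogcSeries],
                  threshold: Optional[float] = None,
                  params: Optional[DetectionParams] = None,
                  t_end: Optional[float] = None) -> list[Episode]:
    """Extract threshold-crossing events from a detector series.

    ``threshold`` defaults to the one carried by the series.  ``t_end``
    (end of the recording, s) lets a FOGC event that runs into a terminal
    stride-free gap extend to the end of the data.
    """
    params = params or DetectionParams()
    if len(series) == 0:
        return []
    thr = series.threshold if threshold is None else threshold
    if isinstance(series, FiSeries):
        return _detect_fi(series, thr, params)
    if isinstance(series, FogcSeries):
        return _detect_fogc(series, thr, params, t_end)
    raise TypeError(f"unsupported series type {type(series).__name__}")


def match_events(detections: Sequence[Episode], annotations: Sequence[Episode],
                 tol_s: float = 1.0) -> EvaluationReport:
    """Score detections against clinician annotations.

    An annotation is detected if any detection overlaps it widened by
    ``tol_s``; one detection overlapping two annotations credits both.  A
    detection overlapping no annotation (at the same tolerance) is one
    false positive.  Detections may mix sources (FI, FOGC); counts are kept
    per source.
    """
    report = EvaluationReport(matching_tolerance_s=tol_s)
    for sev in SEVERITIES:
        report.n_annotated[sev] = sum(1 for a in annotations if a.severity == sev)
    by_source: dict[str, list[Episode]] = {}
    for d in detections:
        by_source.setdefault(d.source, []).append(d)
    for source, dets in sorted(by_source.items()):
        per_sev = {sev: 0 for sev in SEVERITIES}
        for ann in annotations:
            if ann.severity is None:
                continue
            if any(d.start <= ann.end + tol_s and d.end >= ann.start - tol_s
                   for d in dets):
                per_sev[ann.severity] += 1
        fp = sum(
            1 for d in dets
            if not any(d.start <= a.end + tol_s and d.end >= a.start - tol_s
                       for a in annotations)
        )
        report.n_detected[source] = per_sev
        report.false_positives[source] = fp
    report.validate()
    return report


def report_table(report: EvaluationReport) -> pd.DataFrame:
    """Severity × detector table (rows green/orange/red/false positives)."""
    detectors = sorted(report.n_detected.keys())
    rows = {}
    for sev in SEVERITIES:
        rows[sev.capitalize()] = [report.n_annotated.get(sev, 0)] + [
            report.n_detected[d].get(sev, 0) for d in detectors
        ]
    rows["False positives"] = [0] + [report.false_positives.get(d, 0)
                                     for d in detectors]
    df = pd.DataFrame.from_dict(
        rows, orient="index", columns=["Video"] + detectors
    )
    df.index.name = "FOG Intensity"
    return df


def report_to_csv(report: EvaluationReport) -> str:
    buf = _io.StringIO()
    report_table(report).to_csv(buf, lineterminator="\n")
    return buf.getvalue()


def report_from_csv(text: str) -> pd.DataFrame:
    """Reload a report table written by :func:`report_to_csv`."""
    return pd.read_csv(_io.StringIO(text), index_col=0)
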