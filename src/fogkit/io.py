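"""Reading and writing shank-IMU recordings and FOG episode annotations.

File dialect
------------
Recordings are plain CSV with a header line and optional ``#``-prefixed
metadata lines, e.g.::

    # fs: 100.0
    # placement: shank_right
    # acc_unit: m/s2
    # gyro_unit: rad/s
    t,ax,ay,az,gx,gy,gz
    0.00,0.1,...

Columns ``t, ax, ay, az, gx, gy, gz`` are required; ``mx, my, mz`` are
optional.  Internal units are SI throughout (m/s², rad/s); ``g`` and
``deg/s`` on disk are converted at load time.  Time is relative seconds
from recording start.

Annotations are CSV with columns ``start_s, end_s, severity, etype``
(severity ∈ green/orange/red as labelled by the clinician; etype ∈
fog/festination/detection).  Detector output adds ``source`` and
``peak_value`` columns, which the loader accepts and preserves.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

logger = logging.getLogger(__name__)

G_STANDARD = 9.80665  # m/s² per g

PLACEMENTS = ("shank_left", "shank_right", "ankle", "other")
SEVERITIES = ("green", "orange", "red")
ETYPES = ("fog", "festination", "detection")
SOURCES = ("annotation", "FI", "FOGC")

_REQUIRED_COLUMNS = ("t", "ax", "ay", "az", "gx", "gy", "gz")
_MAG_COLUMNS = ("mx", "my", "mz")


@dataclass
class ImuRecording:
    """One synchronized multi-axis inertial time series.

    Attributes
    ----------
    t : (N,) array of relative time, s, strictly increasing, uniform.
    acc : (N, 3) specific force, m/s² (gravity included, sensor frame).
    gyro : (N, 3) angular rate, rad/s.
    mag : optional (N, 3) magnetic field, arbitrary units.
    fs : sampling rate, Hz (≥ 20 Hz so the 3–8 Hz freeze band is resolved
        with margin).
    placement : sensor site token (shank_left/shank_right/ankle/other).
    """

    t: np.ndarray
    acc: np.ndarray
    gyro: np.ndarray
    fs: float
    mag: Optional[np.ndarray] = None
    placement: str = "other"

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.acc = np.asarray(self.acc, dtype=float)
        self.gyro = np.asarray(self.gyro, dtype=float)
        if self.mag is not None:
            self.mag = np.asarray(self.mag, dtype=float)
        self.validate()

    # -- invariants ------------------------------------------------------
    def validate(self) -> None:
        n = self.t.shape[0]
        if n < 2:
            raise ValidationError("recording must contain at least 2 samples")
        for name, arr, width in (("acc", self.acc, 3), ("gyro", self.gyro, 3)):
            if arr.shape != (n, width):
                raise ValidationError(
                    f"{name} has shape {arr.shape}, expected ({n}, {width})"
                )
        if self.mag is not None and self.mag.shape != (n, 3):
            raise ValidationError(
                f"mag has shape {self.mag.shape}, expected ({n}, 3)"
            )
        if self.placement not in PLACEMENTS:
            raise ValidationError(
                f"unknown placement {self.placement!r}; expected one of {PLACEMENTS}"
            )
        if not math.isfinite(self.fs) or self.fs < 20.0:
            raise ValidationError(
                f"fs = {self.fs} Hz; at least 20 Hz is required to resolve the "
                "3-8 Hz freeze band"
            )
        bad = _nan_rows(self.t, self.acc, self.gyro, self.mag)
        if bad.size:
            raise ValidationError(f"NaN values at row indices {bad.tolist()[:20]}")
        dt = np.diff(self.t)
        if np.any(dt <= 0):
            raise ValidationError("time vector is not strictly increasing")
        if np.any(np.abs(dt - 1.0 / self.fs) >= 1e-6):
            worst = float(np.max(np.abs(dt - 1.0 / self.fs)))
            raise ValidationError(
                f"non-uniform sampling: max |Δt - 1/fs| = {worst:.3g} s"
            )

    @property
    def n_samples(self) -> int:
        return int(self.t.shape[0])

    @property
    def duration(self) -> float:
        """Span covered by the samples plus one sample period, s."""
        return float(self.t[-1] - self.t[0] + 1.0 / self.fs)


@dataclass
class Episode:
    """A labelled or detected time interval.

    ``severity`` is mandatory for clinician annotations (source
    ``annotation``) and optional for detector output.
    """

    start: float
    end: float
    etype: str = "fog"
    severity: Optional[str] = None
    source: str = "annotation"
    peak_value: Optional[float] = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.start < self.end):
            raise ValidationError(
                f"episode needs 0 <= start < end, got [{self.start}, {self.end}]"
            )
        if self.etype not in ETYPES:
            raise FormatError(f"unknown episode type {self.etype!r}")
        if self.source not in SOURCES:
            raise FormatError(f"unknown episode source {self.source!r}")
        if self.severity is not None and self.severity not in SEVERITIES:
            raise FormatError(f"unknown severity {self.severity!r}")
        if self.source == "annotation" and self.severity is None:
            raise ValidationError("annotation episodes require a severity label")

    @property
    def duration(self) -> float:
        return self.end - self.start

    def overlaps(self, other: "Episode", tol_s: float = 0.0) -> bool:
        """True if the intervals intersect once ``other`` is widened by tol_s."""
        return self.start <= other.end + tol_s and self.end >= other.start - tol_s


def _nan_rows(*arrays: Optional[np.ndarray]) -> np.ndarray:
    mask = None
    for arr in arrays:
        if arr is None:
            continue
        bad = ~np.isfinite(arr)
        if bad.ndim > 1:
            bad = bad.any(axis=1)
        mask = bad if mask is None else (mask | bad)
    return np.flatnonzero(mask) if mask is not None else np.array([], dtype=int)


# ---------------------------------------------------------------------------
# recordings
# ---------------------------------------------------------------------------

def _parse_metadata(path: Path) -> dict:
    meta: dict = {}
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line.lstrip("#").strip()
            if ":" in body:
                key, _, value = body.partition(":")
                meta[key.strip()] = value.strip()
    return meta


def load_recording(
    path,
    *,
    acc_unit: Optional[str] = None,
    gyro_unit: Optional[str] = None,
) -> ImuRecording:
    """Load a recording CSV.

    Unit tokens (``m/s2``/``g`` for acceleration, ``rad/s``/``deg/s`` for
    angular rate) may come from the file's metadata lines or be forced via
    the keyword arguments; keywords win.  ``fs`` is taken from metadata if
    declared, otherwise inferred from the median sample interval.  The
    loader never resamples, reorders or repairs: malformed input raises.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    meta = _parse_metadata(path)
    df = pd.read_csv(path, comment="#")
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")

    acc_unit = acc_unit or meta.get("acc_unit", "m/s2")
    gyro_unit = gyro_unit or meta.get("gyro_unit", "rad/s")
    if acc_unit not in ("m/s2", "g"):
        raise FormatError(f"unknown acc_unit {acc_unit!r}")
    if gyro_unit not in ("rad/s", "deg/s"):
        raise FormatError(f"unknown gyro_unit {gyro_unit!r}")

    t = df["t"].to_numpy(float)
    acc = df[["ax", "ay", "az"]].to_numpy(float)
    gyro = df[["gx", "gy", "gz"]].to_numpy(float)
    mag = None
    if all(c in df.columns for c in _MAG_COLUMNS):
        mag = df[list(_MAG_COLUMNS)].to_numpy(float)

    bad = _nan_rows(t, acc, gyro, mag)
    if bad.size:
        raise ValidationError(f"{path}: NaN rows at indices {bad.tolist()[:20]}")
    if t.size >= 2 and np.any(np.diff(t) <= 0):
        raise ValidationError(f"{path}: time column is not strictly increasing")

    if acc_unit == "g":
        acc = acc * G_STANDARD
    if gyro_unit == "deg/s":
        gyro = np.deg2rad(gyro)

    if "fs" in meta:
        fs = float(meta["fs"])
    else:
        if t.size < 2:
            raise ValidationError(f"{path}: cannot infer fs from < 2 samples")
        fs = 1.0 / float(np.median(np.diff(t)))
    placement = meta.get("placement", "other")
    return ImuRecording(t=t, acc=acc, gyro=gyro, mag=mag, fs=fs, placement=placement)


def save_recording(rec: ImuRecording, path) -> None:
    """Write a recording so that :func:`load_recording` reproduces it.

    Channels round-trip within 1e-9 (12 significant digits on disk);
    metadata (fs, placement, units) round-trips exactly.
    """
    rec.validate()
    path = Path(path)
    cols = {"t": rec.t}
    for i, name in enumerate(("ax", "ay", "az")):
        cols[name] = rec.acc[:, i]
    for i, name in enumerate(("gx", "gy", "gz")):
        cols[name] = rec.gyro[:, i]
    if rec.mag is not None:
        for i, name in enumerate(_MAG_COLUMNS):
            cols[name] = rec.mag[:, i]
    df = pd.DataFrame(cols)
    header = (
        f"# fs: {rec.fs!r}\n"
        f"# placement: {rec.placement}\n"
        "# acc_unit: m/s2\n"
        "# gyro_unit: rad/s\n"
    )
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(header)
        df.to_csv(fh, index=False, float_format="%.12g", lineterminator="\n")


# ---------------------------------------------------------------------------
# annotations / detections
# ---------------------------------------------------------------------------

def load_annotations(path) -> list[Episode]:
    """Load an episode CSV, sorted by start time.

    Overlapping annotation intervals are legal (a festination can run into
    the freeze it precedes) but are reported through the module logger.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, comment="#")
    for col in ("start_s", "end_s", "severity", "etype"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing annotation column {col!r}")
    episodes = []
    for row in df.itertuples(index=False):
        severity = getattr(row, "severity")
        severity = None if (isinstance(severity, float) and math.isnan(severity)) else severity
        source = getattr(row, "source", "annotation")
        peak = getattr(row, "peak_value", None)
        if isinstance(peak, float) and math.isnan(peak):
            peak = None
        episodes.append(
            Episode(
                start=float(getattr(row, "start_s")),
                end=float(getattr(row, "end_s")),
                severity=severity,
                etype=str(getattr(row, "etype")),
                source=str(source),
                peak_value=peak,
            )
        )
    episodes.sort(key=lambda e: (e.start, e.end))
    for a, b in zip(episodes, episodes[1:]):
        if a.end > b.start:
            logger.warning(
                "overlapping episodes [%0.2f, %0.2f] and [%0.2f, %0.2f] in %s",
                a.start, a.end, b.start, b.end, path,
            )
    return episodes


def save_annotations(episodes: Sequence[Episode], path) -> None:
    """Write episodes as CSV (columns start_s,end_s,severity,etype,source,peak_value)."""
    rows = [
        {
            "start_s": e.start,
            "end_s": e.end,
            "severity": e.severity if e.severity is not None else "",
            "etype": e.etype,
            "source": e.source,
            "peak_value": e.peak_value if e.peak_value is not None else "",
        }
        for e in episodes
    ]
    df = pd.DataFrame(
        rows, columns=["start_s", "end_s", "severity", "etype", "source", "peak_value"]
    )
    df.to_csv(path, index=False, float_format="%.12g", lineterminator="\n")
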