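"""Sagittal-plane projection, gyro-based stride segmentation and stride length.

The shank rotates mainly about the medio-lateral axis during walking, so a
single shank gyroscope carries the gait rhythm: each swing phase produces a
large angular-velocity peak.  Strides are cut between successive mid-swing
peaks.  Stride length is then obtained by integrating the forward
acceleration over the stride, seeding and terminating the velocity with a
rigid-rotation estimate v = ω·r from the gyroscope (lever arm r ≈ shank
length), and removing integration drift with a linear ramp so the terminal
velocities agree.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence, Union

import numpy as np
from scipy.integrate import cumulative_trapezoid, trapezoid
from scipy.signal import find_peaks
from scipy.stats import skew

from .errors import CalibrationError, ValidationError
from .io import ImuRecording


@dataclass
class KinematicsParams:
    """Tunables for projection, segmentation and length estimation.

    peak_prominence : rad/s — minimum prominence for a mid-swing peak.
    c_max : strides/s — maximal plausible cadence; the segmenter never
        returns a stride shorter than 1/c_max.
    max_stride_s : s — inter-peak interval above this is treated as a gait
        interruption (freeze, stop), not a stride.
    r_shank_m : m — lever arm of the rigid-rotation velocity model v = ω·r.
    calibration_window : "auto" or (t0, t1) s — quiet-standing window used
        to estimate the gravity direction.
    calib_len_s : s — length of the auto-detected standing window.
    calib_still_tol : m/s² — RMS acceleration deviation allowed inside a
        window for it to count as quiet standing.
    min_stride_s : s — override of the 1/c_max floor (rarely needed).
    """

    peak_prominence: float = 0.5
    c_max: float = 5.0
    max_stride_s: float = 2.5
    r_shank_m: float = 0.4
    calibration_window: Union[str, tuple] = "auto"
    calib_len_s: float = 2.0
    calib_still_tol: float = 0.3
    min_stride_s: Optional[float] = None

    @property
    def stride_floor_s(self) -> float:
        return self.min_stride_s if self.min_stride_s is not None else 1.0 / self.c_max


@dataclass
class SagittalSignals:
    """Sensor data projected into the sagittal plane, gravity removed.

    omega : shank angular rate about the medio-lateral axis, rad/s
        (positive during forward swing).
    a_fwd, a_vert : forward / vertical acceleration, m/s², gravity-free.
    """

    t: np.ndarray
    omega: np.ndarray
    a_fwd: np.ndarray
    a_vert: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        n = len(self.t)
        for name in ("omega", "a_fwd", "a_vert"):
            if len(getattr(self, name)) != n:
                raise ValidationError(f"{name} length differs from t")


@dataclass
class Stride:
    """One gait cycle, delimited by consecutive mid-swing peaks.

    Indices are 0-based, half-open [i_start, i_end).  C_n is the cadence
    (strides/s, reciprocal duration); L_n the stride length in metres,
    None until estimated.
    """

    i_start: int
    i_end: int
    t_start: float
    t_end: float
    duration: float
    C_n: float
    L_n: Optional[float] = None

    def __post_init__(self) -> None:
        if self.i_end <= self.i_start:
            raise ValidationError("stride needs i_end > i_start")
        if abs(self.C_n * self.duration - 1.0) > 1e-9:
            raise ValidationError("C_n must be the reciprocal of duration")
        if self.L_n is not None and self.L_n < 0:
            raise ValidationError("stride length must be non-negative")

    @property
    def t_mid(self) -> float:
        return 0.5 * (self.t_start + self.t_end)


def make_stride(i_start: int, i_end: int, fs: float, t0: float = 0.0,
                L_n: Optional[float] = None) -> Stride:
    """Build a Stride from sample indices on a uniform grid."""
    duration = (i_end - i_start) / fs
    return Stride(
        i_start=i_start,
        i_end=i_end,
        t_start=t0 + i_start / fs,
        t_end=t0 + i_end / fs,
        duration=duration,
        C_n=1.0 / duration,
        L_n=L_n,
    )


# ---------------------------------------------------------------------------
# sagittal projection
# ---------------------------------------------------------------------------

def _find_standing_window(rec: ImuRecording, params: KinematicsParams) -> slice:
    n_w = max(2, int(round(params.calib_len_s * rec.fs)))
    if params.calibration_window != "auto":
        t0, t1 = params.calibration_window
        i0 = int(np.searchsorted(rec.t, t0))
        i1 = int(np.searchsorted(rec.t, t1))
        if i1 - i0 < 2:
            raise CalibrationError("declared calibration window is too short")
        return slice(i0, i1)
    if rec.n_samples < n_w:
        raise CalibrationError("recording shorter than the calibration window")
    # total acc variance in each sliding window, via cumulative sums
    acc = rec.acc
    c1 = np.cumsum(np.vstack([np.zeros(3), acc]), axis=0)
    c2 = np.cumsum(np.vstack([np.zeros(3), acc ** 2]), axis=0)
    s1 = c1[n_w:] - c1[:-n_w]
    s2 = c2[n_w:] - c2[:-n_w]
    var = (s2 - s1 ** 2 / n_w) / n_w  # per-axis biased variance
    total = var.sum(axis=1)
    i0 = int(np.argmin(total))
    if np.sqrt(max(total[i0], 0.0)) >= params.calib_still_tol:
        raise CalibrationError(
            "no quiet-standing window found; declare calibration_window explicitly"
        )
    return slice(i0, i0 + n_w)


def project_to_sagittal(rec: ImuRecording,
                        params: Optional[KinematicsParams] = None) -> SagittalSignals:
    """Project a raw recording into the sagittal plane.

    Gravity is estimated as the mean accelerometer vector over a
    quiet-standing calibration window; the medio-lateral axis as the
    principal direction of the gyroscope signal (orthogonalised against
    gravity).  Sign conventions are resolved from the data: omega is
    oriented so swing peaks are positive (positive skewness), the forward
    axis so that forward acceleration co-varies with the angular
    acceleration of the swing.
    """
    params = params or KinematicsParams()
    win = _find_standing_window(rec, params)
    g_vec = rec.acc[win].mean(axis=0)
    g_mag = float(np.linalg.norm(g_vec))
    if g_mag < 5.0:
        raise CalibrationError(
            f"degenerate gravity vector (|mean acc| = {g_mag:.2f} m/s²) in the "
            "calibration window"
        )
    v_hat = g_vec / g_mag

    gyro = rec.gyro - rec.gyro[win].mean(axis=0)
    cov = gyro.T @ gyro
    _, vecs = np.linalg.eigh(cov)
    m_hat = vecs[:, -1]  # principal gyro direction
    m_hat = m_hat - (m_hat @ v_hat) * v_hat
    norm = np.linalg.norm(m_hat)
    if norm < 1e-9:  # gyro variance entirely about gravity; pick any transverse axis
        m_hat = np.array([1.0, 0.0, 0.0]) - v_hat[0] * v_hat
        m_hat /= np.linalg.norm(m_hat)
    else:
        m_hat = m_hat / norm

    omega = rec.gyro @ m_hat
    if skew(omega) < 0:
        m_hat = -m_hat
        omega = -omega

    f_hat = np.cross(m_hat, v_hat)
    f_hat /= np.linalg.norm(f_hat)
    a_vert = rec.acc @ v_hat - g_mag
    a_fwd = rec.acc @ f_hat
    a_fwd = a_fwd - a_fwd[win].mean()
    # orient forward axis: forward acceleration tracks the swing's angular
    # acceleration under the rigid-rotation model
    if np.sum(a_fwd * np.gradient(omega)) < 0:
        f_hat = -f_hat
        a_fwd = -a_fwd
    return SagittalSignals(t=rec.t, omega=omega, a_fwd=a_fwd, a_vert=a_vert, fs=rec.fs)


# ---------------------------------------------------------------------------
# stride segmentation
# ---------------------------------------------------------------------------

def segment_strides(sig: SagittalSignals,
                    params: Optional[KinematicsParams] = None) -> list[Stride]:
    """Cut the recording into strides at successive mid-swing omega peaks.

    Candidate inter-peak intervals shorter than 1/c_max are discarded, as
    are intervals longer than max_stride_s (gait interruptions).  Zero
    strides is a valid result (standing, trembling).
    """
    params = params or KinematicsParams()
    if len(sig.t) < 2:
        return []
    peaks, _ = find_peaks(sig.omega, prominence=params.peak_prominence)
    t0 = float(sig.t[0])
    strides: list[Stride] = []
    for p0, p1 in zip(peaks[:-1], peaks[1:]):
        duration = (p1 - p0) / sig.fs
        if params.stride_floor_s <= duration <= params.max_stride_s:
            strides.append(make_stride(int(p0), int(p1), sig.fs, t0=t0))
    return strides


# ---------------------------------------------------------------------------
# stride length
# ---------------------------------------------------------------------------

def estimate_stride_length(sig: SagittalSignals, stride: Stride,
                           params: Optional[KinematicsParams] = None) -> Stride:
    """Return a copy of ``stride`` with L_n estimated.

    Forward velocity is seeded at the stride onset with v0 = ω·r from the
    gyroscope, propagated by trapezoidal integration of the forward
    acceleration, and de-drifted with a linear ramp so the terminal
    velocity matches the gyroscope estimate at the next mid-swing peak.
    The stride length is the time integral of the corrected velocity,
    clamped at zero from below.
    """
    params = params or KinematicsParams()
    i0, i1 = stride.i_start, stride.i_end
    if not (0 <= i0 < i1 < len(sig.t)):
        raise ValidationError("stride indices outside the signal")
    r = params.r_shank_m
    dt = 1.0 / sig.fs
    a = sig.a_fwd[i0:i1 + 1]
    v = sig.omega[i0] * r + cumulative_trapezoid(a, dx=dt, initial=0.0)
    v_end_gyro = sig.omega[i1] * r
    drift = v[-1] - v_end_gyro
    v = v - drift * np.linspace(0.0, 1.0, len(v))
    length = float(trapezoid(v, dx=dt))
    return replace(stride, L_n=max(length, 0.0))


def attach_stride_lengths(sig: SagittalSignals, strides: Sequence[Stride],
                          params: Optional[KinematicsParams] = None) -> list[Stride]:
    """Estimate L_n for every stride in order."""
    return [estimate_stride_length(sig, s, params) for s in strides]


def compute_cadence_series(strides: Sequence[Stride]) -> tuple[np.ndarray, np.ndarray]:
    """Per-stride (midpoint time, cadence) arrays, strides/s."""
    t_mid = np.array([s.t_mid for s in strides], dtype=float)
    cad = np.array([s.C_n for s in strides], dtype=float)
    return t_mid, cad
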