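"""Seeded synthetic shank-IMU scenarios with exact ground truth.

The generator emulates the phenomenology a shank sensor sees in
parkinsonian gait — not musculoskeletal mechanics:

* **walk / festination** — the medio-lateral angular rate is a train of
  half-sine mid-swing pulses at the prescribed (possibly ramping) cadence;
  the forward acceleration is the exact time derivative of a forward
  velocity profile constructed per stride so that the stride's displacement
  equals the prescribed length *exactly*, with boundary velocities obeying
  the rigid-rotation model v = ω·r the estimator assumes.  Vertical
  acceleration oscillates at the step frequency (2× cadence), capped at
  2.5 Hz so that the fundamental stays a full spectral main-lobe width
  inside the locomotor band while the stride cadence ramps up: festination
  shuffling raises the step rate but does not move vertical power into the
  freeze band, which is exactly why spectral freeze detectors miss it.
* **tremble** — trembling-type freezing: no swing pulses (feet stay on the
  ground, so no strides), a freeze-band sinusoid on the vertical channel.
* **stand** — quiet standing: gravity plus measurement noise only.

White Gaussian noise (``noise_sd``) is added to all channels; an optional
fixed sensor-mounting rotation maps the sagittal-frame signals into an
arbitrary sensor frame.  Identical configuration (including seed) yields
bit-identical output.

Ground truth counts full pulse-to-pulse strides: a ``D``-second walk at
cadence ``c`` carries K ≈ D·c pulse centres and K−1 strides, matching the
peak-to-peak convention of :func:`fogkit.kinematics.segment_strides`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np
from scipy.integrate import cumulative_trapezoid, trapezoid
from scipy.spatial.transform import Rotation

from .errors import ParameterError
from .io import G_STANDARD, Episode, ImuRecording
from .kinematics import Stride

SEGMENT_KINDS = ("walk", "festination", "tremble", "stand")

Ramp = Union[float, tuple]


@dataclass
class Segment:
    """One homogeneous stretch of a scenario.

    ``cadence`` (strides/s) and ``stride_length`` (m) accept either a
    constant or a (start, end) linear ramp; they only matter for walk and
    festination segments.  ``severity`` labels the episode the segment
    contributes to the ground truth (tremble → fog, festination →
    festination); walk and stand segments are unlabelled.
    """

    kind: str
    duration: float
    cadence: Ramp = 0.9
    stride_length: Ramp = 1.4
    tremble_freq: float = 6.0
    tremble_amp: float = 1.5
    severity: str = "red"

    def __post_init__(self) -> None:
        if self.kind not in SEGMENT_KINDS:
            raise ParameterError(
                f"unknown segment kind {self.kind!r}; expected one of {SEGMENT_KINDS}"
            )
        if self.duration <= 0:
            raise ParameterError("segment duration must be positive")


@dataclass
class ScenarioConfig:
    """Full scenario description; every quantity the generator uses.

    swing_peak_rad_s and swing_fraction shape the mid-swing pulse (peak
    angular rate and swing time as a fraction of the cycle); r_shank_m is
    the lever arm shared with the estimator; vert_amp the locomotor
    vertical-oscillation amplitude; step_hz_cap the ceiling on the
    vertical-channel step frequency (festination step rate).
    """

    segments: list[Segment] = field(default_factory=list)
    fs: float = 100.0
    seed: int = 0
    noise_sd: float = 0.0
    swing_peak_rad_s: float = 4.0
    swing_fraction: float = 0.35
    r_shank_m: float = 0.4
    vert_amp: float = 1.0
    step_hz_cap: float = 2.5
    mounting_rpy_deg: tuple = (0.0, 0.0, 0.0)
    placement: str = "shank_right"


@dataclass
class GroundTruth:
    """True strides (C_n, L_n exact) and labelled episodes of a scenario."""

    strides: list[Stride] = field(default_factory=list)
    episodes: list[Episode] = field(default_factory=list)


def _ramp(value: Ramp, t: np.ndarray, duration: float) -> np.ndarray:
    if isinstance(value, (tuple, list)):
        v0, v1 = float(value[0]), float(value[1])
        return v0 + (v1 - v0) * t / duration
    return np.full_like(t, float(value))


def _gait_segment(seg: Segment, cfg: ScenarioConfig, n: int, t_offset: float,
                  i_offset: int):
    """Angular rate, forward velocity and true strides for one walk segment."""
    fs, dt = cfg.fs, 1.0 / cfg.fs
    t = np.arange(n) * dt
    duration = n * dt
    c = _ramp(seg.cadence, t, duration)
    if np.any(c <= 0):
        raise ParameterError("cadence must stay positive")
    length = _ramp(seg.stride_length, t, duration)
    phi = cumulative_trapezoid(c, dx=dt, initial=0.0)

    # pulse centres at half-integer phase, kept clear of the segment edges
    targets = np.arange(0.5, phi[-1], 1.0)
    centers = np.interp(targets, phi, t)
    widths = cfg.swing_fraction / np.interp(centers, t, c)
    keep = (centers - widths / 2 >= 0) & (centers + widths / 2 <= t[-1])
    centers, widths = centers[keep], widths[keep]

    A = cfg.swing_peak_rad_s
    omega = np.zeros(n)
    for tc, w in zip(centers, widths):
        m = np.abs(t - tc) <= w / 2
        omega[m] += A * np.cos(np.pi * (t[m] - tc) / w)

    v = cfg.r_shank_m * omega
    strides: list[Stride] = []
    for tc0, tc1 in zip(centers[:-1], centers[1:]):
        i0, i1 = int(round(tc0 * fs)), int(round(tc1 * fs))
        T = tc1 - tc0
        L = float(np.interp(0.5 * (tc0 + tc1), t, length))
        # forward-velocity bump so the stride displacement is exactly L
        sl = slice(i0, i1 + 1)
        base = float(trapezoid(v[sl], dx=dt))
        bump_shape = (2.0 / T) * np.sin(np.pi * (t[sl] - tc0) / T) ** 2
        v[sl] += (L - base) * bump_shape / trapezoid(bump_shape, dx=dt)
        strides.append(Stride(
            i_start=i_offset + i0, i_end=i_offset + i1,
            t_start=t_offset + i0 * dt, t_end=t_offset + i1 * dt,
            duration=(i1 - i0) * dt, C_n=fs / (i1 - i0), L_n=L,
        ))

    f_step = np.minimum(2.0 * c, cfg.step_hz_cap)
    psi = cumulative_trapezoid(f_step, dx=dt, initial=0.0)
    a_vert = cfg.vert_amp * np.sin(2 * np.pi * psi)
    center_idx = [i_offset + int(round(tc * fs)) for tc in centers]
    return omega, v, a_vert, strides, center_idx


def generate(cfg: ScenarioConfig) -> tuple[ImuRecording, GroundTruth]:
    """Render a scenario into a raw sensor recording plus its ground truth."""
    if not cfg.segments:
        raise ParameterError("scenario needs at least one segment")
    fs, dt = cfg.fs, 1.0 / cfg.fs
    omega_parts, v_parts, avert_parts = [], [], []
    strides: list[Stride] = []
    episodes: list[Episode] = []
    t_offset, i_offset = 0.0, 0
    boundary_pairs: list[tuple[int, int]] = []  # strides spanning adjacent gait segments
    prev_gait_last_center: Optional[int] = None

    for seg in cfg.segments:
        n = int(round(seg.duration * fs))
        if seg.kind in ("walk", "festination"):
            omega, v, a_vert, seg_strides, center_idx = _gait_segment(
                seg, cfg, n, t_offset, i_offset)
            strides.extend(seg_strides)
            if prev_gait_last_center is not None and center_idx:
                boundary_pairs.append((prev_gait_last_center, center_idx[0]))
            prev_gait_last_center = center_idx[-1] if center_idx else None
            if seg.kind == "festination":
                episodes.append(Episode(
                    start=t_offset, end=t_offset + n * dt,
                    severity=seg.severity, etype="festination",
                    source="annotation"))
        else:
            prev_gait_last_center = None
            omega = np.zeros(n)
            v = np.zeros(n)
            a_vert = np.zeros(n)
            if seg.kind == "tremble":
                t_local = np.arange(n) * dt
                a_vert = seg.tremble_amp * np.sin(2 * np.pi * seg.tremble_freq * t_local)
                episodes.append(Episode(
                    start=t_offset, end=t_offset + n * dt,
                    severity=seg.severity, etype="fog", source="annotation"))
        omega_parts.append(omega)
        v_parts.append(v)
        avert_parts.append(a_vert)
        t_offset += n * dt
        i_offset += n

    omega = np.concatenate(omega_parts)
    v_fwd = np.concatenate(v_parts)
    a_vert = np.concatenate(avert_parts)
    # gait continues across adjacent walk/festination segments: the stride
    # between the bounding swing pulses is real, with no length prescribed;
    # its true length is the integral of the constructed forward velocity
    for i0, i1 in boundary_pairs:
        if (i1 - i0) * dt > 2.5:  # pause between pulses, not a stride
            continue
        L = max(float(trapezoid(v_fwd[i0:i1 + 1], dx=dt)), 0.0)
        strides.append(Stride(
            i_start=i0, i_end=i1, t_start=i0 * dt, t_end=i1 * dt,
            duration=(i1 - i0) * dt, C_n=fs / (i1 - i0), L_n=L))
    strides.sort(key=lambda s: s.i_start)
    a_fwd = np.gradient(v_fwd, dt)
    n_total = len(omega)
    t = np.arange(n_total) * dt

    # body frame: x forward, y medio-lateral, z up; accelerometer reads
    # specific force, i.e. +g on the up axis at rest
    acc_body = np.column_stack([a_fwd, np.zeros(n_total), a_vert + G_STANDARD])
    gyro_body = np.column_stack([np.zeros(n_total), omega, np.zeros(n_total)])
    if any(cfg.mounting_rpy_deg):
        R = Rotation.from_euler("xyz", cfg.mounting_rpy_deg, degrees=True).as_matrix()
        acc = acc_body @ R  # sensor-frame coordinates of the body-frame vectors
        gyro = gyro_body @ R
    else:
        acc, gyro = acc_body, gyro_body

    if cfg.noise_sd > 0:
        rng = np.random.default_rng(cfg.seed)
        acc = acc + rng.normal(0.0, cfg.noise_sd, acc.shape)
        gyro = gyro + rng.normal(0.0, cfg.noise_sd, gyro.shape)

    rec = ImuRecording(t=t, acc=acc, gyro=gyro, fs=fs, placement=cfg.placement)
    return rec, GroundTruth(strides=strides, episodes=episodes)


def preset_scenarios() -> dict[str, ScenarioConfig]:
    """Named study scenarios.

    All presets are noise-free (so ground truth is exact) and open with a
    3 s quiet-standing lead-in that doubles as the gravity-calibration
    window.  ``fog_tremble``'s trembling lasts 12 s — at least twice the
    6 s FI analysis window, the rule of thumb for the shortest reliably
    detectable freeze.  ``festination_freeze`` reproduces the
    festination-into-freeze sequence: cadence ramping 1 → 3 strides/s
    while the stride shrinks 1 → 0.1 m, ending in a trembling freeze.
    """
    walk = dict(cadence=0.9, stride_length=1.4)
    return {
        "standing": ScenarioConfig(segments=[Segment("stand", 10.0)]),
        "normal_walk": ScenarioConfig(segments=[
            Segment("stand", 3.0),
            Segment("walk", 30.0, **walk),
        ]),
        "fog_tremble": ScenarioConfig(segments=[
            Segment("stand", 3.0),
            Segment("walk", 10.0, **walk),
            Segment("tremble", 12.0, tremble_freq=6.0, severity="red"),
            Segment("walk", 10.0, **walk),
        ]),
        "festination_freeze": ScenarioConfig(segments=[
            Segment("stand", 3.0),
            Segment("walk", 8.0, **walk),
            Segment("festination", 8.0, cadence=(1.0, 3.0),
                    stride_length=(1.0, 0.1), severity="orange"),
            Segment("tremble", 8.0, tremble_freq=6.0, severity="red"),
        ]),
    }
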