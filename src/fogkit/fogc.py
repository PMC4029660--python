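"""Per-stride FOG criterion (FOGC) from cadence and stride length.

Festination — increasingly rapid, ever smaller steps — precedes many
freezing episodes.  The FOGC tracks it with two gait parameters per
detected stride n (cadence C_n, length L_n):

    FOGC_n = C_n · L_min / (C_max · (L_n + L_min))

with C_max the maximal expected cadence (5 strides/s) and L_min the
minimal observable step length (5 cm).  The criterion rises with cadence
and falls with stride length, reaching 1 as L_n → 0 at C_n = C_max; a
high or rising value signals an imminent or ongoing freeze.  The
detection threshold (default 0.008) is a per-patient setting.

Being stride-indexed, the FOGC exists only while steps occur: during a
complete freeze or quiet standing it is undefined and detection falls to
the preceding strides (see :mod:`fogkit.events`) or to the Freeze Index.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import ParameterError, ValidationError
from .kinematics import Stride


@dataclass
class FogcParams:
    """C_max (strides/s), L_min (m) and the detection threshold."""

    c_max: float = 5.0
    l_min_m: float = 0.05
    threshold: float = 0.008

    def __post_init__(self) -> None:
        if self.c_max <= 0 or self.l_min_m <= 0:
            raise ParameterError("c_max and l_min_m must be positive")
        if not (0.0 < self.threshold < 1.0):
            raise ParameterError("threshold must lie in (0, 1)")


@dataclass
class FogcSeries:
    """Stride-indexed FOGC values (one per stride, order preserved)."""

    strides: list[Stride]
    fogc: np.ndarray
    params: FogcParams = field(default_factory=FogcParams)

    def __post_init__(self) -> None:
        if len(self.fogc) != len(self.strides):
            raise ValidationError("fogc must hold one value per stride")

    def __len__(self) -> int:
        return len(self.strides)

    @property
    def t_mid(self) -> np.ndarray:
        return np.array([s.t_mid for s in self.strides])

    @property
    def threshold(self) -> float:
        return self.params.threshold


def compute_fogc(stride: Stride, params: FogcParams | None = None) -> float:
    """Evaluate the criterion for one stride; exact, no clamping."""
    params = params or FogcParams()
    if stride.L_n is None or stride.L_n < 0:
        raise ValidationError("stride needs a non-negative length L_n")
    if stride.C_n <= 0:
        raise ValidationError("stride needs a positive cadence C_n")
    return stride.C_n * params.l_min_m / (params.c_max * (stride.L_n + params.l_min_m))


def compute_fogc_series(strides: Sequence[Stride],
                        params: FogcParams | None = None) -> FogcSeries:
    """FOGC for every stride of a time-ordered list (empty in → empty out)."""
    params = params or FogcParams()
    values = np.array([compute_fogc(s, params) for s in strides], dtype=float)
    return FogcSeries(strides=list(strides), fogc=values, params=params)
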