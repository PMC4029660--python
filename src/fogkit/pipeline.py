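"""One-call detection pipeline: recording → FI + FOGC series and events.

This is the composition the CLI exposes; library users can call it
directly or wire the stages themselves.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import yaml

from .errors import ParameterError
from .events import DetectionParams, detect_events
from .fogc import FogcParams, FogcSeries, compute_fogc_series
from .freeze_index import FiParams, FiSeries, freeze_index_series
from .io import Episode, ImuRecording
from .kinematics import (KinematicsParams, SagittalSignals, Stride,
                         attach_stride_lengths, project_to_sagittal,
                         segment_strides)


@dataclass
class PipelineConfig:
    """Aggregated configuration of every stage."""

    kinematics: KinematicsParams = field(default_factory=KinematicsParams)
    fi: FiParams = field(default_factory=FiParams)
    fogc: FogcParams = field(default_factory=FogcParams)
    detection: DetectionParams = field(default_factory=DetectionParams)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        cfg = cls()
        sections = {
            "kinematics": cfg.kinematics,
            "freeze_index": cfg.fi,
            "fogc": cfg.fogc,
            "events": cfg.detection,
        }
        for section, obj in sections.items():
            for key, value in (data.get(section) or {}).items():
                if not hasattr(obj, key):
                    raise ParameterError(f"unknown config key {section}.{key}")
                setattr(obj, key, value)
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


@dataclass
class DetectionResult:
    sagittal: SagittalSignals
    strides: list[Stride]
    fi_series: FiSeries
    fogc_series: FogcSeries
    fi_events: list[Episode]
    fogc_events: list[Episode]

    @property
    def events(self) -> list[Episode]:
        return sorted(self.fi_events + self.fogc_events, key=lambda e: e.start)


def run_detection(rec: ImuRecording,
                  cfg: Optional[PipelineConfig] = None) -> DetectionResult:
    """Run projection, both detectors and event extraction on a recording."""
    cfg = cfg or PipelineConfig()
    sag = project_to_sagittal(rec, cfg.kinematics)
    strides = attach_stride_lengths(
        sag, segment_strides(sag, cfg.kinematics), cfg.kinematics)

    channel = getattr(sag, cfg.fi.channel, None)
    if channel is None:
        raise ParameterError(f"unknown FI channel {cfg.fi.channel!r}")
    fi_series = freeze_index_series(np.asarray(channel), rec.fs, cfg.fi)
    fogc_series = compute_fogc_series(strides, cfg.fogc)

    t_end = float(rec.t[-1]) + 1.0 / rec.fs
    fi_events = detect_events(fi_series, params=cfg.detection)
    fogc_events = detect_events(fogc_series, params=cfg.detection, t_end=t_end)
    return DetectionResult(
        sagittal=sag, strides=strides, fi_series=fi_series,
        fogc_series=fogc_series, fi_events=fi_events, fogc_events=fogc_events)
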