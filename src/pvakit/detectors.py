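"""Rule-based detection of double triggering and ineffective triggering.

Double triggering (DT): two consecutive ventilator cycles delivered for one
patient effort.  A breath pair qualifies when the first breath has no
expiratory phase (volume never returns to baseline) or its expiratory time
is less than half (configurable) of the rolling-average inspiratory time.

Ineffective triggering (IT): a patient inspiratory effort during expiration
that fails to trigger the ventilator.  It appears as a "flow deflection" —
the expiratory flow curve first rises then falls.  Deflections are located
from sign changes of the first derivative of the (lightly smoothed)
expiratory flow and accepted when their amplitude exceeds 5 L/min and their
duration exceeds 0.12 s.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from ._utils import local_extrema, moving_average
from .errors import ConfigError, ContractError
from .io import VentStream
from .segmentation import (
    Breath,
    SegmentationConfig,
    mean_inspiratory_time,
    segment_breaths,
)


@dataclass
class DetectorConfig:
    """Thresholds of both detectors.

    ``it_amplitude_threshold`` / ``it_duration_threshold`` are the
    flow-deflection acceptance thresholds (strict inequalities).
    ``dt_te_ratio`` is the fraction of the mean inspiratory time below
    which an expiratory time marks a double trigger.  ``duration_mode``
    selects how deflection duration is measured: ``"min_to_min"`` (width of
    the deflection at the level of its higher bounding minimum) or
    ``"peak_to_min"`` (peak to following minimum).
    """

    it_amplitude_threshold: float = 5.0   # L/min
    it_duration_threshold: float = 0.12   # s
    dt_te_ratio: float = 0.5
    volume_baseline_tol: float = 20.0     # mL
    derivative_smoothing_window: int = 5  # samples, odd
    dt_ti_window: int = 10                # breaths in the rolling mean Ti
    duration_mode: str = "min_to_min"

    def __post_init__(self) -> None:
        for name in (
            "it_amplitude_threshold",
            "it_duration_threshold",
            "volume_baseline_tol",
        ):
            if not getattr(self, name) > 0:
                raise ConfigError(f"{name} must be > 0")
        if not 0 < self.dt_te_ratio < 1:
            raise ConfigError("dt_te_ratio must lie in (0, 1)")
        if self.derivative_smoothing_window % 2 == 0 or self.derivative_smoothing_window < 1:
            raise ConfigError("derivative_smoothing_window must be odd and >= 1")
        if self.duration_mode not in ("min_to_min", "peak_to_min"):
            raise ConfigError(f"unknown duration_mode {self.duration_mode!r}")
        if self.dt_ti_window < 1:
            raise ConfigError("dt_ti_window must be >= 1")


@dataclass(frozen=True)
class PvaEvent:
    """A detected patient-ventilator asynchrony event."""

    event_type: str           # "double_trigger" | "ineffective_trigger"
    breath_ordinal: int
    sample_index: int
    features: dict = field(default_factory=dict, compare=False)


def _check_breaths(s: VentStream, breaths: Sequence[Breath]) -> None:
    if breaths and breaths[-1].end_index > len(s):
        raise ContractError("breaths extend beyond the stream")


def detect_double_trigger(
    s: VentStream,
    breaths: Sequence[Breath],
    cfg: Optional[DetectorConfig] = None,
) -> list[PvaEvent]:
    """Flag consecutive breath pairs forming a double trigger.

    For each pair (i, i+1) one event is emitted, anchored at breath i's
    cycle point, when either

    * breath i has no expiratory phase: te = 0, or the volume at the end of
      breath i sits more than ``volume_baseline_tol`` above the volume at
      its trigger (the volume-time curve did not fall back to baseline), or
    * te(i) < ``dt_te_ratio`` x rolling mean Ti (strict), the mean taken
      over the last ``dt_ti_window`` breaths up to and including breath i.
    """
    cfg = cfg or DetectorConfig()
    _check_breaths(s, breaths)
    events = []
    for i in range(len(breaths) - 1):
        b = breaths[i]
        volume_end = float(s.volume[b.end_index - 1])
        volume_excess = volume_end - float(s.volume[b.trigger_index])
        mean_ti = mean_inspiratory_time(breaths, i + 1, cfg.dt_ti_window)
        no_expiration = b.te_s == 0 or volume_excess > cfg.volume_baseline_tol
        short_te = b.te_s < cfg.dt_te_ratio * mean_ti
        if no_expiration or short_te:
            events.append(
                PvaEvent(
                    event_type="double_trigger",
                    breath_ordinal=i,
                    sample_index=b.cycle_index,
                    features={
                        "te_s": b.te_s,
                        "mean_ti_s": mean_ti,
                        "volume_at_cycle": volume_excess,
                    },
                )
            )
    return events


def _deflections(
    seg: np.ndarray, cfg: DetectorConfig, fs: float
) -> list[tuple[int, float, float]]:
    """Candidate flow deflections in one expiratory segment.

    Returns (peak_index, amplitude_lpm, duration_s) for non-overlapping
    rise-then-fall excursions.  Amplitude is peak flow minus the HIGHER of
    the two bounding minima (conservative); min-to-min duration spans the
    bounding minima.  On a passively rising expiratory flow the deflection
    is the first non-monotone feature, so no interior minimum precedes it;
    the segment start then brackets the amplitude and the deflection onset
    (read off the derivative) bounds the duration.
    """
    if seg.size < max(3, cfg.derivative_smoothing_window):
        return []
    sm = moving_average(seg, cfg.derivative_smoothing_window)
    d = np.diff(sm)
    maxima, minima = local_extrema(sm)
    out = []
    last_bound = -1
    for p in maxima:
        if p <= last_bound:
            continue
        left = [m for m in minima if m < p]
        right = [m for m in minima if m > p]
        if right:
            m2 = right[0]
        elif sm[-1] < sm[p]:
            m2 = len(sm) - 1
        else:
            continue
        if left:
            m1_amp = m1_dur = left[-1]
        else:
            # No interior minimum precedes the peak (flow rose monotonically
            # into the deflection, the usual case on a passive expiration).
            # The segment start stands in as the left bracketing minimum for
            # the amplitude (harmless: amplitude uses the HIGHER minimum);
            # the deflection ONSET — the point where the rise steepens,
            # i.e. the minimum of the derivative before its pre-peak
            # maximum — stands in for the duration measurement.
            m1_amp = 0
            d_minima = [k for k in local_extrema(d)[1] if last_bound < k < p]
            m1_dur = d_minima[-1] if d_minima else 0
        amplitude = float(sm[p] - max(sm[m1_amp], sm[m2]))
        if cfg.duration_mode == "peak_to_min":
            duration = (m2 - p) / fs
        else:
            duration = (m2 - m1_dur) / fs
        out.append((p, amplitude, float(duration)))
        last_bound = m2
    return out


def detect_ineffective_trigger(
    s: VentStream,
    breaths: Sequence[Breath],
    cfg: Optional[DetectorConfig] = None,
) -> list[PvaEvent]:
    """Find ineffective-effort flow deflections in each expiratory phase.

    Per breath: the expiratory flow [cycle, end) is smoothed with a short
    moving average, local extrema are read off the sign changes of its
    first difference, and each local maximum bracketed by minima becomes a
    candidate deflection.  An event is emitted at the deflection peak when
    amplitude > ``it_amplitude_threshold`` AND duration >
    ``it_duration_threshold`` (both strict).
    """
    cfg = cfg or DetectorConfig()
    _check_breaths(s, breaths)
    events = []
    for i, b in enumerate(breaths):
        seg = s.flow[b.cycle_index : b.end_index]
        for p, amplitude, duration in _deflections(seg, cfg, s.sample_rate_hz):
            if amplitude > cfg.it_amplitude_threshold and duration > cfg.it_duration_threshold:
                events.append(
                    PvaEvent(
                        event_type="ineffective_trigger",
                        breath_ordinal=i,
                        sample_index=b.cycle_index + p,
                        features={
                            "deflection_amplitude": amplitude,
                            "deflection_duration": duration,
                        },
                    )
                )
    return events


def detect_all(
    s: VentStream,
    seg_cfg: Optional[SegmentationConfig] = None,
    det_cfg: Optional[DetectorConfig] = None,
) -> list[PvaEvent]:
    """Segment the stream and run both detectors; merged, sorted output."""
    breaths = segment_breaths(s, seg_cfg)
    events = detect_double_trigger(s, breaths, det_cfg)
    events += detect_ineffective_trigger(s, breaths, det_cfg)
    return sorted(events, key=lambda e: (e.sample_index, e.event_type))
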