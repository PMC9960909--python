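"""Breath segmentation and per-breath respiratory parameters.

A breath starts where flow rises through ``flow_trigger_threshold`` (armed
by having been below it) and stays above it for ``trigger_hold_s`` — the
hold rejects brief expiratory flow excursions such as ineffective patient
efforts, which by definition do not trigger the ventilator.  Inspiration
ends (the cycle point) at the first subsequent crossing below
``flow_cycle_threshold``; the breath ends at the next trigger or at the end
of the stream.  Indices are 0-based; intervals are half-open [start, end).
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, ContractError, DataError
from .io import VentStream


@dataclass(frozen=True)
class Breath:
    """One ventilator cycle with its phase boundaries and timings."""

    trigger_index: int        # inspiration start (inclusive)
    cycle_index: int          # inspiration -> expiration transition
    end_index: int            # exclusive; next trigger or stream end
    ti_s: float               # inspiratory time, s
    te_s: float               # expiratory time, s

    @classmethod
    def from_indices(
        cls, trigger: int, cycle: int, end: int, sample_rate_hz: float
    ) -> "Breath":
        if not (trigger < cycle <= end):
            raise ContractError(
                f"need trigger < cycle <= end, got {trigger}/{cycle}/{end}"
            )
        return cls(
            trigger_index=trigger,
            cycle_index=cycle,
            end_index=end,
            ti_s=(cycle - trigger) / sample_rate_hz,
            te_s=(end - cycle) / sample_rate_hz,
        )


@dataclass
class SegmentationConfig:
    """Thresholds for flow-based breath delimitation.

    Defaults suit adult volume/pressure ventilation exported at 50 Hz.
    ``trigger_hold_s = 0`` reduces the trigger rule to a bare threshold
    crossing with hysteresis.
    """

    flow_trigger_threshold: float = 2.0    # L/min
    flow_cycle_threshold: float = -2.0     # L/min
    min_ti_s: float = 0.10                 # discard shorter inspirations
    min_breath_s: float = 0.30             # discard shorter candidate breaths
    ti_avg_window: int = 10                # breaths in the rolling mean Ti
    trigger_hold_s: float = 0.20           # flow must stay above threshold

    def __post_init__(self) -> None:
        for name in ("flow_trigger_threshold", "flow_cycle_threshold"):
            if not np.isfinite(getattr(self, name)):
                raise ConfigError(f"{name} must be finite")
        if not self.min_ti_s < self.min_breath_s:
            raise ConfigError("min_ti_s must be < min_breath_s")
        if self.ti_avg_window < 1:
            raise ConfigError("ti_avg_window must be >= 1")
        if self.trigger_hold_s < 0:
            raise ConfigError("trigger_hold_s must be >= 0")


def _confirmed_triggers(flow: np.ndarray, cfg: SegmentationConfig, fs: float) -> list[int]:
    th = cfg.flow_trigger_threshold
    above = flow >= th
    rising = np.flatnonzero(above[1:] & ~above[:-1]) + 1
    candidates = list(rising)
    if above[0]:
        candidates.insert(0, 0)
    hold_n = max(1, int(round(cfg.trigger_hold_s * fs)))
    confirmed = []
    for c in candidates:
        stop = min(c + hold_n, len(flow))
        if above[c:stop].all():
            confirmed.append(int(c))
    return confirmed


def segment_breaths(
    s: VentStream, cfg: Optional[SegmentationConfig] = None
) -> list[Breath]:
    """Partition a cleaned stream into ordered, non-overlapping breaths.

    Candidate breaths whose inspiratory time is below ``min_ti_s`` or whose
    total duration is below ``min_breath_s`` are treated as noise: their
    trigger is removed and the span is absorbed by the preceding breath.
    A breath with no expiratory crossing gets ``cycle_index == end_index``
    (te = 0), which the double-trigger detector reads as "no expiratory
    phase".
    """
    cfg = cfg or SegmentationConfig()
    flow = s.flow
    fs = s.sample_rate_hz
    n = len(flow)
    if n < cfg.min_breath_s * fs:
        raise DataError(
            f"stream of {n} samples is shorter than one minimal breath "
            f"({cfg.min_breath_s} s at {fs} Hz)"
        )
    triggers = _confirmed_triggers(flow, cfg, fs)

    def build(trigs: list[int]) -> list[Breath]:
        out = []
        for j, t in enumerate(trigs):
            end = trigs[j + 1] if j + 1 < len(trigs) else n
            seg = flow[t + 1 : end]
            below = np.flatnonzero(seg < cfg.flow_cycle_threshold)
            cycle = int(t + 1 + below[0]) if below.size else int(end)
            out.append(Breath.from_indices(int(t), cycle, int(end), fs))
        return out

    # iteratively drop noise triggers; removal only lengthens survivors
    while triggers:
        breaths = build(triggers)
        noise = [
            j
            for j, b in enumerate(breaths)
            if b.ti_s < cfg.min_ti_s or (b.end_index - b.trigger_index) / fs < cfg.min_breath_s
        ]
        if not noise:
            return breaths
        keep = set(range(len(triggers))) - set(noise)
        triggers = [triggers[j] for j in sorted(keep)]
    return []


def mean_inspiratory_time(
    breaths: Sequence[Breath], upto: int, window: int
) -> float:
    """Rolling mean Ti over the last ``min(window, upto)`` breaths.

    The mean covers breaths ``upto - k .. upto - 1`` (0-based), i.e. every
    breath strictly before index ``upto``.
    """
    if not breaths:
        raise DataError("cannot average inspiratory time of an empty breath list")
    if upto < 1 or window < 1:
        raise ContractError("upto and window must be >= 1")
    upto = min(upto, len(breaths))
    tis = [b.ti_s for b in breaths[max(0, upto - window) : upto]]
    return float(np.mean(tis))


@dataclass
class BreathStats:
    """Per-breath summary table plus stream-level rates."""

    per_breath: pd.DataFrame
    respiratory_rate_per_min: float
    minute_ventilation_l_per_min: float

    def to_csv(self, path) -> None:
        self.per_breath.to_csv(path, index=False)


def breath_parameters(
    s: VentStream, breaths: Sequence[Breath], peep_window_s: float = 0.2
) -> BreathStats:
    """Ventilation parameters per breath and for the whole stream.

    Per breath: peak airway pressure, PEEP (mean Paw over the last
    ``peep_window_s`` of expiration — a stable plateau region), inspiratory
    tidal volume (max volume minus volume at trigger), Ti and Te.  Stream
    level: respiratory rate (breaths/min) and minute ventilation (L/min),
    both over the span covered by the breaths.
    """
    if not breaths:
        raise DataError("no breaths to summarise")
    fs = s.sample_rate_hz
    rows = []
    peep_n = max(1, int(round(peep_window_s * fs)))
    for k, b in enumerate(breaths):
        paw_seg = s.paw[b.trigger_index : b.end_index]
        vol_seg = s.volume[b.trigger_index : b.end_index]
        tail_start = max(b.cycle_index, b.end_index - peep_n)
        peep_seg = s.paw[tail_start : b.end_index]
        if peep_seg.size == 0:  # te == 0 breath: fall back to last sample
            peep_seg = s.paw[b.end_index - 1 : b.end_index]
        rows.append(
            {
                "ordinal": k,
                "trigger_index": b.trigger_index,
                "cycle_index": b.cycle_index,
                "end_index": b.end_index,
                "ti_s": b.ti_s,
                "te_s": b.te_s,
                "peak_pressure_cmh2o": float(paw_seg.max()),
                "peep_cmh2o": float(peep_seg.mean()),
                "tidal_volume_ml": float(vol_seg.max() - vol_seg[0]),
            }
        )
    df = pd.DataFrame(rows)
    span_min = (breaths[-1].end_index - breaths[0].trigger_index) / fs / 60.0
    rr = len(breaths) / span_min if span_min > 0 else float("nan")
    mv = df["tidal_volume_ml"].sum() / span_min / 1000.0 if span_min > 0 else float("nan")
    return BreathStats(
        per_breath=df,
        respiratory_rate_per_min=float(rr),
        minute_ventilation_l_per_min=float(mv),
    )
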