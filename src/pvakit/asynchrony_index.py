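"""Sliding-window asynchrony index (AI) and severe-asynchrony alarms.

AI over a window = 100 x (asynchrony events) / (ventilator cycles +
ineffective-trigger count).  Ineffective efforts are missed cycles, so they
enter the denominator as well as the numerator; double triggers add events
but no extra denominator term.  Severe asynchrony is AI >= 10%.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .detectors import PvaEvent
from .errors import ConfigError
from .segmentation import Breath

logger = logging.getLogger(__name__)


@dataclass
class AiConfig:
    """Window geometry and alarm threshold for the asynchrony index.

    Clinically meaningful windows are 3-6 min; the default range check can
    be switched off with ``validate_range=False`` for experimentation.
    """

    window_s: float = 240.0
    step_s: float = 1.0
    severe_threshold_pct: float = 10.0
    validate_range: bool = True

    def __post_init__(self) -> None:
        if self.step_s <= 0:
            raise ConfigError("step_s must be > 0")
        if self.window_s <= 0:
            raise ConfigError("window_s must be > 0")
        if self.validate_range and not (180.0 <= self.window_s <= 360.0):
            raise ConfigError(
                f"window_s={self.window_s} outside the 180-360 s range "
                "(pass validate_range=False to override)"
            )


@dataclass
class AiSeries:
    """Asynchrony-index values per sliding window plus alarm flags."""

    window_end_times: np.ndarray   # s
    ai_pct: np.ndarray             # NaN where the denominator is zero
    n_events: np.ndarray
    denominator: np.ndarray
    alarm: np.ndarray              # bool; False where AI is undefined
    config: AiConfig = field(default_factory=AiConfig)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "window_end_s": self.window_end_times,
                "ai_pct": self.ai_pct,
                "n_events": self.n_events,
                "denominator": self.denominator,
                "alarm": self.alarm,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.8g")


def compute_ai(
    breaths: Sequence[Breath],
    events: Sequence[PvaEvent],
    cfg: Optional[AiConfig] = None,
    stream_duration_s: Optional[float] = None,
    sample_rate_hz: float = 50.0,
) -> AiSeries:
    """Asynchrony index over windows [t - window_s, t] stepped by step_s.

    A breath belongs to a window when its trigger time falls inside the
    half-open interval [t - window_s, t); events are binned the same way.
    (Half-open windows make non-overlapping windows partition the stream,
    so event counts are conserved.)
    Windows with zero denominator report AI = NaN and no alarm.  A stream
    shorter than one window yields a single truncated window (logged).
    """
    cfg = cfg or AiConfig()
    if stream_duration_s is None:
        stream_duration_s = (breaths[-1].end_index / sample_rate_hz) if breaths else 0.0
    breath_t = np.sort(np.array([b.trigger_index for b in breaths])) / sample_rate_hz
    ev = sorted(events, key=lambda e: e.sample_index)
    ev_t = np.array([e.sample_index for e in ev]) / sample_rate_hz
    it_t = np.array(
        [e.sample_index for e in ev if e.event_type == "ineffective_trigger"]
    ) / sample_rate_hz

    if stream_duration_s < cfg.window_s:
        logger.warning(
            "stream (%.1f s) shorter than one %.0f s window; "
            "reporting a single truncated window",
            stream_duration_s,
            cfg.window_s,
        )
        ends = np.array([stream_duration_s])
    else:
        n_win = int(np.floor((stream_duration_s - cfg.window_s) / cfg.step_s)) + 1
        ends = cfg.window_s + cfg.step_s * np.arange(n_win)

    starts = np.maximum(ends - cfg.window_s, 0.0)

    def count(times: np.ndarray) -> np.ndarray:
        # half-open [start, end)
        lo = np.searchsorted(times, starts, side="left")
        hi = np.searchsorted(times, ends, side="left")
        return hi - lo

    n_breaths = count(breath_t)
    n_it = count(it_t)
    n_ev = count(ev_t)
    den = n_breaths + n_it
    with np.errstate(invalid="ignore", divide="ignore"):
        ai = np.where(den > 0, 100.0 * n_ev / np.maximum(den, 1), np.nan)
    alarm = np.where(den > 0, ai >= cfg.severe_threshold_pct, False)
    return AiSeries(
        window_end_times=ends,
        ai_pct=ai,
        n_events=n_ev,
        denominator=den,
        alarm=alarm.astype(bool),
        config=cfg,
    )


def alarm_episodes(ai: AiSeries) -> list[tuple[float, float]]:
    """Merge maximal runs of consecutive alarmed windows into episodes.

    Each episode is (end time of first alarmed window, end time of last),
    in seconds; episodes are ordered and non-overlapping.
    """
    episodes = []
    start = None
    for t, a in zip(ai.window_end_times, ai.alarm):
        if a and start is None:
            start = float(t)
        elif not a and start is not None:
            episodes.append((start, prev))
            start = None
        if a:
            prev = float(t)
    if start is not None:
        episodes.append((start, prev))
    return episodes
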