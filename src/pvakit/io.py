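"""Reading, writing, validation and cleaning of ventilator waveform streams.

The on-disk dialect is deliberately open and minimal: a CSV (or JSONL) file
with columns/keys ``time`` (optional, seconds), ``paw`` (airway pressure,
cmH2O), ``flow`` (L/min) and ``volume`` (mL), sampled at a constant rate
(ventilator exports are typically 50 Hz).  Event annotations travel in a
four-column CSV (``event_type,sample_index,end_index,source``).
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from ._utils import moving_average
from .errors import DataError, FormatError

EVENT_TYPES = ("double_trigger", "ineffective_trigger")
EVENT_SOURCES = ("gold", "predicted")

_WAVE_COLUMNS = ("paw", "flow", "volume")

#: maximum tolerated inter-sample clock jitter when inferring the sample
#: rate from a time column (relative to the median interval)
MAX_TIME_JITTER = 0.05

#: cleaning gives up when more than this fraction of a channel is invalid
MAX_INVALID_FRACTION = 0.10


@dataclass
class VentStream:
    """Synchronised airway-pressure / flow / volume sample arrays.

    Units follow ventilator-display convention: ``paw`` in cmH2O, ``flow``
    in L/min, ``volume`` in mL.  All three channels share one sample clock.
    """

    sample_rate_hz: float
    paw: np.ndarray
    flow: np.ndarray
    volume: np.ndarray
    start_time: Optional[str] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.paw = np.asarray(self.paw, dtype=float)
        self.flow = np.asarray(self.flow, dtype=float)
        self.volume = np.asarray(self.volume, dtype=float)
        if not (len(self.paw) == len(self.flow) == len(self.volume)):
            raise DataError(
                "paw/flow/volume must have identical length, got "
                f"{len(self.paw)}/{len(self.flow)}/{len(self.volume)}"
            )
        if len(self.paw) < 1:
            raise DataError("stream must contain at least one sample")
        if not (self.sample_rate_hz > 0):
            raise DataError(f"sample_rate_hz must be > 0, got {self.sample_rate_hz}")

    def __len__(self) -> int:
        return len(self.flow)

    @property
    def duration_s(self) -> float:
        return len(self) / self.sample_rate_hz

    @property
    def time_s(self) -> np.ndarray:
        """Sample times in seconds from stream start."""
        return np.arange(len(self)) / self.sample_rate_hz

    def is_finite(self) -> bool:
        return bool(
            np.isfinite(self.paw).all()
            and np.isfinite(self.flow).all()
            and np.isfinite(self.volume).all()
        )

    def to_frame(self, include_time: bool = True) -> pd.DataFrame:
        data = {}
        if include_time:
            data["time"] = self.time_s
        data.update(paw=self.paw, flow=self.flow, volume=self.volume)
        return pd.DataFrame(data)


@dataclass(frozen=True)
class EventAnnotation:
    """One asynchrony event, detected or gold-standard.

    ``sample_index`` anchors the event on the stream's sample clock;
    ``end_index`` (optional, inclusive of extent semantics upstream) marks
    the end of an event annotated as a span rather than a point.
    """

    event_type: str
    sample_index: int
    end_index: Optional[int] = None
    source: str = "predicted"

    def __post_init__(self) -> None:
        if self.event_type not in EVENT_TYPES:
            raise FormatError(f"unknown event_type {self.event_type!r}")
        if self.source not in EVENT_SOURCES:
            raise FormatError(f"unknown source {self.source!r}")
        if self.sample_index < 0:
            raise FormatError("sample_index must be >= 0")
        if self.end_index is not None and self.end_index < self.sample_index:
            raise FormatError("end_index must be >= sample_index")


def _infer_format(path: Path, fmt: Optional[str]) -> str:
    if fmt is not None:
        return fmt
    suffix = path.suffix.lower()
    if suffix in (".jsonl", ".ndjson"):
        return "jsonl"
    return "csv"


def _rate_from_time(time: np.ndarray) -> float:
    dt = np.diff(time)
    if len(dt) == 0:
        raise DataError("cannot infer sample rate from a single sample")
    if np.any(dt <= 0):
        raise DataError("time column is not strictly increasing")
    med = float(np.median(dt))
    jitter = float(np.max(np.abs(dt - med))) / med
    if jitter >= MAX_TIME_JITTER:
        raise DataError(
            f"inter-sample jitter {jitter:.1%} exceeds {MAX_TIME_JITTER:.0%}; "
            "time column unusable for rate inference"
        )
    return 1.0 / med


def read_stream(
    path: str | Path,
    fmt: Optional[str] = None,
    sample_rate_hz: float = 50.0,
) -> VentStream:
    """Read a waveform file (CSV or JSONL) into a :class:`VentStream`.

    When a ``time`` column is present the sample rate is inferred from the
    median inter-sample interval (rejected if jitter >= 5% or the column is
    not strictly increasing); otherwise ``sample_rate_hz`` is used.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _infer_format(path, fmt)
    try:
        if fmt == "csv":
            df = pd.read_csv(path)
        elif fmt == "jsonl":
            df = pd.read_json(path, lines=True)
        else:
            raise FormatError(f"unknown stream format {fmt!r}")
    except (pd.errors.EmptyDataError, ValueError) as exc:
        if isinstance(exc, FormatError):
            raise
        raise DataError(f"could not parse {path}: {exc}") from exc
    if df.empty:
        raise DataError(f"{path} contains no samples")
    missing = [c for c in _WAVE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path} is missing column(s): {', '.join(missing)}")
    rate = sample_rate_hz
    start_time = None
    if "time" in df.columns:
        time = df["time"].to_numpy(dtype=float)
        if len(time) > 1:
            rate = _rate_from_time(time)
        start_time = str(float(time[0]))
    return VentStream(
        sample_rate_hz=rate,
        paw=df["paw"].to_numpy(dtype=float),
        flow=df["flow"].to_numpy(dtype=float),
        volume=df["volume"].to_numpy(dtype=float),
        start_time=start_time,
        meta={"source_path": str(path)},
    )


def write_stream(
    s: VentStream,
    path: str | Path,
    fmt: Optional[str] = None,
    include_time: bool = True,
) -> None:
    """Write a stream as CSV or JSONL with 8 significant digits per value."""
    path = Path(path)
    fmt = _infer_format(path, fmt)
    df = s.to_frame(include_time=include_time)
    if fmt == "csv":
        df.to_csv(path, index=False, float_format="%.8g")
    elif fmt == "jsonl":
        df.to_json(path, orient="records", lines=True, double_precision=10)
    else:
        raise FormatError(f"unknown stream format {fmt!r}")


def clean_stream(
    s: VentStream,
    policy: str = "interpolate",
    smooth_window: Optional[int] = None,
) -> VentStream:
    """Replace or reject NaN/Inf samples; optionally smooth all channels.

    ``policy="interpolate"`` fills invalid samples by linear interpolation
    against the sample index (edges take the nearest valid value) and fails
    with :class:`DataError` when more than 10% of any channel is invalid —
    past that point detection thresholds are meaningless.
    ``policy="reject"`` raises on the first invalid sample.

    With ``smooth_window`` set (odd integer), a centred moving average is
    applied to every channel after filling.  The default (no smoothing)
    makes the operation idempotent.
    """
    if policy not in ("reject", "interpolate"):
        raise FormatError(f"unknown cleaning policy {policy!r}")
    channels = {}
    for name in _WAVE_COLUMNS:
        x = getattr(s, name).astype(float).copy()
        bad = ~np.isfinite(x)
        if bad.any():
            if policy == "reject":
                raise DataError(f"channel {name!r} contains invalid samples")
            frac = bad.mean()
            if frac > MAX_INVALID_FRACTION:
                raise DataError(
                    f"channel {name!r} is {frac:.1%} invalid "
                    f"(limit {MAX_INVALID_FRACTION:.0%}); signal unusable"
                )
            idx = np.arange(len(x))
            x[bad] = np.interp(idx[bad], idx[~bad], x[~bad])
        if smooth_window is not None:
            x = moving_average(x, smooth_window)
        channels[name] = x
    return replace(s, **channels)


def write_events(events: Sequence[EventAnnotation], path: str | Path) -> None:
    """Write annotations as CSV (sorted by sample index; header always)."""
    rows = sorted(events, key=lambda e: (e.sample_index, e.event_type))
    df = pd.DataFrame(
        {
            "event_type": [e.event_type for e in rows],
            "sample_index": [e.sample_index for e in rows],
            "end_index": [e.end_index for e in rows],
            "source": [e.source for e in rows],
        }
    )
    df.to_csv(path, index=False)


def read_events(path: str | Path) -> list[EventAnnotation]:
    """Read an annotation CSV written by :func:`write_events`."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path} has no header row") from exc
    expected = ["event_type", "sample_index", "end_index", "source"]
    missing = [c for c in expected if c not in df.columns]
    if missing:
        raise FormatError(f"{path} is missing column(s): {', '.join(missing)}")
    events = []
    for row in df.itertuples(index=False):
        try:
            sample_index = int(row.sample_index)
        except (TypeError, ValueError) as exc:
            raise FormatError(f"bad sample_index {row.sample_index!r}") from exc
        end_index = None if pd.isna(row.end_index) else int(row.end_index)
        events.append(
            EventAnnotation(
                event_type=str(row.event_type),
                sample_index=sample_index,
                end_index=end_index,
                source=str(row.source),
            )
        )
    return events
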