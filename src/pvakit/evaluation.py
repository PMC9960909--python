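"""Per-breath event matching, confusion matrices, and diagnostic metrics.

Detected and gold events are projected onto breaths (the clinical unit of
analysis), cross-tabulated into a 2x2 confusion matrix per event type, and
summarised as sensitivity, specificity, positive predictive value and
negative predictive value on the percent scale with half-up rounding.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional, Sequence, Union

import numpy as np

from .detectors import DetectorConfig, PvaEvent, detect_double_trigger, detect_ineffective_trigger
from .errors import ContractError, DataError
from .io import EventAnnotation, VentStream
from .segmentation import Breath, SegmentationConfig, segment_breaths

logger = logging.getLogger(__name__)

AnyEvent = Union[PvaEvent, EventAnnotation]

#: events falling outside every breath attach to the nearest breath within
#: this tolerance (annotation timestamps may sit on breath boundaries)
MATCH_TOLERANCE_S = 0.5


@dataclass(frozen=True)
class ConfusionMatrix:
    """2x2 cross-tabulation of predicted vs gold per-breath labels."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ContractError("confusion-matrix cells must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class Metrics:
    """Diagnostic test metrics in percent; NaN where undefined."""

    sensitivity_pct: float
    specificity_pct: float
    ppv_pct: float
    npv_pct: float


def label_breaths(
    breaths: Sequence[Breath],
    events: Sequence[AnyEvent],
    event_type: str,
    sample_rate_hz: float = 50.0,
) -> np.ndarray:
    """Boolean per-breath labels: True iff >= 1 event of ``event_type`` is
    anchored within the breath's [trigger, end) span.

    An event outside every breath attaches to the nearest breath if it lies
    within 0.5 s of it; otherwise it is dropped with a warning.  Multiple
    events in one breath yield a single positive label.
    """
    if not breaths:
        raise DataError("cannot label an empty breath list")
    labels = np.zeros(len(breaths), dtype=bool)
    trig = np.array([b.trigger_index for b in breaths])
    ends = np.array([b.end_index for b in breaths])
    tol_n = MATCH_TOLERANCE_S * sample_rate_hz
    for e in events:
        if e.event_type != event_type:
            continue
        idx = e.sample_index
        j = int(np.searchsorted(trig, idx, side="right")) - 1
        if j >= 0 and idx < ends[j]:
            labels[j] = True
            continue
        # outside all breaths: distance to the nearest breath span
        dists = np.where(idx < trig, trig - idx, np.maximum(idx - ends + 1, 0))
        jn = int(np.argmin(dists))
        if dists[jn] <= tol_n:
            labels[jn] = True
            logger.warning(
                "event at sample %d outside all breaths; attached to breath %d",
                idx,
                jn,
            )
        else:
            logger.warning(
                "event at sample %d is > %.1f s from any breath; dropped",
                idx,
                MATCH_TOLERANCE_S,
            )
    return labels


def confusion(pred_labels: Sequence[bool], gold_labels: Sequence[bool]) -> ConfusionMatrix:
    """Standard 2x2 cross-tabulation of equal-length boolean sequences."""
    pred = np.asarray(pred_labels, dtype=bool)
    gold = np.asarray(gold_labels, dtype=bool)
    if pred.shape != gold.shape:
        raise ContractError(
            f"label length mismatch: {pred.shape} vs {gold.shape}"
        )
    return ConfusionMatrix(
        tp=int(np.sum(pred & gold)),
        fp=int(np.sum(pred & ~gold)),
        fn=int(np.sum(~pred & gold)),
        tn=int(np.sum(~pred & ~gold)),
    )


def _pct(num: int, den: int, decimals: int) -> float:
    if den == 0:
        return float("nan")
    q = Decimal(num) * 100 / Decimal(den)
    return float(q.quantize(Decimal(1).scaleb(-decimals), rounding=ROUND_HALF_UP))


def metrics(cm: ConfusionMatrix, decimals: int = 2) -> Metrics:
    """Sensitivity, specificity, PPV and NPV in percent.

    Rounding is decimal half-up to ``decimals`` places (the convention of
    clinical reporting; note that float/banker's rounding differs on ties).
    """
    return Metrics(
        sensitivity_pct=_pct(cm.tp, cm.tp + cm.fn, decimals),
        specificity_pct=_pct(cm.tn, cm.tn + cm.fp, decimals),
        ppv_pct=_pct(cm.tp, cm.tp + cm.fp, decimals),
        npv_pct=_pct(cm.tn, cm.tn + cm.fn, decimals),
    )


@dataclass(frozen=True)
class EvalResult:
    confusion: ConfusionMatrix
    metrics: Metrics


def evaluate_run(
    stream: VentStream,
    gold_events: Sequence[AnyEvent],
    seg_cfg: Optional[SegmentationConfig] = None,
    det_cfg: Optional[DetectorConfig] = None,
) -> dict[str, EvalResult]:
    """End-to-end harness: segment, detect, label, cross-tabulate.

    Returns one :class:`EvalResult` per event type
    (``double_trigger`` and ``ineffective_trigger``).
    """
    breaths = segment_breaths(stream, seg_cfg)
    predicted: list[PvaEvent] = detect_double_trigger(stream, breaths, det_cfg)
    predicted += detect_ineffective_trigger(stream, breaths, det_cfg)
    out = {}
    for event_type in ("double_trigger", "ineffective_trigger"):
        pred = label_breaths(breaths, predicted, event_type, stream.sample_rate_hz)
        gold = label_breaths(breaths, gold_events, event_type, stream.sample_rate_hz)
        cm = confusion(pred, gold)
        out[event_type] = EvalResult(confusion=cm, metrics=metrics(cm))
    return out
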