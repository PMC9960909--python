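"""Structured analysis report for one asynchrony-index window.

The report mirrors what a bedside clinician needs when an alarm fires:
patient/ventilator identification, the asynchrony index and its severity,
per-type event counts, the ventilation parameters over the window, and the
sample range of the triggering window so the waveform excerpt can be
pulled up.  Serialisable to canonical JSON (byte-stable for identical
inputs) and to human-readable markdown; the JSON schema ships with the
package (``pvakit/schemas/analysis_report.schema.json``).
"""
from __future__ import annotations

import json
from importlib import resources
from typing import Optional, Sequence

import numpy as np
from pydantic import BaseModel, ConfigDict

from .asynchrony_index import AiSeries
from .detectors import PvaEvent
from .errors import ContractError, DataError
from .io import VentStream
from .segmentation import Breath, breath_parameters


class DiagnosticReference(BaseModel):
    model_config = ConfigDict(extra="forbid")
    window_end_s: float
    window_s: float
    ai_pct: Optional[float]
    severe: bool
    severe_threshold_pct: float
    event_counts: dict[str, int]


class VentilatorParameters(BaseModel):
    model_config = ConfigDict(extra="forbid")
    peak_pressure_cmh2o: Optional[float] = None
    peep_cmh2o: Optional[float] = None
    total_rr_per_min: Optional[float] = None
    tidal_volume_ml: Optional[float] = None
    minute_ventilation_l_per_min: Optional[float] = None
    fio2_pct: Optional[float] = None


class WaveformExcerpt(BaseModel):
    model_config = ConfigDict(extra="forbid")
    start_index: int
    end_index: int


class AnalysisReport(BaseModel):
    """Analysis report for one sliding-window snapshot."""

    model_config = ConfigDict(extra="forbid")
    basic_info: dict[str, str]
    diagnostic_reference: DiagnosticReference
    prompts_findings: list[str]
    ventilator_parameters: VentilatorParameters
    waveform_excerpt: WaveformExcerpt

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.model_dump(), indent=indent, sort_keys=True, allow_nan=False)

    def to_markdown(self) -> str:
        d = self.diagnostic_reference
        v = self.ventilator_parameters
        lines = ["# Mechanical ventilation analysis report", "", "## Basic information"]
        lines += [f"- {k}: {val}" for k, val in sorted(self.basic_info.items())] or ["- (none)"]
        ai_txt = "undefined" if d.ai_pct is None else f"{d.ai_pct:.2f}%"
        lines += [
            "",
            "## Diagnostic reference",
            f"- Window: {d.window_s:.0f} s ending at {d.window_end_s:.0f} s",
            f"- Asynchrony index: {ai_txt} "
            f"(severe threshold {d.severe_threshold_pct:.0f}%)",
            f"- Severe asynchrony: {'YES' if d.severe else 'no'}",
        ]
        lines += [
            f"- {name.replace('_', ' ')} events: {count}"
            for name, count in sorted(d.event_counts.items())
        ]
        lines += ["", "## Prompts and findings"]
        lines += [f"- {p}" for p in self.prompts_findings]
        lines += ["", "## Ventilator parameters"]
        for label, value, unit in (
            ("Peak pressure", v.peak_pressure_cmh2o, "cmH2O"),
            ("PEEP", v.peep_cmh2o, "cmH2O"),
            ("Total respiratory rate", v.total_rr_per_min, "/min"),
            ("Tidal volume", v.tidal_volume_ml, "mL"),
            ("Minute ventilation", v.minute_ventilation_l_per_min, "L/min"),
            ("FiO2", v.fio2_pct, "%"),
        ):
            if value is not None:
                lines.append(f"- {label}: {value:.2f} {unit}")
        lines += [
            "",
            "## Waveform excerpt",
            f"- samples [{self.waveform_excerpt.start_index}, "
            f"{self.waveform_excerpt.end_index})",
            "",
        ]
        return "\n".join(lines)


def report_json_schema() -> dict:
    """The JSON schema of :class:`AnalysisReport` (also shipped on disk)."""
    return AnalysisReport.model_json_schema()


def load_shipped_schema() -> dict:
    text = resources.files("pvakit.schemas").joinpath("analysis_report.schema.json").read_text()
    return json.loads(text)


def validate_report(data: dict) -> AnalysisReport:
    """Validate a report dict against the schema; returns the model."""
    return AnalysisReport.model_validate(data)


def _round2(x: float) -> float:
    return float(np.round(x, 2))


def generate_report(
    stream: VentStream,
    breaths: Sequence[Breath],
    events: Sequence[PvaEvent],
    ai: AiSeries,
    window_end_s: float,
    basic_info: Optional[dict[str, str]] = None,
) -> AnalysisReport:
    """Build the analysis report for the AI window ending at ``window_end_s``.

    The window must match one of the computed AI windows (within half a
    step).  Event counts, severity and ventilation parameters are taken
    over that window only; the prompt strings are deterministic templates
    naming the dominant event type.
    """
    ends = np.asarray(ai.window_end_times, dtype=float)
    if ends.size == 0:
        raise DataError("AI series is empty")
    j = int(np.argmin(np.abs(ends - window_end_s)))
    if abs(ends[j] - window_end_s) > ai.config.step_s / 2 + 1e-9:
        raise ContractError(
            f"no AI window ends at {window_end_s} s "
            f"(nearest: {ends[j]} s)"
        )
    fs = stream.sample_rate_hz
    end_s = float(ends[j])
    start_s = max(end_s - ai.config.window_s, 0.0)
    start_idx = int(round(start_s * fs))
    end_idx = min(int(round(end_s * fs)), len(stream))

    counts = {"double_trigger": 0, "ineffective_trigger": 0}
    for e in events:
        if start_idx <= e.sample_index < end_idx:
            counts[e.event_type] = counts.get(e.event_type, 0) + 1

    window_breaths = [
        b for b in breaths if start_idx <= b.trigger_index < end_idx
    ]
    params = VentilatorParameters()
    if window_breaths:
        stats = breath_parameters(stream, window_breaths)
        df = stats.per_breath
        fio2 = stream.meta.get("fio2_pct")
        params = VentilatorParameters(
            peak_pressure_cmh2o=_round2(df["peak_pressure_cmh2o"].max()),
            peep_cmh2o=_round2(df["peep_cmh2o"].mean()),
            total_rr_per_min=_round2(stats.respiratory_rate_per_min),
            tidal_volume_ml=_round2(df["tidal_volume_ml"].mean()),
            minute_ventilation_l_per_min=_round2(stats.minute_ventilation_l_per_min),
            fio2_pct=float(fio2) if fio2 is not None else None,
        )

    ai_val = float(ai.ai_pct[j])
    ai_out: Optional[float] = None if np.isnan(ai_val) else _round2(ai_val)
    severe = bool(ai.alarm[j])

    prompts = []
    total_events = sum(counts.values())
    if total_events == 0:
        prompts.append("No patient-ventilator asynchrony detected in this window.")
    else:
        dominant = max(sorted(counts), key=lambda k: counts[k])
        prompts.append(
            f"{total_events} asynchrony event(s) in the last "
            f"{ai.config.window_s:.0f} s; dominant type: "
            f"{dominant.replace('_', ' ')}."
        )
        if severe:
            prompts.append(
                f"Severe patient-ventilator asynchrony: index "
                f"{ai_out}% >= {ai.config.severe_threshold_pct:.0f}%. "
                "Review trigger sensitivity, support level and sedation."
            )

    return AnalysisReport(
        basic_info={k: str(v) for k, v in (basic_info or stream.meta).items()},
        diagnostic_reference=DiagnosticReference(
            window_end_s=end_s,
            window_s=float(ai.config.window_s),
            ai_pct=ai_out,
            severe=severe,
            severe_threshold_pct=float(ai.config.severe_threshold_pct),
            event_counts=counts,
        ),
        prompts_findings=prompts,
        ventilator_parameters=params,
        waveform_excerpt=WaveformExcerpt(start_index=start_idx, end_index=end_idx),
    )
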