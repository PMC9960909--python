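"""Synthetic ventilator waveforms from a single-compartment lung model,
with labelled double-trigger and ineffective-trigger injection.

The model is the standard equation of motion Paw = R*Q + V/C + PEEP with
resistance R (cmH2O/(L/s)) and compliance C (mL/cmH2O).  Insufflation is
volume-control style (constant inspiratory flow VT/Ti); expiration is
passive with time constant tau = R*C.  The passive phase is advanced one
sample at a time with the exact exponential (analytic) one-step update, so
the emitted decay matches the closed form to machine precision; emitted
flow is the per-step volume change divided by dt, making the flow and
volume channels exactly conservation-consistent.

Event injection:

* Double trigger (DT): the flagged breath's expiration is truncated at a
  duration drawn uniformly from (0, 0.4*Ti) and a second full insufflation
  follows, guaranteeing Te < 0.5 * mean Ti.
* Ineffective trigger (IT): a raised-cosine inspiratory-effort flow bump
  (amplitude ``it_amplitude_lpm``, span ``it_duration_s``) is driven into
  the passive expiration, together with a small concurrent negative airway
  pressure dip.  The effort volume is re-exhaled through the passive time
  constant, as in a real lung; the effort does not trigger a breath.

Every injection is recorded as a gold annotation and in the breath log;
identical configurations (including seed) produce bit-identical output.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .errors import ConfigError
from .io import EventAnnotation, VentStream

_ML_S_TO_LPM = 60.0 / 1000.0  # mL/s -> L/min


@dataclass
class SimConfig:
    """Simulation parameters.

    Mechanics defaults describe a typical passively ventilated adult
    (R = 10 cmH2O/(L/s), C = 50 mL/cmH2O, tau = 0.5 s, VT = 440 mL,
    PEEP = 5 cmH2O, 15 breaths/min with Ti = 1 s).
    """

    duration_s: float = 60.0
    sample_rate_hz: float = 50.0
    resistance: float = 10.0          # cmH2O/(L/s)
    compliance: float = 50.0          # mL/cmH2O
    peep: float = 5.0                 # cmH2O
    tidal_volume_ml: float = 440.0
    ti_s: float = 1.0
    rr_per_min: float = 15.0
    dt_rate: float = 0.0              # P(double trigger) per breath
    it_rate: float = 0.0              # P(ineffective effort) per expiration
    it_amplitude_lpm: float = 8.0
    it_duration_s: float = 0.3
    it_center_frac: float = 0.65      # effort centre, fraction of expiration
    it_paw_dip_cmh2o: float = 1.5
    dt_te_frac_max: float = 0.4       # truncated Te upper bound, x Ti
    noise_sd_lpm: float = 0.0
    seed: int = 0

    @property
    def period_s(self) -> float:
        return 60.0 / self.rr_per_min

    @property
    def tau_s(self) -> float:
        return self.resistance * self.compliance / 1000.0

    def __post_init__(self) -> None:
        for name in (
            "duration_s",
            "sample_rate_hz",
            "resistance",
            "compliance",
            "tidal_volume_ml",
            "ti_s",
            "rr_per_min",
        ):
            if not getattr(self, name) > 0:
                raise ConfigError(f"{name} must be > 0")
        for name in ("dt_rate", "it_rate"):
            if not 0 <= getattr(self, name) < 1:
                raise ConfigError(f"{name} must lie in [0, 1)")
        if self.ti_s >= self.period_s:
            raise ConfigError("ti_s must be shorter than the breath period")
        if self.dt_rate > 0 and (2 + self.dt_te_frac_max) * self.ti_s >= self.period_s:
            raise ConfigError(
                "a double-trigger pair (two insufflations plus truncated "
                "expiration) does not fit in one breath period"
            )
        if self.it_rate > 0:
            te = self.period_s - self.ti_s
            lo = self.it_center_frac * te - self.it_duration_s / 2
            hi = self.it_center_frac * te + self.it_duration_s / 2
            if lo <= 0 or hi >= te:
                raise ConfigError(
                    "ineffective-effort bump does not fit inside the "
                    "expiratory phase at the configured centre/duration"
                )


@dataclass
class SimResult:
    """Simulated stream, gold annotations, and per-cycle ground truth."""

    stream: VentStream
    gold_events: list[EventAnnotation]
    breath_log: pd.DataFrame
    config: SimConfig = field(repr=False, default=None)


def mechanics_step(
    volume_ml: float,
    cfg: SimConfig,
    drive_flow_mls: Optional[float] = None,
    effort_mls: float = 0.0,
) -> tuple[float, float, float]:
    """Advance the single-compartment model by one sample period.

    ``drive_flow_mls`` set: machine insufflation at that constant flow
    (mL/s); volume change is exactly flow x dt and Paw = PEEP + R*Q + V/C.
    ``drive_flow_mls`` None: passive expiration dV/dt = -V/tau + effort,
    advanced with the exact exponential update; Paw = PEEP + V/C (valve
    open, elastic recoil referenced to PEEP).

    Returns ``(new_volume_ml, paw_cmh2o, flow_lpm)`` where the flow is the
    average flow over the step, i.e. (V_new - V_old)/dt.
    """
    dt = 1.0 / cfg.sample_rate_hz
    if drive_flow_mls is not None:
        new_v = volume_ml + drive_flow_mls * dt
        paw = cfg.peep + cfg.resistance * (drive_flow_mls / 1000.0) + volume_ml / cfg.compliance
        flow_lpm = drive_flow_mls * _ML_S_TO_LPM
    else:
        k = math.exp(-dt / cfg.tau_s)
        new_v = volume_ml * k + effort_mls * cfg.tau_s * (1.0 - k)
        paw = cfg.peep + volume_ml / cfg.compliance
        flow_lpm = (new_v - volume_ml) / dt * _ML_S_TO_LPM
    return new_v, paw, flow_lpm


def _effort_bump(n_exp: int, cfg: SimConfig) -> np.ndarray:
    """Raised-cosine inspiratory-effort flow (mL/s) over an expiration."""
    fs = cfg.sample_rate_hz
    te = n_exp / fs
    center = cfg.it_center_frac * te
    half = cfg.it_duration_s / 2.0
    t = np.arange(n_exp) / fs
    bump = np.zeros(n_exp)
    inside = np.abs(t - center) <= half
    peak_mls = cfg.it_amplitude_lpm / _ML_S_TO_LPM
    bump[inside] = peak_mls * 0.5 * (1.0 + np.cos(np.pi * (t[inside] - center) / half))
    return bump


def _insufflation(cfg: SimConfig) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """One machine insufflation starting from volume 0 (display reset)."""
    fs = cfg.sample_rate_hz
    n = int(round(cfg.ti_s * fs))
    q = cfg.tidal_volume_ml / cfg.ti_s  # mL/s, constant
    vol = np.empty(n)
    paw = np.empty(n)
    flow = np.empty(n)
    v = 0.0
    for i in range(n):
        vol[i] = v
        v, paw[i], flow[i] = mechanics_step(v, cfg, drive_flow_mls=q)
    return paw, flow, vol


def _expiration(
    v0: float, n: int, cfg: SimConfig, effort: Optional[np.ndarray] = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    vol = np.empty(n)
    paw = np.empty(n)
    flow = np.empty(n)
    v = v0
    for i in range(n):
        vol[i] = v
        e = float(effort[i]) if effort is not None else 0.0
        v, paw[i], flow[i] = mechanics_step(v, cfg, effort_mls=e)
    return paw, flow, vol


def simulate(cfg: SimConfig) -> SimResult:
    """Generate a labelled synthetic ventilation run.

    The stream covers ``floor(duration_s / period)`` whole breath periods.
    Decision draws (one uniform per breath for DT, one per breath for IT)
    come from a dedicated stream so event placement is stable under
    changes to event-shape sampling.
    """
    fs = cfg.sample_rate_hz
    n_breaths = int(math.floor(cfg.duration_s / cfg.period_s + 1e-9))
    if n_breaths < 1:
        raise ConfigError("duration_s must cover at least one breath period")
    n_period = int(round(cfg.period_s * fs))
    n_ti = int(round(cfg.ti_s * fs))

    ss = np.random.SeedSequence(cfg.seed)
    rng_decide, rng_shape = (np.random.default_rng(s) for s in ss.spawn(2))

    paw_parts, flow_parts, vol_parts = [], [], []
    gold: list[EventAnnotation] = []
    log_rows = []
    cursor = 0  # absolute sample index of the current breath start
    machine_ordinal = 0

    insp_paw, insp_flow, insp_vol = _insufflation(cfg)

    for k in range(n_breaths):
        u_dt = rng_decide.uniform()
        u_it = rng_decide.uniform()
        is_dt = u_dt < cfg.dt_rate
        is_it = (not is_dt) and (u_it < cfg.it_rate)

        if is_dt:
            te1_s = float(rng_shape.uniform(0.0, cfg.dt_te_frac_max * cfg.ti_s))
            n_te1 = max(3, int(round(te1_s * fs)))
            n_te2 = n_period - 2 * n_ti - n_te1
            e1 = _expiration(cfg.tidal_volume_ml, n_te1, cfg)
            e2 = _expiration(cfg.tidal_volume_ml, n_te2, cfg)
            paw_parts += [insp_paw, e1[0], insp_paw, e2[0]]
            flow_parts += [insp_flow, e1[1], insp_flow, e2[1]]
            vol_parts += [insp_vol, e1[2], insp_vol, e2[2]]
            cycle1 = cursor + n_ti
            gold.append(
                EventAnnotation("double_trigger", sample_index=cycle1, source="gold")
            )
            log_rows.append(
                dict(
                    ordinal=machine_ordinal,
                    kind="dt_first",
                    trigger_index=cursor,
                    cycle_index=cycle1,
                    end_index=cursor + n_ti + n_te1,
                    event_sample=cycle1,
                )
            )
            log_rows.append(
                dict(
                    ordinal=machine_ordinal + 1,
                    kind="dt_second",
                    trigger_index=cursor + n_ti + n_te1,
                    cycle_index=cursor + 2 * n_ti + n_te1,
                    end_index=cursor + n_period,
                    event_sample=-1,
                )
            )
            machine_ordinal += 2
        else:
            n_te = n_period - n_ti
            effort = _effort_bump(n_te, cfg) if is_it else None
            exp = _expiration(cfg.tidal_volume_ml, n_te, cfg, effort=effort)
            exp_paw = exp[0]
            if is_it:
                # concurrent pleural-pressure transmission: small Paw dip
                exp_paw = exp_paw - cfg.it_paw_dip_cmh2o * (
                    _effort_bump(n_te, cfg) / (cfg.it_amplitude_lpm / _ML_S_TO_LPM)
                )
            paw_parts += [insp_paw, exp_paw]
            flow_parts += [insp_flow, exp[1]]
            vol_parts += [insp_vol, exp[2]]
            event_sample = -1
            if is_it:
                center_n = int(round(cfg.it_center_frac * n_te))
                event_sample = cursor + n_ti + center_n
                gold.append(
                    EventAnnotation(
                        "ineffective_trigger", sample_index=event_sample, source="gold"
                    )
                )
            log_rows.append(
                dict(
                    ordinal=machine_ordinal,
                    kind="it_host" if is_it else "normal",
                    trigger_index=cursor,
                    cycle_index=cursor + n_ti,
                    end_index=cursor + n_period,
                    event_sample=event_sample,
                )
            )
            machine_ordinal += 1
        cursor += n_period

    paw = np.concatenate(paw_parts)
    flow = np.concatenate(flow_parts)
    volume = np.concatenate(vol_parts)
    if cfg.noise_sd_lpm > 0:
        flow = flow + rng_shape.normal(0.0, cfg.noise_sd_lpm, size=flow.shape)

    stream = VentStream(
        sample_rate_hz=fs,
        paw=paw,
        flow=flow,
        volume=volume,
        meta={
            "ventilation_mode": "VC",
            "peep_set_cmh2o": cfg.peep,
            "generator": "pvakit-simulator",
            "seed": cfg.seed,
        },
    )
    log = pd.DataFrame(
        log_rows,
        columns=["ordinal", "kind", "trigger_index", "cycle_index", "end_index", "event_sample"],
    )
    return SimResult(stream=stream, gold_events=gold, breath_log=log, config=cfg)
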