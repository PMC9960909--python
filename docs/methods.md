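# Methods

This note documents the models, algorithms, parameter choices and known
limitations behind `pvakit`. Units follow ventilator-display convention
throughout: airway pressure Paw in cmH₂O, flow in L/min, volume in mL,
time in seconds, sampling at 50 Hz unless stated otherwise.

## Data model and cleaning

A `VentStream` holds synchronised Paw/flow/volume arrays with one sample
clock. On reading, a `time` column (if present) must be strictly
increasing with inter-sample jitter < 5% of the median interval; the
sample rate is then the reciprocal median interval. Cleaning replaces
NaN/Inf samples by linear interpolation against the sample index (edges
take the nearest valid value) and refuses streams where any channel is
more than 10% invalid — beyond that, threshold-based detection is not
meaningful. Cleaning without smoothing is idempotent; the optional
moving-average smoothing (odd window) is off by default.

## Breath segmentation

There is no universally published segmentation rule for exported
waveforms, so the package uses the standard clinical approach — flow
threshold crossing — made robust in two ways:

* **Hysteresis:** a trigger requires a rising crossing of
  `flow_trigger_threshold` (default +2 L/min), i.e. flow must have been
  below the threshold immediately before.
* **Confirmation hold (`trigger_hold_s`, default 0.2 s):** flow must stay
  above the threshold for the hold time. This is what keeps an
  ineffective inspiratory effort — which by definition does *not* trigger
  the ventilator — from being segmented as a breath: an 8 L/min effort
  deflection on a near-zero late-expiratory baseline exceeds +2 L/min for
  only ~0.15–0.18 s, while a genuine insufflation stays high for the full
  inspiratory time. Setting the hold to 0 restores a bare crossing rule.
  Very large efforts (≳12 L/min above the trigger threshold) could defeat
  the default hold; raise `trigger_hold_s` if such data are expected.

The cycle point (inspiration→expiration) is the first subsequent crossing
below `flow_cycle_threshold` (default −2 L/min); if none occurs before the
next trigger the breath has `Te = 0` ("no expiratory phase"). A breath
ends at the next trigger, or at the stream end for the last breath.
Candidate breaths with `Ti < 0.10 s` or total duration `< 0.30 s` are
removed as noise and their span is absorbed by the preceding breath.
Indices are 0-based; intervals are half-open `[start, end)`.

The mean inspiratory time used by the double-trigger rule is a rolling
mean over the last 10 breaths (configurable); a global mean would let a
long quiet history mask a local change in Ti.

Per-breath parameters: peak pressure is the Paw maximum over the breath;
PEEP is the mean Paw over the last 0.2 s of expiration (a stable plateau);
tidal volume is the volume-channel maximum minus the volume at trigger;
respiratory rate and minute ventilation are computed over the span from
the first trigger to the last breath end.

## Double-trigger detection

For each consecutive breath pair (i, i+1) one event is emitted, anchored
at breath i's cycle point, when either

1. breath i has **no expiratory phase**: `Te = 0`, or the volume at the
   end of breath i exceeds the volume at its trigger by more than
   `volume_baseline_tol` (default 20 mL) — the volume–time curve did not
   fall back to baseline; or
2. `Te(i) < dt_te_ratio × mean(Ti)` with `dt_te_ratio = 0.5` and the
   rolling mean taken up to and including breath i. The inequality is
   strict: a pair with Te exactly half the mean Ti is not flagged.

The two clauses are disjunctive, and a qualifying pair counts as one
asynchrony occurrence. The 20 mL baseline tolerance operationalises
"volume falls vertically to the baseline": with a typical expiratory time
constant of 0.5 s, normally exhaled breaths retain ≪ 20 mL at end-expiry
while a truncated expiration retains hundreds.

## Ineffective-trigger detection

Each expiratory segment `[cycle, end)` is smoothed with a 5-sample
(0.08 s) centred moving average; raw 50 Hz first differences are noise-
dominated, and 5 samples is the shortest odd window that stabilises the
derivative sign. Local extrema of the smoothed flow are read off sign
changes of its first difference (plateaus carry the previous sign
forward). Each local maximum `p` bracketed by minima `m₁ < p < m₂` is a
candidate deflection with

* `amplitude = flow(p) − max(flow(m₁), flow(m₂))` — the *higher* bounding
  minimum, the conservative choice;
* `duration = t(m₂) − t(m₁)` (min-to-min, the default) or `t(m₂) − t(p)`
  (`duration_mode="peak_to_min"`).

An event is emitted at `p` when `amplitude > 5 L/min` **and**
`duration > 0.12 s` (both strict). Deflections may not overlap: after an
accepted deflection the search resumes past `m₂`.

Two degenerate geometries need care. On a passively recovering expiration
the flow rises monotonically into the first deflection, so no interior
left minimum exists; the segment start then brackets the amplitude
(harmless, since the amplitude uses the higher minimum) and the deflection
*onset* — the last local minimum of the flow derivative before the peak,
i.e. the point where the decay rate starts increasing — bounds the
duration. Second, the effort volume is re-exhaled after the bump, so the
right minimum typically undershoots the pre-bump baseline; measuring the
duration at that minimum's level would roughly double it, which is why the
onset rule is used instead.

Smoothing widens measured durations by about one window (~0.08 s). A
consequence: a very short injected bump (0.10 s span) is rejected chiefly
because the 5-sample average attenuates its amplitude below the 5 L/min
rule, not by the duration rule. The observable behaviour — no event — is
the same.

Amplitude is a difference of flow values, so detection is invariant to a
constant flow offset; raising either threshold can only reduce the event
count (verified as property tests).

## Asynchrony index and alarms

For windows of `window_s` (default 240 s, valid 180–360 s) advanced by
`step_s` (default 1 s):

    AI = 100 × (events in window) / (breath triggers in window + ineffective triggers in window)

Ineffective efforts are missed cycles, so they join the denominator;
double triggers add events but no denominator term. Windows are half-open
`[t − window_s, t)` so that non-overlapping windows partition the stream
and event counts are conserved. A window with zero denominator reports
NaN and never alarms; a stream shorter than one window yields a single
truncated window with a logged warning. The alarm fires at
`AI ≥ severe_threshold_pct` (default 10%), and consecutive alarmed
windows merge into episodes.

## Simulator

A single-compartment lung: `Paw = R·Q + V/C + PEEP` with defaults
R = 10 cmH₂O/(L/s), C = 50 mL/cmH₂O (τ = R·C = 0.5 s), PEEP = 5 cmH₂O,
VT = 440 mL, Ti = 1 s, 15 breaths/min — a typical passively ventilated
adult. Insufflation is volume-control style (constant flow VT/Ti);
expiration is passive, `dV/dt = −V/τ + effort`. The displayed volume
channel resets to zero at each trigger, matching ventilator volume
waveforms.

**Integration.** Each sample advances the passive phase with the exact
exponential one-step update
`V(t+Δt) = V·e^(−Δt/τ) + effort·τ·(1 − e^(−Δt/τ))` rather than forward
Euler: at Δt/τ = 0.04 forward Euler drifts ~4% per time constant from the
closed-form decay, while the analytic update is exact, which lets tests
compare against the closed form at machine precision. Emitted flow is the
per-step volume change divided by Δt, so the flow and volume channels are
exactly conservation-consistent (the inspiratory flow integral equals VT
to round-off).

**Double-trigger injection** truncates the flagged breath's expiration at
a duration drawn uniformly from (0, 0.4·Ti) (floored at 3 samples so the
expiratory crossing is observable at 50 Hz) and delivers a second full
insufflation, guaranteeing `Te < 0.5 × mean Ti`. **Ineffective-effort
injection** drives a raised-cosine effort (amplitude 8 L/min, min-to-min
span 0.3 s by default) into the passive expiration, centred at 65% of the
expiratory phase where the baseline is nearly flat, together with a 1.5
cmH₂O raised-cosine Paw dip (pleural-pressure transmission). Because the
effort enters the dynamics, its volume is re-exhaled — producing the
characteristic small undershoot after the deflection — and end-expiratory
volume still returns to baseline, so an injected effort never fakes a
double trigger on the following pair. Optional Gaussian noise (SD in
L/min) is added to the flow channel only.

**Randomness.** Decision draws (one uniform per breath for DT, one per
breath for IT, consumed in fixed order) come from one stream of a seeded
`SeedSequence`; event-shape draws and noise come from a second spawned
stream, so changing shape sampling cannot move event decisions. IT draws
on a double-triggered breath are consumed but ignored. Identical configs
produce bit-identical output.

**What the simulator does not emulate:** patient effort strong enough to
trigger (auto-triggering, reverse triggering), pressure-support and
flow-cycled modes, leaks, secretions, cuff artefacts, multi-compartment
heterogeneity, and drifting baselines. Perfect detector scores on this
synthetic data therefore demonstrate the correctness of the rule
implementations under the stated morphology, not clinical performance on
patient data — validation studies on annotated patient recordings show
materially lower sensitivity (see `examples/04_diagnostic_metrics.py` for
the metric arithmetic on such external counts).

## Evaluation

Breaths are the unit of analysis. A breath is positive for an event type
iff at least one event of that type is anchored inside `[trigger, end)`;
multiple events in a breath count once. An event outside every breath
attaches to the nearest breath within 0.5 s (annotation timestamps often
sit on boundaries) and is otherwise dropped with a warning. Predicted and
gold labels cross-tabulate into TP/FP/FN/TN, and

    Sv = 100·TP/(TP+FN)   Sp = 100·TN/(TN+FP)
    PPV = 100·TP/(TP+FP)  NPV = 100·TN/(TN+FN)

are rounded half-up to 2 decimals via exact decimal arithmetic (IEEE
round-half-even would mis-print boundary cases); zero denominators yield
NaN.

## Analysis report

`generate_report` snapshots one AI window: basic info (stream metadata
pass-through), diagnostic reference (window, AI, severity, per-type event
counts), deterministic template prompts naming the dominant event type,
ventilation parameters over the window, and the window's sample range as
the waveform excerpt. JSON serialisation sorts keys, so identical inputs
give byte-identical reports; the pydantic-derived JSON schema ships with
the package and the shipped copy is asserted equal to the generated one in
tests.

## Problem sizes in tests and the acceptance script

Simulated runs span 2–15 minutes (30–240 machine cycles) — long enough
for ≥ 200-breath detector-recovery checks, several hundred sliding
windows, and stable injected-event counts, while the whole suite stays
fast. The acceptance script reports, per quantity, the problem size `n`
it used.

## Known limitations

* Flow-threshold segmentation assumes flow-triggered, actively delivered
  breaths; purely pressure-triggered detection is out of scope.
* The DT rule cannot distinguish a true double trigger from two rapid
  patient-triggered breaths (short-cycle tachypnoea); on real data the
  volume-baseline clause mitigates but does not remove this.
* Deflection thresholds (5 L/min, 0.12 s) are fixed rules, not adaptive;
  sensitivity on low-effort patients will be poor by construction.
* Only double triggering and ineffective triggering are detected; delayed
  cycling, premature cycling, flow starvation, auto- and reverse
  triggering are not implemented.
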