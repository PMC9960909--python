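"""Simulate a ventilation run with injected asynchronies and detect them.

Builds 10 minutes of synthetic volume-control ventilation in which 8% of
breaths are double-triggered and 20% of expirations carry an ineffective
inspiratory effort, then runs breath segmentation and both detectors.
"""
from pvakit import SimConfig, detect_all, segment_breaths, simulate

cfg = SimConfig(duration_s=600.0, dt_rate=0.08, it_rate=0.2, seed=42)
result = simulate(cfg)
stream = result.stream

breaths = segment_breaths(stream)
events = detect_all(stream)

n_dt = sum(1 for e in events if e.event_type == "double_trigger")
n_it = len(events) - n_dt
gold_dt = sum(1 for e in result.gold_events if e.event_type == "double_trigger")
gold_it = len(result.gold_events) - gold_dt

print(f"stream: {len(stream)} samples at {stream.sample_rate_hz:.0f} Hz "
      f"({stream.duration_s:.0f} s)")
print(f"segmented breaths:        {len(breaths)}")
print(f"double triggers detected: {n_dt}  (injected: {gold_dt})")
print(f"ineffective efforts:      {n_it}  (injected: {gold_it})")
first_it = next(e for e in events if e.event_type == "ineffective_trigger")
print(f"first effort deflection:  amplitude "
      f"{first_it.features['deflection_amplitude']:.1f} L/min over "
      f"{first_it.features['deflection_duration']:.2f} s")

# On noise-free synthetic data every injected event is recovered and no
# false events appear, so detected counts equal the injection log exactly.
# The deflection features sit near the configured 8 L/min / 0.3 s bump.
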