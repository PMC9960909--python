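"""Score the detectors against gold-standard annotations, per breath.

The simulator's injection log plays the role of expert annotation: each
breath is labelled positive/negative per event type for both the gold and
the detected events, and the 2x2 cross-tabulation yields sensitivity,
specificity, PPV and NPV.
"""
from pvakit import SimConfig, evaluate_run, simulate

result = simulate(SimConfig(duration_s=880.0, dt_rate=0.08, it_rate=0.2, seed=7))
scores = evaluate_run(result.stream, result.gold_events)

for event_type, r in scores.items():
    cm, m = r.confusion, r.metrics
    print(f"{event_type}:")
    print(f"  TP={cm.tp:4d} FP={cm.fp:4d} FN={cm.fn:4d} TN={cm.tn:4d} "
          f"(n={cm.total} breaths)")
    print(f"  sensitivity {m.sensitivity_pct:6.2f}%   specificity {m.specificity_pct:6.2f}%")
    print(f"  PPV         {m.ppv_pct:6.2f}%   NPV         {m.npv_pct:6.2f}%")

# Noise-free injected events are recovered perfectly (all metrics 100%).
# Add noise_sd_lpm or lower it_amplitude_lpm in SimConfig to watch
# sensitivity degrade while specificity stays high.
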