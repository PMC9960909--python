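"""Diagnostic metrics from externally tabulated confusion matrices.

When a detector has been compared with manual expert annotation, the
result is a 2x2 table of breath counts.  `metrics` turns such a table into
sensitivity, specificity, PPV and NPV with exact half-up percent rounding
(the convention of clinical reporting).

The two tables below summarise a validation of rule-based double-trigger
and ineffective-trigger recognition against expert marking of 4496
ventilator breaths.
"""
from pvakit import ConfusionMatrix, metrics

tables = {
    "double trigger":      ConfusionMatrix(tp=481, fp=3, fn=235, tn=3777),
    "ineffective trigger": ConfusionMatrix(tp=727, fp=202, fn=183, tn=3384),
}

for name, cm in tables.items():
    m = metrics(cm)
    print(f"{name} (n={cm.total} breaths, {cm.tp + cm.fn} gold-positive):")
    print(f"  sensitivity {m.sensitivity_pct:5.2f}%   specificity {m.specificity_pct:5.2f}%")
    print(f"  PPV         {m.ppv_pct:5.2f}%   NPV         {m.npv_pct:5.2f}%")

# Prints 67.18/99.92/99.38/94.14 for double triggering and
# 79.89/94.37/78.26/94.87 for ineffective triggering: the trigger-anomaly
# rule is highly specific, while the effort-deflection rule trades some
# specificity for a higher sensitivity.
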