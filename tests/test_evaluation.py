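import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pvakit import (
    Breath,
    ConfusionMatrix,
    ContractError,
    PvaEvent,
    SimConfig,
    confusion,
    evaluate_run,
    label_breaths,
    metrics,
    simulate,
)

FS = 50.0

# printed experiment: double-trigger algorithm on 4496 breaths
DT_TABLE = ConfusionMatrix(tp=481, fp=3, fn=235, tn=3777)
# printed experiment: ineffective-trigger algorithm on the same breaths
IT_TABLE = ConfusionMatrix(tp=727, fp=202, fn=183, tn=3384)


def three_breaths():
    return [
        Breath.from_indices(0, 50, 150, FS),
        Breath.from_indices(150, 200, 300, FS),
        Breath.from_indices(300, 350, 450, FS),
    ]


class TestLabelBreaths:
    def test_containment(self):
        breaths = three_breaths()
        events = [PvaEvent("ineffective_trigger", 1, 220)]
        labels = label_breaths(breaths, events, "ineffective_trigger", FS)
        assert labels.tolist() == [False, True, False]

    def test_multiple_events_single_label(self):
        breaths = three_breaths()
        events = [
            PvaEvent("ineffective_trigger", 1, 210),
            PvaEvent("ineffective_trigger", 1, 260),
        ]
        labels = label_breaths(breaths, events, "ineffective_trigger", FS)
        assert labels.sum() == 1

    def test_straggler_attached_within_tolerance(self):
        breaths = three_breaths()
        # 0.3 s after the last breath end
        events = [PvaEvent("double_trigger", 2, 450 + 15)]
        labels = label_breaths(breaths, events, "double_trigger", FS)
        assert labels.tolist() == [False, False, True]

    def test_far_event_dropped(self):
        breaths = three_breaths()
        events = [PvaEvent("double_trigger", 2, 450 + 100)]  # 2 s past the end
        labels = label_breaths(breaths, events, "double_trigger", FS)
        assert not labels.any()

    def test_other_event_types_ignored(self):
        breaths = three_breaths()
        events = [PvaEvent("double_trigger", 0, 60)]
        labels = label_breaths(breaths, events, "ineffective_trigger", FS)
        assert not labels.any()


class TestConfusion:
    def test_perfect_agreement(self):
        cm = confusion([True, False], [True, False])
        assert (cm.tp, cm.fp, cm.fn, cm.tn) == (1, 0, 0, 1)

    def test_false_positive(self):
        cm = confusion([True], [False])
        assert cm.fp == 1

    def test_length_mismatch_rejected(self):
        with pytest.raises(ContractError):
            confusion([True], [True, False])

    def test_reconstructed_margins(self):
        # 4496 breaths, 716 gold double triggers, 484 predicted positives
        labels_gold = [True] * 716 + [False] * 3780
        labels_pred = [True] * 481 + [False] * 235 + [True] * 3 + [False] * 3777
        cm = confusion(labels_pred, labels_gold)
        assert cm == DT_TABLE
        assert cm.total == 4496


class TestMetrics:
    def test_double_trigger_table(self):
        m = metrics(DT_TABLE)
        assert m.sensitivity_pct == 67.18
        assert m.specificity_pct == 99.92
        assert m.ppv_pct == 99.38
        assert m.npv_pct == 94.14

    def test_ineffective_trigger_table(self):
        m = metrics(IT_TABLE)
        assert m.sensitivity_pct == 79.89
        assert m.specificity_pct == 94.37
        assert m.ppv_pct == 78.26
        assert m.npv_pct == 94.87

    def test_forced_ratios(self):
        m = metrics(ConfusionMatrix(tp=1, fp=0, fn=1, tn=0))
        assert m.sensitivity_pct == 50.00
        assert m.ppv_pct == 100.00
        assert math.isnan(m.specificity_pct)

    def test_all_zero_matrix_is_nan(self):
        m = metrics(ConfusionMatrix(0, 0, 0, 0))
        assert all(
            math.isnan(v)
            for v in (m.sensitivity_pct, m.specificity_pct, m.ppv_pct, m.npv_pct)
        )

    def test_half_up_rounding(self):
        # 1/8 = 12.5% exactly: half-up gives 12.50 at 2 dp, 12.5 -> 13 at 0 dp
        m = metrics(ConfusionMatrix(tp=1, fp=0, fn=7, tn=0), decimals=0)
        assert m.sensitivity_pct == 13.0

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(
        tp=st.integers(0, 500),
        fp=st.integers(0, 500),
        fn=st.integers(0, 500),
        tn=st.integers(0, 500),
    )
    def test_sensitivity_monotone_in_tp(self, tp, fp, fn, tn):
        if tp + fn == 0:
            return
        m1 = metrics(ConfusionMatrix(tp, fp, fn, tn))
        m2 = metrics(ConfusionMatrix(tp + 1, fp, fn, tn))
        assert m2.sensitivity_pct >= m1.sensitivity_pct
        assert m2.ppv_pct >= m1.ppv_pct


class TestEvaluateRun:
    def test_noise_free_injections_fully_recovered(self, event_sim):
        results = evaluate_run(event_sim.stream, event_sim.gold_events)
        for etype in ("double_trigger", "ineffective_trigger"):
            r = results[etype]
            assert r.metrics.sensitivity_pct == 100.00
            assert r.metrics.specificity_pct == 100.00
            assert r.confusion.fp == 0
            assert r.confusion.fn == 0

    def test_margin_conservation(self, event_sim, event_breaths):
        results = evaluate_run(event_sim.stream, event_sim.gold_events)
        gold_it = label_breaths(
            event_breaths, event_sim.gold_events, "ineffective_trigger"
        ).sum()
        cm = results["ineffective_trigger"].confusion
        assert cm.tp + cm.fn == gold_it
        assert cm.total == len(event_breaths)

    def test_sub_threshold_amplitude_yields_zero_sensitivity(self):
        res = simulate(
            SimConfig(duration_s=400.0, it_rate=0.25, it_amplitude_lpm=4.0, seed=11)
        )
        assert any(e.event_type == "ineffective_trigger" for e in res.gold_events)
        r = evaluate_run(res.stream, res.gold_events)["ineffective_trigger"]
        assert r.metrics.sensitivity_pct == 0.00
        assert r.metrics.specificity_pct == 100.00

    def test_rerun_is_deterministic(self, event_sim):
        a = evaluate_run(event_sim.stream, event_sim.gold_events)
        b = evaluate_run(event_sim.stream, event_sim.gold_events)
        assert a == b
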