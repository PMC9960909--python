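import numpy as np
import pytest

from pvakit import (
    Breath,
    ConfigError,
    DetectorConfig,
    SimConfig,
    VentStream,
    detect_all,
    detect_double_trigger,
    detect_ineffective_trigger,
    segment_breaths,
    simulate,
)
from conftest import expiratory_segment

FS = 50.0


def stream_from_flow(flow, volume=None):
    flow = np.asarray(flow, dtype=float)
    volume = np.zeros_like(flow) if volume is None else np.asarray(volume, float)
    return VentStream(FS, paw=np.full_like(flow, 10.0), flow=flow, volume=volume)


def breaths_with_te(te_list_s, ti_s=1.0):
    """Contiguous breaths with fixed Ti and the given expiratory times."""
    breaths = []
    cursor = 0
    for te in te_list_s:
        trig = cursor
        cyc = trig + int(ti_s * FS)
        end = cyc + int(te * FS)
        breaths.append(Breath.from_indices(trig, cyc, max(end, cyc), FS))
        cursor = end
    return breaths


class TestDoubleTrigger:
    def test_short_te_flags_pair(self):
        # te = 0.4 s against a rolling mean Ti of 1.0 s: 0.4 < 0.5 x 1.0
        breaths = breaths_with_te([3.0, 0.4, 3.0, 3.0])
        s = stream_from_flow(np.zeros(breaths[-1].end_index))
        events = detect_double_trigger(s, breaths)
        assert [e.breath_ordinal for e in events] == [1]
        assert events[0].sample_index == breaths[1].cycle_index
        assert events[0].features["te_s"] == pytest.approx(0.4)

    def test_boundary_te_not_flagged(self):
        # te exactly half the mean Ti: strict inequality, no event
        breaths = breaths_with_te([3.0, 0.5, 3.0])
        s = stream_from_flow(np.zeros(breaths[-1].end_index))
        assert detect_double_trigger(s, breaths) == []

    def test_zero_te_flags_no_expiration_case(self):
        breaths = breaths_with_te([3.0, 0.0, 3.0])
        s = stream_from_flow(np.zeros(breaths[-1].end_index))
        events = detect_double_trigger(s, breaths)
        assert [e.breath_ordinal for e in events] == [1]

    def test_volume_not_returning_to_baseline_flags_pair(self):
        breaths = breaths_with_te([3.0, 3.0, 3.0])
        n = breaths[-1].end_index
        volume = np.zeros(n)
        # breath 1 ends 150 mL above its trigger baseline
        volume[breaths[1].end_index - 1] = 150.0
        s = stream_from_flow(np.zeros(n), volume=volume)
        events = detect_double_trigger(s, breaths)
        assert [e.breath_ordinal for e in events] == [1]

    def test_injected_pairs_recovered_exactly(self, event_sim, event_breaths):
        events = detect_double_trigger(event_sim.stream, event_breaths)
        gold = [e.sample_index for e in event_sim.gold_events if e.event_type == "double_trigger"]
        assert sorted(e.sample_index for e in events) == sorted(gold)

    def test_ratio_monotonicity(self, event_sim, event_breaths):
        counts = []
        for ratio in (0.6, 0.5, 0.4, 0.3):
            cfg = DetectorConfig(dt_te_ratio=ratio)
            counts.append(len(detect_double_trigger(event_sim.stream, event_breaths, cfg)))
        assert all(a >= b for a, b in zip(counts, counts[1:]))


class TestIneffectiveTrigger:
    def segment_stream(self, flow_seg):
        """Wrap an expiratory segment as one breath covering the stream."""
        insp = np.full(50, 30.0)
        flow = np.concatenate([insp, flow_seg])
        s = stream_from_flow(flow)
        b = Breath.from_indices(0, 50, len(flow), FS)
        return s, [b]

    def test_supra_threshold_bump_detected_with_features(self):
        seg = expiratory_segment(bump_amplitude_lpm=8.0, bump_span_s=0.3)
        s, breaths = self.segment_stream(seg)
        events = detect_ineffective_trigger(s, breaths)
        assert len(events) == 1
        e = events[0]
        assert e.features["deflection_amplitude"] == pytest.approx(8.0, abs=1.0)
        assert e.features["deflection_duration"] == pytest.approx(0.30, abs=0.15)
        # anchored at the deflection peak
        assert abs(e.sample_index - (50 + int(1.8 * FS))) <= 3

    def test_sub_threshold_amplitude_rejected(self):
        seg = expiratory_segment(bump_amplitude_lpm=4.0, bump_span_s=0.3)
        s, breaths = self.segment_stream(seg)
        assert detect_ineffective_trigger(s, breaths) == []

    def test_sub_threshold_span_rejected(self):
        seg = expiratory_segment(bump_amplitude_lpm=8.0, bump_span_s=0.10)
        s, breaths = self.segment_stream(seg)
        assert detect_ineffective_trigger(s, breaths) == []

    def test_monotone_expiration_has_no_deflection(self):
        seg = expiratory_segment(bump_amplitude_lpm=0.0)
        s, breaths = self.segment_stream(seg)
        assert detect_ineffective_trigger(s, breaths) == []

    def test_injected_efforts_recovered_exactly(self, event_sim, event_breaths):
        events = detect_ineffective_trigger(event_sim.stream, event_breaths)
        gold = [e for e in event_sim.gold_events if e.event_type == "ineffective_trigger"]
        assert len(events) == len(gold)
        for det, g in zip(sorted(events, key=lambda e: e.sample_index), gold):
            assert abs(det.sample_index - g.sample_index) <= 5

    def test_flow_offset_invariance(self, event_sim, event_breaths):
        s = event_sim.stream
        shifted = VentStream(
            s.sample_rate_hz, paw=s.paw, flow=s.flow + 7.5, volume=s.volume
        )
        base = detect_ineffective_trigger(s, event_breaths)
        moved = detect_ineffective_trigger(shifted, event_breaths)
        assert [e.sample_index for e in base] == [e.sample_index for e in moved]
        for a, b in zip(base, moved):
            assert a.features["deflection_amplitude"] == pytest.approx(
                b.features["deflection_amplitude"]
            )

    @pytest.mark.parametrize("field,values", [
        ("it_amplitude_threshold", (3.0, 5.0, 7.0, 9.0)),
        ("it_duration_threshold", (0.06, 0.12, 0.24, 0.48)),
    ])
    def test_threshold_monotonicity(self, event_sim, event_breaths, field, values):
        counts = []
        for v in values:
            cfg = DetectorConfig(**{field: v})
            counts.append(len(detect_ineffective_trigger(event_sim.stream, event_breaths, cfg)))
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_emitted_features_satisfy_thresholds(self, event_sim, event_breaths):
        cfg = DetectorConfig()
        for e in detect_ineffective_trigger(event_sim.stream, event_breaths, cfg):
            assert e.features["deflection_amplitude"] > cfg.it_amplitude_threshold
            assert e.features["deflection_duration"] > cfg.it_duration_threshold

    def test_peak_to_min_duration_mode(self):
        seg = expiratory_segment(bump_amplitude_lpm=8.0, bump_span_s=0.3)
        s, breaths = self.segment_stream(seg)
        cfg = DetectorConfig(duration_mode="peak_to_min")
        events = detect_ineffective_trigger(s, breaths, cfg)
        assert len(events) == 1
        # peak-to-min spans roughly half the deflection
        assert events[0].features["deflection_duration"] == pytest.approx(0.15, abs=0.1)


class TestDetectAll:
    def test_clean_run_has_no_events(self, clean_sim):
        assert detect_all(clean_sim.stream) == []

    def test_merged_events_match_injection_log(self, event_sim):
        events = detect_all(event_sim.stream)
        by_type = {}
        for e in events:
            by_type.setdefault(e.event_type, []).append(e)
        gold_dt = [e for e in event_sim.gold_events if e.event_type == "double_trigger"]
        gold_it = [e for e in event_sim.gold_events if e.event_type == "ineffective_trigger"]
        assert len(by_type.get("double_trigger", [])) == len(gold_dt)
        assert len(by_type.get("ineffective_trigger", [])) == len(gold_it)
        assert [e.sample_index for e in events] == sorted(e.sample_index for e in events)

    def test_deterministic(self, event_sim):
        assert detect_all(event_sim.stream) == detect_all(event_sim.stream)

    def test_invalid_config_rejected(self):
        with pytest.raises(ConfigError):
            DetectorConfig(dt_te_ratio=1.5)
        with pytest.raises(ConfigError):
            DetectorConfig(derivative_smoothing_window=4)
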