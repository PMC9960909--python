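import numpy as np
import pytest

from pvakit import SimConfig, segment_breaths, simulate

FS = 50.0


@pytest.fixture(scope="session")
def clean_sim():
    """60 s of undisturbed volume-control ventilation (15 breaths)."""
    return simulate(SimConfig(duration_s=60.0, seed=1))


@pytest.fixture(scope="session")
def event_sim():
    """~4 min with injected double triggers and ineffective efforts."""
    return simulate(SimConfig(duration_s=880.0, dt_rate=0.08, it_rate=0.2, seed=7))


@pytest.fixture(scope="session")
def event_breaths(event_sim):
    return segment_breaths(event_sim.stream)


def expiratory_segment(
    base_start_lpm: float = -12.0,
    tau_s: float = 0.5,
    duration_s: float = 3.0,
    bump_amplitude_lpm: float = 0.0,
    bump_span_s: float = 0.3,
    bump_center_s: float = 1.8,
    fs: float = FS,
) -> np.ndarray:
    """Hand-built expiratory flow: exponential recovery + raised-cosine bump.

    The base decays toward zero from ``base_start_lpm`` so the deflection
    has genuine bounding minima on both sides.
    """
    t = np.arange(0.0, duration_s, 1.0 / fs)
    flow = base_start_lpm * np.exp(-t / tau_s)
    if bump_amplitude_lpm:
        half = bump_span_s / 2.0
        inside = np.abs(t - bump_center_s) <= half
        flow[inside] += bump_amplitude_lpm * 0.5 * (
            1.0 + np.cos(np.pi * (t[inside] - bump_center_s) / half)
        )
    return flow
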