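"""Small numerical helpers shared by the detectors and the I/O layer."""
from __future__ import annotations

import numpy as np

from .errors import ContractError


def moving_average(x: np.ndarray, window: int) -> np.ndarray:
    """Centred moving average with edge renormalisation.

    Near the boundaries the kernel is truncated and renormalised, so the
    output has the same length as ``x`` and no edge bias toward zero.
    ``window`` must be odd so the filter is phase-neutral.
    """
    if window < 1 or window % 2 == 0:
        raise ContractError(f"smoothing window must be odd and >= 1, got {window}")
    if window == 1 or x.size == 0:
        return np.asarray(x, dtype=float).copy()
    kernel = np.ones(window)
    num = np.convolve(x, kernel, mode="same")
    den = np.convolve(np.ones_like(x, dtype=float), kernel, mode="same")
    return num / den


def local_extrema(y: np.ndarray) -> tuple[list[int], list[int]]:
    """Indices of interior local maxima and minima of ``y``.

    Extrema are located by sign changes of the first difference; plateaus
    carry the previous non-zero sign forward so a flat top counts once, at
    its left edge.
    Returns ``(maxima, minima)`` as index lists in increasing order.
    """
    d = np.diff(np.asarray(y, dtype=float))
    maxima: list[int] = []
    minima: list[int] = []
    prev = 0.0
    for k, dk in enumerate(d):
        s = float(np.sign(dk))
        if s == 0.0:
            continue
        if prev > 0 and s < 0:
            maxima.append(k)
        elif prev < 0 and s > 0:
            minima.append(k)
        prev = s
    return maxima, minima
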