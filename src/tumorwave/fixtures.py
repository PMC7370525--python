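"""Named small-parameter presets for tests and examples.

Presets
-------
``tiny-neutral``
    Neutral, mutation-free run (s = 0, c = 1, mu = 0) at constant size 200:
    stays monomorphic wild-type for all 20 generations.
``tiny-oracle``
    Small instance (n = 1, m = 2, N = 200 constant, T = 20, mu = 1e-3,
    s = 0.05, c = 2) sized so the per-cell brute-force update is feasible.
``default-short``
    Study default parameters truncated to T = 500 generations.
``two-gaussian-waves``
    Synthetic (not simulated) frequency series of two Gaussian pulses with a
    sub-threshold valley between them; exactly two waves at threshold 0.01.
"""

from __future__ import annotations

import numpy as np

from .model import Trajectory, simulate
from .params import ModelParams

__all__ = ["make_fixture", "two_gaussian_series", "PRESETS",
           "TWO_GAUSSIAN_PEAKS"]

PRESETS = ("tiny-neutral", "tiny-oracle", "default-short",
           "two-gaussian-waves")

#: (center, sigma, amplitude) of the two synthetic pulses.
TWO_GAUSSIAN_PEAKS = ((300.0, 40.0, 0.30), (700.0, 60.0, 0.10))


def preset_params(preset: str) -> ModelParams:
    if preset == "tiny-neutral":
        return ModelParams(n=2, m=3, mu=0.0, s=0.0, c=1.0,
                           N0=200, NT=200, T=20)
    if preset == "tiny-oracle":
        return ModelParams(n=1, m=2, mu=1e-3, s=0.05, c=2.0,
                           N0=200, NT=200, T=20)
    if preset == "default-short":
        base = ModelParams()
        return ModelParams(n=base.n, m=base.m, mu=base.mu, s=base.s,
                           c=base.c, N0=base.N0, NT=base.NT, T=500)
    raise KeyError(f"unknown preset {preset!r}; choose from {PRESETS}")


def two_gaussian_series(length: int = 1000) -> np.ndarray:
    """Two Gaussian pulses separated by a sub-threshold valley."""
    t = np.arange(length, dtype=float)
    series = np.zeros(length)
    for center, sigma, amp in TWO_GAUSSIAN_PEAKS:
        series += amp * np.exp(-((t - center) ** 2) / (2 * sigma**2))
    return series


def make_fixture(preset: str, seed: int = 0):
    """Build a named preset: a Trajectory, or a raw series for the
    constructed ``two-gaussian-waves`` preset."""
    if preset == "two-gaussian-waves":
        return two_gaussian_series()
    return simulate(preset_params(preset), seed)
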