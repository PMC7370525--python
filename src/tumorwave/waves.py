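"""Traveling-wave structure of clone-abundance trajectories.

In the two-class model each clone's abundance rises, peaks, and is displaced
by fitter clones, so a clone's time series looks like a (roughly Gaussian)
pulse — a traveling wave through genotype space.  This module detects waves
as maximal contiguous above-threshold episodes of a single clone's series,
summarizes them (counts per superdriver class, widths, peak-height
differences, peak spacings), and fits quadratic polynomials to log abundance
(a Gaussian pulse is exactly parabolic in log space) to extract location,
height and curvature.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import numpy as np

from .experiments import EnsembleTrajectory
from .model import Trajectory

__all__ = [
    "WaveSegment",
    "QuadraticFit",
    "clone_series",
    "detect_waves",
    "count_driver_waves",
    "wave_widths",
    "peak_height_differences",
    "peak_spacings",
    "fit_wave_quadratic",
]

Scale = Literal["counts", "frequency"]

#: Default detection threshold: 1% of the current population (frequency scale).
DEFAULT_THRESHOLD = 0.01
#: Default minimum span (generations) for the wave-width statistic.
DEFAULT_MIN_SPAN = 500
#: Driver classes scanned when counting waves within a superdriver epoch.
DEFAULT_L_MAX = 10


@dataclass(frozen=True)
class WaveSegment:
    """One contiguous above-threshold episode of a clone's abundance series."""

    k: int
    l: int
    start_gen: int
    end_gen: int
    peak_gen: int
    peak_value: float

    @property
    def span(self) -> int:
        return self.end_gen - self.start_gen + 1


@dataclass(frozen=True)
class QuadraticFit:
    """Quadratic fit to log abundance over one wave segment.

    ``location`` is the parabola vertex (generation of maximum), ``height``
    the fitted log abundance at the vertex, ``curvature`` the second-order
    coefficient (negative for a peaked wave; more negative means narrower).
    ``accepted`` is false when the fit has non-negative curvature or a vertex
    outside the segment (e.g., a monotone segment with no interior peak).
    """

    location: float
    height: float
    curvature: float
    r2: float
    accepted: bool


def clone_series(
    traj: Trajectory | EnsembleTrajectory,
    k: int,
    l: int,
    scale: Scale = "frequency",
) -> np.ndarray:
    """Per-generation abundance of clone ``(k, l)``.

    For an ensemble the mean counts/frequencies are used; for a single
    trajectory the replicate's own.
    """
    n, m = traj.params.n, traj.params.m
    if not (0 <= k <= n and 0 <= l <= m):
        raise IndexError(f"clone ({k}, {l}) outside genotype space "
                         f"({n} superdriver, {m} driver loci)")
    if isinstance(traj, EnsembleTrajectory):
        src = traj.mean_counts if scale == "counts" else traj.mean_freqs
        return src[:, k, l].copy()
    counts = traj.counts[:, k, l].astype(float)
    if scale == "counts":
        return counts
    totals = traj.counts.sum(axis=(1, 2))
    return counts / totals


def detect_waves(
    series: np.ndarray,
    threshold: float,
    *,
    k: int = 0,
    l: int = 0,
) -> list[WaveSegment]:
    """Maximal contiguous runs of generations with abundance >= threshold.

    Peak ties break to the earliest generation.  ``k`` and ``l`` only label
    the returned segments.
    """
    if threshold <= 0:
        raise ValueError(f"threshold must be positive, got {threshold}")
    series = np.asarray(series, dtype=float)
    above = series >= threshold
    segments: list[WaveSegment] = []
    t = 0
    n = len(series)
    while t < n:
        if not above[t]:
            t += 1
            continue
        start = t
        while t < n and above[t]:
            t += 1
        end = t - 1
        window = series[start:t]
        peak_off = int(np.argmax(window))  # argmax ties -> earliest
        segments.append(WaveSegment(
            k=k, l=l, start_gen=start, end_gen=end,
            peak_gen=start + peak_off, peak_value=float(window[peak_off]),
        ))
    return segments


def _clone_segments(
    traj: Trajectory | EnsembleTrajectory,
    k: int,
    l: int,
    threshold: float,
    scale: Scale,
) -> list[WaveSegment]:
    return detect_waves(clone_series(traj, k, l, scale), threshold, k=k, l=l)


def count_driver_waves(
    traj: Trajectory | EnsembleTrajectory,
    k: int,
    threshold: float = DEFAULT_THRESHOLD,
    *,
    l_max: int = DEFAULT_L_MAX,
    scale: Scale = "frequency",
) -> int:
    """Number of driver waves within the superdriver-``k`` epoch.

    Operationalized as the number of driver classes ``l`` in ``0..l_max``
    whose clone ``(k, l)`` series contains at least one detected wave.
    """
    l_top = min(l_max, traj.params.m)
    return sum(
        1 for l in range(l_top + 1)
        if _clone_segments(traj, k, l, threshold, scale)
    )


def wave_widths(
    traj: Trajectory | EnsembleTrajectory,
    threshold: float = DEFAULT_THRESHOLD,
    min_span: int = DEFAULT_MIN_SPAN,
    *,
    k_max: int | None = None,
    l_max: int = DEFAULT_L_MAX,
    scale: Scale = "frequency",
) -> dict[tuple[int, int], list[int]]:
    """Spans (generations) of all detected waves with span >= ``min_span``.

    Keyed by clone ``(k, l)``; clones without qualifying waves are omitted.
    """
    n = traj.params.n if k_max is None else min(k_max, traj.params.n)
    out: dict[tuple[int, int], list[int]] = {}
    for k in range(n + 1):
        for l in range(min(l_max, traj.params.m) + 1):
            spans = [
                seg.span
                for seg in _clone_segments(traj, k, l, threshold, scale)
                if seg.span >= min_span
            ]
            if spans:
                out[(k, l)] = spans
    return out


def peak_height_differences(
    traj: Trajectory | EnsembleTrajectory,
    k: int,
    threshold: float = DEFAULT_THRESHOLD,
    *,
    l_max: int = DEFAULT_L_MAX,
    scale: Scale = "frequency",
) -> list[float]:
    """|Peak-height differences| of consecutive driver waves at fixed ``k``.

    All detected waves of clones ``(k, l)`` for ``l = 0..l_max`` are pooled,
    ordered by peak generation, and absolute differences of consecutive peak
    values returned.  Fewer than two waves give an empty list.
    """
    segs: list[WaveSegment] = []
    for l in range(min(l_max, traj.params.m) + 1):
        segs.extend(_clone_segments(traj, k, l, threshold, scale))
    segs.sort(key=lambda seg: seg.peak_gen)
    return [abs(b.peak_value - a.peak_value) for a, b in zip(segs, segs[1:])]


def peak_spacings(
    traj: Trajectory | EnsembleTrajectory,
    l: int,
    threshold: float = DEFAULT_THRESHOLD,
    *,
    k_max: int | None = None,
    scale: Scale = "frequency",
) -> list[float]:
    """Generations between peaks of consecutive superdriver waves at fixed ``l``.

    For each superdriver class ``k = 0, 1, 2, ...`` the highest detected wave
    of clone ``(k, l)`` contributes its peak generation; differences between
    consecutive present classes are returned.
    """
    n = traj.params.n if k_max is None else min(k_max, traj.params.n)
    peaks: list[int] = []
    for k in range(n + 1):
        segs = _clone_segments(traj, k, l, threshold, scale)
        if segs:
            best = max(segs, key=lambda seg: seg.peak_value)
            peaks.append(best.peak_gen)
    return [float(b - a) for a, b in zip(peaks, peaks[1:])]


def fit_wave_quadratic(
    series: np.ndarray,
    segment: WaveSegment,
    *,
    log_scale: bool = True,
) -> QuadraticFit:
    """Least-squares quadratic fit over one wave segment.

    By default the fit is on the natural log of abundance, where a Gaussian
    pulse ``A * exp(-(t - t0)^2 / (2 sigma^2))`` is exactly the parabola
    ``log A - (t - t0)^2 / (2 sigma^2)``: the vertex recovers the wave's
    location ``t0`` and log height ``log A``, and the curvature equals
    ``-1 / (2 sigma^2)``.  ``log_scale=False`` fits the raw series.

    Fits with non-negative curvature or a vertex outside the segment are
    returned with ``accepted=False``.
    """
    if segment.span < 3:
        raise ValueError(
            f"segment must span >= 3 generations to fit, got {segment.span}"
        )
    series = np.asarray(series, dtype=float)
    t = np.arange(segment.start_gen, segment.end_gen + 1, dtype=float)
    y = series[segment.start_gen:segment.end_gen + 1]
    if log_scale:
        if (y <= 0).any():
            raise ValueError("log-scale fit requires positive abundances "
                             "within the segment")
        y = np.log(y)
    # center t for conditioning; vertex mapped back afterwards
    t0 = t.mean()
    a, b, c0 = np.polyfit(t - t0, y, 2)
    if a == 0:
        return QuadraticFit(location=math.nan, height=math.nan,
                            curvature=0.0, r2=_r2(t - t0, y, (a, b, c0)),
                            accepted=False)
    vertex = -b / (2 * a) + t0
    height = c0 - b**2 / (4 * a)
    r2 = _r2(t - t0, y, (a, b, c0))
    accepted = a < 0 and segment.start_gen <= vertex <= segment.end_gen
    return QuadraticFit(location=float(vertex), height=float(height),
                        curvature=float(a), r2=r2, accepted=accepted)


def _r2(t: np.ndarray, y: np.ndarray, coeffs: tuple[float, float, float]) -> float:
    yhat = np.polyval(coeffs, t)
    ss_res = float(((y - yhat) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0:
        return 1.0 if ss_res < 1e-12 else 0.0
    return 1.0 - ss_res / ss_tot
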