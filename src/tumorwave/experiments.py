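"""Replicate ensembles and (s, c) parameter grids.

Results are reported as the arithmetic mean across replicates, following the
study design of averaging clone counts and frequencies over 50 independent
Wright-Fisher runs per parameter combination.  Replicate seeds are derived
deterministically from a single master seed via ``numpy.random.SeedSequence``
spawning, so any individual replicate can be replayed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import FitnessWeighting, SurvivalExponent, Trajectory, simulate
from .params import InvalidParameterError, ModelParams

__all__ = ["GridSpec", "EnsembleTrajectory", "run_ensemble", "run_grid",
           "DEFAULT_S_VALUES", "DEFAULT_C_VALUES"]

# Study defaults: s grid as stated; the c grid's stated ellipsis "1, 1.1,
# 1.3, ..., 3" is resolved to an 11-point list containing every value named
# in the wave-statistics comparisons (1.1, 1.3, 1.5, 2.6, 2.8, 3.0).
DEFAULT_S_VALUES: tuple[float, ...] = (0.005, 0.01, 0.02, 0.03, 0.04, 0.05)
DEFAULT_C_VALUES: tuple[float, ...] = (
    1.0, 1.1, 1.3, 1.5, 1.7, 1.9, 2.1, 2.3, 2.6, 2.8, 3.0
)


@dataclass(frozen=True)
class GridSpec:
    """Parameter grid: every combination of ``s_values`` x ``c_values``."""

    s_values: tuple[float, ...] = DEFAULT_S_VALUES
    c_values: tuple[float, ...] = DEFAULT_C_VALUES
    replicates: int = 50
    master_seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "s_values", tuple(self.s_values))
        object.__setattr__(self, "c_values", tuple(self.c_values))
        for s in self.s_values:
            if not (0.0 <= s <= 1.0):
                raise InvalidParameterError(f"s must be in [0, 1], got {s}")
        for c in self.c_values:
            if c < 1.0:
                raise InvalidParameterError(f"c must be >= 1, got {c}")
        if self.replicates < 1:
            raise InvalidParameterError(
                f"replicates must be >= 1, got {self.replicates}"
            )


@dataclass
class EnsembleTrajectory:
    """Mean clone-count and clone-frequency trajectories across replicates.

    Attributes
    ----------
    mean_counts : ndarray, shape ``(T + 1, n + 1, m + 1)``
        Per-generation mean absolute clone counts across replicates.
    mean_freqs : ndarray
        Per-generation mean relative clone frequencies (each replicate's
        frequencies averaged; sums to one per generation).
    first_hits : ndarray, shape ``(replicates, n + 1, m + 1)``, int
        Per-replicate first generation with >= 1 cell of the exact clone;
        ``-1`` when censored (never reached by ``T``).
    first_hits_at_least : ndarray
        Same, for the cumulative event "any clone (i >= k, j >= l) present".
    trajectories : list of Trajectory, optional
        Full per-replicate trajectories; only retained when requested, since
        each stores ``(T + 1)(n + 1)(m + 1)`` counts.
    """

    params: ModelParams
    replicates: int
    master_seed: int
    mean_counts: np.ndarray = field(repr=False)
    mean_freqs: np.ndarray = field(repr=False)
    first_hits: np.ndarray = field(repr=False)
    first_hits_at_least: np.ndarray = field(repr=False)
    trajectories: list[Trajectory] | None = field(default=None, repr=False)


def replicate_seed(master_seed: int, index: int) -> np.random.SeedSequence:
    """Deterministic substream seed for one replicate of an ensemble."""
    return np.random.SeedSequence(master_seed, spawn_key=(index,))


def run_ensemble(
    params: ModelParams,
    replicates: int,
    master_seed: int,
    *,
    keep_replicates: bool = False,
    fitness_weighting: FitnessWeighting = "offspring",
    survival_exponent: SurvivalExponent = "as_printed",
) -> EnsembleTrajectory:
    """Run independent replicates and average their trajectories.

    Each replicate uses the substream seed ``replicate_seed(master_seed, i)``,
    so the ensemble is reproducible from ``master_seed`` alone and any single
    replicate can be regenerated in isolation.
    """
    if replicates < 1:
        raise InvalidParameterError(f"replicates must be >= 1, got {replicates}")
    sum_counts: np.ndarray | None = None
    sum_freqs: np.ndarray | None = None
    first_hits = np.empty((replicates, *params.shape), dtype=np.int64)
    first_hits_al = np.empty_like(first_hits)
    kept: list[Trajectory] | None = [] if keep_replicates else None
    for i in range(replicates):
        try:
            traj = simulate(
                params,
                replicate_seed(master_seed, i),
                fitness_weighting=fitness_weighting,
                survival_exponent=survival_exponent,
            )
        except Exception as exc:
            raise RuntimeError(f"replicate {i} failed: {exc}") from exc
        counts = traj.counts.astype(np.float64)
        freqs = counts / counts.sum(axis=(1, 2), keepdims=True)
        if sum_counts is None:
            sum_counts = counts
            sum_freqs = freqs
        else:
            sum_counts += counts
            sum_freqs += freqs
        first_hits[i] = traj.first_hit
        first_hits_al[i] = traj.first_hit_at_least
        if kept is not None:
            kept.append(traj)
    assert sum_counts is not None and sum_freqs is not None
    return EnsembleTrajectory(
        params=params,
        replicates=replicates,
        master_seed=master_seed,
        mean_counts=sum_counts / replicates,
        mean_freqs=sum_freqs / replicates,
        first_hits=first_hits,
        first_hits_at_least=first_hits_al,
        trajectories=kept,
    )


def run_grid(
    grid: GridSpec,
    base: ModelParams | None = None,
    *,
    keep_replicates: bool = False,
    fitness_weighting: FitnessWeighting = "offspring",
    survival_exponent: SurvivalExponent = "as_printed",
    progress: bool = False,
) -> dict[tuple[float, float], EnsembleTrajectory]:
    """One ensemble per ``(s, c)`` pair of the grid, keyed by ``(s, c)``.

    Each pair gets its own deterministic master seed derived from the grid's
    master seed and the pair's (s index, c index) position.
    """
    if base is None:
        base = ModelParams()
    results: dict[tuple[float, float], EnsembleTrajectory] = {}
    for si, s in enumerate(grid.s_values):
        for ci, c in enumerate(grid.c_values):
            params = base.with_selection(s=s, c=c)
            pair_seed = pair_master_seed(grid.master_seed, si, ci)
            if progress:
                print(f"[grid] s={s} c={c} seed={pair_seed} "
                      f"R={grid.replicates}", flush=True)
            results[(s, c)] = run_ensemble(
                params,
                grid.replicates,
                pair_seed,
                keep_replicates=keep_replicates,
                fitness_weighting=fitness_weighting,
                survival_exponent=survival_exponent,
            )
    return results


def pair_master_seed(master_seed: int, s_index: int, c_index: int) -> int:
    """Deterministic per-(s, c) master seed below 2**31."""
    ss = np.random.SeedSequence(master_seed, spawn_key=(s_index, c_index))
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))
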