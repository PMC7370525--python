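"""Core Wright-Fisher generation update with two beneficial-mutation classes.

Each generation the population of ``N(t)`` tumor cells is replaced by
``N(t + 1)`` offspring drawn from a multinomial distribution whose category
probabilities combine selection (relative fitness of the offspring clone) and
per-locus mutation (irreversible, so a cell only gains mutations).  Clones are
indexed ``(k, l)``: exactly ``k`` of the ``n`` superdriver loci and ``l`` of
the ``m`` driver loci mutated.

The sampling weight of clone ``(k, l)`` is

    theta_kl = sum_{i<=k} sum_{j<=l} C(n-i, k-i) C(m-j, l-j)
               * mu^(k-i+l-j) * (1-mu)^(n-i+m-j) * omega_kl * x_ij

with relative fitness ``omega_kl = (1+r)^k (1+s)^l / wbar`` and population
mean fitness ``wbar = sum_ij (1+r)^i (1+s)^j x_ij``.  The mutation part of the
kernel is separable into a superdriver factor ``A[i, k]`` and a driver factor
``B[j, l]``, so ``theta = omega * (A.T @ X @ B)`` — two small matrix products
per generation instead of a quadruple sum.

Two documented variants are exposed:

``fitness_weighting``
    ``"offspring"`` (default) weights the kernel by the *offspring* clone's
    fitness ``omega_kl``; ``"parent"`` weights by the parent's ``omega_ij``
    (the classical pick-a-parent-then-mutate process).
``survival_exponent``
    ``"as_printed"`` (default) uses ``(1-mu)^(n-i+m-j)``; ``"per_locus"``
    uses ``(1-mu)^((n-k)+(m-l))``, which makes each per-class kernel an exact
    binomial probability kernel.  At ``mu = 1e-8`` the two differ by less
    than 1e-6 relative.

Under either variant the raw weights need not sum exactly to one, so they are
renormalized before the multinomial draw and the deficit ``1 - raw_sum``
(which is ``O((n + m) mu)``) is recorded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Literal

import numpy as np
from scipy.special import comb

from .params import InvalidParameterError, ModelParams

__all__ = [
    "PopulationState",
    "FitnessMatrix",
    "SamplingDistribution",
    "Trajectory",
    "SimulationError",
    "initial_state",
    "relative_fitness",
    "mutation_kernels",
    "sampling_distribution",
    "step",
    "simulate",
    "oracle_step",
]

FitnessWeighting = Literal["offspring", "parent"]
SurvivalExponent = Literal["as_printed", "per_locus"]

ORACLE_MAX_CELLS = 100_000


class SimulationError(RuntimeError):
    """Raised when a simulation reaches an invalid state."""


@dataclass
class PopulationState:
    """Clone counts of one generation.

    ``counts[i, j]`` is the absolute number ``N_ij`` of cells with ``i``
    superdriver and ``j`` driver mutations; shape ``(n + 1, m + 1)``.
    """

    t: int
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D matrix")
        if (self.counts < 0).any():
            raise ValueError("clone counts must be non-negative")
        if self.t < 0:
            raise ValueError("generation index must be >= 0")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def freqs(self) -> np.ndarray:
        """Relative clone frequencies ``x_ij = N_ij / N(t)``."""
        total = self.total
        if total == 0:
            raise SimulationError(f"population extinct at generation {self.t}")
        return self.counts / total


@dataclass
class FitnessMatrix:
    """Relative fitness ``omega_kl`` of every clone, plus the mean fitness.

    ``omega`` is fitness relative to the population mean, so the population
    mean of ``omega`` itself is one: ``sum_kl omega_kl x_kl == 1``.
    """

    omega: np.ndarray
    mean_fitness: float


@dataclass
class SamplingDistribution:
    """Renormalized multinomial sampling probabilities ``theta_kl``.

    ``raw_sum`` preserves the pre-normalization total; ``1 - raw_sum`` is the
    kernel deficit, of order ``(n + m) * mu``.
    """

    theta: np.ndarray
    raw_sum: float


@dataclass
class Trajectory:
    """One replicate: clone counts for every generation ``t = 0 ... T``.

    Attributes
    ----------
    params : ModelParams
    seed : object
        Seed record (master seed, or a ``(master, replicate)`` pair).
    counts : ndarray, shape ``(T + 1, n + 1, m + 1)``, integer
        Absolute clone counts per generation.
    first_hit : ndarray, shape ``(n + 1, m + 1)``, int
        First generation at which clone ``(k, l)`` had at least one cell
        (exact-clone event); ``-1`` if it never appeared by ``T``.
    first_hit_at_least : ndarray
        Same, for the cumulative event "some clone ``(i >= k, j >= l)``
        present".
    """

    params: ModelParams
    seed: object
    counts: np.ndarray
    first_hit: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]
    first_hit_at_least: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.first_hit is None:
            self.first_hit = _first_hits(self.counts, at_least=False)
        if self.first_hit_at_least is None:
            self.first_hit_at_least = _first_hits(self.counts, at_least=True)

    @property
    def n_generations(self) -> int:
        return self.counts.shape[0] - 1

    def state(self, t: int) -> PopulationState:
        return PopulationState(t=t, counts=self.counts[t])

    @property
    def states(self) -> Iterator[PopulationState]:
        for t in range(self.counts.shape[0]):
            yield self.state(t)


def _first_hits(counts: np.ndarray, at_least: bool) -> np.ndarray:
    """First generation each clone (or its upper-right cone) is non-empty."""
    present = counts > 0
    if at_least:
        # suffix-OR along both clone axes: cell (k,l) true iff any (i>=k, j>=l)
        present = present[:, ::-1, ::-1]
        present = np.logical_or.accumulate(present, axis=1)
        present = np.logical_or.accumulate(present, axis=2)
        present = present[:, ::-1, ::-1]
    ever = present.any(axis=0)
    hit = present.argmax(axis=0).astype(np.int64)
    hit[~ever] = -1
    return hit


def initial_state(params: ModelParams) -> PopulationState:
    """All ``N0`` cells wild-type: clone ``(0, 0)``."""
    counts = np.zeros(params.shape, dtype=np.int64)
    counts[0, 0] = params.population_size(0)
    return PopulationState(t=0, counts=counts)


def _check_shape(state: PopulationState, params: ModelParams) -> None:
    if state.counts.shape != params.shape:
        raise ValueError(
            f"state shape {state.counts.shape} does not match "
            f"params shape {params.shape}"
        )


def relative_fitness(state: PopulationState, params: ModelParams) -> FitnessMatrix:
    """Relative fitness ``omega_kl`` of each clone in the current population.

    Fitness effects are multiplicative: a ``(k, l)`` cell has absolute fitness
    ``(1+r)^k (1+s)^l``, and ``omega_kl`` divides this by the population mean
    ``wbar = sum_ij (1+r)^i (1+s)^j x_ij``.
    """
    _check_shape(state, params)
    w = _absolute_fitness(params)
    x = state.freqs
    mean_fitness = float((w * x).sum())
    return FitnessMatrix(omega=w / mean_fitness, mean_fitness=mean_fitness)


def _absolute_fitness(params: ModelParams) -> np.ndarray:
    ks = np.arange(params.n + 1)
    ls = np.arange(params.m + 1)
    return np.outer((1.0 + params.r) ** ks, (1.0 + params.s) ** ls)


def mutation_kernels(
    params: ModelParams,
    survival_exponent: SurvivalExponent = "as_printed",
) -> tuple[np.ndarray, np.ndarray]:
    """Per-class mutation kernels ``A`` (superdriver) and ``B`` (driver).

    ``A[i, k] = C(n-i, k-i) mu^(k-i) * survival`` is the weight of a parent
    with ``i`` superdriver mutations producing an offspring with ``k``; zero
    for ``k < i`` (no back mutation).  The survival factor is
    ``(1-mu)^(n-i)`` under ``"as_printed"`` (so that the product
    ``A[i,k] * B[j,l]`` carries the printed ``(1-mu)^(n-i+m-j)``) and
    ``(1-mu)^(n-k)`` under ``"per_locus"`` (each unmutated locus of the
    *offspring* stays intact, making every row of ``A`` a proper binomial
    distribution).
    """
    mu = params.mu

    def kernel(size: int) -> tuple[np.ndarray, np.ndarray]:
        idx = np.arange(size + 1)
        d = idx[None, :] - idx[:, None]  # k - i
        valid = d >= 0
        base = np.where(valid, comb(size - idx[:, None], np.where(valid, d, 0)), 0.0)
        base = base * np.where(valid, mu ** np.where(valid, d, 0), 0.0)
        if survival_exponent == "as_printed":
            surv = (1.0 - mu) ** (size - idx)[:, None]  # depends on parent i
        elif survival_exponent == "per_locus":
            surv = (1.0 - mu) ** (size - idx)[None, :]  # depends on offspring k
        else:
            raise ValueError(f"unknown survival_exponent {survival_exponent!r}")
        return base * surv, valid

    A, _ = kernel(params.n)
    B, _ = kernel(params.m)
    return A, B


def sampling_distribution(
    state: PopulationState,
    fitness: FitnessMatrix,
    params: ModelParams,
    *,
    fitness_weighting: FitnessWeighting = "offspring",
    survival_exponent: SurvivalExponent = "as_printed",
    kernels: tuple[np.ndarray, np.ndarray] | None = None,
) -> SamplingDistribution:
    """Multinomial sampling probabilities ``theta_kl`` for the next generation.

    ``kernels`` may be passed to reuse precomputed mutation kernels across
    generations (they depend only on ``params``).
    """
    _check_shape(state, params)
    if kernels is None:
        kernels = mutation_kernels(params, survival_exponent)
    A, B = kernels
    x = state.freqs
    if fitness_weighting == "offspring":
        raw = fitness.omega * (A.T @ x @ B)
    elif fitness_weighting == "parent":
        raw = A.T @ (fitness.omega * x) @ B
    else:
        raise ValueError(f"unknown fitness_weighting {fitness_weighting!r}")
    raw_sum = float(raw.sum())
    if raw_sum <= 0:
        raise SimulationError("sampling distribution has zero total mass")
    return SamplingDistribution(theta=raw / raw_sum, raw_sum=raw_sum)


def step(
    state: PopulationState,
    params: ModelParams,
    rng: np.random.Generator,
    *,
    fitness_weighting: FitnessWeighting = "offspring",
    survival_exponent: SurvivalExponent = "as_printed",
    kernels: tuple[np.ndarray, np.ndarray] | None = None,
) -> PopulationState:
    """One Wright-Fisher generation: selection, mutation, multinomial resample.

    The next generation's total is the scheduled ``N(t + 1)``; counts are an
    exact multinomial draw of that size with probabilities ``theta``.
    """
    _check_shape(state, params)
    if state.total == 0:
        raise SimulationError(f"population extinct at generation {state.t}")
    fitness = relative_fitness(state, params)
    theta = sampling_distribution(
        state, fitness, params,
        fitness_weighting=fitness_weighting,
        survival_exponent=survival_exponent,
        kernels=kernels,
    )
    n_next = params.population_size(state.t + 1)
    counts = rng.multinomial(n_next, theta.theta.ravel()).reshape(params.shape)
    return PopulationState(t=state.t + 1, counts=counts)


def simulate(
    params: ModelParams,
    seed: int | np.random.SeedSequence,
    *,
    fitness_weighting: FitnessWeighting = "offspring",
    survival_exponent: SurvivalExponent = "as_printed",
) -> Trajectory:
    """Simulate one replicate of ``T`` generations from a wild-type population.

    Deterministic given ``seed``: rerunning with the same seed reproduces
    bit-identical counts.
    """
    rng = np.random.default_rng(seed)
    kernels = mutation_kernels(params, survival_exponent)
    counts = np.zeros((params.T + 1, *params.shape), dtype=np.int64)
    state = initial_state(params)
    counts[0] = state.counts
    for t in range(params.T):
        state = step(
            state, params, rng,
            fitness_weighting=fitness_weighting,
            survival_exponent=survival_exponent,
            kernels=kernels,
        )
        counts[t + 1] = state.counts
    seed_record = seed if isinstance(seed, int) else repr(seed)
    return Trajectory(params=params, seed=seed_record, counts=counts)


def oracle_step(
    state: PopulationState,
    params: ModelParams,
    rng: np.random.Generator,
) -> PopulationState:
    """Brute-force per-cell generation update, for testing ``step``.

    Each of the ``N(t + 1)`` offspring independently picks a parent clone
    ``(i, j)`` with probability ``omega_ij * x_ij``, then mutates each of its
    ``n - i`` unmutated superdriver loci and ``m - j`` unmutated driver loci
    independently with probability ``mu``.  Guarded to small populations: it
    is a test oracle, not a production path.
    """
    _check_shape(state, params)
    if state.total > ORACLE_MAX_CELLS:
        raise SimulationError(
            f"oracle_step is limited to {ORACLE_MAX_CELLS} cells, "
            f"got {state.total}"
        )
    n_next = params.population_size(state.t + 1)
    if n_next > ORACLE_MAX_CELLS:
        raise SimulationError(
            f"oracle_step is limited to {ORACLE_MAX_CELLS} offspring, "
            f"got {n_next}"
        )
    fitness = relative_fitness(state, params)
    p = (fitness.omega * state.freqs).ravel()
    p = p / p.sum()
    parents = rng.multinomial(n_next, p).reshape(params.shape)
    counts = np.zeros(params.shape, dtype=np.int64)
    for i in range(params.n + 1):
        for j in range(params.m + 1):
            n_off = int(parents[i, j])
            if n_off == 0:
                continue
            dk = rng.binomial(params.n - i, params.mu, size=n_off)
            dl = rng.binomial(params.m - j, params.mu, size=n_off)
            np.add.at(counts, (i + dk, j + dl), 1)
    return PopulationState(t=state.t + 1, counts=counts)
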