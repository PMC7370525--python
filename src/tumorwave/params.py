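"""Model parameters for the two-class Wright-Fisher tumor model.

The model tracks clones ``(k, l)`` of cells carrying exactly ``k`` superdriver
and ``l`` driver mutations.  Drivers confer a constant selective advantage
``s``; superdrivers are aggressive drivers whose advantage is ``r = c * s``
with fitness-increase factor ``c >= 1``.  The population grows geometrically
from ``N0`` to ``NT`` cells over ``T`` discrete generations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Any

__all__ = ["ModelParams", "derive_growth_factor", "InvalidParameterError"]


class InvalidParameterError(ValueError):
    """Raised when a model parameter violates its domain constraints."""


def derive_growth_factor(N0: float, NT: float, T: int) -> float:
    """Per-generation growth multiplier ``alpha = exp(log(NT / N0) / T)``.

    ``alpha**T * N0 == NT`` up to floating-point round-off, so multiplying the
    population size by ``alpha`` every generation carries it from ``N0`` to
    ``NT`` in exactly ``T`` generations.

    Parameters
    ----------
    N0, NT
        Initial and final population sizes in cells; both must be positive.
    T
        Number of generations, at least 1.
    """
    if N0 <= 0 or NT <= 0:
        raise InvalidParameterError(
            f"population sizes must be positive, got N0={N0}, NT={NT}"
        )
    if T < 1:
        raise InvalidParameterError(f"T must be >= 1, got {T}")
    return math.exp(math.log(NT / N0) / T)


@dataclass(frozen=True)
class ModelParams:
    """Scalar constants of the tumor evolution model.

    Attributes
    ----------
    n : int
        Number of superdriver loci; each cell can acquire at most ``n``
        superdriver mutations.
    m : int
        Number of driver loci (cap on driver mutations per cell).
    mu : float
        Per-gene, per-generation mutation probability.
    s : float
        Driver selective advantage, in ``[0, 1]``.
    c : float
        Superdriver fitness increase factor, ``>= 1``.
    N0, NT : float
        Initial and final population sizes in cells.
    T : int
        Number of discrete generations simulated.

    Derived attributes ``r = c * s`` (superdriver advantage) and ``alpha``
    (per-generation growth multiplier) are computed on construction.
    """

    n: int = 10
    m: int = 100
    mu: float = 1e-8
    s: float = 0.01
    c: float = 2.0
    N0: float = 1e6
    NT: float = 1e9
    T: int = 4500
    r: float = field(init=False)
    alpha: float = field(init=False)

    def __post_init__(self) -> None:
        if self.n < 1:
            raise InvalidParameterError(f"n must be >= 1, got {self.n}")
        if self.m < 1:
            raise InvalidParameterError(f"m must be >= 1, got {self.m}")
        if not (0.0 <= self.mu <= 1.0):
            raise InvalidParameterError(f"mu must be in [0, 1], got {self.mu}")
        if not (0.0 <= self.s <= 1.0):
            raise InvalidParameterError(f"s must be in [0, 1], got {self.s}")
        if self.c < 1.0:
            raise InvalidParameterError(f"c must be >= 1, got {self.c}")
        if self.N0 < 1:
            raise InvalidParameterError(f"N0 must be >= 1, got {self.N0}")
        if self.NT < self.N0:
            raise InvalidParameterError(
                f"NT must be >= N0, got NT={self.NT} < N0={self.N0}"
            )
        object.__setattr__(self, "r", self.c * self.s)
        object.__setattr__(
            self, "alpha", derive_growth_factor(self.N0, self.NT, self.T)
        )

    @property
    def shape(self) -> tuple[int, int]:
        """Shape ``(n + 1, m + 1)`` of the clone-count matrix."""
        return (self.n + 1, self.m + 1)

    def population_size(self, t: int) -> int:
        """Deterministic size schedule ``N(t) = round(N0 * alpha**t)``.

        Precomputing the rounded schedule (rather than re-rounding a running
        product) guarantees ``N(T) == NT`` exactly and avoids cumulative
        rounding drift.
        """
        if not (0 <= t <= self.T):
            raise InvalidParameterError(f"generation {t} outside [0, {self.T}]")
        return round(self.N0 * self.alpha**t)

    def schedule(self) -> list[int]:
        """Full size schedule ``[N(0), ..., N(T)]``."""
        return [self.population_size(t) for t in range(self.T + 1)]

    def with_selection(self, s: float, c: float) -> "ModelParams":
        """Copy of these parameters with new selection coefficients."""
        return ModelParams(
            n=self.n, m=self.m, mu=self.mu, s=s, c=c,
            N0=self.N0, NT=self.NT, T=self.T,
        )

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "ModelParams":
        d = {k: v for k, v in d.items() if k not in ("r", "alpha")}
        return cls(**d)
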