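"""Waiting times to clones with k superdrivers and l drivers.

Empirical waiting times are read off simulated trajectories as the first
generation in which at least one cell of the target clone exists.  The
analytic approximation decouples the two mutation classes: the waiting time
to ``k`` superdrivers alone,

    T_k^S = k * log^2[r / (mu * n)] / (r * log[N(T) * N(0)]),

comes from traveling-wave theory for a single class of beneficial mutations
(one new mutation class establishes per wave period), and likewise ``T_l^D``
with ``(s, m)`` in place of ``(r, n)``.  The joint waiting time is then
approximated by the sum ``tau_kl ~= T_k^S + T_l^D``, and the residual
``tau_sim - tau_approx`` is modeled by ordinary least squares on the model
parameters and target mutation counts.

All logarithms are natural.  The size term is ``log(N(T) * N(0))`` as
printed in the source formula; ``size_log_arg="ratio"`` switches to
``log(N(T) / N(0))`` in case the product form is an erratum.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .experiments import EnsembleTrajectory
from .model import Trajectory
from .params import InvalidParameterError, ModelParams

__all__ = [
    "WaitingTimeRecord",
    "RegressionResult",
    "empirical_waiting_time",
    "analytic_T_super",
    "analytic_T_driver",
    "tau_approx",
    "build_residual_table",
    "records_to_frame",
    "fit_error_model",
]

SizeLogArg = Literal["product", "ratio"]
COVARIATE_SETS = {"s,r,k,l": ("s", "r", "k", "l"),
                  "s,c,k,l": ("s", "c", "k", "l")}


@dataclass(frozen=True)
class WaitingTimeRecord:
    """One residual-table row for a parameter/target combination.

    ``tau_sim`` is the mean first-appearance generation of clone ``(k, l)``
    across uncensored replicates; ``censored`` counts replicates in which the
    clone never appeared within the simulated horizon.  ``residual`` is
    ``tau_sim - (T_super + T_driver)`` and is ``nan`` when fully censored.
    """

    s: float
    c: float
    r: float
    k: int
    l: int
    tau_sim: float
    n_replicates: int
    censored: int
    T_super: float
    T_driver: float

    @property
    def tau_approx(self) -> float:
        return self.T_super + self.T_driver

    @property
    def residual(self) -> float:
        return self.tau_sim - self.tau_approx

    @property
    def censor_fraction(self) -> float:
        return self.censored / self.n_replicates


@dataclass
class RegressionResult:
    """OLS fit of the waiting-time residual on four covariates."""

    covariate_set: str
    beta: dict[str, float]
    std_errors: dict[str, float]
    adj_r2: float
    f_stat: float
    p_value: float
    n_obs: int
    standardized: dict[str, float]


def empirical_waiting_time(
    trajectories: Sequence[Trajectory] | EnsembleTrajectory,
    k: int,
    l: int,
    *,
    at_least: bool = False,
) -> tuple[float, int]:
    """Mean first-appearance generation of clone ``(k, l)`` over replicates.

    Parameters
    ----------
    trajectories
        Either a list of per-replicate trajectories or an ensemble (which
        carries the per-replicate first-hit matrices).
    at_least
        If true, use the cumulative event: the first generation in which any
        clone with at least ``k`` superdrivers *and* at least ``l`` drivers
        exists.  Default is the exact-clone event (the first cell with the
        defined mutation numbers).

    Returns
    -------
    (mean, censored)
        ``mean`` over uncensored replicates (``nan`` if all censored) and
        the number of censored replicates.
    """
    if isinstance(trajectories, EnsembleTrajectory):
        hits = (trajectories.first_hits_at_least if at_least
                else trajectories.first_hits)[:, k, l]
    else:
        attr = "first_hit_at_least" if at_least else "first_hit"
        hits = np.array([getattr(t, attr)[k, l] for t in trajectories])
    censored = int((hits < 0).sum())
    uncensored = hits[hits >= 0]
    mean = float(uncensored.mean()) if uncensored.size else math.nan
    return mean, censored


def analytic_T_super(
    k: int, params: ModelParams, *, size_log_arg: SizeLogArg = "product"
) -> float:
    """Analytic waiting time (generations) to ``k`` superdriver mutations."""
    return _analytic_T(k, params.r, params.n, params, size_log_arg)


def analytic_T_driver(
    l: int, params: ModelParams, *, size_log_arg: SizeLogArg = "product"
) -> float:
    """Analytic waiting time (generations) to ``l`` driver mutations."""
    return _analytic_T(l, params.s, params.m, params, size_log_arg)


def _analytic_T(
    count: int, adv: float, loci: int, params: ModelParams,
    size_log_arg: SizeLogArg,
) -> float:
    if count < 0:
        raise InvalidParameterError(f"mutation count must be >= 0, got {count}")
    if count == 0:
        return 0.0
    if adv <= 0:
        raise InvalidParameterError(
            f"selective advantage must be positive for waiting time, got {adv}"
        )
    if adv <= params.mu * loci:
        raise InvalidParameterError(
            f"waiting-time approximation requires advantage {adv} > "
            f"mu * loci = {params.mu * loci}"
        )
    if size_log_arg == "product":
        size_term = math.log(params.NT * params.N0)
    elif size_log_arg == "ratio":
        size_term = math.log(params.NT / params.N0)
    else:
        raise ValueError(f"unknown size_log_arg {size_log_arg!r}")
    return count * math.log(adv / (params.mu * loci)) ** 2 / (adv * size_term)


def tau_approx(
    k: int, l: int, params: ModelParams, *, size_log_arg: SizeLogArg = "product"
) -> float:
    """Sum approximation ``T_k^S + T_l^D`` of the joint waiting time."""
    return (analytic_T_super(k, params, size_log_arg=size_log_arg)
            + analytic_T_driver(l, params, size_log_arg=size_log_arg))


def build_residual_table(
    grid_results: Mapping[tuple[float, float], EnsembleTrajectory],
    k_range: Iterable[int] = range(1, 7),
    l_range: Iterable[int] = range(1, 11),
    *,
    at_least: bool = False,
    size_log_arg: SizeLogArg = "product",
    require: Iterable[tuple[float, float]] | None = None,
) -> list[WaitingTimeRecord]:
    """One record per ``(s, c, k, l)`` combination of the grid.

    ``require`` may list ``(s, c)`` pairs that must be present in
    ``grid_results``; a missing pair raises naming the gap.
    """
    if require is not None:
        missing = [pair for pair in require if pair not in grid_results]
        if missing:
            raise KeyError(f"grid results missing (s, c) pairs: {missing}")
    records: list[WaitingTimeRecord] = []
    for (s, c), ens in grid_results.items():
        params = ens.params
        for k in k_range:
            for l in l_range:
                tau_sim, censored = empirical_waiting_time(
                    ens, k, l, at_least=at_least
                )
                records.append(WaitingTimeRecord(
                    s=s, c=c, r=params.r, k=k, l=l,
                    tau_sim=tau_sim,
                    n_replicates=ens.replicates,
                    censored=censored,
                    T_super=analytic_T_super(
                        k, params, size_log_arg=size_log_arg),
                    T_driver=analytic_T_driver(
                        l, params, size_log_arg=size_log_arg),
                ))
    return records


def records_to_frame(records: Iterable[WaitingTimeRecord]) -> pd.DataFrame:
    """Residual table as a tidy DataFrame (one row per record)."""
    rows = [{
        "s": rec.s, "c": rec.c, "r": rec.r, "k": rec.k, "l": rec.l,
        "tau_sim": rec.tau_sim, "T_super": rec.T_super,
        "T_driver": rec.T_driver, "tau_approx": rec.tau_approx,
        "residual": rec.residual, "n_replicates": rec.n_replicates,
        "censored": rec.censored,
    } for rec in records]
    return pd.DataFrame(rows)


def fit_error_model(
    table: Iterable[WaitingTimeRecord] | pd.DataFrame,
    covariate_set: str = "s,r,k,l",
    *,
    max_censor_fraction: float = 0.5,
) -> RegressionResult:
    """OLS of the residual ``eps = tau_sim - tau_approx`` on four covariates.

    ``eps = b0 + b1*s + b2*r + b3*k + b4*l`` (covariate set ``"s,r,k,l"``) or
    with ``c = r / s`` in place of ``r`` (covariate set ``"s,c,k,l"``).
    Records with undefined residual or with more than ``max_censor_fraction``
    of replicates censored are excluded.  Standardized coefficients
    (``beta * sd(x) / sd(eps)``) are reported for effect-size comparison.
    """
    if covariate_set not in COVARIATE_SETS:
        raise ValueError(
            f"covariate_set must be one of {sorted(COVARIATE_SETS)}, "
            f"got {covariate_set!r}"
        )
    cols = COVARIATE_SETS[covariate_set]
    if isinstance(table, pd.DataFrame):
        df = table.copy()
        if "residual" not in df:
            df["residual"] = df["tau_sim"] - df["T_super"] - df["T_driver"]
        if "censor_fraction" not in df:
            df["censor_fraction"] = df["censored"] / df["n_replicates"]
    else:
        df = records_to_frame(table)
        df["censor_fraction"] = df["censored"] / df["n_replicates"]
    keep = df["residual"].notna() & (df["censor_fraction"] <= max_censor_fraction)
    df = df.loc[keep]
    if len(df) <= 5:
        raise ValueError(
            f"need more than 5 uncensored rows to fit, got {len(df)}"
        )
    X = df[list(cols)].to_numpy(dtype=float)
    y = df["residual"].to_numpy(dtype=float)
    design = sm.add_constant(X, has_constant="add")
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        deficient = _deficient_columns(design, ("const", *cols))
        raise ValueError(
            f"rank-deficient design (rank {rank} < {design.shape[1]}); "
            f"collinear columns: {deficient}"
        )
    fit = sm.OLS(y, design).fit()
    names = ("const", *cols)
    beta = dict(zip(names, fit.params))
    sd_y = float(y.std(ddof=1))
    standardized = {
        name: float(beta[name] * X[:, i].std(ddof=1) / sd_y)
        for i, name in enumerate(cols)
    }
    return RegressionResult(
        covariate_set=covariate_set,
        beta=beta,
        std_errors=dict(zip(names, fit.bse)),
        adj_r2=float(fit.rsquared_adj),
        f_stat=float(fit.fvalue),
        p_value=float(fit.f_pvalue),
        n_obs=int(fit.nobs),
        standardized=standardized,
    )


def _deficient_columns(design: np.ndarray, names: Sequence[str]) -> list[str]:
    """Columns whose removal does not reduce the design rank."""
    full_rank = np.linalg.matrix_rank(design)
    out = []
    for i, name in enumerate(names):
        reduced = np.delete(design, i, axis=1)
        if np.linalg.matrix_rank(reduced) == full_rank:
            out.append(name)
    return out
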