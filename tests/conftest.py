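"""Shared fixtures: small presets and session-scoped simulation ensembles.

The heavier ensembles (study-scale parameters at reduced replicate counts)
are session-scoped so that several tests can share one simulation run.
"""

from __future__ import annotations

import numpy as np
import pytest

import tumorwave as tw
from tumorwave.fixtures import preset_params


@pytest.fixture(scope="session")
def tiny_neutral_params() -> tw.ModelParams:
    return preset_params("tiny-neutral")


@pytest.fixture(scope="session")
def tiny_oracle_params() -> tw.ModelParams:
    return preset_params("tiny-oracle")


@pytest.fixture(scope="session")
def short_default_traj() -> tw.Trajectory:
    """One replicate of the study defaults truncated to 500 generations."""
    return tw.make_fixture("default-short", seed=20240901)


@pytest.fixture(scope="session")
def ensemble_c2_r5() -> tw.EnsembleTrajectory:
    """Study parameters (s = 0.01, c = 2), 5 replicates, full horizon."""
    return tw.run_ensemble(tw.ModelParams(s=0.01, c=2.0), replicates=5,
                           master_seed=42)


@pytest.fixture(scope="session")
def ensemble_c2_r10() -> tw.EnsembleTrajectory:
    """Study parameters (s = 0.01, c = 2), 10 replicates, full horizon."""
    return tw.run_ensemble(tw.ModelParams(s=0.01, c=2.0), replicates=10,
                           master_seed=43)


@pytest.fixture(scope="session")
def ensembles_low_high_c() -> dict[float, tw.EnsembleTrajectory]:
    """s = 0.01 ensembles at weak (c = 1.1) and strong (c = 3) superdriver
    selection, 5 replicates each."""
    return {
        c: tw.run_ensemble(tw.ModelParams(s=0.01, c=c), replicates=5,
                           master_seed=44)
        for c in (1.1, 3.0)
    }


def make_synthetic_ensemble(
    series_map: dict[tuple[int, int], np.ndarray],
    n: int = 5,
    m: int = 10,
) -> tw.EnsembleTrajectory:
    """Ensemble whose mean frequencies are handed in per clone.

    Residual mass is assigned to clone (0, 0) so frequencies sum to one.
    Used to exercise wave statistics on constructed profiles.
    """
    length = len(next(iter(series_map.values())))
    params = tw.ModelParams(n=n, m=m, N0=1000, NT=1000, T=length - 1)
    freqs = np.zeros((length, n + 1, m + 1))
    for (k, l), series in series_map.items():
        if (k, l) == (0, 0):
            raise ValueError("clone (0, 0) holds the residual mass")
        freqs[:, k, l] = series
    freqs[:, 0, 0] = 1.0 - freqs.sum(axis=(1, 2))
    if (freqs[:, 0, 0] < 0).any():
        raise ValueError("series frequencies exceed 1 somewhere")
    counts = freqs * 1000
    hits = np.zeros((1, n + 1, m + 1), dtype=np.int64)
    return tw.EnsembleTrajectory(
        params=params, replicates=1, master_seed=0,
        mean_counts=counts, mean_freqs=freqs,
        first_hits=hits, first_hits_at_least=hits.copy(),
    )
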