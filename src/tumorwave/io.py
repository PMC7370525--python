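"""Trajectory and ensemble persistence: tidy TSV plus a JSON sidecar.

Trajectories are written long-form with columns
``replicate, generation, k, l, count`` (zero clones omitted; counts are exact
integers for single replicates, means for ensembles).  The sidecar records
everything needed to regenerate the file: model parameters, seeds, the size
schedule end points, analysis switches in force, and the package version.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import __version__
from .experiments import EnsembleTrajectory, GridSpec, pair_master_seed
from .model import Trajectory
from .params import ModelParams

__all__ = [
    "write_trajectory", "read_trajectory",
    "write_ensemble", "read_ensemble",
    "write_grid_manifest",
]

_COLUMNS = ["replicate", "generation", "k", "l", "count"]


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def _write_sidecar(path: Path, payload: dict) -> None:
    _sidecar_path(path).write_text(json.dumps(payload, indent=2, default=str))


def _long_form(counts: np.ndarray, replicate: int) -> pd.DataFrame:
    """(T+1, n+1, m+1) array -> long rows with zero clones dropped."""
    t_idx, k_idx, l_idx = np.nonzero(counts)
    return pd.DataFrame({
        "replicate": replicate,
        "generation": t_idx,
        "k": k_idx,
        "l": l_idx,
        "count": counts[t_idx, k_idx, l_idx],
    })


def write_trajectory(path: str | Path, traj: Trajectory) -> None:
    path = Path(path)
    df = _long_form(traj.counts, replicate=0)
    df.to_csv(path, sep="\t", index=False)
    _write_sidecar(path, {
        "kind": "trajectory",
        "params": traj.params.to_dict(),
        "seed": traj.seed,
        "schedule": {"N0": traj.params.N0, "NT": traj.params.NT,
                     "T": traj.params.T, "alpha": traj.params.alpha},
        "version": __version__,
    })


def read_trajectory(path: str | Path) -> Trajectory:
    """Inverse of :func:`write_trajectory`, bit-exact for integer counts."""
    path = Path(path)
    sidecar = json.loads(_sidecar_path(path).read_text())
    params = ModelParams.from_dict(sidecar["params"])
    df = _read_tsv(path)
    counts = np.zeros((params.T + 1, *params.shape), dtype=np.int64)
    counts[df["generation"], df["k"], df["l"]] = df["count"]
    return Trajectory(params=params, seed=sidecar.get("seed"), counts=counts)


def _read_tsv(path: Path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t")
    except Exception as exc:
        raise ValueError(f"cannot parse {path}: {exc}") from exc
    missing = set(_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    for col in ("generation", "k", "l"):  # replicate -1 is the ensemble sentinel
        bad = df[df[col] < 0]
        if len(bad):
            raise ValueError(
                f"{path}: negative {col} at data line {bad.index[0] + 2}")
    if df["count"].isna().any():
        line = int(df.index[df["count"].isna()][0]) + 2
        raise ValueError(f"{path}: malformed count at data line {line}")
    return df


def write_ensemble(path: str | Path, ens: EnsembleTrajectory,
                   scale: str = "counts") -> None:
    """Persist ensemble means (counts or frequencies) plus first-hit matrices."""
    path = Path(path)
    src = ens.mean_counts if scale == "counts" else ens.mean_freqs
    t_idx, k_idx, l_idx = np.nonzero(src)
    df = pd.DataFrame({
        "replicate": -1,  # sentinel: ensemble mean
        "generation": t_idx, "k": k_idx, "l": l_idx,
        "count": src[t_idx, k_idx, l_idx],
    })
    df.to_csv(path, sep="\t", index=False)
    _write_sidecar(path, {
        "kind": "ensemble",
        "scale": scale,
        "params": ens.params.to_dict(),
        "replicates": ens.replicates,
        "master_seed": ens.master_seed,
        "first_hits": ens.first_hits.tolist(),
        "first_hits_at_least": ens.first_hits_at_least.tolist(),
        "version": __version__,
    })


def read_ensemble(path: str | Path) -> EnsembleTrajectory:
    path = Path(path)
    sidecar = json.loads(_sidecar_path(path).read_text())
    params = ModelParams.from_dict(sidecar["params"])
    df = _read_tsv(path)
    mean = np.zeros((params.T + 1, *params.shape), dtype=np.float64)
    mean[df["generation"], df["k"], df["l"]] = df["count"]
    scale = sidecar.get("scale", "counts")
    if scale == "counts":
        mean_counts = mean
        totals = mean.sum(axis=(1, 2), keepdims=True)
        mean_freqs = mean / totals
    else:
        mean_freqs = mean
        mean_counts = mean * np.array(
            params.schedule(), dtype=float)[:, None, None]
    return EnsembleTrajectory(
        params=params,
        replicates=sidecar["replicates"],
        master_seed=sidecar["master_seed"],
        mean_counts=mean_counts,
        mean_freqs=mean_freqs,
        first_hits=np.array(sidecar["first_hits"], dtype=np.int64),
        first_hits_at_least=np.array(
            sidecar["first_hits_at_least"], dtype=np.int64),
    )


def write_grid_manifest(path: str | Path, grid: GridSpec,
                        files: Mapping[tuple[float, float], str] | None = None,
                        ) -> pd.DataFrame:
    """TSV manifest of a grid run: one row per (s, c) with its derived seed."""
    rows = []
    for si, s in enumerate(grid.s_values):
        for ci, c in enumerate(grid.c_values):
            rows.append({
                "s": s, "c": c, "r": c * s,
                "replicates": grid.replicates,
                "master_seed": pair_master_seed(grid.master_seed, si, ci),
                "file": files.get((s, c), "") if files else "",
            })
    df = pd.DataFrame(rows)
    df.to_csv(path, sep="\t", index=False)
    return df
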