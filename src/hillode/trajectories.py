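"""Expression-trajectory containers and their on-disk format.

A :class:`TrajectorySet` holds a stack of expression trajectories over one
shared, strictly increasing time grid — the universal currency passed
between the simulator, the trainer and the evaluation code.  On disk it is
a long-format TSV ``(trajectory_id, time, gene, value)``; round-trips are
lossless to 1e-12.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ArgumentError, DataFormatError, DimensionError

__all__ = ["TrajectorySet", "read_trajectories_tsv", "write_trajectories_tsv"]


@dataclass(frozen=True)
class TrajectorySet:
    """Expression values indexed (trajectory, time point, gene)."""

    gene_ids: tuple[str, ...]
    times: np.ndarray          # (T,), strictly increasing
    values: np.ndarray         # (n_traj, T, n_genes)

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "values", values)
        if times.ndim != 1 or np.any(np.diff(times) <= 0):
            raise ArgumentError("times must be 1-D and strictly increasing")
        if values.ndim != 3:
            raise DimensionError("values must be (n_traj, n_times, n_genes)")
        if values.shape[1] != times.size or values.shape[2] != len(self.gene_ids):
            raise DimensionError(
                f"values shape {values.shape} inconsistent with "
                f"{times.size} times and {len(self.gene_ids)} genes"
            )

    @property
    def n_traj(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def subset(self, traj_indices) -> "TrajectorySet":
        return TrajectorySet(self.gene_ids, self.times, self.values[np.asarray(traj_indices)])

    def split(self, n_train: int, n_val: int, n_test: int, seed: int | None = None):
        """Partition trajectories into train/validation/test sets.

        With ``seed`` given, the trajectory order is shuffled first;
        otherwise the split is by position.
        """
        if n_train + n_val + n_test > self.n_traj:
            raise ArgumentError("split sizes exceed number of trajectories")
        order = np.arange(self.n_traj)
        if seed is not None:
            np.random.default_rng(seed).shuffle(order)
        a, b = n_train, n_train + n_val
        return (
            self.subset(order[:a]),
            self.subset(order[a:b]),
            self.subset(order[b : b + n_test]),
        )


def write_trajectories_tsv(trajset: TrajectorySet, path) -> None:
    n_traj, n_t, n_g = trajset.values.shape
    traj = np.repeat(np.arange(n_traj), n_t * n_g)
    time = np.tile(np.repeat(trajset.times, n_g), n_traj)
    gene = np.tile(np.asarray(trajset.gene_ids, dtype=object), n_traj * n_t)
    df = pd.DataFrame(
        {"trajectory_id": traj, "time": time, "gene": gene,
         "value": trajset.values.reshape(-1)}
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_trajectories_tsv(path) -> TrajectorySet:
    """Read a long-format trajectory TSV.

    Raises :class:`DataFormatError` on non-numeric cells, duplicate
    (trajectory, time, gene) keys, or an incomplete grid.
    """
    df = pd.read_csv(path, sep="\t", dtype={"gene": str})
    required = {"trajectory_id", "time", "gene", "value"}
    if not required.issubset(df.columns):
        raise DataFormatError(f"{path}: expected columns {sorted(required)}")
    for col in ("time", "value"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = np.where(vals.isna() & df[col].notna())[0]
        if bad.size:
            raise DataFormatError(f"{path}: non-numeric {col!r} at data row {bad[0] + 2}")
        df[col] = vals
    dup = df.duplicated(subset=["trajectory_id", "time", "gene"])
    if dup.any():
        row = int(np.where(dup)[0][0]) + 2
        raise DataFormatError(f"{path}: duplicate (trajectory, time, gene) key at row {row}")
    times = np.sort(df["time"].unique())
    genes = tuple(pd.unique(df["gene"]))
    trajs = pd.unique(df["trajectory_id"])
    pivot = df.set_index(["trajectory_id", "time", "gene"])["value"]
    try:
        values = (
            pivot.unstack("gene")
            .reindex(columns=list(genes))
            .to_numpy()
            .reshape(len(trajs), len(times), len(genes))
        )
    except ValueError as exc:
        raise DataFormatError(f"{path}: incomplete trajectory grid") from exc
    if np.isnan(values).any():
        raise DataFormatError(f"{path}: missing entries in trajectory grid")
    return TrajectorySet(genes, times, values)
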