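"""Expression-table ingestion and normalization.

Accepts the two tabular layouts the rest of the package produces or that
public expression time courses are typically shipped in:

* long TSV with columns (trajectory_id, time, gene, value);
* wide TSV with a gene column and one column per time point, the header
  row carrying the numeric times (one trajectory).

Expression values are min-max normalized to [0, 1] on request, with the
transform parameters returned for inversion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DataFormatError
from .trajectories import TrajectorySet, read_trajectories_tsv

__all__ = ["NormalizationParams", "read_expression_table",
           "normalize_minmax", "denormalize"]


@dataclass(frozen=True)
class NormalizationParams:
    lo: float
    hi: float

    def inverse(self, values: np.ndarray) -> np.ndarray:
        return values * (self.hi - self.lo) + self.lo


def _read_wide(path) -> TrajectorySet:
    df = pd.read_csv(path, sep="\t")
    gene_col = df.columns[0]
    try:
        times = np.array([float(c) for c in df.columns[1:]])
    except ValueError as exc:
        raise DataFormatError(
            f"{path}: wide-format column headers must be numeric times"
        ) from exc
    if np.any(np.diff(times) <= 0):
        raise DataFormatError(f"{path}: time columns must be strictly increasing")
    genes = tuple(df[gene_col].astype(str))
    if len(set(genes)) != len(genes):
        raise DataFormatError(f"{path}: duplicate gene rows")
    mat = df.iloc[:, 1:].apply(pd.to_numeric, errors="coerce").to_numpy()
    if np.isnan(mat).any():
        row = int(np.where(np.isnan(mat).any(axis=1))[0][0]) + 2
        raise DataFormatError(f"{path}: non-numeric cell at row {row}")
    # (genes, times) -> (1 trajectory, times, genes)
    return TrajectorySet(genes, times, mat.T[None, :, :])


def read_expression_table(path, normalize: bool = False):
    """Read a long- or wide-format expression table.

    Returns ``(trajset, norm)`` where ``norm`` is the
    :class:`NormalizationParams` applied (identity parameters when
    ``normalize`` is false).
    """
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
    if {"trajectory_id", "time", "gene", "value"}.issubset(header):
        trajset = read_trajectories_tsv(path)
    else:
        trajset = _read_wide(path)
    if normalize:
        trajset, norm = normalize_minmax(trajset)
    else:
        norm = NormalizationParams(0.0, 1.0)
    return trajset, norm


def normalize_minmax(trajset: TrajectorySet):
    """Min-max scale all values to [0, 1] over the whole dataset."""
    lo = float(trajset.values.min())
    hi = float(trajset.values.max())
    if hi <= lo:
        raise DataFormatError("cannot normalize a constant dataset")
    scaled = (trajset.values - lo) / (hi - lo)
    return (TrajectorySet(trajset.gene_ids, trajset.times, scaled),
            NormalizationParams(lo, hi))


def denormalize(trajset: TrajectorySet, norm: NormalizationParams) -> TrajectorySet:
    return TrajectorySet(trajset.gene_ids, trajset.times,
                         norm.inverse(trajset.values))
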