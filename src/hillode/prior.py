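"""Putative-regulation priors and the linear prior model.

The prior is an n-by-n adjacency ``A`` over the model's gene order, signed
(+1 activating / -1 repressive / 0 none) or existence-only ({1, 0}).  It
drives the soft structural constraint through the linear prior model

    P*(gamma) = (A - I) @ gamma,

evaluated on "ghost inputs": simulated expression vectors drawn uniformly
from [0, 1]^n, at which the learned derivative field is penalized toward
the prior-based derivative.  Benchmark corruption of a known-true prior
(edge removal, spurious additions, sign flips) also lives here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import ArgumentError, DataFormatError, DimensionError
from .grn import GroundTruthGRN

__all__ = ["PriorAdjacency", "GhostBatch", "prior_from_grn", "load_prior",
           "write_prior", "prior_predict", "sample_ghosts", "corrupt_prior"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class PriorAdjacency:
    """Prior regulatory adjacency; rows = targets, columns = regulators."""

    gene_ids: tuple[str, ...]
    A: np.ndarray
    signed: bool = True

    def __post_init__(self) -> None:
        A = np.asarray(self.A, dtype=float)
        object.__setattr__(self, "A", A)
        n = len(self.gene_ids)
        if A.shape != (n, n):
            raise DimensionError(f"A must be {n}x{n}, got {A.shape}")
        allowed = {-1.0, 0.0, 1.0} if self.signed else {0.0, 1.0}
        vals = set(np.unique(A).tolist())
        if not vals.issubset(allowed):
            raise ArgumentError(
                f"adjacency entries {sorted(vals - allowed)} outside "
                f"{'signed' if self.signed else 'existence'} alphabet"
            )

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_edges(self) -> int:
        return int(np.count_nonzero(self.A))


@dataclass(frozen=True)
class GhostBatch:
    """K simulated expression vectors in [0, 1]^n."""

    gamma: np.ndarray   # (K, n)
    seed: int

    def __post_init__(self) -> None:
        gamma = np.asarray(self.gamma, dtype=float)
        object.__setattr__(self, "gamma", gamma)
        if gamma.ndim != 2:
            raise DimensionError("gamma must be (K, n)")
        if gamma.min() < 0 or gamma.max() > 1:
            raise ArgumentError("ghost inputs must lie in [0, 1]")

    @property
    def K(self) -> int:
        return self.gamma.shape[0]


def prior_from_grn(grn: GroundTruthGRN) -> PriorAdjacency:
    """Signed prior equal to the ground-truth adjacency (benchmark use)."""
    return PriorAdjacency(grn.gene_ids, grn.adjacency(), signed=True)


def load_prior(path, gene_ids) -> PriorAdjacency:
    """Read a TSV edge list (source, target[, sign]) onto a gene order.

    Rows whose genes are not in ``gene_ids`` are dropped with a logged
    count.  A missing sign column yields an existence-mode prior.
    """
    gene_ids = tuple(gene_ids)
    idx = {g: i for i, g in enumerate(gene_ids)}
    n = len(gene_ids)
    A = np.zeros((n, n))
    signed = True
    dropped = 0
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) < 2:
            raise DataFormatError(f"{path}: expected >=2 tab-separated columns")
        has_sign = len(header) >= 3
        if not has_sign:
            signed = False
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 2 + has_sign:
                raise DataFormatError(f"{path}:{lineno}: too few columns")
            src, tgt = parts[0], parts[1]
            if has_sign:
                try:
                    sign = int(parts[2])
                except ValueError as exc:
                    raise DataFormatError(f"{path}:{lineno}: bad sign {parts[2]!r}") from exc
                if sign not in (-1, 0, 1):
                    raise DataFormatError(f"{path}:{lineno}: sign must be in {{+1,-1,1,0}}")
            else:
                sign = 1
            if src not in idx or tgt not in idx:
                dropped += 1
                continue
            A[idx[tgt], idx[src]] = sign
    if dropped:
        log.info("load_prior: dropped %d edge rows with unknown genes", dropped)
    return PriorAdjacency(gene_ids, A, signed=signed)


def write_prior(prior: PriorAdjacency, path) -> None:
    """Write the effective prior as a TSV edge list, for provenance."""
    tgt, src = np.nonzero(prior.A)
    with open(path, "w", encoding="utf-8") as fh:
        if prior.signed:
            fh.write("source\ttarget\tsign\n")
            for t, s in zip(tgt, src):
                fh.write(f"{prior.gene_ids[s]}\t{prior.gene_ids[t]}\t{int(prior.A[t, s]):+d}\n")
        else:
            fh.write("source\ttarget\n")
            for t, s in zip(tgt, src):
                fh.write(f"{prior.gene_ids[s]}\t{prior.gene_ids[t]}\n")


def prior_predict(prior: PriorAdjacency, gamma: np.ndarray) -> np.ndarray:
    """Linear prior derivative P*(gamma) = (A - I) gamma.

    ``gamma`` may carry leading batch axes; the map is applied to the last
    axis.
    """
    gamma = np.asarray(gamma, dtype=float)
    if gamma.shape[-1] != prior.n_genes:
        raise DimensionError(
            f"gamma has {gamma.shape[-1]} genes, prior has {prior.n_genes}"
        )
    return gamma @ prior.A.T - gamma


def sample_ghosts(K: int, n: int, seed: int) -> GhostBatch:
    """K i.i.d. U(0,1)^n ghost inputs, deterministic per seed."""
    if K < 1 or n < 1:
        raise ArgumentError("K and n must be >= 1")
    rng = np.random.default_rng(seed)
    return GhostBatch(rng.uniform(size=(K, n)), seed)


def corrupt_prior(prior: PriorAdjacency, level: float, seed: int) -> PriorAdjacency:
    """Corrupt a prior to emulate noisy knowledge of the true network.

    A fraction ``level`` of the edges is removed; an equal number of
    spurious edges is added uniformly among absent off-diagonal pairs; a
    fraction ``level`` of the *surviving* signed edges has its sign
    flipped (skipped for existence-mode priors).  Deterministic per seed.
    """
    if not (0.0 <= level <= 1.0):
        raise ArgumentError("corruption level must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    n = prior.n_genes
    A = prior.A.copy()
    tgt, src = np.nonzero(A)
    E = tgt.size
    n_remove = int(round(level * E))
    remove = rng.choice(E, size=n_remove, replace=False) if n_remove else np.zeros(0, int)
    A[tgt[remove], src[remove]] = 0.0

    offdiag = ~np.eye(n, dtype=bool)
    absent = np.flatnonzero((A == 0) & offdiag)
    n_add = min(n_remove, absent.size)
    add = rng.choice(absent.size, size=n_add, replace=False) if n_add else np.zeros(0, int)
    flat = absent[add]
    signs = rng.choice([-1.0, 1.0], size=n_add) if prior.signed else np.ones(n_add)
    A[np.unravel_index(flat, A.shape)] = signs

    if prior.signed:
        keep = np.setdiff1d(np.arange(E), remove)
        n_flip = int(round(level * keep.size))
        if n_flip:
            flip = rng.choice(keep.size, size=n_flip, replace=False)
            sel = keep[flip]
            A[tgt[sel], src[sel]] *= -1.0
    return PriorAdjacency(prior.gene_ids, A, signed=prior.signed)
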