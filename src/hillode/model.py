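"""Hill-kinetics-structured neural ODE architecture.

The learned vector field for an expression state ``g`` in [0, 1]^n is

    dg/dt = ReLU(upsilon) * ( W_combine @ [c_sums(g) ; c_prods(g)] - g )

with two single-layer blocks sharing Hill-like activations::

    phi_sum(x)  = (x - 0.5) / (1 + |x - 0.5|)          (shifted softsign)
    phi_prod(x) = log(phi_sum(x) + 1)
    c_sums(g)   = W_sums  @ phi_sum(g)  + b_sums
    c_prods(g)  = exp( W_prods @ phi_prod(g) + b_prods )

``c_sums`` captures additive co-regulation on the linear scale;
``c_prods`` works on the log scale, so one-hot rows realize products of
shifted-softsign terms raised to integer weights — the neural analogue of
cooperative Hill kinetics.  A single linear combiner mixes both blocks,
and per-gene multipliers ``ReLU(upsilon)`` let the model represent genes
with exactly zero temporal variation (gradients vanish where
``upsilon <= 0``).

Everything is plain numpy; the training loop differentiates this field
with the hand-derived vector-Jacobian product in :mod:`hillode.autodiff`.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.integrate import solve_ivp

from .errors import ArgumentError, DimensionError, NumericalError
from .trajectories import TrajectorySet

__all__ = ["ModelParameters", "SolverSettings", "ExpressionState", "phi_sum", "phi_prod",
           "phi_sum_deriv", "phi_prod_deriv", "block_sums", "block_prods",
           "derivative", "init_parameters", "default_hidden_width",
           "predict_trajectory", "save_checkpoint", "load_checkpoint"]

log = logging.getLogger(__name__)

#: bound on the pre-exponential inside the products block; exp overflow
#: guard, far outside the operating range for inputs in [0, 1]
PREEXP_CLAMP = 10.0


def phi_sum(x):
    """Shifted softsign activation; odd around x = 0.5, range (-1, 1)."""
    x = np.asarray(x, dtype=float)
    return (x - 0.5) / (1.0 + np.abs(x - 0.5))


def phi_prod(x):
    """Log-scale activation, log(1 + phi_sum(x)); phi_prod(0.5) = 0."""
    return np.log1p(phi_sum(x))


def phi_sum_deriv(x):
    x = np.asarray(x, dtype=float)
    return 1.0 / (1.0 + np.abs(x - 0.5)) ** 2


def phi_prod_deriv(x):
    return phi_sum_deriv(x) / (1.0 + phi_sum(x))


@dataclass(frozen=True)
class SolverSettings:
    """Numerical integration settings for trajectory prediction.

    ``method`` is an adaptive Runge-Kutta family identifier understood by
    :func:`scipy.integrate.solve_ivp` (default Dormand-Prince "RK45"), or
    the fixed-step "rk4" used by the training loop, whose resolution is
    ``rk4_step``.
    """

    method: str = "RK45"
    rtol: float = 1e-5
    atol: float = 1e-7
    max_steps: int = 100_000
    rk4_step: float = 0.25

    def __post_init__(self) -> None:
        if self.rtol <= 0 or self.atol <= 0:
            raise ArgumentError("rtol and atol must be positive")
        if self.rk4_step <= 0:
            raise ArgumentError("rk4_step must be positive")


@dataclass(frozen=True)
class ExpressionState:
    """One expression vector at one time point."""

    gene_ids: tuple[str, ...]
    g: np.ndarray
    t: float

    def __post_init__(self) -> None:
        g = np.asarray(self.g, dtype=float)
        object.__setattr__(self, "g", g)
        if g.shape != (len(self.gene_ids),):
            raise DimensionError(
                f"state vector has shape {g.shape}, expected ({len(self.gene_ids)},)"
            )


@dataclass(frozen=True)
class ModelParameters:
    """Trainable tensors theta = (W_sums, W_prods, b_sums, b_prods, W_combine, upsilon).

    ``W_combine`` (n x 2m) is column-partitioned [U_sums | U_prods]; the
    concatenation order [c_sums; c_prods] is fixed and part of the
    serialization contract.
    """

    gene_ids: tuple[str, ...]
    W_sums: np.ndarray      # (m, n)
    b_sums: np.ndarray      # (m,)
    W_prods: np.ndarray     # (m, n)
    b_prods: np.ndarray     # (m,)
    W_combine: np.ndarray   # (n, 2m)
    upsilon: np.ndarray     # (n,)

    def __post_init__(self) -> None:
        n, m = self.n, self.m
        shapes = {
            "W_sums": (m, n), "b_sums": (m,), "W_prods": (m, n),
            "b_prods": (m,), "W_combine": (n, 2 * m), "upsilon": (n,),
        }
        for name, want in shapes.items():
            arr = np.asarray(getattr(self, name), dtype=float)
            object.__setattr__(self, name, arr)
            if arr.shape != want:
                raise DimensionError(f"{name} must have shape {want}, got {arr.shape}")
            if not np.all(np.isfinite(arr)):
                raise ArgumentError(f"{name} contains non-finite entries")

    @property
    def n(self) -> int:
        return len(self.gene_ids)

    @property
    def m(self) -> int:
        return np.asarray(self.W_sums).shape[0]

    @property
    def U_sums(self) -> np.ndarray:
        return self.W_combine[:, : self.m]

    @property
    def U_prods(self) -> np.ndarray:
        return self.W_combine[:, self.m :]

    def with_arrays(self, **arrays) -> "ModelParameters":
        return replace(self, **arrays)

    def flat(self) -> np.ndarray:
        return np.concatenate([
            self.W_sums.ravel(), self.b_sums, self.W_prods.ravel(),
            self.b_prods, self.W_combine.ravel(), self.upsilon,
        ])


def default_hidden_width(n: int) -> int:
    """Default per-block hidden width: one hidden unit per gene (min 8).

    Narrower blocks force unrelated genes to share hidden units, which
    blurs the extracted effect matrix; width n keeps the parameter count
    at ~4 n^2, comparable to one dense linear system over the genes.
    """
    return max(n, 8)


def init_parameters(gene_ids, m: int | None = None, seed: int = 0) -> ModelParameters:
    """Random initialization: weights/biases U(-s, s) with s = 1/sqrt(fan_in);
    upsilon i.i.d. standard uniform."""
    gene_ids = tuple(gene_ids)
    n = len(gene_ids)
    if n == 0:
        raise ArgumentError("need at least one gene")
    if m is None:
        m = default_hidden_width(n)
    rng = np.random.default_rng(seed)
    s_in = 1.0 / np.sqrt(n)
    s_comb = 1.0 / np.sqrt(2 * m)
    return ModelParameters(
        gene_ids=gene_ids,
        W_sums=rng.uniform(-s_in, s_in, size=(m, n)),
        b_sums=rng.uniform(-s_in, s_in, size=m),
        W_prods=rng.uniform(-s_in, s_in, size=(m, n)),
        b_prods=rng.uniform(-s_in, s_in, size=m),
        W_combine=rng.uniform(-s_comb, s_comb, size=(n, 2 * m)),
        upsilon=rng.uniform(0.0, 1.0, size=n),
    )


def _check_state(g: np.ndarray, params: ModelParameters) -> np.ndarray:
    g = np.asarray(g, dtype=float)
    if g.shape[-1] != params.n:
        raise DimensionError(f"state has {g.shape[-1]} genes, model has {params.n}")
    return g


def block_sums(g, params: ModelParameters) -> np.ndarray:
    """Additive block c_sums(g) = W_sums phi_sum(g) + b_sums (batched on last axis)."""
    g = _check_state(g, params)
    return phi_sum(g) @ params.W_sums.T + params.b_sums


def block_prods(g, params: ModelParameters, clamp: float = PREEXP_CLAMP) -> np.ndarray:
    """Multiplicative block c_prods(g) = exp(W_prods phi_prod(g) + b_prods).

    The pre-exponential is clamped at ±``clamp`` (overflow guard; a hit is
    logged at DEBUG since it is outside the normal operating range).
    """
    g = _check_state(g, params)
    z = phi_prod(g) @ params.W_prods.T + params.b_prods
    if np.any(np.abs(z) > clamp):
        log.debug("block_prods: clamping %d pre-exponential values",
                  int(np.sum(np.abs(z) > clamp)))
        z = np.clip(z, -clamp, clamp)
    return np.exp(z)


def derivative(g, params: ModelParameters) -> np.ndarray:
    """Learned vector field ReLU(upsilon) * (W_combine [c_sums; c_prods] - g)."""
    g = _check_state(g, params)
    c = np.concatenate([block_sums(g, params), block_prods(g, params)], axis=-1)
    u = np.maximum(params.upsilon, 0.0)
    return u * (c @ params.W_combine.T - g)


def predict_trajectory(
    g0: np.ndarray,
    times,
    params: ModelParameters,
    solver: SolverSettings = SolverSettings(),
) -> TrajectorySet:
    """Roll the learned dynamics forward from state(s) ``g0`` over ``times``.

    ``g0`` may be one state (n,) or a batch (B, n); all trajectories are
    integrated as one stacked system.  The first output equals ``g0``
    exactly.  Halving (rtol, atol) changes outputs by < 1e-4 sup-norm at
    the default tolerances.
    """
    times = np.asarray(times, dtype=float)
    if np.any(np.diff(times) <= 0):
        raise ArgumentError("times must be strictly increasing")
    if isinstance(g0, ExpressionState):
        if times[0] != g0.t:
            raise ArgumentError(f"times[0]={times[0]} does not match state time {g0.t}")
        g0 = g0.g
    g0 = np.atleast_2d(np.asarray(g0, dtype=float))
    _check_state(g0, params)
    B, n = g0.shape

    if solver.method.lower() == "rk4":
        from .autodiff import rk4_solve  # no gradients needed here
        values = rk4_solve(g0, times, params, solver.rk4_step)
    else:
        def rhs(_t, y):
            return derivative(y.reshape(B, n), params).reshape(-1)

        sol = solve_ivp(rhs, (times[0], times[-1]), g0.reshape(-1),
                        t_eval=times, method=solver.method,
                        rtol=solver.rtol, atol=solver.atol)
        if not sol.success:
            t_fail = sol.t[-1] if sol.t.size else times[0]
            raise NumericalError(
                f"trajectory prediction failed near t={t_fail:.4g}: {sol.message}"
            )
        values = sol.y.T.reshape(times.size, B, n).transpose(1, 0, 2)
    values[:, 0, :] = g0
    return TrajectorySet(params.gene_ids, times, values)


def save_checkpoint(params: ModelParameters, path, metadata: dict | None = None) -> None:
    """Write parameters plus metadata to a single .npz file; array
    round-trips are bit-exact."""
    meta = dict(metadata or {})
    meta.setdefault("m", params.m)
    np.savez(
        path,
        W_sums=params.W_sums, b_sums=params.b_sums,
        W_prods=params.W_prods, b_prods=params.b_prods,
        W_combine=params.W_combine, upsilon=params.upsilon,
        gene_ids=np.array(params.gene_ids, dtype=object),
        metadata=np.array(json.dumps(meta)),
    )


def load_checkpoint(path) -> tuple[ModelParameters, dict]:
    with np.load(path, allow_pickle=True) as z:
        params = ModelParameters(
            gene_ids=tuple(z["gene_ids"].tolist()),
            W_sums=z["W_sums"], b_sums=z["b_sums"],
            W_prods=z["W_prods"], b_prods=z["b_prods"],
            W_combine=z["W_combine"], upsilon=z["upsilon"],
        )
        meta = json.loads(str(z["metadata"]))
    return params, meta
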