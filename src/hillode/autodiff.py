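"""Reverse-mode differentiation of the learned vector field.

The training loop needs d(loss)/d(theta) through an ODE solve.  The field
is a small fixed composition of affine maps, shifted-softsign activations
and one exponential, so its vector-Jacobian product (VJP) is written out
by hand, and trajectories are differentiated discretize-then-optimize:
the forward solve is a fixed-step classical Runge-Kutta (RK4) scheme and
the backward pass applies the chain rule through every stage of every
step.  Gradients are therefore exact (to machine precision) for the loss
actually minimized, which is what makes them match finite differences in
the gradient-check contract.

All functions accept batched states ``g`` of shape (B, n); parameter
gradients are summed over the batch.
"""

from __future__ import annotations

import numpy as np

from .model import (
    PREEXP_CLAMP,
    ModelParameters,
    phi_prod,
    phi_prod_deriv,
    phi_sum,
    phi_sum_deriv,
)

__all__ = ["zero_grads", "vjp_field", "rk4_solve", "rk4_with_tape", "rk4_backward"]

_PARAM_NAMES = ("W_sums", "b_sums", "W_prods", "b_prods", "W_combine", "upsilon")


def zero_grads(params: ModelParameters) -> dict[str, np.ndarray]:
    return {name: np.zeros_like(getattr(params, name)) for name in _PARAM_NAMES}


def _field(g: np.ndarray, params: ModelParameters):
    """Forward evaluation returning the derivative plus the intermediates
    needed by the VJP."""
    ps = phi_sum(g)
    pp = phi_prod(g)
    c_sum = ps @ params.W_sums.T + params.b_sums
    z = pp @ params.W_prods.T + params.b_prods
    inside = np.abs(z) <= PREEXP_CLAMP
    c_prod = np.exp(np.clip(z, -PREEXP_CLAMP, PREEXP_CLAMP))
    u = np.maximum(params.upsilon, 0.0)
    comb = c_sum @ params.U_sums.T + c_prod @ params.U_prods.T
    f = u * (comb - g)
    return f, (ps, pp, c_sum, c_prod, inside, u, comb)


def field(g: np.ndarray, params: ModelParameters) -> np.ndarray:
    return _field(g, params)[0]


def vjp_field(
    g: np.ndarray,
    params: ModelParameters,
    adj: np.ndarray,
    grads: dict[str, np.ndarray],
) -> np.ndarray:
    """Accumulate adj^T @ d(field)/d(theta) into ``grads`` and return
    adj^T @ d(field)/d(g)."""
    _, (ps, pp, c_sum, c_prod, inside, u, comb) = _field(g, params)
    m = params.m
    grads["upsilon"] += np.sum(adj * (comb - g) * (params.upsilon > 0), axis=0)
    w = adj * u                                   # (B, n)
    grads["W_combine"][:, :m] += w.T @ c_sum
    grads["W_combine"][:, m:] += w.T @ c_prod
    bar_c_sum = w @ params.U_sums                 # (B, m)
    bar_z = (w @ params.U_prods) * c_prod * inside
    grads["b_sums"] += bar_c_sum.sum(axis=0)
    grads["W_sums"] += bar_c_sum.T @ ps
    grads["b_prods"] += bar_z.sum(axis=0)
    grads["W_prods"] += bar_z.T @ pp
    bar_ps = bar_c_sum @ params.W_sums
    bar_pp = bar_z @ params.W_prods
    return bar_ps * phi_sum_deriv(g) + bar_pp * phi_prod_deriv(g) - w


def _segment_steps(t0: float, t1: float, h_max: float) -> tuple[int, float]:
    n_steps = max(1, int(np.ceil((t1 - t0) / h_max - 1e-12)))
    return n_steps, (t1 - t0) / n_steps


def rk4_solve(g0: np.ndarray, times, params: ModelParameters, h_max: float) -> np.ndarray:
    """Fixed-step RK4 integration over ``times``; returns (B, T, n)."""
    times = np.asarray(times, dtype=float)
    g = np.array(g0, dtype=float)
    out = np.empty((g.shape[0], times.size, g.shape[1]))
    out[:, 0] = g
    for k in range(times.size - 1):
        n_steps, h = _segment_steps(times[k], times[k + 1], h_max)
        for _ in range(n_steps):
            g = _rk4_step(g, h, params)
        out[:, k + 1] = g
    return out


def _rk4_step(g: np.ndarray, h: float, params: ModelParameters) -> np.ndarray:
    k1 = field(g, params)
    k2 = field(g + 0.5 * h * k1, params)
    k3 = field(g + 0.5 * h * k2, params)
    k4 = field(g + h * k3, params)
    return g + (h / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)


def rk4_with_tape(
    g0: np.ndarray, t0: float, t1: float, params: ModelParameters, h_max: float
):
    """Integrate t0 -> t1 recording the entry state of every RK4 step.

    Only step entries are stored; the backward pass re-runs the cheap
    stage computations.  Returns (g1, tape) with tape a list of (h, g).
    """
    n_steps, h = _segment_steps(t0, t1, h_max)
    g = np.array(g0, dtype=float)
    tape: list[tuple[float, np.ndarray]] = []
    for _ in range(n_steps):
        tape.append((h, g))
        g = _rk4_step(g, h, params)
    return g, tape


def rk4_backward(
    tape,
    params: ModelParameters,
    bar_g1: np.ndarray,
    grads: dict[str, np.ndarray] | None = None,
):
    """Chain-rule the adjoint back through a taped RK4 solve.

    Returns (bar_g0, grads); ``grads`` accumulates in place if given.
    """
    if grads is None:
        grads = zero_grads(params)
    a = np.array(bar_g1, dtype=float)
    for h, g in reversed(tape):
        k1 = field(g, params)
        k2 = field(g + 0.5 * h * k1, params)
        k3 = field(g + 0.5 * h * k2, params)
        # reverse sweep over the four stages
        bar_k1 = (h / 6.0) * a
        bar_k2 = (h / 3.0) * a
        bar_k3 = (h / 3.0) * a
        bar_k4 = (h / 6.0) * a
        bar_g = a.copy()

        bar_x4 = vjp_field(g + h * k3, params, bar_k4, grads)
        bar_g += bar_x4
        bar_k3 = bar_k3 + h * bar_x4

        bar_x3 = vjp_field(g + 0.5 * h * k2, params, bar_k3, grads)
        bar_g += bar_x3
        bar_k2 = bar_k2 + 0.5 * h * bar_x3

        bar_x2 = vjp_field(g + 0.5 * h * k1, params, bar_k2, grads)
        bar_g += bar_x2
        bar_k1 = bar_k1 + 0.5 * h * bar_x2

        bar_g += vjp_field(g, params, bar_k1, grads)
        a = bar_g
    return a, grads
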