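"""Fitting the neural-ODE parameters to expression trajectories.

The objective blends two terms with a mixing weight ``lambda`` in [0, 1]
(``lambda_prior = 1 - lambda``)::

    L_mod = lambda * L2[ g(t1), solve(g(t0)) ]                (data term)
          + (1 - lambda) * (1/K) sum_k L2[ P*(gamma_k), f(gamma_k) ]

The data term matches observed transitions through the ODE solve; the
prior term evaluates the learned field ``f`` directly (no solve) on K
uniformly drawn "ghost" expression vectors and penalizes its distance to
the linear prior field ``P*(gamma) = (A - I) gamma``.  ``lambda = 1``
recovers the unregularized model.

Training units are transition pairs — consecutive observed expression
vectors — batched over trajectories; whole-trajectory rollout training is
available as a config option.  Optimization is Adam with plateau decay,
with gradients from the hand-derived RK4 backward pass, early stopping on
validation MSE, and the mixing weight tuned on a validation split by grid
search.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from . import autodiff
from .errors import ArgumentError, TrainingError
from .model import (
    ExpressionState,
    ModelParameters,
    SolverSettings,
    default_hidden_width,
    derivative,
    init_parameters,
)
from .prior import GhostBatch, PriorAdjacency, prior_predict, sample_ghosts
from .trajectories import TrajectorySet

__all__ = ["TrainingConfig", "TransitionPair", "FitResult", "transition_pairs",
           "data_loss", "prior_matching_loss", "loss_mod", "train",
           "tune_lambda", "trajectory_metrics"]

log = logging.getLogger(__name__)

DEFAULT_LAMBDA_GRID = (1.0, 0.97, 0.95, 0.9, 0.8, 0.5)


@dataclass(frozen=True)
class TrainingConfig:
    """Hyperparameters for one training run.

    ``lambda_data`` is the data-term weight (prior weight is its
    complement); ``K`` is the ghost batch size drawn afresh at every
    optimization step; ``lambda_grid`` lists the candidates searched by
    :func:`tune_lambda`.
    """

    lambda_data: float = 1.0
    K: int = 64
    epochs: int = 300
    learning_rate: float = 5e-3
    seed: int = 0
    solver: SolverSettings = field(default_factory=lambda: SolverSettings(
        method="rk4", rk4_step=0.5))
    early_stop_patience: int = 20
    lambda_grid: tuple[float, ...] = DEFAULT_LAMBDA_GRID
    hidden_width: int | None = None
    rollout: bool = False
    batch_size: int | None = 20
    prior_warmup_epochs: int = 100
    lr_decay_every: int = 250
    lr_decay_factor: float = 0.5
    min_learning_rate: float = 2e-4

    def __post_init__(self) -> None:
        if not (0.0 <= self.lambda_data <= 1.0):
            raise ArgumentError("lambda_data must lie in [0, 1]")
        if self.epochs < 1 or self.K < 1:
            raise ArgumentError("epochs and K must be >= 1")


@dataclass(frozen=True)
class TransitionPair:
    """Two consecutive observed expression vectors (one training unit)."""

    start: ExpressionState
    end: ExpressionState

    def __post_init__(self) -> None:
        if self.start.gene_ids != self.end.gene_ids:
            raise ArgumentError("transition pair mixes gene orders")
        if self.end.t <= self.start.t:
            raise ArgumentError("transition pair must advance in time")


@dataclass
class FitResult:
    """Trained parameters plus the optimization record."""

    params: ModelParameters
    loss_history: list[tuple[float, float, float]]   # (data, prior, total) per epoch
    chosen_lambda: float
    validation_mse: float | None
    test_metrics: dict | None = None
    lambda_candidates: list[tuple[float, float]] | None = None
    best_epoch: int | None = None


def transition_pairs(trajset: TrajectorySet) -> list[TransitionPair]:
    """All consecutive-time-point pairs of every trajectory."""
    pairs = []
    for b in range(trajset.n_traj):
        for k in range(trajset.times.size - 1):
            pairs.append(TransitionPair(
                ExpressionState(trajset.gene_ids, trajset.values[b, k], trajset.times[k]),
                ExpressionState(trajset.gene_ids, trajset.values[b, k + 1], trajset.times[k + 1]),
            ))
    return pairs


def data_loss(pair: TransitionPair, params: ModelParameters,
              solver: SolverSettings = SolverSettings(method="rk4")) -> float:
    """MSE over genes between the observed end state and the ODE-predicted
    end state of one transition pair."""
    g0 = np.atleast_2d(pair.start.g)
    if solver.method.lower() == "rk4":
        pred = autodiff.rk4_solve(g0, [pair.start.t, pair.end.t], params,
                                  solver.rk4_step)[:, -1]
    else:
        from .model import predict_trajectory
        pred = predict_trajectory(g0, [pair.start.t, pair.end.t], params,
                                  solver).values[:, -1]
    return float(np.mean((pred[0] - pair.end.g) ** 2))


def prior_matching_loss(ghosts: GhostBatch, prior: PriorAdjacency,
                        params: ModelParameters) -> float:
    """Mean over ghosts of the MSE between the prior field and the learned
    field; no ODE solve involved."""
    target = prior_predict(prior, ghosts.gamma)
    pred = derivative(ghosts.gamma, params)
    return float(np.mean((pred - target) ** 2))


def loss_mod(pairs, ghosts: GhostBatch, prior: PriorAdjacency,
             params: ModelParameters, lambda_data: float,
             solver: SolverSettings = SolverSettings(method="rk4")) -> float:
    """The blended objective; exactly linear in ``lambda_data``."""
    if not (0.0 <= lambda_data <= 1.0):
        raise ArgumentError("lambda_data must lie in [0, 1]")
    dl = float(np.mean([data_loss(p, params, solver) for p in pairs])) if pairs else 0.0
    pl = prior_matching_loss(ghosts, prior, params)
    return lambda_data * dl + (1.0 - lambda_data) * pl


# ---------------------------------------------------------------------------
# internal batched machinery

def _pair_groups(trajset: TrajectorySet, rollout: bool):
    """Training units: (times_subgrid, values (B, T_sub, n))."""
    if rollout:
        return [(trajset.times, trajset.values)]
    return [
        (trajset.times[k : k + 2], trajset.values[:, k : k + 2, :])
        for k in range(trajset.times.size - 1)
    ]


def _unit_loss_and_grads(times, obs, params, h_max):
    """Rollout data loss and parameter gradients for one training unit.

    Forward solves segment by segment with tapes; the loss averages the
    squared error at every observed time > times[0]; the backward sweep
    carries the adjoint through all segments.
    """
    B, T, n = obs.shape
    g = obs[:, 0, :]
    tapes = []
    preds = [g]
    for k in range(T - 1):
        g, tape = autodiff.rk4_with_tape(g, times[k], times[k + 1], params, h_max)
        tapes.append(tape)
        preds.append(g)
    denom = B * (T - 1) * n
    loss = sum(float(np.sum((preds[k] - obs[:, k, :]) ** 2)) for k in range(1, T)) / denom
    grads = autodiff.zero_grads(params)
    adj = np.zeros_like(g)
    for k in range(T - 1, 0, -1):
        adj = adj + 2.0 * (preds[k] - obs[:, k, :]) / denom
        adj, _ = autodiff.rk4_backward(tapes[k - 1], params, adj, grads)
    return loss, grads


def _prior_loss_and_grads(gamma, prior_target, params):
    pred = autodiff.field(gamma, params)
    K, n = gamma.shape
    resid = pred - prior_target
    loss = float(np.mean(resid ** 2))
    grads = autodiff.zero_grads(params)
    autodiff.vjp_field(gamma, params, 2.0 * resid / (K * n), grads)
    return loss, grads


def _pairwise_mse(trajset: TrajectorySet, params: ModelParameters, h_max: float) -> float:
    """Mean one-step-ahead transition MSE over a trajectory set."""
    total, count = 0.0, 0
    for k in range(trajset.times.size - 1):
        pred = autodiff.rk4_solve(trajset.values[:, k, :],
                                  trajset.times[k : k + 2], params, h_max)[:, -1]
        total += float(np.sum((pred - trajset.values[:, k + 1, :]) ** 2))
        count += pred.size
    return total / count


def _rollout_mse(trajset: TrajectorySet, params: ModelParameters, h_max: float) -> float:
    """Whole-trajectory MSE: predict from each trajectory's first state
    over the full time grid and compare at every later time point.

    This is the monitoring metric for early stopping and for the lambda
    grid search: unlike one-step-ahead error it probes the learned field
    away from the training manifold (validation trajectories start at
    fresh random states), where the prior constraint earns its keep.
    """
    pred = autodiff.rk4_solve(trajset.values[:, 0, :], trajset.times,
                              params, h_max)
    return float(np.mean((pred[:, 1:, :] - trajset.values[:, 1:, :]) ** 2))


class _Adam:
    def __init__(self, params: ModelParameters, lr: float):
        self.lr = lr
        self.t = 0
        self.m = autodiff.zero_grads(params)
        self.v = autodiff.zero_grads(params)
        self.beta1, self.beta2, self.eps = 0.9, 0.999, 1e-8

    def step(self, params: ModelParameters, grads) -> ModelParameters:
        self.t += 1
        new = {}
        for name, g in grads.items():
            self.m[name] = self.beta1 * self.m[name] + (1 - self.beta1) * g
            self.v[name] = self.beta2 * self.v[name] + (1 - self.beta2) * g * g
            mhat = self.m[name] / (1 - self.beta1 ** self.t)
            vhat = self.v[name] / (1 - self.beta2 ** self.t)
            new[name] = getattr(params, name) - self.lr * mhat / (np.sqrt(vhat) + self.eps)
        return params.with_arrays(**new)


def train(
    trajectories: TrajectorySet,
    prior: PriorAdjacency,
    config: TrainingConfig,
    validation: TrajectorySet | None = None,
) -> FitResult:
    """Gradient-based minimization of the blended objective.

    Deterministic for a fixed config seed.  When ``lambda_data < 1`` the
    run opens with ``prior_warmup_epochs`` cheap prior-only steps that
    align the field with the prior before any ODE solving.  If a
    validation set is given, the monitoring metric is whole-trajectory
    rollout MSE on it (see :func:`_rollout_mse`); the returned parameters
    are the best-validation snapshot and training stops early after
    ``early_stop_patience`` epochs without improvement.
    """
    if trajectories.n_traj < 1 or trajectories.times.size < 2:
        raise ArgumentError("need at least one trajectory with two time points")
    if tuple(trajectories.gene_ids) != tuple(prior.gene_ids):
        raise ArgumentError("trajectories and prior use different gene orders")
    lam = config.lambda_data
    n = trajectories.n_genes
    m = config.hidden_width or default_hidden_width(n)
    params = init_parameters(trajectories.gene_ids, m=m, seed=config.seed)
    opt = _Adam(params, config.learning_rate)
    rng = np.random.default_rng(config.seed + 1)
    units = _pair_groups(trajectories, config.rollout)
    h_max = config.solver.rk4_step
    prior_mat = prior.A - np.eye(n)

    history: list[tuple[float, float, float]] = []
    best_mse = np.inf
    best_params = params
    best_epoch = 0
    stale = 0

    # prior-only warm start: cheap (no ODE solves) alignment of the field
    # with the prior before the mixed objective takes over; each warm-up
    # epoch takes as many optimizer steps as a regular training epoch
    if lam < 1.0 and config.prior_warmup_epochs > 0:
        per_epoch = len(units)
        if config.batch_size:
            per_epoch *= -(-trajectories.n_traj // config.batch_size)
        for wstep in range(config.prior_warmup_epochs * per_epoch):
            gseed = int((config.seed * 999_983 + wstep) % (2**31))
            gamma = sample_ghosts(max(config.K, 64), n, gseed).gamma
            _, pgrads = _prior_loss_and_grads(gamma, gamma @ prior_mat.T, params)
            params = opt.step(params, pgrads)

    for epoch in range(config.epochs):
        # schedule: each unit split into trajectory minibatches, shuffled
        sched = []
        for idx in rng.permutation(len(units)):
            times, obs = units[idx]
            if config.batch_size and obs.shape[0] > config.batch_size:
                perm = rng.permutation(obs.shape[0])
                sched.extend(
                    (times, obs[perm[k: k + config.batch_size]])
                    for k in range(0, obs.shape[0], config.batch_size)
                )
            else:
                sched.append((times, obs))
        data_losses, prior_losses = [], []
        for step, (times, obs) in enumerate(sched):
            total_grads = autodiff.zero_grads(params)
            dl = 0.0
            if lam > 0.0:
                dl, dgrads = _unit_loss_and_grads(times, obs, params, h_max)
                for name in total_grads:
                    total_grads[name] += lam * dgrads[name]
            pl = 0.0
            if lam < 1.0:
                gseed = int((config.seed * 1_000_003 + epoch * 613 + step) % (2**31))
                gamma = sample_ghosts(config.K, n, gseed).gamma
                pl, pgrads = _prior_loss_and_grads(gamma, gamma @ prior_mat.T, params)
                for name in total_grads:
                    total_grads[name] += (1.0 - lam) * pgrads[name]
            if not np.isfinite(dl) or not np.isfinite(pl):
                raise TrainingError(f"non-finite loss at epoch {epoch}")
            data_losses.append(dl)
            prior_losses.append(pl)
            params = opt.step(params, total_grads)
        d_mean = float(np.mean(data_losses))
        p_mean = float(np.mean(prior_losses))
        history.append((d_mean, p_mean, lam * d_mean + (1 - lam) * p_mean))

        monitor = (_rollout_mse(validation, params, h_max)
                   if validation is not None and validation.n_traj > 0
                   else history[-1][2])
        if not np.isfinite(monitor):
            raise TrainingError(f"non-finite validation loss at epoch {epoch}")
        if (epoch + 1) % config.lr_decay_every == 0:
            opt.lr = max(opt.lr * config.lr_decay_factor, config.min_learning_rate)
            log.debug("epoch %d: learning rate decayed to %.2g", epoch, opt.lr)
        if monitor < best_mse - 1e-12:
            best_mse, best_params, best_epoch = monitor, params, epoch
            stale = 0
        else:
            stale += 1
            if validation is not None and stale >= config.early_stop_patience:
                log.info("early stop at epoch %d (best %d)", epoch, best_epoch)
                break

    val_mse = float(best_mse) if validation is not None else None
    final = best_params if validation is not None else params
    return FitResult(
        params=final,
        loss_history=history,
        chosen_lambda=lam,
        validation_mse=val_mse,
        best_epoch=best_epoch,
    )


def tune_lambda(
    trajectories: TrajectorySet,
    prior: PriorAdjacency,
    config: TrainingConfig,
    validation: TrajectorySet,
) -> FitResult:
    """Train one model per candidate mixing weight and keep the best.

    Selection is by validation MSE; exact ties go to the smaller
    ``lambda`` (the more strongly prior-constrained model).
    """
    if not config.lambda_grid:
        raise ArgumentError("lambda_grid must be nonempty")
    if validation is None or validation.n_traj == 0:
        raise ArgumentError("tune_lambda requires a nonempty validation set")
    candidates: list[tuple[float, float]] = []
    best: FitResult | None = None
    for lam in config.lambda_grid:
        cfg = TrainingConfig(**{**config.__dict__, "lambda_data": float(lam)})
        fit = train(trajectories, prior, cfg, validation)
        candidates.append((float(lam), fit.validation_mse))
        log.info("lambda=%.3g -> validation MSE %.4g", lam, fit.validation_mse)
        if (best is None or fit.validation_mse < best.validation_mse
                or (fit.validation_mse == best.validation_mse
                    and lam < best.chosen_lambda)):
            best = fit
    best.lambda_candidates = candidates
    return best


def trajectory_metrics(observed: TrajectorySet, predicted: TrajectorySet) -> dict:
    """MSE and squared Pearson correlation between aligned trajectory sets.

    Both metrics are computed over all (trajectory, time > first, gene)
    entries; the first time point is excluded because predictions start
    from the observed state there.
    """
    if observed.values.shape != predicted.values.shape:
        raise ArgumentError("observed and predicted shapes differ")
    obs = observed.values[:, 1:, :].ravel()
    pred = predicted.values[:, 1:, :].ravel()
    mse = float(np.mean((obs - pred) ** 2))
    if np.std(obs) == 0 or np.std(pred) == 0:
        warnings.warn("zero variance in flattened values; r2 undefined")
        return {"mse": mse, "r2": None}
    rho = float(np.corrcoef(obs, pred)[0, 1])
    return {"mse": mse, "r2": rho ** 2}
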