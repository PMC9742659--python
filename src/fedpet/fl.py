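"""Four training strategies over conformable parameter vectors.

* CB (center-based): train on one center's data only.
* CZ (centralized): pool all centers' data on one server and train.
* FL-PL (parallel federated): each round, broadcast the global theta, train
  locally at every center, then aggregate — either a weighted gradient step

      theta_{t+1} = theta_t - eta * sum_k (N_k / N) grad F_k(theta_t)

  (``aggregation_mode='gradient'``, which demands one full-batch local pass so
  the update is exactly the pooled gradient step), or FedAvg-style weighted
  parameter averaging of the locally trained models
  (``aggregation_mode='parameter_average'``).
* FL-SQ (sequential federated): the model visits centers serially, training a
  fixed number of local epochs at each, for several rounds; no aggregation.

Only theta crosses center boundaries.  Optimizer state (Adam moments) lives
at each center and persists across rounds; it is never exchanged.  Every run
is a pure function of (datasets, config, seed): mini-batch shuffling derives
from (seed, global epoch counter), so degenerate setups (one center;
identical data everywhere) reproduce the centralized trajectory exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .nn import ParameterVector, make_optimizer
from collections import OrderedDict

__all__ = [
    "LocalDataset",
    "StrategyConfig",
    "LocalUpdate",
    "TrainState",
    "LinearModel",
    "local_update",
    "aggregate",
    "run_fl_parallel",
    "run_fl_sequential",
    "run_centralized",
    "run_center_based",
    "pool_datasets",
]

STRATEGIES = ("CB", "CZ", "FL_PL", "FL_SQ")


@dataclass
class LocalDataset:
    """One silo's training samples: X are NAC inputs, Y the ASC targets."""

    center_id: str
    X: np.ndarray
    Y: np.ndarray

    def __post_init__(self):
        if len(self.X) != len(self.Y) or len(self.X) == 0:
            raise ValueError(f"center {self.center_id!r}: empty or mismatched dataset")

    @property
    def N_k(self) -> int:
        return len(self.X)


@dataclass(frozen=True)
class StrategyConfig:
    """Schedule and optimizer recipe for one training strategy.

    CB/CZ ignore ``rounds`` (they train ``local_epochs`` epochs total);
    FL_SQ ignores ``aggregation_mode``.  Defaults follow the common recipe:
    Adam, learning rate 0.001, weight decay 0.0001, L2 loss.
    """

    strategy: str
    rounds: int = 1
    local_epochs: int = 1
    batch_size: int = 8
    optimizer: str = "adam"
    learning_rate: float = 0.001
    weight_decay: float = 0.0001
    center_order: str = "fixed"  # or "shuffled"
    aggregation_mode: str = "parameter_average"  # or "gradient"
    reset_optimizer: bool = False  # fresh local optimizer state every round

    def __post_init__(self):
        if self.strategy not in STRATEGIES:
            raise ValueError(f"strategy must be one of {STRATEGIES}")
        if self.rounds < 1 or self.local_epochs < 1 or self.batch_size < 1:
            raise ValueError("rounds, local_epochs and batch_size must be >= 1")
        if self.aggregation_mode not in ("gradient", "parameter_average"):
            raise ValueError("aggregation_mode must be 'gradient' or 'parameter_average'")
        if self.center_order not in ("fixed", "shuffled"):
            raise ValueError("center_order must be 'fixed' or 'shuffled'")


@dataclass
class LocalUpdate:
    center_id: str
    N_k: int
    kind: str  # "gradient" or "parameters"
    payload: np.ndarray  # flat vector, conformable with global theta
    local_loss_history: list = field(default_factory=list)


@dataclass
class TrainState:
    """Outcome of a training run plus its audit trail."""

    theta: np.ndarray
    t: int
    global_loss_history: list = field(default_factory=list)
    per_center_histories: dict = field(default_factory=dict)
    val_history: list = field(default_factory=list)
    best_theta: np.ndarray = None
    best_index: int = -1
    rng_seed: int = 0


class LinearModel:
    """Least-squares linear map y = X @ W — the convex toy model.

    Implements the same protocol as the image network (flat parameter
    vectors, mean-over-samples squared loss), so every strategy runs on it
    unchanged and gradients have a closed form for oracle tests.
    """

    def __init__(self, d_in: int, d_out: int = 1):
        self.d_in, self.d_out = d_in, d_out
        self.template = ParameterVector(
            OrderedDict([("W", np.zeros((d_in, d_out), dtype=float))])
        )

    @property
    def n_params(self):
        return self.d_in * self.d_out

    def init_params(self, seed: int) -> ParameterVector:
        rng = np.random.default_rng(seed)
        return ParameterVector(
            OrderedDict([("W", rng.normal(0, 0.1, (self.d_in, self.d_out)))])
        )

    def _W(self, theta):
        if isinstance(theta, ParameterVector):
            return theta["W"]
        return np.asarray(theta).reshape(self.d_in, self.d_out)

    def loss(self, theta, X, Y) -> float:
        r = X @ self._W(theta) - Y
        return float((r * r).sum() / len(X))

    def loss_and_grad(self, theta, X, Y):
        W = self._W(theta)
        r = X @ W - Y
        loss = float((r * r).sum() / len(X))
        grad = (2.0 / len(X)) * X.T @ r
        return loss, grad.ravel()

    def predict(self, theta, X):
        return X @ self._W(theta)


def _epoch_rng(seed: int, counter: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(counter,)))


def _flat(theta) -> np.ndarray:
    return theta.to_flat() if isinstance(theta, ParameterVector) else np.asarray(theta, dtype=float)


def _full_gradient(model, theta: np.ndarray, X, Y, chunk: int):
    """Exact full-batch loss/gradient, computed in chunks, weighted by size."""
    n = len(X)
    loss, grad = 0.0, np.zeros_like(theta)
    for lo in range(0, n, chunk):
        hi = min(lo + chunk, n)
        l, g = model.loss_and_grad(theta, X[lo:hi], Y[lo:hi])
        w = (hi - lo) / n
        loss += w * l
        grad += w * g
    return loss, grad


def local_update(
    model,
    theta_t,
    dataset: LocalDataset,
    cfg: StrategyConfig,
    seed: int,
    epoch_offset: int = 0,
    optimizer=None,
):
    """One center's contribution starting from the broadcast ``theta_t``.

    Gradient mode returns the exact local gradient of
    F_k(theta) = (1/N_k) sum_i L(theta; (X_i, Y_i)) (plus the weight-decay
    term) and requires local_epochs == 1 with no mini-batching, so the
    server-side step is exactly the pooled-gradient update.  Parameter mode
    runs ``local_epochs`` epochs of seeded mini-batch optimization and
    returns the updated parameters.  Returns ``(LocalUpdate, optimizer)``;
    pass the optimizer back in to persist Adam moments across rounds.
    """
    theta = _flat(theta_t).copy()
    X, Y = dataset.X, dataset.Y
    if cfg.aggregation_mode == "gradient":
        if cfg.local_epochs != 1:
            raise ValueError(
                "gradient aggregation requires local_epochs=1, full batch: "
                "the exactness of the pooled-gradient update would not hold"
            )
        loss, grad = _full_gradient(model, theta, X, Y, cfg.batch_size)
        grad = grad + cfg.weight_decay * theta
        return (
            LocalUpdate(dataset.center_id, dataset.N_k, "gradient", grad, [loss]),
            optimizer,
        )

    if optimizer is None:
        optimizer = make_optimizer(cfg.optimizer, cfg.learning_rate)
    history = []
    n = dataset.N_k
    for e in range(cfg.local_epochs):
        rng = _epoch_rng(seed, epoch_offset + e)
        perm = rng.permutation(n)
        losses = []
        for lo in range(0, n, cfg.batch_size):
            idx = perm[lo : lo + cfg.batch_size]
            loss, grad = model.loss_and_grad(theta, X[idx], Y[idx])
            grad = grad + cfg.weight_decay * theta
            theta = optimizer.step(theta, grad)
            losses.append(loss)
        history.append(float(np.mean(losses)))
    return (
        LocalUpdate(dataset.center_id, dataset.N_k, "parameters", theta, history),
        optimizer,
    )


def aggregate(updates: list, theta_t, eta: float, mode: str = None) -> np.ndarray:
    """Server-side combination of local updates, weighted by N_k / N.

    Gradient mode: theta_t - eta * sum_k (N_k/N) g_k.
    Parameter-average mode: sum_k (N_k/N) theta_k (FedAvg); with single
    full-batch SGD local steps this reduces to the gradient update.
    """
    if not updates:
        raise ValueError("no updates to aggregate")
    theta_t = _flat(theta_t)
    N = sum(u.N_k for u in updates)
    if N <= 0:
        raise ValueError("total sample count must be positive")
    kinds = {u.kind for u in updates}
    if len(kinds) > 1:
        raise ValueError("cannot mix gradient and parameter updates")
    if mode is None:
        mode = "gradient" if kinds == {"gradient"} else "parameter_average"
    weights = np.array([u.N_k / N for u in updates])
    assert abs(weights.sum() - 1.0) < 1e-12, "center weights must sum to 1"
    for u in updates:
        if u.payload.shape != theta_t.shape:
            raise ValueError(f"update from {u.center_id!r} not conformable with theta")
    combined = sum(w * u.payload for w, u in zip(weights, updates))
    if mode == "gradient":
        return theta_t - eta * combined
    return combined


def _val_loss(model, theta, val, chunk: int) -> float:
    Xv, Yv = val
    n = len(Xv)
    total = 0.0
    for lo in range(0, n, chunk):
        hi = min(lo + chunk, n)
        total += (hi - lo) / n * model.loss(theta, Xv[lo:hi], Yv[lo:hi])
    return total


def _finalize(state: TrainState, model, val, chunk):
    if val is None or not state.val_history:
        state.best_theta = state.theta
        state.best_index = state.t - 1
    return state


def _track_val(state: TrainState, model, val, chunk):
    if val is None:
        return
    v = _val_loss(model, state.theta, val, chunk)
    state.val_history.append(v)
    if state.best_theta is None or v <= min(state.val_history[:-1], default=np.inf):
        state.best_theta = state.theta.copy()
        state.best_index = state.t


def run_fl_parallel(centers: list, model, cfg: StrategyConfig, seed: int, val=None) -> TrainState:
    """FedAvg-style rounds: broadcast, local training everywhere, aggregate."""
    _check_centers(centers, minimum=1)
    theta = model.init_params(seed).to_flat()
    state = TrainState(theta=theta, t=0, rng_seed=seed)
    opts = {c.center_id: None for c in centers}
    for r in range(cfg.rounds):
        updates = []
        for ds in centers:
            up, opts[ds.center_id] = local_update(
                model, theta, ds, cfg, seed,
                epoch_offset=r * cfg.local_epochs,
                optimizer=None if cfg.reset_optimizer else opts[ds.center_id],
            )
            updates.append(up)
            state.per_center_histories.setdefault(ds.center_id, []).extend(
                up.local_loss_history
            )
        theta = aggregate(updates, theta, cfg.learning_rate, cfg.aggregation_mode)
        N = sum(u.N_k for u in updates)
        state.global_loss_history.append(
            float(sum(u.N_k / N * u.local_loss_history[-1] for u in updates))
        )
        state.theta = theta
        state.t = r + 1
        _track_val(state, model, val, cfg.batch_size)
    return _finalize(state, model, val, cfg.batch_size)


def run_fl_sequential(centers: list, model, cfg: StrategyConfig, seed: int, val=None) -> TrainState:
    """The model visits centers serially, passing theta center-to-center."""
    _check_centers(centers, minimum=1)
    theta = model.init_params(seed).to_flat()
    state = TrainState(theta=theta, t=0, rng_seed=seed)
    opts = {c.center_id: None for c in centers}
    counter = 0
    order_rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(0xC0,)))
    for r in range(cfg.rounds):
        order = list(range(len(centers)))
        if cfg.center_order == "shuffled":
            order_rng.shuffle(order)
        for k in order:
            ds = centers[k]
            cfg_local = replace(cfg, aggregation_mode="parameter_average")
            up, opts[ds.center_id] = local_update(
                model, theta, ds, cfg_local, seed,
                epoch_offset=counter, optimizer=opts[ds.center_id],
            )
            counter += cfg.local_epochs
            theta = up.payload
            state.per_center_histories.setdefault(ds.center_id, []).extend(
                up.local_loss_history
            )
        state.global_loss_history.append(
            float(np.mean([state.per_center_histories[c.center_id][-1] for c in centers]))
        )
        state.theta = theta
        state.t = r + 1
        _track_val(state, model, val, cfg.batch_size)
    return _finalize(state, model, val, cfg.batch_size)


def pool_datasets(centers: list, pooled_id: str = "pooled") -> LocalDataset:
    """Concatenate silos in registration order (the CZ server's view)."""
    _check_centers(centers, minimum=1)
    X = np.concatenate([c.X for c in centers])
    Y = np.concatenate([c.Y for c in centers])
    return LocalDataset(pooled_id, X, Y)


def run_centralized(centers: list, model, cfg: StrategyConfig, seed: int, val=None) -> TrainState:
    """Pool all data on one server and train for ``local_epochs`` epochs."""
    pooled = pool_datasets(centers)
    return _run_single(pooled, model, cfg, seed, val)


def run_center_based(center: LocalDataset, model, cfg: StrategyConfig, seed: int, val=None) -> TrainState:
    """Train on a single silo only (the no-collaboration baseline)."""
    return _run_single(center, model, cfg, seed, val)


def _run_single(dataset: LocalDataset, model, cfg: StrategyConfig, seed: int, val=None) -> TrainState:
    theta = model.init_params(seed).to_flat()
    state = TrainState(theta=theta, t=0, rng_seed=seed)
    cfg_local = replace(cfg, aggregation_mode="parameter_average", local_epochs=1)
    opt = None
    for e in range(cfg.local_epochs):
        up, opt = local_update(
            model, theta, dataset, cfg_local, seed, epoch_offset=e, optimizer=opt
        )
        theta = up.payload
        state.global_loss_history.extend(up.local_loss_history)
        state.per_center_histories.setdefault(dataset.center_id, []).extend(
            up.local_loss_history
        )
        state.theta = theta
        state.t = e + 1
        _track_val(state, model, val, cfg.batch_size)
    return _finalize(state, model, val, cfg.batch_size)


def _check_centers(centers, minimum=1):
    if len(centers) < minimum:
        raise ValueError(f"need at least {minimum} center(s)")
    ids = [c.center_id for c in centers]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate center ids")
    for c in centers:
        if c.N_k == 0:
            raise ValueError(f"center {c.center_id!r} has no data")
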