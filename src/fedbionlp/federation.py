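"""Federated training engine: FedAvg, FedProx, and the comparison regimes.

The simulation follows the canonical weight-averaging loop: each round the
server broadcasts the global parameters, every client runs ``local_epochs``
epochs of mini-batch updates on its own data (optionally with the FedProx
proximal penalty ``(mu/2) * ||w - w_global||^2``), and the server aggregates
the returned parameter sets with weights ``p_i = n_i / sum_j n_j``.  With one
client and no aggregation this degenerates exactly to centralized training,
which `run_centralized` and `run_single_client` reuse.

Everything is a pure function of the inputs and ``cfg.seed``: local shuffles
derive their seed from (cfg.seed, client position, round, epoch), and
optimizer state is reset at the start of every local update (only weights are
ever averaged).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

from .corpus_io import Corpus
from .models import ParamSet, gradient

__all__ = [
    "ClientState",
    "FedConfig",
    "RoundLog",
    "DivergenceError",
    "client_weights",
    "aggregate",
    "local_update",
    "run_federated",
    "run_centralized",
    "run_single_client",
    "round_logs_frame",
]


class DivergenceError(RuntimeError):
    """Raised when the training loss becomes non-finite."""


@dataclass(frozen=True)
class ClientState:
    """One federation participant: its id, local training corpus and weight."""

    client_id: str
    train: Corpus
    record_indices: tuple[int, ...] | None = None  # positions in the parent corpus

    def __post_init__(self) -> None:
        if len(self.train) < 1:
            raise ValueError(f"client {self.client_id!r} has an empty corpus")

    @property
    def n_k(self) -> int:
        return len(self.train)


@dataclass(frozen=True)
class FedConfig:
    """All federation hyperparameters.

    ``algorithm="fedavg"`` never touches the proximal term; with
    ``algorithm="fedprox"`` every local step adds ``mu * (w - w_global)`` to
    the gradient.  Setting ``mu=0`` under fedprox therefore reproduces fedavg
    bit for bit.
    """

    rounds: int = 10
    local_epochs: int = 1
    batch_size: int = 32
    learning_rate: float = 0.001
    optimizer: str = "adam"  # "sgd" | "adam"
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    adam_eps: float = 1e-8
    algorithm: str = "fedavg"  # "fedavg" | "fedprox"
    mu: float = 0.0
    scheduler: str = "linear_warmup"  # "linear_warmup" | "none"
    warmup_fraction: float = 0.1
    seed: int = 0
    eval_every: int = 1

    def __post_init__(self) -> None:
        if self.rounds < 0 or self.local_epochs < 1 or self.batch_size < 1:
            raise ValueError("rounds >= 0, local_epochs >= 1, batch_size >= 1 required")
        if self.optimizer not in ("sgd", "adam"):
            raise ValueError(f"unknown optimizer {self.optimizer!r}")
        if self.algorithm not in ("fedavg", "fedprox"):
            raise ValueError(f"unknown algorithm {self.algorithm!r}")
        if self.mu < 0:
            raise ValueError("mu must be non-negative")
        if not 0.0 <= self.warmup_fraction < 1.0:
            raise ValueError("warmup_fraction must lie in [0, 1)")


@dataclass(frozen=True)
class RoundLog:
    round: int
    client_losses: dict[str, float]
    dev_metric: float | None
    global_norm: float


# ---------------------------------------------------------------------------
# Eq.-style client weighting and aggregation


def client_weights(counts: Sequence[int]) -> list[float]:
    """Sample-count weights ``p_i = n_i / sum_j n_j`` (all positive, sum 1)."""
    if not counts:
        raise ValueError("no clients")
    if any(c <= 0 for c in counts):
        raise ValueError("all client sample counts must be positive")
    total = float(sum(counts))
    return [c / total for c in counts]


def aggregate(client_params: Sequence[ParamSet], weights: Sequence[float]) -> ParamSet:
    """Coordinate-wise convex combination ``sum_i p_i w_i`` of client models."""
    if len(client_params) != len(weights):
        raise ValueError("one weight per client ParamSet required")
    if abs(sum(weights) - 1.0) > 1e-12:
        raise ValueError(f"weights must sum to 1, got {sum(weights)!r}")
    out = weights[0] * client_params[0]
    for w, ps in zip(weights[1:], client_params[1:]):
        out = out + w * ps  # validates shape compatibility
    return out


# ---------------------------------------------------------------------------
# Optimizers (state is local to one local_update call, never communicated)


class _SGD:
    def __init__(self, cfg: FedConfig):
        pass

    def step(self, params: ParamSet, grad: ParamSet, lr: float) -> ParamSet:
        return params - lr * grad


class _Adam:
    def __init__(self, cfg: FedConfig):
        self.b1, self.b2, self.eps = cfg.adam_beta1, cfg.adam_beta2, cfg.adam_eps
        self.m: ParamSet | None = None
        self.v: ParamSet | None = None
        self.t = 0

    def step(self, params: ParamSet, grad: ParamSet, lr: float) -> ParamSet:
        if self.m is None:
            self.m = grad.zeros_like()
            self.v = grad.zeros_like()
        self.t += 1
        self.m = self.b1 * self.m + (1 - self.b1) * grad
        self.v = ParamSet(
            {k: self.b2 * self.v[k] + (1 - self.b2) * grad[k] ** 2 for k in grad}
        )
        mhat = 1.0 / (1 - self.b1**self.t) * self.m
        vhat = {k: self.v[k] / (1 - self.b2**self.t) for k in self.v}
        return ParamSet(
            {k: params[k] - lr * mhat[k] / (np.sqrt(vhat[k]) + self.eps) for k in params}
        )


_OPTIMIZERS = {"sgd": _SGD, "adam": _Adam}


def _lr_at(cfg: FedConfig, global_step: int, total_steps: int) -> float:
    """Linear warmup then linear decay to zero, or a constant rate."""
    if cfg.scheduler == "none":
        return cfg.learning_rate
    warm = max(1, int(round(cfg.warmup_fraction * total_steps)))
    if global_step < warm:
        return cfg.learning_rate * (global_step + 1) / warm
    frac = (total_steps - global_step) / max(1, total_steps - warm)
    return cfg.learning_rate * max(0.0, frac)


def _shuffle_rng(cfg: FedConfig, client_pos: int, round_t: int, epoch: int):
    return np.random.default_rng([cfg.seed, client_pos, round_t, epoch])


# ---------------------------------------------------------------------------
# Local update (one client, one round)


def local_update(
    model,
    global_params: ParamSet,
    client: ClientState,
    cfg: FedConfig,
    round_t: int,
    client_pos: int = 0,
) -> ParamSet:
    """Run ``local_epochs`` epochs of mini-batch updates from ``global_params``.

    Starts from a copy of the broadcast parameters, shuffles the client
    corpus each epoch with a deterministic seed, forms ``ceil(n_k / B)``
    batches, and applies one optimizer step per batch on the per-sample-mean
    task loss (plus the proximal gradient under fedprox).  ``global_params``
    is never modified.
    """
    model.set_params(global_params)
    reference = global_params if cfg.algorithm == "fedprox" else None
    opt = _OPTIMIZERS[cfg.optimizer](cfg)
    records = list(client.train)
    steps_per_epoch = math.ceil(len(records) / cfg.batch_size)
    total_steps = cfg.rounds * cfg.local_epochs * steps_per_epoch
    for epoch in range(cfg.local_epochs):
        rng = _shuffle_rng(cfg, client_pos, round_t, epoch)
        order = rng.permutation(len(records))
        for b in range(steps_per_epoch):
            idx = order[b * cfg.batch_size : (b + 1) * cfg.batch_size]
            batch = [records[i] for i in idx]
            loss, grad = model.loss_and_grad(batch)
            if not np.isfinite(loss):
                raise DivergenceError(
                    f"non-finite loss on client {client.client_id!r}, round {round_t}"
                )
            if reference is not None and cfg.mu != 0.0:
                grad = grad + cfg.mu * (model.params - reference)
            step_idx = (
                ((round_t - 1) * cfg.local_epochs + epoch) * steps_per_epoch + b
            )
            lr = _lr_at(cfg, step_idx, total_steps)
            model.set_params(opt.step(model.params, grad, lr))
    return model.params


def _mean_loss(model, corpus: Corpus) -> float:
    loss, _ = model.loss_and_grad(list(corpus))
    return loss


# ---------------------------------------------------------------------------
# Training regimes


def run_federated(
    clients: Sequence[ClientState],
    model_factory: Callable[[int], object],
    cfg: FedConfig,
    dev_corpus: Corpus | None = None,
    dev_metric: Callable[[object, Corpus], float] | None = None,
    param_history: list[ParamSet] | None = None,
) -> tuple[ParamSet, list[RoundLog]]:
    """Full-participation federated training over ``cfg.rounds`` rounds.

    ``model_factory(seed)`` must build the shared model (identical vocabulary
    and tag inventory across clients) with deterministically initialized
    parameters.  If ``param_history`` is passed, the aggregated ParamSet of
    every round is appended to it.
    """
    if not clients:
        raise ValueError("at least one client required")
    if len({c.client_id for c in clients}) != len(clients):
        raise ValueError("duplicate client_id")
    model = model_factory(cfg.seed)
    weights = client_weights([c.n_k for c in clients])
    w = model.params.copy()
    logs: list[RoundLog] = []
    for t in range(1, cfg.rounds + 1):
        updated, losses = [], {}
        for pos, client in enumerate(clients):
            updated.append(local_update(model, w, client, cfg, t, client_pos=pos))
            model.set_params(updated[-1])
            losses[client.client_id] = _mean_loss(model, client.train)
        w = aggregate(updated, weights)
        if param_history is not None:
            param_history.append(w.copy())
        metric = None
        if dev_corpus is not None and dev_metric is not None and t % cfg.eval_every == 0:
            model.set_params(w)
            metric = float(dev_metric(model, dev_corpus))
        logs.append(
            RoundLog(round=t, client_losses=losses, dev_metric=metric,
                     global_norm=float(np.sqrt(w.sq_norm())))
        )
    model.set_params(w)
    return w, logs


def run_centralized(
    pooled: Corpus,
    model_factory: Callable[[int], object],
    cfg: FedConfig,
    dev_corpus: Corpus | None = None,
    dev_metric: Callable[[object, Corpus], float] | None = None,
) -> tuple[ParamSet, list[RoundLog]]:
    """Train one model on all pooled data: the K=1 degeneracy of the loop."""
    client = ClientState(client_id="pooled", train=pooled)
    return run_federated(
        [client], model_factory, cfg, dev_corpus=dev_corpus, dev_metric=dev_metric
    )


def run_single_client(
    clients: Sequence[ClientState],
    model_factory: Callable[[int], object],
    cfg: FedConfig,
) -> list[tuple[str, ParamSet]]:
    """Independent per-client training with no communication."""
    if not clients:
        raise ValueError("at least one client required")
    out = []
    for client in clients:
        w, _ = run_centralized(client.train, model_factory, cfg)
        out.append((client.client_id, w))
    return out


# ---------------------------------------------------------------------------
# Log export


def round_logs_frame(logs: Sequence[RoundLog]):
    """Tidy (round, client, loss, dev_metric, global_norm) table."""
    import pandas as pd

    rows = []
    for log in logs:
        for cid, loss in log.client_losses.items():
            rows.append(
                {
                    "round": log.round,
                    "client": cid,
                    "loss": loss,
                    "dev_metric": log.dev_metric,
                    "global_norm": log.global_norm,
                }
            )
    return pd.DataFrame(rows)
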