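"""The multi-site split learning engine.

One training round:

1. every end-system draws a local mini-batch from its own partition slice and
   runs it through its single hidden layer (:func:`client_forward`);
2. the resulting feature maps — the only client-to-server messages — cross
   the message boundary and are concatenated along the sample axis in
   ascending client order (:func:`concatenate_feature_maps`);
3. the server runs the remaining layers on the joined batch, computes the
   joint loss, updates its own parameters, and returns to each client the
   loss gradient with respect to that client's transmitted activations
   (:func:`server_step`);
4. each client backpropagates its gradient slice through its hidden layer
   and updates its own parameters (:func:`client_backward`).

Clients are independent by default (no weight sharing between hospitals).
With ``sync_client_weights`` enabled the per-client hidden-layer gradients
are summed — which is exactly the pooled-batch gradient, since the joint
loss is a mean over the joined batch — and the identical summed gradient is
applied through every client's optimizer, after which the parameter-mean
synchronization of :func:`sync_client_weights` is a no-op.  A sync-mode run
from a shared initialization is therefore step-for-step identical to
training the monolithic network centrally on the pooled batches.

The protocol is simulated in-process; the message boundary is explicit via
:class:`MessageBus`, and :class:`AuditingBus` hashes every payload that
crosses it so tests can verify the server only ever sees feature maps,
labels, and gradient slices.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from math import ceil
from typing import Any

import numpy as np

from .evaluation import accuracy, rmsle
from .models import ModelSpec, SplitModel, build_split_model
from .nn import Adam, ParameterSet, ShapeError, Stack
from .partition import Partition, _largest_remainder, _repair_min_one

__all__ = [
    "EndSystemState",
    "FeatureMap",
    "GradientSlice",
    "TrainConfig",
    "TrainingHistory",
    "MessageBus",
    "AuditingBus",
    "TrainingAborted",
    "local_batch_sizes",
    "client_forward",
    "concatenate_feature_maps",
    "server_step",
    "client_backward",
    "sync_client_weights",
    "train",
]

logger = logging.getLogger(__name__)


class TrainingAborted(RuntimeError):
    """Raised on non-finite losses/activations; carries the partial history."""

    def __init__(self, message: str, history: "TrainingHistory | None" = None):
        super().__init__(message)
        self.history = history


@dataclass
class FeatureMap:
    """The sole client-to-server message for one local mini-batch."""

    client_id: int
    activations: np.ndarray  # [local_batch, *cut_shape]
    labels: np.ndarray  # [local_batch]
    batch_index: int

    def __post_init__(self) -> None:
        if self.activations.shape[0] < 1:
            raise ValueError("local batch must have at least one sample")
        if self.labels.shape[0] != self.activations.shape[0]:
            raise ShapeError("labels must align with activations")
        if not np.all(np.isfinite(self.activations)):
            raise FloatingPointError(
                f"non-finite activations from client {self.client_id} at batch {self.batch_index}"
            )


@dataclass
class GradientSlice:
    """Server-to-client message: d(loss)/d(transmitted activations)."""

    client_id: int
    grad: np.ndarray
    batch_index: int


@dataclass
class EndSystemState:
    """One participating hospital: its hidden layer and its data slice."""

    client_id: int  # 1-based
    stack: Stack
    params: ParameterSet
    optimizer: Adam
    local_indices: np.ndarray
    rng: np.random.Generator
    _last_caches: list | None = field(default=None, repr=False)
    _last_batch_index: int | None = field(default=None, repr=False)
    _last_shape: tuple | None = field(default=None, repr=False)


@dataclass
class ServerState:
    stack: Stack
    params: ParameterSet
    optimizer: Adam
    loss_name: str


class MessageBus:
    """Explicit message boundary between end-systems and server (identity)."""

    def send_features(self, fm: FeatureMap) -> FeatureMap:
        return fm

    def send_gradients(self, gs: GradientSlice) -> GradientSlice:
        return gs

    def on_server_receive(self, fm: FeatureMap) -> None:  # pragma: no cover - hook
        pass


class AuditingBus(MessageBus):
    """Hashes every payload crossing the boundary, for message-hygiene audits."""

    def __init__(self) -> None:
        self.sent_feature_hashes: set[str] = set()
        self.received_feature_hashes: set[str] = set()
        self.gradient_hashes: set[str] = set()

    @staticmethod
    def _digest(a: np.ndarray) -> str:
        return hashlib.sha256(np.ascontiguousarray(a).tobytes()).hexdigest()

    def send_features(self, fm: FeatureMap) -> FeatureMap:
        self.sent_feature_hashes.add(self._digest(fm.activations))
        return fm

    def on_server_receive(self, fm: FeatureMap) -> None:
        self.received_feature_hashes.add(self._digest(fm.activations))

    def send_gradients(self, gs: GradientSlice) -> GradientSlice:
        self.gradient_hashes.add(self._digest(gs.grad))
        return gs


# ---------------------------------------------------------------------------
# round operations


def local_batch_sizes(
    global_batch: int, partition: Partition, policy: str = "proportional"
) -> list[int]:
    """Per-client mini-batch sizes summing to the global batch size.

    ``proportional`` apportions by local dataset size (largest remainder,
    minimum one sample each); ``equal`` splits the global batch evenly.
    """
    k = partition.n_clients
    if global_batch < k:
        raise ValueError(f"global batch {global_batch} < number of clients {k}")
    if policy == "proportional":
        weights = np.asarray(partition.sizes(), dtype=np.int64)
    elif policy == "equal":
        weights = np.ones(k, dtype=np.int64)
    else:
        raise ValueError(f"unknown batch policy {policy!r}")
    counts = _largest_remainder(global_batch, weights)
    counts = _repair_min_one(counts, weights, global_batch)
    return [int(c) for c in counts]


def client_forward(
    state: EndSystemState, batch_samples: np.ndarray, batch_labels: np.ndarray, batch_index: int = 0
) -> FeatureMap:
    """Run a local mini-batch through the client's hidden layer.

    Returns the feature-map message; the raw samples are not part of it.
    The forward caches are retained on the state for the backward half.
    """
    out, caches = state.stack.forward(batch_samples, state.params)
    state._last_caches = caches
    state._last_batch_index = batch_index
    state._last_shape = out.shape
    return FeatureMap(state.client_id, out, np.asarray(batch_labels), batch_index)


def concatenate_feature_maps(
    maps: list[FeatureMap],
) -> tuple[np.ndarray, np.ndarray, list[tuple[int, int, int]]]:
    """Join feature maps along the sample axis in ascending client order.

    Returns ``(joined_activations, joined_labels, boundaries)`` where
    ``boundaries`` is a list of ``(client_id, start, stop)`` offsets; slicing
    the joined tensor at these offsets inverts the concatenation exactly.
    """
    if not maps:
        raise ValueError("no feature maps to concatenate")
    ids = [fm.client_id for fm in maps]
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate client ids in feature maps: {ids}")
    ordered = sorted(maps, key=lambda fm: fm.client_id)
    per_sample = ordered[0].activations.shape[1:]
    for fm in ordered:
        if fm.activations.shape[1:] != per_sample:
            raise ShapeError(
                f"client {fm.client_id} sent per-sample shape {fm.activations.shape[1:]}, "
                f"expected {per_sample}"
            )
    joined = np.concatenate([fm.activations for fm in ordered], axis=0)
    labels = np.concatenate([fm.labels for fm in ordered], axis=0)
    boundaries = []
    start = 0
    for fm in ordered:
        stop = start + fm.activations.shape[0]
        boundaries.append((fm.client_id, start, stop))
        start = stop
    return joined, labels, boundaries


def server_step(
    server: ServerState,
    joined_activations: np.ndarray,
    joined_labels: np.ndarray,
    boundaries: list[tuple[int, int, int]],
    batch_index: int = 0,
    apply_update: bool = True,
) -> tuple[float, list[GradientSlice]]:
    """One server-side step on a joined batch.

    Computes the joint loss (mean over the joined batch), updates the server
    parameters, and returns the loss plus per-client gradient slices at the
    cut, cut exactly at the recorded boundaries.
    """
    out, caches = server.stack.forward(joined_activations, server.params)
    loss, dx, grads = server.stack.loss_backward(
        joined_labels, out, caches, server.params, server.loss_name
    )
    if not np.isfinite(loss):
        raise TrainingAborted(f"non-finite loss at batch {batch_index}")
    if apply_update:
        server.optimizer.step(server.params, grads)
    slices = [
        GradientSlice(cid, dx[start:stop], batch_index) for cid, start, stop in boundaries
    ]
    return loss, slices


def client_backward(
    state: EndSystemState, gslice: GradientSlice, apply_update: bool = True
) -> ParameterSet:
    """Backpropagate a gradient slice through the client's hidden layer.

    Returns the parameter gradients; with ``apply_update`` the client's own
    optimizer consumes them immediately.
    """
    if gslice.client_id != state.client_id:
        raise ValueError(f"gradient for client {gslice.client_id} sent to {state.client_id}")
    if state._last_caches is None or gslice.batch_index != state._last_batch_index:
        raise ValueError(
            f"stale batch cache on client {state.client_id}: "
            f"have batch {state._last_batch_index}, got gradient for {gslice.batch_index}"
        )
    if gslice.grad.shape != state._last_shape:
        raise ShapeError(
            f"gradient shape {gslice.grad.shape} does not match transmitted map {state._last_shape}"
        )
    _, grads = state.stack.backward(gslice.grad, state._last_caches, state.params)
    if apply_update:
        state.optimizer.step(state.params, grads)
    return grads


def sync_client_weights(clients: list[EndSystemState], mode: str = "mean") -> list[EndSystemState]:
    """Synchronize client hidden-layer parameters across end-systems.

    ``mean`` sets every client to the element-wise mean; ``broadcast`` copies
    client 1.  Idempotent.
    """
    if len(clients) < 2:
        raise ValueError("need at least 2 clients to synchronize")
    names = clients[0].params.names()
    for c in clients[1:]:
        if c.params.names() != names or any(
            c.params[n].shape != clients[0].params[n].shape for n in names
        ):
            raise ValueError("client layer templates do not match")
    if mode == "mean":
        merged = {
            n: np.mean([c.params[n] for c in clients], axis=0) for n in names
        }
    elif mode == "broadcast":
        merged = {n: clients[0].params[n].copy() for n in names}
    else:
        raise ValueError(f"unknown sync mode {mode!r}")
    for c in clients:
        c.params = ParameterSet({n: merged[n].copy() for n in names})
    return clients


# ---------------------------------------------------------------------------
# full training loop


@dataclass
class TrainConfig:
    spec: ModelSpec
    partition: Partition
    sync_mode: bool = False
    optimizer: dict[str, float] = field(default_factory=dict)
    seed: int = 0
    epochs: int | None = None  # None: use spec.epochs
    eval_every: int = 1
    batch_policy: str = "proportional"

    def __post_init__(self) -> None:
        if self.partition.n_clients < 2:
            raise ValueError("split learning needs at least 2 end-systems")

    def fingerprint(self) -> str:
        blob = json.dumps(
            {
                "spec": self.spec.to_dict(),
                "ratio": str(self.partition.ratio),
                "partition_seed": self.partition.seed,
                "sync": self.sync_mode,
                "optimizer": dict(sorted(self.optimizer.items())),
                "seed": self.seed,
                "epochs": self.epochs,
                "batch_policy": self.batch_policy,
            },
            sort_keys=True,
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class TrainingHistory:
    """Per-epoch record of one configuration's training run."""

    rows: list[dict[str, Any]] = field(default_factory=list)
    final: dict[str, Any] = field(default_factory=dict)
    fingerprint: str = ""
    step_losses: list[float] = field(default_factory=list)
    step_batches: list[np.ndarray] = field(default_factory=list)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.rows)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.8f")

    def summary(self) -> dict[str, Any]:
        return {"fingerprint": self.fingerprint, "final": self.final, "n_epochs": len(self.rows)}


def _init_split_params(
    model: SplitModel, seed: int
) -> tuple[ParameterSet, ParameterSet]:
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(0xC11E,))
    client_ss, server_ss = ss.spawn(2)
    cp = model.client_stack.init_params(model.spec.input_shape, np.random.default_rng(client_ss))
    sp = model.server_stack.init_params(model.cut_shape, np.random.default_rng(server_ss))
    return cp, sp


def _epoch_chunks(
    perm: np.ndarray, rounds: int, size: int, policy: str
) -> list[np.ndarray]:
    """Split one client's shuffled epoch indices into per-round batches."""
    if policy == "proportional":
        return np.array_split(perm, rounds)
    # equal policy: fixed per-round size, cycling through the shuffled data
    stream = np.resize(perm, rounds * size)
    return [stream[r * size : (r + 1) * size] for r in range(rounds)]


def _predict(
    model: SplitModel,
    client_params: ParameterSet,
    server_params: ParameterSet,
    x: np.ndarray,
    batch: int = 512,
) -> np.ndarray:
    outs = []
    for start in range(0, x.shape[0], batch):
        fm, _ = model.client_stack.forward(x[start : start + batch], client_params)
        out, _ = model.server_stack.forward(fm, server_params)
        outs.append(out.reshape(-1))
    return np.concatenate(outs)


def _mean_client_params(clients: list[EndSystemState]) -> ParameterSet:
    names = clients[0].params.names()
    return ParameterSet(
        {n: np.mean([c.params[n] for c in clients], axis=0) for n in names}
    )


def train(
    config: TrainConfig,
    x_train: np.ndarray,
    y_train: np.ndarray,
    eval_set: tuple[np.ndarray, np.ndarray] | None = None,
    model: SplitModel | None = None,
    bus: MessageBus | None = None,
    record_steps: bool = False,
) -> tuple[TrainingHistory, dict[str, Any]]:
    """Run the full multi-site split training loop.

    ``x_train``/``y_train`` hold the training subset; the partition's index
    lists refer to their rows.  ``eval_set`` is the shared held-out split,
    evaluated every ``config.eval_every`` epochs with the element-wise mean
    of the client hidden layers as the deployed first layer.

    For the regression task, features and target are z-scored with training
    statistics; predictions are mapped back to original units (and floored
    at zero) before the RMSLE is computed.

    Deterministic given ``config.seed`` on a fixed platform.  Returns
    ``(history, state)`` where ``state`` carries the final client/server
    parameter sets and the scaler.
    """
    spec = config.spec
    bus = bus or MessageBus()
    epochs = spec.epochs if config.epochs is None else config.epochs
    partition = config.partition
    if partition.n_samples != x_train.shape[0]:
        raise ValueError(
            f"partition covers {partition.n_samples} samples, data has {x_train.shape[0]}"
        )

    if model is None:
        model, client_template, server_params = build_split_model(spec, config.seed)
    else:
        client_template, server_params = _init_split_params(model, config.seed)

    # regression preprocessing: z-score features and target on training stats
    scaler: dict[str, Any] = {}
    x_train = np.asarray(x_train, dtype=float)
    y_fit = np.asarray(y_train, dtype=float)
    if spec.task == "regression":
        mu_x, sd_x = x_train.mean(axis=0), x_train.std(axis=0)
        sd_x = np.where(sd_x == 0, 1.0, sd_x)
        mu_y, sd_y = y_fit.mean(), y_fit.std() or 1.0
        x_train = (x_train - mu_x) / sd_x
        y_fit = (y_fit - mu_y) / sd_y
        scaler = {"mu_x": mu_x, "sd_x": sd_x, "mu_y": mu_y, "sd_y": sd_y}

    ss = np.random.SeedSequence(entropy=config.seed, spawn_key=(0x5EED,))
    client_seeds = ss.spawn(partition.n_clients)
    opt_kwargs = dict(config.optimizer)
    clients = [
        EndSystemState(
            client_id=i + 1,
            stack=model.client_stack,
            params=client_template.copy(),
            optimizer=Adam(**opt_kwargs),
            local_indices=np.asarray(partition.by_client[i]),
            rng=np.random.default_rng(client_seeds[i]),
        )
        for i in range(partition.n_clients)
    ]
    server = ServerState(model.server_stack, server_params, Adam(**opt_kwargs), spec.loss_name)

    history = TrainingHistory(fingerprint=config.fingerprint())
    n_train = x_train.shape[0]
    rounds = max(1, ceil(n_train / spec.global_batch_size))
    sizes = local_batch_sizes(spec.global_batch_size, partition, config.batch_policy)
    step = 0

    for epoch in range(epochs):
        t0 = time.perf_counter()
        chunks = [
            _epoch_chunks(c.rng.permutation(c.local_indices), rounds, sizes[i], config.batch_policy)
            for i, c in enumerate(clients)
        ]
        epoch_losses = []
        for r in range(rounds):
            fms = []
            for i, c in enumerate(clients):
                idx = chunks[i][r]
                if idx.size == 0:
                    continue
                fm = client_forward(c, x_train[idx], y_fit[idx], batch_index=step)
                fms.append(bus.send_features(fm))
            for fm in fms:
                bus.on_server_receive(fm)
            joined, labels, boundaries = concatenate_feature_maps(fms)
            try:
                loss, slices = server_step(server, joined, labels, boundaries, batch_index=step)
            except TrainingAborted as exc:
                exc.history = history
                raise
            slices = {s.client_id: bus.send_gradients(s) for s in slices}
            active = [c for c in clients if c.client_id in slices]
            if config.sync_mode:
                grads = [client_backward(c, slices[c.client_id], apply_update=False) for c in active]
                summed = ParameterSet(
                    {
                        n: np.sum([g[n] for g in grads], axis=0)
                        for n in grads[0].names()
                    }
                )
                for c in active:
                    c.optimizer.step(c.params, summed)
                sync_client_weights(clients, mode="mean")
            else:
                for c in active:
                    client_backward(c, slices[c.client_id])
            epoch_losses.append(loss)
            if record_steps:
                history.step_losses.append(loss)
                history.step_batches.append(
                    np.concatenate([chunks[i][r] for i in range(len(clients)) if chunks[i][r].size])
                )
            step += 1
            logger.debug("epoch %d round %d loss %.6f", epoch + 1, r + 1, loss)

        row: dict[str, Any] = {
            "epoch": epoch + 1,
            "train_loss": float(np.mean(epoch_losses)),
            "seconds": time.perf_counter() - t0,
        }
        if eval_set is not None and (epoch + 1) % config.eval_every == 0:
            metric = evaluate(model, _mean_client_params(clients), server.params, eval_set, spec, scaler)
            row["metric_name"] = metric.name
            row["metric_value"] = metric.value
        history.rows.append(row)
        logger.info(
            "epoch %d/%d loss %.6f%s",
            epoch + 1,
            epochs,
            row["train_loss"],
            f" {row['metric_name']}={row['metric_value']:.4f}" if "metric_name" in row else "",
        )

    state = {
        "clients": [c.params for c in clients],
        "client_mean": _mean_client_params(clients),
        "server": server.params,
        "scaler": scaler,
        "model": model,
    }
    if history.rows:
        history.final = {
            "train_loss": history.rows[-1]["train_loss"],
            **(
                {
                    "metric_name": history.rows[-1].get("metric_name"),
                    "metric_value": history.rows[-1].get("metric_value"),
                }
                if "metric_name" in history.rows[-1]
                else {}
            ),
        }
    return history, state


def evaluate(
    model: SplitModel,
    client_params: ParameterSet,
    server_params: ParameterSet,
    eval_set: tuple[np.ndarray, np.ndarray],
    spec: ModelSpec,
    scaler: dict[str, Any] | None = None,
):
    """Held-out metric: accuracy (%) for classification, RMSLE for regression."""
    x_eval, y_eval = eval_set
    x_eval = np.asarray(x_eval, dtype=float)
    if spec.task == "regression" and scaler:
        x_eval = (x_eval - scaler["mu_x"]) / scaler["sd_x"]
    pred = _predict(model, client_params, server_params, x_eval)
    if spec.task == "classification":
        return accuracy(pred, y_eval)
    if scaler:
        pred = pred * scaler["sd_y"] + scaler["mu_y"]
    return rmsle(np.maximum(pred, 0.0), y_eval)
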