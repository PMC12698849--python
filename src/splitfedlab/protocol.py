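"""Split-federated training protocol.

One round: every client forwards its batches to the cut layer and transmits
the smashed activations (plus labels, in the default wiring) to the main
server; the server computes the loss, updates its own part, and returns the
gradient of the loss with respect to the smashed data; the client completes
the backward pass and updates its part; after each round the federation
server averages the client parts weighted by shard sizes and broadcasts the
result.

With one client and no noise the whole procedure is numerically identical to
centralized training of the un-split network — ``train_centralized`` exists
to check exactly that.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import dp as dp_mod
from .data import LabeledImageSet, PartitionPlan, preprocess
from .dp import NoiseSpec, add_noise_to_params, add_noise_to_transmission
from .model import (ParameterVector, SmashedBatch, SplitModel, SplitModelSpec,
                    build_split_model, client_forward, default_spec, predict)
from .nn import Sequential, cross_entropy, make_optimizer


class StaleGradientError(RuntimeError):
    """A gradient packet from a different round than the client expects."""


@dataclass
class TrainConfig:
    """Hyper-parameters of one split-federated run."""

    n_clients: int = 2
    epochs: int = 15
    batch_size: int = 64
    lr: float = 1e-3
    optimizer: str = "adam"     # "adam" (AMSGrad) or "sgd"
    amsgrad: bool = True
    seed: int = 0
    noise: Optional[NoiseSpec] = None
    aggregate_every: int = 1    # rounds between federated averages
    labels_at: str = "server"   # "server": labels ride with smashed data
    target_accuracy: Optional[float] = None
    n_classes: int = 4
    image_size: int = 32
    spec: Optional[SplitModelSpec] = None

    def __post_init__(self) -> None:
        if self.n_clients < 1 or self.batch_size < 1 or self.epochs < 0:
            raise ValueError("n_clients, batch_size must be >= 1; epochs >= 0")
        if self.lr < 0:
            raise ValueError("learning rate must be non-negative")
        if self.labels_at not in ("server", "client"):
            raise ValueError("labels_at must be 'server' or 'client'")

    def resolved_spec(self) -> SplitModelSpec:
        return self.spec if self.spec is not None else default_spec(
            self.n_classes, self.image_size)

    def to_dict(self) -> dict:
        d = {"n_clients": self.n_clients, "epochs": self.epochs,
             "batch_size": self.batch_size, "lr": self.lr,
             "optimizer": self.optimizer, "amsgrad": self.amsgrad,
             "seed": self.seed, "aggregate_every": self.aggregate_every,
             "labels_at": self.labels_at, "target_accuracy": self.target_accuracy,
             "n_classes": self.n_classes, "image_size": self.image_size}
        if self.noise is not None:
            d["noise"] = self.noise.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "TrainConfig":
        d = dict(d)
        if d.get("noise") is not None:
            d["noise"] = NoiseSpec.from_dict(d["noise"])
        return cls(**d)


@dataclass
class GradientPacket:
    """What the main server returns to a client for one batch."""

    smashed_grad: np.ndarray
    client_id: int
    round: int
    sample_indices: Optional[np.ndarray] = None
    loss: float = 0.0
    client_param_grads: Optional[np.ndarray] = None  # filled after client backward


@dataclass
class FederatedState:
    """All parties of an in-process SplitFed deployment."""

    spec: SplitModelSpec
    client_models: list[SplitModel]
    server_part: Sequential
    client_weights: list[int]
    round: int = 0
    global_client: Optional[ParameterVector] = None
    pristine_client_params: Optional[list[ParameterVector]] = None
    last_outbound_params: Optional[list[ParameterVector]] = None
    client_opts: list = field(default_factory=list)
    server_opt: object = None

    @property
    def n_clients(self) -> int:
        return len(self.client_models)

    def model(self) -> SplitModel:
        """The current global model (client parts are identical after
        aggregation)."""
        return SplitModel(self.spec, self.client_models[0].client,
                          self.server_part)


def init_state(cfg: TrainConfig, plan: PartitionPlan) -> FederatedState:
    """Build master parts, hand each client an identical client-part copy,
    share one server part, and attach per-party optimizers."""
    spec = cfg.resolved_spec()
    master = build_split_model(spec, seed=cfg.seed)
    clients = []
    for _ in range(plan.k):
        m = build_split_model(spec, seed=cfg.seed)
        m.server = master.server  # one shared main-server part
        clients.append(m)
    state = FederatedState(spec=spec, client_models=clients,
                           server_part=master.server,
                           client_weights=list(plan.shard_sizes))
    state.server_opt = make_optimizer(cfg.optimizer,
                                      master.server.param_arrays(), cfg.lr,
                                      cfg.amsgrad)
    state.client_opts = [make_optimizer(cfg.optimizer,
                                        m.client.param_arrays(), cfg.lr,
                                        cfg.amsgrad) for m in clients]
    state.global_client = ParameterVector.from_model(master.client)
    return state


def server_step(server: Sequential, opt, smashed: SmashedBatch,
                labels: np.ndarray, cfg: TrainConfig,
                round_idx: int = 0) -> tuple[GradientPacket, float]:
    """Server-side forward/backward/update for one batch.

    Returns the gradient packet (gradient of the mean loss w.r.t. the smashed
    activations) and the batch loss. The smashed-data gradient is computed
    with the pre-update server parameters, exactly as in the un-split
    network.
    """
    labels = np.asarray(labels)
    if len(labels) != len(smashed.activations):
        raise ValueError("label count does not match smashed batch size")
    server.zero_grad()
    scores = server.forward(smashed.activations)
    loss_value, dlogits = cross_entropy(scores, labels)
    dsmashed = server.backward(dlogits)
    packet = GradientPacket(smashed_grad=dsmashed, client_id=smashed.client_id,
                            round=round_idx, sample_indices=smashed.sample_indices,
                            loss=loss_value)
    opt.step(server.grad_arrays())
    return packet, loss_value


def client_step(client: Sequential, opt, packet: GradientPacket,
                cfg: TrainConfig, round_idx: int = 0) -> None:
    """Client-side backward (from the returned smashed-data gradient, through
    the caches of this client's latest forward) and optimizer update."""
    if packet.round != round_idx:
        raise StaleGradientError(
            f"packet from round {packet.round}, client at round {round_idx}")
    client.zero_grad()
    client.backward(packet.smashed_grad)
    packet.client_param_grads = np.concatenate(
        [g.ravel() for g in client.grad_arrays()]) if client.layers else np.zeros(0)
    opt.step(client.grad_arrays())


def fedavg(params: list[ParameterVector], weights) -> ParameterVector:
    """Element-wise weighted mean of parameter vectors, weights n_i / sum n_j."""
    if not params:
        raise ValueError("no parameter vectors to average")
    w = np.asarray(weights, dtype=np.float64)
    if len(w) != len(params):
        raise ValueError("one weight per parameter vector required")
    if (w < 0).any() or w.sum() == 0:
        raise ValueError("weights must be non-negative and not all zero")
    w = w / w.sum()
    ref = params[0]
    out = [np.zeros_like(a) for a in ref.arrays]
    for wi, pv in zip(w, params, strict=True):
        if pv.names != ref.names:
            raise ValueError("parameter vectors have mismatched names")
        for acc, arr in zip(out, pv.arrays, strict=True):
            if arr.shape != acc.shape:
                raise ValueError("parameter vectors have mismatched shapes")
            acc += wi * arr
    return ParameterVector(list(ref.names), out, role=ref.role)


def _epoch_batches(plan: PartitionPlan, client_id: int, batch_size: int,
                   rng: np.random.Generator):
    shard = plan.shard_indices[client_id]
    order = rng.permutation(len(shard))
    for b0 in range(0, len(shard), batch_size):
        yield shard[order[b0:b0 + batch_size]]


def _ensure_preprocessed(data: LabeledImageSet) -> LabeledImageSet:
    if data.value_range != (-1.0, 1.0):
        return preprocess(data)
    return data


def train(data: LabeledImageSet, plan: PartitionPlan, cfg: TrainConfig,
          eval_data: Optional[LabeledImageSet] = None
          ) -> tuple[FederatedState, list[dict]]:
    """Run the full SplitFed loop; returns the final state and a per-round
    history of mean loss (and held-out accuracy when ``eval_data`` is given).

    Stops early once ``cfg.target_accuracy`` is reached on ``eval_data``.
    """
    if cfg.lr <= 0:
        raise ValueError("training requires a positive learning rate")
    data = _ensure_preprocessed(data)
    if eval_data is not None:
        eval_data = _ensure_preprocessed(eval_data)
    state = init_state(cfg, plan)
    shuffle_rng = np.random.default_rng([cfg.seed, 1])
    dp_rng = np.random.default_rng([cfg.seed if cfg.noise is None or
                                    cfg.noise.seed is None else cfg.noise.seed, 2])
    noise = cfg.noise
    history: list[dict] = []
    for epoch in range(cfg.epochs):
        losses, n_seen = [], 0
        for i, cmodel in enumerate(state.client_models):
            for idx in _epoch_batches(plan, i, cfg.batch_size, shuffle_rng):
                x, y = data.images[idx], data.labels[idx]
                smashed = client_forward(cmodel, x, client_id=i,
                                         sample_indices=idx,
                                         labels=y if cfg.labels_at == "server" else None)
                if noise is not None and "activations" in noise.targets:
                    rec = add_noise_to_transmission(smashed, noise, dp_rng)
                    smashed = SmashedBatch(rec.noisy, smashed.client_id,
                                           smashed.sample_indices, smashed.labels)
                packet, loss_value = server_step(state.server_part,
                                                 state.server_opt, smashed, y,
                                                 cfg, round_idx=state.round)
                if noise is not None and "gradients" in noise.targets:
                    rec = add_noise_to_transmission(packet.smashed_grad, noise,
                                                    dp_rng)
                    packet.smashed_grad = rec.noisy
                client_step(cmodel.client, state.client_opts[i], packet, cfg,
                            round_idx=state.round)
                losses.append(loss_value)
                n_seen += len(idx)
        if noise is not None and "parameters" in noise.targets:
            # noise goes on the outbound copies only; local training state
            # stays clean and is formally "restored" after the exchange
            state.pristine_client_params = [
                ParameterVector.from_model(m.client) for m in state.client_models]
            state.last_outbound_params = [
                add_noise_to_params(pv, noise, dp_rng)  # adversary-visible copy
                for pv in state.pristine_client_params]
            dp_mod.restore_parameters(state)
        if (epoch + 1) % cfg.aggregate_every == 0:
            pvs = [ParameterVector.from_model(m.client)
                   for m in state.client_models]
            global_pv = fedavg(pvs, state.client_weights)
            for m in state.client_models:
                global_pv.apply_to(m.client)
            state.global_client = global_pv
        state.round += 1
        row = {"epoch": epoch, "loss": float(np.mean(losses)),
               "n_samples": n_seen}
        if eval_data is not None:
            preds = predict(state.model(), eval_data.images)
            row["accuracy"] = float((preds == eval_data.labels).mean())
        history.append(row)
        if (cfg.target_accuracy is not None and eval_data is not None
                and row["accuracy"] >= cfg.target_accuracy):
            break
    return state, history


def train_centralized(data: LabeledImageSet, plan: PartitionPlan,
                      cfg: TrainConfig,
                      eval_data: Optional[LabeledImageSet] = None
                      ) -> tuple[SplitModel, list[dict]]:
    """Train the un-split network with the same batching, initialization and
    optimizer schedule as a one-client SplitFed run — the centralized oracle."""
    data = _ensure_preprocessed(data)
    if eval_data is not None:
        eval_data = _ensure_preprocessed(eval_data)
    model = build_split_model(cfg.resolved_spec(), seed=cfg.seed)
    mono = model.monolithic()
    shuffle_rng = np.random.default_rng([cfg.seed, 1])
    opt_client = make_optimizer(cfg.optimizer, model.client.param_arrays(),
                                cfg.lr, cfg.amsgrad)
    opt_server = make_optimizer(cfg.optimizer, model.server.param_arrays(),
                                cfg.lr, cfg.amsgrad)
    history: list[dict] = []
    for epoch in range(cfg.epochs):
        losses, n_seen = [], 0
        for i in range(plan.k):
            for idx in _epoch_batches(plan, i, cfg.batch_size, shuffle_rng):
                x = data.images[idx][:, None, :, :]
                mono.zero_grad()
                scores = mono.forward(x)
                loss_value, dlogits = cross_entropy(scores, data.labels[idx])
                # server-part gradients must step before the client part sees
                # them, mirroring the split message order exactly
                mono.backward(dlogits)
                opt_server.step(model.server.grad_arrays())
                opt_client.step(model.client.grad_arrays())
                losses.append(loss_value)
                n_seen += len(idx)
        row = {"epoch": epoch, "loss": float(np.mean(losses)),
               "n_samples": n_seen}
        if eval_data is not None:
            preds = predict(model, eval_data.images)
            row["accuracy"] = float((preds == eval_data.labels).mean())
        history.append(row)
    return model, history


def evaluate(state: FederatedState, test: LabeledImageSet):
    """Deterministic forward over a test set; metric math lives in
    :mod:`splitfedlab.metrics`."""
    from .metrics import compute_metrics

    if len(test) == 0:
        raise ValueError("empty test set")
    test = _ensure_preprocessed(test)
    preds = predict(state.model(), test.images)
    return compute_metrics(test.labels, preds, state.spec.n_classes)
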