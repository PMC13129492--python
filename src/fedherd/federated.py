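"""Federated averaging (FedAvg) simulation and the centralized baseline.

One communication round: the server broadcasts the global parameter
vector k^t, every sampled client trains it for E local epochs of
mini-batch Adam on its own windows, and the server aggregates the
returned vectors by the sample-size-weighted mean

    k^{t+1} = Σ_y (|X_y| / Σ_j |X_j|) · k_y^t .

Clients are stateless: the Adam moments are reset at every round (the
broadcast-then-train reading of the protocol). Aggregation sorts the
updates by client id and reduces with pairwise summation, so the result
is bit-identical under any permutation of the input list.

The centralized baseline trains the same model on the pooled windows in
T blocks of E epochs with a fresh optimizer per block — the identical
schedule a single federated client would follow — so with one client and
full participation the two trajectories agree bit-for-bit, and the
optimization budgets of the two arms match by construction.

Traffic accounting uses the nominal 32-bit payload of the parameter
vector; 1 MB = 2^20 bytes everywhere. No network transport, stragglers,
encryption or differential privacy are simulated (hooks exist as
interface stubs only).
"""

from __future__ import annotations

import dataclasses
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .errors import AggregationError, ConfigError, DataError, StructuralError
from .model import (
    AdamState,
    ModelConfig,
    ParamVector,
    init_params,
    local_loss,
    loss_and_grad,
    param_size_bytes,
    predict_proba,
    save_params,
)
from .preprocess import WindowedDataset
from .seeding import derive_seed

logger = logging.getLogger("fedherd.federated")

MB = 2**20  # ledger convention: 1 MB = 2^20 bytes

__all__ = [
    "MB",
    "FedConfig",
    "ClientUpdate",
    "CommsLedger",
    "RunResult",
    "local_update",
    "fedavg",
    "run_federated",
    "run_centralized",
    "comms_totals",
]


@dataclass
class FedConfig:
    """Federated training configuration; defaults are the reference setup:

    10 clients, 100% participation per round, 50 communication rounds,
    5 local epochs, batch size 32, Adam at learning rate 0.001, binary
    cross-entropy loss.
    """

    n_clients: int = 10
    participation: float = 1.0
    rounds: int = 50
    local_epochs: int = 5
    batch_size: int = 32
    learning_rate: float = 0.001
    optimizer: str = "adam"
    loss: str = "binary_cross_entropy"
    seed: int = 0

    def validate(self) -> None:
        if self.n_clients < 1:
            raise ConfigError("n_clients must be >= 1")
        if not 0.0 < self.participation <= 1.0:
            raise ConfigError("participation must be in (0, 1]")
        if self.rounds < 1:
            raise ConfigError("rounds must be >= 1")
        if self.local_epochs < 0:
            raise ConfigError("local_epochs must be >= 0")
        if self.batch_size < 1:
            raise ConfigError("batch_size must be >= 1")
        if self.learning_rate < 0:
            raise ConfigError("learning_rate must be >= 0")
        if self.optimizer != "adam":
            raise ConfigError(f"unsupported optimizer {self.optimizer!r}")
        if self.loss not in ("binary_cross_entropy", "bce"):
            raise ConfigError(f"unsupported loss {self.loss!r}")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class ClientUpdate:
    """A client's locally trained parameters plus its sample count |X_y|."""

    client_id: str
    params: ParamVector
    n_samples: int
    local_loss_trace: list[float] = field(default_factory=list)


@dataclass
class CommsLedger:
    """Per-round uplink/downlink byte accounting for a federated run."""

    entries: list[dict] = field(default_factory=list)

    def add_round(self, round_idx: int, participants: int, payload_bytes: int) -> None:
        self.entries.append({
            "round": round_idx,
            "uplink_bytes": participants * payload_bytes,
            "downlink_bytes": participants * payload_bytes,
        })

    @classmethod
    def analytic(cls, n_clients: int, rounds: int, payload_bytes: int,
                 participation: float = 1.0) -> "CommsLedger":
        """Pure accounting: ledger for a run that is never executed."""
        led = cls()
        participants = math.ceil(participation * n_clients)
        for t in range(1, rounds + 1):
            led.add_round(t, participants, payload_bytes)
        return led

    @property
    def total_uplink_bytes(self) -> int:
        return sum(e["uplink_bytes"] for e in self.entries)

    @property
    def total_downlink_bytes(self) -> int:
        return sum(e["downlink_bytes"] for e in self.entries)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.entries, columns=["round", "uplink_bytes", "downlink_bytes"])


def comms_totals(ledger: CommsLedger) -> dict:
    """Totals in bytes and MB (1 MB = 2^20 bytes)."""
    up, down = ledger.total_uplink_bytes, ledger.total_downlink_bytes
    return {
        "n_rounds": len(ledger.entries),
        "uplink_bytes": up,
        "downlink_bytes": down,
        "uplink_mb": up / MB,
        "downlink_mb": down / MB,
    }


@dataclass
class RunResult:
    """Outcome of a federated or centralized run."""

    params: ParamVector
    history: list[dict]
    ledger: CommsLedger
    config: dict
    seed: int

    def history_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.history)

    def save(self, out_dir) -> None:
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        save_params(self.params, out / "params.bin")
        self.history_frame().to_csv(out / "history.csv", index=False)
        self.ledger.to_frame().to_csv(out / "ledger.csv", index=False)
        with open(out / "config.yaml", "w") as fh:
            yaml.safe_dump(self.config, fh, sort_keys=True)


def local_update(
    global_params: ParamVector,
    client_data: WindowedDataset,
    fed_cfg: FedConfig,
    model_cfg: ModelConfig,
    round_seed: int,
    client_id: str = "client",
) -> ClientUpdate:
    """E epochs of seeded mini-batch Adam from a copy of the global params.

    Optimizer state is created fresh (stateless clients). Returns the
    trained parameters, the local sample count, and the per-epoch mean
    training loss.
    """
    if len(client_data) == 0:
        raise DataError("local_update requires non-empty client data")
    params = global_params.copy()
    n = len(client_data)
    X = np.asarray(client_data.X, dtype=np.float64)
    y = np.asarray(client_data.y, dtype=np.float64)
    rng = np.random.default_rng(round_seed)
    adam = AdamState(params, lr=fed_cfg.learning_rate)
    trace: list[float] = []
    for _ in range(fed_cfg.local_epochs):
        perm = rng.permutation(n)
        epoch_loss = 0.0
        for s in range(0, n, fed_cfg.batch_size):
            idx = perm[s:s + fed_cfg.batch_size]
            loss, grads = loss_and_grad(params, X[idx], y[idx], model_cfg)
            adam.step(params, grads)
            epoch_loss += loss * len(idx)
        trace.append(epoch_loss / n)
    return ClientUpdate(client_id=client_id, params=params, n_samples=n,
                        local_loss_trace=trace)


def _pairwise_sum(arrays: list[np.ndarray]) -> np.ndarray:
    """Pairwise-tree summation (fixed association, bit-reproducible)."""
    while len(arrays) > 1:
        nxt = []
        for k in range(0, len(arrays) - 1, 2):
            nxt.append(arrays[k] + arrays[k + 1])
        if len(arrays) % 2:
            nxt.append(arrays[-1])
        arrays = nxt
    return arrays[0]


def fedavg(updates: list[ClientUpdate]) -> ParamVector:
    """Sample-size-weighted mean of client parameter vectors.

    Updates are processed in client-id-sorted order with pairwise
    summation so the result is independent of input ordering, bit for
    bit. Weights |X_y| / Σ|X_j| sum to one. The sum is computed anchored
    at the first sorted update, k_0 + Σ_y w_y (k_y − k_0) — algebraically
    the weighted mean, but exact (bit-for-bit) when all updates agree and
    in the single-client case.
    """
    if not updates:
        raise AggregationError("fedavg requires at least one client update")
    updates = sorted(updates, key=lambda u: str(u.client_id))
    total = sum(u.n_samples for u in updates)
    if total <= 0:
        raise AggregationError("zero total samples across client updates")
    ref = updates[0].params
    for u in updates[1:]:
        if not ref.shapes_match(u.params):
            raise StructuralError(
                f"client {u.client_id!r} submitted shape-incompatible parameters"
            )
    weights = [u.n_samples / total for u in updates]
    out = ref.zeros_like()
    for name in ref.names():
        anchor = ref[name]
        out[name] = anchor + _pairwise_sum(
            [w * (u.params[name] - anchor) for w, u in zip(weights, updates)])
    return out


def _evaluate_global(params: ParamVector, test_data: WindowedDataset | None,
                     model_cfg: ModelConfig) -> tuple[float, float]:
    if test_data is None or len(test_data) == 0:
        return float("nan"), float("nan")
    p = predict_proba(params, test_data.X, model_cfg)
    loss = local_loss(params, test_data, model_cfg)
    acc = float(np.mean((p > 0.5).astype(int) == test_data.y))
    return loss, acc


def run_federated(
    clients: list[WindowedDataset],
    fed_cfg: FedConfig,
    model_cfg: ModelConfig,
    test_data: WindowedDataset | None = None,
) -> RunResult:
    """Run the full broadcast → local-train → aggregate loop for T rounds.

    Per round, ⌈participation·n_clients⌉ clients are sampled without
    replacement with a round-derived seed; empty clients are skipped with
    a warning (their aggregation weight is zero). The ledger books one
    uplink and one downlink payload per participant per round.
    """
    fed_cfg.validate()
    model_cfg.validate()
    if not clients or all(len(c) == 0 for c in clients):
        raise DataError("run_federated requires at least one non-empty client")
    k = init_params(model_cfg)
    payload = param_size_bytes(k)
    ledger = CommsLedger()
    history: list[dict] = []
    n_sample = math.ceil(fed_cfg.participation * len(clients))
    for t in range(1, fed_cfg.rounds + 1):
        rng = np.random.default_rng(derive_seed(fed_cfg.seed, "sample", t))
        chosen = np.sort(rng.choice(len(clients), size=n_sample, replace=False))
        updates: list[ClientUpdate] = []
        for pos, ci in enumerate(chosen):
            data = clients[ci]
            if len(data) == 0:
                logger.warning("round %d: client %d is empty; skipped (weight 0)", t, ci)
                continue
            upd = local_update(
                k, data, fed_cfg, model_cfg,
                round_seed=derive_seed(fed_cfg.seed, "local", t, pos),
                client_id=f"client_{ci:03d}",
            )
            updates.append(upd)
        if updates:
            k = fedavg(updates)
        ledger.add_round(t, len(updates), payload)
        g_loss, g_acc = _evaluate_global(k, test_data, model_cfg)
        client_mean_loss = (
            float(np.mean([u.local_loss_trace[-1] for u in updates if u.local_loss_trace]))
            if any(u.local_loss_trace for u in updates) else float("nan")
        )
        history.append({
            "round": t,
            "global_loss": g_loss,
            "global_accuracy": g_acc,
            "client_mean_loss": client_mean_loss,
            "participants": len(updates),
            "uplink_bytes": ledger.entries[-1]["uplink_bytes"],
        })
        logger.info(
            "round %d/%d: loss=%.4f acc=%.4f uplink=%.2f MB", t, fed_cfg.rounds,
            g_loss, g_acc, ledger.total_uplink_bytes / MB,
        )
    return RunResult(
        params=k, history=history, ledger=ledger,
        config={"federated": fed_cfg.to_dict(), "model": model_cfg.to_dict()},
        seed=fed_cfg.seed,
    )


def run_centralized(
    pooled: WindowedDataset,
    fed_cfg: FedConfig,
    model_cfg: ModelConfig,
    test_data: WindowedDataset | None = None,
) -> RunResult:
    """Centralized comparison arm: same model on pooled data, no traffic.

    Trains for rounds × local_epochs epochs, scheduled exactly as a
    single federated client (fresh Adam per block of local_epochs), so
    the one-client federated run is reproduced bit-for-bit.
    """
    fed_cfg.validate()
    model_cfg.validate()
    if pooled is None or len(pooled) == 0:
        raise DataError("run_centralized requires non-empty pooled data")
    k = init_params(model_cfg)
    history: list[dict] = []
    for t in range(1, fed_cfg.rounds + 1):
        upd = local_update(
            k, pooled, fed_cfg, model_cfg,
            round_seed=derive_seed(fed_cfg.seed, "local", t, 0),
            client_id="centralized",
        )
        k = upd.params
        g_loss, g_acc = _evaluate_global(k, test_data, model_cfg)
        history.append({
            "round": t,
            "global_loss": g_loss,
            "global_accuracy": g_acc,
            "client_mean_loss": upd.local_loss_trace[-1] if upd.local_loss_trace else float("nan"),
            "participants": 1,
            "uplink_bytes": 0,
        })
        logger.info("centralized block %d/%d: loss=%.4f acc=%.4f",
                    t, fed_cfg.rounds, g_loss, g_acc)
    return RunResult(
        params=k, history=history, ledger=CommsLedger(),
        config={"federated": fed_cfg.to_dict(), "model": model_cfg.to_dict(),
                "arm": "centralized"},
        seed=fed_cfg.seed,
    )
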