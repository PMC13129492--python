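"""CNN-extensible LSTM stress classifier, its loss, and its gradients.

The classifier maps a normalized sensor window (window_len × n_features,
values in [0, 1]) to a stress probability:

    [optional 1-D temporal convolution + ReLU]  →  LSTM over time
    →  last hidden state  →  [optional dense + ReLU]  →  sigmoid logit

The LSTM cell is the standard four-gate recursion

    i_t = σ(w_i·[h_{t−1}, x_t] + b_i)        input gate
    f_t = σ(w_f·[h_{t−1}, x_t] + b_f)        forget gate
    o_t = σ(w_o·[h_{t−1}, x_t] + b_o)        output gate
    c̃_t = tanh(w_c·[h_{t−1}, x_t] + b_c)     candidate cell
    C_t = f_t ⊙ C_{t−1} + i_t ⊙ c̃_t
    h_t = o_t ⊙ tanh(C_t)

and the convolutional front-end is a valid (no padding) 1-D convolution
along time, y = ReLU(w ∗ z + b), applied to the sensor window — the
"CNN-extensible" part of the architecture; an image branch is out of
scope and exists only as this temporal front-end.

The head is a single sigmoid logit; its output equals the class-1
probability of the equivalent two-class softmax head (σ(u) =
softmax((0, u))₁), which is why binary cross-entropy is the local loss:

    L(k) = (1/|X|) Σ_i −[z_i log p_i + (1−z_i) log(1−p_i)]

Because no autodiff library is used, this module also implements
backpropagation through time by hand; the analytic gradient is verified
against central finite differences in the test suite. Parameters are
held in float64 during training and serialized at 32-bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from collections import OrderedDict
from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .errors import ConfigError, DataError, StructuralError

__all__ = [
    "ModelConfig",
    "ParamVector",
    "CellState",
    "AdamState",
    "init_params",
    "lstm_step",
    "cnn_extract",
    "forward",
    "predict_proba",
    "local_loss",
    "binary_cross_entropy",
    "loss_and_grad",
    "param_size_bytes",
    "params_to_bytes",
    "params_from_bytes",
    "save_params",
    "load_params",
    "PARAM_HEADER_BYTES",
]

#: Fixed nominal container-header size used by the communication ledger.
PARAM_HEADER_BYTES = 64

#: Probability clipping inside the loss (keeps log finite).
LOSS_P_EPS = 1e-7

_GATES = ("i", "f", "o", "c")


@dataclass
class ModelConfig:
    """Architecture and initialization of the classifier.

    The shipped defaults serialize to ~1.2 MB at 32-bit precision,
    inside the ~1–2 MB on-air budget the communication ledger assumes.
    ``dense_hidden = 0`` removes the dense layer (head directly on the
    last hidden state); ``lstm_enabled = False`` is a CNN-only ablation
    that mean-pools the convolution features over time.
    """

    n_features: int = 8
    window_len: int = 8
    cnn_enabled: bool = True
    cnn_channels: int = 32
    cnn_kernel: int = 3
    lstm_hidden: int = 256
    dense_hidden: int = 64
    output_classes: int = 1        # 1 = sigmoid logit (== 2-class softmax)
    init_scale: float = 0.08
    lstm_enabled: bool = True
    seed: int = 0
    max_param_bytes: int | None = 2 * 2**20

    def validate(self) -> None:
        if self.n_features < 1 or self.window_len < 1:
            raise ConfigError("n_features and window_len must be >= 1")
        if self.cnn_enabled:
            if self.cnn_kernel < 1 or self.cnn_channels < 1:
                raise ConfigError("cnn_kernel and cnn_channels must be >= 1")
            if self.cnn_kernel > self.window_len:
                raise ConfigError("cnn_kernel must not exceed window_len")
        if self.lstm_enabled and self.lstm_hidden < 1:
            raise ConfigError("lstm_hidden must be >= 1")
        if self.dense_hidden < 0:
            raise ConfigError("dense_hidden must be >= 0")
        if self.output_classes not in (1, 2):
            raise ConfigError("output_classes must be 1 (sigmoid) or 2 (softmax-equivalent)")
        if self.init_scale <= 0:
            raise ConfigError("init_scale must be > 0")
        if not (self.cnn_enabled or self.lstm_enabled):
            raise ConfigError("at least one of cnn_enabled/lstm_enabled must be set")

    @property
    def lstm_input_dim(self) -> int:
        return self.cnn_channels if self.cnn_enabled else self.n_features

    @property
    def conv_len(self) -> int:
        return self.window_len - self.cnn_kernel + 1 if self.cnn_enabled else self.window_len

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.blake2b(blob, digest_size=8).hexdigest()


class ParamVector:
    """Named, ordered, flat collection of all trainable parameters.

    The unit exchanged in federated rounds. Element-wise arithmetic is
    defined by name; two vectors from the same :class:`ModelConfig`
    share shapes exactly.
    """

    def __init__(self, arrays: "OrderedDict[str, np.ndarray]"):
        self.arrays: OrderedDict[str, np.ndarray] = OrderedDict(
            (k, np.asarray(v, dtype=np.float64)) for k, v in arrays.items()
        )

    def __getitem__(self, name: str) -> np.ndarray:
        return self.arrays[name]

    def __setitem__(self, name: str, value: np.ndarray) -> None:
        self.arrays[name] = np.asarray(value, dtype=np.float64)

    def __contains__(self, name: str) -> bool:
        return name in self.arrays

    def names(self) -> list[str]:
        return list(self.arrays.keys())

    def items(self):
        return self.arrays.items()

    @property
    def n_params(self) -> int:
        return int(sum(a.size for a in self.arrays.values()))

    def copy(self) -> "ParamVector":
        return ParamVector(OrderedDict((k, a.copy()) for k, a in self.arrays.items()))

    def zeros_like(self) -> "ParamVector":
        return ParamVector(OrderedDict((k, np.zeros_like(a)) for k, a in self.arrays.items()))

    def shapes_match(self, other: "ParamVector") -> bool:
        return (self.names() == other.names()
                and all(self[k].shape == other[k].shape for k in self.names()))

    def to_flat(self) -> np.ndarray:
        if not self.arrays:
            return np.zeros(0)
        return np.concatenate([a.ravel() for a in self.arrays.values()])

    def with_flat(self, flat: np.ndarray) -> "ParamVector":
        """New ParamVector with the same shapes, values taken from ``flat``."""
        flat = np.asarray(flat, dtype=np.float64)
        if flat.size != self.n_params:
            raise StructuralError("flat vector length does not match parameter count")
        out = OrderedDict()
        pos = 0
        for k, a in self.arrays.items():
            out[k] = flat[pos:pos + a.size].reshape(a.shape).copy()
            pos += a.size
        return ParamVector(out)

    def allclose(self, other: "ParamVector", **kw) -> bool:
        return self.shapes_match(other) and all(
            np.allclose(self[k], other[k], **kw) for k in self.names()
        )

    def equal(self, other: "ParamVector") -> bool:
        return self.shapes_match(other) and all(
            np.array_equal(self[k], other[k]) for k in self.names()
        )


@dataclass
class CellState:
    """LSTM recurrent state: hidden vector h and cell vector c."""

    h: np.ndarray
    c: np.ndarray


def _param_shapes(cfg: ModelConfig) -> "OrderedDict[str, tuple]":
    shapes: OrderedDict[str, tuple] = OrderedDict()
    if cfg.cnn_enabled:
        shapes["cnn.w"] = (cfg.cnn_channels, cfg.cnn_kernel, cfg.n_features)
        shapes["cnn.b"] = (cfg.cnn_channels,)
    if cfg.lstm_enabled:
        d = cfg.lstm_input_dim
        h = cfg.lstm_hidden
        for g in _GATES:
            shapes[f"lstm.w_{g}"] = (h, h + d)
        for g in _GATES:
            shapes[f"lstm.b_{g}"] = (h,)
        feat_dim = h
    else:
        feat_dim = cfg.lstm_input_dim  # mean-pooled CNN channels
    if cfg.dense_hidden > 0:
        shapes["dense.w"] = (cfg.dense_hidden, feat_dim)
        shapes["dense.b"] = (cfg.dense_hidden,)
        head_in = cfg.dense_hidden
    else:
        head_in = feat_dim
    shapes["head.w"] = (head_in,)
    shapes["head.b"] = (1,)
    return shapes


def init_params(cfg: ModelConfig) -> ParamVector:
    """Seeded uniform(−init_scale, +init_scale) weights; zero biases.

    Identical (config, seed) produce an element-wise identical vector.
    Raises :class:`ConfigError` if the serialized 32-bit size would
    exceed ``cfg.max_param_bytes``.
    """
    cfg.validate()
    shapes = _param_shapes(cfg)
    count = sum(int(np.prod(s)) for s in shapes.values())
    size = PARAM_HEADER_BYTES + 4 * count
    if cfg.max_param_bytes is not None and size > cfg.max_param_bytes:
        raise ConfigError(
            f"model has {count} parameters ({size} bytes serialized), "
            f"over the {cfg.max_param_bytes}-byte budget"
        )
    rng = np.random.default_rng(cfg.seed)
    arrays: OrderedDict[str, np.ndarray] = OrderedDict()
    for name, shape in shapes.items():
        is_bias = name.split(".")[-1].startswith("b")
        if is_bias:
            arrays[name] = np.zeros(shape)
        else:
            arrays[name] = rng.uniform(-cfg.init_scale, cfg.init_scale, shape)
    return ParamVector(arrays)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=np.float64)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def lstm_step(x_t: np.ndarray, state: CellState, params: ParamVector) -> CellState:
    """One LSTM cell update; supports a single vector or a batch.

    Gate pre-activations act on the concatenation [h_{t−1}, x_t].
    """
    x_t = np.asarray(x_t, dtype=np.float64)
    h, c = np.asarray(state.h, dtype=np.float64), np.asarray(state.c, dtype=np.float64)
    w_i = params["lstm.w_i"]
    hidden = w_i.shape[0]
    d = w_i.shape[1] - hidden
    if x_t.shape[-1] != d or h.shape[-1] != hidden or c.shape[-1] != hidden:
        raise StructuralError(
            f"lstm_step shape mismatch: x {x_t.shape}, h {h.shape}, c {c.shape}, "
            f"expected input dim {d} and hidden {hidden}"
        )
    z = np.concatenate([h, x_t], axis=-1)
    i = _sigmoid(z @ params["lstm.w_i"].T + params["lstm.b_i"])
    f = _sigmoid(z @ params["lstm.w_f"].T + params["lstm.b_f"])
    o = _sigmoid(z @ params["lstm.w_o"].T + params["lstm.b_o"])
    g = np.tanh(z @ params["lstm.w_c"].T + params["lstm.b_c"])
    c_new = f * c + i * g
    h_new = o * np.tanh(c_new)
    return CellState(h=h_new, c=c_new)


def cnn_extract(window: np.ndarray, params: ParamVector, cfg: ModelConfig) -> np.ndarray:
    """Valid 1-D temporal convolution + bias + ReLU over a sensor window.

    Output length is window_len − cnn_kernel + 1 per channel.
    """
    if not cfg.cnn_enabled:
        raise ConfigError("cnn_extract requires cnn_enabled")
    w = params["cnn.w"]
    b = params["cnn.b"]
    x = np.asarray(window, dtype=np.float64)
    single = x.ndim == 2
    if single:
        x = x[None]
    if w.shape[1] > x.shape[1]:
        raise ConfigError("convolution kernel longer than window")
    patches = sliding_window_view(x, w.shape[1], axis=1)  # (B, T', F, K)
    a = np.einsum("btfk,ckf->btc", patches, w) + b
    out = np.maximum(a, 0.0)
    return out[0] if single else out


def _forward_full(X: np.ndarray, params: ParamVector, cfg: ModelConfig):
    """Batched forward pass; returns (p, cache) with everything backprop needs."""
    B = X.shape[0]
    cache: dict = {"X": X}
    if cfg.cnn_enabled:
        w = params["cnn.w"]
        patches = sliding_window_view(X, w.shape[1], axis=1)
        a_cnn = np.einsum("btfk,ckf->btc", patches, w) + params["cnn.b"]
        S = np.maximum(a_cnn, 0.0)
        cache["patches"], cache["a_cnn"] = patches, a_cnn
    else:
        S = X
    cache["S"] = S

    if cfg.lstm_enabled:
        H = cfg.lstm_hidden
        W = np.concatenate([params[f"lstm.w_{g}"] for g in _GATES], axis=0)  # (4H, H+D)
        bias = np.concatenate([params[f"lstm.b_{g}"] for g in _GATES])
        h = np.zeros((B, H))
        c = np.zeros((B, H))
        steps = []
        for t in range(S.shape[1]):
            z = np.concatenate([h, S[:, t, :]], axis=1)
            acts = z @ W.T + bias
            i = _sigmoid(acts[:, 0 * H:1 * H])
            f = _sigmoid(acts[:, 1 * H:2 * H])
            o = _sigmoid(acts[:, 2 * H:3 * H])
            g = np.tanh(acts[:, 3 * H:4 * H])
            c_new = f * c + i * g
            tc = np.tanh(c_new)
            h = o * tc
            steps.append({"z": z, "i": i, "f": f, "o": o, "g": g,
                          "c_prev": c, "c": c_new, "tc": tc})
            c = c_new
        feat = h
        cache["steps"] = steps
    else:
        feat = S.mean(axis=1)
    cache["feat"] = feat

    if cfg.dense_hidden > 0:
        a_d = feat @ params["dense.w"].T + params["dense.b"]
        d = np.maximum(a_d, 0.0)
        cache["a_d"], cache["d"] = a_d, d
    else:
        d = feat
    cache["head_in"] = d
    u = d @ params["head.w"] + params["head.b"][0]
    p = _sigmoid(u)
    cache["u"], cache["p"] = u, p
    return p, cache


def forward(window: np.ndarray, params: ParamVector, cfg: ModelConfig) -> np.ndarray | float:
    """Probability of stress for one window (L × F) or a batch (B × L × F).

    Output is strictly inside (0, 1) for any finite input.
    """
    x = np.asarray(window, dtype=np.float64)
    if not np.isfinite(x).all():
        raise DataError("forward received non-finite input values")
    single = x.ndim == 2
    if single:
        x = x[None]
    if x.shape[1] != cfg.window_len or x.shape[2] != cfg.n_features:
        raise StructuralError(
            f"window shape {x.shape[1:]} does not match config "
            f"({cfg.window_len}, {cfg.n_features})"
        )
    p, _ = _forward_full(x, params, cfg)
    p = np.clip(p, 1e-15, 1.0 - 1e-12)
    return float(p[0]) if single else p


def predict_proba(
    params: ParamVector, X: np.ndarray, cfg: ModelConfig, chunk: int = 1024
) -> np.ndarray:
    """Forward pass over many windows in memory-bounded chunks."""
    X = np.asarray(X, dtype=np.float64)
    out = np.empty(X.shape[0])
    for s in range(0, X.shape[0], chunk):
        p, _ = _forward_full(X[s:s + chunk], params, cfg)
        out[s:s + chunk] = p
    return np.clip(out, 1e-15, 1.0 - 1e-12)


def binary_cross_entropy(p: np.ndarray, z: np.ndarray) -> float:
    """Mean BCE, −[z log p + (1−z) log(1−p)], with p clipped to [1e-7, 1−1e-7]."""
    p = np.clip(np.asarray(p, dtype=np.float64), LOSS_P_EPS, 1.0 - LOSS_P_EPS)
    z = np.asarray(z, dtype=np.float64)
    return float(np.mean(-(z * np.log(p) + (1.0 - z) * np.log1p(-p))))


def local_loss(params: ParamVector, data, cfg: ModelConfig) -> float:
    """Mean binary cross-entropy of the model over a windowed dataset."""
    X, y = _as_arrays(data)
    if X.shape[0] == 0:
        raise DataError("local_loss requires a non-empty dataset")
    p = predict_proba(params, X, cfg)
    return binary_cross_entropy(p, y)


def _as_arrays(data) -> tuple[np.ndarray, np.ndarray]:
    if hasattr(data, "X") and hasattr(data, "y"):
        return np.asarray(data.X, dtype=np.float64), np.asarray(data.y)
    X, y = data
    return np.asarray(X, dtype=np.float64), np.asarray(y)


def loss_and_grad(
    params: ParamVector, X: np.ndarray, y: np.ndarray, cfg: ModelConfig
) -> tuple[float, ParamVector]:
    """Mean BCE over the batch and its gradient w.r.t. every parameter.

    Backpropagation through time, hand-derived; gradients follow the
    exact (unclipped) objective dL/du = p − z.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    B = X.shape[0]
    if B == 0:
        raise DataError("loss_and_grad requires a non-empty batch")
    p, cache = _forward_full(X, params, cfg)
    loss = binary_cross_entropy(p, y)
    grads = params.zeros_like()

    du = (p - y) / B                                # (B,)
    d_in = cache["head_in"]
    grads["head.w"] = d_in.T @ du
    grads["head.b"] = np.array([du.sum()])
    dd = np.outer(du, params["head.w"])             # (B, head_in)

    if cfg.dense_hidden > 0:
        da_d = dd * (cache["a_d"] > 0.0)
        grads["dense.w"] = da_d.T @ cache["feat"]
        grads["dense.b"] = da_d.sum(axis=0)
        dfeat = da_d @ params["dense.w"]
    else:
        dfeat = dd

    S = cache["S"]
    if cfg.lstm_enabled:
        H = cfg.lstm_hidden
        W = np.concatenate([params[f"lstm.w_{g}"] for g in _GATES], axis=0)
        dW = np.zeros_like(W)
        db = np.zeros(4 * H)
        dS = np.zeros_like(S)
        dh = dfeat
        dc = np.zeros_like(dh)
        for t in range(S.shape[1] - 1, -1, -1):
            st = cache["steps"][t]
            i, f, o, g, tc = st["i"], st["f"], st["o"], st["g"], st["tc"]
            do = dh * tc
            dc = dc + dh * o * (1.0 - tc * tc)
            di = dc * g
            df = dc * st["c_prev"]
            dg = dc * i
            dc_prev = dc * f
            da = np.concatenate([
                di * i * (1.0 - i),
                df * f * (1.0 - f),
                do * o * (1.0 - o),
                dg * (1.0 - g * g),
            ], axis=1)                              # (B, 4H)
            dW += da.T @ st["z"]
            db += da.sum(axis=0)
            dz = da @ W
            dh = dz[:, :H]
            dS[:, t, :] = dz[:, H:]
            dc = dc_prev
        for gi, gname in enumerate(_GATES):
            grads[f"lstm.w_{gname}"] = dW[gi * H:(gi + 1) * H]
            grads[f"lstm.b_{gname}"] = db[gi * H:(gi + 1) * H]
    else:
        dS = np.broadcast_to(
            (dfeat / S.shape[1])[:, None, :], S.shape
        ).copy()

    if cfg.cnn_enabled:
        da_cnn = dS * (cache["a_cnn"] > 0.0)
        grads["cnn.w"] = np.einsum("btc,btfk->ckf", da_cnn, cache["patches"])
        grads["cnn.b"] = da_cnn.sum(axis=(0, 1))

    return loss, grads


class AdamState:
    """Adam optimizer state (β1=0.9, β2=0.999, ε=1e-8), fresh per round."""

    def __init__(self, params: ParamVector, lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = params.zeros_like()
        self.v = params.zeros_like()

    def step(self, params: ParamVector, grads: ParamVector) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for name in params.names():
            g = grads[name]
            self.m[name] = b1 * self.m[name] + (1.0 - b1) * g
            self.v[name] = b2 * self.v[name] + (1.0 - b2) * (g * g)
            m_hat = self.m[name] / bc1
            v_hat = self.v[name] / bc2
            params[name] = params[name] - self.lr * m_hat / (np.sqrt(v_hat) + self.eps)


# ---------------------------------------------------------------------------
# Serialization: binary container of named float32 arrays + JSON manifest
# ---------------------------------------------------------------------------

_MAGIC = b"FHPV0001"


def param_size_bytes(params: ParamVector) -> int:
    """Nominal on-air size: elements × 4 bytes (32-bit) + 64-byte header.

    The 64-byte header is a fixed, documented accounting constant (the
    actual container's JSON manifest varies slightly in length); the
    communication ledger uses this figure.
    """
    return PARAM_HEADER_BYTES + 4 * params.n_params


def params_to_bytes(params: ParamVector, config_hash: str | None = None) -> bytes:
    manifest = {
        "dtype": "float32",
        "names": params.names(),
        "shapes": [list(params[n].shape) for n in params.names()],
        "config_hash": config_hash,
    }
    mjson = json.dumps(manifest, sort_keys=True, separators=(",", ":")).encode()
    body = b"".join(
        np.ascontiguousarray(params[n], dtype="<f4").tobytes() for n in params.names()
    )
    return _MAGIC + len(mjson).to_bytes(8, "little") + mjson + body


def params_from_bytes(buf: bytes) -> tuple[ParamVector, dict]:
    if buf[:8] != _MAGIC:
        raise DataError("not a fedherd parameter container")
    mlen = int.from_bytes(buf[8:16], "little")
    manifest = json.loads(buf[16:16 + mlen].decode())
    arrays: OrderedDict[str, np.ndarray] = OrderedDict()
    pos = 16 + mlen
    for name, shape in zip(manifest["names"], manifest["shapes"]):
        size = int(np.prod(shape)) if shape else 1
        nbytes = 4 * size
        arr = np.frombuffer(buf[pos:pos + nbytes], dtype="<f4").reshape(shape)
        arrays[name] = arr.astype(np.float64)
        pos += nbytes
    return ParamVector(arrays), manifest


def save_params(params: ParamVector, path, config_hash: str | None = None) -> None:
    with open(path, "wb") as fh:
        fh.write(params_to_bytes(params, config_hash))


def load_params(path) -> tuple[ParamVector, dict]:
    with open(path, "rb") as fh:
        return params_from_bytes(fh.read())
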