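"""1-D convolutional network for spectral regression, in pure NumPy.

Architecture: a pointwise stem, then ``n_blocks`` downsampling blocks, then
global average pooling and an affine head mapping to the target analytes.
Each block is

    out = skip(x) + alpha * PW(ELU(DW(x)))

where DW is a depthwise (per-channel) convolution with stride 2, PW a
pointwise channel-mixing convolution, and ``alpha`` a learnable scalar
initialised to zero, so every block is an identity map (modulo pooling) at
initialisation and the network starts as a shallow linear model.  The skip
path is parameter-free: average pooling by the stride plus channel
duplication when the width grows.  Channels start at ``base_channels`` and
double every ``channel_growth_every`` blocks up to ``channel_cap``; eight
stride-2 blocks reduce a 2048-point spectrum to length 8 before pooling.

Training minimises mean squared error on z-scored targets with AdamW
(decoupled weight decay) under a linear-warmup / exponential-decay learning
rate schedule.  All forward/backward passes are plain NumPy and are verified
against numeric differentiation in the test suite.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
import numpy as np
from pydantic import BaseModel, Field

from .augment import AugmentConfig, augment_shape, mixup_batch

__all__ = [
    "CNNConfig",
    "TrainConfig",
    "RamanCNN",
    "build_model",
    "lr_schedule",
    "train",
    "TrainingHistory",
]


class CNNConfig(BaseModel):
    n_blocks: int = Field(8, ge=1)
    base_channels: int = Field(16, ge=1)
    channel_growth_every: int = Field(2, ge=1)
    channel_cap: int = Field(128, ge=1)
    kernel_size: int = Field(7, ge=1)
    downsample: int = Field(2, ge=1)
    n_targets: int = Field(2, ge=1)
    residual_scale_init: float = 0.0

    def channel_schedule(self) -> list[int]:
        """Output channels of the stem and of every block."""
        chans = [self.base_channels]
        for i in range(self.n_blocks):
            chans.append(min(self.base_channels * 2 ** ((i + 1) // self.channel_growth_every),
                             self.channel_cap))
        return chans

    def validate_input_length(self, length: int) -> None:
        if length % self.downsample**self.n_blocks != 0:
            raise ValueError(
                f"input length {length} not divisible by "
                f"{self.downsample}^{self.n_blocks}"
            )


class TrainConfig(BaseModel):
    peak_lr: float = Field(3e-3, gt=0)
    weight_decay: float = Field(1e-4, ge=0)
    warmup_epochs: int = Field(20, ge=0)
    gamma: float = Field(0.97, gt=0, lt=1)
    epochs: int = Field(100, ge=0)
    batch_size: int = Field(32, ge=1)
    seed: int = 0
    restore_best: bool = True  # roll back to the best-validation epoch


def lr_schedule(epoch: int, config: TrainConfig) -> float:
    """Linear ramp 0 -> peak over the warm-up, then exponential decay."""
    if epoch < 0:
        raise ValueError("epoch must be >= 0")
    if config.warmup_epochs > 0 and epoch < config.warmup_epochs:
        return config.peak_lr * epoch / config.warmup_epochs
    return config.peak_lr * config.gamma ** (epoch - config.warmup_epochs)


# ---------------------------------------------------------------------------
# layer primitives (forward + backward)

def _elu(x: np.ndarray) -> np.ndarray:
    return np.where(x > 0, x, np.expm1(np.minimum(x, 0.0)))


def _elu_grad(y: np.ndarray, x: np.ndarray) -> np.ndarray:
    return np.where(x > 0, 1.0, y + 1.0)


def _dw_pad(kernel: int, stride: int) -> tuple[int, int]:
    total = kernel - stride
    return total // 2, total - total // 2


def _dwconv(x: np.ndarray, w: np.ndarray, stride: int):
    """Depthwise conv, stride-phase decomposed so every tap is a contiguous slice."""
    b, c, length = x.shape
    k = w.shape[1]
    pl, pr = _dw_pad(k, stride)
    xp = np.pad(x, ((0, 0), (0, 0), (pl, pr)))
    phases = [np.ascontiguousarray(xp[:, :, ph::stride]) for ph in range(stride)]
    l_out = length // stride
    out = np.zeros((b, c, l_out), dtype=x.dtype)
    for j in range(k):
        ph, off = j % stride, j // stride
        out += w[:, j, None] * phases[ph][:, :, off : off + l_out]
    return out, phases


def _dwconv_back(g: np.ndarray, phases: list[np.ndarray], w: np.ndarray, stride: int, length: int):
    k = w.shape[1]
    pl, _ = _dw_pad(k, stride)
    l_out = g.shape[2]
    dw = np.empty_like(w)
    dphases = [np.zeros_like(p) for p in phases]
    for j in range(k):
        ph, off = j % stride, j // stride
        sl = phases[ph][:, :, off : off + l_out]
        dw[:, j] = np.einsum("bcl,bcl->c", g, sl)
        dphases[ph][:, :, off : off + l_out] += w[:, j, None] * g
    dxp = np.empty((g.shape[0], g.shape[1], length + k - stride), dtype=g.dtype)
    for ph in range(stride):
        dxp[:, :, ph::stride] = dphases[ph]
    return dw, dxp[:, :, pl : pl + length]


def _pwconv(x: np.ndarray, w: np.ndarray, bias: np.ndarray) -> np.ndarray:
    return np.matmul(w[None], x) + bias[None, :, None]


def _pwconv_back(g: np.ndarray, x: np.ndarray, w: np.ndarray):
    dw = np.matmul(g, x.transpose(0, 2, 1)).sum(axis=0)
    db = g.sum(axis=(0, 2))
    dx = np.matmul(w.T[None], g)
    return dw, db, dx


def _avgpool(x: np.ndarray, stride: int) -> np.ndarray:
    b, c, length = x.shape
    return x.reshape(b, c, length // stride, stride).mean(axis=-1)


def _avgpool_back(g: np.ndarray, stride: int) -> np.ndarray:
    return np.repeat(g / stride, stride, axis=-1)


def _tile_channels(x: np.ndarray, c_out: int) -> np.ndarray:
    c_in = x.shape[1]
    if c_out == c_in:
        return x
    r = c_out // c_in
    return np.repeat(x, r, axis=1)


def _tile_channels_back(g: np.ndarray, c_in: int) -> np.ndarray:
    b, c_out, length = g.shape
    if c_out == c_in:
        return g
    r = c_out // c_in
    return g.reshape(b, c_in, r, length).sum(axis=2)


_BN_EPS = 1e-5


def _bn(x: np.ndarray, gamma: np.ndarray, beta: np.ndarray,
        running: dict | None, train: bool, momentum: float = 0.9):
    """Per-channel batch normalisation over the (batch, position) axes."""
    if train or running is None or running.get("count", 0) == 0:
        mean = x.mean(axis=(0, 2))
        var = x.var(axis=(0, 2))
        if train and running is not None:
            if running.get("count", 0) == 0:
                running["mean"], running["var"] = mean.copy(), var.copy()
            else:
                running["mean"] = momentum * running["mean"] + (1 - momentum) * mean
                running["var"] = momentum * running["var"] + (1 - momentum) * var
            running["count"] = running.get("count", 0) + 1
    else:
        mean, var = running["mean"], running["var"]
    inv = 1.0 / np.sqrt(var + _BN_EPS)
    xhat = (x - mean[None, :, None]) * inv[None, :, None]
    return gamma[None, :, None] * xhat + beta[None, :, None], (xhat, inv)


def _bn_back(g: np.ndarray, cache, gamma: np.ndarray):
    xhat, inv = cache
    dgamma = np.einsum("bcl,bcl->c", g, xhat)
    dbeta = g.sum(axis=(0, 2))
    m = g.shape[0] * g.shape[2]
    # standard batch-norm backward through the batch statistics
    dx = (gamma * inv)[None, :, None] / m * (
        m * g
        - dbeta[None, :, None]
        - xhat * dgamma[None, :, None]
    )
    return dgamma, dbeta, dx


class RamanCNN:
    """The network: a flat dict of parameter arrays plus forward/backward."""

    def __init__(self, config: CNNConfig, rng: np.random.Generator | int | None = 0,
                 dtype=np.float32):
        self.config = config
        self.dtype = np.dtype(dtype)
        gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
        chans = config.channel_schedule()
        k = config.kernel_size
        p: dict[str, np.ndarray] = {}
        p["stem_w"] = gen.normal(0.0, 1.0, (chans[0], 1))
        p["stem_b"] = np.zeros(chans[0])
        for i in range(config.n_blocks):
            c_in, c_out = chans[i], chans[i + 1]
            p[f"b{i}_dw"] = gen.normal(0.0, np.sqrt(2.0 / k), (c_in, k))
            p[f"b{i}_bng"] = np.ones(c_in)
            p[f"b{i}_bnb"] = np.zeros(c_in)
            p[f"b{i}_pw"] = gen.normal(0.0, np.sqrt(2.0 / c_in), (c_out, c_in))
            p[f"b{i}_pwb"] = np.zeros(c_out)
            p[f"b{i}_alpha"] = np.asarray(float(config.residual_scale_init))
        # He-scale head: with zero-init residual scales the whole early
        # gradient reaches the blocks through this matrix, so it must not
        # start vanishingly small
        p["head_w"] = gen.normal(0.0, np.sqrt(1.0 / chans[-1]), (config.n_targets, chans[-1]))
        p["head_b"] = np.zeros(config.n_targets)
        self.params = {k_: v.astype(self.dtype) for k_, v in p.items()}
        self.bn_running: dict[str, dict] = {f"b{i}": {"count": 0} for i in range(config.n_blocks)}
        self._cache: list | None = None

    def n_parameters(self) -> int:
        return sum(v.size for v in self.params.values())

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """(B, 1, L) or (B, L) -> (B, n_targets)."""
        if x.ndim == 2:
            x = x[:, None, :]
        x = np.ascontiguousarray(x, dtype=self.dtype)
        self.config.validate_input_length(x.shape[2])
        p = self.params
        cache: list = []
        z0 = _pwconv(x, p["stem_w"], p["stem_b"])
        # the stem is nonlinear so that globally pooled features are
        # informative from the first step even while every residual gate is
        # still closed (SNV input pools to zero under any linear map)
        h = _elu(z0)
        cache.append(("stem", x, z0, h))
        s = self.config.downsample
        for i in range(self.config.n_blocks):
            z, phases = _dwconv(h, p[f"b{i}_dw"], s)
            zn, bn_cache = _bn(z, p[f"b{i}_bng"], p[f"b{i}_bnb"],
                               self.bn_running[f"b{i}"], train)
            a = _elu(zn)
            conv = _pwconv(a, p[f"b{i}_pw"], p[f"b{i}_pwb"])
            skip = _tile_channels(_avgpool(h, s), conv.shape[1])
            out = skip + p[f"b{i}_alpha"] * conv
            cache.append(("block", i, h, phases, zn, bn_cache, a, conv))
            h = out
        pooled = h.mean(axis=-1)
        cache.append(("head", h, pooled))
        y = pooled @ p["head_w"].T + p["head_b"]
        self._cache = cache if train else None
        return y

    def backward(self, dy: np.ndarray) -> dict[str, np.ndarray]:
        """Gradient of the scalar loss wrt every parameter; dy = dL/doutput."""
        if self._cache is None:
            raise RuntimeError("call forward(train=True) first")
        p = self.params
        grads: dict[str, np.ndarray] = {}
        tag, h_last, pooled = self._cache[-1]
        assert tag == "head"
        grads["head_w"] = dy.T @ pooled
        grads["head_b"] = dy.sum(axis=0)
        dpooled = dy @ p["head_w"]
        g = np.repeat(dpooled[:, :, None], h_last.shape[2], axis=2) / h_last.shape[2]
        s = self.config.downsample
        for entry in reversed(self._cache[1:-1]):
            _, i, h_in, phases, zn, bn_cache, a, conv = entry
            alpha = p[f"b{i}_alpha"]
            grads[f"b{i}_alpha"] = np.asarray(np.sum(g * conv))
            dconv = alpha * g
            dskip = _tile_channels_back(g, h_in.shape[1])
            dpw, dpwb, da = _pwconv_back(dconv, a, p[f"b{i}_pw"])
            grads[f"b{i}_pw"], grads[f"b{i}_pwb"] = dpw, dpwb
            dzn = da * _elu_grad(a, zn)
            dbng, dbnb, dz = _bn_back(dzn, bn_cache, p[f"b{i}_bng"])
            grads[f"b{i}_bng"], grads[f"b{i}_bnb"] = dbng, dbnb
            ddw, dh = _dwconv_back(dz, phases, p[f"b{i}_dw"], s, h_in.shape[2])
            grads[f"b{i}_dw"] = ddw
            g = dh + _avgpool_back(dskip, s)
        tag, x0, z0, h0 = self._cache[0]
        assert tag == "stem"
        dz0 = g * _elu_grad(h0, z0)
        dsw, dsb, _ = _pwconv_back(dz0, x0, p["stem_w"])
        grads["stem_w"], grads["stem_b"] = dsw, dsb
        return grads

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {k: v.copy() for k, v in self.params.items()}
        for name, r in self.bn_running.items():
            if r.get("count", 0):
                state[f"__{name}_rmean__"] = r["mean"].copy()
                state[f"__{name}_rvar__"] = r["var"].copy()
                state[f"__{name}_rcount__"] = np.asarray(r["count"])
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for k in self.params:
            self.params[k] = np.asarray(state[k]).copy()
        for name in self.bn_running:
            if f"__{name}_rmean__" in state:
                self.bn_running[name] = {
                    "mean": np.asarray(state[f"__{name}_rmean__"]).copy(),
                    "var": np.asarray(state[f"__{name}_rvar__"]).copy(),
                    "count": int(state[f"__{name}_rcount__"]),
                }


def build_model(config: CNNConfig, rng: np.random.Generator | int | None = 0,
                input_length: int | None = None) -> RamanCNN:
    if input_length is not None:
        config.validate_input_length(input_length)
    return RamanCNN(config, rng)


class AdamW:
    """Adam with decoupled weight decay; decay skips biases and scalars.

    The residual gate scalars form their own learning-rate group
    (``alpha_lr_scale``): with zero-initialised gates the whole conv path is
    switched off at the start and the gates see only a weak, noisy gradient,
    so at the shared rate they can dwell near zero for a long time.  A
    larger dedicated rate opens the gates quickly; once real signal flows,
    Adam's variance normalisation keeps their dynamics stable.
    """

    def __init__(self, params: dict[str, np.ndarray], weight_decay: float = 0.0,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8,
                 alpha_lr_scale: float = 10.0):
        self.weight_decay = weight_decay
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.alpha_lr_scale = alpha_lr_scale
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray], lr: float) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k, g in grads.items():
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / (1 - b1**self.t)
            vhat = self.v[k] / (1 - b2**self.t)
            update = mhat / (np.sqrt(vhat) + self.eps)
            rate = lr
            if k.endswith("_alpha"):
                rate = lr * self.alpha_lr_scale
            elif self.weight_decay and k.endswith(("_w", "_dw", "_pw")):
                update = update + self.weight_decay * params[k]
            params[k] = params[k] - rate * update


@dataclass
class TrainingHistory:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    lr: list[float] = field(default_factory=list)
    best_epoch: int | None = None

    def __len__(self) -> int:
        return len(self.train_loss)


def train(
    model: RamanCNN,
    x_train: np.ndarray,
    y_train: np.ndarray,
    x_val: np.ndarray | None,
    y_val: np.ndarray | None,
    train_cfg: TrainConfig,
    augment_cfg: AugmentConfig | None = None,
    wavenumbers: np.ndarray | None = None,
    rng: np.random.Generator | int | None = None,
) -> TrainingHistory:
    """Minimise MSE on z-scored targets; augmentation on training batches only.

    ``x_*`` are harmonised (interpolated + SNV) spectra, ``y_*`` z-scored
    targets.  Deterministic for a fixed seed.
    """
    if x_train.shape[0] == 0:
        raise ValueError("empty training set")
    gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(
        train_cfg.seed if rng is None else rng)
    history = TrainingHistory()
    if train_cfg.epochs == 0:
        return history
    optimizer = AdamW(model.params, weight_decay=train_cfg.weight_decay)
    n = x_train.shape[0]
    if wavenumbers is None:
        wavenumbers = np.arange(x_train.shape[-1], dtype=float)
    for epoch in range(train_cfg.epochs):
        lr = lr_schedule(epoch, train_cfg)
        order = gen.permutation(n)
        losses = []
        for start in range(0, n, train_cfg.batch_size):
            idx = order[start : start + train_cfg.batch_size]
            xb, yb = x_train[idx], y_train[idx]
            if augment_cfg is not None:
                if gen.random() < augment_cfg.probability:
                    xb = augment_shape(xb, wavenumbers, augment_cfg, gen)
                xb, yb = mixup_batch(xb, yb, augment_cfg.mixup_alpha, gen)
            pred = model.forward(xb, train=True)
            err = pred - yb
            losses.append(float(np.mean(err**2)))
            dy = 2.0 * err / err.size
            grads = model.backward(dy)
            optimizer.step(model.params, grads, lr)
        history.train_loss.append(float(np.mean(losses)))
        history.lr.append(lr)
        if x_val is not None and x_val.shape[0]:
            val_pred = predict_in_batches(model, x_val)
            val_loss = float(np.mean((val_pred - y_val) ** 2))
            history.val_loss.append(val_loss)
            if train_cfg.restore_best and val_loss <= min(history.val_loss):
                best_state = model.state_dict()
    if train_cfg.restore_best and history.val_loss:
        model.load_state_dict(best_state)
        history.best_epoch = int(np.argmin(history.val_loss))
    return history


def predict_in_batches(model: RamanCNN, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
    outs = [model.forward(x[i : i + batch_size]) for i in range(0, x.shape[0], batch_size)]
    return np.concatenate(outs, axis=0)


def save_checkpoint(path, model: RamanCNN, extra: dict | None = None) -> None:
    """One .npz archive: parameters + JSON-encoded config and metadata."""
    meta = {"config": model.config.model_dump(), **(extra or {})}
    np.savez(path, __meta__=json.dumps(meta, default=str), **model.state_dict())


def load_checkpoint(path) -> tuple[RamanCNN, dict]:
    data = np.load(path, allow_pickle=False)
    meta = json.loads(str(data["__meta__"]))
    model = RamanCNN(CNNConfig(**meta.pop("config")), rng=0)
    model.load_state_dict({k: data[k] for k in data.files if k != "__meta__"})
    return model, meta
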