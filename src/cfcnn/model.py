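"""The two-branch central-focused CNN, written directly in numpy.

Each branch stacks three blocks of two 3x3 "same" convolutions (each followed
by batch normalisation and a PReLU), with a central pooling layer between
blocks, then a fully connected layer. The two branch outputs are
concatenated, passed through a fused fully connected layer, and a final
linear layer feeds a binary softmax: class 1 = nodule, class 0 = background.
With a 35x35 input the pooling chain is 35 -> 18 -> 9, so the branch FC layer
sees 9 x 9 x C features.

Every layer implements an exact backward pass (verified against finite
differences in the test suite); training is mini-batch SGD with momentum

    V_{t+1} = mu * V_t - alpha_t * grad L(W_t),    W_{t+1} = W_t + V_{t+1}

under the inverse-decay schedule alpha_t = alpha_0 * (1 + gamma * t)^(-p),
minimising mean cross-entropy plus an L1 penalty ``lambda * sum |W|`` over
convolution and fully connected parameters (batch-norm parameters and PReLU
slopes are not penalised).

All arithmetic is float64: the package targets desk-scale CPU verification,
where exact gradient checks matter more than throughput.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .errors import ConfigError, DomainError, GeometryError
from .pooling import PoolingPlan, as_uniform_max_pool, plan_for_axis

# ---------------------------------------------------------------------------
# configuration


@dataclass(frozen=True)
class ModelConfig:
    input_size: int = 35
    channels_3d: int = 3
    channels_2d: int = 2
    conv_filters: tuple[tuple[int, int], ...] = ((36, 36), (72, 72), (108, 108))
    kernel_size: int = 3
    fc_branch: int = 256
    fc_fused: int = 128
    n_classes: int = 2
    prelu_init: float = 0.25
    lambda_l1: float = 5e-4
    pooling: str = "central"  # or "uniform_max"
    dtype: str = "float32"  # compute precision; gradient checks use float64

    def __post_init__(self) -> None:
        if self.kernel_size % 2 == 0:
            raise ConfigError("kernel_size must be odd")
        if any(f < 1 for pair in self.conv_filters for f in pair):
            raise ConfigError("filter counts must be >= 1")
        if self.lambda_l1 < 0:
            raise ConfigError("lambda_l1 must be >= 0")
        if self.pooling not in ("central", "uniform_max"):
            raise ConfigError(f"unknown pooling kind {self.pooling!r}")
        if self.dtype not in ("float32", "float64"):
            raise ConfigError(f"dtype must be float32 or float64, got {self.dtype!r}")

    @staticmethod
    def tiny(pooling: str = "central", dtype: str = "float32") -> "ModelConfig":
        """A shrunken preset for tests and desk-scale training."""
        return ModelConfig(
            conv_filters=((4, 4), (8, 8), (12, 12)),
            fc_branch=32,
            fc_fused=16,
            pooling=pooling,
            dtype=dtype,
        )


@dataclass(frozen=True)
class TrainConfig:
    base_lr: float = 6e-5
    gamma: float = 1e-4
    power: float = 0.75
    momentum: float = 0.9
    batch_size: int = 128
    max_epochs: int = 21
    early_stop_patience: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.base_lr <= 0:
            raise ConfigError("base_lr must be > 0")
        if not 0 <= self.momentum < 1:
            raise ConfigError("momentum must be in [0, 1)")
        if self.batch_size < 1:
            raise ConfigError("batch_size must be >= 1")


# ---------------------------------------------------------------------------
# layers


class Layer:
    """A differentiable unit holding named parameters and their gradients."""

    def params(self) -> dict[str, np.ndarray]:
        return {}

    def grads(self) -> dict[str, np.ndarray]:
        return {}

    def penalized(self) -> tuple[str, ...]:
        """Names of parameters included in the L1 penalty."""
        return ()

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv2d(Layer):
    """3x3 zero-padded 'same' convolution via im2col."""

    def __init__(self, in_ch: int, out_ch: int, k: int, rng: np.random.Generator):
        self.in_ch, self.out_ch, self.k = in_ch, out_ch, k
        fan_in = in_ch * k * k
        fan_out = out_ch * k * k
        bound = np.sqrt(6.0 / (fan_in + fan_out))  # Xavier/Glorot uniform
        self.W = rng.uniform(-bound, bound, size=(out_ch, in_ch, k, k))
        self.b = np.zeros(out_ch)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._cache: tuple | None = None

    def params(self):
        return {"W": self.W, "b": self.b}

    def grads(self):
        return {"W": self.dW, "b": self.db}

    def penalized(self):
        return ("W", "b")

    def forward(self, x, training):
        n, c, h, w = x.shape
        if c != self.in_ch:
            raise GeometryError(f"expected {self.in_ch} channels, got {c}")
        p = self.k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        win = sliding_window_view(xp, (self.k, self.k), axis=(2, 3))
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n, h * w, c * self.k * self.k)
        wmat = self.W.reshape(self.out_ch, -1)
        out = cols @ wmat.T + self.b
        if training:
            self._cache = (cols, (n, c, h, w))
        return out.transpose(0, 2, 1).reshape(n, self.out_ch, h, w)

    def backward(self, grad):
        cols, (n, c, h, w) = self._cache
        g = np.ascontiguousarray(
            grad.reshape(n, self.out_ch, h * w).transpose(0, 2, 1)
        )  # (n, hw, out)
        wmat = self.W.reshape(self.out_ch, -1)
        g2 = g.reshape(n * h * w, self.out_ch)
        self.dW[...] = (g2.T @ cols.reshape(n * h * w, -1)).reshape(self.W.shape)
        self.db[...] = g2.sum(axis=0)
        dcols = g @ wmat  # (n, hw, c*k*k)
        p = self.k // 2
        dxp = np.zeros((n, c, h + 2 * p, w + 2 * p), dtype=grad.dtype)
        # one contiguous relayout, then k*k contiguous scatter-adds
        dcols = np.ascontiguousarray(
            dcols.reshape(n, h, w, c, self.k, self.k).transpose(0, 3, 4, 5, 1, 2)
        )  # (n, c, k, k, h, w)
        for a in range(self.k):
            for bcol in range(self.k):
                dxp[:, :, a : a + h, bcol : bcol + w] += dcols[:, :, a, bcol]
        return dxp[:, :, p : p + h, p : p + w]


class BatchNorm2d(Layer):
    """Per-channel batch normalisation; running statistics at inference."""

    def __init__(self, ch: int, eps: float = 1e-5, momentum: float = 0.1):
        self.gamma = np.ones(ch)
        self.beta = np.zeros(ch)
        self.dgamma = np.zeros(ch)
        self.dbeta = np.zeros(ch)
        self.running_mean = np.zeros(ch)
        self.running_var = np.ones(ch)
        self.eps = eps
        self.momentum = momentum
        self._cache: tuple | None = None

    def params(self):
        return {"gamma": self.gamma, "beta": self.beta}

    def grads(self):
        return {"gamma": self.dgamma, "beta": self.dbeta}

    def forward(self, x, training):
        if training:
            m = x.mean(axis=(0, 2, 3))
            v = x.var(axis=(0, 2, 3))
            count = x.shape[0] * x.shape[2] * x.shape[3]
            unbiased = v * count / max(count - 1, 1)
            self.running_mean += self.momentum * (m - self.running_mean)
            self.running_var += self.momentum * (unbiased - self.running_var)
        else:
            m, v = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(v + self.eps)
        xhat = (x - m[:, None, None]) * inv[:, None, None]
        if training:
            self._cache = (xhat, inv)
        return self.gamma[:, None, None] * xhat + self.beta[:, None, None]

    def backward(self, grad):
        xhat, inv = self._cache
        axes = (0, 2, 3)
        self.dgamma[...] = (grad * xhat).sum(axis=axes)
        self.dbeta[...] = grad.sum(axis=axes)
        dxhat = grad * self.gamma[:, None, None]
        m = grad.shape[0] * grad.shape[2] * grad.shape[3]
        dx = (
            dxhat
            - dxhat.mean(axis=axes, keepdims=True)
            - xhat * (dxhat * xhat).mean(axis=axes, keepdims=True)
        ) * inv[:, None, None]
        return dx


class PReLU(Layer):
    """Parametric ReLU with one trainable slope per channel (or unit)."""

    def __init__(self, ch: int, init: float = 0.25, channel_axis: int = 1):
        self.a = np.full(ch, init, dtype=float)
        self.da = np.zeros(ch)
        self.channel_axis = channel_axis
        self._cache: np.ndarray | None = None

    def params(self):
        return {"a": self.a}

    def grads(self):
        return {"a": self.da}

    def _bshape(self, ndim: int):
        shape = [1] * ndim
        shape[self.channel_axis] = -1
        return shape

    def forward(self, x, training):
        if training:
            self._cache = x
        a = self.a.reshape(self._bshape(x.ndim))
        return np.where(x > 0, x, a * x)

    def backward(self, grad):
        x = self._cache
        neg = x <= 0
        axes = tuple(i for i in range(x.ndim) if i != self.channel_axis)
        self.da[...] = (grad * x * neg).sum(axis=axes)
        a = self.a.reshape(self._bshape(x.ndim))
        return np.where(neg, a * grad, grad)


class CentralPool2d(Layer):
    """Batched central pooling over (N, C, H, W) with exact max routing."""

    def __init__(self, row_plan: PoolingPlan, col_plan: PoolingPlan):
        self.row_plan = row_plan
        self.col_plan = col_plan
        self._row_starts = np.array([s for s, _ in row_plan.segments])
        self._col_starts = np.array([s for s, _ in col_plan.segments])
        self._cache: tuple | None = None

    def forward(self, x, training):
        n, c, h, w = x.shape
        if (h, w) != (self.row_plan.axis_length, self.col_plan.axis_length):
            raise GeometryError(
                f"map {(h, w)} does not match plans "
                f"{(self.row_plan.axis_length, self.col_plan.axis_length)}"
            )
        if not training:
            # row pooling first, then column pooling (values only)
            rows = np.maximum.reduceat(x, self._row_starts, axis=2)
            return np.maximum.reduceat(rows, self._col_starts, axis=3)
        rseg = self.row_plan.segments
        cseg = self.col_plan.segments
        out = np.empty((n, c, len(rseg), len(cseg)), dtype=x.dtype)
        arg_r = np.empty((n, c, len(rseg), len(cseg)), dtype=np.int64)
        arg_c = np.empty_like(arg_r)
        for i, (r0, r1) in enumerate(rseg):
            for j, (c0, c1) in enumerate(cseg):
                win = x[:, :, r0:r1, c0:c1]
                ww = win.shape[3]
                flat = win.reshape(n, c, -1)
                idx = flat.argmax(axis=2)
                out[:, :, i, j] = np.take_along_axis(flat, idx[:, :, None], axis=2)[
                    :, :, 0
                ]
                arg_r[:, :, i, j] = r0 + idx // ww
                arg_c[:, :, i, j] = c0 + idx % ww
        self._cache = (arg_r, arg_c, (n, c, h, w))
        return out

    def backward(self, grad):
        arg_r, arg_c, shape = self._cache
        n, c, h, w = shape
        dx = np.zeros(shape, dtype=grad.dtype)
        nn, cc = np.meshgrid(np.arange(n), np.arange(c), indexing="ij")
        nn = nn[:, :, None, None]
        cc = cc[:, :, None, None]
        np.add.at(dx, (nn, cc, arg_r, arg_c), grad)
        return dx


class Flatten(Layer):
    def forward(self, x, training):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class Linear(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        bound = np.sqrt(6.0 / (n_in + n_out))
        self.W = rng.uniform(-bound, bound, size=(n_in, n_out))
        self.b = np.zeros(n_out)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._cache: np.ndarray | None = None

    def params(self):
        return {"W": self.W, "b": self.b}

    def grads(self):
        return {"W": self.dW, "b": self.db}

    def penalized(self):
        return ("W", "b")

    def forward(self, x, training):
        if training:
            self._cache = x
        return x @ self.W + self.b

    def backward(self, grad):
        x = self._cache
        self.dW[...] = x.T @ grad
        self.db[...] = grad.sum(axis=0)
        return grad @ self.W.T


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x, training):
        for layer in self.layers:
            x = layer.forward(x, training)
        return x

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad


# ---------------------------------------------------------------------------
# the model


def _pool_plan(O: int, kind: str) -> PoolingPlan:
    """Plan for one pooling stage; the uniform ablation keeps output sizes.

    The traditional-max-pooling ablation uses all size-2 kernels; for an odd
    axis one size-1 kernel is appended at the edge so both variants share the
    35 -> 18 -> 9 chain and hence the same parameter count.
    """
    if kind == "central":
        return plan_for_axis(O)
    if O % 2 == 0:
        return as_uniform_max_pool(O)
    n2 = O // 2
    return PoolingPlan(axis_length=O, n1=1, n2=n2, n3=0, residual=0,
                       order=(2,) * n2 + (1,))


def _build_branch(
    in_ch: int, config: ModelConfig, rng: np.random.Generator
) -> tuple[Sequential, int]:
    k = config.kernel_size
    size = config.input_size
    layers: list[Layer] = []
    ch = in_ch
    for block, (f1, f2) in enumerate(config.conv_filters):
        for f in (f1, f2):
            layers += [Conv2d(ch, f, k, rng), BatchNorm2d(f), PReLU(f, config.prelu_init)]
            ch = f
        if block < len(config.conv_filters) - 1:
            if size < 2:
                raise ConfigError(f"spatial size collapsed to {size} before pooling")
            plan = _pool_plan(size, config.pooling)
            layers.append(CentralPool2d(plan, plan))
            size = plan.output_length
    layers.append(Flatten())
    layers.append(Linear(ch * size * size, config.fc_branch, rng))
    layers.append(PReLU(config.fc_branch, config.prelu_init, channel_axis=1))
    return Sequential(layers), config.fc_branch


class CFCNN:
    """Two-branch voxel classifier with central pooling.

    ``forward`` maps a batch of (tri-slice, multi-scale) patch pairs to class
    logits; ``predict_proba`` applies the softmax. Layers cache activations
    during training-mode forwards so that ``backward`` can fill every
    parameter gradient exactly.
    """

    _ARRAY_ATTRS = (
        "W", "b", "dW", "db", "gamma", "beta", "dgamma", "dbeta",
        "running_mean", "running_var", "a", "da",
    )

    def __init__(self, config: ModelConfig, seed: int = 0):
        self.config = config
        self.dtype = np.dtype(config.dtype)
        rng = np.random.default_rng(seed)
        self.branch_3d, width3 = _build_branch(config.channels_3d, config, rng)
        self.branch_2d, width2 = _build_branch(config.channels_2d, config, rng)
        self.fused = Sequential(
            [
                Linear(width3 + width2, config.fc_fused, rng),
                PReLU(config.fc_fused, config.prelu_init, channel_axis=1),
                Linear(config.fc_fused, config.n_classes, rng),
            ]
        )
        self._split = width3
        for _, layer in self._named_layers():
            for attr in self._ARRAY_ATTRS:
                if hasattr(layer, attr):
                    setattr(layer, attr, getattr(layer, attr).astype(self.dtype))

    # -- parameter bookkeeping ------------------------------------------------
    def _named_layers(self):
        for prefix, seq in (
            ("b3d", self.branch_3d),
            ("b2d", self.branch_2d),
            ("head", self.fused),
        ):
            for i, layer in enumerate(seq.layers):
                yield f"{prefix}.{i}.{type(layer).__name__}", layer

    def named_params(self) -> dict[str, np.ndarray]:
        out = {}
        for name, layer in self._named_layers():
            for pname, arr in layer.params().items():
                out[f"{name}.{pname}"] = arr
        return out

    def named_grads(self) -> dict[str, np.ndarray]:
        out = {}
        for name, layer in self._named_layers():
            for pname, arr in layer.grads().items():
                out[f"{name}.{pname}"] = arr
        return out

    def penalized_params(self) -> dict[str, np.ndarray]:
        out = {}
        for name, layer in self._named_layers():
            for pname in layer.penalized():
                out[f"{name}.{pname}"] = layer.params()[pname]
        return out

    def n_parameters(self) -> int:
        return sum(a.size for a in self.named_params().values())

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {k: v.copy() for k, v in self.named_params().items()}
        for name, layer in self._named_layers():
            if isinstance(layer, BatchNorm2d):
                state[f"{name}.running_mean"] = layer.running_mean.copy()
                state[f"{name}.running_var"] = layer.running_var.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = self.named_params()
        for key, arr in state.items():
            if key in params:
                params[key][...] = arr
            elif key.endswith(".running_mean") or key.endswith(".running_var"):
                layer_name, stat = key.rsplit(".", 1)
                for name, layer in self._named_layers():
                    if name == layer_name:
                        getattr(layer, stat)[...] = arr
                        break
                else:
                    raise ConfigError(f"unknown state entry {key}")
            else:
                raise ConfigError(f"unknown state entry {key}")

    # -- forward / backward ---------------------------------------------------
    def forward(self, x3: np.ndarray, x2: np.ndarray, training: bool = False) -> np.ndarray:
        x3 = np.asarray(x3, dtype=self.dtype)
        x2 = np.asarray(x2, dtype=self.dtype)
        if x3.ndim != 4 or x2.ndim != 4 or x3.shape[0] != x2.shape[0]:
            raise GeometryError("inputs must be (N, C, H, W) with matching N")
        h3 = self.branch_3d.forward(x3, training)
        h2 = self.branch_2d.forward(x2, training)
        return self.fused.forward(np.concatenate([h3, h2], axis=1), training)

    def backward(self, dlogits: np.ndarray) -> None:
        dcat = self.fused.backward(dlogits)
        self.branch_3d.backward(dcat[:, : self._split])
        self.branch_2d.backward(dcat[:, self._split :])

    def accumulate_l1_grads(self, lam: float) -> None:
        """Add the L1 subgradient lam*sign(W) into the stored gradients."""
        if lam == 0:
            return
        grads = self.named_grads()
        for key, w in self.penalized_params().items():
            grads[key] += lam * np.sign(w)

    def predict_proba(self, x3: np.ndarray, x2: np.ndarray) -> np.ndarray:
        return softmax(self.forward(x3, x2, training=False))

    def predict_batch(self, patches) -> np.ndarray:
        """Nodule (class 1) probability for a list of :class:`PatchPair`."""
        if len(patches) == 0:
            return np.zeros(0)
        x3 = np.stack([p.three_d for p in patches])
        x2 = np.stack([p.two_d for p in patches])
        return self.predict_proba(x3, x2)[:, 1]


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def build_model(config: ModelConfig, seed: int = 0) -> CFCNN:
    size = config.input_size
    for _ in range(len(config.conv_filters) - 1):
        if size < 2:
            raise ConfigError("input too small for the pooling chain")
        size = _pool_plan(size, config.pooling).output_length
    return CFCNN(config, seed=seed)


# ---------------------------------------------------------------------------
# loss, schedule, optimizer

PROB_EPS = 1e-7


def loss_fn(
    probabilities: np.ndarray,
    labels: np.ndarray,
    weights: dict[str, np.ndarray] | None = None,
    lam: float = 0.0,
) -> float:
    """Mean binary cross-entropy plus an L1 penalty on the given weights.

    ``probabilities`` is the per-sample nodule probability p(y=1); labels are
    0/1. Probabilities are clamped to [eps, 1-eps] before the log.
    """
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels)
    if not np.isin(y, (0, 1)).all():
        raise DomainError("labels must be 0 or 1")
    if p.shape != y.shape or p.size == 0:
        raise GeometryError("probabilities and labels must be same nonempty shape")
    p = np.clip(p, PROB_EPS, 1 - PROB_EPS)
    data = -np.mean(y * np.log(p) + (1 - y) * np.log(1 - p))
    reg = 0.0
    if weights and lam:
        reg = lam * sum(float(np.abs(w).sum()) for w in weights.values())
    return float(data + reg)


def lr_schedule(t: int, cfg: TrainConfig) -> float:
    """Inverse-decay learning rate alpha_t = alpha_0 (1 + gamma t)^(-p)."""
    if t < 0:
        raise DomainError("iteration must be >= 0")
    return cfg.base_lr * (1.0 + cfg.gamma * t) ** (-cfg.power)


@dataclass
class OptimizerState:
    iteration: int = 0
    velocity: dict[str, np.ndarray] = field(default_factory=dict)
    lr: float = 0.0


def sgd_step(
    weights: dict[str, np.ndarray],
    gradient: dict[str, np.ndarray],
    state: OptimizerState,
    cfg: TrainConfig,
) -> OptimizerState:
    """One momentum-SGD update, in place on the weight arrays."""
    alpha = lr_schedule(state.iteration, cfg)
    for key, w in weights.items():
        g = gradient[key]
        if not np.all(np.isfinite(g)):
            raise FloatingPointError(f"non-finite gradient in {key}")
        v = state.velocity.get(key)
        if v is None:
            v = np.zeros_like(w)
        v = cfg.momentum * v - alpha * g
        state.velocity[key] = v
        w += v
    state.iteration += 1
    state.lr = alpha
    return state


# ---------------------------------------------------------------------------
# training loop


def train_step(model: CFCNN, x3, x2, y, state: OptimizerState, cfg: TrainConfig) -> float:
    """Forward, backward and SGD update on one mini-batch; returns the loss."""
    n = len(y)
    logits = model.forward(x3, x2, training=True)
    probs = softmax(logits)
    loss = loss_fn(probs[:, 1], y, model.penalized_params(), model.config.lambda_l1)
    onehot = np.zeros_like(probs)
    onehot[np.arange(n), y] = 1.0
    model.backward((probs - onehot) / n)
    model.accumulate_l1_grads(model.config.lambda_l1)
    sgd_step(model.named_params(), model.named_grads(), state, cfg)
    return loss


def train(
    model: CFCNN,
    train_samples: tuple[np.ndarray, np.ndarray, np.ndarray],
    val_phantoms,
    cfg: TrainConfig,
    threshold: float = 0.5,
) -> dict:
    """Mini-batch SGD with per-epoch validation by full-volume dice.

    Parameters
    ----------
    train_samples : (x3, x2, y)
        Pre-extracted patch arrays (N, 3, s, s), (N, 2, s, s) and labels.
    val_phantoms : sequence of PhantomSample
        After each epoch every validation phantom is segmented end-to-end
        (classify -> component selection -> slice propagation) and scored
        with the dice coefficient; the best-dice weights are retained.

    Returns a history dict with per-epoch mean loss, validation dice and
    learning rate, plus the restored best epoch index.
    """
    from .metrics import dice
    from .segmentation import CfcnnVoxelClassifier, segment
    from .volumes import NoduleMask

    x3, x2, y = train_samples
    n = len(y)
    if n == 0:
        raise ConfigError("empty training set")
    if len(val_phantoms) == 0:
        raise ConfigError("validation set must be nonempty")
    rng = np.random.default_rng(cfg.seed)
    state = OptimizerState()
    history: dict = {"loss": [], "val_dsc": [], "lr": []}
    best = {"dsc": -1.0, "state": model.state_dict(), "epoch": -1}
    stale = 0
    for epoch in range(cfg.max_epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            losses.append(train_step(model, x3[idx], x2[idx], y[idx], state, cfg))
        clf = CfcnnVoxelClassifier(model)
        dscs = []
        for ph in val_phantoms:
            try:
                result = segment(clf, ph.volume, ph.start_box, threshold=threshold)
                dscs.append(dice(ph.mask, NoduleMask(result.mask.labels)))
            except ValueError:
                dscs.append(0.0)
        val_dsc = float(np.mean(dscs))
        history["loss"].append(float(np.mean(losses)))
        history["val_dsc"].append(val_dsc)
        history["lr"].append(state.lr)
        if val_dsc > best["dsc"]:
            best = {"dsc": val_dsc, "state": model.state_dict(), "epoch": epoch}
            stale = 0
        else:
            stale += 1
            if cfg.early_stop_patience is not None and stale >= cfg.early_stop_patience:
                break
    model.load_state_dict(best["state"])
    history["best_epoch"] = best["epoch"]
    history["best_val_dsc"] = best["dsc"]
    return history


# ---------------------------------------------------------------------------
# checkpoints


def save_checkpoint(model: CFCNN, path, train_cfg: TrainConfig | None = None) -> None:
    import json

    meta = {
        "model": {
            **{
                k: (list(v) if isinstance(v, tuple) else v)
                for k, v in vars(model.config).items()
            }
        },
        "train": vars(train_cfg) if train_cfg else None,
    }
    arrays = {k.replace(".", "__"): v for k, v in model.state_dict().items()}
    np.savez(path, __meta__=json.dumps(meta), **arrays)


def load_checkpoint(path) -> CFCNN:
    import json

    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(str(data["__meta__"]))
        mc = meta["model"]
        mc["conv_filters"] = tuple(tuple(p) for p in mc["conv_filters"])
        config = ModelConfig(**mc)
        model = CFCNN(config)
        state = {
            k.replace("__", "."): data[k] for k in data.files if k != "__meta__"
        }
    model.load_state_dict(state)
    return model
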