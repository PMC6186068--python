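"""Forward and backward neural models, in plain NumPy.

The forward model is a convolutional neural network with interpretability
built in: a width-1 sigmoid-activated convolutional filter first compresses
the M factor tracks at each of the 3w input positions into a single chromatin
state

    sigma_i = logistic(sum_j W0_j x_{i,j} + beta0),

a scalar in (0,1) per position (inactive ~ 0, active ~ 1).  The resulting
3w-long state sequence feeds a dense ReLU stack of exponentially increasing
layer sizes whose w(w+1)/2 outputs are the flattened local contact map.

The backward model is an independent dense stack solving the inverse problem:
from the w(w+1)/2 local contacts it predicts the inner w chromatin states
(ReLU hidden layers, sigmoid output).

Both are trained by minibatch stochastic gradient descent on a mean-squared
error cost (plus an L2 penalty on the filter weights for the forward model),
with inverted dropout on the dense hidden layers and early stopping when the
validation cost stops improving.  All gradients are exact reverse-mode
derivatives written out by hand, which also powers the sensitivity analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .window_dataset import DatasetSplit, WindowSample

__all__ = [
    "FilterParams",
    "DenseLayer",
    "DenseStackParams",
    "TrainConfig",
    "TrainHistory",
    "ForwardModel",
    "conv_filter_apply",
    "layer_size_schedule",
    "dense_stack_apply",
    "dense_stack_forward",
    "dense_stack_backward",
    "forward_predict",
    "backward_predict",
    "init_forward_model",
    "init_backward_stack",
    "train_forward",
    "train_backward",
    "orient_forward_model",
]

_ACTIVATIONS = ("relu", "sigmoid", "linear")


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=float)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


@dataclass
class FilterParams:
    """Width-1 convolutional filter: one weight per chromatin factor."""

    W0: np.ndarray  # (M,)
    beta0: float

    def __post_init__(self) -> None:
        self.W0 = np.asarray(self.W0, dtype=float).ravel()
        if not np.all(np.isfinite(self.W0)) or not np.isfinite(self.beta0):
            raise ValueError("filter parameters must be finite")


@dataclass
class DenseLayer:
    W: np.ndarray  # (n_out, n_in)
    b: np.ndarray  # (n_out,)
    activation: str

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        self.b = np.asarray(self.b, dtype=float).ravel()
        if self.activation not in _ACTIVATIONS:
            raise ValueError(f"unknown activation {self.activation!r}")
        if self.W.shape[0] != self.b.shape[0]:
            raise ValueError("W/b size mismatch")


@dataclass
class DenseStackParams:
    layers: list[DenseLayer]

    def __post_init__(self) -> None:
        for a, bnext in zip(self.layers, self.layers[1:]):
            if bnext.W.shape[1] != a.W.shape[0]:
                raise ValueError("consecutive layer dimensions incompatible")

    @property
    def n_in(self) -> int:
        return self.layers[0].W.shape[1]

    @property
    def n_out(self) -> int:
        return self.layers[-1].W.shape[0]

    def copy(self) -> "DenseStackParams":
        return DenseStackParams(
            [DenseLayer(l.W.copy(), l.b.copy(), l.activation) for l in self.layers]
        )


@dataclass
class TrainConfig:
    """Training protocol knobs.

    An epoch is one pass over ``n_batches`` contiguous shards of the shuffled
    training set; the validation cost is evaluated (dropout off) after each
    epoch, and fitting stops once it has failed to improve by a relative
    ``min_delta`` for ``patience`` consecutive epochs.  When it plateaus for
    ``lr_patience`` epochs the learning rate is multiplied by ``lr_decay``
    (set ``lr_decay=1`` for a constant rate).
    """

    n_batches: int = 30
    dropout: float = 0.1
    l2_filter: float = 1e-4
    learning_rate: float = 0.5
    momentum: float = 0.9
    max_epochs: int = 500
    patience: int = 25
    min_delta: float = 1e-4
    lr_decay: float = 0.5
    lr_patience: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must be in [0, 1)")
        if self.n_batches < 1:
            raise ValueError("n_batches must be >= 1")


@dataclass
class TrainHistory:
    train_cost: list[float] = field(default_factory=list)
    val_cost: list[float] = field(default_factory=list)
    best_epoch: int = -1
    stopped_early: bool = False


def conv_filter_apply(x: np.ndarray, params: FilterParams) -> np.ndarray:
    """Chromatin state sequence sigma = logistic(W0 . x_i + beta0) per position.

    ``x`` is (M, L) or batched (B, M, L); the filter has width 1, so positions
    never mix and permuting columns permutes sigma identically.
    """
    x = np.asarray(x, dtype=float)
    if x.shape[-2] != params.W0.shape[0]:
        raise ValueError(
            f"track dimension {x.shape[-2]} != filter size {params.W0.shape[0]}"
        )
    energy = np.einsum("j,...jl->...l", params.W0, x) + params.beta0
    return _sigmoid(energy)


def layer_size_schedule(n_in: int, n_out: int, n_layers: int) -> list[int]:
    """Exponentially interpolated layer sizes from ``n_in`` to ``n_out``.

    size(k) = floor(n_in * (n_out/n_in)^(k/n_layers)) for k = 1..n_layers-1;
    the final layer is exactly ``n_out``.
    """
    if min(n_in, n_out, n_layers) < 1:
        raise ValueError("n_in, n_out and n_layers must be >= 1")
    ratio = n_out / n_in
    sizes = [int(np.floor(n_in * ratio ** (k / n_layers))) for k in range(1, n_layers)]
    return sizes + [n_out]


def dense_stack_forward(
    v: np.ndarray,
    params: DenseStackParams,
    train_mode: bool = False,
    dropout_rate: float = 0.0,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, list[dict]]:
    """Run the stack, returning the output and per-layer caches for backprop.

    In train mode, inverted dropout zeroes each hidden unit independently
    with probability ``dropout_rate`` and rescales survivors by 1/(1-rate);
    the output layer is never dropped.  Inference applies no dropout.
    """
    h = np.asarray(v, dtype=float)
    squeeze = h.ndim == 1
    if squeeze:
        h = h[None, :]
    if h.shape[1] != params.n_in:
        raise ValueError(f"input size {h.shape[1]} != stack input {params.n_in}")
    caches: list[dict] = []
    n_layers = len(params.layers)
    for li, layer in enumerate(params.layers):
        z = h @ layer.W.T + layer.b
        if layer.activation == "relu":
            a = np.maximum(z, 0.0)
        elif layer.activation == "sigmoid":
            a = _sigmoid(z)
        else:
            a = z
        mask = None
        if train_mode and dropout_rate > 0 and li < n_layers - 1:
            if rng is None:
                raise ValueError("rng required for dropout in train mode")
            keep = 1.0 - dropout_rate
            mask = (rng.random(a.shape) < keep) / keep
            a = a * mask
        caches.append({"input": h, "z": z, "act": a, "mask": mask})
        h = a
    if np.isnan(h).any():
        raise FloatingPointError("NaN encountered in dense stack output")
    return (h[0] if squeeze else h), caches


def dense_stack_apply(
    v: np.ndarray,
    params: DenseStackParams,
    train_mode: bool = False,
    dropout_rate: float = 0.0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Stack output only (see :func:`dense_stack_forward`)."""
    out, _ = dense_stack_forward(v, params, train_mode, dropout_rate, rng)
    return out


def dense_stack_backward(
    params: DenseStackParams, caches: list[dict], grad_out: np.ndarray
) -> tuple[list[tuple[np.ndarray, np.ndarray]], np.ndarray]:
    """Reverse-mode pass: (per-layer (dW, db) grads, gradient w.r.t. input).

    ``grad_out`` is (B, n_out), the cost gradient at the stack output.  The
    ReLU subgradient at exactly 0 is taken as 0.
    """
    grads: list[tuple[np.ndarray, np.ndarray]] = [None] * len(params.layers)  # type: ignore
    g = np.asarray(grad_out, dtype=float)
    for li in range(len(params.layers) - 1, -1, -1):
        layer = params.layers[li]
        cache = caches[li]
        if cache["mask"] is not None:
            g = g * cache["mask"]
        if layer.activation == "relu":
            g = g * (cache["z"] > 0)
        elif layer.activation == "sigmoid":
            s = _sigmoid(cache["z"])
            g = g * s * (1.0 - s)
        dW = g.T @ cache["input"]
        db = g.sum(axis=0)
        grads[li] = (dW, db)
        g = g @ layer.W
    return grads, g


def forward_predict(
    input_block: np.ndarray, filt: FilterParams, stack: DenseStackParams
) -> np.ndarray:
    """Forward-model prediction: conv filter then dense stack (no dropout)."""
    sigma = conv_filter_apply(input_block, filt)
    return dense_stack_apply(sigma, stack)


def backward_predict(target_vec: np.ndarray, stack: DenseStackParams) -> np.ndarray:
    """Backward-model prediction: local contact vector -> inner-w sigma."""
    return dense_stack_apply(target_vec, stack)


def _init_stack(
    sizes_in: int, sizes: list[int], activations: list[str], rng: np.random.Generator
) -> DenseStackParams:
    layers = []
    n_prev = sizes_in
    for n, act in zip(sizes, activations):
        if act == "relu":  # He init
            scale = np.sqrt(2.0 / n_prev)
        else:  # Glorot init for sigmoid/linear
            scale = np.sqrt(2.0 / (n_prev + n))
        W = rng.normal(0.0, scale, size=(n, n_prev))
        layers.append(DenseLayer(W=W, b=np.zeros(n), activation=act))
        n_prev = n
    return DenseStackParams(layers)


@dataclass
class ForwardModel:
    filter: FilterParams
    stack: DenseStackParams
    w: int

    def predict(self, input_block: np.ndarray) -> np.ndarray:
        return forward_predict(input_block, self.filter, self.stack)

    def states(self, input_block: np.ndarray) -> np.ndarray:
        return conv_filter_apply(input_block, self.filter)


def init_forward_model(
    n_factors: int,
    w: int,
    n_layers: int = 4,
    output_activation: str = "relu",
    seed: int = 0,
) -> ForwardModel:
    """Freshly initialised forward model for M factors and window size w.

    The dense stack is sized by :func:`layer_size_schedule` from the 3w-long
    state sequence to the w(w+1)/2 contact outputs; every layer is ReLU
    (``output_activation`` switches the last layer if desired).
    """
    rng = np.random.default_rng(seed)
    n_in, n_out = 3 * w, w * (w + 1) // 2
    sizes = layer_size_schedule(n_in, n_out, n_layers)
    acts = ["relu"] * (n_layers - 1) + [output_activation]
    stack = _init_stack(n_in, sizes, acts, rng)
    scale = np.sqrt(2.0 / (n_factors + 1))
    filt = FilterParams(W0=rng.normal(0.0, scale, size=n_factors), beta0=0.0)
    return ForwardModel(filter=filt, stack=stack, w=w)


def init_backward_stack(w: int, n_layers: int = 3, seed: int = 0) -> DenseStackParams:
    """Backward model: w(w+1)/2 contacts -> inner w states, sigmoid output."""
    rng = np.random.default_rng(seed)
    n_in, n_out = w * (w + 1) // 2, w
    sizes = layer_size_schedule(n_in, n_out, n_layers)
    acts = ["relu"] * (n_layers - 1) + ["sigmoid"]
    return _init_stack(n_in, sizes, acts, rng)


def _stack_arrays(samples: list[WindowSample]) -> tuple[np.ndarray, np.ndarray]:
    X = np.stack([s.input_block for s in samples])
    Y = np.stack([s.target for s in samples])
    return X, Y


class _Momentum:
    """SGD-with-momentum state for a flat list of parameter arrays."""

    def __init__(self, shapes: list[tuple]) -> None:
        self.v = [np.zeros(s) for s in shapes]

    def step(self, params: list[np.ndarray], grads: list[np.ndarray], lr: float, mom: float) -> None:
        for p, g, v in zip(params, grads, self.v):
            v *= mom
            v -= lr * g
            p += v


def _epoch_shards(
    n: int, n_batches: int, rng: np.random.Generator
) -> list[np.ndarray]:
    order = rng.permutation(n)
    return [shard for shard in np.array_split(order, n_batches) if len(shard)]


def train_forward(
    split: DatasetSplit,
    cfg: TrainConfig,
    model: ForwardModel | None = None,
    n_layers: int = 4,
    output_activation: str = "relu",
) -> tuple[ForwardModel, TrainHistory]:
    """Fit the forward model by minibatch SGD with momentum.

    Cost = MSE between predicted and observed distance-normalized contacts
    + l2_filter * ||W0||^2.  Dropout acts on the dense hidden layers only,
    never on the filter output.  Returns the parameters with the best
    validation cost seen.
    """
    if not split.train or not split.validation:
        raise ValueError("train and validation sets must be non-empty")
    Xtr, Ytr = _stack_arrays(split.train)
    Xva, Yva = _stack_arrays(split.validation)
    n_factors, three_w = Xtr.shape[1], Xtr.shape[2]
    w = three_w // 3
    if model is None:
        model = init_forward_model(
            n_factors, w, n_layers=n_layers,
            output_activation=output_activation, seed=cfg.seed,
        )
    rng = np.random.default_rng(cfg.seed + 1)
    stack = model.stack
    filt = model.filter
    beta0 = np.array([filt.beta0], dtype=float)
    params = [filt.W0, beta0]
    for layer in stack.layers:
        params.extend([layer.W, layer.b])
    opt = _Momentum([p.shape for p in params])
    history = TrainHistory()
    best_cost = np.inf
    best_state = None
    since_best = 0
    lr = cfg.learning_rate

    def val_cost() -> float:
        pred = forward_predict(Xva, FilterParams(filt.W0, float(beta0[0])), stack)
        return float(np.mean((pred - Yva) ** 2) + cfg.l2_filter * np.sum(filt.W0**2))

    for epoch in range(cfg.max_epochs):
        epoch_cost = 0.0
        n_seen = 0
        for shard in _epoch_shards(len(Xtr), cfg.n_batches, rng):
            xb, yb = Xtr[shard], Ytr[shard]
            energy = np.einsum("j,bjl->bl", filt.W0, xb) + beta0[0]
            sigma = _sigmoid(energy)
            pred, caches = dense_stack_forward(
                sigma, stack, train_mode=True, dropout_rate=cfg.dropout, rng=rng
            )
            resid = pred - yb
            cost = float(np.mean(resid**2) + cfg.l2_filter * np.sum(filt.W0**2))
            epoch_cost += cost * len(shard)
            n_seen += len(shard)
            grad_out = 2.0 * resid / resid.size
            layer_grads, grad_sigma = dense_stack_backward(stack, caches, grad_out)
            grad_E = grad_sigma * sigma * (1.0 - sigma)
            gW0 = np.einsum("bl,bjl->j", grad_E, xb) + 2.0 * cfg.l2_filter * filt.W0
            gb0 = np.array([grad_E.sum()])
            flat_grads = [gW0, gb0]
            for gW, gb in layer_grads:
                flat_grads.extend([gW, gb])
            opt.step(params, flat_grads, lr, cfg.momentum)
        history.train_cost.append(epoch_cost / max(n_seen, 1))
        vc = val_cost()
        if not np.isfinite(vc):
            raise FloatingPointError(
                f"validation cost diverged at epoch {epoch}: {vc}"
            )
        history.val_cost.append(vc)
        if vc < best_cost * (1.0 - cfg.min_delta):
            best_cost = vc
            history.best_epoch = epoch
            best_state = (filt.W0.copy(), float(beta0[0]), stack.copy())
            since_best = 0
        else:
            since_best += 1
            if since_best >= cfg.patience:
                history.stopped_early = True
                break
            if cfg.lr_decay < 1.0 and since_best % cfg.lr_patience == 0:
                lr *= cfg.lr_decay
    if best_state is None:
        best_state = (filt.W0.copy(), float(beta0[0]), stack.copy())
    W0, b0, best_stack = best_state
    return ForwardModel(filter=FilterParams(W0, b0), stack=best_stack, w=w), history


def train_backward(
    inputs: np.ndarray,
    labels: np.ndarray,
    val_inputs: np.ndarray,
    val_labels: np.ndarray,
    cfg: TrainConfig,
    stack: DenseStackParams | None = None,
    n_layers: int = 3,
) -> tuple[DenseStackParams, TrainHistory]:
    """Fit the backward model (contacts -> inner-w sigma) by the same protocol.

    ``labels`` are the forward model's chromatin states restricted to the
    inner w positions; the loss is plain MSE on sigma.  ``cfg.max_epochs = 0``
    returns the initialization unchanged.
    """
    inputs = np.asarray(inputs, dtype=float)
    labels = np.asarray(labels, dtype=float)
    w = labels.shape[1]
    if stack is None:
        stack = init_backward_stack(w, n_layers=n_layers, seed=cfg.seed)
    rng = np.random.default_rng(cfg.seed + 1)
    params = []
    for layer in stack.layers:
        params.extend([layer.W, layer.b])
    opt = _Momentum([p.shape for p in params])
    history = TrainHistory()
    best_cost = np.inf
    best_state = None
    since_best = 0
    lr = cfg.learning_rate
    for epoch in range(cfg.max_epochs):
        epoch_cost = 0.0
        n_seen = 0
        for shard in _epoch_shards(len(inputs), cfg.n_batches, rng):
            xb, yb = inputs[shard], labels[shard]
            pred, caches = dense_stack_forward(
                xb, stack, train_mode=True, dropout_rate=cfg.dropout, rng=rng
            )
            resid = pred - yb
            epoch_cost += float(np.mean(resid**2)) * len(shard)
            n_seen += len(shard)
            grad_out = 2.0 * resid / resid.size
            layer_grads, _ = dense_stack_backward(stack, caches, grad_out)
            flat_grads = []
            for gW, gb in layer_grads:
                flat_grads.extend([gW, gb])
            opt.step(params, flat_grads, lr, cfg.momentum)
        history.train_cost.append(epoch_cost / max(n_seen, 1))
        vc = float(np.mean((dense_stack_apply(val_inputs, stack) - val_labels) ** 2))
        if not np.isfinite(vc):
            raise FloatingPointError(f"validation cost diverged at epoch {epoch}")
        history.val_cost.append(vc)
        if vc < best_cost * (1.0 - cfg.min_delta):
            best_cost = vc
            history.best_epoch = epoch
            best_state = stack.copy()
            since_best = 0
        else:
            since_best += 1
            if since_best >= cfg.patience:
                history.stopped_early = True
                break
            if cfg.lr_decay < 1.0 and since_best % cfg.lr_patience == 0:
                lr *= cfg.lr_decay
    if best_state is None:
        best_state = stack.copy()
    return best_state, history


def orient_forward_model(
    model: ForwardModel, sample_blocks: np.ndarray, reference_index: int = 0
) -> tuple[ForwardModel, bool]:
    """Resolve the sigma vs 1-sigma ambiguity of the learned filter.

    The model output is invariant under (W0, beta0) -> (-W0, -beta0) combined
    with W1 -> -W1, b1 -> b1 + W1 @ 1 in the first dense layer (this maps
    sigma -> 1 - sigma exactly).  The filter is oriented so that sigma
    correlates positively with the designated active reference track (row
    ``reference_index`` of the input blocks), evaluated on ``sample_blocks``
    (B, M, L).

    Returns the (possibly reparameterised) model and whether it was flipped.
    """
    sigma = model.states(sample_blocks).ravel()
    ref = np.asarray(sample_blocks, dtype=float)[:, reference_index, :].ravel()
    corr = np.corrcoef(sigma, ref)[0, 1]
    if not corr < 0:
        return model, False
    first = model.stack.layers[0]
    new_first = DenseLayer(
        W=-first.W, b=first.b + first.W.sum(axis=1), activation=first.activation
    )
    new_stack = DenseStackParams([new_first] + model.stack.layers[1:])
    new_filt = FilterParams(W0=-model.filter.W0, beta0=-model.filter.beta0)
    return ForwardModel(filter=new_filt, stack=new_stack, w=model.w), True
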