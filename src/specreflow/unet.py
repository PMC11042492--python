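"""Compact "Light U-net" for specular-highlight segmentation, in pure NumPy.

The network is a standard U-net shrunk to four resolution levels and eight
initial filters: each level is two 3x3 convolutions with batch
normalization and ReLU, levels are joined by 2x2 max-pooling on the way
down and 2x2 stride-2 transposed convolutions (followed by batch norm) on
the way up, with skip connections concatenated before each decoder block,
and a final 1x1 convolution with a sigmoid produces a per-pixel highlight
probability.  With the default configuration the trainable parameter count
is exactly 121,641 (convolution weights and biases plus the affine batch
norm parameters).

Training uses an equal-weight sum of soft-Dice loss and binary
cross-entropy, Adam (initial learning rate 0.01, beta1 0.9, beta2 0.999),
and a reduce-on-plateau schedule (patience 10, factor 0.1), for up to 120
epochs at batch size 8.  Forward, backward, optimizer and scheduler are
all implemented here; the network is small enough that an im2col NumPy
implementation trains a scaled-down synthetic task in minutes on one CPU.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Optional, Sequence

import numpy as np

__all__ = [
    "LightUNetConfig",
    "TrainConfig",
    "TrainingHistory",
    "LightUNet",
    "ReduceLROnPlateau",
    "build_light_unet",
    "train_light_unet",
    "predict_unet_mask",
    "dice_bce_loss",
]


# ---------------------------------------------------------------------------
# configs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LightUNetConfig:
    """Architecture hyperparameters.

    ``depth`` counts resolution levels (so ``depth - 1`` poolings);
    channels double per level starting from ``base_filters``.
    """

    depth: int = 4
    base_filters: int = 8
    in_channels: int = 3
    out_channels: int = 1
    norm: str = "batch"  # batch | none
    upsample: str = "transposed-conv"  # transposed-conv | bilinear+conv

    def __post_init__(self) -> None:
        if self.depth < 2:
            raise ValueError("depth must be at least 2")
        if self.base_filters < 1:
            raise ValueError("base_filters must be at least 1")
        if self.norm not in ("batch", "none"):
            raise ValueError(f"unknown norm {self.norm!r}")
        if self.upsample not in ("transposed-conv", "bilinear+conv"):
            raise ValueError(f"unknown upsample mode {self.upsample!r}")


@dataclass(frozen=True)
class TrainConfig:
    """Optimization recipe: Adam + reduce-on-plateau, Dice + BCE loss."""

    epochs: int = 120
    batch_size: int = 8
    learning_rate: float = 0.01
    beta1: float = 0.9
    beta2: float = 0.999
    plateau_patience: int = 10
    plateau_factor: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("epochs", "batch_size", "learning_rate", "plateau_patience",
                     "plateau_factor"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.epochs > 120:
            raise ValueError("epochs capped at 120; longer training overfits")


@dataclass
class TrainingHistory:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    train_dice: list[float] = field(default_factory=list)
    val_dice: list[float] = field(default_factory=list)
    learning_rate: list[float] = field(default_factory=list)


# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------
# Data layout is NCHW float64 throughout.  Each layer caches what its
# backward pass needs; ``params()`` yields (array, grad) pairs for Adam.

class _Layer:
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def params(self) -> Iterator[tuple[np.ndarray, np.ndarray]]:
        return iter(())


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(N, C, H, W) -> (N, H, W, C*k*k) patches of a zero-padded input."""
    n, c, h, w = x.shape
    p = k // 2
    xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
    windows = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
    # windows: (N, C, H, W, k, k) -> (N, H, W, C*k*k)
    return windows.transpose(0, 2, 3, 1, 4, 5).reshape(n, h, w, c * k * k)


class Conv2D(_Layer):
    """Same-padded k x k convolution with bias."""

    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator):
        self.cin, self.cout, self.k = cin, cout, k
        fan_in = cin * k * k
        # He initialization, suitable for the ReLU blocks
        self.weight = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(cout, cin, k, k))
        self.bias = np.zeros(cout)
        self.grad_weight = np.zeros_like(self.weight)
        self.grad_bias = np.zeros_like(self.bias)
        self._cols: Optional[np.ndarray] = None
        self._in_shape: Optional[tuple] = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        cols = _im2col(x, self.k)  # (N, H, W, C*k*k)
        w2 = self.weight.reshape(self.cout, -1)
        out = cols @ w2.T + self.bias  # (N, H, W, cout)
        if train:
            self._cols = cols
            self._in_shape = x.shape
        return out.transpose(0, 3, 1, 2)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, _, h, w = grad.shape
        g = grad.transpose(0, 2, 3, 1).reshape(-1, self.cout)  # (NHW, cout)
        cols = self._cols.reshape(-1, self.cin * self.k * self.k)
        self.grad_weight += (g.T @ cols).reshape(self.weight.shape)
        self.grad_bias += g.sum(axis=0)
        gcols = g @ self.weight.reshape(self.cout, -1)  # (NHW, C*k*k)
        gcols = gcols.reshape(n, h, w, self.cin, self.k, self.k)
        # scatter-add the patch gradients back onto the padded input
        p = self.k // 2
        gx = np.zeros((n, self.cin, h + 2 * p, w + 2 * p))
        for di in range(self.k):
            for dj in range(self.k):
                gx[:, :, di : di + h, dj : dj + w] += gcols[:, :, :, :, di, dj].transpose(0, 3, 1, 2)
        self._cols = None
        return gx[:, :, p : p + h, p : p + w] if p else gx

    def params(self):
        yield self.weight, self.grad_weight
        yield self.bias, self.grad_bias


class ConvTranspose2x2(_Layer):
    """2x2, stride-2 transposed convolution (non-overlapping upsampling)."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        self.cin, self.cout = cin, cout
        fan_in = cin  # each output pixel sees exactly one input pixel
        self.weight = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(cin, cout, 2, 2))
        self.bias = np.zeros(cout)
        self.grad_weight = np.zeros_like(self.weight)
        self.grad_bias = np.zeros_like(self.bias)
        self._x: Optional[np.ndarray] = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        n, c, h, w = x.shape
        out = np.einsum("nchw,cokl->nohkwl", x, self.weight, optimize=True)
        out = out.reshape(n, self.cout, 2 * h, 2 * w) + self.bias[None, :, None, None]
        if train:
            self._x = x
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, _, h2, w2 = grad.shape
        h, w = h2 // 2, w2 // 2
        g = grad.reshape(n, self.cout, h, 2, w, 2)  # (n, o, h, k, w, l)
        self.grad_weight += np.einsum("nchw,nohkwl->cokl", self._x, g, optimize=True)
        self.grad_bias += grad.sum(axis=(0, 2, 3))
        gx = np.einsum("nohkwl,cokl->nchw", g, self.weight, optimize=True)
        self._x = None
        return gx

    def params(self):
        yield self.weight, self.grad_weight
        yield self.bias, self.grad_bias


class BilinearUpConv(_Layer):
    """2x nearest upsample followed by a 1x1 conv (alternative up path)."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        self.conv = Conv2D(cin, cout, 1, rng)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        up = x.repeat(2, axis=2).repeat(2, axis=3)
        return self.conv.forward(up, train)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        g = self.conv.backward(grad)
        n, c, h2, w2 = g.shape
        return g.reshape(n, c, h2 // 2, 2, w2 // 2, 2).sum(axis=(3, 5))

    def params(self):
        return self.conv.params()


class BatchNorm2D(_Layer):
    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = np.ones(c)
        self.beta = np.zeros(c)
        self.grad_gamma = np.zeros_like(self.gamma)
        self.grad_beta = np.zeros_like(self.beta)
        self.running_mean = np.zeros(c)
        self.running_var = np.ones(c)
        self.momentum = momentum
        self.eps = eps
        self._cache: Optional[tuple] = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv_std[None, :, None, None]
        if train:
            self._cache = (xhat, inv_std)
        return self.gamma[None, :, None, None] * xhat + self.beta[None, :, None, None]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        xhat, inv_std = self._cache
        self._cache = None
        m = grad.shape[0] * grad.shape[2] * grad.shape[3]
        self.grad_gamma += (grad * xhat).sum(axis=(0, 2, 3))
        self.grad_beta += grad.sum(axis=(0, 2, 3))
        gxhat = grad * self.gamma[None, :, None, None]
        mean_g = gxhat.mean(axis=(0, 2, 3))[None, :, None, None]
        mean_gx = (gxhat * xhat).mean(axis=(0, 2, 3))[None, :, None, None]
        return inv_std[None, :, None, None] * (gxhat - mean_g - xhat * mean_gx)

    def params(self):
        yield self.gamma, self.grad_gamma
        yield self.beta, self.grad_beta


class ReLU(_Layer):
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        mask = x > 0
        if train:
            self._mask = mask
        return x * mask

    def backward(self, grad: np.ndarray) -> np.ndarray:
        g = grad * self._mask
        self._mask = None
        return g


class MaxPool2x2(_Layer):
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        n, c, h, w = x.shape
        xr = (
            x.reshape(n, c, h // 2, 2, w // 2, 2)
            .transpose(0, 1, 2, 4, 3, 5)
            .reshape(n, c, h // 2, w // 2, 4)
        )
        idx = xr.argmax(axis=-1)
        out = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]
        if train:
            # argmax breaks ties toward the first position, so gradients
            # are never duplicated across tied pixels
            sel = np.zeros(xr.shape, dtype=bool)
            np.put_along_axis(sel, idx[..., None], True, axis=-1)
            self._sel = sel
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, c, h2, w2 = grad.shape
        g = self._sel * grad[..., None]
        self._sel = None
        return (
            g.reshape(n, c, h2, w2, 2, 2)
            .transpose(0, 1, 2, 4, 3, 5)
            .reshape(n, c, 2 * h2, 2 * w2)
        )


# ---------------------------------------------------------------------------
# the network
# ---------------------------------------------------------------------------

class _Block:
    """conv-(bn)-relu twice."""

    def __init__(self, cin: int, cout: int, cfg: LightUNetConfig, rng):
        self.layers: list[_Layer] = []
        for i, (a, b) in enumerate([(cin, cout), (cout, cout)]):
            self.layers.append(Conv2D(a, b, 3, rng))
            if cfg.norm == "batch":
                self.layers.append(BatchNorm2D(b))
            self.layers.append(ReLU())

    def forward(self, x, train):
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def params(self):
        for layer in self.layers:
            yield from layer.params()


class LightUNet:
    """Encoder-decoder highlight segmenter; see module docstring."""

    def __init__(self, config: LightUNetConfig = LightUNetConfig(), seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        ch = [config.base_filters * 2**i for i in range(config.depth)]
        self.enc = []
        cin = config.in_channels
        for c in ch:
            self.enc.append(_Block(cin, c, config, rng))
            cin = c
        self.pools = [MaxPool2x2() for _ in range(config.depth - 1)]
        self.ups: list[_Layer] = []
        self.up_norms: list[Optional[BatchNorm2D]] = []
        self.dec = []
        for i in range(config.depth - 2, -1, -1):
            if config.upsample == "transposed-conv":
                self.ups.append(ConvTranspose2x2(ch[i + 1], ch[i], rng))
            else:
                self.ups.append(BilinearUpConv(ch[i + 1], ch[i], rng))
            self.up_norms.append(BatchNorm2D(ch[i]) if config.norm == "batch" else None)
            self.dec.append(_Block(2 * ch[i], ch[i], config, rng))
        self.final = Conv2D(ch[0], config.out_channels, 1, rng)
        self._cache: Optional[dict] = None

    # -- plumbing ----------------------------------------------------------

    def _all_layers(self) -> Iterator[_Layer]:
        for b in self.enc:
            yield from b.layers
        yield from self.pools
        for up, norm, dec in zip(self.ups, self.up_norms, self.dec):
            yield up
            if norm is not None:
                yield norm
            yield from dec.layers
        yield self.final

    def params(self) -> list[tuple[np.ndarray, np.ndarray]]:
        out = []
        for layer in self._all_layers():
            out.extend(layer.params())
        return out

    def count_parameters(self) -> int:
        return int(sum(p.size for p, _ in self.params()))

    def zero_grad(self) -> None:
        for _, g in self.params():
            g[...] = 0.0

    def state_dict(self) -> list[np.ndarray]:
        state = [p.copy() for p, _ in self.params()]
        for layer in self._all_layers():
            if isinstance(layer, BatchNorm2D):
                state.append(layer.running_mean.copy())
                state.append(layer.running_var.copy())
        return state

    def load_state_dict(self, state: Sequence[np.ndarray]) -> None:
        params = self.params()
        for (p, _), s in zip(params, state[: len(params)]):
            p[...] = s
        rest = iter(state[len(params) :])
        for layer in self._all_layers():
            if isinstance(layer, BatchNorm2D):
                layer.running_mean[...] = next(rest)
                layer.running_var[...] = next(rest)

    # -- forward / backward ------------------------------------------------

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """x: (N, C, H, W) float in [0, 1]; returns sigmoid probabilities.

        H and W must be divisible by ``2**(depth-1)``; `predict_unet_mask`
        handles padding for arbitrary sizes.
        """
        factor = 2 ** (self.config.depth - 1)
        if x.shape[2] % factor or x.shape[3] % factor:
            raise ValueError(
                f"input spatial dims {x.shape[2:]} must be divisible by {factor}"
            )
        skips = []
        for i, block in enumerate(self.enc):
            x = block.forward(x, train)
            if i < len(self.pools):
                skips.append(x)
                x = self.pools[i].forward(x, train)
        for up, norm, dec in zip(self.ups, self.up_norms, self.dec):
            x = up.forward(x, train)
            if norm is not None:
                x = norm.forward(x, train)
            skip = skips.pop()
            x = np.concatenate([skip, x], axis=1)
            x = dec.forward(x, train)
        logits = self.final.forward(x, train)
        prob = 1.0 / (1.0 + np.exp(-logits))
        if train:
            self._prob = prob
        return prob

    def backward(self, grad_prob: np.ndarray) -> None:
        """Backprop from dLoss/dProb through the whole network."""
        prob = self._prob
        grad = grad_prob * prob * (1.0 - prob)  # through the sigmoid
        self._prob = None
        grad = self.final.backward(grad)
        # dec[j] handles level depth-2-j; walking dec in reverse goes from
        # the shallowest decoder (nearest the output) down to the deepest,
        # so skip gradients come out in encoder order enc[0] .. enc[depth-2]
        skip_grads = []
        for i in range(len(self.dec) - 1, -1, -1):
            grad = self.dec[i].backward(grad)
            c = grad.shape[1] // 2
            skip_grads.append(grad[:, :c])
            grad = grad[:, c:]
            if self.up_norms[i] is not None:
                grad = self.up_norms[i].backward(grad)
            grad = self.ups[i].backward(grad)
        for i in range(len(self.enc) - 1, -1, -1):
            if i < len(self.pools):
                grad = self.pools[i].backward(grad)
                grad = grad + skip_grads.pop()
            grad = self.enc[i].backward(grad)


def build_light_unet(config: LightUNetConfig = LightUNetConfig(), seed: int = 0) -> LightUNet:
    """Construct the segmentation network (defaults give 121,641 parameters)."""
    return LightUNet(config, seed=seed)


# ---------------------------------------------------------------------------
# loss, optimizer, scheduler
# ---------------------------------------------------------------------------

def dice_bce_loss(prob: np.ndarray, target: np.ndarray, eps: float = 1e-6
                  ) -> tuple[float, np.ndarray]:
    """Equal-weight sum of soft-Dice loss and mean binary cross-entropy.

    Returns ``(loss, dLoss/dProb)``.  The soft Dice term is computed over
    the whole batch, which stabilizes batches containing empty masks.
    """
    p = np.clip(prob, eps, 1.0 - eps)
    y = target
    n = p.size
    bce = float(-(y * np.log(p) + (1 - y) * np.log(1 - p)).mean())
    grad_bce = (p - y) / (p * (1 - p)) / n
    inter = float((p * y).sum())
    denom = float(p.sum() + y.sum())
    dice = (2 * inter + eps) / (denom + eps)
    grad_dice = -(2 * y * (denom + eps) - (2 * inter + eps)) / (denom + eps) ** 2
    return (1.0 - dice) + bce, grad_dice + grad_bce


class Adam:
    def __init__(self, model: LightUNet, lr: float, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.model = model
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p) for p, _ in model.params()]
        self.v = [np.zeros_like(p) for p, _ in model.params()]

    def step(self) -> None:
        self.t += 1
        b1t = 1 - self.beta1**self.t
        b2t = 1 - self.beta2**self.t
        for (p, g), m, v in zip(self.model.params(), self.m, self.v):
            m *= self.beta1
            m += (1 - self.beta1) * g
            v *= self.beta2
            v += (1 - self.beta2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


class ReduceLROnPlateau:
    """Multiply the learning rate by ``factor`` after ``patience`` epochs
    without improvement of the monitored loss."""

    def __init__(self, optimizer: Adam, patience: int = 10, factor: float = 0.1,
                 min_lr: float = 0.0):
        self.optimizer = optimizer
        self.patience = patience
        self.factor = factor
        self.min_lr = min_lr
        self.best = np.inf
        self.bad_epochs = 0

    @property
    def lr(self) -> float:
        return self.optimizer.lr

    def step(self, loss: float) -> float:
        """Feed one epoch's monitored loss; returns the (possibly reduced) lr."""
        if loss < self.best:
            self.best = loss
            self.bad_epochs = 0
        else:
            self.bad_epochs += 1
            if self.bad_epochs > self.patience:
                self.optimizer.lr = max(self.optimizer.lr * self.factor, self.min_lr)
                self.bad_epochs = 0
        return self.optimizer.lr


# ---------------------------------------------------------------------------
# training / inference
# ---------------------------------------------------------------------------

def _to_batch(pairs: Sequence[tuple[np.ndarray, np.ndarray]]) -> tuple[np.ndarray, np.ndarray]:
    xs = np.stack([np.moveaxis(img.astype(np.float64) / 255.0, -1, 0) for img, _ in pairs])
    ys = np.stack([m.astype(np.float64)[None] for _, m in pairs])
    return xs, ys


def _hard_dice(prob: np.ndarray, target: np.ndarray, cutoff: float = 0.5) -> float:
    pred = prob > cutoff
    gt = target > 0.5
    inter = np.count_nonzero(pred & gt)
    denom = np.count_nonzero(pred) + np.count_nonzero(gt)
    return 1.0 if denom == 0 else 2.0 * inter / denom


def train_light_unet(
    model: LightUNet,
    dataset: Sequence[tuple[np.ndarray, np.ndarray]],
    config: TrainConfig = TrainConfig(),
    val_dataset: Optional[Sequence[tuple[np.ndarray, np.ndarray]]] = None,
) -> tuple[LightUNet, TrainingHistory]:
    """Train on (enhanced-frame, mask) pairs; returns best-validation weights.

    ``dataset``/``val_dataset`` hold uint8 RGB frames and boolean masks of
    a common shape divisible by ``2**(depth-1)``.  When no validation set
    is supplied the training loss is monitored instead (both for plateau
    scheduling and for best-weights selection).  Deterministic per seed.
    """
    if len(dataset) == 0:
        raise ValueError("empty training dataset")
    rng = np.random.default_rng(config.seed)
    opt = Adam(model, config.learning_rate, config.beta1, config.beta2)
    sched = ReduceLROnPlateau(opt, config.plateau_patience, config.plateau_factor)
    history = TrainingHistory()
    best_loss = np.inf
    best_state = model.state_dict()

    for _epoch in range(config.epochs):
        order = rng.permutation(len(dataset))
        epoch_loss = 0.0
        epoch_dice = 0.0
        n_batches = 0
        for start in range(0, len(order), config.batch_size):
            batch = [dataset[i] for i in order[start : start + config.batch_size]]
            x, y = _to_batch(batch)
            model.zero_grad()
            prob = model.forward(x, train=True)
            loss, grad = dice_bce_loss(prob, y)
            model.backward(grad)
            opt.step()
            epoch_loss += loss
            epoch_dice += _hard_dice(prob, y)
            n_batches += 1
        train_loss = epoch_loss / n_batches
        train_dice = epoch_dice / n_batches

        if val_dataset:
            vx, vy = _to_batch(val_dataset)
            vprob = model.forward(vx, train=False)
            val_loss, _ = dice_bce_loss(vprob, vy)
            val_dice = _hard_dice(vprob, vy)
        else:
            val_loss, val_dice = train_loss, train_dice

        history.train_loss.append(train_loss)
        history.val_loss.append(float(val_loss))
        history.train_dice.append(train_dice)
        history.val_dice.append(float(val_dice))
        history.learning_rate.append(opt.lr)
        if val_loss < best_loss:
            best_loss = val_loss
            best_state = model.state_dict()
        sched.step(float(val_loss))

    model.load_state_dict(best_state)
    return model, history


def predict_unet_mask(model: LightUNet, frame: np.ndarray, prob_cutoff: float = 0.5
                      ) -> np.ndarray:
    """Boolean highlight mask: sigmoid probability map > ``prob_cutoff``.

    The frame is reflect-padded to the next multiple of ``2**(depth-1)``
    and the prediction cropped back, so any frame size is accepted.
    """
    if frame.ndim != 3 or frame.shape[2] != model.config.in_channels:
        raise ValueError(f"expected (H, W, {model.config.in_channels}) frame, got {frame.shape}")
    h, w = frame.shape[:2]
    factor = 2 ** (model.config.depth - 1)
    ph = (-h) % factor
    pw = (-w) % factor
    x = frame.astype(np.float64) / 255.0
    if ph or pw:
        x = np.pad(x, ((0, ph), (0, pw), (0, 0)), mode="reflect")
    x = np.moveaxis(x, -1, 0)[None]
    prob = model.forward(x, train=False)[0, 0, :h, :w]
    return prob > prob_cutoff
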