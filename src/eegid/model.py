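"""The identification classifier: a compact continuous CNN in NumPy.

Architecture (for input planes P = n_subwindows * n_bands, default 20):

    input  (P, 9, 9)
    conv 4x4, stride 1, zero-padded to 9x9, 64 maps,  ReLU
    conv 4x4, stride 1, zero-padded to 9x9, 128 maps, ReLU
    conv 4x4, stride 1, zero-padded to 9x9, 256 maps, ReLU
    conv 1x1, 64 maps (feature fusion), ReLU          -> (64, 9, 9)
    fully connected 5184 -> 1024, ReLU, dropout
    fully connected 1024 -> n_subjects, softmax

There is deliberately no pooling: the 9x9 scalp grid is small enough that
every convolution keeps full spatial resolution.  The network is implemented
directly on NumPy (im2col convolutions, hand-written backprop, Adam,
softmax cross-entropy): at this input size a deep-learning framework buys
nothing, and a pure NumPy forward/backward pass is bit-reproducible from the
seed on one machine.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

__all__ = [
    "ModelSpec",
    "TrainConfig",
    "DECNN",
    "TrainedModel",
    "build_model",
    "count_parameters",
    "param_shapes",
    "train",
    "predict",
    "save_checkpoint",
    "load_checkpoint",
]

GRID = 9


@dataclass(frozen=True)
class ModelSpec:
    """Architecture hyper-parameters; the defaults are the reference network."""

    n_subjects: int
    n_subwindows: int = 5
    n_bands: int = 4
    conv_maps: tuple[int, int, int] = (64, 128, 256)
    kernel: int = 4
    fuse_maps: int = 64
    fc_dim: int = 1024
    dropout: float = 0.5

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("need at least 2 identities")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must be in [0, 1)")
        if self.kernel < 1 or any(m < 1 for m in self.conv_maps):
            raise ValueError("invalid architecture sizes")

    @property
    def in_planes(self) -> int:
        return self.n_subwindows * self.n_bands


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 50
    batch_size: int = 128
    lr: float = 1e-4
    optimizer: str = "adam"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.optimizer not in ("adam", "sgd"):
            raise ValueError(f"unknown optimizer {self.optimizer!r}")


def param_shapes(spec: ModelSpec) -> dict[str, tuple[int, ...]]:
    """Name -> shape for every learnable tensor, in forward order."""
    k = spec.kernel
    c1, c2, c3 = spec.conv_maps
    shapes = {
        "conv1_W": (c1, spec.in_planes, k, k), "conv1_b": (c1,),
        "conv2_W": (c2, c1, k, k), "conv2_b": (c2,),
        "conv3_W": (c3, c2, k, k), "conv3_b": (c3,),
        "fuse_W": (spec.fuse_maps, c3, 1, 1), "fuse_b": (spec.fuse_maps,),
        "fc1_W": (spec.fuse_maps * GRID * GRID, spec.fc_dim), "fc1_b": (spec.fc_dim,),
        "fc2_W": (spec.fc_dim, spec.n_subjects), "fc2_b": (spec.n_subjects,),
    }
    return shapes


def count_parameters(spec: ModelSpec) -> int:
    """Exact learnable-parameter count (weights + biases)."""
    return int(sum(np.prod(s) for s in param_shapes(spec).values()))


# ---------------------------------------------------------------------------
# conv plumbing (im2col; stride 1, zero padding preserving the 9x9 grid)


def _pad_amounts(k: int) -> tuple[int, int]:
    # total pad k-1 keeps H_out == H_in at stride 1; split before/after
    before = (k - 1) // 2
    return before, k - 1 - before


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """Channels-last (B, H, W, C) -> (B, H, W, C*k*k) patch matrix, padded
    so the output grid matches the input grid (stride 1)."""
    b_, h, w, c = x.shape
    if k == 1:
        return x
    pb, pa = _pad_amounts(k)
    xp = np.pad(x, ((0, 0), (pb, pa), (pb, pa), (0, 0)))
    v = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(1, 2))
    # v: (B, H, W, C, k, k), already in (C, i, j) minor order
    return np.ascontiguousarray(v).reshape(b_, h, w, c * k * k)


def _col2im(dcols: np.ndarray, x_shape: tuple, k: int) -> np.ndarray:
    """Adjoint of :func:`_im2col` (channels-last)."""
    b_, h, w, c = x_shape
    if k == 1:
        return dcols
    pb, pa = _pad_amounts(k)
    dxp = np.zeros((b_, h + k - 1, w + k - 1, c), dtype=dcols.dtype)
    d = dcols.reshape(b_, h, w, c, k, k)
    for i in range(k):
        for j in range(k):
            dxp[:, i:i + h, j:j + w, :] += d[:, :, :, :, i, j]
    return dxp[:, pb:pb + h, pb:pb + w, :]


def _conv_forward(x, W, b):
    """x (B,H,W,C), W (F,C,k,k) -> out (B,H,W,F); caches the patch matrix."""
    f, c, k, _ = W.shape
    cols = _im2col(x, k)                       # (B,H,W,C*k*k)
    out = cols @ W.reshape(f, c * k * k).T + b
    return out, (cols, x.shape)


def _conv_backward(dout, W, cache):
    """dout (B,H,W,F) -> (dx, dW, db)."""
    f, c, k, _ = W.shape
    cols, x_shape = cache
    n = cols.shape[0] * cols.shape[1] * cols.shape[2]
    cols2 = cols.reshape(n, -1)
    dflat = dout.reshape(n, f)
    dW = (dflat.T @ cols2).reshape(W.shape)
    db = dflat.sum(axis=0)
    dcols = dflat @ W.reshape(f, c * k * k)
    dx = _col2im(dcols.reshape(cols.shape), x_shape, k)
    return dx, dW, db


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# the network


class DECNN:
    """The classifier with its weights; see the module docstring for layout."""

    def __init__(self, spec: ModelSpec, seed: int = 0, dtype=np.float32):
        self.spec = spec
        self.seed = seed
        self.dtype = dtype
        rng = np.random.default_rng(seed)
        self.params: dict[str, np.ndarray] = {}
        for name, shape in param_shapes(spec).items():
            if name.endswith("_b"):
                self.params[name] = np.zeros(shape, dtype=dtype)
            else:
                if name.startswith(("conv", "fuse")):
                    fan_in = int(np.prod(shape[1:]))     # C*k*k
                else:
                    fan_in = shape[0]
                std = np.sqrt(2.0 / fan_in)
                self.params[name] = (std * rng.standard_normal(shape)).astype(dtype)

    # -- forward -----------------------------------------------------------

    def _check_input(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=self.dtype)
        if X.ndim == 3:
            X = X[None]
        p = self.spec.in_planes
        if X.ndim == 5:  # (B, n_sub, n_bands, 9, 9) -> stacked planes
            X = X.reshape(X.shape[0], -1, X.shape[-2], X.shape[-1])
        if X.shape[1:] != (p, GRID, GRID):
            raise ValueError(f"expected input (*, {p}, {GRID}, {GRID}), got {X.shape}")
        return X

    def forward(self, X: np.ndarray, train: bool = False,
                rng: np.random.Generator | None = None):
        P = self.params
        X = np.ascontiguousarray(X.transpose(0, 2, 3, 1))  # channels-last
        h1, c1 = _conv_forward(X, P["conv1_W"], P["conv1_b"]); a1 = np.maximum(h1, 0)
        h2, c2 = _conv_forward(a1, P["conv2_W"], P["conv2_b"]); a2 = np.maximum(h2, 0)
        h3, c3 = _conv_forward(a2, P["conv3_W"], P["conv3_b"]); a3 = np.maximum(h3, 0)
        h4, c4 = _conv_forward(a3, P["fuse_W"], P["fuse_b"]); a4 = np.maximum(h4, 0)
        flat = a4.reshape(X.shape[0], -1)
        z1 = flat @ P["fc1_W"] + P["fc1_b"]
        f = np.maximum(z1, 0)
        if train and self.spec.dropout > 0:
            keep = 1.0 - self.spec.dropout
            mask = (rng.random(f.shape) < keep).astype(f.dtype) / keep
            f = f * mask
        else:
            mask = None
        logits = f @ P["fc2_W"] + P["fc2_b"]
        probs = _softmax(logits.astype(np.float64))
        cache = (X, h1, c1, a1, h2, c2, a2, h3, c3, a3, h4, c4, flat, z1, f, mask)
        return probs, cache

    def backward(self, probs: np.ndarray, y: np.ndarray, cache) -> dict[str, np.ndarray]:
        P = self.params
        (X, h1, c1, a1, h2, c2, a2, h3, c3, a3, h4, c4, flat, z1, f, mask) = cache
        B = X.shape[0]
        dlogits = probs.copy()
        dlogits[np.arange(B), y] -= 1.0
        dlogits = (dlogits / B).astype(self.dtype)
        g = {}
        g["fc2_W"] = f.T @ dlogits
        g["fc2_b"] = dlogits.sum(axis=0)
        df = dlogits @ P["fc2_W"].T
        if mask is not None:
            df = df * mask
        dz1 = df * (z1 > 0)
        g["fc1_W"] = flat.T @ dz1
        g["fc1_b"] = dz1.sum(axis=0)
        dflat = dz1 @ P["fc1_W"].T
        da4 = dflat.reshape(B, GRID, GRID, self.spec.fuse_maps) * (h4 > 0)
        da3, g["fuse_W"], g["fuse_b"] = _conv_backward(da4, P["fuse_W"], c4)
        da3 = da3 * (h3 > 0)
        da2, g["conv3_W"], g["conv3_b"] = _conv_backward(da3, P["conv3_W"], c3)
        da2 = da2 * (h2 > 0)
        da1, g["conv2_W"], g["conv2_b"] = _conv_backward(da2, P["conv2_W"], c2)
        da1 = da1 * (h1 > 0)
        _, g["conv1_W"], g["conv1_b"] = _conv_backward(da1, P["conv1_W"], c1)
        return g

    # -- inference ---------------------------------------------------------

    def predict_proba(self, X: np.ndarray, batch_size: int = 512) -> np.ndarray:
        """Deterministic class probabilities (dropout off), batch-order preserving."""
        X = self._check_input(X)
        out = np.empty((X.shape[0], self.spec.n_subjects))
        for i in range(0, X.shape[0], batch_size):
            probs, _ = self.forward(X[i:i + batch_size], train=False)
            out[i:i + batch_size] = probs
        return out


def build_model(spec: ModelSpec, seed: int = 0) -> DECNN:
    return DECNN(spec, seed=seed)


# ---------------------------------------------------------------------------
# training


@dataclass
class TrainedModel:
    model: DECNN
    config: TrainConfig
    history: list[dict]  # per-epoch {"epoch", "loss", "accuracy"}

    @property
    def spec(self) -> ModelSpec:
        return self.model.spec


def train(model: DECNN, X: np.ndarray, y: np.ndarray, cfg: TrainConfig) -> TrainedModel:
    """Softmax cross-entropy training with mini-batch Adam (or plain SGD).

    Fully deterministic given ``cfg.seed`` (epoch shuffling and dropout masks
    come from one seeded generator).  Raises if any identity has no clips.
    """
    X = model._check_input(X)
    y = np.asarray(y, dtype=np.int64)
    if X.shape[0] != y.shape[0]:
        raise ValueError("feature/label length mismatch")
    counts = np.bincount(y, minlength=model.spec.n_subjects)
    missing = np.flatnonzero(counts == 0)
    if missing.size:
        raise ValueError(f"no training clips for identities {missing.tolist()}")
    if y.min() < 0 or y.max() >= model.spec.n_subjects:
        raise ValueError("labels outside [0, n_subjects)")

    rng = np.random.default_rng(cfg.seed)
    m = {k: np.zeros_like(v) for k, v in model.params.items()}
    v = {k: np.zeros_like(p) for k, p in model.params.items()}
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    step = 0
    history = []
    n = X.shape[0]
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        tot_loss = tot_correct = 0.0
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            xb, yb = X[idx], y[idx]
            probs, cache = model.forward(xb, train=True, rng=rng)
            loss = -np.mean(np.log(np.maximum(probs[np.arange(len(yb)), yb], 1e-300)))
            grads = model.backward(probs, yb, cache)
            step += 1
            for k, p in model.params.items():
                gk = grads[k]
                if cfg.optimizer == "adam":
                    m[k] = beta1 * m[k] + (1 - beta1) * gk
                    v[k] = beta2 * v[k] + (1 - beta2) * gk * gk
                    mhat = m[k] / (1 - beta1**step)
                    vhat = v[k] / (1 - beta2**step)
                    p -= (cfg.lr * mhat / (np.sqrt(vhat) + eps)).astype(p.dtype)
                else:
                    p -= (cfg.lr * gk).astype(p.dtype)
            tot_loss += loss * len(yb)
            tot_correct += (probs.argmax(axis=1) == yb).sum()
        history.append({
            "epoch": epoch,
            "loss": tot_loss / n,
            "accuracy": tot_correct / n,
        })
    return TrainedModel(model=model, config=cfg, history=history)


def predict(trained: TrainedModel | DECNN, X: np.ndarray) -> np.ndarray:
    """Probability vectors for a batch (or single tensor); rows sum to 1."""
    net = trained.model if isinstance(trained, TrainedModel) else trained
    return net.predict_proba(X)


# ---------------------------------------------------------------------------
# checkpoints


def save_checkpoint(trained: TrainedModel, path: str | Path,
                    extra_meta: dict | None = None) -> Path:
    path = Path(path)
    meta = {
        "spec": asdict(trained.spec),
        "config": asdict(trained.config),
        "seed": trained.model.seed,
        "history": trained.history,
    }
    if extra_meta:
        meta.update(extra_meta)
    np.savez(path, __meta__=json.dumps(meta), **trained.model.params)
    return path if path.suffix == ".npz" else path.with_suffix(path.suffix + ".npz")


def load_checkpoint(path: str | Path) -> TrainedModel:
    with np.load(path, allow_pickle=False) as z:
        meta = json.loads(str(z["__meta__"]))
        params = {k: z[k] for k in z.files if k != "__meta__"}
    spec_d = meta["spec"]
    spec_d["conv_maps"] = tuple(spec_d["conv_maps"])
    spec = ModelSpec(**spec_d)
    net = DECNN(spec, seed=meta["seed"])
    for k in net.params:
        net.params[k] = params[k]
    return TrainedModel(model=net, config=TrainConfig(**meta["config"]),
                        history=meta["history"])
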