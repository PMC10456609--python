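"""Gated dilated-convolution ("Wavenet"-style) classifier over HRV vectors.

The network treats the length-9 HRV feature vector as a one-channel
sequence and applies a stack of causal dilated convolution blocks with
gated activations:

    z_k = tanh(W_f,k * x) (.) sigmoid(W_g,k * x)

where ``*`` is a causal dilated convolution (kernel 2, dilation 2^k) and
``(.)`` elementwise multiplication. Each block's gated output passes
through a per-timestep dense map (ReLU) whose output is collected as a
skip connection; the sum of all skips feeds a ReLU, a flatten, and a
dropout/dense/dropout/dense/softmax head. Causal padding keeps the
temporal length equal to the input length throughout the stack, so the
flatten width is ``input_len * filters`` (576 for the default 9 x 64).

The implementation is pure NumPy: forward pass, reverse-mode gradients and
an Adam optimizer are written out explicitly, which keeps every run
bit-reproducible from its seed on a single thread.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np


class TrainingDivergedError(RuntimeError):
    """Loss became non-finite during optimization."""


@dataclass(frozen=True)
class WavenetSpec:
    """Architecture hyperparameters.

    ``n_blocks`` is the number of gated convolution blocks (the tunable
    "hidden layers" of the grid search); dilations are fixed to the powers
    of two ``1, 2, 4, ..., 2^(n_blocks-1)``.
    """

    input_len: int = 9
    n_blocks: int = 7
    filters: int = 64
    kernel_size: int = 2
    n_classes: int = 5
    dense_units: int = 512
    dropout_rate: float = 0.5
    use_residual: bool = False

    def __post_init__(self) -> None:
        if self.input_len < 1 or self.n_blocks < 1 or self.filters < 1:
            raise ValueError("input_len, n_blocks and filters must be >= 1")
        if self.kernel_size != 2:
            raise ValueError("only kernel_size=2 is supported")
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must lie in [0, 1)")

    @property
    def dilations(self) -> Tuple[int, ...]:
        return tuple(2 ** k for k in range(self.n_blocks))


def flatten_dim(spec: WavenetSpec) -> int:
    """Width of the flattened stack output: input_len x filters."""
    return spec.input_len * spec.filters


def _sigmoid(a: np.ndarray) -> np.ndarray:
    out = np.empty_like(a)
    pos = a >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-a[pos]))
    e = np.exp(a[~pos])
    out[~pos] = e / (1.0 + e)
    return out


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _shift(h: np.ndarray, d: int) -> np.ndarray:
    """Causal shift along the time axis: out[:, t] = h[:, t-d] (zeros before)."""
    out = np.zeros_like(h)
    if d < h.shape[1]:
        out[:, d:] = h[:, :-d] if d > 0 else h
    return out


def _unshift_grad(g: np.ndarray, d: int) -> np.ndarray:
    """Adjoint of :func:`_shift`."""
    out = np.zeros_like(g)
    if d < g.shape[1]:
        if d > 0:
            out[:, :-d] = g[:, d:]
        else:
            out[:] = g
    return out


def _glorot(rng: np.random.Generator, shape: Tuple[int, int]) -> np.ndarray:
    limit = np.sqrt(6.0 / (shape[0] + shape[1]))
    return rng.uniform(-limit, limit, size=shape)


class WavenetClassifier:
    """Seeded, deterministic gated dilated-convolution classifier."""

    def __init__(self, spec: WavenetSpec, seed: int = 0) -> None:
        self.spec = spec
        self.seed = seed
        rng = np.random.default_rng(seed)
        F, C = spec.filters, spec.n_classes
        P: Dict[str, np.ndarray] = {}
        P["pre_W"] = _glorot(rng, (1, F))
        P["pre_b"] = np.zeros(F)
        for k in range(spec.n_blocks):
            for name in ("f", "g"):
                P[f"b{k}_{name}0"] = _glorot(rng, (F, F))
                P[f"b{k}_{name}1"] = _glorot(rng, (F, F))
                P[f"b{k}_{name}b"] = np.zeros(F)
            P[f"b{k}_dW"] = _glorot(rng, (F, F))
            P[f"b{k}_db"] = np.zeros(F)
        width = flatten_dim(spec)
        P["head_W1"] = _glorot(rng, (width, spec.dense_units))
        P["head_b1"] = np.zeros(spec.dense_units)
        P["head_W2"] = _glorot(rng, (spec.dense_units, spec.dense_units))
        P["head_b2"] = np.zeros(spec.dense_units)
        P["out_W"] = _glorot(rng, (spec.dense_units, C))
        P["out_b"] = np.zeros(C)
        self.params = P

    # -- forward -----------------------------------------------------------

    @property
    def n_params(self) -> int:
        return sum(p.size for p in self.params.values())

    def _check_input(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != self.spec.input_len:
            raise ValueError(
                f"input width {X.shape[1]} != spec input_len {self.spec.input_len}")
        return X

    def _forward(self, X: np.ndarray, *, train: bool = False,
                 dropout_rng: Optional[np.random.Generator] = None) -> dict:
        P, spec = self.params, self.spec
        B = X.shape[0]
        cache: dict = {"X": X}
        xr = X[:, :, None]
        pre_a = xr @ P["pre_W"] + P["pre_b"]
        h = np.maximum(pre_a, 0.0)
        cache["pre_a"] = pre_a
        skip = np.zeros_like(h)
        blocks = []
        for k, d in enumerate(spec.dilations):
            hs = _shift(h, d)
            af = hs @ P[f"b{k}_f0"] + h @ P[f"b{k}_f1"] + P[f"b{k}_fb"]
            ag = hs @ P[f"b{k}_g0"] + h @ P[f"b{k}_g1"] + P[f"b{k}_gb"]
            u = np.tanh(af)
            v = _sigmoid(ag)
            z = u * v
            sa = z @ P[f"b{k}_dW"] + P[f"b{k}_db"]
            s = np.maximum(sa, 0.0)
            skip = skip + s
            blocks.append({"h_in": h, "hs": hs, "u": u, "v": v, "z": z,
                           "sa": sa, "d": d})
            h = s + h if spec.use_residual else s
        cache["blocks"] = blocks
        cache["skip"] = skip
        stack = np.maximum(skip, 0.0)
        cache["stack"] = stack
        flat = stack.reshape(B, -1)
        rate = spec.dropout_rate
        if train and rate > 0:
            m1 = (dropout_rng.random(flat.shape) >= rate) / (1 - rate)
        else:
            m1 = None
        fl1 = flat * m1 if m1 is not None else flat
        a1 = fl1 @ P["head_W1"] + P["head_b1"]
        h1 = np.maximum(a1, 0.0)
        if train and rate > 0:
            m2 = (dropout_rng.random(h1.shape) >= rate) / (1 - rate)
        else:
            m2 = None
        h1d = h1 * m2 if m2 is not None else h1
        a2 = h1d @ P["head_W2"] + P["head_b2"]
        h2 = np.maximum(a2, 0.0)
        logits = h2 @ P["out_W"] + P["out_b"]
        cache.update(flat=flat, m1=m1, fl1=fl1, a1=a1, m2=m2, h1d=h1d,
                     a2=a2, h2=h2, logits=logits, probs=_softmax(logits))
        return cache

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Per-class probability rows (deterministic; dropout disabled)."""
        return self._forward(self._check_input(X))["probs"]

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Predicted class indices (argmax of the probability rows)."""
        return np.argmax(self.predict_proba(X), axis=1)

    def stack_activations(self, X: np.ndarray) -> np.ndarray:
        """Post-stack activations (batch, input_len, filters), pre-flatten."""
        return self._forward(self._check_input(X))["stack"]

    # -- backward ----------------------------------------------------------

    def _backward(self, cache: dict, Y: np.ndarray) -> Dict[str, np.ndarray]:
        P, spec = self.params, self.spec
        B = Y.shape[0]
        G: Dict[str, np.ndarray] = {}
        dlogits = (cache["probs"] - Y) / B
        G["out_W"] = cache["h2"].T @ dlogits
        G["out_b"] = dlogits.sum(0)
        dh2 = dlogits @ P["out_W"].T
        da2 = dh2 * (cache["a2"] > 0)
        G["head_W2"] = cache["h1d"].T @ da2
        G["head_b2"] = da2.sum(0)
        dh1d = da2 @ P["head_W2"].T
        dh1 = dh1d * cache["m2"] if cache["m2"] is not None else dh1d
        da1 = dh1 * (cache["a1"] > 0)
        G["head_W1"] = cache["fl1"].T @ da1
        G["head_b1"] = da1.sum(0)
        dfl1 = da1 @ P["head_W1"].T
        dflat = dfl1 * cache["m1"] if cache["m1"] is not None else dfl1
        dstack = dflat.reshape(cache["stack"].shape)
        dskip = dstack * (cache["skip"] > 0)
        dh = np.zeros_like(dskip)
        for k in range(spec.n_blocks - 1, -1, -1):
            blk = cache["blocks"][k]
            ds = dskip + dh
            dsa = ds * (blk["sa"] > 0)
            G[f"b{k}_dW"] = np.tensordot(blk["z"], dsa, axes=([0, 1], [0, 1]))
            G[f"b{k}_db"] = dsa.sum((0, 1))
            dz = dsa @ P[f"b{k}_dW"].T
            du = dz * blk["v"]
            dv = dz * blk["u"]
            daf = du * (1.0 - blk["u"] ** 2)
            dag = dv * blk["v"] * (1.0 - blk["v"])
            G[f"b{k}_f0"] = np.tensordot(blk["hs"], daf, axes=([0, 1], [0, 1]))
            G[f"b{k}_f1"] = np.tensordot(blk["h_in"], daf, axes=([0, 1], [0, 1]))
            G[f"b{k}_fb"] = daf.sum((0, 1))
            G[f"b{k}_g0"] = np.tensordot(blk["hs"], dag, axes=([0, 1], [0, 1]))
            G[f"b{k}_g1"] = np.tensordot(blk["h_in"], dag, axes=([0, 1], [0, 1]))
            G[f"b{k}_gb"] = dag.sum((0, 1))
            dh_in = (daf @ P[f"b{k}_f1"].T + dag @ P[f"b{k}_g1"].T
                     + _unshift_grad(daf @ P[f"b{k}_f0"].T, blk["d"])
                     + _unshift_grad(dag @ P[f"b{k}_g0"].T, blk["d"]))
            if spec.use_residual:
                dh_in = dh_in + dh  # identity passthrough of h_new = s + h
            dh = dh_in
        dpre = dh * (cache["pre_a"] > 0)
        G["pre_W"] = np.tensordot(cache["X"][:, :, None], dpre,
                                  axes=([0, 1], [0, 1]))
        G["pre_b"] = dpre.sum((0, 1))
        return G

    def loss_and_gradients(self, X: np.ndarray, y: np.ndarray, *,
                           train: bool = False,
                           dropout_rng: Optional[np.random.Generator] = None,
                           ) -> Tuple[float, Dict[str, np.ndarray]]:
        """Mean categorical cross-entropy and parameter gradients."""
        X = self._check_input(X)
        Y = _one_hot(y, self.spec.n_classes)
        cache = self._forward(X, train=train, dropout_rng=dropout_rng)
        p = np.clip(cache["probs"], 1e-12, None)
        loss = float(-np.mean(np.log(p[np.arange(len(y)), y])))
        return loss, self._backward(cache, Y)

    # -- training ----------------------------------------------------------

    def fit(self, X: np.ndarray, y: np.ndarray, *, epochs: int,
            batch_size: int, learning_rate: float, seed: int = 0,
            validation_data: Optional[Tuple[np.ndarray, np.ndarray]] = None,
            ) -> "TrainingHistory":
        """Minimize cross-entropy with Adam; fully seeded and single-threaded.

        ``y`` holds integer class indices. With ``epochs=0`` the weights
        are returned untouched and the history is empty. Raises
        :class:`TrainingDivergedError` on a non-finite loss.
        """
        X = self._check_input(X)
        y = np.asarray(y, dtype=int)
        if X.shape[0] == 0:
            raise ValueError("training set is empty")
        rng = np.random.default_rng(seed)
        opt = _Adam(self.params, learning_rate)
        hist = TrainingHistory()
        n = X.shape[0]
        for epoch in range(epochs):
            order = rng.permutation(n)
            for start in range(0, n, batch_size):
                idx = order[start:start + batch_size]
                loss, grads = self.loss_and_gradients(
                    X[idx], y[idx], train=True, dropout_rng=rng)
                if not np.isfinite(loss):
                    raise TrainingDivergedError(
                        f"non-finite loss at epoch {epoch + 1}, "
                        f"batch offset {start} (lr={learning_rate})")
                opt.step(self.params, grads)
            tr_loss, tr_acc = self.evaluate(X, y)
            hist.train_loss.append(tr_loss)
            hist.train_acc.append(tr_acc)
            if validation_data is not None:
                va_loss, va_acc = self.evaluate(*validation_data)
                hist.val_loss.append(va_loss)
                hist.val_acc.append(va_acc)
        return hist

    def evaluate(self, X: np.ndarray, y: np.ndarray) -> Tuple[float, float]:
        """(cross-entropy, accuracy) without dropout."""
        X = self._check_input(X)
        y = np.asarray(y, dtype=int)
        probs = np.clip(self.predict_proba(X), 1e-12, None)
        loss = float(-np.mean(np.log(probs[np.arange(len(y)), y])))
        acc = float(np.mean(np.argmax(probs, axis=1) == y))
        return loss, acc

    # -- persistence -------------------------------------------------------

    def save_weights(self, path) -> None:
        np.savez(path, **self.params)

    def load_weights(self, path) -> None:
        with np.load(path) as data:
            for k in self.params:
                self.params[k] = data[k]


@dataclass
class TrainingHistory:
    """Per-epoch loss/accuracy curves."""

    train_loss: List[float] = field(default_factory=list)
    train_acc: List[float] = field(default_factory=list)
    val_loss: List[float] = field(default_factory=list)
    val_acc: List[float] = field(default_factory=list)


def _one_hot(y: np.ndarray, n_classes: int) -> np.ndarray:
    y = np.asarray(y, dtype=int)
    out = np.zeros((y.size, n_classes))
    out[np.arange(y.size), y] = 1.0
    return out


class _Adam:
    """Adaptive-moment gradient optimizer (beta1=0.9, beta2=0.999)."""

    def __init__(self, params: Dict[str, np.ndarray], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8) -> None:
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params: Dict[str, np.ndarray],
             grads: Dict[str, np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for k, g in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            params[k] -= self.lr * (self.m[k] / b1t) / (
                np.sqrt(self.v[k] / b2t) + self.eps)


def build_model(spec: WavenetSpec, seed: int = 0) -> WavenetClassifier:
    """Construct a classifier with seeded weight initialization."""
    return WavenetClassifier(spec, seed)
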