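"""Multi-branch 3D CNN for four-class motor-imagery decoding.

Three parallel branches — small, medium and large receptive field (SRF, MRF,
LRF) — each run three strided 3D convolutions over the grid x time input,
differing only in temporal kernel size and stride (1/1, 3/2, 5/4 after a
shared-spec but unshared-weight first layer of 3x3x5, strides 2,2,4).  Each
branch ends in its own dense head and softmax; the fused prediction is the
softmax of the elementwise sum of the three branch softmax vectors.  Training
minimises the negative log-likelihood of the fused output plus the three
per-branch NLLs with equal weights.

Implemented directly on NumPy (stride-tricks patch extraction + einsum, with
hand-written backward passes) so that the final-convolution activations and
the exact gradients of any pre-softmax class score with respect to them — the
quantities Grad-CAM consumes — are first-class outputs rather than framework
internals.
"""

from __future__ import annotations

import json
import logging
import math
import os
from dataclasses import dataclass, field, asdict

import numpy as np
from numpy.lib.stride_tricks import as_strided

from .representation import Tensor3DBatch

logger = logging.getLogger(__name__)

__all__ = [
    "ArchitectureError",
    "BranchSpec",
    "DivergenceError",
    "MultiBranchModel",
    "NetworkParams",
    "default_spec",
    "forward",
    "output_shapes",
    "predict",
    "train",
]

BRANCH_NAMES = ("SRF", "MRF", "LRF")


class ArchitectureError(ValueError):
    """A convolution chain collapses a dimension below 1."""


class DivergenceError(RuntimeError):
    """Training loss became non-finite."""


@dataclass(frozen=True)
class BranchSpec:
    """One receptive-field branch: 3 conv layers + dense head width.

    conv_layers entries are ((kh, kw, kt), (sh, sw, st), filters).
    """

    name: str
    conv_layers: tuple
    dense_nodes: int = 32

    def __post_init__(self) -> None:
        if len(self.conv_layers) != 3:
            raise ValueError("a branch has exactly 3 conv layers")
        filters = tuple(f for (_, _, f) in self.conv_layers)
        if filters != (16, 32, 64):
            raise ValueError(f"filter counts must be (16, 32, 64), got {filters}")
        for kernel, strides, _ in self.conv_layers:
            if any(k < 1 for k in kernel) or any(s < 1 for s in strides):
                raise ValueError("kernel/stride entries must be positive")


@dataclass
class NetworkParams:
    branches: tuple
    input_shape: tuple
    n_classes: int = 4
    seed: int = 0
    epochs: int = 30
    batch_size: int = 32
    learning_rate: float = 1e-3
    dropout: float = 0.0
    dtype: str = "float32"

    def __post_init__(self) -> None:
        names = [b.name for b in self.branches]
        if len(self.branches) != 3 or len(set(names)) != 3:
            raise ValueError("exactly three distinctly named branches required")

    def to_json(self) -> str:
        d = asdict(self)
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "NetworkParams":
        d = json.loads(text)
        branches = tuple(
            BranchSpec(
                name=b["name"],
                conv_layers=tuple(
                    (tuple(k), tuple(s), f) for (k, s, f) in b["conv_layers"]
                ),
                dense_nodes=b["dense_nodes"],
            )
            for b in d.pop("branches")
        )
        d["input_shape"] = tuple(d["input_shape"])
        return cls(branches=branches, **d)


def default_spec(
    input_shape: tuple = (6, 7, 312),
    *,
    seed: int = 0,
    epochs: int = 30,
    batch_size: int = 32,
    learning_rate: float = 1e-3,
    dense_nodes: int = 32,
    dropout: float = 0.0,
    dtype: str = "float32",
) -> NetworkParams:
    """The published layer table: identical 3x3x5/strides-2,2,4/16-filter first
    layers (spec-equal but weight-unshared), then temporal kernels/strides of
    1/1 (SRF), 3/2 (MRF), 5/4 (LRF) in conv2 and conv3 with 32 and 64 filters.
    """
    def branch(name: str, kt: int, st: int) -> BranchSpec:
        return BranchSpec(
            name=name,
            conv_layers=(
                ((3, 3, 5), (2, 2, 4), 16),
                ((2, 2, kt), (2, 2, st), 32),
                ((2, 2, kt), (2, 2, st), 64),
            ),
            dense_nodes=dense_nodes,
        )

    return NetworkParams(
        branches=(branch("SRF", 1, 1), branch("MRF", 3, 2), branch("LRF", 5, 4)),
        input_shape=tuple(input_shape),
        seed=seed,
        epochs=epochs,
        batch_size=batch_size,
        learning_rate=learning_rate,
        dropout=dropout,
        dtype=dtype,
    )


def output_shapes(params: NetworkParams) -> dict:
    """Per-branch conv output shapes under 'same' padding: dim -> ceil(dim/stride)."""
    out = {}
    for b in params.branches:
        dims = tuple(params.input_shape)
        shapes = []
        for (_, strides, f) in b.conv_layers:
            dims = tuple(math.ceil(d / s) for d, s in zip(dims, strides))
            if any(d < 1 for d in dims):
                raise ArchitectureError(f"branch {b.name}: conv output dim < 1 ({dims})")
            shapes.append(dims + (f,))
        out[b.name] = shapes
    return out


# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------

def _same_pad(n: int, k: int, s: int) -> tuple[int, int]:
    out = math.ceil(n / s)
    total = max((out - 1) * s + k - n, 0)
    return total // 2, total - total // 2


def _elu(x: np.ndarray) -> np.ndarray:
    out = x.copy()
    neg = x < 0
    out[neg] = np.expm1(x[neg])
    return out


def _elu_grad(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    # y = elu(x); derivative is 1 for x>0 else y+1
    return np.where(x > 0, 1.0, y + 1.0)


class _Conv3D:
    """Strided 3D convolution with 'same' padding over (H, W, T)."""

    def __init__(self, kernel, strides, cin, cout, rng, dtype=np.float64,
                 first_layer=False):
        kh, kw, kt = kernel
        fan_in = kh * kw * kt * cin
        self.W = rng.normal(0.0, math.sqrt(2.0 / fan_in),
                            size=(kh, kw, kt, cin, cout)).astype(dtype)
        self.b = np.zeros(cout, dtype=dtype)
        self.kernel = kernel
        self.strides = strides
        self.first_layer = first_layer  # input gradient is never consumed
        self._cache = None

    def _patches(self, xp, out_dims):
        kh, kw, kt = self.kernel
        sh, sw, st = self.strides
        n, _, _, _, cin = xp.shape
        ho, wo, to = out_dims
        sn, sH, sW, sT, sC = xp.strides
        return as_strided(
            xp,
            shape=(n, ho, wo, to, kh, kw, kt, cin),
            strides=(sn, sH * sh, sW * sw, sT * st, sH, sW, sT, sC),
            writeable=False,
        )

    def forward(self, x: np.ndarray, keep: bool = True) -> np.ndarray:
        n, H, W, T, cin = x.shape
        out_dims = tuple(math.ceil(d / s) for d, s in zip((H, W, T), self.strides))
        pads = [_same_pad(d, k, s) for d, k, s in zip((H, W, T), self.kernel, self.strides)]
        xp = np.pad(x, [(0, 0)] + [list(p) for p in pads] + [(0, 0)])
        kh, kw, kt = self.kernel
        cout = self.W.shape[-1]
        # materialise patches once as a GEMM operand; reused by backward
        pm = np.ascontiguousarray(self._patches(xp, out_dims)).reshape(
            n * np.prod(out_dims), kh * kw * kt * cin
        )
        y = (pm @ self.W.reshape(-1, cout)).reshape((n,) + out_dims + (cout,)) + self.b
        if keep:
            self._cache = (pm, xp.shape, pads, (H, W, T), out_dims, cin)
        return y

    def backward(self, dy: np.ndarray):
        pm, xp_shape, pads, in_dims, out_dims, cin = self._cache
        kh, kw, kt = self.kernel
        sh, sw, st = self.strides
        ho, wo, to = out_dims
        n = dy.shape[0]
        cout = self.W.shape[-1]
        dy2 = np.ascontiguousarray(dy.reshape(-1, cout))
        self.dW = (pm.T @ dy2).reshape(self.W.shape)
        self.db = dy2.sum(axis=0)
        if self.first_layer:
            return None
        # gradient w.r.t. patches, scattered back with overlap-add
        dpm = (dy2 @ self.W.reshape(-1, cout).T).reshape(
            (n, ho, wo, to, kh, kw, kt, cin)
        )
        dxp = np.zeros(xp_shape, dtype=dpm.dtype)
        for i in range(kh):
            for j in range(kw):
                for k in range(kt):
                    dxp[:,
                        i:i + (ho - 1) * sh + 1:sh,
                        j:j + (wo - 1) * sw + 1:sw,
                        k:k + (to - 1) * st + 1:st, :] += dpm[:, :, :, :, i, j, k, :]
        (pH, _), (pW, _), (pT, _) = pads
        H, W, T = in_dims
        return dxp[:, pH:pH + H, pW:pW + W, pT:pT + T, :]

    @property
    def params(self):
        return [("W", self.W), ("b", self.b)]


class _Dense:
    def __init__(self, n_in, n_out, rng, dtype=np.float64):
        self.W = rng.normal(0.0, math.sqrt(2.0 / n_in), size=(n_in, n_out)).astype(dtype)
        self.b = np.zeros(n_out, dtype=dtype)
        self._x = None

    def forward(self, x, keep=True):
        if keep:
            self._x = x
        return x @ self.W + self.b

    def backward(self, dy):
        self.dW = self._x.T @ dy
        self.db = dy.sum(axis=0)
        return dy @ self.W.T

    @property
    def params(self):
        return [("W", self.W), ("b", self.b)]


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


class _Branch:
    """conv1-elu-conv2-elu-conv3-elu (tap) -> flatten -> dense-elu -> dense -> logits."""

    def __init__(self, spec: BranchSpec, input_shape, n_classes, rng, dtype=np.float64):
        self.spec = spec
        self.dtype = dtype
        self.convs = []
        cin = 1
        dims = tuple(input_shape)
        for i, (kernel, strides, f) in enumerate(spec.conv_layers):
            self.convs.append(
                _Conv3D(kernel, strides, cin, f, rng, dtype=dtype, first_layer=(i == 0))
            )
            dims = tuple(math.ceil(d / s) for d, s in zip(dims, strides))
            if any(d < 1 for d in dims):
                raise ArchitectureError(f"branch {spec.name}: conv output dim < 1 ({dims})")
            cin = f
        self.tap_shape = dims + (cin,)
        flat = int(np.prod(self.tap_shape))
        self.fc1 = _Dense(flat, spec.dense_nodes, rng, dtype=dtype)
        self.fc2 = _Dense(spec.dense_nodes, n_classes, rng, dtype=dtype)
        self._cache = None

    def forward(self, x, keep=True, dropout_rate=0.0, rng=None):
        acts = []  # (pre, post) per conv
        h = np.asarray(x, dtype=self.dtype)[..., None]  # add channel axis
        for conv in self.convs:
            pre = conv.forward(h, keep=keep)
            post = _elu(pre)
            acts.append((pre, post))
            h = post
        a3 = h
        flat = a3.reshape(a3.shape[0], -1)
        h1 = self.fc1.forward(flat, keep=keep)
        a1 = _elu(h1)
        mask = None
        if dropout_rate > 0.0 and rng is not None:
            mask = (rng.random(a1.shape) >= dropout_rate) / (1.0 - dropout_rate)
            a1 = a1 * mask
        z = self.fc2.forward(a1, keep=keep)
        if keep:
            self._cache = (acts, h1, a1, mask)
        return z, a3

    def backward(self, dz):
        acts, h1, a1, mask = self._cache
        da1 = self.fc2.backward(dz)
        if mask is not None:
            da1 = da1 * mask
        dh1 = da1 * _elu_grad(h1, _elu(h1))
        dflat = self.fc1.backward(dh1)
        dh = dflat.reshape((-1,) + self.tap_shape)
        for conv, (pre, post) in zip(reversed(self.convs), reversed(acts)):
            dh = dh * _elu_grad(pre, post)
            dh = conv.backward(dh)
        return None if dh is None else dh[..., 0]

    def score_grad_wrt_tap(self, a3: np.ndarray, target_class: int) -> np.ndarray:
        """d(pre-softmax logit of target_class)/d(final conv activation a3).

        Pure head backward — must be called right after forward(keep=True) on
        the same input; dropout is never active here.
        """
        _, h1, _, _ = self._cache
        n = a3.shape[0]
        dz = np.zeros((n, self.fc2.W.shape[1]))
        dz[:, target_class] = 1.0
        da1 = dz @ self.fc2.W.T
        dh1 = da1 * _elu_grad(h1, _elu(h1))
        dflat = dh1 @ self.fc1.W.T
        return dflat.reshape((-1,) + self.tap_shape)

    @property
    def layers(self):
        return self.convs + [self.fc1, self.fc2]


class _Adam:
    def __init__(self, arrays, lr):
        self.lr = lr
        self.t = 0
        self.m = [np.zeros_like(a) for a in arrays]
        self.v = [np.zeros_like(a) for a in arrays]

    def step(self, arrays, grads, b1=0.9, b2=0.999, eps=1e-8):
        self.t += 1
        for i, (a, g) in enumerate(zip(arrays, grads)):
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1 ** self.t)
            vhat = self.v[i] / (1 - b2 ** self.t)
            a -= self.lr * mhat / (np.sqrt(vhat) + eps)


# ---------------------------------------------------------------------------
# model
# ---------------------------------------------------------------------------

class MultiBranchModel:
    """The trained (or freshly initialised) multi-branch network."""

    def __init__(self, params: NetworkParams):
        self.params = params
        self.dtype = np.dtype(params.dtype)
        rng = np.random.default_rng(params.seed)
        self.branches = {
            b.name: _Branch(b, params.input_shape, params.n_classes, rng,
                            dtype=self.dtype)
            for b in params.branches
        }
        self.history: list[dict] = []

    # -- inference ----------------------------------------------------------

    def forward(self, data: np.ndarray):
        """Return (fused probabilities, {branch: probabilities}).

        Each branch emits its own softmax; the fused output is the softmax of
        the elementwise sum of the three branch softmax vectors.
        """
        if data.shape[1:] != tuple(self.params.input_shape):
            raise ValueError(
                f"input shape {data.shape[1:]} != expected {self.params.input_shape}"
            )
        branch_probs = {}
        total = None
        for name in (b.name for b in self.params.branches):
            z, _ = self.branches[name].forward(data, keep=False)
            p = _softmax(z)
            branch_probs[name] = p
            total = p if total is None else total + p
        return _softmax(total), branch_probs

    def predict(self, data: np.ndarray) -> np.ndarray:
        """Argmax of fused probabilities; ties break to the lowest class id."""
        fused, _ = self.forward(data)
        return np.argmax(fused, axis=1)

    def conv_tap(self, data: np.ndarray, branch: str, target_class: int):
        """Final-conv activations and d(score)/d(activations) for one branch.

        Returns (activations, gradients, pre-softmax scores); activations and
        gradients have shape (n, h3, w3, t3, 64).
        """
        br = self.branches[branch]
        z, a3 = br.forward(data, keep=True)
        grad = br.score_grad_wrt_tap(a3, target_class)
        return a3, grad, z

    # -- training -----------------------------------------------------------

    def _loss_and_grads(self, x, y_onehot, rng, train=True):
        """Joint NLL (fused + per-branch) and parameter gradients."""
        n = x.shape[0]
        y_onehot = np.asarray(y_onehot, dtype=self.dtype)
        zs, a3s, probs = {}, {}, {}
        total = None
        order = [b.name for b in self.params.branches]
        for name in order:
            z, a3 = self.branches[name].forward(
                x, keep=True,
                dropout_rate=self.params.dropout if train else 0.0,
                rng=rng,
            )
            p = _softmax(z)
            zs[name], a3s[name], probs[name] = z, a3, p
            total = p if total is None else total + p
        fused = _softmax(total)
        eps = 1e-12
        loss = -np.log(np.maximum(fused[np.arange(n), y_onehot.argmax(1)], eps)).mean()
        for name in order:
            loss += -np.log(
                np.maximum(probs[name][np.arange(n), y_onehot.argmax(1)], eps)
            ).mean()
        if train:
            # d(fused NLL)/d(total) for softmax+NLL
            dtotal = (fused - y_onehot) / n
            for name in order:
                p = probs[name]
                # fused path through p -> total (identity), then softmax Jacobian of p wrt z
                g = dtotal + (-y_onehot / np.maximum(p, eps)) / n
                dz = p * (g - (g * p).sum(axis=1, keepdims=True))
                self.branches[name].backward(dz)
        acc = float((fused.argmax(1) == y_onehot.argmax(1)).mean())
        return float(loss), acc

    def _param_arrays(self):
        arrays = []
        for b in self.params.branches:
            for layer in self.branches[b.name].layers:
                arrays.append(layer.W)
                arrays.append(layer.b)
        return arrays

    def _grad_arrays(self):
        grads = []
        for b in self.params.branches:
            for layer in self.branches[b.name].layers:
                grads.append(layer.dW)
                grads.append(layer.db)
        return grads

    def evaluate(self, batch: Tensor3DBatch, chunk: int = 64) -> tuple[float, float]:
        """(mean joint NLL, fused accuracy) without touching gradients."""
        rng = np.random.default_rng(0)
        n = len(batch)
        loss_sum, correct = 0.0, 0.0
        for start in range(0, n, chunk):
            sl = slice(start, min(start + chunk, n))
            m = sl.stop - sl.start
            loss, acc = self._loss_and_grads(
                batch.data[sl], batch.labels[sl], rng, train=False
            )
            loss_sum += loss * m
            correct += acc * m
        return loss_sum / n, correct / n

    def fit(self, train_batch: Tensor3DBatch, val_batch: Tensor3DBatch | None = None):
        rng = np.random.default_rng(np.uint32(self.params.seed) + np.uint32(1))
        n = len(train_batch)
        arrays = self._param_arrays()
        opt = _Adam(arrays, self.params.learning_rate)
        for epoch in range(self.params.epochs):
            perm = rng.permutation(n)
            ep_loss, ep_acc, n_batches = 0.0, 0.0, 0
            for start in range(0, n, self.params.batch_size):
                idx = perm[start:start + self.params.batch_size]
                loss, acc = self._loss_and_grads(
                    train_batch.data[idx], train_batch.labels[idx], rng, train=True
                )
                if not np.isfinite(loss):
                    raise DivergenceError(f"non-finite loss at epoch {epoch}")
                opt.step(arrays, self._grad_arrays())
                ep_loss += loss
                ep_acc += acc
                n_batches += 1
            rec = {
                "epoch": epoch,
                "train_loss": ep_loss / n_batches,
                "train_accuracy": ep_acc / n_batches,
            }
            if val_batch is not None and len(val_batch):
                vloss, vacc = self.evaluate(val_batch)
                rec["val_loss"], rec["val_accuracy"] = vloss, vacc
            self.history.append(rec)
            logger.debug("epoch %d: %s", epoch, rec)
        return self

    # -- persistence --------------------------------------------------------

    def save(self, directory: str) -> None:
        os.makedirs(directory, exist_ok=True)
        with open(os.path.join(directory, "params.json"), "w") as fh:
            fh.write(self.params.to_json())
        weights = {}
        for bname, br in self.branches.items():
            for i, layer in enumerate(br.layers):
                weights[f"{bname}_{i}_W"] = layer.W
                weights[f"{bname}_{i}_b"] = layer.b
        np.savez(os.path.join(directory, "weights.npz"), **weights)
        if self.history:
            import pandas as pd

            pd.DataFrame(self.history).to_csv(
                os.path.join(directory, "history.csv"), index=False
            )

    @classmethod
    def load(cls, directory: str) -> "MultiBranchModel":
        with open(os.path.join(directory, "params.json")) as fh:
            params = NetworkParams.from_json(fh.read())
        model = cls(params)
        with np.load(os.path.join(directory, "weights.npz")) as z:
            for bname, br in model.branches.items():
                for i, layer in enumerate(br.layers):
                    layer.W[...] = z[f"{bname}_{i}_W"]
                    layer.b[...] = z[f"{bname}_{i}_b"]
        hist = os.path.join(directory, "history.csv")
        if os.path.exists(hist):
            import pandas as pd

            model.history = pd.read_csv(hist).to_dict("records")
        return model


# ---------------------------------------------------------------------------
# functional surface
# ---------------------------------------------------------------------------

def train(
    spec: NetworkParams,
    train_batch: Tensor3DBatch,
    val_batch: Tensor3DBatch | None = None,
) -> MultiBranchModel:
    """Train a fresh model; deterministic given spec.seed on one device."""
    model = MultiBranchModel(spec)
    if spec.epochs > 0:
        model.fit(train_batch, val_batch)
    return model


def forward(model: MultiBranchModel, batch: Tensor3DBatch):
    return model.forward(batch.data)


def predict(model: MultiBranchModel, batch: Tensor3DBatch) -> np.ndarray:
    return model.predict(batch.data)
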