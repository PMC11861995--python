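"""Dense neural networks with hand-derived exact backpropagation.

Three architectures share one contract: ``scores`` for inference and
``loss_and_grads`` for training, the latter returning the weighted
binary-cross-entropy loss, gradients for every parameter, and the gradient
with respect to the input node-feature tensor (needed by the FGSM attack).

All arithmetic is float64 numpy, so identical seeds give bit-identical
training runs.  Batches are stacked along a leading axis: the normalized
adjacency is ``(B, n, n)`` and node features ``(B, n, d)``.

Backprop sketch for the weighted BCE head (per sample i with weight w_i):
``L = -w_i [y log s + (1-y) log(1-s)]`` with ``s = sigmoid(logit)`` gives
``dL/dlogit = w_i (s - y)``; everything upstream is the chain rule through
matmuls, ReLU/tanh, mean/max reductions and dropout masks.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit

__all__ = ["SimpleGCNNet", "ResidualGCNNet", "MLPNet", "Adam"]


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


def _sample_weights(y: np.ndarray, class_weights: tuple[float, float]) -> np.ndarray:
    w0, w1 = class_weights
    return np.where(y == 1, w1, w0)


def _bce_from_logits(
    logits: np.ndarray, y: np.ndarray, class_weights: tuple[float, float]
) -> tuple[float, np.ndarray]:
    """Returns (mean weighted BCE, dL/dlogit)."""
    s = expit(logits)
    w = _sample_weights(y, class_weights)
    eps = 1e-12
    loss = float(-(w * (y * np.log(s + eps) + (1 - y) * np.log(1 - s + eps))).mean())
    dlogit = w * (s - y) / y.size
    return loss, dlogit


def _dropout_mask(rng: np.random.Generator | None, shape, p: float) -> np.ndarray | None:
    if rng is None or p <= 0.0:
        return None
    return (rng.random(shape) >= p) / (1.0 - p)


class _Net:
    """Common parameter plumbing."""

    def params(self) -> dict[str, np.ndarray]:
        raise NotImplementedError

    def n_parameters(self) -> int:
        return int(sum(p.size for p in self.params().values()))

    def get_state(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params().items()}

    def set_state(self, state: dict[str, np.ndarray]) -> None:
        params = self.params()
        for k, v in state.items():
            params[k][...] = v


class SimpleGCNNet(_Net):
    """Stacked ReLU GCN layers -> global pooling -> dropout -> linear -> sigmoid."""

    def __init__(
        self,
        feature_dim: int,
        widths: list[int],
        pooling: str = "mean",
        dropout: float = 0.5,
        rng: np.random.Generator | None = None,
    ):
        if pooling not in ("mean", "max"):
            raise ValueError(f"unknown pooling {pooling!r}")
        rng = rng or np.random.default_rng(0)
        self.pooling = pooling
        self.dropout = dropout
        self.Ws, self.bs = [], []
        d = feature_dim
        for w in widths:
            self.Ws.append(_glorot(rng, d, w))
            self.bs.append(np.zeros(w))
            d = w
        self.w_out = _glorot(rng, d, 1)
        self.b_out = np.zeros(1)

    def params(self) -> dict[str, np.ndarray]:
        out = {}
        for i, (W, b) in enumerate(zip(self.Ws, self.bs)):
            out[f"W{i}"] = W
            out[f"b{i}"] = b
        out["w_out"] = self.w_out
        out["b_out"] = self.b_out
        return out

    def _forward(self, A, X, g_mask=None):
        H = X
        caches = []
        for W, b in zip(self.Ws, self.bs):
            AH = A @ H
            Z = AH @ W + b
            Hn = np.maximum(Z, 0.0)
            caches.append((AH, Z))
            H = Hn
        if self.pooling == "mean":
            g = H.mean(axis=1)
            arg = None
        else:
            arg = H.argmax(axis=1)
            g = np.take_along_axis(H, arg[:, None, :], axis=1)[:, 0, :]
        gd = g if g_mask is None else g * g_mask
        logits = gd @ self.w_out[:, 0] + self.b_out[0]
        return logits, (caches, H, g, gd, arg)

    def scores(self, A: np.ndarray, X: np.ndarray) -> np.ndarray:
        logits, _ = self._forward(A, X)
        return expit(logits)

    def loss_and_grads(self, A, X, y, class_weights=(1.0, 1.0), rng=None, train=True):
        g_mask = _dropout_mask(rng, (X.shape[0], self.Ws[-1].shape[1]), self.dropout) if train else None
        logits, (caches, H, g, gd, arg) = self._forward(A, X, g_mask)
        loss, dlogit = _bce_from_logits(logits, y, class_weights)

        grads = {
            "w_out": (gd.T @ dlogit)[:, None],
            "b_out": np.array([dlogit.sum()]),
        }
        dgd = np.outer(dlogit, self.w_out[:, 0])
        dg = dgd if g_mask is None else dgd * g_mask
        n_nodes = H.shape[1]
        if self.pooling == "mean":
            dH = np.repeat(dg[:, None, :] / n_nodes, n_nodes, axis=1)
        else:
            dH = np.zeros_like(H)
            np.put_along_axis(dH, arg[:, None, :], dg[:, None, :], axis=1)

        for i in reversed(range(len(self.Ws))):
            AH, Z = caches[i]
            dZ = dH * (Z > 0)
            grads[f"W{i}"] = np.einsum("bni,bnj->ij", AH, dZ)
            grads[f"b{i}"] = dZ.sum(axis=(0, 1))
            dAH = dZ @ self.Ws[i].T
            dH = np.swapaxes(A, 1, 2) @ dAH
        return loss, grads, dH


class ResidualGCNNet(_Net):
    """Tanh GCN layers whose per-layer aggregation summaries are concatenated
    at the readout (skip connections); with skips disabled only the final
    layer's summary reaches the classifier head."""

    def __init__(
        self,
        feature_dim: int,
        widths: list[int],
        aggregation: str = "mean",
        use_skips: bool = True,
        dropout: float = 0.5,
        rng: np.random.Generator | None = None,
    ):
        if aggregation not in ("mean", "max"):
            raise ValueError(f"unknown aggregation {aggregation!r}")
        rng = rng or np.random.default_rng(0)
        self.aggregation = aggregation
        self.use_skips = use_skips
        self.dropout = dropout
        self.Ws, self.bs = [], []
        d = feature_dim
        for w in widths:
            self.Ws.append(_glorot(rng, d, w))
            self.bs.append(np.zeros(w))
            d = w
        readout_dim = sum(W.shape[1] for W in self.Ws) if use_skips else self.Ws[-1].shape[1]
        self.w_out = _glorot(rng, readout_dim, 1)
        self.b_out = np.zeros(1)

    def params(self) -> dict[str, np.ndarray]:
        out = {}
        for i, (W, b) in enumerate(zip(self.Ws, self.bs)):
            out[f"W{i}"] = W
            out[f"b{i}"] = b
        out["w_out"] = self.w_out
        out["b_out"] = self.b_out
        return out

    def _forward(self, A, X, r_mask=None):
        H = X
        caches, summaries, args = [], [], []
        for W, b in zip(self.Ws, self.bs):
            AH = A @ H
            Hn = np.tanh(AH @ W + b)
            caches.append((AH, Hn))
            if self.aggregation == "mean":
                summaries.append(Hn.mean(axis=1))
                args.append(None)
            else:
                arg = Hn.argmax(axis=1)
                args.append(arg)
                summaries.append(np.take_along_axis(Hn, arg[:, None, :], axis=1)[:, 0, :])
            H = Hn
        r = np.concatenate(summaries, axis=1) if self.use_skips else summaries[-1]
        rd = r if r_mask is None else r * r_mask
        logits = rd @ self.w_out[:, 0] + self.b_out[0]
        return logits, (caches, args, rd)

    def scores(self, A: np.ndarray, X: np.ndarray) -> np.ndarray:
        logits, _ = self._forward(A, X)
        return expit(logits)

    def loss_and_grads(self, A, X, y, class_weights=(1.0, 1.0), rng=None, train=True):
        r_dim = self.w_out.shape[0]
        r_mask = _dropout_mask(rng, (X.shape[0], r_dim), self.dropout) if train else None
        logits, (caches, args, rd) = self._forward(A, X, r_mask)
        loss, dlogit = _bce_from_logits(logits, y, class_weights)

        grads = {
            "w_out": (rd.T @ dlogit)[:, None],
            "b_out": np.array([dlogit.sum()]),
        }
        drd = np.outer(dlogit, self.w_out[:, 0])
        dr = drd if r_mask is None else drd * r_mask

        L = len(self.Ws)
        widths = [W.shape[1] for W in self.Ws]
        dsummaries = [np.zeros((X.shape[0], w)) for w in widths]
        if self.use_skips:
            off = 0
            for i, w in enumerate(widths):
                dsummaries[i] = dr[:, off : off + w]
                off += w
        else:
            dsummaries[-1] = dr

        n_nodes = X.shape[1]
        dH_next = np.zeros((X.shape[0], n_nodes, widths[-1]))
        for i in reversed(range(L)):
            AH, Hn = caches[i]
            if self.aggregation == "mean":
                dH_summary = np.repeat(dsummaries[i][:, None, :] / n_nodes, n_nodes, axis=1)
            else:
                dH_summary = np.zeros_like(Hn)
                np.put_along_axis(dH_summary, args[i][:, None, :], dsummaries[i][:, None, :], axis=1)
            dHn = dH_next + dH_summary
            dZ = dHn * (1.0 - Hn**2)
            grads[f"W{i}"] = np.einsum("bni,bnj->ij", AH, dZ)
            grads[f"b{i}"] = dZ.sum(axis=(0, 1))
            dAH = dZ @ self.Ws[i].T
            dH_next = np.swapaxes(A, 1, 2) @ dAH
        return loss, grads, dH_next


class MLPNet(_Net):
    """Flattened node-feature input through ReLU hidden layers with dropout,
    then a linear sigmoid head."""

    def __init__(
        self,
        input_dim: int,
        widths: list[int] = (512, 256, 128),
        dropout: float = 0.5,
        rng: np.random.Generator | None = None,
    ):
        rng = rng or np.random.default_rng(0)
        self.input_dim = input_dim
        self.dropout = dropout
        self.Ws, self.bs = [], []
        d = input_dim
        for w in widths:
            self.Ws.append(_glorot(rng, d, w))
            self.bs.append(np.zeros(w))
            d = w
        self.w_out = _glorot(rng, d, 1)
        self.b_out = np.zeros(1)

    def params(self) -> dict[str, np.ndarray]:
        out = {}
        for i, (W, b) in enumerate(zip(self.Ws, self.bs)):
            out[f"W{i}"] = W
            out[f"b{i}"] = b
        out["w_out"] = self.w_out
        out["b_out"] = self.b_out
        return out

    def _forward(self, X, masks=None):
        x = X.reshape(X.shape[0], -1)
        if x.shape[1] != self.input_dim:
            raise ValueError(f"flattened input dim {x.shape[1]} != expected {self.input_dim}")
        caches = []
        h = x
        for i, (W, b) in enumerate(zip(self.Ws, self.bs)):
            Z = h @ W + b
            hn = np.maximum(Z, 0.0)
            m = None if masks is None else masks[i]
            hd = hn if m is None else hn * m
            caches.append((h, Z, m))
            h = hd
        logits = h @ self.w_out[:, 0] + self.b_out[0]
        return logits, (caches, h)

    def scores(self, A: np.ndarray, X: np.ndarray) -> np.ndarray:
        # A accepted for interface uniformity; the MLP ignores graph structure.
        logits, _ = self._forward(X)
        return expit(logits)

    def loss_and_grads(self, A, X, y, class_weights=(1.0, 1.0), rng=None, train=True):
        masks = None
        if train and rng is not None and self.dropout > 0:
            masks = [
                _dropout_mask(rng, (X.shape[0], W.shape[1]), self.dropout) for W in self.Ws
            ]
        logits, (caches, h_last) = self._forward(X, masks)
        loss, dlogit = _bce_from_logits(logits, y, class_weights)

        grads = {
            "w_out": (h_last.T @ dlogit)[:, None],
            "b_out": np.array([dlogit.sum()]),
        }
        dh = np.outer(dlogit, self.w_out[:, 0])
        for i in reversed(range(len(self.Ws))):
            h_prev, Z, m = caches[i]
            if m is not None:
                dh = dh * m
            dZ = dh * (Z > 0)
            grads[f"W{i}"] = h_prev.T @ dZ
            grads[f"b{i}"] = dZ.sum(axis=0)
            dh = dZ @ self.Ws[i].T
        return loss, grads, dh.reshape(X.shape)


class Adam:
    """Adam with L2 weight decay folded into the gradient (the convention of
    mainstream deep-learning optimizers when a weight-decay setting is given)."""

    def __init__(
        self,
        params: dict[str, np.ndarray],
        lr: float = 1e-3,
        weight_decay: float = 0.0,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ):
        self.params = params
        self.lr = lr
        self.weight_decay = weight_decay
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k, p in self.params.items():
            g = grads[k] + self.weight_decay * p
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / (1 - b1**self.t)
            vhat = self.v[k] / (1 - b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
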