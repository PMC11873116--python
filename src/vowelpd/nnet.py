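"""Frozen random convolutional backbone and a trainable MLP head.

The classification recipe for spectrogram images is transfer-learning
style: a *frozen* convolutional feature extractor followed by a small
multi-layer-perceptron head that is the only part trained on the voice
data.  The head matches the published recipe: batch normalization, two
dense layers of 1024 relu units, 20% dropout, and a 2-class softmax
output, trained with Adam (lr 0.001) for 10 epochs at batch size 4.

The backbone shipped here is the "tiny-random" option: a fixed-seed
two-layer random convolutional network with spatial average pooling.
Random convolutional features are a standard lightweight stand-in for
pretrained features — they preserve local spectro-temporal structure
(harmonic band positions, ripple energy) well enough for a linear-ish
head to classify, while keeping the whole model dependency-free and
deterministic.  Any callable mapping image batches to feature matrices
can be plugged in instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

TINY_INPUT_SIZE = 128  # backbone expects (n, 128, 128, 3) images in [0, 1]


class TinyRandomBackbone:
    """Fixed-seed random convolutional feature extractor (frozen).

    Two valid-mode convolution layers (16 filters 7x7 stride 4, then
    32 filters 5x5 stride 2, relu after each) followed by 4x4 spatial
    average pooling, giving a 512-dimensional feature vector per image.
    Weights are drawn once from ``seed`` and never trained.
    """

    def __init__(self, seed: int = 0, input_size: int = TINY_INPUT_SIZE):
        rng = np.random.default_rng(seed)
        self.input_size = input_size
        self.w1 = rng.standard_normal((16, 7, 7, 3)) / np.sqrt(7 * 7 * 3)
        self.w2 = rng.standard_normal((32, 5, 5, 16)) / np.sqrt(5 * 5 * 16)

    @staticmethod
    def _conv(x: np.ndarray, w: np.ndarray, stride: int) -> np.ndarray:
        """Valid-mode strided convolution via im2col; x is (n, H, W, C)."""
        n, h, wid, c = x.shape
        kf, kh, kw, kc = w.shape
        oh = (h - kh) // stride + 1
        ow = (wid - kw) // stride + 1
        s0, s1, s2, s3 = x.strides
        patches = np.lib.stride_tricks.as_strided(
            x,
            shape=(n, oh, ow, kh, kw, c),
            strides=(s0, s1 * stride, s2 * stride, s1, s2, s3),
            writeable=False,
        )
        cols = patches.reshape(n * oh * ow, kh * kw * kc)
        out = cols @ w.reshape(kf, -1).T
        return out.reshape(n, oh, ow, kf)

    def features(self, images: np.ndarray) -> np.ndarray:
        """Map (n, H, W, 3) images in [0, 1] to (n, 512) features."""
        x = np.asarray(images, dtype=np.float64)
        if x.ndim == 3:
            x = x[None]
        if x.shape[1] != self.input_size or x.shape[2] != self.input_size:
            raise ValueError(
                f"backbone expects {self.input_size}x{self.input_size} images, "
                f"got {x.shape[1]}x{x.shape[2]}"
            )
        h1 = np.maximum(self._conv(x - 0.5, self.w1, stride=4), 0.0)
        h2 = np.maximum(self._conv(h1, self.w2, stride=2), 0.0)
        # 4x4 spatial average pooling -> (n, 4, 4, 32) -> (n, 512)
        n, oh, ow, c = h2.shape
        gh, gw = oh // 4, ow // 4
        pooled = (
            h2[:, : gh * 4, : gw * 4]
            .reshape(n, 4, gh, 4, gw, c)
            .mean(axis=(2, 4))
        )
        return pooled.reshape(n, -1)


@dataclass
class TrainingCurve:
    """Per-epoch mean losses recorded while training the head."""

    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)


class MLPHead:
    """Batchnorm -> dense(1024, relu) -> dense(1024, relu) -> dropout(0.2)
    -> dense(2, softmax), trained with Adam.

    The batch-normalization layer is realized as feature standardization
    with statistics frozen from the training set (the inference-mode view
    of batch norm), which is what a frozen-backbone + small-head setup
    reduces to at these data sizes.
    """

    def __init__(
        self,
        hidden: int = 1024,
        dropout: float = 0.2,
        lr: float = 1e-3,
        epochs: int = 10,
        batch_size: int = 4,
        seed: int = 0,
    ):
        self.hidden = hidden
        self.dropout = dropout
        self.lr = lr
        self.epochs = epochs
        self.batch_size = batch_size
        self.seed = seed
        self.curve = TrainingCurve()
        self._fitted = False

    # --- internals ---------------------------------------------------------

    def _forward(
        self, z: np.ndarray, rng: np.random.Generator | None
    ) -> tuple[np.ndarray, tuple]:
        h1 = np.maximum(z @ self.W1 + self.b1, 0.0)
        h2 = np.maximum(h1 @ self.W2 + self.b2, 0.0)
        if rng is not None and self.dropout > 0:
            mask = (rng.uniform(size=h2.shape) >= self.dropout) / (1 - self.dropout)
            h2d = h2 * mask
        else:
            mask = None
            h2d = h2
        logits = h2d @ self.W3 + self.b3
        logits = logits - logits.max(axis=1, keepdims=True)
        e = np.exp(logits)
        probs = e / e.sum(axis=1, keepdims=True)
        return probs, (z, h1, h2, mask, h2d)

    def fit(
        self,
        X: np.ndarray,
        y: np.ndarray,
        X_val: np.ndarray | None = None,
        y_val: np.ndarray | None = None,
    ) -> "MLPHead":
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y, dtype=int)
        if len(np.unique(y)) < 2:
            raise ValueError("training labels must contain both classes")
        rng = np.random.default_rng(self.seed)
        n, d = X.shape

        # batch-norm statistics frozen from the training set
        self.mu = X.mean(axis=0)
        self.sigma = X.std(axis=0) + 1e-8
        Z = (X - self.mu) / self.sigma

        h = self.hidden
        self.W1 = rng.standard_normal((d, h)) * np.sqrt(2.0 / d)
        self.b1 = np.zeros(h)
        self.W2 = rng.standard_normal((h, h)) * np.sqrt(2.0 / h)
        self.b2 = np.zeros(h)
        self.W3 = rng.standard_normal((h, 2)) * np.sqrt(2.0 / h)
        self.b3 = np.zeros(2)

        params = ["W1", "b1", "W2", "b2", "W3", "b3"]
        m = {p: np.zeros_like(getattr(self, p)) for p in params}
        v = {p: np.zeros_like(getattr(self, p)) for p in params}
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        t = 0

        onehot = np.eye(2)[y]
        for _ in range(self.epochs):
            order = rng.permutation(n)
            losses = []
            for start in range(0, n, self.batch_size):
                idx = order[start : start + self.batch_size]
                zb, yb = Z[idx], onehot[idx]
                probs, (_, h1, h2, mask, h2d) = self._forward(zb, rng)
                losses.append(
                    float(-np.mean(np.sum(yb * np.log(probs + 1e-12), axis=1)))
                )
                nb = len(idx)
                dlogits = (probs - yb) / nb
                grads = {}
                grads["W3"] = h2d.T @ dlogits
                grads["b3"] = dlogits.sum(axis=0)
                dh2d = dlogits @ self.W3.T
                dh2 = dh2d * (mask if mask is not None else 1.0)
                dh2 = dh2 * (h2 > 0)
                grads["W2"] = h1.T @ dh2
                grads["b2"] = dh2.sum(axis=0)
                dh1 = dh2 @ self.W2.T
                dh1 = dh1 * (h1 > 0)
                grads["W1"] = zb.T @ dh1
                grads["b1"] = dh1.sum(axis=0)
                t += 1
                for p in params:
                    g = grads[p]
                    m[p] = beta1 * m[p] + (1 - beta1) * g
                    v[p] = beta2 * v[p] + (1 - beta2) * g * g
                    mh = m[p] / (1 - beta1**t)
                    vh = v[p] / (1 - beta2**t)
                    setattr(
                        self,
                        p,
                        getattr(self, p) - self.lr * mh / (np.sqrt(vh) + eps),
                    )
            self.curve.train_loss.append(float(np.mean(losses)))
            if X_val is not None and y_val is not None and len(X_val):
                pv = self.predict_proba_raw(X_val)
                yv = np.eye(2)[np.asarray(y_val, dtype=int)]
                self.curve.val_loss.append(
                    float(-np.mean(np.sum(yv * np.log(pv + 1e-12), axis=1)))
                )
        self._fitted = True
        return self

    def predict_proba_raw(self, X: np.ndarray) -> np.ndarray:
        Z = (np.asarray(X, dtype=np.float64) - self.mu) / self.sigma
        probs, _ = self._forward(Z, rng=None)
        return probs

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Class probabilities, shape (n, 2); column 1 is the positive class."""
        if not self._fitted:
            raise RuntimeError("head is not fitted")
        return self.predict_proba_raw(X)
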