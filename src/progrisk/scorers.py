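"""Reference scorers: small trainable networks mapping a scan payload to one
real-valued score.

Two scorers are provided, matching the two payload kinds of the simulator:

* :class:`MLPScorer` — tanh multilayer perceptron for feature vectors;
* :class:`ConvScorer` — a compact 3-block convolutional network (3x3 conv,
  ReLU, 2x2 average pooling) with a global-average-pooled linear head, for
  2-D grayscale images.

Both are plain numpy with hand-derived backpropagation and expose the same
contract: ``forward(X)`` for inference, ``forward_cache`` / ``backward`` for
training, ``embed(X)`` for the penultimate representation used by the
Siamese contrastive comparator.  ``backward`` accepts the gradient of the
loss w.r.t. the scalar scores and, optionally, w.r.t. the embeddings, and
returns parameter gradients aligned with ``params``.  Inference is
deterministic given fixed parameters.  Optimization uses Adam.
"""

from __future__ import annotations

import numpy as np

__all__ = ["MLPScorer", "ConvScorer", "Adam"]


class Adam:
    """Adam optimizer over a list of parameter arrays (decoupled weight
    decay applied multiplicatively before the update)."""

    def __init__(self, params, lr=0.01, beta1=0.9, beta2=0.999, eps=1e-8,
                 weight_decay=0.0):
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.weight_decay = weight_decay
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params, grads):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, g, m, v in zip(params, grads, self.m, self.v):
            if self.weight_decay and p.ndim > 1:  # decay weights, not biases
                p *= 1.0 - self.lr * self.weight_decay
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class MLPScorer:
    """Tanh MLP: features (n, d) -> scores (n,).

    The last hidden activation is the embedding.  Glorot-uniform init,
    deterministic given ``seed``.
    """

    def __init__(self, n_features, hidden=(16,), seed=0):
        self.n_features = int(n_features)
        self.hidden = tuple(int(h) for h in hidden)
        if not self.hidden:
            raise ValueError("need at least one hidden layer")
        rng = np.random.default_rng([int(seed), 31])
        dims = (self.n_features, *self.hidden, 1)
        self.params = []
        for d_in, d_out in zip(dims, dims[1:]):
            lim = np.sqrt(6.0 / (d_in + d_out))
            self.params.append(rng.uniform(-lim, lim, size=(d_in, d_out)))
            self.params.append(np.zeros(d_out))

    @property
    def embed_dim(self) -> int:
        return self.hidden[-1]

    def _layers(self):
        for i in range(0, len(self.params), 2):
            yield self.params[i], self.params[i + 1]

    def forward_cache(self, X):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        acts = [X]
        n_layers = len(self.params) // 2
        h = X
        for li, (W, b) in enumerate(self._layers()):
            z = h @ W + b
            h = z if li == n_layers - 1 else np.tanh(z)
            acts.append(h)
        scores = acts[-1][:, 0]
        return scores, acts

    def forward(self, X):
        return self.forward_cache(X)[0]

    def embed(self, X):
        """Penultimate (last hidden) activation."""
        _, acts = self.forward_cache(X)
        return acts[-2]

    @staticmethod
    def embed_from_cache(acts):
        return acts[-2]

    def backward(self, acts, dscore, dembed=None):
        """Parameter gradients given d(loss)/d(score) per sample and an
        optional d(loss)/d(embedding)."""
        n_layers = len(self.params) // 2
        grads = [None] * len(self.params)
        delta = np.asarray(dscore, dtype=float)[:, None]  # gradient at output z
        for li in range(n_layers - 1, -1, -1):
            W = self.params[2 * li]
            h_in = acts[li]
            grads[2 * li] = h_in.T @ delta
            grads[2 * li + 1] = delta.sum(axis=0)
            if li > 0:
                dh = delta @ W.T
                if dembed is not None and li == n_layers - 1:
                    dh = dh + dembed
                delta = dh * (1.0 - acts[li] ** 2)  # through tanh
        return grads

    def copy_params(self):
        return [p.copy() for p in self.params]

    def set_params_(self, params):
        for p, q in zip(self.params, params):
            p[...] = q


def _im2col(x, k):
    """(n, c, H, W) -> (n, H', W', c*k*k) of k x k patches (valid padding)."""
    win = np.lib.stride_tricks.sliding_window_view(x, (k, k), axis=(2, 3))
    n, c, hh, ww, _, _ = win.shape
    return np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(
        n, hh, ww, c * k * k
    )


def _col2im(dcol, x_shape, k):
    """Adjoint of :func:`_im2col`: scatter-add patch gradients back."""
    n, c, H, W = x_shape
    hh, ww = H - k + 1, W - k + 1
    dwin = dcol.reshape(n, hh, ww, c, k, k)
    dx = np.zeros(x_shape, dtype=float)
    for di in range(k):
        for dj in range(k):
            dx[:, :, di : di + hh, dj : dj + ww] += dwin[:, :, :, :, di, dj].transpose(
                0, 3, 1, 2
            )
    return dx


class ConvScorer:
    """3-block CNN: grayscale images (n, H, W) -> scores (n,).

    Each block is 3x3 valid convolution -> ReLU -> 2x2 average pooling; the
    final feature maps are globally average-pooled into the embedding, which
    a linear head maps to the score.
    """

    KERNEL = 3

    def __init__(self, image_size, channels=(4, 8, 8), seed=0):
        self.image_size = int(image_size)
        self.channels = tuple(int(c) for c in channels)
        rng = np.random.default_rng([int(seed), 37])
        k = self.KERNEL
        self.params = []
        size = self.image_size
        c_in = 1
        for c_out in self.channels:
            fan_in = c_in * k * k
            lim = np.sqrt(6.0 / (fan_in + c_out))
            self.params.append(rng.uniform(-lim, lim, size=(fan_in, c_out)))
            self.params.append(np.zeros(c_out))
            size = (size - k + 1) // 2
            if size < 1:
                raise ValueError("image too small for 3 conv blocks")
            c_in = c_out
        lim = np.sqrt(6.0 / (c_in + 1))
        self.params.append(rng.uniform(-lim, lim, size=(c_in, 1)))
        self.params.append(np.zeros(1))

    @property
    def embed_dim(self) -> int:
        return self.channels[-1]

    def forward_cache(self, X):
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:
            X = X[None]
        x = X[:, None, :, :]  # (n, 1, H, W)
        cache = {"inputs": [], "cols": [], "relu": [], "pool_hw": []}
        k = self.KERNEL
        for bi in range(len(self.channels)):
            W, b = self.params[2 * bi], self.params[2 * bi + 1]
            cache["inputs"].append(x.shape)
            col = _im2col(x, k)  # (n, h', w', fan_in)
            cache["cols"].append(col)
            z = col @ W + b  # (n, h', w', c_out)
            r = np.maximum(z, 0.0)
            cache["relu"].append(z > 0)
            hh, ww = r.shape[1] // 2 * 2, r.shape[2] // 2 * 2
            cache["pool_hw"].append((r.shape[1], r.shape[2]))
            pooled = r[:, :hh, :ww].reshape(
                r.shape[0], hh // 2, 2, ww // 2, 2, r.shape[3]
            ).mean(axis=(2, 4))
            x = pooled.transpose(0, 3, 1, 2)  # (n, c_out, h, w)
        emb = x.mean(axis=(2, 3))  # global average pool -> (n, c_last)
        cache["emb_in_shape"] = x.shape
        cache["emb"] = emb
        Wh, bh = self.params[-2], self.params[-1]
        scores = (emb @ Wh + bh)[:, 0]
        return scores, cache

    def forward(self, X):
        return self.forward_cache(X)[0]

    def embed(self, X):
        return self.forward_cache(X)[1]["emb"]

    @staticmethod
    def embed_from_cache(cache):
        return cache["emb"]

    def backward(self, cache, dscore, dembed=None):
        grads = [None] * len(self.params)
        emb = cache["emb"]
        dscore = np.asarray(dscore, dtype=float)[:, None]
        grads[-2] = emb.T @ dscore
        grads[-1] = dscore.sum(axis=0)
        demb = dscore @ self.params[-2].T
        if dembed is not None:
            demb = demb + dembed
        n, c, h, w = cache["emb_in_shape"]
        dx = np.broadcast_to(demb[:, :, None, None] / (h * w), (n, c, h, w))
        for bi in range(len(self.channels) - 1, -1, -1):
            dpooled = dx.transpose(0, 2, 3, 1)  # (n, h, w, c)
            rh, rw = cache["pool_hw"][bi]
            hh, ww = rh // 2 * 2, rw // 2 * 2
            dr = np.zeros((dx.shape[0], rh, rw, dx.shape[1]), dtype=float)
            dr[:, :hh, :ww] = np.repeat(
                np.repeat(dpooled, 2, axis=1), 2, axis=2
            ) / 4.0
            dz = dr * cache["relu"][bi]
            col = cache["cols"][bi]
            flat_col = col.reshape(-1, col.shape[-1])
            flat_dz = dz.reshape(-1, dz.shape[-1])
            grads[2 * bi] = flat_col.T @ flat_dz
            grads[2 * bi + 1] = flat_dz.sum(axis=0)
            dcol = flat_dz @ self.params[2 * bi].T
            dx = _col2im(
                dcol.reshape(col.shape), cache["inputs"][bi], self.KERNEL
            )
        return grads

    def copy_params(self):
        return [p.copy() for p in self.params]

    def set_params_(self, params):
        for p, q in zip(self.params, params):
            p[...] = q
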