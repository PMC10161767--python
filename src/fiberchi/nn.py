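"""Minimal fully connected network with MAE loss, Adam, and input gradients.

A compact numpy implementation sized for CPU training on curve-length inputs.
float32 throughout; He-initialized ReLU hidden layers and a linear output.
Exact backpropagation is also exposed with respect to the *input*, which is
what gradient saliency maps need.
"""

from __future__ import annotations

import numpy as np

__all__ = ["MLP"]


class MLP:
    """ReLU multilayer perceptron trained by Adam on mean absolute error."""

    def __init__(self, layer_sizes, seed=0, dtype=np.float32):
        if len(layer_sizes) < 2:
            raise ValueError("need at least input and output sizes")
        self.layer_sizes = tuple(int(s) for s in layer_sizes)
        self.dtype = dtype
        rng = np.random.default_rng(seed)
        self.W, self.b = [], []
        for fan_in, fan_out in zip(self.layer_sizes[:-1], self.layer_sizes[1:]):
            w = rng.standard_normal((fan_in, fan_out)) * np.sqrt(2.0 / fan_in)
            self.W.append(w.astype(dtype))
            self.b.append(np.zeros(fan_out, dtype=dtype))
        self._adam_state = None

    # ------------------------------------------------------------------ core
    def forward(self, X, keep=False):
        """Forward pass; with keep=True also returns per-layer activations."""
        A = [np.asarray(X, dtype=self.dtype)]
        h = A[0]
        n_layers = len(self.W)
        for i, (w, b) in enumerate(zip(self.W, self.b)):
            z = h @ w + b
            h = z if i == n_layers - 1 else np.maximum(z, 0.0)
            if keep:
                A.append(h)
        return (h, A) if keep else h

    predict = forward

    def _backward(self, A, dOut):
        """Gradients of a scalar loss wrt weights, biases and the input,
        given dLoss/dOutput."""
        gW = [None] * len(self.W)
        gb = [None] * len(self.b)
        d = dOut.astype(self.dtype)
        for i in range(len(self.W) - 1, -1, -1):
            if i != len(self.W) - 1:
                d = d * (A[i + 1] > 0)
            gW[i] = A[i].T @ d
            gb[i] = d.sum(axis=0)
            d = d @ self.W[i].T
        return gW, gb, d

    def loss_and_grads(self, X, Y):
        """Mean absolute error over all outputs and its parameter gradients."""
        out, A = self.forward(X, keep=True)
        resid = out - np.asarray(Y, dtype=self.dtype)
        loss = float(np.abs(resid).mean())
        dOut = np.sign(resid) / resid.size
        gW, gb, _ = self._backward(A, dOut)
        return loss, gW, gb

    def input_gradient(self, X, output_index):
        """d output[:, output_index] / d input, one row per sample (exact)."""
        X = np.atleast_2d(np.asarray(X, dtype=self.dtype))
        _, A = self.forward(X, keep=True)
        dOut = np.zeros((X.shape[0], self.layer_sizes[-1]), dtype=self.dtype)
        dOut[:, output_index] = 1.0
        _, _, dX = self._backward(A, dOut)
        return dX

    # ------------------------------------------------------------------ adam
    def adam_step(self, gW, gb, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        if self._adam_state is None:
            self._adam_state = {
                "t": 0,
                "mW": [np.zeros_like(w) for w in self.W],
                "vW": [np.zeros_like(w) for w in self.W],
                "mb": [np.zeros_like(b) for b in self.b],
                "vb": [np.zeros_like(b) for b in self.b],
            }
        s = self._adam_state
        s["t"] += 1
        t = s["t"]
        corr = np.sqrt(1.0 - beta2**t) / (1.0 - beta1**t)
        for i in range(len(self.W)):
            for g, p, m, v in ((gW[i], self.W[i], s["mW"][i], s["vW"][i]),
                               (gb[i], self.b[i], s["mb"][i], s["vb"][i])):
                m *= beta1
                m += (1.0 - beta1) * g
                v *= beta2
                v += (1.0 - beta2) * g * g
                p -= (lr * corr) * m / (np.sqrt(v) + eps)

    # ------------------------------------------------------------ persistence
    def get_weights(self):
        return {"layer_sizes": np.array(self.layer_sizes),
                **{f"W{i}": w for i, w in enumerate(self.W)},
                **{f"b{i}": b for i, b in enumerate(self.b)}}

    @classmethod
    def from_weights(cls, d):
        sizes = [int(s) for s in np.asarray(d["layer_sizes"])]
        net = cls(sizes)
        net.W = [np.asarray(d[f"W{i}"], dtype=net.dtype) for i in range(len(sizes) - 1)]
        net.b = [np.asarray(d[f"b{i}"], dtype=net.dtype) for i in range(len(sizes) - 1)]
        return net
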