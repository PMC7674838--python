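"""A small from-scratch 3-D convolutional network in numpy.

Architecture (fixed layer sequence): one 3-D convolutional layer with
stride, ReLU, strided 3-D max-pooling, a fully-connected layer, soft-max,
and the binary classification output.  Optimization is mini-batch
stochastic gradient descent with momentum (SGDM) on the cross-entropy
loss.  Written in pure numpy so it runs anywhere at desk scale; the
convolution stride may exceed the receptive field (sparse sampling of the
patch), matching the full-scale configuration where both strides are 4.

Training is bit-reproducible for a fixed seed on a single thread.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .io_volumes import ValidationError

__all__ = ["Conv3DNet", "TrainingError"]


class TrainingError(RuntimeError):
    """Optimization produced a non-finite loss."""


def _out_extent(extent: int, window: int, stride: int) -> int:
    return (extent - window) // stride + 1


class Conv3DNet:
    """conv -> ReLU -> max-pool -> fully-connected -> soft-max."""

    def __init__(
        self,
        input_shape: tuple[int, int, int],
        n_filters: int = 8,
        receptive_field: int = 3,
        conv_stride: int = 4,
        pool_window: int = 3,
        pool_stride: int = 4,
        seed: int = 0,
    ):
        self.input_shape = tuple(input_shape)
        self.n_filters = n_filters
        self.rf = receptive_field
        self.cs = conv_stride
        self.pw = pool_window
        self.ps = pool_stride
        self.conv_shape = tuple(
            _out_extent(d, self.rf, self.cs) for d in self.input_shape
        )
        if min(self.conv_shape) < 1:
            raise ValidationError(
                f"input {self.input_shape} too small for receptive field "
                f"{self.rf} at stride {self.cs}"
            )
        if min(self.conv_shape) < self.pw:
            raise ValidationError(
                f"conv output {self.conv_shape} smaller than pool window "
                f"{self.pw}"
            )
        self.pool_shape = tuple(
            _out_extent(d, self.pw, self.ps) for d in self.conv_shape
        )
        self.n_flat = int(np.prod(self.pool_shape)) * n_filters
        rng = np.random.default_rng(seed)
        scale = np.sqrt(2.0 / (self.rf**3))
        self.Wc = rng.normal(0.0, scale, (n_filters, self.rf, self.rf, self.rf))
        self.bc = np.zeros(n_filters)
        self.Wf = rng.normal(0.0, np.sqrt(2.0 / self.n_flat), (self.n_flat, 2))
        self.bf = np.zeros(2)
        self._rng = rng

    # -- forward -----------------------------------------------------------

    def _conv_windows(self, X: np.ndarray) -> np.ndarray:
        w = sliding_window_view(X, (self.rf, self.rf, self.rf), axis=(1, 2, 3))
        return w[:, :: self.cs, :: self.cs, :: self.cs]

    def _forward(self, X: np.ndarray):
        windows = self._conv_windows(X)
        conv = np.einsum("bxyzpqr,fpqr->bxyzf", windows, self.Wc) + self.bc
        act = np.maximum(conv, 0.0)
        pw = sliding_window_view(act, (self.pw, self.pw, self.pw), axis=(1, 2, 3))
        pw = pw[:, :: self.ps, :: self.ps, :: self.ps]
        B = X.shape[0]
        flatwin = pw.reshape(*pw.shape[:5], -1)
        argmax = flatwin.argmax(axis=-1)
        pooled = np.take_along_axis(flatwin, argmax[..., None], axis=-1)[..., 0]
        feats = pooled.reshape(B, -1)
        logits = feats @ self.Wf + self.bf
        logits -= logits.max(axis=1, keepdims=True)
        expz = np.exp(logits)
        probs = expz / expz.sum(axis=1, keepdims=True)
        return windows, conv, act, argmax, feats, probs

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        return self._forward(X)[-1]

    # -- backward ----------------------------------------------------------

    def _gradients(self, X: np.ndarray, y: np.ndarray):
        windows, conv, act, argmax, feats, probs = self._forward(X)
        B = X.shape[0]
        onehot = np.zeros_like(probs)
        onehot[np.arange(B), y] = 1.0
        loss = -np.mean(np.log(np.clip(probs[np.arange(B), y], 1e-12, None)))
        dz = (probs - onehot) / B
        dWf = feats.T @ dz
        dbf = dz.sum(axis=0)
        dfeats = dz @ self.Wf.T
        dpooled = dfeats.reshape(B, *self.pool_shape, self.n_filters)
        # route pooled gradients back to the argmax positions of each window
        dact = np.zeros_like(act)
        P1, P2, P3 = self.pool_shape
        px, py, pz = np.unravel_index(argmax, (self.pw, self.pw, self.pw))
        bx = np.arange(P1)[:, None, None] * self.ps
        by = np.arange(P2)[None, :, None] * self.ps
        bz = np.arange(P3)[None, None, :] * self.ps
        ix = bx[None, :, :, :, None] + px
        iy = by[None, :, :, :, None] + py
        iz = bz[None, :, :, :, None] + pz
        bidx = np.broadcast_to(
            np.arange(B)[:, None, None, None, None], ix.shape
        )
        fidx = np.broadcast_to(
            np.arange(self.n_filters)[None, None, None, None, :], ix.shape
        )
        np.add.at(dact, (bidx, ix, iy, iz, fidx), dpooled)
        dconv = dact * (conv > 0.0)
        dWc = np.einsum("bxyzpqr,bxyzf->fpqr", windows, dconv)
        dbc = dconv.sum(axis=(0, 1, 2, 3))
        return loss, dWc, dbc, dWf, dbf

    # -- training ----------------------------------------------------------

    def fit(
        self,
        X: np.ndarray,
        y: np.ndarray,
        learning_rate: float = 1e-4,
        momentum: float = 0.9,
        epochs: int = 20,
        batch_size: int = 30,
    ) -> list[float]:
        """SGDM training; returns per-epoch mean losses."""
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y, dtype=np.int64)
        n = X.shape[0]
        vWc = np.zeros_like(self.Wc)
        vbc = np.zeros_like(self.bc)
        vWf = np.zeros_like(self.Wf)
        vbf = np.zeros_like(self.bf)
        history = []
        for _ in range(epochs):
            order = self._rng.permutation(n)
            losses = []
            for start in range(0, n, batch_size):
                idx = order[start : start + batch_size]
                loss, dWc, dbc, dWf, dbf = self._gradients(X[idx], y[idx])
                if not np.isfinite(loss):
                    raise TrainingError(
                        f"non-finite loss ({loss}) at epoch {len(history)}; "
                        f"lr={learning_rate}, batch={batch_size}"
                    )
                vWc = momentum * vWc - learning_rate * dWc
                vbc = momentum * vbc - learning_rate * dbc
                vWf = momentum * vWf - learning_rate * dWf
                vbf = momentum * vbf - learning_rate * dbf
                self.Wc += vWc
                self.bc += vbc
                self.Wf += vWf
                self.bf += vbf
                losses.append(loss)
            history.append(float(np.mean(losses)))
        return history
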