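"""A compact mixed-scale dense convolutional network in NumPy.

The architecture follows the mixed-scale dense (MSD) design: every layer
produces a single feature channel by convolving *all* previous channels
(input slab included) with 3×3 kernels at a layer-specific dilation that
cycles through a fixed schedule, applying ReLU; the output is a learned 1×1
combination of every channel in the network.  Dense connectivity keeps the
parameter count tiny (≈ 9·depth·(depth/2 + c_in) weights) while the cycling
dilations grow the receptive field quickly.

Convolutions use zero padding and are realised as nine shifted copies
contracted with the kernel by BLAS, in float32, so desk-scale training
(depth ≈ 20, 64–128 px slices) runs in minutes on one CPU with
bit-reproducible results for a fixed seed and thread count.
"""

from __future__ import annotations

import numpy as np

__all__ = ["MSDNet"]

_OFFSETS = [(dy, dx) for dy in (-1, 0, 1) for dx in (-1, 0, 1)]
_DTYPE = np.float32


def _shift(a: np.ndarray, dy: int, dx: int) -> np.ndarray:
    """out[..., y, x] = a[..., y+dy, x+dx] with zero padding."""
    if dy == 0 and dx == 0:
        return a.copy()
    out = np.zeros_like(a)
    H, W = a.shape[-2:]
    y_src0, y_src1 = max(dy, 0), H + min(dy, 0)
    x_src0, x_src1 = max(dx, 0), W + min(dx, 0)
    y_dst0, y_dst1 = max(-dy, 0), H + min(-dy, 0)
    x_dst0, x_dst1 = max(-dx, 0), W + min(-dx, 0)
    if y_src0 >= y_src1 or x_src0 >= x_src1:
        return out
    out[..., y_dst0:y_dst1, x_dst0:x_dst1] = a[..., y_src0:y_src1, x_src0:x_src1]
    return out


def _shift_stack(a: np.ndarray, d: int, sign: int = 1) -> np.ndarray:
    """Stack of the nine dilated shifts of ``a``: shape (9, *a.shape)."""
    return np.stack([_shift(a, sign * dy * d, sign * dx * d) for dy, dx in _OFFSETS])


class MSDNet:
    """Dense dilated 3×3 CNN, one channel per layer, trained with Adam/MSE."""

    def __init__(
        self,
        depth: int = 20,
        in_channels: int = 5,
        dilations: tuple[int, ...] = tuple(range(1, 11)),
        seed: int = 0,
    ) -> None:
        if depth < 1:
            raise ValueError("depth must be ≥ 1")
        self.depth = depth
        self.in_channels = in_channels
        self.dilations = [dilations[i % len(dilations)] for i in range(depth)]
        rng = np.random.default_rng(seed)
        self.W = []  # layer i: (in_channels + i, 3, 3)
        self.b = np.zeros(depth, dtype=_DTYPE)
        for i in range(depth):
            c_prev = in_channels + i
            self.W.append(
                rng.normal(0.0, np.sqrt(2.0 / (9.0 * c_prev)), (c_prev, 3, 3)).astype(_DTYPE)
            )
        # small random 1×1 output weights so every layer receives gradient
        # from the first step while the initial prediction stays near zero
        n_chan = in_channels + depth
        self.w_out = rng.normal(0.0, 0.1 / np.sqrt(n_chan), n_chan).astype(_DTYPE)
        self.b_out = _DTYPE(0.0)
        self._adam_state = None

    # ---------------------------------------------------------------- forward
    def forward(self, x: np.ndarray, keep_cache: bool = False):
        """x: (B, in_channels, H, W) → prediction (B, H, W)."""
        x = np.ascontiguousarray(x, dtype=_DTYPE)
        B, C0, H, W = x.shape
        if C0 != self.in_channels:
            raise ValueError(f"expected {self.in_channels} input channels, got {C0}")
        buf = np.empty((B, C0 + self.depth, H, W), dtype=_DTYPE)
        buf[:, :C0] = x
        stacks = [] if keep_cache else None
        for i in range(self.depth):
            C = C0 + i
            S = _shift_stack(buf[:, :C], self.dilations[i])  # (9, B, C, H, W)
            Sm = S.transpose(2, 0, 1, 3, 4).reshape(9 * C, B * H * W)
            pre = (self.W[i].reshape(1, 9 * C) @ Sm).reshape(B, H, W)
            pre += self.b[i]
            buf[:, C] = np.maximum(pre, 0.0)
            if keep_cache:
                stacks.append(Sm)
        out = np.tensordot(self.w_out, buf, axes=([0], [1])) + self.b_out
        if keep_cache:
            return out, (buf, stacks)
        return out

    # --------------------------------------------------------------- backward
    def backward(self, cache, dout: np.ndarray):
        """Gradients of a scalar loss given d(loss)/d(prediction).

        Returns (dW list, db, dw_out, db_out).
        """
        buf, stacks = cache
        dout = np.ascontiguousarray(dout, dtype=_DTYPE)
        B, Ctot, H, W = buf.shape
        C0 = self.in_channels
        dw_out = np.einsum("bchw,bhw->c", buf, dout, optimize=True)
        db_out = _DTYPE(dout.sum())
        dchan = self.w_out[None, :, None, None] * dout[:, None]
        dW = [None] * self.depth
        db = np.zeros(self.depth, dtype=_DTYPE)
        for i in range(self.depth - 1, -1, -1):
            C = C0 + i
            g = dchan[:, C] * (buf[:, C] > 0)
            db[i] = g.sum()
            d = self.dilations[i]
            g_flat = g.reshape(B * H * W)
            # dW[i][c, s] = Σ g · shift(prev_c, off_s)
            dW[i] = (stacks[i] @ g_flat).reshape(C, 3, 3)
            # dprev_c += Σ_s W[i][c,s] · shift(g, -off_s)
            Gn = _shift_stack(g, d, sign=-1).reshape(9, B * H * W)
            dprev = (self.W[i].reshape(C, 9) @ Gn).reshape(C, B, H, W)
            dchan[:, :C] += dprev.transpose(1, 0, 2, 3)
        return dW, db, dw_out, db_out

    # ------------------------------------------------------------------ adam
    def adam_step(self, grads, lr: float, beta1=0.9, beta2=0.999, eps=1e-8):
        dW, db, dw_out, db_out = grads
        flat_g = dW + [db, dw_out, np.atleast_1d(db_out)]
        if self._adam_state is None:
            self._adam_state = {
                "t": 0,
                "m": [np.zeros_like(np.asarray(g, dtype=np.float64)) for g in flat_g],
                "v": [np.zeros_like(np.asarray(g, dtype=np.float64)) for g in flat_g],
            }
        st = self._adam_state
        st["t"] += 1
        t = st["t"]
        new = []
        for g, m, v in zip(flat_g, st["m"], st["v"]):
            g = np.asarray(g, dtype=np.float64)
            m *= beta1
            m += (1 - beta1) * g
            v *= beta2
            v += (1 - beta2) * g * g
            mh = m / (1 - beta1**t)
            vh = v / (1 - beta2**t)
            new.append(lr * mh / (np.sqrt(vh) + eps))
        for i in range(self.depth):
            self.W[i] -= new[i].astype(_DTYPE)
        self.b -= new[self.depth].astype(_DTYPE)
        self.w_out -= new[self.depth + 1].astype(_DTYPE)
        self.b_out = _DTYPE(self.b_out - new[self.depth + 2][0])

    # ------------------------------------------------------------- weight I/O
    def get_weights(self) -> dict:
        return {
            "W": [w.copy() for w in self.W],
            "b": self.b.copy(),
            "w_out": self.w_out.copy(),
            "b_out": float(self.b_out),
        }

    def set_weights(self, weights: dict) -> None:
        self.W = [np.asarray(w, dtype=_DTYPE).copy() for w in weights["W"]]
        self.b = np.asarray(weights["b"], dtype=_DTYPE).copy()
        self.w_out = np.asarray(weights["w_out"], dtype=_DTYPE).copy()
        self.b_out = _DTYPE(weights["b_out"])
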