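"""A compact NumPy encoder-decoder for binary semantic segmentation.

SegNet-style architecture: each encoder block is two 3x3 convolutions with
ReLU followed by 2x2 max-pooling whose argmax indices are stored; the
decoder mirrors the encoder, upsampling with index-based max-unpooling so
fine boundary locations survive the bottleneck.  A final 1x1 convolution
produces one logit per pixel; training minimizes binary cross-entropy with
Adam.  Everything is plain NumPy (convolutions run as einsum contractions
over sliding windows), deterministic for a fixed seed.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


def _corr(x: np.ndarray, W: np.ndarray) -> np.ndarray:
    """Valid-mode correlation of padded x (N,C,H+2,W+2) with W (O,C,3,3)."""
    cols = sliding_window_view(x, (3, 3), axis=(2, 3))  # N,C,H,W,3,3
    out = np.tensordot(cols, W, axes=([1, 4, 5], [1, 2, 3]))  # N,H,W,O
    return np.ascontiguousarray(out.transpose(0, 3, 1, 2))


def _conv3x3(x: np.ndarray, W: np.ndarray, b: np.ndarray) -> np.ndarray:
    """x (N,C,H,W), W (O,C,3,3) -> (N,O,H,W), stride 1, zero pad 1."""
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
    return _corr(xp, W) + b[None, :, None, None]


def _conv3x3_backward(x, W, dout):
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
    cols = sliding_window_view(xp, (3, 3), axis=(2, 3))
    dW = np.tensordot(dout, cols, axes=([0, 2, 3], [0, 2, 3]))  # O,C,3,3
    db = dout.sum(axis=(0, 2, 3))
    dp = np.pad(dout, ((0, 0), (0, 0), (1, 1), (1, 1)))
    # input gradient: full correlation with the rotated kernel, channels swapped
    Wflip = np.ascontiguousarray(W[:, :, ::-1, ::-1].transpose(1, 0, 2, 3))
    dx = _corr(dp, Wflip)
    return dx, dW, db


def _maxpool2(x):
    n, c, h, w = x.shape
    xr = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
    xr = xr.reshape(n, c, h // 2, w // 2, 4)
    idx = xr.argmax(axis=-1)
    out = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]
    return out, idx


def _maxunpool2(g, idx, out_hw):
    n, c, hh, ww = g.shape
    up = np.zeros((n, c, hh, ww, 4), dtype=g.dtype)
    np.put_along_axis(up, idx[..., None], g[..., None], axis=-1)
    up = up.reshape(n, c, hh, ww, 2, 2).transpose(0, 1, 2, 4, 3, 5)
    return up.reshape(n, c, out_hw[0], out_hw[1])


class SegNetLite:
    """Symmetric encoder-decoder with pooling-index unpooling.

    Parameters
    ----------
    depth : number of pool/unpool levels.
    channels : feature channels per level, len == depth.
    in_channels : input channels (3 for RGB).
    seed : weight-initialization seed (He-normal).
    """

    def __init__(self, depth: int = 3, channels: tuple[int, ...] = (8, 16, 32),
                 in_channels: int = 3, seed: int = 0):
        if len(channels) != depth:
            raise ValueError("need one channel count per encoder level")
        self.depth = depth
        self.channels = tuple(int(c) for c in channels)
        self.in_channels = in_channels
        self.seed = seed
        self.trained = False
        rng = np.random.default_rng(seed)
        self.params: dict[str, np.ndarray] = {}
        cin = in_channels
        for lvl, c in enumerate(self.channels):
            self._init_conv(rng, f"e{lvl}a", cin, c)
            self._init_conv(rng, f"e{lvl}b", c, c)
            cin = c
        for lvl in reversed(range(depth)):
            cout = self.channels[lvl - 1] if lvl > 0 else self.channels[0]
            self._init_conv(rng, f"d{lvl}a", self.channels[lvl], self.channels[lvl])
            self._init_conv(rng, f"d{lvl}b", self.channels[lvl], cout)
        rngw = rng.normal(0.0, np.sqrt(2.0 / self.channels[0]),
                          size=(1, self.channels[0], 1, 1))
        self.params["head_W"] = rngw
        self.params["head_b"] = np.zeros(1)

    def _init_conv(self, rng, name, cin, cout):
        std = np.sqrt(2.0 / (cin * 9))
        self.params[f"{name}_W"] = rng.normal(0.0, std, size=(cout, cin, 3, 3))
        self.params[f"{name}_b"] = np.zeros(cout)

    @property
    def n_parameters(self) -> int:
        return int(sum(p.size for p in self.params.values()))

    def forward(self, x: np.ndarray, want_cache: bool = False):
        """x (N, C, H, W) float -> per-pixel logits (N, H, W)."""
        if x.ndim != 4 or x.shape[1] != self.in_channels:
            raise ValueError(f"expected (N,{self.in_channels},H,W), got {x.shape}")
        if x.shape[2] % 2 ** self.depth or x.shape[3] % 2 ** self.depth:
            raise ValueError("spatial size must be divisible by 2**depth")
        p = self.params
        cache = {"x": x}
        h = x
        for lvl in range(self.depth):
            for sub in "ab":
                name = f"e{lvl}{sub}"
                z = _conv3x3(h, p[f"{name}_W"], p[f"{name}_b"])
                cache[f"{name}_in"], cache[f"{name}_z"] = h, z
                h = np.maximum(z, 0.0)
            cache[f"pool{lvl}_hw"] = h.shape[2:]
            h, idx = _maxpool2(h)
            cache[f"pool{lvl}_idx"] = idx
        for lvl in reversed(range(self.depth)):
            h = _maxunpool2(h, cache[f"pool{lvl}_idx"], cache[f"pool{lvl}_hw"])
            for sub in "ab":
                name = f"d{lvl}{sub}"
                z = _conv3x3(h, p[f"{name}_W"], p[f"{name}_b"])
                cache[f"{name}_in"], cache[f"{name}_z"] = h, z
                h = np.maximum(z, 0.0)
        cache["head_in"] = h
        logits = np.einsum("nchw,oc->nohw", h, p["head_W"][:, :, 0, 0],
                           optimize=True) + p["head_b"][None, :, None, None]
        logits = logits[:, 0]
        return (logits, cache) if want_cache else logits

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        """Per-pixel fat probability via a numerically stable sigmoid."""
        z = self.forward(x)
        out = np.empty_like(z)
        pos = z >= 0
        out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
        ez = np.exp(z[~pos])
        out[~pos] = ez / (1.0 + ez)
        return out

    def backward(self, cache, dlogits):
        """Reverse pass; returns parameter gradients for one batch."""
        p = self.params
        grads = {}
        h = cache["head_in"]
        g = dlogits[:, None]
        grads["head_W"] = np.einsum("nohw,nchw->oc", g, h,
                                    optimize=True)[:, :, None, None]
        grads["head_b"] = g.sum(axis=(0, 2, 3))
        dh = np.einsum("nohw,oc->nchw", g, p["head_W"][:, :, 0, 0], optimize=True)
        # decoder ran at levels depth-1 .. 0; reverse it bottom-up
        for lvl in range(self.depth):
            for sub in "ba":
                name = f"d{lvl}{sub}"
                dz = dh * (cache[f"{name}_z"] > 0)
                dh, grads[f"{name}_W"], grads[f"{name}_b"] = _conv3x3_backward(
                    cache[f"{name}_in"], p[f"{name}_W"], dz)
            # unpool backward: gather the gradient at the scattered positions
            idx = cache[f"pool{lvl}_idx"]
            n, c, hh, ww = idx.shape
            dr = dh.reshape(n, c, hh, 2, ww, 2).transpose(0, 1, 2, 4, 3, 5)
            dr = dr.reshape(n, c, hh, ww, 4)
            dh = np.take_along_axis(dr, idx[..., None], axis=-1)[..., 0]
        # encoder backward, top level last
        for lvl in reversed(range(self.depth)):
            # pool backward scatters to the argmax positions
            dh = _maxunpool2(dh, cache[f"pool{lvl}_idx"], cache[f"pool{lvl}_hw"])
            for sub in "ba":
                name = f"e{lvl}{sub}"
                dz = dh * (cache[f"{name}_z"] > 0)
                dh, grads[f"{name}_W"], grads[f"{name}_b"] = _conv3x3_backward(
                    cache[f"{name}_in"], p[f"{name}_W"], dz)
        return grads

    def state_dict(self):
        return {k: v.copy() for k, v in self.params.items()}

    def save(self, path: str | Path) -> None:
        path = Path(path)
        np.savez(path, **self.params)
        meta = dict(depth=self.depth, channels=list(self.channels),
                    in_channels=self.in_channels, seed=self.seed,
                    trained=self.trained,
                    threshold=getattr(self, "threshold", None),
                    downsample=getattr(self, "downsample", None))
        path.with_suffix(".json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "SegNetLite":
        path = Path(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        model = cls(depth=meta["depth"], channels=tuple(meta["channels"]),
                    in_channels=meta["in_channels"], seed=meta["seed"])
        with np.load(path if path.suffix == ".npz" else path.with_suffix(".npz")) as z:
            for k in model.params:
                model.params[k] = z[k]
        model.trained = meta["trained"]
        if meta.get("threshold") is not None:
            model.threshold = meta["threshold"]
        if meta.get("downsample") is not None:
            model.downsample = meta["downsample"]
        return model


def bce_with_logits(logits: np.ndarray, targets: np.ndarray,
                    pos_weight: float = 1.0):
    """Mean binary cross-entropy and its gradient w.r.t. the logits.

    ``pos_weight`` scales the loss of positive (fat) pixels, counteracting
    the heavy class imbalance of sparse adipocytes.
    """
    z, y = logits, targets
    w = 1.0 + (pos_weight - 1.0) * y
    loss = w * (np.maximum(z, 0.0) - z * y + np.log1p(np.exp(-np.abs(z))))
    sig = np.where(z >= 0, 1.0 / (1.0 + np.exp(-np.minimum(z, 50))),
                   np.exp(np.maximum(z, -50)) / (1.0 + np.exp(np.maximum(z, -50))))
    grad = w * (sig - y) / y.size
    return float(loss.mean()), grad


class Adam:
    def __init__(self, params: dict[str, np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        for k, g in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1 ** self.t)
            vhat = self.v[k] / (1 - self.b2 ** self.t)
            self.params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
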