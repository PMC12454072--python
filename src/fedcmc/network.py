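"""Compact convolutional network for grayscale patches, in pure numpy.

Architecture (default): conv(3x3, 8) -> ReLU -> maxpool2 -> conv(3x3, 16)
-> ReLU -> maxpool2 -> flatten -> dense(hidden) -> ReLU -> dense(1 logit).
The penultimate dense activation serves as the sample representation for
model-contrastive regularization, and the per-kernel spatial means of the
conv activation maps serve as deep features for the downstream classifier.

Training minimizes focal loss with Adam. The implementation supports the
proximal penalty used by FedProx and gradient injection at the
representation layer for MOON's contrastive term.

Parameters travel as a :class:`ModelParams` — a flat, architecture-tagged
mapping of named arrays — so that server-side aggregation is a plain
block-wise convex combination.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = ["ModelParams", "ConvNetConfig", "ConvNet", "focal_loss", "focal_loss_grad"]

_EPS = 1e-7


# ---------------------------------------------------------------------------
# focal loss
# ---------------------------------------------------------------------------

def focal_loss(p, y, alpha: float = 1.0, gamma: float = 2.0):
    """Mean focal loss for binary labels.

    With p_t = p if y=1 else 1-p and alpha_t = alpha if y=1 else 1-alpha:
    loss = -alpha_t * (1 - p_t)**gamma * ln(p_t), averaged over the batch.
    gamma=0 with alpha=1 reduces to plain cross-entropy (alpha_t is forced
    to 1 in that case so the reduction is exact).
    """
    p = np.clip(np.asarray(p, dtype=np.float64), _EPS, 1.0 - _EPS)
    y = np.asarray(y, dtype=np.float64)
    p_t = np.where(y == 1, p, 1.0 - p)
    if alpha == 1.0:
        a_t = np.ones_like(p_t)
    else:
        a_t = np.where(y == 1, alpha, 1.0 - alpha)
    return float(np.mean(-a_t * (1.0 - p_t) ** gamma * np.log(p_t)))


def focal_loss_grad(p, y, alpha: float = 1.0, gamma: float = 2.0):
    """d(mean focal loss)/d(logit), elementwise over the batch."""
    p = np.clip(np.asarray(p, dtype=np.float64), _EPS, 1.0 - _EPS)
    y = np.asarray(y, dtype=np.float64)
    p_t = np.where(y == 1, p, 1.0 - p)
    if alpha == 1.0:
        a_t = np.ones_like(p_t)
    else:
        a_t = np.where(y == 1, alpha, 1.0 - alpha)
    # dL/dp_t, then chain through dp_t/dlogit = sign * p(1-p)
    one_m = 1.0 - p_t
    if gamma == 0.0:
        dldpt = -a_t / p_t
    else:
        dldpt = a_t * (gamma * one_m ** (gamma - 1.0) * np.log(p_t) - one_m**gamma / p_t)
    sign = np.where(y == 1, 1.0, -1.0)
    return dldpt * sign * p * (1.0 - p) / p.size


def _resolve_alpha(alpha, y) -> float:
    """'auto' -> positive-class weight equal to the negative-class frequency."""
    if alpha == "auto":
        y = np.asarray(y)
        return float(np.clip(1.0 - y.mean(), 0.05, 0.95))
    return float(alpha)


# ---------------------------------------------------------------------------
# parameters
# ---------------------------------------------------------------------------

@dataclass
class ModelParams:
    """Flat, architecture-tagged collection of named parameter arrays."""

    architecture_tag: str
    blocks: dict[str, np.ndarray]
    total_conv_kernels: int

    def copy(self) -> "ModelParams":
        return ModelParams(
            self.architecture_tag,
            {k: v.copy() for k, v in self.blocks.items()},
            self.total_conv_kernels,
        )

    def check_finite(self) -> bool:
        return all(np.all(np.isfinite(v)) for v in self.blocks.values())

    def allclose(self, other: "ModelParams", atol: float = 0.0) -> bool:
        return self.architecture_tag == other.architecture_tag and all(
            np.allclose(self.blocks[k], other.blocks[k], atol=atol, rtol=0.0)
            for k in self.blocks
        )

    def flat(self) -> np.ndarray:
        return np.concatenate([v.ravel() for _, v in sorted(self.blocks.items())])

    def save(self, path) -> None:
        np.savez_compressed(
            path,
            __tag__=np.array(self.architecture_tag),
            __kernels__=np.array(self.total_conv_kernels),
            **self.blocks,
        )

    @classmethod
    def load(cls, path) -> "ModelParams":
        with np.load(path, allow_pickle=False) as z:
            blocks = {k: z[k] for k in z.files if not k.startswith("__")}
            return cls(str(z["__tag__"]), blocks, int(z["__kernels__"]))


# ---------------------------------------------------------------------------
# layers (im2col convolution, 2x2 max pooling)
# ---------------------------------------------------------------------------

def _im2col(x: np.ndarray, kh: int, kw: int) -> np.ndarray:
    """(N, C, H, W) -> (N, H-kh+1, W-kw+1, C*kh*kw) patch matrix (valid conv)."""
    N, C, H, W = x.shape
    oh, ow = H - kh + 1, W - kw + 1
    s = x.strides
    patches = np.lib.stride_tricks.as_strided(
        x, shape=(N, C, oh, ow, kh, kw), strides=(s[0], s[1], s[2], s[3], s[2], s[3])
    )
    return patches.transpose(0, 2, 3, 1, 4, 5).reshape(N, oh, ow, C * kh * kw)


def _conv_forward(x, W, b):
    # W: (C_out, C_in, kh, kw); x: (N, C_in, H, W)
    co, ci, kh, kw = W.shape
    cols = _im2col(x, kh, kw)  # (N, oh, ow, ci*kh*kw)
    out = cols @ W.reshape(co, -1).T + b  # (N, oh, ow, co)
    return out.transpose(0, 3, 1, 2), cols


def _conv_backward(dout, cols, x_shape, W):
    # dout: (N, co, oh, ow)
    co, ci, kh, kw = W.shape
    N, _, H, Wd = x_shape
    d = dout.transpose(0, 2, 3, 1)  # (N, oh, ow, co)
    dW = np.einsum("nhwo,nhwp->op", d, cols).reshape(W.shape)
    db = d.sum(axis=(0, 1, 2))
    dcols = d @ W.reshape(co, -1)  # (N, oh, ow, ci*kh*kw)
    oh, ow = d.shape[1], d.shape[2]
    dx = np.zeros(x_shape)
    dcols = dcols.reshape(N, oh, ow, ci, kh, kw)
    for i in range(kh):
        for j in range(kw):
            dx[:, :, i : i + oh, j : j + ow] += dcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
    return dx, dW, db


def _pool_forward(x):
    N, C, H, W = x.shape
    oh, ow = H // 2, W // 2
    xt = x[:, :, : oh * 2, : ow * 2].reshape(N, C, oh, 2, ow, 2)
    flat = xt.transpose(0, 1, 2, 4, 3, 5).reshape(N, C, oh, ow, 4)
    arg = flat.argmax(axis=-1)
    out = np.take_along_axis(flat, arg[..., None], axis=-1)[..., 0]
    return out, (arg, x.shape)


def _pool_backward(dout, cache):
    arg, x_shape = cache
    N, C, H, W = x_shape
    oh, ow = H // 2, W // 2
    dflat = np.zeros((N, C, oh, ow, 4))
    np.put_along_axis(dflat, arg[..., None], dout[..., None], axis=-1)
    dx = np.zeros(x_shape)
    dx[:, :, : oh * 2, : ow * 2] = (
        dflat.reshape(N, C, oh, ow, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(N, C, oh * 2, ow * 2)
    )
    return dx


# ---------------------------------------------------------------------------
# the network
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConvNetConfig:
    image_size: tuple[int, int] = (16, 16)
    conv_channels: tuple[int, int] = (8, 16)
    kernel_size: int = 3
    hidden_units: int = 32

    @property
    def tag(self) -> str:
        return (
            f"convnet-{self.image_size[0]}x{self.image_size[1]}"
            f"-c{self.conv_channels[0]}.{self.conv_channels[1]}"
            f"-k{self.kernel_size}-h{self.hidden_units}"
        )

    @property
    def total_conv_kernels(self) -> int:
        return sum(self.conv_channels)


class ConvNet:
    """Stateless architecture object; parameters are passed explicitly."""

    def __init__(self, config: ConvNetConfig = ConvNetConfig()):
        self.config = config
        H, W = config.image_size
        k = config.kernel_size
        c1, c2 = config.conv_channels
        h1, w1 = (H - k + 1) // 2, (W - k + 1) // 2
        h2, w2 = (h1 - k + 1) // 2, (w1 - k + 1) // 2
        if h2 < 1 or w2 < 1:
            raise ValueError("image_size too small for this architecture")
        self._flat_dim = c2 * h2 * w2

    # -- init --------------------------------------------------------------
    def init_params(self, seed: int) -> ModelParams:
        rng = np.random.default_rng(seed)
        cfg = self.config
        k = cfg.kernel_size
        c1, c2 = cfg.conv_channels

        def he(shape, fan_in):
            return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)

        blocks = {
            "conv1_W": he((c1, 1, k, k), k * k),
            "conv1_b": np.zeros(c1),
            "conv2_W": he((c2, c1, k, k), c1 * k * k),
            "conv2_b": np.zeros(c2),
            "fc1_W": he((self._flat_dim, cfg.hidden_units), self._flat_dim),
            "fc1_b": np.zeros(cfg.hidden_units),
            "fc2_W": he((cfg.hidden_units, 1), cfg.hidden_units),
            "fc2_b": np.zeros(1),
        }
        return ModelParams(cfg.tag, blocks, cfg.total_conv_kernels)

    # -- forward -----------------------------------------------------------
    def forward(self, params: ModelParams, X: np.ndarray, want_cache: bool = False):
        """X: (N, H, W) -> dict with logits, probabilities, representation.

        With ``want_cache`` the returned dict additionally carries the
        intermediates needed by :meth:`backward`.
        """
        if params.architecture_tag != self.config.tag:
            raise ValueError(
                f"parameter tag {params.architecture_tag!r} does not match {self.config.tag!r}"
            )
        B = params.blocks
        x = np.asarray(X, dtype=np.float64)[:, None, :, :]
        a1, cols1 = _conv_forward(x, B["conv1_W"], B["conv1_b"])
        r1 = np.maximum(a1, 0.0)
        p1, pc1 = _pool_forward(r1)
        a2, cols2 = _conv_forward(p1, B["conv2_W"], B["conv2_b"])
        r2 = np.maximum(a2, 0.0)
        p2, pc2 = _pool_forward(r2)
        flat = p2.reshape(p2.shape[0], -1)
        h_pre = flat @ B["fc1_W"] + B["fc1_b"]
        h = np.maximum(h_pre, 0.0)  # representation (penultimate layer)
        logits = (h @ B["fc2_W"] + B["fc2_b"])[:, 0]
        prob = 1.0 / (1.0 + np.exp(-logits))
        out = {"logits": logits, "prob": prob, "repr": h, "conv_acts": (r1, r2)}
        if want_cache:
            out["cache"] = (x, cols1, a1, pc1, p1, cols2, a2, pc2, p2, flat, h_pre, h)
        return out

    def predict_proba(self, params: ModelParams, X: np.ndarray) -> np.ndarray:
        return self.forward(params, X)["prob"]

    # -- backward ----------------------------------------------------------
    def backward(
        self,
        params: ModelParams,
        cache,
        dlogits: np.ndarray,
        drepr: Optional[np.ndarray] = None,
    ) -> dict[str, np.ndarray]:
        """Gradients of a scalar loss given d(loss)/d(logit) per sample.

        ``drepr`` lets a caller inject an extra gradient at the
        representation layer (used by the model-contrastive term).
        """
        B = params.blocks
        x, cols1, a1, pc1, p1, cols2, a2, pc2, p2, flat, h_pre, h = cache
        g = {}
        dlog = dlogits[:, None]
        g["fc2_W"] = h.T @ dlog
        g["fc2_b"] = dlog.sum(axis=0)
        dh = dlog @ B["fc2_W"].T
        if drepr is not None:
            dh = dh + drepr
        dh_pre = dh * (h_pre > 0)
        g["fc1_W"] = flat.T @ dh_pre
        g["fc1_b"] = dh_pre.sum(axis=0)
        dflat = dh_pre @ B["fc1_W"].T
        dp2 = dflat.reshape(p2.shape)
        dr2 = _pool_backward(dp2, pc2)
        da2 = dr2 * (a2 > 0)
        dp1, g["conv2_W"], g["conv2_b"] = _conv_backward(da2, cols2, p1.shape, B["conv2_W"])
        dr1 = _pool_backward(dp1, pc1)
        da1 = dr1 * (a1 > 0)
        _, g["conv1_W"], g["conv1_b"] = _conv_backward(da1, cols1, x.shape, B["conv1_W"])
        return g

    # -- features ----------------------------------------------------------
    def deep_features(self, params: ModelParams, X: np.ndarray) -> np.ndarray:
        """Per-kernel spatial means of the conv activation maps.

        Returns (N, total_conv_kernels), concatenated in layer order.
        """
        out = self.forward(params, X)
        r1, r2 = out["conv_acts"]
        f1 = r1.mean(axis=(2, 3))
        f2 = r2.mean(axis=(2, 3))
        return np.concatenate([f1, f2], axis=1)


class Adam:
    """Standard Adam over a ModelParams block dict."""

    def __init__(self, params: ModelParams, lr: float = 1e-3, betas=(0.9, 0.999), eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, betas[0], betas[1], eps
        self.m = {k: np.zeros_like(v) for k, v in params.blocks.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.blocks.items()}
        self.t = 0

    def step(self, params: ModelParams, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for k, gk in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1.0 - self.b1) * gk
            self.v[k] = self.b2 * self.v[k] + (1.0 - self.b2) * gk * gk
            params.blocks[k] -= self.lr * (self.m[k] / b1t) / (np.sqrt(self.v[k] / b2t) + self.eps)
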