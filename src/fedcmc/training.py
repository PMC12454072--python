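"""Local SGD/Adam training of the probe network under focal loss.

One function, :func:`train_local`, covers plain local updates, the FedProx
proximal variant (quadratic pull toward the incoming global parameters) and
the MOON model-contrastive variant (the local representation is pulled
toward the global model's representation and pushed away from the previous
local model's). All randomness (batch order) comes from the supplied seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .network import Adam, ConvNet, ModelParams, focal_loss, focal_loss_grad, _resolve_alpha

__all__ = ["TrainConfig", "train_local"]


@dataclass(frozen=True)
class TrainConfig:
    """Hyperparameters of one local training pass."""

    local_epochs: int = 2
    batch_size: int = 32
    learning_rate: float = 1e-3
    focal_gamma: float = 2.0
    focal_alpha: float | str = "auto"  # "auto" = inverse class frequency
    seed: int = 0

    def __post_init__(self):
        if self.local_epochs < 0:
            raise ValueError("local_epochs must be >= 0")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.focal_gamma < 0:
            raise ValueError("focal_gamma must be >= 0")
        if self.focal_alpha != "auto" and not (0.0 < float(self.focal_alpha) <= 1.0):
            raise ValueError("focal_alpha must be in (0, 1] or 'auto'")


def _cosine(a: np.ndarray, b: np.ndarray, eps: float = 1e-12) -> np.ndarray:
    na = np.linalg.norm(a, axis=1) + eps
    nb = np.linalg.norm(b, axis=1) + eps
    return (a * b).sum(axis=1) / (na * nb)


def _moon_repr_grad(h, h_glob, h_prev, mu: float, temperature: float):
    """Gradient (per sample) of the model-contrastive loss w.r.t. h.

    loss = -log( exp(s_g/t) / (exp(s_g/t) + exp(s_p/t)) ), s = cosine sim,
    averaged over the batch and scaled by mu.
    """
    eps = 1e-12
    n = h.shape[0]
    s_g = _cosine(h, h_glob)
    s_p = _cosine(h, h_prev)
    m = np.maximum(s_g, s_p) / temperature
    eg = np.exp(s_g / temperature - m)
    ep = np.exp(s_p / temperature - m)
    z = eg + ep
    ds_g = (eg / z - 1.0) / temperature  # d loss / d s_g
    ds_p = (ep / z) / temperature
    loss = float(np.mean(-np.log(eg / z + eps)))

    def dcos_dh(h, u, s):
        nh = np.linalg.norm(h, axis=1, keepdims=True) + eps
        nu = np.linalg.norm(u, axis=1, keepdims=True) + eps
        return u / (nh * nu) - s[:, None] * h / nh**2

    grad = ds_g[:, None] * dcos_dh(h, h_glob, s_g) + ds_p[:, None] * dcos_dh(h, h_prev, s_p)
    return mu * loss, mu * grad / n


def train_local(
    net: ConvNet,
    params: ModelParams,
    X: np.ndarray,
    y: np.ndarray,
    cfg: TrainConfig,
    *,
    prox_mu: float = 0.0,
    prox_anchor: Optional[ModelParams] = None,
    moon_mu: float = 0.0,
    moon_temperature: float = 0.5,
    moon_global: Optional[ModelParams] = None,
    moon_previous: Optional[ModelParams] = None,
) -> tuple[ModelParams, list[float]]:
    """Train a copy of ``params`` on (X, y); returns (new params, epoch losses).

    With ``local_epochs == 0`` the input parameters are returned unchanged
    (bitwise), which makes a zero-epoch federation a pure aggregation test.
    Raises ``FloatingPointError`` if the loss goes non-finite.
    """
    if len(X) == 0:
        raise ValueError("training data must be non-empty")
    if cfg.local_epochs == 0:
        return params.copy(), []
    params = params.copy()
    alpha = _resolve_alpha(cfg.focal_alpha, y)
    rng = np.random.default_rng(cfg.seed)
    opt = Adam(params, lr=cfg.learning_rate)
    n = len(X)
    losses = []
    use_moon = moon_mu > 0 and moon_global is not None and moon_previous is not None
    for _ in range(cfg.local_epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            xb, yb = X[idx], y[idx]
            out = net.forward(params, xb, want_cache=True)
            loss = focal_loss(out["prob"], yb, alpha=alpha, gamma=cfg.focal_gamma)
            dlog = focal_loss_grad(out["prob"], yb, alpha=alpha, gamma=cfg.focal_gamma)
            drepr = None
            if use_moon:
                h_glob = net.forward(moon_global, xb)["repr"]
                h_prev = net.forward(moon_previous, xb)["repr"]
                con_loss, drepr = _moon_repr_grad(
                    out["repr"], h_glob, h_prev, moon_mu, moon_temperature
                )
                loss += con_loss
            grads = net.backward(params, out["cache"], dlog, drepr=drepr)
            if prox_mu > 0 and prox_anchor is not None:
                for k in grads:
                    grads[k] = grads[k] + prox_mu * (params.blocks[k] - prox_anchor.blocks[k])
                for k in grads:  # penalty value, for the logged loss
                    loss += 0.5 * prox_mu * float(
                        np.sum((params.blocks[k] - prox_anchor.blocks[k]) ** 2)
                    )
            if not np.isfinite(loss):
                raise FloatingPointError("non-finite training loss")
            opt.step(params, grads)
            epoch_loss += loss * len(idx)
        losses.append(epoch_loss / n)
    if not params.check_finite():
        raise FloatingPointError("non-finite parameters after training")
    return params, losses
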