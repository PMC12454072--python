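"""Deep features and the sparse Bayesian extreme learning machine (SBELM).

Feature extraction follows the mean-activation-map convention: every
convolutional kernel of the (personalized) network contributes one feature,
the arithmetic mean of its activation map over spatial positions. The
classifier on top is an extreme learning machine — a hidden layer drawn
once at random and frozen — whose output weights are learned by sparse
Bayesian logistic regression: a zero-mean Gaussian prior with a separate
precision per weight (automatic relevance determination), fit by an
iteratively reweighted Laplace approximation. Precisions of uninformative
weights diverge during fitting and those weights are pruned to exactly
zero, yielding the sparse solutions ELMs with L1-flavored Bayesian priors
are used for. Class imbalance is handled by weighting each sample's
log-likelihood with the focal alpha_t class weight.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .network import ConvNet, ModelParams, _resolve_alpha
from .synthetic import LabeledImage

__all__ = ["FeatureVector", "SBELMModel", "extract_features", "sbelm_fit", "sbelm_predict"]


@dataclass(frozen=True)
class FeatureVector:
    """Mean-pooled conv-kernel activations of one sample."""

    sample_id: str
    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=np.float64)
        if not np.all(np.isfinite(v)):
            raise ValueError("feature values must be finite")
        object.__setattr__(self, "values", v)


def extract_features(net: ConvNet, params: ModelParams, image: LabeledImage) -> FeatureVector:
    """One sample's deep features: one value per conv kernel, in layer order."""
    if image.pixels.shape != net.config.image_size:
        raise ValueError(
            f"image shape {image.pixels.shape} does not match model input {net.config.image_size}"
        )
    values = net.deep_features(params, image.pixels[None])[0]
    assert values.shape == (params.total_conv_kernels,)
    return FeatureVector(sample_id=image.id, values=values)


def feature_matrix(net: ConvNet, params: ModelParams, images) -> np.ndarray:
    """(n, total_conv_kernels) feature matrix for a sequence of images."""
    X = np.stack([im.pixels for im in images])
    return net.deep_features(params, X)


# ---------------------------------------------------------------------------
# SBELM
# ---------------------------------------------------------------------------

@dataclass
class SBELMModel:
    hidden_W: np.ndarray  # (input_dim, n_hidden)
    hidden_b: np.ndarray  # (n_hidden,)
    activation: str  # "sigmoid" or "relu"
    output_weights: np.ndarray  # (n_hidden + 1,) last entry = bias; pruned entries are 0
    relevance_precisions: np.ndarray  # (n_hidden + 1,) ARD precision per weight
    feature_mean: np.ndarray
    feature_sd: np.ndarray
    prune_threshold: float = 1e6
    converged: bool = True
    n_iterations: int = 0

    @property
    def active_mask(self) -> np.ndarray:
        return self.output_weights != 0.0

    @property
    def n_active(self) -> int:
        return int(self.active_mask.sum())


def _activate(Z: np.ndarray, activation: str) -> np.ndarray:
    if activation == "sigmoid":
        return 1.0 / (1.0 + np.exp(-np.clip(Z, -500, 500)))
    if activation == "relu":
        return np.maximum(Z, 0.0)
    raise ValueError(f"unknown activation {activation!r}")


def _design(model_like, X: np.ndarray) -> np.ndarray:
    Xs = (X - model_like.feature_mean) / model_like.feature_sd
    H = _activate(Xs @ model_like.hidden_W + model_like.hidden_b, model_like.activation)
    return np.hstack([H, np.ones((len(X), 1))])


def sbelm_fit(
    features: np.ndarray,
    labels: np.ndarray,
    n_hidden: int = 50,
    seed: int = 0,
    activation: str = "sigmoid",
    focal_alpha: float | str = "auto",
    prune_threshold: float = 1e6,
    max_iter: int = 200,
    tol: float = 1e-4,
) -> SBELMModel:
    """Fit an SBELM on a feature matrix.

    The hidden layer (weights ~ N(0,1), biases ~ U(-1,1)) is drawn once
    from ``seed`` and frozen; features are standardized with train-set
    statistics. The outer loop alternates a Newton (IRLS) step to the
    posterior mode of the output weights under per-weight Gaussian priors
    with an ARD precision update (MacKay fixed point); weights whose
    precision exceeds ``prune_threshold`` are pruned to exactly zero.
    Convergence: max |delta weight| < ``tol`` or ``max_iter`` outer steps
    (non-convergence returns the final iterate, flagged).
    """
    X = np.asarray(features, dtype=np.float64)
    y = np.asarray(labels, dtype=np.float64).ravel()
    if X.ndim != 2 or len(X) != len(y):
        raise ValueError("features must be (n, d) with one label per row")
    if len(X) < 4:
        raise ValueError("need at least 4 samples")
    classes = np.unique(y)
    if not np.array_equal(classes, [0, 1]):
        raise ValueError("labels must contain both classes 0 and 1")

    rng = np.random.default_rng(seed)
    d = X.shape[1]
    hidden_W = rng.normal(0.0, 1.0, size=(d, n_hidden))
    hidden_b = rng.uniform(-1.0, 1.0, size=n_hidden)
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd < 1e-8] = 1.0

    model = SBELMModel(
        hidden_W=hidden_W,
        hidden_b=hidden_b,
        activation=activation,
        output_weights=np.zeros(n_hidden + 1),
        relevance_precisions=np.full(n_hidden + 1, 1e-2),
        feature_mean=mean,
        feature_sd=sd,
        prune_threshold=prune_threshold,
    )
    Phi = _design(model, X)
    M = n_hidden + 1
    a = _resolve_alpha(focal_alpha, y)
    c = np.where(y == 1, a, 1.0 - a)  # per-sample likelihood weight

    alpha_prec = model.relevance_precisions.copy()
    w = np.zeros(M)
    active = np.ones(M, dtype=bool)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        w_old = w.copy()
        idx = np.flatnonzero(active)
        Pa = Phi[:, idx]
        wa = w[idx]
        # one Newton step to the weighted Bernoulli posterior mode
        eta = Pa @ wa
        p = 1.0 / (1.0 + np.exp(-np.clip(eta, -500, 500)))
        g = Pa.T @ (c * (y - p)) - alpha_prec[idx] * wa
        r = np.clip(c * p * (1.0 - p), 1e-10, None)
        Hm = (Pa * r[:, None]).T @ Pa + np.diag(alpha_prec[idx])
        try:
            step = np.linalg.solve(Hm, g)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(Hm, g, rcond=None)[0]
        wa_new = wa + step
        # ARD update from the Laplace posterior covariance at the new mode
        eta = Pa @ wa_new
        p = 1.0 / (1.0 + np.exp(-np.clip(eta, -500, 500)))
        r = np.clip(c * p * (1.0 - p), 1e-10, None)
        Hm = (Pa * r[:, None]).T @ Pa + np.diag(alpha_prec[idx])
        try:
            Sigma = np.linalg.inv(Hm)
        except np.linalg.LinAlgError:
            Sigma = np.linalg.pinv(Hm)
        gamma = 1.0 - alpha_prec[idx] * np.diag(Sigma)
        gamma = np.clip(gamma, 1e-10, 1.0)
        alpha_new = gamma / np.clip(wa_new**2, 1e-12, None)
        alpha_prec[idx] = np.minimum(alpha_new, 10.0 * prune_threshold)

        w = np.zeros(M)
        w[idx] = wa_new
        prune = alpha_prec > prune_threshold
        w[prune] = 0.0
        active = ~prune
        if not active.any():  # keep at least the bias
            active[-1] = True
            alpha_prec[-1] = 1e-2
        if np.max(np.abs(w - w_old)) < tol:
            converged = True
            break

    model.output_weights = w
    model.relevance_precisions = alpha_prec
    model.converged = converged
    model.n_iterations = it
    return model


def sbelm_predict(model: SBELMModel, features: np.ndarray) -> np.ndarray:
    """Class-1 probability per sample: sigmoid of the sparse linear score."""
    X = np.asarray(features, dtype=np.float64)
    if X.ndim == 1:
        X = X[None]
    if X.shape[1] != model.hidden_W.shape[0]:
        raise ValueError(
            f"feature dimension {X.shape[1]} does not match training ({model.hidden_W.shape[0]})"
        )
    Phi = _design(model, X)
    eta = Phi @ model.output_weights
    return 1.0 / (1.0 + np.exp(-np.clip(eta, -500, 500)))
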