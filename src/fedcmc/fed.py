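"""Federated training: local updates, aggregation, baselines, personalization.

The server round is the classic simulation loop: broadcast global
parameters, run a local update at every center, aggregate the returned
parameters as a convex combination. What varies between algorithms is the
local objective and the aggregation weights:

* ``fedcmc`` — centers first prune their pools to core sets (MCDEM); local
  updates run on the cores; weights come from data richness D and per-round
  model quality Q (contribution-fair aggregation). With
  ``use_fair_aggregation`` off the server falls back to uniform averaging,
  and with ``use_mcdem`` off centers train on their full pools — both off
  reproduces plain uniform FedAvg exactly.
* ``fedavg`` — full pools, weights proportional to pool sizes (or uniform).
* ``fedprox`` — FedAvg weighting plus a proximal pull (mu/2)||theta -
  theta_global||^2 in the local objective.
* ``moon`` — FedAvg weighting plus the model-contrastive term comparing the
  current representation with the global and previous-round local ones.

After training, :func:`personalize` fine-tunes the global model per center
on that center's core set (or full pool), yielding personalized models.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from ._rng import subseed
from .contribution import ContributionRecord, compute_quality, compute_richness, compute_weights
from .mcdem import PruneConfig, PrunePartition, extract_core
from .network import ConvNet, ConvNetConfig, ModelParams
from .synthetic import CenterDataset
from .training import TrainConfig, train_local

__all__ = ["AlgoConfig", "GlobalState", "local_update", "aggregate", "run_federated", "personalize"]

ALGORITHMS = ("fedcmc", "fedavg", "fedprox", "moon")


@dataclass(frozen=True)
class AlgoConfig:
    """Which federated algorithm to run, and its knobs."""

    algorithm: str = "fedcmc"
    rounds: int = 20
    fedprox_mu: float = 0.1
    moon_mu: float = 1.0
    moon_temperature: float = 0.5
    personalize_epochs: int = 3
    use_mcdem: bool = True
    use_fair_aggregation: bool = True
    lambda_mix: float = 0.5
    weight_scheme: str = "convex"
    fedavg_weighting: str = "size"  # or "uniform"
    personalize_on_core: bool = True

    def __post_init__(self):
        if self.algorithm not in ALGORITHMS:
            raise ValueError(f"algorithm must be one of {ALGORITHMS}")
        if self.rounds < 1:
            raise ValueError("rounds must be >= 1")
        if self.fedprox_mu < 0 or self.moon_mu < 0:
            raise ValueError("penalty coefficients must be >= 0")
        if self.moon_temperature <= 0:
            raise ValueError("moon_temperature must be > 0")
        if self.personalize_epochs < 0:
            raise ValueError("personalize_epochs must be >= 0")
        if self.fedavg_weighting not in ("size", "uniform"):
            raise ValueError("fedavg_weighting must be 'size' or 'uniform'")


@dataclass
class GlobalState:
    """Server-side state after a federated run."""

    params: ModelParams
    round: int
    weight_history: list[ContributionRecord]
    loss_history: dict[str, list[float]]
    partitions: Optional[list[PrunePartition]] = None
    center_ids: list[str] = field(default_factory=list)
    param_trajectory: list[ModelParams] = field(default_factory=list)


def local_update(
    net: ConvNet,
    global_params: ModelParams,
    X: np.ndarray,
    y: np.ndarray,
    train_cfg: TrainConfig,
    algo_cfg: AlgoConfig,
    *,
    eval_X: Optional[np.ndarray] = None,
    eval_y: Optional[np.ndarray] = None,
    previous_local: Optional[ModelParams] = None,
) -> tuple[ModelParams, float, list[float]]:
    """One center's local pass; returns (params, quality Q, epoch losses).

    Q is accuracy at cutoff 0.5 on (eval_X, eval_y) if given, else on the
    training data itself.
    """
    kwargs = {}
    if algo_cfg.algorithm == "fedprox":
        kwargs = dict(prox_mu=algo_cfg.fedprox_mu, prox_anchor=global_params)
    elif algo_cfg.algorithm == "moon":
        kwargs = dict(
            moon_mu=algo_cfg.moon_mu,
            moon_temperature=algo_cfg.moon_temperature,
            moon_global=global_params,
            moon_previous=previous_local if previous_local is not None else global_params,
        )
    params, losses = train_local(net, global_params, X, y, train_cfg, **kwargs)
    if eval_X is None:
        eval_X, eval_y = X, y
    q = compute_quality(net.predict_proba(params, eval_X), eval_y)
    return params, q, losses


def aggregate(states: Sequence[ModelParams], w: Sequence[float]) -> ModelParams:
    """Block-wise convex combination of center parameters."""
    if len(states) == 0:
        raise ValueError("nothing to aggregate")
    w = np.asarray(w, dtype=np.float64)
    if len(w) != len(states):
        raise ValueError("one weight per center required")
    if np.any(w < -1e-12) or abs(w.sum() - 1.0) > 1e-6:
        raise ValueError("weights must be non-negative and sum to 1 (within 1e-6)")
    tag = states[0].architecture_tag
    keys = set(states[0].blocks)
    for s in states[1:]:
        if s.architecture_tag != tag or set(s.blocks) != keys:
            raise ValueError("architecture tags differ; cannot aggregate")
        for k in keys:
            if s.blocks[k].shape != states[0].blocks[k].shape:
                raise ValueError(f"shape mismatch in block {k!r}")
    blocks = {
        k: sum(wk * s.blocks[k] for wk, s in zip(w, states)) for k in states[0].blocks
    }
    return ModelParams(tag, blocks, states[0].total_conv_kernels)


def _q_eval_sets(ds: CenterDataset, partition: Optional[PrunePartition]):
    """Held-out samples for the per-round quality metric Q.

    With MCDEM on, the last probe cycle's validation fold serves as the
    quality probe; otherwise Q falls back to the center's full training pool.
    """
    if partition is not None and partition.probe_folds:
        ids = sorted(partition.probe_folds[-1][1])
        X, y, _ = ds.arrays(ids)
        return X, y
    X, y, _ = ds.arrays(sorted(ds.train_ids))
    return X, y


def run_federated(
    federation: Sequence[CenterDataset],
    algo_cfg: AlgoConfig,
    train_cfg: TrainConfig,
    prune_cfg: Optional[PruneConfig] = None,
    net: Optional[ConvNet] = None,
    seed: Optional[int] = None,
    partitions: Optional[Sequence[PrunePartition]] = None,
    track_trajectory: bool = False,
) -> GlobalState:
    """Run one federated training and return the final global state.

    ``seed`` (default ``train_cfg.seed``) is the experiment root; every
    local update at (round r, center k) draws its batch order from the named
    sub-stream (seed, "local", r, k), so two algorithms that prescribe the
    same local computation produce bitwise-identical trajectories.
    Pre-computed MCDEM ``partitions`` may be passed in to share the pruning
    across algorithm variants.
    """
    if len(federation) == 0 or all(len(ds.train_ids) == 0 for ds in federation):
        raise ValueError("need at least one center with training data")
    seed = train_cfg.seed if seed is None else seed
    if net is None:
        H, W = federation[0].images[0].pixels.shape
        net = ConvNet(ConvNetConfig(image_size=(H, W)))
    center_ids = [ds.center_id for ds in federation]
    K = len(federation)

    use_mcdem = algo_cfg.algorithm == "fedcmc" and algo_cfg.use_mcdem
    parts: Optional[list[PrunePartition]] = None
    if use_mcdem:
        if partitions is not None:
            parts = list(partitions)
        else:
            if prune_cfg is None:
                prune_cfg = PruneConfig(seed=subseed(seed, "mcdem"))
            parts = [extract_core(ds, prune_cfg, net=net, train_cfg=train_cfg) for ds in federation]

    # training pools (sorted for determinism) and static richness D
    pools = []
    for k, ds in enumerate(federation):
        ids = sorted(parts[k].core) if use_mcdem else sorted(ds.train_ids)
        X, y, _ = ds.arrays(ids)
        pools.append((X, y))
    if use_mcdem:
        D = compute_richness(parts)
    else:
        sizes = np.array([len(X) for X, _ in pools], dtype=np.float64)
        D = sizes / sizes.sum()
    q_sets = [
        _q_eval_sets(ds, parts[k] if use_mcdem else None) for k, ds in enumerate(federation)
    ]

    global_params = net.init_params(subseed(seed, "init"))
    prev_local: list[Optional[ModelParams]] = [None] * K
    weight_history: list[ContributionRecord] = []
    loss_history: dict[str, list[float]] = {cid: [] for cid in center_ids}
    trajectory: list[ModelParams] = []

    for rnd in range(algo_cfg.rounds):
        locals_, qualities = [], []
        for k in range(K):
            X, y = pools[k]
            cfg = TrainConfig(
                local_epochs=train_cfg.local_epochs,
                batch_size=train_cfg.batch_size,
                learning_rate=train_cfg.learning_rate,
                focal_gamma=train_cfg.focal_gamma,
                focal_alpha=train_cfg.focal_alpha,
                seed=subseed(seed, "local", rnd, center_ids[k]),
            )
            params_k, q_k, losses_k = local_update(
                net, global_params, X, y, cfg, algo_cfg,
                eval_X=q_sets[k][0], eval_y=q_sets[k][1],
                previous_local=prev_local[k],
            )
            locals_.append(params_k)
            qualities.append(q_k)
            loss_history[center_ids[k]].append(losses_k[-1] if losses_k else np.nan)

        if algo_cfg.algorithm == "fedcmc":
            if algo_cfg.use_fair_aggregation:
                w = compute_weights(D, qualities, algo_cfg.lambda_mix, algo_cfg.weight_scheme)
            else:
                w = np.full(K, 1.0 / K)  # average aggregation (ablation default)
        elif algo_cfg.algorithm == "fedavg" and algo_cfg.fedavg_weighting == "uniform":
            w = np.full(K, 1.0 / K)
        else:  # fedavg(size), fedprox, moon: classic size-proportional weights
            sizes = np.array([len(X) for X, _ in pools], dtype=np.float64)
            w = sizes / sizes.sum()

        weight_history.append(
            ContributionRecord(
                round=rnd,
                D=tuple(float(d) for d in D),
                Q=tuple(float(q) for q in qualities),
                w=tuple(float(x) for x in w / w.sum()),
                lambda_mix=algo_cfg.lambda_mix,
            )
        )
        global_params = aggregate(locals_, w)
        prev_local = list(locals_)
        if track_trajectory:
            trajectory.append(global_params.copy())

    return GlobalState(
        params=global_params,
        round=algo_cfg.rounds,
        weight_history=weight_history,
        loss_history=loss_history,
        partitions=parts,
        center_ids=center_ids,
        param_trajectory=trajectory,
    )


def personalize(
    state: GlobalState,
    federation: Sequence[CenterDataset],
    train_cfg: TrainConfig,
    personalize_epochs: int,
    net: Optional[ConvNet] = None,
    on_core: bool = True,
    seed: Optional[int] = None,
) -> dict[str, ModelParams]:
    """Fine-tune the global model per center; the global model is untouched.

    Each center tunes on its core set when MCDEM partitions are available
    and ``on_core`` is true, else on its full training pool. With
    ``personalize_epochs == 0`` every personalized model equals the global.
    """
    if personalize_epochs < 0:
        raise ValueError("personalize_epochs must be >= 0")
    if net is None:
        H, W = federation[0].images[0].pixels.shape
        net = ConvNet(ConvNetConfig(image_size=(H, W)))
    seed = train_cfg.seed if seed is None else seed
    parts = {p.center_id: p for p in (state.partitions or [])}
    out: dict[str, ModelParams] = {}
    for ds in federation:
        part = parts.get(ds.center_id)
        ids = sorted(part.core) if (on_core and part is not None) else sorted(ds.train_ids)
        X, y, _ = ds.arrays(ids)
        cfg = TrainConfig(
            local_epochs=personalize_epochs,
            batch_size=train_cfg.batch_size,
            learning_rate=train_cfg.learning_rate,
            focal_gamma=train_cfg.focal_gamma,
            focal_alpha=train_cfg.focal_alpha,
            seed=subseed(seed, "personalize", ds.center_id),
        )
        tuned, _ = train_local(net, state.params, X, y, cfg)
        out[ds.center_id] = tuned
    return out
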