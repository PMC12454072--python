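"""Multi-center core data extraction (MCDEM).

Each center privately partitions its training pool S into a core set C and a
redundant set R. A probe network is trained on a stratified 80% split T of S
and scored on the held-out 20% V; a sample's error epsilon is its mean
validation-side prediction error across several independent probe cycles.
Samples the probe predicts *well* (epsilon strictly below a threshold) carry
information the pool already represents elsewhere — near-duplicates and
over-represented easy cases — and are marked redundant. Low-error pruning
shifts the retained distribution toward under-represented samples.

A single 80/20 cycle only scores one fifth of the pool, so the extraction
runs ``n_repeats`` cycles with fresh splits and fresh probe training;
samples that never land in any V (possible only for tiny pools) default to
core. A ``min_core_fraction`` floor prevents a center's core from collapsing.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._rng import subseed
from .network import ConvNet, ConvNetConfig, ModelParams
from .synthetic import CenterDataset
from .training import TrainConfig, train_local

__all__ = [
    "PruneConfig",
    "PrunePartition",
    "probe_split",
    "probe_errors",
    "select_threshold",
    "extract_core",
    "core_ratio",
    "save_partition",
    "load_partition",
]


@dataclass(frozen=True)
class PruneConfig:
    """Settings of one core-extraction pass."""

    probe_ratio: float = 0.8
    n_repeats: int = 15
    error_kind: str = "cross_entropy"  # or "absolute_prob_error"
    threshold_strategy: str = "quantile"  # or "fixed"
    threshold_param: float = 0.4
    min_core_fraction: float = 0.2
    # probe-specific training: the probe must resolve confidence differences
    # between seen and unseen samples, so it trains harder than a federated
    # local pass and in the gamma -> 0 limit of the focal objective (the
    # focal down-weighting flattens exactly the well-classified regime the
    # redundancy ranking depends on)
    probe_epochs: int = 150
    probe_lr: float = 3e-3
    probe_gamma: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if not (0.0 < self.probe_ratio < 1.0):
            raise ValueError("probe_ratio must be in (0, 1)")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")
        if self.error_kind not in ("absolute_prob_error", "cross_entropy"):
            raise ValueError(f"unknown error_kind {self.error_kind!r}")
        if self.threshold_strategy not in ("quantile", "fixed"):
            raise ValueError(f"unknown threshold_strategy {self.threshold_strategy!r}")
        if self.threshold_param < 0:
            raise ValueError("threshold_param must be >= 0")
        if self.threshold_strategy == "quantile" and not (0.0 < self.threshold_param < 1.0):
            raise ValueError("quantile threshold_param must be in (0, 1)")
        if not (0.0 < self.min_core_fraction <= 1.0):
            raise ValueError("min_core_fraction must be in (0, 1]")


@dataclass
class PrunePartition:
    """Result of pruning one center's training pool."""

    center_id: str
    S: set[str]
    epsilon: dict[str, float]
    threshold: float
    core: set[str]
    redundant: set[str]
    probe_folds: list[tuple[set[str], set[str]]] = field(default_factory=list)

    def __post_init__(self):
        if self.core & self.redundant:
            raise ValueError("core and redundant sets must be disjoint")
        if self.core | self.redundant != self.S:
            raise ValueError("core and redundant sets must partition S")


def probe_split(
    S: Sequence[str], probe_ratio: float, seed: int, labels: Mapping[str, int] | None = None
) -> tuple[set[str], set[str]]:
    """Stratified split of the pool into probe-train T and probe-validation V.

    |T| = round(probe_ratio * |S|) overall; stratification keeps each class's
    share of V within one sample of its share of S (when labels are given).
    """
    S = sorted(S)
    if len(S) < 5:
        raise ValueError("pool too small to probe (need |S| >= 5)")
    rng = np.random.default_rng(seed)
    n_train = int(round(probe_ratio * len(S)))
    n_train = min(max(n_train, 1), len(S) - 1)
    if labels is None:
        ids = list(S)
        rng.shuffle(ids)
        T = set(ids[:n_train])
    else:
        # proportional allocation per class with largest-remainder rounding
        classes: dict[int, list[str]] = {}
        for sid in S:
            classes.setdefault(int(labels[sid]), []).append(sid)
        quotas = {c: probe_ratio * len(ids) for c, ids in classes.items()}
        alloc = {c: int(np.floor(q)) for c, q in quotas.items()}
        short = n_train - sum(alloc.values())
        for c in sorted(classes, key=lambda c: quotas[c] - alloc[c], reverse=True)[:short]:
            alloc[c] += 1
        T = set()
        for c, ids in classes.items():
            ids = list(ids)
            rng.shuffle(ids)
            k = min(max(alloc[c], 0), len(ids))
            T.update(ids[:k])
    V = set(S) - T
    return T, V


def _fold_plan(
    S: Sequence[str],
    labels: Mapping[str, int],
    probe_ratio: float,
    n_repeats: int,
    seed: int,
) -> list[tuple[set[str], set[str]]]:
    """(T, V) splits whose validation folds sweep the whole pool.

    Cycles are organized in sweeps of K = round(1/(1 - probe_ratio))
    stratified folds; within a sweep the V folds are disjoint and cover S,
    so after one full sweep every sample has at least one out-of-probe
    error. Each sweep reshuffles, so extra repeats add independent scores.
    """
    K = max(2, int(round(1.0 / (1.0 - probe_ratio))))
    plan: list[tuple[set[str], set[str]]] = []
    sweep = 0
    while len(plan) < n_repeats:
        rng = np.random.default_rng(subseed(seed, "sweep", sweep))
        folds: list[list[str]] = [[] for _ in range(K)]
        classes: dict[int, list[str]] = {}
        for sid in sorted(S):
            classes.setdefault(int(labels[sid]), []).append(sid)
        offset = 0  # rotate class starts so fold sizes stay balanced
        for c in sorted(classes):
            ids = classes[c]
            rng.shuffle(ids)
            for i, sid in enumerate(ids):
                folds[(i + offset) % K].append(sid)
            offset += len(ids) % K
        for fold in folds:
            if len(plan) == n_repeats:
                break
            V = set(fold)
            plan.append((set(S) - V, V))
        sweep += 1
    return plan


def probe_errors(
    probs: Mapping[str, float], labels: Mapping[str, int], error_kind: str
) -> dict[str, float]:
    """Per-sample prediction error of a probe model on validation samples.

    absolute_prob_error: |y - p|; cross_entropy: -[y ln p + (1-y) ln(1-p)]
    with p clipped to [1e-7, 1 - 1e-7].
    """
    out = {}
    for sid, p in probs.items():
        y = int(labels[sid])
        p = float(p)
        if error_kind == "absolute_prob_error":
            out[sid] = abs(y - p)
        elif error_kind == "cross_entropy":
            p = float(np.clip(p, 1e-7, 1.0 - 1e-7))
            out[sid] = -(y * np.log(p) + (1 - y) * np.log(1.0 - p))
        else:
            raise ValueError(f"unknown error_kind {error_kind!r}")
    return out


def select_threshold(errors: Sequence[float], strategy: str, param: float) -> float:
    """Error threshold below which samples count as redundant."""
    errors = np.asarray(list(errors), dtype=np.float64)
    if errors.size == 0:
        raise ValueError("cannot select a threshold from an empty error set")
    if strategy == "fixed":
        return float(param)
    if strategy == "quantile":
        return float(np.quantile(errors, param))  # linear-interpolation convention
    raise ValueError(f"unknown threshold strategy {strategy!r}")


def extract_core(
    dataset: CenterDataset,
    prune_cfg: PruneConfig,
    net: ConvNet | None = None,
    train_cfg: TrainConfig | None = None,
) -> PrunePartition:
    """Partition a center's training pool into core and redundant samples.

    Runs ``n_repeats`` probe cycles; each cycle trains a fresh probe network
    on T for ``probe_epochs`` epochs and records errors on V. Per-sample
    epsilon is the mean of that sample's validation-side errors. Samples with
    epsilon strictly below the selected threshold are redundant; if that
    would leave fewer than ``min_core_fraction * |S|`` core samples, only
    the lowest-epsilon samples are pruned down to the floor. A probe cycle
    whose training diverges is discarded and rerun with a fresh seed.
    """
    S = sorted(dataset.train_ids)
    labels = dataset.labels
    pool_labels = {sid: labels[sid] for sid in S}
    n_classes = len(set(pool_labels.values()))
    if len(S) == 0:
        raise ValueError("training pool is empty")
    if n_classes < 2 or len(S) < 5:
        # degenerate pool: nothing to probe against; keep everything
        return PrunePartition(dataset.center_id, set(S), {sid: np.inf for sid in S}, 0.0, set(S), set())

    if net is None:
        H, W = dataset.images[0].pixels.shape
        net = ConvNet(ConvNetConfig(image_size=(H, W)))
    if train_cfg is None:
        train_cfg = TrainConfig()

    X_all, y_all, ids_all = dataset.arrays(S)
    pos = {sid: i for i, sid in enumerate(ids_all)}

    err_sum: dict[str, float] = {sid: 0.0 for sid in S}
    err_cnt: dict[str, int] = {sid: 0 for sid in S}
    plan = _fold_plan(
        S, pool_labels, prune_cfg.probe_ratio, prune_cfg.n_repeats,
        subseed(prune_cfg.seed, "folds", dataset.center_id),
    )
    folds = []
    cycle = 0
    attempts = 0
    while cycle < prune_cfg.n_repeats:
        attempt_seed = subseed(prune_cfg.seed, "probe", dataset.center_id, cycle, attempts)
        T, V = plan[cycle]
        ti = [pos[s] for s in sorted(T)]
        vi = sorted(V)
        cfg = TrainConfig(
            local_epochs=prune_cfg.probe_epochs,
            batch_size=train_cfg.batch_size,
            learning_rate=prune_cfg.probe_lr,
            focal_gamma=prune_cfg.probe_gamma,
            focal_alpha=train_cfg.focal_alpha,
            seed=subseed(attempt_seed, "train"),
        )
        try:
            probe = net.init_params(subseed(attempt_seed, "init"))
            probe, _ = train_local(net, probe, X_all[ti], y_all[ti], cfg)
        except FloatingPointError:
            warnings.warn(
                f"probe cycle {cycle} diverged at center {dataset.center_id}; reseeding",
                stacklevel=2,
            )
            attempts += 1
            continue
        p_v = net.predict_proba(probe, X_all[[pos[s] for s in vi]])
        errs = probe_errors(dict(zip(vi, p_v)), pool_labels, prune_cfg.error_kind)
        for sid, e in errs.items():
            err_sum[sid] += e
            err_cnt[sid] += 1
        folds.append((T, V))
        cycle += 1
        attempts = 0

    never_seen = [sid for sid in S if err_cnt[sid] == 0]
    scored = {sid: err_sum[sid] / err_cnt[sid] for sid in S if err_cnt[sid] > 0}
    threshold = select_threshold(
        list(scored.values()), prune_cfg.threshold_strategy, prune_cfg.threshold_param
    )
    redundant = {sid for sid, e in scored.items() if e < threshold}

    floor = int(np.ceil(prune_cfg.min_core_fraction * len(S)))
    max_prune = len(S) - floor
    if len(redundant) > max_prune:
        ranked = sorted(redundant, key=lambda sid: (scored[sid], sid))
        redundant = set(ranked[:max_prune])

    epsilon = dict(scored)
    for sid in never_seen:  # unscored samples default to core
        epsilon[sid] = np.inf
    core = set(S) - redundant
    return PrunePartition(
        center_id=dataset.center_id,
        S=set(S),
        epsilon=epsilon,
        threshold=float(threshold),
        core=core,
        redundant=redundant,
        probe_folds=folds,
    )


def core_ratio(partition: PrunePartition) -> float:
    """|C| / |S| — the retained fraction of the original training pool."""
    if len(partition.S) == 0:
        raise ValueError("empty pool has no core ratio")
    return len(partition.core) / len(partition.S)


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def save_partition(partition: PrunePartition, out_dir, prune_cfg: PruneConfig | None = None) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame(
        {
            "id": sorted(partition.S),
            "epsilon": [partition.epsilon[s] for s in sorted(partition.S)],
            "is_core": [s in partition.core for s in sorted(partition.S)],
        }
    )
    df.to_csv(out_dir / f"partition_{partition.center_id}.csv", index=False)
    side = {"center_id": partition.center_id, "threshold": partition.threshold}
    if prune_cfg is not None:
        side["config"] = {
            k: getattr(prune_cfg, k)
            for k in (
                "probe_ratio", "n_repeats", "error_kind", "threshold_strategy",
                "threshold_param", "min_core_fraction", "probe_epochs", "seed",
            )
        }
    (out_dir / f"partition_{partition.center_id}.json").write_text(json.dumps(side, indent=2))
    return out_dir


def load_partition(csv_path) -> PrunePartition:
    csv_path = Path(csv_path)
    df = pd.read_csv(csv_path)
    side = json.loads(csv_path.with_suffix(".json").read_text())
    core = set(df.loc[df.is_core, "id"])
    return PrunePartition(
        center_id=side["center_id"],
        S=set(df["id"]),
        epsilon=dict(zip(df["id"], df["epsilon"])),
        threshold=float(side["threshold"]),
        core=core,
        redundant=set(df["id"]) - core,
    )
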