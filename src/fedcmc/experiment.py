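"""End-to-end experiment orchestration.

``run_experiment`` takes one federation through every configured algorithm:
federated training, personalization (contribution-fair algorithm only),
deep-feature extraction, a per-center SBELM classifier, per-center test
reports, and the fairness summary against the baselines. ``run_ablation``
produces the three-row component grid (no pruning / pruning with average
aggregation / pruning with contribution-fair aggregation), scored from the
global model's predicted probabilities per center so the grid isolates the
pruning x aggregation effect. All outputs are plain CSV/JSON files plus a
manifest; identical config and seed reproduce identical metric tables.
"""

from __future__ import annotations

import json
import hashlib
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from ._rng import subseed
from .evaluation import FairnessReport, fairness_report, make_report, roc_auc
from .fed import AlgoConfig, GlobalState, personalize, run_federated
from .mcdem import PruneConfig, core_ratio, extract_core, save_partition
from .network import ConvNet, ConvNetConfig
from .sbelm import feature_matrix, sbelm_fit, sbelm_predict
from .synthetic import CenterDataset, GeneratorConfig, generate_federation, save_federation
from .training import TrainConfig

__all__ = ["ExperimentConfig", "run_experiment", "run_ablation", "ABLATION_ROWS"]

ABLATION_ROWS = (
    {"use_mcdem": False, "use_fair_aggregation": False},
    {"use_mcdem": True, "use_fair_aggregation": False},
    {"use_mcdem": True, "use_fair_aggregation": True},
)


@dataclass
class ExperimentConfig:
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    prune: PruneConfig = field(default_factory=PruneConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    algorithms: tuple[str, ...] = ("fedcmc", "fedavg", "fedprox", "moon")
    rounds: int = 20
    personalize_epochs: int = 3
    lambda_mix: float = 0.5
    n_hidden_sbelm: int = 50
    output_dir: str = "fedcmc_run"
    seed: int = 0

    def __post_init__(self):
        # one experiment seed propagates to all sub-configs unless overridden
        self.generator = replace(self.generator, seed=subseed(self.seed, "generator"))
        self.prune = replace(self.prune, seed=subseed(self.seed, "prune"))
        self.train = replace(self.train, seed=self.seed)

    def algo_config(self, algorithm: str, **overrides) -> AlgoConfig:
        return AlgoConfig(
            algorithm=algorithm,
            rounds=self.rounds,
            personalize_epochs=self.personalize_epochs,
            lambda_mix=self.lambda_mix,
            **overrides,
        )

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = dict(raw)
        for key, sub in (("generator", GeneratorConfig), ("prune", PruneConfig), ("train", TrainConfig)):
            if key in kwargs and isinstance(kwargs[key], dict):
                sub_kwargs = dict(kwargs[key])
                for tup in ("per_center_n", "image_size", "prevalence",
                            "heterogeneity_shift", "clone_fraction"):
                    if tup in sub_kwargs and isinstance(sub_kwargs[tup], list):
                        sub_kwargs[tup] = tuple(sub_kwargs[tup])
                kwargs[key] = sub(**sub_kwargs)
        if "algorithms" in kwargs:
            kwargs["algorithms"] = tuple(kwargs["algorithms"])
        return cls(**kwargs)

    def to_yaml(self, path) -> None:
        d = asdict(self)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


def _evaluate_center(net, params, ds: CenterDataset, split_ids, n_hidden, seed,
                     classifier_params=None):
    """Deep features -> SBELM -> test report for one center.

    The SBELM trains on the center's training images and scores the
    requested split with the model whose kernels feed the features
    (``classifier_params`` defaults to ``params``).
    """
    cp = params if classifier_params is None else classifier_params
    train_imgs = ds.subset(sorted(ds.train_ids))
    eval_imgs = ds.subset(sorted(split_ids))
    F_train = feature_matrix(net, cp, train_imgs)
    F_eval = feature_matrix(net, cp, eval_imgs)
    y_train = np.array([im.label for im in train_imgs])
    y_eval = np.array([im.label for im in eval_imgs])
    clf = sbelm_fit(F_train, y_train, n_hidden=n_hidden, seed=seed)
    scores = sbelm_predict(clf, F_eval)
    return make_report(ds.center_id, scores, y_eval), clf, scores, y_eval


def run_experiment(config: ExperimentConfig, federation: Optional[Sequence[CenterDataset]] = None):
    """Run every configured algorithm on one shared federation.

    Returns a result dict (reports, fairness summary, global states) and
    writes CSV/JSON artifacts plus a manifest under ``config.output_dir``.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    if federation is None:
        federation = generate_federation(config.generator)
    save_federation(federation, out / "data")
    H, W = federation[0].images[0].pixels.shape
    net = ConvNet(ConvNetConfig(image_size=(H, W)))

    # MCDEM once, shared by every fedcmc-family run
    partitions = [extract_core(ds, config.prune, net=net, train_cfg=config.train)
                  for ds in federation]
    for p in partitions:
        save_partition(p, out / "partitions", config.prune)

    results: dict = {"reports": {}, "states": {}, "errors": {}, "partitions": partitions}
    auc_table: dict[str, dict[str, float]] = {}
    rows = []
    for algo in config.algorithms:
        try:
            algo_cfg = config.algo_config(algo)
            state = run_federated(
                federation, algo_cfg, config.train,
                prune_cfg=config.prune, net=net, seed=config.seed,
                partitions=partitions if algo == "fedcmc" else None,
            )
            if algo == "fedcmc":
                per_center = personalize(
                    state, federation, config.train, config.personalize_epochs,
                    net=net, on_core=algo_cfg.personalize_on_core, seed=config.seed,
                )
            else:
                per_center = {ds.center_id: state.params for ds in federation}
            reports = {}
            auc_table[algo] = {}
            for ds in federation:
                rep, _, _, _ = _evaluate_center(
                    net, per_center[ds.center_id], ds, ds.test_ids,
                    config.n_hidden_sbelm, subseed(config.seed, "sbelm", algo, ds.center_id),
                )
                reports[ds.center_id] = rep
                auc_table[algo][ds.center_id] = rep.auc
                rows.append({"algorithm": algo, **rep.to_dict()})
            results["reports"][algo] = reports
            results["states"][algo] = state
        except Exception as exc:  # one failed algorithm must not kill the rest
            results["errors"][algo] = repr(exc)

    metrics = pd.DataFrame(rows)
    metrics.to_csv(out / "metrics.csv", index=False, float_format="%.6f")
    fair: Optional[FairnessReport] = None
    if "fedcmc" in auc_table and len(auc_table) > 1:
        fair = fairness_report(auc_table)
        (out / "fairness.json").write_text(json.dumps({
            "performance_improvement_pct": fair.performance_improvement_pct,
            "fairness_improvement_pct": fair.fairness_improvement_pct,
            "auc_table": fair.auc_table,
            "skipped_baselines": fair.skipped_baselines,
        }, indent=2))
    results["fairness"] = fair
    results["core_ratios"] = {p.center_id: core_ratio(p) for p in partitions}

    manifest = {
        "seed": config.seed,
        "algorithms": list(config.algorithms),
        "core_ratios": results["core_ratios"],
        "reports": [
            {"algorithm": a, "center": c} for a in results["reports"] for c in results["reports"][a]
        ],
        "errors": results["errors"],
        "metrics_sha256": hashlib.sha256((out / "metrics.csv").read_bytes()).hexdigest(),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return results


def run_ablation(
    config: ExperimentConfig,
    federation: Optional[Sequence[CenterDataset]] = None,
    out_path: Optional[str] = None,
) -> pd.DataFrame:
    """Three-row component grid: pruning x aggregation, per-center AUCs.

    Row 1 (no pruning, average aggregation) is by construction the plain
    uniform-FedAvg run with the same seeds; rows 2 and 3 switch on MCDEM
    and then contribution-fair aggregation. Each row reports per-center
    train and test AUC of the global model's predicted probabilities.
    """
    if federation is None:
        federation = generate_federation(config.generator)
    H, W = federation[0].images[0].pixels.shape
    net = ConvNet(ConvNetConfig(image_size=(H, W)))
    partitions = [extract_core(ds, config.prune, net=net, train_cfg=config.train)
                  for ds in federation]
    rows = []
    for flags in ABLATION_ROWS:
        algo_cfg = config.algo_config("fedcmc", **flags)
        state = run_federated(
            federation, algo_cfg, config.train, prune_cfg=config.prune,
            net=net, seed=config.seed,
            partitions=partitions if flags["use_mcdem"] else None,
        )
        row = {"mcdem": flags["use_mcdem"], "fair_aggregation": flags["use_fair_aggregation"]}
        for ds in federation:
            for split, ids in (("train", ds.train_ids), ("test", ds.test_ids)):
                X, y, _ = ds.arrays(sorted(ids))
                row[f"{split}_auc_{ds.center_id}"] = roc_auc(net.predict_proba(state.params, X), y)
        rows.append(row)
    table = pd.DataFrame(rows)
    if out_path is not None:
        table.to_csv(out_path, index=False, float_format="%.6f")
    return table
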