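"""Aggregation contracts, algorithm degeneration, and personalization."""

import numpy as np
import pytest

from fedcmc import GeneratorConfig, generate_federation
from fedcmc.fed import AlgoConfig, aggregate, personalize, run_federated
from fedcmc.mcdem import PruneConfig
from fedcmc.network import ConvNet, ConvNetConfig, ModelParams
from fedcmc.training import TrainConfig, train_local


def _scalar_params(*values):
    return [
        ModelParams("toy", {"w": np.array([float(v)])}, 0) for v in values
    ]


@pytest.fixture(scope="module")
def mini_federation():
    cfg = GeneratorConfig(
        per_center_n=(40, 24, 12),
        prevalence=(0.75, 0.8, 0.75),
        heterogeneity_shift=(0.0, 0.1, 0.2),
        clone_fraction=(0.3, 0.3, 0.1),
        seed=23,
    )
    return generate_federation(cfg)


@pytest.fixture(scope="module")
def fast_train():
    return TrainConfig(local_epochs=1, batch_size=16, seed=5)


FAST_PRUNE = PruneConfig(probe_epochs=3, n_repeats=5, seed=5)


class TestAggregate:
    def test_identical_states_fixed_point(self, tiny_net):
        p = tiny_net.init_params(0)
        out = aggregate([p.copy(), p.copy(), p.copy()], [0.2, 0.5, 0.3])
        assert out.allclose(p, atol=1e-12)

    def test_degenerate_weight_selects_state(self, tiny_net):
        states = [tiny_net.init_params(s) for s in range(3)]
        out = aggregate(states, [1.0, 0.0, 0.0])
        assert out.allclose(states[0], atol=0.0)

    def test_scalar_hand_arithmetic(self):
        out = aggregate(_scalar_params(0, 3, 6), [1 / 6, 1 / 3, 1 / 2])
        assert out.blocks["w"][0] == pytest.approx(4.0)

    def test_permutation_equivariance(self, tiny_net):
        states = [tiny_net.init_params(s) for s in range(3)]
        w = [0.2, 0.3, 0.5]
        a = aggregate(states, w)
        b = aggregate([states[2], states[0], states[1]], [0.5, 0.2, 0.3])
        assert a.allclose(b, atol=1e-12)  # summation order may differ in rounding

    def test_off_simplex_rejected(self):
        with pytest.raises(ValueError):
            aggregate(_scalar_params(1, 2), [0.7, 0.4])
        with pytest.raises(ValueError):
            aggregate(_scalar_params(1, 2), [1.5, -0.5])

    def test_shape_mismatch_rejected(self):
        a = ModelParams("toy", {"w": np.zeros(2)}, 0)
        b = ModelParams("toy", {"w": np.zeros(3)}, 0)
        with pytest.raises(ValueError):
            aggregate([a, b], [0.5, 0.5])


class TestLocalUpdate:
    def test_zero_epochs_is_identity(self, tiny_net, mini_federation):
        ds = mini_federation[0]
        X, y, _ = ds.arrays(sorted(ds.train_ids))
        p = tiny_net.init_params(1)
        out, _ = train_local(tiny_net, p, X, y, TrainConfig(local_epochs=0))
        assert out.allclose(p, atol=0.0)

    def test_training_descends_focal_loss(self, tiny_net, mini_federation):
        from fedcmc.network import focal_loss

        ds = mini_federation[0]
        X, y, _ = ds.arrays(sorted(ds.train_ids))
        p = tiny_net.init_params(2)
        before = focal_loss(tiny_net.predict_proba(p, X), y, 0.5, 2.0)
        out, losses = train_local(
            tiny_net, p, X, y, TrainConfig(local_epochs=10, seed=3)
        )
        after = focal_loss(tiny_net.predict_proba(out, X), y, 0.5, 2.0)
        assert after < before

    def test_fedprox_penalty_pulls_toward_anchor(self, tiny_net, mini_federation):
        """Distance from the anchor is non-increasing in the proximal mu."""
        ds = mini_federation[0]
        X, y, _ = ds.arrays(sorted(ds.train_ids))
        dists = []
        for mu in (0.0, 1.0, 10.0):
            d_seeds = []
            for seed in range(3):
                anchor = tiny_net.init_params(seed)
                out, _ = train_local(
                    tiny_net, anchor, X, y,
                    TrainConfig(local_epochs=3, seed=seed),
                    prox_mu=mu, prox_anchor=anchor,
                )
                d_seeds.append(np.linalg.norm(out.flat() - anchor.flat()))
            dists.append(np.mean(d_seeds))
        assert dists[0] >= dists[1] >= dists[2]


class TestRunFederated:
    def test_single_center_equals_centralized(self, tiny_net, mini_federation, fast_train):
        """K=1 collapses aggregation: the trajectory equals local training."""
        from fedcmc._rng import subseed

        fed = mini_federation[:1]
        algo = AlgoConfig(
            algorithm="fedcmc", rounds=3,
            use_mcdem=False, use_fair_aggregation=False,
        )
        state = run_federated(fed, algo, fast_train, net=tiny_net, seed=42)
        # replay manually
        ds = fed[0]
        X, y, _ = ds.arrays(sorted(ds.train_ids))
        p = tiny_net.init_params(subseed(42, "init"))
        for rnd in range(3):
            cfg = TrainConfig(
                local_epochs=fast_train.local_epochs,
                batch_size=fast_train.batch_size,
                learning_rate=fast_train.learning_rate,
                focal_gamma=fast_train.focal_gamma,
                focal_alpha=fast_train.focal_alpha,
                seed=subseed(42, "local", rnd, ds.center_id),
            )
            p, _ = train_local(tiny_net, p, X, y, cfg)
        assert state.params.allclose(p, atol=0.0)

    def test_degenerate_fedcmc_equals_uniform_fedavg(self, tiny_net, mini_federation, fast_train):
        """Both switches off: parameter trajectory bitwise equals uniform FedAvg."""
        a = run_federated(
            mini_federation,
            AlgoConfig(algorithm="fedcmc", rounds=3, use_mcdem=False, use_fair_aggregation=False),
            fast_train, net=tiny_net, seed=7, track_trajectory=True,
        )
        b = run_federated(
            mini_federation,
            AlgoConfig(algorithm="fedavg", rounds=3, fedavg_weighting="uniform"),
            fast_train, net=tiny_net, seed=7, track_trajectory=True,
        )
        for pa, pb in zip(a.param_trajectory, b.param_trajectory):
            for k in pa.blocks:
                assert np.array_equal(pa.blocks[k], pb.blocks[k])

    def test_identical_centers_give_uniform_weights(self, tiny_net, fast_train):
        """A symmetric federation must receive uniform fair weights."""
        cfg = GeneratorConfig(
            n_centers=1, per_center_n=(40,), prevalence=(0.75,),
            heterogeneity_shift=(0.0,), clone_fraction=(0.2,), seed=31,
        )
        base = generate_federation(cfg)[0]
        clones = []
        for cid in ("A", "B", "C"):
            imgs = [
                type(im)(
                    id=im.id.replace("A", cid, 1), center_id=cid, pixels=im.pixels,
                    label=im.label, is_planted_clone=im.is_planted_clone,
                    parent_id=im.parent_id.replace("A", cid, 1) if im.parent_id else None,
                )
                for im in base.images
            ]
            clones.append(type(base)(
                cid, imgs,
                {i.replace("A", cid, 1) for i in base.train_ids},
                {i.replace("A", cid, 1) for i in base.test_ids},
            ))
        state = run_federated(
            clones,
            AlgoConfig(algorithm="fedcmc", rounds=2, use_mcdem=True, use_fair_aggregation=True),
            fast_train, prune_cfg=FAST_PRUNE, net=tiny_net, seed=9,
        )
        for rec in state.weight_history:
            assert np.allclose(rec.w, 1 / 3, atol=1e-6)
            assert abs(sum(rec.w) - 1.0) < 1e-9

    def test_weight_history_bookkeeping(self, tiny_net, mini_federation, fast_train):
        state = run_federated(
            mini_federation,
            AlgoConfig(algorithm="fedcmc", rounds=4, use_mcdem=True),
            fast_train, prune_cfg=FAST_PRUNE, net=tiny_net, seed=13,
        )
        assert len(state.weight_history) == 4
        for rec in state.weight_history:
            assert abs(sum(rec.w) - 1.0) < 1e-9
            assert abs(sum(rec.D) - 1.0) < 1e-9

    @pytest.mark.parametrize("algorithm", ["fedprox", "moon"])
    def test_baselines_run_and_stay_finite(self, algorithm, tiny_net, mini_federation, fast_train):
        state = run_federated(
            mini_federation,
            AlgoConfig(algorithm=algorithm, rounds=2),
            fast_train, net=tiny_net, seed=3,
        )
        assert state.params.check_finite()
        assert state.round == 2


class TestPersonalize:
    def _state(self, tiny_net, mini_federation, fast_train):
        return run_federated(
            mini_federation,
            AlgoConfig(algorithm="fedcmc", rounds=2, use_mcdem=True),
            fast_train, prune_cfg=FAST_PRUNE, net=tiny_net, seed=19,
        )

    def test_zero_epochs_returns_global(self, tiny_net, mini_federation, fast_train):
        state = self._state(tiny_net, mini_federation, fast_train)
        tuned = personalize(state, mini_federation, fast_train, 0, net=tiny_net)
        for p in tuned.values():
            assert p.allclose(state.params, atol=0.0)

    def test_fine_tuning_descends_on_core_and_diverges_between_centers(
        self, tiny_net, mini_federation, fast_train
    ):
        from fedcmc.network import focal_loss

        state = self._state(tiny_net, mini_federation, fast_train)
        tuned = personalize(state, mini_federation, fast_train, 2, net=tiny_net)
        parts = {p.center_id: p for p in state.partitions}
        descended = 0
        for ds in mini_federation:
            X, y, _ = ds.arrays(sorted(parts[ds.center_id].core))
            before = focal_loss(tiny_net.predict_proba(state.params, X), y, 0.5, 2.0)
            after = focal_loss(tiny_net.predict_proba(tuned[ds.center_id], X), y, 0.5, 2.0)
            descended += after <= before
        assert descended >= 2  # descent on the tuning objective (allow one tie)
        ids = [ds.center_id for ds in mini_federation]
        assert not tuned[ids[0]].allclose(tuned[ids[1]], atol=1e-12)
        # global model untouched
        assert state.params.check_finite()
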