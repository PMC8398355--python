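"""RBM and DBN tests against enumeration oracles and toy benchmarks."""

from itertools import product

import numpy as np
import pytest

from semgfusion.dbn import (
    DBNConfig,
    RBM,
    cd_update,
    exact_loglik,
    fc_baseline,
    finetune,
    pretrain,
    reconstruction_error,
    sample_h_given_v,
)


def small_rbm(nv=3, nh=2, seed=0, scale=0.5):
    rng = np.random.default_rng(seed)
    return RBM(
        weights=rng.normal(0, scale, (nv, nh)),
        vbias=rng.normal(0, scale, nv),
        hbias=rng.normal(0, scale, nh),
    )


def enumerate_loglik(rbm, v):
    """Independent oracle: sum Boltzmann weights over all (v, h) states."""
    def weight(vv, hh):
        vv, hh = np.asarray(vv, float), np.asarray(hh, float)
        return np.exp(vv @ rbm.weights @ hh + vv @ rbm.vbias + hh @ rbm.hbias)

    z = sum(
        weight(vv, hh)
        for vv in product([0, 1], repeat=rbm.n_visible)
        for hh in product([0, 1], repeat=rbm.n_hidden)
    )
    num = sum(weight(v, hh) for hh in product([0, 1], repeat=rbm.n_hidden))
    return np.log(num / z)


class TestSampleHGivenV:
    def test_zero_parameters_give_half(self):
        rbm = RBM(np.zeros((4, 3)), np.zeros(4), np.zeros(3))
        p, _ = sample_h_given_v(rbm, np.array([1.0, 0.0, 1.0, 1.0]), rng=0)
        np.testing.assert_array_equal(p, 0.5)

    def test_large_bias_saturates(self):
        rbm = RBM(np.zeros((2, 1)), np.zeros(2), np.array([50.0]))
        p, s = sample_h_given_v(rbm, np.zeros(2), rng=0)
        assert abs(p[0, 0] - 1.0) < 1e-10
        assert s[0, 0] == 1.0

    def test_matches_affine_logistic_oracle(self):
        rbm = small_rbm()
        v = np.array([1.0, 0.0, 1.0])
        p, _ = sample_h_given_v(rbm, v, rng=0)
        expected = 1 / (1 + np.exp(-(v @ rbm.weights + rbm.hbias)))
        np.testing.assert_allclose(p[0], expected, atol=1e-12)

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            sample_h_given_v(small_rbm(), np.zeros(5))

    def test_conditional_independence(self):
        """p(h_j | v) is the per-unit logistic, independent of other units."""
        rbm = small_rbm(nv=4, nh=3, seed=1)
        v = np.array([0.0, 1.0, 1.0, 0.0])
        p, _ = sample_h_given_v(rbm, v, rng=0)
        for j in range(3):
            pj = 1 / (1 + np.exp(-(v @ rbm.weights[:, j] + rbm.hbias[j])))
            assert abs(p[0, j] - pj) < 1e-12


class TestCDUpdate:
    def test_zero_lr_leaves_parameters(self):
        rbm = small_rbm()
        w0 = rbm.weights.copy()
        cd_update(rbm, np.array([[1.0, 0.0, 1.0]]), k=1, lr=0.0, rng=0)
        np.testing.assert_array_equal(rbm.weights, w0)

    def test_duplicated_batch_same_update(self):
        """Averaging: duplicating the batch row leaves the update unchanged."""
        v = np.array([[1.0, 0.0, 1.0]])
        r1, r2 = small_rbm(), small_rbm()
        cd_update(r1, v, k=1, lr=0.1, rng=np.random.default_rng(7))
        cd_update(r2, np.vstack([v, v]), k=1, lr=0.1, rng=np.random.default_rng(7))
        np.testing.assert_allclose(r1.weights, r2.weights, atol=1e-12)
        np.testing.assert_allclose(r1.vbias, r2.vbias, atol=1e-12)
        np.testing.assert_allclose(r1.hbias, r2.hbias, atol=1e-12)

    def test_point_mass_likelihood_increases(self):
        """200 CD-1 steps raise the enumerated log-likelihood of the data."""
        rng = np.random.default_rng(0)
        rbm = RBM.initialize(3, 2, rng=rng)
        v = np.array([[1.0, 0.0, 1.0]])
        before = exact_loglik(rbm, v)
        for _ in range(200):
            cd_update(rbm, v, k=1, lr=0.1, rng=rng)
        assert exact_loglik(rbm, v) > before

    def test_model_distributed_data_is_near_stationary(self):
        """Averaged CD-1 updates vanish when data come from the model itself."""
        rbm = small_rbm(nv=3, nh=2, seed=3)
        all_v = np.array(list(product([0.0, 1.0], repeat=3)))
        logp = np.array([enumerate_loglik(rbm, v) for v in all_v])
        p = np.exp(logp)
        p /= p.sum()
        rng = np.random.default_rng(0)
        data = all_v[rng.choice(len(all_v), size=4000, p=p)]
        ref = small_rbm(nv=3, nh=2, seed=3)
        drift = np.zeros_like(ref.weights)
        for start in range(0, 4000, 50):
            probe = small_rbm(nv=3, nh=2, seed=3)
            cd_update(probe, data[start : start + 50], k=3, lr=1.0, rng=rng)
            drift += probe.weights - ref.weights
        drift /= 80
        assert np.abs(drift).max() < 0.05


class TestExactLoglik:
    def test_zero_parameter_rbm_is_uniform(self):
        rbm = RBM(np.zeros((4, 3)), np.zeros(4), np.zeros(3))
        v = np.array([[1.0, 0.0, 1.0, 0.0]])
        assert abs(exact_loglik(rbm, v) + 4 * np.log(2)) < 1e-12

    def test_probabilities_normalize(self):
        rbm = small_rbm(seed=5)
        total = sum(
            np.exp(exact_loglik(rbm, np.array(v, dtype=float)[None]))
            for v in product([0, 1], repeat=3)
        )
        assert abs(total - 1.0) < 1e-9

    def test_matches_independent_enumeration(self):
        rbm = small_rbm(nv=4, nh=3, seed=9)
        for v in ([1, 0, 1, 1], [0, 0, 0, 0], [1, 1, 1, 1]):
            v = np.array(v, dtype=float)
            assert abs(exact_loglik(rbm, v[None]) - enumerate_loglik(rbm, v)) < 1e-9

    def test_refuses_large_rbm(self):
        with pytest.raises(ValueError):
            exact_loglik(RBM.initialize(15, 10), np.zeros((1, 15)))

    def test_refuses_gaussian_visibles(self):
        with pytest.raises(ValueError):
            exact_loglik(RBM.initialize(3, 2, visible="gaussian"), np.zeros((1, 3)))


def test_exact_gradient_ascent_is_monotone():
    """Gradient ascent on the enumerated likelihood never decreases it."""
    rbm = small_rbm(nv=3, nh=2, seed=11)
    data = np.array([[1.0, 0.0, 1.0], [1.0, 1.0, 0.0]])
    all_v = np.array(list(product([0.0, 1.0], repeat=3)))

    def exact_gradient(rbm):
        # model expectation by enumeration, data expectation in closed form
        logp = np.array([enumerate_loglik(rbm, v) for v in all_v])
        p = np.exp(logp)
        ph_data = 1 / (1 + np.exp(-(data @ rbm.weights + rbm.hbias)))
        ph_all = 1 / (1 + np.exp(-(all_v @ rbm.weights + rbm.hbias)))
        pos = data.T @ ph_data / len(data)
        neg = (all_v * p[:, None]).T @ ph_all
        return pos - neg

    lls = [exact_loglik(rbm, data)]
    for _ in range(50):
        rbm.weights += 0.2 * exact_gradient(rbm)
        lls.append(exact_loglik(rbm, data))
    assert all(b >= a - 1e-12 for a, b in zip(lls, lls[1:]))
    assert lls[-1] > lls[0]


@pytest.fixture
def toy_data():
    rng = np.random.default_rng(0)
    X = rng.normal(size=(90, 10))
    y = np.repeat([1, 2, 3], 30)
    X[:30, 0] += 4
    X[30:60, 1] += 4
    X[60:, 2] += 4
    Xs = (X - X.mean(axis=0)) / X.std(axis=0)
    return Xs, y


TOY_CFG = DBNConfig(layer_sizes=(10, 8, 6), n_classes=3, finetune_epochs=100,
                    finetune_lr=1e-2, pretrain_epochs=10, seed=0)


class TestPretrain:
    def test_stack_shapes(self):
        cfg = DBNConfig(layer_sizes=(8, 4, 3), n_classes=2, pretrain_epochs=1,
                        gaussian_visible=False, seed=0)
        data = (np.random.default_rng(0).random((20, 8)) > 0.5).astype(float)
        stack = pretrain(cfg, data)
        assert [(r.n_visible, r.n_hidden) for r in stack] == [(8, 4), (4, 3)]
        assert stack[0].visible == "bernoulli"

    def test_first_layer_gaussian_by_default(self, toy_data):
        stack = pretrain(TOY_CFG, toy_data[0])
        assert stack[0].visible == "gaussian"
        assert stack[1].visible == "bernoulli"

    def test_reconstruction_error_decreases(self):
        """More CD epochs reduce layer-1 reconstruction error on structured data."""
        rng = np.random.default_rng(1)
        proto = (rng.random((4, 12)) > 0.5).astype(float)
        data = proto[rng.integers(0, 4, 200)]
        flip = rng.random(data.shape) < 0.05
        data = np.abs(data - flip)
        cfg_short = DBNConfig(layer_sizes=(12, 6), n_classes=2, pretrain_epochs=1,
                              pretrain_lr=0.05, gaussian_visible=False, seed=0)
        cfg_long = DBNConfig(layer_sizes=(12, 6), n_classes=2, pretrain_epochs=30,
                             pretrain_lr=0.05, gaussian_visible=False, seed=0)
        err1 = reconstruction_error(pretrain(cfg_short, data)[0], data)
        err2 = reconstruction_error(pretrain(cfg_long, data)[0], data)
        assert err2 < err1

    def test_deterministic(self, toy_data):
        s1 = pretrain(TOY_CFG, toy_data[0])
        s2 = pretrain(TOY_CFG, toy_data[0])
        for a, b in zip(s1, s2):
            np.testing.assert_array_equal(a.weights, b.weights)

    def test_dimension_mismatch(self, toy_data):
        with pytest.raises(ValueError):
            pretrain(DBNConfig(layer_sizes=(7, 4), n_classes=3), toy_data[0])


class TestFinetune:
    def test_posteriors_sum_to_one(self, toy_data):
        X, y = toy_data
        stack = pretrain(TOY_CFG, X)
        clf = finetune(stack, X, y, TOY_CFG)
        proba = clf.predict_proba(X, scaled=True)
        np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-6)

    def test_separable_toy_reaches_95(self, toy_data):
        X, y = toy_data
        stack = pretrain(TOY_CFG, X)
        clf = finetune(stack, X, y, TOY_CFG)
        assert np.mean(clf.predict(X, scaled=True) == y) >= 0.95

    def test_zero_lr_keeps_pretrained_weights(self, toy_data):
        X, y = toy_data
        cfg = DBNConfig(layer_sizes=(10, 8, 6), n_classes=3, finetune_epochs=1,
                        finetune_lr=0.0, pretrain_epochs=2, seed=0)
        stack = pretrain(cfg, X)
        clf = finetune(stack, X, y, cfg)
        np.testing.assert_array_equal(clf.net.layers[0].weight.value, stack[0].weights)

    def test_training_loss_decreases(self, toy_data):
        X, y = toy_data
        stack = pretrain(TOY_CFG, X)
        clf = finetune(stack, X, y, TOY_CFG)
        assert clf.history[-1] < clf.history[0]

    def test_label_out_of_range(self, toy_data):
        X, y = toy_data
        stack = pretrain(TOY_CFG, X)
        with pytest.raises(ValueError):
            finetune(stack, X, np.full_like(y, 9), TOY_CFG)


def test_joint_finetuning_updates_extractor():
    """With an extractor attached, fine-tuning changes its conv weights too."""
    from semgfusion.mffn import MFFNConfig, build_mffn, shape_plan

    cfg_m = MFFNConfig(input_size=16, block_sizes=(1, 1), growth_rate=2,
                       stem_filters=4, seed=0)
    model = build_mffn(cfg_m)
    rng = np.random.default_rng(0)
    images = rng.random((6, 16, 16, 3))
    y = np.array([1, 2, 1, 2, 1, 2])
    flat = shape_plan(cfg_m).flatten_length
    cfg = DBNConfig(layer_sizes=(flat, 8), n_classes=2, pretrain_epochs=1,
                    finetune_epochs=2, seed=0)
    model.eval()
    out = model.forward(np.transpose(images, (0, 3, 1, 2)))
    X = out.reshape(6, -1)
    stack = pretrain(cfg, X)
    w_before = model.stem.layers[0].weight.value.copy()
    clf = finetune(stack, X, y, cfg, extractor=model, images=images)
    assert not np.array_equal(model.stem.layers[0].weight.value, w_before)
    assert clf.predict_proba(
        model.forward(np.transpose(images, (0, 3, 1, 2))).reshape(6, -1),
        scaled=True,
    ).shape == (6, 2)


class TestFCBaseline:
    def test_separable_toy_reaches_95(self, toy_data):
        X, y = toy_data
        clf = fc_baseline(X, y, TOY_CFG)
        assert np.mean(clf.predict(X, scaled=True) == y) >= 0.95

    def test_posteriors_sum_to_one(self, toy_data):
        X, y = toy_data
        clf = fc_baseline(X, y, TOY_CFG)
        np.testing.assert_allclose(
            clf.predict_proba(X, scaled=True).sum(axis=1), 1.0, atol=1e-6
        )
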