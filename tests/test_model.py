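"""Network mechanics: activations, loss, schedule, optimizer, gradients."""

import numpy as np
import pytest

from cfcnn.errors import ConfigError, DomainError
from cfcnn.model import (
    CFCNN,
    ModelConfig,
    OptimizerState,
    PReLU,
    TrainConfig,
    build_model,
    load_checkpoint,
    loss_fn,
    lr_schedule,
    save_checkpoint,
    sgd_step,
    softmax,
    train,
    train_step,
)


@pytest.fixture(scope="module")
def tiny_model():
    return build_model(ModelConfig.tiny(), seed=11)


@pytest.fixture(scope="module")
def small_phantom():
    """A compact phantom keeps per-epoch validation segmentation cheap."""
    from cfcnn.phantoms import PhantomConfig, generate_phantom

    return generate_phantom(
        PhantomConfig(radius_vox=4.5, shape=(14, 40, 40), center=(7, 20, 20), seed=6)
    )


@pytest.fixture(scope="module")
def random_pair(rng):
    x3 = np.random.default_rng(21).normal(size=(4, 3, 35, 35))
    x2 = np.random.default_rng(22).normal(size=(4, 2, 35, 35))
    return x3, x2


class TestActivations:
    def test_softmax_rows_sum_to_one(self, rng):
        p = softmax(rng.normal(size=(50, 2)) * 10)
        assert np.abs(p.sum(axis=1) - 1).max() < 1e-6
        assert (p >= 0).all()

    def test_prelu_zero_slope_is_relu(self, rng):
        x = rng.normal(size=(5, 4, 6, 6))
        layer = PReLU(4, init=0.0)
        assert np.array_equal(layer.forward(x, False), np.maximum(x, 0))

    def test_prelu_unit_slope_is_identity(self, rng):
        x = rng.normal(size=(5, 4, 6, 6))
        layer = PReLU(4, init=1.0)
        assert np.array_equal(layer.forward(x, False), x)


class TestLoss:
    def test_perfect_prediction_near_zero(self):
        y = np.array([1, 0, 1])
        assert loss_fn(np.array([1.0, 0.0, 1.0]), y) <= 1e-6

    def test_half_probability_is_ln2(self):
        assert loss_fn(np.array([0.5]), np.array([1])) == pytest.approx(np.log(2))

    def test_regularizer_only(self, rng):
        weights = {"a": rng.normal(size=(3, 3)), "b": rng.normal(size=5)}
        lam = 0.01
        expected = lam * (np.abs(weights["a"]).sum() + np.abs(weights["b"]).sum())
        got = loss_fn(np.array([1.0]), np.array([1]), weights, lam)
        assert got == pytest.approx(expected, abs=1e-6)

    def test_bad_label_rejected(self):
        with pytest.raises(DomainError):
            loss_fn(np.array([0.5]), np.array([2]))


class TestSchedule:
    def test_initial_rate(self):
        assert lr_schedule(0, TrainConfig()) == pytest.approx(6e-5)

    def test_hand_evaluated_decay(self):
        cfg = TrainConfig()  # gamma 1e-4, power 0.75
        assert lr_schedule(10_000, cfg) == pytest.approx(6e-5 * 2 ** (-0.75))

    def test_strictly_decreasing(self):
        cfg = TrainConfig()
        ts = np.unique(np.geomspace(1, 1_000_000, 200).astype(int))
        rates = [lr_schedule(int(t), cfg) for t in [0, *ts]]
        assert all(a > b for a, b in zip(rates, rates[1:]))


class TestSgdStep:
    def test_momentum_free_is_plain_descent(self):
        w = {"w": np.array([1.0])}
        g = {"w": np.array([2.0])}
        cfg = TrainConfig(base_lr=0.1, gamma=0.0, momentum=0.0)
        sgd_step(w, g, OptimizerState(), cfg)
        assert w["w"][0] == pytest.approx(1.0 - 0.1 * 2.0)

    def test_two_step_hand_recursion(self):
        """V1 = -0.1, w1 = 0.9; V2 = 0.9*(-0.1) - 0.1 = -0.19, w2 = 0.71."""
        w = {"w": np.array([1.0])}
        cfg = TrainConfig(base_lr=0.1, gamma=0.0, momentum=0.9)
        state = OptimizerState()
        sgd_step(w, {"w": np.array([1.0])}, state, cfg)
        assert w["w"][0] == pytest.approx(0.9)
        sgd_step(w, {"w": np.array([1.0])}, state, cfg)
        assert w["w"][0] == pytest.approx(0.71)
        assert state.iteration == 2

    def test_zero_gradient_is_noop(self):
        w = {"w": np.array([3.0, -2.0])}
        sgd_step(w, {"w": np.zeros(2)}, OptimizerState(), TrainConfig())
        assert np.array_equal(w["w"], [3.0, -2.0])

    def test_nonfinite_gradient_identified(self):
        with pytest.raises(FloatingPointError, match="w"):
            sgd_step(
                {"w": np.array([1.0])},
                {"w": np.array([np.nan])},
                OptimizerState(),
                TrainConfig(),
            )


class TestBuildModel:
    def test_forward_probabilities_normalised(self, tiny_model, random_pair):
        p = tiny_model.predict_proba(*random_pair)
        assert p.shape == (4, 2)
        assert np.abs(p.sum(axis=1) - 1).max() < 1e-6

    def test_same_seed_same_weights(self, random_pair):
        a = build_model(ModelConfig.tiny(), seed=3)
        b = build_model(ModelConfig.tiny(), seed=3)
        for k, v in a.named_params().items():
            assert np.array_equal(v, b.named_params()[k])

    def test_parameter_count_matches_shape_arithmetic(self, tiny_model):
        """Hand-computed parameter total for the tiny configuration."""
        k = 3

        def conv(cin, cout):
            return cout * cin * k * k + cout  # kernels + biases

        def bn_prelu(c):
            return 2 * c + c  # gamma, beta + PReLU slopes

        def branch(cin):
            total = 0
            for cinb, cout in [(cin, 4), (4, 4), (4, 8), (8, 8), (8, 12), (12, 12)]:
                total += conv(cinb, cout) + bn_prelu(cout)
            total += 12 * 9 * 9 * 32 + 32  # FC to 32 on the 9x9x12 map
            total += 32  # FC PReLU slopes
            return total

        head = (64 * 16 + 16) + 16 + (16 * 2 + 2)
        assert tiny_model.n_parameters() == branch(3) + branch(2) + head

    def test_too_small_input_rejected(self):
        import dataclasses

        with pytest.raises(ConfigError):
            build_model(dataclasses.replace(ModelConfig.tiny(), input_size=1))


class TestPoolingAblation:
    def test_uniform_variant_same_parameter_count(self, tiny_model, random_pair):
        mp = build_model(ModelConfig.tiny(pooling="uniform_max"), seed=11)
        assert mp.n_parameters() == tiny_model.n_parameters()

    def test_uniform_variant_pools_differently(self, random_pair):
        central = build_model(ModelConfig.tiny(), seed=11)
        uniform = build_model(ModelConfig.tiny(pooling="uniform_max"), seed=11)
        x3, x2 = random_pair
        assert not np.allclose(
            central.forward(x3, x2), uniform.forward(x3, x2)
        )


class TestGradients:
    def test_end_to_end_finite_difference(self):
        """Analytic gradients through conv, BN, PReLU, central pooling and
        the fused head agree with central differences."""
        cfg = ModelConfig.tiny(dtype="float64")
        model = build_model(cfg, seed=5)
        rng = np.random.default_rng(17)
        x3 = rng.normal(size=(4, 3, 35, 35))
        x2 = rng.normal(size=(4, 2, 35, 35))
        y = np.array([1, 0, 1, 0])
        lam = 1e-3

        def full_loss():
            probs = softmax(model.forward(x3, x2, training=True))
            return loss_fn(probs[:, 1], y, model.penalized_params(), lam)

        # analytic pass
        probs = softmax(model.forward(x3, x2, training=True))
        onehot = np.zeros_like(probs)
        onehot[np.arange(4), y] = 1.0
        model.backward((probs - onehot) / 4)
        model.accumulate_l1_grads(lam)
        grads = {k: v.copy() for k, v in model.named_grads().items()}

        params = model.named_params()
        rng_pick = np.random.default_rng(3)
        names = rng_pick.choice(sorted(params), size=10, replace=False)
        h = 1e-5
        checked = 0
        for name in names:
            arr = params[name]
            for _ in range(2):
                idx = tuple(rng_pick.integers(0, s) for s in arr.shape)
                orig = arr[idx]
                arr[idx] = orig + h
                lp = full_loss()
                arr[idx] = orig - h
                lm = full_loss()
                arr[idx] = orig
                fd = (lp - lm) / (2 * h)
                an = grads[name][idx]
                if max(abs(fd), abs(an)) < 1e-8:
                    # both zero within central-difference round-off
                    assert abs(fd - an) < 1e-8
                else:
                    denom = max(abs(fd), abs(an))
                    assert abs(fd - an) / denom < 1e-3, (name, idx, fd, an)
                checked += 1
        assert checked == 20


class TestPredictAndTrain:
    def test_predict_batch_matches_single(self, tiny_model, sphere_phantom):
        from cfcnn.patches import batch_patches

        pairs = batch_patches(
            sphere_phantom.volume, [(16, 32, 32), (16, 10, 10), (16, 32, 32)]
        )
        p = tiny_model.predict_batch(pairs)
        assert ((0 <= p) & (p <= 1)).all()
        assert p[0] == pytest.approx(p[2], abs=1e-6)  # duplicated patch
        single = tiny_model.predict_batch(pairs[:1])
        assert p[0] == pytest.approx(single[0], abs=1e-6)

    def _training_set(self, phantom, n=512):
        from cfcnn.patches import patch_arrays
        from cfcnn.sampling import build_weight_maps, sample_training_voxels

        maps = build_weight_maps(phantom.volume, phantom.mask)
        sset = sample_training_voxels(maps, fraction=0.4, seed=1)
        coords = sset.coords()[:n]
        labels = sset.labels()[:n]
        x3, x2 = patch_arrays(phantom.volume, coords)
        return x3, x2, labels

    def test_history_shape_and_determinism(self, small_phantom):
        x3, x2, y = self._training_set(small_phantom, n=256)
        cfg = TrainConfig(max_epochs=1, seed=4)
        m1 = build_model(ModelConfig.tiny(), seed=8)
        h1 = train(m1, (x3, x2, y), [small_phantom], cfg)
        assert len(h1["loss"]) == 1 and len(h1["val_dsc"]) == 1
        m2 = build_model(ModelConfig.tiny(), seed=8)
        h2 = train(m2, (x3, x2, y), [small_phantom], cfg)
        assert h1["loss"][0] == pytest.approx(h2["loss"][0], rel=1e-7)

    def test_loss_decreases_over_epochs(self, small_phantom):
        x3, x2, y = self._training_set(small_phantom, n=512)
        cfg = TrainConfig(max_epochs=5, seed=4)
        model = build_model(ModelConfig.tiny(), seed=8)
        hist = train(model, (x3, x2, y), [small_phantom], cfg)
        assert hist["loss"][4] < hist["loss"][0]

    def test_empty_training_set_rejected(self, sphere_phantom):
        model = build_model(ModelConfig.tiny(), seed=0)
        empty = (np.zeros((0, 3, 35, 35)), np.zeros((0, 2, 35, 35)), np.zeros(0, int))
        with pytest.raises(ConfigError):
            train(model, empty, [sphere_phantom], TrainConfig())


def test_checkpoint_round_trip(tmp_path, random_pair):
    model = build_model(ModelConfig.tiny(), seed=2)
    x3, x2 = random_pair
    before = model.predict_proba(x3, x2)
    save_checkpoint(model, tmp_path / "ck.npz", TrainConfig())
    restored = load_checkpoint(tmp_path / "ck.npz")
    assert np.allclose(restored.predict_proba(x3, x2), before, atol=1e-7)
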