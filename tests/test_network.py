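import math

import numpy as np
import pytest

from tmenet.hierarchy import MaskSet, build_masks, validate_spec
from tmenet.network import (
    ModelState,
    TrainConfig,
    TrainingError,
    fit,
    forward,
    gradients,
    init_model,
    load_model,
    loss,
    masked_update,
    save_model,
)
from .conftest import random_spec


def _random_model(rng, max_genes=20, n_out=1, use_biases=True, activation="tanh"):
    while True:
        spec = random_spec(rng, max_genes=max_genes)
        if not validate_spec(spec):
            break
    masks = build_masks(spec, n_out=n_out)
    model = init_model(masks, seed=int(rng.integers(1 << 30)),
                       use_biases=use_biases, activation=activation)
    # small random biases so bias gradients are exercised off the origin
    if use_biases:
        for b in model.biases:
            b[:] = rng.normal(0, 0.1, size=b.shape)
    return model


class TestLoss:
    def test_perfect_prediction_limits_to_zero(self):
        assert loss(np.array([1 - 1e-12]), np.array([1.0])) == pytest.approx(0.0, abs=1e-9)

    def test_uninformative_prediction_is_ln2(self):
        assert loss(np.array([0.5]), np.array([0.0])) == pytest.approx(math.log(2))

    def test_mean_reduction_by_hand(self):
        expected = -(math.log(0.9) + math.log(0.8)) / 2  # ~0.164252
        assert loss(np.array([0.9, 0.2]), np.array([1, 0])) == pytest.approx(expected)

    def test_out_of_range_probability_rejected(self):
        with pytest.raises(ValueError, match="strictly inside"):
            loss(np.array([1.0]), np.array([1.0]))

    def test_non_binary_labels_rejected(self):
        with pytest.raises(ValueError, match="binary"):
            loss(np.array([0.5]), np.array([2.0]))


class TestForward:
    def test_zero_weights_predict_half(self, toy_spec):
        model = init_model(build_masks(toy_spec), scheme="zeros")
        p = forward(model, np.random.default_rng(0).normal(size=(5, 4)))
        np.testing.assert_allclose(p, 0.5)

    def test_outputs_strictly_inside_unit_interval(self):
        rng = np.random.default_rng(1)
        model = _random_model(rng)
        p = forward(model, rng.normal(size=(20, model.n_genes)) * 50)
        assert np.all(p > 0) and np.all(p < 1)

    def test_gene_dimension_mismatch_names_counts(self, toy_spec):
        model = init_model(build_masks(toy_spec))
        with pytest.raises(ValueError, match="3.*4|4.*3"):
            forward(model, np.zeros((2, 3)))

    def test_hand_composed_chain(self):
        """1-gene -> 1-component -> 1-cell chain with identity activation."""
        masks = MaskSet(
            gene_component=np.ones((1, 1)), component_cell=np.ones((1, 1)),
            cell_role=np.array([[1.0, 0.0]]), role_output=np.ones((2, 1)),
            genes=("g",), components=("c",), cells=("cell",),
        )
        model = init_model(masks, scheme="zeros", use_biases=True,
                           activation="identity")
        model.weights[0][:] = 2.0
        model.weights[1][:] = 0.5
        model.weights[2][:] = np.array([[3.0, 0.0]])  # masked edge stays 0
        model.weights[3][:] = np.array([[0.1], [7.0]])
        model.biases[3][:] = 0.25
        # x=1: gene 1 -> comp 2 -> cell 1 -> role (3, 0) -> out 0.3+0+0.25
        x = np.array([[1.0]])
        z = 1.0 * 2.0 * 0.5 * 3.0 * 0.1 + 0.25
        assert forward(model, x)[0] == pytest.approx(1 / (1 + math.exp(-z)))

    def test_masked_equals_dense_with_zeroed_inactive_weights(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            model = _random_model(rng)
            dense_masks = MaskSet(
                *(np.ones_like(m) for m in model.masks.all_masks()),
                genes=model.masks.genes, components=model.masks.components,
                cells=model.masks.cells, roles=model.masks.roles)
            dense = ModelState(weights=[w.copy() for w in model.weights],
                               biases=[b.copy() for b in model.biases],
                               masks=dense_masks, activation=model.activation)
            X = rng.normal(size=(8, model.n_genes))
            np.testing.assert_array_equal(forward(model, X), forward(dense, X))


class TestGradients:
    def _finite_difference(self, model, X, y, arr, eps=1e-6):
        g = np.zeros_like(arr)
        it = np.nditer(arr, flags=["multi_index"])
        for _ in it:
            i = it.multi_index
            orig = arr[i]
            arr[i] = orig + eps
            lp = loss(forward(model, X), y)
            arr[i] = orig - eps
            lm = loss(forward(model, X), y)
            arr[i] = orig
            g[i] = (lp - lm) / (2 * eps)
        return g

    @pytest.mark.parametrize("activation", ["tanh", "relu", "identity"])
    @pytest.mark.parametrize("n_out", [1, 2])
    def test_matches_central_differences(self, activation, n_out):
        """Analytic backprop vs the finite-difference oracle, 1e-5 relative.

        Over 100+ random (model, batch) draws across the parametrization.
        """
        rng = np.random.default_rng(hash((activation, n_out)) % (1 << 31))
        n_checked = 0
        while n_checked < 20:
            model = _random_model(rng, activation=activation, n_out=n_out)
            if activation == "relu":
                # keep away from the kink where the derivative is undefined
                for w in model.weights:
                    w += 0.05 * np.sign(w)
            X = rng.normal(size=(6, model.n_genes))
            y = rng.integers(0, 2, size=6).astype(float)
            wg, bg = gradients(model, X, y)
            arrays = list(zip(model.weights, wg)) + list(zip(model.biases, bg))
            for arr, analytic in arrays:
                fd = self._finite_difference(model, X, y, arr)
                np.testing.assert_allclose(analytic, fd, rtol=1e-5, atol=1e-8)
            n_checked += 1

    def test_dense_equivalence_on_active_edges(self):
        """Masked model and dense-with-zeroed-weights twin agree on the
        gradients of every active edge."""
        rng = np.random.default_rng(9)
        for _ in range(10):
            model = _random_model(rng)
            dense_masks = MaskSet(
                *(np.ones_like(m) for m in model.masks.all_masks()),
                genes=model.masks.genes, components=model.masks.components,
                cells=model.masks.cells, roles=model.masks.roles)
            dense = ModelState(weights=[w.copy() for w in model.weights],
                               biases=[b.copy() for b in model.biases],
                               masks=dense_masks, activation=model.activation)
            X = rng.normal(size=(7, model.n_genes))
            y = rng.integers(0, 2, size=7).astype(float)
            wg_m, _ = gradients(model, X, y)
            wg_d, _ = gradients(dense, X, y)
            for gm, gd, mask in zip(wg_m, wg_d, model.masks.all_masks()):
                np.testing.assert_allclose(gm * mask, gd * mask, rtol=1e-12)

    def test_duplicated_batch_leaves_gradient_unchanged(self):
        rng = np.random.default_rng(4)
        model = _random_model(rng)
        X = rng.normal(size=(3, model.n_genes))
        y = np.array([1.0, 0.0, 1.0])
        wg1, bg1 = gradients(model, X, y)
        wg2, bg2 = gradients(model, np.tile(X, (4, 1)), np.tile(y, 4))
        for a, b in zip(wg1 + bg1, wg2 + bg2):
            np.testing.assert_allclose(a, b, rtol=1e-12)


class TestMaskedUpdate:
    def test_hand_computed_elementwise_example(self):
        masks = MaskSet(np.array([[1.0, 0.0]]), np.ones((2, 1)),
                        np.ones((1, 2)), np.ones((2, 1)),
                        genes=("g",), components=("c1", "c2"), cells=("cell",))
        model = init_model(masks, scheme="zeros", use_biases=False)
        model.weights[0][:] = [[0.5, 0.2]]
        grads = ([np.array([[0.1, 0.3]])] + [np.zeros_like(w) for w in model.weights[1:]],
                 None)
        out = masked_update(model, grads, eta=0.1)
        np.testing.assert_allclose(out.weights[0], [[0.49, 0.0]])

    def test_all_zero_masks_zero_the_weights(self):
        masks = MaskSet(np.zeros((2, 2)), np.zeros((2, 2)), np.zeros((2, 2)),
                        np.zeros((2, 1)), genes=("a", "b"),
                        components=("c", "d"), cells=("e", "f"))
        model = init_model(masks, scheme="zeros", use_biases=False)
        for w in model.weights:
            w += np.random.default_rng(0).normal(size=w.shape)  # violate on purpose
        grads = ([np.ones_like(w) for w in model.weights], None)
        out = masked_update(model, grads, eta=5.0)
        for w in out.weights:
            np.testing.assert_array_equal(w, 0.0)

    def test_zero_learning_rate_is_identity_on_masked_weights(self, toy_spec):
        model = init_model(build_masks(toy_spec), seed=3)
        grads = gradients(model, np.random.default_rng(0).normal(size=(4, 4)),
                          np.array([1.0, 0, 1, 0]))
        out = masked_update(model, grads, eta=0.0)
        for a, b in zip(out.weights, model.weights):
            np.testing.assert_array_equal(a, b)


class TestFit:
    def test_separable_cohort_reaches_low_loss_and_full_train_auc(self, toy_spec):
        rng = np.random.default_rng(0)
        n = 60
        y = np.repeat([1.0, 0.0], n // 2)
        X = rng.normal(size=(n, 4))
        X[:, 0] = 3 * y + 0.3 * rng.normal(size=n)  # g1 fully separates
        model = init_model(build_masks(toy_spec), seed=0)
        trained, hist = fit(model, (X, y), TrainConfig(seed=0))
        assert hist[-1] < hist[0]
        p = forward(trained, X)
        pos, neg = p[y == 1], p[y == 0]
        assert (pos[:, None] > neg[None, :]).mean() == 1.0

    def test_loss_history_length_and_determinism(self, toy_spec):
        rng = np.random.default_rng(1)
        X, y = rng.normal(size=(20, 4)), rng.integers(0, 2, 20).astype(float)
        model = init_model(build_masks(toy_spec), seed=7)
        t1, h1 = fit(model, (X, y), TrainConfig(seed=7, epochs=50))
        t2, h2 = fit(model, (X, y), TrainConfig(seed=7, epochs=50))
        assert len(h1) == 50 and h1 == h2
        for a, b in zip(t1.weights, t2.weights):
            np.testing.assert_array_equal(a, b)

    def test_zero_learning_rate_gives_constant_history(self, toy_spec):
        rng = np.random.default_rng(2)
        X, y = rng.normal(size=(10, 4)), rng.integers(0, 2, 10).astype(float)
        model = init_model(build_masks(toy_spec), seed=1)
        _, hist = fit(model, (X, y), TrainConfig(seed=1, epochs=10, learning_rate=0.0))
        assert len(set(hist)) == 1

    def test_mask_preserved_after_every_step_of_long_fit(self, toy_spec):
        """weights (*) (1 - mask) stays exactly zero through 300 epochs."""
        rng = np.random.default_rng(3)
        X, y = rng.normal(size=(30, 4)), rng.integers(0, 2, 30).astype(float)
        model = init_model(build_masks(toy_spec), seed=2)
        trained, _ = fit(model, (X, y),
                         TrainConfig(seed=2, epochs=300, check_masks=True))
        assert trained.mask_violation() == 0.0

    def test_non_finite_loss_aborts_naming_epoch(self, toy_spec):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(10, 4))
        X[3, 1] = np.nan
        y = rng.integers(0, 2, 10).astype(float)
        model = init_model(build_masks(toy_spec), seed=0)
        with pytest.raises(TrainingError, match="epoch 0"):
            fit(model, (X, y), TrainConfig(seed=0, standardize=False, epochs=5))


class TestInit:
    def test_same_seed_identical_states(self, toy_spec):
        masks = build_masks(toy_spec)
        a, b = init_model(masks, seed=7), init_model(masks, seed=7)
        for wa, wb in zip(a.weights, b.weights):
            np.testing.assert_array_equal(wa, wb)

    def test_masked_zero_invariant_after_init(self):
        rng = np.random.default_rng(6)
        for _ in range(10):
            assert _random_model(rng).mask_violation() == 0.0

    def test_unknown_scheme_rejected(self, toy_spec):
        with pytest.raises(ValueError, match="scheme"):
            init_model(build_masks(toy_spec), scheme="orthogonal")


class TestCheckpoint:
    def test_round_trip_bit_exact(self, toy_spec, tmp_path):
        rng = np.random.default_rng(8)
        model = init_model(build_masks(toy_spec), seed=5)
        X, y = rng.normal(size=(20, 4)), rng.integers(0, 2, 20).astype(float)
        trained, _ = fit(model, (X, y), TrainConfig(seed=5, epochs=20))
        p = tmp_path / "model.json"
        save_model(trained, p)
        back = load_model(p)
        for a, b in zip(trained.weights, back.weights):
            np.testing.assert_array_equal(a, b)
        for a, b in zip(trained.biases, back.biases):
            np.testing.assert_array_equal(a, b)
        np.testing.assert_array_equal(trained.input_mean, back.input_mean)
        Xn = rng.normal(size=(5, 4))
        np.testing.assert_array_equal(forward(trained, Xn), forward(back, Xn))
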