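"""Forward pass, backprop training, metrics, cross-validation, H-scan."""

import numpy as np
import pytest

import extractopt as xo
from extractopt.network import _gradients, TrainingDivergedError

# Raw output signal of the published 4-7-1 weights at reference coded points,
# computed once with an independent plain-Python tanh loop and frozen.
GOLDEN_FORWARD = {
    (0.0, 0.0, 0.0, 0.0): 0.9255440798868254,
    (1.0, 1.0, -1.0, 1.0): 1.9193450679018427,
    (-0.1, -0.31, 2.0, 0.13): 1.9468873957164128,
    (0.722, 0.0, 2.0, -2.0): 1.774055280294947,
}


class TestForward:
    def test_zero_weights_give_zero(self):
        w = xo.NetworkWeights(np.zeros((3, 4)), np.zeros(3), np.zeros(3), 0.0)
        assert xo.forward(w, np.ones(4)) == 0.0
        assert xo.forward(w, np.array([2.0, -2.0, 1.0, 0.5])) == 0.0

    @pytest.mark.parametrize("point, expected", list(GOLDEN_FORWARD.items()))
    def test_published_weights_match_frozen_oracle(self, point, expected):
        w = xo.glycyrrhizic_network_weights()
        assert xo.forward(w, np.array(point)) == pytest.approx(expected, abs=1e-12)

    def test_response_scaling_endpoints(self):
        """With min-max scaling, a normalized output of +1 decodes to y_max."""
        w = xo.NetworkWeights(
            np.zeros((1, 4)), np.array([0.0]), np.array([0.0]), 20.0,
            output_activation="tanh", response_scaling=(290.93, 376.46),
        )
        # tanh(20) ~ 1 to machine precision
        assert xo.forward(w, np.zeros(4)) == pytest.approx(376.46)

    def test_batch_matches_single(self, rng):
        w = xo.NetworkWeights(
            rng.normal(size=(5, 4)), rng.normal(size=5), rng.normal(size=5), 0.3,
            response_scaling=(300.0, 380.0),
        )
        X = rng.uniform(-2, 2, size=(8, 4))
        batch = xo.forward(w, X)
        singles = [xo.forward(w, x) for x in X]
        assert np.allclose(batch, singles)

    def test_lipschitz_bound_on_normalized_scale(self, rng):
        """|f(x) - f(x')| <= ||W2||_1 * max_row ||W1 row||_1 * ||dx||_inf."""
        w = xo.NetworkWeights(
            rng.normal(size=(4, 4)), rng.normal(size=4), rng.normal(size=4), 0.1
        )
        bound_slope = np.abs(w.output_weights).sum() * np.abs(w.input_weights).sum(
            axis=1
        ).max()
        for _ in range(50):
            a = rng.uniform(-2, 2, 4)
            b = rng.uniform(-2, 2, 4)
            df = abs(xo.forward(w, a) - xo.forward(w, b))
            assert df <= bound_slope * np.abs(a - b).max() + 1e-12


class TestGradients:
    def test_matches_central_finite_differences(self, rng):
        """Exact backprop gradients vs numeric differentiation."""
        for out_act in ("linear", "tanh"):
            W1 = rng.normal(0, 0.7, size=(3, 4))
            b1 = rng.normal(size=3)
            W2 = rng.normal(size=3)
            b2 = float(rng.normal())
            X = rng.uniform(-2, 2, size=(12, 4))
            t = rng.uniform(-1, 1, size=12)

            def loss(W1, b1, W2, b2):
                hidden = np.tanh(X @ W1.T + b1)
                u = hidden @ W2 + b2
                out = np.tanh(u) if out_act == "tanh" else u
                return float(((out - t) ** 2).mean())

            _, g_W1, g_b1, g_W2, g_b2 = _gradients(W1, b1, W2, b2, X, t, out_act)
            eps = 1e-6

            def numeric(setter):
                plus = loss(*setter(+eps))
                minus = loss(*setter(-eps))
                return (plus - minus) / (2 * eps)

            for i in range(3):
                for j in range(4):
                    def bump(e, i=i, j=j):
                        W = W1.copy()
                        W[i, j] += e
                        return W, b1, W2, b2
                    assert numeric(bump) == pytest.approx(g_W1[i, j], rel=1e-6, abs=1e-9)
                def bump_b1(e, i=i):
                    b = b1.copy()
                    b[i] += e
                    return W1, b, W2, b2
                assert numeric(bump_b1) == pytest.approx(g_b1[i], rel=1e-6, abs=1e-9)
                def bump_w2(e, i=i):
                    W = W2.copy()
                    W[i] += e
                    return W1, b1, W, b2
                assert numeric(bump_w2) == pytest.approx(g_W2[i], rel=1e-6, abs=1e-9)
            assert numeric(lambda e: (W1, b1, W2, b2 + e)) == pytest.approx(
                g_b2, rel=1e-6, abs=1e-9
            )


class TestTrainBackprop:
    def test_bit_reproducible(self, study_data):
        cfg = xo.TrainingConfig(max_epochs=50, seed=7)
        _, h1 = xo.train_backprop(study_data, 3, cfg)
        _, h2 = xo.train_backprop(study_data, 3, cfg)
        assert h1 == h2

    def test_loss_non_increasing_small_step_linear_target(self, study_factors, rng):
        """On a linear response, full-batch descent with a small step is monotone."""
        design = xo.build_ccd(study_factors)
        y = 350 + 10 * design.coded[:, 0] - 5 * design.coded[:, 2]
        design = design.with_responses(y)
        cfg = xo.TrainingConfig(max_epochs=300, learning_rate=1e-3, seed=0)
        _, history = xo.train_backprop(design, 3, cfg)
        assert all(b <= a + 1e-12 for a, b in zip(history, history[1:]))

    def test_interpolation_reachable_on_study_data(self, study_data):
        """With 4 hidden neurons and 2000 epochs, at least one seed reaches a
        training correlation of 0.99 (a steeper step than the conservative
        default is needed for full-batch descent to approach interpolation)."""
        best_r = 0.0
        for seed in range(10):
            cfg = xo.TrainingConfig(max_epochs=2000, learning_rate=0.2, seed=seed)
            w, _ = xo.train_backprop(study_data, 4, cfg)
            m = xo.evaluate(xo.forward(w, study_data.coded), study_data.responses)
            best_r = max(best_r, m.r)
        assert best_r >= 0.99

    def test_constant_response_converges_to_constant(self, study_factors):
        design = xo.build_ccd(study_factors)
        design = design.with_responses([350.0] * len(design))
        cfg = xo.TrainingConfig(max_epochs=2000, learning_rate=0.1, seed=1)
        w, _ = xo.train_backprop(design, 2, cfg)
        pred = xo.forward(w, design.coded)
        assert np.max(np.abs(pred - 350.0)) < 1.0

    def test_divergence_detected(self, study_data):
        cfg = xo.TrainingConfig(max_epochs=2000, learning_rate=50.0, seed=0)
        with pytest.raises(TrainingDivergedError):
            xo.train_backprop(study_data, 6, cfg)


class TestEvaluate:
    def test_identical_vectors(self):
        m = xo.evaluate([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert (m.mae, m.r, m.r_squared) == (0.0, pytest.approx(1.0), pytest.approx(1.0))

    def test_constant_shift(self):
        m = xo.evaluate([2.0, 3.0, 4.0], [1.0, 2.0, 3.0])
        assert m.mae == pytest.approx(1.0)
        assert m.r == pytest.approx(1.0)

    def test_mae_is_maximum_not_mean(self):
        m = xo.evaluate([1.0, 2.0, 3.0], [1.0, 2.0, 5.0])
        assert m.mae == pytest.approx(2.0)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            xo.evaluate([1.0, 1.0], [1.0, 2.0])

    def test_r_squared_matches_anova_definition(self, study_data, full_fit):
        """Same formula as the response-surface R²: 1 - RSS/SS_total."""
        model, table = full_fit
        pred = model.predict(study_data.coded)
        m = xo.evaluate(pred, study_data.responses)
        assert m.r_squared == pytest.approx(table.r_squared)


class TestKFold:
    def test_study_layout(self):
        folds = xo.kfold_split(30, 10, seed=0)
        assert len(folds) == 10
        assert all(len(f) == 3 for f in folds)
        union = np.sort(np.concatenate(folds))
        assert np.array_equal(union, np.arange(30))

    def test_two_folds_of_two(self):
        folds = xo.kfold_split(4, 2, seed=3)
        assert sorted(len(f) for f in folds) == [2, 2]
        assert set(np.concatenate(folds)) == {0, 1, 2, 3}

    def test_seed_determinism(self):
        a = xo.kfold_split(30, 10, seed=9)
        b = xo.kfold_split(30, 10, seed=9)
        assert all(np.array_equal(x, y) for x, y in zip(a, b))

    def test_k_greater_than_n_rejected(self):
        with pytest.raises(ValueError):
            xo.kfold_split(3, 5, seed=0)


class TestScanHiddenNeurons:
    def test_report_columns_and_single_row(self, study_data):
        cfg = xo.TrainingConfig(max_epochs=100, seed=0)
        scan = xo.scan_hidden_neurons(study_data, 3, 3, cfg)
        assert list(scan.columns) == [
            "hidden", "mae_train", "mae_test", "r2_train", "r_train", "r_test", "error",
        ]
        assert len(scan) == 1 and scan.loc[0, "hidden"] == 3

    def test_selection_rule_on_published_scan(self):
        """Minimum test MAE with r_test tie-break picks 7 hidden neurons on
        the published hybrid scan metrics."""
        scan = xo.reference_hybrid_scan()
        assert xo.select_hidden_count(scan) == 7

    def test_capacity_recovery_on_synthetic_network_data(self, study_factors):
        """Data from a known 3-hidden-neuron network: the selection rule
        picks H >= 3 in at least 80% of seeded repeats."""
        gen = np.random.default_rng(7)
        truth = xo.NetworkWeights(
            gen.uniform(-2, 2, (3, 4)), gen.uniform(-1, 1, 3),
            gen.uniform(-1.5, 1.5, 3), 0.2, response_scaling=(300.0, 380.0),
        )
        hits = 0
        n_rep = 50
        for seed in range(n_rep):
            data, _ = xo.generate_network_dataset(
                xo.SyntheticSpec(
                    generator="network", true_weights=truth, noise_sd=1.0, seed=seed
                ),
                study_factors,
            )
            cfg = xo.TrainingConfig(max_epochs=800, learning_rate=0.2, seed=seed)
            scan = xo.scan_hidden_neurons(data, 1, 5, cfg, aggregate="mean")
            if xo.select_hidden_count(scan) >= 3:
                hits += 1
        assert hits / n_rep >= 0.8


def test_weights_json_roundtrip(tmp_path, rng):
    w = xo.NetworkWeights(
        rng.normal(size=(4, 4)), rng.normal(size=4), rng.normal(size=4), 0.25,
        output_activation="tanh", response_scaling=(290.93, 376.46),
    )
    path = tmp_path / "weights.json"
    w.to_json(path)
    again = xo.NetworkWeights.from_json(path)
    assert np.array_equal(again.input_weights, w.input_weights)
    assert again.response_scaling == w.response_scaling
    assert again.output_activation == "tanh"
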