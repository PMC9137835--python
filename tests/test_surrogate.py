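import json

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import approx_fprime

import larvopt as lv
from larvopt.catalog import design_space
from larvopt.encoding import aggregate_replicates, encode_design_matrix
from larvopt.surrogate import (
    ACTIVATIONS,
    TopologySearchConfig,
    _loss_grad,
    count_parameters,
    load_model,
    save_model,
    topology_search,
    train,
)
from conftest import toy_model


class TestParameterCount:
    @pytest.mark.parametrize(
        "dims,expected",
        [((8, 10, 6), 156), ((8, 10, 9), 189), ((8, 10, 5), 145), ((8, 7, 3), 87),
         ((1, 1, 1), 4)],
    )
    def test_closed_form(self, dims, expected):
        assert count_parameters(*dims) == expected

    def test_nonpositive_dimension_rejected(self):
        with pytest.raises(ValueError):
            count_parameters(8, 0, 3)

    @settings(derandomize=True, max_examples=50)
    @given(st.integers(1, 20), st.integers(1, 30))
    def test_matches_constructed_model(self, hidden, outputs):
        rng = np.random.default_rng(0)
        m = toy_model(
            rng.normal(size=(hidden, 8)), rng.normal(size=hidden),
            rng.normal(size=(outputs, hidden)), rng.normal(size=outputs),
            out_names=[f"o{j}" for j in range(outputs)],
        )
        assert m.parameter_count == (8 + 1) * hidden + (hidden + 1) * outputs


class TestGradients:
    @pytest.mark.parametrize("act", sorted(ACTIVATIONS))
    def test_analytic_gradient_matches_finite_differences(self, act):
        rng = np.random.default_rng(3)
        m, h, q, n = 4, 3, 2, 5
        x = rng.normal(size=(n, m)) * 0.5
        t = rng.normal(size=(n, q)) * 0.5
        theta = rng.normal(size=count_parameters(m, h, q)) * 0.3
        out_act = "identity" if act == "exponential" else act
        loss, grad = _loss_grad(theta, x, t, m, h, q, act, out_act)
        num = approx_fprime(
            theta, lambda th: _loss_grad(th, x, t, m, h, q, act, out_act)[0], 1e-6
        )
        np.testing.assert_allclose(grad, num, rtol=1e-4, atol=1e-5)


class TestTraining:
    def test_identity_net_matches_least_squares_oracle(self, noise_free_means):
        """With identity activations the surrogate is affine, so its
        predictions must match closed-form least squares on the one-hot
        design matrix."""
        model, rep = train(
            noise_free_means, "proximate", hidden=10,
            activations=("identity", "identity"), seed=0,
        )
        pts = design_space()
        x = np.hstack([encode_design_matrix(pts), np.ones((18, 1))])
        targets = noise_free_means[list(model.output_names)].to_numpy(float)
        beta, *_ = np.linalg.lstsq(x, targets, rcond=None)
        np.testing.assert_allclose(
            model.predict(pts).to_numpy(), x @ beta, rtol=1e-6, atol=1e-6
        )

    def test_noise_free_interpolation_regime(self, noise_free_means):
        for group in ("proximate", "fatty_acid"):
            _, rep = train(
                noise_free_means, group, hidden=10,
                activations=("identity", "identity"), seed=1,
            )
            assert rep.r2_overall >= 0.999

    def test_same_seed_reproduces_weights(self, noisy_mean_table):
        a, _ = train(noisy_mean_table, "mineral", hidden=6, seed=9)
        b, _ = train(noisy_mean_table, "mineral", hidden=6, seed=9)
        np.testing.assert_array_equal(a.input_to_hidden_weights, b.input_to_hidden_weights)
        np.testing.assert_array_equal(a.hidden_to_output_weights, b.hidden_to_output_weights)

    def test_constant_response_flagged_degenerate(self, noise_free_means):
        mt = noise_free_means.copy()
        mt["crude_ash"] = 4.0
        model, rep = train(mt, "proximate", hidden=10,
                           activations=("identity", "identity"), seed=0)
        assert np.isnan(rep.r2_per_output["crude_ash"])
        np.testing.assert_allclose(
            model.predict(design_space())["crude_ash"], 4.0, atol=1e-6
        )

    def test_too_few_conditions_rejected(self, noise_free_means):
        with pytest.raises(ValueError):
            train(noise_free_means.iloc[:3], "proximate")


class TestTopologySearch:
    def test_restricted_search_returns_hidden_10(self, noisy_mean_table):
        cfg = TopologySearchConfig(hidden_range=(10, 10), restarts=2,
                                   activations=("identity",), seed=0)
        model, rep = topology_search(noisy_mean_table, "amino_acid", cfg)
        assert model.hidden_size == 10
        assert rep.topology_label == "MLP 8-10-9"
        assert model.parameter_count == 189

    def test_selection_consistent_with_documented_tie_rules(self, noise_free_means):
        cfg = TopologySearchConfig(hidden_range=(7, 10), restarts=2,
                                   activations=("identity",), seed=3)
        model, rep = topology_search(noise_free_means, "fatty_acid", cfg)
        cands = rep.candidates_frame()
        tol = cfg.selection_tolerance
        best_q = (cands.val_sos / tol).astype(int).min()
        tied = cands[(cands.val_sos / tol).astype(int) == best_q]
        # winner must carry the smallest parameter count among tied scores
        min_hidden = tied.hidden.min()
        assert model.hidden_size == min_hidden

    def test_parsimony_selects_seven_hidden_for_fatty_acids(self, noise_free_means):
        cfg = TopologySearchConfig(hidden_range=(7, 12), restarts=2,
                                   activations=("identity",), seed=4)
        model, _ = topology_search(noise_free_means, "fatty_acid", cfg)
        assert model.hidden_size == 7
        assert model.parameter_count == 87

    def test_more_restarts_never_worse(self, noisy_mean_table):
        base = dict(hidden_range=(6, 6), activations=("tanh",), seed=11)
        _, r1 = topology_search(noisy_mean_table, "proximate",
                                TopologySearchConfig(restarts=1, **base))
        _, r8 = topology_search(noisy_mean_table, "proximate",
                                TopologySearchConfig(restarts=8, **base))
        assert r8.selection_score <= r1.selection_score + 1e-12

    def test_impossible_split_rejected(self, noise_free_means):
        with pytest.raises(ValueError, match="training conditions"):
            topology_search(
                noise_free_means.iloc[:4], "proximate",
                TopologySearchConfig(validation_fraction=0.5, test_fraction=0.25,
                                     restarts=1),
            )


class TestPrediction:
    def test_interpolating_model_reproduces_training_means(self, identity_models,
                                                           noise_free_means):
        model = identity_models["mineral"]
        pred = model.predict(design_space())
        obs = noise_free_means[list(model.output_names)].to_numpy(float)
        np.testing.assert_allclose(pred.to_numpy(), obs, rtol=5e-3)

    def test_batch_shape_and_columns(self, identity_models):
        pred = identity_models["proximate"].predict(design_space())
        assert pred.shape == (18, 6)
        assert list(pred.columns) == list(identity_models["proximate"].output_names)

    def test_zero_output_layer_predicts_inverse_scaled_zero(self):
        m = toy_model(np.ones((3, 8)), np.zeros(3), np.zeros((2, 3)), np.zeros(2),
                      in_names=list(lv.encoding.ENCODED_INPUT_NAMES),
                      out_names=["a", "b"])
        m.output_scaling = lv.MinMaxScaler(names=["a", "b"],
                                           mins=np.array([5.0, -1.0]),
                                           maxs=np.array([7.0, 1.0]))
        pred = m.predict(design_space()[:4])
        np.testing.assert_allclose(pred["a"], 5.0)
        np.testing.assert_allclose(pred["b"], -1.0)


class TestSerialization:
    def test_round_trip_predicts_identically(self, tanh_models, tmp_path):
        model = tanh_models["amino_acid"]
        path = tmp_path / "m.json"
        save_model(model, path)
        back = load_model(path)
        np.testing.assert_allclose(
            back.predict(design_space()).to_numpy(),
            model.predict(design_space()).to_numpy(),
            atol=1e-10,
        )

    def test_serialized_parameter_entries_match_count(self, identity_models, tmp_path):
        model = identity_models["proximate"]
        path = tmp_path / "m.json"
        save_model(model, path)
        doc = json.loads(path.read_text())
        w = doc["weights"]
        n = (
            sum(len(r) for r in w["input_to_hidden"])
            + len(w["hidden_biases"])
            + sum(len(r) for r in w["hidden_to_output"])
            + len(w["output_biases"])
        )
        assert n == model.parameter_count == 156

    def test_corrupted_file_rejected(self, identity_models, tmp_path):
        path = tmp_path / "m.json"
        save_model(identity_models["mineral"], path)
        path.write_text(path.read_text()[:200])
        with pytest.raises(ValueError):
            load_model(path)

    def test_version_mismatch_rejected(self, identity_models, tmp_path):
        path = tmp_path / "m.json"
        save_model(identity_models["mineral"], path)
        doc = json.loads(path.read_text())
        doc["version"] = 99
        path.write_text(json.dumps(doc))
        with pytest.raises(ValueError, match="version"):
            load_model(path)
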