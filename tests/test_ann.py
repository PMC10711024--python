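"""Feed-forward surrogate: transfer function, forward pass, training, I/O."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from shellopt import (
    AnnParameters,
    Scaler,
    TrainConfig,
    forward,
    load_params,
    load_surrogate,
    sample_surface_dataset,
    save_params,
    save_surrogate,
    select_architecture,
    tansig,
    train,
    train_committee,
)
from shellopt.reference import published_ann_parameters

finite_x = st.floats(-50, 50, allow_nan=False)


class TestTansig:
    @given(finite_x)
    def test_equals_hyperbolic_tangent(self, x):
        assert abs(tansig(x) - np.tanh(x)) < 1e-12

    @given(finite_x)
    def test_odd_symmetry_and_range(self, x):
        assert tansig(x) == pytest.approx(-tansig(-x), abs=1e-15)
        assert -1.0 <= tansig(x) <= 1.0

    def test_zero_maps_to_zero(self):
        assert tansig(0.0) == 0.0

    def test_saturates_without_overflow(self):
        assert tansig(1e4) == 1.0
        assert tansig(-1e4) == -1.0


class TestForward:
    def test_zero_weights_return_output_bias(self):
        p = AnnParameters(np.zeros((4, 3)), np.zeros(4), np.zeros((5, 4)), np.arange(5.0))
        out = forward(p, [0.3, -0.2, 0.9])
        assert np.array_equal(out, np.arange(5.0))

    def test_unit_weight_net_at_origin(self):
        p = AnnParameters(np.ones((2, 2)), np.zeros(2), np.ones((1, 2)), np.zeros(1))
        assert forward(p, [0.0, 0.0]) == pytest.approx(0.0, abs=1e-15)

    def test_reference_parameters_match_bruteforce_oracle(self):
        params = published_ann_parameters()
        rng = np.random.default_rng(7)
        X = rng.uniform(-1, 1, (100, 3))
        got = forward(params, X)
        expected = np.empty_like(got)
        for n, x in enumerate(X):
            hidden = [
                np.tanh(sum(params.W_ih[m, i] * x[i] for i in range(3)) + params.B_h[m])
                for m in range(4)
            ]
            for k in range(5):
                expected[n, k] = (
                    sum(params.W_ho[k, m] * hidden[m] for m in range(4)) + params.B_o[k]
                )
        assert np.abs(got - expected).max() < 1e-10

    def test_outputs_bounded_by_weight_norms(self):
        # hidden activations lie in (-1, 1), so |y_k| <= sum|W_ho[k]| + |b_k|
        params = published_ann_parameters()
        X = np.random.default_rng(1).uniform(-5, 5, (200, 3))
        out = forward(params, X)
        bound = np.abs(params.W_ho).sum(axis=1) + np.abs(params.B_o)
        assert np.all(np.abs(out) <= bound)

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            forward(published_ann_parameters(), [0.0, 0.0])

    def test_inconsistent_parameter_shapes_rejected(self):
        with pytest.raises(ValueError):
            AnnParameters(np.zeros((4, 3)), np.zeros(3), np.zeros((5, 4)), np.zeros(5))
        with pytest.raises(ValueError):
            AnnParameters(np.full((4, 3), np.nan), np.zeros(4), np.zeros((5, 4)), np.zeros(5))


class TestScaler:
    def test_round_trip(self):
        s = Scaler(lo=[10, 30, 10], hi=[30, 40, 30])
        x = np.array([[15.0, 33.0, 24.0], [10.0, 40.0, 30.0]])
        assert np.abs(s.descale(s.scale(x)) - x).max() < 1e-12

    def test_maps_range_to_unit_interval(self):
        s = Scaler(lo=[0.0], hi=[4.0])
        assert s.scale([0.0]) == -1.0 and s.scale([4.0]) == 1.0 and s.scale([2.0]) == 0.0

    def test_degenerate_range_rejected(self):
        with pytest.raises(ValueError):
            Scaler(lo=[1.0, 2.0], hi=[3.0, 2.0])


class TestTrain:
    def test_seeded_runs_are_bitwise_identical(self, noisy_dataset):
        cfg = TrainConfig(iterations=100, seed=3)
        a = train(noisy_dataset.design, cfg, n_hidden=3)
        b = train(noisy_dataset.design, cfg, n_hidden=3)
        for fa, fb in zip(
            (a.params.W_ih, a.params.B_h, a.params.W_ho, a.params.B_o),
            (b.params.W_ih, b.params.B_h, b.params.W_ho, b.params.B_o),
        ):
            assert np.array_equal(fa, fb)

    def test_zero_iterations_returns_initial_net_with_metrics(self, noisy_dataset):
        model = train(noisy_dataset.design, TrainConfig(iterations=0, seed=1), n_hidden=4)
        assert set(model.metrics) == {"train", "test", "validation"}
        assert model.metrics["train"]["n"] == 12

    def test_training_reduces_training_mse(self, noisy_dataset):
        cfg0 = TrainConfig(iterations=0, seed=8)
        cfg = TrainConfig(iterations=500, seed=8)
        before = train(noisy_dataset.design, cfg0, n_hidden=4)
        after = train(noisy_dataset.design, cfg, n_hidden=4)
        assert after.metrics["train"]["mse"] < before.metrics["train"]["mse"]

    def test_surrogate_capacity_on_smooth_target(self):
        # noiseless samples of the quadratic surfaces: 4 hidden units suffice
        data = sample_surface_dataset(200, noise_scale=0.0, seed=3)
        model = train(data, TrainConfig(iterations=2000, seed=5), n_hidden=4)
        assert model.validation_r2 > 0.95

    def test_teacher_student_recovers_input_output_map(self):
        rng = np.random.default_rng(12)
        teacher = AnnParameters(
            W_ih=rng.uniform(-1.5, 1.5, (4, 3)),
            B_h=rng.uniform(-0.5, 0.5, 4),
            W_ho=rng.uniform(-1.5, 1.5, (5, 4)),
            B_o=rng.uniform(-0.5, 0.5, 5),
        )
        import pandas as pd

        X = rng.uniform(10, 30, (400, 3))
        Xs = 2 * (X - 10) / 20 - 1
        Y = forward(teacher, Xs)
        frame = pd.DataFrame(X, columns=["time_min", "temp_C", "ratio"])
        from shellopt.design import RESPONSE_COLUMNS

        for k, name in enumerate(RESPONSE_COLUMNS):
            frame[name] = Y[:, k]
        # single gradient-descent runs can stall in local minima; as in the
        # study protocol, train several runs and keep the best validator
        cfg = TrainConfig(
            hidden_range=(4, 4), iterations=4000, runs_per_architecture=10, seed=2
        )
        model = select_architecture(frame, cfg)
        held = rng.uniform(10, 30, (300, 3))
        held_s = 2 * (held - 10) / 20 - 1
        target = forward(teacher, held_s)
        pred = model.predict(held)
        mse = np.mean((pred - target) ** 2)
        assert mse < 1e-3 * target.var()

    def test_degenerate_response_column_rejected(self, bbd):
        table = bbd.with_responses({"yield_pct": np.full(18, 3.0)})
        with pytest.raises(ValueError):
            train(table, TrainConfig(iterations=10, seed=0), n_hidden=2)


class TestSelectArchitecture:
    CFG = TrainConfig(hidden_range=(4, 4), iterations=200, runs_per_architecture=10, seed=6)

    def test_evaluates_runs_times_range_candidates(self, noisy_dataset):
        best = select_architecture(noisy_dataset.design, self.CFG)
        assert len(best.search_candidates) == 10

    def test_descriptor_and_winner_contract(self):
        data = sample_surface_dataset(120, noise_scale=0.0, seed=9)
        cfg = TrainConfig(hidden_range=(2, 6), iterations=500, runs_per_architecture=2, seed=1)
        best = select_architecture(data, cfg)
        n_in, n_hid, n_out = map(int, best.architecture.split("-"))
        assert (n_in, n_out) == (3, 5)
        assert 2 <= n_hid <= 6
        assert best.validation_r2 == max(r2 for _, r2, _ in best.search_candidates)

    def test_seeded_repeat_selects_identically(self, noisy_dataset):
        a = select_architecture(noisy_dataset.design, self.CFG)
        b = select_architecture(noisy_dataset.design, self.CFG)
        assert a.architecture == b.architecture
        assert np.array_equal(a.params.W_ih, b.params.W_ih)

    def test_committee_averages_members(self, noisy_dataset):
        committee = train_committee(noisy_dataset.design, self.CFG)
        assert len(committee.members) == 10
        x = np.array([[20.0, 35.0, 20.0]])
        mean = np.mean([m.predict(x) for m in committee.members], axis=0)
        assert np.allclose(committee.predict(x), mean)


class TestSerialization:
    def test_round_trip_exact(self, tmp_path):
        params = published_ann_parameters()
        save_params(params, tmp_path / "net.json")
        loaded = load_params(tmp_path / "net.json")
        assert np.array_equal(loaded.W_ih, params.W_ih)
        assert np.array_equal(loaded.B_h, params.B_h)
        assert np.array_equal(loaded.W_ho, params.W_ho)
        assert np.array_equal(loaded.B_o, params.B_o)

    def test_reference_fixture_layout(self):
        params = published_ann_parameters()
        assert params.architecture == "3-4-5"
        assert params.n_values() == 41
        assert np.array_equal(params.W_ih[0], [-7.2336, -1.0604, 4.7262])

    def test_malformed_file_rejected(self, tmp_path):
        p = tmp_path / "bad.json"
        p.write_text('{"W_ih": [[1, 2, 3]]}')
        with pytest.raises(ValueError):
            load_params(p)

    def test_surrogate_round_trip_predicts_identically(self, noisy_dataset, tmp_path):
        model = train(noisy_dataset.design, TrainConfig(iterations=50, seed=4), n_hidden=3)
        save_surrogate(model, tmp_path / "model.json")
        loaded = load_surrogate(tmp_path / "model.json")
        x = np.array([[15.0, 33.0, 24.0]])
        assert np.array_equal(loaded.predict(x), model.predict(x))
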