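"""Network architecture contract, the two-gate LSTM recurrence, loss, training."""

import numpy as np
import pytest

from ppgsas.nn import (ModelSpec, TrainConfig, bce_loss, bce_loss_grad,
                       build_model, paper_lstm_step, predict, train)
from ppgsas.nn.network import SegmentNet, bce_logits_loss_and_grad


def closed_form_param_count(spec: ModelSpec) -> int:
    """Independent parameter arithmetic: conv in*out*k + out per layer,
    standard LSTM 4*(in+hid+1)*hid, two-gate variant 3*(in+hid+1)*hid,
    dense in*out + out."""
    total = 0
    in_ch = 1
    for n_layers, out_ch in spec.conv_groups:
        for _ in range(n_layers):
            total += in_ch * out_ch * spec.kernel_size + out_ch
            in_ch = out_ch
    gates = 4 if spec.lstm_variant == "standard" else 3
    feat = in_ch
    for _ in range(spec.lstm_layers):
        total += gates * (feat + spec.lstm_hidden + 1) * spec.lstm_hidden
        feat = spec.lstm_hidden
    head_in = spec.lstm_hidden if spec.lstm_layers > 0 else in_ch
    total += head_in * spec.fc_sizes[0] + spec.fc_sizes[0]
    total += spec.fc_sizes[0] * spec.fc_sizes[1] + spec.fc_sizes[1]
    return total


class TestArchitectureContract:
    def test_default_spec_matches_described_structure(self):
        spec = ModelSpec()
        assert sum(g[0] for g in spec.conv_groups) == 8
        assert [g[1] for g in spec.conv_groups] == [32, 64, 128, 256]
        assert spec.kernel_size == 3 and spec.lstm_layers == 2
        assert spec.sequence_length == 93  # floor(1500 / 2^4)

    @pytest.mark.parametrize("length,expected", [(1500, 93), (1600, 100), (16, 1)])
    def test_lstm_sequence_length_is_floor_L_over_16(self, length, expected):
        assert ModelSpec(input_length=length).sequence_length == expected

    def test_too_short_input_rejected_with_minimum(self):
        with pytest.raises(ValueError, match="16"):
            ModelSpec(input_length=8).validate()

    @pytest.mark.parametrize("variant", ["standard", "paper"])
    def test_parameter_count_matches_arithmetic_oracle(self, variant, small_spec):
        from dataclasses import replace
        spec = replace(small_spec, lstm_variant=variant)
        net = build_model(spec, seed=0)
        assert net.n_params() == closed_form_param_count(spec)

    def test_ablated_parameter_count_differs_by_lstm_and_head_widening(self, small_spec):
        from dataclasses import replace
        full = build_model(small_spec, seed=0)
        ablated = build_model(replace(small_spec, lstm_layers=0), seed=0)
        assert ablated.n_params() == closed_form_param_count(
            replace(small_spec, lstm_layers=0))
        assert full.n_params() != ablated.n_params()

    def test_output_is_probability_in_open_interval(self, small_spec):
        net = build_model(small_spec, seed=1)
        x = np.random.default_rng(0).normal(size=(5, small_spec.input_length)).astype(np.float32)
        from ppgsas.nn.training import predict_proba
        p = predict_proba(net, x)
        assert np.all((p > 0) & (p < 1))

    def test_construction_is_deterministic(self, small_spec):
        a = build_model(small_spec, seed=3)
        b = build_model(small_spec, seed=3)
        for wa, wb in zip(a.get_weights(), b.get_weights()):
            assert np.array_equal(wa, wb)

    def test_checkpoint_roundtrip(self, tmp_path, small_spec):
        net = build_model(small_spec, seed=2)
        net.save(tmp_path / "model")
        back = SegmentNet.load(tmp_path / "model")
        x = np.random.default_rng(1).normal(size=(3, small_spec.input_length)).astype(np.float32)
        assert np.allclose(net.forward_logits(x, train=False),
                           back.forward_logits(x, train=False))


class TestPaperLSTMStep:
    def setup_method(self):
        rng = np.random.default_rng(0)
        self.h = rng.normal(size=(1, 4))
        self.x = rng.normal(size=(1, 3))
        self.shape = (7, 4)

    def test_forget_gate_saturated_high_selects_candidate(self):
        step = paper_lstm_step(self.h, self.x, W_i=np.zeros(self.shape),
                               W_f=np.zeros(self.shape), W=np.zeros(self.shape),
                               b_f=50.0)
        assert np.allclose(step.h_t, step.h_tilde, atol=1e-6)

    def test_forget_gate_saturated_low_keeps_previous_state(self):
        step = paper_lstm_step(self.h, self.x, W_i=np.zeros(self.shape),
                               W_f=np.zeros(self.shape), W=np.zeros(self.shape),
                               b_f=-50.0)
        assert np.allclose(step.h_t, self.h, atol=1e-6)

    def test_all_zero_weights_and_state(self):
        h0 = np.zeros((1, 4))
        step = paper_lstm_step(h0, self.x, W_i=np.zeros(self.shape),
                               W_f=np.zeros(self.shape), W=np.zeros(self.shape))
        assert np.allclose(step.I_t, 0.5) and np.allclose(step.F_t, 0.5)
        assert np.allclose(step.h_tilde, 0.0) and np.allclose(step.h_t, 0.0)

    def test_gate_and_candidate_ranges_and_update_identity(self):
        rng = np.random.default_rng(4)
        W = rng.normal(size=self.shape)
        step = paper_lstm_step(self.h, self.x, W, W[::-1] * 0.5, W * -0.3)
        assert np.all((step.I_t > 0) & (step.I_t < 1))
        assert np.all((step.F_t > 0) & (step.F_t < 1))
        assert np.all(np.abs(step.h_tilde) < 1)
        assert np.allclose(step.h_t,
                           (1 - step.F_t) * self.h + step.F_t * step.h_tilde)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            paper_lstm_step(self.h, self.x, np.zeros((5, 4)), np.zeros((5, 4)),
                            np.zeros((5, 4)))


class TestBCELoss:
    def test_perfect_prediction_at_clamp(self):
        y = np.array([1.0, 0.0, 1.0])
        assert bce_loss(y, y) <= 1e-6

    def test_uninformative_half_is_ln2(self):
        y = np.array([1, 0, 1, 1, 0])
        assert abs(bce_loss(np.full(5, 0.5), y) - np.log(2)) < 1e-9

    def test_hand_worked_two_sample_example(self):
        # L = -1/2 (ln 0.9 + ln 0.8)
        val = bce_loss(np.array([0.9, 0.2]), np.array([1.0, 0.0]))
        assert abs(val - 0.16425203) < 1e-6

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            bce_loss(np.array([]), np.array([]))

    def test_positivity(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(0.001, 0.999, 50)
        y = rng.integers(0, 2, 50).astype(float)
        assert bce_loss(p, y) > 0

    def test_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(7)
        p = rng.uniform(0.05, 0.95, 20)
        y = rng.integers(0, 2, 20).astype(float)
        g = bce_loss_grad(p, y)
        eps = 1e-7
        for i in range(len(p)):
            pp, pm = p.copy(), p.copy()
            pp[i] += eps
            pm[i] -= eps
            fd = (bce_loss(pp, y) - bce_loss(pm, y)) / (2 * eps)
            assert abs(fd - g[i]) <= 1e-5 * max(abs(fd), 1e-12)

    def test_fused_logits_form_agrees_with_plain_form(self):
        rng = np.random.default_rng(3)
        z = rng.normal(size=30)
        y = rng.integers(0, 2, 30).astype(float)
        from scipy.special import expit
        loss, _ = bce_logits_loss_and_grad(z, y)
        assert abs(loss - bce_loss(expit(z), y)) < 1e-9


class TestBackpropagation:
    def test_directional_gradient_check_all_variants(self, small_spec):
        """Analytic gradients agree with central finite differences in float64."""
        from dataclasses import replace
        import ppgsas.nn.layers as La
        import ppgsas.nn.network as Ne
        orig = La.F32
        La.F32 = Ne.F32 = np.float64
        try:
            for variant_spec in (small_spec,
                                 replace(small_spec, lstm_variant="paper"),
                                 replace(small_spec, lstm_layers=0)):
                net = build_model(replace(variant_spec, input_length=64), seed=0)
                rng = np.random.default_rng(1)
                x = rng.normal(size=(6, 64))
                y = rng.integers(0, 2, 6)

                def loss():
                    return bce_logits_loss_and_grad(net.forward_logits(x), y)[0]

                _, dz = bce_logits_loss_and_grad(net.forward_logits(x), y)
                net.zero_grad()
                net.backward(dz)
                params = net.params()
                dirs = [rng.normal(size=p.value.shape) for p in params]
                analytic = sum(float(np.sum(p.grad * d)) for p, d in zip(params, dirs))
                eps = 1e-6
                olds = [p.value.copy() for p in params]
                for p, d, o in zip(params, dirs, olds):
                    p.value[...] = o + eps * d
                up = loss()
                for p, d, o in zip(params, dirs, olds):
                    p.value[...] = o - eps * d
                down = loss()
                for p, o in zip(params, olds):
                    p.value[...] = o
                fd = (up - down) / (2 * eps)
                assert abs(fd - analytic) <= 1e-6 * max(abs(analytic), 1e-9)
        finally:
            La.F32 = Ne.F32 = orig


class TestTrainingHarness:
    def test_learns_trivial_sine_vs_noise_benchmark(self, small_spec,
                                                    sine_noise_benchmark,
                                                    quick_train_config):
        xt, yt, xv, yv = sine_noise_benchmark
        net = build_model(small_spec, seed=0)
        hist = train(net, xt, yt, xv, yv, quick_train_config)
        assert max(hist["val_acc"]) >= 0.95
        assert len(hist["train_loss"]) <= quick_train_config.max_epochs

    @pytest.mark.parametrize("variant", ["standard", "paper"])
    def test_both_cell_variants_learn_benchmark(self, variant, small_spec,
                                                sine_noise_benchmark,
                                                quick_train_config):
        from dataclasses import replace
        xt, yt, xv, yv = sine_noise_benchmark
        net = build_model(replace(small_spec, lstm_variant=variant), seed=1)
        hist = train(net, xt, yt, xv, yv, quick_train_config)
        assert max(hist["val_acc"]) >= 0.9

    def test_seeded_training_is_reproducible(self, small_spec, sine_noise_benchmark):
        xt, yt, xv, yv = sine_noise_benchmark
        cfg = TrainConfig(max_epochs=3, seed=5)
        h1 = train(build_model(small_spec, seed=5), xt, yt, xv, yv, cfg)
        h2 = train(build_model(small_spec, seed=5), xt, yt, xv, yv, cfg)
        assert abs(h1["best_val_loss"] - h2["best_val_loss"]) < 1e-4

    def test_single_class_training_set_rejected(self, small_spec):
        net = build_model(small_spec, seed=0)
        x = np.zeros((10, small_spec.input_length), np.float32)
        with pytest.raises(ValueError, match="both classes"):
            train(net, x, np.ones(10), x, np.ones(10), TrainConfig(max_epochs=1))

    def test_early_stopping_bounds_history(self, small_spec, sine_noise_benchmark):
        xt, yt, xv, yv = sine_noise_benchmark
        cfg = TrainConfig(max_epochs=30, early_stopping_patience=1,
                          learning_rate=1e-12, seed=0)  # effectively frozen: no improvement
        hist = train(build_model(small_spec, seed=0), xt, yt, xv, yv, cfg)
        # first epoch sets the best loss; the second never improves -> stop
        assert len(hist["val_loss"]) == 2


class TestPredict:
    def test_boundary_probability_is_positive(self, small_spec):
        net = build_model(small_spec, seed=0)
        rng = np.random.default_rng(0)
        x = rng.normal(size=(8, small_spec.input_length)).astype(np.float32)
        p, labels = predict(net, x, threshold=0.5)
        assert np.array_equal(labels, (p >= 0.5).astype(int))
        # explicit tie rule: p exactly at threshold -> positive
        assert (np.array([0.5]) >= 0.5).astype(int)[0] == 1

    def test_threshold_limits(self, small_spec):
        net = build_model(small_spec, seed=0)
        x = np.random.default_rng(1).normal(size=(6, small_spec.input_length)).astype(np.float32)
        _, all_pos = predict(net, x, threshold=0.0)
        assert np.all(all_pos == 1)
        p, at_one = predict(net, x, threshold=1.0)
        assert np.array_equal(at_one, (p >= 1.0).astype(int))

    def test_labels_invariant_under_monotone_rescaling(self):
        rng = np.random.default_rng(2)
        p = rng.uniform(0, 1, 100)
        thr = 0.37
        mono = lambda v: np.log1p(9 * v)  # strictly increasing on [0, 1]
        assert np.array_equal(p >= thr, mono(p) >= mono(thr))

    def test_length_mismatch_rejected(self, small_spec):
        net = build_model(small_spec, seed=0)
        with pytest.raises(ValueError, match="input_length"):
            predict(net, np.zeros((2, 99), np.float32))
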