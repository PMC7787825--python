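"""Architecture declarations, shape traces, activations, training contracts."""

import numpy as np
import pytest

from mfbnet.models import (
    ArchitectureSpec,
    FLAT,
    TrainConfig,
    VARIANTS,
    build_architecture,
    build_full_model,
    build_model,
    dense,
    elu,
    fbcsp_branch_spec,
    maxpool,
    mfcnn_branch_spec,
    parameter_count,
    predict,
    shape_trace,
    softmax,
    train,
)


class TestELU:
    def test_positive_branch_ignores_lambda(self):
        assert elu(2.0, 1.0) == 2.0
        assert elu(2.0, 7.0) == 2.0

    def test_continuous_at_zero(self):
        assert elu(0.0, 1.0) == 0.0
        assert abs(elu(-1e-9, 1.0)) < 1e-8

    def test_negative_branch_value(self):
        assert elu(-np.log(2.0), 1.0) == pytest.approx(-0.5)

    def test_nonpositive_lambda_rejected(self):
        with pytest.raises(ValueError):
            elu(1.0, 0.0)


class TestMaxpool:
    def test_window_maximum(self):
        assert maxpool(np.array([[1.0, 2.0], [3.0, 4.0]])) == 4.0
        assert maxpool(np.full((2, 2), 7.0)) == 7.0

    def test_floor_semantics_in_trace(self):
        trace = shape_trace(fbcsp_branch_spec(), (43, 264, 1))
        assert trace[1] == (20, 116, 32)  # 41x233 pooled with dropped border


class TestShapeTraces:
    def test_mfcnn_branch_reproduces_reference_trace(self):
        trace = shape_trace(mfcnn_branch_spec(), (22, 22, 1))
        assert trace == [
            (22, 22, 32), (11, 11, 32), (11, 11, 64), (11, 11, 64),
            (5, 5, 64), (5, 5, 64), (1600,), (64,),
        ]

    def test_fbcsp_branch_reproduces_reference_trace(self):
        trace = shape_trace(fbcsp_branch_spec(), (43, 264, 1))
        assert trace == [
            (41, 233, 32), (20, 116, 32), (18, 101, 64), (17, 94, 64), (102272,), (64,),
        ]

    def test_fbcsp_branch_at_width_176(self):
        trace = shape_trace(fbcsp_branch_spec(), (43, 176, 1))
        assert trace == [
            (41, 145, 32), (20, 72, 32), (18, 57, 64), (17, 50, 64), (54400,), (64,),
        ]

    def test_engine_shapes_match_trace(self, rng):
        # the built network reproduces the arithmetic trace layer by layer
        arch = build_architecture("full")
        net = build_full_model("full", feature_width=176, seed=0)
        x = {
            "mu": rng.standard_normal((2, 22, 22, 1)),
            "beta": rng.standard_normal((2, 22, 22, 1)),
            "fbcsp": rng.standard_normal((2, 43, 176, 1)),
        }
        for name, layers in net.branches.items():
            out = x[name].astype(np.float32)
            expect = shape_trace(arch.branches[name], (*x[name].shape[1:3], 1))
            for layer, shape in zip(layers, expect):
                out = layer.forward(out)
                assert out.shape[1:] == shape

    def test_parameter_count_matches_built_model(self):
        arch = build_architecture("full")
        expected = sum(
            parameter_count(spec, {"mu": (22, 22, 1), "beta": (22, 22, 1), "fbcsp": (43, 176, 1)}[n])
            for n, spec in arch.branches.items()
        ) + parameter_count(arch.head, (192,))
        net = build_full_model("full", feature_width=176)
        assert net.n_parameters() == expected


class TestVariants:
    def test_full_concatenates_three_branches(self):
        net = build_full_model("full", feature_width=176)
        assert net.concat_dim == 192

    def test_variant_a_removes_mu(self):
        net = build_full_model("A", feature_width=176)
        assert set(net.branches) == {"beta", "fbcsp"}
        assert net.concat_dim == 128

    def test_variant_b_removes_beta(self):
        assert set(build_full_model("B", feature_width=176).branches) == {"mu", "fbcsp"}

    @pytest.mark.parametrize("variant,branch", [("C", "mu"), ("D", "beta")])
    def test_variants_c_d_add_two_convs(self, variant, branch):
        arch = build_architecture(variant)
        n_convs = sum(s.kind == "conv" for s in arch.branches[branch])
        assert n_convs == 6  # 4 + 2 inserted
        # the inserted layers mirror their predecessors' kernels
        kernels = [s.kernel for s in arch.branches[branch] if s.kind == "conv"]
        assert kernels == [(6, 6), (4, 4), (4, 4), (3, 3), (3, 3), (3, 3)]
        # shape trace is unchanged by same-padding insertions
        assert shape_trace(arch.branches[branch], (22, 22, 1))[-1] == (64,)

    def test_variant_e_first_kernel(self):
        arch = build_architecture("E")
        assert arch.branches["fbcsp"][0].kernel == (2, 32)
        assert shape_trace(arch.branches["fbcsp"], (43, 176, 1))[0] == (42, 145, 32)

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError, match="variant"):
            build_architecture("Z")

    def test_all_variants_build_and_emit_probabilities(self, rng):
        x = {
            "mu": rng.standard_normal((3, 22, 22, 1)),
            "beta": rng.standard_normal((3, 22, 22, 1)),
            "fbcsp": rng.standard_normal((3, 43, 176, 1)),
        }
        for variant in VARIANTS:
            net = build_full_model(variant, feature_width=176, seed=1)
            labels, probs = predict(net, x)
            assert probs.shape == (3, 4)
            np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)
            assert labels.shape == (3,)


class TestSoftmaxAndPredict:
    def test_softmax_normalized(self, rng):
        p = softmax(rng.standard_normal((5, 4)))
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-6)

    def test_uniform_probabilities_tie_to_class_one(self):
        probs = np.full((2, 4), 0.25)
        assert list(probs.argmax(axis=1) + 1) == [1, 1]


def _toy_model_and_data(seed=0, n=64):
    """Linearly separable 4-class problem through a tiny dense net."""
    rng = np.random.default_rng(seed)
    arch = ArchitectureSpec(branches={"x": [FLAT, dense(16)]}, head=[dense(4, activation=None)])
    net = build_model(arch, {"x": (4, 4)}, seed=seed)
    y = rng.integers(1, 5, size=n)
    x = rng.standard_normal((n, 4, 4, 1)).astype(np.float32) * 0.1
    for i, label in enumerate(y):
        x[i, label - 1, label - 1, 0] += 3.0  # class-indexed diagonal bump
    return net, {"x": x}, y


class TestTraining:
    def test_separable_problem_reaches_high_training_accuracy(self):
        net, x, y = _toy_model_and_data()
        cfg = TrainConfig(max_epochs=50, patience=50, seed=0)
        hist = train(net, x, y, x, y, cfg)
        labels, _ = predict(net, x)
        assert np.mean(labels == y) >= 0.95
        assert hist.best_epoch >= 0

    def test_best_validation_weights_restored(self):
        net, x, y = _toy_model_and_data(seed=1)
        cfg = TrainConfig(max_epochs=30, patience=30, seed=1)
        hist = train(net, x, y, x, y, cfg)
        probs = net.predict_proba(x)
        acc = np.mean(probs.argmax(axis=1) + 1 == y)
        assert acc == pytest.approx(max(hist.val_acc))

    def test_deterministic_given_seed(self):
        accs = []
        for _ in range(2):
            net, x, y = _toy_model_and_data(seed=2)
            hist = train(net, x, y, x, y, TrainConfig(max_epochs=10, patience=10, seed=2))
            accs.append(hist.val_acc)
        assert accs[0] == accs[1]

    def test_empty_split_rejected(self):
        net, x, y = _toy_model_and_data(seed=3)
        with pytest.raises(ValueError, match="empty"):
            train(net, x, y, {"x": x["x"][:0]}, y[:0], TrainConfig(max_epochs=1))
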