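"""Tests for the assembled network: heads, loss, aggregation, checkpoints."""

import numpy as np
import pytest

from lgnet.errors import ConfigurationError, DataError
from lgnet.fusion import HMUConfig
from lgnet.network import (LGNet, LGNetConfig, lgnet_loss, load_checkpoint,
                           predict, save_checkpoint)
from lgnet.tensor import Tensor

import oracles

TINY = dict(num_classes=4, widths=(6, 12, 18), common_width=6,
            hmu=HMUConfig(groups=2), input_size=64)


def tiny_model(seed=0, **overrides):
    kw = {**TINY, **overrides, "seed": seed}
    return LGNet(LGNetConfig(**kw))


def batch(rng, n=2, size=64):
    return Tensor(rng.standard_normal((n, 3, size, size)).astype(np.float32))


class TestForward:
    def test_one_head_per_active_branch(self, rng):
        model = tiny_model()
        model.eval()
        logits = model(batch(rng))
        assert set(logits) == {"B1", "B2", "B3"}
        assert all(lg.shape == (2, 4) for lg in logits.values())
        assert all(np.isfinite(lg.data).all() for lg in logits.values())

    def test_single_branch_degenerate_topology(self, rng):
        model = tiny_model(active_branches=("B3",))
        model.eval()
        assert model.pairs == []
        logits = model(batch(rng))
        assert set(logits) == {"B3"}

    def test_batch_forward_equals_stacked_singles(self, rng):
        model = tiny_model()
        model.eval()
        x = batch(rng, n=2)
        both = model(x)
        one = model(Tensor(x.data[0:1]))
        two = model(Tensor(x.data[1:2]))
        for name in both:
            stacked = np.concatenate([one[name].data, two[name].data])
            assert np.abs(both[name].data - stacked).max() <= 1e-5

    @pytest.mark.parametrize("branches", [("B1", "B2"), ("B2", "B3"),
                                          ("B1", "B3"), ("B1", "B2", "B3")])
    def test_branch_masking_grid_builds_and_steps(self, rng, branches):
        from lgnet.train_eval import TrainConfig, build_param_groups
        from lgnet.nn import SGD
        model = tiny_model(active_branches=branches)
        x = batch(rng)
        labels = np.array([0, 1])
        opt = SGD(build_param_groups(model, TrainConfig(backbone_lr=0.01,
                                                        new_param_lr=0.01)),
                  momentum=0.9)
        loss, _ = lgnet_loss(model(x), labels)
        opt.zero_grad()
        loss.backward()
        opt.step()
        assert np.isfinite(loss.data)

    @pytest.mark.parametrize("toggles", [(False, False), (True, False),
                                         (False, True), (True, True)])
    def test_module_toggle_grid_runs(self, rng, toggles):
        use_aff, use_hmuff = toggles
        model = tiny_model(use_aff=use_aff, use_hmuff=use_hmuff)
        model.eval()
        logits = model(batch(rng))
        assert all(np.isfinite(lg.data).all() for lg in logits.values())

    @pytest.mark.parametrize("mode", ["local", "global"])
    def test_single_encoder_variants(self, rng, mode):
        model = tiny_model(encoder_mode=mode, use_aff=False, use_hmuff=False)
        model.eval()
        logits = model(batch(rng))
        assert set(logits) == {"B1", "B2", "B3"}


class TestLoss:
    def test_uniform_logits_give_log_k(self):
        logits = {"B3": Tensor(np.zeros((2, 4)))}
        loss, comps = lgnet_loss(logits, np.array([0, 3]))
        assert np.isclose(loss.data, np.log(4))
        assert np.isclose(comps["B3"], np.log(4))

    def test_three_uniform_branches_sum(self):
        logits = {b: Tensor(np.zeros((1, 4))) for b in ("B1", "B2", "B3")}
        loss, _ = lgnet_loss(logits, np.array([2]))
        assert np.isclose(loss.data, 3 * np.log(4))

    def test_matches_scalar_oracle(self, rng):
        arr = rng.standard_normal((5, 3))
        labels = np.array([0, 2, 1, 1, 0])
        loss, _ = lgnet_loss({"B1": Tensor(arr)}, labels)
        assert abs(loss.data - oracles.cross_entropy_loops(arr, labels)) < 1e-6

    def test_out_of_range_label_named(self):
        with pytest.raises(DataError, match="index 1"):
            lgnet_loss({"B1": Tensor(np.zeros((2, 3)))}, np.array([0, 5]))

    def test_loss_weights_scale_components(self, rng):
        arr = rng.standard_normal((3, 4))
        logits = {"B1": Tensor(arr), "B2": Tensor(arr)}
        labels = np.array([0, 1, 2])
        equal, _ = lgnet_loss(logits, labels)
        weighted, _ = lgnet_loss(logits, labels, weights={"B1": 2.0, "B2": 0.0})
        assert np.isclose(weighted.data, equal.data)  # 2+0 == 1+1 on equal logits


class TestPredict:
    def test_single_branch_is_plain_softmax_argmax(self, rng):
        arr = rng.standard_normal((4, 3))
        pred, probs = predict({"B3": Tensor(arr)})
        assert np.array_equal(pred, arr.argmax(axis=-1))
        assert np.allclose(probs.sum(axis=-1), 1.0)

    def test_opposite_logits_tie_break_to_class_zero(self):
        v = np.array([[1.0, 2.0, -3.0]])
        pred, probs = predict({"B1": Tensor(v), "B2": Tensor(-v)})
        assert pred[0] == 0
        assert np.allclose(probs, 1 / 3)

    def test_matches_hand_computed_mean_softmax(self, rng):
        arrs = {b: rng.standard_normal((2, 4)) for b in ("B1", "B2", "B3")}
        pred, probs = predict({b: Tensor(a) for b, a in arrs.items()})
        mean = np.mean(list(arrs.values()), axis=0)
        e = np.exp(mean - mean.max(axis=-1, keepdims=True))
        ref = e / e.sum(axis=-1, keepdims=True)
        assert np.allclose(probs, ref, atol=1e-12)
        assert np.array_equal(pred, ref.argmax(axis=-1))


class TestEmbedding:
    def test_embedding_length_and_determinism(self, rng):
        model = tiny_model()
        model.eval()
        x = batch(rng)
        emb = model.extract_embedding(x)
        assert emb.shape == (2, 3 * TINY["common_width"])
        assert np.array_equal(emb.data, model.extract_embedding(x).data)

    def test_identical_images_identical_embeddings(self, rng):
        model = tiny_model()
        model.eval()
        img = rng.standard_normal((1, 3, 64, 64)).astype(np.float32)
        x = Tensor(np.concatenate([img, img]))
        emb = model.extract_embedding(x).data
        assert np.allclose(emb[0], emb[1], atol=1e-6)

    def test_embedding_independent_of_head_parameters(self, rng):
        model = tiny_model()
        model.eval()
        x = batch(rng)
        before = model.extract_embedding(x).data.copy()
        for head in model.heads:
            head.weight.data = np.random.default_rng(9).standard_normal(
                head.weight.data.shape).astype(head.weight.data.dtype)
        assert np.array_equal(before, model.extract_embedding(x).data)


class TestGradientFlow:
    def test_every_parameter_gets_finite_nonzero_gradient(self, rng):
        model = tiny_model()
        model.train()
        loss, _ = lgnet_loss(model(batch(rng, n=4)), np.array([0, 1, 2, 3]))
        loss.backward()
        for name, p in model.named_parameters():
            assert p.grad is not None, f"{name} got no gradient"
            assert np.isfinite(p.grad).all(), f"{name} gradient not finite"
            assert np.abs(p.grad).max() > 0, f"{name} gradient identically zero"


class TestCheckpoint:
    def test_round_trip_is_bit_identical(self, rng, tmp_path):
        model = tiny_model(seed=4)
        model.eval()
        x = batch(rng)
        ref = {k: v.data.copy() for k, v in model(x).items()}
        path = tmp_path / "ckpt.npz"
        save_checkpoint(path, model, ["a", "b", "c", "d"],
                        norm_mean=[0.5, 0.5, 0.5], norm_std=[0.2, 0.2, 0.2])
        loaded, meta = load_checkpoint(path)
        assert meta["vocabulary"] == ["a", "b", "c", "d"]
        assert loaded.cfg == model.cfg
        out = loaded(x)
        for name in ref:
            assert np.array_equal(out[name].data, ref[name].data)

    @pytest.mark.parametrize("branches", [("B1", "B2"), ("B2", "B3"),
                                          ("B1", "B3"), ("B1", "B2", "B3")])
    def test_masked_configs_save_load_losslessly(self, branches, tmp_path):
        model = tiny_model(active_branches=branches)
        path = tmp_path / "m.npz"
        save_checkpoint(path, model, list("abcd"))
        loaded, _ = load_checkpoint(path)
        s1, s2 = model.state_dict(), loaded.state_dict()
        assert set(s1) == set(s2)
        assert all(np.array_equal(s1[k], s2[k]) for k in s1)


class TestConfigValidation:
    def test_too_few_classes_rejected(self):
        with pytest.raises(ConfigurationError):
            LGNetConfig(num_classes=1)

    def test_bad_branch_name_rejected(self):
        with pytest.raises(ConfigurationError):
            LGNetConfig(active_branches=("B1", "B9"))

    def test_topology_filtered_to_active_branches(self):
        cfg = LGNetConfig(**{**TINY, "active_branches": ("B1", "B3")})
        assert cfg.active_pairs == (("B1", "B3"),)
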