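import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from splicedesign import nn
from splicedesign.model import (FinetuneConfig, PretrainConfig,
                                SpliceCodeConfig, SpliceCodeModel,
                                count_parameters, finetune, make_targets,
                                pretrain, supervision_loss, swap_windows)


class TestMakeTargets:
    def test_positive_change(self):
        rng = np.random.default_rng(0)
        psi, dp, dm = make_targets(0.60, 0.30, rng)
        assert psi == 0.60
        assert dp == pytest.approx(0.30)
        assert 0.001 <= dm <= 0.002

    def test_negative_change(self):
        rng = np.random.default_rng(0)
        psi, dp, dm = make_targets(0.25, 0.50, rng)
        assert dm == pytest.approx(0.25)
        assert 0.001 <= dp <= 0.002

    def test_zero_change(self):
        rng = np.random.default_rng(0)
        _, dp, dm = make_targets(0.4, 0.4, rng)
        assert dp == dm and 0.001 <= dp <= 0.002

    @given(st.floats(0, 1), st.floats(0, 1), st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_target_algebra(self, a, b, seed):
        """dpsi_plus - dpsi_minus reconstructs dPSI to within epsilon
        whenever |dPSI| >= epsilon; both components stay >= 0.001."""
        rng = np.random.default_rng(seed)
        _, dp, dm = make_targets(a, b, rng)
        dpsi = a - b
        assert dp >= 0.001 and dm >= 0.001
        if abs(dpsi) >= 0.002:
            assert abs((dp - dm) - dpsi) <= 0.002


class TestLoss:
    def test_half_target_closed_form(self):
        # p == t == 0.5 for every head: per-head loss is ln 2
        logits = nn.Tensor(np.zeros((4, 3), dtype=np.float32))
        loss = supervision_loss(logits, np.full((4, 3), 0.5))
        assert loss.item() == pytest.approx(3 * np.log(2), rel=1e-6)

    def test_limit_zero(self):
        logits = nn.Tensor(np.full((2, 3), 30.0, dtype=np.float32))
        loss = supervision_loss(logits, np.ones((2, 3)))
        assert loss.item() < 1e-8

    def test_matches_elementwise_formula(self, rng):
        lo = rng.normal(size=(5, 3)).astype(np.float32)
        t = rng.uniform(0, 1, (5, 3)).astype(np.float32)
        p = 1 / (1 + np.exp(-lo.astype(np.float64)))
        expected = -(t * np.log(p) + (1 - t) * np.log(1 - p))
        loss = supervision_loss(nn.Tensor(lo), t)
        assert loss.item() == pytest.approx(
            expected.mean() * 3, rel=1e-5)

    def test_nonnegative(self, rng):
        lo = rng.normal(size=(8, 3)).astype(np.float32)
        t = rng.uniform(0, 1, (8, 3))
        assert supervision_loss(nn.Tensor(lo), t).item() >= 0


class TestParameterCount:
    def test_analytic_matches_built_model(self):
        cfg = SpliceCodeConfig.tiny(cond_mode="token", n_conditions=3)
        model = SpliceCodeModel(cfg, seed=0,
                                condition_names=["a", "b", "c"])
        assert model.n_parameters() == count_parameters(cfg)

    def test_pca_mode_count(self):
        cfg = SpliceCodeConfig.tiny(cond_mode="pca", pca_dim=5)
        model = SpliceCodeModel(cfg, seed=0)
        assert model.n_parameters() == count_parameters(cfg)

    def test_depth_strictly_increases(self):
        base = SpliceCodeConfig.tiny()
        deeper = SpliceCodeConfig.tiny(n_layers=4)
        assert count_parameters(deeper) > count_parameters(base)

    def test_sharing_reduces(self):
        assert count_parameters(SpliceCodeConfig.tiny(
            share_encoders=True)) < count_parameters(
            SpliceCodeConfig.tiny())


@pytest.fixture(scope="module")
def tiny_trained(oracle_spec, small_dataset):
    """A minimally trained tiny model over the 60-event set (2 epochs) —
    enough to exercise prediction paths, not accuracy."""
    cfg = SpliceCodeConfig.tiny(cond_mode="token", n_conditions=3)
    model = SpliceCodeModel(cfg, seed=1,
                            condition_names=oracle_spec.tissues)
    finetune(model, small_dataset.events, small_dataset.records,
             FinetuneConfig.tiny(epochs=2, seed=0))
    return model


class TestPredict:
    def test_outputs_in_unit_interval(self, tiny_trained, small_dataset,
                                      oracle_spec):
        tA, tB = oracle_spec.tissues[:2]
        out = tiny_trained.predict(small_dataset.events[:5], tA, tB)
        for key in ("psi", "dpsi_plus", "dpsi_minus"):
            assert np.all((out[key] > 0) & (out[key] < 1))
        np.testing.assert_allclose(out["dpsi"],
                                   out["dpsi_plus"] - out["dpsi_minus"])

    def test_batched_equals_single(self, tiny_trained, small_dataset,
                                   oracle_spec):
        tA, tB = oracle_spec.tissues[:2]
        batch = tiny_trained.predict(small_dataset.events[:4], tA, tB)
        for i, ev in enumerate(small_dataset.events[:4]):
            single = tiny_trained.predict(ev, tA, tB)
            assert single["psi"] == pytest.approx(batch["psi"][i],
                                                  abs=1e-5)

    def test_unseen_condition_rejected(self, tiny_trained,
                                       small_dataset):
        with pytest.raises(KeyError, match="cannot be queried"):
            tiny_trained.predict(small_dataset.events[0], "kidney",
                                 "tissueA")

    def test_identity_swap_preserves_predictions(self, tiny_trained,
                                                 small_dataset,
                                                 oracle_spec):
        tA, tB = oracle_spec.tissues[:2]
        ev = small_dataset.events[0]
        same = swap_windows(ev, (0, 1, 2, 3))
        a = tiny_trained.predict(ev, tA, tB)
        b = tiny_trained.predict(same, tA, tB)
        assert a["psi"] == pytest.approx(b["psi"], abs=1e-7)

    def test_swap_changes_predictions(self, tiny_trained, small_dataset,
                                      oracle_spec):
        tA, tB = oracle_spec.tissues[:2]
        evs = small_dataset.events[:8]
        swapped = [swap_windows(e, (0, 2, 1, 3)) for e in evs]
        a = tiny_trained.predict(evs, tA, tB)["psi"]
        b = tiny_trained.predict(swapped, tA, tB)["psi"]
        assert np.abs(a - b).max() > 1e-6

    def test_bad_permutation_rejected(self, small_dataset):
        with pytest.raises(ValueError):
            swap_windows(small_dataset.events[0], (0, 1, 1, 3))


class TestFinetune:
    def test_zero_epochs_no_change(self, oracle_spec, small_dataset):
        cfg = SpliceCodeConfig.tiny(cond_mode="token", n_conditions=3)
        model = SpliceCodeModel(cfg, seed=2,
                                condition_names=oracle_spec.tissues)
        before = [p.copy() for p in model.state_dict()]
        finetune(model, small_dataset.events, small_dataset.records,
                 FinetuneConfig.tiny(epochs=0))
        for a, b in zip(before, model.state_dict()):
            np.testing.assert_array_equal(a, b)

    def test_deterministic_with_seed(self, oracle_spec, small_dataset):
        losses = []
        for _ in range(2):
            cfg = SpliceCodeConfig.tiny(cond_mode="token", n_conditions=3)
            model = SpliceCodeModel(cfg, seed=3,
                                    condition_names=oracle_spec.tissues)
            hist = finetune(model, small_dataset.events[:20],
                            small_dataset.records,
                            FinetuneConfig.tiny(epochs=1, seed=7))
            losses.append(hist["train_loss"][-1])
        assert losses[0] == losses[1]


@pytest.fixture(scope="module")
def corpus():
    return ["".join(np.random.default_rng(i).choice(list("ACGT"), 60))
            for i in range(50)]


class TestPretrain:

    def test_zero_steps_is_initialization(self, corpus):
        cfg = SpliceCodeConfig.tiny(n_layers=1, hidden=32, n_heads=2,
                                    window_width=60)
        mlm = pretrain(corpus, cfg, PretrainConfig.tiny(steps=0))
        assert mlm.history == []

    def test_beats_uniform_guessing(self, corpus):
        """After a short run, masked-token recovery clears the uniform
        1/vocab baseline by a wide margin (sequences are revisited, so
        the encoder can memorize local context)."""
        cfg = SpliceCodeConfig.tiny(n_layers=1, hidden=32, n_heads=2,
                                    window_width=60)
        mlm = pretrain(corpus, cfg,
                       PretrainConfig.tiny(steps=300, batch_size=16,
                                           lr=2e-3, warmup=50))
        acc = mlm.masked_accuracy(corpus[:20], rate=0.15, seed=0)
        assert acc > 50.0 / 4101
        assert mlm.history[-1] < mlm.history[0]

    def test_same_seed_same_loss(self, corpus):
        cfg = SpliceCodeConfig.tiny(n_layers=1, hidden=32, n_heads=2,
                                    window_width=60)
        a = pretrain(corpus, cfg, PretrainConfig.tiny(steps=10))
        b = pretrain(corpus, cfg, PretrainConfig.tiny(steps=10))
        assert a.history == b.history


class TestCheckpoint:
    def test_round_trip_preserves_predictions(self, tmp_path,
                                              tiny_trained,
                                              small_dataset,
                                              oracle_spec):
        from splicedesign.model import load_checkpoint, save_checkpoint
        tA, tB = oracle_spec.tissues[:2]
        before = tiny_trained.predict(small_dataset.events[:4], tA, tB)
        save_checkpoint(tiny_trained, tmp_path / "model")
        restored = load_checkpoint(tmp_path / "model")
        after = restored.predict(small_dataset.events[:4], tA, tB)
        np.testing.assert_allclose(after["psi"], before["psi"],
                                   atol=1e-7)
        np.testing.assert_allclose(after["dpsi"], before["dpsi"],
                                   atol=1e-7)
        assert restored.condition_index == tiny_trained.condition_index
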