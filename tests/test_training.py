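"""Loss function oracles and the optimization regime."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from radarbp.config import ResNetConfig, TrainConfig, TransformerConfig
from radarbp.model import DualTransformer, ResNet1D
from radarbp.nn import AdamW, Tensor
from radarbp.segmentation import WindowSample
from radarbp.training import (build_sequences, fit_stage1, fit_stage2,
                              mean_predictor_baseline, predict_stage1,
                              pseudo_huber)


class TestPseudoHuber:
    def test_zero_error_zero_loss(self):
        assert pseudo_huber(0.0, 5.0) == 0.0

    def test_value_at_a_equals_delta(self):
        """a = delta = 1 gives sqrt(2) - 1."""
        assert pseudo_huber(1.0, 1.0) == pytest.approx(np.sqrt(2) - 1,
                                                       abs=1e-12)

    def test_quadratic_asymptotics_for_small_errors(self):
        delta = 5.0
        a = np.concatenate([np.linspace(-delta / 10, -0.01, 10),
                            np.linspace(0.01, delta / 10, 10)])
        ratio = pseudo_huber(a, delta) / (a ** 2 / 2)
        assert np.all(np.abs(ratio - 1) < 0.01)

    def test_linear_asymptotics_for_large_errors(self):
        delta = 5.0
        a = np.array([1e3, 1e4, 1e5])
        ratio = pseudo_huber(a, delta) / (delta * np.abs(a))
        assert np.allclose(ratio, 1.0, atol=1e-2)

    @settings(derandomize=True, max_examples=30)
    @given(delta=st.floats(0.1, 20.0))
    def test_monotone_in_absolute_error(self, delta):
        a = np.linspace(0, 50, 200)
        loss = pseudo_huber(a, delta)
        assert np.all(np.diff(loss) > 0)

    def test_tensor_path_matches_numpy_path(self):
        a = np.linspace(-10, 10, 31)
        t = pseudo_huber(Tensor(a), 5.0)
        assert np.allclose(t.data, pseudo_huber(a, 5.0), atol=1e-12)

    def test_nonpositive_delta_rejected(self):
        with pytest.raises(ValueError):
            pseudo_huber(1.0, 0.0)


def _toy_windows(n, L=60, label_spread=True, seed=0):
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        sbp = 110.0 + (20.0 * (i % 5) / 4 if label_spread else 0.0)
        ch = np.zeros((2, L))
        # amplitude-free shape cue so labels are learnable from content
        ch[0] = np.sin(2 * np.pi * (2 + (sbp - 110) / 10) *
                       np.arange(L) / L) + 0.01 * rng.normal(size=L)
        ch[1] = np.cos(2 * np.pi * (2 + (sbp - 110) / 10) *
                       np.arange(L) / L) + 0.01 * rng.normal(size=L)
        ch /= np.linalg.norm(ch, axis=1, keepdims=True)
        out.append(WindowSample(channels=ch, sbp_label=sbp,
                                dbp_label=sbp - 40.0, subject_id="s000",
                                window_index=i))
    return out


SMALL_NET = ResNetConfig(stem_width=4, feature_dim=8)
SMALL_TR = TransformerConfig(d_model=8, n_heads=2, d_ff=16, sequence_len=4)


class TestStage1Fit:
    def test_loss_decreases_over_training(self):
        wins = _toy_windows(32)
        cfg = TrainConfig(epochs=12, batch_stage1=8, early_stop_patience=12,
                          seed=0)
        res = fit_stage1(wins, wins[:8], cfg, SMALL_NET, model_seed=0)
        first = res.history.train_loss.iloc[0]
        last = res.history.train_loss.iloc[-1]
        assert last < first

    def test_seeded_reproducibility(self):
        wins = _toy_windows(24)
        cfg = TrainConfig(epochs=3, batch_stage1=8, seed=4)
        a = fit_stage1(wins[:16], wins[16:], cfg, SMALL_NET, model_seed=1)
        b = fit_stage1(wins[:16], wins[16:], cfg, SMALL_NET, model_seed=1)
        assert a.best_val_loss == b.best_val_loss
        pa = predict_stage1(a.model, wins[16:])
        pb = predict_stage1(b.model, wins[16:])
        assert np.array_equal(pa, pb)

    def test_beats_mean_predictor_on_separable_toy_data(self):
        wins = _toy_windows(60, seed=1)
        cfg = TrainConfig(epochs=25, batch_stage1=16,
                          early_stop_patience=25, seed=0)
        train, val = wins[:48], wins[48:]
        res = fit_stage1(train, val, cfg, SMALL_NET, model_seed=0)
        preds = predict_stage1(res.model, val)
        labels = np.stack([[w.sbp_label, w.dbp_label] for w in val])
        base = mean_predictor_baseline(train, val)
        assert np.abs(preds - labels).mean() < np.abs(base - labels).mean()

    def test_empty_split_rejected(self):
        with pytest.raises(ValueError):
            fit_stage1([], _toy_windows(4), TrainConfig(), SMALL_NET)


class TestStage2Fit:
    def _seqs(self, wins, model):
        from radarbp.model import stage1_forward
        bundle = stage1_forward(model, wins)
        return build_sequences(wins, bundle, SMALL_TR, fusion=True)

    def test_training_runs_and_improves_loss(self):
        wins = _toy_windows(40)
        s1 = fit_stage1(wins[:32], wins[32:],
                        TrainConfig(epochs=2, batch_stage1=8, seed=0),
                        SMALL_NET, model_seed=0)
        seq_tr = self._seqs(wins[:32], s1.model)
        seq_va = self._seqs(wins[32:], s1.model)
        cfg = TrainConfig(epochs=10, batch_stage2=2,
                          early_stop_patience=10, seed=0)
        res = fit_stage2(seq_tr, seq_va, cfg, SMALL_TR,
                         in_dim=seq_tr[0].shape[2], model_seed=0)
        assert res.history.train_loss.iloc[-1] \
            <= res.history.train_loss.iloc[0]

    def test_no_fusion_reduces_input_width_and_trains(self):
        wins = _toy_windows(24)
        s1 = fit_stage1(wins[:16], wins[16:],
                        TrainConfig(epochs=1, batch_stage1=8, seed=0),
                        SMALL_NET, model_seed=0)
        from radarbp.model import stage1_forward
        b = stage1_forward(s1.model, wins[:16])
        fused = build_sequences(wins[:16], b, SMALL_TR, fusion=True)
        plain = build_sequences(wins[:16],
                                stage1_forward(s1.model, wins[:16]),
                                SMALL_TR, fusion=False)
        # each stream's encoder input loses the crossed scalar estimate
        assert fused[0].shape[2] == plain[0].shape[2] + 1
        cfg = TrainConfig(epochs=2, batch_stage2=2, seed=0)
        res = fit_stage2(plain, plain, cfg, SMALL_TR,
                         in_dim=plain[0].shape[2], model_seed=0)
        assert np.isfinite(res.best_val_loss)

    def test_misaligned_sequences_rejected(self):
        cfg = TrainConfig()
        bad = (np.zeros((2, 4, 10)), np.zeros((2, 4, 10)),
               np.zeros((2, 4, 2)), np.zeros((2, 3, 2)))
        with pytest.raises(ValueError):
            fit_stage2(bad, bad, cfg, SMALL_TR, in_dim=10)


class TestTrainability:
    def test_stage1_loss_strictly_decreases_over_50_steps(self):
        """Single-batch optimization sanity: 50 Adam steps reduce the loss."""
        rng = np.random.default_rng(0)
        model = ResNet1D(SMALL_NET, seed=0)
        model.train()
        x = rng.normal(size=(8, 2, 60))
        y = rng.normal([[120.0, 80.0]], 5.0, size=(8, 2))
        opt = AdamW(model.parameters(), lr=1e-3)
        losses = []
        for _ in range(50):
            _, _, ys, yd = model(Tensor(x))
            loss = pseudo_huber(ys - y[:, 0], 5.0).mean() \
                + pseudo_huber(yd - y[:, 1], 5.0).mean()
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        assert losses[-1] < losses[0]

    def test_stage2_loss_decreases_over_50_steps(self):
        rng = np.random.default_rng(1)
        model = DualTransformer(10, SMALL_TR, seed=0)
        model.train()
        enc_s = rng.normal(size=(4, 4, 10))
        enc_d = rng.normal(size=(4, 4, 10))
        pre = rng.normal(120.0, 5.0, size=(4, 4, 2))
        lab = pre + rng.normal(0, 3.0, size=pre.shape)
        opt = AdamW(model.parameters(), lr=1e-3)
        losses = []
        for _ in range(50):
            out = model(Tensor(enc_s), Tensor(enc_d), Tensor(pre))
            loss = pseudo_huber(out - lab, 5.0).mean(axis=(0, 1)).sum()
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        assert losses[-1] < losses[0]


def test_build_sequences_chunks_by_subject_and_time():
    wins = _toy_windows(10)
    for i, w in enumerate(wins):
        w.subject_id = "s000" if i < 6 else "s001"
    from radarbp.model import FeatureBundle
    bundle = FeatureBundle(F_S=np.zeros((10, 4)), F_D=np.zeros((10, 4)),
                           y_S_prelim=np.arange(10.0),
                           y_D_prelim=np.arange(10.0))
    enc_s, enc_d, pre, lab, idx = build_sequences(wins, bundle, SMALL_TR)
    # subject s000 yields one sequence of 4, s001 yields one; leftovers drop
    assert enc_s.shape[0] == enc_d.shape[0] == 2
    assert idx[0] == [0, 1, 2, 3]
    assert idx[1] == [6, 7, 8, 9]
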