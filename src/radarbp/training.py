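"""Loss and optimization regime for the two stages.

Both stages minimize the summed Pseudo-Huber loss of the systolic and
diastolic errors (in mmHg), with Adam + decoupled weight decay, plateau LR
halving, and early stopping on validation loss.  The test split never
touches any fitting or scheduling decision.

Stage 1 trains per window; its weights are then frozen and its feature
bundles exported.  Stage 2 trains on sequences of fused vectors built from
consecutive same-subject windows within each split (so partitions stay
disjoint), refining the stage-1 estimates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .config import ResNetConfig, TrainConfig, TransformerConfig
from .model import (BPTransformer, FeatureBundle, ResNet1D, fuse,
                    stage1_forward)
from .nn import AdamW, PlateauScheduler, Tensor
from .segmentation import WindowSample

__all__ = ["pseudo_huber", "fit_stage1", "fit_stage2", "build_sequences",
           "predict_stage1", "predict_pipeline", "mean_predictor_baseline",
           "TrainResult"]


def pseudo_huber(a, delta: float):
    """Smooth robust loss: delta^2 (sqrt(1 + (a/delta)^2) - 1).

    Quadratic (~a^2/2) for |a| << delta, linear (~delta*|a|) for
    |a| >> delta.  Works elementwise on numpy arrays and on autodiff
    tensors alike.
    """
    if delta <= 0:
        raise ValueError("delta must be positive")
    r = a * (1.0 / delta)
    if isinstance(a, Tensor):
        return (((r * r + 1.0) ** 0.5) - 1.0) * delta ** 2
    r = np.asarray(r, dtype=float)
    return delta ** 2 * (np.sqrt(1.0 + r * r) - 1.0)


@dataclass
class TrainResult:
    model: object
    history: pd.DataFrame
    best_val_loss: float


def _window_arrays(windows: Sequence[WindowSample]):
    x = np.stack([w.channels for w in windows])
    y = np.stack([[w.sbp_label, w.dbp_label] for w in windows])
    return x, y


def _stage1_loss(model: ResNet1D, xb: np.ndarray, yb: np.ndarray,
                 delta: float) -> Tensor:
    _, _, y_s, y_d = model(Tensor(xb))
    loss_s = pseudo_huber(y_s - yb[:, 0], delta).mean()
    loss_d = pseudo_huber(y_d - yb[:, 1], delta).mean()
    return loss_s + loss_d


def _eval_stage1(model: ResNet1D, x: np.ndarray, y: np.ndarray,
                 delta: float, batch: int) -> float:
    model.eval()
    total, n = 0.0, 0
    for i in range(0, len(x), batch):
        xb, yb = x[i: i + batch], y[i: i + batch]
        loss = _stage1_loss(model, xb, yb, delta)
        total += float(loss.data) * len(xb)
        n += len(xb)
    model.train()
    return total / max(n, 1)


def fit_stage1(train: Sequence[WindowSample], val: Sequence[WindowSample],
               cfg: TrainConfig, net_cfg: ResNetConfig,
               model_seed: int = 0) -> TrainResult:
    """Train the stage-1 residual network on windowed samples."""
    cfg.validate()
    if not train or not val:
        raise ValueError("empty train or validation split")
    x_tr, y_tr = _window_arrays(train)
    x_va, y_va = _window_arrays(val)
    model = ResNet1D(net_cfg, seed=model_seed)
    model.set_output_scaling(y_tr.mean(axis=0),
                             y_tr.std(axis=0, ddof=0) + 1e-6)
    opt = AdamW(model.parameters(), lr=cfg.lr,
                weight_decay=cfg.weight_decay)
    sched = PlateauScheduler(opt, factor=cfg.plateau_factor,
                             patience=cfg.plateau_patience)
    rng = np.random.default_rng(cfg.seed)
    history, bad = [], 0
    # checkpoint selection includes the untrained state, so training can
    # only improve on (or keep) the initial validation loss
    best_val = _eval_stage1(model, x_va, y_va, cfg.delta, cfg.batch_stage1)
    best_state = _get_state(model)
    model.train()
    for epoch in range(cfg.epochs):
        order = rng.permutation(len(x_tr))
        ep_loss, nb = 0.0, 0
        for i in range(0, len(order), cfg.batch_stage1):
            idx = order[i: i + cfg.batch_stage1]
            loss = _stage1_loss(model, x_tr[idx], y_tr[idx], cfg.delta)
            opt.zero_grad()
            loss.backward()
            opt.step()
            ep_loss += float(loss.data)
            nb += 1
        val_loss = _eval_stage1(model, x_va, y_va, cfg.delta,
                                cfg.batch_stage1)
        sched.step(val_loss)
        history.append({"epoch": epoch, "train_loss": ep_loss / max(nb, 1),
                        "val_loss": val_loss, "lr": opt.lr})
        if val_loss < best_val - 1e-12:
            best_val, best_state, bad = val_loss, _get_state(model), 0
        else:
            bad += 1
            if bad >= cfg.early_stop_patience:
                break
    if best_state is not None:
        _set_state(model, best_state)
    model.eval()
    return TrainResult(model, pd.DataFrame(history), best_val)


def _get_state(model) -> List[np.ndarray]:
    return [a.copy() for a in model.state_arrays()]


def _set_state(model, arrays: Sequence[np.ndarray]) -> None:
    i = 0
    for p in model.parameters():
        p.data = arrays[i].copy()
        i += 1
    for m in model.modules():
        for name in getattr(m, "_buffers", ()):
            setattr(m, name, arrays[i].copy())
            i += 1


def build_sequences(windows: Sequence[WindowSample], bundle: FeatureBundle,
                    t_cfg: TransformerConfig, fusion: bool = True,
                    center=None, scale=None):
    """Chunk same-subject, time-ordered windows into length-T sequences.

    Returns (enc_s, enc_d, prelim, labels, index_map): the per-stream
    fused-vector sequences (B, T, D) for the systolic (X_S) and diastolic
    (X_D) models, the stage-1 preliminary estimates (B, T, 2), the mmHg
    labels (B, T, 2), and the window indices each sequence position came
    from.  Leftover windows that do not fill a sequence are omitted (the
    pipeline falls back to stage-1 predictions for them).
    """
    bundle = fuse(bundle, fusion=fusion, center=center, scale=scale)
    prelim = np.stack([bundle.y_S_prelim, bundle.y_D_prelim], axis=1)
    labels = np.stack([[w.sbp_label for w in windows],
                       [w.dbp_label for w in windows]], axis=1)
    t = t_cfg.sequence_len
    order: Dict[str, List[int]] = {}
    for i, w in enumerate(windows):
        order.setdefault(w.subject_id, []).append(i)
    s_seqs, d_seqs, pre_seqs, lab_seqs, idx_seqs = [], [], [], [], []
    for sid in sorted(order):
        idx = sorted(order[sid], key=lambda i: windows[i].window_index)
        for j in range(0, len(idx) - t + 1, t):
            chunk = idx[j: j + t]
            s_seqs.append(bundle.X_S[chunk])
            d_seqs.append(bundle.X_D[chunk])
            pre_seqs.append(prelim[chunk])
            lab_seqs.append(labels[chunk])
            idx_seqs.append(chunk)
    if not s_seqs:
        d = bundle.X_S.shape[1]
        return (np.empty((0, t, d)), np.empty((0, t, d)),
                np.empty((0, t, 2)), np.empty((0, t, 2)), [])
    return (np.stack(s_seqs), np.stack(d_seqs), np.stack(pre_seqs),
            np.stack(lab_seqs), idx_seqs)


def _stage2_loss(model, enc_s: np.ndarray, enc_d: np.ndarray,
                 pre: np.ndarray, lab: np.ndarray, delta: float) -> Tensor:
    out = model(Tensor(enc_s), Tensor(enc_d), Tensor(pre))
    return pseudo_huber(out - lab, delta).mean(axis=(0, 1)).sum()


def fit_stage2(train_seqs, val_seqs, cfg: TrainConfig,
               t_cfg: TransformerConfig, in_dim: int,
               model_seed: int = 0) -> TrainResult:
    """Train the stage-2 transformers on sequences from a frozen stage 1.

    ``train_seqs`` / ``val_seqs`` are (enc_s, enc_d, prelim, labels)
    tuples as produced by :func:`build_sequences`.
    """
    from .model import DualTransformer
    cfg.validate()
    enc_s_tr, enc_d_tr, pre_tr, lab_tr = train_seqs[:4]
    enc_s_va, enc_d_va, pre_va, lab_va = val_seqs[:4]
    if len(enc_s_tr) == 0 or len(enc_s_va) == 0:
        raise ValueError("empty sequence split")
    if enc_s_tr.shape[1] != lab_tr.shape[1]:
        raise ValueError("sequence/label misalignment")
    model = DualTransformer(in_dim, t_cfg, seed=model_seed)
    model.set_prelim_scaling(pre_tr.reshape(-1, 2).mean(axis=0),
                             pre_tr.reshape(-1, 2).std(axis=0) + 1e-6)
    model.sbp.delta_sd = np.array(
        [max(float(np.abs(pre_tr[:, :, 0] - lab_tr[:, :, 0]).mean()), 1.0)])
    model.dbp.delta_sd = np.array(
        [max(float(np.abs(pre_tr[:, :, 1] - lab_tr[:, :, 1]).mean()), 1.0)])
    opt = AdamW(model.parameters(), lr=cfg.lr, weight_decay=cfg.weight_decay)
    sched = PlateauScheduler(opt, factor=cfg.plateau_factor,
                             patience=cfg.plateau_patience)
    rng = np.random.default_rng(cfg.seed + 1)
    history, bad = [], 0
    model.eval()
    # near-identity start: selecting from the untrained state onwards
    # guarantees the refinement validates no worse than stage 1 alone
    best_val = float(_stage2_loss(model, enc_s_va, enc_d_va, pre_va,
                                  lab_va, cfg.delta).data)
    best_state = _get_state(model)
    model.train()
    for epoch in range(cfg.epochs):
        order = rng.permutation(len(enc_s_tr))
        ep_loss, nb = 0.0, 0
        for i in range(0, len(order), cfg.batch_stage2):
            idx = order[i: i + cfg.batch_stage2]
            loss = _stage2_loss(model, enc_s_tr[idx], enc_d_tr[idx],
                                pre_tr[idx], lab_tr[idx], cfg.delta)
            opt.zero_grad()
            loss.backward()
            opt.step()
            ep_loss += float(loss.data)
            nb += 1
        model.eval()
        val_loss = float(_stage2_loss(model, enc_s_va, enc_d_va, pre_va,
                                      lab_va, cfg.delta).data)
        model.train()
        sched.step(val_loss)
        history.append({"epoch": epoch, "train_loss": ep_loss / max(nb, 1),
                        "val_loss": val_loss, "lr": opt.lr})
        if val_loss < best_val - 1e-12:
            best_val, best_state, bad = val_loss, _get_state(model), 0
        else:
            bad += 1
            if bad >= cfg.early_stop_patience:
                break
    if best_state is not None:
        _set_state(model, best_state)
    model.eval()
    return TrainResult(model, pd.DataFrame(history), best_val)


def predict_stage1(model: ResNet1D, windows: Sequence[WindowSample],
                   batch: int = 64) -> np.ndarray:
    """Per-window (N, 2) mmHg predictions from stage 1 alone."""
    preds = []
    for i in range(0, len(windows), batch):
        b = stage1_forward(model, windows[i: i + batch])
        preds.append(np.stack([b.y_S_prelim, b.y_D_prelim], axis=1))
    return np.concatenate(preds) if preds else np.empty((0, 2))


def predict_pipeline(stage1: ResNet1D, stage2,
                     windows: Sequence[WindowSample],
                     t_cfg: TransformerConfig, fusion: bool = True,
                     batch: int = 64) -> np.ndarray:
    """Full-pipeline (N, 2) predictions for a list of windows.

    Windows not covered by a complete stage-2 sequence keep their stage-1
    estimate.
    """
    preds = predict_stage1(stage1, windows, batch=batch)
    if stage2 is None or not windows:
        return preds
    bundles = []
    for i in range(0, len(windows), batch):
        bundles.append(stage1_forward(stage1, windows[i: i + batch]))
    bundle = FeatureBundle(
        F_S=np.concatenate([b.F_S for b in bundles]),
        F_D=np.concatenate([b.F_D for b in bundles]),
        y_S_prelim=np.concatenate([b.y_S_prelim for b in bundles]),
        y_D_prelim=np.concatenate([b.y_D_prelim for b in bundles]))
    enc_s, enc_d, pre, _, idx_map = build_sequences(
        windows, bundle, t_cfg, fusion=fusion,
        center=stage1.out_mean, scale=stage1.out_sd)
    stage2.eval()
    for i in range(0, len(enc_s), batch):
        out = stage2(Tensor(enc_s[i: i + batch]),
                     Tensor(enc_d[i: i + batch]),
                     Tensor(pre[i: i + batch])).data
        for row, chunk in zip(out, idx_map[i: i + batch]):
            preds[chunk] = row
    return preds


def mean_predictor_baseline(train: Sequence[WindowSample],
                            test: Sequence[WindowSample]) -> np.ndarray:
    """Constant predictor: the training-split mean labels."""
    _, y_tr = _window_arrays(train)
    mean = y_tr.mean(axis=0)
    return np.tile(mean, (len(test), 1))
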