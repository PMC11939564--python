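"""The cascaded dual-stage blood-pressure regressor.

Stage 1 is a 1-D residual network (ResNet-18 layout by default: a stride-2
stem convolution, max-pooling, four stages of basic blocks with identity
skip connections, global average pooling).  Two branch heads map the pooled
trunk features to pressure-specific feature vectors F_S and F_D and to
preliminary systolic / diastolic estimates.

Feature fusion exploits the strong SBP-DBP coupling: the systolic feature
vector is extended with the *diastolic* preliminary estimate and vice versa
(X_S = [F_S, y_D / 200], X_D = [F_D, y_S / 200]).

Stage 2 is a pair of transformer encoder-decoders (one per pressure) over
short sequences of consecutive windows.  Each encoder ingests its stream's
fused vectors (embedded + sine-cosine positional encoding); each decoder
runs masked self-attention over a start token followed by that stream's
embedded stage-1 preliminary estimates (shifted right, so position t only
sees estimates up to t-1) and cross-attends to the encoder output.  The
output head predicts a residual correction added to the stage-1
preliminary estimate, so stage 2 refines rather than replaces stage 1.
Keeping the streams separate is what makes the cross-fusion informative:
without it, the systolic model never sees any diastolic evidence.

Both stages regress in a normalized output space: predictions are
``mean + sd * raw`` with the scaling frozen from the training labels.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .config import ResNetConfig, TransformerConfig
from .nn import (AdamW, BatchNorm1d, Conv1d, LayerNorm, Linear, MaxPool1d,
                 Module, MultiHeadAttention, ReLU, Sequential, Tensor,
                 causal_mask, concat, positional_encoding_matrix)
from .segmentation import WindowSample

__all__ = ["FeatureBundle", "BasicBlock1d", "ResNet1D", "BPTransformer",
           "DualTransformer", "stage1_forward", "fuse", "stage2_forward",
           "PRELIM_SCALE"]

# preliminary mmHg estimates are divided by this before entering feature
# space, so their magnitude matches unit-norm features
PRELIM_SCALE = 200.0


@dataclass
class FeatureBundle:
    """Stage-1 outputs for a batch of windows."""

    F_S: np.ndarray           # (N, n) systolic feature vectors
    F_D: np.ndarray           # (N, n) diastolic feature vectors
    y_S_prelim: np.ndarray    # (N,) preliminary SBP, mmHg
    y_D_prelim: np.ndarray    # (N,) preliminary DBP, mmHg
    X_S: Optional[np.ndarray] = None  # (N, n+1) fused systolic matrix
    X_D: Optional[np.ndarray] = None


class BasicBlock1d(Module):
    """Two 3-tap convolutions with batch norm around an identity skip:
    y = F(x) + x (1x1 projection on the skip when shape changes)."""

    def __init__(self, in_ch: int, out_ch: int, stride: int,
                 rng: np.random.Generator):
        self.conv1 = Conv1d(in_ch, out_ch, 3, rng, stride=stride, padding=1)
        self.bn1 = BatchNorm1d(out_ch)
        self.conv2 = Conv1d(out_ch, out_ch, 3, rng, stride=1, padding=1)
        self.bn2 = BatchNorm1d(out_ch)
        if stride != 1 or in_ch != out_ch:
            self.down: Optional[Sequential] = Sequential(
                Conv1d(in_ch, out_ch, 1, rng, stride=stride),
                BatchNorm1d(out_ch))
        else:
            self.down = None

    def forward(self, x: Tensor) -> Tensor:
        res = self.bn2(self.conv2(self.bn1(self.conv1(x)).relu()))
        skip = self.down(x) if self.down is not None else x
        return (res + skip).relu()


class _Trunk(Module):
    def __init__(self, cfg: ResNetConfig, rng: np.random.Generator):
        w = cfg.stem_width
        self.stem = Sequential(
            Conv1d(cfg.in_channels, w, 7, rng, stride=2, padding=3),
            BatchNorm1d(w), ReLU(), MaxPool1d(3, 2, 1))
        blocks: List[Module] = []
        widths = [w, 2 * w, 4 * w, 8 * w]
        in_ch = w
        for stage, (width, n_blocks) in enumerate(zip(widths,
                                                      cfg.stage_blocks)):
            for b in range(n_blocks):
                stride = 2 if (stage > 0 and b == 0) else 1
                blocks.append(BasicBlock1d(in_ch, width, stride, rng))
                in_ch = width
        self.blocks = blocks
        self.out_ch = in_ch

    def forward(self, x: Tensor) -> Tensor:
        x = self.stem(x)
        for blk in self.blocks:
            x = blk(x)
        return x.mean(axis=2)          # global average pool -> (N, C)


class ResNet1D(Module):
    """Stage-1 network: shared (or dual) trunk with systolic/diastolic
    branch feature vectors and dense preliminary-prediction heads."""

    def __init__(self, cfg: ResNetConfig, seed: int = 0):
        cfg.validate()
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        self.trunk = _Trunk(cfg, rng)
        self.trunk_d = None if cfg.shared_trunk else _Trunk(cfg, rng)
        c = self.trunk.out_ch
        n = cfg.feature_dim
        self.branch_s = Sequential(Linear(c, n, rng), ReLU())
        self.branch_d = Sequential(Linear(c, n, rng), ReLU())
        self.head_s = Linear(n, 1, rng, weight_scale=np.sqrt(1.0 / n))
        self.head_d = Linear(n, 1, rng, weight_scale=np.sqrt(1.0 / n))
        # output scaling (mmHg) frozen from training labels
        self.out_mean = np.array([120.0, 75.0])
        self.out_sd = np.array([15.0, 10.0])

    _buffers = ("out_mean", "out_sd")

    def set_output_scaling(self, mean: Sequence[float],
                           sd: Sequence[float]) -> None:
        self.out_mean = np.asarray(mean, dtype=float)
        self.out_sd = np.maximum(np.asarray(sd, dtype=float), 1e-6)

    def forward(self, x: Tensor) -> Tuple[Tensor, Tensor, Tensor, Tensor]:
        """(N, 2, L) batch -> (F_S, F_D, y_S, y_D) with pressures in mmHg."""
        feat_s_in = self.trunk(x)
        feat_d_in = feat_s_in if self.trunk_d is None else self.trunk_d(x)
        F_S = self.branch_s(feat_s_in)
        F_D = self.branch_d(feat_d_in)
        y_S = self.head_s(F_S).reshape(-1) * self.out_sd[0] + self.out_mean[0]
        y_D = self.head_d(F_D).reshape(-1) * self.out_sd[1] + self.out_mean[1]
        return F_S, F_D, y_S, y_D


def stage1_forward(model: ResNet1D,
                   windows: Sequence[WindowSample]) -> FeatureBundle:
    """Run stage 1 in inference mode over a batch of windows."""
    was_training = model.training
    model.eval()
    x = Tensor(np.stack([w.channels for w in windows]))
    F_S, F_D, y_S, y_D = model(x)
    if was_training:
        model.train()
    return FeatureBundle(F_S=F_S.data, F_D=F_D.data,
                         y_S_prelim=y_S.data, y_D_prelim=y_D.data)


def fuse(bundle: FeatureBundle, fusion: bool = True,
         center: Optional[np.ndarray] = None,
         scale: Optional[np.ndarray] = None) -> FeatureBundle:
    """Cross-couple the preliminary estimates into the feature matrices.

    X_S gets the scaled *diastolic* estimate and X_D the *systolic* one;
    with ``fusion=False`` (ablation) the features pass through unchanged.

    By default the appended estimate is divided by 200 mmHg so its
    magnitude matches the unit-norm features.  Passing ``center`` and
    ``scale`` (e.g. the stage-1 output statistics, frozen from the
    training labels) z-scores it instead, which also matches its
    *variance* to the feature scale and makes the cross signal easier for
    the second stage to exploit.
    """
    if fusion:
        if bundle.y_S_prelim is None or bundle.y_D_prelim is None:
            raise ValueError("preliminary predictions missing")
        c = np.zeros(2) if center is None else np.asarray(center, float)
        s = np.full(2, PRELIM_SCALE) if scale is None \
            else np.asarray(scale, float)
        y_s = ((bundle.y_S_prelim - c[0]) / s[0])[:, None]
        y_d = ((bundle.y_D_prelim - c[1]) / s[1])[:, None]
        bundle.X_S = np.concatenate([bundle.F_S, y_d], axis=1)
        bundle.X_D = np.concatenate([bundle.F_D, y_s], axis=1)
    else:
        bundle.X_S = bundle.F_S
        bundle.X_D = bundle.F_D
    return bundle


class _EncoderLayer(Module):
    def __init__(self, cfg: TransformerConfig, rng: np.random.Generator):
        self.mha = MultiHeadAttention(cfg.d_model, cfg.n_heads, rng)
        self.ln1 = LayerNorm(cfg.d_model)
        self.ffn = Sequential(Linear(cfg.d_model, cfg.d_ff, rng), ReLU(),
                              Linear(cfg.d_ff, cfg.d_model, rng))
        self.ln2 = LayerNorm(cfg.d_model)

    def forward(self, x: Tensor) -> Tensor:
        x = self.ln1(x + self.mha(x, x, x))
        return self.ln2(x + self.ffn(x))


class _DecoderLayer(Module):
    def __init__(self, cfg: TransformerConfig, rng: np.random.Generator):
        self.self_mha = MultiHeadAttention(cfg.d_model, cfg.n_heads, rng)
        self.ln1 = LayerNorm(cfg.d_model)
        self.cross_mha = MultiHeadAttention(cfg.d_model, cfg.n_heads, rng)
        self.ln2 = LayerNorm(cfg.d_model)
        self.ffn = Sequential(Linear(cfg.d_model, cfg.d_ff, rng), ReLU(),
                              Linear(cfg.d_ff, cfg.d_model, rng))
        self.ln3 = LayerNorm(cfg.d_model)

    def forward(self, d: Tensor, enc: Tensor,
                mask: np.ndarray) -> Tensor:
        d = self.ln1(d + self.self_mha(d, d, d, mask=mask))
        d = self.ln2(d + self.cross_mha(d, enc, enc))
        return self.ln3(d + self.ffn(d))


class BPTransformer(Module):
    """Stage-2 sequence regressor for one pressure stream.

    The encoder ingests that stream's fused vectors (X_S sequences for the
    systolic model, X_D for the diastolic one); the decoder runs masked
    self-attention over a start token plus the stream's embedded stage-1
    preliminary estimates shifted right, cross-attends to the encoder, and
    the near-zero output head adds a residual correction to the
    preliminary estimate.
    """

    _buffers = ("delta_sd",)

    def __init__(self, in_dim: int, cfg: TransformerConfig, seed: int = 0,
                 dec_dim: int = 1):
        cfg.validate()
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        d = cfg.d_model
        self.embed = Linear(in_dim, d, rng)       # encoder embedding
        self.embed_dec = Linear(dec_dim, d, rng)  # prelim-token embedding
        self.start_token = Tensor(rng.normal(0, 0.02, (1, 1, d)),
                                  requires_grad=True)
        self.enc_layers = [_EncoderLayer(cfg, rng)
                           for _ in range(cfg.encoder_layers)]
        self.dec_layers = [_DecoderLayer(cfg, rng)
                           for _ in range(cfg.decoder_layers)]
        # near-zero head: stage 2 starts as the identity refinement
        self.head = Linear(d, 1, rng, weight_scale=0.01 / np.sqrt(d))
        self.delta_sd = np.array([10.0])  # mmHg scale of corrections

    def forward(self, enc_in: Tensor, prelim: Tensor,
                dec_tokens: Optional[Tensor] = None) -> Tensor:
        """Refine (B, T, 1) mmHg preliminaries given (B, T, in_dim) fused
        sequences.

        ``dec_tokens`` are the (already scaled) decoder inputs; they
        default to prelim / 200.
        """
        b, t = enc_in.shape[0], enc_in.shape[1]
        if t != self.cfg.sequence_len:
            raise ValueError(
                f"sequence length {t} != configured {self.cfg.sequence_len}")
        if dec_tokens is None:
            dec_tokens = prelim * (1.0 / PRELIM_SCALE)
        pe = Tensor(positional_encoding_matrix(t, self.cfg.d_model)[None])
        x = self.embed(enc_in) + pe
        for layer in self.enc_layers:
            x = layer(x)
        # decoder stream: start token, then embedded tokens shifted right
        dec_tok = self.embed_dec(dec_tokens[:, :-1, :])
        start = self.start_token + Tensor(np.zeros((b, 1, self.cfg.d_model)))
        d = concat([start, dec_tok], axis=1) + pe
        mask = causal_mask(t)
        for layer in self.dec_layers:
            d = layer(d, x, mask)
        delta = self.head(d) * Tensor(self.delta_sd[None, None, :])
        return prelim + delta


class DualTransformer(Module):
    """Paired systolic/diastolic stage-2 models with a (B, T, 2) API.

    In fusion mode (``cfg.fusion``) each stream's decoder receives both
    z-scored preliminary estimates, so the cross-pressure signal
    conditions the residual correction directly; without fusion each
    decoder sees only its own stream's estimate.
    """

    _buffers = ("prelim_center", "prelim_scale")

    def __init__(self, in_dim: int, cfg: TransformerConfig, seed: int = 0):
        dec_dim = 2 if cfg.fusion else 1
        self.sbp = BPTransformer(in_dim, cfg, seed=seed, dec_dim=dec_dim)
        self.dbp = BPTransformer(in_dim, cfg, seed=seed + 1000,
                                 dec_dim=dec_dim)
        self.cfg = cfg
        self.prelim_center = np.zeros(2)
        self.prelim_scale = np.full(2, PRELIM_SCALE)

    def set_prelim_scaling(self, center, scale) -> None:
        self.prelim_center = np.asarray(center, dtype=float)
        self.prelim_scale = np.maximum(np.asarray(scale, dtype=float), 1e-6)

    def forward(self, enc_s: Tensor, enc_d: Tensor,
                prelim: Tensor) -> Tensor:
        z = (prelim - Tensor(self.prelim_center[None, None, :])) \
            * Tensor(1.0 / self.prelim_scale[None, None, :])
        if self.cfg.fusion:
            tok_s = tok_d = z
        else:
            tok_s, tok_d = z[:, :, 0:1], z[:, :, 1:2]
        out_s = self.sbp(enc_s, prelim[:, :, 0:1], dec_tokens=tok_s)
        out_d = self.dbp(enc_d, prelim[:, :, 1:2], dec_tokens=tok_d)
        return concat([out_s, out_d], axis=2)


def stage2_forward(model: DualTransformer, enc_s: np.ndarray,
                   enc_d: np.ndarray, prelim: np.ndarray) -> np.ndarray:
    """Inference-mode stage-2 pass; returns (B, T, 2) mmHg predictions."""
    was_training = model.training
    model.eval()
    out = model(Tensor(enc_s), Tensor(enc_d), Tensor(prelim)).data
    if was_training:
        model.train()
    return out
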