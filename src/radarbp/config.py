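"""Configuration records for the whole pipeline.

Every tunable lives in one of the dataclasses below, so a single YAML file
(see :mod:`radarbp.cli`) pins an entire run: simulation, preprocessing,
windowing, both network stages, and the training regime.  Defaults marked
"protocol" mirror the acquisition/training protocol the method was designed
for (2000 Hz radar, 200 Hz BP, 0.5-15 Hz band, 150 Hz working rate,
65/15/20 splits, Adam at 1e-3 with plateau halving); the rest are this
package's own choices, discussed in docs/methods.md.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass, field
from typing import Tuple


def _check_finite(name: str, *values: float) -> None:
    for v in values:
        if not math.isfinite(v):
            raise ValueError(f"{name}: non-finite value {v!r}")


@dataclass
class SimConfig:
    """Parameters of the radar/BP co-simulator.

    The simulator emulates a chest-displacement signal (respiration +
    per-beat cardiac micro-vibration + noise) wrapped into radar I/Q phase,
    and a beat-resolved arterial pressure waveform whose systolic peaks and
    diastolic troughs drift over time.
    """

    duration_s: float = 60.0
    radar_fs: float = 2000.0          # Hz, protocol
    bp_fs: float = 200.0              # Hz, protocol
    wavelength: float = 0.0125        # m; 24 GHz carrier
    hr_range: Tuple[float, float] = (55.0, 95.0)   # beats/min
    resp_rate: float = 0.25           # Hz
    resp_amp_mm: float = 1.5          # mm peak respiration displacement
    sbp_range: Tuple[float, float] = (100.0, 160.0)  # mmHg
    dbp_range: Tuple[float, float] = (55.0, 95.0)    # mmHg
    bp_drift_sd: float = 1.2          # mmHg innovation per beat of the drift process
    sbp_dbp_corr: float = 0.7         # shared-component weight of the drift
    pulse_amp_gain: float = 0.01      # mm of chest pulse per mmHg pulse pressure
    noise_sd: float = 0.05            # mm of additive displacement noise
    scenario: str = "rest"            # rest | valsalva | apnea | tilt
    t0_offset: float = 0.0            # s, radar-vs-BP clock offset
    seed: int = 0

    def validate(self) -> None:
        _check_finite("duration_s", self.duration_s)
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        for name in ("radar_fs", "bp_fs", "wavelength", "resp_rate"):
            v = getattr(self, name)
            _check_finite(name, v)
            if v <= 0:
                raise ValueError(f"{name} must be positive")
        _check_finite("noise", self.noise_sd, self.bp_drift_sd,
                      self.pulse_amp_gain, self.resp_amp_mm, self.t0_offset)
        lo, hi = self.hr_range
        if not (0 < lo <= hi):
            raise ValueError("hr_range must be a positive interval")
        slo, shi = self.sbp_range
        dlo, dhi = self.dbp_range
        # physiologic admissibility: inside the 40-180 mmHg band used for
        # outlier rejection downstream
        if not (40.0 < slo <= shi <= 180.0):
            raise ValueError("sbp_range must lie within (40, 180]")
        if not (40.0 <= dlo <= dhi < 180.0):
            raise ValueError("dbp_range must lie within [40, 180)")
        if self.scenario not in ("rest", "valsalva", "apnea", "tilt"):
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if not 0.0 <= self.sbp_dbp_corr <= 1.0:
            raise ValueError("sbp_dbp_corr must be in [0, 1]")


@dataclass
class PrepConfig:
    """Radar preprocessing chain parameters."""

    band: Tuple[float, float] = (0.5, 15.0)  # Hz, protocol
    butter_order: int = 4                    # protocol
    target_fs: float = 150.0                 # Hz, protocol
    derivative_order: int = 2                # second channel; 1/3 for ablations
    guard_s: float = 0.25                    # s trimmed at record edges

    def validate(self) -> None:
        lo, hi = self.band
        if not (0 < lo < hi < self.target_fs / 2):
            raise ValueError("band must satisfy 0 < low < high < target_fs/2")
        if self.butter_order < 1:
            raise ValueError("butter_order must be >= 1")
        if self.derivative_order not in (0, 1, 2, 3):
            raise ValueError("derivative_order must be one of 0,1,2,3")
        if self.guard_s < 0:
            raise ValueError("guard_s must be >= 0")


@dataclass
class SplitSpec:
    """Train/validation/test partitioning."""

    fractions: Tuple[float, float, float] = (0.65, 0.15, 0.20)  # protocol
    mode: str = "window"  # "window" | "subject"
    seed: int = 0

    def validate(self) -> None:
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValueError("fractions must sum to 1")
        if any(f < 0 for f in self.fractions):
            raise ValueError("fractions must be non-negative")
        if self.mode not in ("window", "subject"):
            raise ValueError("mode must be 'window' or 'subject'")


@dataclass
class ResNetConfig:
    """Stage-1 1D residual network."""

    in_channels: int = 2
    stem_width: int = 64
    stage_blocks: Tuple[int, int, int, int] = (2, 2, 2, 2)  # ResNet-18 layout
    feature_dim: int = 512     # length n of the F_S / F_D branch vectors
    shared_trunk: bool = True  # False -> independent trunks per pressure

    def validate(self) -> None:
        if self.in_channels < 1 or self.stem_width < 1 or self.feature_dim < 1:
            raise ValueError("widths must be positive")
        if len(self.stage_blocks) != 4 or any(b < 1 for b in self.stage_blocks):
            raise ValueError("stage_blocks must be 4 positive counts")


@dataclass
class TransformerConfig:
    """Stage-2 sequence regressor."""

    d_model: int = 64
    n_heads: int = 4
    encoder_layers: int = 2
    decoder_layers: int = 2
    d_ff: int = 128
    sequence_len: int = 8   # consecutive windows per sequence
    fusion: bool = True     # append the crossed preliminary estimate

    @property
    def d_k(self) -> int:
        return self.d_model // self.n_heads

    def validate(self) -> None:
        if self.d_model % self.n_heads != 0:
            raise ValueError("d_model must be divisible by n_heads")
        if min(self.d_model, self.n_heads, self.encoder_layers,
               self.decoder_layers, self.d_ff, self.sequence_len) < 1:
            raise ValueError("all transformer sizes must be positive")


@dataclass
class TrainConfig:
    """Optimization regime shared by both stages."""

    lr: float = 0.001              # protocol
    plateau_factor: float = 0.5    # protocol
    plateau_patience: int = 5      # epochs, protocol
    weight_decay: float = 0.002    # decoupled L2, protocol
    epochs: int = 60               # protocol maximum
    batch_stage1: int = 32         # protocol
    batch_stage2: int = 4          # protocol
    delta: float = 5.0             # mmHg, Pseudo-Huber scale
    early_stop_patience: int = 10  # epochs
    seed: int = 0

    def validate(self) -> None:
        if min(self.lr, self.weight_decay, self.delta) <= 0 and self.weight_decay != 0:
            raise ValueError("lr and delta must be positive, weight_decay >= 0")
        if self.lr <= 0 or self.delta <= 0 or self.weight_decay < 0:
            raise ValueError("lr and delta must be positive, weight_decay >= 0")
        if not 0 < self.plateau_factor < 1:
            raise ValueError("plateau_factor must be in (0, 1)")
        if min(self.plateau_patience, self.epochs, self.batch_stage1,
               self.batch_stage2, self.early_stop_patience) < 1:
            raise ValueError("epoch/batch/patience counts must be positive")


@dataclass
class PipelineConfig:
    """Everything needed to reproduce a full run."""

    sim: SimConfig = field(default_factory=SimConfig)
    prep: PrepConfig = field(default_factory=PrepConfig)
    split: SplitSpec = field(default_factory=SplitSpec)
    resnet: ResNetConfig = field(default_factory=ResNetConfig)
    transformer: TransformerConfig = field(default_factory=TransformerConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    window_s: float = 2.0
    n_subjects: int = 30
    seed: int = 0
    output_dir: str = "runs"

    def validate(self) -> None:
        for sub in (self.sim, self.prep, self.split, self.resnet,
                    self.transformer, self.train):
            sub.validate()
        if self.window_s <= 0:
            raise ValueError("window_s must be positive")
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")

    # -- lossless round-trip through plain dicts (YAML/JSON friendly) -------

    def to_dict(self) -> dict:
        return _asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        return _fromdict(cls, d)

    def config_hash(self) -> str:
        """Stable hash of the full configuration, for provenance logs."""
        blob = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _asdict(obj):
    if dataclasses.is_dataclass(obj):
        return {f.name: _asdict(getattr(obj, f.name))
                for f in dataclasses.fields(obj)}
    if isinstance(obj, tuple):
        return list(obj)
    return obj


_NESTED = {"sim": SimConfig, "prep": PrepConfig, "split": SplitSpec,
           "resnet": ResNetConfig, "transformer": TransformerConfig,
           "train": TrainConfig}


def _fromdict(cls, d: dict):
    kwargs = {}
    for f in dataclasses.fields(cls):
        if f.name not in d:
            continue
        v = d[f.name]
        if f.name in _NESTED and cls is PipelineConfig:
            kwargs[f.name] = _fromdict(_NESTED[f.name], v)
        elif isinstance(v, list):
            kwargs[f.name] = tuple(v)
        else:
            kwargs[f.name] = v
    return cls(**kwargs)
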