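"""Radar preprocessing chain.

Order of operations, fixed by the pipeline contract:

    demodulate -> bandpass -> resample -> (segment) -> detrend
               -> derivative -> L2-normalize

Demodulation recovers chest displacement from I/Q via the four-quadrant
arctangent scaled by wavelength/(4*pi).  The band-pass is a bidirectional
(forward-backward, hence zero-phase) 4th-order Butterworth with a
0.5-15 Hz passband; resampling to the 150 Hz working rate is rational
polyphase (2000 -> 150 Hz is the non-integer ratio 40/3).  Per-window
detrending removes a least-squares line (intercept + slope), the second
centred difference supplies the acceleration-like second channel, and each
channel is scaled to unit Euclidean norm.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import signal as sps

from .config import PrepConfig

__all__ = ["Signal", "TrendModel", "demodulate", "bandpass", "resample_to",
           "detrend", "nth_derivative", "l2_normalize", "preprocess_record"]


@dataclass
class Signal:
    """A uniformly sampled real series with its sampling rate."""

    samples: np.ndarray
    fs: float
    t_start: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.samples.size and not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")

    @property
    def Ts(self) -> float:
        return 1.0 / self.fs

    @property
    def duration(self) -> float:
        return self.samples.size / self.fs

    def times(self) -> np.ndarray:
        return self.t_start + np.arange(self.samples.size) / self.fs


@dataclass
class TrendModel:
    """OLS line removed by :func:`detrend` (units of the input signal)."""

    alpha0: float        # intercept
    alpha1: float        # slope per sample index
    residual: np.ndarray


def demodulate(i: Signal, q: Signal, wavelength: float) -> Signal:
    """Arctangent demodulation of radar I/Q into displacement (mm).

    displacement = unwrap(atan2(q, i)) * wavelength / (4*pi), referenced so
    the first sample is zero (radar phase has an arbitrary constant offset).
    """
    if i.samples.size != q.samples.size or i.fs != q.fs:
        raise ValueError("I and Q must share length and sampling rate")
    if i.samples.size == 0:
        raise ValueError("empty input")
    mag = np.hypot(i.samples, q.samples)
    if np.any(mag < 1e-12):
        raise ValueError("zero-magnitude I/Q sample: phase undefined")
    phase = np.unwrap(np.arctan2(q.samples, i.samples))
    disp_m = phase * wavelength / (4 * np.pi)
    disp_mm = (disp_m - disp_m[0]) * 1000.0
    return Signal(disp_mm, i.fs, i.t_start)


def _design_bandpass(cfg: PrepConfig, fs: float) -> np.ndarray:
    nyq = fs / 2.0
    lo, hi = cfg.band
    if not (0 < lo < hi < nyq):
        raise ValueError(f"band {cfg.band} outside (0, {nyq}) Hz")
    # second-order sections: numerically stable even when the band sits far
    # below Nyquist (0.5 Hz edge at a 2000 Hz rate)
    return sps.butter(cfg.butter_order, [lo, hi], btype="bandpass", fs=fs,
                      output="sos")


def bandpass(x: Signal, cfg: PrepConfig) -> Signal:
    """Zero-phase (forward-backward) Butterworth band-pass.

    Bidirectional application cancels the filter's phase response, so
    band-interior components come through with zero lag; the effective
    magnitude response is the squared one-pass response.  Odd-reflection
    padding of 3x the filter length handles the edges.
    """
    sos = _design_bandpass(cfg, x.fs)
    padlen = 3 * (2 * sos.shape[0] + 1)
    if x.samples.size <= padlen:
        raise ValueError(f"input too short for filtering (need > {padlen})")
    y = sps.sosfiltfilt(sos, x.samples, padtype="odd", padlen=padlen)
    return Signal(y, x.fs, x.t_start)


def bandpass_gain(cfg: PrepConfig, fs: float, freq: float) -> float:
    """Analytic magnitude gain of the bidirectional filter at ``freq`` (Hz).

    Oracle used in tests: the forward-backward pass applies |H(f)|^2.
    """
    sos = _design_bandpass(cfg, fs)
    _, h = sps.sosfreqz(sos, worN=[freq], fs=fs)
    return float(np.abs(h[0]) ** 2)


def resample_to(x: Signal, target_fs: float) -> Signal:
    """Rational polyphase resampling (anti-aliased) to a lower rate."""
    if target_fs >= x.fs:
        raise ValueError("resample_to only downsamples")
    frac = Fraction(target_fs / x.fs).limit_denominator(1000)
    y = sps.resample_poly(x.samples, frac.numerator, frac.denominator)
    return Signal(y, target_fs, x.t_start)


def detrend(x: Signal) -> tuple[Signal, TrendModel]:
    """Remove the least-squares line a0 + a1*i over the window.

    The regressor is the sample index; the residual has (numerically) zero
    mean and zero correlation with the index.
    """
    n = x.samples.size
    if n < 2:
        raise ValueError("detrend needs at least 2 samples")
    idx = np.arange(n, dtype=float)
    alpha1, alpha0 = np.polyfit(idx, x.samples, 1)
    residual = x.samples - (alpha0 + alpha1 * idx)
    return (Signal(residual, x.fs, x.t_start),
            TrendModel(float(alpha0), float(alpha1), residual))


def nth_derivative(x: Signal, order: int) -> Signal:
    """Finite-difference derivative channels.

    Order 2 is the centred scheme y''[n] = (y[n+1] - 2 y[n] + y[n-1]) / Ts^2
    (exact for quadratics).  Orders 1 and 3 use the first-difference kernel
    applied iteratively; odd orders therefore carry a half-sample alignment
    offset, which is irrelevant downstream because each window is
    L2-normalized per channel.  Replicate-edge padding preserves length.
    """
    if order not in (1, 2, 3):
        raise ValueError("order must be 1, 2 or 3")
    y = x.samples
    if y.size < order + 1:
        raise ValueError("input too short for requested order")
    # binomial difference kernel of the requested order
    kernel = np.array([1.0])
    for _ in range(order):
        kernel = np.convolve(kernel, [1.0, -1.0])
    pad_left = order // 2
    pad_right = order - pad_left
    yp = np.pad(y, (pad_left, pad_right), mode="edge")
    d = np.convolve(yp, kernel, mode="valid") / x.Ts ** order
    return Signal(d, x.fs, x.t_start)


def l2_normalize(x: np.ndarray) -> np.ndarray:
    """Scale a vector to unit Euclidean norm (direction preserved)."""
    x = np.asarray(x, dtype=float)
    norm = np.linalg.norm(x)
    if norm < 1e-15:
        raise ValueError("zero vector cannot be L2-normalized")
    return x / norm


def preprocess_record(radar_i: Signal, radar_q: Signal, wavelength: float,
                      cfg: PrepConfig) -> Signal:
    """Record-level chain: demodulate -> bandpass -> resample -> guard-trim.

    Returns the radar chest micro-vibration signal (RCMV) at the working
    rate.  Per-window detrend / derivative / normalization happen at
    segmentation time (see :mod:`radarbp.segmentation`).
    """
    cfg.validate()
    disp = demodulate(radar_i, radar_q, wavelength)
    filt = bandpass(disp, cfg)
    rcmv = resample_to(filt, cfg.target_fs)
    if cfg.guard_s > 0:
        g = int(round(cfg.guard_s * rcmv.fs))
        if 2 * g >= rcmv.samples.size:
            raise ValueError("guard interval longer than record")
        rcmv = Signal(rcmv.samples[g: rcmv.samples.size - g], rcmv.fs,
                      rcmv.t_start + g / rcmv.fs)
    return rcmv
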