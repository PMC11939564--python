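"""Synthetic radar / blood-pressure co-simulator.

Generates subject records with the statistical structure the estimation
pipeline assumes: a chest-displacement signal (respiration sinusoid +
per-beat cardiac micro-vibration + Gaussian noise) wrapped into radar I/Q
phase, and a beat-resolved arterial pressure waveform whose systolic peaks
and diastolic troughs drift as correlated bounded random walks.  The cardiac
pulse amplitude in the displacement is proportional to the instantaneous
pulse pressure (SBP - DBP), so the radar channel genuinely carries the BP
information a downstream regressor is meant to recover.

Everything is driven by a single integer seed; identical (config, seed)
pairs produce bit-identical records.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional

import numpy as np
import pandas as pd

from .config import SimConfig

__all__ = ["SubjectRecord", "simulate_subject", "simulate_cohort",
           "pulse_amplitude"]

# minimum systolic-diastolic separation enforced per beat, mmHg
_MIN_PULSE_PRESSURE = 10.0
# fraction of the beat interval spent on the linear rise to the systolic peak
_RISE_FRACTION = 0.15
# raised-cosine cardiac bump width as a fraction of the beat interval
_PULSE_WIDTH_FRACTION = 0.3


@dataclass
class SubjectRecord:
    """One subject's synchronized radar and BP recording."""

    radar_i: np.ndarray          # unitless I channel at radar_fs
    radar_q: np.ndarray          # unitless Q channel at radar_fs
    radar_fs: float              # Hz
    bp_wave: np.ndarray          # mmHg at bp_fs
    bp_fs: float                 # Hz
    truth: pd.DataFrame          # columns: beat_time (s), sbp, dbp (mmHg)
    scenario: str
    seed: int
    t0_offset: float = 0.0       # s; radar stream lags the BP clock by this
    displacement_mm: Optional[np.ndarray] = None  # ground-truth chest motion
    subject_id: str = "s000"
    config: Optional[SimConfig] = None


def pulse_amplitude(pulse_pressure: np.ndarray | float,
                    gain: float) -> np.ndarray | float:
    """Chest micro-vibration amplitude (mm) for a given pulse pressure (mmHg).

    Strictly increasing in pulse pressure by construction, which is what
    gives the regression stages signal to exploit.
    """
    return gain * np.asarray(pulse_pressure, dtype=float)


def _reflect(x: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Reflect values into [lo, hi] (folded boundary)."""
    if hi <= lo:
        return np.full_like(x, lo)
    span = hi - lo
    y = np.mod(x - lo, 2 * span)
    y = np.where(y > span, 2 * span - y, y)
    return lo + y


def _beat_processes(cfg: SimConfig, rng: np.random.Generator):
    """Beat times (systolic-peak times, first at t=0) and per-beat SBP/DBP."""
    hr_lo, hr_hi = cfg.hr_range
    # generous upper bound on beat count
    n_max = int(np.ceil(cfg.duration_s * hr_hi / 60.0)) + 2
    hr0 = rng.uniform(hr_lo, hr_hi)
    hr_steps = rng.normal(0.0, 1.0, n_max)          # bpm random walk
    hr = _reflect(hr0 + np.cumsum(hr_steps), hr_lo, hr_hi)

    peaks = [0.0]
    while True:
        interval = 60.0 / hr[min(len(peaks) - 1, n_max - 1)]
        t_next = peaks[-1] + interval
        if t_next >= cfg.duration_s:
            break
        peaks.append(t_next)
    n_beats = len(peaks)
    peaks = np.asarray(peaks)

    # correlated SBP/DBP drift: mean-reverting (AR(1)) latent processes
    # built from a shared component plus independent ones, so the
    # stationary level correlation equals sbp_dbp_corr (~0.7 by default,
    # the strong systolic-diastolic coupling seen physiologically).
    # bp_drift_sd is the per-beat innovation in mmHg; the mean-reversion
    # coefficient sets a drift timescale of ~20 beats.
    phi = 0.95
    c = cfg.sbp_dbp_corr

    def _ar1_unit(n: int) -> np.ndarray:
        """Unit-stationary-variance AR(1) sample path."""
        x = np.empty(n)
        x[0] = rng.normal()
        innov = rng.normal(0.0, np.sqrt(1.0 - phi ** 2), n)
        for k in range(1, n):
            x[k] = phi * x[k - 1] + innov[k]
        return x

    shared = _ar1_unit(n_beats)
    eps_s = _ar1_unit(n_beats)
    eps_d = _ar1_unit(n_beats)
    w_sh, w_in = np.sqrt(c), np.sqrt(1.0 - c)
    slo, shi = cfg.sbp_range
    dlo, dhi = cfg.dbp_range
    sbp0 = rng.uniform(slo, shi)
    dbp0 = rng.uniform(dlo, dhi)
    sigma = cfg.bp_drift_sd / np.sqrt(1.0 - phi ** 2)
    sbp = sbp0 + sigma * (w_sh * shared + w_in * eps_s)
    dbp = dbp0 + sigma * (w_sh * shared + w_in * eps_d)

    if cfg.scenario in ("valsalva", "tilt"):
        # transient maneuver: +/-20 mmHg triangular ramp over the middle third
        sign = 1.0 if cfg.scenario == "valsalva" else -1.0
        t1, t2 = cfg.duration_s / 3.0, 2.0 * cfg.duration_s / 3.0
        mid = 0.5 * (t1 + t2)
        ramp = np.clip(1.0 - np.abs(peaks - mid) / (mid - t1 + 1e-12), 0.0, 1.0)
        sbp = sbp + sign * 20.0 * ramp
        dbp = dbp + sign * 20.0 * ramp

    sbp = _reflect(sbp, slo, shi)
    dbp = _reflect(dbp, dlo, dhi)
    dbp = np.minimum(dbp, sbp - _MIN_PULSE_PRESSURE)   # physiologic ordering
    return peaks, sbp, dbp


def _bp_waveform(cfg: SimConfig, peaks: np.ndarray, sbp: np.ndarray,
                 dbp: np.ndarray) -> np.ndarray:
    """Piecewise pressure waveform: exponential decay SBP->DBP after each
    peak, then a linear rise (0.15 x interval) into the next peak.

    The decay uses a shifted exponential that hits DBP exactly at the trough,
    so waveform extrema match the per-beat truth to numerical precision.
    """
    n = int(round(cfg.duration_s * cfg.bp_fs))
    t = np.arange(n) / cfg.bp_fs
    wave = np.empty(n)
    n_beats = len(peaks)
    median_iv = float(np.median(np.diff(peaks))) if n_beats > 1 else 60.0 / 70.0

    for k in range(n_beats):
        p_k = peaks[k]
        p_next = peaks[k + 1] if k + 1 < n_beats else None
        if p_next is not None:
            interval = p_next - p_k
            trough = p_next - _RISE_FRACTION * interval
        else:
            trough = min(p_k + (1.0 - _RISE_FRACTION) * median_iv,
                         cfg.duration_s)
        span = max(trough - p_k, 1.0 / cfg.bp_fs)
        tau = span / 3.0
        seg_end = p_next if p_next is not None else cfg.duration_s
        m = (t >= p_k) & (t < seg_end)
        tt = t[m] - p_k
        denom = 1.0 - np.exp(-span / tau)
        decay = sbp[k] - (sbp[k] - dbp[k]) * (1.0 - np.exp(-np.minimum(tt, span) / tau)) / denom
        if p_next is not None:
            rise_mask = tt > span
            frac = (tt[rise_mask] - span) / max(seg_end - p_k - span, 1e-9)
            decay[rise_mask] = dbp[k] + (sbp[k + 1] - dbp[k]) * frac
        wave[m] = decay
    wave[t < peaks[0]] = sbp[0]   # empty in practice: first peak is at t=0
    return wave


def _raised_cosine(tt: np.ndarray, center: float, width: float) -> np.ndarray:
    """Hanning bump of unit peak centred at ``center`` (zero outside)."""
    arg = (tt - center) / width
    bump = np.where(np.abs(arg) < 0.5,
                    0.5 * (1.0 + np.cos(2 * np.pi * arg)), 0.0)
    return bump


def _displacement(cfg: SimConfig, peaks: np.ndarray, sbp: np.ndarray,
                  dbp: np.ndarray, t: np.ndarray,
                  resp_phase: float) -> np.ndarray:
    """Noise-free chest displacement (mm) evaluated at times ``t``.

    Each beat contributes a primary raised-cosine bump plus a smaller
    reflected-wave bump.  Amplitude scales with pulse pressure; morphology
    encodes the pressures themselves, mimicking pressure-dependent arterial
    stiffness: higher SBP narrows the primary upstroke and pulls the
    reflected wave earlier (faster pulse-wave velocity), while the
    reflected wave's relative amplitude grows with DBP (augmentation).
    This matters because windows are L2-normalized downstream, which
    discards absolute amplitude; the shape cues keep the pressures
    recoverable from normalized windows.
    """
    resp_amp = 0.0 if cfg.scenario == "apnea" else cfg.resp_amp_mm
    d = resp_amp * np.sin(2 * np.pi * cfg.resp_rate * t + resp_phase)
    n_beats = len(peaks)
    intervals = np.diff(peaks)
    median_iv = float(np.median(intervals)) if n_beats > 1 else 60.0 / 70.0
    for k in range(n_beats):
        iv = intervals[k] if k < n_beats - 1 else median_iv
        # normalized pressures in [0, 1] over the admissible 40-180 band
        s_frac = np.clip((sbp[k] - 90.0) / 90.0, 0.0, 1.0)
        d_frac = np.clip((dbp[k] - 40.0) / 80.0, 0.0, 1.0)
        width = (_PULSE_WIDTH_FRACTION - 0.12 * s_frac) * iv
        refl_delay = (0.42 - 0.18 * s_frac) * iv     # earlier when stiffer
        refl_frac = 0.25 + 0.35 * d_frac             # augmentation index
        amp = pulse_amplitude(sbp[k] - dbp[k], cfg.pulse_amp_gain)
        span = refl_delay + width
        lo = np.searchsorted(t, peaks[k] - width)
        hi = np.searchsorted(t, peaks[k] + span)
        if hi > lo:
            tt = t[lo:hi] - peaks[k]
            d[lo:hi] += amp * (_raised_cosine(tt, 0.0, width)
                               + refl_frac * _raised_cosine(
                                   tt, refl_delay, 1.6 * width))
    return d


def simulate_subject(config: SimConfig) -> SubjectRecord:
    """Simulate one subject's synchronized radar I/Q and BP recording."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    resp_phase = rng.uniform(0.0, 2 * np.pi)
    peaks, sbp, dbp = _beat_processes(config, rng)
    bp_wave = _bp_waveform(config, peaks, sbp, dbp)

    n_radar = int(round(config.duration_s * config.radar_fs))
    t_radar = np.arange(n_radar) / config.radar_fs
    # the radar stream lags the BP clock by t0_offset: at radar time t the
    # chest is at its state of BP-clock time t - t0_offset
    d = _displacement(config, peaks, sbp, dbp, t_radar - config.t0_offset,
                      resp_phase)
    if config.noise_sd > 0:
        d = d + rng.normal(0.0, config.noise_sd, n_radar)
    phase = 4 * np.pi * (d / 1000.0) / config.wavelength
    record = SubjectRecord(
        radar_i=np.cos(phase),
        radar_q=np.sin(phase),
        radar_fs=config.radar_fs,
        bp_wave=bp_wave,
        bp_fs=config.bp_fs,
        truth=pd.DataFrame({"beat_time": peaks, "sbp": sbp, "dbp": dbp}),
        scenario=config.scenario,
        seed=config.seed,
        t0_offset=config.t0_offset,
        displacement_mm=d,
        config=config,
    )
    return record


def simulate_cohort(n_subjects: int, base: SimConfig,
                    seed: int) -> List[SubjectRecord]:
    """Simulate a cohort with inter-subject variation of BP level and HR.

    Each subject gets a reproducible child seed of ``seed`` plus a personal
    baseline: BP ranges re-centred around a drawn resting level and an HR
    band shifted within the cohort band.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    base.validate()
    master = np.random.default_rng(seed)
    child_seeds = master.integers(0, 2**31 - 1, size=n_subjects)
    records = []
    for idx in range(n_subjects):
        slo, shi = base.sbp_range
        dlo, dhi = base.dbp_range
        s_center = master.uniform(slo + 10, shi - 10) if shi - slo > 20 \
            else 0.5 * (slo + shi)
        d_center = master.uniform(dlo + 5, dhi - 5) if dhi - dlo > 10 \
            else 0.5 * (dlo + dhi)
        hr_lo, hr_hi = base.hr_range
        hr_shift = master.uniform(-5.0, 5.0) if hr_hi - hr_lo > 10 else 0.0
        cfg = SimConfig(**{**base.__dict__,
                           "sbp_range": (max(slo, s_center - 15),
                                         min(shi, s_center + 15)),
                           "dbp_range": (max(dlo, d_center - 10),
                                         min(dhi, d_center + 10)),
                           "hr_range": (max(30.0, hr_lo + hr_shift),
                                        max(31.0, hr_hi + hr_shift)),
                           "seed": int(child_seeds[idx])})
        rec = simulate_subject(cfg)
        rec.subject_id = f"s{idx:03d}"
        records.append(rec)
    return records
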