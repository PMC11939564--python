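"""Beat detection, outlier rejection, BP-peak-anchored windowing, label
assignment, and train/val/test splitting.

Systolic peaks of the arterial waveform are the temporal landmarks: the
first valid peak anchors a grid of fixed-duration, non-overlapping windows.
Each window carries two L2-normalized channels (detrended chest
micro-vibration and its finite-difference derivative) and is labeled with
the mean systolic / diastolic pressure of the beats whose peaks fall inside
it.  Windows touching an invalid beat (outlier pressure, incomplete beat)
or containing no complete beat are dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np
from scipy import signal as sps

from .config import PrepConfig, SplitSpec
from .preprocess import Signal, detrend, l2_normalize, nth_derivative, \
    preprocess_record
from .simulate import SubjectRecord

__all__ = ["BeatAnnotation", "WindowSample", "detect_beats", "flag_outliers",
           "segment", "make_splits", "windows_from_record"]

# physiologic admissibility band for pressures, mmHg
BP_LOW, BP_HIGH = 40.0, 180.0
# systolic peak detection: minimum inter-peak spacing and prominence
MIN_PEAK_DISTANCE_S = 0.33
MIN_PROMINENCE_MMHG = 10.0


@dataclass
class BeatAnnotation:
    """One heartbeat located on the pressure waveform."""

    peak_index: int      # sample index of the systolic peak
    sbp: float           # mmHg at the peak
    trough_index: int    # sample index of the following diastolic trough
    dbp: float           # mmHg at the trough
    valid: bool = True


@dataclass
class WindowSample:
    """A fixed-length dual-channel input window with its BP labels."""

    channels: np.ndarray      # (2, L); rows L2-normalized
    sbp_label: float          # mmHg
    dbp_label: float          # mmHg
    subject_id: str = "s000"
    scenario: str = "rest"
    window_start_s: float = 0.0
    window_index: int = 0     # position in the record's window grid


def detect_beats(bp: Signal) -> List[BeatAnnotation]:
    """Locate systolic peaks and the diastolic troughs between them.

    Peaks are local maxima at least 0.33 s apart with >= 10 mmHg prominence;
    a peak at the very first sample counts (recordings may start
    peak-aligned).  The trough of a beat is the minimum between its peak and
    the next peak; the final beat uses the minimum up to the record end and
    is only valid when at least the minimum beat spacing remains.
    """
    x = bp.samples
    if x.size < bp.fs:
        raise ValueError("need at least 1 s of pressure samples")
    if np.ptp(x) == 0:
        return []
    # pad the start below the signal floor so a recording that begins on a
    # systolic peak still yields that first beat; the end is not padded (a
    # final-sample maximum has no beat behind it)
    pad = x.min() - 2 * MIN_PROMINENCE_MMHG
    xp = np.concatenate(([pad], x))
    dist = max(1, int(round(MIN_PEAK_DISTANCE_S * bp.fs)))
    peaks, _ = sps.find_peaks(xp, distance=dist,
                              prominence=MIN_PROMINENCE_MMHG)
    peaks = peaks - 1   # undo padding offset
    peaks = peaks[(peaks >= 0) & (peaks < x.size)]
    beats: List[BeatAnnotation] = []
    for j, p in enumerate(peaks):
        if j + 1 < peaks.size:
            seg_end = peaks[j + 1]
            complete = True
        else:
            seg_end = x.size
            complete = (x.size - p) >= dist
        if seg_end - p < 2:
            complete = False
            trough = min(p + 1, x.size - 1)
        else:
            trough = p + 1 + int(np.argmin(x[p + 1: seg_end]))
        sbp = float(x[p])
        dbp = float(x[trough])
        beats.append(BeatAnnotation(peak_index=int(p), sbp=sbp,
                                    trough_index=int(trough), dbp=dbp,
                                    valid=complete and dbp < sbp))
    return beats


def flag_outliers(beats: Sequence[BeatAnnotation]) -> List[BeatAnnotation]:
    """Mark beats with pressures outside the (40, 180) mmHg band invalid.

    Readings above 180 mmHg or below 40 mmHg are treated as measurement
    outliers; order is preserved and already-invalid beats stay invalid.
    """
    out = []
    for b in beats:
        ok = b.valid and (BP_LOW <= b.dbp) and (b.sbp <= BP_HIGH) \
            and (BP_LOW <= b.sbp) and (b.dbp <= BP_HIGH)
        out.append(BeatAnnotation(b.peak_index, b.sbp, b.trough_index,
                                  b.dbp, valid=ok))
    return out


def segment(rcmv: Signal, bp: Signal, beats: Sequence[BeatAnnotation],
            window_s: float, cfg: PrepConfig, *, subject_id: str = "s000",
            scenario: str = "rest") -> Tuple[List[WindowSample], Dict[str, int]]:
    """Tile non-overlapping windows anchored at the first valid peak.

    Returns the emitted windows plus a conservation ledger
    ``{"tiled": n, "emitted": e, "dropped": d}`` with e + d = n.
    """
    L = int(round(window_s * rcmv.fs))
    if L > rcmv.samples.size:
        raise ValueError("window longer than record")
    valid_beats = [b for b in beats if b.valid]
    if not valid_beats:
        return [], {"tiled": 0, "emitted": 0, "dropped": 0}
    anchor = bp.t_start + valid_beats[0].peak_index / bp.fs
    rcmv_end = rcmv.t_start + rcmv.samples.size / rcmv.fs
    bp_end = bp.t_start + bp.samples.size / bp.fs
    end_time = min(rcmv_end, bp_end)

    peak_times = np.array([bp.t_start + b.peak_index / bp.fs for b in beats])
    validity = np.array([b.valid for b in beats])
    sbps = np.array([b.sbp for b in beats])
    dbps = np.array([b.dbp for b in beats])

    windows: List[WindowSample] = []
    tiled = emitted = 0
    k = 0
    while True:
        start = anchor + k * window_s
        stop = start + window_s
        if stop > end_time + 1e-9:
            break
        k += 1
        if start < rcmv.t_start - 1e-9:
            continue   # window precedes the radar record (guard trim)
        tiled += 1
        i0 = int(round((start - rcmv.t_start) * rcmv.fs))
        if i0 < 0 or i0 + L > rcmv.samples.size:
            continue
        in_win = (peak_times >= start - 1e-9) & (peak_times < stop - 1e-9)
        if not in_win.any() or not validity[in_win].all():
            continue   # dropped: no complete beat, or touches an invalid one
        seg = Signal(rcmv.samples[i0: i0 + L], rcmv.fs, start)
        det, _ = detrend(seg)
        try:
            ch0 = l2_normalize(det.samples)
            if cfg.derivative_order == 0:
                ch1 = ch0.copy()
            else:
                ch1 = l2_normalize(
                    nth_derivative(det, cfg.derivative_order).samples)
        except ValueError:
            continue   # degenerate (flat) window
        windows.append(WindowSample(
            channels=np.stack([ch0, ch1]),
            sbp_label=float(sbps[in_win].mean()),
            dbp_label=float(dbps[in_win].mean()),
            subject_id=subject_id, scenario=scenario,
            window_start_s=float(start), window_index=k - 1))
        emitted += 1
    return windows, {"tiled": tiled, "emitted": emitted,
                     "dropped": tiled - emitted}


def windows_from_record(record: SubjectRecord, cfg: PrepConfig,
                        window_s: float = 2.0) -> Tuple[List[WindowSample],
                                                        Dict[str, int]]:
    """Full per-record chain: preprocess, detect beats, reject outliers,
    window and label."""
    rcmv = preprocess_record(
        Signal(record.radar_i, record.radar_fs),
        Signal(record.radar_q, record.radar_fs),
        record.config.wavelength if record.config else 0.0125, cfg)
    bp = Signal(record.bp_wave, record.bp_fs)
    beats = flag_outliers(detect_beats(bp))
    return segment(rcmv, bp, beats, window_s, cfg,
                   subject_id=record.subject_id, scenario=record.scenario)


def make_splits(windows: Sequence[WindowSample],
                spec: SplitSpec) -> Tuple[List[WindowSample],
                                          List[WindowSample],
                                          List[WindowSample]]:
    """Seeded shuffle + partition into train/val/test.

    Window mode permutes windows; subject mode permutes subjects and keeps
    each subject's windows in a single partition.
    """
    spec.validate()
    if len(windows) < 10:
        raise ValueError("need at least 10 windows to split")
    rng = np.random.default_rng(spec.seed)
    f_train, f_val, _ = spec.fractions
    if spec.mode == "window":
        order = rng.permutation(len(windows))
        n_train = int(round(f_train * len(windows)))
        n_val = int(round(f_val * len(windows)))
        idx_train = order[:n_train]
        idx_val = order[n_train: n_train + n_val]
        idx_test = order[n_train + n_val:]
        return ([windows[i] for i in idx_train],
                [windows[i] for i in idx_val],
                [windows[i] for i in idx_test])
    subjects = sorted({w.subject_id for w in windows})
    order = rng.permutation(len(subjects))
    n_train = int(round(f_train * len(subjects)))
    n_val = int(round(f_val * len(subjects)))
    train_ids = {subjects[i] for i in order[:n_train]}
    val_ids = {subjects[i] for i in order[n_train: n_train + n_val]}
    train = [w for w in windows if w.subject_id in train_ids]
    val = [w for w in windows if w.subject_id in val_ids]
    test = [w for w in windows
            if w.subject_id not in train_ids and w.subject_id not in val_ids]
    return train, val, test
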