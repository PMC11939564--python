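"""Beat detection, outlier handling, windowing and splits."""

import numpy as np
import pytest

from radarbp.config import PrepConfig, SimConfig, SplitSpec
from radarbp.preprocess import Signal
from radarbp.segmentation import (BeatAnnotation, detect_beats,
                                  flag_outliers, make_splits, segment,
                                  windows_from_record)
from radarbp.simulate import simulate_cohort, simulate_subject


def _triangle_pulse(fs=200.0, base=60.0, peak=120.0):
    """One triangular pressure pulse base -> peak -> base over 1 s,
    padded with baseline."""
    up = np.linspace(base, peak, int(0.3 * fs))
    down = np.linspace(peak, base, int(0.7 * fs))
    pad = np.full(int(fs), base)
    return Signal(np.concatenate([pad, up, down, pad]), fs)


class TestDetectBeats:
    def test_single_triangle_pulse(self):
        beats = detect_beats(_triangle_pulse())
        assert len(beats) == 1
        assert beats[0].sbp == pytest.approx(120.0)
        assert beats[0].dbp == pytest.approx(60.0)

    def test_monotone_ramp_has_no_beats(self):
        beats = detect_beats(Signal(np.linspace(60, 120, 400), 200.0))
        assert beats == []

    def test_flat_signal_has_no_beats(self):
        assert detect_beats(Signal(np.full(400, 80.0), 200.0)) == []

    def test_recovers_simulator_truth(self, noise_free_record):
        rec = noise_free_record
        beats = detect_beats(Signal(rec.bp_wave, rec.bp_fs))
        valid = [b for b in beats if b.valid]
        truth = rec.truth
        n = min(len(valid), len(truth))
        sbp_err = np.abs([valid[i].sbp - truth.sbp.iloc[i]
                          for i in range(n)])
        dbp_err = np.abs([valid[i].dbp - truth.dbp.iloc[i]
                          for i in range(n)])
        hit = np.mean((sbp_err < 1.0) & (dbp_err < 1.0))
        assert hit >= 0.95

    def test_peak_indices_strictly_increasing(self, drifting_record):
        beats = detect_beats(Signal(drifting_record.bp_wave,
                                    drifting_record.bp_fs))
        idx = [b.peak_index for b in beats]
        assert np.all(np.diff(idx) > 0)


class TestFlagOutliers:
    @pytest.mark.parametrize("sbp,dbp,expect", [
        (185.0, 70.0, False),   # systolic above the 180 mmHg ceiling
        (120.0, 38.0, False),   # diastolic below the 40 mmHg floor
        (120.0, 80.0, True),    # interior point
        (180.0, 40.0, True),    # band edges are admissible
    ])
    def test_band_logic(self, sbp, dbp, expect):
        b = BeatAnnotation(10, sbp, 20, dbp, valid=True)
        assert flag_outliers([b])[0].valid is expect

    def test_order_preserved_and_invalid_stays_invalid(self):
        beats = [BeatAnnotation(10, 120, 20, 80, valid=False),
                 BeatAnnotation(30, 130, 40, 85, valid=True)]
        out = flag_outliers(beats)
        assert [b.peak_index for b in out] == [10, 30]
        assert out[0].valid is False and out[1].valid is True


class TestSegment:
    def test_sixty_second_record_gives_thirty_windows(
            self, noise_free_record, prep_nog):
        windows, stats = windows_from_record(noise_free_record, prep_nog,
                                             2.0)
        assert len(windows) == 30
        assert stats == {"tiled": 30, "emitted": 30, "dropped": 0}

    def test_single_beat_window_labels(self):
        """A window holding exactly one beat carries that beat's values."""
        fs = 150.0
        rcmv = Signal(np.sin(2 * np.pi * 2 * np.arange(900) / fs), fs)
        bp = Signal(np.zeros(1200), 200.0)
        beats = [BeatAnnotation(60, 120.0, 160, 80.0, valid=True),
                 BeatAnnotation(560, 126.0, 660, 84.0, valid=True)]
        wins, _ = segment(rcmv, bp, beats, 2.0, PrepConfig())
        assert wins[0].sbp_label == pytest.approx(120.0)
        assert wins[0].dbp_label == pytest.approx(80.0)

    def test_window_with_invalid_beat_dropped(self, noise_free_record,
                                              prep_nog):
        rec = noise_free_record
        from radarbp.preprocess import preprocess_record
        rcmv = preprocess_record(Signal(rec.radar_i, rec.radar_fs),
                                 Signal(rec.radar_q, rec.radar_fs),
                                 rec.config.wavelength, prep_nog)
        beats = flag_outliers(detect_beats(Signal(rec.bp_wave, rec.bp_fs)))
        # invalidate one mid-record beat; its window must disappear
        beats[10] = BeatAnnotation(beats[10].peak_index, 190.0,
                                   beats[10].trough_index, beats[10].dbp,
                                   valid=False)
        wins, stats = segment(rcmv, Signal(rec.bp_wave, rec.bp_fs), beats,
                              2.0, prep_nog)
        assert stats["dropped"] >= 1
        assert stats["emitted"] + stats["dropped"] == stats["tiled"]
        bad_t = beats[10].peak_index / rec.bp_fs
        for w in wins:
            assert not (w.window_start_s <= bad_t < w.window_start_s + 2.0)

    def test_windows_do_not_overlap(self, drifting_record, prep_nog):
        wins, _ = windows_from_record(drifting_record, prep_nog, 2.0)
        starts = sorted(w.window_start_s for w in wins)
        assert all(b - a >= 2.0 - 1e-9 for a, b in zip(starts, starts[1:]))

    def test_labels_within_physiologic_band_and_normalized(
            self, drifting_record, prep_nog):
        wins, _ = windows_from_record(drifting_record, prep_nog, 2.0)
        for w in wins:
            assert 40.0 <= w.dbp_label < w.sbp_label <= 180.0
            norms = np.linalg.norm(w.channels, axis=1)
            assert np.allclose(norms, 1.0, atol=1e-9)

    def test_label_recovery_noise_free(self, drifting_record, prep_nog):
        """Window labels track generator truth within 1 mmHg on average."""
        wins, _ = windows_from_record(drifting_record, prep_nog, 2.0)
        truth = drifting_record.truth
        errs = []
        for w in wins:
            m = truth.beat_time.between(w.window_start_s,
                                        w.window_start_s + 2.0 - 1e-9)
            if m.any():
                errs.append(abs(truth.sbp[m].mean() - w.sbp_label))
                errs.append(abs(truth.dbp[m].mean() - w.dbp_label))
        assert np.mean(errs) < 1.0

    def test_window_longer_than_record_raises(self):
        with pytest.raises(ValueError):
            segment(Signal(np.zeros(100), 150.0),
                    Signal(np.zeros(100), 200.0), [], 10.0, PrepConfig())


class TestSplits:
    def _windows(self, n, subjects=1):
        from radarbp.segmentation import WindowSample
        return [WindowSample(channels=np.zeros((2, 4)), sbp_label=120.0,
                             dbp_label=80.0,
                             subject_id=f"s{i % subjects:03d}",
                             window_index=i) for i in range(n)]

    def test_default_fractions_on_100_windows(self):
        tr, va, te = make_splits(self._windows(100), SplitSpec(seed=0))
        assert (len(tr), len(va), len(te)) == (65, 15, 20)

    def test_same_seed_same_partition(self):
        w = self._windows(50)
        a = make_splits(w, SplitSpec(seed=3))
        b = make_splits(w, SplitSpec(seed=3))
        for pa, pb in zip(a, b):
            assert [id(x) for x in pa] == [id(x) for x in pb]

    def test_partitions_disjoint_and_exhaustive(self):
        w = self._windows(73)
        tr, va, te = make_splits(w, SplitSpec(seed=1))
        ids = [id(x) for x in tr + va + te]
        assert len(ids) == len(set(ids)) == 73

    def test_subject_level_mode_keeps_subjects_whole(self):
        w = self._windows(300, subjects=30)
        tr, va, te = make_splits(w, SplitSpec(seed=2, mode="subject"))
        sets = [{x.subject_id for x in part} for part in (tr, va, te)]
        assert not (sets[0] & sets[1] or sets[0] & sets[2]
                    or sets[1] & sets[2])

    def test_bad_fractions_rejected(self):
        with pytest.raises(ValueError):
            make_splits(self._windows(20),
                        SplitSpec(fractions=(0.5, 0.2, 0.2)))


def test_cohort_windows_conservation(small_cohort, prep_nog):
    for rec in small_cohort:
        wins, stats = windows_from_record(rec, prep_nog, 2.0)
        assert stats["emitted"] == len(wins)
        assert stats["emitted"] + stats["dropped"] == stats["tiled"]
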