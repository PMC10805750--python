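"""Conditioning chain: resampling, peak detection, QC gates, segmentation, slicing."""

import numpy as np
import pytest

from ecg2ppg import preprocess as pp
from ecg2ppg import signalsim as ss


def _record_from(ecg, fs, ppg=None, annotations=None, rhythm="AF"):
    return ss.WaveformRecord(ecg=ecg, ppg=ppg, fs=fs, rhythm_label=rhythm,
                             subject_id="t", annotations=annotations or [])


class TestResample:
    def test_ratio_one_fifth(self):
        rec = _record_from(np.random.default_rng(0).normal(size=5000), 500.0)
        out = pp.resample(rec, 100.0)
        assert out.fs == 100.0 and out.n_samples == 1000

    def test_identity_when_target_equals_fs(self, af_record):
        out = pp.resample(af_record, af_record.fs)
        assert np.array_equal(out.ecg, af_record.ecg)

    def test_sine_against_closed_form(self):
        t500 = np.arange(5000) / 500.0
        rec = _record_from(np.sin(2 * np.pi * 1.0 * t500), 500.0)
        out = pp.resample(rec, 100.0)
        t100 = np.arange(1000) / 100.0
        expect = np.sin(2 * np.pi * 1.0 * t100)
        core = slice(20, -20)  # ignore filter edge transients
        r = np.corrcoef(out.ecg[core], expect[core])[0, 1]
        assert r > 0.999

    def test_annotations_rescaled_inward(self):
        rec = _record_from(np.zeros(5000) + np.random.default_rng(1).normal(size=5000),
                           500.0, annotations=[(500, 4500, "AF")])
        out = pp.resample(rec, 100.0)
        (s, e, r), = out.annotations
        assert (s, e, r) == (100, 900, "AF")

    def test_zero_length_rejected(self):
        rec = _record_from(np.ones(5), 500.0)
        rec.ecg = np.empty(0)
        with pytest.raises(ValueError):
            pp.resample(rec, 100.0)


class TestPeakDetection:
    def test_r_peak_count_and_accuracy_60bpm(self):
        rr = np.full(32, 1.0)
        ecg = ss.synth_ecg(rr, ss.MorphologySpec(noise_sd=0.0), 100.0)[:3000]
        beats = pp.detect_r_peaks(ecg, 100.0)
        assert 29 <= beats.n_peaks <= 31
        truth = ss.r_peak_times(rr)
        det = beats.peak_indices / 100.0
        assert max(np.min(np.abs(det - t)) for t in truth[:29]) < 0.020

    def test_flat_signal_yields_no_peaks(self):
        assert pp.detect_r_peaks(np.zeros(3000), 100.0).n_peaks == 0
        assert pp.detect_ppg_peaks(np.full(3000, 0.3), 100.0).n_peaks == 0

    def test_af_detected_cv_tracks_generating_cv(self):
        spec = ss.RhythmSpec(rhythm="AF", mean_hr=80.0, af_cv=0.24, seed=21)
        rec = ss.make_record(spec, ss.MorphologySpec(), 120.0)
        beats = pp.detect_r_peaks(rec.ecg, rec.fs)
        iv = beats.intervals()
        cv = iv.std() / iv.mean()
        assert abs(cv - spec.af_cv) / spec.af_cv < 0.20

    def test_ppg_peaks_match_construction(self):
        rr = np.full(32, 1.0)
        m = ss.MorphologySpec(noise_sd=0.0)
        ppg = ss.synth_ppg(rr, m, 100.0)[:3000]
        beats = pp.detect_ppg_peaks(ppg, 100.0)
        assert 29 <= beats.n_peaks <= 31
        truth = ss.r_peak_times(rr) + m.ptt
        det = beats.peak_indices / 100.0
        assert max(np.min(np.abs(det - t)) for t in truth[:29]) < 0.030

    def test_paired_channels_agree_on_beat_count(self, af_record):
        r = pp.detect_r_peaks(af_record.ecg, af_record.fs)
        p = pp.detect_ppg_peaks(af_record.ppg, af_record.fs)
        assert abs(r.n_peaks - p.n_peaks) <= 1


class TestIntervalCorrelationAndQC:
    def test_shifted_copy_correlates_perfectly(self):
        idx = np.cumsum(np.random.default_rng(3).integers(60, 140, size=40))
        a = pp.BeatSeries(idx, 100.0, "ECG")
        b = pp.BeatSeries(idx + 25, 100.0, "PPG")
        assert pp.interval_correlation(a, b) == pytest.approx(1.0)

    def test_clean_pair_above_threshold(self, af_record):
        qc = pp.qc_screen(af_record)
        assert qc.passed and qc.interval_correlation > 0.96

    def test_mismatched_pair_rejected(self):
        a = ss.make_record(ss.RhythmSpec(rhythm="AF", mean_hr=90, seed=1),
                           ss.MorphologySpec(), 60.0)
        b = ss.make_record(ss.RhythmSpec(rhythm="AF", mean_hr=90, seed=2),
                           ss.MorphologySpec(), 60.0)
        franken = _record_from(a.ecg, 100.0, ppg=b.ppg,
                               annotations=[(0, 6000, "AF")])
        qc = pp.qc_screen(franken)
        assert not qc.passed
        assert qc.interval_correlation < 0.96

    def test_too_few_peaks_fails_with_reason(self):
        a = pp.BeatSeries(np.array([10, 100]), 100.0, "ECG")
        b = pp.BeatSeries(np.array([10, 100, 200]), 100.0, "PPG")
        assert np.isnan(pp.interval_correlation(a, b))

    def test_low_hr_excluded(self):
        # 20 bpm: 3-s beats, 60 s of signal
        rr = np.full(22, 3.0)
        m = ss.MorphologySpec(noise_sd=0.0)
        rec = _record_from(ss.synth_ecg(rr, m, 100.0), 100.0,
                           ppg=ss.synth_ppg(rr, m, 100.0))
        qc = pp.qc_screen(rec)
        assert not qc.passed
        assert any("floor" in r for r in qc.reasons)
        assert qc.mean_hr < 30.0

    def test_impossible_threshold_fails_clean_record(self, af_record):
        assert not pp.qc_screen(af_record, threshold=1.0).passed

    def test_qc_deterministic(self, af_record):
        a, b = pp.qc_screen(af_record), pp.qc_screen(af_record)
        assert a.passed == b.passed
        assert a.interval_correlation == b.interval_correlation


class TestSegmentation:
    def _annotated(self, n_s, spans, fs=100.0):
        rng = np.random.default_rng(5)
        n = int(n_s * fs)
        return _record_from(rng.normal(size=n), fs, ppg=rng.normal(size=n),
                            annotations=spans)

    def test_95s_span_gives_three_segments(self):
        rec = self._annotated(95, [(0, 9500, "AF")])
        store = pp.segment_annotated(rec, "AF", 30.0)
        assert len(store) == 3 and store.segments.shape[-1] == 3000

    def test_span_below_window_gives_none(self):
        rec = self._annotated(29, [(0, 2900, "AF")])
        assert len(pp.segment_annotated(rec, "AF", 30.0)) == 0

    def test_windows_never_cross_span_boundaries(self):
        rec = self._annotated(130, [(0, 6000, "AF"), (7000, 13000, "AF")])
        store = pp.segment_annotated(rec, "AF", 30.0)
        assert len(store) == 4  # two 60-s spans -> 2 + 2

    def test_no_matching_annotation_empty(self):
        rec = self._annotated(60, [(0, 6000, "SR")])
        assert len(pp.segment_annotated(rec, "AF", 30.0)) == 0


class TestSlicing:
    def _store(self, n_parents, seconds=30.0, fs=100.0):
        n = int(seconds * fs)
        rng = np.random.default_rng(9)
        return pp.SegmentStore(
            rng.normal(size=(n_parents, n)),
            np.array(["AF"] * n_parents, dtype=object),
            np.array(["real"] * n_parents, dtype=object),
            np.array([f"p{i}" for i in range(n_parents)], dtype=object),
            fs, seconds)

    def test_compat_mode_gives_fifteen_slices(self):
        out = pp.slice_segments(self._store(1))
        assert len(out) == 15
        assert out.segments.shape[-1] == 1500

    def test_full_enumeration_gives_sixteen(self):
        out = pp.slice_segments(self._store(1), compat=False)
        assert len(out) == 16

    def test_identity_window_single_slice(self):
        out = pp.slice_segments(self._store(3), slice_seconds=30.0)
        assert len(out) == 3

    def test_labels_and_parents_inherited(self):
        out = pp.slice_segments(self._store(2))
        assert set(out.parent_id) == {"p0", "p1"}
        assert all(out.labels == "AF")

    def test_bad_stride_rejected(self):
        with pytest.raises(ValueError):
            pp.slice_segments(self._store(1), stride_seconds=0.0)

    def test_paired_store_slices_both_channels(self, paired_store):
        out = pp.slice_segments(paired_store)
        assert out.segments.ndim == 3 and out.segments.shape[1] == 2
        assert out.segments.shape[-1] == 1500
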