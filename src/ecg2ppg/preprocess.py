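"""Data conditioning: resampling, peak detection, interval-correlation QC, slicing.

The conditioning chain mirrors the standard preparation of paired ECG/PPG
recordings for a beat-locked translation model: downsample to a common rate
(100 Hz), detect ECG R-peaks with the Pan–Tompkins algorithm and PPG systolic
peaks with prominence-based local-maximum search, keep only records whose two
inter-peak-interval sequences agree (Pearson r > 0.96) and whose detected mean
heart rate is at least 30 beats/min, then cut rhythm-annotated regions into
fixed 30-s segments and slide a 15-s window in 1-s steps over each.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
from scipy import signal as sps

from .signalsim import WaveformRecord, minmax_scale

__all__ = [
    "BeatSeries",
    "QCReport",
    "SegmentStore",
    "resample",
    "detect_r_peaks",
    "detect_ppg_peaks",
    "interval_correlation",
    "qc_screen",
    "segment_annotated",
    "slice_segments",
]

QC_CORR_THRESHOLD = 0.96
HR_FLOOR_BPM = 30.0
MAX_HR_BPM = 220.0


@dataclass
class BeatSeries:
    """Ordered peak sample-indices for one channel; the unit of rhythm QC."""

    peak_indices: np.ndarray
    fs: float
    channel: str  # "ECG" | "PPG"

    def __post_init__(self) -> None:
        self.peak_indices = np.asarray(self.peak_indices, dtype=int)
        if self.peak_indices.size and np.any(np.diff(self.peak_indices) <= 0):
            raise ValueError("peak indices must be strictly increasing")

    @property
    def n_peaks(self) -> int:
        return int(self.peak_indices.size)

    def intervals(self) -> np.ndarray:
        """Successive inter-peak intervals in seconds (all > 0)."""
        return np.diff(self.peak_indices) / self.fs

    def mean_hr(self) -> float:
        """Mean heart rate in beats/min; NaN with fewer than 2 peaks."""
        iv = self.intervals()
        if iv.size == 0:
            return float("nan")
        return 60.0 / float(np.mean(iv))


@dataclass
class QCReport:
    interval_correlation: float
    mean_hr: float
    passed: bool
    reasons: list = field(default_factory=list)


@dataclass
class SegmentStore:
    """Fixed-length labeled segments with provenance.

    ``segments`` has shape (n, L) for single-channel stores or (n, C, L) for
    paired-channel stores (channel 0 = ECG, channel 1 = PPG).
    """

    segments: np.ndarray
    labels: np.ndarray          # per-segment rhythm: "AF" | "SR"
    origin: np.ndarray          # per-segment provenance: "real" | "generated"
    parent_id: np.ndarray       # per-segment parent identifier
    fs: float
    segment_seconds: float
    channels: tuple = ("ecg",)

    def __post_init__(self) -> None:
        self.segments = np.asarray(self.segments, dtype=float)
        self.labels = np.asarray(self.labels)
        self.origin = np.asarray(self.origin)
        self.parent_id = np.asarray(self.parent_id)
        n = self.segments.shape[0]
        if not (len(self.labels) == len(self.origin) == len(self.parent_id) == n):
            raise ValueError("labels/origin/parent_id must match segment count")
        expect = int(round(self.fs * self.segment_seconds))
        if n and self.segments.shape[-1] != expect:
            raise ValueError(
                f"segment length {self.segments.shape[-1]} != fs*seconds = {expect}"
            )

    def __len__(self) -> int:
        return self.segments.shape[0]

    @property
    def n_channels(self) -> int:
        return 1 if self.segments.ndim == 2 else self.segments.shape[1]

    def channel(self, name: str) -> np.ndarray:
        """Return one channel as an (n, L) array."""
        if self.segments.ndim == 2:
            if self.channels and name != self.channels[0]:
                raise KeyError(name)
            return self.segments
        return self.segments[:, self.channels.index(name), :]

    def subset(self, idx) -> "SegmentStore":
        return SegmentStore(self.segments[idx], self.labels[idx], self.origin[idx],
                            self.parent_id[idx], self.fs, self.segment_seconds,
                            self.channels)

    @staticmethod
    def concat(stores: list["SegmentStore"]) -> "SegmentStore":
        first = stores[0]
        return SegmentStore(
            np.concatenate([s.segments for s in stores]),
            np.concatenate([s.labels for s in stores]),
            np.concatenate([s.origin for s in stores]),
            np.concatenate([s.parent_id for s in stores]),
            first.fs, first.segment_seconds, first.channels,
        )


def resample(record: WaveformRecord, fs_target: float) -> WaveformRecord:
    """Rational-factor polyphase resampling of both channels.

    Annotation indices are remapped proportionally, rounded toward the
    interior of the record so intervals never spill past the new length.
    """
    if fs_target <= 0:
        raise ValueError("fs_target must be > 0")
    if record.n_samples == 0:
        raise ValueError("cannot resample a zero-length record")
    if fs_target == record.fs:
        return record
    frac = Fraction(fs_target / record.fs).limit_denominator(1000)
    up, down = frac.numerator, frac.denominator
    ecg = sps.resample_poly(record.ecg, up, down)
    ppg = sps.resample_poly(record.ppg, up, down) if record.ppg is not None else None
    n_new = len(ecg)
    ratio = fs_target / record.fs
    anns = []
    for start, end, rhythm in record.annotations:
        s = min(int(np.ceil(start * ratio)), n_new)
        e = min(int(np.floor(end * ratio)), n_new)
        if e > s:
            anns.append((s, e, rhythm))
    meta = dict(record.meta)
    return WaveformRecord(ecg=ecg, ppg=ppg, fs=fs_target,
                          rhythm_label=record.rhythm_label,
                          subject_id=record.subject_id,
                          annotations=anns, meta=meta)


def _pan_tompkins_mwi(ecg: np.ndarray, fs: float) -> np.ndarray:
    """Band-pass (5–15 Hz), differentiate, square, moving-window integrate."""
    nyq = fs / 2.0
    lo, hi = 5.0 / nyq, min(15.0 / nyq, 0.99)
    b, a = sps.butter(2, [lo, hi], btype="band")
    filtered = sps.filtfilt(b, a, ecg)
    deriv = np.gradient(filtered)
    squared = deriv**2
    win = max(1, int(round(0.150 * fs)))
    return np.convolve(squared, np.ones(win) / win, mode="same")


def detect_r_peaks(ecg: np.ndarray, fs: float) -> BeatSeries:
    """Pan–Tompkins QRS detection.

    Stages: 5–15 Hz band-pass, derivative, squaring, 150-ms moving-window
    integration, then adaptive signal/noise thresholding with a 200-ms
    refractory period (learning phase: first 2 s). Peak locations are refined
    to the local maximum of the raw ECG within ±100 ms of each QRS candidate.
    Signals too short or flat yield an empty series rather than an error.
    """
    ecg = np.asarray(ecg, dtype=float)
    if len(ecg) < 2 * fs or np.ptp(ecg) == 0:
        return BeatSeries(np.array([], dtype=int), fs, "ECG")
    mwi = _pan_tompkins_mwi(ecg, fs)
    refractory = int(round(0.200 * fs))
    candidates, _ = sps.find_peaks(mwi, distance=refractory)
    if candidates.size == 0:
        return BeatSeries(np.array([], dtype=int), fs, "ECG")

    learn = mwi[: int(2 * fs)]
    spki = float(np.max(learn)) * 0.5 if learn.size else float(np.max(mwi)) * 0.5
    npki = float(np.mean(learn)) * 0.5 if learn.size else 0.0
    threshold = npki + 0.25 * (spki - npki)

    accepted = []
    for idx in candidates:
        peak = mwi[idx]
        if peak > threshold:
            if accepted and idx - accepted[-1] < refractory:
                continue
            accepted.append(idx)
            spki = 0.125 * peak + 0.875 * spki
        else:
            npki = 0.125 * peak + 0.875 * npki
        threshold = npki + 0.25 * (spki - npki)
    if not accepted:
        return BeatSeries(np.array([], dtype=int), fs, "ECG")

    # Refine to the raw-signal R maximum near each integrated-window candidate.
    half = int(round(0.100 * fs))
    refined = []
    for idx in accepted:
        lo, hi = max(0, idx - half), min(len(ecg), idx + half + 1)
        refined.append(lo + int(np.argmax(ecg[lo:hi])))
    refined = np.unique(refined)
    keep = np.concatenate([[True], np.diff(refined) >= refractory])
    return BeatSeries(refined[keep], fs, "ECG")


def detect_ppg_peaks(ppg: np.ndarray, fs: float) -> BeatSeries:
    """Systolic-peak detection: local maxima with a prominence floor and a
    minimum inter-peak distance of 60/max_hr seconds."""
    ppg = np.asarray(ppg, dtype=float)
    if len(ppg) < 2 * fs or np.ptp(ppg) == 0:
        return BeatSeries(np.array([], dtype=int), fs, "PPG")
    # The systolic upstroke lives well below 8 Hz; low-pass first so broadband
    # noise cannot displace the smooth pulse maximum.
    b, a = sps.butter(2, min(8.0 / (fs / 2.0), 0.99), btype="low")
    smooth = sps.filtfilt(b, a, ppg)
    distance = max(1, int(round(fs * 60.0 / MAX_HR_BPM)))
    prominence = 0.3 * float(np.percentile(smooth, 95) - np.percentile(smooth, 5))
    peaks, _ = sps.find_peaks(smooth, distance=distance, prominence=prominence)
    return BeatSeries(peaks, fs, "PPG")


def interval_correlation(a: BeatSeries, b: BeatSeries) -> float:
    """Pearson correlation between the two inter-peak-interval sequences.

    Sequences are truncated to their common length. Computed on intervals,
    not raw index arrays: index arrays are near-collinear by construction,
    whereas intervals carry the rhythm information the QC targets. Returns
    NaN (a QC failure, not an exception) when either series has < 3 peaks.
    """
    if a.n_peaks < 3 or b.n_peaks < 3:
        return float("nan")
    ia, ib = a.intervals(), b.intervals()
    n = min(len(ia), len(ib))
    ia, ib = ia[:n], ib[:n]
    if np.std(ia) == 0 or np.std(ib) == 0:
        # Perfectly regular rhythms: identical interval sequences correlate 1.
        return 1.0 if np.allclose(ia, ib) else float("nan")
    return float(np.corrcoef(ia, ib)[0, 1])


def qc_screen(record: WaveformRecord, threshold: float = QC_CORR_THRESHOLD,
              hr_floor: float = HR_FLOOR_BPM) -> QCReport:
    """Record-level screen: interval-correlation and mean-heart-rate gates.

    A record passes iff the ECG/PPG inter-peak-interval correlation exceeds
    ``threshold`` (when a PPG channel is present) and the mean detected heart
    rate is at least ``hr_floor``. Failures are reported with reasons, never
    raised.
    """
    reasons: list[str] = []
    r_beats = detect_r_peaks(record.ecg, record.fs)
    mean_hr = r_beats.mean_hr()
    if not np.isfinite(mean_hr) or mean_hr < hr_floor:
        reasons.append(f"mean HR {mean_hr:.1f} bpm below floor {hr_floor:.0f} bpm")
    corr = float("nan")
    if record.ppg is not None:
        p_beats = detect_ppg_peaks(record.ppg, record.fs)
        corr = interval_correlation(r_beats, p_beats)
        if not np.isfinite(corr):
            reasons.append("too few peaks for interval correlation")
        elif corr <= threshold:
            reasons.append(
                f"interval correlation {corr:.3f} not above threshold {threshold}"
            )
    return QCReport(interval_correlation=corr, mean_hr=mean_hr,
                    passed=not reasons, reasons=reasons)


def segment_annotated(record: WaveformRecord, rhythm: str,
                      seconds: float = 30.0, channels: str = "both",
                      origin: str = "real",
                      normalize: bool = True) -> SegmentStore:
    """Cut rhythm-annotated regions into non-overlapping fixed-length segments.

    Windows are left-aligned within each matching annotation interval and
    never cross an interval boundary; any remainder shorter than ``seconds``
    is discarded. ``channels`` selects "ecg", "ppg" or "both" (paired).
    Each emitted channel vector is min-max normalized to [-1, 1] by default.
    """
    if record.fs <= 0:
        raise ValueError("record.fs must be set")
    seg_len = int(round(record.fs * seconds))
    if channels == "both" and record.ppg is None:
        raise ValueError("record has no PPG channel")
    chan_names = {"ecg": ("ecg",), "ppg": ("ppg",), "both": ("ecg", "ppg")}[channels]
    segs, labels, origins, parents = [], [], [], []
    for start, end, ann_rhythm in record.annotations:
        if ann_rhythm != rhythm:
            continue
        for k, s in enumerate(range(start, end - seg_len + 1, seg_len)):
            rows = []
            for name in chan_names:
                vec = (record.ecg if name == "ecg" else record.ppg)[s : s + seg_len]
                rows.append(minmax_scale(vec) if normalize else vec)
            segs.append(rows[0] if len(rows) == 1 else np.stack(rows))
            labels.append(rhythm)
            origins.append(origin)
            parents.append(f"{record.subject_id}:{start}:{k}")
    if not segs:
        arr = np.empty((0, len(chan_names), seg_len) if channels == "both"
                       else (0, seg_len))
    else:
        arr = np.stack(segs)
    return SegmentStore(arr, np.array(labels, dtype=object),
                        np.array(origins, dtype=object),
                        np.array(parents, dtype=object),
                        record.fs, seconds, chan_names)


def slice_segments(store: SegmentStore, slice_seconds: float = 15.0,
                   stride_seconds: float = 1.0,
                   compat: bool = True) -> SegmentStore:
    """Slide a window over every parent segment.

    The full enumeration of left-aligned windows gives
    ``floor((segment_seconds - slice_seconds) / stride_seconds) + 1`` slices
    per parent. In compatibility mode (the default) the final window is
    dropped whenever it lands exactly on the segment end, so a 30-s parent
    with a 15-s window and 1-s stride yields windows at offsets 0..14 s — 15
    slices, the convention used to build the reference dataset counts
    (770 parents → 11,550 slices). Labels, origins and parent ids are
    inherited, so group-wise splits can keep sibling slices together.
    """
    if stride_seconds <= 0:
        raise ValueError("stride_seconds must be > 0")
    if slice_seconds > store.segment_seconds:
        raise ValueError("slice_seconds exceeds segment length")
    seg_len = store.segments.shape[-1]
    win = int(round(store.fs * slice_seconds))
    step = int(round(store.fs * stride_seconds))
    n_windows = (seg_len - win) // step + 1
    if compat and n_windows > 1 and (seg_len - win) % step == 0:
        n_windows -= 1
    offsets = np.arange(n_windows) * step
    segs, labels, origins, parents = [], [], [], []
    for i in range(len(store)):
        for off in offsets:
            segs.append(store.segments[i, ..., off : off + win])
            labels.append(store.labels[i])
            origins.append(store.origin[i])
            parents.append(store.parent_id[i])
    arr = (np.stack(segs) if segs
           else np.empty(store.segments.shape[:-1] + (win,))[:0])
    return SegmentStore(arr, np.array(labels, dtype=object),
                        np.array(origins, dtype=object),
                        np.array(parents, dtype=object),
                        store.fs, slice_seconds, store.channels)
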