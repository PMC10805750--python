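"""Morphology and rhythm agreement metrics between reference and generated PPG.

Two segment-level morphology metrics — percent root-mean-square difference
(PRD) and the Pearson correlation coefficient — plus beat-by-beat heart-rate
extraction and a paired t-test for rhythm preservation, and an outlier-aware
cohort summary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .preprocess import detect_ppg_peaks, detect_r_peaks

__all__ = [
    "SegmentMetric",
    "MetricsReport",
    "prd",
    "pearson_cc",
    "beat_hr_series",
    "hr_agreement",
    "summarize",
]


class UndefinedMetricError(ValueError):
    """Raised when a metric is undefined for the given input (e.g. zero variance)."""


@dataclass
class SegmentMetric:
    prd: float
    cc: float
    is_prd_outlier: bool = False
    is_cc_outlier: bool = False


@dataclass
class MetricsReport:
    n_segments: int
    n_prd_outliers: int
    n_cc_outliers: int
    prd_mean: float
    prd_sd: float
    cc_mean: float
    cc_sd: float
    hr_corr_mean: float = float("nan")
    hr_corr_sd: float = float("nan")
    ttest_p: float = float("nan")


def prd(ref: np.ndarray, gen: np.ndarray, centered: bool = True) -> float:
    """Percent root-mean-square difference.

    ``100 * sqrt( sum((ref - gen)^2) / sum((ref - mean(ref))^2) )``.

    The mean-centered denominator is the convention of the ECG-compression
    literature the metric originates from; ``centered=False`` selects the raw
    energy denominator. PRD is 0 for a perfect reconstruction and 100 when
    the reconstruction is the constant reference mean.
    """
    ref = np.asarray(ref, dtype=float)
    gen = np.asarray(gen, dtype=float)
    if ref.shape != gen.shape or ref.size < 2:
        raise ValueError("ref and gen must share a length >= 2")
    denom = np.sum((ref - ref.mean()) ** 2) if centered else np.sum(ref**2)
    if denom <= 0:
        raise UndefinedMetricError("reference has zero variance; PRD undefined")
    return 100.0 * float(np.sqrt(np.sum((ref - gen) ** 2) / denom))


def pearson_cc(ref: np.ndarray, gen: np.ndarray) -> float:
    """Product-moment correlation between two equal-length waveforms."""
    ref = np.asarray(ref, dtype=float)
    gen = np.asarray(gen, dtype=float)
    if ref.shape != gen.shape or ref.size < 2:
        raise ValueError("ref and gen must share a length >= 2")
    if np.std(ref) == 0 or np.std(gen) == 0:
        raise UndefinedMetricError("constant input; correlation undefined")
    return float(np.clip(stats.pearsonr(ref, gen).statistic, -1.0, 1.0))


def beat_hr_series(signal: np.ndarray, fs: float, channel: str = "ECG") -> np.ndarray:
    """Beat-by-beat heart rate, 60 / interval, over successive detected peaks.

    R-peaks are used for the ECG channel and systolic peaks for PPG.
    """
    if channel.upper() == "ECG":
        beats = detect_r_peaks(signal, fs)
    elif channel.upper() == "PPG":
        beats = detect_ppg_peaks(signal, fs)
    else:
        raise ValueError(f"unknown channel {channel!r}")
    if beats.n_peaks < 3:
        raise ValueError(f"fewer than 3 detectable beats on channel {channel}")
    return 60.0 / beats.intervals()


def hr_agreement(ecg_hr: np.ndarray, ppg_hr: np.ndarray) -> tuple[float, float]:
    """Pearson correlation and two-sided paired-t p-value between HR series.

    Series are truncated to their common length. Degenerate difference
    series are handled by convention: all-zero differences give p = 1; a
    zero-variance nonzero-mean difference gives p = 0.
    """
    ecg_hr = np.asarray(ecg_hr, dtype=float)
    ppg_hr = np.asarray(ppg_hr, dtype=float)
    n = min(len(ecg_hr), len(ppg_hr))
    if n < 3:
        raise ValueError("need at least 3 common beats")
    a, b = ecg_hr[:n], ppg_hr[:n]
    if np.std(a) == 0 or np.std(b) == 0:
        corr = 1.0 if np.allclose(a, b) else float("nan")
    else:
        corr = float(stats.pearsonr(a, b).statistic)
    d = a - b
    if np.all(d == 0):
        return corr, 1.0
    if np.std(d, ddof=1) == 0:
        return corr, 0.0
    p = float(stats.ttest_rel(a, b).pvalue)
    return corr, p


def flag_outliers(values: np.ndarray, n_sd: float = 3.0) -> np.ndarray:
    """Boolean mask of values beyond mean ± n_sd·SD, applied once."""
    values = np.asarray(values, dtype=float)
    mu, sd = values.mean(), values.std()
    if sd == 0:
        return np.zeros(values.shape, dtype=bool)
    return np.abs(values - mu) > n_sd * sd


def summarize(metrics: list[SegmentMetric], outlier_sd: float | None = 3.0,
              hr_corrs: np.ndarray | None = None,
              ttest_p: float = float("nan")) -> MetricsReport:
    """Cohort summary with outlier exclusion.

    Outliers are flagged per metric (default: beyond mean ± 3 SD, one pass)
    and excluded from the reported mean/SD; their counts are always reported,
    never silently dropped. ``outlier_sd=None`` disables flagging.
    """
    if not metrics:
        raise ValueError("metrics list is empty")
    prds = np.array([m.prd for m in metrics])
    ccs = np.array([m.cc for m in metrics])
    if outlier_sd is None:
        prd_out = np.zeros(len(metrics), dtype=bool)
        cc_out = np.zeros(len(metrics), dtype=bool)
    else:
        prd_out = flag_outliers(prds, outlier_sd)
        cc_out = flag_outliers(ccs, outlier_sd)
    if prd_out.all() or cc_out.all():
        raise ValueError("every segment was flagged as an outlier")
    for m, po, co in zip(metrics, prd_out, cc_out):
        m.is_prd_outlier = bool(po)
        m.is_cc_outlier = bool(co)
    hr_mean = hr_sd = float("nan")
    if hr_corrs is not None and len(hr_corrs):
        hr_mean = float(np.mean(hr_corrs))
        hr_sd = float(np.std(hr_corrs))
    return MetricsReport(
        n_segments=len(metrics),
        n_prd_outliers=int(prd_out.sum()),
        n_cc_outliers=int(cc_out.sum()),
        prd_mean=float(prds[~prd_out].mean()),
        prd_sd=float(prds[~prd_out].std()),
        cc_mean=float(ccs[~cc_out].mean()),
        cc_sd=float(ccs[~cc_out].std()),
        hr_corr_mean=hr_mean,
        hr_corr_sd=hr_sd,
        ttest_p=ttest_p,
    )
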