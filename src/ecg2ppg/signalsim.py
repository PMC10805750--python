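"""Seeded simulator of paired ECG/PPG records with sinus-rhythm and AF beat statistics.

The simulator produces the paired single-lead ECG + finger-PPG records that the
rest of the pipeline consumes: beat-locked P-QRS-T complexes built from Gaussian
bumps, PPG pulses (systolic + dicrotic wave) delayed by a per-record pulse
transit time (PTT), sinus RR series with respiratory modulation, and AF RR
series with high, serially uncorrelated beat-to-beat variability.

Every operation is deterministic given its seed; ground-truth beat times are
retained on each record so downstream detectors can be checked against the
construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "RhythmSpec",
    "MorphologySpec",
    "WaveformRecord",
    "simulate_rr",
    "r_peak_times",
    "synth_ecg",
    "synth_ppg",
    "make_record",
    "make_cohort",
]

SR = "SR"
AF = "AF"

HR_MIN = 30.0
HR_MAX = 220.0


class InvalidSpecError(ValueError):
    """Raised when a simulation spec violates its physiological bounds."""


@dataclass(frozen=True)
class RhythmSpec:
    """Beat-interval statistics for one record.

    Parameters
    ----------
    rhythm : {"SR", "AF"}
    mean_hr : float
        Target mean heart rate, beats/min. Must lie in [30, 220].
    sr_rsa_depth : float
        Respiratory sinus arrhythmia amplitude as a fraction of the mean RR
        (SR only). Default 0.06 — a typical resting modulation depth.
    sr_rsa_freq : float
        Respiratory frequency in Hz (SR only). Default 0.25 Hz ≈ 15 breaths/min.
    sr_lf_depth, sr_lf_freq : float
        A weaker low-frequency (Mayer-wave, ~0.1 Hz) RR oscillation present in
        resting sinus series; together with RSA this puts the interval SD in
        the 30–60 ms range typical of healthy adults.
    sr_jitter_cv : float
        Coefficient of variation of the residual beat-to-beat jitter in SR.
    af_cv : float
        Coefficient of variation of the RR distribution in AF. AF RR intervals
        are drawn i.i.d. (serially uncorrelated), which is the defining rhythm
        signature of atrial fibrillation at the interval level.
    seed : int
    """

    rhythm: str = SR
    mean_hr: float = 80.0
    sr_rsa_depth: float = 0.06
    sr_rsa_freq: float = 0.25
    sr_lf_depth: float = 0.04
    sr_lf_freq: float = 0.10
    sr_jitter_cv: float = 0.01
    af_cv: float = 0.24
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rhythm not in (SR, AF):
            raise InvalidSpecError(f"rhythm must be 'SR' or 'AF', got {self.rhythm!r}")
        if not (HR_MIN <= self.mean_hr <= HR_MAX):
            raise InvalidSpecError(
                f"mean_hr must lie in [{HR_MIN}, {HR_MAX}] bpm, got {self.mean_hr}"
            )
        if self.af_cv <= 0 or self.sr_jitter_cv < 0:
            raise InvalidSpecError("af_cv must be > 0 and sr_jitter_cv >= 0")
        if self.af_cv <= self.sr_jitter_cv:
            raise InvalidSpecError("af_cv must exceed the SR jitter CV")


# (amplitude, center offset as fraction of RR relative to the R peak, width in s)
_DEFAULT_ECG_WAVES = (
    (0.15, -0.20, 0.025),   # P
    (-0.10, -0.05, 0.010),  # Q
    (1.00, 0.00, 0.012),    # R — strictly the largest bump
    (-0.18, 0.05, 0.010),   # S
    (0.35, 0.30, 0.050),    # T
)


@dataclass(frozen=True)
class MorphologySpec:
    """Waveform shape parameters shared by a record's ECG and PPG channels.

    ECG complexes are sums of Gaussian bumps (one P, Q, R, S, T bump per beat);
    PPG pulses are a systolic Gaussian plus a smaller, delayed dicrotic wave.
    Offsets are fractions of the local RR interval; widths are in seconds so
    the printed morphology stays physiological across heart rates.
    """

    ecg_wave_params: tuple = _DEFAULT_ECG_WAVES
    ppg_systolic_amp: float = 1.0
    ppg_systolic_width: float = 0.08
    ppg_dicrotic_amp: float = 0.30
    ppg_dicrotic_offset: float = 0.30
    ppg_dicrotic_width: float = 0.08
    ptt: float = 0.25
    noise_sd: float = 0.01

    def __post_init__(self) -> None:
        if self.ptt < 0:
            raise InvalidSpecError("ptt must be >= 0")
        if self.noise_sd < 0:
            raise InvalidSpecError("noise_sd must be >= 0")
        r_amp = self.ecg_wave_params[2][0]
        others = [abs(a) for i, (a, _, _) in enumerate(self.ecg_wave_params) if i != 2]
        if not all(r_amp > a for a in others):
            raise InvalidSpecError("R amplitude must be strictly the largest ECG bump")


@dataclass
class WaveformRecord:
    """One paired ECG/PPG recording: the unit of ingestion.

    ``annotations`` is a sorted list of non-overlapping half-open sample-index
    intervals ``(start, end, rhythm)`` covering rhythm labels along the record.
    ``meta`` carries simulator ground truth (R-peak times, the RR sequence)
    when the record is synthetic.
    """

    ecg: np.ndarray
    ppg: np.ndarray | None
    fs: float
    rhythm_label: str
    subject_id: str
    annotations: list = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.ecg = np.asarray(self.ecg, dtype=float)
        if self.ppg is not None:
            self.ppg = np.asarray(self.ppg, dtype=float)
            if len(self.ppg) != len(self.ecg):
                raise ValueError("ecg and ppg must have equal length")
        if self.fs <= 0:
            raise ValueError("fs must be > 0")
        self._check_annotations()

    def _check_annotations(self) -> None:
        prev_end = 0
        for start, end, _ in self.annotations:
            if not (0 <= start < end <= len(self.ecg)):
                raise ValueError(f"annotation ({start}, {end}) outside record")
            if start < prev_end:
                raise ValueError("annotations must be sorted and non-overlapping")
            prev_end = end

    @property
    def n_samples(self) -> int:
        return len(self.ecg)

    @property
    def duration_s(self) -> float:
        return len(self.ecg) / self.fs


def simulate_rr(spec: RhythmSpec, n_beats: int) -> np.ndarray:
    """Draw a sequence of ``n_beats`` RR intervals (seconds) under ``spec``.

    SR: RR = 60/mean_hr modulated sinusoidally at the respiratory frequency,
    plus small Gaussian jitter. AF: RR drawn i.i.d. log-normal with the stated
    mean and coefficient of variation — serially uncorrelated by construction.
    """
    if n_beats < 1:
        raise InvalidSpecError(f"n_beats must be >= 1, got {n_beats}")
    rng = np.random.default_rng(spec.seed)
    base = 60.0 / spec.mean_hr
    if spec.rhythm == AF:
        sigma2 = np.log1p(spec.af_cv**2)
        mu = np.log(base) - sigma2 / 2.0
        rr = rng.lognormal(mean=mu, sigma=np.sqrt(sigma2), size=n_beats)
    else:
        rr = np.empty(n_beats)
        t = 0.0
        jitter = rng.normal(0.0, spec.sr_jitter_cv * base, size=n_beats)
        for i in range(n_beats):
            mod = (spec.sr_rsa_depth * np.sin(2 * np.pi * spec.sr_rsa_freq * t)
                   + spec.sr_lf_depth * np.sin(2 * np.pi * spec.sr_lf_freq * t))
            rr[i] = base * (1.0 + mod) + jitter[i]
            t += rr[i]
    # Physiological floor/ceiling; never binds at default CVs but guarantees RR > 0.
    return np.clip(rr, 0.2, 4.0)


def r_peak_times(rr: np.ndarray, r_frac: float = 0.35) -> np.ndarray:
    """Ground-truth R-peak times for an RR sequence.

    The R peaks form the point process whose increments are exactly the RR
    sequence: ``R_k = r_frac * rr_0 + sum(rr_0..rr_{k-1})``, so
    ``diff(r_peak_times(rr)) == rr[:-1]`` and detected inter-R intervals
    inherit the simulated rhythm statistics unchanged. The ``r_frac`` lead-in
    leaves room for the first beat's P wave.
    """
    rr = np.asarray(rr, dtype=float)
    return r_frac * rr[0] + np.concatenate([[0.0], np.cumsum(rr[:-1])])


def _add_gaussians(signal: np.ndarray, fs: float, centers: np.ndarray,
                   amps: np.ndarray, widths: np.ndarray) -> None:
    """Accumulate Gaussian bumps into ``signal`` in place (4-sigma support)."""
    n = len(signal)
    t = np.arange(n) / fs
    for c, a, w in zip(centers, amps, widths):
        lo = max(0, int((c - 4 * w) * fs))
        hi = min(n, int((c + 4 * w) * fs) + 1)
        if hi <= lo:
            continue
        signal[lo:hi] += a * np.exp(-0.5 * ((t[lo:hi] - c) / w) ** 2)


def synth_ecg(rr: np.ndarray, morph: MorphologySpec, fs: float,
              rng: np.random.Generator | None = None) -> np.ndarray:
    """Synthesize an ECG trace: one P-Q-R-S-T complex per RR interval.

    Output length is ``round(fs * sum(rr))``. Bumps whose offset would push
    them outside their beat interval are clamped (with a warning) rather than
    emitting NaN.
    """
    rr = np.asarray(rr, dtype=float)
    if fs <= 0:
        raise InvalidSpecError("fs must be > 0")
    if rr.size == 0:
        raise InvalidSpecError("rr must be nonempty")
    n = int(round(fs * rr.sum()))
    out = np.zeros(n)
    r_times = r_peak_times(rr)
    prev_rr = np.concatenate([[rr[0]], rr[:-1]])  # gap before each R
    clamped = False
    for amp, frac, width in morph.ecg_wave_params:
        # waves before the R scale with the preceding inter-R gap, waves
        # after it with the following one
        scale = prev_rr if frac < 0 else rr
        centers = r_times + frac * scale
        lo = r_times - 0.45 * prev_rr + width
        hi = r_times + 0.75 * rr - width
        if np.any((centers < lo - width) | (centers > hi + width)):
            clamped = True
        centers = np.clip(centers, np.minimum(lo, hi), np.maximum(lo, hi))
        _add_gaussians(out, fs, centers, np.full_like(centers, amp),
                       np.full_like(centers, width))
    if clamped:
        warnings.warn("ECG bump centers clamped into short beat intervals", stacklevel=2)
    if morph.noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng(0)
        out += rng.normal(0.0, morph.noise_sd, size=n)
    return out


def synth_ppg(rr: np.ndarray, morph: MorphologySpec, fs: float,
              rng: np.random.Generator | None = None) -> np.ndarray:
    """Synthesize the paired PPG trace: systolic + dicrotic pulse per beat.

    Each pulse onset is delayed by the pulse transit time relative to the
    corresponding R peak; the array has the same length as the paired ECG.
    """
    rr = np.asarray(rr, dtype=float)
    if fs <= 0:
        raise InvalidSpecError("fs must be > 0")
    if rr.size == 0:
        raise InvalidSpecError("rr must be nonempty")
    n = int(round(fs * rr.sum()))
    out = np.zeros(n)
    sys_times = r_peak_times(rr) + morph.ptt
    _add_gaussians(out, fs, sys_times,
                   np.full_like(sys_times, morph.ppg_systolic_amp),
                   np.full_like(sys_times, morph.ppg_systolic_width))
    dic_times = sys_times + morph.ppg_dicrotic_offset
    _add_gaussians(out, fs, dic_times,
                   np.full_like(dic_times, morph.ppg_dicrotic_amp),
                   np.full_like(dic_times, morph.ppg_dicrotic_width))
    if morph.noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng(1)
        out += rng.normal(0.0, morph.noise_sd, size=n)
    return out


def minmax_scale(x: np.ndarray) -> np.ndarray:
    """Affinely map ``x`` onto [-1, 1]; a constant signal maps to zeros."""
    lo, hi = float(np.min(x)), float(np.max(x))
    if hi <= lo:
        return np.zeros_like(x)
    return 2.0 * (x - lo) / (hi - lo) - 1.0


def make_record(spec: RhythmSpec, morph: MorphologySpec, duration_s: float,
                fs: float = 100.0, subject_id: str = "synthetic") -> WaveformRecord:
    """Build one paired, min-max-scaled record of the requested duration."""
    max_rr = 60.0 / spec.mean_hr
    if duration_s < max_rr:
        raise InvalidSpecError(
            f"duration {duration_s}s is shorter than one beat at {spec.mean_hr} bpm"
        )
    # Oversample beats, then truncate to the requested sample count.
    n_beats = int(np.ceil(duration_s / max_rr * 1.8)) + 8
    rr = simulate_rr(spec, n_beats)
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0x5EED]).generate_state(1)[0])
    ecg = synth_ecg(rr, morph, fs, rng=rng)
    ppg = synth_ppg(rr, morph, fs, rng=rng)
    n = int(round(fs * duration_s))
    ecg, ppg = ecg[:n], ppg[:n]
    if len(ecg) < n:  # pathological spec (extreme clipping); never at defaults
        raise InvalidSpecError("simulated beats did not cover the requested duration")
    r_times = r_peak_times(rr)
    keep = r_times < duration_s
    return WaveformRecord(
        ecg=minmax_scale(ecg),
        ppg=minmax_scale(ppg),
        fs=fs,
        rhythm_label=spec.rhythm,
        subject_id=subject_id,
        annotations=[(0, n, spec.rhythm)],
        meta={
            "r_times": r_times[keep],
            "rr": rr[: int(keep.sum())],
            "ptt": morph.ptt,
            "rhythm_spec": spec,
        },
    )


def make_cohort(n_records: int, rhythm_mix: float, duration_s: float,
                seed: int, fs: float = 100.0,
                sr_spec: RhythmSpec | None = None,
                af_spec: RhythmSpec | None = None,
                morph: MorphologySpec | None = None) -> list[WaveformRecord]:
    """Simulate a cohort of paired records with a given AF fraction.

    ``round(rhythm_mix * n_records)`` records are AF, the rest SR. Per-record
    seeds are derived deterministically from the cohort seed, so the cohort is
    reproducible as a whole and each record independently.
    """
    if n_records < 1:
        raise InvalidSpecError("n_records must be >= 1")
    if not (0.0 <= rhythm_mix <= 1.0):
        raise InvalidSpecError("rhythm_mix must lie in [0, 1]")
    sr_spec = sr_spec or RhythmSpec(rhythm=SR, mean_hr=70.0)
    af_spec = af_spec or RhythmSpec(rhythm=AF, mean_hr=90.0)
    morph = morph or MorphologySpec()
    n_af = int(round(rhythm_mix * n_records))
    seeds = np.random.SeedSequence(seed).generate_state(n_records) % (2**31)
    records = []
    for i in range(n_records):
        base = af_spec if i < n_af else sr_spec
        spec = replace(base, seed=int(seeds[i]))
        records.append(
            make_record(spec, morph, duration_s, fs=fs, subject_id=f"synth-{seed}-{i:04d}")
        )
    return records
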