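# Methods

This note records the models, the defaults and the numerical choices behind
`ecg2ppg`, and what the synthetic test bed does and does not establish.

## Synthetic paired-waveform model (`signalsim`)

The simulator exists so that every downstream stage — peak detection, QC,
translator training, classification — can be exercised on data whose ground
truth is known exactly.

**Beat process.** R-peak times form a point process whose increments are
exactly the simulated RR sequence, so detected inter-R intervals inherit the
rhythm statistics unchanged.

- *Sinus rhythm (SR):* RR = (60/HR)·(1 + a_RSA·sin 2πf_RSA·t +
  a_LF·sin 2πf_LF·t) + jitter. Defaults: respiratory modulation a_RSA = 0.06
  at f_RSA = 0.25 Hz (≈15 breaths/min), a weaker low-frequency (Mayer-wave)
  term a_LF = 0.04 at 0.10 Hz, and Gaussian jitter with CV 0.01. Together
  these put the interval SD in the 30–60 ms range typical of resting healthy
  adults; with only the respiratory term the series is unrealistically
  metronomic and sits at the quantization floor of 100 Hz peak detection.
- *Atrial fibrillation (AF):* RR i.i.d. log-normal with configurable
  coefficient of variation (default 0.24, mid-range for AF) — serially
  uncorrelated by construction, which is the signature the downstream
  classifier must learn. Mean heart rates default to 70 bpm (SR) and 90 bpm
  (AF), reflecting the faster ventricular response typical of AF.

**Morphology.** The ECG is a sum of five Gaussian bumps per beat (P, Q, R,
S, T) with amplitudes (0.15, −0.10, 1.00, −0.18, 0.35); offsets are
fractions of the local inter-R gap, widths are in seconds so shapes stay
physiological across heart rates. The R bump is strictly the largest — an
enforced invariant, since R dominance is what makes QRS detection
well-posed. The PPG is one systolic Gaussian (width 0.08 s) plus a smaller
dicrotic wave (amplitude 0.30, +0.30 s) per beat, delayed from the R peak
by a per-record pulse transit time (default 0.25 s). The systolic width was
chosen so that short-coupled AF beats (RR ≈ 0.35 s) still produce resolvable
pulses; much wider pulses merge with the preceding dicrotic wave, which is
the physiological "pulse deficit" phenomenon but would make the generator's
target ill-defined at the shortest intervals. White noise (SD 0.01 of the
unit amplitude) is added to both channels; each record is min-max scaled to
[−1, 1], the network input convention.

What the simulator does *not* emulate: motion artifacts, baseline wander,
reflectance-vs-transmission morphology differences, beat-level PTT
dynamics (PTT is fixed per record), ectopy inside sinus records, and
P-wave-only AF. Tests passing on this bed therefore establish the
*mechanics* of the pipeline and the *rhythm-transfer* capability of the
translator, not clinical performance on measured data.

## Conditioning and QC (`preprocess`)

- Resampling is rational-factor polyphase filtering; annotation indices map
  proportionally, rounded toward the interval interior.
- Pan–Tompkins stages: 5–15 Hz band-pass (2nd-order Butterworth, zero-phase),
  derivative, squaring, 150-ms moving-window integration, adaptive
  signal/noise thresholds with a 200-ms refractory period, 2-s learning
  phase; candidates are refined to the raw-ECG maximum within ±100 ms.
- PPG peaks: 8-Hz low-pass then `scipy.signal.find_peaks` with a prominence
  floor (30% of the 5–95 percentile span) and a minimum spacing of
  60/220 s. The low-pass matters: broadband noise displaces the smooth
  systolic maximum by tens of milliseconds otherwise, which at 100 Hz is
  the difference between passing and failing the 0.96 interval-correlation
  gate on sinus records.
- The QC correlation is computed on inter-peak-interval sequences truncated
  to the common count — index arrays are near-collinear by construction and
  would pass anything.
- Slicing: a 30-s parent with a 15-s window and 1-s stride admits 16
  left-aligned windows; compatibility mode (default) drops the final
  flush-right window, emitting offsets 0…14 s — 15 slices per parent, the
  convention matching the reference corpus arithmetic (770 parents →
  11,550 slices; group-wise halves → 5,775).

## Translator (`translator`)

The generator is fully convolutional, so the `input_len` in the spec is a
divisibility constraint (length mod 2^depth = 0), not a fixed size;
training uses random 1024-sample crops and generation reflect-pads 3000 to
3072 and crops back. Defaults sized for single-CPU work: depth 4, base 8
filters (doubling per level, capped at 8×), kernel 9; discriminator 3
strided layers + 1-channel logit conv, receptive field ≈ 172 samples ≪
input. Losses: BCE adversarial (LSGAN selectable) + λ·L1 with λ = 100;
Adam with lr 2·10⁻⁴ and β₁ = 0.5 for both nets; one D step per G step. The
composition follows the established conditional-translation recipe, and λ
= 0 degenerates to a pure adversarial model. Checkpoints store every
parameter plus the config snapshot; reload is bit-identical.

Rhythm transfer was measured at desk scale (460 training pairs, 25 epochs,
~2 minutes): the correlation between held-out source-ECG RR series and
generated-PPG inter-pulse series averages ≈ 0.93–0.96 — computed by the
acceptance suite at run time, threshold 0.8.

## t-SNE and Degree of Overlap (`overlap`)

Affinities, cost and gradient are direct transcriptions of the standard
formulation (Gaussian conditionals with perplexity-matched σᵢ found by
bisection to 10⁻⁴; symmetrized joint p = (P + Pᵀ)/2n; Student-t q;
KL(P‖Q) with gradient 4Σ(p−q)·q·Z·(yᵢ−yⱼ)), verified in tests against
brute-force evaluation (10⁻¹² agreement) and numerical differentiation
(10⁻⁵). The optimizer follows the original recipe — momentum 0.5→0.8,
early exaggeration ×4 for 50 iterations, adaptive gains — except the
learning rate, which defaults to the sample-size-scaled rule
max(n/(4·early_exaggeration), 50): a fixed step of 200 visibly
under-converges desk-scale problems (n ≈ 80 stalls at KL ≈ 2.2 instead of
0.2, and two identical populations then fail to overlap).

Densities are separable Gaussian-product KDEs evaluated at cell centers on
a 100×100 lattice with 3-bandwidth margins and converted to cell masses
summing to 1; bandwidth is Silverman's per-dimension rule on the *joint*
embedding, so both populations are smoothed identically. DO = Σ√(P₁P₂),
clipped to [0, 1] against rounding; DO(P, P) = 1 and DO is symmetric,
exactly. Populations above 2,000 points are seed-subsampled before the
O(n²) embedding.

## Classifier harness (`classifier`)

The printed architecture fixes filters, kernel, activation, initializer,
head and optimizer but not the between-layer downsampling; stride-2
convolutions were chosen so six layers reduce 1500 samples to 24 before
global averaging (receptive field ≈ 1.3 s, two to three beats — enough for
interval-irregularity features to form before pooling). Defaults: batch 64,
no early stopping; epoch counts are per-experiment (the desk-scale ordering
experiment uses 6 — enough for the larger compositions to converge while
the half-data scheme remains visibly data-limited, which is the effect the
experiment exists to show).

Splits are group-wise by parent segment everywhere — sibling 15-s slices
share 14 s of signal, so any slice-level split leaks; `run_validation_experiment`
refuses train/test parent overlap outright. The bootstrap CI for AUROC is
stratified percentile with 2,000 resamples by default (seeded).

In the desk-scale experiment the "generated" AF pool is simulated with
slightly perturbed morphology (narrower systolic, damped dicrotic wave,
doubled noise), emulating an imperfect generator without coupling the
classifier experiment to a trained translator; the mixed scheme (D2)
consistently beats the half-data scheme (D4) and the all-generated scheme
(D1) classifies far above chance, reproducing the qualitative ordering that
motivates augmentation.

## Degenerate inputs and tie-breaks

- Flat or too-short signals yield empty beat series; QC reports reasons,
  never raises.
- Interval correlation with < 3 peaks is NaN (a QC failure); two perfectly
  regular identical rhythms correlate 1 by convention.
- PRD requires non-constant reference (undefined-metric error otherwise);
  the centered denominator is the default, the raw-energy variant is a flag.
- Paired t-test conventions: all-zero differences → p = 1; zero-variance
  nonzero-mean differences → p = 0.
- Affinity bisection with underflowed kernels collapses to the nearest
  neighbour and continues; duplicate points are legal throughout.
- A degenerate (single-point) KDE cloud yields a delta-like mass with a
  warning.

## Problem sizes

Test-suite experiments are sized for a single CPU core: the rhythm-transfer
run trains on ≈ 460 paired 30-s segments for 25 epochs (~2.5 min); the
classifier ordering experiment uses pools of 600 slices per class and three
schemes (~20 s); everything else runs in seconds. Larger cohorts only
sharpen the measured margins.
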