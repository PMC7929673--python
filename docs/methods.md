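# Methods

`pcgqa` rates the quality of single-channel phonocardiogram (PCG) recordings
without segmenting them into cardiac states. The premise: heart sounds are
quasi-periodic, band-limited (roughly 24–144 Hz) and pulse-like, whereas the
noise that ruins auscultation recordings — respiration, handling, ambient
sound — is broadband and aperiodic. Ten features quantify those contrasts and
an SVM maps them to quality classes.

## Preprocessing

Every recording is resampled to 1 kHz through a polyphase antialiasing
low-pass (rational-factor resampling, so 44.1 kHz → 1 kHz is exact as
10/441), high-passed with a 3rd-order Butterworth at 2 Hz to remove baseline
wander, and z-normalised to zero mean / unit population standard deviation.
The high-pass is applied forward–backward (zero phase): envelope timing
matters downstream and phase distortion would shift burst positions.
Recordings shorter than 6 s are excluded — shorter stretches cannot support
the 6 s autocorrelation analysis. Multi-annotator grades (1–5) merge by
rounding the mean, halves away from zero.

Preprocessing is *almost* idempotent: a second pass changes a noise-free
burst train by ~1e-5 RMS in the interior. It is not exactly idempotent for
two reasons worth knowing: the zero-phase filter's edge transients perturb
the whole-signal normalisation constant, and broadband noise retains
transition-band (< 4 Hz) energy that every pass re-attenuates. Tests
therefore check idempotence at 1e-4 on signals without sub-cutoff energy,
comparing interiors re-normalised locally.

## The ten features

| # | name | what it measures |
|---|------|------------------|
| 1 | `kurtosis_signal` | E(x⁴)/E(x²)², pulse-likeness; 3 for Gaussian noise |
| 2 | `energy_ratio_low` | Welch-PSD share in [24, 144) Hz |
| 3 | `energy_ratio_mid` | share in [144, 200) Hz |
| 4 | `energy_ratio_high` | share in [200, 500] Hz |
| 5 | `envelope_std` | spread of the frequency-smoothed envelope |
| 6 | `envelope_sampen` | SampEn(2, 0.2·σ) of the 30 Hz envelope |
| 7 | `autocorr_kurtosis` | peakedness of the envelope autocorrelation |
| 8 | `autocorr_max_peak` | max r(l), lags 0.3–2.0 s (200–30 bpm) |
| 9 | `autocorr_sampen` | SampEn of the 30 Hz autocorrelation |
| 10 | `degree_of_periodicity` | CFSD peak-to-median ratio |

Kurtosis is the raw fourth-moment ratio without centering — the input is
zero-mean by the preprocessing contract. For feature 7 the autocorrelation is
standardised first, since r(l) is not zero-mean.

The Welch estimate splits the signal into the longest Hamming-windowed
segments giving at most eight 50 %-overlapping pieces (L = ⌊2N/9⌋), with no
zero padding. Band edges are half-open [lo, hi) so 144 and 200 Hz bins are
not double-counted; the top band closes at Nyquist. The denominator is the
whole 0–500 Hz range, including the little that survives below 24 Hz.

**Frequency-smoothed envelope.** The STFT is taken with a 30-sample
rectangular window hopping one sample, and |STFT| is averaged over the
one-sided frequency bins at each frame (K = 16). Averaging the magnitude
across frequency smooths the envelope without a time-domain moving average.
One-sided rather than two-sided averaging differs only by a constant factor,
which every downstream use (std after z-norm, SampEn tolerance ∝ σ,
normalised autocorrelation) cancels. Frames are computed only where the full
window fits, so the envelope is 29 samples shorter than the signal; values
belong to window centres. No DFT zero padding: the features use envelope
shape, not spectral resolution.

**Envelope autocorrelation.** The envelope mean is subtracted before
correlating — its large DC offset would otherwise pin r(l) near 1 at every
lag and hide the cardiac peak. The autocorrelation is computed by FFT with
≥ 2N zero padding (no circular wrap), normalised to r(0) = 1, and truncated
to the first 6 s of lags (or to the longest available lag for recordings
barely over 6 s, whose envelope is 29 samples short of 6 s). The peak search
runs over 0.3–2.0 s, i.e. cardiac periods from 200 down to 30 bpm.

**Sample entropy.** SampEn(m, r, N) = −ln(A/B), where B counts ordered pairs
of length-m templates within Chebyshev distance r and A the same at length
m + 1, self-matches excluded, both over the first N − m templates. Defaults
m = 2, r = 0.2·σ. Both series are decimated to 30 Hz first (antialiased
polyphase) to keep N ≈ a few hundred. B = 0 or A = 0 returns +inf, the
documented "no regularity measurable" sentinel; a constant series returns 0.

**Cyclostationarity.** For a cycle-stationary process the autocorrelation
varies periodically in time; its Fourier coefficient at cycle frequency α is
the cyclic autocorrelation

    R_x(α, τ) = ⟨ x(t + τ/2) x(t − τ/2) e^{−j2παt} ⟩_t .

The implementation uses the equivalent asymmetric-lag form
x(t+τ)x(t)·e^{−j2πα(t+τ/2)} — identical time average at integer lags, no
half-sample interpolation — and computes it as one real×complex matrix
product against a precomputed exponential table. For real x the estimator is
exactly even in τ, so only τ ≥ 0 is stored and lags are mirrored before the
lag-DFT. At α = 0 it reduces to the ordinary biased autocorrelation.

The cyclic spectral density S_x(α, f) is the DFT over τ (Hamming lag window,
|τ| ≤ 0.5 s) and the cycle frequency spectral density (CFSD) integrates its
magnitude over f: γ_x(α) = Σ_f |S_x(α, f)|·Δf. The degree of periodicity is
dp = max γ / median γ — 1 for a flat CFSD, large when one cycle frequency
dominates, and invariant to amplitude scaling.

Implementation-defined choices (nothing in the theory fixes them): the α
grid is 0.2–4.0 Hz in 0.02 Hz steps, covering 30–200 bpm fundamentals plus
low harmonics while excluding α = 0, whose stationary spectrum would
trivially dominate both max and median; the median is taken over the full
grid including the peak; analysis uses the first 6 s of the recording,
mirroring the autocorrelation truncation, and is configurable.

## Classification and evaluation

Features are standardised with training-set statistics inside an sklearn
pipeline; the classifier is an RBF-kernel SVM with C = 1 and the
1/(n_features·var) kernel-scale heuristic — robust defaults, configurable.
No class weighting. The binary scheme maps grades {1, 2, 3} → unacceptable,
{4, 5} → acceptable. The triple scheme trains the three pairwise SVMs of a
one-vs-one design (u/g, u/e, g/e) and decodes votes: majority (≥ 2) wins, a
1-1-1 tie returns *unacceptable* — the safe side for a quality gate. This is
built by hand rather than with sklearn's ovo voting because the tie rule is
part of the method.

Metrics come from the binary/triple confusion matrices: per-class
specificity, sensitivity and positive-predictive rates, accuracy, and the
"overall rate" — the unweighted mean of the per-class rates (four in binary,
six in triple), which is fair under class imbalance. Zero denominators yield
NaN sentinels. `split_and_repeat` implements repeated random non-stratified
splits at a given training fraction, reporting mean ± std over repeats;
a split missing a class in training is redrawn with a warning.

Sequential forward selection starts from the empty set and greedily appends
the feature maximising the 5-fold cross-validated binary overall rate, ties
broken by lowest index, returning the full order and score trace. Note the
score trace need not be monotone: greedy addition can plateau or dip.

## Synthetic data

The generator emulates the signal and noise classes a quality assessor must
separate, with a known grade by construction. S1 and S2 are Gaussian-windowed
sinusoids (carriers 45 and 70 Hz, widths 20 and 15 ms, amplitudes 1 and 0.8,
random phases) placed at cycle onsets whose periods jitter by a 3 % fractional
HRV around 60/HR; S2 follows S1 by 0.35 of the cycle. Degradations: additive
white Gaussian noise at a prescribed SNR; Poisson-timed Gaussian transients
at 5–10× signal RMS (contact artefacts); and low-passed noise
amplitude-modulated at 0.15–0.4 Hz (respiration). Defaults: fs = 2 kHz
(typical of public PCG corpora, and it exercises the resampler), 16 s
duration (the modal length of real recordings), heart rates drawn from
55–100 bpm across a cohort.

Grade presets, as (SNR dB, spike rate Hz, respiratory level dB relative to
signal): grade 5 = (30, 0, −40), 4 = (15, 0.05, −20), 3 = (5, 0.2, −10),
2 = (−3, 0.5, −5), 1 = (−10, 1, 0). The 30 dB and −10 dB anchors are the
"almost noise-free" and "buried in noise" extremes; intermediate grades step
the SNR down roughly log-evenly while artefact rates grow.

What the generator does *not* emulate: murmurs and valve pathology, sensor
frequency responses, non-Gaussian ambient noise (speech, music), grade
ambiguity near category boundaries, and annotator disagreement. Synthetic
grades are cleanly separated by construction, so classification accuracies
on synthetic cohorts are upper bounds; passing tests show the pipeline's
machinery is correct and its features respond to noise in the right
direction, not that real-world accuracy would match.

## Problem sizes and numerics

The acceptance script uses cohorts of 100 recordings per grade and the
end-to-end tests 200 per grade, each 16 s — enough for stable medians and
5-fold CV with hundreds of training examples, while a full run stays in the
minutes range on one CPU. Gaussian-kurtosis convergence uses 10 draws of
10⁶ samples. Cyclic analysis cost is dominated by a (501 × 6000)·(6000 × 191)
matrix product per recording, a few tenths of a second.

Degenerate inputs fail loudly: constant signals, sub-1 kHz rates, too-short
segments and empty bands raise typed errors; undefined ratios (zero-match
SampEn, zero-median CFSD, empty confusion rows) return documented sentinels
(+inf / NaN) instead.

## Known limitations

- The 1-1-1 vote tie-break biases the triple scheme toward *unacceptable*
  by design; with well-separated classes ties are rare.
- Envelope and autocorrelation features assume ≥ 6 s of signal; recordings
  between 6 and ~6.03 s use slightly truncated lag ranges.
- SampEn of very regular series can hit the +inf sentinel when no template
  pair matches at length m + 1; the SVM treats such recordings only after
  the caller replaces sentinels (the synthetic cohorts never produce them).
- dp depends on the α grid: a heart rate whose fundamental falls off-grid
  (< 0.2 Hz or > 4 Hz, i.e. outside 12–240 bpm) would be missed; the grid
  covers the physiological range with margin.
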