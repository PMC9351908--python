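# Methods

## The signal model

During atrial fibrillation (AF) the surface ECG on any lead is, to good
approximation, a sum of three parts: a large ventricular waveform (the
QRST complex, ~1 mV) locked to each R peak at irregular RR intervals; the
continuous low-amplitude atrial fibrillatory activity (f-waves, tens of
µV, quasi-periodic at 3–12 Hz); and noise (baseline wander, powerline
interference, broadband sensor noise). Every quantity this package
computes lives on the atrial part, so the pipeline is: band-limit →
locate beats → cancel the beat-locked waveform → measure the residual.

## Preprocessing

Each lead is restricted to roughly 1–32 Hz. The implementation is a
stationary (undecimated) sym8 wavelet decomposition deep enough that the
coarsest retained detail still overlaps 1 Hz (levels 6–10 at 2 kHz);
the signal is rebuilt from those detail levels only, which removes DC and
drift exactly. Because dyadic detail bands roll off slowly above 32 Hz, a
symmetric FIR low-pass (−6 dB at 36 Hz, ~14 Hz Blackman transition) then
cleans the high edge; measured response: 0.55 at 1 Hz, ≥0.99 across
4–25 Hz, 0.03 at 50 Hz, 0.02 at 60 Hz, DC < 10⁻¹⁴. All filtering is
zero-phase with reflect padding; band-limiting twice changes RMS by
<0.1 %.

R peaks are detected on lead II (largest R in both the generator and
typical recordings) by an energy detector: differentiate, square,
integrate over 150 ms, threshold at 30 % of the running 2-s envelope
maximum, refine each detection to the absolute-amplitude maximum of its
region ±50 ms, and enforce a 200 ms refractory period keeping the larger
peak. The beat times are reused for every lead of the record, since beat
timing is lead-invariant. Detected beats become a unit impulse train.

## Event-synchronous adaptive QRST cancellation (ESAF)

The impulse train, advanced by `kernel_pre`, drives an FIR filter whose
kernel spans [−kernel_pre, +kernel_post] seconds around each R peak. A
normalized LMS adaptation with a harmonically decreasing step (the k-th
update of a tap uses `step_size`/k) minimizes residual power over
`n_passes` sweeps; at `step_size = 1` the kernel converges to the plain
R-locked beat average — the minimum-variance template a fixed number of
beats allows — while remaining a stochastic-approximation LMS, and
overlapping beats split the error equally (a Kaczmarz-style least-squares
split). The converged kernel is low-passed at the pipeline's own 36 Hz
edge (the true template is band-limited because the primary input is, so
everything above the band is pure tap-estimation variance), then the
residual is primary − (kernel placed at each beat). Samples outside every
kernel window pass through untouched.

Defaults: `kernel_pre = 0.35 s`, `kernel_post = 0.60 s`, `step_size = 1`,
`n_passes = 3`. The span is deliberately wider than the anatomical QRST
(~0.45 s): the 1 Hz high-pass edge smears the QRST's low-frequency
content (mostly the T wave) into slow tails of several hundred ms, and
any tail the kernel cannot represent leaks into the atrial residual.

### What cancellation can and cannot achieve on a 10-s epoch

On template-only input (no atrial signal, no noise) the cancellation is
essentially exact: ≥26 dB ventricular suppression is reached after the
first sweep, and more sweeps never hurt. With atrial signal present the
template must be *estimated* from the epoch's ~12 beats, and the estimate
unavoidably absorbs part of the atrial signal: for any beat-locked-kernel
method fitted to one epoch, the absorbed fraction is ≈ √(kernel_span /
epoch_duration) of the atrial RMS — about 30 % for a 0.95-s kernel on
10 s — plus the leak of filter tails outside the kernel. An exact
least-squares solve over the same model class (the global optimum)
measures 30–50 % residual RMS error at the reference conditions (1000 µV
QRS, 60 µV f-wave, 10 µV white noise), and the ESAF tracks that optimum.
This floor is a property of single-epoch template cancellation, not of
this implementation; the complexity *metrics* are far more robust to it
than the raw waveform error (DF is recovered to the grid resolution, FWA
to within ~10 % on average).

## Complexity parameters

All five are computed on the atrial residual of each lead.

* **FWA** (µV): Savitzky–Golay smoothing over 20 ms (near-unity gain in
  the fibrillatory band, unlike a boxcar), then alternating local extrema
  at least 40 ms apart with prominence ≥ 1 SD of the signal; FWA is the
  mean absolute difference of successive extrema. The prominence floor
  rejects small cancellation-residual ripple that would otherwise dilute
  the estimate with sub-fibrillatory swings; because it scales with the
  SD, FWA remains exactly amplitude-equivariant. For a pure sinusoid of
  amplitude A, FWA = 2A; the generator plants amplitude with the same
  convention (median successive peak-to-trough), so recovery tests are
  self-consistent. Fewer than 4 extrema flags the value unreliable.
* **Spectrum**: Welch, 2-s Hann segments, 50 % overlap, zero-padded to a
  0.1 Hz grid. A 2-s Hann mainlobe spans ±1 Hz, which concentrates ~95 %
  of a tone's power within ±0.5 Hz and >98 % within ±1 Hz — the leakage
  scale against which the frequency-domain parameters are calibrated.
* **DF** (Hz): argmax of the PSD in 3–12 Hz, ties toward the lower
  frequency; flagged invalid when the in-band peak is below 5 % of the
  full-spectrum peak (no fibrillatory component in band).
* **OI**: power within ±0.6 Hz of k·DF (k = 1..4, k·DF ≤ 25 Hz) over
  total 3–25 Hz power, clipped to [0, 1], rectangle-rule sums (the
  harmonic mask is non-contiguous). The 0.6 Hz half-width just covers the
  Hann mainlobe, so a pure tone scores ≈0.98 while white noise averages
  ≈ the relative window width, ~4.8/22 ≈ 0.2.
* **SE** (nats): Shannon entropy of the normalized 3–12 Hz spectrum on
  the 0.1 Hz grid (91 bins, natural log): 0 for a single bin, ln 91 ≈
  4.511 for a flat band. SE's absolute value depends entirely on this
  binning convention; values from other binnings are not comparable.
* **SampEn**: the signal is anti-alias decimated to 250 Hz (N = 2500 for
  10 s), r = 0.2 × SD, m = 2; B counts ordered template pairs of length m
  within Chebyshev distance r (self-matches excluded), A the same at
  m + 1, SampEn = −ln(A/B). A constant signal returns 0 by convention;
  B = 0 is undefined (flagged); A = 0 caps at −ln(1/B) (flagged). These
  (m, r, fs) conventions also determine SampEn's absolute scale.

## Synthetic data

The waveform generator emulates what the estimators must face: f-waves as
a harmonic series (fundamental 3–12 Hz, geometric harmonic decay 0.5,
3 harmonics) with 15 % amplitude modulation at 0.5 Hz and 2 % frequency
modulation at 0.3 Hz, rescaled so the median successive peak-to-trough
equals the requested amplitude (per-lead defaults 45/65/70/57 µV on
I/II/V1/V6, matching the cohort-level lead profile); QRST complexes built
from raised-cosine segments (Q, R, S dips/spike plus a smooth T) placed
at lognormal RR intervals (mean 0.8 s, CV 0.15, truncated above the QRST
duration — strictly positive and right-skewed like AF RR histograms);
noise as baseline wander below 0.5 Hz, a 50/60 Hz tone, and white noise,
each with configurable RMS. It does **not** model ectopy or varying QRS
morphology, electrode motion artifact, respiration-modulated amplitude,
or any torso geometry — passing tests show the pipeline recovers planted
structure under these idealized conditions, not that it is robust to
every clinical artifact.

The cohort generator draws endpoint labels at the observed prevalences
(86/130 terminations, 71/130 recurrences), then draws each metric from
the normal law of the patient's group under one stratifying endpoint
(default: termination), truncated at 0 for nonnegative quantities.
Defaults are the published per-group means/SDs of the 20 lead-metrics and
of left-atrial CT volume. Metrics are drawn independently (only marginals
are published); the second endpoint is drawn independently of the
metrics, so only effects planted for the stratifying endpoint are real.

## Outcome statistics

Continuous variables are screened per group for normality
(Lilliefors-corrected Kolmogorov–Smirnov at α = .05; both groups must
pass) and compared by Student's t-test or the Mann–Whitney U-test;
categorical variables by chi-square without continuity correction,
switching to Fisher's exact test when any expected cell is below 5.
Screened-in variables (p < .05) enter a maximum-likelihood logistic
model; ORs are per unit with Wald 95 % CIs; perfect or quasi-separation
(|log OR| > 15) makes a fit non-reportable rather than yielding a fake
CI. ROC curves are oriented so the score predicts the adverse outcome
(termination *failure*, recurrence); AUC is the trapezoid over the
empirical curve (identically the tie-aware Mann–Whitney U/(n₁n₂)), its CI
from the DeLong variance, and the reported cutoff maximizes Youden's J
with ties resolved toward higher sensitivity. The combined predictor
dichotomizes FWA V1 ("low", < 60.38 µV) and DF I ("high", > 5.70 Hz) at
their published cutoffs and refits the single indicators and their
conjunction. No multiplicity correction is applied anywhere in the
default flow; the realized type-I error of the screen is measured by
simulation (≈5–6 % at α = .05), not assumed.

## Numerical and scale choices

Acceptance-style harnesses use sizes that keep the whole suite
desk-scale: 3–6 ten-second epochs per waveform property, 20 seeds per DF
point, 500–1000 replicates for the statistical calibrations, N = 1000 for
the brute-force SampEn cross-check. Degenerate inputs are defined rather
than left to chance: flat signals yield empty peak series (flagged), zero
spectra flag every frequency-domain metric, empty impulse trains are
errors, and all-zero leads cancel to all-zero residuals.

## Known limitations

* The ~30 % atrial-waveform recovery floor on 10-s epochs discussed
  above; longer records (the acquisition protocol records ≥60 s) would
  reduce the absorbed fraction as √(span/duration) but the analysis epoch
  is fixed at 10 s.
* SE and SampEn absolute scales are convention-bound; published cohort
  magnitudes for these two metrics cannot be matched without knowing the
  original binning and (m, r, fs).
* The cohort generator plants marginal effects for one endpoint at a
  time; joint metric–endpoint structure beyond that is not represented.
* ECG interchange is CSV only (header row of lead names, µV, `# fs=`
  comment); no EDF/DICOM parsing.
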