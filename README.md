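# fibwave

Fibrillatory-wave complexity analysis of surface ECGs in atrial
fibrillation (AF), for signal-processing and clinical-EP researchers who
want a tested, reproducible implementation of the full chain from raw
multi-lead ECG to outcome statistics.

During AF the P wave is replaced by a continuous low-amplitude atrial
oscillation (the f-wave) hidden under the much larger ventricular QRST
complexes. `fibwave`:

1. **extracts the atrial signal** per lead by event-synchronous adaptive
   filtering (ESAF): each lead is band-limited to ~1–32 Hz, R peaks are
   detected and turned into an impulse train, and a normalized-LMS FIR
   kernel driven by that train learns the R-locked ventricular waveform;
   the residual is the ventricular-cancelled atrial signal;
2. **computes five complexity parameters** per lead — f-wave amplitude
   FWA (mean successive peak-to-trough, µV), dominant frequency DF
   (spectral argmax in 3–12 Hz), organization index OI (harmonic power
   fraction), spectral entropy SE (−Σ pᵢ ln pᵢ over the normalized 3–12 Hz
   spectrum), and sample entropy SampEn (−ln(A/B) at m = 2, r = 0.2 SD);
3. **runs the outcome statistics** used to evaluate such parameters as
   predictors of procedural AF termination and late recurrence after
   catheter ablation: normality-gated univariate screening, multivariate
   logistic regression (OR, Wald 95 % CI), ROC curves with Youden-optimal
   cutoffs and DeLong CIs, and a combined dichotomized predictor
   (low FWA V1 < 60.38 µV ∧ high DF I > 5.70 Hz);
4. **generates synthetic AF ECGs and cohorts** with known ground truth —
   modulated harmonic f-waves plus QRST trains at lognormal RR intervals
   plus noise, and cohort tables with planted group effects — so every
   stage is testable without patient data.

See `docs/methods.md` for the model, parameter conventions, and known
limitations (in particular the inherent atrial-recovery floor of
single-epoch template cancellation).

## Worked example

```python
from fibwave.synthetic import gen_af_ecg
from fibwave.metrics import analyze_epoch

# 10 s, 4 leads at 2 kHz: f-waves (6 Hz fundamental; pk-pk 45/65/70/57 uV
# on I/II/V1/V6) + 1 mV QRST train + baseline/powerline/white noise
epoch, truth = gen_af_ecg(seed=1)

for r in analyze_epoch(epoch):
    print(f"{r.lead:<5} {r.fwa:7.1f} {r.df:6.1f} {r.oi:6.3f} "
          f"{r.se:8.3f} {r.sampen:7.3f}")
```

prints

```
I        40.1    6.0  0.879    3.184   0.596
II       58.0    6.0  0.881    3.194   0.586
V1       61.0    6.0  0.890    3.161   0.538
V6       49.4    6.0  0.886    3.184   0.579
```

DF recovers the planted 6.0 Hz fundamental exactly on every lead; FWA
recovers the planted per-lead amplitudes to within ~10–15 % (cancellation
residual biases it slightly low); OI ≈ 0.88 reflects a strongly organized
harmonic f-wave, and SE ≈ 3.2 nats sits mid-range of its 0–ln 91 ≈ 4.51
scale. The same pipeline is available from the shell:

```sh
fibwave simulate --out data/ --n-patients 10 --seed 7   # ECGs + truth + cohort.csv
fibwave analyze  --records data/ --out metrics.csv      # per-(patient, lead) metrics
fibwave study    --cohort data/cohort.csv --out report/ # screen, logistic, ROC, combined
```

Every output carries a provenance header (version, seed, config hash) and
identical seeds give byte-identical outputs.

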