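# blinkmux

Blink-based multiplexing (BBM) of single-molecule emitters: classifying
spectrally overlapped fluorophores by their blinking dynamics instead of
their emission color.

Under continuous illumination a single fluorophore stochastically switches
between emissive (on) and non-emissive (off) states.  Different molecular
classes — rhodamines and BODIPYs blinking by dispersive electron transfer,
anthraquinones protected by excited-state intramolecular proton transfer,
quantum dots with power-law intermittency — leave different statistical
fingerprints in their binned emission-time traces, even when their spectra
are indistinguishable.  `blinkmux` implements the full analysis pipeline
for exploiting this:

1. **`synth`** — generative simulation of labelled blinking traces:
   alternating on/off renewal processes with lognormal, Weibull,
   (truncated) power-law or exponential interval durations, multiple
   emissive intensity levels, Poisson shot noise, and irreversible
   photobleaching.
2. **`changepoint`** — change-point detection (CPD) on binned photon
   counts: a generalized likelihood-ratio test under a per-bin Poisson
   model, applied by recursive bisection against Monte-Carlo critical
   values, followed by BIC-guided intensity-level grouping and on/off
   labelling (lowest level = off; on requires the mean to clear the off
   mean by one rms-noise unit).
3. **`blinkstats`** — the event taxonomy (segments = constant-intensity
   events; intervals = maximal same-state runs) and the 10 per-molecule
   blinking statistics: N_I, I_min, I_max, ⟨I⟩_t, ⟨t_on,seg⟩, ⟨t_off,seg⟩,
   ⟨t_on,int⟩, ⟨t_off,int⟩, N_on,seg, N_off,seg.
4. **`durationfit`** — CCDFs, P(T ≥ t), of pooled event durations with
   maximum-likelihood fits of heavy-tailed families and
   Kolmogorov–Smirnov goodness of fit (parametric bootstrap p values).
   Lognormal parameters are in log10 seconds: μ is the log10 median, σ
   the dispersion in decades.
5. **`classifier`** — multinomial logistic regression on z-scored
   statistics,

   P_j(x) = exp(w_j·x + b_j) / Σ_k exp(w_k·x + b_k),

   with a pivot class fixed at zero coefficients, stratified 10-fold
   cross-validation (normalisation and fit strictly fold-internal),
   confusion matrices, and probability thresholding: a molecule is kept
   only if its top class probability reaches the threshold, trading *data
   retention* for accuracy.

The estimators follow scikit-learn conventions (`fit` / `predict_proba` /
`get_params`, fitted attributes with trailing underscores) and compose
with sklearn pipelines; module-level functions are thin wrappers.

## Worked example

```python
import blinkmux as bm

cfg = bm.PipelineConfig(seed=42, classes=["R6G", "AZ"], n_per_class=75,
                        window_s=100.0, outdir="bbm_out")
res = bm.run_pipeline(cfg)
rep = res["report"]
print(rep.confusion)
print("accuracy", rep.accuracy, "min-class", rep.min_class_accuracy)
print(res["threshold"])
```

simulates 75 molecules each of an R6G-like dispersive-ET emitter
(lognormal off intervals, μ_off = −1.27, σ_off = 2.07 log10 s) and an
AZ-like ESIPT emitter (lognormal on intervals μ_on = 0.8, σ_on = 1.6;
Weibull off intervals; slower photobleaching), runs CPD with α = 0.05,
extracts the statistics, and cross-validates the classifier.  With
seed 42 it prints:

```
     AZ  R6G
AZ   50   25
R6G  11   64
accuracy 0.76 min-class 0.667
ThresholdResult(threshold=0.9, accuracy=0.903, retention=0.207, ...)
```

Read: at the default argmax rule the two classes separate at 76% pooled
accuracy (worst per-class recall 66.7%); raising the classification
threshold to 0.90 buys 90.3% accuracy over the retained molecules at the
cost of keeping only 20.7% of them — and the per-class retention report
warns that the discarding is disproportionate, so the practitioner should
check per-class retention before trusting the thresholded result.  The
run directory contains the traces, the per-molecule statistics table, the
ranked duration-distribution fits per class, the model record, the full
threshold/retention curve, and a provenance file with the master seed and
a configuration hash.

A command-line interface mirrors the stages
(`blinkmux simulate | detect | stats | fitdist | train | evaluate |
threshold | run | config`).

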