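# Methods

This note documents the models, parameter choices, and numerical
decisions behind `blinkmux`, and what the synthetic tests do and do not
demonstrate about real data.

## Generative model of a blinking trace

A molecule is an alternating renewal process: on and off interval
durations are drawn independently from per-state duration families until
the acquisition window (default 150 s) is covered.  Supported families
and parameterisations:

| family | parameters | survival / density | mechanism it models |
|---|---|---|---|
| lognormal | μ, σ (log10 s) | log10 T ~ N(μ, σ) | dispersive electron transfer (normally distributed activation barriers) |
| weibull | k, λ_s (s) | S(t) = exp(−(t/λ_s)^k) | stretched-exponential dark-state decay (ESIPT-type) |
| power_law | α, x_min | p(t) ∝ t^−α, t ≥ x_min | scale-free intermittency |
| truncated_power_law | α, x_min, cutoff rate | p(t) ∝ t^−α e^−λt | quantum-dot blinking with an exponential tail cutoff |
| exponential | rate | first-order kinetics | triplet blinking |

Lognormal parameters are interpreted in **log10 of the duration in
seconds** throughout: μ ≈ −1.3 then means a ~50 ms median off time,
consistent with event durations ranging from tens of milliseconds to
hundreds of seconds.  This convention is recorded in every output.

**Intensity levels.**  Real traces are non-binary: a molecule visits
several distinct emissive intensities (on–on switching from spectral
diffusion, conformer or photoproduct formation).  No quantitative model
of level multiplicity is available, so the generator makes a deliberately
simple choice: each molecule draws a level count (default uniform on
1–7, bracketing observed values of 5 and 7) and i.i.d. level count-rates
(default uniform 3–15 counts/bin); within an on interval, level switches
occur at sub-segment boundaries drawn from the same on-duration family,
with immediate repeats avoided so every switch is a real intensity
change.  These defaults are placeholders for an unknown mechanism, not
inferences.

**Photobleaching** is a single irreversible off transition at a drawn
time (default exponential, mean 25 s for rhodamine-type emitters — they
generally photobleach in one step within tens of seconds without
oxygen-scavenging buffers; mean 75 s for the ESIPT-protected
anthraquinone, whose proton-transfer pathway competes with the
photo-oxidation channel; no bleaching for quantum dots).

**Rendering.**  Counts per bin (default 10 ms) are Poisson with mean
equal to the time-weighted average of the active rate over the bin —
the background rate (default 0.3 counts/bin) during off time, the
segment's level rate during on time.  A bin straddling a switch gets the
exact fractional mixture.

**Preset classes.**  The presets encode the published lognormal interval
parameters where available: pooled rhodamine on intervals μ_on = 0.01,
σ_on = 1.9; off intervals μ_off = −1.3 (5ROX), −1.27/2.07 (R6G), −0.7
(R560), −0.3/2.6 (RB), −0.1 (R123); PM605 μ_on = 0.3, σ_on = 2.01,
μ_off = −0.7, σ_off = 2.04; AZ μ_on = 0.8, σ_on = 1.6.  Where only the
σ_off range 2.0–2.6 is published (5ROX, R560, R123), values inside that
range were fixed once.  The AZ off-interval Weibull shape/scale and the
quantum-dot truncated-power-law parameters are not published; the
defaults (k = 0.5, λ_s = 1 s; α = 1.6, x_min = 10 ms, cutoff ~0.05–0.1
s⁻¹) are field-typical magnitudes chosen once and documented here.  None
of the acceptance checks depend on them.

**Seeding.**  All randomness flows from one master seed through
`numpy.random.SeedSequence.spawn`, one child per molecule; identical
seeds give bit-identical populations.

## Change-point detection

Per-bin counts are modelled as Poisson.  For a region of m bins with
counts x and split k, the generalized likelihood-ratio statistic is

    G(k) = 2 [ S₁ log(S₁/k) + S₂ log(S₂/(m−k)) − S log(S/m) ],

with S₁, S₂, S the left/right/total counts (0 log 0 := 0).  Detection is
recursive bisection: the maximising split (smallest index on ties) is
accepted iff max G exceeds the critical value for m bins, then both
sides are searched.  Minimum segment length is 2 bins, so a candidate
adjacent to a region boundary is never produced (the two-rate MLE is
undefined on an empty side).

**Critical values** are the (1−α) Monte-Carlo quantiles of max G over
constant-rate Poisson traces, tabulated on a bin-count grid and
interpolated linearly in log(n_bins); default α = 0.05, 1000–2000
replicates, reference rate 5 counts/bin.  The null distribution of max G
depends on the count rate only weakly at the rates relevant here;
conditioning on the total photon count (under which the null becomes
exactly multinomial and rate-free) would remove the residual dependence
at the cost of a two-dimensional table, and is a known refinement not
taken here.  Tables carry their seed and replicate count and serialise
to JSON.

**Level grouping** starts from one level per segment and greedily merges
the adjacent-in-intensity pair that most lowers the BIC of the per-level
Poisson likelihood (−2 log L + L log n_bins), stopping when no merge
helps.  This is a committed stand-in for the unpublished grouping
criterion of the original CPD implementations; it is exactly testable
(the four-segment 1/10/10/1 configuration must give two levels by a
hand-coded BIC comparison, and statistically identical segments must
merge).

**On/off labelling**: the lowest level is off by definition; a level is
on iff its mean exceeds the off mean by more than the rms noise
(default: standard deviation of the bins assigned to the lowest level;
configurable to a fixed value).  Failing levels are folded into off in
one pass and the level table rebuilt.  A consequence worth knowing: a
molecule that never switches within the window has a single level, which
is *off* — without an intensity contrast inside the trace the convention
cannot call it emissive.

## Event taxonomy and statistics

Segments are the constant-intensity events between change points;
intervals are maximal runs of same-state segments.  The first and last
intervals of every trace are window-censored.  They are **included** in
the per-trace counts and averages (so all 10 statistics are defined for
every molecule) but **excluded** from pooled duration-distribution
fitting (where censoring biases the tail); both behaviours are
configurable.  I_min and I_max range over emissive levels only; when a
trace has no on level they are 0 and flagged degenerate, as are empty
duration averages.  ⟨I⟩_t averages over the entire trace including off
time.  Intensities stay in counts per bin, the acquisition unit.

## Duration-distribution fitting

Pooled durations of one class and event kind are summarised as the
empirical CCDF P(T ≥ t) and fitted by MLE.  The lognormal MLE without
truncation is the exact closed form μ̂ = mean(log10 t), σ̂ = population
sd(log10 t); other families use a deterministic Nelder–Mead search from
moment-based starts (the pure power law uses the closed-form Hill
estimator).  The truncated-power-law normalisation uses the upper
incomplete gamma function continued to negative order via the standard
downward recurrence, verified against quadrature in the tests.

**Acquisition floor.**  Durations below one bin time are unobservable.
Pipeline fits on trace-derived events therefore condition every
likelihood on t ≥ bin_time (truncated MLE).  Standalone `fit_mle`
defaults to no conditioning, which is the right estimator for raw
generator output and keeps the lognormal fit in closed form.  The
ranking consequence is real: comparing *unconditioned* likelihoods on
floor-truncated data systematically flatters power laws; with the
floor-conditioned likelihood the true family wins the comparison
essentially always in the simulations.

**Ranking** is by log-likelihood when parameter counts are equal and by
BIC otherwise (configurable); the KS statistic — sup |empirical −
fitted CDF|, conditioned above the floor — is always reported, with a
parametric-bootstrap p value (each replicate refit) on request.

## Classification

Features are the 10 statistics, z-scored with training-set means/sds;
zero-variance statistics are dropped and recorded.  The softmax model is
parameterised against a pivot (last class in sorted order, coefficients
fixed at zero) and fitted by L-BFGS on the penalised multinomial
likelihood from a zero start — deterministic given data.  The default
ridge (10⁻⁶ on coefficients, never intercepts) only guards perfect
separation.  The implementation is cross-checked against an independent
logistic-regression solver in the tests rather than delegating to one,
because the pivot-form coefficient set is itself a reported output.

Evaluation is stratified k-fold (default 10) with normalisation and fit
strictly fold-internal; pooled out-of-fold probabilities feed the
confusion matrix, per-class recall, and the threshold curve.  *Minimum
classification accuracy* is the minimum per-class recall at the argmax
rule — one of several readings of the headline metric, flagged here as
an interpretation.  A full-data coefficient fit is additionally produced
for interpretation only; it never enters the accuracy numbers, avoiding
the leakage inherent in establishing fit parameters on the full dataset
before cross-validating.  Retention generalises the binary rule: a
molecule is retained iff its maximum class probability reaches the
threshold; per-class retention is always reported, and a warning fires
when any class's retention falls below half the overall value (silent
class-wise discarding can reduce a ternary problem to a binary one).
Argmax ties break toward the earlier class label.

## Problem sizes

The package's own test and acceptance runs use desk-scale sizes chosen
to put Monte-Carlo error well inside the assertion tolerances: duration
round trips at n = 5000 over 20 seeds (3 standard errors of the
lognormal MLE ≈ 0.07–0.11 there), classifier calibration with 150
molecules per class over 20 seeds, CPD calibration with 1000–2000 null
replicates and 200–400 evaluation traces, and end-to-end pipeline
demonstrations with 10–75 molecules per class over 20–100 s windows.

## Limitations

- The generator emulates the *statistical* structure of blinking traces,
  not their photophysics: no spectral axis, no photon-by-photon arrival
  times, no photoproduct interconversion, no drift.  Passing tests show
  the pipeline recovers what the generative model puts in; they cannot
  certify performance on experimental traces, whose level structure and
  censoring differ in unknown ways.
- Recovered interval-duration distributions are conditioned on the
  observable window: events shorter than the CPD resolution or longer
  than the trace are missed or clipped, so pooled fits on trace-derived
  events are biased toward the window even when the generator is exactly
  lognormal.  The acceptance round trips therefore test the
  generator→fitter path on raw durations, and the trace path is
  validated structurally (change-point localisation, taxonomy, statistic
  arithmetic) rather than by distribution-parameter equality.
- Critical values are tabulated against n_bins at a reference rate, not
  against (bins, photons) jointly; see above.
- The BIC level-grouping and the one-pass off-folding rule are committed
  approximations to unpublished steps of the original CPD method.
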