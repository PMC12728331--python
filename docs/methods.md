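# Methods

## The experiment being emulated

A dyad sits in front of a shared display while two 14-channel EEG headsets
(10–20 positions AF3, F7, F3, FC5, T7, P7, O1, O2, P8, T8, FC6, F4, F8, AF4;
128 Hz) stream data to a closed-loop program. The session is 120 s
eyes-closed rest, 120 s eyes-open rest, then six 100-s feedback rounds each
followed by a 20-s break (the feedback block totals 720 s; a flag drops the
final break for the 700-s variant). In the *real* arm the display reflects
the dyad's measured interbrain coherence; in the *sham* arm it reflects the
same computation applied to uniform(0, 1) noise. Before and after, both
participants fill in 9-point questionnaires (social connectedness, shared
intentionality, perceived similarity; post-only: sense of joint control),
averaged within the dyad.

## Synthetic dyadic EEG

Each channel is the sum of

- **1/f background** with spectral exponent β (default 1.0) scaled to
  10 µV RMS,
- **band-limited oscillations** in delta/theta/alpha/beta with RMS
  amplitudes 6/4/8/3 µV (alpha-dominant, as in relaxed adults),
- a **target-band component** (default 21–23 Hz, 5 µV RMS), and
- **white sensor noise** (2 µV SD).

During feedback rounds a single band-limited oscillator s(t) is shared
between the partners: the target-band component of every homologous channel
pair is `√κ · s_subject(t) + √(1−κ) · private(t)`, so κ is the *fraction of
target-band power that is shared*. Each subject sees the shared source
through an independent slowly drifting phase jitter (SD 0.2 rad, bandwidth
< 1 Hz), applied by complex rotation of the analytic signal. During rest
and breaks κ is forced to 0 with the private component at full power, so
task and rest have matched spectra and the task − rest contrast isolates
the injected *coupling* rather than a power difference. Band-limited noise
is synthesized in the frequency domain (one-sided Gaussian spectrum with
0.5-Hz raised-cosine edges), which makes the analytic signal available
directly and gives exact band control.

All randomness flows from one integer seed; identical seeds give
bit-identical recordings.

The target-band amplitude (5 µV in a 2-Hz band) makes the injected
component dominate that band's spectral density, so κ maps onto phase
coupling with little dilution — an idealization chosen to make recovery
experiments interpretable, not a claim about effect sizes in real EEG.

### What the generator does *not* emulate

Ocular/muscle artifacts, electrode drift and impedance changes, volume
conduction within a head, inter-individual spectral differences, and any
behavioral feedback loop (κ is fixed within a session; closed-loop
adaptation is out of scope). Passing tests therefore demonstrate
correctness of the *computational chain* and its statistical calibration
under a known generative model, not robustness to real-world artifacts.

## Questionnaire scores

Dyad-level scores follow the serial structural model the analysis
estimates: with standardized coupling X,

```
M1 (joint control)   = a1·X + e1
M2 (Δ shared int.)   = a2·X + d21·M1 + e2
M3 (Δ perc. simil.)  = a3·X + d31·M1 + d32·M2 + e3
Y  (Δ social conn.)  = c'·X + b1·M1 + b2·M2 + b3·M3 + e4
```

Pre-scores are drawn from a baseline distribution and post = pre + Δ. The
default is the unclipped standardized scale; Likert mode maps onto 1–9 and
clips (clipping distorts path recovery, so it is off for estimator tests).
The default "study-like" coefficients (a1 = 0.3, d21 = 0.5, b2 = 0.35,
b1 = 0.25, d32 = 0.3, b3 = 0.2, a2 = 0.1, d31 = 0.1, a3 = c' = 0) were
anchored once to the pairwise correlation magnitudes reported for this
kind of feedback experiment (coupling–joint-control r ≈ 0.3, joint-control–ΔSI
r ≈ 0.5, ΔSI–ΔSC r ≈ 0.55) and give a chained indirect effect
a1·d21·b2 ≈ 0.05. `implied_covariance` returns the model-implied covariance
(I−B)⁻¹Ψ(I−B)⁻ᵀ used by the generator's convergence test.

## Online index: numerical choices

- Causal 4th-order Butterworth band-passes; filtering a whole round once
  and slicing windows is mathematically identical to streaming filter
  state across ticks, and is how the replay is implemented.
- Full-window Hilbert transform per tick, no tapering — matching short-
  window real-time practice; the edge bias this causes is shared by real
  and sham modes and cancels in group contrasts.
- Magnitude (not squared) single-window coherence; per-band coherence →
  mean over pairs → mean over bands → [0, 0.3] min–max normalization, in
  that order. Both conventions the order could take are config switches.
- Fixed 12-Hz update tick by default (deterministic replay of a "roughly
  12/s" loop); the session summary is insensitive to the tick rate because
  adjacent 3-s windows overlap heavily, and the analysis drivers use 2 Hz.
- The sham stream is 14 channels of uniform noise per subject from a
  dedicated seed substream; it consumes nothing from the EEG, and the
  trace is bit-identical when the recording is swapped.

## Offline spectrum: numerical choices

- Morlet wavelets with **6 cycles** at every frequency (σ_t = 6/2πf). A
  6-cycle wavelet at 1 Hz spans ~6 s — longer than a 3-s window — so
  convolution runs on each continuous segment (round or rest block) with
  mirror padding, and phases are windowed afterwards. The last 10 s of
  each round are discarded before windowing.
- Consequence of the 6-cycle choice: the spectral bandwidth is σ_f = f/6
  (≈ 4–5 Hz at 25–30 Hz), so coupling injected at 21–23 Hz genuinely
  raises measured coupling in neighboring bins well above 25 Hz. Narrower
  wavelets would sharpen the spectrum at the cost of temporal resolution.
- |atanh(CCorr)| is applied **per window**, then averaged over windows and
  all 196 ordered channel combinations (a switch provides
  average-then-transform). CCorr is clamped to |r| ≤ 1 − 1e−7 before
  atanh; windows with zero circular variance are excluded from the mean
  (zero-filling would bias toward null). The CCorr inner loop runs on
  unit phasors in complex arithmetic — sin(φ − φ̄) = Im(u·conj(R̂)) — which
  is exactly the textbook formula without trigonometric calls.
- Finite windows of independent phases give a positive mean |zCCorr|
  (≈ 0.042 for iid uniform phases of length 384); the pipeline's null
  level is validated against that Monte-Carlo constant, not against zero.
  Task − rest subtraction removes this common bias.

## Statistics

- Levene (center = mean) gates Student vs Welch at p < 0.05, per the
  analysis convention being reproduced. Cohen's d is recovered as
  t·√(1/n₁ + 1/n₂) for both variants.
- The 2×2 mixed ANOVA uses the exact difference/mean decomposition:
  Group F = t² on dyad means, interaction F = t² on difference scores,
  Time F tests the *unweighted* grand mean of the group difference-score
  means (SPSS Type III convention) against the pooled within error — all
  F(1, N−2). Simple effects reuse the pooled error (df = N−2) with a
  Bonferroni factor of 2.
- BH-FDR comes from statsmodels and is verified against a brute-force
  step-up enumeration.
- Serial mediation: variables are z-scored once on the full sample; four
  nested OLS equations; seven indirect effects as products of path
  coefficients; percentile bootstrap over dyads (default 5000 resamples,
  batched normal-equation solves). The OLS identity
  c = c' + Σ(indirect) holds to machine precision and is asserted in
  tests. No correction is applied across the seven paths — each CI is
  reported as-is, as in the convention being reproduced.
- **Known property**: percentile bootstrap CIs for *products* of
  coefficients are conservative under a complete null (when every leg of
  a path is zero the product estimate concentrates at zero quadratically),
  so the empirical coverage of zero is ~99–100%, not the nominal 95%.
  This is a documented characteristic of the estimator, not a defect of
  the implementation; power for genuinely nonzero chained effects is
  demonstrated by the recovery tests.

## Problem sizes

Full-scale defaults (960-s sessions, six rounds, 12-Hz updates) are used
for single-dyad demonstrations. Replicated experiments use scaled sessions
chosen as the package's standard test sizes: the analysis drivers and the
acceptance script run 20 dyads/arm with two 100-s rounds, 60-s rest blocks
and 2-Hz feedback updates; the recovery test suite uses one 46-s round and
two 24-s rest blocks per dyad (20 replicates of 20 vs 20 for detection;
200 group splits from a 60-dyad null pool for the false-positive rate —
dyads in the null pool are exchangeable, so label resampling gives each
replicate the exact null distribution at the cost of mild dependence
between replicates). Monotonicity/band-specificity properties use a
4-channel montage; everything else runs the full 14-channel layout.

## Limitations

- EDF export is integer-rate, 16-bit, single data-record-per-second — a
  minimal writer sufficient for interchange, not a general EDF+ library
  (reading goes through MNE).
- The ICA artifact-rejection step of a real pipeline is a pass-through
  hook (`preprocess(..., ica_hook=...)`); no component classification is
  provided.
- The online scheduler is idealized (fixed tick, zero latency); display
  rendering and acquisition-side clock sync are out of scope.
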