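# Methods

## Overview

`sweepvep` implements threshold estimation from sweep steady-state
visually evoked potentials (ssVEPs).  During a sweep trial one stimulus
parameter — Michelson contrast (%), spatial frequency (cycles/degree), or
orientation tilt (degrees) — steps through 18 logarithmically spaced
values, one second per step, while pattern reversal at 20 reversals/s
drives an oscillatory EEG response at 20 Hz.  The stimulus range defaults
are 0.1–30 % contrast, 2.7–40 cpd, and 0–4.96° tilt; because a geometric
ladder cannot contain 0°, the orientation sweep uses a configured floor
of 0.05° as its lowest step.  The first and last steps are repeated as
preview and postview, so a trial lasts 20 s.  A participant session is
6 trials × 3 conditions × 2 sweep directions = 36 trials.

"Intensity" is always meant perceptually: an increasing spatial-frequency
sweep (2.7 → 40 cpd) is *decreasing* in intensity, since fine gratings are
harder to resolve.  All amplitude-versus-stimulus modelling uses an
*easiness* axis: log10 native units for contrast and orientation, negated
linear cpd for spatial frequency (mirroring the regression axis used by
linear-extrapolation sweep analyses: linear spatial frequency, log
contrast).

## Synthetic-data generator

The generator is statistical, not biophysical.  Each presented step
carries a sinusoid at 20 Hz plus a 40 Hz harmonic (default 0.3 of the
fundamental), with amplitude

    A(x) = min(cap, gain · max(0, e(x) − e(θ)))

where `e` is the easiness map and θ the true threshold.  Defaults put
thresholds about a third of the way up each sweep (0.55 % contrast,
30 cpd, 0.3°) with gains reaching the 5 µV cap near the easiest steps —
typical occipital ssVEP magnitudes.  The scalp distribution is a Gaussian
in straight-line distance from Oz with σ = 0.02 m.  This width is
deliberately focal: the five-electrode occipital reference subtracts the
cluster's shared signal, and a broader source would leave more response
in the reference than at Oz itself, inverting electrode selection.  With
σ = 0.02 m the referenced amplitude at Oz is ≈0.60·A versus ≈0.40·A
leaking into distant channels, so Oz remains the best electrode, as in
the empirical topographies.

Noise is white Gaussian (1.5 µV SD) plus channel-independent 1/f noise
(3 µV SD, spectral exponent 1), which puts the 1-Hz-bin noise floor of a
six-trial average near 0.1 µV: easy steps reach z ≫ 2.33 while
near-threshold steps are genuinely ambiguous.  Optional blink artifacts
(off by default) are 300 µV biphasic transients on the frontal-pole
channels, present only so peak-to-peak epoch rejection has something to
reject.  Everything is reproducible from a seed.

The generator's default sampling rate is 250 Hz — the analysis rate —
rather than the 2048 Hz of a recording system; 2048 Hz simulation is
supported via the `srate` argument and the decimation path is validated
against analytic sinusoids.  What the generator does **not** model:
pattern-reversal waveform morphology (P100 etc.), eye movements, volume
conduction, correlated noise across channels, alpha rhythms.  Passing
tests therefore demonstrate correctness of the *analysis chain* under
known ground truth, not robustness to every artifact of real EEG.

## Preprocessing

Down-sampling uses polyphase resampling with the built-in anti-alias
filter.  Detrending is per-channel linear; the low-pass is a zero-phase
Hamming-window FIR at 45 Hz with transition bandwidth 25 % of the cutoff
(no notch is needed: 45 Hz already excludes 50/60 Hz mains).  Epochs are
1 s, one per core step; preview/postview are dropped.  Epoch rejection is
an automated peak-to-peak criterion (default 150 µV) standing in for
manual visual inspection — the limit is exposed rather than tuned to any
particular rejection rate.  Bad channels may be interpolated by
inverse-distance weighting over the four nearest neighbours on the
idealized head (spherical splines are available upstream via mne for
users who want them; ICA blink removal is likewise delegated).  The final
reference is the mean of the five occipital electrodes O1, O2, Oz, POz,
Iz (a Laplacian-like local reference); the set is configurable, and
common-average, single-electrode, or native referencing are available.

## Spectral estimation

Retained epochs of the same step are averaged in the time domain, which
cancels non-phase-locked noise, and a single 1-s, 1-Hz-resolution DFT bin
is taken at 20 Hz.  Amplitude normalization is 2|X_k|/N so a sinusoid
a·sin(2πft+φ) reads amplitude `a`; the phase convention is the sine
phase, reported in (−π, π].  The noise floor at 20 Hz is the mean of the
12 neighbouring 1-Hz bins (13–18 and 22–27 Hz), skipping the immediately
adjacent 19 and 21 Hz bins; the noise SD uses the sample (n−1)
normalization.  Derived per (electrode, step): adjusted amplitude
(amp − floor), z (adjusted / floor SD), SNR (amp / floor), and phase.
Rows with numerically zero floor statistics (e.g. noise-free simulations)
are flagged and carry undefined z/SNR rather than infinities.

Two diagnostics mirror standard practice: a pooled mean periodogram at
one electrode (default Oz, re-referenced to the mediofrontal electrode
Fpz) across all retained epochs, and per-step topography vectors of
noise-adjusted amplitude for map plotting.

## Electrode selection and threshold rules

The analysis electrode maximizes the mean z over the easiest half of
tested intensities (2.05–30 % contrast, 2.7–11.2 cpd, 0.34–4.96° tilt;
membership is evaluated with 2 % relative tolerance so printed range
endpoints match the geometric grid).  Ties break to the earlier montage
label.

**Sig method.**  A step is significant when z > 2.33 (one-sided p ≈
0.01), strictly; undefined z counts as non-significant.  For a sweep
whose intensity *decreases* over time, the threshold is the **last**
non-significant step with at least 3 significant steps among the 4
immediately preceding.  For *increasing*-intensity sweeps the rule is
the exact time-reversal: the **first** non-significant step with at
least 3 significant steps among the 4 immediately following.  Exact
mirroring is the design choice here because it is the only reading under
which the two sweep directions agree exactly on clean data (reversing
the mask and the sweep leaves the picked stimulus value unchanged —
a property test asserts this); two alternative readings
(`first_significant`, `swapped`) are kept behind a config switch.  The
threshold is reported as the candidate step's stimulus value — the rule
is defined on steps, so no interpolation is done.

**Reg method.**  Ordinary least squares of raw 20 Hz amplitude against
the condition's fit axis (log10 % contrast, linear cpd, log10 degrees —
the orientation axis is our extension, matching its log-spaced sweep),
ordered easy → hard.  The fit starts at the first local amplitude
maximum (plateaus count, leftmost index) with SNR ≥ 3 and ends just
before the curve first drops below the noise floor (the sub-floor step
is outside the responsive regime and is excluded from the fit), or at
the hardest step.  The threshold is the zero-crossing of the fitted
line mapped back to native units; it may extrapolate beyond the tested
range.  Validity requires ≥ 2 fit points, a slope declining toward
harder stimuli, a crossing on the hard side of the fit onset, and a
phase check: phases (unwrapped) must be constant within π/4 of the
window mean, or gradually leading (contrast) / lagging (spatial
frequency) with per-step increments within ±π/4; orientation accepts
only the constant case.  The phase check is applied to fit-window steps
with SNR ≥ 3 — below that the measured phase is the phase of the noise
and would veto essentially every sweep.

Direction combination averages on the condition's spacing scale:
geometric mean in native units for contrast and orientation, arithmetic
for spatial frequency; a single valid direction passes through flagged.

## QUEST simulation and psychometric fitting

The behavioural arm is a simulated-observer model.  Observers are
cumulative Gaussians p(x) = γ + (1−γ−λ)·Φ((x−α)/β) with γ = 1/alternatives;
the threshold is α, the steepest point, which equals the 75 % point for
lapse-free 2AFC and the 62.5 % point for 4AFC.  The staircase keeps a
posterior over candidate thresholds on a 201-point grid with a Gaussian
prior (the grid must cover the prior mean ± 4 SD), updates it by Bayes'
rule under an assumed cumulative-Gaussian likelihood (assumed β = 0.3
working-log units by default; the Weibull parameterization was not
adopted since the final fit is Gaussian as well), and places each trial
at the posterior mean shifted to the target-probability point — a zero
shift for the canonical 75 %/2AFC and 62.5 %/4AFC designs.  Placement by
posterior mean rather than mode is the default (configurable in spirit:
the state exposes the posterior, so any placement rule can be applied).
Levels are clipped to bounds and to a minimum testable level (0.25° for
the orientation analogue).  Sessions run 60 trials (30 for the 4AFC
acuity analogue); the estimate is the final posterior mean.  Convergence
is checked by evaluating the *true* psychometric function at the
estimate: over 200 sessions the mean true percent-correct comes out
within 3 points of the design target.

`fit_psychometric` is a maximum-likelihood cumulative-Gaussian fit with
γ and λ fixed (Nelder–Mead on (α, log β)); degenerate data (single level,
all-correct or all-wrong) raise a fit error rather than returning a
boundary solution.

## Score tables and statistics

The score-table generator draws latent true scores from a multivariate
normal and adds independent occasion noise with variance (1−ICC)/ICC, so
the expected test-retest ICC(3,1) hits its target.  Between-test targets
are specified as Spearman correlations of repetition-averaged scores;
the latent Pearson matrix is therefore set to 2·sin(π·ρ/6) (inverting
the Gaussian rank-correlation attenuation) and further inflated for the
residual occasion noise in repetition means.  Requests that need latent
correlations beyond ±1 or a non-positive-definite matrix raise a
structure error.

The battery: pairwise outlier exclusion by the modified z-score of
absolute score differences, Zdiff = 0.6745·(diff − median)/MAD with
MAD = median(|diff − median|), excluding Zdiff > 3 (with MAD = 0 nothing
can be excluded; a warning is emitted); exclusion is symmetric — the
participant leaves both vectors of that pair.  ICC(3,1) is computed from
the two-way ANOVA decomposition, r = (MSR − MSE)/(MSR + MSE) for k = 2,
with p from F = MSR/MSE on (n−1, n−1) df.  Spearman is Pearson on
mid-ranks with the t approximation for p (exact permutation enumeration
for n ≤ 9).  Correlations are labelled by Cohen's bands (|r| ≥ 0.1/0.3/0.5
→ small/medium/large).  p values are unadjusted.  EEG test-retest pairs
the increasing and decreasing sweep thresholds as the two "repetitions"
by default (`stats.retest_pairing: directions`).

Note one known property: because Zdiff trimming removes the most
discordant ~1.5 % of a bivariate normal sample, battery correlations are
inflated by roughly +0.05 relative to the untrimmed population value;
the generator's targets refer to untrimmed scores.

## Pipeline, seeds, and problem sizes

`run_pipeline` simulates a cohort (default 12 participants), runs the
full chain, and writes scores, thresholds, the battery report, a pooled
periodogram, and a provenance record (config hash, seed, version); the
run is bit-identical under a fixed config.  Per-participant true
thresholds spread multiplicatively around the population values
(±0.15 log10 decades SD), and each participant's simulated observer
shares a latent factor with their EEG threshold (correlation 0.5), so
between-method correlations are non-trivial.  Per-stage seeds derive
from the master seed through `numpy.random.SeedSequence` spawn keys and
stay below 2³¹.

Problem sizes were chosen so the full default cohort runs in about half
a minute on one CPU (64 channels, 250 Hz, 6 trials per direction) and
the test suite uses a reduced 8-electrode montage — the occipital
reference set plus Pz, Cz and Fpz — wherever the full montage adds cost
but no information.

## Known limitations

* The generator's noise is channel-independent; re-referencing gains
  seen with real spatially correlated noise are not reproduced.
* The Sig rule's step quantization limits EEG score resolution to the
  sweep grid (≈0.146 decades for contrast); test-retest ICCs of
  simulated EEG scores are correspondingly grid-limited.
* The Reg method's orientation fit axis (log degrees) has no external
  precedent and is flagged to users.
* Reading BDF/EDF requires annotations in the documented
  `trial=…;step=…;condition=…;direction=…` description format; arbitrary
  clinical EDFs are out of scope.
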