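# Methods

## The baseline-sensitivity paradigm

Noxious-evoked brain activity in neonates is quantified as the scaling
weight of a fixed template waveform on the Cz EEG in a site-specific
post-stimulus window. A subject's *baseline sensitivity* is the mean weight
across repeated low-intensity experimental noxious stimuli; the *clinical
response* is the weight evoked by a clinically required procedure. Because
the two are strongly linearly related within subjects, entering baseline
sensitivity as a covariate in a between-group comparison of clinical
responses removes most between-subject variance and shrinks the sample size
an intervention study needs.

## Generative model of the simulation study

Each simulated cohort has two balanced arms of `n_per_group` subjects:

- baseline sensitivity `x ~ Uniform(x_min, x_max)` independently per
  subject (defaults 0.15 and 1.85, template-weight units);
- clinical response `y = slope·x + intercept + ε`, `ε ~ N(0, resid_sd²)`
  (defaults 2.62, −0.75 and 0.37, the slope/intercept/residual scale of the
  within-subject relation the paradigm exploits);
- intervention arm: `y` is multiplied by `1 − effect` (default 0.40).

By default the multiplicative effect is applied to the realised response,
noise included ("whole-response" scaling, `scale="response"`), reading the
intervention as acting on whatever the clinical measurement would have
been. `scale="signal"` instead scales only the noise-free component and
adds the residual afterwards, reading the residual as measurement noise the
intervention cannot touch. The two differ in the intervention arm's
variance — `(1−e)²(slope²·Var(x)+ξ²)` vs `(1−e)²slope²·Var(x)+ξ²` — which
matters at large effects and large ξ; both are exercised in the tests.

Analysis per simulated cohort is ordinary least squares
`y ~ 1 + group (+ x)` with a two-sided t-test on the group coefficient at
α = 0.05. Parametric p-values are used inside the power loops (permutation
inference is provided for single-cohort analyses, where it is the primary
method; at 1000 simulations per sample size a permutation inner loop would
add nothing but cost).

Power at a given `n_per_group` is the percentage of 1000 independently
simulated cohorts with a significant group coefficient. The minimal sample
size raises `n` by one (fresh simulations at every step) and reports the
first `n` whose estimated power meets the target — the faithful
"increment" mode. Because the estimate carries binomial noise
(SE ≈ 0.7 points near 95 %), the reported crossing is itself a random
variable and is biased slightly low where the power curve is flat; a
`coarse_fine` mode (double, then bisect, fresh simulations per evaluation)
gives the same answer to within that noise at a fraction of the cost and is
the default choice for the 5 %-effect condition, whose crossing sits in the
hundreds.

### Verification against a closed-form oracle

For the unadjusted arm the group test is exactly the pooled two-sample
t-test, whose power under the generative model has a closed noncentral-t
form in the arms' first two moments. `analytic_unadjusted_power` /
`analytic_unadjusted_min_n` implement it and the test suite requires the
Monte-Carlo search to agree with it to within one increment step. Both
routes give, for example, a minimal unadjusted group size of 58 at a 40 %
effect and 9 at a 95 % effect under the default parameters. Published
figures for nominally the same design can sit noticeably higher (variance
assumptions that are not fully stated in a text description — e.g. whether
the residual is scaled by the intervention, or extra measurement noise on
the covariate — move these crossings a lot); the package reports what the
model stated above implies, and the oracle pins the Monte-Carlo side of
that statement down. The acceptance battery therefore always reports both
the simulated and, where available, the analytic values.

## Synthetic recordings

`gen_recording` emulates a stimulation session: `n_trials` experimental
stimuli then `n_clinical` clinical stimuli at a ≥10 s inter-stimulus
interval, each embedding `amplitude · template` at `latency_ms` plus a
truncated-Normal jitter (SD 10 ms, bounded by the alignment search limit of
±50 ms so ground truth stays recoverable). The amplitude is the subject's
`x` (experimental) or `y` (clinical) plus `N(0, 0.1)` trial noise, on top
of 1/f background noise of SD 0.05 (same arbitrary units; the template is
unit-norm, peak ≈ 0.08, so background and signal are comparable per
sample). The surrogate template is a deterministic biphasic two-Gaussian
waveform (negative lobe at 90 ms, positive at 190 ms of a 300 ms span);
every downstream operator accepts any unit-norm waveform from file, so the
surrogate's exact shape is immaterial to the machinery it exercises.

What the generator does *not* emulate: multi-channel topography, real EEG
non-stationarities (state changes, movement artifact morphology — artifacts
are screened by an amplitude threshold, default 100 µV), imperfect event
timing beyond Gaussian jitter, and any nonlinearity in the x–y relation.
Passing end-to-end tests therefore demonstrate that the processing chain
recovers what was embedded under these idealisations, not that it would
perform identically on clinical recordings.

## Signal processing choices

- Filters: zero-phase (forward–backward) Butterworth band-passes, order 4;
  IIR notch Q = 30 at 50 Hz (EEG) and at 50…450 Hz harmonics (EMG,
  harmonics kept below the 500 Hz band edge). EMG is rectified after all
  filtering.
- Epochs: −500…+1000 ms (EEG) or −2…+4 s (EMG) around each event, event
  sample = `round(t·fs)`, inclusive-start/exclusive-end windows, millisecond
  endpoints rounded to the nearest sample; EEG epochs baseline-corrected to
  the pre-stimulus mean. Edge-clipped or supra-threshold trials are flagged
  with a reason, never dropped silently.
- Latency alignment: exhaustive integer-sample search (step 0.5 ms at
  2 kHz) maximising Pearson correlation between the shifted analysis window
  and the reference; ties break toward the smallest |shift|, then the
  negative one; bound-hitting shifts are flagged `at_bound`. The
  within-subject-average mode runs two passes against the evolving average
  (configurable; a fully iterated variant changed no test outcome and is
  not the default).
- Projection: the magnitude is the least-squares scaling coefficient
  `⟨trial, template⟩ / ⟨template, template⟩` over the aligned window (the
  raw inner product is available behind a flag); with a unit-norm template
  the two coincide.
- Analysis windows by site: foot 400–700 ms, thigh 300–600 ms, hand
  200–500 ms; jitter bounds ±50 ms (experimental) and ±100 ms (clinical).
- Subject summaries: baseline sensitivity is the arithmetic mean over
  accepted experimental trials and is missing when fewer than 8 remain;
  reflex sensitivity uses the median (midpoint convention for even counts).

## Template validation

The cluster test forms per-timepoint paired t-statistics (evoked vs
background per-subject averages), clusters contiguous points with
|t| above the two-sided point-wise 5 % threshold (the cluster-forming rule
is configurable; the mass is the summed |t|), and refers each cluster mass
to the distribution of maximum masses under within-subject condition
sign-flips (full enumeration when `2^n ≤ n_perm`); significance is mass
above the 97.5th percentile of that null, a 5 % two-sided family-wise
level. "Background" observations are averages of epochs cut at
stimulus-free times ≥5 s from any event with the same length and baseline
rule as evoked epochs. The analysis window is the 300 ms interval about the
significant cluster's midpoint, both endpoints rounded half-up to the
nearest 100 ms.

PCA is computed on the column-centred stack of evoked and background
per-subject averages (two rows per subject) restricted to the window —
subject averages rather than single trials, centring on the grand mean, so
the condition difference loads onto the components rather than being
removed. Only the first two components are tested (paired t on the
weights); the significant one — larger |t| if both, the higher-variance
component on numerical ties, and a constant non-zero paired difference
counts as infinitely significant — is selected and correlated with the
template resampled onto the window grid by linear interpolation.

## Inference conventions

Two-sided tests throughout, α = 0.05. Permutation p-values use
`(1 + #{|t*| ≥ |t|}) / (1 + n_perm)` so p is never zero, except in
label-flip full enumeration (chosen automatically when the number of
distinct relabelings is at most `n_perm`), where p is the exact fraction of
relabelings, identity included. Models with the baseline covariate use
Freedman–Lane residual permutation under the nuisance-only model. The
repeated-immunisation comparison is a REML linear mixed model with crossed
random intercepts for subject and immunisation occasion (1st/2nd/3rd);
interpreting "number of immunisations" as a fixed covariate instead is
available via `imm_coding="fixed"` — the occasion count is small and
near-balanced, so the choice moves the group test little, and the random
coding is the default to match the stated random-effects structure.
Boundary/singular fits are flagged, not hidden.

## Problem sizes and determinism

The shipped test-and-acceptance battery uses 1000 simulated cohorts per
evaluated sample size, 400 replications for the cluster null calibration,
1000 random trials for the alignment/projection oracle equivalence and a
20-subject × 15-trial end-to-end recovery run — sizes at which the whole
suite completes in a few minutes on a single core while keeping binomial
noise on any reported rate below about 1.6 points (3 SE). All randomness
flows from explicit seeds through numpy Generators (child streams spawned
per subject/trial); fixed seeds reproduce every table and report
byte-for-byte, and each end-to-end run writes a manifest (parameters, seed,
version, artifact SHA-256) sufficient to reproduce it.

## Known limitations

- The power study inherits every simplification of the generative model
  above; in particular the uniform baseline distribution and exact
  linearity are idealisations, and the whole-response scaling choice is one
  of two defensible readings of a multiplicative intervention.
- The common-slope covariate model is mis-specified under multiplicative
  effects (the intervention arm's slope is `(1−e)·slope`); the group test
  at the mean baseline remains unbiased, which is what the power figures
  measure.
- The EDF writer is deliberately minimal (plain EDF, 16-bit, 1 s records,
  zero-padded tail) — adequate for round-tripping synthetic single-channel
  recordings, not a general-purpose exporter.
- Cohort-level statistics from clinical recordings (correlation strengths,
  group means) depend on data this package does not ship; nothing here
  estimates them.
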