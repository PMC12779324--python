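# Methods

This note documents the models behind `swdsleep`, the defaults and why
they were chosen, the numerical conventions, and what the synthetic
benchmark does and does not establish about real recordings.

## Synthetic recording model

### Vigilance-state dynamics

The hypnogram is an epoch-stepped Markov chain over (WAKE, NREM, REM):
one transition per 5-s epoch, so dwell times are geometric. This is the
simplest mechanism that reproduces polyphasic rodent sleep and it makes
bout statistics analytically predictable (mean bout length of state *i*
is `epoch_len / (1 − P[i,i])`). The default transition matrix

```
            WAKE   NREM    REM
   WAKE    0.955  0.045  0.000
   NREM    0.030  0.950  0.020
   REM     0.030  0.070  0.900
```

has stationary distribution (0.40, 0.50, 0.10) and mean bouts of ~111 s
(wake), ~100 s (NREM) and ~50 s (REM) — typical of adult rat 24-h
telemetry. REM is entered only from NREM: any WAKE→REM mass in a
user-supplied matrix is moved to WAKE→NREM before sampling, mirroring
standard rodent physiology. During the 12-h dark phase the wake
self-transition is multiplied by `dark_phase_wake_bias` (default 1.02,
a mild nocturnal wake excess) and the row renormalized. Recordings
start at 07:00 with lights off at 19:00 by default; both are
configurable, since light-cycle clock times vary between facilities.

### State-conditioned signals

EEG is synthesized per state *bout* (not per epoch) by shaping white
Gaussian noise in the frequency domain, so spectra are stationary
within a bout; bout boundaries are joined with a 0.25-s raised-cosine
crossfade to avoid spectral splatter at state changes. The per-state
PSD is a `1/f^slope` background plus an optional Gaussian band boost,
scaled to a target RMS:

| state | slope | boost          | EEG RMS | EMG RMS |
|-------|-------|----------------|---------|---------|
| WAKE  | 1     | none           | 60 µV   | 30 µV   |
| NREM  | 2     | 2.5 Hz, gain 3 | 85 µV   | 10 µV   |
| REM   | 1     | 7 Hz, gain 2.5 | 60 µV   | 4 µV    |

`gain` is the ratio of boost power to background power. These values
give every NREM epoch delta > theta power and every REM epoch theta >
delta (the generator's spectral-fidelity invariant), REM muscle atonia
(< 0.5× wake EMG), and an NREM/wake amplitude ratio of ~1.4 — high
enough for slow-wave dominance, low enough that NREM background never
crosses the seizure detector's amplitude gate under any realistic state
mix. EMG is white noise whose per-epoch RMS is the state level with
15% lognormal jitter.

### Spike-wave events

Each seizure cycle is a narrow Gaussian spike (width 4% of the cycle)
riding on a slow wave at the fundamental f₀ (default 7 Hz, constrained
to [5, 10] Hz). The spike's sharpness guarantees substantial Fourier
power at 2f₀ and above — the harmonic structure the detector keys on.
Events are scaled to `swd_amplitude_gain` (default 5) times the local
pre-injection background RMS, tapered over 0.15 s at the edges, and
added to every EEG channel.

Event count is Poisson with mean `swd_rate_per_h × hours` (default
10/h, a heavily seizing mutant; an exact count can be requested
instead). Durations are normal (4 ± 1.5 s, floored at 1.5 s). Onset
states are drawn from `swd_state_preference`, default
(0.948, 0.044, 0.005) over (wake, NREM, REM) — the onset-state split
observed in absence-model telemetry. Events are placed uniformly
within epochs of the drawn state, rejected on overlap (≥ 5-s
separation); a bounded-retry failure raises an explicit placement
error rather than silently under-delivering.

Determinism: every stream (hypnogram, signals, events) derives its
generator from `(seed, stream-id)` via `SeedSequence`, so identical
configs give bit-identical output and the streams are independent.
Cohort animals get seeds mixed from `(master seed, group index, animal
index)`, so enlarging a group never reshuffles existing animals.

### What the generator does not emulate

No circadian hormone dynamics, microarousals, spindles/K-complexes,
movement or electrode artifacts, inter-individual spectral variability,
or strain-specific baseline events. Passing tests therefore establish
that the algorithms are *correct against their own assumptions* (and
exactly recover known ground truth at realistic SNR); they do not
certify performance on artifact-laden real data, where thresholds may
need per-lab adjustment — every constant lives in a config object for
that reason.

## Seizure detector

Detection runs on a 1-s grid (finer than the 5-s scoring epoch) because
typical events last only a few seconds. Per epoch the PSD is a single
Hann periodogram zero-padded ×2 (grid ~0.5 Hz, finer than the 1-Hz
harmonic tolerance). Numerical choices that matter:

- **Baseline**: a median filter of width 8 Hz over the PSD. Median
  smoothing is robust both to the 1/f slope and to the peaks
  themselves; 8 Hz keeps a 7-Hz-spaced harmonic comb from inflating
  its own baseline.
- **Daniell smoothing** (3-bin moving average) is applied before peak
  finding. A single-segment periodogram has χ²₂ bin noise; without
  smoothing, random fluctuations in high-amplitude NREM epochs produce
  spurious "prominent peaks" at a rate of several per day.
- **Harmonic prominence**: the local maximum at 2f₀ must itself be
  ≥ 1.5× the baseline (half the fundamental's 3× requirement). A bare
  local-maximum test is nearly always satisfied by noise on a fine grid.
- **Amplitude gate**: epoch RMS ≥ 2× the recording's median epoch RMS.
  Relative-to-median makes detection invariant to overall gain.
- **Merging**: flagged epochs with gaps ≤ 1 s are merged; events < 1 s
  are discarded. Matching against ground truth uses maximal-overlap
  assignment with a ≥ 50%-of-truth-duration criterion.

At these defaults the detector reaches recall = precision = 1.0 on 40
injected 7-Hz events (gain 5×) in 2 h, with 0 false events on 24 h of
seizure-free background.

## Sleep scorer

Per-epoch features: delta power, theta power, theta/delta ratio, total
power (Welch, 2-s Hann windows, 50% overlap) and EMG RMS. The cascade:

1. EMG RMS ≥ its 60th per-recording percentile → WAKE;
2. else delta power ≥ its 60th percentile → NREM;
3. else theta/delta ≥ 1.5 → REM;
4. else theta/delta ≥ 0.10 → WAKE, else NREM.

Percentile calibration makes the scorer invariant to multiplying all
channels by a constant. Two refinements keep the cascade sane at the
edges:

- A feature enters the cascade only if its 85th/15th percentile ratio
  is ≥ 2. On a single-state recording (e.g. all wake) the percentile
  threshold would otherwise split a homogeneous cluster arbitrarily;
  with the gate, such recordings fall through to the dimensionless
  rules and classify uniformly.
- Rule 4 separates quiet broadband (wake-like) epochs from slow-wave
  epochs by spectral shape alone: on 1/f-type spectra the theta/delta
  ratio is ~0.5 for broadband wake and ~0.02 under delta dominance, so
  0.10 sits in the gap. This recovers wake epochs whose EMG falls just
  below the percentile threshold.

Smoothing absorbs interior bouts shorter than 2 epochs into the
preceding state (bouts touching a record boundary are kept — their true
extent is unknown) and relabels REM bouts that directly follow WAKE as
NREM. The two rules are iterated to a fixed point, which makes the
smoother idempotent. Epochs with zero power are flagged degenerate,
labeled UNSCORED, and excluded from threshold calibration and from
agreement denominators.

Seizure periods are *not* handled by the scorer: masking epochs that
overlap detected events (relabeled SWD before state totals, so seizure
time never counts as wake) is an analytics-stage operation, and
onset-state assignment deliberately uses the pre-mask hypnogram.

On a full simulated day at default settings the scorer reaches ~99%
epoch agreement (κ ≈ 0.99) against ground truth. This is the clean-data
ceiling of the benchmark, not a claim about noisy recordings; against
human visual scoring of real telemetry, automated scorers of this type
operate around 90% agreement with κ ≈ 0.8, and the acceptance suite
requires exactly that level (accuracy ≥ 0.90, κ ≥ 0.80).

## Analytics conventions

- Times are decimal seconds from recording start on half-open intervals
  `[start, end)`; epochs are indexed from 0; events are kept sorted and
  non-overlapping, and every reader re-validates these invariants.
- Hour bins are anchored to wall-clock hour of day; an event on a bin
  boundary belongs to the later bin. The light/dark split is two 12-h
  windows starting at `lights_off_clock`.
- An SWD is transition-initiated when its onset state is NREM, the
  enclosing NREM bout begins ≤ 30 s after a WAKE bout ends, and the
  event starts ≤ 30 s into that bout. The 30-s window (6 scoring
  epochs) is a named config constant; published reports rarely state
  their window, so it is kept explicit rather than hard-coded.
- Events are assigned to the hour containing their onset only (an event
  spanning a boundary is not double-counted).
- Means of empty sets are reported as missing (`None`/NaN), never 0,
  and propagate as such into JSON summaries. Percent-of-baseline with a
  zero baseline raises rather than returning a silent 0.
- Masking is state-agnostic: epochs overlapping an event are excluded
  from *all* state totals, not only wake.

## Statistics

- **Fisher exact (2×2)**: two-sided by the minimum-likelihood
  convention — the sum of probabilities of all tables with the observed
  margins whose hypergeometric probability does not exceed the observed
  one (scipy's convention; verified against exhaustive enumeration for
  all tables with margins ≤ 12).
- **Cohen's kappa** is computed directly from the confusion matrix;
  chance agreement pₑ = Σₖ rowₖ·colₖ / N². pₑ = 1 raises (undefined).
- **Pearson**: r with t = r·√(n−2)/√(1−r²), df = n − 2, two-sided p
  from the t distribution.
- **Two-sample**: Welch's t with Satterthwaite df, or Wilcoxon rank-sum
  (reported as W = U + n₁(n₁+1)/2) — exact enumeration when combined
  n ≤ 20 without ties, midrank/normal approximation otherwise.
- Group-level modeling beyond these (mixed models, ANOVA, post-hoc
  tests) is intentionally out of scope; `cohort_table` exports a tidy
  per-animal table for external statistical software.

## Problem sizes used by the test and acceptance suites

Cohort-level power analyses use ground-truth mode (`synthesize=False`):
hypnograms and event tables are generated without rendering raw
signals, since the endpoints (REM minutes, event counts) are functions
of the labels alone. Each replicate simulates 9 control vs 15 mutant
animals for 6 h at a baseline rate of 1 event/h, with mutant effects
REM-dwell ×0.75 and rate ×10; 100 replicates for power and 300 for the
null calibration (a proportion near 5% needs ~300 draws before a
±3-point window is a test of calibration rather than of seed luck).
Detector and scorer checks use fully rendered recordings: 2 h with 40
injected events, and 24 h for false-positive and scoring-recovery runs.

## Known limitations

- Geometric dwell times understate the long-bout tail of real sleep;
  bout-duration *distributions* from the generator should not be read
  as physiological.
- The detector requires a visible first harmonic; atypical discharges
  with weak harmonic content (or fundamentals outside 5–10 Hz) are
  missed by design.
- The scorer's percentile calibration assumes the recording contains a
  broadly representative state mix; very short or single-state
  recordings rely on the dimensionless fallback rules.
- The EDF writer targets plain EDF (16-bit, one sampling rate across
  channels, whole-second record duration with an integral sample
  count); EDF+ annotations and vendor formats are out of scope.
- At 250.4 Hz a 1-s detection epoch is 250.4 samples; epoch windows use
  250 samples anchored to the continuous-time grid, so epoch boundaries
  drift by < 1 sample relative to true time.
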