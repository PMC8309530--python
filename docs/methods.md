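# Methods

This note documents the models, parameters and design choices behind
`ecgid`, including what the synthetic cohort does and does not emulate.

## Preprocessing

Recordings are filtered with an order-8 Butterworth low-pass at 40 Hz,
applied zero-phase (forward–backward, `sosfiltfilt`).  Zero-phase filtering
was chosen to avoid phase distortion of the ECG morphology; the effective
magnitude response is squared, which only deepens the stop band.  Filtering
precedes differencing, and the quantizer operates on the consecutive
differences of the filtered signal.  Differencing removes baseline wander
and makes the pipeline invariant to additive offsets; the equal-frequency
quantizer additionally makes it invariant to positive amplitude scaling,
since quantile breakpoints scale with the data.

The quantizer places breakpoints at linear-interpolation empirical
quantiles `j/|A|`, `j = 1..|A|−1` (the standard deterministic estimator).
Intervals are half-open `[b[j−1], b[j])` with a value equal to a breakpoint
assigned to the upper interval; this tie rule is arbitrary but must be
fixed for bit-exact reproducibility.  A near-constant difference series
yields coincident quantiles; by default this raises a typed error, because
silently collapsing intervals would corrupt downstream code lengths.  An
opt-in `allow_degenerate` collapses duplicates with a warning and shrinks
the alphabet.

Default alphabet size is 20 (capital letters `A`–`T`); alphabets beyond 26
extend into lower-case letters and digits.

## Finite-context models and coding

The order-`k` model stores sparse (context, symbol) counts; contexts are
keyed as fixed-width byte strings and kept in sorted arrays so that
training is a vectorized `np.unique` and coding a vectorized binary search.
The number of stored contexts is bounded by the training length, which is
what makes `k = 20` over a 20-symbol alphabet tractable (a dense table
would have `20^20` entries).

Both training and coding treat sequences as circular: the context of the
first `k` positions wraps to the end of the same sequence.  Every position
therefore contributes exactly one count (training) and one code term
(coding); for the sequence lengths used here the wrap-around contributes
`O(k/n)` of the total and is negligible.

During relative compression the model is static — coding `x` never updates
the counts learned from `y`.  This keeps `C(x||y)` a pure function of the
reference and prevents test data from leaking into the model, which matters
when one test segment is scored against every enrolled subject.

Probabilities are computed in double precision and accumulated as
`−log2` sums.  An unseen context yields exactly the uniform `1/|A|`
(the analytic value of `(0+α)/(0+α|A|)`), so coding under an empty model
costs exactly `log2|A|` bits per symbol, which is the NRC normalizer.

**Smoothing.**  `α` interpolates between maximum likelihood and the uniform
distribution.  The `'auto'` setting resolves `α` per reference model by
evaluating the candidate grid {1, 0.5, 0.25, 0.1, 0.05, 0.02, 0.01} and
keeping the value that minimizes the reference's own self-code length, with
ties resolved toward the larger (more uniform) candidate.  This is a
deterministic, documented surrogate for adaptive smoothing rules used by
FCM compressors elsewhere; any positive numeric `α` can be passed instead
and takes precedence.  On clean quasi-periodic data the grid minimizer sits
at the small end (0.01–0.05), which also sharpens the penalty for contexts
a wrong-subject model has never seen — helpful for discrimination.

## NRC and identification

`NRC(x||y) = C(x||y)/|x|` is reported in two forms: raw bits per symbol,
and normalized by `log2|A|` so that an uninformative model scores exactly
1.  The normalization cannot change the `argmin`, so identification is
unaffected by the choice; it only makes scores comparable across alphabet
sizes.  Smoothing overhead means the normalized score can exceed 1 for a
reference that actively mispredicts (the per-position probability can fall
as low as `α/(t + α|A|)`).

Identification returns the subject with minimum NRC; exact ties go to the
lexicographically smallest subject id and are logged, so reruns are
reproducible.

**Metrics.**  With `N` subjects and exactly one decision per subject, the
evaluator computes macro one-vs-all metrics from the `N×N` confusion
matrix.  Sensitivity is the fraction of subjects correctly identified and
the other quantities follow the closed forms

```
error = 1 − SEN
accuracy = 1 − 2(1 − SEN)/N
specificity = 1 − (1 − SEN)/(N − 1)
```

because every class has exactly one positive.  F1 is the macro mean of
per-class `2TP/(2TP+FP+FN)`; unlike accuracy and specificity it depends on
how misassignments concentrate, not just on the correct count.  The macro
averaging choice is the one consistent with error being reported in steps
of `1/N`.

## Synthetic cohort

Each subject is a five-wave Gaussian PQRST template on the beat's phase
circle (positions θ, amplitudes a in mV, widths b in radians — the
parameterization of classic dynamical ECG synthesizers), plus mean RR and
RR standard deviation.  Subjects are drawn around canonical values with
12 % relative spread and rejection sampling enforces a minimum pairwise
parameter distance of 0.35, so templates are guaranteed distinguishable.

A recording traverses the template beat by beat (RR ~ truncated normal),
then applies, in order:

* **placement morphology** — a fixed per-(subject, placement)
  multiplicative perturbation of the wave parameters (relative sd 0.40
  fingers, 0.30 wrists, 0 chest: the chest is the reference projection).
  This is a crude stand-in for the different projection of the cardiac
  vector seen at each electrode site; it is identical in train and test,
  so it does not impair same-placement identification, but it is what
  makes cross-placement transfer fail;
* **session drift** — a fixed per-(subject, session ≥ 2, placement)
  perturbation (relative sd 0.015 fingers, 0.09 wrists, 0.12 chest),
  encoding the assumption that the broad chest placement area admits the
  largest electrode-repositioning error while the constrained finger
  contact is the most repeatable.  This is an encoded assumption, not a
  discovered fact; the session study then *recovers* its direction;
* **gain and sensor noise** — placement gains 0.55/0.65/1.0 and additive
  white noise of 10/6/4 µV for fingers/wrists/chest (dry electrodes
  noisier than wet gel).  Gain alone is invisible to the pipeline (scale
  invariance); the noise-to-signal ratio is what differs across
  placements;
* **baseline wander** — two slow sinusoids (~0.2–0.4 Hz, 50 µV at rest),
  amplified during movement;
* **movement artifacts** — 2–45 Hz band-limited noise bursts (~55 % duty
  cycle) with amplitude set per (placement, condition) by a proximity
  table: hand movement is strongest at the wrists (17 µV) and fingers
  (14 µV), distal movements are weak, and the chest placement barely
  reacts to anything (4–8 µV).  The amplitudes sit at sensor-noise scale
  deliberately: the pipeline works on consecutive differences, which
  amplify broadband artifact energy roughly tenfold relative to the smooth
  cardiac waveform, so artifacts of mV scale — physically plausible for
  EMG — would obliterate identification everywhere and no protocol effect
  would be visible.

All draws flow from one master seed through named substreams keyed by
(subject, session, block, placement), so a cohort regenerates
byte-identically and the three placements of one block share a single beat
train (simultaneous acquisition).  Rhythm is never perturbed by placement
or session transforms — electrodes move, the heart does not.

**What the generator does not emulate:** real inter-subject morphology
distributions, physiological circadian effects, pathology, respiration
coupling, electrode-skin impedance dynamics, or any validated lead
transform.  Passing tests therefore show that the *pipeline* recovers the
structure the generator encodes at realistic SNR and timing scales; they
are not evidence about real human cohorts.

## Study protocol and problem sizes

Reference models are trained on the first contiguous training window of
the session-1 rest block; same-session tests use the non-overlapping tail,
different-session tests the start of the session-2 rest block.  In the
duration sweep, the test block is cut into disjoint segments, each segment
is quantized and identified independently, and the per-subject decision is
the majority vote over its segments (ties go to the candidate with the
smallest summed NRC); per-segment accuracies are reported alongside, since
the vote saturates quickly.

The emulated protocol is 10 min session-1 rest (8 min train + 2 min test),
three 2-min movement blocks, and 5 min session-2 rest, at 500 Hz.  The test
suite and the acceptance script run the same studies at reduced block
durations — 3 min session-1 rest (2 min train + 1 min test), 30 s movement
blocks, 1 min session-2 rest, duration grid {10, 2} s — which keeps a full
end-to-end run in the minutes range on one CPU while preserving every
factor structure; all durations are plain configuration and scale up
unchanged.  Factor-direction checks in the unit tests use still smaller
cohorts (4–8 subjects).

## Known limitations

* The `'auto'` smoothing rule is a self-calibration surrogate, not a
  reproduction of any particular published FCM compressor's rule.
* The one-decision-per-subject evaluator rejects multiple decisions per
  subject by design; multi-segment protocols must aggregate first (the
  duration sweep's majority vote is the provided aggregator).
* NRC values are comparable within one alphabet size; across alphabet
  sizes only the normalized form is comparable, and both depend on the
  segment's own quantizer fit.
* Generator parameter values are synthetic-world settings chosen so the
  protocol effects are visible and recoverable; they are not claims about
  human electrophysiology.
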