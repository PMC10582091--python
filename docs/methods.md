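# Methods

This note documents the models and numerical choices behind `fearlfp`: what
the synthetic generator simulates, how each estimator is defined, which
defaults were genuinely open choices, and what the passing test suite does
and does not establish about real recordings.

## The scientific setting

In auditory fear conditioning, a tone (CS) paired with footshock comes to
elicit freezing — immobility lasting at least one second, measured here
from a load cell under the chamber. Extinction training (repeated
unreinforced CS presentations) suppresses freezing. Electrophysiologically,
high-fear states are accompanied by a ~4 Hz (3–6 Hz band) theta-range
rhythm in the medial prefrontal cortex (PL/IL), hippocampus and midline
thalamus, whereas movement and extinction retrieval are accompanied by a
~8 Hz (6–9 Hz band) rhythm and elevated mPFC–HPC coherence. Sinusoidal
8 Hz optogenetic stimulation of the nucleus reuniens entrains single units
at the stimulation phase. The pipeline quantifies all of these from
per-session bundles of LFPs, events, spike times and the load-cell trace.

## Synthetic sessions

Animal recordings for this paradigm are not publicly deposited, so the
package ships a generator whose output has the statistical structure the
analyses assume, with ground truth stored alongside each bundle.

**Behavioral state.** A two-state (freeze/move) alternating renewal process
with exponential dwell times truncated at a 1 s minimum. Bout-duration
statistics for this paradigm are not reported anywhere we know of; the
default mean dwells (10 s / 10 s) were chosen once for testability — they
give roughly half-frozen sessions with many bouts — and are not a claim of
behavioral fidelity.

**LFP model.** Each channel is

```
x_c(t) = Σ_k g_{k,c} · a_k(state(t)) · s_k(t − Δ_k·c) + pink + line + artifacts
```

where each oscillator source `s_k` is unit-RMS Gaussian noise bandpassed
(4th-order Butterworth, zero-phase) around its center frequency — band-
limited noise rather than a sinusoid, because real theta spectra are
band-shaped, not lines. The default pair is a 4 Hz oscillator amplified
during freezing (amplitudes 1.0 freeze / 0.25 move) and an 8 Hz oscillator
amplified during movement (0.25 / 1.0), both with 2 Hz bandwidth, shared
across regions with a 20 ms per-region lag. Sharing one source across
channels is what produces controllable inter-region coherence: for two
noisy copies of one source with in-band SNR `S²/N²`, magnitude-squared
coherence approaches `(S²/(S²+N²))²`. State gating uses a 100 ms amplitude
cross-fade to avoid step discontinuities that would leak across the
spectrum. Background is 1/f pink noise (α = 1, unit RMS), a 60 Hz line
component (amplitude 0.2), and optional boxcar motion artifacts.

**Spikes.** An inhomogeneous Poisson process sampled by thinning. During
laser-on epochs the rate is `r(φ) = r₀ · exp(κ cos(φ − φ₀)) / I₀(κ)`, whose
cycle average is exactly `r₀`: units can be strongly phase-locked without
any change in mean rate, which is the dissociation the entrainment stage
must be able to detect. The spike-phase distribution is then von Mises, so
the population MRL is the Bessel ratio `I₁(κ)/I₀(κ)` — the oracle used by
the recovery tests. Laser intensity follows `(1 + sin φ)/2` with φ = 0 at
laser onset, putting maximal light power at φ = 90°.

**Load cell.** Zero-mean Gaussian noise whose standard deviation switches
with state (defaults 0.1 frozen / 1.0 moving), cross-faded like the LFP
amplitudes.

**Protocols.** Conditioning: 180 s baseline, then five 10 s CS each
co-terminating with a 2 s US, 60 s ITIs, 60 s post-shock. Extinction: 45
CS-alone trials, 30 s ITIs. Sinusoidal-laser retrieval: laser on 5 s before
each CS onset and off 5 s after offset. Naive stimulation: twenty 5 s laser
epochs at 15 s ITIs.

## Estimators and conventions

- **Time.** Seconds, float64, session-relative; all event intervals are
  half-open `[onset, offset)`. Epoch extraction includes the sample at
  onset and excludes the sample at offset, so adjacent epochs tile the
  signal exactly.
- **Preprocessing.** Downsampling uses polyphase resampling (anti-alias
  filtered; rational ratios supported). Detrending is per-session linear,
  not per-trial. The 58–62 Hz notch is a 4th-order Butterworth band-stop
  applied forward–backward: zero phase, so it cannot bias downstream
  coherence phase. Filter family and order are configuration, not a
  fidelity claim. Artifact screening replaces manual trial rejection: a
  trial is flagged when more than 0.1% of its samples exceed 6 robust-z
  (median/MAD over the whole session). Median/MAD make the decision
  invariant to channel gain; the 6-MAD default flags only gross transients.
- **Welch PSD.** 2 s Hann windows, 50% overlap (0.5 Hz resolution — needed
  to separate 3–6 from 6–9 Hz on 10 s trials). PSDs are averaged across
  trials per subject *before* band summaries; relative power divides by the
  trapezoidal integral over 2–12 Hz, so it integrates to 1 over that band
  and is invariant to overall gain.
- **Bands.** Band edges are closed (`lo ≤ f ≤ hi`): the 6 Hz bin belongs to
  both the 3–6 and 6–9 Hz bands, matching the overlapping band labels used
  in this literature.
- **Coherence.** Welch cross-spectra with the same windowing; per-trial
  estimates averaged across trials, then the band summary is the maximum
  value in the band (with the frequency at the maximum). A single-segment
  estimate is refused — MSC is identically 1 at K = 1. The expected bias
  for independent signals is ≈ 1/K, which the calibration suite checks.
- **Coherogram.** Sliding-window multitaper estimate built directly from
  DPSS tapers (time-bandwidth 3, 5 tapers — the conventional default of
  the standard multitaper toolboxes), 3 s window, 100 ms step. A literal
  100 ms *overlap* with a 3 s window would leave 2.8 s gaps between
  windows, so the step reading is used; both are configurable.
- **Evoked power / firing.** Per-frequency (or per-bin) z-scores against
  the 2 s pre-event baseline frames. Zero baseline SD yields NaN rows,
  flagged rather than silently zeroed.
- **Entrainment.** Phases pooled across all laser-on intervals of a
  session. MRL and preferred phase from the resultant vector; Rayleigh
  `Z = nR²` with the finite-n corrected p
  `p ≈ exp(√(1 + 4n + 4(n² − (nR)²)) − (1 + 2n))`. Units are classified
  entrained at p < 0.05, uncorrected, per unit — a conventional choice,
  exposed in configuration and reported in outputs. The test is unreliable
  below ~8 spikes; a warning is emitted. Degrees are used in all
  user-facing output.
- **Freezing.** Motion envelope = moving RMS (200 ms window) of the
  detrended load-cell trace; samples below threshold are candidate
  immobility; maximal runs ≥ 1 s become bouts. The acquisition-software
  threshold is not recoverable from the literature, so the default
  (`auto`) places the threshold at the geometric midpoint of the 5th and
  95th envelope percentiles. This was chosen over a median/MAD robust-z
  rule because the envelope of a two-state trace is strongly bimodal and
  median/MAD land inside one mode depending on the freeze fraction,
  making a robust-z cut unstable; the percentile midpoint is gain-invariant
  and lands between the modes whenever both states occupy more than ~5% of
  the session. Robust-z and absolute-unit modes remain available.
- **Statistics.** Unpaired t-tests use pooled variance (Student), matching
  the integer df convention of this literature. RM/mixed ANOVAs are exact
  sums-of-squares partitions for balanced complete designs; unbalanced or
  incomplete designs are refused rather than approximated, and no
  sphericity correction is applied (reported df are uncorrected) — noted
  as a limitation. Tukey post hocs use the studentized-range distribution
  (Tukey–Kramer for unequal n); Bonferroni multiplies raw p by the number
  of comparisons, capped at 1. Fisher's exact test is two-sided by the
  probability rule (sum of hypergeometric probabilities of all tables no
  more probable than the observed one), which is the rule that reproduces
  the reported p = 0.0014 for a 7/8 vs 0/8 table. Three-way ANOVA is out
  of scope; three-factor designs must be decomposed by the caller.

## Problem sizes and determinism

Tests and the acceptance script simulate at 500 Hz (200 Hz for the
load-cell recovery check) with sessions of 30–600 s — sizes chosen so the
full suite and the acceptance run each complete in well under a minute
while leaving Monte-Carlo error comfortably inside the stated tolerances
(e.g. 2000 units for the Rayleigh type-I rate, 50 units per κ for MRL
recovery). All randomness flows through `numpy.random.default_rng` seeds;
identical seeds give bit-identical bundles and byte-identical CSV outputs,
and every pipeline run emits a manifest with the configuration hash and
seed.

## What passing tests do and do not show

The generator reproduces the *statistical structure* the analyses assume —
state-gated band power, lag-shared narrowband coherence, von Mises phase
locking, variance-switching motion. It does not model conductance-based
neuronal dynamics, volume conduction, electrode drift, chewing/grooming
artifact morphology, drug pharmacokinetics, or any coupling between
freezing and spiking. Passing recovery tests therefore establishes that
the estimators are correctly implemented and calibrated on signals with
known ground truth, not that the pipeline's defaults (artifact threshold,
freezing threshold, Welch windows) are optimal for any particular
laboratory's recordings. Figure-level effect magnitudes from animal data
are not reproducible without the original recordings; the acceptance
checks instead anchor on analytic quantities (tail probabilities, the
Fisher table), estimator calibration, and parameter recovery.
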