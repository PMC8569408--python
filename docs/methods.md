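# Methods

## Signal model of the synthetic generator

Each trial of the generator is

    x_c(t) = g_c · A · Σ_{k=1..K} k^(−γ) sin(2π k f t + φ) + n_c(t)

with `f` one of the four stimulus frequencies (stored as the exact
rationals 60/10, 60/9, 60/8, 60/6 of the 60 Hz refresh rate), `K = 4`
harmonics decaying as `k^−γ` (γ = 1 by default), a per-trial phase φ
drawn uniformly from [0, 2π) and shared across harmonics and channels
(the phase-locked SSVEP assumption — the weakest structure sufficient
for the phase-invariant CCA/MSI family), and `g_c` a spatial gain.
Labels are a seeded permutation of the balanced label vector, so every
frequency appears exactly `trials_per_frequency` times.

The noise `n_c(t)` is 1/f^β Gaussian noise (β = 1), generated
independently per channel in the frequency domain and normalized to
unit variance, plus a common-mode 1/f^β term shared by all channels
with weight 0.3 — present so that multichannel spatial filtering has
correlated noise to cancel, as real EEG does. The harmonic amplitude
`A` is set so that the focus channel (gain 1) attains the configured
broadband SNR: `snr_db = 10 log10(signal power / total noise power)`.
`snr_db = −inf` produces pure noise for chance-level checks.

### Spatial gain field

`spatial_gain` is a Gaussian of physical distance on the 3 × 7, 1.3 cm
grid: `g_c = exp(−d_c² / 2σ²)`, exactly 1 at the focus electrode.
Two regimes are used:

* **isotropic** (default): a point focus at Oz with σ = 2.0 cm. This is
  the minimal model of "displacement away from the optimal site loses
  signal" and drives the single-channel spatial-structure checks.
* **middle-row band** (`gain_sigma_col = inf`, σ = 1.3 cm vertical):
  gain 1 along the whole O1–Oz–O2 row, Gaussian falloff off-row. This
  emulates an SSVEP source spread along the occipital midline, the
  regime in which all three nominal sites carry signal and multichannel
  configurations genuinely help. The multichannel ACA/RES comparisons
  and the same-direction shift map use this field.

### Default study conditions

The defaults are fixed once and used everywhere: 25 trials per
frequency per subject (100 trials, mirroring 20 trials × 5 sessions),
5 s trials at 256 Hz, 4 signal harmonics, γ = 1, β = 1, common-mode
weight 0.3. The broadband SNR default is −15 dB with σ = 1.3 cm for
the row-band analyses: a calibration sweep over snr ∈ [−20, −12] dB
and σ ∈ {1.3, 2.0} cm placed the 2.5 s-window classifiers in their
transition region there (single-channel accuracies near 60%, well off
both chance and ceiling), which is where robustness differences are
visible at all; the qualitative orderings reported by the analysis are
stable across that whole swept range, not specific to the chosen
point. Real-data features deliberately *not* modeled: eye blinks, EMG
artifacts, impedance drift, alpha-band oscillations (an optional
`alpha_amplitude` flag adds a 10 Hz background oscillator for stress
testing, off by default because it aliases into the 10 Hz stimulus
class), inter-subject amplitude variability beyond the random
substreams, and any nonstationarity within a trial. Passing tests on
this generator therefore validate the *pipeline* — scoring rules,
combinatorics, measures, statistics — not classifier performance on
human EEG.

## Preprocessing

Decimation to 256 Hz uses an anti-alias filter before stride selection
(`scipy.signal.decimate`, zero-phase); naive striding would fold
broadband noise into the SSVEP band. The analysis band-pass is a
3rd-order Butterworth applied forward–backward (`sosfiltfilt`), i.e.
zero net phase with a 6th-order magnitude response — the standard
realization of a "zero-phase Butterworth". Edge transients are handled
by the filter's default reflective padding; at ≥ 2 s windows the
transient is negligible and windows are not trimmed. Analysis windows
start at stimulus onset (no visual-latency offset).

## Classifier numerics

* Signals and references are mean-centred per row before any
  covariance, giving correlation semantics; the 4 Hz high-pass already
  removes DC, so this is a numerical nicety, not a data change.
* All whitening uses symmetric eigendecomposition with eigenvalues
  floored at `eig_floor` (1e−12) times the largest eigenvalue. This
  makes duplicated channels (the τ = 0 delay-embedding degenerate
  case), constant channels and short windows well-defined; an exactly
  zero covariance returns score 0 instead of raising, so an all-zero
  trial classifies deterministically to the lowest frequency index via
  the tie rule.
* The joint correlation matrix of the synchronization index is built
  with `C21 = C12ᵀ` (the symmetric completion); its eigenvalues are
  clipped at 0, normalized to sum to 1, and the entropy uses natural
  logarithms with the convention `λ′ log λ′ = 0` at `λ′ = 0`. Any
  common log base yields the same S.
* Delay embedding applies to the EEG side only; the reference matrix is
  unchanged. The circular shift moves the last τ samples to the front.
* FBCCA sub-band filters are 3rd-order zero-phase Butterworth
  band-passes (the same family as the preprocessing filter); the edges
  are taken literally, so the 6 Hz fundamental lies outside the
  8–52 Hz and narrower sub-bands and contributes there only through
  its harmonics.
* Argmax ties break toward the lowest frequency index — a deterministic
  contract that only matters on degenerate input.
* Reference matrices and their whitened forms are cached per
  (frequency, harmonic count, rate, window length): the combination
  sweeps reuse each reference thousands of times.

## Robustness measures

Accuracy per combination pools all trials of a subject (sessions are
not distinguished). RES uses the sample (n−1) standard deviation in
the CV; a constant accuracy field yields RES = 1 exactly, and a zero
mean accuracy raises (CV undefined). Combination tuples are ordered
(left, middle, right) in deterministic lexicographic order; the
overlap exclusion removes the 27 + 27 tuples that repeat a channel,
leaving 675. `max_combos` takes an evenly spaced deterministic
subsample of a combination list for scaled-down runs — used by the
smoke tests and example scripts; the full grids remain the default.

The same-direction shift map interprets the nine cases as the 3 × 3
king-move neighbourhood of the (O1, Oz, O2) trio, including the
unshifted centre; min–max normalization is applied within one window
length, and an all-equal map (possible at accuracy ceiling) normalizes
to zeros with a warning rather than 0/0.

## Statistics

The two-way repeated-measures ANOVA (statsmodels `AnovaRM`) reports
uncorrected integer degrees of freedom — (2, 40), (4, 80), (8, 160)
for 21 subjects × 3 channel counts × 5 algorithms — with no sphericity
correction. Post-hoc paired t-tests are two-sided with Bonferroni
correction over the family of all level pairs of the tested factor per
window length (3 pairs for channels, 10 for algorithms), capped at 1.
Zero-variance difference vectors are flagged `degenerate` and reported
non-significant instead of raising, and the table carries a separate
sign-of-difference column so direction is never encoded in the
p-value.

## Problem sizes

The test suite and the reproduction script run scaled-down grids
chosen as the smallest sizes at which the checked contrasts are stable:
10 simulated subjects, 40 trials each, 2.5 s windows, the full
9-combination single-channel grid and a 20-combination subsample of
the 675 three-channel cases. The full 675 × 5-algorithm × 7-window
sweep is available through `run_experiment` / the CLI with
`max_combos = None`.

## Known limitations

* The generator's rank-one spatial model (one gain field, identical
  signal phase across channels) cannot express multi-source occipital
  topographies; MSI/EMSI's advantage over the CCA family on real
  multichannel EEG is therefore only partially reproduced.
* The deposited-dataset `.mat` adapter is best-effort (array/label
  heuristics) and not covered by the acceptance surface.
* Continuous (non-epoched) EEG and standard interchange formats
  (EDF/BDF/BrainVision) are out of scope; recordings live in the
  package's `.npy` + JSON container.
* No artifact rejection, re-referencing or channel interpolation is
  performed anywhere in the pipeline.
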