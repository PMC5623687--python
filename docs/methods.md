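# Methods

## Processing pipeline

Six EMG channels and one MMG (force-sensing-resistor) channel, sampled at
1 kHz, are segmented into sliding windows of 150 ms advancing by 100 ms
(50 ms overlap). Sample counts are derived as `round(ms * fs / 1000)` and
windows are the half-open index ranges `[start, start + W)`; the number of
full windows in `N` samples is `floor((N − W)/I) + 1`. A window is labeled
by its **last** sample's ground truth — the causal convention, chosen
because an online decision may only depend on past samples. (Offline
training segments each class's concatenated contractions separately, so
no window straddles a class boundary there; 16 s of one class yields 159
windows.)

Per window and channel, four time-domain features are computed: MAV, ZC,
WL, SSC. ZC counts sign changes whose amplitude step exceeds a deadband;
SSC counts slope-sign flips whose two adjacent slopes both exceed it. The
deadband defaults to 0 — the classical feature definitions — and is
exposed for noise suppression. Stacked channel-major, six channels give a
24-column feature matrix.

## Classifier

A shared-covariance Gaussian discriminant (LDA): per-class means, pooled
within-class covariance (scatter divided by N − k), empirical priors.
Predictions maximize `x'Σ⁻¹μ_c − ½μ_c'Σ⁻¹μ_c + log π_c`; ties break
deterministically toward the earlier class in the canonical order
(HC, HO, WE, WF, WP, WS, NM). Diagonal shrinkage `λ = 10⁻⁶·trace(Σ)/p`
keeps the pooled covariance invertible on degenerate training sets;
well-conditioned predictions are verified in the tests against both a
dense per-row evaluation and scikit-learn's LDA. Cross-validation uses
stratified folds with a fixed seed (scikit-learn's `StratifiedKFold`);
the error rate is the fraction of misclassified held-out windows.

## Motion-onset detectors and calibration

* **extMAV**: per-window sum of the six channel MAVs.
* **extTKE**: the Teager–Kaiser operator `x²(k) − x(k−1)x(k+1)` at every
  interior sample (the first and last sample of a window carry no value),
  summed across channels, then the per-window maximum.
* **extMMG**: per-window maximum of the raw MMG samples.

EMG-derived thresholds are onset = offset = baseline mean + 3 SD.
Decisions left open by the defining rules, resolved here:

* Baseline statistics are computed over *windows* (not raw samples), from
  rest-labeled windows of the training session, excluding a 300 ms guard
  after each contraction offset so decaying activity cannot inflate the
  baseline.
* The SD is the population SD (divide by n); configurable via `ddof`.
* A usability check warns when the calibrated onset threshold exceeds the
  5th percentile of active-window detector values — the analogue of
  subjects for whom an EMG-derived threshold cannot be determined.

MMG thresholds: onset = ⅓ of the globally smallest initial peaking value
(IPV) over all (class, trial) contractions; per-class offset = ⅔ of that
class's smallest plateau amplitude. The IPV estimator is the maximum MMG
within a 500 ms span after contraction onset; the plateau estimator is
the median over the middle 50% of the contraction span. Both estimator
definitions are this package's choices (the quantities themselves are
standard but their estimators are not fixed by convention); both spans
are configurable. Calibration provenance (every IPV and plateau value
used) is stored in the threshold set.

## The locking state machine

Per window, the detector value `d` and classifier output `c` drive:

1. **Rest**: `d < onset` → emit NM.
2. **Decision**: `d ≥ onset` → emit `c` verbatim (including NM windows,
   which are passed through but not counted) while accumulating the first
   6 *active* outputs; their majority becomes the decision output, and
   the machine locks. If `d` drops below onset first → state 3.
3. **Rest (abort)**: emit NM, return to state 1.
4. **Locking**: emit the decision output every window until `d <
   offset`. For MMG the offset of the *decided* class is looked up. If
   `onset ≤ d < offset` → state 5 (possible only when offset > onset,
   i.e. MMG); if `d < onset` → state 6.
5. **Unlocking**: emit NM. `d ≥ offset` again within a 3-window grace →
   back to state 4 with the same decision; `d < onset` → state 6; grace
   exhausted → state 2 immediately (the decision is remade, starting with
   the current window).
6. **Rest (release)**: emit NM, clear the per-class offset, and require 3
   consecutive windows below onset before a new decision stage may begin
   (an above-onset window during this hold resets the count).

Tie-breaks and counts left open by the state descriptions: the decision
majority breaks ties toward the most recently seen class; grace counting
starts at the first window below offset, and re-locking must occur at or
before the 3rd such window (inclusive); the minimal rest duration is 3
windows (~300 ms). All three counts are configurable (`PostprocConfig`).

With offset = onset (MAV/TKE) state 5 is unreachable and the machine
degenerates to five states. Whenever offset ≥ onset, NM is emitted at
every window with `d < onset` (NM-safety), and the emitted class is
constant within any maximal locking run — both are asserted as properties
on random streams. A sweep can scale the MMG onset above a fixed offset;
lock release then still follows the offset rule, so NM-safety is only
guaranteed for offset ≥ onset.

The production implementation is checked for exact equivalence against an
independently written straight-line interpreter of the rules on 1,000
random streams in both threshold regimes.

The 3-point majority-vote baseline emits the mode of the last three
classifier outputs (first two windows pass through; three distinct
candidates retain the previously emitted output).

## Online metrics

Scored per window against the designated prompt sequence; **any**
deviation counts as an error, including response-delay mismatch — the
metrics judge the whole closed-loop system, not the classifier alone.
TER/MER/RER are error fractions over all/motion/rest windows and satisfy
`TER·L = MER·L_motion + RER·L_rest` exactly as counts. Per designated
class: MSTER (any error), MSAER (wrong-active output only), MSSR
(switches). A switch is counted once at each window where a wrong active
class first appears (the previous window's output differs); entering a
second wrong class directly from a first counts again.

## Threshold sensitivity

Recorded per-window detector values and classifier outputs suffice to
replay the state machine under rescaled thresholds with no signal
reprocessing; replay at multiplier 1.0 is verified to reproduce the
original run exactly. EMG-derived detectors sweep onset and offset
together over 25 log-spaced multipliers in [0.1, 10] (they are defined
equal); MMG sweeps the onset over 13 linear multipliers in [0.5, 2] with
the per-class offsets held at their calibrated values. Each grid's range
follows the respective calibration convention; the grid densities are
package defaults.

## Synthetic session generator

The generator reproduces the phenomenology the method depends on, not
muscle physiology:

* **EMG**: per channel, an on/off gain profile (per-class six-channel
  gain pattern; one dominant electrode, crosstalk 0.45 on its neighbour,
  0.15 elsewhere) smoothed by an exact first-order response with
  asymmetric time constants (rise 30 ms, fall 40 ms — surface-EMG
  amplitude rises and collapses quickly at motion boundaries), multiplied
  by white Gaussian noise, plus independent baseline noise
  (SD 0.06 a.u.). Trial-to-trial force variability is a per-contraction
  log-normal amplitude jitter (SD 0.35) plus a slow sinusoidal force
  modulation (depth 0.15 at 0.6 Hz) and an optional linear fatigue drift
  (0 by default). The jitter value is the main source of class overlap:
  with these defaults the offline fivefold-CV error lands near 3%,
  matching the mid-90s accuracy regime reported for this electrode
  montage and feature set.
* **MMG**: per contraction, a trapezoidal envelope lagging the EMG by
  150 ms (ramps 100/80 ms) scaled by the class plateau (1.7–2.4 a.u.)
  with a multiplicative overshoot pulse at onset (peak/plateau ratio 1.5,
  decay 300 ms) — so the initial peaking value exceeds the plateau, which
  the MMG calibration rule requires — plus additive noise (SD 0.02).
* **Protocols**: offline — six motions held 4 s with 3 s rests, four
  repetitions; online — WP-WE-HO-WS-HC-WF with ~2 s contractions and
  ~2 s rests, four consecutive trials.
* **Output corruption**: `corrupt_outputs` emulates online
  misclassification texture by replacing active windows of a classifier
  stream with wrong active classes until a target fraction is corrupted.
  Episodes are a mixture: with probability 2/3 a single-window transient
  (placed uniformly), otherwise a sustained burst of `burst_len` windows
  carrying one wrong class, placed with a quadratic late-in-contraction
  bias (sustained errors cluster late in contractions, consistent with
  fatigue) and truncated at contraction boundaries. The 2/3 transient
  share puts ~40% of the corrupted window mass in isolated errors — the
  share that a 3-point majority vote is able to remove in published
  online comparisons.

One integer seed drives a single pseudo-random stream consumed in a fixed
order (per-segment jitter and modulation phases in protocol order, EMG
activation noise, EMG baseline noise, MMG noise), so identical inputs are
bit-identical. Amplitudes are arbitrary units throughout; every threshold
is calibrated from the data, so the scale never matters.

**What the generator does not emulate.** Electrode shift, crosstalk
drift, real FSR mechanics, subject response delay, and rest-phase
disturbances are absent. In particular, synthetic rest is cleaner than
real rest: the raw classifier stream makes few rest errors, while lock
release pays a detector-decay tail of one to a few windows at each motion
offset. Consequently the locking scenarios improve the motion error rate
and eliminate within-lock switching — the mechanism under study — but do
*not* reproduce the rest-error improvement seen on real recordings;
passing tests demonstrate the former, not the latter. Absolute error
rates on synthetic sessions are qualitative.

## Problem sizes and numerics

The test suite and the acceptance script use the protocol-length sessions
above (offline: 171 s, 1,113 windows; online: ~98 s, 979 windows), 20
online sessions per batch, 1,000 random streams for the state-machine
equivalence check, and 500 random sequence pairs for metric-identity
checks. Floating-point text round-trips use 12 significant digits.
Detector series are required finite; degenerate cases (empty windows,
too-short baselines, missing calibration classes) raise typed errors
rather than propagating NaNs.
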