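# Methods

This note documents the models, parameters, and design choices behind
`oddballeeg`, and what the synthetic cohort does and does not emulate.

## Analysis pipeline

### Epoching and preprocessing

Continuous recordings (16 channels of the 10–20 subset FZ CZ PZ OZ C1–C6
CP3 CP4 P3 P4 PO7 PO8, 256 Hz, µV) carry stimulus markers labelled
target/non-target. Only target (oddball) events are epoched, from 300 ms
before to 700 ms after the stimulus; at 256 Hz that is
round(76.8) + round(179.2) + 1 = 257 samples (rounding is half away from
zero; both endpoints are included; sample indexing is 0-based). Events too
close to a recording edge are dropped with a logged reason.

DC baseline correction subtracts, per trial and channel, the mean of the
[−200, 0] ms window.

A trial is rejected when **any** rule fires on **any** channel:

| rule | definition | default threshold |
|---|---|---|
| peak-to-peak | max − min of the post-stimulus window | > 200 µV |
| SD | SD of the post-stimulus window | > 50 µV |
| NSR | SD(baseline window) / SD(post-stimulus window) | > 0.7 |

The NSR ("noise-to-signal ratio") is not a standard quantity; the
definition adopted here flags trials whose evoked activity does not rise
above the pre-stimulus background. The SD rule is sometimes printed in
the opposite direction ("< 50 rejects") in protocol descriptions; that
direction would discard clean low-amplitude trials, so the default is
`sd_mode="above"`, with `sd_mode="literal_below"` retained for fidelity
experiments. Per-channel evaluation with whole-trial rejection is the
conservative common ERP practice.

### Time–frequency power

Each kept trial is convolved with unit-energy complex Morlet wavelets on
a 0.5–40 Hz grid in 0.75 Hz steps (53 frequencies); the number of cycles
grows linearly from 2 at 0.5 Hz to 10 at 40 Hz, trading temporal for
spectral precision with frequency. Convolution is frequency-domain, in
single precision, with reflection padding of one epoch length per side so
edge artifacts stay inside the padding; wavelets are truncated at ±3
temporal sigma.

With pow(t) = v(t)², A(f, t) the average of pow over kept trials, and
R(f) the time-average of A over the [−200, 0] ms baseline, the reported
quantity is

    power % change = 100 · (A − R) / R

(≥ −100 by construction; > 0 is event-related synchronization, < 0
desynchronization). Percent change is averaged into bands. The printed
band list (Delta 0.5–3, Theta 4–8, Alpha 9–13, Beta 14–30 Hz) leaves the
0.75 Hz grid points at 3–4, 8–9 and 13–14 Hz unassigned, so bands are
made exhaustive as half-open intervals Delta [0.5, 3.5), Theta [3.5, 8.5),
Alpha [8.5, 13.5), Beta [13.5, 30]; grid frequencies above 30 Hz are
decomposed but belong to no band. Per channel and band the P300 peak
feature is the maximum percent change in [200, 650] ms and its latency;
ties resolve to the earliest time point.

Two properties of this estimator are worth knowing:

* **Baseline back-smearing.** The wavelet's temporal support smears
  post-stimulus power backwards into a baseline that ends at t = 0. For
  an idealized amplitude doubling at t = 0 (4:1 power ratio, ideal
  +300%), the default [−200, 0] ms baseline absorbs enough post-stimulus
  power that the measured change is ~210–230% at any carrier of the
  default bank. The +300% figure is recovered exactly when the baseline
  window is separated from the step by more than the wavelet support
  (the analytic checks in the test-suite use an epoch of −1000..700 ms
  with baseline [−900, −400] ms for precisely this reason). On real
  evoked responses the bias is far smaller because evoked power is a
  modest fraction of total power.
* **Spectral leakage between bands.** Alpha-bin wavelets (~4 cycles) are
  ~2.4 Hz wide, so a strong 6 Hz (theta) transient leaks measurably into
  the lower alpha bins. In the synthetic cohort this biases the alpha
  peak latency by roughly +10 ms identically in both groups; group
  contrasts are unaffected.

### Connectivity (ISPC)

Each band is isolated with a zero-phase 4th-order Butterworth band-pass
(`sosfiltfilt`) at the same band-bin edges used for power, and the
instantaneous phase is the angle of the Hilbert analytic signal. An FIR
filter with a usable transition at the 0.5 Hz Delta edge would need more
taps than the 257-sample epoch holds, hence the IIR choice.

Inter-site phase clustering between channels x and y in band f is

    ISPC_xy(f) = | mean over trials of ( mean over t of e^{i(φx(t) − φy(t))} ) |

with the magnitude taken **after** averaging over trials, and the time
mean running over the epoch minus a 50 ms guard per edge (filter
transients). The source formulation is ambiguous about the aggregation
order; taking the magnitude per trial first was rejected because the
per-trial resultant length of band-limited phase differences has a
Rayleigh floor of roughly 1/√(bandwidth × window) (≈ 0.45 for Alpha over
0.9 s), which destroys the bounded-below-by-zero calibration the
parameter-recovery tests rely on. With the adopted order, a phase offset
that is consistent across trials counts as coupling (ISPC = 1 for any
constant lag), offsets random across trials average out (ISPC → 0 as
1/√n), and von Mises phase jitter with concentration κ gives the
closed-form expectation I₁(κ)/I₀(κ).

The full ISPC table is symmetric with unit diagonal, 120 unique pairs per
band for 16 channels.

### Group statistics

The variable table has, per subject, 16 electrodes × 4 bands × 2
conditions (peak power, peak latency) = 128 power variables and
16 × 15 × 4 = 960 connectivity variables (1088 total). The 960 count
implies both orientations of each symmetric pair are present; they are,
with equal values, and a de-duplicated view (480 unique pairs) is
available where the duplication would inflate test counts.

Screening uses the two-sided Wilcoxon rank-sum test: exact (full
enumeration) when both groups have ≤ 6 subjects and no ties, otherwise
the normal approximation with midranks and continuity correction. With
continuity correction the test is mildly conservative at the study sizes
(null flag rate ≈ 4–5% at α = 0.05). FDR adjustment is the classical
step-up rule: p-values sorted ascending and ranked r = 1..n, the top
rank kept, each next value min(previous adjusted, p(r)·n/r).

The point-wise permutation analysis shuffles subject labels without
replacement (preserving group sizes, default 12/16), rebuilds the
group-mean difference map 1000 times, and reports per pixel the fraction
of |null differences| ≥ |observed| (two-sided, matching the two-tailed
extreme correction). The extreme-point correction records each shuffled
map's minimum and maximum; observed pixels below the 2.5th percentile of
the minima or above the 97.5th percentile of the maxima are
family-wise significant (~5% family-wise error under the null). Both
operations draw the identical permutation stream under the same seed, so
the extreme-point mask is nested inside the pixel-wise p < 0.05 mask on
the same data.

### Classification

Selection mirrors the nested protocol: an outer stratified 4-fold holds
out 25% of each group; on the remaining 75% an inner stratified 3-fold
runs and, per inner fold, every variable with rank-sum p < 0.05 on the
inner-training subjects is tallied; the loop repeats 25 times
(4 × 3 × 25 = 300 tallies) with fold shuffling governed by the run seed.
Held-out outer subjects never influence selection. The top-tallied
variable is the biomarker; the selection is labelled *stable* when the
top variable was significant in ≥ 90% of folds — tallies are strongly
correlated across folds (folds share subjects), so a lucky noise variable
can clear half the folds but not saturate them.

The classifier is a linear SVM with C = 1 (no tuning — the protocol
specifies a "simple" SVM), features z-scored with training-fold
statistics only, evaluated by leave-one-out cross-validation. The
ALS-like group is the positive class, so specificity = fraction of
controls classified correctly. Kernel density views use a Gaussian kernel
with Silverman's bandwidth; a zero-variance group falls back to a fixed
narrow bandwidth of 1e-3·max(1, |mean|).

## Synthetic cohort generator

Real recordings for this paradigm are not publicly distributable, so the
generator produces cohorts with the observed ALS-direction effects under
full experimenter control. Defaults are the study conditions: 16 controls
vs 12 ALS-like subjects, 264 target trials each, 256 Hz, the 16-channel
montage, stimuli 1.25 s apart.

Each continuous session is a sum of:

1. **1/f background noise** — white noise shaped in the frequency domain
   to amplitude ∝ f^(−a/2) (a = 1), flat below 0.5 Hz (EEG is
   AC-coupled; unbounded drift is unphysical), normalized to 1.0 µV SD
   per channel.
2. **Ongoing band oscillations** at the band carriers 1.5 / 6 / 10 / 20
   Hz (amplitudes 1.5 / 1.5 / 4.5 / 1.5 µV), with phase redrawn
   uniformly every inter-stimulus segment and tapered 45 ms at segment
   edges (the epoch windows never touch the tapers). Channel pairs
   designated in the coupling map share the hub channel's phase plus
   independent von Mises jitter with concentration κ, constant within a
   segment — which survives band filtering exactly and yields the
   closed-form expected ISPC I₁(κ)/I₀(κ). Default coupling: Alpha band,
   PO7 against CZ C1 C2 C3 C4 CP4 (the electrodes above the motor
   cortex), κ = 4 (ISPC ≈ 0.86).
3. **Evoked Gabor atoms** after every target stimulus, one per band
   (amplitudes 24 / 4 / 2.2 / 7 µV; latencies 400 / 380 / 430 / 450 ms;
   envelope sigmas 180 / 120 / 100 / 80 ms), with ±15% per-trial
   amplitude jitter, a per-subject lognormal amplitude factor
   (σ = 0.15), and per-subject latency jitter (SD 15 ms). Gabor carrier
   phase is randomized per channel and per trial — unlike a real
   phase-locked ERP — so the evoked response cannot masquerade as phase
   coupling; power features are unaffected because power is phase-blind.
4. **Artifact spikes**: with probability 0.05 per trial, one ±250 µV
   single-sample spike on a random channel in the post-stimulus window,
   which deterministically triggers the peak-to-peak rule.

The ALS-like group applies three effects: Beta Gabor power × 0.5
(amplitude × √0.5), +60 ms latency on the Delta and Alpha atoms, and
κ − 3 on the designated Alpha pairs (κ 4 → 1, ISPC 0.86 → 0.45). Ground
truth (actual multipliers, latencies, κ per pair) is stored with every
session and in the JSON sidecar next to each EDF file.

**How the defaults were chosen.** The amplitude budget is constrained
from several directions at once: clean trials must pass the NSR > 0.7
rejection rule with margin across the subject amplitude distribution
(evoked variance must comfortably exceed baseline variance — hence the
large Delta atom), while the Alpha evoked atom must stay well below the
Alpha carrier so that measured pair phases track the injected coupling
(with the chosen 2.2 vs 4.5 µV ratio the ISPC attenuation through the
full noise + filter + Hilbert chain is ≤ 0.04 across κ ∈ [0.5, 4], inside
the ±0.05 recovery band). The frozen defaults satisfy all generator
contracts simultaneously: zero clean-trial rejections at cohort scale,
artifact rejection rate ≈ the configured rate, Bessel-ratio ISPC
recovery, and rank-sum-detectable latency and power effects at the study
group sizes.

**Known interactions.** With the default +60 ms latency shift, the
delayed Delta atom extends into the epoch-end reflection padding, which
mirrors part of its energy back into the epoch and creates a secondary
Delta peak-power group difference. It is a legitimate consequence of the
injected latency effect interacting with the decomposition's padding, and
it is why the end-to-end recovery checks use cohorts carrying only the
Beta-power and Alpha-coupling effects.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: realistic scalp topography (evoked amplitudes
are spatially uniform), phase-locked ERPs, eye-blink/EMG artifact
morphology (only idealized spikes), volume-conduction correlations
between channels, non-stationarity across a session, overlapping
responses to non-target stimuli (non-targets exist only as event
bookkeeping), and realistic inter-stimulus timing (spacing is chosen for
epoch non-overlap, not paradigm fidelity).

## Numerical choices and problem sizes

* Time–frequency convolution runs in single precision (complex64) with
  power accumulated in double; this changes percent-change values by
  < 0.1% and roughly halves runtime.
* All stochastic stages take explicit integer seeds; per-subject seeds
  derive from the cohort seed via `numpy.random.SeedSequence` and stay
  below 2³¹. Identical configs reproduce bit-identical signals and
  manifests.
* EDF export quantizes to 16 bits over ±1000 µV (step ≈ 0.031 µV) and
  requires an integer sampling rate; reading goes through `mne`, which
  doubles as an independent check on the writer.
* Percentiles in the extreme-point correction use NumPy's default linear
  interpolation.
* The test-suite and the acceptance script run full-size cohorts
  (12 vs 16 × 264 trials) for the structure and recovery checks, and
  scaled-down Monte-Carlo settings chosen once for the purely
  calibrational checks (e.g. 8 cohort draws at 80 trials/subject for the
  Beta-effect detection example; 30 repeats for pixel-wise flag rates;
  200 runs for family-wise error). Null-calibration rates do not depend
  on the per-subject trial count.

## Limitations

* The rank-sum normal approximation (with continuity correction) is
  conservative at n = 12 vs 16; exact enumeration is used only for
  groups of ≤ 6.
* ISPC values at 264 trials carry a sampling SD of ~0.03–0.04 at low
  coupling; recovery statements are about means over sessions.
* The permutation analysis treats subjects as exchangeable under the
  null; covariate imbalance (e.g. age) is not modelled.
* Band-edge effects: the 0.75 Hz grid places no bin exactly at a printed
  band boundary; the half-open binning is one reasonable resolution.
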