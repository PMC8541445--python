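# oddballeeg

EEG analysis pipeline for P300 oddball experiments, built to study how
amyotrophic lateral sclerosis (ALS) alters frequency-specific brain
activity and functional connectivity during a cognitive task. It targets
researchers who have multichannel oddball recordings (or want fully
controlled synthetic ones) and need the complete chain from raw epochs to
a biomarker classifier:

1. **Preprocessing** — epoch −300..+700 ms around target stimuli, DC
   baseline correction over [−200, 0] ms, automatic trial rejection
   (peak-to-peak > 200 µV, post-stimulus SD > 50 µV, noise-to-signal
   ratio > 0.7).
2. **Time–frequency power** — complex Morlet decomposition (0.5–40 Hz,
   0.75 Hz grid, 2–10 cycles), baseline-normalized percent change

       pow(t) = v(t)²,  A(f,t) = ⟨pow⟩_trials,  R(f) = ⟨A⟩_baseline,
       power % change = 100 · (A − R) / R

   averaged into Delta/Theta/Alpha/Beta bands, with the P300 peak power
   and latency extracted per electrode and band in [200, 650] ms.
3. **Connectivity** — inter-site phase clustering per band and electrode
   pair: ISPC = |⟨e^{i(φx−φy)}⟩| over the trial window and trials, from
   zero-phase band-pass + Hilbert phases (1 = phase-locked, ≈0 =
   unrelated).
4. **Group statistics** — the 1088-variable table (128 power + 960
   connectivity), two-sided Wilcoxon rank-sum screening, step-up FDR
   adjustment (adjusted p(r) = min(prev, p(r)·n/r)), and point-wise
   permutation maps with extreme-point (min/max) family-wise correction.
5. **Classification** — nested stratified 4×3-fold rank-sum variable
   selection repeated 25 times, a linear SVM (C = 1) on the top variable
   with leave-one-out cross-validation, and kernel-density views of the
   selected biomarker.

Because clinical recordings of this kind are rarely shareable, the
package ships a **synthetic cohort generator** that emulates the
ALS-vs-control contrast with known ground truth: 1/f background, ongoing
band oscillations with von Mises phase coupling (expected ISPC =
I₁(κ)/I₀(κ)), per-band evoked Gabor atoms, and artifact trials. The
ALS-like group gets reduced Beta evoked power, delayed Delta/Alpha
latency, and reduced Alpha PO7↔central coupling. See
[docs/methods.md](docs/methods.md) for the full model.

## Worked example

The `analysis/` scripts run the whole study on a synthetic cohort at the
study scale (16 controls vs 12 ALS-like subjects, 264 target trials
each). Binary intermediates go to `scratch/`, tables to `results/`:

```bash
python analysis/01_simulate_cohort.py   # EDF + JSON sidecars
python analysis/02_preprocess.py
python analysis/03_tf_power.py
python analysis/04_connectivity.py
python analysis/05_group_stats.py
python analysis/06_classify.py --plot
```

Output of a run with the default seed (2021):

```
kept 7022/7392 trials (5.0% rejected)            # = the 5% artifact rate
          peak_power_pct  latency_ms             # CZ, Beta band
als-like           680.4       447.3
control           1493.8       457.0
alpha PO7<->CZ ISPC by group:
als-like    0.460                                # κ=1 → I1/I0 ≈ 0.446
control     0.839                                # κ=4 → I1/I0 ≈ 0.864
variable table: 1088 variables (128 power + 960 connectivity)
rank-sum significant (raw p<0.05): 232; min FDR-adjusted p: 0.0001109
CZ point-wise permutation: 13621 pixels, 5002 pixel-wise significant,
                           244 extreme-point significant (1000 permutations)
selected variable: pow_FZ_delta_power (300/300 folds, stable)
LOOCV: sensitivity 92%, specificity 100%, accuracy 96%
```

Reading the numbers: the rejection rate matches the injected artifact
rate; the ALS-like group's Beta peak power is roughly halved (the
injected power factor is 0.5) and its Alpha PO7↔CZ coupling drops from
≈0.86 to ≈0.45, both matching the generator's ground truth; screening
flags the injected variable families; and the leave-one-out SVM separates
the groups almost perfectly at these effect sizes. (With the default
latency shift enabled, a delta-power variable can outrank the Beta one in
selection — a documented interaction between the shifted Delta response
and the epoch edge; see the methods note.)

The same pipeline is scriptable from one config:

```bash
oddballeeg run-all --config pipeline.yaml --seed 7 --out my_run
oddballeeg simulate --out my_run          # or stage by stage
```

## Layout

```
src/oddballeeg/     preprocess, tfpower, connectivity, groupstats,
                    classify, synthgen, io, pipeline, cli
analysis/           numbered narrative drivers (see worked example)
tests/              unit + property + acceptance suites
docs/methods.md     models, parameters, design choices, limitations
```
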