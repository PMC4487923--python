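# Methods

## Scoring model

Vigilance staging rests on two physiological regularities: muscle tone
separates wakefulness from sleep (REMS is accompanied by near-complete
atonia), and within sleep the EEG spectrum separates NREMS
(delta-dominant, 0.5–5 Hz) from REMS (theta-dominant, 6–9 Hz). The
pipeline turns these into three per-epoch scalar features and a fixed
two-stage decision tree.

Per epoch of N = `epoch_length_s · fs` samples, the RMS
`sqrt((1/N) Σ xᵢ²)` is computed for the EMG and for the EEG filtered
into five bands (δ 0.5–5, θ 6–9, α 10–15, μ 16–22.75, β 23–31.75 Hz).
The ratio features are

    DELTA = δ_RMS / (α_RMS · μ_RMS · β_RMS)
    THETA = θ_RMS² / (δ_RMS · α_RMS)

DELTA rises when delta power dominates the desynchronized bands
(NREMS); THETA rises when theta dominates both delta and alpha (REMS).
Under a global EEG gain k, every band RMS scales by k, so DELTA scales
by 1/k² while THETA is gain-invariant (degree 2 over degree 2) — a
deliberate robustness to electrode impedance differences, guarded by a
regression test. The muscle feature is exp(EMG_RMS), displayed on the
exponential scale to stretch the wake/sleep gap.

Decision tree, with strict inequalities throughout: an epoch with
exp(EMG_RMS) strictly above the EMG threshold is WAKE; otherwise DELTA
strictly below its threshold **and** THETA strictly above its
threshold is REMS; everything else is NREMS. Equality at a cursor
falls to the default branch (non-WAKE, non-REMS). There is no temporal
smoothing or minimum-bout rule — the tree is purely per-epoch; context
is handled by the manual rescoring pass. Quiet wakefulness (low muscle
tone while awake) is the known failure mode of Decision 1 and is left
to rescoring.

The method is deliberately semi-automatic: threshold placement is the
user's job. `oracle_thresholds` automates it only for synthetic data
with known ground truth, placing each cursor at the geometric mean of
the medians of the two state distributions it must separate.

## Parameters

| parameter | default | unit | rationale |
|---|---|---|---|
| `fs` | 250 | Hz | typical acquisition rate for rodent EEG/EMG |
| `filter_order` | 3 | — | Butterworth design order |
| broadband | 0.5–31.75 | Hz | display band; contains all five scoring bands |
| `epoch_length_s` | 4 | s | conventional scoring epoch for mice; configurable |
| EMG threshold | user | exp(RMS) scale | Decision 1 cursor |
| DELTA, THETA thresholds | user | feature units | Decision 2 cursors |

## Numerical choices

* **Zero-phase filtering.** Bands are filtered with forward–backward
  (`sosfiltfilt`) application of the design-order-3 Butterworth
  band-pass. This doubles the effective magnitude order but removes
  group delay, so the five band series and the EMG stay time-aligned
  within each epoch. Band filters are applied to the raw
  (artifact-masked) EEG rather than to the broadband-filtered EEG; all
  five bands lie inside the broadband, so the choice is near-neutral.
* **NaN propagation.** Filtering restarts on each contiguous finite
  run, so artifacts never smear into clean data; a run shorter than
  the filter's padding length is filtered with reduced padding. Any
  NaN sample inside an epoch makes every feature of that epoch NaN and
  the epoch ARTIFACT. A sample masked in either channel artifacts the
  epoch of both channels (conservative union).
* **Strictness at cursors.** "Above"/"below" are strict; ties go to
  the default branch. Sample amplitudes exactly at a spike cursor are
  not artifacts.
* **Degenerate epochs.** An exactly-zero EEG band RMS would zero a
  ratio numerator or denominator; such epochs are flagged ARTIFACT
  with a warning instead of raising on division. Zero EMG RMS is
  harmless (exp(0) = 1).
* **exp overflow.** The WAKE comparison runs in log space
  (EMG_RMS vs ln(threshold)), identical by monotonicity and immune to
  overflow of exp(EMG_RMS) for large-amplitude EMG.
* **Segment intervals** are half-open `[start, end)` in seconds with
  0-based sample indexing; the left edge floors and the right edge
  ceils to samples, so any overlapped sample is masked.
* **State codes** in exported matrices: WAKE=1, NREMS=2, REMS=3,
  ARTIFACT=0. ARTIFACT rows are retained so epoch indices remain
  aligned with recording time.
* **Transition indexing.** A transition query reports the first epoch
  of the *new* state. With `skip_artifacts`, ARTIFACT epochs are
  transparent (the transition is detected between nearest non-artifact
  neighbours); otherwise they break transitions.
* **Kappa CI.** The 95% interval uses the large-sample standard error
  of Fleiss, Cohen & Everitt; a percentile bootstrap over epochs is
  available as a cross-check. If both scorers are constant on the same
  label (expected agreement 1), chance correction is undefined and
  perfect agreement is reported as κ = 1 with a warning.
* **EMG input.** The scoring step accepts either the raw EMG (assumed
  already hardware band-passed to 40–90 Hz) or a pre-computed
  per-epoch RMS vector (`emg_is_epoch_rms`); a software 40–90 Hz
  filter (`filter_emg`) covers recordings made without the hardware
  filter.

## Synthetic-data generator

The generator produces what the decision tree assumes, with known
ground truth:

* **Hypnogram.** A semi-Markov chain over {WAKE, NREMS, REMS} with
  exponential dwell times (means 60 / 120 / 30 s), discretized to
  epochs (minimum one). Direct WAKE→REMS transitions are forbidden by
  default, the normal constraint in healthy rodents; switchable for
  pathology-like sequences.
* **EEG.** Per epoch, one sinusoid mixture per band (3 sinusoids at
  random frequencies in the band's central 80%, random phases) scaled
  to a per-state target RMS, plus white noise (RMS 3). Default
  weights, ordered (δ, θ, α, μ, β): WAKE (10, 12, 8, 6, 6), NREMS
  (40, 8, 6, 4, 3), REMS (6, 30, 5, 3, 2) — delta-dominant NREMS,
  theta-dominant REMS, mixed moderate WAKE.
* **EMG.** 40–90 Hz band-limited Gaussian noise scaled to per-state
  RMS 3.0 (WAKE), 1.0 (NREMS), 0.3 (REMS) — the atonia ordering.
* **Artifacts.** Single-sample spikes of amplitude 500 (alternating
  sign, far above the clean signal range) at a Poisson rate per
  minute; injected sample indices are returned and recorded in the
  JSON sidecar, so tests can verify that masking recovers exactly the
  injected set.

All randomness flows through one seeded generator; a recording is
bit-reproducible from its seed.

**Fidelity limits.** Sinusoid mixtures give exact band-power control
but are not electrophysiologically realistic: no 1/f background, no
spindles or K-complexes, no gradual state transitions, no circadian
structure, and the per-state spectra are far better separated than in
real animals. Passing the end-to-end tests therefore demonstrates that
the pipeline's machinery is correct — filters select their bands, the
ratios rank states, thresholds partition epochs, artifacts are
conserved — not that any particular agreement level will be reached on
real recordings, where scores are expectedly lower and threshold
placement is genuinely manual.

## Problem sizes

The test suite validates on recordings of 5–10 minutes (75–150 epochs)
and one Monte-Carlo hypnogram check pooling 50 one-hour runs; the
reproduction script (`scripts/acceptance.py`) uses a single one-hour
recording (900 four-second epochs, 900 000 samples per channel).
These sizes give stable medians and agreement statistics while keeping
a full run to seconds.

## Known limitations

* No automatic threshold selection for real data: the method is
  semi-automatic by design.
* No temporal context in the tree (no smoothing, no bout-length
  rules); isolated single-epoch state flips are possible and are the
  main target of the rescoring pass.
* Percent agreement and κ are computed for exactly two scorers;
  multi-rater and weighted variants are out of scope.
* The interactive review is terminal/edit-list based; there is no
  graphical waveform browser.
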