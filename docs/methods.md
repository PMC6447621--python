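# Methods

This package reimplements, end to end, an auditory statistical-learning
experiment built around the mismatch negativity (MMN): the stimulus paradigm,
the stimulus audio, a forward model producing synthetic EEG with the
experiment's expected event-related potentials, the classical preprocessing
chain, and the within-subject factorial statistics. Because no public
recordings exist for this paradigm, the synthetic-EEG module serves as the
testable stand-in for real data: every downstream claim the package makes is
a *recovery* claim — the analysis chain, run blind on simulated recordings,
reproduces the effects that were put in.

## The paradigm

Sounds are organised in triplets: a two-sound **root** (`AB` or `CD`, internal
transition probability 1) followed by an **ending** (`E` or `F`). Each root
has a designated high-probability continuation, P(ending | root) = 0.9, with
the alternative at 0.1; roots follow endings with constant probability 0.5,
so the stream is a first-order Markov (bigram) process over the four words
ABE/ABF/CDF/CDE. Independently, every sound is played from a *standard* or
*deviant* loudspeaker side: root sounds 95 %/5 %, endings 80 %/20 %. Crossing
transition probability with ending location yields four ending categories —
standard (0.72), statistical deviant (0.08), physical deviant (0.18), double
deviant (0.02).

Design choices in the generator:

* **Exact counts, not Bernoulli draws.** Category counts, the low-TP split
  across roots, and the 5 % root-side deviance are assigned by constrained
  shuffling, so the design proportions hold *exactly* in every 400-triplet
  block and are testable as equalities.
* **Separation.** Low-TP triplets are separated by at least three other
  triplets (index gap ≥ 4). Positions are drawn uniformly over all gap-valid
  configurations by the stars-and-bars bijection.
* **Word-boundary balance.** The root following each ending letter is chosen
  by a deficit-correcting urn, keeping the empirical ending→root transition
  probability at 0.5 within integer rounding rather than merely in
  expectation; bounded rejection-resampling (10 000 attempts) guards the rare
  supply dead ends.
* **Cover-task targets.** How many targets occur and where is an open
  parameter of the original procedure; the default is 10 per block, inserted
  at triplet boundaries never closer than three triplets to a low-TP triplet
  so that the 3-s post-target epoch exclusion cannot eat deviant trials.
  Targets occupy a 300 ms slot of the pause-free stream.
* **Seed policy.** One master seed; per-participant and per-purpose child
  seeds derive from `SeedSequence([master, participant, purpose, block])`, so
  any block is regenerable in isolation.

Timing: 300 ms inter-onset interval, 220 ms sounds, hence 80 ms interstimulus
silence. A 400-triplet block is exactly 6 min of sound; with the default 10
targets, 6 min 3 s. The "about 7 minutes" of a live session presumably
includes lead-in/lead-out; block duration here is emergent, not enforced.

## Stimuli

Each of the six sounds is a **Shepard tone** — nine sinusoidal partials one
octave apart — mixed with a percussive transient. The octave placement and
spectral envelope are classic open parameters of Shepard's construction: this
implementation centres the partials at octave offsets −4..+4 around the
nominal pitch class (all sub-Nyquist at 44.1 kHz) under a Gaussian envelope
over log2-frequency (σ = 1.5 octaves, maximum at the nominal pitch), which
keeps the nominal frequency the spectral maximum while flattening pitch
height. Pitch classes: main set F3 174.61 … D#4 311.13 Hz, practice set E3
164.81 … D4 293.66 Hz, cover-task target C#5 554.37 Hz (no percussion).

The percussive components are **synthetic transients** — exponentially
decaying band-passed noise with per-instrument band centre and decay
constants (surdo 90 Hz/150 ms … hi-hat 8 kHz/60 ms) — deterministic per
(kind, seed) and overridable by user-supplied WAV-derived waveforms. They
emulate the orchestral samples' role (distinct broadband timbre per sound)
without reproducing any particular recording.

Components are mixed at equal RMS (ratio 0.5), faded (10 ms linear in, 20 ms
linear out), and then RMS-normalized to a common bank reference. Normalizing
*after* the fade is deliberate: it is the only order under which all bank
sounds share the same RMS exactly (the fade preserves shape up to scale, so
the linear 10-ms rise is unaffected). Rendering places each sound at its
onset sample on the left or right channel only (hard routing standing in for
the two loudspeakers at 60°; no HRTF), sums overlapping tails, and emits a
sample-accurate marker per event.

## Synthetic EEG

The forward model is linear: 63 channels (59-channel 10-10 cap + M1/M2
mastoids + HEOG/VEOG) at 500 Hz; each sound event adds, per firing component,
a Gaussian temporal kernel times a squared-exponential spatial topography
(`exp(-(falloff · d)²)` over normalized 2-D electrode distance). Defaults:

| component | latency | σ | peak | centre | fires on |
|---|---|---|---|---|---|
| P1  | 140 ms | 25 ms | +2.0 µV | Cz  | every sound |
| N1  | 200 ms | 30 ms | −2.0 µV | Cz  | every sound |
| sMMN | 210 ms | 30 ms | −1.50 µV | Fz | low-TP endings |
| phMMN | 180 ms | 28 ms | −3.65 µV | FCz | deviant-location endings |
| P3b | 330 ms | 45 ms | +3.0 µV | Pz | deviant-location endings |

The sMMN/phMMN latencies and amplitudes are the study's reported values; P1,
N1 and P3b are looser morphological stand-ins (the P3b in particular is only
qualitatively constrained) and are excluded from recovery targets.

* **Interaction.** When an ending is both a statistical and a physical
  deviant, the sMMN contribution is multiplied by a suppression factor
  s = 0.2. The value is a configuration choice, not a reported quantity; it
  is set so that, at the default cohort size, the simple effect of
  probability under location deviance is statistically undetectable while
  the factorial interaction term is detectable — the observed pattern.
* **Block dynamics.** Grouped-block scalings modulate sMMN ×(0.85, 1.25,
  0.90) (present from the first grouped block, larger in the second, smaller
  in the third) and phMMN ×(1.15, 1.00, 0.85) (diminishing). They are
  **mean-one** by construction: the reported peak amplitudes are
  across-block grand averages, so any modulation with a different mean would
  bias the recovered peaks away from the nominal values.
* **Referencing convention.** Component topographies are defined as zero at
  the mastoids and EOG: the injected amplitudes are the values observed
  *after* mastoid re-referencing, which is the scale on which the study
  reports them. Mastoids carry noise only.
* **Noise.** Per-channel white noise (SD 8 µV), 1/f noise (SD 6 µV, α = 1),
  slow sinusoidal drifts (10 µV, 0.01–0.08 Hz), and ocular blinks (12/min,
  ~100 µV raised-cosine pulses on VEOG with a prefrontal scalp projection).
  Amplitudes are set so single-trial SNR is strongly negative while the
  paradigm's trial counts still yield clear grand averages, and so that
  blinks — the one artifact class the simulator produces — reliably exceed
  the 25 µV gliding-SD threshold and are caught by rejection rather than
  ICA. A per-subject multiplicative ERP gain ~N(1, 0.1) adds mean-one
  between-subject variability.

What the simulator does **not** emulate: volume conduction/leadfields,
muscle or electrode artifacts beyond broadband noise, latency jitter between
trials or subjects, habituation within blocks, or reaction times. Passing
recovery tests therefore demonstrates that the analysis chain is unbiased
and correctly calibrated under the stated noise model — not that it would
be robust to every pathology of real recordings.

## Preprocessing

Re-reference to mean(M1, M2) (EOG untouched) → 30 Hz low-pass FIR → artifact
mask → epoch → baseline. Numerical choices:

* **Filters.** Windowed-sinc Blackman FIRs with the stated tap counts made
  odd (2751 at 30 Hz; 551 at 0.5 Hz) for exact linear phase; application is
  zero-phase by group-delay compensation of the symmetric kernel with
  reflection padding. The 0.5 Hz high-pass is designed by spectral inversion
  of the complementary low-pass so its DC gain is exactly zero even though
  551 taps at 500 Hz cannot realize a sharp 0.5 Hz transition.
* **Rejection.** A sample is rejected iff any channel's SD (population
  definition) within *any* 200 ms or 800 ms gliding window (stride 1)
  containing it strictly exceeds 25 µV; the mask is the union over window
  lengths. Strict inequality at the boundary. Masks are computed after
  re-referencing and filtering.
* **Epochs.** Endings: −100..400 ms (251 samples at 500 Hz, boundaries
  inclusive, 0 ms = onset sample), baseline-corrected on −100..0 ms. An
  epoch is dropped if *any* of its samples is masked (conservative join), if
  its onset falls within 3 s after a cover-task target, or if it overruns a
  recording edge; every marker is accounted for in a kept/dropped ledger.
  Root epochs: −100..1000 ms anchored at the *preceding* triplet's ending
  onset, restricted to roots following standard triplets, high-pass filtered
  (on the continuous recording, where the 551-tap kernel is well-defined)
  instead of baseline-corrected.

## Statistics

Nine regions of interest form a 3 × 3 scalp-area × lateralisation grid; each
cell is the unweighted mean of its electrodes. Window means (inclusive
boundaries) per subject × condition × ROI × grouped block feed a
fully-crossed repeated-measures ANOVA implemented by orthonormal contrasts:
for each effect, the Kronecker product of per-factor Helmert-type bases
(mean vectors for averaged-out factors) yields subject-level contrast
scores; the effect is tested against its own subject-by-effect stratum, and
Greenhouse–Geisser ε is estimated from the contrast-score covariance. Both
uncorrected and corrected p are reported; the headline analyses read the
uncorrected values. The implementation is cross-checked in the test suite
against statsmodels' `AnovaRM` to 1e-8 relative in F, and its null
rejection rate is Monte-Carlo-calibrated to 5 % ± 1.5 %.

Supporting tests: paired t per grouped block (raw p, optional Holm),
orthogonal-polynomial linear trend over scalp area, and a one-sample t of
familiarity-test percent-correct against chance 0.5 (described as
"independent sample" in the source literature, which is incoherent for one
group against a constant; one-sample is the faithful reading).

Peak measures take the signed extremum of the requested polarity in an
inclusive window, ties broken toward earlier latency. The **sMMN** is the
grand-average (low − high TP, standard location) difference at Fz, peak
sought in 180–260 ms; the **phMMN** is the (deviant − standard location)
difference *at high TP* at FCz, peak in 150–220 ms. Matching the location
contrast at high probability is a deliberate definition: it isolates the
location response exactly (low-TP trials carry the suppressed statistical
response, which would contaminate the difference) and uses nine times as
many trials.

## Problem sizes and determinism

The default study is 21 subjects × 6 blocks × 400 triplets at the full
63-channel montage — the cohort and session size of the emulated experiment —
and runs in minutes on one core; `run_study` is deterministic in its master
seed end to end (design permutations, streams, noise, blinks). The test
suite exercises short 100-triplet blocks for unit-level checks and the full
default study once for recovery checks. `scripts/acceptance.py` recomputes
the design probabilities, the Shepard spectral maximum, and the three
recovery measures from scratch at the default configuration.

## Known limitations

* Recovery tolerances are dominated by peak-picking bias: the extremum of a
  noisy grand average is biased away from zero by roughly one noise SD of
  the smoothed difference wave (~0.1–0.2 µV at the default cohort).
* The ANOVA requires balanced complete designs; cells emptied by extreme
  artifact rates would abort rather than degrade gracefully.
* ICA is not implemented; the threshold mask handles the synthetic blinks,
  which is sufficient here precisely because the simulator produces no
  other structured artifacts.
* Audio and EEG are simulated on separate clocks (44.1 kHz vs 500 Hz); the
  package does not model presentation-hardware latency or jitter between
  them.
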