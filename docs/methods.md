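# Methods

This note documents the models, parameter choices and numerical conventions
of `roving_aep`, including the choices made where the underlying procedure
leaves the design open, and what the packaged simulations can and cannot
show about real recordings.

## Stimuli and paradigm

Tones are 100 %-depth sinusoidally amplitude-modulated carriers,
`y(t) = (1 + d·sin 2π f_m t)·sin 2π f_c t`, rendered at 48 kHz for 450 ms
with 10-ms onset/offset ramps.  The ramp is a raised-cosine (Hann
half-window) taper — the shape is our choice; only the rise/fall time is
prescribed — so the end samples are exactly zero and the taper is monotone.
The product of sines places half-amplitude sidebands at `f_c ± f_m`; the
power ratio sideband:carrier is therefore 1:4, which the stimulus tests
assert via the closed-form expansion.  Exported WAVs are peak-normalized to
0.9 full scale (delivery level is set at the amplifier, so absolute scale
carries no information); fixed polarity throughout.

Sequences alternate tone trains strictly; pseudorandomness enters only
through train lengths, drawn by rejection sampling uniformly over the
compositions of each tone's trial total into parts from {4, 5, 6} (a
bounded repair pass handles pathological configurations; the default block
accepts within a few hundred draws).  With 75 trials per tone a block is
forced to 16 + 15 = 31 trains, hence 30 transitions, 15 per direction
regardless of the start tone.  The block's very first trial belongs to no
condition: it neither continues a train (nondeviant) nor violates one
(deviant), so it is flagged `unlabeled_first` and excluded everywhere.
Standards are also nondeviants (they occupy a non-first train position);
they are included in nondeviant averages.  The scheduled timeline includes
a 2-s lead-in before block 1 so the first trial carries a full prestimulus
baseline, mirroring any real acquisition; stimulation onsets use a fixed
1.000-s asynchrony with no jitter.

## Synthetic EEG

The generator is a linear superposition designed so that every downstream
stage has computable ground truth:

* background: per-channel 1/f^α Gaussian noise (frequency-domain shaping,
  DC removed), default α = 1 and 10 μV RMS — the scalp-EEG regime where a
  microvolt-scale evoked response is invisible on single trials;
* per trial, under the stimulus ramp: a carrier sinusoid (FFR term,
  default 50 nV — nanovolt scale, as at the human scalp), an upper-sideband
  cosine at `f_c + f_m` (half that), and a modulation-rate sinusoid (ASSR,
  default 0.8/0.4 μV for 40/80 Hz);
* per trial, Gaussian-windowed ERP kernels with fixed latency/width/polarity
  (P1 +50 ms, N1 −110 ms, P2 +200 ms, sustained negativity −370 ± 85 ms,
  offset negativity −720 ms); deviants add direction-specific terms —
  ascending transitions scale the N1/P2 kernels up by `ascending_gain`,
  descending transitions add MMN (−144 ms, within the 124–164-ms analysis
  window) and P3a (+240 ms) kernels;
* a 1-Hz sinusoid phase-locked to the onset asynchrony during each
  stimulation period;
* optional Poisson-timed 200–400-μV transients to exercise the ±150-μV
  rejection.

Latencies sit inside the windows where the corresponding real components
are reported; kernel *shapes* are a modelling choice (the physiology
prescribes latency ranges, not waveforms).  Everything is linear in the
configured amplitudes and deterministic per seed (verified by tests), so
noise-free epoch averages equal the kernel sum exactly.

What the generator does **not** emulate: dipolar topography (both channels
receive the same evoked signal up to a scalar gain), ocular/muscular
artifact morphology, non-stationary arousal drift, adaptation of response
amplitude across trials, and any nonlinearity of real neural entrainment.
Passing pipeline tests on this generator therefore demonstrate the
*statistical machinery* (filters, spectra, permutation calibration,
decoding) under realistic SNR — not physiological validity of the
components themselves.

## Preprocessing

All filters are Butterworth applied forward-backward (zero-phase), because
cluster onsets/offsets in milliseconds would otherwise be biased by filter
delay.  The three paths:

* gamma/FFR: 2–1500-Hz band-pass (4th order; the upper edge is clipped to
  0.45 × the sampling rate so the pipeline is rate-agnostic) plus 2-Hz-wide
  notches at 60 Hz and harmonics; epochs −100–450 ms, baseline −100–0 ms,
  rejection at ±150 μV on these broadband epochs *before* narrow-band
  component filtering; nondeviant trials only, averaged per tone; the
  average is then band-passed per component (0.5–2.5, 25–55, 65–95 Hz 2nd
  order; 200–280, 420–540 Hz 4th order) and its 0–450-ms window goes to a
  zero-padded DFT with 0.25-Hz bin spacing.
* 1-Hz: down-sample to 100 Hz, 0.1–20-Hz band-pass, nonoverlapping 15-s
  segments per block (ten per default block → 200 per session) and two per
  rest interval (from its first 30 s), baseline −100–0 ms, average, 0.5–2.5-Hz
  filter, DFT at 0.0125-Hz spacing.
* ERP: down-sample to 250 Hz, 2–20-Hz band-pass (2nd order), epochs
  −100–900 ms, baseline, rejection; classification features are the
  half-open 0–900-ms window (225 points at 250 Hz).

Resting-state (RS) pseudo-trials: the rest intervals carry no events, so
1-s windows are laid out evenly (generally overlapping) within each rest
interval, as many per block as the per-tone nondeviant trial count — this
matches RS and stimulus trial numbers per block, which is the only way the
reported RS trial counts can exceed the number of non-overlapping 1-s rest
segments.  This is an assumption and is isolated in `rs_pseudo_onsets`.

Spectra are normalized to unit total power within the analyzed band (the
component's filter passband — our reading of "analyzed band"); the
individual-level input is the *increment* `max(stim − rest, 0)`,
renormalized.  An increment that is zero everywhere is degenerate and is
reported as "not detected" rather than an error in the pipeline.

## Statistics

* Group cluster tests delegate to MNE-Python's one-sample sign-flip
  cluster permutation with TFCE (`start 0, step 0.1, E 0.5, H 2` — field
  defaults; the procedure names TFCE without parameters), one-tailed for
  spectral power increases, two-tailed for signed ERP contrasts; the two
  sensors are adjacent, the frequency/time axis a chain.  Reported cluster
  onsets/offsets use the Fz∧Cz conjunction.  Tests verify the p-values
  against an independent brute-force TFCE plus exhaustive 2^6 sign-flip
  enumeration on toy grids (agreement within two enumeration steps, which
  covers TFCE threshold-discretization edge effects).
* The individual sustained test shuffles *bin values* of the analyzed
  spectrum (2000 permutations, seeded), statistic = bin − mean(others),
  p = fraction of permuted statistics ≥ observed (no +1 correction), and
  declares a component present on ≥ 3 consecutive p < 0.05 bins within any
  target window (±2 Hz, or ±0.1 Hz for the 1/2-Hz windows) at Fz.  The
  exchangeable unit (bins) is the natural reading of the printed method;
  see *Calibration limitation* below.
* SVM decoding uses scikit-learn `SVC(kernel="linear", C=1.0)`.  The fold
  partition is stratified on class — and additionally on electrode when
  each (class, electrode) cell is large enough — and held fixed across the
  permutation null, which lets the per-fold standardization and linear
  Gram matrices be computed once (features do not change under label
  permutation).  The observed accuracy always comes from the canonical
  `SVC` code path; the 2000-fit null loop uses scikit-learn's low-level
  libsvm bindings (the same solver without per-call validation overhead),
  and only after those bindings have reproduced the `SVC` fold predictions
  exactly on the observed labels at run time — any mismatch falls back to
  `SVC` throughout.  Single-class training folds (possible under extreme
  permutations at small fold counts) predict the constant class.
* Duration curves accumulate blocks in recording order; the fold count
  equals the number of blocks analyzed (two-fold at a single block).
  Stability is the smallest k with sensitivity ≥ 0.90 for *every* k′ ≥ k.

## Calibration limitation of the individual sustained test

The packaged null-calibration battery (20 zero-amplitude simulated
subjects) shows the transient decoding test is well calibrated (1/20
significant), and a unit test confirms the sustained rule keeps its false
positive rate ≤ 0.10 on spectra with exchangeable (white) bins.  On
*pipeline* spectra, however, the same battery measures per-component false
detection rates of roughly 0.20–0.30.  The cause is structural: a PSD
computed from a 0.45-s window and zero-padded to a 0.25-Hz grid is an
interpolation whose bins are correlated over ~2.2 Hz (~9 bins), so "three
consecutive significant bins" is satisfied by any single noise excursion,
and bin shuffling destroys exactly this correlation when building the
null.  Detection then reduces to "the spectrum's largest noise blob
overlaps a ±2-Hz target window", with probability ≈ the window's share of
the analyzed band (components with two windows, the FFRs, show the highest
rates).  An epoch-level permutation would preserve the correlation and
calibrate the test, but departs from the printed bin-wise procedure and
requires re-averaging per permutation; we keep the printed method and
document the inflation instead.  Practically this means individual-level
sustained detections at realistic SNR are trustworthy for strong responses
(the high-SNR battery detects 8/8 with margins far beyond the null) but
single marginal detections should not be over-read.

## Problem sizes in the packaged tests

The multi-subject batteries run at sizes chosen for a single CPU: 20
blocks × 30 trials, 5-kHz simulation rate, seeds 1–8 (recovery) and
101–120 (null), with 500-permutation SVM nulls inside the test suite (the
package default is 2000 everywhere else; permutation count affects only
the Monte-Carlo resolution of the null quantiles, not its location).  The
null battery evaluates the transient comparison on the first 10 blocks
(10-fold CV) — type-I behaviour does not depend on the fold count.  The
directional-asymmetry battery uses one full-size subject (20 × 150
trials).  Sustained detection always uses the full 2000 bin permutations.

## Known limitations

* Two simulated channels share one evoked source; spatial TFCE adjacency
  is exercised, but no topographic inference is possible (matching the
  two-electrode montage itself).
* The EDF writer emits plain 16-bit EDF with per-channel physical scaling
  derived from the data extrema; amplitude resolution therefore depends on
  the largest artifact in the record.
* The individual sustained test's calibration issue above; group-level
  TFCE tests are unaffected.
* `stability_block` is undefined (None) when the level is never reached
  and held; callers must handle that case.
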