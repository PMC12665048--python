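# roving-aep

Simultaneous assessment of subcortical and cortical auditory-evoked EEG
responses with a **frequency-tagged roving paradigm** — stimulus and
sequence generation, a synthetic-EEG generator, and the full multi-level
detection pipeline (spectral and decoding-based), for methods researchers
and clinical electrophysiologists who want to study or extend
single-session, two-electrode (Fz, Cz) auditory assessment.

## The problem

Different auditory responses have conflicting recording requirements.
Sustained, frequency-tagged responses — the frequency-following response
(FFR) phase-locked to a tone's carrier and the auditory steady-state
response (ASSR) entrained to its modulation rate — are nanovolt-to-microvolt
signals that need thousands of averaged trials, while transient cortical
ERPs (P1–N1–P2, mismatch negativity, P3a) need slow stimulus rates and
hundreds of trials.  The paradigm implemented here elicits all of them at
once: two amplitude-modulated tones,

```
y(t) = (1 + sin 2π f_m t) · sin 2π f_c t,      (f_c, f_m) ∈ {(220, 40), (440, 80)} Hz
```

450 ms long with 10-ms ramps, are presented at a fixed 1-s onset asynchrony
in a *roving* sequence: the same tone repeats 4–6 times (a train), then
switches.  The first tone of each new train is a **deviant**, the last tone
of the preceding train its **standard**, and within-train repeats are
**nondeviants**.  A default session is 20 blocks × 150 trials (75 per tone,
31 trains, 15 ascending + 15 descending transitions per block) separated by
35-s rests — every printed count is enforced and tested.

Each AM tone tags the EEG at known frequencies — carrier (220/440 Hz),
upper sideband (260/520 Hz), modulation rate (40/80 Hz) and the 1-Hz
presentation rate — so sustained responses are read off zero-padded DFT
power spectra, while the roving structure yields deviant/standard contrasts
for transient change-detection responses.

## Detection machinery

* **Group level** — paired spatiospectral/spatiotemporal cluster
  permutation across subjects with threshold-free cluster enhancement
  (TFCE, via MNE-Python) on the sensor × frequency or sensor × time grid;
  cluster onset/offset reported where Fz **and** Cz are significant.
* **Individual sustained** — per-subject normalized PSD increment
  (positive part of stimulus − rest, renormalized), then a frequency-wise
  permutation test: each bin against the mean of all other bins, null by
  bin shuffling, 2000 permutations; a component counts as detected when ≥ 3
  consecutive bins with p < 0.05 fall inside the fundamental *or*
  harmonic/sideband window (e.g. 220 Hz or 260 Hz, ±2 Hz) at Fz.
* **Individual transient** — block-wise averaged ERPs (20 blocks × 2
  electrodes = 40 samples per condition, 0–900 ms at 250 Hz), linear SVM
  (C = 1.0) under stratified 20-fold cross-validation with training-set-only
  standardization; significant when the true accuracy exceeds the 95th
  percentile of a 2000-permutation label-shuffled null.
* **Recording duration** — detection repeated on cumulatively growing data
  (1…20 blocks, 3 min each); a component is *stable* at the smallest block
  count where sensitivity reaches and maintains ≥ 0.90.

A seeded synthetic-EEG generator provides ground truth: phase-locked
FFR/sideband/ASSR terms plus Gaussian-windowed ERP kernels (with MMN/P3a
only on descending deviants and N1/P2 enhancement only on ascending ones)
in 1/f background noise, with optional ±150-μV artifact transients.

## Worked example

```python
from roving_aep.paradigm import build_paradigm, ParadigmConfig
from roving_aep.simulate import SimConfig, simulate_subject
from roving_aep.pipeline import prepare_sustained, detect_sustained

schedule = build_paradigm(
    rng_seed=1, config=ParadigmConfig(n_blocks=4, trials_per_block=30)
)
print(f"{schedule.n_trials} trials, {len(schedule.blocks)} blocks, "
      f"{schedule.total_duration_s:.0f} s")

sim = SimConfig(
    sample_rate_hz=2500.0, rng_seed=1, noise_scale_uv=5.0,
    component_amplitudes={
        "FFR_220": 0.0, "FFR_440": 0.0, "SIDEBAND_260": 0.0, "SIDEBAND_520": 0.0,
        "ASSR_40": 1.0, "ASSR_80": 0.0,
    },
)
recording = simulate_subject(schedule, sim)
data = prepare_sustained(recording, schedule)
for name, det in detect_sustained(
    data, rng_seed=1, components=["assr_40hz", "assr_80hz"]
).items():
    print(f"{name}: detected={det.detected}  longest significant run={det.run_length} bins")
```

prints

```
120 trials, 4 blocks, 262 s
assr_40hz: detected=True  longest significant run=6 bins
assr_80hz: detected=False  longest significant run=1 bins
```

A 1-μV 40-Hz ASSR embedded in 5-μV noise is detected from 12 minutes of
simulated recording (six consecutive 0.25-Hz bins around 40 Hz beat the
permutation null), while the absent 80-Hz ASSR is correctly rejected.

The same stages are scriptable from the shell:

```bash
roving-aep gen-paradigm --seed 7 --out run/        # events.tsv (3000 rows)
roving-aep simulate --config run/config.yaml --out run/
roving-aep analyze-sustained --edf run/subject.edf --events run/events.tsv --out run/
roving-aep duration-curves --edf run/subject.edf --events run/events.tsv --out run/
```

EEG travels as 16-bit EDF plus a tab-separated events sidecar; stimuli as
WAV; results as JSON/TSV with the run-config hash embedded.

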