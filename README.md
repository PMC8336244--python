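# nddsleep

Quantitative overnight sleep-EEG biomarkers for neurodevelopmental-disorder
cohorts, built around the three measures that separate children with Dup15q
syndrome (maternal 15q11.2-13.1 duplications) from neurotypical controls on
routine clinical EEG:

1. **Beta band power** — mean spectral power at 12–30 Hz across the night,
   per frontal/central/occipital electrode group (elevated in Dup15q,
   resembling benzodiazepine-induced beta);
2. **Sleep-spindle density** — spindles per minute of artifact-free sleep,
   from a sigma-band (11–16 Hz) relative-power detector (reduced in
   Dup15q);
3. **Percent slow-wave sleep** — by an automated delta-power (1–4 Hz)
   threshold over 30-s epochs, and by an AASM-style N3 scorer
   (0.5–2 Hz waves ≥ 75 µV occupying ≥ 20% of an epoch); reduced or absent
   in Dup15q.

The package is aimed at researchers who have overnight clinical EEG in EDF
(10–20 montage, ~200 Hz) rather than formal polysomnography: it extracts
the 22:00–05:00 window, cleans the data (1–50 Hz zero-phase FIR, four
bad-channel criteria with interpolation, common-average reference, 60 Hz
removal, windowed-RMS burst suppression), computes the three biomarkers per
subject, and compares groups with pooled-variance Student's *t* tests.

Because clinical recordings cannot be redistributed, the package includes a
**synthetic polysomnography generator** (`nddsleep.synthetic`): seeded
multi-channel overnight EEG with a hypnogram and an exact ground-truth
sidecar (every spindle, N3 epoch and artifact), including a "Dup15q-like"
phenotype (elevated beta, few spindles, absent SWS). Every pipeline stage
is validated against this ground truth; see `docs/methods.md` for what the
generator does and does not emulate.

## The measurements

With `P(f)` the one-sided PSD of a 60-s Hann segment (30-s hop), band
power is the mean of `P(f)` over band bins (µV²/Hz). The spindle detector
thresholds the windowed sigma fraction

    relpow(t) = Σ P(f), 11 ≤ f ≤ 16  /  Σ P(f), 1 ≤ f ≤ 30   (2-s windows)

at 0.20, merges candidates < 500 ms apart, discards events outside
0.5–2.0 s, and consolidates cross-channel detections starting < 300 ms
apart. The automated SWS rule takes the lowest-delta half of all 30-s
epochs as baseline, calls an epoch "high-delta" when its delta power
exceeds baseline mean + 1 SD, and keeps only runs of ≥ 32 consecutive
high-delta epochs (16 min); percent SWS is their share of the 7-h night.

## Worked example

```python
import nddsleep as nd
from nddsleep.montage import DEFAULT_MONTAGE_19

params = nd.PipelineParams()
profile = nd.nt_profile()                      # neurotypical-like phenotype
hyp = nd.generate_hypnogram(3600.0, profile, seed=2)
rec, truth = nd.generate_recording(hyp, DEFAULT_MONTAGE_19, profile,
                                   fs=200.0, seed=3)
row = nd.analyze_subject(rec, hyp, params, subject_id="NT-demo", group="NT")

print("beta power (uV^2/Hz): " +
      ", ".join(f"{g}={v:.2f}" for g, v in row.beta_power.items()))
print(f"spindle density: {row.spindle_density:.2f} events/min "
      f"(generated N2 rate {profile.spindle_density_per_min}/min)")
print(f"percent SWS (delta threshold, frontal): "
      f"{row.percent_sws_auto['frontal']:.1f}% "
      f"(hypnogram N3 fraction {100 * hyp.fraction('N3'):.1f}%)")
print(f"percent SWS (AASM, of sleep time): {row.percent_sws_aasm:.1f}%")
```

prints:

```
beta power (uV^2/Hz): frontal=0.78, central=0.56, occipital=0.58
spindle density: 4.24 events/min (generated N2 rate 2.5/min)
percent SWS (delta threshold, frontal): 31.7% (hypnogram N3 fraction 30.8%)
percent SWS (AASM, of sleep time): 32.2%
```

The delta-threshold percent SWS recovers the hypnogram's N3 fraction to
within a single epoch's width. Detected spindle density exceeds the
generated per-minute rate because near-simultaneous detections on
different channels more than 300 ms apart legitimately count as separate
events (see `docs/methods.md`).

The same pipeline runs from the shell:

```bash
nddsleep simulate --out cohort/ --n-dup15q 15 --n-nt 12 --hours 1 --seed 0
nddsleep run --cohort cohort/manifest.csv --out results/
nddsleep extract --in raw.edf --out night.edf      # 22:00-05:00 crop
nddsleep preprocess --in night.edf --out clean.edf --mask mask.json
```

`results/subjects.csv` holds one biomarker row per subject and
`results/comparisons.csv` the group *t* tests with the conventional
significance stars (`*` p<0.05 … `****` p<0.0001).

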