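# Methods

This note documents the models, parameter choices and numerical decisions
behind `nddsleep`, and states what the synthetic-data validation does and
does not demonstrate about real recordings.

## Analysis window and preprocessing

Recordings are cropped to the fixed 22:00–05:00 clock window (7 h when
fully covered; shorter recordings are analyzed over the overlap, and the
effective duration propagates into the percent-SWS denominator). Window
bounds are taken as exact clock times; crops snap to whole samples (floor
on start and length) and are idempotent.

The cleaning chain runs in a fixed order: band-pass filter → bad-channel
detection → interpolation → common-average reference → line-noise removal
→ burst suppression.

**Filter.** A zero-phase FIR band-pass (1–50 Hz), implemented as a
symmetric Hamming-window kernel applied centred (exactly zero phase; an
impulse keeps its peak sample). The transition width is half the high-pass
edge, giving ≥ 50 dB attenuation at 0.5 Hz and 60 Hz and < 0.1 dB pass-band
ripple. Re-running the whole chain is *not* idempotent at the 1% level:
any realizable FIR re-attenuates its own transition bands, and on
delta-dominant sleep spectra the 0.5–1.5 Hz transition carries real power.
What is stable under a second pass is the pass band (2–45 Hz power changes
< 1%) and every post-filter stage (re-applied verbatim they are
near-identities); the test suite asserts exactly that decomposition.

**Bad channels.** Four criteria, computed for every channel and reported
with the flags: (1) log total 1–50 Hz power, robust z (median/MAD) across
channels, |z| > 3 — robust rather than mean/SD so a single extreme channel
cannot mask itself; the scale has a floor (5% of the median magnitude) so
near-tied channel sets cannot flag numerically irrelevant deviations;
(2) flat (near-zero) runs ≥ 5 s; (3) correlation with an
inverse-distance-weighted reconstruction from spatial neighbours below
0.7 — the correlation is the *median of per-4-s-window* Pearson r, so a
brief high-amplitude burst (the burst-suppression stage's job) cannot
condemn a whole channel; (4) line-band (60 ± 1 Hz) to own-broadband power
ratio, robust z > 4, with an absolute scale floor of 10⁻⁴ because after
the 50 Hz low-pass the ratio is numerically tiny for every channel.
Neighbours are channels within 1.0 head-radius unit (chord distance on
unit-sphere 10–20 coordinates): adjacent 10–20 electrodes sit at 0.6–0.8,
next-nearest at ≥ 1.2, so this radius selects exactly the immediate
neighbours. Detection runs once (no iterative re-detection); flagged
channels are replaced by the inverse-distance average of unflagged
neighbours. Inverse-distance averaging was chosen over spherical splines
for exact testability; the choice sits behind one function boundary.

**Line noise.** Per 4-s window, amplitude and phase of the 60 Hz tone
(and its first harmonic when below Nyquist) are fit by least squares and
subtracted — two degrees of freedom per window per harmonic, so broadband
power is untouched (≤ 5% change asserted on tone-free noise, ≥ 20 dB
narrowband attenuation on tones).

**Burst suppression.** A windowed-RMS contract stands in for artifact
subspace reconstruction, which the published pipeline used as a black box:
per channel, the calibration RMS is the median of the cleanest 50% of
half-overlapping 1-s windows; any window exceeding 20× (the published
σ = 20) its channel's calibration on any channel is masked; masked runs
are replaced by edge-continuous linear interpolation and reported as
merged intervals. Samples outside flagged windows pass through
bit-identical. Independent-component rejection (a trained classifier with
manual review in the original pipeline) is deliberately not implemented;
the synthetic generator's ocular/muscle artifacts are sized (~1000 µV
blinks, ~500 µV RMS muscle bursts) so that burst suppression alone
controls them — real artifacts are often smaller and would partially
survive, which is a stated limitation, not a hidden one.

## Spectral analysis

PSD per channel in 60-s Hann segments with a 30-s hop (one-sided, density
normalization; integrated white-noise PSD recovers the variance within
5%). Band power is the **mean PSD over band bins** (µV²/Hz) — "absolute"
power; the alternative reading (integrated power) differs only by a
constant bin-width factor and would not change any group contrast.
Per-subject scalars average channels within a group (frontal = Fp1, Fp2,
F3, F4, F7, F8, Fz; central = C3, C4, Cz; occipital = O1, O2 —
configurable), then epochs; epochs with > 50% artifact-masked samples are
excluded. All night-window epochs enter the average by default; a sleep
restriction via hypnogram is available but not default, since the
clinical-EEG workflow this mirrors had no machine-readable staging.

## Spindle detection

Sigma relative power — sigma-band (11–16 Hz) power over broadband
(1–30 Hz) power, Hann-tapered periodogram per 2-s window — is computed on
a 200-ms hop. The literal reading of "2-s window with 200-ms overlap"
would be a 1.8-s hop, which cannot localize 0.5-s events; 200 ms is the
step the detector this emulates actually uses, and the literal reading
remains available through `spindle_win_shift_s`.

Windows with relpow ≥ 0.20 are candidate activity. A candidate event
spans the first to last **window centre** of a maximal supra-threshold
run: the Hann taper concentrates each window's power estimate at its
centre, which localizes a Gaussian-envelope burst to within ~0.2 s (a
1.0-s burst at 3× background RMS detects as 30.0–31.0 s exactly in the
test construction). Assigning each window its full 2-s support instead
would inflate every event by up to ±2 s and eliminate ordinary spindles
via the 2-s maximum-duration rule. Candidates < 500 ms apart merge
(sentence order: merge first, then duration filter); events < 0.5 s or
> 2.0 s are eliminated; events must lie inside artifact-free sleep runs of
≥ 2 min and touch no masked sample; across channels, events whose starts
differ by < 300 ms consolidate onto the channel with the highest peak
relpow (iterated until no pair violates the rule, so the output invariant
— no two starts closer than 300 ms — holds exactly).

Density is events/min per valid run, averaged unweighted over runs (not
pooled), per the stated definition. All channels contribute after
consolidation (configurable). Two consequences worth knowing: (a) the
same physiological spindle detected on two channels with starts > 300 ms
apart counts twice, so detected density runs ~1.5–2× the generated
per-minute rate on multi-channel synthetic data — a property of the
stated rule set, uniform across groups, and irrelevant to group
contrasts; (b) a single isolated supra-threshold window has zero centre
span and is dropped by the 0.5-s floor, which suppresses one-window noise
events.

An independent brute-force implementation (explicit window loop, explicit
merge/consolidation scans, written separately in the test suite) must
agree exactly on 200 random 60-s signals; recovery against generator
ground truth (events ≥ 2× background RMS) reaches recall and precision
≥ 0.8 with ≥ 50%-overlap matching, many-to-one allowed on the detection
side because of (a).

## Slow-wave sleep

**Automated (delta-threshold) method.** Delta (1–4 Hz) mean PSD per
non-overlapping 30-s epoch (Hann periodogram), per channel plus
channel-group means; the detector runs per group with frontal as the
headline (slow waves are frontally maximal). Baseline = the
`floor(n/2)` epochs with the lowest delta power, ties broken by epoch
index (deterministic); threshold = baseline mean + 1 **population** SD
(at ~420 baseline epochs the sample/population distinction is negligible;
the choice is recorded); high-delta = strictly greater, so a constant
series yields exactly 0% SWS; only runs ≥ 32 consecutive epochs count;
percent SWS = detected time over the 7-h window (or the actual duration
when shorter). The method is scale-invariant by construction. "16 min"
is documentation of 32 × 30 s, not an independent parameter.

**AASM-style method.** On the frontal-group mean signal, individual slow
waves are found by 0.5–2 Hz band-pass (3rd-order Butterworth,
forward-backward) and zero-crossing pairing: a full wave spans three
consecutive crossings, is kept when its period is 0.5–2.0 s and its
peak-to-peak ≥ 75 µV, and kept waves do not overlap. An epoch is N3 when
qualifying waves occupy ≥ 20% of it (6 s); percent SWS = N3 epochs over
*sleep* epochs. The two percent definitions use different denominators
(7-h window vs total sleep time) by design and are never mixed.

## Synthetic data

The generator emulates the statistical structure the analysis assumes;
defaults are the study conditions, not tuning knobs.

* **Hypnogram**: cyclic W → N1 → N2 → (N3) → N2 → REM with stochastic
  stage durations; N3 emitted in bouts of ≥ 32 epochs so the automated
  detector's run-length rule is satisfiable; realized N3 fraction within
  ±0.05 of target for nights ≥ 4 h. When the target is positive but below
  one minimum bout (e.g. 20% of a 1-h recording = 24 epochs < 32), a
  single minimum-length bout (32 plus 0–6 jitter epochs) is emitted,
  overshooting the fraction — the run-length rule and the fraction cannot
  both hold on short recordings.
* **Background**: 1/f² power (amplitude 1/f above 0.5 Hz) — the steep,
  delta-dominant spectral slope of NREM sleep; with it the baseline sigma
  fraction sits near 0.03, far under the 0.20 spindle threshold. Spatial
  structure comes from unit-RMS sources anchored under every electrode
  (plus a few at random scalp points) with Gaussian topographies of 0.8
  head-radius units and 2% independent sensor noise, so neighbouring
  channels correlate ≥ ~0.9 raw and ≥ ~0.7 even after common-average
  referencing — the redundancy the correlation criterion relies on.
* **Beta component**: 16–28 Hz band-limited source-mixed noise at 5 µV
  RMS × `beta_gain` (Dup15q-like: gain 3). The band sits inside 12–30 Hz
  but above the sigma band, modelling the beta peak seen in this
  phenotype (~20–25 Hz) rather than spectrally flat beta; flat 12–30 Hz
  noise would mechanically inflate sigma relative power and contaminate
  spindle counts with an artifact of the synthesis, not of the biology.
* **Spindles**: Poisson-placed in N2 (default NT 2.5/min, Dup15q-like
  0.7/min), 11–16 Hz carrier, Gaussian envelope (σ = duration/6), duration
  uniform 0.5–2.0 s, 45 µV peak (≈ 3× background RMS), synchronous on
  frontocentral channels with per-channel gain 0.7–1.0, ≥ 3 s apart so
  truth events are unambiguous for recall/precision scoring. Ground truth
  records the highest-gain channel.
* **Slow waves**: a common 0.5–2 Hz filtered-noise process per N3 run,
  rescaled per epoch so the **median** full wave reaches the target
  peak-to-peak (150 µV default — pediatric N3 is high-amplitude, and the
  epoch maximum then sits well above the target, as in real children),
  with a graded zero-mean anterior-posterior spatial pattern (positive
  frontal, negative posterior, magnitudes 0.55–1.1) so slow waves survive
  common-average referencing and per-channel power varies smoothly rather
  than bimodally. K-complexes appear sparsely in N2 for realism; nothing
  consumes them.
* **Artifacts**: blinks (frontal 0.3–0.5-s, ~1000 µV transients) and
  muscle bursts (temporal 20–60 Hz noise, ~500 µV RMS, 0.5–2 s) at
  per-hour rates (defaults 4 and 3), plus a 60 Hz sinusoid (2 µV, with
  ±50% per-channel impedance spread). Optionally one injected flat
  channel.
* **Cohorts**: per-subject seeds derive from a master seed
  (`SeedSequence.spawn`); ±20% multiplicative jitter on rates and
  amplitudes. Everything is bit-reproducible given the seed.

**What passing tests do and do not show.** The generator shares the
detectors' structural assumptions (stationary background, band-limited
events, exact stage boundaries at 30-s grid lines). Recovery at the
stated thresholds therefore demonstrates that the implementations compute
their stated rules correctly and that the rules recover events of the
stated prominence — not that the thresholds are clinically optimal, nor
that performance transfers to recordings with drifting electrodes,
arousals, epileptiform discharges (explicitly out of scope) or ambiguous
stage transitions.

## Cohort statistics

Pooled-variance (Student's) two-sample *t* tests, two-sided, with
n₁ + n₂ − 2 degrees of freedom — pooled rather than Welch to match the
named test; Welch is available behind a flag. Zero pooled variance with
equal means reports t = 0, p = 1. No multiple-testing correction is
applied, matching the original analysis; the report says so. Significance
stars: * p < 0.05, ** p < 0.01, *** p < 0.001, **** p < 0.0001. The
packaged Dup15q characteristics table (15 participants) supports offline
descriptives: mean age 5.69 years, ages 9–156 months, 9 with epilepsy,
13 isodicentric / 2 interstitial.

## Problem sizes

Validation uses 20-min single-stage recordings for detector recovery,
4-h nights for percent-SWS recovery, and a 15-vs-12 cohort of 1-h 19-channel
recordings at 200 Hz for the end-to-end group contrast — sizes at which
every quantity under test (event counts ≥ 30, ≥ 480 delta epochs,
per-group n ≥ 12) is well estimated while a full run stays in the minutes
range on one CPU.

## Known limitations

* The EDF writer is minimal (16-bit, 1-s records, integer sampling
  rates); EDF+ annotations are ignored on read.
* REM-specific phenomena, epileptiform-discharge synthesis and detection,
  and spindle morphology features beyond the stated rules are out of
  scope.
* The correlation bad-channel criterion degrades on sparse montages
  (< ~10 channels), where a channel may have only one spatial neighbour.
* Detected spindle density is a detector-defined quantity, not an
  estimate of the true event rate (see consolidation note above); only
  within-study contrasts are meaningful, which is how the measure is
  used.
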