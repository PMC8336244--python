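"""Synthetic overnight polysomnography with exact ground truth.

Generates seeded multi-channel sleep EEG (microvolts, 10-20 montage) plus a
30-s-epoch hypnogram and a sidecar listing every synthesized event, so each
analysis stage can be validated against known truth without clinical data.

The signal model, per channel:

* spatially smooth delta-dominant background (1/f^2 power, the steep
  spectral slope of NREM sleep) -- a handful of noise "sources" with
  Gaussian scalp topographies, plus a small independent sensor-noise term,
  so that neighbouring electrodes are strongly correlated (as the
  bad-channel criteria assume of real EEG);
* a beta-band component (16-28 Hz band-limited noise, also source-mixed)
  whose amplitude scales with ``beta_gain`` -- the "Dup15q-like" phenotype
  of elevated beta is modelled as a 3x gain.  The component is kept above
  the 11-16 Hz sigma band, reflecting the beta peak observed in this
  phenotype (~20-25 Hz) and leaving spindle detection uncontaminated;
* stage-conditional events: N2 epochs receive Poisson-placed spindle bursts
  (11-16 Hz carrier, Gaussian envelope, 0.5-2.0 s) and sparse K-complexes;
  N3 runs receive a common 0.5-2 Hz slow-wave process with a zero-mean
  (dipolar, frontally positive) spatial pattern so slow waves survive
  common-average re-referencing;
* ocular and muscle artifacts at configured per-hour rates, sized so that
  windowed-RMS burst suppression alone controls them, plus a 60 Hz line
  sinusoid; optionally one injected flat channel.

Everything is reproducible to full numeric precision given the seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from . import montage as mon
from .edf_io import Recording, write_recording

__all__ = ["Hypnogram", "GenProfile", "GroundTruth", "nt_profile",
           "dup15q_profile", "generate_hypnogram", "generate_recording",
           "generate_cohort", "write_subject"]

STAGES = ("W", "N1", "N2", "N3", "REM")
SLEEP_STAGES = ("N1", "N2", "N3")

#: beta-band component RMS (uV) at beta_gain = 1
BETA_BASE_RMS_UV = 5.0
_FRONTAL = ("Fp1", "Fp2", "F3", "F4", "F7", "F8", "Fz")
_SPINDLE_CHS = ("F3", "F4", "Fz", "C3", "C4", "Cz")


# --------------------------------------------------------------------------
# Types
# --------------------------------------------------------------------------

@dataclass
class Hypnogram:
    """Per-30-s-epoch sleep-stage labels (W, N1, N2, N3, REM)."""

    stages: list[str]
    epoch_s: float = 30.0
    start_clock: float = 22 * 3600.0

    def __post_init__(self) -> None:
        bad = set(self.stages) - set(STAGES)
        if bad:
            raise ValueError(f"unknown sleep stages: {sorted(bad)}")

    @property
    def n_epochs(self) -> int:
        return len(self.stages)

    @property
    def duration_s(self) -> float:
        return self.n_epochs * self.epoch_s

    def fraction(self, stage: str) -> float:
        return self.stages.count(stage) / max(self.n_epochs, 1)

    def sleep_mask(self) -> np.ndarray:
        """Boolean per-epoch mask of NREM sleep (N1/N2/N3)."""
        return np.array([s in SLEEP_STAGES for s in self.stages])

    def runs_of(self, stage: str) -> list[tuple[int, int]]:
        """Maximal runs of ``stage`` as (start_epoch, n_epochs)."""
        runs, start = [], None
        for i, s in enumerate(self.stages + ["_"]):
            if s == stage and start is None:
                start = i
            elif s != stage and start is not None:
                runs.append((start, i - start))
                start = None
        return runs

    def to_text(self, path: str | Path) -> None:
        Path(path).write_text(
            "".join(f"{i}\t{s}\n" for i, s in enumerate(self.stages)))

    @classmethod
    def from_text(cls, path: str | Path, epoch_s: float = 30.0,
                  start_clock: float = 22 * 3600.0) -> "Hypnogram":
        stages = [line.split("\t")[1].strip()
                  for line in Path(path).read_text().splitlines() if line]
        return cls(stages, epoch_s, start_clock)


@dataclass(frozen=True)
class GenProfile:
    """Generative phenotype parameters for one cohort.

    ``beta_gain`` multiplies the beta-band background amplitude;
    ``spindle_density_per_min`` is the Poisson rate of spindles in N2;
    ``sws_fraction`` the target fraction of epochs synthesized as N3;
    ``artifact_rates`` per-hour rates keyed ``blink``/``muscle``.
    """

    label: str = "NT"
    beta_gain: float = 1.0
    spindle_density_per_min: float = 2.5
    spindle_amp_uv: float = 45.0
    sws_fraction: float = 0.20
    sw_amp_uv: float = 150.0
    noise_1f_scale: float = 15.0
    artifact_rates: dict = field(default_factory=lambda: {"blink": 4.0,
                                                          "muscle": 3.0})
    line_amp_uv: float = 2.0
    beta_stage_mod: dict | None = None  #: optional stage -> beta factor

    def __post_init__(self) -> None:
        for key in ("beta_gain", "spindle_density_per_min", "spindle_amp_uv",
                    "sw_amp_uv", "noise_1f_scale", "line_amp_uv"):
            if getattr(self, key) < 0:
                raise ValueError(f"{key}: must be >= 0")
        if any(v < 0 for v in self.artifact_rates.values()):
            raise ValueError("artifact_rates: must be >= 0")
        if not 0.0 <= self.sws_fraction <= 1.0:
            raise ValueError("sws_fraction: must be in [0, 1]")


def nt_profile(**overrides) -> GenProfile:
    """Neurotypical-like defaults."""
    return replace(GenProfile(), **overrides) if overrides else GenProfile()


def dup15q_profile(**overrides) -> GenProfile:
    """Dup15q-like phenotype: elevated beta, few spindles, absent SWS."""
    base = GenProfile(label="DUP15Q", beta_gain=3.0,
                      spindle_density_per_min=0.7, sws_fraction=0.0)
    return replace(base, **overrides) if overrides else base


@dataclass
class GroundTruth:
    """Exact event lists recorded during synthesis."""

    spindles: list[tuple[str, float, float]] = field(default_factory=list)
    slow_wave_epochs: list[int] = field(default_factory=list)
    bad_channels: list[str] = field(default_factory=list)
    artifact_intervals: list[tuple[float, float, str]] = field(
        default_factory=list)
    hypnogram: Hypnogram | None = None

    def to_json(self, path: str | Path) -> None:
        d = {"spindles": self.spindles,
             "slow_wave_epochs": self.slow_wave_epochs,
             "bad_channels": self.bad_channels,
             "artifact_intervals": self.artifact_intervals,
             "stages": None if self.hypnogram is None
             else self.hypnogram.stages}
        Path(path).write_text(json.dumps(d, indent=1))


# --------------------------------------------------------------------------
# Hypnogram generation
# --------------------------------------------------------------------------

def _n3_bout_lengths(n_epochs: int, fraction: float,
                     min_run: int, rng: np.random.Generator) -> list[int]:
    """Split the N3 budget into bouts of >= ``min_run`` epochs.

    When the budget is positive but below one minimum-length bout, a single
    minimum bout is emitted provided the night is long enough (>= 2x the
    minimum), overshooting the target fraction rather than violating the
    run-length rule.
    """
    target = int(round(fraction * n_epochs))
    if target == 0:
        return []
    if target < min_run:
        if n_epochs < 2 * min_run:
            return []
        return [min_run + int(rng.integers(0, 7))]
    n_bouts = max(1, int(round(target / (1.5 * min_run))))
    while -(-target // n_bouts) < min_run:  # ceil
        n_bouts -= 1
    base = target // n_bouts
    lengths = [base + (1 if i < target % n_bouts else 0)
               for i in range(n_bouts)]
    return [max(min_run, int(round(L * rng.uniform(0.9, 1.1))))
            for L in lengths]


def generate_hypnogram(duration_s: float, profile: GenProfile,
                       seed: int, epoch_s: float = 30.0,
                       start_clock: float = 22 * 3600.0,
                       min_run_epochs: int = 32) -> Hypnogram:
    """Cyclic W -> N1 -> N2 -> (N3) -> N2 -> REM hypnogram.

    N3 is emitted in bouts of at least ``min_run_epochs`` consecutive
    epochs; for nights of >= 4 h the realized N3 fraction tracks
    ``profile.sws_fraction`` within +-0.05.
    """
    n_epochs = int(duration_s // epoch_s)
    if n_epochs < 10:
        raise ValueError(f"duration too short: {duration_s} s "
                         f"(need >= {10 * epoch_s:.0f})")
    rng = np.random.default_rng(seed)
    bouts = _n3_bout_lengths(n_epochs, profile.sws_fraction,
                             min_run_epochs, rng)
    non_n3 = n_epochs - sum(bouts)
    n_cycles = max(len(bouts), max(1, int(round(n_epochs / 180))))

    # fixed per-cycle components; N2 filler absorbs the remainder
    wake = [int(rng.integers(4, 11))] + [int(rng.integers(0, 3))
                                         for _ in range(n_cycles - 1)]
    n1 = [int(rng.integers(2, 7)) for _ in range(n_cycles)]
    rem = [0] + [int(rng.integers(8, 21)) for _ in range(n_cycles - 1)]
    n2b = [int(rng.integers(2, 9)) for _ in range(n_cycles)]

    def fixed_total():
        return sum(wake) + sum(n1) + sum(rem) + sum(n2b)

    # shrink soft components until at least one N2 epoch per cycle fits
    pools = [rem, wake, n2b, n1]
    while non_n3 - fixed_total() < n_cycles:
        donor = max(pools, key=sum)
        i = int(np.argmax(donor))
        if donor[i] == 0:
            raise ValueError("duration too short for the cyclic structure")
        donor[i] -= 1

    slack = non_n3 - fixed_total()
    n2a = [slack // n_cycles] * n_cycles
    for i in range(slack % n_cycles):
        n2a[i] += 1

    stages: list[str] = []
    for c in range(n_cycles):
        stages += ["W"] * wake[c] + ["N1"] * n1[c] + ["N2"] * n2a[c]
        if c < len(bouts):
            stages += ["N3"] * bouts[c]
        stages += ["N2"] * n2b[c] + ["REM"] * rem[c]
    assert len(stages) == n_epochs
    return Hypnogram(stages, epoch_s, start_clock)


# --------------------------------------------------------------------------
# Signal primitives
# --------------------------------------------------------------------------

def _shaped_noise(rng: np.random.Generator, n: int, fs: float,
                  shape_fn) -> np.ndarray:
    """Unit-RMS Gaussian noise with amplitude spectrum ``shape_fn(f)``."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, 1.0 / fs)
    gain = shape_fn(f)
    gain[0] = 0.0
    x = np.fft.irfft(spec * gain, n)
    sd = x.std()
    return x / sd if sd > 0 else x


def _pink_shape(f: np.ndarray, f0: float = 0.5) -> np.ndarray:
    """NREM-like background: power falls as 1/f^2 (amplitude 1/f).

    Sleep EEG has a steeper spectral slope than waking EEG (delta-dominant
    background); with this slope the baseline sigma/broadband fraction sits
    near 0.03, far below the 0.20 spindle threshold.
    """
    return 1.0 / np.maximum(f, f0)


def _band_shape(lo: float, hi: float):
    def shape(f: np.ndarray) -> np.ndarray:
        return ((f >= lo) & (f <= hi)).astype(float)
    return shape


def _source_mixed(rng: np.random.Generator, positions: np.ndarray,
                  n: int, fs: float, shape_fn, n_extra: int,
                  rms: float, sensor_frac: float = 0.02,
                  width: float = 0.8) -> np.ndarray:
    """Spatially smooth multichannel noise (channels x samples).

    One unit-RMS source is anchored under every electrode and ``n_extra``
    more at random scalp points, each with a Gaussian topography of
    ``width`` head-radius units; ``sensor_frac`` of each channel's
    variance is independent sensor noise.  Anchoring sources at the
    electrodes keeps neighbouring channels strongly correlated -- even
    after common-average re-referencing -- as in real EEG, where the
    correlation-based bad-channel criterion relies on exactly that
    redundancy.  Per-channel RMS equals ``rms``.
    """
    n_ch = positions.shape[0]
    extra = rng.standard_normal((n_extra, 3)) if n_extra else \
        np.empty((0, 3))
    if n_extra:
        extra /= np.linalg.norm(extra, axis=1, keepdims=True)
        extra[:, 2] = np.abs(extra[:, 2])  # upper hemisphere
    centers = np.vstack([positions, extra])
    d = np.linalg.norm(positions[:, None, :] - centers[None, :, :], axis=2)
    mix = np.exp(-d ** 2 / (2 * width ** 2))
    mix /= np.linalg.norm(mix, axis=1, keepdims=True)
    sources = np.stack([_shaped_noise(rng, n, fs, shape_fn)
                        for _ in range(centers.shape[0])])
    out = (mix @ sources) * np.sqrt(1.0 - sensor_frac)
    for c in range(n_ch):
        out[c] += np.sqrt(sensor_frac) * _shaped_noise(rng, n, fs, shape_fn)
    return out * rms


def _dipolar_gains(labels: list[str]) -> np.ndarray:
    """Graded zero-mean anterior-posterior pattern, positive frontally.

    Slow waves and K-complexes are given per-channel gains proportional to
    the electrode's front-back coordinate, demeaned (so the pattern
    survives common-average re-referencing) and scaled so the frontal
    channel-group mean gain is 1.  A graded topography keeps per-channel
    power differences smooth, as in real recordings, rather than creating
    an artificial bimodal outlier group.
    """
    y = mon.unit_positions(labels)[:, 1]
    g = y - y.mean()
    top = np.abs(g).max()
    if top <= 1e-9:
        return np.ones(len(labels))  # degenerate montage: unipolar
    # compress magnitudes into [0.55, 1]: the field shrinks and flips
    # front-to-back but never vanishes mid-scalp
    g = np.sign(g) * (0.55 + 0.45 * np.abs(g) / top)
    g -= g.mean()
    front = [i for i, lab in enumerate(labels) if lab in _FRONTAL]
    ref = g[front].mean() if front else np.abs(g).max()
    if abs(ref) <= 1e-9:
        return np.ones(len(labels))
    return g / ref


def _median_wave_p2p(seg: np.ndarray) -> float:
    """Median peak-to-peak of full waves (3 consecutive zero crossings)."""
    sign = np.sign(seg)
    sign[sign == 0] = 1
    crossings = np.flatnonzero(np.diff(sign) != 0) + 1
    p2ps = [seg[a:b].max() - seg[a:b].min()
            for a, b in zip(crossings[:-2:2], crossings[2::2])]
    if not p2ps:
        return float(seg.max() - seg.min())
    return float(np.median(p2ps))


def _spindle_wave(fs: float, dur: float, freq: float, phase: float,
                  amp: float) -> np.ndarray:
    n = max(int(round(dur * fs)), 1)
    t = np.arange(n) / fs
    env = np.exp(-((t - dur / 2) ** 2) / (2 * (dur / 6) ** 2))
    return amp * env * np.sin(2 * np.pi * freq * t + phase)


# --------------------------------------------------------------------------
# Recording generation
# --------------------------------------------------------------------------

def generate_recording(hyp: Hypnogram, montage: list[str],
                       profile: GenProfile, fs: float, seed: int,
                       flat_channel: str | None = None
                       ) -> tuple[Recording, GroundTruth]:
    """Synthesize one overnight recording following ``hyp``.

    Returns the :class:`Recording` (uV) and the :class:`GroundTruth`
    sidecar listing every synthesized spindle, N3 epoch, artifact interval
    and injected bad channel.
    """
    if fs < 100:
        raise ValueError(f"fs must be >= 100 Hz, got {fs}")
    if len(set(montage)) != len(montage) or not montage:
        raise ValueError("montage must be non-empty with unique labels")
    for lab in montage:
        if not mon.is_1020_label(lab):
            raise ValueError(f"channel {lab!r} is not a 10-20 label")
    if flat_channel is not None and flat_channel not in montage:
        raise ValueError(f"flat channel {flat_channel!r} not in montage")

    rng = np.random.default_rng(seed)
    n_ch = len(montage)
    n = int(round(hyp.duration_s * fs))
    epoch_n = int(round(hyp.epoch_s * fs))
    positions = mon.unit_positions(montage)
    truth = GroundTruth(hypnogram=hyp)

    # background 1/f^2 + beta component
    sig = _source_mixed(rng, positions, n, fs, _pink_shape, 6,
                        profile.noise_1f_scale)
    beta = _source_mixed(rng, positions, n, fs, _band_shape(16.0, 28.0), 2,
                         BETA_BASE_RMS_UV * profile.beta_gain)
    if profile.beta_stage_mod:
        scale = np.ones(n)
        for i, st in enumerate(hyp.stages):
            scale[i * epoch_n:(i + 1) * epoch_n] = \
                profile.beta_stage_mod.get(st, 1.0)
        beta = beta * scale
    sig += beta

    # spindles in N2 (synchronous over frontocentral channels)
    sp_idx = [i for i, lab in enumerate(montage) if lab in _SPINDLE_CHS]
    if not sp_idx:
        sp_idx = list(range(n_ch))
    for start_ep, n_ep in hyp.runs_of("N2"):
        run_t0 = start_ep * hyp.epoch_s
        run_dur = n_ep * hyp.epoch_s
        count = rng.poisson(profile.spindle_density_per_min * run_dur / 60.0)
        placed: list[tuple[float, float]] = []
        for _ in range(count):
            dur = rng.uniform(0.5, 2.0)
            lo, hi = run_t0 + 0.5, run_t0 + run_dur - dur - 0.5
            if hi <= lo:
                continue
            for _attempt in range(50):
                s0 = rng.uniform(lo, hi)
                if all(s0 + dur + 3.0 < a or s0 > b + 3.0
                       for a, b in placed):
                    break
            else:
                continue
            placed.append((s0, s0 + dur))
            freq = rng.uniform(11.0, 16.0)
            phase = rng.uniform(0, 2 * np.pi)
            gains = rng.uniform(0.7, 1.0, size=len(sp_idx))
            wave = _spindle_wave(fs, dur, freq, phase, profile.spindle_amp_uv)
            i0 = int(round(s0 * fs))
            for g, c in zip(gains, sp_idx):
                sig[c, i0:i0 + wave.size] += g * wave[:n - i0]
            best = montage[sp_idx[int(np.argmax(gains))]]
            truth.spindles.append((best, s0, s0 + dur))
        # sparse K-complexes for realism (no detector consumes these)
        kg = _dipolar_gains(montage)
        for _ in range(rng.poisson(0.5 * run_dur / 60.0)):
            kdur, kamp = 0.7, 120.0
            kn = int(kdur * fs)
            t = np.arange(kn) / fs
            kwave = -kamp * np.sin(2 * np.pi * t / kdur) * np.hanning(kn)
            s0 = rng.uniform(run_t0, run_t0 + run_dur - kdur)
            i0 = int(round(s0 * fs))
            sig[:, i0:i0 + kn] += kg[:, None] * kwave[None, :]

    # slow waves in N3 (common process, dipolar pattern, per-epoch rescale
    # so the median individual wave meets the target peak-to-peak; the
    # epoch maximum then sits well above it, as in pediatric N3)
    sw_gains = _dipolar_gains(montage)
    for start_ep, n_ep in hyp.runs_of("N3"):
        truth.slow_wave_epochs.extend(range(start_ep, start_ep + n_ep))
        run_n = n_ep * epoch_n
        wave = _shaped_noise(rng, run_n, fs, _band_shape(0.5, 2.0))
        for e in range(n_ep):
            seg = wave[e * epoch_n:(e + 1) * epoch_n]
            med = _median_wave_p2p(seg)
            if med > 0:
                seg *= profile.sw_amp_uv * rng.uniform(1.0, 1.25) / med
        i0 = start_ep * epoch_n
        sig[:, i0:i0 + run_n] += sw_gains[:, None] * wave[None, :]

    # artifacts
    hours = hyp.duration_s / 3600.0
    blink_idx = {lab: g for lab, g in
                 [("Fp1", 1.0), ("Fp2", 1.0), ("F7", 0.4), ("F8", 0.4),
                  ("F3", 0.4), ("F4", 0.4), ("Fz", 0.4)]}
    muscle_idx = {lab: g for lab, g in
                  [("T3", 1.0), ("T4", 1.0), ("F7", 0.7), ("F8", 0.7),
                   ("T5", 0.5), ("T6", 0.5)]}
    for kind, rate in profile.artifact_rates.items():
        for _ in range(rng.poisson(rate * hours)):
            if kind == "blink":
                dur = rng.uniform(0.3, 0.5)
                s0 = rng.uniform(0, hyp.duration_s - dur)
                an = int(dur * fs)
                pulse = 1000.0 * np.hanning(an)
                i0 = int(round(s0 * fs))
                for c, lab in enumerate(montage):
                    g = blink_idx.get(lab, 0.0)
                    if g:
                        sig[c, i0:i0 + an] += g * pulse
            else:  # muscle: broadband high-frequency burst
                dur = rng.uniform(0.5, 2.0)
                s0 = rng.uniform(0, hyp.duration_s - dur)
                an = int(dur * fs)
                burst = _shaped_noise(rng, an, fs,
                                      _band_shape(20.0, min(60.0, fs / 2)))
                burst *= 500.0 * np.hanning(an)
                i0 = int(round(s0 * fs))
                for c, lab in enumerate(montage):
                    g = muscle_idx.get(lab, 0.0)
                    if g:
                        sig[c, i0:i0 + an] += g * burst
            truth.artifact_intervals.append((s0, s0 + dur, kind))

    # line noise
    if profile.line_amp_uv > 0:
        t = np.arange(n) / fs
        tone = np.sin(2 * np.pi * 60.0 * t + rng.uniform(0, 2 * np.pi))
        # electrode-impedance spread: line pickup varies channel to channel
        amps = profile.line_amp_uv * rng.uniform(0.5, 1.5, size=n_ch)
        sig += amps[:, None] * tone[None, :]

    if flat_channel is not None:
        sig[montage.index(flat_channel)] = 0.0
        truth.bad_channels.append(flat_channel)

    rec = Recording(sig, list(montage), fs, hyp.start_clock,
                    meta={"synthetic": True, "profile": profile.label,
                          "seed": seed})
    return rec, truth


def _jitter_profile(profile: GenProfile,
                    rng: np.random.Generator) -> GenProfile:
    """+-20% multiplicative between-subject jitter on rates and amplitudes."""
    j = lambda v: v * rng.uniform(0.8, 1.2)  # noqa: E731
    return replace(
        profile,
        beta_gain=j(profile.beta_gain),
        spindle_density_per_min=j(profile.spindle_density_per_min),
        spindle_amp_uv=j(profile.spindle_amp_uv),
        sws_fraction=min(1.0, j(profile.sws_fraction)),
        sw_amp_uv=j(profile.sw_amp_uv),
        noise_1f_scale=j(profile.noise_1f_scale),
        line_amp_uv=j(profile.line_amp_uv),
        artifact_rates={k: j(v) for k, v in profile.artifact_rates.items()},
    )


def iter_cohort(n_a: int, n_b: int, profile_a: GenProfile,
                profile_b: GenProfile, duration_s: float, seed: int,
                fs: float = 200.0, montage: list[str] | None = None):
    """Lazily yield ``(subject_id, group_label, recording, ground_truth)``.

    Per-subject seeds derive deterministically from the master seed; each
    ground truth carries the subject's hypnogram.  Streaming keeps memory
    flat for large cohorts.
    """
    if n_a < 1:
        raise ValueError("n_a must be >= 1")
    if n_b < 0:
        raise ValueError("n_b must be >= 0")
    montage = montage or list(mon.DEFAULT_MONTAGE_19)
    children = np.random.SeedSequence(seed).spawn(n_a + n_b)
    for i, ss in enumerate(children):
        profile = profile_a if i < n_a else profile_b
        sid = f"{profile.label}-{(i if i < n_a else i - n_a) + 1:02d}"
        sub_seed = int(ss.generate_state(1)[0] % (2 ** 31))
        rng = np.random.default_rng(sub_seed)
        pj = _jitter_profile(profile, rng)
        hyp = generate_hypnogram(duration_s, pj,
                                 int(rng.integers(0, 2 ** 31)))
        rec, truth = generate_recording(hyp, montage, pj, fs,
                                        int(rng.integers(0, 2 ** 31)))
        rec.meta["subject_id"] = sid
        yield sid, profile.label, rec, truth


def generate_cohort(n_a: int, n_b: int, profile_a: GenProfile,
                    profile_b: GenProfile, duration_s: float, seed: int,
                    fs: float = 200.0,
                    montage: list[str] | None = None
                    ) -> list[tuple[str, str, Recording, GroundTruth]]:
    """Materialized :func:`iter_cohort`."""
    return list(iter_cohort(n_a, n_b, profile_a, profile_b, duration_s,
                            seed, fs, montage))


def write_subject(out_dir: str | Path, subject_id: str, rec: Recording,
                  truth: GroundTruth) -> dict[str, Path]:
    """Write one subject's EDF, ground-truth JSON/TSV and hypnogram text."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {"edf": out_dir / f"{subject_id}.edf",
             "truth": out_dir / f"{subject_id}.truth.json",
             "events": out_dir / f"{subject_id}.events.tsv",
             "hypnogram": out_dir / f"{subject_id}.hypnogram.txt"}
    write_recording(rec, paths["edf"])
    truth.to_json(paths["truth"])
    with open(paths["events"], "w") as fh:
        fh.write("channel\tstart_s\tend_s\tkind\n")
        for ch, s, e in truth.spindles:
            fh.write(f"{ch}\t{s:.3f}\t{e:.3f}\tspindle\n")
        if truth.hypnogram is not None:
            ep = truth.hypnogram.epoch_s
            for i in truth.slow_wave_epochs:
                fh.write(f".\t{i * ep:.1f}\t{(i + 1) * ep:.1f}\tsws_epoch\n")
    if truth.hypnogram is not None:
        truth.hypnogram.to_text(paths["hypnogram"])
    return paths
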