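"""Slow-wave sleep quantification, two ways.

AUTO (delta-threshold) method: delta (1-4 Hz) power is computed per
non-overlapping 30-s epoch; the half of epochs with the lowest delta power
defines a non-SWS baseline; epochs whose delta power strictly exceeds the
baseline mean plus one (population) SD are "high-delta"; only runs of at
least 32 consecutive high-delta epochs (16 min) count as SWS, and percent
SWS is their total duration over the 7-h overnight window (or the actual
analyzed duration when shorter).

AASM-style method: an epoch is scored N3 when 0.5-2 Hz slow waves of at
least 75 uV peak-to-peak occupy at least 20% of it (6 s of 30 s), on the
frontal channel-group mean; percent SWS is N3 epochs over sleep epochs.

The two percent definitions use different denominators by design and are
never mixed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .edf_io import Recording
from .params import PipelineParams
from .spectral import ChannelGroups

__all__ = ["DeltaSeries", "SwsResult", "delta_epoch_series",
           "detect_sws_auto", "detect_slow_waves", "score_n3_aasm",
           "high_delta_segments"]


def _night_window_s(params: PipelineParams) -> float:
    """Length of the overnight analysis window (22:00 -> 05:00 is 7 h)."""
    return (params.night_end - params.night_start) % 86400.0


@dataclass
class DeltaSeries:
    """Per-30-s-epoch delta power per channel, with channel-group means."""

    epoch_start_s: np.ndarray
    values: np.ndarray                    # (n_epochs, n_channels), uV^2/Hz
    channel_labels: list[str]
    group_means: dict[str, np.ndarray] = field(default_factory=dict)
    epoch_s: float = 30.0

    @property
    def n_epochs(self) -> int:
        return self.values.shape[0]

    def to_frame(self):
        """Tidy per-epoch table (pandas) for export and delta-dynamics
        plots: epoch_start_s, one column per channel, one per group."""
        import pandas as pd

        df = pd.DataFrame(self.values, columns=self.channel_labels)
        df.insert(0, "epoch_start_s", self.epoch_start_s)
        for name, vals in self.group_means.items():
            df[f"group_{name}"] = vals
        return df


@dataclass
class SwsResult:
    segments: list[tuple[int, int]]       # (start_epoch, n_epochs)
    percent_sws: float | None             # 0-100, or None when undefined
    method: str                           # "AUTO" | "AASM"
    threshold_value: float | None = None  # AUTO only, uV^2/Hz
    n3_epochs: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.percent_sws is not None and not 0 <= self.percent_sws <= 100:
            raise ValueError("percent_sws must be within [0, 100]")


def delta_epoch_series(rec: Recording, params: PipelineParams,
                       groups: ChannelGroups | None = None) -> DeltaSeries:
    """Hann-periodogram mean delta PSD per non-overlapping 30-s epoch."""
    en = int(round(params.sws_epoch_s * rec.fs))
    n_ep = rec.n_samples // en
    if n_ep < 1:
        raise ValueError(
            f"recording ({rec.duration_s:.0f} s) shorter than one "
            f"{params.sws_epoch_s:.0f}-s epoch")
    taper = np.hanning(en)
    scale = 1.0 / (rec.fs * (taper ** 2).sum())   # PSD density normalization
    freqs = np.fft.rfftfreq(en, 1.0 / rec.fs)
    lo, hi = params.delta_band
    band = (freqs >= lo) & (freqs <= hi)
    values = np.empty((n_ep, rec.n_channels))
    chunk = 64
    for e0 in range(0, n_ep, chunk):
        e1 = min(e0 + chunk, n_ep)
        segs = rec.signal[:, e0 * en:e1 * en].reshape(
            rec.n_channels, e1 - e0, en)
        psd = np.abs(np.fft.rfft(segs * taper, axis=2)) ** 2 * scale
        psd[:, :, 1:-1] *= 2.0                    # one-sided
        values[e0:e1] = psd[:, :, band].mean(axis=2).T
    starts = np.arange(n_ep) * params.sws_epoch_s
    series = DeltaSeries(starts, values, list(rec.channel_labels),
                         epoch_s=params.sws_epoch_s)
    if groups is not None:
        for name, labels in groups.as_dict().items():
            idx = [rec.channel_labels.index(l) for l in labels
                   if l in rec.channel_labels]
            if idx:
                series.group_means[name] = values[:, idx].mean(axis=1)
    return series


def high_delta_segments(high: np.ndarray, min_run: int
                        ) -> list[tuple[int, int]]:
    """Maximal runs of True with length >= ``min_run``, as (start, n)."""
    edges = np.diff(np.concatenate(([0], high.view(np.int8), [0])))
    starts = np.flatnonzero(edges == 1)
    ends = np.flatnonzero(edges == -1)
    return [(int(s), int(e - s)) for s, e in zip(starts, ends)
            if e - s >= min_run]


def detect_sws_auto(series: DeltaSeries | np.ndarray,
                    params: PipelineParams,
                    group: str = "frontal") -> SwsResult:
    """Delta-threshold SWS detection on a channel-group mean series.

    The baseline is the ``floor(n/2)`` epochs with the lowest delta power
    (ties broken by epoch index); the threshold is baseline mean + 1
    population SD; high-delta means strictly greater.  The percent
    denominator is the 7-h overnight window, or the analyzed duration when
    shorter.  Scale-invariant: rescaling the recording rescales the
    threshold with it.
    """
    if isinstance(series, DeltaSeries):
        if group in series.group_means:
            x = series.group_means[group]
        else:
            x = series.values.mean(axis=1)
        epoch_s = series.epoch_s
    else:
        x = np.asarray(series, dtype=float)
        epoch_s = params.sws_epoch_s
    n = x.size
    if n < 2:
        raise ValueError("delta series needs at least 2 epochs")
    order = np.argsort(x, kind="stable")          # ties: lower index first
    baseline = x[order[:n // 2]]
    thr = baseline.mean() + params.sws_sd_mult * baseline.std()  # population SD
    high = x > thr
    segments = high_delta_segments(high, int(params.sws_min_run_epochs))
    total_epochs = sum(nseg for _, nseg in segments)
    denom = min(_night_window_s(params), n * epoch_s)
    percent = 100.0 * total_epochs * epoch_s / denom
    n3 = [e for s0, nseg in segments for e in range(s0, s0 + nseg)]
    return SwsResult(segments, percent, "AUTO", float(thr), n3)


def detect_slow_waves(x: np.ndarray, fs: float, params: PipelineParams
                      ) -> list[tuple[float, float, float]]:
    """Individual slow waves on one signal: (start_s, end_s, p2p_uv).

    Band-pass 0.5-2 Hz, then zero-crossing half-wave pairing: a full wave
    spans three consecutive zero crossings; it is kept when its period lies
    in 0.5-2.0 s and its peak-to-peak amplitude reaches 75 uV.  Kept waves
    do not overlap.
    """
    if x.size < 2 * fs:
        raise ValueError("signal shorter than 2 s")
    lo, hi = params.aasm_sw_band
    sos = sps.butter(3, [lo, hi], btype="bandpass", fs=fs, output="sos")
    y = sps.sosfiltfilt(sos, x)
    sign = np.sign(y)
    sign[sign == 0] = 1
    crossings = np.flatnonzero(np.diff(sign) != 0) + 1
    waves = []
    i = 0
    while i + 2 < crossings.size:
        i0, i2 = crossings[i], crossings[i + 2]
        period = (i2 - i0) / fs
        seg = y[i0:i2]
        p2p = seg.max() - seg.min() if seg.size else 0.0
        if 1.0 / hi <= period <= 1.0 / lo and p2p >= params.aasm_sw_amp_uv:
            waves.append((i0 / fs, i2 / fs, float(p2p)))
            i += 2
        else:
            i += 1
    return waves


def score_n3_aasm(rec: Recording, sleep_mask: np.ndarray,
                  params: PipelineParams,
                  groups: ChannelGroups | None = None) -> SwsResult:
    """AASM-style N3 scoring on the frontal channel-group mean.

    ``sleep_mask`` is a per-30-s-epoch boolean sleep indicator whose length
    must equal the epoch count.  Percent SWS is N3 epochs over sleep
    epochs; undefined (None) with zero sleep epochs.
    """
    frontal = (groups or ChannelGroups()).frontal
    idx = [rec.channel_labels.index(l) for l in frontal
           if l in rec.channel_labels]
    if not idx:
        raise ValueError("no frontal channel present in the montage")
    en = int(round(params.sws_epoch_s * rec.fs))
    n_ep = rec.n_samples // en
    sleep_mask = np.asarray(sleep_mask, dtype=bool)
    if sleep_mask.size != n_ep:
        raise ValueError(
            f"sleep mask has {sleep_mask.size} epochs, recording has {n_ep}")
    frontal_mean = rec.signal[idx].mean(axis=0)
    waves = detect_slow_waves(frontal_mean[:n_ep * en], rec.fs, params)

    occupancy = np.zeros(n_ep)
    for s, e, _ in waves:
        e0, e1 = int(s / params.sws_epoch_s), int(e / params.sws_epoch_s)
        for ep in range(e0, min(e1, n_ep - 1) + 1):
            lo = max(s, ep * params.sws_epoch_s)
            hi = min(e, (ep + 1) * params.sws_epoch_s)
            occupancy[ep] += max(0.0, hi - lo)
    need = params.aasm_occupancy_frac * params.sws_epoch_s
    n3 = sleep_mask & (occupancy >= need)
    n_sleep = int(sleep_mask.sum())
    if n_sleep == 0:
        return SwsResult(high_delta_segments(n3, 1), None, "AASM")
    percent = 100.0 * n3.sum() / n_sleep
    return SwsResult(high_delta_segments(n3, 1), percent, "AASM",
                     n3_epochs=list(np.flatnonzero(n3)))
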