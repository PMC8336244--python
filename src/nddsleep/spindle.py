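"""Automated sleep-spindle detection and density.

The detector follows the sigma relative-power scheme: per channel, the
fraction of 1-30 Hz broadband power falling in the 11-16 Hz sigma band is
computed in sliding 2-s Hann-tapered windows (200-ms hop); windows carrying
at least 20% of their power in the sigma band are candidate spindle
activity.  Candidates closer than 500 ms merge, events shorter than 0.5 s
or longer than 2.0 s are eliminated, events are restricted to artifact-free
sleep runs of at least 2 min, and near-simultaneous detections across
channels (starts within 300 ms) consolidate into a single event kept on the
channel with the highest peak relative power.

A candidate's extent is the span from the first to the last window centre
of a maximal supra-threshold run: the Hann taper concentrates each window's
power estimate at its centre, which localizes events well within the 2-s
window length.

Spindle density is events per minute per valid run, averaged (unweighted)
over runs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .edf_io import Recording
from .params import PipelineParams
from .preprocess import ArtifactMask
from .synthetic import Hypnogram

__all__ = ["SpindleEvent", "ValidEpochSet", "sigma_relative_power",
           "detect_spindles", "spindle_density", "build_valid_epochs",
           "write_events_tsv", "write_events_json"]


@dataclass(frozen=True)
class SpindleEvent:
    channel: str
    start_s: float
    end_s: float
    peak_relpow: float

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass
class ValidEpochSet:
    """Sorted, non-overlapping artifact-free sleep intervals, each >= 2 min."""

    intervals: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        iv = sorted(self.intervals)
        for (a0, a1), (b0, b1) in zip(iv[:-1], iv[1:]):
            if b0 < a1:
                raise ValueError("valid intervals overlap")
        self.intervals = iv

    @property
    def total_s(self) -> float:
        return sum(e - s for s, e in self.intervals)

    def contains(self, start: float, end: float) -> bool:
        return any(s <= start and end <= e for s, e in self.intervals)


def build_valid_epochs(mask: ArtifactMask, hypnogram: Hypnogram | None,
                       params: PipelineParams,
                       n_samples: int | None = None) -> ValidEpochSet:
    """Contiguous unmasked (and sleep-staged, when a hypnogram is given)
    runs of at least ``min_valid_epoch_s`` seconds."""
    n = mask.sample_mask.size if n_samples is None else n_samples
    fs = mask.fs
    ok = ~mask.sample_mask[:n]
    if hypnogram is not None:
        sleep = np.zeros(n, dtype=bool)
        en = int(round(hypnogram.epoch_s * fs))
        for i, stage in enumerate(hypnogram.stages):
            if stage in ("N1", "N2", "N3"):
                sleep[i * en:(i + 1) * en] = True
        ok &= sleep
    edges = np.diff(np.concatenate(([0], ok.view(np.int8), [0])))
    starts = np.flatnonzero(edges == 1)
    ends = np.flatnonzero(edges == -1)
    iv = [(s / fs, e / fs) for s, e in zip(starts, ends)
          if (e - s) / fs >= params.min_valid_epoch_s]
    return ValidEpochSet(iv)


# --------------------------------------------------------------------------
# Sigma relative power
# --------------------------------------------------------------------------

def sigma_relative_power(x: np.ndarray, fs: float, params: PipelineParams
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Sliding-window sigma/broadband power fraction for one channel.

    Returns ``(window_start_s, relpow)``; windows are ``spindle_win_s``
    long with a ``spindle_win_shift_s`` hop, Hann-tapered periodograms.
    """
    if fs < 64:
        raise ValueError(f"fs must be >= 64 Hz, got {fs}")
    wn = int(round(params.spindle_win_s * fs))
    hop = max(int(round(params.spindle_win_shift_s * fs)), 1)
    if x.size < wn:
        raise ValueError(
            f"signal ({x.size / fs:.2f} s) shorter than the "
            f"{params.spindle_win_s:.1f}-s analysis window")
    windows = sliding_window_view(x, wn)[::hop]
    taper = np.hanning(wn)
    spec = np.abs(np.fft.rfft(windows * taper, axis=1)) ** 2
    freqs = np.fft.rfftfreq(wn, 1.0 / fs)
    s_lo, s_hi = params.sigma_band
    b_lo, b_hi = params.broadband
    sigma = spec[:, (freqs >= s_lo) & (freqs <= s_hi)].sum(axis=1)
    broad = spec[:, (freqs >= b_lo) & (freqs <= b_hi)].sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        relpow = np.where(broad > 0, sigma / broad, 0.0)
    starts = np.arange(windows.shape[0]) * hop / fs
    return starts, relpow


# --------------------------------------------------------------------------
# Detection
# --------------------------------------------------------------------------

def _candidates_from_relpow(starts: np.ndarray, relpow: np.ndarray,
                            params: PipelineParams
                            ) -> list[tuple[float, float, float]]:
    """(start_s, end_s, peak_relpow) per maximal supra-threshold run."""
    half = params.spindle_win_s / 2.0
    supra = relpow >= params.spindle_relpow_thresh
    out = []
    i, n = 0, len(supra)
    while i < n:
        if not supra[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and supra[j + 1]:
            j += 1
        out.append((starts[i] + half, starts[j] + half,
                    float(relpow[i:j + 1].max())))
        i = j + 1
    return out


def _merge_close(cands: list[tuple[float, float, float]],
                 gap_s: float) -> list[tuple[float, float, float]]:
    merged: list[list[float]] = []
    for s, e, p in cands:
        if merged and s - merged[-1][1] < gap_s:
            merged[-1][1] = max(merged[-1][1], e)
            merged[-1][2] = max(merged[-1][2], p)
        else:
            merged.append([s, e, p])
    return [tuple(m) for m in merged]


def detect_spindles(rec: Recording, mask: ArtifactMask | None,
                    valid: ValidEpochSet,
                    params: PipelineParams) -> list[SpindleEvent]:
    """Multi-channel spindle detection; see module docstring for the rules.

    An empty :class:`ValidEpochSet` yields an empty result with a warning.
    """
    if not valid.intervals:
        warnings.warn("no valid sleep epochs: returning no spindles",
                      stacklevel=2)
        return []
    per_channel: list[SpindleEvent] = []
    for c, lab in enumerate(rec.channel_labels):
        starts, relpow = sigma_relative_power(rec.signal[c], rec.fs, params)
        cands = _candidates_from_relpow(starts, relpow, params)
        cands = _merge_close(cands, params.spindle_merge_gap_s)
        for s, e, p in cands:
            dur = e - s
            if dur < params.spindle_min_dur_s or dur > params.spindle_max_dur_s:
                continue
            if not valid.contains(s, e):
                continue
            if mask is not None:
                i0 = int(s * rec.fs)
                i1 = min(int(np.ceil(e * rec.fs)), mask.sample_mask.size)
                if mask.sample_mask[i0:i1].any():
                    continue
            per_channel.append(SpindleEvent(lab, s, e, p))

    # cross-channel consolidation: starts closer than spindle_consolidate_s
    # collapse onto the event with the highest peak relative power
    events = sorted(per_channel, key=lambda ev: (ev.start_s, -ev.peak_relpow))
    changed = True
    while changed:
        changed = False
        for i in range(len(events) - 1):
            if events[i + 1].start_s - events[i].start_s < \
                    params.spindle_consolidate_s:
                drop = i if events[i].peak_relpow < events[i + 1].peak_relpow \
                    else i + 1
                del events[drop]
                changed = True
                break
    return sorted(events, key=lambda ev: ev.start_s)


def write_events_tsv(events: list[SpindleEvent], path) -> None:
    """BED-like event export: channel, start_s, end_s, peak_relpow."""
    from pathlib import Path

    lines = ["channel\tstart_s\tend_s\tpeak_relpow"]
    lines += [f"{e.channel}\t{e.start_s:.3f}\t{e.end_s:.3f}"
              f"\t{e.peak_relpow:.4f}" for e in events]
    Path(path).write_text("\n".join(lines) + "\n")


def write_events_json(events: list[SpindleEvent], path) -> None:
    import json
    from pathlib import Path

    Path(path).write_text(json.dumps(
        [{"channel": e.channel, "start_s": e.start_s, "end_s": e.end_s,
          "peak_relpow": e.peak_relpow} for e in events], indent=1))


def spindle_density(events: list[SpindleEvent], valid: ValidEpochSet
                    ) -> tuple[float | None, list[dict]]:
    """Spindles per minute, per valid run, averaged unweighted over runs.

    Returns ``(density, per_run_table)``; density is ``None`` (missing)
    when there are no valid runs.
    """
    if not valid.intervals:
        warnings.warn("no valid sleep epochs: spindle density undefined",
                      stacklevel=2)
        return None, []
    rows = []
    for s, e in valid.intervals:
        n_ev = sum(1 for ev in events if s <= ev.start_s and ev.end_s <= e)
        minutes = (e - s) / 60.0
        rows.append({"start_s": s, "end_s": e, "n_spindles": n_ev,
                     "density_per_min": n_ev / minutes})
    density = float(np.mean([r["density_per_min"] for r in rows]))
    return density, rows
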