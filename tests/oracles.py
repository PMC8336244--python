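"""Independent brute-force oracles used by the test suite.

Each oracle re-derives a pipeline quantity with explicit loops and naive
scans, written separately from the package implementation so the two can
be compared on shared inputs.
"""

from __future__ import annotations

import math

import numpy as np


# --------------------------------------------------------------------------
# Spindle detection: explicit window loop, explicit merge/consolidate scans
# --------------------------------------------------------------------------

def brute_force_spindles(signals: np.ndarray, labels: list[str], fs: float,
                         valid_intervals: list[tuple[float, float]],
                         params) -> list[tuple[str, float, float, float]]:
    """Naive re-implementation of the detector; returns
    (channel, start_s, end_s, peak_relpow) tuples sorted by start."""
    wn = int(round(params.spindle_win_s * fs))
    hop = max(int(round(params.spindle_win_shift_s * fs)), 1)
    taper = np.hanning(wn)
    freqs = np.fft.rfftfreq(wn, 1.0 / fs)
    s_lo, s_hi = params.sigma_band
    b_lo, b_hi = params.broadband

    per_channel = []
    for c, lab in enumerate(labels):
        x = signals[c]
        rel, starts = [], []
        k = 0
        while k * hop + wn <= x.size:
            seg = x[k * hop:k * hop + wn] * taper
            spec = np.abs(np.fft.rfft(seg)) ** 2
            sig_p = broad_p = 0.0
            for i, f in enumerate(freqs):
                if b_lo <= f <= b_hi:
                    broad_p += spec[i]
                    if s_lo <= f <= s_hi:
                        sig_p += spec[i]
            rel.append(sig_p / broad_p if broad_p > 0 else 0.0)
            starts.append(k * hop / fs)
            k += 1

        # maximal supra-threshold runs -> [first centre, last centre]
        half = params.spindle_win_s / 2.0
        cands = []
        i = 0
        while i < len(rel):
            if rel[i] < params.spindle_relpow_thresh:
                i += 1
                continue
            j = i
            while j + 1 < len(rel) and \
                    rel[j + 1] >= params.spindle_relpow_thresh:
                j += 1
            cands.append([starts[i] + half, starts[j] + half,
                          max(rel[i:j + 1])])
            i = j + 1

        # merge candidates closer than the merge gap
        merged = []
        for cand in cands:
            if merged and cand[0] - merged[-1][1] < params.spindle_merge_gap_s:
                merged[-1][1] = max(merged[-1][1], cand[1])
                merged[-1][2] = max(merged[-1][2], cand[2])
            else:
                merged.append(list(cand))

        for s, e, p in merged:
            if e - s < params.spindle_min_dur_s:
                continue
            if e - s > params.spindle_max_dur_s:
                continue
            inside = any(a <= s and e <= b for a, b in valid_intervals)
            if inside:
                per_channel.append((lab, s, e, p))

    # cross-channel consolidation: repeatedly collapse the first adjacent
    # pair of starts closer than the consolidation window, keeping the
    # higher peak (the later event on ties)
    events = sorted(per_channel, key=lambda t: (t[1], -t[3]))
    while True:
        for i in range(len(events) - 1):
            if events[i + 1][1] - events[i][1] < params.spindle_consolidate_s:
                drop = i if events[i][3] < events[i + 1][3] else i + 1
                del events[drop]
                break
        else:
            break
    return sorted(events, key=lambda t: t[1])


# --------------------------------------------------------------------------
# Run-length segments: naive linear scan
# --------------------------------------------------------------------------

def naive_segments(high, min_run: int) -> list[tuple[int, int]]:
    segs = []
    i, n = 0, len(high)
    while i < n:
        if high[i]:
            j = i
            while j + 1 < n and high[j + 1]:
                j += 1
            if j - i + 1 >= min_run:
                segs.append((i, j - i + 1))
            i = j + 1
        else:
            i += 1
    return segs


# --------------------------------------------------------------------------
# Pooled-variance two-sample t test: textbook closed form
# --------------------------------------------------------------------------

def pooled_t(a, b) -> tuple[float, int]:
    a, b = list(map(float, a)), list(map(float, b))
    na, nb = len(a), len(b)
    ma, mb = sum(a) / na, sum(b) / nb
    ssa = sum((x - ma) ** 2 for x in a)
    ssb = sum((x - mb) ** 2 for x in b)
    df = na + nb - 2
    sp2 = (ssa + ssb) / df
    t = (ma - mb) / math.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    return t, df


def overlap_s(a0: float, a1: float, b0: float, b1: float) -> float:
    return max(0.0, min(a1, b1) - max(a0, b0))


def recall_precision(truth: list[tuple[float, float]],
                     detected: list[tuple[float, float]],
                     min_frac: float = 0.5) -> tuple[float, float]:
    """Event recovery: a truth event is recalled when some detection covers
    >= ``min_frac`` of it; a detection is correct when truth covers
    >= ``min_frac`` of the detection (many-to-one allowed)."""
    if not truth or not detected:
        return 0.0, 0.0
    rec = sum(1 for s, e in truth
              if any(overlap_s(s, e, d0, d1) >= min_frac * (e - s)
                     for d0, d1 in detected)) / len(truth)
    prec = sum(1 for d0, d1 in detected
               if any(overlap_s(s, e, d0, d1) >= min_frac * (d1 - d0)
                      for s, e in truth)) / len(detected)
    return rec, prec
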