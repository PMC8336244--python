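"""EDF reading/writing and overnight-window extraction.

The in-memory container is :class:`Recording`: a channels x samples matrix in
microvolts with 10-20 labels, sampling rate and the clock time the recording
started.  Reading goes through MNE's EDF reader; writing uses a minimal
16-bit EDF writer (one-second data records, per-channel symmetric physical
range), sufficient for round-tripping pipeline outputs and synthetic data.
"""

from __future__ import annotations

import math
import struct
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .params import PipelineParams

__all__ = ["Recording", "read_recording", "write_recording",
           "extract_night_window"]

_DAY = 86400.0


@dataclass
class Recording:
    """Multichannel EEG in microvolts.

    ``start_clock`` is seconds since local midnight; ``meta`` carries
    free-form provenance notes accumulated by pipeline stages.
    """

    signal: np.ndarray               # (n_channels, n_samples), uV
    channel_labels: list[str]
    fs: float                        # Hz
    start_clock: float = 0.0         # seconds since midnight
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.signal = np.atleast_2d(np.asarray(self.signal, dtype=float))
        if self.signal.ndim != 2:
            raise ValueError("signal must be a channels x samples matrix")
        if len(self.channel_labels) != self.signal.shape[0]:
            raise ValueError(
                f"{len(self.channel_labels)} labels for "
                f"{self.signal.shape[0]} signal rows")
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("channel labels must be unique")
        if not self.fs > 0:
            raise ValueError("fs must be positive")
        if not np.all(np.isfinite(self.signal)):
            raise ValueError("signal contains non-finite samples")

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def copy_with(self, signal: np.ndarray, **meta_updates) -> "Recording":
        meta = dict(self.meta)
        meta.update(meta_updates)
        return Recording(signal, list(self.channel_labels), self.fs,
                         self.start_clock, meta)


# --------------------------------------------------------------------------
# EDF writing (minimal 16-bit writer; 1-s data records)
# --------------------------------------------------------------------------

def _pad(text: str, width: int) -> bytes:
    b = text.encode("ascii", "replace")[:width]
    return b + b" " * (width - len(b))


def write_recording(rec: Recording, path: str | Path) -> Path:
    """Write ``rec`` to ``path`` as 16-bit EDF.

    Physical dimension is uV with a symmetric per-channel physical range
    covering the data, so quantization error is bounded by range / 2**16.
    The sampling rate must yield an integer number of samples per 1-s
    record; a trailing partial second is zero-padded.
    """
    if rec.n_channels == 0:
        raise ValueError("cannot write an EDF with no channels")
    spr = rec.fs
    if abs(spr - round(spr)) > 1e-9:
        raise ValueError(f"non-integer samples per 1-s record (fs={rec.fs})")
    spr = int(round(spr))
    n_rec = math.ceil(rec.n_samples / spr)
    ns = rec.n_channels

    pmax = np.maximum(np.abs(rec.signal).max(axis=1), 1e-6)
    # symmetric digital range: the affine EDF mapping is then exactly
    # linear through zero, so zero samples round-trip exactly
    dig_max, dig_min = 32767, -32767
    scale = pmax / dig_max

    start = int(rec.start_clock) % int(_DAY)
    h, m, s = start // 3600, start % 3600 // 60, start % 60

    header = b"".join([
        _pad("0", 8),
        _pad("X X X X", 80),
        _pad("Startdate 01-JAN-2001 X X X", 80),
        _pad("01.01.01", 8),
        _pad(f"{h:02d}.{m:02d}.{s:02d}", 8),
        _pad(str(256 * (1 + ns)), 8),
        _pad("", 44),
        _pad(str(n_rec), 8),
        _pad("1", 8),
        _pad(str(ns), 4),
    ])
    header += b"".join(_pad(lab, 16) for lab in rec.channel_labels)
    header += b"".join(_pad("", 80) for _ in range(ns))
    header += b"".join(_pad("uV", 8) for _ in range(ns))
    header += b"".join(_pad(f"{-p:.6g}"[:8], 8) for p in pmax)
    header += b"".join(_pad(f"{p:.6g}"[:8], 8) for p in pmax)
    header += b"".join(_pad(str(dig_min), 8) for _ in range(ns))
    header += b"".join(_pad(str(dig_max), 8) for _ in range(ns))
    header += b"".join(_pad("", 80) for _ in range(ns))
    header += b"".join(_pad(str(spr), 8) for _ in range(ns))
    header += b"".join(_pad("", 32) for _ in range(ns))

    padded = np.zeros((ns, n_rec * spr))
    padded[:, :rec.n_samples] = rec.signal
    # re-derive physical maxima from the 6-char header text so that the
    # scale used for digitization matches what a reader will parse back
    pmax_hdr = np.array([float(f"{p:.6g}"[:8]) for p in pmax])
    scale = pmax_hdr / dig_max
    digital = np.clip(np.round(padded / scale[:, None]), dig_min, dig_max)
    digital = digital.astype("<i2")

    path = Path(path)
    with open(path, "wb") as fh:
        fh.write(header)
        for r in range(n_rec):
            fh.write(digital[:, r * spr:(r + 1) * spr].tobytes())
    return path


# --------------------------------------------------------------------------
# EDF reading (MNE-backed, with a header sanity peek)
# --------------------------------------------------------------------------

def _peek_header(path: Path) -> dict:
    with open(path, "rb") as fh:
        head = fh.read(256)
        if len(head) < 256:
            raise ValueError(f"{path}: truncated EDF header")
        try:
            rec_dur = float(head[244:252].decode("ascii").strip())
            ns = int(head[252:256].decode("ascii").strip())
        except (UnicodeDecodeError, ValueError) as exc:
            raise ValueError(f"{path}: malformed EDF header ({exc})") from None
        sig_head = fh.read(ns * 256)
    if len(sig_head) < ns * 256 or ns < 1 or rec_dur <= 0:
        raise ValueError(f"{path}: malformed EDF signal headers")
    labels = [sig_head[i * 16:(i + 1) * 16].decode("ascii", "replace").strip()
              for i in range(ns)]
    spr_off = ns * 216
    spr = [int(sig_head[spr_off + i * 8: spr_off + (i + 1) * 8].decode().strip())
           for i in range(ns)]
    return {"record_duration": rec_dur, "labels": labels,
            "samples_per_record": spr}


def read_recording(path: str | Path) -> Recording:
    """Read an EDF/EDF+ file into a :class:`Recording` (signals in uV).

    All data channels must share one sampling rate; EDF+ annotation channels
    are ignored.  Start clock is taken from the header start time.
    """
    import mne

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    hdr = _peek_header(path)
    rates = {spr / hdr["record_duration"]
             for lab, spr in zip(hdr["labels"], hdr["samples_per_record"])
             if lab != "EDF Annotations"}
    if len(rates) > 1:
        raise ValueError(
            f"{path}: mixed sampling rates across channels: "
            f"{sorted(rates)} Hz; resample upstream")

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    data_uv = raw.get_data() * 1e6  # MNE stores EEG in volts
    meas = raw.info.get("meas_date")
    start_clock = 0.0
    if meas is not None:
        start_clock = meas.hour * 3600.0 + meas.minute * 60.0 + meas.second
    labels = [lab for lab in raw.ch_names]
    return Recording(data_uv, labels, float(raw.info["sfreq"]), start_clock,
                     meta={"source": str(path)})


# --------------------------------------------------------------------------
# Overnight window
# --------------------------------------------------------------------------

def extract_night_window(rec: Recording, params: PipelineParams | None = None
                         ) -> Recording:
    """Crop ``rec`` to the fixed overnight window (default 22:00 -> 05:00).

    The window crosses midnight; the recording is assumed to span a single
    night.  The crop snaps to whole samples (floor on start and on length)
    and is idempotent.  Raises ``ValueError`` when recording and window do
    not overlap.
    """
    params = params or PipelineParams()
    w0 = params.night_start
    w1 = params.night_end if params.night_end > w0 else params.night_end + _DAY

    best = None
    for s0 in (rec.start_clock, rec.start_clock + _DAY):
        s1 = s0 + rec.duration_s
        lo, hi = max(s0, w0), min(s1, w1)
        if hi > lo and (best is None or hi - lo > best[1] - best[0]):
            best = (lo, hi, s0)
    if best is None:
        raise ValueError(
            f"recording ({rec.start_clock:.0f}s + {rec.duration_s:.0f}s) does "
            f"not overlap the night window "
            f"[{params.night_start:.0f}, {params.night_end:.0f}]s")
    lo, hi, s0 = best
    i0 = int(math.floor((lo - s0) * rec.fs))
    n = int(math.floor((hi - lo) * rec.fs))
    out = Recording(rec.signal[:, i0:i0 + n], list(rec.channel_labels),
                    rec.fs, lo % _DAY, dict(rec.meta))
    out.meta["night_window"] = (lo % _DAY, hi % _DAY)
    return out
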